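# Methods

Units throughout: lengths nm, forces pN, energies pN·nm, times s,
concentrations nM. Thermal energy defaults to k_BT = 4.11 pN·nm (298 K),
configurable everywhere through a `Constants` object.

## Polymer elasticity

Two inextensible models cover the two binding modes. A noncooperatively
coated ssDNA stays flexible between bound proteins and is a freely jointed
chain whose rigid link is set by the protein footprint; the Kuhn length is
taken as b = 2p so FJC and WLC persistence lengths are directly
comparable. The cooperative filament is a Marko–Siggia worm-like chain.
Both fits are restricted to low force (FJC ≤ 10 pN, WLC ≤ 5 pN) where
enthalpic backbone stretching is negligible, which is why the inextensible
forms are the default; an optional stretch modulus S adds the (1 + F/S)
factor to the FJC for users who need it. Fits are unweighted least squares
in extension (no per-point uncertainties are assumed), with parameter
uncertainties from the covariance of the fit. The FJC is evaluated with a
series expansion of the Langevin function below u = 10⁻⁴ to avoid
cancellation, and F = 0 returns the exact limit x = 0. The WLC inverse
z(F) uses bracketed Brent root-finding on [0, 1 − 10⁻¹²] at 10⁻¹⁴
tolerance.

Force binning uses left-closed 1-pN intervals [n, n+1) keyed by the lower
edge; per-bin SEMs of extension propagate in quadrature into the
extension-change curve Δx(F) = ⟨x_complex⟩ − ⟨x_bare⟩, reported only on
overlapping bins. A single-sample bin carries SEM 0.

## Kinetic trace decomposition

The binding model is x(t) = x₀ + Σᵢ Δxᵢ(1 − e^(−kᵢt)) with signed
amplitudes: the initial compaction Δx₁ is negative, the two elongations
Δx₂, Δx₃ positive, rates ordered k₁ ≥ k₂ ≥ k₃. The sequential scheme
admits exactly one compaction phase, and compaction precedes elongation.

Noise is estimated robustly as 1.4826·MAD(Δx)/√2 from first differences.
Segmentation smooths with a centered 1-s moving average and finds the
global minimum; the trace is non-monotone (compaction + elongations) when
the minimum lies more than 3 noise SDs below *both* endpoint plateau
levels, each estimated as the median of the first/last 2% of samples —
single smoothed end samples are noise-limited and plateau dips would
otherwise mimic a minimum. A single exponential on the pre-minimum segment
and a two-rate exponential on the post-minimum segment seed a full
three-phase nonlinear least-squares refinement over the entire trace; the
refinement is essential because the slow phases overlap the compaction in
time, and segment fits alone bias amplitudes by the factor e^(−k₂t_min)
(up to ~25% under the canonical conditions below).

Monotone traces are fit with one and two decaying exponentials and
compared by a residual F-test at α = 0.05. A two-phase reading must also
survive three identifiability guards: the rates must differ by ≥ 1.5×
and the slower one must satisfy k·T ≥ 1 over the record length T
(otherwise the extra exponential merely mimics baseline drift); each
phase must contribute a detectable extension change within the record,
|Δx(1 − e^(−kT))| > 3 noise SDs; and the amplitude signs must be
consistent with the sequential taxonomy (not two compactions, and no
elongation faster than the compaction). A lone negative amplitude is Δx₁;
a lone positive amplitude is assigned to Δx₃, the phase that equilibrates
to the final extension.

Dissociation traces are classified among pure linear, single decaying
exponential, and linear + exponential by corrected AIC (k counts fitted
parameters plus the residual variance). Exponential-containing candidates
are dropped when the decay is unresolved within the record (rate·span < 1)
or the amplitude is within 3 noise SDs — an exponential slower than the
record is observationally a straight line. Models within 2 AICc of the
minimum are statistically indistinguishable; the simplest of those is
returned, flagged ambiguous when more than one qualifies. Because the
natural units of the initial linear dissociation rate are ambiguous, both
the raw slope (nm/s) and the slope normalized by the total extension
change (s⁻¹) are reported.

## Rate laws

Bell model: weighted linear regression of ln k on F; Δx = slope·k_BT
(signed), k₀ = e^intercept. The Δx estimate is invariant to rescaling all
rates. Bimolecular law: weighted linear regression of k_obs on c; a
non-positive fitted rate flags the extrapolation as unreliable.
Two-step law k(c) = c·k_b·k_c/(c·k_b + k_c): the minimal sequential form
that rises linearly (slope k_b, the diffusion-limited on-rate) and
saturates at the compaction/oligomerization rate k_c. When the fitted k_c
exceeds 10× the largest observed rate the data lie entirely in the linear
regime and k_c is flagged unbounded.

## Helix geometry

Arc-length conservation per turn, (ρ)² + (2πR)² = (nt/turn · L)², gives
R/ρ = (1/2π)√((L/L′)² − 1); the package asserts this identity to 10⁻⁹ as
a self-consistency check. Two conventions for proteins per turn are
exposed because they answer different questions: the relaxed-filament
convention (nt/turn ÷ reference site size, default 7 nt) describes the
optimally wound low-concentration state, while the axial convention
(pitch ÷ protein axial length h) describes titration sweeps where h stays
fixed at 2.8 nm and the ssDNA footprint shrinks as bss = h/L′. The fully
unwound limit L′ = L is represented by an infinite-pitch sentinel with the
defined limits ratio = 0 and twist = 0 rather than an error. Protein
density is emitted both per nucleotide (1/bss) and per nm of ssDNA contour
(1/(bss·L)), since either normalization is in use. The dsDNA reference
length for the cylinder-volume radius estimate defaults to n_bp·0.34 nm.

## AFM analysis

Traces are resampled to uniform arc steps (default 5 nm, the pixel scale
of typical scans) by linear interpolation; tangents are local segment
directions. The tangent-correlation profile averages cos θ within each
molecule and then equally across molecules (a pooled-pairs weighting is
available), and the 2-D worm-like-chain decay e^(−L/2p) is fit by
unweighted least squares over [0, L_max]. A fitted p above 100·L_max means
the decay was not resolved in the window and is flagged unbounded. For
flexible chains the resample step should be ≲ p/4: chord tangents at steps
comparable to p systematically over-correlate.

Self-contacts are point pairs within the contact radius (default 4 nm,
twice the measured filament radius) separated by more than 4× that radius
along the arc; the longest contiguous run free of contact points is kept.
This segmentation exists for real deposited molecules, whose preserved
solution loops anticorrelate tangents. On ideal generated chains it is
counterproductive: conditioning on contact-free stretches selects
straighter-than-average subchains and overestimates p (≈28 vs 20 nm for
2500-nm chains at p = 20), so synthetic-ensemble estimates use whole
chains.

Integrated volume is Σ max(h − background, 0)·px², with the background
defaulting to the image median (molecules occupy a small area fraction).
The clipped sum has an inherent positive noise bias of
n_pixels·σ·px²/√(2π); at the 0.01-nm height noise of a good scan this is
a few percent of a single 500-nm molecule's volume, and it grows with
scan area — volume work wants low-noise scans or thresholding. Image
skeleton tracing (threshold halfway between background and peak,
skeletonize, nearest-neighbour ordering, pixel-center coordinates) is
provided for synthetic images only.

## Synthetic data

Generators reproduce the functional forms the analysis assumes — not
binding mechanism or thermodynamics — and embed their parameters in the
output metadata for closed-loop recovery tests. Extension noise is
additive Gaussian (optical-trap-like); rate series carry multiplicative
log-normal noise so rates stay positive. Defaults: trace sampling
dt = 0.1 s with 5-nm noise (the visual scatter of a constant-force
recording); force–extension curves ~1 nm; AFM height images 0.01 nm.
2-D chains use i.i.d. Gaussian turning angles of variance step/p, which
makes ⟨cos θ⟩ = e^(−L/2p) exact at the discrete separations; the tip is
modeled as a volume-conserving Gaussian blur, and the injected pre-noise
volume is recorded.

Canonical study conditions used by the tests and analysis scripts (chosen
from the visual scale of the recordings and the fitted rate laws):
triphasic binding at 15 pN/100 nM-like conditions with x₀ = 2800 nm,
amplitudes (−250, +120, +150) nm and rates (0.5, 0.05, 0.005) s⁻¹ over
1200 s at dt = 0.25 s; biphasic elongation omits the compaction;
monophasic compaction is (−180 nm, 0.25 s⁻¹) over 120 s. Dissociation:
linear −0.5 nm/s over 300 s; linear + exponential −0.4 nm/s with 150 nm
at 0.15 s⁻¹; pure exponential 200 nm at 0.11 s⁻¹ over 60 s. Noise is
5 nm, i.e. 2% of the largest amplitude. Under these conditions the
decomposition classifies ≥95% of 100 replicates per regime correctly with
median parameter errors within 10%; ensembles of 50 chains × 2500 nm
recover p within 10% for p ∈ {5, 20, 50} nm.

What passing these tests does and does not show: the generators share the
fitting model's functional form, so recovery tests validate the
estimation machinery (segmentation, model selection, least squares,
identifiability guards) under realistic noise — they cannot detect
model misspecification in real recordings (instrument drift, bead
tracking artifacts, force-feedback transients, non-exponential kinetics),
which is why those corrections are out of scope here.

## Known limitations

- Fits are unweighted unless per-point uncertainties are supplied.
- The FJC deviates from noncooperatively coated ssDNA above ~10–15 pN;
  no model for that regime is provided, matching the fit windows.
- No hysteresis modelling of stretch–release cycles; release curves are
  read in and compared but never jointly fit.
- No hidden-Markov/changepoint inference; force-jump protocols are
  treated as independent constant-force segments.
- General-purpose tracing of experimental AFM images and 3-D tip
  deconvolution are out of scope; the skeleton tracer assumes the clean
  topology of synthetic images.
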