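# Methods

This note documents the models implemented in `kneeus`, the parameters
that matter, what the synthetic phantoms do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Cartilage enhancement

The enhancement is a signed phase-symmetry measure over a 2D Log-Gabor
quadrature bank. Each transfer is the product of a log-radial Gaussian
`exp(-(log(ω/ω0))² / (2 log²κ))` and a single-sided angular Gaussian
`exp(-Δφ²/(2σ_φ²))`; because the angular term is centered on the
orientation *vector* (angle differences computed through sin/cos, no 2π
seam), the inverse transform of `spectrum × transfer` is the analytic
signal: its real part is the even response, its imaginary part the odd
response. Defaults: 2 scales with minimum wavelength 25 px and multiplier
1.55, 6 orientations, radial bandwidth ratio κ = 0.25 (≈ two octaves),
angular spread σ_φ = Δφ/1.2.

Per orientation, a noise floor T_r is estimated from the smallest-scale
local energy: speckle amplitude is modelled as Rayleigh, its scale fitted
robustly from the median (`σ = median/√(2 ln 2)`), and
`T_r = σ(√(π/2) + m·√(2 − π/2))` with m = 3 standard deviations. The
numerator accumulates `max(0, (e − o) − T_r)` — signed responses, no
absolute values, floored at zero — and the denominator is the total local
energy `Σ √(e² + o²) + ε`. Two readings of the printed formula were
resolved as design choices: the numerator bracket is soft-thresholded at
zero (without the floor the map is dominated by large negative values),
and the denominator is the local energy `√(e² + o²)` (the difference
`e² − o²` can be negative under a square root). The result is clipped to
[0, 1] and min-max rescaled. Numerator and T_r both scale linearly with
global intensity, so the map is gain-invariant up to the ε term — measured
mean absolute change < 2·10⁻⁶ for gain factors 0.5 and 2.

## Bone-selective phase features

The enhanced map is band-passed (isotropic ASSD transfer, below) and
multiplied by a normalized depth ramp `(row/(NR−1))^p` with p = 2 — zero
at the transducer face, one at the bottom — so shallow soft-tissue lines
are suppressed relative to the deeper bone. The local-phase tensor is
computed from Gaussian-presmoothed (σ = 1 px) derivatives:
`T_even = trace(H Hᵀ) = U_xx² + 2U_xy² + U_yy²` and
`T_odd = −(∇U · ∇(∇²U))`, with instantaneous phase `φ = atan2(T_odd,
T_even)` and `LPT = max(0, √(T_even² + T_odd²)·cos φ)`. Both responses
are quadratic in the input, so LPT scales as the square of intensity and
φ is scale-invariant.

The monogenic triple band-passes LPT with the α-scale-space-derivative
transfer `H(ω) ∝ ω·exp(−t ω^{2α})` (α = 1.5; two scales with peaks at
wavelengths 25 and 38.75 px, matching the Log-Gabor series) and applies
the Riesz pair `(i u₁/|u|, i u₂/|u|)`. Local-phase energy is
`Σ_sc |USM₁| − √(USM₂² + USM₃²)`, floored at zero; the weighted mean
phase angle is `arctan2(Σ USM₁, √(Σ USM₂² + Σ USM₃²))` remapped to
[0, 1]. Both Riesz components enter the LwPA denominator — the
orientation-independent form — and the arctan2 formulation makes the
measure exactly invariant to positive rescaling without an ε guard. The
final bone image LP is the product of the three maps, each min-max
normalized first.

FFT filtering in this chain pads by 32 px: plain reflection along depth,
odd reflection laterally. Periodic wrap-around otherwise leaks the bright
near-transducer rows into the depth-weighted bottom rows, and plain
lateral reflection mirrors the sloped bone curve into a spurious V-ridge
that biases the edge columns by 3–4 px (odd reflection continues the
slope; edge-column accuracy improves from 89% to 97% within 2 px).

## Bone-shadow model

The confidence map solves the random-walk Dirichlet problem on an
8-connected lattice: top row fixed to 1, bottom row to 0, node attribute
`c = LP^{1/3} · exp(−η·depth)` with η = 2, and edge weights
`exp(−β(|c_i − c_j| + penalty))` with β = 90 and penalty 0 / γ / γ√2 for
vertical / horizontal / diagonal steps (γ = 0.03). The cube-root
compression of LP matters: LP is a product of squared-derivative maps
whose ridge values span decades across columns, and without compression
typical columns present no barrier to the walk at all (no shadow edge
forms; with it, the steepest per-column drop of the shadow image falls
within 3 px of the bone surface in > 90% of columns on clean phantoms).

The transmission map minimizes
`λ/2‖U − CM‖² + Σ_j ‖W_j ∘ (D_j ∗ U)‖₁` with λ = 2, first-difference
kernels D_j and weights `W_j = exp(−|D_j ∗ CM|²)`. The ℓ1 term is
majorized once by `W_j (D_j U)² / (|D_j CM| + ε_s)` with ε_s = 10⁻³,
giving a single sparse SPD solve — deterministic and exact to solver
precision; more majorization sweeps are possible but one suffices at
these scales. The shadow image inverts the scattering/attenuation
composition with ρ = 0.9·max(CM) and δ = 1; with transmission above the
ε = 10⁻⁴ floor, `US_A·BSE + (1 − US_A)·ρ` reproduces CM to machine
precision. The raw inversion saturates far below zero where transmission
bottoms out in deep shadow, so the map handed downstream is min-max
normalized after clipping to the 1st–99th percentile range; the identity
above is always checked on the unclipped values.

## Bone localization

The internal-energy probability is `minmax(LP ⊙ BSE)^{1/3}`; the cube
root evens the dynamic range across columns (argmax positions are
unchanged) so that the fixed region thresholds are meaningful: bone at
probability ≥ 0.55, boneless at ≤ 0.25, jump between. The DP data term is
`255·(1 − probability)` — the energy weights below were calibrated
against 8-bit intensities, and on a [0, 1] data term a single 1-row step
(cost ν = 50) would exceed the entire data range.

External energy per path step ending at column s: bone region
`ν(ΔBL)² + ξ(Δ²BL)² − ς` with ν = 50, ξ = 100 and connectivity reward
ς = 0.15 (stored positive, subtracted); jump region flat 0.8; boneless
region `νD₁² + ξD₂²` = 150 with D₁ = D₂ = 1. The minimization is an
exact second-order dynamic program over (row, previous-row) states, so
the three-point curvature term is handled without approximation and the
returned path is provably optimal for the stated cost — verified against
exhaustive path enumeration with exact floating-point equality on small
grids. Transitions are windowed to ±10 rows per column (full-window mode
exists for the oracle tests); ties break toward the smaller current row,
then the smaller predecessor row. Columns whose optimal pixel lies in the
boneless region are reported as "not found" (sentinel = number of rows,
i.e. one past the last valid index; written as −1 in CSV exports).

## Seeding and segmentation

Foreground seeds translate the localized surface up by
round((MKT/2)/Δ) = 7 px and background seeds by round((2·MKT)/Δ) = 29 px
up and down (MKT = 2.16 mm from cadaver morphometry, Δ = 0.15 mm/px).
Seed polylines are dilated by 1 px. By default the surface is linearly
interpolated across not-found columns before translation — cartilage is
laterally continuous, and a seed gap lets the boundary-only min-cut sever
the band (worst-case Dice drops from ~0.8 to 0.3 without bridging);
`bridge_gaps=False` restores strict per-column seeding.

The random walker builds 4-connected edge weights
`exp(−β(g_i − g_j)²/max(g − g)²)` with β = 130 (a standard literature
default; the source text does not print its value) and solves the
combinatorial Dirichlet problem for the foreground probability; γ > 0
optionally blends a uniform prior through a regularized system, default
γ = 0 (no priors). The watershed backend floods the Sobel gradient
magnitude from the imposed markers (scikit-image implementation). The
graph-cut backend is a boundary-only model: n-links
`exp(−(g_i − g_j)²/(2σ²))` with σ = 0.1, hard terminal links at seeds,
zero regional terms elsewhere; capacities are scaled by 10⁴ and rounded
to integers for the max-flow solver, and the mask is the residual-graph
source side. Post-processing clips the mask to rows strictly above the
localized surface, closes 3×3 gaps, and keeps the largest 4-connected
component; an empty result is reported as "no cartilage found" rather
than an error.

## Thickness and evaluation

The mask boundary is split per column into a deep (bone-side) and a
shallow (synovial-side) chain; the Euclidean distance transform seeded on
the deep chain is sampled along the shallow chain, corrected by +1 px for
the two half-pixel chain discretizations, and averaged in mm. The
rectangle band case is exact (a 14-px band at 0.15 mm/px measures
2.10 mm); a constant-thickness curved band and 15°-rotated bands agree
within one pixel spacing; measuring the generating masks of a 20-phantom
suite recovers thickness with ≤ 0.17 mm mean absolute error. Overlap is
scored by Dice, precision, recall and F-score on pixel counts (two empty
masks score 1 and are flagged degenerate), and agreement by Bland–Altman
mean difference ± 1.96·SD limits.

## Synthetic phantoms: what they emulate

The generator renders the transverse suprapatellar view at 0.15 mm/px on
a 160×120 grid (24 mm depth — deep enough for bone at 12–17 mm plus
shadow): speckled soft tissue; 0–3 wavy hyperechoic fascia layers; a
specular synovial interface echo (brightness 0.85) at the top of a
hypoechoic cartilage band of known thickness (default drawn from the
1.69–2.55 mm healthy range); a bright parabolic bone ridge (Gaussian
cross-section, σ = 2 px, peak 0.95); multiplicative shadow below
(factor 0.15); a smooth lateral contrast-degradation field (worst column
70% contrast) emulating transducer misalignment; unit-mean Rayleigh
speckle blended at weight 0.5 (0 = noise-free, 1 = fully developed); and
a 1-px Gaussian PSF blur. Ground truth (sub-pixel bone curve, rasterized
cartilage mask, generating thickness) is exact by construction.

What the phantom does **not** emulate: curved-array geometry, refraction
and reverberation artefacts, heterogeneous in-plane anatomy, TGC curves
and focal-zone banding, or pathological (thinned, broken) cartilage.
Consequently, passing phantom tests demonstrates that each stage does
what its model claims under controlled conditions — not clinical-grade
performance. One documented consequence: on these phantoms the raw
B-mode image is an honest competitor to the enhanced image for seeded
segmentation (the band boundary is the strongest intensity barrier by
construction), so the clinically observed gap between enhanced-input and
raw-input segmentation does not reproduce at this scale.

## Problem sizes and runtime

Default analyses use 20-phantom suites at 160×120; the full pipeline runs
in ~1 s per frame on one CPU (sparse direct solves for the confidence,
transmission and random-walker systems; the DP is O(NR·NC·W²) with
W = 10). Exhaustive DP oracles run on grids up to 5×6 where enumeration
(≤ 5⁶ paths) is exact and fast.
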