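# kneeus

Fully automatic knee-cartilage enhancement, segmentation and thickness
measurement from 2D B-mode ultrasound.

Ultrasound is an inexpensive, real-time alternative to MRI for monitoring
femoral cartilage in knee osteoarthritis, but B-mode scans are hard to
analyse automatically: speckle, low contrast and shadowing defeat plain
intensity thresholds, and manual thickness measurement is operator
dependent. `kneeus` implements a local-phase processing pipeline that takes
a single B-mode frame (rows = depth, columns = scan lines) to a cartilage
mask and a mean-thickness estimate with no user interaction:

1. **Cartilage enhancement** — a Log-Gabor quadrature bank yields even/odd
   responses e_rs, o_rs per scale and orientation; the enhanced image is
   the signed phase-symmetry measure

   USE = Σ_r Σ_s ⌊(e_rs − o_rs) − T_r⌋₊ / (Σ_r Σ_s √(e_rs² + o_rs²) + ε),

   with T_r a per-orientation Rayleigh noise floor. Both numerator and
   T_r scale linearly with intensity, so USE is invariant to gain.
2. **Bone-selective phase features** — a depth-weighted band-passed map
   feeds the local-phase tensor LPT (Hessian/gradient tensor responses),
   and its monogenic signal (ASSD band-pass + Riesz transform) gives the
   local-phase energy LPE and weighted mean phase angle LwPA; their
   product LP = LPT·LPE·LwPA is high only on the bone surface.
3. **Bone-shadow modelling** — a random-walk confidence map CM of LP
   (transducer row fixed to 1, bottom row to 0) is fitted by an
   edge-preserving transmission map US_A, and the shadow image is the
   inversion BSE = (CM − ρ)/max(US_A, ε)^δ + ρ of the composition
   CM = US_A·BSE + (1 − US_A)·ρ.
4. **Dynamic-programming localization** — the probability map LP⊙BSE is
   split into bone / jump / boneless regions; an exact DP over
   (row, previous-row) states minimizes internal energy plus the external
   energy ν‖dBL/ds‖² + ξ‖d²BL/ds²‖² − ς (bone), Jump_cost (jump),
   νD₁² + ξD₂² (boneless), giving one bone row per column BL(s).
5. **Seeded segmentation** — BL is translated by the mean knee-cartilage
   thickness prior (MKT = 2.16 mm): foreground seeds MKT/2 above the bone,
   background seeds 2·MKT above and below. Three interchangeable backends
   segment the enhanced image: a random walker (Dirichlet problem with
   edge weights w_ij = exp(−β(g_i − g_j)²)), a marker-controlled watershed
   of the gradient relief, and an s–t min-cut with hard seed terminals.
6. **Thickness** — the Euclidean distance transform seeded on the deep
   (bone-side) mask boundary is averaged along the shallow (synovial)
   boundary and converted to mm.

Because no clinical scans ship with the package, a first-class phantom
module renders synthetic knee frames — speckled soft tissue, hyperechoic
fascia layers, a synovial interface echo, a hypoechoic cartilage band of
known thickness, a bright parabolic bone ridge, an acoustic shadow and a
lateral misalignment field — with exact ground truth for every stage.

## Worked example

```python
from kneeus import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline
from kneeus.thickness import overlap_metrics

image, truth = generate_phantom(PhantomSpec(rng_seed=7))
result = run_pipeline(image, PipelineConfig(backend="rw"))
dsc = overlap_metrics(result.segmentation.mask, truth.cartilage_mask).dsc
print(f"DSC {dsc:.3f}  thickness {result.thickness.mean_mm:.2f} mm "
      f"(truth {truth.thickness_mm:.2f} mm)")
```

prints

```
DSC 0.792  thickness 1.97 mm (truth 2.16 mm)
```

i.e. the automatic mask overlaps the generating cartilage band with Dice
0.79 on this (deliberately degraded) phantom and recovers its thickness to
0.19 mm. `examples/` contains short scripts for each capability:
phantom simulation, enhancement + localization, per-backend segmentation,
and Bland–Altman agreement analysis.

A thin CLI mirrors the stages:

```
kneeus simulate --n 5 --seed 3 --out-dir sim/
kneeus enhance sim/phantom_000.png use.png
kneeus localize sim/phantom_000.png --out surface.csv
kneeus segment sim/phantom_000.png --backend rw --out mask.png
kneeus thickness mask.png --out thickness.json
kneeus evaluate mask.png sim/truth_000.png --out metrics.json
```

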