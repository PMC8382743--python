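# memic

Image cytometry, spatial statistics and gradient modelling for one-opening
metabolic-gradient culture chambers.

Cells cultured in a chamber that exchanges medium with a reservoir through a
single narrow opening consume oxygen and nutrients faster than diffusion
resupplies them. The result is a stable, reproducible ischemic gradient
along the chamber axis: well-nurtured cells near the opening, nutrient- and
oxygen-starved cells at the far end. Such devices turn "distance from the
opening" into a controlled metabolic variable, and experiments read it out
with tiled fluorescence microscopy — a uniform nuclear stain plus reporter
channels, one stitched 16-bit TIFF per channel.

This package is the computational side of that experiment, for biologists
and image analysts working with gradient-chamber (or any
position-resolved) fluorescence data:

- **`memic.cytometry`** — nucleus detection (Gaussian smoothing + Otsu),
  watershed splitting of touching nuclei, Voronoi-constrained cell
  territories, and per-cell position/area/intensity measurement.
- **`memic.profiling`** — distance from the opening edge, per-cell channel
  normalization, moving-median ± interquartile profiles, binned positive
  fractions, and the half-max position: the distance x at which a profile
  first reaches min + ½(max − min), the summary statistic for gradient
  position.
- **`memic.stats`** — the comparison procedures: two-sided Wilcoxon
  rank-sum on the n nearest vs n farthest cells, one-way ANOVA on replicate
  half-max positions, per-bin Student's t-tests against the first bin, and
  a "high expressor" classifier (value > 2 × control median).
- **`memic.simulate`** — a 1D diffusion–consumption model,
  ∂c/∂t = D∂²c/∂x² − (ρq/h)·u(c) with c(0) = c₀ and a sealed far wall,
  plus a threshold-type (Hill) hypoxia-reporter response. For zeroth-order
  uptake the steady state is c(x) = c₀ − (ρq/2Dh)·x(2x* − x) with anoxic
  front x* = √(2Dhc₀/ρq), which is what makes cell density ρ and chamber
  height h the decisive parameters — and the opening width a provable
  no-op.
- **`memic.synthetic`** — ground-truth-annotated synthetic chamber images
  (disk nuclei, gradient-driven reporters, Gaussian/Poisson noise, 16-bit
  quantization), so every stage above is benchmarked without any external
  data.

## Worked example

Generate a synthetic chamber with a logistic hypoxia-reporter gradient
centred 800 µm from the opening, run the full pipeline, and recover the
gradient position:

```python
import numpy as np
from memic import *

params = SceneParams(
    field_width=2000, field_height=1000, n_cells=1200,
    noise_sd=380.0, min_center_spacing=15.0,
    reporter_functions={"gfp": lambda x: 200 + 1800 / (1 + np.exp(-(x - 800) / 120))},
    rng_seed=42,
)
scene = generate_scene(params)
labels = detect_nuclei(scene.images["hoechst"])
table = measure_cells(labels, list(scene.images.values()))
table = assign_distance(table, OpeningSpec("left", 0.0))
profile = moving_profile(table, "gfp_mean", window_width=100, step=25, min_cells=20)

print(f"detected cells : {labels.max()}")
print(f"half-max       : {half_max_position(profile):.1f} um (generator midpoint 800 um)")
res = proximal_distal_test(table, "gfp_mean", n_each=300)
print(f"rank-sum       : U = {res.statistic:.0f}, p = {res.p_value:.3g}")

sweep = predict_effects(ChamberSpec(), "medium_height", [50, 100, 200])
print("height sweep   :", [f"{h:.0f} um" for h in sweep.half_max_um])
```

which prints:

```
detected cells : 1200
half-max       : 812.0 um (generator midpoint 800 um)
rank-sum       : U = 0, p = 1.05e-99
height sweep   : ['967 um', '1368 um', '1934 um']
```

All 1200 ground-truth nuclei are found; the recovered half-max (812 µm) sits
within one window step of the generator's 800 µm midpoint; the 300
opening-proximal cells differ overwhelmingly from the 300 most distal ones
(every proximal value below every distal value gives U = 0); and doubling
the chamber height moves the simulated gradient away from the opening by
√2, as the closed form predicts.

The same operations are available from a shell:

```sh
memic synth --out scene --n-cells 500 --seed 1 --noise-sd 380
memic segment --nuclear scene/hoechst.tif --channel gfp=scene/gfp.tif --out seg
memic profile --table seg/cells.csv --value gfp --out profile.csv
memic stats proximal-distal --table seg/cells.csv --value gfp --n 100
memic simulate --sweep medium_height=50,100,200,400 --out sim
```

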