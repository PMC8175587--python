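# retroughness

Roughness analysis of retinal layers from macular OCT: per-layer thickness
maps with tilt correction, spatial normalization to a canonical macular
frame, grayscale box-counting fractal dimension (FD) as the roughness
index, and the cohort statistics used to evaluate layer roughness as an
early Alzheimer's disease (AD) biomarker.

## Scientific background

In early AD, thinned and thickened regions coexist within most retinal
layers. Rather than tracking mean thickness, this package quantifies the
*topographic complexity* that interspersed lesions create on each layer's
en-face thickness map. A thickness map treated as a grayscale relief has a
fractal dimension FD in [2, 3]: FD = 2 for a perfectly smooth map, larger
values for rougher maps. The estimator is differential box counting: at
spatial box size *s* the M x M map is partitioned into *s* x *s* blocks, a
column of boxes of height *h = s G / M* (G = 256 gray levels) is stacked
over each block, the local count is

```
n_r = floor(max / h) - floor(min / h) + 1,
```

and FD is the slope of the least-squares regression of ln N_r (total count)
on the log reciprocal scale. Both the classic and the integer-ratio border
conventions are implemented, with two thickness codings (native depth
units and min-max 8-bit), so that group conclusions can be shown to be
robust to these choices.

Downstream statistics mirror a clinical case-control design: exact
Mann-Whitney rank-sum comparison of per-subject mean FD, paired t across
the per-layer group means, one-sided Pearson correlations of layer FD with
cognitive score (MMSE), visual acuity and age, and a two-factor
maximum-likelihood factor analysis (varimax rotation; KMO, Bartlett and
correlation-determinant diagnostics) of the 10 layer FDs.

A synthetic-cohort generator stands in for clinical data: layered macular
anatomy with a foveal pit, fractional Brownian roughness with controllable
Hurst exponent (theoretical surface FD = 3 - H), a latent two-block factor
structure, a group roughness effect, and covariates linked to roughness
with fixed signs. It is intended for estimator validation, calibration
studies and power simulation.

## Worked example

Run the full pipeline on the default synthetic study design (19 simulated
AD eyes vs 24 controls, 512 x 128 scans, 11 surfaces each):

```
$ retroughness run --out demo_run --seed 1
mean FD: AD 2.1165 vs CTL 2.1090; rank sum W = 488, one-sided p = 0.045
results written to demo_run
```

The per-subject mean FD over the 10 layers is higher in the simulated
disease arm, and the one-sided exact Mann-Whitney test (rank sum W of the
AD sample) rejects at alpha = 0.05. `demo_run/` contains the per-layer FD
table (`fd_table.csv`), the group statistics and correlation matrices
(JSON), the fitted two-factor model and a manifest with per-subject
timings and exclusion accounting.

The same machinery is available as a library:

```python
from retroughness.fd import fractal_dimension, BoxCountingConfig
from retroughness.synthetic import generate_fbm_field

f = generate_fbm_field(0.5, 218, 218, (11.7, 11.7), seed=7)   # unit-RMS fBm
res = fractal_dimension(f * 24 + 80, BoxCountingConfig())      # um relief
print(f"FD = {res.fd:.4f}, R^2 = {res.r_squared:.4f}")
# FD = 2.2042, R^2 = 0.9963
```

Reading real data: per-subject surface stacks are stored in an HDF5
container (`retroughness.surfaces_io.read_stack` / `write_stack`, with a
CSV export for inspection), and `read_figshare_thickness` is an adapter
stub for a publicly deposited per-layer thickness dataset.

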