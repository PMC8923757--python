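# ultrabeam

Adaptive ultrasound beamforming toolkit: RF channel-data simulation for
linear arrays, delay-and-sum and Capon-family adaptive beamformers, B-mode
image formation, and image-quality metrics.

The centrepiece is an improved Capon beamformer (`ISCB`) that combines three
robustness ingredients before the classic minimum-variance weighting:

1. **Forward-backward (Toeplitz) covariance correction** — `F' = F + K·conj(F)·K`
   with `K` the anti-diagonal exchange matrix, decorrelating coherent sources
   and enforcing persymmetry (`covariance.forward_backward_correct`).
2. **Eigen-subspace split** — eigenvalues of `F'` at or above 0.5× the largest
   eigenvalue span the signal subspace (`adaptive_beamformers.eigendecompose_subspace`).
3. **Quadratically constrained steering correction** — minimise the steering
   vector's energy in the signal subspace subject to `‖λ − λ̄‖² ≤ τ`, solved
   via a Lagrange multiplier found by bisection on the monotone constraint
   residual (`adaptive_beamformers.correct_steering_vector`).

Standard Capon (`SCB`), recursive-least-squares (`RLS`) and sequential
regression (`SER`) beamformers are included as baselines, plus plain
delay-and-sum (`DAS`).

## Library quick start

```python
import numpy as np
import ultrabeam as ub

geom = ub.make_linear_array(64, 0.154, 5e6, 40e6)          # 64 el @ 5 MHz
pulse = ub.Pulse(5e6, fractional_bandwidth=0.6)
phantom = ub.make_cyst_phantom((0, 20), 2.0, ((-6, 6), (14, 26)),
                               speckle_density=3.0, seed=0)
data = ub.simulate_channel_data(geom, phantom, pulse, noise_db=-30, seed=0)

grid = ub.ImageGrid(np.linspace(-5, 5, 41), np.linspace(16, 24, 33))
img = ub.beamform_image(data, grid, "ISCB")
ub.render_png(img.bmode_db, "cyst.png", dynamic_range=60)

center = ub.RegionSpec((0, 20), radius_mm=1.4, label="center")
bg = ub.RegionSpec((3.75, 20), half_extents_mm=(0.75, 1.4), label="background")
print(ub.contrast_db(img, center, bg))
```

## Command line

```sh
ultrabeam simulate  --config run.yaml --out data.h5
ultrabeam beamform  data.h5 --method ISCB --config run.yaml \
                    --out-png img.png --out-h5 img.h5
ultrabeam metrics   img.h5 --config run.yaml --out metrics.csv
ultrabeam benchmark --config run.yaml --out report.csv
ultrabeam render    img.h5 --out img.png --colormap gray
```

Configuration is YAML, strictly validated (unknown keys are rejected and all
errors are reported at once); every block has documented defaults, and each
written artifact gets a `<file>.json` sidecar echoing the fully resolved
configuration, package version and seed so the run can be reproduced exactly.
Individual entries can be overridden with `--set`, e.g.
`--set geometry.num_elements=32 --set beamformer.method=SCB`.

Example `run.yaml`:

```yaml
geometry: {num_elements: 64, pitch_mm: 0.154, center_frequency: 5.0e6,
           sampling_frequency: 40.0e6}
phantom:  {cyst_center_mm: [0.0, 20.0], cyst_radius_mm: 2.0,
           field_extent_mm: [[-6.0, 6.0], [14.0, 26.0]], speckle_density: 3.0}
beamformer: {method: ISCB}
grid:     {x_mm: [-5.0, 5.0, 41], z_mm: [16.0, 24.0, 33]}
noise_db: -30.0
seed: 0
```

## Channel-data HDF5 contract

Third-party channel data can be converted into the container read by
`ultrabeam.io.load_channel_data`:

```
/samples                       (elements × time) float or complex matrix
/samples@sampling_frequency    Hz
/samples@time_origin           seconds (time of sample 0)
/geometry@num_elements, pitch_mm, center_frequency,
          sampling_frequency, sound_speed
```

Element `m` sits at lateral position `x_m = (m − (M−1)/2) · pitch` on `z = 0`;
depths are positive below the array.

## Metrics conventions

- Regional power: `10·log10` of the mean squared envelope, referenced to the
  image's global peak.
- Contrast (anechoic cyst): absolute dB difference between background and
  cyst-interior region power — larger is better.
- Resolution: −6 dB lateral full width (mm) of a wire-target profile —
  smaller is better.
- Peak sidelobe: highest secondary maximum of a lateral profile, dB below
  the peak (`−inf` when absent).

`ultrabeam.metrics.benchmark_report` scores any subset of the five methods on
a standardized phantom suite (anechoic cyst in speckle with a bright off-axis
wire, plus an isolated wire for resolution) over multiple seeds and returns a
per-seed table with per-method median summary rows.

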