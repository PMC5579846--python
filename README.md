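# oitkit

Orientation-invariant transformations for wearable motion sensors, with a
complete activity-recognition evaluation pipeline.

## The problem

Window-based human-activity recognition from body-worn inertial units
(tri-axial accelerometer, gyroscope, magnetometer) normally assumes every
unit is mounted at a fixed, known orientation. In practice users strap
sensors on at arbitrary orientations, and a classifier trained on
correctly mounted data degrades badly: an unknown mounting rotation `R`
turns every measured 3-vector `v[n]` into `R v[n]`, scrambling all
per-axis statistics. `oitkit` implements two transformations that map a
tri-axial segment `V = [v[0] … v[N]]` (3×N) to sequences that are
unchanged by any fixed proper rotation of the sensor, so any downstream
time-series classifier becomes orientation-invariant for free.

**Heuristic OIT** (3×L → 9×(L−4)): with `Δv[n] = v[n+1] − v[n]` and
`ΔΔv[n] = Δv[n+1] − Δv[n]`,

```
w1 = ‖v‖       w4 = ∠(v[n], v[n+1])      w7 = ∠(p[n], p[n+1]),  p[n] = v[n] × v[n+1]
w2 = ‖Δv‖      w5 = ∠(Δv[n], Δv[n+1])    w8 = ∠(q[n], q[n+1]),  q[n] = Δv[n] × Δv[n+1]
w3 = ‖ΔΔv‖     w6 = ∠(ΔΔv[n], ΔΔv[n+1])  w9 = ∠(r[n], r[n+1]),  r[n] = ΔΔv[n] × ΔΔv[n+1]
```

Norms and mutual angles survive a common rotation, and the rotation axes
p, q, r co-rotate with the data, so all nine channels are exactly
invariant. Truncations to the first 3 or 6 channels, and the per-sample
Euclidean norm `w1` alone, are also provided.

**SVD-based OIT** (3×N → 3×N): from the compact SVD `V = U Σ Wᵀ`, the
transform keeps `Σ Wᵀ = Uᵀ V` — the segment re-expressed in its own
principal axes — and discards the absolute-orientation factor `U`.
Rotating the sensor maps `U → R U` and leaves `Σ Wᵀ` unchanged up to row
signs, which are canonicalized deterministically. All sensor types of one
unit share a single joint transform after per-type unit-variance scaling.

Around the transforms the package ships the full evaluation pipeline:
random-rotation simulation from uniform Euler angles, windowing, a
per-channel feature set (min, max, mean, skewness, kurtosis, a thinned
autocorrelation sequence, the five largest DFT peaks with frequencies),
per-subject [0, 1] normalization, PCA to M = 30 dimensions, four
classifiers (Gaussian MAP, k-NN with k = 7, RBF-SVM with C = 40 and
γ = 0.2, a single-hidden-layer back-propagation network), and both
10-fold and leave-one-subject-out cross-validation. A seeded synthetic
generator emulates labelled multi-subject, multi-unit recordings so the
whole pipeline is testable without any data download.

## Worked example

Compare the reference condition, randomly rotated sensors, and the
SVD-based transform on the default synthetic benchmark (5 subjects ×
6 activities × 2 units, 25 Hz, 60 s recordings, 360 five-second
segments):

```python
import oitkit as ok

dataset = ok.generate_dataset(ok.SynthConfig(seed=0))
results = []
for case in ("reference", "random_rotation", "svd"):
    cfg = ok.PipelineConfig(case=case, seed=0)
    results.append(ok.run_case(dataset, cfg, classifier="knn", scheme="pfold"))
print(ok.summarize(results).to_string(index=False))
```

prints

```
           case classifier scheme  mean_accuracy  band_low  band_high  delta_vs_reference
      reference        knn  pfold       1.000000  1.000000   1.000000            0.000000
random_rotation        knn  pfold       0.791667  0.623464   0.959869           -0.208333
            svd        knn  pfold       1.000000  1.000000   1.000000            0.000000
```

Reading: with fixed mounting, 10-fold k-NN classifies every test segment
correctly. Rotating each (segment, unit) pair by an independent random
rotation — the arbitrary-mounting scenario — costs 20.8 accuracy points,
because the activity pairs of this benchmark are only distinguishable
through cross-axis structure that rotation scrambles. Applying the
SVD-based transform first restores the reference accuracy exactly: its
output is provably identical whether or not the sensors were rotated.
`band_low`/`band_high` are the mean ± 2 standard deviations over the ten
folds.

The same experiments run from the shell:

```sh
oitkit synth --out data/ --seed 0
oitkit eval --data data/manifest.yaml --case svd --classifier knn \
            --cv pfold --seed 0 --report svd.json
oitkit report svd.json --out summary.csv
```

## Layout

```
src/oitkit/core.py        dataset types, manifest I/O, windowing, gravity high-pass
src/oitkit/rotation.py    Euler-angle rotations, per-unit segment rotation
src/oitkit/heuristic.py   9-channel heuristic OIT, norm transform, truncations
src/oitkit/svd.py         SVD-based OIT, per-sensor-type scaling
src/oitkit/features.py    feature extraction, per-subject normalization, PCA
src/oitkit/classifiers.py Gaussian MAP, k-NN, RBF-SVM, back-propagation MLP
src/oitkit/evaluation.py  five cases, P-fold and leave-one-subject-out CV
src/oitkit/synth.py       seeded synthetic recording generator
src/oitkit/cli.py         `oitkit` command-line interface
```

See `docs/methods.md` for the modelling choices, parameter defaults, and
known limitations.
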