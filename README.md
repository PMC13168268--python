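# hdflow

Label-free, event-driven flow-cytometry classification with binary
hyperdimensional computing (HDC), plus a synthetic optics/event-sensor
simulator for end-to-end testing.

## The problem

In label-free imaging flow cytometry, a coherent beam (632.8 nm He–Ne)
illuminates microparticles flowing through a microfluidic channel; each
particle's diffraction/interference pattern is recorded by an event-based
camera (dynamic vision sensor, 640×480 pixels, 10.56 µm pitch). The sensor
emits an asynchronous stream of `(t, x, y, p)` events — a microsecond
timestamp, a pixel, and a polarity (+1 brightening, −1 dimming) — only
where brightness changes, so a particle transit produces a sparse,
low-latency signature instead of a frame sequence. The task is to classify
particles by size (e.g. polystyrene beads of 9/12/16/20 µm, classes A–D)
from these event signatures, optionally with a ground-glass diffuser in the
optical path that broadens and enriches the patterns.

`hdflow` implements the full post-processing pipeline:

1. **Event data** (`hdflow.events`) — event-stream containers, CSV and HDF5
   I/O, activity-based transit segmentation, per-polarity frame
   accumulation, binarization (presence/absence per pixel), OR-pooled
   down-sampling, and polarity split/merge into a flat binary feature.
2. **HDC core** (`hdflow.hdc`) — binary hypervectors of dimension `D`.
   Training bundles the encoded vectors of each class `l` by bitwise
   majority voting into a prototype

   `P_l = majority(V_1^l, …, V_{N_s}^l)`,

   a single pass with no gradient optimisation. A query `V_q` is scored by
   Hamming distance `Ham(A, B) = Σ_j A_j ⊕ B_j` and assigned to
   `l* = argmin_l Ham(P_l, V_q)`. Uncorrelated hypervectors sit at ≈ 0.5·D,
   so distances well below that carry signal.
3. **Evaluation** (`hdflow.evaluation`) — session-aware protocols.
   Acquisition drifts between measurement sessions (source intensity, beam
   alignment); when each class is recorded in its own run, drift correlates
   with labels and inflates accuracy (*measurement bias*). The
   `single_session` protocol trains and tests inside one session; the
   `intertwined` protocol trains and tests on disjoint sessions
   (leave-one-session-out by default) so the session signature cannot leak.
   Also: confusion matrices, the polarity ablation (split vs merged maps)
   and the feature-dimension sweep.
4. **Simulator** (`hdflow.simulate`) — Airy-type interference patterns with
   first-ring radius ∝ 1/diameter, translating vertically to model flow; a
   ground-glass diffuser as envelope blur (coarser grit → wider) plus a
   fixed seeded speckle field; a per-pixel log-intensity contrast-threshold
   DVS model with interpolated timestamps and Poisson background noise; and
   per-session drift (gain, offset, beam-centre jitter) that can be drawn
   per (class, session) to reproduce measurement bias. Fully deterministic
   from one master seed.
5. **CLI** (`hdflow.cli`) — `hdflow simulate|train|evaluate|ablate-polarity|
   sweep-dims|compare-diffusers`.

## Worked example

Simulate a reduced-scale study (128×96 sensor, 4 classes × 6 sessions × 10
transits), then evaluate with the bias-aware protocol:

```python
from hdflow import simulate as sim, evaluation as evl

cfg = sim.SimulationConfig.reduced(master_seed=42, samples_per_class_session=10)
ds = sim.simulate_session_dataset(cfg)

fc = evl.FeatureConfig(block=(4, 4), polarity_mode="split")
acc, per_session = evl.leave_one_session_out(ds, fc)
print(f"leave-one-session-out accuracy: {acc:.4f}")

spec = evl.SplitSpec(mode="intertwined",
                     train_sessions=frozenset({1, 2, 3, 4, 5}),
                     test_sessions=frozenset({6}))
train, test = evl.split_intertwined(ds, spec)
model = evl.fit(train, fc)
cm = evl.evaluate(model, test, fc)
print(cm.to_frame())
```

This prints:

```
leave-one-session-out accuracy: 0.9167
    A   B   C   D
A  10   0   0   0
B   0  10   0   0
C   0   0  10   0
D   0   0   0  10
```

The mean intertwined accuracy (0.9167) is below the within-session ceiling
because each (class, session) block carries its own drift realisation —
exactly the measurement-bias effect the intertwined protocol is designed to
expose. The confusion matrix rows are true classes, columns predictions;
row sums equal the per-class test counts.

The same pipeline from the shell:

```sh
hdflow simulate --config sim.ini --out data/
hdflow train --data data/ --model model.npz --block 4x4 --sessions 1,2,3,4,5
hdflow evaluate --data data/ --model model.npz --block 4x4 --sessions 6 --out results/
```

## Scope notes

Experimental recordings of the physical system are not bundled; the
simulator provides statistically analogous data, and all claims checked by
the test-suite are directional or structural (orderings, invariants,
closed forms) rather than reproductions of instrument-specific accuracy
figures. Proprietary event-camera formats (EVK/RAW, AEDAT) are out of
scope; the documented CSV and HDF5 dialects are used instead. See
`docs/methods.md` for the model details and design choices.
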