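# emgforce

Surface-EMG interaction-force regression and muscle-contribution ranking.

When a limb pushes against a sensor or a wearable robot, the surface EMG
(sEMG) of the driving muscles precedes and predicts the interaction force.
`emgforce` implements a complete pipeline for studying that mapping, and for
answering a practical question in assistive-robot control: *which muscle's
signal should you trust for which task?*

The pipeline:

1. **Synthetic recordings** — a seeded generator produces four correlated
   muscle channels (biceps BB, triceps TB, brachialis BR, brachioradialis
   BRD) at 1 kHz as envelope-modulated motor-unit action-potential trains
   with 50 Hz powerline and ~110 Hz ECG-like interference, plus a force
   trace that is a saturating function of the activations with a **planted
   dominant muscle per task** (flexion→BB, extension→TB, pronation→BRD,
   supination→BR).
2. **KPCA reduction** — sliding windows (200 ms, 50% overlap) are reduced
   with Gaussian-kernel kernel PCA: eigendecompose the double-centered
   kernel matrix K̃, keep the smallest P components whose cumulative
   contribution rate ξ = Σ₁ᴾ λᵢ / Σ₁ᴺ λᵢ reaches 0.85. Classical PCA and
   time-domain features (MAV, VAR, ZC, WA) are provided as baselines.
3. **DRSN regression** — a 1-D deep residual shrinkage network: residual
   blocks whose features are denoised by soft thresholding
   y = sign(x)·max(|x|−τ, 0), with τ learned per sample by a
   squeeze-and-excitation subnetwork (τ = α·mean|x|, α = sigmoid(·) ∈ (0,1)).
   Implemented in pure numpy with the package's own reverse-mode autodiff;
   training is deterministic given a seed.
4. **MIV ranking** — mean impact value: perturb each muscle's raw signal by
   ±10%, re-run the pipeline, and average the induced change in predicted
   force; |MIV| normalized to sum 1 ranks the muscles, and the shortest
   prefix reaching 90% cumulative contribution is selected.

## Worked example

```bash
python examples/03_train_and_predict.py
```

```
windows: 599 (train 359 / val 119 / test 119)
KPCA components: 3
test MSE  1.217 N^2
test RMS  1.103 N
test MAVE 0.710 N
test rho  98.2 %
muscle ranking by |MIV|: BB,BR,BRD,TB
```

599 windows of a 60 s flexion recording compress to 3 kernel components
each; the trained network tracks the measured force at 98% correlation with
~1 N RMS error on a 0–14 N trace, and the MIV ranking puts the biceps (the
planted dominant flexor) first. `examples/04_muscle_ranking.py` repeats this
across all four tasks and prints the task × muscle contribution heatmap;
`examples/01_synthesize_and_inspect.py` and `examples/02_kpca_reduction.py`
show the generator's spectral content and the kernel spectrum.

The same experiments are scriptable from a shell:

```bash
emgforce simulate --suite --seed 42 --out data/
emgforce run --config my_experiment.yaml --seed 42 --out run1/
emgforce compare-muscles --seed 42 --out comparison/
emgforce spectrum --input data/flexion.csv
```

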