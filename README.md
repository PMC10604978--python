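# dwgc — dynamic window-level Granger causality for real-time fMRI decoding

`dwgc` implements a complete desk-scale pipeline for decoding motor-imagery
brain states from block-design BOLD runs using **dynamic window-level
Granger causality (DWGC)**: directed effective-connectivity features
computed on short sliding windows, fast enough to track state changes
within the repetition time (TR) of a real-time fMRI experiment. It is aimed
at researchers prototyping connectivity-based neurofeedback or
brain–computer-interface decoders, and at anyone who wants a fully
controlled synthetic test bed in which the ground-truth directed coupling
is known exactly.

## The method

For each ordered pair of regions of interest (source *i*, target *j*) and
each sliding window of *k* volumes starting at volume *t*, two
autoregressive predictors of the target are fitted by least squares on a
trailing training span ending strictly before the window:

* **restricted**: the target's next value from its own last *p* values,
* **full**: additionally from the source's last *p* values.

Both predict the *k* window samples one step ahead; their mean squared
errors L1 (restricted) and L2 (full) form

```
F(i -> j; t) = L1 / max(L2, eps),
```

so F materially above 1 means the source's past improved the out-of-sample
prediction of the target *in that window* — Granger causality, resolved in
time. A detection threshold ω is calibrated per pair as the (1 − α)
quantile of F on circular-shift surrogates (which destroy cross-lag
structure while preserving each series' autocorrelation); F values below ω
are set to 0. The thresholded directed-F stream is the feature vector for a
classifier suite (Gaussian naive Bayes, polynomial/RBF SVM, gradient
boosting) evaluated with block-grouped K-fold cross-validation (confusion
matrix, accuracy, Cohen's κ), and a per-TR decoding-accuracy (DA) curve
shows how quickly each feature set detects a new brain state after block
onset. A replay harness runs the whole chain volume-by-volume exactly as a
scanner feed would, bit-identical to the batch pipeline.

The synthetic generator produces the matching study conditions: a
block-design paradigm (10 s task blocks, 20 s rests, TR = 2 s), latent
node signals from a condition-switched first-order vector autoregression,
canonical double-gamma hemodynamic convolution (peak ≈ 5 s), and rendered
4D NIfTI volumes with spherical ROIs plus observation noise.

## Worked example

```python
import numpy as np
from dwgc import DynamicWindowGC, SimulationConfig
from dwgc.paradigm import Block, Paradigm
from dwgc.synthetic import simulate_roi_series

# ten minutes of sustained imagery: M1 drives SMA with gain 0.8
paradigm = Paradigm(tr_seconds=2.0, blocks=[Block("task", 0.0, 600.0)],
                    total_duration_s=600.0)
coupling = np.zeros((2, 2))
coupling[1, 0] = 0.8  # M1 -> SMA
config = SimulationConfig(n_nodes=2, base_ar_coeffs=[0.3, 0.3],
                          coupling_schedule={"task": coupling}, seed=7)
series, truth = simulate_roi_series(config, paradigm, roi_names=["M1", "SMA"])

model = DynamicWindowGC(series, k=4)
results = model.fit(alpha=0.05, n_surrogates=500, seed=7)
print(results)
```

prints

```
DWGC: 2 nodes, k=4, 256 windows, spec=ArModelSpec(order_p=1, basis='linear', degree=2, train_span=40)
source target    omega   mean_F  mean_log_F  detect_frac
   SMA     M1 1.651654 1.319209    0.057173     0.222656
    M1    SMA 1.574012 1.950517    0.312021     0.468750
```

Reading the table: the true direction M1 → SMA has mean window F ≈ 1.95 —
the source's past reduced the target's out-of-sample window error by
roughly half — and survives its surrogate-calibrated threshold
(ω ≈ 1.57) in 47 % of windows. The reverse direction also sits above its
null (a known behaviour of pairwise Granger measures on strongly coupled
pairs observed through a smoothing hemodynamic response), but the true
direction clearly dominates in mean F, mean log F and detection fraction.

## Command line

The same pipeline is exposed as a CLI for file-based workflows:

```bash
dwgc simulate --seed 7 --out run/                 # NIfTI + events.tsv + truth.json
dwgc extract  --nifti run/bold.nii --config run/config.yaml \
              --events run/events.tsv --out series.csv
dwgc dwgc     --series series.csv --k 4 --out conn.csv
dwgc train    --series series.csv --connectivity conn.csv \
              --out model.joblib --report report.json
dwgc replay   --nifti run/bold.nii --config run/config.yaml \
              --model model.joblib --out decisions.tsv
dwgc report   --predictions report.predictions.csv \
              --events run/events.tsv --out dacurve.csv
```

## Layout

| module | contents |
| --- | --- |
| `dwgc.paradigm` | block designs, BIDS-style events TSV I/O |
| `dwgc.synthetic` | condition-switched VAR generator, HRF, NIfTI rendering |
| `dwgc.roi` | sphere masks, mean-series extraction, ACTIVE feature, discard/trim rules |
| `dwgc.model` | window-level GC, surrogate calibration, `DynamicWindowGC`/`DWGCResults` |
| `dwgc.classify` | feature assembly, classifier suite, K-fold reports, DA curves |
| `dwgc.stream` | per-TR replay loop, batch reference, pipeline config |
| `dwgc.cli` | the `dwgc` console entry point |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
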