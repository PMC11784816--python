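# qgafs — quantum-inspired genetic algorithm feature selection

`qgafs` is a Python library and command-line tool for **wrapper feature
selection with a quantum-inspired genetic algorithm (QGA)**, built for the
kind of pipeline common in medical image classification: a deep network
turns images (e.g. brain-MRI scans sorted into tumor-class folders) into
high-dimensional feature vectors, a search procedure selects the subset of
features that actually carries class signal, and a compact classifier head
is retrained on the selected features. It is aimed at researchers who want
a reproducible, testable implementation of that middle step — the QGA mask
search — together with the surrounding pipeline and a careful multiclass
metric suite.

## The algorithm

A feature subset of a d-column matrix is a bitstring (bit *i* = keep
column *i*). Instead of a population of bitstrings, the QGA maintains a
population of **qubit registers**: per gene an amplitude pair (α, β) with

```
α² + β² = 1
```

where β² is the probability of observing a 1. Each generation the
registers are *observed* to concrete bitstrings, each mask is scored by

```
fitness(mask) = mean stratified 5-fold CV accuracy of a logistic probe
                on the masked columns  −  λ · (#selected / d)
```

and every register is rotated toward the best individual *B* found so far
by the gate

```
[α'; β'] = [cos Δθ  −sin Δθ; sin Δθ  cos Δθ] [α; β]
```

applied only at genes that disagree with *B* (fixed magnitude
Δθ = 0.05π, signed toward *B*'s bit, clamped away from collapse). A 1%
amplitude-swap mutation keeps the search ergodic, and elitism makes the
best fitness non-decreasing. After the search, the final head
(dense-128 → dropout 0.5 → softmax, Adam 1e-3, early stopping and
plateau LR decay) is retrained on the selected columns and evaluated once
on a held-out 20% split that never influenced the search.

Reported metrics: per-class precision/recall/F1, accuracy, Cohen's κ =
(p₀ − p_e)/(1 − p_e), and the Matthews correlation coefficient
(covariance form for C > 2, reducing exactly to the binary
TP/TN/FP/FN formula at C = 2).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a 300×16 feature matrix (3 classes, 4 informative columns,
class-mean separation 3σ), then search for the best subset:

```bash
qgafs simulate features --n 300 --d 16 --k 4 --classes 3 --delta 3 \
      --seed 0 --out demo/features.csv
qgafs select demo/features.csv --t-max 20 --seed 0 --out demo/run
```

which prints

```
wrote 300x16 matrix to demo/features.csv
selected 8/16 features, held-out accuracy 1.0000
```

`demo/run/selection.json` records the full result — the selected columns
`["f0", "f2", "f4", "f8", "f10", "f11", "f13", "f14"]`, the best penalized
fitness `0.995`, and the held-out metrics (accuracy 1.0, κ 1.0, MCC 1.0
on the 60-sample test split). The generator's ground truth
(`demo/features.informative.json`) lists `["f1", "f2", "f8", "f14"]` as
informative: the mask keeps three of the four signal columns — with 3σ
separation the fourth is redundant for perfect held-out accuracy, so the
sparsity penalty, not the signal, decides its fate. Every output
directory contains the resolved configuration and derived sub-seeds;
re-running with the same seed reproduces all numbers exactly.

The same flow works end-to-end from images:

```bash
qgafs simulate images --n-per-class 30 --classes 3 --seed 0 --out demo/imgs
qgafs pipeline demo/imgs --dim 32 --t-max 10 --seed 0 --out demo/pipe
```

Other commands: `qgafs optimize` (the raw bitstring optimizer on onemax /
linear / trap benchmarks) and `qgafs evaluate` (metrics report from a CSV
of true/predicted labels). As a library, `QGAFeatureSelector` is a
scikit-learn selector (`fit` / `transform` / `get_support`) and
`SoftmaxHeadClassifier` a scikit-learn classifier; both compose with
pipelines.

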