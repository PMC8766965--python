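# sbcnn — stochastic binarized CNNs for near-sensor vision

`sbcnn` is a toolkit for *fully binarized* vision pipelines aimed at
low-power, near-sensor hardware such as RRAM crossbar accelerators.  In
an ordinary binarized neural network (BNN) every multiply-accumulate is
an XNOR + popcount — except the first layer, which still consumes int8
or float pixels.  This package closes that gap with **stochastic input
binarization**: pixels are standardized per channel,

    X_r = (X_d − μ_i) / σ_i ,

and each of `N_pre` presentations draws one bit per pixel by comparing it
to a normal random threshold, so `P(bit = 1) = Φ(X_r)`.  The network then
runs entirely in one-bit arithmetic:

    a_n = sign(popcount(XNOR(W_0, X > rand)) − b_0)      (presentation n)
    A_0 = sign(Σ_n a_n)
    A_i = sign(popcount(XNOR(W_i, A_{i−1})) − b_i)       (remaining layers)

with learned integer thresholds `b_i` obtained by folding batch norm at
export.  The intended users are researchers prototyping in-memory /
near-sensor inference (e.g. point-of-care microscopy diagnostics) who
need a bit-exact software model of the binarized pipeline plus the
hardware bookkeeping that goes with it.

What is inside:

* `binary_core` — bit-packed ±1 tensors, XNOR/popcount, the binarized
  neuron, straight-through-estimator gradients, exact batch-norm → integer
  threshold folding, and a packed model container.
* `stochastic_input` — mean–sigma normalization, normal/uniform
  stochastic bit sampling, bitstreams over `N_pre` presentations, and a
  behavioural OxRAM cycle-to-cycle-variability threshold source.
* `sbcnn_model` — AlexNet-style full/reduced architecture specs, a NumPy
  binarization-aware training engine (Adam + STE), stochastic inference,
  and the matched- vs max-presentations experiment.
* `detector` — sliding-window heat maps (50% overlap), threshold +
  connected components → boxes, NMS, IoU matching.
* `cost_model` — parameter/memory accounting per precision, op counts,
  32×32 2T-2R crossbar tile mapping, and a configurable energy table.
* `synthetic_data` — synthetic microscopy scenes with planted
  pathogen-like objects and exact ground truth, slice datasets with
  dihedral augmentation and negative rebalancing, and a small multi-class
  RGB classification set.
* `evaluation` — accuracy, ROC AUC, precision–recall / mAP, multi-trial
  averaging.

## Worked example

Hardware cost of the full 2-class AlexNet-style model at `N_pre = 32`:

```sh
$ sbcnn cost --arch full --classes 2 --precision binary --n-pre 32
{
  "total_params": 57012034,
  "memory_mib": {
    "fp32": 217.48365020751953,
    "int8": 54.37091255187988,
    "binary": 6.796364784240723
  },
  "ops": {
    "first_layer_ops": 2248857600,
    "sampling_ops": 4816896,
    "binary_ops": 639823872,
    "total": 2893498368,
    "n_pre": 32
  },
  "cycles": 1856,
  "energy_uj": 29.12765952
}
```

Reading this: the full model carries 57 M weights — 217.48 MiB at fp32,
54.37 MiB at int8, 6.80 MiB at one bit per weight.  The reduced model
(one hidden fc layer removed) needs 4.80 MiB, i.e. a ~45× saving over
the fp32 full model and ~11× over int8.  At `N_pre = 32` the stochastic
first layer accounts for 2.25 G of the 2.89 G one-bit operations per
inference; `cycles` is the crossbar latency under the 32×32-tile mapping
(one row per cycle per resident block), and `energy_uj` uses the
shipped *illustrative* per-op constants — substitute measured platform
constants for absolute numbers.

End-to-end detection on synthetic microscopy scenes (trains a reduced
SBCNN patch classifier on generated slices, then slides it over held-out
scenes):

```sh
$ sbcnn experiment detection --seed 3
{
  "map": 0.9085197990864073,
  "n_truth": 120,
  "n_detections": 126,
  "tp": 113,
  "fp": 13,
  "iou_threshold": 0.3,
  "n_pre": 32
}
```

113 of 120 planted objects are recovered with 13 false positives, a mean
average precision of 0.91 at IoU 0.3 — computed entirely through the
integer XNOR-popcount inference path.

The presentation-strategy study (`sbcnn experiment strategies`) compares
training/inferring at the same `N_pre` ("matched") against training once
at 256 presentations and inferring at fewer ("max"): matched inference
with as few as 8 presentations matches its 32-presentation accuracy,
while max-presentation models degrade sharply at small `N_pre`.

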