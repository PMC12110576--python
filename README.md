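# mclswt

Mirror-contrastive sliding-window transformer for motor-imagery EEG —
with a synthetic ERD/ERS generator so the whole pipeline runs on a
laptop with no EEG downloads.

## The problem

Imagining a left- or right-hand movement suppresses mu-band (8–13 Hz)
power over the *contralateral* sensorimotor cortex (event-related
desynchronization, ERD) and enhances it ipsilaterally (ERS). A
brain–computer interface decodes which hand was imagined from a few
EEG channels (C3, Cz, C4). The package targets the
**subject-independent** setting — train on some people, decode new
people — where inter-subject variability in mu rhythm and ERD topography
is the main obstacle.

## The method

Three pieces, all built around the left/right symmetry of the montage:

- **SWT** — a sliding-window transformer: a Shallow-ConvNet-style
  convolutional front end (temporal filter bank + spatial filter + BN),
  pairs of multi-head self-attention blocks restricted to temporal
  windows of length M = 8 (the second block of each pair cyclically
  shifts the window grid by M/2), and a square → average-pool → log
  band-power head. Windowing makes attention cost linear in the
  sequence length: `Ω(WMSA) = 8LD² + 4MLD` vs `Ω(MSA) = 4LD² + 2L²D`.
- **Mirror trials** — swapping left/right channel data (C3↔C4) and
  flipping the label turns a left trial into a physically plausible
  right trial. Every training batch is doubled with mirrors.
- **Mirror contrastive loss** — a margin hinge on embedding distances,
  `max(α + g·(D − β), 0)` with `g = ±1` for same/different labels,
  applied over original-original pairs (`L_o`) and mirror-original
  pairs (`L_m`; a trial and its own mirror are always a negative
  pair). Total objective `L = L_c + w_o·L_o + w_m·L_m` with
  cross-entropy `L_c`. At inference, **mirror fusion** averages a
  trial's probabilities with the class-swapped probabilities of its
  mirror.

Everything (network, gradients, Adam) runs on NumPy via a small
built-in autodiff engine — no deep-learning framework required.

## Worked example

Simulate an 8-subject dataset, train subject-independently on 6
subjects, and evaluate on the 2 held-out subjects:

```python
from mclswt import ContrastiveConfig
from mclswt.experiments import run_subject_independent, average_accuracy

res = run_subject_independent(seed=606, max_epochs=5,
                              loss_cfg=ContrastiveConfig())
print([round(a, 3) for a in res.history.test_accuracy])
print(round(average_accuracy(res.history), 3))
```

```
[0.885, 1.0, 1.0, 1.0, 1.0]
1.0
```

Held-out (fused) accuracy per epoch: the simulated task (ERD depth
0.5, 8 µV background noise) is strongly lateralized, so the decoder
reaches ceiling within a couple of epochs; the tail average is 100%.
The same experiment with `ContrastiveConfig(w_o=0, w_m=0)` gives the
plain-SWT ablation.

The same pipeline is scriptable from the shell:

```bash
mclswt simulate --subjects 8 --trials 100 --erd 0.5 --seed 7 --out data.npz
mclswt train --train-data train.npz --test-data test.npz --out ckpt/
mclswt evaluate --ckpt ckpt/checkpoint.npz --data test.npz
mclswt erd --data data.npz
```

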