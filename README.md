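# analogynet

A connectionist model of binary-choice verbal analogy problems
(A:B::C:[D1|D2]) for computational cognitive neuroscience: it shows how the
developmental shift from associative to relational responding, and the
analogy deficits that follow frontal versus anterior-temporal degeneration,
can both emerge from a single recurrent network that was never trained on
analogies — only on completing item–relation–item propositions.

## The model in brief

A recurrent network with localist item pools **A** and **B**, a distributed
relation pool **R** (128 units) and a hidden integrator **H** (64 units),
all bidirectionally connected, is trained by backpropagation through time to
complete any triple A:R:B given two of its elements. Relations are instances
of 8 disjoint 16-unit prototypes (two instances of one prototype share 12 of
their 14 active units; instances of different prototypes share none), so
"the same relation" is a matter of pattern similarity, not identity.

The training environment is generated and counterbalanced: cells of five
propositions yield, per cell, three analogy questions whose *semantic
facilitation index* (SFI) is positive, zero or negative according to whether
the correct alternative D1 co-occurs with C more, equally or less often in
training than the foil (frequencies 1/3/9); item and relation frequencies
are globally equated so only co-occurrence carries the manipulation.

Analogies are answered by a weight-tied *twin*: two copies of the trained
network share one relation pool (with hidden-to-relation contributions
halved), so the A:B and C:D halves jointly constrain the relation. Each
alternative is clamped briefly and released; the *echo* — the residual
activation of the candidate's unit after settling — decides the forced
choice. Lesions are applied to the trained networks: *frontal* damage lowers
the A:B half's hidden bias from −2 to −6.5 (context maintenance lost,
associative responding returns), *temporal* damage removes each connection
with probability .42 identically in both halves (pattern completion
degrades across the board).

## Worked example

```python
import analogynet as an

env = an.build_environment(an.EnvironmentConfig(seed=11))
cfg = an.network_config_for(env.config, seed=21)
w = an.init_network(cfg)
w, history = an.train(w, env, cfg, epochs=350)

twin = an.build_twin(w)                      # weight-tied testing twin
acc = an.evaluate(twin, env.questions(), an.ProbeConfig())
print({k: round(v, 3) for k, v in acc.items()})

frontal = an.frontal_lesion(twin, an.LesionSpec("frontal"))
print({k: round(v, 3) for k, v in an.evaluate(frontal, env.questions(), an.ProbeConfig()).items()})
```

Output from this exact script:

```
{'accuracy_overall': 0.958, 'accuracy_positive': 0.975, 'accuracy_zero': 1.0, 'accuracy_negative': 0.9}
{'accuracy_overall': 0.383, 'accuracy_positive': 0.525, 'accuracy_zero': 0.55, 'accuracy_negative': 0.075}
```

The trained network answers 95.8% of the 120 analogy questions correctly,
with the hardest condition (negative SFI, where the foil is the more
strongly associated alternative) at 90%. After the frontal lesion the
negative-SFI condition collapses to 0.075 — far below chance (0.5) — the
signature of a return to association-driven responding.

The same protocol from a shell:

```bash
analogynet sim1 --seed 1 --out runs/s1     # 5 networks, 350 epochs, curves CSV + plot
analogynet sim2 --run runs/s1 --out runs/s2  # control/frontal/temporal battery
analogynet report --run runs/s1
```

`runs/s1/development.csv` holds one row per (network, sampled epoch) with
per-SFI accuracies — early in training positive-SFI questions are answered
best and negative-SFI questions fall below chance; the negative condition
crosses chance for good near epoch 120 and all conditions approach ceiling
by epoch 350 (the relational shift). `runs/s2/lesion_summary.csv` shows the
lesion interaction: the SFI effect (positive minus negative accuracy) is
largest after frontal damage, intermediate after temporal damage, smallest
in controls, while temporal damage lowers all three conditions.

## Layout

| path | contents |
| --- | --- |
| `src/analogynet/relations.py` | relation prototypes and deletion-derived instances |
| `src/analogynet/environment.py` | counterbalanced cells, SFI-labeled questions, epoch expansion |
| `src/analogynet/network.py` | settling dynamics, BPTT training |
| `src/analogynet/probe.py` | twin architecture, echo trials, forced choice |
| `src/analogynet/lesion.py` | frontal and temporal lesion operators |
| `src/analogynet/experiments.py` | the two simulations, summaries, plots |
| `src/analogynet/cli.py` | `analogynet` command-line entry point |
| `docs/methods.md` | model details, operating point, limitations |
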