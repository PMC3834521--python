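# Methods

`analogynet` models binary-choice verbal analogy problems (A:B::C:[D1|D2])
as a by-product of ordinary relational learning: a recurrent network is
trained only to complete item1–relation–item2 propositions, and analogy
performance emerges from the interplay between learned relational knowledge
and the co-occurrence statistics of its training environment. This note
documents the model, the synthetic environment, the testing procedure, the
lesion operators, the numerical choices, and the limitations of each.

## The triple-completion network

Four pools of logistic units: two localist item pools A and B (one unit per
item; first-role and second-role vocabularies are disjoint), a distributed
relation pool R (128 units), and a hidden integrator pool H (64 units). Six
independent directional weight matrices connect A↔H, B↔H and R↔H; there is no
weight tying between directions — bidirectionality refers to connectivity,
not symmetry.

Dynamics are leaky-logistic. On each tick every unclamped unit moves a
fraction λ of the way from its current activation toward the logistic of its
net input:

    a_i(t) = a_i(t-1) + λ · (σ(net_i(t)) − a_i(t-1)),
    net_i(t) = Σ_j w_ij a_j(t-1) + b_i

Unclamped pools start at the resting state σ(b); clamped pools are held at
their clamp value at every tick. The hidden bias is a single fixed scalar
b_H = −2 shared by all hidden units: it is the control knob the frontal
lesion manipulates, so it is excluded from learning. Visible-pool biases are
learned vectors initialized at zero.

Training presents two elements of a proposition triple clamped one-hot (items)
or as the binary relation-instance pattern (R), one third of the time each
combination (A+B→R, A+R→B, B+R→A). The network settles for `n_ticks` = 20
ticks and the loss is the cross-entropy between the target pool's activations
and the target pattern, summed over the final `target_ticks` = 5 ticks —
applying the error only to late ticks rewards settled completions rather than
fast transients. Gradients flow through the unrolled dynamics
(backpropagation through time), including through the resting-state
dependence of the target pool on its own bias. A tiny-network
finite-difference oracle in the test suite checks the gradients to 1e-4
relative error.

### Updates

Trials within an epoch are shuffled, grouped into mini-batches of
`batch_size` = 64 trials sharing one input combination, and the mean batch
gradient is applied after each batch with learning rate `lr`. Batch updates
were chosen over strictly per-trial updates because homogeneous batches keep
the settling computation fully vectorized (the three combinations clamp
different pools); `batch_size=1` recovers per-trial updates. An optional
`weight_decay` multiplier (default 0, i.e. off) shrinks the connection
matrices after each update; it is exposed because bounded weights keep
completions graded, but the default operating point does not need it.

### Operating point

The reference account of this model states the architecture and the lesion
parameters but not the training hyperparameters, so the learning rate,
hidden-pool size, tick counts and probe durations are this package's own
operating point. They were calibrated once, jointly, so that the 5-network
default study reproduces the study-level behavior the model is meant to
show — end-of-training analogy accuracy near 0.97, a below-chance window for
negative-SFI questions early in training, and a sustained crossing of chance
by the negative-SFI condition near epoch 130 — and then frozen:

| parameter | value | role |
| --- | --- | --- |
| `n_hidden` | 64 | hidden integrator size; smaller pools (≤48) cap analogy accuracy ~0.91 |
| `lr` | 0.016 | sets the developmental timescale almost linearly; 0.02 moves the crossing to ~100 epochs, 0.03 to ~80 |
| `n_ticks` / `target_ticks` | 20 / 5 | settling depth per training trial |
| `lam` (λ) | 0.2 | activation step size during training |
| `init_range` | 0.25 | uniform weight initialization half-width |
| `hidden_bias` | −2 | fixed; the frontal lesion lowers it to −6.5 in H1 only |

## The training environment

The environment is generated, not loaded. Its building block is the *cell*:
one source proposition A:R1:B, one relational target C:R1′:D1 where R1 and
R1′ are instances of the same relation prototype, and three foil
propositions C:R2:D2, C:R3:D3, C:R4:D4 from three other prototypes with
weak/moderate/strong training frequencies 1/3/9 (presentations per epoch per
input combination). The source and target share the moderate frequency, so
the semantic facilitation index (SFI) of a question is carried entirely by
the foil: each cell yields one positive-SFI (weak foil), one zero-SFI
(moderate foil) and one negative-SFI (strong foil) question, all sharing
a, b, c and the correct alternative d1.

Relation prototypes are 8 disjoint 16-unit blocks of the 128 relation units
(a chunked random permutation, so disjointness holds by construction).
An instance deletes 2 of a prototype's active units; deleted pairs are kept
disjoint across the instances drawn within one cell group, so same-prototype
instances share exactly 12 active units while different-prototype instances
share none. "Same relation, not identical" is what licenses the analogy.

A frequency manipulation confounds easily with global item/relation
frequency, so the design counterbalances by reuse. Cells come in groups of
five: five second-role items rotate through the roles {B, D1, weak foil,
moderate foil, strong foil} as a Latin square, and five first-role items each
serve once as A and once as C. The four prototype roles rotate with the cell
index so that over any 8 consecutive cells every prototype fills every role
exactly once. Under the defaults (8 groups, 40 cells, 40 items per role
class, 120 questions) every item receives a total training frequency of 19
per input combination per epoch and every prototype a total of 95 — the
max/min ratio within each class is exactly 1 (tested exhaustively). An epoch
therefore expands to 3 × 19 × 40 = 2280 trials.

What the generator does *not* emulate: real word-association norms are
neither symmetric nor counterbalanced, items have no surface similarity
(localist coding), relation instances within a prototype are equidistant,
and frequencies take only three values. Passing tests show that the
*mechanism* produces the developmental and lesion patterns under controlled
statistics; they say nothing about fit to any natural corpus.

## The twin test and the echo measure

Analogies are answered by two weight-tied copies of the trained network
sharing one relation pool: A,B feed hidden pool H1; C and a candidate D feed
H2, with C read through the A-side weights and D through the B-side weights.
Both halves are views of a single weight container, so any change — learning
or lesion — is identical in both by construction. The H1→R and H2→R
contributions are halved: when both halves push the same relation, the R
pool receives net input of the magnitude it saw in training (2 × 0.5 = 1).
The R→H direction is not scaled, and the shared R pool adds its bias once.

Each question runs two independent echo trials from identical initial
conditions, one per alternative. Phase 1 clamps a, b, c and the candidate d
one-hot for `phase1_ticks` = 2 ticks; phase 2 releases the D clamp — the
pool keeps its state rather than being flushed — and lets the network settle
for `phase2_ticks` = 25 ticks with λ = 0.25 while a, b, c stay clamped. The
*echo* is the candidate unit's activation at the final tick; the larger echo
wins (an exact tie, which arises only in degenerate cases such as a total
lesion, is broken by a deterministic coin derived from the question and the
probe seed).

The probe durations are part of the operating point and they matter: the
short clamp phase keeps the candidate from entrenching its own relation
attractor before the joint constraint applies, and the long release phase
gives the A:B half — whose inputs remain clamped — time to win the
tug-of-war over the shared relation pool, eroding support for a
relationally-inconsistent candidate. Longer clamp phases shift the model
toward associative responding (echoes then track co-occurrence frequency);
the chosen values sit where trained networks respond relationally while
untrained networks remain exactly at chance.

## Lesions

*Frontal*: the H1 bias is replaced by −6.5 (H2 and all weights untouched),
modeling loss of the context maintenance that lets the A:B pair constrain
the C:D decision. It changes exactly one scalar, is applied at test time
only, and is exactly reversible.

*Temporal*: every connection in each of the six matrices is independently
zeroed with probability 0.42, modeling degraded pattern completion. Biases
are not projections and are spared. The keep-mask is returned for auditing,
and the shared-container twin makes the lesion mirror-identical across
halves with no copying step. Five independent draws per network give 25
lesioned networks in the default study. If lesioned weights are trained
further, the mask is re-applied after every update so removed connections
stay removed.

## The default study

`simulation1` trains 5 networks (seeds derived from the experiment seed),
each on its own generated environment, for 350 epochs, evaluating all 120
questions every 10 epochs plus epoch 0. `simulation2` evaluates control,
frontal and temporal conditions on the trained networks. At the frozen
operating point (seed 1) the package computes: epoch-0 accuracy 0.495;
final accuracy 0.962; negative-SFI accuracy below chance from epoch ~10 to
~110 (minimum 0.245 at epoch 90) with a sustained crossing of chance at
epoch 120; "became relational" is operationalized as the first sampled epoch
whose mean negative-SFI accuracy exceeds 0.5 and never falls back. Control /
frontal / temporal SFI effects (positive minus negative accuracy) are
ordered 0.04 < 0.47 with the temporal group between them (0.13); the
temporal lesion depresses all three SFI conditions.

## Known limitations

* **Frontal positive-SFI preservation.** Frontal patients in the motivating
  neuropsychological data keep near-control accuracy on positive-SFI
  problems. In this implementation the frontal condition shows the correct
  *relative* pattern (a large SFI effect, negative-SFI far below chance) but
  positive-SFI accuracy falls well below control (~0.3–0.45 drop). The
  underlying trade-off is structural: configurations whose associative
  (frequency-graded) responding survives the lesion — small hidden pools,
  strong learning rates — cap control accuracy near 0.91 and collapse the
  lesion-type interaction, while the operating point that reproduces the
  developmental trajectory trains completions so sharply that, with the A:B
  context removed, retention no longer tracks frequency reliably. The
  reference account itself notes that its simulated SFI effects exceed the
  human ones.
* **Late convergence order.** During acquisition (epochs ~10–140) accuracy
  is strictly ordered positive ≥ zero ≥ negative, as expected if association
  strength dominates early. During late convergence (~150–200) the
  positive-SFI condition reaches ceiling *last*: the weak foil is the most
  rarely trained proposition, and its off-manifold states retain noisy
  echoes that are occasionally mistaken for support, whereas moderate and
  strong foils are reliably suppressed once relational knowledge dominates.
* Relation representations are fixed by the generator; nothing in the model
  learns or reshapes them from exemplars.
* The mapping of the two lesion operators to anatomy is functional, not
  literal; no quantitative fit to patient data is attempted.

## Reproducibility

Every stochastic step — prototype permutation, off-pair draws, weight
initialization, trial shuffling, lesion draws, tie-breaks — flows from
explicit seeds derived with `numpy.random.SeedSequence` from a single
experiment seed, and identical seeds give bit-identical weights and
byte-identical CSVs. The test suite's expensive fixture runs the full
default study once per session; all other tests run on small configurations
(two-group environments, ≤20-unit networks) in seconds.
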