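"""The counterbalanced environment: cells, questions, epoch expansion."""

import collections

import numpy as np
import pytest

import analogynet as an
from analogynet.environment import FOIL_STRENGTHS, INPUT_COMBOS
from analogynet.errors import InvalidConfigError


@pytest.fixture(scope="module")
def default_env():
    return an.build_environment(an.EnvironmentConfig(seed=9))


def test_cell_and_question_counts(default_env, small_env):
    assert len(default_env.cells) == 40
    assert len(default_env.questions()) == 120
    assert len(small_env.cells) == 10
    assert len(small_env.questions()) == 30
    assert small_env.n_first_role == small_env.n_second_role == 10
    single = an.build_environment(an.EnvironmentConfig(n_groups=1, seed=2))
    assert len(single.cells) == 5 and len(single.questions()) == 15
    assert single.n_first_role == single.n_second_role == 5


def test_cell_structure(default_env):
    """Source/target share a prototype with disjoint off-pairs; the three
    foils use three other distinct prototypes and share the C item."""
    for cell in default_env.cells:
        assert cell.source.relation.prototype_id == cell.target.relation.prototype_id
        assert not set(cell.source.relation.off_pair) & set(cell.target.relation.off_pair)
        foil_protos = {f.relation.prototype_id for f in cell.foils}
        assert len(foil_protos) == 3
        assert cell.target.relation.prototype_id not in foil_protos
        for foil in cell.foils:
            assert foil.item1 == cell.target.item1
        assert cell.foil_weak.frequency < cell.foil_moderate.frequency < cell.foil_strong.frequency
        assert cell.target.frequency == cell.foil_moderate.frequency


def test_foil_frequencies_echo_config(default_env):
    cfg = default_env.config
    for cell in default_env.cells:
        assert [f.frequency for f in cell.foils] == [
            cfg.freq_weak, cfg.freq_moderate, cfg.freq_strong
        ]


def test_counterbalance_item_frequencies(default_env):
    """Every item's total training frequency is identical within its role
    class (19 per epoch per input combination under the defaults)."""
    first = collections.Counter()
    second = collections.Counter()
    for p in default_env.propositions:
        first[p.item1] += p.frequency
        second[p.item2] += p.frequency
    assert len(first) == default_env.n_first_role
    assert len(second) == default_env.n_second_role
    assert set(first.values()) == {19}
    assert set(second.values()) == {19}


def test_counterbalance_prototype_roles(default_env):
    """Over any 8 consecutive cells each prototype fills each frequency role
    (target, weak, moderate, strong) exactly once."""
    roles_by_cell = []
    for cell in default_env.cells:
        roles_by_cell.append(
            {
                "target": cell.target.relation.prototype_id,
                **{s: f.relation.prototype_id for s, f in zip(FOIL_STRENGTHS, cell.foils)},
            }
        )
    n_proto = default_env.protoset.n_prototypes
    for start in range(len(roles_by_cell) - n_proto + 1):
        window = roles_by_cell[start : start + n_proto]
        for role in ("target",) + FOIL_STRENGTHS:
            assert sorted(r[role] for r in window) == list(range(n_proto))


def test_questions_from_cell(default_env):
    for i, cell in enumerate(default_env.cells):
        qs = an.questions_from_cell(cell, cell_index=i)
        assert [q.sfi_label for q in qs] == ["positive", "zero", "negative"]
        assert len({(q.a, q.b, q.c, q.d1) for q in qs}) == 1
        assert len({q.d2 for q in qs}) == 3
        for q in qs:
            assert q.d1 == cell.target.item2
        # the label is defined by the foil-vs-target frequency comparison
        assert qs[1].d2 == cell.foil_moderate.item2
        assert cell.foil_moderate.frequency == cell.target.frequency


def test_expand_epoch_counts_and_multiset(small_env):
    trials = an.expand_epoch(small_env, seed=0)
    total_freq = sum(p.frequency for p in small_env.propositions)
    assert len(trials) == 3 * total_freq
    by_combo = collections.Counter(t.input_combo for t in trials)
    assert by_combo == {c: total_freq for c in INPUT_COMBOS}
    # every proposition contributes exactly frequency trials per combination
    key = lambda t: (t.input_combo, t.proposition.item1, t.proposition.item2,
                     t.proposition.relation.prototype_id, t.proposition.relation.off_pair)
    tally = collections.Counter(key(t) for t in trials)
    for p in small_env.propositions:
        for combo in INPUT_COMBOS:
            assert tally[(combo, p.item1, p.item2, p.relation.prototype_id, p.relation.off_pair)] == p.frequency


def test_expand_epoch_shuffle_contract(small_env):
    a = an.expand_epoch(small_env, seed=1)
    b = an.expand_epoch(small_env, seed=2)
    key = lambda t: (t.input_combo, t.proposition.item1, t.proposition.item2)
    assert collections.Counter(map(key, a)) == collections.Counter(map(key, b))
    assert [key(t) for t in a] != [key(t) for t in b]
    assert [key(t) for t in a] == [key(t) for t in an.expand_epoch(small_env, seed=1)]


def test_default_epoch_size():
    env = an.build_environment(an.EnvironmentConfig(seed=1))
    assert len(an.expand_epoch(env, seed=0)) == 2280  # 3 x 19 x 40


def test_target_pool_is_the_missing_element(small_env):
    pools = {t.input_combo: t.target_pool for t in an.expand_epoch(small_env, 0)}
    assert pools == {"AB": "R", "AR": "B", "BR": "A"}


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_groups=0),
        dict(freq_weak=3, freq_moderate=3),
        dict(freq_weak=4, freq_moderate=3, freq_strong=9),
        dict(relation=an.RelationSpaceConfig(n_units=9, n_prototypes=3, n_active=3, n_off=1)),
    ],
)
def test_invalid_environment_configs(kwargs):
    with pytest.raises(InvalidConfigError):
        an.EnvironmentConfig(**kwargs)


def test_off_pair_scope_widens_with_warning():
    """A relation space too small for a group's instance demand resets its
    off-pair bookkeeping instead of failing."""
    rel = an.RelationSpaceConfig(n_units=32, n_prototypes=8, n_active=4, n_off=2)
    with pytest.warns(UserWarning, match="widening"):
        env = an.build_environment(an.EnvironmentConfig(n_groups=1, seed=0, relation=rel))
    assert len(env.cells) == 5


def test_environment_json_roundtrip(small_env):
    restored = an.Environment.from_json(small_env.to_json())
    assert len(restored.cells) == len(small_env.cells)
    assert (restored.protoset.patterns == small_env.protoset.patterns).all()
    for a, b in zip(restored.cells, small_env.cells):
        for pa, pb in zip(a.propositions, b.propositions):
            assert (pa.item1, pa.item2, pa.frequency) == (pb.item1, pb.item2, pb.frequency)
            assert (pa.relation.pattern == pb.relation.pattern).all()
    assert restored.question_table().equals(small_env.question_table())


def test_environment_determinism():
    a = an.build_environment(an.EnvironmentConfig(seed=21))
    b = an.build_environment(an.EnvironmentConfig(seed=21))
    assert a.to_json() == b.to_json()
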