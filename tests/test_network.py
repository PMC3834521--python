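"""Settling dynamics and backpropagation-through-time learning."""

import numpy as np
import pytest
from scipy.special import expit

import analogynet as an
from analogynet.environment import Trial
from analogynet.errors import InvalidConfigError
from analogynet.network import _bptt_batch_grads

TINY = an.NetworkConfig(
    n_first_role=2, n_second_role=2, n_relation=4, n_hidden=3,
    n_ticks=6, target_ticks=2, seed=7,
)


def _tiny_trial(combo="AB"):
    protoset = an.generate_prototypes(an.RelationSpaceConfig(4, 2, 2, 1, seed=0))
    inst = an.generate_instance(protoset, 0, [], rng=np.random.default_rng(0))
    prop = an.Proposition(item1=1, relation=inst, item2=0, frequency=1)
    return Trial(combo, prop)


def test_init_determinism_and_contract():
    cfg = an.NetworkConfig(n_first_role=5, n_second_role=5, seed=13)
    a, b = an.init_network(cfg), an.init_network(cfg)
    for name in a._MATRICES:
        arr = getattr(a, name)
        assert (arr == getattr(b, name)).all()
        assert np.abs(arr).max() <= cfg.init_range
    assert a.b_h == -2.0
    assert (a.b_a == 0).all() and (a.b_b == 0).all() and (a.b_r == 0).all()
    c = an.init_network(an.NetworkConfig(n_first_role=5, n_second_role=5, seed=14))
    assert (a.w_ah != c.w_ah).any()


def test_settle_zero_weights_converges_to_resting_logistic():
    """With zero weights an unclamped unit relaxes toward sigma(bias)."""
    cfg = an.NetworkConfig(n_first_role=3, n_second_role=3, n_relation=4,
                           n_hidden=2, init_range=0.0)
    w = an.init_network(cfg)
    trace = an.run_settle(w, {"A": np.eye(3)[0], "B": np.eye(3)[1]}, n_ticks=200)
    assert trace.h[-1] == pytest.approx(expit(-2.0), abs=1e-6)
    assert trace.r[-1] == pytest.approx(expit(0.0), abs=1e-6)


def test_settle_clamps_held_and_activations_bounded():
    cfg = an.NetworkConfig(n_first_role=4, n_second_role=4, n_relation=8,
                           n_hidden=5, seed=3)
    w = an.init_network(cfg)
    clamp = np.eye(4)[2]
    trace = an.run_settle(w, {"A": clamp}, n_ticks=30)
    assert (trace.a == clamp).all()
    for pool in (trace.a, trace.b, trace.r, trace.h):
        assert pool.min() >= 0.0 and pool.max() <= 1.0


def test_settle_rejects_bad_clamps():
    w = an.init_network(an.NetworkConfig(n_first_role=3, n_second_role=3))
    with pytest.raises(InvalidConfigError):
        an.run_settle(w, {"H": np.zeros(64)})
    with pytest.raises(InvalidConfigError):
        an.run_settle(w, {"A": np.zeros(5)})
    with pytest.raises(InvalidConfigError):
        an.run_settle(w, {"A": np.array([0.0, 2.0, 0.0])})


def test_bptt_zero_learning_rate_leaves_weights_unchanged():
    cfg = an.NetworkConfig(**{**TINY.__dict__, "lr": 0.0})
    w = an.init_network(cfg)
    before = w.copy()
    updated, loss = an.bptt_update(w, _tiny_trial(), cfg)
    assert loss > 0
    for name in w._MATRICES:
        assert (getattr(updated, name) == getattr(before, name)).all()


@pytest.mark.parametrize("combo", ["AB", "AR", "BR"])
def test_bptt_gradient_matches_finite_differences(combo):
    """Analytic BPTT gradients vs central differences on a <=20-unit network."""
    w = an.init_network(TINY)
    trial = _tiny_trial(combo)
    prop = trial.proposition
    ai, bi = np.array([prop.item1]), np.array([prop.item2])
    rpat = prop.relation.pattern[None, :].astype(float)
    combo_code = {"AB": 0, "AR": 1, "BR": 2}[combo]

    grads, _ = _bptt_batch_grads(w, combo_code, ai, bi, rpat, TINY)
    eps = 1e-6
    for name, g in grads.items():
        arr = getattr(w, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = float(_bptt_batch_grads(w, combo_code, ai, bi, rpat, TINY)[1].sum())
            arr[idx] = orig - eps
            lm = float(_bptt_batch_grads(w, combo_code, ai, bi, rpat, TINY)[1].sum())
            arr[idx] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(float(g[idx])), 1e-8)
            assert abs(fd - float(g[idx])) / denom < 1e-4, f"{name}{idx}"


def test_repeated_updates_descend_on_a_fixed_trial():
    cfg = an.NetworkConfig(**{**TINY.__dict__, "lr": 0.05})
    w = an.init_network(cfg)
    trial = _tiny_trial("AB")
    losses = []
    for _ in range(100):
        w, loss = an.bptt_update(w, trial, cfg, in_place=True)
        losses.append(loss)
    assert losses[-1] < 0.2 * losses[0]
    increases = sum(b > a + 1e-9 for a, b in zip(losses, losses[1:]))
    assert increases <= 5  # descent with at most occasional wiggles


def test_train_bookkeeping_and_determinism(small_env):
    cfg = an.network_config_for(small_env.config, seed=17)
    w1, hist1 = an.train(an.init_network(cfg), small_env, cfg, epochs=5)
    w2, hist2 = an.train(an.init_network(cfg), small_env, cfg, epochs=5)
    assert len(hist1) == 5
    assert [h["mean_loss"] for h in hist1] == [h["mean_loss"] for h in hist2]
    for name in w1._MATRICES:
        assert (getattr(w1, name) == getattr(w2, name)).all()
    assert hist1[-1]["mean_loss"] < hist1[0]["mean_loss"]


def test_hidden_bias_frozen_under_training(mini_trained):
    w, cfg, _ = mini_trained
    assert w.b_h == cfg.hidden_bias == -2.0


def test_eval_hook_cadence(small_env):
    cfg = an.network_config_for(small_env.config, seed=2)
    seen = []
    _, hist = an.train(
        an.init_network(cfg), small_env, cfg, epochs=6,
        eval_hook=lambda e, w: seen.append(e) or {"probe": e}, eval_every=2,
    )
    assert seen == [2, 4, 6]
    assert [h.get("probe") for h in hist] == [None, 2, None, 4, None, 6]


def test_trained_network_completes_relations(mini_trained, small_env):
    """Clamping A and B of a trained proposition settles the R pool onto that
    proposition's relation prototype: its cosine similarity is substantial
    and exceeds that of every prototype the two items were never trained
    with (items shared across propositions blend in their other relations)."""
    w, cfg, history = mini_trained
    assert history[-1]["mean_loss"] < history[0]["mean_loss"] / 5
    protos = small_env.protoset.patterns.astype(float)
    norms = np.linalg.norm(protos, axis=1)
    for cell in small_env.cells:
        p = cell.source
        linked = {
            q.relation.prototype_id
            for q in small_env.propositions
            if q.item1 == p.item1 or q.item2 == p.item2
        }
        a = np.eye(w.n_first_role)[p.item1]
        b = np.eye(w.n_second_role)[p.item2]
        trace = an.run_settle(w, {"A": a, "B": b}, n_ticks=cfg.n_ticks, lam=cfg.lam)
        r = trace.r[-1]
        sims = protos @ r / (norms * np.linalg.norm(r))
        own = p.relation.prototype_id
        assert sims[own] > 0.5
        for pid in range(len(protos)):
            if pid not in linked:
                assert sims[own] > sims[pid] + 0.3


def test_completion_error_small_after_training(mini_trained, small_env):
    w, cfg, _ = mini_trained
    assert an.completion_error(w, small_env, cfg) < 0.06


def test_lesion_mask_excludes_connections_from_training(small_env):
    cfg = an.network_config_for(small_env.config, seed=8)
    w = an.init_network(cfg)
    lesioned, mask = an.temporal_lesion(w, an.LesionSpec("temporal", seed=1))
    w2, _ = an.train(lesioned, small_env, cfg, epochs=2, weight_mask=mask)
    for name in w2._MATRICES:
        assert (getattr(w2, name)[getattr(mask, name) == 0] == 0).all()


def test_weights_roundtrip(tmp_path):
    w = an.init_network(an.NetworkConfig(n_first_role=4, n_second_role=4, seed=5))
    path = tmp_path / "w.npz"
    w.save(path)
    back = an.NetworkWeights.load(path)
    for name in w._MATRICES + w._BIASES:
        assert (getattr(back, name) == getattr(w, name)).all()
    assert back.b_h == w.b_h
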