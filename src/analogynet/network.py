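"""The trainable triple-completion network.

Four pools — A and B (localist item pools), R (distributed relation pool) and
H (hidden integrator) — are connected bidirectionally through six independent
directional weight matrices (A->H, H->A, B->H, H->B, R->H, H->R). Units are
logistic with leaky-integrator dynamics: on every tick a unit moves a fraction
``lam`` of the way from its current activation toward the logistic of its net
input. Unclamped units start at the logistic of their bias (resting state);
clamped units are held at their clamp value throughout.

Training presents two elements of a proposition triple clamped and asks the
network to settle into the third. The loss is the cross-entropy between the
target pool's activations and the target pattern, summed over the final
``target_ticks`` ticks of the settling trajectory, and gradients are taken by
backpropagation through the unrolled dynamics (BPTT). The hidden bias is a
single fixed scalar shared by all hidden units; it is the knob the frontal
lesion manipulates and it receives no gradient update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .environment import Environment, Trial, expand_epoch
from .errors import InvalidConfigError

__all__ = [
    "NetworkConfig",
    "NetworkWeights",
    "ActivationTrace",
    "init_network",
    "run_settle",
    "bptt_update",
    "train",
    "completion_error",
]

_EPS = 1e-12
_COMBO_CODE = {"AB": 0, "AR": 1, "BR": 2}


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, dynamics and learning hyperparameters.

    ``hidden_bias`` is the fixed shared bias on hidden units; -2 is the
    unlesioned operating point. The remaining defaults (hidden-pool size,
    tick counts, step size, learning rate, batch size) are the package's
    operating point, chosen so that training on the default environment
    settles reliably and reproduces the developmental trajectory; all are
    overridable.
    """

    n_first_role: int
    n_second_role: int
    n_relation: int = 128
    n_hidden: int = 64
    hidden_bias: float = -2.0
    lr: float = 0.016
    n_ticks: int = 20
    target_ticks: int = 5
    lam: float = 0.2
    init_range: float = 0.25
    weight_decay: float = 0.0
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_first_role, self.n_second_role, self.n_relation, self.n_hidden) <= 0:
            raise InvalidConfigError("pool sizes must be positive")
        if not (0 < self.lam <= 1):
            raise InvalidConfigError("lam must be in (0, 1]")
        if not (1 <= self.target_ticks <= self.n_ticks):
            raise InvalidConfigError("need 1 <= target_ticks <= n_ticks")
        if self.batch_size < 1 or self.lr < 0:
            raise InvalidConfigError("batch_size must be >= 1 and lr >= 0")


@dataclass
class NetworkWeights:
    """Six directional weight matrices plus biases.

    Matrix ``w_xy`` maps pool x to pool y net input and has shape
    (n_y, n_x). Visible-pool biases are learned vectors; the hidden bias is
    a fixed scalar.
    """

    w_ah: np.ndarray  # (n_hidden, n_first_role)
    w_ha: np.ndarray  # (n_first_role, n_hidden)
    w_bh: np.ndarray  # (n_hidden, n_second_role)
    w_hb: np.ndarray  # (n_second_role, n_hidden)
    w_rh: np.ndarray  # (n_hidden, n_relation)
    w_hr: np.ndarray  # (n_relation, n_hidden)
    b_a: np.ndarray
    b_b: np.ndarray
    b_r: np.ndarray
    b_h: float

    _MATRICES = ("w_ah", "w_ha", "w_bh", "w_hb", "w_rh", "w_hr")
    _BIASES = ("b_a", "b_b", "b_r")

    @property
    def n_first_role(self) -> int:
        return self.w_ah.shape[1]

    @property
    def n_second_role(self) -> int:
        return self.w_bh.shape[1]

    @property
    def n_relation(self) -> int:
        return self.w_rh.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_ah.shape[0]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            **{name: getattr(self, name).copy() for name in self._MATRICES + self._BIASES},
            b_h=self.b_h,
        )

    def matrix_checksum(self) -> float:
        """Sum of all connection weights; invariant under bias-only changes."""
        return float(sum(getattr(self, name).sum() for name in self._MATRICES))

    def save(self, path) -> None:
        np.savez(
            path,
            **{name: getattr(self, name) for name in self._MATRICES + self._BIASES},
            b_h=np.float64(self.b_h),
        )

    @classmethod
    def load(cls, path) -> "NetworkWeights":
        with np.load(path) as data:
            kwargs = {name: data[name] for name in cls._MATRICES + cls._BIASES}
            return cls(**kwargs, b_h=float(data["b_h"]))


@dataclass(frozen=True)
class ActivationTrace:
    """Per-tick activations for each pool; row 0 is the initial state."""

    a: np.ndarray  # (n_ticks + 1, n_first_role)
    b: np.ndarray
    r: np.ndarray
    h: np.ndarray


def init_network(cfg: NetworkConfig) -> NetworkWeights:
    """Uniform weights in [-init_range, +init_range], zero visible biases,
    fixed hidden bias. Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    r = cfg.init_range

    def u(n_out: int, n_in: int) -> np.ndarray:
        return rng.uniform(-r, r, size=(n_out, n_in))

    nA, nB, nR, nH = cfg.n_first_role, cfg.n_second_role, cfg.n_relation, cfg.n_hidden
    return NetworkWeights(
        w_ah=u(nH, nA),
        w_ha=u(nA, nH),
        w_bh=u(nH, nB),
        w_hb=u(nB, nH),
        w_rh=u(nH, nR),
        w_hr=u(nR, nH),
        b_a=np.zeros(nA),
        b_b=np.zeros(nB),
        b_r=np.zeros(nR),
        b_h=cfg.hidden_bias,
    )


def run_settle(
    w: NetworkWeights,
    clamps: dict[str, np.ndarray],
    n_ticks: int = 20,
    lam: float = 0.2,
) -> ActivationTrace:
    """Settle the four-pool network with the given pools clamped.

    ``clamps`` maps pool names ("A", "B", "R") to clamp patterns in [0, 1].
    Unclamped pools start at the logistic of their bias and follow the leaky
    logistic update; clamped pools are held fixed at every tick.
    """
    sizes = {"A": w.n_first_role, "B": w.n_second_role, "R": w.n_relation, "H": w.n_hidden}
    for pool, pattern in clamps.items():
        if pool not in ("A", "B", "R"):
            raise InvalidConfigError(f"cannot clamp unknown pool {pool!r}")
        pattern = np.asarray(pattern, dtype=float)
        if pattern.shape != (sizes[pool],):
            raise InvalidConfigError(f"clamp for pool {pool} has wrong shape {pattern.shape}")
        if pattern.min() < 0 or pattern.max() > 1:
            raise InvalidConfigError("clamp values must lie in [0, 1]")

    acts = {
        "A": np.asarray(clamps["A"], dtype=float) if "A" in clamps else expit(w.b_a),
        "B": np.asarray(clamps["B"], dtype=float) if "B" in clamps else expit(w.b_b),
        "R": np.asarray(clamps["R"], dtype=float) if "R" in clamps else expit(w.b_r),
        "H": np.full(sizes["H"], expit(w.b_h)),
    }
    trace = {pool: [acts[pool].copy()] for pool in acts}
    for _ in range(n_ticks):
        net_h = w.w_ah @ acts["A"] + w.w_bh @ acts["B"] + w.w_rh @ acts["R"] + w.b_h
        nets = {
            "A": w.w_ha @ acts["H"] + w.b_a,
            "B": w.w_hb @ acts["H"] + w.b_b,
            "R": w.w_hr @ acts["H"] + w.b_r,
            "H": net_h,
        }
        for pool in acts:
            if pool in clamps:
                continue
            acts[pool] = acts[pool] + lam * (expit(nets[pool]) - acts[pool])
        for pool in acts:
            trace[pool].append(acts[pool].copy())
    return ActivationTrace(
        a=np.array(trace["A"]), b=np.array(trace["B"]), r=np.array(trace["R"]), h=np.array(trace["H"])
    )


def _cross_entropy(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    a = np.clip(a, _EPS, 1.0 - _EPS)
    return -(y * np.log(a) + (1.0 - y) * np.log1p(-a)).sum(axis=-1)


def _cross_entropy_grad(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    a = np.clip(a, _EPS, 1.0 - _EPS)
    return (a - y) / (a * (1.0 - a))


def _settle_fwd_bwd(
    w_th: np.ndarray,
    w_ht: np.ndarray,
    b_t: np.ndarray,
    b_h: float,
    const_h: np.ndarray,
    y: np.ndarray,
    cfg: NetworkConfig,
):
    """Forward settle and BPTT backward pass for a homogeneous batch.

    The batch shares one input combination, so only the completion-target
    pool T and the hidden pool H evolve; the two clamped pools enter through
    the per-trial constant hidden net input ``const_h``. Returns per-trial
    losses, gradients for the T<->H matrices and target bias, and the
    per-trial sum over ticks of dL/d(net_H) (used by the caller to form the
    clamped-pool -> H weight gradients, whose source activations are constant
    across ticks).
    """
    lam, n_ticks, k = cfg.lam, cfg.n_ticks, cfg.target_ticks
    B = const_h.shape[0]
    nH = w_th.shape[0]
    aH = np.full((B, nH), expit(b_h))
    aT0 = expit(np.broadcast_to(b_t, (B, b_t.shape[0])).copy())
    aT = aT0.copy()

    aH_hist = [aH]
    aT_hist = [aT]
    sH_hist: list[np.ndarray] = []
    sT_hist: list[np.ndarray] = []
    for _ in range(n_ticks):
        sH = expit(const_h + aT @ w_th.T + b_h)
        sT = expit(aH @ w_ht.T + b_t)
        aH = aH + lam * (sH - aH)
        aT = aT + lam * (sT - aT)
        sH_hist.append(sH)
        sT_hist.append(sT)
        aH_hist.append(aH)
        aT_hist.append(aT)

    losses = np.zeros(B)
    for t in range(n_ticks - k + 1, n_ticks + 1):
        losses += _cross_entropy(aT_hist[t], y)

    gT = np.zeros_like(aT)
    gH = np.zeros_like(aH)
    g_w_ht = np.zeros_like(w_ht)
    g_w_th = np.zeros_like(w_th)
    g_b_t = np.zeros_like(b_t)
    dnet_h_sum = np.zeros((B, nH))
    for t in range(n_ticks, 0, -1):
        if t > n_ticks - k:
            gT = gT + _cross_entropy_grad(aT_hist[t], y)
        sT = sT_hist[t - 1]
        sH = sH_hist[t - 1]
        dnet_t = gT * lam * sT * (1.0 - sT)
        dnet_h = gH * lam * sH * (1.0 - sH)
        g_w_ht += dnet_t.T @ aH_hist[t - 1]
        g_w_th += dnet_h.T @ aT_hist[t - 1]
        g_b_t += dnet_t.sum(axis=0)
        dnet_h_sum += dnet_h
        gT = gT * (1.0 - lam) + dnet_h @ w_th
        gH = gH * (1.0 - lam) + dnet_t @ w_ht
    # the resting state aT(0) = logistic(b_t) also depends on the target bias
    g_b_t += (gT * aT0 * (1.0 - aT0)).sum(axis=0)
    return losses, g_w_ht, g_w_th, g_b_t, dnet_h_sum


def _scatter_columns(grad: np.ndarray, cols: np.ndarray, rows: np.ndarray) -> None:
    """grad[:, cols[b]] += rows[b] for every batch element b."""
    acc = np.zeros((grad.shape[1], grad.shape[0]))
    np.add.at(acc, cols, rows)
    grad += acc.T


def _bptt_batch_grads(
    w: NetworkWeights,
    combo: int,
    ai: np.ndarray,
    bi: np.ndarray,
    rpat: np.ndarray,
    cfg: NetworkConfig,
):
    """Gradients and losses for a batch sharing one input combination.

    combo 0: A, B clamped (one-hot), complete R;
    combo 1: A, R clamped, complete B;
    combo 2: B, R clamped, complete A.
    """
    B = ai.shape[0] if combo != 2 else bi.shape[0]
    grads: dict[str, np.ndarray] = {}
    if combo == 0:
        const_h = w.w_ah[:, ai].T + w.w_bh[:, bi].T
        losses, g_hr, g_rh, g_br, dnh = _settle_fwd_bwd(
            w.w_rh, w.w_hr, w.b_r, w.b_h, const_h, rpat, cfg
        )
        grads["w_hr"], grads["w_rh"], grads["b_r"] = g_hr, g_rh, g_br
        grads["w_ah"] = np.zeros_like(w.w_ah)
        _scatter_columns(grads["w_ah"], ai, dnh)
        grads["w_bh"] = np.zeros_like(w.w_bh)
        _scatter_columns(grads["w_bh"], bi, dnh)
    elif combo == 1:
        const_h = w.w_ah[:, ai].T + rpat @ w.w_rh.T
        y = np.zeros((B, w.n_second_role))
        y[np.arange(B), bi] = 1.0
        losses, g_hb, g_bh, g_bb, dnh = _settle_fwd_bwd(
            w.w_bh, w.w_hb, w.b_b, w.b_h, const_h, y, cfg
        )
        grads["w_hb"], grads["w_bh"], grads["b_b"] = g_hb, g_bh, g_bb
        grads["w_ah"] = np.zeros_like(w.w_ah)
        _scatter_columns(grads["w_ah"], ai, dnh)
        grads["w_rh"] = dnh.T @ rpat
    else:
        const_h = w.w_bh[:, bi].T + rpat @ w.w_rh.T
        y = np.zeros((B, w.n_first_role))
        y[np.arange(B), ai] = 1.0
        losses, g_ha, g_ah, g_ba, dnh = _settle_fwd_bwd(
            w.w_ah, w.w_ha, w.b_a, w.b_h, const_h, y, cfg
        )
        grads["w_ha"], grads["w_ah"], grads["b_a"] = g_ha, g_ah, g_ba
        grads["w_bh"] = np.zeros_like(w.w_bh)
        _scatter_columns(grads["w_bh"], bi, dnh)
        grads["w_rh"] = dnh.T @ rpat
    return grads, losses


def _apply_grads(
    w: NetworkWeights,
    grads: dict[str, np.ndarray],
    lr: float,
    batch: int,
    weight_mask=None,
    weight_decay: float = 0.0,
) -> None:
    shrink = 1.0 - lr * weight_decay
    for name, g in grads.items():
        arr = getattr(w, name)
        arr -= (lr / batch) * g
        if weight_decay and name in NetworkWeights._MATRICES:
            arr *= shrink
        if weight_mask is not None and name in NetworkWeights._MATRICES:
            arr *= getattr(weight_mask, name)


def bptt_update(
    w: NetworkWeights, trial: Trial, cfg: NetworkConfig, in_place: bool = False
) -> tuple[NetworkWeights, float]:
    """One BPTT gradient step on a single trial; returns (weights, loss).

    The hidden bias receives no update. With ``lr=0`` the weights are
    returned unchanged (loss still computed).
    """
    if not in_place:
        w = w.copy()
    prop = trial.proposition
    combo = _COMBO_CODE[trial.input_combo]
    ai = np.array([prop.item1])
    bi = np.array([prop.item2])
    rpat = prop.relation.pattern[None, :].astype(float)
    grads, losses = _bptt_batch_grads(w, combo, ai, bi, rpat, cfg)
    loss = float(losses[0])
    if not np.isfinite(loss) or any(not np.isfinite(g).all() for g in grads.values()):
        raise FloatingPointError(
            f"non-finite loss/gradient on trial {trial.input_combo} "
            f"({prop.item1}, proto {prop.relation.prototype_id}, {prop.item2}): loss={loss}"
        )
    if cfg.lr > 0:
        _apply_grads(w, grads, cfg.lr, 1)
    return w, loss


def _proposition_arrays(env: Environment):
    props = env.propositions
    item1 = np.array([p.item1 for p in props])
    item2 = np.array([p.item2 for p in props])
    rpat = np.array([p.relation.pattern for p in props], dtype=float)
    freq = np.array([p.frequency for p in props])
    return item1, item2, rpat, freq


def train(
    w: NetworkWeights,
    env: Environment,
    cfg: NetworkConfig,
    epochs: int,
    eval_hook: Optional[Callable[[int, NetworkWeights], dict]] = None,
    eval_every: int = 10,
    weight_mask=None,
    seed: Optional[int] = None,
) -> tuple[NetworkWeights, list[dict]]:
    """Train in place for ``epochs`` epochs; returns (weights, history).

    Each epoch presents every proposition ``frequency`` times in each of the
    three input combinations, in an order shuffled by a per-epoch seed derived
    from the master seed. Trials are grouped into homogeneous-combination
    mini-batches of ``cfg.batch_size`` and the mean batch gradient is applied
    after each batch. ``history`` holds one record per epoch with the mean
    per-trial loss; when ``eval_hook`` is given it is invoked every
    ``eval_every`` epochs and its dict is merged into that epoch's record.
    If ``weight_mask`` is given (a lesion mask), masked connections are
    re-zeroed after every update so they take no further part in learning.
    """
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    item1, item2, rpat, freq = _proposition_arrays(env)
    # static per-trial proposition index; one copy per unit of frequency
    prop_idx = np.repeat(np.arange(len(freq)), freq)
    n_per_combo = prop_idx.shape[0]

    history: list[dict] = []
    for epoch in range(1, epochs + 1):
        rng = np.random.default_rng(master.spawn(1)[0])
        # independent shuffles per combination, then batches interleaved
        batches: list[tuple[int, np.ndarray]] = []
        for combo in range(3):
            order = rng.permutation(n_per_combo)
            for start in range(0, n_per_combo, cfg.batch_size):
                batches.append((combo, prop_idx[order[start : start + cfg.batch_size]]))
        batch_order = rng.permutation(len(batches))

        total_loss = 0.0
        for k in batch_order:
            combo, idx = batches[k]
            grads, losses = _bptt_batch_grads(
                w, combo, item1[idx], item2[idx], rpat[idx], cfg
            )
            total_loss += float(losses.sum())
            if not np.isfinite(total_loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            if cfg.lr > 0:
                _apply_grads(w, grads, cfg.lr, len(idx), weight_mask, cfg.weight_decay)
        record = {"epoch": epoch, "mean_loss": total_loss / (3 * n_per_combo)}
        if eval_hook is not None and epoch % eval_every == 0:
            record.update(eval_hook(epoch, w))
        history.append(record)
    return w, history


def completion_error(w: NetworkWeights, env: Environment, cfg: NetworkConfig) -> float:
    """Mean per-unit absolute completion error over all propositions and
    input combinations, measured at the final settling tick."""
    item1, item2, rpat, _ = _proposition_arrays(env)
    n = len(item1)
    err_sum = 0.0
    unit_count = 0
    for combo in range(3):
        a_fin = _settle_forward_only(w, combo, item1, item2, rpat, cfg)
        if combo == 0:
            y = rpat
        else:
            size = w.n_second_role if combo == 1 else w.n_first_role
            ids = item2 if combo == 1 else item1
            y = np.zeros((n, size))
            y[np.arange(n), ids] = 1.0
        err_sum += float(np.abs(a_fin - y).sum())
        unit_count += y.size
    return err_sum / unit_count


def _settle_forward_only(
    w: NetworkWeights, combo: int, ai: np.ndarray, bi: np.ndarray, rpat: np.ndarray, cfg: NetworkConfig
) -> np.ndarray:
    """Batched forward settle; returns the target pool's final activations."""
    if combo == 0:
        const_h = w.w_ah[:, ai].T + w.w_bh[:, bi].T
        w_th, w_ht, b_t = w.w_rh, w.w_hr, w.b_r
    elif combo == 1:
        const_h = w.w_ah[:, ai].T + rpat @ w.w_rh.T
        w_th, w_ht, b_t = w.w_bh, w.w_hb, w.b_b
    else:
        const_h = w.w_bh[:, bi].T + rpat @ w.w_rh.T
        w_th, w_ht, b_t = w.w_ah, w.w_ha, w.b_a
    B = const_h.shape[0]
    aH = np.full((B, w.n_hidden), expit(w.b_h))
    aT = np.tile(expit(b_t), (B, 1))
    for _ in range(cfg.n_ticks):
        sH = expit(const_h + aT @ w_th.T + w.b_h)
        sT = expit(aH @ w_ht.T + b_t)
        aH = aH + cfg.lam * (sH - aH)
        aT = aT + cfg.lam * (sT - aT)
    return aT
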