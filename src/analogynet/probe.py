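"""Twin testing architecture and the echo-based forced-choice procedure.

Testing uses two weight-tied copies of the trained network that share one
relation pool: pools A, B feed hidden pool H1 and pools C, D feed hidden pool
H2, with C using the A-side weights and D the B-side weights. Both hidden
pools project onto the single shared R pool with their contribution halved,
so that when the two halves agree the R pool receives a net input of the same
magnitude it experienced during training (2 x 0.5 = 1).

A question A:B::C:[D1|D2] is answered by two independent *echo trials*, one
per alternative. In phase 1 the items a, b, c and the candidate d are clamped
one-hot and the network settles; in phase 2 the D clamp is released — the pool
keeps its current state rather than being flushed — while a, b, c stay
clamped, and the network settles further. The *echo* is the residual
activation of the candidate's unit at the final tick: if the A:B and C:d
relations complete consistent patterns in the shared R pool, the partially
filled relation keeps supporting the candidate unit; otherwise its activation
decays. The alternative with the stronger echo is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .environment import AnalogyQuestion
from .errors import InvalidConfigError
from .network import NetworkWeights

__all__ = [
    "TwinState",
    "ProbeConfig",
    "EchoResult",
    "build_twin",
    "echo_trial",
    "answer_question",
    "evaluate",
    "probe_table",
]


@dataclass(frozen=True)
class TwinState:
    """Two weight-tied halves (A,B,H1 / C,D,H2) sharing one relation pool.

    Both halves read the same :class:`NetworkWeights` object, so a change to
    the weights (including a lesion that zeroes entries) is seen identically
    by both. ``h1_bias_override`` replaces the hidden bias in H1 only (the
    frontal-lesion knob); ``lesion_mask`` records which connections a
    temporal lesion removed, for auditing.
    """

    weights: NetworkWeights
    h_to_r_scale: float = 0.5
    h1_bias_override: Optional[float] = None
    lesion_mask: Optional[object] = None

    @property
    def h1_bias(self) -> float:
        return self.weights.b_h if self.h1_bias_override is None else self.h1_bias_override

    @property
    def h2_bias(self) -> float:
        return self.weights.b_h


@dataclass(frozen=True)
class ProbeConfig:
    """Echo-procedure parameters: clamped and post-release settling ticks,
    activation step size, and the seed feeding the deterministic tie rule."""

    phase1_ticks: int = 2
    phase2_ticks: int = 25
    lam: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase1_ticks < 1 or self.phase2_ticks < 1:
            raise InvalidConfigError("both tick counts must be >= 1")


@dataclass(frozen=True)
class EchoResult:
    echo_d1: float
    echo_d2: float
    choice: int
    correct: bool


def build_twin(w: NetworkWeights, h_to_r_scale: float = 0.5) -> TwinState:
    """Wrap trained (or untrained) weights into the testing configuration."""
    return TwinState(weights=w, h_to_r_scale=h_to_r_scale)


def _echo_batch(
    twin: TwinState,
    ai: np.ndarray,
    bi: np.ndarray,
    ci: np.ndarray,
    di: np.ndarray,
    cfg: ProbeConfig,
    return_states: bool = False,
):
    """Echoes for a batch of (a, b, c, d) item quadruples.

    Runs the shared-relation twin dynamics: phase 1 with d clamped, phase 2
    with the D pool released but retaining its state. Returns the final
    activation of each trial's candidate unit (and, when ``return_states``,
    the final pool activations for auditing).
    """
    w = twin.weights
    n_second = w.n_second_role
    for name, idx, bound in (
        ("a", ai, w.n_first_role),
        ("b", bi, n_second),
        ("c", ci, w.n_first_role),
        ("d", di, n_second),
    ):
        if np.any(idx < 0) or np.any(idx >= bound):
            raise InvalidConfigError(f"item id out of range for pool {name}")

    B = ai.shape[0]
    scale = twin.h_to_r_scale
    aR = np.tile(expit(w.b_r), (B, 1))
    aH1 = np.full((B, w.n_hidden), expit(twin.h1_bias))
    aH2 = np.full((B, w.n_hidden), expit(twin.h2_bias))
    aD = np.zeros((B, n_second))
    aD[np.arange(B), di] = 1.0

    const_h1 = w.w_ah[:, ai].T + w.w_bh[:, bi].T  # A and B clamped one-hot
    const_h2 = w.w_ah[:, ci].T  # C clamped; D contributes dynamically
    lam = cfg.lam
    for tick in range(cfg.phase1_ticks + cfg.phase2_ticks):
        clamped_d = tick < cfg.phase1_ticks
        sH1 = expit(const_h1 + aR @ w.w_rh.T + twin.h1_bias)
        sH2 = expit(const_h2 + aD @ w.w_bh.T + aR @ w.w_rh.T + twin.h2_bias)
        sR = expit(scale * (aH1 + aH2) @ w.w_hr.T + w.b_r)
        if not clamped_d:
            sD = expit(aH2 @ w.w_hb.T + w.b_b)
            aD = aD + lam * (sD - aD)
        aH1 = aH1 + lam * (sH1 - aH1)
        aH2 = aH2 + lam * (sH2 - aH2)
        aR = aR + lam * (sR - aR)
    echoes = aD[np.arange(B), di]
    if return_states:
        return echoes, {"h1": aH1, "h2": aH2, "r": aR, "d": aD}
    return echoes


def echo_trial(twin: TwinState, a: int, b: int, c: int, d: int, cfg: ProbeConfig) -> float:
    """Echo of candidate ``d`` for the partial analogy a:b::c:d."""
    return float(
        _echo_batch(
            twin, np.array([a]), np.array([b]), np.array([c]), np.array([d]), cfg
        )[0]
    )


def _tie_break(q: AnalogyQuestion, cfg: ProbeConfig) -> int:
    """Deterministic pseudo-random coin for an exact echo tie."""
    rng = np.random.default_rng([cfg.seed, q.a, q.b, q.c, q.d1, q.d2])
    return int(rng.integers(2))


def answer_question(twin: TwinState, q: AnalogyQuestion, cfg: ProbeConfig) -> EchoResult:
    """Run the two echo trials of a question and pick the stronger echo.

    Both trials start from identical initial conditions and differ only in
    which alternative is clamped on the D pool.
    """
    echoes = _echo_batch(
        twin,
        np.array([q.a, q.a]),
        np.array([q.b, q.b]),
        np.array([q.c, q.c]),
        np.array([q.d1, q.d2]),
        cfg,
    )
    e1, e2 = float(echoes[0]), float(echoes[1])
    if e1 == e2:
        pick = _tie_break(q, cfg)
    else:
        pick = 0 if e1 > e2 else 1
    choice = q.d1 if pick == 0 else q.d2
    return EchoResult(echo_d1=e1, echo_d2=e2, choice=choice, correct=(pick == 0))


def _as_twin(net_or_twin) -> TwinState:
    if isinstance(net_or_twin, TwinState):
        return net_or_twin
    if isinstance(net_or_twin, NetworkWeights):
        return build_twin(net_or_twin)
    raise TypeError(f"expected NetworkWeights or TwinState, got {type(net_or_twin)!r}")


def probe_table(
    net_or_twin, questions: Sequence[AnalogyQuestion], cfg: ProbeConfig
) -> pd.DataFrame:
    """Per-question echoes, choices and correctness, one row per question."""
    twin = _as_twin(net_or_twin)
    if len(questions) == 0:
        raise InvalidConfigError("question set is empty")
    qa = np.array([[q.a, q.b, q.c, q.d1, q.d2] for q in questions])
    # one batch with both alternatives of every question
    echoes = _echo_batch(
        twin,
        np.concatenate([qa[:, 0], qa[:, 0]]),
        np.concatenate([qa[:, 1], qa[:, 1]]),
        np.concatenate([qa[:, 2], qa[:, 2]]),
        np.concatenate([qa[:, 3], qa[:, 4]]),
        cfg,
    )
    n = len(questions)
    e1, e2 = echoes[:n], echoes[n:]
    pick = np.where(e1 > e2, 0, np.where(e1 < e2, 1, -1))
    for i in np.flatnonzero(pick == -1):
        pick[i] = _tie_break(questions[i], cfg)
    return pd.DataFrame(
        {
            "cell": [q.cell_index for q in questions],
            "sfi_label": [q.sfi_label for q in questions],
            "echo_d1": e1,
            "echo_d2": e2,
            "choice": np.where(pick == 0, qa[:, 3], qa[:, 4]),
            "correct": pick == 0,
        }
    )


def evaluate(
    net_or_twin, questions: Sequence[AnalogyQuestion], cfg: ProbeConfig
) -> dict[str, float]:
    """Fraction of questions answered correctly, overall and per SFI label."""
    table = probe_table(net_or_twin, questions, cfg)
    out = {"accuracy_overall": float(table["correct"].mean())}
    for label in ("positive", "zero", "negative"):
        sub = table[table["sfi_label"] == label]
        out[f"accuracy_{label}"] = float(sub["correct"].mean()) if len(sub) else float("nan")
    return out
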