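"""Frontal and temporal lesion operators for a trained network.

The *frontal* lesion models loss of context maintenance: the fixed bias on
the H1 pool (the hidden pool mediating the A:B half of the analogy) is
reduced from its unlesioned value of -2 to -6.5, suppressing H1 activation so
the shared relation pool is driven mostly by the C:D half — and responding
reverts to association strength. It changes exactly one scalar and is applied
at test time only.

The *temporal* lesion models degraded pattern completion: every connection in
each of the six directional weight matrices is independently zeroed with
probability ``p_remove`` (default .42). Because the twin's two halves share
one weight container, the lesion is identical in both halves by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np

from .errors import InvalidConfigError
from .network import NetworkWeights
from .probe import TwinState

__all__ = ["LesionSpec", "WeightMask", "frontal_lesion", "temporal_lesion"]


@dataclass(frozen=True)
class LesionSpec:
    kind: Literal["frontal", "temporal"]
    frontal_bias: float = -6.5
    p_remove: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("frontal", "temporal"):
            raise InvalidConfigError(f"unknown lesion kind {self.kind!r}")
        if not (0.0 <= self.p_remove <= 1.0):
            raise InvalidConfigError("p_remove must lie in [0, 1]")


@dataclass(frozen=True)
class WeightMask:
    """Binary keep-masks, one per directional weight matrix (1 = kept)."""

    w_ah: np.ndarray
    w_ha: np.ndarray
    w_bh: np.ndarray
    w_hb: np.ndarray
    w_rh: np.ndarray
    w_hr: np.ndarray

    def removed_fraction(self) -> float:
        total = sum(getattr(self, n).size for n in NetworkWeights._MATRICES)
        kept = sum(getattr(self, n).sum() for n in NetworkWeights._MATRICES)
        return 1.0 - float(kept) / total

    def save(self, path) -> None:
        np.savez(path, **{n: getattr(self, n) for n in NetworkWeights._MATRICES})

    @classmethod
    def load(cls, path) -> "WeightMask":
        with np.load(path) as data:
            return cls(**{n: data[n] for n in NetworkWeights._MATRICES})


def frontal_lesion(twin: TwinState, spec: LesionSpec) -> TwinState:
    """Set the H1 bias to ``spec.frontal_bias``; H2 and all weights untouched.

    Reversible: re-applying with the unlesioned bias value restores control
    behavior exactly.
    """
    if not isinstance(twin, TwinState):
        raise InvalidConfigError("frontal lesion applies to a built TwinState")
    if spec.kind != "frontal":
        raise InvalidConfigError(f"spec kind is {spec.kind!r}, expected 'frontal'")
    return replace(twin, h1_bias_override=spec.frontal_bias)


def temporal_lesion(
    w: NetworkWeights, spec: LesionSpec
) -> tuple[NetworkWeights, WeightMask]:
    """Zero each connection independently with probability ``spec.p_remove``.

    Returns a lesioned copy of the weights and the keep-mask (for auditing
    and for excluding removed connections from any further training). Biases
    are not projections and are left intact. Deterministic given the spec's
    seed.
    """
    if spec.kind != "temporal":
        raise InvalidConfigError(f"spec kind is {spec.kind!r}, expected 'temporal'")
    rng = np.random.default_rng(spec.seed)
    lesioned = w.copy()
    masks = {}
    for name in NetworkWeights._MATRICES:
        arr = getattr(lesioned, name)
        keep = (rng.random(arr.shape) >= spec.p_remove).astype(float)
        arr *= keep
        masks[name] = keep
    return lesioned, WeightMask(**masks)
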