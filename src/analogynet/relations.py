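"""Distributed relation codes: disjoint prototypes and deletion-derived instances.

A relation is a binary pattern over a fixed pool of units. A *prototype* is a
canonical pattern with ``n_active`` units on; an *instance* of that prototype
is obtained by turning off ``n_off`` of its active units. Instances of the same
prototype are therefore highly similar (with disjoint off-sets they share
``n_active - 2 * n_off`` active units) while instances of different prototypes
share no active units at all, because prototypes are built on disjoint blocks
of the unit pool. The graded overlap between instances is what lets a
pattern-completion network treat same-prototype relations as "the same
relation" for analogy purposes without requiring them to be identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DimensionMismatchError, InvalidConfigError, OffPairExhaustionError

__all__ = [
    "RelationSpaceConfig",
    "PrototypeSet",
    "RelationInstance",
    "generate_prototypes",
    "generate_instance",
    "relation_overlap",
]


@dataclass(frozen=True)
class RelationSpaceConfig:
    """Parameters of the relation code.

    Defaults give 8 prototypes of 16 active units that exactly tile 128
    relation units, with 2-unit deletions per instance (so instances carry
    14 active units and same-prototype instances with disjoint deletions
    share 12).
    """

    n_units: int = 128
    n_prototypes: int = 8
    n_active: int = 16
    n_off: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_units, self.n_prototypes, self.n_active) <= 0 or self.n_off < 0:
            raise InvalidConfigError("relation-space counts must be positive")
        if self.n_prototypes * self.n_active > self.n_units:
            raise InvalidConfigError(
                f"{self.n_prototypes} prototypes x {self.n_active} active units "
                f"do not fit disjointly in {self.n_units} units"
            )
        if self.n_off >= self.n_active:
            raise InvalidConfigError("n_off must be smaller than n_active")


@dataclass(frozen=True)
class PrototypeSet:
    """The prototype patterns, one binary row vector per prototype."""

    patterns: np.ndarray  # (n_prototypes, n_units) uint8
    config: RelationSpaceConfig

    @property
    def n_prototypes(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]

    def active_units(self, prototype_id: int) -> np.ndarray:
        """Sorted indices of the active units of one prototype."""
        return np.flatnonzero(self.patterns[prototype_id])

    def to_json(self) -> str:
        payload = {
            "n_units": self.n_units,
            "active_units": [self.active_units(p).tolist() for p in range(self.n_prototypes)],
            "config": self.config.__dict__,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PrototypeSet":
        payload = json.loads(text)
        cfg = RelationSpaceConfig(**payload["config"])
        patterns = np.zeros((len(payload["active_units"]), payload["n_units"]), dtype=np.uint8)
        for p, units in enumerate(payload["active_units"]):
            patterns[p, units] = 1
        return cls(patterns=patterns, config=cfg)


@dataclass(frozen=True)
class RelationInstance:
    """A prototype pattern with ``n_off`` active units turned off."""

    prototype_id: int
    off_pair: tuple[int, ...]
    pattern: np.ndarray  # (n_units,) uint8

    @property
    def n_active(self) -> int:
        return int(self.pattern.sum())

    def to_dict(self) -> dict:
        return {"prototype_id": self.prototype_id, "off_pair": list(self.off_pair)}

    @classmethod
    def from_dict(cls, d: dict, protoset: PrototypeSet) -> "RelationInstance":
        pattern = protoset.patterns[d["prototype_id"]].copy()
        pattern[list(d["off_pair"])] = 0
        return cls(d["prototype_id"], tuple(sorted(d["off_pair"])), pattern)


def generate_prototypes(cfg: RelationSpaceConfig) -> PrototypeSet:
    """Draw a prototype set: disjoint blocks of a random unit permutation.

    Chunking a permutation guarantees zero pairwise overlap by construction;
    with the defaults (8 x 16 = 128) the prototypes exactly tile the pool.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(cfg.n_units)
    patterns = np.zeros((cfg.n_prototypes, cfg.n_units), dtype=np.uint8)
    for p in range(cfg.n_prototypes):
        block = perm[p * cfg.n_active : (p + 1) * cfg.n_active]
        patterns[p, block] = 1
    return PrototypeSet(patterns=patterns, config=cfg)


def generate_instance(
    protoset: PrototypeSet,
    prototype_id: int,
    used_pairs: Iterable[Sequence[int]],
    cfg: RelationSpaceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RelationInstance:
    """Draw an instance whose off-units avoid every pair in ``used_pairs``.

    The off-units of distinct instances drawn under one bookkeeping scope are
    disjoint, so two instances of the same prototype always differ in which
    units were deleted. Raises :class:`OffPairExhaustionError` once the
    prototype's active set no longer contains ``n_off`` unused units (e.g. a
    9th disjoint request on a 16-active / 2-off prototype).
    """
    cfg = cfg or protoset.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    active = protoset.active_units(prototype_id)
    used = {u for pair in used_pairs for u in pair}
    available = np.array([u for u in active if u not in used])
    if available.size < cfg.n_off:
        raise OffPairExhaustionError(
            f"prototype {prototype_id}: only {available.size} unused active units "
            f"remain, need {cfg.n_off}"
        )
    off = tuple(sorted(rng.choice(available, size=cfg.n_off, replace=False).tolist()))
    pattern = protoset.patterns[prototype_id].copy()
    pattern[list(off)] = 0
    return RelationInstance(prototype_id=prototype_id, off_pair=off, pattern=pattern)


def relation_overlap(r1: RelationInstance, r2: RelationInstance) -> int:
    """Number of active units shared by two relation instances (symmetric)."""
    if r1.pattern.shape != r2.pattern.shape:
        raise DimensionMismatchError(
            f"patterns of length {r1.pattern.shape[0]} and {r2.pattern.shape[0]}"
        )
    return int(np.sum(r1.pattern.astype(bool) & r2.pattern.astype(bool)))
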