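"""The synthetic training environment: counterbalanced cells of propositions.

The environment is a set of item1-relation-item2 *propositions* organized into
*cells*. Each cell holds one source proposition A:R1:B, one relational target
C:R1':D1 (R1 and R1' are instances of the same prototype), and three foil
propositions C:R2:D2 / C:R3:D3 / C:R4:D4 whose relations come from three other
prototypes and whose training frequencies are weak < moderate < strong. Every
cell yields three binary-choice analogy questions A:B::C:[D1|Dk] whose
*semantic facilitation index* (SFI) is positive, zero, or negative depending on
whether the correct alternative D1 is trained with C more, equally, or less
often than the foil.

Because a naive cell design confounds the C:D co-occurrence manipulation with
the global frequency of items and relations, items and prototypes are reused
across cells so that every item within a role class and every prototype
receives the same total amount of training:

* cells come in groups of five sharing five first-role and five second-role
  items; within a group the second-role items rotate through the roles
  {B, D1, weak foil, moderate foil, strong foil} as a Latin square, and the
  first-role items each serve once as A and once as C;
* the four prototype roles (target, weak, moderate, strong) rotate across
  cells so that over any window of ``n_prototypes`` consecutive cells each
  prototype fills each role exactly once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, OffPairExhaustionError
from .relations import (
    PrototypeSet,
    RelationInstance,
    RelationSpaceConfig,
    generate_instance,
    generate_prototypes,
)

__all__ = [
    "Proposition",
    "Cell",
    "AnalogyQuestion",
    "EnvironmentConfig",
    "Environment",
    "Trial",
    "build_environment",
    "questions_from_cell",
    "expand_epoch",
    "INPUT_COMBOS",
    "FOIL_STRENGTHS",
]

SfiLabel = Literal["positive", "zero", "negative"]

#: the three input combinations presented during training; the missing element
#: of the triple is the completion target
INPUT_COMBOS = ("AB", "AR", "BR")
FOIL_STRENGTHS = ("weak", "moderate", "strong")
_CELLS_PER_GROUP = 5
_SECOND_ROLE_ROLES = ("B", "D1", "weak", "moderate", "strong")


@dataclass(frozen=True)
class Proposition:
    """An item1-relation-item2 triple with a per-epoch training frequency."""

    item1: int
    relation: RelationInstance
    item2: int
    frequency: int

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise InvalidConfigError("proposition frequency must be >= 1")


@dataclass(frozen=True)
class Cell:
    """One source, one relational target, and weak/moderate/strong foils."""

    source: Proposition
    target: Proposition
    foil_weak: Proposition
    foil_moderate: Proposition
    foil_strong: Proposition

    @property
    def foils(self) -> tuple[Proposition, Proposition, Proposition]:
        return (self.foil_weak, self.foil_moderate, self.foil_strong)

    @property
    def propositions(self) -> tuple[Proposition, ...]:
        return (self.source, self.target) + self.foils


@dataclass(frozen=True)
class AnalogyQuestion:
    """A:B::C:[D1|D2] with the correct alternative d1 and its SFI label."""

    a: int
    b: int
    c: int
    d1: int
    d2: int
    sfi_label: SfiLabel
    cell_index: int = -1


@dataclass(frozen=True)
class EnvironmentConfig:
    """Environment-design parameters.

    ``n_groups`` groups of five cells give ``5 * n_groups`` cells and a
    vocabulary of ``5 * n_groups`` items per role class. The weak/moderate/
    strong foil frequencies default to 1/3/9 presentations per epoch per input
    combination; the source and relational target share the moderate
    frequency, so the SFI manipulation is carried purely by the foils.
    """

    n_groups: int = 8
    freq_weak: int = 1
    freq_moderate: int = 3
    freq_strong: int = 9
    seed: int = 0
    relation: RelationSpaceConfig = field(default_factory=RelationSpaceConfig)

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise InvalidConfigError("n_groups must be >= 1")
        if not (1 <= self.freq_weak < self.freq_moderate < self.freq_strong):
            raise InvalidConfigError("frequencies must satisfy 1 <= weak < moderate < strong")
        if self.relation.n_prototypes < 4:
            raise InvalidConfigError("cell design needs at least 4 relation prototypes")


@dataclass(frozen=True)
class Environment:
    """The full set of cells plus the relation code they draw on."""

    cells: tuple[Cell, ...]
    protoset: PrototypeSet
    config: EnvironmentConfig

    @property
    def n_first_role(self) -> int:
        return _CELLS_PER_GROUP * self.config.n_groups

    @property
    def n_second_role(self) -> int:
        return _CELLS_PER_GROUP * self.config.n_groups

    @property
    def propositions(self) -> tuple[Proposition, ...]:
        return tuple(p for cell in self.cells for p in cell.propositions)

    def questions(self) -> list[AnalogyQuestion]:
        out: list[AnalogyQuestion] = []
        for i, cell in enumerate(self.cells):
            out.extend(questions_from_cell(cell, cell_index=i))
        return out

    def question_table(self) -> pd.DataFrame:
        qs = self.questions()
        return pd.DataFrame(
            {
                "cell": [q.cell_index for q in qs],
                "a": [q.a for q in qs],
                "b": [q.b for q in qs],
                "c": [q.c for q in qs],
                "d1": [q.d1 for q in qs],
                "d2": [q.d2 for q in qs],
                "sfi_label": [q.sfi_label for q in qs],
            }
        )

    def to_json(self) -> str:
        def prop(p: Proposition) -> dict:
            return {
                "item1": p.item1,
                "item2": p.item2,
                "frequency": p.frequency,
                "relation": p.relation.to_dict(),
            }

        payload = {
            "config": {
                "n_groups": self.config.n_groups,
                "freq_weak": self.config.freq_weak,
                "freq_moderate": self.config.freq_moderate,
                "freq_strong": self.config.freq_strong,
                "seed": self.config.seed,
                "relation": self.config.relation.__dict__,
            },
            "protoset": json.loads(self.protoset.to_json()),
            "cells": [
                {
                    "source": prop(c.source),
                    "target": prop(c.target),
                    "foil_weak": prop(c.foil_weak),
                    "foil_moderate": prop(c.foil_moderate),
                    "foil_strong": prop(c.foil_strong),
                }
                for c in self.cells
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Environment":
        payload = json.loads(text)
        rel_cfg = RelationSpaceConfig(**payload["config"].pop("relation"))
        cfg = EnvironmentConfig(relation=rel_cfg, **payload["config"])
        protoset = PrototypeSet.from_json(json.dumps(payload["protoset"]))

        def prop(d: dict) -> Proposition:
            return Proposition(
                item1=d["item1"],
                relation=RelationInstance.from_dict(d["relation"], protoset),
                item2=d["item2"],
                frequency=d["frequency"],
            )

        cells = tuple(
            Cell(
                source=prop(c["source"]),
                target=prop(c["target"]),
                foil_weak=prop(c["foil_weak"]),
                foil_moderate=prop(c["foil_moderate"]),
                foil_strong=prop(c["foil_strong"]),
            )
            for c in payload["cells"]
        )
        return cls(cells=cells, protoset=protoset, config=cfg)


@dataclass(frozen=True)
class Trial:
    """One training presentation: two clamped pools, one completion target."""

    input_combo: str  # "AB", "AR" or "BR"
    proposition: Proposition

    def __post_init__(self) -> None:
        if self.input_combo not in INPUT_COMBOS:
            raise InvalidConfigError(f"unknown input combination {self.input_combo!r}")

    @property
    def target_pool(self) -> str:
        """The pool absent from the input combination ("R", "B" or "A")."""
        return {"AB": "R", "AR": "B", "BR": "A"}[self.input_combo]


class _OffPairScope:
    """Per-prototype bookkeeping of used off-pairs within one cell group.

    When a prototype's active set is exhausted the scope resets (with a
    warning): the disjointness constraint is local to the bookkeeping scope,
    not global, since an environment may need more instances of a prototype
    than the active set can supply disjoint off-pairs for.
    """

    def __init__(self, protoset: PrototypeSet, rng: np.random.Generator):
        self.protoset = protoset
        self.rng = rng
        self.used: dict[int, list[tuple[int, ...]]] = {}

    def draw(self, prototype_id: int) -> RelationInstance:
        pairs = self.used.setdefault(prototype_id, [])
        try:
            inst = generate_instance(self.protoset, prototype_id, pairs, rng=self.rng)
        except OffPairExhaustionError:
            warnings.warn(
                f"off-pairs for prototype {prototype_id} exhausted; widening scope",
                stacklevel=2,
            )
            pairs.clear()
            inst = generate_instance(self.protoset, prototype_id, pairs, rng=self.rng)
        pairs.append(inst.off_pair)
        return inst


def build_environment(cfg: EnvironmentConfig) -> Environment:
    """Construct the counterbalanced environment. Deterministic given seed.

    Returns ``5 * cfg.n_groups`` cells. See the module docstring for the
    Latin-square / rotation scheme that equates total training frequency
    across items (within a role class) and across relation prototypes.
    """
    rng = np.random.default_rng(cfg.seed)
    rel_seed = int(rng.integers(2**31))
    protoset = generate_prototypes(replace(cfg.relation, seed=rel_seed))
    n_proto = cfg.relation.n_prototypes

    freqs = {
        "weak": cfg.freq_weak,
        "moderate": cfg.freq_moderate,
        "strong": cfg.freq_strong,
    }
    cells: list[Cell] = []
    for g in range(cfg.n_groups):
        first = [_CELLS_PER_GROUP * g + k for k in range(_CELLS_PER_GROUP)]
        second = list(first)  # disjoint vocabulary: second-role ids index the B/D pool
        scope = _OffPairScope(protoset, rng)
        for j in range(_CELLS_PER_GROUP):
            i = _CELLS_PER_GROUP * g + j
            # Latin square over second-role items: role k of cell j gets item (j+k) mod 5
            by_role = {
                role: second[(j + k) % _CELLS_PER_GROUP]
                for k, role in enumerate(_SECOND_ROLE_ROLES)
            }
            a_item = first[j]
            c_item = first[(j + 1) % _CELLS_PER_GROUP]
            # prototype roles rotate with the global cell index
            p_target = i % n_proto
            p_foil = {s: (i + 1 + k) % n_proto for k, s in enumerate(FOIL_STRENGTHS)}
            r1 = scope.draw(p_target)
            r1_prime = scope.draw(p_target)
            cells.append(
                Cell(
                    source=Proposition(a_item, r1, by_role["B"], cfg.freq_moderate),
                    target=Proposition(c_item, r1_prime, by_role["D1"], cfg.freq_moderate),
                    foil_weak=Proposition(
                        c_item, scope.draw(p_foil["weak"]), by_role["weak"], freqs["weak"]
                    ),
                    foil_moderate=Proposition(
                        c_item, scope.draw(p_foil["moderate"]), by_role["moderate"], freqs["moderate"]
                    ),
                    foil_strong=Proposition(
                        c_item, scope.draw(p_foil["strong"]), by_role["strong"], freqs["strong"]
                    ),
                )
            )
    return Environment(cells=tuple(cells), protoset=protoset, config=cfg)


def _sfi_label(target: Proposition, foil: Proposition) -> SfiLabel:
    if foil.frequency < target.frequency:
        return "positive"
    if foil.frequency == target.frequency:
        return "zero"
    return "negative"


def questions_from_cell(cell: Cell, cell_index: int = -1) -> list[AnalogyQuestion]:
    """The three analogy questions of a cell, one per SFI label.

    All three share a, b, c and the correct alternative d1; they differ only
    in which foil supplies d2, and hence in the relative C:d2 association.
    """
    return [
        AnalogyQuestion(
            a=cell.source.item1,
            b=cell.source.item2,
            c=cell.target.item1,
            d1=cell.target.item2,
            d2=foil.item2,
            sfi_label=_sfi_label(cell.target, foil),
            cell_index=cell_index,
        )
        for foil in cell.foils
    ]


def expand_epoch(env: Environment, seed: int) -> list[Trial]:
    """One epoch's trial list: each proposition of frequency f contributes
    f trials of each of the three input combinations; order shuffled by seed.

    The trial multiset is a function of the environment only; the seed
    controls presentation order alone.
    """
    trials = [
        Trial(combo, prop)
        for prop in env.propositions
        for combo in INPUT_COMBOS
        for _ in range(prop.frequency)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]
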