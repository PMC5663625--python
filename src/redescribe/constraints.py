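"""Attribute-constraint handling for constraint-based redescription mining.

Users name one or more sets of attributes of special interest
(C = {C1, ..., Cn}) and a mode deciding how strongly the miner is steered
toward them:

* ``strict``   — only redescriptions whose queries contain *all* attributes
  of at least one Ci are admissible (the classical definition).
* ``soft``     — a redescription must mention at least part of some Ci;
  fuller compliance is rewarded by the constraint score.
* ``suggested``— every redescription is admissible; compliance merely
  improves its optimization score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .data_model import ConjunctiveQuery, Redescription

STRICT = "strict"
SOFT = "soft"
SUGGESTED = "suggested"
MODES = (STRICT, SOFT, SUGGESTED)

#: score sentinel for redescriptions a mode refuses to admit
INADMISSIBLE = float("-inf")


@dataclass(frozen=True)
class ConstraintSpec:
    """Constraint sets plus the mining mode.

    ``granularity`` is reserved for future instance-level constraints; only
    attribute-level constraints are implemented.
    """

    sets: tuple[frozenset, ...]
    mode: str = STRICT
    granularity: str = "attribute"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.sets or any(not s for s in self.sets):
            raise ValueError("every constraint set must be non-empty")
        if self.granularity != "attribute":
            raise NotImplementedError("only attribute-level constraints are supported")
        object.__setattr__(self, "sets", tuple(frozenset(s) for s in self.sets))

    @property
    def all_attributes(self) -> frozenset:
        out: frozenset = frozenset()
        for s in self.sets:
            out |= s
        return out

    @classmethod
    def of(cls, *sets: Iterable[str], mode: str = STRICT) -> "ConstraintSpec":
        return cls(tuple(frozenset(s) for s in sets), mode=mode)


def constraint_score(attrs: frozenset, spec: ConstraintSpec) -> float:
    """Graded compliance of a redescription's attribute set with C.

    Half the score rewards the best per-set coverage,
    max_i |attrs ∩ Ci| / |Ci|, favouring many satisfied constraints from a
    single set; the other half rewards the fraction of the redescription's
    own attributes that are of interest, |attrs ∩ (∪Ci)| / |attrs|.
    """
    if not attrs:
        return 0.0
    best = max(len(attrs & c) / len(c) for c in spec.sets)
    focus = len(attrs & spec.all_attributes) / len(attrs)
    return 0.5 * best + 0.5 * focus


def soft_score(attrs: frozenset, spec: ConstraintSpec) -> float:
    """Soft-mode score: graded compliance, or inadmissible when the
    redescription touches no constraint set at all."""
    if any(attrs & c for c in spec.sets):
        return constraint_score(attrs, spec)
    return INADMISSIBLE


def strict_score(attrs: frozenset, spec: ConstraintSpec) -> float:
    """Strict-mode score: 1 when some Ci is fully contained, else inadmissible."""
    if any(c <= attrs for c in spec.sets):
        return 1.0
    return INADMISSIBLE


def mode_score(attrs: frozenset, spec: ConstraintSpec) -> float:
    """Dispatch to the score of the spec's mode (suggested uses the graded score)."""
    if spec.mode == STRICT:
        return strict_score(attrs, spec)
    if spec.mode == SOFT:
        return soft_score(attrs, spec)
    return constraint_score(attrs, spec)


def admissible(attrs: frozenset, spec: ConstraintSpec | None) -> bool:
    if spec is None:
        return True
    return mode_score(attrs, spec) != INADMISSIBLE


def pair_admissible(q1: ConjunctiveQuery, q2: ConjunctiveQuery,
                    spec: ConstraintSpec | None) -> bool:
    """Pre-screen a rule pair before it is assembled into a redescription.

    The joint attribute set of the two queries is tested: strict mode needs
    some Ci fully covered, soft mode any overlap, suggested mode passes all
    pairs (scoring only).
    """
    if spec is None or spec.mode == SUGGESTED:
        return True
    joint = q1.attributes | q2.attributes
    if spec.mode == STRICT:
        return any(c <= joint for c in spec.sets)
    return any(joint & c for c in spec.sets)


def filter_rule_pairs(rules1: list[ConjunctiveQuery],
                      rules2: list[ConjunctiveQuery],
                      spec: ConstraintSpec | None):
    """Yield admissible (q1, q2) pairs in row-major order over rules1 x rules2."""
    for q1 in rules1:
        for q2 in rules2:
            if pair_admissible(q1, q2, spec):
                yield q1, q2
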