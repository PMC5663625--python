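"""Bounded redescription-set maintenance with redundancy-penalizing scores.

The miner produces far more quality-passing redescriptions than a user wants
to read.  This module keeps a set of at most ``capacity`` members, scoring
each redescription by a weighted sum of its inaccuracy (1 - Jqnm), how
redundantly its support instances are already covered by the rest of the set,
how redundantly its attributes are already used, and (optionally) how well it
complies with user attribute constraints.  Lower scores are better; a new
candidate replaces the member with the largest score difference, provided the
exchange strictly improves that slot.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .constraints import INADMISSIBLE, ConstraintSpec, mode_score
from .data_model import Redescription


@dataclass(frozen=True)
class Alphas:
    """Importance weights of the four score components; must sum to 1.

    ``constraint`` (the weight of the constraint-compliance term) defaults to
    0, which makes the score identical to unconstrained mining.
    """

    error: float = 1 / 3
    inst_redundancy: float = 1 / 3
    attr_redundancy: float = 1 / 3
    constraint: float = 0.0

    def __post_init__(self):
        total = self.error + self.inst_redundancy + self.attr_redundancy + self.constraint
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"alpha weights must sum to 1, got {total}")
        for w in (self.error, self.inst_redundancy, self.attr_redundancy, self.constraint):
            if not 0 <= w <= 1:
                raise ValueError("alpha weights must lie in [0, 1]")


class RedescriptionSet:
    """Bounded collection with live instance- and attribute-coverage counters.

    ``inst_cover[i]`` counts members whose support contains instance i;
    ``attr_cover[a]`` counts members whose attribute set contains a.  Both
    are recomputable from the member list at any time (and the test suite
    checks that they are).
    """

    def __init__(self, n_instances: int, capacity: int = 100):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self.n_instances = n_instances
        self.members: list[Redescription] = []
        self.inst_cover = np.zeros(n_instances, dtype=np.int64)
        self.attr_cover: Counter = Counter()
        self._supp_total = 0   # sum over members of |supp(R)|
        self._attr_total = 0   # sum over members of |attr(R)| (multiset size)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    # -- counter bookkeeping -------------------------------------------------

    def _count(self, r: Redescription, sign: int) -> None:
        self.inst_cover[r.support] += sign
        for a in r.attrs:
            self.attr_cover[a] += sign
        self._supp_total += sign * r.support_size
        self._attr_total += sign * len(r.attr_multiset)

    def recompute_counters(self):
        """From-scratch counters (oracle for consistency checks)."""
        inst = np.zeros(self.n_instances, dtype=np.int64)
        attr: Counter = Counter()
        for r in self.members:
            inst[r.support] += 1
            for a in r.attrs:
                attr[a] += 1
        return inst, attr

    # -- scores ---------------------------------------------------------------

    def red_score_inst(self, r: Redescription, member: bool | None = None) -> float:
        """Instance-redundancy score of ``r`` against this set.

        Numerator: total coverage of r's support instances by the *other*
        members (for a member) or by all current members (for a candidate).
        Denominator: sum of member support sizes, plus the candidate's own.
        """
        if member is None:
            member = any(m is r for m in self.members)
        cover = int(self.inst_cover[r.support].sum())
        if member:
            num = cover - r.support_size  # remove r's own coverage of itself
            denom = self._supp_total
        else:
            num = cover
            denom = self._supp_total + r.support_size
        if denom == 0:
            return 0.0
        return num / denom

    def red_score_attr(self, r: Redescription, member: bool | None = None) -> float:
        """Attribute-redundancy score, the analogue over attribute usage."""
        if member is None:
            member = any(m is r for m in self.members)
        cover = sum(self.attr_cover[a] for a in r.attr_multiset)
        if member:
            num = cover - len(r.attr_multiset)
            denom = self._attr_total
        else:
            num = cover
            denom = self._attr_total + len(r.attr_multiset)
        if denom == 0:
            return 0.0
        return num / denom

    def total_score(self, r: Redescription, alphas: Alphas,
                    cspec: ConstraintSpec | None = None,
                    member: bool | None = None) -> float:
        """Weighted redescription score; lower is better; +inf = inadmissible."""
        err = 1.0 - r.jqnm
        sc = (alphas.error * err
              + alphas.inst_redundancy * self.red_score_inst(r, member)
              + alphas.attr_redundancy * self.red_score_attr(r, member))
        if cspec is not None:
            cs = mode_score(r.attrs, cspec)
            if cs == INADMISSIBLE:
                return math.inf
            sc += alphas.constraint * (1.0 - cs)
        return sc

    # -- set maintenance ------------------------------------------------------

    def add_replace_discard(self, r_new: Redescription, alphas: Alphas,
                            cspec: ConstraintSpec | None = None) -> bool:
        """Insert, replace the worst-fitting member, or discard the candidate.

        Below capacity the candidate is appended outright.  At capacity the
        member maximizing sc(member) - sc(candidate) is replaced iff the
        difference is strictly positive (earliest-inserted member wins ties);
        otherwise the candidate is discarded.  Returns True when the set
        changed.
        """
        sc_new = self.total_score(r_new, alphas, cspec, member=False)
        if math.isinf(sc_new):
            return False
        if len(self.members) < self.capacity:
            self.members.append(r_new)
            self._count(r_new, +1)
            return True
        best_idx, best_diff = -1, 0.0
        for idx, m in enumerate(self.members):
            diff = self.total_score(m, alphas, cspec, member=True) - sc_new
            if diff > best_diff:
                best_idx, best_diff = idx, diff
        if best_idx < 0:
            return False
        outgoing = self.members[best_idx]
        self._count(outgoing, -1)
        self.members[best_idx] = r_new
        self._count(r_new, +1)
        return True

    def replace_member(self, idx: int, r: Redescription) -> None:
        """Swap member ``idx`` for ``r``, keeping counters consistent."""
        self._count(self.members[idx], -1)
        self.members[idx] = r
        self._count(r, +1)

    def remove_member(self, idx: int) -> Redescription:
        out = self.members.pop(idx)
        self._count(out, -1)
        return out


# Module-level aliases matching the operation names used in the docs.

def red_score_inst(r: Redescription, rset: RedescriptionSet) -> float:
    return rset.red_score_inst(r)


def red_score_attr(r: Redescription, rset: RedescriptionSet) -> float:
    return rset.red_score_attr(r)


def total_score(r: Redescription, rset: RedescriptionSet, alphas: Alphas,
                cspec: ConstraintSpec | None = None) -> float:
    return rset.total_score(r, alphas, cspec)


def add_replace_discard(r_new: Redescription, rset: RedescriptionSet,
                        alphas: Alphas,
                        cspec: ConstraintSpec | None = None) -> bool:
    return rset.add_replace_discard(r_new, alphas, cspec)
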