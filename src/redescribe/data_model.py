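"""Core domain types and quality measures for two-view redescription mining.

A *redescription* is a pair of conjunctive queries, one over each of two
disjoint attribute sets (views) describing the same instances, whose support
sets largely coincide.  Because real tables contain missing values, query
membership is three-valued: an instance is definitely *in* a query's support,
definitely *out*, or *unknown* (no condition is violated, but at least one
referenced value is missing).  The nine-way cross of the two states drives
the quality measures implemented here: the query non-missing Jaccard index
and the binomial-tail significance test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

# Tri-state evaluation codes.
IN = 1
OUT = 0
UNKNOWN = -1

NUMERIC = "numeric"
CATEGORICAL = "categorical"
BOOLEAN = "boolean"


class ConfigurationError(ValueError):
    """Raised when a query or constraint references unknown attributes."""


@dataclass(frozen=True)
class Attribute:
    """One column of a view.

    ``observed_range`` is the (min, max) of the non-missing values for a
    numeric attribute, or the tuple of observed categories otherwise; it is
    used to canonicalize one-sided tree splits into closed intervals.
    """

    name: str
    view: int
    kind: str  # numeric | categorical | boolean
    observed_range: tuple = ()

    def __post_init__(self):
        if self.view not in (1, 2):
            raise ValueError(f"view must be 1 or 2, got {self.view}")
        if self.kind not in (NUMERIC, CATEGORICAL, BOOLEAN):
            raise ValueError(f"unknown attribute kind {self.kind!r}")


class TwoViewDataset:
    """Shared instances described by two disjoint attribute sets.

    Parameters
    ----------
    view1, view2:
        DataFrames indexed by instance id (identical ordered index in both),
        missing cells as NaN/None.  Column name sets must be disjoint.
    labels:
        Optional per-instance class label (e.g. a diagnosis), used only by
        post-hoc analyses, never by the miner.
    kinds:
        Optional mapping column -> attribute kind; unmapped columns are
        numeric if their dtype is numeric, categorical otherwise.
    """

    def __init__(self, view1: pd.DataFrame, view2: pd.DataFrame,
                 labels: pd.Series | None = None,
                 kinds: Mapping[str, str] | None = None):
        if not view1.index.equals(view2.index):
            raise ValueError("views must share an identical ordered instance index")
        overlap = set(view1.columns) & set(view2.columns)
        if overlap:
            raise ValueError(f"view attribute sets must be disjoint, shared: {sorted(overlap)}")
        if view1.index.has_duplicates:
            raise ValueError("duplicate instance ids")
        if labels is not None and not labels.index.equals(view1.index):
            labels = labels.reindex(view1.index)
        self.view1 = view1
        self.view2 = view2
        self.labels = labels
        kinds = dict(kinds or {})
        self._attributes: dict[str, Attribute] = {}
        for vnum, vdf in ((1, view1), (2, view2)):
            for col in vdf.columns:
                kind = kinds.get(col)
                if kind is None:
                    kind = NUMERIC if pd.api.types.is_numeric_dtype(vdf[col]) else CATEGORICAL
                obs = vdf[col].dropna()
                if kind == NUMERIC:
                    rng = (float(obs.min()), float(obs.max())) if len(obs) else ()
                else:
                    rng = tuple(sorted(obs.unique(), key=str))
                self._attributes[col] = Attribute(col, vnum, kind, rng)

    @property
    def n(self) -> int:
        return len(self.view1.index)

    @property
    def instance_ids(self) -> pd.Index:
        return self.view1.index

    def view(self, num: int) -> pd.DataFrame:
        if num == 1:
            return self.view1
        if num == 2:
            return self.view2
        raise ValueError(f"no view {num}")

    def attribute(self, name: str) -> Attribute:
        try:
            return self._attributes[name]
        except KeyError:
            raise ConfigurationError(f"unknown attribute {name!r}") from None

    def attributes(self, view: int | None = None) -> list[Attribute]:
        attrs = self._attributes.values()
        if view is None:
            return list(attrs)
        return [a for a in attrs if a.view == view]


@dataclass(frozen=True)
class Condition:
    """A single conjunct: numeric closed interval or categorical membership.

    Numeric: ``lo <= attribute <= hi`` (closed on both ends).  Categorical or
    boolean: ``attribute in values``; a singleton set prints as an equality,
    which is the common case produced by tree splits.
    """

    attribute: str
    lo: float | None = None
    hi: float | None = None
    values: frozenset = frozenset()

    def __post_init__(self):
        if self.values:
            if self.lo is not None or self.hi is not None:
                raise ValueError("condition cannot be both interval and membership")
        else:
            if self.lo is None or self.hi is None:
                raise ValueError("numeric condition needs both bounds")
            if self.lo > self.hi:
                raise ValueError(f"empty interval [{self.lo}, {self.hi}]")

    @property
    def is_numeric(self) -> bool:
        return not self.values

    def evaluate(self, column: pd.Series) -> np.ndarray:
        """Tri-state evaluation of this condition on one column."""
        vals = column.to_numpy()
        missing = pd.isna(vals)
        out = np.full(len(vals), IN, dtype=np.int8)
        if self.is_numeric:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # NaN comparisons
                ok = (vals >= self.lo) & (vals <= self.hi)
        else:
            ok = np.isin(vals, list(self.values))
        out[~ok] = OUT
        out[missing] = UNKNOWN
        return out

    def __str__(self) -> str:
        if self.is_numeric:
            return f"{_fmt(self.lo)} <= {self.attribute} <= {_fmt(self.hi)}"
        if len(self.values) == 1:
            (v,) = self.values
            return f"{self.attribute} = {v}"
        return f"{self.attribute} in {{{', '.join(sorted(map(str, self.values)))}}}"


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class ConjunctiveQuery:
    """A conjunction of conditions over one view, at most one per attribute."""

    view: int
    conditions: tuple[Condition, ...] = ()

    def __post_init__(self):
        names = [c.attribute for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError("at most one condition per attribute")

    @property
    def attributes(self) -> frozenset:
        return frozenset(c.attribute for c in self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    def __str__(self) -> str:
        if not self.conditions:
            return "TRUE"
        return " ∧ ".join(str(c) for c in self.conditions)


def evaluate_query(q: ConjunctiveQuery, data: TwoViewDataset) -> np.ndarray:
    """Evaluate a conjunctive query, returning a tri-state vector.

    An instance is ``IN`` iff every condition holds on non-missing values and
    no referenced value is missing; ``OUT`` iff at least one condition is
    violated by a non-missing value (a definite violation dominates missing
    data, since one false literal falsifies a conjunction); ``UNKNOWN``
    otherwise.
    """
    table = data.view(q.view)
    n = data.n
    state = np.full(n, IN, dtype=np.int8)
    any_unknown = np.zeros(n, dtype=bool)
    for cond in q.conditions:
        attr = data.attribute(cond.attribute)
        if attr.view != q.view:
            raise ConfigurationError(
                f"attribute {cond.attribute!r} belongs to view {attr.view}, "
                f"query is over view {q.view}")
        cstate = cond.evaluate(table[cond.attribute])
        state[cstate == OUT] = OUT
        any_unknown |= cstate == UNKNOWN
    state[(state != OUT) & any_unknown] = UNKNOWN
    return state


_CELLS = ("E11", "E10", "E01", "E00", "E1q", "Eq1", "E0q", "Eq0", "Eqq")
_STATE_CELL = {
    (IN, IN): "E11", (IN, OUT): "E10", (OUT, IN): "E01", (OUT, OUT): "E00",
    (IN, UNKNOWN): "E1q", (UNKNOWN, IN): "Eq1",
    (OUT, UNKNOWN): "E0q", (UNKNOWN, OUT): "Eq0",
    (UNKNOWN, UNKNOWN): "Eqq",
}


@dataclass(frozen=True)
class SupportPartition:
    """The nine-way partition of instances by definite/indefinite membership.

    ``sets`` maps each cell name to the array of instance positions assigned
    to it; ``E11`` .. ``Eqq`` expose the sizes.  The nine sets are pairwise
    disjoint and exhaust the dataset.
    """

    sets: Mapping[str, np.ndarray]

    def __getattr__(self, name):
        if name in _CELLS:
            return len(self.sets[name])
        raise AttributeError(name)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.sets.values())

    def counts(self) -> dict[str, int]:
        return {c: len(self.sets[c]) for c in _CELLS}


def partition_support(q1_eval: np.ndarray, q2_eval: np.ndarray) -> SupportPartition:
    """Cross two tri-state vectors into the nine-cell support partition."""
    if len(q1_eval) != len(q2_eval):
        raise ValueError("tri-state vectors differ in length")
    sets = {}
    for (s1, s2), cell in _STATE_CELL.items():
        sets[cell] = np.flatnonzero((q1_eval == s1) & (q2_eval == s2))
    return SupportPartition(sets)


def jaccard(supp1_size: int, supp2_size: int, intersection_size: int) -> float:
    """Plain Jaccard similarity of two support sets from their sizes."""
    union = supp1_size + supp2_size - intersection_size
    if union == 0:
        warnings.warn("both supports empty; Jaccard defined as 0", stacklevel=2)
        return 0.0
    return intersection_size / union

def qnm_jaccard(p: SupportPartition) -> float:
    """Query non-missing Jaccard index.

    |E11| / (|E11| + |Eq1| + |E1q| + |E01| + |E10|): instances definitely in
    one support but unevaluable by the other query count against the score,
    while doubly-unevaluable and out/unevaluable instances are ignored.
    Reduces to the plain Jaccard index when no missing values interfere.
    """
    denom = p.E11 + p.Eq1 + p.E1q + p.E01 + p.E10
    if denom == 0:
        return 0.0
    return p.E11 / denom


def redescription_pvalue(n: int, supp1_size: int, supp2_size: int,
                         overlap: int) -> float:
    """Binomial-tail significance of an observed support overlap.

    Models the two supports as independently sampled with marginal
    probabilities ``p1 = supp1/n`` and ``p2 = supp2/n``; the intersection
    size is then Binomial(n, p1*p2) and the p-value is the upper tail
    P(X >= overlap), computed with a numerically stable survival function.
    """
    if n <= 0:
        raise ValueError("dataset must be non-empty")
    p12 = (supp1_size / n) * (supp2_size / n)
    if overlap <= 0:
        return 1.0
    # sf(overlap - 1) = P(X >= overlap); stable far into the tail
    return float(binom.sf(overlap - 1, n, p12))


def redescription_log10_pvalue(n: int, supp1_size: int, supp2_size: int,
                               overlap: int) -> float:
    """log10 of the binomial-tail p-value (finite even when sf underflows)."""
    if n <= 0:
        raise ValueError("dataset must be non-empty")
    p12 = (supp1_size / n) * (supp2_size / n)
    if overlap <= 0:
        return 0.0
    return float(binom.logsf(overlap - 1, n, p12) / math.log(10))


@dataclass(frozen=True)
class QualityConstraints:
    """User thresholds a redescription must meet to survive screening."""

    min_jaccard: float = 0.2
    max_pvalue: float = 0.01
    support_interval: tuple[int, int] = (1, 10**9)
    max_query_length: int = 8

    def __post_init__(self):
        if not 0 <= self.min_jaccard <= 1:
            raise ValueError("min_jaccard must be in [0, 1]")
        if not 0 < self.max_pvalue <= 1:
            raise ValueError("max_pvalue must be in (0, 1]")
        lo, hi = self.support_interval
        if lo > hi:
            raise ValueError("empty support interval")


class Redescription:
    """A query pair with its cached support partition and quality measures."""

    __slots__ = ("q1", "q2", "partition", "jqnm", "pvalue", "_n",
                 "_supp1", "_supp2")

    def __init__(self, q1: ConjunctiveQuery, q2: ConjunctiveQuery,
                 data: TwoViewDataset):
        if q1.view == q2.view:
            raise ValueError("redescription queries must come from opposite views")
        if q1.view == 2:
            q1, q2 = q2, q1
        self._init(q1, q2, evaluate_query(q1, data), evaluate_query(q2, data),
                   data.n)

    @classmethod
    def from_evaluations(cls, q1: ConjunctiveQuery, q2: ConjunctiveQuery,
                         e1: np.ndarray, e2: np.ndarray,
                         n: int) -> "Redescription":
        """Build from pre-computed tri-state vectors (avoids re-evaluating
        shared rules when crossing large rule lists)."""
        r = cls.__new__(cls)
        r._init(q1, q2, e1, e2, n)
        return r

    def _init(self, q1, q2, e1, e2, n):
        self.q1 = q1
        self.q2 = q2
        self.partition = partition_support(e1, e2)
        self.jqnm = qnm_jaccard(self.partition)
        self._n = n
        # |supp(q_i)| counts only definite members (see methods note)
        self._supp1 = int(np.sum(e1 == IN))
        self._supp2 = int(np.sum(e2 == IN))
        self.pvalue = redescription_pvalue(self._n, self._supp1, self._supp2,
                                           self.partition.E11)

    @property
    def support(self) -> np.ndarray:
        """Positions of instances definitely described by both queries (E11)."""
        return self.partition.sets["E11"]

    @property
    def support_size(self) -> int:
        return self.partition.E11

    @property
    def attrs(self) -> frozenset:
        """Set of attribute names over both queries."""
        return self.q1.attributes | self.q2.attributes

    @property
    def attr_multiset(self) -> tuple:
        """Attribute names with multiplicity (an attribute may occur in both queries)."""
        return tuple(c.attribute for c in self.q1.conditions + self.q2.conditions)

    def __str__(self) -> str:
        return (f"({self.q1})  <->  ({self.q2})  "
                f"|E11|={self.support_size} Jqnm={self.jqnm:.3f} p={self.pvalue:.3g}")


def check_quality(r: Redescription, q: QualityConstraints) -> tuple[bool, list[str]]:
    """Screen a redescription against the quality thresholds.

    Returns ``(passed, reasons)`` where ``reasons`` lists every failed check.
    """
    reasons = []
    if r.jqnm < q.min_jaccard:
        reasons.append("jaccard")
    if r.pvalue > q.max_pvalue:
        reasons.append("pvalue")
    lo, hi = q.support_interval
    if not lo <= r.support_size <= hi:
        reasons.append("support")
    if len(r.q1) > q.max_query_length or len(r.q2) > q.max_query_length:
        reasons.append("query_length")
    return (not reasons, reasons)
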