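"""Post-hoc analytics over a mined redescription set.

Three questions a domain expert asks of a redescription set: how homogeneous
are the described instance groups with respect to a class label (support-set
entropy), which attribute pairs keep co-occurring across redescription
queries (co-occurrence tables per view-pair), and do co-occurring attributes
actually correlate in the raw data (normality-screened Pearson/Spearman).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Redescription
from .redset import RedescriptionSet

#: support-size groupings used for entropy summaries
DEFAULT_SUPPORT_BINS = ((5, 10), (11, 39), (40, 99), (100, None))


def entropy_from_counts(counts: Sequence[int]) -> float:
    """Shannon entropy (bits) of class counts; zero counts are dropped."""
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if c.size == 0:
        raise ValueError("entropy of an empty support is undefined")
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)  # + 0.0 clears -0.0


def support_entropy(r: Redescription, labels: pd.Series | Sequence) -> float:
    """Entropy of the class labels within a redescription's support set.

    Only classes actually occurring in the support contribute, so a
    label-homogeneous group scores 0 regardless of how many classes exist
    in the full dataset.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    supp = r.support
    if len(supp) == 0:
        raise ValueError("entropy of an empty support is undefined")
    counts = labels.iloc[supp].value_counts(dropna=False)
    return entropy_from_counts(counts.to_numpy())


@dataclass
class CooccurrenceTable:
    """Counts of unordered attribute pairs for one view-pair class.

    ``rows`` is a list of (attribute_a, attribute_b, count) sorted by count
    descending (then lexicographically for determinism).
    """

    view_pair: str
    counts: Counter

    @property
    def rows(self) -> list[tuple[str, str, int]]:
        items = [(a, b, c) for (a, b), c in self.counts.items()]
        return sorted(items, key=lambda t: (-t[2], t[0], t[1]))

    def merge(self, other: "CooccurrenceTable") -> "CooccurrenceTable":
        if other.view_pair != self.view_pair:
            raise ValueError("cannot merge tables of different view-pair classes")
        return CooccurrenceTable(self.view_pair, self.counts + other.counts)


def cooccurrence(rset: RedescriptionSet | Iterable[Redescription],
                 view_map: Mapping[str, str]) -> dict[str, CooccurrenceTable]:
    """Attribute co-occurrence tables split by view-pair class.

    ``view_map`` tags each attribute (e.g. ``"bio"`` or ``"clin"``).  Every
    unordered attribute pair within one redescription's attribute set
    increments the table of its tag pair once per redescription.
    """
    tables: dict[str, CooccurrenceTable] = {}
    for r in rset:
        for a, b in combinations(sorted(r.attrs), 2):
            ta, tb = view_map[a], view_map[b]
            key = "-".join(sorted((ta, tb)))
            if key not in tables:
                tables[key] = CooccurrenceTable(key, Counter())
            tables[key].counts[(a, b)] += 1
    return tables


def pair_correlation(values_a: Sequence, values_b: Sequence,
                     kinds: tuple[str, str] = ("numeric", "numeric"),
                     normality_alpha: float = 0.05):
    """Correlation between two attributes with an automatic method choice.

    Missing entries are dropped pairwise.  Each attribute is screened for
    normality with a one-sample Kolmogorov-Smirnov test against a normal
    distribution with estimated parameters; Pearson's r is used only when
    both attributes pass the screen and neither is ordinal, otherwise
    Spearman's rho.  Returns ``(method, coefficient, p_value)``.
    """
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    ok = a.notna() & b.notna()
    a, b = a[ok].to_numpy(), b[ok].to_numpy()
    if len(a) < 3:
        return ("undefined", float("nan"), float("nan"))

    def looks_normal(x):
        sd = x.std(ddof=1)
        if sd == 0:
            return False
        return stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue >= normality_alpha

    ordinal = any(k == "ordinal" for k in kinds)
    if not ordinal and looks_normal(a) and looks_normal(b):
        coef, p = stats.pearsonr(a, b)
        return ("pearson", float(coef), float(p))
    coef, p = stats.spearmanr(a, b)
    return ("spearman", float(coef), float(p))


def entropy_by_support_interval(rset: RedescriptionSet | Iterable[Redescription],
                                labels: pd.Series,
                                bins=DEFAULT_SUPPORT_BINS) -> dict[str, list[float]]:
    """Group member entropies by support-size interval for summary boxplots."""
    out: dict[str, list[float]] = {}
    for lo, hi in bins:
        name = f"[{lo}, {hi}]" if hi is not None else f">={lo}"
        out[name] = []
    for r in rset:
        s = r.support_size
        if s == 0:
            continue
        for (lo, hi) in bins:
            if s >= lo and (hi is None or s <= hi):
                name = f"[{lo}, {hi}]" if hi is not None else f">={lo}"
                out[name].append(support_entropy(r, labels))
                break
    return out


def group_values(r: Redescription, column: pd.Series, labels: pd.Series,
                 control_class: str = "CN"):
    """Attribute values of a redescription's support vs a control group.

    Returns ``(support_values, control_values)`` with missing entries
    dropped — the inputs expected by standard two-sample location/shape
    tests (Anderson-Darling, Kolmogorov-Smirnov, Mann-Whitney U), which are
    deliberately left to standard statistical routines.
    """
    column = pd.Series(column).reset_index(drop=True)
    labels = pd.Series(labels).reset_index(drop=True)
    supp_vals = column.iloc[r.support].dropna().to_numpy()
    ctrl_vals = column[labels == control_class].dropna().to_numpy()
    return supp_vals, ctrl_vals
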