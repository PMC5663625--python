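"""Multi-target predictive-clustering-tree induction and rule extraction.

A predictive clustering tree (PCT) is a binary decision tree whose splits
maximize impurity reduction summed over *many* targets at once; every node
(internal or leaf) is a cluster of training instances, and the conjunction of
split outcomes on the root-to-node path is a rule describing that cluster.
The miner uses PCTs in two ways: an initialization round that separates real
instances from attribute-wise shuffled copies, and iterative rounds where
the binary targets are memberships in rules extracted on the opposite view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (CATEGORICAL, IN, NUMERIC, Condition, ConjunctiveQuery,
                         TwoViewDataset, evaluate_query)

_GAIN_EPS = 1e-12


@dataclass
class PCTParams:
    """Tree-growth controls: depth, leaf size and the stopping criterion."""

    max_depth: int = 8
    min_leaf_size: int = 1


@dataclass
class TreeNode:
    """One node of a PCT; internal nodes carry a one-attribute test.

    Numeric test: ``attribute <= threshold`` goes left.  Categorical test:
    ``attribute == category`` goes left (one-vs-rest).  ``members`` are the
    training-row positions reaching the node; instances missing the split
    attribute are routed to the child with more non-missing members.
    """

    members: np.ndarray
    depth: int
    attribute: str | None = None
    threshold: float | None = None
    category: object | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def build_initial_data(view_table: pd.DataFrame,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack the view on top of attribute-wise shuffled copies of itself.

    Each synthetic row draws every cell independently from a uniformly random
    original row (with replacement), which preserves the marginal value
    distribution of every column while destroying between-attribute
    correlations.  Originals get target 1, copies target 0; a PCT trained on
    this target isolates regions of genuine attribute correlation.
    """
    n = len(view_table)
    if n == 0:
        raise ValueError("view has no instances")
    shuffled = {}
    for col in view_table.columns:
        picks = rng.integers(0, n, size=n)
        shuffled[col] = view_table[col].to_numpy()[picks]
    copies = pd.DataFrame(shuffled, columns=view_table.columns)
    augmented = pd.concat([view_table.reset_index(drop=True), copies],
                          ignore_index=True)
    target = np.concatenate([np.ones(n), np.zeros(n)])
    return augmented, target


def _column_arrays(view_table: pd.DataFrame, kinds: dict[str, str]):
    """Pre-extract numpy columns and missing masks for fast split search."""
    cols = []
    for name in view_table.columns:
        kind = kinds[name]
        if kind == NUMERIC:
            vals = view_table[name].to_numpy(dtype=float)
            missing = np.isnan(vals)
        else:
            vals = view_table[name].to_numpy(dtype=object)
            missing = pd.isna(vals)
        cols.append((name, kind, vals, missing))
    return cols


def _best_split(cols, targets: np.ndarray, members: np.ndarray,
                min_leaf: int):
    """Exhaustive search for the split with the largest summed gain.

    Gain for a candidate split of the node's non-missing members into
    (L, R) is  sum_t [ S_L^2/|L| + S_R^2/|R| - S^2/m ]  where S_* are
    per-target sums — the total variance reduction for 0/1 targets.
    Missing-valued members are excluded from the gain computation.
    Ties break to the lowest column index, then the smallest threshold
    (strict improvement required), so growth is deterministic.
    """
    best = None  # (gain, col_idx, kind, threshold_or_category)
    for ci, (name, kind, vals, missing) in enumerate(cols):
        nm = members[~missing[members]]
        m = len(nm)
        if m < 2 * min_leaf:
            continue
        Y = targets[nm]  # m x T
        total = Y.sum(axis=0)
        parent = np.sum(total * total) / m
        if kind == NUMERIC:
            v = vals[nm]
            order = np.argsort(v, kind="stable")
            vs = v[order]
            Ys = Y[order]
            csum = np.cumsum(Ys, axis=0)  # csum[j] = sums of first j+1 rows
            # valid split after position j iff vs[j] < vs[j+1]
            distinct = np.flatnonzero(vs[:-1] < vs[1:])
            if len(distinct) == 0:
                continue
            nl = distinct + 1
            nr = m - nl
            ok = (nl >= min_leaf) & (nr >= min_leaf)
            if not ok.any():
                continue
            distinct = distinct[ok]
            nl = nl[ok]
            nr = nr[ok]
            SL = csum[distinct]  # k x T
            SR = total[None, :] - SL
            gains = (np.sum(SL * SL, axis=1) / nl
                     + np.sum(SR * SR, axis=1) / nr - parent)
            j = int(np.argmax(gains))
            # earliest index wins ties within the column (argmax is first max);
            # thresholds are midpoints, scanned in ascending order
            if best is None or gains[j] > best[0] + _GAIN_EPS:
                thr = (vs[distinct[j]] + vs[distinct[j] + 1]) / 2.0
                best = (float(gains[j]), ci, NUMERIC, thr)
        else:
            v = vals[nm]
            cats = sorted(pd.unique(v), key=str)
            for cat in cats:
                lmask = v == cat
                nl = int(lmask.sum())
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                SL = Y[lmask].sum(axis=0)
                SR = total - SL
                gain = (np.sum(SL * SL) / nl + np.sum(SR * SR) / nr - parent)
                if best is None or gain > best[0] + _GAIN_EPS:
                    best = (float(gain), ci, CATEGORICAL, cat)
    if best is None or best[0] <= _GAIN_EPS:
        return None
    return best


def build_pct(view_table: pd.DataFrame, targets: np.ndarray,
              params: PCTParams | None = None,
              kinds: dict[str, str] | None = None) -> TreeNode:
    """Grow a multi-target PCT top-down.

    ``targets`` is an (n_rows, n_targets) 0/1 matrix row-aligned with
    ``view_table``.  Growth stops at ``max_depth``, when a child would fall
    below ``min_leaf_size`` non-missing members, or when no split achieves a
    positive impurity reduction (e.g. all targets constant).
    """
    params = params or PCTParams()
    if targets.ndim == 1:
        targets = targets[:, None]
    targets = np.asarray(targets, dtype=float)
    if len(targets) != len(view_table):
        raise ValueError("targets not row-aligned with the view table")
    if kinds is None:
        kinds = {c: (NUMERIC if pd.api.types.is_numeric_dtype(view_table[c])
                     else CATEGORICAL) for c in view_table.columns}
    cols = _column_arrays(view_table, kinds)
    root = TreeNode(members=np.arange(len(view_table)), depth=0)
    stack = [root]
    while stack:
        node = stack.pop()
        if node.depth >= params.max_depth:
            continue
        found = _best_split(cols, targets, node.members, params.min_leaf_size)
        if found is None:
            continue
        _, ci, kind, crit = found
        name, _, vals, missing = cols[ci]
        memb = node.members
        miss = memb[missing[memb]]
        nm = memb[~missing[memb]]
        if kind == NUMERIC:
            lmask = vals[nm] <= crit
            node.threshold = float(crit)
        else:
            lmask = vals[nm] == crit
            node.category = crit
        node.attribute = name
        lm, rm = nm[lmask], nm[~lmask]
        # missing-valued members follow the child with more non-missing members
        if len(miss):
            if len(lm) >= len(rm):
                lm = np.sort(np.concatenate([lm, miss]))
            else:
                rm = np.sort(np.concatenate([rm, miss]))
        node.left = TreeNode(members=lm, depth=node.depth + 1)
        node.right = TreeNode(members=rm, depth=node.depth + 1)
        stack.append(node.right)
        stack.append(node.left)
    return root


def _observed_sorted(view_table: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for col in view_table.columns:
        if pd.api.types.is_numeric_dtype(view_table[col]):
            vals = view_table[col].dropna().to_numpy(dtype=float)
            out[col] = np.unique(vals)
    return out


def extract_rules(tree: TreeNode, view_table: pd.DataFrame, view: int,
                  kinds: dict[str, str] | None = None) -> list[ConjunctiveQuery]:
    """Turn every non-root node of a PCT into a conjunctive query.

    The query is the conjunction of split outcomes on the root-to-node path.
    One-sided numeric outcomes are canonicalized to closed intervals using
    the observed values of the training column: ``x <= t`` becomes
    ``[min_obs, t]`` and ``x > t`` becomes ``[succ(t), max_obs]`` where
    ``succ(t)`` is the smallest observed value above the threshold.  Multiple
    conditions on one attribute merge by interval intersection (or category-set
    intersection).  Duplicate queries are removed.
    """
    if kinds is None:
        kinds = {c: (NUMERIC if pd.api.types.is_numeric_dtype(view_table[c])
                     else CATEGORICAL) for c in view_table.columns}
    obs = _observed_sorted(view_table)
    domains = {c: frozenset(view_table[c].dropna().unique())
               for c in view_table.columns if kinds[c] != NUMERIC}

    queries: list[ConjunctiveQuery] = []
    seen: set = set()

    def descend(node: TreeNode, path: list):
        # path entries: (attr, 'num', lo, hi) or (attr, 'cat', allowed_set)
        if path:
            conds = _path_to_conditions(path)
            if conds is not None:
                key = frozenset(conds)
                if key not in seen:
                    seen.add(key)
                    queries.append(ConjunctiveQuery(view, tuple(conds)))
        if node.is_leaf:
            return
        a = node.attribute
        if node.threshold is not None:
            lo, hi = obs[a][0], obs[a][-1]
            t = node.threshold
            succ = obs[a][np.searchsorted(obs[a], t, side="right")]
            descend(node.left, path + [(a, "num", lo, min(hi, t))])
            descend(node.right, path + [(a, "num", max(lo, succ), hi)])
        else:
            dom = domains[a]
            descend(node.left, path + [(a, "cat", frozenset([node.category]))])
            descend(node.right, path + [(a, "cat", dom - {node.category})])

    def _path_to_conditions(path):
        merged: dict[str, tuple] = {}
        order: list[str] = []
        for entry in path:
            a = entry[0]
            if a not in merged:
                merged[a] = entry[1:]
                order.append(a)
            elif entry[1] == "num":
                _, lo0, hi0 = merged[a]
                merged[a] = ("num", max(lo0, entry[2]), min(hi0, entry[3]))
            else:
                _, allowed0 = merged[a]
                merged[a] = ("cat", allowed0 & entry[2])
        conds = []
        for a in order:
            spec = merged[a]
            if spec[0] == "num":
                if spec[1] > spec[2]:
                    return None  # contradictory path
                conds.append(Condition(a, lo=float(spec[1]), hi=float(spec[2])))
            else:
                if not spec[1]:
                    return None
                conds.append(Condition(a, values=frozenset(spec[1])))
        return conds

    descend(tree, [])
    return queries


def construct_targets(rules: list[ConjunctiveQuery],
                      data: TwoViewDataset) -> np.ndarray:
    """Binary target matrix: entry (i, j) = 1 iff instance i is definitely
    described by rule j; unknown membership (missing values) counts as 0."""
    n = data.n
    if not rules:
        return np.zeros((n, 0))
    cols = [evaluate_query(q, data) == IN for q in rules]
    return np.column_stack(cols).astype(float)
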