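"""The alternating tree-based mining loop.

One round of the miner re-describes, on each view, the instance groups found
on the *opposite* view in the previous round: rule supports become binary
targets, a multi-target PCT is grown, its nodes become new rules, and new
rules of one view are crossed with the previous round's rules of the other
view.  Quality-passing pairs feed the bounded redescription-set optimizer;
the surviving set is query-minimized at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain

import numpy as np

from . import constraints as cb
from .data_model import (IN, ConjunctiveQuery, QualityConstraints,
                         Redescription, TwoViewDataset, check_quality,
                         evaluate_query)
from .pct import PCTParams, build_initial_data, build_pct, construct_targets, extract_rules
from .redset import Alphas, RedescriptionSet

log = logging.getLogger(__name__)


@dataclass
class EngineConfig:
    """Everything the mining loop needs besides the data.

    ``min_leaf_size`` defaults to the lower bound of the support interval:
    tree nodes smaller than the smallest acceptable support cannot yield
    acceptable redescriptions.
    """

    max_iter: int = 50
    quality: QualityConstraints = field(default_factory=QualityConstraints)
    seed: int = 0
    set_capacity: int = 100
    alphas: Alphas = field(default_factory=Alphas)
    max_depth: int = 8
    min_leaf_size: int | None = None

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def pct_params(self) -> PCTParams:
        min_leaf = self.min_leaf_size
        if min_leaf is None:
            min_leaf = max(1, self.quality.support_interval[0])
        return PCTParams(max_depth=self.max_depth, min_leaf_size=min_leaf)


def minimize_query(r: Redescription, data: TwoViewDataset,
                   quality: QualityConstraints,
                   cspec: cb.ConstraintSpec | None = None) -> Redescription | None:
    """Greedily drop conditions that do not hurt accuracy.

    Each condition (insertion order, repeated to a fixpoint) is tentatively
    removed; the removal sticks iff Jqnm does not decrease and the quality
    constraints still hold.  In strict or soft constraint modes, a
    redescription that lost any attribute of interest during minimization is
    discarded (returns None), since the pruned attribute evidently carried no
    support information.
    """
    current = r
    removed: set[str] = set()
    changed = True
    while changed:
        changed = False
        for which in (1, 2):
            q = current.q1 if which == 1 else current.q2
            for idx in range(len(q.conditions)):
                conds = q.conditions[:idx] + q.conditions[idx + 1:]
                trial_q = ConjunctiveQuery(q.view, conds)
                if which == 1:
                    trial = Redescription(trial_q, current.q2, data)
                else:
                    trial = Redescription(current.q1, trial_q, data)
                if trial.jqnm >= current.jqnm and check_quality(trial, quality)[0]:
                    removed.add(q.conditions[idx].attribute)
                    current = trial
                    changed = True
                    break
            if changed:
                break
    if cspec is not None and cspec.mode in (cb.STRICT, cb.SOFT):
        if removed & cspec.all_attributes:
            return None
    return current


def combine_rules(rules_new: list[ConjunctiveQuery],
                  rules_old: list[ConjunctiveQuery],
                  data: TwoViewDataset, quality: QualityConstraints,
                  cspec: cb.ConstraintSpec | None = None,
                  eval_cache: dict | None = None) -> list[Redescription]:
    """Cross two rule lists from opposite views into screened candidates.

    Every admissible pair (row-major order, so downstream tie behavior is
    deterministic) is evaluated into a Redescription; only candidates passing
    the quality constraints and the constraint mode survive.
    """
    if eval_cache is None:
        eval_cache = {}

    def ev(q):
        if q not in eval_cache:
            eval_cache[q] = evaluate_query(q, data)
        return eval_cache[q]

    out = []
    for q1, q2 in cb.filter_rule_pairs(rules_new, rules_old, cspec):
        if q1.view == 2:
            q1, q2 = q2, q1
        r = Redescription.from_evaluations(q1, q2, ev(q1), ev(q2), data.n)
        if not check_quality(r, quality)[0]:
            continue
        if not cb.admissible(r.attrs, cspec):
            continue
        out.append(r)
    return out


def mine(data: TwoViewDataset, config: EngineConfig,
         cspec: cb.ConstraintSpec | None = None,
         trace: list | None = None) -> RedescriptionSet:
    """Run the full mining loop and return the optimized redescription set.

    ``trace``, when given a list, records one ``(iteration, it_q1, it_q2)``
    triple per candidate pair examined, where ``it_qi`` is the iteration that
    produced each rule — used by structural tests, harmless otherwise.
    """
    if data.view1.shape[1] == 0 or data.view2.shape[1] == 0:
        raise ValueError("both views must have at least one attribute")
    rng = np.random.default_rng(config.seed)
    params = config.pct_params()
    kinds = {1: {a.name: a.kind for a in data.attributes(1)},
             2: {a.name: a.kind for a in data.attributes(2)}}

    # Initialization: separate real rows from attribute-wise shuffled copies.
    rules_prev: dict[int, list[ConjunctiveQuery]] = {}
    iter_of: dict[int, int] = {1: 0, 2: 0}
    for v in (1, 2):
        aug, target = build_initial_data(data.view(v), rng)
        tree = build_pct(aug, target, params, kinds[v])
        rules_prev[v] = extract_rules(tree, aug, v, kinds[v])

    rset = RedescriptionSet(data.n, config.set_capacity)
    eval_cache: dict = {}
    minimize_early = cspec is not None and cspec.mode in (cb.STRICT, cb.SOFT)

    for ind in range(1, config.max_iter + 1):
        rules_new: dict[int, list[ConjunctiveQuery]] = {}
        for v, other in ((1, 2), (2, 1)):
            targets = construct_targets(rules_prev[other], data)
            if targets.shape[1] == 0:
                rules_new[v] = []
                continue
            tree = build_pct(data.view(v), targets, params, kinds[v])
            rules_new[v] = extract_rules(tree, data.view(v), v, kinds[v])
        if not rules_new[1] and not rules_new[2]:
            log.warning("iteration %d produced no rules; skipping", ind)
            continue

        # new rules of each view crossed with the previous rules of the other
        passes = ((rules_new[1], rules_prev[2], ind, iter_of[2]),
                  (rules_prev[1], rules_new[2], iter_of[1], ind))
        for r1, r2, it1, it2 in passes:
            candidates = combine_rules(r1, r2, data, config.quality, cspec,
                                       eval_cache)
            if trace is not None:
                trace.extend((ind, it1, it2) for _ in range(len(r1) * len(r2)))
            for r in candidates:
                if minimize_early:
                    r = minimize_query(r, data, config.quality, cspec)
                    if r is None:
                        continue
                rset.add_replace_discard(r, config.alphas, cspec)

        for v in (1, 2):
            if rules_new[v]:
                rules_prev[v] = rules_new[v]
                iter_of[v] = ind

    # Final pass: minimize every retained redescription.
    for idx in range(len(rset.members) - 1, -1, -1):
        minimized = minimize_query(rset.members[idx], data, config.quality, cspec)
        if minimized is None:
            rset.remove_member(idx)
        elif minimized is not rset.members[idx]:
            rset.replace_member(idx, minimized)
    return rset
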