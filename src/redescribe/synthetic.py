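"""Synthetic two-view datasets with planted redescriptions.

The generator emulates the structure of a clinical/biomarker cohort: two
views of mixed-type attributes over shared subjects, per-attribute missing
values, and a five-level ordinal cognitive-status label (CN, SMC, EMCI,
LMCI, AD).  A *plant* is a subset of instances whose values on a few chosen
attributes in BOTH views fall inside narrow designated intervals, so a
perfect conjunctive redescription of that subset exists by construction;
noise perturbs a fraction of planted cells outside their interval, and
missingness masks cells at a per-attribute rate.  Ground truth (subset plus
defining queries) is returned alongside, which makes end-to-end recovery
testable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Condition, ConjunctiveQuery, TwoViewDataset

LABEL_CLASSES = ("CN", "SMC", "EMCI", "LMCI", "AD")

#: background values are uniform over this range; planted intervals are
#: narrow relative to it so chance overlap stays improbable
_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class Plant:
    """One planted cross-view association.

    ``size`` instances get values inside an interval of width
    ``width * (range span)`` on ``k1`` attributes of view 1 and ``k2`` of
    view 2; ``noise`` is the per-cell probability of perturbing a planted
    cell outside its interval; all planted instances share ``label``.
    """

    size: int
    k1: int = 2
    k2: int = 2
    width: float = 0.15
    noise: float = 0.0
    label: str = "AD"

    def __post_init__(self):
        if not 0 < self.width <= 0.2:
            raise ValueError("interval width must be in (0, 0.2] of the range")
        if not 0 <= self.noise < 1:
            raise ValueError("noise rate must be in [0, 1)")
        if self.label not in LABEL_CLASSES:
            raise ValueError(f"label must be one of {LABEL_CLASSES}")


@dataclass(frozen=True)
class PlantSpec:
    """Full recipe for one synthetic dataset."""

    n_instances: int = 500
    n_attrs1: int = 10
    n_attrs2: int = 10
    plants: tuple[Plant, ...] = (Plant(size=100),)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for p in self.plants:
            if p.size > self.n_instances:
                raise ValueError("plant larger than the dataset")
        if sum(p.k1 for p in self.plants) > self.n_attrs1 \
                or sum(p.k2 for p in self.plants) > self.n_attrs2:
            raise ValueError("plants demand more attributes than the views provide")
        if sum(p.size for p in self.plants) > self.n_instances:
            raise ValueError("plants demand more instances than available")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one plant: the subset and its defining queries."""

    instances: np.ndarray  # positions into the dataset
    q1: ConjunctiveQuery
    q2: ConjunctiveQuery
    label: str


def generate(spec: PlantSpec) -> tuple[TwoViewDataset, list[PlantTruth]]:
    """Generate a dataset according to ``spec``; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = _RANGE
    span = hi - lo
    n = spec.n_instances
    v1 = rng.uniform(lo, hi, size=(n, spec.n_attrs1))
    v2 = rng.uniform(lo, hi, size=(n, spec.n_attrs2))

    # assign disjoint instance subsets and disjoint attribute blocks
    perm = rng.permutation(n)
    truths: list[PlantTruth] = []
    inst_off, a1_off, a2_off = 0, 0, 0
    labels = np.array([LABEL_CLASSES[i] for i in rng.integers(0, 5, size=n)],
                      dtype=object)
    names1 = [f"clin_{j}" for j in range(spec.n_attrs1)]
    names2 = [f"bio_{j}" for j in range(spec.n_attrs2)]

    for plant in spec.plants:
        members = np.sort(perm[inst_off:inst_off + plant.size])
        inst_off += plant.size
        conds1, conds2 = [], []
        nonmembers = np.setdiff1d(np.arange(n), members)
        for view_vals, names, k, off, conds in (
                (v1, names1, plant.k1, a1_off, conds1),
                (v2, names2, plant.k2, a2_off, conds2)):
            intervals = []
            for j in range(off, off + k):
                w = plant.width * span
                a = rng.uniform(lo, hi - w)
                b = a + w
                vals = rng.uniform(a, b, size=plant.size)
                if plant.noise > 0:
                    flip = rng.random(plant.size) < plant.noise
                    vals[flip] = _outside(rng, a, b, lo, hi, int(flip.sum()))
                view_vals[members, j] = vals
                conds.append(Condition(names[j], lo=a, hi=b))
                intervals.append((j, a, b))
            # evict background instances that landed inside the whole box, so
            # the truth query describes exactly the planted subset (modulo noise)
            inside = np.ones(len(nonmembers), dtype=bool)
            for j, a, b in intervals:
                col = view_vals[nonmembers, j]
                inside &= (col >= a) & (col <= b)
            stray = nonmembers[inside]
            if len(stray):
                j, a, b = intervals[0]
                view_vals[stray, j] = _outside(rng, a, b, lo, hi, len(stray))
        a1_off += plant.k1
        a2_off += plant.k2
        labels[members] = plant.label
        truths.append(PlantTruth(members,
                                 ConjunctiveQuery(1, tuple(conds1)),
                                 ConjunctiveQuery(2, tuple(conds2)),
                                 plant.label))

    if spec.missing_rate > 0:
        for arr in (v1, v2):
            mask = rng.random(arr.shape) < spec.missing_rate
            arr[mask] = np.nan

    ids = pd.Index([f"id{i:05d}" for i in range(n)], name="id")
    data = TwoViewDataset(pd.DataFrame(v1, index=ids, columns=names1),
                          pd.DataFrame(v2, index=ids, columns=names2),
                          labels=pd.Series(labels, index=ids, name="label"))
    return data, truths


def _outside(rng: np.random.Generator, a: float, b: float,
             lo: float, hi: float, size: int) -> np.ndarray:
    """Uniform draws from the range with the interval [a, b] cut out."""
    left = a - lo
    right = hi - b
    u = rng.uniform(0, left + right, size=size)
    return np.where(u < left, lo + u, b + (u - left))


def null_dataset(n: int, attrs: int, seed: int = 0) -> TwoViewDataset:
    """Two independently generated views: no true cross-view association.

    Useful as a null model for false-discovery checks — any high-overlap
    query pair found here is a chance event, and the binomial significance
    test should flag random pairs as unremarkable.
    """
    rng = np.random.default_rng(seed)
    lo, hi = _RANGE
    ids = pd.Index([f"id{i:05d}" for i in range(n)], name="id")
    v1 = pd.DataFrame(rng.uniform(lo, hi, size=(n, attrs)), index=ids,
                      columns=[f"clin_{j}" for j in range(attrs)])
    v2 = pd.DataFrame(rng.uniform(lo, hi, size=(n, attrs)), index=ids,
                      columns=[f"bio_{j}" for j in range(attrs)])
    return TwoViewDataset(v1, v2)


def support_jaccard(found: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard overlap between a found support and a ground-truth subset."""
    f, t = set(map(int, found)), set(map(int, truth))
    if not f and not t:
        return 0.0
    return len(f & t) / len(f | t)


def to_files(data: TwoViewDataset, truths: list[PlantTruth],
             out_dir: str | Path) -> dict[str, Path]:
    """Write the two views, labels and a ground-truth sidecar as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "view1": out / "view1.tsv",
        "view2": out / "view2.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "ground_truth.json",
    }
    data.view1.to_csv(paths["view1"], sep="\t")
    data.view2.to_csv(paths["view2"], sep="\t")
    if data.labels is not None:
        data.labels.to_frame().to_csv(paths["labels"], sep="\t")
    sidecar = []
    for k, t in enumerate(truths):
        sidecar.append({
            "plant": k,
            "label": t.label,
            "instances": [str(data.instance_ids[i]) for i in t.instances],
            "q1": str(t.q1),
            "q2": str(t.q2),
        })
    paths["truth"].write_text(json.dumps(sidecar, indent=1))
    return paths
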