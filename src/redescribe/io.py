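"""Reading two-view tables and writing/parsing redescription reports.

Input tables are delimited text (comma for ``.csv``, tab otherwise) with a
header row and the instance identifier in the first column; empty cells and
``?`` are missing.  Reports come in two flavours: a human-readable listing
using the interval/conjunction query syntax (``0 <= GDTOTAL <= 2 ∧
GDALIVE = 0``), and a machine-readable TSV whose query strings round-trip
through :func:`parse_query`.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import (Condition, ConjunctiveQuery, Redescription,
                         TwoViewDataset)
from .redset import RedescriptionSet

log = logging.getLogger(__name__)

NA_TOKENS = ["", "?", "NA", "NaN"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=NA_TOKENS,
                     keep_default_na=True)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate instance ids in {path.name}: {dups[:5]}")
    return df


def read_two_view(view1_path: str | Path, view2_path: str | Path,
                  labels_path: str | Path | None = None,
                  kinds: Mapping[str, str] | None = None) -> TwoViewDataset:
    """Load two view files (and optional labels) into a dataset.

    Instances are aligned by id with an inner join; instances present in
    only one view are dropped with a warning.  Attribute kinds are inferred
    (numeric iff every non-missing cell parses as a number) unless
    overridden via ``kinds``.
    """
    v1 = _read_table(view1_path)
    v2 = _read_table(view2_path)
    shared = v1.index.intersection(v2.index)
    if len(shared) == 0:
        raise ValueError("the two views share no instance ids")
    dropped = (len(v1) - len(shared)) + (len(v2) - len(shared))
    if dropped:
        log.warning("dropping %d instances present in only one view", dropped)
    v1 = v1.loc[shared]
    v2 = v2.loc[shared]
    labels = None
    if labels_path is not None:
        ldf = _read_table(labels_path)
        labels = ldf.iloc[:, 0].reindex(shared)
    return TwoViewDataset(v1, v2, labels=labels, kinds=kinds)


# -- query serialization ------------------------------------------------------

_NUM_RE = re.compile(
    r"^\s*(-?[\d.eE+-]+)\s*<=\s*(\S+)\s*<=\s*(-?[\d.eE+-]+)\s*$")
_SET_RE = re.compile(r"^\s*(\S+)\s+in\s+\{(.*)\}\s*$")
_EQ_RE = re.compile(r"^\s*(\S+)\s*=\s*(.+?)\s*$")


def format_query(q: ConjunctiveQuery, precision: int = 17) -> str:
    """Serialize with enough digits that parsing reproduces the bounds."""
    parts = []
    for c in q.conditions:
        if c.is_numeric:
            parts.append(f"{c.lo:.{precision}g} <= {c.attribute} <= {c.hi:.{precision}g}")
        elif len(c.values) == 1:
            (v,) = c.values
            parts.append(f"{c.attribute} = {v}")
        else:
            vals = "|".join(sorted(map(str, c.values)))
            parts.append(f"{c.attribute} in {{{vals}}}")
    return " & ".join(parts) if parts else "TRUE"


def parse_query(text: str, view: int) -> ConjunctiveQuery:
    """Inverse of :func:`format_query` (categorical values parse as strings)."""
    text = text.strip()
    if text == "TRUE" or not text:
        return ConjunctiveQuery(view, ())
    conds = []
    for part in text.split(" & "):
        m = _NUM_RE.match(part)
        if m:
            lo, name, hi = m.groups()
            conds.append(Condition(name, lo=float(lo), hi=float(hi)))
            continue
        m = _SET_RE.match(part)
        if m:
            name, vals = m.groups()
            conds.append(Condition(name, values=frozenset(vals.split("|"))))
            continue
        m = _EQ_RE.match(part)
        if m:
            name, val = m.groups()
            conds.append(Condition(name, values=frozenset([val])))
            continue
        raise ValueError(f"cannot parse query literal {part!r}")
    return ConjunctiveQuery(view, tuple(conds))


# -- report writing -----------------------------------------------------------

def _label_distribution(r: Redescription, labels: pd.Series) -> str:
    counts = labels.reset_index(drop=True).iloc[r.support].value_counts()
    return ";".join(f"{k}:{v}" for k, v in counts.items())


def write_redescriptions(rset: RedescriptionSet | Iterable[Redescription],
                         out_dir: str | Path,
                         labels: pd.Series | None = None,
                         support_matrix: bool = False,
                         instance_ids: pd.Index | None = None) -> dict[str, Path]:
    """Write the human-readable listing, the stats TSV and (optionally) a
    0/1 support-membership matrix.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    members = list(rset)
    paths = {"text": out / "redescriptions.txt",
             "table": out / "redescriptions.tsv"}

    rows = []
    with paths["text"].open("w", encoding="utf-8") as fh:
        fh.write(f"# {len(members)} redescriptions\n")
        for k, r in enumerate(members):
            fh.write(f"\nR{k}:\n  q1: {r.q1}\n  q2: {r.q2}\n")
            fh.write(f"  |E11| = {r.support_size}   Jqnm = {r.jqnm:.6f}"
                     f"   p = {r.pvalue:.3e}\n")
            if labels is not None:
                fh.write(f"  labels: {_label_distribution(r, labels)}\n")
            row = {"id": f"R{k}",
                   "query1": format_query(r.q1),
                   "query2": format_query(r.q2),
                   "support": r.support_size,
                   "jqnm": f"{r.jqnm:.6f}",
                   "pvalue": f"{r.pvalue:.3e}"}
            if labels is not None:
                row["labels"] = _label_distribution(r, labels)
            rows.append(row)
    columns = ["id", "query1", "query2", "support", "jqnm", "pvalue"]
    if labels is not None:
        columns.append("labels")
    pd.DataFrame(rows, columns=columns).to_csv(paths["table"], sep="\t",
                                               index=False)

    if support_matrix:
        paths["support"] = out / "support.tsv"
        if members:
            n = members[0].partition.total
            mat = np.zeros((n, len(members)), dtype=int)
            for k, r in enumerate(members):
                mat[r.support, k] = 1
            idx = instance_ids if instance_ids is not None else pd.RangeIndex(n)
            pd.DataFrame(mat, index=idx,
                         columns=[f"R{k}" for k in range(len(members))]
                         ).to_csv(paths["support"], sep="\t")
        else:
            paths["support"].write_text("\n")
    return paths


def read_redescription_table(path: str | Path) -> pd.DataFrame:
    """Read the stats TSV back; adds parsed ``q1``/``q2`` query columns."""
    df = pd.read_csv(path, sep="\t", dtype={"query1": str, "query2": str})
    if len(df):
        df["q1"] = [parse_query(s, 1) for s in df["query1"]]
        df["q2"] = [parse_query(s, 2) for s in df["query2"]]
    else:
        df["q1"] = []
        df["q2"] = []
    return df


def rebuild_redescriptions(table: pd.DataFrame,
                           data: TwoViewDataset) -> list[Redescription]:
    """Re-evaluate parsed query pairs against a dataset."""
    return [Redescription(q1, q2, data) for q1, q2 in zip(table["q1"], table["q2"])]
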