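"""Ancestry classification, variety naming, and name-cluster correspondence.

Field accessions are classified from their fitted ancestry fractions:
``pure`` when the major ancestry exceeds 0.90, ``half_hybrid`` when it is
between 0.50 and 0.90 inclusive (single-cross or backcross signatures), and
``multi`` otherwise.  Matched library cultivars give accessions their variety
identity; farmer-elicited names are cross-tabulated against genetic clusters
to quantify synonymy (one cultivar, several names) and homonymy (one name,
several cultivars).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clone_id import CloneAssignment, Library
from .io_geno import SampleMeta

__all__ = [
    "classify_ancestry",
    "VarietyReport",
    "build_variety_report",
    "NameCorrespondence",
    "name_correspondence",
    "summarize_varieties",
    "roman",
]

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    out = []
    for v, s in _ROMAN:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def classify_ancestry(
    Q: np.ndarray, pure_threshold: float = 0.90, half_threshold: float = 0.50
) -> pd.DataFrame:
    """Per-sample ancestry class from fitted Q.

    pure: max_k q_ik > pure_threshold; half_hybrid: half_threshold <= max <=
    pure_threshold; multi: max < half_threshold.  Boundary values land in
    half_hybrid (the pure rule is strict, the half rule inclusive).
    """
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must lie on the simplex")
    mx = Q.max(axis=1)
    major = Q.argmax(axis=1)
    cls = np.where(
        mx > pure_threshold, "pure", np.where(mx >= half_threshold, "half_hybrid", "multi")
    )
    return pd.DataFrame(
        {"ancestry_class": cls, "major_ancestry": major, "major_fraction": mx}
    )


@dataclass
class VarietyReport:
    """Per-accession identification plus the Table-1-style variety summary."""

    accessions: pd.DataFrame  # sample_id, clone_group, matched_cultivar, class, ...
    summary: pd.DataFrame

    def counts_by_class(self) -> pd.Series:
        return self.accessions["ancestry_class"].value_counts()


def build_variety_report(
    assign: CloneAssignment,
    classes: pd.DataFrame,
    sample_ids: Sequence[str],
    library: Library | None = None,
    meta: Sequence[SampleMeta] = (),
) -> VarietyReport:
    """Join clone assignment, library matches and ancestry classes per accession."""
    by_id = {m.sample_id: m for m in meta}
    rows = []
    for i, sid in enumerate(sample_ids):
        gid = assign.assignments[sid]
        g = assign.groups[gid]
        m = by_id.get(sid)
        rows.append(
            {
                "sample_id": sid,
                "clone_group": gid,
                "matched_cultivar": g.matched_library_cultivar,
                "matched_distance": g.matched_distance,
                "ancestry_class": classes["ancestry_class"].iloc[i],
                "major_ancestry": int(classes["major_ancestry"].iloc[i]),
                "major_fraction": float(classes["major_fraction"].iloc[i]),
                "elicited_name": m.elicited_name if m else None,
            }
        )
    acc = pd.DataFrame(rows)
    summary = summarize_varieties(acc, library)
    return VarietyReport(acc, summary)


def summarize_varieties(
    accessions: pd.DataFrame, library: Library | None = None
) -> pd.DataFrame:
    """Variety summary table.

    One row per pure variety (major ancestry group of pure accessions) in
    descending accession count with roman-numeral variety labels, then one
    row per >=50 % major-ancestry hybrid group, then one multi-ancestry row.
    Hybrid rows exclude pure members, so rows partition the accessions and
    counts sum to the number of accessions.
    """
    released = set()
    in_library = {}
    if library is not None:
        for c in library.cultivars:
            in_library[c.cultivar_id] = c.is_released
            released.update(c.released_names)

    def status_of(sub: pd.DataFrame) -> str:
        matched = sub["matched_cultivar"].dropna()
        if matched.empty:
            return "not_in_library"
        top = matched.mode().iloc[0]
        if library is not None and in_library.get(top, False):
            return "released"
        return "landrace" if library is not None else "in_library"

    def names_of(sub: pd.DataFrame) -> str:
        names = sub["elicited_name"].dropna()
        if names.empty:
            return ""
        top = names.value_counts().head(3)
        return ", ".join(top.index)

    rows = []
    pure = accessions[accessions["ancestry_class"] == "pure"]
    order = pure.groupby("major_ancestry").size().sort_values(ascending=False)
    numeral_of = {anc: roman(i + 1) for i, anc in enumerate(order.index)}
    for anc, count in order.items():
        sub = pure[pure["major_ancestry"] == anc]
        rows.append(
            {
                "variety": f"Variety {numeral_of[anc]}",
                "ancestry_group": int(anc),
                "n_accessions": int(count),
                "status": status_of(sub),
                "common_names": names_of(sub),
            }
        )
    half = accessions[accessions["ancestry_class"] == "half_hybrid"]
    for anc, count in half.groupby("major_ancestry").size().sort_values(
        ascending=False
    ).items():
        sub = half[half["major_ancestry"] == anc]
        numeral = numeral_of.get(anc, roman(len(numeral_of) + 1))
        rows.append(
            {
                "variety": f"50% ancestry from Variety {numeral}",
                "ancestry_group": int(anc),
                "n_accessions": int(count),
                "status": status_of(sub),
                "common_names": names_of(sub),
            }
        )
    multi = accessions[accessions["ancestry_class"] == "multi"]
    if len(multi):
        rows.append(
            {
                "variety": "Multi-ancestry clones",
                "ancestry_group": -1,
                "n_accessions": int(len(multi)),
                "status": status_of(multi),
                "common_names": names_of(multi),
            }
        )
    return pd.DataFrame(
        rows, columns=["variety", "ancestry_group", "n_accessions", "status", "common_names"]
    )


@dataclass
class NameCorrespondence:
    """Cluster x elicited-name contingency with synonym/homonym indices."""

    table: pd.DataFrame  # clusters as rows, names as columns
    synonyms_per_cluster: pd.Series  # distinct names per cluster
    homonyms_per_name: pd.Series  # distinct clusters per name
    min_name_count: int


def name_correspondence(
    accessions: pd.DataFrame,
    cluster_col: str = "clone_group",
    min_name_count: int = 10,
) -> NameCorrespondence:
    """Cross-tabulate genetic clusters against farmer-elicited names.

    Only names occurring at least ``min_name_count`` times enter the table
    (set to 1 to keep all).  Synonym count = distinct names observed for a
    cluster; homonym count = distinct clusters sharing a name.
    """
    named = accessions.dropna(subset=["elicited_name"])
    if named.empty:
        raise ValueError("no accession carries an elicited name")
    freq = named["elicited_name"].value_counts()
    keep = freq[freq >= min_name_count].index
    named = named[named["elicited_name"].isin(keep)]
    table = pd.crosstab(named[cluster_col], named["elicited_name"])
    synonyms = (table > 0).sum(axis=1)
    homonyms = (table > 0).sum(axis=0)
    return NameCorrespondence(table, synonyms, homonyms, min_name_count)
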