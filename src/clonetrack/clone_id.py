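"""Clone identification from identity-by-state distances.

Vegetatively propagated varieties are genets whose field copies (ramets)
should be genetically identical up to genotyping error — chiefly
heterozygotes miscalled as homozygotes at low read depth.  The workflow here:

1. pairwise IBS distance (mean per-locus allele-sharing mismatch, on
   pairwise-complete loci, normally pre-imputation);
2. Ward minimum-variance dendrogram of that matrix;
3. an identity threshold calibrated on re-genotyped duplicate DNAs
   (safety factor x the largest duplicate distance, ceiled to 2 decimals);
4. clone groups at that threshold (graph components of d < t, or a tree cut);
5. collapsing a reference library to unique cultivars and matching field
   accessions to the nearest library representative under the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io_geno import GenotypeMatrix, SampleMeta

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "IdentityThreshold",
    "CloneGroup",
    "CloneAssignment",
    "Library",
    "LibraryCultivar",
    "ibs_distance",
    "cross_ibs_distance",
    "ward_tree",
    "calibrate_threshold",
    "clone_groups",
    "collapse_library",
    "match_to_library",
]


def _indicators(dosage: np.ndarray, missing: np.ndarray) -> list[np.ndarray]:
    return [((dosage == c) & ~missing).astype(np.float64) for c in (0, 1, 2)]


def pairwise_ibs(
    dosage: np.ndarray, missing: np.ndarray, require_overlap: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs IBS distance d_ab = mean over jointly observed loci of |g_a-g_b|/2.

    Returns (d, n_shared).  Computed via dosage-class indicator matrix
    products, so cost is a handful of n x m by m x n multiplications.
    """
    i0, i1, i2 = _indicators(dosage, missing)
    obs = (~missing).astype(np.float64)
    shared = obs @ obs.T
    diff1 = i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T
    diff2 = i0 @ i2.T + i2 @ i0.T
    if require_overlap:
        off = ~np.eye(len(dosage), dtype=bool)
        if (shared[off] == 0).any():
            a, b = np.argwhere((shared == 0) & off)[0]
            raise ValueError(f"samples at rows {a} and {b} share no observed loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (0.5 * diff1 + diff2) / shared
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # symmetry against fp noise
    shared_i = shared.astype(np.int64)
    return d, shared_i


@dataclass
class DistanceMatrix:
    """Symmetric IBS distance matrix in [0, 1] with per-pair shared-locus counts."""

    sample_ids: list[str]
    d: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if np.nanmax(self.d, initial=0.0) > 1.0 + 1e-12 or np.nanmin(
            self.d, initial=0.0
        ) < -1e-12:
            raise ValueError("IBS distances must lie in [0, 1]")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("non-zero diagonal")

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def ibs_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """IBS distance over pairwise-complete loci; errors if a pair shares none."""
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    d, shared = pairwise_ibs(G.dosage, G.missing, require_overlap=True)
    return DistanceMatrix(list(G.sample_ids), d, shared)


def cross_ibs_distance(A: GenotypeMatrix, B: GenotypeMatrix) -> pd.DataFrame:
    """IBS distances between every sample of A and every sample of B.

    Computed on the intersection of locus sets (order of A); raises if the
    intersection is empty or a pair shares no observed locus.
    """
    common = [l for l in A.locus_ids if l in set(B.locus_ids)]
    if not common:
        raise ValueError("locus sets are disjoint")
    Asub, Bsub = A.subset(loci=common), B.subset(loci=common)
    ia = _indicators(Asub.dosage, Asub.missing)
    ib = _indicators(Bsub.dosage, Bsub.missing)
    obs_a = (~Asub.missing).astype(float)
    obs_b = (~Bsub.missing).astype(float)
    shared = obs_a @ obs_b.T
    diff1 = ia[0] @ ib[1].T + ia[1] @ ib[0].T + ia[1] @ ib[2].T + ia[2] @ ib[1].T
    diff2 = ia[0] @ ib[2].T + ia[2] @ ib[0].T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"samples {A.sample_ids[i]!r} and {B.sample_ids[j]!r} share no loci"
        )
    d = (0.5 * diff1 + diff2) / shared
    return pd.DataFrame(d, index=A.sample_ids, columns=B.sample_ids)


# ---------------------------------------------------------------------------
# Ward dendrogram


@dataclass
class LinkageTree:
    """Ward agglomeration of a DistanceMatrix.

    ``merges`` follows the scipy linkage convention: row t merges nodes a and b
    (original samples are 0..n-1, internal nodes n+t) at ``height`` into a
    cluster of ``size`` leaves; heights are non-decreasing.
    """

    sample_ids: list[str]
    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, height: float) -> np.ndarray:
        """Flat cluster labels after removing merges at height >= ``height``."""
        return hierarchy.fcluster(self.merges, height, criterion="distance")

    def cophenetic(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(hierarchy.cophenet(self.merges))

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.merges)

        def rec(node, parent_h: float) -> str:
            bl = max(parent_h - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{bl:.6g}"
            kids = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            return f"({kids}):{bl:.6g}"

        return rec(root, root.dist) + ";"


def ward_tree(D: DistanceMatrix) -> LinkageTree:
    """Ward minimum-variance tree of the IBS matrix.

    Uses the Lance-Williams squared-distance update
    d(i+j,k)^2 = ((n_i+n_k)d_ik^2 + (n_j+n_k)d_jk^2 - n_k d_ij^2) / (n_i+n_j+n_k)
    applied to the IBS distances taken as-is (no Euclidean embedding is
    assumed), which is the Ward.D2 convention.
    """
    from scipy.spatial.distance import squareform

    y = squareform(D.d, checks=False)
    Z = hierarchy.linkage(y, method="ward")
    return LinkageTree(list(D.sample_ids), Z)


# ---------------------------------------------------------------------------
# identity threshold


@dataclass
class IdentityThreshold:
    value: float
    duplicate_distances: list[float]
    rule: str
    safety_factor: float


def calibrate_threshold(
    D: DistanceMatrix,
    meta: Sequence[SampleMeta],
    safety_factor: float = 1.25,
) -> IdentityThreshold:
    """Empirical identity threshold from re-genotyped duplicate DNAs.

    value = safety_factor x max(duplicate-pair distance), rounded *up* to two
    decimals.  Warns when the threshold reaches the smallest distance between
    distinct library duplicate groups (calibration would merge real clones).
    """
    by_id = {m.sample_id: m for m in meta}
    idx = {s: i for i, s in enumerate(D.sample_ids)}
    groups: dict[str, list[int]] = {}
    for m in meta:
        if m.source == "library" and m.duplicate_group and m.sample_id in idx:
            groups.setdefault(m.duplicate_group, []).append(idx[m.sample_id])
    dup_d: list[float] = []
    for members in groups.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                dup_d.append(float(D.d[members[a], members[b]]))
    if not dup_d:
        raise ValueError(
            "no duplicate pairs among library samples; supply a threshold manually"
        )
    raw = safety_factor * max(dup_d)
    value = math.ceil(raw * 100.0 - 1e-9) / 100.0
    if max(dup_d) == 0.0:
        value = 0.0
        warnings.warn(
            "all duplicate pairs at distance 0; calibrated threshold is 0.00 "
            "(degenerate — any genotyping error will break identity)"
        )
    # smallest between-group distance among library samples in distinct groups
    lib_rows = [i for g in groups.values() for i in g]
    grp_of = {i: g for g, members in groups.items() for i in members}
    between = [
        float(D.d[a, b])
        for ai, a in enumerate(lib_rows)
        for b in lib_rows[ai + 1 :]
        if grp_of[a] != grp_of[b]
    ]
    if between and value >= min(between):
        warnings.warn(
            f"threshold {value:.2f} >= smallest between-clone library distance "
            f"{min(between):.4f}; distinct library clones would merge"
        )
    rule = (
        f"ceil2({safety_factor} * max duplicate distance "
        f"{max(dup_d):.4f} over {len(dup_d)} pairs)"
    )
    return IdentityThreshold(value, sorted(dup_d), rule, safety_factor)


# ---------------------------------------------------------------------------
# clone groups


@dataclass
class CloneGroup:
    group_id: str
    representative: str
    members: list[str]
    matched_library_cultivar: str | None = None
    matched_distance: float | None = None


@dataclass
class CloneAssignment:
    """Partition of samples into clone groups (plus optional library matches)."""

    assignments: dict[str, str]  # sample_id -> group_id
    groups: dict[str, CloneGroup]
    threshold: float
    rule: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, gid in self.assignments.items():
            g = self.groups[gid]
            rows.append(
                {
                    "sample_id": sid,
                    "clone_group": gid,
                    "representative": g.representative,
                    "group_size": len(g.members),
                    "matched_cultivar": g.matched_library_cultivar,
                    "matched_distance": g.matched_distance,
                }
            )
        return pd.DataFrame(rows)


def _group_labels_to_assignment(
    sample_ids: list[str],
    labels: np.ndarray,
    threshold: float,
    rule: str,
    missing_counts: np.ndarray | None,
) -> CloneAssignment:
    members: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(i)
    # deterministic group ids: by size desc then lexicographically first member
    ordered = sorted(
        members.values(), key=lambda idxs: (-len(idxs), min(sample_ids[i] for i in idxs))
    )
    width = max(3, len(str(len(ordered))))
    groups: dict[str, CloneGroup] = {}
    assignments: dict[str, str] = {}
    for rank, idxs in enumerate(ordered, start=1):
        gid = f"G{rank:0{width}d}"
        if missing_counts is not None:
            rep_i = min(idxs, key=lambda i: (missing_counts[i], sample_ids[i]))
        else:
            rep_i = min(idxs, key=lambda i: sample_ids[i])
        names = sorted(sample_ids[i] for i in idxs)
        groups[gid] = CloneGroup(gid, sample_ids[rep_i], names)
        for i in idxs:
            assignments[sample_ids[i]] = gid
    return CloneAssignment(assignments, groups, threshold, rule)


def clone_groups(
    D: DistanceMatrix,
    t: IdentityThreshold | float,
    rule: Literal["components", "tree_cut"] = "components",
    missing_counts: np.ndarray | None = None,
) -> CloneAssignment:
    """Group samples into clones at the identity threshold.

    ``components``: connected components of the graph with an edge wherever
    d < t (single-linkage transitive closure below the threshold).
    ``tree_cut``: cut the Ward dendrogram at height t.  The representative of
    each group is the member with the fewest missing calls (``missing_counts``
    aligned with D.sample_ids), ties and absence broken lexicographically.
    """
    tv = t.value if isinstance(t, IdentityThreshold) else float(t)
    n = len(D.sample_ids)
    if rule == "components":
        g = nx.Graph()
        g.add_nodes_from(range(n))
        a, b = np.nonzero(np.triu(D.d < tv, k=1))
        g.add_edges_from(zip(a.tolist(), b.tolist()))
        labels = np.empty(n, dtype=int)
        for lab, comp in enumerate(nx.connected_components(g)):
            for i in comp:
                labels[i] = lab
    elif rule == "tree_cut":
        tree = ward_tree(D)
        labels = tree.cut(tv)
    else:
        raise ValueError(f"unknown grouping rule {rule!r}")
    return _group_labels_to_assignment(
        list(D.sample_ids), labels, tv, rule, missing_counts
    )


# ---------------------------------------------------------------------------
# library collapsing and matching


@dataclass
class LibraryCultivar:
    cultivar_id: str
    representative: str
    members: list[str]
    synonyms: list[str]
    released_names: list[str]
    name_conflict: bool = False

    @property
    def is_released(self) -> bool:
        return bool(self.released_names)


@dataclass
class Library:
    """Reference library collapsed to one representative genotype per cultivar."""

    genotypes: GenotypeMatrix  # one row per cultivar, row order = cultivars order
    cultivars: list[LibraryCultivar]

    def __len__(self) -> int:
        return len(self.cultivars)

    def cultivar(self, cultivar_id: str) -> LibraryCultivar:
        for c in self.cultivars:
            if c.cultivar_id == cultivar_id:
                return c
        raise KeyError(cultivar_id)


def collapse_library(
    G_lib: GenotypeMatrix,
    t: IdentityThreshold | float,
    meta: Sequence[SampleMeta] = (),
    rule: Literal["components", "tree_cut"] = "components",
) -> Library:
    """Collapse re-genotyped / redundantly collected library samples to cultivars.

    Samples within the identity threshold merge into one cultivar; all their
    names are kept as synonyms.  Conflicting released-variety names within one
    group are retained and flagged rather than resolved.
    """
    by_id = {m.sample_id: m for m in meta}
    D = ibs_distance(G_lib)
    miss = G_lib.missing.sum(axis=1)
    assign = clone_groups(D, t, rule=rule, missing_counts=miss)
    cultivars: list[LibraryCultivar] = []
    rep_ids: list[str] = []
    for gid in sorted(assign.groups):
        g = assign.groups[gid]
        released: list[str] = []
        synonyms: list[str] = []
        for sid in g.members:
            m = by_id.get(sid)
            if m is None:
                continue
            for name in (m.released_name, m.elicited_name):
                if name and name not in synonyms:
                    synonyms.append(name)
            if m.released_name and m.released_name not in released:
                released.append(m.released_name)
        cid = released[0] if released else (synonyms[0] if synonyms else g.representative)
        cultivars.append(
            LibraryCultivar(
                cultivar_id=cid,
                representative=g.representative,
                members=list(g.members),
                synonyms=synonyms,
                released_names=released,
                name_conflict=len(released) > 1,
            )
        )
        rep_ids.append(g.representative)
    # cultivar ids must be unique; disambiguate colliding names deterministically
    seen: dict[str, int] = {}
    for c in cultivars:
        if c.cultivar_id in seen:
            seen[c.cultivar_id] += 1
            c.cultivar_id = f"{c.cultivar_id}.{seen[c.cultivar_id]}"
        else:
            seen[c.cultivar_id] = 1
    reps = G_lib.subset(samples=rep_ids)
    return Library(reps, cultivars)


def match_to_library(
    G_field: GenotypeMatrix,
    library: Library,
    t: IdentityThreshold | float,
    rule: Literal["components", "tree_cut"] = "components",
) -> CloneAssignment:
    """Group field accessions into clones and match them to library cultivars.

    Each field clone group is matched through its representative to the
    nearest library cultivar representative, accepted only when that distance
    is below the identity threshold; ties break by lowest distance then
    library order.  Unmatched groups carry ``matched_library_cultivar=None``.
    """
    tv = t.value if isinstance(t, IdentityThreshold) else float(t)
    if G_field.n_samples >= 2:
        D = ibs_distance(G_field)
        assign = clone_groups(D, tv, rule=rule, missing_counts=G_field.missing.sum(axis=1))
    else:
        assign = _group_labels_to_assignment(
            list(G_field.sample_ids), np.zeros(G_field.n_samples, dtype=int), tv,
            rule, G_field.missing.sum(axis=1),
        )
    cross = cross_ibs_distance(G_field, library.genotypes)
    cultivar_ids = [c.cultivar_id for c in library.cultivars]
    for g in assign.groups.values():
        row = cross.loc[g.representative].to_numpy()
        j = int(np.argmin(row))  # argmin keeps library order on exact ties
        if row[j] < tv:
            g.matched_library_cultivar = cultivar_ids[j]
            g.matched_distance = float(row[j])
    return assign
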