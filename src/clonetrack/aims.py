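"""Weir-Cockerham F_ST and ancestry-informative marker (AIM) panels.

Per-locus population differentiation is estimated with the Weir-Cockerham
(1984) variance-component estimator theta = a / (a + b + c), where a, b, c
are the among-population, among-individual-within-population and
within-individual components.  Loci exceeding a theta threshold form an AIM
panel; the subset-accuracy experiment refits the supervised admixture model
on a panel (and on equally sized random panels, drawn with replacement) and
scores each refit by the squared Pearson correlation between its aligned
ancestry fractions and those of the full-marker fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestry import AdmixtureFit, align_labels, fit_admixture
from .io_geno import GenotypeMatrix

__all__ = [
    "FstTable",
    "AimPanel",
    "SubsetAccuracy",
    "weir_cockerham_fst",
    "select_aims",
    "labels_from_fit",
    "subset_accuracy_experiment",
]


@dataclass
class FstTable:
    locus_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray  # NaN where undefined
    r: int  # number of subpopulations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "theta": self.theta,
            }
        )

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.theta)


def weir_cockerham_fst(
    G: GenotypeMatrix, subpop_labels: Sequence[int | None] | np.ndarray
) -> FstTable:
    """Per-locus Weir-Cockerham theta for r >= 2 subpopulations.

    ``subpop_labels``: per-sample integer subpopulation, None/-1 to exclude a
    sample.  At each locus the components use only subpopulations with at
    least 2 genotyped samples; theta is NaN where fewer than 2 such
    subpopulations remain or where a + b + c = 0 (monomorphic).
    """
    lab = np.array([-1 if l is None else int(l) for l in subpop_labels])
    pops = np.unique(lab[lab >= 0])
    if len(pops) < 2:
        raise ValueError("need at least 2 subpopulations")
    m = G.n_loci
    obs = ~G.missing
    # per-subpop per-locus: sample count, alt freq, observed het fraction
    n_ij = np.zeros((len(pops), m))
    p_ij = np.zeros((len(pops), m))
    h_ij = np.zeros((len(pops), m))
    for pi, pop in enumerate(pops):
        rows = lab == pop
        o = obs[rows]
        n = o.sum(axis=0)
        dos = np.where(o, G.dosage[rows], 0)
        het = np.where(o, G.dosage[rows] == 1, False)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_ij[pi] = dos.sum(axis=0) / (2.0 * n)
            h_ij[pi] = het.sum(axis=0) / n
        n_ij[pi] = n
    usable = n_ij >= 2
    n_eff = np.where(usable, n_ij, 0.0)
    p_eff = np.where(usable, p_ij, 0.0)
    h_eff = np.where(usable, h_ij, 0.0)
    r_l = usable.sum(axis=0).astype(float)  # subpops contributing per locus
    valid = r_l >= 2
    r_safe = np.where(valid, r_l, 2.0)
    sum_n = n_eff.sum(axis=0)
    nbar = sum_n / r_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r_safe * nbar - (n_eff**2).sum(axis=0) / (r_safe * nbar)) / (r_safe - 1.0)
        pbar = (n_eff * p_eff).sum(axis=0) / (r_safe * nbar)
        s2 = (n_eff * (p_eff - pbar) ** 2).sum(axis=0) / ((r_safe - 1.0) * nbar)
        hbar = (n_eff * h_eff).sum(axis=0) / (r_safe * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1.0 - pbar) - ((r_safe - 1.0) / r_safe) * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r_safe - 1.0) / r_safe) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(valid & (denom != 0.0), a / np.where(denom == 0, 1, denom), np.nan)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return FstTable(list(G.locus_ids), a, b, c, theta, r=len(pops))


@dataclass
class AimPanel:
    threshold: float
    locus_ids: list[str]
    kind: str = "fst"

    @property
    def size(self) -> int:
        return len(self.locus_ids)


def select_aims(fst: FstTable, threshold: float) -> AimPanel:
    """Loci with defined theta strictly above ``threshold``, input order kept."""
    keep = [
        lid
        for lid, th in zip(fst.locus_ids, fst.theta)
        if not np.isnan(th) and th > threshold
    ]
    if not keep:
        raise ValueError(
            f"no locus exceeds F_ST threshold {threshold}; lower the threshold"
        )
    return AimPanel(threshold, keep)


def labels_from_fit(fit: AdmixtureFit, purity: float = 0.90) -> np.ndarray:
    """Subpopulation labels from a fit: argmax ancestry where max Q > purity, else -1."""
    mx = fit.Q.max(axis=1)
    lab = fit.Q.argmax(axis=1)
    return np.where(mx > purity, lab, -1)


@dataclass
class SubsetAccuracy:
    """R^2 of subset-fit ancestry fractions against the full-marker fit."""

    table: pd.DataFrame  # columns: kind, size, threshold, rep, r2
    per_column: pd.DataFrame  # columns: kind, size, rep, component, r2
    replicates: int
    seed: int

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["kind", "size"], as_index=False)["r2"]
            .agg(mean_r2="mean", sd_r2="std", n="count")
            .fillna({"sd_r2": 0.0})
        )


def _pooled_r2(Q_full: np.ndarray, Q_sub: np.ndarray) -> tuple[float, np.ndarray]:
    sigma = align_labels(Q_full, Q_sub)
    A = Q_sub[:, sigma]
    x, y = Q_full.ravel(), A.ravel()
    r = np.corrcoef(x, y)[0, 1]
    pooled = float(r**2) if np.isfinite(r) else 0.0
    per_col = np.zeros(Q_full.shape[1])
    for k in range(Q_full.shape[1]):
        if Q_full[:, k].std() > 0 and A[:, k].std() > 0:
            per_col[k] = np.corrcoef(Q_full[:, k], A[:, k])[0, 1] ** 2
    return pooled, per_col


def subset_accuracy_experiment(
    G: GenotypeMatrix,
    full_fit: AdmixtureFit,
    panels: Sequence[AimPanel],
    reps: int = 20,
    seed: int = 0,
    purity: float = 0.90,
    include_random: bool = True,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> SubsetAccuracy:
    """Refit supervised admixture on each panel and on size-matched random panels.

    Reference individuals for the supervised refits are the samples pure
    (max Q > ``purity``) in the full fit.  Random panels are drawn uniformly
    with replacement across all loci, ``reps`` times per panel size.
    Non-converged replicates are recorded with ``converged=False`` and
    excluded from summaries by the caller if desired.
    """
    if not panels:
        raise ValueError("no panels supplied")
    rng = np.random.default_rng(seed)
    labels = labels_from_fit(full_fit, purity)
    if set(labels[labels >= 0].tolist()) != set(range(full_fit.K)):
        raise ValueError("every founder needs at least one pure sample to supervise")
    rows, col_rows = [], []

    def one_fit(locus_idx: np.ndarray, kind: str, size: int,
                threshold: float | None, rep: int) -> None:
        # index arrays directly: random panels may repeat a locus (drawn with
        # replacement), which a GenotypeMatrix would reject as duplicate ids
        g = G.dosage[:, locus_idx]
        miss = G.missing[:, locus_idx]
        fit_seed = int(rng.integers(0, 2**31 - 1))
        fit = fit_admixture(
            g, full_fit.K, seed=fit_seed, supervised_labels=labels,
            tol=tol, max_iter=max_iter, n_restarts=1, missing=miss,
        )
        r2, per_col = _pooled_r2(full_fit.Q, fit.Q)
        rows.append(
            {"kind": kind, "size": size, "threshold": threshold, "rep": rep,
             "r2": r2, "converged": fit.converged}
        )
        for k, v in enumerate(per_col):
            col_rows.append(
                {"kind": kind, "size": size, "rep": rep, "component": k, "r2": float(v)}
            )

    locus_pos = {lid: j for j, lid in enumerate(G.locus_ids)}
    for panel in panels:
        idx = np.array([locus_pos[l] for l in panel.locus_ids])
        one_fit(idx, panel.kind, panel.size, panel.threshold, 0)
        if include_random:
            for rep in range(reps):
                ridx = rng.integers(0, G.n_loci, size=panel.size)
                one_fit(ridx, "random", panel.size, None, rep)
    return SubsetAccuracy(
        table=pd.DataFrame(rows),
        per_column=pd.DataFrame(col_rows),
        replicates=reps,
        seed=seed,
    )
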