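"""SNP curation: missingness/MAF locus filters and missing-genotype imputation.

The default filter settings drop loci with more than 40 % missing calls and
minor-allele frequency below 0.01 (computed on non-missing calls only,
MAF = min(p, 1-p) with p the mean dosage over 2).  Missingness is evaluated
before MAF, so a locus failing both is reported under "missing".

Two imputers are provided for the residual missing calls: a per-locus
mean-dosage rounded to the nearest integer dosage (default; downstream
distance and frequency computations are robust to it at MAF-filtered loci)
and a k-nearest-sample imputer using IBS similarity on jointly complete loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io_geno import GenotypeMatrix

__all__ = ["QcConfig", "filter_loci", "impute_missing"]


@dataclass
class QcConfig:
    min_maf: float = 0.01
    max_locus_missing: float = 0.40
    imputer: Literal["per_locus_mean_round", "knn"] = "per_locus_mean_round"
    knn_k: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_locus_missing <= 1.0:
            raise ValueError("max_locus_missing must be in [0, 1]")


def filter_loci(
    G: GenotypeMatrix, cfg: QcConfig | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci failing the missingness then MAF rules.

    Returns the filtered matrix and a per-locus report with columns
    ``locus_id``, ``maf``, ``missing_fraction``, ``retained``, ``reason``
    (reason is ``""`` for retained loci, else ``"missing"`` or ``"maf"``).
    """
    if cfg is None:
        cfg = QcConfig()
    if G.n_samples < 1:
        raise ValueError("need at least one sample")
    miss_frac = G.missing.mean(axis=0)
    p = G.allele_freq()
    maf = np.fmin(p, 1.0 - p)  # NaN for all-missing loci
    fails_missing = miss_frac > cfg.max_locus_missing
    fails_maf = ~fails_missing & (np.isnan(maf) | (maf < cfg.min_maf))
    retained = ~(fails_missing | fails_maf)
    reason = np.where(fails_missing, "missing", np.where(fails_maf, "maf", ""))
    report = pd.DataFrame(
        {
            "locus_id": G.locus_ids,
            "maf": maf,
            "missing_fraction": miss_frac,
            "retained": retained,
            "reason": reason,
        }
    )
    if not retained.any():
        raise ValueError(
            "all loci removed by QC filters; relax min_maf/max_locus_missing"
        )
    kept = np.flatnonzero(retained)
    return G.subset(loci=kept.tolist()), report


def impute_missing(
    G: GenotypeMatrix, cfg: QcConfig | None = None, seed: int | None = None
) -> GenotypeMatrix:
    """Fill every missing call; observed entries are never altered.

    Requires every locus to carry at least one observed call.  The returned
    matrix has an all-false missing mask and dosages in {0, 1, 2}.
    """
    if cfg is None:
        cfg = QcConfig()
    if not G.missing.any():
        return G.copy()
    obs_per_locus = (~G.missing).sum(axis=0)
    if (obs_per_locus == 0).any():
        bad = [G.locus_ids[j] for j in np.flatnonzero(obs_per_locus == 0)]
        raise ValueError(f"all-missing loci cannot be imputed: {bad[:5]}")
    if cfg.imputer == "per_locus_mean_round":
        filled = _impute_mean_round(G)
    elif cfg.imputer == "knn":
        filled = _impute_knn(G, cfg.knn_k)
    else:
        raise ValueError(f"unknown imputer {cfg.imputer!r}")
    return GenotypeMatrix(
        list(G.sample_ids),
        list(G.locus_ids),
        filled,
        np.zeros(G.missing.shape, dtype=bool),
    )


def _impute_mean_round(G: GenotypeMatrix) -> np.ndarray:
    mean = 2.0 * G.allele_freq()
    fill = np.clip(np.rint(mean), 0, 2).astype(np.int8)
    out = G.dosage.copy()
    rows, cols = np.nonzero(G.missing)
    out[rows, cols] = fill[cols]
    return out


def _impute_knn(G: GenotypeMatrix, k: int) -> np.ndarray:
    from .clone_id import pairwise_ibs  # local import to avoid a cycle

    d, shared = pairwise_ibs(G.dosage, G.missing, require_overlap=False)
    np.fill_diagonal(d, np.inf)
    d[shared == 0] = np.inf
    out = G.dosage.copy()
    mean_fill = np.clip(np.rint(2.0 * G.allele_freq()), 0, 2).astype(np.int8)
    for i in np.flatnonzero(G.missing.any(axis=1)):
        order = np.argsort(d[i], kind="stable")
        for j in np.flatnonzero(G.missing[i]):
            donors = [h for h in order if np.isfinite(d[i, h]) and not G.missing[h, j]]
            if not donors:
                out[i, j] = mean_fill[j]
                continue
            vals = G.dosage[donors[:k], j].astype(float)
            out[i, j] = int(np.clip(np.rint(vals.mean()), 0, 2))
    return out
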