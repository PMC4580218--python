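"""Discriminant analysis of principal components (DAPC) validation clustering.

DAPC makes no Hardy-Weinberg or linkage assumptions: the dosage matrix is
column-centered and reduced by PCA, k-means with a BIC scan discovers groups,
and linear discriminant axes (between/within scatter of the retained PCs)
yield per-individual membership probabilities via a Gaussian kernel on
discriminant-space distances to group centroids.  Used here to cross-check
model-based admixture clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .ancestry import AdmixtureFit
from .io_geno import GenotypeMatrix

__all__ = [
    "DapcFit",
    "pca_transform",
    "kmeans_bic_scan",
    "dapc_fit",
    "compare_clusterings",
]


def pca_transform(G: GenotypeMatrix | np.ndarray, n_pcs: int) -> np.ndarray:
    """Scores of the column-centered dosage matrix on its top principal axes.

    Missing calls must be imputed beforehand.  Deterministic sign convention:
    on each axis the loading with the largest magnitude is made positive.
    Requests beyond the matrix rank are truncated with a warning.
    """
    if isinstance(G, GenotypeMatrix):
        if G.missing.any():
            raise ValueError("impute missing genotypes before PCA")
        X = G.dosage.astype(float)
    else:
        X = np.asarray(G, dtype=float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if n_pcs > rank:
        warnings.warn(f"requested {n_pcs} PCs but rank is {rank}; truncating")
        n_pcs = rank
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    flip = np.sign(Vt[np.arange(n_pcs), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return U * s * flip


def kmeans_bic_scan(
    scores: np.ndarray,
    k_max: int = 40,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Scan k = 1..k_max by k-means; BIC(k) = n ln(W_k/n) + k ln(n).

    W_k is the within-cluster sum of squares of the best run.  Besides
    ``n_init`` k-means++ starts, each k > 1 also tries an initialization that
    augments the previous k's centers with the farthest point, which makes
    W_k non-increasing in k by construction.  Returns (bic_curve, chosen_k,
    labels at chosen_k).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if k_max >= n:
        raise ValueError("k_max must be below the number of samples")
    bic = np.zeros(k_max)
    all_labels: list[np.ndarray] = []
    prev_centers: np.ndarray | None = None
    prev_W = np.inf
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.zeros(n, dtype=int)
            centers = scores.mean(axis=0, keepdims=True)
            W = float(((scores - centers) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
            labels, centers, W = km.labels_, km.cluster_centers_, float(km.inertia_)
            if prev_centers is not None:
                d2 = ((scores[:, None, :] - prev_centers[None]) ** 2).sum(-1).min(1)
                far = scores[int(np.argmax(d2))]
                init = np.vstack([prev_centers, far])
                km2 = KMeans(n_clusters=k, init=init, n_init=1).fit(scores)
                if float(km2.inertia_) < W:
                    labels, centers, W = km2.labels_, km2.cluster_centers_, float(km2.inertia_)
        bic[k - 1] = n * np.log(max(W, 1e-12) / n) + k * np.log(n)
        all_labels.append(labels.copy())
        prev_centers, prev_W = centers, W
    chosen_k = int(np.argmin(bic)) + 1
    return bic, chosen_k, all_labels[chosen_k - 1]


@dataclass
class DapcFit:
    retained_pcs: int
    bic_curve: np.ndarray | None
    chosen_k: int
    cluster_labels: np.ndarray
    discriminant_axes: np.ndarray  # (retained_pcs, n_axes)
    membership_probs: np.ndarray  # n x k, rows on the simplex

    def assigned(self) -> np.ndarray:
        return self.membership_probs.argmax(axis=1)


def dapc_fit(
    scores: np.ndarray,
    labels: np.ndarray,
    n_pcs: int = 70,
    ridge: float = 1e-8,
) -> DapcFit:
    """Linear discriminant axes and membership probabilities for given groups.

    Axes solve the generalized eigenproblem S_b v = lambda S_w v on the first
    ``n_pcs`` retained PCs (within-scatter ridge-regularized if singular);
    membership_prob(i, g) is proportional to exp(-d^2/2) for the discriminant-
    space distance to centroid g, normalized per individual.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pcs = min(n_pcs, scores.shape[1])
    X = scores[:, :n_pcs]
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([(labels == g).sum() for g in groups])
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 members")
    grand = X.mean(axis=0)
    Sw = np.zeros((n_pcs, n_pcs))
    Sb = np.zeros((n_pcs, n_pcs))
    centroids = np.zeros((len(groups), n_pcs))
    for gi, g in enumerate(groups):
        Xg = X[labels == g]
        mu = Xg.mean(axis=0)
        centroids[gi] = mu
        Sw += (Xg - mu).T @ (Xg - mu)
        Sb += len(Xg) * np.outer(mu - grand, mu - grand)
    Sw += ridge * np.trace(Sw) / max(n_pcs, 1) * np.eye(n_pcs) + 1e-12 * np.eye(n_pcs)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][: min(len(groups) - 1, n_pcs)]
    axes = evecs[:, order]
    # sign convention as in pca_transform, so results ignore eigenvector sign
    flip = np.sign(axes[np.abs(axes).argmax(axis=0), np.arange(axes.shape[1])])
    flip[flip == 0] = 1.0
    axes = axes * flip
    Z = X @ axes
    C = centroids @ axes
    d2 = ((Z[:, None, :] - C[None]) ** 2).sum(axis=-1)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    return DapcFit(
        retained_pcs=n_pcs,
        bic_curve=None,
        chosen_k=len(groups),
        cluster_labels=labels.copy(),
        discriminant_axes=axes,
        membership_probs=probs,
    )


def compare_clusterings(
    dapc: DapcFit,
    adm: AdmixtureFit,
    purity: float = 0.90,
) -> dict:
    """Cross-tabulate admixture purity classes against DAPC cluster assignments.

    Returns a dict with the contingency table of pure-admixture members
    (max Q > purity, keyed by their major ancestry) vs DAPC max-membership
    clusters, per-ancestry best-match agreement rates, the counts of samples
    below the purity threshold under each method, overall agreement over pure
    samples, and the adjusted Rand index on pure samples.
    """
    if len(dapc.membership_probs) != len(adm.Q):
        raise ValueError("sample sets differ")
    dlab = dapc.assigned()
    amax = adm.Q.max(axis=1)
    alab = adm.Q.argmax(axis=1)
    pure = amax > purity
    table = pd.crosstab(
        pd.Series(alab[pure], name="admixture_cluster"),
        pd.Series(dlab[pure], name="dapc_cluster"),
    )
    per_cluster = {}
    agree_n = 0
    for ac in table.index:
        row = table.loc[ac]
        per_cluster[int(ac)] = float(row.max() / row.sum())
        agree_n += int(row.max())
    n_pure = int(pure.sum())
    return {
        "table": table,
        "per_cluster_agreement": per_cluster,
        "overall_agreement": agree_n / n_pure if n_pure else float("nan"),
        "n_below_purity_admixture": int((~pure).sum()),
        "n_below_purity_dapc": int((dapc.membership_probs.max(axis=1) <= purity).sum()),
        "ari_pure": float(adjusted_rand_score(alab[pure], dlab[pure])) if n_pure else float("nan"),
    }
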