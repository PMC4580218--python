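"""Maximum-likelihood admixture ancestry estimation.

The model: individual i's genotype at biallelic locus j is
Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj, where q_i (a point on the
K-simplex) is i's vector of ancestry fractions from K founder populations and
f_k is founder k's allele-frequency vector.  Loci are treated as independent
and founders as in Hardy-Weinberg equilibrium — the standard assumptions of
model-based ancestry estimation.

Fitting is by EM on the complete-data likelihood (allele-by-allele origin
indicators as latent variables), which has the same stationary points as the
block-relaxation optimizers used by dedicated ancestry programs and ascends
the observed-data log-likelihood at every step.  Supervised mode pins the Q
rows of reference individuals to founder indicator vectors.

K is chosen by masked-entry cross-validation: non-missing genotype entries
are partitioned into folds, each fold is hidden in turn, the model refit, and
the hidden dosages predicted by their fitted expectation 2*p_ij; the K with
the lowest mean squared prediction error wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_geno import GenotypeMatrix

__all__ = [
    "AdmixtureFit",
    "CvResult",
    "admixture_loglik",
    "fit_admixture",
    "cross_validate_k",
    "align_labels",
]

FREQ_CLAMP = 1e-6  # founder frequencies kept in [delta, 1-delta]


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # n x K, rows on the simplex
    F: np.ndarray  # K x m, clamped frequencies
    loglik: float
    n_iter: int
    converged: bool
    seed: int | None
    loglik_trace: np.ndarray = field(repr=False, default=None)  # type: ignore

    def q_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        idx = list(sample_ids) if sample_ids is not None else range(len(self.Q))
        return pd.DataFrame(
            self.Q, index=idx, columns=[f"K{k + 1}" for k in range(self.K)]
        )


def _prepare(G: GenotypeMatrix | np.ndarray, missing: np.ndarray | None):
    if isinstance(G, GenotypeMatrix):
        g = G.dosage.astype(np.float64)
        w = (~G.missing).astype(np.float64)
    else:
        g = np.asarray(G, dtype=np.float64)
        w = (
            np.ones_like(g)
            if missing is None
            else (~np.asarray(missing, dtype=bool)).astype(np.float64)
        )
        g = np.where(w > 0, g, 0.0)
    return g, w


def admixture_loglik(
    G: GenotypeMatrix | np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    missing: np.ndarray | None = None,
) -> float:
    """Binomial log-likelihood sum_ij [g ln p + (2-g) ln(1-p)], missing skipped."""
    g, w = _prepare(G, missing)
    P = np.clip(Q @ F, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    return float(np.sum(w * (g * np.log(P) + (2.0 - g) * np.log1p(-P))))


def _init_qf(n: int, m: int, K: int, rng: np.random.Generator):
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, m))
    return Q, F


def _em_once(
    g: np.ndarray,
    w: np.ndarray,
    K: int,
    rng: np.random.Generator,
    supervised: np.ndarray | None,
    tol: float,
    max_iter: int,
) -> AdmixtureFit:
    n, m = g.shape
    Q, F = _init_qf(n, m, K, rng)
    if supervised is not None:
        lab = supervised >= 0
        Q[lab] = np.eye(K)[supervised[lab]]
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
        a = w * g / P  # n x m
        b = w * (2.0 - g) / (1.0 - P)
        # E+M for Q: q_ik <- q_ik * sum_j [a f + b (1-f)] / (2 m_i)
        Qn = Q * (a @ F.T + b @ (1.0 - F).T)
        Qn /= Qn.sum(axis=1, keepdims=True)
        if supervised is not None:
            Qn[lab] = np.eye(K)[supervised[lab]]
        # E+M for F with the *current* Q (standard EM sweep order)
        A = F * (Q.T @ a)
        B = (1.0 - F) * (Q.T @ b)
        with np.errstate(invalid="ignore"):
            Fn = A / (A + B)
        Fn = np.where(np.isfinite(Fn), Fn, 0.5)
        Fn = np.clip(Fn, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
        Q, F = Qn, Fn
        ll = float(np.sum(w * (g * np.log(np.clip(Q @ F, FREQ_CLAMP, 1 - FREQ_CLAMP))
                               + (2.0 - g) * np.log1p(-np.clip(Q @ F, FREQ_CLAMP,
                                                               1 - FREQ_CLAMP)))))
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            prev = ll
            break
        prev = ll
    return AdmixtureFit(
        K=K, Q=Q, F=F, loglik=prev, n_iter=it, converged=converged, seed=None,
        loglik_trace=np.asarray(trace),
    )


def fit_admixture(
    G: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    supervised_labels: Sequence[int | None] | np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
    missing: np.ndarray | None = None,
) -> AdmixtureFit:
    """Fit the K-founder admixture model by EM, best of ``n_restarts`` seeds.

    ``supervised_labels``: per-sample founder index (0..K-1) for reference
    individuals, None/-1 for samples to be estimated; every founder must have
    at least one labelled sample in supervised mode.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    g, w = _prepare(G, missing)
    sup = None
    if supervised_labels is not None:
        sup = np.array(
            [-1 if l is None else int(l) for l in supervised_labels], dtype=int
        )
        if sup.max(initial=-1) >= K:
            raise ValueError("supervised label out of range")
        present = set(sup[sup >= 0].tolist())
        if present and present != set(range(K)):
            missing_founders = sorted(set(range(K)) - present)
            raise ValueError(
                f"supervised mode: founders without labelled samples: {missing_founders}"
            )
    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(1, n_restarts)):
        fit = _em_once(g, w, K, rng, sup, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    best.seed = seed
    if not best.converged:
        warnings.warn(
            f"admixture EM did not converge in {max_iter} iterations "
            f"(K={K}, final loglik {best.loglik:.2f})"
        )
    return best


# ---------------------------------------------------------------------------
# cross-validated choice of K


@dataclass
class CvResult:
    k_values: list[int]
    mean_errors: np.ndarray  # per K
    fold_errors: np.ndarray  # len(k_values) x folds
    folds: int
    seed: int
    reassigned_entries: int = 0

    @property
    def best_k(self) -> int:
        return self.k_values[int(np.argmin(self.mean_errors))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"K": k, "fold": f, "error": float(self.fold_errors[i, f])}
            for i, k in enumerate(self.k_values)
            for f in range(self.folds)
        ]
        return pd.DataFrame(rows)


def _assign_folds(
    w: np.ndarray, folds: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Fold id per observed entry (-1 = never masked), reassigning entries whose
    masking would leave a locus (or sample) with no observations in some fold."""
    fold_of = np.full(w.shape, -1, dtype=np.int8)
    obs = np.argwhere(w > 0)
    perm = rng.permutation(len(obs))
    fold_of[obs[perm, 0], obs[perm, 1]] = np.arange(len(obs)) % folds
    reassigned = 0
    for f in range(folds):
        masked = fold_of == f
        kept = (w > 0) & ~masked
        for axis in (0, 1):
            bad = np.flatnonzero(kept.sum(axis=axis) == 0)
            for j in bad:
                cells = (
                    np.flatnonzero(masked[:, j]) if axis == 0 else np.flatnonzero(masked[j])
                )
                if cells.size == 0:
                    continue
                pick = cells[0]
                if axis == 0:
                    fold_of[pick, j] = -1
                    kept[pick, j] = True
                else:
                    fold_of[j, pick] = -1
                    kept[j, pick] = True
                reassigned += 1
    return fold_of, reassigned


def cross_validate_k(
    G: GenotypeMatrix | np.ndarray,
    k_values: Sequence[int] = range(2, 19),
    folds: int = 10,
    seed: int = 0,
    missing: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 300,
    n_restarts: int = 1,
) -> CvResult:
    """Masked-entry 10-fold cross-validation over candidate K.

    Prediction error for a masked entry is (g - 2*p_hat)^2 with p_hat from the
    model refit without it; per-K error is the mean over folds of the fold
    means.  Deterministic for a fixed seed.
    """
    g, w = _prepare(G, missing)
    k_values = list(k_values)
    rng = np.random.default_rng(seed)
    fold_of, reassigned = _assign_folds(w, folds, rng)
    fold_errors = np.zeros((len(k_values), folds))
    for f in range(folds):
        mask = fold_of == f
        if not mask.any():
            raise ValueError(f"fold {f} is empty; too many folds for the data")
        w_train = w * ~mask
        fit_seed = int(rng.integers(0, 2**31 - 1))
        for ki, K in enumerate(k_values):
            fit = fit_admixture(
                g, K, seed=fit_seed, tol=tol, max_iter=max_iter,
                n_restarts=n_restarts, missing=w_train == 0,
            )
            P = np.clip(fit.Q @ fit.F, FREQ_CLAMP, 1 - FREQ_CLAMP)
            err = (g[mask] - 2.0 * P[mask]) ** 2
            fold_errors[ki, f] = float(err.mean())
    return CvResult(
        k_values=k_values,
        mean_errors=fold_errors.mean(axis=1),
        fold_errors=fold_errors,
        folds=folds,
        seed=seed,
        reassigned_entries=reassigned,
    )


# ---------------------------------------------------------------------------
# label alignment


def align_labels(Q_a: np.ndarray, Q_b: np.ndarray) -> np.ndarray:
    """Column permutation sigma of Q_b maximizing sum_k corr(Q_a[:,k], Q_b[:,sigma(k)]).

    Solved as an optimal assignment; a constant (zero-variance) column
    correlates 0 with everything.  Returns sigma such that
    ``Q_b[:, sigma]`` is aligned with ``Q_a``.
    """
    Q_a, Q_b = np.asarray(Q_a, float), np.asarray(Q_b, float)
    if Q_a.shape != Q_b.shape:
        raise ValueError("Q matrices must have identical shape")
    K = Q_a.shape[1]
    if K == 1:
        return np.array([0])
    ca = Q_a - Q_a.mean(axis=0)
    cb = Q_b - Q_b.mean(axis=0)
    sa = np.sqrt((ca**2).sum(axis=0))
    sb = np.sqrt((cb**2).sum(axis=0))
    corr = np.zeros((K, K))
    ok = np.outer(sa > 0, sb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (ca.T @ cb) / np.outer(sa, sb)
    corr[ok] = raw[ok]
    rows, cols = linear_sum_assignment(-corr)
    sigma = np.empty(K, dtype=int)
    sigma[rows] = cols
    return sigma
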