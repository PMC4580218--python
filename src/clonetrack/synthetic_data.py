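"""Synthetic clonal-crop genotype scenarios with full ground truth.

The generator emulates the statistical structure the pipeline assumes:

* K founder populations with independent Beta-distributed allele-frequency
  vectors (default Beta(0.5, 0.5), the U-shaped spectrum typical of drifted
  subpopulations);
* genotypes drawn Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj — pure clones
  (q a founder indicator), F1 hybrids (0.5/0.5), backcrosses (0.75/0.25) and
  multi-founder admixed individuals (Dirichlet with no ancestry >= 0.5);
* genets (genetically unique cultivars) propagated clonally: ramets equal the
  genet genotype except that each heterozygous call is independently miscalled
  as a random homozygote with probability epsilon (the low-read-depth error
  mode of multiplexed sequencing genotyping) and entries drop out missing
  with probability mu;
* a reference library whose accessions are genotyped in duplicate, with a
  farmer naming model producing synonyms and homonyms.

Everything is driven by a single integer seed and returns a
:class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_geno import (
    GenotypeMatrix,
    SampleMeta,
    write_genotype_table,
    write_sample_metadata,
)

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "Scenario",
    "simulate_founders",
    "design_q",
    "simulate_genotypes",
    "make_clonal_copies",
    "build_scenario",
    "emit_scenario",
    "recovery_scenario",
    "FIELD_SURVEY",
]

FREQ_FLOOR = 1e-3  # founder frequencies clamped away from fixation


@dataclass
class SimParams:
    """Study-design parameters for a full scenario."""

    k_true: int = 11
    m: int = 2000
    founder_freq_beta: tuple[float, float] = (0.5, 0.5)
    # reference library
    n_library_cultivars: int = 34
    n_library_accessions: int = 64  # >= cultivars; extras are re-collected synonyms
    duplicates_per_accession: int = 2
    n_library_founders: int = 8  # founders represented in the library
    n_released: int = 16
    # field collection
    n_field_library_clones: int = 550
    n_field_nonlibrary_clones: int = 150
    n_nonlibrary_genets: int = 9
    n_f1: int = 100
    n_backcross: int = 50
    n_multi: int = 50
    # noise
    het_miscall_rate: float = 0.03
    missing_rate: float = 0.02
    # naming model
    max_synonyms_per_genet: int = 3
    homonym_probability: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.het_miscall_rate, self.missing_rate, self.homonym_probability):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.n_library_accessions < self.n_library_cultivars:
            raise ValueError("need at least one library accession per cultivar")
        if self.n_library_founders > self.k_true:
            raise ValueError("library founders cannot exceed k_true")


@dataclass
class SyntheticTruth:
    """Generating parameters and per-sample ground truth."""

    F: np.ndarray  # k_true x m
    sample_ids: list[str]
    Q: np.ndarray  # n x k_true generating ancestry
    genet_of: dict[str, str]  # sample -> genet (clone pedigree)
    category: dict[str, str]
    genet_names: dict[str, list[str]]
    library_cultivar_of_genet: dict[str, str]  # genet -> library cultivar id ("" if none)

    def q_of(self, sample_id: str) -> np.ndarray:
        return self.Q[self.sample_ids.index(sample_id)]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "F": np.round(self.F, 6).tolist(),
            "sample_ids": self.sample_ids,
            "Q": np.round(self.Q, 6).tolist(),
            "genet_of": self.genet_of,
            "category": self.category,
            "genet_names": self.genet_names,
            "library_cultivar_of_genet": self.library_cultivar_of_genet,
        }
        path.write_text(json.dumps(payload))
        return path


@dataclass
class Scenario:
    G: GenotypeMatrix
    meta: list[SampleMeta]
    truth: SyntheticTruth
    params: SimParams


def simulate_founders(
    k: int, m: int, alpha: float = 0.5, beta: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """K x m founder allele frequencies, iid Beta(alpha, beta), clamped off {0,1}."""
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    rng = np.random.default_rng(rng)
    F = rng.beta(alpha, beta, size=(k, m))
    return np.clip(F, FREQ_FLOOR, 1.0 - FREQ_FLOOR)


def design_q(
    k: int,
    n_pure_per_founder: int | Sequence[int],
    n_f1: int = 0,
    n_backcross: int = 0,
    n_multi: int = 0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Ancestry design matrix for pure, F1 (0.5/0.5), backcross (0.75/0.25)
    and multi-founder (Dirichlet(1,..,1) restricted to max < 0.5) individuals.

    Returns (Q, categories); categories in {pure, f1, backcross, multi}.
    """
    rng = np.random.default_rng(rng)
    if isinstance(n_pure_per_founder, int):
        n_pure = [n_pure_per_founder] * k
    else:
        n_pure = list(n_pure_per_founder)
    rows, cats = [], []
    eye = np.eye(k)
    for f, n in enumerate(n_pure):
        for _ in range(n):
            rows.append(eye[f])
            cats.append("pure")
    for _ in range(n_f1):
        a, b = rng.choice(k, size=2, replace=False)
        q = np.zeros(k)
        q[a], q[b] = 0.5, 0.5
        rows.append(q)
        cats.append("f1")
    for _ in range(n_backcross):
        a, b = rng.choice(k, size=2, replace=False)
        q = np.zeros(k)
        q[a], q[b] = 0.75, 0.25
        rows.append(q)
        cats.append("backcross")
    for _ in range(n_multi):
        if k < 3:
            raise ValueError("multi-ancestry design needs k >= 3")
        while True:
            q = rng.dirichlet(np.ones(k))
            if q.max() < 0.5:
                break
        rows.append(q)
        cats.append("multi")
    return np.array(rows).reshape(len(rows), k), cats


def simulate_genotypes(
    F: np.ndarray,
    Q: np.ndarray,
    rng: np.random.Generator | int | None = None,
    missing_rate: float = 0.0,
    sample_ids: Sequence[str] | None = None,
    locus_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Draw g_ij ~ Binomial(2, (QF)_ij), optionally masking entries missing."""
    rng = np.random.default_rng(rng)
    Q, F = np.asarray(Q, float), np.asarray(F, float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("Q rows must lie on the simplex")
    P = Q @ F
    dosage = rng.binomial(2, P).astype(np.int8)
    n, m = dosage.shape
    missing = (
        rng.random((n, m)) < missing_rate
        if missing_rate > 0
        else np.zeros((n, m), dtype=bool)
    )
    sids = list(sample_ids) if sample_ids else [f"S{i:04d}" for i in range(n)]
    lids = list(locus_ids) if locus_ids else [f"L{j:05d}" for j in range(m)]
    return GenotypeMatrix(sids, lids, dosage, missing)


def make_clonal_copies(
    G: GenotypeMatrix,
    which_samples: Sequence[str],
    copies: int,
    het_miscall_rate: float,
    missing_rate: float,
    seed: int | np.random.Generator = 0,
    id_suffix: str = "rep",
) -> tuple[GenotypeMatrix, list[SampleMeta]]:
    """Re-genotyped clonal copies of the chosen samples, appended to ``G``.

    Each copy equals its source except every heterozygous call independently
    flips to a random homozygote (0 or 2, equal probability) with probability
    ``het_miscall_rate``, and entries are masked missing with probability
    ``missing_rate``.  Copies of sample X are named ``X_<suffix>1..`` and share
    ``duplicate_group = X`` in the returned library metadata.
    """
    if not 0.0 <= het_miscall_rate < 1.0 or not 0.0 <= missing_rate < 1.0:
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    new_rows, new_miss, new_ids, meta = [], [], [], []
    for sid in which_samples:
        i = G.sample_index(sid)
        for c in range(1, copies + 1):
            dos, mis = _noisy_copy(
                G.dosage[i], G.missing[i], het_miscall_rate, missing_rate, rng
            )
            cid = f"{sid}_{id_suffix}{c}"
            new_ids.append(cid)
            new_rows.append(dos)
            new_miss.append(mis)
            meta.append(SampleMeta(cid, "library", duplicate_group=sid))
    aug = GenotypeMatrix(
        list(G.sample_ids) + new_ids,
        list(G.locus_ids),
        np.vstack([G.dosage, np.array(new_rows, dtype=np.int8)]),
        np.vstack([G.missing, np.array(new_miss, dtype=bool)]),
    )
    return aug, meta


def _noisy_copy(
    dosage: np.ndarray,
    missing: np.ndarray,
    eps: float,
    mu: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    dos = dosage.copy()
    het = (dos == 1) & ~missing
    flip = het & (rng.random(dos.shape) < eps)
    dos[flip] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(flip.sum()))
    mis = missing | (rng.random(dos.shape) < mu)
    return dos, mis


# ---------------------------------------------------------------------------
# naming model

_NAME_POOL = [
    "Debor", "Ankra", "Bankye Kokoo", "Afisiafi", "Nkabom", "Tuaka", "Gbezeh",
    "Kotee", "Amapomaa", "Navrongo", "Ampenkyene", "Bankye Broni", "Sika Bankye",
    "Akosua Tumtum", "Bankye Tumtum", "Bankye Kakaduro", "Tek Bankye", "Doku Duade",
]


def _genet_names(
    n_genets: int, max_synonyms: int, homonym_prob: float, rng: np.random.Generator
) -> list[list[str]]:
    """Name sets per genet: 1..max_synonyms names each; with probability
    ``homonym_prob`` a name is reused from an earlier genet (homonymy)."""
    out: list[list[str]] = []
    used: list[str] = []
    counter = 0
    for _ in range(n_genets):
        k = int(rng.integers(1, max_synonyms + 1))
        names: list[str] = []
        for _ in range(k):
            if used and rng.random() < homonym_prob:
                names.append(used[int(rng.integers(len(used)))])
            else:
                base = _NAME_POOL[counter % len(_NAME_POOL)]
                suffix = counter // len(_NAME_POOL)
                nm = base if suffix == 0 else f"{base} {suffix + 1}"
                counter += 1
                names.append(nm)
        names = list(dict.fromkeys(names))
        out.append(names)
        used.extend(names)
    return out


# ---------------------------------------------------------------------------
# full scenarios

FIELD_SURVEY = SimParams()  # the defaults are the field-survey desk-scale design


def build_scenario(params: SimParams | None = None) -> Scenario:
    """A complete desk-scale study: duplicated reference library, field
    accessions (library clones, unrepresented clones, hybrids), noisy names.
    """
    p = params or FIELD_SURVEY
    rng = np.random.default_rng(p.seed)
    F = simulate_founders(p.k_true, p.m, *p.founder_freq_beta, rng=rng)
    lids = [f"L{j:05d}" for j in range(p.m)]

    # --- genets -----------------------------------------------------------
    lib_founders = list(range(p.n_library_founders))
    nonlib_founders = list(range(p.n_library_founders, p.k_true)) or lib_founders
    genet_ids: list[str] = []
    genet_founder: dict[str, int] = {}
    for g in range(p.n_library_cultivars):
        gid = f"GEN{g:03d}"
        genet_ids.append(gid)
        genet_founder[gid] = lib_founders[g % len(lib_founders)]
    for g in range(p.n_nonlibrary_genets):
        gid = f"NGEN{g:03d}"
        genet_ids.append(gid)
        genet_founder[gid] = nonlib_founders[g % len(nonlib_founders)]
    Q_genets = np.eye(p.k_true)[[genet_founder[g] for g in genet_ids]]
    genet_G = simulate_genotypes(F, Q_genets, rng=rng, sample_ids=genet_ids,
                                 locus_ids=lids)
    names = _genet_names(len(genet_ids), p.max_synonyms_per_genet,
                         p.homonym_probability, rng)
    genet_names = dict(zip(genet_ids, names))
    lib_genets = genet_ids[: p.n_library_cultivars]
    released_genets = set(lib_genets[: p.n_released])

    sample_rows: list[np.ndarray] = []
    sample_miss: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta: list[SampleMeta] = []
    truth_q: list[np.ndarray] = []
    genet_of: dict[str, str] = {}
    category: dict[str, str] = {}

    def add_sample(sid, dos, mis, q, genet, cat, m_rec):
        sample_ids.append(sid)
        sample_rows.append(dos)
        sample_miss.append(mis)
        truth_q.append(q)
        genet_of[sid] = genet
        category[sid] = cat
        meta.append(m_rec)

    # --- library: accessions (some genets re-collected) in duplicate ------
    extra = p.n_library_accessions - p.n_library_cultivars
    acc_genets = lib_genets + [
        lib_genets[int(rng.integers(len(lib_genets)))] for _ in range(extra)
    ]
    cultivar_of_genet = {g: f"CV{gi:03d}" for gi, g in enumerate(lib_genets)}
    for a, genet in enumerate(acc_genets):
        acc_id = f"LIB{a:03d}"
        gi = genet_G.sample_index(genet)
        nameset = genet_names[genet]
        ename = nameset[int(rng.integers(len(nameset)))]
        rname = f"REL-{cultivar_of_genet[genet]}" if genet in released_genets else None
        for c in range(1, p.duplicates_per_accession + 1):
            dos, mis = _noisy_copy(
                genet_G.dosage[gi], genet_G.missing[gi],
                p.het_miscall_rate, p.missing_rate, rng,
            )
            sid = f"{acc_id}_dup{c}"
            add_sample(
                sid, dos, mis, Q_genets[genet_ids.index(genet)], genet, "library",
                SampleMeta(sid, "library", duplicate_group=acc_id,
                           elicited_name=ename, released_name=rname),
            )

    # --- field accessions --------------------------------------------------
    def field_clone(idx: int, genet: str, cat: str):
        gi = genet_G.sample_index(genet)
        dos, mis = _noisy_copy(
            genet_G.dosage[gi], genet_G.missing[gi],
            p.het_miscall_rate, p.missing_rate, rng,
        )
        sid = f"FLD{idx:04d}"
        nameset = genet_names[genet]
        ename = nameset[int(rng.integers(len(nameset)))]
        hh = f"HH{int(rng.integers(495)):03d}"
        add_sample(sid, dos, mis, Q_genets[genet_ids.index(genet)], genet, cat,
                   SampleMeta(sid, "field", elicited_name=ename, household_id=hh))

    idx = 0
    for _ in range(p.n_field_library_clones):
        field_clone(idx, lib_genets[int(rng.integers(len(lib_genets)))],
                    "field_library_clone")
        idx += 1
    nonlib_genets = genet_ids[p.n_library_cultivars:]
    for _ in range(p.n_field_nonlibrary_clones):
        if not nonlib_genets:
            break
        field_clone(idx, nonlib_genets[int(rng.integers(len(nonlib_genets)))],
                    "field_nonlibrary_clone")
        idx += 1
    # hybrids and admixed seedlings: unique genets, one sample each
    Q_hyb, cats = design_q(p.k_true, 0, p.n_f1, p.n_backcross, p.n_multi, rng=rng)
    if len(Q_hyb):
        hyb_G = simulate_genotypes(F, Q_hyb, rng=rng, missing_rate=p.missing_rate)
        for h in range(len(Q_hyb)):
            sid = f"FLD{idx:04d}"
            genet = f"HGEN{h:03d}"
            ename = f"Local {h % 40}"
            hh = f"HH{int(rng.integers(495)):03d}"
            add_sample(sid, hyb_G.dosage[h], hyb_G.missing[h], Q_hyb[h], genet,
                       cats[h],
                       SampleMeta(sid, "field", elicited_name=ename, household_id=hh))
            genet_names[genet] = [ename]
            idx += 1

    G = GenotypeMatrix(
        sample_ids, lids,
        np.array(sample_rows, dtype=np.int8),
        np.array(sample_miss, dtype=bool),
    )
    truth = SyntheticTruth(
        F=F,
        sample_ids=sample_ids,
        Q=np.array(truth_q),
        genet_of=genet_of,
        category=category,
        genet_names=genet_names,
        library_cultivar_of_genet={
            g: cultivar_of_genet.get(g, "") for g in genet_of.values()
        },
    )
    return Scenario(G, meta, truth, p)


def emit_scenario(
    params: SimParams | None = None, outdir: str | Path = "."
) -> dict[str, Path]:
    """Write a scenario to ``outdir`` (genotypes.tsv, metadata.csv, truth.json)."""
    sc = build_scenario(params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": write_genotype_table(sc.G, outdir / "genotypes.tsv"),
        "metadata": write_sample_metadata(sc.meta, outdir / "metadata.csv"),
        "truth": sc.truth.to_json(outdir / "truth.json"),
    }
    return paths


def recovery_scenario(
    k_true: int = 5,
    m: int = 2000,
    n_pure_per_founder: int = 48,
    n_f1: int = 40,
    n_multi: int = 20,
    n_backcross: int = 0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray, list[str]]:
    """The standard parameter-recovery design: well-separated Beta(0.5,0.5)
    founders, mostly pure individuals plus F1 and admixed ones.

    Returns (G, Q_true, F_true, categories).
    """
    rng = np.random.default_rng(seed)
    F = simulate_founders(k_true, m, rng=rng)
    Q, cats = design_q(k_true, n_pure_per_founder, n_f1, n_backcross, n_multi, rng=rng)
    G = simulate_genotypes(F, Q, rng=rng, missing_rate=missing_rate)
    return G, Q, F, cats
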