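"""Genotype-table and sample-metadata I/O.

The package works on biallelic SNP dosages: each genotype is the count of the
alternate allele (0 = hom ref, 1 = het, 2 = hom alt), with an explicit boolean
missing mask — no magic sentinel dosage is ever stored internally.  Two file
dialects are supported:

``dosage_tsv``
    One row per sample.  Header: ``sample_id`` followed by locus ids; cells are
    ``0``/``1``/``2`` or ``NA``.

``hapmap_like``
    One row per locus (the transposed layout common to GBS pipelines).
    Header: ``locus_id``, ``alleles`` (``REF/ALT``), then sample ids; cells are
    IUPAC genotype codes (``A`` = AA, ``R`` = A/G het, ... , ``N`` missing),
    converted to alt-allele dosage against the per-locus ref/alt declaration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "SampleMeta",
    "read_genotype_table",
    "write_genotype_table",
    "read_sample_metadata",
    "write_sample_metadata",
]

MISSING_CODE = "NA"

# IUPAC ambiguity codes for unordered heterozygous genotypes.
_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_IUPAC_DECODE = {v: k for k, v in _IUPAC_HET.items()}


@dataclass
class GenotypeMatrix:
    """Samples x loci alternate-allele dosage matrix with a missing mask.

    Invariants (checked on construction): unique ids, conforming shapes, every
    non-missing entry in {0, 1, 2}.  Entries under the mask hold a 0
    placeholder and must never be interpreted as calls.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.missing is None:
            self.missing = np.zeros(self.dosage.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = len(self.sample_ids), len(self.locus_ids)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != ({n} samples, {m} loci)"
            )
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape does not match dosage")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        observed = self.dosage[~self.missing]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            bad = np.unique(observed[(observed < 0) | (observed > 2)])
            raise ValueError(f"non-dosage codes present: {bad.tolist()}")
        # placeholder under the mask is always 0
        self.dosage = self.dosage.copy()
        self.dosage[self.missing] = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.locus_ids),
            self.dosage.copy(),
            self.missing.copy(),
        )

    def subset(
        self,
        samples: Sequence[str] | Sequence[int] | None = None,
        loci: Sequence[str] | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset by id or integer position (order preserved as given)."""
        ridx = _resolve(samples, self.sample_ids)
        cidx = _resolve(loci, self.locus_ids)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in ridx],
            [self.locus_ids[j] for j in cidx],
            self.dosage[np.ix_(ridx, cidx)],
            self.missing[np.ix_(ridx, cidx)],
        )

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over non-missing calls (NaN if none)."""
        obs = (~self.missing).sum(axis=0)
        tot = np.where(self.missing, 0, self.dosage).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs > 0, tot / (2.0 * np.maximum(obs, 1)), np.nan)

    def missing_fraction(self, axis: int = 0) -> np.ndarray:
        return self.missing.mean(axis=axis)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(
                np.where(self.missing, 0, self.dosage),
                np.where(other.missing, 0, other.dosage),
            )
        )


def _resolve(sel, ids: list[str]) -> list[int]:
    if sel is None:
        return list(range(len(ids)))
    sel = list(sel)
    if not sel:
        return []
    if isinstance(sel[0], str):
        lookup = {s: i for i, s in enumerate(ids)}
        try:
            return [lookup[s] for s in sel]
        except KeyError as e:
            raise KeyError(f"unknown id {e.args[0]!r}") from None
    return [int(i) for i in sel]


@dataclass
class SampleMeta:
    """Per-sample study metadata.

    ``duplicate_group`` ties together re-genotyped DNAs of the same library
    accession (used for threshold calibration) and is only meaningful for
    library samples.
    """

    sample_id: str
    source: Literal["field", "library"]
    duplicate_group: str | None = None
    elicited_name: str | None = None
    released_name: str | None = None
    household_id: str | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("field", "library"):
            raise ValueError(f"unknown source {self.source!r} for {self.sample_id!r}")
        if self.duplicate_group is not None and self.source != "library":
            raise ValueError(
                f"duplicate_group set on non-library sample {self.sample_id!r}"
            )


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(
    path: str | Path,
    dialect: Literal["dosage_tsv", "hapmap_like"] = "dosage_tsv",
    unknown_as_missing: bool = False,
) -> GenotypeMatrix:
    """Read a genotype table.

    In strict mode (default) any cell outside the dialect's code set raises;
    with ``unknown_as_missing=True`` such cells are masked missing instead.
    """
    path = Path(path)
    if dialect == "dosage_tsv":
        return _read_dosage_tsv(path, unknown_as_missing)
    if dialect == "hapmap_like":
        return _read_hapmap_like(path, unknown_as_missing)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_dosage_tsv(path: Path, unknown_as_missing: bool) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "sample_id":
        raise ValueError(f"{path}: first header field must be 'sample_id'")
    locus_ids = header[1:]
    sample_ids: list[str] = []
    n, m = len(rows) - 1, len(locus_ids)
    dosage = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    for i, row in enumerate(rows[1:]):
        if len(row) != m + 1:
            raise ValueError(
                f"{path}: ragged row {i + 2}: {len(row)} fields, expected {m + 1}"
            )
        sample_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            if cell == MISSING_CODE:
                missing[i, j] = True
            elif cell in ("0", "1", "2"):
                dosage[i, j] = int(cell)
            elif unknown_as_missing:
                missing[i, j] = True
            else:
                raise ValueError(
                    f"{path}: invalid code {cell!r} at row {i + 2}, locus "
                    f"{locus_ids[j]!r} (strict mode)"
                )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample id")
    return GenotypeMatrix(sample_ids, locus_ids, dosage, missing)


def _read_hapmap_like(path: Path, unknown_as_missing: bool) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2 or header[0] != "locus_id" or header[1] != "alleles":
        raise ValueError(f"{path}: header must start with 'locus_id\\talleles'")
    sample_ids = header[2:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample id")
    locus_ids: list[str] = []
    n, m = len(sample_ids), len(rows) - 1
    dosage = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    for j, row in enumerate(rows[1:]):
        if len(row) != n + 2:
            raise ValueError(f"{path}: ragged row {j + 2}")
        locus_ids.append(row[0])
        try:
            ref, alt = row[1].split("/")
        except ValueError:
            raise ValueError(f"{path}: bad alleles field {row[1]!r} at {row[0]!r}")
        het = _IUPAC_HET.get(frozenset((ref, alt)))
        for i, cell in enumerate(row[2:]):
            if cell in ("N", MISSING_CODE):
                missing[i, j] = True
            elif cell == ref:
                dosage[i, j] = 0
            elif cell == alt:
                dosage[i, j] = 2
            elif cell == het:
                dosage[i, j] = 1
            elif unknown_as_missing:
                missing[i, j] = True
            else:
                raise ValueError(
                    f"{path}: genotype {cell!r} incompatible with alleles "
                    f"{row[1]!r} at locus {row[0]!r} (strict mode)"
                )
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError(f"{path}: duplicate locus id")
    return GenotypeMatrix(sample_ids, locus_ids, dosage, missing)


def write_genotype_table(
    G: GenotypeMatrix,
    path: str | Path,
    dialect: Literal["dosage_tsv", "hapmap_like"] = "dosage_tsv",
    alleles: Sequence[str] | None = None,
) -> Path:
    """Write ``G``; lossless round trip with :func:`read_genotype_table`.

    ``hapmap_like`` needs per-locus ``"REF/ALT"`` strings (``alleles``);
    defaults to ``A/G`` everywhere, which round-trips dosages exactly.
    """
    path = Path(path)
    if dialect == "dosage_tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sample_id", *G.locus_ids])
            for i, sid in enumerate(G.sample_ids):
                cells = [
                    MISSING_CODE if G.missing[i, j] else str(int(G.dosage[i, j]))
                    for j in range(G.n_loci)
                ]
                w.writerow([sid, *cells])
        return path
    if dialect == "hapmap_like":
        if alleles is None:
            alleles = ["A/G"] * G.n_loci
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["locus_id", "alleles", *G.sample_ids])
            for j, lid in enumerate(G.locus_ids):
                ref, alt = alleles[j].split("/")
                het = _IUPAC_HET[frozenset((ref, alt))]
                codes = {0: ref, 1: het, 2: alt}
                cells = [
                    "N" if G.missing[i, j] else codes[int(G.dosage[i, j])]
                    for i in range(G.n_samples)
                ]
                w.writerow([lid, alleles[j], *cells])
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sample metadata

_META_FIELDS = [
    "sample_id",
    "source",
    "duplicate_group",
    "elicited_name",
    "released_name",
    "household_id",
    "lat",
    "lon",
]


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata CSV (header required; empty cells -> None)."""
    path = Path(path)
    out: list[SampleMeta] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"{path}: 'sample_id' column required")
        for lineno, row in enumerate(reader, start=2):
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise ValueError(f"{path}: missing sample_id at line {lineno}")
            kwargs = {}
            for f in _META_FIELDS[2:6]:
                v = (row.get(f) or "").strip()
                kwargs[f] = v or None
            for f in ("lat", "lon"):
                v = (row.get(f) or "").strip()
                kwargs[f] = float(v) if v else None
            out.append(SampleMeta(sid, (row.get("source") or "").strip(), **kwargs))
    return out


def write_sample_metadata(meta: Iterable[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_META_FIELDS)
        for rec in meta:
            w.writerow(
                [
                    rec.sample_id,
                    rec.source,
                    rec.duplicate_group or "",
                    rec.elicited_name or "",
                    rec.released_name or "",
                    rec.household_id or "",
                    "" if rec.lat is None else repr(rec.lat),
                    "" if rec.lon is None else repr(rec.lon),
                ]
            )
    return path
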