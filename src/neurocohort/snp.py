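"""Gene-indexed SNP access over PLINK 1.x binary genotype storage.

Genotypes are held in the bed/bim/fam trio: ``.bed`` packs one call into
2 bits (SNP-major: all subjects for one SNP, then the next SNP), ``.bim``
lists the SNPs with chromosome and base-pair position, ``.fam`` lists
the subjects.  Calls are coded here as integers::

    0  homozygous allele1      (bed bits 00)
    1  heterozygous            (bed bits 10)
    2  homozygous allele2      (bed bits 11)
    -1 missing                 (bed bits 01)

Gene symbols resolve to closed base-pair intervals through a gene
location table; SNPs inside the interval feed an allele spreadsheet
export which is capped by a cumulative per-project ledger and shaped so
it can be merged back into the cohort as a user spreadsheet.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPRecord",
    "GeneRecord",
    "GenotypeMatrix",
    "ExportLedger",
    "read_plink",
    "write_plink",
    "load_gene_table",
    "gene_lookup",
    "snps_in_range",
    "export_alleles",
    "HOM_A1",
    "HET",
    "HOM_A2",
    "MISSING",
]

HOM_A1, HET, HOM_A2, MISSING = 0, 1, 2, -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = bytes([0x01])

# 2-bit code -> call, per the PLINK 1.x binary format
_BITS_TO_CALL = np.array([HOM_A1, MISSING, HET, HOM_A2], dtype=np.int8)
_CALL_TO_BITS = {HOM_A1: 0b00, MISSING: 0b01, HET: 0b10, HOM_A2: 0b11}

_VALID_ALLELES = set("ACGT0")


class SNPError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SNPRecord:
    name: str
    chromosome: str
    bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise SNPError(f"SNP {self.name}: bp must be >= 1 (1-based)")
        for a in (self.allele1, self.allele2):
            if a not in _VALID_ALLELES:
                raise SNPError(f"SNP {self.name}: invalid allele {a!r}")

    @property
    def ncbi_url(self) -> str:
        return f"https://www.ncbi.nlm.nih.gov/snp/{self.name}"


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    name: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise SNPError(f"gene {self.name}: start_bp > end_bp")


@dataclasses.dataclass
class GenotypeMatrix:
    """Subjects x SNPs coded genotype calls."""

    subjects: list[str]
    snps: list[SNPRecord]
    calls: np.ndarray          # (n_subjects, n_snps) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise SNPError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, [HOM_A1, HET, HOM_A2, MISSING])
        if bad.any():
            raise SNPError("calls contain invalid codes")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, name: str) -> int:
        for i, s in enumerate(self.snps):
            if s.name == name:
                return i
        raise SNPError(f"unknown SNP {name!r}")


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------

def write_plink(matrix: GenotypeMatrix, out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write bed/bim/fam (SNP-major bed, 2 bits per call)."""
    prefix = Path(out_prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    try:
        n = matrix.n_subjects
        bytes_per_snp = (n + 3) // 4
        with open(bed, "wb") as fh:
            fh.write(_BED_MAGIC + _SNP_MAJOR)
            for j in range(matrix.n_snps):
                packed = bytearray(bytes_per_snp)
                col = matrix.calls[:, j]
                for i in range(n):
                    packed[i // 4] |= _CALL_TO_BITS[int(col[i])] << (2 * (i % 4))
                fh.write(bytes(packed))
        with open(bim, "w", encoding="utf-8") as fh:
            for s in matrix.snps:
                fh.write(
                    f"{s.chromosome}\t{s.name}\t0\t{s.bp}\t{s.allele1}\t{s.allele2}\n"
                )
        with open(fam, "w", encoding="utf-8") as fh:
            for sub in matrix.subjects:
                fh.write(f"{sub}\t{sub}\t0\t0\t0\t-9\n")
    except OSError as exc:
        raise SNPError(f"cannot write PLINK trio at {prefix}: {exc}") from exc
    return bed, bim, fam


def read_plink(
    bed_path: str | Path, bim_path: str | Path | None = None,
    fam_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Decode a PLINK 1.x SNP-major trio into a :class:`GenotypeMatrix`."""
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise SNPError(f"missing PLINK file: {p}")
    snps: list[SNPRecord] = []
    for line in bim_path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, name, _cm, bp, a1, a2 = line.split()
        snps.append(SNPRecord(name, chrom, int(bp), a1, a2))
    subjects = [
        line.split()[1]
        for line in fam_path.read_text().splitlines()
        if line.strip()
    ]
    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise SNPError(f"{bed_path}: bad bed magic bytes")
    if raw[2:3] != _SNP_MAJOR:
        raise SNPError(f"{bed_path}: only SNP-major bed files are supported")
    n, m = len(subjects), len(snps)
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise SNPError(
            f"{bed_path}: size mismatch (got {len(raw)} bytes, expected "
            f"{expected} for {n} subjects x {m} SNPs)"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    calls = np.empty((n, m), dtype=np.int8)
    if m:
        per_snp = body.reshape(m, bytes_per_snp)
        # unpack 2-bit fields, low bits first
        codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (per_snp >> (2 * k)) & 0b11
        calls[:] = _BITS_TO_CALL[codes[:, :n]].T
    return GenotypeMatrix(subjects, snps, calls)


# ---------------------------------------------------------------------------
# gene table and range queries
# ---------------------------------------------------------------------------

def load_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, dtype={"chromosome": str})
    return [
        GeneRecord(r.name, str(r.chromosome), int(r.start_bp), int(r.end_bp))
        for r in df.itertuples(index=False)
    ]


def gene_lookup(query: str, gene_table: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Case-insensitive name-or-regex search; exact-name hits rank first."""
    try:
        rx = re.compile(query, re.IGNORECASE)
    except re.error:
        rx = re.compile(re.escape(query), re.IGNORECASE)
    exact, fuzzy = [], []
    for g in gene_table:
        if g.name.lower() == query.lower():
            exact.append(g)
        elif rx.search(g.name):
            fuzzy.append(g)
    return exact + fuzzy


def snps_in_range(
    matrix: GenotypeMatrix, chromosome: str, start_bp: int, end_bp: int
) -> list[SNPRecord]:
    """SNPs on the chromosome with start_bp <= bp <= end_bp, in bp order."""
    if start_bp > end_bp:
        raise SNPError("start_bp must be <= end_bp")
    hits = [
        s
        for s in matrix.snps
        if s.chromosome == str(chromosome) and start_bp <= s.bp <= end_bp
    ]
    return sorted(hits, key=lambda s: s.bp)


# ---------------------------------------------------------------------------
# capped allele export
# ---------------------------------------------------------------------------

class ExportLedger:
    """Cumulative per-project cap on exported SNP columns.

    The ledger never decreases and failed exports leave it untouched.
    A whole-matrix export is refused regardless of remaining quota.
    """

    def __init__(self, path: str | Path, cap: int = 1000):
        self.path = Path(path)
        self.cap = cap
        if self.path.exists():
            state = json.loads(self.path.read_text())
            self.cumulative = int(state["cumulative"])
            self.cap = int(state.get("cap", cap))
        else:
            self.cumulative = 0
            self._save()

    def _save(self) -> None:
        self.path.write_text(
            json.dumps({"cumulative": self.cumulative, "cap": self.cap})
        )

    @property
    def remaining(self) -> int:
        return max(self.cap - self.cumulative, 0)

    def charge(self, n: int) -> None:
        if n < 0:
            raise SNPError("cannot charge a negative count")
        if self.cumulative + n > self.cap:
            raise SNPError(
                f"export of {n} SNPs refused: only {self.remaining} of the "
                f"{self.cap}-SNP project quota remain"
            )
        self.cumulative += n
        self._save()


def _call_to_pair(call: int, a1: str, a2: str) -> str:
    if call == MISSING:
        return "00"
    if call == HOM_A1:
        return a1 + a1
    if call == HOM_A2:
        return a2 + a2
    return "".join(sorted((a1, a2)))  # heterozygote: alphabetical pair


def export_alleles(
    matrix: GenotypeMatrix,
    snp_names: Sequence[str],
    ledger: ExportLedger,
    out_path: str | Path,
    visit_id: str | None = None,
) -> Path:
    """Write an allele spreadsheet (SubjID, one column per SNP).

    Cells hold two-letter allele pairs ("AG"), "00" for missing.  With
    ``visit_id`` set, a Visit column is added so the file is a valid
    user spreadsheet for the cohort merge.  The ledger is charged before
    writing; an over-cap request is refused naming the remaining quota
    and leaves the ledger unchanged.
    """
    if not snp_names:
        raise SNPError("no SNPs requested")
    if len(set(snp_names)) >= matrix.n_snps and matrix.n_snps > 0:
        raise SNPError("whole-matrix export is not supported")
    idx = [matrix.snp_index(name) for name in snp_names]  # raises on unknown
    ledger.charge(len(snp_names))
    cols = {"SubjID": matrix.subjects}
    if visit_id is not None:
        cols["Visit"] = [visit_id] * matrix.n_subjects
    for name, j in zip(snp_names, idx):
        s = matrix.snps[j]
        cols[name] = [
            _call_to_pair(int(c), s.allele1, s.allele2) for c in matrix.calls[:, j]
        ]
    out_path = Path(out_path)
    pd.DataFrame(cols).to_csv(out_path, index=False)
    return out_path
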