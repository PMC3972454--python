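"""Cohort spreadsheet ingestion, merging, versioning and QC filtering.

A *session* is all data collected for one subject at one visit; it is
identified by a (subject id, visit id) pair and occupies one row of a
:class:`CohortTable`.  A *measure* is one quantitative or categorical
variable and occupies one column.  Studies deliver several
session-by-measure CSV spreadsheets (an imaging spreadsheet, a "super"
spreadsheet with demographic/cognitive/genetic columns, and optional
user-supplied spreadsheets); this module merges them into a single
analysis-ready table, snapshots immutable dataset versions, and applies
quality-control exclusions.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import io
import json
import shutil
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionKey",
    "CohortTable",
    "QCFlag",
    "DatasetVersion",
    "CohortStore",
    "read_table",
    "merge_tables",
    "complete_cases",
    "canonical_csv",
    "table_checksum",
    "DEFAULT_KEY_COLUMNS",
    "MISSING_SENTINELS",
]

DEFAULT_KEY_COLUMNS = ("SubjID", "Visit")

#: cell contents treated as the missing-marker on read (case-insensitive)
MISSING_SENTINELS = ("", "na", "nan")


class CohortError(ValueError):
    """Raised for contract violations in cohort operations."""


@dataclasses.dataclass(frozen=True, order=True)
class SessionKey:
    subject_id: str
    visit_id: str

    def __post_init__(self) -> None:
        if not self.subject_id or not self.visit_id:
            raise CohortError("SessionKey components must be non-empty")

    def __str__(self) -> str:  # used in error messages: "S001/V1"
        return f"{self.subject_id}/{self.visit_id}"


@dataclasses.dataclass
class CohortTable:
    """Sessions x measures matrix; the unit of all downstream statistics.

    ``data`` is indexed by a two-level (subject, visit) MultiIndex; its
    columns are the measure names.  Missing cells are ``NaN`` (numeric) or
    ``None``/``NaN`` (object columns) — never 0 or "".
    """

    data: pd.DataFrame
    key_columns: tuple[str, str] = DEFAULT_KEY_COLUMNS
    version_label: str = ""

    @property
    def keys(self) -> list[SessionKey]:
        return [SessionKey(str(s), str(v)) for s, v in self.data.index]

    @property
    def measures(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_sessions(self) -> int:
        return len(self.data)

    def is_missing(self, key: SessionKey, measure: str) -> bool:
        return bool(pd.isna(self.data.loc[(key.subject_id, key.visit_id), measure]))

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.key_columns, self.version_label)


@dataclasses.dataclass
class QCFlag:
    key: SessionKey
    status: str  # "pass" | "bad"
    annotation: str
    author: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("pass", "bad"):
            raise CohortError(f"QC status must be 'pass' or 'bad', got {self.status!r}")
        if self.status == "bad" and not self.annotation.strip():
            raise CohortError("a 'bad' QC flag requires a non-empty annotation")
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()


@dataclasses.dataclass
class DatasetVersion:
    label: str
    table_paths: list[str]
    checksum: str


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Convert columns that are numeric apart from missing cells."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        original_missing = df[col].isna()
        # convert only if no non-missing value was destroyed
        if (converted.isna() == original_missing).all():
            out[col] = converted
        else:
            out[col] = df[col]
    return pd.DataFrame(out, index=df.index)[df.columns]


def read_table(
    path: str | Path,
    key_columns: Sequence[str] = DEFAULT_KEY_COLUMNS,
) -> CohortTable:
    """Read a session-by-measure CSV into a :class:`CohortTable`.

    Empty strings and NA/NaN sentinels (any case) become the missing
    marker.  Column order is preserved.  Duplicate session keys are an
    error naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    key_columns = tuple(key_columns)
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=False,
    )
    for kc in key_columns:
        if kc not in df.columns:
            raise CohortError(f"key column {kc!r} not found in {path.name} header")
    # sentinel replacement, case-insensitive
    df = df.apply(lambda s: s.mask(s.str.strip().str.lower().isin(MISSING_SENTINELS)))
    for kc in key_columns:
        if df[kc].isna().any():
            raise CohortError(f"missing value in key column {kc!r} of {path.name}")
    dup = df.duplicated(subset=list(key_columns), keep=False)
    if dup.any():
        bad = df.loc[dup, list(key_columns)].drop_duplicates()
        names = ", ".join(f"{r[0]}/{r[1]}" for r in bad.itertuples(index=False))
        raise CohortError(f"duplicate session key(s) in {path.name}: {names}")
    df = df.set_index(list(key_columns))
    df.index.names = list(key_columns)
    df = _coerce_numeric(df)
    return CohortTable(df, key_columns)


def merge_tables(
    primary: CohortTable,
    others: Iterable[CohortTable] | CohortTable,
    collision_policy: str = "prefer-primary-warn",
) -> CohortTable:
    """Full outer join on session key; union of measures.

    Cells absent from a source are missing.  When a measure name appears
    in both tables, ``prefer-primary-warn`` keeps the already-merged value
    and warns if any non-missing values conflict; ``error`` raises instead.
    """
    if collision_policy not in ("prefer-primary-warn", "error"):
        raise CohortError(f"unknown collision policy {collision_policy!r}")
    if isinstance(others, CohortTable):
        others = [others]
    merged = primary.data.copy()
    for other in others:
        if tuple(other.key_columns) != tuple(primary.key_columns):
            raise CohortError(
                "key-column mismatch: "
                f"{primary.key_columns} vs {other.key_columns}"
            )
        odf = other.data
        shared = [c for c in odf.columns if c in merged.columns]
        new_cols = [c for c in odf.columns if c not in merged.columns]
        all_idx = merged.index.union(odf.index, sort=False)
        merged = merged.reindex(all_idx)
        if new_cols:
            merged = merged.join(odf[new_cols], how="left")
        for col in shared:
            theirs = odf[col].reindex(all_idx)
            ours = merged[col]
            both = ours.notna() & theirs.notna()
            conflict = both & (ours != theirs)
            if conflict.any():
                first = all_idx[conflict][0]
                key = f"{first[0]}/{first[1]}"
                if collision_policy == "error":
                    raise CohortError(
                        f"conflicting values for column {col!r} at session {key}"
                    )
                warnings.warn(
                    f"column {col!r} collides on merge (e.g. session {key}); "
                    "keeping primary value",
                    stacklevel=2,
                )
            merged[col] = ours.where(ours.notna(), theirs)
    return CohortTable(merged, primary.key_columns, primary.version_label)


def complete_cases(table: CohortTable, variables: Sequence[str]) -> CohortTable:
    """Listwise deletion: keep sessions with all listed variables non-missing."""
    unknown = [v for v in variables if v not in table.data.columns]
    if unknown:
        raise CohortError(f"unknown variable(s): {', '.join(unknown)}")
    if not variables:
        return table.copy()
    mask = table.data[list(variables)].notna().all(axis=1)
    return CohortTable(table.data.loc[mask].copy(), table.key_columns, table.version_label)


def canonical_csv(table: CohortTable) -> str:
    """Canonical serialization: UTF-8 CSV, LF endings, measures sorted."""
    df = table.data[sorted(table.data.columns)].reset_index()
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.12g")
    return buf.getvalue()


def table_checksum(table: CohortTable) -> str:
    return hashlib.sha256(canonical_csv(table).encode("utf-8")).hexdigest()


class CohortStore:
    """File-backed store: versioned source snapshots, QC ledger, view cache.

    Layout under ``root``::

        versions.json           registry of DatasetVersions
        versions/<label>/       copied source CSVs (immutable snapshot)
        qc.jsonl                append-only QC ledger (latest per session wins)
        cache/<label>.parquet   materialized analysis view (opaque binary cache)
    """

    def __init__(self, root: str | Path, key_columns: Sequence[str] = DEFAULT_KEY_COLUMNS):
        self.root = Path(root)
        self.key_columns = tuple(key_columns)
        self.root.mkdir(parents=True, exist_ok=True)
        (self.root / "versions").mkdir(exist_ok=True)
        (self.root / "cache").mkdir(exist_ok=True)
        self.cache_hits = 0
        self.cache_misses = 0

    # -- registry ----------------------------------------------------------
    @property
    def _registry_path(self) -> Path:
        return self.root / "versions.json"

    def _load_registry(self) -> dict:
        if self._registry_path.exists():
            return json.loads(self._registry_path.read_text())
        return {}

    def _save_registry(self, reg: dict) -> None:
        self._registry_path.write_text(json.dumps(reg, indent=1, sort_keys=True))

    def list_versions(self) -> list[str]:
        return sorted(self._load_registry())

    def register_version(self, label: str, sources: Sequence[str | Path]) -> DatasetVersion:
        """Snapshot source spreadsheets under an immutable version label."""
        if not label:
            raise CohortError("version label must be non-empty")
        reg = self._load_registry()
        if label in reg:
            raise CohortError(f"version label {label!r} already registered")
        vdir = self.root / "versions" / label
        vdir.mkdir(parents=True)
        copied = []
        for src in sources:
            src = Path(src)
            dst = vdir / src.name
            shutil.copyfile(src, dst)
            copied.append(str(dst))
        table = self._merge_version_files(copied, label)
        version = DatasetVersion(label, copied, table_checksum(table))
        reg[label] = dataclasses.asdict(version)
        self._save_registry(reg)
        return version

    def _merge_version_files(self, paths: Sequence[str], label: str) -> CohortTable:
        tables = [read_table(p, self.key_columns) for p in paths]
        merged = merge_tables(tables[0], tables[1:]) if len(tables) > 1 else tables[0]
        merged.version_label = label
        return merged

    def get_version(self, label: str) -> DatasetVersion:
        reg = self._load_registry()
        if label not in reg:
            raise CohortError(f"unknown version {label!r}")
        d = reg[label]
        return DatasetVersion(d["label"], list(d["table_paths"]), d["checksum"])

    def load_version(self, label: str) -> CohortTable:
        """Re-read the snapshot; bit-identical to registration time."""
        v = self.get_version(label)
        return self._merge_version_files(v.table_paths, label)

    # -- QC ledger ---------------------------------------------------------
    @property
    def _qc_path(self) -> Path:
        return self.root / "qc.jsonl"

    def set_qc_flag(
        self,
        key: SessionKey,
        status: str,
        annotation: str = "",
        author: str = "",
        version_label: str | None = None,
    ) -> QCFlag:
        """Persist a QC flag; 'bad' sessions are excluded from analysis views."""
        labels = [version_label] if version_label else self.list_versions()
        known = False
        for lab in labels:
            table = self.load_version(lab)
            if (key.subject_id, key.visit_id) in table.data.index:
                known = True
                break
        if not known:
            raise CohortError(f"unknown session {key} in registered versions")
        flag = QCFlag(key=key, status=status, annotation=annotation, author=author)
        rec = {
            "subject_id": key.subject_id,
            "visit_id": key.visit_id,
            "status": flag.status,
            "annotation": flag.annotation,
            "author": flag.author,
            "timestamp": flag.timestamp,
        }
        with open(self._qc_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec) + "\n")
        return flag

    def active_flags(self) -> dict[SessionKey, QCFlag]:
        """Latest ledger entry per session wins."""
        flags: dict[SessionKey, QCFlag] = {}
        if not self._qc_path.exists():
            return flags
        for line in self._qc_path.read_text().splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            key = SessionKey(rec["subject_id"], rec["visit_id"])
            flags[key] = QCFlag(
                key, rec["status"], rec["annotation"], rec["author"], rec["timestamp"]
            )
        return flags

    def bad_sessions(self) -> set[SessionKey]:
        return {k for k, f in self.active_flags().items() if f.status == "bad"}

    # -- materialized view -------------------------------------------------
    def _qc_state_token(self) -> str:
        content = self._qc_path.read_text() if self._qc_path.exists() else ""
        return hashlib.sha256(content.encode()).hexdigest()

    def materialize_analysis_view(self, version_label: str) -> CohortTable:
        """Merged table minus bad-flagged sessions, cached as a binary artifact.

        The cache is keyed on (version checksum, QC ledger state); a repeated
        call without changes is a cache hit and does not recompute.
        """
        version = self.get_version(version_label)
        token = f"{version.checksum}:{self._qc_state_token()}"
        cache_file = self.root / "cache" / f"{version_label}.parquet"
        meta_file = self.root / "cache" / f"{version_label}.meta"
        if cache_file.exists() and meta_file.exists() and meta_file.read_text() == token:
            self.cache_hits += 1
            df = pd.read_parquet(cache_file)
            df = df.set_index(list(self.key_columns))
            return CohortTable(df, self.key_columns, version_label)
        self.cache_misses += 1
        table = self.load_version(version_label)
        bad = self.bad_sessions()
        if bad:
            drop = [(k.subject_id, k.visit_id) for k in bad
                    if (k.subject_id, k.visit_id) in table.data.index]
            table.data = table.data.drop(index=drop)
        table.data.reset_index().to_parquet(cache_file, index=False)
        meta_file.write_text(token)
        return table
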