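"""On-disk formats: matrices, BOLD series, subject manifests, result tables.

Matrices and time series are plain delimited text (comma or whitespace),
optionally with a header row / leading label column of region names.
Region order is taken from file order and must agree across one
subject's files; region labels are carried as metadata only. Manifests
are JSON or YAML (or delimited tables) mapping subjects to group labels
and file paths. Result tables are TSV with a sorted, deterministic
column order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ising import CouplingMatrix

__all__ = [
    "GROUPS",
    "BoldSeries",
    "SubjectRecord",
    "read_matrix",
    "write_matrix",
    "read_bold",
    "read_manifest",
    "load_subject",
    "write_results_table",
    "read_results_table",
]

GROUPS = ("HC", "VS_UWS", "MCS_MINUS", "MCS_PLUS")

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass(frozen=True)
class BoldSeries:
    """Region-averaged BOLD time series (time x regions)."""

    values: np.ndarray
    scan_label: str
    sampling_interval: float = 1.0  # seconds; metadata only

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("BOLD series must be a 2-D time x regions matrix")
        if v.shape[0] < 3:
            raise ValueError("BOLD series needs at least 3 time points")
        if not np.all(np.isfinite(v)):
            raise ValueError("BOLD series contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group label, structural connectome, 1-2 BOLD scans."""

    subject_id: str
    group: str
    connectome: CouplingMatrix
    bold_scans: tuple[BoldSeries, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        labels = [b.scan_label for b in self.bold_scans]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate scan labels for subject {self.subject_id}")
        n = self.connectome.n_regions
        for b in self.bold_scans:
            if b.n_regions != n:
                raise ValueError(
                    f"subject {self.subject_id}: scan {b.scan_label} has "
                    f"{b.n_regions} regions, connectome has {n}"
                )
        object.__setattr__(self, "bold_scans", tuple(self.bold_scans))


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    group: str
    connectome_path: Path
    bold_paths: dict[str, Path]  # scan label -> path


def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def read_matrix(
    path: str | Path,
    expect_square: bool = True,
    symmetrize_tol: float = 0.0,
) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix, returning (matrix, region labels).

    Accepts comma- or whitespace-delimited text with an optional header
    row and/or leading label column. With ``expect_square`` the matrix
    must be square; asymmetry up to ``symmetrize_tol`` (absolute) is
    averaged away, beyond it is an error.
    """
    path = Path(path)
    raw_rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                raw_rows.append(_tokenize(line))
    if not raw_rows:
        raise ValueError(f"{path}: empty matrix file")

    labels: list[str] | None = None
    has_header = not _NUM_RE.match(raw_rows[0][-1])
    if has_header:
        labels = [t for t in raw_rows[0] if t]
        raw_rows = raw_rows[1:]
        if not raw_rows:
            raise ValueError(f"{path}: header but no data rows")
    has_label_col = bool(raw_rows) and not _NUM_RE.match(raw_rows[0][0])
    if has_label_col:
        row_labels = [r[0] for r in raw_rows]
        raw_rows = [r[1:] for r in raw_rows]
        if labels is None:
            labels = row_labels
        elif len(labels) == len(raw_rows[0]) + 1:
            labels = labels[1:]  # header had a corner cell

    widths = {len(r) for r in raw_rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    mat = np.empty((len(raw_rows), widths.pop()))
    for i, row in enumerate(raw_rows):
        for j, tok in enumerate(row):
            try:
                mat[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} at row {i + 1}, column {j + 1}"
                ) from None
    if expect_square:
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: expected a square matrix, got {mat.shape}")
        asym = np.abs(mat - mat.T).max()
        if asym > symmetrize_tol:
            raise ValueError(
                f"{path}: asymmetry {asym:g} exceeds tolerance {symmetrize_tol:g}"
            )
        mat = 0.5 * (mat + mat.T)
    return mat, labels


def write_matrix(mat: np.ndarray, path: str | Path, labels: list[str] | None = None) -> None:
    """Write a matrix as comma-delimited text with optional region labels."""
    mat = np.asarray(mat, dtype=float)
    path = Path(path)
    with open(path, "w") as fh:
        if labels is not None:
            fh.write(",".join(labels) + "\n")
        for row in mat:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_bold(path: str | Path, scan_label: str, sampling_interval: float = 1.0) -> BoldSeries:
    """Read a time x regions BOLD matrix from delimited text."""
    values, _ = read_matrix(path, expect_square=False)
    return BoldSeries(values=values, scan_label=scan_label, sampling_interval=sampling_interval)


def _entries_from_records(records: list[dict], base: Path, source: str) -> list[ManifestEntry]:
    entries = []
    seen: set[str] = set()
    for rec in records:
        sid = str(rec.get("subject_id", "")).strip()
        if not sid:
            raise ValueError(f"{source}: record without subject_id")
        if sid in seen:
            raise ValueError(f"{source}: duplicate subject_id {sid!r}")
        seen.add(sid)
        group = str(rec.get("group", "")).strip()
        if group not in GROUPS:
            raise ValueError(
                f"{source}: subject {sid}: unknown group {group!r}; expected one of {GROUPS}"
            )
        cpath = rec.get("connectome_path")
        if not cpath:
            raise ValueError(f"{source}: subject {sid}: missing connectome_path")
        bold: dict[str, Path] = {}
        for label in ("t1", "t2"):
            p = rec.get(f"bold_{label}_path")
            if p is not None and str(p).strip() and str(p).lower() != "nan":
                bold[label] = base / str(p)
        if "t1" not in bold:
            raise ValueError(f"{source}: subject {sid}: missing bold_t1_path")
        entries.append(
            ManifestEntry(
                subject_id=sid, group=group, connectome_path=base / str(cpath), bold_paths=bold
            )
        )
    return entries


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a subject manifest (JSON, YAML, CSV, or TSV).

    Required fields per subject: subject_id, group, connectome_path,
    bold_t1_path; bold_t2_path is optional. Relative paths resolve
    against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    suffix = path.suffix.lower()
    if suffix in (".json", ".yaml", ".yml"):
        with open(path) as fh:
            data = json.load(fh) if suffix == ".json" else yaml.safe_load(fh)
        if isinstance(data, dict):
            data = data.get("subjects", data)
        if not isinstance(data, list):
            raise ValueError(f"{path}: manifest must hold a list of subject records")
        records = data
    else:
        sep = "\t" if suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        records = df.to_dict(orient="records")
    entries = _entries_from_records(records, base, str(path))
    missing = [
        f"{e.subject_id}: {p}"
        for e in entries
        for p in [e.connectome_path, *e.bold_paths.values()]
        if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError("manifest references missing files:\n" + "\n".join(missing))
    return entries


def load_subject(entry: ManifestEntry, symmetrize_tol: float = 1e-6) -> SubjectRecord:
    """Load one subject's connectome and scans from a manifest entry.

    The connectome file is read as raw (e.g. streamline-count) weights;
    normalization happens downstream in the analysis.
    """
    mat, _ = read_matrix(entry.connectome_path, expect_square=True, symmetrize_tol=symmetrize_tol)
    np.fill_diagonal(mat, 0.0)
    connectome = CouplingMatrix(mat, normalization="raw")
    scans = tuple(
        read_bold(entry.bold_paths[label], scan_label=label)
        for label in sorted(entry.bold_paths)
    )
    return SubjectRecord(
        subject_id=entry.subject_id, group=entry.group, connectome=connectome, bold_scans=scans
    )


def write_results_table(rows: list[dict], path: str | Path) -> None:
    """Write keyed records as TSV with a sorted, deterministic column order.

    All rows must share exactly the same key set; floats are written in
    full round-trip precision.
    """
    if not rows:
        raise ValueError("nothing to write: empty row list")
    keys = sorted(rows[0])
    for i, row in enumerate(rows):
        if sorted(row) != keys:
            raise ValueError(f"row {i} keys {sorted(row)} differ from {keys}")

    def fmt(v) -> str:
        if isinstance(v, float) or isinstance(v, np.floating):
            return f"{float(v):.17g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(row[k]) for k in keys) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
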