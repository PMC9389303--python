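"""Readers and writers for all on-disk artifacts.

Handled formats:

* search-engine PSM tables in a MaxQuant ``msms.txt``/``msmsScans.txt``-style
  tab-separated dialect (column names configurable, MaxQuant defaults);
* MS2 spectra from MGF and mzML (via pyteomics);
* cluster-assignment files: tab-separated ``raw_file<TAB>scan<TAB>cluster_id``
  lines, blank lines permitted between clusters, one file per stringency
  threshold with the label as a filename suffix (``clusters.p10.tsv``);
* the augmented transfer output table (original columns plus cluster id,
  cluster category, identification type and transferred sequence/flag).

Raw-file names are reconciled across inputs by basename with the extension
stripped, since the three producers handle paths inconsistently.
"""

from __future__ import annotations

import base64
import math
import os
import re
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf

from .records import TMT10_REPORTER_MZ, ClusterAssignment, PsmRecord, SpectrumRecord


class ConfigurationError(ValueError):
    """A required column or parameter is missing or inconsistent."""


class RowParseError(ValueError):
    """A table cell could not be parsed; message carries file/line context."""


class ClusterFileError(ValueError):
    """Malformed cluster-assignment file (e.g. duplicated scan)."""


def strip_raw_name(path_or_name: str) -> str:
    """Basename with a single trailing extension removed."""
    base = os.path.basename(str(path_or_name))
    return os.path.splitext(base)[0] if "." in base else base


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for PSM tables. Defaults follow MaxQuant."""

    raw_file: str = "Raw file"
    scan_number: str = "Scan number"
    sequence: str = "Sequence"
    modified_sequence: str = "Modified sequence"
    proteins: str = "Proteins"
    score: str = "Score"
    pep: str = "PEP"
    reporter_prefix: str = "Reporter intensity corrected"
    decoy_prefix: str = "REV__"
    contaminant_prefix: str = "CON__"
    protein_separator: str = ";"

    def required_columns(self) -> tuple[str, ...]:
        return (
            self.raw_file,
            self.scan_number,
            self.sequence,
            self.modified_sequence,
            self.proteins,
            self.score,
        )


MAXQUANT_DIALECT = TableDialect()


def _to_float(value, path, line, column) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    text = str(value).strip()
    if text in ("", "NaN", "nan", "NA"):
        return float("nan")
    try:
        return float(text)
    except ValueError as exc:
        raise RowParseError(f"{path}:{line}: unparsable number {text!r} in column {column!r}") from exc


def read_search_results(
    path: str,
    dialect: TableDialect = MAXQUANT_DIALECT,
    keep_best_per_scan: bool = True,
) -> list[PsmRecord]:
    """Read a PSM table into :class:`PsmRecord` objects.

    Rows without a sequence yield unidentified records; decoy and contaminant
    markers in the proteins column are flagged. When a scan carries several
    rows and ``keep_best_per_scan`` is set, the best-scoring row is retained
    (identified rows beat unidentified ones regardless of score).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in dialect.required_columns():
        if column not in df.columns:
            raise ConfigurationError(f"{path}: missing required column {column!r}")
    reporter_cols = _reporter_columns(df.columns, dialect.reporter_prefix)

    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = dict(zip(df.columns, row))
        try:
            scan = int(float(row[dialect.scan_number]))
        except ValueError as exc:
            raise RowParseError(
                f"{path}:{i}: unparsable scan number {row[dialect.scan_number]!r}"
            ) from exc
        proteins_field = row[dialect.proteins].strip()
        proteins = tuple(p for p in proteins_field.split(dialect.protein_separator) if p)
        is_decoy = any(p.startswith(dialect.decoy_prefix) for p in proteins)
        is_cont = any(p.startswith(dialect.contaminant_prefix) for p in proteins)
        reporters = None
        if reporter_cols:
            reporters = np.array([_to_float(row[c], path, i, c) for c in reporter_cols])
        pep_val = None
        if dialect.pep in row:
            pep_float = _to_float(row[dialect.pep], path, i, dialect.pep)
            pep_val = None if math.isnan(pep_float) else pep_float
        records.append(
            PsmRecord(
                raw_file=strip_raw_name(row[dialect.raw_file]),
                scan_number=scan,
                sequence=row[dialect.sequence].strip(),
                modified_sequence=row[dialect.modified_sequence].strip().strip("_"),
                proteins=proteins,
                score=_to_float(row[dialect.score], path, i, dialect.score),
                pep=pep_val,
                is_decoy=is_decoy,
                is_contaminant=is_cont,
                reporter_intensities=reporters,
            )
        )
    if keep_best_per_scan:
        records = best_psm_per_scan(records)
    return records


def best_psm_per_scan(records: Iterable[PsmRecord]) -> list[PsmRecord]:
    """Keep one row per scan: identified beats unidentified, then best score."""
    best: dict[tuple[str, int], PsmRecord] = {}
    for rec in records:
        cur = best.get(rec.key)
        if cur is None:
            best[rec.key] = rec
            continue
        rec_rank = (rec.is_identified, -1.0 if math.isnan(rec.score) else rec.score)
        cur_rank = (cur.is_identified, -1.0 if math.isnan(cur.score) else cur.score)
        if rec_rank > cur_rank:
            best[rec.key] = rec
    return [best[key] for key in sorted(best)]


def _reporter_columns(columns: Sequence[str], prefix: str) -> list[str]:
    found: list[tuple[int, str]] = []
    pattern = re.compile(re.escape(prefix) + r"\s+(\d+)$")
    for col in columns:
        m = pattern.match(col)
        if m:
            found.append((int(m.group(1)), col))
    return [col for _, col in sorted(found)]


def write_search_results(
    records: Iterable[PsmRecord],
    path: str,
    dialect: TableDialect = MAXQUANT_DIALECT,
    plex_size: Optional[int] = None,
) -> None:
    """Write PSM records in the tab-separated dialect (round-trip partner)."""
    records = list(records)
    if plex_size is None:
        sizes = {len(r.reporter_intensities) for r in records if r.reporter_intensities is not None}
        plex_size = sizes.pop() if len(sizes) == 1 else 0
    rows = []
    for r in records:
        row = {
            dialect.raw_file: r.raw_file,
            dialect.scan_number: r.scan_number,
            dialect.sequence: r.sequence,
            dialect.modified_sequence: f"_{r.modified_sequence}_" if r.modified_sequence else "",
            dialect.proteins: dialect.protein_separator.join(r.proteins),
            dialect.score: "" if math.isnan(r.score) else repr(float(r.score)),
            dialect.pep: "" if r.pep is None else repr(float(r.pep)),
        }
        for j in range(plex_size):
            val = ""
            if r.reporter_intensities is not None and j < len(r.reporter_intensities):
                val = repr(float(r.reporter_intensities[j]))
            row[f"{dialect.reporter_prefix} {j + 1}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

_SCAN_RE = re.compile(r"scan[=\s:._]*(\d+)", re.I)


def _scan_from_text(*candidates) -> Optional[int]:
    for text in candidates:
        if text is None:
            continue
        text = str(text)
        m = _SCAN_RE.search(text)
        if m:
            return int(m.group(1))
        # MGF title convention raw.scan.scan.charge
        parts = text.split(".")
        if len(parts) >= 3 and parts[1].isdigit() and parts[1] == parts[2]:
            return int(parts[1])
    return None


def extract_reporter_intensities(
    mz: np.ndarray,
    intensity: np.ndarray,
    reporter_mz: Sequence[float] = TMT10_REPORTER_MZ,
    tolerance: float = 0.003,
) -> np.ndarray:
    """Sum peak intensities inside each reporter m/z window (+- tolerance Th)."""
    out = np.zeros(len(reporter_mz))
    for i, r in enumerate(reporter_mz):
        mask = np.abs(mz - r) <= tolerance
        if np.any(mask):
            out[i] = float(np.sum(intensity[mask]))
    return out


def read_spectra(
    path: str,
    format: Optional[str] = None,
    extract_reporters: bool = True,
    reporter_mz: Sequence[float] = TMT10_REPORTER_MZ,
    reporter_tolerance: float = 0.003,
) -> list[SpectrumRecord]:
    """Read MS2 spectra from an MGF or mzML file.

    Non-MS2 scans in mzML are skipped; spectra without an assigned precursor
    charge are retained with ``precursor_charge=None``. Reporter intensities
    are extracted from peaks inside the configured reporter windows.
    """
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    raw_file = strip_raw_name(path)
    if fmt == "mgf":
        spectra = _read_mgf(path, raw_file)
    elif fmt == "mzml":
        spectra = _read_mzml(path, raw_file)
    else:
        raise ConfigurationError(f"unsupported spectrum format {fmt!r} for {path}")
    if extract_reporters:
        for s in spectra:
            if s.reporter_intensities is None and not s.is_empty:
                s.reporter_intensities = extract_reporter_intensities(
                    s.mz, s.intensity, reporter_mz, reporter_tolerance
                )
    return spectra


def _read_mgf(path: str, raw_file: str) -> list[SpectrumRecord]:
    spectra = []
    fallback_scan = 0
    with mgf.MGF(path) as reader:
        for entry in reader:
            params = entry.get("params", {})
            fallback_scan += 1
            scan = _scan_from_text(params.get("scans"), params.get("title")) or fallback_scan
            charge = params.get("charge")
            charge_val = int(charge[0]) if charge else None
            pepmass = params.get("pepmass", (0.0,))[0]
            rt = params.get("rtinseconds")
            spectra.append(
                SpectrumRecord(
                    raw_file=raw_file,
                    scan_number=scan,
                    precursor_mz=float(pepmass),
                    precursor_charge=charge_val,
                    retention_time=float(rt) / 60.0 if rt is not None else None,
                    mz=entry.get("m/z array", np.empty(0)),
                    intensity=entry.get("intensity array", np.empty(0)),
                )
            )
    return spectra


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("name"): cv.get("value", "")
        for cv in element.iter(f"{_MZML_NS}cvParam")
    }


def _decode_binary_array(array_element) -> Optional[np.ndarray]:
    params = _cv_params(array_element)
    binary = array_element.find(f"{_MZML_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return np.empty(0)
    raw = base64.b64decode(binary.text.strip())
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = np.float32 if "32-bit float" in params else np.float64
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str, raw_file: str) -> list[SpectrumRecord]:
    """mzML reading via lxml iterparse (binary arrays per the PSI standard)."""
    spectra = []
    fallback_scan = 0
    for _, element in etree.iterparse(path, tag=f"{_MZML_NS}spectrum"):
        params = _cv_params(element)
        fallback_scan += 1
        if params.get("ms level") != "2":
            element.clear()
            continue
        scan = _scan_from_text(element.get("id")) or fallback_scan
        prec_mz, charge = 0.0, None
        ion = element.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        if ion is not None:
            ion_params = _cv_params(ion)
            prec_mz = float(ion_params.get("selected ion m/z", 0.0))
            if "charge state" in ion_params:
                charge = int(float(ion_params["charge state"]))
        rt = None
        if "scan start time" in params:
            rt = float(params["scan start time"])
        mz_arr, inten_arr = np.empty(0), np.empty(0)
        for array_element in element.iter(f"{_MZML_NS}binaryDataArray"):
            arr_params = _cv_params(array_element)
            values = _decode_binary_array(array_element)
            if "m/z array" in arr_params:
                mz_arr = values
            elif "intensity array" in arr_params:
                inten_arr = values
        spectra.append(
            SpectrumRecord(
                raw_file=raw_file,
                scan_number=int(scan),
                precursor_mz=prec_mz,
                precursor_charge=charge,
                retention_time=rt,
                mz=mz_arr,
                intensity=inten_arr,
            )
        )
        element.clear()
    return spectra


def write_mgf(spectra: Iterable[SpectrumRecord], path: str) -> None:
    """Write spectra to MGF with a ``raw.scan.scan.charge`` title convention."""
    entries = []
    for s in spectra:
        charge = s.precursor_charge or 0
        params = {
            "title": f"{s.raw_file}.{s.scan_number}.{s.scan_number}.{charge}",
            "pepmass": s.precursor_mz,
            "scans": s.scan_number,
        }
        if s.precursor_charge:
            params["charge"] = [s.precursor_charge]
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time * 60.0
        entries.append({"m/z array": s.mz, "intensity array": s.intensity, "params": params})
    mgf.write(entries, output=path, file_mode="w")


# ---------------------------------------------------------------------------
# Cluster-assignment files
# ---------------------------------------------------------------------------


def read_cluster_assignments(path: str, threshold_label: Optional[str] = None) -> ClusterAssignment:
    """Read a ``raw_file<TAB>scan<TAB>cluster_id`` file; renumber ids densely."""
    if threshold_label is None:
        threshold_label = threshold_label_from_path(path) or ""
    entries: dict[tuple[str, int], int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ClusterFileError(f"{path}:{lineno}: expected 3 tab-separated fields")
            key = (strip_raw_name(parts[0]), int(parts[1]))
            if key in entries:
                raise ClusterFileError(f"{path}:{lineno}: duplicate assignment for scan {key}")
            entries[key] = int(parts[2])
    return ClusterAssignment(threshold_label, entries).renumbered()


def write_cluster_assignments(assignment: ClusterAssignment, path: str) -> None:
    """Write a cluster file, members grouped per cluster, blank line between."""
    by_cluster: dict[int, list[tuple[str, int]]] = {}
    for key, cid in assignment.entries.items():
        by_cluster.setdefault(cid, []).append(key)
    with open(path, "w") as handle:
        for i, cid in enumerate(sorted(by_cluster)):
            if i:
                handle.write("\n")
            for raw, scan in sorted(by_cluster[cid]):
                handle.write(f"{raw}\t{scan}\t{cid}\n")


def threshold_label_from_path(path: str) -> Optional[str]:
    m = re.search(r"\.(p\d+)\.\w+$", os.path.basename(path))
    return m.group(1) if m else None


# ---------------------------------------------------------------------------
# Transfer output table
# ---------------------------------------------------------------------------

TRANSFER_COLUMNS = {
    "raw_file": "Raw file",
    "scan_number": "Scan number",
    "batch_id": "Batch",
    "sequence": "Sequence",
    "modified_sequence": "Modified sequence",
    "proteins": "Proteins",
    "score": "Score",
    "pep": "PEP",
    "cluster_id": "Cluster ID",
    "cluster_category": "Cluster category",
    "identification_type": "Identification type",
    "transferred_flag": "Transferred sequence or flag",
}


def write_transfer_table(table: pd.DataFrame, path: str, dialect: TableDialect = MAXQUANT_DIALECT) -> None:
    """Write the finalized merged table, one row per MS2 scan."""
    from .transfer import CATEGORY_LETTERS  # local import to avoid a cycle

    out = pd.DataFrame()
    for internal, public in TRANSFER_COLUMNS.items():
        if internal not in table.columns:
            continue
        col = table[internal]
        if internal == "cluster_category":
            col = col.map(lambda c: f"{CATEGORY_LETTERS.get(c, '?')}:{c}" if c else "")
        out[public] = col
    reporter_cols = [c for c in table.columns if c.startswith("reporter_")]
    for c in sorted(reporter_cols, key=lambda x: int(x.split("_")[1])):
        out[f"{dialect.reporter_prefix} {int(c.split('_')[1]) + 1}"] = table[c]
    out.to_csv(path, sep="\t", index=False)


def read_transfer_table(path: str, dialect: TableDialect = MAXQUANT_DIALECT) -> pd.DataFrame:
    """Read back a written transfer table into the internal column layout."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = pd.DataFrame()
    for internal, public in TRANSFER_COLUMNS.items():
        if public not in df.columns:
            continue
        col = df[public]
        if internal == "scan_number":
            col = col.astype(int)
        elif internal == "cluster_id":
            col = col.astype(int)
        elif internal in ("score", "pep"):
            col = pd.to_numeric(col.where(col != "", None))
        elif internal == "cluster_category":
            col = col.str.split(":").str[-1]
        table[internal] = col
    pattern = re.compile(re.escape(dialect.reporter_prefix) + r"\s+(\d+)$")
    for col in df.columns:
        m = pattern.match(col)
        if m:
            table[f"reporter_{int(m.group(1)) - 1}"] = pd.to_numeric(df[col].where(df[col] != "", None))
    return table
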