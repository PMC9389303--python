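"""Merge, categorize and transfer: the heart of the pipeline.

Clusters of co-fragmented spectra are categorized by the identifications of
their members into six mutually exclusive classes:

a. ``singleton`` — a single spectrum;
b. ``unanimous`` — every member identified, one peptide;
c. ``fully_unidentified`` — no member identified;
d. ``ambiguous`` — identified members disagree on the unmodified sequence;
e. ``transferable`` — identified and unidentified members, one modified
   sequence among the identified;
f. ``ptm_isomeric`` — identified and unidentified members, one unmodified
   sequence but several modification-site placements.

Classes (e) and (f) drive identification transfer: unidentified *acceptor*
scans receive the *donor* peptide (and protein annotation) of the identified
members. In PTM-isomeric clusters no single modified sequence exists, so the
acceptors receive the unmodified sequence together with a localization flag
listing every candidate site observed in the cluster (see
:mod:`ms2transfer.modseq`). Directly identified rows are never altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .modseq import ModifiedSequenceError, build_localization_flag
from .records import ClusterAssignment, PsmRecord, ScanKey, SpectrumRecord

SINGLETON = "singleton"
UNANIMOUS = "unanimous"
FULLY_UNIDENTIFIED = "fully_unidentified"
AMBIGUOUS = "ambiguous"
TRANSFERABLE = "transferable"
PTM_ISOMERIC = "ptm_isomeric"

CATEGORIES = (SINGLETON, UNANIMOUS, FULLY_UNIDENTIFIED, AMBIGUOUS, TRANSFERABLE, PTM_ISOMERIC)
CATEGORY_LETTERS = {
    SINGLETON: "a",
    UNANIMOUS: "b",
    FULLY_UNIDENTIFIED: "c",
    AMBIGUOUS: "d",
    TRANSFERABLE: "e",
    PTM_ISOMERIC: "f",
}
#: Categories that never donate identifications.
NON_TRANSFER_CATEGORIES = (SINGLETON, UNANIMOUS, FULLY_UNIDENTIFIED, AMBIGUOUS)

DIRECT = "direct"
TRANSFER = "transfer"
NONE = "none"

BatchResolver = Union[None, Mapping[str, str], Callable[[str], str]]


def _resolve_batch(raw_file: str, batch_of: BatchResolver) -> str:
    if batch_of is None:
        return raw_file
    if callable(batch_of):
        return batch_of(raw_file)
    return batch_of.get(raw_file, raw_file)


def merge_tables(
    psms: Iterable[PsmRecord],
    assignment: ClusterAssignment,
    all_scans: Iterable[Union[ScanKey, SpectrumRecord]],
    batch_of: BatchResolver = None,
    plex_size: Optional[int] = None,
) -> pd.DataFrame:
    """Join PSM fields and cluster ids into one row per MS2 scan.

    ``all_scans`` enumerates every MS2 scan of the dataset (scan keys or
    spectrum records; records contribute reporter intensities). Scans missing
    from the assignment receive fresh singleton cluster ids; PSMs for scans
    absent from ``all_scans`` are included with a warning counter, since PSM
    tables are authoritative for scan existence when spectra are not given.
    """
    psm_by_key: dict[ScanKey, PsmRecord] = {}
    for p in psms:
        if p.key in psm_by_key:
            raise ValueError(f"multiple PSMs for scan {p.key}; apply best-per-scan first")
        psm_by_key[p.key] = p

    scan_keys: list[ScanKey] = []
    reporters: dict[ScanKey, np.ndarray] = {}
    seen = set()
    for item in all_scans:
        if isinstance(item, SpectrumRecord):
            key = item.key
            if item.reporter_intensities is not None:
                reporters[key] = item.reporter_intensities
        else:
            key = (str(item[0]), int(item[1]))
        if key in seen:
            raise ValueError(f"duplicate scan key {key} in all_scans")
        seen.add(key)
        scan_keys.append(key)
    orphans = [k for k in psm_by_key if k not in seen]
    scan_keys.extend(sorted(orphans))

    next_cid = max(assignment.entries.values(), default=0) + 1
    rows = []
    for key in scan_keys:
        cid = assignment.entries.get(key)
        if cid is None:
            cid = next_cid
            next_cid += 1
        p = psm_by_key.get(key)
        identified = p.is_identified if p else False
        rep = reporters.get(key)
        if rep is None and p is not None and p.reporter_intensities is not None:
            rep = p.reporter_intensities
        rows.append(
            {
                "raw_file": key[0],
                "scan_number": key[1],
                "batch_id": _resolve_batch(key[0], batch_of),
                "cluster_id": cid,
                "sequence": p.sequence if p else "",
                "modified_sequence": p.modified_sequence if p else "",
                "proteins": ";".join(p.proteins) if p else "",
                "score": p.score if p else math.nan,
                "pep": p.pep if p and p.pep is not None else math.nan,
                "is_decoy": bool(p.is_decoy) if p else False,
                "identification_type": DIRECT if identified else NONE,
                "cluster_category": "",
                "transferred_flag": "",
                "_reporter": rep,
            }
        )
    columns = [
        "raw_file", "scan_number", "batch_id", "cluster_id", "sequence",
        "modified_sequence", "proteins", "score", "pep", "is_decoy",
        "identification_type", "cluster_category", "transferred_flag", "_reporter",
    ]
    table = pd.DataFrame(rows, columns=columns)
    width = plex_size
    if width is None:
        widths = {len(r) for r in reporters.values()} | {
            len(p.reporter_intensities)
            for p in psm_by_key.values()
            if p.reporter_intensities is not None
        }
        width = max(widths) if widths else 0
    for j in range(width):
        table[f"reporter_{j}"] = [
            float(r[j]) if r is not None and j < len(r) else math.nan for r in table["_reporter"]
        ]
    table = table.drop(columns=["_reporter"])
    table.attrs["n_orphan_psms"] = len(orphans)
    return table


def categorize_cluster(rows: pd.DataFrame, require_equal_mod_counts: bool = True) -> str:
    """Assign one of the six categories to the rows of a single cluster.

    Only *direct* identifications count as identified; transferred rows from a
    previous pass are treated as unidentified, which makes the whole
    categorize+transfer cycle idempotent.
    """
    if len(rows) == 1:
        return SINGLETON
    ids = rows[rows["identification_type"] == DIRECT]
    if ids.empty:
        return FULLY_UNIDENTIFIED
    if ids["sequence"].nunique() > 1:
        return AMBIGUOUS
    has_unidentified = bool((rows["identification_type"] != DIRECT).any())
    mod_seqs = set(ids["modified_sequence"])
    if not has_unidentified:
        return UNANIMOUS
    if len(mod_seqs) == 1:
        return TRANSFERABLE
    if require_equal_mod_counts:
        try:
            build_localization_flag(mod_seqs)
        except ModifiedSequenceError:
            return AMBIGUOUS
    return PTM_ISOMERIC


def categorize_clusters(table: pd.DataFrame, require_equal_mod_counts: bool = True) -> pd.DataFrame:
    """Set ``cluster_category`` for every row; returns a new table.

    Vectorized equivalent of applying :func:`categorize_cluster` per cluster.
    """
    out = table.copy()
    cid = out["cluster_id"]
    size = cid.map(cid.value_counts())
    direct = out[out["identification_type"] == DIRECT]
    grouped = direct.groupby("cluster_id")
    n_direct = cid.map(grouped.size()).fillna(0).astype(int)
    n_seq = cid.map(grouped["sequence"].nunique()).fillna(0).astype(int)
    n_mod = cid.map(grouped["modified_sequence"].nunique()).fillna(0).astype(int)
    has_unidentified = size > n_direct
    category = np.select(
        [
            size == 1,
            n_direct == 0,
            n_seq >= 2,
            ~has_unidentified,
            n_mod == 1,
        ],
        [SINGLETON, FULLY_UNIDENTIFIED, AMBIGUOUS, UNANIMOUS, TRANSFERABLE],
        default=PTM_ISOMERIC,
    )
    out["cluster_category"] = category
    if require_equal_mod_counts:
        candidates = out.loc[out["cluster_category"] == PTM_ISOMERIC, "cluster_id"].unique()
        if len(candidates):
            mod_sets = grouped["modified_sequence"].unique()
            demoted = []
            for c in candidates:
                try:
                    build_localization_flag(set(mod_sets[c]))
                except ModifiedSequenceError:
                    demoted.append(c)
            if demoted:
                out.loc[out["cluster_id"].isin(demoted), "cluster_category"] = AMBIGUOUS
    return out


def _reset_previous_transfers(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    mask = out["identification_type"] == TRANSFER
    out.loc[mask, ["sequence", "modified_sequence", "proteins", "transferred_flag"]] = ""
    out.loc[mask, ["score", "pep"]] = math.nan
    out.loc[mask, "identification_type"] = NONE
    return out


def transfer_identifications(
    table: pd.DataFrame, require_equal_mod_counts: bool = True
) -> pd.DataFrame:
    """Run cluster categorization and identification transfer on a merged table.

    Idempotent: any transfers present in the input are recomputed from
    scratch, so running twice equals running once. Decoy rows never donate
    and never accept.
    """
    out = _reset_previous_transfers(table)
    out = categorize_clusters(out, require_equal_mod_counts)
    transferring = out["cluster_category"].isin([TRANSFERABLE, PTM_ISOMERIC])
    acceptors = (
        transferring
        & (out["identification_type"] == NONE)
        & ~out["is_decoy"].astype(bool)
    )
    if not acceptors.any():
        return out
    donors = out[transferring & (out["identification_type"] == DIRECT)]
    best = donors.sort_values(
        ["score", "raw_file", "scan_number"], ascending=[False, True, True]
    ).drop_duplicates("cluster_id").set_index("cluster_id")

    acc_cid = out.loc[acceptors, "cluster_id"]
    out.loc[acceptors, "sequence"] = acc_cid.map(best["sequence"])
    out.loc[acceptors, "proteins"] = acc_cid.map(best["proteins"])
    out.loc[acceptors, "identification_type"] = TRANSFER

    # transferable clusters pass on the donor's modified sequence; PTM-isomeric
    # clusters pass on a localization flag built from every donor form
    transferred_mod = acc_cid.map(best["modified_sequence"])
    isomeric_ids = out.loc[acceptors & (out["cluster_category"] == PTM_ISOMERIC), "cluster_id"].unique()
    if len(isomeric_ids):
        donor_mods = donors.groupby("cluster_id")["modified_sequence"].unique()
        flags = {
            c: build_localization_flag(set(donor_mods[c])).render() for c in isomeric_ids
        }
        transferred_mod = transferred_mod.where(
            ~acc_cid.isin(flags), acc_cid.map(flags)
        )
    out.loc[acceptors, "modified_sequence"] = transferred_mod
    out.loc[acceptors, "transferred_flag"] = transferred_mod
    return out


@dataclass
class TransferSummary:
    """Global, per-batch and per-category accounting of a finalized table."""

    n_scans: int
    n_direct: int
    n_transferred: int
    n_peptides: int
    n_proteins: int
    category_counts: dict[str, int] = field(default_factory=dict)
    per_batch: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def psm_gain_percent(self) -> float:
        return 100.0 * self.n_transferred / self.n_direct if self.n_direct else 0.0


def _first_protein(proteins: str) -> str:
    return proteins.split(";")[0] if proteins else ""


def summarize_transfers(table: pd.DataFrame) -> TransferSummary:
    identified = table[table["identification_type"].isin([DIRECT, TRANSFER])]
    per_batch_rows = []
    for batch, rows in identified.groupby("batch_id"):
        per_batch_rows.append(
            {
                "batch_id": batch,
                "direct_psms": int((rows["identification_type"] == DIRECT).sum()),
                "transferred_psms": int((rows["identification_type"] == TRANSFER).sum()),
                "peptides": rows["sequence"].nunique(),
                "proteins": rows["proteins"].map(_first_protein).nunique(),
            }
        )
    per_cluster = table.drop_duplicates("cluster_id")["cluster_category"]
    category_counts = {c: int((per_cluster == c).sum()) for c in CATEGORIES}
    return TransferSummary(
        n_scans=len(table),
        n_direct=int((table["identification_type"] == DIRECT).sum()),
        n_transferred=int((table["identification_type"] == TRANSFER).sum()),
        n_peptides=identified["sequence"].nunique(),
        n_proteins=identified["proteins"].map(_first_protein).nunique(),
        category_counts=category_counts,
        per_batch=pd.DataFrame(per_batch_rows),
    )
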