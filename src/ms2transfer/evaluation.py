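"""Validation machinery: masking, FDR proxy, presence curves, reporter check.

The masking analysis hides a fraction of the known identifications in each
raw file, reruns the transfer, and scores the transfers landing on masked
scans against the hidden ground truth. Treating re-identification as a
multiclass problem with one class per peptide, the pooled (micro-averaged)
metrics reduce to

    precision = sum(correct transfers) / sum(transfers onto masked scans)
    recall    = sum(correct transfers) / sum(masked spectra)
    FDR       = 1 - precision

Correctness is judged on the unmodified sequence (positional PTM-isomer
transfers carry a localization flag instead of a single modified sequence);
a strict mode additionally requires the modified sequence to match.
Transfers onto scans that never had an identification are unverifiable and
excluded from both numerator and denominator.

The fraction of ambiguous clusters among clusters of size > 1 serves as an
FDR proxy that needs no masking run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import PsmRecord, ScanKey
from .transfer import DIRECT, TRANSFER, AMBIGUOUS, SINGLETON

#: ground truth entry for one masked scan: (unmodified, modified) sequence
MaskTruth = dict[ScanKey, tuple[str, str]]


class MaskingError(ValueError):
    pass


def mask_identifications(
    psms: Iterable[PsmRecord], fraction: float, seed: int = 1
) -> tuple[list[PsmRecord], MaskTruth]:
    """Hide ``round(fraction * n_identified)`` identifications per raw file.

    Sampling is uniform without replacement, stratified per raw file and
    seeded. Masked records keep their scan identity but lose sequence,
    modified sequence and protein annotation; the returned map records the
    hidden truth.
    """
    if not 0 < fraction <= 1:
        raise MaskingError(f"mask fraction must be in (0, 1], got {fraction}")
    psms = list(psms)
    rng = np.random.default_rng(seed)
    truth: MaskTruth = {}
    by_file: dict[str, list[int]] = {}
    for i, p in enumerate(psms):
        if p.is_identified:
            by_file.setdefault(p.raw_file, []).append(i)
    masked_indices: set[int] = set()
    for raw in sorted(by_file):
        indices = by_file[raw]
        n_mask = int(round(fraction * len(indices)))
        chosen = rng.choice(len(indices), size=n_mask, replace=False)
        masked_indices.update(indices[c] for c in chosen)
    out: list[PsmRecord] = []
    for i, p in enumerate(psms):
        if i in masked_indices:
            truth[p.key] = (p.sequence, p.modified_sequence)
            out.append(
                PsmRecord(
                    raw_file=p.raw_file,
                    scan_number=p.scan_number,
                    sequence="",
                    modified_sequence="",
                    proteins=(),
                    score=math.nan,
                    pep=None,
                    is_decoy=False,
                    is_contaminant=p.is_contaminant,
                    reporter_intensities=p.reporter_intensities,
                    batch_id=p.batch_id,
                )
            )
        else:
            out.append(p)
    return out, truth


@dataclass
class MaskingReport:
    """Micro-averaged precision/recall/FDR of one masking run."""

    threshold_label: str
    mask_fraction: float
    n_masked: int
    n_transferred_to_masked: int
    n_correct: int
    precision: float
    recall: float
    fdr: float
    seed: Optional[int] = None
    degenerate: bool = False  # no transfers landed on masked scans

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold_label,
            "mask_fraction": self.mask_fraction,
            "n_masked": self.n_masked,
            "n_transferred_to_masked": self.n_transferred_to_masked,
            "n_correct": self.n_correct,
            "precision": self.precision,
            "recall": self.recall,
            "fdr": self.fdr,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def precision_recall(
    table: pd.DataFrame,
    truth: MaskTruth,
    threshold_label: str = "",
    mask_fraction: float = math.nan,
    seed: Optional[int] = None,
    strict: bool = False,
) -> MaskingReport:
    """Score transfers on a masked dataset against the hidden identifications.

    ``strict`` compares modified sequences (localization-flag transfers then
    count as incorrect); the default compares unmodified sequences, the
    natural metric basis when transferable and PTM-isomeric clusters are
    evaluated together.
    """
    if not truth:
        raise MaskingError("ground-truth map is empty; nothing was masked")
    transfers = table[table["identification_type"] == TRANSFER]
    n_to_masked = 0
    n_correct = 0
    for row in transfers.itertuples(index=False):
        key = (row.raw_file, row.scan_number)
        hidden = truth.get(key)
        if hidden is None:
            continue  # unverifiable: scan never had an identification
        n_to_masked += 1
        expected = hidden[1] if strict else hidden[0]
        observed = row.modified_sequence if strict else row.sequence
        if observed == expected:
            n_correct += 1
    degenerate = n_to_masked == 0
    precision = 1.0 if degenerate else n_correct / n_to_masked
    return MaskingReport(
        threshold_label=threshold_label,
        mask_fraction=mask_fraction,
        n_masked=len(truth),
        n_transferred_to_masked=n_to_masked,
        n_correct=n_correct,
        precision=precision,
        recall=n_correct / len(truth),
        fdr=1.0 - precision,
        seed=seed,
        degenerate=degenerate,
    )


def write_masking_reports(reports: Iterable[MaskingReport], path: str) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, sep="\t", index=False)


@dataclass
class AmbiguousClusterStats:
    """Share of multi-spectrum clusters whose identifications disagree."""

    n_ambiguous: int
    n_multi_clusters: int
    degenerate: bool  # no clusters of size > 1 existed

    @property
    def fraction(self) -> float:
        return self.n_ambiguous / self.n_multi_clusters if self.n_multi_clusters else 0.0


def ambiguous_cluster_fraction(table: pd.DataFrame) -> AmbiguousClusterStats:
    """(# ambiguous clusters) / (# clusters of size > 1) on a categorized table."""
    per_cluster = table.drop_duplicates("cluster_id")["cluster_category"]
    n_multi = int((per_cluster != SINGLETON).sum())
    n_ambiguous = int((per_cluster == AMBIGUOUS).sum())
    return AmbiguousClusterStats(n_ambiguous, n_multi, degenerate=n_multi == 0)


@dataclass
class PresenceCurve:
    """counts[n-1] = number of entities found in at least n batches."""

    level: str  # "peptide" | "protein"
    counts: np.ndarray
    n_batches: int

    def at_least(self, n: int) -> int:
        return int(self.counts[n - 1]) if 1 <= n <= self.n_batches else 0


def batch_presence_curve(
    table: pd.DataFrame, level: str = "peptide", include_transfers: bool = True
) -> PresenceCurve:
    """Cumulative 'found in at least n batches' counts at peptide/protein level.

    An entity is present in a batch iff that batch holds at least one
    identified row for it — direct identifications, plus transfers when
    ``include_transfers``. Peptides are unmodified sequences; proteins use
    the leading identifier of the protein group.
    """
    if level not in ("peptide", "protein"):
        raise ValueError(f"level must be 'peptide' or 'protein', got {level!r}")
    accepted = [DIRECT, TRANSFER] if include_transfers else [DIRECT]
    rows = table[table["identification_type"].isin(accepted) & (table["sequence"] != "")]
    if level == "peptide":
        entities = rows["sequence"]
    else:
        entities = rows["proteins"].map(lambda p: p.split(";")[0] if p else "")
    n_batches = table["batch_id"].nunique()
    frame = pd.DataFrame({"entity": entities, "batch": rows["batch_id"]})
    frame = frame[frame["entity"] != ""]
    presence = frame.groupby("entity")["batch"].nunique()
    counts = np.array([(presence >= n).sum() for n in range(1, n_batches + 1)], dtype=int)
    return PresenceCurve(level=level, counts=counts, n_batches=n_batches)


def write_presence_curves(
    curves: Iterable[PresenceCurve], path: str, names: Optional[Sequence[str]] = None
) -> None:
    rows = []
    for i, curve in enumerate(curves):
        name = names[i] if names else f"curve{i + 1}"
        for n in range(1, curve.n_batches + 1):
            rows.append(
                {"curve": name, "level": curve.level, "min_batches": n, "count": curve.at_least(n)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ReporterAgreement:
    """Correlation of each PSM's reporter ratio pattern with its protein."""

    per_psm: pd.DataFrame
    n_skipped: int

    def median_correlation(self, identification_type: str = TRANSFER) -> float:
        sub = self.per_psm[self.per_psm["identification_type"] == identification_type]
        return float(sub["correlation"].median()) if len(sub) else math.nan


def _log_ratios(reporters: np.ndarray, reference_channel: int) -> Optional[np.ndarray]:
    ref = reporters[reference_channel]
    if not np.isfinite(ref) or ref <= 0:
        return None
    channels = np.delete(reporters, reference_channel % len(reporters))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(channels / ref)
    ratios[~np.isfinite(ratios)] = np.nan
    return ratios


def reporter_ratio_agreement(
    table: pd.DataFrame,
    reference_channel: int = -1,
    min_direct_psms: int = 2,
) -> ReporterAgreement:
    """Compare transferred PSM reporter patterns to their protein's pattern.

    For every identified PSM, the Pearson correlation between its per-channel
    log2 ratio vector (vs the bridge/reference channel) and the median ratio
    vector of the *direct* PSMs of the same protein in the same batch.
    Proteins with fewer than ``min_direct_psms`` direct PSMs in a batch, and
    PSMs with constant or invalid ratio vectors, are skipped and counted.
    """
    reporter_cols = sorted(
        (c for c in table.columns if c.startswith("reporter_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not reporter_cols:
        raise ValueError("table carries no reporter intensity columns")
    rows = table[table["identification_type"].isin([DIRECT, TRANSFER])].copy()
    rows["protein"] = rows["proteins"].map(lambda p: p.split(";")[0] if p else "")
    rows = rows[rows["protein"] != ""]
    reporters = rows[reporter_cols].to_numpy(dtype=float)
    ratio_list = [_log_ratios(r, reference_channel) for r in reporters]

    # per (batch, protein) median pattern over direct PSMs
    medians: dict[tuple[str, str], np.ndarray] = {}
    group_index: dict[tuple[str, str], list[int]] = {}
    keys = list(zip(rows["batch_id"], rows["protein"]))
    is_direct = (rows["identification_type"] == DIRECT).to_numpy()
    for i, key in enumerate(keys):
        group_index.setdefault(key, []).append(i)
    for key, indices in group_index.items():
        direct_ratios = [ratio_list[i] for i in indices if is_direct[i] and ratio_list[i] is not None]
        if len(direct_ratios) >= min_direct_psms:
            medians[key] = np.nanmedian(np.vstack(direct_ratios), axis=0)

    records = []
    n_skipped = 0
    for i, (key, row) in enumerate(zip(keys, rows.itertuples(index=False))):
        ratios = ratio_list[i]
        pattern = medians.get(key)
        if ratios is None or pattern is None:
            n_skipped += 1
            continue
        valid = np.isfinite(ratios) & np.isfinite(pattern)
        if valid.sum() < 3 or np.std(ratios[valid]) == 0 or np.std(pattern[valid]) == 0:
            n_skipped += 1
            continue
        corr = float(np.corrcoef(ratios[valid], pattern[valid])[0, 1])
        records.append(
            {
                "raw_file": row.raw_file,
                "scan_number": row.scan_number,
                "batch_id": row.batch_id,
                "protein": key[1],
                "identification_type": row.identification_type,
                "correlation": corr,
            }
        )
    return ReporterAgreement(per_psm=pd.DataFrame(records), n_skipped=n_skipped)
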