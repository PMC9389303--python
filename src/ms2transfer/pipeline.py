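"""End-to-end orchestration: read -> cluster (or import) -> transfer -> evaluate."""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_PARAMS,
    DEFAULT_THRESHOLDS,
    ClusteringParams,
    StringencyThreshold,
    cluster_at_thresholds,
)
from .evaluation import (
    ambiguous_cluster_fraction,
    mask_identifications,
    precision_recall,
    write_masking_reports,
)
from .formats import (
    ConfigurationError,
    read_cluster_assignments,
    read_search_results,
    read_spectra,
    threshold_label_from_path,
    write_cluster_assignments,
    write_transfer_table,
)
from .records import ClusterAssignment, PsmRecord, SpectrumRecord
from .transfer import (
    BatchResolver,
    merge_tables,
    summarize_transfers,
    transfer_identifications,
)


@dataclass
class PipelineConfig:
    """Inputs, parameters and outputs of one pipeline run.

    Exactly one of internal clustering (the default) or ``import_clusters``
    (a directory of externally produced cluster files) is active per run.
    """

    psm_paths: Sequence[str] = ()
    spectra_paths: Sequence[str] = ()
    import_clusters: Optional[str] = None
    output_dir: str = "."
    thresholds: Sequence[StringencyThreshold] = DEFAULT_THRESHOLDS
    clustering: ClusteringParams = field(default_factory=lambda: DEFAULT_PARAMS)
    mask_fractions: Sequence[float] = ()
    batch_of: BatchResolver = None
    seed: int = 1

    def validate(self) -> None:
        if not self.psm_paths:
            raise ConfigurationError("at least one PSM table is required")
        if self.import_clusters is None and not self.spectra_paths:
            raise ConfigurationError(
                "spectra are required unless cluster assignments are imported"
            )


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    summaries: dict[str, dict]
    output_paths: dict[str, str]
    manifest_path: str


def expand_spectra_paths(paths: Iterable[str]) -> list[str]:
    out: list[str] = []
    for path in paths:
        if os.path.isdir(path):
            for ext in ("*.mgf", "*.mzML", "*.mzml"):
                out.extend(sorted(glob.glob(os.path.join(path, ext))))
        else:
            out.append(path)
    return out


def load_imported_clusters(
    directory: str, thresholds: Sequence[StringencyThreshold]
) -> dict[str, ClusterAssignment]:
    wanted = {t.label for t in thresholds}
    found: dict[str, ClusterAssignment] = {}
    for path in sorted(glob.glob(os.path.join(directory, "*.tsv"))):
        label = threshold_label_from_path(path)
        if label in wanted:
            found[label] = read_cluster_assignments(path, label)
    missing = wanted - set(found)
    if missing:
        raise ConfigurationError(
            f"no cluster file found in {directory} for thresholds: {sorted(missing)}"
        )
    return found


def transfer_at_thresholds(
    spectra: Sequence[SpectrumRecord],
    psms: Sequence[PsmRecord],
    assignments: dict[str, ClusterAssignment],
    batch_of: BatchResolver = None,
    plex_size: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Merge + categorize + transfer for every threshold assignment."""
    all_scans: Sequence = spectra if spectra else sorted({p.key for p in psms})
    out: dict[str, pd.DataFrame] = {}
    for label, assignment in assignments.items():
        merged = merge_tables(psms, assignment, all_scans, batch_of=batch_of, plex_size=plex_size)
        out[label] = transfer_identifications(merged)
    return out


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write per-threshold artifacts.

    Writes, per threshold: the augmented transfer table, the cluster file
    (when clustered internally) and a JSON summary; plus masking reports if
    ``mask_fractions`` is non-empty and a machine-readable run manifest.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)

    psms: list[PsmRecord] = []
    for path in config.psm_paths:
        psms.extend(read_search_results(path))
    spectra: list[SpectrumRecord] = []
    for path in expand_spectra_paths(config.spectra_paths):
        spectra.extend(read_spectra(path))

    if config.import_clusters is not None:
        assignments = load_imported_clusters(config.import_clusters, config.thresholds)
    else:
        assignments = cluster_at_thresholds(spectra, config.thresholds, config.clustering)
        for label, assignment in assignments.items():
            write_cluster_assignments(
                assignment, os.path.join(config.output_dir, f"clusters.{label}.tsv")
            )

    tables = transfer_at_thresholds(spectra, psms, assignments, batch_of=config.batch_of)

    output_paths: dict[str, str] = {}
    summaries: dict[str, dict] = {}
    for label, table in tables.items():
        out_path = os.path.join(config.output_dir, f"transfer.{label}.txt")
        write_transfer_table(table, out_path)
        output_paths[label] = out_path
        summary = summarize_transfers(table)
        ambig = ambiguous_cluster_fraction(table)
        summaries[label] = {
            "n_scans": summary.n_scans,
            "n_direct": summary.n_direct,
            "n_transferred": summary.n_transferred,
            "psm_gain_percent": summary.psm_gain_percent,
            "n_peptides": summary.n_peptides,
            "n_proteins": summary.n_proteins,
            "category_counts": summary.category_counts,
            "ambiguous_cluster_fraction": ambig.fraction,
        }

    if config.mask_fractions:
        reports = []
        for fraction in config.mask_fractions:
            masked_psms, truth = mask_identifications(psms, fraction, seed=config.seed)
            masked_tables = transfer_at_thresholds(
                spectra, masked_psms, assignments, batch_of=config.batch_of
            )
            for label, table in masked_tables.items():
                reports.append(
                    precision_recall(table, truth, label, fraction, seed=config.seed)
                )
        write_masking_reports(reports, os.path.join(config.output_dir, "masking_reports.tsv"))

    summary_path = os.path.join(config.output_dir, "summary.json")
    with open(summary_path, "w") as handle:
        json.dump(summaries, handle, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": [t.label for t in config.thresholds],
        "clustering": {
            "bin_width": config.clustering.bin_width,
            "top_k": config.clustering.top_k,
            "precursor_tol_ppm": config.clustering.precursor_tol_ppm,
        },
        "imported_clusters": config.import_clusters,
        "inputs": {
            path: _sha256(path)
            for path in list(config.psm_paths) + expand_spectra_paths(config.spectra_paths)
        },
    }
    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return PipelineResult(
        tables=tables,
        summaries=summaries,
        output_paths=output_paths,
        manifest_path=manifest_path,
    )
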