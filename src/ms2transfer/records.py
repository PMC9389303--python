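"""Core in-memory records shared by all pipeline stages.

A dataset is addressed throughout by *scan keys*: ``(raw_file, scan_number)``
pairs, where ``raw_file`` is the basename of the acquisition file with its
extension stripped and ``scan_number`` is the 1-based vendor scan index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ScanKey = tuple[str, int]

#: Monoisotopic TMT10plex reporter ion m/z values (Th), channels 126..131C.
TMT10_REPORTER_MZ = (
    126.127726,
    127.124761,
    127.131081,
    128.128116,
    128.134436,
    129.131471,
    129.137790,
    130.134825,
    130.141145,
    131.138180,
)

PROTON_MASS = 1.00727646688  # Da


@dataclass
class SpectrumRecord:
    """One MS2 scan: provenance, precursor attributes and the peak list.

    ``mz``/``intensity`` are parallel arrays sorted ascending by m/z.
    ``precursor_charge`` is ``None`` when the acquisition did not assign a
    charge state. ``reporter_intensities`` has one entry per plex channel and
    may be ``None`` when reporters were neither supplied nor extractable.
    """

    raw_file: str
    scan_number: int
    precursor_mz: float
    precursor_charge: Optional[int] = None
    retention_time: Optional[float] = None  # minutes
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    reporter_intensities: Optional[np.ndarray] = None
    batch_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        if self.reporter_intensities is not None:
            self.reporter_intensities = np.asarray(self.reporter_intensities, dtype=float)

    @property
    def key(self) -> ScanKey:
        return (self.raw_file, self.scan_number)

    @property
    def is_empty(self) -> bool:
        """True for spectra without fragment peaks (excluded from clustering)."""
        return self.mz.size == 0

    @property
    def precursor_neutral_mass(self) -> Optional[float]:
        """Neutral (uncharged) precursor mass in Da, or None if charge unknown."""
        if self.precursor_charge is None or self.precursor_charge <= 0:
            return None
        z = self.precursor_charge
        return (self.precursor_mz - PROTON_MASS) * z


@dataclass
class PsmRecord:
    """One retained search-engine identification attempt for a scan.

    An empty ``sequence`` means the scan was submitted to the search engine
    but yielded no identification surviving the FDR filter; such rows are
    legitimate transfer acceptors.
    """

    raw_file: str
    scan_number: int
    sequence: str = ""
    modified_sequence: str = ""
    proteins: tuple[str, ...] = ()
    score: float = float("nan")
    pep: Optional[float] = None
    is_decoy: bool = False
    is_contaminant: bool = False
    reporter_intensities: Optional[np.ndarray] = None
    batch_id: Optional[str] = None

    @property
    def key(self) -> ScanKey:
        return (self.raw_file, self.scan_number)

    @property
    def is_identified(self) -> bool:
        """Retained target identification usable as a transfer donor."""
        return bool(self.sequence) and not self.is_decoy


@dataclass
class ClusterAssignment:
    """Mapping of scan keys to cluster ids at one stringency threshold."""

    threshold_label: str
    entries: dict[ScanKey, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self.entries.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes

    def renumbered(self) -> "ClusterAssignment":
        """Dense 1-based cluster ids ordered by the smallest member key."""
        smallest: dict[int, ScanKey] = {}
        for key, cid in self.entries.items():
            if cid not in smallest or key < smallest[cid]:
                smallest[cid] = key
        order = {cid: i + 1 for i, (_, cid) in enumerate(sorted((k, c) for c, k in smallest.items()))}
        return ClusterAssignment(
            self.threshold_label, {key: order[cid] for key, cid in self.entries.items()}
        )
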