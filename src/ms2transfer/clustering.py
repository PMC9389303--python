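"""Complete-linkage MS2 spectrum clustering at -log10(p-value) stringencies.

Spectra are reduced to sets of integer fragment bins (top-K most intense
peaks outside the reporter region, ``floor(m/z / bin_width)``). The pairwise
similarity of two spectra is the upper tail of a hypergeometric null for the
number of shared bins: given ``B`` available bins and two spectra occupying
``n_a`` and ``n_b`` of them independently, the score is

    s(a, b) = -log10 P(shared >= observed)

which is symmetric and monotone increasing in the shared-bin count. Spectra
are only compared within a *partition*: same precursor charge and a
precursor-mass window built by single-linkage chaining of neutral masses
within a ppm tolerance (so near-boundary pairs are still compared). Within a
partition, clusters are agglomerated under complete linkage — two clusters
merge only while **every** cross-pair reaches the score — and the single
merge sequence is cut at each requested threshold, which guarantees that the
partition at a stricter threshold refines the looser one.

The stringency ladder follows the field's convention of six default cutoffs
p5, p10, p15, p20, p25, p30 on -log10(p), with p5 the loosest and p30 the
strictest clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .records import ClusterAssignment, ScanKey, SpectrumRecord

LN10 = math.log(10.0)


class EmptySpectrumError(ValueError):
    """Raised when a spectrum without peaks is submitted for binning."""


@dataclass(frozen=True)
class StringencyThreshold:
    """A cutoff of ``value`` on -log10(p); label ``pN`` corresponds to N."""

    label: str
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("stringency threshold must be positive")

    @classmethod
    def from_label(cls, label: str) -> "StringencyThreshold":
        if not label.startswith("p"):
            raise ValueError(f"threshold label must look like 'p10', got {label!r}")
        return cls(label, float(label[1:]))


DEFAULT_THRESHOLDS = tuple(
    StringencyThreshold.from_label(f"p{n}") for n in (5, 10, 15, 20, 25, 30)
)


@dataclass(frozen=True)
class ClusteringParams:
    """Tunable knobs of the spectrum comparison model.

    bin_width
        Fragment bin width in Th; 0.02 suits high-resolution HCD data.
    top_k
        Number of most intense peaks retained per spectrum.
    reporter_window
        m/z region excluded from binning: reporter ions are shared by every
        labeled spectrum and carry no identity signal.
    fragment_range
        m/z span defining the number of available bins ``B`` of the null.
    precursor_tol_ppm
        Tolerance for chaining precursor masses into comparison partitions.
    """

    bin_width: float = 0.02
    top_k: int = 40
    reporter_window: tuple[float, float] = (125.0, 135.0)
    fragment_range: tuple[float, float] = (100.0, 1500.0)
    precursor_tol_ppm: float = 10.0

    @property
    def n_bins_total(self) -> int:
        lo, hi = self.fragment_range
        return int(round((hi - lo) / self.bin_width))


DEFAULT_PARAMS = ClusteringParams()


@dataclass(frozen=True)
class BinnedSpectrum:
    key: ScanKey
    precursor_mass: float  # neutral mass (Da); precursor m/z if charge unknown
    charge: Optional[int]
    bins: frozenset[int]


def bin_spectrum(
    spectrum: SpectrumRecord, params: ClusteringParams = DEFAULT_PARAMS
) -> BinnedSpectrum:
    """Deterministic fragment-bin set of the top-K peaks of one spectrum."""
    if spectrum.is_empty:
        raise EmptySpectrumError(f"spectrum {spectrum.key} has no peaks")
    lo, hi = params.reporter_window
    keep = (spectrum.mz < lo) | (spectrum.mz > hi)
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size > params.top_k:
        # ties broken toward lower m/z for determinism
        order = np.lexsort((mz, -inten))[: params.top_k]
        mz = mz[order]
    bins = frozenset(np.floor(mz / params.bin_width).astype(np.int64).tolist())
    mass = spectrum.precursor_neutral_mass
    return BinnedSpectrum(
        key=spectrum.key,
        precursor_mass=mass if mass is not None else spectrum.precursor_mz,
        charge=spectrum.precursor_charge,
        bins=bins,
    )


@lru_cache(maxsize=1 << 20)
def _neglog_tail(shared: int, n_a: int, n_b: int, n_bins_total: int) -> float:
    logp = hypergeom.logsf(shared - 1, n_bins_total, n_a, n_b)
    val = -float(logp) / LN10
    if not math.isfinite(val):
        val = 1e6  # p underflowed; effectively certain co-identity
    return val


def pair_neglog_pvalue(
    a: BinnedSpectrum, b: BinnedSpectrum, n_bins_total: int = DEFAULT_PARAMS.n_bins_total
) -> float:
    """-log10 of the hypergeometric tail probability of the shared-bin count."""
    shared = len(a.bins & b.bins)
    if shared == 0:
        return 0.0
    n_a, n_b = sorted((len(a.bins), len(b.bins)))
    return _neglog_tail(shared, n_a, n_b, n_bins_total)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def partition_spectra(
    binned: Sequence[BinnedSpectrum], precursor_tol_ppm: float
) -> list[list[BinnedSpectrum]]:
    """Charge groups split into precursor-mass windows by single-linkage chaining.

    Spectra of different charge are never compared; unknown-charge spectra
    form their own charge group. Within a charge group, sorted masses are
    chained while consecutive gaps stay within the ppm tolerance, so pairs
    straddling any fixed bin edge still share a partition.
    """
    by_charge: dict[object, list[BinnedSpectrum]] = {}
    for s in binned:
        by_charge.setdefault(s.charge, []).append(s)
    partitions: list[list[BinnedSpectrum]] = []
    for charge in sorted(by_charge, key=lambda c: (c is None, c)):
        group = sorted(by_charge[charge], key=lambda s: (s.precursor_mass, s.key))
        current = [group[0]]
        for s in group[1:]:
            tol = precursor_tol_ppm * 1e-6 * max(abs(s.precursor_mass), 1.0)
            if s.precursor_mass - current[-1].precursor_mass <= tol:
                current.append(s)
            else:
                partitions.append(current)
                current = [s]
        partitions.append(current)
    return partitions


# ---------------------------------------------------------------------------
# Complete-linkage agglomeration
# ---------------------------------------------------------------------------


@dataclass
class MergeEvent:
    """One agglomeration step: two clusters joined at a linkage height."""

    height: float
    members_a: tuple[ScanKey, ...]
    members_b: tuple[ScanKey, ...]


def complete_linkage_merges(
    keys: Sequence[ScanKey], similarity: np.ndarray, min_height: float
) -> list[MergeEvent]:
    """Greedy complete-linkage agglomeration down to ``min_height``.

    At each step the pair of clusters with the largest linkage value (minimum
    pairwise similarity across members) is merged; ties are broken by the
    lexicographically smallest pair of cluster representatives, a
    representative being the smallest (raw_file, scan) key of the cluster.
    Complete linkage is reducible, so recorded heights are non-increasing and
    cutting the merge list at any height reproduces agglomeration stopped at
    that height.
    """
    n = len(keys)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    reps: dict[int, ScanKey] = {i: keys[i] for i in range(n)}
    link = similarity.astype(float).copy()
    merges: list[MergeEvent] = []
    active = set(range(n))
    while len(active) > 1:
        best: Optional[tuple[float, ScanKey, ScanKey, int, int]] = None
        for i in active:
            for j in active:
                if j <= i:
                    continue
                h = link[i, j]
                if h < min_height:
                    continue
                ra, rb = sorted((reps[i], reps[j]))
                cand = (-h, ra, rb, i, j)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, _, i, j = best
        merges.append(
            MergeEvent(
                height=float(link[i, j]),
                members_a=tuple(keys[m] for m in members[i]),
                members_b=tuple(keys[m] for m in members[j]),
            )
        )
        for k in active:
            if k not in (i, j):
                link[i, k] = link[k, i] = min(link[i, k], link[j, k])
        members[i].extend(members[j])
        reps[i] = min(reps[i], reps[j])
        active.remove(j)
    return merges


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[ScanKey, ScanKey] = {}

    def find(self, x: ScanKey) -> ScanKey:
        parent = self.parent
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: ScanKey, b: ScanKey) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cut_merges(
    all_keys: Iterable[ScanKey], merges: Iterable[MergeEvent], threshold: float
) -> dict[ScanKey, int]:
    """Partition implied by applying every merge with height >= threshold."""
    uf = _UnionFind()
    keys = list(all_keys)
    for key in keys:
        uf.find(key)
    for ev in merges:
        if ev.height >= threshold:
            uf.union(ev.members_a[0], ev.members_b[0])
    roots: dict[ScanKey, list[ScanKey]] = {}
    for key in keys:
        roots.setdefault(uf.find(key), []).append(key)
    assignment: dict[ScanKey, int] = {}
    for cid, root in enumerate(sorted(roots, key=lambda r: min(roots[r])), start=1):
        for key in roots[root]:
            assignment[key] = cid
    return assignment


def cluster_at_thresholds(
    spectra: Iterable[SpectrumRecord],
    thresholds: Sequence[StringencyThreshold] = DEFAULT_THRESHOLDS,
    params: ClusteringParams = DEFAULT_PARAMS,
) -> dict[str, ClusterAssignment]:
    """Cluster spectra once and emit one assignment per stringency threshold.

    Spectra without peaks are excluded (they reappear downstream as
    singletons). The returned assignments are nested: every cluster at a
    stricter threshold is a subset of a cluster at any looser threshold.
    """
    if not thresholds:
        raise ValueError("at least one stringency threshold is required")
    binned = [bin_spectrum(s, params) for s in spectra if not s.is_empty]
    if not binned:
        return {t.label: ClusterAssignment(t.label) for t in thresholds}
    min_height = min(t.value for t in thresholds)
    merges: list[MergeEvent] = []
    for part in partition_spectra(binned, params.precursor_tol_ppm):
        if len(part) < 2:
            continue
        part = sorted(part, key=lambda s: s.key)
        sim = np.zeros((len(part), len(part)))
        for i in range(len(part)):
            for j in range(i + 1, len(part)):
                sim[i, j] = sim[j, i] = pair_neglog_pvalue(part[i], part[j], params.n_bins_total)
        merges.extend(complete_linkage_merges([s.key for s in part], sim, min_height))
    all_keys = sorted(s.key for s in binned)
    return {
        t.label: ClusterAssignment(t.label, cut_merges(all_keys, merges, t.value))
        for t in thresholds
    }
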