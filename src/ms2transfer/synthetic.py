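"""Synthetic multi-batch TMT-like datasets with ground truth.

The generator emulates the structure of multi-batch isobaric-labeling
experiments: a set of tryptic-like peptides fragmented once per batch, with
b/y-ion fragment templates computed from monoisotopic residue masses
(phosphorylation adds 79.966 Da at the modified site), peak dropout / m/z
jitter / intensity noise per spectrum, and per-protein reporter channel
patterns with the last channel acting as the common bridge reference.

Four species classes shape the cluster structure downstream:

* *normal* peptides, identified per batch with probability
  ``per_batch_identification_prob``;
* *positional phospho-isomer* pairs — the same sequence emitted with the
  phospho group on two different sites, the source of PTM-isomeric clusters;
* *look-alike twins* — distinct peptides engineered at the peak level to
  share a configurable number of fragment bins (and a matching precursor
  mass) with a partner peptide, planting cross-peptide cluster ambiguity.
  Twins are modeled as poorly-identifiable species (``lookalike_id_prob``),
  the regime in which look-alikes produce wrong transfers rather than only
  ambiguous clusters;
* *background* spectra that are never identified, mirroring the large
  unidentifiable fraction of real MS2 data (real TMT datasets identify on
  the order of 12-22% of MS2 spectra).

Everything is drawn from a single seeded generator, so a fixed config yields
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .formats import write_mgf, write_search_results
from .records import PsmRecord, ScanKey, SpectrumRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

# Monoisotopic residue masses (Da).
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.0105646863
PROTON = 1.00727646688
PHOSPHO_MASS = 79.96633

NORMAL = "normal"
ISOMER = "isomer"
LOOKALIKE = "lookalike"
BACKGROUND = "background"

WORKED_ISOMER_SEQUENCE = "RASPSPRAA"
WORKED_ISOMER_PROTEIN = "Serine/arginine repetitive matrix protein 1"


@dataclass(frozen=True)
class PeakNoise:
    dropout: float = 0.05       # probability a template peak is absent
    mz_jitter_sd: float = 0.002  # Th
    intensity_cv: float = 0.2    # lognormal sigma on peak intensity


@dataclass(frozen=True)
class ReporterModel:
    base_intensity: float = 1e6
    base_log2_sd: float = 0.5    # spectrum-to-spectrum overall level spread
    protein_log2_sd: float = 0.6  # per-protein channel pattern spread
    noise_log2_sd: float = 0.25   # per-channel measurement noise


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark; see the methods note."""

    n_batches: int = 3
    n_peptides: int = 3000
    n_background_peptides: int = 5400
    peptides_per_protein: int = 8
    peptide_length: tuple[int, int] = (8, 14)
    phospho_fraction: float = 0.25
    isomer_pair_fraction: float = 0.05
    lookalike_pair_fraction: float = 0.0
    lookalike_id_prob: float = 0.2
    lookalike_shared_fraction: tuple[float, float] = (0.3, 0.95)
    per_batch_identification_prob: float = 0.93
    peak_noise: PeakNoise = field(default_factory=PeakNoise)
    plex_size: int = 10
    reporter_model: ReporterModel = field(default_factory=ReporterModel)
    charges: tuple[int, ...] = (2, 3)
    fragment_range: tuple[float, float] = (100.0, 1500.0)
    bin_width: float = 0.02  # used only to engineer look-alike bin sharing
    plant_worked_isomer: bool = False
    seed: int = 1

    def validate(self) -> None:
        for name in (
            "phospho_fraction",
            "isomer_pair_fraction",
            "lookalike_pair_fraction",
            "lookalike_id_prob",
            "per_batch_identification_prob",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.plex_size < 2:
            raise ValueError("plex_size must be >= 2")
        if self.isomer_pair_fraction > 0 and self.phospho_fraction == 0:
            raise ValueError("isomer pairs require phospho_fraction > 0")
        if self.plant_worked_isomer and self.n_batches < 3:
            raise ValueError("the worked isomer example needs >= 3 batches")


@dataclass
class ScanTruth:
    sequence: str
    modified_sequence: str
    protein: str
    kind: str
    identified: bool


@dataclass
class GroundTruth:
    scans: dict[ScanKey, ScanTruth] = field(default_factory=dict)
    peptide_batches: dict[str, set[str]] = field(default_factory=dict)
    peptide_identified_batches: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    spectra: list[SpectrumRecord]
    psms: list[PsmRecord]
    truth: GroundTruth

    def batches(self) -> list[str]:
        return [f"batch{i + 1}" for i in range(self.config.n_batches)]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def fragment_mzs(sequence: str, phospho_sites: tuple[int, ...] = ()) -> np.ndarray:
    """Singly-charged b/y ion m/z values of a (possibly phosphorylated) peptide."""
    masses = np.array([RESIDUE_MASS[a] for a in sequence])
    for site in phospho_sites:
        masses[site - 1] += PHOSPHO_MASS
    prefix = np.cumsum(masses)
    total = prefix[-1]
    b_ions = prefix[:-1] + PROTON
    y_ions = (total - prefix[:-1]) + WATER + PROTON
    return np.sort(np.concatenate([b_ions, y_ions]))


def precursor_mz(sequence: str, charge: int, phospho_sites: tuple[int, ...] = ()) -> float:
    mass = sum(RESIDUE_MASS[a] for a in sequence) + WATER + PHOSPHO_MASS * len(phospho_sites)
    return (mass + charge * PROTON) / charge


def render_modified_sequence(sequence: str, phospho_sites: tuple[int, ...]) -> str:
    out = []
    sites = set(phospho_sites)
    for i, ch in enumerate(sequence, start=1):
        if i in sites:
            out.append("p")
        out.append(ch)
    return "".join(out)


def _random_sequence(rng: np.random.Generator, length: int, require_sty: bool = False) -> str:
    body = "".join(rng.choice(list(AA), size=length - 1))
    seq = body + ("K" if rng.random() < 0.5 else "R")
    if require_sty and not any(c in "STY" for c in seq[1:-1]):
        pos = int(rng.integers(1, length - 1))
        seq = seq[:pos] + "S" + seq[pos + 1:]
    return seq


@dataclass
class _Species:
    """One emitted precursor form: peptide variant, twin or background."""

    sequence: str
    phospho_sites: tuple[int, ...]
    protein: str
    kind: str
    id_prob: float
    charge: int
    precursor_mz: float
    template_mz: np.ndarray
    template_intensity: np.ndarray
    forced_status: Optional[dict[int, list[bool]]] = None  # batch -> statuses


def _make_templates(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[list[_Species], dict[str, np.ndarray]]:
    lo_len, hi_len = config.peptide_length
    n_main = config.n_peptides
    n_phospho = int(round(config.phospho_fraction * n_main))
    n_isomer = int(round(config.isomer_pair_fraction * n_phospho))
    n_twin = int(round(config.lookalike_pair_fraction * n_main))

    sequences: list[str] = []
    seen = set()
    while len(sequences) < n_main + n_twin + config.n_background_peptides:
        need_sty = len(sequences) < n_phospho
        seq = _random_sequence(rng, int(rng.integers(lo_len, hi_len + 1)), require_sty=need_sty)
        if seq in seen:
            continue
        seen.add(seq)
        sequences.append(seq)
    main_seqs = sequences[:n_main]
    twin_seqs = sequences[n_main : n_main + n_twin]
    bg_seqs = sequences[n_main + n_twin :]

    protein_of = {
        seq: f"SYNP{i // config.peptides_per_protein:05d}" for i, seq in enumerate(main_seqs)
    }
    for j, seq in enumerate(twin_seqs):
        protein_of[seq] = f"SYNT{j:05d}"

    proteins = sorted(set(protein_of.values()))
    patterns = {
        prot: rng.normal(0.0, config.reporter_model.protein_log2_sd, size=config.plex_size - 1)
        for prot in proteins
    }

    species: list[_Species] = []
    lo_f, hi_f = config.fragment_range

    def template_for(mzs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        keep = (mzs >= lo_f) & (mzs <= hi_f)
        mzs = np.unique(np.round(mzs[keep], 5))
        intensities = np.exp(rng.normal(0.0, 1.0, size=mzs.size)) * 1e4
        return mzs, intensities

    def add_peptide(seq: str, sites: tuple[int, ...], kind: str, id_prob: float) -> _Species:
        charge = int(rng.choice(config.charges))
        mzs, intens = template_for(fragment_mzs(seq, sites))
        sp = _Species(
            sequence=seq,
            phospho_sites=sites,
            protein=protein_of.get(seq, f"SYNB{len(species):05d}"),
            kind=kind,
            id_prob=id_prob,
            charge=charge,
            precursor_mz=precursor_mz(seq, charge, sites),
            template_mz=mzs,
            template_intensity=intens,
        )
        species.append(sp)
        return sp

    def phospho_site_options(seq: str) -> list[int]:
        return [i for i, c in enumerate(seq, start=1) if c in "STY"]

    q = config.per_batch_identification_prob
    for i, seq in enumerate(main_seqs):
        if i < n_phospho:
            options = phospho_site_options(seq)
            site = int(rng.choice(options))
            main = add_peptide(seq, (site,), NORMAL, q)
            if i < n_isomer and len(options) >= 2:
                other = int(rng.choice([o for o in options if o != site]))
                add_peptide(seq, (other,), ISOMER, q)
        else:
            add_peptide(seq, (), NORMAL, q)

    # look-alike twins mirror the last n_twin (unmodified) main peptides
    bin_width = config.bin_width
    f_lo, f_hi = config.lookalike_shared_fraction
    partners = [sp for sp in species if sp.kind == NORMAL and not sp.phospho_sites][-n_twin:] if n_twin else []
    for twin_seq, partner in zip(twin_seqs, partners):
        n_peaks = partner.template_mz.size
        n_shared = int(round(float(rng.uniform(f_lo, f_hi)) * n_peaks))
        n_shared = min(max(n_shared, 1), n_peaks - 1)
        shared_idx = rng.choice(n_peaks, size=n_shared, replace=False)
        shared_mz = partner.template_mz[shared_idx]
        n_own = max(n_peaks - n_shared, 3)
        forbidden = set(np.floor(partner.template_mz / bin_width).astype(int).tolist())
        own = []
        while len(own) < n_own:
            candidate = float(rng.uniform(150.0, 1400.0))
            if int(candidate / bin_width) not in forbidden:
                own.append(candidate)
        mzs = np.sort(np.concatenate([shared_mz, np.array(own)]))
        twin = _Species(
            sequence=twin_seq,
            phospho_sites=(),
            protein=protein_of[twin_seq],
            kind=LOOKALIKE,
            id_prob=config.lookalike_id_prob,
            charge=partner.charge,
            precursor_mz=partner.precursor_mz * (1.0 + float(rng.uniform(-3e-6, 3e-6))),
            template_mz=mzs,
            template_intensity=np.exp(rng.normal(0.0, 1.0, size=mzs.size)) * 1e4,
        )
        species.append(twin)

    for j, seq in enumerate(bg_seqs):
        sp = add_peptide(seq, (), BACKGROUND, 0.0)
        patterns.setdefault(sp.protein, rng.normal(0.0, config.reporter_model.protein_log2_sd, size=config.plex_size - 1))

    if config.plant_worked_isomer:
        species.extend(_worked_isomer_species(rng, config))
        patterns.setdefault(
            WORKED_ISOMER_PROTEIN,
            rng.normal(0.0, config.reporter_model.protein_log2_sd, size=config.plex_size - 1),
        )
    return species, patterns


def _worked_isomer_species(rng: np.random.Generator, config: SyntheticConfig) -> list[_Species]:
    """Two phospho-isomer forms of one peptide with deterministic id status.

    Batch 1 holds an identified spectrum of each form plus one unidentified
    spectrum; batch 2 an identified spectrum of the first form; batch 3 an
    unidentified spectrum of the second form. Running the pipeline on the
    emitted cluster therefore exercises the PTM-isomeric transfer path with a
    known localization flag.
    """
    out = []
    for sites, forced in (
        ((3,), {0: [True, False], 1: [True]}),
        ((5,), {0: [True], 2: [False]}),
    ):
        mzs = fragment_mzs(WORKED_ISOMER_SEQUENCE, sites)
        out.append(
            _Species(
                sequence=WORKED_ISOMER_SEQUENCE,
                phospho_sites=sites,
                protein=WORKED_ISOMER_PROTEIN,
                kind=ISOMER,
                id_prob=1.0,
                charge=2,
                precursor_mz=precursor_mz(WORKED_ISOMER_SEQUENCE, 2, sites),
                template_mz=mzs,
                template_intensity=np.exp(rng.normal(0.0, 1.0, size=mzs.size)) * 1e4,
                forced_status=forced,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate spectra, PSM rows and ground truth for every batch."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species, patterns = _make_templates(rng, config)
    noise = config.peak_noise
    rep = config.reporter_model

    spectra: list[SpectrumRecord] = []
    psms: list[PsmRecord] = []
    truth = GroundTruth()

    for b in range(config.n_batches):
        raw_file = f"batch{b + 1}"
        scan = 1000
        for sp in species:
            if sp.forced_status is not None:
                statuses = sp.forced_status.get(b, [])
            else:
                statuses = [None]
            for status in statuses:
                scan += 1
                n = sp.template_mz.size
                keep = rng.random(n) >= noise.dropout
                if keep.sum() < min(3, n):
                    keep[np.argsort(sp.template_intensity)[-3:]] = True
                mz = sp.template_mz[keep] + rng.normal(0.0, noise.mz_jitter_sd, size=int(keep.sum()))
                intensity = sp.template_intensity[keep] * np.exp(
                    rng.normal(0.0, noise.intensity_cv, size=int(keep.sum()))
                )
                base = rep.base_intensity * 2.0 ** rng.normal(0.0, rep.base_log2_sd)
                channel_noise = rng.normal(0.0, rep.noise_log2_sd, size=config.plex_size)
                pattern = patterns[sp.protein]
                reporters = np.empty(config.plex_size)
                reporters[:-1] = base * 2.0 ** (pattern + channel_noise[:-1])
                reporters[-1] = base * 2.0 ** channel_noise[-1]  # bridge channel

                identified = rng.random() < sp.id_prob if status is None else status
                order = np.argsort(mz)
                spectrum = SpectrumRecord(
                    raw_file=raw_file,
                    scan_number=scan,
                    precursor_mz=sp.precursor_mz,
                    precursor_charge=sp.charge,
                    retention_time=scan / 100.0,
                    mz=mz[order],
                    intensity=intensity[order],
                    reporter_intensities=reporters,
                    batch_id=raw_file,
                )
                spectra.append(spectrum)
                mod_seq = render_modified_sequence(sp.sequence, sp.phospho_sites)
                psms.append(
                    PsmRecord(
                        raw_file=raw_file,
                        scan_number=scan,
                        sequence=sp.sequence if identified else "",
                        modified_sequence=mod_seq if identified else "",
                        proteins=(sp.protein,) if identified else (),
                        score=float(rng.uniform(60.0, 160.0)) if identified else float("nan"),
                        pep=float(rng.uniform(1e-6, 1e-2)) if identified else None,
                        reporter_intensities=reporters,
                        batch_id=raw_file,
                    )
                )
                truth.scans[(raw_file, scan)] = ScanTruth(
                    sequence=sp.sequence,
                    modified_sequence=mod_seq,
                    protein=sp.protein,
                    kind=sp.kind,
                    identified=bool(identified),
                )
                truth.peptide_batches.setdefault(sp.sequence, set()).add(raw_file)
                if identified:
                    truth.peptide_identified_batches.setdefault(sp.sequence, set()).add(raw_file)
    return SyntheticDataset(config=config, spectra=spectra, psms=psms, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir: str) -> dict[str, list[str]]:
    """Write MGF files (one per batch), the PSM table and the ground truth."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, list[str]] = {"spectra": [], "psms": [], "truth": []}
    by_file: dict[str, list[SpectrumRecord]] = {}
    for s in dataset.spectra:
        by_file.setdefault(s.raw_file, []).append(s)
    for raw_file in sorted(by_file):
        path = os.path.join(outdir, f"{raw_file}.mgf")
        write_mgf(by_file[raw_file], path)
        paths["spectra"].append(path)
    psm_path = os.path.join(outdir, "msms.txt")
    write_search_results(dataset.psms, psm_path, plex_size=dataset.config.plex_size)
    paths["psms"].append(psm_path)
    truth_path = os.path.join(outdir, "ground_truth.tsv")
    rows = [
        {
            "raw_file": raw,
            "scan_number": scan,
            "sequence": t.sequence,
            "modified_sequence": t.modified_sequence,
            "protein": t.protein,
            "kind": t.kind,
            "identified": t.identified,
        }
        for (raw, scan), t in dataset.truth.scans.items()
    ]
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    paths["truth"].append(truth_path)
    return paths
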