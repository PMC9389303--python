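"""Masking analysis, FDR proxy, presence curves and reporter agreement."""

import collections
import math

import numpy as np
import pandas as pd
import pytest

from ms2transfer.clustering import DEFAULT_THRESHOLDS, cluster_at_thresholds
from ms2transfer.evaluation import (
    MaskingError,
    ambiguous_cluster_fraction,
    batch_presence_curve,
    mask_identifications,
    precision_recall,
    reporter_ratio_agreement,
)
from ms2transfer.pipeline import transfer_at_thresholds
from ms2transfer.records import ClusterAssignment, PsmRecord
from ms2transfer.synthetic import SyntheticConfig, generate_dataset
from ms2transfer.transfer import merge_tables, transfer_identifications


def psm(raw, scan, seq="", score=100.0):
    return PsmRecord(raw, scan, seq, seq, ("P1",) if seq else (), score if seq else math.nan)


class TestMasking:
    def test_rounding_rule_half_of_ten(self):
        psms = [psm("a", i, "AAAK") for i in range(10)]
        masked, truth = mask_identifications(psms, 0.5, seed=1)
        assert len(truth) == 5
        assert sum(p.is_identified for p in masked) == 5

    def test_same_seed_same_mask(self):
        psms = [psm("a", i, "AAAK") for i in range(50)]
        _, t1 = mask_identifications(psms, 0.2, seed=9)
        _, t2 = mask_identifications(psms, 0.2, seed=9)
        assert t1.keys() == t2.keys()

    def test_masked_plus_unmasked_partition_identified_set(self):
        psms = [psm("a", i, "AAAK") for i in range(20)] + [psm("a", 100 + i) for i in range(5)]
        masked, truth = mask_identifications(psms, 0.3, seed=2)
        surviving = {p.key for p in masked if p.is_identified}
        assert surviving | set(truth) == {p.key for p in psms if p.is_identified}
        assert surviving & set(truth) == set()

    def test_stratified_per_raw_file(self):
        psms = [psm("a", i, "AAAK") for i in range(10)] + [psm("b", i, "CCCK") for i in range(10)]
        _, truth = mask_identifications(psms, 0.2, seed=3)
        by_file = collections.Counter(k[0] for k in truth)
        assert by_file == {"a": 2, "b": 2}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(MaskingError):
            mask_identifications([psm("a", 1, "AAAK")], 0.0, seed=1)
        with pytest.raises(MaskingError):
            mask_identifications([psm("a", 1, "AAAK")], 1.2, seed=1)


def _masked_run_table(truth_map, transfers):
    """Hand-build a finalized table with the given transfers onto masked scans."""
    rows = []
    for i, ((raw, scan), seq) in enumerate(transfers.items()):
        rows.append({
            "raw_file": raw, "scan_number": scan, "batch_id": raw, "cluster_id": i,
            "sequence": seq, "modified_sequence": seq, "proteins": "P1",
            "score": math.nan, "pep": math.nan, "is_decoy": False,
            "identification_type": "transfer", "cluster_category": "transferable",
            "transferred_flag": seq,
        })
    return pd.DataFrame(rows)


class TestPrecisionRecall:
    def test_printed_formula_arithmetic(self):
        truth = {("a", i): ("AAAK", "AAAK") for i in range(5)}
        transfers = {("a", 0): "AAAK", ("a", 1): "AAAK", ("a", 2): "AAAK", ("a", 3): "XXXK"}
        report = precision_recall(_masked_run_table(truth, transfers), truth)
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.6)
        assert report.fdr == pytest.approx(0.25)

    def test_all_correct_gives_zero_fdr(self):
        truth = {("a", i): ("AAAK", "AAAK") for i in range(3)}
        transfers = {("a", i): "AAAK" for i in range(3)}
        report = precision_recall(_masked_run_table(truth, transfers), truth)
        assert report.fdr == 0.0
        assert report.recall == 1.0

    def test_transfers_onto_never_identified_scans_excluded(self):
        truth = {("a", 0): ("AAAK", "AAAK")}
        transfers = {("a", 0): "AAAK", ("a", 99): "AAAK"}  # scan 99 not in truth
        report = precision_recall(_masked_run_table(truth, transfers), truth)
        assert report.n_transferred_to_masked == 1
        assert report.precision == 1.0

    def test_zero_masked_scans_is_an_error(self):
        with pytest.raises(MaskingError):
            precision_recall(_masked_run_table({}, {}), {})

    def test_fdr_identity_holds_exactly(self):
        truth = {("a", i): ("AAAK", "AAAK") for i in range(7)}
        transfers = {("a", i): ("AAAK" if i % 3 else "XXXK") for i in range(7)}
        report = precision_recall(_masked_run_table(truth, transfers), truth)
        assert report.fdr + report.precision == 1.0

    def test_micro_average_identity_on_synthetic_run(self):
        """Pooled ratios equal per-peptide TP/FP/FN sums tallied independently."""
        config = SyntheticConfig(n_peptides=60, n_background_peptides=20,
                                 lookalike_pair_fraction=0.3, seed=11)
        dataset = generate_dataset(config)
        assignments = cluster_at_thresholds(dataset.spectra, DEFAULT_THRESHOLDS[:1])
        masked, truth = mask_identifications(dataset.psms, 0.3, seed=11)
        table = transfer_at_thresholds(dataset.spectra, masked, assignments)["p5"]
        report = precision_recall(table, truth, "p5", 0.3)

        # independent brute-force per-peptide tally
        tp = collections.Counter()
        fp = collections.Counter()
        fn = collections.Counter()
        transferred = {
            (r.raw_file, r.scan_number): r.sequence
            for r in table.itertuples(index=False)
            if r.identification_type == "transfer"
        }
        for key, (true_seq, _) in truth.items():
            got = transferred.get(key)
            if got == true_seq:
                tp[true_seq] += 1
            else:
                fn[true_seq] += 1
                if got is not None:
                    fp[got] += 1
        sum_tp, sum_fp, sum_fn = sum(tp.values()), sum(fp.values()), sum(fn.values())
        assert sum_tp > 0
        assert report.n_correct == sum_tp
        assert report.precision == sum_tp / (sum_tp + sum_fp)
        assert report.recall == sum_tp / (sum_tp + sum_fn)
        assert report.fdr == 1.0 - report.precision


class TestAmbiguousFraction:
    def _table(self, categories):
        rows = []
        for cid, category in enumerate(categories):
            for j in range(1 if category == "singleton" else 2):
                rows.append({
                    "raw_file": "a", "scan_number": 10 * cid + j, "batch_id": "a",
                    "cluster_id": cid, "sequence": "", "modified_sequence": "",
                    "proteins": "", "score": math.nan, "pep": math.nan,
                    "is_decoy": False, "identification_type": "none",
                    "cluster_category": category, "transferred_flag": "",
                })
        return pd.DataFrame(rows)

    def test_fraction_arithmetic(self):
        categories = ["ambiguous"] + ["unanimous"] * 49
        stats = ambiguous_cluster_fraction(self._table(categories))
        assert stats.fraction == pytest.approx(0.02)

    def test_all_singletons_degenerate(self):
        stats = ambiguous_cluster_fraction(self._table(["singleton"] * 5))
        assert stats.fraction == 0.0
        assert stats.degenerate

    def test_planted_ambiguity_recovered_within_binomial_error(self):
        config = SyntheticConfig(n_peptides=300, n_background_peptides=100,
                                 lookalike_pair_fraction=0.3, lookalike_id_prob=0.9,
                                 seed=21)
        dataset = generate_dataset(config)
        assignments = cluster_at_thresholds(dataset.spectra, DEFAULT_THRESHOLDS[:1])
        table = transfer_at_thresholds(dataset.spectra, dataset.psms, assignments)["p5"]
        stats = ambiguous_cluster_fraction(table)
        # 90 planted pairs (30% of 300 main peptides get a twin) with both
        # partners nearly always identified; each pair merges into a single
        # multi-spectrum cluster, so the denominator is ~300 main + 100
        # background clusters
        n_pairs = int(round(0.3 * 300))
        expected = n_pairs / (300 + 100)
        sd = math.sqrt(expected * (1 - expected) / 400)
        assert abs(stats.fraction - expected) < 4 * sd + 0.02

    def test_mean_fraction_non_increasing_in_stringency(self):
        """FDR proxy falls (or stays) as the clustering gets stricter."""
        fractions = np.zeros((10, len(DEFAULT_THRESHOLDS)))
        for i, seed in enumerate(range(100, 110)):
            config = SyntheticConfig(n_peptides=600, n_background_peptides=100,
                                     lookalike_pair_fraction=0.4, seed=seed)
            dataset = generate_dataset(config)
            assignments = cluster_at_thresholds(dataset.spectra, DEFAULT_THRESHOLDS)
            tables = transfer_at_thresholds(dataset.spectra, dataset.psms, assignments)
            for j, t in enumerate(DEFAULT_THRESHOLDS):
                fractions[i, j] = ambiguous_cluster_fraction(tables[t.label]).fraction
        means = fractions.mean(axis=0)
        assert all(a >= b for a, b in zip(means, means[1:])), means


def _presence_table(entries):
    """entries: (batch, sequence, protein, identification_type) tuples."""
    rows = []
    for i, (batch, seq, prot, id_type) in enumerate(entries):
        rows.append({
            "raw_file": batch, "scan_number": i, "batch_id": batch, "cluster_id": i,
            "sequence": seq, "modified_sequence": seq, "proteins": prot,
            "score": math.nan, "pep": math.nan, "is_decoy": False,
            "identification_type": id_type, "cluster_category": "", "transferred_flag": "",
        })
    return pd.DataFrame(rows)


class TestPresenceCurve:
    def test_peptide_in_two_of_three_batches(self):
        table = _presence_table([
            ("b1", "AAAK", "P1", "direct"),
            ("b2", "AAAK", "P1", "direct"),
            ("b3", "", "", "none"),
        ])
        curve = batch_presence_curve(table, level="peptide")
        assert list(curve.counts) == [1, 1, 0]

    def test_counts_non_increasing(self):
        config = SyntheticConfig(n_peptides=80, n_background_peptides=20, seed=5)
        dataset = generate_dataset(config)
        assignments = cluster_at_thresholds(dataset.spectra, DEFAULT_THRESHOLDS[:1])
        table = transfer_at_thresholds(dataset.spectra, dataset.psms, assignments)["p5"]
        for level in ("peptide", "protein"):
            counts = batch_presence_curve(table, level=level).counts
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_transfers_never_decrease_counts(self):
        config = SyntheticConfig(n_peptides=80, n_background_peptides=20, seed=6)
        dataset = generate_dataset(config)
        assignments = cluster_at_thresholds(dataset.spectra, DEFAULT_THRESHOLDS[:1])
        masked, _ = mask_identifications(dataset.psms, 0.3, seed=6)
        table = transfer_at_thresholds(dataset.spectra, masked, assignments)["p5"]
        before = batch_presence_curve(table, "peptide", include_transfers=False).counts
        after = batch_presence_curve(table, "peptide", include_transfers=True).counts
        assert np.all(after >= before)
        assert after.sum() > before.sum()  # masking created recoverable gaps


class TestReporterAgreement:
    def test_proportional_pattern_gives_correlation_one(self):
        pattern = np.array([1.0, 2.0, 4.0, 0.5, 1.0])
        rows = []
        for i, scale in enumerate([1.0, 2.0, 0.5]):
            rows.append({
                "raw_file": "b1", "scan_number": i, "batch_id": "b1", "cluster_id": 1,
                "sequence": "AAAK", "modified_sequence": "AAAK", "proteins": "P1",
                "score": 100.0, "pep": 0.001, "is_decoy": False,
                "identification_type": "direct" if i < 2 else "transfer",
                "cluster_category": "transferable", "transferred_flag": "",
                **{f"reporter_{j}": scale * v for j, v in enumerate(pattern)},
            })
        agreement = reporter_ratio_agreement(pd.DataFrame(rows))
        transferred = agreement.per_psm[agreement.per_psm["identification_type"] == "transfer"]
        assert transferred["correlation"].iloc[0] == pytest.approx(1.0)

    def test_flat_channels_skipped(self):
        rows = []
        for i in range(3):
            rows.append({
                "raw_file": "b1", "scan_number": i, "batch_id": "b1", "cluster_id": 1,
                "sequence": "AAAK", "modified_sequence": "AAAK", "proteins": "P1",
                "score": 100.0, "pep": 0.001, "is_decoy": False,
                "identification_type": "direct" if i < 2 else "transfer",
                "cluster_category": "transferable", "transferred_flag": "",
                **{f"reporter_{j}": 100.0 for j in range(5)},
            })
        agreement = reporter_ratio_agreement(pd.DataFrame(rows))
        assert len(agreement.per_psm) == 0
        assert agreement.n_skipped == 3

    def test_transfers_track_true_protein_patterns(self):
        """Transfers inherit the right protein's reporter pattern on synthetic
        data, beating a shuffled-protein control."""
        config = SyntheticConfig(n_peptides=120, n_background_peptides=0, seed=8)
        dataset = generate_dataset(config)
        assignments = cluster_at_thresholds(dataset.spectra, DEFAULT_THRESHOLDS[:1])
        masked, _ = mask_identifications(dataset.psms, 0.3, seed=8)
        table = transfer_at_thresholds(dataset.spectra, masked, assignments)["p5"]
        agreement = reporter_ratio_agreement(table)
        median = agreement.median_correlation("transfer")
        assert median > 0.5

        rng = np.random.default_rng(0)
        shuffled = table.copy()
        transfer_mask = shuffled["identification_type"] == "transfer"
        proteins = shuffled.loc[transfer_mask, "proteins"].to_numpy().copy()
        rng.shuffle(proteins)
        shuffled.loc[transfer_mask, "proteins"] = proteins
        control = reporter_ratio_agreement(shuffled).median_correlation("transfer")
        assert median > control
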