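"""Frequency computation, the three filters, and the pipeline."""

import numpy as np
import pandas as pd
import pytest

from mutscan import enrichment as en
from mutscan import synthetic as sd


def make_table(rows, conditions=("act", "lof")):
    """rows: (nt_pos, ref, alt, label, {cond: (count, cov)})"""
    recs = []
    for nt_pos, ref, alt, label, per_cond in rows:
        rec = {"nt_pos": nt_pos, "ref": ref, "alt": alt,
               "protein_change": label}
        for c in conditions:
            rec[f"count_{c}"], rec[f"cov_{c}"] = per_cond[c]
        recs.append(rec)
    return en.VariantCountTable(pd.DataFrame(recs), list(conditions))


class TestFrequencies:
    def test_basic_division(self):
        t = make_table(
            [(1, "A", "C", "K1Q", {"act": (150, 10000), "lof": (0, 10000)})]
        )
        f = en.compute_frequencies(t)
        assert f.frequencies("act")[0] == pytest.approx(0.015)
        assert f.frequencies("lof")[0] == 0.0

    def test_matches_brute_force_on_simulated_table(self):
        cds = sd.random_cds(10, seed=0)
        variants = sd.enumerate_snv_library(cds)
        config = sd.SelectionConfig(rounds=1, depth_per_round=10_000, seed=1)
        table = sd.simulate_selection_counts(variants, config)
        freqs = en.compute_frequencies(table)
        for c in table.conditions:
            expected = (
                table.data[f"count_{c}"] / table.data[f"cov_{c}"]
            ).to_numpy()
            np.testing.assert_array_equal(
                freqs.frequencies(c).to_numpy(), expected
            )

    def test_count_without_coverage_rejected(self):
        df = pd.DataFrame(
            [{"nt_pos": 1, "ref": "A", "alt": "C", "protein_change": "K1Q",
              "count_act": 5, "cov_act": 0}]
        )
        with pytest.raises(en.DataIntegrityError):
            en.VariantCountTable(df, ["act"])


class TestFilterFrequency:
    def _freqs(self, f_act):
        count = int(round(f_act * 100000))
        t = make_table(
            [(1, "A", "C", "K1Q",
              {"act": (count, 100000), "lof": (0, 100000)})]
        )
        return en.compute_frequencies(t)

    def test_above_threshold_kept(self):
        assert en.filter_frequency(self._freqs(0.012), ["act"]) == {
            (1, "A", "C")
        }

    def test_exact_threshold_excluded(self):
        assert en.filter_frequency(self._freqs(0.010), ["act"]) == set()

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(20):
            rows.append(
                (i + 1, "A", "C", f"K{i + 1}Q",
                 {"act": (int(rng.integers(0, 3000)), 100000),
                  "lof": (0, 100000)})
            )
        freqs = en.compute_frequencies(make_table(rows))
        kept = en.filter_frequency(freqs, ["act"], 0.01)
        brute = {
            (r.nt_pos, r.ref, r.alt)
            for r in freqs.data.itertuples()
            if r.freq_act > 0.01
        }
        assert kept == brute

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            en.filter_frequency(self._freqs(0.02), ["nope"])


class TestFoldEnrichment:
    def _freqs(self, f_act, f_ref, cov=100000):
        t = make_table(
            [(1, "A", "C", "K1Q",
              {"act": (int(round(f_act * cov)), cov),
               "lof": (int(round(f_ref * cov)), cov)})]
        )
        return en.compute_frequencies(t)

    def test_ratio_above_fold_kept(self):
        kept = en.filter_fold_enrichment(
            self._freqs(0.016, 0.001), "act", "lof"
        )
        assert kept == {(1, "A", "C")}

    def test_exact_fold_excluded(self):
        kept = en.filter_fold_enrichment(
            self._freqs(0.008, 0.001), "act", "lof"
        )
        assert kept == set()

    def test_zero_reference_uses_pseudofrequency(self):
        # f_ref = 0 at coverage 1e5 -> 5e-6; f_act = 1e-4 -> ratio 20
        kept = en.filter_fold_enrichment(
            self._freqs(1e-4, 0.0), "act", "lof", fold=8.0
        )
        assert kept == {(1, "A", "C")}
        # and ratio 20 is just above; fold=25 excludes
        assert (
            en.filter_fold_enrichment(
                self._freqs(1e-4, 0.0), "act", "lof", fold=25.0
            )
            == set()
        )


class TestCosmicFilter:
    def test_membership(self):
        cosmic = en.CosmicFixture(
            pd.DataFrame(
                {"protein_change": ["L858R", "L927L"],
                 "occurrence_count": [3000, 3]}
            )
        )
        kept = en.filter_cosmic(["L858R", "Q787Q", "L927L", "A999V"], cosmic)
        assert kept == {"L858R", "L927L"}

    def test_unnormalizable_label_warns(self):
        cosmic = en.CosmicFixture(
            pd.DataFrame(
                {"protein_change": ["L858R"], "occurrence_count": [1]}
            )
        )
        with pytest.warns(UserWarning, match="unnormalizable"):
            kept = en.filter_cosmic(["delE746", "L858R"], cosmic)
        assert kept == {"L858R"}

    def test_occurrence_below_one_rejected(self):
        with pytest.raises(en.DataIntegrityError):
            en.CosmicFixture(
                pd.DataFrame(
                    {"protein_change": ["L858R"], "occurrence_count": [0]}
                )
            )


EXPECTED_SURVIVORS = [
    "S442I", "L658Q", "S768I", "T790M", "L858R", "L927L", "H1129Y"
]


class TestPipeline:
    def test_packaged_worked_example(self):
        table = en.load_packaged_counts()
        cosmic = en.load_packaged_cosmic()
        report = en.run_filter_pipeline(
            table, cosmic,
            en.FilterConfig(["actA", "actB"], ["lof"]),
        )
        assert report.survivors == EXPECTED_SURVIVORS
        # each decoy fails exactly one filter
        decoys = report.data[~report.data["verdict"]]
        flags = decoys[["pass_filter1", "pass_filter2", "pass_filter3"]]
        assert (flags.sum(axis=1) == 2).all()

    def test_empty_cosmic_gives_empty_list(self):
        table = en.load_packaged_counts()
        cosmic = en.CosmicFixture(
            pd.DataFrame(
                {"protein_change": ["A1V"], "occurrence_count": [1]}
            )
        )
        report = en.run_filter_pipeline(
            table, cosmic, en.FilterConfig(["actA", "actB"], ["lof"])
        )
        assert report.survivors == []

    def test_order_independence(self):
        """Verdict equals the intersection of standalone filter passes."""
        table = en.load_packaged_counts()
        cosmic = en.load_packaged_cosmic()
        config = en.FilterConfig(["actA", "actB"], ["lof"])
        report = en.run_filter_pipeline(table, cosmic, config)
        freqs = en.compute_frequencies(table)
        s1 = en.filter_frequency(freqs, config.activation_conditions)
        s2 = set()
        for c in config.activation_conditions:
            s2 |= en.filter_fold_enrichment(
                freqs, c, config.reference_conditions
            )
        labels3 = en.filter_cosmic(freqs.data["protein_change"], cosmic)
        keys = list(zip(freqs.data.nt_pos, freqs.data.ref, freqs.data.alt))
        expected = {
            k
            for k, lab in zip(keys, freqs.data.protein_change)
            if k in s1 and k in s2 and lab in labels3
        }
        got = {
            k for k, v in zip(keys, report.data["verdict"]) if v
        }
        assert got == expected

    def test_monotone_in_thresholds(self):
        table = en.load_packaged_counts()
        cosmic = en.load_packaged_cosmic()
        prev = None
        for freq in (0.001, 0.005, 0.01, 0.02, 0.05):
            report = en.run_filter_pipeline(
                table, cosmic,
                en.FilterConfig(["actA", "actB"], ["lof"], freq, 8.0),
            )
            survivors = set(report.survivors)
            if prev is not None:
                assert survivors <= prev
            prev = survivors
        prev = None
        for fold in (1.0, 4.0, 8.0, 30.0, 100.0):
            report = en.run_filter_pipeline(
                table, cosmic,
                en.FilterConfig(["actA", "actB"], ["lof"], 0.01, fold),
            )
            survivors = set(report.survivors)
            if prev is not None:
                assert survivors <= prev
            prev = survivors

    def test_filter_idempotent(self):
        table = en.load_packaged_counts()
        freqs = en.compute_frequencies(table)
        kept = en.filter_frequency(freqs, ["actA"])
        keys = list(zip(freqs.data.nt_pos, freqs.data.ref, freqs.data.alt))
        mask = [k in kept for k in keys]
        sub = en.FrequencyTable(
            freqs.data.loc[mask].reset_index(drop=True), freqs.conditions
        )
        assert en.filter_frequency(sub, ["actA"]) == kept


class TestRecovery:
    def test_planted_variants_recovered_and_artifacts_removed(self):
        """Single-seed version of the full parameter-recovery check."""
        cds = sd.random_cds(50, seed=21)
        variants = sd.enumerate_snv_library(cds)
        # plant only labels not reachable through a C->T change, so the
        # planted set is disjoint from the PCR-artifact channel
        ct_labels = {
            v.protein_change
            for v in variants
            if (v.ref_base, v.alt_base) == ("C", "T")
        }
        labels = sorted(
            {v.protein_change for v in variants if not v.synonymous}
            - ct_labels
        )
        planted = {labels[5]: 4.0, labels[60]: 5.0, labels[110]: 6.0}
        variants = sd.assign_activities(variants, planted)
        config = sd.SelectionConfig(
            rounds=2, gate_stringency=0.1, depth_per_round=500_000,
            pcr_error_rate=5e-4, ct_bias_factor=30.0, seed=13,
        )
        table = sd.simulate_screen(variants, config)
        freqs = en.compute_frequencies(table)
        acts = ["actA_r2", "actB_r2"]
        s1 = en.filter_frequency(freqs, acts)
        s2 = set()
        for c in acts:
            s2 |= en.filter_fold_enrichment(freqs, c, ["lof_ref"])
        keys = list(zip(freqs.data.nt_pos, freqs.data.ref, freqs.data.alt))
        lab = dict(zip(keys, freqs.data.protein_change))
        pass12 = s1 & s2
        got_labels = {lab[k] for k in pass12}
        assert set(planted) <= got_labels
        # nothing neutral passes both filters
        assert got_labels == set(planted)
        # C->T artifacts pass filter 1 but are removed by filter 2
        f1_only = s1 - s2
        assert f1_only
        refs = {k: (k[1], k[2]) for k in f1_only}
        assert all(v == ("C", "T") for v in refs.values())


class TestCoverageQC:
    def test_uniform_high_coverage_passes(self):
        t = make_table(
            [(i, "A", "C", f"K{i}Q",
              {"act": (10, 120000), "lof": (10, 120000)})
             for i in range(1, 10)]
        )
        qc = en.coverage_qc(t, mean_min=100000, per_position_min=40000)
        assert qc.passed

    def test_single_low_position_flagged(self):
        rows = [
            (i, "A", "C", f"K{i}Q", {"act": (10, 120000)})
            for i in range(1, 10)
        ]
        rows[3] = (4, "A", "C", "K4Q", {"act": (10, 39999)})
        t = make_table(rows, conditions=("act",))
        qc = en.coverage_qc(t, mean_min=100000, per_position_min=40000)
        assert not qc.passed
        assert qc.failing_positions["act"] == [4]

    def test_empty_table_invalid(self):
        t = en.VariantCountTable(
            pd.DataFrame(
                columns=["nt_pos", "ref", "alt", "protein_change",
                         "count_act", "cov_act"]
            ),
            ["act"],
        )
        qc = en.coverage_qc(t)
        assert not qc.valid
        assert not qc.passed
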