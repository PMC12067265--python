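"""Clonotype counting, trajectory calls, static splits, and V-gene usage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonotrack as ct
from clonotrack.config import InputError, ParseError, UndefinedStatisticError
from clonotrack.repertoire import (
    SampleRepertoire,
    dominant_chain_filter,
    usage_from_vector,
)


def _records(rows):
    base = {
        "cell_id": "c0", "sample_id": "s1", "patient_id": "p1",
        "timepoint": "pre", "locus": "IGH", "v_call": "IGHV01",
        "junction": "TGT", "junction_aa": "C", "duplicate_count": 1,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestCounting:
    def test_empty_record_list_reports_zero(self):
        counts = ct.count_unique_clonotypes(
            pd.DataFrame(), "BCR", samples=["s1", "s2"]
        )
        assert counts.tolist() == [0, 0]

    def test_five_records_three_keys(self):
        rows = [
            {"cell_id": "c1", "junction": "AAA"},
            {"cell_id": "c2", "junction": "AAA"},
            {"cell_id": "c3", "junction": "CCC"},
            {"cell_id": "c4", "junction": "GGG"},
            {"cell_id": "c5", "junction": "GGG"},
        ]
        counts = ct.count_unique_clonotypes(_records(rows), "BCR")
        assert counts["s1"] == 3

    def test_same_junction_different_locus_is_two_clonotypes(self):
        rows = [
            {"cell_id": "c1", "locus": "IGH", "junction": "AAA"},
            {"cell_id": "c2", "locus": "IGK", "junction": "AAA"},
        ]
        assert ct.count_unique_clonotypes(_records(rows), "BCR")["s1"] == 2

    def test_unknown_locus_raises_parse_error_naming_row(self):
        records = _records([{"cell_id": "c1", "locus": "XXX"}])
        with pytest.raises(ParseError, match="XXX"):
            ct.count_unique_clonotypes(records, "BCR")

    def test_receptor_classes_do_not_mix(self):
        rows = [
            {"cell_id": "c1", "locus": "TRA", "junction": "AAA"},
            {"cell_id": "c2", "locus": "IGH", "junction": "CCC"},
        ]
        records = _records(rows)
        assert ct.count_unique_clonotypes(records, "TCR")["s1"] == 1
        assert ct.count_unique_clonotypes(records, "BCR")["s1"] == 1

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.permutations(list(range(6))))
    def test_count_is_permutation_invariant(self, order):
        rows = [
            {"cell_id": f"c{i}", "junction": j}
            for i, j in enumerate(["AAA", "CCC", "AAA", "GGG", "TTT", "CCC"])
        ]
        records = _records(rows)
        shuffled = records.iloc[order].reset_index(drop=True)
        assert (
            ct.count_unique_clonotypes(records, "BCR")["s1"]
            == ct.count_unique_clonotypes(shuffled, "BCR")["s1"]
        )

    def test_count_is_monotone_under_record_addition(self):
        rows = [{"cell_id": f"c{i}", "junction": f"J{i}"} for i in range(5)]
        records = _records(rows)
        prev = 0
        for k in range(1, 6):
            cur = ct.count_unique_clonotypes(records.head(k), "BCR")["s1"]
            assert cur >= prev
            prev = cur


class TestDominantChainFilter:
    def test_keeps_highest_duplicate_count(self):
        rows = [
            {"cell_id": "c1", "junction": "AAA", "duplicate_count": 1},
            {"cell_id": "c1", "junction": "CCC", "duplicate_count": 5},
        ]
        kept = dominant_chain_filter(_records(rows))
        assert kept["junction"].tolist() == ["CCC"]

    def test_tie_breaks_lexicographically_by_junction(self):
        rows = [
            {"cell_id": "c1", "junction": "GGG", "duplicate_count": 2},
            {"cell_id": "c1", "junction": "AAA", "duplicate_count": 2},
        ]
        kept = dominant_chain_filter(_records(rows))
        assert kept["junction"].tolist() == ["AAA"]


class TestTrajectory:
    def _rep(self, pid, tp, bcr):
        return SampleRepertoire(f"{pid}_{tp}", pid, tp,
                                {"BCR": bcr, "TCR": 0}, bcr)

    @pytest.mark.parametrize(
        "pre, post, delta, increased",
        [(10, 15, 5, True), (12, 12, 0, False), (0, 1, 1, True), (9, 4, -5, False)],
    )
    def test_strict_increase_rule(self, pre, post, delta, increased):
        traj = ct.classify_trajectory(
            self._rep("p1", "pre", pre), self._rep("p1", "post", post), "BCR"
        )
        assert traj.delta == delta
        assert traj.increased is increased

    def test_patient_mismatch_rejected(self):
        with pytest.raises(InputError, match="patient"):
            ct.classify_trajectory(
                self._rep("p1", "pre", 5), self._rep("p2", "post", 9), "BCR"
            )

    def test_timepoint_mismatch_rejected(self):
        with pytest.raises(InputError, match="timepoint"):
            ct.classify_trajectory(
                self._rep("p1", "post", 5), self._rep("p1", "post", 9), "BCR"
            )


class TestStaticDiversity:
    def test_median_split(self):
        out = ct.classify_static_diversity(pd.Series({"a": 1, "b": 2, "c": 3}))
        assert out.tolist() == ["low", "low", "high"]

    def test_all_equal_counts_are_low(self):
        out = ct.classify_static_diversity(pd.Series([4, 4, 4, 4]))
        assert set(out) == {"low"}

    def test_even_count_median(self):
        out = ct.classify_static_diversity(pd.Series({"a": 0, "b": 0, "c": 5, "d": 10}))
        assert out.tolist() == ["low", "low", "high", "high"]

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            ct.classify_static_diversity(pd.Series([3]))


class TestVGeneUsage:
    UNIVERSE = ("IGHV01", "IGHV02", "IGHV03")

    def test_single_gene_support(self):
        rows = [{"cell_id": f"c{i}", "v_call": "IGHV02", "junction": f"J{i}"}
                for i in range(4)]
        usage = ct.vgene_usage(_records(rows), "s1", "IGH", self.UNIVERSE)
        assert usage.frequencies["IGHV02"] == 1.0
        assert usage.frequencies.drop("IGHV02").sum() == 0.0

    def test_empty_sample_flagged(self):
        records = _records([{"cell_id": "c1", "sample_id": "other"}])
        usage = ct.vgene_usage(records, "s1", "IGH", self.UNIVERSE)
        assert usage.empty
        assert usage.frequencies.sum() == 0.0

    def test_out_of_universe_bucketed_as_other_with_warning(self):
        rows = [
            {"cell_id": "c1", "v_call": "IGHV01", "junction": "AAA"},
            {"cell_id": "c2", "v_call": "IGHV99", "junction": "CCC"},
        ]
        with pytest.warns(UserWarning, match="other"):
            usage = ct.vgene_usage(_records(rows), "s1", "IGH", self.UNIVERSE)
        assert usage.frequencies["other"] == 0.5


class TestUsageCorrelation:
    def _usage(self, freqs, sample="s1", patient="p1", tp="pre"):
        return usage_from_vector(sample, "IGH", pd.Series(freqs),
                                 patient_id=patient, timepoint=tp)

    def test_identity_gives_one(self):
        a = self._usage({"IGHV01": 3, "IGHV02": 2, "IGHV03": 1})
        res = ct.usage_correlation(a, a)
        assert res.correlation == pytest.approx(1.0)
        assert res.matched

    def test_reversed_ranks_give_minus_one(self):
        a = self._usage({f"IGHV{i:02d}": w for i, w in enumerate([5, 4, 3, 2, 1], 1)})
        b = self._usage({f"IGHV{i:02d}": w for i, w in enumerate([1, 2, 3, 4, 5], 1)},
                        patient="p2")
        res = ct.usage_correlation(a, b)
        assert res.correlation == pytest.approx(-1.0)
        assert not res.matched

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = self._usage(dict(zip([f"IGHV{i:02d}" for i in range(8)], rng.random(8))))
        b = self._usage(dict(zip([f"IGHV{i:02d}" for i in range(8)], rng.random(8))),
                        patient="p2")
        assert ct.usage_correlation(a, b).correlation == pytest.approx(
            ct.usage_correlation(b, a).correlation
        )

    def test_tiny_support_rejected(self):
        a = self._usage({"IGHV01": 1, "IGHV02": 1})
        with pytest.raises(UndefinedStatisticError):
            ct.usage_correlation(a, a)

    def test_matched_pairs_beat_mismatched_in_one_cohort(self, small_cohort,
                                                         small_config):
        # scRNA-derived vs spatial-probe-derived IGH usage: matched
        # patient-timepoint pairs should out-correlate mismatched ones
        universe = small_config.vgene_universe("IGH")
        matched, mismatched = [], []
        for smp in small_cohort.spatial_samples:
            if smp.compartment != "tumor":
                continue
            probe = usage_from_vector(
                smp.sample_id, "IGH",
                smp.cells[list(universe)].sum(axis=0),
                patient_id=smp.patient_id, timepoint=smp.timepoint,
            )
            for pid in small_cohort.truth["patients"]:
                for tp in ("pre", "post"):
                    sc = ct.vgene_usage(
                        small_cohort.clonotypes, f"{pid}_{tp}", "IGH", universe
                    )
                    if sc.empty:
                        continue
                    res = ct.usage_correlation(probe, sc)
                    (matched if (pid == smp.patient_id and tp == smp.timepoint)
                     else mismatched).append(res.correlation)
        assert np.mean(matched) > np.mean(mismatched)
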