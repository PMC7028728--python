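"""Majority consensus over partitions and barcoding-gap analytics."""

import math

import numpy as np
import pytest

from barcodelim.consensus import (
    consensus_partition,
    gap_stats,
    otus_per_species_counts,
    species_otu_table,
)
from barcodelim.partition import Partition

from .conftest import make_matrix


def part(assignment, method="m"):
    return Partition(method=method, assignment=dict(assignment))


class TestConsensus:
    def test_two_thirds_majority_pairs_kept(self):
        p1 = part({"A": "1", "B": "1", "C": "2"})
        p2 = part({"A": "1", "B": "1", "C": "2"})
        p3 = part({"A": "1", "B": "2", "C": "3"})
        result = consensus_partition([p1, p2, p3], quorum=0.5)
        assert result.consensus.same_otu("A", "B")
        assert not result.consensus.same_otu("A", "C")
        assert result.n_otus == 2
        i, j = result.ids.index("A"), result.ids.index("B")
        assert result.co_assignment[i, j] == pytest.approx(2 / 3)

    def test_identical_inputs_reproduced(self):
        p = part({"A": "x", "B": "x", "C": "y", "D": "z"})
        result = consensus_partition([p, part(p.assignment), part(p.assignment)])
        assert result.consensus.groups() == p.relabeled().groups()

    def test_transitive_chain_merges_with_warning(self):
        p1 = part({"A": "1", "B": "1", "C": "2"})
        p2 = part({"A": "1", "B": "2", "C": "2"})
        result = consensus_partition([p1, p2], quorum=0.5)
        assert result.n_otus == 1  # A-B and B-C at quorum, A-C below
        assert result.transitive_components == ["A"]

    def test_single_input_is_identity(self):
        p = part({"A": "1", "B": "1", "C": "2"})
        result = consensus_partition([p])
        assert result.consensus.groups() == p.relabeled().groups()

    def test_mismatched_id_sets_rejected(self):
        with pytest.raises(ValueError, match="different id set"):
            consensus_partition([part({"A": "1"}), part({"B": "1"})])

    def test_full_quorum_refines_all_inputs(self):
        rng = np.random.default_rng(0)
        ids = [f"r{i}" for i in range(12)]
        parts = [
            part({rid: str(rng.integers(0, 4)) for rid in ids}) for _ in range(5)
        ]
        result = consensus_partition(parts, quorum=1.0)
        for p in parts:
            for a in ids:
                for b in ids:
                    if result.consensus.same_otu(a, b) and a < b:
                        if result.transitive_components:
                            continue  # chained merges are logged, not forbidden
                        assert p.same_otu(a, b)

    def test_count_bounds_on_random_ensembles(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ids = [f"r{i}" for i in range(10)]
            parts = [
                part({rid: str(rng.integers(0, 5)) for rid in ids})
                for _ in range(rng.integers(2, 6))
            ]
            result = consensus_partition(parts)
            assert 1 <= result.n_otus <= len(ids)


class TestGapStats:
    def block(self):
        # two groups of two: intra 0.01, inter 0.05
        d = np.array(
            [
                [0, 0.01, 0.05, 0.05],
                [0.01, 0, 0.05, 0.05],
                [0.05, 0.05, 0, 0.01],
                [0.05, 0.05, 0.01, 0],
            ]
        )
        return make_matrix(["A1", "A2", "B1", "B2"], d)

    def labels(self):
        return {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}

    def test_ratio_of_means_exact(self):
        g = gap_stats(self.block(), self.labels(), level="species")
        assert g.ratio_of_means == pytest.approx(5.0, abs=1e-9)
        assert g.mean_of_ratios == pytest.approx(5.0, abs=1e-9)
        assert not g.overlap_exists

    def test_overlap_detected_when_intra_exceeds_nn(self):
        d = np.array(
            [
                [0, 0.06, 0.02, 0.03],
                [0.06, 0, 0.03, 0.02],
                [0.02, 0.03, 0, 0.01],
                [0.03, 0.02, 0.01, 0],
            ]
        )
        m = make_matrix(["A1", "A2", "B1", "B2"], d)
        g = gap_stats(m, self.labels(), level="species")
        assert g.overlap_exists

    def test_singletons_excluded_from_intra_mean(self):
        d = np.array(
            [
                [0, 0.01, 0.05, 0.07],
                [0.01, 0, 0.05, 0.07],
                [0.05, 0.05, 0, 0.07],
                [0.07, 0.07, 0.07, 0],
            ]
        )
        m = make_matrix(["A1", "A2", "B1", "C1"], d)
        g = gap_stats(m, {"A1": "A", "A2": "A", "B1": "B", "C1": "C"}, level="species")
        # intra mean over non-singletons = 0.01; nn mean over all three groups
        assert g.ratio_of_means == pytest.approx((0.05 + 0.05 + 0.07) / 3 / 0.01)

    def test_histogram_uses_percent_bins(self):
        g = gap_stats(self.block(), self.labels(), level="otu")
        hist = g.histogram
        assert (hist["bin_high_pct"] - hist["bin_low_pct"]).iloc[0] == pytest.approx(1.0)
        assert hist["nn_count"].sum() == 2  # one NN value per group


class TestSpeciesOtuTable:
    def setup_case(self):
        # species S split into two OTUs; species T cohesive
        d = np.array(
            [
                [0, 0.002, 0.060, 0.060, 0.100, 0.100],
                [0.002, 0, 0.060, 0.060, 0.100, 0.100],
                [0.060, 0.060, 0, 0.002, 0.100, 0.100],
                [0.060, 0.060, 0.002, 0, 0.100, 0.100],
                [0.100, 0.100, 0.100, 0.100, 0, 0.002],
                [0.100, 0.100, 0.100, 0.100, 0.002, 0],
            ]
        )
        ids = ["s1", "s2", "s3", "s4", "t1", "t2"]
        m = make_matrix(ids, d)
        species = {i: ("S" if i.startswith("s") else "T") for i in ids}
        consensus = part(
            {"s1": "o1", "s2": "o1", "s3": "o2", "s4": "o2", "t1": "o3", "t2": "o3"}
        )
        return m, species, consensus

    def test_only_split_species_reported(self):
        m, species, consensus = self.setup_case()
        table = species_otu_table(consensus, species, m)
        assert set(table["species"]) == {"S"}
        assert (table["otu"] == "").sum() == 1  # one species header row
        assert len(table[table["otu"] != ""]) == 2  # two OTU sub-rows

    def test_singleton_otu_gets_nan_intra(self):
        m, species, consensus = self.setup_case()
        consensus = part(
            {"s1": "o1", "s2": "o1", "s3": "o2", "s4": "o4", "t1": "o3", "t2": "o3"}
        )
        table = species_otu_table(consensus, species, m)
        sub = table[(table["species"] == "S") & (table["otu"] == "o4")]
        assert math.isnan(sub["max_intra_pct"].iloc[0])

    def test_otus_per_species_counts(self):
        _, species, consensus = self.setup_case()
        counts = otus_per_species_counts(consensus, species)
        assert counts.to_dict() == {1: 1, 2: 1}
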