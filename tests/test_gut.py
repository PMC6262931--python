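"""OTU clustering, pairwise divergence and diet summaries."""

import numpy as np
import pytest

from copelink.gut import (
    CloneSequence,
    cluster_otus,
    diet_summary,
    pairwise_divergence,
    read_clone_fasta,
    write_clone_fasta,
)
from copelink.synthetic import SyntheticCloneSpec, generate_clone_library
from tests.conftest import incidence_matches


def _rand_seq(rng, n=200):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPairwiseDivergence:
    def test_identical_sequences(self):
        assert pairwise_divergence("ACGT" * 50, "ACGT" * 50) == 0.0

    def test_single_substitution_in_200bp(self):
        a = "A" * 100 + "C" * 100
        b = "A" * 99 + "G" + "C" * 100
        assert pairwise_divergence(a, b) == pytest.approx(1 / 200)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = _rand_seq(rng), _rand_seq(rng)
        assert pairwise_divergence(a, b) == pytest.approx(pairwise_divergence(b, a))

    def test_equals_hamming_on_indel_free_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = list(_rand_seq(rng))
            b = a.copy()
            sites = rng.choice(200, size=6, replace=False)
            for i in sites:
                b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
            hamming = sum(x != y for x, y in zip(a, b)) / 200
            assert pairwise_divergence("".join(a), "".join(b)) == pytest.approx(hamming)

    def test_gap_columns_count_as_differences(self):
        # one internal deletion: 1 gap column over 200 alignment columns
        a = "ACGT" * 50
        b = a[:100] + a[101:]
        assert pairwise_divergence(a, b) == pytest.approx(1 / 200)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_divergence("", "ACGT")


class TestClustering:
    def test_all_identical_clones_form_one_otu(self):
        seq = "ACGT" * 50
        clones = [CloneSequence("cop1", f"clone{i}", seq) for i in range(5)]
        result = cluster_otus(clones)
        assert result.n_otus == 1
        assert (result.incidence.values == [[5]]).all()

    def test_planted_four_otus_recovered(self):
        spec = SyntheticCloneSpec(
            n_copepods=8, n_otus=4, within_otu_divergence=0.0,
            between_otu_divergence=0.10, seed=3,
        )
        clones, planted = generate_clone_library(spec)
        result = cluster_otus(clones, threshold=0.01)
        assert result.n_otus == int((planted.sum(axis=0) > 0).sum())
        assert incidence_matches(result.incidence, planted)

    def test_threshold_zero_one_otu_per_unique_sequence(self):
        rng = np.random.default_rng(2)
        seqs = [_rand_seq(rng) for _ in range(4)]
        clones = [CloneSequence("cop1", f"c{i}", s) for i, s in enumerate(seqs + seqs)]
        result = cluster_otus(clones, threshold=1e-9)
        assert result.n_otus == 4

    def test_threshold_one_merges_everything(self):
        rng = np.random.default_rng(3)
        clones = [CloneSequence("cop1", f"c{i}", _rand_seq(rng)) for i in range(6)]
        assert cluster_otus(clones, threshold=1.0).n_otus == 1

    def test_otu_count_non_increasing_in_threshold(self):
        spec = SyntheticCloneSpec(
            n_copepods=6, n_otus=4, within_otu_divergence=0.004,
            between_otu_divergence=0.06, seed=4,
        )
        clones, _ = generate_clone_library(spec)
        counts = [
            cluster_otus(clones, threshold=t).n_otus
            for t in (0.001, 0.01, 0.05, 0.2, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_members_within_threshold_of_representative(self):
        spec = SyntheticCloneSpec(
            n_copepods=6, n_otus=3, within_otu_divergence=0.008,
            between_otu_divergence=0.09, seed=5,
        )
        clones, _ = generate_clone_library(spec)
        result = cluster_otus(clones, threshold=0.01)
        for clone in clones:
            rep = result.representatives[result.otu_assignments[clone.key]]
            assert pairwise_divergence(clone.sequence, rep) < 0.01

    def test_single_linkage_chains_clusters(self):
        # A-B and B-C are each under the threshold, A-C is not: single
        # linkage merges all three, centroid keeps the founder rule.
        base = list("ACGT" * 50)
        b = base.copy(); b[0] = "C"
        c = base.copy(); c[0] = "C"; c[4] = "T"
        clones = [
            CloneSequence("cop1", "a", "".join(base)),
            CloneSequence("cop1", "b", "".join(b)),
            CloneSequence("cop1", "c", "".join(c)),
        ]
        assert cluster_otus(clones, threshold=0.0075, linkage="single").n_otus == 1
        assert cluster_otus(clones, threshold=0.0075, linkage="centroid").n_otus == 2

    def test_incidence_row_sums_equal_clones_per_copepod(self):
        spec = SyntheticCloneSpec(n_copepods=5, n_otus=3, seed=6)
        clones, _ = generate_clone_library(spec)
        result = cluster_otus(clones, threshold=0.01)
        assert (result.incidence.sum(axis=1) == spec.clones_per_copepod).all()

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="at least one clone"):
            cluster_otus([])


class TestDietSummary:
    def test_reference_matrix_condition_counts(self, reference_diet):
        incidence, cond_map, taxonomy = reference_diet
        diet = diet_summary(incidence, cond_map, taxonomy)
        assert diet.n_otus_total == 16
        assert diet.otus_per_condition == {"downwelling": 7, "upwelling": 12}
        assert diet.otus_per_phylum == {"Crustacea": 13, "Mollusca": 2, "Chordata": 1}

    def test_reference_matrix_richness_range_and_stats(self, reference_diet):
        incidence, cond_map, taxonomy = reference_diet
        diet = diet_summary(incidence, cond_map, taxonomy)
        assert diet.richness_per_copepod.between(1, 4).all()
        stats = diet.richness_stats
        assert stats.loc["downwelling", "mean"] == pytest.approx(1.857, abs=0.001)
        assert stats.loc["downwelling", "sd"] == pytest.approx(0.690, abs=0.001)
        assert stats.loc["upwelling", "mean"] == pytest.approx(2.0)
        assert stats.loc["upwelling", "sd"] == pytest.approx(1.155, abs=0.001)

    def test_identical_richness_vectors_give_p_one(self):
        import pandas as pd

        incidence = pd.DataFrame(
            {"o1": [1, 1, 1, 1], "o2": [2, 2, 2, 2]},
            index=["a", "b", "c", "d"],
        )
        cond = {"a": "downwelling", "b": "downwelling", "c": "upwelling", "d": "upwelling"}
        diet = diet_summary(incidence, cond)
        assert diet.p_value == pytest.approx(1.0)

    def test_missing_condition_errors(self, reference_diet):
        incidence, cond_map, _ = reference_diet
        partial = {k: v for k, v in cond_map.items() if k != "C5"}
        with pytest.raises(ValueError, match="C5"):
            diet_summary(incidence, partial)


def test_fasta_round_trip(tmp_path):
    spec = SyntheticCloneSpec(n_copepods=3, n_otus=2, seed=7)
    clones, _ = generate_clone_library(spec)
    path = tmp_path / "clones.fasta"
    write_clone_fasta(clones, path)
    back = read_clone_fasta(path)
    assert [(c.copepod_id, c.clone_id, c.sequence) for c in back] == [
        (c.copepod_id, c.clone_id, c.sequence) for c in clones
    ]
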