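"""Consensus calling, breadth filter, GTR distances, clusters, engraftment."""

import math

import numpy as np
import pandas as pd
import pytest

from microcat import (
    ConsensusGenotype,
    breadth_filter,
    call_site,
    distance_matrix,
    engraftment_rate,
    pairwise_mutation_rate,
    strain_clusters,
)
from microcat.strains import DistanceResult, consensus_from_counts


def genotype(sample, seqs, msp="mspX", breadth=1.0, passed=True):
    return ConsensusGenotype(
        sample_id=sample,
        msp_id=msp,
        sequences=dict(seqs),
        breadth={g: breadth for g in seqs},
        passed_filter=passed,
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq, rate, rng):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestSiteCalling:
    def test_low_depth_masked(self):
        assert call_site({"A": 2}, "A") == "N"
        assert call_site({"A": 1, "G": 1}, "A") == "N"

    def test_minority_allele_encoded_as_iupac(self):
        assert call_site({"A": 9, "G": 1}, "A", f=0.1) == "R"

    def test_dominant_configuration_keeps_major_allele(self):
        assert call_site({"A": 9, "G": 1}, "A", f=0.5) == "A"

    def test_dominant_tie_gives_iupac_of_tied_set(self):
        assert call_site({"A": 5, "G": 5}, "A", f=0.5) == "R"
        assert call_site({"A": 5, "G": 5}, "C", f=0.5) == "R"

    def test_unsupported_reference_dropped(self):
        assert call_site({"G": 10}, "A", f=0.1) == "G"

    def test_fallback_to_majority_when_no_allele_qualifies(self):
        # reference unsupported and no alternate reaches f=0.9
        assert call_site({"A": 6, "G": 4}, "C", f=0.9) == "A"

    def test_three_way_ambiguity(self):
        assert call_site({"A": 4, "C": 3, "G": 3}, "A", f=0.1) == "V"

    def test_consensus_from_counts_and_breadth(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [10, 0, 0, 0]  # A
        counts[1] = [1, 0, 9, 0]  # A/G minority -> R
        counts[2] = [0, 2, 0, 0]  # depth 2 -> N
        counts[3] = [0, 0, 0, 5]  # T
        seq, breadth = consensus_from_counts(counts, "AAGT", f=0.1, min_depth=3)
        assert seq == "ARNT"
        assert breadth == pytest.approx(3 / 4)

    def test_masking_monotone_in_min_depth(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(50, 4))
        n_masked = []
        for md in [1, 3, 5, 8]:
            seq, _ = consensus_from_counts(counts, "A" * 50, min_depth=md)
            n_masked.append(seq.count("N"))
        assert n_masked == sorted(n_masked)


class TestBreadthFilter:
    def make(self, n_ok, n_total):
        breadth = {f"g{i}": 0.6 if i < n_ok else 0.2 for i in range(n_total)}
        g = ConsensusGenotype("s", "m", {k: "A" for k in breadth}, breadth)
        return g

    def test_80_of_100_boundary(self):
        assert breadth_filter(self.make(80, 100)) is True
        assert breadth_filter(self.make(79, 100)) is False

    def test_scaled_requirement_for_small_msp(self):
        assert breadth_filter(self.make(41, 50)) is True
        assert breadth_filter(self.make(40, 50)) is True
        assert breadth_filter(self.make(39, 50)) is False


class TestPairwiseDistance:
    def test_identical_sequences_give_exact_zero(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 500)
        a = genotype("a", {"g1": seq})
        b = genotype("b", {"g1": seq})
        res = pairwise_mutation_rate(a, b)
        assert res.mutation_rate == 0.0
        assert res.informative_sites == 500

    def test_too_few_informative_sites_is_missing(self):
        a = genotype("a", {"g1": "ACGTACGTA" + "N"})
        b = genotype("b", {"g1": "ACGTACGTA" + "N"})
        res = pairwise_mutation_rate(a, b, min_informative=10)
        assert res.informative_sites == 9
        assert res.mutation_rate is None
        assert res.reason == "insufficient_informative_sites"

    def test_n_masks_excluded_from_informative(self):
        a = genotype("a", {"g1": "ANGT" * 10})
        b = genotype("b", {"g1": "ACNT" * 10})
        res = pairwise_mutation_rate(a, b)
        assert res.informative_sites == 20  # positions where both are non-N

    def test_jc69_recovery_at_5pct(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 50_000)
        mutated = mutate(seq, 0.05, rng)
        res = pairwise_mutation_rate(genotype("a", {"g": seq}), genotype("b", {"g": mutated}))
        p_hat = sum(x != y for x, y in zip(seq, mutated)) / len(seq)
        jc = -0.75 * math.log(1 - 4 * p_hat / 3)
        assert res.mutation_rate == pytest.approx(0.05, abs=0.01)
        assert res.mutation_rate == pytest.approx(jc, abs=1e-3)

    @pytest.mark.parametrize("p", [0.001, 0.005, 0.01, 0.03])
    def test_distance_recovery_and_monotonicity(self, p):
        rng = np.random.default_rng(int(p * 1e5))
        genes = {f"g{i}": random_seq(rng, 1000) for i in range(20)}
        mut = {g: mutate(s, p, rng) for g, s in genes.items()}
        res = pairwise_mutation_rate(genotype("a", genes), genotype("b", mut))
        assert res.mutation_rate == pytest.approx(p, rel=0.2)

    def test_ambiguity_counted_fractionally(self):
        # 100 matched sites of all four bases, plus one site that is A in
        # one sample and either R (= A/G mixture, half mismatch weight) or
        # G (full substitution) in the other
        base = "ACGT" * 25 + "A"
        res_amb = pairwise_mutation_rate(
            genotype("a", {"g": base}), genotype("b", {"g": base[:-1] + "R"})
        )
        res_full = pairwise_mutation_rate(
            genotype("a", {"g": base}), genotype("b", {"g": base[:-1] + "G"})
        )
        assert 0 < res_amb.mutation_rate < res_full.mutation_rate

    def test_mismatched_msp_rejected(self):
        from microcat.strains import StrainError

        with pytest.raises(StrainError):
            pairwise_mutation_rate(
                genotype("a", {"g": "ACGT"}, msp="m1"),
                genotype("b", {"g": "ACGT"}, msp="m2"),
            )


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 2000)
        genos = {
            s: genotype(s, {"g": mutate(seq, d, rng)})
            for s, d in [("s1", 0.0), ("s2", 0.01), ("s3", 0.02)]
        }
        mat, results = distance_matrix(genos)
        assert len(results) == 3
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 1000)
        genos = {
            s: genotype(s, {"g": mutate(seq, d, rng)})
            for s, d in [("s1", 0.0), ("s2", 0.01), ("s3", 0.03)]
        }
        mat1, _ = distance_matrix(genos)
        mat2, _ = distance_matrix(dict(reversed(list(genos.items()))))
        pd.testing.assert_frame_equal(mat1, mat2)

    def test_fewer_than_two_passing_samples(self):
        genos = {"s1": genotype("s1", {"g": "ACGT"}), "s2": genotype("s2", {"g": "ACGT"}, passed=False)}
        mat, results = distance_matrix(genos)
        assert mat.empty and results == []


class TestClustering:
    def two_group_matrix(self):
        samples = ["a1", "a2", "a3", "b1", "b2"]
        mat = pd.DataFrame(0.02, index=samples, columns=samples)
        for grp in (["a1", "a2", "a3"], ["b1", "b2"]):
            for x in grp:
                for y in grp:
                    mat.loc[x, y] = 1e-4 if x != y else 0.0
        return mat

    def test_two_planted_clusters_recovered(self):
        labels, unclustered = strain_clusters(self.two_group_matrix(), cutoff=5e-3)
        assert unclustered == []
        assert len(set(labels.values())) == 2
        assert labels["a1"] == labels["a2"] == labels["a3"]
        assert labels["b1"] == labels["b2"] != labels["a1"]

    def test_cutoff_above_max_merges_all(self):
        labels, _ = strain_clusters(self.two_group_matrix(), cutoff=1.0)
        assert len(set(labels.values())) == 1

    def test_zero_cutoff_gives_singletons(self):
        labels, _ = strain_clusters(self.two_group_matrix(), cutoff=0.0)
        assert len(set(labels.values())) == 5

    def test_samples_with_missing_distances_reported_unclustered(self):
        mat = self.two_group_matrix()
        mat.loc["a1", "b1"] = np.nan
        mat.loc["b1", "a1"] = np.nan
        labels, unclustered = strain_clusters(mat, cutoff=5e-3)
        assert len(unclustered) == 1
        assert set(labels) | set(unclustered) == set(mat.index)


class TestEngraftment:
    def result(self, msp, a, b, rate):
        return DistanceResult(msp, a, b, 1000, rate)

    def test_fraction_of_identical_pairs(self):
        distances = [
            self.result(f"m{i}", "donor", "recipient", 0.0 if i < 3 else 0.01)
            for i in range(10)
        ]
        rate = engraftment_rate(distances, [("donor", "recipient")])
        assert rate == pytest.approx(0.3)

    def test_no_shared_species_is_missing(self):
        assert engraftment_rate([], [("donor", "recipient")]) is None

    def test_missing_rates_excluded_from_denominator(self):
        distances = [
            self.result("m1", "d", "r", 0.0),
            DistanceResult("m2", "d", "r", 4, None, "insufficient_informative_sites"),
        ]
        assert engraftment_rate(distances, [("d", "r")]) == pytest.approx(1.0)

    def test_constructed_cohort_rate_is_k_over_m(self):
        rng = np.random.default_rng(9)
        m, k = 5, 3
        donor_seqs = {f"m{i}": random_seq(rng, 3000) for i in range(m)}
        donor = {f"m{i}": genotype("d", {"g": donor_seqs[f"m{i}"]}, msp=f"m{i}") for i in range(m)}
        recip = {}
        for i in range(m):
            seq = donor_seqs[f"m{i}"] if i < k else mutate(donor_seqs[f"m{i}"], 0.01, rng)
            recip[f"m{i}"] = genotype("r", {"g": seq}, msp=f"m{i}")
        distances = [
            pairwise_mutation_rate(donor[f"m{i}"], recip[f"m{i}"]) for i in range(m)
        ]
        assert engraftment_rate(distances, [("d", "r")]) == pytest.approx(k / m)
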