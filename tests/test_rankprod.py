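import itertools

import numpy as np
import pandas as pd
import pytest

from varrank.datamodel import GeneSizeTable, Group
from varrank.errors import ConfigurationError, ValidationError
from varrank.rankprod import (
    GeneRankTable,
    SimulatedExperiment,
    bootstrap_experiments,
    filter_protein_altering,
    gene_aggregate,
    odds_estimator,
    rank_genes,
    rank_product_two_class,
)
from varrank.synthetic import SimulationSpec, VariantSpec, simulate_cohort
from varrank.adjust import adjust_pipeline

from conftest import make_matrix


def _record(subtype=None, functional_class="exonic", alt_af=0.1, imputed=False, pos=1):
    from varrank.datamodel import VariantKey, VariantRecord

    return VariantRecord(
        key=VariantKey("chr1", pos, "A", "G"),
        gene="GENE",
        functional_class=functional_class,
        exonic_subtype=subtype,
        alt_af=alt_af,
        maf_imputed=imputed,
    )


class TestFilterProteinAltering:
    def test_synonymous_excluded(self):
        assert filter_protein_altering([_record("synonymous")]) == []

    def test_frameshift_included(self):
        recs = [_record("frameshift")]
        assert filter_protein_altering(recs) == recs

    @pytest.mark.parametrize("subtype", ["non-synonymous", "non-frameshift", "stop-gain", "stop-loss"])
    def test_protein_altering_subtypes_included(self, subtype):
        assert len(filter_protein_altering([_record(subtype)])) == 1

    def test_non_exonic_excluded(self):
        assert filter_protein_altering([_record(None, functional_class="intronic")]) == []

    def test_exonic_splicing_included(self):
        assert len(filter_protein_altering([_record("non-synonymous", "exonic_splicing")])) == 1

    def test_exonic_without_subtype_rejected(self):
        with pytest.raises(ValidationError):
            filter_protein_altering([_record(None, "exonic")])

    def test_mode_all_keeps_everything(self):
        recs = [_record("synonymous", pos=1), _record(None, "intronic", pos=2)]
        assert filter_protein_altering(recs, mode="all") == recs

    def test_mode_with_altaf_only(self):
        recs = [
            _record("synonymous", alt_af=0.1, pos=1),
            _record("synonymous", alt_af=0.002, imputed=True, pos=2),
        ]
        kept = filter_protein_altering(recs, mode="with-altaf-only")
        assert [r.key.pos for r in kept] == [1]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_protein_altering([], mode="bogus")


class TestBootstrapExperiments:
    def _matrix(self, seed=0, n=12, n_var=6):
        rng = np.random.default_rng(seed)
        dosages = rng.binomial(2, 0.2, size=(n_var, 2 * n))
        return make_matrix(dosages, groups=[Group.SENSITIVE] * n + [Group.RESISTANT] * n)

    def test_resample_shape(self):
        matrix = self._matrix()
        exps = bootstrap_experiments(matrix, Group.RESISTANT, n_experiments=4, k=50, seed=1)
        assert len(exps) == 4
        for frame in exps:
            assert frame.shape == (6, 50)
            assert ((frame.to_numpy() >= 0) & (frame.to_numpy() <= 1)).all()

    def test_same_seed_reproducible(self):
        matrix = self._matrix()
        a = bootstrap_experiments(matrix, Group.SENSITIVE, k=30, seed=7)
        b = bootstrap_experiments(matrix, Group.SENSITIVE, k=30, seed=7)
        for fa, fb in zip(a, b):
            assert fa.equals(fb)

    def test_experiments_differ(self):
        matrix = self._matrix()
        a, b = bootstrap_experiments(matrix, Group.SENSITIVE, n_experiments=2, k=30, seed=7)
        assert not a.equals(b)

    def test_mean_within_three_se_of_observed(self):
        # binomial standard-error oracle for the bootstrap mean of the VAF
        matrix = self._matrix(seed=3)
        n = 12
        k = 999
        (frame,) = bootstrap_experiments(matrix, Group.RESISTANT, n_experiments=1, k=k, seed=5)
        observed = matrix.group_dosages(Group.RESISTANT).sum(axis=1) / (2 * n)
        for i, key in enumerate(matrix.variant_keys):
            q = observed[i]
            se_mean = np.sqrt(q * (1 - q) / (2 * n)) / np.sqrt(k)
            if q in (0.0, 1.0):
                continue
            assert abs(frame.loc[key].mean() - q) <= 3 * se_mean + 1e-12

    def test_too_small_group_rejected(self):
        matrix = make_matrix([[0, 1]], groups=[Group.SENSITIVE, Group.RESISTANT])
        with pytest.raises(ConfigurationError):
            bootstrap_experiments(matrix, Group.SENSITIVE)


class TestGeneAggregate:
    def test_mean(self):
        vafs = pd.DataFrame({"r0": [0.2, 0.4]}, index=["v1", "v2"])
        out = gene_aggregate(vafs, {"v1": "A", "v2": "A"}, method="mean")
        assert out.loc["A", "r0"] == pytest.approx(0.3)

    def test_sum_over_size(self):
        vafs = pd.DataFrame({"r0": [0.2, 0.4]}, index=["v1", "v2"])
        sizes = GeneSizeTable({"A": 1000})
        out = gene_aggregate(vafs, {"v1": "A", "v2": "A"}, method="sum_over_size", sizes=sizes)
        assert out.loc["A", "r0"] == pytest.approx(0.0006)

    def test_single_variant_identity(self):
        vafs = pd.DataFrame({"r0": [0.37]}, index=["v1"])
        out = gene_aggregate(vafs, {"v1": "A"}, method="mean")
        assert out.loc["A", "r0"] == pytest.approx(0.37)

    def test_missing_size_rejected(self):
        vafs = pd.DataFrame({"r0": [0.2]}, index=["v1"])
        with pytest.raises(ConfigurationError):
            gene_aggregate(vafs, {"v1": "A"}, method="sum_over_size", sizes=GeneSizeTable({"B": 10}))

    def test_unmapped_variant_rejected(self):
        vafs = pd.DataFrame({"r0": [0.2]}, index=["v1"])
        with pytest.raises(ConfigurationError):
            gene_aggregate(vafs, {}, method="mean")


class TestOddsEstimator:
    def test_null_case_one(self):
        assert odds_estimator([0.2] * 5, 0.2, n_samples=12) == pytest.approx(1.0)

    def test_single_resample_arithmetic(self):
        # (0.2 * 0.99) / (0.01 * 0.8) = 24.75
        assert odds_estimator([0.2], 0.01, n_samples=12) == pytest.approx(24.75)

    def test_zero_resamples_guarded(self):
        p = 0.1
        n = 12
        eps = 1 / (2 * n + 1)
        expected = eps * (1 - p) / (p * (1 - eps))
        value = odds_estimator([0.0] * 10, p, n_samples=n)
        assert value == pytest.approx(expected)
        assert value > 0

    def test_p_floored(self):
        lo = odds_estimator([0.2], 0.0, n_samples=12, p_floor=1 / 503)
        ref = odds_estimator([0.2], 1 / 503, n_samples=12, p_floor=1 / 503)
        assert lo == pytest.approx(ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            odds_estimator([], 0.1, n_samples=12)


def plain_ranks(values):
    """Average-tie ascending ranks, written independently of scipy."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def oracle_per_class(odds1, odds2):
    """Brute-force two-class rank product with exhaustive per-class permutations."""
    G = odds1.shape[0]

    def rp_of(o1, o2):
        cols = []
        for a in range(o1.shape[1]):
            for b in range(o2.shape[1]):
                cols.append(plain_ranks(o1[:, a] / o2[:, b]))
        return np.exp(np.mean(np.log(np.column_stack(cols)), axis=1))

    rp_obs = rp_of(odds1, odds2)
    counts = np.zeros(G)
    n_null = 0
    for p1 in itertools.permutations(range(G)):
        for p2 in itertools.permutations(range(G)):
            rp_null = rp_of(odds1[list(p1)], odds2[list(p2)])
            n_null += 1
            for g in range(G):
                counts[g] += (rp_null <= rp_obs[g] + 1e-12).sum()
    return rp_obs, counts / (n_null * G)


def toy_experiments():
    odds1 = np.array([[1.0], [2.0], [6.0]])
    odds2 = np.array([[4.0, 5.0], [3.5, 2.5], [1.2, 1.1]])
    genes = pd.Index(["g1", "g2", "g3"])
    class1 = [SimulatedExperiment(Group.SENSITIVE, pd.Series(odds1[:, 0], index=genes), k=9)]
    class2 = [
        SimulatedExperiment(Group.RESISTANT, pd.Series(odds2[:, j], index=genes), k=9)
        for j in range(2)
    ]
    return odds1, odds2, class1, class2


class TestRankProductTwoClass:
    def test_matches_exhaustive_enumeration_oracle(self):
        odds1, odds2, class1, class2 = toy_experiments()
        table = rank_product_two_class(class1, class2, exhaustive=True)
        rp_expected, p_expected = oracle_per_class(odds1, odds2)
        frame = table.data.set_index("gene")
        for g, rp, p in zip(["g1", "g2", "g3"], rp_expected, p_expected):
            assert frame.loc[g, "rp_rsum"] == pytest.approx(rp, abs=1e-12)
            assert frame.loc[g, "p_value"] == pytest.approx(p, abs=1e-12)

    def test_smallest_fc_everywhere_is_rank_one_rp_one(self):
        odds1, odds2, class1, class2 = toy_experiments()
        frame = rank_product_two_class(class1, class2, exhaustive=True).data
        top = frame.iloc[0]
        assert top["gene"] == "g1"  # smallest FC in both pairings
        assert top["rank"] == 1
        assert top["rp_rsum"] == pytest.approx(1.0)

    def test_all_identical_ties_at_middle(self):
        genes = pd.Index(["a", "b", "c"])
        same = pd.Series([2.0, 2.0, 2.0], index=genes)
        class1 = [SimulatedExperiment(Group.SENSITIVE, same, k=9)]
        class2 = [SimulatedExperiment(Group.RESISTANT, same, k=9)]
        frame = rank_product_two_class(class1, class2, n_permutations=10, seed=0).data
        assert np.allclose(frame["rp_rsum"], 2.0)  # (G + 1) / 2

    def test_pfp_is_p_times_g_over_rank(self):
        odds1, odds2, class1, class2 = toy_experiments()
        frame = rank_product_two_class(class1, class2, n_permutations=200, seed=3).data
        G = len(frame)
        assert np.allclose(frame["pfp"], frame["p_value"] * G / frame["rank"])

    def test_invariant_under_experiment_relabeling(self):
        odds1, odds2, class1, class2 = toy_experiments()
        a = rank_product_two_class(class1, class2, n_permutations=50, seed=1)
        b = rank_product_two_class(class1, class2[::-1], n_permutations=50, seed=1)
        assert list(a.data["gene"]) == list(b.data["gene"])
        assert np.allclose(a.data["rp_rsum"], b.data["rp_rsum"])

    def test_direction_flag_reverses_ranking(self):
        odds1, odds2, class1, class2 = toy_experiments()
        res = rank_product_two_class(class1, class2, n_permutations=20, seed=0).data
        sens = rank_product_two_class(
            class1, class2, n_permutations=20, seed=0, direction="sensitive"
        ).data
        assert list(res["gene"]) == list(reversed(list(sens["gene"])))

    def test_mismatched_gene_universe_rejected(self):
        genes_a = pd.Index(["a", "b"])
        genes_b = pd.Index(["a", "c"])
        c1 = [SimulatedExperiment(Group.SENSITIVE, pd.Series([1.0, 2.0], index=genes_a), k=9)]
        c2 = [SimulatedExperiment(Group.RESISTANT, pd.Series([1.0, 2.0], index=genes_b), k=9)]
        with pytest.raises(ConfigurationError):
            rank_product_two_class(c1, c2)

    def test_per_pairing_scheme_matches_independent_rank_oracle(self):
        # spec-stated null: independent uniform rank vectors per pairing
        odds1, odds2, class1, class2 = toy_experiments()
        table = rank_product_two_class(class1, class2, exhaustive=True, null_scheme="per-pairing")
        rp_obs = np.exp(
            np.mean(
                np.log(
                    np.column_stack(
                        [
                            plain_ranks(odds1[:, 0] / odds2[:, 0]),
                            plain_ranks(odds1[:, 0] / odds2[:, 1]),
                        ]
                    )
                ),
                axis=1,
            )
        )
        G = 3
        counts = np.zeros(G)
        n_null = 0
        for r1 in itertools.permutations([1.0, 2.0, 3.0]):
            for r2 in itertools.permutations([1.0, 2.0, 3.0]):
                rp_null = np.exp(np.mean(np.log(np.column_stack([r1, r2])), axis=1))
                n_null += 1
                for g in range(G):
                    counts[g] += (rp_null <= rp_obs[g] + 1e-12).sum()
        p_expected = counts / (n_null * G)
        frame = table.data.set_index("gene")
        for g, p in zip(["g1", "g2", "g3"], p_expected):
            assert frame.loc[g, "p_value"] == pytest.approx(p, abs=1e-12)


class TestRankGenesPipeline:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed + 500)
        variants = [VariantSpec(gene="HOT", maf=0.05, odds_ratio=10.0) for _ in range(3)]
        variants += [
            VariantSpec(gene=f"N{i}", maf=float(rng.uniform(0.02, 0.3))) for i in range(8) for _ in range(3)
        ]
        cohort = simulate_cohort(SimulationSpec(12, 12, variants, seed=seed))
        _, _, adjusted, mafs = adjust_pipeline(cohort.matrix, cohort.popfreq)
        return cohort, adjusted, mafs

    def test_planted_gene_ranks_first(self):
        cohort, adjusted, mafs = self._cohort(seed=4)
        table = rank_genes(adjusted, mafs, filter_mode="all", k=499, n_permutations=100, seed=4)
        assert table.top(1) == ["HOT"]

    def test_gene_universe_excludes_filtered_out_genes(self):
        cohort, adjusted, mafs = self._cohort(seed=5)
        table = rank_genes(adjusted, mafs, filter_mode="all", k=99, n_permutations=50, seed=5)
        assert set(table.data["gene"]) <= {"HOT"} | {f"N{i}" for i in range(8)}

    def test_methods_agree_on_top_genes(self, paperlike, paperlike_adjusted):
        adjusted = paperlike_adjusted["matrix"]
        mafs = paperlike_adjusted["mafs"]
        by_mean = rank_genes(adjusted, mafs, method="mean", k=299, n_permutations=100, seed=9)
        by_size = rank_genes(
            adjusted, mafs, method="sum_over_size", sizes=paperlike.gene_sizes,
            k=299, n_permutations=100, seed=9,
        )
        assert set(by_mean.top(3)) == set(by_size.top(3))

    def test_deterministic_given_seed(self):
        cohort, adjusted, mafs = self._cohort(seed=6)
        a = rank_genes(adjusted, mafs, filter_mode="all", k=99, n_permutations=50, seed=11)
        b = rank_genes(adjusted, mafs, filter_mode="all", k=99, n_permutations=50, seed=11)
        assert a == b
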