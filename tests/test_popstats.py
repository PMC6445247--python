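"""Per-locus statistics: frequencies, HWE, differentials, informativeness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aimpanel import (
    FrequencyTable,
    GenotypeMatrix,
    GroupAssignment,
    LocusRecord,
    allele_frequencies,
    bonferroni_alpha,
    compute_in,
    count_high_in,
    cumulative_in,
    freq_differential,
    hwe_exact,
    hwe_scan,
    informativeness_multigroup,
    informativeness_onevsrest,
    SimulationSpec,
    simulate_genotypes,
)
from conftest import hwe_exact_oracle, in_statistic_oracle, make_loci


def _freq_table(matrix, groups=None, sizes=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    groups = groups or [f"G{j}" for j in range(matrix.shape[1])]
    loci = make_loci(matrix.shape[0])
    return FrequencyTable(loci, groups, matrix, sample_sizes=sizes)


# ---------------------------------------------------------------------------
# allele frequencies

class TestAlleleFrequencies:
    def test_direct_count(self):
        loci = make_loci(1)
        gm = GenotypeMatrix(["a", "b", "c"], ["pop"] * 3, loci, np.array([[2], [1], [0]]))
        ft = allele_frequencies(gm)
        assert ft.freq[0, 0] == pytest.approx(0.5)
        assert ft.sample_sizes == {"pop": 3}

    def test_all_missing_column_is_nan(self):
        loci = make_loci(1)
        gm = GenotypeMatrix(["a", "b"], ["pop"] * 2, loci, np.array([[-1], [-1]]))
        assert np.isnan(allele_frequencies(gm).freq[0, 0])

    def test_missing_excluded_pairwise(self):
        loci = make_loci(1)
        gm = GenotypeMatrix(["a", "b", "c"], ["pop"] * 3, loci, np.array([[2], [-1], [0]]))
        assert allele_frequencies(gm).freq[0, 0] == pytest.approx(0.5)

    def test_binomial_sampling_recovery(self):
        p = 0.3
        table = _freq_table(np.full((5, 1), p), groups=["only"])
        spec = SimulationSpec(groups=[("only", 1000)], loci=table.loci, freq_model=table, seed=12)
        gm, _, _ = simulate_genotypes(spec)
        est = allele_frequencies(gm).freq[:, 0]
        se = math.sqrt(p * (1 - p) / 2000)
        assert np.all(np.abs(est - p) < 3 * se)

    def test_group_pooling_vs_population_mean(self):
        # two populations of unequal size in one group: pooling weights by
        # individuals, mean_of_populations weights populations equally
        loci = make_loci(1)
        geno = np.array([[2]] * 6 + [[0]] * 2)
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(8)], ["p1"] * 6 + ["p2"] * 2, loci, geno
        )
        groups = GroupAssignment({"p1": "G", "p2": "G"})
        assert allele_frequencies(gm, groups).freq[0, 0] == pytest.approx(0.75)
        assert allele_frequencies(gm, groups, mode="mean_of_populations").freq[0, 0] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# HWE exact test

class TestHWEExact:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (2, 0, 2), (3, 5, 2), (0, 2, 0), (7, 1, 9), (12, 0, 1)],
    )
    def test_matches_exact_rational_oracle(self, counts):
        got = hwe_exact(counts)
        want = hwe_exact_oracle(*counts)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    def test_modal_configuration_gives_one(self):
        # (25, 50, 25): every configuration is counted, so p = 1
        assert hwe_exact((25, 50, 25)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("counts", [(10, 0, 0), (0, 0, 7), (5, 1, 0)])
    def test_undefined_when_fewer_than_two_effective_alleles(self, counts):
        assert math.isnan(hwe_exact(counts))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact((-1, 2, 3))

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_oracle_agreement_property(self, a, h, b):
        got, want = hwe_exact((a, h, b)), hwe_exact_oracle(a, h, b)
        assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want, abs=1e-12)

    def test_scan_covers_every_locus_and_population(self, two_group_panel):
        gm, _, _ = two_group_panel
        res = hwe_scan(gm)
        assert len(res) == 2 * gm.n_loci
        assert {r.population for r in res} == {"grpA", "grpB"}

    def test_familywise_control_on_null_panels(self):
        # panels simulated under HWE: Bonferroni keeps the familywise
        # rejection rate at or below alpha (up to binomial noise)
        rng = np.random.default_rng(2024)
        alpha, n_loci, n_panels = 0.05, 20, 1000
        level = bonferroni_alpha(alpha, n_loci)
        rejections = 0
        for _ in range(n_panels):
            p = rng.uniform(0.2, 0.8, size=n_loci)
            geno = rng.binomial(2, p, size=(40, n_loci))
            rejected = False
            for j in range(n_loci):
                c = (np.sum(geno[:, j] == 2), np.sum(geno[:, j] == 1), np.sum(geno[:, j] == 0))
                pv = hwe_exact(c)
                if not math.isnan(pv) and pv < level:
                    rejected = True
                    break
            rejections += rejected
        se = math.sqrt(alpha * (1 - alpha) / n_panels)
        assert rejections / n_panels <= alpha + 3 * se


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 48, 0.00104), (0.05, 1, 0.05), (1.0, 4, 0.25)]
    )
    def test_values(self, alpha, n, expected):
        assert round(bonferroni_alpha(alpha, n), 5) == expected

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


# ---------------------------------------------------------------------------
# frequency differentials

class TestFreqDifferential:
    def test_table2_locus(self, table2):
        pairs, mx = freq_differential(table2, "rs10918196")
        assert mx == pytest.approx(0.8351 - 0.2429, abs=1e-12)
        assert pairs[("African", "East Asian")] == pytest.approx(0.5922, abs=1e-12)

    def test_equal_groups_zero(self):
        _, mx = freq_differential(_freq_table([[0.4, 0.4, 0.4]]), "L0")
        assert mx == 0.0

    def test_opposite_fixation_is_one(self):
        _, mx = freq_differential(_freq_table([[0.0, 1.0]]), "L0")
        assert mx == 1.0

    def test_nan_propagates_to_pairs(self):
        pairs, mx = freq_differential(_freq_table([[0.2, np.nan, 0.9]]), "L0")
        assert math.isnan(pairs[("G0", "G1")])
        assert mx == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# informativeness

class TestInformativeness:
    def test_equal_frequencies_give_zero(self):
        ft = _freq_table([[0.3, 0.3, 0.3, 0.3]])
        assert informativeness_multigroup(ft).iloc[0] == 0.0

    def test_two_group_maximal_divergence_is_ln2(self):
        ft = _freq_table([[1.0, 0.0]])
        assert informativeness_multigroup(ft).iloc[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_scalar_oracle_on_table2(self, table2):
        w = np.full(4, 0.25)
        vals = informativeness_multigroup(table2)
        for rs in ("rs10918196", "rs3762894", "rs10852189"):
            row = table2.row(rs)
            assert vals[rs] == pytest.approx(in_statistic_oracle(row, w), abs=1e-12)

    def test_allele_swap_invariance(self, table2):
        swapped = FrequencyTable(
            table2.loci, table2.group_names, 1.0 - table2.freq, table2.sample_sizes
        )
        np.testing.assert_allclose(
            informativeness_multigroup(table2).to_numpy(),
            informativeness_multigroup(swapped).to_numpy(),
            atol=1e-12,
        )

    @given(
        st.lists(
            st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounds_and_nonnegativity(self, rows):
        ft = _freq_table(np.array(rows))
        vals = informativeness_multigroup(ft).to_numpy()
        assert np.all(vals >= 0.0)
        assert np.all(vals <= math.log(3) + 1e-12)

    def test_onevsrest_zero_when_target_equals_rest_mean(self):
        ft = _freq_table([[0.5, 0.4, 0.6]])  # mean of rest = 0.5 = target
        assert informativeness_onevsrest(ft, "G0", rest_weights="equal").iloc[0] == 0.0

    def test_onevsrest_composes_with_multigroup(self):
        # one-vs-rest == 2-group In on the collapsed (target, mean-rest) table
        rng = np.random.default_rng(5)
        f = rng.uniform(0.05, 0.95, size=(20, 4))
        ft = _freq_table(f)
        for j, g in enumerate(ft.group_names):
            rest = np.delete(f, j, axis=1).mean(axis=1)
            collapsed = _freq_table(np.column_stack([f[:, j], rest]), groups=["t", "r"])
            np.testing.assert_allclose(
                informativeness_onevsrest(ft, g, rest_weights="equal").to_numpy(),
                informativeness_multigroup(collapsed).to_numpy(),
                atol=1e-12,
            )

    def test_onevsrest_bounded_by_ln2(self, table2):
        for g in table2.group_names:
            vals = informativeness_onevsrest(table2, g)
            assert np.all(vals.to_numpy() <= math.log(2) + 1e-12)

    def test_sample_size_weighting_differs_from_equal(self, table2):
        a = informativeness_onevsrest(table2, "African", rest_weights="sample_size")
        b = informativeness_onevsrest(table2, "African", rest_weights="equal")
        assert not np.allclose(a.to_numpy(), b.to_numpy())

    def test_rs10852189_uninformative_in_all_groups(self, table2):
        res = compute_in(table2)
        assert res.in_onevsrest.loc["rs10852189"].max() <= 0.05


class TestInSummaries:
    def test_cumulative_equals_column_sum(self, table2):
        res = compute_in(table2)
        for g in table2.group_names:
            assert cumulative_in(res, g) == pytest.approx(
                res.in_onevsrest[g].sum(), abs=1e-12
            )

    def test_single_locus_cumulative_is_identity(self, table2):
        one = table2.subset(["rs10918196"])
        res = compute_in(one)
        assert cumulative_in(res, "African") == pytest.approx(
            res.in_onevsrest.loc["rs10918196", "African"]
        )

    def test_cumulative_invariant_under_locus_permutation(self, table2):
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(table2.rs_ids))
        res_a, res_b = compute_in(table2), compute_in(table2.subset(perm))
        for g in table2.group_names:
            assert cumulative_in(res_a, g) == pytest.approx(cumulative_in(res_b, g), abs=1e-12)

    def test_count_threshold_zero_counts_all_defined(self, table2):
        res = compute_in(table2)
        assert count_high_in(res, "African", 0.0) == 48

    def test_count_above_ln2_is_zero(self, table2):
        res = compute_in(table2)
        assert count_high_in(res, "African", math.log(2) + 0.01) == 0

    def test_count_threshold_inclusive(self):
        ft = _freq_table(np.array([[0.5, 0.5]]))
        res = compute_in(ft, threshold=0.0)
        assert count_high_in(res, "G0", 0.0) == 1  # In == 0 included at >= 0
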