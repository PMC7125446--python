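"""Unit tests for the hypothesis-test cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mdgnet import screen
from mdgnet.screen import (
    CascadeCutoffs,
    DegenerateSampleError,
    bh_adjust,
    ks_statistic,
    location_test,
    mannwhitney_exact_p,
    normality_ks,
    screen_genes,
    two_sample_ks,
    variance_f_test,
)


class TestTwoSampleKS:
    def test_identical_samples_give_p_one(self):
        x = [0.3, 1.2, -0.5, 2.2]
        assert ks_statistic(x, x) == 0.0
        assert two_sample_ks(x, x) == 1.0

    def test_disjoint_supports_force_tiny_p(self, rng):
        x = rng.standard_normal(50)
        assert two_sample_ks(x, x + 10) < 1e-6

    def test_statistic_from_edf_enumeration(self):
        # EDF steps: sup difference is 1/3 for these interleaved triples
        assert ks_statistic((0.1, 0.2, 0.3), (0.15, 0.25, 0.35)) == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ks([], [1.0, 2.0])


class TestNormalityKS:
    def test_calibration_on_normal_draws(self):
        rng = np.random.default_rng(5)
        passes = sum(
            normality_ks(rng.normal(5.0, 2.0, 200)) > 0.001 for _ in range(100)
        )
        assert passes >= 95

    def test_power_against_two_point_distribution(self):
        rng = np.random.default_rng(6)
        rejects = sum(
            normality_ks(rng.choice([0.0, 1.0], size=200)) < 0.001
            for _ in range(100)
        )
        assert rejects >= 95

    def test_constant_sample_is_nonnormal(self):
        assert normality_ks([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_lilliefors_mode_is_less_conservative(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(size=80)
        assert normality_ks(x, lilliefors=True) <= normality_ks(x)


class TestVarianceFTest:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert variance_f_test(x, x) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.standard_normal(12), 3 * rng.standard_normal(9)
        assert variance_f_test(x, y) == pytest.approx(variance_f_test(y, x))

    def test_closed_form_for_known_variance_ratio(self):
        # samples scaled to sample variances exactly 1 and 16 (n=10 each)
        base = np.arange(10, dtype=float)
        x = base / base.std(ddof=1)
        y = 4.0 * x
        expected = 2 * stats.f(9, 9).sf(16.0)
        assert variance_f_test(y, x) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateSampleError):
            variance_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLocationTest:
    def test_zero_effect_gives_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        for route in ("t", "Welch"):
            assert location_test(x, x, route) == pytest.approx(1.0)
        # identical multisets tie every rank: documented p = 1 convention
        assert location_test(x, x, "MannWhitney") <= 1.0

    def test_all_tied_values_give_p_one(self):
        assert location_test([5.0, 5.0], [5.0, 5.0, 5.0], "MannWhitney") == 1.0

    def test_mannwhitney_exact_separated_triples(self):
        # 2 of the C(6,3)=20 rank assignments are as extreme as U=0
        assert location_test((1, 2, 3), (4, 5, 6), "MannWhitney") == pytest.approx(0.1)
        assert mannwhitney_exact_p((1, 2, 3), (4, 5, 6)) == pytest.approx(0.1)

    def test_mannwhitney_matches_rank_enumeration_oracle(self, rng):
        for _ in range(20):
            n, m = rng.integers(2, 6, size=2)
            pooled = rng.choice(np.arange(100.0), size=n + m, replace=False)
            x, y = pooled[:n], pooled[n:]
            assert location_test(x, y, "MannWhitney") == pytest.approx(
                mannwhitney_exact_p(x, y)
            )

    def test_t_equals_welch_for_balanced_equal_variance(self):
        x = np.array([0.0, 1.0, 2.0])
        y = x + 5.0  # same sample variance, same n: Satterthwaite df = pooled df
        assert location_test(x, y, "t") == pytest.approx(location_test(x, y, "Welch"))

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError):
            location_test([1.0, 2.0], [3.0, 4.0], "median")


class TestBHAdjust:
    def test_single_test_unchanged(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_hand_step_up_three_values(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_hand_step_up_mixed(self):
        # ranks: 0.002*3/1, then min with later: 0.04*3/2=0.06, 0.09*3/3=0.09
        assert bh_adjust([0.04, 0.002, 0.09]) == pytest.approx([0.06, 0.006, 0.09])

    def test_wider_family_matches_step_up_by_hand(self):
        # two tested p-values inside a family of 10: q = p * 10 / rank, step-up
        q = bh_adjust([0.001, 0.02], total_tests=10)
        assert q == pytest.approx([0.01, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_elementwise(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)


class TestScreenCascade:
    def test_identical_gene_unflagged_with_near_unit_p(self, small_pair):
        mc, me = small_pair
        me = me.copy()
        me.iloc[0] = np.resize(mc.iloc[0].to_numpy(), me.shape[1])
        records = screen_genes(mc, me)
        row = records.iloc[0]
        assert not row["flagged"]
        assert row["route"] in ("t", "Welch", "MannWhitney")

    def test_every_gene_gets_exactly_one_route(self, de_dataset_delta0):
        ds = de_dataset_delta0
        records = screen_genes(ds.matrix_c, ds.matrix_e)
        assert records["route"].isin(screen.ROUTES).all()
        assert records["route"].value_counts().sum() == len(records)

    def test_zero_variance_gene_routes_to_mannwhitney(self, small_pair):
        # constant in both cohorts: stage 1 sees identical distributions,
        # the parametric stages are undefined, so the gene falls to MW
        mc, me = small_pair
        mc, me = mc.copy(), me.copy()
        mc.iloc[3] = 7.0
        me.iloc[3] = 7.0
        records = screen_genes(mc, me)
        assert records.iloc[3]["route"] == "MannWhitney"
        assert np.isnan(records.iloc[3]["p_norm_c"])

    def test_route_fidelity_at_zero_shift(self, de_dataset_delta0):
        """With no location shift each branch reaches its designed test."""
        ds = de_dataset_delta0
        records = screen_genes(ds.matrix_c, ds.matrix_e)
        routes = pd.Series(
            records["route"].to_numpy(), index=ds.truth_de.to_numpy()
        )
        expected = {
            "shape": "KS2-different",
            "mean-shift": "t",
            "variance-shift": "Welch",
            "nonnormal-shift": "MannWhitney",
            "null": "t",
        }
        for branch, route in expected.items():
            frac = (routes.loc[branch] == route).mean()
            assert frac >= 0.8, f"{branch}: only {frac:.0%} routed to {route}"
        # and with delta=0 no location difference should be flagged
        flagged = pd.Series(records["flagged"].to_numpy(), index=ds.truth_de.to_numpy())
        for branch in ("mean-shift", "variance-shift", "nonnormal-shift", "null"):
            assert flagged.loc[branch].mean() <= 0.05

    def test_loosening_location_cutoff_never_shrinks_flagged_set(self, small_pair):
        mc, me = small_pair
        previous = set()
        for q_loc in (0.001, 0.01, 0.1):
            records = screen_genes(mc, me, CascadeCutoffs(q_loc=q_loc))
            current = set(screen.flagged_genes(records))
            assert previous <= current
            previous = current

    def test_loosening_all_cutoffs_never_shrinks_flagged_set(self, de_dataset_delta0):
        ds = de_dataset_delta0
        previous = set()
        for scale in (1.0, 10.0, 100.0):
            cutoffs = CascadeCutoffs(
                q_ks2=min(0.0005 * scale, 0.9),
                q_ksnorm=min(0.001 * scale, 0.9),
                q_f=min(0.001 * scale, 0.9),
                q_loc=min(0.001 * scale, 0.9),
            )
            records = screen_genes(ds.matrix_c, ds.matrix_e, cutoffs)
            current = set(screen.flagged_genes(records))
            assert previous <= current
            previous = current

    def test_mismatched_gene_sets_rejected(self, small_pair):
        mc, me = small_pair
        bad = me.copy()
        bad.index = [f"x{i}" for i in range(len(bad))]
        with pytest.raises(ValueError):
            screen_genes(mc, bad)

    def test_global_fdr_scope_is_no_looser_than_staged(self, de_dataset_delta0):
        ds = de_dataset_delta0
        staged = screen_genes(ds.matrix_c, ds.matrix_e, fdr_scope="staged")
        global_ = screen_genes(ds.matrix_c, ds.matrix_e, fdr_scope="global")
        # same family at stage 1 (all genes) but wider families later:
        # global q-values can only match or exceed staged ones
        mask = staged["q_loc"].notna()
        assert np.all(
            global_.loc[mask, "q_loc"].to_numpy()
            >= staged.loc[mask, "q_loc"].to_numpy() - 1e-12
        )

    def test_fisher_normality_rule_runs(self, small_pair):
        mc, me = small_pair
        records = screen_genes(mc, me, normality_rule="fisher")
        assert records["route"].isin(screen.ROUTES).all()
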