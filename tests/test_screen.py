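"""Expression preprocessing and the three-stage cross-strain screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermoscreen as ts
from thermoscreen import datasets
from thermoscreen.errors import InvalidInputError


def make_matrix(log2_by_sample, meta_rows, flags=None):
    genes = [f"g{i}" for i in range(len(next(iter(log2_by_sample.values()))))]
    values = pd.DataFrame(
        {s: 2.0 ** np.asarray(v, float) for s, v in log2_by_sample.items()},
        index=genes,
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "strain", "condition", "replicate"]
    ).set_index("sample")
    fl = None
    if flags is not None:
        fl = pd.DataFrame(flags, index=genes, columns=values.columns)
    return ts.ExpressionMatrix(values=values, metadata=metadata, flags=fl)


def brute_force_screen(folds: pd.DataFrame, tol, ref, sen, thr=1.5):
    """Per-gene pure-python re-statement of the three stages."""
    s1, s2, s3 = set(), set(), set()
    for gene, row in folds.iterrows():
        ft, fr, fs = row[tol], row[ref], row[sen]
        if ft > thr and fr > thr:
            s1.add(gene)
            if ft / fr > thr or fr / fs > thr:
                s2.add(gene)
                if ft > fr > fs:
                    s3.add(gene)
    return s1, s2, s3


class TestNormalization:
    def test_shifted_percentile_is_zero(self):
        rng = np.random.default_rng(0)
        m, _ = ts.simulate_expression_matrix(
            ts.default_strain_trio(), n_genes=100, noise_sd=0.3, seed=3
        )
        norm = ts.percentile_shift_normalize(m)
        q = norm.values.quantile(0.75, axis=0)
        assert np.allclose(q.to_numpy(), 0.0, atol=1e-12)

    def test_global_scale_factor_removed(self):
        m, _ = ts.simulate_expression_matrix(
            ts.default_strain_trio(), n_genes=50, noise_sd=0.2, seed=4
        )
        scaled = ts.ExpressionMatrix(
            values=m.values * 8.0, metadata=m.metadata, flags=m.flags
        )
        a = ts.percentile_shift_normalize(m).values
        b = ts.percentile_shift_normalize(scaled).values
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_per_sample_scale_factors_cancel_in_fold_changes(self):
        # zero-noise matrix distorted by arbitrary per-sample scale factors:
        # after normalization the planted fold changes are recovered exactly
        induction = {"tolerant": 2.5, "reference": 2.0, "sensitive": 1.6}
        m, truth = ts.simulate_expression_matrix(
            ts.default_strain_trio(), n_genes=200,
            planted_induction=induction, noise_sd=0.0, seed=5,
        )
        rng = np.random.default_rng(5)
        factors = rng.uniform(0.25, 4.0, size=len(m.samples))
        distorted = ts.ExpressionMatrix(
            values=m.values * factors, metadata=m.metadata, flags=m.flags
        )
        norm = ts.percentile_shift_normalize(distorted)
        for strain, expected in induction.items():
            fold = ts.fold_change(norm, strain)
            assert fold[truth.planted_gene] == pytest.approx(expected, rel=1e-9)


class TestLowIntensityFilter:
    def _matrix(self):
        log2 = {
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
            "b": [1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5],
        }
        meta = [("a", "s1", "control", 1), ("b", "s1", "heat", 1)]
        return make_matrix(log2, meta)

    def test_fraction_zero_keeps_everything(self):
        assert ts.low_intensity_filter(self._matrix(), 0.0).all()

    def test_gene_lowest_everywhere_removed(self):
        mask = ts.low_intensity_filter(self._matrix(), 0.2)
        assert not mask["g0"] and not mask["g1"]
        assert mask["g2":].all()

    def test_gene_low_in_only_one_sample_kept(self):
        log2 = {
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
            "b": [9.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 1.0, 10.0],
        }
        meta = [("a", "s1", "control", 1), ("b", "s1", "heat", 1)]
        mask = ts.low_intensity_filter(make_matrix(log2, meta), 0.2)
        # g0 is lowest in sample a but near-top in b: kept
        assert mask["g0"]
        # g1 sits in the lowest 20% of both samples: removed
        assert not mask["g1"]


class TestFlagFilter:
    def _matrix(self, flags):
        log2 = {"a": [5.0, 6.0], "b": [5.0, 6.0], "c": [5.0, 6.0], "d": [5.0, 6.0]}
        meta = [
            ("a", "s1", "control", 1),
            ("b", "s1", "control", 2),
            ("c", "s1", "heat", 1),
            ("d", "s1", "heat", 2),
        ]
        return make_matrix(log2, meta, flags=flags)

    def test_all_present_kept(self):
        mask = ts.flag_filter(self._matrix([["present"] * 4] * 2))
        assert mask.all()

    def test_absent_everywhere_removed(self):
        mask = ts.flag_filter(
            self._matrix([["present"] * 4, ["absent"] * 4])
        )
        assert mask["g0"] and not mask["g1"]

    def test_present_in_half_of_samples_kept(self):
        flags = [["present", "present", "absent", "absent"]] * 2
        assert ts.flag_filter(self._matrix(flags)).all()

    def test_no_flags_passes_everything(self):
        m = self._matrix([["present"] * 4] * 2)
        m = ts.ExpressionMatrix(values=m.values, metadata=m.metadata, flags=None)
        assert ts.flag_filter(m).all()

    def test_unknown_flag_label_rejected(self):
        with pytest.raises(InvalidInputError):
            ts.flag_filter(self._matrix([["present"] * 4] * 2), allowed={"weird"})


class TestFoldChange:
    def _matrix(self, ctrl, heat):
        log2 = {"c1": [ctrl[0]], "c2": [ctrl[1]], "h1": [heat[0]], "h2": [heat[1]]}
        meta = [
            ("c1", "s1", "control", 1),
            ("c2", "s1", "control", 2),
            ("h1", "s1", "heat", 1),
            ("h2", "s1", "heat", 2),
        ]
        return make_matrix(log2, meta)

    def test_identical_groups_give_unit_fold(self):
        fold = ts.fold_change(self._matrix([2.0, 4.0], [2.0, 4.0]), "s1")
        assert fold.iloc[0] == pytest.approx(1.0)

    def test_geometric_mean_of_log2_values(self):
        # control log2 {1,3}, heat {4,6}: fold = 2^(5-2) = 8
        fold = ts.fold_change(self._matrix([1.0, 3.0], [4.0, 6.0]), "s1")
        assert fold.iloc[0] == pytest.approx(8.0, rel=1e-12)

    def test_arithmetic_mode_differs_when_replicates_spread(self):
        m = self._matrix([1.0, 3.0], [4.0, 6.0])
        arith = ts.fold_change(m, "s1", mode="arithmetic")
        expected = (2.0**4 + 2.0**6) / (2.0**1 + 2.0**3)
        assert arith.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_noise_planted_gene_reproduces_published_induction(self):
        induction = {"tolerant": 3.68, "reference": 2.18, "sensitive": 1.35}
        m, truth = ts.simulate_expression_matrix(
            ts.default_strain_trio(), n_genes=50, planted_induction=induction,
            noise_sd=0.0, seed=0,
        )
        for strain, expected in induction.items():
            fold = ts.fold_change(m, strain)
            assert fold[truth.planted_gene] == pytest.approx(expected, rel=1e-12)

    def test_missing_condition_rejected(self):
        log2 = {"c1": [1.0], "c2": [2.0]}
        meta = [("c1", "s1", "control", 1), ("c2", "s1", "control", 2)]
        with pytest.raises(InvalidInputError):
            ts.fold_change(make_matrix(log2, meta), "s1")


class TestDifferentialFilter:
    def _matrix(self, ctrl, heat):
        cols = {f"c{i}": [v] for i, v in enumerate(ctrl)}
        cols |= {f"h{i}": [v] for i, v in enumerate(heat)}
        meta = [(f"c{i}", "s1", "control", i) for i in range(len(ctrl))] + [
            (f"h{i}", "s1", "heat", i) for i in range(len(heat))
        ]
        return make_matrix(cols, meta)

    def test_identical_groups_removed(self):
        m = self._matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not ts.differential_filter(m, "s1").iloc[0]

    def test_large_effect_small_noise_kept(self):
        m = self._matrix([1.0, 1.01, 0.99], [5.0, 5.01, 4.99])
        # cross-check with a direct Welch-free t statistic
        from scipy import stats as sps

        t, p = sps.ttest_ind([5.0, 5.01, 4.99], [1.0, 1.01, 0.99])
        assert p < 0.05
        assert ts.differential_filter(m, "s1").iloc[0]

    def test_alpha_one_keeps_all_nondegenerate_genes(self):
        m = self._matrix([1.0, 2.0], [1.5, 2.5])
        assert ts.differential_filter(m, "s1", alpha=1.0).iloc[0]

    def test_single_replicate_rejected(self):
        m = self._matrix([1.0], [2.0])
        with pytest.raises(InvalidInputError):
            ts.differential_filter(m, "s1")


class TestScreenStages:
    @pytest.fixture
    def published(self):
        return datasets.candidate_fold_changes()

    def test_stage1_published_candidates_pass(self, published):
        s1 = ts.screen_stage1(published, datasets.TOLERANT, datasets.REFERENCE)
        assert s1 == {"FMP21", "YER034W", "PRM5"}

    def test_stage1_boundary_fold_fails(self):
        fc = ts.FoldChangeTable(
            folds=pd.DataFrame({"T": [1.5], "R": [1.5], "S": [1.0]}, index=["g"])
        )
        assert ts.screen_stage1(fc, "T", "R") == set()

    def test_stage2_fold_ratio_paths(self):
        fc = ts.FoldChangeTable(
            folds=pd.DataFrame(
                {
                    "T": [3.68, 2.0, 1.0],
                    "R": [2.18, 2.0, 3.2],
                    "S": [1.35, 2.0, 2.0],
                },
                index=["fmp21_like", "flat", "second_disjunct"],
            )
        )
        s2 = ts.screen_stage2(fc, "T", "R", "S")
        assert "fmp21_like" in s2  # 3.68/2.18 ~ 1.688 > 1.5
        assert "flat" not in s2  # both ratios exactly 1
        assert "second_disjunct" in s2  # 3.2/2.0 = 1.6 > 1.5

    def test_stage3_published_rows_are_concordant(self, published):
        order = (datasets.TOLERANT, datasets.REFERENCE, datasets.SENSITIVE)
        assert ts.screen_stage3(published, order) == {"FMP21", "YER034W", "PRM5"}

    def test_stage3_non_monotone_and_tied_genes_fail(self):
        fc = ts.FoldChangeTable(
            folds=pd.DataFrame(
                {"T": [2.0, 2.0], "R": [3.0, 2.0], "S": [1.0, 1.0]},
                index=["bump", "tie"],
            )
        )
        assert ts.screen_stage3(fc, ("T", "R", "S")) == set()

    def test_unknown_strain_rejected(self, published):
        with pytest.raises(InvalidInputError):
            ts.screen_stage1(published, "nope", datasets.REFERENCE)


class TestFullScreen:
    def test_published_table_yields_exactly_three_candidates(self):
        result = ts.screen_fold_changes(
            datasets.candidate_fold_changes(), datasets.STRAIN_ROLES
        )
        assert result.stage3_genes == {"FMP21", "YER034W", "PRM5"}
        assert len(result.stage3_genes) == 3

    def test_zero_noise_matrix_recovers_exactly_the_planted_gene(self, trio, roles):
        m, truth = ts.simulate_expression_matrix(
            trio, n_genes=999, noise_sd=0.0, seed=11
        )
        result = ts.run_screen(m, roles)
        assert result.stage3_genes == {truth.planted_gene}
        assert result.stage1_genes == {truth.planted_gene}  # zero background FP

    def test_stage_subsets_and_audit_cover_all_filtered_genes(self, trio, roles):
        m, _ = ts.simulate_expression_matrix(trio, n_genes=200, noise_sd=0.4, seed=7)
        r = ts.run_screen(m, roles)
        assert r.stage3_genes <= r.stage2_genes <= r.stage1_genes
        assert len(r.audit) == r.n_filtered_genes

    def test_empty_matrix_after_filters_warns(self, trio, roles):
        m, _ = ts.simulate_expression_matrix(
            trio, n_genes=50, noise_sd=0.1, seed=1, absent_flag_fraction=1.0
        )
        # planted gene keeps its "present" call; drop it too via flags
        flags = m.flags.copy()
        flags.loc[:, :] = "absent"
        m = ts.ExpressionMatrix(values=m.values, metadata=m.metadata, flags=flags)
        r = ts.run_screen(m, roles)
        assert r.stage3_genes == frozenset()
        assert r.warnings

    def test_row_and_column_order_invariance(self, trio, roles):
        m, _ = ts.simulate_expression_matrix(trio, n_genes=120, noise_sd=0.3, seed=9)
        rng = np.random.default_rng(0)
        rows = rng.permutation(len(m.genes))
        cols = rng.permutation(len(m.samples))
        shuffled = ts.ExpressionMatrix(
            values=m.values.iloc[rows, cols],
            metadata=m.metadata,
            flags=m.flags.iloc[rows, cols],
        )
        a, b = ts.run_screen(m, roles), ts.run_screen(shuffled, roles)
        assert a.stage1_genes == b.stage1_genes
        assert a.stage2_genes == b.stage2_genes
        assert a.stage3_genes == b.stage3_genes

    def test_differential_filter_mode_keeps_planted_gene(self, trio, roles):
        m, truth = ts.simulate_expression_matrix(
            trio, n_genes=300, noise_sd=0.05, seed=13
        )
        r = ts.run_screen(m, roles, ts.ScreenConfig(differential=True))
        assert truth.planted_gene in r.stage3_genes


class TestScreenAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_per_gene_oracle_on_random_matrices(self, seed, trio, roles):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(20, 201))
        m, _ = ts.simulate_expression_matrix(
            trio, n_genes=n_genes, n_replicates=2, noise_sd=1.0, seed=seed
        )
        # bypass intensity/flag filters: the oracle restates the stages only
        cfg = ts.ScreenConfig(low_fraction=0.0)
        result = ts.run_screen(m, roles, cfg)
        folds = result.fold_changes.folds
        s1, s2, s3 = brute_force_screen(
            folds, "tolerant", "reference", "sensitive"
        )
        assert result.stage1_genes == s1
        assert result.stage2_genes == s2
        assert result.stage3_genes == s3
        assert s3 <= s2 <= s1


class TestPlantedGeneRecovery:
    def test_recovery_rate_at_noise_005(self, trio, roles):
        hits, fps = 0, 0
        n_seeds = 100
        # plant the published FMP21 induction pattern, the signal shape the
        # generator emulates
        induction = {"tolerant": 3.68, "reference": 2.18, "sensitive": 1.35}
        for seed in range(n_seeds):
            m, truth = ts.simulate_expression_matrix(
                trio, n_genes=300, n_replicates=2,
                planted_induction=induction, noise_sd=0.05, seed=seed,
            )
            r = ts.run_screen(m, roles)
            hits += truth.planted_gene in r.stage3_genes
            fps += len(r.stage3_genes - {truth.planted_gene})
        assert hits / n_seeds >= 0.95
        # background false positives stay rare at this noise level
        assert fps / n_seeds < 1.0


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_simulated_matrix_bitwise_reproducible(seed):
    trio = ts.default_strain_trio()
    a, ta = ts.simulate_expression_matrix(trio, n_genes=30, noise_sd=0.3, seed=seed)
    b, tb = ts.simulate_expression_matrix(trio, n_genes=30, noise_sd=0.3, seed=seed)
    assert a.values.equals(b.values)
    assert ta == tb


def test_background_fold_is_unbiased_over_many_seeds(trio):
    # Monte-Carlo over seeds: a background gene's mean empirical fold ~ 1
    folds = []
    for seed in range(1000):
        m, truth = ts.simulate_expression_matrix(
            trio, n_genes=2, n_replicates=2, noise_sd=0.1, seed=seed
        )
        background = [g for g in m.genes if g != truth.planted_gene][0]
        folds.append(ts.fold_change(m, "tolerant")[background])
    assert math.isclose(np.mean(folds), 1.0, abs_tol=0.05)
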