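import warnings

import numpy as np
import pandas as pd
import pytest

import survscreen as sv
from survscreen.containers import ValidationError
from survscreen.evaluation import (
    CVConfig,
    bh_family,
    compare_conditions,
    encode_clinical,
    inclusion_rule,
    integrate_clinical,
    nested_comparison,
    repeated_kfold,
    _prepare_split,
)

from _oracles import exact_wilcoxon_greater
from conftest import make_survival


@pytest.fixture(scope="module")
def eval_cohort():
    spec = sv.SimulationSpec(
        n_patients=150, n_genes=120, n_causal=8, sigma=0.6,
        target_censoring=0.3, seed=77,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = sv.simulate_dataset(spec)
    return ds


@pytest.fixture(scope="module")
def quick_config():
    return CVConfig(K=5, repetitions=2, seed=3, penalty=sv.PenaltySpec("lasso"),
                    K_inner=3, n_lambdas=25)


@pytest.fixture(scope="module")
def quick_result(eval_cohort, quick_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return repeated_kfold(eval_cohort, quick_config)


class TestRepeatedKfold:
    def test_sample_count_is_k_times_reps(self, quick_result, quick_config):
        assert len(quick_result.samples) == quick_config.K * quick_config.repetitions

    def test_partition_contract(self, eval_cohort, quick_config):
        from survscreen.evaluation import _partitions

        parts = _partitions(eval_cohort.survival.event, 5, 2, 3)
        for rep, folds in parts:
            test_union = np.concatenate([te for _, te in folds])
            assert sorted(test_union) == list(range(eval_cohort.n_patients))
            assert len(set(test_union)) == len(test_union)
            for _, te in folds:
                assert eval_cohort.survival.event[te].sum() >= 1

    def test_deterministic_under_seed(self, eval_cohort, quick_config, quick_result):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = repeated_kfold(eval_cohort, quick_config)
        pd.testing.assert_frame_equal(quick_result.samples, again.samples)

    def test_metrics_in_range(self, quick_result):
        c = quick_result.metric("c_index")
        ibs = quick_result.metric("ibs")
        assert np.all((c >= 0) & (c <= 1))
        assert np.all((ibs >= 0) & (ibs <= 1))


class TestLeakageGuard:
    def test_training_artifacts_ignore_test_fold(self, eval_cohort, quick_config):
        """Corrupting the test fold must leave every training-side artifact
        (screen statistics, standardization, fitted model inputs) unchanged."""
        n = eval_cohort.n_patients
        rng = np.random.default_rng(0)
        train_idx = np.arange(0, 100)
        test_idx = np.arange(100, n)

        sd_clean = _prepare_split(eval_cohort, train_idx, test_idx, 0, 0, quick_config)

        corrupted = sv.SurvivalDataset(
            sv.CountMatrix(
                eval_cohort.counts.gene_ids,
                eval_cohort.counts.sample_ids,
                np.where(
                    np.isin(np.arange(n), test_idx)[None, :],
                    rng.integers(0, 10**6, eval_cohort.counts.counts.shape),
                    eval_cohort.counts.counts,
                ),
            ),
            eval_cohort.survival,
        )
        sd_dirty = _prepare_split(corrupted, train_idx, test_idx, 0, 0, quick_config)

        np.testing.assert_array_equal(sd_clean.p_adj, sd_dirty.p_adj)
        np.testing.assert_array_equal(sd_clean.iqr, sd_dirty.iqr)
        np.testing.assert_array_equal(sd_clean.X_train, sd_dirty.X_train)
        assert not np.array_equal(sd_clean.X_test, sd_dirty.X_test)


class TestNested:
    def test_thresholds_one_zero_reduces_to_plain(self, eval_cohort, quick_config):
        from survscreen.evaluation import nested_evaluation, NESTED_SEED_OFFSET

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nested = nested_evaluation(eval_cohort, (1.0, 0.0), quick_config)
            plain_cfg = CVConfig(**{**quick_config.__dict__,
                                    "seed": quick_config.seed + NESTED_SEED_OFFSET})
            plain = repeated_kfold(eval_cohort, plain_cfg)
        pd.testing.assert_frame_equal(nested.samples, plain.samples)

    def test_paired_output_shape(self, eval_cohort, quick_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            both = nested_comparison(eval_cohort, (0.5, 0.5), quick_config)
        assert both["screened"].split_ids() == both["no_screening"].split_ids()
        assert len(both["screened"].samples) == 10


class TestGridSearch:
    def test_restricted_grid_and_pairing(self, eval_cohort):
        cfg = CVConfig(
            K=3, repetitions=1, seed=9, penalty=sv.PenaltySpec("lasso"),
            K_inner=3, n_lambdas=20,
            screen=sv.ScreenConfig(p_grid=(0.5, 1.0), iqr_grid=(0.0, 1.0)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = sv.grid_search_thresholds(eval_cohort, cfg)
        # all cells share split identifiers (paired design)
        ids = [res.split_ids() for res in grid.cells.values()]
        assert all(i == ids[0] for i in ids)
        # kept-gene medians monotone along each axis
        assert np.all(np.diff(grid.median_kept, axis=1) >= 0)
        assert np.all(np.diff(grid.median_kept, axis=0) <= 0)
        # single-cell grid: optimum is that cell
        cfg1 = CVConfig(
            K=3, repetitions=1, seed=9, penalty=sv.PenaltySpec("lasso"),
            K_inner=3, n_lambdas=20,
            screen=sv.ScreenConfig(p_grid=(1.0,), iqr_grid=(0.0,)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g1 = sv.grid_search_thresholds(eval_cohort, cfg1)
        assert g1.optimal["c_index"] == (1.0, 0.0)
        assert g1.optimal["ibs"] == (1.0, 0.0)


class TestNullBand:
    def test_no_signal_median_c_in_null_band_for_every_penalty(self):
        """With zero causal genes the pipeline must not manufacture signal:
        median cross-validated C-index stays in [0.45, 0.55] for each
        lasso-family penalty."""
        spec = sv.SimulationSpec(
            n_patients=150, n_genes=60, n_causal=0, sigma=0.0,
            target_censoring=0.3, seed=31,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds, _ = sv.simulate_dataset(spec)
            for kind in ("ridge", "lasso", "en", "aen"):
                cfg = CVConfig(
                    K=5, repetitions=4, seed=13, penalty=sv.PenaltySpec(kind),
                    K_inner=3, n_lambdas=15,
                )
                res = repeated_kfold(ds, cfg)
                med = res.median("c_index")
                assert 0.45 <= med <= 0.55, f"{kind}: median C {med}"


class TestClinicalIntegration:
    def test_encoding(self):
        df = pd.DataFrame({
            "age": [60.0, 70.0], "gender": ["Male", "female"],
            "T": ["T1", "T3"], "grade": [None, 2],
        }, index=["a", "b"])
        with pytest.warns(UserWarning, match="grade"):
            X, names = encode_clinical(df)
        assert names == ["age", "gender", "T"]
        np.testing.assert_allclose(X[:, 1], [0.0, 1.0])
        np.testing.assert_allclose(X[:, 2], [1.0, 3.0])

    def test_zero_pi_coefficient_reduces_to_clinical_only(self, rng):
        n = 150
        age = rng.uniform(40, 80, n)
        t = rng.exponential(np.exp(-(age - 60) / 20.0))
        d = make_survival(t + 1e-9, np.ones(n, dtype=int))
        clin = pd.DataFrame({"age": age})
        # pure-noise PI: its coefficient is ~0 and C-index matches clinical alone
        fit, pi = integrate_clinical(rng.standard_normal(n), clin, d)
        clin_only = sv.fit_cox(((age - age.mean()) / age.std())[:, None], d)
        c_combined = sv.concordance_index(pi, d).c_index
        c_clin = sv.concordance_index(
            clin_only.params[0] * (age - age.mean()) / age.std(), d
        ).c_index
        assert abs(c_combined - c_clin) < 0.03

    def test_noise_clinical_does_not_hurt_mrna_pi(self, rng):
        n = 200
        pi_true = rng.standard_normal(n)
        t = rng.exponential(np.exp(-pi_true))
        d = make_survival(t + 1e-9, np.ones(n, dtype=int))
        clin = pd.DataFrame({"age": rng.uniform(40, 80, n)})
        fit, pi = integrate_clinical(pi_true, clin, d)
        c_comb = sv.concordance_index(pi, d).c_index
        c_alone = sv.concordance_index(pi_true, d).c_index
        assert abs(c_comb - c_alone) < 0.03


class TestCompareConditions:
    def _mk(self, values):
        df = pd.DataFrame({
            "rep": np.repeat(np.arange(len(values) // 5), 5)[: len(values)],
            "fold": np.tile(np.arange(5), len(values) // 5)[: len(values)],
            "c_index": values, "ibs": 1 - np.asarray(values),
        })
        return sv.CVResult(df)

    def test_identical_conditions_p_one(self):
        a = self._mk(np.linspace(0.5, 0.7, 10))
        assert compare_conditions(a, a) == 1.0

    def test_five_all_positive_exact(self):
        a = self._mk(np.array([0.7, 0.72, 0.68, 0.71, 0.69]))
        b = self._mk(np.array([0.6, 0.62, 0.58, 0.61, 0.59]))
        p = compare_conditions(a, b, alternative="greater")
        assert p == pytest.approx(1 / 32)

    def test_matches_exact_enumeration_oracle(self, rng):
        x = rng.normal(0.65, 0.02, 10)
        y = rng.normal(0.63, 0.02, 10)
        a, b = self._mk(x), self._mk(y)
        p = compare_conditions(a, b, alternative="greater")
        assert p == pytest.approx(exact_wilcoxon_greater(x - y), abs=1e-10)

    def test_unpaired_rejected(self):
        a = self._mk(np.linspace(0.5, 0.7, 10))
        b = self._mk(np.linspace(0.5, 0.7, 15))
        with pytest.raises(ValidationError):
            compare_conditions(a, b)

    def test_bh_family_wraps_adjustment(self):
        adj = bh_family([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])


class TestInclusionRule:
    def _result(self, values):
        df = pd.DataFrame({
            "rep": 0, "fold": range(len(values)), "c_index": values,
        })
        return sv.CVResult(df)

    def test_high_c_included(self):
        assert inclusion_rule(self._result(np.full(50, 0.75)))

    def test_low_c_excluded(self):
        assert not inclusion_rule(self._result(np.full(50, 0.55)))

    def test_calibrated_near_reference(self):
        """C-indices fluctuating around the reference are included at about
        the nominal level."""
        rng = np.random.default_rng(0)
        included = sum(
            inclusion_rule(self._result(rng.normal(0.6, 0.02, 50)))
            for _ in range(200)
        )
        assert included / 200 < 0.05  # close to the 0.01 level, well below 5%
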