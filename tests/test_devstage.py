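"""Two-step stage model: sample filter, power transform, residualization
and the per-stage indicator regression, each against an independent
oracle."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dystogex.devstage import (filter_samples, residualize_gene,
                               run_stage_analysis, stage_model, yeo_johnson,
                               yeo_johnson_transform)
from dystogex.errors import (DegenerateInputError, EmptyResultError,
                             InputError, ModelError)
from dystogex.simulate import BulkSimConfig, generate_bulk

from conftest import grid_yeo_johnson_mle, make_bulk_dataset


class TestFilterSamples:
    def test_exclusion_is_strictly_below_threshold(self):
        ds = make_bulk_dataset(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["ACTB"],
                         columns=["S1", "S2", "S3"]),
            rin=[6.9, 7.0, 9.5])
        out, report = filter_samples(ds)
        assert list(out.samples.index) == ["S2", "S3"]  # RIN 7.0 is kept
        assert report == {"n_in": 3, "n_low_rin": 1,
                          "n_incomplete_metadata": 0, "n_out": 2}

    def test_identity_when_all_pass(self):
        ds = make_bulk_dataset(pd.DataFrame([[1.0, 2.0]], index=["ACTB"],
                                            columns=["S1", "S2"]), rin=[8, 8])
        out, _ = filter_samples(ds)
        assert out.expression.equals(ds.expression)

    def test_empty_result_error(self):
        ds = make_bulk_dataset(pd.DataFrame([[1.0, 2.0]], index=["ACTB"],
                                            columns=["S1", "S2"]), rin=[5, 5])
        with pytest.raises(EmptyResultError):
            filter_samples(ds)

    def test_incomplete_metadata_removed(self):
        ds = make_bulk_dataset(pd.DataFrame([[1.0, 2.0, 3.0]], index=["ACTB"],
                                            columns=["S1", "S2", "S3"]))
        ds.samples.loc["S2", "region"] = np.nan
        out, report = filter_samples(ds)
        assert list(out.samples.index) == ["S1", "S3"]
        assert report["n_incomplete_metadata"] == 1


class TestYeoJohnson:
    def test_identity_at_lambda_one(self, rng):
        x = rng.uniform(0, 10, 20)
        assert np.allclose(yeo_johnson(x, lmbda=1.0).transformed_values, x)

    def test_log_branch_at_lambda_zero(self, rng):
        x = rng.uniform(0, 10, 20)
        assert np.allclose(yeo_johnson(x, lmbda=0.0).transformed_values,
                           np.log1p(x))

    def test_negative_log_branch_at_lambda_two(self):
        x = np.array([-0.5, -2.0, 1.0])
        out = yeo_johnson_transform(x, 2.0)
        assert out[0] == pytest.approx(-np.log1p(0.5))
        assert out[1] == pytest.approx(-np.log1p(2.0))

    def test_matches_scipy_transform(self, rng):
        x = rng.normal(size=30)
        for lm in (-1.3, 0.0, 0.7, 2.0, 3.1):
            assert np.allclose(yeo_johnson_transform(x, lm),
                               scipy.stats.yeojohnson(x, lmbda=lm), atol=1e-12)

    def test_mle_matches_grid_oracle(self):
        x = np.array([0.1, 0.5, 1, 2, 4, 8, 16], dtype=float)
        assert yeo_johnson(x).lmbda == pytest.approx(grid_yeo_johnson_mle(x),
                                                     abs=1e-3)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            yeo_johnson(np.ones(10))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-4.5, 4.5),
           st.lists(st.integers(-5000, 5000), min_size=3, max_size=12,
                    unique=True))
    def test_strictly_increasing_in_input(self, lm, xs):
        # inputs on a 0.01 grid so float rounding cannot collapse outputs
        xs = np.sort(np.asarray(xs, dtype=float)) / 100.0
        out = yeo_johnson_transform(xs, lm)
        assert np.all(np.diff(out) > 0)


def _pinv_residuals(y, X):
    beta = np.linalg.pinv(X) @ y
    return y - X @ beta


class TestResidualize:
    def _covariates(self, rng, n, constant=False):
        return pd.DataFrame({
            "rin": rng.uniform(6, 10, n),
            "sex": ["F"] * n if constant else rng.choice(["F", "M"], n),
            "ethnicity": ["E1"] * n if constant else rng.choice(["E1", "E2"], n),
        })

    def test_constant_categoricals_reduce_to_centering(self, rng):
        n = 4000
        cov = self._covariates(rng, n, constant=True)
        y = rng.normal(5, 1, n)  # independent of rin
        resid = residualize_gene(y, cov)
        assert np.allclose(resid, y - y.mean(), atol=0.05)

    def test_orthogonal_to_design(self, rng):
        n = 50
        cov = self._covariates(rng, n)
        y = rng.normal(size=n)
        resid = residualize_gene(y, cov)
        assert abs(resid.mean()) < 1e-10
        assert abs(resid @ cov["rin"].to_numpy()) / n < 1e-8

    def test_six_sample_normal_equations_oracle(self):
        cov = pd.DataFrame({"rin": [6.5, 7.2, 8.1, 9.0, 7.7, 8.8],
                            "sex": ["F", "M", "F", "M", "F", "M"],
                            "ethnicity": ["E1", "E1", "E2", "E2", "E1", "E2"]})
        y = np.array([1.0, 2.5, 0.7, 3.1, 1.9, 2.2])
        X = np.column_stack([np.ones(6), cov["rin"],
                             (cov["sex"] == "M").astype(float),
                             (cov["ethnicity"] == "E2").astype(float)])
        assert np.allclose(residualize_gene(y, cov), _pinv_residuals(y, X),
                           atol=1e-10)

    def test_missing_covariate_rejected(self):
        cov = pd.DataFrame({"rin": [7.0, np.nan, 8.0],
                            "sex": ["F", "M", "F"],
                            "ethnicity": ["E1", "E1", "E2"]})
        with pytest.raises(InputError):
            residualize_gene(np.ones(3), cov)


def _stage_oracle(table, stage):
    """Normal-equations + t-distribution oracle for the step-two model."""
    y = table["residual"].to_numpy(dtype=float)
    cols = [np.ones(len(table)), (table["stage"] == stage).to_numpy(float)]
    for level in sorted(table["region"].unique())[1:]:
        cols.append((table["region"] == level).to_numpy(float))
    X = np.column_stack(cols)
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * scipy.stats.t.sf(abs(t), dof)
    return beta[1], p


class TestStageModel:
    def _table(self, residuals, stages, regions=None):
        n = len(residuals)
        return pd.DataFrame({
            "gene": ["G1"] * n, "sample_id": [f"S{i}" for i in range(n)],
            "residual": residuals, "stage": stages,
            "region": regions if regions is not None else ["R1"] * n,
        })

    def test_single_region_effect_is_difference_of_group_means(self, rng):
        resid = rng.normal(size=12)
        stages = ["infancy"] * 5 + ["adulthood"] * 7
        effect, _ = stage_model(self._table(resid, stages), "infancy")
        expected = resid[:5].mean() - resid[5:].mean()
        assert effect == pytest.approx(expected, abs=1e-12)

    def test_twelve_row_two_region_oracle(self, rng):
        table = self._table(
            rng.normal(size=12),
            ["infancy"] * 4 + ["childhood"] * 4 + ["adulthood"] * 4,
            regions=list(rng.choice(["cortex", "striatum"], 12)))
        effect, p = stage_model(table, "childhood")
        eff_o, p_o = _stage_oracle(table, "childhood")
        assert effect == pytest.approx(eff_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_missing_stage_rejected(self, rng):
        table = self._table(rng.normal(size=6), ["a"] * 3 + ["b"] * 3)
        with pytest.raises(InputError, match="absent"):
            stage_model(table, "c")

    def test_single_stage_table_rejected(self, rng):
        table = self._table(rng.normal(size=6), ["a"] * 6)
        with pytest.raises(InputError):
            stage_model(table, "a")


class TestRunStageAnalysis:
    def test_one_row_per_stage_and_bh_dominates(self):
        sim = generate_bulk(BulkSimConfig(seed=3, n_genes=44,
                                          n_donors_per_stage=3, regions=("A",)))
        res = run_stage_analysis(sim.dataset, sim.target_genes)
        assert list(res.effects["stage"]) == list(BulkSimConfig().stages)
        assert (res.effects["p_fdr"] >= res.effects["p"] - 1e-15).all()
        assert np.allclose(np.abs(res.effects["signed_neg_log10_fdr"]),
                           -np.log10(res.effects["p_fdr"]))

    def test_missing_genes_reported_and_all_missing_errors(self):
        sim = generate_bulk(BulkSimConfig(seed=3, n_genes=44,
                                          n_donors_per_stage=2, regions=("A",)))
        res = run_stage_analysis(sim.dataset, list(sim.target_genes[:5]) + ["NOPE"])
        assert res.genes_missing == ["NOPE"]
        with pytest.raises(InputError, match="NOPE"):
            run_stage_analysis(sim.dataset, ["NOPE"])

    def test_residuals_orthogonal_to_rin_per_gene(self):
        sim = generate_bulk(BulkSimConfig(seed=6, n_genes=44, n_donors_per_stage=4))
        res = run_stage_analysis(sim.dataset, sim.target_genes[:10])
        meta = sim.dataset.samples
        kept = meta[meta["rin"] >= 7]
        rin = kept["rin"].to_numpy()
        for gene, grp in res.residuals.groupby("gene"):
            r = grp.set_index("sample_id").loc[kept.index, "residual"].to_numpy()
            corr = np.corrcoef(r, rin)[0, 1]
            assert abs(corr) < 1e-8

    def test_larger_planted_effect_never_raises_p(self):
        ps = []
        for eff in (0.3, 0.6, 1.2):
            sim = generate_bulk(BulkSimConfig(
                seed=11, n_genes=44, n_donors_per_stage=4,
                stage_effects={"adulthood": eff}))
            res = run_stage_analysis(sim.dataset, sim.target_genes)
            ps.append(res.effects.set_index("stage").loc["adulthood", "p"])
        assert ps[0] >= ps[1] >= ps[2]
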