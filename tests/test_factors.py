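import numpy as np
import pandas as pd
import pytest
from statsmodels.multivariate.factor_rotation import rotate_factors

from latentq.factors import (
    assign_quartiles,
    efa_stressors,
    extract_profile,
    quartile_descriptives,
    varimax,
    varimax_criterion,
)
from latentq.synthetic import (
    PERSONAL_DOMAINS,
    SOCIOECONOMIC_DOMAINS,
    default_truth,
    generate_dataset,
)


def _equicorrelated(n, r, k=3, seed=0):
    rng = np.random.default_rng(seed)
    cov = np.full((k, k), r)
    np.fill_diagonal(cov, 1.0)
    return pd.DataFrame(
        rng.multivariate_normal(np.zeros(k), cov, size=n),
        columns=[f"v{i}" for i in range(k)],
    )


class TestExtractProfile:
    def test_uncorrelated_columns_explain_one_third(self):
        df = _equicorrelated(20000, 0.0)
        sol = extract_profile(df)
        assert sol.variance_explained == pytest.approx(100 / 3, abs=1.5)

    @pytest.mark.parametrize("r", [0.3, 0.6889])
    def test_equicorrelation_closed_form(self, r):
        df = _equicorrelated(50000, r, seed=4)
        sol = extract_profile(df)
        z = (df - df.mean()) / df.std(ddof=0)
        r_bar = np.mean(np.corrcoef(z.T)[np.triu_indices(3, 1)])
        assert sol.variance_explained == pytest.approx(
            100 * (1 + 2 * r_bar) / 3, abs=0.1
        )

    def test_collinear_columns_explain_everything(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=500)
        df = pd.DataFrame({"a": base, "b": 2 * base + 1, "c": -0.5 * base})
        sol = extract_profile(df)
        assert sol.variance_explained == pytest.approx(100.0, abs=1e-6)

    def test_scores_standardized_and_loadings_positive(self):
        df = _equicorrelated(2000, 0.5, seed=9)
        sol = extract_profile(df)
        s = sol.factor_scores["profile"].to_numpy()
        assert s.mean() == pytest.approx(0.0, abs=1e-8)
        assert s.var() == pytest.approx(1.0, abs=1e-8)
        assert (sol.loadings["profile"] > 0).all()

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            extract_profile(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]}))


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        lam = np.array([[0.8, 0.0], [0.7, 0.0], [0.0, 0.9], [0.0, 0.6]])
        rotated, _ = varimax(lam)
        # recovered up to column sign/permutation
        recov = np.abs(rotated)
        target = np.abs(lam)
        perm = recov[:, [0, 1]] if recov[0, 0] > recov[0, 1] else recov[:, [1, 0]]
        assert np.allclose(perm, target, atol=1e-6)

    def test_two_by_two_grid_search_oracle(self):
        lam = np.array([[0.7, 0.7], [0.7, -0.7]])
        rotated, _ = varimax(lam, normalize=False)
        angles = np.linspace(0, np.pi / 2, 20001)
        best = max(
            varimax_criterion(
                lam
                @ np.array(
                    [[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]
                )
            )
            for a in angles
        )
        assert varimax_criterion(rotated) == pytest.approx(best, abs=1e-8)
        assert varimax_criterion(rotated) > varimax_criterion(lam)

    def test_criterion_never_decreases(self, rng):
        for _ in range(5):
            lam = rng.normal(size=(8, 3))
            rotated, _ = varimax(lam, normalize=False)
            assert varimax_criterion(rotated) >= varimax_criterion(lam) - 1e-12

    def test_rotation_matrix_orthonormal(self, rng):
        lam = rng.normal(size=(11, 2))
        _, rot = varimax(lam)
        assert np.max(np.abs(rot.T @ rot - np.eye(2))) < 1e-10

    def test_matches_statsmodels_criterion(self, rng):
        lam = rng.normal(size=(10, 2))
        mine, _ = varimax(lam, normalize=False)
        theirs, _ = rotate_factors(lam, "varimax")
        assert varimax_criterion(mine) == pytest.approx(
            varimax_criterion(theirs), abs=1e-8
        )

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            varimax(np.ones((5, 1)))


class TestEfaStressors:
    def test_block_structure_recovered(self):
        t = default_truth(n=1000, seed=77)
        ind, _, _ = generate_dataset(t)
        sol = efa_stressors(ind[SOCIOECONOMIC_DOMAINS + PERSONAL_DOMAINS])
        assert sol.n_factors == 2
        groups = {0: set(), 1: set()}
        for dom, f in sol.assignment.items():
            groups[f].add(dom)
        assert {frozenset(groups[0]), frozenset(groups[1])} == {
            frozenset(SOCIOECONOMIC_DOMAINS),
            frozenset(PERSONAL_DOMAINS),
        }

    def test_eigenvalues_sum_to_dimension(self):
        t = default_truth(n=500, seed=3)
        ind, _, _ = generate_dataset(t)
        sol = efa_stressors(ind[SOCIOECONOMIC_DOMAINS + PERSONAL_DOMAINS])
        assert sol.eigenvalues.sum() == pytest.approx(11.0, abs=1e-9)

    def test_scaling_invariance(self):
        t = default_truth(n=800, seed=12)
        ind, _, _ = generate_dataset(t)
        df = ind[SOCIOECONOMIC_DOMAINS + PERSONAL_DOMAINS]
        scaled = df * np.linspace(1, 20, 11)
        a = efa_stressors(df)
        b = efa_stressors(scaled)
        assert a.variance_explained == pytest.approx(b.variance_explained, abs=1e-9)

    def test_single_factor_data_degenerates_with_warning(self, rng):
        # one strong common factor: only one eigenvalue exceeds 1, so the
        # eigenvalue>1 auto rule degenerates and must say so
        f = rng.standard_normal(500)
        df = pd.DataFrame(
            {f"v{i}": 0.95 * f + 0.2 * rng.standard_normal(500) for i in range(6)}
        )
        with pytest.warns(RuntimeWarning, match="fewer than 2"):
            sol = efa_stressors(df)
        assert sol.n_factors == 1

    def test_rotation_preserves_communalities(self):
        t = default_truth(n=900, seed=5)
        ind, _, _ = generate_dataset(t)
        df = ind[SOCIOECONOMIC_DOMAINS + PERSONAL_DOMAINS]
        z = (df - df.mean()) / df.std(ddof=0)
        r = np.corrcoef(z.T)
        eigvals, eigvecs = np.linalg.eigh(r)
        order = np.argsort(eigvals)[::-1][:2]
        unrot = eigvecs[:, order] * np.sqrt(eigvals[order])
        rot, _ = varimax(unrot)
        assert np.allclose(
            (unrot**2).sum(axis=1), (rot**2).sum(axis=1), atol=1e-8
        )

    def test_paf_extraction_runs(self):
        t = default_truth(n=800, seed=21)
        ind, _, _ = generate_dataset(t)
        sol = efa_stressors(
            ind[SOCIOECONOMIC_DOMAINS + PERSONAL_DOMAINS], extraction="paf"
        )
        assert sol.loadings.shape == (11, sol.n_factors)


class TestQuartiles:
    def test_tie_goes_to_lower_quartile(self):
        scores = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0])
        q = assign_quartiles(scores)
        # boundaries are q25=1, q75=2; tied scores stay in the lower quartile
        assert q.tolist() == [1, 1, 1, 1, 3, 3, 3, 3]

    def test_monotone_variable_has_increasing_means(self, rng):
        scores = rng.normal(size=400)
        df = pd.DataFrame({"same": scores})
        rep = quartile_descriptives(df, scores, categorical=[])
        means = [float(rep.loc["same", f"Q{q}"].split(" ±")[0]) for q in (1, 2, 3, 4)]
        assert means == sorted(means)
        assert rep.loc["same", "p_value"] < 1e-10

    def test_constant_variable_not_applicable(self, rng):
        scores = rng.normal(size=100)
        df = pd.DataFrame({"const": np.ones(100)})
        rep = quartile_descriptives(df, scores, categorical=[])
        assert np.isnan(rep.loc["const", "p_value"])
        assert "constant" in rep.loc["const", "note"]

    def test_categorical_zero_cell_flagged(self, rng):
        scores = np.arange(100.0)
        flag = (scores >= 75).astype(int)  # absent from Q1-Q3
        rep = quartile_descriptives(
            pd.DataFrame({"flag": flag}), scores, categorical=["flag"]
        )
        assert "zero cell" in rep.loc["flag", "note"]
        assert rep.loc["flag", "p_value"] < 0.05

    def test_independent_variable_p_uniformish(self, rng):
        pvals = []
        for _ in range(200):
            scores = rng.normal(size=120)
            x = rng.normal(size=120)
            rep = quartile_descriptives(
                pd.DataFrame({"x": x}), scores, categorical=[]
            )
            pvals.append(rep.loc["x", "p_value"])
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01
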