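import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methgex.data_io import BetaMatrix, ExpressionMatrix, ProbeAnnotation
from methgex.preprocess import (bin_expression_profile, compute_beta,
                                impute_knn, normalize_expression,
                                quantile_normalize, sd_filter,
                                select_extreme_probes)
from methgex.simulate import GeneratorConfig, generate_dataset


class TestComputeBeta:
    @pytest.mark.parametrize("M,U,expected", [
        (100, 0, 0.5),
        (0, 0, 0.0),
        (-10, 50, 0.0),   # negative methylated signal floored at zero
        (900, 0, 0.9),
    ])
    def test_known_values(self, M, U, expected):
        assert compute_beta(M, U) == pytest.approx(expected, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(np.inf, 1.0)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6),
           st.floats(0.1, 1e4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, M, U, dm):
        b = compute_beta(M, U)
        assert 0.0 <= b < 1.0
        assert compute_beta(M + dm, U) >= b   # increasing in M
        assert compute_beta(M, U + dm) <= b   # decreasing in U


def _bm(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


class TestImputeKnn:
    def test_complete_matrix_unchanged(self):
        bm = _bm([[0.1, 0.2], [0.3, 0.4]])
        out = impute_knn(bm, k=1)
        pd.testing.assert_frame_equal(out.values, bm.values)

    def test_nearest_neighbour_value_used(self):
        # probe a misses s2; probe b is nearest on the shared sample s1
        bm = _bm([[0.10, np.nan],
                  [0.12, 0.30],
                  [0.90, 0.80]], probes=["a", "b", "c"],
                 samples=["s1", "s2"])
        out = impute_knn(bm, k=1)
        assert out.values.loc["a", "s1"] == 0.10  # observed cell untouched
        assert out.values.loc["a", "s2"] == 0.30

    def test_k_larger_than_available_uses_all(self):
        bm = _bm([[0.1, np.nan], [0.2, 0.4], [0.3, 0.6]])
        out = impute_knn(bm, k=50)
        assert out.values.iloc[0, 1] == pytest.approx(0.5)

    def test_brute_force_agreement_on_random_matrix(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(30, 8))
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        k = 4
        out = impute_knn(_bm(Xm), k=k).values.to_numpy()
        obs = ~np.isnan(Xm)
        for i, j in np.argwhere(mask):
            dists = []
            for r in range(X.shape[0]):
                if r == i or not obs[r, j]:
                    continue
                shared = obs[r] & obs[i]
                if not shared.any():
                    continue
                d = np.sqrt(((Xm[r, shared] - Xm[i, shared]) ** 2).sum())
                dists.append((d, r))
            dists.sort()
            expected = np.mean([Xm[r, j] for _, r in dists[:k]])
            assert out[i, j] == pytest.approx(expected, abs=1e-12)


class TestNormalizeExpression:
    def test_identical_sorted_columns_are_fixed_point(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_hand_computed_column_sorted_means(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = [2.5, 3.5, 4.5]
        assert list(out["a"]) == expected
        assert list(out["b"]) == expected

    def test_probe_medians_zero_after_baseline(self):
        rng = np.random.default_rng(3)
        em = ExpressionMatrix(pd.DataFrame(
            rng.normal(7, 1, size=(50, 9)),
            index=[f"p{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(9)]))
        out = normalize_expression(em)
        assert np.allclose(out.values.median(axis=1), 0.0, atol=1e-12)
        sorted_cols = np.sort(quantile_normalize(em.values).to_numpy(),
                              axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])

    def test_non_positive_value_under_log2_names_cell(self):
        em = ExpressionMatrix(pd.DataFrame([[4.0, 0.0]], index=["p1"],
                                           columns=["s1", "s2"]))
        with pytest.raises(ValueError, match="p1.*s2"):
            normalize_expression(em, log2_transform=True)


def _ann(meth_map, expr_map):
    meth = pd.DataFrame(
        {"entrez_id": list(meth_map.values()),
         "symbol": ["G"] * len(meth_map),
         "cgi_flag": [False] * len(meth_map),
         "prc2_flag": [False] * len(meth_map)},
        index=pd.Index(list(meth_map), name="probe_id"))
    expr = pd.DataFrame(
        {"entrez_id": list(expr_map.values()),
         "symbol": ["G"] * len(expr_map)},
        index=pd.Index(list(expr_map), name="probe_id"))
    return ProbeAnnotation(meth=meth, expr=expr)


class TestBinProfile:
    def test_single_bin_case(self):
        beta = _bm([[0.12] * 4], probes=["cg1"],
                   samples=["s1", "s2", "s3", "s4"])
        expr = ExpressionMatrix(pd.DataFrame(
            [[5.0] * 4], index=["e1"], columns=["s1", "s2", "s3", "s4"]))
        prof = bin_expression_profile(beta, expr,
                                      _ann({"cg1": "g"}, {"e1": "g"}))
        assert prof.mean_max_expr[2] == pytest.approx(5.0)
        assert prof.n_observations[2] == 4
        assert prof.n_observations.sum() == 4

    def test_maximum_over_gene_probes(self):
        beta = _bm([[0.12]], probes=["cg1"], samples=["s1"])
        expr = ExpressionMatrix(pd.DataFrame(
            [[3.0], [7.0]], index=["e1", "e2"], columns=["s1"]))
        prof = bin_expression_profile(
            beta, expr, _ann({"cg1": "g"}, {"e1": "g", "e2": "g"}))
        assert prof.mean_max_expr[2] == pytest.approx(7.0)

    def test_hand_binned_means(self):
        beta = _bm([[0.02, 0.97], [0.04, 0.99]], probes=["cg1", "cg2"],
                   samples=["s1", "s2"])
        expr = ExpressionMatrix(pd.DataFrame(
            [[8.0, 2.0], [6.0, 4.0]], index=["e1", "e2"],
            columns=["s1", "s2"]))
        prof = bin_expression_profile(
            beta, expr, _ann({"cg1": "g1", "cg2": "g2"},
                             {"e1": "g1", "e2": "g2"}))
        assert prof.mean_max_expr[0] == pytest.approx(7.0)
        assert prof.mean_max_expr[19] == pytest.approx(3.0)

    def test_observation_counts_conserved(self, small_cohort):
        ds = small_cohort
        expr_samples = [s for s in ds.beta.sample_ids
                        if s in set(ds.expr.sample_ids)]
        beta = BetaMatrix(ds.beta.values[expr_samples])
        prof = bin_expression_profile(beta, ds.expr, ds.ann)
        meth_genes = ds.ann.meth_genes()
        expr_genes = set(ds.ann.expr_genes())
        linked = [p for p in beta.probe_ids
                  if meth_genes.get(p, "") in expr_genes]
        n_missing = int(beta.values.loc[linked].isna().to_numpy().sum())
        assert prof.n_observations.sum() == \
            len(linked) * len(expr_samples) - n_missing

    def test_recovers_suppression_shape(self):
        # expression depends on beta only through the planted linear slope,
        # so extreme-beta bins must bracket the middle bins
        cfg = GeneratorConfig(n_probes=400, n_genes=300, n_dm_hyper=0,
                              n_dm_hypo=0, n_regulated=80, n_linked=0,
                              n_de_up=0, n_de_down=0, missing_rate=0.0)
        ds = generate_dataset(cfg, seed=5)
        expr_samples = [s for s in ds.beta.sample_ids
                        if s in set(ds.expr.sample_ids)]
        reg = sorted(ds.truth.regulated_probes)
        beta = BetaMatrix(ds.beta.values.loc[reg, expr_samples])
        prof = bin_expression_profile(beta, ds.expr, ds.ann)
        low = np.nanmean(prof.mean_max_expr[1:3])    # beta in [0.05, 0.15)
        high = np.nanmean(prof.mean_max_expr[17:19])  # beta in [0.85, 0.95)
        mid = np.nanmean(prof.mean_max_expr[8:12])
        assert low > mid > high


class TestProbeFilters:
    def test_never_extreme_probe_excluded(self):
        bm = _bm([[0.5] * 6])
        assert select_extreme_probes(bm) == set()

    def test_three_low_samples_select(self):
        bm = _bm([[0.10, 0.12, 0.14, 0.5, 0.5, 0.5]])
        assert select_extreme_probes(bm) == {"p0"}

    def test_tails_counted_separately(self):
        bm = _bm([[0.10, 0.12, 0.95, 0.5, 0.5, 0.5]])
        assert select_extreme_probes(bm) == set()

    def test_constant_probe_never_passes_sd(self):
        bm = _bm([[0.4] * 5])
        assert sd_filter(bm, 0.01, inclusive=True) == set()

    def test_alternating_probe_sd(self):
        bm = _bm([[0.0, 1.0, 0.0, 1.0]])
        assert sd_filter(bm, 0.15, inclusive=False) == {"p0"}
        sd = bm.values.std(axis=1, ddof=1).iloc[0]
        assert sd == pytest.approx(0.57735, abs=1e-5)

    def test_boundary_inclusive_vs_strict(self):
        vals = [0.25, 0.5, 0.75]  # sample SD exactly 0.25 (binary-exact)
        bm = _bm([vals])
        assert sd_filter(bm, 0.25, inclusive=True) == {"p0"}
        assert sd_filter(bm, 0.25, inclusive=False) == set()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            sd_filter(_bm([[0.1]]), 0.1, inclusive=True)
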