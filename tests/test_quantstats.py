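"""Variance components, heritability, correlations and progeny BLUPs."""

import numpy as np
import pandas as pd
import pytest

from tetrags import (
    SimConfig,
    VarianceComponents,
    cv_g,
    fit_variance_components,
    genetic_correlation,
    heritability_broad,
    heritability_single_condition,
    phenotypic_correlations,
    progeny_blups,
    simulate_phenotypes,
    simulate_population,
)
from tetrags.quantstats import _ems_components, _reml_components, is_balanced


def _toy_table() -> pd.DataFrame:
    """4 progenies x 2 conditions x 2 replicates with hand-checkable sums."""
    rows = []
    rng = np.random.default_rng(0)
    g = {"p1": -1.5, "p2": -0.5, "p3": 0.5, "p4": 1.5}
    for prog, gv in g.items():
        for cond in ("c1", "c2"):
            ge = rng.normal(0, 0.5)
            for rep in ("r1", "r2"):
                rows.append(
                    {
                        "progeny": prog,
                        "condition": cond,
                        "replicate": rep,
                        "trait": "t",
                        "value": gv + (1.0 if cond == "c2" else 0.0) + ge + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def _hand_ems(df: pd.DataFrame):
    """Independent expected-mean-squares oracle via direct sums of squares."""
    n = df["progeny"].nunique()
    c = df["condition"].nunique()
    k = df["replicate"].nunique()
    grand = df["value"].mean()
    pm = df.groupby("progeny")["value"].mean()
    cm = df.groupby("condition")["value"].mean()
    cell = df.groupby(["progeny", "condition"])["value"].mean()
    ms_p = c * k * ((pm - grand) ** 2).sum() / (n - 1)
    ss_pc = 0.0
    for (prog, cond), v in cell.items():
        ss_pc += (v - pm[prog] - cm[cond] + grand) ** 2
    ms_pc = k * ss_pc / ((n - 1) * (c - 1))
    ss_e = sum(
        (row["value"] - cell[(row["progeny"], row["condition"])]) ** 2
        for _, row in df.iterrows()
    )
    ms_e = ss_e / (n * c * (k - 1))
    return (ms_p - ms_pc) / (c * k), (ms_pc - ms_e) / k, ms_e


class TestVarianceComponents:
    def test_matches_hand_computed_mean_squares(self):
        df = _toy_table()
        vc = fit_variance_components(df)
        s2g, s2ge, s2e = _hand_ems(df)
        assert vc.sigma2_g == pytest.approx(max(s2g, 0.0))
        assert vc.sigma2_ge == pytest.approx(max(s2ge, 0.0))
        assert vc.sigma2_e == pytest.approx(s2e)

    def test_zero_variance_phenotype_gives_zero_components(self):
        df = _toy_table()
        df["value"] = 3.0
        vc = fit_variance_components(df)
        assert (vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e) == (0.0, 0.0, 0.0)

    def test_recovery_of_generating_components(self):
        """Mean estimates over replicate balanced simulations stay within
        10% of the generating (sigma2_g, sigma2_ge, sigma2_e) = (1, 0.5, 1)."""
        est = np.zeros(3)
        n_sim, n, c, k = 60, 100, 3, 3
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            y = (
                rng.normal(0, 1, (n, 1, 1))
                + rng.normal(0, np.sqrt(0.5), (n, c, 1))
                + rng.normal(0, 1, (n, c, k))
            )
            df = pd.DataFrame(
                {
                    "progeny": np.repeat([f"p{i}" for i in range(n)], c * k),
                    "condition": np.tile(np.repeat([f"c{j}" for j in range(c)], k), n),
                    "replicate": np.tile([f"r{r}" for r in range(k)], n * c),
                    "trait": "t",
                    "value": y.ravel(),
                }
            )
            vc = fit_variance_components(df)
            est += (vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e)
        assert np.all(np.abs(est / n_sim / np.array([1.0, 0.5, 1.0]) - 1.0) < 0.10)

    def test_ems_and_reml_agree_on_balanced_data(self):
        df = _toy_table()
        e = _ems_components(df)
        r = _reml_components(df)
        for a, b in [
            (e.sigma2_g, r.sigma2_g),
            (e.sigma2_ge, r.sigma2_ge),
            (e.sigma2_e, r.sigma2_e),
        ]:
            assert b == pytest.approx(a, rel=1e-6)

    def test_unbalanced_falls_back_to_reml_with_warning(self):
        df = _toy_table().drop(index=0)
        assert not is_balanced(df)
        with pytest.warns(UserWarning, match="unbalanced"):
            vc = fit_variance_components(df)
        assert vc.method == "reml"

    def test_single_condition_rejected(self):
        df = _toy_table()
        with pytest.raises(ValueError):
            fit_variance_components(df[df["condition"] == "c1"])


class TestDerivedStatistics:
    def test_cv_g_arithmetic(self):
        assert cv_g(4.0, 40.0) == pytest.approx(5.0)
        assert cv_g(0.0, 10.0) == 0.0
        assert cv_g(1.0, 1.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            cv_g(1.0, 0.0)

    def test_broad_sense_heritability_formula(self):
        vc = VarianceComponents(1.0, 1.0, 1.0, c=3, k=3)
        assert heritability_broad(vc) == pytest.approx(1 / (1 + 1 / 3 + 1 / 9))
        assert heritability_broad(VarianceComponents(0.0, 1.0, 1.0, 3, 3)) == 0.0
        assert heritability_broad(VarianceComponents(2.0, 0.0, 0.0, 3, 3)) == 1.0
        with pytest.raises(ValueError):
            heritability_broad(VarianceComponents(0.0, 0.0, 0.0, 3, 3))

    def test_heritability_monotone_in_components_and_design(self):
        base = heritability_broad(VarianceComponents(1.0, 1.0, 1.0, 3, 3))
        assert heritability_broad(VarianceComponents(2.0, 1.0, 1.0, 3, 3)) > base
        assert heritability_broad(VarianceComponents(1.0, 1.0, 1.0, 6, 3)) > base
        assert heritability_broad(VarianceComponents(1.0, 1.0, 1.0, 3, 6)) > base

    def test_single_condition_heritability(self):
        assert heritability_single_condition(1.0, 2.0, 2) == pytest.approx(0.5)

    def test_genetic_correlation_formula_and_cap(self):
        assert genetic_correlation(0.5, 0.5, 0.5) == pytest.approx(1.0)
        assert genetic_correlation(0.0, 0.4, 0.6) == 0.0
        # raw value above 1 is truncated, matching capped reported values
        assert genetic_correlation(0.9, 0.5, 0.5) == 1.0
        assert genetic_correlation(-0.9, 0.5, 0.5) == -1.0
        with pytest.raises(ValueError):
            genetic_correlation(0.5, 0.0, 0.5)


class TestProgenyBlups:
    def test_full_shrinkage_when_no_genetic_variance(self):
        df = _toy_table()
        rng = np.random.default_rng(5)
        df["value"] = rng.normal(0, 1, len(df))  # progeny effect absent
        vc = fit_variance_components(df)
        adj = progeny_blups(df)
        if vc.sigma2_g == 0.0:
            assert np.allclose(adj, df["value"].mean())
        h2 = 0.0 if vc.sigma2_g == 0 else heritability_broad(vc)
        raw = df.groupby("progeny")["value"].mean()
        assert np.all(
            np.abs(adj - adj.mean()) <= np.abs(raw - raw.mean()) + 1e-12
        )

    def test_blup_deviations_shrink_and_sum_to_zero(self, small_dataset):
        _, _, _, phenos, _ = small_dataset
        adj = progeny_blups(phenos)
        raw = phenos.groupby("progeny")["value"].mean().reindex(adj.index)
        dev = adj - adj.mean()
        assert abs(dev.sum()) < 1e-8
        assert np.all(np.abs(dev) <= np.abs(raw - raw.mean()) + 1e-12)

    def test_blups_estimate_truth_better_than_raw_means(self):
        """Shrinkage reduces mean-squared error against true breeding values;
        being a monotone transform of the progeny means, it never changes the
        ranking."""
        mse_adj_total = mse_raw_total = 0.0
        for seed in range(40):
            cfg = SimConfig(
                n_genotypes=50, n_markers=80, seed=seed, target_h2=0.3, n_reps=2
            )
            genos = simulate_population(cfg)
            phenos, truth = simulate_phenotypes(genos, cfg)
            adj = progeny_blups(phenos).reindex(genos.sample_ids)
            raw = phenos.groupby("progeny")["value"].mean().reindex(genos.sample_ids)
            g = truth.breeding_values
            mse_adj_total += np.mean((adj - adj.mean() - g) ** 2)
            mse_raw_total += np.mean((raw - raw.mean() - g) ** 2)
            if np.ptp(adj.values) > 1e-9:
                assert np.array_equal(np.argsort(adj.values), np.argsort(raw.values))
        assert mse_adj_total < mse_raw_total


class TestPhenotypicCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(2)
        t = pd.Series(rng.normal(size=30), index=[f"p{i}" for i in range(30)])
        corr = phenotypic_correlations({"a": t, "b": -t})
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_shared_qtl_traits_positively_correlated(self):
        cfg = SimConfig(n_genotypes=200, n_markers=100, n_qtl=20, seed=3, target_h2=0.8)
        genos = simulate_population(cfg)
        rng = np.random.default_rng(4)
        beta1 = np.zeros(100)
        beta2 = np.zeros(100)
        shared = rng.choice(100, 10, replace=False)
        own1 = rng.choice(np.setdiff1d(np.arange(100), shared), 10, replace=False)
        own2 = rng.choice(np.setdiff1d(np.arange(100), np.r_[shared, own1]), 10, replace=False)
        beta1[shared] = beta1[own1] = 1.0
        beta2[shared] = beta2[own2] = 1.0
        X = genos.dosage.astype(float)
        t1 = pd.Series(X @ beta1, index=genos.sample_ids)
        t2 = pd.Series(X @ beta2, index=genos.sample_ids)
        corr = phenotypic_correlations({"t1": t1, "t2": t2})
        se = 1 / np.sqrt(200 - 3)
        assert corr.loc["t1", "t2"] > 3 * se

    def test_constant_trait_flagged(self):
        t = pd.Series(np.arange(5.0), index=list("abcde"))
        const = pd.Series(np.ones(5), index=list("abcde"))
        with pytest.warns(UserWarning, match="constant"):
            corr = phenotypic_correlations({"x": t, "k": const})
        assert np.isnan(corr.loc["x", "k"])
        assert corr.loc["k", "k"] == 1.0
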