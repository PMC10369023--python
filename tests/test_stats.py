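"""Tests for the statistical battery, with independent rank-test oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from distsig.stats import (
    DegenerateDataError,
    distance_correlation_regression,
    dunn_posthoc,
    fit_random_intercept,
    kruskal_wallis,
    lmm_class_distance,
    ordered_quantile_normalize,
    permutation_r_band,
    range_normalize,
    species_median_correlations,
    wald_f_test,
    _categorical_design,
)

# ---------------------------------------------------------------------------
# brute-force rank oracle (no scipy rank helpers)


def brute_ranks(pooled):
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_kruskal(groups):
    pooled = [v for g in groups for v in g]
    ranks = brute_ranks(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (sum(r) / len(g)) ** 2
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def brute_dunn_z(groups):
    pooled = [v for g in groups for v in g]
    ranks = brute_ranks(pooled)
    n = len(pooled)
    means, sizes, start = [], [], 0
    for g in groups:
        r = ranks[start : start + len(g)]
        means.append(sum(r) / len(g))
        sizes.append(len(g))
        start += len(g)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = ((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j])) ** 0.5
            out[(i, j)] = (means[i] - means[j]) / se
    return out


def random_groups(rng, max_groups=4, discrete=True):
    k = rng.integers(2, max_groups + 1)
    gs = []
    for _ in range(k):
        size = rng.integers(3, 9)
        vals = rng.integers(0, 6, size) if discrete else rng.normal(size=size)
        gs.append(np.asarray(vals, dtype=float))
    return gs


class TestRangeNormalize:
    def test_basic(self):
        assert np.allclose(range_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_unit_interval(self):
        x = np.array([0.0, 0.3, 0.8, 1.0])
        assert np.allclose(range_normalize(x), x)

    def test_order_preserved(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(np.argsort(range_normalize(x)), np.argsort(x))

    def test_constant_error(self):
        with pytest.raises(DegenerateDataError):
            range_normalize([1.0, 1.0, 1.0])


class TestKruskalWallis:
    def test_hand_example(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.h == pytest.approx(2.4, abs=1e-12)
        assert res.df == 1

    def test_identical_groups_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.h == pytest.approx(0.0, abs=1e-12)

    def test_within_group_order_invariance(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=5)
        r1 = kruskal_wallis([a, b])
        r2 = kruskal_wallis([a[::-1], rng.permutation(b)])
        assert r1.h == pytest.approx(r2.h, abs=1e-12)

    def test_matches_brute_force(self, rng):
        checked = 0
        while checked < 100:
            gs = random_groups(rng)
            pooled = np.concatenate(gs)
            if np.all(pooled == pooled[0]):
                continue
            assert kruskal_wallis(gs).h == pytest.approx(
                brute_kruskal([list(g) for g in gs]), abs=1e-10
            )
            checked += 1

    def test_matches_scipy(self, rng):
        for _ in range(20):
            gs = random_groups(rng, discrete=False)
            mine = kruskal_wallis(gs)
            ref = sps.kruskal(*gs)
            assert mine.h == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1, 1], [1, 1]])
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1, 2]])


class TestDunn:
    def test_bonferroni_never_below_raw(self, rng):
        for _ in range(20):
            gs = random_groups(rng)
            if np.all(np.concatenate(gs) == gs[0][0]):
                continue
            tab = dunn_posthoc(gs)
            assert (tab["p_adj"] >= tab["p"] - 1e-15).all()
            assert (tab["p_adj"] <= 1.0).all()

    def test_separated_groups_significant(self):
        """Well-separated groups are detected, within the rank-test ceiling.

        With 10 observations per group the largest possible Dunn z between
        adjacent groups is fixed by the ranks alone (z = 2.54, Bonferroni
        p = 0.033), so adjacent pairs are checked at 0.05 and the extreme
        pair — whose rank separation is twice as large — at 0.01.
        """
        rng = np.random.default_rng(42)
        gs = [rng.normal(m, 0.1, 10) for m in (0.0, 5.0, 10.0)]
        tab = dunn_posthoc(gs).set_index(["group_a", "group_b"])
        assert tab.loc[("0", "2"), "p_adj"] < 0.01
        assert (tab["p_adj"] < 0.05).all()

    def test_z_antisymmetric(self, rng):
        a, b, c = (rng.normal(size=6) for _ in range(3))
        t1 = dunn_posthoc([a, b, c], labels=["a", "b", "c"])
        t2 = dunn_posthoc([b, a, c], labels=["b", "a", "c"])
        z1 = t1.set_index(["group_a", "group_b"])["z"]
        z2 = t2.set_index(["group_a", "group_b"])["z"]
        assert z1[("a", "b")] == pytest.approx(-z2[("b", "a")], abs=1e-12)

    def test_matches_brute_force(self, rng):
        checked = 0
        while checked < 100:
            gs = random_groups(rng, max_groups=5)
            pooled = np.concatenate(gs)
            if np.all(pooled == pooled[0]):
                continue
            tab = dunn_posthoc(gs)
            expect = brute_dunn_z([list(g) for g in gs])
            for (i, j), z in expect.items():
                row = tab[(tab.group_a == str(i)) & (tab.group_b == str(j))]
                assert row["z"].iloc[0] == pytest.approx(z, abs=1e-10)
            checked += 1


class TestOrderedQuantileNormalize:
    def test_monotone(self, rng):
        x = rng.normal(size=200)
        z = ordered_quantile_normalize(x)
        assert np.all(np.diff(z[np.argsort(x)]) >= 0)

    def test_near_normal_shape(self, rng):
        x = rng.exponential(size=1000)  # heavily skewed input
        z = ordered_quantile_normalize(x)
        assert abs(sps.skew(z)) < 0.05

    def test_symmetric_scores(self):
        z = ordered_quantile_normalize([1.0, 2.0, 3.0, 4.0])
        assert z[0] == pytest.approx(-z[3])
        assert z[1] == pytest.approx(-z[2])

    def test_min_size(self):
        with pytest.raises(DegenerateDataError):
            ordered_quantile_normalize([1.0, 2.0])


def _sim_records(rng, distance_effect=0.0, n_per=8, sigma_species=0.3, sigma=0.5):
    classes = ["NR"] * 3 + ["II"] * 4 + ["I_II"] * 6
    rows = []
    for s, cls in enumerate(classes):
        b = rng.normal(0, sigma_species)
        for _ in range(n_per):
            for k, d in enumerate((2.0, 5.0, 10.0, 30.0)):
                y = abs(2.0 + b + distance_effect * sigma * k + rng.normal(0, sigma))
                rows.append({"species": f"s{s:02d}", "defence_class": cls,
                             "distance_cm": d, "y": y})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_shift_invariance_of_distance_f(self, rng):
        df = _sim_records(rng)
        X, L, _ = _categorical_design(df, "distance_cm")
        y = df["y"].to_numpy()
        f1 = wald_f_test(fit_random_intercept(y, X, df["species"]), L)
        f2 = wald_f_test(fit_random_intercept(y + 7.0, X, df["species"]), L)
        assert f1.f == pytest.approx(f2.f, rel=1e-6)

    def test_power_with_injected_effect(self):
        rejections = 0
        for sim in range(20):
            rng = np.random.default_rng(500 + sim)
            df = _sim_records(rng, distance_effect=2.0)
            X, L, _ = _categorical_design(df, "distance_cm")
            fit = fit_random_intercept(df["y"].to_numpy(), X, df["species"])
            rejections += wald_f_test(fit, L).p < 0.05
        assert rejections >= 18  # power > 0.9 at this effect size

    def test_singular_fit_falls_back(self, rng):
        # no species variance at all -> boundary estimate
        df = _sim_records(rng, sigma_species=0.0)
        tab = lmm_class_distance(df, "y")
        assert set(tab["method"]) <= {"ols_fallback", "satterthwaite"}

    def test_df_method_robustness(self):
        """Reject/accept conclusions agree between Satterthwaite and
        residual denominator df at these group sizes."""
        for sim in range(5):
            rng = np.random.default_rng(900 + sim)
            df = _sim_records(rng, distance_effect=1.0)
            t_sat = lmm_class_distance(df, "y", ddf_method="satterthwaite")
            t_res = lmm_class_distance(df, "y", ddf_method="residual")
            assert np.array_equal(t_sat["p"] < 0.05, t_res["p"] < 0.05)

    def test_table_shape(self, rng):
        df = _sim_records(rng)
        tab = lmm_class_distance(df, "y")
        scopes = set(tab["scope"])
        assert {"class:NR", "class:II", "class:I_II"} <= scopes
        assert {"distance:2", "distance:5", "distance:10", "distance:30"} <= scopes
        assert (tab["p"].between(0, 1)).all()

    def test_class_test_small_denominator_df(self, rng):
        df = _sim_records(rng)
        tab = lmm_class_distance(df, "y")
        cls_rows = tab[tab["term"] == "defence_class"]
        sat = cls_rows[cls_rows["method"] == "satterthwaite"]
        if len(sat):  # between-species comparison: ddf near the species count
            assert (sat["df_den"] < 20).all()


def _metric_records(rng, coupling=1.0, noise=0.05):
    """Records whose metric medians are (noisily) monotone in u at close
    range and decoupled at 30 cm."""
    us = np.linspace(0, 1, 13)
    rows = []
    for s, u in enumerate(us):
        cls = "NR" if s < 3 else ("II" if s < 7 else "I_II")
        for i in range(5):
            for d in (2.0, 5.0, 10.0, 30.0):
                signal = coupling * u * max(0.0, 1.0 - d / 20.0)
                val = abs(0.5 + signal + rng.normal(0, noise))
                rows.append({"individual_id": f"s{s}_{i}", "species": f"s{s:02d}",
                             "defence_class": cls, "unpalatability": u,
                             "distance_cm": d,
                             "lum_detectability": val,
                             "col_detectability": val,
                             "lum_boldness": val, "col_boldness": val})
    return pd.DataFrame(rows)


class TestDistanceCorrelation:
    def test_per_distance_r_matches_independent_computation(self, rng):
        df = _metric_records(rng)
        table = species_median_correlations(df, metrics=("lum_detectability",))
        sub = df[df.distance_cm == 2.0]
        med = sub.groupby("species").agg(
            v=("lum_detectability", "median"), u=("unpalatability", "first")
        )
        # independent route: scipy rank-normal scores + pearson
        ranks = sps.rankdata(med["v"])
        scores = sps.norm.ppf((ranks - 0.5) / len(ranks))
        u = (med["u"] - med["u"].min()) / (med["u"].max() - med["u"].min())
        expect, _ = sps.pearsonr(scores, u)
        got = table[(table.distance_cm == 2.0)]["r"].iloc[0]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_regression_matches_hand_ols(self, rng):
        df = _metric_records(rng)
        per_d, reg = distance_correlation_regression(df, metrics=("col_boldness",))
        x = per_d["distance_cm"].to_numpy()
        y = per_d["r"].to_numpy()
        # closed-form OLS on the 4 (distance, R) points
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        ss_res = np.sum((y - intercept - slope * x) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot
        row = reg.iloc[0]
        assert row["slope"] == pytest.approx(slope, abs=1e-12)
        assert row["r_squared"] == pytest.approx(r2, abs=1e-12)
        assert row["df_num"] == 1 and row["df_den"] == 2
        assert row["f"] == pytest.approx(r2 * 2 / (1 - r2), rel=1e-9)

    def test_coupled_metric_declines_with_distance(self, rng):
        df = _metric_records(rng)
        _, reg = distance_correlation_regression(df, metrics=("lum_detectability",))
        assert reg["slope"].iloc[0] < 0

    def test_permuted_u_within_band(self):
        rng = np.random.default_rng(3)
        df = _metric_records(rng, coupling=0.0)
        table = species_median_correlations(df, metrics=("lum_boldness",))
        meds = df[df.distance_cm == 2.0].groupby("species")["lum_boldness"].median()
        u = np.linspace(0, 1, 13)
        lo, hi = permutation_r_band(meds.to_numpy(), u, n_perm=999, seed=0)
        inside = table["r"].between(lo, hi)
        assert inside.mean() >= 0.75  # 95% band, 4 distances

    def test_needs_four_species(self, rng):
        df = _metric_records(rng)
        df = df[df["species"].isin(["s00", "s01", "s02"])]
        with pytest.raises(DegenerateDataError):
            species_median_correlations(df)

    def test_constant_medians_dropped(self, rng):
        df = _metric_records(rng)
        df.loc[df.distance_cm == 30.0, "col_boldness"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_d, reg = distance_correlation_regression(df, metrics=("col_boldness",))
        assert 30.0 not in per_d["distance_cm"].values
        assert len(per_d) == 3 and len(reg) == 1
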