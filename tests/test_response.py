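"""Light-response model fits, slope extraction, ANOVA budget, heritability."""

import numpy as np
import pandas as pd
import pytest

import chlfpred as cp
from chlfpred.response import _fit_biomass


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_study):
    _, truth, records = noiseless_study
    fitted = cp.fit_response_model(records, variant="interaction")
    return truth, records, fitted


def test_noiseless_slopes_recovered_exactly(noiseless_fit):
    truth, _, fitted = noiseless_fit
    slopes = cp.extract_slopes(fitted).set_index("line")["slope"]
    expected = pd.Series(truth.true_slope.mean(axis=1), index=truth.line_ids)
    assert np.allclose(slopes.reindex(expected.index), expected, atol=1e-10)


def test_permuting_record_order_leaves_fit_unchanged(noiseless_fit):
    truth, records, fitted = noiseless_fit
    shuffled = records.sample(frac=1.0, random_state=3).reset_index(drop=True)
    refit = cp.fit_response_model(shuffled, variant="interaction")
    s1 = cp.extract_slopes(fitted).set_index("line")["slope"]
    s2 = cp.extract_slopes(refit).set_index("line")["slope"]
    assert np.allclose(s1.sort_index(), s2.sort_index(), atol=1e-12)


def test_too_few_lines_and_constant_ppfr_raise():
    df = pd.DataFrame(
        {
            "trial": "T1",
            "line": ["L1"] * 4,
            "timestamp": pd.Timestamp("2020-09-01"),
            "ppfr": [100.0, 200.0, 300.0, 400.0],
            "fqfm": [0.6, 0.58, 0.56, 0.54],
        }
    )
    with pytest.raises(cp.ResponseModelError, match="at least 2"):
        cp.fit_response_model(df, variant="basic")
    df2 = pd.concat([df, df.assign(line="L2", ppfr=250.0)], ignore_index=True)
    with pytest.raises(cp.ResponseModelError, match="L2"):
        cp.fit_response_model(df2, variant="basic")


# ---------------------------------------------------------------------------
# variance partition


def _balanced_biomass():
    # complete 4-line x 2-env x 2-rep design: env and line are orthogonal
    rows = []
    rng = np.random.default_rng(9)
    line_eff = {f"L{i}": i * 0.5 for i in range(4)}
    for env, env_eff in (("E1", 0.0), ("E2", 1.0)):
        for line, le in line_eff.items():
            for rep in range(2):
                rows.append(
                    {
                        "line": line,
                        "env": env,
                        "row": f"{env}-R{rep}",
                        "col": f"{env}-C{rep}",
                        "value": 10 + env_eff + le + rng.normal(0, 0.1),
                    }
                )
    return pd.DataFrame(rows)


def test_type_one_ss_order_invariant_under_orthogonality():
    fitted = _fit_biomass(_balanced_biomass())
    a = cp.variance_partition(fitted, order=["C(env)", "C(line)"]).set_index("term")
    b = cp.variance_partition(fitted, order=["C(line)", "C(env)"]).set_index("term")
    assert a.loc["C(line)", "sum_sq"] == pytest.approx(b.loc["C(line)", "sum_sq"], rel=1e-9)
    assert a.loc["C(env)", "sum_sq"] == pytest.approx(b.loc["C(env)", "sum_sq"], rel=1e-9)


def test_anova_budget_closes_to_machine_precision(noiseless_fit, small_study):
    _, _, fitted = noiseless_fit
    for f in (fitted, _fit_biomass(_balanced_biomass())):
        part = cp.variance_partition(f)
        y = np.asarray(f.result.model.endog, dtype=float)
        total = float(((y - y.mean()) ** 2).sum())
        assert part["sum_sq"].sum() == pytest.approx(total, rel=1e-12, abs=1e-9)
        assert part["explained_pct"].sum() == pytest.approx(100.0, abs=1e-8)
        assert (part["sum_sq"] > -1e-9).all()


def test_partition_order_changes_attribution_not_budget(small_study):
    records = cp.bands_to_indices(small_study["records"])
    kept, _ = cp.filter_records(records)
    fitted = cp.fit_response_model(kept, variant="interaction")
    default = cp.variance_partition(fitted)
    reordered = cp.variance_partition(fitted, order=list(reversed(fitted.term_names)))
    assert default["sum_sq"].sum() == pytest.approx(reordered["sum_sq"].sum(), rel=1e-12)
    assert int(default["df"].sum()) == int(reordered["df"].sum())


def test_unknown_partition_term_rejected(noiseless_fit):
    _, _, fitted = noiseless_fit
    with pytest.raises(cp.ResponseModelError, match="unknown"):
        cp.variance_partition(fitted, order=["C(banana)"])


# ---------------------------------------------------------------------------
# Cook's-distance screen


def test_planted_gross_outlier_is_screened(noiseless_study):
    _, _, records = noiseless_study
    corrupted = records.copy()
    corrupted.loc[17, "fqfm"] = 0.01
    fitted = cp.fit_response_model(corrupted, variant="basic")
    kept, n_removed = cp.cooks_screen(corrupted, fitted, factor=50.0)
    assert n_removed == 1
    assert 17 not in kept.index

    # independent oracle: statsmodels' Cook's distances flag the same point
    import statsmodels.api as sm

    res = fitted.result
    D = sm.OLS(res.model.endog, res.model.exog).fit().get_influence().cooks_distance[0]
    q1, med, q3 = np.percentile(D, [25, 50, 75])
    flagged = fitted.data.index[D > med + 50.0 * (q3 - q1)]
    assert list(flagged) == [17]


def test_infinite_factor_disables_screen(noiseless_fit):
    _, records, fitted = noiseless_fit
    kept, n_removed = cp.cooks_screen(records, fitted, factor=np.inf)
    assert n_removed == 0
    assert len(kept) == len(records)


def test_equal_influence_design_loses_nothing():
    # balanced 2-line x 2-light design; symmetric +/-c residuals in every cell
    rows = []
    for line, le in (("L1", 0.0), ("L2", -0.02)):
        for ppfr in (200.0, 800.0):
            for sgn in (1.0, -1.0):
                rows.append(
                    {
                        "trial": "T1",
                        "line": line,
                        "timestamp": pd.Timestamp("2020-09-01"),
                        "ppfr": ppfr,
                        "fqfm": 0.7 + le - 1e-4 * ppfr + sgn * 0.005,
                    }
                )
    df = pd.DataFrame(rows)
    fitted = cp.fit_response_model(df, variant="basic")
    _, n_removed = cp.cooks_screen(df, fitted, factor=50.0)
    assert n_removed == 0


# ---------------------------------------------------------------------------
# slope extraction semantics


def _two_line_records(shift=0.0):
    rng = np.random.default_rng(4)
    ppfr = np.tile(np.linspace(150, 1500, 30), 2)
    line = np.repeat(["L1", "L2"], 30)
    slope = np.where(line == "L1", -1e-4, -2e-4)
    fqfm = 0.75 - 1e-3 * np.sqrt(ppfr) + slope * ppfr + shift
    return pd.DataFrame(
        {
            "trial": "T1",
            "line": line,
            "timestamp": pd.Timestamp("2020-09-01"),
            "ppfr": ppfr,
            "fqfm": fqfm,
        }
    )


def test_known_slopes_extracted_exactly():
    fitted = cp.fit_response_model(_two_line_records(), variant="basic")
    s = cp.extract_slopes(fitted).set_index("line")
    assert s.loc["L1", "slope"] == pytest.approx(-1e-4, abs=1e-12)
    assert s.loc["L2", "slope"] == pytest.approx(-2e-4, abs=1e-12)
    assert (s["n_obs"] == 30).all()


def test_affine_equivariance_of_means_and_slopes():
    base = cp.extract_slopes(cp.fit_response_model(_two_line_records(), variant="basic"))
    shifted = cp.extract_slopes(
        cp.fit_response_model(_two_line_records(shift=0.05), variant="basic")
    )
    assert np.allclose(base["slope"], shifted["slope"], atol=1e-12)
    assert np.allclose(shifted["adjusted_mean"] - base["adjusted_mean"], 0.05, atol=1e-10)


def test_unknown_line_lookup_raises(noiseless_fit):
    _, _, fitted = noiseless_fit
    with pytest.raises(KeyError, match="not present"):
        cp.extract_slopes(fitted, lines=["NOPE"])


def test_per_trial_slopes_cover_grid(small_study):
    records = cp.bands_to_indices(small_study["records"])
    kept, _ = cp.filter_records(records)
    slopes = cp.per_trial_slopes(kept)
    cfg = small_study["config"]
    assert set(slopes["env"]) == set(cfg.env_ids)
    assert len(slopes) == cfg.n_lines * cfg.n_environments


def test_noisy_recovery_correlation(small_study):
    records = cp.bands_to_indices(small_study["records"])
    kept, _ = cp.filter_records(records)
    fitted = cp.fit_response_model(kept, variant="interaction")
    est = cp.extract_slopes(fitted).set_index("line")["slope"]
    truth = small_study["truth"]
    true_mean = pd.Series(truth.true_slope.mean(axis=1), index=truth.line_ids)
    r = np.corrcoef(est.reindex(true_mean.index), true_mean)[0, 1]
    assert r >= 0.9


# ---------------------------------------------------------------------------
# spatial adjustment


def test_adjusted_equals_raw_means_without_spatial_effects():
    df = _balanced_biomass()
    adj = cp.spatial_adjust(df).set_index("line")["adjusted_mean"]
    raw = df.groupby("line")["value"].mean()
    assert np.allclose(adj.sort_index(), raw.sort_index(), atol=1e-9)


def test_planted_row_gradient_recovered():
    rng = np.random.default_rng(12)
    n_lines, n_rows, reps = 10, 6, 3
    true = np.linspace(-1, 1, n_lines)
    rows = []
    for i in range(n_lines):
        for j in range(reps):
            r = (i + j) % n_rows  # systematic placement biases raw means
            rows.append(
                {
                    "line": f"L{i:02d}",
                    "row": f"R{r}",
                    "col": f"C{(i * reps + j) % 5}",
                    "value": 10 + true[i] + 0.8 * r,
                }
            )
    df = pd.DataFrame(rows)
    adj = cp.spatial_adjust(df).set_index("line")["adjusted_mean"].sort_index()
    raw = df.groupby("line")["value"].mean().sort_index()
    err_adj = np.abs((adj - adj.mean()) - true)
    err_raw = np.abs((raw - raw.mean()) - true)
    assert err_adj.max() < 1e-8
    assert err_raw.max() > 0.1


def test_balanced_two_line_toy_cancels_row_effect():
    df = pd.DataFrame(
        {
            "line": ["A", "A", "B", "B"],
            "row": ["R1", "R2", "R1", "R2"],
            "col": ["C1", "C2", "C2", "C1"],
            "value": [1.0, 2.0, 3.0, 4.0],  # row R2 adds +1 to both lines
        }
    )
    adj = cp.spatial_adjust(df).set_index("line")["adjusted_mean"]
    assert adj["B"] - adj["A"] == pytest.approx(2.0, abs=1e-9)


def test_confounded_line_warns():
    df = pd.DataFrame(
        {
            "line": ["A", "A", "B", "C"],
            "row": ["R1", "R1", "R2", "R2"],
            "col": ["C1", "C2", "C1", "C2"],
            "value": [1.0, 1.1, 2.0, 3.0],
        }
    )
    with pytest.warns(UserWarning, match="confounded"):
        cp.spatial_adjust(df)


# ---------------------------------------------------------------------------
# heritability


def test_heritability_closed_forms():
    assert cp.heritability(1.0, 1.0, 1.0) == pytest.approx(0.5)
    assert cp.heritability(1.0, 1.0, 1e12) == pytest.approx(1.0, abs=1e-9)
    assert cp.heritability(0.0, 1.0, 2.0) == 0.0


def test_heritability_monotone_in_replicates_and_line_variance():
    h = [cp.heritability(1.0, 2.0, n) for n in (1, 2, 4, 8)]
    assert all(b > a for a, b in zip(h, h[1:]))
    h2 = [cp.heritability(s, 2.0, 2.0) for s in (0.5, 1.0, 2.0)]
    assert all(b > a for a, b in zip(h2, h2[1:]))


def test_heritability_domain_errors():
    with pytest.raises(cp.ResponseModelError):
        cp.heritability(-1.0, 1.0, 1.0)
    with pytest.raises(cp.ResponseModelError):
        cp.heritability(0.0, 0.0, 1.0)
    with pytest.raises(cp.ResponseModelError):
        cp.heritability(1.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# quantile groups


def test_median_split_leaves_no_intermediate_group():
    rng = np.random.default_rng(5)
    s = pd.Series(rng.normal(size=40), index=[f"L{i}" for i in range(40)])
    t = pd.Series(rng.normal(size=40), index=s.index)
    with pytest.raises(cp.ResponseModelError):
        cp.quantile_group_compare(s, t, q=0.5)


def test_too_few_shared_lines_rejected():
    s = pd.Series([1.0] * 5, index=[f"L{i}" for i in range(5)])
    with pytest.raises(cp.ResponseModelError, match="10"):
        cp.quantile_group_compare(s, s, q=0.2)


def test_null_trait_rarely_significant():
    """Type-I control: independent trait and slope give p > 0.05 in >= 90% of runs."""
    rng = np.random.default_rng(42)
    n_sig = 0
    n_rep = 100
    for _ in range(n_rep):
        idx = [f"L{i}" for i in range(50)]
        s = pd.Series(rng.normal(size=50), index=idx)
        t = pd.Series(rng.normal(size=50), index=idx)
        res = cp.quantile_group_compare(s, t, q=0.2)
        row = res["tukey"][
            (res["tukey"]["group1"] == "lower") & (res["tukey"]["group2"] == "upper")
        ]
        if float(row["p-adj"].iloc[0]) < 0.05:
            n_sig += 1
    assert n_sig <= 0.1 * n_rep


def test_planted_slope_yield_link_orders_groups(small_study):
    truth = small_study["truth"]
    slopes = pd.Series(truth.true_slope.mean(axis=1), index=truth.line_ids)
    rng = np.random.default_rng(8)
    yields = pd.Series(
        truth.true_yield.mean(axis=1) + rng.normal(0, 0.1, len(truth.line_ids)),
        index=truth.line_ids,
    )
    res = cp.quantile_group_compare(slopes, yields, q=0.2)
    # shallower (upper-quantile) light response -> higher yield
    assert res["group_means"]["upper"] > res["group_means"]["lower"]
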