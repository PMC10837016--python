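"""Kinship, Gibbs sampler, cross-validation masking, association scan."""

import numpy as np
import pandas as pd
import pytest

import chlfpred as cp


def _toy_snp(dosages, line_prefix="L"):
    dosages = np.asarray(dosages, dtype=float)
    nl, nm = dosages.shape
    return cp.SNPMatrix(
        [f"{line_prefix}{i}" for i in range(nl)],
        [f"Chr01_{1000 + j}_{j}" for j in range(nm)],
        dosages,
    )


# ---------------------------------------------------------------------------
# MAF filter and kinship


def test_maf_filter_hand_counted_boundary():
    # per-marker allele frequencies 0.0, 0.04, 0.05, 0.3 on 50 lines
    n = 50
    cols = []
    for f in (0.0, 0.04, 0.05, 0.3):
        col = np.zeros(n)
        k = int(round(2 * n * f))
        col[:k] = 1.0
        cols.append(col)
    snp = _toy_snp(np.column_stack(cols))
    assert list(cp.maf(snp).round(3)) == [0.0, 0.04, 0.05, 0.3]
    kept = cp.maf_filter(snp, threshold=0.05)
    assert kept.n_markers == 2  # strict '<' at the boundary keeps MAF = 0.05


def test_maf_filter_all_removed_raises():
    snp = _toy_snp(np.zeros((5, 3)))
    with pytest.raises(cp.PredictionError):
        cp.maf_filter(snp)


def test_kinship_identical_lines_share_diagonal():
    rng = np.random.default_rng(1)
    base = rng.binomial(2, 0.3, size=(1, 30)).astype(float)
    dos = np.vstack([base, base, rng.binomial(2, 0.3, size=(2, 30))])
    K = cp.compute_kinship(_toy_snp(dos)).matrix
    assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)
    assert K[0, 1] == pytest.approx(K[1, 1], abs=1e-12)


def test_kinship_matches_direct_formula():
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, 10), size=(4, 10)).astype(float)
    K = cp.compute_kinship(_toy_snp(dos)).matrix
    p = dos.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    W = dos[:, keep] - 2 * p[keep]
    expected = W @ W.T / (2 * np.sum(p[keep] * (1 - p[keep])))
    assert np.allclose(K, expected, atol=1e-12)
    assert np.allclose(W.sum(axis=0), 0.0, atol=1e-9)


def test_monomorphic_markers_warn_and_drop():
    rng = np.random.default_rng(3)
    dos = rng.binomial(2, 0.4, size=(6, 5)).astype(float)
    dos[:, 0] = 2.0
    with pytest.warns(UserWarning, match="monomorphic"):
        K = cp.compute_kinship(_toy_snp(dos))
    assert K.matrix.shape == (6, 6)


# ---------------------------------------------------------------------------
# Gibbs sampler


@pytest.fixture(scope="module")
def toy_model_data():
    rng = np.random.default_rng(7)
    cfg = cp.SimulationConfig(n_lines=20, n_markers=100, seed=5)
    snp = cp.generate_population(cfg)
    K = cp.compute_kinship(cp.maf_filter(snp))
    L = np.linalg.cholesky(K.matrix + 1e-6 * np.eye(20))
    g = L @ rng.standard_normal(20)
    cells = pd.DataFrame(
        {"line": np.repeat(K.line_ids, 2), "env": ["E1", "E2"] * 20}
    )
    env_eff = np.where(cells["env"] == "E2", -0.5, 0.5)
    cells["value"] = env_eff + g[np.repeat(np.arange(20), 2)] + rng.normal(0, 1, 40)
    return K, cells


def test_gibbs_matches_blup_with_fixed_variances(toy_model_data):
    K, cells = toy_model_data
    spec = cp.GibbsSpec(
        model="genotype", iterations=5000, burn_in=1000, thin=1, seed=11,
        fixed_variances={"sigma_g2": 1.0, "sigma_e2": 1.0},
    )
    draws = cp.fit_prediction_model(cells, K, None, spec)
    blup = cp.blup_oracle(cells, K, 1.0, 1.0)
    dev = (draws.g_mean - blup).abs().max() / cells["value"].std()
    assert dev < 0.02


def test_chain_is_seed_reproducible(toy_model_data):
    K, cells = toy_model_data
    spec = cp.GibbsSpec(model="gxe", iterations=300, burn_in=100, thin=2, seed=9)
    a = cp.fit_prediction_model(cells, K, None, spec)
    b = cp.fit_prediction_model(cells, K, None, cp.GibbsSpec(
        model="gxe", iterations=300, burn_in=100, thin=2, seed=9))
    pd.testing.assert_frame_equal(a.var_draws, b.var_draws)
    pd.testing.assert_frame_equal(a.predictions, b.predictions)


def test_draw_count_and_positivity(toy_model_data):
    K, cells = toy_model_data
    spec = cp.GibbsSpec(model="genotype", iterations=500, burn_in=200, thin=5, seed=2)
    draws = cp.fit_prediction_model(cells, K, None, spec)
    assert draws.n_draws == (500 - 200 + 4) // 5
    assert (draws.var_draws > 0).all().all()


def test_constant_response_shrinks_genotype_effects(toy_model_data):
    K, cells = toy_model_data
    flat = cells.assign(value=3.0)
    spec = cp.GibbsSpec(model="genotype", iterations=800, burn_in=300, thin=2, seed=4)
    draws = cp.fit_prediction_model(flat, K, None, spec)
    assert draws.g_mean.abs().max() < 0.05
    # no genetic signal: the variance settles well below its prior mode
    assert draws.var_draws["sigma_g2"].mean() < 0.3


def test_gxec_requires_complete_covariate(toy_model_data):
    K, cells = toy_model_data
    cov = cells[["line", "env"]].copy()
    cov["value"] = 1.0
    cov = cov.iloc[:-3]  # drop some cells
    spec = cp.GibbsSpec(model="gxec", iterations=50, burn_in=10, thin=1, seed=1)
    with pytest.raises(cp.PredictionError, match="covariate"):
        cp.fit_prediction_model(cells, K, cov, spec)
    with pytest.raises(cp.PredictionError, match="covariate"):
        cp.fit_prediction_model(cells, K, None, spec)


def test_spec_validation():
    with pytest.raises(cp.PredictionError):
        cp.GibbsSpec(model="nope").validate()
    with pytest.raises(cp.PredictionError):
        cp.GibbsSpec(burn_in=100, iterations=50).validate()
    with pytest.raises(cp.PredictionError):
        cp.GibbsSpec(thin=0).validate()


# ---------------------------------------------------------------------------
# cross-validation


def test_partitions_cover_every_line_once_per_repetition():
    lines = [f"L{i}" for i in range(17)]
    folds = cp.cv_partitions(lines, reps=4, parts=3, seed=3)
    assert len(folds) == 12
    for rep in range(4):
        held = [l for r, p, chunk in folds if r == rep for l in chunk]
        assert sorted(held) == sorted(lines)


def test_masked_cells_never_in_training(toy_model_data):
    K, cells = toy_model_data
    lines = sorted(cells["line"].unique())
    folds = cp.cv_partitions(lines, reps=1, parts=3, seed=0)
    for f, (rep, part, held) in enumerate(folds):
        tgt = sorted(cells["env"].unique())[f % 2]
        mask = cells["line"].isin(held) & (cells["env"] == tgt)
        train = cells[~mask]
        masked = cells[mask]
        train_cells = set(zip(train["line"], train["env"]))
        masked_cells = set(zip(masked["line"], masked["env"]))
        assert not (train_cells & masked_cells)


def test_pure_noise_trait_has_null_accuracy():
    """Mean CV accuracy over several independent pure-noise traits sits at zero."""
    cfg = cp.SimulationConfig(n_lines=60, n_markers=200, seed=23)
    snp = cp.generate_population(cfg)
    K = cp.compute_kinship(cp.maf_filter(snp))
    accs = []
    for s in range(6):
        rng = np.random.default_rng(100 + s)
        cells = pd.DataFrame(
            {
                "line": np.repeat(K.line_ids, 2),
                "env": ["E1", "E2"] * 60,
                "value": rng.normal(size=120),
            }
        )
        spec = cp.GibbsSpec(model="genotype", iterations=400, burn_in=150, thin=2, seed=3 + s)
        res = cp.cross_validate(cells, K, None, spec, "CV1", reps=2, parts=3, seed=5 + s)
        accs.extend(res.accuracies)
    se = np.std(accs, ddof=1) / np.sqrt(len(accs))
    assert abs(np.mean(accs)) <= max(2 * se, 0.1)


def test_cv_scenario_validation(toy_model_data):
    K, cells = toy_model_data
    with pytest.raises(cp.PredictionError):
        cp.cross_validate(cells, K, None, cp.GibbsSpec(), "CV9")


# ---------------------------------------------------------------------------
# association scan


def test_marker_identical_trait_is_top_hit():
    rng = np.random.default_rng(31)
    dos = rng.binomial(2, rng.uniform(0.2, 0.5, 50), size=(40, 50)).astype(float)
    snp = cp.maf_filter(_toy_snp(dos))
    target = 10
    trait = pd.Series(snp.dosages[:, target], index=snp.line_ids)
    scan, threshold = cp.association_scan(trait, snp)
    top = scan.nsmallest(1, "p").iloc[0]
    assert top["marker"] == snp.marker_ids[target]
    assert top["p"] < threshold


def test_scan_needs_enough_lines():
    dos = np.random.default_rng(1).binomial(2, 0.4, size=(5, 10)).astype(float)
    snp = _toy_snp(dos)
    trait = pd.Series(np.arange(5, dtype=float), index=snp.line_ids)
    with pytest.raises(cp.PredictionError, match="lines"):
        cp.association_scan(trait, snp, n_pcs=3)


def test_scan_requires_complete_trait():
    dos = np.random.default_rng(2).binomial(2, 0.4, size=(30, 10)).astype(float)
    snp = _toy_snp(dos)
    trait = pd.Series(np.arange(29, dtype=float), index=snp.line_ids[:29])
    with pytest.raises(cp.PredictionError, match="missing"):
        cp.association_scan(trait, snp)
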