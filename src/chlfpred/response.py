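"""Linear-model family for the Fq'/Fm' light response and spatially adjusted traits.

The central quantity is the per-line light-response slope: in a fixed-effects
model of Fq'/Fm' with line, light and covariate terms, the line x PPFR
interaction coefficients give each genotype's seasonal response of PSII
operating efficiency to light (slope units: Fq'/Fm' per µmol photons
m^-2 s^-1).  A shallower (less negative) slope indicates higher light-use
efficiency.

Model variants
--------------
``basic``        y = mu + L + P + sqrt(P) + LP + e           (single trial)
``interaction``  adds trial main/interaction terms and the absorbance
                 (MTCI or relative chlorophyll) and reflectance covariates,
                 optionally a device effect                  (multi-trial)
``extended``     adds the auxiliary covariates (PRI, NDVI, chlorophyll,
                 temperature, measurement date)
``biomass``      y = E + L + LE + row + column + e           (spatial adjust)

The main light effects carry both a linear and a square-root term (the
response flattens at high light); the line-specific part is on linear PPFR,
so slopes have per-µmol units.  A ``sqrt_interaction`` switch moves the
interaction onto sqrt(PPFR) instead.

Fits use ordinary least squares with treatment contrasts and a
pseudoinverse, so partially confounded designs (lines not present in every
trial) are handled the way unbalanced phenotyping data require; sequential
(Type-I) sums of squares are computed against explicit term orderings, and
adjusted means / marginal slopes follow estimated-marginal-means semantics
(covariates at their grand means, equal weight per trial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ResponseModelError",
    "FittedResponseModel",
    "fit_response_model",
    "variance_partition",
    "cooks_screen",
    "extract_slopes",
    "per_trial_slopes",
    "spatial_adjust",
    "heritability",
    "variance_components_trait",
    "variance_components_response",
    "heritability_from_trait",
    "heritability_from_slopes",
    "quantile_group_compare",
]

VARIANTS = ("basic", "interaction", "extended", "biomass")


class ResponseModelError(ValueError):
    """Raised for design problems: too few lines, constant light, bad variants."""


@dataclass
class FittedResponseModel:
    """An OLS fit plus the metadata needed for partitioning and extraction."""

    variant: str
    result: object  # statsmodels RegressionResults
    design_info: object  # patsy DesignInfo
    data: pd.DataFrame  # rows actually used in the fit (original index kept)
    response: str
    unit: str  # 'line' or 'plot' -- the genotype-bearing factor
    categorical_factors: dict  # factor name -> levels used
    numeric_means: dict  # covariate name -> grand mean

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.result.params)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    @property
    def term_names(self) -> list:
        return [t for t in self.design_info.term_names if t != "Intercept"]


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "ppfr" in df.columns:
        df["sqrt_ppfr"] = np.sqrt(df["ppfr"].clip(lower=0))
    if "timestamp" in df.columns:
        df["date"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%d")
    return df


def fit_response_model(
    records: pd.DataFrame,
    variant: str = "interaction",
    covariates: Optional[Sequence[str]] = None,
    include_device: bool = False,
    line_as_plot: bool = False,
    sqrt_interaction: bool = False,
    extra_terms: Sequence[str] = (),
) -> FittedResponseModel:
    """Fit one of the Fq'/Fm' model variants (or the biomass spatial model).

    ``covariates`` restricts/overrides the absorbance-and-reflectance
    covariate set; by default whichever of ``mtci``, ``chlorophyll`` and
    ``reflectance`` are present (non-null) enter the ``interaction`` and
    ``extended`` variants.  ``line_as_plot`` swaps the genotype factor for
    the plot factor, the field-trial convention for the basic model where
    spatial variability dominates.  ``extra_terms`` appends raw formula
    terms, which is how bespoke interaction structures are reproduced.
    """
    if variant not in VARIANTS:
        raise ResponseModelError(f"unknown variant '{variant}'; expected one of {VARIANTS}")

    if variant == "biomass":
        return _fit_biomass(records)

    df = _prepare(records)
    unit = "plot" if line_as_plot else "line"
    if unit not in df.columns:
        raise ResponseModelError(f"records lack the '{unit}' column")
    if df[unit].nunique() < 2:
        raise ResponseModelError("need at least 2 lines (or plots) to fit a response model")
    spread = df.groupby(unit)["ppfr"].std()
    flat = spread.index[(spread.fillna(0.0) == 0.0)]
    if len(flat):
        raise ResponseModelError(
            f"constant PPFR within {unit}(s) {list(flat[:5])}: slope not estimable"
        )

    pterm = "sqrt_ppfr" if sqrt_interaction else "ppfr"
    if variant == "basic":
        terms = [f"C({unit})", "ppfr", "sqrt_ppfr", f"{pterm}:C({unit})"]
        covs: list = []
    else:
        if covariates is None:
            covs = [c for c in ("mtci", "chlorophyll", "reflectance")
                    if c in df.columns and df[c].notna().any()]
        else:
            covs = list(covariates)
        multi_trial = df["trial"].nunique() > 1
        terms = []
        if multi_trial:
            terms.append("C(trial)")
        terms += ["ppfr", f"C({unit})"] + covs
        if multi_trial:
            terms.append(f"C(trial):C({unit})")
        terms += ["sqrt_ppfr", f"{pterm}:C({unit})"]
        if multi_trial:
            terms += [f"C(trial):{pterm}:C({unit})", "C(trial):ppfr"]
        if include_device and "device" in df.columns and df["device"].nunique() > 1:
            terms.append("C(device)")
        if variant == "extended":
            for c in ("pri", "ndvi", "temperature"):
                if c in df.columns and df[c].notna().any() and c not in covs:
                    terms.append(c)
            if "date" in df.columns and df["date"].nunique() > 1:
                terms.append("C(date)")
    terms += list(extra_terms)

    used_numeric = [t for t in ["ppfr", "sqrt_ppfr"] + covs if t in df.columns]
    for c in ("pri", "ndvi", "temperature"):
        if c in terms:
            used_numeric.append(c)
    needed = set(used_numeric) | {unit, "fqfm"}
    if any("trial" in t for t in terms):
        needed.add("trial")
    if any("device" in t for t in terms):
        needed.add("device")
    if any("date" in t for t in terms):
        needed.add("date")
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if len(df) == 0:
        raise ResponseModelError("no complete records left for the requested covariates")

    formula = "fqfm ~ " + " + ".join(terms)
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    res = sm.OLS(np.asarray(y).ravel(), np.asarray(X)).fit()

    cat = {}
    for name in ("trial", "device", "date"):
        if any(f"C({name})" in t for t in terms):
            cat[name] = sorted(df[name].unique())
    cat[unit] = sorted(df[unit].unique())
    means = {c: float(df[c].mean()) for c in set(used_numeric)}
    return FittedResponseModel(
        variant=variant,
        result=res,
        design_info=X.design_info,
        data=df,
        response="fqfm",
        unit=unit,
        categorical_factors=cat,
        numeric_means=means,
    )


def _fit_biomass(trait: pd.DataFrame) -> FittedResponseModel:
    df = trait.copy()
    for col in ("line", "row", "col", "value"):
        if col not in df.columns:
            raise ResponseModelError(f"trait table lacks the '{col}' column")
    multi_env = "env" in df.columns and df["env"].nunique() > 1
    terms = ["C(line)"]
    if multi_env:
        terms = ["C(env)", "C(line)", "C(env):C(line)"]
    terms += ["C(row)", "C(col)"]
    formula = "value ~ " + " + ".join(terms)
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    res = sm.OLS(np.asarray(y).ravel(), np.asarray(X)).fit()
    cat = {"line": sorted(df["line"].unique()),
           "row": sorted(df["row"].unique()),
           "col": sorted(df["col"].unique())}
    if multi_env:
        cat["env"] = sorted(df["env"].unique())
    return FittedResponseModel(
        variant="biomass",
        result=res,
        design_info=X.design_info,
        data=df,
        response="value",
        unit="line",
        categorical_factors=cat,
        numeric_means={},
    )


# ---------------------------------------------------------------------------
# variance partition (sequential / Type-I sums of squares)


def variance_partition(fitted: FittedResponseModel, order: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Sequential sums of squares in an explicit term order.

    Terms are added one block at a time; each term's SS is the drop in
    residual SS when its columns join the design, and its df the rank gained
    (which is how partially confounded interactions end up with fewer df
    than levels).  The budget closes exactly: term SS plus the residual row
    equal the total (centered) SS, and the explained percentages sum to 100.

    ``order`` may be any permutation (or subset -- the rest is appended in
    model order) of the fitted term names.
    """
    di = fitted.design_info
    slices = dict(di.term_name_slices)
    model_terms = [t for t in di.term_names if t != "Intercept"]
    if order is None:
        order = model_terms
    else:
        order = list(order)
        unknown = set(order) - set(model_terms)
        if unknown:
            raise ResponseModelError(f"unknown terms in partition order: {sorted(unknown)}")
        order += [t for t in model_terms if t not in order]

    X = np.asarray(fitted.result.model.exog)
    y = np.asarray(fitted.result.model.endog, dtype=float)
    total_ss = float(((y - y.mean()) ** 2).sum())

    cols: list = list(range(*slices["Intercept"].indices(X.shape[1]))) if "Intercept" in slices else []
    rank_prev = 1 if cols else 0
    rss_prev = total_ss
    rows = []
    for term in order:
        cols += list(range(*slices[term].indices(X.shape[1])))
        Xs = X[:, cols]
        beta, rss, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
        rss = float(((y - Xs @ beta) ** 2).sum())
        rows.append(
            {
                "term": term,
                "df": int(rank - rank_prev),
                "sum_sq": rss_prev - rss,
                "explained_pct": 100.0 * (rss_prev - rss) / total_ss,
            }
        )
        rss_prev, rank_prev = rss, rank
    rows.append(
        {
            "term": "Residuals",
            "df": int(len(y) - rank_prev),
            "sum_sq": rss_prev,
            "explained_pct": 100.0 * rss_prev / total_ss,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# influence screening


def cooks_screen(
    records: pd.DataFrame,
    fitted: FittedResponseModel,
    factor: float = 50.0,
) -> tuple[pd.DataFrame, int]:
    """Single-pass Cook's-distance screen for gross measurement errors.

    An observation is discarded when its Cook's distance exceeds the median
    distance by more than ``factor`` times the interquartile range of the
    distances -- an intentionally permissive cut that only removes points
    with leverage-weighted influence far outside the bulk.  The caller
    decides whether to refit; the screen itself is applied once, not
    iterated.  ``factor=inf`` disables removal.
    """
    if not np.isfinite(factor):
        return records, 0
    res = fitted.result
    X = np.asarray(res.model.exog)
    pinv = res.model.pinv_wexog
    h = np.clip(np.einsum("ij,ji->i", X, pinv), 0.0, 1.0 - 1e-10)
    e = np.asarray(res.resid)
    rank = getattr(res.model, "rank", None) or int(res.df_model + 1)
    s2 = res.ssr / res.df_resid
    D = e**2 * h / (rank * s2 * (1.0 - h) ** 2)
    q1, med, q3 = np.percentile(D, [25, 50, 75])
    cut = med + factor * (q3 - q1)
    bad_index = fitted.data.index[D > cut]
    kept = records.loc[~records.index.isin(bad_index)]
    return kept, int(len(bad_index))


# ---------------------------------------------------------------------------
# slope / adjusted-mean extraction


def _grid_combos(fitted: FittedResponseModel) -> list:
    factors = [f for f in ("trial", "device", "date") if f in fitted.categorical_factors]
    if not factors:
        return [dict()]
    levels = [fitted.categorical_factors[f] for f in factors]
    return [dict(zip(factors, combo)) for combo in product(*levels)]


def _build_rows(fitted: FittedResponseModel, rows: list) -> np.ndarray:
    new = pd.DataFrame(rows)
    (X,) = patsy.build_design_matrices([fitted.design_info], new)
    return np.asarray(X)


def extract_slopes(
    fitted: FittedResponseModel,
    lines: Optional[Sequence[str]] = None,
    delta: float = 1.0,
) -> pd.DataFrame:
    """Per-line marginal light-response slopes and adjusted Fq'/Fm' means.

    The slope is the model's linear trend in PPFR for the line -- evaluated
    as a prediction difference over ``delta`` µmol with the square-root
    light term and all covariates held at their grand means, averaged with
    equal weight over the trial (and device/date) reference grid.  Because
    it is a prediction contrast it is invariant to the contrast coding and
    to the ordering of lines in the design.  The adjusted mean is the
    prediction at the grand-mean light level on the same grid.  Standard
    errors come from the coefficient covariance of the fit.
    """
    unit = fitted.unit
    all_lines = fitted.categorical_factors[unit]
    if lines is None:
        lines = all_lines
    else:
        missing = [l for l in lines if l not in all_lines]
        if missing:
            raise KeyError(f"line(s) not present in the fit: {missing[:5]}")

    combos = _grid_combos(fitted)
    means = fitted.numeric_means
    p0 = means.get("ppfr", 0.0)

    def rows_at(ppfr_val):
        rows = []
        for line in lines:
            for combo in combos:
                row = {unit: line, "ppfr": ppfr_val, **means, **combo}
                row["ppfr"] = ppfr_val  # combo/means must not override the probe value
                rows.append(row)
        return rows

    X0 = _build_rows(fitted, rows_at(p0))
    X1 = _build_rows(fitted, rows_at(p0 + delta))
    n_combo = len(combos)
    beta = fitted.params
    cov = np.asarray(fitted.result.cov_params())

    C = (X1 - X0).reshape(len(lines), n_combo, -1).mean(axis=1) / delta
    M = X0.reshape(len(lines), n_combo, -1).mean(axis=1)
    slopes = C @ beta
    se = np.sqrt(np.maximum(np.einsum("ip,pq,iq->i", C, cov, C), 0.0))
    adj = M @ beta

    counts = fitted.data.groupby(unit)[fitted.response].size()
    return pd.DataFrame(
        {
            "line": list(lines),
            "slope": slopes,
            "slope_se": se,
            "adjusted_mean": adj,
            "n_obs": counts.reindex(lines).fillna(0).astype(int).to_numpy(),
        }
    )


def per_trial_slopes(records: pd.DataFrame, **fit_kwargs) -> pd.DataFrame:
    """Fit the basic model separately per trial and collect line x trial slopes."""
    out = []
    for trial, sub in records.groupby("trial", sort=True):
        fitted = fit_response_model(sub, variant="basic", **fit_kwargs)
        s = extract_slopes(fitted)
        s.insert(1, "env", trial)
        out.append(s)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# spatially adjusted trait means


def spatial_adjust(trait: pd.DataFrame, per_trial: bool = False) -> pd.DataFrame:
    """Row/column-adjusted line means for a pot or plot trait (e.g. biomass).

    Fits the trait with environment, line, their interaction and additive
    row/column trends, then evaluates each line's prediction averaged over
    environments (equal weight) and over the row/column reference grid --
    so spatial gradients cancel out of the line comparison.  With
    ``per_trial`` the model is refitted within each environment without the
    environment terms.

    A line whose pots all sit in a single row or column that contains no
    other line is confounded with that spatial effect; a warning is emitted
    and the estimate returned anyway.
    """
    if per_trial and "env" in trait.columns:
        frames = []
        for env, sub in trait.groupby("env", sort=True):
            res = spatial_adjust(sub.drop(columns=["env"]), per_trial=False)
            res.insert(1, "env", env)
            frames.append(res)
        return pd.concat(frames, ignore_index=True)

    _warn_confounded_lines(trait)
    fitted = _fit_biomass(trait)
    cat = fitted.categorical_factors
    lines = cat["line"]
    envs = cat.get("env", [None])
    rows_lv, cols_lv = cat["row"], cat["col"]
    # row/col enter additively, so cycling through max(R, C) paired levels
    # averages both factors without building the full product grid
    k = max(len(rows_lv), len(cols_lv))
    rc = [(rows_lv[i % len(rows_lv)], cols_lv[i % len(cols_lv)]) for i in range(k)]

    grid = []
    for line in lines:
        for env in envs:
            for r, c in rc:
                row = {"line": line, "row": r, "col": c}
                if env is not None:
                    row["env"] = env
                grid.append(row)
    X = _build_rows(fitted, grid).reshape(len(lines), len(envs) * k, -1).mean(axis=1)
    beta = fitted.params
    cov = np.asarray(fitted.result.cov_params())
    adj = X @ beta
    se = np.sqrt(np.maximum(np.einsum("ip,pq,iq->i", X, cov, X), 0.0))
    n_obs = fitted.data.groupby("line")["value"].size().reindex(lines).fillna(0).astype(int)
    return pd.DataFrame(
        {"line": lines, "adjusted_mean": adj, "se": se, "n_obs": n_obs.to_numpy()}
    )


def _warn_confounded_lines(trait: pd.DataFrame) -> None:
    for axis in ("row", "col"):
        counts = trait.groupby(axis)["line"].nunique()
        solo = counts.index[counts == 1]
        for label in solo:
            sub = trait.loc[trait[axis] == label, "line"]
            line = sub.iloc[0]
            if (trait.loc[trait["line"] == line, axis] == label).all():
                warnings.warn(
                    f"line '{line}' is confounded with {axis} '{label}'; "
                    "its adjusted mean absorbs that spatial effect",
                    stacklevel=3,
                )


# ---------------------------------------------------------------------------
# heritability


def heritability(line_variance: float, error_variance: float, mean_replicates: float) -> float:
    """Replicate-adjusted broad-sense heritability on a line-mean basis.

    H^2 = sigma_L / (sigma_L + sigma_eps / n_bar), with n_bar the average
    number of replicates per line -- the correction for unbalanced designs.
    """
    if line_variance < 0 or error_variance < 0:
        raise ResponseModelError("variances must be non-negative")
    if mean_replicates <= 0:
        raise ResponseModelError("mean_replicates must be positive")
    if line_variance == 0 and error_variance == 0:
        raise ResponseModelError("heritability undefined when both variances are zero")
    return line_variance / (line_variance + error_variance / mean_replicates)


def _mixedlm_components(df: pd.DataFrame, response: str, fixed: str) -> tuple[float, float]:
    from scipy import linalg as sla

    scale = df[response].std() or 1.0
    y = (df[response] / scale).to_numpy(float)
    X = np.asarray(patsy.dmatrix(fixed, df))
    # nested row/column/environment factors make the fixed design rank
    # deficient; keep an independent column basis via pivoted QR
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
    X = X[:, np.sort(piv[:rank])]
    model = sm.MixedLM(y, X, groups=df["line"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, maxiter=200)
    sigma_line = float(np.asarray(fit.cov_re)[0, 0]) * scale**2
    sigma_err = float(fit.scale) * scale**2
    return sigma_line, sigma_err


def variance_components_trait(trait: pd.DataFrame, response: str = "value") -> dict:
    """REML variance components for a replicated trait: line random, design fixed.

    The downstream heritability formula needs variance components, so the
    fixed-effects trait model is re-expressed with the line term as a
    Gaussian random effect (environment, row and column stay fixed).
    """
    fixed_terms = [t for t, col in (("C(env)", "env"), ("C(row)", "row"), ("C(col)", "col"))
                   if col in trait.columns and trait[col].nunique() > 1]
    # rows nested within environments span the environment contrasts; keeping
    # both would make the fixed design singular
    if "C(env)" in fixed_terms and "C(row)" in fixed_terms:
        nested = trait.groupby("row")["env"].nunique().max() == 1
        if nested:
            fixed_terms.remove("C(env)")
    fixed = " + ".join(fixed_terms) if fixed_terms else "1"
    sigma_line, sigma_err = _mixedlm_components(trait, response, fixed)
    n_bar = len(trait) / trait["line"].nunique()
    return {"sigma_line": sigma_line, "sigma_error": sigma_err, "n_bar": n_bar}


def variance_components_response(slopes: pd.DataFrame) -> dict:
    """REML components for line x trial slope estimates (line random, trial fixed)."""
    fixed = "C(env)" if slopes["env"].nunique() > 1 else "1"
    sigma_line, sigma_err = _mixedlm_components(slopes, "slope", fixed)
    n_bar = len(slopes) / slopes["line"].nunique()
    return {"sigma_line": sigma_line, "sigma_error": sigma_err, "n_bar": n_bar}


def heritability_from_trait(trait: pd.DataFrame, response: str = "value") -> dict:
    comp = variance_components_trait(trait, response)
    comp["H2"] = heritability(comp["sigma_line"], comp["sigma_error"], comp["n_bar"])
    return comp


def heritability_from_slopes(slopes: pd.DataFrame) -> dict:
    comp = variance_components_response(slopes)
    comp["H2"] = heritability(comp["sigma_line"], comp["sigma_error"], comp["n_bar"])
    return comp


# ---------------------------------------------------------------------------
# quantile-group yield comparison


def quantile_group_compare(
    slopes: pd.Series,
    trait_means: pd.Series,
    q: float = 0.2,
) -> dict:
    """Compare a trait between the outer slope quantile groups.

    Lines are split by their light-response slope into lower-``q``,
    intermediate and upper-``q`` groups; a one-way ANOVA on the trait is
    followed by Tukey's HSD for the pairwise comparisons.  Requires at
    least 10 shared lines, a non-empty intermediate group (q < 0.5) and at
    least two lines per group.
    """
    common = slopes.index.intersection(trait_means.index)
    if len(common) < 10:
        raise ResponseModelError(f"need >= 10 shared lines, got {len(common)}")
    if not (0.0 < q < 0.5):
        raise ResponseModelError("q must lie in (0, 0.5) so the intermediate group is non-empty")
    s = slopes.loc[common].astype(float)
    t = trait_means.loc[common].astype(float)
    lo_cut, hi_cut = s.quantile(q), s.quantile(1.0 - q)
    labels = pd.Series("intermediate", index=common, name="group")
    labels[s <= lo_cut] = "lower"
    labels[s >= hi_cut] = "upper"
    sizes = labels.value_counts()
    for grp in ("lower", "intermediate", "upper"):
        if sizes.get(grp, 0) < 2:
            raise ResponseModelError(f"group '{grp}' has fewer than 2 lines")

    groups = [t[labels == g].to_numpy() for g in ("lower", "intermediate", "upper")]
    anova = sps.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(t.to_numpy(), labels.to_numpy(), alpha=0.05)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return {
        "groups": labels,
        "group_means": {g: float(t[labels == g].mean()) for g in ("lower", "intermediate", "upper")},
        "anova_F": float(anova.statistic),
        "anova_p": float(anova.pvalue),
        "tukey": tukey,
    }
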