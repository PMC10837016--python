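"""Synthetic phenotyping studies with known ground truth.

The generator emulates a multi-trial chlorophyll-fluorescence screening of a
bean breeding panel: a SNP dosage panel, genotype-specific linear light
responses of the PSII operating efficiency (Fq'/Fm') to the photosynthetic
photon fluence rate (PPFR), instrument-style measurement streams with
configurable quality-rule violations, and a partially replicated pot/plot
yield trial with row/column trends.  Every stochastic quantity is driven by
a single seed, so identical configurations reproduce every table
bit-identically.

The measurement model is

    Fq'/Fm' = intercept + a * sqrt(PPFR) + slope(line, env) * PPFR + noise,

clipped to [0, 1], with the line x environment slope composed of a population
mean, a polygenic component built from marker effects (so kinship-based
models downstream are well specified), an optional planted QTL, and a
genotype-by-environment deviation.  Yield expectation increases with the
slope (a shallower, less negative light response means higher light-use
efficiency and more biomass).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .prediction import SNPMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_population",
    "generate_true_effects",
    "simulate_chlf_series",
    "simulate_yield",
    "light_response",
]

N_CHROMOSOMES = 11
LOW_LIGHT_THRESHOLD = 100.0  # µmol photons m^-2 s^-1
MIN_SNR = 30.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class LayoutError(ValueError):
    """Raised when the requested layout cannot hold the requested replication."""


@dataclass
class SimulationConfig:
    """Study design and generative parameters for one synthetic experiment.

    Slopes are in Fq'/Fm' units per µmol photons m^-2 s^-1; the default mean
    of -1e-4 gives a drop of ~0.16 in Fq'/Fm' between shade and full light,
    which is the magnitude seen in season-long canopy screens.  Yield is on
    an arbitrary gram scale with unit genetic standard deviation.
    """

    n_lines: int = 100
    n_markers: int = 1000
    n_environments: int = 2
    maf_range: tuple = (0.05, 0.5)
    # light-response slope composition
    slope_mean: float = -1e-4
    slope_sd_genetic: float = 3e-5
    slope_sd_gxe: float = 1e-5
    qtl: Optional[tuple] = None  # (marker index, slope effect per dosage copy)
    # fluorescence stream
    obs_per_line_per_env: int = 200
    noise_sd_fqfm: float = 0.03
    fqfm_intercept: float = 0.78
    fqfm_sqrt_coef: float = -2e-3
    ppfr_peak: float = 1200.0
    day_length_h: float = 12.0
    ppfr_day_sd: float = 100.0
    n_days: int = 57
    violation_fractions: tuple = (0.0, 0.0, 0.0)  # low light, low SNR, gross outlier
    instrument: str = "lift"
    # yield trial
    h2_yield: float = 0.5
    yield_slope_corr: float = 0.5
    yield_gxe_sd: float = 0.3
    yield_gxe_covariate_share: float = 0.8
    yield_env_sd: float = 1.0
    yield_baseline: float = 10.0
    yield_error_sd: Optional[float] = None  # None: derived from h2_yield
    layout: Optional[tuple] = None  # (rows, columns); auto-sized when None
    row_effect_sd: float = 0.2
    col_effect_sd: float = 0.2
    n_check_lines: int = 4
    check_replicates: int = 6
    base_replicates: tuple = (1, 2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ConfigurationError("n_lines must be >= 2")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be >= 1")
        if self.n_environments < 1:
            raise ConfigurationError("n_environments must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("slope_sd_genetic", "slope_sd_gxe", "noise_sd_fqfm",
                     "ppfr_day_sd", "yield_gxe_sd", "row_effect_sd", "col_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.h2_yield <= 1.0):
            raise ConfigurationError("h2_yield must be in [0, 1]")
        if not (0.0 <= self.yield_gxe_covariate_share <= 1.0):
            raise ConfigurationError("yield_gxe_covariate_share must be in [0, 1]")
        if not (-1.0 <= self.yield_slope_corr <= 1.0):
            raise ConfigurationError("yield_slope_corr must be in [-1, 1]")
        if sum(self.violation_fractions) >= 1.0 or min(self.violation_fractions) < 0:
            raise ConfigurationError("violation fractions must be >= 0 and sum to < 1")
        if self.qtl is not None and not (0 <= self.qtl[0] < self.n_markers):
            raise ConfigurationError("qtl marker index out of range")
        if self.ppfr_peak <= 4 * LOW_LIGHT_THRESHOLD:
            raise ConfigurationError("ppfr_peak too low for a truncated diurnal curve")

    @property
    def line_ids(self) -> list:
        return [f"L{i:04d}" for i in range(self.n_lines)]

    @property
    def env_ids(self) -> list:
        return [f"T{k + 1}" for k in range(self.n_environments)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted signal that the downstream estimators are expected to recover."""

    line_ids: list
    env_ids: list
    true_slope: np.ndarray  # n_lines x n_env
    true_polygenic_value: np.ndarray  # n_lines, yield scale
    true_environment_effect: np.ndarray  # n_env
    true_yield: np.ndarray  # n_lines x n_env expectations
    true_slope_genetic: np.ndarray  # n_lines, line-mean slope deviation

    def __post_init__(self):
        nl, ne = len(self.line_ids), len(self.env_ids)
        if self.true_slope.shape != (nl, ne) or self.true_yield.shape != (nl, ne):
            raise ConfigurationError("ground-truth arrays inconsistent with ids")
        if not np.isfinite(self.true_slope).all():
            raise ConfigurationError("slopes must be finite")

    def slope_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line": np.repeat(self.line_ids, len(self.env_ids)),
                "env": np.tile(self.env_ids, len(self.line_ids)),
                "true_slope": self.true_slope.ravel(),
                "true_yield": self.true_yield.ravel(),
            }
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(config.seed) % (2**31)])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------


def generate_population(config: SimulationConfig) -> SNPMatrix:
    """Draw a line x marker dosage panel with allele frequencies in ``maf_range``.

    Markers are independent (no linkage disequilibrium); dosages are
    Binomial(2, p) draws per line, i.e. a Hardy-Weinberg outbred panel.
    """
    config.validate()
    rng = _rng(config, 1)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, config.n_markers)
    dosages = rng.binomial(2, p, size=(config.n_lines, config.n_markers)).astype(float)
    chrom = np.sort(rng.integers(1, N_CHROMOSOMES + 1, config.n_markers))
    pos = np.sort(rng.integers(10**5, 5 * 10**7, config.n_markers))
    marker_ids = [f"Chr{c:02d}_{q}_{i}" for i, (c, q) in enumerate(zip(chrom, pos))]
    return SNPMatrix(config.line_ids, marker_ids, dosages, chrom, pos)


def generate_true_effects(snp: SNPMatrix, config: SimulationConfig) -> GroundTruth:
    """Plant slope and yield signal on top of the marker panel.

    The polygenic slope component is built from independent marker effects
    through the centered dosage matrix and rescaled so its realized standard
    deviation equals ``slope_sd_genetic`` exactly; the optional QTL effect is
    added afterwards on the raw dosage scale.  The yield-scale genetic value
    correlates with the line-mean slope at ``yield_slope_corr`` (a shallower
    response implies higher yield), and a configurable share of the yield
    G x E deviation is driven by the slope G x E, which is what makes the
    covariate-based reaction-norm prediction model identifiable.
    """
    config.validate()
    if snp.n_lines != config.n_lines or snp.n_markers != config.n_markers:
        raise ConfigurationError("SNP matrix inconsistent with configuration")
    rng = _rng(config, 2)
    nl, ne = config.n_lines, config.n_environments

    W = snp.dosages - snp.dosages.mean(axis=0)
    beta = rng.normal(size=config.n_markers)
    u = W @ beta
    u = _standardize(u) * config.slope_sd_genetic
    if config.qtl is not None:
        idx, eff = config.qtl
        if not (0 <= idx < snp.n_markers):
            raise ConfigurationError("qtl marker index out of range")
        u = u + eff * snp.dosages[:, idx]
    gxe = rng.normal(0.0, config.slope_sd_gxe, size=(nl, ne)) if config.slope_sd_gxe > 0 else np.zeros((nl, ne))
    slope = config.slope_mean + u[:, None] + gxe

    env_eff = rng.normal(0.0, config.yield_env_sd, size=ne)
    # yield-scale genetics: correlated with the (shallower = better) slope;
    # the slope-independent part is polygenic too (a second set of marker
    # effects), so kinship-based yield models are well specified
    z_slope = _standardize(u)
    z_indep = _standardize(W @ rng.normal(size=config.n_markers))
    c = config.yield_slope_corr
    g = c * z_slope + np.sqrt(max(1.0 - c**2, 0.0)) * z_indep
    g = _standardize(g) if g.std() > 0 else g

    s = config.yield_gxe_covariate_share
    z_gxe = _standardize(gxe.ravel()).reshape(nl, ne) if gxe.std() > 0 else np.zeros((nl, ne))
    ge = config.yield_gxe_sd * (
        np.sqrt(s) * z_gxe + np.sqrt(1.0 - s) * rng.normal(size=(nl, ne))
    )
    if config.h2_yield == 0.0:
        g = np.zeros(nl)
        ge = np.zeros((nl, ne))
    true_yield = config.yield_baseline + env_eff[None, :] + g[:, None] + ge
    return GroundTruth(
        line_ids=list(snp.line_ids),
        env_ids=config.env_ids,
        true_slope=slope,
        true_polygenic_value=g,
        true_environment_effect=env_eff,
        true_yield=true_yield,
        true_slope_genetic=u,
    )


def _measurement_noise(rng, sd: float, n: int):
    """Short-tailed (3-sigma-truncated Gaussian) instrument noise.

    Gross errors are a separate, explicitly planted record class; keeping the
    routine noise short-tailed means the interquartile outlier rule separates
    the two cleanly, so filter bookkeeping is exact by construction.
    """
    if sd <= 0:
        return 0.0
    return np.clip(rng.normal(0.0, sd, n), -3.0 * sd, 3.0 * sd)


def light_response(
    ppfr: np.ndarray,
    slope: np.ndarray,
    intercept: float,
    sqrt_coef: float,
) -> np.ndarray:
    """Noise-free generating equation for Fq'/Fm' at a given light level."""
    ppfr = np.asarray(ppfr, dtype=float)
    return np.clip(intercept + sqrt_coef * np.sqrt(ppfr) + slope * ppfr, 0.0, 1.0)


def simulate_chlf_series(
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit per-trial fluorescence measurement streams.

    PPFR follows a half-sine diurnal course truncated at the low-light
    threshold (only the marginal light distribution matters for slope
    estimation), with day-to-day variation of the peak.  Records carry
    timestamps, pot and device labels, temperature, SNR, relative
    chlorophyll, and a three-band red-edge reflectance triple (754/710/680
    nm) consistent with a short-tailed target chlorophyll index, so the
    downstream index computation and interquartile-range outlier rule see
    realistic but controlled inputs.

    ``violation_fractions`` plants disjoint subsets of records violating the
    three stream-level quality rules (PPFR below threshold, SNR below 30,
    gross Fq'/Fm' outliers).  Returns ``(records, planted)`` where
    ``planted`` holds one boolean column per rule, aligned with the record
    index, so filter bookkeeping can be checked exactly.
    """
    config.validate()
    rng = _rng(config, 3)
    nl, ne, nobs = config.n_lines, config.n_environments, config.obs_per_line_per_env
    frames, planted_frames = [], []
    chl_line = rng.uniform(30.0, 45.0, nl)

    for e, env in enumerate(truth.env_ids):
        start = pd.Timestamp("2020-09-01") + pd.Timedelta(days=70 * e)
        n_rec = nl * nobs
        line_idx = np.repeat(np.arange(nl), nobs)

        peaks = np.maximum(
            rng.normal(config.ppfr_peak, config.ppfr_day_sd, config.n_days),
            4 * LOW_LIGHT_THRESHOLD,
        )
        day = rng.integers(0, config.n_days, n_rec)
        frac_low = np.arcsin(LOW_LIGHT_THRESHOLD / peaks[day]) / np.pi
        tfrac = rng.uniform(frac_low, 1.0 - frac_low)
        ppfr = peaks[day] * np.sin(np.pi * tfrac)

        slope = truth.true_slope[line_idx, e]
        noise = _measurement_noise(rng, config.noise_sd_fqfm, n_rec)
        fqfm = np.clip(
            config.fqfm_intercept
            + config.fqfm_sqrt_coef * np.sqrt(ppfr)
            + slope * ppfr
            + noise,
            0.0,
            1.0,
        )
        temperature = 15.0 + 10.0 * np.sin(np.pi * tfrac) + rng.normal(0.0, 0.5, n_rec)
        snr = rng.uniform(40.0, 150.0, n_rec)
        chlorophyll = chl_line[line_idx] + rng.uniform(-2.0, 2.0, n_rec)
        # red-edge bands consistent with a short-tailed target MTCI
        mtci_target = rng.uniform(1.7, 2.3, n_rec)
        r680 = rng.uniform(0.03, 0.05, n_rec)
        r710 = rng.uniform(0.05, 0.08, n_rec)
        r754 = mtci_target * (r710 + r680) + r710

        # planted quality-rule violations on disjoint record subsets
        f_low, f_snr, f_out = config.violation_fractions
        order = rng.permutation(n_rec)
        n_low, n_snr, n_out = (int(round(f * n_rec)) for f in (f_low, f_snr, f_out))
        idx_low = order[:n_low]
        idx_snr = order[n_low:n_low + n_snr]
        idx_out = order[n_low + n_snr:n_low + n_snr + n_out]
        if n_low:
            ppfr[idx_low] = rng.uniform(5.0, 95.0, n_low)
            fqfm[idx_low] = np.clip(
                config.fqfm_intercept
                + config.fqfm_sqrt_coef * np.sqrt(ppfr[idx_low])
                + slope[idx_low] * ppfr[idx_low]
                + _measurement_noise(rng, config.noise_sd_fqfm, n_low),
                0.0,
                1.0,
            )
        if n_snr:
            snr[idx_snr] = rng.uniform(5.0, MIN_SNR - 0.5, n_snr)
        if n_out:
            fqfm[idx_out] = rng.uniform(0.0, 0.02, n_out)

        if n_low + n_snr + n_out:
            # Bookkeeping guarantee: only planted records violate the default
            # 2.5 x IQR outlier rule.  Legitimate records in the extreme tail
            # (steepest line at the brightest moment) are nudged onto the
            # fence computed over the records that survive the range rules.
            # Clipping never crosses a quartile, so the downstream filter
            # recomputes identical bounds and removals match plantings exactly.
            survive = np.ones(n_rec, dtype=bool)
            survive[idx_low] = False
            survive[idx_snr] = False
            legit = survive.copy()
            legit[idx_out] = False
            for arr in (ppfr, temperature, fqfm):
                q1, q3 = np.percentile(arr[survive], [25, 75])
                med = np.percentile(arr[survive], 50)
                iqr = q3 - q1
                if iqr > 0:
                    arr[legit] = np.clip(arr[legit], med - 2.5 * iqr, med + 2.5 * iqr)

        minutes = (6.0 * 60 + tfrac * config.day_length_h * 60).astype(int)
        timestamps = (
            start
            + pd.to_timedelta(day, unit="D")
            + pd.to_timedelta(minutes, unit="m")
        )
        device = (
            "LIFT-1"
            if config.instrument == "lift"
            else pd.Series(rng.integers(1, 5, n_rec)).map(lambda i: f"MSQ-{i}").to_numpy()
        )
        df = pd.DataFrame(
            {
                "trial": env,
                "line": np.asarray(truth.line_ids)[line_idx],
                "plot": [f"{env}-P{j:04d}" for j in line_idx],
                "device": device,
                "timestamp": timestamps,
                "ppfr": ppfr,
                "temperature": temperature,
                "fqfm": fqfm,
                "snr": snr,
                "chlorophyll": chlorophyll,
                "r680": r680,
                "r710": r710,
                "r754": r754,
            }
        )
        planted = pd.DataFrame(
            {
                "trial": env,
                "planted_low_light": np.zeros(n_rec, dtype=bool),
                "planted_low_snr": np.zeros(n_rec, dtype=bool),
                "planted_outlier": np.zeros(n_rec, dtype=bool),
            }
        )
        planted.loc[idx_low, "planted_low_light"] = True
        planted.loc[idx_snr, "planted_low_snr"] = True
        planted.loc[idx_out, "planted_outlier"] = True
        frames.append(df)
        planted_frames.append(planted)

    records = pd.concat(frames, ignore_index=True)
    planted = pd.concat(planted_frames, ignore_index=True)
    return records, planted


def simulate_yield(
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate the partially replicated yield/biomass trial.

    Check lines (the first ``n_check_lines``) are replicated
    ``check_replicates`` times per environment; the remaining lines get a
    random replicate count from ``base_replicates``.  Pots are assigned to a
    rows x columns grid at random, with additive Gaussian row and column
    trends.  Unless ``yield_error_sd`` is given, the residual standard
    deviation is derived from ``h2_yield`` so that the replicate-adjusted
    heritability sigma_L / (sigma_L + sigma_eps / n_bar) lands at the target
    under the realized design.

    Returns a tidy table with columns line, env, replicate, row, col, value.
    Row/column labels are environment-specific.
    """
    config.validate()
    rng = _rng(config, 4)
    nl, ne = config.n_lines, config.n_environments
    lo, hi = config.base_replicates
    reps = np.full(nl, 0, dtype=int)
    n_check = min(config.n_check_lines, nl)
    reps[:n_check] = config.check_replicates
    reps[n_check:] = rng.integers(lo, hi + 1, nl - n_check)

    g_var = float(np.var(truth.true_polygenic_value))
    n_bar = ne * reps.mean()
    if config.yield_error_sd is not None:
        err_sd = config.yield_error_sd
    elif config.h2_yield == 0.0:
        err_sd = 1.0
    else:
        target_resid = n_bar * max(g_var, 1e-12) * (1.0 - config.h2_yield) / config.h2_yield
        err_sd = float(np.sqrt(max(target_resid - config.yield_gxe_sd**2, 0.0)))

    rows_out = []
    for e, env in enumerate(truth.env_ids):
        n_pots = int(reps.sum())
        if config.layout is not None:
            n_rows, n_cols = config.layout
            if n_rows * n_cols < n_pots:
                raise LayoutError(
                    f"layout {n_rows}x{n_cols} cannot hold {n_pots} pots in {env}"
                )
        else:
            n_cols = int(np.ceil(np.sqrt(n_pots)))
            n_rows = int(np.ceil(n_pots / n_cols))
        row_eff = rng.normal(0.0, config.row_effect_sd, n_rows) if config.row_effect_sd > 0 else np.zeros(n_rows)
        col_eff = rng.normal(0.0, config.col_effect_sd, n_cols) if config.col_effect_sd > 0 else np.zeros(n_cols)
        positions = rng.permutation(n_rows * n_cols)[:n_pots]
        line_idx = np.repeat(np.arange(nl), reps)
        rep_no = np.concatenate([np.arange(1, r + 1) for r in reps])
        r_i, c_i = positions // n_cols, positions % n_cols
        err = rng.normal(0.0, err_sd, n_pots) if err_sd > 0 else np.zeros(n_pots)
        value = truth.true_yield[line_idx, e] + row_eff[r_i] + col_eff[c_i] + err
        rows_out.append(
            pd.DataFrame(
                {
                    "line": np.asarray(truth.line_ids)[line_idx],
                    "env": env,
                    "replicate": rep_no,
                    "row": [f"{env}-R{r:02d}" for r in r_i],
                    "col": [f"{env}-C{c:02d}" for c in c_i],
                    "is_check": line_idx < n_check,
                    "value": value,
                }
            )
        )
    return pd.concat(rows_out, ignore_index=True)
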