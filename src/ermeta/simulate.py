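"""Known-truth synthetic data: flux/driver database and soil rasters.

The generator emulates the structure of a multi-site warming-experiment
synthesis: sites contain experiments, experiments contribute one or more
measurement years ("datasets"), and each dataset has control and warmed
plots with daily growing-season flux measurements.  The default
configuration reproduces the study conditions of the synthesis this
package models: 136 datasets across 56 experiments at 28 sites, a pooled
standardized effect of 0.57, experiment-level variance 0.1, a CAR(year)
process with tau2 = 0.05 and rho = 0.6, and up to 13 measurement years per
experiment.

Per-dataset true effects are

    g_true = mu + u_exp + u_ds + w_exp(year) + sum_d slope_d * x_d,

and plot-level fluxes are drawn so that the computed Hedges' g is unbiased
for g_true: control plot means are N(m_c, s_plot^2), warmed plot means are
offset by g_true times the effective between-plot SD (which accounts for
the within-plot daily noise entering the plot-mean estimates), and daily
values are lognormal multiplicative noise around plot means, keeping
fluxes positive so the log ratio of means is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .effects import C_PER_CO2
from .rasters import Raster, SoilStack

__all__ = ["TruthConfig", "simulate_database", "RasterTruthConfig",
           "simulate_rasters", "cn_scatter_from_drivers"]


@dataclass
class TruthConfig:
    """Generating parameters for the synthetic flux + driver database."""

    n_sites: int = 28
    n_experiments: int = 56
    n_datasets: int = 136
    plots_min: int = 3
    plots_max: int = 8
    mu_true: float = 0.57          # pooled SMD
    sigma2_exp: float = 0.1
    sigma2_dataset: float = 0.05
    tau2_car: float = 0.05
    rho_car: float = 0.6
    #: moderator name -> slope on the SMD scale
    moderator_slopes: dict = field(default_factory=dict)
    #: moderator name -> fraction of datasets with an observed value
    moderator_coverage: dict = field(default_factory=dict)
    #: driver base name -> coverage-group label; drivers sharing a label
    #: are observed (or missing) together, like co-measured soil samples
    moderator_groups: dict = field(
        default_factory=lambda: {"TN": "soil", "CN": "soil", "SOC": "soil"})
    #: driver name -> (true mean difference, between-dataset sd,
    #: within-arm sd, control-arm baseline); realized as full 6-statistic
    #: driver blocks so raw-mean-difference meta-analyses recover the mean.
    #: Defaults mirror passive warming-chamber conditions: +1.4 C air,
    #: +0.4 C soil, -1.6 percentage-point soil moisture.
    treatment_effects: dict = field(default_factory=lambda: {
        "air_temperature": (1.4, 1.2, 0.8, 8.0),
        "soil_temperature": (0.4, 0.5, 0.5, 6.0),
        "soil_moisture": (-1.6, 1.5, 2.0, 30.0),
    })
    control_mean_flux: float = 3.0  # gCO2 m-2 d-1
    plot_sd_flux: float = 1.5       # between-plot SD, gCO2 m-2 d-1
    daily_log_sd: float = 0.25      # lognormal sigma of daily noise
    n_days: int = 8                 # measurement days per plot
    max_duration: int = 25
    duration_geom_p: float = 0.25   # mean extra duration ~ 3 y between years
    tn_dtn_correlation: float = -0.43
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < self.n_experiments:
            raise ValueError("need at least one dataset per experiment")
        if self.n_experiments < self.n_sites:
            raise ValueError("need at least one experiment per site")
        if not (0 <= self.rho_car < 1):
            raise ValueError("rho_car must be in [0, 1)")
        for v in (self.sigma2_exp, self.sigma2_dataset, self.tau2_car):
            if v < 0:
                raise ValueError("variance components must be >= 0")


def rom_per_smd(config: TruthConfig) -> float:
    """lnROM change per unit SMD implied by the flux calibration.

    The generator injects truth on the SMD scale; the ratio of the
    effective between-plot sd to the control mean converts published
    ROM-scale moderator coefficients onto that scale.
    """
    s_eff = np.hypot(config.plot_sd_flux,
                     config.control_mean_flux * np.sqrt(
                         (np.exp(config.daily_log_sd**2) - 1) / config.n_days))
    return s_eff / config.control_mean_flux


def study_truth_config(seed: int = 0) -> TruthConfig:
    """The default synthesis-study conditions with soil-driver moderators.

    TN and C:N context slopes are the published two-factor coefficients
    (0.05 - 0.16 TN + 0.01 C:N, lnROM scale) translated to the SMD scale;
    coverage mirrors the real soil-driver availability (~39 of 136
    datasets with TN and C:N, ~42 with the TN-change effect size).
    """
    scale = rom_per_smd(TruthConfig())
    return TruthConfig(
        seed=seed,
        moderator_slopes={"TN": -0.16 / scale, "CN": 0.01 / scale,
                          "dTN": 0.20},
        moderator_coverage={"TN": 0.29, "CN": 0.29, "dTN": 0.31},
    )


def _allocate(n_items: int, n_groups: int, rng, max_per=None) -> np.ndarray:
    """Random allocation of n_items to n_groups, each group >= 1."""
    counts = np.ones(n_groups, dtype=int)
    extra = n_items - n_groups
    while extra > 0:
        g = int(rng.integers(0, n_groups))
        if max_per is None or counts[g] < max_per:
            counts[g] += 1
            extra -= 1
    return counts


def simulate_database(config: TruthConfig, seed: int | None = None):
    """Generate (flux table, driver table, truth record).

    The flux table matches the ingestion schema (site_id, experiment_id,
    plot_id, treatment, date, er_value, er_unit, start_year); the driver
    table is long-format (experiment_id, year, driver, statistic, value).
    The truth record carries every generating parameter and the per-dataset
    true effects for recovery tests.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    exp_per_site = _allocate(config.n_experiments, config.n_sites, rng)
    years_per_exp = _allocate(config.n_datasets, config.n_experiments, rng,
                              max_per=13)

    site_of_exp = np.repeat(np.arange(config.n_sites), exp_per_site)
    u_site_exp = rng.normal(0.0, np.sqrt(config.sigma2_exp),
                            config.n_experiments)

    mods = sorted(config.moderator_slopes)
    flux_rows, driver_rows, truth_ds = [], [], []
    for e in range(config.n_experiments):
        site = f"S{site_of_exp[e]:02d}"
        exp = f"S{site_of_exp[e]:02d}_E{e:02d}"
        start_year = int(rng.integers(1994, 2019))
        n_years = years_per_exp[e]
        durations = np.sort(rng.choice(
            np.arange(config.max_duration + 1), size=n_years, replace=False,
            p=_duration_probs(config)))
        years = start_year + durations
        # CAR process over this experiment's years
        if config.tau2_car > 0:
            dy = np.abs(years[:, None] - years[None, :]).astype(float)
            cov = config.tau2_car * np.power(config.rho_car, dy)
            w_car = rng.multivariate_normal(np.zeros(n_years), cov,
                                            method="cholesky")
        else:
            w_car = np.zeros(n_years)
        for t, year in enumerate(years):
            u_ds = rng.normal(0.0, np.sqrt(config.sigma2_dataset))
            x_mod = _moderator_values(mods, config, rng)
            g_true = (config.mu_true + u_site_exp[e] + u_ds + w_car[t]
                      + sum(config.moderator_slopes[m] * x_mod[m]
                            for m in mods))
            flux_rows.extend(_dataset_fluxes(
                site, exp, int(year), start_year, g_true, config, rng))
            driver_rows.extend(_dataset_drivers(
                exp, int(year), x_mod, config, rng))
            driver_rows.extend(_treatment_driver_rows(
                exp, int(year), config, rng))
            truth_ds.append({"experiment_id": exp, "year": int(year),
                             "duration": int(year - start_year),
                             "g_true": float(g_true), **x_mod})

    flux = pd.DataFrame(flux_rows)
    drivers = pd.DataFrame(
        driver_rows,
        columns=["experiment_id", "year", "driver", "statistic", "value"])
    truth = {
        "config": asdict(config),
        "seed": int(seed),
        "datasets": truth_ds,
    }
    return flux, drivers, truth


def _duration_probs(config) -> np.ndarray:
    d = np.arange(config.max_duration + 1)
    p = (1 - config.duration_geom_p) ** d * config.duration_geom_p
    return p / p.sum()


def _dataset_fluxes(site, exp, year, start_year, g_true, config, rng):
    """Plot-level daily flux rows for one dataset."""
    n_c = int(rng.integers(config.plots_min, config.plots_max + 1))
    n_w = int(rng.integers(config.plots_min, config.plots_max + 1))
    m_c = config.control_mean_flux
    s_plot = config.plot_sd_flux
    # effective between-plot SD of plot-mean estimates: plot variance plus
    # the sampling noise of the per-plot daily mean (mean-dependent for the
    # multiplicative lognormal noise, hence the fixed-point on the offset)
    daily_var_factor = (np.exp(config.daily_log_sd**2) - 1.0) / config.n_days
    offset = 0.0
    for _ in range(8):
        m_w = m_c + offset
        s_eff = np.sqrt(s_plot**2
                        + 0.5 * (m_c**2 + m_w**2) * daily_var_factor)
        offset = g_true * s_eff

    days = rng.choice(pd.date_range(f"{year}-06-01", f"{year}-08-31").values,
                      size=config.n_days, replace=False)
    rows = []
    for treatment, n_plots, shift in (("control", n_c, 0.0),
                                      ("warmed", n_w, offset)):
        plot_means = rng.normal(m_c + shift, s_plot, n_plots)
        plot_means = np.clip(plot_means, 0.05 * m_c, None)
        for pi, pm in enumerate(plot_means):
            noise = np.exp(rng.normal(-config.daily_log_sd**2 / 2,
                                      config.daily_log_sd, config.n_days))
            for d, val in zip(days, pm * noise):
                rows.append({
                    "site_id": site, "experiment_id": exp,
                    "plot_id": f"{treatment[0]}{pi}", "treatment": treatment,
                    "date": pd.Timestamp(d).date().isoformat(),
                    "er_value": float(val), "er_unit": "gCO2 m-2 d-1",
                    "start_year": start_year,
                })
    return rows


def _moderator_values(mods, config, rng):
    """Moderator values on their natural scales.

    ``d<driver>`` names are warming-induced change effect sizes (SMD scale,
    latent N(0,1)); plain names are ambient control-plot conditions (TN %
    lognormal around 0.5, C:N around 15, otherwise N(0,1)).  When both
    ``TN`` and ``dTN`` are requested their latent normals are correlated
    (nutrient-poor sites change more under warming), with the configured
    TN-vs-dTN correlation.
    """
    z = {m: float(rng.standard_normal()) for m in mods}
    if "TN" in z and "dTN" in z:
        rho = config.tn_dtn_correlation
        z["TN"] = rho * z["dTN"] + np.sqrt(max(1 - rho**2, 0.0)) * z["TN"]
    values = {}
    for m in mods:
        if m == "TN":
            values[m] = float(np.exp(np.log(0.5) + 0.5 * z[m]))  # % by mass
        elif m == "CN":
            values[m] = float(np.clip(15.0 + 4.0 * z[m], 5.0, 40.0))
        else:
            values[m] = z[m]
    return values


def _dataset_drivers(exp, year, x_mod, config, rng):
    """Driver-table rows realizing the moderator values.

    A ``d<driver>`` moderator becomes a full 6-statistic block under
    ``<driver>`` whose computed Hedges g equals the value (noise-free by
    construction; the plot-level uncertainty already lives in the ER data);
    plain moderators become control-plot means.  When both exist for one
    driver they share a single block.
    """
    blocks = {m[1:] for m in x_mod if m.startswith("d")}
    contexts = {m for m in x_mod if not m.startswith("d")}
    rows = []
    group_draw: dict = {}

    def covered(base):
        cov = min(config.moderator_coverage.get(base, 1.0),
                  config.moderator_coverage.get("d" + base, 1.0))
        group = config.moderator_groups.get(base, base)
        if group not in group_draw:
            group_draw[group] = rng.random()
        return group_draw[group] < cov

    for base in sorted(blocks | contexts):
        if not covered(base):
            continue
        c_mean = x_mod.get(base, 10.0)
        if base in blocks:
            x = x_mod["d" + base]
            n = 5
            j = 1.0 - 3.0 / (4.0 * (2 * n - 2) - 1.0)
            s = max(0.2 * abs(c_mean), 1e-3)
            rows += [
                (exp, year, base, "control_mean", float(c_mean)),
                (exp, year, base, "control_sd", s),
                (exp, year, base, "n_control", n),
                (exp, year, base, "warmed_mean", float(c_mean + x * s / j)),
                (exp, year, base, "warmed_sd", s),
                (exp, year, base, "n_warmed", n),
            ]
        else:
            rows.append((exp, year, base, "control_mean", float(c_mean)))
    return rows


def _treatment_driver_rows(exp, year, config, rng):
    """Driver blocks for treatment microclimate effects (raw-MD scale)."""
    rows = []
    for name, (mean, sd_between, sd_within, baseline) in \
            config.treatment_effects.items():
        md = rng.normal(mean, sd_between)
        n = 5
        rows += [
            (exp, year, name, "control_mean", baseline),
            (exp, year, name, "control_sd", sd_within),
            (exp, year, name, "n_control", n),
            (exp, year, name, "warmed_mean", baseline + md),
            (exp, year, name, "warmed_sd", sd_within),
            (exp, year, name, "n_warmed", n),
        ]
    return rows


def cn_scatter_from_drivers(rng: np.random.Generator, n: int = 120,
                            bias_intercept: float = 1.5,
                            bias_slope: float = 0.92,
                            noise_sd: float = 2.0):
    """Synthetic (calculated, reported) C:N scatter for the bias regressions.

    Stands in for the study database's reported-vs-derived C:N comparison:
    ``reported = a + b * calculated + noise`` around a known bias line.
    """
    calculated = rng.uniform(8.0, 35.0, n)
    reported = (bias_intercept + bias_slope * calculated
                + rng.normal(0.0, noise_sd, n))
    return calculated, reported


# -- rasters ---------------------------------------------------------------


@dataclass
class RasterTruthConfig:
    """Generating parameters for synthetic soil / baseline rasters."""

    nrows: int = 20
    ncols: int = 20
    cellsize: float = 1000.0  # m
    tn_range: tuple = (0.1, 0.9)      # % by mass, mineral layer
    soc_range: tuple = (1.0, 8.0)     # % by mass
    bd_range: tuple = (1.1, 1.6)      # g/cm3
    rel_sd: float = 0.3               # per-cell sd as fraction of the mean
    organic_fraction: float = 0.1     # cells with no mineral layer
    baseline_range: tuple = (50.0, 300.0)  # gC m-2 yr-1
    intervals: tuple = ((0.0, 30.0), (30.0, 60.0))
    smooth_sigma: float = 2.0
    seed: int = 0


def _smooth_field(rng, shape, lo, hi, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma,
                                mode="wrap")
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + f * (hi - lo)


def simulate_rasters(config: RasterTruthConfig, seed: int | None = None):
    """Generate a :class:`SoilStack` plus truth record.

    Fields are spatially smooth; q05/q95 bands are generated from a known
    per-cell SD through the normal-percentile identity (so
    ``sd_from_percentiles`` recovers the truth exactly); a configured
    fraction of cells is organic in every interval (exercising the
    invalid-cell path) by pushing SOC above the mineral threshold and BD
    below it.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = (config.nrows, config.ncols)
    z95 = stats.norm.ppf(0.95)

    organic = rng.random(shape) < config.organic_fraction
    layers = {}
    truth_fields = {}
    for interval in config.intervals:
        depth_scale = 1.0 - 0.3 * (interval[0] > 0)  # deeper: slightly poorer
        tn = _smooth_field(rng, shape, *config.tn_range,
                           config.smooth_sigma) * depth_scale
        soc = _smooth_field(rng, shape, *config.soc_range,
                            config.smooth_sigma) * depth_scale
        bd = _smooth_field(rng, shape, *config.bd_range, config.smooth_sigma)
        soc = np.where(organic, 15.0, soc)   # > 10% SOC -> organic
        bd = np.where(organic, 0.6, bd)
        for var, mean in (("TN", tn), ("SOC", soc), ("BD", bd)):
            sd = config.rel_sd * mean if var != "BD" else np.zeros(shape)
            layers[(var, "mean", interval)] = Raster(mean.copy(),
                                                     config.cellsize)
            layers[(var, "q05", interval)] = Raster(mean - z95 * sd,
                                                    config.cellsize)
            layers[(var, "q95", interval)] = Raster(mean + z95 * sd,
                                                    config.cellsize)
            truth_fields[f"{var}_{interval[0]:g}_{interval[1]:g}_sd"] = sd
    baseline = _smooth_field(rng, shape, *config.baseline_range,
                             config.smooth_sigma)
    stack = SoilStack(layers=layers,
                      baseline_er=Raster(baseline, config.cellsize))
    truth = {"config": asdict(config), "seed": int(seed),
             "organic_mask": organic.tolist()}
    return stack, truth
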