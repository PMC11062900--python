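"""Monte Carlo spatial upscaling of the soil-driver metaregression.

Applies a fitted two-moderator model (lnROM ~ TN + C:N, mineral layer) to
gridded soil data.  Per grid cell:

1. classify depth intervals (0-60 cm) as mineral by TN/SOC/BD thresholds
   and depth-weight TN and SOC over the mineral layer;
2. convert the 5th/95th percentile bands to a standard deviation,
   sd = (q95 - q05) / (2 * qnorm(0.95));
3. draw correlated (TN, SOC) pairs from a lower-truncated bivariate normal
   whose location is adjusted so the truncated mean hits the grid mean;
4. form C:N = SOC/TN and correct its derivation bias with one of a set of
   bootstrap linear regressions per draw;
5. predict the log response ratio with its standard error for every draw
   and combine draws with the equal-weight normal-mixture SD;
6. report percent change, its SD, the coefficient of variation, the
   soil-input/combined uncertainty ratio, and absolute change against a
   baseline respiration grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import RunConfig
from .meta import MetaModel
from .moderators import predict_with_se
from .rasters import Raster, SoilStack

__all__ = [
    "SoilCell",
    "extract_mineral_layer",
    "sd_from_percentiles",
    "adjust_truncated_means",
    "sample_soil",
    "bootstrap_cn_regressions",
    "cn_bias_correct",
    "mixture_sd",
    "upscale_cell",
    "decompose_uncertainty",
    "build_soil_cells",
    "upscale_grid",
    "regional_totals",
]

#: 2 * qnorm(0.95), the denominator converting a 90% band to a sd.
_Q90_WIDTH = 2.0 * stats.norm.ppf(0.95)


@dataclass
class SoilCell:
    """Mineral-layer summary of one grid cell (TN/SOC in % by mass)."""

    cell_id: int
    area: float  # m2
    tn_mean: float
    tn_sd: float
    soc_mean: float
    soc_sd: float
    baseline_er: float = np.nan  # gC m-2 yr-1
    valid: bool = True


def extract_mineral_layer(
    tops, bottoms, tn, soc, bd, *,
    tn_max: float = 0.01, soc_max: float = 0.1, bd_min: float = 1.0,
    depth_max: float = 60.0,
):
    """Depth-weighted mineral-layer means of TN and SOC for one profile.

    ``tn``/``soc`` are in g/g, ``bd`` in g/cm3; intervals (cm) must tile
    0..depth_max without gaps or overlap.  An interval is mineral iff
    TN <= tn_max and SOC <= soc_max and BD >= bd_min (organic horizons are
    nutrient- and carbon-rich and light).  Returns
    ``(tn_mean, soc_mean, valid)``; a profile with no mineral interval is
    invalid.
    """
    tops = np.asarray(tops, float)
    bottoms = np.asarray(bottoms, float)
    order = np.argsort(tops)
    tops, bottoms = tops[order], bottoms[order]
    tn = np.asarray(tn, float)[order]
    soc = np.asarray(soc, float)[order]
    bd = np.asarray(bd, float)[order]
    if tops[0] != 0.0 or not np.isclose(bottoms[-1], depth_max) or np.any(
            ~np.isclose(bottoms[:-1], tops[1:])):
        raise ValueError("depth intervals must tile 0-%g cm exactly" % depth_max)
    mineral = (tn <= tn_max) & (soc <= soc_max) & (bd >= bd_min)
    if not mineral.any():
        return np.nan, np.nan, False
    w = (bottoms - tops)[mineral]
    w = w / w.sum()
    return float(np.sum(w * tn[mineral])), float(np.sum(w * soc[mineral])), True


def sd_from_percentiles(q05, q95):
    """Standard deviation implied by a normal 5th/95th percentile band."""
    q05 = np.asarray(q05, float)
    q95 = np.asarray(q95, float)
    return (q95 - q05) / _Q90_WIDTH


# -- truncated bivariate sampling -----------------------------------------


def _lower_trunc_means(mux, muy, sx, sy, Lx, Ly, rho):
    """E[X], E[Y] and mass of a bivariate normal truncated below at (Lx, Ly)
    (Rosenbaum moment identities)."""
    a = (Lx - mux) / sx
    b = (Ly - muy) / sy
    s = np.sqrt(1.0 - rho**2)
    P = stats.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]]).cdf(
        [-a, -b])
    if P <= 0:
        return np.nan, np.nan, 0.0
    za = stats.norm.pdf(a) * stats.norm.sf((b - rho * a) / s)
    zb = stats.norm.pdf(b) * stats.norm.sf((a - rho * b) / s)
    return (mux + sx * (za + rho * zb) / P,
            muy + sy * (zb + rho * za) / P, P)


def adjust_truncated_means(mx, sx, Lx, my, sy, Ly, rho,
                           tol: float = 1e-10, max_iter: int = 60):
    """Location parameters whose lower-truncated bivariate normal has means
    (mx, my).

    Alternates per-variable scalar root-finds on the truncated-mean
    identity until both marginal means match the targets.  Returns
    ``(mux, muy, ok)``; on failure (pathological sd >> mean) the unadjusted
    means are returned with ``ok=False`` and the caller clips instead.
    """
    if sx == 0.0 and sy == 0.0:
        return mx, my, True
    # truncation negligible at the unadjusted location -> identity
    _, _, mass = _lower_trunc_means(mx, my, max(sx, 1e-300), max(sy, 1e-300),
                                    Lx, Ly, rho)
    if mass > 1.0 - 1e-12:
        return mx, my, True
    mux, muy = mx, my
    try:
        for _ in range(max_iter):
            prev = (mux, muy)
            if sx > 0:
                mux = optimize.brentq(
                    lambda m: _lower_trunc_means(m, muy, sx, max(sy, 1e-300),
                                                 Lx, Ly, rho)[0] - mx,
                    mx - 8 * sx, mx + sx + 1e-12, xtol=tol)
            if sy > 0:
                muy = optimize.brentq(
                    lambda m: _lower_trunc_means(mux, m, max(sx, 1e-300), sy,
                                                 Lx, Ly, rho)[1] - my,
                    my - 8 * sy, my + sy + 1e-12, xtol=tol)
            if abs(mux - prev[0]) < tol * max(sx, 1.0) and \
               abs(muy - prev[1]) < tol * max(sy, 1.0):
                break
        return mux, muy, True
    except ValueError:
        return mx, my, False


def sample_soil(cell: SoilCell, n_draws: int, corr: float,
                trunc_frac: float, rng: np.random.Generator):
    """Draw ``n_draws`` correlated (TN, SOC) pairs for one cell.

    Pairs come from a bivariate normal with correlation ``corr``, truncated
    below at ``trunc_frac`` times each mean, with the location adjusted so
    the truncated means equal the cell means.  Returns ``(tn, soc, ok)``
    with ``ok=False`` when the adjustment failed and draws were clipped to
    the bound instead.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    mx, sx = cell.tn_mean, cell.tn_sd
    my, sy = cell.soc_mean, cell.soc_sd
    if sx == 0.0 and sy == 0.0:
        return np.full(n_draws, mx), np.full(n_draws, my), True
    Lx, Ly = trunc_frac * mx, trunc_frac * my
    mux, muy, ok = adjust_truncated_means(mx, sx, Lx, my, sy, Ly, corr)
    cov = np.array([[sx**2, corr * sx * sy], [corr * sx * sy, sy**2]])
    chol = np.linalg.cholesky(cov + 1e-300 * np.eye(2))
    loc = np.array([mux, muy])
    tn = np.empty(n_draws)
    soc = np.empty(n_draws)
    filled = 0
    attempts = 0
    while filled < n_draws:
        m = max(2 * (n_draws - filled), 64)
        z = rng.standard_normal((m, 2)) @ chol.T + loc
        if ok:
            acc = z[(z[:, 0] >= Lx) & (z[:, 1] >= Ly)]
        else:
            acc = np.clip(z, [Lx, Ly], None)
        take = min(len(acc), n_draws - filled)
        tn[filled:filled + take] = acc[:take, 0]
        soc[filled:filled + take] = acc[:take, 1]
        filled += take
        attempts += 1
        if attempts > 1000 and filled == 0:
            # acceptance region has negligible mass; fall back to clipping
            ok = False
    return tn, soc, ok


def bootstrap_cn_regressions(calculated_cn, reported_cn, n: int = 100,
                             rng: np.random.Generator | None = None):
    """Bootstrap linear regressions of reported on calculated C:N.

    Returns an (n, 2) array of (intercept, slope) pairs quantifying the
    bias of deriving C:N as SOC/TN; each Monte Carlo iteration uses one of
    them.
    """
    x = np.asarray(calculated_cn, float)
    ycn = np.asarray(reported_cn, float)
    keep = np.isfinite(x) & np.isfinite(ycn)
    x, ycn = x[keep], ycn[keep]
    if x.size < 3:
        raise ValueError("need >= 3 (calculated, reported) C:N pairs")
    rng = np.random.default_rng() if rng is None else rng
    out = np.empty((n, 2))
    for j in range(n):
        idx = rng.integers(0, x.size, x.size)
        slope, intercept = np.polyfit(x[idx], ycn[idx], 1)
        out[j] = (intercept, slope)
    return out


def cn_bias_correct(tn_draw, soc_draw, coeffs):
    """Bias-corrected C:N for draws: a + b * (SOC/TN).

    ``coeffs`` is either one (a, b) pair or an array of pairs cycled over
    draw indices.
    """
    tn_draw = np.asarray(tn_draw, float)
    soc_draw = np.asarray(soc_draw, float)
    if np.any(tn_draw <= 0):
        raise ValueError("nonpositive TN draw (should not occur post-truncation)")
    coeffs = np.atleast_2d(np.asarray(coeffs, float))
    idx = np.arange(tn_draw.size) % coeffs.shape[0]
    a = coeffs[idx, 0]
    b = coeffs[idx, 1]
    return a + b * (soc_draw / tn_draw)


def mixture_sd(means, ses):
    """SD of an equal-weight mixture of normals N(mean_j, se_j^2):
    sqrt(mean(MEAN^2 + SE^2) - mean(MEAN)^2)."""
    means = np.asarray(means, float)
    ses = np.asarray(ses, float)
    if means.shape != ses.shape:
        raise ValueError("means and ses must have equal length")
    var = np.mean(means**2 + ses**2) - np.mean(means) ** 2
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class UpscaleResult:
    cell_id: int
    rom_mean: float
    rom_sd: float
    rom_sd_input: float
    pct_change_mean: float
    pct_change_sd: float
    cv: float
    uncertainty_ratio: float
    abs_change: float
    sampling_ok: bool = True


def _cell_predictions(cell, model, regressions, n_draws, config, rng):
    tn, soc, ok = sample_soil(cell, n_draws, config.tn_soc_correlation,
                              config.truncation_fraction, rng)
    cn = cn_bias_correct(tn, soc, regressions)
    X = np.column_stack([np.ones(n_draws), tn, cn])
    means, ses = predict_with_se(model, X)
    return means, ses, ok


def upscale_cell(cell: SoilCell, model: MetaModel, regressions,
                 n_draws: int, config: RunConfig,
                 rng: np.random.Generator) -> UpscaleResult:
    """Monte Carlo prediction of the warming response for one cell.

    Draw combination happens on the lnROM scale (the model's native scale)
    via :func:`mixture_sd`; percent change and its SD are delta-method
    transforms, and absolute change multiplies the baseline respiration.
    The soil-input-only SD reuses the same draws with the coefficient
    covariance zeroed, so the uncertainty ratio is computed on shared
    substreams by construction.
    """
    if not cell.valid:
        return UpscaleResult(cell.cell_id, *([np.nan] * 8))
    if not model.converged:
        raise ValueError("refusing to upscale a non-converged model")
    means, ses, ok = _cell_predictions(cell, model, regressions, n_draws,
                                       config, rng)
    rom_mean = float(np.mean(means))
    rom_sd = mixture_sd(means, ses)
    rom_sd_input = mixture_sd(means, np.zeros_like(ses))
    pct_mean = 100.0 * (np.exp(rom_mean) - 1.0)
    pct_sd = 100.0 * np.exp(rom_mean) * rom_sd
    cv = pct_sd / abs(pct_mean) if abs(pct_mean) > 1e-6 else np.nan
    ratio = rom_sd_input / rom_sd if rom_sd > 0 else np.nan
    abs_change = cell.baseline_er * (np.exp(rom_mean) - 1.0)
    return UpscaleResult(cell.cell_id, rom_mean, rom_sd, rom_sd_input,
                         pct_mean, pct_sd, cv, ratio, abs_change, ok)


def decompose_uncertainty(cell: SoilCell, model: MetaModel, regressions,
                          n_draws: int, config: RunConfig, seed: int) -> float:
    """Soil-input-only / combined SD ratio for one cell.

    Runs the propagation twice on identical soil-draw substreams: once with
    the full coefficient covariance, once with parameters fixed at their
    estimates (SE = 0).
    """
    rng1 = np.random.default_rng(np.random.SeedSequence(seed))
    rng2 = np.random.default_rng(np.random.SeedSequence(seed))
    means, ses, _ = _cell_predictions(cell, model, regressions, n_draws,
                                      config, rng1)
    means2, _, _ = _cell_predictions(cell, model, regressions, n_draws,
                                     config, rng2)
    assert np.allclose(means, means2)  # shared substream
    combined = mixture_sd(means, ses)
    input_only = mixture_sd(means2, np.zeros_like(means2))
    return input_only / combined if combined > 0 else np.nan


# -- grid-level driver -----------------------------------------------------


def build_soil_cells(stack: SoilStack, config: RunConfig) -> pd.DataFrame:
    """Mineral-layer cell table from a soil stack.

    Layer values are % by mass for TN/SOC (matching the metaregression
    scale) and g/cm3 for BD; classification thresholds in the config are
    g/g.  Cell SDs come from depth-weighted q05/q95 over the mineral
    intervals via :func:`sd_from_percentiles`.
    """
    grid = stack.grid
    nrows, ncols = grid.shape
    intervals = stack.intervals
    tops = np.array([iv[0] for iv in intervals])
    bottoms = np.array([iv[1] for iv in intervals])
    thick = bottoms - tops
    get = lambda var, stat: np.stack(
        [stack.array(var, stat, iv) for iv in intervals])
    tn_mean, soc_mean, bd_mean = (get(v, "mean") for v in ("TN", "SOC", "BD"))
    # mineral classification on the mean layers (thresholds g/g; layers %)
    mineral = ((tn_mean / 100.0 <= config.tn_max)
               & (soc_mean / 100.0 <= config.soc_max)
               & (bd_mean >= config.bd_min))
    w = mineral * thick[:, None, None]
    wsum = w.sum(axis=0)
    valid = (wsum > 0) & ~np.isnan(tn_mean).any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        def wmean(arr):
            return np.where(valid, np.nansum(w * arr, axis=0) / wsum, np.nan)
        tn = wmean(tn_mean)
        soc = wmean(soc_mean)
        tn_sd = sd_from_percentiles(wmean(get("TN", "q05")),
                                    wmean(get("TN", "q95")))
        soc_sd = sd_from_percentiles(wmean(get("SOC", "q05")),
                                     wmean(get("SOC", "q95")))
    base = (stack.baseline_er.data if stack.baseline_er is not None
            else np.full(grid.shape, np.nan))
    rows = []
    for idx in range(nrows * ncols):
        r, c = divmod(idx, ncols)
        rows.append(SoilCell(
            cell_id=idx, area=grid.cell_area,
            tn_mean=float(tn[r, c]), tn_sd=float(tn_sd[r, c]),
            soc_mean=float(soc[r, c]), soc_sd=float(soc_sd[r, c]),
            baseline_er=float(base[r, c]), valid=bool(valid[r, c]),
        ))
    df = pd.DataFrame([vars(s) for s in rows])
    df.attrs["shape"] = grid.shape
    df.attrs["cellsize"] = grid.cellsize
    return df


def upscale_grid(cells: pd.DataFrame, model: MetaModel, regressions,
                 config: RunConfig, seed: int | None = None,
                 n_draws: int | None = None):
    """Upscale every valid cell; returns (results DataFrame, rasters dict).

    Each cell gets its own seed substream derived from ``seed``, so results
    are reproducible and independent of cell evaluation order.
    """
    n_draws = config.mc_draws if n_draws is None else n_draws
    seed = config.seed if seed is None else seed
    results = []
    for row in cells.itertuples(index=False):
        cell = SoilCell(**{f: getattr(row, f) for f in (
            "cell_id", "area", "tn_mean", "tn_sd", "soc_mean", "soc_sd",
            "baseline_er", "valid")})
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(cell.cell_id,)))
        results.append(vars(upscale_cell(cell, model, regressions, n_draws,
                                         config, rng)))
    res = pd.DataFrame(results)
    rasters = {}
    if "shape" in cells.attrs:
        shape = cells.attrs["shape"]
        cs = cells.attrs.get("cellsize", 1000.0)
        for col in ("pct_change_mean", "pct_change_sd", "cv",
                    "uncertainty_ratio", "abs_change"):
            rasters[col] = Raster(res[col].to_numpy(float).reshape(shape),
                                  cellsize=cs)
    return res, rasters


def regional_totals(results: pd.DataFrame, cells: pd.DataFrame) -> dict:
    """Regional respiration totals in PgC yr-1.

    Sums baseline and predicted fluxes over valid cells (area m2 x flux
    gC m-2 yr-1 x 1e-15 Pg/g); the SD of the change treats cells as
    independent (a documented simplification — gridded soil errors carry no
    spatial covariance information).
    """
    df = results.merge(cells[["cell_id", "area", "baseline_er", "valid"]],
                       on="cell_id")
    df = df[df["valid"] & np.isfinite(df["rom_mean"])
            & np.isfinite(df["baseline_er"])]
    if df.empty or df["area"].isna().any():
        raise ValueError("regional totals need per-cell area and baseline ER")
    to_pg = 1e-15
    base = float(np.sum(df["area"] * df["baseline_er"]) * to_pg)
    delta = float(np.sum(df["area"] * df["baseline_er"]
                         * (np.exp(df["rom_mean"]) - 1.0)) * to_pg)
    per_cell_sd = (df["area"] * df["baseline_er"] * np.exp(df["rom_mean"])
                   * df["rom_sd"])
    delta_sd = float(np.sqrt(np.sum(per_cell_sd**2)) * to_pg)
    return {
        "baseline_pg": base,
        "warmed_pg": base + delta,
        "delta_pg": delta,
        "delta_sd_pg": delta_sd,
        "delta_pct": 100.0 * delta / base,
        "delta_pct_sd": 100.0 * delta_sd / base,
        "n_cells": int(len(df)),
    }
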