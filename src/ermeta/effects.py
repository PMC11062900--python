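"""Effect-size construction from plot-level flux data.

Turns daily plot-level ecosystem-respiration (ER) measurements into one
standardized effect size per dataset (one experiment x measurement-year):

1. unit standardization to gCO2 m-2 d-1,
2. a single-pass +/- k.sd outlier filter within each dataset,
3. growing-season treatment summaries (plot means are the replication unit),
4. Hedges' g standardized mean difference (SMD), the log ratio of means
   (lnROM) and the raw mean difference (MD), each with its large-sample
   sampling variance, weighting a dataset by 1/variance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_MASS_CO2",
    "MOLAR_MASS_C",
    "C_PER_CO2",
    "UNIT_FACTORS",
    "TreatmentSummary",
    "standardize_units",
    "filter_outliers",
    "season_summaries",
    "hedges_smd",
    "log_rom",
    "raw_md",
    "percent_change",
    "compute_effect_sizes",
]

MOLAR_MASS_CO2 = 44.009  # g/mol
MOLAR_MASS_C = 12.011  # g/mol
SECONDS_PER_DAY = 86_400.0
#: gC per gCO2
C_PER_CO2 = MOLAR_MASS_C / MOLAR_MASS_CO2

#: Multiplicative factors to gCO2 m-2 d-1.
UNIT_FACTORS = {
    "gCO2 m-2 d-1": 1.0,
    "gCO2 m-2 h-1": 24.0,
    "mgCO2 m-2 h-1": 24.0 * 1e-3,
    "umol CO2 m-2 s-1": 1e-6 * MOLAR_MASS_CO2 * SECONDS_PER_DAY,
    "gC m-2 d-1": MOLAR_MASS_CO2 / MOLAR_MASS_C,
}

DATASET_KEY = ["experiment_id", "year"]


class UnknownUnitError(ValueError):
    pass


def standardize_units(values, units) -> np.ndarray:
    """Convert flux values to gCO2 m-2 d-1.

    ``values`` and ``units`` are broadcastable array-likes; ``units`` entries
    must be keys of :data:`UNIT_FACTORS`.
    """
    units = np.asarray(units, dtype=object)
    values = np.asarray(values, dtype=float)
    bad = sorted({u for u in np.ravel(units) if u not in UNIT_FACTORS})
    if bad:
        raise UnknownUnitError(f"unrecognized flux unit(s): {bad}")
    factors = np.vectorize(UNIT_FACTORS.__getitem__, otypes=[float])(units)
    return values * factors


def filter_outliers(flux: pd.DataFrame, k: float = 3.0):
    """Single-pass outlier removal within each dataset, treatments pooled.

    Observations with |x - mean| > k*sd, where mean and sd are computed once
    over all retained-unit observations of the dataset (both treatments),
    are dropped.  sd = 0 (constant dataset) removes nothing.

    Returns ``(retained, report)`` where ``report`` has one row per dataset
    (n_total, n_removed) plus the global fraction in ``report.attrs``.
    """
    if k <= 0:
        raise ValueError("outlier k must be > 0")
    grp = flux.groupby(DATASET_KEY)["er_value"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    keep = (flux["er_value"] - mean).abs() <= k * sd
    keep |= sd == 0.0
    retained = flux[keep].copy()
    report = (
        pd.DataFrame({"n_total": grp.size(), "n_removed": (~keep).groupby(
            [flux[c] for c in DATASET_KEY]).sum()})
        .reset_index()
    )
    n_tot = int(report["n_total"].sum())
    report.attrs["global_fraction_removed"] = (
        float(report["n_removed"].sum()) / n_tot if n_tot else 0.0
    )
    return retained, report


@dataclass(frozen=True)
class TreatmentSummary:
    """Growing-season summary of one treatment arm of one dataset.

    ``mean``/``sd`` are across plot-level growing-season means (gC m-2 d-1
    for ER); ``n`` counts plots, not plot-days.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("treatment summary needs >= 2 plots")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def season_summaries(dataset: pd.DataFrame):
    """Per-treatment growing-season summaries for one dataset.

    Daily values (gCO2 m-2 d-1) are averaged per plot, converted to
    gC m-2 d-1, then summarized (mean, sd, n) across plots per treatment.

    Raises ``ValueError`` if either treatment has fewer than two plots.
    """
    out = {}
    for treatment, sub in dataset.groupby("treatment", observed=True):
        plot_means = sub.groupby("plot_id")["er_value"].mean() * C_PER_CO2
        if len(plot_means) < 2:
            raise ValueError(
                f"treatment {treatment!r} has {len(plot_means)} plot(s); need >= 2"
            )
        out[treatment] = TreatmentSummary(
            mean=float(plot_means.mean()),
            sd=float(plot_means.std(ddof=1)),
            n=int(len(plot_means)),
        )
    for needed in ("control", "warmed"):
        if needed not in out:
            raise ValueError(f"dataset lacks treatment {needed!r}")
    return out["control"], out["warmed"]


def hedges_smd(c: TreatmentSummary, w: TreatmentSummary):
    """Hedges' g (bias-corrected SMD, warmed minus control) and its variance.

    d = (m_w - m_c)/s_p with the (n-1)-weighted pooled sd; J = 1 - 3/(4m - 1)
    with m = n_w + n_c - 2; g = J*d; var = J^2 * [(n_w+n_c)/(n_w*n_c)
    + d^2/(2(n_w+n_c))].
    """
    m = w.n + c.n - 2
    sp2 = ((w.n - 1) * w.sd**2 + (c.n - 1) * c.sd**2) / m
    if sp2 <= 0:
        raise ZeroDivisionError("zero pooled variance")
    d = (w.mean - c.mean) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    g = j * d
    var = j**2 * ((w.n + c.n) / (w.n * c.n) + d**2 / (2.0 * (w.n + c.n)))
    return float(g), float(var)


def log_rom(c: TreatmentSummary, w: TreatmentSummary):
    """Log ratio of means ln(m_w/m_c) and its large-sample variance."""
    if c.mean <= 0 or w.mean <= 0:
        raise ValueError("log ratio of means needs positive treatment means")
    est = np.log(w.mean / c.mean)
    var = w.sd**2 / (w.n * w.mean**2) + c.sd**2 / (c.n * c.mean**2)
    return float(est), float(var)


def raw_md(c: TreatmentSummary, w: TreatmentSummary):
    """Raw mean difference m_w - m_c and its variance."""
    est = w.mean - c.mean
    var = w.sd**2 / w.n + c.sd**2 / c.n
    return float(est), float(var)


def percent_change(rom: float) -> float:
    """Back-transform a log ratio of means to percent change, 100(e^rom - 1)."""
    return 100.0 * (np.exp(rom) - 1.0)


_ES_FUNCS = {"SMD": hedges_smd, "lnROM": log_rom, "MD": raw_md}


def compute_effect_sizes(
    flux: pd.DataFrame,
    *,
    outlier_k: float = 3.0,
    es_types=("SMD", "lnROM"),
    start_years=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full flux -> effect-size pipeline.

    Parameters
    ----------
    flux
        Long table with columns site_id, experiment_id, plot_id, treatment,
        date (datetime-like), er_value (gCO2 m-2 d-1), and optionally
        start_year and year.  If ``year`` is absent it is taken from
        ``date``.  The outlier filter is applied exactly once, here.
    start_years
        Optional mapping experiment_id -> treatment start year, used (with
        the measurement year) to compute warming duration.  A ``start_year``
        column in ``flux`` takes precedence.

    Returns
    -------
    (effects, exclusions)
        ``effects`` has one row per dataset and effect-size type with
        columns experiment_id, year, es_type, estimate, variance, n_control,
        n_warmed, duration.  ``exclusions`` lists dropped datasets with
        reasons (too few plots, zero pooled variance, nonpositive mean).
    """
    flux = flux.copy()
    if "year" not in flux.columns:
        flux["year"] = pd.to_datetime(flux["date"]).dt.year
    retained, _ = filter_outliers(flux, k=outlier_k)

    rows, excl = [], []
    for (exp, year), ds in retained.groupby(DATASET_KEY):
        if "start_year" in ds.columns and ds["start_year"].notna().any():
            duration = int(year) - int(ds["start_year"].iloc[0])
        elif start_years is not None and exp in start_years:
            duration = int(year) - int(start_years[exp])
        else:
            duration = 0
        try:
            c, w = season_summaries(ds)
        except ValueError as e:
            excl.append({"experiment_id": exp, "year": year, "reason": str(e)})
            continue
        for es_type in es_types:
            try:
                est, var = _ES_FUNCS[es_type](c, w)
            except (ZeroDivisionError, ValueError) as e:
                excl.append(
                    {"experiment_id": exp, "year": year,
                     "reason": f"{es_type}: {e}"}
                )
                continue
            rows.append(
                {"experiment_id": exp, "year": int(year), "es_type": es_type,
                 "estimate": est, "variance": var, "n_control": c.n,
                 "n_warmed": w.n, "duration": duration}
            )
    effects = pd.DataFrame(
        rows, columns=["experiment_id", "year", "es_type", "estimate",
                       "variance", "n_control", "n_warmed", "duration"]
    )
    exclusions = pd.DataFrame(excl, columns=["experiment_id", "year", "reason"])
    return effects, exclusions
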