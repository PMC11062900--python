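"""Tabular ingestion and output schemas.

Canonical interchange formats (tidy CSV):

- flux table: site_id, experiment_id, plot_id, treatment, date (ISO-8601),
  er_value, er_unit [, start_year];
- driver table: experiment_id, year, driver, statistic, value, with
  statistic in {control_mean, control_sd, n_control, warmed_mean,
  warmed_sd, n_warmed};
- effect-size table: experiment_id, year, es_type, estimate, variance,
  n_control, n_warmed, duration.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .effects import TreatmentSummary, standardize_units

log = logging.getLogger("ermeta")

FLUX_COLUMNS = ["site_id", "experiment_id", "plot_id", "treatment", "date",
                "er_value", "er_unit"]
DRIVER_COLUMNS = ["experiment_id", "year", "driver", "statistic", "value"]
DRIVER_STATISTICS = {"control_mean", "control_sd", "n_control",
                     "warmed_mean", "warmed_sd", "n_warmed"}
EFFECT_COLUMNS = ["experiment_id", "year", "es_type", "estimate", "variance",
                  "n_control", "n_warmed", "duration"]


class IngestError(ValueError):
    pass


def read_flux_table(path, config: RunConfig | None = None,
                    permissive: bool = False) -> pd.DataFrame:
    """Read and validate a flux CSV.

    Values are standardized to gCO2 m-2 d-1, rows outside the site's
    growing-season months are dropped (count logged and stored in
    ``df.attrs['n_out_of_season']``), duplicate
    (experiment, plot, treatment, date) records and bad rows are fatal
    unless ``permissive``.
    """
    config = config or RunConfig()
    df = pd.read_csv(path, dtype={"site_id": str, "experiment_id": str,
                                  "plot_id": str})
    missing = [c for c in FLUX_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"flux table missing required column(s): {missing}")

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    values = pd.to_numeric(df["er_value"], errors="coerce")
    bad = df.index[dates.isna() | values.isna()]
    if len(bad):
        msg = f"{len(bad)} row(s) with unparseable date/value (first at row {bad[0]})"
        if not permissive:
            raise IngestError(msg)
        log.warning("dropping %s", msg)
        df = df.drop(index=bad)
        dates = dates.drop(index=bad)
        values = values.drop(index=bad)
    df = df.assign(date=dates, er_value=values.astype(float))

    bad_trt = set(df["treatment"].unique()) - {"control", "warmed"}
    if bad_trt:
        raise IngestError(f"unknown treatment level(s): {sorted(bad_trt)}")

    df["er_value"] = standardize_units(df["er_value"], df["er_unit"])
    df["er_unit"] = "gCO2 m-2 d-1"
    if (df["er_value"] < 0).any():
        raise IngestError("negative flux values after standardization")

    in_season = np.fromiter(
        (row.month in config.season_for(site)
         for site, row in zip(df["site_id"], df["date"])),
        dtype=bool, count=len(df))
    n_out = int((~in_season).sum())
    if n_out:
        log.info("dropping %d observation(s) outside the growing season", n_out)
    df = df[in_season].reset_index(drop=True)

    dup = df.duplicated(["experiment_id", "plot_id", "treatment", "date"])
    if dup.any():
        first = df[dup].iloc[0]
        raise IngestError(
            "duplicate observation for "
            f"({first['experiment_id']}, {first['plot_id']}, "
            f"{first['treatment']}, {first['date'].date()})")

    df["year"] = df["date"].dt.year
    df.attrs["n_out_of_season"] = n_out
    return df


def read_driver_table(path) -> pd.DataFrame:
    """Read and validate a long-format driver table."""
    df = pd.read_csv(path, dtype={"experiment_id": str, "driver": str,
                                  "statistic": str})
    missing = [c for c in DRIVER_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"driver table missing required column(s): {missing}")
    bad_stat = set(df["statistic"].unique()) - DRIVER_STATISTICS
    if bad_stat:
        raise IngestError(f"unknown driver statistic(s): {sorted(bad_stat)}")
    neg_n = df[df["statistic"].str.startswith("n_") & (df["value"] < 0)]
    if len(neg_n):
        raise IngestError(
            f"negative sample size for driver {neg_n.iloc[0]['driver']!r}")
    key = ["experiment_id", "year", "driver", "statistic"]
    dup = df.duplicated(key)
    if dup.any():
        first = df[dup].iloc[0]
        raise IngestError(
            "duplicate driver statistic for "
            f"({first['experiment_id']}, {first['year']}, "
            f"{first['driver']}, {first['statistic']})")
    return df


def driver_control_means(drivers: pd.DataFrame, driver: str) -> pd.Series:
    """Control-plot means of one driver, indexed by (experiment_id, year).

    These are the context-dependency moderators (no warmed summaries
    needed).
    """
    sub = drivers[(drivers["driver"] == driver)
                  & (drivers["statistic"] == "control_mean")]
    s = sub.set_index(["experiment_id", "year"])["value"]
    s.name = driver
    return s


def driver_summaries(drivers: pd.DataFrame, driver: str):
    """Per-dataset (control, warmed) treatment summaries for one driver.

    Only datasets with a complete 6-statistic block are returned; used to
    compute driver effect sizes (the indirect-warming-effect moderators).
    """
    sub = drivers[drivers["driver"] == driver]
    wide = sub.pivot_table(index=["experiment_id", "year"],
                           columns="statistic", values="value")
    needed = ["control_mean", "control_sd", "n_control",
              "warmed_mean", "warmed_sd", "n_warmed"]
    wide = wide.dropna(subset=[c for c in needed if c in wide.columns])
    out = {}
    for key, row in wide.iterrows():
        if any(c not in row for c in needed):
            continue
        out[key] = (
            TreatmentSummary(mean=row["control_mean"], sd=row["control_sd"],
                             n=int(row["n_control"])),
            TreatmentSummary(mean=row["warmed_mean"], sd=row["warmed_sd"],
                             n=int(row["n_warmed"])),
        )
    return out


def driver_effect_sizes(drivers: pd.DataFrame, driver: str,
                        es_type: str = "SMD") -> pd.Series:
    """Effect sizes of a driver itself (e.g. the SMD of TN between warmed
    and control plots), indexed by (experiment_id, year)."""
    from . import effects as es

    fn = {"SMD": es.hedges_smd, "MD": es.raw_md, "lnROM": es.log_rom}[es_type]
    vals = {}
    for key, (c, w) in driver_summaries(drivers, driver).items():
        try:
            vals[key] = fn(c, w)[0]
        except (ZeroDivisionError, ValueError):
            continue
    s = pd.Series(vals, dtype=float)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["experiment_id", "year"]) \
        if len(s) else s.index
    s.name = f"d{driver}" if es_type != "MD" else f"md_{driver}"
    return s


def write_effects(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, index=False, columns=EFFECT_COLUMNS)


def read_effects(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"experiment_id": str})
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"effect table missing column(s): {missing}")
    return df
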