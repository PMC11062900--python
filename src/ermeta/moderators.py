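"""Metaregression programme: temporal patterns, driver moderators, prediction.

Single-factor metaregressions relate per-dataset effect sizes to one
moderator at a time — either warming-induced changes in a driver (the
driver's own standardized effect size) or the ambient context (control-plot
means) — always with the full random structure and on the complete cases of
that moderator.  Temporal structure is summarized through warming duration
and four duration "age classes".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meta

__all__ = [
    "AGE_CLASS_LABELS",
    "assign_age_class",
    "ModeratorFit",
    "fit_single_factor",
    "temporal_analysis",
    "predict_with_se",
    "moderator_correlations",
]

# Closed integer intervals partitioning duration 0, 1, 2, ...
_AGE_BOUNDS = [(0, 4), (5, 9), (10, 14), (15, None)]
AGE_CLASS_LABELS = ["0-4", "5-9", "10-14", "15+"]


def assign_age_class(duration) -> np.ndarray:
    """Map warming duration (whole years; 0 = first summer) to its age class."""
    duration = np.asarray(duration)
    if np.any(duration < 0):
        raise ValueError("negative warming duration")
    out = np.empty(duration.shape, dtype=object)
    for label, (lo, hi) in zip(AGE_CLASS_LABELS, _AGE_BOUNDS):
        mask = duration >= lo if hi is None else (duration >= lo) & (duration <= hi)
        out[mask] = label
    return out


@dataclass
class ModeratorFit:
    """A fitted single-factor metaregression with its summary statistics."""

    moderator: str
    model: meta.MetaModel
    tests: meta.HeterogeneityTests
    pseudo_r2: float
    n: int
    names: list = field(default_factory=list)

    def to_row(self) -> dict:
        slope = self.model.beta[1] if self.model.p > 1 else np.nan
        se = self.model.se[1] if self.model.p > 1 else np.nan
        return {
            "moderator": self.moderator, "n": self.n,
            "estimate": slope, "se": se,
            "Qm": self.tests.Qm, "Qm_df": self.tests.Qm_df,
            "Qm_p": self.tests.Qm_p,
            "QE": self.tests.QE, "QE_p": self.tests.QE_p,
            "pseudo_R2": self.pseudo_r2,
        }


def _design_from_values(values: pd.Series, categorical: bool):
    """Intercept + moderator design (treatment coding for categoricals)."""
    if categorical:
        dummies = pd.get_dummies(values.astype("category"), drop_first=True)
        if dummies.shape[1] == 0:
            raise ValueError("no contrast: moderator is constant")
        X = np.column_stack([np.ones(len(values)), dummies.to_numpy(float)])
        names = ["intercept"] + [str(c) for c in dummies.columns]
    else:
        x = values.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("no contrast: moderator is constant")
        X = np.column_stack([np.ones(len(x)), x])
        names = ["intercept", str(values.name or "moderator")]
    return X, names


def _structure_kw(effects: pd.DataFrame, structure: dict | None):
    kw = {"experiment": effects["experiment_id"].to_numpy(),
          "years": effects["year"].to_numpy(dtype=float),
          "use_exp": True, "use_dataset": True, "use_car": True}
    if structure:
        kw.update(structure)
    return kw


def fit_single_factor(
    effects: pd.DataFrame,
    moderator: pd.Series | str,
    *,
    categorical: bool = False,
    structure: dict | None = None,
) -> ModeratorFit:
    """Fit one single-factor metaregression.

    Parameters
    ----------
    effects
        Effect-size table (one es_type) with experiment_id, year, estimate,
        variance, duration columns.
    moderator
        Either a column name in ``effects`` or a Series indexed by
        (experiment_id, year).  Rows without a moderator value are dropped
        (complete-case per model; the returned ``n`` is what was fitted).
    categorical
        Dummy-code the moderator (treatment coding, first level reference).
    structure
        Overrides for the random structure flags passed to ``meta.fit``.

    Returns the REML fit, Q statistics and McFadden's pseudo-R2 computed
    from ML fits of the model and the intercept-only null on the identical
    complete-case subset.
    """
    df = effects.reset_index(drop=True).copy()
    if isinstance(moderator, str):
        name = moderator
        df["_mod"] = df[moderator]
    else:
        name = str(moderator.name or "moderator")
        keyed = df.set_index(["experiment_id", "year"]).index
        df["_mod"] = moderator.reindex(keyed).to_numpy()
    df = df[df["_mod"].notna()].reset_index(drop=True)
    n = len(df)
    if n < 3:
        raise ValueError(f"moderator {name!r}: only {n} complete cases (need >= 3)")
    X, names = _design_from_values(df["_mod"].rename(name), categorical)

    kw = _structure_kw(df, structure)
    y = df["estimate"].to_numpy(float)
    v = df["variance"].to_numpy(float)
    model = meta.fit(y, v, X, names=names, ml_refit=True, **kw)
    tests = meta.q_statistics(y, v, X, model)

    null = meta.fit(y, v, np.ones((n, 1)), method="ML", **kw)
    ll0, ll1 = null.loglik_ml, model.loglik_ml
    pseudo_r2 = float(1.0 - ll1 / ll0) if ll0 not in (0.0, None) else np.nan

    return ModeratorFit(moderator=name, model=model, tests=tests,
                        pseudo_r2=pseudo_r2, n=n, names=names)


def predict_with_se(model: meta.MetaModel, X_new):
    """Fixed-effect predictions x*'beta with SE sqrt(x*' Vb x*).

    No random-effect variance is added: this is the prediction of the mean
    response surface, as used by the spatial upscaling.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.p:
        raise ValueError(
            f"newdata has {X_new.shape[1]} columns, model has {model.p}")
    mean = X_new @ np.asarray(model.beta, float)
    Vb = np.asarray(model.vcov_beta, float)
    se = np.sqrt(np.einsum("ij,jk,ik->i", X_new, Vb, X_new))
    return mean, se


def temporal_analysis(effects: pd.DataFrame, *, structure: dict | None = None):
    """Temporal pattern of the warming response.

    Returns a dict with:

    - ``class_means``: per-age-class mean effect, SE, CI and z-test of
      mean != 0 from a cell-means model over all data;
    - ``class_qm``: the omnibus Qm for age-class differences from the
      treatment-coded model (first class reference);
    - ``class_slopes``: within-class duration slopes (classes with < 2
      datasets are reported as NA);
    - ``overall_slope``: the across-all-years duration slope model.
    """
    df = effects.reset_index(drop=True).copy()
    if df["duration"].isna().any():
        raise ValueError("durations required for all effects")
    df["age_class"] = assign_age_class(df["duration"].to_numpy())
    kw = _structure_kw(df, structure)
    y = df["estimate"].to_numpy(float)
    v = df["variance"].to_numpy(float)

    present = [c for c in AGE_CLASS_LABELS if (df["age_class"] == c).any()]
    # cell-means coding: one column per class, no intercept
    Xc = np.column_stack([(df["age_class"] == c).to_numpy(float) for c in present])
    cell = meta.fit(y, v, Xc, names=present, **kw)
    class_means = meta.wald_ci(cell)

    class_qm = np.nan
    if len(present) > 1:
        contr = fit_single_factor(df, "age_class", categorical=True,
                                  structure=structure)
        class_qm = contr.tests.Qm

    rows = []
    for label in AGE_CLASS_LABELS:
        sub = df[df["age_class"] == label]
        if len(sub) < 2 or sub["duration"].nunique() < 2:
            rows.append({"age_class": label, "n": len(sub), "slope": np.nan,
                         "se": np.nan, "Qm": np.nan, "Qm_p": np.nan})
            continue
        mf = fit_single_factor(sub, "duration", structure=structure)
        rows.append({"age_class": label, "n": mf.n,
                     "slope": mf.model.beta[1], "se": mf.model.se[1],
                     "Qm": mf.tests.Qm, "Qm_p": mf.tests.Qm_p})
    class_slopes = pd.DataFrame(rows)

    overall = fit_single_factor(df, "duration", structure=structure)
    return {
        "class_means": class_means.assign(age_class=present),
        "class_qm": class_qm,
        "class_slopes": class_slopes,
        "overall_slope": overall,
    }


def moderator_correlations(moderators: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among moderators (collinearity screen).

    Purely a report: nothing is excluded automatically.
    """
    return moderators.corr(method="pearson", numeric_only=True)
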