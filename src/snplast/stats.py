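"""Behavioural statistics: success curves, days-to-criterion, trial-outcome
logistic regression, and rank-based group comparisons.

The shared trial-record schema (one row per trial) is::

    subject, group, stage, day, trial, outcome

with ``group`` in {GFP, light_off, light_on}, ``stage`` 0 (initial) or
1 (reversal), ``day``/``trial`` 1-based within stage/day and ``outcome``
binary.  Real and synthetic cohorts use the same table.

The fixed-effects logistic regression models the per-trial success
probability as

    logit p = b0 + b1.group + b2.trial + b3.stage + b4.trial*stage + b5.group*stage

with light-on as the reference group level (so the two group contrasts and
the group-by-stage interactions measure control-vs-silenced differences) and
``trial`` a running index within stage.  Estimation is maximum likelihood by
iteratively reweighted least squares (via statsmodels GLM); Wald z tests on
the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "TRIAL_COLUMNS",
    "GROUP_LEVELS",
    "GlmFit",
    "SeparationError",
    "validate_records",
    "records_from_session",
    "success_curve",
    "days_to_criterion",
    "build_design_eq1",
    "build_design_eq2",
    "fit_logistic_irls",
    "kruskal_wallis",
]

TRIAL_COLUMNS = ["subject", "group", "stage", "day", "trial", "outcome"]
#: reference level first: contrasts are light_off-vs-light_on, GFP-vs-light_on
GROUP_LEVELS = ["light_on", "light_off", "GFP"]

DESIGN_COLUMNS = [
    "intercept",
    "group_light_off",
    "group_GFP",
    "trial",
    "stage",
    "trial_x_stage",
    "group_light_off_x_stage",
    "group_GFP_x_stage",
]


class SeparationError(RuntimeError):
    """Perfect separation: a coefficient diverges in the logistic fit."""


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the shared trial-record schema; returns the frame unchanged."""
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if not df["group"].isin(GROUP_LEVELS).all():
        bad = sorted(set(df["group"]) - set(GROUP_LEVELS))
        raise ValueError(f"unknown group labels: {bad}")
    if not df["stage"].isin([0, 1]).all():
        raise ValueError("stage must be 0 (initial) or 1 (reversal)")
    if not df["outcome"].isin([0, 1]).all():
        raise ValueError("outcome must be binary")
    return df


def records_from_session(session, subject: str, group: str) -> pd.DataFrame:
    """Convert a :class:`~snplast.simulate.SessionResult` to trial records."""
    rows = [
        (
            subject,
            group,
            0 if tr.stage == "initial" else 1,
            tr.day,
            tr.trial,
            int(tr.outcome == "reward"),
        )
        for tr in session.trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def success_curve(records: pd.DataFrame) -> np.ndarray:
    """Per-day success percentages for one subject, initial then reversal."""
    counts = records.groupby(["stage", "day"])["outcome"].agg(["mean", "size"])
    if (counts["size"] != counts["size"].iloc[0]).any():
        warnings.warn("incomplete days present; using available trials")
    return 100.0 * counts["mean"].sort_index().to_numpy()


def days_to_criterion(curve, threshold: float = 80.0) -> int:
    """Earliest day from which the success rate reaches and maintains
    ``threshold`` for the rest of the stage; ``len(curve) + 1`` if never
    (censored, the worst possible rank)."""
    c = np.asarray(curve, float)
    if c.size == 0:
        raise ValueError("empty curve")
    ok = c >= threshold
    day = c.size + 1
    for d in range(c.size - 1, -1, -1):
        if ok[d]:
            day = d + 1
        else:
            break
    return day


def _group_dummies(groups: pd.Series) -> np.ndarray:
    g = np.zeros((len(groups), 2))
    g[:, 0] = (groups == "light_off").to_numpy()
    g[:, 1] = (groups == "GFP").to_numpy()
    return g


def _running_trial_index(df: pd.DataFrame) -> np.ndarray:
    """Continuous trial regressor: running index within stage.

    Trial t of day d becomes (d-1)*trials_per_day + t, restarting at the
    stage switch.
    """
    per_day = int(df["trial"].max())
    return ((df["day"] - 1) * per_day + df["trial"]).to_numpy(float)


def build_design_eq1(records: pd.DataFrame):
    """Design matrix and outcome vector for the fixed-effects regression.

    Returns ``(X, y, names)`` with columns: intercept, two group contrasts
    (light-off and GFP vs the light-on reference), trial, stage,
    trial-by-stage, and the two group-by-stage contrasts.
    """
    df = validate_records(records)
    n = len(df)
    g = _group_dummies(df["group"])
    trial = _running_trial_index(df)
    stage = df["stage"].to_numpy(float)
    X = np.column_stack(
        [
            np.ones(n),
            g[:, 0],
            g[:, 1],
            trial,
            stage,
            trial * stage,
            g[:, 0] * stage,
            g[:, 1] * stage,
        ]
    )
    y = df["outcome"].to_numpy(float)
    return X, y, list(DESIGN_COLUMNS)


def build_design_eq2(records: pd.DataFrame):
    """Fixed-effects design plus the subject grouping needed for a
    mixed-effects (random intercept + random trial slope) fit.

    Returns ``(X, y, names, subjects, trial)``: the fixed-effects design, the
    per-row subject labels and the trial regressor whose slope varies by
    subject.  Random-effects estimation itself is delegated to external
    GLMM machinery.
    """
    X, y, names = build_design_eq1(records)
    return X, y, names, records["subject"].to_numpy(), _running_trial_index(records)


@dataclass
class GlmFit:
    names: list
    params: np.ndarray
    bse: np.ndarray
    wald_z: np.ndarray
    pvalues: np.ndarray
    llf: float
    aic: float

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    names: list | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Maximum-likelihood logistic fit by IRLS, with Wald statistics.

    Raises :class:`SeparationError` when a coefficient diverges (perfect
    separation) and ``ValueError`` on a rank-deficient design.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient (collinear) design matrix")
    names = names or [f"x{i}" for i in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=max_iter, tol=tol
            )
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(str(exc)) from exc
    # a logit coefficient of ~20 pins fitted probabilities within 2e-9 of
    # 0/1; on this data scale that only happens under (quasi-)separation
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 20.0:
        j = int(np.argmax(np.abs(res.params)))
        raise SeparationError(f"diverging coefficient for column {names[j]!r}")
    return GlmFit(
        names=list(names),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        wald_z=np.asarray(res.params) / np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        llf=float(res.llf),
        aic=float(res.aic),
    )


def kruskal_wallis(groups) -> tuple:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p-value.

    With every observation identical across groups the statistic is defined
    as H = 0 (p = 1), the degenerate no-information case.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)
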