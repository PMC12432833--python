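"""Mixed-effects group inference on fCOI block responses.

The condition model is ``mean_hbo ~ condition + (1 | subject)`` fit by
maximum likelihood, with a Wald t statistic on residual degrees of freedom.
The condition factor is coded preferred = 1, other = 0, so selectivity
implies a positive effect; the sign convention is explicit in all outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "ModelFit",
    "FamilyDecision",
    "fit_condition_model",
    "bonferroni_threshold",
    "dissociation_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Condition-effect estimate (positive condition − negative condition)."""

    beta: float
    se: float
    t: float
    df: float
    p: float
    random_intercept_var: float
    n_obs: int
    n_subjects: int
    converged: bool
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "beta": self.beta, "se": self.se, "t": self.t, "df": self.df, "p": self.p,
            "random_intercept_var": self.random_intercept_var, "n_obs": self.n_obs,
            "n_subjects": self.n_subjects, "converged": self.converged, "note": self.note,
        }


def _ols_fit(y: np.ndarray, x: np.ndarray, n_subjects: int, note: str) -> ModelFit:
    """Ordinary regression fallback (random-intercept variance at zero)."""
    design = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    n = y.size
    df = n - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(design.T @ design)
    se = float(np.sqrt(cov[1, 1]))
    t = float(coef[1] / se)
    p = float(2 * sps.t.sf(abs(t), df))
    return ModelFit(float(coef[1]), se, t, float(df), p, 0.0, n, n_subjects, True, note)


def fit_condition_model(
    responses: pd.DataFrame,
    positive_condition: str,
    negative_condition: str,
    value_col: str = "mean_hbo",
    force_zero_random_effect: bool = False,
) -> ModelFit:
    """Fit the random-intercept condition model to block-level rows.

    ``responses`` needs columns ``subject_id``, ``condition``, and
    ``value_col``. Requires at least two subjects and both conditions.
    Singular fits (zero intercept variance) fall back to the boundary
    solution, flagged in ``note``.
    """
    rows = responses[responses["condition"].isin([positive_condition, negative_condition])]
    if rows.empty:
        raise ValidationError("no rows for the requested conditions")
    conditions = set(rows["condition"])
    if len(conditions) < 2:
        raise ValidationError("both conditions must be present")
    n_subjects = rows["subject_id"].nunique()
    if n_subjects < 2:
        raise ValidationError("need at least two subjects")
    y = rows[value_col].to_numpy(dtype=float)
    x = (rows["condition"] == positive_condition).to_numpy(dtype=float)
    groups = rows["subject_id"].to_numpy()
    n = y.size
    df = n - 2

    if force_zero_random_effect:
        return _ols_fit(y, x, n_subjects, "random intercept variance forced to 0")

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    exog = np.column_stack([np.ones_like(x), x])
    note = ""
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            model = sm.MixedLM(y, exog, groups=groups)
            result = model.fit(reml=False)
            beta = float(result.fe_params[1])
            se = float(result.bse_fe[1])
            # cov_re is already on the response scale
            re_var = float(np.atleast_2d(result.cov_re)[0, 0]) if result.cov_re.size else 0.0
            converged = bool(result.converged)
            if not converged:
                note = "optimizer did not report convergence; using last iterate"
            if re_var <= 1e-12:
                note = (note + "; " if note else "") + "boundary solution (zero intercept variance)"
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
            return _ols_fit(y, x, n_subjects, f"mixed fit failed: {exc}")
    t = beta / se
    p = float(2 * sps.t.sf(abs(t), df))
    return ModelFit(beta, float(se), float(t), float(df), p, re_var, n, n_subjects,
                    converged, note)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold ``alpha / m`` for a family of ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("family size must be >= 1")
    return alpha / m


@dataclass
class FamilyDecision:
    """Bonferroni decision for one family (one task) of comparisons."""

    family: str
    members: list[tuple[str, ModelFit]]
    alpha: float = 0.05
    threshold: float = field(init=False)
    significant: dict[str, bool] = field(init=False)

    def __post_init__(self):
        self.threshold = bonferroni_threshold(self.alpha, len(self.members))
        self.significant = {name: fit.p < self.threshold for name, fit in self.members}


#: The eight cells of the specificity analysis: (space, fCOI type, tested task).
DISSOCIATION_CELLS = [
    (space, fcoi_type, tested)
    for space in ("LIFG", "RIFG")
    for fcoi_type in ("language", "md")
    for tested in ("language", "md")
]


def dissociation_report(
    fits: dict[tuple[str, str, str], ModelFit],
    alpha: float = 0.05,
    family_size: int = 2,
) -> tuple[pd.DataFrame, bool | None]:
    """Summary of the 2 spaces × 2 fCOI types × 2 contrasts cells.

    Returns the cell table and the double-dissociation flag: language fCOIs
    significant for the language contrast but not the demand contrast, and MD
    fCOIs the reverse, in both search spaces. Missing cells leave the flag
    undefined (``None``).
    """
    threshold = bonferroni_threshold(alpha, family_size)
    rows = []
    for space, fcoi_type, tested in DISSOCIATION_CELLS:
        fit = fits.get((space, fcoi_type, tested))
        if fit is None:
            rows.append((space, fcoi_type, tested, *[np.nan] * 4, None, None))
        else:
            significant = bool(fit.p < threshold)
            # Selectivity claims are directional: a below-threshold p with a
            # *negative* effect (e.g. the spatial filter's focal crosstalk)
            # is not a preference for the tested contrast's positive pole.
            rows.append(
                (space, fcoi_type, tested, fit.beta, fit.se, fit.t, fit.p,
                 significant, significant and fit.beta > 0)
            )
    table = pd.DataFrame(
        rows, columns=["space", "fcoi_type", "tested_task", "beta", "se", "t", "p",
                       "significant", "selective"]
    )
    if table["selective"].isna().any():
        return table, None

    def cell(space, fcoi_type, tested) -> bool:
        sel = table[(table.space == space) & (table.fcoi_type == fcoi_type)
                    & (table.tested_task == tested)]
        return bool(sel["selective"].iloc[0])

    flag = all(
        cell(space, "language", "language") and not cell(space, "language", "md")
        and cell(space, "md", "md") and not cell(space, "md", "language")
        for space in ("LIFG", "RIFG")
    )
    return table, flag
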