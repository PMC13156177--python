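"""Interaction (moderation) models with simple-slope probing and
Johnson-Neyman regions of significance.

Models are fit by maximum likelihood on complete cases (OLS for linear,
logistic for binary outcomes) with continuous predictors grand-mean-centered
on the analysis sample. The probing algebra is exact:

    slope(m)  = b_focal + m * b_interaction
    se(m)^2   = v_ff + m^2 * v_ii + 2 m * v_fi

and region boundaries solve |slope(m) / se(m)| = critical value, the standard
quadratic in m, clipped to the moderator's mean +/- ``range_sd`` SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
import statsmodels.api as sm

MIN_COMPLETE_CASES = 10


@dataclass
class ModerationFit:
    """Coefficients + covariance of a fitted interaction model."""

    outcome_name: str
    family: str                 # "linear" | "logistic"
    focal: str
    moderator: str
    interaction: str
    coef: pd.Series
    vcov: Optional[pd.DataFrame]
    n_used: int
    df_resid: Optional[float]
    centering: dict = field(default_factory=dict)
    moderator_mean: float = 0.0   # on the (centered) analysis scale
    moderator_sd: float = float("nan")

    @classmethod
    def from_coefficients(
        cls,
        focal_coef: float,
        interaction_coef: float,
        focal: str = "focal",
        moderator: str = "moderator",
        outcome_name: str = "outcome",
        family: str = "linear",
        vcov: Optional[pd.DataFrame] = None,
        df_resid: Optional[float] = None,
        n_used: int = 0,
        moderator_sd: float = float("nan"),
    ) -> "ModerationFit":
        """Build a fit directly from known coefficients (e.g., a published
        coefficient table) so the probing algebra can be applied to it."""
        interaction = f"{focal}:{moderator}"
        coef = pd.Series({focal: focal_coef, interaction: interaction_coef})
        return cls(
            outcome_name=outcome_name, family=family, focal=focal,
            moderator=moderator, interaction=interaction, coef=coef,
            vcov=vcov, n_used=n_used, df_resid=df_resid,
            moderator_sd=moderator_sd,
        )


@dataclass
class ProbeResult:
    focal: str
    moderator: str
    at_value: Optional[float]
    slope_est: float
    slope_se: float
    t_or_z: float
    p: float
    region_bounds: Optional[list[tuple[float, float]]] = None
    region_range: Optional[tuple[float, float]] = None


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [X.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_interaction_model(
    data: pd.DataFrame,
    outcome: str,
    focal: str,
    moderator: str,
    covariates: Sequence[str] = (),
    family: str = "linear",
) -> ModerationFit:
    """ML fit of ``outcome ~ focal + moderator + focal*moderator +
    covariates`` on complete cases, with continuous predictors grand-mean-
    centered. Covariates may include extra main effects (e.g., a second
    parent factor)."""
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    predictors = [focal, moderator, *covariates]
    cols = [outcome, *predictors]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns not in data: {missing_cols}")
    work = data[cols].dropna().copy()
    n_used = len(work)
    if n_used < MIN_COMPLETE_CASES:
        raise ValueError(
            f"need >= {MIN_COMPLETE_CASES} complete cases, got {n_used}"
        )

    centering: dict[str, float] = {}
    for col in predictors:
        if not _is_binary(work[col]):
            mu = float(work[col].mean())
            centering[col] = mu
            work[col] = work[col] - mu

    moderator_sd = float(work[moderator].std(ddof=1))
    interaction = f"{focal}:{moderator}"
    work[interaction] = work[focal] * work[moderator]

    X = work[[focal, moderator, interaction, *covariates]]
    X = sm.add_constant(X, prepend=True)
    _check_rank(X)
    y = work[outcome]

    if family == "linear":
        res = sm.OLS(y, X).fit()
        df_resid = float(res.df_resid)
    else:
        if not _is_binary(y):
            raise ValueError(f"logistic family needs a 0/1 outcome, got {outcome!r}")
        res = sm.Logit(y, X).fit(disp=0)
        df_resid = None

    return ModerationFit(
        outcome_name=outcome,
        family=family,
        focal=focal,
        moderator=moderator,
        interaction=interaction,
        coef=res.params,
        vcov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        n_used=n_used,
        df_resid=df_resid,
        centering=centering,
        moderator_mean=0.0 if moderator in centering else float(work[moderator].mean()),
        moderator_sd=moderator_sd,
    )


def _slope_variance(fit: ModerationFit, m: float | np.ndarray):
    v = fit.vcov
    v_ff = v.loc[fit.focal, fit.focal]
    v_ii = v.loc[fit.interaction, fit.interaction]
    v_fi = v.loc[fit.focal, fit.interaction]
    return v_ff + m**2 * v_ii + 2 * m * v_fi


def _p_value(fit: ModerationFit, stat: float) -> float:
    if fit.family == "linear" and fit.df_resid is not None:
        return float(2 * stats.t.sf(abs(stat), fit.df_resid))
    return float(2 * stats.norm.sf(abs(stat)))


def simple_slope(fit: ModerationFit, at_value: float) -> ProbeResult:
    """Conditional effect of the focal predictor at a fixed moderator value:
    slope = b_focal + at_value * b_interaction (exact algebraic identity)."""
    if not np.isfinite(at_value):
        raise ValueError(f"at_value must be finite, got {at_value}")
    b_f = float(fit.coef[fit.focal])
    b_i = float(fit.coef[fit.interaction])
    slope = b_f + at_value * b_i
    if fit.vcov is not None:
        se = float(np.sqrt(_slope_variance(fit, at_value)))
        stat = slope / se if se > 0 else float("nan")
        p = _p_value(fit, stat)
    else:
        se, stat, p = float("nan"), float("nan"), float("nan")
    return ProbeResult(
        focal=fit.focal, moderator=fit.moderator, at_value=at_value,
        slope_est=slope, slope_se=se, t_or_z=stat, p=p,
    )


def probe_at_sd_levels(fit: ModerationFit, sd_override: float | None = None) -> list[ProbeResult]:
    """Simple slopes at -1 SD, the grand mean, and +1 SD of the moderator.

    ``sd_override`` substitutes an externally supplied SD (e.g., a published
    descriptive SD) for the analysis-sample SD.
    """
    sd = sd_override if sd_override is not None else fit.moderator_sd
    if not np.isfinite(sd):
        raise ValueError("moderator SD unavailable; supply sd_override")
    m0 = fit.moderator_mean
    return [simple_slope(fit, m0 + k * sd) for k in (-1.0, 0.0, 1.0)]


def probe_binary_levels(fit: ModerationFit) -> list[ProbeResult]:
    """Simple slopes at both levels of a 0/1 moderator."""
    return [simple_slope(fit, 0.0), simple_slope(fit, 1.0)]


def _critical_value(fit: ModerationFit, alpha: float) -> float:
    if fit.family == "linear" and fit.df_resid is not None:
        return float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    return float(stats.norm.ppf(1 - alpha / 2))


def region_of_significance(
    fit: ModerationFit,
    alpha: float = 0.05,
    range_sd: float = 2.0,
    sd_override: float | None = None,
) -> ProbeResult:
    """Johnson-Neyman region: the moderator interval(s) within mean +/-
    ``range_sd`` SD where the conditional focal effect is significant.

    Boundaries solve |slope(m)| = crit * se(m), i.e. the quadratic
    (b_i^2 - c^2 v_ii) m^2 + 2(b_f b_i - c^2 v_fi) m + (b_f^2 - c^2 v_ff) = 0.
    An empty list is a valid result (no significant region in range).
    """
    if fit.vcov is None:
        raise ValueError("region of significance needs a coefficient covariance")
    sd = sd_override if sd_override is not None else fit.moderator_sd
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("moderator SD unavailable; supply sd_override")
    lo = fit.moderator_mean - range_sd * sd
    hi = fit.moderator_mean + range_sd * sd

    b_f = float(fit.coef[fit.focal])
    b_i = float(fit.coef[fit.interaction])
    v = fit.vcov
    v_ff = float(v.loc[fit.focal, fit.focal])
    v_ii = float(v.loc[fit.interaction, fit.interaction])
    v_fi = float(v.loc[fit.focal, fit.interaction])
    crit = _critical_value(fit, alpha)
    c2 = crit**2

    a = b_i**2 - c2 * v_ii
    b = 2 * (b_f * b_i - c2 * v_fi)
    c = b_f**2 - c2 * v_ff

    roots: list[float] = []
    if abs(a) > 0:
        disc = b**2 - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    elif abs(b) > 0:
        roots = [-c / b]
    roots = sorted(r for r in roots if lo < r < hi)

    # partition the clipped range at the boundaries; classify each segment by
    # its midpoint (robust to every orientation of the quadratic)
    edges = [lo, *roots, hi]
    bounds: list[tuple[float, float]] = []
    for a0, a1 in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a0 + a1)
        slope = b_f + mid * b_i
        se = float(np.sqrt(_slope_variance(fit, mid)))
        if se > 0 and abs(slope) / se > crit:
            if bounds and bounds[-1][1] == a0:
                bounds[-1] = (bounds[-1][0], a1)
            else:
                bounds.append((a0, a1))

    base = simple_slope(fit, fit.moderator_mean)
    base.region_bounds = bounds
    base.region_range = (lo, hi)
    return base


def probes_table(probes: Sequence[ProbeResult]) -> pd.DataFrame:
    """Tidy CSV-ready table of probe results."""
    rows = []
    for p in probes:
        rows.append({
            "focal": p.focal,
            "moderator": p.moderator,
            "at_value": p.at_value,
            "slope_est": p.slope_est,
            "slope_se": p.slope_se,
            "t_or_z": p.t_or_z,
            "p": p.p,
            "region_bounds": (
                ";".join(f"{a:.6g}..{b:.6g}" for a, b in p.region_bounds)
                if p.region_bounds is not None else ""
            ),
        })
    return pd.DataFrame(rows)
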