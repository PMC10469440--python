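"""Intraclass correlation estimands computed from posterior draws.

All estimands are computed draw-by-draw and then summarised by the posterior
median and an equal-tailed 95% credible interval, so that summaries remain
faithful to the joint posterior even when variance parameters are correlated
(median of per-draw ICCs, not ICC of median variances).

Estimands
---------
three-level ICC
    (sigma2_subject + sigma2_center) / total: the correlation between two
    measurements of the same subject in the same center, treating
    between-center differences as real biological signal.
within-center ICC
    sigma2_subject / total: compares subjects only to subjects of the same
    center; never exceeds the three-level ICC.
two-level ICC
    sigma2_subject / (sigma2_subject + sigma2_within), for fits that ignore
    the center level.
data-scale ICC (two-level, lognormal)
    (exp(sigma2_b) - 1) / (exp(sigma2_b + sigma2_w) - 1): the Pearson
    correlation of replicate pairs on the original intensity scale implied
    by lognormality. Defined for the two-level decomposition only.

Repeatability classes: ICC < 0.40 poor, 0.40-0.75 fair, > 0.75 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws

__all__ = [
    "ICCResult",
    "icc_three_level",
    "icc_within_center",
    "icc_two_level",
    "icc_two_level_datascale",
    "lognormal_icc",
    "variance_proportions",
    "classify_repeatability",
]

_DEGENERATE_TOL = 1e-8


@dataclass
class ICCResult:
    """Posterior summary of one ICC estimand for one feature/compound."""

    id: str | None
    estimand: str
    icc: float
    ci_low: float
    ci_high: float
    prop_within: float
    prop_subject: float
    prop_center: float
    repeatability: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "estimand": self.estimand,
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "prop_within": self.prop_within,
            "prop_subject": self.prop_subject,
            "prop_center": self.prop_center,
            "repeatability": self.repeatability,
            "degenerate": self.degenerate,
        }


def classify_repeatability(icc: float) -> str:
    """Map an ICC value to its repeatability class.

    Boundaries: [0, 0.40) poor, [0.40, 0.75] fair, (0.75, 1] excellent.
    NaN maps to ``undefined``.
    """
    if icc is None or not np.isfinite(icc):
        return "undefined"
    if icc < 0.40:
        return "poor"
    if icc <= 0.75:
        return "fair"
    return "excellent"


def _variances(draws: PosteriorDraws, require_levels: int | None = None):
    if require_levels is not None and draws.levels != require_levels:
        raise ValueError(
            f"estimand requires a {require_levels}-level model, got {draws.levels}-level draws"
        )
    s1 = draws.stacked("sigma2_within")
    s2 = draws.stacked("sigma2_subject")
    s3 = draws.stacked("sigma2_center") if draws.levels == 3 else np.zeros_like(s1)
    for name, arr in (("sigma2_within", s1), ("sigma2_subject", s2), ("sigma2_center", s3)):
        if np.any(arr < 0):
            raise ValueError(f"negative draw encountered in {name}; sampler contract violated")
    return s1, s2, s3


def _summarize(id, estimand, per_draw, s1, s2, s3) -> ICCResult:
    total = s1 + s2 + s3
    degenerate = float(np.median(total)) < _DEGENERATE_TOL
    if degenerate:
        icc = ci_lo = ci_hi = float("nan")
    else:
        icc = float(np.median(per_draw))
        ci_lo = float(np.percentile(per_draw, 2.5))
        ci_hi = float(np.percentile(per_draw, 97.5))
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.vstack([s1, s2, s3]) / total
    pw, ps, pc = (float(np.nanmedian(props[j])) for j in range(3))
    return ICCResult(
        id=id,
        estimand=estimand,
        icc=icc,
        ci_low=ci_lo,
        ci_high=ci_hi,
        prop_within=pw,
        prop_subject=ps,
        prop_center=pc,
        repeatability=classify_repeatability(icc),
        degenerate=degenerate,
    )


def icc_three_level(draws: PosteriorDraws, id: str | None = None) -> ICCResult:
    """Three-level ICC: (sigma2_subject + sigma2_center) / total, per draw."""
    s1, s2, s3 = _variances(draws, require_levels=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_draw = (s2 + s3) / (s1 + s2 + s3)
    return _summarize(id, "three_level", per_draw, s1, s2, s3)


def icc_within_center(draws: PosteriorDraws, id: str | None = None) -> ICCResult:
    """Within-center ICC: sigma2_subject / total, per draw.

    Draw-wise never larger than the three-level ICC (numerator is a subset
    of the same denominator); equals it exactly when sigma2_center is zero.
    """
    s1, s2, s3 = _variances(draws, require_levels=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_draw = s2 / (s1 + s2 + s3)
    return _summarize(id, "within_center", per_draw, s1, s2, s3)


def icc_two_level(draws: PosteriorDraws, id: str | None = None) -> ICCResult:
    """Two-level (log-scale) ICC: sigma2_subject / (sigma2_subject + sigma2_within)."""
    s1, s2, s3 = _variances(draws, require_levels=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_draw = s2 / (s1 + s2)
    return _summarize(id, "two_level_log", per_draw, s1, s2, s3)


def lognormal_icc(sigma_b2, sigma_w2):
    """Closed-form data-scale ICC of a lognormal two-level model.

    For log-scale between variance ``sigma_b2`` and within variance
    ``sigma_w2``, the correlation of replicate pairs on the original
    (exponentiated) scale is ``(exp(sigma_b2) - 1) / (exp(sigma_b2 +
    sigma_w2) - 1)``. As both variances shrink at a fixed ratio the value
    converges to the log-scale ICC; it never exceeds it.
    """
    sigma_b2 = np.asarray(sigma_b2, dtype=float)
    sigma_w2 = np.asarray(sigma_w2, dtype=float)
    if np.any(sigma_b2 < 0) or np.any(sigma_w2 < 0):
        raise ValueError("variances must be nonnegative")
    num = np.expm1(sigma_b2)
    den = np.expm1(sigma_b2 + sigma_w2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out.item() if out.ndim == 0 else out


def icc_two_level_datascale(draws: PosteriorDraws, id: str | None = None) -> ICCResult:
    """Back-transformed (original intensity scale) ICC from two-level draws.

    Applies the lognormal closed form per draw, then takes the posterior
    median. Rejected for three-level draws: the back-transformation is only
    defined here for the two-level decomposition.
    """
    s1, s2, s3 = _variances(draws, require_levels=2)
    per_draw = lognormal_icc(s2, s1)
    return _summarize(id, "two_level_datascale", per_draw, s1, s2, s3)


def variance_proportions(draws: PosteriorDraws) -> dict[str, float]:
    """Posterior-median share of each variance component in the total.

    Returns medians of per-draw proportions for ``within``, ``subject`` and
    (three-level only) ``center``. Per draw the three proportions sum to 1
    exactly; their medians sum to 1 up to posterior asymmetry.
    """
    s1, s2, s3 = _variances(draws)
    total = s1 + s2 + s3
    with np.errstate(invalid="ignore", divide="ignore"):
        out = {
            "within": float(np.nanmedian(s1 / total)),
            "subject": float(np.nanmedian(s2 / total)),
        }
        if draws.levels == 3:
            out["center"] = float(np.nanmedian(s3 / total))
    return out


def results_to_frame(results: list[ICCResult]) -> pd.DataFrame:
    """Stack a list of ICCResult into a tidy DataFrame."""
    return pd.DataFrame([r.to_dict() for r in results])
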