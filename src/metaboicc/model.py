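"""Bayesian hierarchical tobit model for log-intensities.

Per feature, the natural-log intensity of sample *i* from subject *j* in
center *k* is modelled as a nested random-intercept model

    y_ijk = x_ijk' beta + u_k + u_jk + e_ijk

with u_k ~ N(0, sigma2_center), u_jk ~ N(0, sigma2_subject) and
e_ijk ~ N(0, sigma2_within), all independent. Nondetects are treated as
left-censored at the feature's (log) limit of detection: the likelihood
contribution of a censored observation is P(y < log LOD), handled by Gibbs
data augmentation — each censored response is sampled from its truncated
normal full conditional, after which every other update is conjugate.

Priors follow the weakly-informative defaults common for this model family:
half-Student-t(3, 0, 2.5 * sd(y)) on each random-effect and residual SD
(implemented exactly through the inverse-gamma mixture representation, so
the variance updates stay conjugate), Student-t(3, median(y), 2.5 * sd(y))
on the intercept (normal scale-mixture), and flat priors on regression
coefficients. Covariates are standardised internally; coefficients are
reported back on the original scale.

The sampler is a plain-numpy blocked Gibbs sweep:

1. impute censored responses from truncated normals;
2. draw regression coefficients from their joint normal conditional;
3. draw subject and center intercepts (vectorised over groups);
4. draw the three variances from inverse-gamma conditionals and refresh the
   mixture auxiliaries.

Chains start from dispersed points; split R-hat and bulk ESS are computed
with ArviZ on the retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

__all__ = [
    "MCMCSettings",
    "PriorSpec",
    "ModelSpec",
    "PosteriorDraws",
    "ConvergenceReport",
    "fit_censored_model",
    "build_age_smooth",
    "run_feature_batch",
]

_VARIANCE_PARAMS3 = ("sigma2_within", "sigma2_subject", "sigma2_center")
_VARIANCE_PARAMS2 = ("sigma2_within", "sigma2_subject")


@dataclass
class MCMCSettings:
    """Gibbs sampler run length and seeding.

    Defaults (10 000 iterations, 4 chains, burn-in = half) match common
    practice for this model family; reduce for batch work.
    """

    iterations: int = 10_000
    chains: int = 4
    burn_in: int | None = None  # None -> iterations // 2
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.iterations // 2
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need iterations > burn_in >= 0")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split-R-hat diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_keep(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PriorSpec:
    """Prior family settings.

    ``sd_scale`` / ``intercept_scale`` of None means 2.5 times the sample SD
    of the detected log-intensities (data-scaled weak priors).
    """

    sd_df: float = 3.0
    sd_scale: float | None = None
    intercept_df: float = 3.0
    intercept_scale: float | None = None


@dataclass
class ModelSpec:
    """Model structure: number of levels, fixed effects, priors, diagnostics.

    ``levels=3`` nests subjects in centers; ``levels=2`` ignores centers
    (single variance decomposition into between- and within-subject).
    ``fixed_effects`` names metadata columns entered as linear fixed effects;
    ``age_smooth_df > 0`` additionally enters a centered spline basis in age.
    """

    levels: int = 3
    fixed_effects: tuple[str, ...] = ()
    age_smooth_df: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        if self.levels not in (2, 3):
            raise ValueError("levels must be 2 or 3")
        self.fixed_effects = tuple(self.fixed_effects)

    @classmethod
    def adjusted(cls, age_smooth_df: int = 3, **kw) -> "ModelSpec":
        """Confounder-adjusted spec: smooth age term plus BMI and sex."""
        return cls(fixed_effects=("bmi", "sex"), age_smooth_df=age_smooth_df, **kw)


@dataclass
class PosteriorDraws:
    """Retained joint posterior draws, shaped (chains, draws) per parameter."""

    params: dict[str, np.ndarray]
    levels: int

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def variance_names(self) -> tuple[str, ...]:
        return _VARIANCE_PARAMS3 if self.levels == 3 else _VARIANCE_PARAMS2

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat vector."""
        return np.asarray(self.params[name]).ravel()

    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return first.size

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, arr in self.params.items():
            flat = arr.ravel()
            rows[name] = {
                "median": float(np.median(flat)),
                "q2.5": float(np.percentile(flat, 2.5)),
                "q97.5": float(np.percentile(flat, 97.5)),
            }
        return pd.DataFrame(rows).T


@dataclass
class ConvergenceReport:
    """Split R-hat and bulk ESS per parameter, plus an overall pass flag.

    The pass flag monitors the variance parameters only (features failing it
    should be flagged downstream, not dropped).
    """

    stats: pd.DataFrame
    passed: bool
    rhat_threshold: float
    ess_threshold: float
    degenerate: bool = False


def _diagnostics(params: dict[str, np.ndarray], monitored: tuple[str, ...],
                 rhat_thr: float, ess_thr: float, degenerate: bool) -> ConvergenceReport:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: v for k, v in params.items()})
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    stats = pd.DataFrame(
        {
            "rhat": {k: float(rhat[k].values) for k in params},
            "ess": {k: float(ess[k].values) for k in params},
        }
    )
    ok = bool(
        np.all(stats.loc[list(monitored), "rhat"] < rhat_thr)
        and np.all(stats.loc[list(monitored), "ess"] > ess_thr)
    )
    if degenerate:
        ok = False
    return ConvergenceReport(stats, ok, rhat_thr, ess_thr, degenerate)


def build_age_smooth(age, df: int) -> np.ndarray:
    """Centered, intercept-free B-spline basis in age for use as fixed effects.

    ``df=1`` degenerates to a centered linear term. For ``df >= 2`` a spline
    basis of degree min(3, df) with ``df - degree`` interior knots at age
    quantiles is built; the first basis column is dropped (its span together
    with the constant recovers the full spline space) and columns are
    mean-centered so they are orthogonal to the intercept.
    """
    age = np.asarray(age, dtype=float)
    if age.ndim != 1:
        raise ValueError("age must be a 1-D vector")
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(age)
    if distinct.size < 2:
        raise ValueError("age vector is constant; no smooth term can be built")
    if distinct.size < df + 1:
        raise ValueError(f"need at least df+1={df + 1} distinct ages, got {distinct.size}")
    if df == 1:
        return (age - age.mean())[:, None]
    degree = min(3, df)
    n_interior = df - degree
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(age, qs)
    else:
        interior = np.array([])
    lo, hi = age.min(), age.max()
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    basis = BSpline.design_matrix(age, knots, degree, extrapolate=True).toarray()
    basis = basis[:, 1:]  # drop one column; constant + rest spans the space
    return basis - basis.mean(axis=0)


def _validate_structure(censored, subj_codes, cent_codes, levels):
    if censored.all():
        raise ValueError("all observations are censored; the model is not identifiable")
    counts = np.bincount(subj_codes)
    if not np.any(counts >= 2):
        raise ValueError(
            "no subject has replicate measurements; within- and between-subject "
            "variances are jointly unidentifiable"
        )
    if levels == 3:
        if cent_codes is None:
            raise ValueError("three-level model requires center ids")
        n_cent = cent_codes.max() + 1
        if n_cent < 2:
            raise ValueError("three-level model requires >= 2 centers")
        # nesting: each subject must appear in exactly one center
        pairs = np.unique(np.stack([subj_codes, cent_codes], axis=1), axis=0)
        if len(pairs) != counts.size:
            raise ValueError("subject/center labels are not nested (a subject spans centers)")


def _sample_invgamma(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def fit_censored_model(
    y,
    lod: float,
    subject_ids,
    center_ids=None,
    X=None,
    x_names=None,
    spec: ModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
    stream: int = 0,
) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Fit the censored hierarchical model to one feature by Gibbs sampling.

    Parameters
    ----------
    y
        Natural-log intensities; NaN marks a censored observation (value
        unknown, known to lie below ``lod``).
    lod
        Log-scale censoring threshold shared by all censored entries of the
        feature (the log of the lowest detected intensity).
    subject_ids, center_ids
        Grouping labels per observation; ``center_ids`` may be omitted for a
        two-level spec.
    X, x_names
        Optional fixed-effect design columns (without intercept) and names.
    stream
        Substream index folded into the seed so per-feature fits inside a
        batch are reproducible individually.

    Returns
    -------
    (PosteriorDraws, ConvergenceReport)
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCSettings()

    y = np.asarray(y, dtype=float)
    censored = ~np.isfinite(y)
    n = y.size
    if n == 0:
        raise ValueError("empty response vector")

    subj_codes, _ = pd.factorize(np.asarray(subject_ids))
    cent_codes = None
    if center_ids is not None:
        cent_codes, _ = pd.factorize(np.asarray(center_ids))
    _validate_structure(censored, subj_codes, cent_codes if spec.levels == 3 else None, spec.levels)
    three = spec.levels == 3
    n_sub = subj_codes.max() + 1
    n_cent = int(cent_codes.max() + 1) if three else 0

    if censored.any() and not np.isfinite(lod):
        raise ValueError("finite log-scale LOD required when censored entries are present")

    # fixed-effect design: intercept + standardised covariate columns
    if X is None:
        Xs = np.empty((n, 0))
        x_names = []
        x_mean = np.empty(0)
        x_sd = np.empty(0)
    else:
        Xraw = np.atleast_2d(np.asarray(X, dtype=float))
        if Xraw.shape[0] != n:
            Xraw = Xraw.T
        x_mean = Xraw.mean(axis=0)
        x_sd = Xraw.std(axis=0, ddof=0)
        if np.any(x_sd == 0):
            raise ValueError("constant fixed-effect column; drop it or use the intercept")
        Xs = (Xraw - x_mean) / x_sd
        x_names = list(x_names) if x_names is not None else [f"x{j}" for j in range(Xs.shape[1])]
    p = 1 + Xs.shape[1]
    Xd = np.column_stack([np.ones(n), Xs])
    XtX = Xd.T @ Xd

    y_obs = y[~censored]
    m0 = float(np.median(y_obs))
    s_obs = float(np.std(y_obs, ddof=1)) if y_obs.size > 1 else 0.0
    degenerate = not np.isfinite(s_obs) or s_obs == 0.0
    scale_base = s_obs if not degenerate else 1.0
    pr = spec.priors
    A = pr.sd_scale if pr.sd_scale is not None else 2.5 * scale_base
    s0p = pr.intercept_scale if pr.intercept_scale is not None else 2.5 * scale_base
    nu = pr.sd_df
    nu0 = pr.intercept_df
    inv_A2 = 1.0 / (A * A)

    cens_idx = np.flatnonzero(censored)
    obs_vals = y.copy()
    counts_s = np.bincount(subj_codes, minlength=n_sub).astype(float)
    counts_c = np.bincount(cent_codes, minlength=n_cent).astype(float) if three else None
    intercept_only = p == 1

    var_names = _VARIANCE_PARAMS3 if three else _VARIANCE_PARAMS2
    beta_names = ["intercept"] + x_names
    n_keep = mcmc.n_keep
    keep_var = np.empty((mcmc.chains, n_keep, 3 if three else 2))
    keep_beta = np.empty((mcmc.chains, n_keep, p))

    v_hat = max(s_obs * s_obs, 1e-2)
    for chain in range(mcmc.chains):
        ss = np.random.SeedSequence(entropy=int(mcmc.seed), spawn_key=(int(stream), chain))
        rng = np.random.default_rng(ss)

        # dispersed initial values
        s2_1 = v_hat * rng.uniform(0.3, 3.0)
        s2_2 = v_hat * rng.uniform(0.1, 3.0)
        s2_3 = v_hat * rng.uniform(0.05, 2.0) if three else 0.0
        a1 = a2 = a3 = A * A
        omega0 = 1.0
        beta = np.zeros(p)
        beta[0] = m0 + rng.normal(0.0, np.sqrt(v_hat))
        u_s = rng.normal(0.0, 0.1, size=n_sub)
        u_c = rng.normal(0.0, 0.1, size=n_cent) if three else None

        ycur = obs_vals.copy()
        if cens_idx.size:
            ycur[cens_idx] = lod - np.abs(rng.normal(0.0, np.sqrt(v_hat), size=cens_idx.size))

        k = 0
        for it in range(mcmc.iterations):
            if intercept_only:
                xb = beta[0]
            else:
                xb = Xd @ beta
            mean_all = xb + u_s[subj_codes]
            if three:
                mean_all = mean_all + u_c[cent_codes]

            # 1. data augmentation: truncated-normal draws for censored cells
            if cens_idx.size:
                sig1 = np.sqrt(s2_1)
                alpha = (lod - mean_all[cens_idx]) / sig1
                Fa = ndtr(alpha)
                u = rng.random(cens_idx.size) * Fa
                z = ndtri(np.clip(u, 1e-300, 1.0 - 1e-16))
                ycur[cens_idx] = mean_all[cens_idx] + sig1 * z

            # 2. regression block (intercept t-prior via scale mixture)
            r = ycur - u_s[subj_codes]
            if three:
                r = r - u_c[cent_codes]
            prec0 = omega0 / (s0p * s0p)
            if intercept_only:
                q = n / s2_1 + prec0
                mb = (r.sum() / s2_1 + prec0 * m0) / q
                beta[0] = mb + rng.standard_normal() / np.sqrt(q)
            else:
                Q = XtX / s2_1
                b = (Xd.T @ r) / s2_1
                Q[0, 0] += prec0
                b[0] += prec0 * m0
                cf = cho_factor(Q, lower=True)
                mean_beta = cho_solve(cf, b)
                z = rng.standard_normal(p)
                beta = mean_beta + solve_triangular(cf[0], z, lower=True, trans="T")
            omega0 = rng.gamma(
                (nu0 + 1.0) / 2.0, 2.0 / (nu0 + ((beta[0] - m0) / s0p) ** 2)
            )
            if intercept_only:
                xb = beta[0]
            else:
                xb = Xd @ beta

            # 3. random intercepts
            r2 = ycur - xb
            if three:
                r2c = r2 - u_c[cent_codes]
            else:
                r2c = r2
            sums = np.bincount(subj_codes, weights=r2c, minlength=n_sub)
            prec = counts_s / s2_1 + 1.0 / s2_2
            u_s = sums / s2_1 / prec + rng.standard_normal(n_sub) / np.sqrt(prec)

            if three:
                r3 = r2 - u_s[subj_codes]
                sums_c = np.bincount(cent_codes, weights=r3, minlength=n_cent)
                prec_c = counts_c / s2_1 + 1.0 / s2_3
                u_c = sums_c / s2_1 / prec_c + rng.standard_normal(n_cent) / np.sqrt(prec_c)

            # 4. variances (half-t via inverse-gamma mixture)
            resid = r2c - u_s[subj_codes] if not three else (
                ycur - xb - u_s[subj_codes] - u_c[cent_codes]
            )
            ss1 = float(resid @ resid)
            s2_1 = _sample_invgamma(rng, (nu + n) / 2.0, nu / a1 + ss1 / 2.0)
            a1 = _sample_invgamma(rng, (nu + 1.0) / 2.0, nu / s2_1 + inv_A2)

            ss2 = float(u_s @ u_s)
            s2_2 = _sample_invgamma(rng, (nu + n_sub) / 2.0, nu / a2 + ss2 / 2.0)
            a2 = _sample_invgamma(rng, (nu + 1.0) / 2.0, nu / s2_2 + inv_A2)

            if three:
                ss3 = float(u_c @ u_c)
                s2_3 = _sample_invgamma(rng, (nu + n_cent) / 2.0, nu / a3 + ss3 / 2.0)
                a3 = _sample_invgamma(rng, (nu + 1.0) / 2.0, nu / s2_3 + inv_A2)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if three:
                    keep_var[chain, k, :] = (s2_1, s2_2, s2_3)
                else:
                    keep_var[chain, k, :] = (s2_1, s2_2)
                keep_beta[chain, k, :] = beta
                k += 1

    # back-transform coefficients to the original covariate scale
    beta_orig = keep_beta.copy()
    if p > 1:
        beta_orig[..., 1:] = keep_beta[..., 1:] / x_sd
        beta_orig[..., 0] = keep_beta[..., 0] - np.einsum(
            "ckj,j->ck", keep_beta[..., 1:], x_mean / x_sd
        )

    params: dict[str, np.ndarray] = {}
    for j, name in enumerate(var_names):
        params[name] = keep_var[..., j]
    for j, name in enumerate(beta_names):
        params[name] = beta_orig[..., j]

    draws = PosteriorDraws(params, spec.levels)
    monitored = var_names
    report = _diagnostics(params, monitored, spec.rhat_threshold, spec.ess_threshold, degenerate)
    return draws, report


def _build_design(metadata: pd.DataFrame, spec: ModelSpec):
    cols = []
    names = []
    for name in spec.fixed_effects:
        if name not in metadata.columns:
            raise ValueError(f"fixed effect '{name}' not in metadata")
        cols.append(pd.to_numeric(metadata[name]).to_numpy(dtype=float))
        names.append(name)
    if spec.age_smooth_df > 0:
        basis = build_age_smooth(metadata["age"].to_numpy(dtype=float), spec.age_smooth_df)
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"age_s{j + 1}")
    if not cols:
        return None, None
    return np.column_stack(cols), names


def run_feature_batch(
    table,
    metadata: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
    features=None,
    keep_draws: bool = False,
    progress: bool = False,
):
    """Fit the censored model to every feature of a table independently.

    Each feature gets its own seed substream derived from the master seed and
    the feature's position, so a batch run and a single-feature run of the
    same feature agree draw for draw. Per-feature failures (e.g. an
    all-missing column) are isolated and reported, never fatal to the batch.

    Returns
    -------
    (results, failures[, draws])
        ``results``: one row per successfully fitted feature with variance
        medians and intervals, the three-level (or two-level) ICC summaries,
        variance proportions, repeatability class and convergence statistics.
        ``failures``: dict feature id -> reason. With ``keep_draws=True`` a
        dict of :class:`PosteriorDraws` is returned as a third element.
    """
    from .icc import icc_three_level, icc_two_level, variance_proportions

    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCSettings()
    ints = table.intensities
    missing_meta = ints.index.difference(metadata.index)
    if len(missing_meta):
        raise ValueError(
            f"metadata missing for {len(missing_meta)} samples, e.g. {list(missing_meta[:3])}"
        )
    meta = metadata.loc[ints.index]
    X, x_names = _build_design(meta, spec)
    subject_ids = meta["subject_id"].to_numpy()
    center_ids = meta["center_id"].to_numpy() if spec.levels == 3 else None

    feat_list = list(features) if features is not None else list(ints.columns)
    rows = []
    failures: dict[str, str] = {}
    all_draws: dict[str, PosteriorDraws] = {}
    iterator = enumerate(feat_list)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = enumerate(tqdm(feat_list))
    for idx, fid in iterator:
        try:
            vals = ints[fid].to_numpy(dtype=float)
            detected = np.isfinite(vals)
            if detected.sum() == 0:
                raise ValueError("feature has no detected values")
            lod = float(np.log(np.nanmin(vals)))
            y = np.where(detected, np.log(np.where(detected, vals, 1.0)), np.nan)
            draws, report = fit_censored_model(
                y, lod, subject_ids, center_ids, X=X, x_names=x_names,
                spec=spec, mcmc=mcmc, stream=idx,
            )
            if spec.levels == 3:
                res = icc_three_level(draws, id=fid)
            else:
                res = icc_two_level(draws, id=fid)
            props = variance_proportions(draws)
            row = {
                "feature_id": fid,
                "n": int(vals.size),
                "n_censored": int((~detected).sum()),
                "detection_rate": float(detected.mean()),
                "icc": res.icc,
                "icc_low": res.ci_low,
                "icc_high": res.ci_high,
                "repeatability": res.repeatability,
                "prop_within": props["within"],
                "prop_subject": props["subject"],
                "prop_center": props.get("center", np.nan),
                "max_rhat": float(report.stats["rhat"].max()),
                "min_ess": float(report.stats["ess"].min()),
                "converged": report.passed,
            }
            for vname in draws.variance_names:
                flat = draws.stacked(vname)
                row[f"{vname}_median"] = float(np.median(flat))
                row[f"{vname}_low"] = float(np.percentile(flat, 2.5))
                row[f"{vname}_high"] = float(np.percentile(flat, 97.5))
            rows.append(row)
            if keep_draws:
                all_draws[fid] = draws
        except ValueError as exc:
            failures[fid] = str(exc)
    results = pd.DataFrame(rows)
    if len(results):
        results = results.set_index("feature_id")
    if keep_draws:
        return results, failures, all_draws
    return results, failures
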