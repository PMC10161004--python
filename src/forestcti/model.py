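"""Hierarchical Bayesian regression of community temperature index over time.

The response is the community temperature index (CTI) of subplot *j* in plot
*i* at census *k* (k = 0 baseline, k = 1 resurvey).  The mean structure is

    mu_ijk = b0 + b1*time_k + sum_p b_p x_p + sum_p b_{p'} time_k * x_p
             + u_i + v_ij

with ten subplot/plot-level predictors x2..x11 (baseline climate, climate
change, heat load, fire, insect, conifer fraction), their interactions with
the census indicator, an iid subplot effect v_ij ~ N(0, d^2), and a plot-level
spatial effect u_i drawn from a Gaussian process with Matern covariance over
plot coordinates.  The likelihood is Gaussian with residual variance sigma^2.

With flat (improper) priors on the coefficients, the posterior of beta
conditional on the variance/spatial hyperparameters is Gaussian in closed
form.  By default the hyperparameters (sigma, d, sigma_u, rho) are estimated
by maximizing the restricted log marginal likelihood (empirical Bayes) and
credible intervals come from the conditional Gaussian; hyperparameter
uncertainty is then not propagated.  A random-walk-free ensemble MCMC over
the log hyperparameters (mixing the conditional Gaussian for beta) is
available as ``inference="mcmc"``.

The dense Matern Gaussian process replaces the finite-element GMRF
approximation often used for such fields: at up to a few thousand plots the
exact covariance is tractable, and all covariance algebra here exploits the
two-level grouping (subplot pairs within plots) so each marginal-likelihood
evaluation costs one plot-level Cholesky rather than an observation-level
one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .covariates import CONTINUOUS_PREDICTORS, PREDICTOR_LABELS, PREDICTORS, encode_binary

logger = logging.getLogger(__name__)

VARIANTS = ("all", "mortality", "growth", "recruitment", "sapling")

#: design matrix column order: intercept, census indicator, ten predictors,
#: ten census-by-predictor interactions (22 coefficients in total)
DESIGN_COLUMNS = (
    ["const", "x1"] + list(PREDICTORS) + [f"x1:{p}" for p in PREDICTORS]
)

BETA_LABELS = (
    ["intercept", "time"]
    + [PREDICTOR_LABELS[p] for p in PREDICTORS]
    + [f"time:{PREDICTOR_LABELS[p]}" for p in PREDICTORS]
)


# ---------------------------------------------------------------------------
# Matern kernel
# ---------------------------------------------------------------------------

def matern_cov(dists, sigma_u: float, rho: float, nu: float = 1.0) -> np.ndarray:
    """Matern covariance over a pairwise-distance array.

    ``sigma_u^2 * (2^(1-nu)/Gamma(nu)) * (sqrt(2 nu) d/rho)^nu *
    K_nu(sqrt(2 nu) d/rho)``, with value ``sigma_u^2`` at d = 0.  ``rho`` is
    the range-like length scale (km) and ``nu`` the smoothness; nu = 0.5
    recovers the exponential kernel ``sigma_u^2 exp(-d/rho)``.
    """
    d = np.asarray(dists, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if d.ndim == 2 and d.shape[0] == d.shape[1]:
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
    if rho <= 0 or nu <= 0:
        raise ValueError("rho and nu must be positive")
    arg = np.sqrt(2.0 * nu) * d / rho
    corr = np.ones_like(arg)
    pos = arg > 0
    a = arg[pos]
    corr[pos] = (2.0 ** (1.0 - nu) / special.gamma(nu)) * a**nu * special.kv(nu, a)
    out = sigma_u**2 * corr
    return float(out) if np.isscalar(dists) else out


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    cti: pd.DataFrame,
    covariates: pd.DataFrame,
    variant: str = "all",
    coding_scheme: str = "dummy",
) -> pd.DataFrame:
    """Long-format design: two rows per subplot (k = 0 and k = 1).

    ``cti`` is the long table from :func:`forestcti.community.cti_table`;
    ``covariates`` the standardized table from
    :func:`forestcti.covariates.build_covariates`.  Counterfactual variants
    replace only the second-census response; predictors and baseline CTI are
    shared.  Rows whose CTI is undefined (NaN) are dropped with a logged
    count; the paired row is retained.  Continuous covariates must already be
    standardized (mean 0, SD 1 over the covariate table).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    for col in CONTINUOUS_PREDICTORS:
        x = covariates[col].to_numpy(float)
        if abs(x.mean()) > 1e-6 or abs(x.std(ddof=1) - 1.0) > 1e-6:
            raise ValueError(
                f"covariate {col} ({PREDICTOR_LABELS[col]}) is not standardized"
            )
    sub = cti[cti["variant"] == variant]
    df = sub.merge(covariates, on=["plot_id", "subplot_id"], how="inner")
    n_nan = int(df["cti_degC"].isna().sum())
    if n_nan:
        logger.info(
            "build_design[%s]: dropped %d rows with undefined CTI", variant, n_nan
        )
    df = df.dropna(subset=["cti_degC"]).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no defined CTI observations for variant {variant!r}")

    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"],
            "subplot_id": df["subplot_id"],
            "k": (df["timepoint"] == 2).astype(int),
            "Y": df["cti_degC"].astype(float),
        }
    )
    out["const"] = 1.0
    out["x1"] = out["k"].astype(float)
    for p in PREDICTORS:
        if p in ("x9", "x10"):
            out[p] = encode_binary(df[p].to_numpy(), coding_scheme)
        else:
            out[p] = df[p].astype(float)
        out[f"x1:{p}"] = out["x1"] * out[p]
    out.attrs["coding_scheme"] = coding_scheme
    out.attrs["variant"] = variant
    return out


# ---------------------------------------------------------------------------
# marginal likelihood machinery
# ---------------------------------------------------------------------------

class _MarginalModel:
    """Restricted marginal likelihood of the two-level spatial model.

    Exploits the covariance structure V = sigma^2 I + d^2 J_sub + Z Sigma_u Z'
    (J_sub block-ones within subplot pairs, Z the row-to-plot indicator):
    the subplot part inverts in closed form per block and the plot-level
    field enters through a P x P Woodbury correction, so one evaluation costs
    a plot-level Cholesky only.
    """

    def __init__(self, X, y, sub_idx, plot_idx, plot_dists, nu, jitter=1e-8):
        self.X = X
        self.y = y
        self.sub_idx = sub_idx
        self.plot_idx = plot_idx
        self.dists = plot_dists
        self.nu = nu
        self.jitter = jitter
        self.n, self.q = X.shape
        self.S = int(sub_idx.max()) + 1
        self.P = int(plot_idx.max()) + 1
        self.m = np.bincount(sub_idx, minlength=self.S).astype(float)
        self.A = np.column_stack([X, y])  # solve both systems at once

    def _vinv_apply(self, sigma2, d2, sigma_u2, rho):
        """Return (V^-1 A, logdet V) for A = [X | y]."""
        A = self.A
        denom = sigma2 + self.m * d2  # per-subplot
        cs = np.zeros((self.S, A.shape[1]))
        np.add.at(cs, self.sub_idx, A)
        Dinv_A = (A - (d2 / denom)[self.sub_idx, None] * cs[self.sub_idx]) / sigma2
        logdet = float(np.sum((self.m - 1.0) * np.log(sigma2) + np.log(denom)))

        if sigma_u2 <= 0:
            return Dinv_A, logdet

        # Woodbury: D^-1 Z = diag(a) Z with a_r = 1/(sigma2 + m_s d2)
        a = (1.0 / denom)[self.sub_idx]
        g = np.bincount(self.plot_idx, weights=a, minlength=self.P)  # Z'D^-1 Z diag
        Sigma_u = matern_cov(self.dists, np.sqrt(sigma_u2), rho, self.nu)
        Sigma_u[np.diag_indices_from(Sigma_u)] += self.jitter * sigma_u2
        # symmetric form: C = I + G^1/2 Sigma_u G^1/2
        gh = np.sqrt(g)
        C = np.eye(self.P) + (gh[:, None] * Sigma_u) * gh[None, :]
        cf = linalg.cho_factor(C, lower=True)
        logdet += 2.0 * float(np.sum(np.log(np.diagonal(cf[0]))))
        # T = Z' diag(a) A  (per-plot weighted column sums)
        T = np.zeros((self.P, A.shape[1]))
        np.add.at(T, self.plot_idx, a[:, None] * A)
        # M^-1 T with M = Sigma_u^-1 + G
        SuT = Sigma_u @ T
        Minv_T = SuT - Sigma_u @ (gh[:, None] * linalg.cho_solve(cf, gh[:, None] * SuT))
        Vinv_A = Dinv_A - a[:, None] * Minv_T[self.plot_idx]
        return Vinv_A, logdet

    def neg2_reml(self, sigma2, d2, sigma_u2, rho):
        Vinv_A, logdetV = self._vinv_apply(sigma2, d2, sigma_u2, rho)
        X, y = self.X, self.y
        VinvX, Vinvy = Vinv_A[:, : self.q], Vinv_A[:, self.q]
        XtVX = X.T @ VinvX
        Xty = X.T @ Vinvy
        cf = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve(cf, Xty)
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diagonal(cf[0]))))
        quad = float(y @ Vinvy - Xty @ beta)
        neg2 = (
            (self.n - self.q) * np.log(2.0 * np.pi)
            + logdetV
            + logdet_XtVX
            + quad
        )
        return neg2, beta, XtVX


# ---------------------------------------------------------------------------
# model spec and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Inference settings for the hierarchical spatial regression."""

    matern_nu: float = 1.0
    inference: str = "empirical_bayes"  # or "mcmc"
    jitter: float = 1e-8
    max_iter: int = 400
    xatol: float = 1e-4
    fatol: float = 1e-6
    #: fix a hyperparameter instead of estimating it (None = estimate);
    #: fixing sigma_u or d to 0 removes that random-effect layer
    fix_sigma: float | None = None
    fix_d: float | None = None
    fix_sigma_u: float | None = None
    fix_rho: float | None = None
    seed: int = 0
    mcmc_walkers: int = 12
    mcmc_steps: int = 400
    mcmc_burn: int = 200
    mcmc_thin: int = 10

    def __post_init__(self):
        if self.matern_nu <= 0:
            raise ValueError("matern_nu must be positive")
        for name in ("fix_sigma", "fix_d", "fix_sigma_u"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PosteriorSummary:
    """Posterior summaries of the 22 coefficients and the hyperparameters."""

    params: pd.DataFrame  # param, label, mean, sd, q025, q975
    hyper: pd.DataFrame  # param, mean, sd, q025, q975
    variant: str
    coding_scheme: str
    inference: str
    n_obs: int
    n_plots: int
    log_marginal: float
    converged: bool

    def coef(self, label: str) -> pd.Series:
        row = self.params[self.params["label"] == label]
        if len(row) != 1:
            raise KeyError(label)
        return row.iloc[0]


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diagonal(r))
    bad = diag < max(X.shape) * np.finfo(float).eps * diag.max() * 1e3
    if bad.any():
        cols = [names[piv[i]] for i in np.nonzero(bad)[0]]
        raise ValueError(f"singular design: collinear columns {cols}")


def _prepare(design: pd.DataFrame, plot_coords: pd.DataFrame, spec: ModelSpec):
    X = design[list(DESIGN_COLUMNS)].to_numpy(float)
    y = design["Y"].to_numpy(float)
    _check_collinearity(X, list(DESIGN_COLUMNS))
    # order-independent factorization: sort keys so summaries are invariant
    # to row permutations
    sub_keys = design["plot_id"].astype(str) + "/" + design["subplot_id"].astype(str)
    sub_idx = pd.Categorical(sub_keys, ordered=True).codes.astype(int)
    plot_ids = np.sort(design["plot_id"].unique())
    plot_pos = {p: i for i, p in enumerate(plot_ids)}
    plot_idx = design["plot_id"].map(plot_pos).to_numpy(int)
    if len(plot_ids) < 2:
        raise ValueError("need at least 2 plots")
    coords = (
        plot_coords.drop_duplicates("plot_id")
        .set_index("plot_id")
        .loc[plot_ids, ["x_km", "y_km"]]
        .to_numpy(float)
    )
    dists = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    return _MarginalModel(X, y, sub_idx, plot_idx, dists, spec.matern_nu, spec.jitter)


def _optimize_hyper(mm: _MarginalModel, spec: ModelSpec):
    """Empirical-Bayes point estimates of (sigma2, d2, sigma_u2, rho)."""
    resid = mm.y - mm.X @ np.linalg.lstsq(mm.X, mm.y, rcond=None)[0]
    v0 = max(float(np.var(resid)), 1e-8)
    off = mm.dists[np.triu_indices(mm.P, 1)]
    rho0 = max(float(np.median(off)) / 3.0, 1e-3) if off.size else 1.0

    free: list[str] = []
    init: list[float] = []
    fixed = {
        "sigma2": None if spec.fix_sigma is None else spec.fix_sigma**2,
        "d2": None if spec.fix_d is None else spec.fix_d**2,
        "sigma_u2": None if spec.fix_sigma_u is None else spec.fix_sigma_u**2,
        "rho": spec.fix_rho,
    }
    defaults = {"sigma2": 0.5 * v0, "d2": 0.25 * v0, "sigma_u2": 0.25 * v0, "rho": rho0}
    spatial_off = fixed["sigma_u2"] == 0.0
    for name in ("sigma2", "d2", "sigma_u2", "rho"):
        if fixed[name] is not None or (spatial_off and name == "rho"):
            continue
        free.append(name)
        init.append(np.log(defaults[name]))
    if spatial_off and fixed["rho"] is None:
        fixed["rho"] = rho0  # irrelevant without a field; pin it

    def unpack(theta):
        vals = dict(fixed)
        for name, t in zip(free, theta):
            vals[name] = float(np.exp(np.clip(t, -40.0, 40.0)))
        if vals["sigma2"] == 0.0:
            vals["sigma2"] = 1e-12  # keep the likelihood proper
        return vals

    def obj(theta):
        v = unpack(theta)
        try:
            neg2, _, _ = mm.neg2_reml(v["sigma2"], v["d2"], v["sigma_u2"], v["rho"])
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        return neg2

    if free:
        res = optimize.minimize(
            obj,
            np.array(init),
            method="Nelder-Mead",
            options={
                "maxiter": spec.max_iter * max(len(free), 1),
                "xatol": spec.xatol,
                "fatol": spec.fatol,
            },
        )
        vals = unpack(res.x)
        converged = bool(res.success)
    else:
        vals = unpack([])
        converged = True
    return vals, converged


_BETA_NAMES = [f"beta{i:02d}" for i in range(len(DESIGN_COLUMNS))]


def fit(
    design: pd.DataFrame,
    plot_coords: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> PosteriorSummary:
    """Fit the hierarchical spatial regression and summarize the posterior.

    ``design`` comes from :func:`build_design`; ``plot_coords`` maps
    ``plot_id`` to planar km coordinates.  Returns posterior mean, SD and
    central 95% credible interval for the 22 coefficients plus summaries of
    (sigma, d, sigma_u, rho).
    """
    mm = _prepare(design, plot_coords, spec)
    if spec.inference == "empirical_bayes":
        vals, converged = _optimize_hyper(mm, spec)
        neg2, beta, XtVX = mm.neg2_reml(
            vals["sigma2"], vals["d2"], vals["sigma_u2"], vals["rho"]
        )
        cov = linalg.inv(XtVX)
        sd = np.sqrt(np.diagonal(cov))
        z = stats.norm.ppf(0.975)
        params = pd.DataFrame(
            {
                "param": _BETA_NAMES,
                "label": BETA_LABELS,
                "mean": beta,
                "sd": sd,
                "q025": beta - z * sd,
                "q975": beta + z * sd,
            }
        )
        hyper_vals = {
            "sigma": np.sqrt(vals["sigma2"]),
            "d": np.sqrt(vals["d2"]),
            "sigma_u": np.sqrt(vals["sigma_u2"]),
            "rho": vals["rho"],
        }
        hyper = pd.DataFrame(
            {
                "param": list(hyper_vals),
                "mean": list(hyper_vals.values()),
                "sd": 0.0,
                "q025": list(hyper_vals.values()),
                "q975": list(hyper_vals.values()),
            }
        )
        log_marginal = -0.5 * neg2
    elif spec.inference == "mcmc":
        params, hyper, log_marginal, converged = _fit_mcmc(mm, spec)
    else:
        raise ValueError(f"unknown inference method {spec.inference!r}")

    return PosteriorSummary(
        params=params,
        hyper=hyper,
        variant=design.attrs.get("variant", "all"),
        coding_scheme=design.attrs.get("coding_scheme", "dummy"),
        inference=spec.inference,
        n_obs=mm.n,
        n_plots=mm.P,
        log_marginal=float(log_marginal),
        converged=converged,
    )


def _fit_mcmc(mm: _MarginalModel, spec: ModelSpec):
    """Ensemble MCMC over log hyperparameters, mixing the conditional
    Gaussian for the coefficients (log-uniform hyperpriors)."""
    import emcee

    ndim = 4

    def log_prob(theta):
        if np.any(np.abs(theta) > 25):
            return -np.inf
        s2, d2, su2, rho = np.exp(theta)
        try:
            neg2, _, _ = mm.neg2_reml(s2, d2, su2, rho)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return -np.inf
        return -0.5 * neg2

    vals, _ = _optimize_hyper(mm, spec)
    center = np.log(
        [max(vals["sigma2"], 1e-8), max(vals["d2"], 1e-8),
         max(vals["sigma_u2"], 1e-8), max(vals["rho"], 1e-8)]
    )
    rng = np.random.default_rng(spec.seed)
    p0 = center + 0.1 * rng.standard_normal((spec.mcmc_walkers, ndim))
    sampler = emcee.EnsembleSampler(spec.mcmc_walkers, ndim, log_prob)
    sampler.run_mcmc(p0, spec.mcmc_steps, progress=False)
    chain = sampler.get_chain(discard=spec.mcmc_burn, thin=spec.mcmc_thin, flat=True)

    betas = []
    for theta in chain:
        s2, d2, su2, rho = np.exp(theta)
        _, beta, XtVX = mm.neg2_reml(s2, d2, su2, rho)
        cov = linalg.inv(XtVX)
        betas.append(rng.multivariate_normal(beta, cov))
    betas = np.array(betas)
    params = pd.DataFrame(
        {
            "param": _BETA_NAMES,
            "label": BETA_LABELS,
            "mean": betas.mean(0),
            "sd": betas.std(0, ddof=1),
            "q025": np.quantile(betas, 0.025, axis=0),
            "q975": np.quantile(betas, 0.975, axis=0),
        }
    )
    hsamp = np.exp(chain)
    hvals = np.column_stack(
        [np.sqrt(hsamp[:, 0]), np.sqrt(hsamp[:, 1]), np.sqrt(hsamp[:, 2]), hsamp[:, 3]]
    )
    hyper = pd.DataFrame(
        {
            "param": ["sigma", "d", "sigma_u", "rho"],
            "mean": hvals.mean(0),
            "sd": hvals.std(0, ddof=1),
            "q025": np.quantile(hvals, 0.025, axis=0),
            "q975": np.quantile(hvals, 0.975, axis=0),
        }
    )
    lp = sampler.get_log_prob(discard=spec.mcmc_burn, thin=spec.mcmc_thin, flat=True)
    return params, hyper, float(np.max(lp)), True


# ---------------------------------------------------------------------------
# interpretation helpers
# ---------------------------------------------------------------------------

def mean_thermophilization(
    summary: PosteriorSummary, interval_years: float = 10.0
) -> dict:
    """Population-mean CTI change between censuses, from the census-indicator
    coefficient.

    Valid only under weighted effect coding of the binary predictors (and
    centered continuous predictors): then the census-indicator coefficient is
    the population-mean change rather than the change for the reference
    category.  ``per_year`` divides by the census interval length.
    """
    if summary.coding_scheme != "weighted_effect":
        raise ValueError(
            "population-mean thermophilization requires a weighted_effect-coded "
            f"fit, got {summary.coding_scheme!r}"
        )
    row = summary.coef("time")
    return {
        "estimate": float(row["mean"]),
        "sd": float(row["sd"]),
        "lower": float(row["q025"]),
        "upper": float(row["q975"]),
        "per_year": float(row["mean"]) / interval_years,
        "interval_years": interval_years,
    }


def effect_table(summaries: dict[str, PosteriorSummary]) -> pd.DataFrame:
    """Stack coefficient and hyperparameter summaries across model variants."""
    if not summaries:
        raise ValueError("no fitted variants given")
    frames = []
    for variant, s in summaries.items():
        p = s.params.copy()
        p["variant"] = variant
        h = s.hyper.copy()
        h["label"] = h["param"]
        h["variant"] = variant
        frames.append(p)
        frames.append(h[["param", "label", "mean", "sd", "q025", "q975", "variant"]])
    return pd.concat(frames, ignore_index=True)[
        ["variant", "param", "label", "mean", "sd", "q025", "q975"]
    ]


# ---------------------------------------------------------------------------
# self-simulation (for calibration checks)
# ---------------------------------------------------------------------------

def simulate_response(
    design: pd.DataFrame,
    plot_coords: pd.DataFrame,
    beta: np.ndarray,
    sigma: float,
    d: float,
    sigma_u: float,
    rho: float,
    nu: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a response vector from the model's own generative process."""
    rng = rng or np.random.default_rng()
    X = design[list(DESIGN_COLUMNS)].to_numpy(float)
    mu = X @ np.asarray(beta, float)
    plot_ids = np.sort(design["plot_id"].unique())
    pos = {p: i for i, p in enumerate(plot_ids)}
    pidx = design["plot_id"].map(pos).to_numpy(int)
    coords = (
        plot_coords.drop_duplicates("plot_id")
        .set_index("plot_id")
        .loc[plot_ids, ["x_km", "y_km"]]
        .to_numpy(float)
    )
    if sigma_u > 0:
        dmat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        cov = matern_cov(dmat, sigma_u, rho, nu)
        cov[np.diag_indices_from(cov)] += 1e-10 * sigma_u**2
        u = np.linalg.cholesky(cov) @ rng.standard_normal(len(plot_ids))
    else:
        u = np.zeros(len(plot_ids))
    sub_keys = design["plot_id"].astype(str) + "/" + design["subplot_id"].astype(str)
    sidx = pd.Categorical(sub_keys, ordered=True).codes.astype(int)
    v = d * rng.standard_normal(sidx.max() + 1)
    return mu + u[pidx] + v[sidx] + sigma * rng.standard_normal(len(design))


__all__ = [
    "VARIANTS",
    "DESIGN_COLUMNS",
    "BETA_LABELS",
    "ModelSpec",
    "PosteriorSummary",
    "matern_cov",
    "build_design",
    "fit",
    "mean_thermophilization",
    "effect_table",
    "simulate_response",
]
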