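"""Species temperature-index estimation from occurrence data.

Three estimators of a species' temperature niche along the mean-annual-
temperature (MAT) axis:

* **simple niche mean** — arithmetic mean of MAT at the species' occurrences;
* **modeled niche mean** — density-weighted mean of a smooth occurrence
  response curve fitted against background climate;
* **modeled niche optimum** — the MAT at which that curve peaks.

The response curve is a presence/background logistic regression on a B-spline
basis in MAT: with occurrences coded 1 and background points 0, the fitted
log-odds is (up to a constant) the log ratio of occurrence density to
background density, so ``exp(linear predictor)`` restores the species'
relative occurrence density when the background sample is representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

METHODS = ("simple_mean", "modeled_mean", "modeled_optimum")

DEFAULT_GRID_STEP = 0.1  # degC; below the precision of reported effects
DEFAULT_DF = 10  # spline basis dimension (effective df lands near 8)
DEFAULT_PENALTY = 10.0  # quadratic smoothing penalty weight


@dataclass(frozen=True)
class ResponseCurve:
    """Relative occurrence density of one species along the MAT axis."""

    mat_grid: np.ndarray  # strictly increasing, degC
    density: np.ndarray  # nonnegative relative response, max-normalised
    effective_df: float

    def __post_init__(self):
        if np.any(np.diff(self.mat_grid) <= 0):
            raise ValueError("mat_grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


def simple_niche_mean(occurrence_mats) -> float:
    """Arithmetic mean of MAT over a species' occurrence records."""
    x = np.asarray(list(occurrence_mats), dtype=float)
    if x.size == 0:
        raise ValueError("no occurrences given")
    return float(np.mean(x))


def fit_response_curve(
    occurrence_mats,
    background_mats,
    smoothness: int = DEFAULT_DF,
    grid_step: float = DEFAULT_GRID_STEP,
    penalty: float = DEFAULT_PENALTY,
) -> ResponseCurve:
    """Fit the smooth occurrence-vs-background response curve for one species.

    A penalized cubic-spline logistic regression of presence (1) against
    background (0) along MAT; ``smoothness`` is the basis dimension and
    ``penalty`` the quadratic smoothing weight (the realised effective df is
    recorded on the returned curve).  Occurrences falling outside the
    background MAT range are dropped with a warning (the curve is only
    identified where background is sampled).  Requires at least 20
    occurrences.
    """
    occ = np.asarray(list(occurrence_mats), dtype=float)
    bg = np.asarray(list(background_mats), dtype=float)
    if bg.size < 2:
        raise ValueError("background must contain at least 2 points")
    lo, hi = float(bg.min()), float(bg.max())
    outside = (occ < lo) | (occ > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} occurrences outside the background MAT range "
            f"[{lo:.2f}, {hi:.2f}] were dropped",
            stacklevel=2,
        )
        occ = occ[~outside]
    if occ.size < 20:
        raise ValueError(f"need >= 20 in-range occurrences, got {occ.size}")

    x = np.concatenate([occ, bg])
    y = np.concatenate([np.ones(occ.size), np.zeros(bg.size)])
    splines = BSplines(x[:, None], df=[smoothness], degree=[3])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gam = GLMGam(
            y,
            exog=np.ones((x.size, 1)),
            smoother=splines,
            alpha=[penalty],
            family=sm.families.Binomial(),
        )
        res = gam.fit()

    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    basis = splines.transform(np.clip(grid, lo, hi)[:, None])
    eta = res.params[0] + basis @ res.params[1:]
    dens = np.exp(eta - eta.max())  # relative density, max-normalised
    return ResponseCurve(
        mat_grid=grid, density=dens, effective_df=float(np.sum(res.edf))
    )


def modeled_niche_mean(curve: ResponseCurve) -> float:
    """Density-weighted mean MAT of the response curve (trapezoidal)."""
    if not np.any(curve.density > 0):
        raise ValueError("response curve has zero total mass")
    num = np.trapezoid(curve.mat_grid * curve.density, curve.mat_grid)
    den = np.trapezoid(curve.density, curve.mat_grid)
    return float(num / den)


def modeled_niche_optimum(curve: ResponseCurve) -> float:
    """MAT at the curve's maximum; ties break to the lowest MAT."""
    if not np.any(curve.density > 0):
        raise ValueError("response curve has zero total mass")
    return float(curve.mat_grid[int(np.argmax(curve.density))])


def estimate_indices(
    occurrences: pd.DataFrame,
    background_mats,
    smoothness: int = DEFAULT_DF,
    grid_step: float = DEFAULT_GRID_STEP,
    penalty: float = DEFAULT_PENALTY,
) -> pd.DataFrame:
    """All three temperature indices for every species in an occurrence table.

    Parameters
    ----------
    occurrences
        Long table with columns ``species_id`` and ``mat`` (degC).
    background_mats
        MAT sample representing available climate (shared across species).

    Returns
    -------
    Long table ``(species_id, method, value_degC)`` with one row per species
    per method in :data:`METHODS`.
    """
    rows = []
    for sid, grp in occurrences.groupby("species_id", sort=True):
        mats = grp["mat"].to_numpy()
        curve = fit_response_curve(mats, background_mats, smoothness, grid_step, penalty)
        rows += [
            {"species_id": sid, "method": "simple_mean",
             "value_degC": simple_niche_mean(mats)},
            {"species_id": sid, "method": "modeled_mean",
             "value_degC": modeled_niche_mean(curve)},
            {"species_id": sid, "method": "modeled_optimum",
             "value_degC": modeled_niche_optimum(curve)},
        ]
    return pd.DataFrame(rows)


def index_correlations(indices: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among the three index methods.

    ``indices`` is the long table from :func:`estimate_indices`; at least
    three species with all three methods are required, and no method's values
    may be constant across species.
    """
    wide = indices.pivot(index="species_id", columns="method", values="value_degC")
    missing = [m for m in METHODS if m not in wide.columns]
    if missing:
        raise ValueError(f"missing methods: {missing}")
    wide = wide[list(METHODS)].dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 species with all three index values")
    if np.any(wide.std(axis=0).to_numpy() == 0):
        raise ValueError("correlation undefined: a method's values are constant")
    corr = np.corrcoef(wide.to_numpy().T)
    return pd.DataFrame(corr, index=list(METHODS), columns=list(METHODS))


__all__ = [
    "METHODS",
    "ResponseCurve",
    "simple_niche_mean",
    "fit_response_curve",
    "modeled_niche_mean",
    "modeled_niche_optimum",
    "estimate_indices",
    "index_correlations",
]
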