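"""Derived predictors for the thermophilization regression.

Covers the model's fixed-effect inputs: 15-year sliding-window climate
changes, annual climatic water deficit (CWD), topographic heat load,
z-standardization with stored transforms, and dummy / weighted-effect coding
of the binary disturbance predictors.

Predictor naming follows the regression design: ``x2``-``x4`` are baseline
mean annual temperature, precipitation and CWD; ``x5``-``x7`` their recent
changes; ``x8`` topographic heat load; ``x9``/``x10`` fire and insect damage
flags; ``x11`` the baseline conifer basal-area fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS_PREDICTORS = ("x2", "x3", "x4", "x5", "x6", "x7", "x8", "x11")
BINARY_PREDICTORS = ("x9", "x10")
PREDICTORS = ("x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9", "x10", "x11")

PREDICTOR_LABELS = {
    "x2": "baseline_mat",
    "x3": "baseline_precip",
    "x4": "baseline_cwd",
    "x5": "mat_change",
    "x6": "precip_change",
    "x7": "cwd_change",
    "x8": "heat_load",
    "x9": "fire",
    "x10": "insect",
    "x11": "conifer_fraction",
}


def window_climate_change(
    series: pd.DataFrame, census_year: int, variable: str
) -> float:
    """Recent change in an annual climate variable around a census year.

    Difference between the 15-y mean over ``[t-4, t+10]`` and the 15-y mean
    over ``[t-19, t-5]`` (both windows inclusive), where ``t`` is the census
    year.  ``series`` has columns ``year`` and ``variable``; missing years in
    either window raise an error listing the gap.
    """
    t = int(census_year)
    early = set(range(t - 19, t - 4))
    late = set(range(t - 4, t + 11))
    have = set(series["year"].astype(int))
    gaps = sorted((early | late) - have)
    if gaps:
        raise ValueError(f"climate series missing years {gaps}")
    by_year = series.set_index(series["year"].astype(int))[variable]
    return float(by_year.loc[sorted(late)].mean() - by_year.loc[sorted(early)].mean())


def annual_cwd(pet_monthly, aet_monthly) -> float:
    """Annual climatic water deficit: sum of positive monthly PET - AET (mm)."""
    pet = np.asarray(pet_monthly, dtype=float)
    aet = np.asarray(aet_monthly, dtype=float)
    if pet.shape != (12,) or aet.shape != (12,):
        raise ValueError("pet_monthly and aet_monthly must each have 12 values")
    return float(np.sum(np.maximum(pet - aet, 0.0)))


@dataclass(frozen=True)
class HeatLoadConstants:
    """Coefficients of the folded-aspect heat-load equation.

    Defaults follow the McCune-Keon formulation with the aspect folded about
    the southwest (225 deg) axis, A' = |180 - |aspect - 225||:
    HL = c0 + c_ls*cos(L)*cos(S) - c_l_s*sin(L)*sin(S) - c_as*cos(A')*sin(S).
    """

    c0: float = 0.339
    c_ls: float = 0.808
    c_l_s: float = 0.196
    c_as: float = 0.482
    fold_deg: float = 225.0


def heat_load(
    latitude,
    slope,
    aspect,
    constants: HeatLoadConstants = HeatLoadConstants(),
):
    """Topographic heat load from latitude, slope and aspect (all degrees).

    Dimensionless index of solar heating, maximal on slopes facing the
    folding axis (southwest by default, in the northern hemisphere).  Flat
    ground (slope 0) gives a value independent of aspect.
    """
    lat = np.asarray(latitude, dtype=float)
    slp = np.asarray(slope, dtype=float)
    asp = np.asarray(aspect, dtype=float)
    if np.any((slp < 0) | (slp > 90)):
        raise ValueError("slope must be in [0, 90] degrees")
    if np.any((asp < 0) | (asp >= 360)):
        raise ValueError("aspect must be in [0, 360) degrees")
    folded = np.abs(180.0 - np.abs(asp - constants.fold_deg))
    L, S, A = np.deg2rad(lat), np.deg2rad(slp), np.deg2rad(folded)
    hl = (
        constants.c0
        + constants.c_ls * np.cos(L) * np.cos(S)
        - constants.c_l_s * np.sin(L) * np.sin(S)
        - constants.c_as * np.cos(A) * np.sin(S)
    )
    return hl.item() if np.ndim(hl) == 0 else hl


@dataclass(frozen=True)
class Standardization:
    """Stored z-transform so effect sizes can be mapped back to raw units."""

    mean: float
    sd: float

    def apply(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(values) -> tuple[np.ndarray, Standardization]:
    """Center and scale to mean 0, SD 1 (sample SD), keeping the transform."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standardize needs >= 2 distinct values")
    transform = Standardization(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))
    return transform.apply(x), transform


def encode_binary(values, scheme: str = "dummy") -> np.ndarray:
    """Code a 0/1 predictor for regression.

    ``dummy`` keeps 0/1.  ``weighted_effect`` codes category 1 as 1 and the
    reference category as ``-n1/n0``, so the observation-weighted sum of
    codes is zero and the model intercept estimates the population mean.
    """
    x = np.asarray(values)
    uniq = set(np.unique(x).tolist())
    if not uniq <= {0, 1, True, False}:
        raise ValueError("encode_binary expects 0/1 values")
    x = x.astype(float)
    if scheme == "dummy":
        return x
    if scheme == "weighted_effect":
        n1 = float(np.sum(x == 1))
        n0 = float(np.sum(x == 0))
        if n0 == 0 or n1 == 0:
            # single-category predictor: no contrast, code all zeros
            return np.zeros_like(x)
        return np.where(x == 1, 1.0, -n1 / n0)
    raise ValueError(f"unknown coding scheme {scheme!r}")


def build_covariates(
    landscape: pd.DataFrame,
    conifer_fraction: pd.DataFrame,
    heatload_constants: HeatLoadConstants = HeatLoadConstants(),
) -> tuple[pd.DataFrame, dict[str, Standardization]]:
    """Assemble the standardized predictor table for the regression stage.

    ``landscape`` supplies baseline climate, its recent changes, topography,
    and the fire/insect flags; ``conifer_fraction`` is a per-subplot table
    (``plot_id, subplot_id, conifer_fraction``).  Continuous predictors are
    z-standardized over the analysis set (predictors are time-invariant per
    subplot, so the transform is computed once and shared by both census
    rows); the binary flags are returned raw 0/1 for coding at design-build
    time.  Returns the table plus the stored transforms keyed by predictor.
    """
    df = landscape.merge(conifer_fraction, on=["plot_id", "subplot_id"], how="inner")
    n_undef = int(df["conifer_fraction"].isna().sum())
    if n_undef:
        logger.info(
            "build_covariates: dropped %d subplots with undefined conifer fraction",
            n_undef,
        )
        df = df.dropna(subset=["conifer_fraction"]).reset_index(drop=True)
    out = df[["plot_id", "subplot_id"]].copy()
    raw = {
        "x2": df["baseline_mat"],
        "x3": df["baseline_precip"],
        "x4": df["baseline_cwd"],
        "x5": df["mat_change"],
        "x6": df["precip_change"],
        "x7": df["cwd_change"],
        "x8": heat_load(
            df["latitude"].to_numpy(),
            df["slope"].to_numpy(),
            df["aspect"].to_numpy(),
            heatload_constants,
        ),
        "x11": df["conifer_fraction"],
    }
    transforms: dict[str, Standardization] = {}
    for name, col in raw.items():
        z, tr = standardize(np.asarray(col, dtype=float))
        out[name] = z
        transforms[name] = tr
    out["x9"] = df["fire"].astype(int)
    out["x10"] = df["insect"].astype(int)
    return out[["plot_id", "subplot_id", *PREDICTORS]], transforms


__all__ = [
    "CONTINUOUS_PREDICTORS",
    "BINARY_PREDICTORS",
    "PREDICTORS",
    "PREDICTOR_LABELS",
    "HeatLoadConstants",
    "Standardization",
    "window_climate_change",
    "annual_cwd",
    "heat_load",
    "standardize",
    "encode_binary",
    "build_covariates",
]
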