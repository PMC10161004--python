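"""Community temperature indices and their demographic decomposition.

The community temperature index (CTI) of a subplot at one census is the
basal-area-weighted mean of the temperature indices of the species present.
Change in CTI between two censuses ("thermophilization" when positive) is
decomposed into the contributions of mortality, growth, and recruitment by
rebuilding counterfactual second-census communities in which only one
demographic process acts:

* ``mortality`` — trees that died are removed; survivors are held at their
  first-census size; recruits are omitted;
* ``growth`` — survivors take their observed second-census size; trees that
  died are kept alive at first-census size; recruits are omitted;
* ``recruitment`` — recruits enter at their observed size; everything present
  at the first census is kept alive at fixed size;
* ``all`` — the observed second census (survivors grown, dead removed,
  recruits present).

Each component is CTI(counterfactual T2) - CTI(T1).  Because a weighted mean
is nonlinear in its weights the three components need not sum to the total.

Census boundary rules: trees farther than 7.32 m from the subplot centre are
disregarded, and the main size class comprises stems with DBH >= 12.7 cm at
the census in question (both boundaries inclusive); saplings span
[2.5, 12.7) cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MAIN_DBH_CM, SAPLING_MIN_DBH_CM, SUBPLOT_RADIUS_M

logger = logging.getLogger(__name__)

SCENARIOS = ("all", "mortality", "growth", "recruitment")
FATES = ("survivor", "died", "recruit")


class MissingSpeciesIndexError(KeyError):
    """A tree's species has no temperature index."""


def basal_area(dbh_cm):
    """Stem cross-sectional area pi*(DBH/2)^2 in cm^2."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0) or np.any(~np.isfinite(dbh)):
        raise ValueError("DBH must be positive and finite")
    out = np.pi * (dbh / 2.0) ** 2
    return float(out) if np.isscalar(dbh_cm) else out


def _as_index_map(indices) -> pd.Series:
    """Accept a dict, Series, or (species_id, value_degC) frame."""
    if isinstance(indices, pd.Series):
        return indices
    if isinstance(indices, dict):
        return pd.Series(indices)
    if isinstance(indices, pd.DataFrame):
        return indices.set_index("species_id")["value_degC"]
    raise TypeError("indices must be a dict, Series, or DataFrame")


def census_view(trees: pd.DataFrame, timepoint: int) -> pd.DataFrame:
    """Trees present at census 1 or 2 with a resolved ``dbh`` column."""
    if timepoint == 1:
        present = trees[trees["fate"].isin(["survivor", "died"])].copy()
        present["dbh"] = present["dbh_t1_cm"]
    elif timepoint == 2:
        present = trees[trees["fate"].isin(["survivor", "recruit"])].copy()
        present["dbh"] = present["dbh_t2_cm"]
    else:
        raise ValueError("timepoint must be 1 or 2")
    return present


def filter_census_trees(
    trees: pd.DataFrame,
    min_dbh: float = MAIN_DBH_CM,
    max_dist: float = SUBPLOT_RADIUS_M,
    max_dbh: float | None = None,
) -> pd.DataFrame:
    """Apply the distance and DBH census filters (boundaries inclusive).

    ``trees`` must carry a resolved ``dbh`` column (see :func:`census_view`);
    the filter is applied per timepoint, so a stem below the threshold at the
    first census that crosses it by the second appears only in the second
    census (as a recruit).  ``max_dbh`` (exclusive) selects the sapling band.
    """
    keep = (trees["dist_m"] <= max_dist) & (trees["dbh"] >= min_dbh)
    if max_dbh is not None:
        keep &= trees["dbh"] < max_dbh
    return trees[keep]


def community_temperature_index(trees: pd.DataFrame, indices) -> float:
    """Basal-area-weighted mean species temperature index of one community.

    ``trees`` needs ``species_id`` and a resolved ``dbh`` column.  Returns
    NaN (the undefined-CTI signal) when the community has zero basal area;
    raises :class:`MissingSpeciesIndexError` naming any species without an
    index.
    """
    if len(trees) == 0:
        return float("nan")
    idx = _as_index_map(indices)
    missing = set(trees["species_id"]) - set(idx.index)
    if missing:
        raise MissingSpeciesIndexError(
            f"no temperature index for species: {sorted(missing)}"
        )
    ba = basal_area(trees["dbh"].to_numpy())
    total = ba.sum()
    if total <= 0:
        return float("nan")
    vals = idx.reindex(trees["species_id"]).to_numpy()
    return float(np.sum(ba * vals) / total)


def counterfactual_t2(trees: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Second-census community under one demographic scenario.

    Returns the trees present at the counterfactual T2 with a resolved
    ``dbh`` column following the scenario rules in the module docstring.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    surv = trees[trees["fate"] == "survivor"].copy()
    died = trees[trees["fate"] == "died"].copy()
    rec = trees[trees["fate"] == "recruit"].copy()
    if scenario == "all":
        surv["dbh"] = surv["dbh_t2_cm"]
        rec["dbh"] = rec["dbh_t2_cm"]
        parts = [surv, rec]
    elif scenario == "mortality":
        surv["dbh"] = surv["dbh_t1_cm"]
        parts = [surv]
    elif scenario == "growth":
        surv["dbh"] = surv["dbh_t2_cm"]
        died["dbh"] = died["dbh_t1_cm"]
        parts = [surv, died]
    else:  # recruitment
        surv["dbh"] = surv["dbh_t1_cm"]
        died["dbh"] = died["dbh_t1_cm"]
        rec["dbh"] = rec["dbh_t2_cm"]
        parts = [surv, died, rec]
    return pd.concat(parts, ignore_index=True)


# scenario -> (included fates, dbh column per fate); "t1" is the baseline view
_SCENARIO_DBH = {
    "t1": {"survivor": "dbh_t1_cm", "died": "dbh_t1_cm"},
    "all": {"survivor": "dbh_t2_cm", "recruit": "dbh_t2_cm"},
    "mortality": {"survivor": "dbh_t1_cm"},
    "growth": {"survivor": "dbh_t2_cm", "died": "dbh_t1_cm"},
    "recruitment": {
        "survivor": "dbh_t1_cm",
        "died": "dbh_t1_cm",
        "recruit": "dbh_t2_cm",
    },
}


def _cti_by_subplot(
    trees: pd.DataFrame,
    indices,
    scenario: str,
    min_dbh: float = MAIN_DBH_CM,
    max_dist: float = SUBPLOT_RADIUS_M,
    max_dbh: float | None = None,
    sapling_band: bool = False,
) -> pd.Series:
    """Vectorized CTI per subplot for one (counterfactual) census view.

    Rows stay in table order for every scenario, so scenario identities
    (e.g. zero mortality component when nothing died) hold exactly in
    floating point.  Subplots with zero basal area map to NaN.
    """
    idx = _as_index_map(indices)
    missing = set(trees["species_id"]) - set(idx.index)
    if missing:
        raise MissingSpeciesIndexError(
            f"no temperature index for species: {sorted(missing)}"
        )
    if sapling_band:
        trees = trees[trees["size_class"] == "sapling"]
        min_dbh, max_dbh = SAPLING_MIN_DBH_CM, MAIN_DBH_CM

    if len(trees) == 0:
        return pd.Series(dtype=float, name=scenario)

    fate = trees["fate"].to_numpy()
    dbh = np.full(len(trees), np.nan)
    include = np.zeros(len(trees), dtype=bool)
    for f, col in _SCENARIO_DBH[scenario].items():
        sel = fate == f
        include |= sel
        dbh[sel] = trees[col].to_numpy()[sel]
    include &= (trees["dist_m"].to_numpy() <= max_dist) & (dbh >= min_dbh)
    if max_dbh is not None:
        include &= dbh < max_dbh

    keys, uniques = pd.factorize(
        pd.MultiIndex.from_frame(trees[["plot_id", "subplot_id"]]), sort=True
    )
    num = np.zeros(len(uniques))
    den = np.zeros(len(uniques))
    sel = np.nonzero(include)[0]
    ba = np.pi * (dbh[sel] / 2.0) ** 2
    vals = idx.reindex(trees["species_id"].to_numpy()[sel]).to_numpy()
    np.add.at(num, keys[sel], ba * vals)
    np.add.at(den, keys[sel], ba)
    with np.errstate(invalid="ignore", divide="ignore"):
        cti = np.where(den > 0, num / den, np.nan)
    return pd.Series(cti, index=uniques, name=scenario)


@dataclass(frozen=True)
class DecompositionResult:
    plot_id: int
    subplot_id: int
    cti_t1: float
    delta_total: float
    delta_mortality: float
    delta_growth: float
    delta_recruitment: float

    @property
    def undefined(self) -> dict[str, bool]:
        return {
            "t1": not np.isfinite(self.cti_t1),
            "total": not np.isfinite(self.delta_total),
            "mortality": not np.isfinite(self.delta_mortality),
            "growth": not np.isfinite(self.delta_growth),
            "recruitment": not np.isfinite(self.delta_recruitment),
        }


def _decompose_frame(
    trees: pd.DataFrame,
    indices,
    min_dbh: float = MAIN_DBH_CM,
    max_dist: float = SUBPLOT_RADIUS_M,
) -> pd.DataFrame:
    """Per-subplot baseline CTI, scenario CTIs, and delta components."""
    main = trees[trees["size_class"] != "sapling"] if "size_class" in trees else trees
    views = {
        scen: _cti_by_subplot(main, indices, scen, min_dbh, max_dist)
        for scen in ("t1", *SCENARIOS)
    }
    frame = pd.DataFrame(views)
    frame.index.names = ["plot_id", "subplot_id"]
    out = frame.reset_index().rename(columns={"t1": "cti_t1"})
    for scen, col in (
        ("all", "delta_total"),
        ("mortality", "delta_mortality"),
        ("growth", "delta_growth"),
        ("recruitment", "delta_recruitment"),
    ):
        out[col] = out[scen] - out["cti_t1"]
    return out[
        ["plot_id", "subplot_id", "cti_t1", "all", "mortality", "growth",
         "recruitment", "delta_total", "delta_mortality", "delta_growth",
         "delta_recruitment"]
    ]


def decompose(
    subplot_trees: pd.DataFrame,
    indices,
    min_dbh: float = MAIN_DBH_CM,
    max_dist: float = SUBPLOT_RADIUS_M,
) -> DecompositionResult:
    """Counterfactual decomposition of one subplot's CTI change.

    The census filters are applied per (counterfactual) timepoint.  An empty
    counterfactual community yields a NaN component, flagged via
    :attr:`DecompositionResult.undefined`.
    """
    if len(subplot_trees) == 0:
        return DecompositionResult(-1, -1, *(float("nan"),) * 5)
    frame = _decompose_frame(subplot_trees, indices, min_dbh, max_dist)
    if len(frame) != 1:
        raise ValueError("decompose expects the trees of a single subplot")
    r = frame.iloc[0]
    return DecompositionResult(
        plot_id=r["plot_id"],
        subplot_id=r["subplot_id"],
        cti_t1=r["cti_t1"],
        delta_total=r["delta_total"],
        delta_mortality=r["delta_mortality"],
        delta_growth=r["delta_growth"],
        delta_recruitment=r["delta_recruitment"],
    )


def decompose_subplots(trees: pd.DataFrame, indices) -> pd.DataFrame:
    """Decomposition for every subplot; subplots with undefined baseline CTI
    are excluded with a logged count."""
    frame = _decompose_frame(trees, indices)
    dropped = int((~np.isfinite(frame["cti_t1"])).sum())
    if dropped:
        logger.info("decompose: dropped %d subplots with undefined baseline CTI", dropped)
    keep = frame[np.isfinite(frame["cti_t1"])]
    return keep[
        ["plot_id", "subplot_id", "cti_t1", "delta_total", "delta_mortality",
         "delta_growth", "delta_recruitment"]
    ].reset_index(drop=True)


def sapling_cti(trees: pd.DataFrame, indices, timepoint: int) -> float:
    """CTI restricted to the sapling band [2.5, 12.7) cm at one census
    (single-subplot convenience; NaN when no saplings are present)."""
    scen = "t1" if timepoint == 1 else "all"
    out = _cti_by_subplot(trees, indices, scen, sapling_band=True)
    if len(out) == 0:
        return float("nan")
    if len(out) != 1:
        raise ValueError("sapling_cti expects the trees of a single subplot")
    return float(out.iloc[0])


def cti_table(trees: pd.DataFrame, indices) -> pd.DataFrame:
    """Long CTI table for the five response variants of the regression stage.

    One row per subplot x timepoint x variant with columns ``plot_id,
    subplot_id, timepoint, variant, cti_degC``.  For the counterfactual
    variants the first-census value is the observed baseline CTI (shared with
    ``all``); the second-census value is the counterfactual CTI.  The
    ``sapling`` variant is the observed CTI of the sapling band at each
    census.  Undefined CTIs are recorded as NaN.
    """
    main = trees[trees["size_class"] != "sapling"] if "size_class" in trees else trees
    per_scen = {
        scen: _cti_by_subplot(main, indices, scen) for scen in ("t1", *SCENARIOS)
    }
    per_scen["sapling_t1"] = _cti_by_subplot(trees, indices, "t1", sapling_band=True)
    per_scen["sapling_t2"] = _cti_by_subplot(trees, indices, "all", sapling_band=True)
    frame = pd.DataFrame(per_scen)
    frame.index.names = ["plot_id", "subplot_id"]
    frame = frame.reset_index()
    rows = []
    for variant in SCENARIOS:
        rows.append(
            frame[["plot_id", "subplot_id", "t1"]]
            .rename(columns={"t1": "cti_degC"})
            .assign(timepoint=1, variant=variant)
        )
        rows.append(
            frame[["plot_id", "subplot_id", variant]]
            .rename(columns={variant: "cti_degC"})
            .assign(timepoint=2, variant=variant)
        )
    for tp in (1, 2):
        rows.append(
            frame[["plot_id", "subplot_id", f"sapling_t{tp}"]]
            .rename(columns={f"sapling_t{tp}": "cti_degC"})
            .assign(timepoint=tp, variant="sapling")
        )
    out = pd.concat(rows, ignore_index=True)
    return out[["plot_id", "subplot_id", "timepoint", "variant", "cti_degC"]]


def conifer_basal_fraction(trees: pd.DataFrame, conifer_flags) -> float:
    """Fraction of baseline basal area contributed by conifer species.

    ``trees`` is a baseline community with a resolved ``dbh`` column;
    ``conifer_flags`` maps species_id -> bool.  Returns NaN for zero basal
    area.
    """
    if len(trees) == 0:
        return float("nan")
    flags = (
        conifer_flags
        if isinstance(conifer_flags, pd.Series)
        else pd.Series(conifer_flags)
    )
    ba = basal_area(trees["dbh"].to_numpy())
    total = ba.sum()
    if total <= 0:
        return float("nan")
    is_con = flags.reindex(trees["species_id"]).fillna(False).to_numpy(bool)
    return float(ba[is_con].sum() / total)


def classify_recruit_origin(
    recruit,
    baseline_saplings: pd.DataFrame,
    baseline_seedlings: pd.DataFrame,
) -> str:
    """Baseline status of one new main-class recruit.

    ``sapling`` if a conspecific sapling was recorded in the same subplot at
    baseline; else ``seedling`` if a conspecific baseline seedling tally is
    positive there; else ``not_germinated``.
    """
    pid, sid, sp = recruit["plot_id"], recruit["subplot_id"], recruit["species_id"]
    sap = baseline_saplings[
        (baseline_saplings["plot_id"] == pid)
        & (baseline_saplings["subplot_id"] == sid)
        & (baseline_saplings["species_id"] == sp)
    ]
    if len(sap) > 0:
        return "sapling"
    sed = baseline_seedlings[
        (baseline_seedlings["plot_id"] == pid)
        & (baseline_seedlings["subplot_id"] == sid)
        & (baseline_seedlings["species_id"] == sp)
    ]
    if len(sed) > 0 and sed["count"].sum() > 0:
        return "seedling"
    return "not_germinated"


def classify_recruit_origins(trees: pd.DataFrame, seedlings: pd.DataFrame) -> pd.DataFrame:
    """Origin classification for every main-class recruit in a tree table."""
    recruits = trees[(trees["fate"] == "recruit") & (trees["size_class"] == "main")]
    baseline_saps = trees[
        (trees["size_class"] == "sapling") & (trees["fate"].isin(["survivor", "died"]))
    ][["plot_id", "subplot_id", "species_id"]]
    out = []
    for _, row in recruits.iterrows():
        out.append(
            {
                "tree_id": row["tree_id"],
                "plot_id": row["plot_id"],
                "subplot_id": row["subplot_id"],
                "species_id": row["species_id"],
                "origin": classify_recruit_origin(row, baseline_saps, seedlings),
            }
        )
    return pd.DataFrame(
        out, columns=["tree_id", "plot_id", "subplot_id", "species_id", "origin"]
    )


__all__ = [
    "SCENARIOS",
    "FATES",
    "MissingSpeciesIndexError",
    "DecompositionResult",
    "basal_area",
    "census_view",
    "filter_census_trees",
    "community_temperature_index",
    "counterfactual_t2",
    "decompose",
    "decompose_subplots",
    "sapling_cti",
    "cti_table",
    "conifer_basal_fraction",
    "classify_recruit_origin",
    "classify_recruit_origins",
]
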