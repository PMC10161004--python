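"""End-to-end pipeline: simulate -> niches -> CTI -> covariates -> fit.

Each stage reads and writes plain CSV artifacts in the run directory so any
stage can be re-run from disk; a JSON manifest records configuration hash,
stage timings, row counts and dropped-observation counts.  The CSV column
names and units are fixed:

* ``landscape.csv`` — plot/subplot geometry, topography, baseline climate and
  its changes, fire/insect flags (one row per subplot).
* ``species.csv`` — true species niches (ground truth of the simulation).
* ``trees.csv`` — one row per tree: ``tree_id, plot_id, subplot_id,
  species_id, dbh_t1_cm, dbh_t2_cm, dist_m, fate, size_class`` (missing DBH
  is an empty field).
* ``seedlings.csv`` — baseline conspecific seedling tallies.
* ``occurrences.csv`` — species occurrence MAT records (degC).
* ``climate.csv`` — per-plot annual MAT/precip and monthly PET/AET.
* ``species_indices.csv`` — ``species_id, method, value_degC``.
* ``cti.csv`` — ``plot_id, subplot_id, timepoint, variant, cti_degC``.
* ``decomposition.csv`` — per-subplot CTI change components.
* ``covariates.csv`` — standardized predictors ``x2``..``x11``.
* ``effects.csv`` / ``effects.json`` — posterior summaries per variant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, covariates as cov, model, niches, synthetic
from .synthetic import SimulationConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class NicheSettings:
    method: str = "modeled_mean"  # default index used downstream
    smoothness: int = niches.DEFAULT_DF
    grid_step: float = niches.DEFAULT_GRID_STEP
    n_occurrences: int = 500
    n_background: int = 2000


@dataclass(frozen=True)
class ModelSettings:
    coding_scheme: str = "weighted_effect"
    inference: str = "empirical_bayes"
    variants: tuple[str, ...] = model.VARIANTS
    matern_nu: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    outdir: Path = Path("forestcti_run")
    seed: int = 0
    census_year: int = 2005
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    niche: NicheSettings = field(default_factory=NicheSettings)
    model: ModelSettings = field(default_factory=ModelSettings)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimulationConfig(**d.pop("simulation", {}))
        nic = NicheSettings(**d.pop("niche", {}))
        mset = d.pop("model", {})
        if "variants" in mset:
            mset["variants"] = tuple(mset["variants"])
        mod = ModelSettings(**mset)
        if "outdir" in d:
            d["outdir"] = Path(d["outdir"])
        cfg = cls(simulation=sim, niche=nic, model=mod, **d)
        if cfg.seed != cfg.simulation.seed:
            cfg = dataclasses.replace(
                cfg, simulation=sim.replace(seed=cfg.seed)
            )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["model"]["variants"] = list(self.model.variants)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"required pipeline artifact missing: {path}")
    return pd.read_csv(path)


class Manifest:
    """Accumulates per-stage accounting; written atomically at run end."""

    def __init__(self, config: RunConfig):
        self.data = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "stages": {},
            "headline": {},
            "complete": False,
        }

    def record(self, stage: str, seconds: float, rows_in: int, rows_out: int,
               dropped: int = 0, **extra) -> None:
        self.data["stages"][stage] = {
            "seconds": round(seconds, 3),
            "rows_in": int(rows_in),
            "rows_out": int(rows_out),
            "dropped": int(dropped),
            **extra,
        }

    def write(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        tmp = outdir / "run_manifest.json.tmp"
        with open(tmp, "w") as fh:
            json.dump(self.data, fh, indent=2, default=float)
        os.replace(tmp, outdir / "run_manifest.json")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> dict[str, pd.DataFrame]:
    sim = config.simulation
    landscape = synthetic.generate_landscape(sim)
    species = synthetic.generate_species_pool(sim)
    trees, seedlings = synthetic.generate_tree_censuses(landscape, species, sim)
    grid = np.arange(
        sim.mat_min - 2.0, sim.mat_min + sim.mat_gradient + 2.0 + 1e-9, 0.1
    )
    occurrences = synthetic.generate_occurrences(
        species, grid, config.niche.n_occurrences, seed=sim.seed
    )
    climate = synthetic.generate_climate_series(landscape, config.census_year)
    out = config.outdir
    _write_csv(landscape, out / "landscape.csv")
    _write_csv(species, out / "species.csv")
    _write_csv(trees, out / "trees.csv")
    _write_csv(seedlings, out / "seedlings.csv")
    _write_csv(occurrences, out / "occurrences.csv")
    _write_csv(climate, out / "climate.csv")
    return {
        "landscape": landscape,
        "species": species,
        "trees": trees,
        "seedlings": seedlings,
        "occurrences": occurrences,
        "climate": climate,
    }


def stage_niches(config: RunConfig) -> pd.DataFrame:
    out = config.outdir
    occurrences = _read_csv(out / "occurrences.csv")
    sim = config.simulation
    background = np.linspace(
        sim.mat_min - 2.0,
        sim.mat_min + sim.mat_gradient + 2.0,
        config.niche.n_background,
    )
    indices = niches.estimate_indices(
        occurrences,
        background,
        smoothness=config.niche.smoothness,
        grid_step=config.niche.grid_step,
    )
    _write_csv(indices, out / "species_indices.csv")
    return indices


def _index_series(config: RunConfig) -> pd.Series:
    indices = _read_csv(config.outdir / "species_indices.csv")
    sel = indices[indices["method"] == config.niche.method]
    if len(sel) == 0:
        raise ValueError(f"no species indices for method {config.niche.method!r}")
    return sel.set_index("species_id")["value_degC"]


def stage_cti(config: RunConfig) -> pd.DataFrame:
    out = config.outdir
    trees = _read_csv(out / "trees.csv")
    idx = _index_series(config)
    table = community.cti_table(trees, idx)
    decomp = community.decompose_subplots(trees, idx)
    _write_csv(table, out / "cti.csv")
    _write_csv(decomp, out / "decomposition.csv")
    return table


def stage_covariates(config: RunConfig) -> pd.DataFrame:
    out = config.outdir
    landscape = _read_csv(out / "landscape.csv")
    climate = _read_csv(out / "climate.csv")
    trees = _read_csv(out / "trees.csv")
    species = _read_csv(out / "species.csv")
    t = config.census_year

    # recompute the climate predictors from the annual series rather than
    # trusting the landscape's summary columns
    pet_cols = [f"pet_m{m}" for m in range(1, 13)]
    aet_cols = [f"aet_m{m}" for m in range(1, 13)]
    clim_rows = []
    for pid, grp in climate.groupby("plot_id", sort=True):
        grp = grp.sort_values("year")
        cwd = [
            cov.annual_cwd(row[pet_cols].to_numpy(), row[aet_cols].to_numpy())
            for _, row in grp.iterrows()
        ]
        series = grp[["year", "mat", "precip"]].copy()
        series["cwd"] = cwd
        early = series[(series["year"] >= t - 19) & (series["year"] <= t - 5)]
        clim_rows.append(
            {
                "plot_id": pid,
                "baseline_mat": early["mat"].mean(),
                "baseline_precip": early["precip"].mean(),
                "baseline_cwd": early["cwd"].mean(),
                "mat_change": cov.window_climate_change(series, t, "mat"),
                "precip_change": cov.window_climate_change(series, t, "precip"),
                "cwd_change": cov.window_climate_change(series, t, "cwd"),
            }
        )
    clim = pd.DataFrame(clim_rows)
    land = landscape.drop(
        columns=[
            "baseline_mat", "baseline_precip", "baseline_cwd",
            "mat_change", "precip_change", "cwd_change",
        ]
    ).merge(clim, on="plot_id", how="inner")

    conifer_flags = species.set_index("species_id")["conifer"]
    frac_rows = []
    for (pid, sid), grp in trees.groupby(["plot_id", "subplot_id"], sort=True):
        t1 = community.filter_census_trees(community.census_view(grp, 1))
        frac_rows.append(
            {
                "plot_id": pid,
                "subplot_id": sid,
                "conifer_fraction": community.conifer_basal_fraction(
                    t1, conifer_flags
                ),
            }
        )
    frac = pd.DataFrame(frac_rows)

    table, transforms = cov.build_covariates(land, frac)
    _write_csv(table, out / "covariates.csv")
    with open(out / "covariate_transforms.json", "w") as fh:
        json.dump(
            {k: {"mean": tr.mean, "sd": tr.sd} for k, tr in transforms.items()},
            fh,
            indent=2,
        )
    return table


def stage_fit(config: RunConfig) -> dict[str, model.PosteriorSummary]:
    out = config.outdir
    cti = _read_csv(out / "cti.csv")
    covariates_tbl = _read_csv(out / "covariates.csv")
    landscape = _read_csv(out / "landscape.csv")
    coords = landscape.drop_duplicates("plot_id")[["plot_id", "x_km", "y_km"]]
    spec = model.ModelSpec(
        matern_nu=config.model.matern_nu,
        inference=config.model.inference,
        seed=config.seed,
    )
    summaries: dict[str, model.PosteriorSummary] = {}
    for variant in config.model.variants:
        design = model.build_design(
            cti, covariates_tbl, variant, config.model.coding_scheme
        )
        summaries[variant] = model.fit(design, coords, spec)
    table = model.effect_table(summaries)
    _write_csv(table, out / "effects.csv")

    payload = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "coding_scheme": config.model.coding_scheme,
        "inference": config.model.inference,
        "variants": {
            v: {
                "params": s.params.to_dict(orient="records"),
                "hyper": s.hyper.to_dict(orient="records"),
                "n_obs": s.n_obs,
                "n_plots": s.n_plots,
                "log_marginal": s.log_marginal,
                "converged": s.converged,
            }
            for v, s in summaries.items()
        },
    }
    if config.model.coding_scheme == "weighted_effect":
        payload["mean_thermophilization"] = {
            v: model.mean_thermophilization(s) for v, s in summaries.items()
        }
    with open(out / "effects.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    return summaries


def run_all(config: RunConfig) -> Manifest:
    """Run every stage in order and write the run manifest."""
    manifest = Manifest(config)
    out = config.outdir
    try:
        t0 = time.perf_counter()
        sim = stage_simulate(config)
        manifest.record(
            "simulate", time.perf_counter() - t0,
            rows_in=0, rows_out=len(sim["trees"]),
            n_subplots=len(sim["landscape"]), n_species=len(sim["species"]),
        )

        t0 = time.perf_counter()
        indices = stage_niches(config)
        manifest.record(
            "niches", time.perf_counter() - t0,
            rows_in=len(sim["occurrences"]), rows_out=len(indices),
        )

        t0 = time.perf_counter()
        cti = stage_cti(config)
        n_undef = int(cti["cti_degC"].isna().sum())
        manifest.record(
            "cti", time.perf_counter() - t0,
            rows_in=len(sim["trees"]), rows_out=len(cti),
            dropped=n_undef, dropped_reason="undefined CTI (zero basal area)",
        )

        t0 = time.perf_counter()
        covs = stage_covariates(config)
        manifest.record(
            "covariates", time.perf_counter() - t0,
            rows_in=len(sim["landscape"]), rows_out=len(covs),
            dropped=len(sim["landscape"]) - len(covs),
            dropped_reason="undefined baseline conifer fraction",
        )

        t0 = time.perf_counter()
        summaries = stage_fit(config)
        manifest.record(
            "fit", time.perf_counter() - t0,
            rows_in=len(cti), rows_out=sum(s.n_obs for s in summaries.values()),
            dropped=len(cti) - sum(s.n_obs for s in summaries.values()),
            dropped_reason="undefined CTI or missing covariates",
        )
        if config.model.coding_scheme == "weighted_effect":
            manifest.data["headline"] = {
                v: model.mean_thermophilization(s) for v, s in summaries.items()
            }
        manifest.data["complete"] = True
    finally:
        manifest.write(out)
    return manifest


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Schema/invariant checks; returns a machine-readable violation table.

    Checks the tree fate partition (survivor/died/recruit with the right DBH
    fields present), DBH size-class bands, and landscape ranges
    (slope in [0, 90], aspect in [0, 360), probabilities of nothing — flags
    are booleans).  An empty result means no violations.
    """
    rows: list[dict] = []

    def flag(table, ident, rule, detail):
        rows.append({"table": table, "id": ident, "rule": rule, "detail": detail})

    trees = tables.get("trees")
    if trees is not None:
        for r in trees.itertuples(index=False):
            has1 = np.isfinite(r.dbh_t1_cm)
            has2 = np.isfinite(r.dbh_t2_cm)
            if r.fate == "recruit" and has1:
                flag("trees", r.tree_id, "fate_partition",
                     "recruit has a first-census DBH")
            elif r.fate == "died" and has2:
                flag("trees", r.tree_id, "fate_partition",
                     "died tree has a second-census DBH")
            elif r.fate == "survivor" and not (has1 and has2):
                flag("trees", r.tree_id, "fate_partition",
                     "survivor missing a DBH measurement")
            elif r.fate not in community.FATES:
                flag("trees", r.tree_id, "fate_partition", f"unknown fate {r.fate!r}")
            for dbh, has in ((r.dbh_t1_cm, has1), (r.dbh_t2_cm, has2)):
                if not has:
                    continue
                if r.size_class == "main" and dbh < synthetic.MAIN_DBH_CM:
                    flag("trees", r.tree_id, "size_class",
                         f"main-class DBH {dbh:.2f} below 12.7 cm")
                elif r.size_class == "sapling" and not (
                    synthetic.SAPLING_MIN_DBH_CM <= dbh < synthetic.MAIN_DBH_CM
                ):
                    flag("trees", r.tree_id, "size_class",
                         f"sapling DBH {dbh:.2f} outside [2.5, 12.7)")
            if r.dist_m < 0:
                flag("trees", r.tree_id, "distance", "negative distance")

    landscape = tables.get("landscape")
    if landscape is not None:
        for r in landscape.itertuples(index=False):
            ident = f"{r.plot_id}/{r.subplot_id}"
            if not 0 <= r.slope <= 90:
                flag("landscape", ident, "range", f"slope {r.slope} outside [0, 90]")
            if not 0 <= r.aspect < 360:
                flag("landscape", ident, "range", f"aspect {r.aspect} outside [0, 360)")

    cti = tables.get("cti")
    if cti is not None:
        counts = cti.groupby(["plot_id", "subplot_id", "variant"]).size()
        for key, n in counts.items():
            if n != 2:
                flag("cti", "/".join(map(str, key)), "paired_rows",
                     f"{n} rows instead of 2")

    return pd.DataFrame(rows, columns=["table", "id", "rule", "detail"])


__all__ = [
    "RunConfig",
    "NicheSettings",
    "ModelSettings",
    "Manifest",
    "stage_simulate",
    "stage_niches",
    "stage_cti",
    "stage_covariates",
    "stage_fit",
    "run_all",
    "validate_inputs",
]
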