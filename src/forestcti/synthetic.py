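"""Synthetic repeat-census forest inventory generator.

Emulates the structure of a national forest-inventory plot network: plots of
four circular subplots (radius 7.32 m), a 12.7 cm diameter-at-breast-height
(DBH) census threshold with a 2.5-12.7 cm sapling class, species with distinct
temperature niches, mortality biased toward cool-niche species under warming,
spatially autocorrelated plot effects, binary fire/insect damage, and
warming/drying covariate changes between two censuses 10 years apart.

Every downstream stage of the pipeline (niche estimation, community
temperature indices, demographic decomposition, covariate construction, and
the hierarchical spatial regression) is testable against this generator with
controllable effect sizes.  All randomness flows from ``SimulationConfig.seed``
through per-stage ``numpy`` generators, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUBPLOT_RADIUS_M = 7.32
MAIN_DBH_CM = 12.7
SAPLING_MIN_DBH_CM = 2.5


class ConfigurationError(ValueError):
    """Raised when a simulation config field is out of its valid range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic landscape, species pool, and censuses.

    Effect-size parameters (``mortality_niche_bias``, ``growth_niche_bias``,
    the fire/insect odds multipliers) default to zero / neutral so the default
    configuration is a *null* landscape; planted-mechanism runs switch them on
    explicitly.  Demographic rates default to the per-subplot means typical of
    western-US inventory data (about 5.6 survivors, 1.1 deaths and 0.63
    recruits per subplot over a 10-y interval).
    """

    n_plots: int = 100
    n_subplots_per_plot: int = 4
    n_species: int = 30
    domain_extent_km: float = 500.0
    #: total range of baseline mean annual temperature across the domain (degC)
    mat_gradient: float = 12.0
    mat_min: float = 4.0
    warming_mean: float = 0.32  # degC over the 10-y census interval
    warming_sd: float = 0.15
    precip_baseline_mean: float = 800.0  # mm/yr
    precip_baseline_sd: float = 200.0
    precip_change_mean: float = -20.0
    precip_change_sd: float = 30.0
    cwd_baseline_mean: float = 300.0  # mm/yr
    cwd_baseline_sd: float = 80.0
    cwd_change_mean: float = 15.0
    cwd_change_sd: float = 20.0
    #: additional log-odds of death per degC the species optimum falls below
    #: the subplot's second-census temperature
    mortality_niche_bias: float = 0.0
    #: log growth-increment multiplier per degC the optimum exceeds the
    #: subplot's second-census temperature
    growth_niche_bias: float = 0.0
    recruit_rate: float = 0.63  # main-class recruits per subplot
    trees_per_subplot: float = 7.0  # Poisson mean of baseline main-class count
    saplings_per_subplot: float = 2.0
    sapling_recruit_rate: float = 0.8
    base_mortality: float = 0.16  # 10-y per-tree death probability at the optimum
    fire_prob: float = 0.05
    insect_prob: float = 0.08
    #: multiplicative odds-of-death factors for damaged subplots
    fire_mort_odds: float = 1.0
    insect_mort_odds: float = 1.0
    #: multiplier applied to mortality_niche_bias in insect-damaged subplots,
    #: producing the elevated cool-species mortality seen under insect attack
    insect_bias_multiplier: float = 1.0
    niche_breadth: float = 3.0  # SD of the Gaussian occurrence response (degC)
    niche_breadth_sd: float = 0.5
    conifer_fraction: float = 0.5
    #: temperature offset per unit of topographic heat load used in community
    #: assembly (warm-adapted species favoured on high heat-load subplots)
    heatload_temp_coef: float = 2.0
    #: fractions of main-class recruits present at baseline as saplings /
    #: only as conspecific seedlings / not yet germinated
    recruit_sapling_frac: float = 0.87
    recruit_seedling_frac: float = 0.09
    spatial_sd: float = 0.3  # degC, plot-level Matern field on assembly temperature
    spatial_range_km: float = 50.0
    spatial_nu: float = 1.0
    subplot_sd: float = 0.2  # degC, iid subplot offset on assembly temperature
    residual_sd: float = 0.3  # degC, per-census assembly temperature jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 1:
            raise ConfigurationError("n_plots must be >= 1")
        if self.n_subplots_per_plot < 1:
            raise ConfigurationError("n_subplots_per_plot must be >= 1")
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")
        for name in (
            "warming_sd", "precip_change_sd", "cwd_change_sd", "precip_baseline_sd",
            "cwd_baseline_sd", "spatial_sd", "subplot_sd", "residual_sd",
            "niche_breadth_sd", "recruit_rate", "trees_per_subplot",
            "saplings_per_subplot", "sapling_recruit_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("fire_prob", "insect_prob", "base_mortality", "conifer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        if self.recruit_sapling_frac + self.recruit_seedling_frac > 1.0 + 1e-12:
            raise ConfigurationError(
                "recruit_sapling_frac + recruit_seedling_frac must be <= 1"
            )
        if self.niche_breadth <= 0:
            raise ConfigurationError("niche_breadth must be > 0")
        if self.domain_extent_km <= 0:
            raise ConfigurationError("domain_extent_km must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def generate_landscape(config: SimulationConfig) -> pd.DataFrame:
    """Plot/subplot grid with coordinates, topography, climate and disturbance.

    Baseline mean annual temperature declines smoothly from south (y=0) to
    north, with a gentle east-west undulation; climate *changes* over the
    census interval are drawn from the configured normals at plot level.
    Slope/aspect and fire/insect flags vary at subplot level; coordinates are
    plot-level (the four subplots of a plot share one location at this scale).
    """
    config.validate()
    rng = _rng(config, 0)
    P, S = config.n_plots, config.n_subplots_per_plot
    ext = config.domain_extent_km

    x = rng.uniform(0.0, ext, size=P)
    y = rng.uniform(0.0, ext, size=P)
    latitude = 38.0 + 8.0 * y / ext  # planar domain pinned to mid-latitudes
    # smooth macroclimate: linear N-S gradient plus low-frequency undulation
    baseline_mat = (
        config.mat_min
        + config.mat_gradient * (1.0 - y / ext)
        + 0.08 * config.mat_gradient * np.sin(2.0 * np.pi * x / ext)
    )
    baseline_precip = np.maximum(
        rng.normal(config.precip_baseline_mean, config.precip_baseline_sd, size=P), 50.0
    )
    baseline_cwd = np.maximum(
        rng.normal(config.cwd_baseline_mean, config.cwd_baseline_sd, size=P), 0.0
    )
    mat_change = rng.normal(config.warming_mean, config.warming_sd, size=P)
    precip_change = rng.normal(config.precip_change_mean, config.precip_change_sd, size=P)
    cwd_change = rng.normal(config.cwd_change_mean, config.cwd_change_sd, size=P)

    n = P * S
    plot_idx = np.repeat(np.arange(P), S)
    slope = rng.uniform(0.0, 45.0, size=n)
    aspect = rng.uniform(0.0, 360.0, size=n)
    fire = rng.random(n) < config.fire_prob
    insect = rng.random(n) < config.insect_prob

    return pd.DataFrame(
        {
            "plot_id": plot_idx,
            "subplot_id": np.tile(np.arange(S), P),
            "x_km": x[plot_idx],
            "y_km": y[plot_idx],
            "latitude": latitude[plot_idx],
            "slope": slope,
            "aspect": aspect,
            "baseline_mat": baseline_mat[plot_idx],
            "baseline_precip": baseline_precip[plot_idx],
            "baseline_cwd": baseline_cwd[plot_idx],
            "mat_change": mat_change[plot_idx],
            "precip_change": precip_change[plot_idx],
            "cwd_change": cwd_change[plot_idx],
            "fire": fire,
            "insect": insect,
        }
    )


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def generate_species_pool(config: SimulationConfig) -> pd.DataFrame:
    """Species with true thermal optima spread across the MAT gradient.

    The optima are the ground truth against which the occurrence-based niche
    estimators are validated downstream.
    """
    config.validate()
    rng = _rng(config, 1)
    K = config.n_species
    lo, hi = config.mat_min, config.mat_min + config.mat_gradient
    # evenly spaced with jitter: guarantees coverage of the gradient
    base = np.linspace(lo, hi, K)
    jitter = rng.uniform(-0.4, 0.4, size=K) * (hi - lo) / max(K - 1, 1)
    optima = np.clip(base + jitter, lo, hi)
    breadth = np.maximum(
        rng.normal(config.niche_breadth, config.niche_breadth_sd, size=K), 0.5
    )
    conifer = rng.random(K) < config.conifer_fraction
    return pd.DataFrame(
        {
            "species_id": np.arange(K),
            "true_optimum": optima,
            "niche_breadth": breadth,
            "conifer": conifer,
        }
    )


# ---------------------------------------------------------------------------
# tree censuses
# ---------------------------------------------------------------------------

def _matern_field(coords_km: np.ndarray, sd: float, range_km: float, nu: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw one realisation of a Matern Gaussian field at plot locations."""
    if sd <= 0:
        return np.zeros(len(coords_km))
    from .model import matern_cov  # shared kernel; avoids a second definition

    d = np.sqrt(((coords_km[:, None, :] - coords_km[None, :, :]) ** 2).sum(-1))
    cov = matern_cov(d, sigma_u=sd, rho=range_km, nu=nu)
    cov[np.diag_indices_from(cov)] += 1e-10 * sd**2
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(coords_km))


def _assembly_weights(temp: float, optima: np.ndarray, breadth: np.ndarray) -> np.ndarray:
    logw = -((temp - optima) ** 2) / (2.0 * breadth**2)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def generate_tree_censuses(
    landscape: pd.DataFrame,
    species_pool: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate two tree censuses 10 years apart.

    Returns ``(trees, seedlings)``:

    * ``trees`` — one row per individual with columns ``tree_id, plot_id,
      subplot_id, species_id, dbh_t1_cm, dbh_t2_cm, dist_m, fate, size_class``.
      Fates partition each census: every baseline tree is ``survivor`` or
      ``died``; ``recruit`` rows have no baseline DBH.
    * ``seedlings`` — baseline conspecific seedling tallies
      (``plot_id, subplot_id, species_id, count``) used for recruit-origin
      classification.

    Mechanics: baseline communities are multinomial draws over a Gaussian
    niche response centred on the subplot's assembly temperature (macro MAT
    plus a heat-load offset, a spatially autocorrelated plot effect, a subplot
    offset and census jitter); death odds increase by ``mortality_niche_bias``
    per degC the species optimum falls below the warmed temperature, with
    multiplicative fire/insect odds; survivor growth increments are lognormal,
    scaled by ``growth_niche_bias``; recruits enter just above the 12.7 cm
    threshold with species drawn under the warmed temperature.
    """
    config.validate()
    if len(landscape) == 0:
        raise ValueError("landscape is empty")
    rng = _rng(config, 2)

    from .covariates import heat_load  # subplot heat-load offset for assembly

    optima = species_pool["true_optimum"].to_numpy()
    breadth = species_pool["niche_breadth"].to_numpy()
    sp_ids = species_pool["species_id"].to_numpy()
    K = len(sp_ids)

    plots = landscape.drop_duplicates("plot_id").sort_values("plot_id")
    coords = plots[["x_km", "y_km"]].to_numpy()
    u = _matern_field(coords, config.spatial_sd, config.spatial_range_km,
                      config.spatial_nu, rng)
    u_by_plot = dict(zip(plots["plot_id"], u))

    hl = heat_load(
        landscape["latitude"].to_numpy(),
        landscape["slope"].to_numpy(),
        landscape["aspect"].to_numpy(),
    )
    hl_offset = config.heatload_temp_coef * (hl - float(np.mean(hl)))

    rows: list[dict] = []
    seed_rows: list[dict] = []
    tree_id = 0

    def new_tree(**kw) -> None:
        nonlocal tree_id
        rows.append({"tree_id": tree_id, **kw})
        tree_id += 1

    for r, sub in enumerate(landscape.itertuples(index=False)):
        t_base = (
            sub.baseline_mat
            + hl_offset[r]
            + u_by_plot[sub.plot_id]
            + rng.normal(0.0, config.subplot_sd)
        )
        t1 = t_base + rng.normal(0.0, config.residual_sd)
        t2 = t_base + sub.mat_change + rng.normal(0.0, config.residual_sd)

        w1 = _assembly_weights(t1, optima, breadth)
        w2 = _assembly_weights(t2, optima, breadth)

        bias = config.mortality_niche_bias * (
            config.insect_bias_multiplier if sub.insect else 1.0
        )
        odds_mult = 1.0
        if sub.fire:
            odds_mult *= config.fire_mort_odds
        if sub.insect:
            odds_mult *= config.insect_mort_odds
        base_logit = np.log(config.base_mortality / (1.0 - config.base_mortality))

        def death_prob(opt: float) -> float:
            deficit = max(0.0, t2 - opt)  # degC below the warmed temperature
            logit = base_logit + bias * deficit + np.log(odds_mult)
            return 1.0 / (1.0 + np.exp(-logit))

        def grow(dbh: float, opt: float, cap: float | None = None) -> float:
            incr = rng.lognormal(mean=0.2, sigma=0.5)
            incr *= np.exp(config.growth_niche_bias * (opt - t2))
            out = dbh + incr
            return min(out, cap) if cap is not None else out

        common = {"plot_id": sub.plot_id, "subplot_id": sub.subplot_id}

        # --- baseline main-class trees -------------------------------------
        n_main = rng.poisson(config.trees_per_subplot)
        if n_main > 0:
            species = rng.choice(K, size=n_main, p=w1)
            dbh1 = MAIN_DBH_CM + rng.lognormal(mean=1.8, sigma=0.7, size=n_main)
            dist = SUBPLOT_RADIUS_M * np.sqrt(rng.random(n_main))
            for s_i, d1, dm in zip(species, dbh1, dist):
                opt = optima[s_i]
                if rng.random() < death_prob(opt):
                    new_tree(**common, species_id=sp_ids[s_i], dbh_t1_cm=d1,
                             dbh_t2_cm=np.nan, dist_m=dm, fate="died",
                             size_class="main")
                else:
                    new_tree(**common, species_id=sp_ids[s_i], dbh_t1_cm=d1,
                             dbh_t2_cm=grow(d1, opt), dist_m=dm,
                             fate="survivor", size_class="main")

        # --- baseline saplings (2.5 <= DBH < 12.7 cm microplot class) -------
        n_sap = rng.poisson(config.saplings_per_subplot)
        sap_species: list[int] = []
        if n_sap > 0:
            species = rng.choice(K, size=n_sap, p=w1)
            dbh1 = rng.uniform(SAPLING_MIN_DBH_CM, MAIN_DBH_CM, size=n_sap)
            dist = SUBPLOT_RADIUS_M * np.sqrt(rng.random(n_sap))
            for s_i, d1, dm in zip(species, dbh1, dist):
                opt = optima[s_i]
                sap_species.append(int(sp_ids[s_i]))
                if rng.random() < death_prob(opt):
                    new_tree(**common, species_id=sp_ids[s_i], dbh_t1_cm=d1,
                             dbh_t2_cm=np.nan, dist_m=dm, fate="died",
                             size_class="sapling")
                else:
                    # survivors stay within the sapling band; threshold
                    # crossers are represented by the recruit records below
                    new_tree(**common, species_id=sp_ids[s_i], dbh_t1_cm=d1,
                             dbh_t2_cm=grow(d1, opt, cap=MAIN_DBH_CM - 0.01),
                             dist_m=dm, fate="survivor", size_class="sapling")

        # --- baseline seedling tallies -------------------------------------
        n_seed_sp = rng.poisson(1.5)
        seed_species = (
            rng.choice(K, size=n_seed_sp, p=w1) if n_seed_sp > 0 else np.array([], int)
        )
        seed_counts: dict[int, int] = {}
        for s_i in seed_species:
            seed_counts[int(sp_ids[s_i])] = seed_counts.get(int(sp_ids[s_i]), 0) + int(
                1 + rng.poisson(2.0)
            )

        # --- recruits into the main class ----------------------------------
        n_rec = rng.poisson(config.recruit_rate)
        if n_rec > 0:
            species = rng.choice(K, size=n_rec, p=w2)
            for s_i in species:
                sid = int(sp_ids[s_i])
                d2 = MAIN_DBH_CM + rng.lognormal(mean=-1.0, sigma=0.6)
                dm = SUBPLOT_RADIUS_M * np.sqrt(rng.random())
                new_tree(**common, species_id=sid, dbh_t1_cm=np.nan,
                         dbh_t2_cm=d2, dist_m=dm, fate="recruit",
                         size_class="main")
                # provenance: most recruits were baseline saplings, some only
                # conspecific seedlings, a few not yet germinated
                o = rng.random()
                if o < config.recruit_sapling_frac:
                    if sid not in sap_species:
                        d1 = rng.uniform(8.0, MAIN_DBH_CM)
                        new_tree(**common, species_id=sid, dbh_t1_cm=d1,
                                 dbh_t2_cm=min(d1 + rng.lognormal(0.2, 0.5),
                                               MAIN_DBH_CM - 0.01),
                                 dist_m=SUBPLOT_RADIUS_M * np.sqrt(rng.random()),
                                 fate="survivor", size_class="sapling")
                        sap_species.append(sid)
                elif o < config.recruit_sapling_frac + config.recruit_seedling_frac:
                    if sid not in seed_counts:
                        seed_counts[sid] = int(1 + rng.poisson(1.0))

        # --- sapling-class recruits ----------------------------------------
        n_srec = rng.poisson(config.sapling_recruit_rate)
        if n_srec > 0:
            species = rng.choice(K, size=n_srec, p=w2)
            for s_i in species:
                new_tree(**common, species_id=int(sp_ids[s_i]), dbh_t1_cm=np.nan,
                         dbh_t2_cm=rng.uniform(SAPLING_MIN_DBH_CM, 5.0),
                         dist_m=SUBPLOT_RADIUS_M * np.sqrt(rng.random()),
                         fate="recruit", size_class="sapling")

        for sid, cnt in sorted(seed_counts.items()):
            seed_rows.append({**common, "species_id": sid, "count": cnt})

    trees = pd.DataFrame(
        rows,
        columns=["tree_id", "plot_id", "subplot_id", "species_id", "dbh_t1_cm",
                 "dbh_t2_cm", "dist_m", "fate", "size_class"],
    )
    seedlings = pd.DataFrame(
        seed_rows, columns=["plot_id", "subplot_id", "species_id", "count"]
    )
    return trees, seedlings


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def generate_occurrences(
    species_pool: pd.DataFrame,
    mat_grid: np.ndarray,
    n_per_species: int,
    seed: int,
) -> pd.DataFrame:
    """Species occurrence MAT values: Gaussian response truncated to the grid.

    Each species' occurrence density along the MAT axis is proportional to a
    Gaussian centred on its true optimum with SD equal to its niche breadth,
    truncated to the climatic range spanned by ``mat_grid``.
    """
    mat_grid = np.asarray(mat_grid, dtype=float)
    if mat_grid.size == 0:
        raise ValueError("mat_grid is empty")
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    lo, hi = float(mat_grid.min()), float(mat_grid.max())
    rng = np.random.default_rng([int(seed) % (2**31), 3])
    frames = []
    for row in species_pool.itertuples(index=False):
        a = (lo - row.true_optimum) / row.niche_breadth
        b = (hi - row.true_optimum) / row.niche_breadth
        draws = stats.truncnorm.rvs(
            a, b, loc=row.true_optimum, scale=row.niche_breadth,
            size=n_per_species, random_state=rng,
        )
        frames.append(pd.DataFrame({"species_id": row.species_id, "mat": draws}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# annual climate series consistent with the landscape's change columns
# ---------------------------------------------------------------------------

def generate_climate_series(
    landscape: pd.DataFrame,
    census_year: int = 2005,
    baseline_aet: float = 40.0,
) -> pd.DataFrame:
    """Per-plot annual climate covering the two 15-y averaging windows.

    The series steps from the baseline value to baseline + change at year
    ``census_year - 4`` (the start of the second window), so the 15-y
    sliding-window change computed downstream reproduces the landscape's
    ``*_change`` columns exactly.  Monthly PET/AET are constructed so the
    annual climatic water deficit (sum of positive monthly PET-AET) equals
    the landscape's annual CWD.
    """
    plots = landscape.drop_duplicates("plot_id").sort_values("plot_id")
    years = np.arange(census_year - 19, census_year + 11)
    recs = []
    for p in plots.itertuples(index=False):
        for yr in years:
            late = yr >= census_year - 4
            mat = p.baseline_mat + (p.mat_change if late else 0.0)
            precip = p.baseline_precip + (p.precip_change if late else 0.0)
            cwd = max(p.baseline_cwd + (p.cwd_change if late else 0.0), 0.0)
            rec = {"plot_id": p.plot_id, "year": int(yr), "mat": mat,
                   "precip": precip}
            for m in range(1, 13):
                rec[f"aet_m{m}"] = baseline_aet
                rec[f"pet_m{m}"] = baseline_aet + cwd / 12.0
            recs.append(rec)
    return pd.DataFrame(recs)


__all__ = [
    "SUBPLOT_RADIUS_M",
    "MAIN_DBH_CM",
    "SAPLING_MIN_DBH_CM",
    "ConfigurationError",
    "SimulationConfig",
    "generate_landscape",
    "generate_species_pool",
    "generate_tree_censuses",
    "generate_occurrences",
    "generate_climate_series",
]
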