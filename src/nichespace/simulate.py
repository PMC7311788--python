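"""Synthetic four-biome woody communities with known latent structure.

The field data behind the original analysis are available only on request,
so the pipeline is exercised on simulated communities that reproduce its
statistical assumptions: 11 log-scale traits generated from a block latent
factor model with two latent factors per niche dimension,

    log10(trait) = mu_t + sigma_t * (w_t . z + noise_sd * eps),

where ``z`` is the species' latent position (6 values, 2 per dimension),
``w_t`` loads a trait only on its own dimension's factors, and biome
membership shifts the latent means.  The default biome shifts follow the
published latitudinal gradient: tropical species have low specific leaf
area, high stem density, large leaves and large stature; the cold-temperate
end is the reverse (acquisitive strategy), with a milder gradient in
phenological duration.  Default sizes are 90/70/49/6 species for
TF/SF/WF/CF (215 site-species rows, eight species shared between adjacent
sites), drawn from pools of 116 genera nested in 55 abstract families
(F01..F55); family labels are independent of niche position, which is what
lets distantly related species converge.

Out-of-range draws (e.g. a leaf dry-matter content above 1 g/g) are
resampled, never clipped, so the factor model stays exact on the log scale.
Ground truth (latent positions, the continuous log-trait matrix, planted
cluster membership) is stored alongside the observables for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .traits import (
    BIOMES,
    TRAIT_NAMES,
    PhenologyWindow,
    SpeciesRecord,
    TraitTable,
    julian_day,
)

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SyntheticCommunity",
    "generate_community",
    "generate_phenology",
    "windows_from_traits",
    "plant_convergent_cluster",
    "LATENT_NAMES",
]

#: Latent factor names: two per dimension.  The first factor of each
#: dimension is the one its dominant traits load on (economics, stature,
#: phenological duration); the second carries leaf size, stem density and
#: phenological timing.
LATENT_NAMES = (
    "leaf_economics", "leaf_size",
    "plant_size", "stem_density",
    "phenology_duration", "phenology_time",
)

#: Primary latent factor per dimension (the gradient its PC1 should recover).
PRIMARY_LATENT = {
    "leaf_economy": "leaf_economics",
    "mechanical_support": "plant_size",
    "reproductive_phenology": "phenology_duration",
}

_DIM_LATENTS = {
    "leaf_economy": ("leaf_economics", "leaf_size"),
    "mechanical_support": ("plant_size", "stem_density"),
    "reproductive_phenology": ("phenology_duration", "phenology_time"),
}


@dataclass(frozen=True)
class TraitSpec:
    """Marginal model of one trait on the log10 scale.

    ``loadings`` weight the two latent factors of the trait's dimension;
    ``mu``/``sigma`` are the log10 location and scale; ``lo``/``hi`` bound
    the natural-scale values (violations are resampled).
    """

    dimension: str
    loadings: tuple[float, float]
    mu: float
    sigma: float
    lo: float
    hi: float
    #: per-trait multiplier on the global noise sd (database-derived
    #: phenological timing is noisier than measured traits)
    noise_mult: float = 1.0


def _default_trait_model() -> dict[str, TraitSpec]:
    log10 = math.log10
    return {
        # leaf economy: economics factor drives SLA(+)/LDMC(-)/LNC(+),
        # leaf-size factor drives LA
        "LA": TraitSpec("leaf_economy", (0.0, 0.85), log10(40), 0.35, 0.5, 2000),
        "LDMC": TraitSpec("leaf_economy", (-0.65, 0.10), log10(0.40), 0.10, 0.05, 1.0),
        "SLA": TraitSpec("leaf_economy", (0.95, -0.10), log10(125), 0.22, 5, 1000),
        "LNC": TraitSpec("leaf_economy", (0.60, 0.00), log10(20), 0.12, 1, 60),
        # mechanical support: stature factor drives MPH/MDBH, density factor STD
        "STD": TraitSpec("mechanical_support", (0.15, 0.90), log10(0.57), 0.055, 0.1, 1.4),
        "MPH": TraitSpec("mechanical_support", (0.95, -0.10), log10(11), 0.28, 0.3, 90),
        "MDBH": TraitSpec("mechanical_support", (0.95, 0.10), log10(14), 0.32, 1, 300),
        # phenology: duration factor drives FLD/FRD, timing factor FLT/FRT
        "FLT": TraitSpec("reproductive_phenology", (0.10, 0.65), log10(160), 0.10, 15, 365,
                         noise_mult=2.2),
        "FRT": TraitSpec("reproductive_phenology", (0.10, 0.40), log10(230), 0.08, 15, 365,
                         noise_mult=2.2),
        "FLD": TraitSpec("reproductive_phenology", (0.96, -0.08), log10(75), 0.22, 10, 364),
        "FRD": TraitSpec("reproductive_phenology", (0.94, 0.08), log10(80), 0.22, 10, 364),
    }


def _default_shifts() -> pd.DataFrame:
    """Per-biome latent mean shifts (rows TF..CF, columns latent factors).

    Two distinct monotone latitudinal profiles are used, both spanning
    roughly two within-biome sd: leaf economics and stem density change most
    sharply between the tropical and subtropical sites, while leaf size and
    stature fall off toward the temperate sites and collapse in the
    cold-temperate forest.  Economics increases poleward (higher SLA, the
    acquisitive end); size, density and phenological duration decrease.
    The rank-two between-biome structure puts biome signal on both pooled
    niche axes, as observed for the real communities.
    """
    econ = np.array([1.0, -0.35, -0.75, -1.2])  # sharp tropical-end change
    size = np.array([0.65, 0.35, -0.8, -2.3])     # sharp cold-end change
    data = {
        "leaf_economics": -1.0 * econ,  # TF low SLA ... CF high SLA
        "leaf_size": 1.0 * size,        # TF large leaves
        "plant_size": 1.0 * size,       # TF tall / thick
        "stem_density": 1.0 * econ,     # TF dense stems
        "phenology_duration": 0.30 * econ,
        "phenology_time": 0.0 * econ,
    }
    return pd.DataFrame(data, index=list(BIOMES))


def _default_latent_correlation() -> pd.DataFrame:
    """Within-biome correlation of the latent factors.

    Two cross-dimension couplings mirror the trait covariation the combined
    niche space hinges on: acquisitive species (high economics factor) have
    light stems (r = -0.75 with stem density), and large-leaved species are
    large-statured (r = +0.6 between leaf size and plant size).  These make
    the pooled PC1 an economics/density axis and PC2 a size axis, each
    carrying its own biome gradient.
    """
    R = pd.DataFrame(np.eye(len(LATENT_NAMES)), index=list(LATENT_NAMES),
                     columns=list(LATENT_NAMES))
    R.loc["leaf_economics", "stem_density"] = R.loc["stem_density", "leaf_economics"] = -0.75
    R.loc["leaf_size", "plant_size"] = R.loc["plant_size", "leaf_size"] = 0.6
    return R


@dataclass
class SimConfig:
    """Stated world of the generator; defaults mirror the sampled totals."""

    biome_species: dict[str, int] = field(
        default_factory=lambda: {"TF": 90, "SF": 70, "WF": 49, "CF": 6}
    )
    n_families: int = 55
    n_genera: int = 116
    n_shared_species: int = 8
    noise_sd: float = 0.3
    min_abundance: int = 21
    logseries_p: float = 0.98
    trait_model: dict[str, TraitSpec] = field(default_factory=_default_trait_model)
    biome_shifts: pd.DataFrame = field(default_factory=_default_shifts)
    latent_correlation: pd.DataFrame = field(default_factory=_default_latent_correlation)

    def validate(self) -> None:
        if set(self.trait_model) != set(TRAIT_NAMES):
            raise ValueError("trait_model must cover exactly the 11 traits")
        if any(n <= 0 for n in self.biome_species.values()):
            raise ValueError("biome species counts must be positive")
        if unknown := set(self.biome_species) - set(BIOMES):
            raise ValueError(f"unknown biomes {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.logseries_p < 1:
            raise ValueError("logseries_p must be in (0, 1)")
        if self.n_genera < self.n_families:
            raise ValueError("need at least one genus per family")
        if list(self.biome_shifts.columns) != list(LATENT_NAMES):
            raise ValueError(f"biome_shifts columns must be {list(LATENT_NAMES)}")
        R = np.asarray(self.latent_correlation, dtype=float)
        if R.shape != (len(LATENT_NAMES),) * 2 or not np.allclose(R, R.T):
            raise ValueError("latent_correlation must be a symmetric 6x6 matrix")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("latent_correlation is not positive semidefinite")
        for spec in self.trait_model.values():
            if spec.sigma <= 0 or spec.lo <= 0 or spec.hi <= spec.lo:
                raise ValueError(f"invalid TraitSpec bounds/scale: {spec}")

    @property
    def n_rows(self) -> int:
        return sum(self.biome_species.values())


@dataclass
class SyntheticCommunity:
    """Generated observables plus the ground truth that produced them."""

    records: list[SpeciesRecord]
    trait_table: TraitTable
    windows: list[PhenologyWindow]
    latents: pd.DataFrame       # (species, biome) x 6 latent factors
    log_traits: pd.DataFrame    # continuous log10 trait matrix (pre-window)
    config: SimConfig
    seed: int
    planted: dict | None = None

    @property
    def families(self) -> pd.Series:
        return pd.Series(
            {(r.species_id, r.biome): r.family for r in self.records},
            name="family",
        ).loc[self.trait_table.data.index]

    def per_biome_tables(self) -> dict[str, TraitTable]:
        return {b: self.trait_table.subset(b) for b in self.trait_table.biomes()}


def _log_traits_from_latents(
    latents: np.ndarray, config: SimConfig, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    """Log10 trait matrix for given latent positions.

    With an rng, per-trait noise is drawn and out-of-bounds cells are
    resampled (noise first, then the whole row's noise); returns the values
    and a boolean mask of rows that still violate a bound, for the caller to
    redraw at the latent level.  With ``rng=None`` the map is the
    deterministic noise-free factor model (used for planted clusters).
    """
    n = latents.shape[0]
    lat_idx = {name: i for i, name in enumerate(LATENT_NAMES)}
    out = np.empty((n, len(TRAIT_NAMES)))
    bad_rows = np.zeros(n, dtype=bool)
    for j, trait in enumerate(TRAIT_NAMES):
        spec = config.trait_model[trait]
        la, lb = _DIM_LATENTS[spec.dimension]
        signal = (
            spec.loadings[0] * latents[:, lat_idx[la]]
            + spec.loadings[1] * latents[:, lat_idx[lb]]
        )
        noise_sd = config.noise_sd * spec.noise_mult
        eps = rng.normal(size=n) if rng is not None else np.zeros(n)
        vals = spec.mu + spec.sigma * (signal + noise_sd * eps)
        lo, hi = math.log10(spec.lo), math.log10(spec.hi)
        if rng is not None and noise_sd > 0:
            for _ in range(100):
                bad = (vals < lo) | (vals > hi)
                if not bad.any():
                    break
                vals[bad] = spec.mu + spec.sigma * (
                    signal[bad] + noise_sd * rng.normal(size=int(bad.sum()))
                )
        bad_rows |= (vals < lo) | (vals > hi)
        out[:, j] = vals
    return out, bad_rows


def _sample_community_traits(
    shifts_per_row: np.ndarray, root: np.ndarray, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample latents and log traits until every row is in bounds.

    Rows with cells outside a trait's natural-scale bounds are redrawn from
    scratch (latents included) rather than clipped, so the factor model stays
    exact conditional on acceptance.
    """
    n = shifts_per_row.shape[0]
    latents = shifts_per_row + rng.normal(size=(n, len(LATENT_NAMES))) @ root.T
    logs, bad = _log_traits_from_latents(latents, config, rng)
    for _ in range(200):
        if not bad.any():
            return latents, logs
        idx = np.flatnonzero(bad)
        latents[idx] = shifts_per_row[idx] + (
            rng.normal(size=(len(idx), len(LATENT_NAMES))) @ root.T
        )
        logs[idx], bad_sub = _log_traits_from_latents(latents[idx], config, rng)
        bad = np.zeros(n, dtype=bool)
        bad[idx] = bad_sub
    raise RuntimeError(
        "could not sample traits within their bounds; shifts are too extreme "
        "for the configured trait ranges"
    )


def _month_of_day(day: int) -> int:
    for m in range(12, 0, -1):
        if day >= julian_day(m, "first"):
            return m
    return 1


def windows_from_traits(table: TraitTable) -> list[PhenologyWindow]:
    """Derive month windows consistent (to month resolution) with the
    continuous FLT/FRT/FLD/FRD trait values.

    Fruiting windows are nudged so they never start before flowering does.
    """
    windows: list[PhenologyWindow] = []
    for (sp, biome), row in table.data.iterrows():
        fl_first = _month_of_day(int(np.clip(round(row.FLT - row.FLD / 2), 1, 365)))
        fl_last = _month_of_day(int(np.clip(round(row.FLT + row.FLD / 2), 1, 365)))
        fr_first = _month_of_day(int(np.clip(round(row.FRT - row.FRD / 2), 1, 365)))
        fr_last = _month_of_day(int(np.clip(round(row.FRT + row.FRD / 2), 1, 365)))
        if fr_first < fl_first:
            shift = fl_first - fr_first
            fr_first += shift
            fr_last = min(12, fr_last + shift)
        fr_last = max(fr_last, fr_first)
        windows.append(PhenologyWindow(sp, "flowering", fl_first, max(fl_last, fl_first)))
        windows.append(PhenologyWindow(sp, "fruiting", fr_first, fr_last))
    return windows


def generate_community(config: SimConfig | None = None, seed: int = 0) -> SyntheticCommunity:
    """Generate one four-biome community under the latent factor model."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    families = [f"F{i + 1:02d}" for i in range(config.n_families)]
    genera = [f"G{i + 1:03d}" for i in range(config.n_genera)]
    # each family has at least one genus; remaining genera spread at random
    genus_family = {g: families[i] for i, g in enumerate(genera[: config.n_families])}
    for g in genera[config.n_families:]:
        genus_family[g] = families[rng.integers(config.n_families)]

    biome_order = [b for b in BIOMES if b in config.biome_species]
    rows: list[dict] = []
    counter = 0
    for biome in biome_order:
        for _ in range(config.biome_species[biome]):
            counter += 1
            genus = genera[rng.integers(config.n_genera)]
            rows.append(
                {
                    "species_id": f"S{counter:03d}",
                    "biome": biome,
                    "genus": genus,
                    "family": genus_family[genus],
                }
            )
    # share species identities between adjacent sites (same species measured
    # twice): a later-biome row adopts the identity of a previous-biome row
    shared = 0
    for row in rows:
        if shared >= config.n_shared_species:
            break
        biome = row["biome"]
        pos = biome_order.index(biome)
        if pos == 0:
            continue
        donors = [r for r in rows if r["biome"] == biome_order[pos - 1]]
        donor = donors[rng.integers(len(donors))]
        taken = {r["species_id"] for r in rows if r["biome"] == biome}
        if donor["species_id"] in taken:
            continue
        row["species_id"] = donor["species_id"]
        row["genus"] = donor["genus"]
        row["family"] = donor["family"]
        shared += 1

    index = pd.MultiIndex.from_tuples(
        [(r["species_id"], r["biome"]) for r in rows], names=["species_id", "biome"]
    )
    shifts = config.biome_shifts
    R = np.asarray(config.latent_correlation, dtype=float)
    evals, evecs = np.linalg.eigh(R)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    shift_rows = np.vstack([shifts.loc[r["biome"]].to_numpy() for r in rows])
    latent, logs = _sample_community_traits(shift_rows, root, config, rng)
    latents = pd.DataFrame(latent, index=index, columns=list(LATENT_NAMES))

    log_traits = pd.DataFrame(logs, index=index, columns=list(TRAIT_NAMES))
    table = TraitTable(10.0 ** log_traits)

    abundances = config.min_abundance - 1 + rng.logseries(config.logseries_p, size=len(rows))
    records = [
        SpeciesRecord(
            species_id=r["species_id"],
            family=r["family"],
            genus=r["genus"],
            biome=r["biome"],
            abundance=int(a),
        )
        for r, a in zip(rows, abundances)
    ]
    return SyntheticCommunity(
        records=records,
        trait_table=table,
        windows=windows_from_traits(table),
        latents=latents,
        log_traits=log_traits,
        config=config,
        seed=seed,
    )


def generate_phenology(
    config: SimConfig | None = None, seed: int = 0
) -> list[PhenologyWindow]:
    """Month windows of a fresh community (see :func:`windows_from_traits`)."""
    return generate_community(config, seed).windows


#: Interior latent position the planted cluster is centered on; an arbitrary
#: fixed point away from the latent origin (which maps near grid corners).
DEFAULT_CLUSTER_TARGET = np.full(len(LATENT_NAMES), 0.4)


def plant_convergent_cluster(
    community: SyntheticCommunity,
    n_species: int = 5,
    n_families: int = 5,
    radius: float = 0.05,
    target: np.ndarray | None = None,
    seed: int = 0,
) -> SyntheticCommunity:
    """Plant a taxonomically diverse cluster at one point of latent space.

    ``n_species`` species of the largest biome are moved to ``target`` (plus
    a uniform perturbation within ``radius`` in latent space) and their
    traits regenerated noise-free, so as radius shrinks their niche-space
    positions coincide; their family labels are reassigned across
    ``n_families`` distinct families.  Ground truth records the planted
    membership so the downstream plot-and-ratio machinery can be verified.
    """
    if not 1 <= n_families <= n_species:
        raise ValueError("need 1 <= n_families <= n_species")
    rng = np.random.default_rng(seed)
    target = DEFAULT_CLUSTER_TARGET if target is None else np.asarray(target, float)
    if target.shape != (len(LATENT_NAMES),):
        raise ValueError(f"target must have {len(LATENT_NAMES)} latent coordinates")

    counts = pd.Series([r.biome for r in community.records]).value_counts()
    biome = counts.idxmax()
    ids = [r.species_id for r in community.records if r.biome == biome]
    if n_species > len(ids):
        raise ValueError(f"biome {biome} has only {len(ids)} species")
    chosen = list(rng.choice(ids, size=n_species, replace=False))
    chosen_index = [(sp, biome) for sp in chosen]

    latents = community.latents.copy()
    for key in chosen_index:
        direction = rng.normal(size=len(LATENT_NAMES))
        direction /= np.linalg.norm(direction)
        delta = direction * radius * rng.uniform() ** (1 / len(LATENT_NAMES))
        latents.loc[key] = target + delta

    noise_free = dc_replace(community.config, noise_sd=0.0)
    new_logs, _ = _log_traits_from_latents(
        latents.loc[chosen_index].to_numpy(), noise_free, rng=None
    )
    log_traits = community.log_traits.copy()
    log_traits.loc[chosen_index] = new_logs
    table = TraitTable(10.0 ** log_traits)

    fam_pool = sorted({r.family for r in community.records})
    fam_labels = list(rng.choice(fam_pool, size=n_families, replace=False))
    new_family = {sp: fam_labels[i % n_families] for i, sp in enumerate(chosen)}
    records = [
        dc_replace(r, family=new_family[r.species_id])
        if r.biome == biome and r.species_id in new_family
        else r
        for r in community.records
    ]
    return SyntheticCommunity(
        records=records,
        trait_table=table,
        windows=windows_from_traits(table),
        latents=latents,
        log_traits=log_traits,
        config=community.config,
        seed=community.seed,
        planted={
            "species": chosen_index,
            "biome": biome,
            "target": target,
            "radius": radius,
            "families": fam_labels,
        },
    )
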