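"""Random assembly of tri-trophic plant-herbivore-enemy communities.

A community is generated from pre-specified per-level species richness
(R1, R2, R3), per-level total abundance (A1, A2, A3) and consumer
diet-breadth exponents (alpha2, alpha3):

1. each level receives a lognormal(mu=0, sigma=1) species-abundance
   distribution scaled to the requested total and rounded to integers;
2. each consumer species draws an integer diet breadth from a truncated
   discrete Pareto distribution, p(k) proportional to alpha * k**-(alpha+1)
   on {1..R_lower}, and fills its diet list by sampling uniformly with
   replacement from the resource species present in the community (species
   whose abundance rounded to zero are not on the list; enemies sample
   from the herbivore species still present after herbivore attachment);
3. consumer individuals are attached to resource individuals under a
   one-consumer-per-host rule: individuals of a consumer species are
   assigned a resource species by cycling through the species' diet list
   and claim a random unoccupied individual of that species; an individual
   whose assigned species is fully occupied walks on through the diet list
   and is removed from the community only if every potential host species
   is occupied (or absent).

Unattached consumers are pruned, so realized richness and abundance are at
most the configured values.  The result is an individual-level interaction
table with exactly one row per plant individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateCommunityError

__all__ = [
    "ParameterRanges",
    "CommunityConfig",
    "InteractionTable",
    "Community",
    "draw_config",
    "generate_abundances",
    "diet_breadth_pmf",
    "assign_diet_breadths",
    "assign_diets",
    "assemble_web",
    "generate_community",
]

LEVEL_PREFIX = {1: "P", 2: "H", 3: "E"}


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges for community parameters.

    Defaults are the study conditions: richness uniform on the integers
    {3..120}, level abundance uniform on {3..500}, Pareto exponents uniform
    on the real interval [1, 5].
    """

    r_min: int = 3
    r_max: int = 120
    a_min: int = 3
    a_max: int = 500
    alpha_min: float = 1.0
    alpha_max: float = 5.0

    def __post_init__(self) -> None:
        if self.r_min < 1 or self.r_min > self.r_max:
            raise ConfigurationError(f"invalid richness range [{self.r_min}, {self.r_max}]")
        if self.a_min < 1 or self.a_min > self.a_max:
            raise ConfigurationError(f"invalid abundance range [{self.a_min}, {self.a_max}]")
        if self.alpha_min < 1 or self.alpha_min > self.alpha_max:
            raise ConfigurationError(
                f"invalid alpha range [{self.alpha_min}, {self.alpha_max}]"
            )


@dataclass(frozen=True)
class CommunityConfig:
    """Pre-specified inputs for one community."""

    r1: int
    r2: int
    r3: int
    a1: int
    a2: int
    a3: int
    alpha2: float
    alpha3: float
    seed: int

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "r3", "a1", "a2", "a3"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("alpha2", "alpha3"):
            if getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be >= 1")

    def richness(self, level: int) -> int:
        return (self.r1, self.r2, self.r3)[level - 1]

    def abundance(self, level: int) -> int:
        return (self.a1, self.a2, self.a3)[level - 1]

    def alpha(self, level: int) -> float:
        if level not in (2, 3):
            raise ValueError("alpha is defined for consumer levels 2 and 3 only")
        return self.alpha2 if level == 2 else self.alpha3


def draw_config(
    ranges: ParameterRanges | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> CommunityConfig:
    """Draw one community configuration from the parameter ranges.

    Richness and abundance are uniform on their integer sets, alpha uniform
    on its real interval.  ``seed`` (the per-community RNG seed) is drawn
    from ``rng`` unless given explicitly.  Deterministic given the state of
    ``rng``.
    """
    ranges = ranges or ParameterRanges()
    rng = np.random.default_rng() if rng is None else rng
    r = rng.integers(ranges.r_min, ranges.r_max + 1, size=3)
    a = rng.integers(ranges.a_min, ranges.a_max + 1, size=3)
    alpha = rng.uniform(ranges.alpha_min, ranges.alpha_max, size=2)
    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1))
    return CommunityConfig(
        r1=int(r[0]), r2=int(r[1]), r3=int(r[2]),
        a1=int(a[0]), a2=int(a[1]), a3=int(a[2]),
        alpha2=float(alpha[0]), alpha3=float(alpha[1]),
        seed=int(seed),
    )


def generate_abundances(R: int, A: int, rng: np.random.Generator) -> np.ndarray:
    """Integer per-species abundances for one trophic level.

    A lognormal(0, 1) sample of size ``R`` is scaled to sum exactly to ``A``
    and rounded to the nearest integer, so the realized total can deviate
    from ``A`` by at most R/2.  Species may round to zero (they are dropped
    later from the realized community, shrinking richness).
    """
    if R < 1 or A < 1:
        raise ConfigurationError("R and A must be >= 1")
    draws = rng.lognormal(mean=0.0, sigma=1.0, size=R)
    scaled = draws * (A / draws.sum())
    return np.rint(scaled).astype(np.int64)


def diet_breadth_pmf(R_resource: int, alpha: float) -> np.ndarray:
    """Truncated discrete Pareto pmf over diet breadths {1..R_resource}.

    Probabilities proportional to the Pareto I density alpha * k**-(alpha+1)
    evaluated at the integers and renormalized.
    """
    if R_resource < 1:
        raise DegenerateCommunityError("need at least one resource species")
    k = np.arange(1, R_resource + 1, dtype=float)
    f = k ** -(alpha + 1.0)
    return f / f.sum()


def assign_diet_breadths(
    R_consumer: int, R_resource: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one diet breadth per consumer species, i.i.d. truncated Pareto."""
    if R_resource < 1:
        raise DegenerateCommunityError("no resource species: consumers cannot exist")
    if alpha < 1.0:
        raise ConfigurationError("alpha must be >= 1")
    pmf = diet_breadth_pmf(R_resource, alpha)
    return rng.choice(np.arange(1, R_resource + 1), size=R_consumer, p=pmf)


def assign_diets(
    breadths: np.ndarray,
    resource_labels: list[str],
    rng: np.random.Generator,
) -> list[list[str]]:
    """Fill each consumer species' diet list by uniform sampling with replacement.

    Duplicates are kept: the realized unique diet breadth may be smaller than
    the assigned breadth, and duplicated hosts receive proportionally more
    individuals during assembly (the cycling walks the literal list).
    """
    if len(resource_labels) == 0:
        raise DegenerateCommunityError("empty resource species list")
    labels = np.asarray(resource_labels, dtype=object)
    diets: list[list[str]] = []
    for b in np.asarray(breadths):
        if b < 1:
            raise ConfigurationError(f"diet breadth {b} must be >= 1")
        diets.append(list(rng.choice(labels, size=int(b), replace=True)))
    return diets


@dataclass
class InteractionTable:
    """One row per plant individual: who sits on it, and who sits on that.

    ``frame`` columns: plant_id (1-based int), plant_sp, herb_sp, enemy_sp;
    absent consumers are ``None``.  An enemy implies a herbivore.
    """

    frame: pd.DataFrame

    COLUMNS = ("plant_id", "plant_sp", "herb_sp", "enemy_sp")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"interaction table missing columns: {sorted(missing)}")
        bad = self.frame["enemy_sp"].notna() & self.frame["herb_sp"].isna()
        if bad.any():
            raise ValueError("rows with an enemy but no herbivore are impossible")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_plants(self) -> int:
        return len(self.frame)

    @property
    def n_herbivores(self) -> int:
        return int(self.frame["herb_sp"].notna().sum())

    @property
    def n_enemies(self) -> int:
        return int(self.frame["enemy_sp"].notna().sum())

    def to_csv(self, path) -> None:
        out = self.frame.fillna("")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InteractionTable":
        frame = pd.read_csv(path, dtype={"plant_sp": str, "herb_sp": str, "enemy_sp": str})
        for col in ("herb_sp", "enemy_sp"):
            frame[col] = frame[col].replace("", np.nan)
        frame["plant_id"] = frame["plant_id"].astype(int)
        return cls(frame=frame.where(frame.notna(), None))


@dataclass
class Community:
    """A realized (post-pruning) community plus its provenance.

    ``abundances`` maps trophic level -> Series (species label -> realized
    individual count, count >= 1); ``initial_abundances`` holds the
    generated pre-assembly counts (nonzero-rounded lognormal draws), which
    are the community's species-abundance distribution before consumer
    pruning.  ``assigned_breadths`` and ``diets`` are the diet draws for
    the consumer levels.
    """

    config: CommunityConfig | None
    abundances: dict[int, pd.Series]
    initial_abundances: dict[int, pd.Series]
    assigned_breadths: dict[int, pd.Series]
    diets: dict[int, dict[str, list[str]]]
    table: InteractionTable
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return self.flags.get("no_herbivores", False) or self.flags.get("no_enemies", False)

    def richness(self, level: int) -> int:
        return int(len(self.abundances.get(level, ())))

    def abundance(self, level: int) -> int:
        series = self.abundances.get(level)
        return 0 if series is None else int(series.sum())

    def realized_diet_breadths(self, level: int) -> pd.Series:
        """Unique resources actually used, per realized consumer species."""
        if level == 2:
            pairs = self.table.frame.dropna(subset=["herb_sp"])
            grouped = pairs.groupby("herb_sp")["plant_sp"].nunique()
        elif level == 3:
            pairs = self.table.frame.dropna(subset=["enemy_sp"])
            grouped = pairs.groupby("enemy_sp")["herb_sp"].nunique()
        else:
            raise ValueError("diet breadth is defined for levels 2 and 3 only")
        return grouped

    def to_json_dict(self) -> dict:
        cfg = None
        if self.config is not None:
            cfg = {k: getattr(self.config, k) for k in
                   ("r1", "r2", "r3", "a1", "a2", "a3", "alpha2", "alpha3", "seed")}
        return {
            "config": cfg,
            "abundances": {lvl: ser.to_dict() for lvl, ser in self.abundances.items()},
            "initial_abundances": {lvl: ser.to_dict() for lvl, ser in
                                   self.initial_abundances.items()},
            "assigned_breadths": {lvl: ser.to_dict() for lvl, ser in
                                  self.assigned_breadths.items()},
            "diets": self.diets,
            "flags": dict(self.flags),
        }


def _labels(level: int, R: int) -> list[str]:
    prefix = LEVEL_PREFIX[level]
    return [f"{prefix}{j}" for j in range(1, R + 1)]


def _attach_consumers(
    host_species: np.ndarray,
    occupied: np.ndarray,
    consumer_counts: pd.Series,
    diets: dict[str, list[str]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One-to-one attachment of consumer individuals to host individuals.

    ``host_species`` gives the species label of each host individual;
    ``occupied`` is a same-length object array filled in place with the
    consumer species label occupying each host (None = free).  Consumer
    species are processed in a seeded random order; within a species,
    individual i starts at diet position i mod len(diet) and walks the diet
    list until it finds a species with a free host individual, claiming one
    uniformly at random.  The individual is removed from the community only
    when all of its potential host species are fully occupied.
    """
    free: dict[str, list[int]] = {}
    for idx, sp in enumerate(host_species):
        free.setdefault(sp, []).append(idx)

    species = list(consumer_counts.index)
    order = rng.permutation(len(species))
    for si in order:
        sp = species[si]
        diet = diets[sp]
        n_diet = len(diet)
        n_ind = int(consumer_counts.loc[sp])
        for i in range(n_ind):
            for step in range(i, i + n_diet):
                pool = free.get(diet[step % n_diet])
                if pool:
                    j = int(rng.integers(len(pool)))
                    host_idx = pool[j]
                    pool[j] = pool[-1]
                    pool.pop()
                    occupied[host_idx] = sp
                    break  # next individual; else removed (all hosts occupied)
    return occupied


def assemble_web(
    abundances: dict[int, pd.Series],
    breadths: dict[int, pd.Series],
    diets: dict[int, dict[str, list[str]]],
    rng: np.random.Generator,
    config: CommunityConfig | None = None,
    enemy_diet_factory=None,
) -> Community:
    """Attach herbivores to plants and enemies to herbivores, then prune.

    Expects per-level Series of nonzero initial abundances (species label ->
    count).  If ``enemy_diet_factory`` is given it is called with the list
    of herbivore species that survived attachment and must return
    ``(breadths, diets)`` for level 3 — this lets enemy diets be drawn over
    the herbivore community that actually exists when the enemies arrive.
    Returns the pruned :class:`Community`; its interaction table has
    exactly one row per plant individual.
    """
    plants = abundances[1]
    if plants.sum() < 1:
        raise DegenerateCommunityError("no plant individuals: nothing to assemble")

    plant_sp = np.repeat(plants.index.to_numpy(dtype=object),
                         plants.to_numpy(dtype=np.int64))
    n_plants = len(plant_sp)

    herb_of_plant = np.full(n_plants, None, dtype=object)
    herb_counts = abundances.get(2, pd.Series(dtype=np.int64))
    if len(herb_counts) > 0:
        _attach_consumers(plant_sp, herb_of_plant, herb_counts, diets[2], rng)

    # surviving herbivore individuals become the hosts for enemies
    herb_idx = np.flatnonzero(herb_of_plant != None)  # noqa: E711  (elementwise)
    herb_sp_of_ind = herb_of_plant[herb_idx]
    if enemy_diet_factory is not None:
        herb_present = sorted({str(s) for s in herb_sp_of_ind},
                              key=lambda s: int(s[1:]))
        breadths = dict(breadths)
        diets = dict(diets)
        breadths[3], diets[3] = enemy_diet_factory(herb_present)
    enemy_of_herb = np.full(len(herb_idx), None, dtype=object)
    enemy_counts = abundances.get(3, pd.Series(dtype=np.int64))
    if len(herb_idx) > 0 and len(enemy_counts) > 0 and diets.get(3):
        _attach_consumers(herb_sp_of_ind, enemy_of_herb, enemy_counts, diets[3], rng)

    enemy_of_plant = np.full(n_plants, None, dtype=object)
    enemy_of_plant[herb_idx] = enemy_of_herb

    frame = pd.DataFrame(
        {
            "plant_id": np.arange(1, n_plants + 1),
            "plant_sp": plant_sp,
            "herb_sp": herb_of_plant,
            "enemy_sp": enemy_of_plant,
        }
    )
    table = InteractionTable(frame=frame)

    realized: dict[int, pd.Series] = {1: plants.copy()}
    realized[2] = _realized_counts(herb_of_plant)
    realized[3] = _realized_counts(enemy_of_plant)

    flags = {
        "no_herbivores": len(realized[2]) == 0,
        "no_enemies": len(realized[3]) == 0,
    }
    return Community(
        config=config,
        abundances=realized,
        initial_abundances={lvl: ser.copy() for lvl, ser in abundances.items()},
        assigned_breadths=breadths,
        diets=diets,
        table=table,
        flags=flags,
    )


def _realized_counts(assigned: np.ndarray) -> pd.Series:
    mask = assigned != None  # noqa: E711
    if not mask.any():
        return pd.Series(dtype=np.int64)
    vals, counts = np.unique(assigned[mask].astype(str), return_counts=True)
    return pd.Series(counts, index=vals, dtype=np.int64).sort_index(
        key=lambda ix: ix.str[1:].astype(int)
    )


def generate_community(config: CommunityConfig) -> Community:
    """Run the full generation pipeline for one configuration.

    Deterministic: the same config (including seed) yields an identical
    community and interaction table.
    """
    rng = np.random.default_rng(config.seed)

    abund: dict[int, pd.Series] = {}
    for level in (1, 2, 3):
        counts = generate_abundances(config.richness(level), config.abundance(level), rng)
        labels = _labels(level, config.richness(level))
        series = pd.Series(counts, index=labels, dtype=np.int64)
        abund[level] = series[series > 0]  # zero-rounded species drop out

    if len(abund[1]) == 0 or abund[1].sum() < 1:
        raise DegenerateCommunityError("all plant species rounded to zero abundance")

    def draw_consumer_diets(
        consumers: pd.Series, resources: list[str], alpha: float
    ) -> tuple[pd.Series, dict[str, list[str]]]:
        if len(consumers) == 0 or len(resources) == 0:
            return pd.Series(dtype=np.int64), {}
        b = assign_diet_breadths(len(consumers), len(resources), alpha, rng)
        diet_lists = assign_diets(b, resources, rng)
        return (pd.Series(b, index=consumers.index, dtype=np.int64),
                dict(zip(consumers.index, diet_lists)))

    breadths: dict[int, pd.Series] = {}
    diets: dict[int, dict[str, list[str]]] = {}
    # herbivore diets sample the plant species actually present
    breadths[2], diets[2] = draw_consumer_diets(
        abund[2], list(abund[1].index), config.alpha2
    )
    # enemy diets are drawn over the herbivore species present after
    # herbivore attachment (the community the enemies actually encounter)
    breadths[3], diets[3] = pd.Series(dtype=np.int64), {}

    def enemy_diet_factory(herb_present: list[str]):
        return draw_consumer_diets(abund[3], herb_present, config.alpha3)

    return assemble_web(abund, breadths, diets, rng, config=config,
                        enemy_diet_factory=enemy_diet_factory)


def generate_web(
    ranges: ParameterRanges | None = None,
    rng: np.random.Generator | None = None,
) -> Community:
    """Draw a configuration and generate its community in one call."""
    config = draw_config(ranges, rng)
    return generate_community(config)
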