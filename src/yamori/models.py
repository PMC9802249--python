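"""Divergence-scenario demographic models.

A :class:`DemographicModel` is a rooted population tree: leaf-to-root
``SplitEvent``\\ s (backward in time, a derived population merges into its
ancestor), per-population diploid effective sizes, optional backward
migration rates, and the mutation-rate / generation-time scalars needed to
convert between genetic and calendar units.

The module ships the two presets used for the Japanese-archipelago gecko
dispersal analysis: ``M1`` (pure divergence, no gene flow) and ``M2`` (the
same topology with symmetric migration between adjacent populations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = [
    "PopulationSpec",
    "SplitEvent",
    "MigrationSpec",
    "SizeChange",
    "DemographicModel",
    "build_m1",
    "build_m2",
    "per_generation_rate",
    "years_to_generations",
    "M1_SPLIT_TIMES",
    "M1_POPULATIONS",
    "STUDY_SAMPLE_SIZES",
]

#: Default mutation rate, per site per generation (2.5e-8 per site per year
#: at a 1.5-year generation time).
DEFAULT_MU = 3.75e-8

#: Default generation time in years.
DEFAULT_GENERATION_TIME = 1.5

#: The ten populations of the divergence scenario, colonization order
#: (mainland China first, eastern Japan last).
M1_POPULATIONS = (
    "Nanjing",
    "Fukue",
    "Kyushu",
    "Chugoku",
    "Shikoku",
    "Kinki",
    "Hokuriku",
    "Tohoku",
    "Tokai",
    "Kanto",
)

#: Median split times (generations) of the adopted divergence scenario,
#: keyed by (derived, ancestral) population pair.
M1_SPLIT_TIMES = {
    ("Fukue", "Nanjing"): 6506.0,
    ("Kyushu", "Fukue"): 3486.0,
    ("Chugoku", "Kyushu"): 1434.0,
    ("Shikoku", "Kyushu"): 1380.0,
    ("Kinki", "Shikoku"): 618.5,
    ("Hokuriku", "Kinki"): 260.0,
    ("Tokai", "Kinki"): 253.0,
    ("Tohoku", "Hokuriku"): 100.0,
    ("Kanto", "Tokai"): 80.0,
}

#: Diploid sample sizes of the regional groups entering the divergence
#: analysis (the Kyushu group is the Tsushima-strait monophyletic clade).
STUDY_SAMPLE_SIZES = {
    "Nanjing": 3,
    "Fukue": 6,
    "Kyushu": 16,
    "Chugoku": 16,
    "Shikoku": 12,
    "Kinki": 16,
    "Hokuriku": 39,
    "Tohoku": 15,
    "Tokai": 31,
    "Kanto": 15,
}


@dataclass(frozen=True)
class PopulationSpec:
    """A sampled or ancestral population.

    Parameters
    ----------
    name:
        Unique label.
    ne:
        Present-day diploid effective size (> 0).
    sample_diploids:
        Number of sampled diploid individuals (>= 0).
    """

    name: str
    ne: float
    sample_diploids: int = 0

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError(f"population {self.name!r}: ne must be > 0, got {self.ne}")
        if self.sample_diploids < 0:
            raise ValueError(f"population {self.name!r}: negative sample size")


@dataclass(frozen=True)
class SplitEvent:
    """Backward-in-time merger of ``derived`` into ``ancestral``."""

    time_generations: float
    derived: str
    ancestral: str

    def __post_init__(self) -> None:
        if self.time_generations <= 0:
            raise ValueError("split time must be > 0 generations")
        if self.derived == self.ancestral:
            raise ValueError("a population cannot split from itself")


@dataclass(frozen=True)
class MigrationSpec:
    """Backward-in-time per-lineage migration probability per generation."""

    source: str
    dest: str
    rate_per_generation: float

    def __post_init__(self) -> None:
        if not (0 <= self.rate_per_generation < 1):
            raise ValueError("migration rate must lie in [0, 1)")
        if self.source == self.dest:
            raise ValueError("migration source and dest must differ")


@dataclass(frozen=True)
class SizeChange:
    """Step change of a population's diploid size at ``time_generations``:
    for all older times (until the next change) the population has size ``ne``."""

    population: str
    time_generations: float
    ne: float

    def __post_init__(self) -> None:
        if self.time_generations <= 0:
            raise ValueError("size-change time must be > 0")
        if self.ne <= 0:
            raise ValueError("ne must be > 0")


@dataclass(frozen=True)
class DemographicModel:
    """A rooted divergence scenario with optional migration and size changes.

    Invariants (checked on construction): population names unique; the splits
    form a single rooted tree (exactly ``n_pops - 1`` events, each population
    derived at most once); every split is strictly younger than the next split
    along its ancestral lineage.
    """

    populations: tuple[PopulationSpec, ...]
    splits: tuple[SplitEvent, ...]
    migrations: tuple[MigrationSpec, ...] = ()
    size_changes: tuple[SizeChange, ...] = ()
    mu_per_site_per_generation: float = DEFAULT_MU
    generation_time_years: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "splits", tuple(self.splits))
        object.__setattr__(self, "migrations", tuple(self.migrations))
        object.__setattr__(self, "size_changes", tuple(self.size_changes))
        if self.mu_per_site_per_generation <= 0:
            raise ValueError("mutation rate must be > 0")
        if self.generation_time_years <= 0:
            raise ValueError("generation time must be > 0")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        self._validate_tree()
        self._validate_migration()
        self._validate_size_changes()

    # -- structure ---------------------------------------------------------

    @property
    def pop_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    def pop_index(self, name: str) -> int:
        try:
            return self.pop_names.index(name)
        except ValueError:
            raise KeyError(f"unknown population {name!r}") from None

    def split_of(self, name: str) -> SplitEvent | None:
        """The split event in which ``name`` is the derived population."""
        for s in self.splits:
            if s.derived == name:
                return s
        return None

    @property
    def root(self) -> str:
        """The population that is never derived in any split."""
        derived = {s.derived for s in self.splits}
        roots = [p.name for p in self.populations if p.name not in derived]
        assert len(roots) == 1  # guaranteed by _validate_tree
        return roots[0]

    def children_of(self, name: str) -> tuple[str, ...]:
        return tuple(s.derived for s in self.splits if s.ancestral == name)

    def merge_time(self, name: str) -> float:
        """Time at which ``name`` ceases to exist backward in time (inf for root)."""
        s = self.split_of(name)
        return s.time_generations if s is not None else float("inf")

    def _validate_tree(self) -> None:
        names = set(self.pop_names)
        if len(self.splits) != len(names) - 1:
            raise ValueError(
                f"{len(names)} populations require {len(names) - 1} splits, "
                f"got {len(self.splits)}"
            )
        derived_seen: set[str] = set()
        for s in self.splits:
            for nm in (s.derived, s.ancestral):
                if nm not in names:
                    raise ValueError(f"split references unknown population {nm!r}")
            if s.derived in derived_seen:
                raise ValueError(f"population {s.derived!r} derived in two splits")
            derived_seen.add(s.derived)
        roots = names - derived_seen
        if len(roots) != 1:
            raise ValueError(f"splits must leave exactly one root, found {sorted(roots)}")
        # connectivity / acyclicity: walk ancestor chain from every population
        split_by_derived = {s.derived: s for s in self.splits}
        root = next(iter(roots))
        for name in names:
            seen = set()
            cur = name
            while cur != root:
                if cur in seen:
                    raise ValueError("cycle detected in split events")
                seen.add(cur)
                cur = split_by_derived[cur].ancestral
        # time ordering along each ancestral lineage
        for s in self.splits:
            parent_split = split_by_derived.get(s.ancestral)
            if parent_split is not None and not (
                s.time_generations < parent_split.time_generations
            ):
                raise ValueError(
                    f"split of {s.derived!r} at {s.time_generations} must predate "
                    f"(be younger than) the split of its ancestor {s.ancestral!r} "
                    f"at {parent_split.time_generations}"
                )

    def _validate_migration(self) -> None:
        for m in self.migrations:
            for nm in (m.source, m.dest):
                if nm not in self.pop_names:
                    raise ValueError(f"migration references unknown population {nm!r}")
            # both populations must coexist over some interval: each exists
            # from time 0 until its own merge time, so any pair coexists.

    def _validate_size_changes(self) -> None:
        for c in self.size_changes:
            if c.population not in self.pop_names:
                raise ValueError(f"size change references unknown population {c.population!r}")

    # -- convenience -------------------------------------------------------

    def with_samples(self, sample_diploids: dict[str, int]) -> "DemographicModel":
        pops = tuple(
            dataclasses.replace(p, sample_diploids=sample_diploids.get(p.name, 0))
            for p in self.populations
        )
        return dataclasses.replace(self, populations=pops)

    def with_split_times(self, times: dict[str, float]) -> "DemographicModel":
        """Return a copy with split times replaced, keyed by derived population."""
        splits = tuple(
            dataclasses.replace(s, time_generations=times.get(s.derived, s.time_generations))
            for s in self.splits
        )
        return dataclasses.replace(self, splits=splits)

    def with_ne(self, ne: dict[str, float]) -> "DemographicModel":
        pops = tuple(
            dataclasses.replace(p, ne=ne.get(p.name, p.ne)) for p in self.populations
        )
        return dataclasses.replace(self, populations=pops)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [
                {"name": p.name, "ne": p.ne, "samples": p.sample_diploids}
                for p in self.populations
            ],
            "splits": [
                {"time": s.time_generations, "derived": s.derived, "ancestral": s.ancestral}
                for s in self.splits
            ],
            "migrations": [
                {"source": m.source, "dest": m.dest, "rate": m.rate_per_generation}
                for m in self.migrations
            ],
            "size_changes": [
                {"population": c.population, "time": c.time_generations, "ne": c.ne}
                for c in self.size_changes
            ],
            "mu": self.mu_per_site_per_generation,
            "generation_time": self.generation_time_years,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            populations=tuple(
                PopulationSpec(p["name"], p["ne"], p.get("samples", 0))
                for p in d["populations"]
            ),
            splits=tuple(
                SplitEvent(s["time"], s["derived"], s["ancestral"]) for s in d["splits"]
            ),
            migrations=tuple(
                MigrationSpec(m["source"], m["dest"], m["rate"])
                for m in d.get("migrations", [])
            ),
            size_changes=tuple(
                SizeChange(c["population"], c["time"], c["ne"])
                for c in d.get("size_changes", [])
            ),
            mu_per_site_per_generation=d["mu"],
            generation_time_years=d["generation_time"],
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DemographicModel":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)


# -- presets ---------------------------------------------------------------


def build_m1(
    ne: float | dict[str, float] = 10_000.0,
    split_times: dict[str, float] | None = None,
    sample_diploids: dict[str, int] | None = None,
    mu: float = DEFAULT_MU,
    generation_time_years: float = DEFAULT_GENERATION_TIME,
) -> DemographicModel:
    """The adopted pure-divergence scenario: ten populations colonizing the
    Japanese archipelago west-to-east, with the estimated median split times
    (generations) as defaults and no migration.

    Parameters
    ----------
    ne:
        Diploid effective size for every population (scalar) or per-population
        mapping. Default 10,000.
    split_times:
        Optional overrides keyed by derived population name.
    sample_diploids:
        Diploid sample counts; defaults to the study's regional group sizes.
    """
    if sample_diploids is None:
        sample_diploids = STUDY_SAMPLE_SIZES
    if isinstance(ne, dict):
        ne_of = lambda n: float(ne.get(n, 10_000.0))  # noqa: E731
    else:
        ne_of = lambda n: float(ne)  # noqa: E731
    pops = tuple(
        PopulationSpec(name, ne_of(name), sample_diploids.get(name, 0))
        for name in M1_POPULATIONS
    )
    times = {d: t for (d, _a), t in M1_SPLIT_TIMES.items()}
    if split_times:
        times.update(split_times)
    splits = tuple(
        SplitEvent(times[d], d, a) for (d, a) in M1_SPLIT_TIMES
    )
    return DemographicModel(
        populations=pops,
        splits=splits,
        mu_per_site_per_generation=mu,
        generation_time_years=generation_time_years,
    )


def build_m2(migration_rate: float, **kwargs) -> DemographicModel:
    """The migration variant: identical topology and times to ``M1`` plus
    symmetric migration at ``migration_rate`` between every parent/child
    (adjacent) population pair."""
    if migration_rate < 0:
        raise ValueError("migration rate must be >= 0")
    m1 = build_m1(**kwargs)
    migs = []
    if migration_rate > 0:
        for s in m1.splits:
            migs.append(MigrationSpec(s.derived, s.ancestral, migration_rate))
            migs.append(MigrationSpec(s.ancestral, s.derived, migration_rate))
    return dataclasses.replace(m1, migrations=tuple(migs))


# -- unit conversions ------------------------------------------------------


def per_generation_rate(rate_per_site_per_year: float, generation_time_years: float) -> float:
    """Convert a per-year mutation rate to a per-generation rate."""
    if rate_per_site_per_year <= 0 or generation_time_years <= 0:
        raise ValueError("rates and generation time must be > 0")
    return rate_per_site_per_year * generation_time_years


def years_to_generations(years: float, generation_time_years: float) -> float:
    """Convert calendar years to generations."""
    if generation_time_years <= 0:
        raise ValueError("generation time must be > 0")
    return years / generation_time_years


def generations_to_years(generations: float, generation_time_years: float) -> float:
    """Convert generations to calendar years."""
    if generation_time_years <= 0:
        raise ValueError("generation time must be > 0")
    return generations * generation_time_years
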