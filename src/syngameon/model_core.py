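"""Domain types and the per-individual reproduction decision tree.

The model follows a suite of partially inter-fertile congeneric tree species
("genomic mutualists") embedded in a larger community.  Each reproductive
event, every individual receives pollen from a random subset of the
community whose size is set by the pollen limitation coefficient (PLC).
Conspecific pollen always fertilizes; heterospecific pollen fertilizes with
probability ``hybrid_success``; ovules left unfertilized are selfed, each
succeeding with probability ``self_success``.  Offspring always take the
mother's species identity, so hybridization acts as unidirectional gene
flow into the maternal species rather than creating new taxa.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Origin",
    "Individual",
    "Progeny",
    "MatingParams",
    "Community",
    "round_half_up",
    "donor_count",
    "sample_donors",
    "reproduce_individual",
    "DEFAULT_ABUNDANCES",
    "PLC_GRID",
    "SUCCESS_GRID",
    "FECUNDITY_GRID",
]

#: Default initial abundance vectors per diversity level (community sizes
#: 300, 800 and 1000), mirroring abundance skew observed among congeneric
#: suites in large tropical forest plots.
DEFAULT_ABUNDANCES: dict[int, tuple[int, ...]] = {
    3: (195, 75, 30),
    5: (300, 200, 150, 100, 50),
    10: (220, 200, 125, 110, 100, 90, 75, 50, 20, 10),
}

#: Canonical sweep grids for the pollen limitation coefficient, the
#: selfing/hybridization success probabilities and individual fecundity.
PLC_GRID: tuple[float, ...] = (0.01, 0.015, 0.02, 0.025, 0.1, 0.15, 0.25, 0.5)
SUCCESS_GRID: tuple[float, ...] = (0.0, 0.1, 0.25, 0.4)
FECUNDITY_GRID: tuple[int, ...] = (10, 50, 250)

# Tolerance absorbing binary-float error in products like 0.015 * 300,
# which evaluates to 4.4999999999999996 but must round as 4.5 -> 5.
_HALF_UP_EPS = 1e-9


class Origin(enum.IntEnum):
    """How an individual (or progeny) came to exist."""

    FOUNDER = 0
    OUTCROSS = 1
    SELF = 2
    HYBRID = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class Individual:
    """One tree: identity, species, age and origin of birth."""

    id: int
    species: int
    age: int = 0
    origin: Origin = Origin.FOUNDER

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")


@dataclass(frozen=True)
class Progeny:
    """A viable offspring; species identity is always the mother's."""

    mother_id: int
    species: int
    origin: Origin
    father_id: int | None = None

    def __post_init__(self) -> None:
        if self.origin is Origin.SELF and self.father_id is not None:
            raise ValueError("selfed progeny cannot have a father")
        if self.origin in (Origin.OUTCROSS, Origin.HYBRID) and self.father_id is None:
            raise ValueError(f"{self.origin.label} progeny requires a father")
        if self.origin is Origin.FOUNDER:
            raise ValueError("progeny cannot have founder origin")


@dataclass(frozen=True)
class MatingParams:
    """The six variable model parameters plus fixed stochastic mortality.

    Parameters
    ----------
    n_species
        Initial diversity of the inter-fertile suite (3, 5 or 10 by default).
    initial_abundances
        Positive integers, one per species; their sum fixes community size.
    plc
        Pollen limitation coefficient in (0, 1]: the fraction of the
        community acting as pollen donors to one individual per event.
    self_success, hybrid_success
        Per-ovule probabilities that a selfing attempt / heterospecific
        cross yields a viable offspring.
    fecundity
        Ovules per individual per reproductive event.
    mortality_rate
        Per-event fraction of the community dying at random (default 1.5%).
    n_events
        Number of reproductive events per run (default 500).
    n_replicates
        Replicate runs per parameter combination (default 3).
    conspecific_precedence
        When more donors arrive than there are ovules, attempt conspecific
        crosses first (conspecific pollen is more vigorous).  If False the
        attempted subset is uniform random.
    """

    n_species: int = 3
    initial_abundances: tuple[int, ...] | None = None
    plc: float = 0.1
    self_success: float = 0.0
    hybrid_success: float = 0.0
    fecundity: int = 50
    mortality_rate: float = 0.015
    n_events: int = 500
    n_replicates: int = 3
    conspecific_precedence: bool = True

    def __post_init__(self) -> None:
        if self.initial_abundances is None:
            if self.n_species not in DEFAULT_ABUNDANCES:
                raise ValueError(
                    f"no default abundance vector for n_species={self.n_species}; "
                    "pass initial_abundances explicitly"
                )
            object.__setattr__(
                self, "initial_abundances", DEFAULT_ABUNDANCES[self.n_species]
            )
        ab = tuple(int(a) for a in self.initial_abundances)
        object.__setattr__(self, "initial_abundances", ab)
        if len(ab) != self.n_species:
            raise ValueError(
                f"initial_abundances has length {len(ab)}, expected {self.n_species}"
            )
        if any(a <= 0 for a in ab):
            raise ValueError("all initial abundances must be positive")
        if not 0.0 < self.plc <= 1.0:
            raise ValueError(f"plc must be in (0, 1], got {self.plc}")
        for name in ("self_success", "hybrid_success", "mortality_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fecundity < 1:
            raise ValueError(f"fecundity must be positive, got {self.fecundity}")
        if self.n_events < 1:
            raise ValueError(f"n_events must be positive, got {self.n_events}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be positive, got {self.n_replicates}")

    @property
    def community_size(self) -> int:
        return sum(self.initial_abundances)


class Community:
    """A fixed-size community of individuals, stored as parallel arrays.

    Array storage keeps the 500-event loop fast; :meth:`individuals`
    materializes :class:`Individual` objects when object-level access is
    wanted (tests, small communities).
    """

    __slots__ = ("n_species", "ids", "species", "ages", "origins", "_next_id")

    def __init__(
        self,
        n_species: int,
        ids: np.ndarray,
        species: np.ndarray,
        ages: np.ndarray,
        origins: np.ndarray,
        next_id: int | None = None,
    ) -> None:
        self.n_species = int(n_species)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.species = np.asarray(species, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=np.int64)
        self.origins = np.asarray(origins, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.species) == len(self.ages) == len(self.origins) == n):
            raise ValueError("community arrays must have equal length")
        if len(np.unique(self.ids)) != n:
            raise ValueError("individual ids must be unique within a community")
        self._next_id = int(next_id) if next_id is not None else (
            int(self.ids.max()) + 1 if n else 0
        )

    @classmethod
    def from_abundances(cls, abundances: Sequence[int]) -> "Community":
        """Found a community: ``abundances[k]`` individuals of species ``k``."""
        ab = np.asarray(abundances, dtype=np.int64)
        if (ab < 0).any():
            raise ValueError("abundances must be non-negative")
        species = np.repeat(np.arange(len(ab)), ab)
        n = int(ab.sum())
        return cls(
            n_species=len(ab),
            ids=np.arange(n),
            species=species,
            ages=np.zeros(n, dtype=np.int64),
            origins=np.full(n, Origin.FOUNDER, dtype=np.int64),
        )

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def abundances(self) -> np.ndarray:
        return np.bincount(self.species, minlength=self.n_species)

    @property
    def richness(self) -> int:
        return int((self.abundances > 0).sum())

    def individuals(self) -> list[Individual]:
        return [
            Individual(int(i), int(s), int(a), Origin(int(o)))
            for i, s, a, o in zip(self.ids, self.species, self.ages, self.origins)
        ]

    def index_of(self, individual_id: int) -> int:
        idx = np.flatnonzero(self.ids == individual_id)
        if len(idx) == 0:
            raise KeyError(f"no individual with id {individual_id}")
        return int(idx[0])


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves rounding up.

    A small tolerance absorbs binary floating-point error in products such
    as ``0.015 * 300`` (stored as 4.4999999999999996) so that intended
    halves round up.
    """
    return int(math.floor(x + 0.5 + _HALF_UP_EPS))


def donor_count(plc: float, community_size: int) -> int:
    """Number of pollen donors one individual receives in one event.

    Computed as round-half-up of ``plc * community_size`` (the full
    community size, mother included, enters the product), capped at
    ``community_size - 1`` since an individual cannot be its own donor.
    """
    if community_size < 2:
        raise ValueError(
            f"degenerate community of size {community_size}: at least two "
            "individuals are required for pollen exchange"
        )
    if not 0.0 < plc <= 1.0:
        raise ValueError(f"plc must be in (0, 1], got {plc}")
    return min(round_half_up(plc * community_size), community_size - 1)


def sample_donors(
    community: Community,
    mother: Individual,
    n_donors: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Uniform sample of donors without replacement, mother excluded.

    Mate choice carries no spatial structure: every non-mother individual
    is an equally likely donor.
    """
    if n_donors > community.size - 1:
        raise ValueError(
            f"n_donors={n_donors} exceeds available mates ({community.size - 1})"
        )
    if n_donors == 0:
        return []
    mother_idx = community.index_of(mother.id)
    candidates = np.delete(np.arange(community.size), mother_idx)
    chosen = rng.choice(candidates, size=n_donors, replace=False)
    return [
        Individual(
            int(community.ids[i]),
            int(community.species[i]),
            int(community.ages[i]),
            Origin(int(community.origins[i])),
        )
        for i in chosen
    ]


def reproduce_individual(
    mother: Individual,
    donors: Sequence[Individual],
    params: MatingParams,
    rng: np.random.Generator,
) -> list[Progeny]:
    """Apply the reproduction decision tree for one mother.

    1. At most ``fecundity`` crosses are attempted.  When more donors than
       ovules arrive, conspecific donors take precedence (or, with
       ``conspecific_precedence=False``, a uniform random subset is kept).
    2. Every attempted conspecific cross yields a viable outcrossed progeny.
    3. Every attempted heterospecific cross yields a viable hybrid progeny
       independently with probability ``hybrid_success``.
    4. Each ovule left over after all attempted crosses is selfed,
       succeeding independently with probability ``self_success``.

    Each donor fertilizes at most one ovule; all progeny carry the mother's
    species.  Total viable progeny never exceeds ``fecundity``.
    """
    F = params.fecundity
    donors = list(donors)
    if len(donors) > F:
        if params.conspecific_precedence:
            con = [d for d in donors if d.species == mother.species]
            het = [d for d in donors if d.species != mother.species]
            attempted = (con + het)[:F]
        else:
            keep = rng.choice(len(donors), size=F, replace=False)
            attempted = [donors[i] for i in keep]
    else:
        attempted = donors

    progeny: list[Progeny] = []
    for d in attempted:
        if d.species == mother.species:
            progeny.append(
                Progeny(mother.id, mother.species, Origin.OUTCROSS, father_id=d.id)
            )
        elif rng.random() < params.hybrid_success:
            progeny.append(
                Progeny(mother.id, mother.species, Origin.HYBRID, father_id=d.id)
            )

    remainder = F - len(attempted)
    for _ in range(remainder):
        if rng.random() < params.self_success:
            progeny.append(Progeny(mother.id, mother.species, Origin.SELF))
    return progeny
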