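"""The iterated three-step reproductive event loop.

Each event: (1) every individual reproduces simultaneously and all viable
progeny are pooled into a seed bank; (2) a fixed fraction of individuals
die at random; (3) recruits are drawn at random from the seed bank to
replace the dead (lottery recruitment), entering at age 0 and reproducing
from the next event.  The seed bank does not persist between events.

Because recruitment is a uniform lottery and progeny inherit the mother's
species, only the seed bank's composition by (species, origin) matters
downstream.  The engine therefore draws each mother's progeny counts from
the exact distributions implied by the per-individual decision tree
(hypergeometric donor composition, binomial viability) instead of
materializing Progeny objects — distributionally identical to composing
:func:`syngameon.model_core.reproduce_individual` over the community, and
fast enough for 1000 individuals x 250 ovules x 500 events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model_core import Community, MatingParams, Origin, donor_count, round_half_up

__all__ = [
    "SeedBank",
    "EventRecord",
    "Trajectory",
    "reproduction_step",
    "mortality_step",
    "recruitment_step",
    "run_event",
    "run_simulation",
]

logger = logging.getLogger(__name__)

# Column order of the per-species origin counts in a SeedBank.
_BANK_ORIGINS = (Origin.OUTCROSS, Origin.HYBRID, Origin.SELF)


@dataclass
class SeedBank:
    """Pooled viable progeny of one event, counted by (species, origin).

    ``counts[k, j]`` is the number of viable progeny of species ``k`` with
    origin ``_BANK_ORIGINS[j]`` (outcross, hybrid, self).
    """

    counts: np.ndarray  # shape (n_species, 3), int64

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    def by_origin(self) -> dict[str, int]:
        totals = self.counts.sum(axis=0)
        return {o.label: int(t) for o, t in zip(_BANK_ORIGINS, totals)}


@dataclass(frozen=True)
class EventRecord:
    """Per-event state summary emitted by :func:`run_event`."""

    event_index: int
    abundances: tuple[int, ...]
    richness: int
    n_deaths: int
    recruit_counts_by_origin: dict[str, int]
    seed_bank_size: int
    shortfall_flag: bool = False


@dataclass
class Trajectory:
    """Full record of one simulation run."""

    params: MatingParams
    seed: int
    events: list[EventRecord] = field(default_factory=list)
    final_community: Community | None = None

    @property
    def final_richness(self) -> int:
        return self.events[-1].richness

    def richness_series(self) -> np.ndarray:
        return np.array([e.richness for e in self.events], dtype=np.int64)

    def abundance_matrix(self) -> np.ndarray:
        """(n_events, n_species) abundances at the end of each event."""
        return np.array([e.abundances for e in self.events], dtype=np.int64)


def reproduction_step(
    community: Community, params: MatingParams, rng: np.random.Generator
) -> SeedBank:
    """Generate every individual's progeny and pool them into a seed bank.

    Mothers are processed in ascending index (= id) order; each draws its
    conspecific donor count from the hypergeometric law induced by uniform
    donor sampling without replacement, then binomial viability draws for
    hybrids and selfed ovules.
    """
    N = community.size
    if N == 0:
        raise ValueError("cannot reproduce an empty community")
    S = community.n_species
    F = params.fecundity
    counts = np.zeros((S, 3), dtype=np.int64)
    if N < 2:
        # lone survivor: no donors, all ovules go to selfing
        n_self = rng.binomial(F, params.self_success)
        counts[community.species[0], 2] = n_self
        return SeedBank(counts)

    nd = donor_count(params.plc, N)
    species = community.species
    ab = community.abundances
    con_others = ab[species] - 1  # conspecific candidates per mother

    if nd == 0:
        n_con = np.zeros(N, dtype=np.int64)
        att_con = n_con
        att_het = n_con
    else:
        n_con = rng.hypergeometric(con_others, N - 1 - con_others, nd)
        if nd <= F:
            att_con = n_con
            att_het = nd - n_con
        elif params.conspecific_precedence:
            att_con = np.minimum(n_con, F)
            att_het = F - att_con
        else:
            att_con = rng.hypergeometric(n_con, nd - n_con, F)
            att_het = F - att_con

    n_hyb = rng.binomial(att_het, params.hybrid_success)
    remainder = F - att_con - att_het
    n_self = rng.binomial(remainder, params.self_success)

    np.add.at(counts[:, 0], species, att_con)
    np.add.at(counts[:, 1], species, n_hyb)
    np.add.at(counts[:, 2], species, n_self)
    return SeedBank(counts)


def mortality_step(
    community: Community, params: MatingParams, rng: np.random.Generator
) -> np.ndarray:
    """Choose the individuals dying this event, uniformly at random.

    The death count is round-half-up of ``mortality_rate * size``.  Deaths
    are applied after reproduction, so dying individuals still contribute
    progeny to the current seed bank.  Returns the array indices of the
    dead (not their ids).
    """
    n_deaths = round_half_up(params.mortality_rate * community.size)
    n_deaths = min(n_deaths, community.size)
    if n_deaths == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(community.size, size=n_deaths, replace=False)


def recruitment_step(
    seed_bank: SeedBank, n_deaths: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Draw recruits uniformly without replacement from the seed bank.

    Returns a (n_species, 3) count array matching the bank layout, plus a
    shortfall flag.  If the bank holds fewer progeny than there were
    deaths, everything recruits, the community shrinks, and a warning is
    logged.
    """
    total = seed_bank.size
    if n_deaths >= total:
        shortfall = n_deaths > total
        if shortfall:
            logger.warning(
                "seed bank shortfall: %d progeny for %d deaths", total, n_deaths
            )
        return seed_bank.counts.copy(), shortfall
    flat = seed_bank.counts.ravel()
    drawn = rng.multivariate_hypergeometric(flat, n_deaths)
    return drawn.reshape(seed_bank.counts.shape).astype(np.int64), False


def run_event(
    community: Community,
    params: MatingParams,
    rng: np.random.Generator,
    event_index: int = 0,
) -> tuple[Community, EventRecord]:
    """One reproductive event: reproduce, die, recruit, age.

    Survivors' ages increment by one; recruits enter at age 0 and are able
    to reproduce from the next event.  Returns the updated community and
    its :class:`EventRecord`.
    """
    bank = reproduction_step(community, params, rng)
    dead_idx = mortality_step(community, params, rng)
    n_deaths = len(dead_idx)
    recruit_counts, shortfall = recruitment_step(bank, n_deaths, rng)

    keep = np.ones(community.size, dtype=bool)
    keep[dead_idx] = False
    n_recruits = int(recruit_counts.sum())
    rec_species = np.repeat(
        np.tile(np.arange(community.n_species), 3),
        recruit_counts.T.ravel(),  # origin-major to match tile layout
    )
    rec_origins = np.repeat(
        np.repeat([int(o) for o in _BANK_ORIGINS], community.n_species),
        recruit_counts.T.ravel(),
    )
    new_ids = np.arange(community._next_id, community._next_id + n_recruits)

    updated = Community(
        n_species=community.n_species,
        ids=np.concatenate([community.ids[keep], new_ids]),
        species=np.concatenate([community.species[keep], rec_species]),
        ages=np.concatenate([community.ages[keep] + 1, np.zeros(n_recruits, dtype=np.int64)]),
        origins=np.concatenate([community.origins[keep], rec_origins]),
        next_id=community._next_id + n_recruits,
    )

    origin_totals = recruit_counts.sum(axis=0)
    record = EventRecord(
        event_index=event_index,
        abundances=tuple(int(a) for a in updated.abundances),
        richness=updated.richness,
        n_deaths=n_deaths,
        recruit_counts_by_origin={
            o.label: int(t) for o, t in zip(_BANK_ORIGINS, origin_totals)
        },
        seed_bank_size=bank.size,
        shortfall_flag=shortfall,
    )
    return updated, record


def run_simulation(
    params: MatingParams,
    seed: int,
    stop_at_monodominance: bool = False,
) -> Trajectory:
    """Run the full event loop; deterministic given ``(params, seed)``.

    With ``stop_at_monodominance`` the run ends early once a single
    species remains (richness can only stay flat afterwards), in which
    case the trajectory is shorter than ``params.n_events``.
    """
    rng = np.random.default_rng(seed)
    community = Community.from_abundances(params.initial_abundances)
    traj = Trajectory(params=params, seed=seed)
    prev_richness = community.richness
    for t in range(params.n_events):
        if community.size == 0:
            logger.warning("community fully extinct at event %d; stopping", t)
            break
        community, record = run_event(community, params, rng, event_index=t)
        traj.events.append(record)
        if record.richness < prev_richness:
            gone = prev_richness - record.richness
            logger.info("event %d: %d species extinct, richness %d", t, gone, record.richness)
            prev_richness = record.richness
        if stop_at_monodominance and record.richness <= 1:
            break
    traj.final_community = community
    return traj
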