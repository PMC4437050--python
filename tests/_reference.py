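"""Naive object-level reference implementation of the event loop.

Composes only the per-individual public API (sample_donors,
reproduce_individual) with explicit Progeny lists, for cross-checking the
vectorized engine's distributional behavior on tiny communities.  Slow by
design; never used outside tests.
"""

from __future__ import annotations

import numpy as np

from syngameon.model_core import (
    Community,
    MatingParams,
    Origin,
    Progeny,
    donor_count,
    reproduce_individual,
    sample_donors,
)

ORIGIN_COLS = (Origin.OUTCROSS, Origin.HYBRID, Origin.SELF)


def naive_seed_bank(
    community: Community, params: MatingParams, rng: np.random.Generator
) -> list[Progeny]:
    """Step One via the object API: every individual reproduces, pooled."""
    nd = donor_count(params.plc, community.size)
    bank: list[Progeny] = []
    for mother in community.individuals():
        donors = sample_donors(community, mother, nd, rng)
        bank.extend(reproduce_individual(mother, donors, params, rng))
    return bank


def bank_counts(bank: list[Progeny], n_species: int) -> np.ndarray:
    """(n_species, 3) counts matching the engine's SeedBank layout."""
    counts = np.zeros((n_species, 3), dtype=np.int64)
    for p in bank:
        counts[p.species, ORIGIN_COLS.index(p.origin)] += 1
    return counts


def naive_run(params: MatingParams, seed: int) -> list[int]:
    """Full three-step loop on Progeny objects; returns richness series."""
    rng = np.random.default_rng(seed)
    community = Community.from_abundances(params.initial_abundances)
    richness = []
    next_id = community.size
    for _ in range(params.n_events):
        bank = naive_seed_bank(community, params, rng)
        n_deaths = int(np.floor(params.mortality_rate * community.size + 0.5 + 1e-9))
        dead = rng.choice(community.size, size=min(n_deaths, community.size), replace=False)
        n_rec = min(len(dead), len(bank))
        recruits = [bank[i] for i in rng.choice(len(bank), size=n_rec, replace=False)] if bank else []
        keep = np.ones(community.size, dtype=bool)
        keep[dead] = False
        ids = list(community.ids[keep]) + list(range(next_id, next_id + n_rec))
        species = list(community.species[keep]) + [r.species for r in recruits]
        ages = list(community.ages[keep] + 1) + [0] * n_rec
        origins = list(community.origins[keep]) + [int(r.origin) for r in recruits]
        next_id += n_rec
        community = Community(
            n_species=community.n_species,
            ids=np.array(ids), species=np.array(species),
            ages=np.array(ages), origins=np.array(origins),
            next_id=next_id,
        )
        richness.append(community.richness)
    return richness
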