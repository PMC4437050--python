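"""Synthetic stem-mapped plots with tropical-forest-like structure.

Generates plots that carry the statistical features the neighborhood
analysis assumes: clumped conspecific distributions (Thomas cluster
process per species), strongly skewed abundances (log-series, optionally
truncated so no species dominates), and genus structure in which most
species co-occur with two or more congeners.  These are synthetic
stand-ins for a real 50-ha census, generated at whatever scale a test or
demo needs; no claim is made of matching fitted point-process parameters
of any real plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import StemTable

__all__ = ["PlotSpec", "generate_plot", "pasoh_like_spec"]

#: Fraction of species with 0, 1, 2, ... sympatric congeners (index k =
#: genus of k+1 species), echoing large Asian plots where ~19% of species
#: are the sole representative of their genus and ~two-thirds have >= 2
#: congeners.  Genus-size sampling weights are derived as fraction/size.
_GENUS_SPECIES_FRACTIONS = np.array(
    [0.19, 0.13, 0.12, 0.10, 0.08, 0.07, 0.06, 0.05, 0.05, 0.04, 0.04, 0.03, 0.02, 0.02]
)
_GENUS_SIZE_VALUES = np.arange(1, len(_GENUS_SPECIES_FRACTIONS) + 1)
_GENUS_SIZE_WEIGHTS = _GENUS_SPECIES_FRACTIONS / _GENUS_SIZE_VALUES
_GENUS_SIZE_WEIGHTS = _GENUS_SIZE_WEIGHTS / _GENUS_SIZE_WEIGHTS.sum()


@dataclass(frozen=True)
class PlotSpec:
    """Specification of a synthetic stem-mapped plot.

    Defaults describe a 50-ha plot (1000 m x 500 m).  Abundances come
    either from an explicit vector or a log-series draw (``logser_p``)
    scaled to ``total_stems``; ``max_relative_abundance`` truncates the
    head of the distribution, redistributing excess stems to rarer
    species, so that no species exceeds the given share.  Clustering is a
    Thomas process: per species, ``n_parents`` uniform parent points,
    stems scattered isotropic Gaussian(``sigma``) around a random parent,
    out-of-bounds offsets resampled so abundances stay exact.
    ``sigma=None`` disables clustering (uniform positions).
    """

    width: float = 1000.0
    height: float = 500.0
    n_species: int = 60
    abundances: tuple[int, ...] | None = None
    total_stems: int = 5000
    logser_p: float = 0.995
    max_relative_abundance: float | None = None
    n_parents: int = 8
    sigma: float | None = 20.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.abundances is not None:
            ab = tuple(int(a) for a in self.abundances)
            if any(a <= 0 for a in ab):
                raise ValueError("all abundances must be positive")
            object.__setattr__(self, "abundances", ab)
            object.__setattr__(self, "n_species", len(ab))
            object.__setattr__(self, "total_stems", sum(ab))
        elif self.total_stems < self.n_species:
            raise ValueError("total_stems must be at least n_species")
        if self.max_relative_abundance is not None:
            cap = int(np.floor(self.max_relative_abundance * self.total_stems))
            if cap * self.n_species < self.total_stems:
                raise ValueError(
                    "max_relative_abundance too small to place all stems"
                )
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive (or None for no clustering)")
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")


def pasoh_like_spec(**overrides) -> PlotSpec:
    """A desk-scale preset echoing a large tropical plot's structure.

    150 species, 12000 stems over 50 ha with log-series abundance skew
    truncated at 2.5% relative abundance (the dominant species of a very
    diverse plot holds under 3% of stems) and clumped distributions.
    """
    defaults = dict(
        n_species=150,
        total_stems=12000,
        logser_p=0.995,
        max_relative_abundance=0.025,
        n_parents=10,
        sigma=25.0,
    )
    defaults.update(overrides)
    return PlotSpec(**defaults)


def _fix_total(ab: np.ndarray, total: int) -> np.ndarray:
    """Nudge rounded abundances so they sum exactly to ``total``."""
    diff = total - int(ab.sum())
    step = 1 if diff > 0 else -1
    while diff != 0:
        i = int(np.argmax(ab)) if step > 0 else int(np.argmax(ab * (ab > 1)))
        if step < 0 and ab[i] <= 1:
            raise ValueError("cannot reduce abundances below 1")
        ab[i] += step
        diff -= step
    return ab


def _draw_abundances(spec: PlotSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.abundances is not None:
        return np.array(spec.abundances, dtype=np.int64)
    raw = stats.logser.rvs(spec.logser_p, size=spec.n_species, random_state=rng)
    ab = np.maximum(1, np.round(raw / raw.sum() * spec.total_stems)).astype(np.int64)
    _fix_total(ab, spec.total_stems)
    if spec.max_relative_abundance is not None:
        cap = int(np.floor(spec.max_relative_abundance * spec.total_stems))
        while ab.max() > cap:
            over = ab > cap
            excess = int((ab[over] - cap).sum())
            ab[over] = cap
            under = np.flatnonzero(ab < cap)
            # spread excess over the under-cap species, rarest first
            order = under[np.argsort(ab[under])]
            per = excess // len(order)
            ab[order] += per
            ab[order[: excess - per * len(order)]] += 1
    return ab


def _genus_sizes(n_species: int) -> list[int]:
    """Quota-based genus sizes matching the target sympatry fractions.

    The number of genera of each size is the rounded quota implied by the
    species-level fractions; singleton genera absorb the rounding residue
    so the sizes sum exactly to ``n_species``.
    """
    counts = [
        int(round(n_species * f / k))
        for f, k in zip(_GENUS_SPECIES_FRACTIONS, _GENUS_SIZE_VALUES)
    ]
    sizes: list[int] = []
    for k, c in zip(_GENUS_SIZE_VALUES, counts):
        sizes.extend([int(k)] * c)
    diff = n_species - sum(sizes)
    while diff > 0:
        sizes.append(1)
        diff -= 1
    while diff < 0:
        # shrink the largest genus (drop it entirely if need be)
        sizes.sort()
        take = min(-diff, sizes[-1])
        if take == sizes[-1]:
            sizes.pop()
        else:
            sizes[-1] -= take
        diff += take
    return sorted(sizes, reverse=True)


def _assign_genera(n_species: int, rng: np.random.Generator) -> list[str]:
    """Assign each species a genus; order shuffled so abundance rank and
    genus size are uncorrelated."""
    genus_of_species: list[str] = []
    for g, size in enumerate(_genus_sizes(n_species)):
        genus_of_species.extend([f"G{g:03d}"] * size)
    order = rng.permutation(n_species)
    return [genus_of_species[i] for i in order]


def _thomas_positions(
    n: int, spec: PlotSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Thomas cluster process positions for one species, exact count n."""
    if spec.sigma is None:
        return rng.uniform(0, spec.width, n), rng.uniform(0, spec.height, n)
    px = rng.uniform(0, spec.width, spec.n_parents)
    py = rng.uniform(0, spec.height, spec.n_parents)
    parent = rng.integers(0, spec.n_parents, n)
    x = px[parent] + rng.normal(0, spec.sigma, n)
    y = py[parent] + rng.normal(0, spec.sigma, n)
    # resample out-of-bounds offsets (not clip) so abundances stay exact
    # and no artificial edge pile-up appears
    bad = (x < 0) | (x > spec.width) | (y < 0) | (y > spec.height)
    while bad.any():
        k = int(bad.sum())
        x[bad] = px[parent[bad]] + rng.normal(0, spec.sigma, k)
        y[bad] = py[parent[bad]] + rng.normal(0, spec.sigma, k)
        bad = (x < 0) | (x > spec.width) | (y < 0) | (y > spec.height)
    return x, y


def generate_plot(spec: PlotSpec, seed: int | None = None) -> StemTable:
    """Generate a synthetic stem table; deterministic given ``seed``.

    Abundances match the spec exactly, all coordinates lie in bounds, and
    each species belongs to exactly one genus.
    """
    rng = np.random.default_rng(seed)
    ab = _draw_abundances(spec, rng)
    genera = _assign_genera(len(ab), rng)

    frames = []
    stem_id = 0
    for k, n_k in enumerate(ab):
        x, y = _thomas_positions(int(n_k), spec, rng)
        frames.append(
            pd.DataFrame(
                {
                    "stem_id": np.arange(stem_id, stem_id + n_k),
                    "x": x,
                    "y": y,
                    "species": f"S{k:03d}",
                    "genus": genera[k],
                }
            )
        )
        stem_id += int(n_k)
    stems = pd.concat(frames, ignore_index=True)
    return StemTable(stems, width=spec.width, height=spec.height)
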