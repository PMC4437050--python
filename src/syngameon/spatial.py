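"""Neighborhood censuses and spatial null models for stem-mapped plots.

Works on ForestGEO-style stem tables (stem id, x/y position in meters,
species and genus codes).  The central question is how often a focal tree
encounters conspecifics and congenerics within a fixed radius, and whether
observed local species richness is lower than expected were species labels
unrelated to location — the signature of clumped conspecific distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "StemTable",
    "NeighborhoodStats",
    "NullModelResult",
    "neighborhood_census",
    "select_focals",
    "sympatry_summary",
    "richness_null_model",
    "DEFAULT_DIVERSITY_CLASSES",
]

logger = logging.getLogger(__name__)

#: Congeneric-diversity classes (inclusive ranges of species per genus)
#: used to stratify focal-tree selection.
DEFAULT_DIVERSITY_CLASSES: tuple[tuple[int, int], ...] = ((2, 2), (3, 3), (5, 6), (10, 14))

_CANON_COLS = ["stem_id", "x", "y", "species", "genus"]
_ALIASES = {"gx": "x", "gy": "y", "sp": "species", "tag": "stem_id"}


@dataclass
class StemTable:
    """A stem-mapped plot census.

    ``stems`` holds one row per stem with columns
    ``stem_id, x, y, species, genus`` (meters; species/genus are string
    codes, each species belonging to exactly one genus).
    """

    stems: pd.DataFrame
    width: float
    height: float

    def __post_init__(self) -> None:
        df = self.stems.rename(columns=_ALIASES).copy()
        missing = [c for c in _CANON_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"stem table missing columns: {missing}")
        df = df[_CANON_COLS]
        if df["stem_id"].duplicated().any():
            raise ValueError("stem ids must be unique")
        x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
        if (x < 0).any() or (x > self.width).any() or (y < 0).any() or (y > self.height).any():
            raise ValueError("stem coordinates fall outside the plot bounds")
        genus_per_species = df.groupby("species")["genus"].nunique()
        bad = genus_per_species[genus_per_species > 1]
        if len(bad):
            raise ValueError(f"species mapped to multiple genera: {list(bad.index)}")
        self.stems = df.reset_index(drop=True)
        self._tree: cKDTree | None = None

    def __len__(self) -> int:
        return len(self.stems)

    @property
    def coords(self) -> np.ndarray:
        return self.stems[["x", "y"]].to_numpy(float)

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    def species_of_genus(self) -> pd.Series:
        """Number of distinct species per genus present in the plot."""
        return self.stems.drop_duplicates("species").groupby("genus")["species"].count()

    @classmethod
    def from_csv(cls, path: str | Path, width: float | None = None, height: float | None = None) -> "StemTable":
        """Read a stem table CSV (``gx``/``gy`` accepted as x/y aliases).

        Plot dimensions default to the maximum observed coordinates when
        not given.
        """
        df = pd.read_csv(path).rename(columns=_ALIASES)
        if width is None:
            width = float(df["x"].max())
        if height is None:
            height = float(df["y"].max())
        return cls(df, width=width, height=height)

    def to_csv(self, path: str | Path) -> None:
        self.stems.to_csv(path, index=False)


@dataclass(frozen=True)
class NeighborhoodStats:
    """Census of the neighborhood around one focal stem."""

    focal_id: object
    radius: float
    n_neighbors: int
    n_species: int
    n_conspecific: int
    n_congeneric: int


@dataclass
class NullModelResult:
    """Observed vs null mean neighborhood richness under label permutation."""

    observed_mean_richness: float
    null_mean_richness: float
    null_distribution: np.ndarray
    p_value: float
    n_reps: int

    def summary(self) -> str:
        return (
            f"observed mean neighborhood richness: {self.observed_mean_richness:.2f}\n"
            f"null mean (over {self.n_reps} permutations): {self.null_mean_richness:.2f}\n"
            f"one-sided P(null <= observed) = {self.p_value:.4f}"
        )


def _neighbor_indices(table: StemTable, focal_idx: int, radius: float) -> np.ndarray:
    idx = table.kdtree.query_ball_point(table.coords[focal_idx], r=radius)
    return np.array([i for i in idx if i != focal_idx], dtype=np.int64)


def neighborhood_census(table: StemTable, focal_id: object, radius: float) -> NeighborhoodStats:
    """Count neighbors, species, conspecifics and congenerics around a focal.

    Neighbors are stems at Euclidean distance <= radius, the focal itself
    excluded.  Congeneric counts exclude conspecifics.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    matches = np.flatnonzero(table.stems["stem_id"].to_numpy() == focal_id)
    if len(matches) == 0:
        raise KeyError(f"no stem with id {focal_id!r}")
    fi = int(matches[0])
    nbr = _neighbor_indices(table, fi, radius)
    if len(nbr) == 0:
        return NeighborhoodStats(focal_id, radius, 0, 0, 0, 0)
    sp = table.stems["species"].to_numpy()
    gen = table.stems["genus"].to_numpy()
    nbr_sp, nbr_gen = sp[nbr], gen[nbr]
    n_con = int((nbr_sp == sp[fi]).sum())
    n_cong = int(((nbr_gen == gen[fi]) & (nbr_sp != sp[fi])).sum())
    return NeighborhoodStats(
        focal_id=focal_id,
        radius=radius,
        n_neighbors=len(nbr),
        n_species=int(len(np.unique(nbr_sp))),
        n_conspecific=n_con,
        n_congeneric=n_cong,
    )


def select_focals(
    table: StemTable,
    per_species: int = 15,
    top_species: int = 10,
    diversity_classes: Sequence[tuple[int, int]] = DEFAULT_DIVERSITY_CLASSES,
    edge_buffer: float = 25.0,
    seed: int | None = None,
) -> list:
    """Pick focal stems stratified by congeneric diversity class.

    Within each class (an inclusive range of species-per-genus), the
    ``top_species`` most abundant qualifying species are taken and
    ``per_species`` interior stems (at least ``edge_buffer`` from every
    plot boundary) sampled per species.  Deterministic given ``seed``.
    Under-filled classes are logged, not fatal.
    """
    rng = np.random.default_rng(seed)
    df = table.stems
    interior = (
        (df["x"] >= edge_buffer)
        & (df["x"] <= table.width - edge_buffer)
        & (df["y"] >= edge_buffer)
        & (df["y"] <= table.height - edge_buffer)
    )
    if not interior.any():
        logger.warning("edge buffer %.1f m leaves no interior stems", edge_buffer)
        return []
    genus_sizes = table.species_of_genus()
    sp_genus = df.drop_duplicates("species").set_index("species")["genus"]
    sp_class_size = sp_genus.map(genus_sizes)
    abundance = df["species"].value_counts()

    focals: list = []
    for lo, hi in diversity_classes:
        qualifying = sp_class_size[(sp_class_size >= lo) & (sp_class_size <= hi)].index
        ranked = abundance[abundance.index.isin(qualifying)].index[:top_species]
        if len(ranked) < top_species:
            logger.warning(
                "diversity class %d-%d under-filled: %d of %d species qualify",
                lo, hi, len(ranked), top_species,
            )
        for sp in ranked:
            pool = df.index[interior & (df["species"] == sp)].to_numpy()
            k = min(per_species, len(pool))
            if k < per_species:
                logger.warning(
                    "species %r: only %d interior stems for %d requested focals",
                    sp, len(pool), per_species,
                )
            if k == 0:
                continue
            chosen = rng.choice(pool, size=k, replace=False)
            focals.extend(df.loc[chosen, "stem_id"].tolist())
    return focals


def sympatry_summary(table: StemTable) -> pd.DataFrame:
    """Partition species by how many sympatric congeners they have.

    Rows: 0, 1 and >=2 congeners, with species counts and fractions
    (fractions sum to 1).
    """
    genus_sizes = table.species_of_genus()
    sp_genus = table.stems.drop_duplicates("species").set_index("species")["genus"]
    congeners = sp_genus.map(genus_sizes) - 1
    n = len(congeners)
    counts = {
        "0": int((congeners == 0).sum()),
        "1": int((congeners == 1).sum()),
        ">=2": int((congeners >= 2).sum()),
    }
    return pd.DataFrame(
        {
            "n_congeners": list(counts.keys()),
            "n_species": list(counts.values()),
            "fraction": [c / n for c in counts.values()],
        }
    )


def richness_null_model(
    table: StemTable,
    focals: Sequence,
    radius: float,
    n_reps: int = 1000,
    seed: int | None = None,
    method: str = "label_permutation",
) -> NullModelResult:
    """Test whether observed neighborhood richness is lower than expected.

    Each replicate destroys the species–location association while keeping
    stem positions and the abundance distribution fixed:

    - ``label_permutation`` (default): permute species labels (genus labels
      travel with their species) uniformly over the stem positions.
    - ``relocate``: redraw every stem position uniformly in the plot,
      keeping labels.

    The statistic is the mean over focals of species richness within
    ``radius``.  One-sided lower-tail p-value with the +1 permutation
    correction: ``(1 + #{null <= observed}) / (n_reps + 1)``.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if method not in ("label_permutation", "relocate"):
        raise ValueError(f"unknown null model method {method!r}")
    rng = np.random.default_rng(seed)
    df = table.stems
    ids = df["stem_id"].to_numpy()
    focal_idx = []
    for f in focals:
        m = np.flatnonzero(ids == f)
        if len(m) == 0:
            raise KeyError(f"no stem with id {f!r}")
        focal_idx.append(int(m[0]))

    species_codes, _ = pd.factorize(df["species"])
    nbrs = [_neighbor_indices(table, fi, radius) for fi in focal_idx]

    def mean_richness(codes: np.ndarray, neighbor_lists: list[np.ndarray]) -> float:
        return float(
            np.mean([len(np.unique(codes[nb])) if len(nb) else 0 for nb in neighbor_lists])
        )

    observed = mean_richness(species_codes, nbrs)
    null = np.empty(n_reps)
    if method == "label_permutation":
        for r in range(n_reps):
            perm = rng.permutation(len(df))
            null[r] = mean_richness(species_codes[perm], nbrs)
    else:
        for r in range(n_reps):
            pts = np.column_stack(
                [rng.uniform(0, table.width, len(df)), rng.uniform(0, table.height, len(df))]
            )
            tree = cKDTree(pts)
            lists = [
                np.array([i for i in tree.query_ball_point(pts[fi], r=radius) if i != fi], dtype=np.int64)
                for fi in focal_idx
            ]
            null[r] = mean_richness(species_codes, lists)

    p = (1 + int((null <= observed).sum())) / (n_reps + 1)
    return NullModelResult(
        observed_mean_richness=observed,
        null_mean_richness=float(null.mean()),
        null_distribution=null,
        p_value=p,
        n_reps=n_reps,
    )
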