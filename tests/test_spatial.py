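"""Tests for neighborhood censuses, sympatry summaries and the null model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syngameon.spatial import (
    StemTable,
    neighborhood_census,
    richness_null_model,
    select_focals,
    sympatry_summary,
)
from syngameon.synthetic_plot import PlotSpec, generate_plot


def brute_force_census(table, focal_id, radius):
    """O(n^2)-style reference scan with explicit distances."""
    df = table.stems
    frow = df[df.stem_id == focal_id].iloc[0]
    n_nbr = n_sp = n_con = n_cong = 0
    seen = set()
    for row in df.itertuples(index=False):
        if row.stem_id == focal_id:
            continue
        d = np.hypot(row.x - frow.x, row.y - frow.y)
        if d <= radius:
            n_nbr += 1
            seen.add(row.species)
            if row.species == frow.species:
                n_con += 1
            elif row.genus == frow.genus:
                n_cong += 1
    return n_nbr, len(seen), n_con, n_cong


def random_table(seed, n=80, n_species=6, width=100.0):
    rng = np.random.default_rng(seed)
    species = [f"S{k}" for k in rng.integers(0, n_species, n)]
    genus = [sp if int(sp[1]) % 2 else "G0" for sp in species]  # shared genus G0
    df = pd.DataFrame(
        {
            "stem_id": np.arange(n),
            "x": rng.uniform(0, width, n),
            "y": rng.uniform(0, width, n),
            "species": species,
            "genus": genus,
        }
    )
    return StemTable(df, width=width, height=width)


class TestCensus:
    def test_toy_layout_counts(self, toy_stems):
        # neighbors of stem 0 within 25 m: stems 1 (conspecific, 10 m),
        # 2 (congeneric, 20 m), 3 (other genus, 5 m), 4 (conspecific,
        # exactly 25 m -- boundary included); stem 5 is outside
        stats = neighborhood_census(toy_stems, 0, radius=25.0)
        assert stats.n_neighbors == 4
        assert stats.n_species == 3
        assert stats.n_conspecific == 2
        assert stats.n_congeneric == 1

    def test_boundary_distance_included(self, toy_stems):
        assert neighborhood_census(toy_stems, 0, 25.0).n_neighbors == 4
        assert neighborhood_census(toy_stems, 0, 24.999).n_neighbors == 3

    def test_isolated_focal(self, toy_stems):
        stats = neighborhood_census(toy_stems, 5, radius=5.0)
        assert (stats.n_neighbors, stats.n_species) == (0, 0)
        assert (stats.n_conspecific, stats.n_congeneric) == (0, 0)

    def test_unknown_focal(self, toy_stems):
        with pytest.raises(KeyError):
            neighborhood_census(toy_stems, 99, 25.0)

    @given(seed=st.integers(0, 1000), radius=st.floats(5.0, 60.0))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_scan(self, seed, radius):
        table = random_table(seed)
        focal = int(table.stems.stem_id.iloc[seed % len(table)])
        stats = neighborhood_census(table, focal, radius)
        assert (
            stats.n_neighbors, stats.n_species, stats.n_conspecific, stats.n_congeneric
        ) == brute_force_census(table, focal, radius)

    def test_congeneric_excludes_conspecific(self, toy_stems):
        stats = neighborhood_census(toy_stems, 0, radius=25.0)
        assert stats.n_conspecific + stats.n_congeneric <= stats.n_neighbors


class TestStemTable:
    def test_gx_gy_aliases_roundtrip(self, tmp_path, toy_stems):
        path = tmp_path / "stems.csv"
        renamed = toy_stems.stems.rename(columns={"x": "gx", "y": "gy"})
        renamed.to_csv(path, index=False)
        loaded = StemTable.from_csv(path, width=100, height=100)
        pd.testing.assert_frame_equal(loaded.stems, toy_stems.stems)

    def test_species_in_two_genera_rejected(self):
        df = pd.DataFrame(
            {
                "stem_id": [0, 1], "x": [1.0, 2.0], "y": [1.0, 2.0],
                "species": ["Sa", "Sa"], "genus": ["G1", "G2"],
            }
        )
        with pytest.raises(ValueError, match="multiple genera"):
            StemTable(df, width=10, height=10)

    def test_out_of_bounds_rejected(self):
        df = pd.DataFrame(
            {
                "stem_id": [0], "x": [11.0], "y": [1.0],
                "species": ["Sa"], "genus": ["G"],
            }
        )
        with pytest.raises(ValueError, match="bounds"):
            StemTable(df, width=10, height=10)


class TestSelectFocals:
    def test_buffer_wider_than_plot_empty(self, toy_stems):
        assert select_focals(toy_stems, edge_buffer=60.0, seed=0) == []

    def test_deterministic_given_seed(self):
        table = generate_plot(
            PlotSpec(n_species=20, total_stems=600, width=200, height=200, sigma=15), seed=4
        )
        f1 = select_focals(table, per_species=3, top_species=3, edge_buffer=25, seed=9)
        f2 = select_focals(table, per_species=3, top_species=3, edge_buffer=25, seed=9)
        assert f1 == f2 and len(f1) > 0

    def test_small_species_fully_selected(self):
        # per-species count above a species' interior abundance: take all
        df = pd.DataFrame(
            {
                "stem_id": range(6),
                "x": [50, 60, 70, 50, 60, 70],
                "y": [50.0] * 6,
                "species": ["Sa"] * 3 + ["Sb"] * 3,
                "genus": ["G"] * 6,
            }
        )
        table = StemTable(df, width=120, height=100)
        focals = select_focals(
            table, per_species=10, top_species=2,
            diversity_classes=((2, 2),), edge_buffer=10, seed=0,
        )
        assert sorted(focals) == list(range(6))

    def test_classes_match_genus_sizes(self):
        table = generate_plot(
            PlotSpec(n_species=40, total_stems=2000, width=300, height=300, sigma=20), seed=2
        )
        genus_sizes = table.species_of_genus()
        sp_genus = table.stems.drop_duplicates("species").set_index("species")["genus"]
        focals = select_focals(
            table, per_species=2, top_species=3,
            diversity_classes=((2, 2),), edge_buffer=20, seed=1,
        )
        st_df = table.stems.set_index("stem_id")
        for f in focals:
            assert genus_sizes[sp_genus[st_df.loc[f, "species"]]] == 2


class TestSympatry:
    def test_all_distinct_genera(self):
        df = pd.DataFrame(
            {
                "stem_id": range(3), "x": [1.0, 2.0, 3.0], "y": [1.0] * 3,
                "species": ["Sa", "Sb", "Sc"], "genus": ["G1", "G2", "G3"],
            }
        )
        summary = sympatry_summary(StemTable(df, width=10, height=10))
        assert summary.set_index("n_congeners")["fraction"]["0"] == 1.0

    def test_one_big_genus(self):
        df = pd.DataFrame(
            {
                "stem_id": range(4), "x": [1.0, 2.0, 3.0, 4.0], "y": [1.0] * 4,
                "species": ["Sa", "Sb", "Sc", "Sd"], "genus": ["G"] * 4,
            }
        )
        summary = sympatry_summary(StemTable(df, width=10, height=10))
        by = summary.set_index("n_congeners")
        assert by["fraction"]["0"] == 0.0 and by["fraction"][">=2"] == 1.0

    def test_fractions_sum_to_one(self):
        table = generate_plot(PlotSpec(n_species=50, total_stems=800, sigma=None), seed=3)
        assert sympatry_summary(table)["fraction"].sum() == pytest.approx(1.0)


class TestNullModel:
    def test_single_species_p_is_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "stem_id": range(50),
                "x": rng.uniform(0, 100, 50), "y": rng.uniform(0, 100, 50),
                "species": ["Sa"] * 50, "genus": ["G"] * 50,
            }
        )
        table = StemTable(df, width=100, height=100)
        res = richness_null_model(table, [0, 1, 2], radius=30, n_reps=49, seed=1)
        assert res.p_value == 1.0
        assert (res.null_distribution == res.observed_mean_richness).all()

    def test_invalid_reps(self, toy_stems):
        with pytest.raises(ValueError, match="n_reps"):
            richness_null_model(toy_stems, [0], 25.0, n_reps=0)

    def test_permutation_preserves_abundances(self):
        # the permuted label multiset is identical, so total stems per
        # species never change under the null
        table = random_table(7)
        counts = table.stems["species"].value_counts()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        permuted = table.stems["species"].to_numpy()[perm]
        assert (
            pd.Series(permuted).value_counts().sort_index().equals(counts.sort_index())
        )

    def test_clustered_plot_richness_below_null(self):
        """Clumped conspecific distributions depress local richness
        relative to the label-permutation null."""
        spec = PlotSpec(n_species=30, total_stems=2000, width=400, height=400,
                        sigma=15.0, n_parents=5)
        table = generate_plot(spec, seed=1)
        focals = select_focals(table, per_species=5, top_species=5,
                               edge_buffer=25, seed=1)
        res = richness_null_model(table, focals, radius=25, n_reps=199, seed=1)
        assert res.observed_mean_richness < res.null_mean_richness
        assert res.p_value < 0.05

    def test_uniform_plot_not_extreme(self):
        """With no clustering, observed richness sits inside the bulk of
        the null distribution."""
        spec = PlotSpec(n_species=20, total_stems=1500, width=400, height=400, sigma=None)
        table = generate_plot(spec, seed=5)
        rng = np.random.default_rng(6)
        st_df = table.stems
        interior = st_df[st_df.x.between(25, 375) & st_df.y.between(25, 375)]
        focals = list(rng.choice(interior.stem_id.to_numpy(), 20, replace=False))
        res = richness_null_model(table, focals, radius=25, n_reps=199, seed=7)
        lo, hi = np.quantile(res.null_distribution, [0.025, 0.975])
        assert lo <= res.observed_mean_richness <= hi

    def test_relocation_null_runs(self, toy_stems):
        res = richness_null_model(toy_stems, [0], radius=25, n_reps=19, seed=3,
                                  method="relocate")
        assert 0 < res.p_value <= 1
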