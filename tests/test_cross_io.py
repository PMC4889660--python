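"""csvr round-trips, genotype coding, two-point rf estimation, marker QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgqtl import (
    GeneticMap,
    SimConfig,
    default_map,
    haldane,
    pairwise_recombination_fraction,
    qc_filter,
    read_csvr,
    simulate_f2_population,
    write_csvr,
)
from sgqtl.cross_io import MISSING, CrossParseError
from sgqtl.simdata import _simulate_gametes

from conftest import make_population

HANDCRAFTED = (
    "protein,,,412.5,455,430.1\n"
    "oil,,,190,178.2,183\n"
    "m1,1,0,A,H,B\n"
    "m2,1,12.5,H,-,B\n"
)


class TestCsvrIO:
    def test_handcrafted_round_trip_is_byte_identical(self, tmp_path):
        src = tmp_path / "hand.csv"
        src.write_text(HANDCRAFTED)
        pop = read_csvr(src)
        assert pop.n_individuals == 3
        assert pop.map.markers("1") == ["m1", "m2"]
        out = tmp_path / "out.csv"
        write_csvr(pop, out)
        assert out.read_text() == HANDCRAFTED

    def test_simulated_round_trip_recovers_everything(self, tmp_path, small_map):
        pop = simulate_f2_population(
            SimConfig(map=small_map, n_progeny=40, seed=5, missing_rate=0.05)
        )
        path = tmp_path / "sim.csv"
        write_csvr(pop, path, header_comment="seed: 5")
        back = read_csvr(path)
        assert np.array_equal(back.genotypes.to_numpy(), pop.genotypes.to_numpy())
        assert back.map == pop.map
        np.testing.assert_allclose(
            back.phenotypes[["protein", "oil"]].to_numpy(),
            pop.phenotypes[["protein", "oil"]].to_numpy(),
        )

    def test_unknown_genotype_code_names_marker_and_column(self, tmp_path):
        bad = HANDCRAFTED.replace("m2,1,12.5,H,-,B", "m2,1,12.5,H,C,B")
        src = tmp_path / "bad.csv"
        src.write_text(bad)
        with pytest.raises(CrossParseError, match=r"m2.*column 5|column 5.*m2"):
            read_csvr(src)

    def test_duplicate_marker_rejected(self, tmp_path):
        src = tmp_path / "dup.csv"
        src.write_text(HANDCRAFTED.replace("m2,", "m1,", 1))
        with pytest.raises(CrossParseError, match="duplicate"):
            read_csvr(src)

    def test_ragged_row_rejected(self, tmp_path):
        src = tmp_path / "ragged.csv"
        src.write_text(HANDCRAFTED.replace("m2,1,12.5,H,-,B", "m2,1,12.5,H,-"))
        with pytest.raises(CrossParseError, match="ragged"):
            read_csvr(src)

    def test_all_missing_individual_keeps_phenotype_unflagged(self, tmp_path):
        text = (
            "protein,,,400,410,420\n"
            "m1,1,0,A,-,B\n"
            "m2,1,5,H,-,B\n"
        )
        src = tmp_path / "miss.csv"
        src.write_text(text)
        pop = read_csvr(src)
        assert pop.phenotypes["genotyped"].tolist() == [True, False, True]
        assert pop.phenotypes["protein"].iloc[1] == 410

    def test_en_dash_parses_as_missing(self, tmp_path):
        src = tmp_path / "dash.csv"
        src.write_text(HANDCRAFTED.replace("H,-,B", "H,–,B"))
        pop = read_csvr(src)
        assert pop.genotypes.iloc[1, 1] == MISSING

    def test_unsorted_map_rejected(self, tmp_path):
        src = tmp_path / "unsorted.csv"
        src.write_text(HANDCRAFTED.replace("m2,1,12.5", "m2,1,-3"))
        with pytest.raises(CrossParseError, match="not sorted"):
            read_csvr(src)


def _f2_pair(r_cm: float, n: int, seed: int) -> np.ndarray:
    cm = np.array([0.0, r_cm])
    rng = np.random.default_rng(seed)
    return (
        _simulate_gametes(cm, n, rng) + _simulate_gametes(cm, n, rng)
    ).astype(int)


class TestRecombinationFraction:
    def test_identical_columns_estimate_zero(self):
        g = _f2_pair(10.0, 500, 1)[:, 0]
        assert pairwise_recombination_fraction(g, g) < 1e-8

    def test_phase_flip_pushes_estimate_above_half(self):
        g = _f2_pair(10.0, 1000, 2)
        rf = pairwise_recombination_fraction(g[:, 0], 2 - g[:, 1])
        assert rf > 0.8

    def test_ten_cm_matches_haldane(self):
        g = _f2_pair(10.0, 2000, 3)
        rf = pairwise_recombination_fraction(g[:, 0], g[:, 1])
        r = haldane(10.0)
        se = np.sqrt(r * (1 - r) / (2 * 2000))  # two informative gametes each
        assert abs(rf - r) < 4 * se

    def test_insufficient_pairs_raises(self):
        g = np.array([0, 1, 2, 0, 1] + [MISSING] * 10)
        with pytest.raises(ValueError, match="insufficient"):
            pairwise_recombination_fraction(g, g)

    @given(
        st.lists(st.integers(min_value=0, max_value=2), min_size=20, max_size=60),
        st.lists(st.integers(min_value=0, max_value=2), min_size=20, max_size=60),
    )
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_joint_phase_flip_invariance(self, a, b):
        n = min(len(a), len(b))
        g1 = np.array(a[:n])
        g2 = np.array(b[:n])
        r12 = pairwise_recombination_fraction(g1, g2)
        r21 = pairwise_recombination_fraction(g2, g1)
        r_flip = pairwise_recombination_fraction(2 - g1, 2 - g2)
        assert r12 == pytest.approx(r21, abs=1e-9)
        assert r12 == pytest.approx(r_flip, abs=1e-9)


class TestQCFilter:
    def test_monomorphic_marker_removed_and_reported(self, small_map):
        rng = np.random.default_rng(4)
        geno = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(80, small_map.n_markers))
        geno[:, 3] = 2  # render one marker monomorphic
        pop = make_population(small_map, geno, 400 + rng.normal(size=80))
        filtered, report = qc_filter(pop)
        dropped = small_map.marker_names[3]
        assert dropped not in filtered.genotypes.columns
        assert dropped in set(report.removed["marker"])
        assert (report.removed["reason"] == "monomorphic").any()

    def test_phase_flipped_marker_removed_neighbours_kept(self, small_map):
        pop = simulate_f2_population(
            SimConfig(map=small_map, n_progeny=300, bimorphic_fraction=1.0,
                      missing_rate=0.0, seed=6)
        )
        markers = small_map.markers("1")
        victim = markers[3]
        pop.genotypes[victim] = 2 - pop.genotypes[victim]
        filtered, report = qc_filter(pop)
        assert victim not in filtered.genotypes.columns
        assert markers[2] in filtered.genotypes.columns
        assert markers[4] in filtered.genotypes.columns
        flagged = report.removed.query("reason == 'rf_above_ceiling'")["marker"]
        assert set(flagged) == {victim}

    def test_clean_population_has_zero_removals(self, clean_population):
        filtered, report = qc_filter(clean_population)
        assert len(report.removed) == 0
        assert filtered.genotypes.shape == clean_population.genotypes.shape

    def test_distortion_reported_not_removed(self, small_map):
        rng = np.random.default_rng(9)
        geno = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(120, small_map.n_markers))
        distorted = small_map.marker_names[0]
        geno[:, 0] = rng.choice([0, 1, 2], p=[0.05, 0.35, 0.60], size=120)
        pop = make_population(small_map, geno, 400 + rng.normal(size=120))
        filtered, report = qc_filter(pop)
        row = report.distortion.set_index("marker").loc[distorted]
        assert row["p"] < 0.01
        assert distorted in filtered.genotypes.columns


def test_map_rejects_duplicate_and_unsorted():
    with pytest.raises(ValueError, match="duplicate"):
        GeneticMap({
            "1": pd.Series([0.0], index=["m1"]),
            "2": pd.Series([0.0], index=["m1"]),
        })
    with pytest.raises(ValueError, match="not sorted"):
        GeneticMap({"1": pd.Series([5.0, 1.0], index=["a", "b"])})
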