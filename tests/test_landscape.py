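"""Landscape data model, I/O round-trips and partition summaries."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fitscape.landscape import (
    FitnessLandscape,
    FitnessMeasurement,
    Substitution,
    category_profile,
    fold_from_replicates,
    fold_improvement,
    format_genotype,
    parse_genotype,
    partition_summary,
    read_landscape,
    write_landscape,
)
from fitscape.library_design import DegenerateCodon, LibraryDesign, Site

from conftest import make_landscape


class TestSubstitution:
    def test_parse_and_format_round_trip(self):
        s = Substitution.parse("S41Y")
        assert (s.wild_type, s.position, s.mutant) == ("S", 41, "Y")
        assert str(s) == "S41Y"

    @pytest.mark.parametrize("bad", ["S41S", "X41Y", "S0Y", "41Y", "S41", "s41"])
    def test_invalid_tokens_rejected(self, bad):
        with pytest.raises(ValueError):
            Substitution.parse(bad)

    @given(
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        st.integers(1, 999),
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    )
    def test_string_form_round_trips(self, wt, pos, mut):
        if wt == mut:
            return
        s = Substitution(position=pos, wild_type=wt, mutant=mut)
        assert Substitution.parse(str(s)) == s


class TestGenotypeEncoding:
    def test_wild_type_aliases(self):
        assert parse_genotype("") == ()
        assert parse_genotype("WT") == ()
        assert format_genotype(()) == "WT"

    def test_canonical_order_by_position(self):
        g = parse_genotype("R225V+S41Y")
        assert format_genotype(g) == "S41Y+R225V"

    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_genotype("S41Y+S41W")

    @given(st.integers(0, 2**10 - 1))
    def test_mask_string_round_trip(self, mask):
        subs = [Substitution(position=i + 1, wild_type="A", mutant="V") for i in range(10)]
        land = FitnessLandscape(subs, {"WT": FitnessMeasurement(1.0)})
        assert land.mask_of(land.genotype_string(mask)) == mask


class TestMeasurement:
    def test_replicates_must_match_summary(self):
        FitnessMeasurement.from_replicates([4.0, 6.0])  # consistent by construction
        with pytest.raises(ValueError):
            FitnessMeasurement(mean=5.0, sd=0.0, n=2, replicates=(4.0, 6.0))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            FitnessMeasurement(mean=0.0)

    def test_wild_type_inserted_when_absent(self):
        land = make_landscape({"A1V": 0}, {"A1V": 2.0})
        assert land.mean("WT") == 1.0


class TestIO:
    def test_seven_substitution_file_parses(self, tmp_path):
        rows = ["genotype,mean_fold,sd,n", "WT,1.0,0.0,4"]
        subs = ["S41Y", "H215C", "T219Y", "K222V", "S224R", "R225V", "F227G"]
        rows += [f"{s},1.5,0.1,4" for s in subs]
        p = tmp_path / "land.csv"
        p.write_text("\n".join(rows) + "\n")
        land = read_landscape(p)
        assert land.n == 7
        assert len(land.enumerate_intermediates()) == 126

    def test_round_trip_is_byte_identical(self, tmp_path, toy3):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_landscape(toy3, p1)
        write_landscape(read_landscape(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_errors_carry_row_numbers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("genotype,mean_fold,sd,n\nWT,1.0,0,1\nA1V,-2.0,0,1\n")
        with pytest.raises(ValueError, match="row 3"):
            read_landscape(p)

    def test_duplicate_genotype_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("genotype,mean_fold,sd,n\nA1V,2.0,0,1\nA1V,3.0,0,1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_landscape(p)

    def test_conflicting_alleles_at_one_position_rejected(self, tmp_path):
        p = tmp_path / "conflict.csv"
        p.write_text("genotype,mean_fold,sd,n\nS41Y,2.0,0,1\nS41W,3.0,0,1\n")
        with pytest.raises(ValueError, match="position 41"):
            read_landscape(p)


class TestFoldImprovement:
    def test_ratio_arithmetic(self):
        assert fold_improvement(30.0, 5.0) == 6.0
        assert fold_improvement(5.0, 5.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_improvement(0.0, 5.0)

    def test_batch_paired_ratios_match_hand_computation(self):
        # 3 batches; WT EC50s 2, 4, 5; variant EC50s 6, 10, 20
        df = pd.DataFrame(
            {
                "genotype": ["WT"] * 3 + ["A1V"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
                "batch": ["b1", "b2", "b3", "b1", "b2", "b3"],
                "ec50_uM": [2.0, 4.0, 5.0, 6.0, 10.0, 20.0],
            }
        )
        out = fold_from_replicates(df).set_index("genotype")
        ratios = [6 / 2, 10 / 4, 20 / 5]  # 3.0, 2.5, 4.0
        assert out.loc["A1V", "mean_fold"] == pytest.approx(np.mean(ratios))
        assert out.loc["A1V", "sd"] == pytest.approx(np.std(ratios, ddof=1))
        assert out.loc["A1V", "n"] == 3

    def test_grand_mean_fallback_uses_error_propagation(self):
        df = pd.DataFrame(
            {
                "genotype": ["WT", "WT", "A1V", "A1V"],
                "ec50_uM": [4.0, 6.0, 10.0, 14.0],
            }
        )
        out = fold_from_replicates(df).set_index("genotype")
        ratio = 12.0 / 5.0
        sd = ratio * math.hypot(np.std([10, 14], ddof=1) / 12, np.std([4, 6], ddof=1) / 5)
        assert out.loc["A1V", "mean_fold"] == pytest.approx(ratio)
        assert out.loc["A1V", "sd"] == pytest.approx(sd)


class TestPartitionSummary:
    def test_uniform_landscape_gives_equal_groups(self):
        land = make_landscape(
            {"A1V": 0, "C2W": 0},
            {"WT": 3.0, "A1V": 3.0, "C2W": 3.0, "A1V+C2W": 3.0},
        )
        ps = partition_summary(land, "A1V")
        assert (ps.with_mean, ps.with_sd) == (3.0, 0.0)
        assert (ps.without_mean, ps.without_sd) == (3.0, 0.0)

    def test_matches_exhaustive_hand_computation(self, toy3):
        ps = partition_summary(toy3, "A1V")
        with_vals = [1.5, 2.5, 1.9, 4.0]
        without_vals = [1.0, 0.8, 1.1, 0.9]
        assert ps.with_mean == pytest.approx(np.mean(with_vals))
        assert ps.with_sd == pytest.approx(np.std(with_vals, ddof=1))
        assert ps.without_mean == pytest.approx(np.mean(without_vals))
        assert ps.without_sd == pytest.approx(np.std(without_vals, ddof=1))

    def test_groups_partition_the_lattice(self, toy3):
        ps = partition_summary(toy3, "D3Y")
        assert ps.with_n + ps.without_n == 2**toy3.n

    def test_foreign_substitution_rejected(self, toy3):
        with pytest.raises(KeyError):
            partition_summary(toy3, "S41Y")


class TestCategoryProfile:
    @pytest.fixture
    def design2(self):
        return LibraryDesign(
            sites=(Site(41, "S", DegenerateCodon("NDT")), Site(219, "T", DegenerateCodon("NHT")))
        )

    def test_all_aromatic_position(self, design2):
        profile = category_profile(["YA", "FA", "WA"], design2)
        assert profile.loc[41, "aromatic"] == 100.0
        assert profile.loc[41].sum() == pytest.approx(100.0)

    def test_hand_counted_mixture(self, design2):
        profile = category_profile(["YD", "FD", "SK", "GE"], design2)
        assert profile.loc[41, "aromatic"] == 50.0
        assert profile.loc[41, "polar uncharged"] == 25.0
        assert profile.loc[41, "nonpolar aliphatic"] == 25.0
        assert profile.loc[219, "negatively charged"] == 75.0
        assert profile.loc[219, "positively charged"] == 25.0

    def test_length_mismatch_rejected(self, design2):
        with pytest.raises(ValueError):
            category_profile(["Y"], design2)
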