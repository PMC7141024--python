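"""Profile data model, ingest/round-trip I/O and derived per-specimen quantities."""

import math

import hypothesis.strategies as st
import pandas as pd
import pytest
from hypothesis import given, settings

from csia_tp import (
    AAClassification,
    AminoAcidProfile,
    FormatError,
    IngestError,
    MissingAnalyteError,
    glx_phe_difference,
    mean_source,
    mean_trophic,
    read_profiles,
    read_profiles_wide,
    summarize_by_group,
    write_profiles,
)

LONG_HEADER = "specimen_id,species,tissue,aa,d15n\n"


def make_profile(aa_d15n, sid="s1", **kw):
    return AminoAcidProfile(
        specimen_id=sid, species="beluga", tissue="skin", aa_d15n=aa_d15n, **kw
    )


class TestDataModel:
    def test_aliases_normalised_on_ingest(self):
        p = make_profile({"Glu": 18.75, "Asn": 13.26, "Phe": 6.17})
        assert set(p.aa_d15n) == {"Glx", "Asx", "Phe"}
        assert p.aa_d15n["Glx"] == 18.75

    def test_unknown_code_rejected(self):
        with pytest.raises(IngestError, match="unknown amino acid"):
            make_profile({"Xyz": 10.0})

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -31.0, 61.0])
    def test_implausible_values_rejected(self, bad):
        with pytest.raises(ValueError):
            make_profile({"Glx": bad})

    def test_negative_replicate_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            make_profile({"Glx": 18.0}, aa_sd={"Glx": -0.1})

    def test_alias_collision_is_duplicate(self):
        with pytest.raises(IngestError, match="duplicate"):
            make_profile({"Glu": 18.0, "Gln": 19.0})

    def test_classification_requires_disjoint_nonempty_sets(self):
        with pytest.raises(ValueError):
            AAClassification(trophic=frozenset({"Glx"}), source=frozenset({"Glx"}))
        with pytest.raises(ValueError):
            AAClassification(trophic=frozenset(), source=frozenset({"Phe"}))


class TestDerivedQuantities:
    def test_glx_phe_difference_beluga_skin_means(self):
        p = make_profile({"Glx": 28.99, "Phe": 9.14})
        assert glx_phe_difference(p) == pytest.approx(19.85, abs=1e-12)

    def test_glx_phe_difference_missing_analyte_names_specimen(self):
        with pytest.raises(MissingAnalyteError, match="s1.*Phe"):
            glx_phe_difference(make_profile({"Glx": 18.0}))

    def test_mean_trophic_bowhead_skin(self, bowhead_skin_profile):
        # hand sum of the seven trophic amino acids / 7
        assert mean_trophic(bowhead_skin_profile) == pytest.approx(121.32 / 7, abs=1e-12)
        assert mean_trophic(bowhead_skin_profile) == pytest.approx(17.33, abs=0.005)

    def test_mean_source_singleton(self, bowhead_skin_profile):
        assert mean_source(bowhead_skin_profile) == 5.53

    def test_mean_trophic_strict_requires_full_set(self):
        p = make_profile({"Glx": 18.0, "Phe": 5.0})
        with pytest.raises(MissingAnalyteError):
            mean_trophic(p, strict=True)
        assert mean_trophic(p, strict=False) == 18.0

    def test_excluded_aa_never_enters_means(self, bowhead_skin_profile):
        cls = AAClassification(excluded=frozenset({"Gly", "Ala"}))
        expected = (121.32 - 17.03) / 6
        assert mean_trophic(bowhead_skin_profile, cls) == pytest.approx(expected)

    @given(shift=st.floats(-10, 10), base=st.floats(0, 20))
    @settings(max_examples=50, derandomize=True)
    def test_translation_invariance_of_delta(self, shift, base):
        p1 = make_profile({"Glx": base + 12.0, "Phe": base})
        p2 = make_profile({"Glx": base + 12.0 + shift, "Phe": base + shift})
        assert glx_phe_difference(p2) == pytest.approx(glx_phe_difference(p1), abs=1e-9)

    @given(values=st.lists(st.floats(0, 30), min_size=7, max_size=7))
    @settings(max_examples=50, derandomize=True)
    def test_mean_trophic_order_independence(self, values):
        aas = ["Glx", "Asx", "Ala", "Ile", "Leu", "Pro", "Val"]
        p1 = make_profile(dict(zip(aas, values)))
        p2 = make_profile(dict(zip(reversed(aas), values)))
        assert mean_trophic(p1) == pytest.approx(mean_trophic(p2), abs=1e-9)


class TestIO:
    def test_read_long(self, tmp_path):
        f = tmp_path / "in.csv"
        f.write_text(
            LONG_HEADER
            + "w1,bowhead_whale,baleen,Glx,18.75\n"
            + "w1,bowhead_whale,baleen,Phe,6.17\n"
        )
        (p,) = read_profiles(f)
        assert p.aa_d15n == {"Glx": 18.75, "Phe": 6.17}
        assert p.species == "bowhead_whale"

    def test_read_alias_stored_canonically(self, tmp_path):
        f = tmp_path / "in.csv"
        f.write_text(LONG_HEADER + "w1,bowhead_whale,baleen,Glu,18.75\n")
        (p,) = read_profiles(f)
        assert "Glx" in p.aa_d15n

    def test_read_tab_delimited(self, tmp_path):
        f = tmp_path / "in.tsv"
        f.write_text(LONG_HEADER.replace(",", "\t") + "w1\tbeluga\tskin\tGlx\t28.99\n")
        (p,) = read_profiles(f)
        assert p.aa_d15n["Glx"] == 28.99

    def test_empty_file_gives_empty_collection(self, tmp_path, caplog):
        f = tmp_path / "empty.csv"
        f.write_text("")
        with caplog.at_level("WARNING"):
            assert read_profiles(f) == []
        assert "empty" in caplog.text

    def test_missing_column_is_format_error(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("specimen_id,species,aa,d15n\nw1,beluga,Glx,28.99\n")
        with pytest.raises(FormatError, match="tissue"):
            read_profiles(f)

    def test_duplicate_rows_name_the_specimen(self, tmp_path):
        f = tmp_path / "dup.csv"
        f.write_text(
            LONG_HEADER + "w1,beluga,skin,Glx,28.99\n" + "w1,beluga,skin,Glx,29.01\n"
        )
        with pytest.raises(IngestError, match="w1"):
            read_profiles(f)

    def test_unknown_aa_strict_vs_permissive(self, tmp_path, caplog):
        f = tmp_path / "odd.csv"
        f.write_text(
            LONG_HEADER + "w1,beluga,skin,Glx,28.99\n" + "w1,beluga,skin,Foo,1.0\n"
        )
        with pytest.raises(IngestError):
            read_profiles(f, strict=True)
        with caplog.at_level("WARNING"):
            (p,) = read_profiles(f, strict=False)
        assert set(p.aa_d15n) == {"Glx"}
        assert "Foo" in caplog.text

    def test_wide_reader_matches_long(self, tmp_path):
        fl = tmp_path / "long.csv"
        fl.write_text(
            LONG_HEADER + "w1,beluga,skin,Glx,28.99\n" + "w1,beluga,skin,Phe,9.14\n"
        )
        fw = tmp_path / "wide.csv"
        fw.write_text("specimen_id,species,tissue,Glx,Phe\nw1,beluga,skin,28.99,9.14\n")
        assert read_profiles_wide(fw)[0].aa_d15n == read_profiles(fl)[0].aa_d15n

    def test_round_trip_full_precision(self, tmp_path):
        values = {"Glx": 28.123456789012345, "Phe": 9.87654321098765}
        p = make_profile(values, aa_sd={"Glx": 0.4})
        out = tmp_path / "out.csv"
        write_profiles([p], out)
        (back,) = read_profiles(out)
        for aa, v in values.items():
            assert back.aa_d15n[aa] == pytest.approx(v, rel=1e-14)
        assert back.aa_sd["Glx"] == 0.4


class TestSummaries:
    def test_group_summary_mean_sd_n(self):
        profiles = [
            make_profile({"Glx": 20.0 + d, "Phe": 6.0}, sid=f"s{i}")
            for i, d in enumerate([-1.0, 0.0, 1.0])
        ]
        out = summarize_by_group(profiles)
        row = out.iloc[0]
        assert row["d15n_glx_phe_mean"] == pytest.approx(14.0)
        assert row["d15n_glx_phe_std"] == pytest.approx(1.0)  # n-1 denominator
        assert row["d15n_glx_phe_n"] == 3
        assert row["d15n_Glx_mean"] == pytest.approx(20.0)

    def test_single_member_group_sd_missing(self):
        out = summarize_by_group([make_profile({"Glx": 20.0, "Phe": 6.0})])
        assert math.isnan(out.iloc[0]["d15n_glx_phe_std"])

    def test_species_means_match_published_summaries(self, study_profiles):
        """Recomputed group means of per-individual Δ reproduce the quoted 2-dp values."""
        out = summarize_by_group(study_profiles).set_index(["species", "tissue"])
        expect = {
            ("common_dolphin", "skin"): 13.65,
            ("beluga", "skin"): 19.85,
            ("beluga", "dentine_collagen"): 18.45,
            ("sperm_whale", "skin"): 15.07,
            ("sperm_whale", "dentine_collagen"): 15.52,
            ("mme_killer_whale", "dentine_collagen"): 13.46,
        }
        for key, mean in expect.items():
            assert out.loc[key, "d15n_glx_phe_mean"] == pytest.approx(mean, abs=0.005)
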