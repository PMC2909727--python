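"""Coordinate backbone: cytoband parsing, SNP binding, TSV round-trips."""
import numpy as np
import pandas as pd
import pytest

from cytoscan import (
    GenomeMap,
    MalformedMapError,
    SNPProfile,
    read_cytoband_file,
    read_profile_matrix,
    read_score_matrix,
    write_profile_matrix,
    write_score_matrix,
)
from cytoscan.genome import parse_band_arm


def write_lines(path, lines):
    path.write_text("".join(l + "\n" for l in lines))
    return path


class TestCytobandReader:
    def test_basic_parse(self, tmp_path):
        p = write_lines(tmp_path / "cyto.txt", [
            "chr1\t0\t100\tp36\tgneg",
            "chr1\t100\t250\tp35\tgpos50",
        ])
        g = read_cytoband_file(p)
        assert g.chromosomes == ["1"]
        assert g.band_names == ["1p36", "1p35"]
        assert list(g.bands["arm"]) == ["p", "p"]

    def test_sex_chromosomes_dropped(self, tmp_path):
        p = write_lines(tmp_path / "cyto.txt", [
            "chr2\t0\t50\tp1",
            "chr2\t50\t100\tq1",
            "chrX\t0\t100\tp11",
            "chrY\t0\t100\tq11",
        ])
        g = read_cytoband_file(p)
        assert g.chromosomes == ["2"]
        assert all(not b.startswith("X") for b in g.band_names)

    @pytest.mark.parametrize("lines,match", [
        (["chr1\t100\t50\tp1"], "end <= start"),
        (["chr1\t0\t100\tp2", "chr1\t50\t150\tp1"], "overlap"),
        (["chr1\t0\t100\tp2", "chr1\t150\t200\tp1"], "tile"),
        (["chr1\t0\t100\tb1"], "does not start with p or q"),
        (["chr1\t0\t50\tq1", "chr1\t50\t100\tp1"], "q-arm band precedes"),
    ])
    def test_malformed_files_rejected(self, tmp_path, lines, match):
        p = write_lines(tmp_path / "cyto.txt", lines)
        with pytest.raises((MalformedMapError, ValueError), match=match):
            read_cytoband_file(p)

    def test_genome_order_is_total(self, full_genome):
        names = full_genome.band_names
        keys = []
        for i, name in enumerate(names):
            arm = parse_band_arm(name)
            keys.append((int(arm[:-1]), arm[-1], full_genome.bands["start"].iloc[i]))
        assert keys == sorted(keys)


class TestProfileMatrix:
    def _write_matrix(self, tmp_path, small_genome, shuffle=False, blank=None,
                      name="profiles.tsv"):
        rng = np.random.default_rng(1)
        df = small_genome.snps[["snp_id", "chrom", "pos"]].copy()
        df["sampleA"] = rng.normal(size=len(df))
        df["sampleB"] = rng.normal(size=len(df))
        if shuffle:
            df = df.sample(frac=1.0, random_state=2)
        if blank is not None:
            df = df.astype({"sampleB": object})
            df.iloc[blank, df.columns.get_loc("sampleB")] = ""
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_read_two_samples(self, tmp_path, small_genome):
        path = self._write_matrix(tmp_path, small_genome)
        bound, profiles = read_profile_matrix(path, small_genome)
        assert [p.sample_id for p in profiles] == ["sampleA", "sampleB"]
        assert all(len(p) == small_genome.n_snps for p in profiles)

    def test_row_order_normalized(self, tmp_path, small_genome):
        sorted_path = self._write_matrix(tmp_path, small_genome)
        _, sorted_profiles = read_profile_matrix(sorted_path, small_genome)
        shuf_path = self._write_matrix(tmp_path, small_genome, shuffle=True,
                                       name="shuffled.tsv")
        _, shuf_profiles = read_profile_matrix(shuf_path, small_genome)
        for a, b in zip(sorted_profiles, shuf_profiles):
            np.testing.assert_array_equal(a.values, b.values)

    def test_blank_cell_names_snp_and_sample(self, tmp_path, small_genome):
        path = self._write_matrix(tmp_path, small_genome, blank=7)
        with pytest.raises(ValueError, match=r"sampleB"):
            read_profile_matrix(path, small_genome)

    def test_position_outside_bands_rejected(self, tmp_path, small_genome):
        df = small_genome.snps[["snp_id", "chrom", "pos"]].copy()
        df["s"] = 0.0
        df.loc[0, "pos"] = 10**12
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="outside any cytoband"):
            read_profile_matrix(path, small_genome)

    def test_write_read_round_trip(self, tmp_path, small_genome, rng):
        profiles = [SNPProfile(f"s{i}", rng.normal(size=small_genome.n_snps))
                    for i in range(3)]
        path = tmp_path / "out.tsv"
        write_profile_matrix(profiles, small_genome, path)
        _, back = read_profile_matrix(path, small_genome)
        for a, b in zip(profiles, back):
            assert a.sample_id == b.sample_id
            np.testing.assert_array_equal(a.values, b.values)


class TestScoreMatrix:
    def test_round_trip_identity(self, tmp_path):
        m = pd.DataFrame(
            [[0.1, -2.0, 1 / 3], [np.pi, 1e-17, -1e16]],
            index=["a", "b"], columns=["1p1", "1q1", "2p1"],
        )
        path = tmp_path / "scores.tsv"
        write_score_matrix(m, path)
        back = read_score_matrix(path)
        pd.testing.assert_frame_equal(m, back)

    def test_empty_sample_set(self, tmp_path):
        m = pd.DataFrame(columns=["1p1", "1q1"], dtype=float)
        path = tmp_path / "scores.tsv"
        write_score_matrix(m, path)
        back = read_score_matrix(path)
        assert back.empty and list(back.columns) == ["1p1", "1q1"]

    def test_nan_rejected_on_write(self, tmp_path):
        m = pd.DataFrame([[1.0, np.nan]], index=["a"], columns=["1p1", "1q1"])
        with pytest.raises(ValueError, match="NaN"):
            write_score_matrix(m, tmp_path / "scores.tsv")

    def test_duplicate_cytobands_rejected(self, tmp_path):
        m = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["1p1", "1p1"])
        with pytest.raises(ValueError, match="duplicate"):
            write_score_matrix(m, tmp_path / "scores.tsv")


def test_profile_rejects_nonfinite():
    with pytest.raises(ValueError, match="non-finite"):
        SNPProfile("s", np.array([0.0, np.inf]))


def test_snp_band_assignment(small_genome):
    # every SNP maps to exactly one band, and to the band containing its position
    for _, row in small_genome.snps.sample(20, random_state=0).iterrows():
        band = small_genome.bands.loc[row["band_idx"]]
        assert band["chrom"] == row["chrom"]
        assert band["start"] <= row["pos"] < band["end"]
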