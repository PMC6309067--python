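"""Format parsing, coordinate conventions and lookup structures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindrank.genomic_io import (
    MISSING,
    FormatError,
    GenomicVariant,
    IntervalTrack,
    ScoreTable,
    VariantSet,
    lookup_score,
    normalize_chrom,
    query_interval_membership,
    read_variants,
    write_ranked_output,
)


def _write(path, text):
    path.write_text(text)
    return path


VCF_HEADER = "##fileformat=VCFv4.2\n##contig=<ID=1,length=100000>\n" \
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


class TestVariantParsing:
    def test_vcf_simple_record(self, tmp_path):
        p = _write(tmp_path / "a.vcf", VCF_HEADER + "1\t1000\t.\tA\tG\t.\tPASS\t.\n")
        vs = read_variants(p, "vcf")
        assert len(vs) == 1
        assert vs[0] == GenomicVariant("1", 1000, "A", "G")

    def test_vcf_multiallelic_split(self, tmp_path):
        p = _write(tmp_path / "a.vcf", VCF_HEADER + "1\t1000\t.\tA\tG,T\t.\tPASS\t.\n")
        vs = read_variants(p, "vcf")
        assert [(v.ref, v.alt) for v in vs] == [("A", "G"), ("A", "T")]
        assert all(v.pos == 1000 for v in vs)

    def test_vcf_skips_indels_with_count(self, tmp_path):
        p = _write(
            tmp_path / "a.vcf",
            VCF_HEADER + "1\t1000\t.\tA\tG\t.\tPASS\t.\n1\t2000\t.\tAT\tA\t.\tPASS\t.\n",
        )
        vs = read_variants(p, "vcf")
        assert len(vs) == 1 and vs.n_skipped == 1

    def test_bed_zero_based_to_one_based(self, tmp_path):
        p = _write(tmp_path / "a.bed", "1\t999\t1000\tA/G\n")
        vs = read_variants(p, "bed")
        assert vs[0] == GenomicVariant("1", 1000, "A", "G")

    def test_bed_conversion_matches_oracle_on_random_positions(self, tmp_path, rng):
        # independent oracle: a base at 0-based start s is 1-based s + 1
        starts = rng.integers(0, 10**6, size=100)
        lines = "".join(f"chr2\t{s}\t{s + 1}\tC/T\n" for s in starts)
        vs = read_variants(_write(tmp_path / "r.bed", lines), "bed")
        expected = sorted(int(s) + 1 for s in set(starts))
        assert [v.pos for v in vs] == expected
        assert all(v.chrom == "2" for v in vs)  # chr prefix normalized away

    def test_avinput_snv_rows_only(self, tmp_path):
        p = _write(
            tmp_path / "a.avinput",
            "1\t1000\t1000\tA\tG\n1\t2000\t2002\tAAA\t-\nchr1\t3000\t3000\tC\tT\n",
        )
        vs = read_variants(p, "avinput")
        assert [(v.chrom, v.pos) for v in vs] == [("1", 1000), ("1", 3000)]
        assert vs.n_skipped == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(tmp_path / "bad.bed", "1\t999\n")
        with pytest.raises(FormatError, match=":1"):
            read_variants(p, "bed")

    def test_unknown_format_rejected(self, tmp_path):
        p = _write(tmp_path / "a.txt", "")
        with pytest.raises(ValueError, match="unknown variant format"):
            read_variants(p, "gff")

    def test_parsing_is_loss_counting(self, tmp_path, rng):
        # input records = parsed variants + skipped + duplicates, always
        lines = []
        n_snv = 0
        for i in range(50):
            if rng.random() < 0.3:
                lines.append(f"1\t{1000 + i}\t{1002 + i}\tAA/G\n")  # not a 1-bp record
            else:
                lines.append(f"1\t{1000 + i}\t{1001 + i}\tA/G\n")
                n_snv += 1
        vs = read_variants(_write(tmp_path / "mix.bed", "".join(lines)), "bed")
        assert len(vs) + vs.n_skipped + vs.n_duplicates == 50
        assert len(vs) == n_snv


class TestVariantSet:
    def test_sorted_and_deduplicated(self):
        vs = VariantSet(
            [
                GenomicVariant("2", 5, "A", "G"),
                GenomicVariant("1", 9, "C", "T"),
                GenomicVariant("2", 5, "A", "G"),
            ]
        )
        assert [(v.chrom, v.pos) for v in vs] == [("1", 9), ("2", 5)]
        assert vs.n_duplicates == 1

    def test_invalid_variants_rejected(self):
        with pytest.raises(ValueError):
            GenomicVariant("1", 0, "A", "G")
        with pytest.raises(ValueError):
            GenomicVariant("1", 10, "A", "A")
        with pytest.raises(ValueError):
            GenomicVariant("1", 10, "N", "G")


class TestIntervalMembership:
    def test_half_open_boundaries(self):
        track = IntervalTrack("t", [("1", 999, 1000)])
        assert query_interval_membership(track, GenomicVariant("1", 1000, "A", "G")) == 1
        assert query_interval_membership(track, GenomicVariant("1", 1001, "A", "G")) == 0
        assert query_interval_membership(track, GenomicVariant("1", 999, "A", "G")) == 0

    def test_empty_track_always_zero(self):
        track = IntervalTrack("t", [])
        assert track.contains(GenomicVariant("1", 5, "A", "G")) == 0

    def test_start_ge_end_rejected(self):
        with pytest.raises(ValueError):
            IntervalTrack("t", [("1", 10, 10)])

    def test_matches_brute_force_on_random_track(self, rng):
        starts = rng.integers(0, 50_000, size=200)
        intervals = [("1", int(s), int(s + rng.integers(1, 500))) for s in starts]
        track = IntervalTrack("t", intervals)
        positions = rng.integers(1, 51_000, size=10_000)
        for pos in positions:
            v = GenomicVariant("1", int(pos), "A", "G")
            brute = int(any(s <= pos - 1 < e for _, s, e in intervals))
            assert track.contains(v) == brute


class TestScoreTable:
    def test_lookup_present_and_missing(self):
        t = ScoreTable("s", {("1", 1000, "A", "G"): 3.1})
        assert lookup_score(t, GenomicVariant("1", 1000, "A", "G")) == 3.1
        assert lookup_score(t, GenomicVariant("1", 1000, "A", "T")) is MISSING

    def test_position_mode_ignores_alleles(self):
        t = ScoreTable("s", {("1", 1000): 2.5}, key_mode="position")
        assert lookup_score(t, GenomicVariant("1", 1000, "A", "T")) == 2.5

    def test_matches_dict_oracle_on_random_keys(self, rng):
        keys = [("1", int(p), "A", "G") for p in rng.integers(1, 10**6, size=300)]
        oracle = {k: float(i) for i, k in enumerate(keys)}
        t = ScoreTable("s", dict(oracle))
        for k in keys:
            assert t.lookup(GenomicVariant(*k)) == oracle[k]
        for p in rng.integers(10**6 + 1, 2 * 10**6, size=300):
            assert t.lookup(GenomicVariant("1", int(p), "A", "G")) is MISSING


class TestRankedOutput:
    def test_sorted_descending_with_stable_ties(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"chrom": ["1", "1", "2"], "pos": [5, 3, 1], "score": [0.1, 0.9, 0.5]}
        )
        out = tmp_path / "r.tsv"
        write_ranked_output(df, out)
        back = pd.read_csv(out, sep="\t")
        assert list(back["score"]) == [0.9, 0.5, 0.1]

        tied = pd.DataFrame({"chrom": ["2", "1"], "pos": [1, 1], "score": [0.5, 0.5]})
        write_ranked_output(tied, out)
        back = pd.read_csv(out, sep="\t", dtype={"chrom": str})
        assert list(back["chrom"]) == ["1", "2"]

    def test_round_trip_preserves_scores_to_six_decimals(self, tmp_path, rng):
        import pandas as pd

        df = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(100), "score": rng.random(100)}
        )
        out = tmp_path / "r.tsv"
        write_ranked_output(df, out)
        back = pd.read_csv(out, sep="\t")
        merged = back.sort_values("pos").reset_index(drop=True)
        np.testing.assert_allclose(
            merged["score"], df.sort_values("pos")["score"], atol=5e-7
        )


@settings(derandomize=True, max_examples=50)
@given(start=st.integers(min_value=0, max_value=10**8))
def test_coordinate_round_trip_is_identity(start):
    # 0-based half-open -> 1-based -> back
    one_based = start + 1
    assert one_based - 1 == start


@settings(derandomize=True, max_examples=30)
@given(name=st.sampled_from(["chr1", "1", "chrX", "X", "ChrM", "M"]))
def test_chrom_normalization_idempotent(name):
    once = normalize_chrom(name)
    assert normalize_chrom(once) == once
    assert not once.lower().startswith("chr")
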