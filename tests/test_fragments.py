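"""Fragment readers, QC, conversion estimation, downsampling."""

import numpy as np
import pandas as pd
import pytest

from themis.fragments import (
    Fragment,
    SampleFragments,
    downsample,
    estimate_conversion,
    read_fragment_table,
    read_fragments,
    revcomp,
    write_fragment_table,
)

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def _pair(name, start1, cigar1, xm1, start2, cigar2, xm2, mapq1=60, mapq2=60,
          seqlen1=None, seqlen2=None):
    """A proper pair on chr1; read lengths follow the XM strings."""
    l1 = seqlen1 or len(xm1)
    l2 = seqlen2 or len(xm2)
    tlen = (start2 + l2) - start1
    r1 = (
        f"{name}\t99\tchr1\t{start1 + 1}\t{mapq1}\t{cigar1}\t=\t{start2 + 1}\t{tlen}\t"
        f"{'A' * l1}\t{'I' * l1}\tXM:Z:{xm1}"
    )
    r2 = (
        f"{name}\t147\tchr1\t{start2 + 1}\t{mapq2}\t{cigar2}\t=\t{start1 + 1}\t{-tlen}\t"
        f"{'A' * l2}\t{'I' * l2}\tXM:Z:{xm2}"
    )
    return [r1, r2]


def _write_sam(tmp_path, record_lines):
    path = tmp_path / "toy.sam"
    path.write_text(SAM_HEADER + "\n".join(record_lines) + "\n")
    return str(path)


class TestSamReader:
    def test_pair_merged_with_methylation_tally(self, tmp_path):
        # mates [1000,1100) and [1080,1180): fragment spans 180 bp
        xm1 = "Z" + "." * 98 + "z"  # one methylated + one unmethylated CpG
        xm2 = "." * 50 + "Z" + "." * 49
        sam = _write_sam(tmp_path, _pair("p1", 1000, "100M", xm1, 1080, "100M", xm2))
        out = read_fragments(sam, min_mapq=20)
        assert out.n_total == 1
        f = next(iter(out))
        assert (f.start, f.end, f.length) == (1000, 1180, 180)
        # r2 overlap region [1080,1100) is clipped; its Z sits at 1130 -> kept
        assert (f.cpg_total, f.cpg_methylated) == (3, 2)

    def test_overlap_bases_counted_once_leftmost_wins(self, tmp_path):
        # r2's call inside the overlap must not be tallied
        xm1 = "Z" + "." * 99
        xm2 = "Z" + "." * 99  # at 1080, inside [1080,1100) overlap
        sam = _write_sam(tmp_path, _pair("p1", 1000, "100M", xm1, 1080, "100M", xm2))
        f = next(iter(read_fragments(sam, min_mapq=20)))
        assert (f.cpg_total, f.cpg_methylated) == (1, 1)

    def test_low_mapq_pair_dropped(self, tmp_path):
        sam = _write_sam(
            tmp_path,
            _pair("p1", 1000, "50M", "." * 50, 1100, "50M", "." * 50, mapq1=10),
        )
        out = read_fragments(sam, min_mapq=20)
        assert out.n_total == 0
        assert out.qc_counters["pairs_low_mapq"] == 1

    def test_missing_tag_yields_zero_tallies(self, tmp_path):
        lines = _pair("p1", 1000, "50M", "." * 50, 1100, "50M", "." * 50)
        lines = [l.rsplit("\tXM:Z:", 1)[0] for l in lines]
        sam = _write_sam(tmp_path, lines)
        out = read_fragments(sam, min_mapq=20)
        assert out.n_total == 1
        assert next(iter(out)).cpg_total == 0
        assert out.qc_counters["pairs_missing_tag"] == 1

    def test_aggregate_tallies_match_string_counting_oracle(self, tmp_path, rng):
        lines, exp = [], {"Z": 0, "z": 0, "xh": 0, "XH": 0}
        for i in range(50):
            xm1 = "".join(rng.choice(list("Zzxh XH".replace(" ", "") + "...."), size=60))
            xm2 = "".join(rng.choice(list("Zzxh XH".replace(" ", "") + "...."), size=60))
            s1 = 1000 + 300 * i
            lines += _pair(f"p{i}", s1, "60M", xm1, s1 + 100, "60M", xm2)
            for c in xm1 + xm2:  # no overlap: mates are disjoint
                if c == "Z":
                    exp["Z"] += 1
                elif c == "z":
                    exp["z"] += 1
                elif c in "xh":
                    exp["xh"] += 1
                elif c in "XH":
                    exp["XH"] += 1
        out = read_fragments(_write_sam(tmp_path, lines), min_mapq=20)
        df = out.df
        assert df["cpg_total"].sum() == exp["Z"] + exp["z"]
        assert df["cpg_methylated"].sum() == exp["Z"]
        assert df["noncpg_c_total"].sum() == exp["xh"] + exp["XH"]
        assert df["noncpg_c_converted"].sum() == exp["xh"]

    def test_motif_from_reference_reverse_complement(self, tmp_path):
        seq = ["A"] * 100000
        seq[1148:1152] = list("TGGG")  # fragment end 1152: Crick motif CCCA
        ref = {"chr1": "".join(seq)}
        sam = _write_sam(
            tmp_path, _pair("p1", 1000, "52M", "." * 52, 1052, "100M", "." * 100)
        )
        f = next(iter(read_fragments(sam, min_mapq=20, reference=ref)))
        assert f.end == 1152
        assert f.motif_crick == revcomp("TGGG") == "CCCA"


class TestFragmentTable:
    def _df(self, n=3):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 180,
                "mapq": 60,
                "cpg_total": 4,
                "cpg_methylated": 2,
                "noncpg_c_total": 10,
                "noncpg_c_converted": 10,
                "motif_crick": ["CCCA"] * n,
            }
        )

    def test_valid_table_loads(self, tmp_path):
        p = tmp_path / "f.tsv"
        self._df().to_csv(p, sep="\t", index=False)
        assert read_fragment_table(str(p)).n_total == 3

    def test_invariant_violation_reports_row(self, tmp_path):
        df = self._df()
        df.loc[1, "cpg_methylated"] = 9  # exceeds cpg_total
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="row 2"):
            read_fragment_table(str(p))

    def test_round_trip_identity(self, tmp_path, small_cohort):
        sample = small_cohort.samples[0]
        sub = SampleFragments("s", sample.df.head(1000))
        p = tmp_path / "rt.tsv.gz"
        write_fragment_table(sub, str(p))
        back = read_fragment_table(str(p), sample_id="s")
        pd.testing.assert_frame_equal(
            back.df, sub.df.reset_index(drop=True), check_dtype=False
        )

    def test_dot_motif_parses_as_absent(self, tmp_path):
        df = self._df(1)
        df["motif_crick"] = "."
        p = tmp_path / "dot.tsv"
        df.to_csv(p, sep="\t", index=False)
        assert next(iter(read_fragment_table(str(p)))).motif_crick is None


class TestConversion:
    def _sample(self, rows):
        frags = [
            Fragment("c", 0, 100, 60, ct, cm, nt, nc) for ct, cm, nt, nc in rows
        ]
        return SampleFragments("spk", SampleFragments.from_fragments("s", frags).df)

    def test_simple_rate(self):
        # 100 cytosine observations, 99 converted
        s = self._sample([(40, 1, 60, 60)])
        assert estimate_conversion(s) == pytest.approx(0.99)

    def test_no_observations_is_undefined(self):
        s = self._sample([(0, 0, 0, 0)])
        assert estimate_conversion(s) is None

    def test_pooled_mixed_tallies_match_hand_sum(self, rng):
        rows = []
        conv = tot = 0
        for _ in range(10):
            ct = int(rng.integers(0, 20))
            cm = int(rng.integers(0, ct + 1))
            nt = int(rng.integers(0, 50))
            nc = int(rng.integers(0, nt + 1))
            rows.append((ct, cm, nt, nc))
            conv += (ct - cm) + nc
            tot += ct + nt
        assert estimate_conversion(self._sample(rows)) == pytest.approx(conv / tot)


class TestDownsample:
    def _sample(self, n):
        frags = [Fragment("c", i, i + 100, 60, 3, 3, 5, 5) for i in range(n)]
        return SampleFragments.from_fragments("s", frags)

    def test_identity_when_n_equals_total(self):
        s = self._sample(50)
        out = downsample(s, 50, seed=1)
        assert sorted(out.df["start"]) == sorted(s.df["start"])

    def test_deterministic_under_seed(self):
        s = self._sample(1000)
        a = downsample(s, 100, seed=7).df["start"].tolist()
        b = downsample(s, 100, seed=7).df["start"].tolist()
        assert a == b
        c = downsample(s, 100, seed=8).df["start"].tolist()
        assert a != c

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError, match="keep all"):
            downsample(self._sample(10), 11, seed=0)

    def test_inclusion_frequency_is_uniform(self):
        s = self._sample(200)
        hits = np.zeros(200)
        reps = 400
        for seed in range(reps):
            kept = downsample(s, 100, seed=seed).df["start"].to_numpy() // 1
            hits[kept.astype(int)] += 1
        freq = hits / reps
        se = np.sqrt(0.5 * 0.5 / reps)
        assert np.all(np.abs(freq - 0.5) < 5 * se)
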