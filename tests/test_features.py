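"""The four modality featurizers: MFR, FSI, CAFF/PA, FEM."""

import numpy as np
import pytest

from themis.features import (
    DEFAULT_GATES,
    MOTIFS_4MER,
    SizeGates,
    compute_fem,
    compute_fsi,
    compute_mfr,
    fsi_similarity,
    pa_score,
    reference_fsi_profile,
    size_frequency_test,
)
from themis.fragments import Fragment, SampleFragments
from themis.intervals import GenomicInterval, GenomicWindow, WindowSet


def _windows(n, width, chrom="c"):
    return WindowSet(
        [GenomicWindow(GenomicInterval(chrom, i * width, (i + 1) * width), i) for i in range(n)],
        width,
    )


def _frag(start, length, cpg_t, cpg_m, nc_t=20, nc_c=20, chrom="c", motif=None):
    return Fragment(chrom, start, start + length, 60, cpg_t, cpg_m, nc_t, nc_c, motif)


class TestSizeGates:
    def test_boundaries_follow_printed_wording(self):
        g = DEFAULT_GATES
        L = np.array([99, 100, 166, 167, 168, 169, 240, 241])
        assert g.is_short(L).tolist() == [False, True, True, False, False, False, False, False]
        assert g.is_long(L).tolist() == [False, False, False, False, False, True, True, False]
        L2 = np.array([150, 151, 220, 221])
        assert g.caff_gate(L2).tolist() == [True, False, False, True]
        assert g.fem_gate(np.array([170, 171])).tolist() == [True, False]
        assert g.mfr_gate(np.array([79, 80, 250, 251])).tolist() == [False, True, True, False]

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            SizeGates(short_range=(100, 170), long_range=(169, 240))


class TestSizeFrequencyTest:
    def test_identical_groups_select_nothing(self, rng):
        X = rng.dirichlet(np.ones(20), size=6)
        assert size_frequency_test(X[:3], X[:3], sizes=range(20)) == set()

    def test_planted_shift_recovered_and_null_sizes_absent(self, rng):
        sizes = list(range(100, 160))
        H = rng.normal(10, 0.5, size=(20, len(sizes)))
        C = H[rng.permutation(20)].copy() + rng.normal(0, 0.5, size=(20, len(sizes)))
        shift_cols = [i for i, s in enumerate(sizes) if 120 <= s <= 140]
        C[:, shift_cols] += 5.0
        got = size_frequency_test(C, H, sizes=sizes, alpha=0.01)
        assert set(range(120, 141)) <= got
        assert not (got & set(range(100, 110)))

    def test_alpha_zero_is_empty(self, rng):
        X = rng.normal(0, 1, size=(5, 4))
        assert size_frequency_test(X + 10, X, sizes=range(4), alpha=0.0) == set()

    def test_degenerate_groups_error(self, rng):
        X = rng.normal(0, 1, size=(2, 4))
        with pytest.raises(ValueError):
            size_frequency_test(X, X, sizes=range(4))


class TestMFR:
    def test_window_fraction_of_fully_methylated(self):
        frags = [
            _frag(100, 180, 3, 3),
            _frag(100, 180, 3, 2),
            _frag(100, 180, 4, 4),
            _frag(100, 180, 5, 0),
        ]
        s = SampleFragments.from_fragments("s", frags)
        mfr = compute_mfr(s, _windows(1, 1000))
        assert mfr[0] == pytest.approx(0.5)

    def test_exclusion_criteria(self):
        frags = [
            _frag(100, 180, 2, 2),            # <3 CpGs
            _frag(100, 79, 3, 3),             # too short
            _frag(100, 251, 3, 3),            # too long
            _frag(100, 180, 3, 3, 100, 90),   # conversion 90% <= 95%
            _frag(100, 180, 3, 3),            # qualifies
        ]
        s = SampleFragments.from_fragments("s", frags)
        mfr = compute_mfr(s, _windows(1, 1000))
        assert mfr[0] == pytest.approx(1.0)  # only the last fragment counted

    def test_empty_window_is_missing(self):
        s = SampleFragments.from_fragments("s", [_frag(100, 180, 3, 3)])
        mfr = compute_mfr(s, _windows(2, 1000))
        assert np.isnan(mfr[1])

    def test_matches_per_fragment_oracle(self, rng):
        ws = _windows(10, 1000)
        frags = []
        for _ in range(1000):
            start = int(rng.integers(0, 9500))
            length = int(rng.integers(60, 300))
            ct = int(rng.integers(0, 8))
            cm = int(rng.integers(0, ct + 1))
            nt = int(rng.integers(0, 30))
            nc = int(rng.integers(0, nt + 1))
            frags.append(_frag(start, length, ct, cm, nt, nc))
        s = SampleFragments.from_fragments("s", frags)
        got = compute_mfr(s, ws)
        qual = np.zeros(10)
        full = np.zeros(10)
        for f in frags:
            ok = (
                f.cpg_total >= 3
                and 80 <= f.length <= 250
                and (f.noncpg_c_total == 0 or f.noncpg_c_converted / f.noncpg_c_total > 0.95)
            )
            if not ok:
                continue
            w = ((f.start + f.end) // 2) // 1000
            if w < 10:
                qual[w] += 1
                full[w] += f.cpg_methylated == f.cpg_total
        for j in range(10):
            if qual[j]:
                assert got[j] == pytest.approx(full[j] / qual[j])
            else:
                assert np.isnan(got[j])

    def test_order_invariance(self, rng, small_cohort):
        s = small_cohort.samples[0]
        ws = _windows(8, 1_000_000, chrom="chr1")
        a = compute_mfr(s, ws)
        shuffled = SampleFragments("s", s.df.sample(frac=1, random_state=1))
        b = compute_mfr(shuffled, ws)
        np.testing.assert_allclose(a, b, equal_nan=True)


class TestFSI:
    def _sample_with_counts(self, per_bin_short, per_bin_long, width=1000):
        frags = []
        for b, (ns, nl) in enumerate(zip(per_bin_short, per_bin_long)):
            base = b * width + 10
            frags += [_frag(base, 120, 3, 3) for _ in range(ns)]
            frags += [_frag(base, 200, 3, 3) for _ in range(nl)]
        return SampleFragments.from_fragments("s", frags)

    def test_uniform_ratios_give_zero_z(self, rng):
        n = 100
        s = self._sample_with_counts([5] * n, [5] * n)
        bins = _windows(n, 1000)
        gc = rng.uniform(0.4, 0.6, n)
        merge = {i: i // 50 for i in range(n)}
        fsi = compute_fsi(s, bins, merge, gc)
        assert np.allclose(fsi, 0.0)

    def test_boundary_length_167_in_neither_class(self):
        g = DEFAULT_GATES
        L = np.array([167])
        assert not g.is_short(L)[0] and not g.is_long(L)[0]

    def test_z_contract_and_bruteforce_pipeline_oracle(self, rng):
        n = 100
        short = rng.integers(3, 15, n)
        long_ = rng.integers(3, 15, n)
        short[40:60] += 25  # short-enriched central bins
        s = self._sample_with_counts(short, long_)
        bins = _windows(n, 1000)
        gc = rng.uniform(0.4, 0.6, n)
        merge = {i: i // 10 for i in range(n)}
        got = compute_fsi(s, bins, merge, gc)
        assert abs(got.mean()) < 1e-9 and abs(got.std() - 1) < 1e-6
        # independent straight-line reimplementation
        from themis.profiles import BinProfile, loess_gc_correct

        ratio = (short + 1.0) / (long_ + 1.0)
        corr = loess_gc_correct(BinProfile(ratio, np.ones(n, bool)), gc).values
        win = np.array([corr[i * 10 : (i + 1) * 10].mean() for i in range(10)])
        expected = (win - win.mean()) / win.std()
        np.testing.assert_allclose(got, expected, atol=1e-9)
        assert got.argmax() in {4, 5}  # the short-enriched windows

    def test_reference_profile_and_similarity(self, rng):
        X = rng.normal(0, 1, size=(25, 12))
        ref = reference_fsi_profile(X)
        np.testing.assert_allclose(ref, np.sort(X, axis=0)[12], atol=1e-12)
        assert fsi_similarity(ref, ref) == pytest.approx(1.0)
        assert fsi_similarity(-ref, ref) == pytest.approx(-1.0)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        cov = ((a - a.mean()) * (b - b.mean())).sum()
        expected = cov / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert fsi_similarity(a, b) == pytest.approx(expected)

    def test_single_sample_reference_is_itself(self):
        v = np.array([1.0, 2.0, 9.0])
        assert (reference_fsi_profile(v) == v).all()
        assert reference_fsi_profile(np.array([[1.0], [2.0], [9.0]]))[0] == 2.0


class TestPAScore:
    def test_all_zero(self):
        assert pa_score({f"a{i}": 0.0 for i in range(6)}) == 0.0

    def test_top_five_sum(self):
        z = {"1p": 5.0, "1q": -4.0, "2p": 3.0, "2q": -2.0, "3p": 1.0, "3q": 0.0, "4p": 0.0}
        assert pa_score(z) == 15.0

    def test_matches_exhaustive_subset_oracle(self, rng):
        from itertools import combinations

        z = {f"arm{i:02d}": float(v) for i, v in enumerate(rng.normal(0, 2, 12))}
        best = max(
            sum(abs(z[a]) for a in combo) for combo in combinations(z, 5)
        )
        assert pa_score(z) == pytest.approx(best)

    def test_monotone_in_any_single_arm(self, rng):
        z = {f"a{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 8))}
        base = pa_score(z)
        z2 = dict(z)
        z2["a3"] = z["a3"] + 10.0
        assert pa_score(z2) >= base

    def test_too_few_arms_errors(self):
        with pytest.raises(ValueError):
            pa_score({"a": 1.0, "b": 2.0})


class TestFEM:
    def test_vocabulary_is_256_4mers(self):
        assert len(MOTIFS_4MER) == 256
        assert len(set(MOTIFS_4MER)) == 256
        assert all(len(m) == 4 and set(m) <= set("ACGT") for m in MOTIFS_4MER)

    def test_single_fragment_motif(self):
        s = SampleFragments.from_fragments("s", [_frag(0, 150, 3, 3, motif="CCCA")])
        fem = compute_fem(s)
        assert fem[MOTIFS_4MER.index("CCCA")] == 1.0
        assert fem.sum() == pytest.approx(1.0)

    def test_length_gate_and_missing_motifs(self):
        frags = [
            _frag(0, 170, 3, 3, motif="AAAA"),  # < 171: counted
            _frag(0, 171, 3, 3, motif="CCCC"),  # excluded by length
            _frag(0, 150, 3, 3, motif=None),    # no motif
        ]
        fem = compute_fem(SampleFragments.from_fragments("s", frags))
        assert fem[MOTIFS_4MER.index("AAAA")] == 1.0
        assert fem[MOTIFS_4MER.index("CCCC")] == 0.0

    def test_no_qualifying_fragments_all_zero(self):
        fem = compute_fem(SampleFragments.from_fragments("s", [_frag(0, 200, 3, 3, motif="ACGT")]))
        assert (fem == 0).all()

    def test_matches_tally_oracle_and_duplication_invariance(self, rng):
        frags = []
        counts = {}
        for _ in range(200):
            m = "".join(rng.choice(list("ACGT"), 4))
            L = int(rng.integers(80, 260))
            frags.append(_frag(0, L, 3, 3, motif=m))
            if L <= 170:
                counts[m] = counts.get(m, 0) + 1
        s = SampleFragments.from_fragments("s", frags)
        fem = compute_fem(s)
        total = sum(counts.values())
        for m, c in counts.items():
            assert fem[MOTIFS_4MER.index(m)] == pytest.approx(c / total)
        doubled = SampleFragments.from_fragments("s", frags + frags)
        np.testing.assert_allclose(compute_fem(doubled), fem, atol=1e-12)
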