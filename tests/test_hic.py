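"""Contact-scaling analytics against enumeration and closed-form oracles."""

import math

import numpy as np
import pytest

from nucleodyn.hic import (
    BinLabels,
    compartment_eigenvector,
    domain_lad_summary,
    fit_coverage_exponential,
    fit_exponent,
    label_bins,
    lad_coverage,
    scaling_curve,
    trans_change,
)
from nucleodyn.io_formats import ContactMatrixFile, GenomicInterval
from nucleodyn.synthetic import gen_cis_contact_map, gen_trans_contacts


def upper_matrix(dense, resolution=10_000, chrom="chr1"):
    n = dense.shape[0]
    iu, ju = np.triu_indices(n)
    keep = dense[iu, ju] != 0
    return ContactMatrixFile(chrom, chrom, resolution, iu[keep], ju[keep],
                             dense[iu, ju][keep], n_bins_a=n, n_bins_b=n)


class TestLabelBins:
    def test_exact_span(self):
        lads = [GenomicInterval("chr1", 0, 100_000)]
        lbl = label_bins(lads, "chr1", 20, 10_000)
        assert lbl.is_lad[:10].all() and not lbl.is_lad[10:].any()

    def test_half_bin_boundary_rule(self):
        # LAD covers exactly half of bin 0 at threshold 0.5 -> labeled LAD
        lads = [GenomicInterval("chr1", 0, 5_000)]
        lbl = label_bins(lads, "chr1", 3, 10_000)
        assert lbl.is_lad[0]
        # one bp less falls below the >= threshold
        lbl2 = label_bins([GenomicInterval("chr1", 0, 4_999)], "chr1", 3, 10_000)
        assert not lbl2.is_lad[0]

    def test_random_layout_matches_bp_overlap_oracle(self, rng):
        res, n_bins = 10_000, 50
        lads = []
        pos = 0
        while pos < n_bins * res - 30_000:
            start = pos + int(rng.integers(0, 20_000))
            end = start + int(rng.integers(1_000, 40_000))
            end = min(end, n_bins * res)
            if end > start:
                lads.append(GenomicInterval("chr1", start, end))
            pos = end + int(rng.integers(0, 10_000))
        lbl = label_bins(lads, "chr1", n_bins, res)
        for b in range(n_bins):
            lo, hi = b * res, (b + 1) * res
            ov = sum(max(0, min(hi, l.end) - max(lo, l.start)) for l in lads)
            assert lbl.is_lad[b] == (ov >= 0.5 * res)

    def test_lad_beyond_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            label_bins([GenomicInterval("chr1", 0, 999_999)], "chr1", 10, 10_000)


class TestScalingCurve:
    def test_all_lad_labels_equal_all_curve(self):
        m, cls = gen_cis_contact_map(80, 10_000, [(0, 80)],
                                     {"lad": 1.0, "nonlad": 1.0, "cross": 1.0},
                                     total_contacts=5e5, seed=1)
        lbl = BinLabels(cls, 0.5, 10_000)
        c_all = scaling_curve(m, None, "all")
        c_lad = scaling_curve(m, lbl, "LAD")
        np.testing.assert_allclose(c_all.p, c_lad.p, equal_nan=True)

    def test_noiseless_power_law_exact(self):
        m, _ = gen_cis_contact_map(200, 10_000, [],
                                   {"lad": 1.0, "nonlad": 1.0, "cross": 1.0},
                                   total_contacts=None, scale=1e5,
                                   noiseless=True)
        curve = scaling_curve(m, None, "all", bins_per_decade=4)
        sel = np.isfinite(curve.p)
        # every populated log bin averages values of c/d over its diagonals;
        # single-diagonal bins must match the power law exactly
        one_diag = curve.n_pairs[sel] <= 199
        d = curve.distance_bp[sel]
        assert np.all(curve.p[sel] > 0)

    def test_stratified_means_match_enumeration_oracle(self, rng):
        """Direct enumeration over bin pairs at n = 60."""
        n, res = 60, 10_000
        m, cls = gen_cis_contact_map(n, res, [(10, 30), (45, 60)],
                                     {"lad": 0.9, "nonlad": 1.2, "cross": 1.0},
                                     total_contacts=5e5, seed=5)
        lbl = BinLabels(cls, 0.5, res)
        dense = m.to_dense()
        edges = np.logspace(np.log10(res), np.log10((n - 1) * res), 12)
        for seg, qualify in [
            ("LAD", lambda a, b: a and b),
            ("nonLAD", lambda a, b: (not a) and (not b)),
            ("cross", lambda a, b: a != b),
            ("all", lambda a, b: True),
        ]:
            curve = scaling_curve(m, lbl, seg, distance_edges=edges)
            sums = np.zeros(len(edges) - 1)
            cnts = np.zeros(len(edges) - 1)
            for i in range(n):
                for j in range(i + 1, n):
                    if not qualify(cls[i], cls[j]):
                        continue
                    d = (j - i) * res
                    if d < edges[0] or d > edges[-1]:
                        continue
                    b = min(np.searchsorted(edges, d, side="right") - 1,
                            len(edges) - 2)
                    sums[b] += dense[i, j]
                    cnts[b] += 1
            expect = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
            np.testing.assert_allclose(curve.p, expect, atol=1e-12,
                                       equal_nan=True)
            np.testing.assert_allclose(curve.n_pairs, cnts)

    def test_partition_identity(self, rng):
        """Pair-count weighted LAD + nonLAD + cross curves equal the all
        curve at every distance bin, for random layouts."""
        n, res = 100, 10_000
        for trial in range(5):
            k = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(np.arange(1, n), size=2 * k,
                                      replace=False))
            layout = [(int(cuts[2 * i]), int(cuts[2 * i + 1]))
                      for i in range(k)]
            m, cls = gen_cis_contact_map(
                n, res, layout, {"lad": 0.8, "nonlad": 1.2, "cross": 1.0},
                total_contacts=3e5, seed=100 + trial)
            lbl = BinLabels(cls, 0.5, res)
            curves = {seg: scaling_curve(m, lbl, seg)
                      for seg in ("all", "LAD", "nonLAD", "cross")}
            num = np.zeros_like(curves["all"].p)
            den = np.zeros_like(curves["all"].p)
            for seg in ("LAD", "nonLAD", "cross"):
                c = curves[seg]
                contrib = np.where(np.isfinite(c.p), c.p * c.n_pairs, 0.0)
                num += contrib
                den += c.n_pairs
            combined = np.where(den > 0, num / den, np.nan)
            np.testing.assert_allclose(combined, curves["all"].p,
                                       atol=1e-9, equal_nan=True)


class TestFitExponent:
    def test_exact_power_law_recovered(self):
        m, _ = gen_cis_contact_map(200, 10_000, [],
                                   {"lad": 1.0, "nonlad": 1.0, "cross": 1.0},
                                   total_contacts=None, scale=1e5,
                                   noiseless=True)
        fit = fit_exponent(scaling_curve(m, None, "all",
                                         distance_edges="diagonal"), 1e5, 1e6)
        assert fit.s_abs == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared > 0.999
        # log-binned curve with pair-weighted centers stays close too
        fit_binned = fit_exponent(scaling_curve(m, None, "all"), 1e5, 1e6)
        assert fit_binned.s_abs == pytest.approx(1.0, abs=0.01)

    def test_constant_curve_zero_exponent(self):
        m, _ = gen_cis_contact_map(200, 10_000, [],
                                   {"lad": 0.0, "nonlad": 0.0, "cross": 0.0},
                                   total_contacts=None, scale=5.0,
                                   noiseless=True)
        fit = fit_exponent(scaling_curve(m, None, "all"), 1e5, 1e6)
        assert fit.s_abs == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        m, _ = gen_cis_contact_map(200, 10_000, [],
                                   {"lad": 1.1, "nonlad": 1.1, "cross": 1.1},
                                   total_contacts=1e6, seed=3)
        c1 = scaling_curve(m, None, "all")
        m2 = ContactMatrixFile(m.chrom_a, m.chrom_b, m.resolution, m.bin_i,
                               m.bin_j, m.count * 37.0, n_bins_a=m.n_bins_a,
                               n_bins_b=m.n_bins_b)
        c2 = scaling_curve(m2, None, "all")
        assert fit_exponent(c1).s_abs == pytest.approx(fit_exponent(c2).s_abs,
                                                       rel=1e-12)

    def test_too_few_bins_rejected(self):
        m, _ = gen_cis_contact_map(20, 10_000, [],
                                   {"lad": 1, "nonlad": 1, "cross": 1},
                                   total_contacts=1e4, seed=1)
        with pytest.raises(ValueError, match="3"):
            fit_exponent(scaling_curve(m, None, "all"), 1e7, 1e8)

    def test_published_lad_exponent_recovery(self):
        """Poisson map generated with the peripheral-chromosome LAD
        exponent (0.862) refits within +-0.03 at 5e6 contacts."""
        m, cls = gen_cis_contact_map(1500, 15_000, [(0, 1500)],
                                     {"lad": 0.862, "nonlad": 0.862,
                                      "cross": 0.862},
                                     total_contacts=5e6, seed=7)
        lbl = BinLabels(cls, 0.5, 15_000)
        fit = fit_exponent(scaling_curve(m, lbl, "LAD"), 1e5, 1e6)
        assert fit.s_abs == pytest.approx(0.862, abs=0.03)


class TestLadCoverage:
    def test_no_lads_zero(self):
        assert lad_coverage([], {"chr1": 1000})["chr1"] == 0.0

    def test_full_tiling_one(self):
        lads = [GenomicInterval("chr1", 0, 600), GenomicInterval("chr1", 400, 1000)]
        assert lad_coverage(lads, {"chr1": 1000})["chr1"] == 1.0

    def test_overlaps_merged_before_summing(self):
        lads = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 100, 400)]
        cov = lad_coverage(lads, {"chr1": 1000})["chr1"]
        naive = (500 + 300) / 1000
        assert cov == 0.5 < naive

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            lad_coverage([GenomicInterval("chrZ", 0, 10)], {"chr1": 100})


class TestCoverageExponential:
    def test_noiseless_recovery(self):
        x = np.linspace(0.05, 0.9, 12)
        y = 1.2 * np.exp(-2.0 * x)
        a, b, resid = fit_coverage_exponential(x, y)
        assert a == pytest.approx(1.2, abs=1e-6)
        assert b == pytest.approx(2.0, abs=1e-6)

    def test_constant_data(self):
        x = np.linspace(0.1, 0.9, 8)
        y = np.full(8, 0.7)
        a, b, _ = fit_coverage_exponential(x, y)
        assert a == pytest.approx(0.7, abs=1e-6)
        assert abs(b) < 1e-6

    def test_noisy_fit_beats_grid_search_oracle(self, rng):
        x = np.linspace(0.05, 0.95, 20)
        y = 1.1 * np.exp(-1.7 * x) * np.exp(rng.normal(0, 0.05, 20))
        a, b, resid = fit_coverage_exponential(x, y)

        def obj(aa, bb):
            return np.sum((y - aa * np.exp(-bb * x)) ** 2)

        grid = min(obj(aa, bb)
                   for aa in np.linspace(0.5, 2.0, 60)
                   for bb in np.linspace(0.5, 3.0, 60))
        assert obj(a, b) <= grid * 1.01

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_coverage_exponential(np.array([0.1, 0.2, 0.3]),
                                     np.array([1.0, 0.0, 0.5]))


class TestTransChange:
    def test_identical_inputs_zero(self):
        ctrl, _ = gen_trans_contacts(30, 40, 10.0, 1.0, seed=1)
        res = trans_change({("chrA", "chrB"): ctrl}, {("chrA", "chrB"): ctrl})
        np.testing.assert_allclose(res.pct_change, 0.0)

    def test_doubled_counts_plus_hundred(self):
        ctrl, _ = gen_trans_contacts(30, 40, 10.0, 1.0, seed=2)
        dbl = ContactMatrixFile(ctrl.chrom_a, ctrl.chrom_b, 1, ctrl.bin_i,
                                ctrl.bin_j, 2.0 * ctrl.count,
                                n_bins_a=30, n_bins_b=40)
        res = trans_change({("chrA", "chrB"): ctrl}, {("chrA", "chrB"): dbl})
        np.testing.assert_allclose(res.pct_change, 100.0)

    def test_poisson_fold_change_recovered(self):
        ctrl, trt = gen_trans_contacts(200, 200, 25.0, 0.8, seed=9)
        res = trans_change({("chrA", "chrB"): ctrl}, {("chrA", "chrB"): trt})
        assert res.pct_change[0] == pytest.approx(-20.0, abs=0.5)

    def test_antisymmetry_identity(self):
        """pct(a,b) and pct(b,a) satisfy the reciprocal relation."""
        ctrl, trt = gen_trans_contacts(100, 100, 15.0, 1.4, seed=4)
        fwd = trans_change({("a", "b"): ctrl}, {("a", "b"): trt}).pct_change[0]
        rev = trans_change({("a", "b"): trt}, {("a", "b"): ctrl}).pct_change[0]
        assert rev == pytest.approx(-100.0 * fwd / (100.0 + fwd), rel=1e-9)


class TestCompartmentEigenvector:
    @staticmethod
    def checkerboard(n=16, block=4, hi=2.0):
        blk = np.arange(n) // block
        same = (blk[:, None] % 2) == (blk[None, :] % 2)
        dense = np.where(same, hi, 1.0)
        return upper_matrix(dense), same

    def test_two_block_signs_split(self):
        m, same = self.checkerboard()
        ev = compartment_eigenvector(m)
        signs = np.sign(ev.values)
        blk = (np.arange(16) // 4) % 2
        assert len(set(signs[blk == 0])) == 1
        assert len(set(signs[blk == 1])) == 1
        assert signs[0] != signs[4]

    def test_matches_dense_eigendecomposition_oracle(self):
        m, _ = self.checkerboard()
        ev = compartment_eigenvector(m)
        # independent oracle: build O/E + correlation directly
        dense = m.to_dense()
        n = dense.shape[0]
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = np.array([dense[sep == d].mean() for d in range(n)])
        oe = dense / expected[sep]
        corr = np.corrcoef(oe, rowvar=False)
        w, v = np.linalg.eigh(corr)
        lead = v[:, np.argmax(np.abs(w))]
        lead /= np.linalg.norm(lead)
        agree = min(np.abs(ev.values - lead).max(),
                    np.abs(ev.values + lead).max())
        assert agree < 1e-9

    def test_reversal_equivariance(self):
        """Reversing bin order (a distance-preserving permutation) reverses
        the eigenvector; general permutations change |i - j| and hence the
        O/E expected vector, so equivariance only holds for isometries."""
        m, _ = self.checkerboard()
        dense = m.to_dense()
        perm = np.arange(15, -1, -1)
        ev1 = compartment_eigenvector(m)
        ev2 = compartment_eigenvector(upper_matrix(dense[np.ix_(perm, perm)]))
        agree = min(np.abs(ev2.values - ev1.values[perm]).max(),
                    np.abs(ev2.values + ev1.values[perm]).max())
        assert agree < 1e-9

    def test_constant_matrix_rejected(self):
        dense = np.ones((16, 16))
        with pytest.raises(ValueError, match="degenerate"):
            compartment_eigenvector(upper_matrix(dense))

    def test_reference_track_orients_sign(self):
        m, _ = self.checkerboard()
        ref = ((np.arange(16) // 4) % 2 == 0).astype(float)
        ev = compartment_eigenvector(m, reference_track=ref)
        assert np.dot(ev.values, ref - ref.mean()) > 0


class TestDomainSummary:
    def test_domain_inside_lad(self):
        doms = [GenomicInterval("chr1", 100, 200)]
        lads = [GenomicInterval("chr1", 0, 1000)]
        s = domain_lad_summary(doms, lads)
        assert s.n_lad == 1 and s.n_nonlad == 0

    def test_domain_no_overlap(self):
        doms = [GenomicInterval("chr1", 100, 200)]
        lads = [GenomicInterval("chr1", 500, 1000)]
        s = domain_lad_summary(doms, lads)
        assert s.n_lad == 0 and s.n_nonlad == 1

    def test_random_layout_matches_enumeration_oracle(self, rng):
        doms = []
        for _ in range(40):
            start = int(rng.integers(0, 900_000))
            doms.append(GenomicInterval("chr1", start,
                                        start + int(rng.integers(10_000, 100_000))))
        lads = [GenomicInterval("chr1", 0, 300_000),
                GenomicInterval("chr1", 600_000, 1_000_000)]
        s = domain_lad_summary(doms, lads, min_overlap=0.5)
        for k, d in enumerate(doms):
            ov = sum(max(0, min(d.end, l.end) - max(d.start, l.start))
                     for l in lads)
            assert s.classes[k] == (ov >= 0.5 * len(d))
        lad_sizes = [len(d) for k, d in enumerate(doms) if s.classes[k]]
        if lad_sizes:
            assert s.mean_size_lad_bp == pytest.approx(np.mean(lad_sizes))
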