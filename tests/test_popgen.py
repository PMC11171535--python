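"""Diversity/differentiation estimators against brute-force oracles."""

import itertools

import numpy as np
import pytest

from introscan import (
    AlleleFrequencyTable,
    allele_freqs,
    dxy_window,
    fst_hudson_pair,
    fst_matrix,
    fst_wc_window,
    make_windows,
    nm_from_fst,
    pi_window,
    tajima_constants,
    tajimas_d_window,
)

from conftest import build_panel, popmap_for


# ---------------------------------------------------------------------------
# oracles: all-pairs enumeration on explicit haplotypes
# ---------------------------------------------------------------------------

def pairwise_pi_sum(haps: np.ndarray) -> float:
    """Mean pairwise Hamming distance summed over sites, by enumeration."""
    n = haps.shape[0]
    total = sum(
        np.sum(haps[i] != haps[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def pairwise_dxy_sum(haps_a: np.ndarray, haps_b: np.ndarray) -> float:
    """Mean between-group pairwise Hamming distance summed over sites."""
    total = sum(np.sum(a != b) for a in haps_a for b in haps_b)
    return total / (haps_a.shape[0] * haps_b.shape[0])


def tajimas_d_oracle(haps: np.ndarray) -> float:
    """Tajima's D by stepwise evaluation of the 1989 constants."""
    n, S_total = haps.shape
    seg = [(haps[:, s].sum() not in (0, n)) for s in range(S_total)]
    S = sum(seg)
    c = tajima_constants(n)
    pi_sum = pairwise_pi_sum(haps)
    return (pi_sum - S / c["a1"]) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))


def rand_haps(rng, n, S):
    return (rng.random((n, S)) < rng.uniform(0.1, 0.9, size=S)).astype(np.int8)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFreqs:
    def test_direct_count(self):
        # two samples: 0/0 and 0/1 at one site
        panel = build_panel(np.array([[0], [0], [0], [1]], dtype=np.int8), pos=[5])
        pm = popmap_for(panel, ["A", "A"])
        t = allele_freqs(panel, pm)
        assert t.called_count[0, 0] == 4
        assert t.freq[0, 0] == pytest.approx(0.25)

    def test_all_missing_population_gets_nan(self):
        haps = np.array([[0], [1], [-1], [-1]], dtype=np.int8)
        panel = build_panel(haps, pos=[5])
        pm = popmap_for(panel, ["A", "B"])
        t = allele_freqs(panel, pm)
        assert np.isnan(t.freq[0, t.populations.index("B")])
        assert t.freq[0, t.populations.index("A")] == pytest.approx(0.5)

    def test_matches_per_sample_recount_on_simulation(self, sim_small, sim_small_freqs):
        panel, popmap, _, _ = sim_small
        t = sim_small_freqs
        rng = np.random.default_rng(11)
        for pop in popmap.populations:
            cols = [panel.samples.index(s) for s in popmap.samples_for(pop)]
            k = t.populations.index(pop)
            for site in rng.integers(0, panel.n_sites, size=25):
                g = panel.genotypes[site, cols, :]
                alt = int((g == 1).sum())
                called = int((g >= 0).sum())
                assert t.alt_count[site, k] == alt
                assert t.called_count[site, k] == called


# ---------------------------------------------------------------------------
# FST and Nm
# ---------------------------------------------------------------------------

def table_from_freqs(freq_a, freq_b, n_a, n_b, pos=None):
    S = len(freq_a)
    pos = pos if pos is not None else np.arange(1, S + 1)
    alt = np.column_stack([
        np.round(np.asarray(freq_a) * n_a), np.round(np.asarray(freq_b) * n_b)
    ]).astype(np.int64)
    called = np.column_stack([np.full(S, n_a), np.full(S, n_b)]).astype(np.int64)
    return AlleleFrequencyTable(
        chrom=np.full(S, "1", dtype=object), pos=np.asarray(pos),
        populations=["A", "B"], alt_count=alt, called_count=called,
    )


class TestHudsonFst:
    def test_fixed_difference_approaches_one(self):
        t = table_from_freqs([1.0] * 5, [0.0] * 5, 1000, 1000)
        assert fst_hudson_pair(t, "A", "B") == pytest.approx(1.0, abs=1e-2)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.1, 0.9, 50)
        t = table_from_freqs(f, f, 200, 200)
        assert abs(fst_hudson_pair(t, "A", "B")) < 0.01

    def test_matches_per_site_formula_oracle(self):
        rng = np.random.default_rng(2)
        fa = rng.integers(0, 41, 20) / 40
        fb = rng.integers(0, 31, 20) / 30
        t = table_from_freqs(fa, fb, 40, 30)
        num = den = 0.0
        for pa, pb in zip(fa, fb):
            num += (pa - pb) ** 2 - pa * (1 - pa) / 39 - pb * (1 - pb) / 29
            den += pa * (1 - pb) + pb * (1 - pa)
        assert fst_hudson_pair(t, "A", "B") == pytest.approx(num / den, abs=1e-12)

    def test_allele_label_symmetry(self):
        rng = np.random.default_rng(3)
        fa = rng.integers(0, 21, 30) / 20
        fb = rng.integers(0, 21, 30) / 20
        t = table_from_freqs(fa, fb, 20, 20)
        t_flip = table_from_freqs(1 - fa, 1 - fb, 20, 20)
        assert fst_hudson_pair(t, "A", "B") == pytest.approx(
            fst_hudson_pair(t_flip, "A", "B"), abs=1e-12
        )

    def test_no_joint_sites_errors(self):
        t = AlleleFrequencyTable(
            chrom=np.array(["1"], dtype=object), pos=np.array([1]),
            populations=["A", "B"],
            alt_count=np.array([[1, 0]]), called_count=np.array([[10, 0]]),
        )
        with pytest.raises(ValueError, match="jointly called"):
            fst_hudson_pair(t, "A", "B")


class TestNm:
    @pytest.mark.parametrize(
        "fst,expected",
        [(0.001, 249.750), (0.004, 62.250), (0.726, 0.094)],
    )
    def test_printed_anchor_values(self, fst, expected):
        assert round(nm_from_fst(fst), 3) == expected

    def test_monotone_decreasing_and_boundary(self):
        grid = np.linspace(0.01, 1.0, 50)
        vals = [nm_from_fst(f) for f in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert nm_from_fst(1.0) == 0.0

    def test_nonpositive_fst_gives_inf_with_warning(self):
        with pytest.warns(UserWarning):
            assert nm_from_fst(0.0) == float("inf")


class TestFstMatrix:
    def test_symmetric_with_zero_diagonal(self, sim_small, sim_small_freqs):
        _, popmap, _, _ = sim_small
        m = fst_matrix(sim_small_freqs, popmap)
        np.testing.assert_allclose(m.fst, m.fst.T, atol=1e-12)
        assert np.all(np.diag(m.fst) == 0)

    def test_nested_topology_orders_fst(self, sim_small, sim_small_freqs):
        _, popmap, _, _ = sim_small
        m = fst_matrix(sim_small_freqs, popmap)
        f = m.to_frame("fst")
        assert f.loc["P1", "P2"] < f.loc["P1", "P3"] < f.loc["P1", "O"]

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(4)
        haps = rand_haps(rng, 40, 200)
        panel = build_panel(np.vstack([haps, haps]), pos=np.arange(1, 201))
        pm = popmap_for(panel, ["A"] * 20 + ["B"] * 20)
        m = fst_matrix(allele_freqs(panel, pm), pm)
        # identical frequency vectors: ratio-of-sums collapses to -1/(n-1)
        assert m.to_frame("fst").loc["A", "B"] == pytest.approx(-1 / 39, abs=1e-12)
        assert abs(m.to_frame("fst").loc["A", "B"]) < 0.03


class TestWeirCockerhamWindows:
    def test_identical_pops_near_zero(self):
        rng = np.random.default_rng(5)
        haps = rand_haps(rng, 40, 100)
        panel = build_panel(np.vstack([haps, haps]), pos=np.arange(1, 101))
        pm = popmap_for(panel, ["A"] * 20 + ["B"] * 20)
        w = make_windows(panel.chrom, panel.pos, 1000)
        res = fst_wc_window(panel, pm, "A", "B", w)
        assert abs(res["fst_wc"].iloc[0]) < 0.05

    def test_single_site_matches_component_oracle(self):
        # 5 + 4 diploids, explicit genotypes
        haps = np.array(
            [[1], [1], [1], [0], [0], [0], [1], [0], [0], [0],   # pop A: 5 dips
             [1], [1], [0], [0], [1], [0], [0], [0]], dtype=np.int8
        )
        panel = build_panel(haps, pos=[50])
        pm = popmap_for(panel, ["A"] * 5 + ["B"] * 4)
        w = make_windows(panel.chrom, panel.pos, 100)
        got = fst_wc_window(panel, pm, "A", "B", w)["fst_wc"].iloc[0]

        # oracle: Weir & Cockerham components evaluated stepwise
        g = panel.genotypes[0]
        ga, gb = g[:5], g[5:]
        n1, n2 = 5.0, 4.0
        p1 = (ga == 1).sum() / (2 * n1)
        p2 = (gb == 1).sum() / (2 * n2)
        h1 = float(np.mean(ga[:, 0] != ga[:, 1]))
        h2 = float(np.mean(gb[:, 0] != gb[:, 1]))
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        assert got == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_agrees_with_hudson_genomewide(self, sim_small, sim_small_freqs):
        panel, popmap, _, _ = sim_small
        hudson = fst_hudson_pair(sim_small_freqs, "P1", "P3")
        w = make_windows(panel.chrom, panel.pos, 1_000_000_000)
        wc = fst_wc_window(panel, popmap, "P1", "P3", w)["fst_wc"].iloc[0]
        assert wc == pytest.approx(hudson, abs=0.05)


# ---------------------------------------------------------------------------
# pi / dxy / Tajima's D
# ---------------------------------------------------------------------------

class TestDiversityWindows:
    def test_two_haplotypes_one_diff_in_10bp(self):
        haps = np.array([[0], [1]], dtype=np.int8)
        panel = build_panel(haps, pos=[3])
        pm = popmap_for(panel, ["A"])
        w = make_windows(np.array(["1"] * 1, dtype=object), np.array([10]), 10)
        res = pi_window(panel, pm, "A", w)
        assert res["pi"].iloc[0] == pytest.approx(0.1)

    def test_monomorphic_window_is_zero(self):
        haps = np.zeros((6, 3), dtype=np.int8)
        panel = build_panel(haps, pos=[1, 5, 9])
        pm = popmap_for(panel, ["A"] * 3)
        w = make_windows(panel.chrom, panel.pos, 10)
        assert pi_window(panel, pm, "A", w)["pi"].iloc[0] == 0.0

    def test_pi_equals_allpairs_enumeration(self):
        rng = np.random.default_rng(6)
        haps = rand_haps(rng, 12, 40)
        panel = build_panel(haps, pos=np.arange(1, 41))
        pm = popmap_for(panel, ["A"] * 6)
        w = make_windows(panel.chrom, panel.pos, 40)
        got = pi_window(panel, pm, "A", w)["pi"].iloc[0]
        assert got == pytest.approx(pairwise_pi_sum(haps) / 40, abs=1e-9)

    def test_dxy_single_site_half(self):
        haps = np.array([[0], [1], [0], [1]], dtype=np.int8)
        panel = build_panel(haps, pos=[1])
        pm = popmap_for(panel, ["A", "B"])
        w = make_windows(panel.chrom, panel.pos, 1)
        assert dxy_window(panel, pm, "A", "B", w)["dxy"].iloc[0] == pytest.approx(0.5)

    def test_dxy_identical_monomorphic_pops_zero(self):
        haps = np.ones((8, 5), dtype=np.int8)
        panel = build_panel(haps, pos=[1, 2, 3, 4, 5])
        pm = popmap_for(panel, ["A"] * 2 + ["B"] * 2)
        w = make_windows(panel.chrom, panel.pos, 5)
        assert dxy_window(panel, pm, "A", "B", w)["dxy"].iloc[0] == 0.0

    def test_dxy_equals_cross_pair_enumeration(self):
        rng = np.random.default_rng(7)
        ha, hb = rand_haps(rng, 8, 30), rand_haps(rng, 6, 30)
        panel = build_panel(np.vstack([ha, hb]), pos=np.arange(1, 31))
        pm = popmap_for(panel, ["A"] * 4 + ["B"] * 3)
        w = make_windows(panel.chrom, panel.pos, 30)
        got = dxy_window(panel, pm, "A", "B", w)["dxy"].iloc[0]
        assert got == pytest.approx(pairwise_dxy_sum(ha, hb) / 30, abs=1e-9)


class TestTajimasD:
    def test_worked_four_haplotype_instance(self):
        haps = np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        panel = build_panel(haps, pos=[1, 2, 3])
        pm = popmap_for(panel, ["A", "A"])
        w = make_windows(panel.chrom, panel.pos, 10)
        got = tajimas_d_window(panel, pm, "A", w)["tajimas_d"].iloc[0]
        assert got == pytest.approx(tajimas_d_oracle(haps), abs=1e-9)
        assert got == pytest.approx(2.01, abs=0.01)

    def test_matches_enumeration_oracle_on_random_panels(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            haps = rand_haps(rng, 10, 25)
            if len(np.unique(haps.sum(axis=0))) < 2:
                continue
            panel = build_panel(haps, pos=np.arange(1, 26))
            pm = popmap_for(panel, ["A"] * 5)
            w = make_windows(panel.chrom, panel.pos, 25)
            got = tajimas_d_window(panel, pm, "A", w)["tajimas_d"].iloc[0]
            assert got == pytest.approx(tajimas_d_oracle(haps), abs=1e-9)

    def test_all_singletons_negative(self):
        haps = np.zeros((10, 8), dtype=np.int8)
        for s in range(8):
            haps[s % 10, s] = 1
        panel = build_panel(haps, pos=np.arange(1, 9))
        pm = popmap_for(panel, ["A"] * 5)
        w = make_windows(panel.chrom, panel.pos, 8)
        assert tajimas_d_window(panel, pm, "A", w)["tajimas_d"].iloc[0] < 0

    def test_no_segregating_sites_missing(self):
        haps = np.zeros((8, 4), dtype=np.int8)
        panel = build_panel(haps, pos=[1, 2, 3, 4])
        pm = popmap_for(panel, ["A"] * 4)
        w = make_windows(panel.chrom, panel.pos, 4)
        assert np.isnan(tajimas_d_window(panel, pm, "A", w)["tajimas_d"].iloc[0])
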