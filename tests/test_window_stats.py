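"""Window statistics against brute-force oracles, limits and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralscan.variant_io import GenomeLayout
from feralscan.window_stats import (TajimaConstants, diploid_fst_components,
                                    haploid_fst_components, make_windows,
                                    pooled_heterozygosity, standardize,
                                    tajimas_d, weir_cockerham_fst)

from oracles import (hp_oracle, tajima_oracle, wc_diploid_site_oracle,
                     wc_haploid_site_oracle)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("length,size,step,expected", [
    (100_000, 40_000, 20_000, [(0, 40_000), (20_000, 60_000),
                               (40_000, 80_000), (60_000, 100_000)]),
    (30_000, 40_000, 20_000, []),
    (100_000, 25_000, 25_000, [(0, 25_000), (25_000, 50_000),
                               (50_000, 75_000), (75_000, 100_000)]),
])
def test_make_windows_geometry(length, size, step, expected):
    layout = GenomeLayout(("chr1",), (length,))
    w = make_windows(layout, size, step)
    assert list(zip(w["start"], w["end"])) == expected


def test_make_windows_rejects_step_larger_than_size():
    layout = GenomeLayout(("chr1",), (100_000,))
    with pytest.raises(ValueError):
        make_windows(layout, 10_000, 20_000)


# ---------------------------------------------------------------------------
# pooled heterozygosity
# ---------------------------------------------------------------------------


def test_hp_monomorphic_window_is_zero():
    assert pooled_heterozygosity(np.array([10, 10, 10]),
                                 np.array([0, 0, 0])) == 0.0


def test_hp_symmetric_counts_reach_maximum():
    assert pooled_heterozygosity(np.array([5, 5, 5]),
                                 np.array([5, 5, 5])) == pytest.approx(0.5,
                                                                       abs=0)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                min_size=3, max_size=30))
def test_hp_matches_oracle_and_bounds(counts):
    major = np.array([max(a, b) for a, b in counts])
    minor = np.array([min(a, b) for a, b in counts])
    hp = pooled_heterozygosity(major, minor)
    if (major + minor).sum() == 0:
        assert np.isnan(hp)
    else:
        assert hp == pytest.approx(hp_oracle(major, minor), abs=1e-12)
        assert 0.0 <= hp <= 0.5
        # Hp = 0 iff no minor allele anywhere in the window
        assert (hp == 0.0) == (minor.sum() == 0)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def test_tajima_constants_small_n():
    c = TajimaConstants.from_n(2)
    assert c.a1 == 1.0
    # c1 and c2 (hence e1, e2) vanish exactly at n = 3; positive from n = 4
    c = TajimaConstants.from_n(3)
    assert c.e1 == pytest.approx(0.0, abs=1e-15)
    assert c.e2 == pytest.approx(0.0, abs=1e-15)
    for n in (4, 10, 46):
        c = TajimaConstants.from_n(n)
        assert all(v > 0 for v in (c.a1, c.a2, c.b1, c.b2, c.e1, c.e2))


def test_tajima_two_haplotypes_is_zero():
    # n = 2: theta_pi = S and a1 = 1 force a zero numerator for any S
    rng = np.random.default_rng(0)
    g = rng.integers(0, 2, size=(8, 1)) * 2  # one diploid = 2 haplotypes
    g[:5, 0] = 1  # make 5 heterozygous (segregating) sites
    assert tajimas_d(g) == 0.0


def test_tajima_no_segregating_sites_invalid():
    g = np.zeros((5, 10), dtype=np.int8)
    assert np.isnan(tajimas_d(g))


def test_tajima_matches_pairwise_difference_oracle(rng):
    for _ in range(100):
        n_hap, n_sites = 10, rng.integers(3, 12)
        haps = rng.integers(0, 2, size=(n_hap, n_sites))
        seg = ((haps.sum(axis=0) > 0) & (haps.sum(axis=0) < n_hap)).sum()
        if seg < 3:
            continue
        genotypes = (haps[0::2] + haps[1::2]).T  # (sites, individuals)
        expected = tajima_oracle(haps)
        assert tajimas_d(genotypes) == pytest.approx(expected, abs=1e-12)


def test_tajima_neutral_coalescent_calibration():
    """On panmictic neutral coalescent data mean windowed D is near zero,
    and per-window values agree with tskit's site-mode Tajima's D."""
    msprime = pytest.importorskip("msprime")
    ts = msprime.sim_ancestry(samples=23, population_size=10_000,
                              sequence_length=5_000_000,
                              recombination_rate=1e-8, random_seed=5)
    ts = msprime.sim_mutations(ts, rate=2.5e-8, random_seed=5,
                               discrete_genome=False)
    haps = ts.genotype_matrix()  # (sites, 2N)
    positions = np.array([s.position for s in ts.sites()])
    genotypes = haps[:, 0::2] + haps[:, 1::2]
    starts = np.arange(0, 5_000_000 - 40_000 + 1, 20_000)
    ours = []
    for s in starts:
        sel = (positions >= s) & (positions < s + 40_000)
        ours.append(tajimas_d(genotypes[sel]))
    ours = np.array(ours)
    assert np.isfinite(ours).sum() >= 200
    assert abs(np.nanmean(ours)) < 0.5
    # independent cross-check on non-overlapping windows
    edges = np.arange(0, 5_000_001, 40_000, dtype=float)
    theirs = ts.Tajimas_D(windows=edges, mode="site")
    ours_tiled = []
    for s in edges[:-1]:
        sel = (positions >= s) & (positions < s + 40_000)
        ours_tiled.append(tajimas_d(genotypes[sel]))
    ok = np.isfinite(ours_tiled) & np.isfinite(theirs)
    assert ok.sum() > 100
    np.testing.assert_allclose(np.array(ours_tiled)[ok], theirs[ok],
                               atol=1e-9)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def test_fst_fixed_difference_is_one():
    g1 = np.full((5, 10), 2, dtype=np.int8)
    g2 = np.zeros((5, 10), dtype=np.int8)
    a, b, c = diploid_fst_components(g1, g2)
    assert np.allclose(b, 0) and np.allclose(c, 0)
    assert weir_cockerham_fst(a, a + b + c) == pytest.approx(1.0, abs=0)
    counts1 = np.tile([0, 20], (5, 1))
    counts2 = np.tile([20, 0], (5, 1))
    ah, dh = haploid_fst_components(counts1, counts2)
    assert weir_cockerham_fst(ah, dh) == pytest.approx(1.0, abs=1e-12)


def test_fst_identical_populations_near_zero(rng):
    g = rng.integers(0, 3, size=(200, 25), dtype=np.int8)
    a, b, c = diploid_fst_components(g, g)
    fst = weir_cockerham_fst(a, a + b + c)
    assert abs(fst) <= 0.05
    # exact value still matches the oracle site by site
    for i in range(0, 200, 37):
        ao, bo, co = wc_diploid_site_oracle(list(g[i]), list(g[i]))
        assert a[i] == pytest.approx(ao, abs=1e-12)


def test_fst_diploid_matches_component_oracle(rng):
    for _ in range(100):
        n1, n2 = rng.integers(4, 20), rng.integers(4, 20)
        g1 = rng.integers(0, 3, size=(6, n1), dtype=np.int8)
        g2 = rng.integers(0, 3, size=(6, n2), dtype=np.int8)
        a, b, c = diploid_fst_components(g1, g2)
        for i in range(6):
            ao, bo, co = wc_diploid_site_oracle(list(g1[i]), list(g2[i]))
            assert a[i] == pytest.approx(ao, abs=1e-12)
            assert b[i] == pytest.approx(bo, abs=1e-12)
            assert c[i] == pytest.approx(co, abs=1e-12)


def test_fst_haploid_matches_component_oracle(rng):
    for _ in range(100):
        c1 = rng.integers(1, 40, size=(4, 2))
        c2 = rng.integers(1, 40, size=(4, 2))
        a, d = haploid_fst_components(c1, c2)
        for i in range(4):
            ao, do = wc_haploid_site_oracle(*c1[i], *c2[i])
            assert a[i] == pytest.approx(ao, abs=1e-12)
            assert d[i] == pytest.approx(do, abs=1e-12)


def test_fst_permutation_invariance(rng):
    g1 = rng.integers(0, 3, size=(20, 12), dtype=np.int8)
    g2 = rng.integers(0, 3, size=(20, 15), dtype=np.int8)
    a, b, c = diploid_fst_components(g1, g2)
    perm1 = rng.permutation(12)
    perm2 = rng.permutation(15)
    a2, b2, c2 = diploid_fst_components(g1[:, perm1], g2[:, perm2])
    np.testing.assert_allclose(a, a2, atol=1e-14)
    np.testing.assert_allclose(b, b2, atol=1e-14)
    np.testing.assert_allclose(c, c2, atol=1e-14)


def test_fst_no_informative_sites_is_nan():
    num = np.array([np.nan, np.nan])
    den = np.array([np.nan, np.nan])
    assert np.isnan(weir_cockerham_fst(num, den))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def test_standardize_mean_zero_sd_one(rng):
    x = rng.normal(3.0, 2.0, size=500)
    z = standardize(x)
    assert abs(z.mean()) < 1e-9
    assert abs(z.std(ddof=1) - 1.0) < 1e-9


def test_standardize_constant_input_errors():
    with pytest.raises(ValueError):
        standardize(np.full(10, 2.5))


@settings(derandomize=True, max_examples=30)
@given(st.floats(-100, 100), st.floats(0.01, 100))
def test_standardize_affine_invariance(shift, scale):
    x = np.linspace(-3, 5, 40)
    np.testing.assert_allclose(standardize(x), standardize(shift + scale * x),
                               atol=1e-9)


def test_standardize_respects_validity_mask(rng):
    x = rng.normal(size=50)
    valid = np.ones(50, dtype=bool)
    valid[::7] = False
    z = standardize(x, valid)
    assert np.isnan(z[~valid]).all()
    assert abs(np.nanmean(z[valid])) < 1e-9
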