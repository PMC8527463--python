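import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsttrace import (
    fst_covariance,
    global_fst_nc83,
    migrants_from_fst,
    pairwise_fst_nc83,
    popspecific_fst_wg,
)
from fsttrace.genepop import AlleleFreqTable
from conftest import make_af, random_af


# ---------------------------------------------------------------- oracles


def nc83_pair_oracle(af, i, j, use_het):
    """Direct per-locus formula evaluation, ratio of locus sums."""
    p = af.frequencies()
    num = den = 0.0
    for l in range(af.n_loci):
        ni, nj = af.n[l, i], af.n[l, j]
        if ni == 0 or nj == 0:
            continue
        ntilde = 2.0 / (1.0 / ni + 1.0 / nj)
        hi = 1.0 - np.sum(p[l, i] ** 2)
        hj = 1.0 - np.sum(p[l, j] ** 2)
        hbar = (hi + hj) / 2.0
        pbar = (p[l, i] + p[l, j]) / 2.0
        ht_raw = 1.0 - np.sum(pbar**2)
        if use_het:
            if ntilde <= 1:
                continue
            h0 = (af.het[l, i] / ni + af.het[l, j] / nj) / 2.0
            hs = ntilde / (ntilde - 1.0) * (hbar - h0 / (2.0 * ntilde))
            ht = ht_raw + hs / (2.0 * ntilde) - h0 / (4.0 * ntilde)
        else:
            hs = 2.0 * ntilde / (2.0 * ntilde - 1.0) * hbar
            ht = ht_raw + hs / (4.0 * ntilde)
        num += ht - hs
        den += ht
    return num / den if den > 0 else np.nan


def wg_matching_oracle(af):
    """Enumerate allele-copy pairs to get matching proportions, then
    aggregate the genome-wide ratio of sums."""
    K, L = af.n_populations, af.n_loci
    mw = np.zeros((L, K))
    mb = np.zeros(L)
    typed = af.n > 0
    for l in range(L):
        copy_lists = [
            np.repeat(np.arange(len(af.allele_codes)), af.counts[l, k])
            for k in range(K)
        ]
        for k in range(K):
            c = copy_lists[k]
            if len(c) == 0:
                continue
            same = sum(
                int(c[a] == c[b])
                for a in range(len(c))
                for b in range(len(c))
                if a != b
            )
            mw[l, k] = same / (len(c) * (len(c) - 1))
        pair_vals = []
        for i in range(K):
            for j in range(i + 1, K):
                ci, cj = copy_lists[i], copy_lists[j]
                if len(ci) and len(cj):
                    pair_vals.append(
                        np.mean(ci[:, None] == cj[None, :]))
        mb[l] = np.mean(pair_vals) if pair_vals else 0.0
    fst = np.full(K, np.nan)
    for i in range(K):
        v = typed[:, i] & (typed.sum(axis=1) >= 2)
        if v.any():
            fst[i] = (mw[v, i] - mb[v]).sum() / (1.0 - mb[v]).sum()
    return fst


# ------------------------------------------------------------- pairwise


def test_pairwise_identical_frequencies_near_zero():
    n = 10_000
    af = make_af([[[n, n], [n, n]]])
    assert abs(pairwise_fst_nc83(af).values[0, 1]) < 1e-3


def test_pairwise_fixed_difference_is_one():
    n = 10_000
    af = make_af([[[2 * n, 0], [0, 2 * n]]])
    assert pairwise_fst_nc83(af).values[0, 1] == pytest.approx(1.0, abs=1e-3)


def test_pairwise_matches_formula_oracle_small_instances():
    rng = np.random.default_rng(11)
    for _ in range(100):
        af = random_af(rng)
        for use_het in (False,):
            pw = pairwise_fst_nc83(af, use_het=use_het)
            for i in range(af.n_populations):
                for j in range(i + 1, af.n_populations):
                    expected = nc83_pair_oracle(af, i, j, use_het)
                    if np.isnan(expected):
                        assert np.isnan(pw.values[i, j])
                    else:
                        assert pw.values[i, j] == pytest.approx(
                            expected, abs=1e-10)


def test_pairwise_with_heterozygote_tallies_matches_oracle():
    rng = np.random.default_rng(12)
    for _ in range(30):
        af0 = random_af(rng)
        het = np.minimum(rng.integers(0, af0.n + 1), af0.n)
        af = AlleleFreqTable(af0.populations, af0.loci, af0.allele_codes,
                             af0.counts, af0.n, het)
        pw = pairwise_fst_nc83(af, use_het=True)
        for i in range(af.n_populations):
            for j in range(i + 1, af.n_populations):
                expected = nc83_pair_oracle(af, i, j, True)
                if not np.isnan(expected):
                    assert pw.values[i, j] == pytest.approx(expected, abs=1e-10)


def test_pairwise_monomorphic_pair_warns_nan():
    af = make_af([[[20, 0], [20, 0], [10, 10]]])
    with pytest.warns(UserWarning, match="no co-typed polymorphic locus"):
        pw = pairwise_fst_nc83(af)
    assert np.isnan(pw.values[0, 1])
    assert np.isfinite(pw.values[0, 2])


def test_pairwise_symmetric_and_distance_clamp():
    rng = np.random.default_rng(13)
    af = random_af(rng, max_loci=8)
    pw = pairwise_fst_nc83(af)
    np.testing.assert_allclose(pw.values, pw.values.T)
    d = pw.distances()
    assert (d >= 0).all()
    assert np.diag(d).sum() == 0


# ------------------------------------------------- population-specific


def test_popspecific_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(21)
    for _ in range(100):
        af = random_af(rng, max_n=8)
        got = popspecific_fst_wg(af, covariance=False).fst
        expected = wg_matching_oracle(af)
        np.testing.assert_allclose(got, expected, atol=1e-10)


def test_popspecific_identical_large_n_near_zero():
    n = 10**6
    af = make_af(np.tile([[n, n]], (3, 4, 1)))
    fst = popspecific_fst_wg(af, covariance=False).fst
    assert np.abs(fst).max() < 1e-5


def test_popspecific_negative_value_admissible():
    # H_S1 = 0.5 with H_B = 0.4 gives psFst = 1 - 0.5/0.4 = -0.25
    n = 10**7
    p = 0.887298334620742  # p^2 + (1-p)^2 = 0.8 for the other two pops
    c_other = [round(2 * n * p), 2 * n - round(2 * n * p)]
    af = make_af([[[n, n], c_other, c_other]])
    fst = popspecific_fst_wg(af, covariance=False).fst
    assert fst[0] == pytest.approx(-0.25, abs=1e-3)


def test_popspecific_ratio_of_averages_identity():
    """Genome-wide psFst_i == 1 - sum_l H_Si / sum_l H_B exactly."""
    rng = np.random.default_rng(22)
    for _ in range(20):
        af = random_af(rng, max_loci=8)
        res = popspecific_fst_wg(af, covariance=False)
        hs = 1.0 - res.m_w
        hb = 1.0 - res.m_b
        for i in range(af.n_populations):
            v = res.valid[:, i]
            if v.any():
                alt = 1.0 - hs[v, i].sum() / hb[v].sum()
                assert res.fst[i] == pytest.approx(alt, abs=1e-12)


def test_popspecific_monotone_in_own_heterozygosity():
    """Concentrating a population onto its majority allele at every locus
    (minimizing its heterozygosity) cannot decrease its psFst."""
    rng = np.random.default_rng(23)
    for _ in range(200):
        af = random_af(rng)
        f0 = popspecific_fst_wg(af, covariance=False).fst
        if np.isnan(f0).any():  # every locus monomorphic: undefined
            continue
        i = int(rng.integers(af.n_populations))
        c = af.counts.copy()
        for l in range(af.n_loci):
            tot = c[l, i].sum()
            maj = np.argmax(c[l, i])
            c[l, i] = 0
            c[l, i, maj] = tot
        f1 = popspecific_fst_wg(make_af(c), covariance=False).fst
        if not np.isnan(f1[i]):
            assert f1[i] >= f0[i] - 1e-12


def test_popspecific_requires_two_populations():
    af = make_af([[[10, 10]]])
    with pytest.raises(ValueError):
        popspecific_fst_wg(af)


# ------------------------------------------------------------ jackknife


def test_jackknife_se_shrinks_with_duplicated_loci():
    rng = np.random.default_rng(31)
    L, K, U, n = 40, 4, 3, 10
    counts = np.stack(
        [rng.multinomial(2 * n, rng.dirichlet(np.ones(U)), size=L)
         for _ in range(K)], axis=1)
    af = make_af(counts)
    _, se1 = fst_covariance(af)
    k = 4
    af_dup = AlleleFreqTable(
        af.populations, [f"{l}_{r}" for r in range(k) for l in af.loci],
        af.allele_codes, np.tile(af.counts, (k, 1, 1)), np.tile(af.n, (k, 1)),
    )
    _, se_k = fst_covariance(af_dup)
    ratio = se1 / se_k
    np.testing.assert_allclose(ratio, np.sqrt(k), rtol=0.05)


def test_jackknife_covariance_is_psd_with_nonneg_diagonal():
    rng = np.random.default_rng(32)
    done = 0
    while done < 20:
        af = random_af(rng, max_loci=8)
        if af.n_loci < 2:
            continue
        done += 1
        omega, se = fst_covariance(af)
        assert (np.diag(omega) >= 0).all()
        assert np.linalg.eigvalsh(omega).min() >= -1e-12
        np.testing.assert_allclose(se, np.sqrt(np.diag(omega)))


def test_jackknife_needs_two_loci():
    af = make_af([[[10, 10], [4, 16]]])
    with pytest.raises(ValueError):
        fst_covariance(af)


# ---------------------------------------------------------------- misc


@pytest.mark.parametrize("fst, expected", [(0.02, 49.0), (0.5, 1.0),
                                           (1 / 101, 100.0)])
def test_migrants_from_fst(fst, expected):
    assert migrants_from_fst(fst) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
def test_migrants_from_fst_domain(bad):
    with pytest.raises(ValueError):
        migrants_from_fst(bad)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_estimators_agree_with_oracles_property(seed):
    """Both genome-wide estimators coincide with their brute-force
    oracles on arbitrary seeded small instances."""
    rng = np.random.default_rng(seed)
    af = random_af(rng, max_n=6)
    np.testing.assert_allclose(
        popspecific_fst_wg(af, covariance=False).fst,
        wg_matching_oracle(af), atol=1e-10)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        pw = pairwise_fst_nc83(af, use_het=False)
    for i in range(af.n_populations):
        for j in range(i + 1, af.n_populations):
            expected = nc83_pair_oracle(af, i, j, False)
            if np.isnan(expected):
                assert np.isnan(pw.values[i, j])
            else:
                assert pw.values[i, j] == pytest.approx(expected, abs=1e-10)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(1e-9, 1 - 1e-9))
def test_migrant_conversion_inverts_island_model(fst):
    """4Nem = 1/fst - 1 inverts fst = 1/(4Nem + 1) across the domain."""
    nm = migrants_from_fst(fst)
    assert nm > 0
    assert 1.0 / (nm + 1.0) == pytest.approx(fst, rel=1e-9)


def test_global_fst_between_zero_and_pairwise_extremes():
    n = 10_000
    af = make_af([[[2 * n, 0], [0, 2 * n]]])
    assert global_fst_nc83(af) == pytest.approx(1.0, abs=1e-3)
    af0 = make_af([[[n, n], [n, n], [n, n]]])
    assert abs(global_fst_nc83(af0)) < 1e-3
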