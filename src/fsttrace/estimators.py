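"""Genome-wide F_ST moment estimators.

Two bias-corrected "ratio of averages" estimators:

* Pairwise F_ST between populations (i, j) in the Nei–Chesser (1983)
  form, pwF_ST = (H_T - H_S) / H_T, with per-locus gene diversities
  corrected for finite sample size (harmonic-mean sample size over the
  pair, and the observed-heterozygote correction when genotype tallies
  are available).

* Population-specific F_ST in the Weir–Goudet allele-matching form,
  psF_ST^i = (M_Wi - M_B) / (1 - M_B) = 1 - H_Si / H_B, where M_Wi is
  the probability that two distinct allele copies drawn from population
  i match, and M_B the matching probability averaged over all pairs of
  populations.  psF_ST^i may be negative when population i is more
  diverse than the between-pair average — the signature of an ancestral
  (source) population.

Both estimators aggregate over loci as the ratio of summed numerators
to summed denominators, which converges to the true value by the law of
large numbers as the number of loci grows.  Standard errors and the
between-population covariance of the population-specific estimates come
from a leave-one-locus-out jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genepop import AlleleFreqTable

__all__ = [
    "PairwiseFstMatrix",
    "PopSpecificFstResult",
    "pairwise_fst_nc83",
    "popspecific_fst_wg",
    "fst_covariance",
    "migrants_from_fst",
    "global_fst_nc83",
]


@dataclass
class PairwiseFstMatrix:
    """Symmetric matrix of genome-wide pairwise F_ST (NC83).

    ``num[i, j]`` and ``den[i, j]`` hold the locus sums of
    (H_T - H_S) and H_T, so ``values = num / den`` is the ratio of
    averages; the diagonal is 0 by convention.
    """

    populations: list[str]
    values: np.ndarray
    num: np.ndarray
    den: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations,
                            columns=self.populations)

    def distances(self) -> np.ndarray:
        """Values as a distance matrix: negatives clamped to 0, diagonal 0.

        Raw (possibly negative) estimates stay available in ``values``.
        """
        d = np.where(np.isnan(self.values), 0.0, np.maximum(self.values, 0.0))
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class PopSpecificFstResult:
    """Genome-wide population-specific F_ST with SEs and covariance.

    ``m_w[l, i]`` / ``m_b[l]`` are the per-locus within-population and
    between-pair matching components; ``valid[l, i]`` marks the loci
    entering population i's sums.  ``se`` and ``omega`` are filled by
    the jackknife (:func:`fst_covariance`).
    """

    populations: list[str]
    fst: np.ndarray
    m_w: np.ndarray
    m_b: np.ndarray
    valid: np.ndarray
    se: Optional[np.ndarray] = None
    omega: Optional[np.ndarray] = None

    def to_dataframe(self) -> pd.DataFrame:
        data = {"population": self.populations, "Fst": self.fst}
        if self.se is not None:
            data["SE"] = self.se
        return pd.DataFrame(data)


def migrants_from_fst(fst: float) -> float:
    """Island-model effective migrant number 4Nem from an equilibrium F_ST.

    Under Wright's island model at drift–migration–mutation equilibrium,
    F_ST ≈ 1 / (4Nem + 1), so 4Nem = 1/F_ST - 1 (e.g. F_ST = 0.02 gives
    49 migrants per generation).
    """
    if not (0.0 < fst < 1.0):
        raise ValueError(f"fst must lie in (0, 1), got {fst}")
    return 1.0 / fst - 1.0


def _pair_components(p, sumsq, n, h0, i, j, use_het):
    """Per-locus (H_S, H_T, valid) for one population pair."""
    valid = (n[:, i] > 0) & (n[:, j] > 0)
    ni = n[:, i].astype(float)
    nj = n[:, j].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ntilde = 2.0 / (1.0 / ni + 1.0 / nj)
        hbar = 1.0 - 0.5 * (sumsq[:, i] + sumsq[:, j])
        pbar = 0.5 * (p[:, i, :] + p[:, j, :])
        ht_raw = 1.0 - np.einsum("lu,lu->l", pbar, pbar)
        if use_het:
            h0bar = 0.5 * (h0[:, i] / ni + h0[:, j] / nj)
            hs = (ntilde / (ntilde - 1.0)) * (hbar - h0bar / (2.0 * ntilde))
            ht = ht_raw + hs / (2.0 * ntilde) - h0bar / (4.0 * ntilde)
            valid &= ntilde > 1.0
        else:
            hs = (2.0 * ntilde / (2.0 * ntilde - 1.0)) * hbar
            ht = ht_raw + hs / (4.0 * ntilde)
    return hs, ht, valid


def pairwise_fst_nc83(af: AlleleFreqTable,
                      use_het: Optional[bool] = None) -> PairwiseFstMatrix:
    """Genome-wide NC83 pairwise F_ST between all population pairs.

    Per locus and pair, the bias-corrected within-pair gene diversity
    Ĥ_S and total gene diversity Ĥ_T use the harmonic-mean sample size
    ñ over the two populations.  When observed-heterozygote tallies are
    available (``use_het`` defaults to their presence) the full NC83
    correction applies; otherwise the frequency-only 2ñ/(2ñ-1) form.
    Loci monomorphic across a pair contribute 0 to both locus sums; a
    pair with no co-typed polymorphic locus is reported as NaN with a
    warning.
    """
    K = af.n_populations
    if K < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    if use_het is None:
        use_het = af.het is not None
    if use_het and af.het is None:
        raise ValueError("use_het=True but no heterozygote tallies available")

    p = af.frequencies()
    p = np.where(np.isnan(p), 0.0, p)
    sumsq = np.einsum("lku,lku->lk", p, p)
    h0 = af.het.astype(float) if af.het is not None else None

    values = np.zeros((K, K))
    num = np.zeros((K, K))
    den = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            hs, ht, valid = _pair_components(p, sumsq, af.n, h0, i, j, use_het)
            s_num = np.where(valid, ht - hs, 0.0).sum()
            s_den = np.where(valid, ht, 0.0).sum()
            num[i, j] = num[j, i] = s_num
            den[i, j] = den[j, i] = s_den
            if s_den <= 0.0:
                warnings.warn(
                    f"populations {af.populations[i]!r} and {af.populations[j]!r} "
                    "share no co-typed polymorphic locus; pairwise F_ST undefined"
                )
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = s_num / s_den
    return PairwiseFstMatrix(list(af.populations), values, num, den)


def _matching_components(af: AlleleFreqTable):
    """Per-locus M_Wi (within) and M_B (mean over population pairs)."""
    n2 = 2.0 * af.n  # allele copies
    c = af.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # matching of two distinct copies drawn without replacement
        m_w = np.einsum("lku->lk", c * (c - 1.0)) / (n2 * (n2 - 1.0))
    typed = af.n > 0
    m_w = np.where(typed, m_w, 0.0)

    p = af.frequencies()
    p = np.where(np.isnan(p), 0.0, p)
    k_typed = typed.sum(axis=1).astype(float)
    s = p.sum(axis=1)  # (L, U) sum of freqs over typed pops
    cross = 0.5 * (np.einsum("lu,lu->l", s, s) - np.einsum("lku,lku->l", p, p))
    n_pairs = k_typed * (k_typed - 1.0) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        m_b = cross / n_pairs
    usable = k_typed >= 2
    m_b = np.where(usable, m_b, 0.0)
    valid = typed & usable[:, None]
    return m_w, m_b, valid


def popspecific_fst_wg(af: AlleleFreqTable,
                       covariance: bool = True) -> PopSpecificFstResult:
    """Genome-wide Weir–Goudet population-specific F_ST.

    Per locus, M̂_Wi = Σ_u c_u(c_u - 1) / (2n(2n - 1)) and M̂_B is the
    unweighted mean over population pairs typed at the locus of
    Σ_u p̃_iu p̃_i'u.  Genome wide,
    psF̂_i = Σ_l (M̂_Wi - M̂_B) / Σ_l (1 - M̂_B), summing over the loci
    typed in population i (with ≥2 populations typed).  With
    ``covariance=True`` the jackknife SEs and covariance are attached.
    """
    if af.n_populations < 2:
        raise ValueError("population-specific F_ST needs at least two populations")
    m_w, m_b, valid = _matching_components(af)
    if not valid.any(axis=0).all():
        missing = [p for p, ok in zip(af.populations, valid.any(axis=0)) if not ok]
        warnings.warn(f"populations typed at zero usable loci: {missing}")

    num = np.where(valid, m_w - m_b[:, None], 0.0).sum(axis=0)
    den = np.where(valid, 1.0 - m_b[:, None], 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = num / den
    fst = np.where(valid.any(axis=0), fst, np.nan)
    res = PopSpecificFstResult(list(af.populations), fst, m_w, m_b, valid)
    if covariance:
        omega, se = fst_covariance(af, _components=res)
        res.omega, res.se = omega, se
    return res


def fst_covariance(af: Optional[AlleleFreqTable] = None,
                   _components: Optional[PopSpecificFstResult] = None):
    """Jackknife covariance of the population-specific F_ST vector.

    Leave-one-locus-out over the L usable loci:
    Ω̂ = ((L-1)/L) Σ_l (F̂^(-l) - F̄)(F̂^(-l) - F̄)ᵀ, projected onto the
    positive semi-definite cone if numerically indefinite.  Returns
    ``(omega, se)`` with ``se = sqrt(diag(omega))``.
    """
    if _components is None:
        if af is None:
            raise ValueError("provide an AlleleFreqTable")
        _components = popspecific_fst_wg(af, covariance=False)
    m_w, m_b, valid = _components.m_w, _components.m_b, _components.valid
    usable = valid.any(axis=1)
    L = int(usable.sum())
    if L < 2:
        raise ValueError("jackknife needs at least two usable loci")

    num_l = np.where(valid, m_w - m_b[:, None], 0.0)
    den_l = np.where(valid, 1.0 - m_b[:, None], 0.0)
    num = num_l.sum(axis=0)
    den = den_l.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_loo = (num[None, :] - num_l[usable]) / (den[None, :] - den_l[usable])
    fbar = f_loo.mean(axis=0)
    dev = f_loo - fbar
    omega = (L - 1.0) / L * dev.T @ dev
    omega = nearest_psd(omega)
    se = np.sqrt(np.diag(omega))
    return omega, se


def nearest_psd(a: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    if w.min(initial=0.0) >= -tol:
        return a
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def global_fst_nc83(af: AlleleFreqTable,
                    use_het: Optional[bool] = None) -> float:
    """Single overall NC83 F_ST across all populations (convenience).

    Ratio of locus sums of (Ĥ_T - Ĥ_S) to Ĥ_T with s = number of typed
    populations per locus and ñ their harmonic-mean sample size.
    """
    if use_het is None:
        use_het = af.het is not None
    p = af.frequencies()
    p = np.where(np.isnan(p), 0.0, p)
    typed = af.n > 0
    s = typed.sum(axis=1).astype(float)
    ok = s >= 2
    nf = af.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ntilde = s / np.where(typed, 1.0 / np.where(typed, nf, 1.0), 0.0).sum(axis=1)
        hbar = 1.0 - np.einsum("lku,lku->lk", p, p)
        hbar = np.where(typed, hbar, 0.0).sum(axis=1) / s
        pbar = p.sum(axis=1) / s[:, None]
        ht_raw = 1.0 - np.einsum("lu,lu->l", pbar, pbar)
        if use_het:
            h0 = np.where(typed, af.het / np.where(typed, nf, 1.0), 0.0).sum(axis=1) / s
            hs = (ntilde / (ntilde - 1.0)) * (hbar - h0 / (2.0 * ntilde))
            ht = ht_raw + hs / (ntilde * s) - h0 / (2.0 * ntilde * s)
            ok &= ntilde > 1.0
        else:
            hs = (2.0 * ntilde / (2.0 * ntilde - 1.0)) * hbar
            ht = ht_raw + hs / (2.0 * ntilde * s)
    s_num = np.where(ok, ht - hs, 0.0).sum()
    s_den = np.where(ok, ht, 0.0).sum()
    if s_den <= 0:
        raise ValueError("no usable polymorphic locus")
    return float(s_num / s_den)
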