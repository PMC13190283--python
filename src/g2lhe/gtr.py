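"""Reversible substitution-model machinery shared by the sequence simulator
and the likelihood engine.

A model is ``(exchangeabilities, equilibrium frequencies)`` plus a
rate-heterogeneity mixture: a point mass of invariant sites and K
equal-weight discrete-gamma categories (category means, Yang's method).
Rates are normalized jointly so the expected substitution rate over the
whole mixture is 1, i.e. branch lengths are expected substitutions per
site. Works for any alphabet size (4 for nucleotides, 20 for proteins).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

NT_ORDER = "ACGT"
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def rate_matrix(exchangeabilities: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Build the normalized instantaneous rate matrix Q.

    *exchangeabilities* is the strict upper triangle, row-major
    (6 values for 4 states: AC, AG, AT, CG, CT, GT), or a full symmetric
    matrix. Q is scaled so the mean rate at equilibrium is 1.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = len(freqs)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("equilibrium frequencies must sum to 1")
    ex = np.asarray(exchangeabilities, dtype=float)
    if ex.ndim == 1:
        S = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        if len(ex) != len(iu[0]):
            raise ValueError(f"expected {len(iu[0])} exchangeabilities, got {len(ex)}")
        S[iu] = ex
        S = S + S.T
    else:
        S = ex.copy()
    Q = S * freqs[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def spectral(Q: np.ndarray, freqs: np.ndarray):
    """Symmetrizing eigendecomposition of a reversible Q.

    Returns ``(eigvals, U, Uinv)`` with ``expm(Q t) = U diag(e^{w t}) Uinv``.
    """
    d = np.sqrt(freqs)
    # B = D^{1/2} Q D^{-1/2} is exactly symmetric for a reversible Q
    # (B_ij = s_ij sqrt(pi_i pi_j)); averaging only damps roundoff
    A = (Q * d[:, np.newaxis]) / d[np.newaxis, :]
    A = (A + A.T) / 2.0
    w, V = np.linalg.eigh(A)
    U = V / d[:, np.newaxis]
    Uinv = V.T * d[np.newaxis, :]
    return w, U, Uinv


def transition_matrix(w, U, Uinv, t: float) -> np.ndarray:
    P = (U * np.exp(w * t)[np.newaxis, :]) @ Uinv
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def gamma_category_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of *n_categories* equal-probability discrete-gamma bins
    (mean-1 gamma), computed from the incomplete-gamma identity."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    # mean within each bin: shape*scale * (F_{a+1}(hi) - F_{a+1}(lo)) * k
    cdf1 = _gamma_dist.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = (cdf1[1:] - cdf1[:-1]) * k
    return rates / rates.mean()


def mixture_rates(shape: float, p_invariant: float, n_categories: int):
    """Rates and weights of the +I+G mixture, jointly normalized to mean 1.

    Category 0 is the invariant class (rate 0, weight p_invariant); the
    remaining classes are equal-weight gamma categories scaled by
    ``1/(1 - p_invariant)`` so the mixture mean is exactly 1.
    """
    if not 0 <= p_invariant < 1:
        raise ValueError("p_invariant must be in [0, 1)")
    g = gamma_category_rates(shape, n_categories) / (1.0 - p_invariant)
    rates = np.concatenate([[0.0], g])
    weights = np.concatenate(
        [[p_invariant], np.full(n_categories, (1.0 - p_invariant) / n_categories)]
    )
    return rates, weights
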