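"""Amino-acid substitution model: reversible rate matrix + discrete gamma.

The rate matrix is built from symmetric exchangeabilities s_ij and
stationary frequencies pi as Q_ij = s_ij * pi_j, normalized so the expected
number of substitutions per unit branch length is one
(-sum_i pi_i Q_ii = 1).  The LG model (Le & Gascuel 2008) ships as a
PAML-dialect text file; model frequencies are used as-is.

Rate heterogeneity across sites uses the discrete-gamma approximation with
equal-probability bins and the mean-of-bin convention (each category rate is
the conditional mean of the mean-1 gamma within its bin, rescaled so the
category mean is exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .io_formats import AMINO_ACIDS


@dataclass(frozen=True)
class RateModel:
    """Reversible amino-acid (or generic S-state) substitution model."""

    alphabet: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    Q: np.ndarray
    name: str = "custom"
    # cached symmetric eigendecomposition for fast matrix exponentials
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{ -1/2} V
    _right: np.ndarray = field(repr=False, default=None)  # V^T D^{1/2}

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def state_index(self, residue: str) -> int:
        i = self.alphabet.find(residue.upper())
        if i < 0:
            raise KeyError(f"residue {residue!r} not in alphabet")
        return i


def build_rate_matrix(exchangeabilities, frequencies,
                      alphabet: str = AMINO_ACIDS,
                      name: str = "custom") -> RateModel:
    """Assemble a normalized reversible rate matrix from exchangeabilities
    and stationary frequencies."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    S = len(alphabet)
    if s.shape != (S, S):
        raise ValueError(f"exchangeability matrix must be {S}x{S}, got {s.shape}")
    if not np.allclose(s, s.T, rtol=0, atol=1e-12):
        raise ValueError("exchangeability matrix is not symmetric")
    if np.any(s < 0) or np.any(np.diag(s) != 0):
        raise ValueError("exchangeabilities must be nonnegative with zero diagonal")
    if pi.shape != (S,) or np.any(pi <= 0):
        raise ValueError("frequencies must be a positive length-S vector")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"frequencies sum to {pi.sum():.10f}, not 1")
    pi = pi / pi.sum()

    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    Q = Q / mu

    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = 0.5 * (B + B.T)  # exactly symmetric
    w, V = np.linalg.eigh(B)
    left = V / sq[:, None]
    right = V.T * sq[None, :]
    return RateModel(alphabet, s, pi, Q, name=name,
                     _eigvals=w, _left=left, _right=right)


def _parse_paml_matrix(text: str, n_states: int = 20):
    values = [float(tok) for tok in text.split()]
    n_tri = n_states * (n_states - 1) // 2
    if len(values) < n_tri + n_states:
        raise ValueError("truncated PAML model file")
    tri, freqs = values[:n_tri], values[n_tri:n_tri + n_states]
    s = np.zeros((n_states, n_states))
    k = 0
    for i in range(1, n_states):
        for j in range(i):
            s[i, j] = s[j, i] = tri[k]
            k += 1
    return s, np.array(freqs)


def load_model(name: str = "LG") -> RateModel:
    """Load a bundled empirical model (currently: LG)."""
    fname = {"LG": "lg.dat"}.get(name.upper())
    if fname is None:
        raise ValueError(f"unknown bundled model {name!r}")
    text = resources.files("ohnoscope.data").joinpath(fname).read_text()
    s, pi = _parse_paml_matrix(text)
    pi = pi / pi.sum()
    return build_rate_matrix(s, pi, AMINO_ACIDS, name=name.upper())


@dataclass(frozen=True)
class GammaRates:
    """Discrete-gamma rate categories (uniform weights, mean rate 1)."""

    alpha: float
    k: int
    rates: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)


def discrete_gamma(alpha: float, k: int) -> GammaRates:
    """Equal-probability discrete-gamma categories, mean-of-bin convention."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if k < 1:
        raise ValueError("category count k must be >= 1")
    if k == 1:
        return GammaRates(alpha, 1, np.array([1.0]))
    # mean-1 gamma: shape alpha, rate alpha. Bin boundaries at quantiles.
    bounds = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # conditional mean of bin [l, u]: k * (P(alpha+1, alpha*u) - P(alpha+1, alpha*l))
    upper = gammainc(alpha + 1, alpha * edges[1:-1])
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    rates = rates / (rates.mean())  # exact mean 1
    return GammaRates(alpha, k, rates)


def transition_matrix(model: RateModel, t: float, r: float = 1.0) -> np.ndarray:
    """P(t*r) = exp(Q t r) via the cached symmetric eigendecomposition."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    if not np.isfinite(r) or r < 0:
        raise ValueError(f"rate multiplier must be finite and >= 0, got {r}")
    tau = t * r
    if tau == 0.0:
        return np.eye(model.n_states)
    P = (model._left * np.exp(model._eigvals * tau)) @ model._right
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_matrices(model: RateModel, t: float,
                        rates: np.ndarray) -> np.ndarray:
    """Stack of P(t*r_k) for each rate category, shape (k, S, S)."""
    tau = np.asarray(rates, dtype=float) * t
    if t == 0.0:
        return np.broadcast_to(np.eye(model.n_states),
                               (len(tau), model.n_states, model.n_states)).copy()
    expw = np.exp(model._eigvals[None, :] * tau[:, None])  # (k, S)
    P = (model._left[None, :, :] * expw[:, None, :]) @ model._right
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P
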