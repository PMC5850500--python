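"""Goldman–Yang-style (GY94) codon substitution model.

One module owns the rate-matrix algebra used everywhere else: sequence
simulation, pairwise maximum-likelihood dN/dS, and the multi-branch pruning
likelihood.  The model is the classic codon continuous-time Markov chain:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

for sense codons i != j differing at exactly one nucleotide position, zero
otherwise, with kappa the transition/transversion rate ratio and omega the
nonsynonymous/synonymous rate ratio.  The generator is normalised so that one
unit of branch length t equals one expected nucleotide substitution per codon
(the codeml convention), and it satisfies detailed balance with respect to the
codon frequencies pi, so likelihoods are root-placement invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import (
    N_CODONS,
    NEIGHBOUR_I,
    NEIGHBOUR_J,
    NEIGHBOUR_SYN,
    NEIGHBOUR_TS,
)


def rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                normalise: bool = True) -> np.ndarray:
    """Build the 61x61 GY94 generator Q.

    With ``normalise`` the expected substitution flux -sum_i pi_i Q_ii is
    scaled to 1, so branch lengths are in expected substitutions per codon.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-9:
        raise ValueError("pi must be a 61-vector of frequencies summing to 1")
    rates = pi[NEIGHBOUR_J] * np.where(NEIGHBOUR_TS, kappa, 1.0)
    rates = rates * np.where(NEIGHBOUR_SYN, 1.0, omega)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[NEIGHBOUR_I, NEIGHBOUR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalise:
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero flux)")
        Q /= mu
    return Q


@dataclass(frozen=True)
class SpectralQ:
    """Eigendecomposition of a reversible generator, for fast P(t).

    Reversibility (pi_i q_ij = pi_j q_ji) lets us symmetrise
    B = D^{1/2} Q D^{-1/2} with D = diag(pi) and use a real symmetric
    eigendecomposition; P(t) = D^{-1/2} V exp(L t) V' D^{1/2}.
    """

    eigvals: np.ndarray
    left: np.ndarray    # D^{-1/2} V   (61 x 61)
    right: np.ndarray   # V' D^{1/2}   (61 x 61)
    pi: np.ndarray

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        # eigensolver round-off can leave tiny negatives
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def spectral(Q: np.ndarray, pi: np.ndarray) -> SpectralQ:
    """Eigendecompose a reversible generator via its symmetrised form."""
    sqrt_pi = np.sqrt(pi)
    B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    B = 0.5 * (B + B.T)  # enforce exact symmetry before eigh
    eigvals, V = np.linalg.eigh(B)
    left = V / sqrt_pi[:, None]
    right = V.T * sqrt_pi[None, :]
    return SpectralQ(eigvals=eigvals, left=left, right=right, pi=pi)


def substitution_proportions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(rho_S, rho_N): proportions of the substitution flux that are
    synonymous / nonsynonymous at stationarity under (kappa, omega)."""
    Q = rate_matrix(kappa, omega, pi, normalise=False)
    flux = pi[NEIGHBOUR_I] * Q[NEIGHBOUR_I, NEIGHBOUR_J]
    syn = float(flux[NEIGHBOUR_SYN].sum())
    non = float(flux[~NEIGHBOUR_SYN].sum())
    tot = syn + non
    return syn / tot, non / tot


def dn_ds_from_params(t: float, kappa: float, omega: float,
                      pi: np.ndarray) -> tuple[float, float]:
    """Decompose a divergence t (substitutions/codon) into (dN, dS).

    Sites follow the mutational-opportunity definition used by codeml: the
    synonymous site fraction is the synonymous flux proportion of the same
    model at omega = 1 (kappa and pi retained), so that 3 * rho_S(omega=1)
    synonymous sites exist per codon.  The resulting dN/dS equals omega.
    """
    rho_s, rho_n = substitution_proportions(kappa, omega, pi)
    rho_s1, rho_n1 = substitution_proportions(kappa, 1.0, pi)
    dS = t * rho_s / (3.0 * rho_s1)
    dN = t * rho_n / (3.0 * rho_n1)
    return dN, dS
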