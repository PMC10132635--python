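"""Robust Design likelihood with temporary emigration.

Each individual moves through three latent states between primary periods:
*available* (alive, on the surveyed reef), *unavailable* (alive, temporarily
emigrated) and *dead/permanently gone*.  Within a primary period the
population is closed, and an available individual is detected independently
each month with its occasion- and class-specific probability; unavailable
or dead individuals cannot be detected.

Between consecutive primaries an individual first survives with probability
S (apparent survival: death and permanent emigration are confounded), then
moves: an available animal becomes unavailable with probability gamma''
(gamma_dprime), an unavailable animal stays unavailable with probability
gamma' (gamma_prime).

The fitting likelihood is conditional on first capture (Huggins-style):
the recursion starts at the individual's first-capture primary in the
available state, and the mixture-weighted history probability is divided by
the mixture-weighted probability of at least one detection in that primary:

    L_i = sum_c pi_c P_c(history) / sum_c pi_c p*_{f(i),c}

Abundance is not a likelihood parameter; it is derived as N_t = n_t / p*_t.
"""

from __future__ import annotations

import numpy as np

from .design import StudyDesign
from .matrix import CaptureMatrix
from .specs import RDParameters


def _primary_slices(design: StudyDesign) -> list[np.ndarray]:
    """Occasion column indices of each primary period."""
    prim = np.array([o.primary for o in design.occasions])
    return [np.nonzero(prim == t + 1)[0] for t in range(design.n_primary)]


def _emissions(histories: np.ndarray, p_class: np.ndarray,
               slices: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-primary emission terms for one detection class.

    Returns
    -------
    em_avail : (n, T) probability of the primary's detection pattern given
        the individual is available throughout the primary.
    em_zero : (n, T) 1.0 where the pattern is all-zero (the only pattern an
        unavailable or dead individual can emit), else 0.0.
    """
    h = histories
    n, T = h.shape[0], len(slices)
    em_avail = np.empty((n, T))
    em_zero = np.empty((n, T))
    for t, cols in enumerate(slices):
        y = h[:, cols]
        pc = p_class[cols]
        em_avail[:, t] = np.prod(np.where(y == 1, pc, 1.0 - pc), axis=1)
        em_zero[:, t] = (y.sum(axis=1) == 0).astype(float)
    return em_avail, em_zero


def _pstar_per_primary(p_class: np.ndarray, slices: list[np.ndarray]) -> np.ndarray:
    """P(detected at least once in primary t | available), per class."""
    return np.array([1.0 - np.prod(1.0 - p_class[cols]) for cols in slices])


def _forward(em_avail: np.ndarray, em_zero: np.ndarray, first: np.ndarray,
             S: np.ndarray, gp: np.ndarray, gdp: np.ndarray) -> np.ndarray:
    """Forward recursion over latent states from each history's first capture.

    ``first`` gives the 0-based first-capture primary of each history; the
    recursion starts there in the available state and marginalizes the
    latent state forward to the last primary.
    """
    n, T = em_avail.shape
    out = np.empty(n)
    for f in np.unique(first):
        idx = np.nonzero(first == f)[0]
        aA = em_avail[idx, f].copy()
        aU = np.zeros(len(idx))
        aD = np.zeros(len(idx))
        for t in range(f + 1, T):
            s, g1, g2 = S[t - 1], gp[t - 1], gdp[t - 1]
            alive_A = aA * s * (1.0 - g2) + aU * s * (1.0 - g1)
            alive_U = aA * s * g2 + aU * s * g1
            dead = aD + (aA + aU) * (1.0 - s)
            aA = alive_A * em_avail[idx, t]
            aU = alive_U * em_zero[idx, t]
            aD = dead * em_zero[idx, t]
        out[idx] = aA + aU + aD
    return out


def conditional_history_probabilities(
    histories: np.ndarray, params: RDParameters, design: StudyDesign,
) -> np.ndarray:
    """P(history | first captured when it was), one value per row.

    Mixture classes are marginalized before conditioning:
    ``sum_c pi_c P_c(history) / sum_c pi_c p*_{f,c}``.
    """
    h = np.asarray(histories, dtype=np.int8)
    if h.ndim == 1:
        h = h[None, :]
    if np.any(h.sum(axis=1) == 0):
        raise ValueError("histories must contain at least one detection")
    slices = _primary_slices(design)
    prim_of_occ = np.array([o.primary - 1 for o in design.occasions])
    first = np.array([prim_of_occ[np.nonzero(row)[0][0]] for row in h])

    num = np.zeros(h.shape[0])
    den = np.zeros(h.shape[0])
    for c, w in enumerate(params.pi):
        em_avail, em_zero = _emissions(h, params.p[:, c], slices)
        pstar = _pstar_per_primary(params.p[:, c], slices)
        num += w * _forward(em_avail, em_zero, first,
                            params.S, params.gamma_prime, params.gamma_dprime)
        den += w * pstar[first]
    return num / den


def history_probability(history, params: RDParameters,
                        design: StudyDesign) -> float:
    """Conditional probability of a single capture history."""
    return float(conditional_history_probabilities(history, params, design)[0])


def unconditional_history_probability(history, params: RDParameters,
                                      design: StudyDesign) -> float:
    """P(history) for an individual available at the first primary period.

    Unlike the fitting likelihood this does not condition on first capture;
    all-zero histories are allowed (the probability of never being
    detected).  Used for normalization checks: over all observable
    histories, P(history)/P(ever detected) sums to one.
    """
    h = np.asarray(history, dtype=np.int8)[None, :]
    slices = _primary_slices(design)
    total = 0.0
    for c, w in enumerate(params.pi):
        em_avail, em_zero = _emissions(h, params.p[:, c], slices)
        total += w * _forward(em_avail, em_zero, np.array([0]),
                              params.S, params.gamma_prime,
                              params.gamma_dprime)[0]
    return float(total)


def ever_detected_probability(params: RDParameters, design: StudyDesign) -> float:
    """P(detected at least once) for an individual available at primary 1."""
    zero = np.zeros(design.n_occasions, dtype=np.int8)
    return 1.0 - unconditional_history_probability(zero, params, design)


def rd_log_likelihood(matrix: CaptureMatrix | np.ndarray,
                      params: RDParameters,
                      design: StudyDesign | None = None) -> float:
    """Conditional log-likelihood of a capture matrix.

    Identical rows are collapsed to unique histories with multiplicities
    before evaluation.  Parameters outside [0, 1] raise ``ValueError``.
    """
    if isinstance(matrix, CaptureMatrix):
        design = matrix.design
        data = matrix.data
    else:
        if design is None:
            raise ValueError("design required when passing a bare array")
        data = np.asarray(matrix, dtype=np.int8)
    params.validate()
    uniq, counts = np.unique(data, axis=0, return_counts=True)
    probs = conditional_history_probabilities(uniq, params, design)
    if np.any(probs <= 0):
        return -np.inf
    return float(np.dot(counts, np.log(probs)))
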