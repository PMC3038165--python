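"""Pairwise evolutionary distances: Kimura two-parameter (DNA) and JTT ML (protein).

K2P corrects separately for transitions and transversions,
``d = -1/2 ln((1-2P-Q) sqrt(1-2Q))``, with P and Q the transition and
transversion proportions over shared (pairwise-deleted) columns.

The protein distance is the maximum-likelihood pairwise distance under the
reversible JTT replacement process: the rate matrix is assembled from the
published exchangeabilities and equilibrium frequencies (model frequencies,
not alignment-empirical ones), normalised to one expected replacement per
site per unit distance, and the per-pair likelihood is maximised with a
bounded scalar optimiser. Distances past a configurable ceiling ``d_max``
are treated as saturated: NJ needs complete matrices, so matrix builders
clamp to the ceiling while the scalar functions raise by default.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .jtt_data import JTT_FREQS, JTT_LOWER, JTT_ORDER
from .seq import normalize_nuc, normalize_prot

__all__ = [
    "SaturationError",
    "k2p_from_counts",
    "k2p_distance",
    "k2p_matrix",
    "JTTModel",
    "JTT",
    "jtt_ml_distance",
    "jtt_matrix",
    "simulate_jtt_pair",
    "encode_nuc",
    "encode_prot",
]

DEFAULT_D_MAX = 5.0


class SaturationError(ValueError):
    """Observed divergence is beyond the reach of the distance correction."""


# --------------------------------------------------------------------------
# Kimura two-parameter
# --------------------------------------------------------------------------

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_nuc(seq: str) -> np.ndarray:
    """Encode DNA as int8 (A,C,G,T -> 0..3; ambiguity codes -> -1)."""
    s = normalize_nuc(seq)
    return np.fromiter((_NT_INDEX.get(c, -1) for c in s), dtype=np.int8, count=len(s))


def k2p_from_counts(p: float, q: float, d_max: float | None = None) -> float:
    """K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        if d_max is not None:
            return float(d_max)
        raise SaturationError(f"K2P undefined for P={p}, Q={q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no shared unambiguous columns")
    diff = valid & (a != b)
    transitions = int((diff & (np.abs(a - b) == 2)).sum())
    transversions = int(diff.sum()) - transitions
    return transitions / n, transversions / n, n


def k2p_distance(a, b, d_max: float | None = None) -> float:
    """K2P distance between two equal-length sequences (strings or encodings).

    Columns where either sequence carries an ambiguity code are excluded
    (pairwise deletion). Saturated pairs raise SaturationError unless a
    ``d_max`` ceiling is supplied.
    """
    av = a if isinstance(a, np.ndarray) else encode_nuc(a)
    bv = b if isinstance(b, np.ndarray) else encode_nuc(b)
    if len(av) != len(bv):
        raise ValueError("sequences must be aligned to equal length")
    p, q, _ = _pair_counts(av, bv)
    return k2p_from_counts(p, q, d_max=d_max)


def k2p_matrix(x: np.ndarray, d_max: float = DEFAULT_D_MAX) -> np.ndarray:
    """All-pairs K2P distances for an encoded alignment ``x`` of shape (n, L)."""
    xi = x[:, None, :]
    xj = x[None, :, :]
    valid = (xi >= 0) & (xj >= 0)
    nvalid = valid.sum(-1)
    diff = valid & (xi != xj)
    ts = (diff & (np.abs(xi.astype(np.int16) - xj) == 2)).sum(-1)
    tv = diff.sum(-1) - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ts / nvalid
        q = tv / nvalid
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        d = -0.5 * np.log(w1 * np.sqrt(w2))
    d = np.where((w1 <= 0) | (w2 <= 0) | ~np.isfinite(d), d_max, d)
    d = np.minimum(d, d_max)
    np.fill_diagonal(d, 0.0)
    return d


# --------------------------------------------------------------------------
# JTT maximum-likelihood protein distance
# --------------------------------------------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(JTT_ORDER)}


def encode_prot(seq: str) -> np.ndarray:
    """Encode protein as int8 in JTT residue order ('X'/'*' -> -1)."""
    s = normalize_prot(seq)
    return np.fromiter((_AA_INDEX.get(c, -1) for c in s), dtype=np.int8, count=len(s))


class JTTModel:
    """Eigendecomposed JTT rate matrix with cached transition-probability grids."""

    def __init__(self) -> None:
        n = 20
        s = np.zeros((n, n))
        k = 0
        for i in range(1, n):
            for j in range(i):
                s[i, j] = s[j, i] = JTT_LOWER[k]
                k += 1
        pi = np.asarray(JTT_FREQS, dtype=float)
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to 1 expected replacement per site per unit distance
        q /= -(pi * np.diag(q)).sum()
        self.freqs = pi
        self.rate_matrix = q
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]      # D^-1/2 U
        self._right = eigvec.T * sq[None, :]   # U^T D^1/2

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) with rows = ancestral residue, columns = descendant residue."""
        p = (self._left * np.exp(self._eigval * d)) @ self._right
        return np.clip(p, 1e-300, None)

    @lru_cache(maxsize=8)
    def log_joint_grid(self, d_max: float = DEFAULT_D_MAX, size: int = 128):
        """(grid, log pi_a P_ab(grid)) cached for grid-based matrix building."""
        grid = np.geomspace(5e-4, d_max, size)
        logp = np.stack(
            [np.log(self.freqs[:, None] * self.transition_matrix(d)) for d in grid]
        )
        return grid, logp


JTT = JTTModel()


def _jtt_loglik(counts: np.ndarray, d: float, model: JTTModel) -> float:
    p = model.transition_matrix(d)
    return float((counts * np.log(model.freqs[:, None] * p)).sum())


def jtt_ml_distance(
    a,
    b,
    d_max: float = DEFAULT_D_MAX,
    model: JTTModel = JTT,
    raise_on_saturation: bool = True,
) -> float:
    """ML distance between two aligned proteins under the JTT process.

    Columns containing 'X' (or '*') in either sequence are excluded
    (pairwise deletion). Symmetric by reversibility of the process. An
    optimum pinned at ``d_max`` is reported as saturation.
    """
    av = a if isinstance(a, np.ndarray) else encode_prot(a)
    bv = b if isinstance(b, np.ndarray) else encode_prot(b)
    if len(av) != len(bv):
        raise ValueError("sequences must be aligned to equal length")
    valid = (av >= 0) & (bv >= 0)
    if not valid.any():
        raise ValueError("no shared unambiguous columns")
    ai, bi = av[valid].astype(int), bv[valid].astype(int)
    if np.array_equal(ai, bi):
        return 0.0
    counts = np.zeros((20, 20))
    np.add.at(counts, (ai, bi), 1.0)
    res = minimize_scalar(
        lambda d: -_jtt_loglik(counts, d, model),
        bounds=(1e-9, d_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    d = float(res.x)
    if d > d_max * 0.999:
        if raise_on_saturation:
            raise SaturationError("JTT ML distance pinned at d_max (saturation)")
        return d_max
    return d


def _one_hot(x: np.ndarray) -> np.ndarray:
    """(n, L) encoded proteins -> (n, L, 20) one-hot; invalid residues all-zero."""
    n, length = x.shape
    out = np.zeros((n, length, 20))
    idx = np.nonzero(x >= 0)
    out[idx[0], idx[1], x[idx]] = 1.0
    return out


def jtt_matrix(
    x: np.ndarray,
    d_max: float = DEFAULT_D_MAX,
    model: JTTModel = JTT,
    grid_size: int = 64,
) -> np.ndarray:
    """All-pairs JTT ML distances (grid-resolved) for encoded proteins (n, L).

    A fixed log-spaced grid of candidate distances keeps the cost of the many
    matrices needed for bootstrapping manageable; the grid resolution is far
    below the sampling noise of the short homeobox alignments this serves.
    Use :func:`jtt_ml_distance` where exact optima matter. The per-distance
    objective is evaluated as a pair of matrix products over one-hot encoded
    sequences (columns with 'X' drop out as all-zero rows).
    """
    n, length = x.shape
    grid, logp = model.log_joint_grid(d_max, grid_size)
    oh = _one_hot(x)
    flat = oh.reshape(n, length * 20)
    obj = np.empty((len(grid), n, n))
    for g in range(len(grid)):
        w = oh @ logp[g]                      # (n, L, 20)
        obj[g] = w.reshape(n, length * 20) @ flat.T
    d = grid[obj.argmax(axis=0)]
    valid = (x[:, None, :] >= 0) & (x[None, :, :] >= 0)
    identical = valid.sum(-1) == (valid & (x[:, None, :] == x[None, :, :])).sum(-1)
    d = np.where(identical, 0.0, d)
    np.fill_diagonal(d, 0.0)
    return np.minimum((d + d.T) / 2.0, d_max)


def jtt_row(
    block: np.ndarray,
    frag: np.ndarray,
    d_max: float = DEFAULT_D_MAX,
    model: JTTModel = JTT,
    grid_size: int = 64,
) -> np.ndarray:
    """Grid-resolved JTT distances from one fragment to each row of ``block``."""
    grid, logp = model.log_joint_grid(d_max, grid_size)
    valid = (block >= 0) & (frag[None, :] >= 0)
    bc = np.clip(block, 0, 19)
    fc = np.clip(frag, 0, 19)
    curves = logp[:, bc, fc[None, :]]          # (G, n, L)
    obj = np.where(valid[None, :, :], curves, 0.0).sum(-1)
    d = grid[obj.argmax(axis=0)]
    identical = (valid & (block == frag[None, :])).sum(-1) == valid.sum(-1)
    return np.where(identical, 0.0, np.minimum(d, d_max))


def k2p_row(block: np.ndarray, frag: np.ndarray, d_max: float = DEFAULT_D_MAX) -> np.ndarray:
    """K2P distances from one encoded fragment to each row of ``block``."""
    valid = (block >= 0) & (frag[None, :] >= 0)
    nvalid = valid.sum(-1)
    diff = valid & (block != frag[None, :])
    ts = (diff & (np.abs(block.astype(np.int16) - frag[None, :]) == 2)).sum(-1)
    tv = diff.sum(-1) - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ts / nvalid
        q = tv / nvalid
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        d = -0.5 * np.log(w1 * np.sqrt(w2))
    d = np.where((w1 <= 0) | (w2 <= 0) | ~np.isfinite(d), d_max, d)
    return np.minimum(d, d_max)


def simulate_jtt_pair(
    d: float, length: int, rng: np.random.Generator, model: JTTModel = JTT
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an aligned sequence pair separated by distance ``d`` under JTT."""
    a = rng.choice(20, size=length, p=model.freqs)
    p = model.transition_matrix(d)
    # normalise rows defensively against clip-induced drift
    p = p / p.sum(axis=1, keepdims=True)
    u = rng.random(length)
    cum = np.cumsum(p, axis=1)
    b = (u[:, None] > cum[a]).sum(axis=1)
    return a.astype(np.int8), b.astype(np.int8)


def aligned_protein(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-length protein strings into an encoded (n, L) array."""
    arrs = [encode_prot(s) for s in seqs]
    if len({len(a) for a in arrs}) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return np.vstack(arrs)


def aligned_nucleotide(seqs: Sequence[str]) -> np.ndarray:
    arrs = [encode_nuc(s) for s in seqs]
    if len({len(a) for a in arrs}) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return np.vstack(arrs)
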