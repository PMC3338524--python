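"""Amino-acid substitution machinery.

Two distinct objects live here and should not be confused:

* :class:`ScoringMatrix` — an integer *similarity* matrix (BLOSUM62 by
  default) used to score observed substitutions between clades and the
  outgroup.  Large positive entries are conservative replacements,
  negative entries radical ones.
* :class:`RateModel` — a continuous-time Markov model of sequence
  evolution (the JTT empirical replacement model with discrete-gamma rate
  heterogeneity) used for distance estimation and for simulating neutral
  alignments along a tree.

The JTT exchangeabilities and equilibrium frequencies are shipped as
package data (the published 20x20 table).  The rate matrix is built as
``Q[i,j] = s[i,j] * pi[j]`` with rows rescaled so that the expected rate at
stationarity is one substitution per site per unit branch length.  Because
the model is time-reversible, ``exp(Q t)`` is computed once per branch via
a symmetric eigendecomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv

from .alignment import AMINO_ACIDS, AA_INDEX

N_AA = 20

DEFAULT_GAMMA_SHAPE = 1.0
DEFAULT_GAMMA_CATEGORIES = 4
#: distances are optimised on [0, D_MAX]; estimates at the cap are flagged
D_MAX = 10.0


class DomainError(ValueError):
    """Raised when a scoring lookup is asked for a gap/ambiguous letter."""


class UndefinedDistanceError(ValueError):
    """Raised when two sequences share no gap-free column."""


# ---------------------------------------------------------------------------
# similarity scoring
# ---------------------------------------------------------------------------
class ScoringMatrix:
    """Symmetric integer amino-acid similarity matrix.

    Wraps a Biopython substitution matrix into a dense 20x20 ``numpy``
    array ordered like :data:`~cladeshift.alignment.AMINO_ACIDS` so that
    integer-coded alignments can be scored by fancy indexing.
    """

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (N_AA, N_AA):
            raise ValueError("scoring matrix must be 20x20")
        if not np.array_equal(scores, scores.T):
            raise ValueError("scoring matrix must be symmetric")
        self.scores = scores
        self.name = name

    @classmethod
    def blosum62(cls) -> "ScoringMatrix":
        return cls.from_biopython("BLOSUM62")

    @classmethod
    def from_biopython(cls, name: str) -> "ScoringMatrix":
        m = substitution_matrices.load(name)
        out = np.empty((N_AA, N_AA))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                out[i, j] = m[a, b]
        return cls(out, name=name)

    @classmethod
    def from_ncbi_file(cls, path: str | Path, name: str | None = None) -> "ScoringMatrix":
        """Load from an NCBI-format matrix file (as used by BLAST)."""
        with open(path) as fh:
            m = substitution_matrices.read(fh)
        out = np.empty((N_AA, N_AA))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                out[i, j] = m[a, b]
        return cls(out, name=name or Path(path).name)

    def score(self, a: str, b: str) -> float:
        if a not in AA_INDEX or b not in AA_INDEX:
            raise DomainError(f"cannot score pair ({a!r}, {b!r})")
        return float(self.scores[AA_INDEX[a], AA_INDEX[b]])


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------
def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean-of-quantile discrete approximation to Gamma(shape, shape).

    The gamma density with mean 1 is cut into ``n`` equal-probability
    slices; each category rate is the conditional mean within its slice,
    so the rates average exactly to 1.
    """
    if shape <= 0 or n_categories < 1:
        raise ValueError("shape and n_categories must be positive")
    n = n_categories
    # slice boundaries on the Gamma(shape, rate=shape) scale
    probs = np.arange(1, n) / n
    cuts = gammaincinv(shape, probs) / shape
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X | a < X < b] for X ~ Gamma(shape, rate=shape):
    #   (shape/shape) * [I(shape+1, b*shape) - I(shape+1, a*shape)] * n
    upper = gammainc(shape + 1, np.where(np.isinf(bounds[1:]), np.inf, bounds[1:] * shape))
    lower = gammainc(shape + 1, bounds[:-1] * shape)
    rates = n * (upper - lower)
    return rates


def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    ref = resources.files("cladeshift.data").joinpath("jtt.json")
    payload = json.loads(ref.read_text())
    order = payload["alphabet"]
    s = np.array(payload["exchangeabilities"], dtype=float)
    pi = np.array(payload["frequencies"], dtype=float)
    # re-order to the package alphabet (they match, but do not rely on it)
    idx = [order.index(a) for a in AMINO_ACIDS]
    s = s[np.ix_(idx, idx)]
    pi = pi[idx]
    pi = pi / pi.sum()
    return s, pi


@dataclass
class RateModel:
    """Reversible amino-acid replacement model with discrete-gamma rates.

    Attributes
    ----------
    exchangeabilities
        Symmetric 20x20 matrix ``s`` with zero diagonal.
    frequencies
        Equilibrium frequencies ``pi`` (sum to 1).
    gamma_shape, n_categories
        Discrete-gamma rate heterogeneity; category rates are
        equiprobable and average to 1.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float = DEFAULT_GAMMA_SHAPE
    n_categories: int = DEFAULT_GAMMA_CATEGORIES
    name: str = "JTT"
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def jtt(
        cls,
        gamma_shape: float = DEFAULT_GAMMA_SHAPE,
        n_categories: int = DEFAULT_GAMMA_CATEGORIES,
    ) -> "RateModel":
        s, pi = _load_jtt()
        return cls(s, pi, gamma_shape=gamma_shape, n_categories=n_categories)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_AA, N_AA) or pi.shape != (N_AA,):
            raise ValueError("bad model dimensions")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise: expected rate at stationarity = 1 subst/site
        mu = -(pi * np.diag(q)).sum()
        q /= mu
        self.Q = q
        self.frequencies = pi
        self.rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def _eigendecomposition(self):
        if self._eig is None:
            pi = self.frequencies
            d = np.sqrt(pi)
            b = self.Q * (d[:, None] / d[None, :])
            b = (b + b.T) / 2.0  # symmetrise away rounding noise
            w, v = np.linalg.eigh(b)
            left = v.T * d[None, :]          # rows: v_k^T D^{1/2}
            right = v / d[:, None]           # D^{-1/2} v
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Q t)``; rows sum to 1."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        w, right, left = self._eigendecomposition()
        p = (right * np.exp(w * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, t: float) -> np.ndarray:
        """One transition matrix per gamma category, shape (n_cat, 20, 20)."""
        return np.stack([self.transition_matrix(t * r) for r in self.rates])


# ---------------------------------------------------------------------------
# pairwise maximum-likelihood distance
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PairwiseDistance:
    distance: float
    saturated: bool
    n_sites: int


def _pair_counts(c1: np.ndarray, c2: np.ndarray) -> tuple[np.ndarray, int]:
    ok = (c1 >= 0) & (c2 >= 0)
    a, b = c1[ok], c2[ok]
    counts = np.zeros((N_AA, N_AA))
    np.add.at(counts, (a, b), 1.0)
    return counts, int(ok.sum())


def pairwise_distance(
    s1: np.ndarray | str,
    s2: np.ndarray | str,
    model: RateModel,
    *,
    d_max: float = D_MAX,
) -> PairwiseDistance:
    """ML evolutionary distance between two aligned sequences.

    Accepts integer-coded rows (gaps as -1) or plain aligned strings.
    Columns where either sequence is gapped are excluded pairwise.  The
    likelihood mixes the gamma categories with equal weight:

        L(d) = prod_sites  pi_a * mean_k P_k(a -> b; d r_k)

    maximised over ``d`` in ``[0, d_max]``; hitting the cap sets the
    ``saturated`` flag rather than raising.
    """
    if isinstance(s1, str):
        s1 = _encode(s1)
    if isinstance(s2, str):
        s2 = _encode(s2)
    counts, n = _pair_counts(np.asarray(s1), np.asarray(s2))
    if n == 0:
        raise UndefinedDistanceError("no gap-free columns shared by the pair")
    if np.array_equal(s1, s2) or counts.sum() == np.trace(counts):
        return PairwiseDistance(0.0, False, n)

    log_pi = np.log(model.frequencies)

    def neg_loglik(d: float) -> float:
        p = np.mean(model.transition_matrices(d), axis=0)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(p))
        return -np.sum(ll[counts > 0])

    res = minimize_scalar(neg_loglik, bounds=(1e-9, d_max), method="bounded",
                          options={"xatol": 1e-8})
    d = float(res.x)
    saturated = d > d_max - 1e-3
    return PairwiseDistance(d, saturated, n)


def _encode(seq: str) -> np.ndarray:
    from .alignment import GAP_CODE

    lut = np.full(128, GAP_CODE, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
    return lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def distance_matrix(
    matrix: np.ndarray, model: RateModel, *, d_max: float = D_MAX
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise ML distances for an integer-coded alignment.

    Returns ``(D, saturated)`` where ``D`` is symmetric with zero diagonal
    and ``saturated`` is a boolean matrix flagging capped estimates.
    """
    n = matrix.shape[0]
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            pd = pairwise_distance(matrix[i], matrix[j], model, d_max=d_max)
            d[i, j] = d[j, i] = pd.distance
            sat[i, j] = sat[j, i] = pd.saturated
    return d, sat


# ---------------------------------------------------------------------------
# neutral sequence evolution along a tree
# ---------------------------------------------------------------------------
@dataclass
class EvolvedAlignment:
    """Simulated gapless alignment: taxa exactly match the tree leaves."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, length) integer codes 0..19
    seed: int | None = None

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    def sequences(self) -> list[tuple[str, str]]:
        return [
            (t, "".join(AMINO_ACIDS[c] for c in row))
            for t, row in zip(self.taxa, self.matrix)
        ]


def _sample_markov(
    parent_states: np.ndarray, cum_p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw child states given parent states and a cumulative P matrix."""
    u = rng.random(parent_states.shape[0])
    rows = cum_p[parent_states]
    return (rows < u[:, None]).sum(axis=1).astype(np.int8)


def evolve_alignment(
    tree,
    length: int,
    model: RateModel,
    seed: int | np.random.Generator | None = None,
    *,
    n_replicates: int = 1,
) -> EvolvedAlignment | list[EvolvedAlignment]:
    """Simulate neutral evolution of ``length`` columns along ``tree``.

    ``tree`` is a :class:`cladeshift.tree.GeneTree` (or any object exposing
    ``iter_edges()`` yielding ``(parent_id, child_id, branch_length,
    leaf_name_or_None)`` in preorder, plus ``leaf_names``).  The root
    sequence is drawn from the model's equilibrium frequencies; every site
    is independently assigned one of the gamma categories; characters then
    evolve along each branch with ``P = exp(Q r t)``.

    Because sites are i.i.d., ``n_replicates`` alignments are simulated in
    one pass by concatenating their columns; this is the fast path used by
    null calibration.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = length * n_replicates
    pi = model.frequencies
    n_cat = model.n_categories

    cats = rng.integers(0, n_cat, size=total)
    root = rng.choice(N_AA, size=total, p=pi).astype(np.int8)

    states: dict[int, np.ndarray] = {tree.root_id: root}
    leaf_rows: dict[str, np.ndarray] = {}
    # per (branch length, category) cumulative transition matrices, cached
    cum_cache: dict[tuple[float, int], np.ndarray] = {}
    for parent_id, child_id, blen, leaf_name in tree.iter_edges():
        if not np.isfinite(blen):
            raise ValueError(f"non-finite branch length on edge to {child_id}")
        parent_states = states[parent_id]
        child = np.empty(total, dtype=np.int8)
        for k in range(n_cat):
            key = (blen, k)
            if key not in cum_cache:
                cum_cache[key] = np.cumsum(
                    model.transition_matrix(blen * model.rates[k]), axis=1
                )
            mask = cats == k
            child[mask] = _sample_markov(parent_states[mask], cum_cache[key], rng)
        states[child_id] = child
        if leaf_name is not None:
            leaf_rows[leaf_name] = child

    taxa = list(tree.leaf_names)
    big = np.vstack([leaf_rows[t] for t in taxa])
    seed_val = seed if isinstance(seed, int) else None
    if n_replicates == 1:
        return EvolvedAlignment(taxa, big, seed_val)
    return [
        EvolvedAlignment(taxa, big[:, i * length : (i + 1) * length], seed_val)
        for i in range(n_replicates)
    ]
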