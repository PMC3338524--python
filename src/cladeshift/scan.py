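"""Per-site functional-divergence scoring and significance calibration.

At a tested internal node the leaves split into clade A, clade B and the
outgroup.  For one alignment column, every non-gap (clade member, outgroup
member) residue pair is scored with the similarity matrix; with

* ``x1``, ``x2``  the mean pair scores for clades A and B,
* ``s1^2``, ``s2^2`` their sample variances (n-1 denominator),
* ``n1``, ``n2``  the pair counts,

the site statistic is the Welch-type contrast

    FD = |x1 - x2| / sqrt(s1^2/n1 + s2^2/n2).

A large FD means one clade's residues have drifted radically away from
the outgroup while the other clade has not — the signature of a
clade-specific functional shift.

Significance is empirical: neutral alignments are simulated on the very
gene tree being tested (same topology and branch lengths, JTT with
discrete-gamma rates), every simulated column is scored at the same
partition, and the pooled scores form the null distribution.  Observed
sites get add-one upper-tail p-values against that pool and are corrected
per node with Benjamini-Hochberg.  A branch is called functionally
divergent when at least one site survives FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .substitution import RateModel, ScoringMatrix, evolve_alignment
from .tree import GeneTree, NodePartition

#: when the two clade means differ but the pooled SE is exactly zero the
#: SE is floored here, making the site a very large but finite score
SE_FLOOR = 1e-6

DEFAULT_ALPHA = 0.05
DEFAULT_NULL_FLOOR = 1000
DEFAULT_NULL_BATCH = 100
DEFAULT_NULL_CAP = 10_000
DEFAULT_NULL_TOL = 1e-6


@dataclass(frozen=True)
class SiteScore:
    column: int
    xbar_a: float
    xbar_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int
    fd_score: float


@dataclass
class NullDistribution:
    """Pooled simulated FD scores for one tested node."""

    node_id: int
    scores: np.ndarray
    n_replicates: int
    converged: bool
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        self.mean = float(self.scores.mean()) if self.scores.size else float("nan")
        self.sd = float(self.scores.std(ddof=1)) if self.scores.size > 1 else float("nan")


@dataclass
class BranchResult:
    group_id: str
    node_id: int
    partition: NodePartition
    site_scores: list[SiteScore]
    p_values: np.ndarray
    q_values: np.ndarray
    significant_sites: list[int]
    null: NullDistribution | None = None

    @property
    def is_fd(self) -> bool:
        return len(self.significant_sites) > 0


class CalibrationError(ValueError):
    """Raised when p-values are requested against an empty null."""


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------
def _clade_stats(
    clade: np.ndarray, outgroup: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair-score mean/variance/count per column for clade-vs-outgroup.

    ``clade``/``outgroup`` are integer-coded sub-alignments (rows x L,
    gaps -1).  Returns arrays of shape (L,): mean, sample variance (n-1,
    zero when n<=1) and pair count over non-gap pairs.
    """
    a = clade[:, None, :]
    o = outgroup[None, :, :]
    if clade.min() >= 0 and outgroup.min() >= 0:
        # gapless fast path (all simulated alignments take it)
        pair = scores[a, o]
        n_pairs = clade.shape[0] * outgroup.shape[0]
        mean = pair.mean(axis=(0, 1))
        if n_pairs > 1:
            var = pair.var(axis=(0, 1), ddof=1)
        else:
            var = np.zeros(clade.shape[1])
        return mean, var, np.full(clade.shape[1], float(n_pairs))
    valid = (a >= 0) & (o >= 0)
    pair = scores[np.clip(a, 0, None), np.clip(o, 0, None)]
    n = valid.sum(axis=(0, 1)).astype(float)
    safe_n = np.maximum(n, 1.0)
    s = np.where(valid, pair, 0.0)
    mean = s.sum(axis=(0, 1)) / safe_n
    dev2 = np.where(valid, (pair - mean[None, None, :]) ** 2, 0.0)
    var = np.where(n > 1, dev2.sum(axis=(0, 1)) / np.maximum(n - 1.0, 1.0), 0.0)
    mean = np.where(n > 0, mean, np.nan)
    return mean, var, n


def _clade_stats_chunked(
    clade: np.ndarray,
    outgroup: np.ndarray,
    scores: np.ndarray,
    max_elems: int = 8_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-blocked :func:`_clade_stats` to bound peak memory."""
    n_pairs = clade.shape[0] * outgroup.shape[0]
    L = clade.shape[1]
    block = max(1, max_elems // max(n_pairs, 1))
    if L <= block:
        return _clade_stats(clade, outgroup, scores)
    outs = [
        _clade_stats(clade[:, i : i + block], outgroup[:, i : i + block], scores)
        for i in range(0, L, block)
    ]
    return tuple(np.concatenate([o[k] for o in outs]) for k in range(3))


def score_columns(
    matrix: np.ndarray,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    rows_out: np.ndarray,
    scoring: ScoringMatrix,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """FD scores for every column of an integer-coded alignment.

    Returns ``(fd, parts)`` where ``fd`` has NaN at not-scorable columns
    (zero non-gap pairs for either clade) and ``parts`` carries the
    per-clade means/variances/counts for reporting.
    """
    s = scoring.scores
    m1, v1, n1 = _clade_stats_chunked(matrix[rows_a], matrix[rows_out], s)
    m2, v2, n2 = _clade_stats_chunked(matrix[rows_b], matrix[rows_out], s)
    diff = np.abs(m1 - m2)
    se = np.sqrt(v1 / np.maximum(n1, 1.0) + v2 / np.maximum(n2, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        fd = np.where(diff == 0.0, 0.0, diff / np.maximum(se, SE_FLOOR))
    fd = np.where((n1 > 0) & (n2 > 0), fd, np.nan)
    parts = {"xbar_a": m1, "xbar_b": m2, "var_a": v1, "var_b": v2, "n_a": n1, "n_b": n2}
    return fd, parts


def score_site(
    column: dict[str, str] | list[tuple[str, str]],
    partition: NodePartition,
    scoring: ScoringMatrix,
) -> SiteScore | None:
    """Score a single column given as seq_id -> residue (or pairs).

    Returns ``None`` when the column is not scorable (a clade or the
    outgroup contributes no non-gap pair).  This is the readable
    one-column counterpart of :func:`score_columns`.
    """
    from .alignment import AA_INDEX, GAP_CODE

    if not isinstance(column, dict):
        column = dict(column)

    def codes(ids: frozenset[str]) -> np.ndarray:
        return np.array(
            [[AA_INDEX.get(column[s], GAP_CODE)] for s in sorted(ids)], dtype=np.int8
        )

    mat = {
        "a": codes(partition.clade_a),
        "b": codes(partition.clade_b),
        "o": codes(partition.outgroup),
    }
    m1, v1, n1 = _clade_stats(mat["a"], mat["o"], scoring.scores)
    m2, v2, n2 = _clade_stats(mat["b"], mat["o"], scoring.scores)
    if n1[0] == 0 or n2[0] == 0:
        return None
    diff = abs(m1[0] - m2[0])
    se = np.sqrt(v1[0] / n1[0] + v2[0] / n2[0])
    fd = 0.0 if diff == 0.0 else diff / max(se, SE_FLOOR)
    return SiteScore(
        column=0,
        xbar_a=float(m1[0]),
        xbar_b=float(m2[0]),
        var_a=float(v1[0]),
        var_b=float(v2[0]),
        n_a=int(n1[0]),
        n_b=int(n2[0]),
        fd_score=float(fd),
    )


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------
def calibrate_nulls(
    tree: GeneTree,
    partitions: list[NodePartition],
    length: int,
    model: RateModel,
    scoring: ScoringMatrix,
    seed: int | np.random.Generator | None = None,
    *,
    floor: int = DEFAULT_NULL_FLOOR,
    batch: int = DEFAULT_NULL_BATCH,
    cap: int = DEFAULT_NULL_CAP,
    tol: float = DEFAULT_NULL_TOL,
) -> dict[int, NullDistribution]:
    """Simulate neutral alignments on ``tree`` and pool FD scores per node.

    One stream of simulated alignments (shared across the nodes of the
    tree, since they all live on the same gene tree) is scored at every
    partition.  After ``floor`` replicates, simulation continues in
    batches of ``batch`` until the running mean *and* standard deviation
    of every node's pool change by less than ``tol`` between batches, up
    to ``cap`` replicates (a warning is emitted if still unconverged).
    Deterministic given ``seed``.
    """
    if length < 1:
        raise ValueError("simulated length must be >= 1 (degenerate alignment)")
    if not partitions:
        return {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pools: dict[int, list[np.ndarray]] = {p.node_id: [] for p in partitions}
    n_done = 0
    converged = False

    def run_chunk(n_reps: int) -> None:
        nonlocal n_done
        # sites are i.i.d. given the tree, so n_reps replicates of length L
        # are simulated as one alignment of n_reps * L columns
        sim = evolve_alignment(tree, length * n_reps, model, rng)
        pos = {t: i for i, t in enumerate(sim.taxa)}
        for p in partitions:
            ra = np.array(sorted(pos[t] for t in p.clade_a), dtype=np.intp)
            rb = np.array(sorted(pos[t] for t in p.clade_b), dtype=np.intp)
            ro = np.array(sorted(pos[t] for t in p.outgroup), dtype=np.intp)
            fd, _ = score_columns(sim.matrix, ra, rb, ro, scoring)
            pools[p.node_id].append(fd[~np.isnan(fd)])
        n_done += n_reps

    run_chunk(floor)
    while n_done < cap:
        prev = {
            nid: (np.concatenate(v).mean(), np.concatenate(v).std(ddof=1))
            for nid, v in pools.items()
        }
        run_chunk(min(batch, cap - n_done))
        cur = {
            nid: (np.concatenate(v).mean(), np.concatenate(v).std(ddof=1))
            for nid, v in pools.items()
        }
        if all(
            abs(cur[nid][0] - prev[nid][0]) < tol and abs(cur[nid][1] - prev[nid][1]) < tol
            for nid in pools
        ):
            converged = True
            break
    if not converged and n_done >= cap:
        warnings.warn(
            f"null calibration hit the {cap}-replicate cap before the "
            f"{tol:g} mean/sd convergence tolerance",
            stacklevel=2,
        )

    return {
        nid: NullDistribution(
            node_id=nid,
            scores=np.concatenate(v),
            n_replicates=n_done,
            converged=converged,
        )
        for nid, v in pools.items()
    }


def calibrate_null(
    tree: GeneTree,
    partition: NodePartition,
    length: int,
    model: RateModel,
    scoring: ScoringMatrix,
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> NullDistribution:
    """Null distribution for a single node (see :func:`calibrate_nulls`)."""
    return calibrate_nulls(tree, [partition], length, model, scoring, seed, **kwargs)[
        partition.node_id
    ]


# ---------------------------------------------------------------------------
# p-values and FDR
# ---------------------------------------------------------------------------
def site_pvalues(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Add-one empirical upper-tail p-values against the pooled null.

    ``p = (1 + #{null >= obs}) / (1 + n_null)``; NaN observations (not
    scorable) propagate as NaN.
    """
    if null.scores.size == 0:
        raise CalibrationError("empty null distribution")
    obs = np.asarray(observed, dtype=float)
    n = null.scores.size
    ge = n - np.searchsorted(null.scores, obs, side="left")
    p = (1.0 + ge) / (1.0 + n)
    return np.where(np.isnan(obs), np.nan, p)


def fdr_correct(
    pvalues: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q_values, significant_mask).

    NaN p-values are excluded from the correction and stay NaN/False.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
        sig[ok] = q_ok <= alpha
    return q, sig


def call_branch(
    group_id: str,
    partition: NodePartition,
    fd: np.ndarray,
    parts: dict[str, np.ndarray],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    *,
    keep_null: bool = False,
) -> BranchResult:
    """Assemble the per-node result: p, q, significant sites, FD call."""
    p = site_pvalues(fd, null)
    q, sig = fdr_correct(p, alpha)
    site_scores = [
        SiteScore(
            column=i,
            xbar_a=float(parts["xbar_a"][i]),
            xbar_b=float(parts["xbar_b"][i]),
            var_a=float(parts["var_a"][i]),
            var_b=float(parts["var_b"][i]),
            n_a=int(parts["n_a"][i]),
            n_b=int(parts["n_b"][i]),
            fd_score=float(fd[i]),
        )
        for i in range(fd.size)
        if not np.isnan(fd[i])
    ]
    return BranchResult(
        group_id=group_id,
        node_id=partition.node_id,
        partition=partition,
        site_scores=site_scores,
        p_values=p,
        q_values=q,
        significant_sites=[int(i) for i in np.nonzero(sig)[0]],
        null=null if keep_null else None,
    )
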