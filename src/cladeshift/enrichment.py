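"""Enrichment statistics over branch-level divergence calls.

Every tested branch (internal node of a gene tree) either is or is not
called functionally divergent.  Branches are attributed to units —
functional categories (via the group's tag), species (via clade
membership: a branch counts for every species with at least one sequence
in clade A or clade B; outgroup-only species are not attributed), and
category-within-species cells.  For each unit a 2x2 chi-squared test
(Yates-corrected, Fisher's exact when any expected count falls below 5)
compares the unit's proportion of divergence-positive branches with the
background proportion over all *other* branches:

* ``enriched``      p < 0.05 and observed > expected,
* ``impoverished``  p < 0.05 and observed < expected,
* ``neither``       otherwise; units with no tested branch are ``no-data``.

Lifestyle associations compare the 3-way status distribution (enriched /
neither / impoverished) of two groups of species in a 2x3 table.

Branch tables are tidy :class:`pandas.DataFrame` objects with columns
``group_id, node_id, is_fd, category, species`` (species ';'-joined), so
downstream statistics can be re-run from a TSV without redoing the scan.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

ALPHA = 0.05
#: minimum expected cell count for the chi-squared approximation
MIN_EXPECTED = 5.0


class Status(enum.Enum):
    ENRICHED = "enriched"
    IMPOVERISHED = "impoverished"
    NEITHER = "neither"
    NO_DATA = "no-data"

    @property
    def code(self) -> float:
        return {"enriched": 1.0, "impoverished": -1.0, "neither": 0.0}.get(
            self.value, float("nan")
        )


@dataclass(frozen=True)
class EnrichmentCell:
    unit: str
    observed_fd: int
    total_tests: int
    expected_fd: float
    statistic: float | None
    p_value: float
    status: Status
    test_used: str


@dataclass(frozen=True)
class LifestyleTable:
    focal: str
    comparison: str
    counts: np.ndarray  # 2x3: rows (focal, comparison), cols (enr, nei, imp)
    test_used: str
    statistic: float | None
    p_value: float
    direction: str  # '+', '-' or '' when not significant


# ---------------------------------------------------------------------------
# basic tests
# ---------------------------------------------------------------------------
def chi_squared(
    observed: np.ndarray, expected: np.ndarray, df: int | None = None
) -> tuple[float, float]:
    """Goodness-of-fit statistic sum((O-E)^2/E) and its upper-tail p.

    ``df`` defaults to ``len(observed) - 1``.  A zero expected count is a
    degenerate test and raises; callers fall back to an exact test.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed/expected length mismatch")
    if np.any(e <= 0):
        raise ValueError("zero expected count: chi-squared test undefined")
    stat = float(((o - e) ** 2 / e).sum())
    if df is None:
        df = o.size - 1
    return stat, float(stats.chi2.sf(stat, df))


def _log_table_prob(table: np.ndarray) -> float:
    """log P(table | margins) under the multiple hypergeometric."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact_2xc(
    table: np.ndarray,
    *,
    max_tables: int = 200_000,
    n_monte_carlo: int = 20_000,
    seed: int = 0,
) -> float:
    """Exact (or seeded Monte Carlo) Fisher test for a 2-row table.

    Enumerates all tables with the observed margins when their number is
    tractable (the count is driven by the smaller row margin), summing the
    probabilities of tables no more probable than the observed one.  For
    margins too large to enumerate, falls back to Patefield sampling with
    a fixed seed.  Tables with more than two rows are transposed when that
    yields two columns.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if t.shape[0] != 2:
        if t.shape[1] == 2:
            t = t.T
        else:
            raise ValueError("exact test implemented for 2xC tables only")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if rows.min() == 0 or (cols == 0).all():
        return 1.0
    # enumerate over the smaller row margin
    if rows[1] < rows[0]:
        t = t[::-1]
        rows = rows[::-1]
    r1 = int(rows[0])
    c = t.shape[1]
    n_candidates = math.comb(r1 + c - 1, c - 1)
    log_p_obs = _log_table_prob(t)
    eps = 1e-7
    if n_candidates <= max_tables:
        total = 0.0
        for combo in itertools.combinations(range(r1 + c - 1), c - 1):
            # stars-and-bars decomposition of r1 into c cells
            parts = []
            prev = -1
            for pos in combo:
                parts.append(pos - prev - 1)
                prev = pos
            parts.append(r1 + c - 2 - prev)
            top = np.array(parts)
            bottom = cols - top
            if (bottom < 0).any():
                continue
            lp = _log_table_prob(np.vstack([top, bottom]))
            if lp <= log_p_obs + eps:
                total += math.exp(lp)
        return min(1.0, total)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    samples = sampler.rvs(n_monte_carlo, random_state=rng)
    hits = sum(
        1 for s in samples if _log_table_prob(s) <= log_p_obs + eps
    )
    return (1.0 + hits) / (1.0 + n_monte_carlo)


def _two_by_two(
    o_in: int, t_in: int, o_rest: int, t_rest: int, *, yates: bool = True
) -> tuple[float | None, float, str]:
    """Unit-vs-rest x positive-vs-negative test; (stat, p, test name)."""
    table = np.array(
        [[o_in, t_in - o_in], [o_rest, t_rest - o_rest]], dtype=float
    )
    if table.sum() == 0:
        return None, 1.0, "none"
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        return None, 1.0, "none"
    if expected.min() < MIN_EXPECTED:
        _, p = stats.fisher_exact(table.astype(int))
        return None, float(p), "fisher"
    res = stats.chi2_contingency(table, correction=yates)
    name = "chi2-yates" if yates else "chi2"
    return float(res.statistic), float(res.pvalue), name


def _classify(
    unit: str, o_in: int, t_in: int, o_rest: int, t_rest: int, *,
    alpha: float = ALPHA, yates: bool = True,
) -> EnrichmentCell:
    if t_in == 0:
        return EnrichmentCell(unit, 0, 0, float("nan"), None, float("nan"),
                              Status.NO_DATA, "none")
    background = o_rest / t_rest if t_rest > 0 else float("nan")
    expected = t_in * background
    stat, p, test = _two_by_two(o_in, t_in, o_rest, t_rest, yates=yates)
    if np.isnan(expected) or test == "none" or not p < alpha:
        status = Status.NEITHER
    elif o_in - expected > 0:
        status = Status.ENRICHED
    elif o_in - expected < 0:
        status = Status.IMPOVERISHED
    else:
        status = Status.NEITHER
    return EnrichmentCell(unit, o_in, t_in, expected, stat, p, status, test)


# ---------------------------------------------------------------------------
# branch tables and per-unit enrichment
# ---------------------------------------------------------------------------
BRANCH_COLUMNS = ["group_id", "node_id", "is_fd", "category", "species"]


def make_branch_table(records: list[dict]) -> pd.DataFrame:
    """Normalise branch records into the tidy table used downstream."""
    df = pd.DataFrame(records, columns=BRANCH_COLUMNS)
    df["is_fd"] = df["is_fd"].astype(bool)
    df["species"] = df["species"].map(
        lambda s: ";".join(sorted(s)) if not isinstance(s, str) else s
    )
    return df


def _cells_from_counts(
    counts: pd.DataFrame, *, alpha: float = ALPHA, yates: bool = True
) -> dict[str, EnrichmentCell]:
    """counts: index unit, columns ['o', 't'] -> per-unit cells."""
    total_o = int(counts["o"].sum())
    total_t = int(counts["t"].sum())
    out = {}
    for unit, row in counts.iterrows():
        o_in, t_in = int(row["o"]), int(row["t"])
        out[str(unit)] = _classify(
            str(unit), o_in, t_in, total_o - o_in, total_t - t_in,
            alpha=alpha, yates=yates,
        )
    return out


def enrich_by_category(
    branch_table: pd.DataFrame, *, alpha: float = ALPHA, yates: bool = True
) -> dict[str, EnrichmentCell]:
    g = branch_table.groupby("category")["is_fd"]
    counts = pd.DataFrame({"o": g.sum(), "t": g.size()})
    return _cells_from_counts(counts, alpha=alpha, yates=yates)


def _explode_species(branch_table: pd.DataFrame) -> pd.DataFrame:
    df = branch_table.copy()
    df["species"] = df["species"].str.split(";")
    return df.explode("species")


def enrich_by_species(
    branch_table: pd.DataFrame, *, alpha: float = ALPHA, yates: bool = True
) -> dict[str, EnrichmentCell]:
    """Attribute each branch to its clade species and test per species.

    The margins count attributed (branch, species) pairs, so a branch
    spanning several species contributes once per species.
    """
    df = _explode_species(branch_table)
    g = df.groupby("species")["is_fd"]
    counts = pd.DataFrame({"o": g.sum(), "t": g.size()})
    return _cells_from_counts(counts, alpha=alpha, yates=yates)


def enrich_species_by_category(
    branch_table: pd.DataFrame, *, alpha: float = ALPHA, yates: bool = True
) -> tuple[pd.DataFrame, dict[tuple[str, str], EnrichmentCell]]:
    """Per-(species, category) enrichment and the coded status matrix.

    Returns ``(status_matrix, cells)``: the matrix has species rows,
    category columns and values +1 / 0 / -1 / NaN (no-data).
    """
    df = _explode_species(branch_table)
    g = df.groupby(["species", "category"])["is_fd"]
    counts = pd.DataFrame({"o": g.sum(), "t": g.size()})
    total_o = int(counts["o"].sum())
    total_t = int(counts["t"].sum())
    species = sorted(df["species"].unique())
    categories = sorted(df["category"].unique())
    cells: dict[tuple[str, str], EnrichmentCell] = {}
    matrix = pd.DataFrame(np.nan, index=species, columns=categories)
    for sp in species:
        for cat in categories:
            if (sp, cat) in counts.index:
                o_in = int(counts.loc[(sp, cat), "o"])
                t_in = int(counts.loc[(sp, cat), "t"])
            else:
                o_in = t_in = 0
            cell = _classify(
                f"{sp}|{cat}", o_in, t_in, total_o - o_in, total_t - t_in,
                alpha=alpha, yates=yates,
            )
            cells[(sp, cat)] = cell
            matrix.loc[sp, cat] = cell.status.code
    return matrix, cells


# ---------------------------------------------------------------------------
# lifestyle association
# ---------------------------------------------------------------------------
_STATUS_ORDER = [Status.ENRICHED, Status.NEITHER, Status.IMPOVERISHED]


def lifestyle_table_test(
    counts: np.ndarray, *, seed: int = 0
) -> tuple[str, float | None, float]:
    """Test a 2x3 status table; returns (test name, statistic, p).

    Uses the chi-squared test of independence (Yates-corrected when
    df = 1) unless any expected count is below 5, in which case the exact
    Fisher test is used.
    """
    t = np.asarray(counts, dtype=float)
    keep = t.sum(axis=0) > 0
    t = t[:, keep]
    if t.shape[1] < 2 or t.sum(axis=1).min() == 0:
        return "none", None, 1.0
    expected = stats.contingency.expected_freq(t)
    if expected.min() < MIN_EXPECTED:
        return "fisher", None, fisher_exact_2xc(t.astype(int), seed=seed)
    res = stats.chi2_contingency(t, correction=(t.shape == (2, 2)))
    name = "chi2-yates" if t.shape == (2, 2) else "chi2"
    return name, float(res.statistic), float(res.pvalue)


def lifestyle_association(
    species_status: dict[str, Status],
    lifestyle_of: dict[str, str],
    focal: str,
    comparison: str,
    *,
    alpha: float = ALPHA,
    seed: int = 0,
) -> LifestyleTable:
    """Association between a lifestyle and species enrichment status.

    Builds the 2x3 contingency of status counts for species with the
    ``focal`` lifestyle against species with the ``comparison`` lifestyle
    (species lacking either annotation are ignored) and tests it with
    :func:`lifestyle_table_test`.  When significant, the direction is '+'
    if the focal group leans towards enrichment and '-' towards
    impoverishment, judged by the sign of observed-minus-expected in the
    enriched and impoverished columns.
    """
    counts = np.zeros((2, 3), dtype=int)
    for sp, status in species_status.items():
        ls = lifestyle_of.get(sp)
        if ls == focal:
            row = 0
        elif ls == comparison:
            row = 1
        else:
            continue
        if status in _STATUS_ORDER:
            counts[row, _STATUS_ORDER.index(status)] += 1
    test, stat, p = lifestyle_table_test(counts, seed=seed)
    direction = ""
    if p < alpha and counts.sum() > 0:
        expected = stats.contingency.expected_freq(counts.astype(float))
        lean_enr = counts[0, 0] - expected[0, 0]
        lean_imp = counts[0, 2] - expected[0, 2]
        direction = "+" if lean_enr >= lean_imp else "-"
    return LifestyleTable(
        focal=focal,
        comparison=comparison,
        counts=counts,
        test_used=test,
        statistic=stat,
        p_value=p,
        direction=direction,
    )


def cells_to_frame(cells: dict[str, EnrichmentCell]) -> pd.DataFrame:
    rows = [
        {
            "unit": c.unit,
            "observed_fd": c.observed_fd,
            "total_tests": c.total_tests,
            "expected_fd": c.expected_fd,
            "statistic": c.statistic,
            "p_value": c.p_value,
            "status": c.status.value,
            "test": c.test_used,
        }
        for c in cells.values()
    ]
    return pd.DataFrame(rows).sort_values("unit").reset_index(drop=True)
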