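"""Model/Results interface for the divergence scan and enrichment stages.

:class:`DivergenceScan` is built from one aligned homolog group; calling
:meth:`~DivergenceScan.fit` estimates the gene tree, scores every
testable node, calibrates the simulated null and returns a
:class:`ScanResults` carrying per-site scores, p/q-values and the
branch-level divergence calls, with ``summary()`` and tidy DataFrame
accessors.

:class:`EnrichmentAnalysis` is built from a branch table (one fitted scan
per group, or a TSV from a previous run); its results hold the
per-category and per-species cells, the species x category status matrix,
lifestyle tests and the clustered-heatmap plotting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment as enr
from .alignment import AlignmentGroup, read_alignment, simulated_length
from .scan import (
    DEFAULT_ALPHA,
    DEFAULT_NULL_BATCH,
    DEFAULT_NULL_CAP,
    DEFAULT_NULL_FLOOR,
    DEFAULT_NULL_TOL,
    BranchResult,
    calibrate_nulls,
    call_branch,
    score_columns,
)
from .substitution import RateModel, ScoringMatrix, distance_matrix
from .tree import GeneTree


class DivergenceScan:
    """Per-group functional-divergence scan.

    Parameters
    ----------
    group
        The aligned homolog group to analyse.
    scoring
        Similarity matrix for site scoring (default BLOSUM62).
    rate_model
        Evolution model for distances and null simulation (default JTT
        with 4-category gamma, shape 1.0).
    alpha
        FDR level for site significance (default 0.05).
    min_clade_size
        Minimum leaves per descendant clade for a node to be tested.
    null_floor, null_batch, null_cap, null_tol
        Null-calibration schedule: at least ``null_floor`` simulated
        alignments, then batches of ``null_batch`` until the pooled mean
        and sd move less than ``null_tol``, capped at ``null_cap``.
    """

    def __init__(
        self,
        group: AlignmentGroup,
        *,
        scoring: ScoringMatrix | None = None,
        rate_model: RateModel | None = None,
        alpha: float = DEFAULT_ALPHA,
        min_clade_size: int = 4,
        null_floor: int = DEFAULT_NULL_FLOOR,
        null_batch: int = DEFAULT_NULL_BATCH,
        null_cap: int = DEFAULT_NULL_CAP,
        null_tol: float = DEFAULT_NULL_TOL,
        keep_nulls: bool = False,
    ):
        self.group = group
        self.scoring = scoring or ScoringMatrix.blosum62()
        self.rate_model = rate_model or RateModel.jtt()
        self.alpha = alpha
        self.min_clade_size = min_clade_size
        self.null_floor = null_floor
        self.null_batch = null_batch
        self.null_cap = null_cap
        self.null_tol = null_tol
        self.keep_nulls = keep_nulls

    @classmethod
    def from_files(cls, fasta, annotations, **kwargs) -> "DivergenceScan":
        return cls(read_alignment(fasta, annotations), **kwargs)

    def fit(self, seed: int | None = None, tree: GeneTree | None = None) -> "ScanResults":
        """Run the scan; deterministic given ``seed``.

        ``tree`` may be supplied to skip distance estimation and tree
        building (used by simulation studies where the true tree is
        known; the default is to estimate it from the alignment).
        """
        group = self.group
        mat = group.matrix()
        saturated_pairs = 0
        if tree is None:
            d, sat = distance_matrix(mat, self.rate_model)
            saturated_pairs = int(sat.sum() // 2)
            tree = GeneTree.from_distances(d, group.seq_ids)
        partitions = [
            p
            for p in tree.enumerate_partitions()
            if len(p.clade_a) >= self.min_clade_size
            and len(p.clade_b) >= self.min_clade_size
            and len(p.outgroup) >= 1
        ]
        sim_length = simulated_length(group)
        branches: list[BranchResult] = []
        if partitions:
            nulls = calibrate_nulls(
                tree,
                partitions,
                sim_length,
                self.rate_model,
                self.scoring,
                seed=np.random.default_rng(seed),
                floor=self.null_floor,
                batch=self.null_batch,
                cap=self.null_cap,
                tol=self.null_tol,
            )
            for p in partitions:
                fd, parts = score_columns(
                    mat,
                    group.row_index(p.clade_a),
                    group.row_index(p.clade_b),
                    group.row_index(p.outgroup),
                    self.scoring,
                )
                branches.append(
                    call_branch(
                        group.group_id, p, fd, parts, nulls[p.node_id],
                        self.alpha, keep_null=self.keep_nulls,
                    )
                )
        return ScanResults(
            model=self,
            tree=tree,
            branch_results=branches,
            simulated_length=sim_length,
            saturated_pairs=saturated_pairs,
            seed=seed,
        )


@dataclass
class ScanResults:
    """Fitted scan for one group."""

    model: DivergenceScan
    tree: GeneTree
    branch_results: list[BranchResult]
    simulated_length: int
    saturated_pairs: int
    seed: int | None

    @property
    def group(self) -> AlignmentGroup:
        return self.model.group

    @property
    def n_tested_nodes(self) -> int:
        return len(self.branch_results)

    @property
    def is_fd(self) -> bool:
        """Any tested branch with at least one significant site."""
        return any(b.is_fd for b in self.branch_results)

    def significant_sites(self) -> list[int]:
        """Union of significant site indices over all tested nodes."""
        out: set[int] = set()
        for b in self.branch_results:
            out.update(b.significant_sites)
        return sorted(out)

    def sites_frame(self) -> pd.DataFrame:
        """One row per (node, scorable site): scores, p and q values."""
        rows = []
        for b in self.branch_results:
            for s in b.site_scores:
                rows.append(
                    {
                        "group_id": b.group_id,
                        "node_id": b.node_id,
                        "n_clade_a": len(b.partition.clade_a),
                        "n_clade_b": len(b.partition.clade_b),
                        "n_outgroup": len(b.partition.outgroup),
                        "site": s.column,
                        "fd_score": s.fd_score,
                        "p_value": float(b.p_values[s.column]),
                        "q_value": float(b.q_values[s.column]),
                        "significant": s.column in b.significant_sites,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "group_id", "node_id", "n_clade_a", "n_clade_b", "n_outgroup",
                "site", "fd_score", "p_value", "q_value", "significant",
            ],
        )

    def branch_frame(self) -> pd.DataFrame:
        """One row per tested node with the divergence call."""
        rows = []
        for b in self.branch_results:
            rows.append(
                {
                    "group_id": b.group_id,
                    "node_id": b.node_id,
                    "n_clade_a": len(b.partition.clade_a),
                    "n_clade_b": len(b.partition.clade_b),
                    "n_outgroup": len(b.partition.outgroup),
                    "n_scored_sites": len(b.site_scores),
                    "n_significant_sites": len(b.significant_sites),
                    "significant_sites": ";".join(map(str, b.significant_sites)),
                    "is_fd": b.is_fd,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "group_id", "node_id", "n_clade_a", "n_clade_b", "n_outgroup",
                "n_scored_sites", "n_significant_sites", "significant_sites",
                "is_fd",
            ],
        )

    def branch_records(self) -> list[dict]:
        """Records for :func:`cladeshift.enrichment.make_branch_table`."""
        group = self.group
        cat = next(iter(group.category_tags.values()), "")
        out = []
        for b in self.branch_results:
            species = {
                group.species_of[s]
                for s in (b.partition.clade_a | b.partition.clade_b)
            }
            out.append(
                {
                    "group_id": b.group_id,
                    "node_id": b.node_id,
                    "is_fd": b.is_fd,
                    "category": cat,
                    "species": frozenset(species),
                }
            )
        return out

    def summary(self) -> str:
        g = self.group
        buf = io.StringIO()
        buf.write("Functional divergence scan\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"group:            {g.group_id}\n")
        buf.write(f"sequences:        {g.n_sequences}  columns: {g.length}\n")
        buf.write(f"simulated length: {self.simulated_length}\n")
        buf.write(f"tested nodes:     {self.n_tested_nodes}\n")
        buf.write(f"alpha (FDR):      {self.model.alpha}\n")
        if self.saturated_pairs:
            buf.write(f"saturated pairs:  {self.saturated_pairs}\n")
        buf.write("-" * 60 + "\n")
        for b in self.branch_results:
            mark = "FD" if b.is_fd else "--"
            sites = ",".join(map(str, b.significant_sites)) or "-"
            buf.write(
                f"node {b.node_id:3d} [{mark}]  clades "
                f"{len(b.partition.clade_a)}|{len(b.partition.clade_b)} "
                f"out {len(b.partition.outgroup):2d}  "
                f"significant sites: {sites}\n"
            )
        return buf.getvalue()


# ---------------------------------------------------------------------------
# enrichment model
# ---------------------------------------------------------------------------
class EnrichmentAnalysis:
    """Dataset-level enrichment over a branch table.

    Parameters
    ----------
    branch_table
        Tidy table with columns ``group_id, node_id, is_fd, category,
        species`` (build with :func:`cladeshift.enrichment
        .make_branch_table`, from fitted scans or a saved TSV).
    lifestyle_of
        Optional species -> lifestyle labels for association tests.
    """

    def __init__(
        self,
        branch_table: pd.DataFrame,
        lifestyle_of: dict[str, str] | None = None,
        *,
        alpha: float = enr.ALPHA,
        yates: bool = True,
    ):
        missing = set(enr.BRANCH_COLUMNS) - set(branch_table.columns)
        if missing:
            raise ValueError(f"branch table lacks columns {sorted(missing)}")
        if len(branch_table) == 0:
            raise ValueError("branch table is empty")
        self.branch_table = branch_table.reset_index(drop=True)
        self.lifestyle_of = dict(lifestyle_of or {})
        self.alpha = alpha
        self.yates = yates

    @classmethod
    def from_scans(
        cls, results: list[ScanResults], lifestyle_of=None, **kwargs
    ) -> "EnrichmentAnalysis":
        records = [r for res in results for r in res.branch_records()]
        return cls(enr.make_branch_table(records), lifestyle_of, **kwargs)

    def fit(self, seed: int = 0) -> "EnrichmentResults":
        by_category = enr.enrich_by_category(
            self.branch_table, alpha=self.alpha, yates=self.yates
        )
        by_species = enr.enrich_by_species(
            self.branch_table, alpha=self.alpha, yates=self.yates
        )
        status_matrix, cells = enr.enrich_species_by_category(
            self.branch_table, alpha=self.alpha, yates=self.yates
        )
        lifestyle_tests = {}
        labels = sorted(set(self.lifestyle_of.values()))
        species_status = {sp: c.status for sp, c in by_species.items()}
        if len(labels) >= 2:
            for focal in labels:
                for comparison in labels:
                    if focal != comparison:
                        lifestyle_tests[(focal, comparison)] = enr.lifestyle_association(
                            species_status, self.lifestyle_of, focal, comparison,
                            alpha=self.alpha, seed=seed,
                        )
        return EnrichmentResults(
            model=self,
            by_category=by_category,
            by_species=by_species,
            species_by_category=cells,
            status_matrix=status_matrix,
            lifestyle_tests=lifestyle_tests,
        )


@dataclass
class EnrichmentResults:
    model: EnrichmentAnalysis
    by_category: dict[str, enr.EnrichmentCell]
    by_species: dict[str, enr.EnrichmentCell]
    species_by_category: dict[tuple[str, str], enr.EnrichmentCell]
    status_matrix: pd.DataFrame
    lifestyle_tests: dict[tuple[str, str], enr.LifestyleTable]
    _cluster: object = field(default=None, repr=False)

    def category_frame(self) -> pd.DataFrame:
        return enr.cells_to_frame(self.by_category)

    def species_frame(self) -> pd.DataFrame:
        return enr.cells_to_frame(self.by_species)

    def cluster(self, **kwargs):
        from .cluster import cluster_matrix

        if self._cluster is None:
            self._cluster = cluster_matrix(self.status_matrix, **kwargs)
        return self._cluster

    def plot_heatmap(self, path, tsv_path=None, **kwargs) -> None:
        from .cluster import render_heatmap

        render_heatmap(self.cluster(), path, tsv_path=tsv_path, **kwargs)

    def summary(self) -> str:
        buf = io.StringIO()
        bt = self.model.branch_table
        buf.write("Enrichment analysis\n")
        buf.write("=" * 60 + "\n")
        buf.write(
            f"tested branches: {len(bt)}  divergence-positive: "
            f"{int(bt['is_fd'].sum())} "
            f"({bt['is_fd'].mean():.1%} background)\n"
        )
        buf.write("-" * 60 + "\n")
        buf.write("category  O/total  expected  p-value  status\n")
        for cat, c in sorted(self.by_category.items()):
            exp = f"{c.expected_fd:.2f}" if np.isfinite(c.expected_fd) else "-"
            p = f"{c.p_value:.4g}" if np.isfinite(c.p_value) else "-"
            buf.write(
                f"{cat:<9} {c.observed_fd}/{c.total_tests:<7} {exp:<9} "
                f"{p:<8} {c.status.value}\n"
            )
        for (focal, comparison), t in self.lifestyle_tests.items():
            sig = f"p={t.p_value:.4g}" + (f" ({t.direction})" if t.direction else "")
            buf.write(f"lifestyle {focal} vs {comparison}: {t.test_used}, {sig}\n")
        return buf.getvalue()
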