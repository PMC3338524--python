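"""End-to-end scan over a directory of homolog groups.

Input layout: a directory of aligned FASTA files (``*.fasta``/``*.fa``,
one group each), an ``annotations.tsv`` (``seq_id  species  category``)
and optionally ``lifestyle.tsv`` (``species  lifestyle``).  The run
filters groups, fits a :class:`~cladeshift.model.DivergenceScan` per
passing group, aggregates branch calls into the enrichment stage and
writes all tables, the clustered status matrix, the heatmap and a
manifest.

Reproducibility contract: each group's RNG stream is derived by hashing
the master seed with the group id, so results are identical for any
scheduling or worker order; the manifest records everything needed to
re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import (
    DEFAULT_EXCLUDED_TAGS,
    DEFAULT_MIN_SEQUENCES,
    GroupFilterReport,
    filter_group,
    read_alignment,
    read_annotations,
    write_filter_reports,
)
from .enrichment import make_branch_table
from .model import DivergenceScan, EnrichmentAnalysis
from .scan import (
    DEFAULT_ALPHA,
    DEFAULT_NULL_BATCH,
    DEFAULT_NULL_CAP,
    DEFAULT_NULL_FLOOR,
    DEFAULT_NULL_TOL,
)
from .substitution import RateModel, ScoringMatrix

log = logging.getLogger("cladeshift")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str
    output_dir: str
    annotations: str | None = None       # default: <input_dir>/annotations.tsv
    lifestyle: str | None = None         # default: <input_dir>/lifestyle.tsv if present
    alpha: float = DEFAULT_ALPHA
    gamma_shape: float = 1.0
    gamma_categories: int = 4
    min_group_size: int = DEFAULT_MIN_SEQUENCES
    min_clade_size: int = 4
    excluded_categories: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDED_TAGS))
    null_floor: int = DEFAULT_NULL_FLOOR
    null_batch: int = DEFAULT_NULL_BATCH
    null_cap: int = DEFAULT_NULL_CAP
    null_tol: float = DEFAULT_NULL_TOL
    seed: int = 0
    strict_alphabet: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_group_size", "min_clade_size", "null_floor",
                     "null_batch", "null_cap", "gamma_categories"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a flat ``key = value`` (or ``key: value``) config file."""
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":"):
                    if sep in line:
                        key, _, raw = line.partition(sep)
                        break
                else:
                    raise ValueError(f"bad config line: {line!r}")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key: {key}")
                if key == "excluded_categories":
                    values[key] = tuple(sorted(t for t in raw.replace(",", " ").split() if t))
                else:
                    typ = fields[key].type
                    if "int" in typ:
                        values[key] = int(raw)
                    elif "float" in typ:
                        values[key] = float(raw)
                    elif "bool" in typ:
                        values[key] = raw.lower() in {"1", "true", "yes"}
                    else:
                        values[key] = raw
        values.update(overrides)
        return cls(**values)


def derive_seed(master_seed: int, group_id: str) -> int:
    """Order-independent per-group seed: hash of (master seed, group id)."""
    digest = hashlib.sha256(f"{master_seed}:{group_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class EmptyInputError(RuntimeError):
    """No group passed the filters."""


@dataclass
class RunBundle:
    config: RunConfig
    filter_reports: list[GroupFilterReport]
    scans: list
    branch_table: object
    enrichment: object
    quarantined: dict[str, str] = field(default_factory=dict)


def run_scan(config: RunConfig) -> RunBundle:
    """Execute filter -> tree -> scan -> enrichment -> clustering."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)

    ann_path = Path(config.annotations or indir / "annotations.tsv")
    annotations = read_annotations(ann_path)
    lifestyle_path = (
        Path(config.lifestyle) if config.lifestyle else indir / "lifestyle.tsv"
    )
    lifestyle_of: dict[str, str] = {}
    if lifestyle_path.exists():
        with open(lifestyle_path) as fh:
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                if i == 0 and parts[0].lower() == "species":
                    continue
                if len(parts) >= 2:
                    lifestyle_of[parts[0]] = parts[1]

    fastas = sorted(list(indir.glob("*.fasta")) + list(indir.glob("*.fa")))
    if not fastas:
        raise EmptyInputError(f"no FASTA files in {indir}")

    scoring = ScoringMatrix.blosum62()
    rate_model = RateModel.jtt(config.gamma_shape, config.gamma_categories)

    reports: list[GroupFilterReport] = []
    scans = []
    quarantined: dict[str, str] = {}
    for fasta in fastas:
        gid = fasta.stem
        try:
            group = read_alignment(
                fasta, annotations, strict=config.strict_alphabet
            )
            report = filter_group(
                group,
                min_sequences=config.min_group_size,
                excluded_tags=set(config.excluded_categories),
            )
            reports.append(report)
            if not report.passed:
                log.info("filtered out %s: %s", gid, ";".join(report.failure_reasons))
                continue
            scan = DivergenceScan(
                group,
                scoring=scoring,
                rate_model=rate_model,
                alpha=config.alpha,
                min_clade_size=config.min_clade_size,
                null_floor=config.null_floor,
                null_batch=config.null_batch,
                null_cap=config.null_cap,
                null_tol=config.null_tol,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = scan.fit(seed=derive_seed(config.seed, gid))
            scans.append(result)
            log.info(
                "scanned %s: %d tested nodes, FD=%s",
                gid, result.n_tested_nodes, result.is_fd,
            )
        except Exception as exc:  # quarantine-and-continue
            quarantined[gid] = f"{type(exc).__name__}: {exc}"
            log.error("quarantined %s: %s\n%s", gid, exc, traceback.format_exc())

    if not scans:
        raise EmptyInputError("no group passed the filters and scanned cleanly")

    records = [r for res in scans for r in res.branch_records()]
    branch_table = make_branch_table(records)
    analysis = EnrichmentAnalysis(branch_table, lifestyle_of, alpha=config.alpha)
    enrichment = analysis.fit(seed=config.seed)

    _write_outputs(outdir, config, reports, scans, branch_table, enrichment, quarantined)
    return RunBundle(
        config=config,
        filter_reports=reports,
        scans=scans,
        branch_table=branch_table,
        enrichment=enrichment,
        quarantined=quarantined,
    )


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="w"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


def _write_outputs(outdir, config, reports, scans, branch_table, enrichment, quarantined):
    import pandas as pd

    write_filter_reports(reports, outdir / "filter_report.tsv")
    site_frames = [f for r in scans if len(f := r.sites_frame())]
    sites = (
        pd.concat(site_frames, ignore_index=True) if site_frames
        else scans[0].sites_frame()
    )
    sites.to_csv(outdir / "site_results.tsv", sep="\t", index=False, float_format="%.6g")
    branch_frames = [f for r in scans if len(f := r.branch_frame())]
    branches = (
        pd.concat(branch_frames, ignore_index=True) if branch_frames
        else scans[0].branch_frame()
    )
    branches.to_csv(outdir / "branch_summary.tsv", sep="\t", index=False)
    branch_table.to_csv(outdir / "branch_table.tsv", sep="\t", index=False)
    enrichment.category_frame().to_csv(
        outdir / "enrichment_by_category.tsv", sep="\t", index=False, float_format="%.6g"
    )
    enrichment.species_frame().to_csv(
        outdir / "enrichment_by_species.tsv", sep="\t", index=False, float_format="%.6g"
    )
    sm = enrichment.status_matrix.copy()
    sm.index.name = "species"
    sm.to_csv(outdir / "status_matrix.tsv", sep="\t", na_rep="NA", float_format="%.0f")
    try:
        enrichment.plot_heatmap(
            outdir / "heatmap.png", tsv_path=outdir / "status_matrix_ordered.tsv"
        )
    except ValueError as exc:
        log.warning("heatmap skipped: %s", exc)
    if enrichment.lifestyle_tests:
        with open(outdir / "lifestyle_tests.tsv", "w") as fh:
            fh.write(
                "focal\tcomparison\tenriched\tneither\timpoverished\t"
                "test\tstatistic\tp_value\tdirection\n"
            )
            for (f0, c0), t in enrichment.lifestyle_tests.items():
                cnt = "\t".join(
                    f"{t.counts[0, j]}/{t.counts[1, j]}" for j in range(3)
                )
                stat = f"{t.statistic:.4f}" if t.statistic is not None else "-"
                fh.write(
                    f"{f0}\t{c0}\t{cnt}\t{t.test_used}\t{stat}\t"
                    f"{t.p_value:.6g}\t{t.direction}\n"
                )
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_groups_seen": len(reports),
        "n_groups_passed": sum(r.passed for r in reports),
        "n_groups_scanned": len(scans),
        "quarantined": quarantined,
        "per_group_seeds": {
            r.group.group_id: derive_seed(config.seed, r.group.group_id) for r in scans
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
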