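"""Synthetic homolog-group generators with known ground truth.

Everything the scan consumes can be generated here: aligned groups
evolved neutrally (JTT with discrete-gamma rates) along random Yule-shaped
gene trees, positive controls with *planted* clade-specific radical
substitutions, and whole multi-group datasets with species, category and
lifestyle annotations plus a machine-readable truth file.

Planting works by residue replacement, not rate inflation: at each
planted column every sequence of one clade is overwritten with the
residue scoring worst (most negative BLOSUM62 entry) against the
outgroup consensus.  That creates exactly the conserved, radical
clade-vs-outgroup contrast the site statistic targets, with unambiguous
ground truth for recovery tests.

Default generator settings model a typical bacterial protein family:
16 taxa, 300 aligned columns, Yule topologies with i.i.d. exponential
branch lengths of mean 0.15 substitutions/site, gapless.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import AMINO_ACIDS, AlignmentGroup
from .substitution import RateModel, ScoringMatrix, evolve_alignment
from .tree import GeneTree, NodePartition

DEFAULT_N_TAXA = 16
DEFAULT_N_COLUMNS = 300
DEFAULT_BRANCH_SCALE = 0.15


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_groups: int = 10
    n_taxa: int = DEFAULT_N_TAXA
    n_columns: int = DEFAULT_N_COLUMNS
    branch_scale: float = DEFAULT_BRANCH_SCALE
    gamma_shape: float = 1.0
    gamma_categories: int = 4
    seed: int = 0


@dataclass
class GroupTruth:
    """Ground truth attached to a generated group."""

    tree: GeneTree
    planted_partition: NodePartition | None = None
    planted_sites: list[int] = field(default_factory=list)
    planted_clade: frozenset[str] = frozenset()


def yule_tree(
    n_taxa: int,
    seed: int,
    *,
    branch_scale: float = DEFAULT_BRANCH_SCALE,
    prefix: str = "t",
) -> GeneTree:
    """Random Yule (pure-birth) topology with exponential branch lengths."""
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"{prefix}{i:02d}" for i in range(n_taxa)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    np_rng = np.random.default_rng(seed)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(np_rng.exponential(branch_scale))
    tree.is_rooted = True
    return GeneTree(tree)


def _group_from_sim(
    group_id: str,
    matrix: np.ndarray,
    taxa: list[str],
    species_of: dict[str, str],
    category: str,
) -> AlignmentGroup:
    seqs = [(t, "".join(AMINO_ACIDS[c] for c in row)) for t, row in zip(taxa, matrix)]
    return AlignmentGroup(
        group_id=group_id,
        sequences=seqs,
        species_of=dict(species_of),
        category_tags={t: category for t in taxa},
    )


def make_neutral_group(
    group_id: str = "g0",
    *,
    n_taxa: int = DEFAULT_N_TAXA,
    n_columns: int = DEFAULT_N_COLUMNS,
    branch_scale: float = DEFAULT_BRANCH_SCALE,
    category: str = "J",
    species_of: dict[str, str] | None = None,
    tree: GeneTree | None = None,
    model: RateModel | None = None,
    seed: int = 0,
) -> tuple[AlignmentGroup, GroupTruth]:
    """One neutrally evolved group plus the true tree it was grown on.

    By default each sequence is its own species (``spNN``), so species
    attribution in enrichment tests is unambiguous.
    """
    model = model or RateModel.jtt()
    if tree is None:
        tree = yule_tree(n_taxa, seed, branch_scale=branch_scale)
    sim = evolve_alignment(tree, n_columns, model, seed=np.random.default_rng(seed))
    taxa = sim.taxa
    if species_of is None:
        species_of = {t: f"sp{i:02d}" for i, t in enumerate(sorted(taxa))}
    group = _group_from_sim(group_id, sim.matrix, taxa, species_of, category)
    return group, GroupTruth(tree=tree)


def radical_residue(consensus: int, scoring: ScoringMatrix) -> int:
    """The residue with the most negative score against ``consensus``."""
    return int(np.argmin(scoring.scores[consensus]))


def _plantable_columns(
    mat: np.ndarray, scoring: ScoringMatrix, n_sites: int
) -> list[int]:
    """Columns to plant at, best signature first.

    Functional divergence of the kind the statistic targets is a radical
    replacement at an otherwise *conserved* position, so planting prefers
    fully conserved gap-free columns, ranked by the achievable contrast
    (the consensus residue's self score minus its most negative row
    entry); remaining slots fall back to the most conserved columns.
    Deterministic: ties break on the column index.
    """
    n_rows, length = mat.shape
    keys = []
    for col in range(length):
        column = mat[:, col]
        if (column < 0).any():
            keys.append((2, 0.0, col))
            continue
        counts = np.bincount(column, minlength=20)
        consensus = int(counts.argmax())
        conserved = counts[consensus] == n_rows
        contrast = float(
            scoring.scores[consensus, consensus] - scoring.scores[consensus].min()
        )
        keys.append((0 if conserved else 1, -contrast, col))
    keys.sort()
    return [col for _, _, col in keys[:n_sites]]


def make_divergent_group(
    group_id: str = "g0",
    *,
    n_sites: int = 5,
    partition: NodePartition | None = None,
    planted_clade: str = "a",
    scoring: ScoringMatrix | None = None,
    **kwargs,
) -> tuple[AlignmentGroup, GroupTruth]:
    """A neutral group with ``n_sites`` planted radical clade shifts.

    The shift is planted at ``partition`` (default: the first testable
    node of the true tree, preorder) in clade A or B per
    ``planted_clade``: at each planted column every sequence of that
    clade is overwritten with the residue scoring worst against the
    column consensus.  With ``n_sites=0`` the output is identical to
    :func:`make_neutral_group` under the same seed.
    """
    scoring = scoring or ScoringMatrix.blosum62()
    group, truth = make_neutral_group(group_id, **kwargs)
    if partition is None:
        testable = truth.tree.testable_partitions()
        if not testable:
            raise ValueError(f"{group_id}: true tree has no testable node to plant at")
        partition = testable[0]
    elif not partition.testable:
        raise ValueError(f"{group_id}: requested partition is not testable")
    clade = partition.clade_a if planted_clade == "a" else partition.clade_b
    mat = group.matrix().copy()
    sites = sorted(_plantable_columns(mat, scoring, n_sites))
    rows_clade = group.row_index(clade)
    rows_out = group.row_index(partition.outgroup)
    for col in sites:
        out_col = mat[rows_out, col]
        out_col = out_col[out_col >= 0]
        consensus = int(np.bincount(out_col, minlength=20).argmax()) if out_col.size else 0
        mat[rows_clade, col] = radical_residue(consensus, scoring)
    seqs = [
        (sid, "".join(AMINO_ACIDS[c] if c >= 0 else "-" for c in mat[i]))
        for i, (sid, _) in enumerate(group.sequences)
    ]
    planted = AlignmentGroup(
        group_id=group.group_id,
        sequences=seqs,
        species_of=group.species_of,
        category_tags=group.category_tags,
    )
    return planted, GroupTruth(
        tree=truth.tree,
        planted_partition=partition,
        planted_sites=sites,
        planted_clade=frozenset(clade),
    )


# ---------------------------------------------------------------------------
# structured family trees for end-to-end fixtures
# ---------------------------------------------------------------------------
def paralog_family_tree(
    clade_a: list[str],
    clade_b: list[str],
    outgroup: list[str],
    *,
    tip_length: float = 0.1,
    stem_length: float = 0.15,
    outgroup_length: float = 0.5,
) -> GeneTree:
    """A (cladeA, cladeB) + distant-outgroup family tree.

    Clades are balanced (easier for distance methods to recover than
    ladders) and the outgroup stem is the longest path, which pins
    midpoint rooting onto it so the node joining the two clades is
    testable with the outgroup sequences as the reference.  Clades must
    have at least 2 leaves each.
    """

    def balanced(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{tip_length}"
        mid = (len(names) + 1) // 2
        return (
            f"({balanced(names[:mid])},{balanced(names[mid:])}):{tip_length}"
        )

    ingroup = f"({balanced(clade_a)}:{stem_length},{balanced(clade_b)}:{stem_length})"
    out = (
        f"{outgroup[0]}:{outgroup_length}"
        if len(outgroup) == 1
        else f"{balanced(outgroup)}:{outgroup_length}"
    )
    return GeneTree.from_newick(f"({ingroup}:{outgroup_length},{out});")


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------
@dataclass
class FixtureDataset:
    groups: list[AlignmentGroup]
    truths: dict[str, GroupTruth]
    lifestyle_of: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        """Write FASTAs, annotation TSV, lifestyle TSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .alignment import write_alignment

        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write("seq_id\tspecies\tcategory\n")
            for g in self.groups:
                write_alignment(g, outdir / f"{g.group_id}.fasta")
                for sid in g.seq_ids:
                    fh.write(f"{sid}\t{g.species_of[sid]}\t{g.category_tags[sid]}\n")
        with open(outdir / "lifestyle.tsv", "w") as fh:
            fh.write("species\tlifestyle\n")
            for sp, ls in sorted(self.lifestyle_of.items()):
                fh.write(f"{sp}\t{ls}\n")
        truth = {
            gid: {
                "planted_sites": t.planted_sites,
                "planted_clade": sorted(t.planted_clade),
                "tree": t.tree.to_newick(),
            }
            for gid, t in self.truths.items()
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def make_dataset(
    *,
    n_planted_groups: int = 6,
    n_neutral_groups: int = 10,
    planted_category: str = "U",
    neutral_category: str = "J",
    planted_species: str = "sp01",
    n_other_species: int = 9,
    n_columns: int = 200,
    n_planted_sites: int = 5,
    model: RateModel | None = None,
    seed: int = 0,
) -> FixtureDataset:
    """A multi-group dataset with divergence planted in one species.

    Planted groups are paralog families of ``planted_species`` (two
    clades of four paralogs plus one outgroup sequence from another
    species) annotated with ``planted_category``; radical shifts are
    planted in clade A.  Neutral groups have the same shape but rotate
    through the other species and carry ``neutral_category``.  Because
    branch-level species attribution uses clade membership only, all
    divergence-positive tests land in the (planted species, planted
    category) cell.
    """
    model = model or RateModel.jtt()
    others = [f"sp{i:02d}" for i in range(2, n_other_species + 2)]
    groups: list[AlignmentGroup] = []
    truths: dict[str, GroupTruth] = {}

    def family(gid: str, species: str, out_species: str, category: str,
               planted: bool, seed_i: int):
        a = [f"{gid}_a{k}" for k in range(4)]
        b = [f"{gid}_b{k}" for k in range(4)]
        o = [f"{gid}_o0"]
        tree = paralog_family_tree(a, b, o)
        species_of = {**{s: species for s in a + b}, o[0]: out_species}
        part = next(
            p for p in tree.testable_partitions()
            if p.outgroup == frozenset(o)
        )
        if planted:
            g, t = make_divergent_group(
                gid, n_sites=n_planted_sites, partition=part,
                tree=tree, species_of=species_of, category=category,
                n_columns=n_columns, model=model, seed=seed_i,
            )
        else:
            g, t = make_neutral_group(
                gid, tree=tree, species_of=species_of, category=category,
                n_columns=n_columns, model=model, seed=seed_i,
            )
        groups.append(g)
        truths[gid] = t

    for i in range(n_planted_groups):
        family(
            f"planted{i:02d}", planted_species, others[i % len(others)],
            planted_category, True, seed * 1_000_003 + i,
        )
    for i in range(n_neutral_groups):
        family(
            f"neutral{i:02d}", others[i % len(others)],
            others[(i + 1) % len(others)], neutral_category, False,
            seed * 1_000_003 + 500 + i,
        )
    lifestyle = {planted_species: "host-associated"}
    lifestyle.update({sp: "free-living" for sp in others})
    return FixtureDataset(groups=groups, truths=truths, lifestyle_of=lifestyle)
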