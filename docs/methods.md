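# Methods

`cladeshift` detects *functional divergence* in protein families: alignment
positions where one clade of a gene tree has accumulated radical amino-acid
replacements relative to an outgroup while its sister clade has not. Such
clade-specific shifts in site-level substitution behaviour are the classic
sequence signature of a change in protein function (type-II divergence).
Because every family is analysed on its own gene tree, the approach tolerates
the rampant horizontal gene transfer that makes a single species tree
unusable for bacterial proteomes.

## The scan, step by step

**1. Group filtering.** Input is one aligned protein family per FASTA file
plus per-sequence species and one-letter functional-category annotations
(COG-style). Families enter the scan only if they have at least 9 sequences
(one outgroup plus two testable clades of 4), carry a single category tag,
and that tag is not one of the poorly characterised categories `R`/`S`.
Multi-letter annotations count as multi-tag. The 9-sequence minimum and the
tag filters are screening conventions for proteome-scale scans; the filter
report records modal-tag frequencies for every group either way.

**2. Gene trees.** Pairwise distances are maximum-likelihood estimates under
the JTT replacement model with 4-category discrete-gamma rate heterogeneity
(shape fixed at α = 1.0; estimating α per family is deliberately avoided so
proteome-scale runs stay cheap). Gap-containing columns are excluded
pairwise; the optimiser is bounded at 10 substitutions/site and capped
estimates are flagged as saturated rather than fatal. Trees are built with
BIONJ — the variance-weighted neighbour-joining variant, implemented here in
full (variance-minimising reduction weight λ, ties in the Q criterion broken
by lowest taxon-index pair, negative branch estimates clamped to zero) — and
midpoint-rooted. Midpoint rooting is a pragmatic choice: the scan needs
*some* deterministic root to enumerate nodes, and the node statistics are
driven by the clade/outgroup split, which is insensitive to the exact root
position in most topologies.

**3. Site scoring.** Every internal node whose two child clades hold ≥ 4
leaves each, with ≥ 1 leaf left over as outgroup, is tested. At one column,
all non-gap (clade member, outgroup member) residue pairs are scored with
BLOSUM62; with x̄₁, x̄₂ the clade means, s₁², s₂² the sample variances
(n − 1 denominator, zero when a clade contributes a single pair) and n₁, n₂
the pair counts, the site statistic is the Welch-type contrast

    FD = |x̄₁ − x̄₂| / SE,   SE = √(s₁²/n₁ + s₂²/n₂).

The pair-mean reading of "mean substitution score relative to the outgroup"
is the most direct one; scoring is symmetric in the two clades (absolute
difference), so a shift in either clade is detected. A column is
not-scorable when either clade contributes no non-gap pair. When the means
differ but SE = 0 (both clades perfectly conserved), SE is floored at 1e−6:
the site receives a very large but finite score instead of a
division-by-zero. A consequence worth knowing: fully conserved contrasting
columns (clade fixed at one residue, outgroup at another) occupy the extreme
tail of the statistic, ordered among themselves by |x̄₁ − x̄₂|. With small
outgroups this "conserved radical fixation" class dominates the top ranks —
which is exactly the biology the statistic targets, and the empirical null
calibrates it correctly because the same class arises in the simulations.

**4. Significance.** The null distribution is empirical and per-family:
neutral alignments are simulated on the *same* estimated tree (topology and
branch lengths) under JTT+Γ₄, with the simulated length set to the alignment
length minus the mean per-sequence gap count (rounded half-to-even), so the
amount of data matches the observed effective length. Each simulated column
is scored at every tested node; scores pool per node. At least 1000
replicate alignments are simulated; simulation then continues in batches of
100 until the pooled mean and standard deviation both move by less than
1e−6 between batches, up to a hard cap (library default 10,000) with a
warning when unconverged. In practice the 1e−6 tolerance is never reached
before the cap — adding a 100-replicate batch to a pool of hundreds of
thousands of scores shifts the running mean by far more than 1e−6 whenever
the pool has any variance — so the cap is the operative bound, and results
are insensitive to it beyond the 1000-replicate floor (the null is a rate
estimate; extra replicates reduce its noise, not its location). Since gamma
categories are fixed a priori, the same α = 1.0 heterogeneity is used in the
null simulations as in distance estimation.

Observed sites get add-one empirical upper-tail p-values,
p = (1 + #{null ≥ obs}) / (1 + N). Benjamini–Hochberg runs per node across
that node's scorable sites at α = 0.05 (q ≤ α rejects). A branch is called
functionally divergent when at least one site survives FDR.

**5. Enrichment.** Branch calls aggregate three ways: per functional
category (a branch inherits its group's tag), per species (a branch is
attributed to every species with ≥ 1 sequence in either tested clade —
outgroup membership does not attribute), and per category-within-species.
Each unit gets a 2×2 test (unit vs rest × divergence-positive vs negative)
with Yates' correction, switching to Fisher's exact test when any expected
cell drops below 5; `enriched` means p < 0.05 with observed > expected,
`impoverished` the opposite direction, `neither` otherwise, `no-data` when
the unit has no tested branch. No multiple-testing correction is applied
across units (statuses are descriptive labels, not inferences). Lifestyle
associations compare two groups of species in a 2×3 status table (Yates for
2×2 after empty-column pruning, plain chi-squared at df 2, Fisher when
expected counts fall below 5). The 2-row Fisher test is exact whenever the
number of candidate tables (stars-and-bars over the smaller row margin) is
tractable, otherwise seeded Patefield Monte Carlo.

**6. Reporting.** The species × category status matrix (+1 / 0 / −1, NaN
for no-data) is clustered in both dimensions with Euclidean distance and
complete linkage (the linkage is configurable; only the distance is
canonical). Missing cells are imputed as 0 for distance purposes only and
flagged. Labels are sorted before clustering so the dendrograms depend only
on cell values, never input order. Output is a four-colour heatmap with
marginal dendrograms, the reordered matrix as TSV, and Newick exports of
both dendrograms.

## Reproducibility

Every stochastic step flows from one master seed. Per-group streams are
derived as SHA-256(master seed, group id) mod 2³¹, so pipeline results are
identical for any scheduling or worker order; the run manifest records the
config, package version and all derived seeds. Group-level failures are
quarantined and logged, never fatal to the run.

## The synthetic-data generator

`cladeshift.simulate` generates everything the pipeline consumes, with known
ground truth.

*Neutral groups* evolve a root sequence drawn from the JTT equilibrium
frequencies along a random Yule topology with i.i.d. exponential branch
lengths (default mean 0.15 substitutions/site, a typical within-family
divergence), 16 taxa and 300 gapless columns by default, under JTT+Γ₄
(α = 1.0). Site rate categories are i.i.d. across sites and replicates.

*Positive controls* plant clade-specific radical shifts by residue
replacement: at each planted column, every sequence of one clade of a
designated testable node is overwritten with the residue scoring worst
(most negative BLOSUM62 entry) against the outgroup consensus. Planting
targets fully conserved gap-free columns, ranked by achievable contrast
(consensus self-score minus its most negative row entry): a radical
replacement at an otherwise invariant position is precisely the signature
the statistic is built to find, and it gives unambiguous ground truth.
Planted fixture families use a fixed balanced topology — two clades of four
(tips 0.1, clade stems 0.15) and a distant outgroup (stem 0.5). The
geometry serves three constraints at once: clade stems long enough for
BIONJ to recover the clades from the data, short enough that *neutral*
clade-level fixations (which fall in the same extreme-score class as
planted sites) stay rare, and an outgroup stem long enough that midpoint
rooting stays on it even though the planted columns inflate the planted
clade's estimated distances.

*Whole datasets* combine planted paralog families of one species (category
`U`, secretion-style) with neutral families rotating through the other
species (category `J`), plus annotation, lifestyle and truth files —
sufficient structure for the end-to-end enrichment recovery check, where
only the (planted species, `U`) cell should come out enriched.

What the generator does **not** emulate: indel processes (simulated
alignments are gapless; gap handling is exercised by unit fixtures),
alignment error, among-site compositional heterogeneity, covarion-style
rate shifts, and real orthology-call noise. Passing the synthetic recovery
tests therefore demonstrates correctness of the statistics and machinery
under the model's own assumptions, not robustness to misalignment or model
violation in field data.

## Problem sizes in the test and acceptance runs

The statistical checks run at sizes chosen to make their expectations
sharp but cheap: the neutral false-positive run uses 20 groups of 16 taxa ×
300 columns with the 1000-replicate null floor and a 1500–2000 replicate
cap; planted-site recovery uses 20 generator seeds at 10 taxa × 400
columns; the end-to-end enrichment check uses 10 master seeds × 16 groups
of 9 taxa × 200 columns. Yule topologies on 16 taxa yield no testable node
in roughly 40% of draws (balanced 4+4 splits are uncommon); such alignments
report zero divergent sites and are included in the false-positive average.

## Numerical choices and degenerate inputs

- Transition matrices come from a symmetric eigendecomposition of the
  reversible rate matrix (exact, reused across branch lengths); rows are
  clipped/renormalised against rounding noise.
- Discrete-gamma rates are mean-of-slice (each category is the conditional
  mean of its probability slice), so rates average to 1 exactly.
- Distance optimisation: bounded scalar minimisation on [1e−9, 10] with
  1e−8 tolerance; identical sequences short-circuit to 0.
- BIONJ λ is clamped to [0, 1]; a zero-variance pair falls back to λ = ½.
- Zero-diameter trees midpoint-root deterministically on the first leaf in
  label order.
- Empirical p-values are add-one, so p = 0 is impossible and p-values are
  valid (stochastically ≥ uniform) under the null.
- All-missing rows/columns are dropped before clustering, with a warning.

## Known limitations

- Midpoint rooting is a heuristic; families with strongly asymmetric rates
  may root badly, which can cost testable nodes (never false calls — the
  null is conditioned on whatever tree was used).
- The SE floor makes the extreme tail rank-only: the numeric FD values of
  perfectly conserved contrasts (~10⁷) are not interpretable as effect
  sizes, only their order is.
- BH runs per node; sites tested at several nested nodes are not corrected
  jointly across nodes.
- The per-species attribution counts a branch once per clade species, so
  species co-occurring in clades share attribution; with one sequence per
  species per family (the generator's default roster) this is unambiguous.
- Fixed α = 1.0 rate heterogeneity is a modelling convention inherited from
  proteome-scale practice, not an estimate.
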