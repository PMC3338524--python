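# cladeshift

Proteome-wide detection of **functional divergence** in protein families:
alignment sites where one clade of a gene tree has accumulated radical
amino-acid substitutions relative to an outgroup while its sister clade has
not. Such clade-specific shifts in site-level substitution behaviour are the
classic sequence signature of a change in protein function, and — because
every family is analysed on its own gene tree — the approach stays valid for
bacteria, where horizontal gene transfer makes a single species tree
unreliable.

`cladeshift` is for molecular evolutionists and comparative genomicists who
want to scan many homolog families at once, get per-site candidate residues
for follow-up, and see dataset-level patterns: which functional categories,
which species, and which category-within-species cells are enriched or
impoverished for divergence.

## The statistic

For each internal node of a family's tree whose two child clades hold ≥ 4
sequences each (with ≥ 1 sequence left as outgroup), every alignment column
is scored. All non-gap (clade member, outgroup member) residue pairs are
scored with BLOSUM62; with x̄₁, x̄₂ the clade-wise mean pair scores, s₁², s₂²
their sample variances and n₁, n₂ the pair counts, the site statistic is the
Welch-type contrast

```
FD = |x̄₁ − x̄₂| / SE,    SE = √(s₁²/n₁ + s₂²/n₂)
```

A large FD means one clade's residues score radically against the outgroup
while the sister clade's do not. Significance is empirical: ≥ 1000 neutral
alignments are simulated on the same tree (JTT + 4-category gamma, α = 1.0),
scored identically, and pooled into a per-node null; observed sites get
add-one upper-tail p-values, Benjamini–Hochberg FDR at α = 0.05 runs per
node, and a branch with ≥ 1 surviving site is called divergent. Branch calls
then feed chi-squared (Yates; Fisher when expected counts < 5) enrichment
tests per category, per species and per category-within-species, and the
resulting status matrix is clustered into a heatmap.

Trees are BIONJ (variance-weighted neighbour joining) over pairwise
maximum-likelihood JTT+Γ₄ distances, midpoint-rooted. See
[docs/methods.md](docs/methods.md) for the full model description,
parameter table and limitations.

## Worked example

Generate a synthetic dataset with divergence planted in the secretion-system
(`U`) paralog families of one species, scan it, and read the results:

```python
from cladeshift.simulate import make_dataset
from cladeshift.pipeline import RunConfig, run_scan

make_dataset(seed=5).write("families")          # 6 planted 'U' + 10 neutral 'J' groups
bundle = run_scan(RunConfig(input_dir="families", output_dir="results",
                            seed=5, null_floor=1000, null_cap=1500))
print(bundle.scans[4].summary())
print(bundle.enrichment.summary())
```

which prints (abridged):

```
Functional divergence scan
============================================================
group:            planted00
sequences:        9  columns: 200
simulated length: 200
tested nodes:     1
alpha (FDR):      0.05
------------------------------------------------------------
node   2 [FD]  clades 4|4 out  1  significant sites: 11,37,70,84,87,160,174

Enrichment analysis
============================================================
tested branches: 15  divergence-positive: 4 (26.7% background)
------------------------------------------------------------
category  O/total  expected  p-value  status
J         0/10      8.00      0.003663 impoverished
U         4/5       0.00      0.003663 enriched
```

The planted group's single testable node is called divergent (`[FD]`) and
the significant-site list includes the five planted columns (11, 37, 70,
84, 87 here; two extra sites ride along at this FDR level). At dataset
level the `U` category is enriched and `J` impoverished, and the species ×
category status matrix puts `+1` in exactly the (sp01, U) cell the truth
file says was planted. `results/` also holds per-site and per-branch TSVs,
the clustered status matrix, a heatmap and a manifest with every derived
seed.

The same pipeline runs from a shell:

```bash
cladeshift simulate families --seed 5
cladeshift scan families results --seed 5
cladeshift enrich results/branch_table.tsv enr --lifestyle families/lifestyle.tsv
cladeshift cluster results/status_matrix.tsv clus
```

For a single family, the model interface is two lines:

```python
from cladeshift import DivergenceScan
result = DivergenceScan.from_files("family.fasta", "annotations.tsv").fit(seed=1)
print(result.summary())
```

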