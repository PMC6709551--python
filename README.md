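# circpanel

Reusable analysis pipeline for circular RNA (circRNA) profiles across large
cancer cell-line panels.  circRNAs arise when a downstream 5′ splice site is
joined back to an upstream 3′ splice site ("backsplicing"); reads spanning
that circular junction are the unit of detection and quantification.
Because individual detectors disagree substantially, panel-scale studies
call circRNAs by ensemble voting over several detectors and then ask
downstream questions about lineage specificity, biogenesis regulation, and
pharmacogenomic associations.  `circpanel` implements that downstream
analysis as a tested library with a thin CLI, for anyone who has per-tool
junction call tables (BED-like TSVs) and the usual panel side-tables
(expression, lineage labels, library sizes, gene annotation, drug response
AUC, mutations).

## What it computes

* **Consensus calling** — a circRNA is accepted in a cell line when at
  least 2 detectors each report it with ≥ 2 backsplicing reads; its
  abundance is the mean read count over detecting tools, normalized by the
  cell line's total mapped reads (reads per million by default).
  Coordinates from each detector dialect are converted to a common 0-based
  half-open convention so that "same circRNA" is exact key equality.
* **Lineage specificity** — gene specificity score
  s<sub>j</sub><sup>(l)</sup> = (med(e<sub>j</sub><sup>(l)</sup>) −
  med(e<sub>j</sub><sup>(all)</sup>)) / IQR(e<sub>j</sub><sup>(all)</sup>),
  with s > 0.5 calling a gene specific to lineage *l*; circRNAs are
  classified as lineage-specific (detected in exactly one lineage),
  ubiquitous (≥ 15 lineages), or intermediate, and the overlap between
  lineage-specific circRNAs and their parental genes' specificity is
  reported per lineage.
* **Biogenesis screen** — Spearman correlation of candidate regulator
  expression (spliceosome factors, 3′-end processing factors, RNA
  helicases, RBPs) against total normalized backsplice load, flagged at
  |Rs| > 0.3 and Benjamini–Hochberg FDR < 0.05, panel-wide and per lineage;
  EMT scores (mean mesenchymal minus mean epithelial marker z-score);
  circRNA-high/low median split of cell lines; Student's t comparison of
  load between treatment conditions; GCT/CLS export for external gene-set
  enrichment tools.
* **Matched permutation enrichment** — whether a focal gene set (e.g.
  clinically actionable genes) is enriched for circRNA formation or RBP
  binding-peak burden relative to 10,000 random gene sets of equal size
  drawn from a background matched on gene length, exon length, intron
  length, exon count, or expression; empirical p uses the add-one rule
  p = (1 + #{permuted ≥ observed}) / (1 + N), so the minimum at N = 10,000
  is 1/10,001.  A Pearson chi-squared helper covers the 2×2 rate
  comparison.
* **Association screen** — per circRNA, cell lines are split at the row
  median of normalized reads (or by presence); drug AUC / mRNA / protein
  features are tested with the two-sided Wilcoxon rank-sum test (effect =
  mean difference), mutations with Fisher's exact test (effect = odds
  ratio); BH correction is applied across the whole screen and
  associations with FDR < 0.05 are flagged, summarized per feature by
  direction.
* **Synthetic panel generator** — a fully seeded generator emulating
  multi-tool calls (per-tool sensitivity and false-call rates), lineage
  structure, depth- and EMT-dependent negative-binomial read counts,
  planted regulators, planted actionable-gene enrichment, and planted
  circRNA–drug effects, together with a machine-readable truth table, so
  the entire pipeline is testable with no sequencing data.

## Worked example

```python
import circpanel as cp
from circpanel.specificity import classify_breadth, CATEGORY_SPECIFIC
from circpanel.biogenesis import correlate_regulators

cfg = cp.PanelConfig(seed=42, n_lineages=4, lines_per_lineage=25,
                     n_genes=500, n_circ=1000, n_drugs=10, n_planted_drug_effects=2)
panel = cp.simulate_panel(cfg)
merged = cp.merge_calls(panel.tool_calls)            # >= 2 tools, >= 2 reads each
matrix = cp.normalize_reads(merged, panel.meta, cell_lines=panel.cell_lines)
counts = cp.count_circ_per_line(matrix)
print(f"{matrix.values.shape[0]} circRNAs across {matrix.values.shape[1]} cell lines")
print(f"mean circRNAs per line: {counts.mean():.1f} (min {counts.min()}, max {counts.max()})")

breadth = classify_breadth(matrix, panel.meta, ubiquity_min=4)
n_spec = (breadth["category"] == CATEGORY_SPECIFIC).sum()
print(f"lineage-specific: {n_spec} ({cp.format_percent(n_spec, len(breadth), 1)})")

load = cp.total_backsplice_load(matrix)
truth = panel.truth.genes
planted = list(truth[truth.regulator_effect != 0]["gene"])
nulls = [g for g in panel.expression.index if g not in set(planted)][:45]
corr = correlate_regulators(panel.expression, load, planted + nulls)
hit = corr[corr["significant"]]
print("flagged regulators:",
      ", ".join(f"{r.gene} (Rs={r.rs:.2f}, q={r.q:.1e})" for r in hit.itertuples()))
```

Output:

```
968 circRNAs across 100 cell lines
mean circRNAs per line: 36.0 (min 17, max 48)
lineage-specific: 744 (76.9%)
flagged regulators: G00103 (Rs=0.53, q=2.1e-07), G00155 (Rs=0.60, q=1.0e-09), G00242 (Rs=0.63, q=1.5e-10), G00291 (Rs=0.44, q=4.0e-05), G00353 (Rs=0.57, q=8.1e-09)
```

968 of the 1,000 simulated circRNAs survive the ≥2-tools/≥2-reads filter
somewhere in the panel; 76.9% are detected in a single lineage (the
generator restricts 75% of circRNAs to one lineage); and the regulator
screen flags exactly the five genes whose expression the generator coupled
to the total backsplice load, with no false positives among the 45 null
candidates.

## Command line

```bash
circpanel simulate --seed 1 --out panel/          # synthetic panel + truth
circpanel run --config run.yaml --out results/    # configured stage chain
circpanel consensus|specificity|biogenesis|enrich|associate --config run.yaml --out out/
```

The YAML config names the input directory (or a `simulate` block), the
stages to run, and per-stage parameters; every run writes a
`manifest.json` with the config hash and SHA-256 checksums of all outputs,
and reruns from the same manifest are byte-identical.

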