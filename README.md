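# occc-molpro

Downstream molecular-profiling analysis for ovarian clear cell carcinoma
(OCCC) panel sequencing.  The package takes *called* somatic variants,
microsatellite-marker statuses, raw fusion candidates, and targeted RNA
counts — the outputs of upstream callers — and implements everything that
turns them into a cohort report:

* **Variant interpretation** — rule-based deleterious (class 4/5)
  classification: every frameshift, nonsense, no-start, no-stop, or
  consensus-splice-site variant is deleterious; a missense variant only when
  its ClinVar-style class is pathogenic/likely pathogenic.  One recurrent
  *POLE* nonsense (NM_006231.2:c.3961A>T, p.(R1321X)) is excluded from
  *POLE* driver status because it does not produce the ultramutated
  phenotype.  TERT-promoter positivity is an exact HGVS match against the
  three clinically relevant hotspots (c.-124C>T, c.-124C>A, c.-146C>T).
* **Tumor mutational burden** — TMB = countable variants / 1.708 Mb of panel
  coding territory, counting synonymous and nonsynonymous variants with
  allele frequency ≥ 10%, excluding presumed-germline polymorphisms unless
  they are known drivers; evaluable only at ≥ 40% tumor cells; TMB-High at
  ≥ 10 mut/Mb.
* **Microsatellite instability** — MSI-High when > 20% of the (up to 17)
  evaluated microsatellite markers are unstable; strictly greater, so exactly
  20% is MSS.
* **Fusion filtering** — a candidate is a true fusion only if both partners
  are protein-coding, both breakpoints sit at exon-exon junctions (± 15 bp),
  crossing reads make up ≥ 10% of reads at the location, the region shows
  substantial expression, and no artifact screen fires (same gene family,
  transcriptional readthrough, frequently repeated pair not in the
  known-fusion table).  Reading frame is predicted from the retained 5' CDS
  length and the 3' breakpoint codon phase (in-frame iff they agree mod 3);
  novelty is a known-fusion-table lookup.
* **Expression profiling** — TMM (trimmed mean of M-values) normalization,
  TMM-adjusted log2 CPM, per-gene Z-scores, then agglomerative clustering
  with Manhattan distance and complete linkage; differential expression by a
  per-gene negative binomial GLM with moderated dispersion, Wald tests and
  Benjamini–Hochberg adjustment; in parallel, RPKM normalized to the
  geometric mean of the *VCP*/*SF3B1*/*ATP5F1B* reference genes.
* **Molecular subtyping** — TCGA-style classes by hierarchical precedence
  POLEmut > MSI-High > p53abn > NSMP.
* **Cohort statistics and survival** — Fisher/chi-squared association tests,
  mutual-exclusivity screens, RFS/OS endpoint construction, Kaplan–Meier
  with log-rank and likelihood-ratio comparisons, and Cox proportional
  hazards with univariable screening and backward elimination.

Because the original study cohort is not publicly deposited, the package
ships a **synthetic cohort generator** that plants the cohort's marginal
structure exactly — per-gene mutated-sample counts, per-sample countable
variant loads (so TMB emerges through the real counting path), MSI marker
instability, filter-passing fusions plus one decoy per rejection class, a
93/12 two-cluster expression structure, and outcome patterns — together with
truth labels and an internal self-check that re-derives every rule-derivable
label from the raw tables.

## Worked example

```bash
occc-molpro generate --seed 42 --out cohort/
occc-molpro run-dir --input cohort/ --out report/
```

prints

```
{
  "variants": "ok", "tmb": "ok", "msi": "ok", "subtype": "ok",
  "fusions": "ok", "expression": "ok", "survival": "ok"
}
```

and `report/gene_frequencies.tsv` starts

```
gene    mutated_samples percent
ARID1A  51.0    51.0
PIK3CA  47.0    47.0
KRAS    18.0    18.0
TP53    12.0    12.0
```

meaning 51 of the 100 DNA samples carry at least one class 4/5 *ARID1A*
mutation, and so on.  `report/tmb.tsv` holds per-sample TMB (9 samples reach
TMB-High ≥ 10 mut/Mb; cohort median 2.93 mut/Mb, TMB-High-subgroup median
25.18 mut/Mb), `report/msi.tsv` the marker-fraction MSI calls (7 MSI-High),
`report/fusion_verdicts.tsv` one verdict per candidate with machine-readable
rejection reasons (14 of 105 RNA samples are fusion-positive), and
`report/clusters.tsv` the expression cluster labels (93/12 split).
`report/manifest.json` records SHA-256 hashes of every input consumed.

The same operations are available as a library:

```python
from occc_molpro import generate_cohort, compute_tmb, call_msi

bundle = generate_cohort(seed=42)
res = compute_tmb([v for v in bundle.variants if v.sample_id == "S001"],
                  tumor_cell_fraction=0.7, kb=bundle.kb)
print(res.tmb_rounded, res.tmb_high)
```

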