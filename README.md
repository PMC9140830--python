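# syndriver

Synonymous single-nucleotide variants (sSNVs) are usually dismissed as
functionally silent, yet a handful are established cancer drivers — acting
through aberrant splicing, altered mRNA structure, or disrupted RNA-binding
protein (RBP) motifs rather than through the protein sequence. `syndriver`
implements, as a tested and reusable Python pipeline, a screening procedure
that nominates candidate cancer-driving sSNVs from somatic variant tables and
annotates their likely mechanism. It is aimed at cancer genomicists who want
to prioritise synonymous mutations for experimental follow-up, and at method
developers who need a fully synthetic, ground-truth-labeled benchmark for
this class of screen.

## The screen

Four categories of sSNVs are considered: germline, somatic in normal tissue,
somatic in cancer tissue, and a *putative driver* reference set (variants in
or above the 95th percentile of a composite database score). From that
reference set two thresholds are derived — the median machine-learned effect
score τ_eff and the median conservation (GERP-type) score τ_cons. A somatic
cancer sSNV is a **proposed driver** when it satisfies all four criteria:

1. effect score > τ_eff (strict),
2. conservation score > τ_cons (strict),
3. located in a cancer-associated gene,
4. recurrent: observed in ≥ 2 distinct patients.

Genes are stratified by the deepest cumulative filter any of their sSNVs
passes (non-recurrent only / recurrent / + conserved / + high effect), and
genes with passing-variant counts strictly above a chosen percentile of the
count distribution are selected as candidate cancer genes. Proposed drivers
are then annotated for mechanism: splicing (CADD-splice > 15 or any
splice-site delta > 0.5), mRNA structure change (p < α, default 0.2), and
RBP-motif overlap via a built-in FIMO-style PWM scanner with exact
(dynamic-programming) p-values.

Supporting statistics include per-gene burden (sSNV count / CDS length),
nsSNV/sSNV ratios, Kruskal–Wallis + Dunn (Holm) category comparisons with a
compact letter display, and hypergeometric over-representation of gene lists
with Jaccard-based redundancy pruning.

## Worked example

```python
from syndriver import driver_screen, synthetic_data, pipeline

# the percentile rule on a small per-gene count table
counts = synthetic_data.make_worked_example()   # 1,1,2,2,3,3,3,3,8,9
sel = driver_screen.percentile_select(counts, 70)
print(sorted(counts[g] for g in sel))           # -> [8, 9]

# a full synthetic cohort with 50 planted drivers among ~5800 somatic keys
cohort = synthetic_data.generate_cohort(seed=1)
out = pipeline.run_full_screen(cohort.variants, cohort.gene_sets,
                               transcripts=cohort.transcripts,
                               motifs=cohort.motifs)
print(round(out.thresholds.tau_effect, 3))      # -> 0.842
print(len(out.proposed_keys))                   # -> 50
print(out.venn["union"])                        # -> 35
```

At seed 1 the derived effect threshold is 0.842 (the median of the
reference set's effect scores), all 50 planted drivers are recovered with no
false positives, and 35 of them carry at least one mechanism tag.

The same steps are available from the shell:

```bash
syndriver simulate --seed 1 --out cohort/
syndriver screen --variants cohort/variants.tsv --tau-effect 0.84 \
    --tau-cons 4.16 --gene-sets cohort/gene_sets.gmt --out ledger
syndriver motifscan --motifs cohort/motifs.meme --fasta cohort/transcripts.fa \
    --out hits.tsv
```

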