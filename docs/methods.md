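# Methods

## The screening procedure

The pipeline treats a variant's genomic key `(chrom, pos, ref, alt)` as its
identity; transcript-level rows are a one-to-many expansion of that key.
All coordinates are 1-based and fully closed (VCF-style).

**Reference set and thresholds.** The putative-driver reference set is the
subset of reference variants whose composite database score lies *in or
above* the 95th percentile of all such scores (inclusive cut, percentile by
linear interpolation between order statistics). From it, two thresholds are
derived: τ_eff, the median machine-learned effect score (a probability in
[0, 1] that the sSNV has a molecular effect), and τ_cons, the median
conservation score (GERP-type, unbounded; higher = more constrained). The
median of an even-length list is the mean of the two central order
statistics. By the definition of the median and the strictness of the
filters, at least ⌈n/2⌉ of the reference variants themselves fail each
threshold filter — the thresholds characterise the reference, they do not
re-select it.

**The four filters.** A somatic-cancer sSNV is proposed as a driver iff
(1) effect > τ_eff, (2) conservation > τ_cons — both *strict*, so a score
exactly at a threshold fails; (3) its gene is in the union of the supplied
cancer gene sets; and (4) it is recurrent. Recurrence counts *distinct
patient identifiers* per genomic key: two samples from one patient do not
make a variant recurrent. Keys missing an effect or conservation score get
indeterminate flags and are excluded from the driver set (and counted in
the log) rather than silently failed. The four flags are computed
independently and conjoined, so the survivor count is non-increasing under
any filter order and the final set is order-invariant.

**Gene groups and percentile selection.** Genes are assigned the deepest
cumulative variant condition they satisfy: group 2 = at least one recurrent
sSNV, group 3 = recurrent and conserved, group 4 = recurrent, conserved and
high-effect; group 1 (non-recurrent sSNVs only) is the strict complement of
group 2. Groups are nested by construction. Per-gene counts of passing
variants default to distinct genomic keys (a row-counting switch is
provided, since raw mutation exports tally per-sample observations).
Selection at percentile x keeps genes whose count is *strictly greater*
than the interpolated x-th percentile of the count distribution; on the
canonical ten-gene example (1,1,2,2,3,3,3,3,8,9) the 70th percentile is 3
and the genes with 8 and 9 variants are selected. Nearest-rank
percentiles would give the same selection on that example; interpolation
was chosen as the common numerical default.

**Mechanism annotation.** Splicing: CADD-splice > 15 (the predictor's
recommended cutoff) OR any of the four splice-site deltas (acceptor/donor
gain/loss) > 0.5; a missing annotation family is non-contributing, both
missing is indeterminate. Structure: the structure-change p-value of an
external folding predictor, significant when p < α; the pipeline does not
fold RNA itself — it consumes the p-value and retains the mode-selection
rule (mode 1 for transcripts < 200 nt, mode 2 otherwise) so users can drive
the external tool correctly. α defaults to 0.2, the folding tool's
documented convention, and is configurable. RBP motifs: overlap of the
variant's transcript position with a significant PWM occurrence. Transcript
rows are called individually; a genomic key is called positive if any of
its transcript rows is, and both accounting levels are reported.

**Motif scanning.** Log-odds scores use smoothed probabilities
p' = (p + c·b)/(1 + c) with pseudocount c = 0.1 of the background (so a row
equal to the background scores 0 and nothing is −∞). P-values are exact:
scores are discretized at 1e-3 bits (configurable) and the distribution of
the window score of an i.i.d. background string is built by dynamic
programming, position by position; the reported p is the tail P(S ≥ s).
The default output threshold is p < 1e-4. Note that a width-w motif cannot
score below 4^(−w), so motifs shorter than 7 nt can never reach the 1e-4
default — a well-known property of exact PWM p-values, relevant when
choosing widths. Scanning defaults to the sense strand only (RBPs bind the
mRNA); a `both` mode scores antisense windows against the
reverse-complemented matrix for parity with DNA-alphabet scanners.

**Burden and set statistics.** Burden is the per-gene sSNV count divided by
CDS length; every observation row counts by default (`--unique-variants`
switches to distinct keys). Top-fraction selection takes ⌈f·n⌉ genes with
ties at the cut broken lexicographically for determinism. Category score
distributions are compared with a tie-corrected Kruskal–Wallis test and a
Dunn post hoc on pooled ranks; pairwise p-values are Holm-adjusted by
default (the convention of the common post-hoc toolchains; BH and
Bonferroni are available) and drive an insert-and-absorb compact letter
display in which two categories share a letter iff not significantly
different. The all-constant degenerate case is defined as H = 0. Gene-list
enrichment is one-sided hypergeometric over-representation with BH
adjustment across sets — the appropriate formulation for an unranked
high-burden gene list — and redundancy among enriched sets is pruned by a
rank-order scan dropping any set with Jaccard similarity > 0.5 to a
retained higher-ranked set (ontology-graph semantic similarity is out of
scope; Jaccard of memberships is used at the same cutoff).

## The synthetic cohorts

`synthetic_data.generate_cohort` emulates the four-category design with one
transcript per gene on a single synthetic chromosome (gene i occupies its
own 100 kb tile, so genomic keys never collide across genes). Defaults:
300 genes with CDS lengths uniform on [90, 3000], 40 cancer genes split
into two overlapping sets, 200 patients, 2000 germline / 1000
somatic-normal / 5000 somatic-cancer background / 500 putative-driver
variant keys, 5000 missense rows (with a 3× placement weight in cancer
genes, giving the nsSNV/sSNV ratio signal), and 50 planted drivers.

Score distributions are in the README table: effect ~ Beta per category
(drivers 8,2; normal 3,3; cancer 2,5; germline 2,4), conservation ~
Normal(4, 1) for drivers and Normal(0, 2) otherwise, chosen so category
medians respect the ordering driver > somatic-normal > somatic-cancer with
a wide margin. Population frequency is zero except for a per-category
observed fraction (0.95 germline, 0.2 normal, 0.1 cancer). Ten random genes
get a 2× burden multiplier. Background somatic-cancer keys are recurrent
(2–3 patients) with probability 0.1.

Planted drivers are placed in cancer genes, given 3–6 distinct patients,
and their effect/conservation scores are rejection-sampled from the driver
distributions *truncated above the derived thresholds*, so they pass all
four criteria by construction; screening recall below 1.0 on a generated
cohort is therefore always an implementation defect. Mechanism labels are
drawn per driver (splicing 0.4, structure 0.35, RBP 0.35) and the
annotation values are generated on the corresponding side of the default
cutoffs with a safety margin, so mechanism recovery is exact by
construction. RBP-positive drivers sit inside a planted consensus
occurrence of a sharp width-7 motif (consensus p ≈ 6·10⁻⁵ < 10⁻⁴);
RBP-negative drivers are placed outside every significant motif occurrence
of their transcript. Reference bases always match the (motif-planted)
transcript FASTA at the variant's transcript position.

What the generator does *not* emulate: mutational signatures and
trinucleotide context, multiple transcripts per gene, chromosome-scale
coordinates, linkage between the composite reference score and the other
annotations, and tumor heterogeneity in recurrence. Passing tests therefore
demonstrate the correctness of the screening logic under its stated
assumptions, not the empirical yield of the screen on real mutation
databases, whose headline counts depend on the full external data dumps.

## Numerical choices and problem sizes

Percentiles interpolate linearly; medians of even-length lists average the
central pair; hypergeometric tails come from `scipy.stats.hypergeom`
(validated in tests against exhaustive subset enumeration for universes up
to 12); PWM p-value tables conserve probability mass to 1e-9 and are
validated against full 4^w word enumeration for widths up to 6. The Dunn
test uses the pooled tie-correction Σ(t³−t)/(12(N−1)) and two-sided normal
p-values, validated to 1e-10 against a from-definition oracle. Test
fixtures use scaled-down cohorts (60 genes, ~1200 variant keys) where
distributional claims are not at stake; planted-driver recovery and the
category-ordering checks run on 20 default-size cohorts. The burden-boost
recovery check uses a 20 000-variant cohort because at 5000 background
variants the Poisson counting noise of short genes is comparable to a 2×
burden shift.

## Known limitations

The screen inherits the accuracy of its input annotations; indeterminate
variants are excluded rather than imputed. The compact letter display uses
a greedy insert-and-absorb construction, which is standard but not
guaranteed minimal in pathological non-transitive significance patterns.
The COSMIC-export dialect parses the common single-base substitution
notation only; complex alleles are dropped and counted. Burden normalises
by CDS length alone and does not model per-gene mutability covariates
(expression, replication timing).
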