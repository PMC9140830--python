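"""Per-gene mutation burden and the statistics built on top of it.

Burden is the number of synonymous SNVs observed in a gene divided by the
gene's coding length (per-nucleotide rate).  The module also compares
annotation-score distributions between variant categories (Kruskal-Wallis
with a Dunn post hoc and a compact letter display), tests gene lists for
over-representation in named gene sets (one-sided hypergeometric with BH
adjustment), and prunes redundant enriched sets by Jaccard similarity.

By default every observation row counts toward burden (a per-sample mutation
tally, the way COSMIC-style exports enumerate mutations); ``unique_variants``
switches to counting distinct genomic keys.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_io import GeneModel, GeneSetCollection, VariantRecord

logger = logging.getLogger(__name__)

_ADJUST_METHODS = {"holm": "holm", "bh": "fdr_bh", "bonferroni": "bonferroni"}


# ---------------------------------------------------------------------------
# burden


def compute_burden(
    variants: list[VariantRecord],
    gene_models: list[GeneModel],
    unique_variants: bool = False,
) -> pd.DataFrame:
    """Per-gene sSNV burden and nsSNV/sSNV ratio.

    Returns one row per modeled gene with columns ``gene, n_ssnv, cds_length,
    burden, n_nssnv, ratio``; ``ratio`` is NaN when the gene has no sSNV.
    Variants in genes without a model are excluded with a warning.
    """
    models = {m.gene: m for m in gene_models}
    n_unmodeled = 0
    counts_syn: dict[str, int] = {g: 0 for g in models}
    counts_mis: dict[str, int] = {g: 0 for g in models}
    seen_syn: dict[str, set] = {g: set() for g in models}
    seen_mis: dict[str, set] = {g: set() for g in models}
    for v in variants:
        if v.gene not in models:
            n_unmodeled += 1
            continue
        if v.consequence == "synonymous":
            counts_syn[v.gene] += 1
            seen_syn[v.gene].add(v.key)
        elif v.consequence == "missense":
            counts_mis[v.gene] += 1
            seen_mis[v.gene].add(v.key)
    if n_unmodeled:
        logger.warning("compute_burden: %d variants in unmodeled genes excluded", n_unmodeled)
    rows = []
    for gene in sorted(models):
        n_s = len(seen_syn[gene]) if unique_variants else counts_syn[gene]
        n_m = len(seen_mis[gene]) if unique_variants else counts_mis[gene]
        cds = models[gene].cds_length
        rows.append(
            {
                "gene": gene,
                "n_ssnv": n_s,
                "cds_length": cds,
                "burden": n_s / cds,
                "n_nssnv": n_m,
                "ratio": n_m / n_s if n_s > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_ssnv", "cds_length", "burden", "n_nssnv", "ratio"])


def top_fraction_genes(table: pd.DataFrame, fraction: float) -> list[str]:
    """The ``ceil(fraction * n)`` genes of highest burden.

    Ties at the cut are broken by gene symbol (ascending) for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if table.empty:
        raise ValueError("burden table is empty")
    k = math.ceil(fraction * len(table))
    ordered = table.sort_values(["burden", "gene"], ascending=[False, True], kind="mergesort")
    return ordered["gene"].head(k).tolist()


def ratio_extremes_cancer_fraction(
    table: pd.DataFrame, gene_sets: GeneSetCollection, k: int
) -> tuple[float, float]:
    """Cancer-set membership among the k genes of highest vs lowest nsSNV/sSNV ratio."""
    eligible = table.dropna(subset=["ratio"])
    if len(eligible) < 2 * k:
        raise ValueError(f"need >= {2 * k} genes with defined ratio, have {len(eligible)}")
    cancer = gene_sets.union()
    ordered = eligible.sort_values(["ratio", "gene"], ascending=[False, True], kind="mergesort")
    top = ordered["gene"].head(k)
    bottom = ordered["gene"].tail(k)
    return (
        float(top.isin(cancer).sum()) / k,
        float(bottom.isin(cancer).sum()) / k,
    )


def correlate_counts(table: pd.DataFrame) -> float:
    """Pearson correlation between per-gene nsSNV and sSNV counts."""
    if len(table) < 3:
        raise ValueError("need >= 3 genes for a correlation")
    x = table["n_ssnv"].to_numpy(dtype=float)
    y = table["n_nssnv"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in counts")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn post hoc


@dataclass
class GroupComparison:
    """Omnibus Kruskal-Wallis result with Dunn pairwise comparisons.

    ``pairwise`` has one row per unordered category pair: the Dunn z
    statistic, raw two-sided p, and adjusted p.  ``letters`` is a compact
    letter display: two categories share a letter iff their adjusted p is
    >= alpha.
    """

    kw_statistic: float
    kw_pvalue: float
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn z statistics on pooled tie-corrected ranks, two-sided normal p."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {
        g: float(ranks[offsets[i] : offsets[i + 1]].mean()) for i, g in enumerate(names)
    }
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "pvalue": min(p, 1.0)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "pvalue"])


def _compact_letters(names: list[str], nonsig: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff their pair is in ``nonsig`` (not significantly
    different).  Starts from one block containing everything and splits on
    each significant pair, absorbing redundant blocks.
    """
    blocks: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if frozenset((a, b)) in nonsig:
            continue
        new_blocks: list[set[str]] = []
        for blk in blocks:
            if a in blk and b in blk:
                new_blocks.extend((blk - {a}, blk - {b}))
            else:
                new_blocks.append(blk)
        # absorb blocks contained in another
        blocks = []
        for blk in sorted(new_blocks, key=len, reverse=True):
            if blk and not any(blk <= kept for kept in blocks):
                blocks.append(blk)
    # ensure every connected non-significant pair still shares a letter is
    # guaranteed by construction; order letters by first member for stability
    blocks.sort(key=lambda blk: min(names.index(g) for g in blk))
    letters: dict[str, str] = {g: "" for g in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for j, blk in enumerate(blocks):
        for g in names:
            if g in blk:
                letters[g] += alphabet[j]
    return letters


def compare_categories(
    groups: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    adjust: str = "holm",
) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Dunn post hoc across categories.

    ``groups`` maps category name to its score sample.  H uses the standard
    tie correction; pairwise Dunn p-values are adjusted (Holm by default)
    and drive the compact letter display at significance level ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjust!r}")
    pooled = np.concatenate(list(arrays.values()))
    names = list(arrays)
    if np.ptp(pooled) == 0:
        # every observation identical: all ranks tie, H = 0 by definition
        h, p = 0.0, 1.0
        pairwise = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "z": 0.0, "pvalue": 1.0, "padj": 1.0}
                for a, b in itertools.combinations(names, 2)
            ],
            columns=["group_a", "group_b", "z", "pvalue", "padj"],
        )
    else:
        h, p = stats.kruskal(*arrays.values())
        pairwise = _dunn_pairwise(arrays)
        pairwise["padj"] = multipletests(
            pairwise["pvalue"].to_numpy(), method=_ADJUST_METHODS[adjust]
        )[1]
    nonsig = {
        frozenset((row.group_a, row.group_b))
        for row in pairwise.itertuples()
        if row.padj >= alpha
    }
    letters = _compact_letters(names, nonsig)
    return GroupComparison(
        kw_statistic=float(h),
        kw_pvalue=float(p),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation table plus per-set membership.

    ``table`` columns: set_name, k (overlap), K (set size in universe),
    n (query size), N (universe size), pvalue, padj, gene_ratio (k/n).
    ``members`` keeps each set's genes (intersected with the universe) so
    redundancy pruning can compute Jaccard similarities.
    """

    table: pd.DataFrame
    members: dict[str, frozenset[str]]


def ora_enrichment(
    query: "set[str] | list[str]",
    gene_sets: GeneSetCollection,
    universe: "set[str] | None" = None,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    p = P(overlap >= k) drawing |query| genes from the universe; BH-adjusted
    across sets; sorted by adjusted p then set name.
    """
    query_set = set(query)
    if universe is None:
        universe = gene_sets.universe
    if universe is None:
        raise ValueError("a universe is required (explicit or on the collection)")
    universe = set(universe)
    if not query_set or not universe:
        raise ValueError("query and universe must be non-empty")
    stray = query_set - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    big_n = len(universe)
    n = len(query_set)
    rows = []
    members: dict[str, frozenset[str]] = {}
    for name, genes in gene_sets.sets.items():
        in_universe = frozenset(genes & universe)
        members[name] = in_universe
        big_k = len(in_universe)
        k = len(query_set & in_universe)
        pval = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "pvalue": min(pval, 1.0),
                "gene_ratio": k / n,
            }
        )
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "pvalue", "gene_ratio"])
    table["padj"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(["padj", "set_name"], kind="mergesort").reset_index(drop=True)
    table = table[["set_name", "k", "K", "n", "N", "pvalue", "padj", "gene_ratio"]]
    return EnrichmentResult(table=table, members=members)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def prune_redundant_terms(
    result: EnrichmentResult, threshold: float = 0.5
) -> EnrichmentResult:
    """Drop lower-ranked sets too similar to a retained higher-ranked one.

    Scans rows in rank order (ascending adjusted p) and removes any set whose
    Jaccard similarity of gene membership with an already-retained set
    exceeds ``threshold``.  Idempotent; output rows are a subset of input.
    """
    kept_names: list[str] = []
    for row in result.table.itertuples():
        mem = result.members[row.set_name]
        if all(_jaccard(mem, result.members[k]) <= threshold for k in kept_names):
            kept_names.append(row.set_name)
    table = result.table[result.table["set_name"].isin(kept_names)].reset_index(drop=True)
    return EnrichmentResult(table=table, members=dict(result.members))
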