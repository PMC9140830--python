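"""The core screen: from somatic variant tables to proposed driver sSNVs.

The procedure derives two score thresholds from a reference set of putative
drivers (the top 5% of composite database scores): the median machine-learned
effect score and the median evolutionary-conservation (GERP-style) score.  A
somatic cancer sSNV is *proposed* as a driver when it jointly satisfies four
criteria, all strict where a threshold is involved:

1. effect score strictly above the reference median;
2. conservation score strictly above the reference median;
3. located in a cancer-associated gene;
4. recurrent, i.e. observed in at least two distinct patients.

Genes are then stratified by the deepest cumulative variant filter they
satisfy (group 1: non-recurrent sSNVs only; 2: some recurrent sSNV; 3:
recurrent and conserved; 4: recurrent, conserved and high-effect), and the
genes with the most passing variants are selected by a strict percentile
rule on per-gene counts.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GeneSetCollection, VariantRecord

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]


@dataclass(frozen=True)
class ThresholdSet:
    """Score thresholds derived from the reference (putative-driver) set."""

    tau_effect: float
    tau_cons: float
    reference_size: int

    def __post_init__(self) -> None:
        if self.reference_size < 1:
            raise ValueError("reference_size must be >= 1")
        if not (math.isfinite(self.tau_effect) and math.isfinite(self.tau_cons)):
            raise ValueError("thresholds must be finite")


@dataclass
class ScreenResult:
    """Per-variant filter ledger and per-gene group assignment.

    ``variants``: one row per genomic key with recurrence_count and the four
    pass flags plus their conjunction ``is_proposed_driver``.
    ``genes``: one row per gene with its group (1-4) and passing-variant
    counts per cumulative filter.
    ``log``: survivor counts after each cumulative filter.
    """

    variants: pd.DataFrame
    genes: pd.DataFrame
    log: dict | None = None


def select_reference_set(
    variants: list[VariantRecord], percentile: float = 95.0
) -> list[VariantRecord]:
    """Variants whose composite database score is in or above the percentile.

    The cut is inclusive (score >= the linearly interpolated percentile
    value).  Every input must carry ``synmicdb_score``.
    """
    if not variants:
        raise ValueError("cannot select a reference set from no variants")
    missing = [v.key for v in variants if "synmicdb_score" not in v.scores]
    if missing:
        raise ValueError(f"variants missing synmicdb_score: {missing[:5]}")
    scores = np.array([v.scores["synmicdb_score"] for v in variants])
    cut = float(np.percentile(scores, percentile))
    return [v for v in variants if v.scores["synmicdb_score"] >= cut]


def derive_thresholds(reference: list[VariantRecord]) -> ThresholdSet:
    """Median effect and conservation scores of the reference set.

    The median of an even-length list is the mean of the two central order
    statistics.  Missing scores are a hard error listing the offending keys.
    """
    if not reference:
        raise ValueError("reference set is empty")
    missing = [
        v.key
        for v in reference
        if "effect_score" not in v.scores or "gerp" not in v.scores
    ]
    if missing:
        raise ValueError(f"reference variants missing effect_score/gerp: {missing[:5]}")
    tau_effect = float(np.median([v.scores["effect_score"] for v in reference]))
    tau_cons = float(np.median([v.scores["gerp"] for v in reference]))
    return ThresholdSet(tau_effect=tau_effect, tau_cons=tau_cons, reference_size=len(reference))


def tag_recurrent(variants: list[VariantRecord]) -> dict[Key, int]:
    """Distinct-patient count per genomic key.

    A variant is recurrent when seen in >= 2 *different* patients; repeated
    samples from one patient do not count.
    """
    patients: dict[Key, set[str]] = defaultdict(set)
    for v in variants:
        patients[v.key].add(v.patient_id)
    return {key: len(p) for key, p in patients.items()}


def _per_key_scores(variants: list[VariantRecord]) -> dict[Key, dict]:
    """Collapse transcript/patient rows onto genomic keys.

    Scores are aggregated by max over rows (rows of one key normally carry
    identical variant-level scores); gene membership collects every gene
    symbol the key maps to.
    """
    agg: dict[Key, dict] = {}
    for v in variants:
        entry = agg.setdefault(v.key, {"genes": set(), "effect": None, "gerp": None})
        entry["genes"].add(v.gene)
        for field, name in (("effect", "effect_score"), ("gerp", "gerp")):
            val = v.scores.get(name)
            if val is not None:
                prev = entry[field]
                entry[field] = val if prev is None else max(prev, val)
    return agg


def apply_driver_filters(
    variants: list[VariantRecord],
    thresholds: ThresholdSet,
    cancer_genes: GeneSetCollection,
    recurrence: dict[Key, int] | None = None,
) -> ScreenResult:
    """Apply the four driver criteria to every genomic variant key.

    Both score filters are strict inequalities; the cancer-gene filter is
    membership of the variant's gene in the union of the supplied sets.
    Keys missing an effect or conservation score get indeterminate flags and
    are excluded from the proposed drivers (counted in the log).
    """
    if recurrence is None:
        recurrence = tag_recurrent(variants)
    cancer = cancer_genes.union()
    agg = _per_key_scores(variants)
    rows = []
    n_indeterminate = 0
    for key in sorted(agg):
        entry = agg[key]
        rec_count = recurrence.get(key, 0)
        indeterminate = entry["effect"] is None or entry["gerp"] is None
        if indeterminate:
            n_indeterminate += 1
        p_eff = (not indeterminate) and entry["effect"] > thresholds.tau_effect
        p_cons = (not indeterminate) and entry["gerp"] > thresholds.tau_cons
        p_cancer = bool(entry["genes"] & cancer)
        p_rec = rec_count >= 2
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "gene": sorted(entry["genes"])[0],
                "recurrence_count": rec_count,
                "passed_recurrence": p_rec,
                "passed_conservation": p_cons,
                "passed_effect": p_eff,
                "passed_cancer_gene": p_cancer,
                "indeterminate": indeterminate,
                "is_proposed_driver": p_rec and p_cons and p_eff and p_cancer
                and not indeterminate,
            }
        )
    if n_indeterminate:
        logger.warning(
            "apply_driver_filters: %d keys with missing scores excluded from drivers",
            n_indeterminate,
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene",
            "recurrence_count",
            "passed_recurrence",
            "passed_conservation",
            "passed_effect",
            "passed_cancer_gene",
            "indeterminate",
            "is_proposed_driver",
        ],
    )
    log = {
        "n_keys": len(table),
        "after_recurrence": int(table["passed_recurrence"].sum()),
        "after_recurrence_conservation": int(
            (table["passed_recurrence"] & table["passed_conservation"]).sum()
        ),
        "after_recurrence_conservation_effect": int(
            (
                table["passed_recurrence"]
                & table["passed_conservation"]
                & table["passed_effect"]
            ).sum()
        ),
        "proposed_drivers": int(table["is_proposed_driver"].sum()),
        "indeterminate": n_indeterminate,
    }
    genes = classify_gene_groups(variants, thresholds)
    return ScreenResult(variants=table, genes=genes, log=log)


def classify_gene_groups(
    variants: list[VariantRecord],
    thresholds: ThresholdSet,
    recurrence: dict[Key, int] | None = None,
    count_unique: bool = True,
) -> pd.DataFrame:
    """Stratify genes by the deepest cumulative variant filter they satisfy.

    Group 2 requires >= 1 recurrent sSNV; group 3 additionally conserved
    (strictly above tau_cons); group 4 additionally high effect (strictly
    above tau_effect).  Groups are nested by construction; group 1 is the
    complement of group 2 (genes with non-recurrent sSNVs only).  Only
    synonymous variants participate.

    Returns one row per gene: group plus per-filter passing-variant counts
    (``n_total, n_recurrent, n_recurrent_conserved,
    n_recurrent_conserved_effect``), counting distinct genomic keys by
    default (``count_unique=False`` counts observation rows).
    """
    syn = [v for v in variants if v.consequence == "synonymous"]
    if recurrence is None:
        recurrence = tag_recurrent(syn)
    per_gene: dict[str, dict[str, set | int]] = {}
    for v in syn:
        g = per_gene.setdefault(
            v.gene, {"total": set(), "g2": set(), "g3": set(), "g4": set()}
        )
        token = v.key if count_unique else (v.key, id(v))
        g["total"].add(token)
        rec = recurrence.get(v.key, 0) >= 2
        eff = v.scores.get("effect_score")
        cons = v.scores.get("gerp")
        if rec:
            g["g2"].add(token)
            if cons is not None and cons > thresholds.tau_cons:
                g["g3"].add(token)
                if eff is not None and eff > thresholds.tau_effect:
                    g["g4"].add(token)
    rows = []
    for gene in sorted(per_gene):
        g = per_gene[gene]
        n2, n3, n4 = len(g["g2"]), len(g["g3"]), len(g["g4"])
        group = 1
        if n4:
            group = 4
        elif n3:
            group = 3
        elif n2:
            group = 2
        rows.append(
            {
                "gene": gene,
                "group": group,
                "n_total": len(g["total"]),
                "n_recurrent": n2,
                "n_recurrent_conserved": n3,
                "n_recurrent_conserved_effect": n4,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "group",
            "n_total",
            "n_recurrent",
            "n_recurrent_conserved",
            "n_recurrent_conserved_effect",
        ],
    )


def percentile_select(counts, x: float) -> list[str]:
    """Genes whose passing-variant count is strictly above the x-th percentile.

    The percentile is computed by linear interpolation between order
    statistics.  Example: counts (1,1,2,2,3,3,3,3,8,9) at x = 70 give a
    percentile value of 3, so the genes with 8 and 9 variants are selected.
    """
    if isinstance(counts, dict):
        counts = pd.Series(counts)
    if len(counts) == 0:
        raise ValueError("counts are empty")
    if not 0 <= x < 100:
        raise ValueError(f"percentile must be in [0, 100), got {x}")
    cut = float(np.percentile(counts.to_numpy(dtype=float), x))
    return sorted(counts.index[counts > cut].tolist())


def cancer_fraction(
    selected: "list[str] | set[str]", gene_sets: GeneSetCollection
) -> dict[str, float]:
    """Fraction of selected genes in each cancer set and in their union."""
    selected = set(selected)
    if not selected:
        raise ValueError("selection is empty")
    out = {
        name: len(selected & members) / len(selected)
        for name, members in gene_sets.sets.items()
    }
    out["union"] = len(selected & gene_sets.union()) / len(selected)
    return out


def exclude_population_observed(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Drop variants observed in the general population (pop_freq > 0)."""
    return [v for v in variants if v.scores.get("pop_freq", 0.0) == 0.0]
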