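"""Functional-mechanism annotation of proposed driver sSNVs.

Synonymous drivers can act through (at least) three post-transcriptional
channels: disrupting splicing regulation, changing mRNA secondary structure,
or destroying an RNA-binding-protein motif.  This module turns per-variant
annotation scores into boolean mechanism calls, aggregates transcript-level
rows onto genomic keys (a key is called if ANY of its transcripts is), and
tabulates the three-set Venn with pairwise hypergeometric overlap tests.

Decision rules (strict inequalities throughout):

* splicing: CADD-splice > 15 OR any of the four splice-site deltas
  (acceptor gain/loss, donor gain/loss) > 0.5;
* structure: structure-change p-value < alpha (default 0.2, the documented
  convention of the structure predictor);
* RBP: the variant's transcript position falls inside a significant motif
  occurrence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]

DEFAULT_STRUCTURE_ALPHA = 0.2
DEFAULT_CADD_CUT = 15.0
DEFAULT_SPLICEAI_CUT = 0.5

_SPLICEAI_COLS = ("spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl")


@dataclass
class MechanismCall:
    """Mechanism flags for one genomic variant key."""

    key: Key
    splicing: bool
    structure: bool
    rbp: bool
    support: dict = field(default_factory=dict)

    @property
    def any_mechanism(self) -> bool:
        return self.splicing or self.structure or self.rbp


def call_splicing(
    cadd_splice: float | None,
    spliceai_deltas,
    cadd_cut: float = DEFAULT_CADD_CUT,
    spliceai_cut: float = DEFAULT_SPLICEAI_CUT,
) -> bool | None:
    """Splicing-disruption call from CADD-splice and splice-delta scores.

    True iff CADD-splice strictly exceeds ``cadd_cut`` or any of the four
    deltas strictly exceeds ``spliceai_cut``.  A missing annotation family
    does not contribute; both missing -> None (indeterminate).
    """
    deltas = None if spliceai_deltas is None else [d for d in spliceai_deltas if d is not None]
    if cadd_splice is None and not deltas:
        return None
    hit = False
    if cadd_splice is not None:
        hit = cadd_splice > cadd_cut
    if deltas:
        hit = hit or max(deltas) > spliceai_cut
    return hit


def select_rnasnp_mode(spliced_length: int) -> str:
    """Folding mode for the structure predictor: mode1 below 200 nt, else mode2."""
    if spliced_length < 1:
        raise ValueError(f"spliced length must be >= 1, got {spliced_length}")
    return "mode1" if spliced_length < 200 else "mode2"


def call_structure(
    structure_p: float | None, alpha: float = DEFAULT_STRUCTURE_ALPHA
) -> bool | None:
    """Structure-change call: p strictly below alpha; missing p -> None."""
    if structure_p is None:
        return None
    if not 0.0 <= structure_p <= 1.0:
        raise ValueError(f"structure_p={structure_p} outside [0, 1]")
    return structure_p < alpha


def annotate_mechanisms(
    driver_variants: list[VariantRecord],
    motif_overlap: dict | None = None,
    alpha: float = DEFAULT_STRUCTURE_ALPHA,
    cadd_cut: float = DEFAULT_CADD_CUT,
    spliceai_cut: float = DEFAULT_SPLICEAI_CUT,
) -> tuple[list[MechanismCall], pd.DataFrame]:
    """Mechanism calls for proposed drivers, at both accounting levels.

    ``driver_variants`` are the transcript-level rows of the proposed
    drivers; ``motif_overlap`` maps ``(chrom, pos, ref, alt, transcript)``
    to ``(flag, motif_ids)`` as produced by
    :func:`syndriver.motif_scan.variant_motif_overlap`.

    Transcript rows are evaluated individually (second return value, one row
    each); a genomic key's flag is the OR over its transcript rows, with
    indeterminate rows non-contributing.  Keys indeterminate on all three
    mechanisms are excluded from the calls and logged.
    """
    motif_overlap = motif_overlap or {}
    tx_rows = []
    per_key: dict[Key, dict] = {}
    for v in driver_variants:
        spl = call_splicing(
            v.scores.get("cadd_splice"),
            [v.scores.get(c) for c in _SPLICEAI_COLS],
            cadd_cut,
            spliceai_cut,
        )
        strc = call_structure(v.scores.get("structure_p"), alpha)
        rbp_flag, motif_ids = motif_overlap.get(
            (v.chrom, v.pos, v.ref, v.alt, v.transcript), (None, [])
        )
        tx_rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "transcript": v.transcript,
                "splicing": spl,
                "structure": strc,
                "rbp": rbp_flag,
                "motif_ids": ",".join(motif_ids),
            }
        )
        entry = per_key.setdefault(
            v.key,
            {"splicing": None, "structure": None, "rbp": None, "support": {"motif_ids": set()}},
        )
        for name, val in (("splicing", spl), ("structure", strc), ("rbp", rbp_flag)):
            if val is not None:
                entry[name] = bool(entry[name]) or val
        entry["support"]["motif_ids"] |= set(motif_ids)
        for col in ("cadd_splice", "structure_p", *_SPLICEAI_COLS):
            if col in v.scores:
                prev = entry["support"].get(col)
                val = v.scores[col]
                if col == "structure_p":
                    entry["support"][col] = val if prev is None else min(prev, val)
                else:
                    entry["support"][col] = val if prev is None else max(prev, val)
    calls: list[MechanismCall] = []
    n_excluded = 0
    for key in sorted(per_key):
        entry = per_key[key]
        if entry["splicing"] is None and entry["structure"] is None and entry["rbp"] is None:
            n_excluded += 1
            continue
        support = dict(entry["support"])
        support["motif_ids"] = sorted(support["motif_ids"])
        calls.append(
            MechanismCall(
                key=key,
                splicing=bool(entry["splicing"]),
                structure=bool(entry["structure"]),
                rbp=bool(entry["rbp"]),
                support=support,
            )
        )
    if n_excluded:
        logger.warning(
            "annotate_mechanisms: %d keys with all annotations missing excluded",
            n_excluded,
        )
    tx_table = pd.DataFrame(
        tx_rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "transcript",
            "splicing",
            "structure",
            "rbp",
            "motif_ids",
        ],
    )
    return calls, tx_table


_REGIONS = (
    "splicing_only",
    "structure_only",
    "rbp_only",
    "splicing_structure",
    "splicing_rbp",
    "structure_rbp",
    "all_three",
)


def venn_counts(calls: list[MechanismCall]) -> dict[str, int]:
    """The seven regions of the splicing/structure/RBP Venn plus the union."""
    if not calls:
        raise ValueError("no mechanism calls")
    counts = dict.fromkeys(_REGIONS, 0)
    union = 0
    for c in calls:
        s, t, r = c.splicing, c.structure, c.rbp
        if not (s or t or r):
            continue
        union += 1
        if s and t and r:
            counts["all_three"] += 1
        elif s and t:
            counts["splicing_structure"] += 1
        elif s and r:
            counts["splicing_rbp"] += 1
        elif t and r:
            counts["structure_rbp"] += 1
        elif s:
            counts["splicing_only"] += 1
        elif t:
            counts["structure_only"] += 1
        else:
            counts["rbp_only"] += 1
    counts["union"] = union
    return counts


def pairwise_overlap_test(set_a: set, set_b: set, universe_size: int) -> float:
    """Upper-tail hypergeometric p of the observed overlap of two variant sets.

    P(overlap >= observed) when |B| items are drawn from a universe of
    ``universe_size`` containing |A| marked items.
    """
    a, b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    if a > universe_size or b > universe_size:
        raise ValueError("set larger than the universe")
    return float(min(stats.hypergeom.sf(k - 1, universe_size, a, b), 1.0))


def mechanism_overlap_tests(
    calls: list[MechanismCall], universe_size: int | None = None
) -> pd.DataFrame:
    """Pairwise hypergeometric overlap tests among the three mechanism sets.

    ``universe_size`` defaults to the number of calls (the annotated
    proposed-driver keys).
    """
    sets = {
        "splicing": {c.key for c in calls if c.splicing},
        "structure": {c.key for c in calls if c.structure},
        "rbp": {c.key for c in calls if c.rbp},
    }
    n = universe_size if universe_size is not None else len(calls)
    rows = []
    for a, b in itertools.combinations(sets, 2):
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "size_a": len(sets[a]),
                "size_b": len(sets[b]),
                "overlap": len(sets[a] & sets[b]),
                "universe": n,
                "pvalue": pairwise_overlap_test(sets[a], sets[b], n),
            }
        )
    return pd.DataFrame(
        rows, columns=["set_a", "set_b", "size_a", "size_b", "overlap", "universe", "pvalue"]
    )
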