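"""End-to-end composition of the screen: variants in, annotated drivers out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import driver_screen, mechanism_annotation, motif_scan
from .driver_screen import ScreenResult, ThresholdSet
from .mechanism_annotation import MechanismCall
from .variant_io import GeneSetCollection, VariantRecord


@dataclass
class ScreenOutcome:
    """Everything the full screen produces on one cohort."""

    thresholds: ThresholdSet
    screen: ScreenResult
    proposed_keys: set[tuple[str, int, str, str]]
    mechanism_calls: list[MechanismCall]
    mechanism_tx_table: pd.DataFrame
    venn: dict[str, int] | None
    overlap_tests: pd.DataFrame | None


def run_full_screen(
    variants: list[VariantRecord],
    gene_sets: GeneSetCollection,
    transcripts: dict[str, str] | None = None,
    motifs: list | None = None,
    thresholds: ThresholdSet | None = None,
    reference_percentile: float = 95.0,
    structure_alpha: float = mechanism_annotation.DEFAULT_STRUCTURE_ALPHA,
    cadd_cut: float = mechanism_annotation.DEFAULT_CADD_CUT,
    spliceai_cut: float = mechanism_annotation.DEFAULT_SPLICEAI_CUT,
    motif_p_threshold: float = motif_scan.DEFAULT_P_THRESHOLD,
) -> ScreenOutcome:
    """Run reference selection, the four-filter screen, and mechanism calls.

    The reference set is the putative-driver category of ``variants`` unless
    explicit ``thresholds`` are given.  Only synonymous somatic-cancer rows
    enter the screen.  Motif overlap is computed when transcripts and motifs
    are supplied, scanning only the transcripts of proposed drivers.
    """
    if thresholds is None:
        reference = driver_screen.select_reference_set(
            [v for v in variants if v.category == "putative_driver"],
            reference_percentile,
        )
        thresholds = driver_screen.derive_thresholds(reference)
    somatic = [
        v
        for v in variants
        if v.category == "somatic_cancer" and v.consequence == "synonymous"
    ]
    screen = driver_screen.apply_driver_filters(somatic, thresholds, gene_sets)
    flagged = screen.variants[screen.variants["is_proposed_driver"]]
    proposed_keys = {
        (r.chrom, r.pos, r.ref, r.alt) for r in flagged.itertuples()
    }
    driver_rows = [v for v in somatic if v.key in proposed_keys]
    overlap = None
    if transcripts is not None and motifs:
        needed = {v.transcript for v in driver_rows}
        hits = motif_scan.scan_transcripts(
            {tx: transcripts[tx] for tx in sorted(needed) if tx in transcripts},
            motifs,
            motif_p_threshold,
        )
        overlap = motif_scan.variant_motif_overlap(driver_rows, hits)
    calls, tx_table = mechanism_annotation.annotate_mechanisms(
        driver_rows, overlap, alpha=structure_alpha, cadd_cut=cadd_cut,
        spliceai_cut=spliceai_cut,
    )
    venn = mechanism_annotation.venn_counts(calls) if calls else None
    tests = mechanism_annotation.mechanism_overlap_tests(calls) if calls else None
    return ScreenOutcome(
        thresholds=thresholds,
        screen=screen,
        proposed_keys=proposed_keys,
        mechanism_calls=calls,
        mechanism_tx_table=tx_table,
        venn=venn,
        overlap_tests=tests,
    )
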