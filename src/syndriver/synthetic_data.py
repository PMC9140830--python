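"""Ground-truth-labeled synthetic cohorts for exercising the whole pipeline.

The generator emulates the four-category study design — germline sSNVs,
somatic sSNVs in normal tissue, somatic sSNVs in cancer tissue, and a
putative-driver reference set — with category-shifted score distributions,
per-patient recurrence structure, and a configurable number of *planted*
driver variants inside designated cancer genes.  Planted drivers satisfy all
four screening criteria by construction (their scores are sampled from the
driver distributions truncated above the reference-derived thresholds), and
their functional-mechanism labels are planted jointly with the annotation
values, so screening recall and mechanism recovery have an exact truth to
compare against.

Default score distributions (chosen so that category medians respect the
observed ordering driver > somatic-normal > somatic-cancer with a wide
margin; no parametric forms are prescribed by the screening procedure
itself):

===============  ================  ==============  =================
category         effect score      conservation    observed-in-popn
===============  ================  ==============  =================
putative driver  Beta(8, 2)        Normal(4, 1)    0.00
somatic normal   Beta(3, 3)        Normal(0, 2)    0.20
somatic cancer   Beta(2, 5)        Normal(0, 2)    0.10
germline         Beta(2, 4)        Normal(0, 2)    0.95
===============  ================  ==============  =================
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import driver_screen, motif_scan, variant_io
from .motif_scan import MotifPWM
from .variant_io import GeneModel, GeneSetCollection, VariantRecord

Key = tuple[str, int, str, str]

_TISSUES = ("skin", "large_intestine", "lung", "liver", "breast", "ovary")


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 300
    n_cancer_genes: int = 40
    cds_length_range: tuple[int, int] = (90, 3000)
    n_patients: int = 200
    # per-category variant counts (distinct genomic keys)
    n_germline: int = 2000
    n_somatic_normal: int = 1000
    n_somatic_cancer: int = 5000  # background, excluding planted drivers
    n_putative_driver: int = 500
    n_missense: int = 5000
    n_planted_drivers: int = 50
    # recurrence structure
    min_driver_patients: int = 3
    max_driver_patients: int = 6
    background_recurrent_fraction: float = 0.1
    # score distributions per category
    effect_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "germline": (2.0, 4.0),
            "somatic_normal": (3.0, 3.0),
            "somatic_cancer": (2.0, 5.0),
            "putative_driver": (8.0, 2.0),
        }
    )
    gerp_normal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "germline": (0.0, 2.0),
            "somatic_normal": (0.0, 2.0),
            "somatic_cancer": (0.0, 2.0),
            "putative_driver": (4.0, 1.0),
        }
    )
    pop_observed_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "germline": 0.95,
            "somatic_normal": 0.2,
            "somatic_cancer": 0.1,
            "putative_driver": 0.0,
        }
    )
    # mechanism planting probabilities per planted driver
    p_splicing: float = 0.4
    p_structure: float = 0.35
    p_rbp: float = 0.35
    # annotation thresholds the planted labels are generated against
    structure_alpha: float = 0.2
    cadd_cut: float = 15.0
    spliceai_cut: float = 0.5
    motif_p_threshold: float = 1e-4
    # motif set
    n_motifs: int = 5
    motif_width_range: tuple[int, int] = (5, 7)
    # burden structure
    n_burden_boost_genes: int = 10
    burden_multiplier: float = 2.0
    missense_cancer_multiplier: float = 3.0
    reference_percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.n_cancer_genes > self.n_genes:
            raise ValueError("n_cancer_genes exceeds n_genes")
        if self.n_planted_drivers > self.n_somatic_cancer:
            raise ValueError("more planted drivers than somatic-cancer variants")
        for count in (
            self.n_germline,
            self.n_somatic_normal,
            self.n_somatic_cancer,
            self.n_putative_driver,
            self.n_missense,
            self.n_planted_drivers,
        ):
            if count < 0:
                raise ValueError("counts must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    driver_keys: set[Key]
    mechanism_labels: dict[Key, dict[str, bool]]
    cancer_genes: frozenset[str]
    burden_multipliers: dict[str, float]
    thresholds: driver_screen.ThresholdSet


@dataclass
class Cohort:
    """A complete generated input bundle plus its ground truth."""

    variants: list[VariantRecord]
    gene_models: list[GeneModel]
    gene_sets: GeneSetCollection
    transcripts: dict[str, str]
    motifs: list[MotifPWM]
    motif_registry: list[tuple[str, int, str]]
    truth: GroundTruth
    config: CohortConfig

    def write(self, outdir) -> None:
        """Write all inputs in the formats the io layer reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        variant_io.write_variant_table(self.variants, out / "variants.tsv")
        variant_io.write_gene_models(self.gene_models, out / "gene_models.tsv")
        variant_io.write_gene_sets_gmt(self.gene_sets, out / "gene_sets.gmt")
        variant_io.write_fasta(self.transcripts, out / "transcripts.fa")
        variant_io.write_meme_motifs(self.motifs, out / "motifs.meme")


def _random_pwm(rng: np.random.Generator, motif_id: str, width: int) -> MotifPWM:
    """A sharp PWM: one dominant letter (p=0.85) per position."""
    probs = np.full((width, 4), 0.05)
    dominant = rng.integers(0, 4, size=width)
    probs[np.arange(width), dominant] = 0.85
    return MotifPWM(motif_id=motif_id, probs=probs)


def _consensus_pvalue(pwm: MotifPWM) -> float:
    lom = motif_scan.log_odds_matrix(pwm)
    dist = motif_scan.score_pvalues(lom, pwm.background)
    best = int(dist.scaled.max(axis=1).sum())
    return dist.pvalue(best)


def _truncated(draw, lower: float, rng_budget: int = 10000) -> float:
    """Rejection-sample ``draw()`` until strictly above ``lower``."""
    for _ in range(rng_budget):
        x = draw()
        if x > lower:
            return x
    raise RuntimeError(f"could not sample above {lower}; distribution too far below")


def plant_motif_instances(
    transcripts: dict[str, str],
    motifs: list[MotifPWM],
    rate: float,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Write motif consensus sequences into random transcript positions.

    Each transcript receives one instance with probability ``rate``.  The
    registry records ``(transcript, start, motif_id)`` with 1-based starts.
    ``rate=0`` returns the transcripts unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = dict(transcripts)
    registry: list[tuple[str, int, str]] = []
    if rate <= 0 or not motifs:
        return out, registry
    for tx_id in sorted(out):
        if rng.random() >= rate:
            continue
        pwm = motifs[int(rng.integers(0, len(motifs)))]
        seq = out[tx_id]
        if len(seq) < pwm.width:
            continue
        start0 = int(rng.integers(0, len(seq) - pwm.width + 1))
        consensus = pwm.consensus()
        out[tx_id] = seq[:start0] + consensus + seq[start0 + pwm.width :]
        registry.append((tx_id, start0 + 1, pwm.motif_id))
    return out, registry


def make_worked_example() -> dict[str, int]:
    """Ten dummy genes carrying 1, 1, 2, 2, 3, 3, 3, 3, 8 and 9 sSNVs."""
    counts = (1, 1, 2, 2, 3, 3, 3, 3, 8, 9)
    return {f"WG{i + 1:02d}": c for i, c in enumerate(counts)}


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a fully labeled cohort; reproducible given the seed.

    Planted drivers are guaranteed to pass all four screening criteria at
    the thresholds derived from the generated putative-driver reference set,
    and mechanism annotation values are drawn on the side of the default
    thresholds dictated by the planted labels.  Reference bases of every
    variant match the (motif-planted) transcript FASTA at ``tx_pos``.
    """
    if config is None:
        config = CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    # --- genes, transcripts, gene sets -----------------------------------
    lo, hi = config.cds_length_range
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    cds_lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    utr = rng.integers(30, 301, size=config.n_genes)
    tx_names = [f"T{i + 1:04d}" for i in range(config.n_genes)]
    tx_lengths = cds_lengths + utr
    gene_models = [
        GeneModel(gene=g, cds_length=int(c), transcripts=[(t, int(ln))])
        for g, c, t, ln in zip(gene_names, cds_lengths, tx_names, tx_lengths)
    ]
    tx_of_gene = dict(zip(gene_names, tx_names))
    gene_index = {g: i for i, g in enumerate(gene_names)}

    cancer_idx = rng.choice(config.n_genes, size=config.n_cancer_genes, replace=False)
    cancer_genes = frozenset(gene_names[i] for i in cancer_idx)
    cancer_sorted = sorted(cancer_genes)
    two_thirds = max(1, math.ceil(2 * len(cancer_sorted) / 3))
    gene_sets = GeneSetCollection(
        sets={
            "cancer_census": frozenset(cancer_sorted[:two_thirds]),
            "cancer_pathway": frozenset(cancer_sorted[-two_thirds:]),
        },
        universe=frozenset(gene_names),
    )

    transcripts = {
        t: "".join(rng.choice(list("ACGT"), size=int(ln)))
        for t, ln in zip(tx_names, tx_lengths)
    }

    # --- motifs -----------------------------------------------------------
    wlo, whi = config.motif_width_range
    widths = [whi] + [int(rng.integers(wlo, whi + 1)) for _ in range(config.n_motifs - 1)]
    motifs = [_random_pwm(rng, f"RBP_{i + 1}", w) for i, w in enumerate(widths)]
    plantable = [m for m in motifs if _consensus_pvalue(m) < config.motif_p_threshold]
    if config.n_planted_drivers and config.p_rbp > 0 and not plantable:
        raise RuntimeError("no motif sharp enough to plant recoverable instances")

    # --- driver placement: decide keys and plant motif instances first ---
    driver_meta = []
    used_positions: set[tuple[str, int]] = set()
    for d in range(config.n_planted_drivers):
        gene = cancer_sorted[int(rng.integers(0, len(cancer_sorted)))]
        labels = {
            "splicing": bool(rng.random() < config.p_splicing),
            "structure": bool(rng.random() < config.p_structure),
            "rbp": bool(rng.random() < config.p_rbp),
        }
        driver_meta.append({"gene": gene, "labels": labels})

    motif_registry: list[tuple[str, int, str]] = []
    for meta in driver_meta:
        if not meta["labels"]["rbp"]:
            continue
        tx = tx_of_gene[meta["gene"]]
        pwm = plantable[int(rng.integers(0, len(plantable)))]
        seq = transcripts[tx]
        start0 = int(rng.integers(0, len(seq) - pwm.width + 1))
        transcripts[tx] = seq[:start0] + pwm.consensus() + seq[start0 + pwm.width :]
        motif_registry.append((tx, start0 + 1, pwm.motif_id))
        meta["instance"] = (start0 + 1, pwm.width)

    # hits on driver transcripts, for placing rbp-negative drivers off-motif
    driver_txs = sorted({tx_of_gene[m["gene"]] for m in driver_meta})
    hits_by_tx: dict[str, list] = {tx: [] for tx in driver_txs}
    for tx in driver_txs:
        for pwm in motifs:
            hits_by_tx[tx].extend(
                motif_scan.scan_transcript(
                    transcripts[tx], pwm, config.motif_p_threshold, "sense_only", tx
                )
            )

    # --- helpers ----------------------------------------------------------
    patients = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    chrom = "1"

    def genomic_pos(gene: str, tx_pos: int) -> int:
        return gene_index[gene] * 100_000 + tx_pos

    def new_position(gene: str, forbidden=None) -> int:
        """A fresh tx_pos on the gene's transcript, outside forbidden intervals."""
        tx = tx_of_gene[gene]
        length = len(transcripts[tx])
        for _ in range(10000):
            tx_pos = int(rng.integers(1, length + 1))
            if (tx, tx_pos) in used_positions:
                continue
            if forbidden and any(a <= tx_pos <= b for a, b in forbidden):
                continue
            used_positions.add((tx, tx_pos))
            return tx_pos
        raise RuntimeError(f"could not place a variant on {tx}")

    def alleles(gene: str, tx_pos: int) -> tuple[str, str]:
        tx = tx_of_gene[gene]
        ref = transcripts[tx][tx_pos - 1]
        others = [b for b in "ACGT" if b != ref]
        return ref, others[int(rng.integers(0, 3))]

    def beta(category: str) -> float:
        a, b = config.effect_beta[category]
        return float(rng.beta(a, b))

    def gerp(category: str) -> float:
        m, s = config.gerp_normal[category]
        return float(rng.normal(m, s))

    def pop_freq(category: str) -> float:
        if rng.random() < config.pop_observed_fraction[category]:
            return float(rng.uniform(1e-4, 0.05))
        return 0.0

    def background_annotations() -> dict[str, float]:
        """Splicing/structure annotations on the non-disruptive side."""
        out = {
            "cadd_splice": float(rng.uniform(0, config.cadd_cut - 1.0)),
            "structure_p": float(
                rng.uniform(min(config.structure_alpha + 0.05, 1.0), 1.0)
            ),
        }
        for c in ("spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl"):
            out[c] = float(rng.uniform(0, config.spliceai_cut - 0.05))
        return out

    def pick_gene(weights: np.ndarray) -> str:
        return gene_names[int(rng.choice(config.n_genes, p=weights))]

    base_w = cds_lengths.astype(float)
    burden_mult = np.ones(config.n_genes)
    boost_idx = rng.choice(config.n_genes, size=config.n_burden_boost_genes, replace=False)
    burden_mult[boost_idx] = config.burden_multiplier
    burden_multipliers = {gene_names[i]: float(burden_mult[i]) for i in boost_idx}
    w_plain = base_w / base_w.sum()
    w_boosted = base_w * burden_mult
    w_boosted /= w_boosted.sum()
    mis_mult = np.ones(config.n_genes)
    mis_mult[cancer_idx] = config.missense_cancer_multiplier
    w_missense = base_w * mis_mult
    w_missense /= w_missense.sum()

    variants: list[VariantRecord] = []

    def emit_background(category: str, n: int, weights: np.ndarray, consequence: str) -> None:
        for _ in range(n):
            gene = pick_gene(weights)
            tx_pos = new_position(gene)
            ref, alt = alleles(gene, tx_pos)
            scores = {
                "effect_score": beta(category),
                "gerp": gerp(category),
                "pop_freq": pop_freq(category),
            }
            if category == "putative_driver":
                scores["synmicdb_score"] = float(rng.uniform(0, 100))
            if category == "somatic_cancer" and consequence == "synonymous":
                scores.update(background_annotations())
            key_rows = 1
            if (
                category == "somatic_cancer"
                and consequence == "synonymous"
                and rng.random() < config.background_recurrent_fraction
            ):
                key_rows = int(rng.integers(2, 4))
            chosen = rng.choice(
                config.n_patients, size=min(key_rows, config.n_patients), replace=False
            )
            tissue = _TISSUES[int(rng.integers(0, len(_TISSUES)))]
            for pidx in chosen:
                variants.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=genomic_pos(gene, tx_pos),
                        ref=ref,
                        alt=alt,
                        gene=gene,
                        transcript=tx_of_gene[gene],
                        patient_id=patients[int(pidx)],
                        tx_pos=tx_pos,
                        tissue=tissue,
                        category=category,
                        consequence=consequence,
                        scores=dict(scores),
                    )
                )

    emit_background("germline", config.n_germline, w_plain, "synonymous")
    emit_background("somatic_normal", config.n_somatic_normal, w_plain, "synonymous")
    emit_background("putative_driver", config.n_putative_driver, w_plain, "synonymous")
    emit_background("somatic_cancer", config.n_somatic_cancer, w_boosted, "synonymous")
    emit_background("somatic_cancer", config.n_missense, w_missense, "missense")

    # --- thresholds from the generated reference set ----------------------
    reference_pool = [v for v in variants if v.category == "putative_driver"]
    thresholds = driver_screen.derive_thresholds(
        driver_screen.select_reference_set(reference_pool, config.reference_percentile)
    )

    # --- planted drivers --------------------------------------------------
    driver_keys: set[Key] = set()
    mechanism_labels: dict[Key, dict[str, bool]] = {}
    for meta in driver_meta:
        gene = meta["gene"]
        tx = tx_of_gene[gene]
        labels = meta["labels"]
        if labels["rbp"]:
            start, width = meta["instance"]
            # inside the planted occurrence (guaranteed covered by a hit)
            tx_pos = int(rng.integers(start, start + width))
            used_positions.add((tx, tx_pos))
        else:
            forbidden = [(h.start, h.end) for h in hits_by_tx[tx]]
            tx_pos = new_position(gene, forbidden)
        ref, alt = alleles(gene, tx_pos)
        scores: dict[str, float] = {
            "effect_score": _truncated(
                lambda: beta("putative_driver"), thresholds.tau_effect
            ),
            "gerp": _truncated(lambda: gerp("putative_driver"), thresholds.tau_cons),
            "pop_freq": 0.0,
        }
        if labels["splicing"]:
            route = rng.random()
            if route < 0.5:
                scores["cadd_splice"] = float(rng.uniform(config.cadd_cut + 0.5, 40.0))
                for c in ("spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl"):
                    scores[c] = float(rng.uniform(0, config.spliceai_cut - 0.05))
            else:
                scores["cadd_splice"] = float(rng.uniform(0, config.cadd_cut - 1.0))
                deltas = [float(rng.uniform(0, config.spliceai_cut - 0.05)) for _ in range(4)]
                deltas[int(rng.integers(0, 4))] = float(
                    rng.uniform(config.spliceai_cut + 0.05, 1.0)
                )
                for c, d in zip(
                    ("spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl"), deltas
                ):
                    scores[c] = d
        else:
            scores["cadd_splice"] = float(rng.uniform(0, config.cadd_cut - 1.0))
            for c in ("spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl"):
                scores[c] = float(rng.uniform(0, config.spliceai_cut - 0.05))
        if labels["structure"]:
            scores["structure_p"] = float(
                rng.uniform(0, max(config.structure_alpha - 0.01, 1e-6))
            )
        else:
            scores["structure_p"] = float(
                rng.uniform(min(config.structure_alpha + 0.01, 1.0), 1.0)
            )
        n_pat = int(
            rng.integers(config.min_driver_patients, config.max_driver_patients + 1)
        )
        chosen = rng.choice(config.n_patients, size=n_pat, replace=False)
        tissue = _TISSUES[int(rng.integers(0, len(_TISSUES)))]
        key = (chrom, genomic_pos(gene, tx_pos), ref, alt)
        driver_keys.add(key)
        mechanism_labels[key] = dict(labels)
        for pidx in chosen:
            variants.append(
                VariantRecord(
                    chrom=chrom,
                    pos=key[1],
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    transcript=tx,
                    patient_id=patients[int(pidx)],
                    tx_pos=tx_pos,
                    tissue=tissue,
                    category="somatic_cancer",
                    consequence="synonymous",
                    scores=dict(scores),
                )
            )

    truth = GroundTruth(
        driver_keys=driver_keys,
        mechanism_labels=mechanism_labels,
        cancer_genes=cancer_genes,
        burden_multipliers=burden_multipliers,
        thresholds=thresholds,
    )
    return Cohort(
        variants=variants,
        gene_models=gene_models,
        gene_sets=gene_sets,
        transcripts=transcripts,
        motifs=motifs,
        motif_registry=motif_registry,
        truth=truth,
        config=config,
    )
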