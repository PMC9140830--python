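"""Readers and writers for every external format the pipeline touches.

Conventions used throughout:

* genomic and transcript coordinates are 1-based and fully closed (VCF-style);
* the identity of a variant is its genomic key ``(chrom, pos, ref, alt)``;
  transcript-level rows are a one-to-many expansion of that key;
* unknown per-variant score columns are carried through untouched in the open
  ``scores`` map, so new annotators can be plugged in without code changes.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_scan import MotifPWM

logger = logging.getLogger(__name__)

CATEGORIES = ("germline", "somatic_normal", "somatic_cancer", "putative_driver")
CONSEQUENCES = ("synonymous", "missense", "other")

#: score columns with a bounded domain, validated on construction
_UNIT_INTERVAL_SCORES = ("pop_freq", "effect_score", "structure_p")

#: registry of well-known score columns (any other numeric column is also kept)
KNOWN_SCORES = (
    "effect_score",
    "gerp",
    "pop_freq",
    "cadd_splice",
    "spliceai_ag",
    "spliceai_al",
    "spliceai_dg",
    "spliceai_dl",
    "structure_p",
    "synmicdb_score",
)

_GENERIC_MANDATORY = ("chrom", "pos", "ref", "alt", "gene", "transcript", "patient_id")
_GENERIC_OPTIONAL = (
    "tx_pos",
    "tissue",
    "category",
    "consequence",
    "somatic_status",
    "description",
)
_COSMIC_MANDATORY = (
    "Gene name",
    "Accession Number",
    "ID_sample",
    "Primary site",
    "Mutation CDS",
    "Mutation Description",
    "Mutation somatic status",
    "Mutation genome position",
)

_BASES = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One SNV observation (one patient, one transcript context)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    patient_id: str
    tx_pos: int | None = None
    tissue: str = ""
    category: str = "somatic_cancer"
    consequence: str = "synonymous"
    scores: dict[str, float] = field(default_factory=dict)
    somatic_status: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        self.ref = str(self.ref).upper()
        self.alt = str(self.alt).upper()
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"alleles must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.tx_pos is not None:
            self.tx_pos = int(self.tx_pos)
            if self.tx_pos < 1:
                raise ValueError(f"tx_pos must be >= 1, got {self.tx_pos}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for name in _UNIT_INTERVAL_SCORES:
            val = self.scores.get(name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity of the variant."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    """A gene with its coding length and member transcripts.

    ``cds_length`` normalizes per-gene mutation burden; transcript spliced
    lengths drive the RNA-structure mode rule (mode 1 below 200 nt).
    """

    gene: str
    cds_length: int
    transcripts: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"gene {self.gene}: cds_length must be > 0")
        for tx, ln in self.transcripts:
            if ln <= 0:
                raise ValueError(f"gene {self.gene}, transcript {tx}: length must be > 0")

    def spliced_length(self, transcript: str) -> int:
        for tx, ln in self.transcripts:
            if tx == transcript:
                return ln
        raise KeyError(f"transcript {transcript} not in gene {self.gene}")


@dataclass
class GeneSetCollection:
    """Named gene sets (cancer census, pathways, ontologies) plus an optional universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(self.universe)
            for name, members in self.sets.items():
                stray = members - self.universe
                if stray:
                    raise ValueError(
                        f"set {name!r} has members outside the universe: "
                        f"{sorted(stray)[:5]}"
                    )

    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for members in self.sets.values():
            out |= members
        return out


# ---------------------------------------------------------------------------
# variant tables


def _row_scores(row: pd.Series, score_cols: list[str]) -> dict[str, float]:
    out = {}
    for col in score_cols:
        val = row[col]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            continue
        out[col] = float(val)
    return out


def read_variant_table(path, dialect: str = "generic_tsv") -> list[VariantRecord]:
    """Read a tab-separated variant table.

    ``generic_tsv`` expects the documented column registry (chrom, pos, ref,
    alt, gene, transcript, patient_id, plus optional context and score
    columns).  ``cosmic_export`` understands the COSMIC genome-screens export
    layout (``Mutation genome position`` as chrom:start-end, alleles from
    ``Mutation CDS`` like ``c.123C>T``) and keeps the raw somatic-status and
    mutation-description strings for :func:`filter_cosmic_rows`.

    Rows whose mandatory fields cannot be parsed, or that violate record
    invariants (e.g. ref == alt), are dropped and counted in the log; a
    missing mandatory column is a hard error.
    """
    if dialect not in ("generic_tsv", "cosmic_export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = _GENERIC_MANDATORY if dialect == "generic_tsv" else _COSMIC_MANDATORY
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} for dialect {dialect}")
    if df.empty:
        logger.warning("%s: empty variant table", path)
        return []
    records: list[VariantRecord] = []
    dropped = 0
    if dialect == "generic_tsv":
        known = set(_GENERIC_MANDATORY) | set(_GENERIC_OPTIONAL)
        score_cols = [c for c in df.columns if c not in known]
        for _, row in df.iterrows():
            try:
                scores = {
                    k: float(row[k]) for k in score_cols if str(row[k]).strip() != ""
                }
                records.append(
                    VariantRecord(
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        gene=row["gene"],
                        transcript=row["transcript"],
                        patient_id=row["patient_id"],
                        tx_pos=(
                            int(row["tx_pos"])
                            if "tx_pos" in df.columns and str(row["tx_pos"]).strip()
                            else None
                        ),
                        tissue=row.get("tissue", ""),
                        category=row.get("category", "somatic_cancer") or "somatic_cancer",
                        consequence=row.get("consequence", "synonymous") or "synonymous",
                        scores=scores,
                        somatic_status=row.get("somatic_status") or None,
                        description=row.get("description") or None,
                    )
                )
            except (ValueError, KeyError):
                dropped += 1
    else:
        pos_re = re.compile(r"^([^:]+):(\d+)-(\d+)$")
        cds_re = re.compile(r"c\.\*?-?\d+([ACGT])>([ACGT])$")
        for _, row in df.iterrows():
            m = pos_re.match(row["Mutation genome position"].strip())
            c = cds_re.search(row["Mutation CDS"].strip())
            if m is None or c is None or m.group(2) != m.group(3):
                dropped += 1
                continue
            try:
                records.append(
                    VariantRecord(
                        chrom=m.group(1),
                        pos=int(m.group(2)),
                        ref=c.group(1),
                        alt=c.group(2),
                        gene=row["Gene name"],
                        transcript=row["Accession Number"],
                        patient_id=row["ID_sample"],
                        tissue=row["Primary site"],
                        category="somatic_cancer",
                        consequence="other",
                        somatic_status=row["Mutation somatic status"],
                        description=row["Mutation Description"],
                    )
                )
            except ValueError:
                dropped += 1
    if dropped:
        logger.warning("%s: dropped %d unparsable/invalid rows", path, dropped)
    return records


_VARIANT_COLUMNS = list(_GENERIC_MANDATORY) + list(_GENERIC_OPTIONAL)


def write_variant_table(records: list[VariantRecord], path) -> None:
    """Write records as a generic TSV; score columns in sorted order."""
    score_cols = sorted({k for r in records for k in r.scores})
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "transcript": r.transcript,
            "patient_id": r.patient_id,
            "tx_pos": "" if r.tx_pos is None else r.tx_pos,
            "tissue": r.tissue,
            "category": r.category,
            "consequence": r.consequence,
            "somatic_status": r.somatic_status or "",
            "description": r.description or "",
        }
        for col in score_cols:
            row[col] = repr(r.scores[col]) if col in r.scores else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=_VARIANT_COLUMNS + score_cols)
    df.to_csv(path, sep="\t", index=False)


_DASHES = re.compile(r"[‐‑‒–—―]")
_WS = re.compile(r"\s+")


def _normalize_label(text: str) -> str:
    """Collapse whitespace and unify hyphen/en-dash variants.

    COSMIC exports print "Substitution - coding silent" while secondary
    sources often use an en-dash without spaces; both normalize identically.
    """
    text = _DASHES.sub("-", text)
    text = _WS.sub(" ", text).strip()
    text = re.sub(r"\s*-\s*", "-", text)
    return text


_CONFIRMED = _normalize_label("Confirmed somatic variant")
_SILENT = _normalize_label("Substitution - coding silent")


def filter_cosmic_rows(records: list[VariantRecord]) -> list[VariantRecord]:
    """Keep confirmed somatic, coding-silent substitution rows.

    Exact string match after label normalization; survivors get
    ``consequence='synonymous'``.  Idempotent; may return an empty list.
    """
    out = []
    for r in records:
        if r.somatic_status is None or r.description is None:
            continue
        if (
            _normalize_label(r.somatic_status) == _CONFIRMED
            and _normalize_label(r.description) == _SILENT
        ):
            out.append(replace(r, consequence="synonymous"))
    return out


# ---------------------------------------------------------------------------
# gene models / gene sets


def read_gene_models(path) -> list[GeneModel]:
    """Read a BED-like TSV of (gene, cds_length, transcript, tx_length)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "cds_length", "transcript", "tx_length"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    seen: set[tuple[str, str]] = set()
    models: dict[str, GeneModel] = {}
    for i, row in df.iterrows():
        gene, tx = row["gene"], row["transcript"]
        if (gene, tx) in seen:
            raise ValueError(f"row {i + 2}: duplicated (gene, transcript) ({gene}, {tx})")
        seen.add((gene, tx))
        cds, txlen = int(row["cds_length"]), int(row["tx_length"])
        if cds <= 0 or txlen <= 0:
            raise ValueError(f"row {i + 2}: non-positive length for gene {gene}")
        if gene in models:
            if models[gene].cds_length != cds:
                raise ValueError(f"row {i + 2}: inconsistent cds_length for gene {gene}")
            models[gene].transcripts.append((tx, txlen))
        else:
            models[gene] = GeneModel(gene=gene, cds_length=cds, transcripts=[(tx, txlen)])
    return list(models.values())


def write_gene_models(models: list[GeneModel], path) -> None:
    rows = [
        {"gene": m.gene, "cds_length": m.cds_length, "transcript": tx, "tx_length": ln}
        for m in models
        for tx, ln in m.transcripts
    ]
    pd.DataFrame(rows, columns=["gene", "cds_length", "transcript", "tx_length"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, tab-separated members."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t.\t{members}\n")


# ---------------------------------------------------------------------------
# motifs (MEME minimal text format)


def read_meme_motifs(path) -> list[MotifPWM]:
    """Parse a MEME minimal-format motif file into PWMs.

    Letter-probability rows must sum to within [0.99, 1.01] and are
    renormalized to machine precision; RNA alphabets (ACGU) are accepted and
    mapped onto DNA.  Background defaults to uniform when no
    ``Background letter frequencies`` block is present.
    """
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[MotifPWM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip().upper().replace("U", "T")
            if alpha != "ACGT":
                raise ValueError(f"unknown alphabet {alpha!r} (DNA/RNA only)")
            i += 1
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freq = {
                tokens[j].upper().replace("U", "T"): float(tokens[j + 1])
                for j in range(0, len(tokens), 2)
            }
            if set(freq) != set("ACGT"):
                raise ValueError(f"background must cover ACGT, got {sorted(freq)}")
            background = np.array([freq[c] for c in "ACGT"])
            background = background / background.sum()
            i += 1
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            if i >= n:
                raise ValueError(f"motif {motif_id}: missing letter-probability matrix")
            header = lines[i].strip()
            m = re.search(r"w=\s*(\d+)", header)
            if m is None:
                raise ValueError(f"motif {motif_id}: matrix header lacks width (w=)")
            width = int(m.group(1))
            i += 1
            rows = []
            for _ in range(width):
                vals = [float(x) for x in lines[i].split()]
                if len(vals) != 4:
                    raise ValueError(f"motif {motif_id}: matrix row has {len(vals)} columns")
                s = sum(vals)
                if not 0.99 <= s <= 1.01:
                    raise ValueError(
                        f"motif {motif_id}: matrix row sums to {s:.4f}, outside [0.99, 1.01]"
                    )
                rows.append([v / s for v in vals])
                i += 1
            motifs.append(
                MotifPWM(motif_id=motif_id, probs=np.array(rows), background=background)
            )
        else:
            i += 1
    return motifs


def write_meme_motifs(motifs: list[MotifPWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{c} {bg[j]:.6f}" for j, c in enumerate("ACGT")) + "\n\n")
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read transcript sequences; uppercase, U mapped to T, IDs must be unique."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA ID {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tx_id, description="") for tx_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# screen reports


def write_screen_report(result, path_prefix) -> None:
    """Write a screen ledger as ``<prefix>.variants.tsv`` + ``<prefix>.genes.tsv``.

    Column order is deterministic; re-reading with :func:`read_screen_report`
    reproduces the ledger.
    """
    if result is None:
        raise ValueError("result must not be None")
    prefix = str(path_prefix)
    result.variants.to_csv(prefix + ".variants.tsv", sep="\t", index=False)
    result.genes.to_csv(prefix + ".genes.tsv", sep="\t", index=False)


def read_screen_report(path_prefix):
    from .driver_screen import ScreenResult

    prefix = str(path_prefix)
    variants = pd.read_csv(prefix + ".variants.tsv", sep="\t", dtype={"chrom": str})
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")
    for col in variants.columns:
        if col.startswith("passed_") or col == "is_proposed_driver":
            variants[col] = variants[col].astype(bool)
    return ScreenResult(variants=variants, genes=genes)
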