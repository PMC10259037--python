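"""Synthetic cohort generator with exactly planted marginal structure.

The study's raw data is not publicly deposited, so this module generates a
full replica of the study inputs — per-sample variant tables, MSI marker
table, fusion candidates with transcript models, a 147-gene expression
matrix, and a clinical table — in which every cohort-level quantity the
pipeline reports is planted exactly: which samples carry a deleterious
mutation in which gene, per-sample countable variant loads (so TMB emerges
through the real counting path), MSI marker instability, filter-passing
fusions plus one decoy of every rejection class, a two-group expression
structure, and outcome patterns.  Truth labels for every planted quantity
ship alongside the raw tables and a self-check pass re-derives them from the
raw data.

Planting is exact-count (hypergeometric assignment of carrier samples), not
Bernoulli, so cohort percentages are reproduced exactly rather than in
expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .burden import call_msi, compute_tmb
from .expression import ExpressionMatrix
from .fusions import (
    FusionFilterConfig,
    TranscriptModel,
    filter_cohort,
    write_fusion_candidates,
    write_transcripts,
)
from .interpret import build_gene_status_matrix, classify_variant
from .knowledge import KnowledgeBase, write_knowledge_base
from .types import (
    Biotype,
    ClinicalRecord,
    ClinVarClass,
    Consequence,
    FigoStage,
    FusionCandidate,
    MarkerStatus,
    RecurrenceType,
    SurvivalStatus,
    VariantRecord,
)


class SpecValidationError(Exception):
    pass


class GenerationError(Exception):
    pass


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


#: Default per-gene planted mutated-sample counts (carriers per 100 samples).
DEFAULT_GENE_COUNTS: dict[str, int] = {
    "ARID1A": 51,
    "PIK3CA": 47,
    "KRAS": 18,
    "TP53": 12,
    "ATM": 10,
    "PPP2R1A": 7,
    "PTEN": 6,
    "NF1": 6,
    "POLE": 4,
}

#: Planted TMB-high structure: group label -> per-sample target densities
#: (mut/Mb).  POLE-mutated hypermutators span 24-86, MSI-high 14-26, plus one
#: MSS/POLE-wild-type sample; the nine realized values have median ~25.
DEFAULT_TMB_HIGH_GROUPS: list[tuple[str, list[float]]] = [
    ("POLEmut", [24, 30, 58, 86]),
    ("MSI-High", [14, 18, 25, 26]),
    ("MSS_POLEwt", [13]),
]

#: Target densities for the 91 non-hypermutated samples, chosen so the
#: full-cohort realized median sits at the 3 mut/Mb level and the low end of
#: the range is 0.
DEFAULT_LOW_TMB_DENSITIES: list[float] = (
    [0] * 3 + [1] * 10 + [2] * 20 + [3] * 20 + [4] * 10 + [5] * 8 + [6] * 6 + [7] * 5 + [8] * 5 + [9] * 4
)

#: Marker genes over-expressed in the minority expression cluster.
CLUSTER2_UP_GENES = ("AKT3", "DDR2", "CTNNB1", "JAK2", "KIT", "PDGFRA")
#: Marker genes under-expressed in the minority expression cluster.
CLUSTER2_DOWN_GENES = ("CDH1", "ERBB2", "ERBB3", "FGFR3", "HIST1H3B", "HNF1B", "POLQ")
REFERENCE_GENES = ("VCP", "SF3B1", "ATP5F1B")

#: Known fusion pairs bundled with the cohort knowledge base (the pairs with
#: prior database/literature reports).
KNOWN_FUSION_PAIRS = frozenset(
    {
        ("CAPZA2", "MET"),
        ("ST7", "MET"),
        ("ERBB4", "IKZF2"),
        ("ESR1", "ARMT1"),
        ("TFG", "ADGRG7"),
    }
)

#: Planted filter-passing fusions.  Breakpoints are transcript (r.)
#: coordinates; ``n_samples`` > 1 plants the same fusion in several samples.
#: ``total`` is the read count at the breakpoint location; where the assay's
#: printed per-gene read totals imply a sub-threshold fraction they cannot be
#: the location totals, and a location total giving a passing fraction is
#: synthesized instead.
PLANTED_FUSIONS: list[dict] = [
    dict(gene5="LAMB1", tx5="NM_002291.3", gene3="MET", tx3="NM_001127500.3",
         b5=560, b3=3181, e5=5, e3=13, frame="IF", chrom5="7", chrom3="7",
         strand5="-", strand3="+", crossing=3729, total=6307, n_samples=1),
    dict(gene5="CCDC3", tx5="NM_031455.4", gene3="AKT3", tx3="NM_005465.7",
         b5=692, b3=363, e5=2, e3=3, frame="FS", chrom5="10", chrom3="1",
         strand5="-", strand3="-", crossing=112, total=602, n_samples=1),
    dict(gene5="CAPZA2", tx5="NM_006136.3", gene3="MET", tx3="NM_001127500.3",
         b5=180, b3=1789, e5=3, e3=4, frame="FS", chrom5="7", chrom3="7",
         strand5="+", strand3="+", crossing=1093, total=3793, n_samples=1),
    dict(gene5="LGALS3", tx5="NM_002306.4", gene3="EZH2", tx3="NM_004456.4",
         b5=650, b3=440, e5=5, e3=4, frame="IF", chrom5="14", chrom3="7",
         strand5="+", strand3="-", crossing=33, total=47, n_samples=1),
    dict(gene5="ST7", tx5="NM_021908.3", gene3="MET", tx3="NM_001127500.3",
         b5=191, b3=1597, e5=1, e3=3, frame="FS", chrom5="7", chrom3="7",
         strand5="+", strand3="+", crossing=56, total=224, n_samples=1),
    dict(gene5="ST7", tx5="NM_021908.3", gene3="MET", tx3="NM_001127500.3",
         b5=191, b3=3034, e5=1, e3=12, frame="FS", chrom5="7", chrom3="7",
         strand5="+", strand3="+", crossing=514, total=4312, n_samples=1),
    dict(gene5="ARID1A", tx5="NM_006015.6", gene3="MIA2", tx3="NM_005930.4",
         b5=1526, b3=139, e5=1, e3=2, frame="IF", chrom5="1", chrom3="14",
         strand5="+", strand3="+", crossing=22, total=88, n_samples=1),
    dict(gene5="DHX15", tx5="NM_001358.3", gene3="ATR", tx3="NM_001184.4",
         b5=1646, b3=7071, e5=8, e3=42, frame="IF", chrom5="4", chrom3="3",
         strand5="-", strand3="-", crossing=42, total=140, n_samples=1),
    dict(gene5="ERBB4", tx5="NM_005235.3", gene3="IKZF2", tx3="NM_016260.3",
         b5=354, b3=412, e5=1, e3=4, frame="IF", chrom5="2", chrom3="2",
         strand5="-", strand3="-", crossing=258, total=641, n_samples=1),
    dict(gene5="NBN", tx5="NM_002485.4", gene3="CNGB3", tx3="NM_019098.4",
         b5=1234, b3=387, e5=9, e3=4, frame="IF", chrom5="8", chrom3="8",
         strand5="-", strand3="-", crossing=66, total=71, n_samples=1),
    dict(gene5="ESR1", tx5="NM_001122742.1", gene3="ARMT1", tx3="NM_024573.3",
         b5=1466, b3=122, e5=6, e3=2, frame="FS", chrom5="6", chrom3="6",
         strand5="+", strand3="+", crossing=51, total=305, n_samples=1),
    dict(gene5="NF1", tx5="NM_000267.3", gene3="GOSR1", tx3="NM_004871.3",
         b5=443, b3=179, e5=1, e3=3, frame="FS", chrom5="17", chrom3="17",
         strand5="+", strand3="+", crossing=942, total=3140, n_samples=1),
    dict(gene5="TFG", tx5="NM_001007565.2", gene3="ADGRG7", tx3="NM_032787.3",
         b5=453, b3=372, e5=3, e3=2, frame="IF", chrom5="3", chrom3="3",
         strand5="+", strand3="+", crossing=120, total=400, n_samples=2),
]

#: 3' transcript total lengths, read off the planted r. ranges.
_TX3_LENGTHS = {
    "NM_001127500.3": 6876,
    "NM_005465.7": 7281,
    "NM_004456.4": 2723,
    "NM_005930.4": 3630,
    "NM_001184.4": 8158,
    "NM_016260.3": 9515,
    "NM_019098.4": 4347,
    "NM_024573.3": 2397,
    "NM_004871.3": 5993,
    "NM_032787.3": 3128,
}


@dataclass
class ExpressionSpec:
    cluster_sizes: tuple[int, int] = (93, 12)
    n_genes: int = 147
    up_genes: tuple[str, ...] = CLUSTER2_UP_GENES
    down_genes: tuple[str, ...] = CLUSTER2_DOWN_GENES
    fold_up: float = 2.5
    fold_down: float = 0.4
    dispersion: float = 0.05
    reference_dispersion: float = 0.02
    library_size_span: float = 3.5  # max/min ratio of library-size factors


@dataclass
class ClinicalSpec:
    n_followup: int = 87
    recurrence_prob_r0: float = 0.15
    recurrence_prob_not_r0: float = 0.50
    r0_prob: float = 0.75
    adjuvant_prob: float = 0.88


@dataclass
class CohortSpec:
    """All planted structure of the synthetic cohort replica."""

    n_dna_samples: int = 100
    n_rna_samples: int = 105
    gene_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_COUNTS))
    tertp_count: int = 27
    tmb_high_groups: list[tuple[str, list[float]]] = field(
        default_factory=lambda: [(g, list(d)) for g, d in DEFAULT_TMB_HIGH_GROUPS]
    )
    low_tmb_densities: list[float] = field(default_factory=lambda: list(DEFAULT_LOW_TMB_DENSITIES))
    msi_high_count: int = 7
    msi_overlap_pole: bool = True
    planted_fusions: list[dict] = field(default_factory=lambda: [dict(f) for f in PLANTED_FUSIONS])
    n_recurrent_artifact_samples: int = 25
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    coding_mb: float = 1.708
    seed: int = 42

    def validate(self) -> None:
        n = self.n_dna_samples
        for gene, count in self.gene_counts.items():
            if not (0 <= count <= n):
                raise SpecValidationError(f"{gene}: planted count {count} exceeds cohort size {n}")
        if self.tertp_count > n:
            raise SpecValidationError("tertp_count exceeds cohort size")
        n_high = sum(len(d) for _, d in self.tmb_high_groups)
        if n_high + len(self.low_tmb_densities) != n:
            raise SpecValidationError(
                f"TMB density lists cover {n_high + len(self.low_tmb_densities)} samples, "
                f"cohort has {n}"
            )
        pole_group = dict(self.tmb_high_groups).get("POLEmut", [])
        if self.gene_counts.get("POLE", 0) != len(pole_group):
            raise SpecValidationError(
                "planted POLE carrier count must match the POLEmut TMB group size"
            )
        msi_group = dict(self.tmb_high_groups).get("MSI-High", [])
        if self.msi_high_count < len(msi_group) + (1 if self.msi_overlap_pole else 0):
            raise SpecValidationError("msi_high_count too small for the planted TMB structure")
        if self.msi_high_count > n:
            raise SpecValidationError("msi_high_count exceeds cohort size")
        n_fusion_samples = sum(f.get("n_samples", 1) for f in self.planted_fusions)
        if n_fusion_samples > self.n_rna_samples:
            raise SpecValidationError("planted fusion samples exceed RNA cohort size")
        if sum(self.expression.cluster_sizes) != self.n_rna_samples:
            raise SpecValidationError(
                f"expression cluster sizes {self.expression.cluster_sizes} do not sum to "
                f"{self.n_rna_samples}"
            )
        if self.clinical.n_followup > n:
            raise SpecValidationError("n_followup exceeds cohort size")
        if self.coding_mb <= 0:
            raise SpecValidationError("coding_mb must be positive")


@dataclass
class CohortBundle:
    """Generated raw inputs plus the planted truth record."""

    spec: CohortSpec
    variants: list[VariantRecord]
    purity: dict[str, float]
    msi_markers: dict[str, list[MarkerStatus]]
    fusion_candidates: list[FusionCandidate]
    transcripts: dict[str, TranscriptModel]
    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    kb: KnowledgeBase
    truth: dict[str, pd.DataFrame]

    @property
    def dna_samples(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.spec.n_dna_samples)]

    @property
    def rna_samples(self) -> list[str]:
        return [f"R{i + 1:03d}" for i in range(self.spec.n_rna_samples)]


# ---------------------------------------------------------------------------
# transcript construction
# ---------------------------------------------------------------------------

def _interpolate_boundaries(anchors: dict[int, int], n_exons: int) -> list[int]:
    """Cumulative exon-end positions honoring anchored boundaries."""
    anchors = dict(anchors)
    anchors.setdefault(0, 0)
    if n_exons not in anchors:
        raise GenerationError("final exon end must be anchored")
    ends = [0] * (n_exons + 1)
    keys = sorted(anchors)
    for lo, hi in zip(keys, keys[1:]):
        span = anchors[hi] - anchors[lo]
        steps = hi - lo
        if span < steps:
            raise GenerationError(
                f"cannot fit {steps} exons into {span} bases between anchors {lo} and {hi}"
            )
        for i in range(steps + 1):
            ends[lo + i] = anchors[lo] + round(span * i / steps)
        ends[hi] = anchors[hi]
    # enforce strictly increasing
    for i in range(1, n_exons + 1):
        if ends[i] <= ends[i - 1]:
            raise GenerationError("exon boundaries not strictly increasing")
    return ends[1:]


def _build_transcript(
    gene: str,
    tx_id: str,
    chrom: str,
    strand: str,
    genomic_start: int,
    anchors: dict[int, int],
    n_exons: int,
    cds_start: int,
    cds_end: int | None = None,
) -> TranscriptModel:
    ends = _interpolate_boundaries(anchors, n_exons)
    exons = []
    prev = 0
    for e in ends:
        exons.append((prev + 1, e))
        prev = e
    length = ends[-1]
    if cds_end is None:
        tail = max(length - 30, cds_start + 2)
        cds_end = cds_start + ((tail - cds_start + 1) // 3) * 3 - 1
    return TranscriptModel(
        gene=gene,
        transcript_id=tx_id,
        chrom=chrom,
        strand=strand,
        genomic_start=genomic_start,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def _generic_transcript(
    gene: str, tx_id: str, chrom: str, strand: str, genomic_start: int,
    n_exons: int = 6, exon_len: int = 200,
) -> TranscriptModel:
    anchors = {n_exons: n_exons * exon_len}
    return _build_transcript(gene, tx_id, chrom, strand, genomic_start, anchors, n_exons, cds_start=10)


class _GenomeLayout:
    """Hands out well-separated genomic start positions per chromosome."""

    def __init__(self, spacing: int = 2_000_000) -> None:
        self.cursors: dict[str, int] = {}
        self.spacing = spacing

    def place(self, chrom: str) -> int:
        pos = self.cursors.get(chrom, 1_000_000)
        self.cursors[chrom] = pos + self.spacing
        return pos


def build_fusion_annotation(spec: CohortSpec) -> dict[str, TranscriptModel]:
    """Construct miniature transcript models for every planted fusion partner.

    5'-gene CDS starts are solved so that each planted fusion realizes its
    intended reading frame (in-frame when the retained 5' CDS length matches
    the 3' breakpoint's codon phase modulo 3); exon boundaries are anchored
    exactly at the planted breakpoints.
    """
    layout = _GenomeLayout()
    models: dict[str, TranscriptModel] = {}

    # 3' transcripts first: anchored exon start at each breakpoint, fixed CDS start
    cds3_start = 26
    tx3_anchor: dict[str, dict[int, int]] = {}
    tx3_meta: dict[str, dict] = {}
    for f in spec.planted_fusions:
        tx3_anchor.setdefault(f["tx3"], {})
        # exon e3 starts at b3 -> exon e3-1 ends at b3 - 1
        tx3_anchor[f["tx3"]][f["e3"] - 1] = f["b3"] - 1
        tx3_meta[f["tx3"]] = dict(gene=f["gene3"], chrom=f["chrom3"], strand=f["strand3"])
    for tx_id, anchors in tx3_anchor.items():
        meta = tx3_meta[tx_id]
        length = _TX3_LENGTHS.get(tx_id, max(anchors.values()) + 2000)
        max_anchor_exon = max(anchors)
        n_exons = max(max_anchor_exon + 8, 12)
        anchors = dict(anchors)
        anchors[n_exons] = length
        models[tx_id] = _build_transcript(
            meta["gene"], tx_id, meta["chrom"], meta["strand"],
            layout.place(meta["chrom"]), anchors, n_exons, cds_start=cds3_start,
        )

    # 5' transcripts: anchored exon end at each breakpoint; CDS start solved
    # per transcript for the planted frame outcome
    tx5_anchor: dict[str, dict[int, int]] = {}
    tx5_meta: dict[str, dict] = {}
    tx5_cds: dict[str, int] = {}
    for f in spec.planted_fusions:
        tx5_anchor.setdefault(f["tx5"], {})
        tx5_anchor[f["tx5"]][f["e5"]] = f["b5"]
        tx5_meta[f["tx5"]] = dict(gene=f["gene5"], chrom=f["chrom5"], strand=f["strand5"])
        phase3 = (f["b3"] - cds3_start) % 3
        want = phase3 if f["frame"] == "IF" else (phase3 + 1) % 3
        # retained = b5 - c5 + 1 must be ≡ want (mod 3)
        c5 = next(c for c in (1, 2, 3) if (f["b5"] - c + 1) % 3 == want)
        if f["tx5"] in tx5_cds and tx5_cds[f["tx5"]] != c5:
            raise GenerationError(
                f"{f['tx5']}: conflicting frame requirements across planted fusions"
            )
        tx5_cds[f["tx5"]] = c5
    for tx_id, anchors in tx5_anchor.items():
        meta = tx5_meta[tx_id]
        max_anchor_exon = max(anchors)
        n_exons = max_anchor_exon + 4
        anchors = dict(anchors)
        anchors[n_exons] = max(anchors.values()) + 1200
        models[tx_id] = _build_transcript(
            meta["gene"], tx_id, meta["chrom"], meta["strand"],
            layout.place(meta["chrom"]), anchors, n_exons, cds_start=tx5_cds[tx_id],
        )

    # decoy gene models
    for gene, tx_id, chrom, strand in [
        ("DCY1A", "TX_DCY1A", "5", "+"), ("DCY1B", "TX_DCY1B", "9", "-"),
        ("DCY2A", "TX_DCY2A", "5", "+"), ("DCY2B", "TX_DCY2B", "12", "+"),
        ("HLA-A", "TX_HLAA", "6", "+"), ("HLA-B", "TX_HLAB", "6", "-"),
        ("NCPC", "TX_NCPC", "11", "+"), ("LINC-DCY", "TX_LINCDCY", "15", "+"),
        ("ARTF1", "TX_ARTF1", "19", "+"), ("ARTF2", "TX_ARTF2", "20", "-"),
        ("LOEX1", "TX_LOEX1", "21", "+"), ("LOEX2", "TX_LOEX2", "22", "-"),
    ]:
        models[tx_id] = _generic_transcript(gene, tx_id, chrom, strand, layout.place(chrom))

    # readthrough decoy pair: adjacent, same strand, 40 kb apart on one chromosome
    rt_start = layout.place("11")
    models["TX_RT1"] = _generic_transcript("RT1", "TX_RT1", "11", "+", rt_start)
    models["TX_RT2"] = _generic_transcript("RT2", "TX_RT2", "11", "+", rt_start + 40_000)
    return models


# ---------------------------------------------------------------------------
# DNA cohort
# ---------------------------------------------------------------------------

_CHROM_BY_GENE = {
    "ARID1A": "1", "PIK3CA": "3", "KRAS": "12", "TP53": "17", "ATM": "11",
    "PPP2R1A": "19", "PTEN": "10", "NF1": "17", "POLE": "12", "TERT": "5",
}

#: Transcript accessions for the signature genes (representative RefSeq-style).
_TX_BY_GENE = {
    "ARID1A": "NM_006015.6", "PIK3CA": "NM_006218.4", "KRAS": "NM_033360.4",
    "TP53": "NM_000546.6", "ATM": "NM_000051.4", "PPP2R1A": "NM_014225.6",
    "PTEN": "NM_000314.8", "NF1": "NM_000267.3", "POLE": "NM_006231.2",
    "TERT": "NM_198253.3",
}

EXCLUDED_POLE_HGVS = "c.3961A>T"
TERTP_HOTSPOTS = ("c.-124C>T", "c.-124C>A", "c.-146C>T")
_BASES = ("A", "C", "G", "T")


class _DnaGenerator:
    def __init__(self, spec: CohortSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng
        self.samples = [f"S{i + 1:03d}" for i in range(spec.n_dna_samples)]
        self.variants: list[VariantRecord] = []
        self._pos_counter = 1000

    def _next_pos(self) -> int:
        self._pos_counter += int(self.rng.integers(50, 500))
        return self._pos_counter

    def _alleles(self) -> tuple[str, str]:
        ref = _BASES[int(self.rng.integers(0, 4))]
        alt = _BASES[(int(_BASES.index(ref)) + int(self.rng.integers(1, 4))) % 4]
        return ref, alt

    def _af(self) -> float:
        return round(float(self.rng.uniform(0.15, 0.65)), 4)

    def class45_variant(self, sample: str, gene: str) -> VariantRecord:
        kind = ["frameshift", "nonsense", "missense"][int(self.rng.integers(0, 3))]
        if gene == "POLE":
            kind = "missense"  # exonuclease-domain pathogenic missense
        ref, alt = self._alleles()
        pos = self._next_pos()
        cpos = int(self.rng.integers(100, 4000))
        if kind == "frameshift":
            return VariantRecord(
                sample, gene, _TX_BY_GENE.get(gene, ""), _CHROM_BY_GENE.get(gene, "1"),
                pos, ref + "A", ref, f"c.{cpos}del", f"p.(T{cpos // 3}fs)",
                Consequence.FRAMESHIFT, self._af(),
            )
        if kind == "nonsense":
            return VariantRecord(
                sample, gene, _TX_BY_GENE.get(gene, ""), _CHROM_BY_GENE.get(gene, "1"),
                pos, "C", "T", f"c.{cpos}C>T", f"p.(Q{cpos // 3}X)",
                Consequence.NONSENSE, self._af(),
            )
        return VariantRecord(
            sample, gene, _TX_BY_GENE.get(gene, ""), _CHROM_BY_GENE.get(gene, "1"),
            pos, ref, alt, f"c.{cpos}{ref}>{alt}", f"p.(R{cpos // 3}W)",
            Consequence.MISSENSE, self._af(),
            clinvar_class=ClinVarClass.PATHOGENIC if self.rng.random() < 0.6
            else ClinVarClass.LIKELY_PATHOGENIC,
        )

    def countable_filler(self, sample: str) -> VariantRecord:
        """Countable (TMB-eligible) variant that must not be class 4/5."""
        gene = f"PANEL{int(self.rng.integers(1, 400)):03d}"
        ref, alt = self._alleles()
        pos = self._next_pos()
        cpos = int(self.rng.integers(100, 3000))
        if self.rng.random() < 0.55:
            return VariantRecord(
                sample, gene, "", "2", pos, ref, alt, f"c.{cpos}{ref}>{alt}",
                "p.(=)", Consequence.SYNONYMOUS, self._af(),
            )
        return VariantRecord(
            sample, gene, "", "2", pos, ref, alt, f"c.{cpos}{ref}>{alt}",
            f"p.(A{cpos // 3}V)", Consequence.MISSENSE, self._af(),
            clinvar_class=ClinVarClass.VUS if self.rng.random() < 0.7 else ClinVarClass.ABSENT,
        )

    def noncountable_decoy(self, sample: str) -> VariantRecord:
        """Decoy the TMB counter must exclude (low AF, polymorphism, non-coding)."""
        gene = f"PANEL{int(self.rng.integers(1, 400)):03d}"
        ref, alt = self._alleles()
        pos = self._next_pos()
        cpos = int(self.rng.integers(100, 3000))
        kind = int(self.rng.integers(0, 3))
        if kind == 0:  # below the 10% AF gate
            return VariantRecord(
                sample, gene, "", "2", pos, ref, alt, f"c.{cpos}{ref}>{alt}",
                f"p.(G{cpos // 3}S)", Consequence.MISSENSE,
                round(float(self.rng.uniform(0.02, 0.0999)), 4),
                clinvar_class=ClinVarClass.VUS,
            )
        if kind == 1:  # presumed germline polymorphism
            return VariantRecord(
                sample, gene, "", "2", pos, ref, alt, f"c.{cpos}{ref}>{alt}",
                "p.(=)", Consequence.SYNONYMOUS, self._af(), in_polymorphism_db=True,
            )
        return VariantRecord(
            sample, gene, "", "2", pos, ref, alt, f"c.{cpos}{ref}>{alt}", "",
            Consequence.OTHER_NONCODING, self._af(),
        )


def _generate_dna(spec: CohortSpec, rng: np.random.Generator):
    gen = _DnaGenerator(spec, rng)
    samples = gen.samples
    n = spec.n_dna_samples

    # --- special-sample layout ----------------------------------------------
    densities_by_group = dict(spec.tmb_high_groups)
    n_high = sum(len(d) for d in densities_by_group.values())
    high_samples = list(rng.choice(samples, size=n_high, replace=False))
    idx = 0
    group_samples: dict[str, list[str]] = {}
    high_density: dict[str, float] = {}
    for label, densities in spec.tmb_high_groups:
        group_samples[label] = high_samples[idx: idx + len(densities)]
        for s, d in zip(group_samples[label], densities):
            high_density[s] = d
        idx += len(densities)

    pole_samples = group_samples.get("POLEmut", [])
    msi_tmb_samples = group_samples.get("MSI-High", [])

    msi_set: set[str] = set(msi_tmb_samples)
    if spec.msi_overlap_pole and pole_samples:
        msi_set.add(pole_samples[0])
    remaining_msi = spec.msi_high_count - len(msi_set)
    low_pool = [s for s in samples if s not in set(high_samples)]
    if remaining_msi > 0:
        msi_set.update(rng.choice(low_pool, size=remaining_msi, replace=False))

    # --- gene carrier planting (exact counts) --------------------------------
    carriers: dict[str, set[str]] = {}
    kras_count = spec.gene_counts.get("KRAS", 0)
    tp53_count = spec.gene_counts.get("TP53", 0)
    if kras_count + tp53_count > n:
        raise SpecValidationError("KRAS and TP53 planted counts cannot be disjoint")
    both = list(rng.choice(samples, size=kras_count + tp53_count, replace=False))
    carriers["KRAS"] = set(both[:kras_count])
    carriers["TP53"] = set(both[kras_count:])
    for gene, count in spec.gene_counts.items():
        if gene in ("KRAS", "TP53"):
            continue
        if gene == "POLE":
            carriers["POLE"] = set(pole_samples)
            continue
        carriers[gene] = set(rng.choice(samples, size=count, replace=False))

    tert_samples = set(rng.choice(samples, size=spec.tertp_count, replace=False))

    # --- emit class 4/5 variants ---------------------------------------------
    class45_count = {s: 0 for s in samples}
    for gene in sorted(carriers):
        for s in sorted(carriers[gene]):
            gen.variants.append(gen.class45_variant(s, gene))
            class45_count[s] += 1

    # TERT promoter hotspots (non-coding, never countable) plus non-hotspot decoys
    for i, s in enumerate(sorted(tert_samples)):
        hotspot = TERTP_HOTSPOTS[i % len(TERTP_HOTSPOTS)]
        gen.variants.append(
            VariantRecord(
                s, "TERT", _TX_BY_GENE["TERT"], _CHROM_BY_GENE["TERT"],
                1_295_113, "G", "A", hotspot, "", Consequence.PROMOTER, gen._af(),
            )
        )
    non_tert = [s for s in samples if s not in tert_samples]
    for s in rng.choice(non_tert, size=min(5, len(non_tert)), replace=False):
        gen.variants.append(
            VariantRecord(
                str(s), "TERT", _TX_BY_GENE["TERT"], _CHROM_BY_GENE["TERT"],
                1_295_135, "C", "T", "c.-100C>T", "", Consequence.PROMOTER, gen._af(),
            )
        )

    # --- TMB targets through the counting path -------------------------------
    low_samples = sorted(low_pool, key=lambda s: (-class45_count[s], s))
    low_targets = sorted(
        (_round_half_up(d * spec.coding_mb) for d in spec.low_tmb_densities), reverse=True
    )
    target_counts: dict[str, int] = {}
    for s, t in zip(low_samples, low_targets):
        target_counts[s] = t
    for s, d in high_density.items():
        target_counts[s] = _round_half_up(d * spec.coding_mb)

    # the recurrent POLE nonsense without ultramutated phenotype: planted in a
    # POLE-wild-type sample with spare countable budget; it counts toward TMB
    # but must never register as a POLE driver
    r1321x_hosts = sorted(
        s for s in samples
        if s not in carriers["POLE"] and target_counts[s] > class45_count[s]
    )
    if r1321x_hosts:
        r1321x_sample = str(rng.choice(r1321x_hosts))
        gen.variants.append(
            VariantRecord(
                r1321x_sample, "POLE", "NM_006231.2", _CHROM_BY_GENE["POLE"],
                gen._next_pos(), "A", "T", EXCLUDED_POLE_HGVS, "p.(R1321X)",
                Consequence.NONSENSE, gen._af(),
            )
        )
        class45_count[r1321x_sample] += 1  # countable though not class 4/5

    for s in samples:
        deficit = target_counts[s] - class45_count[s]
        if deficit < 0:
            raise GenerationError(
                f"{s}: planted class 4/5 load {class45_count[s]} exceeds TMB target "
                f"{target_counts[s]}; spec infeasible"
            )
        for _ in range(deficit):
            gen.variants.append(gen.countable_filler(s))
        for _ in range(int(rng.integers(2, 6))):
            gen.variants.append(gen.noncountable_decoy(s))

    purity = {s: round(float(rng.uniform(0.40, 0.95)), 2) for s in samples}

    # --- MSI marker table -----------------------------------------------------
    markers: dict[str, list[MarkerStatus]] = {}
    for s in samples:
        statuses = [MarkerStatus.STABLE] * io_mod.N_MSI_MARKERS
        if s in msi_set:
            n_unstable = int(rng.integers(4, 9))
            n_eval = io_mod.N_MSI_MARKERS
        else:
            n_unstable = int(rng.integers(0, 3))
            n_eval = int(rng.integers(14, io_mod.N_MSI_MARKERS + 1))
        order = rng.permutation(io_mod.N_MSI_MARKERS)
        for i in order[:n_unstable]:
            statuses[i] = MarkerStatus.UNSTABLE
        for i in order[n_unstable: n_unstable + (io_mod.N_MSI_MARKERS - n_eval)]:
            statuses[i] = MarkerStatus.NOT_EVALUATED
        markers[s] = statuses

    truth_samples = pd.DataFrame(
        {
            "sample_id": samples,
            "tmb_target_count": [target_counts[s] for s in samples],
            "tmb_target_density": [round(target_counts[s] / spec.coding_mb, 4) for s in samples],
            "tmb_high": [target_counts[s] / spec.coding_mb >= 10.0 for s in samples],
            "pole_mut": [s in carriers["POLE"] for s in samples],
            "msi_high": [s in msi_set for s in samples],
            "tertp": [s in tert_samples for s in samples],
            "tp53": [s in carriers["TP53"] for s in samples],
        }
    ).set_index("sample_id")
    truth_genes = pd.DataFrame(
        [
            {"gene": g, "planted_count": len(cs)}
            for g, cs in sorted(carriers.items())
        ]
    ).set_index("gene")
    truth_carriers = pd.DataFrame(
        [{"gene": g, "sample_id": s} for g in sorted(carriers) for s in sorted(carriers[g])]
    )
    return (
        gen.variants, purity, markers,
        {"samples": truth_samples, "gene_counts": truth_genes, "carriers": truth_carriers},
    )


# ---------------------------------------------------------------------------
# fusion candidates
# ---------------------------------------------------------------------------

def generate_fusion_candidates(
    spec: CohortSpec,
    annotation: dict[str, TranscriptModel],
    rng: np.random.Generator,
) -> tuple[list[FusionCandidate], pd.DataFrame]:
    """Emit the raw candidate table: planted true fusions plus decoys.

    Every truth-accepted candidate passes all filter criteria by
    construction; one decoy of each rejection class is planted, plus a
    recurrent artifact pair present in >20% of the RNA samples.  Returns the
    candidates and a truth table (one row per candidate, with the intended
    verdict and reason).
    """
    rna_samples = [f"R{i + 1:03d}" for i in range(spec.n_rna_samples)]
    n_true = sum(f.get("n_samples", 1) for f in spec.planted_fusions)
    positive = list(rng.choice(rna_samples, size=n_true, replace=False))
    candidates: list[FusionCandidate] = []
    truth_rows: list[dict] = []

    def genomic(tx: TranscriptModel, breakpoint: int) -> int:
        return tx.genomic_start + breakpoint

    i = 0
    for f in spec.planted_fusions:
        for _ in range(f.get("n_samples", 1)):
            s = positive[i]
            i += 1
            t5, t3 = annotation[f["tx5"]], annotation[f["tx3"]]
            cand = FusionCandidate(
                sample_id=s, gene5=f["gene5"], gene3=f["gene3"],
                transcript5=f["tx5"], transcript3=f["tx3"],
                chrom5=f["chrom5"], chrom3=f["chrom3"],
                strand5=f["strand5"], strand3=f["strand3"],
                breakpoint5=f["b5"], breakpoint3=f["b3"],
                genomic_pos5=genomic(t5, f["b5"]), genomic_pos3=genomic(t3, f["b3"]),
                crossing_reads=f["crossing"], total_reads_at_location=f["total"],
                region_median_reads=round(f["total"] / 4.0, 1),
            )
            candidates.append(cand)
            truth_rows.append(
                {"sample_id": s, "gene5": f["gene5"], "gene3": f["gene3"],
                 "accept": True, "reason": ".", "frame": f["frame"],
                 "exon_junction": f"e{f['e5']}-e{f['e3']}"}
            )

    decoy_pool = [s for s in rna_samples if s not in set(positive)]
    rng.shuffle(decoy_pool)
    pool_iter = iter(decoy_pool)

    def decoy(gene5, tx5, gene3, tx3, *, b5=None, b3=None, crossing=40, total=400,
              region_median=None, reason="", sample=None):
        t5, t3 = annotation[tx5], annotation[tx3]
        b5 = b5 if b5 is not None else t5.exons[2][1]  # exon 3 end
        b3 = b3 if b3 is not None else t3.exons[3][0]  # exon 4 start
        s = sample or next(pool_iter)
        cand = FusionCandidate(
            sample_id=s, gene5=gene5, gene3=gene3, transcript5=tx5, transcript3=tx3,
            chrom5=t5.chrom, chrom3=t3.chrom, strand5=t5.strand, strand3=t3.strand,
            breakpoint5=b5, breakpoint3=b3,
            genomic_pos5=genomic(t5, b5), genomic_pos3=genomic(t3, b3),
            crossing_reads=crossing, total_reads_at_location=total,
            region_median_reads=region_median if region_median is not None else round(total / 4.0, 1),
            biotype3=Biotype.OTHER if gene3 == "LINC-DCY" else Biotype.PROTEIN_CODING,
        )
        candidates.append(cand)
        truth_rows.append(
            {"sample_id": s, "gene5": gene5, "gene3": gene3, "accept": False,
             "reason": reason, "frame": ".", "exon_junction": "."}
        )

    decoy("DCY1A", "TX_DCY1A", "DCY1B", "TX_DCY1B", crossing=9, total=100,
          reason="low_read_fraction")
    off_b5 = annotation["TX_DCY2A"].exons[2][1] + 16  # 16 bp past the exon edge
    decoy("DCY2A", "TX_DCY2A", "DCY2B", "TX_DCY2B", b5=off_b5,
          reason="off_exon_boundary")
    decoy("HLA-A", "TX_HLAA", "HLA-B", "TX_HLAB", reason="gene_family")
    decoy("RT1", "TX_RT1", "RT2", "TX_RT2", reason="readthrough")
    decoy("NCPC", "TX_NCPC", "LINC-DCY", "TX_LINCDCY", reason="non_coding_partner")
    decoy("LOEX1", "TX_LOEX1", "LOEX2", "TX_LOEX2", total=150, crossing=40,
          region_median=150.0, reason="low_expression_support")
    artifact_samples = rng.choice(rna_samples, size=spec.n_recurrent_artifact_samples, replace=False)
    for s in artifact_samples:
        decoy("ARTF1", "TX_ARTF1", "ARTF2", "TX_ARTF2", sample=str(s),
              reason="recurrent_artifact")

    return candidates, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.Series]:
    """Negative-binomial count matrix with a planted two-group structure.

    The minority group's up-marker genes are shifted by ``fold_up`` and the
    down-markers by ``fold_down``; library-size factors span a
    ``library_size_span``-fold range to exercise normalization.  Returns the
    matrix and the planted cluster labels (1 = majority, 2 = minority).
    """
    ex = spec.expression
    rna_samples = [f"R{i + 1:03d}" for i in range(spec.n_rna_samples)]
    n1, n2 = ex.cluster_sizes
    minority = set(rng.choice(rna_samples, size=n2, replace=False))
    labels = pd.Series(
        [2 if s in minority else 1 for s in rna_samples], index=rna_samples, name="cluster"
    )

    markers = list(ex.up_genes) + list(ex.down_genes)
    n_filler = ex.n_genes - len(markers) - len(REFERENCE_GENES)
    if n_filler < 0:
        raise SpecValidationError("n_genes too small for markers plus references")
    genes = markers + list(REFERENCE_GENES) + [f"EXPR{i + 1:03d}" for i in range(n_filler)]

    base_mean = {}
    for g in genes:
        if g in REFERENCE_GENES:
            base_mean[g] = float(rng.uniform(800, 1200))
        elif g in markers:
            base_mean[g] = float(rng.uniform(250, 600))
        else:
            base_mean[g] = float(np.exp(rng.normal(5.0, 1.0)))
    lengths = pd.Series(
        {g: int(rng.integers(500, 5000)) for g in genes}, name="gene_length"
    )

    # library-size factors with an exact planted span, shuffled across samples
    span = ex.library_size_span
    factors = np.exp(np.linspace(np.log(1.0 / math.sqrt(span)), np.log(math.sqrt(span)),
                                 spec.n_rna_samples))
    factors = factors[rng.permutation(spec.n_rna_samples)]

    counts = np.zeros((len(genes), spec.n_rna_samples), dtype=np.int64)
    for gi, g in enumerate(genes):
        disp = ex.reference_dispersion if g in REFERENCE_GENES else ex.dispersion
        r = 1.0 / disp
        for si, s in enumerate(rna_samples):
            mu = base_mean[g] * factors[si]
            if labels[s] == 2:
                if g in ex.up_genes:
                    mu *= ex.fold_up
                elif g in ex.down_genes:
                    mu *= ex.fold_down
            p = r / (r + mu)
            counts[gi, si] = rng.negative_binomial(r, p)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=rna_samples),
        gene_lengths=lengths,
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def _generate_clinical(
    spec: CohortSpec, rng: np.random.Generator, protected: set[str]
) -> list[ClinicalRecord]:
    """Clinical table; ``protected`` samples (POLEmut and/or MSI-High) are
    planted with no recurrence-free-survival event."""
    cs = spec.clinical
    samples = [f"S{i + 1:03d}" for i in range(spec.n_dna_samples)]
    no_followup = set(
        rng.choice(
            [s for s in samples if s not in protected],
            size=spec.n_dna_samples - cs.n_followup,
            replace=False,
        )
    )
    figo_levels = [FigoStage.IA, FigoStage.IB, FigoStage.IC, FigoStage.II, FigoStage.III, FigoStage.IV]
    figo_probs = [0.37, 0.01, 0.35, 0.08, 0.18, 0.01]
    records = []
    for s in samples:
        age_mu = 52.0 if s in protected else 61.0
        age = float(np.clip(rng.normal(age_mu, 9.0), 34, 82))
        figo = figo_levels[int(rng.choice(len(figo_levels), p=figo_probs))]
        t_high = bool(rng.random() < 0.17)
        r0 = bool(rng.random() < cs.r0_prob)
        adjuvant = bool(rng.random() < cs.adjuvant_prob)
        if s in no_followup:
            records.append(
                ClinicalRecord(
                    sample_id=s, age=round(age, 1), figo_stage=figo, t_stage_high=t_high,
                    resection_r0=r0, adjuvant_therapy=adjuvant,
                    survival_status=SurvivalStatus.NA,
                )
            )
            continue
        followup = round(float(np.clip(rng.gamma(3.0, 14.0), 2.0, 120.0)), 1)
        if s in protected:
            status = SurvivalStatus.NED if rng.random() < 0.8 else SurvivalStatus.AWD
            recurrence: bool | None = False
            rec_months = None
            rec_type = RecurrenceType.NA
        else:
            p_rec = cs.recurrence_prob_r0 if r0 else cs.recurrence_prob_not_r0
            recurrence = bool(rng.random() < p_rec)
            rec_months = round(followup * float(rng.uniform(0.2, 0.9)), 1) if recurrence else None
            rec_type = (
                [RecurrenceType.LOCAL, RecurrenceType.DISTANT, RecurrenceType.COMBINED][
                    int(rng.choice(3, p=[0.6, 0.35, 0.05]))
                ]
                if recurrence
                else RecurrenceType.NA
            )
            if recurrence:
                status = [SurvivalStatus.AWD, SurvivalStatus.DOD, SurvivalStatus.NED][
                    int(rng.choice(3, p=[0.45, 0.35, 0.20]))
                ]
            else:
                status = [
                    SurvivalStatus.NED, SurvivalStatus.AWD, SurvivalStatus.DTC,
                    SurvivalStatus.DUC, SurvivalStatus.DOC,
                ][int(rng.choice(5, p=[0.78, 0.08, 0.03, 0.05, 0.06]))]
        records.append(
            ClinicalRecord(
                sample_id=s, age=round(age, 1), figo_stage=figo, t_stage_high=t_high,
                resection_r0=r0, adjuvant_therapy=adjuvant, recurrence=recurrence,
                recurrence_type=rec_type, survival_status=status,
                followup_months=followup, recurrence_months=rec_months,
            )
        )
    return records


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def _build_kb(spec: CohortSpec, variants: list[VariantRecord]) -> KnowledgeBase:
    polymorphisms = {
        (v.gene, v.hgvs_c): True for v in variants if v.in_polymorphism_db
    }
    drivers = {(v.gene, v.hgvs_c): True for v in variants if v.known_driver}
    families = {"HLA-A": "HLA", "HLA-B": "HLA", "HLA-C": "HLA"}
    panel = frozenset(
        {v.gene for v in variants} | set(DEFAULT_GENE_COUNTS) | {"TERT"}
    )
    return KnowledgeBase(
        driver_variants=drivers,
        polymorphism_table=polymorphisms,
        known_fusion_pairs=KNOWN_FUSION_PAIRS,
        gene_families=families,
        coding_regions={"panel_coding": int(round(spec.coding_mb * 1e6))},
        panel_genes=panel,
        excluded_pole_variants=frozenset(
            {EXCLUDED_POLE_HGVS, f"NM_006231.2:{EXCLUDED_POLE_HGVS}"}
        ),
    )


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> CohortBundle:
    """Generate the full synthetic cohort bundle.

    Deterministic for a fixed spec and seed (``seed`` overrides
    ``spec.seed``).  Raises :class:`SpecValidationError` before generating
    anything when the spec is infeasible.
    """
    spec = spec if spec is not None else CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    variants, purity, markers, dna_truth = _generate_dna(spec, rng)
    kb = _build_kb(spec, variants)
    annotation = build_fusion_annotation(spec)
    candidates, fusion_truth = generate_fusion_candidates(spec, annotation, rng)
    expression, cluster_labels = generate_expression(spec, rng)
    protected = set(
        dna_truth["samples"].index[
            dna_truth["samples"]["pole_mut"] | dna_truth["samples"]["msi_high"]
        ]
    )
    clinical = _generate_clinical(spec, rng, protected)

    truth = dict(dna_truth)
    truth["fusions"] = fusion_truth
    truth["expression_clusters"] = cluster_labels.to_frame()

    bundle = CohortBundle(
        spec=spec, variants=variants, purity=purity, msi_markers=markers,
        fusion_candidates=candidates, transcripts=annotation,
        expression=expression, clinical=clinical, kb=kb, truth=truth,
    )
    verify_bundle(bundle)
    return bundle


def verify_bundle(bundle: CohortBundle) -> None:
    """Self-consistency pass: re-derive every rule-derivable truth label from
    the generated raw tables and require 100% agreement.

    Covers gene carrier counts (via classification), TERTp, TMB targets and
    high calls, MSI calls, and fusion verdicts.  Raises
    :class:`GenerationError` on any disagreement.
    """
    spec = bundle.spec
    kb = bundle.kb
    truth = bundle.truth["samples"]

    matrix = build_gene_status_matrix(bundle.variants, kb, sample_ids=bundle.dna_samples)
    counts = matrix.gene_counts()
    for gene, row in bundle.truth["gene_counts"].iterrows():
        got = int(counts.get(gene, 0))
        if got != int(row["planted_count"]):
            raise GenerationError(
                f"self-check: {gene} classified carriers {got} != planted {row['planted_count']}"
            )
    if matrix.tertp_count() != int(truth["tertp"].sum()):
        raise GenerationError("self-check: TERTp call count mismatch")

    by_sample: dict[str, list[VariantRecord]] = {s: [] for s in bundle.dna_samples}
    for v in bundle.variants:
        by_sample[v.sample_id].append(v)
    for s in bundle.dna_samples:
        res = compute_tmb(by_sample[s], bundle.purity[s], kb, coding_mb=spec.coding_mb)
        if res.counted_variants != int(truth.loc[s, "tmb_target_count"]):
            raise GenerationError(
                f"self-check: {s} counted {res.counted_variants} != target "
                f"{truth.loc[s, 'tmb_target_count']}"
            )
        if bool(res.tmb_high) != bool(truth.loc[s, "tmb_high"]):
            raise GenerationError(f"self-check: {s} TMB-high flag mismatch")
        msi = call_msi(s, bundle.msi_markers[s])
        if bool(msi.msi_high) != bool(truth.loc[s, "msi_high"]):
            raise GenerationError(f"self-check: {s} MSI call mismatch")

    verdicts = filter_cohort(
        bundle.fusion_candidates, bundle.transcripts, kb, spec.n_rna_samples,
        FusionFilterConfig(),
    )
    ft = bundle.truth["fusions"]
    for v, (_, row) in zip(verdicts, ft.iterrows()):
        if v.accepted != bool(row["accept"]):
            raise GenerationError(
                f"self-check: fusion {row['gene5']}::{row['gene3']} in {row['sample_id']} "
                f"verdict {v.accepted} != planted {row['accept']} (reasons {v.reasons})"
            )
        if not v.accepted and row["reason"] != ".":
            got = {r.value for r in v.reasons}
            if row["reason"] not in got:
                raise GenerationError(
                    f"self-check: fusion {row['gene5']}::{row['gene3']} rejected for {got}, "
                    f"planted reason {row['reason']}"
                )
        if v.accepted:
            if v.frame.value != {"IF": "in_frame", "FS": "frameshift"}[row["frame"]]:
                raise GenerationError(
                    f"self-check: {row['gene5']}::{row['gene3']} frame {v.frame} != "
                    f"planted {row['frame']}"
                )
            junction = f"{v.exon_junction[0]}-{v.exon_junction[1]}"
            if junction != row["exon_junction"]:
                raise GenerationError(
                    f"self-check: {row['gene5']}::{row['gene3']} junction {junction} != "
                    f"planted {row['exon_junction']}"
                )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write the complete input directory layout the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.write_variants(bundle.variants, outdir / "variants.tsv", dialect="tsv")
    io_mod.write_purity(bundle.purity, outdir / "purity.tsv")
    io_mod.write_msi_markers(bundle.msi_markers, outdir / "msi_markers.tsv")
    write_fusion_candidates(bundle.fusion_candidates, outdir / "fusion_candidates.tsv")
    write_transcripts(bundle.transcripts, outdir / "transcripts.tsv")
    bundle.expression.to_tsv(outdir / "expression_counts.tsv")
    io_mod.write_clinical(bundle.clinical, outdir / "clinical.tsv")
    write_knowledge_base(bundle.kb, outdir / "kb")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, df in bundle.truth.items():
        df.to_csv(truth_dir / f"{name}.tsv", sep="\t")
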