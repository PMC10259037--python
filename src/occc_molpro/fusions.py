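"""Fusion-candidate filtering, reading-frame prediction, and novelty calls.

A candidate is accepted as a true fusion only when every criterion holds:
both partners protein-coding, both breakpoints at standard exon-exon
junctions (within +-15 bp of an exon boundary), crossing-read fraction at
the breakpoint location >= 10%, expression support at the region, and no
artifact screen fired (same-gene-family pair, transcriptional readthrough,
or a frequently repeated pair absent from the known-fusion table).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .knowledge import KnowledgeBase
from .types import Biotype, FusionCandidate


class RejectReason(str, enum.Enum):
    NON_CODING_PARTNER = "non_coding_partner"
    OFF_EXON_BOUNDARY = "off_exon_boundary"
    LOW_READ_FRACTION = "low_read_fraction"
    LOW_EXPRESSION_SUPPORT = "low_expression_support"
    GENE_FAMILY = "gene_family"
    READTHROUGH = "readthrough"
    RECURRENT_ARTIFACT = "recurrent_artifact"
    UNEVALUABLE = "unevaluable"


class Frame(str, enum.Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    UNKNOWN = "unknown"


class Novelty(str, enum.Enum):
    NOVEL = "novel"
    KNOWN = "known"


@dataclass(frozen=True)
class FusionFilterConfig:
    """All thresholds of the acceptance criteria, with assay defaults."""

    exon_boundary_tolerance_bp: int = 15  # inclusive
    read_fraction_threshold: float = 0.10  # inclusive
    expression_support_factor: float = 2.0  # total reads >= factor * region median
    readthrough_window_bp: int = 200_000
    recurrent_fraction: float = 0.20  # strict: artifact when pair in > this fraction


@dataclass
class TranscriptModel:
    """Minimal transcript model: ordered exons in 1-based transcript coordinates.

    ``exons`` are (start, end) inclusive intervals in transcript coordinates,
    ordered 5'->3' and contiguous (exon i+1 starts at end_i + 1); CDS start
    and end are transcript coordinates.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    genomic_start: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.exons:
            if s != prev_end + 1 or e < s:
                raise ValueError(
                    f"{self.transcript_id}: exons must be ordered, contiguous 1-based intervals"
                )
            prev_end = e
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript bounds")

    @property
    def length(self) -> int:
        return self.exons[-1][1]

    def exon_label(self, index: int) -> str:
        """1-based exon label, e.g. 'e5'."""
        return f"e{index}"


class AnnotationError(Exception):
    pass


TRANSCRIPT_COLUMNS = [
    "gene",
    "transcript_id",
    "chrom",
    "strand",
    "genomic_start",
    "exon_index",
    "exon_start",
    "exon_end",
    "cds_start",
    "cds_end",
]


def write_transcripts(models: dict[str, TranscriptModel], path: str | Path) -> None:
    """Write transcript models as a GTF-like exon-per-row TSV."""
    rows = []
    for tx in models.values():
        for i, (s, e) in enumerate(tx.exons, start=1):
            rows.append(
                {
                    "gene": tx.gene,
                    "transcript_id": tx.transcript_id,
                    "chrom": tx.chrom,
                    "strand": tx.strand,
                    "genomic_start": tx.genomic_start,
                    "exon_index": i,
                    "exon_start": s,
                    "exon_end": e,
                    "cds_start": tx.cds_start,
                    "cds_end": tx.cds_end,
                }
            )
    pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcripts(path: str | Path) -> dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    models: dict[str, TranscriptModel] = {}
    for tx_id, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("exon_index")
        first = grp.iloc[0]
        models[str(tx_id)] = TranscriptModel(
            gene=str(first["gene"]),
            transcript_id=str(tx_id),
            chrom=str(first["chrom"]),
            strand=str(first["strand"]),
            genomic_start=int(first["genomic_start"]),
            exons=[(int(r.exon_start), int(r.exon_end)) for r in grp.itertuples()],
            cds_start=int(first["cds_start"]),
            cds_end=int(first["cds_end"]),
        )
    return models


FUSION_COLUMNS = [
    "sample_id",
    "gene5",
    "gene3",
    "transcript5",
    "transcript3",
    "chrom5",
    "chrom3",
    "strand5",
    "strand3",
    "breakpoint5",
    "breakpoint3",
    "genomic_pos5",
    "genomic_pos3",
    "crossing_reads",
    "total_reads_at_location",
    "region_median_reads",
    "biotype5",
    "biotype3",
]


def write_fusion_candidates(candidates: list[FusionCandidate], path: str | Path) -> None:
    rows = [{c: getattr(cand, c) for c in FUSION_COLUMNS} for cand in candidates]
    for r in rows:
        r["biotype5"] = r["biotype5"].value
        r["biotype3"] = r["biotype3"].value
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fusion_candidates(path: str | Path) -> list[FusionCandidate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        out.append(
            FusionCandidate(
                sample_id=str(d["sample_id"]),
                gene5=str(d["gene5"]),
                gene3=str(d["gene3"]),
                transcript5=str(d["transcript5"]),
                transcript3=str(d["transcript3"]),
                chrom5=str(d["chrom5"]),
                chrom3=str(d["chrom3"]),
                strand5=str(d["strand5"]),
                strand3=str(d["strand3"]),
                breakpoint5=int(d["breakpoint5"]),
                breakpoint3=int(d["breakpoint3"]),
                genomic_pos5=int(d["genomic_pos5"]),
                genomic_pos3=int(d["genomic_pos3"]),
                crossing_reads=int(d["crossing_reads"]),
                total_reads_at_location=int(d["total_reads_at_location"]),
                region_median_reads=float(d["region_median_reads"]),
                biotype5=Biotype(d["biotype5"]),
                biotype3=Biotype(d["biotype3"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-candidate criteria
# ---------------------------------------------------------------------------

def check_exon_boundary(
    candidate: FusionCandidate,
    transcripts: dict[str, TranscriptModel],
    tolerance_bp: int = 15,
) -> tuple[bool, str | None, bool, str | None]:
    """Check both breakpoints against annotated exon edges.

    The 5' breakpoint must lie within ``tolerance_bp`` (inclusive) of the 3'
    edge (end) of some exon of the 5' transcript; the 3' breakpoint within
    tolerance of the 5' edge (start) of some exon of the 3' transcript.
    Returns ``(ok5, exon_label5, ok3, exon_label3)``; an unknown transcript
    raises :class:`AnnotationError`.
    """
    for side in ("transcript5", "transcript3"):
        if getattr(candidate, side) not in transcripts:
            raise AnnotationError(
                f"{candidate.sample_id} {candidate.gene5}::{candidate.gene3}: "
                f"unknown transcript {getattr(candidate, side)!r}"
            )
    t5 = transcripts[candidate.transcript5]
    t3 = transcripts[candidate.transcript3]

    ok5, label5 = False, None
    best5 = None
    for i, (_, end) in enumerate(t5.exons, start=1):
        d = abs(candidate.breakpoint5 - end)
        if best5 is None or d < best5[0]:
            best5 = (d, i)
    if best5 is not None and best5[0] <= tolerance_bp:
        ok5, label5 = True, t5.exon_label(best5[1])

    ok3, label3 = False, None
    best3 = None
    for i, (start, _) in enumerate(t3.exons, start=1):
        d = abs(candidate.breakpoint3 - start)
        if best3 is None or d < best3[0]:
            best3 = (d, i)
    if best3 is not None and best3[0] <= tolerance_bp:
        ok3, label3 = True, t3.exon_label(best3[1])

    return ok5, label5, ok3, label3


def read_fraction_filter(candidate: FusionCandidate, threshold: float = 0.10) -> bool:
    """Crossing-read fraction gate: pass iff crossing/total >= threshold.

    A zero read total makes the candidate unevaluable (handled by the caller
    as a rejection).
    """
    if candidate.total_reads_at_location <= 0:
        raise ValueError("total_reads_at_location must be positive")
    return candidate.crossing_reads / candidate.total_reads_at_location >= threshold


def expression_support_filter(candidate: FusionCandidate, factor: float = 2.0) -> bool:
    """Substantial-expression screen against the cohort median at the region."""
    return candidate.total_reads_at_location >= factor * candidate.region_median_reads


def is_readthrough(candidate: FusionCandidate, window_bp: int = 200_000) -> bool:
    """Transcriptional readthrough geometry.

    Same chromosome, same strand, partners within ``window_bp`` and ordered
    consistently with the direction of transcription (5' partner genomically
    upstream on '+', downstream on '-').
    """
    if candidate.chrom5 != candidate.chrom3 or candidate.strand5 != candidate.strand3:
        return False
    distance = abs(candidate.genomic_pos3 - candidate.genomic_pos5)
    if distance > window_bp:
        return False
    if candidate.strand5 == "+":
        return candidate.genomic_pos5 < candidate.genomic_pos3
    return candidate.genomic_pos5 > candidate.genomic_pos3


def exclusion_screen(
    candidate: FusionCandidate,
    kb: KnowledgeBase,
    pair_sample_fraction: dict[tuple[str, str], float] | None = None,
    config: FusionFilterConfig = FusionFilterConfig(),
) -> set[RejectReason]:
    """Artifact screens: biotype, gene family, readthrough, recurrence.

    ``pair_sample_fraction`` maps gene pairs to the fraction of cohort samples
    carrying a candidate with that pair; when absent the recurrence screen is
    disabled.  Known fusions are never flagged as recurrent artifacts.
    """
    reasons: set[RejectReason] = set()
    if candidate.biotype5 is not Biotype.PROTEIN_CODING or candidate.biotype3 is not Biotype.PROTEIN_CODING:
        reasons.add(RejectReason.NON_CODING_PARTNER)
    if kb.same_family(candidate.gene5, candidate.gene3):
        reasons.add(RejectReason.GENE_FAMILY)
    if is_readthrough(candidate, config.readthrough_window_bp):
        reasons.add(RejectReason.READTHROUGH)
    if pair_sample_fraction is not None:
        frac = pair_sample_fraction.get(candidate.pair, 0.0)
        if frac > config.recurrent_fraction and not kb.is_known_fusion(*candidate.pair):
            reasons.add(RejectReason.RECURRENT_ARTIFACT)
    return reasons


def predict_frame(
    candidate: FusionCandidate, transcripts: dict[str, TranscriptModel]
) -> Frame:
    """Predict the reading frame of the chimeric transcript.

    The junction preserves frame when the retained 5' CDS length and the
    codon-phase offset of the 3' breakpoint agree modulo 3; breakpoints
    outside either CDS give ``unknown``.
    """
    t5 = transcripts.get(candidate.transcript5)
    t3 = transcripts.get(candidate.transcript3)
    if t5 is None or t3 is None:
        return Frame.UNKNOWN
    b5, b3 = candidate.breakpoint5, candidate.breakpoint3
    if not (t5.cds_start <= b5 <= t5.cds_end):
        return Frame.UNKNOWN
    if not (t3.cds_start <= b3 <= t3.cds_end):
        return Frame.UNKNOWN
    retained5 = b5 - t5.cds_start + 1
    phase3 = (b3 - t3.cds_start) % 3
    return Frame.IN_FRAME if retained5 % 3 == phase3 else Frame.FRAMESHIFT


@dataclass
class FusionVerdict:
    candidate: FusionCandidate
    accepted: bool
    reasons: set[RejectReason] = field(default_factory=set)
    frame: Frame = Frame.UNKNOWN
    novelty: Novelty = Novelty.NOVEL
    exon_junction: tuple[str | None, str | None] = (None, None)

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must hold exactly when no rejection reason fired")


def evaluate_candidate(
    candidate: FusionCandidate,
    transcripts: dict[str, TranscriptModel],
    kb: KnowledgeBase,
    pair_sample_fraction: dict[tuple[str, str], float] | None,
    config: FusionFilterConfig = FusionFilterConfig(),
) -> FusionVerdict:
    """Apply every acceptance criterion to one candidate."""
    reasons: set[RejectReason] = set()
    junction: tuple[str | None, str | None] = (None, None)
    try:
        ok5, label5, ok3, label3 = check_exon_boundary(
            candidate, transcripts, config.exon_boundary_tolerance_bp
        )
        junction = (label5, label3)
        if not (ok5 and ok3):
            reasons.add(RejectReason.OFF_EXON_BOUNDARY)
    except AnnotationError:
        reasons.add(RejectReason.UNEVALUABLE)

    try:
        if not read_fraction_filter(candidate, config.read_fraction_threshold):
            reasons.add(RejectReason.LOW_READ_FRACTION)
    except ValueError:
        reasons.add(RejectReason.UNEVALUABLE)

    if not expression_support_filter(candidate, config.expression_support_factor):
        reasons.add(RejectReason.LOW_EXPRESSION_SUPPORT)

    reasons |= exclusion_screen(candidate, kb, pair_sample_fraction, config)

    return FusionVerdict(
        candidate=candidate,
        accepted=not reasons,
        reasons=reasons,
        frame=predict_frame(candidate, transcripts),
        novelty=Novelty.KNOWN if kb.is_known_fusion(*candidate.pair) else Novelty.NOVEL,
        exon_junction=junction,
    )


def pair_sample_fractions(
    candidates: list[FusionCandidate], n_samples: int
) -> dict[tuple[str, str], float]:
    """Fraction of cohort samples in which each gene pair appears as a candidate."""
    samples_by_pair: dict[tuple[str, str], set[str]] = {}
    for c in candidates:
        samples_by_pair.setdefault(c.pair, set()).add(c.sample_id)
    return {p: len(s) / n_samples for p, s in samples_by_pair.items()}


def filter_cohort(
    candidates: list[FusionCandidate],
    transcripts: dict[str, TranscriptModel],
    kb: KnowledgeBase,
    n_samples: int,
    config: FusionFilterConfig = FusionFilterConfig(),
) -> list[FusionVerdict]:
    """Evaluate every candidate in cohort context.

    Errors on individual candidates become rejections with an explicit
    reason; the cohort run never aborts.
    """
    fractions = pair_sample_fractions(candidates, n_samples)
    return [
        evaluate_candidate(c, transcripts, kb, fractions, config) for c in candidates
    ]


def summarize_fusions(verdicts: list[FusionVerdict], n_samples: int) -> dict:
    """Cohort-level fusion summary from per-candidate verdicts."""
    accepted = [v for v in verdicts if v.accepted]
    samples = sorted({v.candidate.sample_id for v in accepted})
    pairs = sorted({v.candidate.pair for v in accepted})
    # distinct fusion events: same gene pair with different breakpoints counts twice
    events = sorted(
        {(v.candidate.pair, v.candidate.breakpoint5, v.candidate.breakpoint3) for v in accepted}
    )
    pair_counts: dict[tuple[str, str], int] = {}
    partner3_counts: dict[str, int] = {}
    for v in accepted:
        pair_counts[v.candidate.pair] = pair_counts.get(v.candidate.pair, 0) + 1
        g3 = v.candidate.gene3
        partner3_counts[g3] = partner3_counts.get(g3, 0) + 1
    return {
        "n_candidates": len(verdicts),
        "n_accepted": len(accepted),
        "n_rejected": len(verdicts) - len(accepted),
        "positive_samples": samples,
        "n_positive_samples": len(samples),
        "percent_positive_samples": 100.0 * len(samples) / n_samples if n_samples else 0.0,
        "distinct_pairs": pairs,
        "n_distinct_pairs": len(pairs),
        "n_distinct_fusions": len(events),
        "recurrent_pairs": sorted(p for p, k in pair_counts.items() if k > 1),
        "recurrent_3prime_partners": sorted(g for g, k in partner3_counts.items() if k > 1),
        "n_novel": sum(1 for v in accepted if v.novelty is Novelty.NOVEL),
        "n_known": sum(1 for v in accepted if v.novelty is Novelty.KNOWN),
    }


def verdicts_to_frame(verdicts: list[FusionVerdict]) -> pd.DataFrame:
    """Flatten verdicts into a TSV-ready table."""
    rows = []
    for v in verdicts:
        c = v.candidate
        rows.append(
            {
                "sample_id": c.sample_id,
                "gene5": c.gene5,
                "gene3": c.gene3,
                "accepted": int(v.accepted),
                "reasons": ",".join(sorted(r.value for r in v.reasons)) or ".",
                "frame": v.frame.value,
                "novelty": v.novelty.value,
                "exon_junction": f"{v.exon_junction[0] or '?'}-{v.exon_junction[1] or '?'}",
                "crossing_reads": c.crossing_reads,
                "total_reads_at_location": c.total_reads_at_location,
            }
        )
    return pd.DataFrame(rows)
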