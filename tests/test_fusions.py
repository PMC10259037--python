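"""Fusion acceptance criteria: exon boundaries, read fractions, artifact
screens, frame prediction, and equivalence with an independent brute-force
re-evaluation of every criterion."""

import numpy as np
import pytest

from occc_molpro.fusions import (
    Frame,
    FusionFilterConfig,
    Novelty,
    RejectReason,
    TranscriptModel,
    check_exon_boundary,
    evaluate_candidate,
    filter_cohort,
    is_readthrough,
    pair_sample_fractions,
    predict_frame,
    read_fraction_filter,
    summarize_fusions,
)
from occc_molpro.knowledge import KnowledgeBase
from occc_molpro.synthetic import CohortSpec, build_fusion_annotation
from occc_molpro.types import Biotype, FusionCandidate


def make_tx(gene="GA", tx="TXA", n_exons=5, exon_len=100, cds_start=10, **kw):
    defaults = dict(
        gene=gene, transcript_id=tx, chrom="1", strand="+", genomic_start=1_000_000,
        exons=[(i * exon_len + 1, (i + 1) * exon_len) for i in range(n_exons)],
        cds_start=cds_start, cds_end=n_exons * exon_len - 20,
    )
    defaults.update(kw)
    return TranscriptModel(**defaults)


def make_candidate(**kw):
    defaults = dict(
        sample_id="R001", gene5="GA", gene3="GB", transcript5="TXA", transcript3="TXB",
        chrom5="1", chrom3="2", strand5="+", strand3="+",
        breakpoint5=300, breakpoint3=201, genomic_pos5=1_000_300, genomic_pos3=5_000_201,
        crossing_reads=50, total_reads_at_location=200, region_median_reads=50.0,
    )
    defaults.update(kw)
    return FusionCandidate(**defaults)


@pytest.fixture()
def two_transcripts():
    return {
        "TXA": make_tx(),
        "TXB": make_tx(gene="GB", tx="TXB", chrom="2", genomic_start=5_000_000),
    }


@pytest.mark.parametrize(
    "offset, ok",
    [(0, True), (15, True), (-15, True), (16, False), (-16, False)],
)
def test_exon_boundary_tolerance_inclusive(two_transcripts, offset, ok):
    """The +-15 bp window around an exon edge is boundary-inclusive."""
    cand = make_candidate(breakpoint5=300 + offset)
    ok5, label5, ok3, _ = check_exon_boundary(cand, two_transcripts)
    assert ok5 is ok
    assert ok3
    if ok:
        assert label5 == "e3"


def test_exon_boundary_unknown_transcript_is_error(two_transcripts):
    cand = make_candidate(transcript5="MISSING")
    from occc_molpro.fusions import AnnotationError

    with pytest.raises(AnnotationError):
        check_exon_boundary(cand, two_transcripts)


@pytest.mark.parametrize(
    "crossing, total, ok",
    [(3729, 6307, True), (10, 100, True), (9, 100, False)],
)
def test_read_fraction_threshold_inclusive(crossing, total, ok):
    cand = make_candidate(crossing_reads=crossing, total_reads_at_location=total)
    assert read_fraction_filter(cand) is ok


def test_readthrough_geometry():
    """Adjacent same-strand pair 40 kb apart is a readthrough; different
    chromosomes never are."""
    rt = make_candidate(chrom5="1", chrom3="1", strand5="+", strand3="+",
                        genomic_pos5=1_000_000, genomic_pos3=1_040_000)
    assert is_readthrough(rt)
    far = make_candidate(chrom5="1", chrom3="1", strand5="+", strand3="+",
                         genomic_pos5=1_000_000, genomic_pos3=1_300_000)
    assert not is_readthrough(far)
    diff_chrom = make_candidate(genomic_pos5=1_000_000, genomic_pos3=1_040_000)
    assert not is_readthrough(diff_chrom)
    wrong_order = make_candidate(chrom5="1", chrom3="1", strand5="+", strand3="+",
                                 genomic_pos5=1_040_000, genomic_pos3=1_000_000)
    assert not is_readthrough(wrong_order)
    minus = make_candidate(chrom5="1", chrom3="1", strand5="-", strand3="-",
                           genomic_pos5=1_040_000, genomic_pos3=1_000_000)
    assert is_readthrough(minus)


def test_frame_codon_boundaries(two_transcripts):
    """Both breakpoints at codon boundaries preserve the frame (0 mod 3)."""
    # TXA cds_start 10: retained = b5 - 10 + 1 ; TXB phase = (b3 - 10) % 3
    cand = make_candidate(breakpoint5=10 + 2, breakpoint3=10)  # retained 3, phase 0
    assert predict_frame(cand, two_transcripts) is Frame.IN_FRAME
    shifted = make_candidate(breakpoint5=10 + 3, breakpoint3=10)  # retained 4
    assert predict_frame(shifted, two_transcripts) is Frame.FRAMESHIFT
    outside_cds = make_candidate(breakpoint5=5, breakpoint3=10)
    assert predict_frame(outside_cds, two_transcripts) is Frame.UNKNOWN


def test_table_fixture_frames_match_planted_annotations():
    """The bundled fusion annotation realizes the printed frame calls
    (LAMB1::MET in-frame, CCDC3::AKT3 frameshift) at the printed junctions."""
    spec = CohortSpec()
    annotation = build_fusion_annotation(spec)
    by_pair = {(f["gene5"], f["gene3"]): f for f in spec.planted_fusions}

    lamb1 = by_pair[("LAMB1", "MET")]
    cand = make_candidate(
        gene5="LAMB1", gene3="MET", transcript5=lamb1["tx5"], transcript3=lamb1["tx3"],
        breakpoint5=lamb1["b5"], breakpoint3=lamb1["b3"],
    )
    assert predict_frame(cand, annotation) is Frame.IN_FRAME
    ok5, l5, ok3, l3 = check_exon_boundary(cand, annotation)
    assert ok5 and ok3 and (l5, l3) == ("e5", "e13")

    ccdc3 = by_pair[("CCDC3", "AKT3")]
    cand = make_candidate(
        gene5="CCDC3", gene3="AKT3", transcript5=ccdc3["tx5"], transcript3=ccdc3["tx3"],
        breakpoint5=ccdc3["b5"], breakpoint3=ccdc3["b3"],
    )
    assert predict_frame(cand, annotation) is Frame.FRAMESHIFT
    ok5, l5, ok3, l3 = check_exon_boundary(cand, annotation)
    assert ok5 and ok3 and (l5, l3) == ("e2", "e3")


def test_known_fusion_retained_not_artifact(default_bundle):
    """TFG::ADGRG7 recurs but sits in the known-fusion table: retained and
    marked known, never flagged as a recurrent artifact."""
    verdicts = filter_cohort(
        default_bundle.fusion_candidates, default_bundle.transcripts,
        default_bundle.kb, default_bundle.spec.n_rna_samples,
    )
    tfg = [v for v in verdicts if v.candidate.pair == ("TFG", "ADGRG7")]
    assert len(tfg) == 2
    assert all(v.accepted and v.novelty is Novelty.KNOWN for v in tfg)


def test_novelty_is_pure_lookup(default_bundle):
    """Emptying the known-fusion table makes every accepted fusion novel."""
    kb_empty = KnowledgeBase(
        gene_families=default_bundle.kb.gene_families,
        known_fusion_pairs=frozenset(),
        coding_regions=dict(default_bundle.kb.coding_regions),
    )
    verdicts = filter_cohort(
        default_bundle.fusion_candidates, default_bundle.transcripts,
        kb_empty, default_bundle.spec.n_rna_samples,
    )
    assert all(v.novelty is Novelty.NOVEL for v in verdicts if v.accepted)


def test_every_rejection_has_reason_and_partition(default_bundle, pipeline_result):
    verdicts = filter_cohort(
        default_bundle.fusion_candidates, default_bundle.transcripts,
        default_bundle.kb, default_bundle.spec.n_rna_samples,
    )
    accepted = [v for v in verdicts if v.accepted]
    rejected = [v for v in verdicts if not v.accepted]
    assert len(accepted) + len(rejected) == len(verdicts)
    assert all(len(v.reasons) >= 1 for v in rejected)


def test_threshold_monotonicity(default_bundle):
    """Raising the read-fraction threshold never enlarges the accepted set."""
    prev = None
    for thr in (0.05, 0.10, 0.30, 0.60):
        cfg = FusionFilterConfig(read_fraction_threshold=thr)
        verdicts = filter_cohort(
            default_bundle.fusion_candidates, default_bundle.transcripts,
            default_bundle.kb, default_bundle.spec.n_rna_samples, cfg,
        )
        accepted = {
            (v.candidate.sample_id, v.candidate.pair) for v in verdicts if v.accepted
        }
        if prev is not None:
            assert accepted <= prev
        prev = accepted


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------

def brute_force_verdict(cand, transcripts, kb, fractions, cfg):
    """Independent criterion-by-criterion re-evaluation (plain loops over the
    raw fields, no calls into the filter implementation)."""
    reasons = set()
    t5 = transcripts.get(cand.transcript5)
    t3 = transcripts.get(cand.transcript3)
    if t5 is None or t3 is None:
        reasons.add("unevaluable")
    else:
        dist5 = min(abs(cand.breakpoint5 - e) for _, e in t5.exons)
        dist3 = min(abs(cand.breakpoint3 - s) for s, _ in t3.exons)
        if dist5 > cfg.exon_boundary_tolerance_bp or dist3 > cfg.exon_boundary_tolerance_bp:
            reasons.add("off_exon_boundary")
    if cand.total_reads_at_location <= 0:
        reasons.add("unevaluable")
    elif cand.crossing_reads / cand.total_reads_at_location < cfg.read_fraction_threshold:
        reasons.add("low_read_fraction")
    if cand.total_reads_at_location < cfg.expression_support_factor * cand.region_median_reads:
        reasons.add("low_expression_support")
    if cand.biotype5 != Biotype.PROTEIN_CODING or cand.biotype3 != Biotype.PROTEIN_CODING:
        reasons.add("non_coding_partner")
    fam5 = kb.gene_families.get(cand.gene5)
    fam3 = kb.gene_families.get(cand.gene3)
    if fam5 is not None and fam5 == fam3:
        reasons.add("gene_family")
    if cand.chrom5 == cand.chrom3 and cand.strand5 == cand.strand3:
        d = abs(cand.genomic_pos3 - cand.genomic_pos5)
        upstream = (
            cand.genomic_pos5 < cand.genomic_pos3
            if cand.strand5 == "+"
            else cand.genomic_pos5 > cand.genomic_pos3
        )
        if d <= cfg.readthrough_window_bp and upstream:
            reasons.add("readthrough")
    frac = fractions.get((cand.gene5, cand.gene3), 0.0)
    if frac > cfg.recurrent_fraction and (cand.gene5, cand.gene3) not in kb.known_fusion_pairs:
        reasons.add("recurrent_artifact")
    return reasons


def test_filter_agrees_with_brute_force_oracle_on_random_candidates(default_bundle):
    """1,000 randomized candidates: the filter and an independent
    re-evaluation of every criterion give identical verdicts and reasons."""
    rng = np.random.default_rng(2024)
    transcripts = default_bundle.transcripts
    kb = default_bundle.kb
    cfg = FusionFilterConfig()
    tx_ids = sorted(transcripts)
    genes_extra = ["HLA-A", "HLA-B", "ARTF1", "ARTF2"]

    candidates = []
    for i in range(1000):
        t5 = transcripts[tx_ids[rng.integers(len(tx_ids))]]
        t3 = transcripts[tx_ids[rng.integers(len(tx_ids))]]
        total = int(rng.integers(1, 5000))
        cand = FusionCandidate(
            sample_id=f"R{int(rng.integers(1, 106)):03d}",
            gene5=t5.gene if rng.random() > 0.1 else genes_extra[rng.integers(4)],
            gene3=t3.gene if rng.random() > 0.1 else genes_extra[rng.integers(4)],
            transcript5=t5.transcript_id, transcript3=t3.transcript_id,
            chrom5=t5.chrom, chrom3=t3.chrom, strand5=t5.strand, strand3=t3.strand,
            breakpoint5=int(rng.integers(1, t5.length + 1)),
            breakpoint3=int(rng.integers(1, t3.length + 1)),
            genomic_pos5=int(t5.genomic_start + rng.integers(0, 300_000)),
            genomic_pos3=int(t3.genomic_start + rng.integers(0, 300_000)),
            crossing_reads=int(rng.integers(0, total + 1)),
            total_reads_at_location=total,
            region_median_reads=float(rng.integers(1, 2000)),
            biotype5=Biotype.PROTEIN_CODING if rng.random() > 0.05 else Biotype.OTHER,
            biotype3=Biotype.PROTEIN_CODING if rng.random() > 0.05 else Biotype.OTHER,
        )
        candidates.append(cand)

    fractions = pair_sample_fractions(candidates, 105)
    for cand in candidates:
        verdict = evaluate_candidate(cand, transcripts, kb, fractions, cfg)
        expected = brute_force_verdict(cand, transcripts, kb, fractions, cfg)
        got = {r.value for r in verdict.reasons}
        assert got == expected, f"{cand.gene5}::{cand.gene3} {got} != {expected}"
        assert verdict.accepted == (not expected)


def test_cohort_summary_counts(default_bundle):
    verdicts = filter_cohort(
        default_bundle.fusion_candidates, default_bundle.transcripts,
        default_bundle.kb, default_bundle.spec.n_rna_samples,
    )
    summary = summarize_fusions(verdicts, default_bundle.spec.n_rna_samples)
    assert summary["n_positive_samples"] == 14
    assert summary["n_distinct_fusions"] == 13
    assert summary["n_known"] == 7 and summary["n_novel"] == 7
    assert ("TFG", "ADGRG7") in summary["recurrent_pairs"]
    assert "MET" in summary["recurrent_3prime_partners"]
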