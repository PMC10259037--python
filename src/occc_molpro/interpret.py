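"""Deleterious (class 4/5) variant classification and molecular subtyping.

The rule set: every frameshift, nonsense, no-start, no-stop, or
consensus-splice-site variant is deleterious regardless of database class;
a missense variant is deleterious only when its ClinVar-style class is
pathogenic or likely pathogenic.  One recurrent POLE nonsense variant is
known not to produce the ultramutated phenotype and is excluded from POLE
driver status (it still counts toward mutation burden, which is
classification-blind).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import pandas as pd

from .knowledge import KnowledgeBase
from .types import (
    ClinVarClass,
    Consequence,
    MolecularSubtype,
    TRUNCATING_CONSEQUENCES,
    VariantRecord,
)

logger = logging.getLogger(__name__)


class ClassificationRule(str, enum.Enum):
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    NO_START = "no_start"
    NO_STOP = "no_stop"
    SPLICE_CONSENSUS = "splice_consensus"
    CLINVAR_PATHOGENIC_MISSENSE = "clinvar_pathogenic_missense"
    EXCLUDED_POLE_NONSENSE = "excluded_pole_nonsense"
    NONE = "none"


@dataclass
class Classification:
    is_class45: bool
    rule_fired: ClassificationRule
    notes: str = ""

    def __post_init__(self) -> None:
        expected = self.rule_fired not in (
            ClassificationRule.NONE,
            ClassificationRule.EXCLUDED_POLE_NONSENSE,
        )
        if self.is_class45 != expected:
            raise ValueError(
                f"is_class45={self.is_class45} inconsistent with rule {self.rule_fired}"
            )


_TRUNCATING_RULES = {
    Consequence.FRAMESHIFT: ClassificationRule.FRAMESHIFT,
    Consequence.NONSENSE: ClassificationRule.NONSENSE,
    Consequence.NO_START: ClassificationRule.NO_START,
    Consequence.NO_STOP: ClassificationRule.NO_STOP,
    Consequence.SPLICE_CONSENSUS: ClassificationRule.SPLICE_CONSENSUS,
}


def classify_variant(variant: VariantRecord, kb: KnowledgeBase) -> Classification:
    """Classify one variant as deleterious (class 4/5) or not.

    Pure and deterministic.  The excluded POLE nonsense is identified by its
    ``transcript:hgvs_c`` key in ``kb.excluded_pole_variants``.
    """
    cons = variant.consequence
    if cons in TRUNCATING_CONSEQUENCES:
        if cons is Consequence.NONSENSE and variant.gene == "POLE":
            key = f"{variant.transcript_id}:{variant.hgvs_c}" if variant.transcript_id else variant.hgvs_c
            if key in kb.excluded_pole_variants or variant.hgvs_c in kb.excluded_pole_variants:
                return Classification(
                    False,
                    ClassificationRule.EXCLUDED_POLE_NONSENSE,
                    "POLE nonsense without ultramutated phenotype",
                )
        return Classification(True, _TRUNCATING_RULES[cons])
    if cons is Consequence.MISSENSE:
        if variant.clinvar_class in (ClinVarClass.PATHOGENIC, ClinVarClass.LIKELY_PATHOGENIC):
            return Classification(True, ClassificationRule.CLINVAR_PATHOGENIC_MISSENSE)
        return Classification(False, ClassificationRule.NONE)
    if isinstance(cons, Consequence):
        # synonymous, inframe indel, promoter, other non-coding
        return Classification(False, ClassificationRule.NONE)
    raise ValueError(f"unknown consequence token {cons!r}")


def call_tertp(variants: list[VariantRecord], kb: KnowledgeBase) -> bool:
    """TERT promoter hotspot call for one sample.

    Positive iff at least one TERT variant's HGVS c. string matches the
    hotspot set exactly; absence of variants is a negative call.
    """
    return any(v.gene == "TERT" and v.hgvs_c in kb.tertp_hotspots for v in variants)


@dataclass
class GeneStatusMatrix:
    """Sample x gene boolean class 4/5 status matrix with a TERTp column.

    ``support`` maps ``(sample_id, gene)`` to the variants backing a true
    cell; a cell is true iff at least one supporting variant exists.
    """

    status: pd.DataFrame  # bool, index=sample_id, columns=genes
    tertp: pd.Series  # bool, index=sample_id
    support: dict[tuple[str, str], list[VariantRecord]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.status.index)

    def gene_counts(self) -> pd.Series:
        """Mutated-sample count per gene (sample-level, not variant-level)."""
        return self.status.sum(axis=0).astype(int)

    def gene_percentages(self) -> pd.Series:
        """Mutated-sample percentage per gene over non-missing samples."""
        return 100.0 * self.status.mean(axis=0)

    def tertp_count(self) -> int:
        return int(self.tertp.sum())

    def tertp_percentage(self) -> float:
        return 100.0 * float(self.tertp.mean())

    def recurrent_view(self, min_samples: int = 2) -> pd.DataFrame:
        """Genes mutated in at least ``min_samples`` samples (oncoprint filter)."""
        counts = self.gene_counts()
        keep = counts[counts >= min_samples].index
        return self.status.loc[:, keep]


def build_gene_status_matrix(
    variants: list[VariantRecord],
    kb: KnowledgeBase,
    sample_ids: list[str] | None = None,
) -> GeneStatusMatrix:
    """Classify a cohort's variants into a gene-level status matrix.

    Counting is sample-level: multiple qualifying variants in one gene of one
    sample set a single cell.  Duplicate (sample, variant) rows are
    deduplicated with a warning.  ``sample_ids`` fixes the sample universe
    (samples with no variants get all-false rows); by default it is the set of
    samples seen in the input, in first-appearance order.
    """
    seen: set[tuple] = set()
    unique: list[VariantRecord] = []
    for v in variants:
        key = (v.sample_id, v.gene, v.chrom, v.pos, v.ref, v.alt, v.hgvs_c)
        if key in seen:
            logger.warning("duplicate variant row dropped: %s %s %s", v.sample_id, v.gene, v.hgvs_c)
            continue
        seen.add(key)
        unique.append(v)

    if sample_ids is None:
        sample_ids = list(dict.fromkeys(v.sample_id for v in unique))

    genes = sorted({v.gene for v in unique if v.gene and v.gene != "TERT"})
    status = pd.DataFrame(False, index=pd.Index(sample_ids, name="sample_id"), columns=genes, dtype=bool)
    support: dict[tuple[str, str], list[VariantRecord]] = {}
    by_sample: dict[str, list[VariantRecord]] = {s: [] for s in sample_ids}
    for v in unique:
        by_sample.setdefault(v.sample_id, []).append(v)
        cls = classify_variant(v, kb)
        if cls.is_class45 and v.gene in status.columns and v.sample_id in status.index:
            status.loc[v.sample_id, v.gene] = True
            support.setdefault((v.sample_id, v.gene), []).append(v)
    tertp = pd.Series(
        {s: call_tertp(by_sample.get(s, []), kb) for s in sample_ids}, name="TERTp"
    ).reindex(sample_ids)
    return GeneStatusMatrix(status=status, tertp=tertp, support=support)


def pole_mut_status(variants: list[VariantRecord], kb: KnowledgeBase) -> bool:
    """POLE driver status: >=1 class 4/5 POLE variant outside the excluded set."""
    return any(
        v.gene == "POLE" and classify_variant(v, kb).is_class45 for v in variants
    )


def assign_subtype(
    pole_mut: bool | None,
    msi_high: bool | None,
    tp53_class45: bool | None,
) -> MolecularSubtype:
    """Assign the TCGA-style molecular subtype by hierarchical precedence.

    POLEmut > MSI-High > p53abn > NSMP; a sample that is both POLE-mutated and
    MSI-High is POLEmut.  Any missing input status makes the sample
    not-evaluable — never silently NSMP.
    """
    if pole_mut is None or msi_high is None or tp53_class45 is None:
        return MolecularSubtype.NOT_EVALUABLE
    if pole_mut:
        return MolecularSubtype.POLEMUT
    if msi_high:
        return MolecularSubtype.MSI_HIGH
    if tp53_class45:
        return MolecularSubtype.P53ABN
    return MolecularSubtype.NSMP
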