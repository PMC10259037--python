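"""Core domain types shared by every pipeline stage.

All genomic coordinates in this package are 1-based inclusive (HGVS/VCF
convention).  Conversion to and from half-open BED-style intervals lives in
:mod:`occc_molpro.io`; nothing else does coordinate arithmetic across
conventions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Consequence(str, enum.Enum):
    """Coding-effect category of a variant call, as annotated upstream."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_CONSENSUS = "splice_consensus"
    NO_START = "no_start"
    NO_STOP = "no_stop"
    SYNONYMOUS = "synonymous"
    PROMOTER = "promoter"
    OTHER_NONCODING = "other_noncoding"

    @property
    def is_coding(self) -> bool:
        """Whether the variant falls in annotated coding territory.

        Promoter and other non-coding calls never count toward panel TMB.
        """
        return self not in (Consequence.PROMOTER, Consequence.OTHER_NONCODING)


#: Consequences that are deleterious by category alone, independent of any
#: database classification (truncating or consensus-splice-site events).
TRUNCATING_CONSEQUENCES = frozenset(
    {
        Consequence.FRAMESHIFT,
        Consequence.NONSENSE,
        Consequence.NO_START,
        Consequence.NO_STOP,
        Consequence.SPLICE_CONSENSUS,
    }
)


class ClinVarClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    ABSENT = "absent"


@dataclass
class VariantRecord:
    """One annotated somatic variant call in one sample.

    ``allele_frequency`` may be ``None`` when the caller did not report it;
    missingness is explicit, never a silent 0.  The assay cannot distinguish
    somatic from germline events, so no such field exists; population-database
    presence (``in_polymorphism_db``) is the only germline proxy carried.
    """

    sample_id: str
    gene: str
    transcript_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    hgvs_p: str
    consequence: Consequence
    allele_frequency: float | None
    clinvar_class: ClinVarClass = ClinVarClass.ABSENT
    in_polymorphism_db: bool = False
    known_driver: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.allele_frequency is not None and not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(f"allele_frequency {self.allele_frequency} outside [0, 1]")
        if not isinstance(self.consequence, Consequence):
            self.consequence = Consequence(self.consequence)
        if not isinstance(self.clinvar_class, ClinVarClass):
            self.clinvar_class = ClinVarClass(self.clinvar_class)


class FigoStage(str, enum.Enum):
    IA = "IA"
    IB = "IB"
    IC = "IC"
    II = "II"
    III = "III"
    IV = "IV"
    NA = "NA"


class SurvivalStatus(str, enum.Enum):
    """Follow-up status codes.

    NED no evidence of disease; AWD alive with disease; DOD death of disease;
    DTC death of treatment complication; DUC death of uncertain cause; DOC
    death of other cause.
    """

    NED = "NED"
    AWD = "AWD"
    DOD = "DOD"
    DTC = "DTC"
    DUC = "DUC"
    DOC = "DOC"
    NA = "NA"

    @property
    def is_death(self) -> bool:
        return self in (SurvivalStatus.DOD, SurvivalStatus.DTC, SurvivalStatus.DUC, SurvivalStatus.DOC)


class RecurrenceType(str, enum.Enum):
    LOCAL = "local"
    DISTANT = "distant"
    COMBINED = "combined"
    NA = "NA"


@dataclass
class ClinicalRecord:
    """Clinico-pathological fields needed for endpoint construction.

    Tri-state fields use ``True``/``False``/``None``; ``None`` is an explicit
    not-available category and downstream percentages use non-missing
    denominators only.
    """

    sample_id: str
    age: float | None = None
    figo_stage: FigoStage = FigoStage.NA
    t_stage_high: bool | None = None
    resection_r0: bool | None = None
    adjuvant_therapy: bool | None = None
    recurrence: bool | None = None
    recurrence_type: RecurrenceType = RecurrenceType.NA
    survival_status: SurvivalStatus = SurvivalStatus.NA
    followup_months: float | None = None
    recurrence_months: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.figo_stage, FigoStage):
            self.figo_stage = FigoStage(self.figo_stage)
        if not isinstance(self.survival_status, SurvivalStatus):
            self.survival_status = SurvivalStatus(self.survival_status)
        if not isinstance(self.recurrence_type, RecurrenceType):
            self.recurrence_type = RecurrenceType(self.recurrence_type)
        for name in ("followup_months", "recurrence_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if (
            self.recurrence_months is not None
            and self.followup_months is not None
            and self.recurrence_months > self.followup_months
        ):
            raise ValueError(
                f"{self.sample_id}: recurrence_months {self.recurrence_months} "
                f"> followup_months {self.followup_months}"
            )


class MolecularSubtype(str, enum.Enum):
    """TCGA-style molecular subtype, assigned by hierarchical precedence."""

    POLEMUT = "POLEmut"
    MSI_HIGH = "MSI-High"
    P53ABN = "p53abn"
    NSMP = "NSMP"
    NOT_EVALUABLE = "not_evaluable"


class MarkerStatus(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NOT_EVALUATED = "not_evaluated"


class Biotype(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    OTHER = "other"


@dataclass
class FusionCandidate:
    """One candidate transcript fusion emitted by the upstream caller.

    Breakpoints are 1-based transcript (r.) coordinates: ``breakpoint5`` is the
    last retained base of the 5' partner, ``breakpoint3`` the first retained
    base of the 3' partner.  Genomic positions are carried for readthrough
    geometry only.  ``region_median_reads`` is the cohort median read depth at
    the breakpoint region, supplied upstream, used for the expression-support
    screen.
    """

    sample_id: str
    gene5: str
    gene3: str
    transcript5: str
    transcript3: str
    chrom5: str
    chrom3: str
    strand5: str
    strand3: str
    breakpoint5: int
    breakpoint3: int
    genomic_pos5: int
    genomic_pos3: int
    crossing_reads: int
    total_reads_at_location: int
    region_median_reads: float
    biotype5: Biotype = Biotype.PROTEIN_CODING
    biotype3: Biotype = Biotype.PROTEIN_CODING

    def __post_init__(self) -> None:
        if self.crossing_reads > self.total_reads_at_location:
            raise ValueError(
                f"{self.sample_id} {self.gene5}::{self.gene3}: crossing_reads "
                f"{self.crossing_reads} > total_reads_at_location {self.total_reads_at_location}"
            )
        if self.breakpoint5 < 1 or self.breakpoint3 < 1:
            raise ValueError("transcript breakpoints are 1-based, must be >= 1")
        if not isinstance(self.biotype5, Biotype):
            self.biotype5 = Biotype(self.biotype5)
        if not isinstance(self.biotype3, Biotype):
            self.biotype3 = Biotype(self.biotype3)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class SampleProfile:
    """Per-sample molecular summary assembled by the pipeline orchestrator.

    Composed strictly from upstream stage outputs; nothing is computed here.
    """

    sample_id: str
    gene_status: dict[str, bool] = field(default_factory=dict)
    tertp_positive: bool | None = None
    tmb: "object | None" = None  # TMBResult
    msi: "object | None" = None  # MSIResult
    subtype: MolecularSubtype | None = None
    fusions: list[str] = field(default_factory=list)
    expression_cluster: int | None = None
    clinical: ClinicalRecord | None = None
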