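"""Panel tumor mutational burden and microsatellite instability calling.

TMB counts every coding variant (synonymous and nonsynonymous alike) with
allele frequency >= 10%, excluding presumed-germline variants — those present
in a population polymorphism database — unless they are also flagged as known
drivers.  The count is normalized to the panel's coding territory (1.708 Mb
by default) and a sample is TMB-High at >= 10 mut/Mb.  TMB is evaluable only
for samples with >= 40% tumor cells.

MSI uses up to 17 microsatellite markers: a sample is MSI-High when strictly
more than 20% of its *evaluated* markers are unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .knowledge import KnowledgeBase
from .types import MarkerStatus, VariantRecord

TMB_HIGH_THRESHOLD = 10.0  # mut/Mb, inclusive
MIN_TUMOR_CELL_FRACTION = 0.40
MIN_ALLELE_FREQUENCY = 0.10  # inclusive
MSI_UNSTABLE_FRACTION = 0.20  # strict: MSI-High iff fraction > 0.20


class TMBConfigurationError(Exception):
    pass


@dataclass
class TMBResult:
    sample_id: str
    counted_variants: int
    coding_mb: float
    tmb: float | None  # mut/Mb, None when not evaluable
    evaluable: bool
    tmb_high: bool
    excluded_counts: dict[str, int] = field(default_factory=dict)
    reason_not_evaluable: str | None = None

    @property
    def tmb_rounded(self) -> float | None:
        """TMB for reporting, 2 decimals; threshold calls use the raw value."""
        return None if self.tmb is None else round(self.tmb, 2)


def compute_tmb(
    variants: list[VariantRecord],
    tumor_cell_fraction: float | None,
    kb: KnowledgeBase,
    coding_mb: float | None = None,
    germline_policy: str = "exclude_polymorphisms",
) -> TMBResult:
    """Compute panel TMB for one sample.

    ``germline_policy`` is ``exclude_polymorphisms`` (default: drop
    polymorphism-database variants unless known drivers) or ``count_all``.
    Variants with missing allele frequency cannot pass the >= 10% gate and are
    excluded with an explicit reason.
    """
    if coding_mb is None:
        coding_mb = kb.coding_mb
    if coding_mb <= 0:
        raise TMBConfigurationError(f"coding_mb must be positive, got {coding_mb}")
    if germline_policy not in ("exclude_polymorphisms", "count_all"):
        raise TMBConfigurationError(f"unknown germline policy {germline_policy!r}")

    sample_id = variants[0].sample_id if variants else ""
    excluded = {"low_AF": 0, "missing_AF": 0, "presumed_germline": 0, "noncoding": 0}
    counted = 0
    for v in variants:
        if not v.consequence.is_coding:
            excluded["noncoding"] += 1
            continue
        if v.allele_frequency is None:
            excluded["missing_AF"] += 1
            continue
        if v.allele_frequency < MIN_ALLELE_FREQUENCY:
            excluded["low_AF"] += 1
            continue
        if (
            germline_policy == "exclude_polymorphisms"
            and v.in_polymorphism_db
            and not v.known_driver
        ):
            excluded["presumed_germline"] += 1
            continue
        counted += 1

    if tumor_cell_fraction is None:
        return TMBResult(
            sample_id, counted, coding_mb, None, False, False, excluded,
            reason_not_evaluable="missing tumor cell fraction",
        )
    if tumor_cell_fraction < MIN_TUMOR_CELL_FRACTION:
        return TMBResult(
            sample_id, counted, coding_mb, None, False, False, excluded,
            reason_not_evaluable=f"tumor cell fraction {tumor_cell_fraction:.2f} < 0.40",
        )
    tmb = counted / coding_mb
    return TMBResult(
        sample_id, counted, coding_mb, tmb, True, tmb >= TMB_HIGH_THRESHOLD, excluded
    )


@dataclass
class MSIResult:
    sample_id: str
    markers_evaluated: int
    markers_unstable: int
    unstable_fraction: float | None
    msi_high: bool
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.markers_unstable > self.markers_evaluated:
            raise ValueError("markers_unstable > markers_evaluated")


def call_msi(sample_id: str, marker_statuses: list[MarkerStatus]) -> MSIResult:
    """Call MSI status from one sample's marker panel (up to 17 markers).

    The instability fraction is computed over evaluated markers only; the
    MSI-High rule is a strict inequality (> 0.20), so exactly 20% is MSS.
    A sample with zero evaluated markers is not evaluable, never MSS by
    default.
    """
    statuses = [MarkerStatus(s) for s in marker_statuses]
    evaluated = sum(1 for s in statuses if s is not MarkerStatus.NOT_EVALUATED)
    unstable = sum(1 for s in statuses if s is MarkerStatus.UNSTABLE)
    if evaluated == 0:
        return MSIResult(sample_id, 0, 0, None, False, evaluable=False)
    frac = unstable / evaluated
    return MSIResult(sample_id, evaluated, unstable, frac, frac > MSI_UNSTABLE_FRACTION)
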