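"""Local knowledge-base snapshot consumed by the interpretation stages.

External lookups (ClinVar, dbSNP/ExAC, COSMIC, fusion databases) are modeled
as offline TSV tables so every run is reproducible; nothing here queries a
live service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Clinically relevant telomerase (TERT) promoter hotspot variants.
DEFAULT_TERTP_HOTSPOTS = frozenset({"c.-124C>T", "c.-124C>A", "c.-146C>T"})

#: The recurrent POLE nonsense variant that does not produce an ultramutated
#: phenotype and therefore never counts as a POLE driver event.
DEFAULT_EXCLUDED_POLE_VARIANTS = frozenset({"NM_006231.2:c.3961A>T"})

#: Coding territory of the capture panel, in base pairs (1708 kbp of the
#: 2097 kbp target). Used as the default TMB normalization denominator.
DEFAULT_CODING_BP = 1_708_000

#: Number of genes (or gene parts) on the DNA capture panel.
DEFAULT_PANEL_GENE_COUNT = 727


class KnowledgeBaseError(Exception):
    """Raised when a knowledge-base directory is malformed."""


@dataclass
class KnowledgeBase:
    """Offline lookup tables for variant and fusion interpretation.

    ``driver_variants`` and ``polymorphism_table`` are keyed by
    ``(gene, hgvs_c)``; ``known_fusion_pairs`` holds ordered (5', 3') gene
    symbol pairs; ``gene_families`` maps symbols to a family label used by the
    same-family fusion exclusion.
    """

    tertp_hotspots: frozenset[str] = DEFAULT_TERTP_HOTSPOTS
    driver_variants: dict[tuple[str, str], bool] = field(default_factory=dict)
    polymorphism_table: dict[tuple[str, str], bool] = field(default_factory=dict)
    known_fusion_pairs: frozenset[tuple[str, str]] = frozenset()
    gene_families: dict[str, str] = field(default_factory=dict)
    coding_regions: dict[str, int] = field(default_factory=lambda: {"panel_coding": DEFAULT_CODING_BP})
    panel_genes: frozenset[str] = frozenset()
    excluded_pole_variants: frozenset[str] = DEFAULT_EXCLUDED_POLE_VARIANTS

    def __post_init__(self) -> None:
        for label, size in self.coding_regions.items():
            if size <= 0:
                raise KnowledgeBaseError(f"coding region {label!r} has non-positive size {size}")

    @property
    def coding_mb(self) -> float:
        """Panel coding size in megabases (default 1.708)."""
        return self.coding_regions["panel_coding"] / 1e6

    def is_known_fusion(self, gene5: str, gene3: str) -> bool:
        return (gene5, gene3) in self.known_fusion_pairs

    def same_family(self, gene_a: str, gene_b: str) -> bool:
        fa = self.gene_families.get(gene_a)
        return fa is not None and fa == self.gene_families.get(gene_b)


_TABLE_FILES = {
    "tertp_hotspots": "tertp_hotspots.tsv",
    "driver_variants": "driver_variants.tsv",
    "polymorphism": "polymorphism.tsv",
    "known_fusions": "known_fusions.tsv",
    "gene_families": "gene_families.tsv",
}


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)


def load_knowledge_base(directory: str | Path | None = None) -> KnowledgeBase:
    """Load a knowledge base from a directory of TSV tables.

    Every table is optional; absent tables fall back to the bundled defaults
    (notably the three TERT promoter hotspots and the excluded POLE nonsense).
    Duplicate keyed rows are deduplicated with a logged count.

    Table schemas (tab-delimited, UTF-8, '.' for missing):

    * ``tertp_hotspots.tsv``: column ``hgvs_c``
    * ``driver_variants.tsv``: columns ``gene``, ``hgvs_c``
    * ``polymorphism.tsv``: columns ``gene``, ``hgvs_c``
    * ``known_fusions.tsv``: columns ``gene5``, ``gene3``
    * ``gene_families.tsv``: columns ``gene``, ``family``
    * ``panel.tsv`` (optional): columns ``gene``; ``coding_bp`` read from
      ``panel_meta.tsv`` (columns ``key``, ``value``) when present.
    * ``excluded_pole.tsv`` (optional): column ``hgvs_c``
    """
    kb = KnowledgeBase()
    if directory is None:
        return kb
    directory = Path(directory)
    if not directory.is_dir():
        raise KnowledgeBaseError(f"knowledge-base directory not found: {directory}")

    kwargs: dict = {}

    p = directory / _TABLE_FILES["tertp_hotspots"]
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["hgvs_c"])
        kwargs["tertp_hotspots"] = frozenset(df["hgvs_c"].dropna())

    p = directory / _TABLE_FILES["driver_variants"]
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["gene", "hgvs_c"])
        df = _dedup(df, ["gene", "hgvs_c"], p)
        kwargs["driver_variants"] = {(r.gene, r.hgvs_c): True for r in df.itertuples()}

    p = directory / _TABLE_FILES["polymorphism"]
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["gene", "hgvs_c"])
        df = _dedup(df, ["gene", "hgvs_c"], p)
        kwargs["polymorphism_table"] = {(r.gene, r.hgvs_c): True for r in df.itertuples()}

    p = directory / _TABLE_FILES["known_fusions"]
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["gene5", "gene3"])
        kwargs["known_fusion_pairs"] = frozenset(zip(df["gene5"], df["gene3"]))

    p = directory / _TABLE_FILES["gene_families"]
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["gene", "family"])
        df = _dedup(df, ["gene"], p)
        kwargs["gene_families"] = dict(zip(df["gene"], df["family"]))

    p = directory / "panel.tsv"
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["gene"])
        kwargs["panel_genes"] = frozenset(df["gene"].dropna())

    p = directory / "panel_meta.tsv"
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["key", "value"])
        meta = dict(zip(df["key"], df["value"]))
        if "coding_bp" in meta:
            kwargs["coding_regions"] = {"panel_coding": int(meta["coding_bp"])}

    p = directory / "excluded_pole.tsv"
    if p.exists():
        df = _read_tsv(p)
        _require(df, p, ["hgvs_c"])
        kwargs["excluded_pole_variants"] = frozenset(df["hgvs_c"].dropna())

    return KnowledgeBase(**kwargs)


def write_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write all knowledge-base tables as TSV under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"hgvs_c": sorted(kb.tertp_hotspots)}).to_csv(
        directory / "tertp_hotspots.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"gene": g, "hgvs_c": c} for (g, c) in sorted(kb.driver_variants)]
    ).reindex(columns=["gene", "hgvs_c"]).to_csv(directory / "driver_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "hgvs_c": c} for (g, c) in sorted(kb.polymorphism_table)]
    ).reindex(columns=["gene", "hgvs_c"]).to_csv(directory / "polymorphism.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene5": a, "gene3": b} for (a, b) in sorted(kb.known_fusion_pairs)]
    ).reindex(columns=["gene5", "gene3"]).to_csv(directory / "known_fusions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "family": f} for g, f in sorted(kb.gene_families.items())]
    ).reindex(columns=["gene", "family"]).to_csv(directory / "gene_families.tsv", sep="\t", index=False)
    if kb.panel_genes:
        pd.DataFrame({"gene": sorted(kb.panel_genes)}).to_csv(directory / "panel.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"key": "coding_bp", "value": kb.coding_regions["panel_coding"]}]
    ).to_csv(directory / "panel_meta.tsv", sep="\t", index=False)
    pd.DataFrame({"hgvs_c": sorted(kb.excluded_pole_variants)}).to_csv(
        directory / "excluded_pole.tsv", sep="\t", index=False
    )


def _require(df: pd.DataFrame, path: Path, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"{path}: missing mandatory column(s) {missing}")


def _dedup(df: pd.DataFrame, keys: list[str], path: Path) -> pd.DataFrame:
    n = len(df)
    out = df.drop_duplicates(subset=keys)
    if len(out) < n:
        logger.warning("%s: deduplicated %d duplicate row(s)", path, n - len(out))
    return out
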