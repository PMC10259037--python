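"""End-to-end orchestration: run every stage on an input directory and emit
cohort summary tables.

The report directory contains one TSV per stage output plus a provenance
manifest with SHA-256 hashes of every input file consumed, so every number in
the report traces to a stage output computed from hashed inputs.  Stages with
absent inputs are skipped and recorded as such; a stage failure marks the
stage failed, skips dependent stages, and makes :func:`run_pipeline` raise
at the end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as io_mod
from .burden import call_msi, compute_tmb
from .expression import (
    ExpressionMatrix,
    cluster_samples,
    nb_two_group_test,
    reference_normalize,
    rpkm,
    tmm_log_cpm_z,
)
from .fusions import (
    FusionFilterConfig,
    filter_cohort,
    read_fusion_candidates,
    read_transcripts,
    summarize_fusions,
    verdicts_to_frame,
)
from .interpret import assign_subtype, build_gene_status_matrix
from .knowledge import load_knowledge_base
from .survival import build_endpoints, cox_model, km_logrank, mutual_exclusivity
from .types import MolecularSubtype

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters; every spec threshold surfaces as a key."""

    input_dir: Path
    output_dir: Path
    kb_dir: Path | None = None
    coding_mb: float | None = None  # default: knowledge-base panel size
    min_tumor_cell_fraction: float = 0.40
    min_allele_frequency: float = 0.10
    tmb_high_threshold: float = 10.0
    msi_unstable_fraction: float = 0.20
    exon_boundary_tolerance_bp: int = 15
    read_fraction_threshold: float = 0.10
    expression_clusters: int = 2
    min_gene_recurrence: int = 2
    germline_policy: str = "exclude_polymorphisms"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["input_dir"] = Path(raw["input_dir"])
        raw["output_dir"] = Path(raw["output_dir"])
        if raw.get("kb_dir"):
            raw["kb_dir"] = Path(raw["kb_dir"])
        return cls(**raw)


@dataclass
class PipelineResult:
    output_dir: Path
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/skipped/failed
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)

    def stage_ok(self, name: str) -> bool:
        return self.stages.get(name) == "ok"


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | str | Path) -> PipelineResult:
    """Run every stage whose inputs exist; write the report directory."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(output_dir=outdir)
    manifest: dict[str, str] = {}
    failed = False

    kb_dir = config.kb_dir if config.kb_dir else (indir / "kb" if (indir / "kb").is_dir() else None)
    kb = load_knowledge_base(kb_dir)
    coding_mb = config.coding_mb if config.coding_mb is not None else kb.coding_mb

    def track(path: Path) -> Path:
        manifest[str(path)] = _hash_file(path)
        return path

    # ---------------- DNA stages ----------------
    variants_path = indir / "variants.tsv"
    status_matrix = None
    variants_by_sample: dict[str, list] = {}
    if variants_path.exists():
        try:
            variants = io_mod.read_variants(track(variants_path), dialect="tsv")
            sample_ids = sorted({v.sample_id for v in variants})
            status_matrix = build_gene_status_matrix(variants, kb, sample_ids=sample_ids)
            for v in variants:
                variants_by_sample.setdefault(v.sample_id, []).append(v)
            freq = pd.DataFrame(
                {
                    "mutated_samples": status_matrix.gene_counts(),
                    "percent": status_matrix.gene_percentages().round(1),
                }
            ).sort_values("mutated_samples", ascending=False)
            freq.loc["TERTp"] = [status_matrix.tertp_count(), round(status_matrix.tertp_percentage(), 1)]
            freq.index.name = "gene"
            freq.to_csv(outdir / "gene_frequencies.tsv", sep="\t")
            result.tables["gene_frequencies"] = freq

            onco = status_matrix.recurrent_view(config.min_gene_recurrence)
            order = onco.sum(axis=0).sort_values(ascending=False).index
            onco = onco[order].astype(int)
            onco.insert(0, "TERTp", status_matrix.tertp.astype(int))
            onco.to_csv(outdir / "oncoprint_matrix.tsv", sep="\t")
            result.tables["oncoprint"] = onco
            result.stages["variants"] = "ok"
        except Exception:
            logger.exception("variant stage failed")
            result.stages["variants"] = "failed"
            failed = True
    else:
        result.stages["variants"] = "skipped"

    purity_path = indir / "purity.tsv"
    tmb_table = None
    if result.stage_ok("variants") and purity_path.exists():
        try:
            purity = io_mod.read_purity(track(purity_path))
            rows = []
            for s in sorted(variants_by_sample):
                res = compute_tmb(
                    variants_by_sample[s], purity.get(s), kb,
                    coding_mb=coding_mb, germline_policy=config.germline_policy,
                )
                rows.append(
                    {
                        "sample_id": s,
                        "counted_variants": res.counted_variants,
                        "tmb": res.tmb_rounded if res.tmb is not None else ".",
                        "evaluable": int(res.evaluable),
                        "tmb_high": int(res.tmb_high),
                    }
                )
            tmb_table = pd.DataFrame(rows).set_index("sample_id")
            tmb_table.to_csv(outdir / "tmb.tsv", sep="\t")
            result.tables["tmb"] = tmb_table
            evaluable = tmb_table[tmb_table["evaluable"] == 1]
            tmb_vals = pd.to_numeric(evaluable["tmb"], errors="coerce")
            high = evaluable[evaluable["tmb_high"] == 1]
            result.summaries["tmb"] = {
                "n_evaluable": int(len(evaluable)),
                "n_tmb_high": int(len(high)),
                "percent_tmb_high": round(100.0 * len(high) / len(evaluable), 1) if len(evaluable) else None,
                "median_tmb": float(tmb_vals.median()) if len(evaluable) else None,
                "median_tmb_high": float(pd.to_numeric(high["tmb"]).median()) if len(high) else None,
                "tmb_range": [float(tmb_vals.min()), float(tmb_vals.max())] if len(evaluable) else None,
            }
            result.stages["tmb"] = "ok"
        except Exception:
            logger.exception("TMB stage failed")
            result.stages["tmb"] = "failed"
            failed = True
    else:
        result.stages["tmb"] = "skipped" if not result.stage_ok("variants") or not purity_path.exists() else "failed"

    msi_path = indir / "msi_markers.tsv"
    msi_table = None
    if msi_path.exists():
        try:
            markers = io_mod.read_msi_markers(track(msi_path))
            rows = []
            for s, statuses in markers.items():
                res = call_msi(s, statuses)
                rows.append(
                    {
                        "sample_id": s,
                        "markers_evaluated": res.markers_evaluated,
                        "markers_unstable": res.markers_unstable,
                        "unstable_fraction": round(res.unstable_fraction, 4)
                        if res.unstable_fraction is not None
                        else ".",
                        "msi_high": int(res.msi_high),
                        "evaluable": int(res.evaluable),
                    }
                )
            msi_table = pd.DataFrame(rows).set_index("sample_id")
            msi_table.to_csv(outdir / "msi.tsv", sep="\t")
            result.tables["msi"] = msi_table
            ev = msi_table[msi_table["evaluable"] == 1]
            result.summaries["msi"] = {
                "n_evaluable": int(len(ev)),
                "n_msi_high": int(ev["msi_high"].sum()),
                "percent_msi_high": round(100.0 * ev["msi_high"].sum() / len(ev), 1) if len(ev) else None,
            }
            result.stages["msi"] = "ok"
        except Exception:
            logger.exception("MSI stage failed")
            result.stages["msi"] = "failed"
            failed = True
    else:
        result.stages["msi"] = "skipped"

    # subtype assignment needs variants + MSI
    if result.stage_ok("variants") and result.stage_ok("msi"):
        try:
            from .interpret import pole_mut_status

            rows = []
            for s in sorted(variants_by_sample):
                pole = pole_mut_status(variants_by_sample[s], kb)
                msi_high = bool(msi_table.loc[s, "msi_high"]) if s in msi_table.index else None
                tp53 = (
                    bool(status_matrix.status.loc[s, "TP53"])
                    if "TP53" in status_matrix.status.columns
                    else False
                )
                subtype = assign_subtype(pole, msi_high, tp53)
                rows.append({"sample_id": s, "pole_mut": int(pole), "subtype": subtype.value})
            subtype_table = pd.DataFrame(rows).set_index("sample_id")
            subtype_table.to_csv(outdir / "subtypes.tsv", sep="\t")
            result.tables["subtypes"] = subtype_table
            counts = subtype_table["subtype"].value_counts().to_dict()
            evaluable = subtype_table[subtype_table["subtype"] != MolecularSubtype.NOT_EVALUABLE.value]
            result.summaries["subtypes"] = {
                "counts": counts,
                "percent": {
                    k: round(100.0 * v / len(evaluable), 1)
                    for k, v in counts.items()
                    if k != MolecularSubtype.NOT_EVALUABLE.value
                },
                "percent_pole_mut": round(100.0 * subtype_table["pole_mut"].sum() / len(subtype_table), 1),
            }
            result.stages["subtype"] = "ok"
        except Exception:
            logger.exception("subtype stage failed")
            result.stages["subtype"] = "failed"
            failed = True
    else:
        result.stages["subtype"] = "skipped"

    # ---------------- RNA stages ----------------
    fusion_path = indir / "fusion_candidates.tsv"
    tx_path = indir / "transcripts.tsv"
    fusion_samples: list[str] = []
    if fusion_path.exists() and tx_path.exists():
        try:
            candidates = read_fusion_candidates(track(fusion_path))
            transcripts = read_transcripts(track(tx_path))
            n_rna = _count_rna_samples(indir, candidates)
            fcfg = FusionFilterConfig(
                exon_boundary_tolerance_bp=config.exon_boundary_tolerance_bp,
                read_fraction_threshold=config.read_fraction_threshold,
            )
            verdicts = filter_cohort(candidates, transcripts, kb, n_rna, fcfg)
            vt = verdicts_to_frame(verdicts)
            vt.to_csv(outdir / "fusion_verdicts.tsv", sep="\t", index=False)
            result.tables["fusion_verdicts"] = vt
            summary = summarize_fusions(verdicts, n_rna)
            fusion_samples = summary["positive_samples"]
            result.summaries["fusions"] = summary
            pd.DataFrame([{k: str(v) for k, v in summary.items()}]).to_csv(
                outdir / "fusion_summary.tsv", sep="\t", index=False
            )
            result.stages["fusions"] = "ok"
        except Exception:
            logger.exception("fusion stage failed")
            result.stages["fusions"] = "failed"
            failed = True
    else:
        result.stages["fusions"] = "skipped"

    expr_path = indir / "expression_counts.tsv"
    cluster_labels = None
    if expr_path.exists():
        try:
            matrix = ExpressionMatrix.from_tsv(track(expr_path))
            z = tmm_log_cpm_z(matrix)
            clusters = cluster_samples(z, k=config.expression_clusters)
            cluster_labels = clusters.labels
            clusters.labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
            result.tables["clusters"] = clusters.labels.to_frame()
            result.summaries["clusters"] = {
                "sizes": clusters.sizes,
                "minority_size": clusters.minority_size,
            }
            de = nb_two_group_test(matrix, clusters.labels)
            de.table.round(6).to_csv(outdir / "differential_expression.tsv", sep="\t")
            result.tables["differential_expression"] = de.table
            ref_norm = reference_normalize(rpkm(matrix))
            ref_norm.round(4).to_csv(outdir / "reference_normalized_rpkm.tsv", sep="\t")
            result.stages["expression"] = "ok"
        except Exception:
            logger.exception("expression stage failed")
            result.stages["expression"] = "failed"
            failed = True
    else:
        result.stages["expression"] = "skipped"

    # ---------------- survival ----------------
    clin_path = indir / "clinical.tsv"
    if clin_path.exists():
        try:
            clinical = io_mod.read_clinical(track(clin_path))
            endpoints = build_endpoints(clinical)
            endpoints.to_csv(outdir / "endpoints.tsv", sep="\t")
            result.tables["endpoints"] = endpoints
            if result.stage_ok("subtype"):
                subtype_table = result.tables["subtypes"]
                protected = subtype_table["subtype"].isin(
                    [MolecularSubtype.POLEMUT.value, MolecularSubtype.MSI_HIGH.value]
                )
                groups = protected.map({True: "POLEmut/MSI-High", False: "POLEwt/MSS"})
                km = km_logrank(endpoints, groups)
                result.summaries["survival"] = {
                    "rfs_logrank_p": km.logrank_p,
                    "rfs_lr_p": km.lr_p,
                    "protected_events": int(
                        endpoints.loc[
                            endpoints.index.intersection(groups[groups == "POLEmut/MSI-High"].index),
                            "rfs_event",
                        ].sum()
                    ),
                }
                covs = pd.DataFrame(
                    {
                        "age": [c.age for c in clinical],
                        "stage_high": [None if c.t_stage_high is None else int(c.t_stage_high) for c in clinical],
                        "resection_r0": [None if c.resection_r0 is None else int(c.resection_r0) for c in clinical],
                        "adjuvant": [None if c.adjuvant_therapy is None else int(c.adjuvant_therapy) for c in clinical],
                    },
                    index=[c.sample_id for c in clinical],
                )
                fit = cox_model(endpoints, covs, strategy="multivariable_backward")
                if fit.evaluable and not fit.summary.empty:
                    fit.summary.round(5).to_csv(outdir / "cox_rfs_multivariable.tsv", sep="\t")
                    result.tables["cox_rfs"] = fit.summary
            if result.stage_ok("variants"):
                status = status_matrix.status
                if {"KRAS", "TP53"} <= set(status.columns):
                    me = mutual_exclusivity(status, "KRAS", "TP53")
                    result.summaries["mutual_exclusivity"] = {
                        "genes": "KRAS/TP53",
                        "overlap": me.n_both,
                        "fisher_p": me.fisher_p,
                        "direction": me.direction,
                    }
            result.stages["survival"] = "ok"
        except Exception:
            logger.exception("survival stage failed")
            result.stages["survival"] = "failed"
            failed = True
    else:
        result.stages["survival"] = "skipped"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {"stages": result.stages, "inputs_sha256": manifest, "summaries": _jsonable(result.summaries)},
            fh,
            indent=2,
            sort_keys=True,
        )
    if failed:
        raise RuntimeError(f"pipeline finished with failed stage(s): {result.stages}")
    return result


def build_sample_profiles(result: PipelineResult) -> dict[str, "SampleProfile"]:
    """Compose per-sample molecular profiles from stage outputs.

    Pure assembly: every field is read off a stage table, nothing is
    recomputed here.  Samples are the DNA cohort; fusion and cluster fields
    stay empty for samples without RNA results.
    """
    from .types import SampleProfile

    profiles: dict[str, SampleProfile] = {}
    onco = result.tables.get("oncoprint")
    if onco is None:
        return profiles
    for s in onco.index:
        profiles[s] = SampleProfile(
            sample_id=s,
            gene_status={g: bool(onco.loc[s, g]) for g in onco.columns if g != "TERTp"},
            tertp_positive=bool(onco.loc[s, "TERTp"]),
        )
    tmb = result.tables.get("tmb")
    if tmb is not None:
        for s in tmb.index.intersection(onco.index):
            profiles[s].tmb = tmb.loc[s].to_dict()
    msi = result.tables.get("msi")
    if msi is not None:
        for s in msi.index.intersection(onco.index):
            profiles[s].msi = msi.loc[s].to_dict()
    subtypes = result.tables.get("subtypes")
    if subtypes is not None:
        from .types import MolecularSubtype as MS

        for s in subtypes.index.intersection(onco.index):
            profiles[s].subtype = MS(subtypes.loc[s, "subtype"])
    verdicts = result.tables.get("fusion_verdicts")
    if verdicts is not None:
        accepted = verdicts[verdicts["accepted"] == 1]
        for _, row in accepted.iterrows():
            if row["sample_id"] in profiles:
                profiles[row["sample_id"]].fusions.append(f"{row['gene5']}::{row['gene3']}")
    clusters = result.tables.get("clusters")
    if clusters is not None:
        for s in clusters.index.intersection(onco.index):
            profiles[s].expression_cluster = int(clusters.loc[s, "cluster"])
    return profiles


def _count_rna_samples(indir: Path, candidates) -> int:
    """RNA cohort size: expression matrix columns when present, else
    distinct candidate samples."""
    expr = indir / "expression_counts.tsv"
    if expr.exists():
        header = pd.read_csv(expr, sep="\t", nrows=0)
        return len([c for c in header.columns if c not in ("gene", "gene_length")])
    return len({c.sample_id for c in candidates})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj
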