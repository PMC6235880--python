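"""End-to-end cohort runs from a flat key-value config file.

``simulate`` writes a synthetic cohort to disk (one directory per patient
with normal/tumor/metastasis variant tables, purity/ploidy metadata,
common-variant positions, copy-number segments and truth labels);
``run`` executes TiNDA rescue, stratification, per-stratum signature
decomposition, kataegis detection, copy-number and cohort-level summaries,
and writes a versioned machine-readable JSON report plus TSV tables. Every
parameter and seed is logged; reruns with the same config and seed produce
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, cna, cohort_stats, kataegis, signatures, stratify, tinda
from .io_formats import (
    read_arms,
    read_gene_models,
    read_segments,
    read_signature_matrix,
    read_variant_table,
    write_gene_models,
    write_segments,
    write_variant_table,
)
from .stratify import TrioDataset
from .synthetic import (
    default_arms,
    generate_gene_models,
    generate_segments,
    generate_trio,
    paper_cohort_configs,
    synthetic_signature_matrix,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

REPORT_SECTIONS = (
    "tinda", "stratification", "signatures", "strata_comparison",
    "kataegis", "cna", "cohort",
)


@dataclass(slots=True)
class RunConfig:
    """Validated parameters for a pipeline or simulation run."""

    cohort_dir: str = "cohort"
    output_dir: str = "results"
    gene_models: str | None = None
    signature_matrix: str | None = None
    arms: str | None = None
    seed: int = 1
    maf_threshold: float = 0.05
    min_alt_reads: int = 2
    germline_ratio: float = 2.0
    tinda_k: int = 9
    tinda_above_identity: float = 0.75
    tinda_min_sample_maf: float = 0.01
    tinda_max_control_maf: float = 0.45
    kataegis_min_mutations: int = 5
    kataegis_window: int = 10_000
    cna_threshold: float = 0.7
    signature_cutoff: float = 0.06
    recurrence_min_samples: int = 4
    # simulation-only
    n_patients: int = 12
    n_snvs: int | None = None
    n_genes: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must be in (0, 1)")
        if self.min_alt_reads < 0 or self.tinda_k < 1:
            raise ValueError("min_alt_reads and tinda_k must be positive")
        if self.kataegis_min_mutations < 2 or self.kataegis_window < 1:
            raise ValueError("kataegis parameters out of range")
        if self.cna_threshold < 0:
            raise ValueError("cna_threshold must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def parse_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    values: dict[str, object] = {}
    known = {f.name: f for f in fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if raw.lower() in ("none", ""):
            values[key] = None
            continue
        target = known[key].type
        if "int" in str(target):
            values[key] = int(raw)
        elif "float" in str(target):
            values[key] = float(raw)
        else:
            values[key] = raw
    return RunConfig(**values)


# ---------------------------------------------------------------------------
# simulation


def simulate_command(config: RunConfig) -> list[str]:
    """Write a synthetic cohort under ``cohort_dir``; returns patient ids."""
    root = Path(config.cohort_dir)
    W = (
        read_signature_matrix(config.signature_matrix)
        if config.signature_matrix
        else synthetic_signature_matrix()
    )
    trio_configs = paper_cohort_configs(
        n_patients=config.n_patients, seed=config.seed, n_snvs=config.n_snvs
    )
    root.mkdir(parents=True, exist_ok=True)
    models = generate_gene_models(n_genes=config.n_genes, seed=config.seed)
    write_gene_models(models, root / "gene_models.bed")
    arms = default_arms()
    with open(root / "arms.tsv", "w") as handle:
        handle.write("chrom\tarm\tstart\tend\n")
        for chrom, arm, start, end in arms.arms():
            handle.write(f"{chrom}\t{arm}\t{start}\t{end}\n")
    patient_ids = []
    for cfg in trio_configs:
        pdir = root / cfg.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        trio, truth = generate_trio(cfg, W)
        write_variant_table(trio.normal.values(), pdir / "normal.tsv")
        write_variant_table(trio.tumor.values(), pdir / "tumor.tsv")
        write_variant_table(trio.metastasis.values(), pdir / "metastasis.tsv")
        write_segments(generate_segments(cfg), pdir / "segments.tsv")
        with open(pdir / "common_variants.tsv", "w") as handle:
            for chrom, pos in sorted(truth.common_variant_positions):
                handle.write(f"{chrom}\t{pos}\n")
        meta = {
            "patient_id": cfg.patient_id,
            "purity_tumor": cfg.purity_tumor,
            "purity_met": cfg.purity_met,
            "ploidy_tumor": cfg.ploidy_tumor,
            "ploidy_met": cfg.ploidy_met,
            "coverage": cfg.mean_coverage,
        }
        (pdir / "meta.json").write_text(json.dumps(meta, indent=1))
        truth_out = {
            "stratum": {"|".join(map(str, k)): v for k, v in truth.stratum.items()},
            "contaminated": sorted("|".join(map(str, k)) for k in truth.contaminated),
        }
        (pdir / "truth.json").write_text(json.dumps(truth_out, indent=1))
        patient_ids.append(cfg.patient_id)
        logger.info("simulated %s: %d SNVs", cfg.patient_id, cfg.n_snvs)
    return patient_ids


def load_trio(patient_dir: str | Path) -> tuple[TrioDataset, set[tuple[str, int]]]:
    """Load one patient directory into a TrioDataset + common-variant set."""
    pdir = Path(patient_dir)
    meta = json.loads((pdir / "meta.json").read_text())
    calls = {}
    for role in ("normal", "tumor", "metastasis"):
        records = read_variant_table(pdir / f"{role}.tsv", dialect="tsv")
        calls[role] = {r.key: r for r in records}
    common: set[tuple[str, int]] = set()
    common_path = pdir / "common_variants.tsv"
    if common_path.exists():
        for line in common_path.read_text().splitlines():
            if line.strip():
                chrom, pos = line.split("\t")[:2]
                common.add((chrom, int(pos)))
    trio = TrioDataset(
        patient_id=meta["patient_id"],
        normal=calls["normal"],
        tumor=calls["tumor"],
        metastasis=calls["metastasis"],
        purity_tumor=meta["purity_tumor"],
        purity_met=meta["purity_met"],
        ploidy_tumor=meta["ploidy_tumor"],
        ploidy_met=meta["ploidy_met"],
        coverage={role: meta.get("coverage", 36.0) for role in calls},
    )
    return trio, common


# ---------------------------------------------------------------------------
# the full run


def _stratum_catalog(trio: TrioDataset, catalog_keys, stratum: str):
    source = trio.metastasis if stratum == "met_private" else trio.tumor
    records = [
        source[k] for k in catalog_keys
        if k in source and source[k].is_snv and source[k].context is not None
    ]
    if not records:
        return None
    return signatures.build_catalog(records)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a cohort directory; returns the report dict.

    Stage failures abort with the stage name; optional inputs (gene
    models, segments, arms) missing mark their sections skipped.
    """
    root = Path(config.cohort_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort_dir {root} does not exist")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("metatrio").addHandler(handler)
    try:
        report = _run_pipeline_inner(config, root, out)
    finally:
        logging.getLogger("metatrio").removeHandler(handler)
        handler.close()
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report


def _run_pipeline_inner(config: RunConfig, root: Path, out: Path) -> dict:
    logger.info("run parameters: %s", json.dumps(config.to_dict(), sort_keys=True))
    W = (
        read_signature_matrix(config.signature_matrix)
        if config.signature_matrix
        else synthetic_signature_matrix()
    )
    gene_models_path = (
        Path(config.gene_models) if config.gene_models else root / "gene_models.bed"
    )
    models = read_gene_models(gene_models_path) if gene_models_path.exists() else None
    arms_path = Path(config.arms) if config.arms else root / "arms.tsv"
    arms = read_arms(arms_path) if arms_path.exists() else None

    patient_dirs = sorted(p for p in root.iterdir() if (p / "meta.json").exists())
    if not patient_dirs:
        raise FileNotFoundError(f"no patient directories under {root}")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": config.to_dict(),
    }
    tinda_section: dict = {}
    strat_section: dict = {}
    exposures_by_patient: dict = {}
    per_patient_exposures_json: dict = {}
    kataegis_section: dict = {"per_patient": {}, "recurrent_regions": []}
    all_segments = []
    ploidies: dict[str, float] = {}
    annotated_by_sample: dict[str, list] = {}
    loci_by_sample: dict[str, list] = {}
    strat_rows = []

    for pdir in patient_dirs:
        stage = f"load({pdir.name})"
        try:
            trio, common = load_trio(pdir)
            stage = f"tinda({pdir.name})"
            trio, tinda_results = tinda.apply_tinda(
                trio, common, k=config.tinda_k, seed=config.seed,
                above_identity=config.tinda_above_identity,
                min_sample_maf=config.tinda_min_sample_maf,
                max_control_maf=config.tinda_max_control_maf,
            )
            tinda_section[trio.patient_id] = {
                role: {
                    "n_points": len(res.assignments),
                    "n_rescued": res.n_rescued,
                    "clusters": res.cluster_stats,
                }
                for role, res in tinda_results.items()
            }
            stage = f"stratify({pdir.name})"
            catalog = stratify.stratify_trio(
                trio,
                maf_threshold=config.maf_threshold,
                min_alt=config.min_alt_reads,
                germline_ratio=config.germline_ratio,
            )
            strat_section[trio.patient_id] = {
                "f_shared": catalog.f_shared,
                "f_tumor_private": catalog.f_tumor,
                "f_met_private": catalog.f_met,
                "n_snvs": catalog.n_snvs,
            }
            strat_rows.append(
                {"patient": trio.patient_id, **strat_section[trio.patient_id]}
            )
            stage = f"signatures({pdir.name})"
            catalogs = {}
            for stratum in ("shared", "tumor_private", "met_private"):
                cat = _stratum_catalog(trio, catalog.keys_in(stratum), stratum)
                if cat is not None and cat.total > 0:
                    catalogs[stratum] = cat
            exposures_by_patient[trio.patient_id] = catalogs
            stage = f"kataegis({pdir.name})"
            snv_positions = kataegis.positions_by_chromosome(
                trio.tumor[k] if k in trio.tumor else trio.metastasis[k]
                for k in catalog.assignments
                if len(k[2]) == 1 and len(k[3]) == 1
            )
            loci = kataegis.detect_kataegis(
                snv_positions, k=config.kataegis_min_mutations,
                window=config.kataegis_window,
            )
            if models is not None:
                loci = kataegis.annotate_locus_proximity(
                    loci, models, max_dist=config.kataegis_window
                )
            loci_by_sample[trio.patient_id] = loci
            kataegis_section["per_patient"][trio.patient_id] = [
                {"chrom": l.chrom, "start": l.start, "end": l.end,
                 "size": l.size, "proximal_genes": list(l.proximal_genes)}
                for l in loci
            ]
            stage = f"cna-load({pdir.name})"
            seg_path = pdir / "segments.tsv"
            if seg_path.exists():
                all_segments.extend(read_segments(seg_path))
                ploidies[f"{trio.patient_id}-T"] = trio.ploidy_tumor
                ploidies[f"{trio.patient_id}-M"] = trio.ploidy_met
            if models is not None:
                stage = f"annotate({pdir.name})"
                for role, calls in (("T", trio.tumor), ("M", trio.metastasis)):
                    sample = f"{trio.patient_id}-{role}"
                    annotated = [
                        annotate.annotate_variant(calls[k], models)
                        for k in catalog.assignments
                        if k in calls
                        and (role == "T") == (catalog.assignments[k] != "met_private")
                    ]
                    annotated_by_sample[sample] = annotated
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage} failed on input {pdir}: {exc}"
            ) from exc

    report["tinda"] = tinda_section
    report["stratification"] = {
        "per_patient": strat_section,
        "cohort_mean": {
            key: float(np.mean([v[key] for v in strat_section.values()]))
            for key in ("f_shared", "f_tumor_private", "f_met_private")
        },
    }
    pd.DataFrame(strat_rows).to_csv(out / "stratification.tsv", sep="\t", index=False)

    # cohort-level signature detection, then per-stratum fits on survivors
    all_catalogs = [
        cat for byp in exposures_by_patient.values() for cat in byp.values()
    ]
    sig_section: dict = {"active_signatures": [], "per_patient": {}}
    fitted: dict = {}
    if all_catalogs:
        active = signatures.cohort_signature_detection(
            all_catalogs, W, config.signature_cutoff
        )
        sig_section["active_signatures"] = list(active)
        W_active = W.subset(active)
        for patient, byp in exposures_by_patient.items():
            fitted[patient] = {}
            per_json = {}
            for stratum, cat in byp.items():
                fit = signatures.nnls_decompose(cat, W_active)
                fit = signatures.apply_signature_cutoffs(
                    fit, config.signature_cutoff, cat, W_active
                )
                fitted[patient][stratum] = fit
                per_json[stratum] = {
                    "absolute": {s: float(v) for s, v in
                                 zip(fit.signature_ids, fit.exposures)},
                    "normalized": {s: float(v) for s, v in
                                   zip(fit.signature_ids, fit.normalized)},
                    "residual": fit.residual,
                }
            sig_section["per_patient"][patient] = per_json
    report["signatures"] = sig_section

    complete = {
        p: f for p, f in fitted.items()
        if all(s in f for s in ("shared", "tumor_private", "met_private"))
    }
    if len(complete) >= 3:
        table = signatures.compare_strata_exposures(complete)
        table.to_csv(out / "strata_comparison.tsv", sep="\t", index=False)
        report["strata_comparison"] = table.to_dict(orient="records")
    else:
        report["strata_comparison"] = {"skipped": "fewer than 3 complete patients"}

    kataegis_section["recurrent_regions"] = [
        {k: v for k, v in region.items()}
        for region in kataegis.recurrent_regions(loci_by_sample)
    ]
    report["kataegis"] = kataegis_section

    if all_segments and arms is not None:
        recurrence = cna.arm_recurrence(
            all_segments, arms, ploidies, threshold=config.cna_threshold
        )
        recurrence.to_csv(out / "arm_recurrence.tsv", sep="\t", index=False)
        report["cna"] = {"arm_recurrence": recurrence.to_dict(orient="records")}
        if models is not None:
            gene_states = cna.annotate_genes_cna(all_segments, models)
            report["cna"]["n_gene_states"] = int(len(gene_states))
    else:
        report["cna"] = {"skipped": "segments or arm definitions missing"}

    if annotated_by_sample:
        cohort_section: dict = {}
        for channel in cohort_stats.CHANNELS:
            matrix = cohort_stats.build_mutation_matrix(annotated_by_sample, channel)
            rec = cohort_stats.recurrent_genes(
                matrix, min_samples=config.recurrence_min_samples
            )
            channel_report = {
                "n_genes": int(matrix.shape[0]),
                "recurrent": rec.to_dict(orient="records"),
            }
            if len(rec) >= 2:
                pairs = cohort_stats.mutual_exclusivity_table(
                    matrix, rec["gene"].tolist()
                )
                channel_report["mutual_exclusivity"] = pairs.to_dict(orient="records")
            cohort_section[channel] = channel_report
            matrix.to_csv(out / f"mutation_matrix_{channel}.tsv", sep="\t")
        report["cohort"] = cohort_section
    else:
        report["cohort"] = {"skipped": "gene models missing"}
    return report
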