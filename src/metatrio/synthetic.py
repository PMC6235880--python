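"""Synthetic trio cohorts with known truth labels.

Generates matched normal/primary-tumor/metastasis datasets that emulate a
12-patient whole-genome colorectal trio cohort statistically: 5,000-17,000
somatic SNVs per patient, tumor cell content 0.35-0.85, ploidy 2-3, ~36x
coverage, and strata fractions around 65% truncal / 15% tumor-private /
20% metastasis-private. Every generated variant carries a truth record
(stratum, generating signature, contamination flag, kataegis locus), so
stratification, rescue, signature fitting and kataegis detection are all
verifiable against ground truth.

Model assumptions (single dominant clone per stratum, one mutated copy):
the expected variant allele fraction of a somatic SNV is

    VAF = purity x mult / (purity x CN + 2 (1 - purity)),   mult = 1,

with CN set to the sample ploidy. Read support is depth ~ Poisson(coverage)
truncated at >= 1 and alt ~ Binomial(depth, VAF). The emulated upstream
caller flags a record somatic when alt >= 3 and MAF >= 0.05; truncal
variants hit by tumor-in-normal contamination (true normal VAF uniform in
(0.01, 0.15)) are flagged germline in both tumor and metastasis and must
be recovered by the TiNDA stage. Trinucleotide contexts are assigned
directly from per-stratum signature exposures (no reference FASTA needed);
half the records are stored on the purine strand to exercise strand
collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contexts import (
    COMPLEMENT,
    CONTEXT_LABELS,
    HS37D5_AUTOSOMES,
    parse_context_label,
    reverse_complement,
)
from .io_formats import SignatureMatrix, VariantRecord
from .signatures import Catalog96
from .stratify import Key, TrioDataset

TRUTH_STRATA = ("truncal", "tumor_private", "met_private")

#: emulated upstream caller: somatic iff alt >= 3 reads and MAF >= 5%
CALLER_MIN_ALT = 3
CALLER_MIN_MAF = 0.05

#: per-stratum signature exposures used by the cohort preset; the truncal
#: stratum leans on clock-like and mismatch-repair-defect signatures, the
#: private strata gain a double-strand-break-repair-defect component
DEFAULT_STRATUM_EXPOSURES: dict[str, dict[str, float]] = {
    "truncal": {"AC1": 0.45, "AC5": 0.25, "AC6": 0.20, "AC15": 0.10},
    "tumor_private": {"AC1": 0.40, "AC3": 0.30, "AC5": 0.30},
    "met_private": {"AC1": 0.35, "AC3": 0.40, "AC5": 0.25},
}


def synthetic_signature_matrix(
    n_signatures: int = 30, seed: int = 96, concentration: float = 0.1
) -> SignatureMatrix:
    """A synthetic stand-in signature matrix in the 96-context layout.

    Columns are sparse Dirichlet draws (signature ids ``AC1``..``ACn``),
    mimicking the shape — not the values — of a curated reference
    signature set. Purely synthetic: suitable for simulation and testing,
    not for interpreting real tumors.
    """
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    ids = tuple(f"AC{i + 1}" for i in range(n_signatures))
    return SignatureMatrix(ids, W)


@dataclass(slots=True)
class TrioConfig:
    """Generation parameters for one synthetic trio."""

    n_snvs: int = 10_000
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    purity_tumor: float = 0.6
    purity_met: float = 0.6
    ploidy_tumor: float = 2.0
    ploidy_met: float = 2.0
    mean_coverage: float = 36.0
    coverage_tumor: float | None = None
    coverage_met: float | None = None
    exposures: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            s: dict(e) for s, e in DEFAULT_STRATUM_EXPOSURES.items()
        }
    )
    contamination_fraction: float = 0.05
    n_germline_hets: int = 1_000
    common_variant_fraction: float = 0.9
    genome: dict[str, int] = field(default_factory=lambda: dict(HS37D5_AUTOSOMES))
    seed: int = 0
    patient_id: str = "P01"

    def __post_init__(self) -> None:
        if self.n_snvs < 0:
            raise ValueError("n_snvs must be >= 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        for purity in (self.purity_tumor, self.purity_met):
            if not 0 < purity <= 1:
                raise ValueError(f"purity must be in (0, 1], got {purity}")
        for ploidy in (self.ploidy_tumor, self.ploidy_met):
            if ploidy <= 0:
                raise ValueError(f"ploidy must be positive, got {ploidy}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not 0 <= self.contamination_fraction < 0.5:
            raise ValueError("contamination_fraction must be in [0, 0.5)")
        for stratum in TRUTH_STRATA:
            if stratum not in self.exposures:
                raise ValueError(f"exposures missing stratum {stratum!r}")
            exp = self.exposures[stratum]
            if any(v < 0 for v in exp.values()):
                raise ValueError(f"negative exposure in stratum {stratum!r}")
            if abs(sum(exp.values()) - 1.0) > 1e-9:
                raise ValueError(f"exposures for {stratum!r} must sum to 1")

    @property
    def cov_tumor(self) -> float:
        return self.coverage_tumor if self.coverage_tumor is not None else self.mean_coverage

    @property
    def cov_met(self) -> float:
        return self.coverage_met if self.coverage_met is not None else self.mean_coverage


@dataclass(slots=True)
class TrioTruth:
    """Ground truth for one generated trio."""

    stratum: dict[Key, str] = field(default_factory=dict)
    signature: dict[Key, str] = field(default_factory=dict)
    contaminated: set[Key] = field(default_factory=set)
    kataegis_locus: dict[Key, int] = field(default_factory=dict)
    germline_het_keys: set[Key] = field(default_factory=set)
    common_variant_positions: set[tuple[str, int]] = field(default_factory=set)

    def stratum_fractions(self) -> dict[str, float]:
        n = len(self.stratum)
        out = {s: 0 for s in TRUTH_STRATA}
        for s in self.stratum.values():
            out[s] += 1
        return {s: c / n if n else 0.0 for s, c in out.items()}


def expected_vaf(purity: float, copy_number: float, mult: float = 1.0) -> float:
    """Expected allele fraction of a mutation on ``mult`` of ``copy_number`` copies."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if copy_number <= 0 or mult <= 0:
        raise ValueError("copy numbers must be positive")
    return purity * mult / (purity * copy_number + 2.0 * (1.0 - purity))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_catalog_from_exposures(
    W: SignatureMatrix, e_norm: Sequence[float] | Mapping[str, float], n: int, seed=0
) -> Catalog96:
    """Multinomial draw of ``n`` contexts from the mixture W . e_norm."""
    if isinstance(e_norm, Mapping):
        e = np.array([float(e_norm.get(s, 0.0)) for s in W.signature_ids])
    else:
        e = np.asarray(e_norm, dtype=float)
    if e.shape != (W.n_signatures,):
        raise ValueError("exposure vector length must match signature count")
    if np.any(e < 0):
        raise ValueError("negative exposure")
    if abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("exposure fractions must sum to 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    p = W.W @ e
    return Catalog96(rng.multinomial(n, p).astype(float))


def simulate_read_counts(
    true_vaf: float, mean_coverage: float, seed=0, size: int | None = None
):
    """Draw (depth, alt_count): depth ~ Poisson(coverage) truncated at >= 1,
    alt ~ Binomial(depth, true_vaf)."""
    if not 0 <= true_vaf <= 1:
        raise ValueError("true_vaf must be in [0, 1]")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    rng = _rng(seed)
    n = 1 if size is None else size
    depth = rng.poisson(mean_coverage, size=n)
    zero = depth == 0
    while zero.any():  # truncate at depth >= 1
        depth[zero] = rng.poisson(mean_coverage, size=int(zero.sum()))
        zero = depth == 0
    alt = rng.binomial(depth, true_vaf)
    if size is None:
        return int(depth[0]), int(alt[0])
    return depth, alt


def _draw_positions(
    rng: np.random.Generator, genome: Mapping[str, int], count: int
) -> list[tuple[str, int]]:
    """``count`` distinct (chrom, pos) pairs, chromosomes weighted by length."""
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    seen: set[tuple[str, int]] = set()
    out: list[tuple[str, int]] = []
    while len(out) < count:
        need = count - len(out)
        idx = rng.choice(len(chroms), size=need, p=probs)
        pos = rng.integers(1, lengths[idx].astype(np.int64) + 1)
        for i, p in zip(idx, pos):
            key = (chroms[i], int(p))
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def _draw_contexts(
    rng: np.random.Generator,
    W: SignatureMatrix,
    exposure: Mapping[str, float],
    n: int,
) -> tuple[list[str], list[int]]:
    """Per-variant generating signature ids and context-label indices."""
    sig_ids = list(W.signature_ids)
    e = np.array([float(exposure.get(s, 0.0)) for s in sig_ids])
    if abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("stratum exposures must sum to 1")
    unknown = set(exposure) - set(sig_ids)
    if unknown:
        raise ValueError(f"exposures reference unknown signature(s) {sorted(unknown)}")
    which = rng.choice(len(sig_ids), size=n, p=e)
    ctx_idx = np.empty(n, dtype=int)
    for s in np.unique(which):
        mask = which == s
        ctx_idx[mask] = rng.choice(96, size=int(mask.sum()), p=W.W[:, s])
    return [sig_ids[s] for s in which], list(ctx_idx)


def _make_record(
    chrom: str, pos: int, ref: str, alt: str, sample_id: str,
    depth: int, alt_count: int, caller_somatic: bool, context: str | None,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample_id,
        ref_count=depth - alt_count, alt_count=alt_count,
        caller_somatic=caller_somatic, context=context,
    )


def generate_trio(
    config: TrioConfig, W: SignatureMatrix | None = None, seed: int | None = None
) -> tuple[TrioDataset, TrioTruth]:
    """Generate one trio with truth labels.

    Truncal variants are present in both tumor and metastasis; private
    variants in one sample (the other carries a zero-alt evidence record).
    The matched normal carries evidence records at every somatic site
    (alt 0 except at contaminated sites) plus germline heterozygous sites
    near BAF 0.5, most of which are listed as common variants.
    """
    if W is None:
        W = synthetic_signature_matrix()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_snvs
    strata_counts = rng.multinomial(n, np.asarray(config.fractions))
    positions = _draw_positions(rng, config.genome, n + config.n_germline_hets)
    somatic_pos = positions[:n]
    het_pos = positions[n:]

    vaf_t = expected_vaf(config.purity_tumor, config.ploidy_tumor)
    vaf_m = expected_vaf(config.purity_met, config.ploidy_met)

    truth = TrioTruth()
    normal: dict[Key, VariantRecord] = {}
    tumor: dict[Key, VariantRecord] = {}
    metastasis: dict[Key, VariantRecord] = {}

    cursor = 0
    for stratum, count in zip(TRUTH_STRATA, strata_counts):
        count = int(count)
        if count == 0:
            continue
        pos_block = somatic_pos[cursor: cursor + count]
        cursor += count
        sigs, ctx_idx = _draw_contexts(rng, W, config.exposures[stratum], count)
        flip = rng.random(count) < 0.5
        in_tumor = stratum in ("truncal", "tumor_private")
        in_met = stratum in ("truncal", "met_private")
        depth_t, alt_t = simulate_read_counts(
            vaf_t if in_tumor else 0.0, config.cov_tumor, rng, size=count
        )
        depth_m, alt_m = simulate_read_counts(
            vaf_m if in_met else 0.0, config.cov_met, rng, size=count
        )
        depth_n = simulate_read_counts(0.0, config.mean_coverage, rng, size=count)[0]
        if stratum == "truncal" and config.contamination_fraction > 0:
            contam = rng.random(count) < config.contamination_fraction
            contam_vaf = rng.uniform(0.01, 0.15, size=count)
            alt_n = np.where(
                contam, rng.binomial(depth_n, contam_vaf), 0
            )
        else:
            contam = np.zeros(count, dtype=bool)
            alt_n = np.zeros(count, dtype=int)
        for i, (chrom, pos) in enumerate(pos_block):
            ref, alt, ctx = parse_context_label(CONTEXT_LABELS[ctx_idx[i]])
            if flip[i]:
                ref, alt, ctx = COMPLEMENT[ref], COMPLEMENT[alt], reverse_complement(ctx)
            key: Key = (chrom, pos, ref, alt)
            truth.stratum[key] = stratum
            truth.signature[key] = sigs[i]
            if contam[i]:
                truth.contaminated.add(key)
            dt, at = int(depth_t[i]), int(alt_t[i])
            dm, am = int(depth_m[i]), int(alt_m[i])
            called_t = (not contam[i]) and at >= CALLER_MIN_ALT and at / dt >= CALLER_MIN_MAF
            called_m = (not contam[i]) and am >= CALLER_MIN_ALT and am / dm >= CALLER_MIN_MAF
            tumor[key] = _make_record(chrom, pos, ref, alt, f"{config.patient_id}-T",
                                      dt, at, called_t, ctx)
            metastasis[key] = _make_record(chrom, pos, ref, alt, f"{config.patient_id}-M",
                                           dm, am, called_m, ctx)
            normal[key] = _make_record(chrom, pos, ref, alt, f"{config.patient_id}-N",
                                       int(depth_n[i]), int(alt_n[i]), False, ctx)

    # germline heterozygous sites (BAF ~ 0.5 everywhere); most are listed
    # as common variants, as a population-variant filter would see them
    if config.n_germline_hets:
        common_mask = rng.random(config.n_germline_hets) < config.common_variant_fraction
        for role_cov, calls, suffix in (
            (config.mean_coverage, normal, "N"),
            (config.cov_tumor, tumor, "T"),
            (config.cov_met, metastasis, "M"),
        ):
            depth, alt = simulate_read_counts(0.5, role_cov, rng, size=config.n_germline_hets)
            for i, (chrom, pos) in enumerate(het_pos):
                key = (chrom, pos, "A", "G")
                calls[key] = _make_record(
                    chrom, pos, "A", "G", f"{config.patient_id}-{suffix}",
                    int(depth[i]), int(alt[i]), False, None,
                )
        for i, (chrom, pos) in enumerate(het_pos):
            truth.germline_het_keys.add((chrom, pos, "A", "G"))
            if common_mask[i]:
                truth.common_variant_positions.add((chrom, pos))

    trio = TrioDataset(
        patient_id=config.patient_id,
        normal=normal,
        tumor=tumor,
        metastasis=metastasis,
        purity_tumor=config.purity_tumor,
        purity_met=config.purity_met,
        ploidy_tumor=config.ploidy_tumor,
        ploidy_met=config.ploidy_met,
        coverage={
            "normal": config.mean_coverage,
            "tumor": config.cov_tumor,
            "metastasis": config.cov_met,
        },
    )
    return trio, truth


def inject_kataegis(
    trio: TrioDataset,
    truth: TrioTruth,
    n_loci: int,
    cluster_size: int = 5,
    span: int = 10_000,
    seed: int = 0,
    config: TrioConfig | None = None,
) -> tuple[TrioDataset, TrioTruth]:
    """Add ``n_loci`` clustered truncal SNV loci, recording locus ids in truth.

    Each locus is ``cluster_size`` SNVs at distinct positions spanning at
    most ``span`` bp, present (and called) in both tumor and metastasis.
    """
    if cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    if span < cluster_size:
        raise ValueError("span too small for cluster_size distinct positions")
    if n_loci == 0:
        return trio, truth
    cfg = config or TrioConfig(patient_id=trio.patient_id)
    rng = np.random.default_rng(seed)
    genome = cfg.genome
    chroms = sorted(genome)
    vaf_t = expected_vaf(trio.purity_tumor, trio.ploidy_tumor)
    vaf_m = expected_vaf(trio.purity_met, trio.ploidy_met)
    next_id = max(truth.kataegis_locus.values(), default=-1) + 1
    for locus_id in range(next_id, next_id + n_loci):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, genome[chrom] - span))
        offsets = np.sort(rng.choice(span + 1, size=cluster_size, replace=False))
        ctx_labels = rng.choice(96, size=cluster_size)
        for i, off in enumerate(offsets):
            pos = start + int(off)
            ref, alt, ctx = parse_context_label(CONTEXT_LABELS[int(ctx_labels[i])])
            key: Key = (chrom, pos, ref, alt)
            if key in truth.stratum:
                continue
            dt, at = simulate_read_counts(vaf_t, trio.coverage["tumor"], rng)
            dm, am = simulate_read_counts(vaf_m, trio.coverage["metastasis"], rng)
            dn = simulate_read_counts(0.0, trio.coverage["normal"], rng)[0]
            trio.tumor[key] = _make_record(chrom, pos, ref, alt,
                                           f"{trio.patient_id}-T", dt, max(at, CALLER_MIN_ALT),
                                           True, ctx)
            trio.metastasis[key] = _make_record(chrom, pos, ref, alt,
                                                f"{trio.patient_id}-M", dm, max(am, CALLER_MIN_ALT),
                                                True, ctx)
            trio.normal[key] = _make_record(chrom, pos, ref, alt,
                                            f"{trio.patient_id}-N", dn, 0, False, ctx)
            truth.stratum[key] = "truncal"
            truth.signature[key] = "kataegis"
            truth.kataegis_locus[key] = locus_id
    return trio, truth


def paper_cohort_configs(
    n_patients: int = 12,
    seed: int = 1,
    n_snvs: int | None = None,
    mean_coverage: float = 36.0,
) -> list[TrioConfig]:
    """The "paper-cohort" preset: 12 trios emulating the study cohort.

    Fractions (0.65, 0.15, 0.20), SNV counts uniform in [5,000, 17,000]
    (or fixed via ``n_snvs``), purities uniform in [0.35, 0.85], ploidies
    drawn from {2, 3}, 36x coverage, 5% tumor-in-normal contamination.
    Per-trio seeds are derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n_patients):
        n = int(n_snvs) if n_snvs is not None else int(rng.integers(5_000, 17_001))
        configs.append(
            TrioConfig(
                n_snvs=n,
                fractions=(0.65, 0.15, 0.20),
                purity_tumor=float(rng.uniform(0.35, 0.85)),
                purity_met=float(rng.uniform(0.35, 0.85)),
                ploidy_tumor=float(rng.choice([2.0, 3.0])),
                ploidy_met=float(rng.choice([2.0, 3.0])),
                mean_coverage=mean_coverage,
                contamination_fraction=0.05,
                seed=int(rng.integers(0, 2**31 - 1)),
                patient_id=f"P{i + 1:02d}",
            )
        )
    return configs


def generate_segments(
    config: TrioConfig, seed: int | None = None
) -> list:
    """Synthetic allele-specific copy-number segments for tumor and metastasis.

    One whole-chromosome segment per chromosome and sample: total copy
    number at the sample ploidy, with occasional +1 gains (p=0.2) and -1
    losses (p=0.1); losses drop the minor allele (LOH).
    """
    from .io_formats import CNSegment

    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    segments = []
    for suffix, ploidy in (("T", config.ploidy_tumor), ("M", config.ploidy_met)):
        sample = f"{config.patient_id}-{suffix}"
        for chrom in sorted(config.genome):
            u = rng.random()
            if u < 0.2:
                tcn, minor = ploidy + 1.0, 1.0
            elif u < 0.3:
                tcn, minor = max(ploidy - 1.0, 0.0), 0.0
            else:
                tcn, minor = ploidy, 1.0
            segments.append(
                CNSegment(sample_id=sample, chrom=chrom, start=1,
                          end=config.genome[chrom], tcn=tcn, minor_cn=minor)
            )
    return segments


def default_arms(genome: Mapping[str, int] | None = None, p_fraction: float = 0.4):
    """A simple arm map: the first 40% of each chromosome is p, the rest q."""
    from .io_formats import ArmMap

    genome = dict(HS37D5_AUTOSOMES) if genome is None else dict(genome)
    arms = {}
    for chrom, length in genome.items():
        split = max(1, int(length * p_fraction))
        arms[chrom] = {"p": (1, split), "q": (split + 1, length)}
    return ArmMap(arms)


def generate_gene_models(
    genome: Mapping[str, int] | None = None,
    n_genes: int = 200,
    seed: int = 0,
    ncrna_fraction: float = 0.15,
):
    """Synthetic interval gene models (no transcript sequence).

    Protein-coding genes get UTR5 / 3 CDS exons with introns / UTR3;
    non-coding genes a single ncRNA exon. Gene ids are ``G0001``...
    """
    from .io_formats import GeneInterval, GeneModelSet

    genome = dict(HS37D5_AUTOSOMES) if genome is None else dict(genome)
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    models = GeneModelSet()
    for g in range(n_genes):
        gene_id = f"G{g + 1:04d}"
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        span = 20_000
        start = int(rng.integers(1, max(2, genome[chrom] - span)))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < ncrna_fraction:
            models.add(GeneInterval(chrom, start, start + 1_999, strand,
                                    gene_id, "ncRNA_exon"))
            continue
        cursor = start
        pieces = [("UTR5", 500)]
        for _ in range(3):
            pieces += [("CDS", 300), ("intron", 2_000)]
        pieces = pieces[:-1] + [("UTR3", 800)]
        for region, length in pieces:
            models.add(GeneInterval(chrom, cursor, cursor + length - 1, strand,
                                    gene_id, region))
            cursor += length
    return models
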