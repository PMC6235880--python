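"""Trio stratification: shared (truncal) vs tumor- and metastasis-private SNVs.

A variant called somatic in only one of tumor/metastasis may still be
present in the other sample at sub-caller levels, especially at low tumor
cell content. Presence in the other sample is therefore *rescued* when its
mutant allele fraction (MAF) exceeds 5%, is supported by at least 2 reads,
and is at least twice the matched germline control's MAF. The 2-read floor
is motivated by a Poisson model of read support: at the cohort medians
(purity 0.475, 36x coverage, triploid) a single-copy variant is expected
on 0.475 x 36 / 3 = 5.7 reads, so 2 supporting reads sit well inside the
bulk of that distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from scipy import stats

from .annotate import AnnotatedVariant, is_mutation_of_interest
from .io_formats import VariantRecord

Key = tuple[str, int, str, str]

STRATA = ("shared", "tumor_private", "met_private")

#: DNA mismatch-repair genes checked for microsatellite-instability drivers
MMR_GENES = frozenset({"MLH1", "MLH3", "MSH2", "MSH3", "MSH6", "PMS2"})
POLE_GENE = "POLE"

DEFAULT_MAF_THRESHOLD = 0.05
DEFAULT_MIN_ALT_READS = 2
DEFAULT_GERMLINE_RATIO = 2.0


@dataclass(slots=True)
class TrioDataset:
    """Aligned normal/tumor/metastasis calls for one patient.

    Each sample maps the variant key (chrom, pos, ref, alt) to at most one
    record; a record may exist purely as read-count evidence (not called
    somatic by the upstream caller).
    """

    patient_id: str
    normal: dict[Key, VariantRecord]
    tumor: dict[Key, VariantRecord]
    metastasis: dict[Key, VariantRecord]
    purity_tumor: float
    purity_met: float
    ploidy_tumor: float
    ploidy_met: float
    coverage: dict[str, float] = field(default_factory=dict)

    def somatic_union(self) -> list[Key]:
        """Keys called somatic in tumor or metastasis, in sorted order."""
        keys = {
            k for k, r in self.tumor.items() if r.caller_somatic
        } | {
            k for k, r in self.metastasis.items() if r.caller_somatic
        }
        return sorted(keys)

    def swapped(self) -> "TrioDataset":
        """Tumor and metastasis roles exchanged (for symmetry checks)."""
        return TrioDataset(
            patient_id=self.patient_id,
            normal=self.normal,
            tumor=self.metastasis,
            metastasis=self.tumor,
            purity_tumor=self.purity_met,
            purity_met=self.purity_tumor,
            ploidy_tumor=self.ploidy_met,
            ploidy_met=self.ploidy_tumor,
            coverage={
                "normal": self.coverage.get("normal", 0.0),
                "tumor": self.coverage.get("metastasis", 0.0),
                "metastasis": self.coverage.get("tumor", 0.0),
            },
        )


@dataclass(slots=True)
class StratifiedCatalog:
    """Per-variant strata plus summary fractions over somatic SNVs."""

    patient_id: str
    assignments: dict[Key, str]
    f_shared: float
    f_tumor: float
    f_met: float
    n_snvs: int
    indel_keys: frozenset[Key] = frozenset()  # stratified as an extension

    def keys_in(self, stratum: str) -> list[Key]:
        if stratum not in STRATA:
            raise ValueError(f"unknown stratum {stratum!r}")
        return sorted(k for k, s in self.assignments.items() if s == stratum)

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f_shared, self.f_tumor, self.f_met)


def expected_read_support(purity: float, coverage: float, ploidy: float) -> float:
    """Expected reads supporting a single-copy variant: purity x coverage / ploidy."""
    if purity <= 0 or coverage <= 0 or ploidy <= 0:
        raise ValueError("purity, coverage and ploidy must all be positive")
    return purity * coverage / ploidy


def poisson_support_probability(k: int, mu: float) -> float:
    """Poisson pmf P(X = k) = e^(-mu) mu^k / k! for read support k."""
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    return float(stats.poisson.pmf(int(k), mu))


def min_alt_reads_for_maf(coverage: int, maf_threshold: float) -> int:
    """Smallest alt read count r with r/coverage strictly above the threshold."""
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not 0 < maf_threshold < 1:
        raise ValueError("maf_threshold must be in (0, 1)")
    r = 0
    while r / coverage <= maf_threshold:
        r += 1
    return r


def _rescued_in(
    record: VariantRecord | None,
    control_maf: float,
    maf_threshold: float,
    min_alt: int,
    germline_ratio: float,
) -> bool:
    """MAF cross-rescue rule for presence in a not-directly-called sample.

    A control MAF of 0 leaves only the MAF and read-count conditions (any
    positive MAF is at least twice 0).
    """
    if record is None:
        return False
    return (
        record.maf > maf_threshold
        and record.alt_count >= min_alt
        and record.maf >= germline_ratio * control_maf
    )


def rescue_in_pair(
    variant_key: Key,
    trio: TrioDataset,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    min_alt: int = DEFAULT_MIN_ALT_READS,
    germline_ratio: float = DEFAULT_GERMLINE_RATIO,
) -> tuple[bool, bool]:
    """Presence flags (tumor, metastasis) for a somatic variant.

    Presence by direct somatic call is always retained; presence in the
    other sample of the pair is granted by the MAF cross-rescue rule.
    """
    t = trio.tumor.get(variant_key)
    m = trio.metastasis.get(variant_key)
    called_t = t is not None and t.caller_somatic
    called_m = m is not None and m.caller_somatic
    if not called_t and not called_m:
        raise ValueError(
            f"variant {variant_key} not called somatic in either sample"
        )
    n = trio.normal.get(variant_key)
    control_maf = n.maf if n is not None else 0.0
    present_t = called_t or (
        called_m and _rescued_in(t, control_maf, maf_threshold, min_alt, germline_ratio)
    )
    present_m = called_m or (
        called_t and _rescued_in(m, control_maf, maf_threshold, min_alt, germline_ratio)
    )
    return present_t, present_m


def assign_stratum(present_tumor: bool, present_met: bool) -> str:
    if present_tumor and present_met:
        return "shared"
    if present_tumor:
        return "tumor_private"
    if present_met:
        return "met_private"
    raise ValueError("variant present in neither sample")


def stratify_trio(
    trio: TrioDataset,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    min_alt: int = DEFAULT_MIN_ALT_READS,
    germline_ratio: float = DEFAULT_GERMLINE_RATIO,
) -> StratifiedCatalog:
    """Stratify every somatic variant of the trio.

    Summary fractions are computed over the union of somatic SNVs; indels
    are stratified under the same rules but flagged as an extension and
    excluded from the fractions.
    """
    keys = trio.somatic_union()
    if not keys:
        raise ValueError(f"trio {trio.patient_id}: no somatic variants to stratify")
    assignments: dict[Key, str] = {}
    indels: set[Key] = set()
    counts = {"shared": 0, "tumor_private": 0, "met_private": 0}
    n_snvs = 0
    for key in keys:
        present_t, present_m = rescue_in_pair(
            key, trio, maf_threshold, min_alt, germline_ratio
        )
        stratum = assign_stratum(present_t, present_m)
        assignments[key] = stratum
        is_snv = len(key[2]) == 1 and len(key[3]) == 1
        if is_snv:
            counts[stratum] += 1
            n_snvs += 1
        else:
            indels.add(key)
    if n_snvs == 0:
        raise ValueError(f"trio {trio.patient_id}: no somatic SNVs to stratify")
    return StratifiedCatalog(
        patient_id=trio.patient_id,
        assignments=assignments,
        f_shared=counts["shared"] / n_snvs,
        f_tumor=counts["tumor_private"] / n_snvs,
        f_met=counts["met_private"] / n_snvs,
        n_snvs=n_snvs,
        indel_keys=frozenset(indels),
    )


def mutation_rate_per_mb(n_snvs: int, mappable_bases: float) -> float:
    """Somatic SNVs per megabase of mappable genome, to one decimal."""
    if mappable_bases <= 0:
        raise ValueError("mappable_bases must be positive")
    return round(n_snvs / (mappable_bases / 1e6), 1)


def classify_sample_msi_pole(
    annotated: Iterable[AnnotatedVariant],
    mmr_genes: frozenset[str] = MMR_GENES,
    pole_gene: str = POLE_GENE,
) -> dict[str, bool]:
    """Flags for mismatch-repair and POLE driver hits among mutations of interest.

    Only non-silent mutations of interest count; e.g. a 3'-UTR hit on POLE
    does not flag the sample.
    """
    mmr_hit = False
    pole_hit = False
    for av in annotated:
        if not is_mutation_of_interest(av):
            continue
        genes = set(av.gene_ids)
        if genes & mmr_genes:
            mmr_hit = True
        if pole_gene in genes:
            pole_hit = True
    return {"mmr_hit": mmr_hit, "pole_hit": pole_hit}
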