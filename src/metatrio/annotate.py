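"""Region classification and mutation-of-interest flagging.

Variants are classified against interval gene models (no transcript
engine): the highest-priority overlapping region class wins, with

    splice_site > CDS > UTR3 > UTR5 > ncRNA_exon > intron > intergenic.

A position counts as splice site when it lies outside an exonic interval
(CDS/UTR/ncRNA exon) but within 2 bp of its boundary, or when it overlaps
an explicitly annotated splice_site interval.

Without codon information every CDS SNV is treated as potentially
non-silent; a caller that knows a variant is synonymous can say so and it
is then excluded. 3'-UTR variants are a separate analysis channel, not
mutations of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import EXONIC_CLASSES, GeneModelSet, VariantRecord

#: classification priority, highest first
REGION_PRIORITY = (
    "splice_site", "CDS", "UTR3", "UTR5", "ncRNA_exon", "intron", "intergenic"
)

_PRIORITY_RANK = {c: i for i, c in enumerate(REGION_PRIORITY)}

SPLICE_SITE_BP = 2


@dataclass(slots=True)
class AnnotatedVariant:
    variant: VariantRecord
    region_class: str
    gene_ids: tuple[str, ...]
    indel_frame: str  # frameshift | inframe | not_applicable
    non_silent: bool

    def __post_init__(self) -> None:
        if self.region_class not in _PRIORITY_RANK:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.variant.is_snv and self.indel_frame != "not_applicable":
            raise ValueError("indel_frame must be not_applicable for SNVs")


def classify_region(
    variant: VariantRecord, models: GeneModelSet
) -> tuple[str, tuple[str, ...]]:
    """Region class and gene ids for a variant; intergenic when nothing overlaps."""
    pos = variant.pos
    hits = models.query_window(variant.chrom, pos - SPLICE_SITE_BP, pos + SPLICE_SITE_BP)
    classes: dict[str, set[str]] = {}
    for iv in hits:
        covering = iv.start <= pos <= iv.end
        if covering:
            classes.setdefault(iv.region_class, set()).add(iv.gene_id)
        elif iv.region_class in EXONIC_CLASSES:
            # near an exon boundary but outside the exon: splice site
            classes.setdefault("splice_site", set()).add(iv.gene_id)
    for cls in REGION_PRIORITY:
        if cls in classes:
            return cls, tuple(sorted(classes[cls]))
    return "intergenic", ()


def classify_indel_frame(variant: VariantRecord) -> str:
    """``frameshift`` iff the length change is not a multiple of 3."""
    if variant.is_snv:
        raise ValueError("classify_indel_frame requires an indel, got an SNV")
    return "frameshift" if abs(len(variant.ref) - len(variant.alt)) % 3 != 0 else "inframe"


def annotate_variant(
    variant: VariantRecord,
    models: GeneModelSet,
    synonymous: bool | None = None,
) -> AnnotatedVariant:
    """Classify one variant; ``synonymous=True`` marks a CDS SNV as silent."""
    region_class, gene_ids = classify_region(variant, models)
    if variant.is_snv:
        indel_frame = "not_applicable"
        non_silent = region_class in ("CDS", "splice_site") and synonymous is not True
    else:
        indel_frame = classify_indel_frame(variant)
        non_silent = region_class in ("CDS", "splice_site")
    return AnnotatedVariant(variant, region_class, gene_ids, indel_frame, non_silent)


def is_mutation_of_interest(annotated: AnnotatedVariant) -> bool:
    """Non-silent coding change, splice-site mutation, or non-coding exonic hit.

    3'-UTR and intronic variants are not mutations of interest; indels
    count when they touch coding sequence or a splice site.
    """
    if annotated.region_class == "ncRNA_exon":
        return True
    if annotated.region_class in ("CDS", "splice_site"):
        return annotated.non_silent
    return False
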