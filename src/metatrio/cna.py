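"""Copy-number state calling and arm-level recurrence summaries.

Segments (consumed from an allele-specific copy-number caller) are labelled
gain or loss when their total copy number deviates from the sample's base
ploidy by strictly more than 0.7; LOH when the minor-allele copy number is
below 0.5 (i.e. rounds to zero). Arm-level recurrence reports, per
chromosome arm, the proportion of samples carrying at least one gain, loss
or LOH segment overlapping the arm.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import ArmMap, CNSegment, GeneModelSet

DEFAULT_CNA_THRESHOLD = 0.7
LOH_MINOR_CN = 0.5

SEX_CHROMS = frozenset({"X", "Y"})


def call_cna_state(
    segment: CNSegment, base_ploidy: float, threshold: float = DEFAULT_CNA_THRESHOLD
) -> str:
    """gain / loss / neutral relative to base ploidy (strict > threshold)."""
    if base_ploidy <= 0:
        raise ValueError("base_ploidy must be positive")
    dev = segment.tcn - base_ploidy
    # a deviation exactly at the threshold is neutral; guard the strict
    # comparison against float round-off (2.7 - 2.0 > 0.7 in binary)
    if math.isclose(abs(dev), threshold, rel_tol=1e-12, abs_tol=1e-12):
        return "neutral"
    if dev > threshold:
        return "gain"
    if -dev > threshold:
        return "loss"
    return "neutral"


def call_loh(segment: CNSegment) -> bool | None:
    """LOH iff the minor-allele copy number is known and below 0.5."""
    if segment.minor_cn is None:
        return None
    return segment.minor_cn < LOH_MINOR_CN


def call_states(
    segments: Iterable[CNSegment],
    ploidy_by_sample: Mapping[str, float],
    threshold: float = DEFAULT_CNA_THRESHOLD,
) -> list[CNSegment]:
    """Fill ``state`` and ``loh`` on every segment whose sample has a ploidy.

    Segments of samples without a ploidy are returned untouched (state
    None) with a warning.
    """
    out = []
    missing: set[str] = set()
    for seg in segments:
        ploidy = ploidy_by_sample.get(seg.sample_id)
        if ploidy is None:
            missing.add(seg.sample_id)
        else:
            seg.state = call_cna_state(seg, ploidy, threshold)
            seg.loh = call_loh(seg)
        out.append(seg)
    if missing:
        warnings.warn(f"samples without ploidy excluded from CNA calls: {sorted(missing)}")
    return out


def _overlaps(seg: CNSegment, start: int, end: int) -> bool:
    return seg.start <= end and seg.end >= start


def arm_recurrence(
    segments: Iterable[CNSegment],
    arms: ArmMap,
    ploidy_by_sample: Mapping[str, float],
    threshold: float = DEFAULT_CNA_THRESHOLD,
    include_sex: bool = False,
) -> pd.DataFrame:
    """Per-arm proportion of samples with >= 1 gain / loss / LOH segment.

    A sample counts for an arm when any of its segments with that state
    overlaps the arm by at least 1 bp; a segment spanning the centromere
    counts for both arms. The denominator for an arm is the number of
    samples with any segment data on that chromosome. Sex chromosomes are
    excluded unless requested.
    """
    segments = call_states(list(segments), ploidy_by_sample, threshold)
    segments = [s for s in segments if s.state is not None]
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    rows = []
    for chrom, arm, start, end in arms.arms():
        if not include_sex and chrom in SEX_CHROMS:
            continue
        chrom_segs = by_chrom.get(chrom, [])
        samples_with_data = {s.sample_id for s in chrom_segs}
        denom = len(samples_with_data)
        hit = {"gain": set(), "loss": set(), "loh": set()}
        for seg in chrom_segs:
            if not _overlaps(seg, start, end):
                continue
            if seg.state in ("gain", "loss"):
                hit[seg.state].add(seg.sample_id)
            if seg.loh is True:
                hit["loh"].add(seg.sample_id)
        rows.append(
            {
                "chrom": chrom,
                "arm": arm,
                "n_samples": denom,
                "prop_gain": len(hit["gain"]) / denom if denom else 0.0,
                "prop_loss": len(hit["loss"]) / denom if denom else 0.0,
                "prop_loh": len(hit["loh"]) / denom if denom else 0.0,
            }
        )
    return pd.DataFrame(rows)


def annotate_genes_cna(
    segments: Iterable[CNSegment], models: GeneModelSet
) -> pd.DataFrame:
    """Per (sample, gene) copy-number state by direct overlap with gene spans.

    A gene inherits the state of every overlapping non-neutral segment;
    when both a gain and a loss overlap the same gene the call is
    ``complex``. Genes overlapped only by neutral segments are
    ``neutral``; genes with no overlapping segment are absent.
    """
    spans = models.gene_spans()
    rows = []
    by_sample: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for sample in sorted(by_sample):
        for gene_id in sorted(spans):
            chrom, gstart, gend = spans[gene_id]
            states = {
                seg.state
                for seg in by_sample[sample]
                if seg.chrom == chrom and _overlaps(seg, gstart, gend)
                and seg.state is not None
            }
            if not states:
                continue
            non_neutral = states - {"neutral"}
            if len(non_neutral) > 1:
                state = "complex"
            elif non_neutral:
                state = non_neutral.pop()
            else:
                state = "neutral"
            rows.append({"sample_id": sample, "gene": gene_id, "state": state})
    return pd.DataFrame(rows, columns=["sample_id", "gene", "state"])
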