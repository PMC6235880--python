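"""Kataegis detection from inter-mutation distances.

Kataegis (localized somatic hypermutation) is operationalized as any run
of at least 5 consecutive mutations spanning at most 10 kb on one
chromosome. Overlapping qualifying runs are merged into maximal loci; a
locus is proximal to a gene when it lies within 10 kb of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModelSet, VariantRecord
from .contexts import normalize_chrom

DEFAULT_MIN_MUTATIONS = 5
DEFAULT_WINDOW = 10_000


@dataclass(slots=True)
class KataegisLocus:
    chrom: str
    start: int  # position of the first member mutation
    end: int    # position of the last member mutation
    members: tuple[int, ...]  # member positions, ascending
    proximal_genes: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


def positions_by_chromosome(
    variants: Iterable[VariantRecord],
) -> dict[str, list[int]]:
    """Sorted SNV positions per chromosome (kataegis input)."""
    out: dict[str, list[int]] = {}
    for rec in variants:
        out.setdefault(rec.chrom, []).append(rec.pos)
    for positions in out.values():
        positions.sort()
    return out


def _ensure_sorted(positions: Sequence[int]) -> list[int]:
    positions = list(positions)
    if any(a > b for a, b in zip(positions, positions[1:])):
        warnings.warn("positions not sorted; sorting internally")
        positions.sort()
    return positions


def intermutation_distances(
    positions_per_chrom: Mapping[str, Sequence[int]],
) -> dict[str, list[int]]:
    """Distance of each mutation to its predecessor on the same chromosome.

    The first mutation of a chromosome has no distance; duplicate
    positions yield a distance of 0.
    """
    out: dict[str, list[int]] = {}
    for chrom, positions in positions_per_chrom.items():
        positions = _ensure_sorted(positions)
        out[chrom] = [b - a for a, b in zip(positions, positions[1:])]
    return out


def detect_kataegis(
    positions_per_chrom: Mapping[str, Sequence[int]],
    k: int = DEFAULT_MIN_MUTATIONS,
    window: int = DEFAULT_WINDOW,
) -> list[KataegisLocus]:
    """Maximal loci formed by runs of >= k mutations spanning <= window bp.

    Every run of k consecutive mutations whose span (last - first) is at
    most ``window`` seeds a locus; overlapping or index-adjacent
    qualifying runs merge, and members are all mutations inside the
    merged index range.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if window < 1:
        raise ValueError("window must be >= 1")
    loci: list[KataegisLocus] = []
    for chrom in sorted(positions_per_chrom):
        positions = _ensure_sorted(positions_per_chrom[chrom])
        n = len(positions)
        runs = [
            (i, i + k - 1)
            for i in range(n - k + 1)
            if positions[i + k - 1] - positions[i] <= window
        ]
        if not runs:
            continue
        merged: list[list[int]] = []
        for lo, hi in runs:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            members = tuple(positions[lo: hi + 1])
            loci.append(
                KataegisLocus(
                    chrom=normalize_chrom(chrom),
                    start=members[0],
                    end=members[-1],
                    members=members,
                )
            )
    return loci


def annotate_locus_proximity(
    loci: Iterable[KataegisLocus],
    models: GeneModelSet,
    max_dist: int = DEFAULT_WINDOW,
) -> list[KataegisLocus]:
    """Attach genes whose span lies within ``max_dist`` bp of each locus.

    Overlap counts as distance 0; the boundary is inclusive (a gene ending
    exactly ``max_dist`` bp away is listed).
    """
    spans = models.gene_spans()
    out = []
    for locus in loci:
        genes = []
        for gene_id, (chrom, gstart, gend) in spans.items():
            if chrom != locus.chrom:
                continue
            gap = max(0, gstart - locus.end, locus.start - gend)
            if gap <= max_dist:
                genes.append(gene_id)
        out.append(
            KataegisLocus(
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
                members=locus.members,
                proximal_genes=tuple(sorted(genes)),
            )
        )
    return out


def recurrent_regions(
    loci_by_sample: Mapping[str, Sequence[KataegisLocus]],
    min_samples: int = 2,
) -> list[dict]:
    """Genomic regions where kataegis loci from >= min_samples samples intersect.

    Loci across all samples are merged into maximal overlapping regions;
    each region reports the distinct samples contributing a locus.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for sample, loci in loci_by_sample.items():
        for locus in loci:
            by_chrom.setdefault(locus.chrom, []).append(
                (locus.start, locus.end, sample)
            )
    regions = []
    for chrom in sorted(by_chrom):
        intervals = sorted(by_chrom[chrom])
        current = None
        for start, end, sample in intervals:
            if current is not None and start <= current["end"]:
                current["end"] = max(current["end"], end)
                current["samples"].add(sample)
            else:
                if current is not None:
                    regions.append(current)
                current = {"chrom": chrom, "start": start, "end": end,
                           "samples": {sample}}
        if current is not None:
            regions.append(current)
    out = []
    for region in regions:
        if len(region["samples"]) >= min_samples:
            region["samples"] = sorted(region["samples"])
            out.append(region)
    return out
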