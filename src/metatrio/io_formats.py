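"""Readers and writers for the on-disk formats the pipeline consumes.

All in-memory coordinates are 1-based inclusive (VCF convention); BED-style
0-based half-open inputs are converted at this boundary and converted back
on write. Chromosome names are normalized by stripping any ``chr`` prefix.

Formats
-------
- variant tables: a TSV dialect (8 named columns, optional ``context``) and
  a VCF subset (VCFv4.2 with per-sample AD allele depths);
- gene models: BED-like with a region-class column;
- signature matrices: TSV, context labels in the first column, one column
  per signature;
- copy-number segments and chromosome-arm definitions: simple TSVs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .contexts import CONTEXT_INDEX, CONTEXT_LABELS, normalize_chrom


class FormatError(ValueError):
    """File structure (header, column count, dialect) is wrong."""


class ValidationError(ValueError):
    """File parsed but a record violates an invariant."""


REGION_CLASSES = frozenset(
    {"CDS", "UTR5", "UTR3", "ncRNA_exon", "intron", "splice_site"}
)

#: exonic classes whose boundaries define splice sites
EXONIC_CLASSES = frozenset({"CDS", "UTR5", "UTR3", "ncRNA_exon"})


# ---------------------------------------------------------------------------
# variant records


@dataclass(slots=True)
class VariantRecord:
    """One somatic/germline call with per-sample read support.

    ``pos`` is 1-based. ``caller_somatic`` is the upstream caller's verdict;
    TiNDA may later promote germline-labelled records. ``context`` is the
    reference-strand trinucleotide (5' base, ref, 3' base) for SNVs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    ref_count: int
    alt_count: int
    caller_somatic: bool = True
    context: str | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(str(self.chrom))
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"negative read count at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele at {self.chrom}:{self.pos}")
        if self.context is not None:
            self.context = self.context.upper()
            if len(self.context) != 3:
                raise ValidationError(
                    f"context must be 3 bases at {self.chrom}:{self.pos}"
                )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def maf(self) -> float:
        """Mutant allele fraction, alt reads over total reads (0 if no reads)."""
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


_TSV_COLUMNS = (
    "chrom", "pos", "ref", "alt", "sample_id",
    "ref_count", "alt_count", "caller_somatic",
)

_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "t": True, "f": False}


def _parse_bool(value: str, row: int) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise FormatError(f"row {row}: cannot parse boolean {value!r}") from None


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read a variant table; returns validated records in input order.

    ``dialect`` is ``"tsv"`` (8 named columns, optional 9th ``context``) or
    ``"vcf_subset"`` (VCFv4.2 with per-sample AD). Multi-allelic VCF rows
    are split into one record per alternate allele. Records violating an
    invariant are rejected with their row number.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf_subset":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "chrom":
                expected = list(_TSV_COLUMNS)
                got = [c.strip().lower() for c in row[: len(expected)]]
                if got != expected:
                    raise FormatError(
                        f"malformed header: expected columns {expected}, got {got}"
                    )
                continue
            if len(row) < 8:
                raise FormatError(f"row {lineno}: expected >= 8 columns, got {len(row)}")
            try:
                pos = int(row[1])
                ref_count = int(row[5])
                alt_count = int(row[6])
            except ValueError:
                raise FormatError(f"row {lineno}: non-integer numeric field") from None
            context = row[8].strip() or None if len(row) > 8 else None
            try:
                records.append(
                    VariantRecord(
                        chrom=row[0], pos=pos, ref=row[2], alt=row[3],
                        sample_id=row[4], ref_count=ref_count,
                        alt_count=alt_count,
                        caller_somatic=_parse_bool(row[7], lineno),
                        context=context,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {lineno}: {exc}") from None
    return records


def _read_variant_vcf(path: str | Path) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from None
    with vcf:
        if "AD" not in vcf.header.formats:
            raise FormatError("VCF subset dialect requires a per-sample AD FORMAT field")
        for row, rec in enumerate(vcf, start=1):
            somatic = bool(rec.info.get("SOMATIC", False))
            alts = rec.alts or ()
            for sample_id, sample in rec.samples.items():
                ad = sample.get("AD")
                if ad is None or ad[0] is None:
                    continue
                for i, alt in enumerate(alts):
                    alt_count = ad[i + 1] if len(ad) > i + 1 and ad[i + 1] is not None else 0
                    try:
                        records.append(
                            VariantRecord(
                                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                                alt=str(alt), sample_id=sample_id,
                                ref_count=int(ad[0]), alt_count=int(alt_count),
                                caller_somatic=somatic,
                            )
                        )
                    except ValidationError as exc:
                        raise ValidationError(f"VCF record {row}: {exc}") from None
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as the TSV dialect (with header); read round-trips exactly."""
    records = list(records)
    with_context = any(r.context is not None for r in records)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        header = list(_TSV_COLUMNS) + (["context"] if with_context else [])
        writer.writerow(header)
        for r in records:
            row = [r.chrom, r.pos, r.ref, r.alt, r.sample_id,
                   r.ref_count, r.alt_count, int(r.caller_somatic)]
            if with_context:
                row.append(r.context or "")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True, slots=True)
class GeneInterval:
    """One gene-model interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    region_class: str


class GeneModelSet:
    """Point-queryable gene-model intervals (1-based inclusive in memory)."""

    def __init__(self, intervals: Iterable[GeneInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GeneInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GeneInterval) -> None:
        if iv.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region_class {iv.region_class!r}")
        if iv.start > iv.end:
            raise ValidationError(
                f"empty interval {iv.chrom}:{iv.start}-{iv.end} for {iv.gene_id}"
            )
        # interval tree is half-open; store [start, end+1)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end + 1, iv
        )
        self._intervals.append(iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GeneInterval]:
        return iter(self._intervals)

    def query(self, chrom: str, pos: int) -> list[GeneInterval]:
        """All intervals covering the 1-based position."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.at(pos)),
            key=lambda iv: (iv.start, iv.end, iv.gene_id, iv.region_class),
        )

    def query_window(self, chrom: str, start: int, end: int) -> list[GeneInterval]:
        """All intervals overlapping the 1-based inclusive window."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(start, end + 1)),
            key=lambda iv: (iv.start, iv.end, iv.gene_id, iv.region_class),
        )

    def gene_spans(self) -> dict[str, tuple[str, int, int]]:
        """Per gene_id the (chrom, min start, max end) over its intervals."""
        spans: dict[str, tuple[str, int, int]] = {}
        for iv in self._intervals:
            if iv.gene_id in spans:
                chrom, s, e = spans[iv.gene_id]
                spans[iv.gene_id] = (chrom, min(s, iv.start), max(e, iv.end))
            else:
                spans[iv.gene_id] = (iv.chrom, iv.start, iv.end)
        return spans


def read_gene_models(path: str | Path) -> GeneModelSet:
    """Read BED-like gene models: chrom, start, end, gene_id, score, strand, region_class.

    Coordinates on disk are 0-based half-open (BED) and are converted to
    1-based inclusive in memory.
    """
    models = GeneModelSet()
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"row {lineno}: expected 7 BED columns, got {len(fields)}"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"row {lineno}: non-integer coordinate") from None
            if start0 >= end0:
                raise ValidationError(
                    f"row {lineno}: empty BED interval {fields[0]}:{start0}-{end0}"
                )
            try:
                models.add(
                    GeneInterval(
                        chrom=normalize_chrom(fields[0]),
                        start=start0 + 1,
                        end=end0,
                        strand=fields[5],
                        gene_id=fields[3],
                        region_class=fields[6],
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {lineno}: {exc}") from None
    return models


def write_gene_models(models: GeneModelSet, path: str | Path) -> None:
    """Write gene models back to BED (0-based half-open)."""
    with open(path, "w") as handle:
        for iv in models:
            handle.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene_id}\t.\t"
                f"{iv.strand}\t{iv.region_class}\n"
            )


# ---------------------------------------------------------------------------
# signature matrices


@dataclass(slots=True)
class SignatureMatrix:
    """96-context x S signature probability matrix (columns sum to 1)."""

    signature_ids: tuple[str, ...]
    W: np.ndarray
    contexts: tuple[str, ...] = field(default=CONTEXT_LABELS)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.signature_ids = tuple(self.signature_ids)
        self.contexts = tuple(self.contexts)
        if self.contexts != CONTEXT_LABELS:
            raise ValidationError("contexts must be the canonical 96-label order")
        if self.W.shape != (96, len(self.signature_ids)):
            raise ValidationError(
                f"W must be 96x{len(self.signature_ids)}, got {self.W.shape}"
            )
        if len(set(self.signature_ids)) != len(self.signature_ids):
            raise ValidationError("duplicate signature ids")
        if np.any(self.W < 0):
            raise ValidationError("negative entry in signature matrix")
        sums = self.W.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError(
                f"signature columns must sum to 1 +- 1e-6, got {sums}"
            )

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def subset(self, signature_ids: Sequence[str]) -> "SignatureMatrix":
        """Restrict to the given signatures (order preserved as given)."""
        idx = [self.signature_ids.index(s) for s in signature_ids]
        return SignatureMatrix(tuple(signature_ids), self.W[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.W, index=list(self.contexts), columns=list(self.signature_ids)
        )


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a signature TSV: first column context labels, one column per signature.

    Rows may appear in any order; they are canonicalized to the fixed
    96-label order. Columns are renormalized to exactly 1 only when their
    sum is within 1e-3 of 1; otherwise the file is rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError("signature matrix needs at least one signature column")
    missing = [lab for lab in CONTEXT_LABELS if lab not in df.index]
    if missing:
        raise ValidationError(f"missing context row(s): {missing[:5]}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicated context row(s): {dups[:5]}")
    extra = [lab for lab in df.index if lab not in CONTEXT_INDEX]
    if extra:
        raise ValidationError(f"unknown context row(s): {extra[:5]}")
    df = df.loc[list(CONTEXT_LABELS)]
    W = df.to_numpy(dtype=float)
    if np.any(W < 0):
        raise ValidationError("negative entry in signature matrix")
    sums = W.sum(axis=0)
    bad = np.abs(sums - 1.0) > 1e-3
    if np.any(bad):
        bad_ids = [str(c) for c, b in zip(df.columns, bad) if b]
        raise ValidationError(
            f"column(s) {bad_ids} do not sum to 1 within 1e-3"
        )
    W = W / sums
    return SignatureMatrix(tuple(str(c) for c in df.columns), W)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="context")


# ---------------------------------------------------------------------------
# copy-number segments


@dataclass(slots=True)
class CNSegment:
    """Allele-specific copy-number segment (1-based inclusive coordinates).

    ``state``/``loh`` are filled in by the CNA caller; ``loh`` is None when
    the minor-allele copy number is unknown.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    tcn: float
    minor_cn: float | None = None
    state: str | None = None
    loh: bool | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(str(self.chrom))
        if self.start > self.end:
            raise ValidationError(
                f"segment start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.tcn < 0:
            raise ValidationError(f"negative total copy number {self.tcn}")
        if self.minor_cn is not None and self.minor_cn > self.tcn / 2 + 0.51:
            raise ValidationError(
                f"minor_cn {self.minor_cn} inconsistent with tcn {self.tcn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read a segments TSV: chrom, start, end, tcn, [minor_cn], [sample_id].

    Header optional. Returns segments sorted by (sample, chrom, start);
    overlapping segments within a sample are rejected.
    """
    segs: list[CNSegment] = []
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().lower() == "chrom":
                continue
            if len(fields) < 4:
                raise FormatError(f"row {lineno}: expected >= 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                tcn = float(fields[3])
                minor = (
                    float(fields[4])
                    if len(fields) > 4 and fields[4].strip() not in ("", "NA", ".")
                    else None
                )
            except ValueError:
                raise FormatError(f"row {lineno}: cannot parse numeric field") from None
            sample = fields[5] if len(fields) > 5 and fields[5].strip() else "sample"
            try:
                segs.append(
                    CNSegment(sample_id=sample, chrom=fields[0], start=start,
                              end=end, tcn=tcn, minor_cn=minor)
                )
            except ValidationError as exc:
                raise ValidationError(f"row {lineno}: {exc}") from None
    segs.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    for a, b in zip(segs, segs[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start <= a.end:
            raise ValidationError(
                f"overlapping segments for {a.sample_id}: "
                f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
            )
    return segs


def write_segments(segments: Iterable[CNSegment], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tstart\tend\ttcn\tminor_cn\tsample_id\n")
        for s in segments:
            minor = "" if s.minor_cn is None else f"{s.minor_cn:g}"
            handle.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.tcn:g}\t{minor}\t{s.sample_id}\n"
            )


# ---------------------------------------------------------------------------
# chromosome arms


class ArmMap:
    """Per-chromosome p/q arm extents, 1-based inclusive, p preceding q."""

    def __init__(self, arms: dict[str, dict[str, tuple[int, int]]]) -> None:
        for chrom, d in arms.items():
            for arm, (start, end) in d.items():
                if arm not in ("p", "q"):
                    raise ValidationError(f"unknown arm {arm!r} on {chrom}")
                if start > end:
                    raise ValidationError(f"empty arm {chrom}{arm}")
            if "p" in d and "q" in d and d["p"][1] >= d["q"][0]:
                raise ValidationError(f"arms overlap on {chrom}")
        self._arms = arms

    def chromosomes(self) -> list[str]:
        return sorted(self._arms)

    def arms(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield (chrom, arm, start, end) with p before q."""
        for chrom in self.chromosomes():
            for arm in ("p", "q"):
                if arm in self._arms[chrom]:
                    start, end = self._arms[chrom][arm]
                    yield chrom, arm, start, end

    def get(self, chrom: str, arm: str) -> tuple[int, int] | None:
        return self._arms.get(normalize_chrom(chrom), {}).get(arm)


def read_arms(path: str | Path) -> ArmMap:
    """Read a cytoband-like arms TSV: chrom, arm (p/q), start, end (1-based)."""
    arms: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().lower() == "chrom":
                continue
            if len(fields) < 4:
                raise FormatError(f"row {lineno}: expected 4 columns")
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError:
                raise FormatError(f"row {lineno}: non-integer coordinate") from None
            chrom = normalize_chrom(fields[0])
            arm = fields[1].strip()
            if arm in arms.setdefault(chrom, {}):
                raise ValidationError(f"row {lineno}: duplicate arm {chrom}{arm}")
            arms[chrom][arm] = (start, end)
    return ArmMap(arms)
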