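"""Mutational catalogs and supervised signature decomposition.

A sample's SNVs are binned into the 96 pyrimidine-centered trinucleotide
substitution contexts (the mutational catalog C). Given a signature matrix
W (96 x S probability columns), exposures are the non-negative least
squares solution

    e = argmin_{e >= 0} || C - W e ||_2,

in mutation-count units; normalized exposures are e / sum(e). Weakly
contributing signatures are pruned by signature-specific cutoffs on the
normalized exposure, re-fitting after each removal; cohort-level detection
fits the summed cohort catalog and restricts all per-sample fits to the
surviving signatures. Exposures of the shared, tumor-private and
metastasis-private strata are compared per signature across patients with
a paired Wilcoxon signed-rank test, Benjamini-Hochberg corrected across
signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import nnls as _scipy_nnls

from .contexts import CONTEXT_INDEX, CONTEXT_LABELS, context_label
from .io_formats import SignatureMatrix, VariantRecord
from .cohort_stats import bh_adjust


@dataclass(slots=True)
class Catalog96:
    """Counts over the 96 canonical substitution contexts."""

    counts: np.ndarray
    skipped: int = 0  # SNVs dropped for N-containing/invalid contexts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have 96 bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative catalog count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "Catalog96") -> "Catalog96":
        return Catalog96(self.counts + other.counts, self.skipped + other.skipped)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS))


@dataclass(slots=True)
class ExposureVector:
    """Fitted per-signature exposures for one catalog.

    ``exposures`` are absolute (mutation-count units); ``normalized``
    divides by the total exposure. ``residual`` is ||C - W e||_2.
    """

    signature_ids: tuple[str, ...]
    exposures: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        self.signature_ids = tuple(self.signature_ids)
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.shape != (len(self.signature_ids),):
            raise ValueError("exposures/signature_ids length mismatch")
        if np.any(self.exposures < -1e-12):
            raise ValueError("negative exposure")
        self.exposures = np.clip(self.exposures, 0.0, None)

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    @property
    def normalized(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros_like(self.exposures)
        return self.exposures / total

    def to_series(self, normalized: bool = False) -> pd.Series:
        values = self.normalized if normalized else self.exposures
        return pd.Series(values, index=list(self.signature_ids))


def build_catalog(snvs: Iterable[VariantRecord]) -> Catalog96:
    """Bin SNVs with trinucleotide contexts into the 96-context catalog.

    Purine-reference SNVs are reverse-complemented onto the pyrimidine
    strand. SNVs whose context contains N (or is otherwise invalid) are
    skipped and counted in ``skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for rec in snvs:
        if not rec.is_snv:
            raise ValueError(f"non-SNV record at {rec.chrom}:{rec.pos}")
        if rec.context is None:
            raise ValueError(f"SNV at {rec.chrom}:{rec.pos} lacks a context")
        try:
            label = context_label(rec.ref, rec.alt, rec.context)
        except ValueError:
            skipped += 1
            continue
        counts[CONTEXT_INDEX[label]] += 1
    return Catalog96(counts, skipped=skipped)


def attach_contexts_from_fasta(
    variants: Iterable[VariantRecord], fasta_path: str
) -> int:
    """Fill in trinucleotide contexts from a reference FASTA (real data).

    Returns the number of SNVs that received a context. Flanks are
    uppercased; the FASTA must be faidx-indexable.
    """
    import pysam

    n = 0
    with pysam.FastaFile(fasta_path) as fasta:
        for rec in variants:
            if not rec.is_snv:
                continue
            seq = fasta.fetch(rec.chrom, rec.pos - 2, rec.pos + 1).upper()
            if len(seq) == 3:
                rec.context = seq
                n += 1
    return n


def nnls_decompose(catalog: Catalog96, W: SignatureMatrix) -> ExposureVector:
    """Non-negative least-squares decomposition of a catalog against W."""
    if catalog.total <= 0:
        raise ValueError("zero catalog: nothing to decompose, skip this sample")
    e, residual = _scipy_nnls(W.W, catalog.counts)
    return ExposureVector(W.signature_ids, e, float(residual))


def _as_cutoff_array(
    cutoffs: float | Mapping[str, float], signature_ids: Sequence[str]
) -> np.ndarray:
    if isinstance(cutoffs, Mapping):
        return np.array([float(cutoffs.get(s, 0.0)) for s in signature_ids])
    return np.full(len(signature_ids), float(cutoffs))


DEFAULT_CUTOFF = 0.06


def apply_signature_cutoffs(
    exposures: ExposureVector,
    cutoffs: float | Mapping[str, float],
    catalog: Catalog96,
    W: SignatureMatrix,
) -> ExposureVector:
    """Prune signatures below their normalized-exposure cutoff and re-fit.

    Signatures whose normalized exposure falls below their cutoff are
    removed — one per iteration, the one furthest below its cutoff — and
    the NNLS re-run on the remaining columns, until every surviving
    signature meets its cutoff. One-at-a-time removal keeps the result in
    step with the best admissible subset (removing several at once can
    discard a signature that would clear its cutoff after the re-fit).
    Removed signatures keep a zero exposure so the vector stays aligned
    with W. If nothing survives a zero vector is returned with a warning.
    """
    sig_ids = list(W.signature_ids)
    if tuple(exposures.signature_ids) != tuple(sig_ids):
        raise ValueError("exposure vector and W signature ids disagree")
    cut = _as_cutoff_array(cutoffs, sig_ids)
    active = [i for i in range(len(sig_ids))]
    current = exposures
    while active:
        norm = current.normalized
        margins = [(norm[j] - cut[i], i) for j, i in enumerate(active)]
        worst = min(margins)
        if worst[0] >= 0:
            break
        active = [i for i in active if i != worst[1]]
        if not active:
            break
        sub = W.subset([sig_ids[i] for i in active])
        current = nnls_decompose(catalog, sub)
    if not active:
        warnings.warn("all signatures removed by cutoffs; returning zero exposures")
        residual = float(np.linalg.norm(catalog.counts))
        return ExposureVector(tuple(sig_ids), np.zeros(len(sig_ids)), residual)
    full = np.zeros(len(sig_ids))
    for j, i in enumerate(active):
        full[i] = current.exposures[j]
    return ExposureVector(tuple(sig_ids), full, current.residual)


def cohort_signature_detection(
    catalogs: Sequence[Catalog96],
    W: SignatureMatrix,
    cutoffs: float | Mapping[str, float] = DEFAULT_CUTOFF,
) -> tuple[str, ...]:
    """Signatures active in the summed cohort catalog after cutoff pruning.

    The surviving set defines the restricted matrix used for all
    per-sample and per-stratum fits.
    """
    if not catalogs:
        raise ValueError("empty cohort")
    total = catalogs[0]
    for cat in catalogs[1:]:
        total = total + cat
    fit = nnls_decompose(total, W)
    pruned = apply_signature_cutoffs(fit, cutoffs, total, W)
    active = tuple(
        s for s, e in zip(pruned.signature_ids, pruned.exposures) if e > 0
    )
    if not active:
        raise ValueError("no signature survives the cohort-level cutoffs")
    return active


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; exact for small n, 1 if all ties."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return 1.0
    method = "exact" if len(d) <= 25 and not np.any(d == 0) else "auto"
    res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


STRATA_PAIRS = (
    ("tumor_private", "met_private"),
    ("tumor_private", "shared"),
    ("met_private", "shared"),
)


def compare_strata_exposures(
    exposures_by_patient: Mapping[str, Mapping[str, ExposureVector]],
) -> pd.DataFrame:
    """Per-signature paired comparison of normalized exposures across strata.

    For every signature and every strata pair a two-sided paired Wilcoxon
    signed-rank test is run across patients; p-values are BH-adjusted
    across signatures within each pair. ``median_diff`` is the median of
    the per-patient differences (first minus second stratum).
    """
    patients = sorted(exposures_by_patient)
    if len(patients) < 3:
        raise ValueError("strata comparison needs at least 3 patients")
    first = exposures_by_patient[patients[0]]
    sig_ids = None
    for stratum in ("shared", "tumor_private", "met_private"):
        if stratum not in first:
            raise ValueError(f"patient {patients[0]} lacks stratum {stratum!r}")
        if sig_ids is None:
            sig_ids = first[stratum].signature_ids
    rows = []
    for a, b in STRATA_PAIRS:
        pvals = []
        for si, sig in enumerate(sig_ids):
            x = np.array([exposures_by_patient[p][a].normalized[si] for p in patients])
            y = np.array([exposures_by_patient[p][b].normalized[si] for p in patients])
            pvals.append(_paired_wilcoxon(x, y))
            rows.append(
                {
                    "signature": sig,
                    "pair": f"{a}_vs_{b}",
                    "median_diff": float(np.median(x - y)),
                    "p": pvals[-1],
                }
            )
        qvals = bh_adjust(pvals)
        for j, q in enumerate(qvals):
            rows[len(rows) - len(sig_ids) + j]["q"] = float(q)
    return pd.DataFrame(rows)


def cluster_exposures(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering of exposure rows (complete linkage, Euclidean).

    Returns the deterministic leaf order (row labels) and the scipy
    linkage matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    X = matrix.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return [str(matrix.index[i]) for i in order], Z


def associate_exposure_with_group(
    exposures: pd.DataFrame, in_group: Sequence[bool]
) -> pd.DataFrame:
    """Per-signature two-sided Mann-Whitney U between two sample groups.

    ``exposures`` is samples x signatures; ``in_group`` marks group
    membership (e.g. aneuploid vs diploid). BH correction across
    signatures.
    """
    mask = np.asarray(in_group, dtype=bool)
    if len(mask) != exposures.shape[0]:
        raise ValueError("group vector length mismatch")
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    pvals = []
    for sig in exposures.columns:
        x = exposures.loc[mask, sig].to_numpy(dtype=float)
        y = exposures.loc[~mask, sig].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == x[0]):
            p = 1.0
        else:
            combined = np.concatenate([x, y])
            has_ties = len(np.unique(combined)) < len(combined)
            method = "exact" if not has_ties and len(combined) <= 25 else "auto"
            p = float(
                stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
            )
        pvals.append(p)
        rows.append({"signature": sig, "p": p})
    for row, q in zip(rows, bh_adjust(pvals)):
        row["q"] = float(q)
    return pd.DataFrame(rows)
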