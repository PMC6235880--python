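"""Tumor-in-normal rescue (TiNDA-style) for miscalled somatic variants.

Tumor DNA contaminating the matched normal sample lifts the control's
B-allele frequency (BAF) at true somatic sites, so the upstream caller
labels them germline. Plotting each mutated position of a tumor/metastasis
pair in (control BAF, sample BAF) space separates contaminated somatic
sites — low control BAF but clearly above the identity line — from true
germline heterozygous sites near (0.5, 0.5). Points are clustered (single
pass, 9 clusters by default); a cluster is called tumor-in-normal when at
least 75% of its points lie strictly above the identity line, its centroid
sample MAF exceeds 1% and its centroid control MAF is below 45%.
Germline-labelled members of such clusters are promoted to somatic;
somatic calls are never demoted.

The clustering here is a Bayesian Gaussian mixture capped at 9 components
(full covariances, fixed seed, 100 EM iterations, single pass — no
model-selection loop), a deterministic stand-in for the tree-model
clusterer this procedure was originally built on. A mixture model is used
rather than k-means because the germline-heterozygous mode near (0.5, 0.5)
must stay one component: inertia-based partitioning tends to split it down
the identity line, and the upper half-cluster then sneaks past the
cluster-level bounds. As a second guard the same three bounds are also
applied to each rescued point individually.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import BayesianGaussianMixture

from .io_formats import VariantRecord
from .stratify import Key, TrioDataset

logger = logging.getLogger(__name__)

DEFAULT_K = 9
DEFAULT_ABOVE_IDENTITY = 0.75
DEFAULT_MIN_SAMPLE_MAF = 0.01
DEFAULT_MAX_CONTROL_MAF = 0.45


@dataclass(slots=True)
class BafPoint:
    key: Key
    control_baf: float
    sample_baf: float
    original_label: str  # somatic | germline
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.control_baf <= 1.0 and 0.0 <= self.sample_baf <= 1.0):
            raise ValueError(f"BAF out of [0,1] at {self.key}")
        if self.original_label not in ("somatic", "germline"):
            raise ValueError(f"bad label {self.original_label!r}")


@dataclass(slots=True)
class TindaResult:
    """Cluster audit and the set of rescued (promoted) variant keys."""

    assignments: dict[Key, int]
    cluster_stats: list[dict]
    rescued: frozenset[Key]

    @property
    def n_rescued(self) -> int:
        return len(self.rescued)


def build_baf_points(
    sample_calls: Mapping[Key, VariantRecord],
    control_calls: Mapping[Key, VariantRecord],
    common_variant_positions: Iterable[tuple[str, int]],
) -> list[BafPoint]:
    """One BAF point per retained mutated position of one tumor/metastasis sample.

    Positions in the common-variant set are removed; positions without
    control read counts are dropped (count logged).
    """
    common = set(common_variant_positions)
    points: list[BafPoint] = []
    dropped = 0
    for key in sorted(sample_calls):
        rec = sample_calls[key]
        if (key[0], key[1]) in common:
            continue
        control = control_calls.get(key)
        if control is None or control.depth == 0:
            dropped += 1
            continue
        if rec.depth == 0:
            dropped += 1
            continue
        points.append(
            BafPoint(
                key=key,
                control_baf=control.maf,
                sample_baf=rec.maf,
                original_label="somatic" if rec.caller_somatic else "germline",
            )
        )
    if dropped:
        logger.info("build_baf_points: dropped %d positions without usable counts", dropped)
    return points


def cluster_baf_pairs(
    points: Sequence[BafPoint], k: int = DEFAULT_K, seed: int = 0
) -> list[BafPoint]:
    """Assign every point to one of k clusters (deterministic given seed).

    Points are sorted by variant key before clustering so the result does
    not depend on input order. With fewer points than k, k is reduced to
    the point count with a warning.
    """
    points = sorted(points, key=lambda p: p.key)
    if not points:
        return []
    if len(points) < k:
        warnings.warn(f"only {len(points)} points; reducing k from {k}")
        k = len(points)
    X = np.array([[p.control_baf, p.sample_baf] for p in points])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = BayesianGaussianMixture(
            n_components=k, covariance_type="full", max_iter=100,
            random_state=seed % (2**31),
        )
        labels = model.fit_predict(X)
    for p, lab in zip(points, labels):
        p.cluster_id = int(lab)
    return list(points)


def classify_clusters(
    points: Sequence[BafPoint],
    above_identity: float = DEFAULT_ABOVE_IDENTITY,
    min_sample_maf: float = DEFAULT_MIN_SAMPLE_MAF,
    max_control_maf: float = DEFAULT_MAX_CONTROL_MAF,
) -> TindaResult:
    """Call tumor-in-normal clusters and collect their germline members.

    A cluster qualifies iff the fraction of member points strictly above
    the identity line is >= ``above_identity``, its centroid sample MAF is
    > ``min_sample_maf`` and its centroid control MAF is < ``max_control_maf``.
    A germline member of a qualifying cluster is rescued only if it also
    satisfies the identity-line and MAF bounds itself (per-point guard
    against stray germline points inside a somatic-dominated cluster).
    """
    clusters: dict[int, list[BafPoint]] = {}
    for p in points:
        if p.cluster_id is None:
            raise ValueError("points must be clustered first")
        clusters.setdefault(p.cluster_id, []).append(p)
    stats: list[dict] = []
    rescued: set[Key] = set()
    for cid in sorted(clusters):
        members = clusters[cid]
        frac_above = sum(p.sample_baf > p.control_baf for p in members) / len(members)
        centroid_sample = float(np.mean([p.sample_baf for p in members]))
        centroid_control = float(np.mean([p.control_baf for p in members]))
        qualifies = (
            frac_above >= above_identity
            and centroid_sample > min_sample_maf
            and centroid_control < max_control_maf
        )
        if qualifies:
            rescued.update(
                p.key
                for p in members
                if p.original_label == "germline"
                and p.sample_baf > p.control_baf
                and p.sample_baf > min_sample_maf
                and p.control_baf < max_control_maf
            )
        stats.append(
            {
                "cluster_id": cid,
                "size": len(members),
                "frac_above_identity": frac_above,
                "centroid_sample_maf": centroid_sample,
                "centroid_control_maf": centroid_control,
                "tumor_in_normal": qualifies,
            }
        )
    assignments = {p.key: p.cluster_id for p in points}
    return TindaResult(assignments, stats, frozenset(rescued))


def apply_tinda(
    trio: TrioDataset,
    common_variant_positions: Iterable[tuple[str, int]],
    k: int = DEFAULT_K,
    seed: int = 0,
    above_identity: float = DEFAULT_ABOVE_IDENTITY,
    min_sample_maf: float = DEFAULT_MIN_SAMPLE_MAF,
    max_control_maf: float = DEFAULT_MAX_CONTROL_MAF,
) -> tuple[TrioDataset, dict[str, TindaResult]]:
    """Run the rescue on both samples of a trio and promote rescued calls.

    A variant key rescued in either sample is promoted (caller_somatic set
    True) on its germline-labelled records in both tumor and metastasis —
    the mutation is one event. Every reclassification is logged; somatic
    labels are never demoted.
    """
    common = set(common_variant_positions)
    results: dict[str, TindaResult] = {}
    rescued_union: set[Key] = set()
    for role, calls in (("tumor", trio.tumor), ("metastasis", trio.metastasis)):
        points = build_baf_points(calls, trio.normal, common)
        if not points:
            results[role] = TindaResult({}, [], frozenset())
            continue
        points = cluster_baf_pairs(points, k=k, seed=seed)
        result = classify_clusters(
            points, above_identity, min_sample_maf, max_control_maf
        )
        results[role] = result
        rescued_union |= result.rescued
    n_promoted = 0
    for key in sorted(rescued_union):
        for calls in (trio.tumor, trio.metastasis):
            rec = calls.get(key)
            if rec is not None and not rec.caller_somatic:
                rec.caller_somatic = True
                n_promoted += 1
                logger.info(
                    "TiNDA rescue: %s:%d %s>%s (%s) reclassified somatic",
                    key[0], key[1], key[2], key[3], rec.sample_id,
                )
    logger.info("TiNDA: %d records promoted across %d variant keys",
                n_promoted, len(rescued_union))
    return trio, results
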