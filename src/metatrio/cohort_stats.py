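"""Cohort-level recurrence, mutual exclusivity and enrichment statistics.

The oncoprint-style mutation matrix is a genes x samples binary matrix per
analysis channel (coding non-silent, non-coding exonic, 3'-UTR). Two genes
are mutually exclusive when at most one sample carries mutations in both;
significance comes from a two-sided Fisher exact test on the 2x2
presence/absence table. Enrichment of a hit list against user-supplied
gene sets uses the upper-tail hypergeometric test; all families of tests
are Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotatedVariant

CHANNELS = ("coding_nonsilent", "ncRNA", "UTR3")


def _in_channel(av: AnnotatedVariant, channel: str) -> bool:
    if channel == "coding_nonsilent":
        return av.region_class in ("CDS", "splice_site") and av.non_silent
    if channel == "ncRNA":
        return av.region_class == "ncRNA_exon"
    if channel == "UTR3":
        return av.region_class == "UTR3"
    raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


def build_mutation_matrix(
    annotated_by_sample: Mapping[str, Iterable[AnnotatedVariant]],
    channel: str = "coding_nonsilent",
) -> pd.DataFrame:
    """Binary genes x samples matrix for one analysis channel.

    Multiple mutations of a gene in one sample collapse to a single 1; a
    variant on overlapping genes counts once for each gene.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    samples = sorted(annotated_by_sample)
    hits: dict[str, set[str]] = {}
    for sample in samples:
        for av in annotated_by_sample[sample]:
            if not _in_channel(av, channel):
                continue
            for gene in av.gene_ids:
                hits.setdefault(gene, set()).add(sample)
    genes = sorted(hits)
    matrix = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for gene, hit_samples in hits.items():
        matrix.loc[gene, sorted(hit_samples)] = 1
    matrix.attrs["channel"] = channel
    return matrix


def recurrent_genes(matrix: pd.DataFrame, min_samples: int = 4) -> pd.DataFrame:
    """Genes mutated in >= min_samples samples, by count desc then name."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts = matrix.sum(axis=1)
    keep = counts[counts >= min_samples]
    out = keep.rename("n_samples").rename_axis("gene").reset_index()
    return (
        out.sort_values(["n_samples", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's. Any
    zero margin gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi2_test_2x2(table: Sequence[Sequence[int]]) -> float:
    """Pearson chi-square p (df=1, no continuity correction) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    total = t.sum()
    if total == 0:
        raise ValueError("empty table; use fisher_exact_2x2")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("expected count of 0; use fisher_exact_2x2 instead")
    _, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p)


def mutual_exclusivity(
    matrix: pd.DataFrame, gene_a: str, gene_b: str, max_overlap: int = 1
) -> dict:
    """Mutual-exclusivity call plus Fisher test for a gene pair.

    ``exclusive`` means no more than ``max_overlap`` samples carry
    mutations in both genes. Symmetric in the two genes.
    """
    for gene in (gene_a, gene_b):
        if gene not in matrix.index:
            raise ValueError(f"gene {gene!r} not in mutation matrix")
    a = matrix.loc[gene_a].to_numpy(dtype=bool)
    b = matrix.loc[gene_b].to_numpy(dtype=bool)
    both = int(np.sum(a & b))
    only_a = int(np.sum(a & ~b))
    only_b = int(np.sum(~a & b))
    neither = int(np.sum(~a & ~b))
    table = [[both, only_a], [only_b, neither]]
    # odds ratio < 1 on this layout means the genes avoid each other
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (both * neither) / (only_a * only_b) if only_a * only_b else np.inf
    direction = "exclusive" if odds < 1 else ("co-occurring" if odds > 1 else "none")
    return {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "overlap": both,
        "exclusive": both <= max_overlap,
        "fisher_p": fisher_exact_2x2(table),
        "odds_direction": direction,
    }


def mutual_exclusivity_table(
    matrix: pd.DataFrame, genes: Sequence[str] | None = None, max_overlap: int = 1
) -> pd.DataFrame:
    """All-pairs mutual-exclusivity summary with BH-adjusted Fisher p-values."""
    genes = list(genes) if genes is not None else list(matrix.index)
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            rows.append(mutual_exclusivity(matrix, ga, gb, max_overlap))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fisher_q"] = bh_adjust(df["fisher_p"].to_numpy())
    return df


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    hit_set: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for overlap of a hit list with a gene set."""
    universe = set(universe)
    hits = set(hit_set)
    genes = set(gene_set)
    if not hits <= universe or not genes <= universe:
        raise ValueError("hit_set and gene_set must be subsets of the universe")
    k = len(hits & genes)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(genes), len(hits)))
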