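# metatrio

Comparative whole-genome analysis of matched **normal / primary-tumor /
metastasis trios** in colorectal cancer. Given per-sample somatic and
germline variant calls with read counts, copy-number segments and gene
models, the package:

- rescues somatic variants miscalled as germline due to **tumor-in-normal
  contamination** (TiNDA-style clustering of control vs tumor B-allele
  frequencies);
- stratifies somatic SNVs into **shared (truncal)**, **tumor-private** and
  **metastasis-private** sets using MAF cross-rescue between the tumor and
  metastasis of each patient;
- decomposes per-stratum 96-context mutational catalogs against a signature
  matrix by **non-negative least squares (NNLS)** with signature-specific
  cutoffs and cohort-level signature detection, and compares normalized
  exposures across strata (paired Wilcoxon, Benjamini–Hochberg corrected);
- detects **kataegis** loci (≥ 5 mutations within 10 kb) and annotates
  nearby genes;
- calls **gain / loss / LOH** states on copy-number segments relative to
  sample base ploidy and summarizes arm-level recurrence;
- computes cohort-level recurrence, **mutual exclusivity** (Fisher exact),
  χ² association and hypergeometric enrichment statistics.

A first-class synthetic-data module generates trio cohorts with known truth
labels (stratum, generating signature, contamination, kataegis loci), so
every stage is verifiable at desk scale without access to controlled data.

## The core quantities

For a variant with `a` alt reads out of depth `d`, the mutant allele
fraction is MAF = a/d. A variant called somatic in only one sample of a
tumor/metastasis pair is considered **present in the other sample** when

    MAF > 0.05,  alt reads ≥ 2,  MAF ≥ 2 × control MAF.

The 2-read floor reflects the expected read support of a single-copy
variant, `purity × coverage / ploidy` (5.7 reads at the cohort medians
0.475 × 36 / 3), under a Poisson read-support model. Presence flags map to
strata: both → shared, tumor only → tumor-private, metastasis only →
metastasis-private.

Signature exposures solve `e = argmin_{e ≥ 0} ‖C − W e‖₂`, where `C` is the
96-bin catalog and `W` the 96 × S signature matrix; exposures are reported
absolute (mutation counts) and normalized (`e / Σe`).

## Worked example

```python
import metatrio as mt

W = mt.synthetic_signature_matrix()                      # synthetic 96x30 matrix
cfg = mt.paper_cohort_configs(n_patients=1, seed=1, n_snvs=10_000)[0]
trio, truth = mt.generate_trio(cfg, W)
trio, tinda = mt.apply_tinda(trio, truth.common_variant_positions, seed=1)
catalog = mt.stratify_trio(trio)
shared = mt.build_catalog([trio.tumor[k] for k in catalog.keys_in("shared")])
exposures = mt.nnls_decompose(shared, W)
```

prints (via the repository's example driver):

```
patient P01: purity T/M = 0.61/0.83, ploidy T/M = 2/2
TiNDA rescued 325 germline-labelled variants
strata: shared 64.6%, tumor-private 15.0%, metastasis-private 20.4% of 9995 SNVs
top shared-stratum signature exposures:
  AC1: 0.446
  AC5: 0.239
  AC6: 0.199
  AC15: 0.100
```

The trio was generated with 65/15/20% strata, 5% tumor-in-normal
contamination and shared-stratum exposures (0.45, 0.25, 0.20, 0.10) over
AC1/AC5/AC6/AC15 — the pipeline recovers the strata (the contaminated
truncal variants only enter the shared set because TiNDA promoted them)
and the generating exposures.

## Command line

```sh
metatrio simulate --config cfg.txt    # write a synthetic cohort with truth
metatrio run --config cfg.txt         # TiNDA -> stratification -> signatures
                                      # -> kataegis -> CNA -> cohort stats
metatrio validate path/to/file        # check any input file's invariants
```

Configs are flat `key = value` files; `metatrio run` writes a versioned
`report.json` plus TSV tables, and reruns with the same seed are
byte-identical.

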