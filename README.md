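# cfmarrow

Reading bone-marrow activity out of cell-free mRNA.

Circulating cell-free messenger RNA (cf-mRNA) in plasma or serum is a mixture
of transcripts shed by solid tissues, circulating blood cells, and — crucially
— bone-marrow-resident progenitors that are otherwise reachable only by
biopsy. `cfmarrow` implements the computational stages needed to exploit
that mixture for non-invasive marrow monitoring:

- **Signature construction** (`cfmarrow.signatures`): cell-type-specific
  marker genes mined from reference atlases (GTEx-style tissue panels,
  Blueprint-style hematopoietic panels) with the strict 20-fold specificity
  rule, and pairwise-enriched gene sets (e.g. bone marrow vs whole blood,
  fold change > 5).
- **Deconvolution** (`cfmarrow.deconvolution`): per-sample tissue/cell-type
  proportions by (a) unsupervised non-negative matrix factorization of
  max-normalized TPM with reference-guided component annotation, and
  (b) signature-based quadratic programming
  — min ‖x − Sᵀp‖² s.t. p ≥ 0, Σpᵢ = 1.
- **Lineage trajectories** (`cfmarrow.timecourse`): time-varying gene
  selection (max > 50 TPM, max/min > 5), max-normalization, k-means or
  hierarchical clustering of temporal shapes, and average fold-change /
  percent-change trajectories of lineage gene sets across marrow ablation
  and reconstitution.
- **Ig clonotype tracking** (`cfmarrow.repertoire`): immunoglobulin
  segment relative abundances, dominant (clonal) segment detection, and
  loss-of-dominance dating through myeloma therapy.
- **Chimerism monitoring** (`cfmarrow.chimerism`): allograft engraftment
  from expressed SNP reference-allele frequencies
  f = (1−m)·f_host + m·f_donor — genotype classification, host→donor
  transition detection (e.g. hom-ref → het), and averaged trajectories.
- **Compartment comparison** (`cfmarrow.compare`): paired cf-mRNA vs
  cellular-compartment fold changes and the two-sided Wilcoxon/Mann-Whitney
  rank-sum test (exact enumeration for small groups, tie-corrected normal
  approximation otherwise).
- **Synthetic data** (`cfmarrow.synthetic`): generators for every input
  above with known ground truth — marker-planted references, TPM mixtures,
  ablation/reconstitution time courses, clonal Ig repertoires, and
  host/donor SNP allele-count series — so every stage is testable without
  any download.

## Worked example

Estimate cell-type fractions from a simulated cf-mRNA sample whose true
composition is known (1000 genes, 6 cell types, multinomial read noise at
one million reads):

```python
from cfmarrow import synthetic as syn, deconvolution as dec

cfg = syn.SimulationConfig(noise_model="multinomial", read_depth=1_000_000, seed=7)
reference, truth = syn.generate_reference(cfg)
mix, mix_truth = syn.generate_mixture(
    reference, [0.29, 0.28, 0.13, 0.03, 0.11, 0.16], cfg)

markers = list(truth.marker_assignment)               # 180 planted marker genes
signature = (reference.div(reference.sum(axis=1), axis=0) * 1e6)[markers]
estimate = dec.estimate_fractions(mix["S001"][markers], signature)
print(estimate.fractions.round(4))
```

```
CT1    0.2903
CT2    0.2792
CT3    0.1292
CT4    0.0301
CT5    0.1099
CT6    0.1612
```

The estimated proportions match the planted composition
(0.29 / 0.28 / 0.13 / 0.03 / 0.11 / 0.16) to within a few parts in a
thousand; the residual is read-sampling noise. On noiseless input the
recovery is exact to machine precision.

The same pipeline is available from the shell:

```sh
cfmarrow simulate reference --seed 1 --out sim/
cfmarrow signatures --reference sim/reference.tsv --out sig/
cfmarrow deconvolve qp --matrix mixture.tsv --signature signature.tsv --out qp/
cfmarrow timecourse --matrix timecourse.tsv --cluster kmeans --k 8 --seed 1 --out tc/
cfmarrow repertoire --counts ig_counts.tsv --out rep/
cfmarrow chimerism --counts snp_counts.tsv --out chim/
```

Every command writes tab-separated result tables plus a YAML manifest
(configuration, seeds, input checksums) sufficient to reproduce the run.

## Documentation

`docs/methods.md` describes the generative models behind the synthetic
data, the estimators and their numerical details, default parameter
choices, and known limitations.
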