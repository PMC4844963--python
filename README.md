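# pirnadev

Analysis toolkit for characterizing PIWI-interacting RNAs (piRNAs) across
postnatal mouse-brain development from small-RNA sequencing and CAGE data.

piRNAs are 24–31 nt small non-coding RNAs that silence transposable
elements in complex with PIWI-family proteins (MILI binds ~26–27 nt
piRNAs, MIWI ~29–30 nt). Although long thought to be germline-restricted,
they also appear in somatic tissues, including adult brain. This package
implements the computational pipeline needed to make and defend that call
from sequencing data:

- **preprocess** — small-RNA tag cleaning (truncate at the first base with
  Phred ≤ 15, strip the 4-base 5′ barcode and ≥ 1 base of 3′ adapter, keep
  25–35 nt inserts) and CAGE forward-mate trimming (drop the 9-base
  barcode + GGG prefix, keep > 15 nt).
- **clusters** — piRNA-cluster expression calling. A cluster with
  contained-read count *c*, cluster length *L*, and library size *N* is
  expressed iff

  *c* ≥ 100, RPKM = *c* / ((*L*/1000)(*N*/10⁶)) ≥ 10, and
  max-depth/*c* < 0.9,

  the last criterion suppressing PCR-duplicate stacks. Includes the
  one-tailed Fisher (hypergeometric) test for intergenic enrichment and
  the mapping-summary percentage formatter.
- **character** — piRNA hallmarks: positional base composition and
  information content, the exact one-sided binomial 1U-bias test against a
  0.25 background, length histograms with mode detection, exact-sequence
  sharing between samples, and perfect-match ncRNA contamination.
- **coverage** — piRNA production profiles in 100-base windows along each
  cluster, compared across samples by Pearson correlation with a p ≤ 0.001
  retention filter and median summary.
- **cage** — CTSS aggregation, power-law normalization (map each library
  onto a reference law R(x) = c·x^(−α) by matching reverse cumulatives,
  giving tpm), promoter-window gene expression (Σ tpm over unique CTSSs in
  [TSS − 1 kb, TSS + 0.5 kb], expressed at ≥ 0.5), and the
  activator/repressor TF scenario filter.
- **targets** — piRNA target prediction: top-scoring hit selection
  (score ≥ 160) with the non-zero fold-change Mann-Whitney deadenylation
  test, and the guide/sense partial-complementarity signature scan
  (zero-mismatch 10-nt 5′ seed, Phred-sum mismatch budget ≤ 160, opposite-
  strand overlap with an exact sense read), with 75 %-of-consensus repeat
  filtering and mRNA/repeat target annotation.
- **simulate** — a ground-truthed miniature study (genome, clusters,
  genes, repeats, ncRNAs, raw FASTQ reads, truth alignments, CTSS tables,
  planted target sites) reproducing the stage/tissue signal structure, so
  every stage is testable without external data.

## Worked example

Simulate an adult-brain-like sample (50 000 reads, 7 % of mapped reads in
clusters, strong 1U bias, 26–27 nt peak), clean it, and call cluster
expression:

```python
from pirnadev.simulate import SimulationConfig, StageProfile, generate_reference
from pirnadev.pipeline import run_small_rna_sample, recovery_rates

config = SimulationConfig(rng_seed=1)          # 400 kb genome, 40 clusters
reference = generate_reference(config)

adult = StageProfile("brain_adult", n_reads=50_000, cluster_read_fraction=0.07,
                     u1_fraction=0.8, length_mixture=[(26, 1.0)],
                     shared_pool_id="BT")
result = run_small_rna_sample(reference, adult, seed=42)

recall, false_rate = recovery_rates(result)
print(f"expressed-cluster recall: {recall:.2f}, false-call rate: {false_rate:.2f}")
print(f"1U fraction (all mapped reads): {result.u1.u1_fraction:.3f} "
      f"(p = {result.u1.p_value:.2e}, significant: {result.u1.significant})")
print(f"length mode(s): {result.length_modes}")
print(result.expression[result.expression.expressed].head(3).to_string(index=False))
```

prints

```
expressed-cluster recall: 1.00, false-call rate: 0.00
1U fraction (all mapped reads): 0.289 (p = 3.95e-88, significant: True)
length mode(s): [26]
  cluster_id      klass  read_count        rpkm  max_depth  depth_ratio  expressed
cluster_0000 intergenic         350 2646.295694         51     0.145714       True
cluster_0010 intergenic         267 3288.720060         38     0.142322       True
cluster_0014 intergenic         198 1816.732769         23     0.116162       True
```

Every truth-expressed cluster is recovered and none of the silent ones is
called; the sample-wide first-base T fraction (0.289 against the 0.25
background, at n ≈ 49 000 mapped reads) is overwhelmingly significant, and
the read-length mode sits at 26 nt — the three hallmarks that identify a
piRNA population. A `pirnadev` command-line interface wraps the same steps
(`pirnadev simulate | preprocess | clusters | character | cage`).

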