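# posclip

Positional analysis of protein–RNA cross-linking data, built for
studies that ask not just *which* mRNAs an RNA-binding protein (RBP)
occupies but *where* on each transcript it sits — and what that
position implies for the transcript's fate. The motivating biology is
an RBP that binds some mRNAs in the 5'UTR (consistent with a role in
translation initiation), others around the stop codon — including
replication-dependent histone mRNAs, immediately upstream of their
3' stem-loop — and whose loss changes histone mRNA half-life and
S-phase progression.

`posclip` turns that analysis into a tested, reusable pipeline:

* **Cross-link sites** from read alignments (the iCLIP truncation
  convention: the contact is the base immediately 5' of each read's
  5' end).
* **Peak calling** per gene by a sliding-window score against a
  uniform-redistribution permutation null with local FDR control;
  adjacent peaks merge into binding regions kept above 20 reads.
* **Enrichment testing** of per-gene iCLIP reads-in-peaks against total
  RNA with a negative-binomial Wald test (median-of-ratios size
  factors, robust trended method-of-moments dispersion): *enriched* =
  fold > 2 and BH-adjusted p < 0.05; *non-binder* = |log2FC| < 0.2 and
  p > 0.1.
* **Five-region occupancy** per transcript — 5'UTR, ±50 nt around the
  start codon, CDS, ±50 nt around the stop codon, 3'UTR — as RPKM, and
  **perturbation-consensus k-means** (k = 5, 200 rounds, 70% occurrence,
  1 − Pearson distance, median centres) that assigns each gene a
  positional archetype or leaves it unassigned.
* **Profiles**: metagene densities anchored at start/stop codons and
  stem-loop-anchored profiles for histone-like mRNAs.
* **Motif region export** (best region per enriched gene, ±20 nt of the
  centre) with a k-mer enrichment scorer (sizes 4/6/8/10, one-sided
  hypergeometric), and a **segment-preserving overlap randomization
  test** against a second RBP's binding regions.
* **Assay fits**: one-site binding K_D from fluorescence polarization,
  one-phase decay half-life (t½ = ln2/k), unwinding velocity from the
  linear part of a progress curve, comparative-Ct qPCR and RIP
  enrichment, and Watson pragmatic cell-cycle deconvolution of
  DNA-content histograms.
* A **synthetic-data module** that generates every input with planted
  ground truth — positional archetypes, planted enrichment, histone-like
  stem-loop genes, assay curves — so the entire pipeline is exercised
  and scored end-to-end without any external download.

## Worked example

Generate a synthetic cohort and fit the bundled assay tables:

```bash
posclip simulate --seed 3 --outdir demo/sim
posclip fit-decay --series demo/sim/decay.csv
posclip cellcycle --histogram demo/sim/dna_histogram.csv
```

prints (abridged):

```
{ "k": 0.3225, "plateau": 0.0, "t_half": 2.149, "se_t_half": 0.163, "converged": true }
{ "g1": 0.600, "s": 0.302, "g2m": 0.098, "g1_mean": 99.89, "g2_mean": 200.26 }
```

The decay series was generated at t½ = 2 h with noise — the pooled
one-phase fit recovers 2.15 ± 0.16 h. The DNA histogram was generated
at G1/S/G2-M = 0.60/0.30/0.10 — the Watson fit returns 0.600/0.302/0.098
with the G2 mean at twice the G1 mean, as diploid DNA content requires.

The full pipeline runs from a YAML config naming the annotation,
cross-link sites (or alignments), RNA counts and optional stem-loop /
sequence / reference-region inputs:

```bash
posclip run --config run.yaml --outdir demo/run
```

and writes sites, peaks, regions, the enrichment table, five-region
occupancy, consensus cluster assignments, metagene and stem-loop
profiles, motif FASTA exports with k-mer scores, and a reproducibility
manifest (config and input hashes, per-stage record counts). Re-running
with the same seed reproduces every output byte for byte.

In library code the same stages are plain functions
(`posclip.clip.call_peaks`, `posclip.positional.consensus_cluster`,
`posclip.assays.fit_one_site`, ...) operating on pandas frames and
small dataclasses.

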