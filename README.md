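# cnvmod

Genome-wide analysis of copy-number-variant (CNV) modifiers of breast and
ovarian cancer risk in *BRCA1* pathogenic-variant carriers: consensus
deletion calling from SNP-array intensity signals, transcript-union gene
overlap, and an ascertainment-corrected retrospective-likelihood score test
of risk association, exercised end to end on synthetic cohorts with known
truth.

## Who this is for

Statistical geneticists and bioinformaticians studying risk modifiers in
mutation-carrier cohorts. Such cohorts are sampled conditional on disease
status (e.g. early-onset breast cancer cases heavily over-represented), so
ordinary prospective survival models are biased; and CNV genotypes are not
observed directly but called from noisy array intensities (log R ratio, LRR;
B-allele frequency, BAF), so the genotype itself carries caller-dependent
error. This package implements both halves — the calling pipeline and the
ascertainment-corrected test — together with a synthetic-data generator so
every stage is testable without access to the original genotype data.

## The model at the core

For carrier status z ∈ {0, 1} of a deletion over a gene locus, age at onset
follows a proportional-hazards model with known piecewise-constant baseline
hazard:

    λ(t | z) = λ₀(t) · exp(β z)

Because samples are ascertained on phenotype, each subject contributes the
*retrospective* likelihood P(z | δ, t) of the genotype given the observed
outcome (δ = affected indicator, t = analysis age). The 1-d.f. score test of
H₀: β = 0 with plug-in carrier frequency p̂ = mean(z) has

    U = Σᵢ (zᵢ − p̂)(δᵢ − Λ₀(tᵢ)),     V = p̂(1 − p̂) Σᵢ (δᵢ − Λ₀(tᵢ))²

with U²/V ~ χ²₁, where Λ₀ is the cumulative baseline hazard. The one-step
estimate β̂ = U/V with s.e. 1/√V gives the approximate relative risk
RR = exp(β̂) and its 95% CI. Per-gene P-values are corrected by a
discrete-statistic FDR: genes with fewer than four deletions are filtered
out, then Benjamini–Hochberg q-values are computed on the retained set.

Upstream, deletions are called per sample by two independent algorithms — a
five-state copy-number HMM over ordered probes (distance-dependent
transitions, joint LRR/BAF emissions, Viterbi decoding) and a circular-style
binary segmentation of LRR — then merged by ≥1 bp overlap into consensus
calls. Consensus calls ≥1000 kb, calls supported by a single algorithm, and
conflicting deletion+duplication pairs in the MHC region are excluded.

## Worked example

```python
import cnvmod as cm

# synthetic cohort: 2 chromosomes x 2000 probes, 200 ascertained carriers,
# 5 deletion loci; GENE1 is causal with log-RR = log 2 on breast cancer
truth = cm.make_truth_set(seed=7)
result = cm.run_pipeline(truth.report, truth.transcripts, truth.phenotypes)

gene1 = [r for r in result.genomewide.results if r.gene == "GENE1"][0]
print(gene1.summary())
```

prints

```
Retrospective-likelihood score test (1 d.f.)
  gene:            GENE1
  samples:         200  (carriers: 22, freq 11.00%)
  score U:         5.513
  variance V:      11.27
  chi-square:      2.698
  P-value:         0.1005
  approx. RR:      1.63 (95% CI 0.91–2.92)
```

The carrier frequency among the 200 ascertained samples (11%) exceeds the
10% population frequency because carriers are enriched in the early-onset
stratum; the score U > 0 and RR > 1 recover the direction of the simulated
effect, and the causal locus ranks first by P-value among the loci with
called carriers in this replicate.
`result.association_table` holds the full per-gene table (carrier
frequencies, U, V, χ², P, RR with CI, q-values) and
`cm.io.write_association_table` writes it as TSV.

The same stages are exposed as a CLI for file-based workflows:

```bash
cnvmod simulate --seed 7 --out cohort/
cnvmod qc       --intensities cohort/intensities.tsv --out qc/
cnvmod call     --intensities cohort/intensities.tsv --samples qc/kept_samples.txt --out calls.tsv
cnvmod merge    --calls calls.tsv --out consensus.bed
cnvmod overlap  --calls-bed consensus.bed --annotation cohort/transcripts.tsv \
                --samples qc/kept_samples.txt --out overlap/
cnvmod associate --carrier-matrix overlap/carrier_matrix.tsv \
                 --phenotypes cohort/phenotypes.tsv --out association.tsv
cnvmod validate --calls-bed consensus.bed --truth cohort/truth_segments.tsv \
                --annotation cohort/transcripts.tsv --out validation.tsv
```

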