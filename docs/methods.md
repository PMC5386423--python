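# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `cnvmod`, in the order the pipeline runs them.

## Problem setting

Cohorts of *BRCA1* pathogenic-variant carriers used for modifier discovery
are not random samples: recruitment deliberately over-represents early-onset
breast cancer cases (one stratum diagnosed before age 40) against a second
stratum of unaffected carriers or carriers with a first ovarian cancer at 35
or later. Association tests of a genotype against age at onset must correct
for this outcome-dependent sampling. At the same time the genotype of
interest — carrying a germline deletion over a gene — is not observed but
inferred from SNP-array intensity signals, with appreciable caller error.
`cnvmod` implements the full chain: signal simulation, array QC, dual-caller
deletion calling with consensus filtering, gene-interval overlap, the
retrospective-likelihood score test, and discrete-statistic FDR.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with known truth.

**Probe grid.** Chromosomes carry probes at strictly increasing positions
with i.i.d. exponential inter-probe gaps (default mean 5 kb, the density of
a ~610k genome-wide array). Default test scale: 2 chromosomes × 2000 probes.

**Intensity signal.** LRR = per-copy-number mean + sinusoidal waviness +
Gaussian noise. Copy-number LRR means default to (−3.5, −0.66, 0, 0.40,
0.68) for copies 0–4, the classic log₂-ratio expectations on this array
class; noise s.d. 0.15 (a typical passing sample is well below the 0.28 QC
threshold); waviness amplitude 0.01 with 4 Mb wavelength, a deliberately
simple surrogate for GC-wave artifacts that exists only to exercise the
waviness QC metric. BAF is drawn from the genotype clusters implied by the
copy number at a per-probe population B-allele frequency (uniform on [0,1]),
with cluster s.d. 0.03, clipped to [0,1]; hemizygous probes have no
heterozygous cluster; copy-0 probes emit uniform noise. An optional BAF
drift parameter pulls homozygote clusters inward to trigger the drift
metric. The `SignalModel` invariants allow zero s.d. so noiseless fixtures
can assert exact recovery.

**Deletion loci.** Non-overlapping probe windows of 12–25 probes. Carriers
are heterozygous (copy 1) by default, matching dominant carrier coding;
homozygous deletions are available per locus via `copy_number=0`. Carrier
frequencies default to a geometric spread over 0.5–5% for null loci — inside
the observed 0.2–8.2% deletion spectrum — and 10% for the causal locus.
The causal frequency sits at the top of the plausible range (validated
common deletions reach 12.9%) because a 200-sample cohort is ~12× smaller
than the real one; an a-priori power calculation showed that at 3–5%
frequency the scaled-down design has essentially no power, while at 10% the
score test detects β = log 2 reliably. This is a property of the scaled
design, not of the test.

**Phenotypes and ascertainment.** Ages at onset are drawn by inverting the
piecewise-exponential survival function under λ₀(t)·exp(βz) for the chosen
endpoint; the competing endpoint keeps its baseline hazard and acts only as
a censoring event, mirroring the separate breast/ovarian analyses. An
independent censoring age is uniform on [35, 75] years — a single
distribution that folds together end of follow-up and prophylactic surgery,
and is consistent with an adult cohort whose unaffected stratum requires
observation at 35+. Candidates are assigned to stratum A (breast cancer
before 40) or stratum B (no breast cancer; any ovarian cancer at ≥35) and
accepted in pool order until each stratum reaches its target (default 100);
the acceptance rate is recorded. An unfillable stratum (e.g. zero hazard)
raises an error.

**Baseline incidence defaults.** Decade-wise hazards give cumulative risk to
age 70 of ~63% for breast and ~41% for ovarian cancer, inside the published
ranges for BRCA1 carriers (44–75% and 43–76%). The generator and the test
suite share these tables, so all statistical checks are self-consistent and
no external rates are needed. Real per-cohort incidence tables can be
supplied through the YAML config.

**What the generator does not emulate.** No family structure or kinship, no
genotyping batch effects, no GC-content waves beyond the sinusoid, no
duplication phenotypes, no competing-risks dependence between endpoints.
Passing tests therefore demonstrate the correctness of the pipeline's
arithmetic and its behaviour under idealized signal assumptions — not
calling performance on real arrays, which is known to be far worse (the
package's own validation-metrics module exists to quantify exactly that).

## Quality control

Per-sample metrics, computed on autosomes only (chromosome names matching
X/Y are skipped): s.d. of LRR; BAF drift as the fraction of BAF values in
[0.20, 0.25) ∪ (0.75, 0.80] (the drifted-homozygote bands, chosen so a
constructed drift fixture must be flagged); a signed waviness factor — the
s.d. of per-1 Mb-window median LRR, signed by the lag-1 autocorrelation of
the window medians (positive autocorrelation = slowly varying waves);
robust outlier rates for LRR and for mid-band BAF (beyond ±3 × 1.4826·MAD of
the median); and the s.d. of BAF restricted to the heterozygous band
[0.25, 0.75]. The external tools these metrics imitate do not publish their
internal formulas; the definitions above are this package's own, fixed so
the documented thresholds are testable. Exclusion thresholds keep the quoted
inequality senses exactly: LRR s.d. > 0.28 (strict), BAF drift > 0.01,
|waviness| > 0.05, BAF outliers > 0.1, LRR outliers ≥ 0.1 (inclusive),
BAF s.d. ≥ 0.2, LRR s.d. ≥ 0.4. A sample failing any rule is excluded;
fewer than 100 usable probes is an error.

## CNV calling

**HMM caller.** Five states (copy 0–4) over ordered probes. Emissions are
the product of an LRR Gaussian (state means as above; s.d. 0.2 for copies
1–4, 1.0 for copy 0, whose intensity is essentially background) and a BAF
term: an equal-weight Gaussian mixture (s.d. 0.04) over the genotype
clusters implied by the state — {0,1} for copy 1, {0,½,1} for copy 2,
{0,⅓,⅔,1} for copy 3, {0,¼,½,¾,1} for copy 4 — and uniform for copy 0.
Equal weights avoid assuming the population allele frequency at each probe;
missing LRR or BAF contributes nothing, so masked probes are skipped without
disturbing probe order. Transitions are distance-dependent: stay probability
1 − p_event·(1 − exp(−d/D)) with gap d, scale D = 100 kb and p_event =
0.005, off-diagonal mass split evenly. Decoding is exact Viterbi (verified
against exhaustive path enumeration on small instances); maximal
constant-state non-diploid runs of ≥3 probes become calls, with confidence
the path log-likelihood minus the all-diploid path over the run.

**Segmentation caller.** Circular-style binary segmentation: each segment is
scanned for the interior window (width between 3 and 300 probes, windows
touching a segment end included — these are ordinary binary splits) that
maximizes the pooled two-sample t statistic of window vs. rest; if |t| > 5
the segment is cut at the window boundaries and the pieces are re-scanned.
The interior-window form is used instead of plain single-split binary
segmentation because a short deletion embedded in a 2000-probe chromosome
dilutes the best single-split t to ~2 and would never be found; the interior
t for the same event is >15. A zero-variance step with unequal means gives
t = ∞, so noiseless changepoints are always accepted at the exact boundary.
Final segments are classified by mean LRR: < −2.0 → copy 0, < −0.3 →
copy 1, > 0.25 → copy 3, else diploid (no call). The 300-probe cap bounds
the scan linearly in segment length; events near the 1000 kb consensus
length filter (~200 probes at 5 kb spacing) are still fully covered.

**Consensus.** Per sample and direction (deletion = copy < 2, duplication =
copy > 2), calls from all callers overlapping by ≥1 bp are grouped
transitively; each group becomes one consensus call with the union interval
and the set of distinct supporting callers. Union (not intersection) is used
because it preserves the downstream ≥1 bp gene-overlap test monotonically.
Filters, applied to merged calls: union length ≥ 1,000,000 bp removed;
support < 2 removed; within the MHC region (default chr6:29.6–33.1 Mb,
configurable since only the region name is standard), a sample carrying both
a supported deletion and a supported duplication has both removed as
irreconcilable. All boundaries are probe positions, 1-based inclusive.

## Gene overlap

Gene intervals are the transcript union per symbol ([min start, max end]); a
symbol annotated on two chromosomes is an error. A sample carries a gene
deletion if any kept consensus deletion overlaps the gene interval by ≥1 bp
(inclusive coordinates: max(starts) ≤ min(ends)); two deletions over one
gene still give z = 1 (dominant coding). Intersection uses an interval tree
per chromosome and is required by tests to equal the quadratic brute force.
The reported "carrier frequency" is the carrier proportion carriers/N — the
convention under which the reported cohort percentages reproduce from their
counts — with the allele-count convention carriers/2N emitted alongside for
reference. Duplications are excluded: their genomic location is not
interpretable from array data the way a deletion's is, and deletions are the
functionally disruptive, historically risk-associated class.

## Association

Outcome construction per endpoint follows the censoring rules exactly:
breast — analysis age is the first of breast diagnosis, ovarian diagnosis,
bilateral prophylactic mastectomy, or last observation, affected only if
that first event is the breast diagnosis; ovarian — first of ovarian
diagnosis, oophorectomy, or last observation, additionally bounded by the
breast diagnosis age (breast cases count as unaffected at their diagnosis
age). Diagnosis wins age ties. Events recorded after the last observation
age are errors.

The score test is as in the README: U = Σ(zᵢ − p̂)(δᵢ − Λ₀(tᵢ)),
V = p̂(1 − p̂)Σ(δᵢ − Λ₀(tᵢ))², U²/V ~ χ²₁. U is the analytic derivative of
the retrospective log-likelihood at β = 0 with the plug-in null MLE
p̂ = mean(z) (profiling p changes nothing at β = 0), and V is the expected
information there. β̂ = U/V is a one-step approximation, not the MLE; tests
cross-check U against a finite difference of the implemented log-likelihood
(relative error < 10⁻⁶) and χ² against the numerically maximized likelihood
ratio (within 15% on a 20-record fixture). Degenerate cases (constant z, or
V = 0) return U = 0, P = 1 and an undefined RR. Samples are treated as
independent — no kinship or family clustering — which is a documented
limitation for real carrier cohorts, where relatives are common.

Genome-wide, each gene with ≥1 carrier is tested in deterministic column
order; 0-carrier genes are skipped with a reason. The discrete FDR first
removes genes with fewer than 4 total deletions (such discrete statistics
cannot reach small P-values and only dilute the correction — a Tarone-style
filter), then computes Benjamini–Hochberg step-up q-values on the retained
set. Filtered genes carry no q-value and a `filtered` flag.

## Validation metrics

Detection sensitivity is detected truth segments over all truth segments;
"specificity" is implemented as positive predictive value — confirmed calls
over all calls — because true negatives are uncountable for rare structural
variants and the conventional "100% specificity" for a fully confirmed call
set is exactly that ratio. Percentages round to the nearest integer, half
away from zero; all reported count→percentage pairs (14/22 → 64, 8/29 → 28,
8/20 → 40, 7/352 → 2, 9/52 → 17, 13/72 → 18) reproduce exactly.

## Numerical choices and degenerate inputs

- Internal coordinates are 1-based inclusive; BED output converts as
  (start − 1, end). The conversion is a bijection, tested by round trip.
- Missing intensity values are retained as NaN and masked, never imputed;
  imputation would silently move call boundaries.
- Viterbi ties break toward the lower copy number; with continuous
  emissions ties have probability zero.
- The BAF mixture density adds 10⁻³⁰⁰ before the log to avoid −∞ from
  underflow at extreme observations; the retrospective likelihood uses a
  log-sum-exp normalizer.
- Λ₀(t) beyond the last age band extends the final hazard; inversion of a
  zero-hazard tail returns +∞ (never affected).
- Association tables are written with 4 significant figures; round trips
  are tested at that precision.

## Problem sizes used in the test suite

Unit tests run on fixtures of 20–5000 probes and 10–60 samples. The
end-to-end check uses 50 replicates of the default synthetic design
(2 chromosomes × 2000 probes × 200 samples, 5 loci, causal β = log 2) and
requires the causal locus in the top 2 by P-value in ≥45 of 50; type-I error
uses 2000 null cohorts of n = 500 at carrier frequency 5% and must lie in
[0.037, 0.063] at nominal 0.05. The full suite runs in a few minutes on one
CPU; `scripts/acceptance.py` in well under a minute.

## Known limitations

- Two bespoke callers stand in for the four external tools used on the real
  cohort; the consensus machinery is caller-count-agnostic, but concordance
  properties of the real tool ensemble are not reproduced.
- The segmentation caller ignores BAF entirely; it is a deliberately
  independent second opinion, not a best-possible caller.
- No LOH or mosaic states; no GC-wave correction; sex chromosomes excluded.
- The retrospective likelihood conditions on the phenotype but not on the
  sampling design itself; with the score evaluated at β = 0 this matches the
  standard carrier-cohort treatment, and the type-I calibration test
  confirms validity under the two-stratum design.
- Independence across samples is assumed throughout (no kinship).
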