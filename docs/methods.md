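# Methods

This note documents the models and procedural choices behind `k27tools`: what
each stage assumes, which knobs matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Broad-domain (island) calling

Diffuse marks like H3K27me3 are poorly served by point-source peak models; the
caller instead scores gap-tolerant runs of enriched windows.

**Model.** IP fragment midpoints are counted into fixed windows of width
`w = 200` bp. Under the background hypothesis a window count is
Poisson(λ_w), with λ_w the genome-wide IP rate per window (library size ×
w / effective genome length; the synthetic genome is fully mappable, so the
effective fraction defaults to 1). A window is *eligible* when its count `k`
satisfies `P(X ≥ k | λ_w) ≤ p₀` (`p₀ = 0.2`) and `k ≥ 1`. Runs of eligible
windows merge across at most `gap = 3` consecutive ineligible windows
(600 bp), and candidates are trimmed to end on eligible windows. Each
candidate is then tested against an input-derived expectation

    E = max( input_count × N_IP/N_input ,  c × L_island × λ_bp ),

with Poisson upper-tail `p = P(X ≥ IP_count | E)`, `fold = IP_count / E`, and
Benjamini–Hochberg `q` across all candidates. Islands with `q ≤ 0.05` and
`fold > 1` are retained — both filters are asserted on every run.

**The background floor `c`.** The floor exists because a candidate's local
input count is itself a small Poisson draw; scoring a *selected-high* IP run
against a *randomly-low* input count manufactures significance. At desk scale
(megabase genomes, 10⁵-fragment libraries) we measured the failure directly:
with `c = 0.25` every one of 12 null datasets (no planted enrichment)
retained 6–45 islands through a BH cascade over ~1,500 selected candidates.
`c = 1.25` — the expectation never falls below 1.25× the island's share of the
genome-wide IP rate, in the spirit of MACS's `max(λ_local, λ_BG)` — gave zero
retained islands in 18/18 null datasets at two genome scales while leaving
planted domains of fold ≥ 2 fully recovered. `c` remains a parameter; the
practical price of 1.25 is insensitivity to true enrichment below ~1.25-fold,
which the `fold > 1` retention rule largely forfeits anyway.

**Stage-level calls** pool the ChIP replicates before calling (one peak set
per stage); per-replicate calling remains available for QC.

## Promoter signal

The promoter is the ±5 kb window around the strand-resolved TSS (one TSS per
gene; on real GTFs with several transcripts the longest is canonical). Window
membership everywhere uses the fragment-midpoint rule: unambiguous, conserves
totals, and keeps the RPKM and gene-set modules provably consistent (a
cross-module test asserts they share the same windows and rule).

Promoter density is RPKM = n / (L/10³ × N/10⁶). The mark level of a gene at a
stage is the ratio-then-average estimator

    level = mean_r ( (IP_RPKM_r + ε) / (input_RPKM_r + ε) ),    ε = 0.1 RPKM,

with replicates paired by index. Average-then-ratio is implemented as an
alternative; the two differ only at second order for balanced replicates. The
pseudocount ε stabilises empty windows (0/0 → 1, i.e. "no evidence of
enrichment") and sets an effective detection floor: promoter input densities
in realistic designs sit around 1–10 RPKM, so ε = 0.1 perturbs real signal by
a few percent at most.

TSS profiles and TSS→TES meta-profiles use the same ε-stabilised, library-
normalised log2 IP/input ratio in 100-bp bins (gene bodies rescaled to a fixed
number of bins in the metagene), strand-oriented so upstream is always left.
Curves average the per-gene log-ratio within each expression class.

## Expression

TPM is the length-normalised rate rescaled to 10⁶ per sample. A gene is
*expressed* if TPM ≥ 0.5 in at least one sample of any stage — a global flag;
genes never reaching it are *silent* everywhere. Within each stage, quartiles
of the stage-mean TPM of expressed genes (linear-interpolation estimator,
configurable) split expressed genes into high (≥ Q3), low (≤ Q1) and medium.
The quartile population and estimator are deliberate choices, not facts about
nature; both are parameters.

**Differential expression.** Only globally expressed genes are tested,
between successive stages, with a compact NB Wald test:

* size factors by median-of-ratios over genes with no zero count;
* per-gene dispersion α by method of moments on the pooled within-group
  variance of normalised counts, then shrunk 50/50 toward a trend
  `α(μ) = a₀ + a₁/μ` fitted across genes by least squares;
* per-group NB mean MLEs by Newton iteration with the size factors as
  offsets; the Wald statistic is the log-ratio of MLEs over its Fisher
  standard error **inflated by √(ν/(ν−2))**, where ν = (residual df)/(shrink
  weight)² is the effective df of the moderated dispersion (ν = 16 at 3 vs 3).
  The inflation is the variance of a t with ν df: it widens the null spread
  exactly where dispersion-estimation noise does, without adopting the t's
  heavy far tail (which would destroy BH-adjusted power for strong effects).
  Calibration measured at 3 vs 3, dispersion 0.05: type-I error 0.044–0.052
  at p ≤ 0.05 across seeds and mean structures; power 0.96 for a 4-fold gene
  at μ = 500 after BH over 2,000 genes.
* reported log2FC is the ratio of size-factor-normalised group means with a
  0.5 pseudocount (later stage over earlier, so "up at a transition" is
  positive); BH over tested genes.

DEGs satisfy padj ≤ 0.05 and |log2FC| ≥ 1 (both inclusive) in ≥ 1 transition.
Each DEG is assigned to the stage of its maximal stage-mean TPM, ties to the
earliest stage; the assignment partitions the DEG set by construction.

## Integration

For transition *t* (stage i → i+1), a significant DEG joins cluster 2t+1 when
its log2FC > 0 and Δlevel < −δ, or cluster 2t+2 when log2FC < 0 and
Δlevel > +δ, with Δlevel the log2 ratio of ε-stabilised promoter levels and
δ = 0 by default (sign-only; a magnitude threshold is one flag away). The
negative-correlation set is the union over clusters; HDEGs are its
intersection with the across-stage union of promoter-modified genes. The
discordant class — modified DEGs outside the negative-correlation set — is
reported alongside. Invariants asserted on every run:
HDEG ⊆ negcorr ⊆ DEG and HDEG ⊆ modified.

## Enrichment

ORA: hypergeometric upper tail P(X ≥ k) with fold enrichment (k/n)/(K/N);
BH within one collection; the background universe is an explicit, required
input (results are only interpretable relative to it). GSEA: weighted
running-sum ES (hit steps ∝ |score|^p, p = 1; miss steps 1/(N−K)); the null
permutes gene labels (random K-subsets of the ranked list) rather than
phenotypes, because 3 replicates per stage make phenotype permutation
degenerate; NES normalises by the mean |null ES| of matching sign and the
permutation p uses +1 smoothing.

## The synthetic generator

The generator emulates the study design the pipeline targets, not sequencing
data: fixed-length (150 bp) fragment *intervals* over a miniature
multi-chromosome genome; no sequence, mappability, GC or insert-size
structure. Defaults are the conditions under which the package's recovery
properties are stated:

| parameter | default | rationale |
|---|---|---|
| genome | 4 × 15 Mb | 30 kb gene slots keep ±5 kb promoters sparse (~⅓ of the genome promoter-covered, as in real annotations); denser packing makes every island "promoter" and the modified universe saturates |
| genes | 2,000 | desk-scale stand-in for a transcriptome |
| ChIP background | 0.01 fragments/bp | ~150k-fragment libraries, promoter input counts ~100/replicate — Poisson noise ~10% |
| domain fold / width | 8 / 10 kb | a strong broad domain centred on the TSS |
| replicates | 2 ChIP per channel, 3 RNA | the staged-design convention |
| NB dispersion | 0.05 | typical bulk RNA-seq biological CV ~22% |
| planted \|log2FC\| | 2 | comfortably above the ≥2-fold DEG rule |
| true HDEGs / decoys | 100 / 100 | decoys split half expression-shift-only (no promoter domain at any stage), half domain-flip-only (no expression shift) |
| silent fraction | 0.15 | exercises the silent class |

True HDEGs get a domain presence vector that flips opposite to their planted
expression sign at their transition (up-regulation ⇒ domain lost). The
expression-shift decoys carry *no* planted domain — the literal reading of "no
domain change" — so the two decoy families probe the two halves of the HDEG
intersection separately. An optional mode plants constant promoter domains
with class-dependent probability (silent > low > medium > high) to reproduce
the anti-coupled TSS-profile ordering. Every output sample draws from its own
RNG stream hashed from (master seed, sample label), so outputs are
bit-reproducible and adding a sample never perturbs the others.

What passing tests on this generator show: the pipeline's logic, calibration
and recovery behave correctly when the model assumptions hold exactly. What
they do not show: robustness to mappability artefacts, copy-number bias,
fragment-length variation, unbalanced libraries, or annotation errors — all
absent from the generator by design.

## Numerical and dialect choices

* Intervals are 0-based half-open internally; GTF converts at the boundary
  (1-based closed); BED fragments carry MAPQ in the name column.
* Minus-strand TSS is the last covered base (`end − 1`).
* Feature precedence promoter > 5′UTR > 3′UTR > exon > intron > intergenic on
  the island midpoint; nearest-gene ties go to the smaller gene id.
* BH is the standard step-up (scipy); q-values are order-preserving and ≥ p.
* The NB mean Newton solver runs 50 damped iterations from the moment
  estimate with a 1e-10 floor; at these sample sizes it converges to machine
  precision in < 10.
* Degenerate inputs: all-zero RNA samples yield zero TPM with a warning;
  empty IP libraries yield an empty call list with a warning; fewer than 4
  expressed genes make quartiles undefined (error); empty strata are omitted
  from profiles (warning).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` state their own scales: 6,000 null
genes for type-I calibration; 200 simulated 2,000-gene matrices for power;
50 random ≤100-window genomes for brute-force oracle equivalence of the
island caller; a full default run (2,000 genes) plus 10–20 null runs
(300 genes, 11 Mb) for HDEG recovery and false-call calibration; 400 genes
for the profile-ordering check. These sizes were chosen as the smallest at
which the binomial noise of the measured rates is well inside the asserted
margins.

## Known limitations

* The island caller's Poisson scoring ignores overdispersion between ChIP
  replicates (replicates are pooled); a replicate-aware NB island model would
  be the next step for noisy real data.
* No log2FC shrinkage: effect ranking at low counts is noisier than
  shrinkage-based engines; the DEG decision rule is unaffected.
* One TSS per gene; alternative promoters are invisible.
* GSEA reports one set at a time with sign-matched NES; no multi-set FDR
  field like the permutation-family q of reference implementations.
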