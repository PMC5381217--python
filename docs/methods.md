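# Methods

This document describes the statistical model behind `micquant`, the
assumptions it rests on, the meaning and rationale of every tunable
parameter, what the simulator does and does not emulate, and the package's
numerical conventions and known limitations.

## 1. Internal calibration

### Model

Each PCR reaction is spiked with `S` copies of a synthetic internal
calibrator (IC) amplicon sharing the 16S primer sites. After sequencing,
the sample-specific correction factor is

```
CF = S / r_IC                     [gene copies · read⁻¹]
ĉ(o) = r(o) · CF                  [gene copies per reaction]
```

where `r_IC` is the IC read count and `r(o)` the read count of OTU `o`.

### Assumptions

* The IC amplifies with the same efficiency as natural templates (same
  primer sites, similar length/GC). Any shared multiplicative loss —
  amplification, clean-up, loading, depth, rarefaction — cancels in the
  ratio `r(o)/r_IC`.
* Reads are proportional to template copies *within* a sample. Per-taxon
  efficiency differences violate this in bulk PCR; micelle PCR is how the
  wet-lab protocol restores it (clonal amplification, see §4).
* `r_IC` is large enough that `1/r_IC` noise is tolerable. `calibrate()`
  raises on `r_IC = 0` and warns below `min_ic_reads = 10` (a CF based on
  fewer than ~10 reads has ≥ 30 % relative sampling error).

### Spike recommendation

`recommend_spike(expected_total)` returns `0.10 × expected_total`, floored
at 50 copies. ~10 % of the template pool is large enough to be sequenced
reliably yet small enough not to suppress the biological signal; the
50-copy floor keeps the IC above Poisson dropout in low-biomass samples
and is the fixed choice for NECs, whose expected biological content is
zero.

### Rarefaction

Optional down-sampling to a common depth uses the multivariate
hypergeometric distribution (draw *without* replacement from the observed
reads), not multinomial resampling — at depths close to the library size
the hypergeometric variance shrinkage matters. Calibrated copies are
invariant in expectation to rarefaction because IC reads scale with
everything else.

## 2. Two-step decontamination

Every biological sample and every negative extraction control (NEC) is
amplified and sequenced in triplicate. The two steps target the two
contamination classes and run in a fixed order:

1. **Consensus filter (sporadic/environmental contamination).** An OTU is
   retained iff it has `> min_copies` (default 0, i.e. at least one read)
   in **all three** replicates. Environmental contamination strikes
   replicates independently; an OTU appearing in each replicate
   independently with probability `p` survives with probability `p³`.
   Removed OTUs are ledgered as `not_reproducible`.
2. **NEC subtraction (reproducible/reagent contamination).** Reagent
   contaminants appear in every library, including NECs, so the consensus
   filter cannot remove them. For each OTU quantified in all three NEC
   replicates, the threshold `mean + 3·SD` (sample SD, `ddof=1`) is
   computed from the NEC copy values and subtracted from the specimen's
   triplicate-mean copies; non-positive remainders are removed as
   `below_nec_threshold`. `mean + 3·SD` is the usual upper bound of the
   blank distribution: a specimen signal below it is indistinguishable
   from reagent background.

The order matters: subtraction operates on triplicate means, and sporadic
OTUs must not leak a diluted (mean/3) signal past a threshold that was
derived for reproducible signal. The corrected profile partitions every
observed OTU into exactly one of {retained, removed-with-reason}.

## 3. Accuracy metrics

All metrics operate on absolute copies, usually from mock-community
dilution series with known input `E` copies per taxon.

* **Trueness** `= mean(replicates) / E` (fold of expected; 1.0 is ideal).
* **Precision (CV)** `= SD(replicates, ddof=1) / mean` per taxon × level.
* **Pooled CV**: the CV of all per-replicate values of one method × level
  pooled together. `pooled_cv()` refuses mixtures of different expected
  values unless `expected_values` is supplied — pooling non-equimolar cells
  inflates the SD with between-taxon spread that is not imprecision.
* **Median fold**: median trueness over all cells of one method; a robust
  one-number bias summary.
* **Detection limit (LOD)**: the smallest input level of a dilution series
  at which every expected taxon is retained after correction, requiring
  contiguity (all higher levels must also detect); a gap returns the level
  above the gap, total failure returns `inf`.
* **Concordance**: per-sample fold `calibrated total / independent qPCR
  total`, summarized by mean ± SD; gauges absolute-scale agreement with an
  orthogonal method.
* **Paired Wilcoxon signed-rank** compares per-cell CVs between two
  methods. Implemented in-package: zero differences are dropped, tied
  absolute differences get mid-ranks, and for `n ≤ 20` the p-value is
  *exact*, computed by dynamic programming over the distribution of the
  signed mid-rank sum (two-sided, `p = min(1, 2·P(W ≤ w_obs))`). Above
  `n = 20` a normal approximation with tie and continuity correction is
  used. The exact branch exists because library routines either forbid
  ties in exact mode or silently fall back to the approximation — at
  `n = 16` pairs that difference is material.
* **KS normality** (scipy) supports checking replicate-noise assumptions.

## 4. Simulator

The generative model contrasts micelle PCR with conventional bulk PCR on
mock-community dilution series. Per replicate, in order:

1. **Template sampling.** Realized molecules per taxon ~ Poisson(level):
   pipetting 2.5 copies is a Poisson draw, and at the lowest dilutions this
   dropout — not sequencing — limits detection. The IC spike follows the
   §1 rule (`0.10 × 4·level`, floor 50). Reagent contaminants (defaults:
   `Ralstonia_reagent` 30, `Bradyrhizobium_reagent` 15,
   `Pseudomonas_reagent` 8 copies) enter every replicate, Poisson-sampled.
   Environmental contaminants hit each replicate independently: the number
   of sporadic taxa ~ Poisson(`env_rate = 2.0`), drawn from an 8-taxon
   pool, with log-normal copies (`logmean = ln 10`, `logsd = 1.0`).
2. **Amplification.**
   * *Micelle*: each template molecule amplifies clonally and
     independently; its yield is LogNormal(0, `σ = 0.3`). Per-OTU mass is
     the sum over its molecules. No cross-template interaction by
     construction, so relative yields concentrate around truth as copy
     number grows.
   * *Bulk*: each OTU × replicate draws one efficiency
     `E ~ U(0.85, 0.95)` compounded over `cycles = 30`: mass
     `= n·(1+E)³⁰`. The 10-point efficiency spread compounds to a
     ≈ 4.8-fold mass ratio between equal inputs — the template-competition
     bias micelle PCR removes.
3. **Sequencing.** Reads ~ Multinomial(depth 5,000, mass proportions). A
   chimera fraction of reads (micelle 0.01 %, bulk 4.5 % — emulsion
   compartments suppress hybrid formation) recombines two parent OTUs;
   chimera QC removes each with sensitivity 0.95, survivors appear as
   novel `chimera:A+B` OTUs. Libraries are rarefied to 1,000 reads.
4. **Inhibition flag.** `host_dna_excess` models host-DNA swamping: bulk
   libraries fail with `host_failure_prob`; compartmentalized reactions
   are immune.

Seeding is hierarchical (`numpy SeedSequence.spawn`): one master seed
deterministically derives independent streams per group, replicate, and
stage, so experiments are bit-reproducible and adding a level does not
perturb the others.

**Not emulated:** primer-site mismatches, 16S copy-number variation per
genome, length/GC-dependent polymerase bias, index hopping, PCR-error
(non-chimeric) sequence noise, taxonomic misassignment, and micelle
occupancy > 1 (perfect compartmentalization is assumed).

## 5. Pipeline and file formats

`micquant quantify` consumes either a simulation config or two TSV files:

* **Count table**: dense `otu_id × sample` integer read matrix (absent =
  explicit 0); the mothur `.shared` dialect is also read.
* **Metadata**: one row per sample with `sample_id`, `replicate_index`
  (1–3), `role` (`specimen`/`nec`), `ic_otu_id`, `ic_spike_copies`, and
  optional `group_id` (defaults to `sample_id` minus a trailing replicate
  token), `expected_copies_per_taxon`, `qpcr_total_copies`.

Exactly one NEC triplicate is required per run. A replicate whose
calibration fails (e.g. zero IC reads) invalidates its whole group: the
group is skipped and reported, never silently patched. Outputs carry no
timestamps, so reruns are byte-identical; `manifest.yaml` records the full
resolved configuration and package version.

## 6. Numerical conventions

* Reported statistics round half-away-from-zero (`round_half_away`), the
  convention of the clinical-chemistry literature the accuracy table
  follows, not banker's rounding.
* Copies are kept as floats end-to-end; only read counts are integers.
* SDs use `ddof=1` throughout (triplicates: n = 3).
* All stochastic entry points take either a seed or a numpy `Generator`.

## 7. Limitations

* The IC corrects multiplicative losses only; it cannot fix per-taxon
  amplification bias within a bulk PCR — that requires the micelle
  protocol itself.
* `mean + 3·SD` from n = 3 NEC replicates is a noisy threshold; a single
  aberrant NEC replicate can under- or overshoot it. More NEC triplicates
  per reagent lot would tighten it, but the model fixes n = 3 to mirror
  the specimen design.
* The consensus filter removes genuinely present taxa that drop out of one
  replicate; near the detection limit (Poisson presence ≈ 92 % per
  replicate at 2.5 copies) this is the dominant cause of the ~25-copy LOD.
* The exact Wilcoxon branch is O(n²·max-rank-sum) dynamic programming;
  fine for n ≤ 20, which is why larger n switches to the approximation.
* Accuracy reporting requires known expected copies (mock communities);
  on real specimens the pipeline yields calibrated, decontaminated copies
  and precision diagnostics, but trueness is undefined.
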