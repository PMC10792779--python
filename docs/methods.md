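# Methods

## Problem setting

Deep targeted panels (hundreds to thousands of reads per base over a few
dozen cancer genes) are the standard assay for clinically actionable gene
fusions (*ALK*, *RET*, *ROS1*, *NTRK1/2/3* and partners) and intragenic
events such as *MET* exon-skipping deletions. Sensitive SV callers recover
these events down to sub-percent variant allele fractions but at a high
false-positive cost. `svjudge` models the curation step that normally
happens by manual inspection: given a candidate SV and the local alignment
evidence, decide whether it is real.

## Data model and conventions

All coordinates are 0-based half-open internally; conversion to/from the
1-based VCF convention happens only in the I/O layer. The four breakend
join classes are carried in Delly `CT` notation (`3to5`, `5to3`, `3to3`,
`5to5`); a record without a stated join class has orientation `None`, which
is treated as compatible with anything during matching. Translocations and
fusions are unified under a single `BND` type with two unconstrained
breakpoints. Caller support counts distinguish *missing* (`None`, the
caller did not report the field) from an observed zero; imputation to 0
happens only at feature-matrix construction, paired with an indicator
column, so the forest can learn the difference.

One lossy corner: a `BND` with unknown orientation serializes to VCF in the
default `t[p[` adjacency form, so a read-back infers the `3to5` class.
Records with a known orientation round-trip exactly.

## Spike-in simulator

The generator works at the alignment level rather than editing raw reads
and re-aligning, because the feature extractor consumes alignments — this
keeps the whole loop desk-scale and dependency-free while preserving the
allele-sampling semantics of read-editing spike-in tools.

* **Background**: uniformly placed concordant proper pairs (100 bp reads,
  normal insert ~N(300, 40), clamped below at two read lengths), so mean
  depth over the region equals the target by construction. Requesting a
  depth below `min_depth` (default 100×) is an error.
* **Spiking**: each read pair crossing a breakpoint converts independently
  with probability `vaf`; the crossing read becomes a split read whose
  soft-clip boundary sits at the breakpoint with 0–2 bp uniform jitter
  (configurable), and its mate is repositioned next to the partner
  breakpoint, making the pair discordant. A pair converts at most once per
  event (tracked by pair name). If fewer than `min_mut_reads` (default 3)
  pairs convert, extra crossing pairs are converted and the truth record is
  flagged `forced_topup` — this mirrors the spike-in floor used for panel
  simulations and introduces a small upward bias at the lowest gradients
  (≈0.1 percentage points at 0.5% VAF and ~600 crossing pairs), well inside
  the 1-point unbiasedness budget checked by the acceptance experiments.
* **Gradients**: the default VAF series is 0.5%, 1%, 2%, 5%, 10%; child
  seeds derive deterministically from (base seed, gradient index, replicate
  index), so replicates are independent and the whole series reproduces
  bit-identically.

What the simulator does **not** emulate: sequencing error beyond Gaussian
base-quality noise, FFPE artifacts, mappability structure, GC coverage
bias, or the re-alignment ambiguity of real breakpoint-spanning reads.
Passing the recovery experiments therefore shows the machinery is
self-consistent at realistic depths and VAFs, not that the trained forest
transfers to any particular instrument or specimen type.

## Benchmarking

A call matches a truth event iff the SV types are equal, both breakpoints
lie within `tolerance_bp` (default 10 bp — covering the simulator's clip
jitter plus caller rounding) on the correct chromosomes under either
breakpoint pairing, and orientations do not conflict. The one-to-one
matching is an exact optimal assignment: maximum cardinality first, then
minimum total breakpoint distance, solved with the Hungarian algorithm. A
brute-force enumeration over all injective assignments serves as an
independent oracle in the tests; because the optimum need not be unique,
equivalence is asserted on the objective (match count, total distance)
rather than on pair identity.

Detection rate is matched-truth / total-truth per replicate, averaged
arithmetically; replicates with empty truth sets are excluded with a
warning. Caller comparison uses the two-sided equal-variance Student's
t-test (Welch behind a flag), which requires non-degenerate groups.

## Feature schema (version 1)

Per breakpoint: window depth, soft-clip read count, clip-length
min/max/mean, mapq min/max/mean, mean base quality, discordant-pair count,
repeat-overlap flag, and an empty-window indicator. Shared: DV, RV, DV+RV,
RV/(DV+RV) with an undefined-ratio indicator, a support-missingness
indicator, the SV-type one-hot, and an inter-chromosomal flag — 36 columns
in a fixed order, hashed; every trained bundle stores the hash and refuses
matrices built under any other schema.

Choices worth recording:

* A read is "in window" if any aligned base overlaps
  `[pos − 20, pos + 20)`; clip statistics only count clips whose boundary
  coordinate falls inside the window, so a clipped read passing through
  contributes depth but not clip signal.
* "Discordant" means not-proper-pair with the mate within 1 kb of the
  partner breakpoint on its chromosome — the convention callers use for
  pair evidence.
* Statistics over empty sets impute to 0 alongside the indicator column;
  no sentinel values, and the matrix is asserted finite.
* No scaling or normalization: tree ensembles are scale-invariant.
* Mean base quality is the mean of per-read means, which weights short
  overlaps equally with full overlaps; at panel depths the difference from
  a base-weighted mean is negligible.

## Decision model

* **Labels**: any-dissent-is-FP adjudication over ≥2 reviewer labels —
  conservative by design for clinical reporting.
* **Split**: train = floor(0.8·N), which gives the canonical 904/227 split
  of 1131 candidates. The split (and the CV folds) stratify by label by
  default; this is a deliberate mild strengthening of a plain random split
  to protect small test partitions, and can be turned off.
* **Search**: stage one samples (default 100 draws, without replacement)
  from a wide space — `n_estimators` 50…3000 in 60 even steps, `max_depth`
  None plus 10…500 in 50 even steps, `min_samples_split` {2, 5, 10},
  `min_samples_leaf` {1, 2, 4, 8}, `max_features` {auto, sqrt},
  `bootstrap` {True, False}. Stage two exhausts a grid around stage one's
  best point (`n_estimators` 180…220, `max_depth` 30…50,
  `min_samples_split` 3…7, rest pinned at sqrt/1/True). Both stages score
  by mean stratified 10-fold CV accuracy; ties go to the earlier candidate
  in draw/enumeration order, making results reproducible. `auto` is mapped
  to all features, per the historical convention under which the
  {auto, sqrt} pair is a meaningful contrast.
* **Defaults**: the shipped `FINAL_HYPERPARAMS`
  (186/sqrt/40/6/1/bootstrap) are the two-stage protocol's final values on
  the original panel cohort and are used by `train` unless overridden.
* **Decision threshold**: 0.5 on the TP probability, configurable per run;
  raising it can only shrink the retained set.
* No class re-weighting or resampling: the TP:FP imbalance in curated
  panel callsets is mild (~38:62).
* Metrics with zero denominators are reported as undefined (`None`), never
  silently as 0.

## Two-step pipeline

`read calls → panel filter → featurize → predict → retain p ≥ threshold`.
Off-panel calls are dropped before featurization (cheaper, and their
evidence is irrelevant to reporting). A call is on-panel if a breakpoint
overlaps a panel target interval or its annotated gene pair is on the
clinically-relevant SV list; strict mode additionally requires the event's
gene pair to be listed. Every input record leaves the pipeline exactly once,
retained with its probability or dropped with a reason (`off-panel` /
`model-FP`), and runs are idempotent given identical inputs and seeds.

The shipped panel tables are synthetic demonstrations (27 genes, 61 SVs in
a 4/20/37 prognostic/diagnostic/predictive split) with invented
coordinates; the panel is user data, supplied as editable TSVs.

## Experiment sizes and numerical tolerances

The recovery experiments run at desk scale chosen once as representative:
VAF recovery uses 200 events (40 per gradient) on 600 bp loci at 300×;
model recovery uses n = 1000 synthetic feature rows with a 3 SD planted
separation (and a 550/450 null table); the end-to-end experiment uses a
10 kb, 500× territory inside a panel gene with 10 planted deletions at 10%
VAF and 15 artifact calls. Real tumor panels run deeper (median ~1800×);
depth enters the features only through window counts, which the forest
handles without rescaling.

Floating-point notes: VCF QUAL survives round trips at float32/%g
precision; feature matrices are float64 and asserted finite; binomial
recovery intervals are central 99% intervals from `scipy.stats.binom.ppf`.

## Known limitations

* The simulator's evidence model cannot probe caller-internal behavior
  (assembly, local realignment); it benchmarks matching and filtering
  machinery, not callers themselves.
* The feature schema is a declared, versioned superset of the breakpoint
  characteristics named in expert-review practice; "signal strength" as a
  reviewer criterion has no computable counterpart here and is excluded.
* Cohort-specific results (confusion matrices, per-caller detection rates
  on patient-derived simulations) depend on data that cannot be shipped;
  the acceptance experiments substitute distribution-level properties on
  synthetic data.
* BAM is consumed via SAM-text semantics; CRAM and reference-dependent
  breakend normalization are out of scope.
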