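# Methods

## Model

The glucose-phosphate stress circuit is modeled as a well-mixed chemical
master equation over eight species: inactive and active *sgrS* gene copies
(`Ds_off`, `Ds_on`), *ptsG* gene copies (`Dp`), free SgrS (`S`), free Hfq
(`H`), the Hfq–SgrS complex (`HS`), free *ptsG* mRNA (`P`), and the
Hfq–SgrS–*ptsG* ternary complex (`HSP`). The full model has 11 mass-action
channels:

| # | channel | propensity |
|---|---------|------------|
| 1 | `Ds_off → Ds_on` | `k_on_Ds · n(Ds_off)` |
| 2 | `Ds_on → Ds_off` | `k_off_Ds · n(Ds_on)` |
| 3 | `Ds_on → Ds_on + S` | `k_t_s · n(Ds_on)` |
| 4 | `Dp → Dp + P` | `k_t_p · n(Dp)` |
| 5 | `P → ∅` | `beta_p · n(P)` |
| 6 | `S → ∅` | `k_ds · n(S)` |
| 7 | `S + H → HS` | `(k_bind/hfq_pool) · n(S) · n(H)` |
| 8 | `HS → H` | `k_unbind · n(HS)` |
| 9 | `HS + P → HSP` | `k_on · n(HS) · n(P)` |
| 10 | `HSP → HS + P` | `k_off · n(HSP)` |
| 11 | `HSP → H` | `k_cat · n(HSP)` |

Three structural choices deserve comment.

* **Hfq binding is truly bimolecular.** The binding rate is reported as a
  pseudo-first-order constant at the nominal pool; dividing by the pool
  size recovers that rate exactly when Hfq is free while letting pool
  depletion slow binding. The conservation law `H + HS + HSP = hfq_pool`
  holds along every trajectory and is asserted in tests.
* **Channel 8 consumes SgrS.** `k_unbind` is calibrated to the measured
  SgrS decay rate in Hfq-expressing cells under the assumption that
  unbinding is the rate-limiting step of that decay. If unbinding instead
  released intact SgrS, immediate rebinding (`k_bind ≫ k_ds · k_unbind /
  k_bind`) would give an effective decay ~3× slower than the measurement,
  so direct consumption is the reading consistent with the calibration.
* **Channel 11 recycles Hfq.** Only the two RNAs are co-degraded from the
  ternary complex; recycling is forced by the Hfq conservation law.

*ptsG* transcription is constitutive (Mlc repression is relieved under
stress and PtsG protein turnover is far slower than the 20-min window), and
all gene copies switch and transcribe independently at identical rates.

### Variants

Four variant tags support the model-complexity ladder, each a reduction of
the full model:

* `FULL` — regulation + gene duplication + explicit Hfq (11 channels).
* `NO_REG` — channels 1–2 removed; every *sgrS* copy transcribes regardless
  of switching state, implemented as one transcription channel per
  gene-state species (10 channels).
* `NO_GENEDUP` — full channel list, but a single copy of each gene.
* `NO_HFQ_NO_GENEDUP` — additionally removes `H`/`HS`: SgrS binds *ptsG*
  directly (`S + P → SP` at `k_on`, dissociation `k_off`, co-degradation
  `k_cat`) and free SgrS decays at the with-Hfq effective rate `k_unbind`
  (8 channels over 6 species). This is the constitutive single-copy
  baseline of earlier deterministic work; its free-SgrS decay assignment is
  the one defensible choice given that baseline lumps Hfq stabilization
  into the sRNA lifetime.

The ladder is ordered `NO_HFQ_NO_GENEDUP → NO_GENEDUP → NO_REG → FULL`.

## Parameters

Defaults (wild type): `k_t_p = 0.12 s⁻¹` per *ptsG* copy, `beta_p =
3.7×10⁻³ s⁻¹`, `k_on_Ds = 3.0×10⁻² s⁻¹`, `k_off_Ds = 9.5×10⁻³ s⁻¹`,
`k_t_s = 0.33 s⁻¹` per ON copy, `k_ds = 0.022 s⁻¹` (Hfq-null SgrS decay),
`k_bind = 0.063 s⁻¹`, `k_unbind = 0.0018 s⁻¹` (with-Hfq SgrS decay),
`k_on = 3.1×10⁻⁴ molecule⁻¹s⁻¹`, `k_off = 0.22 s⁻¹`, `k_cat = 0.3 s⁻¹`;
25% of cells carry 4 *sgrS* copies (else 2) and 46% carry 2 *ptsG* copies
(else 1); the Hfq pool available to the SgrS regulon is 250 molecules. The
`U224G` preset (a polyU-tail point mutant impairing Hfq recruitment)
overrides exactly `k_bind = 0.033`, `k_unbind = 0.003`, `k_on = 2.1×10⁻⁴`,
`k_off = 0.27`.

Percent differences for mutant-vs-WT reporting are rounded to the nearest
integer percent (`+67%` for `0.003` vs `0.0018`, `+23%` for `0.27` vs
`0.22`).

## Simulation

The Gillespie direct method (exact CME sampling) is used throughout; copy
numbers are small enough that approximate accelerations would buy nothing.
States are recorded on a fixed grid with last-event-before-time semantics
(the right-continuous step function). The inner loop is numba-compiled;
a pure-Python fallback with the same draw order exists. Replicate `i` of an
ensemble is seeded `base_seed + i` (kept below 2³¹), with separate streams
for dosage/basal sampling and the event loop, so ensembles are reproducible
and embarrassingly parallel.

Each replicate stands for one imaged cell: gene dosage is drawn by two
independent coin flips, basal counts from discrete-uniform distributions
(SgrS on {1..3}, ptsG on {30..40}; pluggable empirical histograms are
supported since only the measured ranges are published), all *sgrS* copies
start OFF, Hfq starts fully free, and snapshots are taken at minutes
{0, 2, 4, 6, 8, 10, 15, 20} of a 25-min horizon. The t = 0 snapshot is the
sampled pre-induction state. Labeled totals are `S + HS + HSP` (SgrS) and
`P + HSP` (ptsG): tiled smFISH probes count a transcript whether or not it
is protein-bound, and any other mapping would break count conservation
during binding.

## Statistics

* **KDE.** Gaussian kernel with Scott's-rule bandwidth `σ·n^(−1/5)`
  (bandwidth unspecified in the source analysis); densities are evaluated
  on a common 512-point grid spanning `[min − 3σ, max + 3σ]` of the pooled
  samples. Zero-variance samples are rejected unless an absolute bandwidth
  override is supplied (the fitting objective falls back to 0.5 counts for
  degenerate candidates).
* **KL divergence.** Natural logarithm (matching the natural-log decay
  fits), direction experimental‖simulated, grid-cell-width weights, both
  densities floored at 10⁻¹² inside the log ratio — this keeps the value
  finite where the simulated density vanishes and exactly zero when the
  two densities coincide. Discretization can make the value negative by at
  most ~10⁻⁶.
* **Decay fits.** Ordinary least squares of `ln(mean count)` on time in
  seconds; the rate is the negated slope. Non-positive means are refused
  (background must be handled by the caller); the chase helper drops
  timepoints whose sample mean is zero — with ~500 cells and rates around
  0.022 s⁻¹ the expected count at 8 min is ~10⁻³ per cell, below the
  detection limit of a finite sample, and a log-linear fit cannot use such
  points.
* **Unit conversion.** `pseudo_to_second_order` divides a 1/s rate by the
  partner concentration `pool/(N_A·V)`; the default volume is 1 fL, which
  maps 0.063 s⁻¹ at 250 molecules to 1.5×10⁵ M⁻¹s⁻¹. The implied cytosolic
  concentration of 250 molecules in 1 fL is ~0.4 µM; a published rounding
  of that concentration to 0.5 µM would imply ~0.83 fL, so the volume is an
  explicit argument rather than a constant.

## Fitting

The objective simulates an ensemble at the candidate parameters and sums
KL(reference ‖ simulated) over timepoints and both species. Common random
numbers (a fixed base seed across candidate evaluations) make the objective
a deterministic, relatively smooth function of the candidate, which
derivative-free Nelder–Mead handles well; rates and the Hfq pool are
optimized in log space (the pool rounded to an integer per evaluation) and
fractions in logit space, with box bounds enforced by clipping plus a
quadratic penalty. Free parameters start at the geometric midpoint of their
bounds unless given explicitly, and the evaluation budget defaults to 60.
These choices (optimizer, transforms, starts, budget) are the package's
own; the source analysis does not state its optimization procedure.
Single-parameter recovery on synthetic data is the supported, tested
regime; joint fits of many parameters run but are weakly identifiable, as
the large published uncertainties (e.g. pool 250 ± 167) already suggest.

## Synthetic data

The generator emulates exactly what the analysis consumes: per-timepoint
per-cell integer counts with 85–200 cells per timepoint (drawn uniformly
unless fixed). Synthetic cells ARE model replicates — no measurement noise
is added by default, because the analysis compares background-subtracted
probe counts to raw simulated counts. An optional per-cell additive Poisson
background stresses the fitting path. The generator does not emulate
imaging-level artifacts (probe photophysics, clustering, drift), partial
probe hybridization, segmentation errors, or cell-cycle correlations
between timepoints (the same replicate is observed at every timepoint,
whereas real aliquots are disjoint cells; only per-timepoint marginals are
used downstream). Passing tests therefore validate the analysis machinery
on data whose generative model is known, not the model's fidelity to any
particular experiment.

## Problem sizes

Tests and the acceptance script use 1,000-replicate ensembles for
population means, 500 cells/replicates for fitting-recovery and chase
experiments, and 800 for the variant ladder — sizes at which the checked
quantities are stable to well within their asserted tolerances.

## Known limitations

* With the default rate table the simulated mean of labeled SgrS at 2 min
  is ~35 copies (1,000–2,000 replicates; an independent mean-field
  integration of the same equations agrees), which falls short of the
  published ">40 copies within 2 min": over 120 s the ON-state integral
  yields ≈59 transcripts, of which ~26% die at `k_ds` before Hfq capture
  and ~7 are co-degraded with *ptsG*. The corresponding acceptance test
  asserts the published bound and is expected to fail; the package reports
  what the equations produce.
* No cell division, volume growth or partitioning: dosage is static per
  replicate over the 20-min window.
* No spatial effects (RNase-E localization, co-transcriptional target
  binding) and no competing SgrS targets (*manXYZ*, *yigL*); the Hfq pool
  parameter absorbs competition for the chaperone.
* Published parameter uncertainties are used only as recovery bands;
  no uncertainty quantification beyond repeat-fit spread is attempted.
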