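# Methods

This note records the models, parameter choices and numerical conventions
behind `rhpanel`, and what the simulation-based tests do and do not
establish about real panels.

## The generative panel model

One simulated experiment (a `PanelScenario`) proceeds in four stages.

1. **Germline breakage (RH₀).** The irradiated embryo's germline is G
   independent cells. In each cell, each homolog of each D chromosome
   receives breaks as a homogeneous Poisson process at
   `break_rate_per_Gb_per_Gy × dose_Gy` breaks per Gb. Breaks partition
   the chromosome into fragments; each fragment not containing the
   centromere is deleted with probability `fragment_loss_prob`, while the
   centric fragment is always retained. This viability convention keeps
   whole-chromosome loss out of the model and marker loss at the few-percent
   level observed in surviving plants. Deletions are stored as 0-based
   half-open bp intervals, merged per homolog.

2. **Transmission (RH₁).** Each sibling draws one germline cell uniformly
   from the G cells and one of its two homologs uniformly, and inherits
   that homolog's deletions. Nothing about the 1/(2G) law is hard-coded:
   it emerges from uniform cell and homolog choice, and the test suite
   verifies it empirically.

3. **Scoring.** A marker call is lost iff the transmitted homolog's
   deletion set covers the marker position. Each call is independently
   replaced by *missing* with probability `missing_rate`; true calls are
   never flipped between retained and lost (the marker assays carry
   internal PCR controls, so failure reads as ambiguity, not absence).

4. **Truth record.** The simulator returns the germline deletions, each
   line's source cell/homolog and inherited intervals, and the true marker
   order, enabling parameter-recovery tests without circularity.

### Default scenario (the study conditions)

| parameter | default | basis |
|---|---|---|
| `dose_Gy` | 450 | higher of the two production doses |
| `n_families` | 312 | families in the real panel |
| `siblings_per_family` | 4.8 | panel mean (Poisson, clipped ≥ 1) |
| `G` | 5 | the panel's estimated GECN (≈5) |
| `break_rate_per_Gb_per_Gy` | 0.01775 | calibrated, see below |
| `fragment_loss_prob` | 0.04058 | calibrated, see below |
| `missing_rate` | 0.01 | no published rate; 1% is a realistic PCR-ambiguity rate |

The default marker map (`uniform_marker_map`) emulates the 35-locus
whole-genome SSR screen: five evenly spaced markers per chromosome, on
round-figure chromosome lengths totalling ≈4.0 Gb with midpoint
centromeres.

### Calibration

The expected per-marker loss has the closed form
`fragment_loss_prob × (1 − exp(−λ·|pos − centromere|))` with λ the break
rate per bp, because a marker leaves the centric fragment iff at least one
break falls between it and the centromere. `calibrate_scenario` fits the
two rate parameters by least squares to the observed dose → loss anchors
(1.2, 1.7, 1.9, 2.4% at 150–450 Gy); the defaults above are that fit on
the default map. The fit reproduces the anchors to within ~0.15 percentage
points — the observed dose curve is slightly less saturating than the
single-exponential form.

### What the simulator does not emulate

* **Deletion granularity.** The calibrated model produces more, smaller
  deletions than the real panel: at matched 2.3–2.4% marker loss it makes
  ~50% of lines informative versus the observed ~26%, with correspondingly
  fewer markers lost per informative line. Tests that depend on who-loses
  -what granularity (informative fraction, multi-chromosome profiles) are
  therefore checked directionally, not numerically.
* No viability selection beyond the centric-fragment rule: lethality of
  gene-rich deletions, germination differences between cross directions,
  and embryo-rescue rates are outside the model.
* Only the monosomic D genome is represented; the A/B genomes buffer
  deletions biologically but carry no markers here.
* Homologs are irradiated independently and deletions can arise on both
  homologs of a cell; a sibling receives exactly one homolog.

Consequently, passing simulation tests demonstrate the correctness of the
estimators and the mapping engine under the stated generative model — not
that the model captures every feature of real irradiated germlines.

## GECN estimation

`unique_deletion_estimates` finds, per family and chromosome, maximal runs
of adjacent markers (map order) with identical carrier sets and treats each
run as one unique deletion mutation; *t* is taken at the run's best-scored
marker, *d* is the carrier count, and the estimate is t/(2d), kept
real-valued. Missing calls count in neither t nor d.

Decisions worth knowing:

* **Fixed deletions** (d = t) would read GECN 0.5 and contradict a
  chimeric germline; they are flagged and excluded from averages by
  default.
* **Truncation bias.** Conditioning on observing at least one carrier
  (d ≥ 1) makes E[t/(2d)] < G at modest family sizes: with t = 12 and
  G = 5 the expectation is ≈4.4. The test suite shows the bias and its
  decay with family size rather than hiding it; the acceptance band
  (±0.75) is wide enough to contain it.
* `min_family_size(5, 0.95)` returns 29, the exact smallest n with
  1 − 0.9ⁿ ≥ 0.95 (1 − 0.9²⁹ = 0.953). Published discussions of the same
  design sometimes round this bound up to 30.
* `spiked_rh0` plants exactly one single-cell, single-homolog deletion per
  locus. It is the generator used for estimator parameter-recovery
  studies because dose-driven breakage occasionally hits the same locus in
  two cells, inflating d and deflating the estimate by construction rather
  than by estimator error (with the default calibration, ~10% of
  marker-deletions are doubled, shifting the mean estimate from ≈4.4 to
  ≈4.1 at G = 5).

## Panel statistics

All frequencies are conditional on scored calls: missing is excluded from
numerator and denominator, and a unit with nothing scored reports NaN, not
zero. Per-chromosome loss is the unweighted mean over the chromosome's
per-marker losses (marker granularity preserved, ranges reported).
"Informative" requires a confirmed lost call. The homogeneity test is the
Pearson chi-square on the k×2 (lost, retained) table without continuity
correction (delegated to `scipy.stats.chi2_contingency`; an independent
hand-formula oracle lives in the tests); expected cells below 1 set a flag
but do not suppress the result.

## Mapping engine

**Two-point.** The haploid equal-retention likelihood (pattern
probabilities in the module docstring) has a quadratic score equation, so
θ̂ is closed-form; the tests verify it against a 10⁻⁴ grid search of the
same likelihood. r is the mean marker retention of the marker set,
estimated once and held fixed during ordering — the simplest identifiable
choice. Missing calls drop lines pairwise. θ̂ at the boundary 1 is
reported unlinked (infinite cR).

**Order scoring.** An order's multipoint likelihood under the Markov chain
of retention states factorizes into adjacent-pair joint log-likelihoods
(each at its own θ̂) minus interior marginal terms. With complete data
this equals the full multipoint maximum likelihood; with missing calls the
pairwise-complete counts make it a composite likelihood. The
factorization makes one order evaluation O(n) after an O(n²·lines)
precomputation, which is what keeps 100-replicate order-recovery studies
cheap. The score is invariant under order reversal, as it must be.

**Framework construction** (`build_framework`): markers are first grouped
into retention-pattern bins (missing as wildcard, transitively closed,
conflicts reported — the relation can be intransitive under heavy
missingness); one representative per bin enters the search, because
pattern-identical markers can never separate by any LOD margin. Anchors
fix the backbone; a candidate is placed only when its best insertion slot
beats the second best by ≥ `lod_threshold` (log₁₀ units, default 3);
accepted markers are re-ordered within their interval — exhaustively for
≤ 8, otherwise greedy insertion in sorted order, then pairwise swaps and a
width-4 sliding-window polish to convergence; passes repeat until nothing
places. The search is fully deterministic: candidates are visited in
sorted order and ties break toward the first-found order; the final
orientation follows the stated anchor order. A warning is raised if some
anchor permutation beats the stated order by more than the same LOD
margin.

**Distances and summaries.** Positions are cumulative adjacent-pair cR;
adjacent unlinked pairs (θ̂ ≈ 1, not expected for markers that passed
placement) are capped at θ = 0.99 with a warning. Obligate breaks count
retained↔lost transitions in map order, skipping missing calls; ends
contribute nothing, so terminal deletions count one break and interior
deletions two (the end convention is a package choice). Resolution is
span_bp/1000/n_breaks, read as an upper bound on marker separation.

### Order-recovery study conditions

The ordering acceptance study uses a 25-marker, 655 Mb chromosome with 400
informative lines drawn from a breakage-rich scenario (0.018 breaks/Gb/Gy
at 450 Gy ≈ 5 breaks per transmitted homolog, acentric loss probability
0.5, 1% missing) — "adequate breaks" in the sense that adjacent-marker
breakage fractions sit near 0.2 and mean retention near 0.6, the regime
classic RH panels operate in. Under these conditions the framework search
recovers the true order or its reverse in ≥95 of 100 seeded replicates;
recovery degrades gracefully as lines are removed.

## Numerical conventions

* Coordinates 0-based half-open bp; intervals merged after sampling.
* One top-level seed per scenario; child streams are spawned per family
  and for the scoring-noise stage (`numpy` `SeedSequence.spawn`), so
  panels are bitwise reproducible and families are independent.
* Likelihood ties (< 10⁻¹² natural-log units) resolve toward the
  lexicographically earlier order.
* Chi-square on a table with an all-zero column returns χ² = 0, p = 1
  (nothing to test) with the low-expected flag set.
* Problem sizes in the test suite (200 GECN panels, 100 ordering
  replicates, 10³ chi-square replicates) were chosen as the smallest sizes
  at which Monte-Carlo error is far below the tested tolerances.

## Known limitations

* The mapping engine is functionally analogous to, not bit-compatible
  with, the Carthagene-based pipeline used on the real panel; the real
  panel's data-derived numbers (453 cR for 2D, 37 obligate breaks, 15
  bins, 1:5.2 cM/cR) cannot be recomputed because the underlying genotype
  matrix is unpublished. The package covers them structurally (same
  statistics, same arithmetic) on simulated data.
* The composite-likelihood ordering score is exact only with complete
  data; at the 1% default missingness the approximation is negligible,
  but heavy missingness would argue for a forward-algorithm multipoint
  likelihood, which is not implemented.
* Retention r is treated as equal across markers of a chromosome, while
  the generative model (centric fragments always retained) makes retention
  rise toward the centromere; the mismatch is absorbed by θ̂ and does not
  disturb ordering in practice, but cR distances near centromeres are
  model-dependent.
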