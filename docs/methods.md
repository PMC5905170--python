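# Methods

## The procedure

`plasmaquant` implements a label-free quantification workflow for
multi-run LC–MS/MS peptide data, of the kind exported per sample by a
database-search engine (sequence, measured and theoretical monoisotopic
mass, retention time, peak area, Xcorr, confidence, rank, candidate
accessions).  The pipeline harmonizes features across runs and tests
proteins for differential abundance between a case and a control group,
with an internal discovery/test replication step:

1. **Record filtering.**  Peptide identifications with rank ≤ 5 and any
   confidence level (high/medium/low) are retained; both cutoffs are
   configurable.

2. **Retention-time calibration.**  One run is designated the reference
   (flagged in the study design; a helper can suggest the run with the
   widest joint mass/rt coverage).  For every other run, peptides are
   matched to the reference by exact sequence identity — sequences
   occurring more than once in either run are excluded as ambiguous —
   and a LOWESS curve rt_sample → rt_reference is fitted on the matched
   pairs (span 0.3, three robustifying iterations by default; at least
   10 pairs required).  The fitted curve is made non-decreasing by
   isotonic regression and extended outside the observed range by
   constant-offset extrapolation from the nearest endpoint, so the
   mapping is monotone and total and preserves within-run elution
   order.  Applying a run's own model to the reference is the identity.

3. **Feature clustering.**  All calibrated records are placed in the
   (mass, rt) plane.  Every point seeds a candidate center; each center
   repeatedly moves to the mean of the points inside its window — mass
   ± 5 ppm of the center mass, rt ± 5 % of the center rt — a
   flat-kernel mean shift with per-point relative windows (at most 50
   iterations, convergence at 10⁻⁶ window-normalized movement).
   Converged centers closer than half a window in both dimensions merge
   onto the center capturing more points (ties: lower mass, then lower
   rt).  Points are assigned to the admissible center with the smallest
   window-normalized Euclidean distance, centers are recomputed once
   from their members, and members outside the recomputed center's
   window are released.  Only clusters with ≥ 2 members enter the
   cluster list; window containment is asserted on every run.  The
   procedure is deterministic: points are sorted by (mass, rt) before
   seeding and all tie-breaks are total orders.

4. **Sequence and protein assignment.**  Each cluster's representative
   sequence is the modal member sequence; frequency ties go to the
   sequence whose members attain the highest Xcorr, then
   lexicographically.  Members whose measured mass deviates from the
   theoretical mass by ≥ 5 ppm are then removed (strictly `< 5 ppm`
   retained), cascading clusters below 2 members.  Shared peptides
   (several candidate accessions, taken as the union of the members'
   candidate lists) resolve to the accession represented with the
   highest frequency across the whole cluster list — by default
   counting clusters whose candidate sets include the accession
   (counting member records instead is available via
   `protein_count_mode="records"`); ties resolve to the
   lexicographically smallest accession.  This makes protein assignment
   a function of the entire cluster list, which the tests exercise with
   a constructed counterexample.

5. **Quantification** (per set, discovery and test analyzed
   separately).  Each cluster × sample cell is *detected with area*,
   *identified but no area retrieved*, or *not identified*.  In the
   discovery set only, peptides detected in at least 50 % of the
   samples of at least one group are kept; the test set is unfiltered.
   Identified-but-no-area cells are imputed with the mean observed area
   of the sample's group within the set (zero if the group has no
   observation); not-identified cells become zero; observed cells are
   never altered.  Areas are then ppm-normalized — each cell divided by
   its sample's total and scaled by 10⁶, so every sample column sums to
   one million — and protein abundance is the sum of the protein's
   normalized peptide areas, with the peptide count taken as the number
   of distinct representative sequences per protein.

6. **Differential abundance.**  Per protein, the case/control ratio of
   group-mean abundances (proteins observed in only one group yield
   explicit only-in-cases / only-in-controls sentinels, which count as
   changed in their direction) and a two-sided Mann–Whitney p-value.
   The exact rank-sum distribution is used for tie-free samples with
   n₁+n₂ ≤ 30 (or on request); otherwise the normal approximation with
   tie and continuity correction; the branch used is recorded per
   protein.  Two identical constant groups get p = 1.  A discovery hit
   requires ≥ 2 peptides, p ≤ 0.05 and ≥ 2-fold change; verification
   requires the same trend with ≥ 2-fold change in the test set, and
   test-set significance additionally p ≤ 0.05 there.  No
   multiple-testing correction enters the calls (the design relies on
   fold, peptide-count and replication filters); a Benjamini–Hochberg
   column is emitted for information.

Concordance with external data (e.g. reported plasma concentrations)
uses Spearman rank correlation on log₁₀-transformed positive pairs;
non-positive pairs are dropped and counted.  Rank correlation is
invariant under the strictly increasing transform — it is applied and
reported for fidelity with standard practice.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `mass_window_ppm` | 5 ppm | clustering mass half-window, relative to center mass |
| `rt_window_frac` | 0.05 | clustering rt half-window, relative to center rt |
| `mass_accuracy_ppm` | 5 ppm | strict upper bound on measured-vs-theoretical deviation |
| `min_members` | 2 | minimum cluster size retained |
| `detection_fraction` | 0.5 | discovery-set detection filter threshold |
| `min_peptides` | 2 | peptide support required for a DE call |
| `fold` / `alpha` | 2.0 / 0.05 | fold-change and significance thresholds |
| `lowess_fraction` | 0.3 | LOWESS span for rt calibration |
| `split_fraction` | 2/3 | discovery share of each group when the design is unsplit |

The group-wise split uses `ceil(fraction · n)` per group, preserving
case/control balance; the reference run is guaranteed a discovery slot
(swapped deterministically if the shuffle places it in the test set).

## The synthetic generator

Because the pipeline's accuracy cannot be judged without truth, the
`synth` module generates whole studies with known ground truth.  Its
defaults are the study conditions used throughout the tests: 13 + 8
discovery and 6 + 5 test samples (cases + controls), 40 proteins with
2–6 tryptic-like peptides each (monoisotopic masses from pyteomics), rt
uniform on 20–480 min (an eight-hour-gradient class separation), six
true differential proteins at |log₂ effect| = 1.5 (half up, half down),
2 ppm Gaussian mass error, 0.05 min rt apex jitter, per-sample monotone
drift (affine slope 0.97–1.03, intercept ±3 min, plus a bounded
sinusoid of amplitude ≤ 1.5 min and period 200 min), log-normal base
areas (ln-scale μ = 16, σ = 1.5) with per-subject biological variation
(σ = 0.4, shared by a protein's peptides within a sample) and technical
noise (σ = 0.2), 10 % identification dropout, 2 % missing areas among
identifications, 5 % run-unique spurious singletons, and 5 % shared
peptides.  Distinct true features are kept ≥ 3 clustering windows apart
in mass or rt so the feature ↔ cluster correspondence is well defined.

The generator emulates the *statistical* structure the pipeline
assumes, not raw spectra: no chromatographic peak shapes, no charge
states, no search-engine FDR structure, and feature collisions
(co-eluting isobaric peptides) are excluded by construction.  Passing
tests therefore demonstrate correctness of the processing rules and
robustness to the modeled noise sources — not performance on real
instrument data.

`SynthConfig.zero_noise()` produces the perfect-recovery regime
(identity drift, exact masses, no dropout, no decoys, no biological or
technical noise, and no shared peptides, since shared-peptide
assignment is genuinely ambiguous at the protein level): there the full
pipeline must recover the feature set, per-sample protein ranks
(Spearman ρ = 1) and the DE set exactly, and the tests assert that it
does.

## Numerical and design choices

* Masses are neutral monoisotopic Da throughout; any charge handling is
  upstream of the pipeline.
* A missing peak area is an empty TSV field, distinct from `0.0` — the
  two states are imputed differently.
* "Moved until capturing most data points" -style center seeking is
  operationalized as flat-kernel mean shift seeded at every point; with
  per-point relative windows this is deterministic under the stated
  sort and tie rules.  An independent plain-Python re-derivation serves
  as the reference implementation in the tests.
* The discovery detection filter uses ≥ 50 % (not strictly more than),
  and the mass-accuracy filter uses strictly < 5 ppm.
* Group means for imputation are computed on raw (pre-normalization)
  observed areas, within the set; normalization totals are computed
  over the peptides surviving the set's filters.
* Calibration is fitted on post-filter records (rank/confidence filter
  first); mass is never recalibrated, only rt.
* Fold changes use group means (consistent with mean-based imputation
  and the sentinel convention); tests are two-sided.
* Repeated identifications of one feature within a run are averaged,
  not summed, to avoid double-counting one chromatographic peak.
* Tie-breaks (merge order, assignment, sequence, accession) are total
  orders chosen for reproducibility; rerunning a pipeline with the same
  inputs, config and seed is byte-identical, and outputs carry no
  timestamps.

## Problem sizes used in the checks

The test-suite and acceptance studies use the default 40-protein /
32-sample configuration (~150–180 true features, ~5 000 records), with
the DE regression bound pooled over 20 seeded replicates and the
acceptance DE metrics pooled over 5.  At these sizes the pooled
discovery sensitivity is ≈ 0.8–0.9 and the pooled false-discovery
proportion ≈ 0–0.1 under the default conditions; both are asserted only
as regression bounds (≥ 0.7 and ≤ 0.15).

## Known limitations

* Protein inference is the frequency rule only — no parsimony grouping;
  protein grouping is assumed disabled upstream.
* Joint clustering of all samples with set-wise quantification
  afterwards; sets are never normalized jointly.
* The exact Mann–Whitney branch ignores ties (the auto branch switches
  to the corrected normal approximation whenever ties occur).
* The rt drift model is smooth and monotone; non-monotone drifts (e.g.
  column failure mid-run) are out of scope and rejected by the
  generator's validation.
* Real Proteome Discoverer binary formats, mzML/mzTab, and spectral
  processing are out of scope; the documented TSV dialect is the
  interchange format.
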