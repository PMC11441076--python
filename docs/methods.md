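# Methods

## Analysis model

The pipeline treats each imaging week as a 3D point cloud of nucleus
centroids with per-nucleus labels. Four stages are chained:

1. **Registration.** Weekly fields differ by a small rigid motion and a
   near-unity uniform scale (slow cortical atrophy). The similarity
   transform is estimated from paired fiducial nuclei by the closed-form
   least-squares absolute-orientation solution (SVD/Umeyama form) with
   isotropic scale; the sign correction guarantees a proper rotation even
   for reflected or noisy input. Anisotropic stretch and shear are
   deliberately not fitted: over 4 weeks at this field size the
   deformation is near-isotropic, and the closed form keeps the stage
   exactly reproducible. All sessions are mapped into the week-1 frame
   and cropped to the intersection of their bounding boxes, so every
   analysed nucleus was observable in every week. Residuals are reported
   in μm and in voxel units (XY pitch 509/1024 ≈ 0.497 μm, Z pitch 2 μm).

2. **Tracking.** Consecutive sessions are linked by mutual nearest
   neighbours under a hard gate (default 8 μm — about one nucleus
   diameter, and below the 12 μm hard-core separation of cortical
   nuclei, so chains cannot swap identity). A disappearance is called
   only when the absence persists through the final session. Two
   censoring rules produce fate `ambiguous`: a spatially compatible
   unassigned nucleus reappearing near the lost position (transient
   invisibility), and any track that ever comes within the edge guard
   band (2 μm) of the crop boundary. The edge rule is applied to *all*
   tracks, dying and surviving alike: censoring only broken tracks
   removes deaths but not survivors from the counts and biases loss
   fractions low by about half a percentage point at default noise.
   Ambiguous tracks are excluded from every death numerator and
   denominator and reported separately.

3. **Microstructure.** d₃ is the mean distance to the 3 nearest
   neighbours; the local enlargement ratio divides a neuron's d₃ by the
   mean d₃ of all neurons within 100 μm (inclusive radius, focal
   excluded) minus one, with a strict 0.60 flagging cutoff and a strict
   0.20 cutoff available for volume changes. The local mean requires at
   least 5 neighbours (records below that get a null ratio rather than
   being dropped); neurons whose 100 μm ball is clipped by the crop
   bounds carry an edge flag but are not excluded, since the ratio is
   locally normalised. For the longitudinal statistic, each neuron's 4
   nearest persistently-present neighbours (fixed at the first observed
   week; fiducial tracks excluded — they anchor the registration, so
   using them as displacement-sensitive vertices would tie the statistic
   to the alignment) span a tetrahedron whose volume |det(b−a, c−a,
   d−a)|/6 is followed weekly. The percent change over the window
   (death−2, death−1) is the pre-death statistic; persistent neurons are
   evaluated on the matched final-2-week window.

   *Degeneracy guard.* The percent change of a nearly flat tetrahedron
   is dominated by the noisy baseline volume in the denominator
   (|det| of noise). Aggregations therefore exclude windows whose
   baseline shape quality V/L³ʳᵐˢ is below 0.02 (a regular tetrahedron
   scores ≈ 0.118): below that, the baseline volume of a typical
   neighbourhood (~30 μm edges, ~0.5 μm centroid noise) is comparable to
   its own measurement noise. Excluded windows are counted and reported.

4. **Survival summaries.** Grouped fate tables give loss fractions
   (100·died/total), per-week loss on the at-risk population, and two
   hazard-ratio variants: cumulative (ratio of overall loss fractions)
   and weekly (ratio of mean per-week rates). Both are always reported —
   a published per-week summary is generally not derivable from printed
   totals, while the cumulative variant is. The 2×2 chi-square uses the
   Pearson closed form without continuity correction: on the published
   fate table the uncorrected statistic reproduces the printed 17.8
   (Yates-corrected would give ≈ 16.9). The snapshot loss projection
   100·flagged_fraction·per_period_rate·periods_per_year is a simple
   proportional annualisation whose period length is an explicit input.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
it is the test bed for every stage, not a biophysical simulation.

* **Geometry.** Nuclei are a hard-core point process (dart throwing
  with a cell-list acceptance test; packing failure raises an explicit
  error) in a 509 × 509 × 200 μm field, default 1,500 nuclei at 12 μm
  minimum separation. At that density the mean d₃ is ~25 μm, matching
  persisting-neuron distances; the density alone fixes this value.
* **Fates.** Per-week death is Bernoulli with hazard 0.036 (non-tangle)
  or 0.010 (tangle), optionally scaled by a change-point factor from a
  given week (the tau-suppression scenario). Hazards are weighted by
  d₃^α (α = 2, normalised to preserve the mean hazard), so doomed
  neurons preferentially sit in sparse neighbourhoods — the directional
  first-week d₃ property the analysis must reproduce. The change-point
  recovery scenario uses α = 0: with coupling on, survivor selection on
  the hazard weight makes the true post/pre rate ratio ≈ 0.46 rather
  than the planted 0.5, and that scenario tests hazard recovery alone.
  Tangle flags start at 7.4% and convert at 2.2%/week among survivors;
  fiducials (8, one per field octant, 4 upper / 4 lower) never die.
* **Pre-death ramp.** Each dying neuron observed for ≥ 2 prior weeks
  pushes its 4 nearest persistent neighbours radially outward so the
  neighbour tetrahedron grows by exactly `ramp_volume_pct` (default
  29.5%) across its final observed window. Because nearby dying neurons
  share neighbours, the push magnitudes are coupled; they are solved
  jointly (Gauss–Seidel sweeps, bounded bisection per neuron) under two
  feasibility constraints with per-vertex compensation: no vertex may
  jump more than 5 μm in one week (it would sever its own track at the
  8 μm gate), and no displaced vertex may drift into the edge guard
  band (it would be censored). The neighbour set is chosen exactly as
  the analysis will see it — jittered week-1 positions in the reference
  frame, candidates restricted to nuclei that stay inside the expected
  crop box every week.
* **Observation.** Week-w sessions are the surviving truth points mapped
  through that week's similarity transform (defaults: ≤ 3° rotation,
  scale 0.98–1.02, ≤ 15 μm translation, week 1 identity) plus isotropic
  centroid jitter (σ = 0.5 μm), in shuffled row order. Fixed seeds give
  bit-identical outputs.
* **Snapshot.** The human-like cloud (20,000 nuclei in 1 × 1 × 0.5 mm)
  plants a 2% subpopulation in locally rarefied neighbourhoods: every
  nucleus within ρ = (1 + 80/100)·median(d₃) of a planted centre is
  pushed into a thin shell just beyond ρ, preserving the total count;
  intruding pushed points from partially overlapping holes are
  re-cleared in up to three passes. 9.3% of planted neurons carry a
  tangle (so ~90.7% of enlarged neurons are tangle-negative); the
  background tangle fraction defaults to 10%, a plausible cortical
  figure not otherwise pinned. Hard box edges inflate d₃ at corners,
  producing ~0.3% real boundary false positives at the 0.60 cutoff;
  recovery of the planted fraction is therefore asserted in the
  1.5–2.5% band rather than at Monte-Carlo precision.
* **Voxel fixtures.** `render_stack` draws one Gaussian blob per nucleus
  (σ = 1.5 μm) into a (z, y, x) stack at the native pitch; it feeds the
  blob detector and the 100-voxel tangle-object filter in tests. No
  photon noise, PSF anisotropy or vasculature is modelled.

### What passing tests do and do not show

Round-trip recovery on this generator demonstrates that the pipeline is
internally consistent — it recovers exactly the effects it assumes, at
the study's scale and noise. Real data add segmentation errors,
non-rigid tissue deformation, uneven labelling, and nuclei entering or
leaving the field; none of these are modelled, so recovery rates here
are upper bounds on real-data performance.

## Numerical choices and edge cases

* Degenerate fiducials (n < 3 or collinear) raise an explicit error;
  coplanar sets are allowed (scale and rotation remain determined).
* Coplanar tetrahedron vertices give volume 0 with a warning; a zero
  baseline volume raises on percent change.
* k-NN ties are broken by neuron id for determinism; the mutual-NN
  matching is deterministic by construction.
* Session CSVs carry per-session row order; fiducial correspondence
  follows the shared landmark ids (the hand-curated stable-ID subset),
  and all sessions must flag the same fiducial ids.
* Loss percentages are reported unrounded; display rounding (one
  decimal, two for sub-1% fractions) is applied at the reporting layer.
* Problem sizes in the recovery suite — 20 seeds at n = 1500 for
  hazards/ramp/hazard-ratio, 10 seeds over 8 weeks for the change
  point, 3 snapshots of 20,000 nuclei — keep the full suite to a few
  minutes while holding Monte-Carlo standard errors a factor ≥ 3 below
  the planted effects.

## Known limitations

* The ambiguous-fate rule is a design choice; the original workflow
  resolved such cases by eye, and no published rule exists to match.
* The weekly hazard-ratio aggregation behind a published 3.59 ± 1.05
  (per mouse? SE across what?) is unstated; both implemented variants
  are reported instead, and the cumulative 4.53 is the reproducible
  desk quantity.
* Whether the 100 μm normalisation radius is inclusive is unstated; we
  use ≤. Whether dying-vs-persistent d₃ was pooled or averaged per
  animal first is ambiguous; the pipeline emits per-group values so
  either reduction can be formed.
* The generator's dying neurons are placed by hazard weighting, not by
  any modelled biology of selective vulnerability; the spatial
  distribution of death (clustered vs random) is otherwise random.
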