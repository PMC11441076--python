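# neurofate

Longitudinal neuron-fate analysis on 3D nucleus point clouds from weekly
in-vivo two-photon imaging of tau-transgenic mouse cortex, plus the
single-snapshot analogue for cleared human tissue.

## The problem

In tauopathy models (rTg4510, ThyTau22) and in Alzheimer's disease,
neuronal loss far outstrips neurofibrillary-tangle counts. Deciding
whether tangle-bearing neurons actually die faster requires following
*individual* neurons across weeks: registering each week's imaged field
into a common frame, linking nuclei across sessions, calling
disappearances, and relating fate to tangle status and to the local
cortical microstructure. This package implements that pipeline for
centroid tables (one row per nucleus: x, y, z in μm, tangle flag,
fiducial flag), together with a synthetic-data generator that emulates
the imaging data so every stage is testable without any download.

## What it computes

* **Registration** — the similarity transform (uniform scale *s*,
  rotation *R*, translation *t*) minimising
  ∑ᵢ ‖s·R·pᵢ + t − qᵢ‖² over paired fiducial nuclei (closed-form
  absolute orientation, reflections excluded), followed by cropping of
  all sessions to their common overlap.
* **Tracking** — mutual-nearest-neighbour linking under a hard gate
  (default 8 μm); a disappearance is called only when absence persists
  through the final session; transiently invisible or boundary-zone
  tracks are censored as ambiguous.
* **Tangle status** — a track is tangle-bearing from the first week a
  tangle object (connected component ≥ 100 voxels ≈ 49 μm³) lies within
  the association radius; ever-tangled = initially tangled + new onsets.
* **Microstructure** — d₃, the mean distance to a neuron's 3 nearest
  neighbours; the local enlargement ratio
  d₃ / mean{d₃ of all neurons within 100 μm} − 1 with neurons above the
  strict 0.60 cutoff flagged; and the tetrahedron volume spanned by a
  neuron's 4 nearest persistently-present neighbours, whose percent
  change over the 2 weeks before disappearance is the longitudinal
  statistic. An isotropic volume change of v% is equivalent to a
  distance increase of d·((1 + v/100)^⅓ − 1).
* **Survival summaries** — grouped died/survived tables, per-week loss
  on the at-risk population, cumulative and weekly hazard-ratio
  variants, and the Pearson 2×2 chi-square (no continuity correction).

## Worked example

```python
import neurofate as nf

# simulate one imaged field: ~1500 nuclei, 4 weekly sessions,
# 3.6%/week death for non-tangle neurons, 1%/week with a tangle
sessions, truth = nf.simulate_longitudinal(nf.SimulationConfig(seed=0))

registered, transforms, reports = nf.register_sessions(sessions)
print(f"week-2 registration RMS: {reports[1].rms_um:.2f} um")
cropped = nf.crop_to_overlap(registered)
tracks = nf.build_tracks(cropped, gate_um=8.0)

table = nf.FateTable.from_tracks(tracks)
for label in ("non-tangle", "tangle"):
    print(label, f"{nf.loss_fraction(table, label):.1f}% lost")
print("weekly hazard ratio:",
      round(nf.hazard_ratio(table, "non-tangle", "tangle")["weekly"], 2))
```

prints (seed 0):

```
week-2 registration RMS: 1.05 um
non-tangle 10.5% lost
tangle 1.6% lost
weekly hazard ratio: 6.97
```

The registration residual is at the 1–2 voxel level; the non-tangle
group loses ~10% of neurons over three inter-session intervals (the
geometric expectation for a 3.6% weekly hazard), while the
tangle-bearing group — protected in this simulation as in the published
counts — loses far fewer. A single field's tangle group is small
(~110 neurons), so its per-seed hazard ratio is noisy; the 20-seed
recovery test pins the pooled value near the planted ratio.

The published fate counts ship in `neurofate.datasets`, and
`neurofate.reference_report()` reproduces the printed worked-example
numbers from them (chi-square 17.8 with df 1; loss fractions 10.3%,
2.6%, 11.6%, 0.5%, 2.8%, 0.1%; cumulative hazard ratio 4.53; 128 + 107 =
235 ever-tangled; 49 μm³ tangle cutoff; 2.2 μm distance equivalent).

A `neurofate` command exposes the stages
(`simulate`, `register`, `track`, `micro`, `survive`, `report`,
`run-all`) on CSV/JSON/YAML files.

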