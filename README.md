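# geotax

Automated analysis of the *Drosophila* negative-geotaxis (climbing) assay.

In this assay, vials of flies are mechanically tapped to the bottom and
filmed while they climb; the recording holds four tap-and-pause cycles
(60 fps, 1280x720, 12 vials side by side against a white background).
`geotax` turns such a recording — or a fully synthetic equivalent with
exact ground truth — into time-resolved locomotor metrics and statistics:

1. **Trial splitting** (`geotax.trialsplit`) — per-frame motion energy
   (summed areas of moving foreground regions ≥ 2,000 px²) spikes above
   100,000 movement units at each tap; each trial starts at the first frame
   below the 30,000-unit inactivity threshold and runs to the end of the
   first ≥ 270-frame inactivity run, capped at 900 frames (15 s).
2. **Vial detection** (`geotax.vialdetect`) — a deterministic rule-based
   detector (column-intensity profiling) or any plugged-in learned backend;
   detections are confidence-filtered (≥ 0.85), sorted left-to-right and
   matched to the `geotaxis_metadata.csv` vial numbers; IoU evaluation
   against ground truth is built in.
3. **Fly tracking** (`geotax.flytrack`) — per-trim background = per-pixel
   maximum of the red channel over all frames; flies are the connected
   components of the thresholded background deficit; each centroid is
   assigned a vial and a low/middle/high-performer zone; heights convert to
   cm via `Y_cm = 17 · adj / 720` and frames to seconds via `t = frame/fps`.
   The first 780 frames of each trim are tracked and subsampled every 30
   frames (2 Hz).
4. **Aggregation** (`geotax.aggregate`) — sex-split wide tables (rows =
   replicates `Genotype_repN`, columns = seconds) for position, velocity
   (`np.gradient` of height vs. time), and LP/MP/HP occupancy.
5. **Statistics** (`geotax.geostats`) — per sex and modality a linear
   mixed-effects model fitted by REML,

   `y_ijt = β0 + β_geno + β_time + β_geno×time + b_j + b_j1·t + ε_ijt`,

   with categorical time, treatment-coded genotype, and a per-subject random
   intercept and slope; Wald p-values for the genotype main effect and all
   genotype×time interactions are combined per comparison with the harmonic
   mean p-value `HMP = min(1, r / Σ 1/(p_i+ε))`, starred as
   `***  p ≤ 0.001, ** p ≤ 0.01, * p ≤ 0.05, NS`.  Mann–Whitney U tests run
   per time point (rendered as −log10(p) heatmaps) and on per-replicate
   peak values.

A synthetic-scene generator (`geotax.synthgen`) renders the whole assay —
vial holder, climbing/stalling/slipping flies, tap bursts — with
bit-deterministic ground truth, so every stage is testable without any
recordings.

## Worked example

Build a two-recording synthetic experiment in which the `clkout` line
climbs at the same instantaneous speed as the `w1118` control but slips
back to the vial bottom more often from mid-assay on, then analyse it:

```sh
geotax synth exp --seed 1 --folders 2 --scale 0.25
geotax run exp --seed 1 --control w1118 --compare clkout --tmax 13
```

This populates each recording folder with trim segmentations, vial CSVs and
summary tables, writes the ten modality tables under `exp/Output Males` and
`exp/Output Females`, and prints/saves the comparison statistics under
`exp/Stats` (`pvalues_M.json`, figure panels).  For the run above the male
table reads:

| metric | w1118 vs clkout |
| --- | --- |
| position_LME | 0.0013 (**) |
| velocity_LME | 0.2961 (NS) |
| position_Peak | 0.3095 (NS) |
| velocity_Peak | 0.1797 (NS) |

i.e. the mutant's *sustained height* trajectory is highly significantly
impaired while its *instantaneous climbing velocity* is statistically
indistinguishable from control — the dissociation expected when endurance,
not motor speed, is compromised.

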