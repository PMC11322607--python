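# tumotrack

Quantitative analysis of T-cell attack on matrix-embedded tumoroids from
multi-channel 3D time-lapse fluorescence microscopy — with a ground-truthed
synthetic assay generator so the whole pipeline is testable without raw
imaging data.

The package targets the common co-culture cytotoxicity design: a roughly
spherical tumoroid (nuclei stained Hoechst-like, blue) embedded in a
collagen gel, T-cells (CMFDA-like, green) added on top, cell death read out
by propidium iodide (PI, red). Confocal z-stacks (10 µm z-step) are captured
hourly for ~72 h. From such stacks the library computes:

* **Whole-tumoroid killing fraction** — per z-plane, nuclei and PI objects
  are segmented, PI signal is related to nuclei (a nucleus is dead iff a PI
  centroid falls on its footprint; stray PI is discarded), and the
  stack-wide fraction Σ dead / Σ nuclei is reported per timepoint, with
  optional normalization to a cisplatin-like positive control.
* **In-tumoroid T-cell count** — a tumoroid boundary mask is built from the
  nuclei channel; T-cells whose centroid falls inside it are summed over
  all z-sections.
* **3D T-cell trajectories** — per timepoint, the T-cell channel volume is
  thresholded and connected components with a single-cell volume
  (280 µm³ < V < 10,000 µm³, strict) are reduced to intensity-weighted 3D
  centers of mass; consecutive frames are linked by globally optimal
  (Hungarian) gated assignment.
* **Motility model** — per trajectory the time-averaged mean squared
  displacement is fitted to directed-plus-diffusive motion,

  ```
  msd(t_lag) = 4 D t_lag + v² t_lag²
  ```

  giving a diffusion constant D (µm²/h) and persistent speed v (µm/h), and
  the diffusive fraction at a fixed lag t_D = 10 h,

  ```
  f_D = 1 / (1 + v² t_D / (4 D))
  ```

  which is ≈1 for random motility and →0 when directed motion dominates.
  Populations are summarized by median ± SD and compared with
  Kruskal–Wallis plus Dunn's post hoc; killing dose–responses with two-way
  ANOVA plus Bonferroni-adjusted comparisons against a reference condition.

The synthetic module generates the whole assay in silico — packed tumoroid
nuclei, T-cells entering from the top of the gel, an initial random-walk
phase, a contact-triggered recruitment wave, contact killing with delayed
PI onset, and rendering into calibrated OME-TIFF stacks — with full ground
truth (true positions, trajectories and death times), so every stage can be
validated quantitatively.

## Worked example

`examples/track_and_fit_motility.py` simulates a purely diffusive T-cell
population and one drifting toward a distant tumoroid, fits the MSD model
per cell and compares diffusive fractions:

```
diffusive  median D = 2.46 um2/h, median v = 0.00 um/h, median f_D(10 h) = 1.000  (n = 80)
directed   median D = 1.59 um2/h, median v = 2.95 um/h, median f_D(10 h) = 0.068  (n = 80)

Kruskal-Wallis on f_D: H = 123.3, p = 1.21e-28
```

The diffusive population was generated with a per-axis diffusion
coefficient of 2 µm²/h — because the model applies the 2D-form coefficient
4 D to 3D displacements, a pure random walk is recovered as
D = 1.5 · d_axis ≈ 3 µm²/h (median 2.46 here reflects the small downward
bias of the unweighted fit). The directed population was generated with
v = 3 µm/h and is recovered at 2.95 µm/h with f_D near 0; the two f_D
distributions separate decisively.

`examples/simulate_and_quantify.py` runs the full image pipeline on an
effective-bsAb-like scenario and prints the killing/recruitment time
courses (T-cell count peaks and declines while killing saturates), and
`examples/compare_killing_groups.py` shows the dose–response statistics.

A thin CLI mirrors the stages for shell use:

```
tumotrack simulate --out scene --seed 1
tumotrack run --stack scene/stack.ome.tif --out results
tumotrack track --stack scene/stack.ome.tif --out traj.csv
tumotrack motility --trajectories traj.csv --max-lag 25 --td 10
```

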