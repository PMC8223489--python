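# Methods

This note documents the models, conventions and design choices behind
`hexpaint`: what each stage computes, which parameters matter, what the
simulator does and does not emulate, and the known limitations.

## Units and conventions

Localization coordinates are kept in **camera pixels** end to end; the
pixel size (`camera_pixel_nm`, default 87 nm) travels in the table metadata
and conversions to nanometres happen only at analysis boundaries (site
coordinates, NND statistics). This keeps the quality thresholds, which are
naturally pixel-denominated (e.g. precision > 0.03 px), exact. Frames are
0-based; coordinates refer to pixel centres; the field of view is the
half-open square `[0, width) × [0, height)` px. Ellipticity is the
minor/major ratio of the fitted spot widths, in (0, 1]; low values mean
asymmetric, suspect fits. The per-row `precision` column is treated as an
opaque quality number — no particular estimator (NeNA, Mortensen, ...) is
assumed.

## Design registry

Each pattern is modelled as a **regular hexagon**: six sites at the
vertices, circumradius equal to the edge length. The registered edge is the
nominal mean nucleotide-to-nucleotide distance of the six edges as realized
on the origami; per-edge deviations of the folded structure are not
modelled, since regularity is the design intent and only the mean is
specified. Rendering oversampling factors are bound to designs by size
class (37 and 26 nm → 60×, 19 nm → 100×, 16 and 9–11 nm → 120×, ~6 nm →
150×), so the super-resolution bin (87 nm / oversampling ≈ 0.6–1.5 nm) is
always several times smaller than the site spacing being resolved.

## Simulator

`paint_sim` generates localization tables with per-row ground truth, at
frame resolution (no sub-frame photophysics, no raw camera frames, no 3D):

* **Scene**: structure centres uniform in a margin-inset field of view with
  a minimum separation (default 500 nm, rejection-sampled), i.i.d. uniform
  rotations. Each of the six sites is independently present with
  probability `occupancy` — the quantity the pipeline must recover.
* **Kinetics**: a present site alternates between exponential dark periods
  with rate `dark_rate_per_nM_per_s × imager_conc_nM` and geometric bright
  runs with mean `mean_bright_frames`. Defaults (10 nM imager, on-rate
  coefficient 1e-3 /nM/s ≙ k_on = 1e6 /M/s, 2.5 bright frames at 300 ms)
  give a steady-state bright fraction ρ ≈ 0.0074, i.e. ≈ 89 localizations
  per site over 12000 frames — a typical DNA-PAINT budget. The measured
  bright/dark times of the actual imager/docking pair are not published;
  these are free parameters of the config, and all recovery benchmarks
  state them explicitly.
* **Noise**: each bright frame yields one localization at the site position
  plus isotropic Gaussian noise `loc_precision_nm`; photons are normal
  (mean 3000, SD 800, clipped at 1); fitted widths jitter around 1.3 px;
  `precision` is synthesized with σ/√photons scaling. Background
  localizations are homogeneous Poisson in space-time; a configurable
  fraction of them can be made strongly elliptical ("asymmetric junk") to
  exercise the ellipticity filter. Fiducials emit every frame at high
  photon counts. Linear drift is added cumulatively to all positions.
* **High-SNR benchmarking regime** (`high_snr_params()`): 1 nm precision,
  full occupancy unless stated, zero background/drift/fiducials. DNA-PAINT
  routinely resolves < 5 nm; this regime isolates pipeline bias from
  photophysics, which is the point of the recovery benchmarks.

What the simulator does **not** emulate: sub-frame blinking and photon
integration, PSF/EMCCD noise (localizations are drawn, not fitted),
structure deformation on surface landing, steric blocking of docking sites,
and double-binding events beyond the photon-count proxy. Passing recovery
tests therefore demonstrate that the *analysis* is unbiased under its
stated noise model, not that experimental occupancies are unbiased —
on real data, surface deformation shrinks large patterns and steric
blocking suppresses apparent occupancy.

## Quality filtering

The three rules (precision > 0.03 px; ellipticity < 0.1; photons > mean +
2·SD with the sample SD, ddof = 1) are applied **simultaneously**: the
photon statistics are computed on the full input table before any row is
removed, and a row is dropped if it trips any rule. Survivors keep their
order and values. The report records per-rule counts and the photon
statistics used, so re-running with frozen statistics is idempotent.
Fiducial localizations can be excluded with a radius mask around declared
or picked positions.

## Drift correction (RCC)

The acquisition is cut into fragments of `segment_frames` (default 200)
frames; each fragment is rendered at 4× oversampling and lightly smoothed
(σ = 1 bin) to stabilize the correlation of sparse count histograms. All
fragment *pairs* are cross-correlated via FFT; each correlation peak is
refined to sub-pixel by an intensity-weighted centroid over its 3×3
neighbourhood. The redundant set of pairwise offsets `d_j − d_i` is solved
in least squares for one offset per fragment, evaluated at fragment
mid-times, linearly interpolated (and extrapolated) per frame, and
gauge-fixed to zero mean. Correction subtracts the trace; applying the
negated trace restores the input exactly. On the simulated scenes the null
trace stays below ~0.05 px and an injected 24 px end-to-end linear drift is
recovered to ~1%. A second estimate/apply pass restricted to ROI members
is available as an optional refinement stage.

## Structure detection

The filtered table is rendered at 20× (bins of 4.35 nm at 87 nm pixels),
binarized at count ≥ 1, closed with a 3×3 structuring element to bridge
single-pixel gaps, and segmented into 8-connected components. Because a
high-precision sub-resolution pattern can render as up to six disjoint
one-pixel blobs, component centroids closer than one ROI half-width are
merged (localization-count weighted) before ROIs are created — without
this, one structure yields several coincident ROIs. Each final centre gets
a square ROI of half-width 1.5 px (≈ 130 nm, comfortably holding the
largest 37 nm pattern), echoing the 1.5-px pick-region scale of interactive
workflows.

Noise rejection uses two QC criteria, surfaced in `RoiParams`:

* **temporal span** ≥ 0.5 × n_frames (default): genuine docking sites
  blink throughout the acquisition; transient stickers do not;
* **member count** within `[min_locs, max_locs]`. When an expected
  localization budget is known, `default_roi_params` sets the lower bound
  to 0.2× the expected count of a *single* site and the upper bound to 5×
  a fully occupied structure. Scaling the lower bound per-site rather than
  per-structure matters at partial occupancy: a structure carrying one
  peptide is a genuine detection, and rejecting it would condition the
  occupancy estimate upward.

## Site calling

Per ROI: render members at the design oversampling; normalize to [0, 1];
Gaussian-smooth with σ = 1 super-resolution pixel (so physical smoothing
scales with the oversampling class); find strict 8-neighbourhood local
maxima at ≥ 0.2 of the smoothed maximum; refine each to sub-pixel with a
3×3 intensity-weighted centroid (the bin at 150× is 0.58 nm, so refinement
keeps quantization well under the localization noise); merge maxima closer
than 0.5× the designed edge into intensity-weighted centroids (iteratively,
closest pair first, until no violation remains); then keep one cluster.

**Cluster selection.** Surviving maxima are single-linkage clustered and
the most populous cluster is kept, ties broken by centroid proximity to
the ROI centre (count-first was chosen over centrality-first; the tie-break
covers the ambiguous cases). The linkage cutoff is 2.1× the design edge:
a hexagon's vertex pairs lie at 1×, √3× and 2× the edge, so any subset of
a *partially occupied* hexagon stays one cluster only if the cutoff exceeds
2× the edge. Enumerating all 2⁶ occupancy patterns shows that a smaller
cutoff (e.g. 1.5×) splits alternate-vertex patterns and biases the expected
kept-site fraction at true occupancy 0.5 from 0.50 down to 0.44; with
structures ≥ 500 nm apart the larger cutoff still rejects strays from
neighbouring structures.

Counts above six (spurious splits) are kept in the histogram but capped at
six for the occupancy estimate, which is defined against the six designed
protrusions: `occupancy = mean(min(n_sites, 6)) / 6`. The mean NND per ROI
is the mean over detected sites of the distance to the nearest other site;
it requires ≥ 2 sites and is flagged undefined otherwise.

## Numerical behaviour and benchmark scales

All stochastic benchmarks run the full pipeline on simulated scenes of
120 structures with the full 12000-frame budget (a few seconds per scene),
and seeds are fixed everywhere. At full occupancy the recovered mean NND
sits 0.7–4.2% **below** the design edge depending on size (W37 −0.7%, W6
−4.2%): smoothing of partially overlapping site blobs pulls adjacent maxima
toward each other, and the pull grows as the edge approaches the effective
blob width (σ ≈ 1.2 nm at 150×). The bias is stable across seeds and stays
within the 5% recovery tolerance for every registered design. Occupancy is
recovered within ±0.03 at 0.5–1.0; the residual error is dominated by
binomial sampling of site presence plus the unavoidable invisibility of
all-empty structures.

## Limitations

* No template-fit hexagon registration and no per-site identity assignment:
  the pipeline counts sites and measures distances, it does not match
  detections to designed positions.
* The detection-stage thresholds (binarization, span fraction, count
  window) are free parameters; the defaults are validated on the simulator
  and should be revisited for experimental data with different kinetics.
* RCC here is a planar, histogram-based implementation; it assumes rigid
  lateral drift and enough structures per fragment to correlate.
* Gel dosimetry takes band intensities as numbers; image-plane band
  selection is out of scope, as are IC50 fits and hypothesis tests.
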