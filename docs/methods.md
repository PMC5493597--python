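# Methods

## Model and assumptions

`micasa` treats a two-channel fluorescence image of a tissue section as
two realizations of spatial random fields on a common pixel grid with a
known physical pixel size. The quantities of interest are second-order:
the power spectrum of each channel (structure of one cell population at
each spatial scale) and the magnitude coherence between channels
(scale-resolved association of the two populations). Both are assumed
approximately stationary and isotropic at the scales analysed — the
justification for summarizing 2D spectra by their circular average.
Absolute staining intensity is treated as arbitrary: images are
converted to floating point and mean-subtracted, but not otherwise
normalized, so log-spectra are offset by overall gain while confidence
intervals and between-condition comparisons (within a jointly processed
experiment) compare like with like.

## Multitaper estimation

Direct periodograms of a single image are inconsistent estimators with
heavy leakage. The multitaper approach windows the image with M
orthonormal tapers that maximise spectral concentration in a
half-bandwidth W, yielding M quasi-independent spectral estimates from
one image; with N images this gives NM estimates per channel.

2D tapers are built as outer products of the 1D discrete prolate
spheroidal sequences (DPSS) of each dimension, ranked by the product of
their 1D concentration eigenvalues, ties broken lexicographically on the
index pair. This separable construction is the standard extension of
the 1D theory to rectangular images; true 2D prolate functions on a disk
are not used. Defaults: time-bandwidth product NW = 2 per dimension,
giving ceil(2·NW) − 1 = 3 concentrated sequences per axis, 9 candidate
products, of which the leading **M = 7** are retained — enough degrees
of freedom for stable intervals without excessive spectral smoothing.
The half-bandwidth in physical units is NW/(n·px) cycles/µm for an
n-pixel side; larger NW smooths over a wider frequency band.

Each channel is mean-subtracted, multiplied by each taper, and
transformed with the unnormalized forward 2D FFT. Per estimate, the
log-spectrum is `log(|J|² + ε)` with ε the smallest positive double —
a floor that only exactly-zero bins feel. The coherence is pooled over
all NM estimates before normalization,

    C(k) = |Σ J_a conj(J_b)| / sqrt(Σ|J_a|² · Σ|J_b|²),

because the normalized cross-spectrum of a *single* tapered estimate is
identically 1; `atanh` is applied after capping C at 1 − 10⁻⁶ (atanh
diverges at 1; the cap is reached only by self-coherent inputs). No
asymptotic variance-stabilizing scaling is applied inside the atanh —
uncertainty comes from the jackknife, not from an asymptotic normal
approximation. The log/atanh transforms are applied *per estimate*
(before averaging over estimates), so the spread of the NM transformed
estimates is what the downstream intervals and variance curves measure.

## Circular averaging and the radial grid

Each 2D field is reduced to a function of radial frequency
f = |**k**| on a log-spaced grid of (by default) **60 bins** from the
image fundamental 1/(longest side in µm) to the pixel Nyquist
1/(2·px). Bin values are unweighted means of all 2D frequencies whose
radius falls in the bin; empty bins are masked. Sixty bins resolve
structure from cellular (~4 µm at 2 µm/px) to organ scales on
millimetre-sized sections without empty interior bins.

Two exclusions apply everywhere:

- the **DC bin** (the mean is removed anyway);
- all frequencies with radius at or below the tapers' **DC concentration
  lobe**, NW/(min side·px). The tapered transform of the (positive)
  image mean leaks its energy into exactly this region, so values there
  cannot be distinguished from the mean level; for bright-field-like
  nonnegative images this leakage otherwise dominates every
  low-frequency bin.

Averaging order: each of the NM 2D estimates is circularly averaged *on
its image's native frequency grid*, and the resulting 1D curves are then
linearly interpolated in log-frequency onto one shared grid (the
intersection of the per-image bands when sections differ in size);
out-of-range bins are masked, never extrapolated. Averaging first avoids
2D resampling artifacts. A curve's frequency f is labelled with the
length scale 1/f µm in all outputs.

## Jackknife intervals and the choice of resampling unit

Per radial bin, the estimate of a log-spectrum is the mean of the
per-estimate curves; its standard error comes from a delete-one
jackknife with a t-critical value at (units − 1) degrees of freedom. For
the pooled coherence — which has no per-estimate curve — the pooled
statistic is recomputed with each unit deleted, the jackknife SE is
formed from those delete-one curves, and the interval is centred on the
all-in estimate.

**The deletion unit is one image (its whole M-taper block), not one
(image, taper) estimate.** This is the package's key statistical design
choice, and it is deliberate. At a single frequency, coefficients from
different tapers are exactly uncorrelated (the tapers are orthogonal),
and a per-frequency jackknife over all NM estimates would be sound. But
the curves being jackknifed here are *bin averages over many
frequencies*, and tapered coefficients at *nearby* frequencies — within
the taper bandwidth, and for taper pairs sharing a 1D factor, within the
1D bandwidth along one axis — are correlated *across* tapers. Bin
averaging therefore makes the M per-taper curves of one image positively
correlated with each other, and a jackknife that treats all NM curves as
exchangeable underestimates the standard error, producing intervals that
are systematically narrower than their nominal level. Whole images are
independent by design of the experiment, so deleting images respects the
correlation structure and restores nominal coverage — which is exactly
what the acceptance experiment measures. The price is fewer degrees of
freedom (N − 1 instead of NM − 1) and hence wider intervals at small N.

`AnalysisConfig(jackknife_unit="estimate")` restores the NM-unit
jackknife for users who want the larger nominal degrees of freedom and
accept its anticonservatism, and it is used automatically when N = 1,
where the multitaper construction is the only source of replication —
the single-section use case the method's design makes possible at all.
Result objects always record N, M and NM.

## Variance curves

The three variance curves quantify replicate-to-replicate consistency of
organization — the "disorganized versus differently organized"
distinction. Per bin they are the sample variance across the jackknife
unit curves (per-image curves by default): directly for the log-spectra;
via jackknife pseudo-values, `n·all_in − (n−1)·delete_one_i`, for the
coherence. Intervals are chi-square with (units − 1) degrees of freedom,
`[(n−1)s²/χ²_hi, (n−1)s²/χ²_lo]`. The chi-square interval assumes
approximate normality of the unit curves per bin; for strongly skewed
small-sample bins it is approximate, which the comparison logic partly
absorbs by requiring full CI disjointness.

## Comparing conditions

Two results (re-interpolated to a common grid if needed) differ
significantly on a bin when their confidence intervals are disjoint;
maximal runs of such bins are reported as bands with µm endpoints and a
direction. Masked bins never count. Note the inference is per-band CI
non-overlap at the configured level, with no multiple-testing correction
across bins — band *locations* near the detection threshold should be
read qualitatively.

## Synthetic data generators

All tests and the acceptance experiments run on seeded synthetic
conditions; every generator is a pure function of its spec including the
seed, with per-replicate seeds split off a base seed via NumPy seed
sequences.

- **White noise** (i.i.d. Gaussian pixels, default σ = 1): the null
  field whose flat spectrum and known per-bin sampling distribution
  calibrate interval coverage.
- **Blob lattice**: Gaussian-profile blobs (truncated at 3 radii) on a
  square lattice of stated spacing, with optional Gaussian positional
  jitter. Emulates a cell population with a characteristic separation:
  the radial log-spectrum must peak at 1/spacing. The validation
  experiments use jitter = spacing/10 and blob radius = spacing/6 —
  cells are clustered, not crystalline, and the disorder gives the
  spectrum the diffuse isotropic component real tissue has (a perfect
  lattice concentrates the fundamental ring's power in four axis points,
  which the log-then-average order dilutes below the leakage floor).
  Image extent is chosen so the radial bin width at the lowest lattice
  frequency is no narrower than the taper bandwidth — the resolution
  limit for localizing any spectral peak.
- **Compartments**: a Gaussian random field smoothed with a kernel of
  width scale/2, thresholded at the quantile giving the stated fill
  fraction; channel A is bright inside the mask (stain baseline plus
  field excess), channel B outside, supports exactly disjoint. Each
  channel is modulated by independent gamma speckle (mean 1, cv 0.5) —
  the two markers stain *different cells*, so fine-scale texture is
  channel-private while compartment structure is shared. Consequently
  the coherence peaks near the compartment scale and decays at cellular
  scales, which is what makes a compartment-scale shift detectable as a
  coherence band shift. `replicate_variability` rescales the scale per
  replicate by a log-normal factor (log-sd equal to the parameter; 0
  gives exactly 1), creating pure variance phenotypes.

What the generators do **not** emulate: microscope point-spread
functions, shot/readout noise models, stitching artifacts, intensity
inhomogeneity across a section, anisotropic tissue architecture, and
partially overlapping marker populations. Passing tests therefore
demonstrate the statistical machinery is calibrated and sensitive on
controlled fields, not that any particular biological effect size is
detectable in real sections.

## Region densities

The region module partitions a section from a medullary-marker channel:
medulla = smoothed (Gaussian, default 20 µm) Otsu-thresholded marker
with specks under 400 µm² removed; CMJ = band within 100 µm outside the
medulla (Euclidean distance transform); subcapsular = band within 100 µm
inside the tissue perimeter; cortex = remainder. Where the CMJ and
subcapsular bands would overlap in thin tissue the CMJ wins; the four
masks are pairwise disjoint and tile the tissue mask (Otsu of the summed
channels, hole-filled). Marker-positive objects are simple
threshold-plus-connected-components detections with a minimum area,
assigned to regions by centroid; densities are counts per µm², reported
as missing (not a division error) for zero-area regions. The detector is
a deliberately plain stand-in for dedicated cell-segmentation software;
the region logic, not the detector, is the point.

## Validation experiment sizes

The packaged experiments (`micasa.validation`) use: coverage — 200
replicates of N=3 white-noise pairs at 128×128 with a 10,000-estimate
oracle for the population mean, scored on interior bins (≥ 16 native
frequencies; sparser bins measure small-sample skewness of log-power
rather than the interval); null comparison — 12 same-generator
compartment condition pairs at 192×192, scale 100 µm; peak recovery —
spacings 20/40/80 µm on 768×768 images; phenotype detection — scales
200 vs 320 µm at 512×512 with nine sections per condition (three
sections from each of three animals is a typical design), and
replicate variability 0 vs 0.5 with four sections. These sizes give
each experiment comfortable statistical power while keeping a full run
in the minutes range on one core.

## Known limitations

- Isotropy is assumed; angular structure is averaged away by design.
- The chi-square variance intervals and the t-intervals inherit
  approximate normality of per-unit bin averages; lowest-frequency bins
  (few averaged frequencies) are the least normal.
- With the default image-unit jackknife, N = 2 yields extremely wide
  (1 degree of freedom) intervals; N ≥ 3 is the practical minimum, and
  the N = 1 fallback's estimate-unit intervals are anticonservative for
  bin-averaged curves (see above).
- Coherence pooling across sections of different pixel dimensions is
  done per shape group and combined on the shared grid weighted by
  estimate count; with many distinct shapes and few images per shape the
  group pooling loses efficiency.
- No multiple-testing correction across frequency bins.
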