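# Methods

`axonloc` re-implements, as a tested library, the quantitative analyses
used to study RNA-binding-protein-dependent mRNA localization to axons of
*Drosophila* mushroom-body (MB) γ neurons: smFISH spot quantification with
compartment enrichment ratios, iCLIP metatranscript profiling and 3′UTR
crosslink quantification, multi-assay target gating, GO-term
deduplication, and courtship-memory indices. Every stage can be exercised
on synthetic data with known ground truth; this note records the models,
parameter choices and their limits.

## Synthetic lobe stacks (`axonloc.simulate`)

The MB γ lobe is modelled as a straight cylinder along the x axis
(proximal end at x = 0), not the curved lobe of a real brain: downstream
analysis only requires a monotone proximal→distal axial coordinate, and a
straight tube is the simplest geometry satisfying that assumption. Voxel
sizes default to the acquisition geometry (0.07 μm laterally, 0.25 μm z
step).

Spots are a homogeneous Poisson point process with separate intensities
(spots/μm³) in the proximal two thirds and distal third of the lobe;
positions are uniform within each segment and spots whose containing
voxel falls outside the voxelized lobe mask are rejected, so ground-truth
containment is exact at voxel resolution. Setting `min_separation > 0`
thins the process to a hard-core process, modelling a field of
individually resolvable molecules. Each spot is rendered as an
anisotropic Gaussian (σ from the detector's 0.4 μm xy / 0.8 μm z FWHMs by
default) of constant amplitude on a constant background with additive
Gaussian read noise; Poisson shot noise is off by default
(`shot_noise=True` enables it). The reference channel is the smoothed
lobe mask plus mild noise.

What this emulates — compartment-dependent spot densities, anisotropic
PSF, realistic voxel anisotropy, noise-limited detection. What it does
not — intensity variability between molecules, autofluorescent
structures, lobe curvature, optical aberrations, bleed-through. Passing
tests therefore validate the geometry and statistics of the
quantification, not robustness to real-tissue artefacts. No
signal-to-noise characterization of real stacks was available; the
default amplitude 300 / noise SD 10 was chosen to place single spots far
above the detection floor, and detector stress tests lower the amplitude
to SNR 5 explicitly.

One integer seed drives each generator; per-component sub-streams are
spawned deterministically, so outputs are byte-identical for a fixed
seed.

## Spot detection (`axonloc.spots`)

Spots are detected with a Laplacian-of-Gaussian (LoG) band-pass filter
whose per-axis scales derive from the expected spot size, treating the
stated diameters as FWHM: σ = FWHM/2.355, i.e. σ_xy = 0.4/2.355 μm and
σ_z = 0.8/2.355 μm, converted to voxels through the voxel sizes. The
small-particle detector used for 2D cell-body crops is an external,
unpublished-in-detail algorithm; only its component-size cutoff (4 px)
and per-probe thresholds (0.62 default; 0.42, 0.32, 0.82 for specific
probes) are public, so any band-pass detector honouring those constants
is a faithful stand-in.

Two numerical choices matter:

- **Response normalization.** Thresholds in (0, 1) require a per-image
  response unit. Dividing by the raw image-wide maximum response is
  fragile: a single pair of overlapping spots doubles the maximum and
  silently halves every other spot's normalized response, and a blank
  image normalizes pure noise to 1.0. Instead the response is divided by
  the *median response of candidate local maxima above an absolute noise
  floor*. With spots of a common amplitude this median is the response of
  a typical isolated spot, making the printed thresholds meaningful
  fractions of a single-molecule response; on a blank image there are no
  candidates and no spots are returned. Reported responses are clipped to
  [0, 1].
- **Noise floor.** The floor is `noise_floor_sigma` (default 8) robust
  standard deviations of the response, estimated by the median absolute
  deviation. The LoG response of Gaussian noise is Gaussian, and the
  maximum over ~10⁷ voxels sits near 6σ, so 8σ suppresses false maxima on
  signal-free images while single spots at SNR 5 respond at ≳20σ.

2D detection thresholds the normalized response, discards connected
components smaller than `min_component_px` (default 4) and reports one
spot per surviving component at its response-weighted centroid. 3D
detection reports local maxima (anisotropic footprint of ~1σ per axis)
above both the relative threshold and the floor; plateau ties break to
the lowest (z, y, x) index. Positions are voxel centers in μm — voxel
index i maps to (i + 0.5)·voxel size — so positions re-bin exactly to
their source voxel. No sub-voxel fitting is attempted; the localization
error is bounded by half a voxel per axis (≤ 0.125 μm in z), well inside
the 0.3 μm matching radius used in recovery tests.

Contrast rescaling maps [min, q] linearly to [0, 1], where q is the
(1 − saturation_fraction) quantile (default 10⁻⁴, i.e. 0.01% of pixels
saturated); constant images pass through unchanged with a warning.

## Lobe segmentation and compartments

The reference channel is Gaussian-smoothed at the surface-detail scale
(0.146 μm), thresholded automatically by Otsu's method, reduced to its
largest connected component and hole-filled. The axial coordinate s of
each mask voxel is its projection onto the mask's first principal axis
(PCA of voxel-center coordinates), min–max normalized to [0, 1] and
oriented so a user-supplied proximal anchor maps near 0. A principal
axis, rather than a skeleton, is used because the modelled lobe is
tubular; for strongly curved lobes PCA would compress the axial
coordinate and a centerline estimator should replace it.

Axonal spots are in-lobe spots with s ≥ 1/3 (the distal two thirds);
samples with fewer than 10 axonal spots are flagged excluded. For the
compartment enrichment ratio the lobe is split at s = 2/3 into the distal
γ5 compartment and the proximal γ2–4 remainder; spot counts are divided
by the corresponding voxel volumes and the ratio is distal density over
proximal density. A zero proximal count leaves the ratio undefined
(flagged with a reason) rather than infinite. Counts and volumes
partition exactly: n_γ5 + n_γ2-4 equals the in-region spot count and the
two compartment volumes sum to the lobe volume.

Normalization of per-sample axonal counts divides each sample by the
mean count of its replicate batch's control group — a convention chosen
here (the source procedure is unstated) and isolated in
`normalize_counts`.

### Benchmark conditions

The ratio-recovery benchmark plants density ratios {1, 2, 3} in a
120 μm × 3.6 μm lobe at 0.05–0.15 spots/μm³ and asserts the median
recovered ratio over 20 seeds within 15%. These sizes were fixed by a
power analysis of the benchmark itself: with ≳300 spots per stack the
planted (Poisson) ratio of a single stack has a standard deviation of
~0.1·ratio, so a 20-seed median resolves a 15% band with several σ of
margin, while at spot densities above ~0.3 spots/μm³ unresolvable
neighbours (closer than roughly the LoG response width, ~0.5 μm laterally
and ~1 μm axially) merge and bias the denser compartment's count
downward. Real axonal smFISH operates at far lower densities — tens to a
few hundred molecules per lobe — so the low-density regime is the
realistic one; the residual merge bias of the benchmark conditions is
~2–3%. The detection recall/precision benchmark (≥ 0.95 at SNR 5) uses a
hard-core process (min_separation 1 μm) because it measures detection,
not resolution of overlapping molecules.

## Metatranscript profiling (`axonloc.metatranscript`)

Internal coordinates are 0-based half-open; GTF (1-based closed) and BED
(0-based half-open) are converted at the boundary. The reference keeps
one transcript per gene: transcripts off the major chromosome arms
(X, Y, MT, 2L, 2R, 3L, 3R), non-coding transcripts and transcripts with
an ambiguous annotation status (`incomplete`/`unknown`, modelled as an
explicit attribute) are dropped, then the longest transcript by summed
exon length wins, ties broken by smallest transcript id. A transcript
whose CDS lies outside its exons is rejected with a warning naming it.

Genomic↔transcript mapping is spliced and strand-aware (position 0 is
the 5′ end on either strand; the two maps are exact inverses). Regions
are half-open: the CDS start base is CDS, the base at CDS end is 3′UTR.
Positions rescale region-wise onto the virtual transcript — 5′UTR to
[0, 19], CDS to [20, 69], 3′UTR to [70, 100] — with the region's first
base at the lower bound and its last base at the upper bound
(meta = lo + p/(Lr − 1)·(hi − lo); a single-base region maps to lo).
The alternative p/Lr convention is rejected because it never attains the
printed upper bounds. Consequently the first CDS base maps to 20, the
first 3′UTR base to 70 and the transcript's last base to 100.

Only transcripts carrying ≥ 20 significant peaks contribute to the
profile. Pooled rescaled positions are smoothed by a Gaussian KDE with
Scott's-rule bandwidth and reflection at 0 and 100, so the density
integrates to 1 over the metatranscript (verified to ±0.01 numerically
on a 0.5-step grid). Peaks are weighted equally rather than by cDNA
support — the source weighting is unstated — and both bandwidth and
weighting are overridable. Interval peaks should be reduced to their
5′-most transcript-strand base before profiling; the profiler treats
peaks as single-nucleotide anchors.

3′UTR quantification sums cDNA counts of crosslinks whose transcript
position falls in the 3′UTR, per gene and sample, then normalizes by
median-of-ratios size factors: for each gene with nonzero counts in all
samples, the ratio of its count to its geometric mean across samples is
formed, and a sample's size factor is the median of these ratios. This is
the size-factor step of standard differential-expression normalization,
implemented directly because only the normalization — not the GLM — is
part of the pipeline. Samples with all-zero counts are an error.

## Target gating (`axonloc.targets`)

All thresholds are applied exactly as printed, with their printed
strictness, and each boundary is pinned by a unit test:

| gate | rule |
| --- | --- |
| expression pre-filter | ≥ 1 nonzero count and CPM > 0.5 in ≥ 3 samples |
| synaptically enriched | log2FC ≥ 0.85 **and** padj < 0.05 |
| synaptically depleted | log2FC ≤ −0.85 **and** padj < 0.05 |
| RIP | log2FC > 1 in *every* comparison |
| iCLIP | ≥ 1 significant peak with ≥ 5 uniquely mapped cDNAs |
| overlap synaptosome arm | log2FC > 0 |

The candidate target set is the triple intersection of the synaptosome,
RIP and iCLIP sets. Differential-expression fitting itself is consumed as
a statistics table, not reproduced.

GO-term deduplication computes the Jaccard distance
d(A,B) = 1 − |A∩B|/|A∪B| between term gene sets and clusters terms by
average-linkage hierarchical clustering cut at 0.5; each cluster reports
the member with the smallest summed distance to the others as
representative. Linkage and cut height are not specified by the source
procedure (which states only the index) and are configurable; average
linkage at 0.5 groups terms sharing a majority of genes while keeping
moderately overlapping terms separate.

## Courtship memory (`axonloc.behavior`)

The courtship index (CI) is the fraction of frames with courting = true
in the half-open scoring window [2.5, 12.5) min, frames assigned by
start time; the recording must cover the window, and the full window is
the denominator (time-alive corrections are not modelled). The memory
index of a trained fly is MI = 1 − CI_trained/mean(CI_naive), unclipped,
so MI ≤ 1 always and negative values mean courting above the naive
average. The synthetic generator draws naive CIs around `naive_mean`
(default 0.6, a typical naive courtship level) and trained CIs around
`naive_mean·(1 − suppression)`, both clipped to [0, 1]; clipping makes
the realized mean MI converge to the planted suppression only when the
noise SD is small relative to the means, which the defaults respect.
Group comparisons (Welch t, Mann–Whitney) are thin wrappers over
standard tests for reporting only.

## Degenerate inputs and tie-breaks

- Constant images: contrast rescaling warns and passes through;
  segmentation raises.
- Blank images/stacks: zero spots (noise floor), not a relative-maximum
  artefact.
- Empty proximal compartment: enrichment ratio flagged undefined.
- Zero-length 5′UTR/3′UTR: position 0 is CDS; degenerate regions never
  receive peaks in the generator.
- Plateau maxima: lowest (z, y, x) index wins.
- Longest-transcript ties: smallest transcript id.
- Both-empty gene sets: Jaccard distance is an error (0/0).

## Problem sizes

Tests run synthetic stacks of 12–50 μm lobes for unit checks and
120 μm lobes for the ratio benchmark (≈ 8·10⁶ voxels, ~300–400 spots per
stack, 20 seeds per planted ratio), 40–100 synthetic genes for
annotation-based checks, and 100-gene/9-target tables over 20 seeds for
overlap recovery — sizes at which every targeted effect is resolvable
with multi-σ margins.

## Known limitations

- The detector does not split merged spots; counts in fields denser than
  ~0.3 spots/μm³ are biased low.
- The axial coordinate assumes a roughly straight lobe (principal axis).
- The per-batch control-mean normalization of axonal counts and the
  Imaris-internal 3D quality threshold are conventions chosen here, each
  isolated behind one parameter/operation.
- The metatranscript KDE bandwidth/weighting and the GO clustering
  linkage/cut are documented defaults, not inferred values.
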