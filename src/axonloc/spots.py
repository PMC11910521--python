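"""smFISH spot detection and compartment-wise quantification.

Diffraction-limited mRNA spots are detected with a normalized
Laplacian-of-Gaussian (LoG) band-pass response whose per-axis scales come
from the expected spot size (0.4 μm lateral diameter, 0.8 μm axial
elongation of the point-spread function, treated as FWHM). The axon-lobe
reference channel is segmented by Gaussian smoothing and automatic (Otsu)
thresholding; an axial coordinate s ∈ [0, 1] (0 = proximal, 1 = distal)
is assigned along the lobe's principal axis. Spots inside the lobe are
counted in the distal 2/3 (axonal spots), and the distal-compartment
enrichment is the ratio of spot densities (spots/μm³) in the distal third
(γ5 compartment) versus the remaining proximal two thirds (γ2–4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from axonloc.stack import ImageStack

FWHM_TO_SIGMA = 1.0 / 2.355  # sigma = FWHM / (2 sqrt(2 ln 2))

#: per-probe detection thresholds for the 2D cell-body pipeline
PROBE_THRESHOLDS = {"default": 0.62, "rpl24-like": 0.42, "eIF4A": 0.32, "bnb": 0.82}


class GeometryError(ValueError):
    """Requested geometry does not fit the image grid."""


class SegmentationError(RuntimeError):
    """Lobe segmentation produced an empty mask."""


@dataclass
class DetectionParams:
    """Spot detection parameters.

    xy_diameter and z_elongation are the expected spot FWHMs in μm;
    response_threshold is a fraction of the image-wide maximum normalized
    LoG response; components smaller than min_component_px pixels are
    discarded (2D); saturation_fraction is the pixel fraction saturated by
    contrast rescaling.
    """

    xy_diameter: float = 0.4
    z_elongation: float = 0.8
    response_threshold: float = 0.62
    min_component_px: int = 4
    saturation_fraction: float = 1e-4
    noise_floor_sigma: float = 8.0  # absolute floor, in robust noise SDs of the response

    def __post_init__(self):
        if self.xy_diameter <= 0 or self.z_elongation <= 0:
            raise ValueError("diameters must be positive")
        if not 0 < self.response_threshold < 1:
            raise ValueError("response_threshold must be in (0, 1)")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")

    @classmethod
    def for_probe(cls, probe: str, **kwargs) -> "DetectionParams":
        thr = PROBE_THRESHOLDS.get(probe, PROBE_THRESHOLDS["default"])
        return cls(response_threshold=thr, **kwargs)

    @property
    def sigma_xy(self) -> float:
        return self.xy_diameter * FWHM_TO_SIGMA

    @property
    def sigma_z(self) -> float:
        return self.z_elongation * FWHM_TO_SIGMA


@dataclass(frozen=True)
class Spot:
    """A detected spot at a μm position with its normalized response."""

    position: tuple[float, float, float]  # (x, y, z) μm
    response: float

    @property
    def x(self):
        return self.position[0]

    @property
    def y(self):
        return self.position[1]

    @property
    def z(self):
        return self.position[2]


def rescale_contrast(image: np.ndarray, saturation_fraction: float = 1e-4) -> np.ndarray:
    """Linearly rescale intensities, saturating the brightest pixel fraction.

    Maps ``[min, q]`` to ``[0, 1]`` where ``q`` is the
    ``1 - saturation_fraction`` quantile; values above ``q`` are clipped to
    1. A constant image is returned unchanged with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo = img.min()
    q = np.quantile(img, 1.0 - saturation_fraction)
    if q == lo:
        warnings.warn("constant image: contrast rescaling is a no-op")
        return img.copy()
    return np.clip((img - lo) / (q - lo), 0.0, 1.0)


def _log_response(image: np.ndarray, sigma) -> np.ndarray:
    """LoG band-pass response with bright spots positive."""
    return -ndimage.gaussian_laplace(np.asarray(image, dtype=np.float32), sigma=sigma)


def _noise_floor(response: np.ndarray, n_sigmas: float) -> float:
    """Absolute response floor from a robust (MAD) noise-SD estimate."""
    flat = response.ravel()
    if flat.size > 500_000:  # subsample for the robust scale estimate
        flat = flat[:: flat.size // 500_000]
    med = np.median(flat)
    mad = np.median(np.abs(flat - med))
    return float(med + n_sigmas * mad / 0.6745)


def _reference_response(response: np.ndarray, maxfilt: np.ndarray, floor: float) -> float:
    """Robust normalization reference: median response of candidate maxima.

    Candidate local maxima above the noise floor are overwhelmingly true
    spots of a common amplitude; their median response is a stable
    per-image unit that, unlike the raw image maximum, is not inflated by
    a single pair of overlapping spots and is undefined (0) on a blank
    image rather than normalizing noise to 1.
    """
    cand = response[(response == maxfilt) & (response >= floor)]
    return float(np.median(cand)) if cand.size else 0.0


def detect_spots_2d(image: np.ndarray, params: DetectionParams | None = None,
                    pixel_size: float = 0.07) -> list[Spot]:
    """Detect spots in a 2D crop (small-particle detection).

    The normalized LoG response is thresholded at
    ``params.response_threshold``; connected components smaller than
    ``params.min_component_px`` pixels are discarded and each surviving
    component yields one spot at its response-weighted centroid.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return []
    sigma = params.sigma_xy / pixel_size
    response = _log_response(img, sigma)
    floor = _noise_floor(response, params.noise_floor_sigma)
    foot = 2 * max(1, round(sigma)) + 1
    maxfilt = ndimage.maximum_filter(response, size=foot, mode="nearest")
    ref = _reference_response(response, maxfilt, floor)
    if ref <= 0:
        return []
    mask = (response >= params.response_threshold * ref) & (response >= floor)
    labels = cc_label(mask, connectivity=2)
    spots = []
    for idx in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == idx)
        if ys.size < params.min_component_px:
            continue
        w = response[ys, xs]
        cy = float(np.average(ys, weights=w))
        cx = float(np.average(xs, weights=w))
        spots.append(Spot(position=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size, 0.0),
                          response=min(1.0, float(w.max()) / ref)))
    spots.sort(key=lambda s: s.position)
    return spots


def detect_spots_3d(stack: ImageStack, channel: str,
                    params: DetectionParams | None = None) -> list[Spot]:
    """Detect spots in a 3D stack with an anisotropic LoG filter.

    Per-axis filter sigmas derive from the stated FWHMs (xy_diameter,
    z_elongation) converted to voxels; local maxima of the normalized
    response above ``response_threshold`` (and above an absolute noise
    floor) are reported at their voxel centers in μm. Ties on plateaus
    are broken by lowest (z, y, x) index.
    """
    params = params or DetectionParams()
    img = stack.channels[channel]
    sigma_vox = (params.sigma_z / stack.voxel_z,
                 params.sigma_xy / stack.voxel_xy,
                 params.sigma_xy / stack.voxel_xy)
    min_depth = int(np.ceil(2 * sigma_vox[0])) + 1
    if img.shape[0] < min_depth:
        raise GeometryError(
            f"stack depth {img.shape[0]} below the filter support; "
            f"need at least {min_depth} z planes"
        )
    response = _log_response(img, sigma_vox)
    floor = _noise_floor(response, params.noise_floor_sigma)
    foot = tuple(2 * max(1, round(s)) + 1 for s in sigma_vox)
    maxfilt = ndimage.maximum_filter(response, size=foot, mode="nearest")
    ref = _reference_response(response, maxfilt, floor)
    if ref <= 0:
        return []
    candidates = ((response >= params.response_threshold * ref)
                  & (response >= floor) & (response == maxfilt))
    labels, n = ndimage.label(candidates)
    zz, yy, xx = np.nonzero(candidates)
    lab = labels[zz, yy, xx]
    order = np.lexsort((xx, yy, zz, lab))  # lowest (z, y, x) wins on plateaus
    lab, zz, yy, xx = lab[order], zz[order], yy[order], xx[order]
    first = np.concatenate([[True], lab[1:] != lab[:-1]])
    spots = []
    for vz, vy, vx in zip(zz[first], yy[first], xx[first]):
        pos = ((vx + 0.5) * stack.voxel_xy, (vy + 0.5) * stack.voxel_xy,
               (vz + 0.5) * stack.voxel_z)
        spots.append(Spot(position=pos,
                          response=min(1.0, float(response[vz, vy, vx]) / ref)))
    spots.sort(key=lambda s: s.position)
    return spots


# ---------------------------------------------------------------------------
# Lobe segmentation and compartments
# ---------------------------------------------------------------------------

@dataclass
class LobeRegion:
    """Segmented axon lobe with a normalized proximal→distal axial coordinate."""

    mask: np.ndarray  # boolean (z, y, x)
    voxel_xy: float
    voxel_z: float
    s: np.ndarray  # per-voxel axial coordinate in [0, 1], NaN outside mask
    axis: np.ndarray  # unit direction, proximal → distal, (x, y, z)
    smoothing_scale: float = 0.146

    @property
    def voxel_volume(self) -> float:
        return self.voxel_xy ** 2 * self.voxel_z

    @property
    def volume(self) -> float:
        """Lobe volume in μm³."""
        return float(self.mask.sum()) * self.voxel_volume

    def _voxels_of(self, spots) -> np.ndarray:
        pos = np.array([s.position for s in spots], dtype=float).reshape(-1, 3)
        iz = np.floor(pos[:, 2] / self.voxel_z).astype(int)
        iy = np.floor(pos[:, 1] / self.voxel_xy).astype(int)
        ix = np.floor(pos[:, 0] / self.voxel_xy).astype(int)
        return np.column_stack([iz, iy, ix])

    def contains(self, spots) -> np.ndarray:
        vox = self._voxels_of(spots)
        nz, ny, nx = self.mask.shape
        ok = ((vox >= 0).all(axis=1) & (vox[:, 0] < nz)
              & (vox[:, 1] < ny) & (vox[:, 2] < nx))
        out = np.zeros(len(spots), dtype=bool)
        v = vox[ok]
        out[ok] = self.mask[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def s_of(self, spots) -> np.ndarray:
        """Axial coordinate of each spot's voxel (NaN outside the mask)."""
        vox = self._voxels_of(spots)
        inside = self.contains(spots)
        out = np.full(len(spots), np.nan)
        v = vox[inside]
        out[inside] = self.s[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def compartment_volume(self, s_lo: float, s_hi: float) -> float:
        """Volume (μm³) of mask voxels with s in [s_lo, s_hi)."""
        sel = self.mask & (self.s >= s_lo) & (self.s < s_hi)
        return float(sel.sum()) * self.voxel_volume


def segment_lobe(stack: ImageStack, channel: str, smoothing_scale: float = 0.146,
                 proximal_anchor=(0.0, 0.0, 0.0)) -> LobeRegion:
    """Segment the lobe from the reference channel and assign axial coordinates.

    The channel is Gaussian-smoothed at ``smoothing_scale`` (μm, the
    surface-detail scale), thresholded automatically (Otsu), the largest
    connected component is retained and holes are filled. The axial
    coordinate s is the projection of voxel centers onto the mask's first
    principal axis, min–max normalized to [0, 1] and oriented so that
    ``proximal_anchor`` (μm) maps near 0.
    """
    img = stack.channels[channel]
    sigma_vox = (smoothing_scale / stack.voxel_z,
                 smoothing_scale / stack.voxel_xy,
                 smoothing_scale / stack.voxel_xy)
    smooth = ndimage.gaussian_filter(img.astype(np.float32), sigma=sigma_vox)
    if smooth.max() == smooth.min():
        raise SegmentationError("reference channel is constant; nothing to segment")
    thr = threshold_otsu(smooth)
    mask = smooth > thr
    if not mask.any():
        raise SegmentationError("empty mask after automatic thresholding")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()
    mask = ndimage.binary_fill_holes(mask)

    zz, yy, xx = np.nonzero(mask)
    coords = np.column_stack([
        (xx + 0.5) * stack.voxel_xy,
        (yy + 0.5) * stack.voxel_xy,
        (zz + 0.5) * stack.voxel_z,
    ])
    center = coords.mean(axis=0)
    cov = np.cov((coords - center).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    proj = (coords - center) @ axis
    anchor_proj = (np.asarray(proximal_anchor, dtype=float) - center) @ axis
    if anchor_proj > 0:
        axis = -axis
        proj = -proj
    lo, hi = proj.min(), proj.max()
    s_vals = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
    s = np.full(mask.shape, np.nan)
    s[zz, yy, xx] = s_vals
    return LobeRegion(mask=mask, voxel_xy=stack.voxel_xy, voxel_z=stack.voxel_z,
                      s=s, axis=axis, smoothing_scale=smoothing_scale)


def filter_spots_in_region(spots, region: LobeRegion) -> list[Spot]:
    """Keep only spots whose position voxel lies inside the lobe mask."""
    inside = region.contains(spots)
    return [sp for sp, ok in zip(spots, inside) if ok]


def count_axonal(spots, region: LobeRegion, min_spots: int = 10,
                 distal_fraction: float = 2 / 3) -> tuple[int, bool]:
    """Count spots in the distal 2/3 of the lobe; flag samples with < 10.

    Returns ``(count, included)``: ``count`` is the number of in-region
    spots with axial coordinate s >= 1/3 (i.e. within the distal 2/3 of
    the lobe axis), and ``included`` is False when the count falls below
    ``min_spots`` — such samples are excluded from downstream analysis.
    """
    s = region.s_of(spots)
    count = int(np.sum(s >= 1.0 - distal_fraction))
    return count, count >= min_spots


@dataclass
class CompartmentQuant:
    """Compartment-wise spot counts, densities and the γ5 enrichment ratio."""

    n_axonal: int
    included: bool
    n_gamma5: int
    n_gamma24: int
    vol_gamma5: float
    vol_gamma24: float
    density_gamma5: float
    density_gamma24: float
    enrichment_ratio: float | None
    undefined_reason: str | None = None


def compartment_ratio(spots, region: LobeRegion, gamma5_start: float = 2 / 3,
                      min_spots: int = 10) -> CompartmentQuant:
    """Spot density ratio between the distal γ5 compartment and proximal γ2–4.

    The lobe volume is split at axial coordinate s = 2/3: the γ5
    compartment (s >= 2/3) versus the remaining proximal two thirds.
    Spot counts in each part are divided by the corresponding volume
    (spots/μm³) and the enrichment ratio is distal density over proximal
    density; a zero proximal count leaves the ratio undefined with a
    reason. Samples with fewer than ``min_spots`` axonal spots are flagged
    as excluded.
    """
    s = region.s_of(spots)
    s = s[~np.isnan(s)]
    n5 = int(np.sum(s >= gamma5_start))
    n24 = int(s.size - n5)
    vol5 = region.compartment_volume(gamma5_start, np.inf)
    vol24 = region.volume - vol5
    d5 = n5 / vol5 if vol5 > 0 else np.nan
    d24 = n24 / vol24 if vol24 > 0 else np.nan
    n_axonal, included = count_axonal(spots, region, min_spots=min_spots)
    if n24 == 0 or vol24 == 0 or vol5 == 0:
        ratio, reason = None, (
            "zero proximal spot count" if n24 == 0 else "degenerate compartment volume"
        )
    else:
        ratio, reason = d5 / d24, None
    return CompartmentQuant(
        n_axonal=n_axonal, included=included, n_gamma5=n5, n_gamma24=n24,
        vol_gamma5=vol5, vol_gamma24=vol24, density_gamma5=d5,
        density_gamma24=d24, enrichment_ratio=ratio, undefined_reason=reason,
    )


def normalize_counts(counts, groups, batches=None, control_group: str = "control") -> np.ndarray:
    """Normalize per-sample spot counts by the control-group mean of each batch."""
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    batches = np.zeros(len(counts), dtype=int) if batches is None else np.asarray(batches)
    out = np.empty_like(counts)
    for b in np.unique(batches):
        sel = batches == b
        ctrl = counts[sel & (groups == control_group)]
        if ctrl.size == 0:
            raise ValueError(f"batch {b!r} has no {control_group!r} samples")
        m = ctrl.mean()
        if m == 0:
            raise ValueError(f"batch {b!r} control mean is zero")
        out[sel] = counts[sel] / m
    return out
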