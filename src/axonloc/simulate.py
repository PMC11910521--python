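"""Synthetic data with ground truth for every pipeline stage.

Four generators emulate the pipeline's inputs:

- :func:`simulate_stack` — a two-channel confocal stack of a tubular axon
  lobe (straight cylinder along x, proximal end at x = 0) with
  diffraction-limited spots planted at compartment-dependent Poisson
  densities, plus background and noise.
- :func:`simulate_annotation` — multi-exon coding transcripts on both
  strands of the major chromosome arms, with crosslink peaks placed
  inside exons according to a 5′UTR/CDS/3′UTR region bias.
- :func:`simulate_assay_tables` — per-gene statistics for the three
  target-identification assays with a planted overlapping target set.
- :func:`simulate_courtship` — naive/trained courtship-index samples with
  a planted suppression effect.

One integer seed drives everything; per-component sub-streams are derived
deterministically, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from axonloc.metatranscript import (
    CrosslinkRecord,
    PeakRecord,
    TranscriptModel,
    assign_region,
    transcript_to_genomic,
)
from axonloc.spots import GeometryError
from axonloc.stack import ImageStack

CHROMOSOMES = ("2L", "2R", "3L", "3R", "X", "Y", "MT")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the synthetic lobe stack.

    Voxel sizes default to the acquisition geometry (0.07 μm lateral,
    0.25 μm z step). Spot sigmas default to the detector's FWHM
    convention (0.4 μm xy diameter, 0.8 μm z elongation). Densities are
    spots/μm³ in the proximal (axial coordinate s < 2/3) and distal
    (s >= 2/3) parts of the lobe. ``min_separation`` > 0 thins the Poisson
    process to a hard-core process with that minimum spot distance (μm).
    """

    seed: int = 0
    lobe_length: float = 30.0  # μm
    lobe_radius: float = 2.5  # μm
    voxel_xy: float = 0.07
    voxel_z: float = 0.25
    density_proximal: float = 0.2  # spots/μm³
    density_distal: float = 0.2
    psf_sigma_xy: float = 0.4 / 2.355  # μm
    psf_sigma_z: float = 0.8 / 2.355
    spot_amplitude: float = 300.0
    background_mean: float = 100.0
    noise_sd: float = 10.0
    margin_xy: float = 0.7  # μm of padding around the lobe
    margin_z: float = 1.0
    min_separation: float = 0.0
    shot_noise: bool = False
    shape: tuple[int, int, int] | None = None  # (nz, ny, nx) override

    def __post_init__(self):
        for name in ("lobe_length", "lobe_radius", "density_proximal",
                     "density_distal", "psf_sigma_xy", "psf_sigma_z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass
class GroundTruth:
    """Planted spots, lobe mask and axial orientation of a simulated stack."""

    spot_positions: np.ndarray  # (n, 3) μm, (x, y, z)
    spot_compartments: np.ndarray  # 'proximal' / 'distal'
    region_mask: np.ndarray  # boolean (z, y, x)
    axial_orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    @property
    def n_spots(self) -> int:
        return len(self.spot_positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_um": self.spot_positions[:, 0],
            "y_um": self.spot_positions[:, 1],
            "z_um": self.spot_positions[:, 2],
            "compartment": self.spot_compartments,
        })


def _sample_cylinder(rng, n, x_lo, x_hi, radius, cy, cz):
    x = rng.uniform(x_lo, x_hi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([x, cy + r * np.cos(theta), cz + r * np.sin(theta)])


def _thin_hardcore(points: np.ndarray, min_sep: float) -> np.ndarray:
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.sum((p - q) ** 2) >= min_sep ** 2 for q in kept):
            kept.append(p)
    return np.array(kept).reshape(-1, 3)


def _render_spots(image, positions, amplitude, sigma_xy, sigma_z, voxel_xy, voxel_z):
    nz, ny, nx = image.shape
    sx = sigma_xy / voxel_xy
    sz = sigma_z / voxel_z
    wx, wz = int(np.ceil(4 * sx)), int(np.ceil(4 * sz))
    for x, y, z in positions:
        cx, cy, cz = x / voxel_xy - 0.5, y / voxel_xy - 0.5, z / voxel_z - 0.5
        ix, iy, iz = int(round(cx)), int(round(cy)), int(round(cz))
        x0, x1 = max(0, ix - wx), min(nx, ix + wx + 1)
        y0, y1 = max(0, iy - wx), min(ny, iy + wx + 1)
        z0, z1 = max(0, iz - wz), min(nz, iz + wz + 1)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2 * sx ** 2))
        gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2 * sx ** 2))
        gz = np.exp(-((np.arange(z0, z1) - cz) ** 2) / (2 * sz ** 2))
        image[z0:z1, y0:y1, x0:x1] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def simulate_stack(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate a two-channel lobe stack with planted spots.

    The ``reference`` channel carries the smoothed lobe-mask intensity
    used for segmentation; the ``spots`` channel carries anisotropic
    Gaussian spots at Poisson-sampled positions (``density_proximal``
    where the axial coordinate s < 2/3, ``density_distal`` where
    s >= 2/3), on a constant background with additive Gaussian noise
    (optionally Poisson shot noise).
    """
    cfg = config
    nx = int(np.ceil((cfg.lobe_length + 2 * cfg.margin_xy) / cfg.voxel_xy))
    ny = int(np.ceil((2 * cfg.lobe_radius + 2 * cfg.margin_xy) / cfg.voxel_xy))
    nz = int(np.ceil((2 * cfg.lobe_radius + 2 * cfg.margin_z) / cfg.voxel_z))
    if cfg.shape is not None:
        nz_r, ny_r, nx_r = cfg.shape
        if nz_r < nz or ny_r < ny or nx_r < nx:
            raise GeometryError(
                f"lobe needs at least (nz,ny,nx)=({nz},{ny},{nx}) voxels; "
                f"requested {cfg.shape}"
            )
        nz, ny, nx = nz_r, ny_r, nx_r
    rng_count, rng_pos, rng_noise, rng_ref = _rngs(cfg.seed, 4)

    x0 = cfg.margin_xy
    cy = ny * cfg.voxel_xy / 2
    cz = nz * cfg.voxel_z / 2

    # lobe mask on voxel centers
    xs = (np.arange(nx) + 0.5) * cfg.voxel_xy
    ys = (np.arange(ny) + 0.5) * cfg.voxel_xy
    zs = (np.arange(nz) + 0.5) * cfg.voxel_z
    in_x = (xs >= x0) & (xs <= x0 + cfg.lobe_length)
    rr = (ys[None, :, None] - cy) ** 2 + (zs[:, None, None] - cz) ** 2
    mask = (rr <= cfg.lobe_radius ** 2) & in_x[None, None, :]

    # plant spots: Poisson counts per compartment, uniform in each segment
    seg_area = np.pi * cfg.lobe_radius ** 2
    len_prox = cfg.lobe_length * 2 / 3
    len_dist = cfg.lobe_length / 3
    n_prox = rng_count.poisson(cfg.density_proximal * seg_area * len_prox)
    n_dist = rng_count.poisson(cfg.density_distal * seg_area * len_dist)
    prox = _sample_cylinder(rng_pos, n_prox, x0, x0 + len_prox, cfg.lobe_radius, cy, cz)
    dist = _sample_cylinder(rng_pos, n_dist, x0 + len_prox, x0 + cfg.lobe_length,
                            cfg.lobe_radius, cy, cz)
    positions = np.vstack([prox, dist])
    labels = np.array(["proximal"] * len(prox) + ["distal"] * len(dist))
    if len(positions):
        # keep only spots whose containing voxel is inside the voxelized mask
        iz = np.floor(positions[:, 2] / cfg.voxel_z).astype(int)
        iy = np.floor(positions[:, 1] / cfg.voxel_xy).astype(int)
        ix = np.floor(positions[:, 0] / cfg.voxel_xy).astype(int)
        ok = mask[iz, iy, ix]
        positions, labels = positions[ok], labels[ok]
    if cfg.min_separation > 0 and len(positions):
        order = rng_pos.permutation(len(positions))
        thinned = _thin_hardcore(positions[order], cfg.min_separation)
        # recompute labels from the axial coordinate of surviving spots
        positions = thinned
        s = (positions[:, 0] - x0) / cfg.lobe_length if cfg.lobe_length > 0 else np.zeros(len(positions))
        labels = np.where(s < 2 / 3, "proximal", "distal")

    signal = np.zeros((nz, ny, nx), dtype=float)
    _render_spots(signal, positions, cfg.spot_amplitude, cfg.psf_sigma_xy,
                  cfg.psf_sigma_z, cfg.voxel_xy, cfg.voxel_z)
    signal += cfg.background_mean
    if cfg.shot_noise:
        signal = rng_noise.poisson(np.clip(signal, 0, None)).astype(float)
    spot_channel = np.clip(signal + rng_noise.normal(0, cfg.noise_sd, signal.shape), 0, None)

    from scipy import ndimage

    ref = ndimage.gaussian_filter(mask.astype(float) * 1000.0,
                                  sigma=(0.15 / cfg.voxel_z, 0.15 / cfg.voxel_xy,
                                         0.15 / cfg.voxel_xy))
    ref = np.clip(ref + rng_ref.normal(0, 5.0, ref.shape), 0, None)

    stack = ImageStack(channels={"reference": ref, "spots": spot_channel},
                       voxel_xy=cfg.voxel_xy, voxel_z=cfg.voxel_z)
    truth = GroundTruth(spot_positions=positions, spot_compartments=labels,
                        region_mask=mask)
    return stack, truth


# ---------------------------------------------------------------------------
# Transcript annotations and crosslink peaks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAnnotationSet:
    """Synthetic transcripts with region-biased crosslinks and peaks."""

    transcripts: list[TranscriptModel]
    crosslinks: list[CrosslinkRecord]
    peaks: list[PeakRecord]
    region_bias: tuple[float, float, float]
    decoys: list[dict] = field(default_factory=list)  # GTF-only records dropped by build_reference

    def write_gtf(self, path) -> None:
        write_gtf(self.transcripts, path, decoys=self.decoys)

    def write_peaks_bed(self, path) -> None:
        write_peaks_bed(self.peaks, path)


def _validate_bias(region_bias) -> tuple[float, float, float]:
    bias = tuple(float(b) for b in region_bias)
    if len(bias) != 3 or any(b < 0 for b in bias):
        raise ValueError("region_bias must be three non-negative probabilities")
    if abs(sum(bias) - 1.0) > 1e-9:
        raise ValueError(f"region_bias must sum to 1, got {sum(bias)}")
    return bias


def _random_transcript(rng, gene_id, transcript_id, chromosome, strand, start):
    """Build one multi-exon coding transcript starting at `start` on the genome."""
    l5 = int(rng.integers(40, 300))
    lcds = 3 * int(rng.integers(80, 500))
    l3 = int(rng.integers(80, 800))
    total = l5 + lcds + l3
    n_exons = int(rng.integers(2, 7))
    # cut the spliced length into exons of >= 20 nt
    cuts = np.sort(rng.choice(np.arange(20, total - 20), size=n_exons - 1, replace=False))
    lengths = np.diff(np.concatenate([[0], cuts, [total]]))
    while (lengths < 20).any():
        cuts = np.sort(rng.choice(np.arange(20, total - 20), size=n_exons - 1, replace=False))
        lengths = np.diff(np.concatenate([[0], cuts, [total]]))
    introns = rng.integers(50, 500, size=n_exons - 1)
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        exons.append((int(pos), int(pos + ln)))
        pos += ln + (introns[i] if i < n_exons - 1 else 0)
    model = TranscriptModel(gene_id=gene_id, transcript_id=transcript_id,
                            chromosome=chromosome, strand=strand,
                            exons=tuple(exons), cds_start=exons[0][0],
                            cds_end=exons[-1][1])
    # place the CDS via transcript coordinates to get the requested UTR lengths
    g_a = transcript_to_genomic(model, l5)
    g_b = transcript_to_genomic(model, l5 + lcds - 1)
    cds_start, cds_end = min(g_a, g_b), max(g_a, g_b) + 1
    return TranscriptModel(gene_id=gene_id, transcript_id=transcript_id,
                           chromosome=chromosome, strand=strand,
                           exons=tuple(exons), cds_start=cds_start, cds_end=cds_end)


def simulate_annotation(n_genes: int, region_bias=(0.1, 0.2, 0.7),
                        min_peaks_per_transcript: int = 20, seed: int = 0,
                        n_decoys: int = 0) -> SyntheticAnnotationSet:
    """Simulate coding transcripts and region-biased crosslink peaks.

    Each of ``n_genes`` genes gets one multi-exon coding transcript on a
    random strand of a random major chromosome arm. Each transcript
    carries at least ``min_peaks_per_transcript`` significant peaks whose
    region (5′UTR/CDS/3′UTR) is drawn from ``region_bias`` and whose
    position is uniform within that region; peaks are mapped back to
    genomic coordinates, so every peak falls inside an exon by
    construction. The default bias is 3′UTR-heavy, mirroring the 3′UTR
    preference typical of mRNA-transport RBPs. ``n_decoys`` adds GTF-only
    records (non-coding, ambiguous-status and off-chromosome transcripts)
    that a correct reference builder must drop.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    bias = _validate_bias(region_bias)
    rng_tr, rng_pk, rng_decoy = _rngs(seed, 3)
    cursors = {c: 1000 for c in CHROMOSOMES}
    transcripts, peaks, crosslinks = [], [], []
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        gid = f"g{i + 1:0{width}d}"
        chrom = str(rng_tr.choice(CHROMOSOMES))
        strand = "+" if rng_tr.random() < 0.5 else "-"
        model = _random_transcript(rng_tr, gid, f"{gid}.t1", chrom, strand, cursors[chrom])
        cursors[chrom] = model.exons[-1][1] + int(rng_tr.integers(500, 2000))
        transcripts.append(model)

        n_peaks = min_peaks_per_transcript + int(rng_pk.poisson(5))
        regions = rng_pk.choice(3, size=n_peaks, p=bias)
        lens = (model.l5, model.lcds, model.l3)
        starts = (0, model.l5, model.l5 + model.lcds)
        for r in regions:
            if lens[r] == 0:  # degenerate region under an extreme bias
                r = 1
            t = starts[r] + int(rng_pk.integers(0, lens[r]))
            g = transcript_to_genomic(model, t)
            support = 5 + int(rng_pk.poisson(10))
            peaks.append(PeakRecord(chromosome=chrom, position=g, strand=strand,
                                    support=support, significant=True, gene_id=gid))
            crosslinks.append(CrosslinkRecord(chromosome=chrom, position=g,
                                              strand=strand, count=support))
    decoys = []
    for j in range(n_decoys):
        kind = ("noncoding", "ambiguous", "offchrom")[j % 3]
        chrom = "4" if kind == "offchrom" else str(rng_decoy.choice(CHROMOSOMES))
        start = 10_000_000 + 5000 * j
        decoys.append({
            "kind": kind, "chromosome": chrom, "strand": "+",
            "gene_id": f"decoy{j + 1}", "transcript_id": f"decoy{j + 1}.t1",
            "exons": [(start, start + 600)],
            "cds": None if kind == "noncoding" else (start + 100, start + 400),
            "biotype": "ncRNA" if kind == "noncoding" else "protein_coding",
            "status": "incomplete" if kind == "ambiguous" else None,
        })
    return SyntheticAnnotationSet(transcripts=transcripts, crosslinks=crosslinks,
                                  peaks=peaks, region_bias=bias, decoys=decoys)


def simulate_crosslink_samples(annotation: SyntheticAnnotationSet, sample_names,
                               depth_factors=None, seed: int = 0) -> dict:
    """Per-sample crosslink tables by resampling the annotation's crosslinks.

    ``depth_factors`` scale each sample's expected cDNA counts, emulating
    library-depth differences that size-factor normalization must undo.
    """
    rng = np.random.default_rng(seed)
    depth_factors = depth_factors or [1.0] * len(sample_names)
    out = {}
    for name, f in zip(sample_names, depth_factors):
        records = []
        for xl in annotation.crosslinks:
            c = int(rng.poisson(xl.count * f))
            if c >= 1:
                records.append(CrosslinkRecord(chromosome=xl.chromosome,
                                               position=xl.position,
                                               strand=xl.strand, count=c))
        out[name] = records
    return out


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAssayTables:
    """Per-gene statistics for the three assays with a planted target set.

    Planted targets pass all three gates by construction (synaptosome
    log2FC > 0, RIP log2FC > 1 in every comparison, >= 1 significant
    iCLIP peak with >= 5 supporting cDNAs); every non-target fails at
    least one gate.
    """

    synaptosome_stats: pd.DataFrame  # gene_id, log2FC, padj, mean_rpm
    rip_stats: pd.DataFrame  # gene_id + one log2FC column per comparison
    iclip_peak_support: pd.DataFrame  # gene_id, support, significant (per peak)
    planted_target_set: set[str]

    def write_tsvs(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.synaptosome_stats.to_csv(d / "synaptosome_stats.tsv", sep="\t", index=False)
        self.rip_stats.to_csv(d / "rip_stats.tsv", sep="\t", index=False)
        self.iclip_peak_support.to_csv(d / "iclip_peak_support.tsv", sep="\t", index=False)
        pd.Series(sorted(self.planted_target_set), name="gene_id").to_csv(
            d / "planted_targets.tsv", sep="\t", index=False)


def simulate_assay_tables(n_genes: int, n_targets: int, seed: int = 0,
                          n_comparisons: int = 4) -> SyntheticAssayTables:
    """Simulate the three per-gene assay tables with a planted target set."""
    if n_targets > n_genes:
        raise ValueError("n_targets must be <= n_genes")
    rng, = _rngs(seed, 1)
    width = max(4, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    targets = set(rng.choice(genes, size=n_targets, replace=False)) if n_targets else set()

    syn_fc, syn_p, rip_fc, best_support, sig = [], [], [], [], []
    for g in genes:
        if g in targets:
            syn_fc.append(rng.uniform(0.9, 3.0))
            syn_p.append(rng.uniform(1e-6, 0.04))
            rip_fc.append(rng.uniform(1.1, 3.0, n_comparisons))
            best_support.append(int(rng.integers(5, 60)))
            sig.append(True)
        else:
            # fail at least one gate; draw which gates fail (>= 1)
            fails = rng.random(3) < 0.6
            if not fails.any():
                fails[rng.integers(0, 3)] = True
            syn_fc.append(rng.uniform(-2.0, 0.0) if fails[0] else rng.uniform(0.1, 3.0))
            syn_p.append(rng.uniform(0.0, 1.0))
            fc = rng.uniform(1.1, 3.0, n_comparisons)
            if fails[1]:
                fc[rng.integers(0, n_comparisons)] = rng.uniform(-1.0, 1.0)
            rip_fc.append(fc)
            best_support.append(int(rng.integers(1, 5)) if fails[2] else int(rng.integers(5, 60)))
            sig.append(not fails[2] or rng.random() < 0.5)
    syn = pd.DataFrame({
        "gene_id": genes, "log2FC": syn_fc, "padj": syn_p,
        "mean_rpm": rng.uniform(1, 500, n_genes),
    })
    rip = pd.DataFrame(np.array(rip_fc),
                       columns=[f"log2FC_cmp{i + 1}" for i in range(n_comparisons)])
    rip.insert(0, "gene_id", genes)
    iclip = pd.DataFrame({"gene_id": genes, "support": best_support, "significant": sig})
    return SyntheticAssayTables(synaptosome_stats=syn, rip_stats=rip,
                                iclip_peak_support=iclip, planted_target_set=targets)


# ---------------------------------------------------------------------------
# Courtship
# ---------------------------------------------------------------------------

@dataclass
class CourtshipDataset:
    """Naive and trained courtship indices with a planted suppression effect."""

    naive_cis: np.ndarray
    trained_cis: np.ndarray
    suppression: float  # planted 1 - E[CI_trained] / E[CI_naive]

    def to_frame(self) -> pd.DataFrame:
        rows = [("naive", ci) for ci in self.naive_cis]
        rows += [("trained", ci) for ci in self.trained_cis]
        return pd.DataFrame(rows, columns=["group", "ci"])


def simulate_courtship(n_naive: int, n_trained: int, naive_mean: float = 0.6,
                       suppression: float = 0.5, noise_sd: float = 0.1,
                       seed: int = 0) -> CourtshipDataset:
    """Simulate naive/trained courtship indices.

    Naive CIs are drawn around ``naive_mean`` and trained CIs around
    ``naive_mean * (1 - suppression)``, both with Gaussian noise of
    ``noise_sd`` and clipped to [0, 1].
    """
    if not 0 < naive_mean <= 1:
        raise ValueError("naive_mean must be in (0, 1]")
    if suppression > 1:
        raise ValueError("suppression must be <= 1")
    rng, = _rngs(seed, 1)
    naive = np.clip(rng.normal(naive_mean, noise_sd, n_naive), 0.0, 1.0)
    trained_mean = naive_mean * (1.0 - suppression)
    trained = np.clip(rng.normal(trained_mean, noise_sd, n_trained), 0.0, 1.0)
    return CourtshipDataset(naive_cis=naive, trained_cis=trained,
                            suppression=suppression)


# ---------------------------------------------------------------------------
# Writers for the on-disk formats
# ---------------------------------------------------------------------------

def write_gtf(transcripts, path, decoys=()) -> None:
    """Write transcript models as GTF (1-based, closed intervals)."""
    with open(path, "w") as fh:
        def attr(gid, tid, extra=""):
            return f'gene_id "{gid}"; transcript_id "{tid}";{extra}'

        for m in transcripts:
            lo = min(s for s, _ in m.exons) + 1
            hi = max(e for _, e in m.exons)
            extra = ' transcript_biotype "protein_coding";'
            fh.write(f"{m.chromosome}\tsim\ttranscript\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"{attr(m.gene_id, m.transcript_id, extra)}\n")
            for s, e in m.exons:
                fh.write(f"{m.chromosome}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f"{attr(m.gene_id, m.transcript_id)}\n")
            for s, e in m.exons:
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs < ce:
                    fh.write(f"{m.chromosome}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t"
                             f"{attr(m.gene_id, m.transcript_id)}\n")
        for d in decoys:
            extra = f' transcript_biotype "{d["biotype"]}";'
            if d["status"]:
                extra += f' status "{d["status"]}";'
            lo = min(s for s, _ in d["exons"]) + 1
            hi = max(e for _, e in d["exons"])
            fh.write(f"{d['chromosome']}\tsim\ttranscript\t{lo}\t{hi}\t.\t{d['strand']}\t.\t"
                     f"{attr(d['gene_id'], d['transcript_id'], extra)}\n")
            for s, e in d["exons"]:
                fh.write(f"{d['chromosome']}\tsim\texon\t{s + 1}\t{e}\t.\t{d['strand']}\t.\t"
                         f"{attr(d['gene_id'], d['transcript_id'])}\n")
            if d["cds"]:
                cs, ce = d["cds"]
                fh.write(f"{d['chromosome']}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{d['strand']}\t.\t"
                         f"{attr(d['gene_id'], d['transcript_id'])}\n")


def write_peaks_bed(peaks, path) -> None:
    """Write peaks as 6-column BED (0-based, half-open; score = cDNA support)."""
    rows = [(p.chromosome, p.position, p.position + 1,
             p.gene_id or ".", p.support, p.strand)
            for p in peaks if p.significant]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> list[PeakRecord]:
    """Read significant peaks from a 6-column BED (score = cDNA support)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [PeakRecord(chromosome=str(r.chrom), position=int(r.start),
                       strand=str(r.strand), support=int(r.score),
                       significant=True,
                       gene_id=None if r.name == "." else str(r.name))
            for r in df.itertuples()]
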