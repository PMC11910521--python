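"""Transcript reference building, coordinate mapping and metatranscript profiling.

The metatranscript view pools protein-RNA crosslink peaks from many genes
onto one virtual transcript: each peak's position is first converted from
genomic to spliced transcript coordinates, labeled by the region it falls
into (5′UTR, CDS or 3′UTR), and then linearly rescaled so that the 5′UTR
spans meta-coordinates 0–19, the CDS 20–69 and the 3′UTR 70–100. The
density of pooled rescaled positions (Gaussian KDE with boundary
reflection) shows where along an mRNA a binding protein preferentially
crosslinks, independent of absolute transcript lengths.

Internally all coordinates are 0-based, half-open. GTF input (1-based,
closed) and BED input (0-based, half-open) are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALLOWED_CHROMOSOMES = frozenset({"X", "Y", "MT", "2L", "2R", "3L", "3R"})

#: meta-coordinate interval (lo, hi) assigned to each transcript region
REGION_INTERVALS = {"5UTR": (0.0, 19.0), "CDS": (20.0, 69.0), "3UTR": (70.0, 100.0)}


class NotInExon(Exception):
    """A genomic position does not fall inside any exon of the transcript."""


@dataclass(frozen=True)
class CrosslinkRecord:
    """A single-nucleotide protein-RNA crosslink site with cDNA support."""

    chromosome: str
    position: int  # 0-based genomic
    strand: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("cDNA count must be >= 1")


@dataclass(frozen=True)
class PeakRecord:
    """A significant crosslink peak anchored at a single nucleotide."""

    chromosome: str
    position: int  # 0-based genomic
    strand: str
    support: int  # uniquely mapped cDNAs backing the peak
    significant: bool = True
    gene_id: str | None = None

    def __post_init__(self):
        if self.support < 0:
            raise ValueError("cDNA support must be >= 0")


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced gene model with 5′UTR/CDS/3′UTR partition.

    ``exons`` are 0-based half-open genomic intervals, sorted and disjoint;
    ``cds_start``/``cds_end`` delimit the CDS on the genome (half-open).
    Transcript coordinates run 5′→3′ on the transcript strand, so position
    0 is the first transcribed base on either strand.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ex = tuple(tuple(map(int, e)) for e in self.exons)
        if not ex:
            raise ValueError(f"{self.transcript_id}: no exons")
        for s, e in ex:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (_, e0), (s1, _) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
        object.__setattr__(self, "exons", ex)
        if self.cds_end <= self.cds_start:
            raise ValueError(f"{self.transcript_id}: empty CDS")
        # CDS endpoints must land on exonic bases
        for pos in (self.cds_start, self.cds_end - 1):
            if not any(s <= pos < e for s, e in ex):
                raise ValueError(
                    f"{self.transcript_id}: CDS boundary {pos} outside exons"
                )

    @property
    def length(self) -> int:
        """Spliced transcript length L = sum of exon lengths (nt)."""
        return sum(e - s for s, e in self.exons)

    @property
    def cds_t(self) -> tuple[int, int]:
        """CDS as a half-open transcript-coordinate interval."""
        a = genomic_to_transcript(self, self.cds_start)
        b = genomic_to_transcript(self, self.cds_end - 1)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    @property
    def l5(self) -> int:
        return self.cds_t[0]

    @property
    def lcds(self) -> int:
        lo, hi = self.cds_t
        return hi - lo

    @property
    def l3(self) -> int:
        return self.length - self.cds_t[1]


def genomic_to_transcript(model: TranscriptModel, genomic_position: int,
                          chromosome: str | None = None) -> int:
    """Map a genomic position to a spliced transcript coordinate.

    Position 0 is the transcript 5′ end on either strand. Raises
    :class:`NotInExon` for intronic or flanking positions.
    """
    if chromosome is not None and chromosome != model.chromosome:
        raise ValueError(
            f"chromosome mismatch: {chromosome!r} vs model on {model.chromosome!r}"
        )
    g = int(genomic_position)
    offset = 0
    for s, e in model.exons:
        if s <= g < e:
            plus_t = offset + (g - s)
            if model.strand == "+":
                return plus_t
            return model.length - 1 - plus_t
        offset += e - s
    raise NotInExon(f"position {g} not in exons of {model.transcript_id}")


def transcript_to_genomic(model: TranscriptModel, transcript_position: int) -> int:
    """Inverse of :func:`genomic_to_transcript`."""
    t = int(transcript_position)
    if not 0 <= t < model.length:
        raise ValueError(f"transcript position {t} outside [0, {model.length})")
    plus_t = t if model.strand == "+" else model.length - 1 - t
    offset = 0
    for s, e in model.exons:
        if plus_t < offset + (e - s):
            return s + (plus_t - offset)
        offset += e - s
    raise AssertionError("unreachable")


def assign_region(model: TranscriptModel, transcript_position: int) -> str:
    """Label a transcript position as ``5UTR``, ``CDS`` or ``3UTR``.

    Regions are half-open: the CDS start base belongs to the CDS and the
    base at CDS end belongs to the 3′UTR.
    """
    t = int(transcript_position)
    if not 0 <= t < model.length:
        raise ValueError(f"position {t} outside transcript [0, {model.length})")
    lo, hi = model.cds_t
    if t < lo:
        return "5UTR"
    if t < hi:
        return "CDS"
    return "3UTR"


def rescale_position(model: TranscriptModel, transcript_position: int) -> float:
    """Rescale a transcript position onto the 0–100 metatranscript.

    Within a region of length ``Lr`` at region-local 0-based offset ``p``,
    the meta-coordinate is ``lo + p / (Lr - 1) * (hi - lo)`` (``lo`` for a
    single-base region), with (lo, hi) = (0, 19) for the 5′UTR, (20, 69)
    for the CDS and (70, 100) for the 3′UTR. The first base of a region
    maps to the interval's lower bound and the last base to its upper
    bound, so the CDS start maps to 20, the 3′UTR start to 70 and the
    transcript's last base to 100.
    """
    t = int(transcript_position)
    region = assign_region(model, t)
    lo_t, hi_t = model.cds_t
    if region == "5UTR":
        p, lr = t, model.l5
    elif region == "CDS":
        p, lr = t - lo_t, model.lcds
    else:
        p, lr = t - hi_t, model.l3
    lo, hi = REGION_INTERVALS[region]
    if lr == 1:
        return lo
    return lo + p / (lr - 1) * (hi - lo)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

_NONCODING_BIOTYPES = {
    "ncRNA", "lncRNA", "miRNA", "snRNA", "snoRNA", "rRNA", "tRNA",
    "pseudogene", "antisense",
}
_AMBIGUOUS_STATUSES = {"incomplete", "unknown"}


def build_reference(gtf_path, allowed_chromosomes=ALLOWED_CHROMOSOMES) -> list[TranscriptModel]:
    """Build a standardized one-transcript-per-gene reference from a GTF.

    Transcripts outside the allowed chromosomes (X, Y, MT, 2L, 2R, 3L, 3R
    by default), non-coding transcripts (no CDS, or a non-coding biotype)
    and transcripts flagged with an ambiguous annotation status
    (``incomplete``/``unknown``) are removed; for each remaining gene the
    longest transcript (by summed exon length, ties broken by smallest
    transcript id) is kept. A transcript whose CDS falls outside its exons
    is rejected with a warning naming it.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    candidates: dict[str, list[TranscriptModel]] = {}
    for tr in db.features_of_type("transcript"):
        chrom = tr.seqid.removeprefix("chr")
        if chrom not in allowed_chromosomes:
            continue
        biotype = tr.attributes.get("transcript_biotype", [None])[0]
        if biotype in _NONCODING_BIOTYPES:
            continue
        status = tr.attributes.get("status", [None])[0]
        if status in _AMBIGUOUS_STATUSES:
            continue
        exons = sorted((f.start - 1, f.end) for f in db.children(tr, featuretype="exon"))
        cds = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
        if not cds:
            continue  # non-coding
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        try:
            model = TranscriptModel(
                gene_id=gid, transcript_id=tid, chromosome=chrom,
                strand=tr.strand, exons=tuple(exons),
                cds_start=min(s for s, _ in cds), cds_end=max(e for _, e in cds),
            )
        except ValueError as err:
            warnings.warn(f"rejected transcript {tid}: {err}")
            continue
        candidates.setdefault(gid, []).append(model)
    reference = []
    for gid, models in candidates.items():
        models.sort(key=lambda m: (-m.length, m.transcript_id))
        reference.append(models[0])
    reference.sort(key=lambda m: m.gene_id)
    return reference


# ---------------------------------------------------------------------------
# Metatranscript profile
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Peak density along the 0–100 virtual transcript."""

    grid: np.ndarray
    density: np.ndarray
    n_transcripts: int
    n_peaks: int
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mass(self, lo: float, hi: float) -> float:
        """Fraction of density mass inside meta-interval [lo, hi]."""
        sel = (self.grid >= lo) & (self.grid <= hi)
        return float(np.trapezoid(self.density[sel], self.grid[sel]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"meta_coord": self.grid, "density": self.density})

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.grid, self.density, alpha=0.4)
        ax.plot(self.grid, self.density)
        for edge in (20, 70):
            ax.axvline(edge, color="k", lw=0.5, ls="--")
        ax.set_xlabel("metatranscript coordinate (5′UTR 0–19, CDS 20–69, 3′UTR 70–100)")
        ax.set_ylabel("crosslink peak density")
        return ax


def rescaled_peak_positions(models, peaks, min_peaks: int = 20):
    """Rescaled meta-coordinates of peaks, pooled over qualifying transcripts.

    Only transcripts carrying at least ``min_peaks`` significant exonic
    peaks contribute. Returns ``(positions, n_transcripts, n_peaks)``.
    """
    by_gene: dict[str, list[PeakRecord]] = {}
    for pk in peaks:
        if not pk.significant:
            continue
        if pk.gene_id is None:
            raise ValueError("peaks must carry a gene assignment")
        by_gene.setdefault(pk.gene_id, []).append(pk)
    model_by_gene = {m.gene_id: m for m in models}
    pooled: list[float] = []
    n_tr = 0
    for gid, gene_peaks in by_gene.items():
        model = model_by_gene.get(gid)
        if model is None:
            continue
        t_positions = []
        for pk in gene_peaks:
            if pk.chromosome != model.chromosome or pk.strand != model.strand:
                continue
            try:
                t_positions.append(genomic_to_transcript(model, pk.position))
            except NotInExon:
                continue
        if len(t_positions) < min_peaks:
            continue
        n_tr += 1
        pooled.extend(rescale_position(model, t) for t in t_positions)
    return np.asarray(pooled, dtype=float), n_tr, len(pooled)


def metaprofile(models, peaks, min_peaks: int = 20, bandwidth=None,
                grid_step: float = 0.5) -> MetaProfile:
    """Kernel density of rescaled peak positions on the metatranscript.

    Gaussian KDE (Scott's-rule bandwidth unless ``bandwidth`` overrides it)
    with boundary reflection at 0 and 100, so the density integrates to 1
    over the metatranscript. Peaks are weighted equally, not by cDNA
    support.
    """
    positions, n_tr, n_pk = rescaled_peak_positions(models, peaks, min_peaks)
    if n_tr == 0:
        raise ValueError(
            f"no transcript carries >= {min_peaks} significant peaks (min_peaks={min_peaks})"
        )
    if np.ptp(positions) == 0:
        raise ValueError("all peak positions identical; KDE undefined")
    kde = stats.gaussian_kde(positions, bw_method=bandwidth)
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    # reflect at both boundaries so no mass leaks outside [0, 100]
    density = kde(grid) + kde(-grid) + kde(200.0 - grid)
    return MetaProfile(
        grid=grid, density=density, n_transcripts=n_tr, n_peaks=n_pk,
        bandwidth=float(kde.factor),
    )


# ---------------------------------------------------------------------------
# Target gating and 3'UTR quantification
# ---------------------------------------------------------------------------

def gate_iclip_targets(peaks, min_support: int = 5) -> set[str]:
    """Genes with at least one significant peak supported by >= ``min_support`` cDNAs."""
    out = set()
    for pk in peaks:
        if pk.significant and pk.support >= min_support and pk.gene_id is not None:
            out.add(pk.gene_id)
    return out


@dataclass
class UTRCountTable:
    """Per-gene 3′UTR crosslink counts with median-of-ratios normalization."""

    counts: pd.DataFrame  # genes x samples, raw 3'UTR cDNA counts
    size_factors: pd.Series
    normalized: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        self.normalized = self.counts / self.size_factors

    def to_frame(self) -> pd.DataFrame:
        raw = self.counts.add_suffix("_raw")
        norm = self.normalized.add_suffix("_norm")
        return pd.concat([raw, norm], axis=1)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over a genes × samples count matrix.

    For each gene with a nonzero geometric mean across samples, the ratio
    of its count to that geometric mean is computed; each sample's size
    factor is the median of its ratios.
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat.sum(axis=0) == 0):
        dead = counts.columns[mat.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.all(np.isfinite(logs), axis=1)
    if not finite.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_geomean = logs[finite].mean(axis=1)
    log_ratios = logs[finite] - log_geomean[:, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _assign_gene(models_by_chrom, record):
    for model in models_by_chrom.get((record.chromosome, record.strand), ()):
        for s, e in model.exons:
            if s <= record.position < e:
                return model
    return None


def quantify_3utr(models, crosslinks_by_sample: dict) -> UTRCountTable:
    """Count 3′UTR crosslink cDNAs per gene and normalize across samples.

    Only crosslinks whose spliced transcript position falls in the 3′UTR
    of the gene's reference transcript are counted; counts are then
    normalized by median-of-ratios size factors computed after merging all
    samples.
    """
    if len(crosslinks_by_sample) < 2:
        raise ValueError("need >= 2 samples for normalization")
    by_chrom: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault((m.chromosome, m.strand), []).append(m)
    genes = sorted(m.gene_id for m in models)
    table = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"),
                         columns=list(crosslinks_by_sample))
    for sample, records in crosslinks_by_sample.items():
        for rec in records:
            model = _assign_gene(by_chrom, rec)
            if model is None:
                continue
            t = genomic_to_transcript(model, rec.position)
            if assign_region(model, t) == "3UTR":
                table.loc[model.gene_id, sample] += rec.count
    sf = median_of_ratios_size_factors(table)
    return UTRCountTable(counts=table, size_factors=sf)
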