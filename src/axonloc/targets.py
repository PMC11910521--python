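"""Gene-level gating, multi-assay overlap, and GO-term deduplication.

Candidate transport targets of an RNA-binding protein are defined by the
intersection of three independent assays: transcripts enriched in
synaptosome fractions (bulk RNA-seq, log2FC > 0), transcripts enriched in
RNA immunoprecipitations (log2FC > 1 in every pairwise comparison), and
transcripts with at least one significant iCLIP crosslink peak supported
by at least 5 uniquely mapped cDNAs. All thresholds here are applied
exactly as printed, with their stated strictness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class GeneSetAnnotation:
    """A GO term (or any gene-set annotation) with its member genes."""

    term_id: str
    name: str
    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")


@dataclass
class OverlapResult:
    """The three assay gene sets and their triple intersection."""

    synaptosome: set
    rip: set
    iclip: set

    @property
    def intersection(self) -> set:
        return self.synaptosome & self.rip & self.iclip


def cpm_filter(counts: pd.DataFrame, cpm_threshold: float = 0.5,
               min_samples: int = 3) -> pd.Index:
    """Expression pre-filter on a genes × samples count matrix.

    Keeps genes with at least one nonzero count and CPM > ``cpm_threshold``
    in at least ``min_samples`` samples, where CPM is the count divided by
    the sample total times 10⁶.
    """
    if counts.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {counts.shape[1]}")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        dead = counts.columns[totals == 0].tolist()
        raise ValueError(f"sample(s) with zero total counts: {dead}")
    cpm = counts / totals * 1e6
    keep = ((counts > 0).any(axis=1)) & ((cpm > cpm_threshold).sum(axis=1) >= min_samples)
    return counts.index[keep]


def classify_synaptic(stats: pd.DataFrame, fc_threshold: float = 0.85,
                      padj_threshold: float = 0.05) -> pd.Series:
    """Label genes enriched / depleted / neither by fold change and padj.

    Enriched: log2FC >= 0.85 and padj < 0.05. Depleted: log2FC <= -0.85
    and padj < 0.05. Genes with missing padj are labeled neither, with a
    warning.
    """
    fc = stats["log2FC"]
    padj = stats["padj"]
    if padj.isna().any():
        warnings.warn(f"{int(padj.isna().sum())} gene(s) missing padj; labeled 'neither'")
    sig = padj.notna() & (padj < padj_threshold)
    labels = pd.Series("neither", index=stats.index, name="label")
    labels[sig & (fc >= fc_threshold)] = "enriched"
    labels[sig & (fc <= -fc_threshold)] = "depleted"
    return labels


def rip_gate(rip_fc: pd.DataFrame, fc_threshold: float = 1.0) -> set:
    """Genes with log2FC > 1 in every pairwise comparison (strict)."""
    if rip_fc.shape[1] < 1:
        raise ValueError("need at least one comparison column")
    keep = (rip_fc > fc_threshold).all(axis=1)
    return set(rip_fc.index[keep])


def triple_overlap(synaptosome_stats: pd.DataFrame, rip_set: set,
                   iclip_set: set) -> OverlapResult:
    """Overlap the three assays' gene sets.

    The synaptosome set takes all genes with log2FC > 0; the RIP and iCLIP
    sets are supplied already gated (:func:`rip_gate`,
    :func:`axonloc.metatranscript.gate_iclip_targets`).
    """
    syn_set = set(synaptosome_stats.index[synaptosome_stats["log2FC"] > 0])
    if syn_set and rip_set and iclip_set and not (syn_set | rip_set) & iclip_set \
            and not (syn_set | iclip_set) & rip_set:
        warnings.warn("assay gene namespaces do not overlap at all")
    return OverlapResult(synaptosome=syn_set, rip=set(rip_set), iclip=set(iclip_set))


def jaccard_distance(a, b) -> float:
    """Jaccard distance d(A, B) = 1 − |A∩B| / |A∪B| between two gene sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard distance undefined for two empty sets")
    return 1.0 - len(a & b) / len(union)


@dataclass
class TermCluster:
    """A cluster of redundant GO terms with a representative."""

    terms: list[GeneSetAnnotation]
    representative: GeneSetAnnotation


def cluster_terms(annotations, cut_height: float = 0.5) -> list[TermCluster]:
    """Deduplicate GO terms by average-linkage clustering on Jaccard distance.

    The pairwise Jaccard distance matrix over the terms' gene sets is
    clustered with average linkage and cut at ``cut_height``; each cluster
    reports as representative the term with the smallest summed distance
    to the cluster's other members (ties broken by term id).
    """
    annotations = list(annotations)
    if len(annotations) < 2:
        raise ValueError("need >= 2 terms to cluster")
    n = len(annotations)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jaccard_distance(annotations[i].genes,
                                                       annotations[j].genes)
    link = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(link, t=cut_height, criterion="distance")
    clusters = []
    for c in np.unique(assignment):
        idx = np.nonzero(assignment == c)[0]
        sums = dist[np.ix_(idx, idx)].sum(axis=1)
        best = min(range(len(idx)), key=lambda k: (sums[k], annotations[idx[k]].term_id))
        clusters.append(TermCluster(terms=[annotations[i] for i in idx],
                                    representative=annotations[idx[best]]))
    clusters.sort(key=lambda cl: cl.representative.term_id)
    return clusters
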