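# axonloc

Quantitative analysis of axonal mRNA localization in *Drosophila*
mushroom-body (MB) γ neurons — for neurobiologists and computational
biologists quantifying where mRNAs sit along an axon bundle, which
transcripts an RNA-binding protein (RBP) binds and where on those
transcripts, and whether the resulting localization matters for memory.

Local translation at synapses requires mRNAs to be transported into
axons, typically by RBPs (e.g. the Imp/ZBP1/IGF2BP1 family) recognizing
3′UTR elements. `axonloc` implements the measurement side of that
biology as a reusable, tested pipeline:

- **smFISH spot quantification** (`axonloc.spots`): single mRNA
  molecules appear as diffraction-limited spots. An anisotropic
  Laplacian-of-Gaussian detector (spot FWHM 0.4 μm laterally / 0.8 μm
  axially) finds spots in 3D stacks (0.07 μm xy / 0.25 μm z voxels); the
  γ lobe is segmented from a reference channel (Otsu threshold after
  0.146 μm smoothing) and given a proximal→distal axial coordinate
  s ∈ [0, 1]. Axonal spots are those in the distal 2/3 (s ≥ 1/3; samples
  with < 10 are excluded), and compartment enrichment is

  γ5 ratio = (spots/μm³ at s ≥ 2/3) / (spots/μm³ at s < 2/3),

  the spot-density ratio of the distal γ5 compartment versus the
  proximal γ2–4 region.
- **Metatranscript profiling** (`axonloc.metatranscript`): iCLIP
  crosslink peaks are mapped from genomic to spliced transcript
  coordinates on a one-longest-transcript-per-gene reference, labeled
  5′UTR/CDS/3′UTR, rescaled onto a virtual transcript (5′UTR→0–19,
  CDS→20–69, 3′UTR→70–100) and pooled (transcripts with ≥ 20 significant
  peaks) into a boundary-reflected Gaussian KDE. Per-gene 3′UTR
  crosslink counts are normalized by median-of-ratios size factors.
- **Target gating** (`axonloc.targets`): candidate RBP transport targets
  are the triple overlap of synaptosome-enriched transcripts
  (log2FC > 0; enrichment class: log2FC ≥ 0.85 & padj < 0.05), RIP
  targets (log2FC > 1 in every comparison) and iCLIP targets (≥ 1
  significant peak with ≥ 5 uniquely mapped cDNAs). Redundant GO terms
  are clustered by Jaccard distance d(A,B) = 1 − |A∩B|/|A∪B|.
- **Courtship memory** (`axonloc.behavior`): courtship index
  CI = fraction of the [2.5, 12.5) min window spent courting; memory
  (suppression) index MI = 1 − CI_trained / mean(CI_naive).
- **Synthetic data** (`axonloc.simulate`): every input — lobe stacks
  with Poisson-planted spots, spliced gene models with region-biased
  peaks, assay tables with a planted target set, courtship datasets with
  a planted suppression — is generated with ground truth, so the whole
  pipeline is testable without downloads.

## Worked example

Plant a 3:1 distal:proximal spot density in a synthetic lobe and recover
the γ5 enrichment ratio:

```python
from axonloc.simulate import SimulationConfig, simulate_stack
from axonloc.spots import (compartment_ratio, detect_spots_3d,
                           filter_spots_in_region, segment_lobe)

cfg = SimulationConfig(seed=7, lobe_length=40.0, lobe_radius=3.0,
                       density_proximal=0.08, density_distal=0.24)
stack, truth = simulate_stack(cfg)
region = segment_lobe(stack, "reference")
spots = filter_spots_in_region(detect_spots_3d(stack, "spots"), region)
q = compartment_ratio(spots, region)
print(f"planted spots: {truth.n_spots}, detected in lobe: {len(spots)}")
print(f"axonal spots (distal 2/3): {q.n_axonal}, included: {q.included}")
print(f"enrichment ratio: {q.enrichment_ratio:.2f} (planted 3.0)")
```

```
planted spots: 159, detected in lobe: 148
axonal spots (distal 2/3): 109, included: True
enrichment ratio: 2.70 (planted 3.0)
```

148 of 159 planted molecules are recovered inside the segmented lobe
(the shortfall is unresolvable near-coincident pairs), 109 lie in the
distal two thirds — comfortably above the 10-spot inclusion cutoff — and
the recovered density ratio 2.70 estimates the planted 3.0 within the
sampling noise of ~150 spots.

Gating and behavior run the same way:

```python
from axonloc.simulate import simulate_assay_tables, simulate_courtship
from axonloc.targets import rip_gate, triple_overlap
from axonloc.behavior import memory_table

tables = simulate_assay_tables(n_genes=100, n_targets=9, seed=7)
syn = tables.synaptosome_stats.set_index("gene_id")
rip = rip_gate(tables.rip_stats.set_index("gene_id"))
iclip = {g for g, s, sig in tables.iclip_peak_support.itertuples(index=False)
         if sig and s >= 5}
print(len(triple_overlap(syn, rip, iclip).intersection))   # -> 9

ds = simulate_courtship(n_naive=20, n_trained=20, naive_mean=0.6,
                        suppression=0.5, noise_sd=0.1, seed=7)
print(round(memory_table(ds.trained_cis, ds.naive_cis)["mi"].mean(), 3))
# -> 0.535   (planted suppression 0.5)
```

A `click` CLI mirrors the library
(`axonloc simulate|spots|metaprofile|gate|behavior ...`); run
`axonloc --help` for the command tree.

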