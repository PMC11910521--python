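import numpy as np
import pytest

from axonloc.metatranscript import TranscriptModel
from axonloc.simulate import SimulationConfig, simulate_stack


@pytest.fixture(scope="session")
def toy_transcript() -> TranscriptModel:
    """Single-exon plus-strand transcript: 5'UTR 200 nt, CDS 600 nt, 3'UTR 400 nt."""
    return TranscriptModel(
        gene_id="toy", transcript_id="toy.t1", chromosome="2L", strand="+",
        exons=((1000, 2200),), cds_start=1200, cds_end=1800,
    )


@pytest.fixture(scope="session")
def spliced_pair():
    """Equivalent three-exon transcripts on opposite strands.

    Both have 5'UTR 50 nt, CDS 120 nt, 3'UTR 80 nt (spliced length 250),
    so coordinate maps and rescaling must agree between them.
    """
    exons_plus = ((100, 200), (300, 400), (500, 550))
    plus = TranscriptModel(gene_id="gp", transcript_id="gp.t1", chromosome="3R",
                           strand="+", exons=exons_plus, cds_start=150, cds_end=370)
    # mirror geometry: same exon lengths, minus strand; 5' end is the highest base
    minus = TranscriptModel(gene_id="gm", transcript_id="gm.t1", chromosome="3R",
                            strand="-", exons=exons_plus, cds_start=180, cds_end=400)
    return plus, minus


@pytest.fixture(scope="session")
def small_stack():
    """A compact simulated lobe stack shared by segmentation/detection tests."""
    cfg = SimulationConfig(seed=11, lobe_length=20.0, lobe_radius=2.0,
                           density_proximal=0.3, density_distal=0.3)
    stack, truth = simulate_stack(cfg)
    return cfg, stack, truth


def greedy_match_count(truth_pos, det_pos, radius=0.3):
    """Number of one-to-one truth/detection matches within ``radius`` μm."""
    from scipy.optimize import linear_sum_assignment

    truth_pos = np.asarray(truth_pos, float).reshape(-1, 3)
    det_pos = np.asarray(det_pos, float).reshape(-1, 3)
    if len(truth_pos) == 0 or len(det_pos) == 0:
        return 0
    d = np.linalg.norm(truth_pos[:, None, :] - det_pos[None, :, :], axis=2)
    cost = np.where(d <= radius, d, 1e9)
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(cost[ri, ci] <= radius))
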