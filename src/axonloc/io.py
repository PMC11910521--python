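"""Tabular readers/writers for spots, quantification and ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from axonloc.spots import Spot


def write_spots_tsv(spots, path, s=None, compartments=None) -> None:
    df = pd.DataFrame({
        "x_um": [sp.x for sp in spots],
        "y_um": [sp.y for sp in spots],
        "z_um": [sp.z for sp in spots],
        "response": [sp.response for sp in spots],
    })
    if s is not None:
        df["s"] = np.asarray(s, dtype=float)
    if compartments is not None:
        df["compartment"] = list(compartments)
    df.to_csv(path, sep="\t", index=False)


def read_spots_tsv(path) -> list[Spot]:
    df = pd.read_csv(path, sep="\t")
    return [Spot(position=(r.x_um, r.y_um, r.z_um), response=r.response)
            for r in df.itertuples()]


def write_ground_truth(truth, tsv_path, mask_tiff_path=None) -> None:
    truth.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if mask_tiff_path is not None:
        tifffile.imwrite(mask_tiff_path, truth.region_mask.astype(np.uint8))


def write_quantification_tsv(rows, path) -> None:
    """Write per-sample quantification (sample, n_axonal, ratio, included)."""
    pd.DataFrame(rows, columns=["sample", "n_axonal", "ratio", "included"]).to_csv(
        path, sep="\t", index=False)
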