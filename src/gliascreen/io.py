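"""Reading and writing the pipeline's on-disk formats.

Fields travel as multipage TIFF (channel order: hoechst, neuo, ib4, draq7),
label masks as single-page integer TIFF, tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import CHANNELS, ChannelStack, GroundTruthScene

COUNT_COLUMNS = ["repeat", "plate", "row", "column", "well", "compound_id", "lps",
                 "neuron", "microglia", "astrocyte", "other", "condensed",
                 "necrotic", "debris", "median_formfactor"]


def write_field(path, stack: ChannelStack, channels: tuple = CHANNELS) -> None:
    """Write a field as a multipage float32 TIFF, one page per channel."""
    pages = np.stack([stack[ch].astype(np.float32) for ch in channels])
    tifffile.imwrite(path, pages, metadata={"axes": "CYX", "channels": list(channels)})


def read_field(path, channels: tuple = CHANNELS,
               channel_map: dict | None = None) -> ChannelStack:
    """Read a multipage TIFF as a ChannelStack.

    ``channel_map`` can rename arbitrary page order, e.g. ``{"hoechst": 0}``.
    """
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if channel_map is None:
        channel_map = {ch: i for i, ch in enumerate(channels)}
    missing = [ch for ch in channels if channel_map.get(ch, len(pages)) >= len(pages)]
    if missing:
        raise ValueError(f"channels missing from {path}: {missing}")
    return ChannelStack(channels={ch: np.asarray(pages[channel_map[ch]], dtype=np.float64)
                                  for ch in channels})


def write_mask(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int32)


def write_truth(prefix, truth: GroundTruthScene) -> None:
    """Ground truth as a label TIFF + per-object CSV (label, class, row, col)."""
    prefix = Path(prefix)
    write_mask(prefix.with_suffix(".labels.tif"), truth.label_mask)
    df = pd.DataFrame({
        "label": np.arange(1, truth.n_objects + 1),
        "class": truth.classes,
        "row": truth.centroids[:, 0] if truth.n_objects else [],
        "col": truth.centroids[:, 1] if truth.n_objects else [],
    })
    df.to_csv(prefix.with_suffix(".objects.csv"), index=False)


def write_counts(path, counts: pd.DataFrame) -> None:
    cols = [c for c in COUNT_COLUMNS if c in counts.columns]
    cols += [c for c in counts.columns if c not in cols]
    counts[cols].to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "lps" in df.columns:
        df["lps"] = df["lps"].astype(bool)
    return df
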