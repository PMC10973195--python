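"""Per-object intensity and shape measurements.

Produces the feature table the cell-type classifier consumes: for every
labeled object, per-channel intensity statistics (including percentiles,
boundary-pixel statistics and mass displacement) plus nuclear shape
descriptors.  The exact feature list is schema-driven; the default schema
has 14 statistics x 4 channels + 10 shape features = 66 columns and can be
extended (extra percentiles, texture) without touching the classifier,
which only ever sees named columns.

Perimeter uses the weighted boundary-pixel counting convention of
``skimage.measure.regionprops`` (CellProfiler-style).  FormFactor
(= ImageJ circularity, 4*pi*area/perimeter^2) is capped at 1 because the
digitized perimeter of small discs can undershoot the analytic value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .simulate import ChannelStack

DEFAULT_CHANNEL_STATS = (
    "mean", "std", "min", "max", "integrated", "median", "mad",
    "p5", "p25", "p75", "p95", "edge_mean", "edge_std", "mass_displacement",
)
DEFAULT_SHAPE_STATS = (
    "area", "perimeter", "form_factor", "eccentricity", "solidity", "extent",
    "major_axis", "minor_axis", "equivalent_diameter", "compactness",
)
#: columns carried for provenance/location but excluded from classification
NON_FEATURE_COLUMNS = ("object_id", "centroid_row", "centroid_col",
                       "repeat", "plate", "well", "field", "true_class")


class FeatureError(ValueError):
    pass


@dataclass
class FeatureSchema:
    channels: tuple = ("hoechst", "neuo", "ib4", "draq7")
    channel_stats: tuple = DEFAULT_CHANNEL_STATS
    shape_stats: tuple = DEFAULT_SHAPE_STATS

    @property
    def columns(self) -> list[str]:
        cols = [f"{ch}_{st}" for ch in self.channels for st in self.channel_stats]
        cols += [f"shape_{st}" for st in self.shape_stats]
        return cols

    @property
    def n_features(self) -> int:
        return len(self.columns)


DEFAULT_SCHEMA = FeatureSchema()


def form_factor(area: float, perimeter: float) -> float:
    """FormFactor 4*pi*area/perimeter^2, capped at 1.

    1 for a perfect circle, -> 0 for elongated or ramified shapes.
    """
    if perimeter <= 0:
        raise FeatureError("perimeter must be positive")
    return min(1.0, 4.0 * math.pi * area / perimeter ** 2)


def _channel_stats(values: np.ndarray, edge_values: np.ndarray,
                   mass_disp: float, stats: tuple) -> dict[str, float]:
    out = {}
    med = None
    for st in stats:
        if st == "mean":
            out[st] = float(values.mean())
        elif st == "std":
            out[st] = float(values.std())
        elif st == "min":
            out[st] = float(values.min())
        elif st == "max":
            out[st] = float(values.max())
        elif st == "integrated":
            out[st] = float(values.sum())
        elif st == "median":
            med = float(np.median(values))
            out[st] = med
        elif st == "mad":
            if med is None:
                med = float(np.median(values))
            out[st] = float(np.median(np.abs(values - med)))
        elif st.startswith("p") and st[1:].isdigit():
            out[st] = float(np.percentile(values, int(st[1:])))
        elif st == "edge_mean":
            out[st] = float(edge_values.mean())
        elif st == "edge_std":
            out[st] = float(edge_values.std())
        elif st == "mass_displacement":
            out[st] = mass_disp
        else:
            raise FeatureError(f"unknown channel statistic {st!r}")
    return out


def measure_objects(stack: ChannelStack, labels: np.ndarray,
                    schema: FeatureSchema = DEFAULT_SCHEMA,
                    provenance: dict | None = None) -> pd.DataFrame:
    """Measure every object in ``labels`` on every schema channel.

    Returns one row per label with ``object_id``, centroid coordinates,
    optional provenance columns, and all schema features.  Edge statistics
    are computed on the 1-px object boundary.  Raises on NaN pixels; an
    empty mask yields an empty table.
    """
    labels = np.asarray(labels)
    if labels.shape != stack.shape:
        raise FeatureError("mask shape does not match channel shape")
    for ch in schema.channels:
        if ch not in stack.channels:
            raise FeatureError(f"channel {ch!r} missing from stack")
        if np.isnan(stack[ch]).any():
            raise FeatureError(f"NaN pixels in channel {ch!r}")
    n = int(labels.max())
    cols = ["object_id", "centroid_row", "centroid_col", *schema.columns]
    if n == 0:
        return pd.DataFrame(columns=cols)

    slices = ndi.find_objects(labels)
    rows = []
    for k in range(1, n + 1):
        sl = slices[k - 1]
        if sl is None:
            continue
        sub = labels[sl] == k
        edge = sub & ~ndi.binary_erosion(sub)
        rr, cc = np.nonzero(sub)
        crow = rr.mean() + sl[0].start
        ccol = cc.mean() + sl[1].start
        row: dict[str, float] = {"object_id": k, "centroid_row": crow, "centroid_col": ccol}
        for ch in schema.channels:
            img = stack[ch][sl]
            vals = img[sub]
            evals = img[edge] if edge.any() else vals
            total = vals.sum()
            if total > 0:
                wr = (img * sub * np.arange(sub.shape[0])[:, None]).sum() / total
                wc = (img * sub * np.arange(sub.shape[1])[None, :]).sum() / total
                md = math.hypot(wr - rr.mean(), wc - cc.mean())
            else:
                md = 0.0
            st = _channel_stats(vals, evals, md, schema.channel_stats)
            row.update({f"{ch}_{k2}": v for k2, v in st.items()})
        props = regionprops(sub.astype(np.uint8))[0]
        shape_vals = _shape_stats(props, schema.shape_stats)
        row.update({f"shape_{k2}": v for k2, v in shape_vals.items()})
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    if provenance:
        for k2, v in provenance.items():
            df[k2] = v
    if not np.isfinite(df[schema.columns].to_numpy()).all():
        raise FeatureError("non-finite feature values")
    return df


def _shape_stats(props, stats: tuple) -> dict[str, float]:
    area = float(props.area)
    perim = float(props.perimeter)
    out = {}
    for st in stats:
        if st == "area":
            out[st] = area
        elif st == "perimeter":
            out[st] = perim
        elif st == "form_factor":
            out[st] = form_factor(area, perim) if perim > 0 else 1.0
        elif st == "eccentricity":
            out[st] = float(props.eccentricity)
        elif st == "solidity":
            out[st] = float(props.solidity)
        elif st == "extent":
            out[st] = float(props.extent)
        elif st == "major_axis":
            out[st] = float(props.axis_major_length)
        elif st == "minor_axis":
            out[st] = float(props.axis_minor_length)
        elif st == "equivalent_diameter":
            out[st] = float(props.equivalent_diameter_area)
        elif st == "compactness":
            out[st] = perim ** 2 / (4 * math.pi * area) if area > 0 else np.nan
        else:
            raise FeatureError(f"unknown shape statistic {st!r}")
    return out


def feature_columns(df: pd.DataFrame,
                    schema: FeatureSchema = DEFAULT_SCHEMA) -> list[str]:
    """The classification feature columns present in ``df`` (schema order)."""
    return [c for c in schema.columns if c in df.columns]
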