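"""Microglial morphometry from seeded IB4 cell masks.

Nuclei classified as microglia seed a secondary segmentation of the IB4
channel; the shape of each resulting cell mask is summarized per image by
the median, FormFactor being the statistic carried into downstream
analysis (it separates LPS-activated amoeboid microglia, FormFactor near
1, from ramified resting microglia).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .features import form_factor
from .segmentation import segment_from_seeds, subtract_background
from .simulate import ChannelStack


@dataclass
class MorphologyRecord:
    n_microglia: int
    median_formfactor: float | None
    median_eccentricity: float | None = None
    median_solidity: float | None = None
    median_area: float | None = None
    flagged_seeds: int = 0
    provenance: dict = field(default_factory=dict)


def microglia_morphology(stack: ChannelStack, nuclei: np.ndarray, classes,
                         ib4_channel: str = "ib4",
                         background_radius: int | None = None,
                         threshold: float | None = None) -> MorphologyRecord:
    """Per-image median microglial shape statistics.

    ``classes`` holds one label per nucleus (``classes[k-1]`` for nucleus
    ``k``); only nuclei classified ``"microglia"`` are used as seeds.  An
    image without microglia yields ``n_microglia = 0`` and missing medians
    rather than an error.
    """
    classes = np.asarray(classes, dtype=object)
    nuclei = np.asarray(nuclei)
    if int(nuclei.max()) != len(classes):
        raise ValueError("classes must align with nucleus labels")
    keep = np.flatnonzero(classes == "microglia") + 1
    if keep.size == 0:
        return MorphologyRecord(n_microglia=0, median_formfactor=None)
    seeds = np.where(np.isin(nuclei, keep), nuclei, 0)
    # relabel seeds consecutively for the watershed
    remap = {old: i + 1 for i, old in enumerate(keep)}
    seeds = np.vectorize(lambda v: remap.get(v, 0), otypes=[np.int32])(seeds)

    ib4 = stack[ib4_channel]
    if background_radius:
        ib4 = subtract_background(ib4, background_radius)
    masks, flagged = segment_from_seeds(seeds, ib4, threshold=threshold)

    ffs, eccs, sols, areas = [], [], [], []
    for prop in regionprops(masks):
        if prop.perimeter <= 0:
            continue
        ffs.append(form_factor(prop.area, prop.perimeter))
        eccs.append(prop.eccentricity)
        sols.append(prop.solidity)
        areas.append(prop.area)
    if not ffs:
        return MorphologyRecord(n_microglia=0, median_formfactor=None,
                                flagged_seeds=int(flagged.sum()))
    return MorphologyRecord(
        n_microglia=len(ffs),
        median_formfactor=float(np.median(ffs)),
        median_eccentricity=float(np.median(eccs)),
        median_solidity=float(np.median(sols)),
        median_area=float(np.median(areas)),
        flagged_seeds=int(flagged.sum()),
    )
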