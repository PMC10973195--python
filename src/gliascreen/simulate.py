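"""Ground-truthed synthetic fluorescence fields of neuron-glia cocultures.

Renders 4-channel (Hoechst 33342 / NeuO / IB4-AF594 / DRAQ7) field images
containing the seven object classes used throughout the pipeline, together
with an exact ground-truth label mask.  The staining rules are built in by
construction:

* every nucleus is Hoechst-positive except debris (dim, irregular specks);
* only live neurons are NeuO-bright;
* only microglia carry bright IB4 staining, painted on an amoeboid
  cytoplasm region surrounding the microglial nucleus;
* only necrotic cells are DRAQ7-positive;
* astrocyte nuclei are larger and dimmer in Hoechst than neuronal nuclei,
  condensed (apoptotic) nuclei are the smallest and brightest.

A configurable fraction of neurons is placed touching another nucleus
(exercising declumping) or adjacent to a microglial cytoplasm (giving the
neuron IB4 edge staining, as seen for real neurons bordering microglia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

CLASSES = ("neuron", "microglia", "astrocyte", "other", "condensed", "necrotic", "debris")
CHANNELS = ("hoechst", "neuo", "ib4", "draq7")

# Per class x channel (mean, sd) of object signal amplitude above background.
# Orderings are deliberate: astrocyte Hoechst < neuron Hoechst < other < condensed,
# mirroring how the classes are told apart by eye.
DEFAULT_INTENSITY_MODEL = {
    "neuron":    {"hoechst": (120, 15), "neuo": (150, 25), "ib4": (3, 2), "draq7": (2, 1)},
    "microglia": {"hoechst": (110, 15), "neuo": (6, 3),    "ib4": (140, 25), "draq7": (2, 1)},
    "astrocyte": {"hoechst": (70, 10),  "neuo": (6, 3),    "ib4": (3, 2), "draq7": (2, 1)},
    "other":     {"hoechst": (165, 18), "neuo": (12, 5),   "ib4": (3, 2), "draq7": (2, 1)},
    "condensed": {"hoechst": (230, 20), "neuo": (5, 3),    "ib4": (3, 2), "draq7": (3, 2)},
    "necrotic":  {"hoechst": (140, 20), "neuo": (4, 2),    "ib4": (3, 2), "draq7": (180, 25)},
    "debris":    {"hoechst": (40, 6),   "neuo": (2, 1),    "ib4": (2, 1), "draq7": (2, 1)},
}

# Per class (equivalent diameter mean/sd in px at 10x, eccentricity mean/sd,
# boundary jitter amplitude).  Astrocytes large and oval; condensed/necrotic
# small; debris irregular.
DEFAULT_SHAPE_MODEL = {
    "neuron":    {"diameter": (11.0, 1.0), "eccentricity": (0.45, 0.12), "jitter": 0.06},
    "microglia": {"diameter": (12.0, 1.2), "eccentricity": (0.50, 0.12), "jitter": 0.06},
    "astrocyte": {"diameter": (18.0, 1.6), "eccentricity": (0.65, 0.10), "jitter": 0.06},
    "other":     {"diameter": (10.5, 1.0), "eccentricity": (0.45, 0.12), "jitter": 0.06},
    "condensed": {"diameter": (6.5, 0.7),  "eccentricity": (0.35, 0.10), "jitter": 0.06},
    "necrotic":  {"diameter": (6.0, 0.7),  "eccentricity": (0.35, 0.10), "jitter": 0.08},
    "debris":    {"diameter": (8.0, 1.5),  "eccentricity": (0.70, 0.15), "jitter": 0.35},
}

DEFAULT_BACKGROUND_MODEL = {
    # channel -> (constant level, planar gradient amplitude across the field)
    "hoechst": (10.0, 3.0),
    "neuo": (8.0, 2.0),
    "ib4": (6.0, 2.0),
    "draq7": (4.0, 1.0),
}

DEFAULT_NOISE_MODEL = {"poisson_scale": 0.5, "read_sd": 2.0}

DEFAULT_CLASS_DENSITIES = {
    "neuron": 40, "microglia": 15, "astrocyte": 12, "other": 12,
    "condensed": 12, "necrotic": 12, "debris": 15,
}

# Microglial IB4 cytoplasm presets.  `irregularity` controls boundary
# roughness; low irregularity gives round (amoeboid, LPS-activated) masks with
# FormFactor near 1, high irregularity gives ramified, low-FormFactor masks.
MICROGLIA_AMOEBOID = {"scale": 1.7, "irregularity": 0.08}
MICROGLIA_RAMIFIED = {"scale": 2.2, "irregularity": 0.55}


class SceneSpecError(ValueError):
    """Invalid or unsatisfiable scene specification."""


@dataclass
class ChannelStack:
    """One field's registered channel images plus pixel metadata."""

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # microns per pixel
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: im.shape for ch, im in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, ch: str) -> np.ndarray:
        return self.channels[ch]


@dataclass
class GroundTruthScene:
    """Exact per-object truth for a rendered field."""

    label_mask: np.ndarray           # 0 background, k = object k
    classes: np.ndarray              # classes[k-1] = class of object k
    centroids: np.ndarray            # (n, 2) row/col
    cytoplasm_mask: np.ndarray | None = None  # microglial IB4 footprint labels

    @property
    def n_objects(self) -> int:
        return len(self.classes)

    @property
    def true_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in CLASSES}


@dataclass
class SceneSpec:
    """Parameters of one synthetic field.

    ``class_densities`` are exact object counts per field (rounded to int).
    ``clump_fraction`` of neurons are placed touching another nucleus;
    ``adjacency_fraction`` of neurons are placed bordering a microglial
    cytoplasm.  Intensity/shape models may be partially overridden; missing
    entries fall back to the defaults above.
    """

    field_size: tuple[int, int] = (512, 512)
    class_densities: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_DENSITIES))
    clump_fraction: float = 0.15
    adjacency_fraction: float = 0.10
    intensity_model: dict = field(default_factory=lambda: {})
    nucleus_shape_model: dict = field(default_factory=lambda: {})
    background_model: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND_MODEL))
    noise_model: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_MODEL))
    microglia_cytoplasm: dict = field(default_factory=lambda: dict(MICROGLIA_AMOEBOID))
    pixel_size: float = 0.65
    seed: int = 0

    def resolved_intensity(self) -> dict:
        out = {c: dict(DEFAULT_INTENSITY_MODEL[c]) for c in CLASSES}
        for c, chans in self.intensity_model.items():
            out[c].update(chans)
        return out

    def resolved_shape(self) -> dict:
        out = {c: dict(DEFAULT_SHAPE_MODEL[c]) for c in CLASSES}
        for c, pars in self.nucleus_shape_model.items():
            out[c].update(pars)
        return out

    def validate(self) -> None:
        h, w = self.field_size
        if h < 64 or w < 64:
            raise SceneSpecError("field_size must be at least 64x64")
        for c, d in self.class_densities.items():
            if c not in CLASSES:
                raise SceneSpecError(f"unknown class {c!r}")
            if d < 0:
                raise SceneSpecError(f"negative density for {c!r}")
        inten = self.resolved_intensity()
        if not (inten["astrocyte"]["hoechst"][0] < inten["neuron"]["hoechst"][0]
                < inten["condensed"]["hoechst"][0]):
            raise SceneSpecError("Hoechst means must be ordered astrocyte < neuron < condensed")
        shp = self.resolved_shape()
        if not (shp["astrocyte"]["diameter"][0] > shp["neuron"]["diameter"][0]
                > shp["condensed"]["diameter"][0]):
            raise SceneSpecError("diameters must be ordered astrocyte > neuron > condensed")
        if not 0 <= self.clump_fraction <= 1 or not 0 <= self.adjacency_fraction <= 1:
            raise SceneSpecError("fractions must be in [0, 1]")


def _jittered_ellipse(rng, center, a, b, theta, jitter, n_vertices=64):
    """Vertex rows/cols of an ellipse with smooth Fourier boundary jitter."""
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(ang)
    if jitter > 0:
        for harm in (2, 3, 5):
            amp = jitter * rng.uniform(0.3, 1.0) / harm
            r += amp * np.cos(harm * ang + rng.uniform(0, 2 * np.pi))
    x = a * r * np.cos(ang)
    y = b * r * np.sin(ang)
    rows = center[0] + x * np.cos(theta) - y * np.sin(theta)
    cols = center[1] + x * np.sin(theta) + y * np.cos(theta)
    return rows, cols


def _rasterize(rows, cols, shape):
    rr, cc = draw_polygon(rows, cols, shape)
    return rr, cc


@dataclass
class _Placed:
    center: tuple[float, float]
    a: float
    b: float
    theta: float
    cls: str
    jitter: float


def _sample_shape(rng, shp):
    d = max(3.0, rng.normal(*shp["diameter"]))
    e = float(np.clip(rng.normal(*shp["eccentricity"]), 0.0, 0.95))
    r = d / 2.0
    # equivalent-diameter-preserving semi-axes: a*b = r^2, b/a = sqrt(1-e^2)
    ratio = math.sqrt(1.0 - e * e)
    a = r / ratio ** 0.5
    b = r * ratio ** 0.5
    return a, b, rng.uniform(0, np.pi)


def render_field(spec: SceneSpec) -> tuple[ChannelStack, GroundTruthScene]:
    """Render one 4-channel field and its exact ground truth.

    Deterministic given ``spec.seed``.  Raises :class:`SceneSpecError` when
    the requested densities cannot be placed in the field, naming the
    limiting class.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    shp_model = spec.resolved_shape()
    inten_model = spec.resolved_intensity()

    counts = {c: int(round(spec.class_densities.get(c, 0))) for c in CLASSES}
    # feasibility: generous packing bound
    occupied = sum(n * math.pi * ((shp_model[c]["diameter"][0] / 2 + 2) ** 2)
                   for c, n in counts.items())
    if occupied > 0.38 * h * w:
        limiting = max(counts, key=lambda c: counts[c] * shp_model[c]["diameter"][0] ** 2)
        raise SceneSpecError(
            f"field too small for requested densities (limiting class: {limiting})")

    placed: list[_Placed] = []
    microglia_idx: list[int] = []

    def radius_of(p: _Placed) -> float:
        return max(p.a, p.b)

    def try_place(cls, mode="isolated", anchor=None, gap=1.5):
        a, b, theta = _sample_shape(rng, shp_model[cls])
        r = max(a, b)
        for _ in range(300):
            if mode == "isolated":
                c = (rng.uniform(r + 2, h - r - 2), rng.uniform(r + 2, w - r - 2))
                ok = all(math.hypot(c[0] - p.center[0], c[1] - p.center[1])
                         >= radius_of(p) + r + gap for p in placed)
            else:
                # place at controlled distance from anchor, clear of others
                dist = mode_dist(anchor, r)
                ang = rng.uniform(0, 2 * np.pi)
                c = (anchor.center[0] + dist * math.cos(ang),
                     anchor.center[1] + dist * math.sin(ang))
                if not (r + 1 < c[0] < h - r - 1 and r + 1 < c[1] < w - r - 1):
                    continue
                ok = all(p is anchor
                         or math.hypot(c[0] - p.center[0], c[1] - p.center[1])
                         >= radius_of(p) + r + gap for p in placed)
            if ok:
                placed.append(_Placed(c, a, b, theta, cls, shp_model[cls]["jitter"]))
                return True
        return False

    def mode_dist(anchor: _Placed, r: float) -> float:
        # touching: centers closer than the sum of mean radii
        ra = (anchor.a + anchor.b) / 2
        return 0.92 * (ra + r)

    # placement order: everything that neurons may clump to / sit next to first
    order = ["microglia", "astrocyte", "other", "condensed", "necrotic", "debris"]
    for cls in order:
        for _ in range(counts[cls]):
            if not try_place(cls):
                raise SceneSpecError(f"could not place all objects (limiting class: {cls})")
            if cls == "microglia":
                microglia_idx.append(len(placed) - 1)

    n_neuron = counts["neuron"]
    n_clump = int(round(spec.clump_fraction * n_neuron))
    n_adj = int(round(spec.adjacency_fraction * n_neuron))
    n_adj = min(n_adj, n_neuron - n_clump)
    n_iso = n_neuron - n_clump - n_adj
    for _ in range(n_iso):
        if not try_place("neuron"):
            raise SceneSpecError("could not place all objects (limiting class: neuron)")
    for _ in range(n_adj):
        if microglia_idx:
            anchor = placed[microglia_idx[int(rng.integers(len(microglia_idx)))]]
            # sit at the rim of the microglial cytoplasm so the neuron border
            # overlaps the IB4 footprint
            cyto = spec.microglia_cytoplasm.get("scale", 1.7)
            a, b, theta = _sample_shape(rng, shp_model["neuron"])
            r = max(a, b)
            done = False
            for _ in range(300):
                ra = (anchor.a + anchor.b) / 2 * cyto
                dist = 0.9 * ra + 0.3 * r
                ang = rng.uniform(0, 2 * np.pi)
                c = (anchor.center[0] + dist * math.cos(ang),
                     anchor.center[1] + dist * math.sin(ang))
                if not (r + 1 < c[0] < h - r - 1 and r + 1 < c[1] < w - r - 1):
                    continue
                if all(p is anchor or math.hypot(c[0] - p.center[0], c[1] - p.center[1])
                       >= radius_of(p) + r + 1.5 for p in placed):
                    placed.append(_Placed(c, a, b, theta, "neuron",
                                          shp_model["neuron"]["jitter"]))
                    done = True
                    break
            if not done:
                raise SceneSpecError("could not place all objects (limiting class: neuron)")
        else:
            if not try_place("neuron"):
                raise SceneSpecError("could not place all objects (limiting class: neuron)")
    for _ in range(n_clump):
        if placed:
            anchor = placed[int(rng.integers(len(placed)))]
            if not try_place("neuron", mode="anchored", anchor=anchor, gap=1.5):
                raise SceneSpecError("could not place all objects (limiting class: neuron)")
        else:
            if not try_place("neuron"):
                raise SceneSpecError("could not place all objects (limiting class: neuron)")

    # rasterize nuclei; earlier-drawn pixels win so touching nuclei share a border
    labels = np.zeros((h, w), dtype=np.int32)
    kept: list[_Placed] = []
    masks: list[tuple[np.ndarray, np.ndarray]] = []
    for p in placed:
        rows, cols = _jittered_ellipse(rng, p.center, p.a, p.b, p.theta, p.jitter)
        rr, cc = _rasterize(rows, cols, (h, w))
        free = labels[rr, cc] == 0
        rr, cc = rr[free], cc[free]
        if rr.size < 5:
            continue  # fully occluded; drop from truth
        lab = len(kept) + 1
        labels[rr, cc] = lab
        kept.append(p)
        masks.append((rr, cc))

    classes = np.array([p.cls for p in kept], dtype=object)
    centroids = np.array([[rr.mean(), cc.mean()] for rr, cc in masks]) \
        if kept else np.zeros((0, 2))

    # clean intensity images
    clean = {}
    for ch in CHANNELS:
        level, grad = spec.background_model.get(ch, (0.0, 0.0))
        yy, xx = np.mgrid[0:h, 0:w]
        direction = rng.uniform(0, 2 * np.pi)
        plane = (yy * math.cos(direction) + xx * math.sin(direction))
        plane = (plane - plane.min()) / max(np.ptp(plane), 1)
        clean[ch] = level + grad * plane

    cyto_labels = np.zeros((h, w), dtype=np.int32)
    cyto_pars = spec.microglia_cytoplasm
    for i, p in enumerate(kept):
        inten = inten_model[p.cls]
        if p.cls == "microglia":
            # IB4 cytoplasm footprint around the nucleus
            rows, cols = _jittered_ellipse(
                rng, p.center, p.a * cyto_pars.get("scale", 1.7),
                p.b * cyto_pars.get("scale", 1.7), p.theta,
                cyto_pars.get("irregularity", 0.08), n_vertices=128)
            rr, cc = _rasterize(rows, cols, (h, w))
            cyto_labels[rr, cc] = i + 1
            amp = max(0.0, rng.normal(*inten["ib4"]))
            clean["ib4"][rr, cc] += amp
        rr, cc = masks[i]
        for ch in CHANNELS:
            if p.cls == "microglia" and ch == "ib4":
                continue  # painted on the cytoplasm already
            amp = max(0.0, rng.normal(*inten[ch]))
            if p.cls == "neuron" and ch == "neuo":
                # NeuO stains the neuronal soma: nucleus plus a thin halo
                rows2, cols2 = _jittered_ellipse(
                    rng, p.center, p.a * 1.25, p.b * 1.25, p.theta, p.jitter)
                rr2, cc2 = _rasterize(rows2, cols2, (h, w))
                clean[ch][rr2, cc2] += amp
            else:
                clean[ch][rr, cc] += amp

    # shot + read noise
    ps = spec.noise_model.get("poisson_scale", 0.0)
    read = spec.noise_model.get("read_sd", 0.0)
    images = {}
    for ch in CHANNELS:
        im = clean[ch]
        if ps and ps > 0:
            im = rng.poisson(np.clip(im, 0, None) * ps).astype(np.float64) / ps
        if read and read > 0:
            im = im + rng.normal(0, read, size=im.shape)
        images[ch] = np.clip(im, 0, None)

    stack = ChannelStack(channels=images, pixel_size=spec.pixel_size)
    truth = GroundTruthScene(label_mask=labels, classes=classes,
                             centroids=centroids, cytoplasm_mask=cyto_labels)
    return stack, truth


def label_objects_from_truth(predicted: np.ndarray, truth: GroundTruthScene,
                             min_overlap: float = 0.5):
    """Assign each predicted object the class of the truth object it overlaps.

    Majority-pixel vote; objects whose dominant truth overlap is below
    ``min_overlap`` of their own area get ``None``.  Returns an object array
    of length ``predicted.max()``.
    """
    if predicted.shape != truth.label_mask.shape:
        raise ValueError("shape mismatch between predicted and truth masks")
    npred = int(predicted.max())
    out = np.full(npred, None, dtype=object)
    if npred == 0:
        return out
    t = truth.label_mask
    both = (predicted > 0)
    pairs = predicted[both].astype(np.int64) * (int(t.max()) + 1) + t[both]
    uniq, cnt = np.unique(pairs, return_counts=True)
    pred_ids = uniq // (int(t.max()) + 1)
    truth_ids = uniq % (int(t.max()) + 1)
    areas = np.bincount(predicted.ravel(), minlength=npred + 1)
    best = {}
    for pid, tid, n in zip(pred_ids, truth_ids, cnt):
        if tid == 0:
            continue
        if pid not in best or n > best[pid][1]:
            best[pid] = (tid, n)
    for pid, (tid, n) in best.items():
        if n / areas[pid] >= min_overlap:
            out[pid - 1] = truth.classes[tid - 1]
    return out
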