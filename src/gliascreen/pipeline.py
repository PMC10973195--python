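"""End-to-end orchestration of the screen analysis.

``run_full_pipeline`` runs either from field images (synthetic or TIFF) —
segmentation, feature measurement, classification, per-well aggregation —
or directly from a collated per-well counts table ("counts-only" mode, for
reanalyzing deposited image-level data); both converge on the same
downstream statistics: QC, Min-Max normalization, assay-quality metrics,
Dunnett hit calling and phenotype clustering.  Every run writes its
resolved configuration and a manifest (config hash + seed) into a fresh run
directory; re-running the same config and seed reproduces the CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification as clf
from . import io as gio
from . import phenotype as ph
from . import screen_stats as ss
from .screen_sim import ScreenDesign, default_compounds, simulate_screen
from .segmentation import segment_nuclei
from .features import DEFAULT_SCHEMA, measure_objects, feature_columns
from .morphology import microglia_morphology
from .simulate import CLASSES, SceneSpec, render_field, label_objects_from_truth


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    out_dir: str = "runs/run"
    mode: str = "counts"            # "counts" | "images" | "simulate"
    counts_csv: str | None = None   # counts mode input
    seed: int = 0
    # simulate mode
    n_repeats: int = 2
    plates_per_repeat: int = 1
    plate_rows: int = 8
    plate_cols: int = 8
    n_compounds: int = 8
    n_control_replicates: int = 6
    fields_per_well: int = 4
    # imaging-stage parameters
    n_fields: int = 12
    sigma: float = 1.0
    min_area: int = 20
    declump: bool = True
    per_class: int = 60
    # statistics
    alpha: float = 0.05
    k_clusters: int = 3
    control: str = "DMSO"
    positive_control: str = "BAY61"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _controls(cfg: RunConfig) -> dict:
    from .screen_sim import ARCHETYPES
    return {"DMSO": (ARCHETYPES["null"], cfg.n_control_replicates),
            cfg.positive_control: (ARCHETYPES["positive_control"],
                                   cfg.n_control_replicates)}


#: per-field baseline object counts for the imaging demonstration path
FIELD_BASELINE = {"neuron": 40, "microglia": 10, "astrocyte": 12, "other": 10,
                  "condensed": 10, "necrotic": 4, "debris": 12}


def _field_densities(arch, lps: bool, lps_effects: dict) -> dict:
    """Expected per-field object counts for a well's condition."""
    dens = {}
    for cls, base in FIELD_BASELINE.items():
        eff = lps_effects.get(cls, 1.0)
        if cls == "neuron":
            mu = (base * eff + arch.neuron_protection * (base - base * eff)
                  if lps else base * arch.neuron_toxicity_lpsneg)
        elif cls == "microglia":
            mu = base * (eff * arch.microglia_multiplier_lps if lps
                         else arch.microglia_multiplier_nolps)
        elif cls == "astrocyte":
            mu = base * (eff if lps else 1.0) * arch.astrocyte_multiplier
        elif cls == "necrotic":
            mu = base * (eff if lps else 1.0) * arch.necrotic_multiplier
        else:
            mu = base * (eff if lps else 1.0)
        dens[cls] = max(0, round(mu))
    return dens


def _counts_from_images(cfg: RunConfig, out: Path) -> pd.DataFrame:
    """Simulate fields, run the imaging stages, and emit a tiny counts table.

    A compact demonstration path: one simulated field per well of a small
    chequerboard layout, classified by a forest trained on ground-truth
    labels from held-out fields.
    """
    rng = np.random.default_rng(cfg.seed)
    # train a classifier on ground-truth-labeled objects from training fields
    pool, labels = [], []
    for i in range(cfg.n_fields):
        spec = SceneSpec(seed=int(rng.integers(2 ** 31)))
        stack, truth = render_field(spec)
        mask = segment_nuclei(stack["hoechst"], sigma=cfg.sigma,
                              min_area=cfg.min_area, declump=cfg.declump)
        ft = measure_objects(stack, mask)
        cls = label_objects_from_truth(mask, truth)
        keep = np.array([c is not None for c in cls])
        pool.append(ft[keep])
        labels.append(cls[keep])
    pool_df = pd.concat(pool, ignore_index=True)
    y = np.concatenate(labels)
    ts = clf.assemble_training_set(pool_df, y, per_class=cfg.per_class,
                                  feature_cols=feature_columns(pool_df),
                                  seed=cfg.seed)
    model = clf.train_classifier(ts, seed=cfg.seed)
    model.save(out / "classifier.pkl")

    # classify one field per well of a small layout and aggregate
    design = ScreenDesign(
        n_repeats=cfg.n_repeats, plates_per_repeat=cfg.plates_per_repeat,
        plate_rows=cfg.plate_rows, plate_cols=cfg.plate_cols,
        compounds=default_compounds(cfg.n_compounds),
        controls=_controls(cfg), seed=cfg.seed)
    layout, _ = simulate_screen(design)
    arch_of = {cid: a for cid, a in design.compounds}
    for cid, (a, _) in design.controls.items():
        arch_of[cid] = a
    rows = []
    for _, wrow in layout.iterrows():
        dens = _field_densities(arch_of[wrow["compound_id"]], bool(wrow["lps"]),
                                design.lps_effects)
        spec = SceneSpec(class_densities=dens, seed=int(rng.integers(2 ** 31)))
        stack, truth = render_field(spec)
        mask = segment_nuclei(stack["hoechst"], sigma=cfg.sigma,
                              min_area=cfg.min_area, declump=cfg.declump)
        ft = measure_objects(stack, mask)
        pred = clf.classify_objects(model, ft)
        counts = {c: int(np.sum(pred == c)) for c in CLASSES}
        morph = microglia_morphology(stack, mask, pred)
        rows.append({**wrow[["repeat", "plate", "row", "column", "well",
                             "compound_id", "lps"]].to_dict(),
                     **counts,
                     "median_formfactor": morph.median_formfactor})
    return pd.DataFrame(rows)


def run_full_pipeline(cfg: RunConfig) -> Path:
    """Run the configured pipeline; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    (out / "manifest.json").write_text(json.dumps(
        {"config_hash": cfg.config_hash, "seed": cfg.seed}, indent=2))

    if cfg.mode == "counts":
        if not cfg.counts_csv:
            raise ValueError("counts mode requires counts_csv")
        counts = gio.read_counts(cfg.counts_csv)
    elif cfg.mode == "simulate":
        design = ScreenDesign(
            n_repeats=cfg.n_repeats, plates_per_repeat=cfg.plates_per_repeat,
            plate_rows=cfg.plate_rows, plate_cols=cfg.plate_cols,
            compounds=default_compounds(cfg.n_compounds),
            controls=_controls(cfg), seed=cfg.seed)
        counts, truth = simulate_screen(design)
        truth.to_csv(out / "truth.csv", index=False)
    elif cfg.mode == "images":
        counts = _counts_from_images(cfg, out)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    gio.write_counts(out / "well_counts.csv", counts)

    # QC
    try:
        qc = ss.qc_plates(counts, control=cfg.control)
        qc.plate_pca.to_csv(out / "qc_plate_pca.csv", index=False)
        (out / "qc_flags.json").write_text(json.dumps(
            [list(map(str, f)) for f in qc.flagged], indent=2))
    except ss.ScreenStatsError as exc:
        (out / "qc_flags.json").write_text(json.dumps({"skipped": str(exc)}))

    # normalization + assay quality
    nc, anchors = ss.minmax_normalize(counts)
    gio.write_counts(out / "normalized_counts.csv", nc)
    dmso = nc[nc["compound_id"] == cfg.control]
    metrics: dict = {}
    try:
        metrics["zprime_dmso"] = ss.zprime(
            dmso.loc[~dmso["lps"], "normalized_neuron"],
            dmso.loc[dmso["lps"], "normalized_neuron"])
        metrics["robust_zfactor_dmso"] = ss.robust_zfactor(
            dmso.loc[~dmso["lps"], "normalized_neuron"],
            dmso.loc[dmso["lps"], "normalized_neuron"])
        metrics["cv_reduction_percent"] = ss.cv_reduction(counts, nc)
    except ss.ScreenStatsError as exc:
        metrics["warning"] = str(exc)

    # hit calling: protection (LPS+) and toxicity (LPS-) from one family pair
    hits = ss.call_hits(nc, response="normalized_neuron",
                        control=cfg.control, alpha=cfg.alpha)
    hits.to_csv(out / "hit_table.csv", index=False)
    protective = hits[(hits["lps"]) & hits["significant"]
                      & (hits["mean_diff"] < 0)]["compound_id"].tolist()
    metrics["n_hits"] = len(protective)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    # phenotype clustering of hits + control
    pm = ph.build_phenotype_matrix(counts)
    keep = [c for c in protective + [cfg.control] if c in pm.values.index]
    if len(keep) >= max(2, cfg.k_clusters):
        pm_hits = ph.build_phenotype_matrix(counts, compounds=keep)
        cr = ph.cluster_phenotypes(pm_hits, k=min(cfg.k_clusters, len(keep)))
        pm_hits.values.loc[cr.order].to_csv(out / "phenotype_matrix.csv")
        cr.assignments.rename("category").to_csv(out / "clusters.csv")
        ph.heatmap(pm_hits, cr, path=out / "heatmap.png")
        summary = ph.summarize_categories(cr, hits, pm_hits,
                                          exclude=(cfg.control,))
        summary.to_csv(out / "category_summary.csv", index=False)
    else:
        pm.values.to_csv(out / "phenotype_matrix.csv")
    return out
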