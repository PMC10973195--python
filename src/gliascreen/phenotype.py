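"""Phenotypic profiling of hit compounds.

Builds the compounds x phenotype matrix — per-compound mean counts of each
cell class and median microglial FormFactor, with and without LPS (14
columns) — min-max normalizes each parameter jointly across its two LPS
columns, clusters rows by complete-linkage hierarchical clustering on
Euclidean distances, and summarizes the mechanistic categories a cut of
the tree produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .simulate import CLASSES

PHENOTYPE_PARAMS = (*CLASSES[:6], "median_formfactor")  # debris excluded


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeMatrix:
    values: pd.DataFrame            # rows compounds, 14 normalized columns
    raw: pd.DataFrame               # same layout, unnormalized means
    normalized: bool = True


@dataclass
class ClusterResult:
    linkage: np.ndarray
    assignments: pd.Series          # compound -> cluster id (1..k)
    order: list = field(default_factory=list)  # leaf order for heatmaps

    @property
    def k(self) -> int:
        return int(self.assignments.nunique())


def build_phenotype_matrix(counts: pd.DataFrame,
                           compounds: list | None = None,
                           params: tuple = PHENOTYPE_PARAMS) -> PhenotypeMatrix:
    """Per-compound mean profiles, min-max normalized per parameter.

    Means are taken over repeat means (each repeat contributes equally).
    Normalization for a parameter uses the joint min and max across both its
    LPS columns over all compounds present in ``counts``; filtering to a
    subset (``compounds``) happens after normalization so that hit-only
    matrices reuse the all-compound scaling.  A parameter constant across
    all rows maps to 0.5 with a warning.
    """
    missing = [p for p in params if p not in counts.columns]
    if missing:
        raise PhenotypeError(f"columns missing from counts table: {missing}")
    rep_means = (counts.groupby(["compound_id", "lps", "repeat"], observed=True)[list(params)]
                 .mean().groupby(["compound_id", "lps"], observed=True).mean())
    raw = rep_means.unstack("lps")
    raw.columns = [f"{p}_{'LPS+' if bool(l) else 'LPS-'}" for p, l in raw.columns]
    ordered = [f"{p}_{s}" for p in params for s in ("LPS-", "LPS+")]
    raw = raw[ordered]

    norm = raw.copy()
    for p in params:
        cols = [f"{p}_LPS-", f"{p}_LPS+"]
        block = raw[cols].to_numpy(dtype=float)
        finite = block[np.isfinite(block)]
        if finite.size == 0 or finite.max() == finite.min():
            warnings.warn(f"parameter {p!r} constant; columns set to 0.5", stacklevel=2)
            norm[cols] = 0.5
        else:
            lo, hi = finite.min(), finite.max()
            norm[cols] = (block - lo) / (hi - lo)
    if compounds is not None:
        keep = [c for c in compounds if c in norm.index]
        norm = norm.loc[keep]
        raw = raw.loc[keep]
    return PhenotypeMatrix(values=norm, raw=raw, normalized=True)


def cluster_phenotypes(pm: PhenotypeMatrix, k: int) -> ClusterResult:
    """Complete-linkage Euclidean clustering cut into ``k`` clusters.

    Deterministic for a given row order; distance ties are broken by row
    index (scipy's ordering), so tie-sensitive inputs should be ordered
    deliberately.
    """
    X = pm.values.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise PhenotypeError(f"k={k} exceeds {n} rows")
    if k < 1:
        raise PhenotypeError("k must be >= 1")
    if not np.isfinite(X).all():
        raise PhenotypeError("phenotype matrix has non-finite entries")
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    order = [pm.values.index[i] for i in leaves_list(Z)]
    return ClusterResult(linkage=Z,
                         assignments=pd.Series(labels, index=pm.values.index),
                         order=order)


def summarize_categories(cr: ClusterResult, hits: pd.DataFrame,
                         pm: PhenotypeMatrix,
                         exclude: tuple = ("DMSO",)) -> pd.DataFrame:
    """Per-category mean phenotype and protection summary.

    ``hits`` is a hit table with ``compound_id, lps, protection_percent``.
    Reference rows (DMSO) are excluded from summaries; empty categories are
    dropped with a warning.
    """
    prot = (hits[hits["lps"].astype(bool)]
            .set_index("compound_id")["protection_percent"])
    rows = []
    for cat in sorted(cr.assignments.unique()):
        members = [c for c in cr.assignments.index[cr.assignments == cat]
                   if c not in exclude]
        if not members:
            warnings.warn(f"category {cat} empty after exclusions", stacklevel=2)
            continue
        raw = pm.raw.loc[members]
        row = {"category": cat, "n_compounds": len(members),
               "members": ",".join(map(str, members)),
               "mean_protection_percent": float(prot.reindex(members).mean())}
        for col in pm.raw.columns:
            row[f"mean_{col}"] = float(raw[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap(pm: PhenotypeMatrix, cr: ClusterResult | None = None, path=None):
    """Write the ordered normalized matrix as a heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cr.order if cr is not None else list(pm.values.index)
    data = pm.values.loc[order]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(data))))
    im = ax.imshow(data.to_numpy(dtype=float), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="min-max normalized value")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
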