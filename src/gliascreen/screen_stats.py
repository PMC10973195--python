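"""Plate-screen statistics: aggregation, QC, normalization and hit calling.

The analysis chain mirrors how the neuroprotection screen is analyzed:

* per-well per-class counts are aggregated over a well's fields;
* plate-level QC uses PCA of standardized per-plate count summaries with
  ROUT (FDR-controlled robust outlier detection, Q = 1%) on the principal
  components;
* neuron and microglia counts are Min-Max normalized per biological repeat,
  anchoring the repeat-wise LPS-condition medians to 0 and 1 (direction
  chosen per cell type: neurons fall with LPS, microglia rise);
* assay quality is summarized by the Z'-factor and its robust
  (median/MAD) variant;
* hits are called by a repeated-measures two-way model on repeat-level
  condition means (repeat as block) with Dunnett many-to-one comparisons of
  every compound against DMSO within each LPS level.  The LS mean
  difference is DMSO - compound, so -1 is full protection back to LPS-
  neuron levels and protection% = -100 x difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from ._dunnett import dunnett_crit, dunnett_sf
from .simulate import CLASSES


class ScreenStatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# aggregation

def aggregate_well_counts(field_counts: pd.DataFrame, layout: pd.DataFrame,
                          expected_fields: int = 4) -> pd.DataFrame:
    """Sum per-field class counts into per-well counts.

    ``field_counts`` has one row per field with ``repeat, plate, well, field``
    and per-class counts; ``layout`` maps ``repeat, plate, well`` to
    ``compound_id`` and ``lps``.  Wells with fewer than ``expected_fields``
    fields are flagged ``partial``; fields whose well is not in the layout
    raise.
    """
    key = ["repeat", "plate", "well"]
    known = set(map(tuple, layout[key].itertuples(index=False)))
    seen = set(map(tuple, field_counts[key].drop_duplicates().itertuples(index=False)))
    unknown = seen - known
    if unknown:
        raise ScreenStatsError(f"fields map to unknown wells: {sorted(unknown)[:5]}")
    class_cols = [c for c in CLASSES if c in field_counts.columns]
    agg = {c: "sum" for c in class_cols}
    if "median_formfactor" in field_counts.columns:
        agg["median_formfactor"] = "mean"  # per-well: mean of the image medians
    out = (field_counts.groupby(key, as_index=False)
           .agg(n_fields=("field", "nunique"), **{c: (c, f) for c, f in agg.items()}))
    out["partial"] = out["n_fields"] < expected_fields
    return out.merge(layout, on=key, how="left")


# --------------------------------------------------------------------------
# outliers / QC

def rout_outliers(values, Q: float = 1.0) -> np.ndarray:
    """ROUT-style robust outlier flags at FDR level ``Q`` percent.

    Robust center = median; robust scale (RSDR) = 68.27th percentile of
    absolute residuals, the robust analog of one standard deviation.  The
    30% most extreme points are then tested from the outside in with an
    FDR-controlled (Benjamini-Hochberg) threshold on their t-tail
    probabilities.  If the robust scale is zero, any point off the median is
    infinitely many robust SDs away and is flagged; identical values yield
    no flags.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise ScreenStatsError("need at least 5 values for outlier analysis")
    med = np.median(x)
    resid = x - med
    rsdr = np.percentile(np.abs(resid), 68.27) * n / max(n - 1, 1)
    flags = np.zeros(n, dtype=bool)
    if rsdr == 0:
        flags[resid != 0] = True
        return flags
    order = np.argsort(-np.abs(resid))
    m = max(1, int(np.floor(0.3 * n)))
    cand = order[:m]
    t = np.abs(resid[cand]) / rsdr
    p = 2 * sps.t.sf(t, df=n - 1)
    q = Q / 100.0
    # BH from the most extreme inward: flag the largest prefix passing
    keep = 0
    for i in range(m):
        if p[i] <= q * (i + 1) / n:
            keep = i + 1
    # ensure prefix property (p sorted by extremeness, may not be monotone)
    flags[cand[:keep]] = True
    return flags


@dataclass
class QCReport:
    plate_pca: pd.DataFrame                 # per-plate PC coordinates
    flagged: list = field(default_factory=list)   # (repeat, plate, reason)
    row_trend: pd.DataFrame | None = None
    col_trend: pd.DataFrame | None = None


def qc_plates(counts: pd.DataFrame, control: str = "DMSO",
              rout_q: float = 1.0) -> QCReport:
    """Plate-level QC from control-well counts.

    Standardizes per-plate median class counts of LPS-untreated control
    wells (robustly, by median and scaled MAD, so a deviant plate cannot
    mask itself by inflating the column scale), projects onto the first two
    principal components, and flags plates that are ROUT outliers on either
    component.  Also reports row/column marginal trends of neuron counts
    over all wells.
    """
    class_cols = [c for c in CLASSES if c in counts.columns]
    ctrl = counts[(counts["compound_id"] == control) & (~counts["lps"].astype(bool))]
    if ctrl.empty:
        raise ScreenStatsError(f"no LPS- wells for control {control!r}")
    per_plate = ctrl.groupby(["repeat", "plate"])[class_cols].median()
    if len(per_plate) < 3:
        raise ScreenStatsError("need at least 3 plates for QC")
    X = per_plate.to_numpy(dtype=float)
    center = np.median(X, axis=0)
    scale = np.median(np.abs(X - center), axis=0) * 1.4826
    fallback = X.std(axis=0)
    scale = np.where(scale > 0, scale, np.where(fallback > 0, fallback, 1.0))
    Xs = (X - center) / scale
    ncomp = min(2, Xs.shape[1], len(per_plate))
    pca = PCA(n_components=ncomp)
    pcs = pca.fit_transform(Xs)
    pca_df = pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(ncomp)],
                          index=per_plate.index).reset_index()
    flagged = []
    if len(per_plate) >= 5:
        for i in range(ncomp):
            fl = rout_outliers(pcs[:, i], Q=rout_q)
            for (rep, plate), f in zip(per_plate.index, fl):
                if f:
                    flagged.append((rep, plate, f"PC{i + 1} outlier (ROUT Q={rout_q}%)"))
    row_trend = counts.groupby("row")["neuron"].mean().reset_index() \
        if "row" in counts.columns else None
    col_trend = counts.groupby("column")["neuron"].mean().reset_index() \
        if "column" in counts.columns else None
    return QCReport(plate_pca=pca_df, flagged=sorted(set(flagged)),
                    row_trend=row_trend, col_trend=col_trend)


# --------------------------------------------------------------------------
# normalization

#: direction of the LPS response per normalized class: neurons fall with
#: LPS (LPS- median -> 1), microglia rise (LPS+ median -> 1)
NORMALIZED_CLASSES = {"neuron": "down", "microglia": "up"}


def minmax_normalize(counts: pd.DataFrame,
                     classes: dict = NORMALIZED_CLASSES,
                     anchor_wells: str = "all",
                     control: str = "DMSO") -> tuple[pd.DataFrame, dict]:
    """Adapted Min-Max normalization anchored on repeat-wise LPS medians.

    For a falling class (neurons): x -> (x - med_LPS+)/(med_LPS- - med_LPS+),
    so the LPS- median maps to exactly 1 and the LPS+ median to exactly 0.
    For a rising class (microglia) the anchors swap.  Anchors are computed
    per repeat from all wells (``anchor_wells="all"``) or control wells only
    (``"control"``).  Returns the table with ``normalized_<class>`` columns
    plus the anchor dictionary ``{(repeat, class): (med_lpsneg, med_lpspos)}``.
    """
    out = counts.copy()
    anchors: dict = {}
    lps = out["lps"].astype(bool)
    for rep, grp in out.groupby("repeat"):
        sel = grp if anchor_wells == "all" else grp[grp["compound_id"] == control]
        if sel["lps"].astype(bool).nunique() < 2:
            raise ScreenStatsError(f"repeat {rep} lacks one of the LPS levels")
        for cls, direction in classes.items():
            med_neg = sel.loc[~sel["lps"].astype(bool), cls].median()
            med_pos = sel.loc[sel["lps"].astype(bool), cls].median()
            if med_neg == med_pos:
                raise ScreenStatsError(
                    f"equal LPS anchors for {cls!r} in repeat {rep}")
            anchors[(rep, cls)] = (med_neg, med_pos)
            mask = out["repeat"] == rep
            x = out.loc[mask, cls].astype(float)
            if direction == "down":
                out.loc[mask, f"normalized_{cls}"] = (x - med_pos) / (med_neg - med_pos)
            else:
                out.loc[mask, f"normalized_{cls}"] = (x - med_neg) / (med_pos - med_neg)
    return out, anchors


# --------------------------------------------------------------------------
# assay-quality metrics

def zprime(positive, negative) -> float:
    """Z'-factor: 1 - 3(sd_p + sd_n)/|mean_p - mean_n| (sample sds)."""
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ScreenStatsError("need at least 2 values per group")
    dm = abs(p.mean() - n.mean())
    if dm == 0:
        raise ScreenStatsError("group means are equal; Z'-factor undefined")
    return 1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / dm


def robust_zfactor(positive, negative) -> float:
    """Z'-factor with medians and scaled MADs (x1.4826) for mean/sd."""
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ScreenStatsError("need at least 2 values per group")
    mp, mn = np.median(p), np.median(n)
    if mp == mn:
        raise ScreenStatsError("group medians are equal; robust Z-factor undefined")
    madp = np.median(np.abs(p - mp)) * 1.4826
    madn = np.median(np.abs(n - mn)) * 1.4826
    return 1.0 - 3.0 * (madp + madn) / abs(mp - mn)


def cv_reduction(raw: pd.DataFrame, normalized: pd.DataFrame,
                 raw_col: str = "neuron", norm_col: str = "normalized_neuron",
                 rel_floor: float = 0.05) -> float:
    """Percent reduction in the average per-condition CV after normalization.

    CV = sd/mean per condition (compound x LPS level).  Conditions whose
    |mean| falls below ``rel_floor`` times the largest |condition mean| in
    either table are excluded from both (CV is undefined near a zero mean;
    this removes normalized LPS+ conditions of inactive compounds, whose
    anchor-mapped mean is ~0 by construction and sits well below 5% of the
    LPS- level, while any condition with a real response sits well above).
    Exclusions are matched across tables and warned about.
    """
    def condition_stats(df, col):
        g = df.groupby(["compound_id", "lps"])[col]
        return g.mean(), g.std(ddof=1)

    m_raw, s_raw = condition_stats(raw, raw_col)
    m_nrm, s_nrm = condition_stats(normalized, norm_col)
    common = m_raw.index.intersection(m_nrm.index)
    if len(common) == 0:
        raise ScreenStatsError("no matched conditions between tables")
    m_raw, s_raw = m_raw.loc[common], s_raw.loc[common]
    m_nrm, s_nrm = m_nrm.loc[common], s_nrm.loc[common]
    keep = ((np.abs(m_raw) >= rel_floor * np.abs(m_raw).max())
            & (np.abs(m_nrm) >= rel_floor * np.abs(m_nrm).max())
            & (m_raw != 0) & (m_nrm != 0))
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} near-zero-mean conditions excluded from CV",
                      stacklevel=2)
    if not keep.any():
        raise ScreenStatsError("all conditions excluded from CV comparison")
    cv_raw = (s_raw[keep] / m_raw[keep]).abs().mean()
    cv_nrm = (s_nrm[keep] / m_nrm[keep]).abs().mean()
    return 100.0 * (1.0 - cv_nrm / cv_raw)


# --------------------------------------------------------------------------
# hit calling

def protection_percent(mean_diff: float) -> float:
    """Protection % from the LS mean difference (DMSO - compound, LPS+).

    -1 (compound restores neurons to the LPS- median) maps to 100%.
    """
    return -100.0 * mean_diff


def _blocked_fit(cm: pd.DataFrame):
    """Residual MSE/df of y ~ condition + repeat on a conditions x repeats table."""
    R = cm.shape[1]
    if cm.notna().all().all():
        # balanced: residual by double centering
        Y = cm.to_numpy(dtype=float)
        E = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + Y.mean()
        df_err = (Y.shape[0] - 1) * (R - 1)
        mse = float((E ** 2).sum() / df_err)
        cell_means = pd.Series(Y.mean(axis=1), index=cm.index)
        n_per_cell = pd.Series(R, index=cm.index)
    else:
        # unbalanced: OLS on the available condition means, reduced df
        long = cm.stack().rename("y").reset_index()
        X_cell = pd.get_dummies(long.iloc[:, 0], drop_first=False)
        X_rep = pd.get_dummies(long["repeat"], drop_first=True)
        X = np.column_stack([X_cell.to_numpy(float), X_rep.to_numpy(float)])
        y = long["y"].to_numpy(float)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df_err = len(y) - rank
        if df_err <= 0:
            raise ScreenStatsError("no residual degrees of freedom")
        mse = float((resid ** 2).sum() / df_err)
        cell_means = cm.mean(axis=1)
        n_per_cell = cm.notna().sum(axis=1)
    return mse, df_err, cell_means, n_per_cell


def call_hits(nc: pd.DataFrame, response: str = "normalized_neuron",
              control: str = "DMSO", alpha: float = 0.05) -> pd.DataFrame:
    """Repeated-measures Dunnett hit calling against the shared control.

    Condition means are computed per repeat (repeat = blocking factor) and a
    blocked model ``response ~ treatment + repeat`` is fitted within each LPS
    level; its residual error is the Dunnett error term for that family.
    The error term is per LPS family rather than pooled across both because
    the normalized response has an order of magnitude more variance in LPS-
    than in LPS+ wells; pooling would anti-conservatively shrink the LPS-
    standard errors.  Every compound is compared to the control within its
    family; p-values are adjusted via the equicorrelated multivariate-t
    distribution of the many-to-one contrasts.

    Returns one row per compound x LPS level with the LS mean difference
    (control - compound), its simultaneous CI, adjusted p, significance
    flag, and protection % for LPS+ rows (-1 difference = 100% protection).
    """
    if control not in set(nc["compound_id"]):
        raise ScreenStatsError(f"control {control!r} absent from the table")
    df = nc.dropna(subset=[response])
    rows = []
    attrs = {}
    for lps in (False, True):
        sub = df[df["lps"].astype(bool) == lps]
        if sub.empty:
            continue
        cm = (sub.groupby(["compound_id", "repeat"], observed=True)[response]
              .mean().unstack("repeat"))
        if cm.shape[1] < 2:
            raise ScreenStatsError("need at least 2 repeats")
        if control not in cm.index:
            raise ScreenStatsError(f"control missing at LPS={lps}")
        mse, df_err, cell_means, n_per_cell = _blocked_fit(cm)
        comp_ids = [cid for cid in cm.index if cid != control]
        k = len(comp_ids)
        if k == 0:
            continue
        crit = dunnett_crit(alpha, k, df_err)
        diffs = np.array([cell_means[control] - cell_means[cid] for cid in comp_ids])
        ses = np.array([np.sqrt(mse * (1.0 / n_per_cell[control] + 1.0 / n_per_cell[cid]))
                        for cid in comp_ids])
        with np.errstate(divide="ignore"):
            tvals = np.where(ses > 0, diffs / ses, np.inf)
        padj = np.atleast_1d(dunnett_sf(np.abs(tvals), k, df_err))
        for cid, d, se, t, p in zip(comp_ids, diffs, ses, tvals, padj):
            rows.append({
                "compound_id": cid, "lps": lps, "mean_diff": float(d),
                "ci_low": float(d - crit * se), "ci_high": float(d + crit * se),
                "t": float(t), "p_adj": float(p), "significant": bool(p < alpha),
                "protection_percent": protection_percent(d) if lps else np.nan,
            })
        attrs[f"df_err_lps{'+' if lps else '-'}"] = df_err
        attrs[f"mse_lps{'+' if lps else '-'}"] = mse
    out = pd.DataFrame(rows)
    out.attrs.update(attrs)
    out.attrs["alpha"] = alpha
    return out
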