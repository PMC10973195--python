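"""Screen statistics: aggregation, ROUT, QC, normalization, Z', hit calling."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gliascreen as gs
from gliascreen.screen_sim import ARCHETYPES, EffectArchetype, ScreenDesign, \
    default_compounds, simulate_screen
from gliascreen.screen_stats import (ScreenStatsError, aggregate_well_counts,
                                     call_hits, cv_reduction, minmax_normalize,
                                     protection_percent, qc_plates,
                                     robust_zfactor, rout_outliers, zprime)
from gliascreen.simulate import CLASSES


# ------------------------------------------------------------ aggregation

def _field_table():
    rows = []
    for field, n in enumerate([2, 3, 4, 5], start=1):
        rows.append(dict(repeat=1, plate=1, well="A1", field=field, neuron=n,
                         microglia=1, astrocyte=0, other=0, condensed=0,
                         necrotic=0, debris=0))
    rows.append(dict(repeat=1, plate=1, well="A2", field=1, neuron=7,
                     microglia=0, astrocyte=2, other=0, condensed=0,
                     necrotic=0, debris=0))
    return pd.DataFrame(rows)


def _layout():
    return pd.DataFrame([
        dict(repeat=1, plate=1, well="A1", compound_id="DMSO", lps=False),
        dict(repeat=1, plate=1, well="A2", compound_id="C001", lps=True),
    ])


def test_well_counts_sum_over_fields():
    out = aggregate_well_counts(_field_table(), _layout())
    a1 = out[out.well == "A1"].iloc[0]
    assert a1["neuron"] == 14 and a1["n_fields"] == 4 and not a1["partial"]


def test_missing_field_flagged_partial():
    out = aggregate_well_counts(_field_table(), _layout())
    a2 = out[out.well == "A2"].iloc[0]
    assert a2["partial"] and a2["n_fields"] == 1
    # disjoint wells do not cross-contaminate
    assert a2["neuron"] == 7 and a2["astrocyte"] == 2


def test_unknown_well_rejected():
    fields = _field_table()
    fields.loc[0, "well"] = "Z9"
    with pytest.raises(ScreenStatsError):
        aggregate_well_counts(fields, _layout())


# ------------------------------------------------------------ ROUT

def test_single_gross_outlier_flagged():
    flags = rout_outliers([10, 10, 10, 10, 10, 100])
    assert list(flags) == [False] * 5 + [True]


def test_identical_values_no_flags():
    assert not rout_outliers([7.0] * 10).any()


def test_null_false_positive_rate_controlled():
    rng = np.random.default_rng(0)
    fractions = [rout_outliers(rng.normal(size=1000), Q=1.0).mean()
                 for _ in range(200)]
    assert np.mean(fractions) <= 0.03   # Q = 1%, 3x tolerance


def test_too_few_values_rejected():
    with pytest.raises(ScreenStatsError):
        rout_outliers([1, 2, 3])


# ------------------------------------------------------------ plate QC

def _plate_counts(n_plates=8, bad_plate=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for plate in range(1, n_plates + 1):
        neuron_scale = 0.75 if plate == bad_plate else 1.0
        necrotic_scale = 4.0 if plate == bad_plate else 1.0
        for w in range(6):
            rows.append(dict(
                repeat=1, plate=plate, row=w + 1, column=1, well=f"{plate}-{w}",
                compound_id="DMSO", lps=False,
                neuron=int(2000 * neuron_scale + rng.normal(0, 30)),
                microglia=int(150 + rng.normal(0, 6)),
                astrocyte=int(120 + rng.normal(0, 5)),
                other=int(80 + rng.normal(0, 4)),
                condensed=int(100 + rng.normal(0, 5)),
                necrotic=int(30 * necrotic_scale + rng.normal(0, 3)),
                debris=int(150 + rng.normal(0, 6))))
    return pd.DataFrame(rows)


def test_identical_plates_not_flagged():
    # byte-identical plates: no variation, nothing to flag
    rows = []
    for plate in range(1, 9):
        for w in range(6):
            rows.append(dict(repeat=1, plate=plate, row=w + 1, column=1,
                             well=f"{plate}-{w}", compound_id="DMSO", lps=False,
                             neuron=2000, microglia=150, astrocyte=120, other=80,
                             condensed=100, necrotic=30, debris=150))
    report = qc_plates(pd.DataFrame(rows))
    assert report.flagged == []
    assert {"PC1", "PC2"} <= set(report.plate_pca.columns)


def test_low_neuron_high_necrosis_plate_flagged():
    counts = _plate_counts(bad_plate=3)
    report = qc_plates(counts)
    assert any(plate == 3 for _, plate, _ in report.flagged)


def test_too_few_plates_rejected():
    with pytest.raises(ScreenStatsError):
        qc_plates(_plate_counts(n_plates=2))


def test_row_column_trends_flat_without_nuisance():
    design = ScreenDesign(n_repeats=2, plates_per_repeat=3, plate_rows=8,
                          plate_cols=8, compounds=default_compounds(20),
                          nuisance={"repeat": 0, "plate": 0, "row": 0, "column": 0},
                          controls={"DMSO": (ARCHETYPES["null"], 6)}, seed=0)
    obs, _ = simulate_screen(design)
    report = qc_plates(obs, control="DMSO")
    trend = report.row_trend["neuron"]
    assert trend.std() / trend.mean() < 0.1


# ------------------------------------------------------------ normalization

def _counts_two_repeats():
    # odd well counts per LPS level so the medians are attained values
    rows = []
    for rep, (mneg, mpos) in enumerate([(4000, 400), (3000, 300)], start=1):
        for i in range(9):
            rows.append(dict(repeat=rep, compound_id=f"C{i}", lps=False,
                             neuron=mneg + (i - 4) * 10, microglia=100 + (i - 4)))
            rows.append(dict(repeat=rep, compound_id=f"C{i}", lps=True,
                             neuron=mpos + (i - 4) * 2, microglia=300 + (i - 4)))
    return pd.DataFrame(rows)


def test_anchor_medians_map_to_unit_interval_exactly():
    counts = _counts_two_repeats()
    nc, anchors = minmax_normalize(counts)
    for rep in (1, 2):
        sub = nc[nc["repeat"] == rep]
        med_neg, med_pos = anchors[(rep, "neuron")]
        # wells at the anchor values normalize to exactly 1 and 0
        at_neg = sub.loc[sub["neuron"] == med_neg, "normalized_neuron"]
        at_pos = sub.loc[sub["neuron"] == med_pos, "normalized_neuron"]
        assert (at_neg == 1.0).all() and len(at_neg)
        assert (at_pos == 0.0).all() and len(at_pos)
        # microglia direction reversed: LPS+ median -> 1
        mneg, mpos = anchors[(rep, "microglia")]
        at_mpos = sub.loc[sub["microglia"] == mpos, "normalized_microglia"]
        assert (at_mpos == 1.0).all() and len(at_mpos)


def test_midpoint_interpolates_linearly():
    counts = pd.DataFrame([
        dict(repeat=1, compound_id="a", lps=False, neuron=4000, microglia=100),
        dict(repeat=1, compound_id="b", lps=False, neuron=4000, microglia=100),
        dict(repeat=1, compound_id="c", lps=False, neuron=4000, microglia=100),
        dict(repeat=1, compound_id="a", lps=True, neuron=400, microglia=300),
        dict(repeat=1, compound_id="c", lps=True, neuron=400, microglia=300),
        dict(repeat=1, compound_id="b", lps=True, neuron=2200, microglia=500),
    ])
    nc, anchors = minmax_normalize(counts)
    assert nc.loc[(nc.compound_id == "b") & nc.lps, "normalized_neuron"].iloc[0] \
        == pytest.approx(0.5)
    # microglia direction reversed: x above the LPS+ anchor maps above 1
    mneg, mpos = anchors[(1, "microglia")]
    got = nc.loc[(nc.compound_id == "b") & nc.lps, "normalized_microglia"].iloc[0]
    assert got == pytest.approx((500 - mneg) / (mpos - mneg))


def test_microglia_reversed_direction_worked_example():
    # anchors med- = 100, med+ = 300 by construction; x = 500 -> 2.0
    rows = []
    for cid, mg in zip("abc", (90, 100, 110)):
        rows.append(dict(repeat=1, compound_id=cid, lps=False, neuron=4000, microglia=mg))
    for cid, mg in zip("abc", (290, 300, 500)):
        rows.append(dict(repeat=1, compound_id=cid, lps=True, neuron=400, microglia=mg))
    nc, anchors = minmax_normalize(pd.DataFrame(rows))
    assert anchors[(1, "microglia")] == (100, 300)
    got = nc.loc[(nc.compound_id == "c") & nc.lps, "normalized_microglia"].iloc[0]
    assert got == pytest.approx(2.0)


def test_equal_anchors_name_the_repeat():
    counts = pd.DataFrame([
        dict(repeat=5, compound_id="a", lps=False, neuron=100, microglia=100),
        dict(repeat=5, compound_id="a", lps=True, neuron=100, microglia=100),
    ])
    with pytest.raises(ScreenStatsError, match="5"):
        minmax_normalize(counts)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=10))
def test_normalization_invariant_to_repeat_rescaling(scale):
    counts = _counts_two_repeats()
    nc1, _ = minmax_normalize(counts)
    scaled = counts.copy()
    scaled[["neuron", "microglia"]] = scaled[["neuron", "microglia"]].astype(float)
    sel = scaled["repeat"] == 1
    scaled.loc[sel, ["neuron", "microglia"]] *= scale
    nc2, _ = minmax_normalize(scaled)
    np.testing.assert_allclose(nc1["normalized_neuron"], nc2["normalized_neuron"],
                               rtol=1e-9)


# ------------------------------------------------------------ Z factors

def test_zprime_formula_value():
    # groups with means 1 and 0 and sample sds s: Z' = 1 - 6s
    pos = np.array([0.9, 1.0, 1.1])
    neg = np.array([-0.1, 0.0, 0.1])
    s = pos.std(ddof=1)
    assert zprime(pos, neg) == pytest.approx(1 - 6 * s)


def test_zprime_noiseless_limit_and_bound():
    assert zprime([1.0, 1.0], [0.0, 0.0]) == 1.0
    rng = np.random.default_rng(1)
    for _ in range(20):
        p, n = rng.normal(1, 0.3, 5), rng.normal(0, 0.3, 5)
        if abs(p.mean() - n.mean()) > 1e-12:
            assert zprime(p, n) <= 1.0


def test_zprime_equal_means_rejected():
    with pytest.raises(ScreenStatsError):
        zprime([1.0, 1.0], [1.0, 1.0])


def test_robust_zfactor_hand_computed():
    val = robust_zfactor([0.9, 1.0, 1.1], [-0.1, 0.0, 0.1])
    assert val == pytest.approx(1 - 3 * (0.14826 + 0.14826) / 1.0, abs=1e-6)


def test_robust_zfactor_constant_groups_and_symmetry():
    assert robust_zfactor([2.0, 2.0], [1.0, 1.0]) == 1.0
    a, b = [0.8, 1.0, 1.3], [-0.2, 0.0, 0.1]
    assert robust_zfactor(a, b) == pytest.approx(robust_zfactor(b, a))


def test_robust_equals_plain_for_symmetric_noiseless():
    pos, neg = [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]
    assert robust_zfactor(pos, neg) == zprime(pos, neg) == 1.0


# ------------------------------------------------------------ CV reduction

def _cv_table(cvs, means=(100.0, 200.0), col="neuron"):
    rows = []
    rng = np.random.default_rng(0)
    for (cid, lps), cv, mu in zip([("a", False), ("b", False)], cvs, means):
        for i in range(40):
            rows.append(dict(compound_id=cid, lps=lps, repeat=1,
                             **{col: mu * (1 + cv * ((i % 2) * 2 - 1))}))
    return pd.DataFrame(rows)


def test_cv_reduction_arithmetic():
    # raw CVs {0.5, 0.3}; normalized CVs {0.3, 0.24} -> 32.5%
    raw = _cv_table([0.5, 0.3])
    norm = _cv_table([0.3, 0.24], col="normalized_neuron")
    norm["neuron"] = 0
    assert cv_reduction(raw, norm) == pytest.approx(32.5, abs=0.1)


def test_identity_normalization_zero_reduction():
    raw = _cv_table([0.4, 0.2])
    norm = raw.copy()
    norm["normalized_neuron"] = norm["neuron"]
    assert cv_reduction(raw, norm) == pytest.approx(0.0, abs=1e-9)


def test_pure_rescaling_gives_zero_reduction():
    raw = _cv_table([0.4, 0.2])
    norm = raw.copy()
    norm["normalized_neuron"] = norm["neuron"] * 0.001   # per-condition scale-free
    assert cv_reduction(raw, norm) == pytest.approx(0.0, abs=1e-9)


def test_minmax_reduces_cv_across_seeds():
    wins = 0
    for seed in range(40):
        design = ScreenDesign(n_repeats=4, plates_per_repeat=3, plate_rows=8,
                              plate_cols=8, compounds=default_compounds(20),
                              seed=seed,
                              controls={"DMSO": (ARCHETYPES["null"], 6),
                                        "BAY61": (ARCHETYPES["positive_control"], 6)})
        obs, _ = simulate_screen(design)
        nc, _ = minmax_normalize(obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wins += cv_reduction(obs, nc) > 0
    assert wins >= 38


# ------------------------------------------------------------ hit calling

def test_protection_percent_contract():
    assert protection_percent(-0.7291) == pytest.approx(72.91)
    assert protection_percent(-1.0) == pytest.approx(100.0)


def test_planted_full_protection_called_significant(small_screen):
    design, _, _ = small_screen
    comps = list(design.compounds)
    comps[0] = (comps[0][0], EffectArchetype(neuron_protection=1.0))
    d2 = ScreenDesign(**{**design.__dict__, "compounds": comps, "seed": 77})
    obs, _ = simulate_screen(d2)
    nc, _ = minmax_normalize(obs)
    hits = call_hits(nc)
    row = hits[(hits.compound_id == comps[0][0]) & hits.lps].iloc[0]
    assert row.significant and row.mean_diff < 0
    assert row.protection_percent == pytest.approx(100, abs=15)


def test_missing_control_rejected(small_screen):
    _, obs, _ = small_screen
    nc, _ = minmax_normalize(obs)
    with pytest.raises(ScreenStatsError):
        call_hits(nc[nc.compound_id != "DMSO"])


def test_pure_protection_archetypes_not_flagged_toxic(small_screen):
    design, _, _ = small_screen
    comps = [(cid, ARCHETYPES["category1"]) for cid, _ in design.compounds]
    d2 = ScreenDesign(**{**design.__dict__, "compounds": comps, "seed": 13})
    obs, _ = simulate_screen(d2)
    nc, _ = minmax_normalize(obs)
    hits = call_hits(nc)
    tox = hits[(~hits.lps) & hits.significant & (hits.mean_diff > 0)
               & (hits.compound_id != "BAY61")]
    assert len(tox) == 0
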