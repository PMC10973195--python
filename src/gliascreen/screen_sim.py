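"""Multi-repeat, multi-plate well-level screen simulation.

Emulates the count tables produced by the imaging pipeline for a compound
screen against LPS-induced neuronal loss: a chequerboard LPS layout on
18x14-well plates, one replicate of every compound per plate per LPS level,
randomly placed controls, and per-class counts with LPS effects,
compound-effect archetypes, plate/row/column nuisance structure and
negative-binomial (gamma-Poisson) noise.

Default effect sizes follow the biology of the assay: LPS kills 90-95% of
live neurons, raises microglial numbers 2-3x and necrotic cells ~10x, and
leaves astrocytes unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .simulate import CLASSES


class ScreenDesignError(ValueError):
    """Invalid or unsatisfiable screen design."""


@dataclass
class EffectArchetype:
    """Compound effect on the culture, on the normalized/multiplicative scale.

    ``neuron_protection`` shifts the expected LPS+ neuron count linearly from
    the LPS+ baseline (0 = no protection) to the LPS- baseline (1 = full
    protection).  Multipliers act on the corresponding class means;
    ``formfactor_shift`` is added to the median microglial FormFactor of LPS+
    wells.
    """

    neuron_protection: float = 0.0
    neuron_toxicity_lpsneg: float = 1.0
    microglia_multiplier_lps: float = 1.0
    microglia_multiplier_nolps: float = 1.0
    astrocyte_multiplier: float = 1.0
    necrotic_multiplier: float = 1.0
    formfactor_shift: float = 0.0


# The three hit phenotypes seen when clustering neuroprotective compounds:
# category1 ~ weak protection, glia untouched; category2 ~ strong protection
# with increased, de-activated microglia; category3 ~ strongest protection via
# glial depletion (more necrotic debris at baseline).
ARCHETYPES: dict[str, EffectArchetype] = {
    "null": EffectArchetype(),
    "category1": EffectArchetype(neuron_protection=0.57),
    "category2": EffectArchetype(neuron_protection=0.91,
                                 microglia_multiplier_lps=1.39,
                                 formfactor_shift=-0.18),
    "category3": EffectArchetype(neuron_protection=0.98,
                                 microglia_multiplier_lps=0.45,
                                 microglia_multiplier_nolps=0.45,
                                 astrocyte_multiplier=0.65,
                                 necrotic_multiplier=5.0),
    "positive_control": EffectArchetype(neuron_protection=0.97,
                                        microglia_multiplier_lps=0.5,
                                        microglia_multiplier_nolps=0.6,
                                        astrocyte_multiplier=0.7,
                                        necrotic_multiplier=4.0),
}

DEFAULT_BASELINE_COUNTS = {
    "neuron": 2000, "microglia": 150, "astrocyte": 120, "other": 80,
    "condensed": 100, "necrotic": 30, "debris": 150,
}

DEFAULT_LPS_EFFECTS = {
    "neuron": 0.075, "microglia": 2.5, "astrocyte": 1.0, "other": 1.3,
    "condensed": 1.5, "necrotic": 10.0, "debris": 1.0,
}

DEFAULT_NUISANCE = {"repeat": 0.25, "plate": 0.06, "row": 0.03, "column": 0.03}

DEFAULT_DISPERSION = {c: 0.01 for c in CLASSES}

# median microglial FormFactor (mean, sd) per LPS level: highly variable and
# ramified without LPS, round/amoeboid and tight with LPS
FORMFACTOR_MODEL = {False: (0.45, 0.12), True: (0.72, 0.04)}


def default_compounds(n: int = 227, archetype: str | EffectArchetype = "null"
                      ) -> list[tuple[str, EffectArchetype]]:
    arch = ARCHETYPES[archetype] if isinstance(archetype, str) else archetype
    return [(f"C{i + 1:03d}", arch) for i in range(n)]


@dataclass
class ScreenDesign:
    """Layout and statistical structure of a simulated screen."""

    n_repeats: int = 4
    plates_per_repeat: int = 6
    plate_rows: int = 14
    plate_cols: int = 18
    fields_per_well: int = 4
    compounds: list = field(default_factory=lambda: default_compounds(227))
    controls: dict = field(default_factory=lambda: {
        "DMSO": (ARCHETYPES["null"], 6),
        "BAY61": (ARCHETYPES["positive_control"], 6),
    })
    baseline_counts: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_COUNTS))
    lps_effects: dict = field(default_factory=lambda: dict(DEFAULT_LPS_EFFECTS))
    nuisance: dict = field(default_factory=lambda: dict(DEFAULT_NUISANCE))
    dispersion: dict = field(default_factory=lambda: dict(DEFAULT_DISPERSION))
    formfactor_model: dict = field(default_factory=lambda: dict(FORMFACTOR_MODEL))
    seed: int = 0

    @property
    def wells_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    def validate(self) -> None:
        if self.wells_per_plate % 2:
            raise ScreenDesignError("plate grid must have an even number of wells "
                                    "for a balanced chequerboard")
        cap = self.capacity_per_plate_per_lps()
        if cap < 1:
            raise ScreenDesignError("controls alone exceed plate capacity")
        groups = self.n_groups()
        if groups > self.plates_per_repeat:
            raise ScreenDesignError(
                f"{len(self.compounds)} compounds do not fit in "
                f"{self.plates_per_repeat} plates of capacity {cap} per LPS level")
        if self.plates_per_repeat % groups:
            raise ScreenDesignError(
                "plates_per_repeat must be divisible by the number of compound groups")

    def capacity_per_plate_per_lps(self) -> int:
        n_ctrl = sum(reps for _, reps in self.controls.values())
        return self.wells_per_plate // 2 - n_ctrl

    def n_groups(self) -> int:
        return max(1, math.ceil(len(self.compounds) / max(self.capacity_per_plate_per_lps(), 1)))


def _split_groups(compounds, n_groups):
    """Deterministic near-even split preserving input order."""
    out = [[] for _ in range(n_groups)]
    base = len(compounds) // n_groups
    extra = len(compounds) % n_groups
    i = 0
    for g in range(n_groups):
        take = base + (1 if g < extra else 0)
        out[g] = compounds[i:i + take]
        i += take
    return out


def simulate_screen(design: ScreenDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one full screen.

    Returns ``(observations, truth)``: one row per used well with per-class
    counts and median microglial FormFactor, and the ground-truth archetype
    table for later sensitivity/FWER scoring.  Deterministic given
    ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    groups = _split_groups(design.compounds, design.n_groups())
    plates_per_group = design.plates_per_repeat // len(groups)

    arch_of = {cid: a for cid, a in design.compounds}
    for cid, (a, _) in design.controls.items():
        arch_of[cid] = a

    rows_out = []
    rr, cc = np.mgrid[0:design.plate_rows, 0:design.plate_cols]
    lps_grid = ((rr + cc) % 2).astype(bool)

    # nuisance effects, multiplicative log-normal
    rep_eff = np.exp(rng.normal(0, design.nuisance.get("repeat", 0.0), design.n_repeats))
    row_eff = np.exp(rng.normal(0, design.nuisance.get("row", 0.0), design.plate_rows))
    col_eff = np.exp(rng.normal(0, design.nuisance.get("column", 0.0), design.plate_cols))

    for rep in range(design.n_repeats):
        for plate in range(design.plates_per_repeat):
            group = groups[plate // plates_per_group]
            plate_eff = math.exp(rng.normal(0, design.nuisance.get("plate", 0.0)))
            entries = [cid for cid, _ in group]
            for cid, (_, reps) in design.controls.items():
                entries += [cid] * reps
            for lps in (False, True):
                wells = np.argwhere(lps_grid == lps)
                perm = rng.permutation(len(wells))[:len(entries)]
                if len(entries) > len(wells):
                    raise ScreenDesignError("entries exceed wells per LPS level")
                for cid, wi in zip(entries, perm):
                    r, c = wells[wi]
                    rows_out.append((rep + 1, plate + 1, int(r) + 1, int(c) + 1,
                                     cid, lps,
                                     rep_eff[rep] * plate_eff * row_eff[r] * col_eff[c]))

    obs = pd.DataFrame(rows_out, columns=["repeat", "plate", "row", "column",
                                          "compound_id", "lps", "_nuis"])
    obs["well"] = (obs["plate"].astype(str) + "-"
                   + obs["row"].astype(str) + "." + obs["column"].astype(str))

    lps = obs["lps"].to_numpy()
    nuis = obs["_nuis"].to_numpy()
    arch_rows = obs["compound_id"].map(arch_of)

    for cls in CLASSES:
        base = design.baseline_counts[cls]
        eff = design.lps_effects[cls]
        if cls == "neuron":
            prot = arch_rows.map(lambda a: a.neuron_protection).to_numpy()
            tox = arch_rows.map(lambda a: a.neuron_toxicity_lpsneg).to_numpy()
            mu = np.where(lps,
                          base * eff + prot * (base - base * eff),
                          base * tox)
        elif cls == "microglia":
            m_lps = arch_rows.map(lambda a: a.microglia_multiplier_lps).to_numpy()
            m_no = arch_rows.map(lambda a: a.microglia_multiplier_nolps).to_numpy()
            mu = base * np.where(lps, eff * m_lps, m_no)
        elif cls == "astrocyte":
            m = arch_rows.map(lambda a: a.astrocyte_multiplier).to_numpy()
            mu = base * np.where(lps, eff, 1.0) * m
        elif cls == "necrotic":
            m = arch_rows.map(lambda a: a.necrotic_multiplier).to_numpy()
            mu = base * np.where(lps, eff, 1.0) * m
        else:
            mu = base * np.where(lps, eff, 1.0)
        mu = mu * nuis
        alpha = design.dispersion.get(cls, 0.0)
        if alpha <= 0:
            obs[cls] = np.round(mu).astype(int)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
            obs[cls] = rng.poisson(lam)

    # median microglial FormFactor per well
    ffm = design.formfactor_model
    mean_ff = np.where(lps, ffm[True][0], ffm[False][0])
    sd_ff = np.where(lps, ffm[True][1], ffm[False][1])
    shift = arch_rows.map(lambda a: a.formfactor_shift).to_numpy()
    ff = mean_ff + np.where(lps, shift, 0.0) + rng.normal(0, 1, len(obs)) * sd_ff
    ff = np.clip(ff, 0.05, 1.0)
    ff[obs["microglia"].to_numpy() == 0] = np.nan
    obs["median_formfactor"] = ff

    obs = obs.drop(columns="_nuis")
    obs = obs[["repeat", "plate", "row", "column", "well", "compound_id", "lps",
               *CLASSES, "median_formfactor"]]

    truth = pd.DataFrame(
        [{"compound_id": cid, "role": ("control" if cid in design.controls else "compound"),
          **asdict(arch_of[cid])}
         for cid in dict.fromkeys(list(arch_of))])
    return obs, truth
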