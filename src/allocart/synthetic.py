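"""CALM-like virtual datasets: regimens, covariates, observations, truth.

The generator emulates the structure of the phase-I study the model was
built on: 26 PK/PD sets; UCART19 dose levels 6e6 (n=6), 6-8e7 (n=12) and
1.8-2.4e8 (n=8) cells; three fludarabine doses on days -7..-5 and three
cyclophosphamide doses on days -4..-2; alemtuzumab as 40 mg (n=8), 60 mg
(n=5) or 1 mg/kg (n=11) split into five daily doses from day -7, or
absent (n=2); flow-cytometry LOQ 0.001 G/L and alemtuzumab LOQ 0.01
ug/mL.  Five sets lack allogeneic elimination (persistent profiles), two
of which carry the transient blood-only elimination that produces
"truncated" profiles.

Everything is reproducible from a single seed and emitted as plain-CSV
tables (dosing, covariates, observations, truth), the dialect consumed
by the population engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    ALEM_LOQ,
    ALEM_SCHEDULE,
    CELL_SCHEDULE,
    FLOW_LOQ,
    PopulationModel,
    SubjectParameters,
    sample_individual,
    simulate_subject,
    typical_subject,
)
from .inference import DEFAULT_ERROR_MODELS, err_sd
from .treatment import DoseEvent, Drug, RegimenSpec

__all__ = [
    "StudyTemplate",
    "SyntheticDataset",
    "generate_study",
    "archetype_profiles",
    "archetype_regimen",
]


@dataclass
class StudyTemplate:
    """Design constants of the emulated trial."""

    n_sets: int = 26
    # UCART19 dose bands (cells): nominal low dose, then two ranges
    dose_level_counts: dict = field(
        default_factory=lambda: {(6e6, 6e6): 6, (6e7, 8e7): 12, (1.8e8, 2.4e8): 8}
    )
    alem_arm_counts: dict = field(
        default_factory=lambda: {"40mg-flat": 8, "60mg-flat": 5, "1mg/kg": 11, "none": 2}
    )
    n_allo_off: int = 5
    n_truncated: int = 2
    loq_cells: float = FLOW_LOQ
    loq_alem: float = ALEM_LOQ
    fluda_total_range: tuple[float, float] = (120.0, 275.0)
    cyclo_total_range: tuple[float, float] = (2010.0, 4802.0)
    body_weight_range: tuple[float, float] = (50.0, 100.0)
    cell_schedule: np.ndarray = field(default_factory=lambda: CELL_SCHEDULE.copy())
    alem_schedule: np.ndarray = field(default_factory=lambda: ALEM_SCHEDULE.copy())

    def __post_init__(self) -> None:
        if sum(self.alem_arm_counts.values()) != self.n_sets:
            raise ValueError("alemtuzumab arm counts must sum to n_sets")
        if sum(self.dose_level_counts.values()) != self.n_sets:
            raise ValueError("dose-level counts must sum to n_sets")
        if self.n_truncated > self.n_allo_off:
            raise ValueError("truncated sets are drawn among allo-off sets")


@dataclass
class SyntheticDataset:
    dosing: pd.DataFrame
    covariates: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame
    regimens: list[RegimenSpec]
    seed: int

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.dosing.to_csv(directory / "dosing.csv", index=False)
        self.covariates.to_csv(directory / "covariates.csv", index=False)
        self.observations.to_csv(directory / "observations.csv", index=False)
        self.truth.to_csv(directory / "truth.csv", index=False)


def _regimen_for_set(
    rng: np.random.Generator,
    template: StudyTemplate,
    arm: str,
    dose_band: tuple[float, float],
    body_weight: float,
) -> RegimenSpec:
    events = []
    total_f = rng.uniform(*template.fluda_total_range)
    for day in (-7.0, -6.0, -5.0):
        events.append(DoseEvent(Drug.FLUDARABINE, day, total_f / 3.0))
    total_c = rng.uniform(*template.cyclo_total_range)
    for day in (-4.0, -3.0, -2.0):
        events.append(DoseEvent(Drug.CYCLOPHOSPHAMIDE, day, total_c / 3.0))
    if arm != "none":
        if arm == "40mg-flat":
            total_a = 40.0
        elif arm == "60mg-flat":
            total_a = 60.0
        else:
            total_a = 1.0 * body_weight
        for i in range(5):
            events.append(DoseEvent(Drug.ALEMTUZUMAB, -7.0 + i, total_a / 5.0))
    lo, hi = dose_band
    ucart_dose = lo if lo == hi else rng.uniform(lo, hi)
    events.append(DoseEvent(Drug.UCART19, 0.0, ucart_dose))
    return RegimenSpec(events=events, body_weight=body_weight)


def generate_study(
    template: StudyTemplate,
    pop: PopulationModel,
    seed: int,
) -> SyntheticDataset:
    """Generate a full virtual study: dose, simulate, observe, censor.

    Arm and dose-level assignments follow the template counts exactly;
    the allo-off (persistent) and truncated flags land only on
    alemtuzumab-receiving sets, matching the observed composition.
    """
    rng = np.random.default_rng(seed)
    n = template.n_sets

    arms = [a for a, c in template.alem_arm_counts.items() for _ in range(c)]
    bands = [b for b, c in template.dose_level_counts.items() for _ in range(c)]
    rng.shuffle(arms)
    rng.shuffle(bands)

    alem_idx = [i for i, a in enumerate(arms) if a != "none"]
    allo_off = set(rng.choice(alem_idx, size=template.n_allo_off, replace=False))
    trunc = set(rng.choice(sorted(allo_off), size=template.n_truncated, replace=False))

    dosing_rows, cov_rows, obs_rows, truth_rows = [], [], [], []
    regimens: list[RegimenSpec] = []
    err = dict(DEFAULT_ERROR_MODELS)

    for i in range(n):
        sid = i + 1
        bw = rng.uniform(*template.body_weight_range)
        regimen = _regimen_for_set(rng, template, arms[i], bands[i], bw)
        regimens.append(regimen)
        fractions = rng.dirichlet((8.0, 8.0, 4.0))
        cov = {
            "refHostNK": float(0.2 * np.exp(rng.normal(0.0, 0.6))),
            "refHostT": float(0.8 * np.exp(rng.normal(0.0, 0.6))),
            "dose_fractions": tuple(fractions),
            "allo_active": i not in allo_off,
            "trunc_active": i in trunc,
        }
        subject = sample_individual(pop, rng, covariates=cov)

        for e in regimen.events:
            dosing_rows.append(
                {"ID": sid, "TIME": e.time, "AMT": e.amount, "DRUG": e.drug.value, "BW": bw}
            )
        cov_rows.append(
            {
                "ID": sid,
                "ALLO_ACTIVE": int(cov["allo_active"]),
                "TRUNC_ACTIVE": int(cov["trunc_active"]),
                "FSCM": fractions[0],
                "FCM": fractions[1],
                "FEM": fractions[2],
                "REFNK": cov["refHostNK"],
                "REFHOSTT": cov["refHostT"],
            }
        )
        for name, value in subject.values.items():
            truth_rows.append({"ID": sid, "parameter": name, "value": value})
        truth_rows.append({"ID": sid, "parameter": "refHostNK", "value": cov["refHostNK"]})
        truth_rows.append({"ID": sid, "parameter": "refHostT", "value": cov["refHostT"]})

        schedules = {
            "IL7": template.cell_schedule,
            "NK": template.cell_schedule,
            "HOSTT": template.cell_schedule,
            "LYMPH": template.cell_schedule,
            "UCART": template.cell_schedule,
        }
        if arms[i] != "none":
            schedules["ALEM"] = template.alem_schedule
        grid = np.unique(np.concatenate(list(schedules.values())))
        traj = simulate_subject(subject, regimen, grid=grid)
        loqs = {
            "ALEM": template.loq_alem,
            "NK": template.loq_cells,
            "HOSTT": template.loq_cells,
            "LYMPH": template.loq_cells,
            "UCART": template.loq_cells,
            "IL7": 0.0,
        }
        for dvid, times in schedules.items():
            series = traj.observable(dvid)
            idx = np.searchsorted(grid, times)
            pred = series[idx]
            obs = pd.DataFrame({"TIME": times, "DVID": dvid})
            sd = err_sd(err, obs, pred)
            dv = np.clip(pred + rng.normal(0.0, 1.0, pred.size) * sd, 0.0, None)
            loq = loqs[dvid]
            for t, v in zip(times, dv):
                cens = int(v < loq)
                obs_rows.append(
                    {
                        "ID": sid,
                        "TIME": float(t),
                        "DV": float(loq if cens else v),
                        "DVID": dvid,
                        "CENS": cens,
                        "LOQ": loq,
                    }
                )

    return SyntheticDataset(
        dosing=pd.DataFrame(dosing_rows),
        covariates=pd.DataFrame(cov_rows),
        observations=pd.DataFrame(obs_rows),
        truth=pd.DataFrame(truth_rows),
        regimens=regimens,
        seed=seed,
    )


def archetype_regimen(alem_total_mg: float = 40.0) -> RegimenSpec:
    """Reference FCA regimen: median F/C totals, five alemtuzumab doses."""
    events = [DoseEvent(Drug.FLUDARABINE, d, 55.0) for d in (-7.0, -6.0, -5.0)]
    events += [DoseEvent(Drug.CYCLOPHOSPHAMIDE, d, 890.0) for d in (-4.0, -3.0, -2.0)]
    if alem_total_mg > 0:
        events += [
            DoseEvent(Drug.ALEMTUZUMAB, -7.0 + i, alem_total_mg / 5.0) for i in range(5)
        ]
    events.append(DoseEvent(Drug.UCART19, 0.0, 6e6))
    return RegimenSpec(events=events)


def archetype_profiles(seed: int = 0) -> dict[str, SubjectParameters]:
    """Three parameter presets spanning the observed profile taxonomy.

    Under the reference FCA regimen (:func:`archetype_regimen`):

    * ``persistence`` — no allogeneic elimination; blood UCART19 stays
      above LOQ through day 84;
    * ``transient`` — typical subject with allogeneic elimination: clear
      peak then decline below LOQ as host T cells recover;
    * ``no_expansion`` — weak alemtuzumab effect on host T cells, so
      lymphodepletion is too shallow and the profile stays below LOQ.

    The presets are individual parameter vectors, not typical ones: the
    persistent and transient archetypes sit on the favourable side of the
    IL-7 axis (high production baseline and IL-7 potency draws), the way
    observed expanders did, while the no-expansion archetype has a weak
    alemtuzumab effect on host cells and therefore shallow
    lymphodepletion.  ``seed`` is accepted for interface symmetry; the
    presets are fixed.
    """
    del seed
    # high baseline IL-7 production puts these subjects on the favourable
    # side of the expansion gate, as observed expanders were
    favourable = dict(k_inIL7=2.2)
    persistence = typical_subject(allo_active=False).replace(
        t_persist=20.0, **favourable
    )
    # a weak (but present) allogeneic response lets a clear peak form
    # before the recovering host T cells remove the graft
    transient = typical_subject(allo_active=True).replace(k_allo=3.0, **favourable)
    no_expansion = typical_subject(allo_active=True).replace(
        k_effAlhostT=0.05, k_effAlhostNK=0.02
    )
    return {
        "persistence": persistence,
        "transient": transient,
        "no_expansion": no_expansion,
    }
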