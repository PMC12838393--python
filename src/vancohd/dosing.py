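"""Regimen classification and Monte-Carlo target attainment.

Regimens are classified on three axes (cumulative initial two doses,
loading dose, maintenance dose) into low/standard/high bands; target
attainment is the fraction of a virtual population whose second-term AUC
falls in 400-700 ug.h/mL, simulated under post-dialytic dosing and a fixed
48-h inter-dialysis interval irrespective of the true schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .auc import term_auc
from .cohort import CohortSpec, draw_physiology, hd_dose_events
from .pk import HDSession, PopulationPKModel, simulate_profile

# (name, lower, upper) with half-open [lo, hi) bands except the top band,
# which is closed at its upper bound; outside all bands -> "unclassified".
CUMULATIVE_BANDS = (("low", 24.75, 31.5), ("standard", 31.5, 38.5), ("high", 38.5, 46.2))
LOADING_BANDS = (("low", 18.0, 22.5), ("standard", 22.5, 27.5), ("high", 27.5, 33.0))
MAINTENANCE_BANDS = (("low", 6.75, 9.0), ("standard", 9.0, 11.0), ("high", 11.0, 12.0))

AUC_BAND_EDGES = (400.0, 600.0, 700.0)


@dataclass(frozen=True)
class RegimenClass:
    cumulative_class: str
    loading_class: str
    maintenance_class: str


@dataclass(frozen=True)
class AttainmentSummary:
    n: int
    frac_below_400: float
    frac_400_600: float
    frac_600_700: float
    frac_ge_700: float

    @property
    def frac_target(self) -> float:
        """Fraction with AUC(24-48h) in the 400-700 ug.h/mL target window."""
        return self.frac_400_600 + self.frac_600_700


def _classify_axis(value: float, bands) -> str:
    for i, (name, lo, hi) in enumerate(bands):
        top = i == len(bands) - 1
        if lo <= value < hi or (top and value == hi):
            return name
    return "unclassified"


def classify_regimen(loading_mg_per_kg: float, maintenance_mg_per_kg: float) -> RegimenClass:
    """Band classification of a loading+maintenance regimen (mg/kg)."""
    if loading_mg_per_kg <= 0 or maintenance_mg_per_kg <= 0:
        raise ValueError("doses must be > 0")
    cumulative = loading_mg_per_kg + maintenance_mg_per_kg
    return RegimenClass(
        cumulative_class=_classify_axis(cumulative, CUMULATIVE_BANDS),
        loading_class=_classify_axis(loading_mg_per_kg, LOADING_BANDS),
        maintenance_class=_classify_axis(maintenance_mg_per_kg, MAINTENANCE_BANDS),
    )


def simulate_auc2_under_48h(
    loading_mg_per_kg: float,
    maintenance_mg_per_kg: float,
    phys: dict,
    pop: PopulationPKModel,
    t_inf: float = 1.0,
    step: float = 0.1,
) -> float:
    """Second-term AUC for one virtual patient under the 48-h-interval
    assumption: sessions at elapsed and elapsed+48 h, loading at t=0,
    maintenance immediately after the first session; later events ignored."""
    params = pop.individual(phys["weight_kg"], phys["eta"])
    dur = phys["session_duration_h"]
    s1 = HDSession(start=phys["elapsed_h"], duration=dur)
    s2 = HDSession(start=s1.start + 48.0, duration=dur)
    anchor = s1.end
    horizon = anchor + 48.0  # == s2.end
    doses = hd_dose_events(phys["weight_kg"], loading_mg_per_kg, maintenance_mg_per_kg,
                           [s1, s2], t_inf, horizon)
    profile = simulate_profile(doses, params, [s1, s2], phys["settings"],
                               t_end=horizon, step=step)
    return term_auc(profile, anchor, 2).auc


def simulate_attainment(
    loading_mg_per_kg: float,
    maintenance_mg_per_kg: float,
    pop: PopulationPKModel,
    cohort_spec: CohortSpec | None = None,
    n: int = 500,
    seed: int = 0,
    step: float = 0.1,
) -> AttainmentSummary:
    """Monte-Carlo attainment of the 400-700 ug.h/mL AUC(24-48h) window.

    The same seed draws the same virtual patients, so regimens can be
    compared on a fixed cohort.  Band edges 400/600/700 are inclusive-left.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = cohort_spec or CohortSpec()
    rng = np.random.default_rng(seed)
    aucs = np.empty(n)
    for i in range(n):
        phys = draw_physiology(rng, spec, pop)
        aucs[i] = simulate_auc2_under_48h(loading_mg_per_kg, maintenance_mg_per_kg,
                                          phys, pop, t_inf=spec.t_inf, step=step)
    e1, e2, e3 = AUC_BAND_EDGES
    return AttainmentSummary(
        n=n,
        frac_below_400=float(np.mean(aucs < e1)),
        frac_400_600=float(np.mean((aucs >= e1) & (aucs < e2))),
        frac_600_700=float(np.mean((aucs >= e2) & (aucs < e3))),
        frac_ge_700=float(np.mean(aucs >= e3)),
    )


def attainment_sweep(
    regimens: list[tuple[float, float]],
    pop: PopulationPKModel,
    cohort_spec: CohortSpec | None = None,
    n: int = 500,
    seed: int = 0,
    step: float = 0.1,
) -> dict[tuple[float, float], AttainmentSummary]:
    """Attainment for several regimens on the same seeded virtual cohort."""
    return {
        reg: simulate_attainment(reg[0], reg[1], pop, cohort_spec, n=n, seed=seed, step=step)
        for reg in regimens
    }
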