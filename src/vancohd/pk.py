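"""Two-compartment vancomycin PK with session-gated dialyzer clearance.

The drug model is a linear two-compartment system driven by zero-order
infusions.  Total clearance is the patient's physiological (body) clearance
plus, transiently during each haemodialysis session, an extracorporeal
clearance derived from the dialyzer's mass-transfer-area coefficient (KoA)
and the session's blood/dialysate/ultrafiltration flows.  Profiles are
integrated with a fixed-step fourth-order Runge-Kutta-Gill scheme whose
steps are aligned to every dose and session boundary, so the right-hand
side is smooth within each step.

Units: times in hours, amounts in mg, volumes in L, clearances in L/h
internally; user-facing dialysis flow rates are mL/min and are converted
once at ingestion (1 mL/min = 0.06 L/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

ML_MIN_TO_L_H = 0.06

MW_CREATININE = 113.0
MW_B12 = 1355.0
MW_VANCOMYCIN = 1449.0

_SQRT2 = math.sqrt(2.0)


class InfeasibleMembraneError(ValueError):
    """Baseline clearance is not attainable at the stated reference flows."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class PopulationPKModel(BaseModel):
    """Population prior for the two-compartment model.

    ``omega`` holds the log-scale inter-individual SDs in the order
    (CL, V1, Q, V2); an entry of 0 fixes that parameter at its typical
    value.  The residual model combines a proportional and an additive
    component: Var = (sigma_prop * C)^2 + sigma_add^2.

    The shipped defaults are literature-informed placeholders for anuric
    haemodialysis patients, not any specific published model's estimates;
    override them from configuration for production use.
    """

    cl_body_typ: float = Field(gt=0, description="body clearance (L/h)")
    v1_typ: float = Field(gt=0, description="central volume (L, or L/kg if weight-scaled)")
    q_typ: float = Field(gt=0, description="inter-compartmental clearance (L/h)")
    v2_typ: float = Field(gt=0, description="peripheral volume (L)")
    v1_per_kg: bool = True
    omega: tuple[float, float, float, float] = (0.30, 0.25, 0.0, 0.0)
    sigma_prop: float = Field(default=0.15, ge=0)
    sigma_add: float = Field(default=0.5, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PopulationPKModel":
        if any(w < 0 for w in self.omega):
            raise ValueError("omega entries must be >= 0")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError("at least one residual error component must be > 0")
        return self

    def individual(
        self, weight_kg: float, eta: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    ) -> "IndividualPKParams":
        """Individual parameters param_i = typ_i * exp(eta_i)."""
        e = tuple(float(x) for x in eta)
        if len(e) != 4:
            raise ValueError("eta must have 4 entries (CL, V1, Q, V2)")
        v1_typ = self.v1_typ * weight_kg if self.v1_per_kg else self.v1_typ
        return IndividualPKParams(
            cl_body=self.cl_body_typ * math.exp(e[0]),
            v1=v1_typ * math.exp(e[1]),
            q=self.q_typ * math.exp(e[2]),
            v2=self.v2_typ * math.exp(e[3]),
            eta=e,
        )


#: Placeholder anuric-HD prior (NOT a published model's estimates).
DEFAULT_HD_POP = PopulationPKModel(
    cl_body_typ=0.45, v1_typ=0.24, q_typ=6.5, v2_typ=38.0
)

#: Placeholder prior for non-dialysis patients with moderate renal function.
DEFAULT_NONHD_POP = PopulationPKModel(
    cl_body_typ=3.3, v1_typ=0.24, q_typ=7.0, v2_typ=40.0
)


@dataclass(frozen=True)
class IndividualPKParams:
    cl_body: float
    v1: float
    q: float
    v2: float
    eta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("cl_body", "v1", "q", "v2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class HDSettings(BaseModel):
    """Dialysis-circuit settings; flows in mL/min.

    The membrane is characterised by baseline clearances of creatinine and
    vitamin B12 measured at reference flows.  Vitamin B12 (1355 Da) is the
    default vancomycin (1449 Da) surrogate; ``use_mw_interpolation`` instead
    fits log KoA linearly in log molecular weight through the two baselines
    and evaluates it at vancomycin's weight.
    """

    q_blood: float = Field(ge=0)
    q_dialysate: float = Field(gt=0)
    q_uf: float = Field(default=0.0, ge=0)
    cl_b12_baseline: float = Field(gt=0)
    cl_cr_baseline: float = Field(default=0.0, ge=0)
    q_blood_ref: float = Field(default=200.0, gt=0)
    q_dialysate_ref: float = Field(default=500.0, gt=0)
    use_mw_interpolation: bool = False

    @model_validator(mode="after")
    def _check(self) -> "HDSettings":
        if self.cl_b12_baseline >= min(self.q_blood_ref, self.q_dialysate_ref):
            raise InfeasibleMembraneError(
                "cl_b12_baseline must be below min(reference flows)"
            )
        if self.use_mw_interpolation and self.cl_cr_baseline <= 0:
            raise ValueError("MW interpolation requires cl_cr_baseline > 0")
        return self


class HDSession(BaseModel):
    start: float = Field(ge=0, description="hours since therapy start")
    duration: float = Field(gt=0, description="session length (h)")

    @property
    def end(self) -> float:
        return self.start + self.duration


class DoseEvent(BaseModel):
    time: float = Field(ge=0, description="infusion start (h)")
    amount: float = Field(gt=0, description="dose (mg)")
    t_inf: float = Field(gt=0, description="infusion duration (h)")


class Observation(BaseModel):
    time: float = Field(ge=0)
    conc: float = Field(gt=0, description="measured concentration (ug/mL)")
    assay_derived: bool = False

    @model_validator(mode="after")
    def _range(self) -> "Observation":
        if self.assay_derived and not (0.8 <= self.conc <= 50.0):
            raise ValueError("assay-derived concentration outside dynamic range 0.8-50")
        return self


def validate_sessions(sessions: Sequence[HDSession]) -> None:
    for prev, cur in zip(sessions, sessions[1:]):
        if cur.start < prev.end:
            raise ValueError("HD sessions must be time-ordered and non-overlapping")


@dataclass
class ConcentrationProfile:
    """Dense simulated concentration-time profile (central compartment).

    ``grid`` carries every integration node; ``a1``/``a2`` the compartment
    amounts, kept so mass-balance checks and AUC tails are possible.
    """

    grid: np.ndarray
    conc: np.ndarray
    step: float
    a1: np.ndarray = field(repr=False, default=None)
    a2: np.ndarray = field(repr=False, default=None)

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.grid[0] - 1e-9) or np.any(t > self.grid[-1] + 1e-9):
            raise ValueError("time outside simulated horizon")
        out = np.interp(t, self.grid, self.conc)
        return float(out) if out.ndim == 0 else out

    def covers(self, t0: float, t1: float) -> bool:
        return self.grid[0] <= t0 + 1e-9 and self.grid[-1] >= t1 - 1e-9


# ---------------------------------------------------------------------------
# dialyzer clearance
# ---------------------------------------------------------------------------


def dialyzer_forward_clearance(koa: float, q_blood: float, q_dialysate: float) -> float:
    """Diffusive clearance (mL/min) of a countercurrent dialyzer.

    CL = Qb * (exp(z) - 1) / (exp(z) - Qb/Qd) with
    z = (KoA/Qb) * (1 - Qb/Qd); the equal-flow limit z -> 0 gives
    CL = Qb * KoA / (Qb + KoA).  CL is bounded above by min(Qb, Qd).
    """
    if koa <= 0 or q_blood <= 0 or q_dialysate <= 0:
        return 0.0
    r = q_blood / q_dialysate
    if abs(1.0 - r) < 1e-12:
        return q_blood * koa / (q_blood + koa)
    z = (koa / q_blood) * (1.0 - r)
    if z > 500.0:
        return q_blood
    if z < -500.0:
        return q_dialysate
    return q_blood * math.expm1(z) / (math.exp(z) - r)


def dialyzer_koa(cl_baseline: float, q_blood_ref: float, q_dialysate_ref: float) -> float:
    """Invert the countercurrent formula for KoA (mL/min) at reference flows."""
    if not 0 < cl_baseline < min(q_blood_ref, q_dialysate_ref):
        raise InfeasibleMembraneError(
            "baseline clearance must lie in (0, min(reference flows))"
        )

    def f(koa: float) -> float:
        return dialyzer_forward_clearance(koa, q_blood_ref, q_dialysate_ref) - cl_baseline

    hi = max(q_blood_ref, q_dialysate_ref)
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:  # pragma: no cover - cannot happen for feasible baselines
        raise InfeasibleMembraneError("failed to bracket KoA")
    return float(brentq(f, 1e-10, hi, xtol=1e-12, rtol=1e-14))


def _vancomycin_koa(settings: HDSettings) -> float:
    koa_b12 = dialyzer_koa(
        settings.cl_b12_baseline, settings.q_blood_ref, settings.q_dialysate_ref
    )
    if not settings.use_mw_interpolation:
        return koa_b12
    koa_cr = dialyzer_koa(
        settings.cl_cr_baseline, settings.q_blood_ref, settings.q_dialysate_ref
    )
    # log KoA linear in log MW through (creatinine, B12), evaluated at vancomycin
    slope = (math.log(koa_b12) - math.log(koa_cr)) / (
        math.log(MW_B12) - math.log(MW_CREATININE)
    )
    return math.exp(
        math.log(koa_b12) + slope * (math.log(MW_VANCOMYCIN) - math.log(MW_B12))
    )


def dialyzer_clearance(settings: HDSettings) -> float:
    """Extracorporeal vancomycin clearance during a session, in L/h.

    Diffusive component: membrane KoA (from the vitamin-B12 baseline) scaled
    to the actual flows through the forward countercurrent formula.
    Convective component: q_uf * (1 - CL_diff/Qb), the ultrafiltration flow
    acting on blood already partially cleared by diffusion.
    """
    if settings.q_blood <= 0:
        return 0.0
    koa = _vancomycin_koa(settings)
    cl_diff = dialyzer_forward_clearance(koa, settings.q_blood, settings.q_dialysate)
    cl_ml_min = cl_diff + settings.q_uf * (1.0 - cl_diff / settings.q_blood)
    return cl_ml_min * ML_MIN_TO_L_H


def total_clearance(
    t: float,
    params: IndividualPKParams,
    sessions: Sequence[HDSession],
    settings: HDSettings | None,
) -> float:
    """Body clearance plus dialyzer clearance when t is inside a session.

    Session gating is half-open [start, start+duration), so clearance is
    piecewise constant with unambiguous boundary values.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    cl = params.cl_body
    if settings is not None and sessions:
        for s in sessions:
            if s.start <= t < s.end:
                cl += dialyzer_clearance(settings)
                break
    return cl


# ---------------------------------------------------------------------------
# Runge-Kutta-Gill integrator
# ---------------------------------------------------------------------------

_A31 = (_SQRT2 - 1.0) / 2.0
_A32 = (2.0 - _SQRT2) / 2.0
_A42 = -_SQRT2 / 2.0
_A43 = 1.0 + _SQRT2 / 2.0
_W1 = 1.0 / 6.0
_W2 = (2.0 - _SQRT2) / 6.0
_W3 = (2.0 + _SQRT2) / 6.0
_W4 = 1.0 / 6.0


@njit(cache=False)
def _rkg_loop(h_arr, cl_arr, rin_arr, v1, q, v2, a1_out, a2_out):  # pragma: no cover
    a1 = a1_out[0]
    a2 = a2_out[0]
    kq1 = q / v1
    kq2 = q / v2
    for i in range(h_arr.shape[0]):
        h = h_arr[i]
        ke = cl_arr[i] / v1
        rin = rin_arr[i]

        k1a = rin - (ke + kq1) * a1 + kq2 * a2
        k1b = kq1 * a1 - kq2 * a2

        y1 = a1 + h * 0.5 * k1a
        y2 = a2 + h * 0.5 * k1b
        k2a = rin - (ke + kq1) * y1 + kq2 * y2
        k2b = kq1 * y1 - kq2 * y2

        y1 = a1 + h * (_A31 * k1a + _A32 * k2a)
        y2 = a2 + h * (_A31 * k1b + _A32 * k2b)
        k3a = rin - (ke + kq1) * y1 + kq2 * y2
        k3b = kq1 * y1 - kq2 * y2

        y1 = a1 + h * (_A42 * k2a + _A43 * k3a)
        y2 = a2 + h * (_A42 * k2b + _A43 * k3b)
        k4a = rin - (ke + kq1) * y1 + kq2 * y2
        k4b = kq1 * y1 - kq2 * y2

        a1 = a1 + h * (_W1 * k1a + _W2 * k2a + _W3 * k3a + _W4 * k4a)
        a2 = a2 + h * (_W1 * k1b + _W2 * k2b + _W3 * k3b + _W4 * k4b)
        a1_out[i + 1] = a1
        a2_out[i + 1] = a2


def _event_breakpoints(
    doses: Sequence[DoseEvent], sessions: Sequence[HDSession], t_end: float
) -> np.ndarray:
    pts = {0.0, float(t_end)}
    for d in doses:
        if d.time < t_end:
            pts.add(float(d.time))
            pts.add(float(min(d.time + d.t_inf, t_end)))
    for s in sessions:
        if s.start < t_end:
            pts.add(float(s.start))
            pts.add(float(min(s.end, t_end)))
    return np.array(sorted(p for p in pts if 0.0 <= p <= t_end))


def simulate_profile(
    doses: Sequence[DoseEvent],
    params: IndividualPKParams,
    sessions: Sequence[HDSession] = (),
    settings: HDSettings | None = None,
    t_end: float = 48.0,
    step: float = 0.05,
) -> ConcentrationProfile:
    """Integrate the two-compartment model over [0, t_end].

    Steps are chosen so that every dose start/stop and session start/stop
    falls exactly on a grid boundary; within each inter-event segment the
    nominal step is shrunk to divide the segment evenly (actual step <=
    ``step``).  The default 0.05 h step resolves 1-h infusions and 3.5-h
    sessions far below observation error for this stiffness-free system.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    validate_sessions(list(sessions))

    cl_hd = dialyzer_clearance(settings) if settings is not None and sessions else 0.0
    bps = _event_breakpoints(doses, sessions, t_end)

    h_list: list[np.ndarray] = []
    cl_list: list[np.ndarray] = []
    rin_list: list[np.ndarray] = []
    t_nodes: list[np.ndarray] = [np.array([0.0])]
    for b0, b1 in zip(bps[:-1], bps[1:]):
        seg = b1 - b0
        if seg <= 1e-12:
            continue
        n = max(1, int(math.ceil(seg / step - 1e-9)))
        h = seg / n
        mid = b0 + 0.5 * h  # any interior point identifies the regime
        rin = sum(d.amount / d.t_inf for d in doses if d.time <= mid < d.time + d.t_inf)
        in_session = any(s.start <= mid < s.end for s in sessions)
        cl = params.cl_body + (cl_hd if in_session else 0.0)
        h_list.append(np.full(n, h))
        cl_list.append(np.full(n, cl))
        rin_list.append(np.full(n, rin))
        t_nodes.append(b0 + h * np.arange(1, n + 1))

    h_arr = np.concatenate(h_list) if h_list else np.empty(0)
    cl_arr = np.concatenate(cl_list) if cl_list else np.empty(0)
    rin_arr = np.concatenate(rin_list) if rin_list else np.empty(0)
    grid = np.concatenate(t_nodes)
    grid[-1] = t_end  # guard against cumulative round-off

    a1 = np.zeros(grid.shape[0])
    a2 = np.zeros(grid.shape[0])
    _rkg_loop(h_arr, cl_arr, rin_arr, params.v1, params.q, params.v2, a1, a2)

    conc = np.maximum(a1 / params.v1, 0.0)
    return ConcentrationProfile(grid=grid, conc=conc, step=step, a1=a1, a2=a2)


def terminal_rate_constant(params: IndividualPKParams) -> float:
    """Slow (terminal) eigenvalue magnitude of the disposition matrix (1/h)."""
    k10 = params.cl_body / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    return 0.5 * (s - disc)
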