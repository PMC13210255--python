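"""Compartmental glutamate–glutamine–GABA cycle.

Three compartments — extracellular space, astrocyte, GABAergic neuron —
exchange glutamate carbon through five steps:

1. astrocytic uptake of extracellular glutamate (Michaelis–Menten),
2. glutamine synthetase (GS) conversion glutamate → glutamine in the
   astrocyte, which shuts off once cumulative conversion reaches a fixed
   fraction (default 90%) of cumulative uptake,
3. glutamine shuttle astrocyte → neuron (first order),
4. neuronal glutaminase glutamine → glutamate (first order),
5. glutamate decarboxylase (GAD) glutamate → GABA (first order,
   irreversible).

Ammonia is held constant and is folded into the GS rate constant; ATP is
bookkept as ``atp_per_glu`` molecules consumed per glutamate taken up.  The
cycle is closed: every flux transfers carbon between tracked pools, so the
sum of all six pools is exactly conserved.  Optional neuronal re-release
(``release_rate`` > 0) feeds glutamate back to the extracellular space and
gives the cycle a finite resting level; it is off by default, which makes
extracellular glutamate monotone nonincreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .batch import NOT_REACHED, NumericalError, _rk4, mm_rate
from .params import ConfigError

__all__ = [
    "CycleState",
    "CycleParams",
    "CycleTrajectory",
    "cycle_rhs",
    "integrate_cycle",
    "threshold_times",
    "min_extracellular_glu",
    "conversion_fraction",
    "resting_preset",
]

POOLS = ("glu_ecm", "glu_astro", "gln_astro", "gln_neuron",
         "glu_neuron", "gaba_neuron")
_STATE_FIELDS = POOLS + ("atp_consumed", "cum_uptake", "cum_gs")
_IDX = {name: i for i, name in enumerate(_STATE_FIELDS)}


@dataclass
class CycleState:
    """Pool concentrations (mol/m³) plus cumulative diagnostics.

    ``atp_consumed``, ``cum_uptake`` and ``cum_gs`` are cumulative amounts
    (mol/m³) of ATP spent, glutamate taken up, and glutamate converted by
    GS; the latter two drive the conversion cap.
    """

    time: float = 0.0
    glu_ecm: float = 0.0
    glu_astro: float = 0.0
    gln_astro: float = 0.0
    gln_neuron: float = 0.0
    glu_neuron: float = 0.0
    gaba_neuron: float = 0.0
    atp_consumed: float = 0.0
    cum_uptake: float = 0.0
    cum_gs: float = 0.0

    def __post_init__(self) -> None:
        for name in _STATE_FIELDS:
            if getattr(self, name) < 0:
                raise ConfigError(f"negative pool {name}")

    def total_carbon(self) -> float:
        """Sum of all glutamate-carbon pools (conserved)."""
        return sum(getattr(self, p) for p in POOLS)

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _STATE_FIELDS])

    @classmethod
    def from_vector(cls, time: float, y: np.ndarray) -> "CycleState":
        return cls(time=time, **{n: float(max(y[i], 0.0))
                                 for n, i in _IDX.items()})


@dataclass(frozen=True)
class CycleParams:
    """Rate constants of the cycle.

    All first-order constants are 1/s; ``uptake_Vmax`` is mol/(m³·s) and
    ``uptake_KM`` mol/m³.  ``completion_cap`` is the fraction of cumulative
    uptake that GS is allowed to convert; ``cap_mode`` selects how the cap
    is enforced: ``"hard"`` (flux = 0 once reached; exact asymptote),
    ``"smooth"`` (logistic gate of width ``smooth_width``), or ``"pool"``
    (gate on the astrocytic glutamine fraction instead of cumulative
    amounts, which admits a steady cycling state).
    """

    uptake_Vmax: float = 0.01
    uptake_KM: float = 0.05
    gs_rate: float = 0.05
    completion_cap: float = 0.90
    gln_transfer_rate: float = 0.05
    glnase_rate: float = 0.05
    gad_rate: float = 0.05
    release_rate: float = 0.0
    atp_per_glu: float = 1.5
    cap_mode: str = "hard"
    smooth_width: float = 0.009

    def __post_init__(self) -> None:
        if not (0 < self.completion_cap < 1):
            raise ConfigError("completion_cap must be in (0, 1)")
        if not (self.atp_per_glu > 1):
            raise ConfigError("atp_per_glu must be > 1")
        for name in ("uptake_Vmax", "gs_rate", "gln_transfer_rate",
                     "glnase_rate", "gad_rate", "release_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (self.uptake_KM > 0):
            raise ConfigError("uptake_KM must be > 0")
        if self.cap_mode not in ("hard", "smooth", "pool"):
            raise ConfigError(f"unknown cap_mode {self.cap_mode!r}")
        if not (self.smooth_width > 0):
            raise ConfigError("smooth_width must be > 0")


def resting_preset() -> CycleParams:
    """Parameters calibrated to a resting steady state in the 1–5 µM band.

    Slow loop turnover (~2.9e-3 1/s), neuronal re-release on, GAD off, and
    the pool-fraction cap mode, so the closed glutamate/glutamine loop
    settles at a finite extracellular level (~2 µM for a 0.53 mol/m³ total
    load) instead of draining to zero.
    """
    k = 2.9e-3
    return CycleParams(gs_rate=k, gln_transfer_rate=k, glnase_rate=k,
                       release_rate=k, gad_rate=0.0, cap_mode="pool")


def resting_state(total_carbon: float,
                  params: CycleParams | None = None) -> CycleState:
    """Steady cycling state of the resting preset for a given carbon load.

    At steady state every loop flux equals the uptake flux R = MM(c*), and
    each first-order pool holds R/k; c* solves the closed-form carbon
    balance total = c* + R·(1/gs + 1/transfer + 1/glnase + 1/release).
    """
    from scipy.optimize import brentq

    p = params if params is not None else resting_preset()
    if p.release_rate <= 0 or p.gad_rate != 0:
        raise ConfigError("resting_state needs re-release on and GAD off")
    if not (total_carbon > 0):
        raise ConfigError("total_carbon must be > 0")

    inv = (1.0 / p.gs_rate + 1.0 / p.gln_transfer_rate
           + 1.0 / p.glnase_rate + 1.0 / p.release_rate)

    def residual(c):
        return c + mm_rate(c, p.uptake_Vmax, p.uptake_KM) * inv - total_carbon

    c_star = brentq(residual, 0.0, total_carbon)
    R = float(mm_rate(c_star, p.uptake_Vmax, p.uptake_KM))
    return CycleState(
        glu_ecm=c_star,
        glu_astro=R / p.gs_rate,
        gln_astro=R / p.gln_transfer_rate,
        gln_neuron=R / p.glnase_rate,
        glu_neuron=R / p.release_rate,
    )


def _gs_gate(cum_gs: float, cum_uptake: float, gln_astro: float,
             glu_astro: float, p: CycleParams) -> float:
    if p.cap_mode == "pool":
        total = glu_astro + gln_astro
        if total <= 0:
            return 1.0
        return 1.0 if gln_astro / total < p.completion_cap else 0.0
    if cum_uptake <= 0:
        return 1.0
    frac = cum_gs / cum_uptake
    if p.cap_mode == "hard":
        # continuous ramp on the remaining headroom: full flux until the
        # converted fraction is within 0.1% of the cap, then flux ∝ headroom,
        # so cum_gs approaches cap·cum_uptake exponentially from below and
        # never overshoots.
        headroom = p.completion_cap * cum_uptake - cum_gs
        scale = 1e-3 * p.completion_cap * cum_uptake
        return float(np.clip(headroom / scale, 0.0, 1.0))
    # smooth logistic gate
    x = (frac - p.completion_cap) / p.smooth_width
    return 1.0 / (1.0 + math.exp(min(x, 50.0)))


def cycle_fluxes(state: CycleState, params: CycleParams) -> dict[str, float]:
    """Instantaneous fluxes (mol/m³/s) of the five cycle steps."""
    uptake = float(mm_rate(state.glu_ecm, params.uptake_Vmax, params.uptake_KM))
    gate = _gs_gate(state.cum_gs, state.cum_uptake, state.gln_astro,
                    state.glu_astro, params)
    gs = params.gs_rate * state.glu_astro * gate
    transfer = params.gln_transfer_rate * state.gln_astro
    glnase = params.glnase_rate * state.gln_neuron
    gad = params.gad_rate * state.glu_neuron
    release = params.release_rate * state.glu_neuron
    return {"uptake": uptake, "gs": gs, "transfer": transfer,
            "glnase": glnase, "gad": gad, "release": release}


def cycle_rhs(state: CycleState, params: CycleParams) -> dict[str, float]:
    """Time derivatives of every pool and cumulative diagnostic."""
    f = cycle_fluxes(state, params)
    return {
        "glu_ecm": -f["uptake"] + f["release"],
        "glu_astro": f["uptake"] - f["gs"],
        "gln_astro": f["gs"] - f["transfer"],
        "gln_neuron": f["transfer"] - f["glnase"],
        "glu_neuron": f["glnase"] - f["gad"] - f["release"],
        "gaba_neuron": f["gad"],
        "atp_consumed": params.atp_per_glu * f["uptake"],
        "cum_uptake": f["uptake"],
        "cum_gs": f["gs"],
    }


@dataclass
class CycleTrajectory:
    """Sampled cycle trajectory."""

    times: np.ndarray
    values: np.ndarray  # (nt, len(_STATE_FIELDS))
    params: CycleParams

    def series(self, name: str) -> np.ndarray:
        return self.values[:, _IDX[name]]

    def state(self, k: int) -> CycleState:
        return CycleState.from_vector(float(self.times[k]), self.values[k])

    def to_frame(self):
        import pandas as pd

        frames = [pd.DataFrame({"time_s": self.times, "species": n,
                                "concentration": self.series(n)})
                  for n in _STATE_FIELDS]
        return pd.concat(frames, ignore_index=True)


def _cycle_rhs_vec(t, y, params: CycleParams):
    state = CycleState.from_vector(t, np.maximum(y, 0.0))
    d = cycle_rhs(state, params)
    return np.array([d[n] for n in _STATE_FIELDS])


def integrate_cycle(state0: CycleState, params: CycleParams, t_end: float,
                    dt_out: float = 0.5, method: str = "LSODA",
                    dt: float | None = None) -> CycleTrajectory:
    """Integrate the cycle from ``state0`` to ``t_end``.

    LSODA with tight tolerances by default; the hard conversion gate is a
    one-way switch, which adaptive solvers traverse without difficulty.
    """
    if not (t_end > 0):
        raise ConfigError(f"t_end must be > 0, got {t_end!r}")
    y0 = state0.as_vector()
    n_out = int(round(t_end / dt_out))
    t_eval = state0.time + np.linspace(0.0, t_end, n_out + 1)
    if method == "rk4":
        vals = _rk4(_cycle_rhs_vec, y0, t_eval, dt if dt else dt_out,
                    args=(params,))
    else:
        sol = solve_ivp(_cycle_rhs_vec, (t_eval[0], t_eval[-1]), y0,
                        method=method, t_eval=t_eval, args=(params,),
                        rtol=1e-10, atol=1e-14)
        if not sol.success:
            last = CycleState.from_vector(float(sol.t[-1]), sol.y[:, -1]) \
                if sol.t.size else state0
            raise NumericalError(f"cycle integration failed: {sol.message}", last)
        vals = sol.y.T
    return CycleTrajectory(times=t_eval, values=np.maximum(vals, 0.0),
                           params=params)


def threshold_times(traj: CycleTrajectory, thresholds) -> dict[float, float]:
    """First time extracellular glutamate falls below each threshold.

    Linear interpolation between samples; ``NOT_REACHED`` (inf) when a
    threshold is never crossed.
    """
    if len(traj.times) == 0:
        raise ConfigError("empty trajectory")
    glu = traj.series("glu_ecm")
    out: dict[float, float] = {}
    for thr in thresholds:
        below = np.nonzero(glu < thr)[0]
        if below.size == 0:
            out[float(thr)] = NOT_REACHED
            continue
        k = int(below[0])
        if k == 0:
            out[float(thr)] = float(traj.times[0])
        else:
            t0, t1 = traj.times[k - 1], traj.times[k]
            c0, c1 = glu[k - 1], glu[k]
            out[float(thr)] = float(t0 + (c0 - thr) / (c0 - c1) * (t1 - t0))
    return out


def min_extracellular_glu(traj: CycleTrajectory) -> float:
    """Minimum extracellular glutamate over the trajectory, mol/m³."""
    if len(traj.times) == 0:
        raise ConfigError("empty trajectory")
    return float(np.min(traj.series("glu_ecm")))


def conversion_fraction(traj: CycleTrajectory) -> float:
    """Cumulative GS conversion as a fraction of cumulative uptake at the
    final sample (the quantity capped at ``completion_cap``)."""
    cum_up = traj.series("cum_uptake")[-1]
    if cum_up <= 0:
        return 0.0
    return float(traj.series("cum_gs")[-1] / cum_up)
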