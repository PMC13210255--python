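"""Well-mixed batch-reactor model of the scaffold release network.

Five delivery species — free scaffold SC, free peptide p, free complex pSC,
matrix-immobilized peptide mp, and matrix-immobilized complex mpSC — evolve
by reversible scaffold–peptide binding plus Michaelis–Menten enzymatic
degradation of the two matrix-bound species.  Each degradation event cleaves
one glutamate-bearing unit of the poly-γ-glutamic-acid shell, producing one
GABA and one CO₂ (irreversible decarboxylation); the enzyme itself is a
catalyst and is never consumed.

Matrix-bound concentrations are stored per unit area (mol/m²) and enter the
bulk balances multiplied by the specific surface area Ssa, so the batch
reactor and the spatial solver share one kinetics implementation
(:func:`network_rates`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .params import ConfigError, KineticParams, NETWORK_SPECIES

__all__ = [
    "BatchState",
    "BatchTrajectory",
    "RateTerms",
    "NumericalError",
    "mm_rate",
    "network_rates",
    "rate_vector",
    "equilibrate",
    "integrate_batch",
    "depletion_time",
    "conservation_totals",
]

NOT_REACHED = math.inf  # sentinel for thresholds never crossed

_IDX = {name: i for i, name in enumerate(NETWORK_SPECIES)}


class NumericalError(RuntimeError):
    """Integration failure; carries the last good state when available."""

    def __init__(self, message: str, last_state: "BatchState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class BatchState:
    """Time-stamped concentration vector of the well-mixed reactor.

    Bulk species are mol/m³; matrix-bound species (mp, mpSC) are mol/m².
    """

    time: float
    conc: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.conc) - set(NETWORK_SPECIES)
        if unknown:
            raise ConfigError(f"unknown species in state: {sorted(unknown)}")
        for name in NETWORK_SPECIES:
            self.conc.setdefault(name, 0.0)
        for name, c in self.conc.items():
            if c < 0:
                raise ConfigError(f"negative concentration {name}={c!r}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.conc[n] for n in NETWORK_SPECIES])

    @classmethod
    def from_vector(cls, time: float, y: np.ndarray) -> "BatchState":
        return cls(time=time, conc={n: float(y[i]) for i, n in enumerate(NETWORK_SPECIES)})


@dataclass(frozen=True)
class RateTerms:
    """Net production rate per species (mol/m³/s bulk, mol/m²/s bound),
    plus the two Michaelis–Menten degradation fluxes in bulk units."""

    rates: Mapping[str, float]
    RMM_mp: float
    RMM_mpSC: float


def mm_rate(c, Vmax, KM):
    """Michaelis–Menten rate Vmax·c/(KM + c); saturates at Vmax.

    Accepts scalars or arrays; c and Vmax must be non-negative, KM positive.
    """
    if not np.all(np.asarray(KM) > 0):
        raise ConfigError(f"KM must be > 0, got {KM!r}")
    if np.any(np.asarray(c) < 0):
        raise ConfigError("mm_rate: negative concentration")
    if np.any(np.asarray(Vmax) < 0):
        raise ConfigError("mm_rate: negative Vmax")
    return Vmax * c / (KM + c)


def network_rates(csc, cp, cpsc, vmp, vmpsc, kf1, kr1, Vmax, KM):
    """Net rates of the release network in bulk-equivalent units.

    ``vmp`` and ``vmpsc`` are the matrix species already scaled to bulk
    equivalents (surface concentration × Ssa, mol/m³).  Returns
    ``(Rsc, Rp, Rpsc, Rvmp, Rvmpsc, Rgaba, RMMmp, RMMmpsc)`` where Rvmp and
    Rvmpsc are rates of the bulk-equivalent matrix concentrations; divide by
    Ssa for the per-area rates.  All arguments may be arrays (the spatial
    solver passes per-cell fields and a per-cell Vmax mask).
    """
    RMMmp = mm_rate(vmp, Vmax, KM)
    RMMmpsc = mm_rate(vmpsc, Vmax, KM)
    bind_free = kf1 * csc * cp - kr1 * cpsc       # SC + p  -> pSC
    bind_matrix = kf1 * csc * vmp - kr1 * vmpsc   # SC + mp -> mpSC
    Rsc = -(bind_free + bind_matrix)
    Rp = -bind_free + RMMmp
    Rpsc = bind_free + RMMmpsc
    Rvmp = -bind_matrix - RMMmp
    Rvmpsc = bind_matrix - RMMmpsc
    Rgaba = RMMmp + RMMmpsc
    return Rsc, Rp, Rpsc, Rvmp, Rvmpsc, Rgaba, RMMmp, RMMmpsc


def rate_vector(state: BatchState, params: KineticParams) -> RateTerms:
    """Evaluate the full rate expressions at a batch state.

    Degradation acts on bulk-equivalent matrix concentrations (surface
    concentration × Ssa); the enzyme is catalytic with zero net rate; GABA
    and CO₂ appear stoichiometrically with degradation.
    """
    c = state.conc
    ssa = params.Ssa
    Rsc, Rp, Rpsc, Rvmp, Rvmpsc, Rgaba, RMMmp, RMMmpsc = network_rates(
        c["SC"], c["p"], c["pSC"], c["mp"] * ssa, c["mpSC"] * ssa,
        params.kf1, params.kr1, params.Vmax, params.KM,
    )
    rates = {
        "SC": float(Rsc),
        "p": float(Rp),
        "pSC": float(Rpsc),
        "mp": float(Rvmp / ssa),      # per-area, mol/m²/s
        "mpSC": float(Rvmpsc / ssa),  # per-area, mol/m²/s
        "enzyme": 0.0,
        "GABA": float(Rgaba),
        "CO2": float(Rgaba),
    }
    return RateTerms(rates=rates, RMM_mp=float(RMMmp), RMM_mpSC=float(RMMmpsc))


def equilibrium_partition(total_peptide: float, total_scaffold: float,
                          bound_fraction: float, params: KineticParams
                          ) -> dict[str, float]:
    """Partition moiety totals at binding equilibrium, bulk-equivalent units.

    Solves kf1·cSC·cp = kr1·cpSC and kf1·cSC·vmp = kr1·vmpSC subject to
    exact conservation of the scaffold total (cSC + cpSC + vmpSC) and the
    peptide total (cp + cpSC + vmp + vmpSC), with ``bound_fraction`` of the
    peptide immobilized.  The shared dissociation constant K = kr1/kf1 makes
    cSC the root of a single binding quadratic.
    """
    if total_peptide < 0 or total_scaffold < 0:
        raise ConfigError("totals must be >= 0")
    if not (0 <= bound_fraction <= 1):
        raise ConfigError("bound_fraction must be in [0, 1]")
    P, S = total_peptide, total_scaffold
    K = params.kr1 / params.kf1
    if S == 0:
        csc = 0.0
    else:
        b = K + P - S
        csc = 0.5 * (-b + math.sqrt(b * b + 4.0 * S * K))
    assert csc >= 0, "binding quadratic produced a negative root"
    denom = K + csc
    cp = (1.0 - bound_fraction) * P * K / denom
    vmp = bound_fraction * P * K / denom
    cpsc = csc * cp / K
    vmpsc = csc * vmp / K
    return {"SC": csc, "p": cp, "pSC": cpsc, "vmp": vmp, "vmpSC": vmpsc}


def equilibrate(total_peptide: float, total_scaffold: float,
                bound_fraction_of_peptide: float,
                params: KineticParams) -> BatchState:
    """Initial batch state with the binding network at equilibrium.

    Matrix species are stored per-area (bulk equivalent / Ssa); enzyme at
    ``params.enzyme0``; GABA and CO₂ at zero (no degradation has occurred).
    """
    eq = equilibrium_partition(total_peptide, total_scaffold,
                               bound_fraction_of_peptide, params)
    conc = {
        "SC": eq["SC"], "p": eq["p"], "pSC": eq["pSC"],
        "mp": eq["vmp"] / params.Ssa, "mpSC": eq["vmpSC"] / params.Ssa,
        "enzyme": params.enzyme0, "GABA": 0.0, "CO2": 0.0,
    }
    return BatchState(time=0.0, conc=conc)


@dataclass
class BatchTrajectory:
    """Sampled batch trajectory: times (s) and per-species series."""

    times: np.ndarray              # (nt,)
    conc: np.ndarray               # (nt, n_species) in NETWORK_SPECIES order
    params: KineticParams

    def species(self, name: str) -> np.ndarray:
        return self.conc[:, _IDX[name]]

    def state(self, k: int) -> BatchState:
        return BatchState.from_vector(float(self.times[k]), self.conc[k])

    def states(self):
        return [self.state(k) for k in range(len(self.times))]

    def to_frame(self):
        """Tidy long-format DataFrame: time_s, species, concentration."""
        import pandas as pd

        frames = []
        for name in NETWORK_SPECIES:
            frames.append(pd.DataFrame({
                "time_s": self.times,
                "species": name,
                "concentration": self.species(name),
            }))
        return pd.concat(frames, ignore_index=True)


def _batch_rhs(t, y, params: KineticParams):
    ssa = params.Ssa
    c = np.maximum(y, 0.0)  # guard against tiny negative excursions
    Rsc, Rp, Rpsc, Rvmp, Rvmpsc, Rgaba, _, _ = network_rates(
        c[_IDX["SC"]], c[_IDX["p"]], c[_IDX["pSC"]],
        c[_IDX["mp"]] * ssa, c[_IDX["mpSC"]] * ssa,
        params.kf1, params.kr1, params.Vmax, params.KM,
    )
    dy = np.zeros_like(y)
    dy[_IDX["SC"]] = Rsc
    dy[_IDX["p"]] = Rp
    dy[_IDX["pSC"]] = Rpsc
    dy[_IDX["mp"]] = Rvmp / ssa
    dy[_IDX["mpSC"]] = Rvmpsc / ssa
    dy[_IDX["GABA"]] = Rgaba
    dy[_IDX["CO2"]] = Rgaba
    # enzyme: catalytic, rate identically zero
    return dy


def _rk4(rhs, y0, t_eval, dt, args=()):
    """Fixed-step classical RK4 sampled at t_eval (t_eval ⊆ step grid)."""
    t0, t_end = t_eval[0], t_eval[-1]
    n_steps = int(round((t_end - t0) / dt))
    y = np.array(y0, dtype=float)
    out = np.empty((len(t_eval), len(y0)))
    out[0] = y
    next_out = 1
    t = t0
    for k in range(n_steps):
        k1 = rhs(t, y, *args)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1, *args)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2, *args)
        k4 = rhs(t + dt, y + dt * k3, *args)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + (k + 1) * dt
        while next_out < len(t_eval) and t >= t_eval[next_out] - 1e-12 * max(1.0, abs(t)):
            out[next_out] = y
            next_out += 1
    while next_out < len(t_eval):  # pragma: no cover - guard
        out[next_out] = y
        next_out += 1
    return out


def integrate_batch(state0: BatchState, params: KineticParams, t_end: float,
                    dt_out: float = 0.1, method: str = "LSODA",
                    dt: float | None = None,
                    rtol: float = 1e-10, atol: float = 1e-14) -> BatchTrajectory:
    """Integrate the batch reactor from ``state0`` to ``t_end``.

    The default integrator is stiff-safe adaptive LSODA with tight
    tolerances (moiety conservation to ~1e-10 relative).  ``method="rk4"``
    selects a fixed-step classical Runge–Kutta scheme with step ``dt``,
    used by the time-step independence study.
    """
    if not (t_end > 0):
        raise ConfigError(f"t_end must be > 0, got {t_end!r}")
    if not (dt_out > 0):
        raise ConfigError(f"dt_out must be > 0, got {dt_out!r}")
    y0 = state0.as_vector()
    n_out = int(round(t_end / dt_out))
    t_eval = state0.time + np.linspace(0.0, t_end, n_out + 1)

    if method == "rk4":
        step = dt if dt is not None else min(dt_out, 0.01)
        conc = _rk4(_batch_rhs, y0, t_eval, step, args=(params,))
    else:
        sol = solve_ivp(_batch_rhs, (t_eval[0], t_eval[-1]), y0,
                        method=method, t_eval=t_eval, args=(params,),
                        rtol=rtol, atol=atol)
        if not sol.success:
            last = BatchState.from_vector(float(sol.t[-1]), sol.y[:, -1]) if sol.t.size else state0
            raise NumericalError(f"batch integration failed: {sol.message}", last)
        conc = sol.y.T
    conc = np.where(np.abs(conc) < 1e2 * atol, np.maximum(conc, 0.0), conc)
    if np.any(conc < -1e2 * atol):
        raise NumericalError("negative concentrations beyond tolerance")
    return BatchTrajectory(times=t_eval, conc=np.maximum(conc, 0.0), params=params)


def depletion_time(traj: BatchTrajectory, species: str, fraction: float) -> float:
    """First time conc(species) drops below ``fraction`` × its initial value.

    Linear interpolation between output samples; returns ``NOT_REACHED``
    (inf) if the threshold is never crossed.
    """
    if len(traj.times) == 0:
        raise ConfigError("empty trajectory")
    if not (0 < fraction < 1):
        raise ConfigError("fraction must be in (0, 1)")
    series = traj.species(species)
    c0 = series[0]
    if c0 <= 0:
        return NOT_REACHED
    thr = fraction * c0
    below = np.nonzero(series < thr)[0]
    if below.size == 0:
        return NOT_REACHED
    k = int(below[0])
    if k == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[k - 1], traj.times[k]
    c_prev, c_next = series[k - 1], series[k]
    return float(t0 + (c_prev - thr) / (c_prev - c_next) * (t1 - t0))


def conservation_totals(state: BatchState, params: KineticParams
                        ) -> tuple[float, float, float]:
    """Conserved moiety totals (bulk-equivalent mol/m³).

    scaffold = SC + pSC + mpSC·Ssa; peptide = p + pSC + (mp + mpSC)·Ssa;
    enzyme as-is.  Both moieties are exactly conserved by the network.
    """
    c = state.conc
    ssa = params.Ssa
    scaffold = c["SC"] + c["pSC"] + c["mpSC"] * ssa
    peptide = c["p"] + c["pSC"] + (c["mp"] + c["mpSC"]) * ssa
    return scaffold, peptide, c["enzyme"]
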