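"""Scenario fixtures: every input the pipeline needs, generated in code.

The default fixture is the frozen study condition: a 12 mm × 3 mm cylinder,
binding-equilibrium depot loading, enzyme at 2e-6 mol/m³ in the cellular
zone, dt = 0.01 s, and the documented kinetic defaults.  Each value carries
a provenance note distinguishing transcribed anchors from calibrated
stand-ins.  Seeded parameter ensembles support sensitivity sweeps of the
binding and degradation constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from . import params as _p
from .batch import BatchState, equilibrate, equilibrium_partition
from .params import (ConfigError, DepotLoading, KineticParams,
                     ParameterBundle, bundle_to_config, default_config,
                     load_params)
from .spatial import (DomainMap, Grid, SpatialScenario, assign_domains,
                      build_grid, default_output_times)

__all__ = [
    "ScenarioFixture",
    "default_params",
    "default_scenario",
    "sample_params",
    "make_initial_fields",
]

#: provenance notes for the default fixture's headline values.
DEFAULT_PROVENANCE = {
    "kinetics.enzyme0": "transcribed: initial enzyme 2e-6 mol/m3",
    "grid.R": "transcribed: cylinder radius 3 mm",
    "grid.L": "transcribed: cylinder length 12 mm",
    "sim.dt": "transcribed: time step 0.01 s",
    "transport.A_const": "transcribed: A = 260 cm2/(s*Dalton^(1/3))",
    "transport.gel_factor": "transcribed: gel correction 0.9",
    "cycle.completion_cap": "transcribed: conversion stops at 90%",
    "kinetics.kf1": "calibrated default (affinity-delivery literature scale)",
    "kinetics.kr1": "calibrated default (affinity-delivery literature scale)",
    "kinetics.Vmax": "calibrated once to the ~16 s mpSC depletion anchor",
    "kinetics.KM": "calibrated default (mM-scale enzyme constant)",
    "kinetics.Ssa": "calibrated default",
    "loading.total_scaffold": "calibrated default depot loading",
    "loading.total_peptide": "calibrated default depot loading",
    "loading.bound_fraction": "calibrated default depot loading",
    "cycle.uptake_Vmax": "calibrated default",
    "cycle.uptake_KM": "calibrated default (GLT-1-scale affinity)",
    "species.*.molecular_weight": "exact for metabolites; documented "
                                  "placeholders for peptide/scaffold species",
}


@dataclass
class ScenarioFixture:
    """Self-contained, reproducible scenario description.

    ``config`` is the flat key→value mapping every CLI subcommand accepts;
    the remaining attributes are the materialized objects derived from it.
    """

    config: dict[str, Any]
    bundle: ParameterBundle
    seed: int = 0
    provenance: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PROVENANCE))

    @property
    def kinetics(self) -> KineticParams:
        return self.bundle.kinetics

    @property
    def loading(self) -> DepotLoading:
        return self.bundle.loading

    def grid(self) -> Grid:
        c = self.config
        return build_grid(int(c.get("grid.nr", 16)), int(c.get("grid.nz", 64)),
                          float(c.get("grid.R", 3e-3)), float(c.get("grid.L", 12e-3)))

    def domain_map(self, grid: Grid | None = None) -> DomainMap:
        return assign_domains(self.config.get("domains.preset", "default"),
                              grid or self.grid())

    def batch_state0(self) -> BatchState:
        ld = self.loading
        return equilibrate(ld.total_peptide, ld.total_scaffold,
                           ld.bound_fraction, self.kinetics)

    def spatial_scenario(self, nr: int | None = None, nz: int | None = None,
                         t_end: float | None = None,
                         method: str = "RK45") -> SpatialScenario:
        grid = self.grid()
        if nr is not None or nz is not None:
            grid = build_grid(nr or grid.nr, nz or grid.nz, grid.R, grid.L)
        dmap = self.domain_map(grid)
        fields = make_initial_fields(grid, dmap, self.loading, self.bundle)
        te = float(t_end if t_end is not None else self.config.get("sim.t_end", 60.0))
        return SpatialScenario(
            bundle=self.bundle, grid=grid, domain_map=dmap,
            initial_fields=fields, t_end=te,
            dt=float(self.config.get("sim.dt", 0.01)),
            method=method, output_times=default_output_times(te),
        )

    def cycle_params(self):
        from .cycle import CycleParams

        c = self.config
        kw = {}
        for f in dataclasses.fields(CycleParams):
            key = f"cycle.{f.name}"
            if key in c:
                kw[f.name] = c[key] if f.name == "cap_mode" else float(c[key])
        return CycleParams(**kw)

    def cycle_state0(self):
        from .cycle import CycleState

        return CycleState(glu_ecm=float(self.config.get("cycle.glu_ecm0", 0.53)))


def default_params(seed: int = 0, overrides: Mapping[str, Any] | None = None
                   ) -> ScenarioFixture:
    """The frozen default scenario fixture.

    Deterministic: two calls yield identical fixtures.  ``overrides`` are
    flat config keys applied on top of the packaged defaults.
    """
    cfg = default_config()
    if overrides:
        cfg.update(overrides)
    return ScenarioFixture(config=cfg, bundle=load_params(cfg), seed=seed)


# alias mirroring the fixture's role as a full scenario
default_scenario = default_params

#: log-uniform sweep bounds (factor below, factor above the default).
DEFAULT_RANGES = {"kinetics.kf1": (0.1, 10.0), "kinetics.kr1": (0.1, 10.0),
                  "kinetics.Vmax": (0.1, 10.0), "kinetics.KM": (0.1, 10.0)}


def sample_params(seed: int, n: int,
                  ranges: Mapping[str, tuple[float, float]] | None = None
                  ) -> list[ScenarioFixture]:
    """Seeded ensemble of fixtures with log-uniformly perturbed constants.

    ``ranges`` maps config keys to (lo_factor, hi_factor) multiplicative
    bounds around the default value; defaults to ×/÷10 on kf1, kr1, Vmax
    and KM.  The same seed always yields the identical ensemble.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    ranges = dict(ranges if ranges is not None else DEFAULT_RANGES)
    for key, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ConfigError(f"invalid range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    base = default_config()
    out = []
    for k in range(n):
        cfg = dict(base)
        for key in sorted(ranges):
            lo, hi = ranges[key]
            factor = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            cfg[key] = float(base[key]) * factor
        out.append(ScenarioFixture(config=cfg, bundle=load_params(cfg),
                                   seed=seed,
                                   provenance={"ensemble": f"member {k} of "
                                               f"seed-{seed} sweep"}))
    return out


def make_initial_fields(grid: Grid, domain_map: DomainMap,
                        loading: DepotLoading, bundle: ParameterBundle
                        ) -> dict[str, np.ndarray]:
    """Initial concentration fields for a spatial run.

    Depot cells carry the binding-equilibrium partition of the loadings
    (matrix species per-area); every delivery species is zero outside the
    depot; the enzyme starts in the cellular zone at ``enzyme0``.
    """
    if loading.total_scaffold < 0 or loading.total_peptide < 0:
        raise ConfigError("loading must be >= 0")
    kin = bundle.kinetics
    eq = equilibrium_partition(loading.total_peptide, loading.total_scaffold,
                               loading.bound_fraction, kin)
    depot = domain_map.depot_mask.astype(float)
    cellular = domain_map.cellular_mask.astype(float)
    zeros = np.zeros((grid.nr, grid.nz))
    return {
        "SC": eq["SC"] * depot,
        "p": eq["p"] * depot,
        "pSC": eq["pSC"] * depot,
        "mp": eq["vmp"] / kin.Ssa * depot,
        "mpSC": eq["vmpSC"] / kin.Ssa * depot,
        "enzyme": kin.enzyme0 * cellular,
        "GABA": zeros.copy(),
        "CO2": zeros.copy(),
    }
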