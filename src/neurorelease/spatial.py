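"""2D axisymmetric finite-volume reaction–diffusion solver.

The geometry is a cylinder of radius ``R`` (default 3 mm) and length ``L``
(default 12 mm), discretized on a uniform cell-centered (r, z) grid.  Cell
volumes are 2π·r·Δr·Δz; radial faces have area 2π·r_face·Δz and axial faces
2π·r·Δr.  All outer boundaries are no-flux: zero flux at the r = 0 symmetry
axis and reflecting (symmetric) conditions at r = R, z = 0 and z = L, which
makes the domain closed — total amounts are discretely conserved.

Three biological zones partition the cylinder: the cellular zone (k = 1),
the biomaterial depot (k = 2) and the surrounding media (k = 3).  The full
release network including Michaelis–Menten degradation runs in the depot;
only binding/dissociation runs elsewhere (Vmax forced to zero).  The
matrix-bound species mp and mpSC exist only on depot cells and do not
diffuse; their surface rates couple to the bulk through the specific
surface area Ssa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .batch import NumericalError, _rk4, network_rates
from .params import ConfigError, KineticParams, NETWORK_SPECIES, ParameterBundle

__all__ = [
    "Grid",
    "DomainMap",
    "SpatialRecord",
    "build_grid",
    "assign_domains",
    "axisym_laplacian",
    "spatial_rhs",
    "run_spatial",
    "total_bulk_concentration",
    "default_output_times",
]

CELLULAR, DEPOT, MEDIA = 1, 2, 3
BOUND_SPECIES = ("mp", "mpSC")
_IDX = {name: i for i, name in enumerate(NETWORK_SPECIES)}


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered axisymmetric mesh."""

    nr: int
    nz: int
    R: float = 3.0e-3
    L: float = 12.0e-3

    def __post_init__(self) -> None:
        if self.nr < 4 or self.nz < 4:
            raise ConfigError("nr and nz must be >= 4")
        if not (self.R > 0 and self.L > 0):
            raise ConfigError("R and L must be > 0")

    @property
    def dr(self) -> float:
        return self.R / self.nr

    @property
    def dz(self) -> float:
        return self.L / self.nz

    @property
    def r(self) -> np.ndarray:
        """Cell-center radii, shape (nr,)."""
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z(self) -> np.ndarray:
        """Cell-center axial coordinates, shape (nz,)."""
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def r_faces(self) -> np.ndarray:
        """Radial face positions, shape (nr+1,)."""
        return np.arange(self.nr + 1) * self.dr

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes 2π·r·Δr·Δz, shape (nr, nz)."""
        return (2.0 * np.pi * self.r * self.dr * self.dz)[:, None] * np.ones(self.nz)

    def total_volume(self) -> float:
        return float(self.cell_volumes().sum())


def build_grid(nr: int, nz: int, R: float = 3.0e-3, L: float = 12.0e-3) -> Grid:
    """Construct a uniform axisymmetric grid (validates its arguments)."""
    return Grid(nr=nr, nz=nz, R=R, L=L)


@dataclass(frozen=True)
class DomainMap:
    """Per-cell biological-zone labels (1 cellular, 2 depot, 3 media)."""

    labels: np.ndarray  # (nr, nz) int array

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.isin(lab, (CELLULAR, DEPOT, MEDIA)).all():
            raise ConfigError("domain labels must be 1, 2 or 3")
        if not (lab == DEPOT).any():
            raise ConfigError("depot (k=2) must be nonempty")
        object.__setattr__(self, "labels", lab)

    @property
    def depot_mask(self) -> np.ndarray:
        return self.labels == DEPOT

    @property
    def cellular_mask(self) -> np.ndarray:
        return self.labels == CELLULAR


#: named layout presets.  Region extents are fractions of (R, L).
PRESETS = {
    # coaxial depot: inner half-radius, central third of length; cellular
    # end-cap slab: outer sixth of the length at the z = L end; rest media.
    "default": {
        "depot": (0.0, 0.5, 1.0 / 3.0, 2.0 / 3.0),
        "cellular": (0.0, 1.0, 5.0 / 6.0, 1.0),
    },
    "depot-only": {"depot": (0.0, 1.0, 0.0, 1.0)},
    # depot and cellular zone sharing an interface at mid-length
    "abutting": {
        "depot": (0.0, 0.5, 1.0 / 3.0, 0.5),
        "cellular": (0.0, 0.5, 0.5, 2.0 / 3.0),
    },
}


def assign_domains(layout, grid: Grid) -> DomainMap:
    """Build a :class:`DomainMap` from a preset name or explicit regions.

    ``layout`` is either a key of :data:`PRESETS` or a mapping
    ``{"depot": (r0, r1, z0, z1), "cellular": (...)}`` with fractional
    extents of (R, L); cells are classified by a center-in-region rule,
    depot taking precedence over cellular, remainder labeled media.
    """
    if isinstance(layout, str):
        try:
            regions = PRESETS[layout]
        except KeyError:
            raise ConfigError(f"unknown layout preset {layout!r}") from None
    else:
        regions = dict(layout)
    labels = np.full((grid.nr, grid.nz), MEDIA, dtype=int)
    rf = grid.r / grid.R
    zf = grid.z / grid.L
    for name in ("cellular", "depot"):  # depot last: takes precedence
        if name not in regions:
            continue
        r0, r1, z0, z1 = regions[name]
        mask = ((rf[:, None] >= r0) & (rf[:, None] <= r1)
                & (zf[None, :] >= z0) & (zf[None, :] <= z1))
        labels[mask] = DEPOT if name == "depot" else CELLULAR
    if not (labels == DEPOT).any():
        raise ConfigError("layout leaves the depot empty")
    return DomainMap(labels=labels)


def _face_diffusivity(D: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean diffusivity at internal faces along ``axis``."""
    if axis == 0:
        a, b = D[:-1, :], D[1:, :]
    else:
        a, b = D[:, :-1], D[:, 1:]
    out = np.zeros_like(a)
    nz_mask = (a > 0) & (b > 0)
    out[nz_mask] = 2.0 * a[nz_mask] * b[nz_mask] / (a[nz_mask] + b[nz_mask])
    return out


def _laplacian_operator(grid: Grid, D) -> "callable":
    """Precompute geometry and face diffusivities; return field → ∇·(D∇c)."""
    dr, dz = grid.dr, grid.dz
    vols = grid.cell_volumes()
    area_r = (2.0 * np.pi * grid.r_faces[1:-1] * dz)[:, None]   # (nr-1, 1)
    area_z = (2.0 * np.pi * grid.r * dr)[:, None]               # (nr, 1)
    D_arr = np.broadcast_to(np.asarray(D, dtype=float),
                            (grid.nr, grid.nz))
    # face transmissibilities T = D_face·A/Δ (harmonic mean across cells)
    T_r = _face_diffusivity(D_arr, axis=0) * area_r / dr
    T_z = _face_diffusivity(D_arr, axis=1) * area_z / dz

    def op(field: np.ndarray) -> np.ndarray:
        out = np.zeros_like(field)
        flux_r = T_r * (field[1:, :] - field[:-1, :])
        out[:-1, :] += flux_r
        out[1:, :] -= flux_r
        flux_z = T_z * (field[:, 1:] - field[:, :-1])
        out[:, :-1] += flux_z
        out[:, 1:] -= flux_z
        return out / vols

    return op


def axisym_laplacian(field: np.ndarray, D, grid: Grid) -> np.ndarray:
    """Divergence of the diffusive flux, ∇·(D∇c), per cell (mol/m³/s).

    Finite-volume flux form with no-flux (symmetric) conditions on every
    boundary: radial faces carry area 2π·r_face·Δz, axial faces 2π·r·Δr,
    and the r = 0 axis face has zero area, which realizes ∂c/∂r = 0 there.
    ``D`` may be a scalar or an (nr, nz) array; across domain boundaries
    the face diffusivity is the harmonic mean of the two cell values.  The
    volume-weighted sum of the result is zero to rounding (closed box).
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.nr, grid.nz):
        raise ConfigError("field shape does not match grid")
    return _laplacian_operator(grid, D)(field)


@dataclass
class SpatialScenario:
    """Everything a spatial run needs: parameters, mesh, layout, initial
    fields and integrator settings."""

    bundle: ParameterBundle
    grid: Grid
    domain_map: DomainMap
    initial_fields: Mapping[str, np.ndarray]  # name -> (nr, nz)
    t_end: float = 60.0
    dt: float = 0.01             # fixed step for method="rk4"
    method: str = "RK45"
    output_times: np.ndarray | None = None
    rtol: float = 1e-6
    atol: float = 1e-12
    diffusion: bool = True       # False: pure-reaction (batch-oracle) mode
    cycle_sources: bool = False  # reserved hook; off by default


def default_output_times(t_end: float = 60.0, n: int = 25) -> np.ndarray:
    """Geometric output schedule over (0, t_end], plus t = 0."""
    return np.concatenate([[0.0], np.geomspace(t_end / 200.0, t_end, n)])


@dataclass
class SpatialRecord:
    """Space–time record: per-species field stacks at the output times."""

    times: np.ndarray                       # (nt,)
    fields: dict[str, np.ndarray]           # name -> (nt, nr, nz)
    grid: Grid
    domain_map: DomainMap
    params: KineticParams

    def field_at(self, species: str, k: int) -> np.ndarray:
        return self.fields[species][k]

    def total_amount(self, species: str) -> np.ndarray:
        """Total moles of a species per output time (surface species are
        integrated as amount = c·Ssa·V_cell / Ssa·... i.e. bulk-equivalent)."""
        vol = self.grid.cell_volumes()
        arr = self.fields[species]
        if species in BOUND_SPECIES:
            return np.einsum("trz,rz->t", arr, vol) * self.params.Ssa
        return np.einsum("trz,rz->t", arr, vol)


def _pack(fields: Mapping[str, np.ndarray]) -> np.ndarray:
    return np.stack([fields[n] for n in NETWORK_SPECIES]).ravel()


def _unpack(y: np.ndarray, grid: Grid) -> np.ndarray:
    return y.reshape(len(NETWORK_SPECIES), grid.nr, grid.nz)


def make_spatial_rhs(bundle: ParameterBundle, grid: Grid, domain_map: DomainMap,
                     diffusion: bool = True):
    """Build the vectorized method-of-lines right-hand side.

    Diffusion applies to diffusive bulk species only, with the gel
    diffusivity inside the depot and the water diffusivity elsewhere.
    Degradation (Vmax) is restricted to depot cells; binding/dissociation
    runs everywhere.  Bound-species rates are masked to the depot.
    """
    kin = bundle.kinetics
    depot = domain_map.depot_mask
    Vmax_map = np.where(depot, kin.Vmax, 0.0)
    lap_ops = {}
    if diffusion:
        for name in NETWORK_SPECIES:
            if bundle.species[name].diffusive:
                D_map = np.where(depot, bundle.D_gel(name), bundle.D_water(name))
                lap_ops[name] = _laplacian_operator(grid, D_map)
    ssa = kin.Ssa

    def rhs(t, y):
        c = _unpack(y, grid)
        c = np.maximum(c, 0.0)
        dy = np.zeros_like(c)
        csc, cp, cpsc = c[_IDX["SC"]], c[_IDX["p"]], c[_IDX["pSC"]]
        vmp, vmpsc = c[_IDX["mp"]] * ssa, c[_IDX["mpSC"]] * ssa
        Rsc, Rp, Rpsc, Rvmp, Rvmpsc, Rgaba, _, _ = network_rates(
            csc, cp, cpsc, vmp, vmpsc, kin.kf1, kin.kr1, Vmax_map, kin.KM)
        dy[_IDX["SC"]] = Rsc
        dy[_IDX["p"]] = Rp
        dy[_IDX["pSC"]] = Rpsc
        dy[_IDX["mp"]] = np.where(depot, Rvmp / ssa, 0.0)
        dy[_IDX["mpSC"]] = np.where(depot, Rvmpsc / ssa, 0.0)
        dy[_IDX["GABA"]] = Rgaba
        dy[_IDX["CO2"]] = Rgaba
        for name, op in lap_ops.items():
            i = _IDX[name]
            dy[i] += op(c[i])
        return dy.ravel()

    return rhs


def spatial_rhs(fields: Mapping[str, np.ndarray], bundle: ParameterBundle,
                grid: Grid, domain_map: DomainMap) -> dict[str, np.ndarray]:
    """One evaluation of the method-of-lines RHS on named fields."""
    rhs = make_spatial_rhs(bundle, grid, domain_map)
    dy = _unpack(rhs(0.0, _pack(fields)), grid)
    return {name: dy[i] for name, i in _IDX.items()}


def _stable_dt(bundle: ParameterBundle, grid: Grid) -> float:
    """Explicit diffusion stability estimate (forward-Euler bound)."""
    Dmax = max(bundle.D_water(n) for n in NETWORK_SPECIES
               if bundle.species[n].diffusive)
    if Dmax <= 0:
        return np.inf
    return 1.0 / (2.0 * Dmax * (1.0 / grid.dr ** 2 + 1.0 / grid.dz ** 2))


def run_spatial(scenario: SpatialScenario) -> SpatialRecord:
    """Integrate the spatial model and sample the fields at the output times.

    Aborts with :class:`NumericalError` on NaN or negative concentrations
    beyond tolerance.  With all-reflecting boundaries the run is closed:
    each conserved moiety's total drifts by < 1e-6 relative.
    """
    grid, dm = scenario.grid, scenario.domain_map
    t_out = (np.asarray(scenario.output_times, dtype=float)
             if scenario.output_times is not None
             else default_output_times(scenario.t_end))
    if t_out[0] != 0.0:
        t_out = np.concatenate([[0.0], t_out])
    y0 = _pack({n: np.asarray(scenario.initial_fields.get(
        n, np.zeros((grid.nr, grid.nz))), dtype=float)
        for n in NETWORK_SPECIES})
    rhs = make_spatial_rhs(scenario.bundle, grid, dm,
                           diffusion=scenario.diffusion)

    if scenario.method == "rk4":
        dt = min(scenario.dt, 0.4 * _stable_dt(scenario.bundle, grid))
        span = t_out[-1] - t_out[0]
        n_steps = max(1, int(np.ceil(span / dt)))
        conc = _rk4(rhs, y0, t_out, span / n_steps)
    else:
        sol = solve_ivp(rhs, (t_out[0], t_out[-1]), y0, method=scenario.method,
                        t_eval=t_out, rtol=scenario.rtol, atol=scenario.atol)
        if not sol.success:
            raise NumericalError(f"spatial integration failed: {sol.message}")
        conc = sol.y.T
    if not np.all(np.isfinite(conc)):
        raise NumericalError("non-finite concentrations in spatial run")
    neg_tol = scenario.rtol * max(np.abs(conc).max(), 1e-30)
    if conc.min() < -neg_tol:
        raise NumericalError(
            f"negative concentrations beyond tolerance: min={conc.min():.3e}")
    conc = np.maximum(conc, 0.0)
    stacks = conc.reshape(len(t_out), len(NETWORK_SPECIES), grid.nr, grid.nz)
    fields = {n: np.ascontiguousarray(stacks[:, i]) for n, i in _IDX.items()}
    return SpatialRecord(times=t_out, fields=fields, grid=grid,
                         domain_map=dm, params=scenario.bundle.kinetics)


def total_bulk_concentration(record: SpatialRecord, species: str) -> np.ndarray:
    """Volume-averaged bulk concentration time series, mol/m³."""
    if len(record.times) == 0:
        raise ConfigError("empty record")
    if species in BOUND_SPECIES:
        raise ConfigError(f"{species} is matrix-bound, not a bulk species")
    vol = record.grid.cell_volumes()
    return np.einsum("trz,rz->t", record.fields[species], vol) / vol.sum()
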