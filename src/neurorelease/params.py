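"""Physical constants, species properties, and the diffusivity model.

All internal computation is in SI units (mol, m, s); concentrations are
mol/m³ for bulk species and mol/m² for matrix-bound species.  The
molecular-weight → diffusivity correlation is evaluated in cm²/s (its
native units) and converted to m²/s at the boundary of this module.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "SpeciesSpec",
    "TransportParams",
    "KineticParams",
    "DepotLoading",
    "ParameterBundle",
    "water_diffusivity",
    "gel_diffusivity",
    "load_params",
    "load_config",
    "save_config",
    "default_config",
]


class ConfigError(ValueError):
    """Raised for invalid configuration values or malformed config files."""


#: Canonical species of the release network and the glutamate cycle.
#: mp and mpSC are matrix-bound (surface) species and do not diffuse.
SPECIES_NAMES = (
    "SC", "p", "pSC", "mp", "mpSC", "enzyme", "GABA", "GLU", "GLN", "NH3", "CO2",
)
MATRIX_BOUND = frozenset({"mp", "mpSC"})

#: Species integrated by the batch reactor and spatial solver, in state order.
NETWORK_SPECIES = ("SC", "p", "pSC", "mp", "mpSC", "enzyme", "GABA", "CO2")

# Default molecular weights in Daltons.  Small metabolites are exact; the
# peptide/scaffold values are documented bulk-average placeholders (peptide
# ~1 kDa, scaffold ~10 kDa, enzyme ~65 kDa); complexes are sums of parts.
DEFAULT_MW = {
    "p": 1.0e3,
    "mp": 1.0e3,
    "SC": 1.0e4,
    "pSC": 1.1e4,
    "mpSC": 1.1e4,
    "enzyme": 6.5e4,
    "GABA": 103.12,
    "GLU": 147.13,
    "GLN": 146.15,
    "NH3": 17.03,
    "CO2": 44.01,
}


@dataclass(frozen=True)
class SpeciesSpec:
    """Identity and transport class of one chemical species.

    Parameters
    ----------
    name : str
        One of :data:`SPECIES_NAMES`.
    molecular_weight : float
        Molar mass in Daltons; must be positive.
    phase : str
        ``"bulk"`` or ``"matrix-bound"``.  Matrix-bound species live on the
        biomaterial surface (mol/m²) and never diffuse.
    """

    name: str
    molecular_weight: float
    phase: str = "bulk"

    def __post_init__(self) -> None:
        if self.name not in SPECIES_NAMES:
            raise ConfigError(f"unknown species name {self.name!r}")
        if not (self.molecular_weight > 0):
            raise ConfigError(
                f"species {self.name}: molecular_weight must be > 0, "
                f"got {self.molecular_weight!r}"
            )
        if self.phase not in ("bulk", "matrix-bound"):
            raise ConfigError(f"species {self.name}: bad phase {self.phase!r}")
        expected = "matrix-bound" if self.name in MATRIX_BOUND else "bulk"
        if self.phase != expected:
            raise ConfigError(
                f"species {self.name} must have phase {expected!r}"
            )

    @property
    def diffusive(self) -> bool:
        return self.phase == "bulk"


@dataclass(frozen=True)
class TransportParams:
    """Diffusivity correlation D = A·MW^(-1/3)·eq2_scale (cm²/s) and the
    porous-gel correction factor.

    ``eq2_scale`` defaults to 1e-7, which places protein diffusivities in
    the 1e-6…1e-7 cm²/s range expected for macromolecules in water.
    """

    A_const: float = 260.0          # cm²/(s·Dalton^(1/3))
    eq2_scale: float = 1.0e-7       # dimensionless scale of the correlation
    gel_factor: float = 0.9         # D_gel / D_water

    def __post_init__(self) -> None:
        if not (self.A_const > 0):
            raise ConfigError("A_const must be > 0")
        if not (self.eq2_scale > 0):
            raise ConfigError("eq2_scale must be > 0")
        if not (0 < self.gel_factor <= 1):
            raise ConfigError("gel_factor must be in (0, 1]")

    def water_diffusivity(self, molecular_weight: float) -> float:
        """Diffusivity in water, m²/s, from molecular weight in Daltons."""
        if not (molecular_weight > 0):
            raise ConfigError(
                f"molecular_weight must be > 0, got {molecular_weight!r}"
            )
        d_cm2 = self.A_const * molecular_weight ** (-1.0 / 3.0) * self.eq2_scale
        return d_cm2 * 1.0e-4  # cm²/s → m²/s

    def gel_diffusivity(self, d_water: float) -> float:
        """Diffusivity in the hydrogel, m²/s, from the water value."""
        if d_water < 0:
            raise ConfigError(f"D_water must be >= 0, got {d_water!r}")
        return self.gel_factor * d_water


def water_diffusivity(molecular_weight: float,
                      transport: TransportParams | None = None) -> float:
    """Module-level convenience wrapper around
    :meth:`TransportParams.water_diffusivity`."""
    return (transport or TransportParams()).water_diffusivity(molecular_weight)


def gel_diffusivity(d_water: float,
                    transport: TransportParams | None = None) -> float:
    """Module-level convenience wrapper around
    :meth:`TransportParams.gel_diffusivity`."""
    return (transport or TransportParams()).gel_diffusivity(d_water)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the binding/dissociation + degradation network.

    kf1
        scaffold–peptide association rate, m³/(mol·s).
    kr1
        complex dissociation rate, 1/s.
    Vmax, KM
        Michaelis–Menten parameters of the matrix-degrading enzyme,
        mol/(m³·s) and mol/m³.  One (Vmax, KM) pair serves both matrix
        substrates (mp and mpSC), each with its own saturation term.
    Ssa
        specific surface area of the biomaterial, 1/m; couples surface
        (mol/m²) reaction rates into bulk (mol/m³) balances.
    enzyme0
        initial enzyme concentration in the cellular zone, mol/m³.
    """

    kf1: float = 100.0       # m³/(mol·s)  (= 1e5 M⁻¹ s⁻¹)
    kr1: float = 0.01        # 1/s
    Vmax: float = 0.288      # mol/(m³·s)  (calibrated default, see docs)
    KM: float = 1.0          # mol/m³
    Ssa: float = 1.0e5       # 1/m
    enzyme0: float = 2.0e-6  # mol/m³

    def __post_init__(self) -> None:
        for name in ("kf1", "kr1", "KM", "Ssa"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        # Vmax = 0 is admissible: it switches degradation off, which the
        # spatial solver uses outside the depot and tests use to probe the
        # pure binding equilibrium.
        if self.Vmax < 0:
            raise ConfigError(f"Vmax must be >= 0, got {self.Vmax!r}")
        if self.enzyme0 < 0:
            raise ConfigError(f"enzyme0 must be >= 0, got {self.enzyme0!r}")


@dataclass(frozen=True)
class DepotLoading:
    """Total moiety loadings of the depot, in bulk-equivalent mol/m³.

    ``bound_fraction`` is the fraction of total peptide covalently
    immobilized to the matrix (mp + mpSC); the rest is free (p + pSC).
    """

    total_scaffold: float = 1.0e-3   # mol/m³
    total_peptide: float = 1.0e-2    # mol/m³
    bound_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.total_scaffold < 0 or self.total_peptide < 0:
            raise ConfigError("loadings must be >= 0")
        if not (0 <= self.bound_fraction <= 1):
            raise ConfigError("bound_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ParameterBundle:
    """Validated bundle of species specs, transport and kinetic parameters."""

    species: Mapping[str, SpeciesSpec]
    transport: TransportParams
    kinetics: KineticParams
    loading: DepotLoading

    def __post_init__(self) -> None:
        missing = set(SPECIES_NAMES) - set(self.species)
        if missing:
            raise ConfigError(f"missing species: {sorted(missing)}")

    def D_water(self, name: str) -> float:
        """Diffusivity of a species in water, m²/s (0 for bound species)."""
        sp = self.species[name]
        if not sp.diffusive:
            return 0.0
        return self.transport.water_diffusivity(sp.molecular_weight)

    def D_gel(self, name: str) -> float:
        """Diffusivity of a species in the hydrogel, m²/s."""
        return self.transport.gel_diffusivity(self.D_water(name))

    def diffusivity_table(self) -> dict[str, dict[str, float]]:
        """Per-species water and gel diffusivities, m²/s."""
        return {
            name: {"D_water": self.D_water(name), "D_gel": self.D_gel(name)}
            for name in SPECIES_NAMES
        }


# --- flat key-value configuration ------------------------------------------

_TRANSPORT_KEYS = {f.name for f in dataclasses.fields(TransportParams)}
_KINETIC_KEYS = {f.name for f in dataclasses.fields(KineticParams)}
_LOADING_KEYS = {f.name for f in dataclasses.fields(DepotLoading)}


def default_config() -> dict[str, Any]:
    """The packaged default configuration as a flat key→value mapping."""
    text = (
        importlib.resources.files("neurorelease")
        .joinpath("data/defaults.yaml")
        .read_text()
    )
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):  # pragma: no cover - packaging sanity
        raise ConfigError("packaged defaults are malformed")
    return cfg


def load_config(source: Any | None = None) -> dict[str, Any]:
    """Load a flat config mapping from a path, file object, mapping or None."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    if hasattr(source, "read"):
        cfg = yaml.safe_load(source.read())
    else:
        with open(source, "r") as fh:
            cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a flat key: value mapping")
    return cfg


def _as_float(key: str, value: Any) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{key}: expected a number, got {value!r}") from None
    if not math.isfinite(out):
        raise ConfigError(f"{key}: value must be finite, got {value!r}")
    return out


def load_params(config_source: Any | None = None) -> ParameterBundle:
    """Build a validated :class:`ParameterBundle` from a flat config.

    Recognised keys are ``species.<NAME>.molecular_weight``,
    ``transport.<field>``, ``kinetics.<field>`` and ``loading.<field>``.
    Keys in other namespaces (grid.*, sim.*, cycle.*, domains.*) are the
    concern of other modules and pass through untouched; unknown keys
    *inside* the namespaces handled here are rejected.
    """
    cfg = load_config(config_source)

    mw = dict(DEFAULT_MW)
    transport_kw: dict[str, float] = {}
    kinetic_kw: dict[str, float] = {}
    loading_kw: dict[str, float] = {}

    for key, value in cfg.items():
        parts = str(key).split(".")
        ns = parts[0]
        if ns == "species":
            if len(parts) != 3 or parts[2] != "molecular_weight":
                raise ConfigError(f"unknown config key {key!r}")
            name = parts[1]
            if name not in SPECIES_NAMES:
                raise ConfigError(f"unknown species name {name!r} in {key!r}")
            mw[name] = _as_float(key, value)
        elif ns == "transport":
            if len(parts) != 2 or parts[1] not in _TRANSPORT_KEYS:
                raise ConfigError(f"unknown config key {key!r}")
            transport_kw[parts[1]] = _as_float(key, value)
        elif ns == "kinetics":
            if len(parts) != 2 or parts[1] not in _KINETIC_KEYS:
                raise ConfigError(f"unknown config key {key!r}")
            kinetic_kw[parts[1]] = _as_float(key, value)
        elif ns == "loading":
            if len(parts) != 2 or parts[1] not in _LOADING_KEYS:
                raise ConfigError(f"unknown config key {key!r}")
            loading_kw[parts[1]] = _as_float(key, value)
        elif ns in ("grid", "sim", "cycle", "domains"):
            continue  # owned by other modules
        else:
            raise ConfigError(f"unknown config key {key!r}")

    species = {
        name: SpeciesSpec(
            name=name,
            molecular_weight=mw[name],
            phase="matrix-bound" if name in MATRIX_BOUND else "bulk",
        )
        for name in SPECIES_NAMES
    }
    bundle = ParameterBundle(
        species=species,
        transport=TransportParams(**transport_kw),
        kinetics=KineticParams(**kinetic_kw),
        loading=DepotLoading(**loading_kw),
    )

    # physical-plausibility guard on every diffusive species
    for name in SPECIES_NAMES:
        d = bundle.D_water(name)
        if d and not (1e-12 <= d <= 1e-8):
            raise ConfigError(
                f"D_water({name}) = {d:.3e} m²/s outside the plausible "
                "macromolecule range 1e-12…1e-8 m²/s"
            )
    return bundle


def bundle_to_config(bundle: ParameterBundle) -> dict[str, Any]:
    """Flatten a bundle back to the flat key→value config form."""
    cfg: dict[str, Any] = {}
    for name in SPECIES_NAMES:
        cfg[f"species.{name}.molecular_weight"] = bundle.species[name].molecular_weight
    for f in dataclasses.fields(TransportParams):
        cfg[f"transport.{f.name}"] = getattr(bundle.transport, f.name)
    for f in dataclasses.fields(KineticParams):
        cfg[f"kinetics.{f.name}"] = getattr(bundle.kinetics, f.name)
    for f in dataclasses.fields(DepotLoading):
        cfg[f"loading.{f.name}"] = getattr(bundle.loading, f.name)
    return cfg


def save_config(cfg: Mapping[str, Any], path) -> None:
    """Write a flat config mapping to a YAML file, keys sorted, full
    floating-point precision preserved."""
    out = {}
    for k in sorted(cfg):
        v = cfg[k]
        out[k] = float(v) if isinstance(v, (int, float, np.floating)) and not isinstance(v, bool) else v
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, default_flow_style=False, sort_keys=True)
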