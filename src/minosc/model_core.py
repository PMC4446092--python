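"""Pointwise kinetics of the MinD/MinE membrane cycle.

The model tracks six species: cytosolic MinD.ATP monomers (``D``) and MinE
homodimers (``E2``), plus four membrane-bound states -- MinD monomers (``d``),
MinD dimers (``d2``), MinE dimers (``e2``) and the MinDE heterotetramer
(``d2e2``).  Cytosolic concentrations are volumetric (per um^3), membrane
concentrations are areal (per um^2).

All cytosolic MinD is treated as nucleotide-active: MinD released from the
membrane after hydrolysis is returned directly to the ``D`` pool.  Every
reaction is irreversible (back rates are zero).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MEMBRANE_DIFFUSION_SCALING",
    "SPECIES",
    "RateParameters",
    "ConcentrationTotals",
    "PointState",
    "TemperatureScaling",
    "MembraneRates",
    "ExchangeFluxes",
    "membrane_reaction_rates",
    "exchange_fluxes",
    "boltzmann_factor",
    "boltzmann_scaled_hydr",
    "mine_equilibrium_partition",
    "preset",
    "PRESETS",
]

#: Molar gas constant in kcal mol^-1 K^-1 (activation energies are quoted
#: per mole, so the per-mole constant is the right normalisation).
GAS_CONSTANT_KCAL = 1.987204258640832e-3

#: Canonical species ordering used throughout the package.
SPECIES = ("D", "E2", "d", "d2", "e2", "d2e2")

#: Membrane diffusion prefactor for each bound species, as a fraction of the
#: base membrane diffusion coefficient D_m.  The factor is the inverse of the
#: number of membrane targeting sequences in the complex.
MEMBRANE_DIFFUSION_SCALING = {"d": 1.0, "d2": 0.5, "e2": 0.5, "d2e2": 0.25}


@dataclass(frozen=True)
class RateParameters:
    """The nine rate and diffusion constants of the reaction network.

    Units: ``omega_db``/``omega_eb`` um s^-1 (surface binding of a volumetric
    species), ``omega_edf``/``omega_dim`` um^2 s^-1 (bimolecular membrane
    reactions), ``omega_hydr``/``omega_er`` s^-1, diffusion coefficients
    um^2 s^-1.
    """

    omega_db: float = 4.0
    omega_edf: float = 22.0
    omega_dim: float = 0.002
    omega_hydr: float = 0.12
    omega_eb: float = 0.07
    omega_er: float = 30.0
    D_D: float = 16.0
    D_E: float = 20.0
    D_m: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate parameter {f.name} must be finite and >= 0, got {v}")

    def replace(self, **kw) -> "RateParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RateParameters":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown rate parameter(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ConcentrationTotals:
    """Cell-average protein concentrations held fixed over the cell cycle.

    ``minD_total`` counts MinD monomers, ``minE_dimer_total`` counts MinE
    homodimers (each carrying two monomers), both per um^3 of cytoplasm.
    """

    minD_total: float = 1389.0
    minE_dimer_total: float = 486.0

    def __post_init__(self) -> None:
        if self.minD_total <= 0 or self.minE_dimer_total <= 0:
            raise ValueError("total concentrations must be positive")

    @property
    def minE_monomer_total(self) -> float:
        return 2.0 * self.minE_dimer_total

    def scaled(self, factor: float) -> "ConcentrationTotals":
        return ConcentrationTotals(self.minD_total * factor, self.minE_dimer_total * factor)


@dataclass(frozen=True)
class PointState:
    """Concentrations of all six species at a single axial position.

    Fields may be scalars or equal-shaped arrays; the kinetics below are
    vectorised.
    """

    D: float | np.ndarray = 0.0
    E2: float | np.ndarray = 0.0
    d: float | np.ndarray = 0.0
    d2: float | np.ndarray = 0.0
    e2: float | np.ndarray = 0.0
    d2e2: float | np.ndarray = 0.0

    def validate(self) -> None:
        for name in SPECIES:
            v = np.asarray(getattr(self, name))
            if not np.all(np.isfinite(v)):
                raise ValueError(f"species {name} contains non-finite values")
            if np.any(v < 0):
                raise ValueError(f"species {name} is negative")


@dataclass(frozen=True)
class TemperatureScaling:
    """Arrhenius/Boltzmann scaling of the hydrolysis rate.

    ``epsilon`` is the activation energy of the combined ATP hydrolysis and
    heterotetramer dissociation step in kcal mol^-1; ``T0`` the reference
    temperature (305.15 K = 32 C) at which the scaling factor is exactly 1.
    """

    epsilon: float = 11.5
    T0: float = 305.15
    k: float = GAS_CONSTANT_KCAL


class MembraneRates(NamedTuple):
    """Reaction-only time derivatives of the four membrane species (um^-2 s^-1)."""

    d: float | np.ndarray
    d2: float | np.ndarray
    e2: float | np.ndarray
    d2e2: float | np.ndarray


class ExchangeFluxes(NamedTuple):
    """Net membrane-to-cytosol surface fluxes (um^-2 s^-1), positive = release."""

    minD: float | np.ndarray
    minE: float | np.ndarray


def membrane_reaction_rates(s: PointState, p: RateParameters, *, check: bool = True) -> MembraneRates:
    """Reaction terms of the four membrane-bound species.

    Includes arrival from the cytosol (``omega_db * D`` into ``d``,
    ``omega_eb * E2`` into ``e2``) and loss to the cytosol (MinE release,
    MinE-stimulated monomer release, hydrolysis of the heterotetramer), so
    that together with :func:`exchange_fluxes` the MinD monomer and MinE
    dimer budgets close exactly.
    """
    if check:
        s.validate()
    dimerisation = p.omega_dim * s.d * s.d
    monomer_strip = p.omega_edf * s.e2 * s.d
    tetramer_form = p.omega_edf * s.e2 * s.d2
    hydrolysis = p.omega_hydr * s.d2e2
    return MembraneRates(
        d=p.omega_db * s.D - 2.0 * dimerisation - monomer_strip,
        d2=dimerisation - tetramer_form,
        e2=p.omega_eb * s.E2 - p.omega_er * s.e2 - tetramer_form + hydrolysis,
        d2e2=tetramer_form - hydrolysis,
    )


def exchange_fluxes(s: PointState, p: RateParameters, *, check: bool = True) -> ExchangeFluxes:
    """Net surface fluxes feeding the cytosolic species.

    MinD returns to the cytosol when MinE strips a membrane monomer
    (``omega_edf * e2 * d``) and when hydrolysis dissolves a heterotetramer
    (two monomers per ``d2e2``); it leaves by membrane binding.  MinE dimers
    leave the membrane at ``omega_er`` and bind at ``omega_eb``.
    """
    if check:
        s.validate()
    minD = p.omega_edf * s.e2 * s.d + 2.0 * p.omega_hydr * s.d2e2 - p.omega_db * s.D
    minE = p.omega_er * s.e2 - p.omega_eb * s.E2
    return ExchangeFluxes(minD=minD, minE=minE)


def boltzmann_factor(T: float, ts: TemperatureScaling = TemperatureScaling()) -> float:
    """Rate scaling factor exp(eps * (T - T0) / (k * T * T0)); 1 at T = T0."""
    if T <= 0:
        raise ValueError(f"temperature must be positive (kelvin), got {T}")
    return float(np.exp(ts.epsilon * (T - ts.T0) / (ts.k * T * ts.T0)))


def boltzmann_scaled_hydr(p: RateParameters, T: float, ts: TemperatureScaling = TemperatureScaling()) -> float:
    """Hydrolysis rate rescaled to temperature ``T`` (kelvin)."""
    return p.omega_hydr * boltzmann_factor(T, ts)


def mine_equilibrium_partition(p: RateParameters) -> tuple[float, float]:
    """MinE membrane binding/release balance in the absence of MinD.

    Returns ``(omega_er / omega_eb, cytoplasmic fraction in %)``.  The
    abundance comparison between an areal and a volumetric pool needs a
    surface-to-volume conversion; a unit length (1 um^-1) convention is used,
    so the cytoplasmic fraction is ``1 / (1 + omega_eb / omega_er)``.
    """
    if p.omega_eb == 0:
        return float("inf"), 100.0
    if p.omega_er == 0:
        return 0.0, 0.0
    ratio = p.omega_er / p.omega_eb
    fraction = 100.0 / (1.0 + p.omega_eb / p.omega_er)
    return ratio, fraction


#: Named parameter sets.  The two presets model the same cell under different
#: GFP labelling of MinD: full labelling stabilises the membrane-bound dimer
#: (slower hydrolysis/dissociation) and slows cytosolic diffusion.
PRESETS: dict[str, RateParameters] = {
    "fully_labelled": RateParameters(omega_hydr=0.12, D_D=16.0),
    "partially_labelled": RateParameters(omega_hydr=0.5, D_D=24.0),
}


def preset(name: str) -> RateParameters:
    """Return one of the built-in parameter sets (see :data:`PRESETS`)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
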