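"""Analytic dielectric models of cells, beads and suspension media.

Cells are described by the classical single-shell model: a conducting
cytoplasm sphere wrapped in a thin, poorly conducting membrane.  The module
exposes the equivalent complex permittivity of the shelled sphere and the
Clausius--Mossotti (CM) factor of a particle suspended in a medium, the two
quantities that set the amplitude and phase of an impedance-cytometry
signal at each excitation frequency.

All public functions accept frequencies in Hz.  Geometric fields keep the
units in their names (``diameter_um``, ``membrane_thickness_nm``); they are
converted to SI exactly once, inside the model evaluation.

Material presets (the editable table shipped as ``data/presets.yaml``) are
loaded through :func:`load_presets` / :func:`get_preset`.  The preset values
are plausible literature-style stand-ins, not measured constants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import yaml

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class CellLabel(str, enum.Enum):
    WBC = "WBC"
    TUMOR = "TUMOR"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Medium:
    """Homogeneous suspension medium (e.g. PBS)."""

    conductivity_S_per_m: float
    relative_permittivity: float

    def __post_init__(self) -> None:
        if self.conductivity_S_per_m <= 0:
            raise ValueError("medium conductivity must be > 0")
        if self.relative_permittivity < 1:
            raise ValueError("medium relative permittivity must be >= 1")

    def complex_permittivity(self, frequency: float) -> complex:
        """Relative complex permittivity eps_r - j*sigma/(omega*eps0)."""
        _check_frequency(frequency)
        omega = 2.0 * math.pi * frequency
        return self.relative_permittivity - 1j * self.conductivity_S_per_m / (omega * EPS0)


@dataclass(frozen=True)
class ShelledCell:
    """Single-shell cell: cytoplasm core + thin membrane shell."""

    diameter_um: float
    membrane_thickness_nm: float
    membrane_conductivity_S_per_m: float
    membrane_relative_permittivity: float
    cytoplasm_conductivity_S_per_m: float
    cytoplasm_relative_permittivity: float
    label: CellLabel = CellLabel.OTHER
    subtype: str = ""

    def __post_init__(self) -> None:
        if not (1.0 < self.diameter_um < 50.0):
            raise ValueError(f"diameter must be in (1, 50) um, got {self.diameter_um}")
        radius_nm = self.diameter_um * 1e3 / 2.0
        if not (0.0 < self.membrane_thickness_nm < radius_nm):
            raise ValueError("membrane thickness must be in (0, radius)")
        if self.membrane_conductivity_S_per_m < 0 or self.cytoplasm_conductivity_S_per_m < 0:
            raise ValueError("conductivities must be >= 0")
        if self.membrane_relative_permittivity < 1 or self.cytoplasm_relative_permittivity < 1:
            raise ValueError("relative permittivities must be >= 1")

    @property
    def radius_m(self) -> float:
        return self.diameter_um * 1e-6 / 2.0

    @property
    def specific_membrane_capacitance(self) -> float:
        """Membrane capacitance per unit area, F/m^2 (derived convenience)."""
        return EPS0 * self.membrane_relative_permittivity / (self.membrane_thickness_nm * 1e-9)

    def with_diameter(self, diameter_um: float) -> "ShelledCell":
        """Copy of this cell with a different diameter (same dielectrics)."""
        return ShelledCell(
            diameter_um=diameter_um,
            membrane_thickness_nm=self.membrane_thickness_nm,
            membrane_conductivity_S_per_m=self.membrane_conductivity_S_per_m,
            membrane_relative_permittivity=self.membrane_relative_permittivity,
            cytoplasm_conductivity_S_per_m=self.cytoplasm_conductivity_S_per_m,
            cytoplasm_relative_permittivity=self.cytoplasm_relative_permittivity,
            label=self.label,
            subtype=self.subtype,
        )


@dataclass(frozen=True)
class BeadParticle:
    """Homogeneous dielectric sphere (e.g. polystyrene calibration bead)."""

    diameter_um: float
    relative_permittivity: float
    conductivity_S_per_m: float = 0.0
    label: CellLabel = field(default=CellLabel.OTHER)
    subtype: str = "bead"

    def __post_init__(self) -> None:
        if not (1.0 < self.diameter_um < 50.0):
            raise ValueError(f"diameter must be in (1, 50) um, got {self.diameter_um}")
        if self.conductivity_S_per_m < 0:
            raise ValueError("conductivity must be >= 0")
        if self.relative_permittivity < 1:
            raise ValueError("relative permittivity must be >= 1")

    @property
    def radius_m(self) -> float:
        return self.diameter_um * 1e-6 / 2.0

    def with_diameter(self, diameter_um: float) -> "BeadParticle":
        return BeadParticle(
            diameter_um=diameter_um,
            relative_permittivity=self.relative_permittivity,
            conductivity_S_per_m=self.conductivity_S_per_m,
            label=self.label,
            subtype=self.subtype,
        )


Particle = Union[ShelledCell, BeadParticle]


def _check_frequency(frequency: float) -> None:
    if not (frequency > 0):
        raise ValueError(f"frequency must be > 0 Hz, got {frequency}")


def _complex_permittivity(relative_permittivity: float, conductivity: float, frequency: float) -> complex:
    omega = 2.0 * math.pi * frequency
    return relative_permittivity - 1j * conductivity / (omega * EPS0)


def equivalent_complex_permittivity(cell: ShelledCell, frequency: float) -> complex:
    """Relative complex permittivity of the shelled sphere.

    Standard two-phase (shell around core) reduction: with gamma the cubed
    ratio of outer to inner radius and u the core/shell contrast factor,

        eps_eq = eps_shell * (gamma + 2 u) / (gamma - u),
        u = (eps_core - eps_shell) / (eps_core + 2 eps_shell).

    Degenerates to the core permittivity when shell == core or when the
    shell thickness vanishes.
    """
    _check_frequency(frequency)
    r_outer = cell.radius_m
    r_inner = r_outer - cell.membrane_thickness_nm * 1e-9
    if r_inner <= 0:
        raise ValueError("membrane thickness must be smaller than the radius")
    eps_mem = _complex_permittivity(
        cell.membrane_relative_permittivity, cell.membrane_conductivity_S_per_m, frequency
    )
    eps_cyt = _complex_permittivity(
        cell.cytoplasm_relative_permittivity, cell.cytoplasm_conductivity_S_per_m, frequency
    )
    gamma = (r_outer / r_inner) ** 3
    u = (eps_cyt - eps_mem) / (eps_cyt + 2.0 * eps_mem)
    return eps_mem * (gamma + 2.0 * u) / (gamma - u)


def particle_complex_permittivity(particle: Particle, frequency: float) -> complex:
    """Relative complex permittivity of any supported particle type."""
    if isinstance(particle, ShelledCell):
        return equivalent_complex_permittivity(particle, frequency)
    if isinstance(particle, BeadParticle):
        _check_frequency(frequency)
        return _complex_permittivity(
            particle.relative_permittivity, particle.conductivity_S_per_m, frequency
        )
    raise TypeError(f"unsupported particle type: {type(particle)!r}")


def clausius_mossotti(particle: Particle, medium: Medium, frequency: float) -> complex:
    """Complex Clausius--Mossotti factor (eps_p - eps_m) / (eps_p + 2 eps_m).

    The real part is bounded in [-0.5, 1.0] for physical parameters.
    """
    _check_frequency(frequency)
    eps_p = particle_complex_permittivity(particle, frequency)
    eps_m = medium.complex_permittivity(frequency)
    return (eps_p - eps_m) / (eps_p + 2.0 * eps_m)


def cm_spectrum(particle: Particle, medium: Medium, frequencies) -> np.ndarray:
    """Vector of CM factors at each frequency (complex ndarray)."""
    return np.array([clausius_mossotti(particle, medium, f) for f in frequencies])


# ---------------------------------------------------------------------------
# Preset table
# ---------------------------------------------------------------------------

_PRESET_CACHE: dict | None = None


def _default_preset_path():
    return resources.files("cytosim").joinpath("data/presets.yaml")


def load_presets(path: str | Path | None = None) -> dict:
    """Load the material / population preset table.

    Without ``path`` the packaged default table is used (and cached).
    The file layout is documented in ``data/presets.yaml`` itself.
    """
    global _PRESET_CACHE
    if path is None:
        if _PRESET_CACHE is None:
            with _default_preset_path().open("r") as fh:
                _PRESET_CACHE = yaml.safe_load(fh)
        return _PRESET_CACHE
    with open(path, "r") as fh:
        return yaml.safe_load(fh)


def get_medium(name: str = "PBS", presets: dict | None = None) -> Medium:
    presets = presets or load_presets()
    try:
        entry = presets["media"][name]
    except KeyError as exc:
        raise KeyError(f"unknown medium preset {name!r}") from exc
    return Medium(
        conductivity_S_per_m=float(entry["conductivity_S_per_m"]),
        relative_permittivity=float(entry["relative_permittivity"]),
    )


def get_preset(name: str, diameter_um: float | None = None, presets: dict | None = None) -> Particle:
    """Build a particle from a named preset, optionally overriding diameter."""
    presets = presets or load_presets()
    if name in presets.get("cells", {}):
        entry = presets["cells"][name]
        return ShelledCell(
            diameter_um=float(diameter_um if diameter_um is not None else entry["diameter_um"]),
            membrane_thickness_nm=float(entry["membrane_thickness_nm"]),
            membrane_conductivity_S_per_m=float(entry["membrane_conductivity_S_per_m"]),
            membrane_relative_permittivity=float(entry["membrane_relative_permittivity"]),
            cytoplasm_conductivity_S_per_m=float(entry["cytoplasm_conductivity_S_per_m"]),
            cytoplasm_relative_permittivity=float(entry["cytoplasm_relative_permittivity"]),
            label=CellLabel(entry.get("label", "OTHER")),
            subtype=name,
        )
    if name in presets.get("beads", {}):
        entry = presets["beads"][name]
        return BeadParticle(
            diameter_um=float(diameter_um if diameter_um is not None else entry.get("diameter_um", 10.0)),
            relative_permittivity=float(entry["relative_permittivity"]),
            conductivity_S_per_m=float(entry.get("conductivity_S_per_m", 0.0)),
            subtype=name,
        )
    raise KeyError(f"unknown particle preset {name!r}")


def population_defaults(name: str, presets: dict | None = None) -> dict:
    """Diameter-distribution defaults for a named population preset."""
    presets = presets or load_presets()
    try:
        return dict(presets["populations"][name])
    except KeyError as exc:
        raise KeyError(f"unknown population preset {name!r}") from exc
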