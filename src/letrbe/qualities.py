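"""Radiation qualities and nuclear geometry.

A :class:`RadiationQuality` bundles the particle type and its dose-averaged
linear energy transfer (LET, keV/um), which together determine how damage is
distributed in space: photons deposit energy quasi-uniformly across the
nucleus, while charged particles concentrate damage along straight tracks,
with the number of tracks per unit dose falling as 1/LET.

The preset registry covers six qualities spanning 0.45-129.3 keV/um
(225 kVp X-rays, 58 MeV and 11 MeV protons, 71 MeV/u and 26 MeV/u carbon
ions, and 2.88 MeV alpha particles), loaded from ``data/qualities.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

_PARTICLES = ("photon", "proton", "carbon", "alpha")

#: Dose-fluence conversion constant: D[Gy] = 0.1602 * LET[keV/um] * Phi[um^-2] / rho[g/cm^3]
FLUENCE_DOSE_CONSTANT = 0.1602


@dataclass(frozen=True)
class RadiationQuality:
    """A radiation quality: particle species, energy and dose-averaged LET.

    Parameters
    ----------
    label : str
        Human-readable identifier, e.g. ``"xray"`` or ``"carbon_73"``.
    particle : {"photon", "proton", "carbon", "alpha"}
        Particle species. Photons use the uniform (non-track) spatial model.
    energy_mev : float
        Beam energy in MeV (MeV/u for ions); informational only.
    let : float
        Dose-averaged LET in keV/um. Must be positive.
    """

    label: str
    particle: str
    energy_mev: float
    let: float

    def __post_init__(self) -> None:
        if self.particle not in _PARTICLES:
            raise ValueError(f"unknown particle {self.particle!r}; expected one of {_PARTICLES}")
        if not self.let > 0:
            raise ValueError(f"LET must be positive, got {self.let}")

    @property
    def is_photon(self) -> bool:
        return self.particle == "photon"


@dataclass(frozen=True)
class NucleusGeometry:
    """Spherical cell-nucleus geometry used for track sampling.

    The cross-sectional area pi*r^2 converts particle fluence into an
    expected number of track traversals per nucleus.

    Parameters
    ----------
    radius : float
        Nuclear radius in um.
    density : float
        Tissue density in g/cm^3 (water-equivalent by default).
    """

    radius: float = 4.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("nucleus radius must be positive")
        if not self.density > 0:
            raise ValueError("density must be positive")

    @property
    def cross_sectional_area(self) -> float:
        """Cross-sectional area pi*r^2 in um^2."""
        return math.pi * self.radius**2

    @property
    def volume(self) -> float:
        """Nuclear volume in um^3."""
        return 4.0 / 3.0 * math.pi * self.radius**3


def _load_quality_presets() -> dict[str, RadiationQuality]:
    text = resources.files("letrbe").joinpath("data/qualities.yaml").read_text()
    raw = yaml.safe_load(text)
    presets: dict[str, RadiationQuality] = {}
    for label, spec in raw.items():
        missing = {"particle", "energy_mev", "let"} - set(spec)
        if missing:
            raise ValueError(f"quality preset {label!r} missing fields {sorted(missing)}")
        presets[label] = RadiationQuality(
            label=label,
            particle=spec["particle"],
            energy_mev=float(spec["energy_mev"]),
            let=float(spec["let"]),
        )
    return presets


#: The six study qualities, keyed by label, ordered by increasing LET.
QUALITY_PRESETS: dict[str, RadiationQuality] = _load_quality_presets()

#: Preset labels sorted by LET (ascending).
QUALITY_ORDER: tuple[str, ...] = tuple(
    sorted(QUALITY_PRESETS, key=lambda k: QUALITY_PRESETS[k].let)
)
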