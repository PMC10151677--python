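"""Material definitions, photon cross sections and the 6 MV source spectrum.

Everything the dose engines need to turn geometry into attenuation lives
here: elemental mass attenuation tables (bundled CSV, see :mod:`.xsgen`),
the mixture rule, closed-form transmission, interaction-channel and
Compton sampling, and a parameterized 6 MV bremsstrahlung spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .xsgen import (
    M_E_C2,
    PAIR_THRESHOLD,
    compton_energy_transfer_fraction,
)

CHANNELS = ("photoelectric", "compton", "pair")
_CHANNEL_COLUMNS = {"photoelectric": "photoelectric", "compton": "incoherent", "pair": "pair"}


class UnknownElementError(KeyError):
    pass


class EnergyRangeError(ValueError):
    pass


@dataclass(frozen=True)
class Material:
    """A homogeneous material: name, bulk density and elemental composition.

    ``composition`` is a tuple of (element symbol, mass fraction); fractions
    must sum to one within 1e-6.
    """

    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, expected 1")

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, self.composition)


def _formula_fractions(counts: dict[str, int]) -> tuple[tuple[str, float], ...]:
    from .xsgen import ELEMENTS

    mass = {el: n * ELEMENTS[el][1] for el, n in counts.items()}
    total = sum(mass.values())
    return tuple((el, m / total) for el, m in mass.items())


# -- canonical materials -----------------------------------------------------
# Densities follow the printed values: Ti casing 4.54, NdFeB magnet 7.6
# (geometry) / 7.4 (physics default, see build notes), PEEK 1.3, wax 0.92,
# silicone shell 1.1; "plastic water" is treated as water at unit density.
WATER = Material("water", 1.0, (("H", 0.1119), ("O", 0.8881)))
AIR = Material("air", 0.0012, (("N", 0.765), ("O", 0.235)))
WAX = Material("wax", 0.92, _formula_fractions({"C": 25, "H": 52}))
PEEK = Material("peek", 1.3, _formula_fractions({"C": 19, "H": 12, "O": 3}))
SILICONE = Material("silicone", 1.1, _formula_fractions({"C": 2, "H": 6, "O": 1, "Si": 1}))
TITANIUM = Material("titanium", 4.54, (("Ti", 1.0),))
NDFEB = Material("ndfeb", 7.4, _formula_fractions({"Nd": 2, "Fe": 14, "B": 1}))
NDFEB_76 = NDFEB.with_density(7.6)

MATERIALS: dict[str, Material] = {
    m.name: m for m in (WATER, AIR, WAX, PEEK, SILICONE, TITANIUM, NDFEB)
}


class CrossSectionTable:
    """Elemental mass attenuation coefficients with log-log interpolation.

    Backed by the bundled CSV (energy grid 0.01-10 MeV, 60 log-spaced
    points, channels photoelectric / incoherent / pair).  Partial channels
    sum to the total by construction.
    """

    def __init__(self, frame: pd.DataFrame):
        self._elements: dict[str, dict[str, np.ndarray]] = {}
        for el, grp in frame.groupby("element"):
            grp = grp.sort_values("energy_mev")
            self._elements[el] = {
                "energy": grp["energy_mev"].to_numpy(),
                "photoelectric": grp["photoelectric"].to_numpy(),
                "incoherent": grp["incoherent"].to_numpy(),
                "pair": grp["pair"].to_numpy(),
                "total": grp["total"].to_numpy(),
            }
        any_el = next(iter(self._elements.values()))
        self.energy_grid = any_el["energy"]

    @classmethod
    def bundled(cls) -> "CrossSectionTable":
        with resources.files("expanderdose.data").joinpath("cross_sections.csv").open() as fh:
            frame = pd.read_csv(fh, comment="#")
        return cls(frame)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._elements)

    def element_mu_rho(self, symbol: str, energy, channel: str = "total"):
        """mu/rho (cm^2/g) for one element, log-log interpolated."""
        if symbol not in self._elements:
            raise UnknownElementError(symbol)
        tab = self._elements[symbol]
        e = np.asarray(energy, dtype=float)
        if np.any(e < tab["energy"][0] - 1e-12) or np.any(e > tab["energy"][-1] + 1e-9):
            raise EnergyRangeError(f"energy outside table range: {energy}")
        col = {"total": "total", **_CHANNEL_COLUMNS}[channel]
        y = tab[col]
        loge = np.log(np.clip(e, 1e-12, None))
        # pair channel is zero below threshold; log-interp on positive part
        with np.errstate(divide="ignore"):
            logy = np.log(np.clip(y, 1e-300, None))
        out = np.exp(np.interp(loge, np.log(tab["energy"]), logy))
        if col == "pair":
            out = np.where(e <= PAIR_THRESHOLD, 0.0, out)
        return out if np.ndim(energy) else float(out)


_TABLE: CrossSectionTable | None = None


def default_table() -> CrossSectionTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = CrossSectionTable.bundled()
    return _TABLE


def mixture_mass_attenuation(material: Material, energy, channel: str = "total", table: CrossSectionTable | None = None):
    """Mass attenuation of a mixture: sum_i w_i (mu/rho)_i, cm^2/g."""
    table = table or default_table()
    if channel not in ("total",) + CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    e = np.asarray(energy, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for el, w in material.composition:
        out = out + w * np.asarray(table.element_mu_rho(el, e, channel))
    return out if np.ndim(energy) else float(out)


def transmission(material: Material, thickness_cm: float, energy, table: CrossSectionTable | None = None):
    """Narrow-beam primary transmission exp(-(mu/rho) rho t); in [0, 1]."""
    if np.any(np.asarray(thickness_cm) < 0):
        raise ValueError("thickness must be non-negative")
    mu_rho = mixture_mass_attenuation(material, energy, "total", table)
    return np.exp(-np.asarray(mu_rho) * material.density * thickness_cm)


def channel_probabilities(material: Material, energy, table: CrossSectionTable | None = None) -> np.ndarray:
    """Interaction channel probabilities [photoelectric, compton, pair]."""
    parts = np.array([mixture_mass_attenuation(material, energy, ch, table) for ch in CHANNELS])
    return parts / parts.sum(axis=0)


def sample_interaction(energy, material: Material, rng: np.random.Generator, table: CrossSectionTable | None = None) -> str:
    """Draw an interaction channel with probability proportional to mu_ch."""
    p = channel_probabilities(material, energy, table)
    return CHANNELS[rng.choice(len(CHANNELS), p=p)]


def sample_compton(energy: float, rng: np.random.Generator, size: int | None = None):
    """Sample (scattered energy, polar angle) from Klein-Nishina.

    Kahn-style rejection on the scattered-to-incident energy ratio for the
    free-electron KN differential cross section.  Returns scalars for
    ``size=None``, else arrays of length ``size``.
    """
    n = 1 if size is None else size
    a = energy / M_E_C2
    eps_min = 1.0 / (1.0 + 2.0 * a)
    out_eps = np.empty(n)
    filled = 0
    while filled < n:
        m = (n - filled) * 2 + 8
        # proposal eps ~ 1/eps on [eps_min, 1]; dsigma/deps ~ eps + 1/eps - sin^2,
        # so accept with weight eps*(eps + 1/eps - sin^2)/2 = (eps^2 + 1 - eps*sin^2)/2 <= 1
        eps = eps_min * np.exp(rng.random(m) * np.log(1.0 / eps_min))
        cos_t = 1.0 - (1.0 / eps - 1.0) / a
        sin2 = np.clip(1.0 - cos_t**2, 0.0, None)
        accept = rng.random(m) < (eps**2 + 1.0 - eps * sin2) / 2.0
        sel = eps[accept][: n - filled]
        out_eps[filled : filled + len(sel)] = sel
        filled += len(sel)
    e_prime = out_eps * energy
    cos_t = np.clip(1.0 - (energy / e_prime - 1.0) / a, -1.0, 1.0)
    theta = np.arccos(cos_t)
    if size is None:
        return float(e_prime[0]), float(theta[0])
    return e_prime, theta


@dataclass
class SpectrumModel:
    """Discrete photon fluence spectrum: bin energies (MeV) and weights."""

    energies: np.ndarray
    weights: np.ndarray
    label: str = "6mv"

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("spectrum has zero total weight")
        self.weights = self.weights / s

    @property
    def effective_energy(self) -> float:
        """Fluence-weighted mean energy, MeV."""
        return float(np.sum(self.energies * self.weights))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.energies, size=size, p=self.weights)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)


def build_spectrum_6mv(
    n_bins: int = 40,
    e_min: float = 0.25,
    e_max: float = 6.0,
    mean_parameter: float = 0.90,
    monoenergetic: float | None = None,
) -> SpectrumModel:
    """Parameterized 6 MV bremsstrahlung fluence spectrum.

    The default shape is phi(E) ~ E * exp(-E / E0) truncated to
    [e_min, e_max], a piecewise-linear stand-in for a flattened 6 MV
    TrueBeam spectrum; E0 = ``mean_parameter`` places the fluence-weighted
    mean near 1.8 MeV, inside the 1.6-2.2 MeV range typical of published
    6 MV spectra.  ``monoenergetic`` overrides everything with a single line
    (used by the transport oracles).
    """
    if monoenergetic is not None:
        return SpectrumModel(np.array([monoenergetic]), np.array([1.0]), label=f"mono{monoenergetic}")
    edges = np.linspace(e_min, e_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights = centers * np.exp(-centers / mean_parameter) * np.diff(edges)
    return SpectrumModel(centers, weights)


def material_to_dict(material: Material) -> dict:
    """JSON-style material description (name, density, composition)."""
    return {
        "name": material.name,
        "density_g_cm3": material.density,
        "composition": {el: w for el, w in material.composition},
    }


def material_from_dict(d: dict) -> Material:
    comp = tuple((el, float(w)) for el, w in d["composition"].items())
    return Material(d["name"], float(d["density_g_cm3"]), comp)


def spectrum_to_dict(spectrum: SpectrumModel) -> dict:
    return {
        "label": spectrum.label,
        "energies_mev": spectrum.energies.tolist(),
        "weights": spectrum.weights.tolist(),
        "effective_energy_mev": spectrum.effective_energy,
    }


def spectrum_from_dict(d: dict) -> SpectrumModel:
    return SpectrumModel(np.array(d["energies_mev"]), np.array(d["weights"]), d.get("label", "custom"))


def energy_transfer_fraction(material: Material, energy, table: CrossSectionTable | None = None):
    """Mean fraction of interacted photon energy transferred to electrons.

    Weighted over channels: photoelectric transfers everything, Compton the
    KN mean electron fraction, pair E - 2 m_e c^2.
    """
    table = table or default_table()
    e = np.asarray(energy, dtype=float)
    mu_pe = np.asarray(mixture_mass_attenuation(material, e, "photoelectric", table))
    mu_c = np.asarray(mixture_mass_attenuation(material, e, "compton", table))
    mu_pp = np.asarray(mixture_mass_attenuation(material, e, "pair", table))
    f_c = np.asarray(compton_energy_transfer_fraction(e))
    f_pp = np.clip(1.0 - PAIR_THRESHOLD / np.clip(e, 1e-9, None), 0.0, 1.0)
    tot = mu_pe + mu_c + mu_pp
    out = (mu_pe + mu_c * f_c + mu_pp * f_pp) / np.where(tot > 0, tot, 1.0)
    return out if np.ndim(energy) else float(out)
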