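"""Scalar estimators and unit conversions for FG-phase biophysics.

Covers the arithmetic around phase-separating FG domains: molar/mass/motif
concentration conversions, the local FG-domain concentration implied by
nuclear-pore geometry and copy number, the ratiometric estimate of the
intra-particle concentration from a fluorescence calibration series, the
polypeptide volume fraction via the partial specific volume, the critical
(saturation) concentration from a phase-separation titration, oversaturation
folds, Stokes-Einstein diffusion coefficients, and diffusive traversal times
across a thin barrier.

Unit conventions: molar concentrations in mol/L (M), mass concentrations in
g/L (numerically equal to mg/ml), molar masses in kDa, lengths in nm for
geometry and um for diffusion, diffusion coefficients in um^2/s, volumes in
litres, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

N_A = constants.Avogadro
K_B = constants.Boltzmann


@dataclass(frozen=True)
class MolecularSpecies:
    """A molecular species with molar mass (kDa) and FG motifs per molecule."""

    name: str
    molar_mass_kda: float
    motifs_per_molecule: int = 0

    def __post_init__(self) -> None:
        if self.molar_mass_kda <= 0:
            raise ValueError("molar_mass_kda must be positive")
        if self.motifs_per_molecule < 0:
            raise ValueError("motifs_per_molecule must be >= 0")


@dataclass(frozen=True)
class NPCGeometry:
    """Geometry and stoichiometry of the nuclear-pore FG compartment.

    Defaults describe a central channel 80 nm long and 40 nm wide whose
    anchored FG domains reach 70 nm into nuclear and cytoplasmic space,
    with 48 FG-domain copies per pore.  ``accessible_volume_litres`` is
    the accepted accessible-volume figure and is used verbatim; the
    cylinder model built from the dimensions is advisory only (it gives
    a smaller volume, i.e. the accessible region is not a bare cylinder).
    """

    channel_length_nm: float = 80.0
    channel_diameter_nm: float = 40.0
    axial_extension_each_side_nm: float = 70.0
    copies_per_npc: int = 48
    accessible_volume_litres: float | None = 1.5e-18

    def __post_init__(self) -> None:
        for v in (self.channel_length_nm, self.channel_diameter_nm,
                  self.axial_extension_each_side_nm):
            if v <= 0:
                raise ValueError("all dimensions must be positive")
        if self.copies_per_npc < 0:
            raise ValueError("copies_per_npc must be >= 0")


def molar_to_mass(c_molar: float, species: MolecularSpecies) -> float:
    """Molar concentration (M) -> mass concentration (g/L == mg/ml)."""
    if c_molar < 0:
        raise ValueError("concentration must be >= 0")
    return c_molar * species.molar_mass_kda * 1000.0


def mass_to_molar(c_mass_g_per_l: float, species: MolecularSpecies) -> float:
    """Mass concentration (g/L) -> molar concentration (M)."""
    if c_mass_g_per_l < 0:
        raise ValueError("concentration must be >= 0")
    return c_mass_g_per_l / (species.molar_mass_kda * 1000.0)


def motif_concentration(c_domain_molar: float,
                        species: MolecularSpecies) -> float:
    """Molar FG-motif concentration implied by a domain concentration."""
    if c_domain_molar < 0:
        raise ValueError("concentration must be >= 0")
    return c_domain_molar * species.motifs_per_molecule


def cylinder_volume(geometry: NPCGeometry) -> float:
    """Volume (litres) of the cylinder spanned by channel + extensions.

    pi * (d/2)^2 * (L + 2*extension), in nm^3 converted to litres.  This
    underestimates the accepted accessible volume (the FG cloud extends
    laterally beyond the channel bore), so it is reported for comparison
    rather than used as the default.
    """
    r = geometry.channel_diameter_nm / 2.0
    height = (geometry.channel_length_nm
              + 2.0 * geometry.axial_extension_each_side_nm)
    vol_nm3 = np.pi * r * r * height
    return float(vol_nm3 * 1e-24)  # 1 nm^3 = 1e-24 L


def npc_local_concentration(
    geometry: NPCGeometry,
    species: MolecularSpecies,
    use_cylinder_model: bool = False,
) -> dict[str, float]:
    """Local FG concentrations implied by copy number and accessible volume.

    Returns a dict with ``domain_molar`` (M), ``motifs_molar`` (M) and
    ``mass_g_per_l`` (mg/ml).  The accessible-volume override is used by
    default; ``use_cylinder_model`` switches to the advisory cylinder.
    """
    if use_cylinder_model or geometry.accessible_volume_litres is None:
        volume = cylinder_volume(geometry)
    else:
        volume = geometry.accessible_volume_litres
    if volume <= 0:
        raise ValueError("accessible volume must be positive")
    c_domain = geometry.copies_per_npc / (N_A * volume)
    return {
        "domain_molar": c_domain,
        "motifs_molar": motif_concentration(c_domain, species),
        "mass_g_per_l": molar_to_mass(c_domain, species),
        "volume_litres": volume,
    }


@dataclass
class CalibrationSeries:
    """Fluorescence standards for the ratiometric concentration estimate.

    ``standards`` pairs known extra-particle standard concentrations (M)
    with their measured signals (arbitrary units).  ``intra_signal`` is
    the signal of the labelled tracer inside the particle, which reports
    on ``labeled_fraction`` of the total molecules there.
    """

    standards: list[tuple[float, float]]
    intra_signal: float
    labeled_fraction: float

    def __post_init__(self) -> None:
        if not self.standards:
            raise ValueError("need at least one standard")
        if not (0 < self.labeled_fraction <= 1):
            raise ValueError("labeled_fraction must be in (0, 1]")
        if self.intra_signal < 0 or any(s < 0 for _, s in self.standards):
            raise ValueError("signals must be >= 0")


def labeled_fraction(labeled_molar: float, unlabeled_molar: float,
                     relative_to_total: bool = False) -> float:
    """Tracer fraction from labelled and unlabelled pool concentrations.

    By default the fraction is taken relative to the unlabelled pool
    (e.g. 14 nM tracer in 10 uM domain -> 1/714); set
    ``relative_to_total`` to divide by the total pool instead.
    """
    if labeled_molar <= 0 or unlabeled_molar <= 0:
        raise ValueError("concentrations must be positive")
    denom = unlabeled_molar + (labeled_molar if relative_to_total else 0.0)
    return labeled_molar / denom


def ratiometric_intra_concentration(cal: CalibrationSeries) -> float:
    """Total intra-particle molar concentration from a calibration series.

    The standards define a through-origin least-squares line signal =
    s * concentration; the intra-particle tracer concentration is
    intra_signal / s, and dividing by the labelled fraction gives the
    total concentration.
    """
    conc = np.array([c for c, _ in cal.standards], dtype=float)
    sig = np.array([s for _, s in cal.standards], dtype=float)
    denom = float(np.dot(conc, conc))
    if denom == 0 or not np.any(sig > 0):
        raise ValueError("standards carry no signal")
    slope = float(np.dot(conc, sig)) / denom
    return (cal.intra_signal / slope) / cal.labeled_fraction


def polypeptide_volume_fraction(
    c_mass_g_per_l: float, partial_specific_volume_ml_per_g: float = 0.73
) -> float:
    """Fraction of volume occupied by polypeptide at a mass concentration.

    Uses the partial specific volume of protein (default 0.73 ml/g);
    the remainder of the volume is water/buffer.
    """
    if c_mass_g_per_l < 0:
        raise ValueError("concentration must be >= 0")
    frac = (c_mass_g_per_l / 1000.0) * partial_specific_volume_ml_per_g
    if frac > 1.0:
        raise ValueError("impossible concentration (volume fraction > 1)")
    return frac


@dataclass
class TitrationSeries:
    """Phase-separation titration: total vs soluble (monomer) concentration.

    ``points`` pairs total concentrations with either the co-existing
    soluble/monomer concentration (``method='pellet_supernatant'``) or
    the monomer mass fraction from light scattering
    (``method='dls_fraction'``).
    """

    points: list[tuple[float, float]]
    method: str = "pellet_supernatant"

    def __post_init__(self) -> None:
        if self.method not in ("dls_fraction", "pellet_supernatant"):
            raise ValueError(f"unknown method {self.method!r}")
        for total, val in self.points:
            soluble = val * total if self.method == "dls_fraction" else val
            if soluble > total * (1 + 1e-9):
                raise ValueError("soluble concentration exceeds total")


@dataclass
class CriticalConcentrationEstimate:
    value_molar: float
    phase_separated: bool
    bracket_low: float | None  # highest total with no particles
    bracket_high: float | None  # lowest total with particles


def critical_concentration(
    titration: TitrationSeries, rel_tol: float = 1e-9
) -> CriticalConcentrationEstimate:
    """Saturation concentration from a titration series.

    Wherever particles coexist with monomers (soluble < total), the
    soluble concentration estimates the critical concentration; the
    returned value is their mean.  If no point phase-separated, the
    result is flagged and carries the highest fully-soluble total as a
    lower bound.

    ``rel_tol`` is the particle-detection threshold: a point counts as
    phase-separated only when its soluble concentration falls below
    (1 - rel_tol) * total.  For noisy measurements set it at a few
    standard deviations of the relative measurement noise, otherwise
    fully-soluble points can be mistaken for shallow phase separation
    and bias the estimate downward.
    """
    solubles, with_particles, without = [], [], []
    for total, val in titration.points:
        soluble = (val * total if titration.method == "dls_fraction" else val)
        if soluble < total * (1 - rel_tol):
            solubles.append(soluble)
            with_particles.append(total)
        else:
            without.append(total)
    if not solubles:
        return CriticalConcentrationEstimate(
            value_molar=max(t for t, _ in titration.points),
            phase_separated=False,
            bracket_low=max(without) if without else None,
            bracket_high=None,
        )
    return CriticalConcentrationEstimate(
        value_molar=float(np.mean(solubles)),
        phase_separated=True,
        bracket_low=max(without) if without else None,
        bracket_high=min(with_particles),
    )


def oversaturation_ratio(local_molar: float,
                         critical_molar: float) -> tuple[float, bool]:
    """Fold oversaturation of a local concentration over the critical one.

    Returns (ratio, saturated) where ``saturated`` is False when the
    local concentration is below the critical concentration.
    """
    if critical_molar <= 0:
        raise ValueError("critical concentration must be positive")
    ratio = local_molar / critical_molar
    return ratio, ratio >= 1.0


def stokes_einstein(radius_nm: float, temperature_k: float = 293.0,
                    viscosity_mpa_s: float = 1.0) -> float:
    """Stokes-Einstein diffusion coefficient (um^2/s) of a sphere.

    D = k_B T / (6 pi eta r) for hydrodynamic radius ``radius_nm`` in a
    medium of viscosity ``viscosity_mpa_s`` (mPa*s == cP).
    """
    if radius_nm <= 0 or temperature_k <= 0 or viscosity_mpa_s <= 0:
        raise ValueError("all inputs must be positive")
    d_m2_s = K_B * temperature_k / (
        6.0 * np.pi * viscosity_mpa_s * 1e-3 * radius_nm * 1e-9)
    return float(d_m2_s * 1e12)  # m^2/s -> um^2/s


TRAVERSAL_CONVENTIONS = {
    "L2_over_2D": 2.0,
    "L2_over_6D": 6.0,
    "L2_over_D": 1.0,
}


def slab_traversal_time(thickness_nm: float, d_um2_s: float,
                        convention: str = "L2_over_2D") -> float:
    """Characteristic diffusive time (s) to traverse a slab barrier.

    Default convention L^2/(2D), the 1-D mean first-passage time to an
    absorbing far boundary; L^2/(6D) and L^2/D are also available.
    """
    if thickness_nm <= 0 or d_um2_s <= 0:
        raise ValueError("inputs must be positive")
    if convention not in TRAVERSAL_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    l_um = thickness_nm * 1e-3
    return l_um * l_um / (TRAVERSAL_CONVENTIONS[convention] * d_um2_s)
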