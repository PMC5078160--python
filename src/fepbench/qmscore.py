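"""Composite QM/MM binding scores and quasi-RRHO thermochemistry.

The QM/MM scoring protocol combines a subtractive-scheme QM/MM energy, a
large-QM-region interaction energy evaluated in a COSMO continuum, and five
corrections into a six-term binding free energy:

    dG_bind = dG_BQ + dE_bsc + dE_disp + dG_therm + dE_strain + ddG_L,solv

where dG_BQ is the big-QM interaction energy in COSMO, dE_bsc the
basis-set correction (quadruple-zeta minus split-valence), dE_disp the
DFT-D3 dispersion, dG_therm the quasi-RRHO thermal correction, dE_strain
the ligand relaxation (strain) energy, and ddG_L,solv the COSMO-RS minus
COSMO ligand solvation difference.

Component tables store the ligand-relaxation column as printed (negative);
it enters the composite negated, which is the only sign convention that
reproduces both the tabulated dG_bind column and the positive 10-61 kJ/mol
strain range.  The ``as_submitted`` variant flips the sign of the solvation
difference, reproducing the originally submitted scores which carried a
sign error in that term.

Thermal corrections follow the rigid-rotor harmonic-oscillator model with
Grimme's free-rotor interpolation for low-lying modes: each mode's entropy
is ``w*S_HO + (1-w)*S_FR`` with damping ``w = 1/(1+(omega0/omega)^4)`` and
``omega0 = 100 cm^-1``; the free-rotor moment of inertia is capped by an
average molecular moment ``B_av = 1e-44 kg m^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    AVOGADRO,
    B_AV_DEFAULT,
    BOLTZMANN,
    OMEGA0_DEFAULT,
    PLANCK,
    R_GAS,
    SPEED_OF_LIGHT_CM,
    THERMO_TEMPERATURE,
)
from .exceptions import InputError

__all__ = [
    "QmmmComponents",
    "InteractionTriple",
    "BasisSetPair",
    "VibrationalModes",
    "EnergyComponents",
    "BindingScore",
    "QuasiRrhoResult",
    "qmmm_energy",
    "interaction_energy",
    "basis_set_correction",
    "free_rotor_weight",
    "mode_entropy",
    "quasi_rrho_gibbs",
    "composite_binding_energy",
]


def _require_finite(name: str, *values):
    for v in values:
        if v is None or not math.isfinite(v):
            raise InputError(f"{name}: non-finite or missing value {v!r}")


@dataclass(frozen=True)
class QmmmComponents:
    """The three terms of the subtractive QM/MM energy (kJ/mol).

    ``e_qm1_ptch2_hl``: QM energy of the link-atom-capped QM region in the
    point-charge field of the surroundings; ``e_mm12_q1_0_cl``: MM energy of
    the whole system with QM charges zeroed; ``e_mm1_q1_0_hl``: MM energy of
    the truncated QM region without electrostatics.
    """

    e_qm1_ptch2_hl: float
    e_mm12_q1_0_cl: float
    e_mm1_q1_0_hl: float

    def __post_init__(self):
        _require_finite(
            "QmmmComponents",
            self.e_qm1_ptch2_hl, self.e_mm12_q1_0_cl, self.e_mm1_q1_0_hl,
        )


@dataclass(frozen=True)
class InteractionTriple:
    """Energies of complex, protein, and ligand in one energy model."""

    e_complex: float
    e_protein: float
    e_ligand: float

    def __post_init__(self):
        _require_finite(
            "InteractionTriple", self.e_complex, self.e_protein, self.e_ligand
        )


@dataclass(frozen=True)
class BasisSetPair:
    """Energies at the large (quadruple-zeta) and small basis sets."""

    e_large: float
    e_small: float

    def __post_init__(self):
        _require_finite("BasisSetPair", self.e_large, self.e_small)


@dataclass
class VibrationalModes:
    """Vibrational wavenumbers (cm^-1) with thermodynamic conditions.

    Non-positive wavenumbers (imaginary modes) are filtered out and counted
    in ``n_imaginary``.
    """

    wavenumbers: np.ndarray
    temperature: float = THERMO_TEMPERATURE
    pressure: float = 1.0
    n_imaginary: int = 0

    def __post_init__(self):
        arr = np.asarray(self.wavenumbers, dtype=float).ravel()
        if arr.size == 0:
            raise InputError("VibrationalModes: empty frequency list")
        if not np.all(np.isfinite(arr)):
            raise InputError("VibrationalModes: non-finite wavenumbers")
        keep = arr > 0
        self.n_imaginary = int(np.sum(~keep))
        self.wavenumbers = arr[keep]
        if self.wavenumbers.size == 0:
            raise InputError("VibrationalModes: no positive wavenumbers left")
        if self.temperature <= 0:
            raise InputError("VibrationalModes: temperature must be positive")


@dataclass(frozen=True)
class EnergyComponents:
    """One ligand's score components, in the component-table layout (kJ/mol).

    ``ligand_relax_printed`` is stored as printed in the table (negative);
    the assembly negates it to obtain the positive strain energy.
    """

    ligand: str
    bigqm_ptch: float
    bigqm_cosmo: float
    dispersion: float
    basis_correction: float
    g_therm: float
    ligand_relax_printed: float
    solv_cosmo: float
    solv_cosmors: float

    def __post_init__(self):
        for name in (
            "bigqm_ptch", "bigqm_cosmo", "dispersion", "basis_correction",
            "g_therm", "ligand_relax_printed", "solv_cosmo", "solv_cosmors",
        ):
            value = getattr(self, name)
            if value is None or not math.isfinite(value):
                raise InputError(
                    f"EnergyComponents({self.ligand}): missing or non-finite "
                    f"component {name!r}"
                )


@dataclass(frozen=True)
class BindingScore:
    """A composite binding free energy and how it was assembled."""

    ligand: str
    dg_bind: float
    variant: str
    exclusions: tuple[str, ...] = ()


def qmmm_energy(c: QmmmComponents) -> float:
    """Total QM/MM energy of the subtractive (ONIOM-like) scheme:
    ``E = E_QM1+ptch2(HL) + E_MM12,q1=0(CL) - E_MM1,q1=0(HL)``."""
    return c.e_qm1_ptch2_hl + c.e_mm12_q1_0_cl - c.e_mm1_q1_0_hl


def interaction_energy(t: InteractionTriple) -> float:
    """``dE_int = E(complex) - E(protein) - E(ligand)``."""
    return t.e_complex - t.e_protein - t.e_ligand


def basis_set_correction(p: BasisSetPair) -> float:
    """``dE_bsc = E(large basis) - E(small basis)``."""
    return p.e_large - p.e_small


def free_rotor_weight(wavenumber: float, omega0: float = OMEGA0_DEFAULT) -> float:
    """Grimme damping ``w = 1/(1+(omega0/omega)^4)``; 0.5 at omega0."""
    if wavenumber <= 0:
        raise InputError("free_rotor_weight: wavenumber must be positive")
    return 1.0 / (1.0 + (omega0 / wavenumber) ** 4)


def mode_entropy(
    wavenumber: float,
    temperature: float = THERMO_TEMPERATURE,
    omega0: float = OMEGA0_DEFAULT,
    b_av: float = B_AV_DEFAULT,
) -> tuple[float, float, float]:
    """Per-mode entropies (kJ/mol/K): (quasi-RRHO, harmonic, free-rotor).

    The free-rotor entropy uses the mode's effective moment of inertia
    ``mu = hbar / (4 pi c nu)`` capped via ``mu' = mu*B_av/(mu+B_av)``.
    """
    if wavenumber <= 0:
        raise InputError("mode_entropy: wavenumber must be positive")
    x = PLANCK * SPEED_OF_LIGHT_CM * wavenumber / (BOLTZMANN * temperature)
    s_ho = R_GAS * (x / np.expm1(x) - np.log1p(-np.exp(-x)))

    nu_hz = SPEED_OF_LIGHT_CM * wavenumber  # s^-1
    mu = PLANCK / (8.0 * np.pi**2 * nu_hz)
    mu_eff = mu * b_av / (mu + b_av)
    arg = 8.0 * np.pi**3 * mu_eff * BOLTZMANN * temperature / PLANCK**2
    s_fr = R_GAS * (0.5 + 0.5 * np.log(arg))

    w = free_rotor_weight(wavenumber, omega0)
    return float(w * s_ho + (1.0 - w) * s_fr), float(s_ho), float(s_fr)


@dataclass(frozen=True)
class QuasiRrhoResult:
    """Vibrational thermal correction decomposed into its parts (kJ/mol)."""

    g_therm: float
    zpe: float
    thermal_energy: float
    entropy: float  # kJ/mol/K, quasi-RRHO
    n_imaginary: int


def quasi_rrho_gibbs(
    modes: VibrationalModes,
    omega0: float = OMEGA0_DEFAULT,
    b_av: float = B_AV_DEFAULT,
) -> QuasiRrhoResult:
    """Vibrational Gibbs correction with free-rotor-damped entropy.

    ``G = ZPE + E_vib(T) - T * S_quasi-RRHO``; additive over modes and
    continuous and monotone in each wavenumber.  Imaginary modes were
    removed at construction and are echoed in ``n_imaginary``.
    """
    t = modes.temperature
    nu = modes.wavenumbers
    x = PLANCK * SPEED_OF_LIGHT_CM * nu / (BOLTZMANN * t)
    zpe_per_mode = 0.5 * PLANCK * SPEED_OF_LIGHT_CM * nu * AVOGADRO / 1000.0
    e_vib = R_GAS * t * x / np.expm1(x)
    entropy = sum(mode_entropy(float(v), t, omega0, b_av)[0] for v in nu)
    zpe = float(zpe_per_mode.sum())
    thermal = float(e_vib.sum())
    g = zpe + thermal - t * entropy
    return QuasiRrhoResult(
        g_therm=float(g), zpe=zpe, thermal_energy=thermal,
        entropy=float(entropy), n_imaginary=modes.n_imaginary,
    )


_VALID_EXCLUSIONS = {"g_therm", "ligand_relax"}


def composite_binding_energy(
    ec: EnergyComponents,
    variant: str = "corrected",
    exclusions: tuple[str, ...] = (),
) -> BindingScore:
    """Assemble the six-term composite binding free energy.

    ``variant="corrected"`` adds the ligand solvation difference with its
    proper sign (COSMO-RS minus COSMO); ``variant="as_submitted"``
    reproduces the originally submitted scores, whose solvation difference
    entered with the opposite sign.  ``exclusions`` removes named terms;
    excluding ``g_therm`` yields the reduced score column of the component
    table (dG' = dG_bind - dG_therm).
    """
    if variant not in ("corrected", "as_submitted"):
        raise InputError(f"unknown variant {variant!r}")
    bad = set(exclusions) - _VALID_EXCLUSIONS
    if bad:
        raise InputError(f"unknown exclusions: {sorted(bad)}")
    solv_diff = ec.solv_cosmors - ec.solv_cosmo
    if variant == "as_submitted":
        solv_diff = -solv_diff
    total = ec.bigqm_cosmo + ec.basis_correction + ec.dispersion + solv_diff
    if "g_therm" not in exclusions:
        total += ec.g_therm
    if "ligand_relax" not in exclusions:
        total += -ec.ligand_relax_printed  # strain enters positive
    return BindingScore(
        ligand=ec.ligand, dg_bind=float(total), variant=variant,
        exclusions=tuple(sorted(exclusions)),
    )
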