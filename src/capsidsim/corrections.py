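"""Analytical RNA-effect corrections to capsid assembly rate constants.

The presence of a packaged RNA genome perturbs the kinetics of capsid
self-assembly relative to the empty (in vitro) capsid.  Four separable
contributions are modelled with Flory-type mean-field polymer theory, each
yielding a free-energy change (in units of kBT) or an effective-concentration
change for the assembling shell:

* **RNA-RNA** — the Flory free energy of the confined polyelectrolyte chain,
  balancing chain stretching ``l**2 / (N b**2)`` against excluded-volume
  repulsion ``v N**2 / (2 V)`` inside the thin RNA shell.
* **Compression** — the entropic cost of squeezing the chain into the shell,
  counted in compression blobs: ``N b**2 / (R**2 - (R - D)**2)``.
* **RNA-protein** — the adsorption energy of the charged chain on the
  oppositely charged capsid interior: ``-delta * M * r / D``.
* **Concentration** — the enhancement of local coat-protein concentration for
  subunits condensed on the RNA coil, estimated from the weak-confinement
  (Flory) radius ``R3 = a * M**nu``.

Each contribution is converted to a multiplicative scaling of the equilibrium
constant of a single subunit-addition step by distributing the whole-capsid
free energy over the coat monomers of the complete shell
(``K = exp(-F / n)`` with ``n = 180`` monomers for a T=3 capsid).  Effects
whose physical origin perturbs binding symmetrically (RNA-RNA, RNA-protein)
are split evenly between on- and off-rates (``kon *= sqrt(K)``,
``koff /= sqrt(K)``); effects that act by slowing or speeding the approach to
the bound state (Compression, Concentration) are applied to on-rates only.

Combinations of effects are written as a four-digit binary code in the order
RNA-RNA, Compression, RNA-protein, Concentration; ``"0000"`` is the hollow
capsid and ``"1111"`` enables everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import pandas as pd

__all__ = [
    "AVOGADRO",
    "RNAEffectParams",
    "EffectFactors",
    "Effect",
    "kuhn_segment_count",
    "pervaded_shell_volume",
    "rna_rna_free_energy",
    "confinement_free_energy",
    "adsorption_free_energy",
    "concentration_factor",
    "excluded_volume_eq3",
    "effect_factors",
    "combine_effects",
    "all_effect_codes",
    "factors_table",
    "free_energy_table",
]

AVOGADRO = 6.02214076e23  # mol^-1


class Effect(Enum):
    """The four modelled RNA contributions, in code-digit order."""

    RNA_RNA = 0
    COMPRESSION = 1
    RNA_PROTEIN = 2
    CONCENTRATION = 3


@dataclass(frozen=True)
class RNAEffectParams:
    """Physical constants of the CCMV RNA1 / capsid system.

    Lengths are in nm except ``monomer_length_a`` which follows the
    weak-confinement-regime convention of Å.  Defaults are the CCMV RNA1
    values (3171 nt genome segment, T=3 shell of 90 coat dimers).
    """

    kuhn_length_b: float = 2.6           # nm, ~2x RNA persistence length at 1M salt
    nucleotides_M: int = 3171            # RNA1 length, nt
    nucleotide_length_r: float = 0.34    # nm per nucleotide
    inner_radius_R: float = 10.5         # nm, capsid interior radius
    shell_thickness_D: float = 1.18      # nm, RNA layer against the capsid wall
    bjerrum_length: float = 0.7          # nm
    debye_length: float = 0.3            # nm, 1M monovalent salt
    excluded_volume_v: float = 3.537     # nm^3 per Kuhn segment
    adsorption_delta: float = 0.5        # kBT per nucleotide-protein contact
    monomer_length_a: float = 3.4        # Å, nucleotide step for the WCR radius
    flory_exponent_nu3: float = 0.6      # good-solvent Flory exponent
    bulk_concentration_c0: float = 15.6  # µM coat dimer
    capsid_dimers: int = 90              # dimers in the complete T=3 shell
    distribution_count_n: int = 180      # coat monomers the free energy is spread over

    def __post_init__(self) -> None:
        positive = (
            "kuhn_length_b",
            "nucleotide_length_r",
            "inner_radius_R",
            "shell_thickness_D",
            "bjerrum_length",
            "debye_length",
            "excluded_volume_v",
            "monomer_length_a",
            "bulk_concentration_c0",
            "capsid_dimers",
            "distribution_count_n",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nucleotides_M < 0:
            raise ValueError("nucleotides_M must be non-negative")
        if self.shell_thickness_D > self.inner_radius_R:
            raise ValueError("shell_thickness_D must not exceed inner_radius_R")
        if not (0.5 < self.flory_exponent_nu3 < 1.0):
            raise ValueError("flory_exponent_nu3 must lie in (0.5, 1.0)")
        if self.adsorption_delta < 0:
            raise ValueError("adsorption_delta must be non-negative")

    def with_overrides(self, **kwargs: float) -> "RNAEffectParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EffectFactors:
    """Multiplicative (K_eq, k_on, k_off) scaling triple for an effect code."""

    code: str
    keq_factor: float
    kon_factor: float
    koff_factor: float

    def __post_init__(self) -> None:
        if len(self.code) != 4 or any(c not in "01" for c in self.code):
            raise ValueError(f"effect code must be 4 binary digits, got {self.code!r}")
        if min(self.keq_factor, self.kon_factor, self.koff_factor) <= 0:
            raise ValueError("all factors must be strictly positive")

    def __mul__(self, other: "EffectFactors") -> "EffectFactors":
        code = "".join(
            "1" if a == "1" or b == "1" else "0" for a, b in zip(self.code, other.code)
        )
        return EffectFactors(
            code,
            self.keq_factor * other.keq_factor,
            self.kon_factor * other.kon_factor,
            self.koff_factor * other.koff_factor,
        )


IDENTITY_FACTORS = EffectFactors("0000", 1.0, 1.0, 1.0)


def kuhn_segment_count(
    nucleotides: int, nucleotide_length: float, kuhn_length: float
) -> float:
    """Number of Kuhn segments in a chain of ``nucleotides`` bases (real-valued)."""
    if kuhn_length <= 0:
        raise ValueError("kuhn_length must be strictly positive")
    return nucleotides * nucleotide_length / kuhn_length


def pervaded_shell_volume(inner_radius: float, thickness: float) -> float:
    """Volume of the spherical shell of given thickness against the capsid wall (nm^3)."""
    if not 0 <= thickness <= inner_radius:
        raise ValueError("thickness must lie in [0, inner_radius]")
    R, D = inner_radius, thickness
    return 4.0 / 3.0 * math.pi * (R**3 - (R - D) ** 3)


def rna_rna_free_energy(params: RNAEffectParams) -> tuple[float, float, float]:
    """Flory free energy of the confined chain, in kBT.

    Returns ``(total, stretch_term, excluded_volume_term)`` where the stretch
    term is ``l**2 / (N b**2)`` with end-to-end distance ``l = pi * R`` (the
    longest path within the RNA shell) and the excluded-volume term is
    ``v N**2 / (2 V)`` over the pervaded shell volume ``V``.
    """
    N = kuhn_segment_count(
        params.nucleotides_M, params.nucleotide_length_r, params.kuhn_length_b
    )
    ell = math.pi * params.inner_radius_R
    if N == 0:
        if ell > 0:
            raise ZeroDivisionError("zero-length chain with nonzero end-to-end distance")
        return 0.0, 0.0, 0.0
    stretch = ell**2 / (N * params.kuhn_length_b**2)
    V = pervaded_shell_volume(params.inner_radius_R, params.shell_thickness_D)
    excluded = 0.5 * params.excluded_volume_v * N**2 / V
    return stretch + excluded, stretch, excluded


def confinement_free_energy(params: RNAEffectParams) -> float:
    """Compression-blob entropic cost of confining the chain to the shell (kBT)."""
    N = kuhn_segment_count(
        params.nucleotides_M, params.nucleotide_length_r, params.kuhn_length_b
    )
    R, D = params.inner_radius_R, params.shell_thickness_D
    denom = R**2 - (R - D) ** 2
    if denom == 0:
        raise ZeroDivisionError("shell_thickness_D = 0 leaves no shell area")
    return N * params.kuhn_length_b**2 / denom


def adsorption_free_energy(params: RNAEffectParams) -> float:
    """Adsorption free energy of the chain on the capsid wall (kBT, negative)."""
    if params.shell_thickness_D == 0:
        raise ZeroDivisionError("shell_thickness_D = 0")
    return (
        -params.adsorption_delta
        * params.nucleotides_M
        * params.nucleotide_length_r
        / params.shell_thickness_D
    )


def concentration_factor(params: RNAEffectParams) -> tuple[float, float, float, float]:
    """Local-concentration enhancement from the weak-confinement-regime coil.

    Returns ``(wcr_radius_A, expected_dimers, on_factor, effective_conc_uM)``.
    The WCR radius is ``a * M**nu`` in Å; the expected dimer count is the bulk
    concentration converted to a number density times the coil volume; the
    on-rate factor is the ratio needed to put a full capsid's worth of dimers
    in that volume.
    """
    if params.bulk_concentration_c0 <= 0:
        raise ValueError("bulk_concentration_c0 must be strictly positive")
    r3 = params.monomer_length_a * params.nucleotides_M**params.flory_exponent_nu3
    volume_A3 = 4.0 / 3.0 * math.pi * r3**3
    # µM -> molecules per Å^3: 1e-6 mol/L * NA / (1e27 Å^3 per L)
    density = params.bulk_concentration_c0 * 1e-6 * AVOGADRO * 1e-27
    expected = density * volume_A3
    if expected == 0:
        raise ValueError("vanishing coil volume")
    on_factor = params.capsid_dimers / expected
    return r3, expected, on_factor, params.bulk_concentration_c0 * on_factor


def excluded_volume_eq3(params: RNAEffectParams) -> float:
    """Literal evaluation of the counterion-screened excluded volume formula (nm^3).

    Diagnostic only: with the default constants this evaluates to ~2.07 nm^3
    and does NOT reproduce the adopted ``excluded_volume_v`` = 3.537 nm^3,
    which is kept as a stored constant because the downstream free-energy
    arithmetic of the parameterization is built on it.
    """
    b = params.kuhn_length_b
    return (
        math.pi * b**3 / 48.0
        + 64.0 * math.pi * params.bjerrum_length**3 * params.debye_length**2 / b**2
    )


def effect_factors(effect: Effect, params: RNAEffectParams | None = None) -> EffectFactors:
    """Scaling triple for a single RNA effect.

    RNA-RNA and RNA-protein split their equilibrium change evenly between on-
    and off-rates; Compression and Concentration act on on-rates only.
    """
    if params is None:
        params = RNAEffectParams()
    n = params.distribution_count_n
    code = ["0", "0", "0", "0"]
    code[effect.value] = "1"
    code = "".join(code)
    if effect is Effect.RNA_RNA:
        total, _, _ = rna_rna_free_energy(params)
        keq = math.exp(-total / n)
        root = math.sqrt(keq)
        return EffectFactors(code, keq, root, 1.0 / root)
    if effect is Effect.COMPRESSION:
        keq = math.exp(-confinement_free_energy(params) / n)
        return EffectFactors(code, keq, keq, 1.0)
    if effect is Effect.RNA_PROTEIN:
        keq = math.exp(-adsorption_free_energy(params) / n)
        root = math.sqrt(keq)
        return EffectFactors(code, keq, root, 1.0 / root)
    if effect is Effect.CONCENTRATION:
        _, _, on_factor, _ = concentration_factor(params)
        return EffectFactors(code, on_factor, on_factor, 1.0)
    raise ValueError(f"unknown effect {effect!r}")


def combine_effects(code: str, params: RNAEffectParams | None = None) -> EffectFactors:
    """Element-wise product of the single-effect factors selected by ``code``.

    ``code`` is four binary digits in the order RNA-RNA, Compression,
    RNA-protein, Concentration; ``"0000"`` returns the exact identity.
    """
    if len(code) != 4 or any(c not in "01" for c in code):
        raise ValueError(f"effect code must be 4 binary digits, got {code!r}")
    if params is None:
        params = RNAEffectParams()
    result = EffectFactors(code, 1.0, 1.0, 1.0)
    for effect in Effect:
        if code[effect.value] == "1":
            single = effect_factors(effect, params)
            result = EffectFactors(
                code,
                result.keq_factor * single.keq_factor,
                result.kon_factor * single.kon_factor,
                result.koff_factor * single.koff_factor,
            )
    return result


def all_effect_codes() -> list[str]:
    """The 16 effect codes in ascending binary order."""
    return [format(i, "04b") for i in range(16)]


_CODE_LABELS = {
    "0000": "Hollow",
    "1000": "RNA-RNA",
    "0100": "RNA Compression",
    "0010": "RNA-Protein",
    "0001": "Concentration",
}


def factors_table(params: RNAEffectParams | None = None) -> pd.DataFrame:
    """All 16 effect combinations as a DataFrame (full precision)."""
    rows = []
    for code in all_effect_codes():
        f = combine_effects(code, params)
        rows.append(
            {
                "code": code,
                "label": _CODE_LABELS.get(code, ""),
                "keq_factor": f.keq_factor,
                "kon_factor": f.kon_factor,
                "koff_factor": f.koff_factor,
            }
        )
    return pd.DataFrame(rows)


def free_energy_table(params: RNAEffectParams | None = None) -> pd.DataFrame:
    """One-row summary of the underlying free energies and WCR quantities."""
    if params is None:
        params = RNAEffectParams()
    total, stretch, excluded = rna_rna_free_energy(params)
    r3, expected, on_factor, eff_conc = concentration_factor(params)
    return pd.DataFrame(
        [
            {
                "kuhn_segments_N": kuhn_segment_count(
                    params.nucleotides_M,
                    params.nucleotide_length_r,
                    params.kuhn_length_b,
                ),
                "F_rna_kBT": total,
                "F_rna_stretch_kBT": stretch,
                "F_rna_excluded_kBT": excluded,
                "F_conf_kBT": confinement_free_energy(params),
                "F_ch_kBT": adsorption_free_energy(params),
                "wcr_radius_A": r3,
                "expected_dimers": expected,
                "concentration_on_factor": on_factor,
                "effective_concentration_uM": eff_conc,
            }
        ]
    )
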