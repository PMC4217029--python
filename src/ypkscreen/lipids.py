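"""Monoisotopic mass arithmetic for targeted sphingolipid identification.

Sphingoid long-chain bases (LCBs: phytosphingosine, dihydrosphingosine),
their 1-phosphates and ceramides are identified in positive-mode LC-MS by
the exact mass of the protonated precursor ion [M+H]+ and confirmed by
characteristic product ions — for LCBs the headgroup fragment produced by
sequential water losses, e.g. phytosphingosine 318.3003 -> 282.3 after two
water losses.  Quantities are referred to a spiked internal standard
(C17-sphingosine, 5 nmol per sample) via peak-area ratios.

Adduct arithmetic uses the proton mass (1.007276 Da), not the hydrogen
atom mass; element monoisotopic masses come from the NIST table shipped
with pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pymass

PROTON_MASS: float = 1.007276
WATER_MASS: float = 18.010565

_NIST = _pymass.nist_mass  # element -> {isotope: (mass, abundance)}


class LipidError(ValueError):
    """Raised on invalid formulas, adducts or quantitation inputs."""


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an elemental formula.

    ``formula`` maps element symbols (C, H, N, O, P, S, ...) to
    nonnegative integer counts; at least one atom is required.
    """
    total = 0.0
    n_atoms = 0
    for element, count in formula.items():
        if count < 0 or count != int(count):
            raise LipidError(f"count for {element} must be a nonnegative integer")
        if element not in _NIST:
            raise LipidError(f"unknown element {element!r}")
        total += count * _NIST[element][0][0]
        n_atoms += int(count)
    if n_atoms == 0:
        raise LipidError("formula contains no atoms")
    return total


def adduct_mz(neutral_mass: float, adduct: str = "M+H") -> float:
    """m/z of an adduct ion; only the singly protonated [M+H]+ is supported."""
    if neutral_mass <= 0:
        raise LipidError("neutral mass must be positive")
    if adduct not in ("M+H", "[M+H]+"):
        raise LipidError(f"unsupported adduct {adduct!r}")
    return (neutral_mass + PROTON_MASS) / 1


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid with an elemental formula and a class label.

    For ceramides, ``lcb_formula`` names the long-chain-base moiety so the
    headgroup fragment after amide cleavage can be computed.
    """

    name: str
    formula: Mapping[str, int]
    lipid_class: str  # LCB | LCBP | ceramide | internal_standard | other
    lcb_formula: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.lipid_class not in ("LCB", "LCBP", "ceramide", "internal_standard", "other"):
            raise LipidError(f"invalid lipid class {self.lipid_class!r}")
        monoisotopic_mass(self.formula)  # validates
        if self.lipid_class == "ceramide" and self.lcb_formula is None:
            raise LipidError(f"{self.name}: ceramide requires an lcb_formula")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def precursor_mz(self) -> float:
        return adduct_mz(self.neutral_mass)


@dataclass(frozen=True)
class MassTarget:
    species: LipidSpecies
    adduct: str = "M+H"
    product_ions: tuple[tuple[str, float], ...] = ()

    @property
    def precursor_mz(self) -> float:
        return adduct_mz(self.species.neutral_mass, self.adduct)


@dataclass(frozen=True)
class PeakMatch:
    observed_mz: float
    target: MassTarget
    delta_ppm: float


def lcb_headgroup_ion(species: LipidSpecies, water_losses: int = 2) -> float:
    """m/z of the LCB headgroup fragment after the stated water losses.

    For an LCB this is the protonated precursor minus ``water_losses``
    waters; for a ceramide, amide cleavage regenerates the protonated LCB
    moiety, which then loses the stated waters (phytoceramide -> 282.3,
    the same fragment as free phytosphingosine).
    """
    if water_losses < 0:
        raise LipidError("water_losses must be nonnegative")
    if species.lipid_class in ("LCB", "internal_standard"):
        base = species.precursor_mz
    elif species.lipid_class == "ceramide":
        assert species.lcb_formula is not None
        base = adduct_mz(monoisotopic_mass(species.lcb_formula))
    else:
        raise LipidError(f"no headgroup fragment defined for class {species.lipid_class!r}")
    return base - water_losses * WATER_MASS


def match_peaks(
    observed: Sequence[float],
    targets: Sequence[MassTarget],
    tol_ppm: float = 10.0,
) -> tuple[list[PeakMatch], list[float]]:
    """Assign each observed peak to its nearest target within tolerance.

    Returns (matches, unmatched_peaks); assignment is nearest-first in ppm
    and deterministic.  Several peaks may match the same target (profile
    data); tolerance is relative (ppm of the target m/z).
    """
    if tol_ppm <= 0:
        raise LipidError("tol_ppm must be positive")
    matches: list[PeakMatch] = []
    unmatched: list[float] = []
    for mz in observed:
        best: tuple[float, MassTarget] | None = None
        for t in targets:
            delta_ppm = (mz - t.precursor_mz) / t.precursor_mz * 1e6
            if best is None or abs(delta_ppm) < abs(best[0]):
                best = (delta_ppm, t)
        if best is not None and abs(best[0]) <= tol_ppm:
            matches.append(PeakMatch(observed_mz=mz, target=best[1], delta_ppm=best[0]))
        else:
            unmatched.append(mz)
    return matches, unmatched


def quantify_with_internal_standard(
    analyte_area: float,
    is_area: float,
    is_amount_nmol: float = 5.0,
    response_factor: float = 1.0,
    intercept: float = 0.0,
) -> float:
    """Convert a peak-area ratio to nmol via the spiked internal standard.

    Default is single-point quantitation with response factor 1 (the
    convention when no analyte-specific calibration exists); a linear
    standard-curve hook (``response_factor`` slope, ``intercept``) is
    provided and defaults to identity.
    """
    if is_area <= 0:
        raise LipidError("internal-standard area must be positive")
    if analyte_area < 0 or is_amount_nmol < 0:
        raise LipidError("areas and amounts must be nonnegative")
    return (analyte_area / is_area) * is_amount_nmol * response_factor + intercept


def normalize_activity(product_nmol: float, enzyme_signal: float, reaction_time_min: float) -> float:
    """Enzyme activity as product per unit enzyme per minute.

    Recovered product from an in vitro reaction is normalised to the
    amount of enzyme in the immunoprecipitate and the incubation time.
    """
    if enzyme_signal <= 0:
        raise LipidError("enzyme signal must be positive")
    if reaction_time_min <= 0:
        raise LipidError("reaction time must be positive")
    if product_nmol < 0:
        raise LipidError("product amount must be nonnegative")
    return product_nmol / (enzyme_signal * reaction_time_min)


# -- packaged species table -------------------------------------------------

_PHS = {"C": 18, "H": 39, "N": 1, "O": 3}
_DHS = {"C": 18, "H": 39, "N": 1, "O": 2}

#: standard sphingolipid formulas (textbook chemistry, packaged as data)
DEFAULT_SPECIES: tuple[LipidSpecies, ...] = (
    LipidSpecies("phytosphingosine", _PHS, "LCB"),
    LipidSpecies("dihydrosphingosine", _DHS, "LCB"),
    LipidSpecies("phytosphingosine-1-phosphate", {"C": 18, "H": 40, "N": 1, "O": 6, "P": 1}, "LCBP"),
    LipidSpecies("dihydrosphingosine-1-phosphate", {"C": 18, "H": 40, "N": 1, "O": 5, "P": 1}, "LCBP"),
    LipidSpecies("C18-phytoceramide", {"C": 36, "H": 73, "N": 1, "O": 4}, "ceramide", lcb_formula=_PHS),
    LipidSpecies("C17-sphingosine", {"C": 17, "H": 35, "N": 1, "O": 2}, "internal_standard"),
)

SPECIES_BY_NAME: Mapping[str, LipidSpecies] = {s.name: s for s in DEFAULT_SPECIES}


def default_targets(include_internal_standard: bool = True) -> list[MassTarget]:
    """Precursor mass list for the packaged species."""
    species = [
        s
        for s in DEFAULT_SPECIES
        if include_internal_standard or s.lipid_class != "internal_standard"
    ]
    return [MassTarget(s) for s in species]
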