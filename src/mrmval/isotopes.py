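"""Theoretical isotope patterns and adduct m/z values for molecular formulas.

The isotope distribution of a formula is the convolution of the per-element
isotope distributions (each atom contributes an independent multinomial draw
over its natural isotopes). Patterns can be kept at exact isotopologue masses
or aggregated to nominal (unit) mass, which is how low-resolution triple-
quadrupole spectra present them — e.g. the familiar M / M+2 / M+4 chlorine
signature of a Cl2 compound at relative abundances ~0.574 : 0.367 : 0.059.

Adducts are singly charged: [M+H]+ and [M-H]- add/remove a proton, and
[M+HCOO]- attaches a formate anion (formed in negative electrospray when the
mobile phase contains formate). The electron mass (0.00054858 Da) is ignored
in m/z — three orders of magnitude below the unit-mass resolution these
identity checks work at — so the proton mass is used for +/-H.

Isotope masses and abundances are pinned below to the CODATA/CIAAW standard
reference values so results are reproducible across environments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

#: Proton mass, Da. The electron mass is deliberately not applied (see above).
PROTON_MASS = 1.007276466879
ELECTRON_MASS = 0.00054857990907  # documented; unused in m/z

#: Standard isotopic composition: element -> [(exact mass Da, abundance)].
ISOTOPE_TABLE: Dict[str, List[Tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483780, 0.0107)],
    "N": [(14.00307400480, 0.99636), (15.00010889820, 0.00364)],
    "O": [(15.99491461956, 0.99757), (16.99913170, 0.00038), (17.99916100, 0.00205)],
    "F": [(18.99840322, 1.0)],
    "Na": [(22.98976928090, 1.0)],
    "Si": [(27.97692653250, 0.92223), (28.97649470000, 0.04685), (29.97377017000, 0.03092)],
    "P": [(30.97376163, 1.0)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "Cl": [(34.96885268, 0.7576), (36.96590259, 0.2424)],
    "K": [(38.96370668, 0.932581), (39.96399848, 0.000117), (40.96182576, 0.067302)],
    "Br": [(78.91833710, 0.5069), (80.91629060, 0.4931)],
    "I": [(126.90447300, 1.0)],
}


class FormulaError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularFormula:
    element_counts: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.element_counts or sum(n for _, n in self.element_counts) == 0:
            raise FormulaError("formula must contain at least one atom")
        for el, n in self.element_counts:
            if el not in ISOTOPE_TABLE:
                raise FormulaError(f"unrecognized element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el!r}")

    def as_dict(self) -> Dict[str, int]:
        return dict(self.element_counts)

    @property
    def monoisotopic_mass(self) -> float:
        """Mass with every atom as its most abundant isotope."""
        total = 0.0
        for el, n in self.element_counts:
            principal = max(ISOTOPE_TABLE[el], key=lambda p: p[1])[0]
            total += n * principal
        return total


@dataclass
class IsotopePattern:
    peaks: List[Tuple[float, float]]  # (mass Da, abundance fraction), mass-sorted
    nominal: bool = False  # aggregated at unit mass

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("peak masses must be strictly increasing")
        total = sum(a for _, a in self.peaks)
        if self.peaks and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {total}")

    def shifted(self, delta: float) -> "IsotopePattern":
        return IsotopePattern(
            peaks=[(m + delta, a) for m, a in self.peaks], nominal=self.nominal
        )

    @property
    def base_peak(self) -> Tuple[float, float]:
        return max(self.peaks, key=lambda p: p[1])


@dataclass(frozen=True)
class AdductSpec:
    kind: str  # "[M+H]+", "[M-H]-", "[M+HCOO]-"
    mass_delta: float
    charge_sign: int


_FORMATE_MASS = (
    ISOTOPE_TABLE["H"][0][0] + ISOTOPE_TABLE["C"][0][0] + 2 * ISOTOPE_TABLE["O"][0][0]
)

ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", +PROTON_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", +_FORMATE_MASS, -1),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string like ``C11H5Cl2F3N4O`` (implicit
    count 1). Unknown symbols raise with the offending position."""
    counts: Dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if not m:
            raise FormulaError(f"cannot parse formula at position {pos}: {stripped!r}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPE_TABLE:
            raise FormulaError(
                f"unrecognized element symbol {el!r} at position {pos} in {stripped!r}"
            )
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if not counts:
        raise FormulaError(f"empty formula {text!r}")
    return MolecularFormula(tuple(counts.items()))


Peaks = List[Tuple[float, float]]


def _merge(peaks: Peaks, mass_tol: float = 1e-9) -> Peaks:
    peaks.sort()
    merged: Peaks = []
    for m, a in peaks:
        if merged and m - merged[-1][0] <= mass_tol:
            pm, pa = merged[-1]
            tot = pa + a
            merged[-1] = ((pm * pa + m * a) / tot, tot)
        else:
            merged.append((m, a))
    return merged


def _convolve(a: Peaks, b: Peaks, prune: float) -> Peaks:
    out = [(ma + mb, aa * ab) for ma, aa in a for mb, ab in b]
    out = _merge(out)
    if prune > 0:
        out = [(m, ab) for m, ab in out if ab >= prune]
    return out


def _element_power(el: str, n: int, prune: float) -> Peaks:
    """Distribution of n atoms of one element, by binary exponentiation."""
    base: Peaks = list(ISOTOPE_TABLE[el])
    result: Peaks = [(0.0, 1.0)]
    while n:
        if n & 1:
            result = _convolve(result, base, prune)
        n >>= 1
        if n:
            base = _convolve(base, base, prune)
    return result


def isotope_distribution(
    formula: MolecularFormula,
    aggregate_nominal: bool = False,
    prune: float = 1e-10,
) -> IsotopePattern:
    """Isotope pattern of a neutral formula by per-element multinomial
    convolution. Peaks below ``prune`` (absolute abundance) are dropped during
    accumulation and the final pattern is renormalized to sum to 1. With
    ``aggregate_nominal`` the isotopologues are binned at the nearest integer
    Da (abundance-weighted mean mass per bin)."""
    peaks: Peaks = [(0.0, 1.0)]
    for el, n in formula.element_counts:
        if n:
            peaks = _convolve(peaks, _element_power(el, n, prune), prune)
    if aggregate_nominal:
        bins: Dict[int, Tuple[float, float]] = {}
        for m, a in peaks:
            k = round(m)
            if k in bins:
                bm, ba = bins[k]
                bins[k] = ((bm * ba + m * a) / (ba + a), ba + a)
            else:
                bins[k] = (m, a)
        peaks = sorted(bins.values())
    total = sum(a for _, a in peaks)
    peaks = [(m, a / total) for m, a in peaks]
    return IsotopePattern(peaks=peaks, nominal=aggregate_nominal)


def adduct_mz(formula: MolecularFormula, adduct: AdductSpec) -> float:
    """Monoisotopic m/z of a singly charged adduct of the formula."""
    if abs(adduct.charge_sign) != 1:
        raise ValueError("only singly charged adducts are supported")
    if adduct.kind not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct.kind!r}")
    return formula.monoisotopic_mass + adduct.mass_delta


def adduct_pattern(
    formula: MolecularFormula,
    adduct: AdductSpec,
    aggregate_nominal: bool = False,
    prune: float = 1e-10,
) -> IsotopePattern:
    """Isotope pattern of the adduct: the neutral pattern shifted by the
    adduct mass delta (the H/formate atoms' own minor isotopes are a
    sub-0.1 % correction and are not convolved in)."""
    pattern = isotope_distribution(formula, aggregate_nominal=False, prune=prune)
    shifted = pattern.shifted(adduct.mass_delta)
    if not aggregate_nominal:
        return shifted
    return IsotopePattern(
        peaks=_nominal_bins(shifted.peaks), nominal=True
    )


def _nominal_bins(peaks: Peaks) -> Peaks:
    bins: Dict[int, Tuple[float, float]] = {}
    for m, a in peaks:
        k = round(m)
        if k in bins:
            bm, ba = bins[k]
            bins[k] = ((bm * ba + m * a) / (ba + a), ba + a)
        else:
            bins[k] = (m, a)
    out = sorted(bins.values())
    total = sum(a for _, a in out)
    return [(m, a / total) for m, a in out]


@dataclass
class SpectrumMatch:
    matched: List[Tuple[float, float, float]]  # (observed mass, predicted mass, abundance deviation)
    unexplained_observed: List[float] = field(default_factory=list)
    unmatched_predicted: List[float] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def compare_spectra(
    observed: IsotopePattern,
    predicted: IsotopePattern,
    tolerance: float,
) -> SpectrumMatch:
    """Pair observed peaks with the nearest predicted peak within
    ``tolerance`` Da and report abundance-ratio deviations (both patterns
    normalized to their base peak) plus peaks left unexplained on either
    side — an intense observed peak with no predicted counterpart flags an
    interference or a chemical transformation of the analyte."""
    if not observed.peaks or not predicted.peaks:
        raise ValueError("both patterns must be nonempty")
    obs_base = observed.base_peak[1]
    pred_base = predicted.base_peak[1]
    taken = [False] * len(predicted.peaks)
    matched: List[Tuple[float, float, float]] = []
    unexplained: List[float] = []
    for om, oa in observed.peaks:
        best, best_d = None, tolerance
        for j, (pm, _) in enumerate(predicted.peaks):
            d = abs(om - pm)
            if not taken[j] and d <= best_d:
                best, best_d = j, d
        if best is None:
            unexplained.append(om)
        else:
            taken[best] = True
            pm, pa = predicted.peaks[best]
            matched.append((om, pm, oa / obs_base - pa / pred_base))
    unmatched_pred = [
        pm for j, (pm, _) in enumerate(predicted.peaks) if not taken[j]
    ]
    return SpectrumMatch(
        matched=matched,
        unexplained_observed=unexplained,
        unmatched_predicted=unmatched_pred,
    )
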