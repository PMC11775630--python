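"""Mass arithmetic for dehydroamino-acid (DHAA) chemistry.

Dehydroamino acids arise by eliminylation: loss of H₂O from Ser/Thr (or of
phosphate from pSer/pThr, mass-equivalent relative to the unphosphorylated
residue) and loss of H₂S from Cys.  The resulting electrophilic alkene
undergoes Michael addition with biological nucleophiles — glutathione,
homocysteine, the reducing agents DTT and TCEP — or with Cys/Lys/His side
chains of another peptide, forming a protein–protein crosslink (DHAA-XL).

This module provides the elemental-composition algebra, modification and
crosslink mass deltas, ¹⁸O C-terminal label shifts, and theoretical isotope
patterns on which the rest of the pipeline is built.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import (
    ISOTOPE_SPACING,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    RESIDUE_FORMULAS,
)

__all__ = [
    "ElementalComposition",
    "ModificationDef",
    "Peptidoform",
    "CrosslinkSpecies",
    "IsotopePattern",
    "peptide_composition",
    "monoisotopic_mass",
    "mz_from_mass",
    "mass_from_mz",
    "eliminylation_delta",
    "conjugate_delta",
    "crosslink_species_mass",
    "crosslink_species_mz",
    "isotope_distribution",
    "label_18O_shift",
    "builtin_modifications",
    "load_modifications",
]

_ELEMENT_ORDER = ("C", "H", "N", "O", "S", "P", "O18")


class ElementalComposition(Counter):
    """A multiset of element counts (C, H, N, O, S, P plus heavy ``O18``).

    Counts are non-negative integers.  Addition is the usual multiset sum;
    subtraction raises if any count would go negative.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        super().__init__()
        merged = dict(counts or {})
        merged.update(kw)
        for el, n in merged.items():
            if el not in _ELEMENT_ORDER:
                raise ValueError(f"unsupported element species: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                self[el] = int(n)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return out

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({new})"
                )
            if new:
                out[el] = new
            else:
                out.pop(el, None)
        return out

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill_formula(self) -> str:
        return "".join(
            f"{el}{self[el]}" for el in _ELEMENT_ORDER if self.get(el, 0)
        )


WATER = ElementalComposition(H=2, O=1)
H2S = ElementalComposition(H=2, S=1)


def monoisotopic_mass(c: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of an elemental composition; mass({}) = 0."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in c.items())


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of a protonated species [M + zH]^{z+}."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral monoisotopic mass from observed m/z and charge."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return mz * z - z * PROTON_MASS


@dataclass(frozen=True)
class ModificationDef:
    """A named mass delta with its chemistry class and residue targets.

    ``delta_composition`` is optional but, when present, must agree with
    ``delta_mass`` to 1e-4 Da.  A *signed* composition is expressed as a
    (gain, loss) pair: ``delta_composition`` is the gain and
    ``loss_composition`` the loss, so e.g. dehydroalanine formation from Ser
    is gain=∅, loss=H₂O.
    """

    name: str
    mod_class: str  # eliminylation | conjugate | label | fixed | crosslink_delta
    targets: frozenset[str]
    delta_mass: float
    delta_composition: ElementalComposition | None = None
    loss_composition: ElementalComposition | None = None

    _CLASSES = frozenset(
        {"eliminylation", "conjugate", "label", "fixed", "crosslink_delta"}
    )

    def __post_init__(self):
        if self.mod_class not in self._CLASSES:
            raise ValueError(f"unknown mod_class {self.mod_class!r}")
        if self.mod_class not in {"crosslink_delta", "label"} and not self.targets:
            raise ValueError(f"{self.name}: residue-attached mods need targets")
        if self.delta_composition is not None:
            comp_mass = monoisotopic_mass(self.delta_composition)
            if self.loss_composition is not None:
                comp_mass -= monoisotopic_mass(self.loss_composition)
            if abs(comp_mass - self.delta_mass) >= 1e-4:
                raise ValueError(
                    f"{self.name}: composition mass {comp_mass:.6f} disagrees "
                    f"with delta_mass {self.delta_mass:.6f}"
                )

    @property
    def has_composition(self) -> bool:
        return self.delta_composition is not None


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with site-resolved modifications.

    Positions are 1-based.  ``c_term_heavy_o`` counts ¹⁸O atoms substituted
    into the C-terminal carboxylate (0 for light material, 2 after tryptic
    digestion in heavy water).
    """

    residues: str
    site_mods: Mapping[int, ModificationDef] = field(default_factory=dict)
    c_term_heavy_o: int = 0

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty peptide")
        for r in self.residues:
            if r not in RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue code {r!r}")
        if self.c_term_heavy_o not in (0, 2):
            raise ValueError("c_term_heavy_o must be 0 or 2")
        for pos, mod in self.site_mods.items():
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"mod position {pos} outside peptide")
            res = self.residues[pos - 1]
            if mod.targets and res not in mod.targets:
                raise ValueError(
                    f"{mod.name} does not target residue {res} at {pos}"
                )
        object.__setattr__(self, "site_mods", dict(self.site_mods))

    def __len__(self) -> int:
        return len(self.residues)

    def __hash__(self):
        return hash(self.key())

    def __eq__(self, other):
        return isinstance(other, Peptidoform) and self.key() == other.key()

    def key(self) -> tuple:
        """Hashable identity: sequence, (position, mod-name) pairs, label state."""
        return (
            self.residues,
            tuple(sorted((p, m.name) for p, m in self.site_mods.items())),
            self.c_term_heavy_o,
        )

    @property
    def mass(self) -> float:
        m = sum(_residue_mass(r) for r in self.residues) + WATER.mass
        m += sum(mod.delta_mass for mod in self.site_mods.values())
        m += label_18O_shift(1) * (self.c_term_heavy_o // 2)
        return m

    def proforma(self) -> str:
        """Human-readable form, e.g. ``SPVV[DHA]GDTSPR``."""
        out = []
        for i, r in enumerate(self.residues, start=1):
            out.append(r)
            if i in self.site_mods:
                out.append(f"[{self.site_mods[i].name}]")
        if self.c_term_heavy_o:
            out.append("-[18O2]")
        return "".join(out)


_RESIDUE_MASS_CACHE: dict[str, float] = {}


def _residue_mass(r: str) -> float:
    try:
        return _RESIDUE_MASS_CACHE[r]
    except KeyError:
        c, h, n, o, s = RESIDUE_FORMULAS[r]
        m = (
            c * MONOISOTOPIC_MASS["C"]
            + h * MONOISOTOPIC_MASS["H"]
            + n * MONOISOTOPIC_MASS["N"]
            + o * MONOISOTOPIC_MASS["O"]
            + s * MONOISOTOPIC_MASS["S"]
        )
        _RESIDUE_MASS_CACHE[r] = m
        return m


def peptide_composition(p: Peptidoform) -> ElementalComposition:
    """Elemental composition of a peptidoform.

    Sum of residue formulas + one water, plus each site mod's signed
    composition, with ``c_term_heavy_o`` ¹⁶O atoms swapped for ¹⁸O.  Raises
    if any site mod lacks a composition.
    """
    comp = ElementalComposition(WATER)
    for r in p.residues:
        c, h, n, o, s = RESIDUE_FORMULAS[r]
        comp = comp + ElementalComposition(C=c, H=h, N=n, O=o, S=s)
    for mod in p.site_mods.values():
        if not mod.has_composition:
            raise ValueError(
                f"modification {mod.name} carries no elemental composition"
            )
        comp = comp + ElementalComposition(mod.delta_composition)
        if mod.loss_composition is not None:
            comp = comp - ElementalComposition(mod.loss_composition)
    if p.c_term_heavy_o:
        n = p.c_term_heavy_o
        comp = comp - ElementalComposition(O=n) + ElementalComposition(O18=n)
    return comp


DONOR_RESIDUES = frozenset({"S", "T", "C"})
ACCEPTOR_RESIDUES = frozenset({"C", "K", "H"})


def eliminylation_delta(residue: str) -> float:
    """Mass delta of DHAA formation relative to the unmodified residue.

    Ser/Thr lose water (−18.010565 Da); Cys loses H₂S (−33.987721 Da).
    pSer/pThr eliminate phosphate, but relative to the *unphosphorylated*
    residue the product delta is the same water loss.
    """
    if residue in ("S", "T"):
        return -WATER.mass
    if residue == "C":
        return -H2S.mass
    raise ValueError(f"residue {residue!r} cannot form a dehydroamino acid")


#: Intact nucleophile compositions for Michael-addition conjugates.
_NUCLEOPHILES: dict[str, ElementalComposition] = {
    "GSH": ElementalComposition(C=10, H=17, N=3, O=6, S=1),  # glutathione
    "HC": ElementalComposition(C=4, H=9, N=1, O=2, S=1),  # homocysteine
    "DTT": ElementalComposition(C=4, H=10, O=2, S=2),  # dithiothreitol
    "TCEP": ElementalComposition(C=9, H=15, O=6, P=1),  # phosphine reductant
}


def conjugate_delta(conjugate: str, precursor_residue: str) -> float:
    """Mass delta of a DHAA–nucleophile conjugate vs the unmodified residue.

    Michael addition is mass-neutral bond formation, so the delta is the
    eliminylation loss plus the full monoisotopic mass of the intact
    nucleophile.
    """
    try:
        nuc = _NUCLEOPHILES[conjugate]
    except KeyError:
        raise ValueError(f"unknown conjugate {conjugate!r}") from None
    return eliminylation_delta(precursor_residue) + nuc.mass


@dataclass(frozen=True)
class CrosslinkSpecies:
    """Two peptidoforms joined donor-site → acceptor-site by a DHAA.

    The donor residue (S/T/C on the alpha chain) eliminates to a DHAA, which
    then bonds to a nucleophilic acceptor residue (C/K/H on the beta chain);
    the crosslinker delta is the eliminylation loss (−H₂O or −H₂S).
    """

    alpha: Peptidoform
    beta: Peptidoform
    donor_site: int
    acceptor_site: int
    crosslinker: ModificationDef

    def __post_init__(self):
        if self.crosslinker.mod_class != "crosslink_delta":
            raise ValueError("crosslinker must be a crosslink_delta mod")
        donor_res = self.alpha.residues[self.donor_site - 1]
        if donor_res not in DONOR_RESIDUES:
            raise ValueError(f"donor residue {donor_res} not in S/T/C")
        acc_res = self.beta.residues[self.acceptor_site - 1]
        if acc_res not in ACCEPTOR_RESIDUES:
            raise ValueError(f"acceptor residue {acc_res} not in C/K/H")
        if acc_res == "C":
            mod = self.beta.site_mods.get(self.acceptor_site)
            if mod is not None and mod.mod_class == "fixed":
                raise ValueError(
                    "acceptor Cys is alkylated and chemically blocked"
                )

    @property
    def mass(self) -> float:
        return crosslink_species_mass(self)

    def swapped_mass(self) -> float:
        """Mass computed with the chain roles exchanged (symmetry check)."""
        return self.beta.mass + self.alpha.mass + self.crosslinker.delta_mass


def crosslink_species_mass(x: CrosslinkSpecies) -> float:
    """Neutral monoisotopic mass of a crosslinked species.

    mass(alpha) + mass(beta) + crosslinker delta; symmetric in the chains.
    """
    return x.alpha.mass + x.beta.mass + x.crosslinker.delta_mass


def crosslink_species_mz(x: CrosslinkSpecies, z: int) -> float:
    return mz_from_mass(crosslink_species_mass(x), z)


def label_18O_shift(n_labeled_termini: int) -> float:
    """Mass shift of n C-termini carrying two ¹⁸O each (nominal 4n Da).

    Tryptic digestion in heavy water exchanges both C-terminal carboxylate
    oxygens, so a linear peptide shifts +4 Da and a crosslinked pair of
    peptides, having two C-termini, shifts +8 Da.
    """
    if n_labeled_termini not in (0, 1, 2):
        raise ValueError("n_labeled_termini must be 0, 1 or 2")
    return n_labeled_termini * 2 * (
        MONOISOTOPIC_MASS["O18"] - MONOISOTOPIC_MASS["O"]
    )


@dataclass(frozen=True)
class IsotopePattern:
    """Theoretical isotope peaks: (mass or m/z, relative intensity).

    Intensities sum to 1.  ``charge`` 0 means neutral-mass peaks; for a
    charged pattern the peaks are m/z values of the protonated species.
    """

    peaks: tuple[tuple[float, float], ...]
    charge: int = 0

    def __post_init__(self):
        total = sum(i for _, i in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"intensities sum to {total}, not 1")
        mzs = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak masses must be strictly increasing")

    @property
    def mzs(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


def _element_shift_pattern(el: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (intensity, intensity×mass) arrays indexed by neutron shift."""
    iso = ISOTOPES[el]
    base = iso[0][0]
    max_shift = max(int(round(m - base)) for m, _ in iso)
    inten = np.zeros(max_shift + 1)
    wmass = np.zeros(max_shift + 1)
    for m, a in iso:
        k = int(round(m - base))
        inten[k] += a
        wmass[k] += a * m
    return inten, wmass


def isotope_distribution(
    c: Mapping[str, int], z: int = 0, n_peaks: int = 6
) -> IsotopePattern:
    """Aggregated theoretical isotope pattern of a composition.

    Convolves per-element isotopologue polynomials, tracking both the
    probability and the abundance-weighted mass in each neutron-shift bin,
    so each reported peak mass is the centroid of its isotopologue cluster.
    Truncates to ``n_peaks`` and renormalizes to sum 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    # distribution over neutron shifts: P[k], and M[k] = sum of p*mass
    P = np.array([1.0])
    M = np.array([0.0])
    limit = n_peaks + 4  # keep a little tail before final truncation
    for el, count in c.items():
        if count == 0:
            continue
        e_int, e_wm = _element_shift_pattern(el)
        e_mean = np.divide(
            e_wm, e_int, out=np.zeros_like(e_wm), where=e_int > 0
        )
        for _ in range(count):
            newP = np.convolve(P, e_int)[:limit]
            # E[mass] adds: convolve P*M with e_int plus P with e_int*e_mass
            newM = (
                np.convolve(M, e_int)[:limit]
                + np.convolve(P, e_int * e_mean)[:limit]
            )
            # prune negligible tail mass to keep convolutions cheap
            tail = np.cumsum(newP[::-1])[::-1]  # probability in bins k..end
            nz = np.nonzero(tail > 1e-12)[0]
            keep = int(nz[-1]) + 1 if nz.size else 1
            P, M = newP[:keep], newM[:keep]
    n = min(n_peaks, len(P))
    P, M = P[:n], M[:n]
    nonzero = P > 0
    P, M = P[nonzero], M[nonzero]
    centroid = M / P
    inten = P / P.sum()
    if z >= 1:
        centroid = (centroid + z * PROTON_MASS) / z
    peaks = tuple(zip(centroid.tolist(), inten.tolist()))
    return IsotopePattern(peaks=peaks, charge=z)


def enumerate_isotopologues(c: Mapping[str, int]) -> list[tuple[float, float]]:
    """Exhaustive isotopologue enumeration — small compositions only.

    Brute-force oracle for :func:`isotope_distribution`: walks every
    assignment of isotopes to atoms via multinomial expansion and aggregates
    by neutron shift.  Exponential in atom count; intended for tests.
    """
    from itertools import combinations_with_replacement

    states: list[tuple[float, float, int]] = [(0.0, 1.0, 0)]  # mass, prob, shift
    for el, count in c.items():
        iso = ISOTOPES[el]
        base = iso[0][0]
        new_states = []
        for combo in combinations_with_replacement(range(len(iso)), count):
            # multinomial coefficient for this isotope assignment
            counts = Counter(combo)
            coef = math.factorial(count)
            prob = 1.0
            mass = 0.0
            shift = 0
            for idx, k in counts.items():
                coef //= math.factorial(k)
                prob *= ISOTOPES[el][idx][1] ** k
                mass += ISOTOPES[el][idx][0] * k
                shift += int(round(ISOTOPES[el][idx][0] - base)) * k
            for m0, p0, s0 in states:
                new_states.append((m0 + mass, p0 * prob * coef, s0 + shift))
        states = new_states
    agg: dict[int, tuple[float, float]] = {}
    for m, p, s in states:
        pm, pp = agg.get(s, (0.0, 0.0))
        agg[s] = (pm + p * m, pp + p)
    out = []
    for s in sorted(agg):
        wm, p = agg[s]
        out.append((wm / p, p))
    total = sum(p for _, p in out)
    return [(m, p / total) for m, p in out]


# ---------------------------------------------------------------------------
# built-in modification registry


def _mk(name, mod_class, targets, gain=None, loss=None, mass=None):
    gain_c = ElementalComposition(gain) if gain is not None else None
    loss_c = ElementalComposition(loss) if loss is not None else None
    if mass is None:
        mass = (gain_c.mass if gain_c else 0.0) - (loss_c.mass if loss_c else 0.0)
    return ModificationDef(
        name=name,
        mod_class=mod_class,
        targets=frozenset(targets),
        delta_mass=mass,
        delta_composition=gain_c if gain is not None or loss is not None else None,
        loss_composition=loss_c,
    )


def builtin_modifications() -> dict[str, ModificationDef]:
    """The shipped modification set covering the DHAA discovery chemistry."""
    mods = [
        _mk("DHA", "eliminylation", "SC", gain={}, loss={"H": 2, "O": 1}),
        _mk("DHB", "eliminylation", "T", gain={}, loss={"H": 2, "O": 1}),
        _mk("DHA-C", "eliminylation", "C", gain={}, loss={"H": 2, "S": 1}),
        _mk("GSH-DHAA", "conjugate", "ST",
            gain={"C": 10, "H": 17, "N": 3, "O": 6, "S": 1},
            loss={"H": 2, "O": 1}),
        _mk("GSH-DHAA-C", "conjugate", "C",
            gain={"C": 10, "H": 17, "N": 3, "O": 6, "S": 1},
            loss={"H": 2, "S": 1}),
        _mk("HC-DHAA", "conjugate", "ST",
            gain={"C": 4, "H": 9, "N": 1, "O": 2, "S": 1},
            loss={"H": 2, "O": 1}),
        _mk("HC-DHAA-C", "conjugate", "C",
            gain={"C": 4, "H": 9, "N": 1, "O": 2, "S": 1},
            loss={"H": 2, "S": 1}),
        _mk("DTT-DHAA", "conjugate", "ST",
            gain={"C": 4, "H": 10, "O": 2, "S": 2},
            loss={"H": 2, "O": 1}),
        _mk("DTT-DHAA-C", "conjugate", "C",
            gain={"C": 4, "H": 10, "O": 2, "S": 2},
            loss={"H": 2, "S": 1}),
        _mk("TCEP-DHAA", "conjugate", "ST",
            gain={"C": 9, "H": 15, "O": 6, "P": 1},
            loss={"H": 2, "O": 1}),
        _mk("TCEP-DHAA-C", "conjugate", "C",
            gain={"C": 9, "H": 15, "O": 6, "P": 1},
            loss={"H": 2, "S": 1}),
        _mk("Carbamidomethyl", "fixed", "C",
            gain={"C": 2, "H": 3, "N": 1, "O": 1}),
        _mk("Propionamide", "fixed", "C",
            gain={"C": 3, "H": 5, "N": 1, "O": 1}),
        _mk("Phospho", "conjugate", "STY", gain={"H": 1, "O": 3, "P": 1}),
        ModificationDef(
            name="18O2-Cterm", mod_class="label", targets=frozenset(),
            delta_mass=label_18O_shift(1),
            delta_composition=ElementalComposition(O18=2),
            loss_composition=ElementalComposition(O=2),
        ),
        ModificationDef(
            name="XL-ST", mod_class="crosslink_delta", targets=frozenset("ST"),
            delta_mass=-WATER.mass,
            delta_composition=ElementalComposition(),
            loss_composition=ElementalComposition(H=2, O=1),
        ),
        ModificationDef(
            name="XL-C", mod_class="crosslink_delta", targets=frozenset("C"),
            delta_mass=-H2S.mass,
            delta_composition=ElementalComposition(),
            loss_composition=ElementalComposition(H=2, S=1),
        ),
    ]
    return {m.name: m for m in mods}


def load_modifications(path) -> dict[str, ModificationDef]:
    """Load modification definitions from a YAML config.

    Each entry: ``name``, ``class``, ``targets`` (string of residue codes),
    and either ``gain``/``loss`` element-count mappings or a bare ``mass``.
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    mods = {}
    for e in entries:
        mods[e["name"]] = _mk(
            e["name"], e["class"], e.get("targets", ""),
            gain=e.get("gain"), loss=e.get("loss"), mass=e.get("mass"),
        )
    return mods
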