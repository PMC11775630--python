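"""Seeded generator of synthetic ground truth for the whole pipeline.

Emulates the study's raw-data conditions at desk scale: tryptic-friendly
random proteomes; planted DHAA sites, conjugates and intra/inter crosslinks;
paired light (H₂¹⁶O) and heavy (H₂¹⁸O, 95% exchange) digests of the same
material with ppm-scale mass error; and disease/control intensity matrices
with log-normal noise and planted fold changes (10-fold on crosslink
features, the effect size reported for disease tissue).  Every stage is
fully deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import (
    ElementalComposition,
    ModificationDef,
    Peptidoform,
    builtin_modifications,
    isotope_distribution,
    label_18O_shift,
    mz_from_mass,
    peptide_composition,
)
from .digest import DigestParams, tryptic_digest
from .io import ProteinRecord, SpectrumRecord
from .search import theoretical_fragments, generate_crosslink_fragments

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "PlantedSite",
    "PlantedCrosslink",
    "generate_proteome",
    "plant_modifications",
    "simulate_spectra",
    "simulate_intensity_matrix",
]

#: sequences of the synthetic crosslinked-peptide standards; embedding them
#: gives the worked-example tests natural tryptic substrates
FIXTURE_PEPTIDES = ("IGSTENLK", "SPVVSGDTSPR", "CGSKDNIK")

_AA = "ACDEFGHIKLMNPQRSTVWY"
# residue sampling weights: roughly natural frequencies with enough K/R to
# give tryptic peptides of usable length
_AA_W = np.array([
    0.07, 0.03, 0.05, 0.06, 0.04, 0.07, 0.03, 0.05, 0.06, 0.09,
    0.02, 0.04, 0.05, 0.04, 0.06, 0.07, 0.06, 0.06, 0.01, 0.04,
])
_AA_W = _AA_W / _AA_W.sum()


@dataclass(frozen=True)
class SimulationParams:
    seed: int = 0
    n_proteins: int = 30
    protein_length: tuple[int, int] = (120, 240)
    n_specimens_ad: int = 48
    n_specimens_ctr: int = 44
    n_direct_sites: int = 8
    n_conjugate_sites: int = 4  # per conjugate kind (GSH, HC, DTT, TCEP)
    n_crosslinks_intra: int = 6
    n_crosslinks_inter: int = 6
    n_crosslinks_light_only: int = 4
    n_background_peptides: int = 40
    ppm_error_sd: float = 2.0
    rt_jitter_sd: float = 0.3  # minutes
    intensity_sigma: float = 0.3  # log-normal sigma on natural-log scale
    fold_change_crosslink: float = 10.0
    heavy_exchange_fraction: float = 0.95
    noise_peaks: int = 30
    embed_fixtures: bool = False

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 <= self.heavy_exchange_fraction <= 1:
            raise ValueError("heavy_exchange_fraction outside [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    accession: str
    position: int  # protein coordinate of the modified residue
    residue: str
    form: str  # direct | GSH | HC | DTT | TCEP
    mod_name: str
    peptide: str
    peptide_start: int
    charge: int
    rt: float
    base_intensity: float


@dataclass(frozen=True)
class PlantedCrosslink:
    xl_id: str
    alpha_accession: str
    alpha_peptide: str
    alpha_start: int
    donor_position: int  # protein coordinate
    donor_residue: str
    beta_accession: str
    beta_peptide: str
    beta_start: int
    acceptor_position: int
    acceptor_residue: str
    crosslinker_name: str  # XL-ST | XL-C
    link_class: str  # intra | inter
    light_only: bool
    charge: int
    rt: float
    base_intensity: float

    def key(self) -> tuple:
        a = (self.alpha_accession, self.donor_position, self.alpha_peptide)
        b = (self.beta_accession, self.acceptor_position, self.beta_peptide)
        return tuple(sorted([a, b])) + (self.crosslinker_name,)


@dataclass
class GroundTruth:
    params: SimulationParams
    proteins: list[ProteinRecord] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_crosslinks: list[PlantedCrosslink] = field(default_factory=list)
    background_peptides: list[tuple[str, str, int, int, float, float]] = (
        field(default_factory=list)
    )  # (accession, peptide, start, charge, rt, base_intensity)

    @property
    def proteins_by_accession(self) -> dict[str, ProteinRecord]:
        return {p.accession: p for p in self.proteins}


def _rng(params: SimulationParams, *streams: int) -> np.random.Generator:
    return np.random.default_rng([params.seed % (2**31), *streams])


def generate_proteome(params: SimulationParams) -> GroundTruth:
    """Random tryptic-friendly proteome; same seed → identical output."""
    rng = _rng(params, 1)
    proteins = []
    for i in range(params.n_proteins):
        n = int(rng.integers(*params.protein_length))
        seq = "".join(rng.choice(list(_AA), size=n, p=_AA_W))
        if params.embed_fixtures and i < len(FIXTURE_PEPTIDES):
            fix = FIXTURE_PEPTIDES[i]
            at = n // 2
            seq = seq[:at] + "K" + fix + seq[at:]
        proteins.append(ProteinRecord(
            accession=f"SYN{i + 1:03d}",
            description=f"synthetic protein {i + 1}",
            sequence=seq,
        ))
    return GroundTruth(params=params, proteins=proteins)


def _eligible_peptides(truth: GroundTruth) -> list[tuple[str, str, int]]:
    """Zero-missed tryptic peptides (accession, peptide, start) per protein."""
    dp = DigestParams(max_missed_cleavages=0, min_length=6, max_length=30)
    out = []
    for prot in truth.proteins:
        for pep, start in tryptic_digest(prot, dp):
            out.append((prot.accession, pep, start))
    return out


def plant_modifications(truth: GroundTruth) -> GroundTruth:
    """Plant the requested numbers of each evidence form without collisions.

    Direct sites and conjugates go on S/T/C residues of distinct tryptic
    peptides; crosslinks pair a donor peptide (S/T or C) with an acceptor
    peptide carrying an internal C/K/H, split intra/inter as requested.
    """
    params = truth.params
    rng = _rng(params, 2)
    mods = builtin_modifications()
    peptides = _eligible_peptides(truth)
    order = rng.permutation(len(peptides))
    pool = [peptides[i] for i in order]
    used: set[tuple[str, str]] = set()

    def take(pred):
        for k, entry in enumerate(pool):
            acc, pep, start = entry
            if (acc, pep) in used:
                continue
            hit = pred(acc, pep)
            if hit is not None:
                used.add((acc, pep))
                del pool[k]
                return entry, hit
        return None, None

    def linear_site_positions(pep, residues):
        # internal positions only, so fragment ladders can localize
        return [i for i, r in enumerate(pep[:-1], start=1) if r in residues]

    sites: list[PlantedSite] = []

    def plant_linear(form, residues, mod_for):
        entry, pos = take(lambda acc, pep: (
            rng.choice(linear_site_positions(pep, residues))
            if linear_site_positions(pep, residues) else None
        ))
        if entry is None:
            raise ValueError(f"not enough eligible residues for {form}")
        acc, pep, start = entry
        pos = int(pos)
        res = pep[pos - 1]
        sites.append(PlantedSite(
            accession=acc, position=start + pos - 1, residue=res,
            form=form, mod_name=mod_for(res), peptide=pep,
            peptide_start=start,
            charge=int(rng.integers(2, 4)),
            rt=float(rng.uniform(15, 110)),
            base_intensity=float(np.exp(rng.normal(np.log(1e6), 0.5))),
        ))

    for _ in range(params.n_direct_sites):
        plant_linear(
            "direct", "STC",
            lambda r: {"S": "DHA", "T": "DHB", "C": "DHA-C"}[r],
        )
    for kind in ("GSH", "HC", "DTT", "TCEP"):
        for _ in range(params.n_conjugate_sites):
            plant_linear(
                kind, "STC",
                lambda r, k=kind: f"{k}-DHAA-C" if r == "C" else f"{k}-DHAA",
            )

    xls: list[PlantedCrosslink] = []
    n_total_xl = (
        params.n_crosslinks_intra + params.n_crosslinks_inter
        + params.n_crosslinks_light_only
    )
    for j in range(n_total_xl):
        if j < params.n_crosslinks_intra:
            link_class, light_only = "intra", False
        elif j < params.n_crosslinks_intra + params.n_crosslinks_inter:
            link_class, light_only = "inter", False
        else:
            link_class = "inter" if j % 2 else "intra"
            light_only = True
        # pick donor and acceptor jointly so an intra link never strands a
        # donor on a protein without a second, acceptor-bearing peptide
        same = link_class == "intra"
        chosen = None
        for di, donor_entry in enumerate(pool):
            dacc, dpep, dstart = donor_entry
            if (dacc, dpep) in used:
                continue
            dsites = linear_site_positions(dpep, "STC")
            if not dsites:
                continue
            for ai, acc_entry in enumerate(pool):
                if ai == di:
                    continue
                aacc, apep, astart = acc_entry
                if (aacc, apep) in used or same != (aacc == dacc):
                    continue
                if aacc == dacc and (
                    astart == dstart + len(dpep)
                    or dstart == astart + len(apep)
                ):
                    # adjacent tryptic peptides: a water-loss crosslink
                    # between them is isobaric with the missed-cleavage
                    # linear peptide and inherently unidentifiable
                    continue
                asites = [
                    i for i, r in enumerate(apep[:-1], start=1) if r in "CKH"
                ]
                if asites:
                    chosen = (donor_entry, dsites, acc_entry, asites)
                    break
            if chosen:
                break
        if chosen is None:
            raise ValueError(
                f"no donor/acceptor peptide pair available for {link_class} "
                "crosslink (S/T/C donor and internal C/K/H acceptor needed)"
            )
        donor_entry, dsites, acc_entry, asites = chosen
        dacc, dpep, dstart = donor_entry
        aacc, apep, astart = acc_entry
        used.add((dacc, dpep))
        used.add((aacc, apep))
        pool.remove(donor_entry)
        pool.remove(acc_entry)
        dpos = int(rng.choice(dsites))
        dres = dpep[dpos - 1]
        apos = int(rng.choice(asites))
        xls.append(PlantedCrosslink(
            xl_id=f"XL{j + 1:02d}",
            alpha_accession=dacc, alpha_peptide=dpep, alpha_start=dstart,
            donor_position=dstart + dpos - 1, donor_residue=dres,
            beta_accession=aacc, beta_peptide=apep, beta_start=astart,
            acceptor_position=astart + apos - 1,
            acceptor_residue=apep[apos - 1],
            crosslinker_name="XL-C" if dres == "C" else "XL-ST",
            link_class=link_class, light_only=light_only,
            charge=int(rng.integers(3, 5)),
            rt=float(rng.uniform(15, 110)),
            base_intensity=float(np.exp(rng.normal(np.log(1e6), 0.5))),
        ))

    background = []
    for entry in pool[: params.n_background_peptides]:
        acc, pep, start = entry
        background.append((
            acc, pep, start,
            int(rng.integers(2, 4)),
            float(rng.uniform(15, 110)),
            float(np.exp(rng.normal(np.log(1e6), 0.5))),
        ))

    return replace_truth(truth, sites, xls, background)


def replace_truth(truth, sites, xls, background) -> GroundTruth:
    out = GroundTruth(params=truth.params, proteins=truth.proteins)
    out.planted_sites = sites
    out.planted_crosslinks = xls
    out.background_peptides = background
    return out


# ---------------------------------------------------------------------------
# spectrum simulation


def _site_peptidoform(site: PlantedSite, mods) -> Peptidoform:
    local = site.position - site.peptide_start + 1
    return Peptidoform(site.peptide, {local: mods[site.mod_name]})


def _xl_composition(xl: PlantedCrosslink, mods, heavy: bool):
    alpha = Peptidoform(xl.alpha_peptide, c_term_heavy_o=2 if heavy else 0)
    beta = Peptidoform(xl.beta_peptide, c_term_heavy_o=2 if heavy else 0)
    comp = peptide_composition(alpha) + peptide_composition(beta)
    loss = mods[xl.crosslinker_name].loss_composition
    return comp - ElementalComposition(loss)


def simulate_spectra(
    truth: GroundTruth,
    label_state: str = "light",
    run_id: str = "run1",
    run_stream: int = 0,
) -> list[SpectrumRecord]:
    """One MS2 spectrum per planted species (plus background peptides).

    Heavy runs carry the double-¹⁸O C-terminal label on every peptide; a
    crosslinked pair therefore shifts ~8 Da and a linear peptide ~4 Da.
    With probability 1 − heavy_exchange_fraction a heavy species is only
    partially exchanged (one labelled terminus), stressing the validator.
    Precursor and fragment m/z carry Gaussian ppm error; uniform noise peaks
    are added; the MS1 isotope block comes from the theoretical pattern of
    the species' elemental composition.
    """
    params = truth.params
    heavy = label_state == "heavy"
    rng = _rng(params, 3, run_stream, 1 if heavy else 0)
    mods = builtin_modifications()
    spectra: list[SpectrumRecord] = []
    counter = 0

    def ppm_noise(mz):
        return mz * (1.0 + rng.normal(0.0, params.ppm_error_sd) * 1e-6)

    def make_spectrum(name, neutral_mass, comp, frag_mzs, z, rt, intensity):
        nonlocal counter
        counter += 1
        mz = mz_from_mass(neutral_mass, z)
        frags = sorted(
            (ppm_noise(f), float(rng.uniform(0.3, 1.0)) * intensity)
            for f in frag_mzs
        )
        base = max(i for _, i in frags) if frags else intensity
        for _ in range(params.noise_peaks):
            frags.append((
                float(rng.uniform(200, 1500)),
                float(rng.uniform(0.01, 0.1)) * base,
            ))
        ms1 = []
        if comp is not None:
            pattern = isotope_distribution(comp, z=z, n_peaks=5)
            ms1 = [
                (ppm_noise(m), float(i) * intensity)
                for m, i in pattern.peaks
            ]
        spectra.append(SpectrumRecord(
            spectrum_id=f"{run_id}.{counter}.{name}",
            run_id=run_id,
            label_state=label_state,
            precursor_mz=ppm_noise(mz),
            precursor_z=z,
            rt=max(0.0, rt + rng.normal(0.0, params.rt_jitter_sd)),
            fragments=sorted(frags),
            ms1_peaks=sorted(ms1),
            precursor_intensity=intensity,
        ))

    def heavy_o() -> int:
        if not heavy:
            return 0
        return 2 if rng.random() < params.heavy_exchange_fraction else 0

    for acc, pep, start, z, rt, inten in truth.background_peptides:
        pf = Peptidoform(pep, c_term_heavy_o=heavy_o() if heavy else 0)
        mzs = [m for _, m in theoretical_fragments(pf, (1,))]
        make_spectrum(
            f"bg.{pep}", pf.mass, peptide_composition(pf), mzs, z, rt, inten
        )

    for site in truth.planted_sites:
        pf = _site_peptidoform(site, mods)
        if heavy:
            pf = Peptidoform(pf.residues, pf.site_mods, c_term_heavy_o=heavy_o())
        mzs = [m for _, m in theoretical_fragments(pf, (1,))]
        make_spectrum(
            f"site.{site.accession}.{site.position}",
            pf.mass, peptide_composition(pf), mzs, site.charge, site.rt,
            site.base_intensity,
        )

    for xl in truth.planted_crosslinks:
        if xl.light_only and heavy:
            continue
        if not heavy:
            o = o2 = 0
        elif rng.random() < params.heavy_exchange_fraction:
            o = o2 = 2  # fully exchanged: both C-termini labelled
        else:
            # partial exchange: only one of the two termini carries the label
            o, o2 = (2, 0) if rng.random() < 0.5 else (0, 2)
        alpha = Peptidoform(xl.alpha_peptide, c_term_heavy_o=o)
        beta = Peptidoform(xl.beta_peptide, c_term_heavy_o=o2)
        delta = mods[xl.crosslinker_name].delta_mass
        mass = alpha.mass + beta.mass + delta
        dlocal = xl.donor_position - xl.alpha_start + 1
        alocal = xl.acceptor_position - xl.beta_start + 1
        frags = generate_crosslink_fragments(
            alpha, beta, dlocal, alocal, delta, (1,)
        )
        comp = None
        if o == 2 and o2 == 2 or not heavy:
            comp = _xl_composition(xl, mods, heavy)
        make_spectrum(
            f"xl.{xl.xl_id}", mass, comp,
            [m for _, _, m, _ in frags], xl.charge, xl.rt,
            xl.base_intensity,
        )

    return spectra


# ---------------------------------------------------------------------------
# intensity matrix


def simulate_intensity_matrix(
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Feature × specimen intensities with planted disease effects.

    Crosslink features carry the planted fold change in disease (AD)
    specimens; background-peptide features are null.  Intensities are
    log-normal around each feature's base intensity.  Returns (matrix,
    effect table, specimen→group map).
    """
    params = truth.params
    rng = _rng(params, 4)
    specimens = (
        [f"AD{i + 1:02d}" for i in range(params.n_specimens_ad)]
        + [f"CTR{i + 1:02d}" for i in range(params.n_specimens_ctr)]
    )
    groups = {
        s: ("AD" if s.startswith("AD") else "CTR") for s in specimens
    }
    features = []
    for acc, pep, start, _, _, inten in truth.background_peptides:
        features.append((f"bg.{acc}.{pep}", inten, 1.0))
    for site in truth.planted_sites:
        features.append((
            f"site.{site.accession}.{site.position}.{site.form}",
            site.base_intensity, 1.0,
        ))
    for xl in truth.planted_crosslinks:
        features.append((
            f"xl.{xl.xl_id}", xl.base_intensity,
            params.fold_change_crosslink,
        ))
    rows = {}
    effects = []
    for name, base, fold in features:
        mu = np.log(base)
        vals = np.exp(rng.normal(mu, params.intensity_sigma, len(specimens)))
        ad_mask = np.array([groups[s] == "AD" for s in specimens])
        vals[ad_mask] *= fold
        rows[name] = vals
        effects.append({"feature": name, "planted_fold": fold})
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=specimens)
    return mat, pd.DataFrame(effects), groups
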