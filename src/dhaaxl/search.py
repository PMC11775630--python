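"""Linear and crosslink spectrum searching with target-decoy FDR.

Three search modes mirror the discovery workflow:

1. a standard bottom-up search of linear peptides (``search_linear``),
2. open delta-mass discovery that explains unidentified precursor mass
   offsets with candidate DHAA/conjugate modifications and localizes them
   onto target residues (``discover_delta_mods``), and
3. a crosslink search that pairs a DHAA donor peptide with a nucleophilic
   acceptor peptide so their summed mass plus the crosslinker delta matches
   the precursor, scoring crosslink-containing fragments from both chains
   (``search_crosslinks``).

Scoring is a transparent matched-ion count plus fraction of fragment
intensity explained; confidence is estimated by searching reversed-sequence
decoys alongside targets and converting decoy counts to q-values.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .chem import (
    ModificationDef,
    Peptidoform,
    PROTON_MASS,
    label_18O_shift,
    mass_from_mz,
    mz_from_mass,
)
from .digest import DigestParams, SiteSpecificCrosslinkMod, tryptic_digest
from .io import CsmRecord, ProteinRecord, PsmRecord, SpectrumRecord

__all__ = [
    "SearchParams",
    "ScoredMatch",
    "theoretical_fragments",
    "generate_crosslink_fragments",
    "score_match",
    "search_linear",
    "discover_delta_mods",
    "search_crosslinks",
    "estimate_fdr",
    "PeptideIndex",
    "DiscoveredMod",
]


@dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    precursor_charges: tuple[int, int] = (2, 5)
    fragment_charges: tuple[int, ...] = (1, 2)
    variable_mods: tuple[ModificationDef, ...] = ()
    fixed_mods: tuple[ModificationDef, ...] = ()
    fdr_threshold: float = 0.01
    decoy_mode: str = "reverse"
    min_matched_ions: int = 4
    digest: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold outside (0, 1]")


@dataclass
class ScoredMatch:
    matched_ion_count: int
    fraction_intensity_explained: float
    score: float
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fragment generation


def theoretical_fragments(
    p: Peptidoform, charges: tuple[int, ...] = (1,)
) -> list[tuple[str, float]]:
    """b- and y-ion m/z values for a peptidoform (HCD-style b/y only).

    Site modification masses fall into every ion spanning the modified
    position; the C-terminal ¹⁸O label mass falls into every y ion.
    """
    n = len(p.residues)
    if n < 2:
        raise ValueError("need at least 2 residues for fragments")
    from .chem import _residue_mass  # residue monoisotopic masses

    res = [_residue_mass(r) for r in p.residues]
    for pos, mod in p.site_mods.items():
        res[pos - 1] += mod.delta_mass
    prefix = np.cumsum(res)
    total = prefix[-1]
    water = 18.01056468374
    label = label_18O_shift(1) * (p.c_term_heavy_o // 2)
    out = []
    for z in charges:
        for i in range(1, n):
            b_neutral = prefix[i - 1]
            out.append((f"b{i}^{z}", (b_neutral + z * PROTON_MASS) / z))
        for j in range(1, n):
            y_neutral = total - prefix[n - j - 1] + water + label
            out.append((f"y{j}^{z}", (y_neutral + z * PROTON_MASS) / z))
    return out


def generate_crosslink_fragments(
    alpha: Peptidoform,
    beta: Peptidoform,
    donor_site: int,
    acceptor_site: int,
    crosslinker_delta: float,
    charges: tuple[int, ...] = (1,),
) -> list[tuple[str, str, float, bool]]:
    """Fragments of a crosslinked pair: (chain, ion, m/z, carries_crosslink).

    Ions that span the linked residue carry the entire partner-peptide mass
    plus the crosslinker delta as a modification mass; ions that do not are
    identical to the plain linear fragments.
    """
    out = []
    for chain, own, partner, site in (
        ("A", alpha, beta, donor_site),
        ("B", beta, alpha, acceptor_site),
    ):
        extra = partner.mass + crosslinker_delta
        n = len(own.residues)
        for label, mz in theoretical_fragments(own, charges):
            ion, z_s = label.split("^")
            z = int(z_s)
            idx = int(ion[1:])
            if ion[0] == "b":
                spans = idx >= site
            else:
                spans = idx >= n - site + 1
            out.append((
                chain,
                label,
                mz + (extra / z if spans else 0.0),
                spans,
            ))
    return out


# ---------------------------------------------------------------------------
# scoring


def score_match(
    spectrum: SpectrumRecord,
    theoretical_mzs: list[float],
    fragment_tol_ppm: float,
) -> ScoredMatch:
    """Greedy nearest-peak matching within a ppm tolerance.

    Each observed peak may explain at most one theoretical ion.  The score
    is the matched-ion count plus the fraction of total fragment intensity
    explained, so ties on count break toward the more intense explanation.
    """
    peaks = spectrum.fragments
    if not peaks or not theoretical_mzs:
        return ScoredMatch(0, 0.0, 0.0)
    obs_mz = [p[0] for p in peaks]
    used = [False] * len(peaks)
    matched = 0
    matched_intensity = 0.0
    pairs = []
    for tmz in sorted(theoretical_mzs):
        tol = tmz * fragment_tol_ppm * 1e-6
        lo = bisect_left(obs_mz, tmz - tol)
        hi = bisect_right(obs_mz, tmz + tol)
        best, best_err = -1, tol
        for k in range(lo, hi):
            if used[k]:
                continue
            err = abs(obs_mz[k] - tmz)
            if err <= best_err:
                best, best_err = k, err
        if best >= 0:
            used[best] = True
            matched += 1
            matched_intensity += peaks[best][1]
            pairs.append((tmz, obs_mz[best]))
    total_intensity = sum(i for _, i in peaks)
    frac = matched_intensity / total_intensity if total_intensity else 0.0
    return ScoredMatch(matched, frac, matched + frac, pairs)


# ---------------------------------------------------------------------------
# candidate index


def _reverse_decoy(seq: str) -> str:
    """Reverse a peptide keeping its C-terminal residue (tryptic decoy)."""
    return seq[-1] if len(seq) == 1 else seq[:-1][::-1] + seq[-1]


@dataclass
class _Candidate:
    peptidoform: Peptidoform
    mass: float
    accession: str
    start: int
    is_decoy: bool
    donor_positions: tuple[int, ...] = ()
    acceptor_positions: tuple[int, ...] = ()


class PeptideIndex:
    """Sorted-by-mass index of digested candidate peptidoforms.

    Targets come from the protein database; decoys from per-protein sequence
    reversal (flagged, ``DECOY_`` accession prefix).  Variable modifications
    are expanded at most one per peptide; fixed modifications are applied to
    every matching residue.
    """

    def __init__(
        self,
        proteins: list[ProteinRecord],
        params: SearchParams,
        with_decoys: bool = True,
        site_specific_mods: list[SiteSpecificCrosslinkMod] | None = None,
        donor_residues: tuple[str, ...] = (),
        acceptor_residues: tuple[str, ...] = (),
    ):
        if not proteins:
            raise ValueError("empty protein database")
        cands: list[_Candidate] = []
        entries = [(p, False) for p in proteins]
        if with_decoys:
            entries += [
                (ProteinRecord(
                    f"DECOY_{p.accession}", p.description,
                    _reverse_decoy(p.sequence),
                ), True)
                for p in proteins
            ]
        site_mods_by_acc: dict[str, list[SiteSpecificCrosslinkMod]] = {}
        for sm in site_specific_mods or []:
            site_mods_by_acc.setdefault(sm.accession, []).append(sm)
        for prot, is_decoy in entries:
            for pep, start in tryptic_digest(prot, params.digest):
                base_mods: dict[int, ModificationDef] = {}
                for fm in params.fixed_mods:
                    for i, r in enumerate(pep, start=1):
                        if r in fm.targets:
                            base_mods[i] = fm
                forms: list[dict[int, ModificationDef]] = [dict(base_mods)]
                for vm in params.variable_mods:
                    for i, r in enumerate(pep, start=1):
                        if r in vm.targets and i not in base_mods:
                            m = dict(base_mods)
                            m[i] = vm
                            forms.append(m)
                if not is_decoy:
                    for sm in site_mods_by_acc.get(prot.accession, []):
                        local = sm.position - start + 1
                        if 1 <= local <= len(pep):
                            m = dict(base_mods)
                            m[local] = sm.mod
                            forms.append(m)
                for mods in forms:
                    pf = Peptidoform(pep, mods)
                    cands.append(_Candidate(
                        peptidoform=pf,
                        mass=pf.mass,
                        accession=prot.accession,
                        start=start,
                        is_decoy=is_decoy,
                        donor_positions=tuple(
                            i for i, r in enumerate(pep, start=1)
                            if r in donor_residues and i not in mods
                        ),
                        acceptor_positions=tuple(
                            i for i, r in enumerate(pep, start=1)
                            if r in acceptor_residues and i not in mods
                        ),
                    ))
        cands.sort(key=lambda c: c.mass)
        self.candidates = cands
        self.masses = np.array([c.mass for c in cands])

    def within_ppm(self, mass: float, tol_ppm: float) -> list[_Candidate]:
        tol = mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, mass - tol, side="left")
        hi = np.searchsorted(self.masses, mass + tol, side="right")
        return self.candidates[lo:hi]

    def within_window(self, lo_mass: float, hi_mass: float) -> list[_Candidate]:
        lo = np.searchsorted(self.masses, lo_mass, side="left")
        hi = np.searchsorted(self.masses, hi_mass, side="right")
        return self.candidates[lo:hi]


# ---------------------------------------------------------------------------
# target-decoy FDR


def estimate_fdr(scores, is_decoy) -> np.ndarray:
    """q-values from target-decoy competition.

    At score threshold s the FDR estimate is #decoys≥s / #targets≥s; the
    q-value of a match is the minimum estimate over all thresholds at or
    below its score, capped at 1.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.size == 0:
        return np.array([])
    if (~is_decoy).sum() == 0:
        raise ValueError("no target matches")
    order = np.argsort(-scores, kind="stable")
    dec_sorted = is_decoy[order]
    cum_dec = np.cumsum(dec_sorted)
    cum_tgt = np.cumsum(~dec_sorted)
    # counts at thresholds equal to each distinct score: take the last index
    # of every tied block so ties share counts
    sorted_scores = scores[order]
    fdr = np.empty_like(sorted_scores)
    i = 0
    n = len(sorted_scores)
    while i < n:
        j = i
        while j + 1 < n and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        d, t = cum_dec[j], cum_tgt[j]
        fdr[i:j + 1] = min(1.0, d / t) if t else 1.0
        i = j + 1
    # q = min FDR over lower-or-equal thresholds (i.e. from the bottom up)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# linear search


def _heavy_adjust(spectrum: SpectrumRecord) -> float:
    return label_18O_shift(1) if spectrum.label_state == "heavy" else 0.0


def _as_heavy(p: Peptidoform) -> Peptidoform:
    return Peptidoform(p.residues, p.site_mods, c_term_heavy_o=2)


def search_linear(
    spectra: list[SpectrumRecord],
    proteins: list[ProteinRecord],
    params: SearchParams = SearchParams(),
    site_specific_mods: list[SiteSpecificCrosslinkMod] | None = None,
    specimen_of_run: dict[str, str] | None = None,
    group_of_specimen: dict[str, str] | None = None,
    keep_decoys: bool = False,
    index: PeptideIndex | None = None,
) -> list[PsmRecord]:
    """Bottom-up search: best candidate per spectrum, q-values, FDR filter.

    Heavy-labelled spectra are matched against candidates carrying the fixed
    double-¹⁸O C-terminal modification (+4.00849 Da per peptide).
    """
    if index is None:
        index = PeptideIndex(
            proteins, params, site_specific_mods=site_specific_mods
        )
    best: list[tuple[SpectrumRecord, _Candidate, ScoredMatch, float]] = []
    for s in spectra:
        neutral = mass_from_mz(s.precursor_mz, s.precursor_z)
        shift = _heavy_adjust(s)
        hits = index.within_ppm(neutral - shift, params.precursor_tol_ppm)
        top = None
        for cand in hits:
            pf = cand.peptidoform if not shift else _as_heavy(cand.peptidoform)
            mzs = [mz for _, mz in theoretical_fragments(
                pf, params.fragment_charges
            )]
            sm = score_match(s, mzs, params.fragment_tol_ppm)
            if sm.matched_ion_count < params.min_matched_ions:
                continue
            if top is None or sm.score > top[1].score:
                ppm = (neutral - shift - cand.mass) / cand.mass * 1e6
                top = (cand, sm, ppm)
        if top is not None:
            best.append((s, top[0], top[1], top[2]))
    if not best:
        return []
    q = estimate_fdr(
        [sm.score for _, _, sm, _ in best],
        [c.is_decoy for _, c, _, _ in best],
    )
    out = []
    for (s, cand, sm, ppm), qv in zip(best, q):
        if qv > params.fdr_threshold:
            continue
        if cand.is_decoy and not keep_decoys:
            continue
        pf = cand.peptidoform
        if s.label_state == "heavy":
            pf = _as_heavy(pf)
        specimen = (specimen_of_run or {}).get(s.run_id, s.run_id)
        out.append(PsmRecord(
            spectrum_id=s.spectrum_id,
            peptidoform=pf,
            accession=cand.accession,
            start=cand.start,
            score=sm.score,
            q_value=float(qv),
            mass_error_ppm=ppm,
            intensity=s.precursor_intensity,
            specimen_id=specimen,
            group=(group_of_specimen or {}).get(specimen, ""),
            is_decoy=cand.is_decoy,
        ))
    return out


# ---------------------------------------------------------------------------
# delta-mass (open modification) discovery


@dataclass(frozen=True)
class DiscoveredMod:
    """A localized candidate modification explaining a precursor delta."""

    accession: str
    position: int  # 1-based protein coordinate
    mod: ModificationDef
    peptide: str
    peptide_position: int
    spectrum_id: str
    score: float
    ambiguous: bool


def discover_delta_mods(
    spectra: list[SpectrumRecord],
    proteins: list[ProteinRecord],
    candidate_mods: list[ModificationDef],
    params: SearchParams = SearchParams(),
    index: PeptideIndex | None = None,
) -> list[DiscoveredMod]:
    """Explain unidentified precursor deltas with candidate modifications.

    For each spectrum, each candidate modification whose delta closes the
    gap between the precursor mass and an unmodified digest peptide is
    placed on every eligible residue of that peptide; the placement with the
    best fragment score wins (ties → lowest position, flagged ambiguous).
    """
    if index is None:
        index = PeptideIndex(proteins, params, with_decoys=False)
    out = []
    for s in spectra:
        neutral = mass_from_mz(s.precursor_mz, s.precursor_z) - _heavy_adjust(s)
        best: DiscoveredMod | None = None
        for mod in candidate_mods:
            target_mass = neutral - mod.delta_mass
            if target_mass <= 0:
                continue
            for cand in index.within_ppm(target_mass, params.precursor_tol_ppm):
                pep = cand.peptidoform.residues
                placements = [
                    i for i, r in enumerate(pep, start=1) if r in mod.targets
                ]
                scored = []
                for pos in placements:
                    pf = Peptidoform(
                        pep, {pos: mod},
                        c_term_heavy_o=2 if s.label_state == "heavy" else 0,
                    )
                    mzs = [mz for _, mz in theoretical_fragments(
                        pf, params.fragment_charges
                    )]
                    sm = score_match(s, mzs, params.fragment_tol_ppm)
                    scored.append((sm.score, pos))
                if not scored:
                    continue
                top_score = max(sc for sc, _ in scored)
                winners = [pos for sc, pos in scored if sc == top_score]
                pos = min(winners)
                entry = DiscoveredMod(
                    accession=cand.accession,
                    position=cand.start + pos - 1,
                    mod=mod,
                    peptide=pep,
                    peptide_position=pos,
                    spectrum_id=s.spectrum_id,
                    score=top_score,
                    ambiguous=len(winners) > 1,
                )
                if (
                    top_score >= params.min_matched_ions
                    and (best is None or top_score > best.score)
                ):
                    best = entry
        if best is not None:
            out.append(best)
    return out


# ---------------------------------------------------------------------------
# crosslink search


def search_crosslinks(
    spectra: list[SpectrumRecord],
    proteins: list[ProteinRecord],
    crosslinker: ModificationDef,
    donor_residues: tuple[str, ...] = ("S", "T"),
    acceptor_residues: tuple[str, ...] = ("C", "K", "H"),
    params: SearchParams = SearchParams(),
    keep_decoys: bool = False,
) -> list[CsmRecord]:
    """DHAA crosslink search over a targeted protein database.

    Enumerates (alpha, beta) digest-peptide pairs whose summed mass plus the
    crosslinker delta matches the precursor within tolerance, requiring a
    donor residue (S/T for the water-loss chemistry, C for the H₂S-loss
    chemistry) on alpha and a nucleophilic acceptor (C/K/H) on beta.  Both
    chains' crosslink-containing fragments are scored jointly; linked sites
    are localized to the best-scoring placement.  Heavy-water runs add the
    fixed double-¹⁸O C-terminal label to every peptide, so a crosslinked
    pair shifts by ~8 Da relative to the light search.
    """
    return search_crosslinks_multi(
        spectra, proteins, [(crosslinker, donor_residues)],
        acceptor_residues=acceptor_residues, params=params,
        keep_decoys=keep_decoys,
    )


def search_crosslinks_multi(
    spectra: list[SpectrumRecord],
    proteins: list[ProteinRecord],
    chemistries: list[tuple[ModificationDef, tuple[str, ...]]],
    acceptor_residues: tuple[str, ...] = ("C", "K", "H"),
    params: SearchParams = SearchParams(),
    keep_decoys: bool = False,
) -> list[CsmRecord]:
    """Crosslink search across several donor chemistries at once.

    Each spectrum competes over the union of the chemistry-specific
    candidate spaces (target and decoy), and q-values are estimated once on
    the pooled best-per-spectrum matches.  Spectrum-level competition
    matters: a spectrum whose true explanation lives in another chemistry's
    space would otherwise only have decoys to match, inflating that
    search's FDR estimate.
    """
    donor_union = tuple(sorted({r for _, ds in chemistries for r in ds}))
    index = PeptideIndex(
        proteins, params,
        donor_residues=donor_union,
        acceptor_residues=acceptor_residues,
    )
    best_rows = []
    for s in spectra:
        shift = _heavy_adjust(s)  # per C-terminus; two termini in a pair
        neutral = mass_from_mz(s.precursor_mz, s.precursor_z)
        tol = neutral * params.precursor_tol_ppm * 1e-6
        top = None
        for crosslinker, donor_residues in chemistries:
            pair_mass = neutral - 2 * shift - crosslinker.delta_mass
            for a in index.candidates:
                dpos = tuple(
                    p for p in a.donor_positions
                    if a.peptidoform.residues[p - 1] in donor_residues
                )
                if not dpos:
                    continue
                partner_lo = pair_mass - a.mass - tol
                partner_hi = pair_mass - a.mass + tol
                for b in index.within_window(partner_lo, partner_hi):
                    if not b.acceptor_positions:
                        continue
                    sm, dsite, asite = _score_crosslink(
                        s, a, b, crosslinker.delta_mass, shift, params,
                        donor_positions=dpos,
                    )
                    if sm.matched_ion_count < params.min_matched_ions:
                        continue
                    if top is None or sm.score > top[0].score:
                        theo = (
                            a.mass + b.mass + crosslinker.delta_mass
                            + 2 * shift
                        )
                        ppm = (neutral - theo) / theo * 1e6
                        top = (sm, a, b, dsite, asite, ppm, crosslinker)
        if top is not None:
            best_rows.append((s, *top))
    if not best_rows:
        return []
    q = estimate_fdr(
        [row[1].score for row in best_rows],
        [row[2].is_decoy or row[3].is_decoy for row in best_rows],
    )
    out = []
    for (s, sm, a, b, dsite, asite, ppm, crosslinker), qv in zip(
        best_rows, q
    ):
        is_decoy = a.is_decoy or b.is_decoy
        if qv > params.fdr_threshold:
            continue
        if is_decoy and not keep_decoys:
            continue
        alpha_pf = a.peptidoform
        beta_pf = b.peptidoform
        if s.label_state == "heavy":
            alpha_pf, beta_pf = _as_heavy(alpha_pf), _as_heavy(beta_pf)
        out.append(CsmRecord(
            spectrum_id=s.spectrum_id,
            run_id=s.run_id,
            label_state=s.label_state,
            alpha_peptidoform=alpha_pf,
            alpha_accession=a.accession,
            alpha_site=a.start + dsite - 1,
            beta_peptidoform=beta_pf,
            beta_accession=b.accession,
            beta_site=b.start + asite - 1,
            crosslinker_name=crosslinker.name,
            precursor_mass=mass_from_mz(s.precursor_mz, s.precursor_z),
            score=sm.score,
            q_value=float(qv),
            mass_error_ppm=ppm,
            rt=s.rt,
            is_decoy=is_decoy,
        ))
    return out


def _score_crosslink(
    s: SpectrumRecord,
    a: _Candidate,
    b: _Candidate,
    delta: float,
    label_shift: float,
    params: SearchParams,
    donor_positions: tuple[int, ...] | None = None,
) -> tuple[ScoredMatch, int, int]:
    """Best site placement and joint score for one candidate pair."""
    heavy = label_shift > 0
    alpha = _as_heavy(a.peptidoform) if heavy else a.peptidoform
    beta = _as_heavy(b.peptidoform) if heavy else b.peptidoform

    def chain_best(own, partner, sites):
        best_site, best_score = sites[0], -1.0
        for site in sites:
            frags = generate_crosslink_fragments(
                own, partner, site, 1, delta, params.fragment_charges
            )
            mzs = [mz for ch, _, mz, _ in frags if ch == "A"]
            sc = score_match(s, mzs, params.fragment_tol_ppm).score
            if sc > best_score:
                best_site, best_score = site, sc
        return best_site

    dsite = chain_best(alpha, beta, list(donor_positions or a.donor_positions))
    asite = chain_best(beta, alpha, list(b.acceptor_positions))
    frags = generate_crosslink_fragments(
        alpha, beta, dsite, asite, delta, params.fragment_charges
    )
    joint = score_match(
        s, [mz for _, _, mz, _ in frags], params.fragment_tol_ppm
    )
    return joint, dsite, asite
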