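"""Readers and writers for the pipeline's file formats.

FASTA and MGF go through pyteomics; the identification tables (PSMs, CSMs,
eliminylation sites) are plain TSV with a fixed column order so that results
round-trip losslessly and diff cleanly.  MS1 isotope-peak blocks ride inside
MGF user headers (``MS1PEAKS=``) so a simulated run stays a single file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import mgf as _mgf

from .chem import ModificationDef, Peptidoform

logger = logging.getLogger("dhaaxl")

__all__ = [
    "ProteinRecord",
    "SpectrumRecord",
    "PsmRecord",
    "CsmRecord",
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "map_to_protein",
    "classify_link",
    "write_psms",
    "read_psms",
    "write_csms",
    "read_csms",
]


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.accession}: sequence must be uppercase")


@dataclass
class SpectrumRecord:
    """One centroided MS2 scan plus its MS1 context."""

    spectrum_id: str
    run_id: str
    label_state: str  # light | heavy
    precursor_mz: float
    precursor_z: int
    rt: float  # minutes
    fragments: list[tuple[float, float]] = field(default_factory=list)
    ms1_peaks: list[tuple[float, float]] = field(default_factory=list)
    precursor_intensity: float = 0.0

    def __post_init__(self):
        if self.precursor_z < 1:
            raise ValueError("precursor charge must be >= 1")
        if self.rt < 0:
            raise ValueError("negative retention time")
        for name in ("fragments", "ms1_peaks"):
            peaks = getattr(self, name)
            if any(b[0] < a[0] for a, b in zip(peaks, peaks[1:])):
                logger.warning(
                    "%s: unsorted %s auto-sorted", self.spectrum_id, name
                )
                setattr(self, name, sorted(peaks))


@dataclass
class PsmRecord:
    """A scored linear peptide–spectrum match mapped to protein coordinates."""

    spectrum_id: str
    peptidoform: Peptidoform
    accession: str
    start: int  # 1-based protein position of the peptide N-terminus
    score: float
    q_value: float
    mass_error_ppm: float
    intensity: float = 0.0
    specimen_id: str = ""
    group: str = ""  # AD | CTR | ""
    is_decoy: bool = False

    def __post_init__(self):
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q_value outside [0, 1]")


@dataclass
class CsmRecord:
    """A crosslink–spectrum match: two chains with protein-coordinate sites."""

    spectrum_id: str
    run_id: str
    label_state: str
    alpha_peptidoform: Peptidoform
    alpha_accession: str
    alpha_site: int  # 1-based protein coordinate of the donor residue
    beta_peptidoform: Peptidoform
    beta_accession: str
    beta_site: int  # protein coordinate of the acceptor residue
    crosslinker_name: str
    precursor_mass: float
    score: float
    q_value: float
    mass_error_ppm: float
    rt: float
    is_decoy: bool = False

    def __post_init__(self):
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q_value outside [0, 1]")

    @property
    def link_class(self) -> str:
        return classify_link(self)

    def pair_key(self) -> tuple:
        """Identity of the crosslinked pair irrespective of label state."""
        a = (self.alpha_accession, self.alpha_site, self.alpha_peptidoform.residues)
        b = (self.beta_accession, self.beta_site, self.beta_peptidoform.residues)
        return tuple(sorted([a, b])) + (self.crosslinker_name,)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA database; accessions must be unique."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _fasta.read(str(path)) as fh:
        for description, sequence in fh:
            acc = description.split()[0]
            if acc in seen:
                raise ValueError(f"duplicate accession {acc!r}")
            seen.add(acc)
            desc = description[len(acc):].strip()
            records.append(ProteinRecord(acc, desc, sequence.upper()))
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    entries = [
        (f"{r.accession} {r.description}".strip(), r.sequence) for r in records
    ]
    _fasta.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# MGF


def _encode_peaks(peaks: list[tuple[float, float]]) -> str:
    return ";".join(f"{mz:.6f}:{inten:.6g}" for mz, inten in peaks)


def _decode_peaks(text: str) -> list[tuple[float, float]]:
    if not text:
        return []
    out = []
    for tok in text.split(";"):
        mz, inten = tok.split(":")
        out.append((float(mz), float(inten)))
    return out


def write_mgf(spectra: list[SpectrumRecord], path) -> None:
    """Write spectra as MGF, carrying run/label/MS1 data in user headers."""
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": [mz for mz, _ in s.fragments],
            "intensity array": [i for _, i in s.fragments],
            "params": {
                "title": s.spectrum_id,
                "pepmass": (s.precursor_mz, s.precursor_intensity),
                "charge": s.precursor_z,
                "rtinseconds": s.rt * 60.0,
                "run_id": s.run_id,
                "label_state": s.label_state,
                "ms1peaks": _encode_peaks(s.ms1_peaks),
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[SpectrumRecord]:
    spectra = []
    with _mgf.read(str(path), convert_arrays=1, use_index=False) as fh:
        for entry in fh:
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError("MGF block without PEPMASS")
            pepmass = params["pepmass"]
            charge = params.get("charge")
            z = int(charge[0]) if charge else 1
            frags = list(zip(
                entry["m/z array"].tolist(), entry["intensity array"].tolist()
            ))
            spectra.append(SpectrumRecord(
                spectrum_id=str(params.get("title", "")),
                run_id=str(params.get("run_id", "")),
                label_state=str(params.get("label_state", "light")),
                precursor_mz=float(pepmass[0]),
                precursor_intensity=float(pepmass[1] or 0.0),
                precursor_z=z,
                rt=float(params.get("rtinseconds", 0.0)) / 60.0,
                fragments=frags,
                ms1_peaks=_decode_peaks(str(params.get("ms1peaks", ""))),
            ))
    return spectra


# ---------------------------------------------------------------------------
# coordinate mapping and link classification


def map_to_protein(
    peptidoform: Peptidoform, protein: ProteinRecord
) -> list[tuple[int, dict[int, int]]]:
    """All occurrences of a peptide in a protein, with site coordinates.

    Returns ``(start, {peptide_pos: protein_pos})`` per occurrence, 1-based;
    empty list when the peptide does not occur.
    """
    seq, pep = protein.sequence, peptidoform.residues
    out = []
    idx = seq.find(pep)
    while idx != -1:
        start = idx + 1
        sites = {pos: start + pos - 1 for pos in peptidoform.site_mods}
        out.append((start, sites))
        idx = seq.find(pep, idx + 1)
    return out


def classify_link(csm: CsmRecord) -> str:
    """'intra' iff both chains map to the same accession, else 'inter'.

    Same-accession links may be intra- or intermolecular between protein
    copies; by convention they are labelled intra.
    """
    return "intra" if csm.alpha_accession == csm.beta_accession else "inter"


# ---------------------------------------------------------------------------
# TSV tables

PSM_COLUMNS = [
    "spectrum_id", "peptide", "mods", "c_term_heavy_o", "accession", "start",
    "score", "q_value", "mass_error_ppm", "intensity", "specimen_id",
    "group", "is_decoy",
]

CSM_COLUMNS = [
    "spectrum_id", "run_id", "label_state",
    "alpha_peptide", "alpha_mods", "alpha_heavy_o", "alpha_accession",
    "alpha_site",
    "beta_peptide", "beta_mods", "beta_heavy_o", "beta_accession",
    "beta_site",
    "crosslinker", "precursor_mass", "score", "q_value", "mass_error_ppm",
    "rt", "link_class", "is_decoy",
]


def _mods_str(p: Peptidoform) -> str:
    return ",".join(
        f"{pos}:{mod.name}" for pos, mod in sorted(p.site_mods.items())
    )


def _parse_mods(text: str, mod_db: dict[str, ModificationDef]):
    if not text or pd.isna(text):
        return {}
    out = {}
    for tok in str(text).split(","):
        pos, name = tok.split(":")
        out[int(pos)] = mod_db[name]
    return out


def _peptidoform(seq, mods_text, heavy_o, mod_db) -> Peptidoform:
    return Peptidoform(
        residues=seq,
        site_mods=_parse_mods(mods_text, mod_db),
        c_term_heavy_o=int(heavy_o),
    )


def write_psms(psms: list[PsmRecord], path) -> None:
    rows = [{
        "spectrum_id": p.spectrum_id,
        "peptide": p.peptidoform.residues,
        "mods": _mods_str(p.peptidoform),
        "c_term_heavy_o": p.peptidoform.c_term_heavy_o,
        "accession": p.accession,
        "start": p.start,
        "score": p.score,
        "q_value": p.q_value,
        "mass_error_ppm": p.mass_error_ppm,
        "intensity": p.intensity,
        "specimen_id": p.specimen_id,
        "group": p.group,
        "is_decoy": p.is_decoy,
    } for p in psms]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psms(path, mod_db: dict[str, ModificationDef]) -> list[PsmRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(PsmRecord(
            spectrum_id=str(row.spectrum_id),
            peptidoform=_peptidoform(
                row.peptide, row.mods, row.c_term_heavy_o, mod_db
            ),
            accession=str(row.accession),
            start=int(row.start),
            score=float(row.score),
            q_value=float(row.q_value),
            mass_error_ppm=float(row.mass_error_ppm),
            intensity=float(row.intensity),
            specimen_id=str(row.specimen_id),
            group=str(row.group),
            is_decoy=str(row.is_decoy) == "True",
        ))
    return out


def write_csms(csms: list[CsmRecord], path) -> None:
    rows = [{
        "spectrum_id": c.spectrum_id,
        "run_id": c.run_id,
        "label_state": c.label_state,
        "alpha_peptide": c.alpha_peptidoform.residues,
        "alpha_mods": _mods_str(c.alpha_peptidoform),
        "alpha_heavy_o": c.alpha_peptidoform.c_term_heavy_o,
        "alpha_accession": c.alpha_accession,
        "alpha_site": c.alpha_site,
        "beta_peptide": c.beta_peptidoform.residues,
        "beta_mods": _mods_str(c.beta_peptidoform),
        "beta_heavy_o": c.beta_peptidoform.c_term_heavy_o,
        "beta_accession": c.beta_accession,
        "beta_site": c.beta_site,
        "crosslinker": c.crosslinker_name,
        "precursor_mass": c.precursor_mass,
        "score": c.score,
        "q_value": c.q_value,
        "mass_error_ppm": c.mass_error_ppm,
        "rt": c.rt,
        "link_class": c.link_class,
        "is_decoy": c.is_decoy,
    } for c in csms]
    pd.DataFrame(rows, columns=CSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_csms(path, mod_db: dict[str, ModificationDef]) -> list[CsmRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(CsmRecord(
            spectrum_id=str(row.spectrum_id),
            run_id=str(row.run_id),
            label_state=str(row.label_state),
            alpha_peptidoform=_peptidoform(
                row.alpha_peptide, row.alpha_mods, row.alpha_heavy_o, mod_db
            ),
            alpha_accession=str(row.alpha_accession),
            alpha_site=int(row.alpha_site),
            beta_peptidoform=_peptidoform(
                row.beta_peptide, row.beta_mods, row.beta_heavy_o, mod_db
            ),
            beta_accession=str(row.beta_accession),
            beta_site=int(row.beta_site),
            crosslinker_name=str(row.crosslinker),
            precursor_mass=float(row.precursor_mass),
            score=float(row.score),
            q_value=float(row.q_value),
            mass_error_ppm=float(row.mass_error_ppm),
            rt=float(row.rt),
            is_decoy=str(row.is_decoy) == "True",
        ))
    return out
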