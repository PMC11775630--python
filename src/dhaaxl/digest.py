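"""In-silico tryptic digestion and crosslink search planning.

Covers the candidate-generation side of the pipeline: digesting protein
databases, assembling the targeted databases a crosslink search needs to
keep its search space manageable, enumerating the donor-chemistry ×
acceptor-residue × dataset × database search grid, and appending accepted
crosslinks back onto a modification database as site-specific custom
modifications for full-proteome re-searching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import parser as _parser

from .chem import (
    ElementalComposition,
    ModificationDef,
    Peptidoform,
    WATER,
    label_18O_shift,
)
from .io import ProteinRecord

__all__ = [
    "DigestParams",
    "SearchPlan",
    "SearchJob",
    "tryptic_digest",
    "build_targeted_database",
    "plan_crosslink_searches",
    "append_crosslinks_to_database",
]

# trypsin cleaves after K/R; the no-proline rule suppresses cleavage before P
_TRYPSIN_P = r"(?<=[KR])"
_TRYPSIN = r"(?<=[KR])(?!P)"


@dataclass(frozen=True)
class DigestParams:
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 40
    cleave_before_proline: bool = False

    def __post_init__(self):
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.max_missed_cleavages < 0:
            raise ValueError("negative missed cleavages")


def tryptic_digest(
    protein: ProteinRecord, params: DigestParams = DigestParams()
) -> list[tuple[str, int]]:
    """Tryptic peptides of a protein as (sequence, 1-based start) pairs.

    Cleaves after K/R (suppressed before P unless requested), includes all
    missed-cleavage products up to the configured maximum, and applies the
    length filter.  Zero-missed peptides tile the protein exactly.
    """
    rule = _TRYPSIN_P if params.cleave_before_proline else _TRYPSIN
    seen = set()
    for start, pep in _parser.icleave(
        protein.sequence, rule,
        missed_cleavages=params.max_missed_cleavages,
        min_length=params.min_length,
        max_length=params.max_length,
    ):
        seen.add((pep, start + 1))
    return sorted(seen, key=lambda t: (t[1], len(t[0])))


@dataclass(frozen=True)
class SearchJob:
    donor_chemistry: str  # S | T | C (DHAA precursor residue)
    acceptor: str  # C | K | H
    dataset_id: str
    database_id: str


@dataclass(frozen=True)
class SearchPlan:
    jobs: tuple[SearchJob, ...]

    def __len__(self) -> int:
        return len(self.jobs)


def plan_crosslink_searches(
    donor_chemistries: tuple[str, ...] = ("S", "T", "C"),
    acceptors: tuple[str, ...] = ("C", "K", "H"),
    dataset_ids: tuple[str, ...] = (),
    database_ids: tuple[str, ...] = (),
) -> SearchPlan:
    """Full factorial crosslink search grid.

    Three potential DHAA precursors against three nucleophilic acceptors
    gives nine chemistry combinations per (dataset, database) pair; with 16
    datasets and 3 databases that is the study-scale 9 × 16 × 3 = 432 jobs.
    """
    for name, ids in (
        ("donor_chemistries", donor_chemistries), ("acceptors", acceptors),
        ("dataset_ids", dataset_ids), ("database_ids", database_ids),
    ):
        if not ids:
            raise ValueError(f"{name} is empty")
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate entries in {name}")
    jobs = tuple(
        SearchJob(d, a, ds, db)
        for ds in dataset_ids
        for db in database_ids
        for d in donor_chemistries
        for a in acceptors
    )
    return SearchPlan(jobs=jobs)


def load_aggregation_panel(path=None) -> list[str]:
    """Identifiers of the shipped curated aggregation-prone protein panel.

    The default file lists proteins reported to aggregate in
    neurodegenerative disease; it is editable configuration, not ground
    truth.
    """
    if path is None:
        from importlib import resources

        path = resources.files("dhaaxl").joinpath(
            "data/aggregation_panel.txt"
        )
    lines = Path(str(path)).read_text().splitlines()
    return [
        ln.strip() for ln in lines
        if ln.strip() and not ln.startswith("#")
    ]


def build_targeted_database(
    mode: str,
    *,
    curated: list[ProteinRecord] | None = None,
    site_accessions: list[str] | None = None,
    abundance_ranking: dict[str, float] | None = None,
    proteins_by_accession: dict[str, ProteinRecord] | None = None,
    n: int = 500,
) -> list[ProteinRecord]:
    """Assemble a targeted protein database for crosslink searching.

    Modes:

    - ``aggregation_panel``: a curated list (e.g. proteins known to
      aggregate in neurodegeneration) passed through verbatim, deduplicated.
    - ``dhaa_containing``: the distinct accessions carrying DHAA or
      conjugate evidence in earlier search results.
    - ``top_abundant``: the n most abundant proteins of a specimen by LFQ
      intensity, ties broken by accession.
    """
    if mode == "aggregation_panel":
        if curated is None:
            raise ValueError("aggregation_panel requires curated records")
        seen, out = set(), []
        for r in curated:
            if r.accession not in seen:
                seen.add(r.accession)
                out.append(r)
        return out
    if proteins_by_accession is None:
        raise ValueError(f"{mode} requires proteins_by_accession")
    if mode == "dhaa_containing":
        if not site_accessions:
            raise ValueError("dhaa_containing requires site accessions")
        accs = sorted(set(site_accessions))
        return [proteins_by_accession[a] for a in accs
                if a in proteins_by_accession]
    if mode == "top_abundant":
        if not abundance_ranking:
            raise ValueError("top_abundant requires an abundance ranking")
        ranked = sorted(
            abundance_ranking.items(), key=lambda kv: (-kv[1], kv[0])
        )
        out = []
        for acc, _ in ranked:
            if acc in proteins_by_accession:
                out.append(proteins_by_accession[acc])
            if len(out) == n:
                break
        return out
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class SiteSpecificCrosslinkMod:
    """A crosslink re-expressed as a custom modification at its donor site.

    For full-proteome validation a crosslink alpha-peptide behaves like a
    linear peptide carrying, at the donor residue, the whole mass of the
    partner peptide plus the crosslinker delta.
    """

    accession: str
    position: int  # 1-based protein coordinate
    mod: ModificationDef


def append_crosslinks_to_database(
    mod_db: dict[str, ModificationDef],
    accepted_crosslinks,
    label_state: str = "light",
) -> tuple[dict[str, ModificationDef], list[SiteSpecificCrosslinkMod]]:
    """Augment a modification database with accepted crosslinks.

    Each crosslink contributes one site-specific modification per chain whose
    delta is the partner peptide's mass plus the crosslinker delta.  In heavy
    mode the partner's C-terminus carries the double-¹⁸O label, adding
    +4.00849 Da relative to the light custom modification.
    """
    out_db = dict(mod_db)
    site_mods: list[SiteSpecificCrosslinkMod] = []
    heavy_extra = label_18O_shift(1) if label_state == "heavy" else 0.0
    for csm in accepted_crosslinks:
        halves = [
            (csm.alpha_accession, csm.alpha_site, csm.alpha_peptidoform,
             csm.beta_peptidoform),
            (csm.beta_accession, csm.beta_site, csm.beta_peptidoform,
             csm.alpha_peptidoform),
        ]
        xl_delta = _crosslinker_delta(csm, mod_db)
        for acc, pos, own, partner in halves:
            if pos < 1:
                raise ValueError("crosslink without resolved protein site")
            partner_light = Peptidoform(
                residues=partner.residues,
                site_mods={
                    p: m for p, m in partner.site_mods.items()
                    if m.mod_class != "label"
                },
                c_term_heavy_o=0,
            )
            delta = partner_light.mass + xl_delta + heavy_extra
            name = (
                f"XLmod-{acc}-{pos}-{partner.residues}-{label_state}"
            )
            mod = ModificationDef(
                name=name,
                mod_class="conjugate",
                targets=frozenset("STCKH"),
                delta_mass=delta,
            )
            out_db[name] = mod
            site_mods.append(SiteSpecificCrosslinkMod(acc, pos, mod))
    return out_db, site_mods


def _crosslinker_delta(csm, mod_db: dict[str, ModificationDef]) -> float:
    mod = mod_db.get(csm.crosslinker_name)
    if mod is None:
        raise ValueError(f"unknown crosslinker {csm.crosslinker_name!r}")
    return mod.delta_mass
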