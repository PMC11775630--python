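"""Heavy/light crosslink validation: the three-criterion acceptance rule.

A candidate crosslink is accepted only when

1. the same crosslinked pair is found in both the standard (light) and the
   heavy-water (¹⁸O) preparation, with the heavy precursor exactly one
   crosslinked-pair label shift (~8.017 Da, two labelled C-termini) above
   the light one, within a retention-time window — a linear peptide can
   only shift ~4 Da, so the +8 signature is specific to crosslinks;
2. the observed MS1 isotope envelope matches the theoretical isotope
   distribution of the crosslinked species (mass within tolerance and
   normalized-dot-product similarity above threshold); and
3. both label forms survive a full-proteome search at 1% FDR after the
   crosslink is appended to the database as a site-specific modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import IsotopePattern, label_18O_shift
from .io import CsmRecord

__all__ = [
    "PairingParams",
    "CrosslinkEvidence",
    "pair_heavy_light",
    "isotope_similarity",
    "accept_crosslink",
]

#: mass difference between heavy and light forms of a crosslinked pair
PAIR_LABEL_SHIFT: float = label_18O_shift(2)


@dataclass(frozen=True)
class PairingParams:
    rt_window: float = 5.0  # minutes
    mass_tol_ppm: float = 10.0
    isotope_similarity_min: float = 0.95
    full_proteome_q_max: float = 0.01

    def __post_init__(self):
        for name in ("rt_window", "mass_tol_ppm", "isotope_similarity_min",
                     "full_proteome_q_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CrosslinkEvidence:
    """Assembled evidence for one candidate crosslink."""

    light: CsmRecord
    heavy: CsmRecord | None = None
    ms1_similarity: float = 0.0
    ms1_mass_error_ppm: float = float("inf")
    full_proteome_q_light: float = 1.0
    full_proteome_q_heavy: float = 1.0
    accepted: bool = False
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def link_class(self) -> str:
        return self.light.link_class


def pair_heavy_light(
    csms_light: list[CsmRecord],
    csms_heavy: list[CsmRecord],
    params: PairingParams = PairingParams(),
) -> list[CrosslinkEvidence]:
    """Match light CSMs to their ¹⁸O-shifted heavy counterparts.

    A pair requires the identical peptide pair and linked sites, a
    heavy−light neutral mass difference of one crosslinked-pair label shift
    within tolerance, and retention times within the window.  Every light
    CSM yields one evidence record (heavy slot empty when unpaired).
    """
    heavy_by_key: dict[tuple, list[CsmRecord]] = {}
    for h in csms_heavy:
        heavy_by_key.setdefault(h.pair_key(), []).append(h)
    out = []
    for l in csms_light:
        match = None
        for h in heavy_by_key.get(l.pair_key(), []):
            dmass = h.precursor_mass - l.precursor_mass
            ppm = abs(dmass - PAIR_LABEL_SHIFT) / l.precursor_mass * 1e6
            if ppm > params.mass_tol_ppm:
                continue
            if abs(h.rt - l.rt) > params.rt_window:
                continue
            if match is None or abs(h.rt - l.rt) < abs(match.rt - l.rt):
                match = h
        out.append(CrosslinkEvidence(light=l, heavy=match))
    return out


def isotope_similarity(
    observed_peaks: list[tuple[float, float]],
    theory: IsotopePattern,
    mass_tol_ppm: float = 10.0,
) -> float:
    """Normalized dot product between observed and theoretical envelopes.

    Observed peaks are aligned to theoretical peaks within a ppm tolerance;
    theoretical peaks without an observed counterpart contribute zero, so a
    truncated or shifted envelope scores low.
    """
    if not theory.peaks:
        raise ValueError("empty theoretical pattern")
    if not observed_peaks:
        return 0.0
    obs_mz = np.array([m for m, _ in observed_peaks])
    obs_int = np.array([i for _, i in observed_peaks])
    aligned = np.zeros(len(theory.peaks))
    for k, (tmz, _) in enumerate(theory.peaks):
        tol = tmz * mass_tol_ppm * 1e-6
        d = np.abs(obs_mz - tmz)
        j = int(np.argmin(d))
        if d[j] <= tol:
            aligned[k] = obs_int[j]
    theo_int = theory.intensities
    denom = np.linalg.norm(aligned) * np.linalg.norm(theo_int)
    if denom == 0:
        return 0.0
    return float(np.dot(aligned, theo_int) / denom)


def accept_crosslink(
    evidence: CrosslinkEvidence,
    params: PairingParams = PairingParams(),
) -> CrosslinkEvidence:
    """Apply the three-criterion rule; fills the per-criterion report.

    Criterion 1: a heavy partner with the +8 Da signature exists.
    Criterion 2: MS1 mass error within tolerance and isotope-envelope
    similarity at or above threshold.
    Criterion 3: both light and heavy forms at or below the full-proteome
    FDR threshold.
    """
    c1 = evidence.heavy is not None
    c2 = (
        abs(evidence.ms1_mass_error_ppm) <= params.mass_tol_ppm
        and evidence.ms1_similarity >= params.isotope_similarity_min
    )
    c3 = (
        evidence.full_proteome_q_light <= params.full_proteome_q_max
        and evidence.full_proteome_q_heavy <= params.full_proteome_q_max
    )
    evidence.criteria = {
        "heavy_light_pair": c1,
        "ms1_isotope_match": c2,
        "full_proteome_fdr": c3,
    }
    evidence.accepted = c1 and c2 and c3
    return evidence
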