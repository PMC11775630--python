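"""Eliminylation-site calling, prevalence, quantification and statistics.

A site is *confirmed* only when at least one conjugate species (GSH-, HC-,
DTT-, TCEP-modified DHAA or a DHAA crosslink) is observed there: the direct
−18/−34 Da loss can arise artifactually in the instrument, so direct-only
sites are retained but flagged unconfirmed.

Quantification follows the label-free convention: per-peptidoform precursor
intensities summed within a specimen (across fractions), specimens
median-normalized to a common scale.  Differential abundance between
disease (AD) and control groups uses a two-tailed t-test with a
permutation-based FDR, and site occupancy is the modified fraction of total
signal with its standard error across specimens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import PsmRecord
from .search import DiscoveredMod

logger = logging.getLogger("dhaaxl")

__all__ = [
    "EliminylationSite",
    "DifferentialResult",
    "CONJUGATE_FORMS",
    "call_sites",
    "prevalence_summary",
    "lfq_aggregate",
    "differential_abundance",
    "permutation_fdr",
    "occupancy",
    "association_fraction",
]

#: evidence forms that confirm a site (direct loss alone does not)
CONJUGATE_FORMS = frozenset({"GSH", "HC", "DTT", "TCEP", "XL"})

_FORM_OF_MOD = {
    "DHA": "direct", "DHB": "direct", "DHA-C": "direct",
    "GSH-DHAA": "GSH", "GSH-DHAA-C": "GSH",
    "HC-DHAA": "HC", "HC-DHAA-C": "HC",
    "DTT-DHAA": "DTT", "DTT-DHAA-C": "DTT",
    "TCEP-DHAA": "TCEP", "TCEP-DHAA-C": "TCEP",
}


@dataclass
class EliminylationSite:
    accession: str
    residue: str
    position: int
    evidence_forms: set[str] = field(default_factory=set)
    specimens_observed: set[str] = field(default_factory=set)

    @property
    def confirmed(self) -> bool:
        return bool(self.evidence_forms & CONJUGATE_FORMS)


@dataclass
class DifferentialResult:
    feature_id: str
    log2_fold_change: float
    t_statistic: float
    p_value: float
    q_permutation: float = float("nan")
    zero_variance: bool = False


def _form_of(mod_name: str) -> str | None:
    if mod_name in _FORM_OF_MOD:
        return _FORM_OF_MOD[mod_name]
    if mod_name.startswith("XLmod-") or mod_name.startswith("XL"):
        return "XL"
    return None


def call_sites(
    observations,
    residue_of_site: dict[tuple[str, int], str] | None = None,
) -> list[EliminylationSite]:
    """Aggregate evidence into one record per (accession, position).

    ``observations`` is an iterable of (accession, position, residue,
    evidence form, specimen id) tuples; helpers below build these from PSMs
    or discovery results.  Evidence forms: direct | GSH | HC | DTT | TCEP |
    XL.
    """
    sites: dict[tuple[str, int], EliminylationSite] = {}
    for acc, pos, residue, form, specimen in observations:
        key = (acc, pos)
        site = sites.get(key)
        if site is None:
            site = EliminylationSite(acc, residue, pos)
            sites[key] = site
        site.evidence_forms.add(form)
        if specimen:
            site.specimens_observed.add(specimen)
    return sorted(sites.values(), key=lambda s: (s.accession, s.position))


def site_observations_from_psms(psms: list[PsmRecord]):
    """(accession, position, residue, form, specimen) rows from PSMs."""
    for p in psms:
        for pep_pos, mod in p.peptidoform.site_mods.items():
            form = _form_of(mod.name)
            if form is None:
                continue
            yield (
                p.accession,
                p.start + pep_pos - 1,
                p.peptidoform.residues[pep_pos - 1],
                form,
                p.specimen_id,
            )


def site_observations_from_discoveries(
    discoveries: list[DiscoveredMod], specimen_of_spectrum=None
):
    for d in discoveries:
        form = _form_of(d.mod.name)
        if form is None:
            continue
        specimen = ""
        if specimen_of_spectrum:
            specimen = specimen_of_spectrum.get(d.spectrum_id, "")
        yield (
            d.accession, d.position, d.peptide[d.peptide_position - 1],
            form, specimen,
        )


SITE_COLUMNS = [
    "accession", "residue", "position", "evidence_forms", "n_specimens",
    "specimens", "confirmed",
]


def write_sites(sites: list[EliminylationSite], path) -> None:
    """Write the eliminylation-site table as TSV (fixed column order)."""
    rows = [{
        "accession": s.accession,
        "residue": s.residue,
        "position": s.position,
        "evidence_forms": ",".join(sorted(s.evidence_forms)),
        "n_specimens": len(s.specimens_observed),
        "specimens": ",".join(sorted(s.specimens_observed)),
        "confirmed": s.confirmed,
    } for s in sites]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_sites(path) -> list[EliminylationSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(EliminylationSite(
            accession=str(row.accession),
            residue=str(row.residue),
            position=int(row.position),
            evidence_forms=set(
                str(row.evidence_forms).split(",")
            ) if row.evidence_forms else set(),
            specimens_observed=set(
                str(row.specimens).split(",")
            ) if row.specimens else set(),
        ))
    return out


def prevalence_summary(
    sites: list[EliminylationSite],
    n_specimens: int,
    thresholds: tuple[float, ...] = (0.0, 0.5, 0.8, 1.0),
    confirmed_only: bool = True,
) -> pd.DataFrame:
    """Sites and distinct proteins observed in at least a fraction of specimens.

    A site qualifies at threshold θ iff it was observed in ≥ θ·n specimens
    (inclusive; θ=0 means any specimen).  Counts are non-increasing in θ.
    """
    if n_specimens == 0:
        raise ValueError("specimen universe is empty")
    rows = []
    pool = [s for s in sites if s.confirmed or not confirmed_only]
    for theta in thresholds:
        qualifying = [
            s for s in pool
            if len(s.specimens_observed) >= theta * n_specimens
            and (len(s.specimens_observed) > 0 if theta == 0 else True)
        ]
        rows.append({
            "threshold": theta,
            "n_sites": len(qualifying),
            "n_proteins": len({s.accession for s in qualifying}),
        })
    return pd.DataFrame(rows)


def lfq_aggregate(psms: list[PsmRecord], normalize: bool = True) -> pd.DataFrame:
    """Feature × specimen intensity matrix from PSM precursor intensities.

    Feature identity is the peptidoform (sequence + modifications + label
    state).  Intensities are summed per specimen across fractions/runs, then
    specimens are median-normalized to a common scale.  Missing stays NaN.
    """
    if not psms:
        return pd.DataFrame()
    rows = [{
        "feature": p.peptidoform.proforma(),
        "specimen": p.specimen_id,
        "intensity": p.intensity,
    } for p in psms]
    df = pd.DataFrame(rows)
    mat = df.pivot_table(
        index="feature", columns="specimen", values="intensity", aggfunc="sum"
    )
    if normalize and mat.shape[1] > 1:
        med = mat.median(axis=0, skipna=True)
        target = med.median()
        with np.errstate(invalid="ignore"):
            mat = mat * (target / med)
    return mat


def differential_abundance(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    paired: bool = False,
    min_per_group: int = 2,
) -> list[DifferentialResult]:
    """Per-feature fold change and t-test between AD and CTR specimens.

    log2FC is computed from group means on the intensity scale.  The default
    test is Welch's two-sample t-test; ``paired=True`` switches to a paired
    test and requires balanced groups in matching column order.  Features
    with fewer than ``min_per_group`` observed values in either group are
    skipped.  Zero-variance features get the limiting p (0 if means differ
    else 1) and a flag rather than an error.
    """
    ad_cols = [c for c in matrix.columns if groups.get(c) == "AD"]
    ctr_cols = [c for c in matrix.columns if groups.get(c) == "CTR"]
    if paired and len(ad_cols) != len(ctr_cols):
        raise ValueError("paired test requires balanced groups")
    out = []
    for feat, row in matrix.iterrows():
        a = row[ad_cols].dropna().to_numpy(dtype=float)
        c = row[ctr_cols].dropna().to_numpy(dtype=float)
        if len(a) < min_per_group or len(c) < min_per_group:
            logger.debug("%s skipped: insufficient observations", feat)
            continue
        mean_a, mean_c = a.mean(), c.mean()
        log2fc = np.log2(mean_a / mean_c) if mean_a > 0 and mean_c > 0 else (
            np.inf if mean_a > 0 else -np.inf
        )
        zero_var = a.var(ddof=1) == 0 and c.var(ddof=1) == 0
        if zero_var:
            t = 0.0 if mean_a == mean_c else np.inf * np.sign(mean_a - mean_c)
            p = 1.0 if mean_a == mean_c else 0.0
        elif paired:
            t, p = _st.ttest_rel(a, c)
        else:
            t, p = _st.ttest_ind(a, c, equal_var=False)
        out.append(DifferentialResult(
            feature_id=str(feat),
            log2_fold_change=float(log2fc),
            t_statistic=float(t),
            p_value=float(max(p, np.finfo(float).tiny)),
            zero_variance=zero_var,
        ))
    return out


def _t_stats(mat: np.ndarray, is_ad: np.ndarray) -> np.ndarray:
    """Vectorized Welch t statistics, NaN-aware, one row per feature."""
    a = np.where(is_ad, mat, np.nan)
    c = np.where(~is_ad, mat, np.nan)
    na = np.sum(~np.isnan(a), axis=1)
    nc = np.sum(~np.isnan(c), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(a, axis=1)
        mc = np.nanmean(c, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vc = np.nanvar(c, axis=1, ddof=1)
        se = np.sqrt(va / na + vc / nc)
        t = (ma - mc) / se
    return t


def permutation_fdr(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    observed: list[DifferentialResult],
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[DifferentialResult]:
    """Permutation-based FDR for the differential abundance results.

    Group labels are permuted unrestrictedly; for each observed |t|
    threshold, q = mean over permutations of the number of permuted |t|
    values at or above the threshold, divided by the observed count at or
    above it — monotonized so q never decreases as |t| decreases, capped
    at 1.  Deterministic for a fixed seed and invariant to feature order.
    ``exhaustive=True`` enumerates every distinct label assignment instead
    of sampling (feasible only for small designs).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols = [c for c in matrix.columns if groups.get(c) in ("AD", "CTR")]
    feats = [r.feature_id for r in observed]
    mat = matrix.loc[feats, cols].to_numpy(dtype=float)
    is_ad = np.array([groups[c] == "AD" for c in cols])
    obs_t = np.abs(np.array([r.t_statistic for r in observed]))
    order = np.argsort(-obs_t)  # descending |t|
    if exhaustive:
        from itertools import combinations

        n_ad = int(is_ad.sum())
        perms = []
        for idx in combinations(range(len(cols)), n_ad):
            mask = np.zeros(len(cols), dtype=bool)
            mask[list(idx)] = True
            perms.append(mask)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(is_ad) for _ in range(n_perm))
    exceed = np.zeros(len(observed))
    for perm in perms:
        pt = np.abs(_t_stats(mat, perm))
        pt = np.sort(pt[np.isfinite(pt)])
        # permuted |t| >= each observed threshold, via sorted lookup
        exceed += len(pt) - np.searchsorted(pt, obs_t, side="left")
    obs_sorted = obs_t[order]
    obs_count = np.arange(1, len(order) + 1, dtype=float)
    # handle ties on |t|: counts at a threshold include all tied features
    for i in range(len(order) - 2, -1, -1):
        if obs_sorted[i] == obs_sorted[i + 1]:
            obs_count[i] = obs_count[i + 1]
    raw = np.minimum(1.0, (exceed[order] / n_perm) / obs_count)
    # q of a feature = best achievable FDR at any threshold it survives
    qsorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty_like(qsorted)
    q[order] = qsorted
    out = []
    for r, qv in zip(observed, q):
        out.append(DifferentialResult(
            feature_id=r.feature_id,
            log2_fold_change=r.log2_fold_change,
            t_statistic=r.t_statistic,
            p_value=r.p_value,
            q_permutation=float(qv),
            zero_variance=r.zero_variance,
        ))
    return out


def occupancy(
    modified: np.ndarray, unmodified: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Site occupancy across specimens: mean fraction ± SEM.

    Per specimen, occupancy = modified / (modified + unmodified); specimens
    whose total signal is zero are dropped.  Returns (mean, SEM, per-specimen
    fractions); the SEM is the standard error of the per-specimen fractions.
    """
    modified = np.asarray(modified, dtype=float)
    unmodified = np.asarray(unmodified, dtype=float)
    if np.any(modified < 0) or np.any(unmodified < 0):
        raise ValueError("negative intensities")
    total = modified + unmodified
    keep = total > 0
    if not keep.any():
        raise ValueError("all specimens have zero total signal")
    frac = modified[keep] / total[keep]
    mean = float(frac.mean())
    sem = float(frac.std(ddof=1) / np.sqrt(len(frac))) if len(frac) > 1 else 0.0
    return mean, sem, frac


def association_fraction(
    ptm_groups: dict[str, set[str]],
    aggregate_lists: dict[str, set[str]],
) -> pd.DataFrame:
    """Fraction of each PTM-defined protein group found in each aggregate list.

    Rows: PTM groups; columns: aggregate lists (e.g. neurofibrillary-tangle
    and senile-plaque proteomes).  fraction = |group ∩ list| / |group|.
    """
    rows = {}
    for ptm, accs in ptm_groups.items():
        if not accs:
            raise ValueError(f"empty PTM group {ptm!r}")
        rows[ptm] = {
            name: len(accs & lst) / len(accs)
            for name, lst in aggregate_lists.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")
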