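"""Site calling, prevalence, LFQ aggregation, differential statistics."""

import numpy as np
import pandas as pd
import pytest

from dhaaxl.chem import Peptidoform, builtin_modifications
from dhaaxl.io import PsmRecord
from dhaaxl.stats import (
    EliminylationSite,
    association_fraction,
    call_sites,
    differential_abundance,
    lfq_aggregate,
    occupancy,
    permutation_fdr,
    prevalence_summary,
    site_observations_from_psms,
)

MODS = builtin_modifications()


class TestSiteCalling:
    def test_direct_loss_alone_is_unconfirmed(self):
        [site] = call_sites([("P1", 50, "S", "direct", "sp1")])
        assert not site.confirmed

    def test_single_conjugate_observation_confirms(self):
        [site] = call_sites([("P1", 50, "S", "GSH", "sp1")])
        assert site.confirmed

    def test_crosslink_evidence_confirms(self):
        [site] = call_sites([("P1", 50, "S", "XL", "sp1")])
        assert site.confirmed

    def test_evidence_accumulates_per_site(self):
        sites = call_sites([
            ("P1", 50, "S", "direct", "sp1"),
            ("P1", 50, "S", "GSH", "sp2"),
            ("P1", 60, "C", "direct", "sp1"),
        ])
        assert len(sites) == 2
        confirmed = {s.position: s.confirmed for s in sites}
        assert confirmed == {50: True, 60: False}
        assert next(
            s for s in sites if s.position == 50
        ).specimens_observed == {"sp1", "sp2"}

    def test_observations_extracted_from_psms(self):
        psm = PsmRecord(
            spectrum_id="s",
            peptidoform=Peptidoform("IGSTENLK", {3: MODS["GSH-DHAA"]}),
            accession="P1", start=10, score=10.0, q_value=0.0,
            mass_error_ppm=0.0, specimen_id="AD01",
        )
        [(acc, pos, res, form, sp)] = list(
            site_observations_from_psms([psm])
        )
        assert (acc, pos, res, form, sp) == ("P1", 12, "S", "GSH", "AD01")


def _site(acc, pos, specimens):
    return EliminylationSite(
        accession=acc, residue="S", position=pos,
        evidence_forms={"GSH"}, specimens_observed=set(specimens),
    )


class TestPrevalence:
    def test_inclusive_thresholds(self):
        sites = [_site("P1", 1, ["a", "b"]), _site("P1", 2, ["a"] )]
        df = prevalence_summary(sites, n_specimens=4)
        by_t = df.set_index("threshold")
        assert by_t.loc[0.0, "n_sites"] == 2
        assert by_t.loc[0.5, "n_sites"] == 1  # 2/4 counts at 50%
        assert by_t.loc[0.8, "n_sites"] == 0

    def test_full_prevalence(self):
        sites = [_site("P1", 1, list("abcd"))]
        df = prevalence_summary(sites, n_specimens=4)
        assert df.set_index("threshold").loc[1.0, "n_sites"] == 1

    def test_counts_monotone_and_match_brute_force(self):
        rng = np.random.default_rng(5)
        universe = [f"sp{i}" for i in range(8)]
        for _ in range(200):
            sites = [
                _site(
                    f"P{rng.integers(3)}", int(rng.integers(100)),
                    [s for s in universe if rng.random() < 0.5],
                )
                for _ in range(int(rng.integers(1, 8)))
            ]
            # distinct positions only
            sites = list({(s.accession, s.position): s for s in sites}
                         .values())
            df = prevalence_summary(sites, n_specimens=8)
            assert (df.n_sites.diff().dropna() <= 0).all()
            for _, row in df.iterrows():
                want = [
                    s for s in sites
                    if len(s.specimens_observed) >= row.threshold * 8
                    and len(s.specimens_observed) > 0
                ]
                assert row.n_sites == len(want)
                assert row.n_proteins == len({s.accession for s in want})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            prevalence_summary([], 0)


def _psm(pep, specimen, intensity, run="r1"):
    return PsmRecord(
        spectrum_id=f"{run}.{pep}.{intensity}",
        peptidoform=Peptidoform(pep), accession="P1", start=1,
        score=10.0, q_value=0.0, mass_error_ppm=0.0,
        intensity=intensity, specimen_id=specimen,
    )


class TestLfqAggregate:
    def test_fractions_summed_within_specimen(self):
        mat = lfq_aggregate(
            [_psm("IGSTENLK", "sp1", 10.0), _psm("IGSTENLK", "sp1", 20.0)],
            normalize=False,
        )
        assert mat.loc["IGSTENLK", "sp1"] == 30.0

    def test_median_normalization_equalizes_scaled_specimens(self):
        psms = []
        for pep, base in (("IGSTENLK", 10.0), ("CGSKDNIK", 30.0),
                          ("SPVVSGDTSPR", 50.0)):
            psms.append(_psm(pep, "sp1", base))
            psms.append(_psm(pep, "sp2", base * 2))
        mat = lfq_aggregate(psms)
        assert mat["sp1"].median() == pytest.approx(mat["sp2"].median())

    def test_empty_input(self):
        assert lfq_aggregate([]).empty


class TestDifferentialAbundance:
    def test_ten_fold_feature(self):
        mat = pd.DataFrame(
            {"AD1": [9.9], "AD2": [10.0], "AD3": [10.1],
             "CTR1": [0.9], "CTR2": [1.0], "CTR3": [1.1]},
            index=["f"],
        )
        groups = {c: ("AD" if c.startswith("AD") else "CTR")
                  for c in mat.columns}
        [r] = differential_abundance(mat, groups)
        assert 2 ** r.log2_fold_change == pytest.approx(10.0)
        assert r.log2_fold_change == pytest.approx(np.log2(10), abs=1e-9)
        # oracle: Welch t by hand
        a, c = np.array([9.9, 10.0, 10.1]), np.array([0.9, 1.0, 1.1])
        se = np.sqrt(a.var(ddof=1) / 3 + c.var(ddof=1) / 3)
        assert r.t_statistic == pytest.approx((a.mean() - c.mean()) / se)
        assert r.p_value < 1e-6

    def test_identical_groups_null(self):
        mat = pd.DataFrame(
            {"AD1": [1.0], "AD2": [2.0], "CTR1": [1.0], "CTR2": [2.0]},
            index=["f"],
        )
        groups = {"AD1": "AD", "AD2": "AD", "CTR1": "CTR", "CTR2": "CTR"}
        [r] = differential_abundance(mat, groups)
        assert r.log2_fold_change == 0.0
        assert r.t_statistic == 0.0
        assert r.p_value == 1.0

    def test_zero_variance_flagged_not_crashed(self):
        mat = pd.DataFrame(
            {"AD1": [2.0], "AD2": [2.0], "CTR1": [1.0], "CTR2": [1.0]},
            index=["f"],
        )
        groups = {"AD1": "AD", "AD2": "AD", "CTR1": "CTR", "CTR2": "CTR"}
        [r] = differential_abundance(mat, groups)
        assert r.zero_variance and r.p_value < 1e-300  # limiting p, kept > 0

    def test_missing_values_skip_feature(self):
        mat = pd.DataFrame(
            {"AD1": [1.0], "AD2": [np.nan], "CTR1": [1.0], "CTR2": [2.0]},
            index=["f"],
        )
        groups = {"AD1": "AD", "AD2": "AD", "CTR1": "CTR", "CTR2": "CTR"}
        assert differential_abundance(mat, groups) == []

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(17)
        n_feat, n, alpha = 400, 20, 0.05
        cols = [f"AD{i}" for i in range(n)] + [f"CTR{i}" for i in range(n)]
        groups = {c: c[:-len(str(i))] if False else
                  ("AD" if c.startswith("AD") else "CTR") for i, c in
                  enumerate(cols)}
        mat = pd.DataFrame(
            rng.lognormal(10, 0.3, size=(n_feat, 2 * n)), columns=cols
        )
        res = differential_abundance(mat, groups)
        frac = np.mean([r.p_value <= alpha for r in res])
        se = np.sqrt(alpha * (1 - alpha) / n_feat)
        assert abs(frac - alpha) < 3 * se + 1e-9


class TestPermutationFdr:
    def _matrix(self, rng, n_feat, n_ad, n_ctr, fold_idx=(), fold=10.0):
        cols = [f"AD{i}" for i in range(n_ad)] + [
            f"CTR{i}" for i in range(n_ctr)
        ]
        groups = {c: ("AD" if c.startswith("AD") else "CTR") for c in cols}
        vals = rng.lognormal(10, 0.3, size=(n_feat, len(cols)))
        for i in fold_idx:
            vals[i, :n_ad] *= fold
        mat = pd.DataFrame(vals, columns=cols,
                           index=[f"f{i}" for i in range(n_feat)])
        return mat, groups

    def test_strong_feature_gets_q_zero(self):
        rng = np.random.default_rng(2)
        mat, groups = self._matrix(rng, 50, 10, 10, fold_idx=(0,))
        res = differential_abundance(mat, groups)
        res = permutation_fdr(mat, groups, res, n_perm=500, seed=1)
        by_id = {r.feature_id: r for r in res}
        assert by_id["f0"].q_permutation == 0.0

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(4)
        mat, groups = self._matrix(rng, 30, 6, 6, fold_idx=(3,))
        res = differential_abundance(mat, groups)
        q1 = [r.q_permutation for r in permutation_fdr(
            mat, groups, res, n_perm=200, seed=9
        )]
        q2 = [r.q_permutation for r in permutation_fdr(
            mat, groups, res, n_perm=200, seed=9
        )]
        assert q1 == q2
        shuffled = list(reversed(res))
        q3 = {r.feature_id: r.q_permutation for r in permutation_fdr(
            mat, groups, shuffled, n_perm=200, seed=9
        )}
        # same per-feature values regardless of input order
        for r, q in zip(res, q1):
            assert q3[r.feature_id] == pytest.approx(q, abs=1e-12)

    def test_agrees_with_exhaustive_enumeration_3v3(self):
        from itertools import combinations
        rng = np.random.default_rng(8)
        mat, groups = self._matrix(rng, 12, 3, 3, fold_idx=(0, 1))
        res = differential_abundance(mat, groups)
        got = {
            r.feature_id: r.q_permutation
            for r in permutation_fdr(mat, groups, res, exhaustive=True)
        }
        # oracle: direct counting over all C(6,3) label assignments
        vals = mat.to_numpy()
        cols = list(mat.columns)
        obs_t = np.abs([r.t_statistic for r in res])
        perm_ts = []
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(idx)] = True
            a = vals[:, mask]
            c = vals[:, ~mask]
            se = np.sqrt(a.var(1, ddof=1) / 3 + c.var(1, ddof=1) / 3)
            perm_ts.append(np.abs((a.mean(1) - c.mean(1)) / se))
        perm_ts = np.concatenate(perm_ts)
        n_perm = 20
        raw = {}
        for r, t0 in zip(res, obs_t):
            exceed = np.sum(perm_ts >= t0) / n_perm
            obs_count = np.sum(obs_t >= t0)
            raw[r.feature_id] = min(1.0, exceed / obs_count)
        for r in res:
            want = min(
                v for k, v in raw.items()
                if np.abs(np.array(
                    [x.t_statistic for x in res if x.feature_id == k]
                ))[0] <= abs(r.t_statistic)
            )
            assert got[r.feature_id] == pytest.approx(want, abs=1e-12)


class TestOccupancy:
    def test_simple_fraction(self):
        mean, sem, frac = occupancy(np.array([25.0]), np.array([75.0]))
        assert mean == 0.25 and sem == 0.0

    def test_fully_unmodified(self):
        mean, sem, _ = occupancy(
            np.zeros(5), np.full(5, 100.0)
        )
        assert mean == 0.0 and sem == 0.0

    def test_sem_close_to_bootstrap(self):
        rng = np.random.default_rng(12)
        n = 40
        modified = rng.lognormal(3, 0.4, n)
        unmodified = rng.lognormal(4, 0.4, n)
        mean, sem, frac = occupancy(modified, unmodified)
        boots = [
            frac[rng.integers(0, n, n)].mean() for _ in range(2000)
        ]
        assert sem == pytest.approx(np.std(boots, ddof=1), rel=0.10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            occupancy(np.zeros(3), np.zeros(3))


class TestAssociationFraction:
    def test_subset_and_disjoint(self):
        df = association_fraction(
            {"XL": {"a", "b"}, "GSH": {"c"}},
            {"NFT": {"a", "b", "z"}, "SP": {"q"}},
        )
        assert df.loc["XL", "NFT"] == 1.0
        assert df.loc["GSH", "NFT"] == 0.0
        assert df.loc["XL", "SP"] == 0.0

    def test_matches_direct_set_arithmetic(self):
        rng = np.random.default_rng(6)
        universe = [f"P{i}" for i in range(30)]
        for _ in range(50):
            groups = {
                "g1": {p for p in universe if rng.random() < 0.4} or {"P0"},
                "g2": {p for p in universe if rng.random() < 0.2} or {"P1"},
            }
            lists = {
                "L1": {p for p in universe if rng.random() < 0.3},
                "L2": {p for p in universe if rng.random() < 0.6},
            }
            df = association_fraction(groups, lists)
            for g, accs in groups.items():
                for ln, lst in lists.items():
                    assert df.loc[g, ln] == len(accs & lst) / len(accs)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            association_fraction({"g": set()}, {"L": {"a"}})


class TestSiteTable:
    def test_round_trip(self, tmp_path):
        sites = call_sites([
            ("P1", 50, "S", "GSH", "sp1"),
            ("P1", 50, "S", "direct", "sp2"),
            ("P2", 9, "C", "direct", "sp2"),
        ])
        from dhaaxl.stats import read_sites, write_sites
        path = tmp_path / "sites.tsv"
        write_sites(sites, path)
        back = read_sites(path)
        assert [(s.accession, s.position, s.residue, s.confirmed,
                 s.evidence_forms, s.specimens_observed) for s in back] == [
            (s.accession, s.position, s.residue, s.confirmed,
             s.evidence_forms, s.specimens_observed) for s in sites
        ]
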