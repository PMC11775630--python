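"""Fragment generation, scoring, target-decoy FDR, and the search modes."""

import numpy as np
import pytest

from dhaaxl.chem import (
    Peptidoform,
    builtin_modifications,
    label_18O_shift,
    mz_from_mass,
    PROTON_MASS,
)
from dhaaxl.io import ProteinRecord, SpectrumRecord
from dhaaxl.search import (
    SearchParams,
    discover_delta_mods,
    estimate_fdr,
    generate_crosslink_fragments,
    score_match,
    search_crosslinks,
    search_linear,
    theoretical_fragments,
)
from dhaaxl.simulate import simulate_spectra

MODS = builtin_modifications()


class TestTheoreticalFragments:
    def test_ion_count_length_8(self):
        frags = theoretical_fragments(Peptidoform("CGSKDNIK"), (1,))
        assert len(frags) == 14  # 7 b + 7 y

    def test_heavy_label_shifts_y_ions_only(self):
        light = dict(theoretical_fragments(Peptidoform("CGSKDNIK"), (1,)))
        heavy = dict(theoretical_fragments(
            Peptidoform("CGSKDNIK", c_term_heavy_o=2), (1,)
        ))
        for ion in light:
            if ion.startswith("y"):
                assert heavy[ion] - light[ion] == pytest.approx(
                    label_18O_shift(1), abs=1e-6
                )
            else:
                assert heavy[ion] == pytest.approx(light[ion], abs=1e-9)

    def test_complementarity(self):
        # b_i + y_{n-i} = precursor + proton masses
        pf = Peptidoform("IGSTENLK")
        frags = dict(theoretical_fragments(pf, (1,)))
        n = len(pf.residues)
        for i in range(1, n):
            total = frags[f"b{i}^1"] + frags[f"y{n - i}^1"]
            assert total == pytest.approx(
                pf.mass + 2 * PROTON_MASS, abs=1e-6
            )


class TestCrosslinkFragments:
    def _frags(self):
        return generate_crosslink_fragments(
            Peptidoform("SPVVSGDTSPR"), Peptidoform("CGSKDNIK"),
            donor_site=5, acceptor_site=1,
            crosslinker_delta=MODS["XL-ST"].delta_mass, charges=(1,),
        )

    def test_spanning_y_ion_carries_partner_mass(self):
        frags = {(c, l): mz for c, l, mz, _ in self._frags()}
        # alpha y7 spans the linked serine: neutral 1563.731118 Da
        assert frags[("A", "y7^1")] == pytest.approx(
            1563.731118 + PROTON_MASS, abs=1e-5
        )

    def test_non_spanning_ion_equals_linear_fragment(self):
        frags = {(c, l): mz for c, l, mz, _ in self._frags()}
        linear = dict(theoretical_fragments(Peptidoform("SPVVSGDTSPR"), (1,)))
        assert frags[("A", "b4^1")] == pytest.approx(
            linear["b4^1"], abs=1e-9
        )

    def test_total_ion_count(self):
        # chains of length 11 and 8 at one charge: 2×10 + 2×7 ions
        assert len(self._frags()) == 34

    def test_degenerates_to_linear_without_partner(self):
        frags = generate_crosslink_fragments(
            Peptidoform("IGSTENLK"), Peptidoform("GG"),
            donor_site=3, acceptor_site=1,
            crosslinker_delta=-Peptidoform("GG").mass, charges=(1,),
        )
        linear = dict(theoretical_fragments(Peptidoform("IGSTENLK"), (1,)))
        for chain, label, mz, _ in frags:
            if chain == "A":
                assert mz == pytest.approx(linear[label], abs=1e-9)


def _spectrum(frag_mzs, intensities=None, **kw):
    intensities = intensities or [1.0] * len(frag_mzs)
    defaults = dict(
        spectrum_id="s", run_id="r", label_state="light",
        precursor_mz=500.0, precursor_z=2, rt=10.0,
    )
    defaults.update(kw)
    return SpectrumRecord(
        fragments=sorted(zip(frag_mzs, intensities)), **defaults
    )


class TestScoring:
    def test_self_match_explains_everything(self):
        mzs = [mz for _, mz in theoretical_fragments(
            Peptidoform("CGSKDNIK"), (1,)
        )]
        sm = score_match(_spectrum(mzs), mzs, 20.0)
        assert sm.matched_ion_count == 14
        assert sm.fraction_intensity_explained == pytest.approx(1.0)

    def test_empty_spectrum_scores_zero(self):
        sm = score_match(_spectrum([]), [100.0, 200.0], 20.0)
        assert sm.matched_ion_count == 0 and sm.score == 0.0

    def test_peaks_outside_tolerance_unmatched(self):
        mzs = [500.0, 800.0]
        shifted = [m * (1 + 3 * 20e-6) for m in mzs]
        sm = score_match(_spectrum(shifted), mzs, 20.0)
        assert sm.matched_ion_count == 0

    def test_score_invariant_to_peak_order(self):
        mzs = [300.0, 400.0, 500.0]
        s1 = _spectrum(mzs, [1.0, 2.0, 3.0])
        s2 = _spectrum(list(reversed(mzs)), [3.0, 2.0, 1.0])
        assert score_match(s1, mzs, 20.0).score == (
            score_match(s2, mzs, 20.0).score
        )

    def test_each_peak_used_once(self):
        # two theoretical ions inside tolerance of one observed peak
        sm = score_match(_spectrum([500.0]), [500.0, 500.001], 20.0)
        assert sm.matched_ion_count == 1


class TestEstimateFdr:
    def test_all_targets_q_zero(self):
        q = estimate_fdr([3.0, 2.0, 1.0], [False, False, False])
        assert np.all(q == 0.0)

    def test_interleaved_equal_scores_q_one(self):
        q = estimate_fdr([1.0, 1.0, 1.0, 1.0], [True, False, True, False])
        assert np.all(q == 1.0)

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            decoy = rng.random(n) < 0.4
            if decoy.all():
                decoy[0] = False
            q = estimate_fdr(scores, decoy)
            # oracle: direct counting at each score, then best achievable
            # FDR over thresholds at or below each score
            fdr_at = {}
            for s in scores:
                d = np.sum(decoy & (scores >= s))
                t = np.sum(~decoy & (scores >= s))
                fdr_at[s] = min(1.0, d / t) if t else 1.0
            for i, s in enumerate(scores):
                want = min(v for u, v in fdr_at.items() if u <= s)
                assert q[i] == pytest.approx(want, abs=1e-12), (
                    scores.tolist(), decoy.tolist()
                )

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr([1.0], [True])


@pytest.fixture(scope="module")
def planted(small_truth_module):
    return small_truth_module


@pytest.fixture(scope="module")
def small_truth_module():
    from dhaaxl.simulate import (
        SimulationParams, generate_proteome, plant_modifications,
    )
    params = SimulationParams(
        seed=11, n_proteins=20, n_direct_sites=6, n_conjugate_sites=3,
        n_crosslinks_intra=4, n_crosslinks_inter=4,
        n_crosslinks_light_only=2, n_background_peptides=30,
    )
    return plant_modifications(generate_proteome(params))


class TestLinearSearch:
    def test_recovers_planted_background_peptides(self, small_truth_module):
        truth = small_truth_module
        spectra = simulate_spectra(truth, "light", "l1", 0)
        bg = {s.spectrum_id for s in spectra if ".bg." in s.spectrum_id}
        psms = search_linear(spectra, truth.proteins)
        found = {p.spectrum_id for p in psms}
        assert bg <= found | set()  # every unmodified peptide identified
        assert all(p.q_value <= 0.01 for p in psms)

    def test_empty_database_rejected(self, small_truth_module):
        with pytest.raises(ValueError):
            search_linear([], [])

    def test_spectrum_without_candidate_yields_no_psm(self):
        prot = ProteinRecord("P", "", "MKAAAGGGKLLLK")
        s = _spectrum([300.0, 400.0], precursor_mz=5000.0, precursor_z=2)
        assert search_linear([s], [prot]) == []


class TestDeltaDiscovery:
    def test_planted_conjugates_localized(self, small_truth_module):
        truth = small_truth_module
        spectra = [
            s for s in simulate_spectra(truth, "light", "l1", 0)
            if ".site." in s.spectrum_id
        ]
        cand = [MODS[n] for n in (
            "DHA", "DHB", "DHA-C", "GSH-DHAA", "GSH-DHAA-C", "HC-DHAA",
            "HC-DHAA-C", "DTT-DHAA", "DTT-DHAA-C", "TCEP-DHAA",
            "TCEP-DHAA-C",
        )]
        found = discover_delta_mods(spectra, truth.proteins, cand)
        planted = {
            (s.accession, s.position): s.form for s in truth.planted_sites
        }
        hits = {
            (d.accession, d.position) for d in found
        }
        assert len(hits & set(planted)) >= 0.9 * len(planted)

    def test_zero_delta_not_explained(self, small_truth_module):
        truth = small_truth_module
        spectra = [
            s for s in simulate_spectra(truth, "light", "l1", 0)
            if ".bg." in s.spectrum_id
        ][:5]
        cand = [MODS["GSH-DHAA"]]
        assert discover_delta_mods(spectra, truth.proteins, cand) == []


class TestCrosslinkSearch:
    def test_planted_links_recovered_wrong_chemistry_rejected(
        self, small_truth_module
    ):
        truth = small_truth_module
        spectra = [
            s for s in simulate_spectra(truth, "light", "l1", 0)
            if ".xl." in s.spectrum_id
        ]
        st_links = {
            xl.key() for xl in truth.planted_crosslinks
            if xl.crosslinker_name == "XL-ST"
        }
        right = search_crosslinks(
            spectra, truth.proteins, MODS["XL-ST"], donor_residues=("S", "T")
        )
        got = {c.pair_key() for c in right}
        assert len(got & st_links) >= 0.9 * len(st_links)
        # the same spectra searched with the H2S-loss chemistry: the ~16 Da
        # crosslinker difference exceeds the precursor tolerance everywhere
        wrong = search_crosslinks(
            spectra, truth.proteins, MODS["XL-C"], donor_residues=("S", "T")
        )
        assert {c.pair_key() for c in wrong} & st_links == set()

    def test_linear_spectra_yield_no_confident_csm(self, small_truth_module):
        truth = small_truth_module
        spectra = [
            s for s in simulate_spectra(truth, "light", "l1", 0)
            if ".bg." in s.spectrum_id
        ]
        csms = search_crosslinks(spectra, truth.proteins, MODS["XL-ST"])
        assert len(csms) <= 0.05 * len(spectra)
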