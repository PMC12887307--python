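"""Formula descriptors, exact-mass assignment and DOM summaries."""

import math

import numpy as np
import pytest

from cesdyn.constants import (MASS_C, MASS_H, MASS_N, MASS_O, MASS_S,
                              PROTON_MASS, deprotonated_mz)
from cesdyn.dom import (
    AssignedPeak, AssignmentConfig, MolecularFormula, Peak, assign_peaklist,
    candidate_formulas, chemodiversity, class_abundance, classify,
    compare_formula_sets, default_class_scheme, descriptors,
    formula_to_string, parse_formula, _catalog_for,
)
from cesdyn.errors import AnalysisError
from cesdyn.synthetic import gen_dom_peaklists

from conftest import make_dom_scenario

GLUCOSE = MolecularFormula(6, 12, 0, 6, 0)


def brute_force_candidates(mz, config):
    """Independent enumeration: loop the (c, n, o, s) grid, solve the hydrogen
    count from the residual mass, and re-derive every validity rule from
    scratch. Only the shared atomic-mass constants are reused."""
    neutral = mz + PROTON_MASS
    tol = config.tolerance_ppm * 1e-6 * mz
    out = []
    for c in range(config.c_range[0], config.c_range[1] + 1):
        if c * MASS_C > neutral + tol:
            break
        for n in range(config.n_range[0], config.n_range[1] + 1):
            for s in range(config.s_range[0], config.s_range[1] + 1):
                for o in range(config.o_range[0], config.o_range[1] + 1):
                    rest = (neutral - c * MASS_C - n * MASS_N - o * MASS_O
                            - s * MASS_S)
                    h_lo = math.ceil((rest - tol) / MASS_H)
                    h_hi = math.floor((rest + tol) / MASS_H)
                    for h in range(h_lo, h_hi + 1):
                        if not config.h_range[0] <= h <= config.h_range[1]:
                            continue
                        theo = (c * MASS_C + h * MASS_H + n * MASS_N
                                + o * MASS_O + s * MASS_S - PROTON_MASS)
                        ppm = (mz - theo) / theo * 1e6
                        if abs(ppm) > config.tolerance_ppm:
                            continue
                        if not config.hc_range[0] <= h / c <= config.hc_range[1]:
                            continue
                        if o / c > config.oc_range[1]:
                            continue
                        dbe = c - h / 2 + n / 2 + 1
                        if dbe != int(dbe):
                            continue
                        if not config.dbe_range[0] <= dbe <= config.dbe_range[1]:
                            continue
                        nosc = 4 - (4 * c + h - 3 * n - 2 * o - 2 * s) / c
                        if not config.nosc_range[0] <= nosc <= config.nosc_range[1]:
                            continue
                        out.append((MolecularFormula(c, h, n, o, s), ppm))
    return out


class TestDescriptors:
    @pytest.mark.parametrize("formula, hc, oc, dbe, nosc, series", [
        (GLUCOSE, 2.0, 1.0, 1.0, 0.0, "CHO"),
        (MolecularFormula(1, 4), 4.0, 0.0, 0.0, -4.0, "CHO"),
        (MolecularFormula(1, 0, 0, 2), 0.0, 2.0, 2.0, 4.0, "CHO"),
        (MolecularFormula(10, 15, 1, 4, 1), 1.5, 0.4, 4.0, -0.2, "CHNOS"),
    ])
    def test_hand_evaluated_descriptor_identities(self, formula, hc, oc, dbe,
                                                  nosc, series):
        d = descriptors(formula)
        assert d.hc_ratio == pytest.approx(hc)
        assert d.oc_ratio == pytest.approx(oc)
        assert d.dbe == pytest.approx(dbe)
        assert d.nosc == pytest.approx(nosc)
        assert d.series == series

    def test_glucose_monoisotopic_mass_and_ion(self):
        d = descriptors(GLUCOSE)
        assert d.neutral_monoisotopic_mass == pytest.approx(180.063388, abs=1e-6)
        assert d.theoretical_mz == pytest.approx(180.063388 - 1.007276, abs=1e-6)

    def test_formula_string_round_trip(self):
        for f in (GLUCOSE, MolecularFormula(10, 15, 1, 4, 1),
                  MolecularFormula(5, 8, 0, 2, 1)):
            assert parse_formula(formula_to_string(f)) == f

    def test_carbonless_formula_rejected(self):
        with pytest.raises(ValueError):
            descriptors(MolecularFormula(0, 2, 0, 1, 0))


class TestCandidateEnumeration:
    def test_glucose_ion_found_at_negligible_ppm(self):
        cands = candidate_formulas(deprotonated_mz(6, 12, 0, 6, 0))
        formulas = [f for f, _ in cands]
        assert GLUCOSE in formulas
        ppm = dict(cands)[GLUCOSE]
        assert abs(ppm) < 1e-9

    def test_zero_tolerance_empty(self):
        cfg = AssignmentConfig(tolerance_ppm=0.0)
        assert candidate_formulas(100.0, cfg) == []

    def test_mz_outside_instrument_window_rejected(self):
        with pytest.raises(ValueError):
            candidate_formulas(50.0)

    def test_matches_brute_force_oracle_on_random_mz(self):
        cfg = AssignmentConfig()
        rng = np.random.default_rng(0)
        for mz in rng.uniform(120, 780, 25):
            got = candidate_formulas(float(mz), cfg)
            expected = brute_force_candidates(float(mz), cfg)
            assert sorted(f for f, _ in got) == sorted(f for f, _ in expected)
            exp_ppm = dict(expected)
            for f, ppm in got:
                assert ppm == pytest.approx(exp_ppm[f], abs=1e-9)

    def test_theoretical_mz_round_trips_to_zero_ppm(self):
        rng = np.random.default_rng(1)
        cat = _catalog_for(AssignmentConfig())
        for i in rng.integers(0, len(cat.mz), 50):
            f = MolecularFormula(*map(int, cat.elements[i]))
            cands = candidate_formulas(descriptors(f).theoretical_mz)
            assert dict(cands)[f] == pytest.approx(0.0, abs=1e-9)


class TestAssignment:
    def test_noiseless_peaklist_fully_recovered(self):
        study = gen_dom_peaklists(make_dom_scenario(ppm_noise_sd=0.0))
        sample = next(iter(study.peaklists))
        res = assign_peaklist(study.peaklists[sample])
        got = {formula_to_string(a.formula) for a in res.assigned}
        truth = set(study.truth_records[sample].formula)
        assert got == truth
        assert res.unassigned == []

    def test_equidistant_tie_broken_by_fewer_heteroatoms(self):
        # find two adjacent catalog formulas and place the peak at the m/z
        # equidistant in ppm (the harmonic mean of the two theoretical m/z)
        cfg = AssignmentConfig()
        cat = _catalog_for(cfg)
        gaps = np.diff(cat.mz) / cat.mz[:-1] * 1e6
        idx = int(np.argmin(gaps))
        f1 = MolecularFormula(*map(int, cat.elements[idx]))
        f2 = MolecularFormula(*map(int, cat.elements[idx + 1]))
        t1, t2 = cat.mz[idx], cat.mz[idx + 1]
        mz = 2 * t1 * t2 / (t1 + t2)
        res = assign_peaklist([Peak(mz, 1.0)], cfg)
        ns1 = f1.n + f1.s
        ns2 = f2.n + f2.s
        assert ns1 != ns2  # near-isobars differ in heteroatom content
        winner = min((f1, f2), key=lambda f: f.n + f.s)
        assert res.assigned[0].formula == winner

    def test_duplicate_formulas_merge_by_summing_intensity(self):
        mz = deprotonated_mz(6, 12, 0, 6, 0)
        res = assign_peaklist([Peak(mz, 3.0), Peak(mz * (1 + 2e-7), 7.0)])
        assert len(res.assigned) == 1
        assert res.assigned[0].intensity == pytest.approx(10.0)
        assert res.assigned[0].formula == GLUCOSE

    def test_unassignable_peak_reported_not_dropped(self):
        cfg = AssignmentConfig(tolerance_ppm=1e-6)
        res = assign_peaklist([Peak(500.0, 1.0),
                               Peak(deprotonated_mz(6, 12, 0, 6, 0), 2.0)],
                              cfg)
        assert len(res.unassigned) >= 1
        assert res.n_peaks == 2

    def test_recovery_monotone_in_ppm_noise(self):
        rates = []
        for noise in (0.0, 0.5, 3.0):
            study = gen_dom_peaklists(
                make_dom_scenario(ppm_noise_sd=noise, seed=9))
            sample = next(iter(study.peaklists))
            res = assign_peaklist(study.peaklists[sample])
            truth = study.truth_records[sample].formula
            got = {formula_to_string(a.formula) for a in res.assigned}
            rates.append(truth.isin(got).mean())
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]


class TestClassification:
    @pytest.mark.parametrize("hc, oc, label", [
        (1.2, 0.4, "lignin/CRAM-like"),
        (1.8, 0.1, "lipids"),
        (2.0, 0.8, "carbohydrates"),
        (1.8, 0.4, "aliphatic/peptides"),
        (1.0, 0.05, "unsaturated hydrocarbons"),
        (1.0, 0.8, "tannins"),
        (0.5, 0.3, "aromatic structures"),
        (2.6, 0.5, "unclassified"),
    ])
    def test_default_scheme_boxes(self, hc, oc, label):
        d = descriptors(MolecularFormula(10, 10, 0, 1, 0))
        d = type(d)(**{**d.__dict__, "hc_ratio": hc, "oc_ratio": oc})
        assert classify(d) == label

    def test_first_matching_rule_wins_on_shared_edges(self):
        # H/C 1.5, O/C 0.2 lies in both the lipid box and the (later)
        # unsaturated-hydrocarbon neighborhood: the lipid rule fires first
        d = descriptors(MolecularFormula(10, 15, 1, 2, 0))
        assert d.hc_ratio == 1.5
        assert classify(d) == "lipids"


class TestSummaries:
    def _assigned(self, specs):
        out = []
        for f, intensity in specs:
            d = descriptors(f)
            out.append(AssignedPeak(d.theoretical_mz, intensity, f, d, 0.0,
                                    classify(d), 1))
        return out

    def test_single_class_has_unit_abundance(self):
        a = self._assigned([(GLUCOSE, 5.0), (MolecularFormula(6, 10, 0, 5), 2.0)])
        frac = class_abundance(a)
        assert frac.sum() == pytest.approx(1.0)
        assert frac["carbohydrates"] == pytest.approx(1.0)

    def test_intensity_vs_count_weighting(self):
        a = self._assigned([
            (GLUCOSE, 30.0),                       # carbohydrates
            (MolecularFormula(20, 24, 0, 8), 35.0),  # lignin/CRAM-like
            (MolecularFormula(18, 22, 0, 7), 20.0),  # lignin/CRAM-like
            (MolecularFormula(16, 20, 0, 6), 15.0),  # lignin/CRAM-like
        ])
        by_int = class_abundance(a, "intensity")
        by_cnt = class_abundance(a, "count")
        assert by_int["carbohydrates"] == pytest.approx(0.3)
        assert by_int["lignin/CRAM-like"] == pytest.approx(0.7)
        assert by_cnt["carbohydrates"] == pytest.approx(0.25)
        assert by_cnt["lignin/CRAM-like"] == pytest.approx(0.75)

    def test_empty_input_is_an_error(self):
        with pytest.raises(AnalysisError):
            class_abundance([])
        with pytest.raises(AnalysisError):
            chemodiversity([])

    def test_chemodiversity_uniform_single_and_hand_cases(self):
        assert chemodiversity(np.ones(4)) == pytest.approx(math.log(4))
        assert chemodiversity(np.array([7.0])) == 0.0
        assert chemodiversity(np.array([1.0, 1.0, 2.0])) == pytest.approx(
            1.0397207708399179)

    def test_chemodiversity_rejects_nonpositive_intensity(self):
        with pytest.raises(AnalysisError):
            chemodiversity(np.array([1.0, 0.0]))

    def test_chemodiversity_bounded_by_log_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = rng.lognormal(0, 1.5, rng.integers(2, 50))
            assert chemodiversity(w) <= math.log(len(w)) + 1e-12

    def test_formula_set_comparison(self):
        a = self._assigned([(GLUCOSE, 1.0),
                            (MolecularFormula(10, 14, 0, 4), 1.0)])
        b = self._assigned([(GLUCOSE, 2.0)])
        cmp_res = compare_formula_sets(a, b)
        assert cmp_res.shared == [GLUCOSE]
        assert cmp_res.unique_to_a == [MolecularFormula(10, 14, 0, 4)]
        assert cmp_res.unique_to_b == []
        assert cmp_res.class_tallies["shared"]["carbohydrates"] == 1
        identical = compare_formula_sets(a, a)
        assert identical.unique_to_a == identical.unique_to_b == []
        disjoint = compare_formula_sets(
            [a[1]], b)
        assert disjoint.shared == []
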