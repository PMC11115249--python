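import numpy as np
import pytest

from cyclodeps.fragments import all_fragments
from cyclodeps.mass import IonSpecies, parse_formula
from cyclodeps.residues import CyclicDepsipeptide, cyclic_equivalent
from cyclodeps.sequencing import (
    annotate_congeners,
    infer_residues,
    match_fragments,
    neutral_mass_of,
)
from cyclodeps.simulate import random_peptide, simulate_spectrum
from cyclodeps.spectra import Spectrum


def make_spectrum(mz, intensity, precursor, species=None, feature_id=None):
    return Spectrum(
        precursor_mz=precursor,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        species=species,
        feature_id=feature_id,
    )


class TestMatchFragments:
    def test_printed_values_all_matched(self, cycle_a, sodiated):
        peaks = [799.4562, 652.3932, 306.2035, 164.0677]
        s = make_spectrum(peaks, [1e4] * 4, 799.4562, sodiated)
        report = match_fragments(all_fragments(cycle_a, sodiated), s, tol_ppm=10)
        assert report.n_matched >= 4
        matched_peaks = {idx for _, idx, _ in report.matches}
        assert matched_peaks == {0, 1, 2, 3}

    def test_empty_spectrum_zero_coverage(self, cycle_a, sodiated):
        s = make_spectrum([], [], 799.4616, sodiated)
        report = match_fragments(all_fragments(cycle_a, sodiated), s)
        assert report.coverage == 0.0
        assert report.n_matched == 0

    def test_tolerance_boundary(self, cycle_a, sodiated):
        ion = all_fragments(cycle_a, sodiated)[0]
        off = ion.mz * (1 + 20e-6)
        s = make_spectrum([off], [1.0], 799.4616, sodiated)
        report = match_fragments([ion], s, tol_ppm=10)
        assert report.n_matched == 0

    def test_each_peak_used_once(self, cycle_a, sodiated):
        ions = all_fragments(cycle_a, sodiated)[:3]
        s = make_spectrum([ions[0].mz], [1.0], 799.4616, sodiated)
        report = match_fragments(ions, s, tol_ppm=10)
        assert report.n_matched == 1

    def test_ppm_within_tolerance(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, ppm_sd=2.0, n_noise=0, seed=3)
        report = match_fragments(all_fragments(cycle_a, sodiated), s, tol_ppm=10)
        assert all(abs(ppm) <= 10 for _, _, ppm in report.matches)

    def test_invalid_tolerance(self, cycle_a, sodiated):
        s = make_spectrum([100.0], [1.0], 799.4616, sodiated)
        with pytest.raises(ValueError):
            match_fragments(all_fragments(cycle_a, sodiated), s, tol_ppm=0)


class TestInferResidues:
    def test_noiseless_roundtrip(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, ppm_sd=0.0, n_noise=0, seed=1)
        top = infer_residues(s, cycle_a.formula())[0]
        assert cyclic_equivalent(top.residues, cycle_a.names, wildcard=True)
        assert top.two_pathway_support

    def test_worked_example_peak_list(self, cycle_a, sodiated, fig_peaks):
        """A peak list assembled from the printed fragment values recovers
        the published residue sequence."""
        mz, intensity = fig_peaks
        s = make_spectrum(mz, intensity, 799.4562, sodiated)
        top = infer_residues(s, parse_formula("C44H64N4O8"))[0]
        assert cyclic_equivalent(
            top.residues, ("Phe", "Lxx", "Hba", "Phe", "Lxx", "Hda"), wildcard=True
        )

    def test_pure_noise_yields_empty(self, sodiated):
        rng = np.random.default_rng(0)
        s = make_spectrum(
            rng.uniform(100, 750, size=30), rng.uniform(1e3, 1e5, size=30),
            799.4616, sodiated,
        )
        assert infer_residues(s, parse_formula("C44H64N4O8")) == []

    def test_unknown_species_rejected(self, cycle_a):
        s = make_spectrum([306.2035], [1.0], 799.4616, species=None)
        with pytest.raises(ValueError, match="species"):
            infer_residues(s, cycle_a.formula())

    def test_composition_soundness(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, ppm_sd=5.0, n_noise=20, seed=5)
        neutral = cycle_a.formula()
        for cand in infer_residues(s, neutral):
            assert cand.total_formula == neutral

    def test_without_formula_constraint(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, ppm_sd=0.0, n_noise=0, seed=2)
        top = infer_residues(s, None)[0]
        assert cyclic_equivalent(top.residues, cycle_a.names, wildcard=True)

    def test_max_results_respected(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, ppm_sd=5.0, n_noise=20, seed=6)
        assert len(infer_residues(s, cycle_a.formula(), max_results=3)) <= 3

    def test_score_monotone_in_matched_peaks(self, cycle_a, sodiated):
        """Adding a matched peak never lowers a candidate's score."""
        base = simulate_spectrum(cycle_a, sodiated, ppm_sd=0.0, n_noise=0, seed=1)
        preds = all_fragments(cycle_a, sodiated)
        partial = make_spectrum(base.mz[:-1], base.intensity[:-1],
                                base.precursor_mz, sodiated)
        full = make_spectrum(base.mz, base.intensity, base.precursor_mz, sodiated)
        r_partial = match_fragments(preds, partial)
        r_full = match_fragments(preds, full)
        assert r_full.score >= r_partial.score
        assert r_full.n_matched >= r_partial.n_matched

    def test_neutral_mass_of(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, seed=0)
        assert neutral_mass_of(s) == pytest.approx(cycle_a.mass, abs=1e-6)


class TestRecovery:
    def test_top1_recovery_rate(self, sodiated):
        """>= 95 of 100 random hexadepsipeptides recovered at 5 ppm jitter
        plus 20 noise peaks (fixed seed)."""
        rng = np.random.default_rng(1)
        ok = 0
        for _ in range(100):
            p = random_peptide(rng)
            s = simulate_spectrum(p, sodiated, ppm_sd=5.0, n_noise=20, seed=rng)
            cands = infer_residues(s, p.formula())
            if cands and cyclic_equivalent(cands[0].residues, p.names, wildcard=True):
                ok += 1
        assert ok >= 95


class TestAnnotateCongeners:
    SUBS = [("Hba", "Lac"), ("Hda", "Hdda")]

    def test_self_assignment_is_identity(self, cycle_a, sodiated):
        s = simulate_spectrum(cycle_a, sodiated, ppm_sd=0, n_noise=0, seed=1,
                              feature_id="a")
        [rec] = annotate_congeners(cycle_a, [s], self.SUBS)
        assert rec.assigned and rec.substitutions == ()

    def test_lac_substitution(self, cycle_a, cycle_b, sodiated):
        s = simulate_spectrum(cycle_b, sodiated, ppm_sd=0, n_noise=0, seed=2,
                              feature_id="b")
        [rec] = annotate_congeners(cycle_a, [s], self.SUBS)
        assert rec.assigned
        assert {(f, t) for _, f, t in rec.substitutions} == {("Hba", "Lac")}

    def test_lac_plus_hdda_substitution(self, cycle_a, cycle_c, sodiated):
        s = simulate_spectrum(cycle_c, sodiated, ppm_sd=0, n_noise=0, seed=3,
                              feature_id="c")
        [rec] = annotate_congeners(cycle_a, [s], self.SUBS)
        assert rec.assigned
        assert {(f, t) for _, f, t in rec.substitutions} == {
            ("Hba", "Lac"), ("Hda", "Hdda")
        }

    def test_hdda_only_substitution(self, cycle_a, cycle_d, sodiated):
        s = simulate_spectrum(cycle_d, sodiated, ppm_sd=0, n_noise=0, seed=4,
                              feature_id="d")
        [rec] = annotate_congeners(cycle_a, [s], self.SUBS)
        assert {(f, t) for _, f, t in rec.substitutions} == {("Hda", "Hdda")}

    def test_unresolvable_reported_unassigned(self, cycle_a, sodiated):
        stray = make_spectrum([100.0], [1.0], 500.0, sodiated, feature_id="x")
        [rec] = annotate_congeners(cycle_a, [stray], self.SUBS)
        assert not rec.assigned
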