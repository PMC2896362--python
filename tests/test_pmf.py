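import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathprofiler import pmf, synthetic
from pathprofiler.pmf import PeakList, SearchConfig

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


class TestDigest:
    @pytest.mark.parametrize("seq,mc,expected", [
        ("AKRG", 0, ["AK", "R", "G"]),
        ("AKPR", 0, ["AKPR"]),                      # Keil: K before P
        ("AKRG", 1, ["AK", "R", "G", "AKR", "RG"]),
        ("RPR", 0, ["RPR"]),
        ("KK", 0, ["K", "K"]),                      # duplicates retained
    ])
    def test_examples(self, seq, mc, expected):
        assert pmf.digest(seq, mc) == expected

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            pmf.digest("AKXR", 0)

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_concatenation_reconstructs_sequence(self, seq):
        assert "".join(pmf.digest(seq, 0)) == seq

    @given(sequences, st.integers(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_missed_cleavage_products_are_substrings(self, seq, mc):
        for pep in pmf.digest(seq, mc):
            assert pep in seq


class TestPeptideMz:
    def test_glycine(self):
        assert pmf.peptide_mz("G", n_oxidized_met=0)[0] == \
            pytest.approx(76.0393, abs=1e-3)

    def test_cysteine_carries_fixed_mod(self):
        assert pmf.peptide_mz("C", n_oxidized_met=0)[0] == \
            pytest.approx(179.0485, abs=1e-3)

    def test_acth_calibrant(self):
        mz = pmf.peptide_mz("RPVKVYPNGAEDESAEAFPLEF", n_oxidized_met=0)[0]
        assert mz == pytest.approx(2465.199, abs=0.01)

    def test_oxidation_expansion(self):
        masses = pmf.peptide_mz("MAMK")
        assert len(masses) == 3
        assert masses[1] - masses[0] == pytest.approx(pmf.MET_OXIDATION)
        assert masses[2] - masses[0] == pytest.approx(2 * pmf.MET_OXIDATION)

    def test_too_many_oxidations(self):
        with pytest.raises(ValueError):
            pmf.peptide_mz("MAK", n_oxidized_met=2)

    def test_carboxymethyl_selectable(self):
        cfg = SearchConfig(cys_mod=pmf.CARBOXYMETHYL)
        delta = pmf.peptide_mz("C", cfg, 0)[0] - \
            pmf.peptide_mz("C", n_oxidized_met=0)[0]
        assert delta == pytest.approx(pmf.CARBOXYMETHYL -
                                      pmf.CARBAMIDOMETHYL)

    @given(sequences, sequences)
    @settings(max_examples=100, deadline=None)
    def test_residue_mass_additivity(self, a, b):
        mass = lambda s: pmf.peptide_mz(s, n_oxidized_met=0)[0]
        lhs = mass(a + b)
        rhs = mass(a) + mass(b) - pmf.WATER - pmf.PROTON
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestMatchPeaks:
    def peaks(self, mz):
        return PeakList("t", np.asarray(mz), np.ones(len(mz)))

    def test_boundary_inclusive_at_50ppm(self):
        pairs = pmf.match_peaks(self.peaks([1000.05]), [1000.0], 50.0)
        assert pairs == [(0, 0)]

    def test_exact_match(self):
        assert pmf.match_peaks(self.peaks([1500.0]), [1500.0], 50.0) == \
            [(0, 0)]

    def test_outside_tolerance(self):
        assert pmf.match_peaks(self.peaks([2000.2]), [2000.0], 50.0) == []

    def test_nearest_wins(self):
        pairs = pmf.match_peaks(self.peaks([1000.01]),
                                [1000.0, 1000.03], 50.0)
        assert pairs == [(0, 0)]

    def test_each_peak_matches_once(self):
        pairs = pmf.match_peaks(self.peaks([1000.0]),
                                [999.99, 1000.01], 50.0)
        assert len(pairs) == 1


class TestFilterBackground:
    def batch_with_bins(self, n_lists=20, in3=1200.0, in2=2200.0):
        """Every list gets a unique peak; ``in3`` appears in 3 lists
        (15%), ``in2`` in 2 lists (10%)."""
        batch = []
        for i in range(n_lists):
            mz = [800.0 + 17.3 * i]
            if i < 3:
                mz.append(in3)
            if i < 2:
                mz.append(in2)
            batch.append(PeakList(f"L{i}", np.array(sorted(mz)),
                                  np.ones(len(mz))))
        return batch

    def test_over_ten_percent_removed_everywhere(self):
        filtered, report = pmf.filter_background(self.batch_with_bins())
        assert len(report) == 1
        assert report["occurrence"].iloc[0] == pytest.approx(0.15)
        for pl in filtered:
            assert not np.any(np.isclose(pl.mz, 1200.0))

    def test_exactly_ten_percent_kept(self):
        filtered, report = pmf.filter_background(self.batch_with_bins())
        survivors = [pl for pl in filtered
                     if np.any(np.isclose(pl.mz, 2200.0))]
        assert len(survivors) == 2

    def test_small_batch_refused(self):
        batch = self.batch_with_bins()[:5]
        with pytest.raises(ValueError, match=">= 10"):
            pmf.filter_background(batch)

    def test_permutation_invariance(self):
        batch = self.batch_with_bins()
        f1, r1 = pmf.filter_background(batch)
        f2, r2 = pmf.filter_background(batch[::-1])
        removed1 = {round(x, 3) for x in r1["bin_mz"]}
        removed2 = {round(x, 3) for x in r2["bin_mz"]}
        assert removed1 == removed2
        total1 = sorted(np.concatenate([pl.mz for pl in f1]))
        total2 = sorted(np.concatenate([pl.mz for pl in f2]))
        np.testing.assert_allclose(total1, total2)

    def test_planted_background_bins_removed(self, small_db):
        """With jittered synthetic batches, exactly the contaminant bins
        whose realized occurrence exceeds 10% are removed."""
        accs = sorted(small_db) * 3     # 60 lists
        batch, _ = synthetic.make_peak_lists(
            small_db, accs, detect_prob=0.7, ppm_jitter=10.0,
            n_background=5, background_occurrence=0.15, seed=7)
        # realized occurrence of each planted contaminant mass
        rng_pool = synthetic._rng("peaks", 7)
        pool = rng_pool.uniform(800.0, 3000.0, 5)
        frequent = []
        for m in pool:
            hits = sum(np.any(np.abs(pl.mz / m - 1.0) < 2e-4)
                       for pl in batch)
            if hits / len(batch) > 0.10:
                frequent.append(m)
        assert frequent, "fixture should plant at least one frequent bin"
        _, report = pmf.filter_background(batch, 0.10, 100.0)
        for m in frequent:
            assert np.any(np.abs(report["bin_mz"] / m - 1.0) < 2e-4)


class TestScoring:
    def test_planted_identity_ranks_first(self, small_db, config):
        acc = sorted(small_db)[0]
        batch, _ = synthetic.make_peak_lists(
            small_db, [acc], detect_prob=1.0, ppm_jitter=0.0,
            n_background=0, background_occurrence=0.0, seed=1)
        results = pmf.score_candidates(batch[0], small_db, config)
        best = results[0]
        assert best.accession == acc
        assert (best.rank1, best.rank2, best.rank3) == (1, 1, 1)
        assert best.consensus

    def test_no_match_spectrum(self, toy_db, config):
        peaks = PeakList("none", np.array([810.123]), np.array([1.0]))
        results = pmf.score_candidates(peaks, toy_db, config)
        assert all(r.score1 == 0 and r.score2 == 0 and r.score3 == 0
                   for r in results)
        assert not any(r.consensus for r in results)
        assert pmf.best_identification(peaks, toy_db, config) is None

    def test_shared_peptides_toy_ranking(self, toy_db, config):
        """P1 owns three tryptic peptides of which P2 shares the first
        two, so a spectrum of all three ranks P1 first by shared peaks
        (3 vs 2)."""
        masses = [pmf.peptide_mz(p, config, 0)[0]
                  for p in ("ELVISLIVESK", "GENTLYWINGSR",
                            "DAVIDWASHAPPYK")]
        peaks = PeakList("toy", np.array(sorted(masses)), np.ones(3))
        results = {r.accession: r
                   for r in pmf.score_candidates(peaks, toy_db, config)}
        assert results["P1"].score1 == 3
        assert results["P2"].score1 == 2
        assert results["P1"].rank1 < results["P2"].rank1

    def test_scorer1_equals_match_count(self, small_db, config):
        acc = sorted(small_db)[3]
        batch, _ = synthetic.make_peak_lists(
            small_db, [acc], detect_prob=0.8, ppm_jitter=5.0,
            n_background=3, background_occurrence=1.0, seed=5)
        index = pmf.DigestIndex(small_db, config)
        for r in pmf.score_candidates(batch[0], index, config):
            theo = [t.mz for t in index.entries[r.accession]]
            assert r.score1 == len(pmf.match_peaks(batch[0], theo,
                                                   config.tolerance_ppm))

    def test_empty_peak_list_yields_no_identification(self, toy_db):
        peaks = PeakList("empty", np.array([]), np.array([]))
        assert pmf.best_identification(peaks, toy_db) is None


class TestMrPi:
    def test_termini_only_pi(self):
        pka = {"nterm": 9.6, "cterm": 2.34}
        assert pmf.isoelectric_point("G", pka) == \
            pytest.approx(5.97, abs=0.01)

    @pytest.mark.parametrize("seq", ["GHKR", "ELVISK", "DEADCAT"
                                     .replace("T", "Y")])
    def test_charge_at_ph0(self, seq):
        expected = 1 + sum(seq.count(aa) for aa in "HKR")
        assert pmf.net_charge(seq, 0.0) == pytest.approx(expected,
                                                         abs=1e-3)

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_charge_strictly_decreasing(self, seq):
        grid = np.linspace(0.0, 14.0, 30)
        charges = [pmf.net_charge(seq, ph) for ph in grid]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_check_mr_pi_consistent(self, toy_db):
        seq = toy_db["P1"]
        mr, pi = pmf.protein_mr_kda(seq), pmf.isoelectric_point(seq)
        assert pmf.check_mr_pi("P1", mr * 1.1, pi + 0.5, toy_db)
        assert not pmf.check_mr_pi("P1", mr * 1.5, pi, toy_db)
        assert not pmf.check_mr_pi("P1", mr, pi + 1.5, toy_db)

    def test_missing_accession(self, toy_db):
        with pytest.raises(KeyError):
            pmf.check_mr_pi("NOPE", 30.0, 6.0, toy_db)
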