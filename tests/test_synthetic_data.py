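import numpy as np
import pytest

from pepmine import synthetic_data as sd
from pepmine.composition_features import aa_composition
from pepmine.physchem import net_charge
from pepmine.translate_scan import translate_frame


class TestClassProfiles:
    def test_default_profiles_are_valid(self):
        for prof in (sd.acp_profile(), sd.amp_negative_profile(),
                     sd.random_profile()):
            f = np.array(prof.target_freqs)
            assert f.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(f >= 0)

    def test_acp_profile_shifts(self):
        f = dict(zip("ACDEFGHIKLMNPQRSTVWY", sd.acp_profile().target_freqs))
        assert f["K"] == pytest.approx(0.10)
        assert f["L"] == pytest.approx(0.10)
        assert f["D"] == pytest.approx(0.02)
        assert f["C"] == pytest.approx(0.04)  # rebalanced residue

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            sd.ClassProfile("X", tuple([0.1] * 20))  # sums to 2
        with pytest.raises(ValueError):
            sd.ClassProfile("X", tuple([0.05] * 20), length_range=(3, 10))


class TestTrainingSets:
    def test_degenerate_profile_gives_homopolymers(self):
        freqs = [0.0] * 20
        freqs[8] = 1.0  # K
        prof = sd.ClassProfile("ACP", tuple(freqs))
        peps = sd.simulate_training_sets([prof], 3, seed=0)["ACP"]
        assert len(peps) == 3
        assert all(set(p) == {"K"} for p in peps)

    def test_seed_determinism(self):
        profs = [sd.acp_profile(), sd.random_profile()]
        a = sd.simulate_training_sets(profs, 10, seed=42)
        b = sd.simulate_training_sets(profs, 10, seed=42)
        assert a == b

    def test_empirical_composition_tracks_targets(self):
        acp = sd.profile_from_deltas("ACP", {"K": 0.10})
        rnd = sd.random_profile()
        sets = sd.simulate_training_sets([acp, rnd], 225, seed=3)
        for prof, label in ((acp, "ACP"), (rnd, "RANDOM")):
            mean = np.mean([aa_composition(p) for p in sets[label]], axis=0)
            k = "ACDEFGHIKLMNPQRSTVWY".index("K")
            assert abs(mean[k] - prof.target_freqs[k]) < 0.02

    def test_composition_fidelity_over_seeds(self):
        """Empirical class means stay within 0.03 of targets (10 seeds)."""
        prof = sd.acp_profile()
        worst = 0.0
        for seed in range(10):
            peps = sd.simulate_training_sets([prof], 200, seed=seed)["ACP"]
            mean = np.mean([aa_composition(p) for p in peps], axis=0)
            worst = max(worst, float(np.max(np.abs(mean - prof.target_freqs))))
        assert worst <= 0.03

    def test_lengths_respect_range(self):
        prof = sd.acp_profile(length_range=(7, 9))
        peps = sd.simulate_training_sets([prof], 50, seed=1)["ACP"]
        assert all(7 <= len(p) <= 9 for p in peps)


class TestReverseTranslate:
    @pytest.mark.parametrize("pep, dna", [("M", "ATG"), ("W", "TGG")])
    def test_single_codon_residues(self, pep, dna):
        assert sd.reverse_translate(pep, seed=0) == dna

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
        dna = sd.reverse_translate(pep, seed=seed)
        assert len(dna) == 3 * len(pep)
        assert translate_frame(dna, 1) == pep

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            sd.reverse_translate("AXB")


class TestMetagenome:
    def test_no_plants_empty_truth(self):
        cfg = sd.SimulationConfig(seed=0, n_reads=20, n_planted=0)
        reads, truth = sd.simulate_metagenome(cfg)
        assert len(reads) == 20 and truth.empty

    def test_byte_identical_under_seed(self):
        cfg = sd.SimulationConfig(seed=9, n_reads=50, n_planted=3)
        r1, t1 = sd.simulate_metagenome(cfg)
        r2, t2 = sd.simulate_metagenome(cfg)
        assert r1 == r2
        assert t1.equals(t2)

    def test_truth_coordinates_consistent(self):
        cfg = sd.SimulationConfig(seed=2, n_reads=30, n_planted=10)
        reads, truth = sd.simulate_metagenome(cfg)
        by_id = {r.read_id: r for r in reads}
        for row in truth.itertuples():
            assert row.read_end - row.read_start + 1 == 3 * len(row.peptide_sequence)

    def test_plants_recoverable_at_zero_error(self):
        """Translating the recorded interval at the recorded frame recovers
        every planted peptide exactly, on forward and reverse strands."""
        cfg = sd.SimulationConfig(seed=5, n_reads=40, n_planted=20)
        reads, truth = sd.simulate_metagenome(cfg)
        by_id = {r.read_id: r for r in reads}
        frames_seen = set()
        for row in truth.itertuples():
            read = by_id[row.read_id]
            frames_seen.add(row.frame)
            sub = read.bases[row.read_start - 1:row.read_end]
            if row.frame < 0:
                from pepmine.translate_scan import reverse_complement

                sub = reverse_complement(sub)
            assert translate_frame(sub, 1) == row.peptide_sequence
            # and the full-read frame translation contains the plant
            assert row.peptide_sequence in translate_frame(read.bases, row.frame)
        assert any(f < 0 for f in frames_seen)  # reverse strand exercised

    def test_plants_are_cationic_by_default(self):
        cfg = sd.SimulationConfig(seed=6, n_reads=20, n_planted=10)
        _, truth = sd.simulate_metagenome(cfg)
        assert all(net_charge(p) > 0 for p in truth.peptide_sequence)

    def test_substitution_errors_applied(self):
        cfg_clean = sd.SimulationConfig(seed=4, n_reads=20, n_planted=0)
        cfg_noisy = sd.SimulationConfig(seed=4, n_reads=20, n_planted=0,
                                        substitution_error_rate=0.05)
        clean, _ = sd.simulate_metagenome(cfg_clean)
        noisy, _ = sd.simulate_metagenome(cfg_noisy)
        diffs = sum(a != b for r1, r2 in zip(clean, noisy)
                    for a, b in zip(r1.bases, r2.bases))
        assert diffs > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(n_reads=5, n_planted=6)
        with pytest.raises(ValueError):
            sd.SimulationConfig(substitution_error_rate=1.5)
        with pytest.raises(ValueError):
            sd.SimulationConfig(read_length_mean=60.0,
                                plant_length_range=(25, 30))

    def test_quality_model_end_decay(self):
        cfg = sd.SimulationConfig(seed=1, n_reads=10, n_planted=0)
        reads, _ = sd.simulate_metagenome(cfg)
        q = np.array(reads[0].qualities)
        mid = q[15:-15].mean()
        ends = np.concatenate([q[:3], q[-3:]]).mean()
        assert mid - ends > 4  # linear decay toward the ends
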