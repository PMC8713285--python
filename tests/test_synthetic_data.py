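import json

import numpy as np
import pytest

from cystmine.mining import framework_of
from cystmine.peptide_mass import monoisotopic_mass, mz
from cystmine.seq_core import reverse_complement, translate
from cystmine.synthetic_data import (
    CONSERVED_UTR3,
    SimConfig,
    TruthManifest,
    encode_transcript,
    make_peak_list,
    make_precursor,
    simulate,
    write_bundle,
)


class TestSimConfig:
    def test_seed_required(self):
        with pytest.raises(TypeError):
            SimConfig()

    def test_mutation_rate_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, core_mutation_rate=1.5)

    def test_gc_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, gc_decoy_modes=((0.4, 0.3), (0.6, 0.3)))

    def test_named_substreams_differ(self):
        cfg = SimConfig(seed=1)
        a = cfg.rng("precursors").integers(1 << 30)
        b = cfg.rng("codons").integers(1 << 30)
        assert a != b

    def test_substreams_reproducible(self):
        assert (SimConfig(seed=1).rng("x").integers(1 << 30)
                == SimConfig(seed=1).rng("x").integers(1 << 30))


class TestMakePrecursor:
    def test_zero_mutation_core_equals_template(self, sim_config):
        cfg = sim_config(core_mutation_rate=0.0)
        protein, prov = make_precursor(cfg, cfg.rng("p"))
        assert prov["core"] == cfg.core_template.sequence
        assert prov["mutations"] == ()
        assert protein.endswith(prov["core"])

    def test_leader_ends_in_ala(self, sim_config):
        cfg = sim_config()
        for i in range(20):
            _, prov = make_precursor(cfg, cfg.rng(f"p{i}"))
            assert prov["leader"].endswith("A")

    @pytest.mark.parametrize("mode,expected", [
        ("short", 19), ("long105", 105), ("long112", 112),
    ])
    def test_leader_modes(self, sim_config, mode, expected):
        cfg = sim_config(leader_mode=mode)
        _, prov = make_precursor(cfg, cfg.rng("p"))
        assert len(prov["leader"]) == expected

    def test_framework_preserved_across_seeded_draws(self, sim_config):
        cfg = sim_config(core_mutation_rate=0.4, preserve_framework=True)
        fw = framework_of(cfg.core_template)
        rng = cfg.rng("many")
        for _ in range(100):
            _, prov = make_precursor(cfg, rng)
            assert framework_of(prov["core"]) == fw

    def test_unpreserved_framework_can_break(self, sim_config):
        cfg = sim_config(core_mutation_rate=0.8, preserve_framework=False)
        rng = cfg.rng("many")
        fw = framework_of(cfg.core_template)
        broken = 0
        for _ in range(50):
            _, prov = make_precursor(cfg, rng)
            try:
                if framework_of(prov["core"]) != fw:
                    broken += 1
            except ValueError:
                broken += 1
        assert broken > 0


class TestEncodeTranscript:
    def _encode(self, cfg, stream="c"):
        protein, prov = make_precursor(cfg, cfg.rng("p"))
        return protein, encode_transcript(
            protein, prov, cfg, cfg.rng(stream), "t1", "pep"
        )

    def test_round_trip_translation(self, sim_config):
        cfg = sim_config()
        protein, (rec, truth) = self._encode(cfg)
        lo, hi = truth.orf_nt_span
        nt = rec.sequence[lo:hi]
        if truth.frame < 0:
            nt = reverse_complement(nt)
        assert translate(nt) == protein

    def test_different_codon_streams_same_protein(self, sim_config):
        cfg = sim_config()
        p1, (rec1, t1) = self._encode(cfg, "c1")
        p2, (rec2, t2) = self._encode(cfg, "c2")
        assert p1 == p2
        assert rec1.sequence != rec2.sequence

    def test_conserved_utr3_present(self, sim_config):
        cfg = sim_config()
        _, (rec, truth) = self._encode(cfg)
        seq = rec.sequence
        if truth.frame < 0:
            seq = reverse_complement(seq)
        assert CONSERVED_UTR3 in seq

    def test_polya_at_least_min(self, sim_config):
        cfg = sim_config()
        _, (rec, truth) = self._encode(cfg)
        assert truth.polya_len >= cfg.polya_min
        seq = rec.sequence
        if truth.frame < 0:
            seq = reverse_complement(seq)
        assert seq.endswith("A" * truth.polya_len)

    def test_flipped_records_get_minus_frame(self, sim_config):
        cfg = sim_config()
        frames = set()
        for i in range(20):
            protein, prov = make_precursor(cfg, cfg.rng("p"))
            _, truth = encode_transcript(
                protein, prov, cfg, cfg.rng(f"c{i}"), "t", "pep"
            )
            frames.add(np.sign(truth.frame))
        assert frames == {-1, 1}


class TestMakePeakList:
    def test_exact_reference_peak_without_jitter(self, sim_config,
                                                 barrettide_c):
        cfg = sim_config(mz_jitter_sd=0.0, peak_noise_count=0,
                         peak_charges=(2,))
        pl, planted = make_peak_list([barrettide_c], cfg, cfg.rng("pk"))
        assert len(pl.peaks) == 1
        assert round(pl.peaks[0][0], 4) == 1619.6808
        assert planted[0].charge == 2

    def test_noise_only(self, sim_config):
        cfg = sim_config(peak_noise_count=1000)
        pl, planted = make_peak_list([], cfg, cfg.rng("pk"))
        assert len(pl.peaks) == 1000
        assert planted == []

    def test_scan_range_bounds_noise_peaks(self, sim_config):
        # planted ions may exceed the scan range at low charge (the m/z of
        # a 3.2 kDa peptide at z<=2 does); noise must stay inside it
        cfg = sim_config(peak_noise_count=500)
        pl, _ = make_peak_list([], cfg, cfg.rng("pk"))
        assert all(50 <= p[0] <= 1500 for p in pl.peaks)

    def test_jitter_moves_peaks(self, sim_config, barrettide_c):
        cfg = sim_config(mz_jitter_sd=0.01, peak_noise_count=0,
                         peak_charges=(2,))
        pl, planted = make_peak_list([barrettide_c], cfg, cfg.rng("pk"))
        assert pl.peaks[0][0] != pytest.approx(planted[0].true_mz, abs=1e-9)
        assert pl.peaks[0][0] == pytest.approx(planted[0].true_mz, abs=0.1)


class TestSimulateBundle:
    def test_deterministic_byte_identical(self, sim_config, tmp_path):
        cfg = sim_config(seed=123)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_bundle(simulate(cfg), d1)
        p2 = write_bundle(simulate(cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, sim_config):
        b1 = simulate(sim_config(seed=1))
        b2 = simulate(sim_config(seed=2))
        assert (b1.transcripts[0].sequence != b2.transcripts[0].sequence)

    def test_counts(self, sim_config):
        cfg = sim_config(n_decoys=7, n_precursors=2)
        b = simulate(cfg)
        assert len(b.transcripts) == 9
        assert len(b.genomic) == 2
        assert len(b.manifest.transcripts) == 2

    def test_manifest_round_trip(self, sim_config, tmp_path):
        b = simulate(sim_config())
        path = tmp_path / "m.json"
        b.manifest.to_json(path)
        loaded = TruthManifest.from_json(path)
        assert loaded.transcripts == b.manifest.transcripts
        assert loaded.peaks == b.manifest.peaks

    def test_planted_peaks_match_mass_model(self, sim_config):
        b = simulate(sim_config(core_mutation_rate=0.0))
        template = b.config.core_template
        expected = {
            round(mz(monoisotopic_mass(template.sequence,
                                       template.n_disulfides), z), 6)
            for z in b.config.peak_charges
        }
        planted = {round(p.true_mz, 6) for p in b.manifest.peaks}
        assert planted == expected
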