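import numpy as np
import pytest

from glacierpace import molevo
from glacierpace import synthetic_data as synth
from glacierpace.synthetic_data import BurstSimConfig


class TestBurstSimConfig:
    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            BurstSimConfig(seed=0, pi=(0.5, 0.5, 0.5, 0.5))

    def test_increasing_burst_times_rejected(self):
        with pytest.raises(ValueError):
            BurstSimConfig(seed=0, burst_times=(1e5, 2e5))

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            BurstSimConfig(seed=0, n_codons=10)


class TestBurstFamily:
    def test_no_bursts_yields_single_copy(self):
        records, history = synth.simulate_burst_family(BurstSimConfig(seed=5))
        assert len(records) == 1
        assert history.events == ()

    def test_event_times_match_bursts(self):
        times = tuple(2.6e5 * k for k in range(5, 0, -1))
        cfg = BurstSimConfig(seed=2, n_codons=60, burst_times=times,
                             copies_per_burst=3)
        _, history = synth.simulate_burst_family(cfg)
        assert set(history.event_times) == set(times)
        assert len(history.events) == 5 * 3

    def test_tip_count_is_one_plus_duplications(self):
        cfg = BurstSimConfig(seed=9, n_codons=60, burst_times=(3e5, 1e5),
                             copies_per_burst=4, extra_root_copies=2)
        records, history = synth.simulate_burst_family(cfg)
        assert len(records) == 1 + 2 + len(history.events)
        assert set(r.id for r in records) == set(history.tip_ids)

    def test_same_seed_byte_identical(self):
        cfg = BurstSimConfig(seed=42, n_codons=100, burst_times=(2e5,),
                             copies_per_burst=2)
        a, _ = synth.simulate_burst_family(cfg)
        b, _ = synth.simulate_burst_family(cfg)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_omega_zero_preserves_protein(self):
        cfg = BurstSimConfig(seed=3, n_codons=200, mu_year=1e-7, omega=0.0,
                             burst_times=(5e5,), copies_per_burst=1)
        records, _ = synth.simulate_burst_family(cfg)
        proteins = set()
        for rec in records:
            prot = "".join(
                molevo.GENETIC_CODE[rec.seq[i:i + 3]] for i in range(0, len(rec.seq), 3)
            )
            proteins.add(prot)
        assert len(proteins) == 1

    def test_pairwise_ds_matches_2mut_over_replicates(self):
        """Poisson substitution oracle: two copies split t years ago have
        expected dS = 2*mu*t; checked on the replicate mean."""
        t, mu, n_codons, reps = 2e6, 4e-9, 500, 100
        vals = []
        for seed in range(reps):
            cfg = BurstSimConfig(seed=seed, n_codons=n_codons, mu_year=mu,
                                 omega=0.0, burst_times=(t,), copies_per_burst=1)
            records, _ = synth.simulate_burst_family(cfg)
            vals.append(molevo.ng86_pairwise(records[0].seq, records[1].seq).ds)
        expect = 2 * mu * t
        assert np.mean(vals) == pytest.approx(expect, rel=0.12)

    def test_pseudogenization_allows_stops(self):
        cfg = BurstSimConfig(seed=8, n_codons=300, mu_year=5e-8, omega=0.0,
                             burst_times=(2e6,), copies_per_burst=2,
                             pseudogenization_rate=1e-5)
        records, _ = synth.simulate_burst_family(cfg)
        has_stop = any(
            molevo.GENETIC_CODE[r.seq[i:i + 3]] == "*"
            for r in records for i in range(0, len(r.seq) - 3, 3)
        )
        assert has_stop


class TestNullFamily:
    def test_shapes_and_determinism(self):
        a = synth.simulate_null_family(seed=4, n_tips=4, n_codons=80, tree_depth=0.01)
        b = synth.simulate_null_family(seed=4, n_tips=4, n_codons=80, tree_depth=0.01)
        assert len(a) == 4
        assert all(len(r.seq) == 240 for r in a)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_base_composition_near_pi(self):
        # law of large numbers over >= 1e5 sites
        recs = synth.simulate_null_family(seed=3, n_tips=4, n_codons=12000,
                                          tree_depth=0.02)
        allseq = "".join(r.seq for r in recs)
        for base, target in zip("ACGT", synth.NULL_PI):
            assert allseq.count(base) / len(allseq) == pytest.approx(target, abs=0.02)

    def test_realized_dnds_near_two(self):
        # NG86 estimator consistency on long sequences
        recs = synth.simulate_null_family(seed=3, n_tips=6, n_codons=30000,
                                          tree_depth=0.05)
        ratios = []
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                r = molevo.ng86_pairwise(recs[i].seq, recs[j].seq)
                if r.ds is not None and r.ds > 0.01:
                    ratios.append(r.dn / r.ds)
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.2)


class TestCnvCounts:
    def design(self, cn, lib=1e6):
        return synth.CnvDesign(
            samples={"s1": "P1"},
            true_cn={("P1", "fam"): cn},
            gene_lengths={"fam": 1500, "atraid": 1200, "rgs20": 1100},
            library_sizes={"s1": lib},
        )

    def test_zero_copy_number_zero_counts(self):
        tab = synth.simulate_cnv_counts(0, self.design(0.0))
        fam = tab.counts.query("gene == 'fam'")["mapped_reads"]
        assert (fam == 0).all()

    def test_doubling_library_doubles_expected_counts(self):
        reps = 200
        small = np.mean([
            synth.simulate_cnv_counts(s, self.design(2.0, 1e6))
            .counts.query("gene == 'fam'")["mapped_reads"].sum()
            for s in range(reps)
        ])
        big = np.mean([
            synth.simulate_cnv_counts(s, self.design(2.0, 2e6))
            .counts.query("gene == 'fam'")["mapped_reads"].sum()
            for s in range(reps)
        ])
        assert big / small == pytest.approx(2.0, rel=0.1)

    def test_determinism(self):
        a = synth.simulate_cnv_counts(7, self.design(3.0)).counts
        b = synth.simulate_cnv_counts(7, self.design(3.0)).counts
        assert a.equals(b)


class TestClrTrack:
    def test_background_only_top_positions(self):
        track = synth.simulate_clr_track(seed=0, n_positions=1000)
        assert track.positions.size == 1000
        assert track.clr.max() < 15  # exponential background, no bumps

    def test_bump_dominates(self):
        track = synth.simulate_clr_track(seed=0, n_positions=1000,
                                         sweep_centers=(500,), sweep_height=100.0)
        assert track.positions[np.argmax(track.clr)] == pytest.approx(500, abs=5)

    def test_determinism(self):
        a = synth.simulate_clr_track(seed=5, n_positions=500, sweep_centers=(100,))
        b = synth.simulate_clr_track(seed=5, n_positions=500, sweep_centers=(100,))
        assert np.array_equal(a.clr, b.clr)


class TestGlacialCurveSim:
    def test_span_and_step(self):
        curve = synth.synthetic_glacial_curve()
        assert curve.age[0] == 0
        assert curve.age[-1] == pytest.approx(1.8e6)
        assert np.allclose(np.diff(curve.age), 1e3)

    def test_continuous_at_switch(self):
        curve = synth.synthetic_glacial_curve()
        i = np.searchsorted(curve.age, 1.0e6)
        jump = abs(curve.d18o[i] - curve.d18o[i - 1])
        neighbor = abs(curve.d18o[i - 1] - curve.d18o[i - 2])
        assert jump < 3 * neighbor + 1e-9

    def test_fft_dominant_periods_per_regime(self):
        curve = synth.synthetic_glacial_curve()
        for lo, hi, period in [(0, 1.0e6, 1.0e5), (1.0e6, 1.8e6, 4.0e4)]:
            mask = (curve.age >= lo) & (curve.age <= hi)
            x = curve.d18o[mask] - curve.d18o[mask].mean()
            freqs = np.fft.rfftfreq(x.size, d=1e3)
            power = np.abs(np.fft.rfft(x)) ** 2
            fdom = freqs[1:][np.argmax(power[1:])]
            bin_width = freqs[1]
            assert abs(fdom - 1.0 / period) <= bin_width
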