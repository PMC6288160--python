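"""Daily growth-migration-dilution protocol engine."""

import numpy as np
import pytest

from crossprotect import (
    ModelParams,
    PatchState,
    ProtocolParams,
    apply_dilution,
    apply_migration,
    benign_protocol,
    extinction_status,
    run_pair_simulation,
)


class TestMigration:
    def test_m_zero_is_identity(self):
        a = PatchState(100, 50, 10, 8)
        b = PatchState(3, 7, 2, 1)
        a2, b2 = apply_migration(a, b, 0.0)
        assert np.allclose(a2.as_array(), a.as_array())
        assert np.allclose(b2.as_array(), b.as_array())

    def test_full_mixing_at_half(self):
        a = PatchState(100, 0, 10, 0)
        b = PatchState(0, 100, 0, 10)
        a2, b2 = apply_migration(a, b, 0.5)
        assert np.allclose(a2.as_array(), [50, 50, 5, 5])
        assert np.allclose(b2.as_array(), [50, 50, 5, 5])

    def test_ten_percent_exchange_arithmetic(self):
        a = PatchState(100, 0, 0, 0)
        b = PatchState(0, 100, 0, 0)
        a2, b2 = apply_migration(a, b, 0.1)
        assert np.allclose(a2.as_array(), [90, 10, 0, 0])
        assert np.allclose(b2.as_array(), [10, 90, 0, 0])

    @pytest.mark.parametrize("m", [0.0, 0.01, 0.1, 0.37, 0.5])
    def test_pairwise_totals_conserved(self, m):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = PatchState(*rng.uniform(0, 1e4, 4))
            b = PatchState(*rng.uniform(0, 1e4, 4))
            a2, b2 = apply_migration(a, b, m)
            assert np.allclose(
                a2.as_array() + b2.as_array(),
                a.as_array() + b.as_array(),
                rtol=1e-12,
            )

    def test_out_of_range_rate_rejected(self):
        a = PatchState(1, 1, 1, 1)
        with pytest.raises(ValueError):
            apply_migration(a, a, 0.7)


class TestDilution:
    def test_hundredfold_dilution_arithmetic(self):
        proto = benign_protocol()
        out = apply_dilution(PatchState(5000, 2000, 3, 2), proto)
        assert out.N1 == pytest.approx(50.0)
        assert out.N2 == pytest.approx(20.0)

    def test_fresh_antibiotics_without_carryover(self):
        proto = benign_protocol(antibiotic_carryover=False)
        out = apply_dilution(PatchState(5000, 2000, 7, 5), proto)
        assert out.A1 == proto.A1_fresh
        assert out.A2 == proto.A2_fresh

    def test_carryover_adds_diluted_residual(self):
        proto = benign_protocol(antibiotic_carryover=True)
        out = apply_dilution(PatchState(5000, 2000, 7, 5), proto)
        assert out.A1 == pytest.approx(proto.A1_fresh + 7 / proto.D)
        assert out.A2 == pytest.approx(proto.A2_fresh + 5 / proto.D)

    def test_subthreshold_density_zeroed(self):
        proto = benign_protocol()
        out = apply_dilution(PatchState(0.4, 5000, 0, 0), proto)
        assert out.N1 == 0.0  # 0.4/100 < 0.005
        assert out.N2 == pytest.approx(50.0)

    def test_noisy_dilution_reproducible_given_seed(self):
        proto = benign_protocol(noise_cv=0.15)
        s = PatchState(5000, 2000, 3, 2)
        o1 = apply_dilution(s, proto, np.random.default_rng(42))
        o2 = apply_dilution(s, proto, np.random.default_rng(42))
        assert o1 == o2
        o3 = apply_dilution(s, proto, np.random.default_rng(43))
        assert o1 != o3

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            apply_dilution(
                PatchState(1, 1, 1, 1), benign_protocol(noise_cv=0.15)
            )


class TestExtinctionStatus:
    def test_empty_patch_extinct(self):
        st = extinction_status(PatchState(0, 0, 1, 1), 0.005)
        assert st["patch_extinct"]

    def test_one_strain_alive_keeps_patch(self):
        st = extinction_status(PatchState(0.01, 0, 1, 1), 0.005)
        assert not st["patch_extinct"]
        assert st["N2_extinct"] and not st["N1_extinct"]

    def test_boundary_below_threshold(self):
        st = extinction_status(PatchState(0.004, 1, 1, 1), 0.005)
        assert st["N1_extinct"]


class TestRunPairSimulation:
    def test_m_zero_decouples_from_partner(self, model, benign):
        """At m=0 patch A's series is independent of what patch B does."""
        a = PatchState(500, 500, 10, 8)
        b1 = PatchState(900, 100, 10, 8)
        b2 = PatchState(100, 900, 10, 8)
        s1 = run_pair_simulation(a, b1, model, benign, 30)
        s2 = run_pair_simulation(a, b2, model, benign, 30)
        for r1, r2 in zip(s1.records, s2.records):
            assert np.allclose(
                r1.end_state_A.as_array(), r2.end_state_A.as_array()
            )

    def test_identical_patches_stay_identical(self, model, benign):
        init = PatchState(400, 600, 10, 8)
        proto = benign.replace(m=0.1)
        s = run_pair_simulation(init, init, model, proto, 30)
        for r in s.records:
            assert np.allclose(
                r.end_state_A.as_array(), r.end_state_B.as_array()
            )

    def test_deterministic_protocol_bit_reproducible(self, model, benign):
        init = PatchState(400, 600, 10, 8)
        s1 = run_pair_simulation(init, init, model, benign, 20)
        s2 = run_pair_simulation(init, init, model, benign, 20)
        for r1, r2 in zip(s1.records, s2.records):
            assert (
                r1.end_state_A.as_array() == r2.end_state_A.as_array()
            ).all()

    def test_noisy_protocol_reproducible_given_seed(self, model, benign):
        init = PatchState(400, 600, 10, 8)
        proto = benign.replace(noise_cv=0.15, m=0.05)
        s1 = run_pair_simulation(init, init, model, proto, 15, rng_seed=11)
        s2 = run_pair_simulation(init, init, model, proto, 15, rng_seed=11)
        assert np.allclose(
            s1.records[-1].end_state_A.as_array(),
            s2.records[-1].end_state_A.as_array(),
        )

    def test_one_day_reduces_to_affine_map_without_growth(self):
        """With all growth rates zero and no degradation, a protocol day
        is pure mixing + scaling, checkable by hand."""
        frozen = ModelParams(
            gamma1R=1e-12, gamma2R=1e-12, gamma2D=1e-12,
            I12=1.0, I21=1.0, K=1e5, Vmax=1e-15, Km=1.0, c2=1e-15,
            t_lag=1.0,
        )
        proto = ProtocolParams(
            m=0.1, D=100.0, A1_fresh=10.0, A2_fresh=8.0,
            extinction_threshold=1e-9, antibiotic_carryover=False,
        )
        a = PatchState(1000.0, 2000.0, 10.0, 8.0)
        b = PatchState(4000.0, 500.0, 10.0, 8.0)
        s = run_pair_simulation(a, b, frozen, proto, 2)
        start_next = s.start_states[1]  # post-migration, post-dilution
        # hand arithmetic: N1_A' = (0.9*1000 + 0.1*4000)/100 = 13
        got = run_pair_simulation(
            PatchState(*start_next[:4]), PatchState(*start_next[4:]),
            frozen, proto, 1,
        )
        assert s.records[0].end_state_A.N1 == pytest.approx(1000.0, rel=1e-6)
        next_day = got.records[0].end_state_A
        assert next_day.N1 == pytest.approx(13.0, rel=1e-6)
        assert next_day.N2 == pytest.approx((0.9 * 2000 + 0.1 * 500) / 100, rel=1e-6)

    def test_monotone_harshness_at_m_zero(self, model):
        """Raising the chloramphenicol load never extends deterministic
        survival of an isolated pair."""
        init = PatchState(500, 500, 10, 8)
        days = []
        for a2 in [8.0, 12.0, 16.0, 20.0]:
            proto = ProtocolParams(A1_fresh=10.0, A2_fresh=a2)
            init_a = PatchState(500, 500, 10.0, a2)
            s = run_pair_simulation(init_a, init_a, model, proto, 60)
            days.append(s.extinction_day or 61)
        assert all(d1 >= d2 for d1, d2 in zip(days, days[1:]))

    def test_extinction_day_recorded_and_run_stops(self, model, harsh):
        init = PatchState(500, 500, 10, 16)
        s = run_pair_simulation(init, init, model, harsh, 40)
        assert s.extinction_day is not None
        assert s.extinction_day < 40
        assert s.n_days == s.extinction_day
        assert s.records[-1].day == s.extinction_day
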