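import numpy as np
import pytest

from pbftsim import (
    ConfigError,
    ParticleState,
    SimulationConfig,
    SourceModel,
    StoppingPowerModel,
    TransportMedia,
    build_geometry,
    build_sobp,
    builtin_material,
    make_source,
    run,
    sample_source,
    sobp_depth_dose,
    step_proton,
    trace_history,
    transport_alpha,
)
from pbftsim.transport import DepositEvent, ReactionEvent


class TestSource:
    def test_disk_sampling_moments(self, rng):
        src = SourceModel(300.0, 1000.0, np.array([25.0]), np.array([1.0]))
        x, y, e = src.sample_arrays(rng, 100000)
        r2 = x * x + y * y
        assert np.sqrt(r2.max()) <= 300.0
        assert np.all(e == 25.0)
        # uniform-disk moment: E[r^2] = r0^2/2, var(r^2) = r0^4/12
        se = 300.0 ** 2 / np.sqrt(12 * len(r2))
        assert abs(r2.mean() - 300.0 ** 2 / 2) < 3 * se

    def test_sample_source_scalar(self, rng):
        src = SourceModel(300.0, 1000.0, np.array([25.0]), np.array([1.0]))
        s = sample_source(src, rng)
        assert s.species == "proton" and s.energy == 25.0
        assert s.position[2] == 1000.0
        assert np.allclose(s.direction, [0, 0, -1])


class TestSOBP:
    def test_single_point_is_pristine_peak(self):
        src = build_sobp(80.0, 1, builtin_material("buffer"))
        assert src.energies.tolist() == [80.0]
        assert src.weights.tolist() == [1.0]

    def test_plateau_flat_within_five_percent(self):
        buf = builtin_material("buffer")
        src = build_sobp(80.0, 25, buf)
        model = StoppingPowerModel(buf, "proton")
        r_max = float(model.csda_range(80.0))
        z = np.linspace(0.0, 1.03 * r_max, 900)
        total = sobp_depth_dose(src.energies, src.weights, buf, z)
        r_min = float(model.csda_range(src.energies.min()))
        mask = (z >= r_min + 0.02 * r_max) & (z <= r_max - 0.015 * r_max)
        plateau = total[mask]
        assert (plateau.max() - plateau.min()) / plateau.mean() <= 0.05

    def test_distal_edge_at_csda_range(self):
        buf = builtin_material("buffer")
        src = build_sobp(80.0, 15, buf)
        model = StoppingPowerModel(buf, "proton")
        r_max = float(model.csda_range(80.0))  # g/cm2 == cm in water
        z = np.linspace(0.0, 1.15 * r_max, 2000)
        total = sobp_depth_dose(src.energies, src.weights, buf, z)
        plateau_level = np.median(total[(z > 0.8 * r_max) & (z < 0.97 * r_max)])
        distal = z[np.where(total > 0.5 * plateau_level)[0][-1]]
        assert distal == pytest.approx(r_max, rel=0.03)

    def test_weights_normalized(self):
        src = build_sobp(70.0, 12, builtin_material("buffer"))
        assert src.weights.sum() == pytest.approx(1.0)
        assert np.all(src.weights >= 0)


class TestStepProton:
    def test_single_step_deposits_in_buffer(self, rng):
        cfg = SimulationConfig(n=3, e0=25.0, seed=1)
        geom = build_geometry(cfg)
        media = TransportMedia(cfg)
        state = ParticleState("proton", 25.0, np.array([0.0, 0.0, 999.0]),
                              np.array([0.0, 0.0, -1.0]))
        events, new = step_proton(state, geom, media, rng)
        deps = [e for e in events if isinstance(e, DepositEvent)]
        assert deps and deps[0].region == ("buffer",)
        assert new.energy < 25.0
        assert new.position[2] < 1000.0

    def test_hydrogen_only_never_reacts(self, rng):
        cfg = SimulationConfig(n=3, e0=25.0, tbuffer=500.0, seed=2,
                               cytob=1, nuclb=1, watb=1, r0=0.04)
        geom = build_geometry(cfg)
        media = TransportMedia(cfg, hydrogen_only=True)
        for h in range(50):
            src = make_source(cfg, media)
            s = sample_source(src, rng)
            events, _ = trace_history(s, geom, media, rng)
            assert not any(isinstance(e, ReactionEvent) for e in events)

    def test_full_absorption_without_cross_sections(self, rng):
        # hydrogen world with a buffer deeper than the proton range:
        # every MeV ends up deposited, nothing escapes.  r0 is kept inside
        # the small array footprint so the beam cannot miss the buffer.
        cfg = SimulationConfig(n=3, e0=20.0, tbuffer=6000.0, seed=3, r0=0.04)
        geom = build_geometry(cfg)
        media = TransportMedia(cfg, hydrogen_only=True)
        src = make_source(cfg, media)
        s = sample_source(src, rng)
        _, ledger = trace_history(s, geom, media, rng)
        assert ledger["deposited"] == pytest.approx(20.0, abs=1e-9)
        assert ledger["escaped"] == 0.0

    def test_thin_target_reaction_rate_matches_analytic(self):
        """Reaction count in a thin slab follows 1 - exp(-Sigma ds)."""
        cfg = SimulationConfig(n=2, e0=8.0, tbuffer=30.0, r0=0.02,
                               maxcas=1500000, maxbch=2, seed=21)
        media = TransportMedia(cfg)
        model = media.proton_model(0)
        r8 = float(model.csda_range(8.0))
        e_exit = float(model.energy_from_range(r8 - 1.0 * 30e-4))
        e_mid = 0.5 * (8.0 + e_exit)
        sigma = float(media.sigma_total(0, e_mid))
        p = -np.expm1(-sigma * 30e-4)
        res = run(cfg)
        n_hist = cfg.maxcas * cfg.maxbch
        expected = n_hist * p
        observed = res.counter_total("rx_buffer")
        assert abs(observed - expected) <= 3 * np.sqrt(expected)


class TestTransportAlpha:
    def test_low_energy_alpha_contained_in_nucleus(self, small_geometry,
                                                   default_media):
        state = ParticleState("alpha", 0.5, np.array([0.0, 0.0, -15.0]),
                              np.array([1.0, 0.0, 0.0]))
        segs = transport_alpha(state, small_geometry, default_media)
        assert all(s.region == ("cell", 1, 1, "nucleus") for s in segs)
        assert sum(s.e_deposit for s in segs) == pytest.approx(0.5)

    def test_energy_conservation_across_segments(self, small_geometry,
                                                 default_media):
        state = ParticleState("alpha", 6.0, np.array([0.0, 0.0, 10.0]),
                              np.array([0.0, 0.0, -1.0]))
        segs = transport_alpha(state, small_geometry, default_media)
        assert len(segs) >= 3  # buffer, cytoplasm, nucleus at least
        total = sum(s.e_deposit for s in segs)
        assert total == pytest.approx(6.0, abs=1e-6)  # stops inside

    def test_matches_fine_step_euler_slowing(self, small_geometry,
                                             default_media):
        """Per-segment deposits against a 10 nm Euler integration."""
        geom, media = small_geometry, default_media
        state = ParticleState("alpha", 6.0, np.array([0.0, 0.0, 10.0]),
                              np.array([0.0, 0.0, -1.0]))
        segs = transport_alpha(state, geom, media)

        # independent oracle: explicit Euler march over the same column
        ds = 0.01  # µm
        z, e = 10.0, 6.0
        dep = {}
        while e > 1e-4:
            region = geom.locate((0.0, 0.0, z - ds / 2))
            if region == ("escaped",):
                break
            mid = media.material_id(region, geom)
            s = float(media.alpha_model(mid).stopping_power(max(e, 1e-3)))
            de = min(s * media.rho[mid] * ds * 1e-4, e)
            dep[region] = dep.get(region, 0.0) + de
            e -= de
            z -= ds
        by_region = {}
        for seg in segs:
            by_region[seg.region] = by_region.get(seg.region, 0.0) \
                + seg.e_deposit
        for region, expected in dep.items():
            assert by_region[region] == pytest.approx(expected, rel=0.01)


class TestRun:
    def test_zero_histories_rejected(self):
        with pytest.raises(ConfigError, match="maxcas"):
            SimulationConfig(maxcas=0)

    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n=5, e0=25.0, tbuffer=500.0, maxcas=5000,
                               maxbch=2, cytob=2, nuclb=1, seed=42)
        a = run(cfg)
        b = run(cfg)
        for sp in ("proton", "alpha"):
            assert np.array_equal(a.cell_dep[sp], b.cell_dep[sp])
            assert np.array_equal(a.buffer_dep[sp], b.buffer_dep[sp])
        assert np.array_equal(a.source_energy, b.source_energy)
        assert a.counters.keys() == b.counters.keys()
        for k in a.counters:
            assert np.array_equal(a.counters[k], b.counters[k])

    def test_fresh_seed_recorded_when_missing(self):
        cfg = SimulationConfig(n=2, maxcas=100, maxbch=1, tbuffer=100.0)
        res = run(cfg)
        assert res.config.seed is not None

    def test_batch_energy_ledger_closes(self):
        cfg = SimulationConfig(n=5, e0=25.0, tbuffer=1000.0, maxcas=20000,
                               maxbch=2, cytob=1, nuclb=1, seed=8)
        res = run(cfg)
        resid = res.conservation_residual()
        # residual per batch is bounded by the per-history tolerance
        assert np.all(np.abs(resid) < 1e-4 * cfg.maxcas)

    def test_more_batches_shrink_standard_error(self):
        base = dict(n=5, e0=25.0, tbuffer=2000.0, maxcas=4000, seed=13)
        few = run(SimulationConfig(maxbch=4, **base))
        many = run(SimulationConfig(maxbch=16, **base))
        _, se_few = few.batch_mean_se(few.buffer_dep["proton"] / few.maxcas)
        _, se_many = many.batch_mean_se(many.buffer_dep["proton"] / many.maxcas)
        assert se_many < se_few
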