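import numpy as np
import pytest

import pbftsim as pb
from pbftsim import (
    AlphaTrack,
    SimulationConfig,
    TrackSegment,
    axial_profile,
    build_geometry,
    count_hits,
    energy_fraction,
    enhancement_factor,
    run,
    track_map,
)
from pbftsim.tallies import HitCountSummary, TallyResults


def _seg(start, end, region, dep, species="alpha"):
    return TrackSegment(np.array(start, float), np.array(end, float),
                        region, species, dep, dep)


@pytest.fixture(scope="module")
def boron_run():
    # boron-rich slow-down scenario: protons cross the fusion resonance
    # inside the loaded cell layer, so alpha events are guaranteed
    from pbftsim import StoppingPowerModel, builtin_material
    model = StoppingPowerModel(builtin_material("buffer"), "proton")
    tbuffer = float(model.csda_range(4.0) - model.csda_range(1.2)) * 1e4
    cfg = SimulationConfig(n=10, e0=4.0, tbuffer=round(tbuffer, 1),
                           maxcas=150000, maxbch=4, cytob=1, nuclb=1,
                           ppm=2e5, r0=0.15, seed=31)
    return run(cfg)


class TestAxialProfile:
    def test_profile_integral_equals_cell_total(self, boron_run):
        prof = axial_profile(boron_run, nbins=30)
        total = boron_run.cell_total_per_source("alpha").mean()
        assert prof.mean.sum() == pytest.approx(total, rel=1e-9)

    def test_synthetic_deep_biased_tracks(self):
        """Hand-built segments land in the constructed depth bins."""
        cfg = SimulationConfig(n=1, maxcas=1, maxbch=2, seed=0)
        res = run(cfg.replace(maxcas=10, tbuffer=100.0))
        # replace tracks with two synthetic ones of known z extents
        res.alpha_tracks = [
            AlphaTrack(0, 0, 2.0, ("cell", 0, 0, "cytoplasm"),
                       [_seg((0, 0, -2), (0, 0, -8), ("cell", 0, 0,
                                                      "cytoplasm"), 2.0)]),
            AlphaTrack(1, 0, 1.0, ("cell", 0, 0, "nucleus"),
                       [_seg((0, 0, -25), (0, 0, -28), ("cell", 0, 0,
                                                        "cytoplasm"), 1.0)]),
        ]
        prof = axial_profile(res, nbins=30)
        # bins are 1 µm; first track spreads 2 MeV uniformly over z -2..-8
        per_src = 1.0 / res.maxcas
        shallow = prof.mean[(prof.depth_um < -2) & (prof.depth_um > -8)]
        assert np.allclose(shallow, (2.0 / 6.0) * per_src / 2)
        deep = prof.mean[(prof.depth_um < -25) & (prof.depth_um > -28)]
        assert np.allclose(deep, (1.0 / 3.0) * per_src / 2)
        assert prof.mean.sum() == pytest.approx(3.0 * per_src / 2)

    def test_single_batch_warns(self):
        cfg = SimulationConfig(n=2, maxcas=100, maxbch=1, tbuffer=100.0,
                               seed=1)
        res = run(cfg)
        with pytest.warns(UserWarning, match="single batch"):
            prof = axial_profile(res)
        assert np.all(np.isnan(prof.se))


class TestHitCounts:
    def test_hand_countable_crossings(self, small_geometry):
        g = small_geometry
        tracks = [
            # crosses centre cell cytoplasm then nucleus: 1 + 1 hits
            AlphaTrack(0, 0, 5.0, ("cell", 1, 1, "cytoplasm"), [
                _seg((0, 0, -5), (0, 0, -10), ("cell", 1, 1, "cytoplasm"), 1.0),
                _seg((0, 0, -10), (0, 0, -18), ("cell", 1, 1, "nucleus"), 2.0),
            ]),
            # confined to the buffer: 0 hits
            AlphaTrack(0, 1, 1.0, ("buffer",), [
                _seg((0, 0, 500), (0, 0, 490), ("buffer",), 1.0),
            ]),
            # re-enters the same nucleus twice: still one hit per subdomain
            AlphaTrack(0, 2, 3.0, ("cell", 1, 1, "nucleus"), [
                _seg((0, 0, -12), (2, 0, -14), ("cell", 1, 1, "nucleus"), 1.0),
                _seg((2, 0, -14), (8, 0, -15), ("cell", 1, 1, "cytoplasm"), 0.5),
                _seg((8, 0, -15), (4, 0, -16), ("cell", 1, 1, "nucleus"), 1.0),
            ]),
            # crosses two neighbouring cells' cytoplasm: 2 cytoplasm hits
            AlphaTrack(0, 3, 2.0, ("cell", 0, 1, "cytoplasm"), [
                _seg((-20, 0, -25), (-16, 0, -25), ("cell", 0, 1,
                                                    "cytoplasm"), 0.5),
                _seg((-14, 0, -25), (-10, 0, -25), ("cell", 1, 1,
                                                    "cytoplasm"), 0.5),
            ]),
        ]
        hits = count_hits(tracks, g)
        assert hits.nucleus == 2
        assert hits.cytoplasm == 4

    def test_summary_bounds_ordered_and_order_invariant(self):
        runs = [3, 7, 5]
        s = HitCountSummary(nucleus=(min(runs), np.mean(runs), max(runs)),
                            cytoplasm=(0, 0, 0))
        assert s.nucleus == (3, 5.0, 7)
        with pytest.raises(ValueError):
            HitCountSummary(nucleus=(5, 4, 6), cytoplasm=(0, 0, 0))


class TestEnhancementFactor:
    def test_identity_is_exactly_one(self, boron_run):
        ef = enhancement_factor(boron_run, boron_run)
        assert ef.value == 1.0
        assert ef.mean_of_ratios == 1.0

    def test_doubled_deposition_gives_two(self, boron_run):
        import copy
        doubled = copy.copy(boron_run)
        doubled.cell_dep = {k: 2 * v for k, v in boron_run.cell_dep.items()}
        ef = enhancement_factor(doubled, boron_run)
        assert ef.value == pytest.approx(2.0)
        assert ef.mean_of_ratios == pytest.approx(2.0)

    def test_zero_denominator_flagged(self, boron_run):
        import copy
        empty = copy.copy(boron_run)
        empty.cell_dep = {k: 0 * v for k, v in boron_run.cell_dep.items()}
        ef = enhancement_factor(boron_run, empty)
        assert not ef.defined


class TestEnergyFraction:
    def test_limits_and_arithmetic(self, boron_run):
        import copy
        res = copy.copy(boron_run)
        shape = boron_run.cell_dep["alpha"].shape
        res.cell_dep = {"proton": np.zeros(shape), "alpha": np.zeros(shape),
                        "recoil": np.zeros(shape)}
        res.cell_dep["alpha"][0, 0, 0, 0] = 1.0
        assert energy_fraction(res).total == 1.0
        res2 = copy.copy(res)
        res2.cell_dep = dict(res.cell_dep)
        res2.cell_dep["alpha"] = np.zeros(shape)
        res2.cell_dep["proton"] = np.ones(shape)
        assert energy_fraction(res2).total == 0.0
        res3 = copy.copy(res)
        res3.cell_dep = dict(res.cell_dep)
        a = np.zeros(shape); a[0, 0, 0, 0] = 1.0
        p = np.zeros(shape); p[0, 0, 0, 0] = 3.0
        res3.cell_dep["alpha"], res3.cell_dep["proton"] = a, p
        assert energy_fraction(res3).total == pytest.approx(0.25)

    def test_real_run_fraction_in_unit_interval(self, boron_run):
        f = energy_fraction(boron_run)
        assert 0.0 <= f.total <= 1.0 and f.defined


class TestTrackMap:
    def test_axial_proton_fills_single_pixel_column(self):
        segs = [_seg((0, 0, 100), (0, 0, -30), ("buffer",), 1.0,
                     species="proton")]
        m = track_map(segs, plane="xy", resolution=64, extent=(-320, 320))
        assert (m["proton"] > 0).sum() == 1

    def test_species_layers_separate(self):
        segs = [
            _seg((0, 0, 0), (0, 0, -10), ("buffer",), 1.0, species="proton"),
            _seg((50, 50, 0), (60, 50, 0), ("buffer",), 1.0, species="alpha"),
        ]
        m = track_map(segs, resolution=32, extent=(-100, 100))
        assert set(m) == {"proton", "alpha"}


class TestPersistence:
    def test_results_json_round_trip(self, boron_run, tmp_path):
        p = tmp_path / "res.json"
        boron_run.save(p)
        back = TallyResults.load(p)
        assert np.allclose(back.cell_dep["alpha"],
                           boron_run.cell_dep["alpha"])
        assert back.config == boron_run.config
        assert len(back.alpha_tracks) == len(boron_run.alpha_tracks)
        ef = enhancement_factor(back, boron_run)
        assert ef.value == 1.0
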