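import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbftsim import (
    AMBIENT,
    BUFFER,
    ESCAPED,
    ConfigError,
    SimulationConfig,
    assign_boron,
    build_geometry,
    locate_region,
    render_boron_grid,
)


class TestConfig:
    def test_defaults_follow_reference_scenario(self, default_config):
        c = default_config
        assert (c.n, c.lcell, c.tcell, c.lnuc) == (20, 30.0, 30.0, 10.0)
        assert c.r0 == 0.30 and c.e0 == 25.0

    @pytest.mark.parametrize("field,value", [
        ("n", 0), ("lcell", -1.0), ("lnuc", 30.0), ("e0", 0.0),
        ("ppm", -5.0), ("cytob", 3), ("sobp", 2), ("maxcas", 0),
        ("maxbch", 0), ("boron_threshold", 1.5),
    ])
    def test_invalid_config_names_offending_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**{field: value})

    def test_sobp_requires_two_points(self):
        with pytest.raises(ConfigError, match="nsobp"):
            SimulationConfig(sobp=1, nsobp=1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n=7, e0=42.5, cytob=2, seed=3)
        p = tmp_path / "cfg.yaml"
        cfg.save(p)
        assert SimulationConfig.load(p) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            SimulationConfig.from_dict({"bogus": 1})


class TestBuildGeometry:
    def test_reference_array_has_400_cells(self, default_geometry):
        regions = default_geometry.regions()
        assert len(regions) == 800  # 400 cells x (cytoplasm + nucleus)
        cells = {(r.i, r.j) for r in regions}
        assert len(cells) == 400

    def test_single_cell_array(self):
        cfg = SimulationConfig(n=1)
        g = build_geometry(cfg)
        regions = g.regions()
        assert len(regions) == 2
        total = sum(r.volume for r in regions)
        assert total == pytest.approx(cfg.lcell ** 2 * cfg.tcell)

    def test_confluent_faces_n3(self, small_geometry):
        g = small_geometry
        assert g.half == 45.0
        xs = sorted({g.cell_bounds(i, 0, "cytoplasm")[0] for i in range(3)})
        assert xs == [-45.0, -15.0, 15.0]
        # shared internal faces at +-15 um, array spans [-45, 45)
        assert g.cell_bounds(0, 0, "cytoplasm")[1] == -15.0
        assert g.cell_bounds(1, 0, "cytoplasm")[0] == -15.0

    def test_volume_conservation_per_cell(self, default_geometry):
        by_cell = {}
        for r in default_geometry.regions():
            by_cell.setdefault((r.i, r.j), 0.0)
            by_cell[(r.i, r.j)] += r.volume
        expected = 30.0 ** 3
        for v in by_cell.values():
            assert v == pytest.approx(expected)


class TestAssignBoron:
    def test_mode0_and_mode1(self):
        g0 = build_geometry(SimulationConfig(cytob=0))
        assert g0.boron_fraction == 0.0
        g1 = build_geometry(SimulationConfig(cytob=1))
        assert g1.boron_fraction == 1.0

    def test_mode2_fraction_within_binomial_band(self):
        cfg = SimulationConfig(n=100, cytob=2, seed=5)
        frac = float(np.mean(assign_boron(cfg)))
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 1e4)

    def test_mode2_mean_over_many_seeds(self):
        fractions = [
            float(np.mean(assign_boron(SimulationConfig(n=20, cytob=2,
                                                        seed=s))))
            for s in range(30)
        ]
        n_tot = 400 * 30
        assert abs(np.mean(fractions) - 0.5) <= 3 * np.sqrt(0.25 / n_tot)

    def test_custom_threshold(self):
        cfg = SimulationConfig(n=100, cytob=2, seed=5, boron_threshold=0.1)
        frac = float(np.mean(assign_boron(cfg)))
        assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 1e4)

    def test_seed_reproduces_layout(self):
        cfg = SimulationConfig(n=20, cytob=2, seed=77)
        assert np.array_equal(assign_boron(cfg), assign_boron(cfg))

    def test_nucleus_inherits_only_with_nuclb(self):
        cfg = SimulationConfig(n=4, cytob=1, nuclb=0)
        g = build_geometry(cfg)
        assert all(g.nucleus_boron(i, j) == 0 for i in range(4)
                   for j in range(4))
        g2 = build_geometry(cfg.replace(nuclb=1))
        assert all(g2.nucleus_boron(i, j) == 1 for i in range(4)
                   for j in range(4))


class TestLocateRegion:
    def test_known_points(self, small_geometry):
        g = small_geometry
        # centre cell of a 3x3 array is (1,1); its nucleus spans
        # x,y in [-5,5) and z in [-20,-10) for 30 um cells / 10 um nucleus
        assert locate_region(g, (0, 0, -15)) == ("cell", 1, 1, "nucleus")
        assert locate_region(g, (0, 0, -29)) == ("cell", 1, 1, "cytoplasm")
        assert locate_region(g, (0, 0, 500)) == BUFFER
        assert locate_region(g, (0, 0, -40)) == AMBIENT
        assert locate_region(g, (0, 0, 2e5)) == ESCAPED

    def test_half_open_face_ownership(self, small_geometry):
        g = small_geometry
        # the face x = -15 belongs to the cell on its +x side
        assert locate_region(g, (-15.0, 0, -5)) == ("cell", 1, 1, "cytoplasm")
        assert locate_region(g, (-15.0 - 1e-9, 0, -5))[1] == 0
        # z = 0 belongs to the buffer (cells own [-tcell, 0))
        assert locate_region(g, (0, 0, 0.0)) == BUFFER
        assert locate_region(g, (0, 0, -1e-9))[0] == "cell"

    def test_every_sampled_point_has_unique_region(self, small_geometry):
        g = small_geometry
        rng = np.random.default_rng(0)
        pts = np.column_stack([
            rng.uniform(-44.9, 44.9, 100000),
            rng.uniform(-44.9, 44.9, 100000),
            rng.uniform(-29.9, -0.1, 100000),
        ])
        for p in pts[:2000]:
            r = g.locate(p)
            assert r[0] == "cell"
        # vector check of full coverage: region must never be ambient
        # inside the array bounds
        regions = {g.locate(p)[0] for p in pts[::37]}
        assert regions == {"cell"}

    @settings(deadline=None, max_examples=60)
    @given(x=st.floats(-14.9, 14.9), y=st.floats(-14.9, 14.9),
           z=st.floats(-29.9, -0.1))
    def test_translation_consistency(self, small_geometry, x, y, z):
        g = small_geometry
        r0 = g.locate((x, y, z))
        r1 = g.locate((x + 30.0, y, z))
        assert r1[1] == r0[1] + 1 and r1[2] == r0[2] and r1[3] == r0[3]


class TestRenderGrid:
    def test_uniform_grids(self):
        g1 = build_geometry(SimulationConfig(n=2, cytob=1, nuclb=1))
        assert render_boron_grid(g1).split() == ["B"] * 4
        g0 = build_geometry(SimulationConfig(n=2, cytob=0))
        assert render_boron_grid(g0).split() == ["."] * 4

    def test_random_grid_matches_flags(self):
        cfg = SimulationConfig(n=20, cytob=2, seed=7)
        g = build_geometry(cfg)
        lines = render_boron_grid(g).splitlines()
        for j in range(20):
            row = lines[19 - j].split()
            for i in range(20):
                assert (row[i] != ".") == bool(g.borcheck[i, j])
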