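"""Montage geometry, grid assignment and topographic rendering."""

import numpy as np
import pandas as pd
import pytest

import eegfatigue as ef
from eegfatigue.errors import ConfigurationError, InputError
from eegfatigue.topomap import (CHANNEL_NAMES, HOMOLOGOUS_PAIRS,
                                MIDLINE_CHANNELS, _disk_mask, build_grid,
                                render_map)


class TestProjection:
    def test_vertex_maps_to_origin(self):
        assert np.allclose(ef.project_azimuthal([0, 0, 1]), [0, 0])

    def test_equal_polar_angle_equal_radius(self):
        a = ef.project_azimuthal([np.sin(0.7), 0, np.cos(0.7)])
        b = ef.project_azimuthal([0, np.sin(0.7), np.cos(0.7)])
        assert np.isclose(np.linalg.norm(a), np.linalg.norm(b))

    def test_radius_linear_in_arc_length(self, rng):
        for _ in range(10):
            theta = rng.uniform(0.05, np.pi / 2)
            phi = rng.uniform(0, 2 * np.pi)
            p = [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                 np.cos(theta)]
            r = np.linalg.norm(ef.project_azimuthal(p))
            assert np.isclose(r, theta, atol=1e-9)

    def test_below_equator_rejected(self):
        with pytest.raises(InputError):
            ef.project_azimuthal([0.5, 0.5, -0.3])


class TestMontage:
    def test_injective_grid_assignment(self, montage):
        assert len(set(montage.cells)) == 32
        assert all(0 <= r < 9 and 0 <= c < 9 for r, c in montage.cells)

    def test_cz_at_center(self, montage):
        assert montage.cell_of("Cz") == (4, 4)
        assert np.allclose(montage.points2d[list(montage.names).index("Cz")],
                           [0, 0], atol=1e-9)

    def test_homologous_pairs_mirror_columns(self, montage):
        for left, right in HOMOLOGOUS_PAIRS:
            rl, cl = montage.cell_of(left)
            rr, cr = montage.cell_of(right)
            assert rl == rr, f"{left}/{right} rows differ"
            assert cl + cr == 8, f"{left}/{right} not mirrored"

    def test_midline_channels_in_center_column(self, montage):
        for name in MIDLINE_CHANNELS:
            assert montage.cell_of(name)[1] == 4

    def test_points_in_upper_hemisphere_unit_disk(self, montage):
        assert np.all(montage.points3d[:, 2] >= -1e-12)
        radii = np.linalg.norm(montage.points2d, axis=1)
        assert radii.max() <= np.pi / 2 + 1e-9

    def test_channel_names_ship_verbatim(self, montage):
        assert "C7" in montage.names and "C8" in montage.names
        assert len(montage.names) == 32

    def test_collision_resolution_moves_later_channel(self):
        pts = np.array([[0.0, 0.0], [0.01, 0.01], [1.0, 0.0]])
        cells, _ = build_grid(["a", "b", "c"], pts)
        assert len(set(cells)) == 3
        assert cells[0] == (4, 4)  # first channel keeps the contested cell


class TestRenderMap:
    def test_constant_input_renders_half(self, montage):
        img = render_map(np.full(32, 3.7), montage)
        mask = _disk_mask(montage.radius)
        assert img.shape == (72, 72)
        assert np.all(img[mask] == 0.5)
        assert np.all(img[~mask] == 0.0)

    def test_hot_channel_locality_all_channels(self, montage):
        for i, name in enumerate(montage.names):
            values = np.zeros(32)
            values[i] = 1.0
            img = render_map(values, montage)
            r, c = montage.cells[i]
            block = img[8 * r:8 * r + 8, 8 * c:8 * c + 8]
            assert block.max() == img.max(), f"peak not at {name}'s cell"

    def test_range_and_mask_invariants(self, montage, rng):
        img = render_map(rng.random(32), montage)
        mask = _disk_mask(montage.radius)
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert np.all(img[~mask] == 0.0)

    def test_non_finite_values_rejected(self, montage):
        values = np.ones(32)
        values[5] = np.nan
        with pytest.raises(InputError):
            render_map(values, montage)

    def test_monotone_in_single_channel(self, montage):
        rng = np.random.default_rng(3)
        base = rng.random(32)
        i = list(montage.names).index("C3")
        r, c = montage.cells[i]
        prev = None
        for bump in np.linspace(0.0, 2.0, 5):
            values = base.copy()
            values[i] = base[i] + bump
            img = render_map(values, montage)
            px = img[8 * r + 4, 8 * c + 4]
            if prev is not None:
                assert px >= prev - 1e-9
            prev = px


class TestComposeInput:
    def features(self, rng):
        data = rng.random((32, 4))
        return pd.DataFrame(data, index=CHANNEL_NAMES,
                            columns=["delta", "theta", "alpha", "beta"])

    def test_band3_shape_and_assignment(self, montage, rng):
        img = ef.compose_input(self.features(rng), montage)
        assert img.pixels.shape == (72, 72, 3)
        assert img.band_assignment == ("delta", "theta", "alpha")

    def test_channel_order_irrelevant(self, montage, rng):
        f = self.features(rng)
        shuffled = f.sample(frac=1.0, random_state=1)
        a = ef.compose_input(f, montage).pixels
        b = ef.compose_input(shuffled, montage).pixels
        assert np.array_equal(a, b)

    def test_rgb_constant_is_colormap_midpoint(self, montage):
        import matplotlib
        f = pd.DataFrame(np.ones((32, 4)), index=CHANNEL_NAMES,
                         columns=["delta", "theta", "alpha", "beta"])
        img = ef.compose_input(f, montage, mode="rgb", band="theta")
        mask = _disk_mask(montage.radius)
        expected = matplotlib.colormaps["viridis"](0.5)[:3]
        assert np.allclose(img.pixels[mask], expected)
        assert np.all(img.pixels[~mask] == 0.0)

    def test_unknown_mode_rejected(self, montage, rng):
        with pytest.raises(ConfigurationError):
            ef.compose_input(self.features(rng), montage, mode="stack9")

    def test_missing_band_rejected(self, montage, rng):
        f = self.features(rng).drop(columns=["theta"])
        with pytest.raises(InputError):
            ef.compose_input(f, montage)


def test_theta_map_tracks_rpsd_increase(montage_fixture=None):
    """End-to-end monotonicity: raising one channel's theta RPSD never
    lowers the theta-map value at that channel's cell."""
    montage = ef.standard_montage()
    rng = np.random.default_rng(11)
    base = pd.DataFrame(rng.random((32, 4)) * 0.4 + 0.1,
                        index=CHANNEL_NAMES,
                        columns=["delta", "theta", "alpha", "beta"])
    i = list(montage.names).index("Pz")
    r, c = montage.cells[i]
    prev = None
    for bump in [0.0, 0.2, 0.4]:
        f = base.copy()
        f.loc["Pz", "theta"] += bump
        img = ef.compose_input(f, montage).pixels
        px = img[8 * r + 4, 8 * c + 4, 1]  # channel 1 = theta
        if prev is not None:
            assert px >= prev - 1e-9
        prev = px
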