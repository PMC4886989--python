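import numpy as np
import pytest

import sfxprep as sp
from sfxprep.spotfind import (
    SpotFindError,
    binarize,
    connected_components,
    crystfel_peaks_block,
    score_candidate,
    spots_to_tsv,
)

from conftest import clean_sim_params, plant_frame


def _frame(panels, tag=0):
    return sp.CalibratedFrame(
        tag=tag,
        panels=[np.asarray(p, dtype=np.int16) for p in panels],
        photon_energy_ev=7300.0,
        photodiode=0.0,
        spectrum_mean_ev=7300.0,
    )


def _zeros(geom):
    return _frame([np.zeros(geom.panel_shape) for _ in range(8)])


def flood_fill_components(mask, connectivity):
    """Independent oracle: BFS flood fill, returns frozenset of frozensets."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            comp = []
            while stack:
                rr, cc = stack.pop()
                comp.append((rr, cc))
                for dr, dc in nbrs:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            comps.append(frozenset(comp))
    return frozenset(comps)


def label_partition(labels):
    out = {}
    for r, c in zip(*np.nonzero(labels)):
        out.setdefault(labels[r, c], set()).add((int(r), int(c)))
    return frozenset(frozenset(s) for s in out.values())


class TestBinarize:
    def test_all_zero(self, mini_geom):
        masks = binarize(_zeros(mini_geom), 50)
        assert all(not m.any() for m in masks)

    def test_threshold_inclusive(self):
        panel = np.zeros((5, 5))
        panel[2, 3] = 50
        masks = binarize([panel] * 8, 50)
        assert masks[0].sum() == 1 and masks[0][2, 3]

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        panel = rng.integers(-100, 200, (20, 15))
        mask = binarize([panel] * 8, 60)[0]
        for r in range(20):
            for c in range(15):
                assert mask[r, c] == (panel[r, c] >= 60)


class TestConnectedComponents:
    def test_diagonal_connectivity_semantics(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert connected_components(mask, 8)[1] == 1
        assert connected_components(mask, 4)[1] == 2

    def test_empty_mask(self):
        assert connected_components(np.zeros((5, 5), dtype=bool), 8)[1] == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_flood_fill_oracle_random(self, connectivity):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mask = rng.random((24, 18)) < 0.15
            labels, n = connected_components(mask, connectivity)
            oracle = flood_fill_components(mask, connectivity)
            assert n == len(oracle)
            assert label_partition(labels) == oracle

    def test_invalid_connectivity(self):
        with pytest.raises(SpotFindError):
            connected_components(np.zeros((2, 2), dtype=bool), 6)


class TestScoreCandidate:
    def test_zero_background_noise_floor(self, mini_geom):
        # 9-pixel spot of value 100 on a flat zero background: background 0,
        # noise floored at 1 deci-photon -> snr = 100
        panel = np.zeros(mini_geom.panel_shape)
        panel[10:13, 10:13] = 100
        frame = _frame([panel] + [np.zeros(mini_geom.panel_shape)] * 7)
        spots = sp.find_spots(frame, sp.SpotFindParams(min_snr=0.0))
        assert len(spots.accepted) == 1
        c = spots.accepted[0]
        assert c.area == 9
        assert c.snr == pytest.approx(100.0)
        assert c.integrated_intensity == pytest.approx(900.0)
        assert (c.fast, c.slow) == (11.0, 11.0)

    def test_saturation_flag(self, mini_geom):
        panel = np.zeros(mini_geom.panel_shape)
        panel[5, 5] = 3240
        frame = _frame([panel] + [np.zeros(mini_geom.panel_shape)] * 7)
        params = sp.SpotFindParams(min_snr=0.0, saturation_value=3240.0)
        spots = sp.find_spots(frame, params)
        assert spots.accepted[0].is_saturated
        assert spots.n_saturated == 1
        params2 = sp.SpotFindParams(min_snr=0.0, saturation_value=4000.0)
        assert not sp.find_spots(frame, params2).accepted[0].is_saturated

    def test_background_subtracted(self, mini_geom):
        panel = np.full(mini_geom.panel_shape, 20.0)
        panel[30:32, 30:32] = 220
        frame = _frame([panel] + [np.zeros(mini_geom.panel_shape)] * 7)
        spots = sp.find_spots(frame, sp.SpotFindParams(min_snr=0.0))
        c = spots.accepted[0]
        assert c.background == pytest.approx(20.0)
        assert c.integrated_intensity == pytest.approx(4 * 200.0)
        assert c.snr == pytest.approx(200.0)  # noise floor 1

    def test_planted_integration_within_poisson(self):
        # gain 100 so 10000-photon spots stay far below the full well
        from sfxprep.fixtures import mini_geometry

        geom = mini_geometry(gains=(100.0,) * 8)
        calib = sp.CalibrationParams(gains=geom.gains)
        params = clean_sim_params(
            seed=10, spots_per_hit_mean=1.0, spot_photons_mean=10000.0,
            spot_photons_sd=0.0,
        )
        manifest = sp.RunManifest(n_dark=2, n_exposed=25)
        frames, truths = sp.simulate_run(manifest, params, geom)
        dark = sp.compute_dark(frames[:2])
        checked = 0
        for f, t in zip(frames[2:], truths[2:]):
            if len(t.spots) != 1 or t.spots[0].is_saturated:
                continue
            cal = sp.calibrate(f, dark, calib)
            spots = sp.find_spots(cal, sp.SpotFindParams())
            assert len(spots.accepted) == 1
            found = spots.accepted[0].integrated_intensity / 10.0  # photons
            planted = t.spots[0].integrated_photons
            # 3 sigma Poisson plus the sub-threshold tail outside the component
            assert abs(found - planted) <= 3 * np.sqrt(planted) + 0.01 * planted
            checked += 1
        assert checked >= 5


class TestFindSpots:
    def test_all_zero_frame(self, mini_geom):
        spots = sp.find_spots(_zeros(mini_geom), sp.SpotFindParams())
        assert spots.accepted == []
        assert spots.n_rejected_area == spots.n_rejected_snr == 0

    def test_25_planted_spots_recovered(self, mini_geom):
        rng = np.random.default_rng(5)
        positions = []
        taken = set()
        while len(positions) < 25:
            m = int(rng.integers(8))
            f = int(rng.integers(8, 56))
            s = int(rng.integers(8, 120))
            if all(abs(f - f2) + abs(s - s2) > 16 for m2, f2, s2 in positions if m2 == m):
                positions.append((m, f, s))
        frame = plant_frame(mini_geom, positions, amplitude=1000.0)
        spots = sp.find_spots(frame, sp.SpotFindParams())
        assert len(spots.accepted) == 25
        for c in spots.accepted:
            assert any(
                c.module == m and abs(c.fast - f) <= 1 and abs(c.slow - s) <= 1
                for m, f, s in positions
            )

    def test_area_filter(self, mini_geom):
        panel = np.zeros(mini_geom.panel_shape)
        panel[10:30, 10:20] = 100  # 200-pixel blob
        frame = _frame([panel] + [np.zeros(mini_geom.panel_shape)] * 7)
        spots = sp.find_spots(frame, sp.SpotFindParams(max_area=100))
        assert spots.accepted == []
        assert spots.n_rejected_area == 1

    def test_monotonicity(self, clean_pairs):
        frame = clean_pairs[0][0]
        counts = [
            len(sp.find_spots(frame, sp.SpotFindParams(pixel_threshold=t)).accepted)
            for t in (30.0, 50.0, 120.0, 400.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts = [
            len(sp.find_spots(frame, sp.SpotFindParams(min_snr=s)).accepted)
            for s in (0.0, 3.0, 8.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts = [
            len(sp.find_spots(frame, sp.SpotFindParams(min_area=a)).accepted)
            for a in (1, 3, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_panel_isolation(self, mini_geom):
        # a blob touching the boundary rows of two adjacent panels must be
        # reported as two candidates, never merged across modules
        p0 = np.zeros(mini_geom.panel_shape)
        p1 = np.zeros(mini_geom.panel_shape)
        p0[126:128, 30:33] = 200
        p1[0:2, 30:33] = 200
        frame = _frame([p0, p1] + [np.zeros(mini_geom.panel_shape)] * 6)
        spots = sp.find_spots(frame, sp.SpotFindParams(min_snr=0.0))
        assert len(spots.accepted) == 2
        assert sorted(c.module for c in spots.accepted) == [0, 1]

    def test_roi_mask_excludes(self, mini_geom):
        panel = np.zeros(mini_geom.panel_shape)
        panel[10, 10] = 500
        panel[50, 50] = 500
        frame = _frame([panel] + [np.zeros(mini_geom.panel_shape)] * 7)
        roi = [np.ones(mini_geom.panel_shape, dtype=bool) for _ in range(8)]
        roi[0][50, 50] = False
        spots = sp.find_spots(frame, sp.SpotFindParams(min_snr=0.0), roi=roi)
        assert len(spots.accepted) == 1
        assert spots.accepted[0].slow == 10.0


class TestParams:
    def test_invalid(self):
        with pytest.raises(SpotFindError):
            sp.SpotFindParams(connectivity=5)
        with pytest.raises(SpotFindError):
            sp.SpotFindParams(min_area=5, max_area=2)
        with pytest.raises(SpotFindError):
            sp.SpotFindParams(annulus_inner=5, annulus_outer=5)


class TestTextOutput:
    def test_tsv_and_stream_block(self, clean_pairs, tmp_path):
        frame, truth = clean_pairs[0]
        spots = sp.find_spots(frame, sp.SpotFindParams())
        text = spots_to_tsv(spots, tmp_path / "spots.tsv")
        assert len(text.splitlines()) == len(spots.accepted) + 1
        block = crystfel_peaks_block(spots, slow_extent=128)
        assert block.startswith("Peaks from peak search")
        assert block.rstrip().endswith("End of peak list")
        assert len(block.splitlines()) == len(spots.accepted) + 3
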