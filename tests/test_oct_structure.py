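import numpy as np
import pytest

from retimetrics.config import PipelineConfig
from retimetrics.errors import AnalysisError, FormatError
from retimetrics.oct_structure import (
    EtdrsGrid,
    count_hrf,
    detect_hrf_candidates,
    filter_hrf,
    layer_thickness,
    layer_thickness_profile,
    layer_thickness_volume,
    sector_of,
)
from retimetrics.synth import FocusSpec, generate_bscan
from retimetrics.types import MARKER_ORDER, BScanRecord

BASE_DEPTHS = {"ILM": 80., "RNFL_o": 95., "GCL_o": 138., "IPL_o": 173.,
               "INL_o": 208., "OPL_o": 238., "ELM": 318., "EZ": 343.,
               "OS": 363., "RPE": 378., "BM": 398.}


def _flat_bounds(n, scale=3.9, depths=None):
    depths = depths or BASE_DEPTHS
    return {m: np.full(n, depths[m] / scale) for m in MARKER_ORDER}


class TestSectorOf:
    @pytest.mark.parametrize("point,expected", [
        ((0, 0), "C1"),                    # exact center
        ((0, 1000), "I-sup"),              # 1 mm straight up
        ((3100, 0), "outside"),            # beyond the 6 mm disc
        ((1000, 0), "I-nas"),              # right eye: nasal is +x
        ((-1000, 0), "I-temp"),
        ((0, -2000), "O-inf"),
        ((400, 0), "C1"),                  # inside the 1 mm disc
        ((0, 3000), "O-sup"),              # 6 mm rim is included
    ])
    def test_ring_and_quadrant_geometry(self, point, expected):
        assert sector_of(point, EtdrsGrid()) == expected

    def test_laterality_swaps_nasal_temporal(self):
        grid_os = EtdrsGrid(laterality="OS")
        assert sector_of((1000, 0), grid_os) == "I-temp"
        assert sector_of((-1000, 0), grid_os) == "I-nas"

    def test_rings_partition_the_disc(self):
        rng = np.random.default_rng(0)
        grid = EtdrsGrid()
        for _ in range(200):
            x, y = rng.uniform(-3500, 3500, 2)
            s = sector_of((x, y), grid)
            r = np.hypot(x, y)
            if r > 3000:
                assert s == "outside"
            else:
                assert s != "outside"


class TestLayerThickness:
    def test_constant_field_reproduced_in_every_sector(self):
        n = 41
        x = np.linspace(-3000, 3000, n)
        bounds = {m: np.full((n, n), v / 3.9) for m, v in BASE_DEPTHS.items()}
        tm = layer_thickness_volume(bounds, 3.9, x, x)
        assert np.allclose(tm.sector_means.loc["GCL"].dropna(), 43.0, atol=1e-9)
        assert tm.central["GCL"] == pytest.approx(43.0, abs=1e-9)
        assert tm.ring_mean["GCL"] == pytest.approx(43.0, abs=1e-9)

    def test_piecewise_field_ring_mean_closed_form(self):
        # GCL 50 µm inside the inner ring, 30 µm outside: the ring mean is
        # the average of 4 quadrants at 50 and 4 at 30, i.e. 40.
        n = 121
        x = np.linspace(-3000, 3000, n)
        X, Y = np.meshgrid(x, x)
        inner = np.hypot(X, Y) < 1500
        bounds = {m: np.full((n, n), v / 3.9) for m, v in BASE_DEPTHS.items()}
        shift = np.where(inner, 50.0, 30.0) - 43.0
        for m in ("GCL_o", "IPL_o", "INL_o", "OPL_o", "ELM", "EZ", "OS",
                  "RPE", "BM"):
            bounds[m] = bounds[m] + shift / 3.9
        tm = layer_thickness_volume(bounds, 3.9, x, x)
        assert tm.ring_mean["GCL"] == pytest.approx(40.0)
        assert tm.central["GCL"] == pytest.approx(50.0)

    def test_layer_sum_reconciles_with_total(self):
        record, _ = generate_bscan(speckle_level=0, seed=0)
        tm = layer_thickness(record)
        total = (record.boundaries["BM"] - record.boundaries["ILM"]).mean() \
            * record.axial_scale
        for sector, value in tm.total_thickness().dropna().items():
            assert abs(value - total) <= 1.0

    def test_crossing_boundaries_error_names_column(self):
        bounds = _flat_bounds(64)
        bounds["GCL_o"][17] = bounds["IPL_o"][17] + 5
        with pytest.raises(AnalysisError, match="cross at col 17"):
            layer_thickness_profile(bounds, 3.9)

    def test_bscan_record_rejects_crossing_boundaries(self):
        bounds = _flat_bounds(64)
        bounds["GCL_o"][17] = bounds["IPL_o"][17] + 5
        with pytest.raises(FormatError, match="cross at col 17"):
            BScanRecord(pixels=np.zeros((128, 64)), axial_scale=3.9,
                        lateral_scale=5.7, fovea_col=32, boundaries=bounds)


class TestHRFDetection:
    def test_noise_free_single_focus_localized(self):
        spec = FocusSpec(lateral_um=-500, compartment="IR", diameter_um=25)
        record, truth = generate_bscan(foci_spec=(spec,), speckle_level=0,
                                       seed=1)
        cands = detect_hrf_candidates(record)
        near = [c for c in cands
                if abs(c.center_row - truth[0].center_row) <= 2
                and abs(c.center_col - truth[0].center_col) <= 2]
        assert len(near) >= 1

    def test_focus_outside_central_window_not_counted(self):
        spec = FocusSpec(lateral_um=1800, compartment="IR", diameter_um=25)
        record, _ = generate_bscan(foci_spec=(spec,), speckle_level=0, seed=1)
        assert detect_hrf_candidates(record) == []

    def test_window_boundary_is_closed(self):
        # included at exactly 1.5 mm, excluded one pixel further out
        for lateral, expected in ((1500.0, 1), (1500.0 + 5.7, 0)):
            spec = FocusSpec(lateral_um=lateral, compartment="IR",
                             diameter_um=25)
            record, _ = generate_bscan(foci_spec=(spec,), speckle_level=0,
                                       seed=1)
            assert len(detect_hrf_candidates(record)) == expected, lateral

    def test_uniform_image_yields_no_candidates(self):
        record = BScanRecord(pixels=np.full((224, 640), 0.4),
                             axial_scale=3.9, lateral_scale=5.7,
                             fovea_col=320, boundaries=_flat_bounds(640))
        assert detect_hrf_candidates(record) == []

    def test_narrow_scan_rejected(self):
        record = BScanRecord(pixels=np.full((224, 100), 0.4),
                             axial_scale=3.9, lateral_scale=5.7,
                             fovea_col=50, boundaries=_flat_bounds(100))
        with pytest.raises(AnalysisError, match="narrower"):
            detect_hrf_candidates(record)


class TestHRFFilter:
    def test_compliant_focus_retained_with_compartment(self):
        specs = (FocusSpec(lateral_um=-600, compartment="IR", diameter_um=25),
                 FocusSpec(lateral_um=500, compartment="OR", diameter_um=22))
        record, truth = generate_bscan(foci_spec=specs, seed=3)
        foci = filter_hrf(detect_hrf_candidates(record), record)
        assert len(foci) == 2
        got = sorted((f.compartment, round(f.center_col)) for f in foci)
        want = sorted((t.compartment, round(t.center_col)) for t in truth)
        assert [g[0] for g in got] == [w[0] for w in want]

    def test_oversized_focus_rejected_on_size(self):
        spec = FocusSpec(lateral_um=0, compartment="IR", diameter_um=40)
        record, _ = generate_bscan(foci_spec=(spec,), seed=4)
        assert filter_hrf(detect_hrf_candidates(record), record) == []

    def test_shadowed_focus_rejected_on_shadowing(self):
        spec = FocusSpec(lateral_um=0, compartment="IR", diameter_um=25,
                         has_shadow=True)
        record, _ = generate_bscan(foci_spec=(spec,), seed=5)
        assert filter_hrf(detect_hrf_candidates(record), record) == []

    def test_high_reflectivity_focus_rejected(self):
        spec = FocusSpec(lateral_um=0, compartment="IR", diameter_um=25,
                         level="high")
        record, _ = generate_bscan(foci_spec=(spec,), speckle_level=0, seed=6)
        assert filter_hrf(detect_hrf_candidates(record), record) == []

    def test_ir_convention_switch(self):
        # a focus in the INL-OPL band is IR under the text convention only
        spec = FocusSpec(lateral_um=0, compartment="OR", diameter_um=25,
                         depth_frac=0.25)
        record, _ = generate_bscan(foci_spec=(spec,), speckle_level=0, seed=7)
        cfg_text = PipelineConfig(hrf_ir_convention="text")
        foci = filter_hrf(detect_hrf_candidates(record), record, cfg_text)
        assert all(f.compartment in ("IR", "OR") for f in foci)


class TestCountHRF:
    def test_planted_counts_recovered(self):
        specs = tuple(
            FocusSpec(lateral_um=x, compartment="IR", diameter_um=24)
            for x in (-1200, -600, 200)
        ) + tuple(
            FocusSpec(lateral_um=x, compartment="OR", diameter_um=22)
            for x in (700, 1200)
        )
        record, _ = generate_bscan(foci_spec=specs, seed=8)
        assert count_hrf(record) == (3, 2)

    def test_no_foci_counts_zero(self):
        record, _ = generate_bscan(seed=9)
        assert count_hrf(record) == (0, 0)

    def test_detector_monotonicity_in_planted_count(self):
        """Reported vs planted compliant count has slope ~1 (noise-free)."""
        planted, reported = [], []
        for n in range(0, 11, 2):
            xs = np.linspace(-1300, 1300, max(n, 1))[:n]
            specs = tuple(FocusSpec(lateral_um=float(x), compartment="IR",
                                    diameter_um=24) for x in xs)
            record, _ = generate_bscan(foci_spec=specs, speckle_level=0,
                                       seed=10)
            n_ir, n_or = count_hrf(record)
            planted.append(n)
            reported.append(n_ir + n_or)
        slope = np.polyfit(planted, reported, 1)[0]
        assert abs(slope - 1.0) <= 0.1
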