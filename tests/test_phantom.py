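"""Voxel phantom construction and the scan-grid protocol."""

import math

import numpy as np
import pytest

from dotphantom.phantom import (CORE_LABEL, HOST_LABEL, SHELL_LABEL,
                                CoreShellInclusion, OpticalProperties,
                                ScanGrid, build_slab, embed_core_shell,
                                fixture_phantom, grid_positions)

HOST = OpticalProperties(0.00177, 0.954, n=1.40)
CORE = OpticalProperties(0.0179, 0.883, n=1.56)
SHELL = OpticalProperties(0.00210, 1.158, n=1.56)


class TestOpticalProperties:
    @pytest.mark.parametrize("kwargs", [
        {"mua": -1e-3, "musp": 1.0},
        {"mua": 0.01, "musp": 0.0},
        {"mua": 0.01, "musp": 1.0, "g": 1.0},
        {"mua": 0.01, "musp": 1.0, "n": 0.9},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OpticalProperties(**kwargs)

    def test_transport_scattering_from_anisotropy(self):
        p = OpticalProperties(0.01, 0.9, g=0.9)
        assert p.mus == pytest.approx(9.0)


class TestBuildSlab:
    def test_full_size_slab_shape(self):
        ph = build_slab((200.0, 200.0, 40.0), HOST)
        assert ph.shape == (200, 200, 40)
        assert ph.thickness == 40.0

    def test_voxel_count(self):
        ph = build_slab((10.0, 10.0, 10.0), HOST)
        assert ph.labels.size == 1000
        assert (ph.labels == HOST_LABEL).all()

    def test_non_divisible_dimensions_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_slab((10.0, 10.0, 10.0), HOST, voxel_size=3.0)


class TestEmbedCoreShell:
    def _embed(self, voxel_size=1.0):
        ph = build_slab((60.0, 60.0, 40.0), HOST, voxel_size=voxel_size)
        inc = CoreShellInclusion((0.0, 0.0, 20.0), CORE, SHELL)
        return embed_core_shell(ph, inc)

    def test_rasterized_volumes_match_analytic_spheres(self):
        counts = self._embed().label_counts()
        v_core = math.pi / 6.0 * 10.0 ** 3
        v_shell = math.pi / 6.0 * (20.0 ** 3 - 10.0 ** 3)
        assert abs(counts[CORE_LABEL] - v_core) / v_core < 0.10
        assert abs(counts[SHELL_LABEL] - v_shell) / v_shell < 0.10

    def test_center_voxel_is_core(self):
        ph = self._embed()
        # voxel containing the inclusion centre (0, 0, 20)
        assert ph.labels[30, 30, 20] == CORE_LABEL

    def test_volume_error_shrinks_with_voxel_size(self):
        v_core = math.pi / 6.0 * 10.0 ** 3
        errors = []
        for h in (2.0, 1.0, 0.5):
            counts = self._embed(voxel_size=h).label_counts()
            errors.append(abs(counts[CORE_LABEL] * h ** 3 - v_core) / v_core)
        assert errors[2] < errors[0]
        assert errors[2] < 0.02

    def test_degenerate_shell_is_homogeneous_sphere(self):
        ph = build_slab((60.0, 60.0, 40.0), HOST)
        inc = CoreShellInclusion((0.0, 0.0, 20.0), CORE, SHELL,
                                 core_diameter=10.0, shell_diameter=10.0)
        counts = embed_core_shell(ph, inc).label_counts()
        assert SHELL_LABEL not in counts

    def test_label_bookkeeping(self):
        ph = self._embed()
        counts = ph.label_counts()
        assert sum(counts.values()) == ph.labels.size

    def test_out_of_slab_inclusion_rejected(self):
        ph = build_slab((60.0, 60.0, 40.0), HOST)
        inc = CoreShellInclusion((0.0, 0.0, 5.0), CORE, SHELL)
        with pytest.raises(ValueError, match="boundary"):
            embed_core_shell(ph, inc)


class TestScanGrid:
    def test_protocol_yields_25_positions(self):
        assert len(grid_positions(ScanGrid(extent=40.0, step=10.0))) == 25

    def test_zero_extent_single_position(self):
        assert grid_positions(ScanGrid(extent=0.0)) == [(0.0, 0.0)]

    def test_positions_symmetric_under_inversion(self):
        pos = set(grid_positions(ScanGrid(40.0, 10.0)))
        assert {(-x, -y) for x, y in pos} == pos

    def test_non_integral_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            grid_positions(ScanGrid(extent=40.0, step=7.0))


class TestFixturePhantom:
    def test_adc_solid_670_measured_properties(self):
        ph = fixture_phantom("ADC", "solid", 670)
        assert ph.materials[CORE_LABEL].mua == pytest.approx(0.0179)
        assert ph.materials[CORE_LABEL].musp == pytest.approx(0.883)
        assert ph.materials[SHELL_LABEL].mua == pytest.approx(0.00210)
        assert ph.materials[SHELL_LABEL].musp == pytest.approx(1.158)
        assert ph.materials[HOST_LABEL].mua == pytest.approx(0.00177)
        assert ph.materials[HOST_LABEL].musp == pytest.approx(0.954)

    def test_fadn_liquid_830_measured_properties(self):
        ph = fixture_phantom("FADN", "liquid", 830)
        assert ph.materials[CORE_LABEL].mua == pytest.approx(0.00102)
        assert ph.materials[CORE_LABEL].musp == pytest.approx(0.731)
        assert ph.materials[HOST_LABEL].mua == pytest.approx(0.00209)
        assert ph.materials[HOST_LABEL].musp == pytest.approx(0.759)

    def test_malignant_core_absorbs_about_four_times_benign(self):
        adc = fixture_phantom("ADC", "solid", 670).materials[CORE_LABEL].mua
        fadn = fixture_phantom("FADN", "solid", 670).materials[CORE_LABEL].mua
        assert adc / fadn == pytest.approx(3.97, abs=0.01)

    def test_geometry_and_refractive_indices(self):
        ph = fixture_phantom("FADN", "solid", 670)
        assert ph.shape == (200, 200, 40)
        assert ph.materials[CORE_LABEL].n == pytest.approx(1.56)
        assert ph.materials[HOST_LABEL].n == pytest.approx(1.40)
        assert ph.exterior_n == pytest.approx(1.0)
        # inclusion centred at mid-depth on the beam axis
        assert ph.labels[100, 100, 20] == CORE_LABEL

    def test_homogeneous_variant_has_no_inclusion(self):
        ph = fixture_phantom("ADC", "solid", 670, include_inclusion=False)
        assert (ph.labels == HOST_LABEL).all()

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            fixture_phantom("XYZ", "solid", 670)
        with pytest.raises(ValueError):
            fixture_phantom("ADC", "solid", 700)
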