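"""Voxel phantom: subdomain layout, conduction-chain topology, lesions."""

import numpy as np
import pytest

from torsoecg.geometry import (DEFAULT_PASSIVE, HEART_LABELS, GeometryConfig,
                               GeometryError, Label, LesionSpec, LesionError,
                               apply_infarct, build_default_geometry,
                               build_tissue, conductivity_maps,
                               face_adjacency_count, lesion_mask,
                               lesion_preset, validate_geometry)

CHAIN = [(Label.SAN, Label.ATRIA), (Label.ATRIA, Label.AVN),
         (Label.AVN, Label.HIS), (Label.HIS, Label.BNL),
         (Label.BNL, Label.PURKINJE), (Label.PURKINJE, Label.VENTRICLES)]


@pytest.fixture(scope="module")
def default_field():
    return build_default_geometry()


class TestBuild:
    def test_seven_heart_regions_plus_passive(self, default_field):
        counts = default_field.counts()
        heart = [l.name for l in HEART_LABELS]
        assert all(name in counts for name in heart)
        assert sum(1 for name in heart if counts[name] > 0) == 7
        for name in ("TORSO", "LUNGS", "BLOOD"):
            assert counts[name] > 0

    def test_conduction_chain_adjacency(self, default_field):
        lab = default_field.labels
        for a, b in CHAIN:
            assert face_adjacency_count(lab, a, b) > 0, f"{a.name}-{b.name}"

    def test_av_isolation(self, default_field):
        assert face_adjacency_count(default_field.labels,
                                    Label.ATRIA, Label.VENTRICLES) == 0

    def test_determinism(self, default_field):
        again = build_default_geometry()
        assert np.array_equal(again.labels, default_field.labels)
        assert again.origin == default_field.origin

    def test_coarser_grid_keeps_topology(self):
        fld = build_default_geometry(GeometryConfig(dx=0.0045))
        assert validate_geometry(fld).passed

    def test_unresolvable_region_rejected(self):
        with pytest.raises(GeometryError, match="wall_thickness"):
            GeometryConfig(dx=0.004, wall_thickness=0.006)

    def test_heart_must_fit_in_torso(self):
        with pytest.raises(GeometryError, match="fit"):
            GeometryConfig(heart_center=(0.13, 0.02, 0.05))

    def test_volume_sanity(self, default_field):
        # heart voxel volume vs analytic estimate: spherical shell + septum
        # slab - AV gap ring; the voxelized surface accounts for the slack
        cfg = GeometryConfig()
        Ro, Ri = cfg.heart_outer_radius, cfg.inner_radius
        shell = 4 / 3 * np.pi * (Ro ** 3 - Ri ** 3)
        septum = cfg.septum_thickness * np.pi * Ri ** 2
        rho = np.sqrt(Ro ** 2 - cfg.av_plane_offset ** 2)
        ring = 2 * np.pi * rho * cfg.wall_thickness * cfg.gap_thickness
        expected = shell + septum - ring
        n_heart = int(default_field.heart_mask().sum())
        assert abs(n_heart * cfg.dx ** 3 - expected) < 0.15 * expected


class TestValidator:
    def test_default_passes(self, default_field):
        report = validate_geometry(default_field)
        assert report.passed
        assert "av-isolation" in str(report)

    def test_deleted_avn_breaks_chain(self, default_field):
        fld = default_field.copy()
        fld.labels[fld.labels == Label.AVN] = Label.ATRIA
        report = validate_geometry(fld)
        assert not report.passed
        failing = {c.name for c in report.checks if not c.passed}
        assert any("AVN" in n for n in failing)

    def test_stray_contact_fails_isolation_with_coordinates(self, default_field):
        fld = default_field.copy()
        lab = fld.labels
        # relabel one gap voxel directly above a ventricular voxel as atria
        vent = np.argwhere(lab == Label.VENTRICLES)
        for i, j, k in vent:
            if lab[i, j, k + 1] in (Label.TORSO, Label.BLOOD):
                lab[i, j, k + 1] = Label.ATRIA
                break
        report = validate_geometry(fld)
        iso = next(c for c in report.checks if c.name == "av-isolation")
        assert not iso.passed
        assert "voxels" in iso.detail  # coordinates are reported


class TestConductivity:
    def test_passive_values(self, default_field):
        _, _, sigma_o = conductivity_maps(default_field)
        lab = default_field.labels
        assert np.all(sigma_o[lab == Label.TORSO] == 0.2)
        assert np.all(sigma_o[lab == Label.LUNGS] == 0.04)
        assert np.all(sigma_o[lab == Label.BLOOD] == 0.7)

    def test_heart_values_and_zero_outside(self, default_field):
        sigma_i, sigma_e, sigma_o = conductivity_maps(default_field)
        lab = default_field.labels
        assert np.all(sigma_e[lab == Label.PURKINJE] == pytest.approx(0.035))
        assert np.all(sigma_i[lab == Label.PURKINJE] == pytest.approx(0.035))
        assert np.all(sigma_i[lab == Label.AVN] == pytest.approx(0.0005))
        assert np.all(sigma_i[~default_field.heart_mask()] == 0.0)
        assert np.all(sigma_o[default_field.heart_mask()] == 0.0)

    def test_missing_region_parameters(self, default_field):
        from torsoecg.cells import all_region_defaults

        params = all_region_defaults()
        del params["Purkinje"]
        with pytest.raises(KeyError, match="Purkinje"):
            conductivity_maps(default_field, params=params)


class TestInfarct:
    def test_preset_zeroes_k_and_sigma_i(self, default_field):
        cfg = GeometryConfig()
        tissue = build_tissue(default_field)
        lesion = lesion_preset("anterior-MI", cfg)
        out = apply_infarct(default_field, tissue, lesion)
        mask = lesion_mask(default_field, lesion)
        assert mask.sum() > 0
        assert np.all(out.k[mask] == 0.0)
        assert np.all(out.sigma_i[mask] == 0.0)
        assert np.all(out.Vi0[mask] == -0.060)
        assert np.all(out.Ve0[mask] == -0.020)

    def test_locality(self, default_field):
        tissue = build_tissue(default_field)
        lesion = lesion_preset("inferior-MI", GeometryConfig())
        out = apply_infarct(default_field, tissue, lesion)
        mask = lesion_mask(default_field, lesion)
        for name in ("k", "sigma_i", "Vi0", "Ve0", "sigma_e", "sigma_o"):
            assert np.array_equal(getattr(out, name)[~mask],
                                  getattr(tissue, name)[~mask]), name

    def test_empty_lesion_is_identity(self, default_field):
        tissue = build_tissue(default_field)
        lesion = LesionSpec("null", center=(0.04, 0.02, 0.0), radii=(0, 0, 0))
        out = apply_infarct(default_field, tissue, lesion)
        assert np.array_equal(out.k, tissue.k)
        assert np.array_equal(out.Vi0, tissue.Vi0)

    def test_lesion_outside_heart_rejected(self, default_field):
        tissue = build_tissue(default_field)
        bad = LesionSpec("torso-blob", center=(-0.12, 0.0, -0.2),
                         radii=(0.01, 0.01, 0.01))
        with pytest.raises(LesionError, match="heart"):
            apply_infarct(default_field, tissue, bad)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="anterior-MI"):
            lesion_preset("lateral-MI", GeometryConfig())
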