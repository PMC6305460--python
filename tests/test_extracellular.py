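import numpy as np
import pytest
from scipy import integrate

from neuroforward.extracellular import (Anisotropic, Homogeneous, MoILayers,
                                        OneSphere, ProbeSpec,
                                        anisotropic_line_kernel,
                                        anisotropic_point_kernel,
                                        disc_average, kernel_matrix,
                                        line_source_kernel,
                                        moi_surface_kernel,
                                        moi_three_layer_kernel,
                                        one_sphere_potential,
                                        point_source_kernel,
                                        soma_as_point_kernel)

SIGMA = 0.3


def probe_at(points, medium=None, **kw):
    return ProbeSpec(np.atleast_2d(points), medium=medium or Homogeneous(SIGMA), **kw)


class TestPointSource:
    def test_reference_value(self):
        """1 nA at 100 um in sigma = 0.3 S/m gives 2.653 uV."""
        M = point_source_kernel([[0.0, 0, 0]], probe_at([100.0, 0, 0]))
        assert M.M[0, 0] * 1e3 == pytest.approx(2.653, abs=1e-3)

    def test_linearity_and_zero_current(self):
        M = point_source_kernel([[0.0, 0, 0], [50.0, 0, 0]],
                                probe_at([[100.0, 0, 0], [0, 200.0, 0]]))
        i = np.array([0.0, 0.0])
        assert np.all(M @ i == 0.0)
        i2 = np.array([1.0, -2.0])
        assert np.allclose(M @ (3 * i2), 3 * (M @ i2))

    def test_singularity_clamp(self):
        """A contact inside the segment radius sees the radius potential."""
        at_zero = point_source_kernel([[0.0, 0, 0]], probe_at([0.0, 0, 0]),
                                      radii=np.array([1.0]))
        at_radius = point_source_kernel([[0.0, 0, 0]], probe_at([1.0, 0, 0]))
        assert at_zero.M[0, 0] == pytest.approx(at_radius.M[0, 0], rel=1e-12)

    def test_reciprocity(self):
        a = np.array([10.0, -20.0, 35.0])
        b = np.array([-40.0, 5.0, 100.0])
        M1 = point_source_kernel([a], probe_at(b))
        M2 = point_source_kernel([b], probe_at(a))
        assert M1.M[0, 0] == pytest.approx(M2.M[0, 0], rel=1e-14)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            Homogeneous(0.0)


class TestLineSource:
    START, END = np.array([[0.0, 0, -50.0]]), np.array([[0.0, 0, 50.0]])

    def test_against_quadrature_oracle(self):
        """Closed form matches numerical quadrature of the point kernel."""
        contact = np.array([100.0, 0, 0.0])
        M = line_source_kernel(self.START, self.END, probe_at(contact))
        integral, _err = integrate.quad(lambda z: 1.0 / np.hypot(100.0, z),
                                        -50.0, 50.0)
        oracle = integral / (4 * np.pi * SIGMA * 100.0)
        assert M.M[0, 0] == pytest.approx(oracle, rel=1e-9)
        assert M.M[0, 0] * 1e3 == pytest.approx(2.553, abs=1e-3)

    def test_far_field_matches_point(self):
        """At perpendicular distance 10 segment lengths the difference
        from the point kernel is below 0.1%."""
        contact = np.array([1000.0, 0, 0.0])
        Ml = line_source_kernel(self.START, self.END, probe_at(contact))
        Mp = point_source_kernel([[0.0, 0, 0]], probe_at(contact))
        assert abs(Ml.M[0, 0] / Mp.M[0, 0] - 1) < 1e-3

    def test_mirror_symmetry(self):
        contacts = np.array([[80.0, 0, 30.0], [80.0, 0, -30.0]])
        M = line_source_kernel(self.START, self.END, probe_at(contacts))
        assert M.M[0, 0] == pytest.approx(M.M[1, 0], rel=1e-12)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            line_source_kernel([[0.0, 0, 0]], [[0.0, 0, 0]],
                               probe_at([10.0, 0, 0]))


class TestSomaAsPoint:
    def test_composition(self, ball_and_stick):
        probe = probe_at([[150.0, 0, 100.0], [0.0, 200.0, 300.0]])
        M = soma_as_point_kernel(ball_and_stick, probe)
        Mp = point_source_kernel(ball_and_stick.mid, probe,
                                 radii=ball_and_stick.radius)
        Ml = line_source_kernel(ball_and_stick.start, ball_and_stick.end,
                                probe, radii=ball_and_stick.radius)
        soma = ball_and_stick.label == "soma"
        assert np.allclose(M.M[:, soma], Mp.M[:, soma])
        assert np.allclose(M.M[:, ~soma], Ml.M[:, ~soma])

    def test_no_soma_rejected(self):
        from neuroforward.morphology import Section, discretize
        tree = discretize([Section(0, "dend",
                                   np.array([[0.0, 0, 0], [0, 0, 100.0]]),
                                   np.full(2, 2.0))])
        with pytest.raises(ValueError, match="soma"):
            soma_as_point_kernel(tree, probe_at([50.0, 0, 0]))


class TestDiscAverage:
    def test_zero_radius_is_identity(self):
        probe = probe_at([100.0, 0, 0], r_contact=0.0)
        src = np.array([[0.0, 0, 0]])
        M0 = point_source_kernel(src, probe)
        Md = disc_average(lambda pts: point_source_kernel(src, probe_at(pts)),
                          probe, seed=5)
        assert np.allclose(M0.M, Md.M)

    def test_constant_field_average(self):
        """Averaging a spatially constant kernel returns the same value."""
        probe = probe_at([100.0, 0, 0], r_contact=10.0, m=64)

        class Const:
            def __init__(self, pts):
                self.M = np.ones((len(np.atleast_2d(pts)), 1)) * 0.123
        Md = disc_average(lambda pts: Const(pts), probe, seed=1)
        assert Md.M[0, 0] == pytest.approx(0.123)

    def test_against_quadrature(self):
        """Monte Carlo disc average matches 2D quadrature within 0.5%."""
        r_c = 20.0
        src = np.array([0.0, 0, 0])
        center = np.array([4 * r_c, 0.0, 0.0])
        probe = probe_at(center, r_contact=r_c, m=10**4)
        probe.normals = np.array([[1.0, 0, 0]])  # disc in the yz-plane

        def phi(y, z):
            d = np.linalg.norm(center + np.array([0.0, y, z]) - src)
            return 1.0 / (4 * np.pi * SIGMA * d)

        val, _ = integrate.dblquad(
            lambda r, th: phi(r * np.cos(th), r * np.sin(th)) * r,
            0, 2 * np.pi, 0, r_c)
        exact = val / (np.pi * r_c**2)
        Md = disc_average(
            lambda pts: point_source_kernel([src], probe_at(pts)),
            probe, seed=7)
        assert abs(Md.M[0, 0] / exact - 1) < 5e-3

    def test_zero_normal_rejected(self):
        probe = probe_at([100.0, 0, 0], r_contact=5.0)
        probe.normals = np.zeros((1, 3))
        with pytest.raises(ValueError, match="normal"):
            disc_average(lambda pts: point_source_kernel([[0.0, 0, 0]],
                                                         probe_at(pts)),
                         probe, seed=0)


class TestAnisotropic:
    def test_isotropic_limit(self):
        pa = probe_at([100.0, 50, 30], medium=Anisotropic(SIGMA, SIGMA, SIGMA))
        Ma = anisotropic_point_kernel([[0.0, 0, 0]], pa)
        Mh = point_source_kernel([[0.0, 0, 0]], probe_at([100.0, 50, 30]))
        assert abs(Ma.M[0, 0] / Mh.M[0, 0] - 1) < 1e-12

    def test_depth_conductivity_shapes_potential(self):
        """sigma_z > sigma_x = sigma_y (currents flow with less resistance
        along depth): the closed form phi = I/(4 pi sqrt(...)) makes the
        potential along z depend only on sigma_x*sigma_y, so it is *larger*
        on the z-axis than at equal distance laterally (where sigma_z
        enters and shunts the field)."""
        med = Anisotropic(0.15, 0.15, 0.45)
        pz = anisotropic_point_kernel([[0.0, 0, 0]],
                                      probe_at([0.0, 0, 100.0], medium=med))
        px = anisotropic_point_kernel([[0.0, 0, 0]],
                                      probe_at([100.0, 0, 0.0], medium=med))
        assert pz.M[0, 0] == pytest.approx(
            1.0 / (4 * np.pi * 100.0 * np.sqrt(0.15 * 0.15)), rel=1e-12)
        assert px.M[0, 0] == pytest.approx(
            1.0 / (4 * np.pi * 100.0 * np.sqrt(0.15 * 0.45)), rel=1e-12)
        assert pz.M[0, 0] > px.M[0, 0]

    def test_conductivity_scaling(self):
        m1 = anisotropic_point_kernel([[0.0, 0, 0]],
                                      probe_at([70.0, 20, 50],
                                               medium=Anisotropic(0.2, 0.3, 0.4)))
        m2 = anisotropic_point_kernel([[0.0, 0, 0]],
                                      probe_at([70.0, 20, 50],
                                               medium=Anisotropic(0.4, 0.6, 0.8)))
        assert m2.M[0, 0] == pytest.approx(m1.M[0, 0] / 2.0, rel=1e-12)

    def test_line_by_quadrature_consistency(self):
        """Anisotropic line kernel reduces to the isotropic line kernel."""
        med = Anisotropic(SIGMA, SIGMA, SIGMA)
        s, e = np.array([[0.0, 0, -50]]), np.array([[0.0, 0, 50]])
        Ma = anisotropic_line_kernel(s, e, probe_at([120.0, 0, 10], medium=med))
        Mi = line_source_kernel(s, e, probe_at([120.0, 0, 10]))
        assert abs(Ma.M[0, 0] / Mi.M[0, 0] - 1) < 1e-6

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            Anisotropic(0.0, 0.3, 0.3)


class TestMoI:
    def test_equal_conductivities_reduce_to_homogeneous(self):
        med = MoILayers(SIGMA, SIGMA, SIGMA, h=300.0, n_images=20)
        M = moi_three_layer_kernel([[0.0, 0, 150.0]],
                                   probe_at([100.0, 0, 150.0], medium=med))
        Mh = point_source_kernel([[0.0, 0, 150.0]],
                                 probe_at([100.0, 0, 150.0]))
        assert abs(M.M[0, 0] / Mh.M[0, 0] - 1) < 1e-10

    def test_insulating_surface_doubles_potential(self):
        """sigma_s = 0: the image doubles the surface potential."""
        med = MoILayers(SIGMA, SIGMA, 0.0, h=300.0)
        M = moi_surface_kernel([[0.0, 0, 200.0]],
                               probe_at([0.0, 0, 300.0], medium=med))
        assert M.M[0, 0] * 1e3 == pytest.approx(2 * 2.6526, abs=2e-3)

    def test_highly_conductive_surface_shorts_potential(self):
        """sigma_s -> inf: image coefficient -> -1, surface potential -> 0."""
        med = MoILayers(SIGMA, SIGMA, 1e9, h=300.0)
        M = moi_surface_kernel([[0.0, 0, 200.0]],
                               probe_at([0.0, 0, 300.0], medium=med))
        free = 1.0 / (4 * np.pi * SIGMA * 100.0)
        assert abs(M.M[0, 0]) < 1e-6 * free

    def test_single_interface_reduction(self):
        """sigma_s = sigma_t leaves only the electrode boundary at z = 0."""
        med = MoILayers(0.1, SIGMA, SIGMA, h=300.0, n_images=30)
        M = moi_three_layer_kernel([[0.0, 0, 120.0]],
                                   probe_at([80.0, 0, 50.0], medium=med))
        W = (SIGMA - 0.1) / (SIGMA + 0.1)
        expected = (1 / (4 * np.pi * SIGMA * np.hypot(80, 70))
                    + W / (4 * np.pi * SIGMA * np.hypot(80, 170)))
        assert M.M[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_image_series_convergence(self):
        kw = dict(sigma_g=0.0, sigma_t=SIGMA, sigma_s=1.5, h=300.0)
        src, contact = [[0.0, 0, 150.0]], [50.0, 0, 0.0]
        M30 = moi_three_layer_kernel(
            src, probe_at(contact, medium=MoILayers(n_images=30, **kw)))
        M60 = moi_three_layer_kernel(
            src, probe_at(contact, medium=MoILayers(n_images=60, **kw)))
        assert abs(M30.M[0, 0] / M60.M[0, 0] - 1) < 1e-6
        # geometric decay: each extra reflection order shrinks by |W_TS W_TG|
        M20 = moi_three_layer_kernel(
            src, probe_at(contact, medium=MoILayers(n_images=20, **kw)))
        err20 = abs(M20.M[0, 0] / M60.M[0, 0] - 1)
        err30 = abs(M30.M[0, 0] / M60.M[0, 0] - 1)
        assert err30 < err20

    def test_line_source_special_case(self):
        """Line sources allowed only for sigma_g = 0 with contacts at z=0;
        in the homogeneous-limit parameterization the mirrored line matches
        the free-space line kernel doubled (insulating floor)."""
        med = MoILayers(0.0, SIGMA, SIGMA, h=1000.0, n_images=40)
        s, e = np.array([[0.0, 0, 100.0]]), np.array([[0.0, 0, 200.0]])
        M = moi_three_layer_kernel(None, probe_at([150.0, 0, 0.0], medium=med),
                                   starts=s, ends=e)
        free = line_source_kernel(s, e, probe_at([150.0, 0, 0.0]))
        # the z = 0 mirror term dominates; saline images are ~1e3 um away
        mirrored = line_source_kernel(np.array([[0.0, 0, -100.0]]),
                                      np.array([[0.0, 0, -200.0]]),
                                      probe_at([150.0, 0, 0.0]))
        assert M.M[0, 0] == pytest.approx(
            free.M[0, 0] + mirrored.M[0, 0], rel=0.02)
        with pytest.raises(ValueError, match="sigma_g"):
            moi_three_layer_kernel(
                None, probe_at([150.0, 0, 0.0],
                               medium=MoILayers(0.1, SIGMA, SIGMA, h=1000.0)),
                starts=s, ends=e)

    def test_source_outside_slab_rejected(self):
        med = MoILayers(0.0, SIGMA, 1.5, h=300.0)
        with pytest.raises(ValueError, match="slab"):
            moi_three_layer_kernel([[0.0, 0, -10.0]],
                                   probe_at([0.0, 0, 0.0], medium=med))


class TestOneSphere:
    def test_homogeneous_limit(self):
        med = OneSphere(SIGMA, SIGMA, 500.0)
        M = one_sphere_potential([[0.0, 0, 100.0]],
                                 probe_at([[200.0, 0, 0], [900.0, 0, 0]],
                                          medium=med))
        for i, contact in enumerate([[200.0, 0, 0], [900.0, 0, 0]]):
            d = np.linalg.norm(np.array(contact) - [0, 0, 100.0])
            assert M.M[i, 0] == pytest.approx(1 / (4 * np.pi * SIGMA * d),
                                              rel=1e-10)

    def test_surface_continuity(self):
        """Potential is continuous across the sphere surface."""
        med = OneSphere(SIGMA, 1.5, 500.0)
        eps = 1e-6 * 500.0
        src = [[0.0, 0, 100.0]]
        a = one_sphere_potential(src, probe_at([500.0 - eps, 0, 0], medium=med))
        b = one_sphere_potential(src, probe_at([500.0 + eps, 0, 0], medium=med))
        assert abs(a.M[0, 0] / b.M[0, 0] - 1) < 1e-3

    def test_large_sphere_limit(self):
        med = OneSphere(SIGMA, 1.5, 5e4)
        M = one_sphere_potential([[0.0, 0, 100.0]],
                                 probe_at([300.0, 0, 0], medium=med))
        d = np.hypot(300.0, 100.0)
        assert abs(M.M[0, 0] * 4 * np.pi * SIGMA * d - 1) < 0.01

    def test_source_outside_rejected(self):
        med = OneSphere(SIGMA, 1.5, 500.0)
        with pytest.raises(ValueError, match="inside"):
            one_sphere_potential([[0.0, 0, 600.0]],
                                 probe_at([0.0, 0, 0], medium=med))


class TestDispatcher:
    def test_superposition_and_concatenation(self, ball_and_stick):
        probe = probe_at([[0.0, 100.0, 200.0]], source_model="linesource")
        M = kernel_matrix(ball_and_stick, probe)
        i1 = np.ones(ball_and_stick.n_segments)
        i2 = np.arange(ball_and_stick.n_segments, dtype=float)
        assert np.allclose(M @ (i1 + i2), M @ i1 + M @ i2)
        # concatenated sources = concatenated kernels
        half_a = line_source_kernel(ball_and_stick.start[:4],
                                    ball_and_stick.end[:4], probe,
                                    radii=ball_and_stick.radius[:4])
        half_b = line_source_kernel(ball_and_stick.start[4:],
                                    ball_and_stick.end[4:], probe,
                                    radii=ball_and_stick.radius[4:])
        full = line_source_kernel(ball_and_stick.start, ball_and_stick.end,
                                  probe, radii=ball_and_stick.radius)
        assert np.allclose(np.hstack([half_a.M, half_b.M]), full.M)
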