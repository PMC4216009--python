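"""Force-field family: convolution correctness, reductions, kernel laws, GVF."""

import numpy as np
import pytest

from convef.edgemap import VectorField, edge_map, gradient
from convef.forces import (
    GvfParams,
    KernelSpec,
    convef_field,
    convef_kernels,
    fft_convolve,
    gvf_field,
    normalize_field,
    vef_field,
    vfc_field,
)
from convef.fixtures import ShapeSpec, make_shape_image


def direct_convolve(grid, kernel):
    """O(N^2 t^2) double-loop linear convolution oracle."""
    rows, cols = grid.shape
    kr, kc = kernel.shape
    t_r, t_c = kr // 2, kc // 2
    out = np.zeros_like(grid, dtype=float)
    for y0 in range(rows):
        for x0 in range(cols):
            acc = 0.0
            for dy in range(-t_r, t_r + 1):
                for dx in range(-t_c, t_c + 1):
                    ys, xs = y0 - dy, x0 - dx
                    if 0 <= ys < rows and 0 <= xs < cols:
                        acc += kernel[dy + t_r, dx + t_c] * grid[ys, xs]
            out[y0, x0] = acc
    return out


def brute_force_field(q, n, h, radius):
    """Charge-by-charge summation with the modified distance."""
    rows, cols = q.shape
    u = np.zeros_like(q, dtype=float)
    v = np.zeros_like(q, dtype=float)
    ys, xs = np.nonzero(q)
    for y0 in range(rows):
        for x0 in range(cols):
            for y, x in zip(ys, xs):
                dx, dy = x - x0, y - y0
                if abs(dx) > radius or abs(dy) > radius:
                    continue
                if dx == 0 and dy == 0 and h == 0:
                    continue
                w = q[y, x] * (dx * dx + dy * dy + h) ** (-(n + 2) / 2.0)
                u[y0, x0] += dx * w
                v[y0, x0] += dy * w
    return u, v


class TestFftConvolve:
    def test_identity_kernel(self, rng):
        grid = rng.random((20, 20))
        k = np.zeros((5, 5))
        k[2, 2] = 1.0
        assert np.allclose(fft_convolve(grid, k), grid, atol=1e-12)

    def test_impulse_grid_reproduces_kernel(self, rng):
        grid = np.zeros((15, 15))
        grid[7, 7] = 1.0
        k = rng.random((7, 7))
        out = fft_convolve(grid, k)
        assert np.allclose(out[4:11, 4:11], k, atol=1e-12)

    def test_matches_direct_summation(self, rng):
        grid = rng.random((24, 24))
        kernel = rng.standard_normal((9, 9))
        out = fft_convolve(grid, kernel)
        ref = direct_convolve(grid, kernel)
        assert np.max(np.abs(out - ref)) / np.max(np.abs(ref)) < 1e-10

    def test_rejects_even_kernel_and_empty(self):
        with pytest.raises(ValueError):
            fft_convolve(np.ones((8, 8)), np.ones((4, 5)))
        with pytest.raises(ValueError):
            fft_convolve(np.empty((0, 0)), np.ones((3, 3)))


class TestConvef:
    def test_zero_charges_zero_everything(self):
        field, pot = convef_field(np.zeros((16, 16)), KernelSpec(family="convef", n=2, h=3))
        assert not field.u.any() and not field.v.any() and not pot.any()

    def test_reduces_to_vef(self, rng):
        q = rng.random((24, 24))
        f_convef, _ = convef_field(q, KernelSpec(family="convef", n=1.0, h=0.0))
        f_vef = vef_field(q)
        assert np.max(np.abs(f_convef.u - f_vef.u)) <= 1e-10
        assert np.max(np.abs(f_convef.v - f_vef.v)) <= 1e-10

    def test_single_charge_closed_form_and_brute_force(self):
        q = np.zeros((21, 21))
        q[10, 10] = 1.0
        n, h, d = 2.0, 5.0, 6
        field, _ = convef_field(q, KernelSpec(family="convef", n=n, h=h))
        expected_u = d / (d * d + h) ** ((n + 2) / 2.0)  # pointing toward the charge
        assert field.u[10, 10 - d] == pytest.approx(expected_u, rel=1e-12)
        assert field.v[10, 10 - d] == pytest.approx(0.0, abs=1e-12)
        bu, bv = brute_force_field(q, n, h, radius=10)
        assert np.allclose(field.u, bu, atol=1e-10)
        assert np.allclose(field.v, bv, atol=1e-10)

    @pytest.mark.parametrize("n,h", [(1.0, 0.0), (3.0, 0.0), (0.5, 20.0), (2.0, 6.0)])
    def test_matches_brute_force_sparse(self, rng, n, h):
        q = np.zeros((16, 16))
        q[rng.integers(0, 16, 5), rng.integers(0, 16, 5)] = rng.random(5)
        field, _ = convef_field(q, KernelSpec(family="convef", n=n, h=h, radius=8))
        bu, bv = brute_force_field(q, n, h, radius=8)
        assert np.allclose(field.u, bu, atol=1e-12)
        assert np.allclose(field.v, bv, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(family="convef", n=0.0)
        with pytest.raises(ValueError):
            KernelSpec(family="convef", h=-1.0)


class TestVef:
    def test_symmetric_charges_cancel_at_midpoint(self):
        q = np.zeros((21, 21))
        q[10, 4] = q[10, 16] = 1.0
        field = vef_field(q)
        assert field.u[10, 10] == pytest.approx(0.0, abs=1e-12)
        assert field.v[10, 10] == pytest.approx(0.0, abs=1e-12)

    def test_single_charge_attracts_everywhere(self):
        q = np.zeros((15, 15))
        q[7, 7] = 1.0
        field = vef_field(q)
        yy, xx = np.mgrid[0:15, 0:15]
        inner = field.u * (7 - xx) + field.v * (7 - yy)  # alignment with offset to charge
        mask = (xx != 7) | (yy != 7)
        assert np.all(inner[mask] > 0)


class TestVfc:
    def test_m1_gamma2_parallel_to_vef(self, rng):
        q = np.zeros((24, 24))
        q[rng.integers(0, 24, 6), rng.integers(0, 24, 6)] = rng.random(6)
        f1 = vfc_field(q, KernelSpec(family="vfc_m1", gamma=2.0))
        fv = vef_field(q)
        m1, mv = f1.magnitude(), fv.magnitude()
        mask = (m1 > 1e-12) & (mv > 1e-12)
        cos = (f1.u * fv.u + f1.v * fv.v)[mask] / (m1 * mv)[mask]
        assert cos.min() >= 1.0 - 1e-9

    def test_m2_single_charge_gaussian_magnitude(self):
        q = np.zeros((21, 21))
        q[10, 10] = 1.0
        zeta = 3.0
        f = vfc_field(q, KernelSpec(family="vfc_m2", zeta=zeta))
        for d in (1, 3, 5, 7):
            assert f.magnitude()[10, 10 - d] == pytest.approx(np.exp(-(d**2) / zeta**2), rel=1e-10)

    def test_zero_charges(self):
        f = vfc_field(np.zeros((12, 12)), KernelSpec(family="vfc_m2", zeta=2.0))
        assert not f.u.any()

    def test_wrong_family_rejected(self):
        with pytest.raises(ValueError):
            vfc_field(np.ones((8, 8)), KernelSpec(family="convef"))


class TestGvf:
    def test_constant_edge_map_stays_zero(self):
        f = gvf_field(np.full((16, 16), 0.5), GvfParams(mu=0.2, iterations=50))
        assert not f.u.any() and not f.v.any()

    def test_zero_iterations_is_gradient(self, ushape_edgemap):
        f = gvf_field(ushape_edgemap, GvfParams(mu=0.2, iterations=0))
        g = gradient(ushape_edgemap.values)
        assert np.array_equal(f.u, g.u) and np.array_equal(f.v, g.v)

    def test_energy_non_increasing_on_ushape(self, ushape_edgemap):
        _, energies = gvf_field(
            ushape_edgemap, GvfParams(mu=0.2, iterations=200), return_energy=True
        )
        assert np.all(np.diff(energies) <= 0)

    def test_unstable_dt_rejected_with_bound(self):
        with pytest.raises(ValueError, match="dt"):
            GvfParams(mu=0.2, dt=2.0)


class TestFieldProperties:
    def test_linearity(self, rng):
        q1, q2 = rng.random((16, 16)), rng.random((16, 16))
        spec = KernelSpec(family="convef", n=2.0, h=4.0)
        f12, _ = convef_field(q1 + q2, spec)
        f1, _ = convef_field(q1, spec)
        f2, _ = convef_field(q2, spec)
        assert np.allclose(f12.u, f1.u + f2.u, atol=1e-10)

    def test_translation_equivariance_interior(self):
        q = np.zeros((32, 32))
        q[10, 12] = 1.0
        spec = KernelSpec(family="convef", n=1.5, h=2.0, radius=6)
        f1, _ = convef_field(q, spec)
        f2, _ = convef_field(np.roll(q, (4, 3), axis=(0, 1)), spec)
        assert np.allclose(np.roll(f1.u, (4, 3), axis=(0, 1))[8:24, 8:24], f2.u[8:24, 8:24], atol=1e-12)

    def test_kernel_antisymmetry(self):
        _, kx, ky = convef_kernels((33, 33), n=2.0, h=3.0)
        assert np.allclose(kx, -kx[::-1, ::-1], atol=0)
        assert np.allclose(ky, -ky[::-1, ::-1], atol=0)

    def test_h_weighs_down_nearby_points(self):
        """Near/far potential-kernel ratio strictly decreases with h."""
        ratios = []
        for h in (0.0, 5.0, 10.0, 20.0, 25.0):
            near = (1.0 + h) ** -0.5
            far = (225.0 + h) ** -0.5
            ratios.append(near / far)
        assert np.all(np.diff(ratios) < 0)

    def test_n_speeds_up_decay(self):
        ratios = []
        for n in (0.5, 1.0, 2.0, 3.0):
            pot, _, _ = convef_kernels((33, 33), n=n, h=0.0)
            c = pot.shape[0] // 2
            ratios.append(pot[c, c + 1] / pot[c, c + 15])
        assert np.all(np.diff(ratios) > 0)

    @pytest.mark.parametrize("n,h", [(2.0, 4.0), (1.0, 0.0), (3.0, 10.0)])
    def test_convef_field_is_curl_free_away_from_charges(self, rng, n, h):
        """The field is a gradient field: its discrete curl in a charge-free
        region vanishes to central-difference truncation accuracy.  The
        kernel must cover the full offset range — a truncated square support
        breaks the gradient structure at the support boundary."""
        q = np.zeros((32, 32))
        q[rng.integers(2, 8, 6), rng.integers(2, 30, 6)] = rng.random(6)
        f, _ = convef_field(q, KernelSpec(family="convef", n=n, h=h, radius=31))
        curl = (gradient(f.v).u - gradient(f.u).v)[18:30, 2:30]
        far_magnitude = f.magnitude()[18:30, 2:30].max()
        assert np.max(np.abs(curl)) < 1e-2 * far_magnitude


def test_normalize_field(zero_field):
    f = VectorField(np.full((4, 4), 3.0), np.full((4, 4), 4.0))
    out = normalize_field(f)
    assert np.allclose(out.u, 0.6) and np.allclose(out.v, 0.8)
    z = normalize_field(zero_field)
    assert not z.u.any() and not z.v.any()
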