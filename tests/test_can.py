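import numpy as np
import pytest

from gridplace.can import (
    TORUS_HEIGHT,
    GridModule,
    ModuleStack,
    TorusGeometry,
    build_weights,
    bump_center,
    burn_in,
    calibrate_gamma,
    can_step,
    init_activity,
    integrate_position,
    quantize_displacement,
    torus_coords,
    torus_displacement,
)

LATTICE = [
    (a + 0.5 * b, TORUS_HEIGHT * b) for a in range(-3, 4) for b in range(-3, 4)
]


def exhaustive_displacement(d):
    """Reference minimal-image displacement via a wide lattice search."""
    cands = np.asarray(d) + np.asarray(LATTICE)
    return cands[np.argmin(np.einsum("ij,ij->i", cands, cands))]


class TestTorusGeometry:
    def test_identity_and_wrap(self):
        assert np.allclose(torus_displacement((0.3, 0.4), (0.3, 0.4)), 0.0)
        d = torus_displacement((0.95, 0.0), (0.05, 0.0))
        assert np.allclose(d, [-0.10, 0.0], atol=1e-12)

    def test_matches_exhaustive_shift_search(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            a = rng.uniform([0, 0], [1, TORUS_HEIGHT])
            b = rng.uniform([0, 0], [1, TORUS_HEIGHT])
            got = torus_displacement(a, b)
            ref = exhaustive_displacement(a - b)
            assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(ref), abs=1e-12)

    def test_coordinate_layout(self):
        c = torus_coords(20, 20)
        assert c.shape == (400, 2)
        assert c[0] == pytest.approx([0.025, TORUS_HEIGHT * 0.025])
        assert np.all(c[:, 0] < 1.0) and np.all(c[:, 1] < TORUS_HEIGHT)

    def test_group_kernel_equals_direct_weights(self, geometry):
        """The cached group-circulant path matches the per-pair computation."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.uniform(-0.15, 0.15, 2)
            fast = geometry.weights(v, 0.3, 0.24, 0.035)
            direct = build_weights(geometry.coords, v, 0.3, 0.24, 0.035)
            assert np.abs(fast - direct).max() < 1e-12

    def test_weight_bounds_and_symmetry(self, geometry):
        w = geometry.weights(np.zeros(2), 0.3, 0.24, 0.035)
        assert np.allclose(np.diag(w), 0.3 - 0.035)
        assert np.all(w >= -0.035 - 1e-12) and np.all(w <= 0.3 - 0.035 + 1e-12)
        assert np.allclose(w, w.T)
        far = w.min()
        assert far == pytest.approx(-0.035, abs=0.01)  # inhibition floor


class TestDynamics:
    def test_toy_network_matches_scalar_transcription(self):
        """One step on a 2x2 sheet equals a literal loop transcription."""
        geo = TorusGeometry(2, 2)
        mod = GridModule(gain=0.05, geometry=geo)
        rng = np.random.default_rng(0)
        init_activity(mod, rng)
        a0 = mod.activity.copy()
        v = np.array([0.3, -0.2])
        can_step(mod, v)

        v_r = mod.gain * v  # beta = 0
        n = 4
        w = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                d = geo.coords[i] - geo.coords[j] + v_r
                best = min(
                    (d[0] + sx) ** 2 + (d[1] + sy) ** 2 for sx, sy in LATTICE
                )
                w[i, j] = mod.i_a * np.exp(-best / mod.sigma_w**2) - mod.t_shift
        b = np.array([sum(a0[i] * w[i, j] for i in range(n)) for j in range(n)])
        expected = np.maximum((1 - mod.tau) * b + mod.tau * b / b.mean(), 0.0)
        assert np.abs(mod.activity - expected).max() < 1e-12

    def test_activity_nonnegative_and_bump_forms(self, geometry):
        mod = GridModule(gain=0.05, geometry=geometry)
        init_activity(mod, np.random.default_rng(2))
        assert np.all(mod.activity >= 0) and np.all(mod.activity <= 0.05)
        burn_in(mod, 500)
        assert np.all(mod.activity >= 0)
        # a single bump: every strong local maximum sits inside one packet
        # around the global maximum rather than forming a second bump
        a = mod.activity
        from scipy import ndimage

        sheet = a.reshape(20, 20)
        is_max = (ndimage.maximum_filter(sheet, size=5, mode="wrap") == sheet).ravel()
        strong = np.flatnonzero(is_max & (a > 0.5 * a.max()))
        top = geometry.coords[int(np.argmax(a))]
        for idx in strong:
            sep = np.linalg.norm(torus_displacement(geometry.coords[idx], top))
            assert sep < 0.35

    def test_init_determinism(self, geometry):
        m1 = init_activity(GridModule(0.05, geometry), np.random.default_rng(5))
        m2 = init_activity(GridModule(0.05, geometry), np.random.default_rng(5))
        assert np.array_equal(m1.activity, m2.activity)

    def test_zero_velocity_stability(self, geometry):
        """With v = 0 the bump stays put and total activity is constant."""
        mod = GridModule(gain=0.05, geometry=geometry)
        init_activity(mod, np.random.default_rng(3))
        burn_in(mod, 500)
        c0 = bump_center(mod)
        totals = []
        for _ in range(200):
            can_step(mod, np.zeros(2))
            totals.append(mod.activity.sum())
        drift = np.linalg.norm(torus_displacement(bump_center(mod), c0))
        assert drift < 0.01
        totals = np.asarray(totals)
        assert totals.std() / totals.mean() < 0.01

    def test_bump_center_point_mass_and_wraparound(self, geometry):
        mod = GridModule(gain=0.05, geometry=geometry)
        mod.activity = np.zeros(400)
        mod.activity[37] = 1.0
        assert np.allclose(bump_center(mod), geometry.coords[37], atol=1e-9)
        # two equal masses across the x seam average to 0, not 0.5
        mod.activity = np.zeros(400)
        i = int(np.argmin(np.abs(geometry.coords[:, 0] - 0.125)))
        j = int(np.argmin(np.abs(geometry.coords[:, 0] - 0.875)))
        row = 5
        mod.activity[row * 20 + i % 20] = 1.0
        mod.activity[row * 20 + j % 20] = 1.0
        cx = bump_center(mod)[0]
        assert min(cx, 1 - cx) < 0.01
        mod.activity = np.zeros(400)
        with pytest.raises(ValueError):
            bump_center(mod)

    def test_bump_center_near_argmax(self, geometry):
        mod = GridModule(gain=0.05, geometry=geometry)
        init_activity(mod, np.random.default_rng(4))
        burn_in(mod, 500)
        c = bump_center(mod)
        amax = geometry.coords[int(np.argmax(mod.activity))]
        dist = np.linalg.norm(torus_displacement(c, amax))
        # the settled bump crest is several neurons wide, so the weighted
        # mean can sit most of a pitch away from the arg-max neuron
        assert dist < 1.0 / 20


class TestPathIntegration:
    def test_integrate_position_arithmetic(self):
        assert np.allclose(integrate_position((1, 2), (0, 0), 3.0), [1, 2])
        assert np.allclose(
            integrate_position((0, 0), (0.5, -0.25), 2.0), [1.0, -0.5]
        )

    def test_quantization_grid(self):
        q = quantize_displacement([0.026, -0.02], n_x=20)
        assert q[0] == pytest.approx(0.05)
        assert q[1] == pytest.approx(0.0)

    def test_calibration_determinism_and_scale(self, geometry):
        g1 = calibrate_gamma(
            GridModule(0.05, geometry), np.random.default_rng(11), n_burn=300
        )
        g2 = calibrate_gamma(
            GridModule(0.05, geometry), np.random.default_rng(11), n_burn=300
        )
        assert g1 == g2
        assert 0.25 / 0.05 < g1 < 2.0 / 0.05  # same order as 1/gain

    def test_continuous_readout_recovers_inverse_gain(self, geometry):
        """Without lattice rounding the calibrated scale is 1/gain."""
        g = calibrate_gamma(
            GridModule(0.05, geometry), np.random.default_rng(12),
            n_burn=300, quantize=False,
        )
        assert g == pytest.approx(1.0 / 0.05, rel=0.02)

    def test_straight_run_self_consistency(self, geometry):
        """After calibration a 100-step straight run lands within 10%."""
        rng = np.random.default_rng(13)
        mod = GridModule(0.05, geometry)
        init_activity(mod, rng)
        burn_in(mod, 500)
        mod.gamma = calibrate_gamma(mod, np.random.default_rng(13), n_burn=300)
        pos = np.zeros(2)
        true = np.zeros(2)
        prev = bump_center(mod)
        for _ in range(100):
            speed = float(np.clip(rng.normal(0.8, 0.25), 0.1, 1.5))
            v = np.array([speed, 0.0])
            can_step(mod, v)
            cur = bump_center(mod)
            db = quantize_displacement(torus_displacement(cur, prev), 20)
            prev = cur
            pos = integrate_position(pos, db, mod.gamma)
            true += v
        dist = np.linalg.norm(true)
        assert np.linalg.norm(pos - true) < 0.10 * dist

    def test_equivariance_under_velocity_rotation(self, geometry):
        """Rotating the velocity stream rotates the integrated path (beta=0).

        Checked with the continuous (unquantized) readout, which isolates the
        attractor's directional response from the lattice rounding.
        """
        rng = np.random.default_rng(21)
        vels = rng.normal(0.0, 0.5, size=(300, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )

        def integrate(vseq):
            mod = GridModule(0.05, geometry)
            init_activity(mod, np.random.default_rng(22))
            burn_in(mod, 500)
            prev = bump_center(mod)
            total = np.zeros(2)
            for v in vseq:
                can_step(mod, v)
                cur = bump_center(mod)
                total += torus_displacement(cur, prev)
                prev = cur
            return total

        base = integrate(vels)
        rotated = integrate(vels @ rot.T)
        path = np.sum(np.linalg.norm(vels, axis=1)) * 0.05
        assert np.linalg.norm(rotated - rot @ base) < 0.05 * path

    def test_uncorrected_error_grows_with_path_length(self, geometry):
        """Pure path integration degrades: late errors exceed early errors.

        The per-module drift is a random walk, so the comparison is made on
        the module-mean error, averaged over seeds.
        """
        from gridplace.arena import Arena, default_landmarks, generate_trajectory

        arena = Arena(100.0, default_landmarks())
        early_all, late_all = [], []
        for seed in (5, 6, 7):
            traj = generate_trajectory("center_biased", 1000, arena, seed=seed)
            stack = ModuleStack.build(
                np.random.default_rng(seed), start_pos=traj.pos[0], geometry=geometry
            )
            errs = np.zeros((len(traj), len(stack.modules)))
            for t in range(1, len(traj)):
                stack.step(traj.pos[t] - traj.pos[t - 1])
                errs[t] = np.linalg.norm(stack.estimates - traj.pos[t], axis=1)
            early_all.append(errs[1:500].mean())
            late_all.append(errs[500:].mean())
        assert np.mean(late_all) > np.mean(early_all)

    def test_stack_spacing_factor_orders_gammas(self, geometry):
        stack = ModuleStack.build(
            np.random.default_rng(7), (50.0, 50.0), geometry=geometry,
            calibrate=False, spacing_factor=0.95,
        )
        gammas = [m.gamma for m in stack.modules]
        base = [1.0 / m.gain for m in stack.modules]
        ratio = [g / b for g, b in zip(gammas, base)]
        assert np.allclose(ratio, [0.95**k for k in range(5)])
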