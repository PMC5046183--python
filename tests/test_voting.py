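"""Voting engine: fan membership, kernels, passes, brute-force equivalence."""

import numpy as np
import pytest

from nucleivote import gradients, phantoms, voting
from nucleivote.gradients import VectorField

from oracles import brute_force_votes


def small_disk_field(radius=9.0, size=48, noise=0.0, seed=0):
    """Edge-masked inverse-gradient field of a single-disk phantom."""
    spec = phantoms.PhantomSpec(
        height=size,
        width=size,
        nuclei=[phantoms.Nucleus(center=(size / 2.0, size / 2.0), radius=radius)],
        noise_sigma=noise,
        seed=seed,
    )
    img, gt = phantoms.make_solid_disks(spec)
    i_s = gradients.smooth(img[:, :, 0].astype(float), 1.5)
    e = gradients.detect_edges(i_s)
    return gradients.mask_gradient(gradients.inverse_gradient(i_s), e), gt


class TestSchedule:
    def test_geometric_halving(self):
        assert voting.aperture_schedule(np.pi / 4, 3) == pytest.approx(
            [np.pi / 4, np.pi / 8, np.pi / 16]
        )

    def test_single_pass(self):
        assert voting.aperture_schedule(0.6, 1) == [0.6]

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_strictly_decreasing(self, n):
        s = voting.aperture_schedule(1.1, n)
        assert all(b < a for a, b in zip(s, s[1:]))

    def test_explicit_schedule_must_decrease(self):
        with pytest.raises(ValueError):
            voting.VotingParams(n_passes=2, schedule=[0.3, 0.3])


class TestInArea:
    def test_point_on_axis_mid_radius(self):
        assert voting.in_area((20.5, 0), (0, 0), 0.0, 1, 40, np.pi / 4)

    def test_beyond_r_max(self):
        assert not voting.in_area((41, 0), (0, 0), 0.0, 1, 40, np.pi / 4)

    def test_angular_boundary(self):
        d = 0.3
        r = 20.0
        for eps, expect in ((-0.01, True), (0.01, False)):
            a = d + eps
            q = (r * np.cos(a), r * np.sin(a))
            assert voting.in_area(q, (0, 0), 0.0, 1, 40, d) is expect


class TestKernelCenter:
    def test_along_x(self):
        assert voting.kernel_center((0, 0), 0.0, 1, 40) == pytest.approx((20.5, 0.0))

    def test_along_y_down(self):
        u, v = voting.kernel_center((0, 0), np.pi / 2, 1, 40)
        assert (u, v) == pytest.approx((0.0, 20.5), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 2.5, -2.0])
    def test_center_lies_inside_own_area(self, alpha):
        c = voting.kernel_center((5, 5), alpha, 1, 40)
        assert voting.in_area(c, (5, 5), alpha, 1, 40, 0.01)


class TestCastVotes:
    def test_single_voter_matches_oracle_and_area(self):
        params = voting.VotingParams(r_min=1, r_max=12, sigma=2.0, sigma_radial=3.0)
        field = VectorField(np.zeros((32, 32)), np.zeros((32, 32)))
        field.gx[16, 10] = 1.0
        d = voting.initial_directions(field)
        v = voting.cast_votes(field, d, params, 0.5)
        ref = brute_force_votes((32, 32), [10], [16], [0.0], 1, 12, 2.0, 3.0, 0.5)
        assert np.max(np.abs(v - ref)) < 1e-9
        ys, xs = np.nonzero(v)
        for x, y in zip(xs, ys):
            assert voting.in_area((x, y), (10, 16), 0.0, 1, 12, 0.5)

    def test_matches_brute_force_on_disk_phantom(self):
        # 64x64 phantom, <= 200 active pixels, pass-1 aperture
        field, _ = small_disk_field(radius=12.0, size=64)
        assert 0 < field.support().sum() <= 200
        params = voting.VotingParams()
        d = voting.initial_directions(field)
        v = voting.cast_votes(field, d, params, params.deltas()[0])
        ref = brute_force_votes(
            (64, 64),
            d.xs,
            d.ys,
            d.alpha,
            params.r_min,
            params.r_max,
            params.sigma,
            params.radial_sigma(),
            params.deltas()[0],
        )
        assert np.max(np.abs(v - ref)) < 1e-9

    def test_voter_order_irrelevant(self):
        field, _ = small_disk_field(radius=9.0)
        params = voting.VotingParams()
        d = voting.initial_directions(field)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(d))
        shuffled = voting.DirectionMap(d.xs[perm], d.ys[perm], d.alpha[perm])
        a = voting.cast_votes(field, d, params, 0.6)
        b = voting.cast_votes(field, shuffled, params, 0.6)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_empty_support_gives_zero_image(self):
        field = VectorField(np.zeros((16, 16)), np.zeros((16, 16)))
        v = voting.cast_votes(
            field, voting.initial_directions(field), voting.VotingParams(), 0.5
        )
        assert not v.any()

    @pytest.mark.parametrize("alpha", [0.0, 0.7, 2.1])
    def test_vote_mass_rotation_invariant(self, alpha):
        params = voting.VotingParams(r_min=1, r_max=15, sigma=3.0)
        field = VectorField(np.zeros((101, 101)), np.zeros((101, 101)))
        field.gx[50, 50] = np.cos(alpha)
        field.gy[50, 50] = np.sin(alpha)
        v = voting.cast_votes(field, voting.initial_directions(field), params, 0.7)
        ref_field = VectorField(np.zeros((101, 101)), np.zeros((101, 101)))
        ref_field.gx[50, 50] = 1.0
        ref = voting.cast_votes(
            ref_field, voting.initial_directions(ref_field), params, 0.7
        )
        assert v.sum() == pytest.approx(ref.sum(), rel=0.05)


class TestUpdateDirections:
    def test_single_maximum_defines_new_direction(self):
        params = voting.VotingParams(r_min=1, r_max=10, sigma=2.0)
        field = VectorField(np.zeros((24, 24)), np.zeros((24, 24)))
        field.gx[12, 4] = 1.0
        d = voting.initial_directions(field)
        v = np.zeros((24, 24))
        v[8, 9] = 1.0  # q0 = (9, 8), inside the fan of (4, 12) pointing +x
        nd = voting.update_directions(v, d, params, np.pi / 4)
        assert nd.alpha[0] == pytest.approx(np.arctan2(8 - 12, 9 - 4))
        assert (nd.tx[0], nd.ty[0]) == (9.0, 8.0)

    def test_constant_votes_tie_break_nearest_then_row_major(self):
        params = voting.VotingParams(r_min=1, r_max=10, sigma=2.0)
        field = VectorField(np.zeros((24, 24)), np.zeros((24, 24)))
        field.gx[12, 4] = 1.0  # alpha = 0
        d = voting.initial_directions(field)
        v = np.ones((24, 24))
        nd = voting.update_directions(v, d, params, np.pi / 4)
        # nearest in-area pixels at r=1: only (5, 12) lies within the fan
        assert (nd.tx[0], nd.ty[0]) == (5.0, 12.0)
        assert nd.alpha[0] == pytest.approx(0.0)

    def test_off_image_fan_keeps_direction(self):
        params = voting.VotingParams(r_min=1, r_max=5, sigma=2.0)
        field = VectorField(np.zeros((10, 40)), np.zeros((10, 40)))
        field.gx[5, 39] = 1.0  # fan (+x) falls fully off-image except r<=? none
        d = voting.initial_directions(field)
        nd = voting.update_directions(np.ones((10, 40)), d, params, 0.05)
        assert nd.alpha[0] == d.alpha[0]

    def test_two_disk_rims_aim_at_own_centers(self):
        spec = phantoms.PhantomSpec(
            height=120,
            width=120,
            nuclei=[
                phantoms.Nucleus(center=(30.0, 60.0), radius=12.0),
                phantoms.Nucleus(center=(90.0, 60.0), radius=12.0),
            ],
            noise_sigma=0.0,
        )
        img, gt = phantoms.make_solid_disks(spec)
        i_s = gradients.smooth(img[:, :, 0].astype(float), 1.5)
        e = gradients.detect_edges(i_s)
        field = gradients.mask_gradient(gradients.inverse_gradient(i_s), e)
        params = voting.VotingParams()
        d = voting.initial_directions(field)
        v = voting.cast_votes(field, d, params, params.deltas()[0])
        nd = voting.update_directions(v, d, params, params.deltas()[0])
        good = 0
        for x, y, a in zip(nd.xs, nd.ys, nd.alpha):
            c = min(gt.centers, key=lambda c: np.hypot(c[0] - x, c[1] - y))
            bearing = np.arctan2(c[1] - y, c[0] - x)
            dev = abs(voting.wrap_angle(a - bearing))
            good += dev < np.radians(15)
        assert good / len(nd) >= 0.9


class TestRunVoting:
    def test_single_pass_equals_one_cast(self):
        field, _ = small_disk_field(radius=9.0)
        params = voting.VotingParams(n_passes=1)
        direct = voting.cast_votes(
            field,
            voting.initial_directions(field),
            params,
            params.delta_max,
            sigma_radial=params.radial_sigma(),
        )
        direct /= direct.max()
        assert np.allclose(voting.run_voting(field, params), direct)

    @pytest.mark.parametrize("radius", [10.0, 14.0, 18.0])
    def test_disk_vote_peak_at_center(self, radius):
        field, gt = small_disk_field(radius=radius, size=96)
        v = voting.run_voting(field, voting.VotingParams())
        my, mx = np.unravel_index(np.argmax(v), v.shape)
        assert np.hypot(mx - gt.centers[0][0], my - gt.centers[0][1]) <= 2.0

    def test_translation_equivariance(self):
        field, _ = small_disk_field(radius=9.0, size=64)
        shifted = VectorField(np.roll(field.gx, 7, axis=1), np.roll(field.gy, 7, axis=1))
        params = voting.VotingParams(r_min=1, r_max=14)
        a = voting.run_voting(field, params)
        b = voting.run_voting(shifted, params)
        # compare on the interior, away from the wrap-around columns
        assert np.allclose(np.roll(a, 7, axis=1)[:, 24:50], b[:, 24:50], atol=1e-9)

    def test_all_zero_field_stays_zero(self):
        field = VectorField(np.zeros((20, 20)), np.zeros((20, 20)))
        assert not voting.run_voting(field, voting.VotingParams()).any()

    def test_output_normalised(self):
        field, _ = small_disk_field(radius=9.0)
        v = voting.run_voting(field, voting.VotingParams())
        assert v.max() == pytest.approx(1.0)
        assert v.min() >= 0.0
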