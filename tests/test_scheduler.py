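"""Sector classification, LED-couple selection and path scheduling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photopath import (
    Move,
    Point3,
    SectorConvention,
    Toolpath,
    all_on_schedule,
    classify_sector,
    inject_led_commands,
    schedule_path,
    sector_to_leds,
    xy_direction,
)

CONV = SectorConvention()


def nearest_center_sector(theta: float) -> int:
    """Brute-force oracle: nearest of the 8 sector centers by angular
    distance; a tie goes to the sector whose lower boundary the angle is."""
    dists = []
    for k, c in enumerate(CONV.centers):
        d = abs((theta - c + 180.0) % 360.0 - 180.0)
        dists.append((d, k))
    best = min(d for d, _ in dists)
    winners = [k for d, k in dists if math.isclose(d, best, abs_tol=1e-9)]
    if len(winners) == 1:
        return winners[0]
    for k in winners:  # boundary tie: lower-boundary-inclusive sector
        lower = (k * 45.0 - 22.5) % 360.0
        if math.isclose(theta % 360.0, lower, abs_tol=1e-9):
            return k
    raise AssertionError("unresolvable tie")


class TestXyDirection:
    def test_plus_x(self):
        mv = Move("print", Point3(0, 0, 0), Point3(5, 0, 0))
        (vx, vy), theta = xy_direction(mv)
        assert (vx, vy) == (1.0, 0.0) and theta == 0.0

    def test_pure_z_degenerate(self):
        mv = Move("print", Point3(0, 0, 0), Point3(0, 0, 0.2))
        assert xy_direction(mv) is None

    def test_z_component_ignored_in_projection(self):
        mv = Move("print", Point3(0, 0, 0), Point3(3, 3, 1))
        (vx, vy), theta = xy_direction(mv)
        assert theta == pytest.approx(45.0)
        assert math.hypot(vx, vy) == pytest.approx(1.0, abs=1e-9)

    def test_travel_rejected(self):
        mv = Move("travel", Point3(0, 0, 0), Point3(5, 0, 0))
        with pytest.raises(ValueError):
            xy_direction(mv)


class TestClassifySector:
    @pytest.mark.parametrize("theta,expected", [(0.0, 0), (30.0, 1), (350.0, 0)])
    def test_known_angles(self, theta, expected):
        assert classify_sector(theta) == expected

    def test_agrees_with_nearest_center_all_integer_degrees(self):
        for theta in range(360):
            assert classify_sector(float(theta)) == nearest_center_sector(theta)

    def test_agrees_with_nearest_center_random_angles(self):
        rng = np.random.default_rng(2023)
        for theta in rng.uniform(0.0, 360.0, size=10_000):
            assert classify_sector(theta) == nearest_center_sector(theta)

    def test_boundary_belongs_to_upper_sector(self):
        assert classify_sector(22.5) == 1
        assert classify_sector(337.5) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_sector(360.0)


class TestSectorToLeds:
    def test_plus_x_lights_couple_behind(self):
        azimuths, code = sector_to_leds(0)
        assert azimuths == frozenset({180.0}) and code == 1

    def test_diagonal_lights_two_couples(self):
        azimuths, code = sector_to_leds(1)
        assert azimuths == frozenset({180.0, 270.0}) and code == 2

    def test_minus_x_lights_front_couple(self):
        azimuths, code = sector_to_leds(4)
        assert azimuths == frozenset({0.0}) and code == 5

    def test_couple_count_one_iff_cardinal(self):
        for k in range(8):
            azimuths, _ = sector_to_leds(k)
            assert len(azimuths) == (1 if k % 2 == 0 else 2)

    def test_opposite_side_property_over_full_sectors(self):
        # every active azimuth lies in the half-plane behind any direction
        # of its sector: cos(azimuth - theta) <= cos(112.5 deg)
        bound = math.cos(math.radians(112.5)) + 1e-12
        for k in range(8):
            azimuths, _ = sector_to_leds(k)
            for theta in np.linspace(k * 45.0 - 22.5, k * 45.0 + 22.5, 64,
                                     endpoint=False):
                for a in azimuths:
                    assert math.cos(math.radians(a - theta)) <= bound

    def test_code_is_sector_plus_one_by_default(self):
        assert [sector_to_leds(k)[1] for k in range(8)] == list(range(1, 9))

    def test_custom_code_map(self):
        conv = SectorConvention(code_map=(8, 7, 6, 5, 4, 3, 2, 1))
        assert sector_to_leds(0, conv)[1] == 8


def _random_path(rng, n_moves=6):
    pts = [(0.0, 0.0, 0.0)]
    for _ in range(n_moves):
        ang = rng.uniform(0, 2 * math.pi)
        step = rng.uniform(0.5, 5.0)
        x, y, z = pts[-1]
        pts.append((x + step * math.cos(ang), y + step * math.sin(ang), z))
    return Toolpath.from_points(pts, feed=5.0)


def _rotated(path, degrees):
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    pts = [path.moves[0].start.as_tuple()] + [m.end.as_tuple() for m in path.moves]
    rot = [(c * x - s * y, s * x + c * y, z) for x, y, z in pts]
    return Toolpath.from_points(rot, feed=5.0)


class TestSchedulePath:
    def test_single_move_plus_x(self):
        path = Toolpath.from_points([(0, 0, 0), (5, 0, 0)], feed=5)
        sched = schedule_path(path)
        assert [s.code for s in sched] == [1]

    def test_serpentine_codes_alternate_with_connectors(self):
        # two +x/-x rows joined by +y connectors
        pts = [(0, 0, 0), (10, 0, 0), (10, 1, 0), (0, 1, 0), (0, 2, 0), (10, 2, 0)]
        sched = schedule_path(Toolpath.from_points(pts, feed=5))
        assert [s.code for s in sched] == [1, 3, 5, 3, 1]

    def test_closed_ccw_square(self):
        pts = [(0, 0, 0), (5, 0, 0), (5, 5, 0), (0, 5, 0), (0, 0, 0)]
        sched = schedule_path(Toolpath.from_points(pts, feed=5))
        assert [s.code for s in sched] == [1, 3, 5, 7]

    def test_degenerate_and_travel_hold_previous_state(self):
        pts = [(0, 0, 0), (5, 0, 0), (5, 0, 0.2), (5, 5, 0.2)]
        kinds = ["print", "print", "travel"]
        sched = schedule_path(Toolpath.from_points(pts, kinds, feed=5))
        assert [s.code for s in sched] == [1, 1, 1]
        assert [s.inherited for s in sched] == [False, True, True]

    def test_leading_degenerate_gets_code_zero(self):
        pts = [(0, 0, 0), (0, 0, 0.2), (5, 0, 0.2)]
        kinds = ["travel", "print"]
        sched = schedule_path(Toolpath.from_points(pts, kinds, feed=5))
        assert [s.code for s in sched] == [0, 1]

    def test_empty_path_empty_schedule(self):
        assert schedule_path(Toolpath([])) == []

    @settings(max_examples=150, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_by_45_shifts_codes_cyclically(self, seed):
        rng = np.random.default_rng(seed)
        path = _random_path(rng)
        base = [s.code for s in schedule_path(path)]
        rot = [s.code for s in schedule_path(_rotated(path, 45.0))]
        assert rot == [(c - 1 + 1) % 8 + 1 for c in base]


class TestInject:
    def test_one_move_path_single_command_plus_trailing_off(self):
        path = Toolpath.from_points([(0, 0, 0), (5, 0, 0)], feed=5)
        doc = inject_led_commands(path)
        m102 = [ln for ln in doc.splitlines() if ln.startswith("M102")]
        assert m102 == ["M102 P1", "M102 P0"]

    def test_first_print_move_preceded_by_command(self, grid_path):
        doc = inject_led_commands(grid_path)
        motion_seen = False
        for ln in doc.splitlines():
            if ln.startswith(("G0 ", "G1 ")):
                motion_seen = True
                break
            if ln.startswith("M102"):
                assert not motion_seen
                return
        raise AssertionError("no M102 before the first motion line")

    def test_command_count_is_changes_plus_trailing(self, grid_path):
        sched = schedule_path(grid_path)
        changes = sum(
            1 for a, b in zip([None] + [s.code for s in sched], [s.code for s in sched])
            if a != b
        )
        doc = inject_led_commands(grid_path, sched)
        n = sum(1 for ln in doc.splitlines() if ln.startswith("M102"))
        assert n == changes + 1  # + trailing all-off

    def test_all_on_control_single_m102_p9(self, grid_path):
        doc = inject_led_commands(grid_path, all_on=True, trailing_off=False)
        m102 = [ln for ln in doc.splitlines() if ln.startswith("M102")]
        assert m102 == ["M102 P9"]

    def test_off_on_travel_reemits_code_after_travel(self):
        pts = [(0, 0, 0), (10, 0, 0), (10, 5, 0), (20, 5, 0)]
        kinds = ["print", "travel", "print"]
        path = Toolpath.from_points(pts, kinds, feed=5)
        doc = inject_led_commands(path, off_on_travel=True, trailing_off=False)
        m102 = [ln for ln in doc.splitlines() if ln.startswith("M102")]
        assert m102 == ["M102 P1", "M102 P0", "M102 P1"]

    def test_all_on_schedule_codes(self, grid_path):
        assert {s.code for s in all_on_schedule(grid_path)} == {9}
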