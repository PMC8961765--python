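"""Structure features: SASA, burial, fit, secondary structure, clustering."""

import numpy as np
import pytest

from protovar.datamodel import ProteinContext, VariantRecord
from protovar.simulate import make_toy_structure
from protovar.structfeat import (
    assign_secondary_structure,
    burial_category,
    cluster1d_count,
    cluster3d_count,
    compute_rel_sasa,
    disordered_flag,
    goodness_of_fit,
    modelled_status,
    sidechain_sasa_percent,
)

# van der Waals radii matching the engine's defaults (by element)
_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


def _fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def oracle_atom_sasa(coords, elements, idx, probe=1.4, n_points=2000):
    """Independent sphere-point SASA of one atom (dense quadrature)."""
    centers = np.asarray(coords, dtype=float)
    radii = np.array([_RADII[e] for e in elements]) + probe
    r = radii[idx]
    pts = centers[idx] + r * _fibonacci_sphere(n_points)
    free = np.ones(len(pts), dtype=bool)
    for j, (c, rj) in enumerate(zip(centers, radii)):
        if j == idx:
            continue
        free &= np.linalg.norm(pts - c, axis=1) >= rj
    return 4.0 * np.pi * r**2 * free.mean()


def _residue_list(coords):
    """Flatten a coords dict into (positions, atom names, xyz, elements)."""
    pos_l, names, xyz, elems = [], [], [], []
    for p in sorted(coords):
        for name, c in coords[p].items():
            pos_l.append(p)
            names.append(name)
            xyz.append(c)
            elems.append(name[0])
    return pos_l, names, np.array(xyz), elems


class TestRelSasa:
    def test_isolated_residue_fully_exposed(self):
        coords = {1: {
            "N": np.array([-1.2, 0.0, 0.0]), "CA": np.array([0.0, 0.0, 0.0]),
            "C": np.array([1.2, 0.0, 0.0]), "O": np.array([1.8, 1.0, 0.0]),
            "CB": np.array([0.0, 1.4, 0.8]),
        }}
        out = sidechain_sasa_percent(coords, {1: "A"})
        assert out[1] >= 95.0

    def test_packed_core_is_buried_and_matches_oracle(self):
        _, coords, seq = make_toy_structure(60, "packed_globule", seed=1)
        names = {i + 1: seq[i] for i in range(60)}
        rel = sidechain_sasa_percent(coords, names)
        most_buried = min(rel, key=rel.get)
        assert rel[most_buried] <= 10.0
        # independent dense-quadrature oracle on the buried CB atom
        pos_l, atom_names, xyz, elems = _residue_list(coords)
        idx = next(i for i, (p, n) in enumerate(zip(pos_l, atom_names))
                   if p == most_buried and n == "CB")
        area = oracle_atom_sasa(xyz, elems, idx)
        iso = oracle_atom_sasa(
            np.array(list(coords[most_buried].values())),
            [n[0] for n in coords[most_buried]],
            list(coords[most_buried]).index("CB"),
        )
        assert 100.0 * area / iso <= 10.0

    def test_sphere_point_convergence(self):
        _, coords, seq = make_toy_structure(40, "packed_globule", seed=2)
        names = {i + 1: seq[i] for i in range(40)}
        # in the converged regime, doubling the point count moves no
        # residue by 2 percentage points
        a = sidechain_sasa_percent(coords, names, n_points=960)
        b = sidechain_sasa_percent(coords, names, n_points=1920)
        diffs = np.array([abs(a[p] - b[p]) for p in a])
        assert diffs.max() < 2.0
        # the faster default keeps the bulk of residues within the same
        # band (worst-case quadrature noise ~2 A^2 on a CB-sized ref)
        d300 = sidechain_sasa_percent(coords, names, n_points=300)
        diffs_default = np.array([abs(d300[p] - a[p]) for p in a])
        assert np.quantile(diffs_default, 0.95) < 2.5
        assert diffs_default.max() < 5.0

    def test_rigid_motion_stability(self):
        _, coords, seq = make_toy_structure(40, "packed_globule", seed=3)
        names = {i + 1: seq[i] for i in range(40)}
        base = sidechain_sasa_percent(coords, names)
        shift = np.array([7.0, -3.0, 11.0])
        translated = {p: {a: v + shift for a, v in at.items()}
                      for p, at in coords.items()}
        trans = sidechain_sasa_percent(translated, names)
        assert max(abs(base[p] - trans[p]) for p in base) < 1e-9
        c, s = np.cos(0.7), np.sin(0.7)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rotated = {p: {a: R @ v for a, v in at.items()}
                   for p, at in coords.items()}
        rot = sidechain_sasa_percent(rotated, names)
        # fixed sphere-point quadrature is only statistically rotation
        # invariant; values must stay within quadrature noise
        assert max(abs(base[p] - rot[p]) for p in base) < 5.0

    def test_unmodelled_position_is_missing(self):
        ctx = ProteinContext("g", "ACDEF", coords={})
        assert compute_rel_sasa(ctx, 3) is None


class TestBurial:
    @pytest.mark.parametrize("value,expected", [
        (5.0, "buried"), (8.99, "buried"), (9.0, "intermediate"),
        (36.0, "intermediate"), (36.01, "exposed"), (None, None),
    ])
    def test_bins(self, value, expected):
        assert burial_category(value) == expected

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            burial_category(-1.0)


class TestGoodnessOfFit:
    def test_large_residue_into_buried_site(self):
        from protovar.seqfeat import volume_change
        delta, _ = volume_change("G", "W")
        assert goodness_of_fit("G", "W", "buried", delta)
        assert not goodness_of_fit("G", "W", "exposed", delta)

    def test_small_volume_change_fits(self):
        from protovar.seqfeat import volume_change
        delta, _ = volume_change("T", "S")
        assert abs(delta) < 40.0
        assert not goodness_of_fit("T", "S", "buried", delta)

    def test_missing_burial_is_false(self):
        assert not goodness_of_fit("G", "W", None, 170.0)


class TestSecondaryStructure:
    def test_ideal_helix_is_h(self):
        _, coords, seq = make_toy_structure(30, "helix", seed=0)
        ctx = ProteinContext("g", seq, coords=coords)
        ss = assign_secondary_structure(ctx)
        interior = [ss[p] for p in range(2, 30)]
        assert all(s == "H" for s in interior)

    def test_ideal_strand_is_e(self):
        _, coords, seq = make_toy_structure(30, "strand", seed=0)
        ctx = ProteinContext("g", seq, coords=coords)
        ss = assign_secondary_structure(ctx)
        assert all(ss[p] == "E" for p in range(2, 30))

    def test_track_takes_precedence(self):
        _, coords, seq = make_toy_structure(10, "helix", seed=0)
        track = {p: "C" for p in range(1, 11)}
        ctx = ProteinContext("g", seq, coords=coords,
                             tracks={"secondary_structure": track})
        assert assign_secondary_structure(ctx) == track

    def test_no_input_means_no_assignment(self):
        ctx = ProteinContext("g", "ACDEF")
        assert assign_secondary_structure(ctx) == {}


class TestModelledStatus:
    def test_inside_and_outside(self):
        _, coords, seq = make_toy_structure(20, "helix", seed=0)
        kept = {p: coords[p] for p in range(5, 21)}
        ctx = ProteinContext("g", seq + "A" * 20, coords=kept)
        assert modelled_status(10, ctx)
        assert not modelled_status(30, ctx)

    def test_empty_structure_all_unmodelled(self):
        ctx = ProteinContext("g", "ACDEF")
        assert not any(modelled_status(p, ctx) for p in range(1, 6))


class TestClustering:
    def _linear_coords(self, n, spacing=3.8):
        return {i: {"CA": np.array([spacing * i, 0.0, 0.0])}
                for i in range(1, n + 1)}

    def _pv(self, pos):
        return VariantRecord("g", pos, "A", "V", "pathogenic")

    def test_no_other_pathogenic_is_zero(self):
        coords = self._linear_coords(10)
        assert cluster3d_count(self._pv(5), [self._pv(5)], coords) == 0

    def test_linear_fixture_count(self):
        # neighbours at i±1 (3.8 A) and i±2 (7.6 A) all inside 8 A
        coords = self._linear_coords(11)
        center = self._pv(6)
        paths = [center] + [self._pv(6 + d) for d in (-2, -1, 1, 2)]
        assert cluster3d_count(center, paths, coords, radius=8.0) == 4

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 50
        coords = {i: {"CA": rng.uniform(0, 30, size=3)}
                  for i in range(1, n + 1)}
        paths = [self._pv(i) for i in range(1, n + 1)]
        for v in paths[:10]:
            expected = sum(
                1 for o in paths
                if o.position != v.position
                and np.linalg.norm(coords[o.position]["CA"]
                                   - coords[v.position]["CA"]) <= 8.0
            )
            assert cluster3d_count(v, paths, coords) == expected

    def test_leave_one_out(self):
        coords = self._linear_coords(11)
        center = self._pv(6)
        others = [self._pv(6 + d) for d in (-1, 1)]
        with_self = cluster3d_count(center, [center] + others, coords)
        without_self = cluster3d_count(center, others, coords)
        assert with_self == without_self == 2

    def test_unmodelled_is_missing(self):
        coords = self._linear_coords(5)
        assert cluster3d_count(self._pv(9), [self._pv(1)], coords) is None

    def test_sequence_window_count(self):
        center = self._pv(10)
        others = [self._pv(p) for p in (4, 5, 10, 15, 16)]
        # 5, 15 within +-5; 4, 16 outside; 10 is another variant at the
        # same position (distance 0)
        center2 = VariantRecord("g", 10, "A", "L", "pathogenic")
        assert cluster1d_count(center2, others, window=5) == 3


class TestDisorderedFlag:
    def _ctx(self, track):
        return ProteinContext("g", "A" * 10, tracks={"disorder_prob": track})

    def test_threshold_closed(self):
        assert disordered_flag(1, self._ctx({1: 0.9}))
        assert disordered_flag(1, self._ctx({1: 0.5}))
        assert not disordered_flag(1, self._ctx({1: 0.49}))

    def test_missing_track(self):
        assert disordered_flag(1, ProteinContext("g", "A" * 10)) is None
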