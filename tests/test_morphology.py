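"""Sholl analysis, tree metrics, soma measurements, transcript coverage,
and multi-reference qPCR quantification."""

import numpy as np
import pandas as pd
import pytest

from neuroquant.expression import relative_expression
from neuroquant.imaging import PixelGeometry
from neuroquant.morphology import (
    NeuronTree,
    read_swc,
    sholl,
    soma_metrics,
    soma_transcript_coverage,
    tree_metrics,
)


def _tree(rows):
    return NeuronTree(nodes=pd.DataFrame(rows))


def _node(i, x, y, z, parent, typ=3):
    return {"id": i, "type": typ, "x": x, "y": y, "z": z, "radius": 1.0, "parent": parent}


@pytest.fixture
def straight_dendrite():
    return _tree([_node(1, 0, 0, 0, -1, 1), _node(2, 55, 0, 0, 1)])


@pytest.fixture
def y_branch():
    return _tree(
        [
            _node(1, 0, 0, 0, -1, 1),
            _node(2, 25, 0, 0, 1),
            _node(3, 45, 10, 0, 2),
            _node(4, 45, -10, 0, 2),
        ]
    )


def _random_tree(rng, n_branches=8):
    rows = [_node(1, 0, 0, 0, -1, 1)]
    next_id = 2
    frontier = [1]
    coords = {1: np.zeros(3)}
    while next_id < 2 + 2 * n_branches:
        parent = int(rng.choice(frontier))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(8, 40)
        p = coords[parent] + direction * length
        rows.append(_node(next_id, *p, parent))
        coords[next_id] = p
        frontier.append(next_id)
        next_id += 1
    return _tree(rows)


def _sholl_oracle(tree, step=10.0):
    """Dense-sampling oracle: walk each segment at 0.1-um steps and count
    sign changes of (distance to soma - r) for every radius."""
    segs = tree.segments()
    soma = tree.soma_xyz
    dmax = max(np.linalg.norm(s - soma) for seg in segs for s in seg)
    radii = np.arange(step, dmax + step, step)
    counts = np.zeros(len(radii), dtype=int)
    for seg in segs:
        a, b = seg
        L = np.linalg.norm(b - a)
        n = max(int(L / 0.1), 2)
        t = np.linspace(0, 1, n)
        pts = a[None] + t[:, None] * (b - a)[None]
        d = np.linalg.norm(pts - soma, axis=1)
        for k, r in enumerate(radii):
            counts[k] += int(np.sum(np.diff(np.sign(d - r)) != 0))
    return radii, counts


class TestSholl:
    def test_straight_dendrite_profile(self, straight_dendrite):
        prof = sholl(straight_dendrite)
        assert prof["intersections"].tolist() == [1, 1, 1, 1, 1, 0]
        assert prof.attrs["sum_intersections"] == 5

    def test_y_branch_profile(self, y_branch):
        prof = sholl(y_branch)
        assert prof["intersections"].tolist()[:4] == [1, 1, 2, 2]

    def test_radii_beyond_extent_are_zero(self, straight_dendrite):
        prof = sholl(straight_dendrite, max_radius_um=100.0)
        beyond = prof[prof["radius_um"] > 55]
        assert (beyond["intersections"] == 0).all()

    def test_matches_dense_sampling_oracle_on_random_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            tree = _random_tree(rng)
            prof = sholl(tree)
            radii, oracle = _sholl_oracle(tree)
            got = prof.set_index("radius_um")["intersections"]
            for r, c in zip(radii, oracle):
                assert got.get(r, 0) == c


class TestTreeMetrics:
    def test_single_unbranched_dendrite(self, straight_dendrite):
        m = tree_metrics(straight_dendrite)
        assert m == {
            "total_length_um": 55.0,
            "n_branches": 1,
            "n_branch_points": 0,
            "n_end_tips": 1,
            "max_branch_order": 1,
        }

    def test_symmetric_binary_tree_depth_two(self):
        # trunk 50, two level-1 children 50 each, four level-2 children 50
        rows = [_node(1, 0, 0, 0, -1, 1), _node(2, 50, 0, 0, 1)]
        nid = 3
        for p, (dx, dy) in [(2, (35.36, 35.36)), (2, (35.36, -35.36))]:
            rows.append(_node(nid, 50 + dx, dy, 0, p))
            nid += 1
        for p in (3, 4):
            base = rows[p - 1]
            for sign in (1, -1):
                rows.append(_node(nid, base["x"] + 35.36, base["y"] + sign * 35.36, 0, p))
                nid += 1
        m = tree_metrics(_tree(rows))
        assert m["n_branches"] == 7
        assert m["n_branch_points"] == 3
        assert m["n_end_tips"] == 4
        assert m["max_branch_order"] == 3
        assert m["total_length_um"] == pytest.approx(7 * 50.0, rel=0.01)

    def test_metrics_invariant_to_rotation(self, y_branch):
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        rot = y_branch.nodes.copy()
        x, y = rot["x"].to_numpy(), rot["y"].to_numpy()
        rot["x"], rot["y"] = c * x - s * y, s * x + c * y
        m1 = tree_metrics(y_branch)
        m2 = tree_metrics(NeuronTree(rot))
        assert m1["total_length_um"] == pytest.approx(m2["total_length_um"])
        for k in ("n_branches", "n_branch_points", "n_end_tips", "max_branch_order"):
            assert m1[k] == m2[k]

    def test_totals_additive_over_subtrees(self, y_branch):
        m = tree_metrics(y_branch)
        # the two child branches plus the trunk account for the whole length
        segs = y_branch.segments()
        assert m["total_length_um"] == pytest.approx(
            np.sum(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1))
        )

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError):
            _tree([_node(1, 0, 0, 0, 2, 1), _node(2, 1, 0, 0, 1)])


class TestSwcIO(object):
    def test_round_trip_through_swc_file(self, tmp_path, y_branch):
        path = tmp_path / "cell.swc"
        lines = ["# synthetic reconstruction"]
        for _, r in y_branch.nodes.iterrows():
            lines.append(
                f"{int(r['id'])} {int(r['type'])} {r['x']} {r['y']} {r['z']} {r['radius']} {int(r['parent'])}"
            )
        path.write_text("\n".join(lines))
        tree = read_swc(path)
        assert tree_metrics(tree) == tree_metrics(y_branch)


class TestSomaMetrics:
    geom = PixelGeometry(0.1)

    def _disk(self, r_px=50, size=200):
        yy, xx = np.mgrid[0:size, 0:size]
        return (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= r_px**2

    def test_circle_area_and_diameter(self):
        m = soma_metrics(self._disk(), self.geom, apical_axis_deg=90.0)
        assert m["area_um2"] == pytest.approx(np.pi * 5.0**2, rel=0.02)
        assert m["diameter_um"] == pytest.approx(10.0, rel=0.03)

    def test_ellipse_diameter_perpendicular_to_apical(self):
        yy, xx = np.mgrid[0:200, 0:200]
        # major axis along x (10 um), minor along y (6 um)
        mask = ((xx - 100) / 50.0) ** 2 + ((yy - 100) / 30.0) ** 2 <= 1.0
        m = soma_metrics(mask, self.geom, apical_axis_deg=0.0)
        assert m["diameter_um"] == pytest.approx(6.0, rel=0.05)

    def test_rotating_mask_and_axis_together_preserves_diameter(self):
        yy, xx = np.mgrid[0:200, 0:200]
        mask0 = ((xx - 100) / 50.0) ** 2 + ((yy - 100) / 30.0) ** 2 <= 1.0
        m0 = soma_metrics(mask0, self.geom, apical_axis_deg=0.0)
        theta = 90.0
        mask90 = mask0.T  # rotate the ellipse by 90 degrees
        m90 = soma_metrics(mask90, self.geom, apical_axis_deg=theta)
        assert m90["diameter_um"] == pytest.approx(m0["diameter_um"], rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            soma_metrics(np.zeros((10, 10), bool), self.geom)


class TestTranscriptCoverage:
    def test_full_and_zero_coverage(self):
        mask = np.zeros((50, 50), bool)
        mask[10:40, 10:40] = True
        full = np.where(mask, 80.0, 0.0)
        assert soma_transcript_coverage(mask, full, "fixed", 10.0) == 100.0
        assert soma_transcript_coverage(mask, np.zeros((50, 50)), "fixed", 10.0) == 0.0

    def test_planted_puncta_match_pixel_count(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        ch = np.zeros((60, 60))
        ch[12:18, 12:18] = 90.0  # 36 px
        ch[30:35, 30:37] = 90.0  # 35 px
        pct = soma_transcript_coverage(mask, ch, "fixed", 45.0)
        assert pct == pytest.approx(100.0 * 71 / 1600)


class TestRelativeExpression:
    def _table(self, groups, ct_target, refs=(20.0, 19.0, 26.0), noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, (grp, ctt) in enumerate(zip(groups, ct_target)):
            for gene, ct in [
                ("target", ctt),
                ("GAPDH", refs[0]),
                ("ACTB", refs[1]),
                ("HPRT", refs[2]),
            ]:
                for _ in range(3):
                    rows.append(
                        {
                            "sample": f"s{i}",
                            "group": grp,
                            "gene": gene,
                            "ct": ct + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_calibrator_sample_has_unit_fold(self):
        tab = self._table(["control", "control"], [25.0, 25.0])
        out = relative_expression(tab, "target", ["GAPDH", "ACTB", "HPRT"], "control")
        assert np.allclose(out["fold"], 1.0)

    def test_one_cycle_lower_doubles_expression(self):
        tab = self._table(["control", "treat"], [25.0, 24.0])
        out = relative_expression(tab, "target", ["GAPDH", "ACTB", "HPRT"], "control")
        assert out.loc[out["group"] == "treat", "fold"].iloc[0] == pytest.approx(2.0)

    def test_invariant_to_constant_ct_shift(self):
        tab = self._table(["control", "treat"], [25.0, 23.5])
        out1 = relative_expression(tab, "target", ["GAPDH", "ACTB", "HPRT"], "control")
        tab2 = tab.copy()
        tab2["ct"] = tab2["ct"] + 3.0
        out2 = relative_expression(tab2, "target", ["GAPDH", "ACTB", "HPRT"], "control")
        assert np.allclose(out1["fold"], out2["fold"])

    def test_cohort_recovers_programmed_fold(self):
        # 18 vs 15 samples with Ct noise 0.2 around a true 2.84-fold effect
        rng = np.random.default_rng(9)
        d_ct = np.log2(2.84)
        groups = ["control"] * 18 + ["treat"] * 15
        cts = [25.0 + rng.normal(0, 0.2) for _ in range(18)] + [
            25.0 - d_ct + rng.normal(0, 0.2) for _ in range(15)
        ]
        tab = self._table(groups, cts, noise=0.05, seed=10)
        out = relative_expression(tab, "target", ["GAPDH", "ACTB", "HPRT"], "control")
        est = out.loc[out["group"] == "treat", "fold"].mean()
        assert est == pytest.approx(2.84, rel=0.12)

    def test_incomplete_reference_sample_excluded(self, caplog):
        tab = self._table(["control", "control", "treat"], [25.0, 25.0, 24.0])
        tab = tab[~((tab["sample"] == "s2") & (tab["gene"] == "HPRT"))]
        out = relative_expression(tab, "target", ["GAPDH", "ACTB", "HPRT"], "control")
        assert "s2" not in out["sample"].tolist()

    def test_implausible_ct_rejected(self):
        tab = self._table(["control", "control"], [25.0, 60.0])
        with pytest.raises(ValueError, match="range"):
            relative_expression(tab, "target", ["GAPDH", "ACTB", "HPRT"], "control")
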