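"""Compartment-tree model, SWC I/O and morphometric operations."""

import io

import numpy as np
import pytest

from retisim import synth
from retisim.morphology import (
    MorphologyError,
    SectionLabel,
    axon_initial_length,
    axon_path_length,
    count_bifurcations,
    count_terminals,
    measure,
    read_swc,
    reposition,
    segmentize,
    validate,
    write_swc,
)

from conftest import A, D, S, T, build_cell


class TestSwcIO:
    def test_minimal_three_point_file(self):
        cell = read_swc(io.StringIO(
            "1 1 0 0 0 3.5 -1\n2 2 0 0 -5 0.5 1\n3 2 0 0 -10 0.5 2\n"))
        assert cell.n == 3
        assert cell.root() == 0
        assert list(cell.labels) == [1, 2, 2]
        assert cell.diameter[0] == pytest.approx(7.0)

    @pytest.mark.parametrize("text,match", [
        ("1 1 0 0 0 3.5 2\n2 2 0 0 -5 0.5 1\n", "line 1"),   # forward parent
        ("1 9 0 0 0 3.5 -1\n", "unknown SWC type"),
        ("1 1 0 0 0 3.5 -1\n1 2 0 0 -5 0.5 1\n", "duplicate"),
        ("1 1 0 0 0 3.5 -1\n2 2 0 0 -5 0.5\n", "7 columns"),
        ("1 1 0 0 0 3.5 1\n", "own parent"),
    ])
    def test_malformed_input_raises_with_line(self, text, match):
        with pytest.raises(MorphologyError, match=match):
            read_swc(io.StringIO(text))

    def test_round_trip_is_identity(self, tmp_path, on_cell):
        p1 = tmp_path / "a.swc"
        p2 = tmp_path / "b.swc"
        write_swc(on_cell, p1)
        back = read_swc(p1, cell_class=on_cell.cell_class,
                        condition=on_cell.condition, cell_id=on_cell.cell_id)
        write_swc(back, p2)
        assert p1.read_text() == p2.read_text()
        assert np.array_equal(back.ids, on_cell.ids)
        assert np.array_equal(back.parent, on_cell.parent)
        assert np.array_equal(back.labels, on_cell.labels)
        np.testing.assert_allclose(back.xyz, on_cell.xyz, atol=1e-6)
        np.testing.assert_allclose(back.diameter, on_cell.diameter, atol=1e-6)


class TestCounts:
    def test_unbranched_chain_has_no_bifurcations(self, chain_cell):
        assert count_bifurcations(chain_cell) == 0
        assert count_terminals(chain_cell) == 1

    def test_y_axon(self, y_cell):
        assert count_bifurcations(y_cell) == 1
        assert count_terminals(y_cell) == 2

    def test_balanced_depth4_tree(self, balanced_axon_cell):
        # 2^4 leaves, 2^4 - 1 internal branch nodes
        assert count_terminals(balanced_axon_cell) == 16
        assert count_bifurcations(balanced_axon_cell) == 15

    def test_empty_label_subtree_warns_and_returns_zero(self, y_cell):
        only_dendrite = [SectionLabel.DENDRITE]
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, -5, 1.0, 0),
                           (T, 0, 0, -9, 1.0, 1)])
        with pytest.warns(UserWarning):
            assert count_bifurcations(cell, only_dendrite) == 0


class TestPathLengths:
    def test_straight_axon_both_definitions(self):
        rows = [(S, 0, 0, 0, 7.0, -1), (D, 0, 0, 3, 1.0, 0)]
        prev = 0  # axon chain hangs off the soma, not the dendrite
        for k in range(10):
            rows.append((A if k < 9 else T, 0, 0, -10.0 * (k + 1), 1.0, prev))
            prev = len(rows) - 1
        cell = build_cell(rows)
        assert axon_path_length(cell, "mean_root_to_tip") == pytest.approx(100.0)
        assert axon_path_length(cell, "total_cable") == pytest.approx(100.0)

    def test_y_mean_vs_total(self, y_cell):
        assert axon_path_length(y_cell, "mean_root_to_tip") == pytest.approx(15.0)
        assert axon_path_length(y_cell, "total_cable") == pytest.approx(20.0)

    def test_zero_length_chain(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, 0, 1.0, 0),
                           (T, 0, 0, 0, 1.0, 1)])
        assert axon_path_length(cell) == 0.0

    def test_no_axon_raises(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (D, 0, 0, 3, 1.0, 0)])
        with pytest.raises(MorphologyError):
            axon_path_length(cell)

    def test_unknown_definition_rejected(self, y_cell):
        with pytest.raises(ValueError):
            axon_path_length(y_cell, "geodesic")

    def test_initial_length_y_stalk(self, y_cell):
        assert axon_initial_length(y_cell) == pytest.approx(10.0)

    def test_initial_length_unbranched(self, chain_cell):
        assert axon_initial_length(chain_cell) == pytest.approx(30.0)

    def test_initial_length_three_segment_stalk(self):
        rows = [(S, 0, 0, 0, 7.0, -1)]
        for k in range(3):
            rows.append((A, 0, 0, -4.0 * (k + 1), 1.0, len(rows) - 1))
        rows.append((T, 2, 0, -15, 0.5, 3))
        rows.append((T, -2, 0, -15, 0.5, 3))
        cell = build_cell(rows)
        assert axon_initial_length(cell) == pytest.approx(12.0)


class TestSegmentize:
    def test_splits_into_equal_pieces(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, -10, 1.0, 0),
                           (T, 0, 0, -12, 0.5, 1)])
        fine = segmentize(cell, 2.0)
        ax = fine.labels == SectionLabel.AXON
        assert ax.sum() == 5
        np.testing.assert_allclose(fine.lengths()[ax], 2.0)

    def test_identity_when_already_fine(self, y_cell):
        out = segmentize(y_cell, 50.0)
        assert out.n == y_cell.n
        np.testing.assert_allclose(out.xyz, y_cell.xyz)

    def test_conserves_cable_and_membrane_area(self, on_cell):
        fine = segmentize(on_cell, 2.0)
        assert np.all(fine.lengths() <= 2.0 + 1e-9)
        assert fine.lengths().sum() == pytest.approx(on_cell.lengths().sum(), rel=1e-9)
        for lab in SectionLabel:
            a0 = on_cell.areas()[on_cell.labels == lab].sum()
            a1 = fine.areas()[fine.labels == lab].sum()
            assert a1 == pytest.approx(a0, rel=1e-9)

    def test_preserves_counts_and_paths(self, on_cell):
        fine = segmentize(on_cell, 2.0)
        m0, m1 = measure(on_cell), measure(fine)
        assert m1.n_terminals == m0.n_terminals
        assert m1.n_bifurcations == m0.n_bifurcations
        assert m1.path_length == pytest.approx(m0.path_length, rel=1e-9)

    def test_rejects_nonpositive_max(self, y_cell):
        with pytest.raises(ValueError):
            segmentize(y_cell, 0.0)


class TestReposition:
    def test_identity_when_at_target(self, y_cell):
        out = reposition(y_cell, 86.0)
        np.testing.assert_allclose(out.xyz, y_cell.xyz, atol=1e-12)

    def test_translates_to_target_and_remeasures(self, y_cell):
        out = reposition(y_cell, 60.0)
        term = (out.labels == SectionLabel.AXON_TERMINAL) & out.is_leaf()
        assert out.xyz[term, 2].min() == pytest.approx(60.0)
        # rigid: pairwise distances unchanged
        d0 = np.linalg.norm(y_cell.xyz[:, None] - y_cell.xyz[None, :], axis=-1)
        d1 = np.linalg.norm(out.xyz[:, None] - out.xyz[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_zero_target_rejected(self, y_cell):
        with pytest.raises(ValueError):
            reposition(y_cell, 0.0)

    def test_crossing_electrode_plane_rejected(self):
        # terminal only 2 μm above the lowest compartment: moving terminals
        # to 1 μm would push that compartment through the plane
        cell = build_cell([(S, 0, 0, 50, 7.0, -1), (A, 0, 0, 10, 1.0, 0),
                           (T, 0, 0, 12, 1.0, 1)])
        with pytest.raises(ValueError, match="electrode side"):
            reposition(cell, 1.0)


class TestValidation:
    def test_topological_order_enforced(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, -5, 1.0, 2),
                           (A, 0, 0, -10, 1.0, 0)])
        with pytest.raises(MorphologyError, match="topological"):
            validate(cell)

    def test_nonpositive_diameter_rejected(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, -5, 0.0, 0)])
        with pytest.raises(MorphologyError, match="diameter"):
            validate(cell)

    def test_two_roots_rejected(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, -5, 1.0, -1)])
        with pytest.raises(MorphologyError):
            validate(cell)

    def test_terminal_with_axon_child_rejected(self):
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (T, 0, 0, -5, 1.0, 0),
                           (A, 0, 0, -10, 1.0, 1)])
        with pytest.raises(MorphologyError, match="terminal"):
            validate(cell)

    def test_missing_sections_flagged_in_strict_mode(self, chain_cell):
        validate(chain_cell, require_all_sections=True)
        cell = build_cell([(S, 0, 0, 0, 7.0, -1), (A, 0, 0, -5, 1.0, 0)])
        validate(cell)  # lenient passes
        with pytest.raises(MorphologyError, match="missing"):
            validate(cell, require_all_sections=True)
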