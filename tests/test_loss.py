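"""Tests for the Betti-prior barcode loss and its pixel gradient."""

import numpy as np
import pytest

from topofit.cubical import Bar, Barcode, compute_barcode
from topofit.loss import TopologicalPrior, descend_on_field, topo_loss, topo_loss_on_field
from topofit.cubical import betti_at_threshold

from conftest import random_distinct_field


def binary_ring(shape=(16, 16)):
    from topofit.synthetic import make_phantom

    return make_phantom("ring", shape, seed=0).target


class TestTopoLoss:
    def test_zero_on_matching_binary_ring(self):
        rep = topo_loss_on_field(binary_ring(), TopologicalPrior.from_betti((1, 1)))
        assert rep.total == 0.0
        # the minimum sits on the boundary of [0,1]: the wanted bars' birth
        # cells are still pushed towards 1 and death cells towards 0, so
        # clamped descent leaves a perfect binary field unchanged
        f = binary_ring()
        import numpy as _np
        stepped = _np.clip(f - 0.1 * rep.gradient_array(f.shape), 0.0, 1.0)
        assert _np.array_equal(stepped, f)

    def test_unwanted_loop_costs_its_squared_length(self):
        rep = topo_loss_on_field(binary_ring(), TopologicalPrior.from_betti((1, 0)))
        assert rep.total == 1.0  # the loop bar (1, 0) is unwanted: |1-0|^2
        bc = compute_barcode(binary_ring(), max_dim=1)
        loop = bc.of_dim(1)[0]
        assert rep.gradient[loop.birth_cell] == pytest.approx(2.0)
        assert rep.gradient[loop.death_cell] == pytest.approx(-2.0)

    def test_missing_wanted_bars_each_cost_one(self):
        rep = topo_loss_on_field(np.zeros((6, 6)), TopologicalPrior.from_betti((1, 0)))
        assert rep.total == 1.0
        rep = topo_loss_on_field(np.zeros((6, 6)), TopologicalPrior.from_betti((2, 3)))
        assert rep.total == 5.0
        assert rep.gradient == {}

    def test_single_pixel_closed_form(self):
        rep = topo_loss_on_field(np.array([[0.7]]), TopologicalPrior.from_betti((1,)))
        assert rep.total == pytest.approx(1 - 0.7**2)
        assert rep.gradient == {0: pytest.approx(-1.4)}

    def test_per_dim_weights_scale_loss_and_gradient(self):
        # restrict the prior to dim 1 so every term carries the dim-1 weight
        prior1 = TopologicalPrior(desired={1: 0})
        prior2 = TopologicalPrior(desired={1: 0}, weights={1: 2.5})
        f = binary_ring()
        r1, r2 = topo_loss_on_field(f, prior1), topo_loss_on_field(f, prior2)
        assert r1.total == 1.0  # the unwanted loop bar
        assert r2.total == pytest.approx(2.5 * r1.total)
        for cell, g in r1.gradient.items():
            assert r2.gradient[cell] == pytest.approx(2.5 * g)

    def test_ignore_window_excludes_ranks_from_both_sums(self):
        bars = [
            Bar(0, 1.0, 0.0, 0, -1, essential=True),
            Bar(0, 0.8, 0.2, 1, 2),
            Bar(0, 0.6, 0.3, 3, 4),
        ]
        bc = Barcode(bars, shape=(3, 3))
        plain = topo_loss(bc, TopologicalPrior(desired={0: 1}))
        windowed = topo_loss(
            bc, TopologicalPrior(desired={0: 1}, ignore_window={0: (2, 2)})
        )
        # rank 2 (length 0.6) no longer pays its unwanted penalty
        assert plain.total - windowed.total == pytest.approx(0.6**2)
        assert 1 not in windowed.gradient and 2 not in windowed.gradient

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            TopologicalPrior(desired={0: -1})
        with pytest.raises(ValueError):
            TopologicalPrior(desired={5: 1})
        with pytest.raises(ValueError):
            TopologicalPrior(desired={0: 1}, weights={0: -0.5})
        with pytest.raises(ValueError):
            TopologicalPrior(desired={0: 2}, ignore_window={0: (1, 3)})

    def test_loss_nonnegative_on_random_fields(self):
        rng = np.random.default_rng(2)
        prior = TopologicalPrior.from_betti((1, 1))
        for _ in range(20):
            rep = topo_loss_on_field(random_distinct_field(rng, (6, 6)), prior)
            assert rep.total >= 0.0


class TestGradient:
    def test_finite_difference_agreement(self):
        rng = np.random.default_rng(4)
        prior = TopologicalPrior.from_betti((1, 1))
        eps = 1e-6
        for _ in range(15):
            x = random_distinct_field(rng, (8, 8))
            rep = topo_loss_on_field(x, prior)
            g = rep.gradient_array(x.shape)
            for idx in rep.gradient:
                i, j = np.unravel_index(idx, x.shape)
                xp, xm = x.copy(), x.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                fd = (
                    topo_loss_on_field(xp, prior).total
                    - topo_loss_on_field(xm, prior).total
                ) / (2 * eps)
                assert abs(fd - g[i, j]) <= 1e-4

    def test_gap_pixel_is_pushed_up(self, ring_with_gap):
        # the loop is born when the gap pixel (value 0.4) enters, so the
        # wanted dim-1 bar's birth gradient is negative there: descent raises it
        rep = topo_loss_on_field(ring_with_gap, TopologicalPrior.from_betti((1, 1)))
        gap_idx = int(np.ravel_multi_index((2, 4), ring_with_gap.shape))
        assert rep.gradient[gap_idx] < 0

    def test_monotone_relabelling_changes_loss_via_bar_lengths(self):
        rng = np.random.default_rng(9)
        prior = TopologicalPrior.from_betti((1, 1))
        x = random_distinct_field(rng, (6, 6))
        g = lambda v: v**2  # noqa: E731
        # recompute the expected loss directly from the relabelled bar lengths
        expected = 0.0
        bc = compute_barcode(g(x))
        for k in (0, 1):
            bars = bc.of_dim(k)
            want = prior.desired[k]
            for ell, bar in enumerate(bars, start=1):
                expected += (1 - bar.length**2) if ell <= want else bar.length**2
            expected += max(0, want - len(bars))
        assert topo_loss_on_field(g(x), prior).total == pytest.approx(expected)


def test_descent_repairs_gap(ring_with_gap):
    prior = TopologicalPrior.from_betti((1, 1))
    assert betti_at_threshold(ring_with_gap, 0.5, 1) == 0
    out = descend_on_field(ring_with_gap, prior, steps=200, lr=0.05)
    assert betti_at_threshold(out, 0.5, 0) == 1
    assert betti_at_threshold(out, 0.5, 1) == 1


def test_loss_report_json_roundtrip(tmp_path, ring5):
    rep = topo_loss_on_field(ring5, TopologicalPrior.from_betti((1, 0)))
    obj = rep.to_json(tmp_path / "rep.json")
    assert obj["total"] == rep.total
    assert (tmp_path / "rep.json").exists()
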