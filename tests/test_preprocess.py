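import numpy as np
import pandas as pd
import pytest

from qsarforge import DescriptorTable, filter_collinear, filter_constant
from qsarforge.exceptions import EmptyTableError, TableError
from qsarforge.synth import SynthConfig, generate


def _table(cols: dict, y=None):
    frame = pd.DataFrame(cols)
    frame.index = [f"C{i}" for i in range(len(frame))]
    act = pd.Series(y, index=frame.index) if y is not None else None
    return DescriptorTable(frame, act)


class TestConstantFilter:
    def test_zero_variance_column_removed(self):
        t = _table({"z": np.zeros(10), "x": np.arange(10.0)})
        reduced, log = filter_constant(t)
        assert reduced.descriptor_names == ["x"]
        assert log.removed_constant == ["z"]

    def test_counts_match_direct_frequency_scan(self):
        cfg = SynthConfig(n_compounds=50, n_descriptors=40, n_constant=4,
                          n_near_constant=3, n_collinear_pairs=0, seed=8)
        ds = generate(cfg)
        reduced, log = filter_constant(ds.table, 0.95)
        # independent scan: mode frequency per column
        removed = 0
        for j in range(ds.table.n_descriptors):
            col = ds.table.X[:, j]
            _, counts = np.unique(col, return_counts=True)
            removed += counts.max() / len(col) >= 0.95
        assert len(log.removed) == removed == cfg.n_constant + cfg.n_near_constant

    def test_fraction_one_keeps_near_constant(self):
        col = np.zeros(20)
        col[0] = 1.0  # 95% mode, but not exactly constant
        t = _table({"nc": col, "c": np.ones(20), "x": np.arange(20.0)})
        reduced, log = filter_constant(t, near_constant_fraction=1.0)
        assert log.removed_constant == ["c"]
        assert reduced.descriptor_names == ["nc", "x"]

    def test_idempotent_and_order_preserving(self, default_dataset):
        once, _ = filter_constant(default_dataset.table)
        twice, log2 = filter_constant(once)
        assert not log2.removed
        assert twice.descriptor_names == once.descriptor_names
        raw = default_dataset.table.descriptor_names
        surviving = [n for n in raw if n in set(once.descriptor_names)]
        assert once.descriptor_names == surviving

    def test_all_removed_raises(self):
        t = _table({"a": np.ones(5), "b": np.full(5, 2.0)})
        with pytest.raises(EmptyTableError):
            filter_constant(t)


class TestCollinearFilter:
    def test_worse_correlated_member_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.8 * x + rng.normal(0, 0.5, size=40)
        b = x + rng.normal(0, 0.2, size=40)  # collinear with x, noisier vs y
        assert abs(np.corrcoef(x, b)[0, 1]) > 0.9
        assert abs(np.corrcoef(x, y)[0, 1]) > abs(np.corrcoef(b, y)[0, 1])
        t = _table({"A": x, "B": b, "N": rng.normal(size=40)}, y)
        reduced, log = filter_collinear(t, 0.9)
        assert reduced.descriptor_names == ["A", "N"]
        (kept, dropped, *_), = log.collinear_pairs
        assert (kept, dropped) == ("A", "B")

    def test_exact_tie_keeps_lexicographically_smaller_name(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.5, size=30)
        t = _table({"B": x, "A": x.copy()}, y)  # identical: r to y ties exactly
        reduced, log = filter_collinear(t, 0.9)
        assert reduced.descriptor_names == ["A"]
        assert log.collinear_pairs[0][:2] == ("A", "B")

    def test_planted_pairs_resolved_against_oracle(self):
        cfg = SynthConfig(n_compounds=50, n_descriptors=40, n_constant=0,
                          n_near_constant=0, n_collinear_pairs=3, seed=13)
        ds = generate(cfg)
        reduced, log = filter_collinear(ds.table, 0.9)
        assert len(log.collinear_pairs) == 3
        y = ds.table.y
        for kept, dropped, r, r_y_kept, r_y_dropped in log.collinear_pairs:
            # oracle: recompute both correlations directly
            rk = np.corrcoef(ds.table.data[kept], y)[0, 1]
            rd = np.corrcoef(ds.table.data[dropped], y)[0, 1]
            assert abs(rk) >= abs(rd)
            assert rk == pytest.approx(r_y_kept)
            assert rd == pytest.approx(r_y_dropped)

    def test_independent_noise_untouched_at_high_cut(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 20))
        y = rng.normal(size=200)
        t = DescriptorTable(
            pd.DataFrame(X, index=[f"C{i}" for i in range(200)],
                         columns=[f"D{j}" for j in range(20)]),
            pd.Series(y, index=[f"C{i}" for i in range(200)]))
        C = np.corrcoef(X, rowvar=False)
        assert np.abs(C[np.triu_indices(20, 1)]).max() < 0.999  # oracle scan
        reduced, log = filter_collinear(t, 0.999)
        assert not log.collinear_pairs
        assert reduced.descriptor_names == t.descriptor_names

    def test_surviving_pairs_below_cut(self, default_dataset):
        constantless, _ = filter_constant(default_dataset.table)
        reduced, _ = filter_collinear(constantless, 0.9)
        C = np.corrcoef(reduced.X, rowvar=False)
        assert np.abs(C[np.triu_indices(reduced.n_descriptors, 1)]).max() <= 0.9

    def test_idempotence(self, default_dataset):
        constantless, _ = filter_constant(default_dataset.table)
        once, _ = filter_collinear(constantless, 0.9)
        twice, log2 = filter_collinear(once, 0.9)
        assert not log2.collinear_pairs
        assert twice.descriptor_names == once.descriptor_names

    def test_requires_activity(self):
        t = _table({"a": np.arange(5.0), "b": np.arange(5.0)})
        with pytest.raises(TableError):
            filter_collinear(t)
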