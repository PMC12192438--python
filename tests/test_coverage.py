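"""Q2Q3 statistic, coverage tables, normalization and detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gvshuttle.coverage import (
    CoverageTable,
    NormMode,
    coverage_table,
    detect,
    fraction_reads_mapped,
    normalize,
    q2q3,
)
from gvshuttle.errors import ConfigError, InputError


def q2q3_oracle(depths):
    """Brute-force reference: sort, drop lowest/highest floor(L/4), average."""
    s = sorted(float(x) for x in depths)
    L = len(s)
    if L < 4:
        return sum(s) / L
    k = L // 4
    kept = s[k : L - k]
    return sum(kept) / len(kept)


class TestQ2Q3:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([7] * 8, 7.0),
            ([100, 50, 10, 3, 2, 1, 0, 0], 4.0),  # sorted: trim 2 each side
            ([0] * 8 + [9, 9], 0.0),  # breadth 2/10 <= floor(L/4): trimmed to zeros
            ([1, 2, 3], 2.0),  # L < 4: plain mean
            ([5], 5.0),
        ],
    )
    def test_examples(self, vec, expected):
        assert q2q3(vec) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            q2q3([])

    def test_negative_depth_rejected(self):
        with pytest.raises(InputError):
            q2q3([1, -1, 2, 3])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=400))
    def test_matches_brute_force_oracle(self, vec):
        assert q2q3(vec) == pytest.approx(q2q3_oracle(vec))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=100),
        st.floats(0, 50, allow_nan=False),
    )
    def test_scale_equivariance_and_bounds(self, vec, c):
        v = np.asarray(vec)
        stat = q2q3(v)
        assert q2q3(c * v) == pytest.approx(c * stat, abs=1e-9)
        assert v.min() - 1e-12 <= stat <= v.max() + 1e-12

    def test_detection_breadth_law(self):
        """Depth-1 coverage on L=100 is detected from 26 covered positions on."""
        for n_cov, detected in [(25, False), (26, True)]:
            vec = [1] * n_cov + [0] * (100 - n_cov)
            assert (q2q3(vec) > 0) is detected


class TestCoverageTable:
    @pytest.fixture
    def catalog(self):
        return pd.DataFrame({"contig_id": ["c1", "c2"], "length_bp": [8, 10]})

    def _write(self, tmp_path, name, rows):
        p = tmp_path / name
        p.write_text("".join(f"{c}\t{pos}\t{d}\n" for c, pos, d in rows))
        return p

    def test_uniform_and_absent_contigs(self, tmp_path, catalog):
        f = self._write(tmp_path, "s1.tsv", [("c1", i, 3) for i in range(1, 9)])
        tab = coverage_table({"s1": f}, catalog)
        assert tab.values.loc["c1", "s1"] == pytest.approx(3.0)
        assert tab.values.loc["c2", "s1"] == 0.0

    def test_empty_depth_file_gives_zero_column(self, tmp_path, catalog):
        f = tmp_path / "s1.tsv"
        f.write_text("")
        tab = coverage_table({"s1": f}, catalog)
        assert (tab.values["s1"] == 0).all()

    def test_position_past_contig_end_names_sample(self, tmp_path, catalog):
        f = self._write(tmp_path, "bad.tsv", [("c1", 9, 3)])
        with pytest.raises(InputError, match="s1"):
            coverage_table({"s1": f}, catalog)

    def test_unknown_contig_rejected(self, tmp_path, catalog):
        f = self._write(tmp_path, "bad.tsv", [("ghost", 1, 3)])
        with pytest.raises(InputError, match="ghost"):
            coverage_table({"s1": f}, catalog)


class TestNormalize:
    def _table(self, col):
        return CoverageTable(pd.DataFrame({"s1": col}, index=[f"c{i}" for i in range(len(col))]))

    def test_sum_to_one(self):
        out = normalize(self._table([2, 3, 5]), "sum_to_one")
        assert list(out.values["s1"]) == pytest.approx([0.2, 0.3, 0.5])
        assert out.mode is NormMode.SUM_TO_ONE

    def test_max_of_sample(self):
        out = normalize(self._table([2, 4, 8]), "max_of_sample")
        assert list(out.values["s1"]) == pytest.approx([0.25, 0.5, 1.0])

    def test_all_zero_column_passes_through(self):
        for mode in ("sum_to_one", "max_of_sample"):
            out = normalize(self._table([0, 0, 0]), mode)
            assert (out.values["s1"] == 0).all()
            assert not out.values.isna().any().any()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            normalize(self._table([1, 2]), "zscore")

    def test_normalizing_twice_rejected(self):
        once = normalize(self._table([1, 2]), "sum_to_one")
        with pytest.raises(ConfigError):
            normalize(once, "sum_to_one")

    def test_contracts_on_random_matrix(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(1.0, 5.0, size=(30, 8))
        vals[:, 3] = 0.0  # an all-zero sample column
        raw = CoverageTable(pd.DataFrame(vals))
        s1 = normalize(raw, "sum_to_one").values.to_numpy()
        mx = normalize(raw, "max_of_sample").values.to_numpy()
        nonzero = vals.sum(axis=0) > 0
        assert np.allclose(s1[:, nonzero].sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(mx[:, nonzero].max(axis=0), 1.0)
        assert (s1[:, ~nonzero] == 0).all() and (mx[:, ~nonzero] == 0).all()

    def test_normalization_preserves_zero_pattern(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(0.5, 5.0, size=(20, 6))
        vals[vals < 2] = 0.0
        raw = CoverageTable(pd.DataFrame(vals))
        det_raw = detect(raw)
        rel = normalize(raw, "sum_to_one")
        assert ((rel.values > 0) == det_raw).all().all()


class TestReadsMapped:
    def test_examples(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "total_reads": [1_000_000, 100, 50],
                "mapped_reads": [5_000, 0, 50],
            }
        )
        pct = fraction_reads_mapped(meta)
        assert pct["a"] == pytest.approx(0.5)
        assert pct["b"] == 0.0
        assert pct["c"] == 100.0

    def test_mapped_exceeding_total_rejected(self):
        meta = pd.DataFrame(
            {"sample_id": ["a"], "total_reads": [10], "mapped_reads": [11]}
        )
        with pytest.raises(InputError, match="a"):
            fraction_reads_mapped(meta)
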