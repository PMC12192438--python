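"""Gene significance, co-abundance modules and flux-correlated selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gvshuttle.errors import InputError
from gvshuttle.fluxnet import (
    build_modules,
    gene_significance,
    module_trait_correlation,
    select_flux_correlated,
)


def flux_frame(values):
    return pd.DataFrame({
        "sample_id": [f"t{i}" for i in range(len(values))],
        "flux": values,
    })


def trap_frame(rows, n):
    return pd.DataFrame(rows, columns=[f"t{i}" for i in range(n)])


class TestGeneSignificance:
    def test_profile_identical_to_flux_has_r_one(self):
        y = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        gs = gene_significance(trap_frame([y], 6), flux_frame(y))
        assert gs["r"].iloc[0] == pytest.approx(1.0)
        assert gs["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_profile_flagged_and_nan(self):
        gs = gene_significance(
            trap_frame([[2.0] * 6, [1, 2, 3, 4, 5, 6]], 6),
            flux_frame([1.0, 3.0, 2.0, 5.0, 4.0, 6.0]))
        assert gs["flagged_constant"].iloc[0]
        assert np.isnan(gs["r"].iloc[0])
        assert not gs["flagged_constant"].iloc[1]

    def test_fewer_than_four_samples_rejected(self):
        with pytest.raises(InputError):
            gene_significance(trap_frame([[1, 2, 3]], 3), flux_frame([1, 2, 3]))

    def test_p_matches_t_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(size=10)
        gs = gene_significance(trap_frame([list(y)], 10), flux_frame(list(x)))
        r = gs["r"].iloc[0]
        t = r * np.sqrt(8) / np.sqrt(1 - r * r)
        assert gs["p"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), df=8), abs=1e-12)

    def test_p_agrees_with_scipy_pearsonr(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2.0, 1.0, size=(5, 20))
        y = rng.normal(size=20)
        gs = gene_significance(trap_frame(list(X), 20), flux_frame(list(y)))
        for i in range(5):
            r_ref, p_ref = stats.pearsonr(X[i], y)
            assert gs["r"].iloc[i] == pytest.approx(r_ref)
            assert gs["p"].iloc[i] == pytest.approx(p_ref, abs=1e-12)

    def test_p_agrees_with_permutation_null(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        gs = gene_significance(trap_frame([list(y)], 12), flux_frame(list(x)))
        r_obs = abs(gs["r"].iloc[0])
        count = 0
        n_perm = 1000
        prng = np.random.default_rng(3)
        yc = y - y.mean()
        for _ in range(n_perm):
            xp = prng.permutation(x)
            xp = xp - xp.mean()
            r = (xp @ yc) / np.sqrt((xp @ xp) * (yc @ yc))
            if abs(r) >= r_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert gs["p"].iloc[0] == pytest.approx(p_perm, abs=0.02)


class TestModules:
    def _block_table(self, rng, n_samples=30):
        base1 = rng.normal(size=n_samples)
        base2 = rng.normal(size=n_samples)
        rows, ids = [], []
        for i in range(6):
            rows.append(base1 * (i + 1) + 5)
            ids.append(f"a{i}")
        for i in range(6):
            rows.append(base2 * (i + 1) + 5)
            ids.append(f"b{i}")
        return pd.DataFrame(rows, index=ids,
                            columns=[f"t{i}" for i in range(n_samples)])

    def test_two_perfect_blocks_give_two_modules(self):
        table = self._block_table(np.random.default_rng(5))
        mods = build_modules(table, min_module_size=3)
        labels = mods.labels
        a = set(labels[[f"a{i}" for i in range(6)]])
        b = set(labels[[f"b{i}" for i in range(6)]])
        assert len(a) == 1 and len(b) == 1 and a != b
        assert "grey" not in a | b

    def test_small_clusters_left_unassigned(self):
        table = self._block_table(np.random.default_rng(5))
        mods = build_modules(table, min_module_size=10)
        assert (mods.labels == "grey").all()

    def test_labels_invariant_to_input_order(self):
        table = self._block_table(np.random.default_rng(6))
        shuffled = table.sample(frac=1.0, random_state=1)
        m1 = build_modules(table, min_module_size=3)
        m2 = build_modules(shuffled, min_module_size=3)
        pd.testing.assert_series_equal(m1.labels.sort_index(), m2.labels.sort_index())

    def test_eigengene_is_best_single_direction(self):
        # PCA optimality: the eigengene explains at least as much member
        # variance as any random unit vector over samples
        table = self._block_table(np.random.default_rng(7))
        mods = build_modules(table, min_module_size=3)
        mod = mods.eigengenes.columns[0]
        members = mods.members(mod)
        M = table.loc[members].to_numpy()
        Ms = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
        e = mods.eigengenes[mod].to_numpy()
        var_e = ((Ms @ e / np.linalg.norm(e)) ** 2).sum()
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.normal(size=Ms.shape[1])
            v /= np.linalg.norm(v)
            assert var_e >= ((Ms @ v) ** 2).sum() - 1e-9

    def test_all_constant_matrix_rejected(self):
        table = pd.DataFrame(np.ones((3, 10)),
                             columns=[f"t{i}" for i in range(10)])
        with pytest.raises(InputError):
            build_modules(table)

    def test_module_trait_correlation_flags_coupled_module(self):
        rng = np.random.default_rng(9)
        table = self._block_table(rng)
        flux = flux_frame(list(table.loc["a0"] + rng.normal(0, 0.1, size=30)))
        mods = build_modules(table, min_module_size=3)
        mt = module_trait_correlation(mods, flux)
        a_mod = mods.labels["a0"]
        row = mt.set_index("module").loc[a_mod]
        assert abs(row["r"]) > 0.9 and row["p"] < 1e-6


class TestSelection:
    def _gs(self, rows):
        return pd.DataFrame(rows, columns=["contig_id", "r", "p", "n",
                                           "flagged_constant"])

    def test_positive_significant_selected(self):
        gs = self._gs([("c1", 0.9, 0.01, 10, False)])
        assert select_flux_correlated(gs) == ["c1"]

    def test_negative_correlation_excluded(self):
        gs = self._gs([("c1", -0.9, 0.001, 10, False)])
        assert select_flux_correlated(gs) == []

    def test_constant_rows_excluded(self):
        gs = self._gs([("c1", 0.9, 0.001, 10, True)])
        assert select_flux_correlated(gs) == []

    def test_tighter_alpha_gives_subset(self):
        rng = np.random.default_rng(10)
        gs = self._gs([
            (f"c{i}", float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.2)), 20, False)
            for i in range(50)
        ])
        loose = set(select_flux_correlated(gs, alpha=0.1))
        tight = set(select_flux_correlated(gs, alpha=0.01))
        assert tight <= loose

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(12)
        gs = self._gs([
            (f"c{i}", 0.5, float(rng.uniform(0.001, 0.2)), 20, False)
            for i in range(40)
        ])
        raw = set(select_flux_correlated(gs))
        bh = set(select_flux_correlated(gs, bh_correction=True))
        assert bh <= raw

    def test_module_gate_restricts_selection(self):
        # module A tracks flux; module B does not. b0 sits in B but carries
        # enough flux admixture to be GS-significant on its own — the gate
        # must drop it while keeping A's members.
        rng = np.random.default_rng(13)
        n = 40
        base_a = rng.normal(size=n)
        base_b = rng.normal(size=n)
        flux_vals = base_a + rng.normal(0, 0.15, size=n)
        rows, ids = [], []
        for i in range(6):
            rows.append(base_a * (1 + 0.1 * i) + 5 + rng.normal(0, 0.05, n))
            ids.append(f"a{i}")
        rows.append(base_b + 0.55 * base_a + 5)
        ids.append("b0")
        for i in range(1, 6):
            rows.append(base_b * (1 + 0.1 * i) + 5 + rng.normal(0, 0.05, n))
            ids.append(f"b{i}")
        table = pd.DataFrame(rows, index=ids, columns=[f"t{i}" for i in range(n)])
        flux = flux_frame(list(flux_vals))
        gs = gene_significance(table, flux)
        mods = build_modules(table, min_module_size=3)
        mt = module_trait_correlation(mods, flux)
        ungated = set(select_flux_correlated(gs, mods))
        gated = set(select_flux_correlated(gs, mods, require_module_gate=True))
        assert "b0" in ungated
        assert gated <= ungated
        assert "b0" not in gated
        good_modules = set(mt.loc[(mt["r"] > 0) & (mt["p"] < 0.05), "module"])
        assert all(mods.labels[c] in good_modules for c in gated)
        assert {f"a{i}" for i in range(6)} <= gated

    def test_planted_flux_coupled_contigs_recovered(self, small_bundle):
        from gvshuttle.coverage import NormMode, normalize
        rel = normalize(small_bundle.coverage, NormMode.SUM_TO_ONE)
        trap = list(small_bundle.metadata.loc[
            small_bundle.metadata.habitat == "sediment_trap", "sample_id"])
        gs = gene_significance(rel.values[trap], small_bundle.flux)
        chosen = set(select_flux_correlated(gs))
        planted = small_bundle.flux_coupled_ids
        assert len(chosen & planted) / len(planted) >= 0.9
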