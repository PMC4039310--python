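import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoint import rnai_screen as rs
from oncoint import synthetic_data as sd
from oncoint.errors import InputError


def _screen(rows):
    return rs.ViabilityScreen(
        data=pd.DataFrame(
            rows, columns=["cell_line", "gene", "replicate", "readout", "is_control"]
        )
    )


class TestNormalize:
    def test_division_by_control_mean(self):
        s = _screen(
            [
                ("L1", "NTC", 1, 2000.0, True),
                ("L1", "NTC", 2, 2000.0, True),
                ("L1", "g", 1, 2000.0, False),
                ("L1", "g", 2, 2200.0, False),
            ]
        )
        out = rs.normalize(s)
        assert list(out.replicates("L1", "g")) == pytest.approx([1.0, 1.1])
        assert np.mean(out.control_replicates("L1")) == pytest.approx(1.0)

    def test_idempotent(self):
        s = _screen(
            [
                ("L1", "NTC", 1, 1900.0, True),
                ("L1", "NTC", 2, 2100.0, True),
                ("L1", "g", 1, 777.0, False),
                ("L1", "g", 2, 888.0, False),
            ]
        )
        once = rs.normalize(s)
        twice = rs.normalize(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_zero_control_mean_names_line(self):
        s = _screen([("L7", "NTC", 1, 0.0, True), ("L7", "g", 1, 5.0, False)])
        with pytest.raises(InputError, match="L7"):
            rs.normalize(s)

    def test_missing_controls_rejected(self):
        with pytest.raises(InputError, match="without control"):
            _screen([("L1", "g", 1, 5.0, False)])


class TestCallHits:
    def test_worked_hit(self, small_screen):
        calls = {(c.cell_line, c.gene): c for c in rs.call_hits(small_screen)}
        hit = calls[("L1", "g_hit")]
        # gene {0.40, 0.45, 0.42} (after /1.0 control) vs control {1.00, 1.02, 0.98}
        g = np.array([0.38, 0.40, 0.42])
        ctrl = np.array([0.98, 1.00, 1.02])
        # independent pooled-variance t statistic
        sp = math.sqrt(((g.var(ddof=1) + ctrl.var(ddof=1)) / 2) * (2 / 3))
        t_manual = (g.mean() - ctrl.mean()) / sp
        from scipy.stats import t as tdist

        p_manual = 2 * tdist.sf(abs(t_manual), df=4)
        assert hit.p_value == pytest.approx(p_manual, rel=1e-9)
        assert hit.inhibition > 0.5 and hit.p_value < 0.05 and hit.is_hit

    def test_threshold_rule_blocks_weak_inhibition(self):
        s = _screen(
            [("L1", "NTC", r, 1000.0, True) for r in (1, 2, 3)]
            + [("L1", "g", r, v, False) for r, v in ((1, 600.0), (2, 550.0), (3, 580.0))]
        )
        (c,) = rs.call_hits(s)
        assert c.inhibition < 0.5 and not c.is_hit
        assert c.p_value < 0.05  # significant but under-threshold

    def test_identical_to_control_not_hit(self):
        s = _screen(
            [("L1", "NTC", r, 1000.0, True) for r in (1, 2, 3)]
            + [("L1", "g", r, 1000.0, False) for r in (1, 2, 3)]
        )
        (c,) = rs.call_hits(s)
        assert not c.is_hit and c.p_value == pytest.approx(1.0)

    def test_single_replicate_skipped_with_warning(self):
        s = _screen(
            [("L1", "NTC", 1, 1000.0, True), ("L1", "NTC", 2, 1000.0, True),
             ("L1", "g", 1, 100.0, False)]
        )
        with pytest.warns(UserWarning, match="<2 replicates"):
            assert rs.call_hits(s) == []

    def test_monotonicity_lowering_viability_keeps_hit(self, small_screen):
        calls = {(c.cell_line, c.gene): c for c in rs.call_hits(small_screen)}
        assert calls[("L1", "g_hit")].is_hit
        lowered = small_screen.data.copy()
        mask = (lowered["gene"] == "g_hit") & (lowered["cell_line"] == "L1")
        lowered.loc[mask, "readout"] *= 0.5
        calls2 = {
            (c.cell_line, c.gene): c
            for c in rs.call_hits(rs.ViabilityScreen(data=lowered))
        }
        assert calls2[("L1", "g_hit")].is_hit


class TestCoreNetwork:
    def test_intersection(self):
        core = rs.core_network([{"g1", "g2", "g3"}, {"g2", "g3", "g4"}, {"g2", "g3"}])
        assert core == ["g2", "g3"]

    def test_empty_set_empties_core(self):
        assert rs.core_network([{"g1"}, set()]) == []

    def test_needs_two_lines(self):
        with pytest.raises(InputError):
            rs.core_network([{"g1"}])

    def test_core_subset_of_every_hit_set(self):
        sets = [{"a", "b", "c"}, {"b", "c", "d"}, {"b", "c"}]
        core = set(rs.core_network(sets))
        for s in sets:
            assert core <= s

    def test_simulated_recovery(self):
        cfg = sd.SimulationConfig(seed=21, screen_n_lines=3, screen_n_mutant=3)
        screen, truth = sd.simulate_screen(cfg)
        hits = rs.hits_by_line(rs.call_hits(screen))
        core = rs.core_network(list(hits.values()))
        assert set(core) == truth.true_core_genes


class TestPairOverlap:
    def test_partition(self):
        shared, p_only, r_only = rs.pair_overlap({"a", "b", "c"}, {"b", "c", "d"})
        assert (shared, p_only, r_only) == ({"b", "c"}, {"a"}, {"d"})

    def test_identical(self):
        shared, p_only, r_only = rs.pair_overlap({"x"}, {"x"})
        assert shared == {"x"} and not p_only and not r_only

    def test_disjoint(self):
        shared, _, _ = rs.pair_overlap({"a"}, {"b"})
        assert shared == set()


class TestResistantGain:
    def _paired_screen(self, parent_vals, resistant_vals):
        rows = []
        for line, vals in (("P", parent_vals), ("R", resistant_vals)):
            rows += [(line, "NTC", r, 1000.0, True) for r in (1, 2, 3)]
            rows += [(line, "g", r, 1000.0 * v, False) for r, v in enumerate(vals, 1)]
        return _screen(rows)

    def test_reported(self):
        s = self._paired_screen((0.9, 0.92, 0.88), (0.4, 0.42, 0.41))
        assert rs.resistant_gain(s, "P", "R", min_delta=0.2) == ["g"]

    def test_identical_not_reported(self):
        s = self._paired_screen((0.5, 0.52, 0.48), (0.5, 0.52, 0.48))
        assert rs.resistant_gain(s, "P", "R") == []

    def test_direction_rule(self):
        s = self._paired_screen((0.4, 0.42, 0.41), (0.9, 0.92, 0.88))
        assert rs.resistant_gain(s, "P", "R") == []


class TestRankSum:
    def test_worked_exact_case(self):
        # mutant {0.2, 0.3} vs wild-type {0.8, 0.9, 1.0}: p = 2/C(5,2)
        assert rs.rank_sum_test([0.2, 0.3], [0.8, 0.9, 1.0]) == pytest.approx(0.2)

    def test_identical_groups_p_one(self):
        assert rs.rank_sum_test([1.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_exact_matches_enumeration_small(self):
        """Brute-force oracle over every split with n1+n2 <= 8."""
        rng = np.random.default_rng(17)
        for n in range(2, 9):
            for n1 in range(1, n):
                pooled = np.round(rng.uniform(0, 1, size=n), 1)  # ties likely
                x, y = pooled[:n1], pooled[n1:]
                from scipy.stats import rankdata

                ranks = rankdata(pooled)
                w_obs = ranks[:n1].sum()
                mu = n1 * (n + 1) / 2
                total = hits = 0
                for idx in combinations(range(n), n1):
                    total += 1
                    if abs(sum(ranks[i] for i in idx) - mu) >= abs(w_obs - mu) - 1e-9:
                        hits += 1
                assert rs.rank_sum_test(x, y) == pytest.approx(hits / total)

    def test_normal_approx_reasonable(self):
        x = list(np.linspace(0.1, 0.4, 12))
        y = list(np.linspace(0.6, 1.0, 12))
        p = rs.rank_sum_test(x, y)
        assert p < 1e-4


class TestSpecificity:
    def test_simulated_panel_exact_recovery(self):
        cfg = sd.SimulationConfig(
            seed=5, screen_n_lines=17, screen_n_mutant=5, screen_n_genes=15,
            core_genes=tuple(f"G{i:04d}" for i in range(1, 10)),
        )
        screen, truth = sd.simulate_screen(cfg)
        results = rs.specificity_test(rs.normalize(screen))
        tiered = {r.gene for r in results if r.tier}
        assert tiered == truth.true_core_genes
        for r in results:
            if r.gene in truth.true_core_genes:
                assert r.lower_in_mutant and r.tier == rs.TIER_STRONG

    def test_tiers_consistent(self):
        cfg = sd.SimulationConfig(seed=6, screen_n_lines=6, screen_n_mutant=3,
                                  screen_n_genes=14)
        screen, _ = sd.simulate_screen(cfg)
        for r in rs.specificity_test(rs.normalize(screen)):
            if r.p_value < 0.01:
                assert r.tier == rs.TIER_STRONG
            elif r.p_value < 0.05:
                assert r.tier == rs.TIER_WEAK
            else:
                assert r.tier == rs.TIER_NONE

    def test_scale_invariance(self):
        cfg = sd.SimulationConfig(seed=7, screen_n_lines=5, screen_n_mutant=2,
                                  screen_n_genes=14)
        screen, _ = sd.simulate_screen(cfg)
        scaled = screen.data.copy()
        scaled.loc[scaled["cell_line"] == "M01", "readout"] *= 37.0
        r1 = rs.specificity_test(rs.normalize(screen))
        r2 = rs.specificity_test(
            rs.normalize(rs.ViabilityScreen(data=scaled, meta=screen.meta))
        )
        assert [a.gene for a in r1] == [b.gene for b in r2]
        assert [a.p_value for a in r1] == pytest.approx([b.p_value for b in r2])

    def test_small_group_rejected(self):
        cfg = sd.SimulationConfig(seed=8, screen_n_lines=3, screen_n_mutant=1,
                                  screen_n_genes=14)
        screen, _ = sd.simulate_screen(cfg)
        with pytest.raises(InputError):
            rs.specificity_test(rs.normalize(screen))


class TestConcordanceAndHeatmap:
    def test_identical_screens_rho_one(self, small_screen):
        assert rs.replicate_concordance(small_screen, small_screen) == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        from scipy.stats import spearmanr

        rho, _ = spearmanr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(1 - 6 * 2 / (4 * 15))  # = 0.8 by hand
        assert rho == pytest.approx(0.8)

    def test_reversed_ranks(self):
        day1_rows, day2_rows = [], []
        values = [0.2, 0.4, 0.6, 0.8]
        for i, v in enumerate(values):
            for rep in (1, 2):
                day1_rows.append(("L", f"g{i}", rep, 1000 * v, False))
                day2_rows.append(("L", f"g{i}", rep, 1000 * (1.0 - v + 0.1), False))
        for rep in (1, 2):
            day1_rows.append(("L", "NTC", rep, 1000.0, True))
            day2_rows.append(("L", "NTC", rep, 1000.0, True))
        rho = rs.replicate_concordance(_screen(day1_rows), _screen(day2_rows))
        assert rho == pytest.approx(-1.0)

    def test_too_few_keys(self, small_screen):
        tiny = _screen(
            [("L1", "NTC", 1, 1000.0, True), ("L1", "NTC", 2, 1000.0, True),
             ("L1", "g", 1, 500.0, False), ("L1", "g", 2, 500.0, False)]
        )
        with pytest.raises(InputError):
            rs.replicate_concordance(tiny, tiny)

    def test_heatmap_matrix(self, small_screen, tmp_path):
        m = rs.viability_heatmap(
            small_screen, tsv_path=tmp_path / "h.tsv", png_path=tmp_path / "h.png"
        )
        assert m.shape == (2, 2)
        assert m.loc["g_hit", "L1"] == pytest.approx(0.4)
        assert (tmp_path / "h.tsv").exists() and (tmp_path / "h.png").exists()

    def test_heatmap_replicate_order_invariant(self, small_screen):
        shuffled = small_screen.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        m1 = rs.viability_heatmap(small_screen)
        m2 = rs.viability_heatmap(rs.ViabilityScreen(data=shuffled))
        pd.testing.assert_frame_equal(m1, m2)

    def test_row_means_match_grand_means(self, small_screen):
        m = rs.viability_heatmap(small_screen)
        norm = rs.normalize(small_screen)
        for gene in m.index:
            per_line = [np.mean(norm.replicates(l, gene)) for l in m.columns]
            assert m.loc[gene].mean() == pytest.approx(np.mean(per_line))


@settings(max_examples=60, deadline=None)
@given(
    st.sets(st.text(alphabet="abcdefgh", min_size=1, max_size=2), max_size=8),
    st.sets(st.text(alphabet="abcdefgh", min_size=1, max_size=2), max_size=8),
)
def test_pair_overlap_is_partition(a, b):
    shared, p_only, r_only = rs.pair_overlap(a, b)
    assert shared | p_only | r_only == a | b
    assert shared.isdisjoint(p_only) and shared.isdisjoint(r_only)
    assert p_only.isdisjoint(r_only)
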