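"""Replicate statistics, t-tests, log-fold heat maps, pigment summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

import chloroquench as cq
from chloroquench.compare import ReplicateSet
from chloroquench.errors import ChloroquenchError


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * stdtr(df, -abs(t))
    return t, p


class TestReplicateStats:
    def test_constant_values(self):
        assert cq.replicate_stats(ReplicateSet("g", [1.0, 1.0, 1.0])) == (1.0, 0.0)

    def test_hand_computed_pair(self):
        mean, sd = cq.replicate_stats(ReplicateSet("g", [2.0, 4.0]))
        assert mean == 3.0
        assert sd == pytest.approx(math.sqrt(2))

    def test_single_value_sd_undefined(self):
        mean, sd = cq.replicate_stats(ReplicateSet("g", [5.0]))
        assert mean == 5.0
        assert math.isnan(sd)

    def test_empty_set_rejected(self):
        with pytest.raises(ChloroquenchError):
            ReplicateSet("g", [])


class TestTTest:
    def test_identical_groups(self):
        r = cq.t_test(ReplicateSet("a", [1.0, 2.0, 3.0]),
                      ReplicateSet("b", [1.0, 2.0, 3.0]))
        assert r.t == 0.0
        assert r.p_value == 1.0
        assert not r.significant

    def test_large_shift_is_significant(self):
        r = cq.t_test(ReplicateSet("a", [1.0, 2.0, 3.0]),
                      ReplicateSet("b", [11.0, 12.0, 13.0]))
        assert r.p_value < 1e-3
        assert r.significant

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-1, 1), 1, nb)
            res = cq.t_test(ReplicateSet("a", a), ReplicateSet("b", b))
            t_ref, p_ref = pooled_t_oracle(a, b)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p_value == pytest.approx(p_ref, abs=1e-8)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ChloroquenchError):
            cq.t_test(ReplicateSet("a", [1.0]), ReplicateSet("b", [1.0, 2.0]))


class TestLogFold:
    @pytest.mark.parametrize("m,w,expected", [(2.0, 2.0, 0.0),
                                              (4.0, 2.0, 1.0),
                                              (1.0, 2.0, -1.0)])
    def test_base_definition(self, m, w, expected):
        assert cq.log_fold(m, w) == pytest.approx(expected)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 10, 2)
            assert cq.log_fold(a, b) == pytest.approx(-cq.log_fold(b, a))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ChloroquenchError):
            cq.log_fold(0.0, 1.0)


def tidy_panel(rng, genotypes=("WT", "mut"), times=(10.0, 20.0), shift=0.0):
    rows = []
    for g in genotypes:
        for t in times:
            for rep in range(4):
                base = 1.0 + (shift if g != "WT" else 0.0)
                rows.append({"genotype": g, "replicate": rep, "time_min": t,
                             "value": base + 0.01 * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestHeatmapMatrix:
    def test_wt_row_is_zero_and_never_significant(self, rng):
        m = cq.heatmap_matrix(tidy_panel(rng), "WT")
        assert np.all(m.cells.loc["WT"] == 0.0)
        assert not m.significance.loc["WT"].any()

    def test_shifted_mutant_flagged(self, rng):
        m = cq.heatmap_matrix(tidy_panel(rng, shift=1.0), "WT")
        assert np.all(m.cells.loc["mut"] > 0.9)
        assert m.significance.loc["mut"].all()

    def test_row_permutation_equivariance(self, rng):
        df = tidy_panel(rng, genotypes=("WT", "a", "b"))
        m1 = cq.heatmap_matrix(df, "WT")
        df2 = pd.concat([df[df.genotype == g] for g in ("b", "WT", "a")])
        m2 = cq.heatmap_matrix(df2, "WT")
        assert m2.genotypes == ["b", "WT", "a"]
        pd.testing.assert_frame_equal(m1.cells.loc[m2.genotypes], m2.cells)

    def test_missing_wt_rejected(self, rng):
        with pytest.raises(ChloroquenchError, match="wild-type"):
            cq.heatmap_matrix(tidy_panel(rng), "Col-0")

    def test_misaligned_time_grids_rejected(self, rng):
        df = tidy_panel(rng)
        df.loc[(df.genotype == "mut") & (df.time_min == 20.0), "time_min"] = 21.0
        with pytest.raises(ChloroquenchError, match="time grid"):
            cq.heatmap_matrix(df, "WT")

    def test_near_zero_wt_mean_reported_missing(self, rng):
        df = tidy_panel(rng)
        df.loc[df.genotype == "WT", "value"] = 0.0
        m = cq.heatmap_matrix(df, "WT")
        assert m.cells.loc["mut"].isna().all()

    def test_large_mutant_phi_cells_negative_in_fluctuating_phases(
            self, single_day, wt, large):
        # noiseless forward model: the large-chloroplast class suffers more
        # photoinhibition, so its Φ_II falls below WT under fluctuating light
        rows = []
        for g in (wt, large):
            trace, truth = cq.simulate_experiment(single_day, g)
            pulses = cq.render_observed_pulses(truth, trace, cv_noise=0.0)
            qs = cq.process_series(pulses)
            for rep in range(2):  # identical replicates: noiseless contract
                for _, q in qs.frame.iterrows():
                    rows.append({"genotype": g.name, "replicate": rep,
                                 "time_min": q.time_min, "value": q.phi_ii})
        m = cq.heatmap_matrix(pd.DataFrame(rows), "WT")
        fluct_times = [s.end_time - 1.0 for s in single_day.steps
                       if s.phase == "fluctuating"]
        cells = m.cells.loc["large", fluct_times]
        assert (cells <= 0).all()
        late = [t for t in fluct_times if t > 300]
        assert (m.cells.loc["large", late] < 0).all()


@pytest.fixture(scope="module")
def table():
    return cq.pigment_summary()


class TestPigmentSummary:

    @pytest.mark.parametrize("genotype,condition,expected", [
        ("arc6-5", "before", 84.2),
        ("ftsZ1-1", "after", 88.8),
        ("minD1-1", "before", 107.8),
    ])
    def test_published_worked_examples(self, table, genotype, condition, expected):
        row = table[(table.genotype == genotype) & (table.condition == condition)]
        assert row["percent_of_wt"].iloc[0] == expected

    def test_wt_rows_are_100(self, table):
        wt_rows = table[table.genotype == table.parental_wt]
        assert (wt_rows["percent_of_wt"] == 100.0).all()

    def test_missing_wt_block_rejected(self):
        df = pd.DataFrame([{"block": "x", "genotype": "mut",
                            "parental_wt": "WT", "condition": "before",
                            "chl_content": 900.0, "chl_a_b": 3.0,
                            "chl_car": 4.0}])
        with pytest.raises(ChloroquenchError, match="wild-type"):
            cq.pigment_summary(df)


class TestMovementTable:
    def test_summary_columns_and_percent(self, ladder_regime, wt, large):
        traces = {
            "WT": [cq.simulate_movement(ladder_regime, wt, 0.002, seed=s)[0]
                   for s in range(4)],
            "large": [cq.simulate_movement(ladder_regime, large, 0.002, seed=s)[0]
                      for s in range(4, 8)],
        }
        table = cq.movement_table(traces, "WT")
        wt_row = table[table.genotype == "WT"].iloc[0]
        lg_row = table[table.genotype == "large"].iloc[0]
        assert wt_row["avoidance_percent_of_wt"] == 100.0
        assert lg_row["avoidance_percent_of_wt"] < 50.0
        assert lg_row["avoidance_significant"]

    def test_missing_wt_rejected(self, ladder_regime, wt):
        traces = {"g": [cq.simulate_movement(ladder_regime, wt, 0.0)[0]]}
        with pytest.raises(ChloroquenchError, match="wild-type"):
            cq.movement_table(traces, "WT")
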