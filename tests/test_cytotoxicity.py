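"""Calcein-trace readouts: viability, survival index, paired donor tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from surftarget.cytotoxicity import CalceinTraceSet, paired_donor_test, survival_index, viability_at
from surftarget.simulate import SimulationConfig, simulate_calcein_traces


def traces_from(wells: dict[str, tuple[str, str, np.ndarray]], times=None) -> CalceinTraceSet:
    """wells: well_id -> (condition, cell_line, trace array); donor fixed."""
    times = np.arange(0, 961, 10) if times is None else times
    rows = []
    for well, (cond, line, trace) in wells.items():
        for t, v in zip(times, trace):
            rows.append(
                {
                    "well_id": well,
                    "donor": "d1",
                    "cell_line": line,
                    "condition": cond,
                    "ratio": "1:10" if cond == "treated" else "-",
                    "time_min": int(t),
                    "fluorescence": float(v),
                }
            )
    return CalceinTraceSet(data=pd.DataFrame(rows))


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Brute-force two-sided exact signed-rank p by enumerating sign flips."""
    ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    stats = []
    for signs in product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    mean_w = ranks.sum() / 2.0
    # two-sided: as or more extreme in distance from the null mean
    p = np.mean(np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return float(p)


class TestViability:
    def test_constant_trace(self):
        n = 97
        tr = traces_from({"w1": ("control", "WT", np.full(n, 42.0))})
        assert viability_at(tr, 300).loc["w1"] == 42.0
        assert viability_at(tr, 955).loc["w1"] == 42.0

    def test_exact_grid_point_no_interpolation(self):
        times = np.arange(0, 961, 10)
        trace = times.astype(float)  # value equals its own timepoint
        tr = traces_from({"w1": ("control", "WT", trace)})
        assert viability_at(tr, 300).loc["w1"] == 300.0
        assert viability_at(tr, 304).loc["w1"] == 300.0  # snaps to nearest grid point

    def test_exponential_decay_closed_form(self):
        times = np.arange(0, 961, 10)
        k = 0.004
        tr = traces_from({"w1": ("control", "WT", 1000.0 * np.exp(-k * times))})
        assert viability_at(tr, 300).loc["w1"] == pytest.approx(1000 * np.exp(-k * 300), rel=1e-12)

    def test_out_of_range_errors(self):
        tr = traces_from({"w1": ("control", "WT", np.full(97, 1.0))})
        with pytest.raises(ValueError, match="outside"):
            viability_at(tr, 2000)


class TestSurvivalIndex:
    def test_treated_equals_control_index_one(self):
        n = 97
        tr = traces_from(
            {
                "c1": ("control", "WT", np.full(n, 500.0)),
                "t1": ("treated", "WT", np.full(n, 500.0)),
            }
        )
        si = survival_index(tr)
        assert si["survival_index"].iloc[0] == pytest.approx(1.0)

    def test_half_intensity_index_half(self):
        n = 97
        tr = traces_from(
            {
                "c1": ("control", "WT", np.full(n, 800.0)),
                "t1": ("treated", "WT", np.full(n, 500.0)),
                "t2": ("treated", "WT", np.full(n, 300.0)),
            }
        )
        si = survival_index(tr)
        assert si["survival_index"].iloc[0] == pytest.approx(0.5)

    def test_gain_invariance(self):
        n = 97
        base = {
            "c1": ("control", "WT", np.full(n, 640.0)),
            "t1": ("treated", "WT", np.full(n, 130.0)),
        }
        scaled = {w: (c, l, v * 3.7) for w, (c, l, v) in base.items()}
        si1 = survival_index(traces_from(base))
        si2 = survival_index(traces_from(scaled))
        assert si1["survival_index"].iloc[0] == pytest.approx(si2["survival_index"].iloc[0])

    def test_zero_control_errors(self):
        n = 97
        tr = traces_from(
            {
                "c1": ("control", "WT", np.zeros(n)),
                "t1": ("treated", "WT", np.full(n, 10.0)),
            }
        )
        with pytest.raises(ValueError, match="control"):
            survival_index(tr)

    def test_simulated_kill_rate_closed_form(self):
        cfg = SimulationConfig(
            seed=31,
            calcein_donors=3,
            calcein_kill_rates={"WT": 0.001},
            calcein_donor_log_sd=0.0,
            calcein_noise_sd=0.0,
            calcein_ratios=("1:10",),
        )
        tr = simulate_calcein_traces(cfg)
        si = survival_index(tr, 300)
        assert np.allclose(si["survival_index"], np.exp(-0.001 * 300), rtol=1e-9)

    def test_zero_kill_rate_index_one(self):
        cfg = SimulationConfig(
            seed=32,
            calcein_donors=2,
            calcein_kill_rates={"WT": 0.0},
            calcein_noise_sd=0.0,
            calcein_ratios=("1:10",),
        )
        si = survival_index(simulate_calcein_traces(cfg), 300)
        assert np.allclose(si["survival_index"], 1.0)


class TestPairedDonorTest:
    @staticmethod
    def _frame(indices, line):
        return pd.DataFrame(
            {
                "donor": [f"d{i}" for i in range(len(indices))],
                "cell_line": line,
                "ratio": "1:10",
                "mean_treated": indices,
                "mean_control": 1.0,
                "survival_index": indices,
            }
        )

    def test_identical_arms_p_near_one(self):
        wt = self._frame([0.9, 0.8, 0.7, 0.6, 0.85], "WT")
        ko = self._frame([0.9, 0.8, 0.7, 0.6, 0.85], "KO")
        out = paired_donor_test(wt, ko, method="ttest")
        assert np.isnan(out["ttest_p"]) or out["ttest_p"] > 0.9

    def test_all_concordant_ten_donors_exact_p(self):
        rng = np.random.default_rng(8)
        wt_vals = rng.uniform(0.8, 1.0, size=10)
        ko_vals = wt_vals - rng.uniform(0.2, 0.4, size=10)
        out = paired_donor_test(self._frame(wt_vals, "WT"), self._frame(ko_vals, "KO"))
        assert out["wilcoxon_p"] == pytest.approx(2 / 1024)
        assert out["wilcoxon_p"] == pytest.approx(exact_signed_rank_p(wt_vals - ko_vals))

    def test_exact_p_matches_enumeration_mixed_signs(self):
        diffs = np.array([0.3, -0.1, 0.25, 0.4, -0.05, 0.2, 0.15])
        wt = self._frame(0.8 + diffs, "WT")
        ko = self._frame(np.full(7, 0.8), "KO")
        out = paired_donor_test(wt, ko)
        assert out["wilcoxon_p"] == pytest.approx(exact_signed_rank_p(diffs))

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        wt_vals = rng.uniform(0.5, 1.0, size=8)
        ko_vals = wt_vals + rng.uniform(-0.3, 0.3, size=8)
        p1 = paired_donor_test(self._frame(wt_vals, "WT"), self._frame(ko_vals, "KO"))["wilcoxon_p"]
        p2 = paired_donor_test(self._frame(ko_vals, "KO"), self._frame(wt_vals, "WT"))["wilcoxon_p"]
        assert p1 == pytest.approx(p2)

    def test_donor_reordering_invariance(self):
        rng = np.random.default_rng(10)
        wt_vals = rng.uniform(0.5, 1.0, size=6)
        ko_vals = wt_vals - 0.2
        wt, ko = self._frame(wt_vals, "WT"), self._frame(ko_vals, "KO")
        p1 = paired_donor_test(wt, ko)["wilcoxon_p"]
        p2 = paired_donor_test(wt.iloc[::-1], ko)["wilcoxon_p"]
        assert p1 == pytest.approx(p2)

    def test_mismatched_donors_error(self):
        wt = self._frame([0.9, 0.8, 0.7], "WT")
        ko = self._frame([0.9, 0.8, 0.7, 0.6], "KO")
        with pytest.raises(ValueError, match="donor"):
            paired_donor_test(wt, ko)


class TestSimulatedTraces:
    def test_missing_control_condition_rejected(self):
        with pytest.raises(ValueError, match="control"):
            SimulationConfig(seed=1, calcein_conditions=("treated",))

    def test_ko_killed_faster_than_wt(self):
        cfg = SimulationConfig(seed=33, calcein_donors=10)
        si = survival_index(simulate_calcein_traces(cfg), 300)
        wt = si[(si["cell_line"] == "WT") & (si["ratio"] == "1:10")].set_index("donor")["survival_index"]
        ko = si[(si["cell_line"] == "KO") & (si["ratio"] == "1:10")].set_index("donor")["survival_index"]
        assert (ko < wt).all()
        out = paired_donor_test(
            si[(si["cell_line"] == "WT") & (si["ratio"] == "1:10")],
            si[(si["cell_line"] == "KO") & (si["ratio"] == "1:10")],
        )
        assert out["wilcoxon_p"] < 0.01
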