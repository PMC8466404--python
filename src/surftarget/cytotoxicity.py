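"""T-cell cytotoxicity readout from calcein-release time series.

Calcein-labelled tumor cells lose fluorescence as effector T cells
kill them. Each well is recorded every 10 min for up to 16 h; tumor
viability is read at a fixed evaluation time (default 5 h), and the
survival index of a (donor, cell line, effector ratio) stratum is the
mean fluorescence of its treated wells divided by the mean of the
matched control wells (tumor cells only). An index of 1 means no
killing. Donor-level indices of wild-type vs knockout tumor lines are
compared with the exact paired Wilcoxon signed-rank test (paired t
available as well).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CalceinTraceSet",
    "viability_at",
    "survival_index",
    "paired_donor_test",
]

REQUIRED_COLUMNS = ("well_id", "donor", "cell_line", "condition", "time_min", "fluorescence")


@dataclass
class CalceinTraceSet:
    """Long-format per-well fluorescence traces.

    ``data`` columns: well_id, donor, cell_line, condition
    (control|treated), ratio (e.g. "1:10"; optional), time_min,
    fluorescence. Timepoints must be strictly increasing within a well
    and fluorescence non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if "ratio" not in self.data.columns:
            self.data = self.data.assign(ratio="-")
        if (self.data["fluorescence"] < 0).any():
            raise ValueError("fluorescence must be non-negative")
        for well, grp in self.data.groupby("well_id"):
            t = grp["time_min"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"timepoints not strictly increasing in well {well!r}")
        conditions = set(self.data["condition"])
        if "control" not in conditions:
            raise ValueError("no control (tumor cells only) wells present")

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())


def viability_at(traces: CalceinTraceSet, t_eval: float = 300.0) -> pd.Series:
    """Per-well fluorescence at the recorded timepoint nearest ``t_eval``.

    On the regular 10-min grid the match is exact; no interpolation is
    performed. ``t_eval`` outside the recorded range is an error.
    """
    tp = traces.timepoints
    if t_eval < tp.min() or t_eval > tp.max():
        raise ValueError(f"t_eval={t_eval} outside recorded range [{tp.min()}, {tp.max()}]")
    t_near = tp[np.argmin(np.abs(tp - t_eval))]
    snap = traces.data[traces.data["time_min"] == t_near]
    return snap.set_index("well_id")["fluorescence"]


def survival_index(traces: CalceinTraceSet, t_eval: float = 300.0) -> pd.DataFrame:
    """Survival index per (donor, cell line, ratio) stratum.

    index = mean fluorescence over treated replicate wells /
    mean over the matched control wells, at ``t_eval``.
    """
    vals = viability_at(traces, t_eval)
    meta = traces.data.drop_duplicates("well_id").set_index("well_id")
    df = meta.loc[vals.index, ["donor", "cell_line", "condition", "ratio"]].copy()
    df["fluorescence"] = vals
    rows = []
    for (donor, line, ratio), grp in df.groupby(["donor", "cell_line", "ratio"], sort=True):
        treated = grp.loc[grp["condition"] == "treated", "fluorescence"]
        control = df.loc[
            (df["donor"] == donor) & (df["cell_line"] == line) & (df["condition"] == "control"),
            "fluorescence",
        ]
        if treated.empty:
            continue
        if control.empty or control.mean() == 0:
            raise ValueError(f"no usable control wells for donor={donor!r} line={line!r}")
        rows.append(
            {
                "donor": donor,
                "cell_line": line,
                "ratio": ratio,
                "mean_treated": float(treated.mean()),
                "mean_control": float(control.mean()),
                "survival_index": float(treated.mean() / control.mean()),
            }
        )
    return pd.DataFrame(rows)


def paired_donor_test(
    results_wt: pd.DataFrame,
    results_ko: pd.DataFrame,
    method: str = "wilcoxon",
) -> dict:
    """Paired donor-level comparison of survival indices (WT vs KO).

    Both frames come from :func:`survival_index`; donors are matched by
    the ``donor`` column. Default is the exact Wilcoxon signed-rank
    test; ``method="ttest"`` runs a paired t, ``method="both"`` reports
    both. Fewer than 5 donor pairs triggers a low-power warning but the
    exact p-value is still computed.
    """
    wt = results_wt.set_index("donor")["survival_index"]
    ko = results_ko.set_index("donor")["survival_index"]
    donors = wt.index.intersection(ko.index)
    if not wt.index.symmetric_difference(ko.index).empty:
        raise ValueError("donor sets differ between arms")
    if len(donors) < 5:
        logger.warning("only %d donor pairs; the paired test has low power", len(donors))
    a, b = wt.loc[donors].to_numpy(), ko.loc[donors].to_numpy()
    out: dict = {"n_donors": int(len(donors)), "mean_wt": float(a.mean()), "mean_ko": float(b.mean())}
    if method in ("wilcoxon", "both"):
        res = stats.wilcoxon(a, b, alternative="two-sided", method="exact")
        out["wilcoxon_statistic"] = float(res.statistic)
        out["wilcoxon_p"] = float(res.pvalue)
    if method in ("ttest", "both"):
        res = stats.ttest_rel(a, b)
        out["ttest_statistic"] = float(res.statistic)
        out["ttest_p"] = float(res.pvalue)
    if method not in ("wilcoxon", "ttest", "both"):
        raise ValueError(f"unknown method {method!r}")
    return out
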