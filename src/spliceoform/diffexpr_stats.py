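"""Temperature x stage expression statistics and the canonical/isoform ratio table.

Expression matrices are tidy DataFrames: one row per biological sample with
``stage``, ``temperature``, ``replicate`` columns plus one column per
transcript holding relative expression (qPCR) or CPM (RNA-seq path).

The inference toolkit is deliberately classical: a two-way fixed-effects
ANOVA (temperature, stage, interaction) on log expression, per-stage Welch
t-tests with no multiple-testing correction at alpha 0.05, and per-stage
t-tests on the log canonical/isoform ratio.  Fold changes are reported in
log2 units; ANOVA internals use natural logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "StatResult",
    "anova_expression",
    "posthoc_ttests",
    "transcript_ratio_table",
    "counts_de_test",
]

FACTOR_COLS = ("stage", "temperature", "replicate")


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: float
    p_value: float
    group_means: Mapping[str, float]
    effect: float  # log2 fold change (MPT - FPT) where applicable

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_design(matrix: pd.DataFrame, transcript: str) -> None:
    if transcript not in matrix.columns:
        raise KeyError(f"transcript {transcript!r} not in matrix")
    cells = matrix.groupby(["stage", "temperature"]).size()
    full = [
        (s, t)
        for s in matrix["stage"].unique()
        for t in matrix["temperature"].unique()
    ]
    for cell in full:
        if cell not in cells.index or cells[cell] < 2:
            raise ValueError(f"design cell stage={cell[0]}, temperature={cell[1]} "
                             "is empty or has < 2 replicates")


def anova_expression(matrix: pd.DataFrame, transcript: str) -> dict[str, StatResult]:
    """Two-way ANOVA (temperature * stage) on log expression; one result per term."""
    matrix = matrix.dropna(subset=[transcript])
    _check_design(matrix, transcript)
    df = matrix[["stage", "temperature"]].copy()
    df["y"] = np.log(matrix[transcript].to_numpy(dtype=float))
    group_means = {
        f"{t}": float(g) for t, g in df.groupby("temperature")["y"].mean().items()
    }
    if np.ptp(df["y"].to_numpy()) == 0:
        # constant response: no variation to apportion to any term
        return {
            term: StatResult(f"anova[{term}]", 0.0, np.nan, 1.0, group_means, 0.0)
            for term in ("temperature", "stage", "temperature:stage")
        }
    model = smf.ols("y ~ C(temperature) * C(stage)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(temperature)": "temperature",
        "C(stage)": "stage",
        "C(temperature):C(stage)": "temperature:stage",
    }
    out = {}
    for raw, term in rename.items():
        row = table.loc[raw]
        out[term] = StatResult(
            f"anova[{term}]",
            float(row["F"]),
            float(row["df"]),
            float(row["PR(>F)"]),
            group_means,
            0.0,
        )
    return out


def _welch_log(a: np.ndarray, b: np.ndarray, test_name: str, alpha: float) -> StatResult:
    """Welch t-test on natural-log values; effect reported as log2(a/b)."""
    la, lb = np.log(a), np.log(b)
    effect = float((la.mean() - lb.mean()) / np.log(2.0))
    if np.ptp(la) == 0 and np.ptp(lb) == 0 and la.mean() == lb.mean():
        return StatResult(test_name, 0.0, np.nan, 1.0,
                          {"a": float(a.mean()), "b": float(b.mean())}, 0.0)
    t, p = stats.ttest_ind(la, lb, equal_var=False)
    df = _welch_df(la, lb)
    return StatResult(
        test_name,
        float(t),
        df,
        float(p),
        {"a": float(a.mean()), "b": float(b.mean())},
        effect,
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return float(len(a) + len(b) - 2)
    return float(
        (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    )


def posthoc_ttests(
    matrix: pd.DataFrame,
    transcript: str,
    alpha: float = 0.05,
    group_a: str = "MPT",
    group_b: str = "FPT",
) -> pd.DataFrame:
    """Per-stage Welch t-tests of log expression between temperatures.

    No multiple-testing correction is applied across stages; each stage is
    flagged significant at ``alpha`` on its own.  Stages with fewer than two
    replicates in either group are skipped.
    """
    if transcript not in matrix.columns:
        raise KeyError(f"transcript {transcript!r} not in matrix")
    rows = []
    for stage, grp in matrix.groupby("stage"):
        a = grp.loc[grp["temperature"] == group_a, transcript].to_numpy(dtype=float)
        b = grp.loc[grp["temperature"] == group_b, transcript].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]  # samples lost to qPCR QC
        if len(a) < 2 or len(b) < 2:
            import warnings

            warnings.warn(f"stage {stage}: < 2 replicates in a group, skipped")
            continue
        res = _welch_log(a, b, f"welch[{transcript}@stage{stage}]", alpha)
        rows.append(
            {
                "stage": stage,
                "transcript": transcript,
                "t": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "log2fc": res.effect,
                "mean_" + group_a: res.group_means["a"],
                "mean_" + group_b: res.group_means["b"],
                "significant": bool(res.p_value < alpha),
            }
        )
    return pd.DataFrame(rows)


def transcript_ratio_table(
    matrix: pd.DataFrame,
    numerator: str,
    denominator: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonical/isoform-style ratio analysis per stage x temperature.

    Per-sample ratios numerator/denominator (samples with a zero denominator
    are excluded and logged via a warning), cell means per stage x
    temperature, and a per-stage Welch t-test on the log ratio between
    temperatures.  Returns (cell-mean table with a p-value row, per-stage
    test table).  The cell-mean table is shaped rows = temperatures, columns
    = stages.
    """
    for col in (numerator, denominator):
        if col not in matrix.columns:
            raise KeyError(f"transcript {col!r} not in matrix")
    work = matrix.dropna(subset=[numerator, denominator])
    bad = work[denominator].to_numpy(dtype=float) <= 0
    if bad.any():
        import warnings

        warnings.warn(f"{int(bad.sum())} sample(s) with non-positive denominator excluded")
        work = work[~bad]
    work = work.assign(ratio=work[numerator] / work[denominator])
    cell_means = work.pivot_table(
        index="temperature", columns="stage", values="ratio", aggfunc="mean"
    )
    tests = []
    for stage, grp in work.groupby("stage"):
        a = grp.loc[grp["temperature"] == "MPT", "ratio"].to_numpy(dtype=float)
        b = grp.loc[grp["temperature"] == "FPT", "ratio"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        res = _welch_log(a, b, f"ratio@stage{stage}", alpha)
        tests.append(
            {
                "stage": stage,
                "t": res.statistic,
                "p_value": res.p_value,
                "significant": bool(res.p_value < alpha),
            }
        )
    tests_df = pd.DataFrame(tests)
    p_row = tests_df.set_index("stage")["p_value"].reindex(cell_means.columns)
    table = pd.concat([cell_means, p_row.to_frame("p_value").T])
    return table, tests_df


def counts_de_test(
    matrix: pd.DataFrame,
    transcripts: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript, per-stage Welch t-test on log2(CPM + 1) between temperatures.

    log2FC is the difference of group means on the log2(CPM+1) scale
    (MPT minus FPT).  All-zero transcripts are skipped with a note column.
    """
    if transcripts is None:
        transcripts = [c for c in matrix.columns if c not in FACTOR_COLS]
    rows = []
    for tr in transcripts:
        values = matrix[tr].to_numpy(dtype=float)
        if (values == 0).all():
            rows.append(
                {"transcript": tr, "stage": None, "t": np.nan, "p_value": np.nan,
                 "log2fc": np.nan, "significant": False, "note": "all zero, skipped"}
            )
            continue
        for stage, grp in matrix.groupby("stage"):
            a = np.log2(grp.loc[grp["temperature"] == "MPT", tr].to_numpy(dtype=float) + 1.0)
            b = np.log2(grp.loc[grp["temperature"] == "FPT", tr].to_numpy(dtype=float) + 1.0)
            if len(a) < 2 or len(b) < 2:
                continue
            effect = float(a.mean() - b.mean())
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
                t, p, df = 0.0, 1.0, np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                df = _welch_df(a, b)
            rows.append(
                {
                    "transcript": tr,
                    "stage": stage,
                    "t": float(t),
                    "p_value": float(p),
                    "log2fc": effect,
                    "significant": bool(p < alpha),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
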