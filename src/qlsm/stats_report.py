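"""Group-comparison statistics and tabular reporting.

Metrics arrive as a long-format table (sample, group factors, metric,
value).  Pairwise contrasts use a two-tailed Welch t-test; factorial
designs (e.g. age x region) use a two-way ANOVA with Type-II sums of
squares followed by Tukey HSD contrasts on the marginal level means, with
the studentized-range adjustment and the two-way model's residual mean
square.  P < 0.05 is the conventional significance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "t_test_two_tailed",
    "two_way_anova_tukey",
    "AnovaTukeyResult",
    "write_report",
]


def t_test_two_tailed(
    group_a, group_b, welch: bool = True
) -> tuple[float, float, float]:
    """Two-tailed t-test; Welch (unequal variances) by default.

    Returns (t, df, p).  The degenerate case of zero variance in both
    groups with equal means is reported as t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class AnovaTukeyResult:
    anova: pd.DataFrame  # per-effect sum_sq, df, F, p
    tukey: pd.DataFrame  # per factor-level pair: diff, q, p_adj
    residual_df: float
    residual_ms: float


def two_way_anova_tukey(
    table: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
) -> AnovaTukeyResult:
    """Two-way ANOVA (Type II, with interaction) plus Tukey HSD.

    Requires >= 2 levels per factor and >= 2 replicates per cell (no empty
    cells).  Tukey HSD compares the marginal means of each factor's levels
    using the residual mean square of the full two-way model; mild
    imbalance is handled with the harmonic mean of the level counts
    (Tukey-Kramer).  The degenerate all-constant case is reported as F = 0,
    p = 1 for every effect.
    """
    df = table[[value, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = df.groupby([factor_a, factor_b], observed=True)[value].count()
    full = pd.MultiIndex.from_product([df[factor_a].unique(), df[factor_b].unique()])
    missing = [c for c in full if c not in cells.index or cells.get(c, 0) < 2]
    if missing:
        raise ValueError(f"cells with fewer than 2 replicates: {missing}")

    df = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    resid_df = float(model.df_resid)
    resid_ms = float(model.ssr / model.df_resid)

    if np.allclose(df["_y"].var(ddof=1), 0.0):
        effects = ["C(_fa)", "C(_fb)", "C(_fa):C(_fb)"]
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": [df["_fa"].nunique() - 1, df["_fb"].nunique() - 1, np.nan], "F": 0.0, "PR(>F)": 1.0},
            index=effects,
        )
    else:
        anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={"C(_fa)": factor_a, "C(_fb)": factor_b, "C(_fa):C(_fb)": f"{factor_a}:{factor_b}"})

    tukey_rows = []
    for fcol, fname in (("_fa", factor_a), ("_fb", factor_b)):
        means = df.groupby(fcol, observed=True)["_y"].mean()
        counts = df.groupby(fcol, observed=True)["_y"].count()
        k = len(means)
        for l1, l2 in combinations(means.index, 2):
            n_h = 2.0 / (1.0 / counts[l1] + 1.0 / counts[l2])  # harmonic mean n
            diff = float(means[l2] - means[l1])
            se = np.sqrt(resid_ms / n_h)
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, resid_df))
            tukey_rows.append(
                {"factor": fname, "level_1": l1, "level_2": l2, "diff": diff, "q": float(q), "p_adj": p_adj}
            )
    return AnovaTukeyResult(
        anova=anova, tukey=pd.DataFrame(tukey_rows), residual_df=resid_df, residual_ms=resid_ms
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_METRIC_FILES = {
    "volume_density": "density.csv",
    "phenotype_fraction": "phenotype_fraction.csv",
    "compartment_fraction": "compartment_fraction.csv",
    "association_fraction": "association_fraction.csv",
}


def write_report(results: pd.DataFrame, out_dir, alpha: float = 0.05) -> dict:
    """Write per-metric CSVs (group mean ± SD plus pairwise Welch tests)
    and a machine-readable JSON summary.

    ``results`` is long-format with columns ``sample``, ``group``,
    ``region``, ``compartment``, ``metric``, ``value`` (region/compartment
    may be empty strings).  Output is deterministic: fixed column order,
    sorted rows, fixed float formatting.  Returns the summary dict.
    """
    required = {"sample", "group", "region", "compartment", "metric", "value"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"alpha": alpha, "metrics": {}}
    metrics = sorted(results["metric"].unique()) if len(results) else []
    written = {}
    for metric, fname in sorted({m: _METRIC_FILES.get(m, f"{m}.csv") for m in metrics}.items()):
        sub = results[results["metric"] == metric]
        rows = []
        tests = []
        for (region, compartment), block in sub.groupby(["region", "compartment"], dropna=False):
            stats_tbl = block.groupby("group")["value"].agg(["count", "mean", "std"]).reset_index()
            for _, r in stats_tbl.iterrows():
                rows.append(
                    {
                        "metric": metric,
                        "region": region,
                        "compartment": compartment,
                        "group": r["group"],
                        "n": int(r["count"]),
                        "mean": r["mean"],
                        "sd": r["std"],
                    }
                )
            groups = sorted(block["group"].unique())
            for g1, g2 in combinations(groups, 2):
                a = block.loc[block["group"] == g1, "value"].to_numpy()
                b = block.loc[block["group"] == g2, "value"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                t, dfree, p = t_test_two_tailed(a, b)
                tests.append(
                    {
                        "metric": metric,
                        "region": region,
                        "compartment": compartment,
                        "group_1": g1,
                        "group_2": g2,
                        "t": t,
                        "df": dfree,
                        "p": p,
                        "significant": bool(p < alpha),
                    }
                )
        frame = pd.DataFrame(rows, columns=["metric", "region", "compartment", "group", "n", "mean", "sd"])
        frame = frame.sort_values(["region", "compartment", "group"]).reset_index(drop=True)
        test_frame = pd.DataFrame(
            tests,
            columns=["metric", "region", "compartment", "group_1", "group_2", "t", "df", "p", "significant"],
        ).sort_values(["region", "compartment", "group_1", "group_2"]).reset_index(drop=True)
        frame.to_csv(out_dir / fname, index=False, float_format="%.10g")
        test_frame.to_csv(out_dir / fname.replace(".csv", "_tests.csv"), index=False, float_format="%.10g")
        written[metric] = fname
        summary["metrics"][metric] = {
            "file": fname,
            "n_groups": int(sub["group"].nunique()),
            "n_significant_contrasts": int(test_frame["significant"].sum()) if len(test_frame) else 0,
        }
    # header-only files for standard panels with no data, so re-runs are stable
    for metric, fname in _METRIC_FILES.items():
        if metric not in written:
            pd.DataFrame(columns=["metric", "region", "compartment", "group", "n", "mean", "sd"]).to_csv(
                out_dir / fname, index=False
            )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
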