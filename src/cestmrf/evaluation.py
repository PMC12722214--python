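"""Statistical machinery for recovery analysis and group comparisons.

Correlation and reliability between estimated and true parameters are
summarized with Pearson's r and the intraclass correlation coefficient.
The ICC variant is fixed package-wide to the two-way random-effects,
absolute-agreement, single-measure form (ICC(2,1)): unlike Pearson's r it
penalizes systematic offset and scale error, which is exactly what a
quantitative-mapping validation needs.  Group comparisons use paired
two-tailed t-tests and one-way ANOVA followed by two-sided Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["pearson", "icc", "paired_ttest", "anova_tukey", "recovery_row",
           "RecoveryReport", "phantom_recovery_report", "ICC_VARIANT"]

ICC_VARIANT = "ICC2 (two-way random, absolute agreement, single measure)"


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-distributed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc(x, y, variant: str = "ICC2") -> tuple[float, float]:
    """Intraclass correlation between two measurements of the same targets.

    Default (and package-wide) variant: two-way random effects, absolute
    agreement, single measure, with the F-based p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    n = x.size
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([x, y]),
    })
    table = pg.intraclass_corr(data=df, targets="target", raters="rater",
                               ratings="score").set_index("Type")
    # pingouin labels the absolute-agreement single-measure form either
    # "ICC2" (Shrout-Fleiss numbering) or "ICC(A,1)" (McGraw-Wong).
    aliases = {"ICC2": ("ICC2", "ICC(A,1)"), "ICC3": ("ICC3", "ICC(C,1)"),
               "ICC1": ("ICC1", "ICC(1,1)")}
    for label in aliases.get(variant, (variant,)):
        if label in table.index:
            row = table.loc[label]
            return float(row["ICC"]), float(row["pval"])
    raise KeyError(f"ICC variant {variant!r} not found in table")


def paired_ttest(before, after) -> tuple[float, float]:
    """Paired two-tailed t-test on the change ``after - before``.

    A positive t means ``after`` exceeds ``before``.  Identical vectors
    give (0, 1).  A constant nonzero shift makes the difference variance
    zero and the statistic undefined; that degenerate case is flagged as
    an error rather than returning +-inf.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("need equal-length 1-D vectors")
    diff = after - before
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero variance of differences with nonzero shift: "
                         "t statistic undefined")
    res = sps.ttest_rel(after, before)
    return float(res.statistic), float(res.pvalue)


def anova_tukey(groups: list) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA followed by two-sided Tukey HSD multiple comparisons.

    Returns (F, p, tukey_table) with one table row per group pair
    (columns: group1, group2, meandiff, p_adj, lower, upper, reject).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    F, p = sps.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    tk = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    table = table.rename(columns={"p-adj": "p_adj"})
    return float(F), float(p), table


def recovery_row(parameter: str, scope: str, truth: np.ndarray,
                 estimate: np.ndarray) -> dict:
    """One recovery-statistics record over vial means."""
    r, r_p = pearson(truth, estimate)
    icc_val, icc_p = icc(truth, estimate)
    err = estimate - truth
    return {
        "parameter": parameter, "scope": scope, "n": int(truth.size),
        "pearson_r": r, "pearson_p": r_p, "icc": icc_val, "icc_p": icc_p,
        "bias": float(err.mean()), "rmse": float(np.sqrt((err**2).mean())),
    }


@dataclass
class RecoveryReport:
    """Recovery table + provenance, serializable as CSV + JSON."""

    table: pd.DataFrame
    seed: int
    noise_sigma: float
    dictionary_hashes: dict[str, str] = field(default_factory=dict)
    icc_variant: str = ICC_VARIANT

    def save(self, directory) -> None:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "recovery.csv", index=False)
        meta = {"seed": self.seed, "noise_sigma": self.noise_sigma,
                "dictionary_hashes": self.dictionary_hashes,
                "icc_variant": self.icc_variant,
                "table": self.table.to_dict(orient="records")}
        (directory / "recovery.json").write_text(json.dumps(meta, indent=2))

    def value(self, parameter: str, scope: str, column: str) -> float:
        sel = self.table[(self.table.parameter == parameter)
                         & (self.table.scope == scope)]
        if sel.empty:
            raise KeyError((parameter, scope))
        return float(sel.iloc[0][column])


def phantom_recovery_report(quant, truth, seed: int = 0,
                            noise_sigma: float = 0.01,
                            dictionary_hashes: dict | None = None) -> RecoveryReport:
    """Full recovery report for a quantified phantom (vial-mean statistics)."""
    from .pipeline import evaluate_recovery

    table = evaluate_recovery(quant, truth)
    return RecoveryReport(table=table, seed=seed, noise_sigma=noise_sigma,
                          dictionary_hashes=dictionary_hashes or {})
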