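"""Group summaries and the two-group comparison plan.

Measurements are pooled by experimental condition (CT vs HA), timepoint
(24 vs 48 h) and dermis layer (papillary vs reticular) and reported as
mean +/- SEM. Pairwise group comparisons use the two-sided Mann-Whitney
U test for every variable except D-band periodicity, which uses the
two-sample t-test; significance is declared at p < 0.05 with no
multiple-testing correction. "Paired comparisons" here means pairwise
comparisons of independent groups — there is no pairing key between
tissue measurements — so independent-samples tests are used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_CUTOFF = 8  # exact Mann-Whitney enumeration when min(n) <= 8, no ties

VARIABLES = (
    "amorphous_pct",
    "bundle_thickness",
    "linearity_index",
    "fibril_size",
    "interfibrillar_distance",
    "d_band_length",
)
UNITS = {
    "amorphous_pct": "%",
    "bundle_thickness": "nm",
    "linearity_index": "ratio",
    "fibril_size": "nm",
    "interfibrillar_distance": "nm",
    "d_band_length": "nm",
}
#: variable -> test name; D-band periodicity is the t-test variable
TEST_FOR_VARIABLE = {v: "mann_whitney" for v in VARIABLES}
TEST_FOR_VARIABLE["d_band_length"] = "t_test"


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    test: str  # mann_whitney | t_test
    statistic: float
    p_value: float
    significant: bool
    method_note: str  # exact | normal_approx | student | welch | degenerate
    variable: str = ""
    contrast: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def summarize(values) -> GroupSummary:
    """Mean and standard error (sd with n-1 denominator over sqrt(n))."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2 to summarize a group")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite measurement values")
    return GroupSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sem=float(v.std(ddof=1) / np.sqrt(v.size)),
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate((a, b))
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a, b, mode: str = "auto", group_a: str = "A", group_b: str = "B"
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` uses the exact null distribution (enumeration over
    all labelings) when min(n1, n2) <= 8 and the pooled sample is
    tie-free, else the normal approximation with tie and continuity
    corrections. The returned statistic is U for sample `a`;
    U_a + U_b = n1*n2 always.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    exact = mode == "exact" or (
        mode == "auto" and min(a.size, b.size) <= EXACT_CUTOFF and not _has_ties(a, b)
    )
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=p,
        significant=p < ALPHA,
        method_note="exact" if exact else "normal_approx",
    )


def t_test(
    a, b, variant: str = "student", group_a: str = "A", group_b: str = "B"
) -> ComparisonResult:
    """Two-sample two-sided t-test (equal-variance Student by default,
    Welch available). Zero-variance degeneracies resolve by convention:
    identical means -> p = 1; distinct means -> p = 0, flagged."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        same = a.mean() == b.mean()
        return ComparisonResult(
            group_a=group_a,
            group_b=group_b,
            test="t_test",
            statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            significant=not same,
            method_note="degenerate",
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    p = float(res.pvalue)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        test="t_test",
        statistic=float(res.statistic),
        p_value=p,
        significant=p < ALPHA,
        method_note=variant,
    )


# ---------------------------------------------------------------------------
# the comparison plan
# ---------------------------------------------------------------------------

CONDITIONS = ("CT", "HA")
TIMEPOINTS = (24, 48)
LAYERS = ("papillary", "reticular")


def _glabel(cond: str, tp: int, layer: str) -> str:
    return f"{cond}-{tp}h-{layer}"


def comparison_plan() -> list[tuple[str, tuple, tuple]]:
    """The fixed list of (contrast, group_a, group_b) per variable:
    CT vs HA within layer x timepoint; 24 vs 48 h within condition x
    layer; papillary vs reticular within condition x timepoint."""
    plan = []
    for layer in LAYERS:
        for tp in TIMEPOINTS:
            plan.append(
                ("treatment", ("CT", tp, layer), ("HA", tp, layer))
            )
    for cond in CONDITIONS:
        for layer in LAYERS:
            plan.append(("time", (cond, 24, layer), (cond, 48, layer)))
    for cond in CONDITIONS:
        for tp in TIMEPOINTS:
            plan.append(
                ("layer", (cond, tp, "papillary"), (cond, tp, "reticular"))
            )
    return plan


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per variable x group summary table (n, mean, sem)."""
    rows = []
    for (var, cond, tp, layer), sub in table.groupby(
        ["variable", "condition", "timepoint", "layer"], sort=True
    ):
        if len(sub) < 2:
            logger.warning("group %s/%s too small to summarize", var, (cond, tp, layer))
            continue
        s = summarize(sub["value"].to_numpy())
        rows.append(
            {
                "variable": var,
                "condition": cond,
                "timepoint": int(tp),
                "layer": layer,
                "group": _glabel(cond, int(tp), layer),
                "n": s.n,
                "mean": s.mean,
                "sem": s.sem,
            }
        )
    return pd.DataFrame(rows)


def run_comparison_plan(table: pd.DataFrame) -> list[ComparisonResult]:
    """Run every planned comparison for every variable in the table.

    `table` is the long-format measurement table with columns
    (variable, value, condition, timepoint, layer). D-band length uses
    the t-test, all other variables the Mann-Whitney U test. Missing
    groups skip their comparisons with a log message.
    """
    required = {"variable", "value", "condition", "timepoint", "layer"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    results: list[ComparisonResult] = []
    for var in [v for v in VARIABLES if v in set(table["variable"])]:
        sub = table[table["variable"] == var]
        groups = {
            (c, int(t), l): g["value"].to_numpy()
            for (c, t, l), g in sub.groupby(["condition", "timepoint", "layer"])
        }
        test = TEST_FOR_VARIABLE[var]
        for contrast, ga, gb in comparison_plan():
            if ga not in groups or gb not in groups:
                logger.warning("skipping %s %s vs %s: missing group", var, ga, gb)
                continue
            la, lb = _glabel(*ga), _glabel(*gb)
            if test == "t_test":
                res = t_test(groups[ga], groups[gb], group_a=la, group_b=lb)
            else:
                res = mann_whitney_u(groups[ga], groups[gb], group_a=la, group_b=lb)
            results.append(
                ComparisonResult(
                    **{
                        **res.__dict__,
                        "variable": var,
                        "contrast": contrast,
                    }
                )
            )
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# null calibration at the measurement-table level
# ---------------------------------------------------------------------------

def null_rejection_rate(
    n_replicates: int,
    n_per_group: int = 20,
    test: str = "mann_whitney",
    seed: int = 0,
) -> float:
    """Empirical type-I error of the comparison plan under the null.

    Each replicate draws every group's measurements i.i.d. from the same
    right-skewed (lognormal) population — no group differences — runs
    the full comparison plan for one variable using `test`, and counts
    significant outcomes. Returns rejections / comparisons across all
    replicates.
    """
    rng = np.random.default_rng(seed)
    var = "d_band_length" if test == "t_test" else "linearity_index"
    n_sig = 0
    n_tot = 0
    for _ in range(n_replicates):
        rows = []
        for cond in CONDITIONS:
            for tp in TIMEPOINTS:
                for layer in LAYERS:
                    vals = rng.lognormal(0.0, 0.4, n_per_group)
                    rows += [
                        {
                            "variable": var,
                            "value": v,
                            "condition": cond,
                            "timepoint": tp,
                            "layer": layer,
                        }
                        for v in vals
                    ]
        results = run_comparison_plan(pd.DataFrame(rows))
        n_sig += sum(r.significant for r in results)
        n_tot += len(results)
    return n_sig / n_tot
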