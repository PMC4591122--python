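"""Annotation-quality evaluation on experimental expression data.

Two complementary measures compare an annotation against a reference
annotation (e.g. a genome-only re-annotation with quality ratings):

* probes are grouped into five disjoint categories — good by both tools
  ("Both"), by neither ("None"), by only one ("InRA" / "InRM"), or flagged
  as repeat-region by the reference tool ("InRepeat") — and the coefficient
  of variation of probe intensities is compared between categories with
  two-sided Wilcoxon rank-sum tests, subsampling the larger reference group
  to match sizes;
* per tool, a 2x2 contingency table of expression status (detection
  p-value below threshold in at least half the samples) against annotation
  quality yields an odds ratio with a Woolf (log-normal) confidence
  interval — a well-annotated probe should be more likely to be expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalConfig",
    "ContingencyTable",
    "CATEGORIES",
    "expression_status",
    "categorize",
    "cv",
    "wilcoxon_matched",
    "odds_ratio",
    "read_matrix",
    "read_quality_table",
    "compare_annotations",
]

CATEGORIES = ("Both", "None", "InRA", "InRM", "InRepeat")


@dataclass
class EvalConfig:
    """Evaluation parameters.

    detection_p
        Per-sample detection p-value threshold (strict ``<``; default 0.01).
    detection_fraction
        Minimum fraction of samples that must pass for a probe to be called
        expressed (default 0.5 — e.g. 18 of 36 subjects).
    ci_level
        Confidence level of the odds-ratio interval (default 0.95).
    good_labels
        Quality ratings counted as "good" in a reference annotation table.
    """

    detection_p: float = 0.01
    detection_fraction: float = 0.5
    ci_level: float = 0.95
    good_labels: tuple[str, ...] = ("Perfect", "Good")

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_p < 1.0):
            raise ValueError("detection_p must be in (0, 1)")
        if not (0.0 < self.detection_fraction <= 1.0):
            raise ValueError("detection_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of expression status against annotation quality."""

    a: int  # expressed & good
    b: int  # expressed & bad
    c: int  # not expressed & good
    d: int  # not expressed & bad

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def swap_rows(self) -> "ContingencyTable":
        """Swap the expressed/not-expressed rows (inverts the odds ratio)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)

    def swap_columns(self) -> "ContingencyTable":
        """Swap the good/bad columns (inverts the odds ratio)."""
        return ContingencyTable(self.b, self.a, self.d, self.c)


def expression_status(detection_p: pd.DataFrame, config: EvalConfig | None = None) -> pd.Series:
    """Expressed/not-expressed call per probe from a detection p-value matrix.

    A probe (row) is expressed iff its detection p-value is strictly below
    ``detection_p`` in at least ``ceil(detection_fraction * n_samples)``
    samples.  Returns a boolean Series indexed by probe.
    """
    config = config or EvalConfig()
    if detection_p.size == 0:
        raise ValueError("empty detection p-value matrix")
    values = detection_p.to_numpy(dtype=float)
    if np.nanmin(values) < 0 or np.nanmax(values) > 1:
        raise ValueError("detection p-values must lie in [0, 1]")
    need = math.ceil(config.detection_fraction * detection_p.shape[1])
    n_pass = (values < config.detection_p).sum(axis=1)
    return pd.Series(n_pass >= need, index=detection_p.index, name="expressed")


def categorize(
    good_ra: Iterable[str],
    good_rm: Iterable[str],
    repeat_rm: Iterable[str],
    universe: Iterable[str],
) -> pd.Series:
    """Assign each probe of *universe* to one of the five categories.

    Repeat-flagged probes are peeled off first (the categories must be
    disjoint); the remainder splits by which tool rated the probe good.
    """
    good_ra, good_rm, repeat_rm = set(good_ra), set(good_rm), set(repeat_rm)
    out = {}
    for pid in universe:
        if pid in repeat_rm:
            cat = "InRepeat"
        elif pid in good_ra and pid in good_rm:
            cat = "Both"
        elif pid in good_ra:
            cat = "InRA"
        elif pid in good_rm:
            cat = "InRM"
        else:
            cat = "None"
        out[pid] = cat
    return pd.Series(out, name="category")


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean.

    Undefined (NaN) for zero mean or fewer than two observations.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def wilcoxon_matched(
    group_x: Sequence[float],
    group_ref: Sequence[float],
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with size-matched subsampling.

    When the reference group is larger, a uniform random subsample of it
    (without replacement, size ``len(group_x)``, driven by *seed*) is drawn
    before testing, so group sizes are matched.  Returns ``(W, p)`` where W
    is the rank sum of *group_x* (midranks for ties).  The p-value is exact
    when both groups have <= 25 observations and the pooled data is
    tie-free, otherwise a normal approximation with continuity and tie
    correction is used.
    """
    x = np.asarray(group_x, dtype=float)
    ref = np.asarray(group_ref, dtype=float)
    if x.size == 0 or ref.size == 0:
        raise ValueError("both groups must be non-empty")
    if ref.size > x.size:
        rng = np.random.default_rng(seed)
        ref = rng.choice(ref, size=x.size, replace=False)
    pooled = np.concatenate([x, ref])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 25 and ref.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, ref, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


def odds_ratio(
    table: ContingencyTable | tuple[int, int, int, int],
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Odds ratio of a 2x2 table with a Woolf log-normal confidence interval.

    ``OR = (a*d) / (b*c)``; the CI is ``exp(ln OR +/- z * sqrt(1/a + 1/b +
    1/c + 1/d))``.  A table containing zero cells gets the Haldane-Anscombe
    +0.5 correction (all cells) with a warning; an all-zero table is an
    error.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise ValueError("all-zero contingency table")
    if min(a, b, c, d) == 0:
        import warnings

        warnings.warn(
            "zero cell in contingency table; applying Haldane-Anscombe +0.5",
            stacklevel=2,
        )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


# ---------------------------------------------------------------------------
# file input and the full comparison
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Probes-by-samples TSV matrix (first column = probe id, header row)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_quality_table(
    path,
    probe_col: str = "probe_id",
    quality_col: str = "quality",
    repeat_col: str = "repeat",
    config: EvalConfig | None = None,
) -> tuple[set[str], set[str]]:
    """Read a reference annotation table; returns (good probes, repeat probes).

    "Good" means the quality rating is one of ``config.good_labels``; the
    repeat column is truthy ("1"/"True"/"yes") for repeat-flagged probes.
    """
    config = config or EvalConfig()
    df = pd.read_csv(path, sep="\t", dtype=str)
    good = set(df.loc[df[quality_col].isin(config.good_labels), probe_col])
    truthy = {"1", "true", "yes", "y"}
    rep = set(
        df.loc[
            df[repeat_col].fillna("").str.strip().str.lower().isin(truthy), probe_col
        ]
    )
    return good, rep


def contingency_from_sets(
    expressed: pd.Series, good: set[str]
) -> ContingencyTable:
    """Build the expression-by-quality table for one tool's good-probe set."""
    a = b = c = d = 0
    for pid, is_expr in expressed.items():
        is_good = pid in good
        if is_expr and is_good:
            a += 1
        elif is_expr:
            b += 1
        elif is_good:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compare_annotations(
    expression: pd.DataFrame,
    detection_p: pd.DataFrame,
    good_ra: set[str],
    good_rm: set[str],
    repeat_rm: set[str],
    config: EvalConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Full head-to-head evaluation of two annotations on one dataset.

    Returns category sizes and mean/SD CV per category over expressed
    probes, Wilcoxon comparisons of InRA/InRM/InRepeat against both
    reference categories, and the two contingency tables with odds ratios.
    All randomness (subsampling) derives from *seed*.
    """
    config = config or EvalConfig()
    expressed = expression_status(detection_p, config)
    categories = categorize(
        good_ra, good_rm, repeat_rm, universe=list(expression.index)
    )
    cvs = expression.apply(lambda row: cv(row.to_numpy()), axis=1)

    expr_ids = [pid for pid in expression.index if expressed.get(pid, False)]
    cat_cvs = {
        cat: cvs.loc[[p for p in expr_ids if categories[p] == cat]].dropna()
        for cat in CATEGORIES
    }
    tests = {}
    for cat in ("InRA", "InRM", "InRepeat"):
        for ref_cat in ("Both", "None"):
            key = f"{cat}_vs_{ref_cat}"
            x, ref = cat_cvs[cat], cat_cvs[ref_cat]
            if len(x) == 0 or len(ref) == 0:
                tests[key] = {"W": None, "p": None}
                continue
            w, p = wilcoxon_matched(x.to_numpy(), ref.to_numpy(), seed=seed)
            tests[key] = {"W": w, "p": p}

    out = {
        "category_sizes": {cat: int(len(cat_cvs[cat])) for cat in CATEGORIES},
        "category_cv": {
            cat: {
                "mean": float(cat_cvs[cat].mean()) if len(cat_cvs[cat]) else None,
                "sd": float(cat_cvs[cat].std(ddof=1)) if len(cat_cvs[cat]) > 1 else None,
            }
            for cat in CATEGORIES
        },
        "wilcoxon": tests,
        "odds_ratio": {},
    }
    for name, good in (("RA", good_ra), ("RM", good_rm)):
        t = contingency_from_sets(expressed, good)
        or_, lo, hi = odds_ratio(t, config.ci_level)
        out["odds_ratio"][name] = {
            "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
            "or": or_,
            "ci_low": lo,
            "ci_high": hi,
        }
    return out
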