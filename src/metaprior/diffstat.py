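"""Per-study two-group differential statistics.

One record per retained feature: a raw two-sided p-value (no multiplicity
correction at this screening stage), the ERneg/ERpos fold change on the
linear scale, and a direction. Metabolite and protein data are tested with
the Mann-Whitney U test; transcript data with a Welch t-test on log2
abundances (a stand-in for moderated microarray statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import ERNEG, ERPOS, OmicsMatrix

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration up to this pooled size


@dataclass
class DiffTable:
    """Differential-test results for one study and platform.

    ``table`` has one row per retained feature with columns
    feature, raw_p, fold_change, direction, test_name, n_neg, n_pos;
    ``skipped`` records features that could not be tested, with reasons.
    """

    study_id: str
    platform: str
    table: pd.DataFrame
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature", "reason"]))


@dataclass(frozen=True)
class SummaryCounts:
    total: int
    altered: int
    down: int
    up: int


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration of the U null distribution when the pooled size is
    <= 12 and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observed values")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def welch_t_p(x, y) -> float:
    """Two-sided Welch t-test p-value (Satterthwaite degrees of freedom)."""
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observed values")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def fold_change(x, y, geometric: bool = False) -> tuple[float, str]:
    """Fold change mean(ERneg)/mean(ERpos) with its direction.

    Arithmetic group means on the linear scale by default; ``geometric``
    switches to geometric means. Direction refers to the ERneg group:
    up for ratio > 1, down for ratio < 1, unchanged at exactly 1.
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    if geometric:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("geometric mean requires positive values")
        mx, my = np.exp(np.mean(np.log(x))), np.exp(np.mean(np.log(y)))
    else:
        mx, my = float(np.mean(x)), float(np.mean(y))
    if mx <= 0 or my <= 0:
        raise ValueError("non-positive group mean")
    ratio = mx / my
    direction = "up" if ratio > 1 else ("down" if ratio < 1 else "unchanged")
    return float(ratio), direction


def prevalence_filter(matrix: OmicsMatrix, min_per_group: int = 6) -> OmicsMatrix:
    """Keep features observed in >= min_per_group samples of EITHER group.

    The either-group rule: a feature found in six ERpos samples but no ERneg
    sample is retained.
    """
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    neg = matrix.group_columns(ERNEG)
    pos = matrix.group_columns(ERPOS)
    n_neg = matrix.values[neg].notna().sum(axis=1)
    n_pos = matrix.values[pos].notna().sum(axis=1)
    keep = (n_neg >= min_per_group) | (n_pos >= min_per_group)
    return OmicsMatrix(matrix.values.loc[keep], matrix.labels,
                       matrix.platform, matrix.study_id)


_TESTS = {"mwu": mann_whitney_p, "welch": welch_t_p}


def run_differential(matrix: OmicsMatrix, test: str = "auto",
                     geometric_fold: bool = False) -> DiffTable:
    """Test every feature of a labeled matrix; one DiffRecord row each.

    ``test``: "mwu", "welch", or "auto" (Welch on log2 abundances for
    transcripts, Mann-Whitney otherwise). Untestable features (fewer than two
    observations in a group, non-positive mean) are skipped with a logged
    reason, never raised.
    """
    if test == "auto":
        test = "welch" if matrix.platform == "transcript" else "mwu"
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    test_fn = _TESTS[test]

    neg_cols = matrix.group_columns(ERNEG)
    pos_cols = matrix.group_columns(ERPOS)
    rows, skipped = [], []
    for feat, series in matrix.values.iterrows():
        x = _clean(series[neg_cols].to_numpy())
        y = _clean(series[pos_cols].to_numpy())
        if len(x) < 2 or len(y) < 2:
            skipped.append((feat, "fewer than 2 observations in a group"))
            continue
        try:
            ratio, direction = fold_change(x, y, geometric=geometric_fold)
        except ValueError as exc:
            skipped.append((feat, str(exc)))
            continue
        if test == "welch":
            p = test_fn(np.log2(x), np.log2(y))
        else:
            p = test_fn(x, y)
        rows.append((feat, p, ratio, direction, test, len(x), len(y)))

    for feat, reason in skipped:
        logger.warning("skipping %s: %s", feat, reason)
    table = pd.DataFrame(rows, columns=["feature", "raw_p", "fold_change",
                                        "direction", "test_name",
                                        "n_neg", "n_pos"])
    return DiffTable(matrix.study_id, matrix.platform, table,
                     pd.DataFrame(skipped, columns=["feature", "reason"]))


def summarize_counts(table: DiffTable, alpha: float = 0.05) -> SummaryCounts:
    """Total / altered / down / up feature counts at significance alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    t = table.table
    sig = t["raw_p"] < alpha
    down = int((sig & (t["fold_change"] < 1)).sum())
    up = int((sig & (t["fold_change"] > 1)).sum())
    return SummaryCounts(total=len(t), altered=down + up, down=down, up=up)


def write_diff_tsv(diff: DiffTable, path) -> None:
    diff.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_diff_tsv(path, study_id: str = "", platform: str = "transcript"
                  ) -> DiffTable:
    """Read a differential table TSV (also accepts pre-computed external
    exports with at least columns feature, p/raw_p and fold/fold_change)."""
    t = pd.read_csv(path, sep="\t")
    t = t.rename(columns={"p": "raw_p", "fold": "fold_change"})
    if "direction" not in t.columns:
        t["direction"] = np.where(t["fold_change"] > 1, "up",
                                  np.where(t["fold_change"] < 1, "down",
                                           "unchanged"))
    for col, default in (("test_name", "external"), ("n_neg", -1), ("n_pos", -1)):
        if col not in t.columns:
            t[col] = default
    return DiffTable(study_id, platform,
                     t[["feature", "raw_p", "fold_change", "direction",
                        "test_name", "n_neg", "n_pos"]])
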