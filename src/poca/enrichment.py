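"""Label-free differential enrichment and annotation-ROC benchmarking.

The chain mirrors the standard LFQ proteomics workflow: log2 transform and
per-sample median centering of raw intensities, downshifted-normal
("Perseus-type") imputation of missing values, a per-protein Welch t-test
between the two bait groups, Benjamini–Hochberg FDR adjustment, and hit
calling at a strict >1 log2 fold change and adjusted p < 0.05.  Hit lists
are benchmarked against compartment annotations by treating the log2 fold
change as a continuous classifier score: ROC curve, trapezoid AUC, and
the Youden-optimal threshold (max TPR − FPR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QuantMatrix", "RocResult",
    "log_transform_and_normalize", "impute_perseus", "differential_test",
    "bh_adjust", "call_hits", "annotation_roc", "run_differential_enrichment",
]


@dataclass
class QuantMatrix:
    """A protein x sample intensity matrix with two-group sample labels.

    ``intensities`` is indexed by protein ID with sample columns;
    ``groups`` maps sample ID to its group label.  ``is_log2`` records
    whether the values have been log2 transformed.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    is_log2: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in self.intensities.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.groups = self.groups.loc[self.intensities.columns]
        counts = self.groups.value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly 2 groups, got {list(counts.index)}")
        if (counts < 2).any():
            raise ValueError("each group needs at least 2 samples for testing")

    def group_columns(self) -> dict:
        return {g: list(self.groups.index[self.groups == g])
                for g in self.groups.unique()}


@dataclass
class RocResult:
    """ROC of log2FC against a compartment-annotation positive set."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden: np.ndarray
    youden_optimal_threshold: float
    youden_max: float
    n_positive: int
    n_negative: int


def log_transform_and_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Log2 transform and center each sample's median on the global median.

    Zeros and NaNs are treated as missing (LFQ convention).  A sample
    with no observed value is an error.
    """
    if matrix.is_log2:
        raise ValueError("matrix is already log2 transformed")
    if (matrix.intensities < 0).any().any():
        raise ValueError("raw intensities must be non-negative")
    raw = matrix.intensities.where(matrix.intensities > 0)
    empty = [s for s in raw.columns if raw[s].notna().sum() == 0]
    if empty:
        raise ValueError(f"samples with zero observed values: {empty}")
    log2 = np.log2(raw)
    global_median = float(np.nanmedian(log2.to_numpy()))
    centered = log2 - log2.median(axis=0) + global_median
    return QuantMatrix(intensities=centered, groups=matrix.groups, is_log2=True)


def impute_perseus(matrix: QuantMatrix, downshift: float = 1.8,
                   width: float = 0.3, seed: int = 0) -> QuantMatrix:
    """Downshifted-normal imputation of missing log2 values, per sample.

    Each missing entry of sample ``s`` is drawn from
    ``Normal(mean_s - downshift * sd_s, (width * sd_s)**2)`` where
    ``mean_s``/``sd_s`` are that sample's observed log2 statistics — the
    canonical model of values missing because they fall below the
    detection limit.  Observed values are untouched.
    """
    if not matrix.is_log2:
        raise ValueError("impute_perseus expects a log2-transformed matrix")
    rng = np.random.default_rng(seed)
    out = matrix.intensities.copy()
    for s in out.columns:
        col = out[s]
        observed = col.dropna()
        if len(observed) < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 observed values")
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        mu = observed.mean()
        sd = observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        out.loc[col.isna(), s] = draws
    return QuantMatrix(intensities=out, groups=matrix.groups, is_log2=True)


def differential_test(matrix: QuantMatrix, group_a: str | None = None,
                      group_b: str | None = None) -> pd.DataFrame:
    """Per-protein log2FC and two-sided Welch t-test p-value.

    ``log2fc = mean(group_a) - mean(group_b)``.  Group order defaults to
    the order labels first appear in the sample annotation.  Proteins
    with zero variance in both groups get p = 1 when the means agree and
    are flagged in ``test_failed`` (p = NaN) otherwise.
    """
    if not matrix.is_log2:
        raise ValueError("differential_test expects log2 intensities")
    cols = matrix.group_columns()
    if group_a is None or group_b is None:
        group_a, group_b = list(cols)
    a = matrix.intensities[cols[group_a]].to_numpy()
    b = matrix.intensities[cols[group_b]].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    # zero-variance rows are handled explicitly below; silence scipy's
    # constant-input/precision warnings for them
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    failed = zero_var & (log2fc != 0)
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    p = np.where(failed, np.nan, p)
    return pd.DataFrame({
        "log2fc": log2fc,
        "p_value": p,
        "test_failed": failed,
    }, index=matrix.intensities.index.rename("protein_id"))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    NaN entries (failed tests) are excluded from the family and returned
    as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    if valid.sum():
        adj[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return adj


def call_hits(table: pd.DataFrame, fc_threshold: float = 1.0,
              q_threshold: float = 0.05, two_sided: bool = False) -> pd.DataFrame:
    """Flag hits: log2FC strictly above threshold AND adj_p strictly below.

    The default directional rule (``log2fc > fc_threshold``) flags
    proteins enriched toward the first group; ``two_sided=True`` uses
    ``|log2fc| > fc_threshold`` for symmetric bait-vs-bait comparisons.
    Both inequalities are strict (greater than 2-fold, FDR < 0.05).
    """
    if "adj_p" not in table.columns:
        raise ValueError("call_hits requires an adj_p column; run bh_adjust first")
    out = table.copy()
    fc = out["log2fc"].abs() if two_sided else out["log2fc"]
    out["is_hit"] = (fc > fc_threshold) & (out["adj_p"] < q_threshold)
    out.loc[out["adj_p"].isna(), "is_hit"] = False
    return out


def annotation_roc(table: pd.DataFrame, positives: set) -> RocResult:
    """ROC of log2FC as a classifier of compartment annotation.

    Detected proteins annotated to the compartment are the positive
    class; all remaining detected proteins are negatives.  AUC is the
    trapezoid area of the tie-aware ROC curve, and the optimal log2FC
    cutoff maximizes the Youden index J = TPR − FPR.
    """
    positives = set(positives)
    y = table.index.isin(positives).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need both classes among detected proteins "
            f"(positives={n_pos}, negatives={n_neg})")
    score = table["log2fc"].to_numpy()
    fpr, tpr, thresholds = skmetrics.roc_curve(y, score)
    auc = float(skmetrics.auc(fpr, tpr))
    youden = tpr - fpr
    best = int(np.argmax(youden))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     youden=youden,
                     youden_optimal_threshold=float(thresholds[best]),
                     youden_max=float(youden[best]),
                     n_positive=n_pos, n_negative=n_neg)


def run_differential_enrichment(raw: pd.DataFrame, groups: pd.Series,
                                group_a: str | None = None,
                                group_b: str | None = None,
                                fc_threshold: float = 1.0,
                                q_threshold: float = 0.05,
                                two_sided: bool = False,
                                downshift: float = 1.8, width: float = 0.3,
                                seed: int = 0) -> pd.DataFrame:
    """Full chain: normalize → impute → Welch test → BH → hit calling."""
    qm = QuantMatrix(intensities=raw, groups=groups)
    qm = log_transform_and_normalize(qm)
    qm = impute_perseus(qm, downshift=downshift, width=width, seed=seed)
    table = differential_test(qm, group_a=group_a, group_b=group_b)
    table["adj_p"] = bh_adjust(table["p_value"])
    return call_hits(table, fc_threshold=fc_threshold,
                     q_threshold=q_threshold, two_sided=two_sided)
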