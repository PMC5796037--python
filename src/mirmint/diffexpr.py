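"""Per-cohort differential expression.

The calling rule mirrors the classic microarray screen: a two-sample
Student's t-test per feature (pooled variance by default, Welch behind a
flag) combined with a log2 fold-change cutoff.  mRNAs require
|log2FC| > 1, miRNAs only a nonzero log2FC (significance-driven calling),
and the single-sample overexpression contrast uses |log2FC| >= log2(1.5)
= 0.5849 with inclusive bounds.  Raw p-values are compared with alpha;
Benjamini-Hochberg correction is available as an opt-in flag but is off
by default, matching the screen this module reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, FormatError
from .io_formats import ExpressionDataset

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "none")

#: log2(1.5) to the printed precision used throughout the overexpression filter.
LOG2_1P5 = 0.5849


@dataclass(frozen=True)
class DEThresholds:
    """Significance and fold-change cutoffs for the three feature classes."""

    alpha: float = 0.05
    lfc_mrna: float = 1.0
    lfc_mirna: float = 0.0
    lfc_overexpression: float = LOG2_1P5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        for name in ("lfc_mrna", "lfc_mirna", "lfc_overexpression"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def lfc_for(self, feature_class: str) -> float:
        if feature_class == "mrna":
            return self.lfc_mrna
        if feature_class == "mirna":
            return self.lfc_mirna
        raise ConfigError(f"unknown feature class {feature_class!r}")


@dataclass(frozen=True)
class DERecord:
    """One feature's test outcome in one cohort."""

    feature_id: str
    log2fc: float
    t_stat: float
    df: float
    p_value: float
    direction: str
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass
class DatasetDEResult:
    """All per-feature records of one cohort, plus the thresholds applied."""

    dataset_id: str
    feature_class: str
    thresholds: DEThresholds
    table: pd.DataFrame  # index feature_id; log2fc, t, df, p, direction

    def features(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["direction"] == direction])

    def direction_of(self, feature_id: str) -> str:
        return str(self.table.at[feature_id, "direction"])

    @property
    def n_de(self) -> int:
        return int((self.table["direction"] != "none").sum())

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature_id\tlog2fc\tt\tdf\tp\tdirection\n")
            for fid, row in self.table.iterrows():
                fh.write(
                    f"{fid}\t{row['log2fc']:.6f}\t{row['t']:.6f}\t"
                    f"{row['df']:.6f}\t{row['p']:.6g}\t{row['direction']}\n"
                )

    @classmethod
    def from_tsv(cls, path, dataset_id: str, feature_class: str = "mrna",
                 thresholds: DEThresholds | None = None) -> "DatasetDEResult":
        table = pd.read_csv(path, sep="\t", index_col=0)
        if table.index.duplicated().any():
            raise FormatError(f"{path}: duplicate feature id in DE table")
        return cls(dataset_id, feature_class, thresholds or DEThresholds(), table)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def log2_fold_change(tumor_values, normal_values) -> float:
    """mean(tumor) - mean(normal); inputs already in log2 space."""
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ConfigError("log2_fold_change: empty group")
    return float(t.mean() - n.mean())


def student_t_test(a, b, equal_variance: bool = True):
    """Two-sample t-test returning ``(t, df, two_sided_p)``.

    Degenerate conventions: both groups constant with equal means gives
    (0, df, 1); constant groups with unequal means gives the p -> 0 limit
    with an infinite t of the sign of the mean difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("student_t_test needs >= 2 samples per group")
    df_pooled = a.size + b.size - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(df_pooled), 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * np.inf, float(df_pooled), 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort-level calling
# ---------------------------------------------------------------------------

def call_de(
    dataset: ExpressionDataset,
    thresholds: DEThresholds | None = None,
    feature_class: str = "mrna",
    equal_variance: bool = True,
    bh: bool = False,
) -> DatasetDEResult:
    """Call per-feature differential expression for one cohort.

    A direction is assigned iff p < alpha AND |log2FC| strictly exceeds
    the class threshold.  ``bh=True`` replaces raw p-values with
    Benjamini-Hochberg adjusted ones before thresholding.
    """
    thresholds = thresholds or DEThresholds()
    dataset.require_de_usable()

    tumor = dataset.group_values("tumor").to_numpy(dtype=float)
    normal = dataset.group_values("normal").to_numpy(dtype=float)
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(tumor, normal, axis=1, equal_var=equal_variance)
    t = np.array(res.statistic, dtype=float, copy=True)
    p = np.array(res.pvalue, dtype=float, copy=True)
    df = np.array(np.broadcast_to(res.df, p.shape), dtype=float, copy=True)

    # zero within-group variance rows: scipy yields nan
    var0 = (tumor.var(axis=1, ddof=1) == 0.0) & (normal.var(axis=1, ddof=1) == 0.0)
    degenerate = var0 & (lfc != 0.0)
    t[var0 & (lfc == 0.0)] = 0.0
    p[var0 & (lfc == 0.0)] = 1.0
    t[degenerate] = np.sign(lfc[degenerate]) * np.inf
    p[degenerate] = 0.0
    df[var0] = tumor.shape[1] + normal.shape[1] - 2
    if degenerate.any():
        logger.warning(
            "%s: %d feature(s) with zero within-group variance and unequal "
            "means; p treated as the 0-limit", dataset.dataset_id, degenerate.sum()
        )

    p_eff = p
    if bh:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p, method="fdr_bh")[1]

    cut = thresholds.lfc_for(feature_class)
    direction = np.full(len(lfc), "none", dtype=object)
    sig = p_eff < thresholds.alpha
    direction[sig & (lfc > cut)] = "up"
    direction[sig & (lfc < -cut)] = "down"

    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "df": df, "p": p_eff, "direction": direction},
        index=dataset.feature_ids,
    )
    return DatasetDEResult(dataset.dataset_id, feature_class, thresholds, table)


def overexpression_filter(
    table: pd.DataFrame, thresholds: DEThresholds | None = None
) -> tuple[list[str], list[str]]:
    """Split genes of a two-column (mimic, scrambled) log2 table by fold change.

    down = {g : log2(mimic) - log2(scrambled) <= -lfc_overexpression};
    up is symmetric.  Bounds are inclusive: a gene at exactly -0.5849 is
    down-regulated.  No replicate statistics are attempted.
    """
    thresholds = thresholds or DEThresholds()
    for col in ("mimic", "scrambled"):
        if col not in table.columns:
            raise FormatError(f"overexpression table missing column {col!r}")
    lfc = table["mimic"].astype(float) - table["scrambled"].astype(float)
    cut = thresholds.lfc_overexpression
    up = list(lfc.index[lfc >= cut])
    down = list(lfc.index[lfc <= -cut])
    return up, down
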