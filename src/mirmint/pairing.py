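"""Integration of DE consensus, inverse correlation and site prediction.

A miRNA-mRNA pair enters the final table only when (a) the two features
have strictly opposite consensus directions, (b) their expression is
significantly negatively correlated (Pearson) across the matched-sample
cohort, and (c) the mRNA's 3'UTR carries at least one consensus-
predicted site for the miRNA.  Correlation uses tumor samples only by
default: pooling tumor and normal inflates |r| through the group-mean
shift, so the pooled mode is available but opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, UndefinedCorrelationError
from .consensus import ConsensusFeature
from .io_formats import ExpressionDataset
from .target_predict import PredictedSite

logger = logging.getLogger(__name__)


@dataclass
class TargetPair:
    """An integrated miRNA-mRNA pair with its supporting evidence."""

    mirna_id: str
    mirna_direction: str
    mrna_id: str
    mrna_direction: str
    pearson_r: float
    r_pvalue: float
    n_matched_samples: int
    predicted_sites: list[PredictedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if {self.mirna_direction, self.mrna_direction} != {"up", "down"}:
            raise ConfigError("pair directions must be strictly opposite")
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ConfigError("pearson_r outside [-1, 1]")

    @property
    def n_predictors(self) -> int:
        """Predictors passed by the best site (0-3)."""
        if not self.predicted_sites:
            return 0
        return max(len(s.predictors_passed) for s in self.predicted_sites)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigError("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_pairs(
    mirna_consensus: list[ConsensusFeature],
    mrna_consensus: list[ConsensusFeature],
    matched_mirna: ExpressionDataset,
    matched_mrna: ExpressionDataset,
    sites: list[PredictedSite],
    r_threshold: float = 0.0,
    alpha: float = 0.05,
    tumor_only: bool = True,
    bh: bool = False,
) -> list[TargetPair]:
    """Emit every pair satisfying the direction, correlation and site rules.

    The matched cohorts must share one identical ordered sample list.
    ``bh=True`` applies Benjamini-Hochberg across all candidate pairs'
    correlation p-values before the alpha cut (off by default).  Output
    is sorted by (mirna_id, mrna_id).
    """
    if matched_mirna.sample_ids != matched_mrna.sample_ids:
        raise ConfigError("matched cohorts do not share an ordered sample list")

    samples = (
        matched_mirna.samples_in("tumor") if tumor_only else matched_mirna.sample_ids
    )
    site_index: dict[tuple[str, str], list[PredictedSite]] = {}
    for s in sites:
        site_index.setdefault((s.mirna_id, s.mrna_id), []).append(s)

    candidates = []
    for mir in sorted(mirna_consensus, key=lambda f: f.feature_id):
        for gene in sorted(mrna_consensus, key=lambda f: f.feature_id):
            if {mir.direction, gene.direction} != {"up", "down"}:
                continue
            pair_sites = site_index.get((mir.feature_id, gene.feature_id))
            if not pair_sites:
                continue
            if (mir.feature_id not in matched_mirna.values.index
                    or gene.feature_id not in matched_mrna.values.index):
                continue
            x = matched_mirna.values.loc[mir.feature_id, samples]
            y = matched_mrna.values.loc[gene.feature_id, samples]
            try:
                r, p = pearson_r(x, y)
            except UndefinedCorrelationError:
                logger.warning(
                    "pair %s/%s skipped: constant expression vector",
                    mir.feature_id, gene.feature_id,
                )
                continue
            candidates.append((mir, gene, r, p, pair_sites))

    pvals = np.array([c[3] for c in candidates], dtype=float)
    if bh and len(pvals):
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]

    pairs = []
    for (mir, gene, r, _raw_p, pair_sites), p in zip(candidates, pvals):
        if r < r_threshold and p < alpha:
            pairs.append(
                TargetPair(
                    mirna_id=mir.feature_id,
                    mirna_direction=mir.direction,
                    mrna_id=gene.feature_id,
                    mrna_direction=gene.direction,
                    pearson_r=r,
                    r_pvalue=float(p),
                    n_matched_samples=len(samples),
                    predicted_sites=pair_sites,
                )
            )
    pairs.sort(key=lambda p: (p.mirna_id, p.mrna_id))
    return pairs


def summarize_pairs(pairs: list[TargetPair]) -> dict[str, int]:
    """Funnel counts: total pairs, distinct features, both orientations."""
    up_down = sum(1 for p in pairs if p.mirna_direction == "up")
    down_up = sum(1 for p in pairs if p.mirna_direction == "down")
    return {
        "n_pairs": len(pairs),
        "n_mirnas": len({p.mirna_id for p in pairs}),
        "n_mrnas": len({p.mrna_id for p in pairs}),
        "n_up_mirna_down_mrna": up_down,
        "n_down_mirna_up_mrna": down_up,
    }


def pairs_to_tsv(pairs: list[TargetPair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "mirna_id\tmirna_direction\tmrna_id\tmrna_direction\t"
            "pearson_r\tr_pvalue\tn_matched_samples\tn_sites\tn_predictors\n"
        )
        for p in pairs:
            fh.write(
                f"{p.mirna_id}\t{p.mirna_direction}\t{p.mrna_id}\t"
                f"{p.mrna_direction}\t{p.pearson_r:.6f}\t{p.r_pvalue:.6g}\t"
                f"{p.n_matched_samples}\t{len(p.predicted_sites)}\t{p.n_predictors}\n"
            )


def pairs_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
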