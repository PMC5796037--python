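"""Cross-cohort intersection rules.

miRNAs survive if called differentially expressed with the *same*
direction in at least ``min_datasets`` cohorts and never in the opposite
direction; mRNAs survive if the pooled array source and the sequencing
source agree on the direction.  Direction consistency is required:
features with conflicting calls across cohorts are dropped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._errors import ConfigError, FormatError
from .diffexpr import DatasetDEResult
from .io_formats import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusFeature:
    feature_id: str
    direction: str
    supporting_datasets: tuple[str, ...]

    @property
    def n_support(self) -> int:
        return len(self.supporting_datasets)


def _support_by_direction(results: list[DatasetDEResult]):
    """feature -> {direction -> [dataset ids]} over all supplied cohorts."""
    support: dict[str, dict[str, list[str]]] = {}
    for res in results:
        for direction in ("up", "down"):
            for fid in res.features(direction):
                support.setdefault(fid, {}).setdefault(direction, []).append(
                    res.dataset_id
                )
    return support


def consensus_mirna(
    results: list[DatasetDEResult], min_datasets: int = 3
) -> list[ConsensusFeature]:
    """Features DE with one consistent direction in >= ``min_datasets`` cohorts."""
    ids = [r.dataset_id for r in results]
    if len(ids) != len(set(ids)):
        raise ConfigError("duplicate dataset ids in consensus input")
    if len(results) < min_datasets:
        raise ConfigError(
            f"need >= {min_datasets} cohorts, got {len(results)}"
        )
    out: list[ConsensusFeature] = []
    for fid, dirs in sorted(_support_by_direction(results).items()):
        best = max(dirs, key=lambda d: len(dirs[d]))
        if len(dirs[best]) < min_datasets:
            continue
        if len(dirs) > 1:
            logger.warning(
                "consensus: %s has conflicting directions %s; dropped",
                fid, {d: len(v) for d, v in dirs.items()},
            )
            continue
        out.append(ConsensusFeature(fid, best, tuple(sorted(dirs[best]))))
    return out


def consensus_mrna(
    geo_pooled_result: DatasetDEResult, tcga_result: DatasetDEResult
) -> list[ConsensusFeature]:
    """Two-source agreement: same direction in the pooled-array and the
    sequencing cohort."""
    return consensus_mirna([geo_pooled_result, tcga_result], min_datasets=2)


def near_misses(
    results: list[DatasetDEResult], min_datasets: int = 3
) -> list[ConsensusFeature]:
    """Audit sidecar: consistent features supported by exactly
    ``min_datasets - 1`` cohorts."""
    out = []
    for fid, dirs in sorted(_support_by_direction(results).items()):
        if len(dirs) != 1:
            continue
        (direction, datasets), = dirs.items()
        if len(datasets) == min_datasets - 1:
            out.append(ConsensusFeature(fid, direction, tuple(sorted(datasets))))
    return out


def pool_geo_datasets(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Column-concatenate array cohorts on their common feature set.

    Sample ids are prefixed with the cohort of origin (kept in
    ``sample_origin``), so pooling a dataset with itself is well defined
    and simply doubles every group.
    """
    if not datasets:
        raise ConfigError("pool_geo_datasets: no datasets supplied")
    common = list(datasets[0].feature_ids)
    universe = [set(d.feature_ids) for d in datasets]
    common = [f for f in common if all(f in u for u in universe)]
    if not common:
        raise FormatError("pool_geo_datasets: empty feature intersection")
    n_union = len(set().union(*universe))
    if n_union != len(common):
        logger.warning(
            "pool_geo_datasets: inner join kept %d of %d features",
            len(common), n_union,
        )

    blocks, groups, origin = [], [], []
    for k, ds in enumerate(datasets):
        prefix = f"{ds.dataset_id}.{k}:"
        block = ds.values.loc[common].copy()
        block.columns = [prefix + s for s in block.columns]
        blocks.append(block)
        groups.append(pd.Series(
            [ds.groups[s] for s in ds.sample_ids],
            index=block.columns,
        ))
        origin.append(pd.Series(ds.dataset_id, index=block.columns))

    return ExpressionDataset(
        dataset_id="+".join(d.dataset_id for d in datasets),
        platform="array",
        values=pd.concat(blocks, axis=1),
        groups=pd.concat(groups),
        sample_origin=pd.concat(origin),
    )


def consensus_to_tsv(features: list[ConsensusFeature], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tdirection\tn_support\tsupporting_datasets\n")
        for f in features:
            fh.write(
                f"{f.feature_id}\t{f.direction}\t{f.n_support}\t"
                + ",".join(f.supporting_datasets) + "\n"
            )


def consensus_from_tsv(path) -> list[ConsensusFeature]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ConsensusFeature(
            row["feature_id"], row["direction"],
            tuple(row["supporting_datasets"].split(",")),
        )
        for _, row in table.iterrows()
    ]
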