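"""End-to-end orchestration of the multistep analysis.

Stages (plain-file handoff, every intermediate re-parses under
:mod:`mirmint.io_formats`):

1. inputs — synthetic cohorts (generated from ``simulate:`` config) or
   user-supplied expression TSVs / FASTAs / GMT;
2. per-cohort differential expression (miRNA cohorts individually; array
   mRNA cohorts pooled, sequencing cohort separate);
3. cross-cohort consensus (miRNA >= min_datasets; mRNA two-source);
4. consensus target-site prediction for the retained features;
5. inverse-correlation pairing on the matched cohort;
6. overexpression intersection and candidate nomination for one focus
   miRNA;
7. set enrichment of the down-regulated gene list;
8. a manifest JSON recording the funnel counts, the config hash and the
   seed — rerunning with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._errors import ConfigError, MirmintError, StageError
from . import synthetic_cohort as syn
from .candidates import annotate_and_select, intersect_candidates
from .consensus import (
    consensus_mirna,
    consensus_mrna,
    consensus_to_tsv,
    near_misses,
    pool_geo_datasets,
)
from .diffexpr import DEThresholds, call_de, overexpression_filter
from .enrichment import enrich, enrichment_to_tsv
from .io_formats import (
    read_expression_tsv,
    read_fasta,
    read_gmt,
    write_expression_tsv,
)
from .pairing import build_pairs, pairs_to_tsv, summarize_pairs
from .target_predict import (
    MatureMirna,
    PredictorThresholds,
    predict_targets,
    sites_to_tsv,
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    simulate: syn.SimulationConfig | None = None
    inputs: dict | None = None           # alternative: paths to existing files
    de: DEThresholds = field(default_factory=DEThresholds)
    predictors: PredictorThresholds = field(default_factory=PredictorThresholds)
    min_datasets: int = 3
    mode: str = "all3"                   # all3 | union
    r_threshold: float = 0.0
    pairing_alpha: float = 0.05
    tumor_only: bool = True
    bh: bool = False
    focus_mirna: str | None = None
    required_terms: list[str] = field(default_factory=list)
    use_ease: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("all3", "union"):
            raise ConfigError(f"mode must be all3 or union, got {self.mode!r}")
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs either a simulate: or an inputs: section")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("simulate") is not None:
            kwargs["simulate"] = syn.SimulationConfig(**kwargs["simulate"])
        if "de" in kwargs:
            kwargs["de"] = DEThresholds(**kwargs["de"])
        if "predictors" in kwargs:
            kwargs["predictors"] = PredictorThresholds(**kwargs["predictors"])
        return cls(**kwargs)

    def canonical(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _stage(name):
    """Decorator-free stage wrapper: re-raise anything as StageError(name)."""
    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            # input/config errors keep their own exit-code class;
            # anything unexpected becomes a stage failure naming the stage
            if exc is not None and not isinstance(exc, MirmintError):
                raise StageError(f"stage {self.label!r} failed: {exc}") from exc
            return False

    return _Ctx(name)


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Return (mirna_datasets, mrna_datasets, matched pair, utrs, mirna
    sequences, overexpression table, gene sets, truth-or-None)."""
    import pandas as pd

    if config.simulate is not None:
        cfg = config.simulate
        mirna_ds, mrna_ds, matched, truth = syn.simulate_cohorts(cfg)
        utrs = syn.simulate_utrs(cfg, truth)
        mirseqs = truth.mirna_sequences
        focus = config.focus_mirna
        if focus is None and truth.planted_pairs:
            focus = truth.planted_pairs[0][0]
        oe = (
            syn.simulate_overexpression(truth, focus, cfg)
            if focus is not None
            else None
        )
        gene_sets = syn.simulate_gene_sets(cfg, truth, focus_mirna=focus)
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)
        for ds in mirna_ds + mrna_ds:
            write_expression_tsv(ds, inputs_dir / f"{ds.dataset_id}.tsv")
        truth.to_json(inputs_dir / "truth.json")
        return mirna_ds, mrna_ds, matched, utrs, mirseqs, oe, gene_sets, truth, focus

    paths = config.inputs or {}
    for key in ("mirna_datasets", "mrna_datasets", "utrs", "mirnas"):
        if key not in paths:
            raise ConfigError(f"inputs: missing {key!r}")
    for key in ("utrs", "mirnas", "overexpression", "gene_sets", "truth"):
        if key in paths and not Path(paths[key]).exists():
            raise ConfigError(f"input file not found: {paths[key]}")
    for key in ("mirna_datasets", "mrna_datasets"):
        for p in paths[key]:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    def load_list(key, platform_last="rnaseq"):
        out = []
        items = paths[key]
        for i, p in enumerate(items):
            platform = platform_last if i == len(items) - 1 else "array"
            out.append(
                read_expression_tsv(p, dataset_id=Path(p).stem, platform=platform)
            )
        return out

    mirna_ds = load_list("mirna_datasets")
    mrna_ds = load_list("mrna_datasets")
    matched = (mirna_ds[-1], mrna_ds[-1])
    utrs = read_fasta(paths["utrs"])
    mirseqs = read_fasta(paths["mirnas"])
    oe = None
    if "overexpression" in paths:
        oe = pd.read_csv(paths["overexpression"], sep="\t", index_col=0)
    gene_sets = read_gmt(paths["gene_sets"]) if "gene_sets" in paths else None
    truth = (
        syn.SyntheticTruth.from_json(paths["truth"]) if "truth" in paths else None
    )
    return (
        mirna_ds, mrna_ds, matched, utrs, mirseqs, oe, gene_sets, truth,
        config.focus_mirna,
    )


def run_all(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute every stage, write all artifacts under ``outdir`` and
    return the manifest (also written as ``manifest.json``)."""
    outdir = Path(outdir)
    if seed is not None and config.simulate is not None:
        config.simulate.rng_seed = seed

    with _stage("inputs"):
        (mirna_ds, mrna_ds, matched, utrs, mirseqs, oe, gene_sets, truth,
         focus) = _load_inputs(config, outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.simulate.rng_seed if config.simulate else seed,
        "stages": {},
    }

    with _stage("diffexpr"):
        mirna_results = [
            call_de(ds, config.de, feature_class="mirna") for ds in mirna_ds
        ]
        array_mrna = mrna_ds[:-1]
        pooled = (
            pool_geo_datasets(array_mrna) if len(array_mrna) > 1 else array_mrna[0]
        )
        pooled_result = call_de(pooled, config.de, feature_class="mrna")
        matched_mrna_result = call_de(mrna_ds[-1], config.de, feature_class="mrna")
        for res in mirna_results + [pooled_result, matched_mrna_result]:
            res.to_tsv(outdir / f"de_{res.dataset_id}.tsv")
        manifest["stages"]["diffexpr"] = {
            "n_de_per_mirna_cohort": {r.dataset_id: r.n_de for r in mirna_results},
            "n_de_mrna_pooled": pooled_result.n_de,
            "n_de_mrna_matched": matched_mrna_result.n_de,
        }

    with _stage("consensus"):
        mirna_cons = consensus_mirna(mirna_results, min_datasets=config.min_datasets)
        mrna_cons = consensus_mrna(pooled_result, matched_mrna_result)
        consensus_to_tsv(mirna_cons, outdir / "mirna_consensus.tsv")
        consensus_to_tsv(mrna_cons, outdir / "mrna_consensus.tsv")
        consensus_to_tsv(
            near_misses(mirna_results, config.min_datasets),
            outdir / "mirna_consensus_near_misses.tsv",
        )
        manifest["stages"]["consensus"] = {
            "n_mirnas": len(mirna_cons),
            "n_mrnas": len(mrna_cons),
        }

    with _stage("predict"):
        cons_mirnas = [
            MatureMirna(f.feature_id, mirseqs[f.feature_id])
            for f in mirna_cons
            if f.feature_id in mirseqs
        ]
        cons_utrs = {
            f.feature_id: utrs[f.feature_id]
            for f in mrna_cons
            if f.feature_id in utrs
        }
        sites = predict_targets(
            cons_mirnas, cons_utrs, config.predictors,
            require_all_three=(config.mode == "all3"),
        )
        sites_to_tsv(sites, outdir / "sites.tsv")
        manifest["stages"]["predict"] = {"n_sites": len(sites)}

    with _stage("pairing"):
        pairs = build_pairs(
            mirna_cons, mrna_cons, matched[0], matched[1], sites,
            r_threshold=config.r_threshold, alpha=config.pairing_alpha,
            tumor_only=config.tumor_only, bh=config.bh,
        )
        pairs_to_tsv(pairs, outdir / "pairs.tsv")
        summary = summarize_pairs(pairs)
        manifest["stages"]["pairing"] = summary
        if truth is not None:
            precision, recall, f1 = syn.evaluate_recovery(pairs, truth)
            manifest["stages"]["pairing"]["recovery"] = {
                "precision": round(precision, 6),
                "recall": round(recall, 6),
                "f1": round(f1, 6),
            }

    with _stage("candidates"):
        if focus is not None and oe is not None and focus in mirseqs:
            focus_sites = predict_targets(
                [MatureMirna(focus, mirseqs[focus])], utrs, config.predictors,
                require_all_three=(config.mode == "all3"),
            )
            predicted = sorted({s.mrna_id for s in focus_sites})
            up, down = overexpression_filter(oe, config.de)
            common = intersect_candidates(predicted, down)
            if config.required_terms and gene_sets is not None:
                selected = annotate_and_select(common, gene_sets, config.required_terms)
                kept = [c.mrna_id for c in selected]
            else:
                kept = common
            with open(outdir / "candidates.tsv", "w", encoding="utf-8") as fh:
                fh.write("mrna_id\n")
                for g in kept:
                    fh.write(g + "\n")
            manifest["stages"]["candidates"] = {
                "focus_mirna": focus,
                "n_predicted_targets": len(predicted),
                "n_down_after_overexpression": len(down),
                "n_common": len(common),
                "n_selected": len(kept),
            }
        else:
            manifest["stages"]["candidates"] = {"focus_mirna": None}
            up, down = [], []

    with _stage("enrichment"):
        if gene_sets is not None and down:
            results = enrich(down, gene_sets, use_ease=config.use_ease)
            enrichment_to_tsv(results, outdir / "enrichment.tsv")
            manifest["stages"]["enrichment"] = {"n_terms_tested": len(results)}
        else:
            manifest["stages"]["enrichment"] = {"n_terms_tested": 0}

    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
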