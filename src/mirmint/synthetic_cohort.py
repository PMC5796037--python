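"""Synthetic multi-cohort tumor/normal data with planted regulatory truth.

The generator emulates the statistical structure the downstream analysis
assumes rather than platform noise physics: every cohort (array-like or
sequencing-like) is a Gaussian log2 expression matrix in which a minority
of features are shifted by +-de_shift in tumors, and a planted set of
miRNA -> mRNA pairs is (a) oppositely dysregulated, (b) negatively
coupled across the matched-sample cohort pair, and (c) linked by a seed
site embedded in the target's 3'UTR.

Planted sites are embedded as the complement of miRNA positions 2..L
plus a 3'-terminal base selecting the seed class (an A opposite position
1 gives the 8mer), so planted sites carry full 3'-supplementary pairing;
the recorded truth interval is the seed-match window the scanner
reports.  All non-embedded background is generated free of 6mer-or-
better seed matches for every differentially expressed miRNA, so
site-level false positives downstream are attributable to the predictor,
not the generator.

Everything is deterministic under ``rng_seed``: each stage derives an
independent stream from ``numpy.random.SeedSequence([rng_seed, stage])``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .diffexpr import LOG2_1P5
from .io_formats import (
    ExpressionDataset,
    GeneSetCollection,
    write_expression_tsv,
    write_fasta,
    write_gmt,
)
from .target_predict import (
    RNA_COMPLEMENT,
    reverse_complement,
    seed_of,
)

_BASES = "ACGU"

# SeedSequence stage keys
_STAGE_COHORTS = 0
_STAGE_UTRS = 1
_STAGE_OVEREXPR = 2
_STAGE_GENESETS = 3


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Shifts and standard deviations are in log2 expression units; the
    default effect size (de_shift = 1.5 = 3 * noise_sd) gives near-
    certain single-cohort detection at 20 samples per group, emulating
    the clearly separable tumor/normal features the real screen keeps.
    """

    n_mirna_datasets: int = 4      # 3 array-like + 1 matched sequencing-like
    n_mrna_datasets: int = 2       # 1 array-like + 1 matched sequencing-like
    samples_per_group: int = 20
    n_mirnas: int = 300
    n_mrnas: int = 600
    frac_de_mirna: float = 0.4
    frac_de_mrna: float = 0.3
    de_shift: float = 1.5          # delta, log2 units
    noise_sd: float = 0.5          # sigma, log2 units
    n_planted_pairs: int = 50
    targets_per_mirna: int = 1
    coupling: float = 0.8          # beta: target = baseline - beta * miRNA + eps
    utr_length: int = 600
    seed_site_class: str = "8mer"
    mirna_length: int = 22
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    n_oe_bystanders: int = 40      # off-target genes given random overexpression FCs
    oe_margin: float = 0.5         # planted targets beat the filter by >= this
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            "n_mirna_datasets", "n_mrna_datasets", "samples_per_group",
            "n_mirnas", "n_mrnas", "n_planted_pairs", "utr_length",
            "n_oe_bystanders", "targets_per_mirna",
        )
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_mirna_datasets < 1 or self.n_mrna_datasets < 1:
            raise ConfigError("need at least one cohort per feature class")
        if self.seed_site_class not in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
            raise ConfigError(f"unknown seed class {self.seed_site_class!r}")
        if not 18 <= self.mirna_length <= 26:
            raise ConfigError("mirna_length must be 18-26")
        if self.n_planted_pairs:
            need_mirnas = math.ceil(self.n_planted_pairs / max(1, self.targets_per_mirna))
            if need_mirnas > self.n_down_mirnas:
                raise ConfigError(
                    f"planting needs {need_mirnas} down-regulated miRNAs, "
                    f"only {self.n_down_mirnas} available"
                )
            if self.n_planted_pairs > self.n_up_mrnas:
                raise ConfigError(
                    f"planting needs {self.n_planted_pairs} up-regulated mRNAs, "
                    f"only {self.n_up_mrnas} available"
                )
            if self.utr_length < self.mirna_length + 60:
                raise ConfigError("utr_length too short to embed a planted site")

    # -- derived counts --------------------------------------------------
    @property
    def n_de_mirnas(self) -> int:
        return round(self.frac_de_mirna * self.n_mirnas)

    @property
    def n_down_mirnas(self) -> int:
        return -(-self.n_de_mirnas // 2)  # ceil: down-regulated miRNAs lead

    @property
    def n_de_mrnas(self) -> int:
        return round(self.frac_de_mrna * self.n_mrnas)

    @property
    def n_up_mrnas(self) -> int:
        return -(-self.n_de_mrnas // 2)

    def mirna_ids(self) -> list[str]:
        return [f"miR-syn-{i:04d}" for i in range(self.n_mirnas)]

    def mrna_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_mrnas)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    de_mirnas: dict[str, str]                       # id -> up|down
    de_mrnas: dict[str, str]
    planted_pairs: list[tuple[str, str, float]]     # (miRNA, mRNA, beta)
    mirna_sequences: dict[str, str]                 # id -> 5'->3' RNA
    planted_sites: dict[str, dict] = field(default_factory=dict)
    # mRNA id -> {mirna_id, start, end, seed_class}

    def pair_set(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.planted_pairs}

    def targets_of(self, mirna_id: str) -> list[str]:
        return [g for m, g, _ in self.planted_pairs if m == mirna_id]

    def to_json(self, path) -> None:
        payload = {
            "de_mirnas": self.de_mirnas,
            "de_mrnas": self.de_mrnas,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "mirna_sequences": self.mirna_sequences,
            "planted_sites": self.planted_sites,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            de_mirnas=d["de_mirnas"],
            de_mrnas=d["de_mrnas"],
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            mirna_sequences=d["mirna_sequences"],
            planted_sites=d["planted_sites"],
        )


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def _draw_mirna_sequences(config: SimulationConfig, rng) -> dict[str, str]:
    """Random mature sequences with pairwise-distinct seed hexamers.

    The seed (positions 2-7) is unique per miRNA so each differentially
    expressed miRNA contributes exactly one forbidden background 6mer,
    and a miRNA's own seed never recurs inside positions 2..L (keeping
    the planted site the only seed match in its UTR).
    """
    n, L = config.n_mirnas, config.mirna_length
    if n > 4 ** 6:
        raise ConfigError("more miRNAs than distinct seed hexamers")
    codes = rng.choice(4 ** 6, size=n, replace=False)
    out = {}
    for mid, code in zip(config.mirna_ids(), codes):
        seed6 = ""
        c = int(code)
        for _ in range(6):
            seed6 += _BASES[c % 4]
            c //= 4
        while True:
            head = _BASES[rng.integers(4)]
            tail = "".join(_BASES[b] for b in rng.integers(0, 4, size=L - 7))
            seq = head + seed6 + tail
            if seq[1:].count(seed6) == 1:
                break
        out[mid] = seq
    return out


def _assign_truth(config: SimulationConfig, rng) -> SyntheticTruth:
    mirnas = config.mirna_ids()
    mrnas = config.mrna_ids()

    de_mirna_ids = list(rng.choice(mirnas, size=config.n_de_mirnas, replace=False))
    de_mirnas = {
        mid: ("down" if i < config.n_down_mirnas else "up")
        for i, mid in enumerate(de_mirna_ids)
    }
    de_mrna_ids = list(rng.choice(mrnas, size=config.n_de_mrnas, replace=False))
    de_mrnas = {
        gid: ("up" if i < config.n_up_mrnas else "down")
        for i, gid in enumerate(de_mrna_ids)
    }

    down_mirnas = [m for m in de_mirna_ids if de_mirnas[m] == "down"]
    up_mrnas = [g for g in de_mrna_ids if de_mrnas[g] == "up"]
    pairs = []
    k = max(1, config.targets_per_mirna)
    for idx in range(config.n_planted_pairs):
        pairs.append((down_mirnas[idx // k], up_mrnas[idx], config.coupling))

    return SyntheticTruth(
        de_mirnas=de_mirnas,
        de_mrnas=de_mrnas,
        planted_pairs=pairs,
        mirna_sequences={},
    )


def _simulate_matrix(
    feature_ids, truth_dirs, config, rng, samples, groups
) -> pd.DataFrame:
    n_feat, n_samp = len(feature_ids), len(samples)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_feat)
    tumor_ind = np.array([1.0 if groups[s] == "tumor" else 0.0 for s in samples])
    shift = np.array(
        [
            {"up": 1.0, "down": -1.0}.get(truth_dirs.get(f), 0.0)
            for f in feature_ids
        ]
    )
    values = (
        baseline[:, None]
        + config.de_shift * shift[:, None] * tumor_ind[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_feat, n_samp))
    )
    return pd.DataFrame(values, index=feature_ids, columns=samples)


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], list[ExpressionDataset],
           tuple[ExpressionDataset, ExpressionDataset], SyntheticTruth]:
    """Generate all cohorts plus the planted truth.

    Returns ``(mirna_datasets, mrna_datasets, (matched_mirna,
    matched_mrna), truth)``.  The last dataset of each list is the
    matched sequencing-like cohort; the matched pair shares one ordered
    sample list, and each planted pair's target is negatively coupled to
    its miRNA there: target = baseline + dir*delta*tumor
    - beta*(centered miRNA) + Normal(0, noise_sd/2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, _STAGE_COHORTS]))
    truth = _assign_truth(config, rng)
    truth.mirna_sequences = _draw_mirna_sequences(config, rng)

    def cohort_samples(tag: str):
        n = config.samples_per_group
        samples = [f"{tag}-N{i:03d}" for i in range(n)] + [
            f"{tag}-T{i:03d}" for i in range(n)
        ]
        groups = pd.Series(
            ["normal"] * n + ["tumor"] * n, index=samples
        )
        return samples, groups

    mirna_datasets: list[ExpressionDataset] = []
    for d in range(config.n_mirna_datasets - 1):
        did = f"MIR-ARRAY{d + 1}"
        samples, groups = cohort_samples(did)
        values = _simulate_matrix(
            config.mirna_ids(), truth.de_mirnas, config, rng, samples, groups
        )
        mirna_datasets.append(ExpressionDataset(did, "array", values, groups))

    mrna_datasets: list[ExpressionDataset] = []
    for d in range(config.n_mrna_datasets - 1):
        did = f"MRNA-ARRAY{d + 1}"
        samples, groups = cohort_samples(did)
        values = _simulate_matrix(
            config.mrna_ids(), truth.de_mrnas, config, rng, samples, groups
        )
        mrna_datasets.append(ExpressionDataset(did, "array", values, groups))

    # matched sequencing-like pair on one shared sample list
    samples, groups = cohort_samples("SEQ")
    mir_values = _simulate_matrix(
        config.mirna_ids(), truth.de_mirnas, config, rng, samples, groups
    )
    mrna_values = _simulate_matrix(
        config.mrna_ids(), truth.de_mrnas, config, rng, samples, groups
    )
    tumor_ind = np.array([1.0 if groups[s] == "tumor" else 0.0 for s in samples])
    for mirna_id, gene_id, beta in truth.planted_pairs:
        m = mir_values.loc[mirna_id].to_numpy()
        direction = 1.0 if truth.de_mrnas[gene_id] == "up" else -1.0
        mrna_values.loc[gene_id] = (
            rng.normal(config.baseline_mean, config.baseline_sd)
            + config.de_shift * direction * tumor_ind
            - beta * (m - m.mean())
            + rng.normal(0.0, config.noise_sd / 2.0, size=len(samples))
        )
    matched_mirna = ExpressionDataset("MIR-SEQ", "rnaseq", mir_values, groups)
    matched_mrna = ExpressionDataset("MRNA-SEQ", "rnaseq", mrna_values, groups.copy())
    mirna_datasets.append(matched_mirna)
    mrna_datasets.append(matched_mrna)

    return mirna_datasets, mrna_datasets, (matched_mirna, matched_mrna), truth


# ---------------------------------------------------------------------------
# UTR sequences
# ---------------------------------------------------------------------------

_MAX_UTR_RETRIES = 200


def _forbidden_hexamers(truth: SyntheticTruth) -> set[str]:
    """Background-excluded 6mers: the seed-match core of every DE miRNA."""
    out = set()
    for mid in truth.de_mirnas:
        _, seed6 = seed_of(truth.mirna_sequences[mid])
        out.add(reverse_complement(seed6))
    return out


def _sample_clean(length: int, forbidden: set[str], rng) -> str:
    """Sample a sequence whose every 6-window avoids ``forbidden``.

    Bases are drawn left to right; a base that would complete a
    forbidden 6mer is excluded at its position.  Dead ends (all four
    bases forbidden) trigger a bounded restart.
    """
    if not forbidden:
        return "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
    for _ in range(_MAX_UTR_RETRIES):
        chars: list[str] = []
        ok = True
        for _pos in range(length):
            allowed = [
                b for b in _BASES
                if len(chars) < 5 or "".join(chars[-5:]) + b not in forbidden
            ]
            if not allowed:
                ok = False
                break
            chars.append(allowed[rng.integers(len(allowed))])
        if ok:
            return "".join(chars)
    raise ConfigError(
        "could not sample a seed-free UTR background; "
        "try a different utr_length or fewer DE miRNAs"
    )


def _planted_embed(mirna_seq: str, seed_class: str) -> tuple[str, int, int]:
    """Embedded site text and the seed-match interval relative to it.

    The site complements miRNA positions 2..L (3'-supplementary pairing
    included); the last one or two characters select the seed class.
    """
    L = len(mirna_seq)
    seed7, seed6 = seed_of(mirna_seq)
    m8_comp = RNA_COMPLEMENT[seed7[-1]]
    not_m8 = next(b for b in _BASES if b != m8_comp)
    if seed_class == "8mer":
        embed = reverse_complement(mirna_seq[1:]) + "A"
        rel = (L - 8, L)
    elif seed_class == "7mer-m8":
        embed = reverse_complement(mirna_seq[1:]) + "C"
        rel = (L - 8, L - 1)
    elif seed_class == "7mer-A1":
        embed = reverse_complement(mirna_seq[8:]) + not_m8 + reverse_complement(seed6) + "A"
        rel = (L - 7, L)
    else:  # 6mer
        embed = reverse_complement(mirna_seq[8:]) + not_m8 + reverse_complement(seed6) + "C"
        rel = (L - 7, L - 1)
    return embed, rel[0], rel[1]


def _windows_clean(utr: str, forbidden: set[str], exempt: tuple[int, int]) -> bool:
    """True iff no forbidden 6mer occurs outside the exempt interval."""
    lo, hi = exempt
    for i in range(len(utr) - 5):
        if lo <= i and i + 6 <= hi:
            continue
        if utr[i:i + 6] in forbidden:
            return False
    return True


def simulate_utrs(config: SimulationConfig, truth: SyntheticTruth) -> dict[str, str]:
    """Generate one 3'UTR per mRNA and record planted site intervals.

    Planted targets receive one embedded site of the configured seed
    class for their miRNA; every other window of every UTR is free of
    6mer-or-better matches for all DE miRNAs.  Chance matches *inside*
    an embedded site for a different miRNA are possible (the embedded
    text is fixed by the planted miRNA) and left to the predictor to
    reject.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, _STAGE_UTRS]))
    forbidden = _forbidden_hexamers(truth)
    planted_by_gene = {g: m for m, g, _ in truth.planted_pairs}
    margin = 25

    utrs: dict[str, str] = {}
    truth.planted_sites = {}
    for gid in config.mrna_ids():
        if gid not in planted_by_gene:
            utrs[gid] = _sample_clean(config.utr_length, forbidden, rng)
            continue
        mid = planted_by_gene[gid]
        embed, rel_lo, rel_hi = _planted_embed(
            truth.mirna_sequences[mid], config.seed_site_class
        )
        for attempt in range(_MAX_UTR_RETRIES):
            background = _sample_clean(config.utr_length, forbidden, rng)
            pos = int(rng.integers(margin, config.utr_length - len(embed) - margin))
            utr = background[:pos] + embed + background[pos + len(embed):]
            if _windows_clean(utr, forbidden, (pos, pos + len(embed))):
                break
        else:
            raise ConfigError(
                f"could not place a clean planted site for {gid}; "
                "try a different utr_length"
            )
        utrs[gid] = utr
        truth.planted_sites[gid] = {
            "mirna_id": mid,
            "start": pos + rel_lo,
            "end": pos + rel_hi,
            "seed_class": config.seed_site_class,
        }
    return utrs


# ---------------------------------------------------------------------------
# overexpression profile
# ---------------------------------------------------------------------------

def simulate_overexpression(
    truth: SyntheticTruth, mirna_id: str, config: SimulationConfig
) -> pd.DataFrame:
    """Two-column (mimic, scrambled) log2 table after overexpressing one miRNA.

    Direct (planted) targets drop by at least ``LOG2_1P5 + oe_margin``;
    ``n_oe_bystanders`` random off-target genes get uniform fold changes
    in [-2, 2]; everything else stays near zero.
    """
    if mirna_id not in truth.mirna_sequences:
        raise ConfigError(f"{mirna_id!r} is not a simulated miRNA")
    idx = config.mirna_ids().index(mirna_id)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, _STAGE_OVEREXPR, idx])
    )
    genes = config.mrna_ids()
    targets = set(truth.targets_of(mirna_id))

    scrambled = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    fc = rng.normal(0.0, 0.1, size=len(genes))
    non_targets = [i for i, g in enumerate(genes) if g not in targets]
    n_by = min(config.n_oe_bystanders, len(non_targets))
    if n_by:
        bystanders = rng.choice(non_targets, size=n_by, replace=False)
        fc[bystanders] = rng.uniform(-2.0, 2.0, size=n_by)
    for i, g in enumerate(genes):
        if g in targets:
            fc[i] = -(LOG2_1P5 + config.oe_margin) - abs(rng.normal(0.0, 0.3))
    return pd.DataFrame(
        {"mimic": scrambled + fc, "scrambled": scrambled}, index=genes
    )


# ---------------------------------------------------------------------------
# synthetic gene sets (for the enrichment and candidate stages)
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    config: SimulationConfig,
    truth: SyntheticTruth,
    focus_mirna: str | None = None,
    n_random_terms: int = 8,
    term_size: int = 30,
) -> GeneSetCollection:
    """A GMT-style collection: one term concentrating the planted targets
    of ``focus_mirna`` (default: the first planted miRNA) plus random
    terms over the gene universe."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, _STAGE_GENESETS])
    )
    genes = config.mrna_ids()
    if focus_mirna is None and truth.planted_pairs:
        focus_mirna = truth.planted_pairs[0][0]
    sets: dict[str, tuple[str, list[str]]] = {}
    if focus_mirna is not None:
        targets = truth.targets_of(focus_mirna)
        filler = [g for g in genes if g not in targets]
        extra = list(rng.choice(filler, size=max(0, term_size - len(targets)),
                                replace=False))
        sets["SYN:0001"] = ("regulation of cell cycle", sorted(set(targets + extra)))
    for t in range(n_random_terms):
        members = sorted(rng.choice(genes, size=term_size, replace=False))
        sets[f"SYN:{t + 2:04d}"] = (f"random process {t + 1}", members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(reported_pairs, truth: SyntheticTruth):
    """Precision/recall/F1 of reported (miRNA, mRNA) pairs against truth.

    Convention: precision is 1.0 whenever nothing was reported (no false
    positives were produced); recall is 1.0 when nothing was planted.
    """
    reported: set[tuple[str, str]] = set()
    for item in reported_pairs:
        if hasattr(item, "mirna_id"):
            reported.add((item.mirna_id, item.mrna_id))
        else:
            m, g = item[0], item[1]
            reported.add((m, g))
    planted = truth.pair_set()
    hits = len(reported & planted)
    precision = hits / len(reported) if reported else 1.0
    recall = hits / len(planted) if planted else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def simulate_to_dir(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Run every generator stage and write all artifacts under ``outdir``.

    Emits per-cohort expression TSVs, the UTR and miRNA FASTAs, the truth
    JSON, one overexpression TSV for the first planted miRNA, and a
    synthetic GMT.  Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna_ds, mrna_ds, _matched, truth = simulate_cohorts(config)
    utrs = simulate_utrs(config, truth)

    paths: dict[str, Path] = {}
    for ds in mirna_ds + mrna_ds:
        p = outdir / f"{ds.dataset_id}.tsv"
        write_expression_tsv(ds, p)
        paths[ds.dataset_id] = p

    paths["utrs"] = outdir / "utrs.fa"
    write_fasta(utrs, paths["utrs"])
    paths["mirnas"] = outdir / "mirnas.fa"
    write_fasta(truth.mirna_sequences, paths["mirnas"])

    if truth.planted_pairs:
        focus = truth.planted_pairs[0][0]
        oe = simulate_overexpression(truth, focus, config)
        paths["overexpression"] = outdir / "overexpression.tsv"
        with open(paths["overexpression"], "w", encoding="utf-8") as fh:
            fh.write("gene_id\tmimic\tscrambled\n")
            for g, row in oe.iterrows():
                fh.write(f"{g}\t{row['mimic']:.6f}\t{row['scrambled']:.6f}\n")
        paths["focus_mirna"] = focus  # type: ignore[assignment]

    gene_sets = simulate_gene_sets(config, truth)
    if len(gene_sets):
        paths["gene_sets"] = outdir / "gene_sets.gmt"
        write_gmt(gene_sets, paths["gene_sets"])

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
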