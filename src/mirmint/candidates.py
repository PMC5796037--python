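"""Candidate-target nomination and qPCR relative quantification.

The nomination funnel intersects the consensus-predicted targets of one
miRNA with the genes down-regulated after overexpressing that miRNA,
optionally screens out interactions already catalogued elsewhere (an
exclusion list of known miRNA-gene pairs), and finally keeps candidates
annotated with at least one required functional term.

The ddCt calculator converts cycle-threshold triplicates into a relative
quantity RQ = 2**(-ddCt), the standard comparative-Ct readout used to
validate candidate repression.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from ._errors import ConfigError
from .io_formats import GeneSetCollection
from .target_predict import PredictedSite


@dataclass
class CandidateTarget:
    """A gene surviving the prediction x down-regulation intersection."""

    mrna_id: str
    overexpression_log2fc: float | None = None
    predicted_sites: list[PredictedSite] = field(default_factory=list)
    annotation_terms_hit: list[str] = field(default_factory=list)


def intersect_candidates(predicted_targets_of_mirna, down_list) -> list[str]:
    """Sorted intersection of the predicted and down-regulated gene sets."""
    return sorted(set(predicted_targets_of_mirna) & set(down_list))


def exclude_known(candidate_ids, known_pairs, mirna_id: str) -> list[str]:
    """Drop candidates whose interaction with ``mirna_id`` is already known.

    ``known_pairs`` is an iterable of (miRNA id, gene id) interactions.
    """
    known = {g for m, g in known_pairs if m == mirna_id}
    return [g for g in candidate_ids if g not in known]


def annotate_and_select(
    candidate_ids,
    gene_sets: GeneSetCollection,
    required_terms,
) -> list[CandidateTarget]:
    """Keep candidates annotated with >= 1 required term, recording the hits.

    ``required_terms`` entries may be term ids or term names; a required
    term absent from the collection is an error (listing all missing
    terms), so a typo cannot silently empty the candidate list.
    """
    by_name = {name: term for term, (name, _) in gene_sets.sets.items()}
    resolved: list[str] = []
    missing: list[str] = []
    for req in required_terms:
        if req in gene_sets.sets:
            resolved.append(req)
        elif req in by_name:
            resolved.append(by_name[req])
        else:
            missing.append(req)
    if missing:
        raise ConfigError(f"required terms not in the gene-set collection: {missing}")

    out: list[CandidateTarget] = []
    for gid in candidate_ids:
        hits = [t for t in resolved if gid in gene_sets.members(t)]
        if hits:
            out.append(CandidateTarget(mrna_id=gid, annotation_terms_hit=hits))
    return out


# ---------------------------------------------------------------------------
# ddCt relative quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdctInput:
    """Cycle-threshold triplicates (cycles) for target and reference genes
    in the case condition and the calibrator condition."""

    ct_target_case: tuple[float, ...]
    ct_ref_case: tuple[float, ...]
    ct_target_calibrator: tuple[float, ...]
    ct_ref_calibrator: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in (
            "ct_target_case", "ct_ref_case",
            "ct_target_calibrator", "ct_ref_calibrator",
        ):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in vals))
            vals = getattr(self, name)
            if not vals:
                raise ConfigError(f"{name}: empty Ct triplicate")
            if any(v <= 0 for v in vals):
                raise ConfigError(f"{name}: Ct values must be > 0")


@dataclass(frozen=True)
class RelativeQuantification:
    """RQ = 2**(-ddCt) with the intermediate quantities and per-triplicate SD."""

    rq: float
    ddct: float
    dct_case: float
    dct_calibrator: float
    sd: dict[str, float]


def relative_quantification(data: DdctInput) -> RelativeQuantification:
    """Comparative-Ct fold change of the case condition over the calibrator.

    dCt = mean(Ct target) - mean(Ct reference) per condition;
    ddCt = dCt_case - dCt_calibrator; RQ = 2**(-ddCt).
    """
    def mean(v):
        return sum(v) / len(v)

    def sd(v):
        return statistics.stdev(v) if len(v) > 1 else 0.0

    dct_case = mean(data.ct_target_case) - mean(data.ct_ref_case)
    dct_cal = mean(data.ct_target_calibrator) - mean(data.ct_ref_calibrator)
    ddct = dct_case - dct_cal
    return RelativeQuantification(
        rq=2.0 ** (-ddct),
        ddct=ddct,
        dct_case=dct_case,
        dct_calibrator=dct_cal,
        sd={
            "ct_target_case": sd(data.ct_target_case),
            "ct_ref_case": sd(data.ct_ref_case),
            "ct_target_calibrator": sd(data.ct_target_calibrator),
            "ct_ref_calibrator": sd(data.ct_ref_calibrator),
        },
    )
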