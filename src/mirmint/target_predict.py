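"""Three independent miRNA target-site predictors and their consensus.

Each predictor judges a candidate site along one decision axis, the same
axes the classic tools divide between themselves:

``seed_align``
    a local antiparallel complementarity alignment score with the seed
    region (miRNA positions 2-8) weighted double (the miRanda axis);
``mfe``
    the nearest-neighbor minimum free energy of the intermolecular
    miRNA:target duplex (the RNAhybrid axis);
``accessibility``
    the duplex energy minus the cost of opening local target secondary
    structure, estimated from a maximum-base-pairing fold of the site
    plus flanks (the PITA axis).

These are deliberately small, fully documented scoring schemes, not
reimplementations of the original programs: every table and penalty is a
module constant so the numbers can be verified by hand or by exhaustive
enumeration.  The consensus call retains a site only when the seed class
passes and, in all-three mode, all three predictors agree.

Coordinates are 0-based half-open on the UTR read 5'->3'; only the sense
strand is scanned, since a 3'UTR is single-stranded mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._errors import ConfigError, FormatError
from .io_formats import normalize_rna

# ---------------------------------------------------------------------------
# alphabet
# ---------------------------------------------------------------------------

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick pairs plus the GU wobble, keyed miRNA-base + target-base.
WATSON_CRICK = {"AU", "UA", "GC", "CG"}
WOBBLE = {"GU", "UG"}
PAIRABLE = WATSON_CRICK | WOBBLE

SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SEED_CLASS_RANK = {c: i for i, c in enumerate(SEED_CLASSES, start=1)}


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    seq = normalize_rna(seq)
    try:
        return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise FormatError(f"non-RNA base {exc.args[0]!r}") from None


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA sequence, 5'->3', 18-26 nt over {A,C,G,U}."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise FormatError(f"{self.mirna_id}: non-RNA base {bad.pop()!r}")
        if not 18 <= len(self.sequence) <= 26:
            raise FormatError(
                f"{self.mirna_id}: mature miRNA must be 18-26 nt, "
                f"got {len(self.sequence)}"
            )


def _seq_of(mirna) -> str:
    if isinstance(mirna, MatureMirna):
        return mirna.sequence
    return normalize_rna(str(mirna))


def _id_of(mirna) -> str:
    return mirna.mirna_id if isinstance(mirna, MatureMirna) else ""


def seed_of(mirna) -> tuple[str, str]:
    """``(seed7, seed6)``: miRNA positions 2-8 and 2-7, 1-based from 5'."""
    seq = _seq_of(mirna)
    if len(seq) < 8:
        raise ConfigError("miRNA shorter than 8 nt has no seed")
    return seq[1:8], seq[1:7]


# ---------------------------------------------------------------------------
# seed-match scanner
# ---------------------------------------------------------------------------

@dataclass
class PredictedSite:
    """A scored candidate binding site on one UTR.

    ``predictors_passed`` is the subset of {"seed_align", "mfe",
    "accessibility"} whose thresholds the site cleared; energies are in
    kcal/mol, ``None`` meaning the quantity was not (or could not be)
    computed.
    """

    mirna_id: str
    mrna_id: str
    start: int
    end: int
    seed_class: str
    align_score: float | None = None
    duplex_mfe: float | None = None
    ddg_accessibility: float | None = None
    predictors_passed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ConfigError(f"bad site interval [{self.start},{self.end})")
        if self.seed_class not in SEED_CLASS_RANK:
            raise ConfigError(f"unknown seed class {self.seed_class!r}")
        if self.duplex_mfe is not None and self.duplex_mfe > 0:
            raise ConfigError("reported duplex MFE must be <= 0")


def find_seed_sites(mirna, utr: str, mrna_id: str = "") -> list[PredictedSite]:
    """Scan a UTR 5'->3' for canonical seed matches.

    Site patterns on the target strand (rc = reverse complement):
    8mer = rc(seed7)+A, 7mer-m8 = rc(seed7), 7mer-A1 = rc(seed6)+A,
    6mer = rc(seed6).  Each seed-match occurrence is reported once, at
    the highest class it supports, with the interval covering the full
    matched substring.
    """
    seed7, seed6 = seed_of(mirna)
    utr = normalize_rna(utr)
    core = reverse_complement(seed6)  # 6 nt shared by all four patterns
    m8_complement = RNA_COMPLEMENT[seed7[-1]]  # pairs miRNA position 8

    sites: list[PredictedSite] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8_complement
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            cls, start, end = "8mer", pos - 1, pos + 7
        elif has_m8:
            cls, start, end = "7mer-m8", pos - 1, pos + 6
        elif has_a1:
            cls, start, end = "7mer-A1", pos, pos + 7
        else:
            cls, start, end = "6mer", pos, pos + 6
        sites.append(PredictedSite(_id_of(mirna), mrna_id, start, end, cls))
        pos = utr.find(core, pos + 1)
    return sites


# ---------------------------------------------------------------------------
# duplex minimum free energy (nearest-neighbor stacks)
# ---------------------------------------------------------------------------

#: Half-stack strength per pair type, kcal/mol.  A stack of two adjacent
#: pairs contributes minus the sum of the two strengths, giving
#: literature-scale magnitudes (GC/GC -3.3, AU/AU -1.1, GU/GU -0.5).
PAIR_HALF_STACK = {
    "GC": 1.65, "CG": 1.65,
    "AU": 0.55, "UA": 0.55,
    "GU": 0.25, "UG": 0.25,
}

#: Full stack table, keyed by the two stacked pairs (each miRNA+target base).
STACK_ENERGIES = {
    (p, q): -(PAIR_HALF_STACK[p] + PAIR_HALF_STACK[q])
    for p in PAIR_HALF_STACK
    for q in PAIR_HALF_STACK
}

#: Affine penalty for k unpaired nucleotides between consecutive pairs
#: (bulge or internal loop): LOOP_OPEN + LOOP_EXT * k, kcal/mol.
LOOP_OPEN = 3.0
LOOP_EXT = 0.5

MAX_DUPLEX_WINDOW = 40


def duplex_mfe(mirna, utr_window: str) -> float | None:
    """Minimum free energy of the intermolecular miRNA:window duplex.

    The duplex is antiparallel and free of intramolecular structure:
    paired columns must be Watson-Crick or GU, adjacent pairs contribute
    a stack energy from :data:`STACK_ENERGIES`, and unpaired stretches
    between pairs cost an affine loop penalty.  Dangling ends are free.
    Returns ``None`` ("no duplex") when the sequences share no pairable
    position; otherwise a value <= 0 (a lone pair has zero stacks).
    """
    u = _seq_of(mirna)
    w = normalize_rna(utr_window)
    if len(w) > MAX_DUPLEX_WINDOW:
        raise ConfigError(
            f"duplex window of {len(w)} nt exceeds {MAX_DUPLEX_WINDOW}"
        )
    if not u or not w:
        return None
    v = w[::-1]  # antiparallel register: align miRNA 5'->3' with window 3'->5'
    n, m = len(u), len(v)
    INF = float("inf")

    # best[i][j]: min energy of a duplex whose last paired column is (i, j).
    # Loop penalties are affine and separable, so the min over all earlier
    # pairs reduces to a running rectangle minimum of best - LOOP_EXT*(i+j)
    # (taking the "loop" transition from the adjacent cell is dominated by
    # the stack transition, so including it is harmless).
    best = [[INF] * m for _ in range(n)]
    rmin = [[INF] * m for _ in range(n)]
    overall = INF
    for i in range(n):
        for j in range(m):
            if u[i] + v[j] in PAIRABLE:
                e = 0.0  # open a fresh duplex at this pair
                if i > 0 and j > 0:
                    prev = best[i - 1][j - 1]
                    if prev < INF:
                        e = min(
                            e, prev + STACK_ENERGIES[(u[i - 1] + v[j - 1], u[i] + v[j])]
                        )
                    loop_base = rmin[i - 1][j - 1]
                    if loop_base < INF:
                        e = min(e, loop_base + LOOP_OPEN + LOOP_EXT * (i + j - 2))
                best[i][j] = e
                overall = min(overall, e)
            q = best[i][j] - LOOP_EXT * (i + j)
            if i > 0:
                q = min(q, rmin[i - 1][j])
            if j > 0:
                q = min(q, rmin[i][j - 1])
            rmin[i][j] = q
    return None if overall == INF else overall


# ---------------------------------------------------------------------------
# alignment score (seed-weighted local complementarity)
# ---------------------------------------------------------------------------

#: Substitution scores (dimensionless): Watson-Crick pair, GU wobble,
#: mismatch; affine gap costs.  Columns opposite miRNA positions 2-8
#: have their substitution score doubled.
ALIGN_PAIR = 5.0
ALIGN_WOBBLE = 2.0
ALIGN_MISMATCH = -3.0
ALIGN_GAP_OPEN = -8.0
ALIGN_GAP_EXT = -2.0
SEED_WEIGHT = 2.0

MAX_ALIGN_WINDOW = 60

_NEG = float("-inf")


def align_score(mirna, utr_window: str) -> float:
    """Best local antiparallel complementarity alignment score.

    Gotoh dynamic programming over the miRNA (5'->3') against the
    reversed window, deterministic; an empty window scores 0.
    """
    u = _seq_of(mirna)
    w = normalize_rna(utr_window)
    if len(w) > MAX_ALIGN_WINDOW:
        raise ConfigError(
            f"alignment window of {len(w)} nt exceeds {MAX_ALIGN_WINDOW}"
        )
    if not u or not w:
        return 0.0
    v = w[::-1]
    n, m = len(u), len(v)

    def sub(i: int, j: int) -> float:
        pair = u[i - 1] + v[j - 1]
        if pair in WATSON_CRICK:
            s = ALIGN_PAIR
        elif pair in WOBBLE:
            s = ALIGN_WOBBLE
        else:
            s = ALIGN_MISMATCH
        return s * (SEED_WEIGHT if 2 <= i <= 8 else 1.0)

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in miRNA
    score = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + ALIGN_GAP_OPEN, X[i - 1][j] + ALIGN_GAP_EXT)
            Y[i][j] = max(M[i][j - 1] + ALIGN_GAP_OPEN, Y[i][j - 1] + ALIGN_GAP_EXT)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = max(0.0, diag + sub(i, j))
            if M[i][j] > score:
                score = M[i][j]
    return score


# ---------------------------------------------------------------------------
# site accessibility (maximum base pairing opening cost)
# ---------------------------------------------------------------------------

MIN_HAIRPIN_LOOP = 3


def nussinov_pairs(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> int:
    """Maximum number of nested base pairs (Watson-Crick or GU) with a
    minimum hairpin loop of ``min_loop`` unpaired nucleotides."""
    s = normalize_rna(seq)
    n = len(s)
    if n == 0:
        return 0
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]
            for k in range(i, j - min_loop):
                if s[k] + s[j] in PAIRABLE:
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            N[i][j] = best
    return N[0][n - 1]


#: Energy credited per base pair that must be opened, kcal/mol.
OPEN_COST_PER_PAIR = 1.0


def accessibility_ddg(
    mirna, utr: str, site_interval: tuple[int, int], flank: int = 17
) -> float | None:
    """Accessibility-corrected binding energy of a site.

    ddG = duplex MFE of the miRNA:site hybrid minus the opening energy
    dG_open = -(pairs in a maximum-base-pairing fold of the site plus
    ``flank`` nt on each side) * OPEN_COST_PER_PAIR.  Lower (more
    negative) is more favorable; ``None`` when the site supports no
    duplex at all.
    """
    utr = normalize_rna(utr)
    start, end = site_interval
    if not (0 <= start < end <= len(utr)):
        raise ConfigError(
            f"site interval [{start},{end}) out of bounds for UTR of {len(utr)} nt"
        )
    region = utr[max(0, start - flank): min(len(utr), end + flank)]
    n_open = nussinov_pairs(region)
    mfe = duplex_mfe(mirna, utr[start:end])
    if mfe is None:
        return None
    return mfe + OPEN_COST_PER_PAIR * n_open


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorThresholds:
    """Pass/fail cutoffs for the three predictors plus the seed-class gate."""

    min_align_score: float = 80.0
    max_duplex_mfe: float = -14.0  # kcal/mol
    max_ddg: float = -5.0          # kcal/mol
    min_seed_class: str = "6mer"

    def __post_init__(self) -> None:
        if self.max_duplex_mfe > 0 or self.max_ddg > 0:
            raise ConfigError("energy thresholds must be <= 0")
        if self.min_seed_class not in SEED_CLASS_RANK:
            raise ConfigError(f"unknown seed class {self.min_seed_class!r}")


def _windows(site: PredictedSite, mirna_len: int, utr_len: int):
    """Duplex/alignment windows: the seed match plus room upstream on the
    UTR for 3'-supplementary pairing (the miRNA 3' end pairs 5' of the
    seed site on the target)."""
    upstream = mirna_len - (site.end - site.start) + 4
    duplex = (max(0, site.start - upstream), site.end)
    align = (max(0, site.start - upstream - 8), min(utr_len, site.end + 2))
    return duplex, align


def score_site(
    mirna: MatureMirna,
    utr: str,
    site: PredictedSite,
    thresholds: PredictorThresholds | None = None,
) -> PredictedSite:
    """Fill the three predictor scores and the pass set for one seed site."""
    thresholds = thresholds or PredictorThresholds()
    utr = normalize_rna(utr)
    (dstart, dend), (astart, aend) = _windows(site, len(mirna.sequence), len(utr))

    mfe = duplex_mfe(mirna, utr[dstart:dend])
    ascore = align_score(mirna, utr[astart:aend])
    ddg = accessibility_ddg(mirna, utr, (dstart, dend))

    passed = set()
    if ascore >= thresholds.min_align_score:
        passed.add("seed_align")
    if mfe is not None and mfe <= thresholds.max_duplex_mfe:
        passed.add("mfe")
    if ddg is not None and ddg <= thresholds.max_ddg:
        passed.add("accessibility")

    return PredictedSite(
        mirna_id=mirna.mirna_id,
        mrna_id=site.mrna_id,
        start=site.start,
        end=site.end,
        seed_class=site.seed_class,
        align_score=ascore,
        duplex_mfe=mfe,
        ddg_accessibility=ddg,
        predictors_passed=frozenset(passed),
    )


def consensus_predict(
    mirna: MatureMirna,
    utr: str,
    thresholds: PredictorThresholds | None = None,
    require_all_three: bool = True,
    mrna_id: str = "",
) -> list[PredictedSite]:
    """Seed-gated consensus across the three predictors for one miRNA/UTR.

    A site is reported iff its seed class reaches ``min_seed_class`` and
    either all three predictors pass (all-three mode) or at least one
    does (union mode, mirroring a multi-tool union stage).
    """
    thresholds = thresholds or PredictorThresholds()
    min_rank = SEED_CLASS_RANK[thresholds.min_seed_class]
    out = []
    for site in find_seed_sites(mirna, utr, mrna_id=mrna_id):
        if SEED_CLASS_RANK[site.seed_class] < min_rank:
            continue
        scored = score_site(mirna, utr, site, thresholds)
        n_pass = len(scored.predictors_passed)
        if (require_all_three and n_pass == 3) or (not require_all_three and n_pass >= 1):
            out.append(scored)
    return out


def predict_targets(
    mirnas: list[MatureMirna],
    utrs: dict[str, str],
    thresholds: PredictorThresholds | None = None,
    require_all_three: bool = True,
) -> list[PredictedSite]:
    """Consensus prediction over every miRNA x UTR combination."""
    sites: list[PredictedSite] = []
    for mirna in mirnas:
        for mrna_id, utr in utrs.items():
            sites.extend(
                consensus_predict(
                    mirna, utr, thresholds, require_all_three, mrna_id=mrna_id
                )
            )
    sites.sort(key=lambda s: (s.mirna_id, s.mrna_id, s.start, s.end))
    return sites


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_SITE_COLS = (
    "mirna_id\tmrna_id\tstart\tend\tseed_class\talign_score\tduplex_mfe"
    "\tddg\tpredictors_passed"
)


def sites_to_tsv(sites: list[PredictedSite], path) -> None:
    def fmt(x):
        return "NA" if x is None else f"{x:.6f}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_SITE_COLS + "\n")
        for s in sites:
            fh.write(
                f"{s.mirna_id}\t{s.mrna_id}\t{s.start}\t{s.end}\t{s.seed_class}\t"
                f"{fmt(s.align_score)}\t{fmt(s.duplex_mfe)}\t"
                f"{fmt(s.ddg_accessibility)}\t"
                + ",".join(sorted(s.predictors_passed)) + "\n"
            )


def sites_from_tsv(path) -> list[PredictedSite]:
    table = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    out = []
    for _, row in table.iterrows():
        passed = row["predictors_passed"]
        out.append(
            PredictedSite(
                mirna_id=str(row["mirna_id"]),
                mrna_id=str(row["mrna_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                seed_class=str(row["seed_class"]),
                align_score=None if pd.isna(row["align_score"]) else float(row["align_score"]),
                duplex_mfe=None if pd.isna(row["duplex_mfe"]) else float(row["duplex_mfe"]),
                ddg_accessibility=None if pd.isna(row["ddg"]) else float(row["ddg"]),
                predictors_passed=frozenset(
                    p for p in str(passed).split(",") if p and not pd.isna(passed)
                ),
            )
        )
    return out
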