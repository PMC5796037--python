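"""Readers and writers for every on-disk artifact of the pipeline.

All dialects are plain text with fixed, documented conventions so that a
write -> read round trip is the identity (floats are printed with six
decimals, which bounds the round-trip error at 5e-7):

* expression matrices: TSV, row 1 ``feature_id<TAB>sample...``, optional
  row 2 ``group<TAB>{tumor|normal}...``, remaining rows numeric;
* sequences: multi-line FASTA, normalised internally to the uppercase RNA
  alphabet (T -> U); the id is the header token before the first whitespace;
* gene sets: GMT (``term_id<TAB>description<TAB>member...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import FormatError

GROUPS = ("tumor", "normal")
PLATFORMS = ("array", "rnaseq")

_FLOAT_FMT = "%.6f"


@dataclass
class ExpressionDataset:
    """One cohort's log2 expression matrix with tumor/normal labels.

    ``values`` is a features x samples DataFrame of log2 expression;
    ``groups`` maps every sample id to ``"tumor"`` or ``"normal"``.
    ``sample_origin`` (optional) records the source cohort of each sample
    after pooling.
    """

    dataset_id: str
    platform: str
    values: pd.DataFrame
    groups: pd.Series
    sample_origin: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"{self.dataset_id}: unknown platform {self.platform!r}"
            )
        for axis, name in ((self.values.index, "feature"), (self.values.columns, "sample")):
            dup = axis[axis.duplicated()]
            if len(dup):
                raise FormatError(
                    f"{self.dataset_id}: duplicate {name} id {dup[0]!r}"
                )
        if list(self.groups.index) != list(self.values.columns):
            raise FormatError(
                f"{self.dataset_id}: group labels do not cover the sample list"
            )
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise FormatError(f"{self.dataset_id}: unknown group label {bad.pop()!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError(f"{self.dataset_id}: non-finite expression value")

    # -- conveniences ----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one group, original sample order kept."""
        return self.values[self.samples_in(group)]

    def require_de_usable(self) -> None:
        """At least two samples per group, as the t-test requires."""
        for g in GROUPS:
            if len(self.samples_in(g)) < 2:
                raise FormatError(
                    f"{self.dataset_id}: fewer than 2 {g!r} samples"
                )


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, members); members non-empty and deduplicated."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} has no members")
            if len(members) != len(set(members)):
                raise FormatError(f"gene set {term!r} has duplicate members")

    def members(self, term_id: str) -> list[str]:
        return self.sets[term_id][1]

    def term_name(self, term_id: str) -> str:
        return self.sets[term_id][0]

    def background(self) -> list[str]:
        """Union of all members, sorted (default enrichment background)."""
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path,
    group_line_present: bool = True,
    dataset_id: str | None = None,
    platform: str = "array",
) -> ExpressionDataset:
    """Parse an expression TSV into an :class:`ExpressionDataset`.

    Raises :class:`FormatError` on ragged rows, duplicate ids or
    non-numeric cells, naming the offending row/column.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip("\r\n")]
    if not lines:
        raise FormatError(f"{path}: empty expression file")

    header = lines[0].split("\t")
    if header[0] != "feature_id":
        raise FormatError(f"{path}: first header field must be 'feature_id'")
    samples = header[1:]
    ncol = len(header)

    if group_line_present:
        if len(lines) < 2:
            raise FormatError(f"{path}: missing group row")
        grow = lines[1].split("\t")
        if grow[0] != "group" or len(grow) != ncol:
            raise FormatError(f"{path}: malformed group row")
        groups = pd.Series(grow[1:], index=samples)
        body = lines[2:]
    else:
        groups = pd.Series(["tumor"] * len(samples), index=samples)
        body = lines[1:]

    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(body, start=3 if group_line_present else 2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {ncol})"
            )
        feature_ids.append(fields[0])
        vals = []
        for col, cell in enumerate(fields[1:], start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column "
                    f"{header[col]!r}"
                ) from None
        rows.append(vals)

    values = pd.DataFrame(rows, index=feature_ids, columns=samples, dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id or str(path),
        platform=platform,
        values=values,
        groups=groups,
    )


def write_expression_tsv(dataset: ExpressionDataset, path, group_line: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(dataset.sample_ids) + "\n")
        if group_line:
            fh.write("group\t" + "\t".join(dataset.groups[s] for s in dataset.sample_ids) + "\n")
        arr = dataset.values.to_numpy(dtype=float)
        for fid, row in zip(dataset.feature_ids, arr):
            fh.write(fid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_rna(seq: str) -> str:
    """Uppercase and convert the DNA alphabet to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered ``{id: RNA sequence}``; duplicate/empty records error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = normalize_rna(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: empty FASTA record {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(normalize_rna(seq)), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            term, name = fields[0], fields[1]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            members = list(dict.fromkeys(f for f in fields[2:] if f))
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = (name, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (name, members) in collection.sets.items():
            fh.write("\t".join([term, name, *members]) + "\n")
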