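"""AIRR-format repertoire I/O and domain containers.

Implements the data layer of the pipeline: annotated heavy-chain
rearrangements (AIRR Rearrangement TSV, one file per subject), per-subject
repertoires, labelled cohorts, and germline references.  Alignments are
IMGT-gapped nucleotide strings; all positions used elsewhere in the package
are 1-based inclusive on the gapped coordinates, and the gap character is
``"."`` (``"-"`` is accepted on read and normalised).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "."
_VALID_NT = set("ACGTN.")

#: columns every rearrangement file must provide
REQUIRED_COLUMNS = (
    "sequence_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "sequence_alignment",
    "germline_alignment",
)

#: recognised optional columns (anything else is carried opaquely in `extras`)
OPTIONAL_COLUMNS = ("d_call", "duplicate_count", "clone_id")


class AirrFormatError(ValueError):
    """File-level violation of the AIRR Rearrangement contract."""


def _normalise_seq(value: str) -> str:
    return value.strip().upper().replace("-", GAP)


@dataclass
class RearrangementRecord:
    """One annotated heavy-chain sequence with its inferred germline."""

    sequence_id: str
    v_call: str
    j_call: str
    junction: str
    junction_aa: str
    sequence_alignment: str
    germline_alignment: str
    d_call: str | None = None
    duplicate_count: int | None = None
    clone_id: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence_alignment = _normalise_seq(self.sequence_alignment)
        self.germline_alignment = _normalise_seq(self.germline_alignment)
        self.junction = self.junction.strip().upper()
        self.junction_aa = self.junction_aa.strip().upper()
        if len(self.sequence_alignment) != len(self.germline_alignment):
            raise ValueError(
                f"{self.sequence_id}: sequence_alignment and germline_alignment "
                "lengths differ"
            )
        if self.duplicate_count is not None and self.duplicate_count < 1:
            raise ValueError(f"{self.sequence_id}: duplicate_count must be >= 1")

    @property
    def v_gene(self) -> str:
        return gene_of(self.v_call)

    @property
    def j_gene(self) -> str:
        return gene_of(self.j_call)

    @property
    def v_family(self) -> str:
        return family_of(self.v_call)

    @property
    def cdr3_aa(self) -> str:
        """CDR3 = IMGT junction minus the conserved first/last residues."""
        return self.junction_aa[1:-1] if len(self.junction_aa) >= 2 else ""


def gene_of(call: str) -> str:
    """First call of a multi-assignment, truncated to gene level (allele dropped)."""
    first = call.split(",")[0].strip()
    return first.split("*")[0]


def family_of(call: str) -> str:
    gene = gene_of(call)
    return gene.split("-")[0].split("/")[0]


@dataclass
class Repertoire:
    """All rearrangements of one subject, in file order."""

    subject_id: str
    records: list[RearrangementRecord]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"repertoire {self.subject_id!r} is empty")
        ids = [r.sequence_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"repertoire {self.subject_id!r}: duplicate sequence_id")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RearrangementRecord]:
        return iter(self.records)


@dataclass
class Cohort:
    """Labelled collection of repertoires; `case` is the positive class."""

    repertoires: list[Repertoire]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        subjects = {r.subject_id for r in self.repertoires}
        if subjects != set(self.labels):
            raise ValueError("labels do not match repertoire subject_ids")
        bad = {v for v in self.labels.values() if v not in ("case", "control")}
        if bad:
            raise ValueError(f"unknown internal labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.repertoires)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.repertoires]

    def repertoire(self, subject_id: str) -> Repertoire:
        for rep in self.repertoires:
            if rep.subject_id == subject_id:
                return rep
        raise KeyError(subject_id)


@dataclass
class GermlineReference:
    """Named germline segments; V sequences may be IMGT-gapped."""

    sequences: dict[str, str]
    segment_types: dict[str, str]  # name -> V | D | J

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            seq = _normalise_seq(seq)
            if set(seq) - _VALID_NT:
                raise ValueError(f"{name}: invalid characters in germline sequence")
            self.sequences[name] = seq
        if set(self.segment_types.values()) - {"V", "D", "J"}:
            raise ValueError("segment types must be V, D or J")

    def of_type(self, segment: str) -> dict[str, str]:
        return {
            n: s for n, s in self.sequences.items() if self.segment_types[n] == segment
        }


def read_airr(path: str | Path, subject_id: str | None = None) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Rows whose alignments have unequal lengths are skipped (counted and
    logged), matching the accounting invariant records-in = kept + rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AirrFormatError(f"{path}: missing required column(s) {missing}")
    extra_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    records: list[RearrangementRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        data = row._asdict()
        kwargs = {c: data[c] for c in REQUIRED_COLUMNS}
        for col in OPTIONAL_COLUMNS:
            val = data.get(col, "")
            if val == "":
                continue
            kwargs[col] = int(val) if col == "duplicate_count" else val
        kwargs["extras"] = {c: data[c] for c in extra_cols}
        try:
            records.append(RearrangementRecord(**kwargs))
        except ValueError as exc:
            n_rejected += 1
            logger.warning("%s: skipping record: %s", path, exc)
    if n_rejected:
        logger.info("%s: %d record(s) rejected", path, n_rejected)
    rep = Repertoire(subject_id or path.stem, records)
    rep.metadata["n_rejected"] = str(n_rejected)
    return rep


def write_airr(repertoire: Repertoire, path: str | Path) -> Path:
    """Write a repertoire as AIRR TSV; round-trips through :func:`read_airr`."""
    path = Path(path)
    rows = []
    optional_present = {
        c
        for c in OPTIONAL_COLUMNS
        if any(getattr(r, c) is not None for r in repertoire)
    }
    extra_cols: list[str] = []
    for rec in repertoire:
        for key in rec.extras:
            if key not in extra_cols:
                extra_cols.append(key)
    for rec in repertoire:
        row = {c: getattr(rec, c) for c in REQUIRED_COLUMNS}
        for c in optional_present:
            val = getattr(rec, c)
            row[c] = "" if val is None else val
        for c in extra_cols:
            row[c] = rec.extras.get(c, "")
        rows.append(row)
    columns = (
        list(REQUIRED_COLUMNS)
        + [c for c in OPTIONAL_COLUMNS if c in optional_present]
        + extra_cols
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


DEFAULT_LABEL_MAP = {
    "case": "case",
    "control": "control",
    "cd": "case",
    "ctrl": "control",
    "healthy": "control",
}


def load_cohort(
    manifest: str | Path, label_map: Mapping[str, str] | None = None
) -> Cohort:
    """Load a cohort from a manifest TSV (columns subject_id, file, label).

    Relative file paths are resolved against the manifest's directory.
    ``label_map`` translates study label vocabulary to the internal
    {case, control}; matching is case-insensitive.
    """
    manifest = Path(manifest)
    mapping = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    df = pd.read_csv(manifest, sep="\t", dtype=str)
    for col in ("subject_id", "file", "label"):
        if col not in df.columns:
            raise AirrFormatError(f"{manifest}: manifest missing column {col!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in manifest: {dupes}")
    repertoires, labels = [], {}
    for row in df.itertuples(index=False):
        token = row.label.strip().lower()
        if token not in mapping:
            raise ValueError(f"unknown label {row.label!r} for subject {row.subject_id}")
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = manifest.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(
                f"subject {row.subject_id}: repertoire file {fpath} not found"
            )
        repertoires.append(read_airr(fpath, subject_id=row.subject_id))
        labels[row.subject_id] = mapping[token]
    return Cohort(repertoires, labels)


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _junction_productive(rec: RearrangementRecord) -> bool:
    junc = rec.junction
    if len(junc) % 3 != 0 or not junc:
        return False
    return not any(junc[i : i + 3] in _STOP_CODONS for i in range(0, len(junc), 3))


def filter_records(
    repertoire: Repertoire,
    v_family: str | None = None,
    productive_only: bool = False,
    min_aligned_length: int | None = None,
) -> tuple[Repertoire, dict[str, int]]:
    """Subset a repertoire; returns (filtered repertoire, removed-per-rule counts).

    ``v_family`` keeps records whose V gene starts with the given prefix
    (e.g. ``"IGHV1"``); ``productive_only`` keeps in-frame, stop-free
    junctions; ``min_aligned_length`` is over non-gap alignment positions.
    """
    removed = {"v_family": 0, "productive": 0, "min_aligned_length": 0}
    kept: list[RearrangementRecord] = []
    for rec in repertoire:
        if v_family is not None and not rec.v_gene.startswith(v_family):
            removed["v_family"] += 1
            continue
        if productive_only and not _junction_productive(rec):
            removed["productive"] += 1
            continue
        if min_aligned_length is not None:
            aligned = sum(1 for c in rec.sequence_alignment if c != GAP)
            if aligned < min_aligned_length:
                removed["min_aligned_length"] += 1
                continue
        kept.append(rec)
    if not kept:
        raise ValueError(
            f"filtering removed every record of {repertoire.subject_id!r}"
        )
    out = Repertoire(repertoire.subject_id, kept, dict(repertoire.metadata))
    return out, removed


def read_germline_fasta(
    path: str | Path, segment_types: Mapping[str, str] | None = None
) -> GermlineReference:
    """Read a germline FASTA.

    Segment type is taken from ``segment_types`` when given, otherwise
    inferred from the name (IGHV/IGHD/IGHJ prefixes).
    """
    sequences: dict[str, str] = {}
    types: dict[str, str] = {}
    for seqrec in SeqIO.parse(str(path), "fasta"):
        name = seqrec.id
        if name in sequences:
            raise ValueError(f"duplicate germline name {name!r}")
        sequences[name] = str(seqrec.seq)
        if segment_types and name in segment_types:
            types[name] = segment_types[name]
        else:
            for seg in ("V", "D", "J"):
                if f"IGH{seg}" in name.upper():
                    types[name] = seg
                    break
            else:
                raise ValueError(f"cannot infer segment type for {name!r}")
    return GermlineReference(sequences, types)
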