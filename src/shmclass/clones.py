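"""Clonal inference: group rearrangements into B-cell clones.

Sequences descending from one VDJ rearrangement share V gene, J gene and
junction length; within each such group, clones are formed by single-linkage
clustering of junction nucleotide sequences at a normalised Hamming distance
threshold (Immcantation-style practice; default 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .airr_io import Repertoire, RearrangementRecord


@dataclass
class CloneAssignment:
    """Partition of a repertoire's sequences into clones."""

    sequence_to_clone: dict[str, str]
    clone_members: dict[str, list[str]]
    clone_info: dict[str, dict] = field(default_factory=dict)
    n_missing_junction: int = 0

    def __post_init__(self) -> None:
        flattened = [s for members in self.clone_members.values() for s in members]
        if len(flattened) != len(set(flattened)) or set(flattened) != set(
            self.sequence_to_clone
        ):
            raise ValueError("clone membership is not a partition")

    @property
    def n_clones(self) -> int:
        return len(self.clone_members)

    def to_tsv(self, path) -> None:
        """Two-column export (sequence_id, clone_id), mergeable into AIRR files."""
        with open(path, "w") as fh:
            fh.write("sequence_id\tclone_id\n")
            for sid, cid in self.sequence_to_clone.items():
                fh.write(f"{sid}\t{cid}\n")


@dataclass
class AbundanceProfile:
    """Relative clone abundances p_i (sum to one)."""

    abundances: dict[str, float]
    weighting: str  # "sequence-count" | "duplicate-count"

    def __post_init__(self) -> None:
        values = np.array(list(self.abundances.values()), dtype=float)
        if (values < 0).any() or abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.abundances.values()), dtype=float)


def junction_distance(a: str, b: str) -> float:
    """Normalised Hamming distance between equal-length junctions.

    Positions where either base is N are ignored (not mismatches).
    """
    if len(a) != len(b):
        raise ValueError("junctions must have equal length")
    if not a:
        return 0.0
    mismatches = sum(
        1 for x, y in zip(a, b) if x != y and x != "N" and y != "N"
    )
    return mismatches / len(a)


def _single_linkage_components(junctions: list[str], threshold: float) -> list[int]:
    """Component label per junction under single linkage cut at `threshold`.

    Union-find over all pairs at distance <= threshold; equivalent to cutting
    the single-linkage dendrogram since merging is transitive closure.
    """
    n = len(junctions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if junction_distance(junctions[i], junctions[j]) <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return [find(i) for i in range(n)]


def partition_clones(
    repertoire: Repertoire, threshold: float = 0.15
) -> CloneAssignment:
    """Partition a repertoire into clones.

    Records are first grouped by (V gene, J gene, junction length); within a
    group, single-linkage clustering on normalised junction Hamming distance
    is cut at ``threshold``.  Records without a junction become singleton
    clones.  Clone ids are deterministic given record order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    groups: dict[tuple, list[RearrangementRecord]] = {}
    missing: list[RearrangementRecord] = []
    for rec in repertoire:
        if not rec.junction:
            missing.append(rec)
            continue
        groups.setdefault((rec.v_gene, rec.j_gene, len(rec.junction)), []).append(rec)

    sequence_to_clone: dict[str, str] = {}
    clone_members: dict[str, list[str]] = {}
    clone_info: dict[str, dict] = {}
    clone_counter = 0
    # sort groups for order-invariance of the partition (labels may differ)
    for key in sorted(groups):
        recs = groups[key]
        labels = _single_linkage_components([r.junction for r in recs], threshold)
        for comp in sorted(set(labels)):
            clone_counter += 1
            cid = f"clone_{clone_counter}"
            members = [r.sequence_id for r, l in zip(recs, labels) if l == comp]
            clone_members[cid] = members
            clone_info[cid] = {
                "v_gene": key[0],
                "j_gene": key[1],
                "junction_length": key[2],
            }
            for sid in members:
                sequence_to_clone[sid] = cid
    for rec in missing:
        clone_counter += 1
        cid = f"clone_{clone_counter}"
        clone_members[cid] = [rec.sequence_id]
        clone_info[cid] = {
            "v_gene": rec.v_gene,
            "j_gene": rec.j_gene,
            "junction_length": None,
        }
        sequence_to_clone[rec.sequence_id] = cid
    return CloneAssignment(
        sequence_to_clone, clone_members, clone_info, n_missing_junction=len(missing)
    )


def clone_abundance(
    assignment: CloneAssignment,
    repertoire: Repertoire | None = None,
    weighting: str = "sequence-count",
) -> AbundanceProfile:
    """Relative abundance per clone.

    ``sequence-count`` weights each unique sequence equally;
    ``duplicate-count`` weights by the record's duplicate_count (missing
    counts fall back to 1) and needs the repertoire for lookup.
    """
    if weighting not in ("sequence-count", "duplicate-count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "duplicate-count":
        if repertoire is None:
            raise ValueError("duplicate-count weighting requires the repertoire")
        counts = {
            r.sequence_id: (r.duplicate_count or 1) for r in repertoire
        }
        weights = {
            cid: float(sum(counts[s] for s in members))
            for cid, members in assignment.clone_members.items()
        }
    else:
        weights = {
            cid: float(len(members))
            for cid, members in assignment.clone_members.items()
        }
    total = sum(weights.values())
    return AbundanceProfile(
        {cid: w / total for cid, w in weights.items()}, weighting
    )


def select_representatives(
    repertoire: Repertoire, assignment: CloneAssignment
) -> Repertoire:
    """One record per clone: highest duplicate_count, ties by smallest sequence_id."""
    by_id = {r.sequence_id: r for r in repertoire}
    order = {r.sequence_id: i for i, r in enumerate(repertoire)}
    reps: list[RearrangementRecord] = []
    for cid in assignment.clone_members:
        members = [by_id[s] for s in assignment.clone_members[cid]]
        best = min(members, key=lambda r: (-(r.duplicate_count or 1), r.sequence_id))
        reps.append(best)
    reps.sort(key=lambda r: order[r.sequence_id])
    return Repertoire(repertoire.subject_id, reps, dict(repertoire.metadata))


def attach_clone_ids(repertoire: Repertoire, assignment: CloneAssignment) -> Repertoire:
    """Return a copy of the repertoire with clone_id filled from the assignment."""
    records = []
    for rec in repertoire:
        new = RearrangementRecord(
            sequence_id=rec.sequence_id,
            v_call=rec.v_call,
            j_call=rec.j_call,
            junction=rec.junction,
            junction_aa=rec.junction_aa,
            sequence_alignment=rec.sequence_alignment,
            germline_alignment=rec.germline_alignment,
            d_call=rec.d_call,
            duplicate_count=rec.duplicate_count,
            clone_id=assignment.sequence_to_clone[rec.sequence_id],
            extras=dict(rec.extras),
        )
        records.append(new)
    return Repertoire(repertoire.subject_id, records, dict(repertoire.metadata))
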