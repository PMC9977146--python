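"""Repertoire-level features: gene usage, CDR3 k-mers, clusters, diversity.

Everything here reduces one repertoire (or a cohort) to named numeric
features that the classifier consumes.  Frequency families are normalised
to sum to one within a repertoire; the default weighting counts each unique
sequence once (DNA libraries sample cells uniformly), with clone- and
duplicate-count weighting available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airr_io import Cohort, Repertoire
from .clones import AbundanceProfile, clone_abundance, partition_clones
from . import shm


@dataclass
class FeatureTable:
    """Subjects x features matrix with a family tag per column."""

    values: pd.DataFrame                 # index = subject_ids
    families: pd.Series = field(default=None)  # feature name -> family tag

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate subjects in feature table")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.families is None:
            self.families = pd.Series("unknown", index=self.values.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.families[out.columns], out.columns], names=["family", "feature"]
        )
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        families = pd.Series(
            df.columns.get_level_values(0), index=df.columns.get_level_values(1)
        )
        df.columns = df.columns.get_level_values(1)
        return cls(df, families)


@dataclass
class DiversityProfile:
    """Hill numbers D_q along a q grid; non-increasing in q."""

    q_values: np.ndarray
    d_values: np.ndarray


def _clone_weights(
    repertoire: Repertoire, weighting: str, assignment=None
) -> pd.DataFrame:
    """Per-record weights: clone weighting gives each clone's representative 1."""
    if weighting == "clone":
        assignment = assignment or partition_clones(repertoire)
        from .clones import select_representatives

        reps = select_representatives(repertoire, assignment)
        return pd.DataFrame(
            {
                "v_gene": [r.v_gene for r in reps],
                "j_gene": [r.j_gene for r in reps],
                "weight": 1.0,
            }
        )
    if weighting == "sequence":
        return pd.DataFrame(
            {
                "v_gene": [r.v_gene for r in repertoire],
                "j_gene": [r.j_gene for r in repertoire],
                "weight": 1.0,
            }
        )
    raise ValueError(f"unknown weighting {weighting!r}")


def v_gene_usage(
    repertoire: Repertoire,
    level: str = "gene",
    weighting: str = "sequence",
    assignment=None,
) -> pd.Series:
    """V gene (or family) usage frequencies, summing to 1."""
    df = _clone_weights(repertoire, weighting, assignment)
    if level == "family":
        keys = df["v_gene"].str.split("-").str[0]
    elif level == "gene":
        keys = df["v_gene"]
    else:
        raise ValueError(f"unknown level {level!r}")
    counts = df.groupby(keys)["weight"].sum()
    return (counts / counts.sum()).sort_index()


def vj_gene_usage(
    repertoire: Repertoire, weighting: str = "sequence", assignment=None
) -> pd.Series:
    """(V gene, J gene) pair usage frequencies, summing to 1."""
    df = _clone_weights(repertoire, weighting, assignment)
    keys = df["v_gene"] + "|" + df["j_gene"]
    counts = df.groupby(keys)["weight"].sum()
    return (counts / counts.sum()).sort_index()


def cdr3_kmer_frequencies(repertoire: Repertoire, k: int = 3) -> pd.Series:
    """Amino-acid k-mer frequencies over all CDR3s (junction minus flanks)."""
    counts: dict[str, int] = {}
    for rec in repertoire:
        cdr3 = rec.cdr3_aa
        if len(cdr3) < k:
            continue
        for i in range(len(cdr3) - k + 1):
            kmer = cdr3[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    if not counts:
        return pd.Series(dtype=float)
    series = pd.Series(counts, dtype=float).sort_index()
    return series / series.sum()


def _vjl_triples(repertoire: Repertoire) -> pd.Series:
    keys = pd.Series(
        [f"{r.v_gene}|{r.j_gene}|{len(r.cdr3_aa)}" for r in repertoire]
    )
    counts = keys.value_counts()
    return counts / counts.sum()


def vjl_cluster_features(cohort: Cohort, min_freq: float = 0.001) -> FeatureTable:
    """Frequencies of large (V gene, J gene, CDR3 length) clusters.

    A triple is kept when its frequency reaches ``min_freq`` (inclusive) in
    at least one subject; kept triples are reported for every subject
    (absent = 0).
    """
    per_subject = {r.subject_id: _vjl_triples(r) for r in cohort.repertoires}
    keep: set[str] = set()
    for freqs in per_subject.values():
        keep.update(freqs.index[freqs >= min_freq])
    columns = sorted(keep)
    table = pd.DataFrame(
        {s: f.reindex(columns).fillna(0.0) for s, f in per_subject.items()}
    ).T
    return FeatureTable(table, pd.Series("vjl_clusters", index=table.columns))


def cdr3_identity_cluster_features(
    cohort: Cohort, identity: float = 0.85, min_freq: float = 0.001
) -> FeatureTable:
    """Cross-subject greedy CDR3 identity clusters within V/J/length triples.

    CDR3s are pooled across subjects per (V gene, J gene, length) triple and
    clustered greedily: in canonical order (descending total count, then
    lexical), a sequence joins the first centroid with AA identity
    (matches/length) >= ``identity``, else founds a new centroid.  Features
    are per-subject frequencies of clusters reaching ``min_freq`` in at
    least one subject.
    """
    pooled: dict[str, dict[str, dict[str, int]]] = {}
    totals: dict[str, int] = {}
    for rep in cohort.repertoires:
        totals[rep.subject_id] = len(rep)
        for rec in rep:
            cdr3 = rec.cdr3_aa
            if not cdr3:
                continue
            triple = f"{rec.v_gene}|{rec.j_gene}|{len(cdr3)}"
            bucket = pooled.setdefault(triple, {})
            per_subj = bucket.setdefault(cdr3, {})
            per_subj[rep.subject_id] = per_subj.get(rep.subject_id, 0) + 1

    cluster_counts: dict[str, dict[str, int]] = {}
    for triple in sorted(pooled):
        seqs = pooled[triple]
        ordered = sorted(
            seqs, key=lambda s: (-sum(seqs[s].values()), s)
        )
        centroids: list[str] = []
        for seq in ordered:
            home = None
            for centroid in centroids:
                matches = sum(a == b for a, b in zip(seq, centroid))
                if matches / len(seq) >= identity:
                    home = centroid
                    break
            if home is None:
                centroids.append(seq)
                home = seq
            name = f"{triple}|{home}"
            counts = cluster_counts.setdefault(name, {})
            for subj, n in seqs[seq].items():
                counts[subj] = counts.get(subj, 0) + n

    freq = pd.DataFrame(cluster_counts).fillna(0.0)
    freq = freq.div(pd.Series(totals), axis=0)
    keep = freq.columns[(freq >= min_freq).any(axis=0)]
    table = (
        freq[sorted(keep)]
        .reindex([r.subject_id for r in cohort.repertoires])
        .fillna(0.0)
    )
    return FeatureTable(
        table, pd.Series("cdr3_identity_clusters", index=table.columns)
    )


def hill_diversity(
    profile: AbundanceProfile, q_values: list[float]
) -> DiversityProfile:
    """Hill numbers D_q = (sum p_i^q)^(1/(1-q)); D_1 via the Shannon limit."""
    p = profile.as_array()
    p = p[p > 0]
    q_arr = np.asarray(q_values, dtype=float)
    if (q_arr < 0).any():
        raise ValueError("q values must be non-negative")
    d = np.empty_like(q_arr)
    for i, q in enumerate(q_arr):
        if abs(q - 1.0) < 1e-12:
            d[i] = np.exp(-np.sum(p * np.log(p)))
        else:
            d[i] = np.sum(p**q) ** (1.0 / (1.0 - q))
    return DiversityProfile(q_arr, d)


def repertoire_percentiles(repertoire: Repertoire) -> pd.Series:
    """10/50/90 percentiles of CDR3 AA length and of germline identity.

    Germline identity is matching/informative positions over the V region
    (gapped positions 1..312) of each alignment; percentiles use linear
    interpolation between order statistics.
    """
    lengths, identities = [], []
    for rec in repertoire:
        lengths.append(len(rec.cdr3_aa))
        g = rec.germline_alignment[: shm.IMGT_V_LENGTH]
        s = rec.sequence_alignment[: shm.IMGT_V_LENGTH]
        pairs = [
            (a, b)
            for a, b in zip(g, s)
            if a in shm.NUCLEOTIDES and b in shm.NUCLEOTIDES
        ]
        if pairs:
            identities.append(sum(a == b for a, b in pairs) / len(pairs))
    out = {}
    for name, data in (("cdr3_length", lengths), ("germline_identity", identities)):
        pct = np.percentile(data, [10, 50, 90]) if data else [np.nan] * 3
        for p, v in zip((10, 50, 90), pct):
            out[f"{name}_p{p}"] = float(v)
    return pd.Series(out)


#: implemented feature families for assemble_feature_table
FEATURE_FAMILIES = (
    "v_usage",
    "vj_usage",
    "cdr3_kmers",
    "vjl_clusters",
    "cdr3_identity_clusters",
    "shm_5mer",
    "shm_3mer",
    "shm_wa_tw",
    "shm_wrc_gyw",
    "shm_synonymous",
    "percentiles",
)


def _shm_feature_vectors(
    cohort: Cohort,
    family: str,
    models: dict[str, shm.TargetingModel] | None,
    parts: tuple[str, ...],
    min_background: int,
) -> dict[str, pd.Series]:
    vectors = {}
    for rep in cohort.repertoires:
        synonymous = family == "shm_synonymous"
        if models is not None and not synonymous:
            model = models[rep.subject_id]
        else:
            model = shm.estimate_targeting_model(
                rep, synonymous_only=synonymous, min_background=min_background
            )
        if family == "shm_3mer":
            vec = shm.collapse_to_3mer(model).to_series()
            vec.index = "mut3|" + vec.index
        else:
            motif = {"shm_wa_tw": shm.WA_TW, "shm_wrc_gyw": shm.WRC_GYW}.get(family)
            vec = shm.flatten_model_features(model, parts=parts, motif_filter=motif)
        vectors[rep.subject_id] = vec
    return vectors


def assemble_feature_table(
    cohort: Cohort,
    families: tuple[str, ...],
    shm_parts: tuple[str, ...] = ("mutability", "substitution", "targeting"),
    min_background: int = 10,
    shm_models: dict[str, shm.TargetingModel] | None = None,
    kmer_k: int = 3,
) -> FeatureTable:
    """Column-aligned feature table across the cohort's subjects.

    ``shm_models`` lets callers reuse per-subject targeting models across
    several SHM-derived families instead of re-estimating them.
    """
    if not families:
        raise ValueError("need at least one feature family")
    if bad := set(families) - set(FEATURE_FAMILIES):
        raise ValueError(f"unknown feature families {sorted(bad)}")
    blocks: list[pd.DataFrame] = []
    tags: list[pd.Series] = []
    subject_order = [r.subject_id for r in cohort.repertoires]
    for family in families:
        if family in ("v_usage", "vj_usage", "cdr3_kmers", "percentiles"):
            fn = {
                "v_usage": lambda r: v_gene_usage(r).rename(lambda n: f"v|{n}"),
                "vj_usage": lambda r: vj_gene_usage(r).rename(lambda n: f"vj|{n}"),
                "cdr3_kmers": lambda r: cdr3_kmer_frequencies(r, kmer_k).rename(
                    lambda n: f"kmer|{n}"
                ),
                "percentiles": repertoire_percentiles,
            }[family]
            block = pd.DataFrame({r.subject_id: fn(r) for r in cohort.repertoires}).T
            if family != "percentiles":
                block = block.fillna(0.0)
        elif family == "vjl_clusters":
            block = vjl_cluster_features(cohort).values
        elif family == "cdr3_identity_clusters":
            block = cdr3_identity_cluster_features(cohort).values
        else:
            vectors = _shm_feature_vectors(
                cohort, family, shm_models, shm_parts, min_background
            )
            block = pd.DataFrame(vectors).T
            block.columns = [f"{family}:{c}" for c in block.columns]
        if block.shape[1] == 0:
            raise ValueError(f"feature family {family!r} produced no features")
        block = block.reindex(subject_order)
        blocks.append(block)
        tags.append(pd.Series(family, index=block.columns))
    values = pd.concat(blocks, axis=1)
    return FeatureTable(values, pd.concat(tags))
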