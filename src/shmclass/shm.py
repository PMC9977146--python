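"""Per-repertoire 5-mer somatic-hypermutation targeting models.

The SHM machinery mutates B-cell receptor genes in a strongly
context-dependent way: AID deaminates cytosines in WRC/GYW motifs and the
error-prone polymerase eta leaves mutations at WA/TW motifs (IUPAC
W = {A,T}, R = {A,G}, Y = {C,T}; the mutated position is the motif's
centre).  This module estimates, for one repertoire, the empirical 5-mer
*mutability* (probability that a mutation falls in a given germline 5-mer
context), the per-5-mer *substitution* profile (distribution over the three
replacement bases), and their product, the *targeting* model — the same
decomposition popularised by the S5F family of models.  Mutations are
counted by comparing each observed sequence with its inferred germline, so
the estimate reflects the combined effect of SHM targeting and
affinity-dependent selection.

Alignments are IMGT-gapped; contexts are always read from the gap-stripped
germline, windows that run off either end of the sequence are uninformative
(no padding), and multiple mutations in one sequence are each counted
against the unmutated germline context.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .airr_io import GAP, Repertoire, RearrangementRecord

NUCLEOTIDES = "ACGT"
ALL_FIVEMERS = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=5)]
ALL_THREEMERS = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]

WA_TW = "WA/TW"
WRC_GYW = "WRC/GYW"
NEUTRAL = "neutral"

_W = set("AT")
_R = set("AG")
_Y = set("CT")

# byte-code lookup: A,C,G,T -> 0..3, gap -> 4, anything else (N...) -> 5
_CODE = np.full(256, 5, dtype=np.int8)
for _i, _b in enumerate(NUCLEOTIDES):
    _CODE[ord(_b)] = _i
_CODE[ord(GAP)] = 4

# IMGT unique-numbering region boundaries on gapped V coordinates (1-based)
IMGT_V_REGIONS = (
    (1, 78, "FWR"),    # FR1
    (79, 114, "CDR"),  # CDR1
    (115, 165, "FWR"), # FR2
    (166, 195, "CDR"), # CDR2
    (196, 312, "FWR"), # FR3
)
IMGT_V_LENGTH = 312

_CODON_TABLE = {
    "".join(c): aa
    for c, aa in zip(
        itertools.product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}


def classify_hotspot(fivemer: str) -> str | None:
    """Classify a 5-mer as WA/TW, WRC/GYW or neutral (None if non-ACGT).

    WA: centre A preceded by W.  TW: centre T followed by W.  WRC: centre C
    with W,R at the two preceding positions.  GYW: centre G followed by Y
    then W.  The classes partition the 1024 ACGT 5-mers (disjoint by central
    base: A/T can only be WA/TW, C/G only WRC/GYW).
    """
    if len(fivemer) != 5 or any(b not in NUCLEOTIDES for b in fivemer):
        return None
    centre = fivemer[2]
    if centre == "A":
        return WA_TW if fivemer[1] in _W else NEUTRAL
    if centre == "T":
        return WA_TW if fivemer[3] in _W else NEUTRAL
    if centre == "C":
        return WRC_GYW if fivemer[0] in _W and fivemer[1] in _R else NEUTRAL
    return WRC_GYW if fivemer[3] in _Y and fivemer[4] in _W else NEUTRAL


#: motif class per 5-mer index, aligned with ALL_FIVEMERS
MOTIF_CLASSES = np.array([classify_hotspot(w) for w in ALL_FIVEMERS])


@dataclass
class Mutation:
    """A single germline->observed point mutation."""

    sequence_id: str
    position: int  # 1-based on the gapped alignment
    context: str | None  # germline 5-mer, None when uninformative
    from_base: str
    to_base: str
    region: str = "unknown"  # FWR | CDR | unknown
    synonymy: str = "ambiguous"

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("from_base and to_base must differ")
        if self.context is not None and self.context[2] != self.from_base:
            raise ValueError("context centre must equal from_base")


def region_of_position(position: int) -> str:
    """IMGT region (FWR/CDR) of a 1-based gapped V position; unknown past FR3."""
    for start, end, name in IMGT_V_REGIONS:
        if start <= position <= end:
            return name
    return "unknown"


_REGION_CACHE: dict[int, np.ndarray] = {}


def _region_codes(length: int) -> np.ndarray:
    """0=FWR, 1=CDR, 2=unknown per gapped column, cached per length."""
    if length not in _REGION_CACHE:
        names = [region_of_position(p) for p in range(1, length + 1)]
        _REGION_CACHE[length] = np.array(
            [{"FWR": 0, "CDR": 1, "unknown": 2}[n] for n in names], dtype=np.int8
        )
    return _REGION_CACHE[length]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class _AlignmentView:
    """Vectorised view of one aligned record used by the estimators."""

    stripped_cols: np.ndarray   # gapped column index (0-based) per germline base
    germ: np.ndarray            # codes of gap-stripped germline
    obs: np.ndarray             # codes of observed bases at those columns
    centres: np.ndarray         # stripped indices with a full ACGT 5-mer window
    fivemers: np.ndarray        # 5-mer index per centre
    region: np.ndarray          # region code per centre (0 FWR, 1 CDR, 2 unknown)


def _view(record: RearrangementRecord) -> _AlignmentView:
    g = _encode(record.germline_alignment)
    o = _encode(record.sequence_alignment)
    stripped_cols = np.flatnonzero(g != 4)
    germ = g[stripped_cols]
    obs = o[stripped_cols]
    ok = germ < 4
    n = len(germ)
    if n >= 5:
        win_ok = ok[:-4] & ok[1:-3] & ok[2:-2] & ok[3:-1] & ok[4:]
        centres = np.flatnonzero(win_ok) + 2
        g64 = germ.astype(np.int64)
        fivemers = (
            g64[centres - 2] * 256
            + g64[centres - 1] * 64
            + g64[centres] * 16
            + g64[centres + 1] * 4
            + g64[centres + 2]
        )
    else:
        centres = np.empty(0, dtype=np.int64)
        fivemers = np.empty(0, dtype=np.int64)
    region = _region_codes(len(g))[stripped_cols[centres]] if len(centres) else (
        np.empty(0, dtype=np.int8)
    )
    return _AlignmentView(stripped_cols, germ, obs, centres, fivemers, region)


def enumerate_mutations(
    record: RearrangementRecord, region_mask: set[str] | None = None
) -> list[Mutation]:
    """List all point mutations of a record against its germline.

    A mutation needs germline and observed base both in ACGT; its 5-mer
    context is read from the gap-stripped germline and is None
    (uninformative) when the window runs off an end or contains a non-ACGT
    character.  ``region_mask`` keeps only mutations in the given regions.
    """
    view = _view(record)
    informative = set(view.centres.tolist())
    region_names = np.array(["FWR", "CDR", "unknown"])
    out: list[Mutation] = []
    gapped_regions = _region_codes(len(record.germline_alignment))
    for i in np.flatnonzero((view.germ < 4) & (view.obs < 4) & (view.germ != view.obs)):
        col = int(view.stripped_cols[i])
        region = str(region_names[gapped_regions[col]])
        if region_mask is not None and region not in region_mask:
            continue
        if i in informative:
            ctx = "".join(NUCLEOTIDES[c] for c in view.germ[i - 2 : i + 3])
        else:
            ctx = None
        mut = Mutation(
            sequence_id=record.sequence_id,
            position=col + 1,
            context=ctx,
            from_base=NUCLEOTIDES[view.germ[i]],
            to_base=NUCLEOTIDES[view.obs[i]],
            region=region,
        )
        mut.synonymy = classify_synonymy(record, mut)
        out.append(mut)
    return out


def classify_synonymy(record: RearrangementRecord, mutation: Mutation) -> str:
    """Synonymy of a single mutation against the germline codon.

    The reading frame starts at position 1 of the gapped alignment and IMGT
    gaps occur in codon triplets, so codons are consecutive gapped-column
    triplets.  Codons containing gaps or non-ACGT characters are ambiguous.
    """
    codon_idx = (mutation.position - 1) // 3
    start = codon_idx * 3
    codon = record.germline_alignment[start : start + 3]
    if len(codon) < 3 or any(b not in NUCLEOTIDES for b in codon):
        return "ambiguous"
    offset = (mutation.position - 1) % 3
    if codon[offset] != mutation.from_base:
        return "ambiguous"
    mutated = codon[:offset] + mutation.to_base + codon[offset + 1 :]
    aa_from, aa_to = _CODON_TABLE[codon], _CODON_TABLE[mutated]
    if aa_to == "*":
        return "stop"
    return "synonymous" if aa_from == aa_to else "nonsynonymous"


@dataclass
class TargetingModel:
    """5-mer mutability, substitution and targeting for one repertoire.

    Arrays are indexed by :data:`ALL_FIVEMERS`; absent entries are NaN.
    Present mutability values sum to 1; each present substitution row sums
    to 1 over the three non-centre bases.
    """

    mutability: np.ndarray          # (1024,) float, NaN = absent
    substitution: np.ndarray        # (1024, 4) float, NaN rows absent
    mutation_count: np.ndarray      # (1024,) int
    background_count: np.ndarray    # (1024,) int
    options: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return int(self.mutation_count.sum()) == 0

    @property
    def targeting(self) -> np.ndarray:
        return self.mutability[:, None] * self.substitution

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.mutability)

    def validate(self) -> None:
        present = self.present
        if present.any():
            total = np.nansum(self.mutability[present])
            if abs(total - 1.0) > 1e-9:
                raise ValueError("present mutability does not sum to 1")
        sub_present = ~np.isnan(self.substitution).all(axis=1)
        rows = np.nansum(self.substitution[sub_present], axis=1)
        if sub_present.any() and np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError("substitution rows do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "fivemer": ALL_FIVEMERS,
                "mutability": self.mutability,
                "mutation_count": self.mutation_count,
                "background_count": self.background_count,
            }
        )
        for b_idx, base in enumerate(NUCLEOTIDES):
            df[f"sub_{base}"] = self.substitution[:, b_idx]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TargetingModel":
        df = pd.read_csv(path, sep="\t").set_index("fivemer").reindex(ALL_FIVEMERS)
        sub = df[[f"sub_{b}" for b in NUCLEOTIDES]].to_numpy(dtype=float)
        return cls(
            mutability=df["mutability"].to_numpy(dtype=float),
            substitution=sub,
            mutation_count=df["mutation_count"].fillna(0).to_numpy(dtype=int),
            background_count=df["background_count"].fillna(0).to_numpy(dtype=int),
        )


def estimate_targeting_model(
    repertoire: Repertoire,
    synonymous_only: bool = False,
    region_mask: set[str] | None = None,
    representatives_only: bool = False,
    clone_assignment=None,
    min_background: int = 10,
) -> TargetingModel:
    """Estimate the 5-mer targeting model of one repertoire.

    Background counts are germline 5-mer occurrences at informative
    positions (full ACGT window, region mask applied); mutation counts are
    mutations whose germline context is that 5-mer.  Raw mutability is
    mutations/background where the background reaches ``min_background``
    (absent below it — absent, not zero), then normalised to sum to 1 over
    present 5-mers.  ``synonymous_only`` restricts mutation counts to
    synonymous mutations while keeping the all-position background.
    """
    if representatives_only:
        from .clones import partition_clones, select_representatives

        assignment = clone_assignment or partition_clones(repertoire)
        repertoire = select_representatives(repertoire, assignment)

    region_keep = None
    if region_mask is not None:
        code_of = {"FWR": 0, "CDR": 1, "unknown": 2}
        region_keep = np.array([code_of[r] for r in region_mask], dtype=np.int8)

    background = np.zeros(1024, dtype=np.int64)
    mut_count = np.zeros(1024, dtype=np.int64)
    sub_count = np.zeros((1024, 4), dtype=np.int64)
    for record in repertoire:
        view = _view(record)
        centres, fivemers, regions = view.centres, view.fivemers, view.region
        if region_keep is not None and len(centres):
            keep = np.isin(regions, region_keep)
            centres, fivemers = centres[keep], fivemers[keep]
        if not len(centres):
            continue
        np.add.at(background, fivemers, 1)
        obs_at = view.obs[centres]
        is_mut = (obs_at < 4) & (obs_at != view.germ[centres])
        if not is_mut.any():
            continue
        mut_centres = centres[is_mut]
        mut_fivemers = fivemers[is_mut]
        mut_obs = obs_at[is_mut]
        if synonymous_only:
            keep_syn = []
            for c, w, o in zip(mut_centres, mut_fivemers, mut_obs):
                m = Mutation(
                    sequence_id=record.sequence_id,
                    position=int(view.stripped_cols[c]) + 1,
                    context=ALL_FIVEMERS[w],
                    from_base=NUCLEOTIDES[view.germ[c]],
                    to_base=NUCLEOTIDES[o],
                )
                keep_syn.append(classify_synonymy(record, m) == "synonymous")
            keep_syn = np.array(keep_syn, dtype=bool)
            mut_fivemers, mut_obs = mut_fivemers[keep_syn], mut_obs[keep_syn]
        np.add.at(mut_count, mut_fivemers, 1)
        np.add.at(sub_count, (mut_fivemers, mut_obs), 1)

    mutability = np.full(1024, np.nan)
    present = background >= max(min_background, 1)
    raw = mut_count[present] / background[present]
    total = raw.sum()
    if total > 0:
        mutability[present] = raw / total
    substitution = np.full((1024, 4), np.nan)
    row_tot = sub_count.sum(axis=1)
    has_sub = row_tot > 0
    substitution[has_sub] = sub_count[has_sub] / row_tot[has_sub, None]
    model = TargetingModel(
        mutability=mutability,
        substitution=substitution,
        mutation_count=mut_count,
        background_count=background,
        options={
            "synonymous_only": synonymous_only,
            "region_mask": sorted(region_mask) if region_mask else None,
            "representatives_only": representatives_only,
            "min_background": min_background,
        },
    )
    model.validate()
    return model


@dataclass
class ThreemerModel:
    """Central-3-mer mutability collapsed from a 5-mer model."""

    mutability: np.ndarray        # (64,) float, NaN = absent
    background_count: np.ndarray  # (64,) int, collapse weights

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.mutability)

    def to_series(self) -> pd.Series:
        return pd.Series(self.mutability, index=ALL_THREEMERS)


def collapse_to_3mer(model: TargetingModel) -> ThreemerModel:
    """Collapse 5-mer mutability to the 64 central 3-mers.

    Each 3-mer value is the background-weighted mean of its 16 constituent
    5-mers' mutabilities (positions 2-4 equal the 3-mer), renormalised to
    sum to 1 over present 3-mers.
    """
    if model.degenerate or not model.present.any():
        raise ValueError("cannot collapse a degenerate targeting model")
    values = np.full(64, np.nan)
    weights = np.zeros(64, dtype=np.int64)
    fivemer_inner = np.arange(1024) % 256 // 4  # index of positions 2-4
    for m in range(64):
        members = np.flatnonzero(fivemer_inner == m)
        ok = members[model.present[members]]
        if not len(ok):
            continue
        bg = model.background_count[ok]
        if bg.sum() == 0:
            continue
        values[m] = np.average(model.mutability[ok], weights=bg)
        weights[m] = bg.sum()
    present = ~np.isnan(values)
    total = values[present].sum()
    if total > 0:
        values[present] = values[present] / total
    return ThreemerModel(values, weights)


_PART_NAMES = ("mutability", "substitution", "targeting")


def flatten_model_features(
    model: TargetingModel,
    parts: tuple[str, ...] = _PART_NAMES,
    motif_filter: str | None = None,
) -> pd.Series:
    """Flatten a model into a named feature vector.

    Names are ``mut|AACGT``, ``sub|AACGT>T``, ``targ|AACGT>T``; absent
    entries are NaN.  ``motif_filter`` keeps only 5-mers of that motif
    class (WA/TW or WRC/GYW).
    """
    if not parts:
        raise ValueError("parts must be non-empty")
    if bad := set(parts) - set(_PART_NAMES):
        raise ValueError(f"unknown parts {sorted(bad)}")
    keep = np.ones(1024, dtype=bool)
    if motif_filter is not None:
        keep = MOTIF_CLASSES == motif_filter
    names: list[str] = []
    values: list[float] = []
    if "mutability" in parts:
        for w_idx in np.flatnonzero(keep):
            names.append(f"mut|{ALL_FIVEMERS[w_idx]}")
            values.append(model.mutability[w_idx])
    for part, tag, matrix in (
        ("substitution", "sub", model.substitution),
        ("targeting", "targ", model.targeting),
    ):
        if part not in parts:
            continue
        for w_idx in np.flatnonzero(keep):
            centre = ALL_FIVEMERS[w_idx][2]
            for b_idx, base in enumerate(NUCLEOTIDES):
                if base == centre:
                    continue
                names.append(f"{tag}|{ALL_FIVEMERS[w_idx]}>{base}")
                values.append(matrix[w_idx, b_idx])
    return pd.Series(values, index=names, dtype=float)


def motif_of_feature(name: str) -> str | None:
    """Motif class of a flattened feature name."""
    fivemer = name.split("|")[1].split(">")[0]
    return classify_hotspot(fivemer)


def compare_cohort_models(
    feature_vectors: dict[str, pd.Series], labels: dict[str, str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-feature case/control comparison plus per-motif-class Spearman.

    Returns a table (mean_case, mean_control, t, p_value, motif) over
    features present in at least half the subjects, and the Spearman rho of
    (mean_control, mean_case) within each motif class.
    """
    table = pd.DataFrame(feature_vectors).T  # subjects x features
    y = np.array([labels[s] == "case" for s in table.index])
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two subjects per class")
    coverage = table.notna().mean(axis=0)
    table = table.loc[:, coverage >= 0.5]
    rows = []
    for name in table.columns:
        col = table[name]
        a, b = col[y].dropna(), col[~y].dropna()
        if len(a) < 2 or len(b) < 2 or (col.dropna().nunique() <= 1):
            continue  # constant or underpowered feature: p undefined, dropped
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "feature": name,
                "mean_case": a.mean(),
                "mean_control": b.mean(),
                "t": t,
                "p_value": p,
                "motif": motif_of_feature(name),
            }
        )
    result = pd.DataFrame(rows).set_index("feature")
    spearman: dict[str, float] = {}
    for motif in (WA_TW, WRC_GYW, NEUTRAL):
        sub = result[result["motif"] == motif]
        if len(sub) >= 3:
            rho, _ = stats.spearmanr(sub["mean_control"], sub["mean_case"])
            spearman[motif] = float(rho)
    return result, spearman


GENERALIZED_MOTIFS = ("AAN", "TAN", "NTT", "NTA")


def _motif_members(motif: str) -> list[str]:
    choices = [NUCLEOTIDES if b == "N" else b for b in motif]
    return ["".join(p) for p in itertools.product(*choices)]


def motif_ratio_summary(
    threemer_models: dict[str, ThreemerModel], labels: dict[str, str]
) -> dict[str, pd.Series]:
    """Case/control mean-mutability ratios per generalised 3-mer motif.

    For each of AAN, TAN, NTT, NTA, returns the member 3-mers' ratios
    mean(case)/mean(control); members with zero (or absent) control mean
    are excluded.
    """
    table = pd.DataFrame(
        {s: m.to_series() for s, m in threemer_models.items()}
    ).T  # subjects x 64
    y = np.array([labels[s] == "case" for s in table.index])
    mean_case = table[y].mean(axis=0)
    mean_control = table[~y].mean(axis=0)
    out: dict[str, pd.Series] = {}
    for motif in GENERALIZED_MOTIFS:
        ratios = {}
        for member in _motif_members(motif):
            mc, mctl = mean_case[member], mean_control[member]
            if pd.isna(mctl) or mctl == 0 or pd.isna(mc):
                continue
            ratios[member] = mc / mctl
        out[motif] = pd.Series(ratios, dtype=float)
    return out
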