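"""Synthetic AIRR cohorts with VDJ structure, clonal expansion and SHM.

The generator builds what the estimation pipeline assumes real data look
like: each subject's repertoire is a set of clones founded by a VDJ
recombination event (toy germline segments, IMGT-gapped V), expanded under
a power-law clone-size distribution, with each sequence mutated under a
context-dependent 5-mer targeting model.  Case subjects can receive a
multiplicative shift of the mutability of one hotspot motif class
(e.g. WA/TW x 1.5), emulating a group-level difference in polymerase-eta
activity, so the whole analysis — model estimation, hotspot dissection,
classification — is testable end to end with known ground truth.

The toy germline set is synthetic (generated from a frozen seed with
IGHV-like structure: 312-column IMGT-gapped V ending in the conserved
cysteine codon, J segments carrying the conserved tryptophan) rather than
database content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .airr_io import Cohort, GermlineReference, RearrangementRecord, Repertoire
from . import shm
from .shm import ALL_FIVEMERS, Mutation, TargetingModel

_STOP_FREE_CODONS = [
    c for c in shm._CODON_TABLE if shm._CODON_TABLE[c] != "*"
]

#: frozen seeds: the toy reference and baseline model are fixed study
#: conditions, independent of the user's master seed
_GERMLINE_SEED = 202301
_BASELINE_MODEL_SEED = 202302


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_STOP_FREE_CODONS) for _ in range(n))


def default_germline_reference() -> GermlineReference:
    """Deterministic toy germline set: 10 V, 6 D, 4 J segments.

    V segments span the 312 IMGT positions with per-gene gap blocks (whole
    codons) inside CDR1/CDR2, end with the conserved TGT cysteine codon,
    and are free of in-frame stops.  J segments are 6 nt + TGG + a
    stop-free 30-nt tail.
    """
    rng = np.random.default_rng(_GERMLINE_SEED)
    sequences: dict[str, str] = {}
    types: dict[str, str] = {}
    gap_layouts = [  # (CDR1 gap codons, CDR2 gap codons), per V gene
        (2, 1), (3, 2), (1, 0), (2, 2), (0, 1),
        (2, 1), (4, 2), (1, 1), (3, 0), (2, 3),
    ]
    for i, (g1, g2) in enumerate(gap_layouts):
        family, gene = i % 5 + 1, i // 5 + 1
        codons = [_random_codons(rng, 1) for _ in range(104)]
        codons[103] = "TGT"  # conserved 2nd-CYS at positions 310-312
        # gap whole codons at the 3' end of CDR1 (<=114) and CDR2 (<=195)
        for start_codon, n_gaps in ((38 - g1, g1), (65 - g2, g2)):
            for c in range(start_codon, start_codon + n_gaps):
                codons[c] = "..."
        sequences[f"IGHV{family}-{gene}*01"] = "".join(codons)
        types[f"IGHV{family}-{gene}*01"] = "V"
    for i in range(6):
        length = int(rng.integers(12, 21))
        seq = "".join(rng.choice(list(shm.NUCLEOTIDES), size=length))
        sequences[f"IGHD{i + 1}-1*01"] = seq
        types[f"IGHD{i + 1}-1*01"] = "D"
    for i in range(4):
        pre = "".join(rng.choice(list(shm.NUCLEOTIDES), size=6))
        tail = _random_codons(rng, 10)
        sequences[f"IGHJ{i + 1}*01"] = pre + "TGG" + tail
        types[f"IGHJ{i + 1}*01"] = "J"
    return GermlineReference(sequences, types)


def synthetic_targeting_model(
    seed: int = _BASELINE_MODEL_SEED,
    wa_tw_rate: float = 4.0,
    wrc_gyw_rate: float = 6.0,
    neutral_rate: float = 1.0,
    jitter_sigma: float = 0.5,
) -> TargetingModel:
    """A full-coverage baseline targeting model with hotspot structure.

    Mutability is the motif-class base rate times per-5-mer lognormal
    jitter, normalised to sum to 1; substitution rows are
    transition-biased Dirichlet draws.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    base = np.full(1024, neutral_rate)
    base[shm.MOTIF_CLASSES == shm.WA_TW] = wa_tw_rate
    base[shm.MOTIF_CLASSES == shm.WRC_GYW] = wrc_gyw_rate
    mutability = base * rng.lognormal(0.0, jitter_sigma, size=1024)
    mutability /= mutability.sum()
    transition = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
    substitution = np.zeros((1024, 4))
    for w in range(1024):
        centre = (w // 16) % 4
        alphas = np.full(4, 4.0)
        alphas[transition[centre]] = 8.0
        alphas[centre] = 0.0
        draw = rng.gamma(np.where(alphas > 0, alphas, 1e-12))
        draw[centre] = 0.0
        substitution[w] = draw / draw.sum()
    return TargetingModel(
        mutability=mutability,
        substitution=substitution,
        mutation_count=np.zeros(1024, dtype=np.int64),
        background_count=np.zeros(1024, dtype=np.int64),
        options={"synthetic": True},
    )


def with_motif_effect(
    model: TargetingModel, motif: str, factor: float
) -> TargetingModel:
    """Multiply the mutability of one motif class by ``factor``, renormalise."""
    if factor <= 0:
        raise ValueError("effect factor must be positive")
    mutability = model.mutability.copy()
    mask = shm.MOTIF_CLASSES == motif
    if not mask.any():
        raise ValueError(f"unknown motif class {motif!r}")
    mutability[mask] *= factor
    mutability /= np.nansum(mutability)
    return TargetingModel(
        mutability=mutability,
        substitution=model.substitution.copy(),
        mutation_count=np.zeros(1024, dtype=np.int64),
        background_count=np.zeros(1024, dtype=np.int64),
        options={**model.options, "effect": (motif, factor)},
    )


def with_polarized_wa_tw_effect(
    model: TargetingModel, factor: float
) -> TargetingModel:
    """Shift mutational specificity within the Pol-eta (WA/TW) class.

    WA contexts (centre A) are multiplied by ``factor`` and TW contexts
    (centre T) are rescaled so the total WA/TW mutability mass — and hence
    the overall mutation load and every non-WA/TW 5-mer — is unchanged.
    This reproduces the observed pattern of an increase at AAN/TAN motifs
    with a concomitant decrease at NTT/NTA, without altering overall SHM
    frequency.
    """
    if factor <= 0:
        raise ValueError("effect factor must be positive")
    mutability = model.mutability.copy()
    centre = (np.arange(1024) // 16) % 4  # A=0, T=3
    wa = (shm.MOTIF_CLASSES == shm.WA_TW) & (centre == 0)
    tw = (shm.MOTIF_CLASSES == shm.WA_TW) & (centre == 3)
    s_wa, s_tw = mutability[wa].sum(), mutability[tw].sum()
    tw_scale = (s_wa + s_tw - factor * s_wa) / s_tw
    if tw_scale <= 0:
        raise ValueError(
            f"factor {factor} would drive TW mutability negative"
        )
    mutability[wa] *= factor
    mutability[tw] *= tw_scale
    mutability /= np.nansum(mutability)
    return TargetingModel(
        mutability=mutability,
        substitution=model.substitution.copy(),
        mutation_count=np.zeros(1024, dtype=np.int64),
        background_count=np.zeros(1024, dtype=np.int64),
        options={**model.options, "effect": ("WA+/TW-", factor)},
    )


@dataclass
class SimulationConfig:
    """Conditions of a simulated two-group study."""

    subjects_per_group: int = 20
    n_sequences: int = 2000
    clone_exponent: float = 2.5       # power-law exponent of clone sizes
    expected_mutations: float = 15.0  # Poisson mean per sequence
    effect_motif: str = shm.WA_TW
    effect_factor: float = 1.0        # 1.0 = null cohort
    effect_mode: str = "uniform"      # uniform | polarized (WA up, TW down)
    insertion_mean: float = 4.0       # Poisson mean of N-region lengths
    master_seed: int = 0
    germline: GermlineReference | None = None
    baseline_model: TargetingModel | None = None
    record_mutations: bool = True
    context_update: bool = False

    def __post_init__(self) -> None:
        if self.subjects_per_group < 1 or self.n_sequences < 1:
            raise ValueError("counts must be positive")
        if self.effect_factor <= 0:
            raise ValueError("effect factor must be positive")
        if self.germline is None:
            self.germline = default_germline_reference()
        if self.baseline_model is None:
            self.baseline_model = synthetic_targeting_model()


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    models: dict[str, TargetingModel] = field(default_factory=dict)
    clone_members: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    mutations: dict[str, dict[str, list[tuple[int, str, str]]]] = field(
        default_factory=dict
    )

    def to_json(self, path) -> None:
        import json

        payload = {
            "models": {
                s: {"mutability": m.mutability.tolist(),
                    "options": m.options}
                for s, m in self.models.items()
            },
            "clone_members": self.clone_members,
            "mutations": {
                s: {sid: [list(t) for t in muts] for sid, muts in per.items()}
                for s, per in self.mutations.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _clone_size_sampler(config: SimulationConfig):
    sizes = np.arange(1, config.n_sequences + 1, dtype=float)
    weights = sizes ** -config.clone_exponent
    weights /= weights.sum()
    return sizes.astype(int), weights


def _recombine(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, str, str, str, str, str]:
    """One VDJ founder; returns (v_call, d_call, j_call, gapped_seq, junction, junction_aa)."""
    ref = config.germline
    v_names = sorted(ref.of_type("V"))
    d_names = sorted(ref.of_type("D"))
    j_names = sorted(ref.of_type("J"))
    for _ in range(50):
        v_call = v_names[rng.integers(len(v_names))]
        d_call = d_names[rng.integers(len(d_names))]
        j_call = j_names[rng.integers(len(j_names))]
        v_gapped = ref.sequences[v_call]
        d_seq = ref.sequences[d_call]
        j_seq = ref.sequences[j_call]
        d5, d3 = rng.integers(0, 5, size=2)
        if d5 + d3 >= len(d_seq) - 2:
            continue
        d_trim = d_seq[d5 : len(d_seq) - d3]
        j_trim_len = int(rng.integers(0, 5))
        j_trim = j_seq[j_trim_len:]
        pre_w = 6 - j_trim_len  # nt before the conserved TGG
        n1 = int(rng.poisson(config.insertion_mean))
        n2 = int(rng.poisson(config.insertion_mean))
        # pad n2 so the junction is a whole number of codons
        junction_len = 3 + n1 + len(d_trim) + n2 + pre_w + 3
        n2 += (-junction_len) % 3
        n1_seq = "".join(rng.choice(list(shm.NUCLEOTIDES), size=n1)) if n1 else ""
        n2_seq = "".join(rng.choice(list(shm.NUCLEOTIDES), size=n2)) if n2 else ""
        tail = n1_seq + d_trim + n2_seq + j_trim
        v_ungapped = v_gapped.replace(".", "")
        junction = v_ungapped[-3:] + tail[: n1 + len(d_trim) + n2 + pre_w + 3]
        codons = [junction[i : i + 3] for i in range(0, len(junction), 3)]
        if any(shm._CODON_TABLE[c] == "*" for c in codons):
            continue
        junction_aa = "".join(shm._CODON_TABLE[c] for c in codons)
        return v_call, d_call, j_call, v_gapped + tail, junction, junction_aa
    raise RuntimeError("could not build a productive junction in 50 attempts")


def simulate_naive_repertoire(
    config: SimulationConfig, rng: np.random.Generator, subject_id: str = "subject"
) -> tuple[Repertoire, GroundTruth]:
    """Unmutated clonally-expanded repertoire for one subject.

    Clone founders are VDJ recombinations; clone sizes follow the
    configured power law (truncated to fill ``n_sequences`` exactly);
    members inherit the founder sequence and junction verbatim.
    """
    sizes, weights = _clone_size_sampler(config)
    records: list[RearrangementRecord] = []
    clone_members: dict[str, list[str]] = {}
    clone_idx = 0
    while len(records) < config.n_sequences:
        clone_idx += 1
        v_call, d_call, j_call, seq, junction, junction_aa = _recombine(config, rng)
        size = int(rng.choice(sizes, p=weights))
        size = min(size, config.n_sequences - len(records))
        cid = f"{subject_id}_clone_{clone_idx}"
        members = []
        for _ in range(size):
            sid = f"{subject_id}_seq_{len(records) + 1}"
            records.append(
                RearrangementRecord(
                    sequence_id=sid,
                    v_call=v_call,
                    d_call=d_call,
                    j_call=j_call,
                    junction=junction,
                    junction_aa=junction_aa,
                    sequence_alignment=seq,
                    germline_alignment=seq,
                    duplicate_count=int(rng.geometric(0.6)),
                    clone_id=cid,
                )
            )
            members.append(sid)
        clone_members[cid] = members
    truth = GroundTruth(clone_members={subject_id: clone_members})
    return Repertoire(subject_id, records), truth


def _substitution_row(model: TargetingModel, w: int) -> np.ndarray:
    row = model.substitution[w]
    centre = (w // 16) % 4
    if np.isnan(row).any():
        row = np.full(4, 1 / 3)
        row[centre] = 0.0
    return row


def apply_shm(
    record: RearrangementRecord,
    model: TargetingModel,
    expected_mutations: float,
    rng: np.random.Generator,
    context_update: bool = False,
) -> tuple[RearrangementRecord, list[Mutation]]:
    """Mutate one record under a targeting model.

    The mutation count is Poisson(``expected_mutations``); positions are
    drawn without replacement with probability proportional to the
    mutability of the germline 5-mer context (uniform fallback for absent
    contexts), and replacement bases follow the model's substitution row.
    With ``context_update`` the contexts are instead re-read from the
    partially mutated sequence after each placement.
    """
    n_requested = int(rng.poisson(expected_mutations))
    if n_requested == 0:
        return record, []
    seq = bytearray(record.sequence_alignment.encode("ascii"))
    mutations: list[Mutation] = []

    def place(n_place: int, view: shm._AlignmentView) -> list[int]:
        if not len(view.centres):
            return []
        w = model.mutability[view.fivemers]
        w = np.where(np.isnan(w), 1.0 / 1024, w)
        if w.sum() == 0:
            return []
        n_place = min(n_place, int(np.count_nonzero(w)))
        chosen = rng.choice(len(view.centres), size=n_place, replace=False,
                            p=w / w.sum())
        out = []
        for c in chosen:
            centre = view.centres[c]
            fivemer = int(view.fivemers[c])
            col = int(view.stripped_cols[centre])
            row = _substitution_row(model, fivemer)
            to = int(rng.choice(4, p=row))
            from_base = chr(seq[col])
            seq[col] = ord(shm.NUCLEOTIDES[to])
            mutations.append(
                Mutation(
                    sequence_id=record.sequence_id,
                    position=col + 1,
                    context=ALL_FIVEMERS[fivemer],
                    from_base=from_base,
                    to_base=shm.NUCLEOTIDES[to],
                )
            )
            out.append(col)
        return out

    base_view = shm._view(record)
    informative = len(base_view.centres)
    if n_requested > informative:
        warnings.warn(
            f"{record.sequence_id}: requested {n_requested} mutations, "
            f"only {informative} informative positions",
            stacklevel=2,
        )
        n_requested = informative
    if context_update:
        for _ in range(n_requested):
            current = RearrangementRecord(
                sequence_id=record.sequence_id,
                v_call=record.v_call,
                j_call=record.j_call,
                junction=record.junction,
                junction_aa=record.junction_aa,
                sequence_alignment=seq.decode("ascii"),
                germline_alignment=seq.decode("ascii"),
                duplicate_count=record.duplicate_count,
            )
            place(1, shm._view(current))
    else:
        place(n_requested, base_view)
    mutated = RearrangementRecord(
        sequence_id=record.sequence_id,
        v_call=record.v_call,
        j_call=record.j_call,
        junction=record.junction,
        junction_aa=record.junction_aa,
        sequence_alignment=seq.decode("ascii"),
        germline_alignment=record.germline_alignment,
        d_call=record.d_call,
        duplicate_count=record.duplicate_count,
        clone_id=record.clone_id,
    )
    return mutated, mutations


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a labelled two-group cohort.

    Controls are mutated under the baseline model; cases under the baseline
    with the configured motif-class effect applied and renormalised.  Fully
    reproducible from ``config.master_seed``.
    """
    control_model = config.baseline_model
    if config.effect_factor == 1.0:
        case_model = control_model
    elif config.effect_mode == "polarized":
        if config.effect_motif != shm.WA_TW:
            raise ValueError("polarized effect is defined for WA/TW only")
        case_model = with_polarized_wa_tw_effect(
            control_model, config.effect_factor
        )
    else:
        case_model = with_motif_effect(
            control_model, config.effect_motif, config.effect_factor
        )
    n = config.subjects_per_group
    seeds = np.random.SeedSequence(config.master_seed).spawn(2 * n)
    repertoires: list[Repertoire] = []
    labels: dict[str, str] = {}
    truth = GroundTruth()
    subjects = [(f"case_{i + 1:02d}", "case", case_model) for i in range(n)] + [
        (f"ctrl_{i + 1:02d}", "control", control_model) for i in range(n)
    ]
    for (subject_id, label, model), seed in zip(subjects, seeds):
        rng = np.random.default_rng(seed)
        naive, sub_truth = simulate_naive_repertoire(config, rng, subject_id)
        mutated_records = []
        per_seq: dict[str, list[tuple[int, str, str]]] = {}
        for rec in naive:
            mut_rec, muts = apply_shm(
                rec, model, config.expected_mutations, rng,
                context_update=config.context_update,
            )
            mutated_records.append(mut_rec)
            if config.record_mutations:
                per_seq[rec.sequence_id] = [
                    (m.position, m.from_base, m.to_base) for m in muts
                ]
        repertoires.append(Repertoire(subject_id, mutated_records))
        labels[subject_id] = label
        truth.models[subject_id] = model
        truth.clone_members[subject_id] = sub_truth.clone_members[subject_id]
        if config.record_mutations:
            truth.mutations[subject_id] = per_seq
    return Cohort(repertoires, labels), truth
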