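import itertools
import re

import numpy as np
import pandas as pd
import pytest

from shmclass import shm
from shmclass.airr_io import Repertoire
from shmclass.shm import (
    ALL_FIVEMERS,
    Mutation,
    TargetingModel,
    classify_hotspot,
    classify_synonymy,
    collapse_to_3mer,
    compare_cohort_models,
    enumerate_mutations,
    estimate_targeting_model,
    flatten_model_features,
    motif_ratio_summary,
)
from tests.conftest import make_record


# ---------------------------------------------------------------- hotspots

def iupac_hotspot_oracle(w):
    """Independent regex-based motif classifier (IUPAC wildcards)."""
    if re.fullmatch(r".[AT]A..", w):
        return "WA/TW"
    if re.fullmatch(r"..T[AT].", w):
        return "WA/TW"
    if re.fullmatch(r"[AT][AG]C..", w):
        return "WRC/GYW"
    if re.fullmatch(r"..G[CT][AT]", w):
        return "WRC/GYW"
    return "neutral"


@pytest.mark.parametrize(
    "fivemer,expected",
    [
        ("TTACG", "WA/TW"),    # centre A preceded by T (Pol-eta hotspot)
        ("TAGCA", "WRC/GYW"),  # centre G followed by C (Y) then A (W)
        ("GGCGG", "neutral"),  # centre C but -2 base G not in W
        ("AATAG", "WA/TW"),    # centre T followed by A (W)
        ("TACAT", "WRC/GYW"),  # WRC with T,A preceding C
        ("CCCCC", "neutral"),
    ],
)
def test_hotspot_examples(fivemer, expected):
    assert classify_hotspot(fivemer) == expected


def test_hotspot_classes_partition_all_fivemers():
    counts = {"WA": 0, "TW": 0, "WRC": 0, "GYW": 0, "neutral": 0}
    for w in ALL_FIVEMERS:
        got = classify_hotspot(w)
        assert got == iupac_hotspot_oracle(w)
        if got == shm.WA_TW:
            counts["WA" if w[2] == "A" else "TW"] += 1
        elif got == shm.WRC_GYW:
            counts["WRC" if w[2] == "C" else "GYW"] += 1
        else:
            counts["neutral"] += 1
    assert counts == {"WA": 128, "TW": 128, "WRC": 64, "GYW": 64, "neutral": 640}


def test_hotspot_rejects_ambiguous():
    assert classify_hotspot("TTNCG") is None
    assert classify_hotspot("TTAC") is None


# ------------------------------------------------------------- mutations

def test_enumerate_single_mutation_with_context():
    rec = make_record(germline="ATGCATGCA", observed="ATGGATGCA")
    muts = enumerate_mutations(rec)
    assert len(muts) == 1
    m = muts[0]
    assert (m.position, m.from_base, m.to_base) == (4, "C", "G")
    assert m.context == "TGCAT"


def test_enumerate_identical_sequences_empty():
    rec = make_record(germline="ATGCATGCA")
    assert enumerate_mutations(rec) == []


def test_enumerate_strips_gaps_for_context():
    rec = make_record(germline="A.TGCAT", observed="A.TGGAT")
    muts = enumerate_mutations(rec)
    assert len(muts) == 1
    assert muts[0].context == "TGCAT"
    assert muts[0].position == 5  # gapped coordinate of the mutated column


def test_enumerate_edge_windows_uninformative():
    rec = make_record(germline="ATGCA", observed="TTGCA")  # mutation at pos 1
    muts = enumerate_mutations(rec)
    assert len(muts) == 1
    assert muts[0].context is None


def test_enumerate_n_in_context_uninformative():
    rec = make_record(germline="ANGCATG", observed="ANGGATG")
    muts = enumerate_mutations(rec)
    assert len(muts) == 1
    assert muts[0].context is None  # N inside the 5-mer window


# -------------------------------------------------------------- synonymy

@pytest.mark.parametrize(
    "germline,pos,to,expected",
    [
        ("GGG", 3, "A", "synonymous"),     # GGG->GGA, Gly->Gly
        ("AAA", 1, "G", "nonsynonymous"),  # AAA->GAA, Lys->Glu
        ("TGG", 3, "A", "stop"),           # TGG->TGA
    ],
)
def test_synonymy_codon_table(germline, pos, to, expected):
    rec = make_record(germline=germline, observed=germline)
    mut = Mutation("seq1", pos, None, germline[pos - 1], to)
    assert classify_synonymy(rec, mut) == expected


def test_synonymy_gapped_codon_ambiguous():
    rec = make_record(germline="A..CAT", observed="A..CAT")
    mut = Mutation("seq1", 1, None, "A", "G")
    assert classify_synonymy(rec, mut) == "ambiguous"


def test_synonymy_respects_gapped_frame():
    # IMGT gaps come in whole codons: codon 2 is '...' so codon 3 is GGG
    rec = make_record(germline="ATG...GGGTAA", observed="ATG...GGGTAA")
    mut = Mutation("seq1", 9, None, "G", "A")  # third base of GGG
    assert classify_synonymy(rec, mut) == "synonymous"


# ------------------------------------------------------ model estimation

def test_single_mutation_model():
    rec = make_record(germline="TTAAT", observed="TTGAT")
    rep = Repertoire("s", [rec])
    model = estimate_targeting_model(rep, min_background=1)
    w = ALL_FIVEMERS.index("TTAAT")
    assert model.mutability[w] == pytest.approx(1.0)
    assert model.substitution[w, shm.NUCLEOTIDES.index("G")] == pytest.approx(1.0)
    assert model.mutation_count[w] == 1
    assert model.background_count[w] == 1


def test_zero_mutation_repertoire_is_degenerate():
    rep = Repertoire("s", [make_record(germline="ATGCATGCA")])
    model = estimate_targeting_model(rep, min_background=1)
    assert model.degenerate
    assert np.isnan(model.mutability).all()


def test_min_background_gives_absent_not_zero():
    rec = make_record(germline="TTAATGG", observed="TTGATGG")
    model = estimate_targeting_model(Repertoire("s", [rec]), min_background=2)
    w = ALL_FIVEMERS.index("TTAAT")
    assert np.isnan(model.mutability[w])  # background 1 < 2: absent


def brute_force_counts(repertoire, synonymous_only=False, region_mask=None):
    """Nested-loop oracle over gap-stripped germline strings."""
    background = {w: 0 for w in ALL_FIVEMERS}
    mutations = {w: 0 for w in ALL_FIVEMERS}
    subs = {(w, b): 0 for w in ALL_FIVEMERS for b in "ACGT"}
    for rec in repertoire:
        pairs = [
            (i, g, s)
            for i, (g, s) in enumerate(
                zip(rec.germline_alignment, rec.sequence_alignment)
            )
            if g != "."
        ]
        for k in range(len(pairs)):
            if k < 2 or k >= len(pairs) - 2:
                continue
            window = "".join(p[1] for p in pairs[k - 2 : k + 3])
            if any(c not in "ACGT" for c in window):
                continue
            col, g, s = pairs[k]
            if region_mask is not None:
                if shm.region_of_position(col + 1) not in region_mask:
                    continue
            background[window] += 1
            if s in "ACGT" and s != g:
                if synonymous_only:
                    mut = Mutation(rec.sequence_id, col + 1, window, g, s)
                    if classify_synonymy(rec, mut) != "synonymous":
                        continue
                mutations[window] += 1
                subs[(window, s)] += 1
    return background, mutations, subs


@pytest.mark.parametrize("synonymous_only,region_mask",
                         [(False, None), (True, None), (False, {"CDR"})])
def test_estimator_matches_brute_force_oracle(small_cohort, synonymous_only,
                                              region_mask):
    cohort, _ = small_cohort
    rep = Repertoire("sub", cohort.repertoires[0].records[:50])
    model = estimate_targeting_model(
        rep, synonymous_only=synonymous_only, region_mask=region_mask,
        min_background=1,
    )
    background, mutations, _ = brute_force_counts(
        rep, synonymous_only, region_mask
    )
    for i, w in enumerate(ALL_FIVEMERS):
        assert model.background_count[i] == background[w], w
        assert model.mutation_count[i] == mutations[w], w


def test_model_normalisation_across_option_paths(small_cohort):
    cohort, _ = small_cohort
    rep = cohort.repertoires[0]
    for kwargs in (
        {},
        {"synonymous_only": True},
        {"region_mask": {"FWR"}},
        {"representatives_only": True},
    ):
        model = estimate_targeting_model(rep, min_background=5, **kwargs)
        model.validate()
        present = model.present
        assert np.nansum(model.mutability[present]) == pytest.approx(1.0)


def test_model_tsv_round_trip(small_cohort, tmp_path):
    cohort, _ = small_cohort
    model = estimate_targeting_model(cohort.repertoires[0])
    path = tmp_path / "model.tsv"
    model.to_tsv(path)
    back = TargetingModel.from_tsv(path)
    np.testing.assert_allclose(back.mutability, model.mutability, equal_nan=True)
    np.testing.assert_array_equal(back.background_count, model.background_count)


# --------------------------------------------------------------- collapse

def manual_model(entries, backgrounds):
    """Model with given {fivemer: raw mutability} and background counts."""
    mutability = np.full(1024, np.nan)
    background = np.zeros(1024, dtype=np.int64)
    mut_count = np.zeros(1024, dtype=np.int64)
    for w, v in entries.items():
        mutability[ALL_FIVEMERS.index(w)] = v
        mut_count[ALL_FIVEMERS.index(w)] = 1
    for w, b in backgrounds.items():
        background[ALL_FIVEMERS.index(w)] = b
    total = np.nansum(mutability)
    mutability = mutability / total
    return TargetingModel(
        mutability=mutability,
        substitution=np.full((1024, 4), np.nan),
        mutation_count=mut_count,
        background_count=background,
    ), total


def test_collapse_weighted_mean():
    # two constituents of central 3-mer TAA: 0.2/0.4 with backgrounds 100/300
    entries = {"ATAAC": 0.2, "CTAAG": 0.4, "AAAAA": 0.4}
    backgrounds = {"ATAAC": 100, "CTAAG": 300, "AAAAA": 100}
    model, total = manual_model(entries, backgrounds)
    collapsed = collapse_to_3mer(model)
    taa = collapsed.mutability[shm.ALL_THREEMERS.index("TAA")]
    aaa = collapsed.mutability[shm.ALL_THREEMERS.index("AAA")]
    # weighted mean 0.35 vs 0.4 before renormalisation; ratio survives it
    assert taa / aaa == pytest.approx(0.35 / 0.4)


def test_collapse_equal_members_proportional_to_mu():
    entries = {w: 0.5 for w in ALL_FIVEMERS if w[1:4] == "ACG"}
    entries.update({w: 0.25 for w in ALL_FIVEMERS if w[1:4] == "TTT"})
    backgrounds = {w: 50 for w in entries}
    model, _ = manual_model(entries, backgrounds)
    collapsed = collapse_to_3mer(model)
    acg = collapsed.mutability[shm.ALL_THREEMERS.index("ACG")]
    ttt = collapsed.mutability[shm.ALL_THREEMERS.index("TTT")]
    assert acg / ttt == pytest.approx(2.0)


def test_collapse_degenerate_raises():
    model = TargetingModel(
        mutability=np.full(1024, np.nan),
        substitution=np.full((1024, 4), np.nan),
        mutation_count=np.zeros(1024, dtype=np.int64),
        background_count=np.zeros(1024, dtype=np.int64),
    )
    with pytest.raises(ValueError, match="degenerate"):
        collapse_to_3mer(model)


def test_collapse_commutes_with_normalisation(small_cohort):
    """Collapse-then-normalise equals normalise-then-collapse."""
    cohort, _ = small_cohort
    model = estimate_targeting_model(cohort.repertoires[0], min_background=5)
    collapsed = collapse_to_3mer(model)
    # rescale mutability by a global constant: collapse is invariant
    scaled = TargetingModel(
        mutability=model.mutability * 7.0,
        substitution=model.substitution,
        mutation_count=model.mutation_count,
        background_count=model.background_count,
    )
    collapsed2 = collapse_to_3mer(scaled)
    np.testing.assert_allclose(
        collapsed.mutability, collapsed2.mutability, equal_nan=True, rtol=1e-12
    )


# --------------------------------------------------------------- features

def test_flatten_cardinalities(small_cohort):
    cohort, _ = small_cohort
    model = estimate_targeting_model(cohort.repertoires[0])
    mut_only = flatten_model_features(model, parts=("mutability",))
    assert len(mut_only) == 1024
    full = flatten_model_features(model)
    assert len(full) == 1024 + 3072 + 3072
    wa = flatten_model_features(model, parts=("mutability",), motif_filter=shm.WA_TW)
    assert len(wa) == 256  # 128 WA + 128 TW five-mers
    assert all(classify_hotspot(n.split("|")[1]) == shm.WA_TW for n in wa.index)


def test_flatten_empty_parts_rejected(small_cohort):
    cohort, _ = small_cohort
    model = estimate_targeting_model(cohort.repertoires[0])
    with pytest.raises(ValueError):
        flatten_model_features(model, parts=())


# ------------------------------------------------------- cohort comparison

def _fake_vectors(rng, n_per_class, shift_feature=None, shift=0.0):
    names = [f"mut|{w}" for w in ALL_FIVEMERS[:60]]
    vectors, labels = {}, {}
    for i in range(2 * n_per_class):
        subject = f"s{i}"
        is_case = i < n_per_class
        values = rng.normal(1.0, 0.1, size=len(names))
        if shift_feature is not None and is_case:
            values[names.index(shift_feature)] += shift
        vectors[subject] = pd.Series(values, index=names)
        labels[subject] = "case" if is_case else "control"
    return vectors, labels


def test_compare_identical_tables(rng):
    vectors, labels = _fake_vectors(rng, 4)
    # make case i identical to control i
    for i in range(4):
        vectors[f"s{i}"] = vectors[f"s{i + 4}"].copy()
    table, spearman = compare_cohort_models(vectors, labels)
    np.testing.assert_allclose(table["mean_case"], table["mean_control"])
    assert all(rho == pytest.approx(1.0) for rho in spearman.values())


def test_compare_detects_shifted_feature(rng):
    target = "mut|AAAAA"
    vectors, labels = _fake_vectors(rng, 6, shift_feature=target, shift=0.3)
    table, _ = compare_cohort_models(vectors, labels)
    assert table["p_value"].idxmin() == target


def test_compare_drops_constant_features(rng):
    vectors, labels = _fake_vectors(rng, 3)
    for v in vectors.values():
        v["mut|AAAAA"] = 5.0  # constant everywhere: t undefined
    table, _ = compare_cohort_models(vectors, labels)
    assert "mut|AAAAA" not in table.index


# ------------------------------------------------------------ motif ratios

def make_threemer(values):
    arr = np.array(values, dtype=float)
    return shm.ThreemerModel(arr / arr.sum(), np.ones(64, dtype=np.int64))


def test_motif_ratios_identical_cohorts(rng):
    base = rng.uniform(0.5, 2.0, size=64)
    models = {f"s{i}": make_threemer(base) for i in range(6)}
    labels = {f"s{i}": "case" if i < 3 else "control" for i in range(6)}
    ratios = motif_ratio_summary(models, labels)
    assert set(ratios) == {"AAN", "TAN", "NTT", "NTA"}
    for series in ratios.values():
        np.testing.assert_allclose(series.values, 1.0)


def test_motif_members_enumeration(rng):
    base = rng.uniform(0.5, 2.0, size=64)
    models = {f"s{i}": make_threemer(base) for i in range(4)}
    labels = {f"s{i}": "case" if i < 2 else "control" for i in range(4)}
    ratios = motif_ratio_summary(models, labels)
    assert sorted(ratios["AAN"].index) == ["AAA", "AAC", "AAG", "AAT"]
    assert sorted(ratios["NTT"].index) == ["ATT", "CTT", "GTT", "TTT"]
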