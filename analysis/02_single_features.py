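"""Classical single-feature comparisons between the two groups.

For the discovery cohort this computes, per subject, the 10/50/90
percentiles of CDR3 amino-acid length and germline identity, Hill diversity
numbers D_q over a q grid (from inferred clones), and V gene usage, then
compares each feature between cases and controls with a two-sample t-test.

Because the injected group difference is a shift of SHM *specificity* (not
of mutation load, diversity, or gene usage), none of these classical
summaries is expected to separate the groups — mirroring the situation
where multivariate SHM patterns carry the only usable signal.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from shmclass.airr_io import load_cohort
from shmclass.clones import clone_abundance, partition_clones
from shmclass.features import hill_diversity, repertoire_percentiles, v_gene_usage

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "single_features"
Q_GRID = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0]


def main() -> None:
    cohort = load_cohort(ROOT / "results" / "cohorts" / "discovery" / "manifest.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    rows = {}
    for rep in cohort.repertoires:
        feats = repertoire_percentiles(rep)
        assignment = partition_clones(rep)
        profile = clone_abundance(assignment)
        diversity = hill_diversity(profile, Q_GRID)
        for q, d in zip(diversity.q_values, diversity.d_values):
            feats[f"hill_q{q:g}"] = d
        usage = v_gene_usage(rep, level="family", weighting="clone")
        for fam, freq in usage.items():
            feats[f"vfam_{fam}"] = freq
        rows[rep.subject_id] = feats
    table = pd.DataFrame(rows).T.fillna(0.0)
    table.insert(0, "label", [cohort.labels[s] for s in table.index])
    table.to_csv(OUT / "subject_features.tsv", sep="\t")

    y = table["label"] == "case"
    records = []
    for col in table.columns.drop("label"):
        a, b = table.loc[y, col], table.loc[~y, col]
        if a.std() == 0 and b.std() == 0:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        records.append({"feature": col, "mean_case": a.mean(),
                        "mean_control": b.mean(), "t": t, "p_value": p})
    tests = pd.DataFrame(records).set_index("feature").sort_values("p_value")
    tests.to_csv(OUT / "feature_tests.tsv", sep="\t")

    n_nominal = int((tests["p_value"] < 0.05).sum())
    print(f"{len(tests)} single features tested; "
          f"{n_nominal} nominally significant at p<0.05 "
          f"(~{0.05 * len(tests):.1f} expected by chance)")
    print("smallest p-values:")
    print(tests.head(5).round(4).to_string())


if __name__ == "__main__":
    main()
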