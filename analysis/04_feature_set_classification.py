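"""Feature-set comparison: which repertoire representation classifies?

Runs the leave-one-out elastic-net pipeline on the discovery cohort for a
panel of feature sets — CDR3 amino-acid 3-mers, V gene usage, V-J-CDR3
length clusters, the full 5-mer SHM model, its WA/TW- and WRC/GYW-restricted
subsets, and the collapsed 3-mer model — each with a shuffled-label null.

With a Pol-eta specificity shift injected, only the SHM-derived feature
sets (and specifically the WA/TW-restricted one, not WRC/GYW) are expected
to classify above their null bands.
"""

from pathlib import Path

from shmclass.airr_io import load_cohort
from shmclass.classify import ElasticNetTuning
from shmclass.pipeline import ExperimentConfig, run_experiment

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "feature_set_classification"

RUNS = [
    "cdr3_3mer",
    "v_usage",
    "vjl_clusters",
    "shm_5mer_all",
    "shm_wa_tw",
    "shm_wrc_gyw",
    "shm_3mer",
]


def main() -> None:
    cohort = load_cohort(ROOT / "results" / "cohorts" / "discovery" / "manifest.tsv")
    config = ExperimentConfig(
        runs=RUNS,
        top_k=30,
        n_permutations=8,
        master_seed=11,
        out_dir=str(OUT),
        tuning=ElasticNetTuning(),
    )
    report = run_experiment(config, cohort=cohort)
    print(report.comparison.round(3).to_string())
    for run, reason in report.failures.items():
        print(f"FAILED {run}: {reason}")


if __name__ == "__main__":
    main()
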