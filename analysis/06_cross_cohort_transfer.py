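"""Cross-cohort transfer: does the stratifying signal generalise?

Trains the elastic-net model (with t-test screening) on the discovery
cohort's 5-mer SHM features and applies it, without refitting, to the
replication cohort, which carries the same injected effect under an
independent seed.  Above-chance transfer accuracy indicates the classifier
learned the group effect rather than cohort idiosyncrasies; a second
transfer onto the null cohort provides the matching negative control.
"""

from pathlib import Path

from shmclass.airr_io import load_cohort
from shmclass.pipeline import run_transfer

ROOT = Path(__file__).resolve().parent.parent
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "transfer"


def main() -> None:
    train = load_cohort(COHORTS / "discovery" / "manifest.tsv")
    for target in ("replication", "null"):
        test = load_cohort(COHORTS / target / "manifest.tsv")
        metrics = run_transfer(
            train, test, run="shm_5mer_all", top_k=30, master_seed=17,
            out_dir=OUT / target,
        )
        line = ", ".join(
            f"{m}={metrics[m]['value']:.3f}" if metrics[m]["value"] is not None
            else f"{m}=undefined"
            for m in ("accuracy", "sensitivity", "specificity", "f1")
        )
        print(f"discovery -> {target}: {line}")


if __name__ == "__main__":
    main()
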