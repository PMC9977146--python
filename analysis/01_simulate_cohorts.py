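"""Simulate the study cohorts used by the downstream analysis scripts.

Three synthetic AIRR cohorts are written under results/cohorts/:

* ``discovery``   — 8 case + 8 control subjects, 500 sequences each, with a
  Pol-eta specificity shift in cases (WA mutability x1.5, TW rescaled so the
  total A/T hotspot mass and overall mutation load are unchanged);
* ``replication`` — same generative conditions, independent seed (plays the
  role of a second cohort for transfer experiments);
* ``null``        — same sizes, no group effect (classifier calibration).

Each cohort directory contains one AIRR Rearrangement TSV per subject plus a
``manifest.tsv`` consumable by every other script and by the CLI.
"""

from pathlib import Path

from shmclass.airr_io import write_airr
from shmclass.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"

COHORTS = {
    "discovery": dict(effect_factor=1.5, effect_mode="polarized", master_seed=101),
    "replication": dict(effect_factor=1.5, effect_mode="polarized", master_seed=202),
    "null": dict(effect_factor=1.0, master_seed=303),
}


def main() -> None:
    for name, overrides in COHORTS.items():
        config = SimulationConfig(
            subjects_per_group=8, n_sequences=500, record_mutations=False,
            **overrides,
        )
        cohort, _ = simulate_cohort(config)
        out_dir = OUT / name
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for rep in cohort.repertoires:
            write_airr(rep, out_dir / f"{rep.subject_id}.tsv")
            rows.append(
                f"{rep.subject_id}\t{rep.subject_id}.tsv\t"
                f"{cohort.labels[rep.subject_id]}"
            )
        (out_dir / "manifest.tsv").write_text(
            "subject_id\tfile\tlabel\n" + "\n".join(rows) + "\n"
        )
        n_seq = sum(len(r) for r in cohort.repertoires)
        print(f"{name}: {len(cohort)} subjects, {n_seq} sequences -> {out_dir}")


if __name__ == "__main__":
    main()
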