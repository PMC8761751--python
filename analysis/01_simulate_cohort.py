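"""Generate the synthetic study cohort.

Emulates the reference design — 8 patients (4 deparaffinized, 4
formalin-fixed), paired tumor / adjacent-normal blocks, 3 technical
repeats, 25 -> 37 deg C ramp in 3 deg steps — and writes the ground-truth
table and the raw measurement records under results/cohort/.
"""

from pathlib import Path

from etpheno.io_cli import RunConfig, write_measurements, write_table
from etpheno.synthetic_study import generate_study

OUT = Path("results/cohort")
SEED = 7


def main() -> None:
    cfg = RunConfig(seed=SEED, outdir=str(OUT))
    truth_df, meas_df = generate_study(cfg.study_config())
    write_table(truth_df, OUT / "truth.csv", cfg)
    write_measurements(meas_df, OUT / "measurements.csv", cfg)
    n_t = (truth_df.group == "tumor").sum()
    n_n = (truth_df.group == "normal").sum()
    print(f"cohort: {len(truth_df)} samples ({n_t} tumor + {n_n} normal), "
          f"{len(meas_df)} measurement records -> {OUT}")


if __name__ == "__main__":
    main()
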