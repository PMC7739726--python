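"""Fit the four demand regressions per athlete and summarise their coefficients.

Reads the cohorts from 01, writes models/ge_reg CSVs under results/, and
prints group-mean intercepts, slopes, r^2 and SEE per regression variant —
the linear no-baseline fits should track each scenario's generative curve.
"""

from pathlib import Path

from skicap.io import fit_cohort_frames, read_csv, write_csv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("dp", "ds"):
        stages = read_csv(ROOT / "data" / name / "stages.csv")
        athletes = read_csv(ROOT / "data" / name / "athletes.csv")
        models, ge_reg = fit_cohort_frames(stages, athletes)
        write_csv(models, ROOT / f"models_{name}.csv")
        write_csv(ge_reg, ROOT / f"ge_reg_{name}.csv")
        print(f"\n{name.upper()} group means over {models['athlete_id'].nunique()} athletes:")
        summary = models.groupby("method")[["intercept", "l_coeff", "q_coeff", "r2", "see"]].mean()
        print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
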