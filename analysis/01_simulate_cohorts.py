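"""Generate the two synthetic study cohorts (double poling and diagonal stride).

Sixteen athletes each, stage-rate noise SD 2%, study-condition protocols.
Writes stages/tt/athletes/truth CSVs under results/data/{dp,ds}/.
"""

from pathlib import Path

from skicap.io import cohort_to_frames, write_csv
from skicap.simulate import dp_scenario, ds_scenario, generate_cohort

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    for name, scen_fn in (("dp", dp_scenario), ("ds", ds_scenario)):
        scen = scen_fn(n=16, stage_noise_sd=0.02)
        cohort = generate_cohort(scen, seed=SEED)
        frames = cohort_to_frames(cohort)
        for fname, df in frames.items():
            write_csv(df, OUT / name / f"{fname}.csv", seed=SEED, config=scen.model_dump())
        truth = frames["truth"]
        print(
            f"{name.upper()}: {len(cohort)} athletes | "
            f"TT speed {truth['tt_speed_kmh'].mean():.1f} km/h | "
            f"true deficit {truth['true_o2_deficit_ml_kg'].mean():.1f} "
            f"+/- {truth['true_o2_deficit_ml_kg'].std(ddof=1):.1f} mL/kg"
        )
    print(f"data written under {OUT}")


if __name__ == "__main__":
    main()
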