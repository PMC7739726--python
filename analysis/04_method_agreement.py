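"""Pairwise Bland–Altman agreement between the capacity-estimation methods.

Reads the estimates from 03, writes the 21-pair agreement grid per
sub-technique, and prints the pairs with the smallest and largest typical
error — on the diagonal-stride-like cohort the no-baseline linear and
fixed-GE methods should agree closely, mirroring the study's main finding.
"""

from pathlib import Path

from skicap.agreement import pairwise_comparisons
from skicap.io import read_csv, write_csv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("dp", "ds"):
        est = read_csv(ROOT / f"estimates_{name}.csv")
        comp = pairwise_comparisons(est)
        write_csv(comp, ROOT / f"agreement_{name}.csv")
        comp = comp.sort_values("typical_error")
        best, worst = comp.iloc[0], comp.iloc[-1]
        print(f"\n{name.upper()} ({len(comp)} method pairs):")
        print(f"  closest agreement : {best['method_a']} vs {best['method_b']} "
              f"(mean diff {best['mean_diff']:.1f}, TE {best['typical_error']:.1f} mL/kg)")
        print(f"  poorest agreement : {worst['method_a']} vs {worst['method_b']} "
              f"(mean diff {worst['mean_diff']:.1f}, TE {worst['typical_error']:.1f} mL/kg)")


if __name__ == "__main__":
    main()
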