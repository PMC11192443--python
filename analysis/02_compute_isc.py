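"""Leave-one-out ISC for every (participant, condition, fROI) cell, plus
the resting-state baseline check.

Reads results/data/, writes results/isc.tsv and results/isc_rest.tsv,
and prints the condition-type means and the rest t test.
"""

from pathlib import Path

import natisc as n
from natisc.isc import TimeCourseSet

DATA = Path("results/data")
OUT = Path("results")


def main():
    design = n.SimDesign.from_json(DATA / "design.json")
    tcs = TimeCourseSet.from_tsv(
        DATA / "timecourses.tsv", condition_types=design.condition_types()
    )
    isc = n.compute_isc_table(n.preprocess(tcs))
    isc.to_csv(OUT / "isc.tsv", sep="\t", index=False)
    print("mean ISC (r) by condition type:")
    print(isc.groupby("condition_type")["r"].mean().round(4).to_string())

    rest = TimeCourseSet.from_tsv(DATA / "rest.tsv", condition_types={"rest": "rest"})
    rest_isc = n.compute_isc_table(n.preprocess(rest))
    rest_isc.to_csv(OUT / "isc_rest.tsv", sep="\t", index=False)
    t, df, p = n.rest_baseline_test(rest_isc)
    print(f"rest baseline: one-tailed t({df}) = {t:.3f}, p = {p:.3f} "
          f"({'no' if p > 0.05 else 'SPURIOUS'} intersubject coupling at rest)")


if __name__ == "__main__":
    main()
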