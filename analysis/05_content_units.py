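"""Content-unit scoring of the description corpora and its association
with ISC: does semantic richness explain the condition-type differences?

Reads results/data/corpus.json + results/isc.tsv, writes
results/cu_counts.tsv and results/cu_association.json.
"""

import json
from pathlib import Path

import pandas as pd

import natisc as n

OUT = Path("results")


def main():
    design = n.SimDesign.from_json("results/data/design.json")
    corpus = n.DescriptionCorpus.from_json("results/data/corpus.json")
    isc = pd.read_csv(OUT / "isc.tsv", sep="\t")

    table = n.score_corpus(corpus, min_participants=3)
    table.counts.to_csv(OUT / "cu_counts.tsv", sep="\t", index=False)
    print("mean CU count per stimulus:")
    print(table.mean_cu_per_stimulus().round(2).to_string())

    fit = n.cu_condition_model(table, design.condition_types())
    print("\nCU ~ condition type (stimulus random intercept):")
    print(fit.terms.round(4).to_string(index=False))

    plus_m = [c.name for c in design.conditions if c.condition_type != "-M/-L"]
    results = {}
    for metric in ("mean_cu", "shared_cu"):
        assoc = n.cu_isc_association(table, isc, metric=metric, scope=plus_m)
        results[metric] = {k: v for k, v in assoc.items() if k != "fits"}
        results[metric]["cu_beta_in_joint_model"] = list(
            results[metric]["cu_beta_in_joint_model"]
        )
        print(
            f"\n{metric}: r = {assoc['pearson_r']:.3f} (p = {assoc['p']:.3f}, "
            f"n = {assoc['n_stimuli']} meaningful stimuli); "
            f"LRT add-CU chi2 = {assoc['lrt_add_cu']['chi2']:.2f} "
            f"(p = {assoc['lrt_add_cu']['p']:.3f}); "
            f"delta-AIC CU-only = {assoc['delta_aic_cu_only']:.2f}"
        )
    (OUT / "cu_association.json").write_text(json.dumps(results, indent=1))


if __name__ == "__main__":
    main()
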