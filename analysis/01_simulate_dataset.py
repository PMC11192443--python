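"""Simulate the study dataset: 10 naturalistic conditions, rest scans,
and description corpora, with the published per-condition sample sizes.

Writes results/data/{design.json, timecourses.tsv, rest.tsv, corpus.json}.
"""

from pathlib import Path

import natisc as n

SEED = 20240601
OUT = Path("results/data")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = n.make_design("paper", seed=SEED)
    design.to_json(OUT / "design.json")

    tcs = n.simulate_timecourses(design)
    tcs.to_tsv(OUT / "timecourses.tsv")
    print(f"simulated {len(tcs.data)} (participant, condition, fROI) series")

    rest = n.simulate_rest(design=design, seed=SEED)
    rest.to_tsv(OUT / "rest.tsv")
    print(f"simulated rest scans for {len(rest.participants())} participants")

    corpus = n.simulate_corpus(design, n_participants=20, n_subclips=10, seed=SEED)
    corpus.to_json(OUT / "corpus.json")
    print(f"simulated description corpora for {len(corpus.stimuli())} stimuli")


if __name__ == "__main__":
    main()
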