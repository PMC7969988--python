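#!/usr/bin/env python
"""Simulate the two synthetic hemocyte 'studies' used by the rest of the
analysis.

Both studies profile the same 8-subgroup population (a dominant
unspecified pool >50%, a rare PSC-like subgroup <1%) but differ in
sequencing depth and dropout, and share only 60% of each subgroup's
marker genes — the situation faced when comparing independently
published atlases.  Writes counts, labels and the planted ground truth
under results/synthetic/.
"""

from pathlib import Path

import pandas as pd

import hemoconcord as hc

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    (cma, gta), (cmb, gtb) = hc.generate_study_pair(
        hc.StudyConfig(seed=SEED), shared_truth_seed=SEED + 100
    )
    for tag, cm, gt in (("a", cma, gta), ("b", cmb, gtb)):
        hc.write_counts(cm, OUT / f"counts_{tag}.tsv")
        hc.write_labels(gt.labeling, OUT / f"labels_{tag}.tsv")
        gt.markers.to_csv(OUT / f"planted_markers_{tag}.tsv", sep="\t", index=False)
        sizes = {s: len(gt.labeling.cells_of(s)) for s in gt.labeling.labels}
        print(f"study {tag}: {cm.n_cells} cells x {cm.n_genes} genes, "
              f"median library {int(pd.Series(cm.values.sum(axis=1)).median())} counts")
        print(f"  composition: {sizes}")
    pd.DataFrame(
        sorted(gta.correspondence.items()), columns=["subgroup_a", "subgroup_b"]
    ).to_csv(OUT / "planted_correspondence.tsv", sep="\t", index=False)
    print(f"planted correspondence written to {OUT/'planted_correspondence.tsv'}")


if __name__ == "__main__":
    main()
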