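"""Trajectory classification: synthetic spots and the 21 annotated proteins.

Classifies every synthetic spot into the four condition-trajectory groups,
checks recovery of the planted labels, and classifies the curated
condition-wise patterns of the 21 annotated significant proteins (13 shoot,
8 root), reporting the headline continuing / condition-specific fractions.

Reads results/diffstats/ and results/synthetic/; writes results/trajectory/.
"""

from pathlib import Path

import pandas as pd

from digeflow import io, load_annotated_trajectories, trajectory

OUT = Path("results/trajectory")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for organ in io.ORGANS:
        table = io.read_spot_table(
            Path("results/diffstats") / f"{organ}_normalized.tsv",
            Path("results/synthetic") / f"{organ}_samples.tsv")
        calls = trajectory.classify_table(table)
        calls.to_csv(OUT / f"{organ}_calls.tsv", sep="\t")
        truth = pd.read_csv(Path("results/synthetic") / f"{organ}_truth.tsv",
                            sep="\t", index_col=0)["group"]
        accuracy = (calls["group"] == truth.reindex(calls.index)).mean()
        summary = trajectory.headline_fractions(calls)
        print(f"{organ}: groups {trajectory.group_counts(calls)}; "
              f"planted-label recovery {100 * accuracy:.1f}%; "
              f"continuing {summary['continuing_pct']:.1f}%")

    tab = load_annotated_trajectories()
    tab["group"] = [
        trajectory.classify_trajectory(r.mean_control, r.mean_anoxia,
                                       r.mean_reaeration)
        for r in tab.itertuples()
    ]
    tab["max_condition"] = [
        trajectory.condition_of_max(r.mean_control, r.mean_anoxia,
                                    r.mean_reaeration)
        for r in tab.itertuples()
    ]
    tab.to_csv(OUT / "annotated_proteins.tsv", sep="\t", index=False)
    summary = trajectory.headline_fractions(tab)
    print(f"annotated proteins (n={summary['n']}): "
          f"continuing {summary['continuing']} ({summary['continuing_pct']:.0f}%), "
          f"condition-specific {summary['condition_specific']} "
          f"({summary['condition_specific_pct']:.0f}%): "
          f"{summary['anoxia_specific']} anoxia-specific, "
          f"{summary['reaeration_specific']} re-aeration-specific")


if __name__ == "__main__":
    main()
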