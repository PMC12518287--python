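"""Differential spot statistics per organ.

Log2-transforms and quantile-normalizes each organ's spot table, runs the
three significance frameworks (Kruskal-Wallis, random-intercept mixed
model, empirical-Bayes moderated F), adjusts p-values with BH and Holm, and
selects significant spots at adjusted p < 0.05 under the moderated test
(the framework the study settled on).

Reads results/synthetic/; writes results/diffstats/.
"""

from pathlib import Path

import pandas as pd

from digeflow import io, spotstats

IN = Path("results/synthetic")
OUT = Path("results/diffstats")
ALPHA = 0.05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for organ in io.ORGANS:
        table = io.read_spot_table(IN / f"{organ}_spots.tsv",
                                   IN / f"{organ}_samples.tsv")
        normalized = spotstats.quantile_normalize(spotstats.log2_and_average(table))
        io.write_spot_table(normalized, OUT / f"{organ}_normalized.tsv")

        frames = []
        for method in ("kruskal", "mixed", "moderated"):
            for adjustment in ("BH", "Holm"):
                frames.append(spotstats.differential_tests(
                    normalized, method=method, adjustment=adjustment))
        results = pd.concat(frames, ignore_index=True)
        results.to_csv(OUT / f"{organ}_tests.tsv", sep="\t", index=False)

        chosen = results[(results.method == "moderated") &
                         (results.adjustment == "BH")]
        significant = spotstats.select_significant(chosen, ALPHA)
        pd.Series(significant, name="spot_id").to_csv(
            OUT / f"{organ}_significant.tsv", sep="\t", index=False)
        counts = {
            m: len(spotstats.select_significant(
                results[(results.method == m) & (results.adjustment == "BH")],
                ALPHA))
            for m in ("kruskal", "mixed", "moderated")
        }
        print(f"{organ}: significant spots at BH-adjusted p<{ALPHA}: {counts} "
              f"of {table.n_spots} (rank-based KW cannot clear BH at "
              f"3 replicates/condition — its smallest attainable raw p is "
              f"~0.027; variance moderation is what makes this design "
              f"powered)")


if __name__ == "__main__":
    main()
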