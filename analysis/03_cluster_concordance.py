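"""Clustering of samples and spots, and concordance between algorithms.

Clusters the pseudo-samples (columns) and the significant spots (rows) of
each organ's normalized table with k-means (elbow-selected k) and
complete-linkage hierarchical clustering (silhouette-selected k), then
scores the agreement between the two algorithms with the Simpson and
Jaccard concordance statistics.

Reads results/diffstats/; writes results/clustering/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from digeflow import cluster, io

IN = Path("results/diffstats")
OUT = Path("results/clustering")
SEED = 2025


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for organ in io.ORGANS:
        table = io.read_spot_table(IN / f"{organ}_normalized.tsv",
                                   IN / f"{organ}_samples.tsv"
                                   if (IN / f"{organ}_samples.tsv").exists()
                                   else Path("results/synthetic") / f"{organ}_samples.tsv")
        # samples
        X = table.matrix.T
        ids = table.sheet.sample_ids
        k_elbow, wss = cluster.select_k_elbow(X, k_max=len(ids) - 1, seed=SEED)
        km = cluster.kmeans_cluster(X, k_elbow, seed=SEED, item_ids=ids)
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        k_sil, _ = cluster.select_k_silhouette(D, item_ids=ids)
        hc = cluster.hier_cluster(D, k_sil, item_ids=ids)
        km.to_frame().to_csv(OUT / f"{organ}_samples_kmeans.tsv", sep="\t", index=False)
        hc.to_frame().to_csv(OUT / f"{organ}_samples_hier.tsv", sep="\t", index=False)
        (OUT / f"{organ}_samples_dendrogram.nwk").write_text(
            cluster.linkage_to_newick(cluster.complete_linkage_tree(D), ids) + "\n")
        # the qualitative stress-similarity claim is a two-way split:
        # do anoxia and re-aeration samples share a cluster apart from control?
        km2 = cluster.kmeans_cluster(X, 2, seed=SEED, item_ids=ids)
        hc2 = cluster.hier_cluster(D, 2, item_ids=ids)
        conds = table.sheet.conditions
        together = all(
            len(set(part.labels[(conds == "anoxia") | (conds == "reaeration")])) == 1
            and set(part.labels[conds == "control"])
            != set(part.labels[conds == "anoxia"])
            for part in (km2, hc2)
        )
        print(f"{organ} samples: k-means k={k_elbow}, hierarchical k={k_sil}; "
              f"at k=2 anoxia clusters with re-aeration apart from control: "
              f"{together}")

        # spots
        Xs = table.matrix
        spot_ids = table.spot_ids
        ks_elbow, _ = cluster.select_k_elbow(Xs, k_max=8, seed=SEED)
        km_s = cluster.kmeans_cluster(Xs, ks_elbow, seed=SEED, item_ids=spot_ids)
        Ds = np.linalg.norm(Xs[:, None] - Xs[None, :], axis=2)
        ks_sil, _ = cluster.select_k_silhouette(Ds, item_ids=spot_ids)
        hc_s = cluster.hier_cluster(Ds, ks_sil, item_ids=spot_ids)
        km_s.to_frame().to_csv(OUT / f"{organ}_spots_kmeans.tsv", sep="\t", index=False)
        hc_s.to_frame().to_csv(OUT / f"{organ}_spots_hier.tsv", sep="\t", index=False)
        for mode in ("simpson", "jaccard"):
            score = cluster.partition_concordance(km_s, hc_s, mode)
            rows.append({"organ": organ, "items": "spots", "mode": mode,
                         "S": score.S, "k_kmeans": km_s.k, "k_hier": hc_s.k})
        print(f"{organ} spots: k-means k={ks_elbow} vs hierarchical k={ks_sil}; "
              f"S_simpson={rows[-2]['S']:.3f}, S_jaccard={rows[-1]['S']:.3f}")

    pd.DataFrame(rows).to_csv(OUT / "concordance.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
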