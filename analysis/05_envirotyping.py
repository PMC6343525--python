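#!/usr/bin/env python
"""Classify environments by stress pattern and profile the genotypes.

Reads the indicator and yield tables written by 04_crop_simulation.py,
clusters environments on principal components of the standardized
indicators (Ward linkage, automatic k), names each cluster by its
dominant stress, scores recovery against the planted archetypes, and
ranks genotypes by top-rank frequency within each environment type.
Writes:

    results/env_typing.csv         environment, cluster, name
    results/genotype_profiles.csv  top-rank frequency per cluster
    results/location_clusters.csv  per-location cluster frequencies
"""

import argparse
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from heliastress.enviro import cluster_environments, location_summary, rank_genotypes

OUT = Path(__file__).resolve().parents[1] / "results"


def main(k="auto"):
    mat = pd.read_csv(OUT / "indicators.csv", index_col=0)
    yields = pd.read_csv(OUT / "yields.csv", index_col=0)
    labels = pd.read_csv(OUT / "env_labels.csv", index_col=0)["archetype"]

    typing = cluster_environments(mat, k=k)
    ari = adjusted_rand_score(labels.loc[typing.labels.index], typing.labels)
    print(f"Clustered {len(typing.labels)} environments into {typing.k} types "
          f"(ARI vs planted archetypes: {ari:.2f}):")
    for cid, name in sorted(typing.cluster_names.items()):
        n = int((typing.labels == cid).sum())
        print(f"  {name:10s} {n:3d} environments")
    typed = typing.labels.rename("cluster").to_frame()
    typed["name"] = typed["cluster"].map(typing.cluster_names)
    typed.to_csv(OUT / "env_typing.csv")

    prof = rank_genotypes(yields, typing)
    prof.to_csv(OUT / "genotype_profiles.csv", index=False)
    print("\nTop-rank frequency by environment type:")
    print(prof.pivot_table(index="genotype", columns="cluster_name",
                           values="top_rank_frequency").round(2).to_string())

    loc = location_summary(typing)
    loc.to_csv(OUT / "location_clusters.csv")
    print(f"\nWrote per-location cluster frequencies for {len(loc)} locations.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--k", default="auto")
    main(ap.parse_args().k)
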