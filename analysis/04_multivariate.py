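"""Source identification by correlation, PCA, Ward HCA and k-means.

Standardises the survey, reports the strongest element correlations, the
PCA variance profile, and clusters both elements and sites; element
clusters are compared with the planted source groups.
"""

from pathlib import Path

import pandas as pd

from schooldust import read_concentration_csv
from schooldust.multivariate import (
    hierarchical_cluster,
    kmeans_cluster,
    partitions_agree,
    pca_decomposition,
    pearson_matrix,
    select_k,
    zscore_standardize,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    conc = read_concentration_csv(ROOT / "data" / "concentrations.csv")
    groups = pd.read_csv(ROOT / "data" / "element_groups.csv", index_col="element")["group"]
    out = ROOT / "multivariate"
    out.mkdir(parents=True, exist_ok=True)

    Z = zscore_standardize(conc)
    corr = pearson_matrix(conc.data)
    corr.to_csv(out / "correlation.csv")
    # strongest off-diagonal correlations
    strong = (
        corr.stack()
        .loc[lambda s: [a < b for a, b in s.index]]
        .sort_values(ascending=False)
    )
    print("strongest element correlations:")
    for (a, b), r in strong.head(4).items():
        print(f"  {a}-{b}: r = {r:.2f}")

    pca = pca_decomposition(Z)
    pd.DataFrame({"explained_variance_ratio": pca.explained_variance_ratio}).to_csv(
        out / "variance.csv", index=False
    )
    cum = pca.cumulative_variance
    print(f"\nPCA: 2 components explain {100 * cum[1]:.1f}%, 3 explain {100 * cum[2]:.1f}%")

    hca_el = hierarchical_cluster(Z, mode="elements", n_clusters=3)
    hca_el.labels.rename_axis("element").to_csv(out / "hca_labels_elements.csv")
    pd.DataFrame(
        hca_el.linkage_matrix, columns=["left", "right", "height", "size"]
    ).to_csv(out / "linkage_elements.csv", index=False)
    km_el = kmeans_cluster(Z.T, 3, seed=0)
    km_el.rename_axis("element").to_csv(out / "kmeans_labels_elements.csv")

    truth = pd.Series(pd.factorize(groups)[0] + 1, index=groups.index)
    print("\nelement clusters (HCA, k=3):")
    for cid, members in hca_el.groups().items():
        print(f"  cluster {cid}: {', '.join(members)}")
    print(
        "HCA matches planted groups:",
        partitions_agree(hca_el.labels, truth),
        "| k-means matches HCA:",
        partitions_agree(km_el, hca_el.labels),
    )

    ksel = select_k(Z, seed=0)
    pd.DataFrame({"wcss": ksel.wcss, "silhouette": ksel.silhouette}).rename_axis("k").to_csv(
        out / "k_selection_sites.csv"
    )
    hca_sites = hierarchical_cluster(Z, mode="sites", n_clusters=ksel.k_selected)
    hca_sites.labels.rename_axis("site").to_csv(out / "hca_labels_sites.csv")
    print(f"\nsite clustering: silhouette selects k = {ksel.k_selected}")


if __name__ == "__main__":
    main()
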