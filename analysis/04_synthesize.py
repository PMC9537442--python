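"""Synthesise a scenario table: variance partitioning, CCA, ANOVA, figures.

Reads the long scenario table produced by the run scripts, partitions the
explained variance of the three accuracy statistics among the factor groups
(mechanism, surface, remaining movement parameters or destination bias, and
model choice), runs a canonical correspondence analysis with level centroids,
a factorial ANOVA per statistic, and writes summary CSVs plus boxplots and a
biplot.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from landconn.ordination import anova_factorial, cca, variance_partition
from landconn.pipeline import partition_groups, response_matrix, summarize_by_model
from landconn.plots import grouped_boxplots, ordination_biplot, partition_barplot


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", default="results/first_scenarios.csv")
    ap.add_argument("--analysis", choices=["first", "second"], default="first")
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    out = Path(args.out or f"results/synthesis_{args.analysis}")
    out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.table)
    Y = response_matrix(table)
    groups = partition_groups(table, args.analysis)
    # drop factor groups that do not vary in this table (reduced profiles)
    groups = {g: X for g, X in groups.items() if any(X[c].nunique() > 1 for c in X)}

    pooled = summarize_by_model(table)
    pooled.to_csv(out / "pooled_by_model.csv")
    print("pooled accuracy by model:")
    print(pooled.round(4).to_string())

    part = variance_partition(Y, groups)
    rows = [("+".join(k), v) for k, v in part.components.items()]
    rows.append(("residual", part.residual))
    pd.DataFrame(rows, columns=["component", "fraction"]).to_csv(
        out / "variance_partition.csv", index=False
    )
    partition_barplot(part, str(out / "variance_partition.png"),
                      title=f"{args.analysis} analysis")
    print("\nunique variance fractions (largest factor drives accuracy):")
    for g in groups:
        print(f"  {g}: {part.unique(g):.4f}")

    factors = pd.concat(list(groups.values()), axis=1).astype(str)
    ord_res = cca(Y - Y.min(axis=0), factors)  # min-shift: CCA needs Y >= 0
    pd.DataFrame(
        {"axis": np.arange(1, ord_res.eigenvalues_constrained.size + 1),
         "eigenvalue": ord_res.eigenvalues_constrained}
    ).to_csv(out / "cca_eigenvalues.csv", index=False)
    ordination_biplot(ord_res, str(out / "cca_biplot.png"),
                      title=f"CCA, {args.analysis} analysis")
    print(f"\nCCA: {ord_res.proportion_constrained:.3f} of inertia constrained")

    aov_factors = table[["mechanism", "surface_id", "model"]].astype(str)
    for stat in ("rmse", "pearson", "overlap"):
        aov = anova_factorial(table[stat].to_numpy(), aov_factors)
        aov.to_csv(out / f"anova_{stat}.csv")
        inter = aov[aov.index.str.contains(":")]["sum_sq"]
        print(f"ANOVA [{stat}]: largest interaction {inter.idxmax()} "
              f"(SS {inter.max():.3g} of total {aov['sum_sq'].sum():.3g})")

    key = "D" if args.analysis == "second" else "surface_id"
    grouped_boxplots(table, "model", str(out / "boxplots_by_model.png"))
    grouped_boxplots(table, key, str(out / f"boxplots_by_{key}.png"))
    print(f"figures and tables in {out}")


if __name__ == "__main__":
    main()
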