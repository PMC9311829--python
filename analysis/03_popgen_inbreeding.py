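"""Marker screening and inbreeding indices for bumblebees and ants.

Per locus: observed/expected heterozygosity and the exact conditional
Hardy-Weinberg test; per locus pair: the genotypic linkage-
disequilibrium permutation test; both Holm-corrected within their
families.  Per individual: multilocus heterozygosity and d^2.  Also
runs the study's group comparisons (species within location, location
within species) with the normality-gated t / Mann-Whitney choice and a
batch Holm correction.

Writes results/locus_stats.csv, results/ld_stats.csv,
results/inbreeding_indices.csv and results/group_comparisons.csv.
"""
import pathlib
import warnings

import pandas as pd

from asymlink.popgen import (
    GenotypeTable,
    compare_groups_batch,
    inbreeding_indices,
    locus_screen,
)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 1002


def main():
    warnings.filterwarnings("ignore")
    tables = {
        "bees": GenotypeTable.from_csv(ROOT / "study" / "genotypes_bees.csv",
                                       motifs={f"loc{j:02d}": 2 for j in range(1, 8)}),
        "ants": GenotypeTable.from_csv(ROOT / "study" / "genotypes_ants.csv",
                                       motifs={f"loc{j:02d}": 2 for j in range(1, 14)}),
    }
    locus_frames, ld_frames, index_frames = [], [], []
    for name, table in tables.items():
        stats, ld = locus_screen(table, seed=SEED)
        stats = stats.reset_index(); stats.insert(0, "dataset", name)
        ld.insert(0, "dataset", name)
        idx = inbreeding_indices(table).join(table.groups).reset_index()
        idx.insert(0, "dataset", name)
        locus_frames.append(stats); ld_frames.append(ld); index_frames.append(idx)
        n_hwe = (stats["hwe_p_holm"] < 0.05).sum()
        n_ld = (ld["ld_p_holm"] < 0.05).sum()
        print(f"{name}: {n_hwe}/{len(stats)} loci off Hardy-Weinberg, "
              f"{n_ld}/{len(ld)} locus pairs linked (Holm-corrected)")

    indices = pd.concat(index_frames, ignore_index=True)
    ants = indices[indices["dataset"] == "ants"]
    comparisons = {}
    for loc in ants["location"].unique():
        sub = ants[ants["location"] == loc]
        groups = {s: g["mlh"].to_numpy() for s, g in sub.groupby("species")}
        if len(groups) == 2 and all(len(v) >= 3 for v in groups.values()):
            comparisons[f"mlh_species_within_{loc}"] = groups
    for species in ants["species"].unique():
        sub = ants[ants["species"] == species]
        groups = {l: g["mlh"].to_numpy() for l, g in sub.groupby("location")}
        if len(groups) == 2 and all(len(v) >= 3 for v in groups.values()):
            comparisons[f"mlh_location_within_{species}"] = groups
    comps = compare_groups_batch(comparisons)
    print(comps[["test", "statistic", "p", "p_holm"]].round(4))

    pd.concat(locus_frames, ignore_index=True).to_csv(ROOT / "locus_stats.csv", index=False)
    pd.concat(ld_frames, ignore_index=True).to_csv(ROOT / "ld_stats.csv", index=False)
    indices.to_csv(ROOT / "inbreeding_indices.csv", index=False)
    comps.to_csv(ROOT / "group_comparisons.csv")
    print(f"wrote locus, LD, index and comparison tables under {ROOT}")


if __name__ == "__main__":
    main()
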