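"""Richness, shared/unique gene overlap, and per-category group tests.

Answers the first-order questions of the study design: does overall gene
richness differ between elevation groups, which functional categories
are enriched at high elevation, and which lineages carry the signal.

Writes results/tables/{richness.tsv, category_tests.tsv, taxa_stress.tsv}.
"""

from pathlib import Path

from fmena import io as fio
from fmena.group_stats import (
    category_ttest,
    overlap,
    results_table,
    richness,
    taxa_function_aggregate,
)
from fmena.preprocess import run_preprocessing

DATA = Path("results/data")
TABLES = Path("results/tables")


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    raw, annotation = fio.read_signal_table(DATA / "signals.tsv")
    design = fio.read_design(DATA / "design.tsv")
    pre = run_preprocessing(raw, design)

    rich = richness(pre.matrix, design, annotation)
    rich.per_group_category.to_csv(TABLES / "richness.tsv", sep="\t")
    print(f"probes detected overall: {rich.total}; per group: {rich.per_group.to_dict()}")

    ov = overlap(pre.matrix, design)
    print(
        f"overlap: {ov.pct_shared:.2f}% shared, {ov.pct_unique_low:.2f}% unique to low, "
        f"{ov.pct_unique_high:.2f}% unique to high (union {ov.union})"
    )

    tests = category_ttest(pre.matrix, design, annotation, level="category")
    table = results_table(tests).sort_values("p")
    table.to_csv(TABLES / "category_tests.tsv", sep="\t", index=False)
    sig = table[(table["p"] < 0.05) & (table["mean_high"] > table["mean_low"])]
    print("\ncategories enriched at high elevation (p < 0.05):")
    print(sig[["unit", "mean_low", "mean_high", "t", "p"]].to_string(index=False))

    taxa = results_table(
        taxa_function_aggregate(pre.matrix, annotation, design, "stress response")
    ).sort_values("p")
    taxa.to_csv(TABLES / "taxa_stress.tsv", sep="\t", index=False)
    exclusive = taxa[taxa["group_exclusive"].notna()]
    if len(exclusive):
        print("\ngroup-exclusive lineages within stress response:")
        print(exclusive[["unit", "group_exclusive"]].to_string(index=False))


if __name__ == "__main__":
    main()
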