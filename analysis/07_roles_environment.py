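"""Node roles, top-connectivity genes, and module-environment links.

Classifies every network node by within-module degree z-score (Zi) and
participation coefficient (Pi), ranks genes by connectivity, computes
the eigengene (first principal component) of each of the five largest
modules, and correlates eigengenes with the environment table by
Spearman rank correlation.

Reads results/networks/ and results/data/; writes
results/tables/{roles_<group>.tsv, module_env_<group>.tsv}.
"""

from pathlib import Path

from fmena import io as fio
from fmena.datatypes import SignalMatrix
from fmena.preprocess import run_preprocessing
from fmena.roles import (
    env_correlation,
    env_correlation_table,
    module_eigengene,
    node_roles,
    roles_table,
    top_connectivity_genes,
)
from fmena.topology import fast_greedy_modules

DATA = Path("results/data")
NETS = Path("results/networks")
TABLES = Path("results/tables")


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    raw, annotation = fio.read_signal_table(DATA / "signals.tsv")
    design = fio.read_design(DATA / "design.tsv")
    env = fio.read_env(DATA / "env.tsv")
    pre = run_preprocessing(raw, design)

    for group in ("low", "high"):
        net = fio.read_network_graphml(NETS / f"{group}.graphml")
        part = fast_greedy_modules(net)
        roles = node_roles(net, part)
        table = roles_table(roles, annotation)
        table.to_csv(TABLES / f"roles_{group}.tsv", sep="\t")
        counts = table["role"].value_counts().to_dict()
        print(f"[{group}] roles: {counts}")
        top = top_connectivity_genes(net, k=5)
        named = [(g, annotation.loc[g, "gene_family"], k) for g, k in top]
        print(f"  top-connectivity genes: {named}")

        samples = [s for s in pre.matrix.samples if design.group_of_sample(s) == group]
        group_matrix = SignalMatrix(
            pre.matrix.values[samples], transformed=True, normalized=True
        )
        eigengenes = module_eigengene(group_matrix, part, top_k_modules=5)
        corrs = env_correlation(eigengenes, env.loc[samples])
        etable = env_correlation_table(corrs)
        etable.to_csv(TABLES / f"module_env_{group}.tsv", sep="\t", index=False)
        strong = etable[(etable["p"] < 0.05) & etable["rho"].notna()]
        print("  significant module-environment correlations:")
        if len(strong):
            print(strong.round(3).to_string(index=False))
        else:
            print("    none at p < 0.05")


if __name__ == "__main__":
    main()
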