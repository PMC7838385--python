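"""Infer the functional molecular ecological networks (fMENs).

For each elevation group: select the commonly detected genes of the
carbon/nitrogen/phosphorus-cycling and stress-response categories,
compute the Pearson correlation matrix over the group's 12 samples, scan
similarity thresholds for the Poisson transition of the eigenvalue
nearest-neighbour spacing distribution, and build the signed network.
When the spacing scan cannot stabilize at this sample size the fixed
threshold |r| >= 0.8 is used instead (reported as such).

Writes results/networks/{low,high}.graphml, .sif and the scan summaries.
"""

from pathlib import Path

from fmena import io as fio
from fmena.preprocess import run_preprocessing
from fmena.rmt import (
    ThresholdScanError,
    build_network,
    pearson_matrix,
    select_common_genes,
    select_threshold,
)

DATA = Path("results/data")
NETS = Path("results/networks")
FALLBACK_ST = 0.8


def main() -> None:
    NETS.mkdir(parents=True, exist_ok=True)
    raw, annotation = fio.read_signal_table(DATA / "signals.tsv")
    design = fio.read_design(DATA / "design.tsv")
    pre = run_preprocessing(raw, design)

    for group in design.groups:
        genes = select_common_genes(pre.matrix, design, annotation, group)
        samples = [s for s in pre.matrix.samples if design.group_of_sample(s) == group]
        corr = pearson_matrix(pre.matrix.values.loc[genes, samples])
        print(f"\n[{group}] {len(genes)} candidate genes, {len(samples)} samples")
        try:
            scan = select_threshold(corr)
            st = scan.selected_st
            scan.summary().to_csv(NETS / f"{group}_scan.tsv", sep="\t", index=False)
            print(f"  RMT scan selected st = {st}")
        except ThresholdScanError as exc:
            st = FALLBACK_ST
            print(f"  spacing scan did not stabilize ({exc});")
            print(f"  using fixed threshold |r| >= {st}")
        net = build_network(corr, st, annotation)
        fio.write_network(net, NETS / f"{group}.graphml", "graphml")
        fio.write_network(net, NETS / f"{group}.sif", "sif")
        print(
            f"  network: n = {net.n}, links = {net.L} "
            f"({net.pct_positive:.0f}% positive / {net.pct_negative:.0f}% negative)"
        )


if __name__ == "__main__":
    main()
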