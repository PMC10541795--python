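#!/usr/bin/env python
"""Generate the synthetic reciprocal-cross study used by the later steps.

Writes a complete fixture bundle (trio VCF, masked genome FASTA, reads
SAM, annotation GTF, count/design/truth TSVs) plus the two statistical
experiments: an F0+F1 count experiment with known cis/trans structure and
a reciprocal-cross imprinting experiment with known parental bias.
"""

import argparse
from pathlib import Path

from asecross.allele_assignment import AlleleCountTable
from asecross.io_formats import CountMatrix
from asecross.synthetic_data import (SimConfig, simulate_count_experiment,
                                     simulate_imprinting_experiment,
                                     write_fixture_bundle)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out
    (out / "bundle").mkdir(parents=True, exist_ok=True)

    paths = write_fixture_bundle(out / "bundle", SimConfig(seed=args.seed))
    print("fixture bundle:")
    for name, path in paths.items():
        print(f"  {name}: {path}")

    counts = simulate_count_experiment(SimConfig(seed=args.seed, n_genes=2400))
    CountMatrix(counts.f0_counts).to_tsv(out / "f0_counts.tsv")
    AlleleCountTable.from_alleles(
        counts.f1_allele_a, counts.f1_allele_b).to_tsv(
        out / "f1_allele_counts.tsv")
    counts.design.to_csv(out / "design.tsv", sep="\t", index=False)
    counts.truth.to_csv(out / "cis_trans_truth.tsv", sep="\t")
    print(f"\ncount experiment: {counts.f0_counts.shape[0]} genes, "
          f"{counts.f0_counts.shape[1]} F0 + "
          f"{counts.f1_allele_a.shape[1]} F1 libraries "
          f"-> {out}/f0_counts.tsv, f1_allele_counts.tsv")
    print("true category counts:")
    print(counts.truth["category"].value_counts().to_string())

    imp = simulate_imprinting_experiment(
        SimConfig(seed=args.seed + 1, n_genes=2000, imprint_fraction=0.25,
                  maternal_bias=0.9, n_per_direction=3))
    AlleleCountTable.from_alleles(imp.allele_a, imp.allele_b).to_tsv(
        out / "imprinting_allele_counts.tsv")
    imp.design.to_csv(out / "imprinting_design.tsv", sep="\t", index=False)
    imp.truth.to_csv(out / "imprinting_truth.tsv", sep="\t")
    n_imp = (imp.truth["true_imprint"] != "none").sum()
    print(f"\nimprinting experiment: {len(imp.truth)} genes, "
          f"{n_imp} with parental bias -> {out}/imprinting_*.tsv")


if __name__ == "__main__":
    main()
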