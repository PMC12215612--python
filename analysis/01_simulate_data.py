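"""Generate every synthetic dataset the downstream analyses consume.

Writes, under results/data/:
  genomes/      - reference + 20 evolved haplotype annotations with hit
                  tables and the planted hyper-conserved window (the
                  SDR stand-in), plus ground truth
  population/   - VCF of 10 diploids with a 150-kbp non-recombining,
                  sex-linked region, plus ground truth

Run:  python analysis/01_simulate_data.py [--seed 1] [--out results/data]
"""

import argparse
from pathlib import Path

from grapesdr.simulate import (
    GenomeSimConfig,
    PopSimConfig,
    simulate_genome_set,
    simulate_population,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    genome_dir = args.out / "genomes"
    gs = simulate_genome_set(GenomeSimConfig(seed=args.seed))
    gs.write(genome_dir)
    print(
        f"genome set: {len(gs.annotations)} haplotypes, "
        f"{gs.truth.params['n_genes']} ancestral genes, planted window "
        f"{gs.truth.params['planted_window']} -> {genome_dir}"
    )

    pop_dir = args.out / "population"
    pop_dir.mkdir(parents=True, exist_ok=True)
    pop = simulate_population(PopSimConfig(seed=args.seed))
    pop.write_vcf(pop_dir / "population.vcf")
    pop.truth.to_json(pop_dir / "truth.json")
    lo, hi = pop.truth.params["sdr_interval"]
    print(
        f"population: {pop.truth.params['n_variants']} SNPs, "
        f"SDR {lo}-{hi} bp, {pop.truth.params['n_markers']} sex-linked "
        f"marker sites -> {pop_dir}"
    )


if __name__ == "__main__":
    main()
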