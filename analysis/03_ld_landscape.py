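"""LD landscape of the simulated population: SDR detection.

Filters SNPs with the resequencing profile, computes pairwise r² within
300 kbp, fits Hill-Weir decay (half-decay distance), aggregates the
1-kbp LD landscape, recovers the elevated-LD segment, and contrasts
hom/het ratios between heterogametic and homogametic samples inside
the recovered region.

Reads results/data/population/ (from 01); writes results/ld/.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from grapesdr.formats import read_vcf_region, write_tsv
from grapesdr.ld import (
    FilterProfile,
    aggregate_ld_bins,
    compare_ratio_groups,
    filter_variants,
    fit_ld_decay,
    hom_het_ratio,
    pairwise_r2,
    recover_high_ld_interval,
)
from grapesdr.simulate import SimTruth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/population"))
    ap.add_argument("--out", type=Path, default=Path("results/ld"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = SimTruth.from_json(args.data / "truth.json")
    m = read_vcf_region(args.data / "population.vcf")
    filtered, tally = filter_variants(m, FilterProfile())
    print(f"filtered {m.n_variants} -> {filtered.n_variants} SNPs ({tally})")

    pairs = pairwise_r2(filtered)
    fit = fit_ld_decay(pairs, 2 * filtered.n_samples)
    print(
        f"{len(pairs)} pairs; Hill-Weir rho = {fit.rho:.3g}, half-decay at "
        f"{fit.half_decay_bp:.0f} bp"
    )

    span = int(filtered.positions.max()) + 1000
    landscape = aggregate_ld_bins(
        pairs, (0, span), 1000, min_snps=5, positions=filtered.positions
    )
    write_tsv(landscape, args.out / "landscape.tsv")
    interval = recover_high_ld_interval(landscape)
    lo, hi = truth.params["sdr_interval"]
    print(f"high-LD segment {interval} (planted SDR {lo}-{hi})")

    ratios = hom_het_ratio(m, tuple(interval) if interval else (lo, hi))
    group_of = {
        s: ("het" if f else "hom")
        for s, f in zip(m.samples, truth.params["heterogametic"])
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        H, p, dunn = compare_ratio_groups(ratios, group_of)
    write_tsv(ratios.assign(group=ratios["sample"].map(group_of)),
              args.out / "hom_het_ratios.tsv")
    print(f"hom/het contrast: H = {H:.2f}, p = {p:.3g}")

    inside = landscape[(landscape.bin_start >= lo) & (landscape.bin_start < hi)]
    flank = landscape[
        ((landscape.bin_start >= lo - 200_000) & (landscape.bin_start < lo))
        | ((landscape.bin_start >= hi) & (landscape.bin_start < hi + 200_000))
    ]
    report = {
        "n_snps": filtered.n_variants,
        "n_pairs": len(pairs),
        "hill_weir": {
            "rho": fit.rho,
            "n_chromosomes": fit.n,
            "half_decay_bp": None if fit.no_decay else fit.half_decay_bp,
        },
        "high_ld_interval": list(interval) if interval else None,
        "planted_sdr": [lo, hi],
        "mean_r2_inside": float(np.nanmean(inside["mean_r2"])),
        "mean_r2_flanks": float(np.nanmean(flank["mean_r2"])),
        "hom_het_kruskal_p": float(p),
        "hom_het_dunn": dunn.to_dict(orient="records"),
    }
    with open(args.out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


if __name__ == "__main__":
    main()
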