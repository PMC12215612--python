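"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: a clade-
structured set of genomes evolved from an ancestral gene order (with one
planted hyper-conserved window standing in for the sex-determining
region), a diploid population with a planted non-recombining region
carrying sex-linked haplotypes, codon alignments diverged at known dS,
LTR pairs diverged at known K, and promoter sets with group-specific
planted motifs.  All generators are pure functions of config + seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    GeneModel,
    GenomeAnnotation,
    GenotypeMatrix,
    HitTable,
    HomologyHit,
    write_fasta,
    write_gff_genes,
)
from .motifs import Promoter

__all__ = [
    "SimTruth",
    "GenomeSimConfig",
    "GenomeSet",
    "simulate_genome_set",
    "PopSimConfig",
    "PopulationSim",
    "simulate_population",
    "simulate_codon_pairs",
    "simulate_ltr_pair",
    "simulate_promoter_groups",
]


@dataclass
class SimTruth:
    """Ground-truth record serialized alongside every simulated dataset."""

    kind: str
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], params=d["params"])


# ---------------------------------------------------------------------------
# Genome set


@dataclass
class GenomeSimConfig:
    """Clade-structured genome evolution from one ancestral gene order.

    Rates are events per gene per unit divergence time.  Bit scores
    follow pair = self * exp(-lambda * t * (1 - boost)) with lognormal
    noise of sd ``score_noise_sd``; ``boost`` applies only to genes of
    the planted window.  Non-flowering haplotypes lose the planted
    window entirely, angiosperms never lose or rearrange it.
    """

    n_genes: int = 2400
    window_size: int = 12
    clade_sizes: dict = field(
        default_factory=lambda: {
            "eudicot": 8,
            "other-angiosperm": 8,
            "non-flowering": 4,
        }
    )
    time_ranges: dict = field(
        default_factory=lambda: {
            "eudicot": (0.4, 1.2),
            "other-angiosperm": (0.8, 1.6),
            "non-flowering": (1.8, 2.2),
        }
    )
    loss_rate: float = 0.03
    gain_rate: float = 0.02
    inversion_rate: float = 0.002
    tandem_dup_rate: float = 0.01
    inversion_mean_genes: int = 8
    wgd_haplotypes: tuple = ()
    planted_window: int = 40
    planted_boost: float = 0.9
    self_score_mean: float = 500.0
    self_score_sd: float = 100.0
    decay_lambda: float = 0.4
    score_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("loss_rate", "gain_rate", "inversion_rate",
                     "tandem_dup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.planted_boost <= 1.0:
            raise ValueError("planted_boost must be in [0, 1]")
        t_max = max(hi for _, hi in self.time_ranges.values())
        if self.loss_rate * t_max >= 1.0:
            raise ValueError(
                "loss_rate x max divergence time >= 1: expected losses "
                "exceed the gene count"
            )
        n_windows = self.n_genes // self.window_size
        if not 0 <= self.planted_window < n_windows:
            raise ValueError("planted_window outside the windowed range")


@dataclass
class GenomeSet:
    ref: GenomeAnnotation
    annotations: dict  # haplotype id -> GenomeAnnotation
    hit_tables: dict  # haplotype id -> HitTable
    truth: SimTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gff_genes(self.ref, outdir / "reference.gff3")
        for hap, ann in self.annotations.items():
            write_gff_genes(ann, outdir / f"{hap}.gff3")
            table = self.hit_tables[hap]
            with open(outdir / f"{hap}.hits.tsv", "w") as fh:
                for g, s in sorted(table.self_scores.items()):
                    fh.write(_outfmt6(g, g, s, 0.0))
                for h in table.hits:
                    fh.write(_outfmt6(h.query_id, h.subject_id, h.bitscore,
                                      h.evalue))
        self.truth.to_json(outdir / "truth.json")


def _outfmt6(q: str, s: str, bitscore: float, evalue: float) -> str:
    # qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    # evalue bitscore
    return (
        f"{q}\t{s}\t90.0\t300\t30\t0\t1\t300\t1\t300\t{evalue:g}\t{bitscore:.1f}\n"
    )


def _ref_annotation(n_genes: int) -> GenomeAnnotation:
    genes = [
        GeneModel(f"g{i:05d}", "chr1", i * 2000, i * 2000 + 1000, "+", i)
        for i in range(n_genes)
    ]
    return GenomeAnnotation("reference", "eudicot", {"chr1": genes})


def simulate_genome_set(cfg: GenomeSimConfig) -> GenomeSet:
    """Evolve one descendant haplotype per configured lineage.

    Each lineage independently applies gene losses, tandem duplications,
    gene gains and segmental inversions to the ancestral order, then
    draws homology bit scores from the divergence-decay model.  WGD
    haplotypes carry the whole gene order twice (contigs chr1/chr2).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0x6E0])
    n = cfg.n_genes
    ref = _ref_annotation(n)
    w0 = cfg.planted_window * cfg.window_size
    planted = set(range(w0, w0 + cfg.window_size))
    self_scores = {
        f"g{i:05d}": float(s)
        for i, s in enumerate(
            np.clip(
                rng.normal(cfg.self_score_mean, cfg.self_score_sd, n), 50.0, None
            )
        )
    }

    annotations: dict[str, GenomeAnnotation] = {}
    hit_tables: dict[str, HitTable] = {}
    clade_of: dict[str, str] = {}
    times: dict[str, float] = {}
    hap_idx = 0
    for clade in sorted(cfg.clade_sizes):
        lo, hi = cfg.time_ranges[clade]
        for _ in range(cfg.clade_sizes[clade]):
            hap = f"{clade}_{hap_idx:02d}"
            hap_idx += 1
            t = float(rng.uniform(lo, hi))
            clade_of[hap] = clade
            times[hap] = t
            protected = planted if clade != "non-flowering" else set()

            # genome = list of (source ref index or None, strand)
            genome: list[tuple[int | None, str]] = [(i, "+") for i in range(n)]
            if clade == "non-flowering":
                genome = [g for g in genome if g[0] not in planted]
            # losses
            p_loss = 1.0 - np.exp(-cfg.loss_rate * t)
            keep = rng.random(len(genome)) >= p_loss
            genome = [
                g
                for g, k in zip(genome, keep)
                if k or (g[0] in protected)
            ]
            # tandem duplications
            n_td = rng.poisson(cfg.tandem_dup_rate * n * t)
            for _ in range(n_td):
                if not genome:
                    break
                pos = int(rng.integers(len(genome)))
                genome.insert(pos + 1, genome[pos])
            # gene gains (novel genes, no homology to the reference)
            n_gain = rng.poisson(cfg.gain_rate * n * t)
            for _ in range(n_gain):
                pos = int(rng.integers(len(genome) + 1))
                genome.insert(pos, (None, "+"))
            # inversions (never across the protected window)
            n_inv = rng.poisson(cfg.inversion_rate * n * t)
            for _ in range(n_inv):
                if len(genome) < 2:
                    break
                for _attempt in range(20):
                    length = int(rng.geometric(1.0 / cfg.inversion_mean_genes))
                    length = max(2, min(length, len(genome)))
                    start = int(rng.integers(0, len(genome) - length + 1))
                    segment = genome[start : start + length]
                    if protected and any(s in protected for s, _ in segment):
                        continue
                    genome[start : start + length] = [
                        (s, "-" if st == "+" else "+")
                        for s, st in reversed(segment)
                    ]
                    break

            contigs = {"c1": genome}
            if hap in cfg.wgd_haplotypes:
                contigs["c2"] = list(genome)

            genes: list[GeneModel] = []
            hits: list[HomologyHit] = []
            gid = 0
            for contig in sorted(contigs):
                for pos, (src, strand) in enumerate(contigs[contig]):
                    gene_id = f"{hap}_{gid:05d}"
                    gid += 1
                    genes.append(
                        GeneModel(
                            gene_id, contig, pos * 2000, pos * 2000 + 1000,
                            strand, pos,
                        )
                    )
                    if src is None:
                        continue
                    ref_id = f"g{src:05d}"
                    boost = cfg.planted_boost if src in planted else 0.0
                    score = self_scores[ref_id] * np.exp(
                        -cfg.decay_lambda * t * (1.0 - boost)
                    )
                    if cfg.score_noise_sd > 0:
                        score *= np.exp(
                            rng.normal(0.0, cfg.score_noise_sd)
                        )
                    score = float(min(score, self_scores[ref_id]))
                    hits.append(HomologyHit(ref_id, gene_id, score, 1e-60))
            annotations[hap] = GenomeAnnotation.from_genes(hap, genes,
                                                           clade=clade)
            hit_tables[hap] = HitTable(hits=hits, self_scores=dict(self_scores))

    truth = SimTruth(
        kind="genome_set",
        params={
            "seed": cfg.seed,
            "n_genes": n,
            "window_size": cfg.window_size,
            "planted_window": cfg.planted_window,
            "planted_boost": cfg.planted_boost,
            "clade_of": clade_of,
            "divergence_times": times,
            "wgd_haplotypes": list(cfg.wgd_haplotypes),
            "decay_lambda": cfg.decay_lambda,
        },
    )
    return GenomeSet(ref, annotations, hit_tables, truth)


# ---------------------------------------------------------------------------
# Population with a planted non-recombining region


@dataclass
class PopSimConfig:
    """Diploid population with one recombination-free, sex-linked region.

    Haplotypes are founder-copying mosaics: the copied founder switches
    along the chromosome with probability ``recomb_switch_per_bp`` per
    bp outside ``sdr_interval`` and never inside it.  Heterogametic
    samples carry one M-like SDR haplotype marked by M-specific alleles
    at density ``sdr_marker_per_bp`` (the diverged sex haplotype);
    everyone else carries F-like SDR haplotypes.
    """

    n_samples: int = 10
    # sample sex: True = heterogametic (one M-like SDR haplotype)
    heterogametic: tuple = (
        False, False, False, True, True, True, False, False, False, False,
    )
    chrom_length_bp: int = 2_000_000
    snp_per_bp: float = 1.0 / 500.0
    n_founders: int = 6
    recomb_switch_per_bp: float = 1e-5
    sdr_interval: tuple = (925_000, 1_075_000)
    sdr_marker_per_bp: float = 1.0 / 100.0
    dp_median: int = 30
    contig: str = "chr2"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples for LD")
        if len(self.heterogametic) != self.n_samples:
            raise ValueError("heterogametic flags must match n_samples")
        lo, hi = self.sdr_interval
        if not (0 <= lo < hi <= self.chrom_length_bp):
            raise ValueError("sdr_interval outside the chromosome")
        if self.snp_per_bp <= 0 or self.sdr_marker_per_bp <= 0:
            raise ValueError("densities must be positive")


@dataclass
class PopulationSim:
    config: PopSimConfig
    positions: np.ndarray
    genotypes: np.ndarray  # (n_variants, n_samples) codes 0/1/2
    truth: SimTruth

    def genotype_matrix(self) -> GenotypeMatrix:
        """In-memory matrix with model QUAL/DP/INFO fields (all passing)."""
        rng = np.random.default_rng([self.config.seed, 0xF1E1D])
        nv, ns = self.genotypes.shape
        qual = np.round(np.clip(rng.normal(60.0, 8.0, nv), 31.0, None), 2)
        depths = rng.poisson(self.config.dp_median, size=(nv, ns)).astype(
            np.int32
        )
        depths = np.clip(depths, 6, int(2.9 * self.config.dp_median))
        info = pd.DataFrame(
            {
                "QD": np.round(rng.uniform(10.0, 30.0, nv), 2),
                "FS": np.round(rng.uniform(0.0, 5.0, nv), 3),
                "MQ": np.full(nv, 60.0),
                "MQRankSum": np.round(rng.normal(0.0, 0.5, nv), 3),
                "ReadPosRankSum": np.round(rng.normal(0.0, 0.5, nv), 3),
                "SOR": np.round(rng.uniform(0.5, 2.0, nv), 3),
            }
        )
        samples = [
            ("het" if h else "hom") + f"_{i:02d}"
            for i, h in enumerate(self.config.heterogametic)
        ]
        return GenotypeMatrix(
            self.config.contig,
            self.positions,
            ["A"] * nv,
            ["G"] * nv,
            qual,
            self.genotypes.astype(np.int8),
            depths,
            info,
            samples,
        )

    def write_vcf(self, path) -> None:
        m = self.genotype_matrix()
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                f"##contig=<ID={m.contig},length={self.config.chrom_length_bp}>\n"
            )
            for name, desc in [
                ("QD", "Variant quality by depth"),
                ("FS", "Fisher strand bias"),
                ("MQ", "RMS mapping quality"),
                ("MQRankSum", "Mapping quality rank sum"),
                ("ReadPosRankSum", "Read position rank sum"),
                ("SOR", "Strand odds ratio"),
            ]:
                fh.write(
                    f'##INFO=<ID={name},Number=1,Type=Float,Description="{desc}">\n'
                )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(m.samples)
                + "\n"
            )
            for i in range(m.n_variants):
                info = ";".join(
                    f"{k}={m.info[k].iloc[i]:g}" for k in m.info.columns
                )
                cells = "\t".join(
                    f"{gt_str[int(g)]}:{int(d)}"
                    for g, d in zip(m.genotypes[i], m.depths[i])
                )
                fh.write(
                    f"{m.contig}\t{m.positions[i]}\t.\tA\tG\t"
                    f"{m.qual[i]:g}\t.\t{info}\tGT:DP\t{cells}\n"
                )


def simulate_population(cfg: PopSimConfig) -> PopulationSim:
    """Simulate genotypes under the founder-copying model."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0x90B])
    L = cfg.chrom_length_bp
    lo, hi = cfg.sdr_interval

    n_bg = rng.poisson(cfg.snp_per_bp * L)
    bg_pos = np.unique(rng.integers(1, L + 1, size=n_bg))
    n_mk = rng.poisson(cfg.sdr_marker_per_bp * (hi - lo))
    mk_pos = np.unique(rng.integers(lo + 1, hi + 1, size=n_mk))
    mk_pos = np.setdiff1d(mk_pos, bg_pos)
    positions = np.union1d(bg_pos, mk_pos)
    is_marker = np.isin(positions, mk_pos)
    nv = len(positions)

    # founder alleles at background sites; intermediate frequencies so
    # most sites clear the MAF filter
    freqs = rng.uniform(0.2, 0.8, nv)
    founder_alleles = (rng.random((cfg.n_founders, nv)) < freqs).astype(np.int8)
    founder_alleles[:, is_marker] = 0  # markers segregate only on M

    in_sdr = (positions > lo) & (positions <= hi)
    gaps = np.diff(positions, prepend=positions[0])
    p_switch = 1.0 - np.exp(-cfg.recomb_switch_per_bp * gaps)
    p_switch[in_sdr] = 0.0

    def mosaic_haplotype() -> np.ndarray:
        switches = rng.random(nv) < p_switch
        fids = np.empty(nv, dtype=np.int64)
        cur = int(rng.integers(cfg.n_founders))
        for i in range(nv):
            if switches[i]:
                cur = int(rng.integers(cfg.n_founders))
            fids[i] = cur
        return founder_alleles[fids, np.arange(nv)]

    genotypes = np.zeros((nv, cfg.n_samples), dtype=np.int8)
    for s in range(cfg.n_samples):
        h1 = mosaic_haplotype()
        h2 = mosaic_haplotype()
        if cfg.heterogametic[s]:
            # one chromosome carries the diverged M-like SDR haplotype
            h1 = h1.copy()
            h1[in_sdr & is_marker] = 1
        genotypes[:, s] = h1 + h2

    truth = SimTruth(
        kind="population",
        params={
            "seed": cfg.seed,
            "sdr_interval": list(cfg.sdr_interval),
            "n_samples": cfg.n_samples,
            "heterogametic": list(map(bool, cfg.heterogametic)),
            "recomb_switch_per_bp": cfg.recomb_switch_per_bp,
            "n_markers": int(is_marker.sum()),
            "n_variants": nv,
        },
    )
    return PopulationSim(cfg, positions, genotypes, truth)


# ---------------------------------------------------------------------------
# Codon pairs, LTR pairs, promoters


#: Codon prefixes whose third position is fully degenerate and whose
#: first/second positions admit no synonymous single-base change: each
#: codon contributes exactly one synonymous site.
_FOURFOLD_PREFIXES = ("TC", "CC", "AC", "GT", "GC", "GG")


def simulate_codon_pairs(
    true_ds: float, n_codons: int, seed: int = 0, pair_id: str = "sim"
):
    """Codon alignment pair diverged at a known synonymous distance.

    Codons come from four-fold degenerate families with exactly one
    synonymous site each; third positions are substituted at the
    Jukes-Cantor hit probability implied by ``true_ds``.  No stop codon
    can ever arise.
    """
    from .dating import CodonAlignment

    if true_ds < 0:
        raise ValueError("true_ds must be >= 0")
    p_hit = 0.75 * (1.0 - np.exp(-4.0 * true_ds / 3.0))
    if p_hit >= 0.75:
        raise ValueError("true_ds beyond NG86 saturation")
    rng = np.random.default_rng([seed, 0xC0D0])
    prefixes = rng.integers(len(_FOURFOLD_PREFIXES), size=n_codons)
    thirds = rng.integers(4, size=n_codons)
    bases = "ACGT"
    seq_a = "".join(
        _FOURFOLD_PREFIXES[p] + bases[t] for p, t in zip(prefixes, thirds)
    )
    hit = rng.random(n_codons) < p_hit
    shift = rng.integers(1, 4, size=n_codons)
    thirds_b = np.where(hit, (thirds + shift) % 4, thirds)
    seq_b = "".join(
        _FOURFOLD_PREFIXES[p] + bases[t] for p, t in zip(prefixes, thirds_b)
    )
    return CodonAlignment(pair_id, seq_a, seq_b)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def simulate_ltr_pair(
    true_K: float, length: int = 5000, seed: int = 0
) -> tuple[str, str]:
    """Two LTR sequences diverged at expected K substitutions per site.

    Substitution events are Poisson per site with a 2:1 transition:
    transversion ratio, so both K2P terms are exercised; multiple hits
    occur naturally and the estimator's correction is what recovers K.
    """
    if true_K < 0:
        raise ValueError("true_K must be >= 0")
    rng = np.random.default_rng([seed, 0x17A])
    bases = "ACGT"
    seq_a = "".join(bases[i] for i in rng.integers(4, size=length))
    n_events = rng.poisson(true_K, size=length)
    out = []
    for base, k in zip(seq_a, n_events):
        cur = base
        for _ in range(k):
            if rng.random() < 2.0 / 3.0:
                cur = _TRANSITION[cur]
            else:
                cur = _TRANSVERSIONS[cur][int(rng.integers(2))]
        out.append(cur)
    return seq_a, "".join(out)


def simulate_promoter_groups(
    consensus: str,
    group_sizes: dict,
    planted_offsets: dict,
    length: int = 3000,
    seed: int = 0,
) -> list[Promoter]:
    """Random promoters with a motif planted in designated groups only.

    ``planted_offsets`` maps group -> bp-upstream offset of the planted
    consensus (groups absent from the map receive background sequence
    only).  The offset follows the scanner's convention: the motif's 5'
    start sits ``offset`` bp upstream of the TSS.
    """
    for group, off in planted_offsets.items():
        if not len(consensus) <= off <= length:
            raise ValueError(
                f"offset {off} for group {group!r} outside promoter"
            )
    rng = np.random.default_rng([seed, 0x980])
    bases = "ACGT"
    out: list[Promoter] = []
    for group in sorted(group_sizes):
        for i in range(group_sizes[group]):
            seq = list(bases[j] for j in rng.integers(4, size=length))
            if group in planted_offsets:
                start = length - planted_offsets[group]
                seq[start : start + len(consensus)] = consensus
            out.append(
                Promoter(
                    gene_id="YABBY3",
                    haplotype_id=f"{group}{i}",
                    group=group,
                    sequence="".join(seq),
                )
            )
    return out
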