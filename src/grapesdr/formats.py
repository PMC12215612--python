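"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: everything in memory is 0-based half-open
(``[start, end)``); GFF3 is 1-based inclusive and VCF positions are 1-based
at the I/O boundary.  Gene rank is the dense 0-based order of a gene on its
contig, sorted by start (ties broken by end, then gene id).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "HomologyHit",
    "HitTable",
    "GenotypeMatrix",
    "read_gff_genes",
    "write_gff_genes",
    "read_hit_table",
    "read_vcf_region",
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "parse_region",
]

#: Controlled vocabulary for clade labels on annotations.
CLADE_LABELS = frozenset(
    {"eudicot", "monocot", "other-angiosperm", "non-flowering", "unknown"}
)

MISSING = -1  # genotype code for a missing call


class FormatError(ValueError):
    """A malformed input file."""


@dataclass(frozen=True)
class GeneModel:
    """One gene on one contig, in internal 0-based half-open coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one haplotype, grouped by contig."""

    haplotype_id: str
    clade: str = "unknown"
    contigs: dict[str, list[GeneModel]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clade not in CLADE_LABELS:
            raise ValueError(
                f"clade {self.clade!r} not in {sorted(CLADE_LABELS)}"
            )

    def iter_genes(self) -> Iterator[GeneModel]:
        for contig in self.contigs.values():
            yield from contig

    def gene(self, gene_id: str) -> GeneModel:
        return self._index()[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index()

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.contigs.values())

    def _index(self) -> dict[str, GeneModel]:
        idx = getattr(self, "_gene_index", None)
        if idx is None or len(idx) != self.n_genes:
            idx = {g.gene_id: g for g in self.iter_genes()}
            object.__setattr__(self, "_gene_index", idx)
        return idx

    @classmethod
    def from_genes(
        cls, haplotype_id: str, genes: Iterable[GeneModel], clade: str = "unknown"
    ) -> "GenomeAnnotation":
        """Group, sort and re-rank an arbitrary gene collection."""
        by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g)
        out: dict[str, list[GeneModel]] = {}
        seen: set[str] = set()
        for contig in sorted(by_contig):
            ordered = sorted(
                by_contig[contig], key=lambda g: (g.start, g.end, g.gene_id)
            )
            ranked = []
            for rank, g in enumerate(ordered):
                if g.gene_id in seen:
                    raise FormatError(f"duplicate gene id {g.gene_id!r}")
                seen.add(g.gene_id)
                ranked.append(
                    GeneModel(g.gene_id, contig, g.start, g.end, g.strand, rank)
                )
            out[contig] = ranked
        return cls(haplotype_id, clade, out)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError("bitscore must be positive")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class HitTable:
    """Filtered all-vs-all protein hits plus per-gene self scores."""

    hits: list[HomologyHit] = field(default_factory=list)
    self_scores: dict[str, float] = field(default_factory=dict)

    def by_query(self) -> dict[str, list[HomologyHit]]:
        out: dict[str, list[HomologyHit]] = {}
        for h in self.hits:
            out.setdefault(h.query_id, []).append(h)
        return out

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class GenotypeMatrix:
    """Biallelic SNPs x samples on one contig.

    ``genotypes`` holds codes 0 (hom-ref), 1 (het), 2 (hom-alt) and -1
    (missing).  ``positions`` are 1-based (VCF convention) and strictly
    increasing.  ``info`` carries the GATK site annotations used by the
    hard filters (QD, FS, MQ, ...), NaN where absent.
    """

    contig: str
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    qual: np.ndarray
    genotypes: np.ndarray  # (n_variants, n_samples) int8
    depths: np.ndarray  # (n_variants, n_samples) int32
    info: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise FormatError(
                f"{self.contig}: variant positions not strictly increasing"
            )
        n = len(self.positions)
        for name, arr in (("qual", self.qual), ("genotypes", self.genotypes),
                          ("depths", self.depths)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} variants")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row-subset preserving order."""
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return GenotypeMatrix(
            self.contig,
            self.positions[idx],
            [self.ref[i] for i in idx],
            [self.alt[i] for i in idx],
            self.qual[idx],
            self.genotypes[idx],
            self.depths[idx],
            self.info.iloc[idx].reset_index(drop=True),
            list(self.samples),
        )


# ---------------------------------------------------------------------------
# GFF3


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_gff_genes(
    path,
    feature: str = "gene",
    haplotype_id: str | None = None,
    clade: str = "unknown",
) -> GenomeAnnotation:
    """Read features of one type from a GFF3 file into a ranked annotation.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  The ``ID`` attribute names the gene.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != feature:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene_id = None
            for item in attrs.split(";"):
                key, _, value = item.strip().partition("=")
                if key == "ID":
                    gene_id = value
                    break
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: feature without ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            # 1-based inclusive -> 0-based half-open
            genes.append(GeneModel(gene_id, contig, start_i - 1, end_i, strand, 0))
    hap = haplotype_id if haplotype_id is not None else Path(path).stem
    return GenomeAnnotation.from_genes(hap, genes, clade=clade)


def write_gff_genes(ann: GenomeAnnotation, path, feature: str = "gene") -> None:
    """Emit the annotation back to GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(ann.contigs):
            for g in ann.contigs[contig]:
                fh.write(
                    f"{contig}\tgrapesdr\t{feature}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BLAST/DIAMOND tabular (outfmt 6)


def read_hit_table(
    path, evalue_max: float = 0.001, max_targets: int = 100
) -> HitTable:
    """Read a 12-column tabular hit file with aligner-style filtering.

    Hits with e-value above ``evalue_max`` are dropped; per query only the
    ``max_targets`` best-bitscore subjects are kept (ties broken by subject
    id, mirroring ``-max-target-seqs`` deterministically).  Self hits are
    routed to :attr:`HitTable.self_scores` and never count against the cap.
    """
    per_query: dict[str, dict[str, tuple[float, float]]] = {}
    self_scores: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            qseqid, sseqid = cols[0], cols[1]
            try:
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore"
                ) from exc
            if qseqid == sseqid:
                # keep the best self alignment
                if bitscore > self_scores.get(qseqid, 0.0):
                    self_scores[qseqid] = bitscore
                continue
            if evalue > evalue_max:
                continue
            subjects = per_query.setdefault(qseqid, {})
            prev = subjects.get(sseqid)
            if prev is None or bitscore > prev[0]:
                subjects[sseqid] = (bitscore, evalue)
    hits: list[HomologyHit] = []
    for qseqid in sorted(per_query):
        subjects = per_query[qseqid]
        ranked = sorted(subjects.items(), key=lambda kv: (-kv[1][0], kv[0]))
        for sseqid, (bitscore, evalue) in ranked[:max_targets]:
            hits.append(HomologyHit(qseqid, sseqid, bitscore, evalue))
    return HitTable(hits=hits, self_scores=self_scores)


# ---------------------------------------------------------------------------
# VCF


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``contig`` or ``contig:start-end`` (1-based inclusive)."""
    if ":" not in region:
        return region, None, None
    contig, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    return contig, int(start_s.replace(",", "")), int(end_s.replace(",", ""))


def read_vcf_region(path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a genotype matrix.

    Multiallelic records and non-SNP records are skipped (a single warning
    reports the count).  Genotypes are coded 0/1/2 with -1 for missing.
    """
    from cyvcf2 import VCF

    info_fields = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR"]
    contig = start = end = None
    if region is not None:
        contig, start, end = parse_region(region)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qual: list[float] = []
    genos: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    info_rows: list[list[float]] = []
    n_skipped = 0
    seen_contig = None
    for rec in vcf:
        if contig is not None and rec.CHROM != contig:
            continue
        if start is not None and not (start <= rec.POS <= end):
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if seen_contig is None:
            seen_contig = rec.CHROM
        elif rec.CHROM != seen_contig:
            raise FormatError(
                "matrix spans multiple contigs; pass a region to restrict"
            )
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        codes = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt)).astype(np.int8)
        try:
            dp = rec.format("DP")
            dp = (
                np.full(len(samples), -1, dtype=np.int32)
                if dp is None
                else np.where(dp < 0, -1, dp).astype(np.int32).reshape(-1)
            )
        except KeyError:
            dp = np.full(len(samples), -1, dtype=np.int32)
        positions.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        qual.append(rec.QUAL if rec.QUAL is not None else np.nan)
        genos.append(codes)
        depths.append(dp)
        row = []
        for name in info_fields:
            v = rec.INFO.get(name)
            row.append(float(v) if v is not None else np.nan)
        info_rows.append(row)
    vcf.close()
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} non-biallelic-SNP record(s)",
            stacklevel=2,
        )
    n = len(positions)
    label = contig if contig is not None else (seen_contig or "")
    if n == 0 and region is not None:
        warnings.warn(f"{path}: no variants in region {region}", stacklevel=2)
    return GenotypeMatrix(
        contig=label,
        positions=np.array(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        qual=np.array(qual, dtype=float),
        genotypes=(
            np.vstack(genos) if n else np.empty((0, len(samples)), dtype=np.int8)
        ),
        depths=(
            np.vstack(depths) if n else np.empty((0, len(samples)), dtype=np.int32)
        ),
        info=pd.DataFrame(info_rows, columns=info_fields, dtype=float),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# FASTA and TSV


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence map."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for FASTA record {rec.id!r}")
            out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(table: pd.DataFrame, path) -> None:
    """Write a table as header-ed, newline-terminated TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
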