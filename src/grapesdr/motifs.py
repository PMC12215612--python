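"""Promoter extraction and position-weight-matrix scanning.

Promoters are the up-to-3-kbp regions immediately upstream of the
transcription start site, oriented 5'->3' toward the TSS (minus-strand
genes are reverse-complemented).  JASPAR-style count matrices are
scanned as log-odds on both strands; hits are reported with their
relative score in [0, 1] and their start offset in bp upstream of the
TSS.  Group-specific sites — e.g. a site present in every M-allele
promoter and in no F or H promoter — are the readout for
allele-specific regulatory divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GenomeAnnotation

__all__ = [
    "Promoter",
    "PWM",
    "MotifHit",
    "extract_promoters",
    "read_jaspar_pfm",
    "scan_pwm",
    "group_specific_sites",
    "differential_site_counts",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Promoter:
    gene_id: str
    haplotype_id: str
    group: str  # allele group, e.g. "M", "F", "H"
    sequence: str  # 5'->3', last base adjacent to the TSS

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty promoter")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PWM:
    """A position count/frequency matrix with a background model."""

    motif_id: str
    matrix: np.ndarray  # (4, L), rows A C G T
    background: np.ndarray | None = None  # length-4 frequencies

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: matrix must have 4 rows (ACGT)")
        totals = self.matrix.sum(axis=0)
        if not np.allclose(totals, totals[0]):
            raise ValueError(f"{self.motif_id}: column sums differ")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, pseudocount: float = 0.8) -> np.ndarray:
        counts = self.matrix
        if np.allclose(counts.sum(axis=0), 1.0):  # frequencies: rescale
            counts = counts * 100.0
        adj = counts + pseudocount * self.background[:, None]
        freqs = adj / adj.sum(axis=0, keepdims=True)
        return np.log2(freqs / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    gene_id: str
    haplotype_id: str
    group: str
    upstream_offset: int  # bp upstream of the TSS at the hit's 5' start
    strand: str
    relative_score: float


def extract_promoters(
    ann: GenomeAnnotation,
    genome: dict[str, str],
    max_len: int = 3000,
    group_of: dict[str, str] | None = None,
) -> list[Promoter]:
    """Extract up-to-``max_len``-bp upstream promoters for every gene.

    The TSS is the annotated gene start (plus strand) or end (minus
    strand); promoters truncate at contig edges, and genes with zero
    upstream sequence are skipped with a warning.  ``group_of`` maps
    gene ids to allele groups (default "" = ungrouped).
    """
    group_of = group_of or {}
    out: list[Promoter] = []
    skipped = []
    for g in ann.iter_genes():
        seq = genome[g.contig]
        if g.strand == "+":
            lo = max(0, g.start - max_len)
            prom = seq[lo : g.start]
        else:
            prom = reverse_complement(seq[g.end : g.end + max_len])
        if not prom:
            skipped.append(g.gene_id)
            continue
        out.append(
            Promoter(g.gene_id, ann.haplotype_id, group_of.get(g.gene_id, ""), prom)
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} gene(s) with no upstream sequence: "
            + ", ".join(skipped[:5]),
            stacklevel=2,
        )
    return out


def read_jaspar_pfm(path) -> list[PWM]:
    """Read JASPAR-format position frequency matrices via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out: list[PWM] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            name = m.matrix_id or m.name
            out.append(PWM(name, mat))
    return out


def scan_pwm(
    promoter: Promoter,
    pwm: PWM,
    min_rel_score: float = 0.80,
    both_strands: bool = True,
    pseudocount: float = 0.8,
) -> list[MotifHit]:
    """Scan a promoter with one PWM; report hits above a relative score.

    relative_score = (score - min) / (max - min) where min/max are the
    lowest and highest achievable log-odds sums.  ``upstream_offset`` is
    the distance from the TSS to the promoter-coordinate start of the
    matched window, so a motif planted N bp upstream is reported at N.
    """
    L = len(promoter)
    m = pwm.length
    if m > L:
        return []
    lods = pwm.log_odds(pseudocount)
    smin = lods.min(axis=0).sum()
    smax = lods.max(axis=0).sum()
    span = smax - smin if smax > smin else 1.0

    seq = promoter.sequence
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=int)
    n_win = L - m + 1
    # score every window; ambiguous bases score as the column minimum
    col_min = lods.min(axis=0)
    scores = np.zeros(n_win)
    for j in range(m):
        c = codes[j : j + n_win]
        scores += np.where(c >= 0, lods[np.clip(c, 0, 3), j], col_min[j])
    hits: list[MotifHit] = []

    def emit(idx: np.ndarray, strand: str, window_start_of) -> None:
        for i in idx:
            rel = (
                (fwd_scores[i] if strand == "+" else rev_scores[i]) - smin
            ) / span
            start = window_start_of(int(i))
            hits.append(
                MotifHit(
                    pwm.motif_id,
                    promoter.gene_id,
                    promoter.haplotype_id,
                    promoter.group,
                    L - start,
                    strand,
                    float(rel),
                )
            )

    fwd_scores = scores
    rel_fwd = (fwd_scores - smin) / span
    emit(np.flatnonzero(rel_fwd >= min_rel_score), "+", lambda i: i)

    if both_strands:
        rc = reverse_complement(seq)
        codes_rc = np.array([_BASE_INDEX.get(b, -1) for b in rc], dtype=int)
        rev_scores = np.zeros(n_win)
        for j in range(m):
            c = codes_rc[j : j + n_win]
            rev_scores += np.where(c >= 0, lods[np.clip(c, 0, 3), j], col_min[j])
        rel_rev = (rev_scores - smin) / span
        # window i on the reverse strand starts at L - i - m in promoter coords
        emit(
            np.flatnonzero(rel_rev >= min_rel_score), "-", lambda i: L - i - m
        )
    hits.sort(key=lambda h: (-h.upstream_offset, h.strand))
    return hits


def group_specific_sites(
    hits: list[MotifHit],
    promoters: list[Promoter],
    window_bp: int = 30,
) -> pd.DataFrame:
    """Sites present in every promoter of one group and in no other.

    A (motif, group) pair is reported when some offset c exists such
    that every promoter of the group has a hit within ``window_bp`` of
    c and no promoter of any other group has any hit for that motif
    within the window.  Columns: motif_id, group, consensus_offset.
    """
    members: dict[str, set[tuple[str, str]]] = {}
    for p in promoters:
        members.setdefault(p.group, set()).add((p.haplotype_id, p.gene_id))
    by_motif: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)

    rows = []
    for motif_id, mhits in sorted(by_motif.items()):
        for group, group_members in sorted(members.items()):
            own = [h for h in mhits if h.group == group]
            others = [h for h in mhits if h.group != group]
            candidates = sorted({h.upstream_offset for h in own})
            for c in candidates:
                near_own = [h for h in own if abs(h.upstream_offset - c) <= window_bp]
                covered = {(h.haplotype_id, h.gene_id) for h in near_own}
                if covered != group_members:
                    continue
                if any(abs(h.upstream_offset - c) <= window_bp for h in others):
                    continue
                rows.append(
                    (
                        motif_id,
                        group,
                        float(np.mean([h.upstream_offset for h in near_own])),
                    )
                )
                break
    return pd.DataFrame(rows, columns=["motif_id", "group", "consensus_offset"])


def differential_site_counts(
    hits: list[MotifHit], promoters: list[Promoter]
) -> pd.DataFrame:
    """Per-motif mean hit counts per promoter per group, with direction.

    A motif is listed when one group's mean strictly exceeds every other
    group's; ``margin`` is the gap to the runner-up.  Columns: motif_id,
    direction, margin, then mean_<group> per group.
    """
    groups = sorted({p.group for p in promoters})
    n_prom = {g: sum(1 for p in promoters if p.group == g) for g in groups}
    counts: dict[str, dict[str, int]] = {}
    for h in hits:
        counts.setdefault(h.motif_id, {g: 0 for g in groups})
        counts[h.motif_id][h.group] = counts[h.motif_id].get(h.group, 0) + 1
    rows = []
    for motif_id in sorted(counts):
        means = {
            g: counts[motif_id].get(g, 0) / n_prom[g] if n_prom[g] else 0.0
            for g in groups
        }
        ordered = sorted(means.items(), key=lambda kv: -kv[1])
        if len(ordered) < 2 or ordered[0][1] <= ordered[1][1]:
            continue  # no strict winner
        rows.append(
            (motif_id, ordered[0][0], ordered[0][1] - ordered[1][1])
            + tuple(means[g] for g in groups)
        )
    return pd.DataFrame(
        rows,
        columns=["motif_id", "direction", "margin"] + [f"mean_{g}" for g in groups],
    )
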