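"""Windowed collinearity conservation scoring.

The reference gene order is split into fixed-size windows of consecutive
genes (twelve by default, the size of the grape sex-determining region).
Each window is mapped per haplotype either to the single collinear block
covering the most window genes (*orthologous* mode) or to every collinear
region touching it (*homologous* mode, which admits paralogous and
whole-genome-duplication copies).  Collinear genes are scored by their
pair bitscore divided by the reference protein's self-alignment bitscore,
clamped to [0, 1], and scores are rank-normalized within clade groups to
control for evolutionary distance from the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GenomeAnnotation
from .stats import dunn_posthoc, kruskal_groups, rank_normalize
from .synteny import CollinearBlock, block_window_overlap

__all__ = [
    "GeneWindow",
    "WindowAssignment",
    "make_windows",
    "assign_orthologous",
    "assign_homologous",
    "conservation_score",
    "rank_normalize_scores",
    "summarize_windows",
    "compare_windows",
]


@dataclass(frozen=True)
class GeneWindow:
    window_index: int
    contig: str
    gene_ids: tuple[str, ...]


@dataclass
class WindowAssignment:
    window_index: int
    haplotype_id: str
    mode: str  # "orthologous" | "homologous"
    selected_blocks: list[str]
    collinear_gene_count: int
    region_count: int
    gene_scores: dict[str, float] = field(default_factory=dict)


def make_windows(ref: GenomeAnnotation, window_size: int = 12) -> list[GeneWindow]:
    """Non-overlapping consecutive windows per contig, in rank order.

    Trailing genes that do not fill a window are dropped, so every window
    has exactly ``window_size`` genes.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    windows: list[GeneWindow] = []
    idx = 0
    for contig in sorted(ref.contigs):
        genes = ref.contigs[contig]
        for start in range(0, len(genes) - window_size + 1, window_size):
            ids = tuple(g.gene_id for g in genes[start : start + window_size])
            windows.append(GeneWindow(idx, contig, ids))
            idx += 1
    return windows


def conservation_score(pair_bitscore: float, self_bitscore: float) -> float:
    """Pair bitscore over reference self bitscore, clamped to [0, 1]."""
    if self_bitscore <= 0:
        raise ValueError("self bitscore must be positive")
    return min(1.0, pair_bitscore / self_bitscore)


def _window_anchors(
    block: CollinearBlock, gene_ids: set[str]
) -> dict[str, float]:
    """Best anchor bitscore per window gene within one block."""
    best: dict[str, float] = {}
    for a in block.anchors:
        if a.ref_gene_id in gene_ids and a.bitscore > best.get(a.ref_gene_id, 0.0):
            best[a.ref_gene_id] = a.bitscore
    return best


def assign_orthologous(
    windows: list[GeneWindow],
    blocks: list[CollinearBlock],
    self_scores: dict[str, float],
    haplotype_id: str,
) -> list[WindowAssignment]:
    """Map each window to its best single collinear block.

    The block anchoring the greatest number of distinct window genes wins;
    ties go to the larger summed anchor bitscore, then the smaller block
    id.  Scores use the best-bitscore anchor of each window gene within
    the selected block only.
    """
    out: list[WindowAssignment] = []
    for w in windows:
        gene_set = set(w.gene_ids)
        best_block: CollinearBlock | None = None
        best_key: tuple | None = None
        for b in blocks:
            count = block_window_overlap(b, gene_set)
            if count == 0:
                continue
            key = (count, b.score, _NegStr(b.block_id))
            if best_key is None or key > best_key:
                best_key, best_block = key, b
        if best_block is None:
            out.append(
                WindowAssignment(w.window_index, haplotype_id, "orthologous",
                                 [], 0, 0)
            )
            continue
        anchors = _window_anchors(best_block, gene_set)
        scores = {
            g: conservation_score(bs, self_scores[g]) for g, bs in anchors.items()
        }
        out.append(
            WindowAssignment(
                w.window_index,
                haplotype_id,
                "orthologous",
                [best_block.block_id],
                len(anchors),
                1,
                scores,
            )
        )
    return out


def assign_homologous(
    windows: list[GeneWindow],
    blocks: list[CollinearBlock],
    self_scores: dict[str, float],
    haplotype_id: str,
    min_window_anchors: int = 2,
) -> list[WindowAssignment]:
    """Map each window to all collinear regions touching it.

    A block counts as a region when it anchors at least
    ``min_window_anchors`` window genes.  Each window gene is scored from
    its greatest-bitscore partner across all counted regions.
    """
    out: list[WindowAssignment] = []
    for w in windows:
        gene_set = set(w.gene_ids)
        selected: list[CollinearBlock] = [
            b
            for b in blocks
            if block_window_overlap(b, gene_set) >= min_window_anchors
        ]
        best_bs: dict[str, float] = {}
        for b in selected:
            for g, bs in _window_anchors(b, gene_set).items():
                if bs > best_bs.get(g, 0.0):
                    best_bs[g] = bs
        scores = {
            g: conservation_score(bs, self_scores[g]) for g, bs in best_bs.items()
        }
        out.append(
            WindowAssignment(
                w.window_index,
                haplotype_id,
                "homologous",
                sorted(b.block_id for b in selected),
                len(best_bs),
                len(selected),
                scores,
            )
        )
    return out


class _NegStr(str):
    """String whose ordering is reversed, for 'smaller id wins' in a max."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Clade-wise normalization and summary


#: Default mapping of clade labels to rank-normalization groups: eudicots
#: are normalized apart from the other angiosperm clades.
DEFAULT_CLADE_GROUPS = {
    "eudicot": "eudicot",
    "monocot": "other-angiosperm",
    "other-angiosperm": "other-angiosperm",
    "non-flowering": "non-flowering",
}


def rank_normalize_scores(
    scores: dict[tuple, float], group_of: dict[tuple, str]
) -> dict[tuple, float]:
    """Rank-normalize gene-pair scores within each clade group.

    ``scores`` maps an arbitrary key (e.g. (haplotype, gene)) to a raw
    conservation score; ``group_of`` maps the same keys to group labels.
    Within each group, normalized = (rank-1)/(n-1) with mean ranks for
    ties; singleton groups map to 0.5; empty groups are skipped.
    """
    by_group: dict[str, list[tuple]] = {}
    for key in scores:
        by_group.setdefault(group_of[key], []).append(key)
    out: dict[tuple, float] = {}
    for group, keys in by_group.items():
        if not keys:
            warnings.warn(f"empty normalization group {group!r}", stacklevel=2)
            continue
        vals = np.array([scores[k] for k in keys])
        normed = rank_normalize(vals)
        out.update(zip(keys, normed))
    return out


def summarize_windows(
    windows: list[GeneWindow],
    assignments: dict[str, list[WindowAssignment]],
    clade_of: dict[str, str],
    clade_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-window-per-haplotype table with clade-normalized scores.

    Columns: window_index, haplotype, clade, mode, collinear_gene_count,
    region_count, mean_score, mean_normalized_score.
    """
    clade_groups = clade_groups or DEFAULT_CLADE_GROUPS
    raw: dict[tuple, float] = {}
    group_of: dict[tuple, str] = {}
    for hap, asgs in assignments.items():
        group = clade_groups[clade_of[hap]]
        for a in asgs:
            for gene, s in a.gene_scores.items():
                key = (hap, a.window_index, gene)
                raw[key] = s
                group_of[key] = group
    normed = rank_normalize_scores(raw, group_of) if raw else {}
    rows = []
    for hap, asgs in assignments.items():
        for a in asgs:
            keys = [(hap, a.window_index, g) for g in a.gene_scores]
            mean_score = (
                float(np.mean([raw[k] for k in keys])) if keys else np.nan
            )
            mean_norm = (
                float(np.mean([normed[k] for k in keys])) if keys else np.nan
            )
            rows.append(
                (
                    a.window_index,
                    hap,
                    clade_of[hap],
                    a.mode,
                    a.collinear_gene_count,
                    a.region_count,
                    mean_score,
                    mean_norm,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "window_index", "haplotype", "clade", "mode",
            "collinear_gene_count", "region_count",
            "mean_score", "mean_normalized_score",
        ],
    )
    return df.sort_values(["window_index", "haplotype"]).reset_index(drop=True)


def compare_windows(
    summary: pd.DataFrame, focus_window: int
) -> dict[str, dict[str, float]]:
    """Kruskal-Wallis contrast of the focus window against all others.

    Compares, across haplotypes, the focus window's collinear-gene counts
    and mean normalized conservation scores against those of every other
    window.  Returns ``{"counts": {"H":..,"p":..}, "scores": {...}}``.
    For three or more groups use :func:`grapesdr.stats.dunn_posthoc` on
    the same columns.
    """
    focus = summary[summary["window_index"] == focus_window]
    rest = summary[summary["window_index"] != focus_window]
    if len(focus) < 2 or len(rest) < 2:
        raise ValueError("need >= 2 observations in focus and background")
    out: dict[str, dict[str, float]] = {}
    for label, col in (("counts", "collinear_gene_count"),
                       ("scores", "mean_normalized_score")):
        a = focus[col].dropna().to_numpy(dtype=float)
        b = rest[col].dropna().to_numpy(dtype=float)
        res = kruskal_groups({"focus": a, "background": b})
        out[label] = {"H": res.H, "p": res.p}
    return out
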