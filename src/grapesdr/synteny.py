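"""Collinear gene-block detection between two annotated haplotypes.

Blocks are chains of anchor pairs (homologous genes in conserved order)
found by dynamic-programming chaining over gene ranks, emulating the
MCScanX parameterization: a minimum of ``min_block_size`` anchors per
block (-s), a maximum rank gap of ``max_gap`` genes between consecutive
anchors on either genome (-m), and single block membership per anchor
(-w).  Plus and minus orientations are chained independently; the best
scoring chain (summed anchor bitscores) is extracted greedily, its
anchors removed, and the search repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .formats import GenomeAnnotation, HitTable

__all__ = [
    "AnchorPair",
    "CollinearBlock",
    "detect_collinear_blocks",
    "block_window_overlap",
    "validate_block",
    "write_collinearity",
    "blocks_to_tsv",
]


@dataclass(frozen=True)
class AnchorPair:
    ref_gene_id: str
    target_gene_id: str
    ref_rank: int
    target_rank: int
    bitscore: float

    @property
    def key(self) -> tuple:
        return (self.ref_rank, self.target_rank, self.target_gene_id)


@dataclass
class CollinearBlock:
    block_id: str
    ref_contig: str
    target_contig: str
    anchors: list[AnchorPair]
    orientation: str  # "plus" | "minus"

    @property
    def score(self) -> float:
        return sum(a.bitscore for a in self.anchors)

    @property
    def ref_gene_ids(self) -> set[str]:
        return {a.ref_gene_id for a in self.anchors}

    def __len__(self) -> int:
        return len(self.anchors)


def validate_block(block: CollinearBlock, min_block_size: int, max_gap: int) -> None:
    """Raise if a block violates the chain invariants."""
    if len(block.anchors) < min_block_size:
        raise AssertionError(f"{block.block_id}: fewer than {min_block_size} anchors")
    sign = 1 if block.orientation == "plus" else -1
    for prev, cur in zip(block.anchors, block.anchors[1:]):
        dr = cur.ref_rank - prev.ref_rank
        dt = sign * (cur.target_rank - prev.target_rank)
        if not (1 <= dr <= max_gap + 1):
            raise AssertionError(f"{block.block_id}: ref rank step {dr} invalid")
        if not (1 <= dt <= max_gap + 1):
            raise AssertionError(f"{block.block_id}: target rank step {dt} invalid")


def _build_anchors(
    ref: GenomeAnnotation, target: GenomeAnnotation, hits: HitTable
) -> dict[tuple[str, str], list[AnchorPair]]:
    """Anchor candidates per (ref contig, target contig) pair."""
    missing: list[str] = []
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for h in hits.hits:
        if h.query_id not in ref:
            missing.append(h.query_id)
            continue
        if h.subject_id not in target:
            missing.append(h.subject_id)
            continue
        rg = ref.gene(h.query_id)
        tg = target.gene(h.subject_id)
        by_pair.setdefault((rg.contig, tg.contig), []).append(
            AnchorPair(h.query_id, h.subject_id, rg.rank, tg.rank, h.bitscore)
        )
    if missing:
        raise KeyError(
            "hits reference genes absent from the annotations: "
            + ", ".join(sorted(set(missing))[:10])
        )
    for anchors in by_pair.values():
        anchors.sort(key=lambda a: a.key)
    return by_pair


def _best_chain(
    anchors: list[AnchorPair], orientation: str, min_block_size: int, max_gap: int
) -> list[AnchorPair] | None:
    """Max-score chain with >= min_block_size anchors, or None.

    DP over anchors sorted by (ref_rank, target_rank) with chain length
    capped at ``min_block_size`` in the state, so the best chain *among
    those long enough* is found even when a shorter chain scores higher.
    Ties broken by total score, then true length, then lexicographically
    smallest anchor-key sequence (via smallest-key predecessor choice).
    """
    n = len(anchors)
    if n < min_block_size:
        return None
    sign = 1 if orientation == "plus" else -1
    cap = min_block_size
    # index anchors by ref_rank for gap-bounded predecessor lookup
    by_ref_rank: dict[int, list[int]] = {}
    for i, a in enumerate(anchors):
        by_ref_rank.setdefault(a.ref_rank, []).append(i)
    # state[i][k] = (score, truelen, pred_index, pred_k) for capped length k
    NEG = float("-inf")
    score = [[NEG] * (cap + 1) for _ in range(n)]
    truelen = [[0] * (cap + 1) for _ in range(n)]
    pred = [[(-1, -1)] * (cap + 1) for _ in range(n)]
    for j, aj in enumerate(anchors):
        score[j][1] = aj.bitscore
        truelen[j][1] = 1
        for dr in range(1, max_gap + 2):
            r = aj.ref_rank - dr
            for i in by_ref_rank.get(r, ()):
                ai = anchors[i]
                dt = sign * (aj.target_rank - ai.target_rank)
                if not (1 <= dt <= max_gap + 1):
                    continue
                for k in range(1, cap + 1):
                    if score[i][k] == NEG:
                        continue
                    k2 = min(k + 1, cap)
                    s2 = score[i][k] + aj.bitscore
                    l2 = truelen[i][k] + 1
                    cand = (s2, l2, -ai.ref_rank, -ai.target_rank)
                    pi, pk = pred[j][k2]
                    if pi >= 0:
                        cur = (
                            score[j][k2],
                            truelen[j][k2],
                            -anchors[pi].ref_rank,
                            -anchors[pi].target_rank,
                        )
                    else:
                        cur = (score[j][k2], truelen[j][k2], 1, 1)
                    if s2 > score[j][k2] or (score[j][k2] == s2 and cand > cur):
                        score[j][k2] = s2
                        truelen[j][k2] = l2
                        pred[j][k2] = (i, k)
    best_j = -1
    best = (NEG, 0, ())
    for j in range(n):
        if score[j][cap] == NEG:
            continue
        cand = (score[j][cap], truelen[j][cap],
                (-anchors[j].ref_rank, -anchors[j].target_rank))
        if cand > best:
            best = cand
            best_j = j
    if best_j < 0:
        return None
    chain: list[AnchorPair] = []
    j, k = best_j, cap
    while j >= 0:
        chain.append(anchors[j])
        j, k = pred[j][k]
    chain.reverse()
    return chain


def detect_collinear_blocks(
    ref: GenomeAnnotation,
    target: GenomeAnnotation,
    hits: HitTable,
    min_block_size: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Detect collinear blocks between two haplotypes.

    Defaults mirror the MCScanX run this pipeline emulates (``-s5 -m25``).
    Output order is deterministic: by (ref_contig, first ref rank,
    target_contig).
    """
    if min_block_size < 1 or max_gap < 1:
        raise ValueError("min_block_size and max_gap must be >= 1")
    by_pair = _build_anchors(ref, target, hits)
    blocks: list[CollinearBlock] = []
    for (rc, tc) in sorted(by_pair):
        anchors = by_pair[(rc, tc)]
        remaining = list(anchors)
        while True:
            candidates = []
            for orientation in ("plus", "minus"):
                chain = _best_chain(remaining, orientation, min_block_size, max_gap)
                if chain is not None:
                    candidates.append(
                        (
                            sum(a.bitscore for a in chain),
                            len(chain),
                            orientation == "plus",
                            chain,
                            orientation,
                        )
                    )
            if not candidates:
                break
            candidates.sort(
                key=lambda c: (c[0], c[1], c[2], [(-a.ref_rank, -a.target_rank)
                                                  for a in c[3]]),
                reverse=True,
            )
            _, _, _, chain, orientation = candidates[0]
            blocks.append(CollinearBlock("", rc, tc, chain, orientation))
            used = {a.key for a in chain}
            remaining = [a for a in remaining if a.key not in used]
    blocks.sort(key=lambda b: (b.ref_contig, b.anchors[0].ref_rank, b.target_contig))
    for i, b in enumerate(blocks):
        b.block_id = f"b{i:04d}"
    return blocks


def block_window_overlap(block: CollinearBlock, window_gene_ids: set[str]) -> int:
    """Distinct reference window genes anchored at least once in the block."""
    return len(block.ref_gene_ids & set(window_gene_ids))


def write_collinearity(blocks: list[CollinearBlock], path) -> None:
    """MCScanX-like plain-text collinearity report."""
    with open(path, "w") as fh:
        fh.write("############### collinear blocks ###############\n")
        for b in blocks:
            sign = "plus" if b.orientation == "plus" else "minus"
            fh.write(
                f"## Alignment {b.block_id}: score={b.score:.1f} "
                f"N={len(b)} {b.ref_contig}&{b.target_contig} {sign}\n"
            )
            for i, a in enumerate(b.anchors):
                fh.write(
                    f"{b.block_id}-{i}:\t{a.ref_gene_id}\t{a.target_gene_id}"
                    f"\t{a.bitscore:.1f}\n"
                )


def blocks_to_tsv(blocks: list[CollinearBlock]) -> pd.DataFrame:
    rows = [
        (b.block_id, b.orientation, b.ref_contig, b.target_contig,
         a.ref_gene_id, a.target_gene_id, a.bitscore)
        for b in blocks
        for a in b.anchors
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "orientation", "ref_contig", "target_contig",
            "ref_gene", "target_gene", "bitscore",
        ],
    )
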