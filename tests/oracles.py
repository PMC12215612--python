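"""Independent brute-force oracles used by the tests.

The chain-enumeration oracle mirrors the greedy block-extraction
semantics of the synteny module but finds each round's best chain by
exhaustive DFS over all valid chains instead of dynamic programming.
"""

from __future__ import annotations

from grapesdr.synteny import AnchorPair


def best_chain_brute(
    anchors: list[AnchorPair], orientation: str, min_size: int, max_gap: int
):
    """Best-scoring chain with >= min_size anchors, by full enumeration."""
    sign = 1 if orientation == "plus" else -1
    anchors = sorted(anchors, key=lambda a: a.key)
    best: list[tuple] = []

    def rec(chain: list[AnchorPair]) -> None:
        if len(chain) >= min_size:
            cand = (sum(a.bitscore for a in chain), len(chain))
            if not best or cand > best[0][0]:
                best.clear()
                best.append((cand, list(chain)))
        last = chain[-1]
        for a in anchors:
            dr = a.ref_rank - last.ref_rank
            dt = sign * (a.target_rank - last.target_rank)
            if 1 <= dr <= max_gap + 1 and 1 <= dt <= max_gap + 1:
                chain.append(a)
                rec(chain)
                chain.pop()

    for a in anchors:
        rec([a])
    return best[0][1] if best else None


def oracle_blocks(
    anchors: list[AnchorPair], min_size: int, max_gap: int
) -> list[tuple[str, frozenset]]:
    """Greedy extraction of best chains via the brute-force searcher.

    Returns (orientation, frozenset of anchor keys) per block, unordered.
    """
    remaining = list(anchors)
    out = []
    while True:
        candidates = []
        for orientation in ("plus", "minus"):
            chain = best_chain_brute(remaining, orientation, min_size, max_gap)
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
            return out
        candidates.sort(key=lambda c: (c[0], c[1], c[2]), reverse=True)
        _, _, _, chain, orientation = candidates[0]
        out.append((orientation, frozenset(a.key for a in chain)))
        used = {a.key for a in chain}
        remaining = [a for a in remaining if a.key not in used]
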