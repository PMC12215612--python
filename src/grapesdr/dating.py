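"""Molecular-evolution distances and the divergence clock.

Implements the Kimura two-parameter (K2P) nucleotide distance, the
Nei-Gojobori (1986) synonymous divergence dS, and the clock

    T = K / (2 mu) x generation time

with the grape defaults mu = 2.5e-9 substitutions per base per year and
a 3-year generation, reported in million years.  dS along the
sex-determining region is summarized as a loess-smoothed landscape with
an inside-vs-outside Kruskal-Wallis contrast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .stats import kruskal_groups

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "ClockParams",
    "kimura2p",
    "ng86_ds",
    "divergence_time",
    "date_feature",
    "ds_landscape",
    "loess_smooth",
    "SaturationError",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "TCAG"
_CODON_TABLE = {
    t + c + a: aa
    for (t, c, a), aa in zip(
        itertools.product(BASES, BASES, BASES),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}
_PURINES = frozenset("AG")


class SaturationError(ValueError):
    """Observed divergence beyond the estimator's domain."""


@dataclass(frozen=True)
class ClockParams:
    mu: float = 2.5e-9  # substitutions / base / year
    generation_time_years: float = 3.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_time_years <= 0:
            raise ValueError("clock parameters must be positive")


@dataclass
class CodonAlignment:
    """A gap-free pairwise codon alignment."""

    id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.id}: unequal sequence lengths")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.id}: length not divisible by 3")
        for seq, label in ((self.seq_a, "a"), (self.seq_b, "b")):
            codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            if any(c in STOP_CODONS for c in codons):
                raise ValueError(f"{self.id}: internal stop codon in seq_{label}")

    def codon_pairs(self):
        """(codon_a, codon_b) pairs, skipping gapped/ambiguous columns."""
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if set(ca + cb) <= set("ACGT"):
                yield ca, cb


@dataclass
class DivergenceEstimate:
    kind: str  # "K2P" | "dS"
    value: float
    P: float | None = None  # transition proportion (K2P)
    Q: float | None = None  # transversion proportion (K2P)
    sites: float | None = None  # compared sites (K2P) or synonymous sites S (dS)
    time_my: float | None = None
    time_sd_my: float | None = None


# ---------------------------------------------------------------------------
# K2P


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def kimura2p(seq_a: str, seq_b: str) -> DivergenceEstimate:
    """Kimura two-parameter distance between equal-length sequences.

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the observed
    transition and transversion proportions over unambiguous columns.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a != b:
            if _is_transition(a, b):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined at P={P:.3f}, Q={Q:.3f} (saturation)"
        )
    K = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return DivergenceEstimate("K2P", float(K), P=P, Q=Q, sites=float(n))


# ---------------------------------------------------------------------------
# NG86 dS


@lru_cache(maxsize=1)
def _ng86_tables():
    """Precomputed per-codon synonymous-site fractions and per-codon-pair
    path-averaged (synonymous, total) difference counts."""
    codons = [c for c in _CODON_TABLE if c not in STOP_CODONS]
    syn_sites: dict[str, float] = {}
    for codon in codons:
        s = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue  # paths through stops excluded, NG86 convention
                if _CODON_TABLE[mut] == _CODON_TABLE[codon]:
                    s += 1.0 / 3.0
        syn_sites[codon] = s

    def pair_diffs(ca: str, cb: str) -> tuple[float, float]:
        positions = [i for i in range(3) if ca[i] != cb[i]]
        if not positions:
            return 0.0, 0.0
        syn_paths: list[int] = []
        for order in itertools.permutations(positions):
            cur = ca
            syn = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS:
                    ok = False
                    break
                if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                    syn += 1
                cur = nxt
            if ok:
                syn_paths.append(syn)
        if not syn_paths:  # all paths pass through a stop; fall back to all
            for order in itertools.permutations(positions):
                cur = ca
                syn = 0
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if _CODON_TABLE.get(nxt, "*") == _CODON_TABLE[cur]:
                        syn += 1
                    cur = nxt
                syn_paths.append(syn)
        return float(np.mean(syn_paths)), float(len(positions))

    diffs = {
        (ca, cb): pair_diffs(ca, cb) for ca in codons for cb in codons
    }
    return syn_sites, diffs


def ng86_ds(aln: CodonAlignment) -> DivergenceEstimate:
    """Nei-Gojobori (1986) synonymous divergence with Jukes-Cantor correction.

    S is the average synonymous site count of the two sequences; Sd the
    path-averaged synonymous difference count; pS = Sd/S and
    dS = -(3/4) ln(1 - (4/3) pS).
    """
    syn_sites, diffs = _ng86_tables()
    S = Sd = 0.0
    n_codons = 0
    for ca, cb in aln.codon_pairs():
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # terminal stops carry no synonymous-site information
        n_codons += 1
        S += 0.5 * (syn_sites[ca] + syn_sites[cb])
        Sd += diffs[(ca, cb)][0]
    if n_codons == 0:
        raise ValueError(f"{aln.id}: no comparable codons")
    if S <= 0:
        raise ValueError(f"{aln.id}: zero synonymous sites")
    pS = Sd / S
    if pS >= 0.75:
        raise SaturationError(f"{aln.id}: pS={pS:.3f} >= 3/4 (saturation)")
    ds = -0.75 * np.log(1.0 - (4.0 / 3.0) * pS)
    return DivergenceEstimate("dS", float(ds), sites=float(S))


# ---------------------------------------------------------------------------
# Clock


def divergence_time(K: float, clock: ClockParams | None = None) -> float:
    """Clock-date a genetic distance; returns million years.

    T = K/(2 mu) x generation time, following the printed arithmetic of
    the grape clock (mu per year with a generation-time multiplier).
    """
    clock = clock or ClockParams()
    if K < 0:
        raise ValueError("genetic distance must be non-negative")
    years = K / (2.0 * clock.mu) * clock.generation_time_years
    return years / 1e6


def date_feature(
    flank_estimates: list[float], clock: ClockParams | None = None
) -> tuple[float, float | None]:
    """Date a feature (inversion, LTR insertion) from >= 1 K estimates.

    Returns (mean time, sd) in million years, the sd taken over the
    dated estimates (population form, n in the denominator); it is None
    for a single estimate.
    """
    if not flank_estimates:
        raise ValueError("need at least one distance estimate")
    times = [divergence_time(k, clock) for k in flank_estimates]
    mean = float(np.mean(times))
    sd = float(np.std(times)) if len(times) > 1 else None
    return mean, sd


# ---------------------------------------------------------------------------
# dS landscape


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Loess with tricube weights and local polynomial fits.

    Evaluated at the input x positions; ``span`` is the fraction of
    points in each local neighbourhood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        idx = np.argsort(dist, kind="stable")[:k]
        dmax = dist[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (dist[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        deg = min(degree, len(idx) - 1)
        coeffs = np.polyfit(x[idx] - x[i], y[idx], deg, w=np.sqrt(w))
        out[i] = coeffs[-1]  # polynomial evaluated at the centre
    return out


def ds_landscape(
    gene_pairs: list[tuple[float, CodonAlignment]],
    sdr_interval: tuple[float, float],
    span: float = 0.75,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-gene dS along a region with loess smoothing and an SDR contrast.

    ``gene_pairs`` is an ordered list of (position, alignment).  Returns
    (table with position/ds/smoothed/inside_sdr, (H, p)) where the test
    compares dS inside the interval against outside.
    """
    if len(gene_pairs) < 5:
        raise ValueError("need at least 5 genes for a landscape")
    positions = np.array([p for p, _ in gene_pairs], dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("gene positions must be ordered")
    ds = np.array([ng86_ds(a).value for _, a in gene_pairs])
    smoothed = loess_smooth(positions, ds, span=span)
    lo, hi = sdr_interval
    inside = (positions >= lo) & (positions <= hi)
    if inside.all() or not inside.any():
        raise ValueError("all genes on one side of the SDR interval")
    if inside.sum() < 2 or (~inside).sum() < 2:
        raise ValueError("need >= 2 genes inside and outside the interval")
    res = kruskal_groups({"inside": ds[inside], "outside": ds[~inside]})
    table = pd.DataFrame(
        {
            "position": positions,
            "ds": ds,
            "smoothed": smoothed,
            "inside_sdr": inside,
        }
    )
    return table, (res.H, res.p)
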