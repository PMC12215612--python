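"""SNP filtering, pairwise r², LD-decay fitting and the LD landscape.

This is the machinery behind sex-determining-region (SDR) boundary
detection: recombination suppression leaves a block of elevated,
slowly decaying linkage disequilibrium, while the heterogametic sex
accumulates heterozygous sites on its diverged haplotype.

r² is the squared Pearson correlation of unphased genotype codes
(composite LD, as plink computes it).  Decay with distance is fitted to
the Hill & Weir (1988) drift expectation

    E[r²](C) = [(10+C) / ((2+C)(11+C))] ·
               [1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))]

with C = rho·d, where d is the distance in bp, rho the per-bp
recombination coefficient and n the number of sampled chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .formats import MISSING, GenotypeMatrix
from .stats import dunn_posthoc, kruskal_groups

__all__ = [
    "FilterProfile",
    "TETRASTIGMA_PROFILE",
    "LDPair",
    "HillWeirFit",
    "filter_variants",
    "pairwise_r2",
    "hill_weir_expected",
    "fit_ld_decay",
    "aggregate_ld_bins",
    "recover_high_ld_interval",
    "hom_het_ratio",
    "compare_ratio_groups",
]

#: GATK-style hard removal conditions: metric -> (comparator, threshold);
#: a record is removed when the condition holds.  Missing metrics pass.
DEFAULT_HARD_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "SOR": (">", 3.0),
}


@dataclass
class FilterProfile:
    """Post-calling SNP filters.

    Defaults are the standard resequencing profile: QUAL > 30, per-sample
    depth > 5 and at most 3x the sample's median depth, minor allele
    frequency > 0.05, no missing genotypes, plus the GATK hard filters.
    ``dp_bounds_override`` replaces the depth rule with exclusive bounds
    (low < DP < high) — the low-coverage profile uses (1, 15).
    """

    qual_min: float = 30.0
    dp_min: int = 5
    dp_max_factor: float = 3.0
    maf_min: float = 0.05
    max_missing: int = 0
    hard_filters: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_HARD_FILTERS)
    )
    dp_bounds_override: tuple[int, int] | None = None


#: Low-coverage profile: depth strictly between 1 and 15 reads.
TETRASTIGMA_PROFILE = FilterProfile(dp_bounds_override=(1, 15))


@dataclass(frozen=True)
class LDPair:
    pos_a: int
    pos_b: int
    r2: float

    @property
    def distance(self) -> int:
        return abs(self.pos_b - self.pos_a)


def _maf(genos: np.ndarray) -> np.ndarray:
    """Minor allele frequency per row over non-missing codes."""
    g = np.ma.masked_equal(genos, MISSING)
    p = g.mean(axis=1).filled(np.nan) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_variants(
    m: GenotypeMatrix, profile: FilterProfile | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the post-calling filters; return survivors and a tally.

    Each rejected record is tallied under the first failing filter, in
    the order qual, depth, maf, missing, hard.  Record order is kept.
    """
    profile = profile or FilterProfile()
    n = m.n_variants
    tally = {"qual": 0, "depth": 0, "maf": 0, "missing": 0, "hard": 0}
    if n == 0:
        return m, tally

    fail_qual = ~(m.qual > profile.qual_min)

    dp = m.depths
    if profile.dp_bounds_override is not None:
        low, high = profile.dp_bounds_override
        dp_ok = (dp > low) & (dp < high)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.where(dp < 0, np.nan, dp), axis=0)  # per sample
        med = np.where(np.isnan(med), 0, med)
        dp_ok = (dp > profile.dp_min) & (dp <= profile.dp_max_factor * med)
    fail_depth = ~dp_ok.all(axis=1)

    maf = _maf(m.genotypes)
    fail_maf = ~(maf > profile.maf_min)

    n_missing = (m.genotypes == MISSING).sum(axis=1)
    fail_missing = n_missing > profile.max_missing

    fail_hard = np.zeros(n, dtype=bool)
    for name, (op, thr) in profile.hard_filters.items():
        if name not in m.info.columns:
            continue
        v = m.info[name].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if op in ("<", "<="):
                cond = v < thr if op == "<" else v <= thr
            elif op in (">", ">="):
                cond = v > thr if op == ">" else v >= thr
            else:
                raise ValueError(f"bad comparator {op!r}")
        fail_hard |= np.nan_to_num(cond, nan=False).astype(bool)

    keep = np.ones(n, dtype=bool)
    for name, fail in (
        ("qual", fail_qual),
        ("depth", fail_depth),
        ("maf", fail_maf),
        ("missing", fail_missing),
        ("hard", fail_hard),
    ):
        newly = keep & fail
        tally[name] = int(newly.sum())
        keep &= ~fail
    return m.take(keep), tally


def pairwise_r2(
    m: GenotypeMatrix,
    maf_min: float = 0.05,
    max_dist_bp: int = 300_000,
) -> list[LDPair]:
    """All intra-region SNP pairs within ``max_dist_bp``, with r².

    Sites failing the MAF cut or monomorphic over shared non-missing
    samples are skipped; pairs with fewer than 3 shared calls are
    dropped.  r² is the squared correlation of genotype codes.
    """
    pos = m.positions
    G = m.genotypes.astype(float)
    G[G == MISSING] = np.nan
    maf = _maf(m.genotypes)
    usable = np.flatnonzero(np.nan_to_num(maf) > maf_min)
    pairs: list[LDPair] = []
    if len(usable) < 2:
        return pairs
    pos_u = pos[usable]
    G_u = G[usable]
    has_missing = np.isnan(G_u).any()
    if not has_missing:
        # fast path: standardized rows, dot products per distance window
        mu = G_u.mean(axis=1, keepdims=True)
        sd = G_u.std(axis=1, keepdims=True)
        poly = (sd[:, 0] > 0)
        Z = np.where(sd > 0, (G_u - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        ns = G_u.shape[1]
        for i in range(len(usable) - 1):
            if not poly[i]:
                continue
            j_hi = np.searchsorted(pos_u, pos_u[i] + max_dist_bp, side="right")
            js = np.arange(i + 1, j_hi)
            js = js[poly[js]]
            if js.size == 0:
                continue
            r = Z[js] @ Z[i] / ns
            for j, rv in zip(js, r * r):
                pairs.append(LDPair(int(pos_u[i]), int(pos_u[j]), float(min(rv, 1.0))))
        return pairs
    for i in range(len(usable) - 1):
        j_hi = np.searchsorted(pos_u, pos_u[i] + max_dist_bp, side="right")
        for j in range(i + 1, j_hi):
            a, b = G_u[i], G_u[j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3:
                continue
            x, y = a[ok], b[ok]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            pairs.append(LDPair(int(pos_u[i]), int(pos_u[j]), float(min(r * r, 1.0))))
    return pairs


# ---------------------------------------------------------------------------
# Hill-Weir decay


def hill_weir_expected(d, rho: float, n: int):
    """Hill & Weir (1988) sample-size-adjusted E[r²] at distance d bp."""
    C = rho * np.asarray(d, dtype=float)
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return term1 * term2


@dataclass
class HillWeirFit:
    rho: float
    n: int
    half_decay_bp: float  # inf when the curve never falls to half its d->0 value
    residual: float

    def expected(self, d):
        return hill_weir_expected(d, self.rho, self.n)

    @property
    def no_decay(self) -> bool:
        return not np.isfinite(self.half_decay_bp)


def fit_ld_decay(pairs: list[LDPair], n: int) -> HillWeirFit:
    """Least-squares Hill-Weir fit; half-decay distance by bisection.

    The half-decay distance is the d at which the fitted curve equals
    half its value at d -> 0 ("half of the maximum average r²").  The fit
    is flagged no-decay (``half_decay_bp = inf``) when the asymptote 1/n
    exceeds that level or the curve only reaches it beyond the observed
    distance range (rho ~ 0).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 LD pairs to fit")
    d = np.array([p.distance for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs], dtype=float)
    if np.allclose(r2, r2[0]):
        raise ValueError("degenerate fit: all r2 values identical")
    scale = max(d.max(), 1.0)

    def model(dd, rho):
        return hill_weir_expected(dd, rho, n)

    best = None
    for rho0 in (0.1 / scale, 1.0 / scale, 10.0 / scale, 100.0 / scale):
        try:
            popt, _ = optimize.curve_fit(
                model, d, r2, p0=[rho0], bounds=(0.0, np.inf), maxfev=10_000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((model(d, popt[0]) - r2) ** 2))
        if best is None or rss < best[1]:
            best = (float(popt[0]), rss)
    if best is None:
        raise RuntimeError("Hill-Weir fit did not converge from any start")
    rho, rss = best

    r2_0 = hill_weir_expected(0.0, rho, n)
    target = r2_0 / 2.0
    if rho <= 0 or target <= 1.0 / n:
        half = np.inf
    else:
        hi = 1.0
        while hill_weir_expected(hi, rho, n) > target and hi < 1e15:
            hi *= 10.0
        half = float(
            optimize.brentq(
                lambda x: hill_weir_expected(x, rho, n) - target, 0.0, hi
            )
        )
        if half > d.max():
            half = np.inf  # curve does not fall to half within the data
    return HillWeirFit(rho=rho, n=n, half_decay_bp=half, residual=rss)


# ---------------------------------------------------------------------------
# LD landscape


def aggregate_ld_bins(
    pairs: list[LDPair],
    region: tuple[int, int],
    bin_bp: int = 1000,
    min_snps: int = 0,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Collapse pairwise r² onto a 1-kbp (by default) positional grid.

    Each pair contributes its r² to the bin of each of its two SNP
    positions.  ``snp_count`` per bin comes from ``positions`` when
    given (all SNPs in the matrix), otherwise from the distinct pair
    endpoints.  Bins with fewer than ``min_snps`` SNPs are masked.
    Columns: bin_start, mean_r2, snp_count, masked.
    """
    start, end = region
    edges = np.arange(start, end + bin_bp, bin_bp)
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)

    def bin_of(pos: int) -> int:
        return int((pos - start) // bin_bp)

    endpoint_sets: list[set[int]] = [set() for _ in range(nbins)]
    for p in pairs:
        for pos in (p.pos_a, p.pos_b):
            if not (start <= pos < end):
                continue
            b = bin_of(pos)
            sums[b] += p.r2
            counts[b] += 1
            endpoint_sets[b].add(pos)
    if positions is not None:
        positions = np.asarray(positions)
        inside = positions[(positions >= start) & (positions < end)]
        snp_count = np.bincount(
            ((inside - start) // bin_bp).astype(int), minlength=nbins
        )
    else:
        snp_count = np.array([len(s) for s in endpoint_sets])
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    masked = snp_count < min_snps
    mean_r2 = np.where(masked, np.nan, mean_r2)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "mean_r2": mean_r2,
            "snp_count": snp_count,
            "masked": masked,
        }
    )


def recover_high_ld_interval(
    landscape: pd.DataFrame,
    r2_min: float = 0.4,
    max_gap_bins: int = 2,
) -> tuple[int, int] | None:
    """Longest run of high-LD bins, the empirical SDR boundary estimate.

    Unmasked bins with ``mean_r2 >= r2_min`` are merged into runs,
    tolerating up to ``max_gap_bins`` intervening low/empty bins; the
    longest merged run is returned as (start_bp, end_bp), end exclusive.
    """
    df = landscape
    bin_bp = (
        int(df["bin_start"].iloc[1] - df["bin_start"].iloc[0])
        if len(df) > 1
        else 1000
    )
    hot = df[(~df["masked"]) & (df["mean_r2"] >= r2_min)]["bin_start"].to_numpy()
    if hot.size == 0:
        return None
    runs: list[list[int]] = [[int(hot[0]), int(hot[0])]]
    for b in hot[1:]:
        if b - runs[-1][1] <= (max_gap_bins + 1) * bin_bp:
            runs[-1][1] = int(b)
        else:
            runs.append([int(b), int(b)])
    best = max(runs, key=lambda r: r[1] - r[0])
    return best[0], best[1] + bin_bp


# ---------------------------------------------------------------------------
# Heterozygosity contrast


def hom_het_ratio(
    m: GenotypeMatrix, region: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per-sample ratio of homozygous-alt to heterozygous calls.

    Samples with zero het calls get ``ratio = inf`` and ``infinite=True``.
    Columns: sample, hom_alt, het, ratio, infinite.
    """
    g = m.genotypes
    if region is not None:
        lo, hi = region
        sel = (m.positions >= lo) & (m.positions <= hi)
        g = g[sel]
    hom = (g == 2).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(het > 0, hom / np.maximum(het, 1), np.inf)
    return pd.DataFrame(
        {
            "sample": m.samples,
            "hom_alt": hom,
            "het": het,
            "ratio": ratio,
            "infinite": het == 0,
        }
    )


def compare_ratio_groups(
    ratios: pd.DataFrame, group_of: dict[str, str]
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis + BH-adjusted Dunn's test on hom/het ratios.

    Infinite ratios are excluded with a warning.  Returns (H, p, dunn
    table); the Dunn table is empty for two groups.
    """
    df = ratios.copy()
    df["group"] = df["sample"].map(group_of)
    if df["infinite"].any():
        warnings.warn(
            f"excluding {int(df['infinite'].sum())} sample(s) with no het calls",
            stacklevel=2,
        )
        df = df[~df["infinite"]]
    groups = {
        g: sub["ratio"].to_numpy(dtype=float) for g, sub in df.groupby("group")
    }
    res = kruskal_groups(groups)
    dunn = dunn_posthoc(groups)
    return res.H, res.p, dunn
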