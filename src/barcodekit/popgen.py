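"""Genetic-diversity and neutrality statistics.

Implements the DnaSP-style per-locus summary for a set of aligned
sequences: segregating sites S, total mutations Eta, mean pairwise
differences k, haplotype number/diversity, Watterson's theta and
nucleotide diversity pi; the two neutrality tests (Tajima's D and Fu's
Fs); and the pairwise mismatch distribution with its shape statistics
(raggedness r, Ramos-Onsins & Rozas R2) and a sudden-expansion tau
estimate.

All statistics are computed after alignment-wide complete deletion, so
that they share one set of fully resolved columns with the distance
module. Haplotypes are distinct residue strings on those columns.

Tajima's D
    D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1)), with the standard
    coefficients a1..e2 determined by the sample size n. Its significance
    band uses the beta approximation to D's null distribution.

Fu's Fs
    With theta-hat = k (per-sequence units), S' = Pr(K >= k_obs) under
    the Ewens sampling distribution, Pr(K = j) = |S1(n, j)| theta^j /
    (theta (theta+1) ... (theta+n-1)) with unsigned Stirling numbers of
    the first kind, and Fs = ln(S' / (1 - S')). Evaluation is exact in
    log space (stable to n >= 2000). The significance band is obtained by
    coalescent simulation at theta-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .msa_io import Alignment, AlignmentError, complete_deletion


class UndefinedStatistic(ValueError):
    """The requested statistic is undefined for this input (e.g. S = 0)."""


# ---------------------------------------------------------------------------
# Diversity statistics (Table-4 bundle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    n: int
    S: int
    Eta: int
    k: float  # mean pairwise differences per sequence
    h: int  # haplotype count
    Hd: float  # haplotype diversity
    theta_w: float  # Watterson's estimator per site
    pi: float  # nucleotide diversity per site
    L_eff: int  # complete columns the statistics were computed on


@dataclass(frozen=True)
class TajimaCoefficients:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass(frozen=True)
class NeutralityResult:
    statistic: str  # "D" or "Fs"
    value: float
    p_value: float | None
    p_band: str  # significance band as printed, e.g. "< 0.05"


@dataclass(frozen=True)
class MismatchDistribution:
    x: np.ndarray  # relative frequency of pairwise difference counts 0..d_max
    r: float  # raggedness
    R2: float | None  # Ramos-Onsins & Rozas statistic (None when undefined)
    U: np.ndarray  # per-sequence singleton-mutation counts
    tau: float  # sudden-expansion time estimate (mutational units)
    cv: float | None  # coefficient of variation of pairwise difference counts


def harmonic(n: int, power: int = 1) -> float:
    """Sum_{i=1}^{n} 1/i**power."""
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


def tajima_coefficients(n: int) -> TajimaCoefficients:
    """The standard sample-size constants entering Tajima's D."""
    if n < 2:
        raise UndefinedStatistic("Tajima coefficients need n >= 2")
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(a1, a2, b1, b2, c1, c2, e1, e2)


def _pairwise_differences(rows: list[str]) -> list[int]:
    return [
        sum(1 for x, y in zip(a, b) if x != y) for a, b in combinations(rows, 2)
    ]


def diversity_stats(aln: Alignment) -> DiversityStats:
    """The per-locus diversity bundle, computed on complete columns."""
    if aln.n < 2:
        raise AlignmentError("diversity_stats needs at least 2 sequences")
    work, _ = complete_deletion(aln)
    rows = [r.residues for r in work.records]
    n, L = work.n, work.length

    S = Eta = 0
    for j in range(L):
        distinct = len({row[j] for row in rows})
        if distinct > 1:
            S += 1
            Eta += distinct - 1

    diffs = _pairwise_differences(rows)
    k = float(np.mean(diffs))

    hap_counts: dict[str, int] = {}
    for row in rows:
        hap_counts[row] = hap_counts.get(row, 0) + 1
    h = len(hap_counts)
    p2 = sum((c / n) ** 2 for c in hap_counts.values())
    Hd = n * (1.0 - p2) / (n - 1)

    a1 = harmonic(n - 1)
    return DiversityStats(
        n=n, S=S, Eta=Eta, k=k, h=h, Hd=Hd,
        theta_w=S / (a1 * L), pi=k / L, L_eff=L,
    )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _band(p: float) -> str:
    if p < 0.001:
        return "< 0.001"
    if p < 0.01:
        return "< 0.01"
    if p < 0.05:
        return "< 0.05"
    if p < 0.10:
        return "0.10 > P > 0.05"
    return "> 0.10"


def tajimas_d_value(n: int, S: int, k: float) -> float:
    """Tajima's D from sample size, segregating sites and mean differences."""
    if S < 1:
        raise UndefinedStatistic("Tajima's D undefined for S = 0")
    if n < 4:
        raise UndefinedStatistic("Tajima's D needs n >= 4")
    c = tajima_coefficients(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (k - S / c.a1) / math.sqrt(var)


def tajimas_d(stats: DiversityStats) -> NeutralityResult:
    """Tajima's D with a beta-approximation significance band.

    Under neutrality D is approximately a shifted/scaled beta on
    [Dmin, Dmax] with mean 0 and variance 1 (Dmin attained when all
    mutations are singletons, Dmax at frequency 1/2); the two-tailed
    p-value is read from that distribution.
    """
    D = tajimas_d_value(stats.n, stats.S, stats.k)
    n = stats.n
    c = tajima_coefficients(n)
    dmin = (2.0 / n - 1.0 / c.a1) / math.sqrt(c.e2)
    dmax = ((n / (2.0 * (n - 1.0))) - 1.0 / c.a1) / math.sqrt(c.e2)
    span = dmax - dmin
    alpha = -(1.0 + dmin * dmax) * dmax / span
    bta = (1.0 + dmin * dmax) * dmin / span
    p: float | None = None
    if alpha > 0 and bta > 0 and span > 0:
        u = min(max((D - dmin) / span, 0.0), 1.0)
        cdf = float(beta_dist.cdf(u, bta, alpha))
        p = 2.0 * min(cdf, 1.0 - cdf)
        p = min(p, 1.0)
    return NeutralityResult("D", D, p, _band(p) if p is not None else "NA")


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |S1(n, j)| for j = 0..n (unsigned Stirling, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S1(0,0)| = 1
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        # |S1(m+1, j)| = m * |S1(m, j)| + |S1(m, j-1)|
        with np.errstate(divide="ignore"):
            scaled = row + (math.log(m) if m > 0 else -np.inf)
        new[1:] = np.logaddexp(scaled[1:], row[:-1])
        new[0] = scaled[0]
        row = new
    return row


def _log_ewens_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = j | theta) for j = 0..n under the Ewens distribution."""
    ls1 = _log_stirling_row(n)
    j = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return ls1 + j * math.log(theta) - log_rising


def fus_fs_value(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs from sample size, haplotype count and theta-hat = k."""
    if theta <= 0:
        raise UndefinedStatistic("Fu's Fs undefined for k = 0")
    if not 1 <= k_obs <= n:
        raise ValueError("haplotype count must be in [1, n]")
    logp = _log_ewens_pmf(n, theta)
    log_sp = float(logsumexp(logp[k_obs:]))  # log S'  = log Pr(K >= k_obs)
    if k_obs == 1:
        raise UndefinedStatistic("S' = 1 exactly (every sample has K >= 1)")
    log_one_minus = float(logsumexp(logp[1:k_obs]))  # log (1 - S')
    return log_sp - log_one_minus


def fus_fs(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    simulate_band: bool = True,
) -> NeutralityResult:
    """Fu's Fs for an alignment, with a simulated significance band.

    The band is the fraction of constant-size coalescent replicates at
    theta-hat = k whose Fs is <= the observed value (Fs's rejection tail
    is the low/negative side).
    """
    stats = diversity_stats(aln)
    work, _ = complete_deletion(aln)
    fs = fus_fs_value(stats.n, stats.h, stats.k)
    p: float | None = None
    if simulate_band and n_reps > 0:
        from .synthetic_data import simulate_coalescent

        rng = np.random.default_rng(seed)
        L_sim = max(4 * stats.L_eff, 200)
        hits = total = 0
        for _ in range(n_reps):
            rep = simulate_coalescent(
                stats.n, stats.k, L_sim, int(rng.integers(2**31 - 1))
            )
            rstats = diversity_stats(rep)
            if rstats.k <= 0:
                # monomorphic replicate: Fs is +inf, never <= observed
                total += 1
                continue
            try:
                fs_rep = fus_fs_value(rstats.n, rstats.h, rstats.k)
            except UndefinedStatistic:
                total += 1
                continue
            total += 1
            if fs_rep <= fs:
                hits += 1
        p = hits / total if total else None
    return NeutralityResult("Fs", fs, p, _band(p) if p is not None else "NA")


# ---------------------------------------------------------------------------
# Mismatch distribution
# ---------------------------------------------------------------------------

def _singleton_counts(rows: list[str]) -> np.ndarray:
    """Per-sequence counts of singleton mutations (bases unique to one row)."""
    n = len(rows)
    U = np.zeros(n, dtype=int)
    if n == 0:
        return U
    for j in range(len(rows[0])):
        col = [row[j] for row in rows]
        if len(set(col)) < 2:
            continue
        for b in set(col):
            if col.count(b) == 1:
                U[col.index(b)] += 1
    return U


def _fit_tau(x: np.ndarray) -> float:
    """Least-squares fit of a Poisson(tau) sudden-expansion mismatch curve.

    The expected mismatch distribution immediately after a sudden
    expansion from a small population is approximately Poisson with mean
    tau (pairwise differences accumulate clock-like on star-shaped
    genealogies); tau is chosen on a grid to minimize the squared
    deviation from the observed relative frequencies.
    """
    d_max = len(x) - 1
    if d_max == 0:
        return 0.0
    from scipy.stats import poisson

    grid = np.linspace(0.0, 2.0 * d_max, 801)
    i = np.arange(d_max + 1)
    best_tau, best_sse = 0.0, np.inf
    for tau in grid:
        expected = poisson.pmf(i, tau) if tau > 0 else (i == 0).astype(float)
        sse = float(np.sum((x - expected) ** 2))
        if sse < best_sse:
            best_tau, best_sse = tau, sse
    return best_tau


def mismatch_distribution(aln: Alignment) -> MismatchDistribution:
    """Pairwise mismatch distribution with r, R2, tau and C.V."""
    if aln.n < 2:
        raise AlignmentError("mismatch_distribution needs at least 2 sequences")
    work, _ = complete_deletion(aln)
    rows = [r.residues for r in work.records]
    n = work.n
    diffs = np.array(_pairwise_differences(rows))
    d_max = int(diffs.max())
    x = np.bincount(diffs, minlength=d_max + 1).astype(float) / len(diffs)

    # raggedness: squared successive differences, padded with 0 past d_max
    padded = np.concatenate([x, [0.0]])
    r = float(np.sum(np.diff(padded) ** 2))

    k = float(diffs.mean())
    S = sum(1 for j in range(work.length) if len({row[j] for row in rows}) > 1)
    U = _singleton_counts(rows)
    R2: float | None = None
    if S > 0 and n >= 3:
        R2 = float(math.sqrt(np.mean((U - k / 2.0) ** 2)) / S)

    cv = float(diffs.std(ddof=1) / k) if k > 0 and len(diffs) > 1 else None
    return MismatchDistribution(x=x, r=r, R2=R2, U=U, tau=_fit_tau(x), cv=cv)
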