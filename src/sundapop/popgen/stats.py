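"""Diversity, neutrality and demographic-expansion statistics.

All pairwise difference counts use pairwise deletion of ambiguous sites
(N or gap).  Monte-Carlo p-values for Tajima's D and Fu's FS come from
neutral coalescent simulations conditioned on the observed number of
segregating sites (the convention of the classical population-genetics
packages); p-values use the (b + 1)/(m + 1) estimator and are one-tailed in
the direction of the observed deviation from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import SequenceAlignment, collapse_haplotypes, pair_site_counts
from .coalescent import simulate_coalescent

__all__ = [
    "DiversityStats",
    "NeutralityStats",
    "MismatchResult",
    "pairwise_differences",
    "segregating_sites",
    "diversity",
    "tajimas_d",
    "fus_fs",
    "ewens_sf_prime",
    "mismatch",
]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. no variation)."""


def pairwise_differences(aln: SequenceAlignment) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts, pairwise-deleted."""
    n = aln.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ts, _, _, tv = pair_site_counts(aln.sequences[i], aln.sequences[j])
            out[i, j] = out[j, i] = ts + tv
    return out


def segregating_sites(aln: SequenceAlignment) -> int:
    """Number of columns with >= 2 distinct unambiguous bases."""
    mat = aln.matrix
    s = 0
    acgt = np.frombuffer(b"ACGT", np.uint8)
    m = mat.view(np.uint8)
    for col in m.T:
        bases = np.unique(col[np.isin(col, acgt)])
        if len(bases) >= 2:
            s += 1
    return s


def mean_pairwise_differences(aln: SequenceAlignment) -> float:
    d = pairwise_differences(aln)
    n = aln.n
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


@dataclass
class DiversityStats:
    n: int
    n_haplotypes: int
    gene_diversity: float
    gene_diversity_se: float
    theta_pi: float
    theta_pi_sd: float
    segregating_sites: int


def diversity(aln: SequenceAlignment) -> DiversityStats:
    """Gene (haplotype) diversity with Nei's standard error, and theta_pi.

    H = n(1 - sum p_i^2)/(n - 1); its sampling variance is Nei's (1987)
    formula.  theta_pi is the mean number of pairwise differences; its
    standard deviation uses the total (sampling + evolutionary) variance
    (n+1)/(3(n-1)) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2.
    """
    n = aln.n
    if n < 2:
        raise UndefinedStatisticError("need at least 2 sequences")
    table = collapse_haplotypes(aln)
    p = table.frequencies()
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    h = n * (1.0 - sum2) / (n - 1)
    var_h = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    pi = mean_pairwise_differences(aln)
    var_pi = (n + 1) / (3.0 * (n - 1)) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return DiversityStats(
        n=n,
        n_haplotypes=table.n_haplotypes,
        gene_diversity=h,
        gene_diversity_se=float(np.sqrt(max(var_h, 0.0))),
        theta_pi=pi,
        theta_pi_sd=float(np.sqrt(var_pi)),
        segregating_sites=segregating_sites(aln),
    )


@dataclass
class NeutralityStats:
    tajima_d: float
    tajima_p: float
    fu_fs: float
    fu_p: float


def tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d_value(n: int, s: int, pi: float) -> float:
    if s < 1:
        raise UndefinedStatisticError("Tajima's D undefined with S = 0")
    c = tajima_constants(n)
    return (pi - s / c["a1"]) / np.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))


def tajimas_d(
    aln: SequenceAlignment, n_sim: int = 1000, seed: int | None = 0
) -> dict[str, float]:
    """Tajima's D with a coalescent-simulation p-value conditional on S."""
    s = segregating_sites(aln)
    pi = mean_pairwise_differences(aln)
    d = float(tajimas_d_value(aln.n, s, pi))
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_sim):
        sim = simulate_coalescent(aln.n, rng, s=s)
        d_sim = tajimas_d_value(aln.n, sim.s, sim.pi)
        if (d <= 0 and d_sim <= d) or (d > 0 and d_sim >= d):
            extreme += 1
    return {"D": d, "p": (extreme + 1) / (n_sim + 1), "S": s, "pi": pi}


def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        with np.errstate(divide="ignore"):
            grow = row + np.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(grow[1:], row[:-1])
        if m == 1:
            new[1] = 0.0
        row = new
    return row


def ewens_sf_prime(n: int, k_obs: int, theta: float) -> float:
    """S' = Pr(K >= k_obs) under the Ewens sampling distribution.

    Pr(K = k) = |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)),
    evaluated in log space via the unsigned-Stirling recurrence.
    """
    if theta <= 0:
        raise UndefinedStatisticError("theta must be positive")
    log_stir = _log_stirling_row(n)
    k = np.arange(n + 1)
    log_rising = float(np.log(theta + np.arange(n)).sum())
    logp = log_stir + k * np.log(theta) - log_rising
    p = np.exp(logp[1:])  # k = 1..n
    p /= p.sum()  # guard accumulated rounding; sums to 1 analytically
    return float(p[k_obs - 1 :].sum())


def fus_fs_value(n: int, k_obs: int, pi: float, clamp: float = 1e-12) -> float:
    if pi <= 0:
        raise UndefinedStatisticError("Fu's FS undefined with pi = 0")
    sp = ewens_sf_prime(n, k_obs, pi)
    if sp <= clamp or sp >= 1.0 - clamp:
        warnings.warn(
            f"S' = {sp:.3g} clamped to [{clamp}, {1 - clamp}] before the logit; "
            "FS is effectively at its boundary"
        )
    sp = min(max(sp, clamp), 1.0 - clamp)
    return float(np.log(sp / (1.0 - sp)))


def fus_fs(
    aln: SequenceAlignment, n_sim: int = 1000, seed: int | None = 0
) -> dict[str, float]:
    """Fu's FS with a coalescent-simulation p-value conditional on S.

    FS = ln(S'/(1 - S')) with S' the Ewens probability of observing at least
    the sampled number of haplotypes given theta estimated by pi.
    """
    pi = mean_pairwise_differences(aln)
    k_obs = collapse_haplotypes(aln).n_haplotypes
    fs = fus_fs_value(aln.n, k_obs, pi)
    s = segregating_sites(aln)
    rng = np.random.default_rng(seed)
    extreme = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary clamps in null replicates
        for _ in range(n_sim):
            sim = simulate_coalescent(aln.n, rng, s=max(s, 1))
            if sim.pi <= 0:
                continue
            fs_sim = fus_fs_value(aln.n, sim.haplotype_count(), sim.pi)
            if fs_sim <= fs:
                extreme += 1
    return {"FS": fs, "p": (extreme + 1) / (n_sim + 1), "k": k_obs, "pi": pi}


def neutrality(aln: SequenceAlignment, n_sim: int = 1000, seed: int | None = 0) -> NeutralityStats:
    d = tajimas_d(aln, n_sim=n_sim, seed=seed)
    f = fus_fs(aln, n_sim=n_sim, seed=None if seed is None else seed + 1)
    return NeutralityStats(
        tajima_d=d["D"], tajima_p=d["p"], fu_fs=f["FS"], fu_p=f["p"]
    )


@dataclass
class MismatchResult:
    histogram: np.ndarray  # relative frequencies, classes 0..d
    raggedness: float
    r2: float | None
    mean_differences: float


def singletons_per_sequence(aln: SequenceAlignment) -> np.ndarray:
    """U_i: number of sites where sequence i carries a base seen only once."""
    m = aln.matrix.view(np.uint8)
    acgt = np.frombuffer(b"ACGT", np.uint8)
    u = np.zeros(aln.n, int)
    for col in m.T:
        valid = np.isin(col, acgt)
        bases, counts = np.unique(col[valid], return_counts=True)
        if len(bases) < 2:
            continue
        for b in bases[counts == 1]:
            carrier = np.where(valid & (col == b))[0]
            u[carrier[0]] += 1
    return u


def raggedness(histogram: np.ndarray) -> float:
    """Harpending's raggedness index of a relative-frequency histogram."""
    x = np.concatenate([np.asarray(histogram, float), [0.0]])
    return float(((x[1:] - x[:-1]) ** 2).sum())


def mismatch(aln: SequenceAlignment) -> MismatchResult:
    """Mismatch distribution with raggedness r and Ramos-Onsins & Rozas R2."""
    d = pairwise_differences(aln)
    n = aln.n
    iu = np.triu_indices(n, k=1)
    diffs = d[iu].astype(int)
    hist = np.bincount(diffs).astype(float)
    hist /= hist.sum()
    pi = float(diffs.mean())
    s = segregating_sites(aln)
    if s == 0:
        r2 = None
    else:
        u = singletons_per_sequence(aln)
        r2 = float(np.sqrt(((u - pi / 2.0) ** 2).sum() / n) / s)
    return MismatchResult(
        histogram=hist, raggedness=raggedness(hist), r2=r2, mean_differences=pi
    )
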