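"""Distance-based analysis of molecular variance (AMOVA) and Phi-statistics.

Variance components follow the sums-of-squared-distances decomposition of
Excoffier, Smouse & Quattro: for a matrix of squared inter-individual
molecular distances, the total sum of squares and its within-population /
within-group restrictions yield mean squares whose expectations are linear
in the variance components.  Phi_ST for a pair of populations is
sigma^2_a / (sigma^2_a + sigma^2_b); the hierarchical (group / population /
individual) design additionally yields Phi_CT and Phi_SC.

Negative component estimates are reported as computed (they are unbiased
estimates that may fall below zero) and flagged when strongly negative.

Significance is by permutation: individuals between the two populations for
pairwise Phi_ST; for the hierarchical design, whole populations among groups
(Phi_CT), individuals among populations within their group (Phi_SC) and
individuals among all populations (Phi_ST); p = (b + 1)/(m + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .distances import tn93_matrix

__all__ = ["AMOVAResult", "pairwise_phist", "amova", "two_level_components"]


def _ssd_of_partition(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    """Sum over parts of (sum of squared distances within part) / part size."""
    total = 0.0
    for idx in parts:
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def two_level_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) for a populations/individuals design."""
    labels = np.asarray(labels)
    pops = sorted(set(labels.tolist()))
    n_tot = len(labels)
    parts = [np.where(labels == p)[0] for p in pops]
    sizes = np.array([len(p) for p in parts])
    ssd_t = d2.sum() / (2.0 * n_tot)
    ssd_wp = _ssd_of_partition(d2, parts)
    ssd_ap = ssd_t - ssd_wp
    df_ap = len(pops) - 1
    df_wp = n_tot - len(pops)
    sigma_w = ssd_wp / df_wp if df_wp > 0 else 0.0
    n0 = (n_tot - (sizes**2).sum() / n_tot) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_w) / n0
    return float(sigma_a), float(sigma_w)


def _phist_from_components(sigma_a: float, sigma_w: float) -> float:
    tot = sigma_a + sigma_w
    if tot == 0:
        raise ZeroDivisionError("no molecular variance; Phi_ST undefined")
    return sigma_a / tot


def pairwise_phist(
    aln: SequenceAlignment,
    n_perm: int = 1000,
    seed: int | None = 0,
    d2: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Pairwise Phi_ST between all populations, on squared TN93 distances.

    Populations with fewer than 2 sequences are excluded with a warning.
    Negative estimates are reported as computed, not truncated at zero.
    """
    labels = np.asarray(aln.populations)
    pops = aln.population_names
    sizes = {p: int((labels == p).sum()) for p in pops}
    small = [p for p in pops if sizes[p] < 2]
    if small:
        warnings.warn(f"populations with n < 2 excluded from Phi_ST: {small}")
        pops = [p for p in pops if sizes[p] >= 2]
    if len(pops) < 2:
        raise ValueError("need at least 2 populations with n >= 2")
    if d2 is None:
        d2 = tn93_matrix(aln) ** 2
    rng = np.random.default_rng(seed)
    g = len(pops)
    phist = np.zeros((g, g))
    pvals = np.full((g, g), np.nan)
    for a in range(g):
        for b in range(a + 1, g):
            idx = np.where((labels == pops[a]) | (labels == pops[b]))[0]
            sub = d2[np.ix_(idx, idx)]
            sub_labels = labels[idx]
            sa, sw = two_level_components(sub, sub_labels)
            obs = _phist_from_components(sa, sw)
            phist[a, b] = phist[b, a] = obs
            if n_perm:
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(sub_labels)
                    pa, pw = two_level_components(sub, perm)
                    try:
                        stat = _phist_from_components(pa, pw)
                    except ZeroDivisionError:
                        continue
                    if stat >= obs:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
                pvals[a, b] = pvals[b, a] = p
    return {
        "phist": pd.DataFrame(phist, index=pops, columns=pops),
        "p": pd.DataFrame(pvals, index=pops, columns=pops),
    }


@dataclass
class AMOVAResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float | None
    p_sc: float | None
    p_st: float | None
    table: pd.DataFrame = field(repr=False)

    @property
    def percentages(self) -> tuple[float, float, float]:
        tot = self.sigma_a + self.sigma_b + self.sigma_c
        return (
            100.0 * self.sigma_a / tot,
            100.0 * self.sigma_b / tot,
            100.0 * self.sigma_c / tot,
        )


def _three_level(
    d2: np.ndarray, pop_labels: np.ndarray, group_of: dict[str, str]
) -> tuple[float, float, float, dict]:
    pops = sorted(set(pop_labels.tolist()))
    groups = sorted(set(group_of[p] for p in pops))
    n_tot = len(pop_labels)
    n_pops = len(pops)
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")

    pop_idx = {p: np.where(pop_labels == p)[0] for p in pops}
    grp_idx = {
        g: np.concatenate([pop_idx[p] for p in pops if group_of[p] == g])
        for g in groups
    }
    pop_sizes = {p: len(pop_idx[p]) for p in pops}
    grp_sizes = {g: len(grp_idx[g]) for g in groups}

    ssd_t = d2.sum() / (2.0 * n_tot)
    ssd_wp = _ssd_of_partition(d2, list(pop_idx.values()))
    ssd_wg = _ssd_of_partition(d2, list(grp_idx.values()))
    ssd_ap = ssd_wg - ssd_wp  # among populations within groups
    ssd_ag = ssd_t - ssd_wg  # among groups

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_tot - n_pops

    sigma_c = ssd_wp / df_wp
    a_term = sum(
        sum(pop_sizes[p] ** 2 for p in pops if group_of[p] == g) / grp_sizes[g]
        for g in groups
    )
    b_term = sum(pop_sizes[p] ** 2 for p in pops) / n_tot
    n1 = (n_tot - a_term) / df_ap
    n2 = (a_term - b_term) / df_ag
    n3 = (n_tot - sum(grp_sizes[g] ** 2 for g in groups) / n_tot) / df_ag
    sigma_b = (ssd_ap / df_ap - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    meta = {
        "ssd": (ssd_ag, ssd_ap, ssd_wp),
        "df": (df_ag, df_ap, df_wp),
    }
    return sigma_a, sigma_b, sigma_c, meta


def amova(
    aln: SequenceAlignment,
    groups: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = 0,
    d2: np.ndarray | None = None,
) -> AMOVAResult:
    """Hierarchical AMOVA (groups / populations / individuals).

    ``groups`` maps group name -> list of population names; every population
    in the alignment must be assigned to exactly one group.
    """
    labels = np.asarray(aln.populations)
    pops = set(aln.population_names)
    group_of: dict[str, str] = {}
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} contains no populations")
        for p in members:
            if p not in pops:
                raise KeyError(f"group {gname!r} references unknown population {p!r}")
            if p in group_of:
                raise ValueError(f"population {p!r} assigned to two groups")
            group_of[p] = gname
    unassigned = pops - set(group_of)
    if unassigned:
        raise ValueError(f"populations not assigned to any group: {sorted(unassigned)}")

    if d2 is None:
        d2 = tn93_matrix(aln) ** 2
    if d2.sum() == 0:
        raise ZeroDivisionError("all sequences identical; AMOVA degenerate")
    sigma_a, sigma_b, sigma_c, meta = _three_level(d2, labels, group_of)
    tot = sigma_a + sigma_b + sigma_c
    if sigma_a < -0.05 * abs(tot) or sigma_b < -0.05 * abs(tot):
        warnings.warn(
            f"strongly negative variance component (a={sigma_a:.4g}, b={sigma_b:.4g})"
        )
    phi_ct = sigma_a / tot
    phi_sc = sigma_b / (sigma_b + sigma_c)
    phi_st = (sigma_a + sigma_b) / tot

    p_ct = p_sc = p_st = None
    if n_perm:
        rng = np.random.default_rng(seed)
        pop_list = sorted(pops)
        grp_of_pops = np.array([group_of[p] for p in pop_list])
        hits_ct = hits_sc = hits_st = 0
        for _ in range(n_perm):
            # Phi_CT: permute populations among groups
            perm_groups = dict(zip(pop_list, rng.permutation(grp_of_pops)))
            try:
                a, b, c, _ = _three_level(d2, labels, perm_groups)
                if a / (a + b + c) >= phi_ct:
                    hits_ct += 1
            except (ZeroDivisionError, ValueError):
                pass
            # Phi_SC: permute individuals among populations within groups
            perm_labels = labels.copy()
            for gname, members in groups.items():
                idx = np.where(np.isin(labels, members))[0]
                perm_labels[idx] = labels[rng.permutation(idx)]
            try:
                a, b, c, _ = _three_level(d2, perm_labels, group_of)
                if b / (b + c) >= phi_sc:
                    hits_sc += 1
            except ZeroDivisionError:
                pass
            # Phi_ST: permute individuals among all populations
            perm_all = labels[rng.permutation(len(labels))]
            try:
                a, b, c, _ = _three_level(d2, perm_all, group_of)
                if (a + b) / (a + b + c) >= phi_st:
                    hits_st += 1
            except ZeroDivisionError:
                pass
        p_ct = (hits_ct + 1) / (n_perm + 1)
        p_sc = (hits_sc + 1) / (n_perm + 1)
        p_st = (hits_st + 1) / (n_perm + 1)

    pct = (100 * sigma_a / tot, 100 * sigma_b / tot, 100 * sigma_c / tot)
    table = pd.DataFrame(
        {
            "source": [
                "among groups",
                "among populations within groups",
                "within populations",
            ],
            "df": list(meta["df"]),
            "sum_sq": list(meta["ssd"]),
            "variance": [sigma_a, sigma_b, sigma_c],
            "pct": list(pct),
            "phi": [phi_ct, phi_sc, phi_st],
            "p": [p_ct, p_sc, p_st],
        }
    )
    return AMOVAResult(
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        sigma_c=sigma_c,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_ct=p_ct,
        p_sc=p_sc,
        p_st=p_st,
        table=table,
    )
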