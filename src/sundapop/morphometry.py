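"""Landmark-based wing-shape analysis.

The morphometric pipeline is the standard geometric-morphometrics stack:

1. 15 two-dimensional landmarks per wing (left wings reflected to right
   orientation on input);
2. generalized Procrustes analysis (GPA) removing translation, scale and
   rotation, leaving shape variables;
3. multivariate regression of shape on centroid size to quantify and remove
   allometry, with a permutation test of size/shape independence;
4. canonical variate analysis (CVA) of the allometry-corrected shapes over
   a-priori site groups, with permutation tests on pairwise Mahalanobis and
   Procrustes distances;
5. one-way ANOVA (+ Tukey HSD) on centroid size.

Centroid size is the standard isometric size measure: the square root of the
summed squared distances of the landmarks from their centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_LANDMARKS = 15

__all__ = [
    "N_LANDMARKS",
    "LandmarkConfiguration",
    "ShapeDataset",
    "ProcrustesResult",
    "AllometryResult",
    "CVAResult",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa_align",
    "procrustes_distance",
    "allometric_regression",
    "cva",
    "centroid_size_anova",
]


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide; size and shape are undefined."""


@dataclass
class LandmarkConfiguration:
    specimen_id: str
    site: str
    side: str  # "left" | "right"
    coords: np.ndarray  # (15, 2), right-wing orientation

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"specimen {self.specimen_id!r}: expected {N_LANDMARKS} landmarks, "
                f"got shape {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class ShapeDataset:
    configurations: list[LandmarkConfiguration]

    def __post_init__(self) -> None:
        if len(self.configurations) < 2:
            raise ValueError("need at least 2 configurations")

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def sites(self) -> list[str]:
        return [c.site for c in self.configurations]

    @property
    def array(self) -> np.ndarray:
        """(n, 15, 2) stacked coordinates."""
        return np.stack([c.coords for c in self.configurations])

    def __len__(self) -> int:
        return len(self.configurations)


def read_tps(path, site_map) -> ShapeDataset:
    """Read a TPS landmark file plus a specimen→site TSV.

    ``site_map`` is a path to (or DataFrame of) a TSV with columns
    ``specimen_id``, ``site`` and optionally ``side``.  Left-side specimens
    are reflected about the vertical axis (x negated) so that every stored
    configuration is in right-wing orientation.
    """
    if not isinstance(site_map, pd.DataFrame):
        site_map = pd.read_csv(site_map, sep="\t", dtype=str)
    site_map = site_map.set_index("specimen_id")

    records = _parse_tps(path)
    configs = []
    for rec_id, coords in records:
        if coords.shape[0] != N_LANDMARKS:
            raise ValueError(
                f"specimen {rec_id!r}: TPS record has {coords.shape[0]} landmarks, "
                f"expected {N_LANDMARKS}"
            )
        if rec_id not in site_map.index:
            raise KeyError(f"specimen {rec_id!r} missing from site map")
        row = site_map.loc[rec_id]
        side = str(row.get("side", "right") or "right").lower()
        if side == "left":
            coords = coords * np.array([-1.0, 1.0])
        configs.append(
            LandmarkConfiguration(rec_id, str(row["site"]), side, coords)
        )
    return ShapeDataset(configs)


def _parse_tps(path) -> list[tuple[str, np.ndarray]]:
    records = []
    lm_count = None
    coords: list[list[float]] = []
    rec_id = None
    image = None

    def _flush():
        nonlocal lm_count, coords, rec_id, image
        if lm_count is None:
            return
        name = rec_id or image or f"record_{len(records)}"
        if len(coords) != lm_count:
            raise ValueError(
                f"specimen {name!r}: LM={lm_count} but {len(coords)} coordinate rows"
            )
        records.append((name, np.array(coords, float)))
        lm_count, coords, rec_id, image = None, [], None, None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            key = line.split("=", 1)[0].upper()
            if key == "LM":
                _flush()
                lm_count = int(line.split("=", 1)[1])
            elif key == "ID":
                rec_id = line.split("=", 1)[1].strip()
            elif key == "IMAGE":
                image = line.split("=", 1)[1].strip().rsplit(".", 1)[0]
            elif key in ("SCALE", "CURVES", "POINTS"):
                continue
            else:
                parts = line.split()
                coords.append([float(parts[0]), float(parts[1])])
    _flush()
    return records


def write_tps(dataset: ShapeDataset, path) -> None:
    """Write a dataset back to TPS (left wings re-reflected to file orientation)."""
    with open(path, "w") as fh:
        for c in dataset.configurations:
            coords = c.coords.copy()
            if c.side == "left":
                coords[:, 0] *= -1.0
            fh.write(f"LM={coords.shape[0]}\n")
            for x, y in coords:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={c.specimen_id}\n")


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """sqrt of the summed squared landmark distances from the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return cs


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (n, k, 2) unit-size, centred, rotated to consensus
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,) sizes of the raw configurations
    ids: list[str]
    sites: list[str]
    n_iterations: int

    @property
    def flat(self) -> np.ndarray:
        """(n, 2k) shape variables."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)

    def procrustes_distance(self, i: int, j: int) -> float:
        return procrustes_distance(self.aligned[i], self.aligned[j])


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimizing ||a R - b||."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-of-squares between two optimally superimposed configurations.

    Both configurations are centred and scaled to unit centroid size, then b
    is rotated onto a (rotation only; reflections are handled upstream by
    wing-side normalization).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac /= np.sqrt((ac**2).sum())
    bc /= np.sqrt((bc**2).sum())
    r = _optimal_rotation(bc, ac)
    return float(np.sqrt(((bc @ r - ac) ** 2).sum()))


def gpa_align(
    dataset: ShapeDataset | np.ndarray,
    tol: float = 1e-14,
    max_iter: int = 1000,
) -> ProcrustesResult:
    """Generalized Procrustes analysis.

    Configurations are centred and scaled to unit centroid size, then
    iteratively rotated to the running consensus (arithmetic mean shape,
    renormalized to unit size) until the consensus moves by less than
    ``tol`` (root-sum-of-squares) or ``max_iter`` is reached.
    """
    if isinstance(dataset, ShapeDataset):
        arr = dataset.array
        ids, sites = dataset.ids, dataset.sites
    else:
        arr = np.asarray(dataset, float)
        ids = [str(i) for i in range(arr.shape[0])]
        sites = [""] * arr.shape[0]
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    centred = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if (sizes == 0).any():
        bad = ids[int(np.argmin(sizes))]
        raise DegenerateConfigurationError(f"specimen {bad!r} is degenerate")
    scaled = centred / sizes[:, None, None]

    consensus = scaled[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    aligned = scaled.copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )
    # canonical orientation: consensus on its principal axes, first landmark
    # on the positive x half-plane — makes the result independent of which
    # configuration seeded the iteration (and GPA exactly idempotent)
    evals_c, vecs = np.linalg.eigh(consensus.T @ consensus)
    vecs = vecs[:, ::-1]  # major axis first
    if np.linalg.det(vecs) < 0:
        vecs[:, 1] *= -1.0
    consensus = consensus @ vecs
    aligned = aligned @ vecs
    if consensus[0, 0] < 0:
        consensus = -consensus
        aligned = -aligned
    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        ids=ids,
        sites=sites,
        n_iterations=n_it,
    )


@dataclass
class AllometryResult:
    pct_shape_explained: float
    p_value: float
    coefficients: np.ndarray  # (2k,) slope of shape on centroid size
    fitted: np.ndarray  # (n, 2k), includes the mean shape
    residuals: np.ndarray  # (n, 2k); fitted + residuals == input
    n_perm: int


def allometric_regression(
    result: ProcrustesResult,
    n_perm: int = 10_000,
    seed: int | None = 0,
    sizes: np.ndarray | None = None,
) -> AllometryResult:
    """Multivariate regression of the shape variables on centroid size.

    The share of shape variance explained is 100 * SS(fitted)/SS(total),
    both taken about the mean shape.  The permutation test shuffles centroid
    sizes against shapes (null hypothesis of size/shape independence); the
    p-value is (exceedances + 1)/(n_perm + 1).
    """
    y = result.flat
    x = np.asarray(result.centroid_sizes if sizes is None else sizes, float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens")
    if np.ptp(x) == 0:
        raise ValueError("centroid size is constant; regression undefined")
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    beta = (xc @ yc) / (xc @ xc)  # (2k,)
    fitted_c = np.outer(xc, beta)
    ss_total = float((yc**2).sum())
    ss_fit = float((fitted_c**2).sum())
    pct = 100.0 * ss_fit / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = rng.permutation(xc)
        bp = (xp @ yc) / (xp @ xp)
        ss_p = float((xp**2).sum() * (bp**2).sum())
        if ss_p >= ss_fit:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    fitted = fitted_c + y.mean(axis=0)
    return AllometryResult(
        pct_shape_explained=pct,
        p_value=p,
        coefficients=beta,
        fitted=fitted,
        residuals=y - fitted,
        n_perm=n_perm,
    )


@dataclass
class CVAResult:
    groups: list[str]
    scores: np.ndarray  # (n, n_cv)
    pct_variance: np.ndarray  # (n_cv,) sums to 100
    mahalanobis: pd.DataFrame
    procrustes_group: pd.DataFrame
    p_mahalanobis: pd.DataFrame
    p_procrustes: pd.DataFrame
    group_labels: np.ndarray = field(repr=False, default=None)


def _pca_reduce(y: np.ndarray, rel_tol: float = 1e-12, max_rank: int | None = None):
    """Project onto principal components carrying > rel_tol relative variance."""
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    var = s**2
    keep = var > rel_tol * var.max()
    if max_rank is not None:
        keep &= np.arange(len(s)) < max_rank
    basis = vt[keep].T  # (p, r)
    return yc @ basis, basis


def _group_stats(z: np.ndarray, labels: np.ndarray, groups: list[str]):
    means = np.stack([z[labels == g].mean(axis=0) for g in groups])
    n = z.shape[0]
    g = len(groups)
    w = np.zeros((z.shape[1], z.shape[1]))
    for k, grp in enumerate(groups):
        d = z[labels == grp] - means[k]
        w += d.T @ d
    w /= n - g
    return means, w


def _pairwise_distances(z, labels, groups, w_inv):
    g = len(groups)
    means = np.stack([z[labels == grp].mean(axis=0) for grp in groups])
    maha = np.zeros((g, g))
    proc = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = means[i] - means[j]
            maha[i, j] = maha[j, i] = np.sqrt(d @ w_inv @ d)
            proc[i, j] = proc[j, i] = np.linalg.norm(d)
    return maha, proc


def cva(
    residual_shapes: np.ndarray,
    groups: list[str] | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> CVAResult:
    """Canonical variate analysis with permutation tests on group distances.

    The shape variables are first projected onto principal components with
    non-negligible variance (rank <= n - g enforced) so the pooled
    within-group covariance W is invertible.  Canonical variates are the
    eigenvectors of W^{-1} B; Mahalanobis distances between group means use
    the pooled within-group metric, and the "Procrustes" group distance is
    the Euclidean distance between group mean shapes in the aligned shape
    space.  Permutation p-values reallocate specimens to groups with group
    sizes preserved, p = (b + 1)/(m + 1).
    """
    y = np.asarray(residual_shapes, float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    g = len(names)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = {grp: int((labels == grp).sum()) for grp in names}
    small = [grp for grp, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 specimens: {small}")
    n = y.shape[0]

    z, _ = _pca_reduce(y, max_rank=n - g)
    means, w = _group_stats(z, labels, names)
    cond = np.linalg.cond(w)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular after reduction"
        )
    w_inv = np.linalg.inv(w)

    grand = z.mean(axis=0)
    b = np.zeros_like(w)
    for k, grp in enumerate(names):
        d = (means[k] - grand)[:, None]
        b += counts[grp] * (d @ d.T)
    b /= g - 1

    # eigen-decomposition of W^{-1} B via the symmetric whitened form
    wh_vals, wh_vecs = np.linalg.eigh(w)
    wh_vals = np.clip(wh_vals, 1e-300, None)
    w_isqrt = wh_vecs @ np.diag(wh_vals**-0.5) @ wh_vecs.T
    m_sym = w_isqrt @ b @ w_isqrt
    evals, evecs = np.linalg.eigh(m_sym)
    order = np.argsort(evals)[::-1]
    n_cv = min(g - 1, z.shape[1])
    evals = np.clip(evals[order][:n_cv], 0.0, None)
    axes = (w_isqrt @ evecs[:, order][:, :n_cv])  # scores have unit within-group var
    scores = (z - grand) @ axes
    pct = 100.0 * evals / evals.sum() if evals.sum() > 0 else np.full(n_cv, np.nan)

    maha_obs, proc_obs = _pairwise_distances(z, labels, names, w_inv)

    rng = np.random.default_rng(seed)
    b_maha = np.zeros_like(maha_obs)
    b_proc = np.zeros_like(proc_obs)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, w_p = _group_stats(z, perm, names)
        try:
            w_p_inv = np.linalg.inv(w_p)
        except np.linalg.LinAlgError:
            continue
        maha_p, proc_p = _pairwise_distances(z, perm, names, w_p_inv)
        b_maha += maha_p >= maha_obs
        b_proc += proc_p >= proc_obs
    p_maha = (b_maha + 1) / (n_perm + 1)
    p_proc = (b_proc + 1) / (n_perm + 1)
    np.fill_diagonal(p_maha, np.nan)
    np.fill_diagonal(p_proc, np.nan)

    def _df(m):
        return pd.DataFrame(m, index=names, columns=names)

    return CVAResult(
        groups=names,
        scores=scores,
        pct_variance=pct,
        mahalanobis=_df(maha_obs),
        procrustes_group=_df(proc_obs),
        p_mahalanobis=_df(p_maha),
        p_procrustes=_df(p_proc),
        group_labels=labels,
    )


def centroid_size_anova(sizes, groups) -> dict:
    """One-way ANOVA on centroid size over sites, with Tukey HSD post hoc."""
    sizes = np.asarray(sizes, float)
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [sizes[labels == g] for g in names]
    if any(len(s) < 2 for s in samples):
        bad = [g for g, s in zip(names, samples) if len(s) < 2]
        raise ValueError(f"groups of size 1: {bad}")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        warnings.warn("all values identical; ANOVA degenerate (F reported as 0)")
        return {
            "F": 0.0,
            "df": (len(names) - 1, len(sizes) - len(names)),
            "p": 1.0,
            "tukey_pairs": pd.DataFrame(
                columns=["group_a", "group_b", "diff", "p_adj", "significant"]
            ),
        }
    f, p = stats.f_oneway(*samples)
    tuk = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_adj": float(tuk.pvalue[i, j]),
                    "significant": bool(tuk.pvalue[i, j] < 0.05),
                }
            )
    return {
        "F": float(f),
        "df": (len(names) - 1, len(sizes) - len(names)),
        "p": float(p),
        "tukey_pairs": pd.DataFrame(rows),
    }
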