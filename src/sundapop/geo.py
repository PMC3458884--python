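"""Geographic distances, isolation-by-distance regression and MDS ordination.

Two geographic distance modes are supported for testing competing dispersal
hypotheses around the South China Sea:

``euclidean``
    great-circle (haversine) distance, the shortest possible separation of two
    sampling sites, with no biogeographic assumptions;
``path``
    an ordered "land-arc" distance: sites are placed on a one-dimensional
    path (mainland Asia, down the Thai/Malay peninsula, through the
    archipelago and up to the Philippines) and the distance between two sites
    is the sum of the consecutive great-circle legs separating them along
    that path.  This emulates dispersal constrained to the land margin of the
    South China Sea / exposed Sunda shelf.

Isolation by distance is quantified by ordinary least squares on the
site-pair distances (Pearson r, r^2) plus a Mantel permutation test, which is
the appropriate inferential tool given the non-independence of pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import skbio

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "SiteTable",
    "GeoDistanceMatrix",
    "IBDResult",
    "MDSResult",
    "parse_dms",
    "format_dms",
    "haversine_km",
    "geo_matrix",
    "path_distance_km",
    "ibd_regression",
    "mds_embed",
]

_DMS_RE = re.compile(
    r"""^\s*(\d+)\s*[°d:\s]\s*(\d+)\s*['m:\s]\s*(\d+(?:\.\d+)?)\s*["s]*\s*([NSEW])\s*$""",
    re.VERBOSE,
)


def parse_dms(value: str | float) -> float:
    """Convert a DMS string like ``25°00'53"N`` to signed decimal degrees.

    Decimal input (float or numeric string) is passed through unchanged.
    """
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().replace("''", '"').replace("’", "'").replace("”", '"')
    try:
        return float(s)
    except ValueError:
        pass
    m = _DMS_RE.match(s)
    if m is None:
        raise ValueError(f"cannot parse coordinate {value!r}")
    deg, minute, sec, hemi = m.groups()
    dec = int(deg) + int(minute) / 60.0 + float(sec) / 3600.0
    if hemi in "SW":
        dec = -dec
    return dec


def format_dms(decimal: float, kind: str = "lat") -> str:
    """Format decimal degrees back to a ``DD°MM'SS"H`` string (integer seconds)."""
    if kind == "lat":
        hemi = "N" if decimal >= 0 else "S"
    elif kind == "lon":
        hemi = "E" if decimal >= 0 else "W"
    else:
        raise ValueError("kind must be 'lat' or 'lon'")
    v = abs(decimal)
    deg = int(v)
    rem = (v - deg) * 60.0
    minute = int(rem)
    sec = round((rem - minute) * 60.0)
    if sec == 60:  # carry from float rounding
        sec = 0
        minute += 1
    if minute == 60:
        minute = 0
        deg += 1
    return f"{deg}°{minute:02d}'{sec:02d}\"{hemi}"


@dataclass
class SiteTable:
    """Sampling sites with coordinates and optional metadata.

    Parameters
    ----------
    frame
        DataFrame with at least columns ``site``, ``lat``, ``lon`` (decimal
        degrees; DMS strings are converted on construction).  Any extra
        columns (taxon labels, sample sizes) are carried along untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col, kind in (("lat", "lat"), ("lon", "lon")):
            if col not in df.columns:
                raise ValueError(f"site table missing column {col!r}")
            df[col] = [parse_dms(v) for v in df[col]]
        if df["site"].duplicated().any():
            dupes = df.loc[df["site"].duplicated(), "site"].tolist()
            raise ValueError(f"duplicate site names: {dupes}")
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            raise ValueError("coordinates out of range")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SiteTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"site": str}))

    @property
    def sites(self) -> list[str]:
        return list(self.frame["site"])

    def coords(self, site: str) -> tuple[float, float]:
        row = self.frame.loc[self.frame["site"] == site]
        if row.empty:
            raise KeyError(f"unknown site {site!r}")
        return float(row["lat"].iloc[0]), float(row["lon"].iloc[0])

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, site: str) -> bool:
        return site in set(self.frame["site"])


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"coordinates out of range: {(lat, lon)}")
    la1, lo1, la2, lo2 = map(np.radians, (*a, *b))
    h = np.sin((la2 - la1) / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(
        (lo2 - lo1) / 2.0
    ) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


@dataclass
class GeoDistanceMatrix:
    """Symmetric site-by-site distance matrix in km."""

    mode: str  # "euclidean" | "path"
    sites: list[str]
    values: np.ndarray
    path_order: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.sites)

    def submatrix(self, sites: list[str]) -> np.ndarray:
        idx = [self.sites.index(s) for s in sites]
        return self.values[np.ix_(idx, idx)]


def geo_matrix(
    sites: SiteTable,
    mode: str = "euclidean",
    path_order: list[str] | None = None,
) -> GeoDistanceMatrix:
    """Pairwise geographic distances between all sites, in km.

    In ``path`` mode every site must occur exactly once in ``path_order`` and
    the distance between two sites is the sum of consecutive great-circle
    legs between them along the ordered arc (additive along the path).
    """
    names = sites.sites
    g = len(names)
    out = np.zeros((g, g))
    if mode == "euclidean":
        for i in range(g):
            for j in range(i + 1, g):
                d = haversine_km(sites.coords(names[i]), sites.coords(names[j]))
                out[i, j] = out[j, i] = d
        return GeoDistanceMatrix("euclidean", names, out)
    if mode != "path":
        raise ValueError(f"unknown mode {mode!r}")
    if path_order is None:
        raise ValueError("path mode requires path_order")
    if sorted(path_order) != sorted(names):
        missing = set(names) - set(path_order)
        extra = set(path_order) - set(names)
        raise ValueError(
            f"path_order must list every site exactly once "
            f"(missing={sorted(missing)}, unknown={sorted(extra)})"
        )
    legs = np.array(
        [
            haversine_km(sites.coords(a), sites.coords(b))
            for a, b in zip(path_order[:-1], path_order[1:])
        ]
    )
    cum = np.concatenate([[0.0], np.cumsum(legs)])
    pos = {s: cum[k] for k, s in enumerate(path_order)}
    for i in range(g):
        for j in range(g):
            out[i, j] = abs(pos[names[i]] - pos[names[j]])
    return GeoDistanceMatrix("path", names, out, path_order=list(path_order))


def path_distance_km(
    sites: SiteTable,
    path_order: list[str],
    start: str,
    end: str,
    skip_legs: list[tuple[str, str]] | None = None,
) -> float:
    """Along-path distance from ``start`` to ``end``, optionally dropping legs.

    ``skip_legs`` names consecutive (a, b) pairs of ``path_order`` whose leg
    length is excluded from the sum — used when two neighbouring sites are to
    be treated as a single stop on the arc.
    """
    i, j = path_order.index(start), path_order.index(end)
    if i > j:
        i, j = j, i
    skip = {frozenset(p) for p in (skip_legs or [])}
    total = 0.0
    for a, b in zip(path_order[i:j], path_order[i + 1 : j + 1]):
        if frozenset((a, b)) in skip:
            continue
        total += haversine_km(sites.coords(a), sites.coords(b))
    return total


@dataclass
class IBDResult:
    """Isolation-by-distance regression over the g(g-1)/2 site pairs."""

    pearson_r: float
    slope: float
    intercept: float
    p_ols: float
    n_pairs: int
    p_mantel: float | None = None
    r_squared: float = field(init=False)

    def __post_init__(self) -> None:
        # r^2 is derived, never stored independently: the two can never drift apart
        self.r_squared = self.pearson_r**2


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return np.asarray(m)[i, j]


def ibd_regression(
    dist: np.ndarray,
    geo: GeoDistanceMatrix | np.ndarray,
    sites: list[str] | None = None,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> IBDResult:
    """Regress a genetic/morphometric distance matrix on geographic distance.

    OLS on the lower-triangle pairs gives the Pearson r, r^2 and the naive
    parametric p-value; because site pairs are not independent a Mantel
    permutation p-value (site labels of one matrix permuted) is also
    reported and is the one to trust.
    """
    if isinstance(geo, GeoDistanceMatrix):
        gvals = geo.submatrix(sites) if sites is not None else geo.values
    else:
        gvals = np.asarray(geo, float)
    dist = np.asarray(dist, float)
    if dist.shape != gvals.shape or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrices must be square and congruent")
    g = dist.shape[0]
    if g < 4:
        raise ValueError("need at least 4 sites for an IBD regression")
    x = _lower_triangle(gvals)
    y = _lower_triangle(dist)
    if np.ptp(x) == 0:
        raise ValueError("constant geographic predictor")
    fit = stats.linregress(x, y)
    p_mantel = None
    if n_perm and n_perm > 0:
        dm_y = skbio.DistanceMatrix(_symmetrize(dist))
        dm_x = skbio.DistanceMatrix(_symmetrize(gvals))
        _, p_mantel, _ = skbio.stats.distance.mantel(
            dm_y, dm_x, method="pearson", permutations=n_perm, alternative="two-sided",
            seed=seed,
        )
        p_mantel = float(p_mantel)
    return IBDResult(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_ols=float(fit.pvalue),
        n_pairs=len(x),
        p_mantel=p_mantel,
    )


def _symmetrize(m: np.ndarray) -> np.ndarray:
    m = np.array(m, float)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    # Mantel only needs a hollow symmetric matrix; negative entries (possible
    # for Phi_ST estimates) are legal for the correlation but not for the
    # skbio container, so shift is avoided by clamping at 0 here.
    m[m < 0] = 0.0
    return m


@dataclass
class MDSResult:
    coordinates: np.ndarray  # (g, 2)
    stress: float
    stress_history: list[float]
    sites: list[str] | None = None


def mds_embed(
    dist: np.ndarray,
    sites: list[str] | None = None,
    n_iter: int = 300,
    tol: float = 1e-12,
) -> MDSResult:
    """Two-dimensional metric MDS of a (genetic) distance matrix.

    Classical Torgerson scaling provides the start configuration; SMACOF
    (Guttman-transform majorization) then minimizes the raw stress
    ``sum((d_ij - delta_ij)^2)``, which is non-increasing per iteration.
    Negative input entries (possible for Phi_ST estimates) are clamped to 0.
    """
    d = np.asarray(dist, float).copy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("MDS requires a symmetric square matrix")
    if (d < 0).any():
        d[d < 0] = 0.0
    np.fill_diagonal(d, 0.0)
    g = d.shape[0]
    # Torgerson: double-centre the squared distances
    j = np.eye(g) - np.ones((g, g)) / g
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    lam = np.clip(w[order], 0.0, None)
    x = v[:, order] * np.sqrt(lam)

    def _stress(conf: np.ndarray) -> float:
        dd = np.linalg.norm(conf[:, None, :] - conf[None, :, :], axis=-1)
        iu = np.triu_indices(g, k=1)
        return float(((dd[iu] - d[iu]) ** 2).sum())

    history = [_stress(x)]
    for _ in range(n_iter):
        dd = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dd > 0, d / dd, 0.0)
        bmat = -ratio
        np.fill_diagonal(bmat, 0.0)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x_new = bmat @ x / g
        s_new = _stress(x_new)
        history.append(s_new)
        if history[-2] - s_new < tol:
            x = x_new
            break
        x = x_new
    return MDSResult(coordinates=x, stress=history[-1], stress_history=history, sites=sites)
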