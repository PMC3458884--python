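"""Synthetic sequence and wing-landmark datasets with the statistical
structure the analysis pipeline assumes.

``simulate_sequences`` draws COI-like alignments from a structured coalescent
on a linear (stepping-stone) habitat: the sampled sites lie on an ordered
arc, migration occurs between path-adjacent demes only, and an optional
instantaneous expansion in the recent past produces the star-like,
singleton-enriched genealogies that give negative Tajima's D / Fu's FS.
Genealogies come from msprime; infinite-sites mutations (HKY-style kinetics
with a strong transition bias, as in insect mtDNA) are mapped onto discrete
positions of a fixed-length sequence, collisions re-drawn, so outputs are
plain equal-length FASTA.

``simulate_wings`` draws 15-landmark configurations per specimen:
a fixed template plus a clinal mean-shape displacement proportional to the
site's along-path position, an allometric shape component proportional to
centroid-size deviation, and isotropic landmark noise.  About 10% of
specimens are flagged as left wings (stored reflected, as digitised).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .geo import SiteTable, geo_matrix
from .morphometry import LandmarkConfiguration, N_LANDMARKS, ShapeDataset
from .popgen.alignment import SequenceAlignment

__all__ = [
    "SeqSimConfig",
    "ShapeSimConfig",
    "simulate_sequences",
    "simulate_wings",
    "WING_TEMPLATE",
]

#: COI-like equilibrium base frequencies (A, C, G, T); insect mtDNA is AT-rich.
BASE_FREQS = np.array([0.31, 0.16, 0.14, 0.39])

#: Idealized right-wing landmark template (vein intersections / terminations),
#: arbitrary image units, non-degenerate and roughly wing-proportioned.
WING_TEMPLATE = np.array(
    [
        [0.00, 0.45],
        [0.35, 0.80],
        [0.90, 1.00],
        [1.80, 1.05],
        [2.90, 0.95],
        [3.80, 0.70],
        [4.20, 0.40],
        [3.90, 0.05],
        [3.10, -0.20],
        [2.20, -0.30],
        [1.30, -0.25],
        [0.60, -0.10],
        [1.60, 0.40],
        [2.50, 0.35],
        [3.20, 0.25],
    ]
)


@dataclass
class SeqSimConfig:
    """Stepping-stone coalescent parameters for the sequence simulator.

    ``theta`` is the per-deme scaled mutation rate for the whole locus
    (2 * N_deme * mu_locus, haploid mtDNA); ``migration`` the per-lineage
    per-generation migration rate between path-adjacent demes; ``growth``
    the factor by which each deme expanded at ``expansion_time`` (in units
    of the deme size N, coalescent time) before the present.  Defaults
    emulate the study design: nine sites on the arc, 12-22 sequences per
    site, haplotype-rich data with a recent-expansion signature.
    """

    #: per-site sample sizes follow the *path order* of the sites
    #: (default: the nine-site arc, total 156 sequences)
    n_sites: int = 9
    samples_per_site: tuple[int, ...] = (19, 19, 19, 12, 20, 22, 15, 13, 17)
    theta: float = 20.0
    migration: float = 2.0
    seq_length: int = 642
    growth: float = 100.0
    expansion_time: float = 0.1
    kappa: float = 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.samples_per_site, int):
            self.samples_per_site = (self.samples_per_site,) * self.n_sites
        self.samples_per_site = tuple(self.samples_per_site)
        if len(self.samples_per_site) != self.n_sites:
            raise ValueError("samples_per_site length must equal n_sites")
        if any(s < 2 for s in self.samples_per_site):
            raise ValueError("each site needs at least 2 samples")
        if self.theta <= 0 or self.migration < 0 or self.growth < 1:
            raise ValueError("rates must be non-negative (theta > 0, growth >= 1)")


def simulate_sequences(
    cfg: SeqSimConfig, site_names: list[str] | None = None
) -> SequenceAlignment:
    """Simulate an aligned sample under the linear stepping-stone coalescent."""
    if site_names is None:
        site_names = [f"site{i + 1}" for i in range(cfg.n_sites)]
    if len(site_names) != cfg.n_sites:
        raise ValueError("site_names length must equal n_sites")
    rng = np.random.default_rng(cfg.seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))

    # Haploid demes of size N = theta/2 and locus mutation rate 1 give
    # E[pairwise differences within a deme] = theta (no structure, no growth).
    n_deme = cfg.theta / 2.0
    demography = msprime.Demography()
    for name in site_names:
        demography.add_population(name=_safe(name), initial_size=n_deme)
    for a, b in zip(site_names[:-1], site_names[1:]):
        demography.set_symmetric_migration_rate(
            [_safe(a), _safe(b)], cfg.migration
        )
    if cfg.growth > 1:
        for name in site_names:
            demography.add_population_parameters_change(
                time=cfg.expansion_time * n_deme,
                initial_size=n_deme / cfg.growth,
                population=_safe(name),
            )
    if cfg.migration == 0 and cfg.n_sites > 1:
        # fully isolated demes would never find a common ancestor; model the
        # isolation as deep structure with ancient panmixia instead
        demography.add_migration_rate_change(time=50.0 * n_deme, rate=1.0)
    demography.sort_events()
    ts = msprime.sim_ancestry(
        samples={_safe(s): n for s, n in zip(site_names, cfg.samples_per_site)},
        demography=demography,
        ploidy=1,
        sequence_length=cfg.seq_length,
        discrete_genome=False,
        random_seed=ms_seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=1.0 / cfg.seq_length,
        model=msprime.HKY(kappa=cfg.kappa, equilibrium_frequencies=BASE_FREQS),
        discrete_genome=False,
        random_seed=mut_seed,
    )

    n_total = sum(cfg.samples_per_site)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=cfg.seq_length, p=BASE_FREQS)
    columns = np.tile(seq[:, None], (1, n_total))  # (L, n)
    used: set[int] = set()
    for var in mts.variants():
        pos = int(var.site.position)
        if pos in used:  # infinite-sites collision: re-draw uniformly
            free = np.array(sorted(set(range(cfg.seq_length)) - used))
            pos = int(rng.choice(free))
        used.add(pos)
        alleles = np.array(var.alleles)
        columns[pos] = alleles[var.genotypes]
    seqs = ["".join(columns[:, i]) for i in range(n_total)]

    ids, pops = [], []
    k = 0
    for name, n_s in zip(site_names, cfg.samples_per_site):
        for i in range(n_s):
            ids.append(f"{_safe(name)}_{i + 1:02d}")
            pops.append(name)
            k += 1
    return SequenceAlignment(seqs, ids, pops)


def _safe(name: str) -> str:
    return name.replace(" ", "_").replace("/", "_")


@dataclass
class ShapeSimConfig:
    """Wing-landmark simulator parameters.

    ``displacement_scale`` shifts the site mean shape per km of along-path
    position (unit-shape space); ``allometry_coeff`` is the shape change per
    unit of centroid-size deviation from the grand mean.  Defaults put about
    5% of shape variance in the allometric component and produce a strong
    shape-vs-path-distance cline; sizes emulate wings of centroid size
    ~6 +/- 0.35 image units with isotropic digitising noise.
    """

    mean_shape: np.ndarray = field(default_factory=lambda: WING_TEMPLATE.copy())
    displacement_scale: float = 1.2e-5
    allometry_coeff: float = 0.04
    size_mean: float = 6.0
    size_sd: float = 0.35
    noise_sd: float = 0.01
    left_fraction: float = 0.10
    #: per-site sample sizes follow the path order (nine-site arc, total 169)
    samples_per_site: tuple[int, ...] | int = (20, 20, 20, 20, 20, 20, 14, 15, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, float)
        if self.mean_shape.shape != (N_LANDMARKS, 2):
            raise ValueError(f"mean_shape must be ({N_LANDMARKS}, 2)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _unit_directions(k: int = N_LANDMARKS) -> tuple[np.ndarray, np.ndarray]:
    """Two fixed, centred, orthonormal shape-direction vectors (2k,)."""
    gen = np.random.default_rng(20120730)  # fixed: directions are constants
    u = gen.standard_normal((k, 2))
    v = gen.standard_normal((k, 2))
    u -= u.mean(axis=0)
    u = u.ravel()
    u /= np.linalg.norm(u)
    v -= v.mean(axis=0)
    v = v.ravel()
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    return u, v


def simulate_wings(
    cfg: ShapeSimConfig,
    sites: SiteTable,
    path_order: list[str],
) -> ShapeDataset:
    """Simulate landmark configurations for every site along the path.

    Specimen shape (unit-shape space, template normalized to unit centroid
    size) = template + displacement_scale * (along-path km) * U
    + allometry_coeff * (size - size_mean) * V + N(0, noise_sd^2) noise,
    with U, V fixed orthonormal directions; raw coordinates are the shape
    scaled by the specimen's centroid size.  Left-flagged specimens are
    reflected (as they would be digitised) and carry ``side='left'``.
    """
    rng = np.random.default_rng(cfg.seed)
    u, v = _unit_directions()
    template = cfg.mean_shape - cfg.mean_shape.mean(axis=0)
    template = template / np.sqrt((template**2).sum())

    gm = geo_matrix(sites, mode="path", path_order=path_order)
    first = path_order[0]
    positions = {s: gm.to_frame().loc[first, s] for s in path_order}

    per_site = cfg.samples_per_site
    if isinstance(per_site, int):
        per_site = (per_site,) * len(path_order)
    if len(per_site) != len(path_order):
        raise ValueError("samples_per_site length must match path_order")

    configs = []
    for name, n_s in zip(path_order, per_site):
        pos = positions[name]
        for i in range(n_s):
            size = rng.normal(cfg.size_mean, cfg.size_sd)
            shape = (
                template.ravel()
                + cfg.displacement_scale * pos * u
                + cfg.allometry_coeff * (size - cfg.size_mean) * v
                + rng.normal(0.0, cfg.noise_sd, 2 * N_LANDMARKS)
            ).reshape(N_LANDMARKS, 2)
            coords = size * shape
            # stored coordinates are always right-wing orientation; the side
            # flag drives re-reflection when writing TPS (file orientation)
            side = "left" if rng.random() < cfg.left_fraction else "right"
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{_safe(name)}_w{i + 1:02d}",
                    site=name,
                    side=side,
                    coords=coords,
                )
            )
    return ShapeDataset(configs)


def expected_allometry_pct(cfg: ShapeSimConfig, positions_km: np.ndarray,
                           per_site: np.ndarray) -> float:
    """Closed-form expectation of the allometric share of shape variance.

    Shape variance decomposes into the allometric component
    a^2 Var(size), the clinal component d^2 Var(position) and the noise
    floor noise_sd^2 * (2k - 4) (four degrees of freedom are consumed by
    the Procrustes alignment).
    """
    a2 = cfg.allometry_coeff**2 * cfg.size_sd**2
    w = per_site / per_site.sum()
    pos_var = float(np.average((positions_km - np.average(positions_km, weights=w)) ** 2,
                               weights=w))
    d2 = cfg.displacement_scale**2 * pos_var
    noise = cfg.noise_sd**2 * (2 * N_LANDMARKS - 4)
    return 100.0 * a2 / (a2 + d2 + noise)
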