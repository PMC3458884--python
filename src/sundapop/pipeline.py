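"""Pipeline orchestration: configuration, stage sequencing, report assembly.

A run is described by a :class:`RunConfig` (optionally loaded from YAML).
``run_morphometrics`` executes read → GPA → centroid-size ANOVA → allometric
regression → CVA → IBD (both geographic modes); ``run_genetics`` executes
read → haplotype collapse → per-site and total diversity/neutrality →
pairwise Phi_ST → hierarchical AMOVA → mismatch distribution →
median-joining network → MDS → IBD (both modes).  Every stage writes a CSV
(or GraphML) into the output directory and is recorded, with parameters,
seeds, wall time, warnings and output checksums, in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, geo, morphometry, network, popgen
from .datasets import MDS_GROUPS, SUNDALAND_ARC, study_sites

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "run_morphometrics", "run_genetics", "run_all"]

DEFAULT_PERMUTATIONS = {
    "allometry": 10_000,
    "cva": 1000,
    "phist": 1000,
    "amova": 1000,
    "mantel": 999,
    "neutrality": 1000,
}


@dataclass
class RunConfig:
    output_dir: str = "sundapop_out"
    seed: int = 0
    fasta: str | None = None
    pop_map: str | None = None
    tps: str | None = None
    site_map: str | None = None
    site_table: str | None = None  # TSV; None -> built-in nine-site design
    path_order: list[str] = field(default_factory=lambda: list(SUNDALAND_ARC))
    groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in MDS_GROUPS.items()}
    )
    permutations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PERMUTATIONS)
    )

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PERMUTATIONS)
        merged.update(self.permutations)
        self.permutations = merged
        bad = {k: v for k, v in self.permutations.items() if v < 99}
        if bad:
            raise ValueError(f"permutation counts must be >= 99: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sites(self) -> geo.SiteTable:
        if self.site_table is None:
            return study_sites()
        return geo.SiteTable.from_tsv(self.site_table)

    def require(self, *attrs: str) -> None:
        missing = [a for a in attrs if getattr(self, a) is None]
        if missing:
            raise FileNotFoundError(f"configuration missing inputs: {missing}")
        for a in attrs:
            p = Path(getattr(self, a))
            if not p.exists():
                raise FileNotFoundError(f"{a} path does not exist: {p}")


@dataclass
class Report:
    output_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def add(self, stage: str, name: str, path: Path) -> None:
        self.tables[name] = path
        self.manifest.setdefault("outputs", {})[name] = {
            "stage": stage,
            "path": str(path.relative_to(self.output_dir)),
            "sha256": _sha256(path),
        }

    def write_manifest(self) -> Path:
        out = self.output_dir / "manifest.json"
        with open(out, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageTimer:
    def __init__(self, report: Report, stage: str):
        self.report = report
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.caught: list[str] = []
        self._ctx = warnings.catch_warnings(record=True)
        self._records = self._ctx.__enter__()
        warnings.simplefilter("always")
        logger.info("stage %s: start", self.stage)
        return self

    def __exit__(self, exc_type, exc, tb):
        wall = time.perf_counter() - self.t0
        msgs = [str(w.message) for w in self._records]
        self._ctx.__exit__(None, None, None)
        stages = self.report.manifest.setdefault("stages", {})
        stages[self.stage] = {"wall_s": round(wall, 3), "warnings": msgs}
        if exc is not None:
            stages[self.stage]["error"] = repr(exc)
            raise RuntimeError(f"stage {self.stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.stage, wall)
        return False


def _init_report(cfg: RunConfig) -> Report:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(output_dir=out)
    report.manifest["version"] = __version__
    report.manifest["seed"] = cfg.seed
    report.manifest["permutations"] = cfg.permutations
    report.manifest["path_order"] = cfg.path_order
    report.manifest["groups"] = cfg.groups
    inputs = {}
    for a in ("fasta", "pop_map", "tps", "site_map", "site_table"):
        p = getattr(cfg, a)
        if p is not None and Path(p).exists():
            inputs[a] = {"path": str(p), "sha256": _sha256(Path(p))}
    report.manifest["inputs"] = inputs
    return report


def _geo_pair(cfg: RunConfig, sites: geo.SiteTable):
    g_euc = geo.geo_matrix(sites, mode="euclidean")
    g_path = geo.geo_matrix(sites, mode="path", path_order=cfg.path_order)
    return g_euc, g_path


def _ibd_rows(dist_df: pd.DataFrame, cfg: RunConfig, sites: geo.SiteTable,
              marker: str) -> pd.DataFrame:
    rows = []
    names = list(dist_df.index)
    for mode, gm in zip(("euclidean", "path"), _geo_pair(cfg, sites)):
        res = geo.ibd_regression(
            dist_df.to_numpy(),
            gm,
            sites=names,
            n_perm=cfg.permutations["mantel"],
            seed=cfg.seed,
        )
        rows.append(
            {
                "marker": marker,
                "geo_mode": mode,
                "pearson_r": res.pearson_r,
                "r_squared": res.r_squared,
                "p_ols": res.p_ols,
                "p_mantel": res.p_mantel,
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows)


def run_morphometrics(cfg: RunConfig, report: Report | None = None) -> Report:
    """Wing-shape stages: sizes, GPA, allometry, CVA, IBD."""
    cfg.require("tps", "site_map")
    report = report or _init_report(cfg)
    out = report.output_dir
    sites = cfg.sites()

    with _StageTimer(report, "read_tps"):
        dataset = morphometry.read_tps(cfg.tps, cfg.site_map)
        unknown = sorted(set(dataset.sites) - set(sites.sites))
        if unknown:
            raise KeyError(f"site map references unknown sites: {unknown}")

    with _StageTimer(report, "gpa"):
        gpa = morphometry.gpa_align(dataset)

    with _StageTimer(report, "centroid_size_anova"):
        anova = morphometry.centroid_size_anova(gpa.centroid_sizes, gpa.sites)
        sizes = pd.DataFrame(
            {"specimen_id": gpa.ids, "site": gpa.sites,
             "centroid_size": gpa.centroid_sizes}
        )
        p = out / "centroid_sizes.csv"
        sizes.to_csv(p, index=False)
        report.add("centroid_size_anova", "centroid_sizes", p)
        p = out / "centroid_size_anova.csv"
        pd.DataFrame(
            [{"F": anova["F"], "df_between": anova["df"][0],
              "df_within": anova["df"][1], "p": anova["p"]}]
        ).to_csv(p, index=False)
        report.add("centroid_size_anova", "anova", p)
        p = out / "centroid_size_tukey.csv"
        anova["tukey_pairs"].to_csv(p, index=False)
        report.add("centroid_size_anova", "tukey", p)

    with _StageTimer(report, "allometry"):
        allom = morphometry.allometric_regression(
            gpa, n_perm=cfg.permutations["allometry"], seed=cfg.seed
        )
        p = out / "allometry.csv"
        pd.DataFrame(
            [{"pct_shape_explained": allom.pct_shape_explained,
              "p_value": allom.p_value, "n_perm": allom.n_perm}]
        ).to_csv(p, index=False)
        report.add("allometry", "allometry", p)

    with _StageTimer(report, "cva"):
        cva_res = morphometry.cva(
            allom.residuals, gpa.sites,
            n_perm=cfg.permutations["cva"], seed=cfg.seed,
        )
        p = out / "cva_scores.csv"
        score_df = pd.DataFrame(
            cva_res.scores,
            columns=[f"CV{i + 1}" for i in range(cva_res.scores.shape[1])],
        )
        score_df.insert(0, "specimen_id", gpa.ids)
        score_df.insert(1, "site", gpa.sites)
        score_df.to_csv(p, index=False)
        report.add("cva", "cva_scores", p)
        p = out / "cva_pct_variance.csv"
        pd.DataFrame(
            {"cv": [f"CV{i + 1}" for i in range(len(cva_res.pct_variance))],
             "pct_variance": cva_res.pct_variance}
        ).to_csv(p, index=False)
        report.add("cva", "cva_pct_variance", p)
        for name, df in (
            ("mahalanobis", cva_res.mahalanobis),
            ("mahalanobis_p", cva_res.p_mahalanobis),
            ("procrustes_group", cva_res.procrustes_group),
            ("procrustes_group_p", cva_res.p_procrustes),
        ):
            p = out / f"cva_{name}.csv"
            df.to_csv(p)
            report.add("cva", f"cva_{name}", p)

    with _StageTimer(report, "ibd_shape"):
        ibd = _ibd_rows(cva_res.mahalanobis, cfg, sites, marker="mahalanobis")
        p = out / "ibd_shape.csv"
        ibd.to_csv(p, index=False)
        report.add("ibd_shape", "ibd_shape", p)

    report.write_manifest()
    return report


def run_genetics(cfg: RunConfig, report: Report | None = None) -> Report:
    """Sequence stages: haplotypes, diversity, Phi_ST, AMOVA, network, IBD."""
    cfg.require("fasta", "pop_map")
    report = report or _init_report(cfg)
    out = report.output_dir
    sites = cfg.sites()
    nperm = cfg.permutations

    with _StageTimer(report, "read_alignment"):
        aln = popgen.read_alignment(cfg.fasta, cfg.pop_map)
        unknown = sorted(set(aln.populations) - set(sites.sites))
        if unknown:
            raise KeyError(f"population map references unknown sites: {unknown}")
        for gname, members in cfg.groups.items():
            bad = sorted(set(members) - set(sites.sites))
            if bad:
                raise KeyError(f"group {gname!r} references unknown sites: {bad}")

    with _StageTimer(report, "haplotypes"):
        table = popgen.collapse_haplotypes(aln)
        p = out / "haplotype_counts.csv"
        table.counts.to_csv(p)
        report.add("haplotypes", "haplotype_counts", p)

    with _StageTimer(report, "diversity_neutrality"):
        rows = []
        units = [("total", aln)] + [
            (s, aln.subset(s)) for s in aln.population_names
        ]
        for label, sub in units:
            div = popgen.diversity(sub)
            row = {
                "population": label,
                "n": div.n,
                "n_haplotypes": div.n_haplotypes,
                "gene_diversity": div.gene_diversity,
                "gene_diversity_se": div.gene_diversity_se,
                "theta_pi": div.theta_pi,
                "theta_pi_sd": div.theta_pi_sd,
                "segregating_sites": div.segregating_sites,
            }
            try:
                d = popgen.tajimas_d(sub, n_sim=nperm["neutrality"], seed=cfg.seed)
                row.update(tajima_d=d["D"], tajima_p=d["p"])
            except popgen.UndefinedStatisticError:
                row.update(tajima_d=np.nan, tajima_p=np.nan)
            try:
                f = popgen.fus_fs(sub, n_sim=nperm["neutrality"], seed=cfg.seed + 1)
                row.update(fu_fs=f["FS"], fu_p=f["p"])
            except popgen.UndefinedStatisticError:
                row.update(fu_fs=np.nan, fu_p=np.nan)
            rows.append(row)
        p = out / "diversity_neutrality.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        report.add("diversity_neutrality", "diversity_neutrality", p)
        report.manifest["ts_tv_ratio"] = popgen.ts_tv_ratio(aln)

    with _StageTimer(report, "phist"):
        d2 = popgen.tn93_matrix(aln) ** 2
        ph = popgen.pairwise_phist(
            aln, n_perm=nperm["phist"], seed=cfg.seed, d2=d2
        )
        p = out / "phist.csv"
        ph["phist"].to_csv(p)
        report.add("phist", "phist", p)
        p = out / "phist_p.csv"
        ph["p"].to_csv(p)
        report.add("phist", "phist_p", p)

    with _StageTimer(report, "amova"):
        am = popgen.amova(
            aln, cfg.groups, n_perm=nperm["amova"], seed=cfg.seed, d2=d2
        )
        p = out / "amova.csv"
        am.table.to_csv(p, index=False)
        report.add("amova", "amova", p)

    with _StageTimer(report, "mismatch"):
        mm = popgen.mismatch(aln)
        p = out / "mismatch.csv"
        pd.DataFrame(
            {"differences": np.arange(len(mm.histogram)),
             "frequency": mm.histogram}
        ).to_csv(p, index=False)
        report.add("mismatch", "mismatch", p)
        report.manifest["mismatch"] = {
            "raggedness": mm.raggedness, "r2": mm.r2,
            "mean_differences": mm.mean_differences,
        }

    with _StageTimer(report, "network"):
        net = network.median_joining(table)
        p = out / "network.graphml"
        network.write_graphml(net, p)
        report.add("network", "network_graphml", p)
        p = out / "network_edges.csv"
        network.edge_list(net).to_csv(p, index=False)
        report.add("network", "network_edges", p)

    with _StageTimer(report, "mds"):
        mds = geo.mds_embed(
            ph["phist"].to_numpy(), sites=list(ph["phist"].index)
        )
        p = out / "mds_coordinates.csv"
        pd.DataFrame(
            mds.coordinates, columns=["dim1", "dim2"], index=mds.sites
        ).to_csv(p)
        report.add("mds", "mds_coordinates", p)
        report.manifest["mds_stress"] = mds.stress

    with _StageTimer(report, "ibd_genetic"):
        ibd = _ibd_rows(ph["phist"], cfg, sites, marker="phist")
        p = out / "ibd_genetic.csv"
        ibd.to_csv(p, index=False)
        report.add("ibd_genetic", "ibd_genetic", p)

    report.write_manifest()
    return report


def run_all(cfg: RunConfig) -> Report:
    report = _init_report(cfg)
    run_morphometrics(cfg, report=report)
    run_genetics(cfg, report=report)
    return report
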