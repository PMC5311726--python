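"""End-to-end orchestration: simulate -> coverage -> differential ->
regions -> group stats -> qPCR -> figures, from one serializable config,
with a manifest of every output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (
    BinTrack,
    Sample,
    bin_counts,
    background_median_normalize,
    depth_normalize,
    moving_average,
    stranded_coverage,
    weight_reads,
)
from .differential import (
    DependencyCriteria,
    DependencySet,
    SignificanceConfig,
    call_changed_bins,
    call_dependent_regions,
    compute_ratio,
    venn_overlap,
)
from .figures import (
    boxplot,
    coverage_plot,
    scatter_plot,
    smoothed_plot,
    stranded_plot,
    venn_plot,
)
from .qpcr import read_plate_csv, assemble_profile, write_plate_csv, write_profiles_tsv
from .regions import RegionSet
from .regionstats import RegionClassConfig, group_ratio_stats, percentile_regions
from .samio import read_sam, write_sam
from .simulate import (
    ConfigurationError,
    SimulationConfig,
    generate_layout,
    simulate_aligned_reads,
    simulate_qpcr,
    simulate_stranded_premrna,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_full"]

_DEFAULT_QPCR_TRUTH = {
    "WT": {"P0": 0.05, "F1": 0.1, "F2": 0.2, "F3": 0.35},
}


@dataclass
class RunConfig:
    """One serializable description of a full run."""

    seed: int = 0
    outdir: str = "nucrnai_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_replicates: int = 2
    fold: float = 2.0
    alpha: float = 0.05
    max_delta: float = 0.5
    top_percentile: float = 5.0
    background_band: tuple[float, float] = (5.0, 25.0)
    pseudocount: float | None = None
    window: int = 50_000
    qpcr_noise_sd: float = 0.05
    qpcr_truth: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_QPCR_TRUTH.items()})

    def __post_init__(self) -> None:
        self.background_band = tuple(self.background_band)  # type: ignore[assignment]
        self.simulation.seed = self.seed
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    # ------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_band"] = list(self.background_band)
        if math.isinf(self.simulation.dispersion):
            d["simulation"]["dispersion"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if sim.get("dispersion") in ("inf", ".inf", None):
            sim["dispersion"] = math.inf
        d["simulation"] = SimulationConfig(**sim)
        if "background_band" in d:
            d["background_band"] = tuple(d["background_band"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def params_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Outputs, hashes and timings of one pipeline run."""

    outdir: Path
    files: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    params_hash: str = ""
    version: str = __version__
    seed: int = 0

    def add(self, key: str, path: Path) -> Path:
        path = Path(path)
        if not path.exists() or path.stat().st_size == 0:
            raise RuntimeError(f"stage output {key} missing or empty: {path}")
        self.files[key] = {
            "path": str(path),
            "bytes": path.stat().st_size,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
        return path

    def write(self, path: str | Path) -> Path:
        data = {
            "version": self.version,
            "seed": self.seed,
            "params_hash": self.params_hash,
            "timings_s": self.timings,
            "files": self.files,
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))
        return Path(path)


class _Stage:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.timings[self.name] = round(time.perf_counter() - self.t0, 3)
        if exc is not None:
            log.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, self.manifest.timings[self.name])


def _pool(tracks: list[BinTrack]) -> BinTrack:
    """Sum raw replicate tracks into one pooled raw track."""
    pooled = tracks[0].values.copy()
    for t in tracks[1:]:
        pooled += t.values
    return BinTrack(
        layout=tracks[0].layout,
        values=pooled,
        sample=dataclasses.replace(tracks[0].sample, replicate=0),
        normalization_state="raw",
        raw_total=sum(t.raw_total or t.total for t in tracks),
    )


def run_full(config: RunConfig) -> RunManifest:  # noqa: C901
    """Execute every stage in dependency order and return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.setLevel(logging.INFO)
    log.addHandler(fh)
    log.info("run start: seed=%d outdir=%s version=%s", config.seed, out, __version__)
    manifest = RunManifest(outdir=out, params_hash=config.params_hash(), seed=config.seed)

    sim = config.simulation
    genotypes = list(sim.depletion_factors)
    if "WT" not in genotypes:
        raise ConfigurationError("depletion_factors must include a 'WT' genotype")
    mutants = [g for g in genotypes if g != "WT"]

    try:
        # ------------------------------------------------------------ simulate
        with _Stage(manifest, "simulate"):
            layout, truth = generate_layout(sim)
            config.to_yaml(out / "effective_config.yaml")
            manifest.add("config", out / "effective_config.yaml")
            layout.write_chrom_sizes(out / "chrom.sizes")
            manifest.add("chrom_sizes", out / "chrom.sizes")
            for key, path in truth.write(out).items():
                manifest.add(f"truth_{key}", path)

            raw: dict[str, list[BinTrack]] = {g: [] for g in genotypes}
            for g in genotypes:
                for rep in range(1, config.n_replicates + 1):
                    sample = Sample("H3K9me3", g, rep)
                    reads = simulate_aligned_reads(sim, layout, truth, sample)
                    sam = out / f"{sample.name}.sam"
                    write_sam(sam, layout, reads)
                    manifest.add(f"sam_{sample.name}", sam)

            premrna_reads = {}
            for g in genotypes:
                sample = Sample("pre-mRNA", g, 1)
                premrna_reads[g] = (sample, simulate_stranded_premrna(sim, layout, truth, sample))

            plate_files = []
            for g, by_gen in config.qpcr_truth.items():
                for gen, fold in by_gen.items():
                    plate = simulate_qpcr(
                        sim, fold, config.qpcr_noise_sd, generation=gen, genotype=g
                    )
                    p = out / f"qpcr_{g}_{gen}.csv"
                    write_plate_csv(plate, p)
                    plate_files.append(p)
                    manifest.add(f"qpcr_{g}_{gen}", p)

        # ------------------------------------------------------------ coverage
        with _Stage(manifest, "coverage"):
            for g in genotypes:
                for rep in range(1, config.n_replicates + 1):
                    sample = Sample("H3K9me3", g, rep)
                    track = bin_counts(
                        weight_reads(read_sam(out / f"{sample.name}.sam")), layout, sample
                    )
                    raw[g].append(track)
                    norm = depth_normalize(track)
                    bg = out / f"{sample.name}.bedgraph"
                    norm.write_bedgraph(bg)
                    manifest.add(f"bedgraph_{sample.name}", bg)
            pooled_raw = {g: _pool(raw[g]) for g in genotypes}
            pooled_depth = {g: depth_normalize(pooled_raw[g]) for g in genotypes}

        # ------------------------------------------------------------- regions
        with _Stage(manifest, "regions"):
            pos_rs, neg_rs = percentile_regions(
                pooled_depth["WT"],
                RegionClassConfig(config.top_percentile, config.background_band),
            )
            for rs, tag in ((pos_rs, "positive"), (neg_rs, "negative")):
                p = out / f"regions_{tag}.bed"
                rs.write_bed(p)
                manifest.add(f"regions_{tag}", p)

        # -------------------------------------------------------- differential
        with _Stage(manifest, "differential"):
            dep_sets: list[DependencySet] = []
            stats_rows = []
            scatter_results = {}
            for g in mutants:
                pairs = list(zip(raw[g], raw["WT"]))
                dep = call_dependent_regions(
                    pairs,
                    DependencyCriteria(
                        config.max_delta, config.alpha, min(config.n_replicates, len(pairs))
                    ),
                    label=g,
                )
                dep_sets.append(dep)
                p = out / f"dependent_{g}.bed"
                dep.regions.write_bed(p)
                manifest.add(f"dependent_{g}", p)

                result = call_changed_bins(
                    pooled_raw[g],
                    pooled_raw["WT"],
                    SignificanceConfig(config.fold, config.alpha, pseudocount=config.pseudocount),
                )
                scatter_results[g] = result
                tsv = out / f"scatter_{g}_vs_WT.tsv"
                bins = [layout.bin_location(i) for i in range(layout.n_bins)]
                pd.DataFrame(
                    {
                        "chrom": [b[0] for b in bins],
                        "start": [b[1] for b in bins],
                        "abundance": result.abundance,
                        "delta": result.delta,
                        "p": result.pvalues,
                        "padj": result.padj,
                        "called": result.changed,
                    }
                ).query("abundance > 0").to_csv(tsv, sep="\t", index=False)
                manifest.add(f"scatter_{g}", tsv)

                mut_bgnorm = background_median_normalize(
                    pooled_depth[g], neg_rs, pooled_depth["WT"]
                )
                wt_ref = pooled_depth["WT"].with_values(
                    pooled_depth["WT"].values, "depth+background", ("background-median", 1.0)
                )
                ratio = compute_ratio(mut_bgnorm, wt_ref, config.pseudocount)
                for rs in (truth.grts_like, truth.grh_like, pos_rs, neg_rs):
                    if len(rs) == 0:
                        continue
                    gs = group_ratio_stats(ratio, rs, reference=neg_rs)
                    stats_rows.append(
                        {"comparison": f"{g}/WT", "assay": "H3K9me3", **dataclasses.asdict(gs)}
                    )
            if stats_rows:
                p = out / "group_stats.tsv"
                pd.DataFrame(stats_rows).to_csv(p, sep="\t", index=False)
                manifest.add("group_stats", p)
            if 2 <= len(dep_sets) <= 3:
                cells = venn_overlap(dep_sets)
                p = out / "venn_cells.json"
                p.write_text(json.dumps(cells, indent=2, sort_keys=True))
                manifest.add("venn_cells", p)

        # ------------------------------------------------------------ pre-mRNA
        with _Stage(manifest, "premrna"):
            stranded = {}
            for g, (sample, reads) in premrna_reads.items():
                sense, anti = stranded_coverage(
                    weight_reads(reads), truth.grts_like, layout, sample
                )
                stranded[g] = (sense, anti)
                for t, tag in ((sense, "sense"), (anti, "antisense")):
                    p = out / f"premrna_{g}_{tag}.bedgraph"
                    t.write_bedgraph(p)
                    manifest.add(f"premrna_{g}_{tag}", p)

        # ---------------------------------------------------------------- qPCR
        with _Stage(manifest, "qpcr"):
            profiles = []
            by_genotype: dict[str, list] = {}
            for p in plate_files:
                plate = read_plate_csv(p)
                by_genotype.setdefault(plate.genotype or "", []).append(plate)
            for g, plates in by_genotype.items():
                profiles.append(assemble_profile(plates))
            p = out / "heritable_profiles.tsv"
            write_profiles_tsv(profiles, p)
            manifest.add("qpcr_profiles", p)

        # ------------------------------------------------------------- figures
        with _Stage(manifest, "figures"):
            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            profiles_sm = [moving_average(pooled_depth[g], config.window) for g in genotypes]
            manifest.add(
                "fig_profile",
                smoothed_plot(profiles_sm, layout.chromosomes[0], figdir / "genome_profile.png", genotypes),
            )
            if truth.grts_like.intervals:
                locus = truth.grts_like.intervals[0]
                manifest.add(
                    "fig_coverage",
                    coverage_plot(
                        [pooled_depth[g] for g in genotypes], locus, figdir / "locus_coverage.png"
                    ),
                )
                g0 = mutants[0] if mutants else "WT"
                manifest.add(
                    "fig_stranded",
                    stranded_plot(*stranded[g0], locus, figdir / "stranded_premrna.png"),
                )
            for g, result in scatter_results.items():
                manifest.add(
                    f"fig_scatter_{g}",
                    scatter_plot(
                        result,
                        figdir / f"scatter_{g}.png",
                        highlights={"GRH-like": truth.grh_like} if truth.grh_like.intervals else None,
                    ),
                )
            if 2 <= len(dep_sets) <= 3:
                manifest.add("fig_venn", venn_plot(dep_sets, figdir / "venn.png"))
            if stats_rows:
                from .regionstats import GroupStats

                gs_objs = [
                    GroupStats(
                        label=f"{r['comparison']}:{r['label']}",
                        n_bins=r["n_bins"],
                        median=r["median"],
                        q1=r["q1"],
                        q3=r["q3"],
                        whisker_lo=r["whisker_lo"],
                        whisker_hi=r["whisker_hi"],
                    )
                    for r in stats_rows
                ]
                manifest.add("fig_boxplot", boxplot(gs_objs, figdir / "group_boxplot.png"))
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest.add("run_log", out / "run.log")
    manifest.write(out / "manifest.json")
    return manifest
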