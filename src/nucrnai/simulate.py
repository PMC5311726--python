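"""Synthetic genomes, enriched-domain read data, stranded transcription
signal, and qPCR plates, with ground truth for parameter-recovery tests.

The generator plants broad enriched domains on a bin grid, applies
genotype-specific multiplicative depletion, draws negative-binomial (or
Poisson) per-bin counts with per-library depth scalers, emits 50-nt
single-end placements including exact-copy multi-mappers, and produces
stranded pre-mRNA reads with planted de-silencing at annotated loci.

All randomness flows from one seed; per-library substreams are derived by
stable hashing of the library name, so outputs are bit-identical for
identical configs regardless of call order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .coverage import AlignedReadRecord, BinTrack, Sample
from .layout import GenomeLayout
from .qpcr import CONDITIONS, QpcrPlate
from .regions import Interval, RegionSet

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "ConfigurationError",
    "generate_layout",
    "simulate_bin_counts",
    "simulate_aligned_reads",
    "simulate_stranded_premrna",
    "simulate_qpcr",
]

_ROMAN = ["I", "II", "III", "IV", "V", "X", "VI", "VII", "VIII", "IX"]


class ConfigurationError(ValueError):
    pass


def _substream(seed: int, *tags) -> np.random.Generator:
    """Independent generator keyed by seed plus stable-hashed string tags."""
    keys = [int(seed)]
    for tag in tags:
        digest = hashlib.sha256(str(tag).encode()).digest()
        keys.append(int.from_bytes(digest[:8], "little"))
    return np.random.default_rng(keys)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for every synthetic dataset.

    ``depletion_factors`` maps genotype -> factor in [0, 1] applied to the
    planted-domain enrichment (1 = WT, 0 = complete loss).
    ``desilencing_factors`` maps genotype -> fold increase of sense-strand
    pre-mRNA at planted transcription-target loci.  ``dispersion`` is the
    negative-binomial size parameter; ``inf`` gives Poisson counts.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chromosome_length: int = 1_000_000
    bin_size: int = 1000
    background_mean: float = 5.0
    domain_enrichment: float = 10.0
    depletion_factors: dict = field(default_factory=lambda: {"WT": 1.0})
    dispersion: float = math.inf
    library_depth_scalers: dict = field(default_factory=dict)
    multimapping_fraction: float = 0.0
    multimapping_copies: int = 2
    desilencing_factors: dict = field(default_factory=dict)
    n_domains: int = 5
    domain_length: int = 20_000
    n_grts_like: int = 1
    n_grh_like: int = 1
    grts_locus_length: int = 4000
    read_length: int = 50
    premrna_background_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.chromosome_length < self.bin_size:
            raise ConfigurationError("need chromosome_length >= bin_size > 0")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        for name, value in [
            ("background_mean", self.background_mean),
            ("domain_enrichment", self.domain_enrichment),
            ("premrna_background_mean", self.premrna_background_mean),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for gt, f in self.depletion_factors.items():
            if not 0 <= f:
                raise ConfigurationError(f"depletion factor for {gt} must be >= 0")
        for gt, f in self.desilencing_factors.items():
            if f < 0:
                raise ConfigurationError(f"desilencing factor for {gt} must be >= 0")
        for lib, s in self.library_depth_scalers.items():
            if s <= 0:
                raise ConfigurationError(f"depth scaler for {lib} must be > 0")
        if not 0 <= self.multimapping_fraction <= 1:
            raise ConfigurationError("multimapping_fraction must be in [0, 1]")
        if self.multimapping_fraction > 0 and self.multimapping_copies < 2:
            raise ConfigurationError("multimapping_copies must be >= 2 when multimapping_fraction > 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0 (inf for Poisson)")
        if self.n_domains < 0 or self.domain_length <= 0:
            raise ConfigurationError("invalid domain parameters")
        if self.n_grts_like + self.n_grh_like > self.n_domains:
            raise ConfigurationError("n_grts_like + n_grh_like exceeds n_domains")
        total_domain = self.n_domains * self.domain_length
        genome = self.n_chromosomes * self.chromosome_length
        if total_domain > genome:
            raise ConfigurationError(
                f"planted domains ({total_domain} bp) exceed the genome ({genome} bp)"
            )

    def depth_scaler(self, library: str) -> float:
        return float(self.library_depth_scalers.get(library, 1.0))

    def echo_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["dispersion"] = "inf" if math.isinf(self.dispersion) else self.dispersion
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class PlantedTruth:
    """Planted intervals with their true per-genotype effect sizes."""

    domains: RegionSet
    grts_like: RegionSet
    grh_like: RegionSet
    depletion_factors: dict
    desilencing_factors: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, rs in [
            ("domains", self.domains),
            ("grts_like", self.grts_like),
            ("grh_like", self.grh_like),
        ]:
            paths[key] = outdir / f"truth_{key}.bed"
            rs.write_bed(paths[key])
        return paths

    @classmethod
    def read(cls, outdir: str | Path, config: "SimulationConfig") -> "PlantedTruth":
        outdir = Path(outdir)
        return cls(
            domains=RegionSet.from_bed(outdir / "truth_domains.bed", "domains"),
            grts_like=RegionSet.from_bed(outdir / "truth_grts_like.bed", "grts_like"),
            grh_like=RegionSet.from_bed(outdir / "truth_grh_like.bed", "grh_like"),
            depletion_factors=dict(config.depletion_factors),
            desilencing_factors=dict(config.desilencing_factors),
        )


# ------------------------------------------------------------------- layout
def generate_layout(config: SimulationConfig) -> tuple[GenomeLayout, PlantedTruth]:
    """Build the bin grid and plant non-overlapping, bin-aligned domains.

    Domains are distributed round-robin over chromosomes; within a
    chromosome, each domain is placed at a random bin-aligned offset inside
    its own equal segment, which guarantees non-overlap.  A subset of the
    domains becomes stranded transcription-target (GRTS-like) loci and
    another disjoint subset becomes heterochromatin-target (GRH-like) loci.
    """
    names = tuple(
        f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"
        for i in range(config.n_chromosomes)
    )
    layout = GenomeLayout(
        names, (config.chromosome_length,) * config.n_chromosomes, config.bin_size
    )
    rng = _substream(config.seed, "layout")
    bs = config.bin_size
    dom_bins = -(-config.domain_length // bs)

    per_chrom: dict[str, int] = {c: 0 for c in names}
    for d in range(config.n_domains):
        per_chrom[names[d % len(names)]] += 1

    domains: list[Interval] = []
    for chrom in names:
        k = per_chrom[chrom]
        if k == 0:
            continue
        nb = layout.n_bins_of(chrom)
        segment = nb // k
        if dom_bins > segment:
            raise ConfigurationError(
                f"cannot fit {k} domains of {dom_bins} bins on {chrom} ({nb} bins)"
            )
        for s in range(k):
            off = int(rng.integers(0, segment - dom_bins + 1))
            start = (s * segment + off) * bs
            domains.append(Interval(chrom, start, start + dom_bins * bs, name=f"dom{len(domains)}"))

    order = rng.permutation(len(domains))
    grts: list[Interval] = []
    for i in order[: config.n_grts_like]:
        dom = domains[i]
        locus_bins = max(1, min(config.grts_locus_length // bs, dom.length // bs))
        off = int(rng.integers(0, dom.length // bs - locus_bins + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start = dom.start + off * bs
        grts.append(Interval(dom.chrom, start, start + locus_bins * bs, strand, f"grts{len(grts)}"))
    grh = [
        Interval(domains[i].chrom, domains[i].start, domains[i].end, None, f"grh{j}")
        for j, i in enumerate(order[config.n_grts_like : config.n_grts_like + config.n_grh_like])
    ]
    truth = PlantedTruth(
        domains=RegionSet("domains", domains),
        grts_like=RegionSet("grts_like", grts),
        grh_like=RegionSet("grh_like", grh),
        depletion_factors=dict(config.depletion_factors),
        desilencing_factors=dict(config.desilencing_factors),
    )
    return layout, truth


# ------------------------------------------------------------------- counts
def _library_sample(library) -> Sample:
    if isinstance(library, Sample):
        return library
    if isinstance(library, str):
        return Sample(assay="H3K9me3", genotype=library)
    raise TypeError(f"library descriptor must be Sample or genotype string, got {library!r}")


def _expected_means(
    config: SimulationConfig, layout: GenomeLayout, truth: PlantedTruth, sample: Sample
) -> np.ndarray:
    if sample.genotype not in config.depletion_factors:
        raise ConfigurationError(
            f"genotype {sample.genotype!r} not in depletion_factors "
            f"({sorted(config.depletion_factors)})"
        )
    dep = config.depletion_factors[sample.genotype]
    scaler = config.depth_scaler(sample.name)
    means = np.full(layout.n_bins, config.background_mean * scaler)
    in_domain = truth.domains.to_bin_mask(layout)
    # depleted domains never drop below the nonspecific background floor:
    # full depletion leaves domain bins distributed like background bins
    means[in_domain] *= max(1.0, config.domain_enrichment * dep)
    return means


def _draw_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(means).astype(np.float64)
    p = dispersion / (dispersion + means)
    return rng.negative_binomial(dispersion, p).astype(np.float64)


def simulate_bin_counts(
    config: SimulationConfig,
    layout: GenomeLayout,
    truth: PlantedTruth,
    library,
) -> BinTrack:
    """Draw per-bin counts directly (no read placement).

    Mean per bin = background_mean x (domain_enrichment x depletion factor
    inside planted domains) x the library's depth scaler; noise is
    negative-binomial with the configured size (Poisson at size = inf).
    """
    sample = _library_sample(library)
    means = _expected_means(config, layout, truth, sample)
    rng = _substream(config.seed, "bin-counts", sample.name)
    values = _draw_counts(rng, means, config.dispersion)
    return BinTrack(
        layout=layout,
        values=values,
        sample=sample,
        normalization_state="raw",
        raw_total=float(values.sum()),
    )


# -------------------------------------------------------------------- reads
def simulate_aligned_reads(
    config: SimulationConfig,
    layout: GenomeLayout,
    truth: PlantedTruth,
    library,
) -> list[AlignedReadRecord]:
    """Emit fixed-length single-end placements, including multi-mappers.

    A fraction of the reads born in planted domains become multi-mappers:
    each appears at exactly ``multimapping_copies`` distinct placements
    (the original plus copies at random domain bins), every placement
    tagged with the full placement count, so 1/N weighting conserves read
    mass exactly.
    """
    sample = _library_sample(library)
    means = _expected_means(config, layout, truth, sample)
    rng = _substream(config.seed, "reads", sample.name)
    counts = _draw_counts(rng, means, config.dispersion).astype(np.int64)

    domain_mask = truth.domains.to_bin_mask(layout)
    domain_bins = np.nonzero(domain_mask)[0]
    copy_pool = domain_bins if domain_bins.size else np.arange(layout.n_bins)

    records: list[AlignedReadRecord] = []
    read_id = 0
    bs = layout.bin_size
    for bin_idx in np.nonzero(counts)[0]:
        chrom, bin_start, _ = layout.bin_location(int(bin_idx))
        chrom_len = layout.length_of(chrom)
        n_reads = int(counts[bin_idx])
        offsets = rng.integers(0, bs, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        multi = (
            domain_mask[bin_idx]
            and config.multimapping_fraction > 0
        )
        is_multi = (
            rng.random(n_reads) < config.multimapping_fraction if multi else np.zeros(n_reads, bool)
        )
        for off, minus, mm in zip(offsets, strands, is_multi):
            name = f"r{read_id:08d}"
            read_id += 1
            start = min(int(bin_start + off), chrom_len - config.read_length)
            n_loci = config.multimapping_copies if mm else 1
            records.append(
                AlignedReadRecord(
                    chrom, start, config.read_length, "-" if minus else "+", n_loci, name
                )
            )
            for _ in range(n_loci - 1):
                cb = int(copy_pool[rng.integers(0, copy_pool.size)])
                c_chrom, c_start, _ = layout.bin_location(cb)
                c_off = int(rng.integers(0, bs))
                pos = min(c_start + c_off, layout.length_of(c_chrom) - config.read_length)
                records.append(
                    AlignedReadRecord(
                        c_chrom, pos, config.read_length, "-" if minus else "+", n_loci, name
                    )
                )
    return records


def simulate_stranded_premrna(
    config: SimulationConfig,
    layout: GenomeLayout,
    truth: PlantedTruth,
    library,
) -> list[AlignedReadRecord]:
    """Stranded transcription reads with planted de-silencing.

    Background Poisson rate per bin per strand; at transcription-target
    loci the sense-strand rate (the locus's annotated strand) is multiplied
    by the genotype's de-silencing factor, while the antisense rate stays
    at background.
    """
    sample = _library_sample(library)
    if isinstance(library, str):
        sample = Sample(assay="pre-mRNA", genotype=library)
    for iv in truth.grts_like:
        if iv.strand is None:
            raise ConfigurationError(f"locus {iv.name or iv} lacks a strand annotation")
    factor = float(truth.desilencing_factors.get(sample.genotype, 1.0))
    scaler = config.depth_scaler(sample.name)

    base = config.premrna_background_mean * scaler
    rate_plus = np.full(layout.n_bins, base)
    rate_minus = np.full(layout.n_bins, base)
    for iv in truth.grts_like:
        mask = RegionSet("locus", [iv]).to_bin_mask(layout)
        (rate_plus if iv.strand == "+" else rate_minus)[mask] *= factor

    rng = _substream(config.seed, "premrna", sample.name)
    records: list[AlignedReadRecord] = []
    read_id = 0
    bs = layout.bin_size
    for strand, rates in (("+", rate_plus), ("-", rate_minus)):
        counts = rng.poisson(rates)
        for bin_idx in np.nonzero(counts)[0]:
            chrom, bin_start, _ = layout.bin_location(int(bin_idx))
            chrom_len = layout.length_of(chrom)
            for off in rng.integers(0, bs, size=int(counts[bin_idx])):
                start = min(int(bin_start + off), chrom_len - config.read_length)
                records.append(
                    AlignedReadRecord(
                        chrom, start, config.read_length, strand, 1, f"p{read_id:08d}"
                    )
                )
                read_id += 1
    return records


# --------------------------------------------------------------------- qPCR
def simulate_qpcr(
    config: SimulationConfig,
    true_fold_change: float,
    ct_noise_sd: float = 0.0,
    generation: str | None = None,
    genotype: str | None = None,
    analyte: str = "mRNA",
) -> QpcrPlate:
    """Triplicate CT values whose expected ddCT is -log2(true fold change).

    Reference CTs sit at a fixed base cycle in both conditions; the treated
    target CT is shifted by -log2(fold) relative to the control target.
    Gaussian cycle noise of sd ``ct_noise_sd`` is added per well.
    """
    if true_fold_change <= 0:
        raise ConfigurationError("true_fold_change must be > 0")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd must be >= 0")
    rng = _substream(config.seed, "qpcr", generation, genotype, analyte, true_fold_change)
    base_ct = {"reference": 16.0, "target": 24.0}
    ct: dict[tuple[str, str], np.ndarray] = {}
    for cond in CONDITIONS:
        for role in ("target", "reference"):
            mean = base_ct[role]
            if role == "target" and cond == "treated":
                mean = mean - math.log2(true_fold_change)
            ct[(role, cond)] = mean + ct_noise_sd * rng.standard_normal(3)
    return QpcrPlate(ct=ct, generation=generation, genotype=genotype, analyte=analyte)
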