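"""Fully specified synthetic inputs with planted ground truth.

Generates a genome, a gene catalog with a heavy tail of >300 kb genes,
zero-inflated expression levels, TAD boundaries spaced every 0.4-1.2 Mb,
and control/stress replication-timing read counts with V-shaped delays
planted at chosen expressed large boundary-spanning genes (plus
intra-TAD delayed controls to exercise the negative arm of the
signature, and advanced-RT bumps elsewhere).  Every generator is a
deterministic function of (config, seed), and the emitted files are
exactly the formats the pipeline consumes: chrom-sizes, bedGraph, BED12,
boundary BED, band TSV and a ground-truth TSV.

The latent RT model: the control landscape is a Gaussian-smoothed random
field scaled into the [-3, 3] log2(early/late) range; the stress
condition adds the planted deltas; each replicate perturbs the latent RT
with N(0, sigma_rep) noise; per-bin reads are split early/late by a
binomial draw whose early fraction follows a logistic link on the
log2-odds scale, p = 1 / (1 + 2^-RT), so that the measured
log2(early/late) reproduces the latent RT in expectation.
"""

from __future__ import annotations

import bisect
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io_genomics import (
    BinnedTrack,
    GenomeTable,
    GenomicInterval,
    GeneRecord,
    write_bedgraph,
)
from .tad_architecture import ContactMatrix, TADBoundary

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the
    default benchmark: 4 x 50 Mb chromosomes, 500 genes, 12 planted
    fragile genes and 12 intra-TAD delayed controls, V depth -1.5 RT
    units, replicate noise SD 0.2, 4 replicates per condition, 200 reads
    per 5 kb bin."""

    seed: int
    n_chromosomes: int = 4
    chrom_length: int = 50_000_000
    n_genes: int = 500
    gene_len_log_mean: float = float(np.log(30_000))
    gene_len_log_sigma: float = 1.0
    large_fraction: float = 0.05
    pareto_alpha: float = 2.5
    min_gene_length: int = 5_000
    max_gene_length: int = 1_500_000
    zero_inflation: float = 0.4
    expr_log_mean: float = float(np.log(5.0))
    expr_log_sigma: float = 1.0
    planted_expr_low: float = 20.0
    planted_expr_high: float = 60.0
    tad_spacing: tuple[int, int] = (400_000, 1_200_000)
    boundary_width: int = 25_000
    n_fragile: int = 12
    n_intra_tad_controls: int = 12
    fragile_len_range: tuple[int, int] = (400_000, 700_000)
    control_len_range: tuple[int, int] = (310_000, 450_000)
    delay_depth: float = -1.5
    n_advanced: int = 8
    advanced_magnitude: float = 1.2
    advanced_width: int = 200_000
    n_replicates: int = 4
    replicate_sd: float = 0.2
    reads_per_bin: int = 200
    bin_size: int = 5_000
    rt_smooth_bins: int = 40
    expr_bin_size: int = 1_000
    expr_background_rate: float = 0.05
    band_size: int = 5_000_000
    matrix_bin_size: int = 25_000
    contact_scale: float = 30.0
    tad_contrast: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.delay_depth > 0:
            raise ValueError("delay depth must be <= 0 (a delay)")
        for name in ("n_genes", "n_fragile", "n_intra_tad_controls", "n_advanced"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring recovered calls."""

    genome: GenomeTable
    genes: list[GeneRecord]
    gene_table: pd.DataFrame  # gene_id, coords, length, expr_level, flags, vertex
    boundaries: list[TADBoundary]
    advanced_regions: list[GenomicInterval]
    bands: pd.DataFrame
    fragile_band_ids: list[str]

    @property
    def fragile_gene_ids(self) -> set[str]:
        t = self.gene_table
        return set(t.loc[t["planted_fragile"], "gene_id"])

    @property
    def control_gene_ids(self) -> set[str]:
        t = self.gene_table
        return set(t.loc[t["planted_control"], "gene_id"])


def _sample_gene_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    if rng.random() < cfg.large_fraction:
        length = 300_000 * (1.0 + rng.pareto(cfg.pareto_alpha))
    else:
        length = float(np.exp(rng.normal(cfg.gene_len_log_mean, cfg.gene_len_log_sigma)))
    return int(np.clip(length, cfg.min_gene_length, cfg.max_gene_length))


class _Placer:
    """Rejection-sampled non-overlapping placement bookkeeping."""

    def __init__(self, genome: GenomeTable):
        self.by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
        self.genome = genome

    def fits(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.genome[chrom]:
            return False
        placed = self.by_chrom[chrom]
        i = bisect.bisect_left(placed, (start, start))
        if i > 0 and placed[i - 1][1] > start:
            return False
        if i < len(placed) and placed[i][0] < end:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self.by_chrom[chrom], (start, end))


def simulate_genome(cfg: SimulationConfig) -> GroundTruth:
    """Genome, boundaries, gene catalog and planted flags.

    Genes are non-overlapping; boundaries are spaced uniformly in the
    configured range; the requested numbers of large, highly expressed
    genes are positioned to contain a boundary (planted fragile) or to
    sit fully inside a TAD (planted intra-TAD delayed controls).  Every
    planted fragile gene satisfies all four signature components by
    construction.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = GenomeTable(
        [(f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chromosomes)]
    )
    # --- TAD boundaries -----------------------------------------------------
    boundaries: list[TADBoundary] = []
    lo, hi = cfg.tad_spacing
    for chrom in genome:
        pos = int(rng.integers(lo, hi))
        while pos + cfg.boundary_width < genome[chrom] - lo:
            b0 = (pos // cfg.boundary_width) * cfg.boundary_width
            boundaries.append(
                TADBoundary(
                    GenomicInterval(chrom, b0, b0 + cfg.boundary_width), np.nan
                )
            )
            pos += int(rng.integers(lo, hi))
    placer = _Placer(genome)
    rows: list[dict] = []
    genes: list[GeneRecord] = []

    def register(gid, chrom, start, end, level, fragile, ctrl_flag, vertex):
        placer.add(chrom, start, end)
        genes.append(GeneRecord(gid, chrom, start, end, "+" if rng.random() < 0.5 else "-"))
        rows.append(
            dict(
                gene_id=gid, chrom=chrom, start=start, end=end, length=end - start,
                expr_level=level, planted_fragile=fragile, planted_control=ctrl_flag,
                vertex=vertex, delay_depth=cfg.delay_depth if (fragile or ctrl_flag) else 0.0,
            )
        )

    # --- planted fragile genes: contain a boundary midpoint -----------------
    host_order = rng.permutation(len(boundaries))
    placed_fragile = 0
    for bi in host_order:
        if placed_fragile >= cfg.n_fragile:
            break
        b = boundaries[bi]
        length = int(rng.uniform(*cfg.fragile_len_range))
        vertex = b.midpoint
        offset = int(length * rng.uniform(0.3, 0.7))
        start, end = vertex - offset, vertex - offset + length
        if placer.fits(b.interval.chrom, start, end):
            register(
                f"FRAG{placed_fragile + 1:03d}", b.interval.chrom, start, end,
                float(rng.uniform(cfg.planted_expr_low, cfg.planted_expr_high)),
                True, False, vertex,
            )
            placed_fragile += 1
    if placed_fragile < cfg.n_fragile:
        raise ValueError("genome too small to place the planted fragile genes")
    # --- intra-TAD delayed controls: fully inside one TAD -------------------
    margin = 30_000
    tads: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[int]] = {c: [] for c in genome}
    for b in boundaries:
        by_chrom[b.interval.chrom].append(b.midpoint)
    for chrom, mids in by_chrom.items():
        mids = sorted(mids)
        edges = [0] + mids + [genome[chrom]]
        for a, b2 in zip(edges[:-1], edges[1:]):
            tads.append((chrom, a, b2))
    tad_order = rng.permutation(len(tads))
    placed_ctrl = 0
    for ti in tad_order:
        if placed_ctrl >= cfg.n_intra_tad_controls:
            break
        chrom, t0, t1 = tads[ti]
        length = int(rng.uniform(*cfg.control_len_range))
        if t1 - t0 < length + 2 * margin:
            continue
        start = int(rng.integers(t0 + margin, t1 - margin - length))
        end = start + length
        if placer.fits(chrom, start, end):
            register(
                f"CTRL{placed_ctrl + 1:03d}", chrom, start, end,
                float(rng.uniform(cfg.planted_expr_low, cfg.planted_expr_high)),
                False, True, (start + end) // 2,
            )
            placed_ctrl += 1
    if placed_ctrl < cfg.n_intra_tad_controls:
        raise ValueError("not enough wide TADs for the intra-TAD control genes")
    # --- background gene catalog --------------------------------------------
    chrom_names = list(genome)
    n_background = cfg.n_genes - placed_fragile - placed_ctrl
    if n_background < 0:
        raise ValueError("n_genes smaller than the number of planted genes")
    for gi in range(n_background):
        for _try in range(200):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            length = _sample_gene_length(cfg, rng)
            start = int(rng.integers(0, max(1, genome[chrom] - length)))
            if placer.fits(chrom, start, start + length):
                level = 0.0 if rng.random() < cfg.zero_inflation else float(
                    np.exp(rng.normal(cfg.expr_log_mean, cfg.expr_log_sigma))
                )
                register(f"GENE{gi + 1:04d}", chrom, start, start + length,
                         level, False, False, -1)
                break
        else:
            raise ValueError("genome too small for the requested gene count")
    # --- advanced-RT bumps (intergenic relative to planted genes) -----------
    advanced: list[GenomicInterval] = []
    planted_ivs = [g.interval for g in genes if g.gene_id.startswith(("FRAG", "CTRL"))]
    tries = 0
    while len(advanced) < cfg.n_advanced and tries < 1000:
        tries += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(0, genome[chrom] - cfg.advanced_width))
        iv = GenomicInterval(chrom, start, start + cfg.advanced_width)
        if not any(iv.overlaps(p) for p in planted_ivs):
            advanced.append(iv)
    # --- cytogenetic-style bands ---------------------------------------------
    band_rows = []
    for chrom in genome:
        n_bands = -(-genome[chrom] // cfg.band_size)
        for i in range(n_bands):
            band_rows.append(
                dict(
                    band_id=f"{chrom}_b{i + 1}", chrom=chrom,
                    start=i * cfg.band_size,
                    end=min((i + 1) * cfg.band_size, genome[chrom]),
                )
            )
    bands = pd.DataFrame(band_rows)
    fragile_ivs = [g.interval for g in genes if g.gene_id.startswith("FRAG")]
    fragile_band_ids = [
        r["band_id"]
        for r in band_rows
        if any(
            GenomicInterval(r["chrom"], r["start"], r["end"]).overlaps(iv)
            for iv in fragile_ivs
        )
    ]
    table = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    genes = sorted(genes, key=lambda g: (g.chrom, g.start))
    boundaries.sort(key=lambda b: (b.interval.chrom, b.interval.start))
    return GroundTruth(genome, genes, table, boundaries, advanced, bands, fragile_band_ids)


# ---------------------------------------------------------------------------
# replication timing


def latent_rt_fields(
    truth: GroundTruth, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[BinnedTrack, BinnedTrack]:
    """Latent control and stress RT landscapes (no replicate noise).

    Control: Gaussian-smoothed white noise scaled into [-3, 3] per
    chromosome.  Stress: control plus the planted V-shaped deltas at the
    fragile and intra-TAD control genes and Gaussian advanced bumps.
    """
    bs = cfg.bin_size
    ctrl = BinnedTrack.allocate(truth.genome, bs)
    aph = BinnedTrack.allocate(truth.genome, bs)
    for chrom in truth.genome:
        n = truth.genome.n_bins(chrom, bs)
        white = rng.standard_normal(n)
        sm = gaussian_filter1d(white, cfg.rt_smooth_bins, mode="reflect")
        peak = np.abs(sm).max()
        ctrl.values[chrom] = 3.0 * sm / peak if peak > 0 else sm
        aph.values[chrom] = ctrl.values[chrom].copy()
    planted = truth.gene_table[
        truth.gene_table["planted_fragile"] | truth.gene_table["planted_control"]
    ]
    for _, g in planted.iterrows():
        v = aph.values[g["chrom"]]
        b0, b1 = int(g["start"]) // bs, (int(g["end"]) - 1) // bs + 1
        vx = int(g["vertex"]) // bs
        x = np.arange(b0, b1)
        left_span = max(vx - b0, 1)
        right_span = max(b1 - 1 - vx, 1)
        shape = np.where(
            x <= vx, 1.0 - (vx - x) / left_span, 1.0 - (x - vx) / right_span
        )
        v[b0:b1] += g["delay_depth"] * np.clip(shape, 0.0, 1.0)
    for iv in truth.advanced_regions:
        v = aph.values[iv.chrom]
        c = (iv.start + iv.end) / 2 / bs
        w = iv.length / 4 / bs
        x = np.arange(len(v))
        v += cfg.advanced_magnitude * np.exp(-0.5 * ((x - c) / w) ** 2)
    return ctrl, aph


def simulate_rt_reads(
    truth: GroundTruth, cfg: SimulationConfig
) -> dict[str, list[tuple[BinnedTrack, BinnedTrack]]]:
    """Early/late read-count tracks per replicate per condition.

    Each replicate adds N(0, sigma_rep) noise to the latent RT; the
    per-bin early read count is Binomial(reads_per_bin, p) with
    p = 1 / (1 + 2^-RT) and the late count is the remainder, so an RT of
    0 yields an early fraction of 1/2 in expectation and the measured
    log2(early/late) reproduces the latent RT.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ctrl_latent, aph_latent = latent_rt_fields(truth, cfg, rng)
    out: dict[str, list[tuple[BinnedTrack, BinnedTrack]]] = {"control": [], "APH": []}
    for condition, latent in (("control", ctrl_latent), ("APH", aph_latent)):
        for _rep in range(cfg.n_replicates):
            early = BinnedTrack.allocate(truth.genome, cfg.bin_size)
            late = BinnedTrack.allocate(truth.genome, cfg.bin_size)
            for chrom in truth.genome:
                rt = latent.values[chrom] + rng.normal(
                    0.0, cfg.replicate_sd, len(latent.values[chrom])
                )
                p = 1.0 / (1.0 + np.exp2(-rt))
                e = rng.binomial(cfg.reads_per_bin, p).astype(float)
                early.values[chrom] = e
                late.values[chrom] = cfg.reads_per_bin - e
            out[condition].append((early, late))
    return out


# ---------------------------------------------------------------------------
# nascent transcription


def simulate_nascent_counts(
    truth: GroundTruth, cfg: SimulationConfig
) -> dict[str, tuple[BinnedTrack, float]]:
    """Poisson nascent-RNA counts in fine bins, per condition.

    Per-bin rate = intergenic background + the gene's expression level
    (expected reads per bin) over its body; expression does not respond
    to the stress treatment.  Library size is the total read count, so
    doubling all rates doubles the library in expectation while leaving
    RPM densities invariant.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    bs = cfg.expr_bin_size
    out: dict[str, tuple[BinnedTrack, float]] = {}
    rate = BinnedTrack.allocate(truth.genome, bs, fill=cfg.expr_background_rate)
    for _, g in truth.gene_table.iterrows():
        if g["expr_level"] <= 0:
            continue
        v = rate.values[g["chrom"]]
        b0, b1 = int(g["start"]) // bs, (int(g["end"]) - 1) // bs + 1
        for b in range(b0, min(b1, len(v))):
            frac = (min(int(g["end"]), (b + 1) * bs) - max(int(g["start"]), b * bs)) / bs
            v[b] += g["expr_level"] * frac
    for condition in ("control", "APH"):
        counts = BinnedTrack.allocate(truth.genome, bs)
        total = 0.0
        for chrom in truth.genome:
            c = rng.poisson(rate.values[chrom]).astype(float)
            counts.values[chrom] = c
            total += c.sum()
        out[condition] = (counts, float(total))
    return out


# ---------------------------------------------------------------------------
# chromatin contacts


def simulate_block_matrix(
    block_sizes: list[int],
    within: float = 10.0,
    between: float = 1.0,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
    bin_size: int = 25_000,
) -> ContactMatrix:
    """Planted-block contact matrix with Poisson noise.

    Cells within a block have mean ``within``, cells between blocks mean
    ``between``; the sampled matrix is symmetrised so it remains a valid
    contact matrix."""
    n = sum(block_sizes)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    mean = np.where(labels[:, None] == labels[None, :], within, between)
    if rng is None:
        m = mean
    else:
        draw = rng.poisson(mean).astype(float)
        m = np.triu(draw) + np.triu(draw, 1).T
    return ContactMatrix(chrom, bin_size, m)


def simulate_contact_matrix(
    truth: GroundTruth,
    cfg: SimulationConfig,
    chrom: str,
    region: tuple[int, int] | None = None,
) -> ContactMatrix:
    """TAD-structured contact matrix with distance decay and Poisson noise.

    Within-TAD contacts are boosted ``tad_contrast``-fold over the
    distance-decay baseline ``contact_scale / (1 + d)``."""
    rng = np.random.default_rng(cfg.seed + 3)
    bs = cfg.matrix_bin_size
    start, end = region if region else (0, truth.genome[chrom])
    n = (end - start) // bs
    mids = sorted(
        b.midpoint for b in truth.boundaries
        if b.interval.chrom == chrom and start <= b.midpoint < end
    )
    edges = np.array([start] + mids + [end])
    labels = np.searchsorted(edges, start + np.arange(n) * bs + bs // 2, side="right")
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    base = cfg.contact_scale / (1.0 + d)
    mean = base * np.where(labels[:, None] == labels[None, :], cfg.tad_contrast, 1.0)
    draw = rng.poisson(mean).astype(float)
    m = np.triu(draw) + np.triu(draw, 1).T
    return ContactMatrix(chrom, bs, m)


# ---------------------------------------------------------------------------
# file emission


def simulate_to_dir(cfg: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Run all generators and emit the pipeline's input files.

    Writes chrom.sizes, genes.bed (BED12-compatible 6 columns), per-
    replicate early/late RT bedGraphs, nascent-count bedGraphs with
    library sizes, boundary BED, band table, fragile-band list and the
    ground-truth gene table.  Deterministic for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_genome(cfg)
    truth.genome.to_file(out / "chrom.sizes")
    with open(out / "genes.bed", "w") as fh:
        for g in truth.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    reads = simulate_rt_reads(truth, cfg)
    for condition, reps in reads.items():
        for i, (early, late) in enumerate(reps):
            write_bedgraph(early, out / f"early_{condition}_{i + 1}.bedgraph")
            write_bedgraph(late, out / f"late_{condition}_{i + 1}.bedgraph")
    nascent = simulate_nascent_counts(truth, cfg)
    lib_rows = []
    for condition, (counts, lib) in nascent.items():
        write_bedgraph(counts, out / f"nascent_{condition}.bedgraph")
        lib_rows.append({"condition": condition, "library_size": lib})
    pd.DataFrame(lib_rows).to_csv(out / "library_sizes.tsv", sep="\t", index=False)
    with open(out / "boundaries.bed", "w") as fh:
        for b in truth.boundaries:
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\tboundary\t0\n"
            )
    truth.bands.to_csv(out / "bands.tsv", sep="\t", index=False)
    with open(out / "fragile_bands.txt", "w") as fh:
        for bid in truth.fragile_band_ids:
            fh.write(bid + "\n")
    truth.gene_table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    with open(out / "sim_config.json", "w") as fh:
        import json

        json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return truth


def pipeline_config_for(
    sim_dir: str | Path, out_dir: str | Path, cfg: SimulationConfig, **overrides
) -> "PipelineConfig":
    """Build a :class:`fragility.PipelineConfig` pointing at emitted files."""
    from .fragility import PipelineConfig

    d = Path(sim_dir)
    libs = pd.read_csv(d / "library_sizes.tsv", sep="\t").set_index("condition")
    fragile_ids = [
        line.strip() for line in open(d / "fragile_bands.txt") if line.strip()
    ]
    kwargs = dict(
        chrom_sizes=str(d / "chrom.sizes"),
        genes=str(d / "genes.bed"),
        early={
            c: [str(d / f"early_{c}_{i + 1}.bedgraph") for i in range(cfg.n_replicates)]
            for c in ("control", "APH")
        },
        late={
            c: [str(d / f"late_{c}_{i + 1}.bedgraph") for i in range(cfg.n_replicates)]
            for c in ("control", "APH")
        },
        nascent={
            c: (str(d / f"nascent_{c}.bedgraph"), float(libs.at[c, "library_size"]))
            for c in ("control", "APH")
        },
        boundaries_bed=str(d / "boundaries.bed"),
        bands_tsv=str(d / "bands.tsv"),
        fragile_band_ids=fragile_ids,
        out_dir=str(out_dir),
        seed=cfg.seed,
        bin_size=cfg.bin_size,
        expr_bin_size=cfg.expr_bin_size,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
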