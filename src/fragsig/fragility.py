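"""Fragility-signature calling and core fragility region (CFR) mapping.

Under mild replication stress, fragile loci show a V-shaped local RT
delay — a minimum of the stress-minus-control RT difference with rising
flanks — produced by long single forks traversing a region without
internal origin firing.  A gene is called a fragility candidate when all
four signature components hold: it is large (>300 kb), highly
transcribed (expression quartile q3/q4), overlaps a stress-delayed RT
region, and spans a TAD boundary.  The CFR is the contiguous stretch of
bins around the V vertex whose delay stays within a fraction of the
vertex depth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io_genomics as iog
from . import repliseq as rs
from . import rt_variability as rv
from . import tad_architecture as ta
from . import transcription as tx
from .io_genomics import BinnedTrack, GenomicInterval, GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class VShapeResult:
    """Localized V-shaped RT delay within a gene body (plus flanks)."""

    vertex: int  # bp position of the most delayed bin
    depth: float  # dRT at the vertex relative to the flank reference
    is_v: bool
    left_flank: GenomicInterval | None
    right_flank: GenomicInterval | None
    cfr: GenomicInterval | None  # bins with dRT within cfr_fraction of depth


@dataclass
class FragilityCall:
    """Per-gene signature verdict with all component evidence."""

    gene_id: str
    is_large: bool
    is_highly_transcribed: bool
    is_rt_delayed: bool
    spans_boundary: bool
    verdict: bool
    delay_magnitude: float
    supporting_regions: list[int] = field(default_factory=list)
    boundary_ids: list[int] = field(default_factory=list)
    cfr: GenomicInterval | None = None
    v_depth: float = np.nan
    is_v: bool = False


def detect_v_shape(
    delta: np.ndarray,
    body_slice: slice,
    chrom: str,
    origin: int,
    bin_size: int,
    sigma_bins: float = 2.0,
    min_depth: float = 0.5,
    cfr_fraction: float = 0.8,
) -> VShapeResult:
    """Detect a V-shaped stress-induced delay in a dRT window.

    ``delta`` holds mean(APH) − mean(control) RT values at ``bin_size``
    resolution over the gene body plus flanks; ``body_slice`` marks the
    gene-body bins, ``origin`` the bp coordinate of ``delta[0]``.  After
    Gaussian smoothing the vertex is the most delayed bin inside the
    body; the depth is measured relative to the median flank level.  A V
    is called when depth <= −min_depth and the smoothed dRT rises by at
    least min_depth/2 on both sides of the vertex within the searched
    span.  The CFR is the contiguous run of bins around the vertex with
    dRT <= flank reference + cfr_fraction x depth; it always contains
    the vertex and never leaves the searched window.
    """
    delta = np.asarray(delta, dtype=float)
    body_lo, body_hi = body_slice.indices(len(delta))[:2]
    if body_hi - body_lo < 3:
        raise ValueError("gene body shorter than 3 bins")
    sm = rs._smooth_array(delta, sigma_bins)
    body = sm[body_lo:body_hi]
    if np.all(np.isnan(body)):
        return VShapeResult(origin + ((body_lo + body_hi) // 2) * bin_size, np.nan, False, None, None, None)
    vi = body_lo + int(np.nanargmin(body))
    flank_vals = np.concatenate([sm[:body_lo], sm[body_hi:]])
    flank_vals = flank_vals[~np.isnan(flank_vals)]
    ref = float(np.median(flank_vals)) if len(flank_vals) else 0.0
    depth = float(sm[vi] - ref)
    with np.errstate(invalid="ignore"):
        left = sm[: vi + 1]
        right = sm[vi:]
        rise_left = float(np.nanmax(left) - sm[vi]) if np.isfinite(left).any() else 0.0
        rise_right = float(np.nanmax(right) - sm[vi]) if np.isfinite(right).any() else 0.0
    is_v = depth <= -min_depth and rise_left >= min_depth / 2 and rise_right >= min_depth / 2
    cfr = None
    left_flank = right_flank = None
    if is_v:
        cut = ref + cfr_fraction * depth  # depth < 0: bins at least this delayed
        lo = vi
        while lo - 1 >= 0 and not np.isnan(sm[lo - 1]) and sm[lo - 1] <= cut:
            lo -= 1
        hi = vi
        while hi + 1 < len(sm) and not np.isnan(sm[hi + 1]) and sm[hi + 1] <= cut:
            hi += 1
        cfr = GenomicInterval(chrom, origin + lo * bin_size, origin + (hi + 1) * bin_size)
        if lo > 0:
            left_flank = GenomicInterval(chrom, origin, origin + lo * bin_size)
        if hi + 1 < len(sm):
            right_flank = GenomicInterval(
                chrom, origin + (hi + 1) * bin_size, origin + len(sm) * bin_size
            )
    vertex_bp = origin + vi * bin_size + bin_size // 2
    return VShapeResult(vertex_bp, depth, bool(is_v), left_flank, right_flank, cfr)


def v_shape_for_gene(
    delta_track: BinnedTrack,
    gene: GeneRecord,
    flank_bp: int = 500_000,
    sigma_bins: float = 2.0,
    min_depth: float = 0.5,
    cfr_fraction: float = 0.8,
) -> VShapeResult:
    """Run :func:`detect_v_shape` on a gene body plus fixed flanks."""
    bs = delta_track.bin_size
    v = delta_track.values[gene.chrom]
    b0 = gene.start // bs
    b1 = (gene.end - 1) // bs + 1
    lo = max(0, b0 - flank_bp // bs)
    hi = min(len(v), b1 + flank_bp // bs)
    window = v[lo:hi]
    return detect_v_shape(
        window,
        slice(b0 - lo, b1 - lo),
        gene.chrom,
        lo * bs,
        bs,
        sigma_bins=sigma_bins,
        min_depth=min_depth,
        cfr_fraction=cfr_fraction,
    )


def gene_rt_delay(
    gene: GeneRecord, regions: Sequence[rv.RTVariableRegion]
) -> tuple[bool, list[int], float]:
    """Does any delayed-direction variable region overlap the gene body?

    Returns (is_rt_delayed, supporting region indices, magnitude), where
    the magnitude is the most negative mean delta among overlapping
    delayed regions (NaN when none overlap).
    """
    ids = [
        i
        for i, r in enumerate(regions)
        if r.direction == rv.DELAYED and r.interval.overlaps(gene.interval)
    ]
    magnitude = min((regions[i].mean_delta for i in ids), default=np.nan)
    return bool(ids), ids, float(magnitude)


def call_fragility_signature(
    genes: Sequence[GeneRecord],
    size_table: pd.DataFrame,
    expression_table: pd.DataFrame,
    architecture_table: pd.DataFrame,
    regions: Sequence[rv.RTVariableRegion],
    delta_track: BinnedTrack | None = None,
    require_v: bool = False,
    v_flank_bp: int = 500_000,
    v_sigma_bins: float = 2.0,
    v_min_depth: float = 0.5,
    cfr_fraction: float = 0.8,
) -> tuple[list[FragilityCall], dict[str, int]]:
    """Compose the four-component fragility signature per gene.

    verdict = is_large AND highly transcribed (q3/q4) AND RT-delayed
    (>=1 delayed variable region overlapping the body) AND spans a TAD
    boundary.  When a dRT track is given, V-shape detection refines each
    candidate with a vertex/CFR (and gates the verdict if ``require_v``).
    Also returns the cohort funnel: large; large & transcribed; large &
    transcribed & delayed; final candidates.
    """
    ids = [g.gene_id for g in genes]
    for name, table in (
        ("size", size_table),
        ("expression", expression_table),
        ("architecture", architecture_table),
    ):
        missing = set(ids) - set(table["gene_id"])
        if missing:
            raise ValueError(
                f"{name} table missing genes: {sorted(missing)[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    size = size_table.set_index("gene_id")
    expr = expression_table.set_index("gene_id")
    arch = architecture_table.set_index("gene_id")
    calls: list[FragilityCall] = []
    for g in genes:
        is_large = bool(size.at[g.gene_id, "is_large"])
        is_ht = bool(expr.at[g.gene_id, "highly_transcribed"])
        spans = bool(arch.at[g.gene_id, "spans_boundary"])
        bids = list(arch.at[g.gene_id, "boundary_ids"]) if "boundary_ids" in arch.columns else []
        delayed, rids, mag = gene_rt_delay(g, regions)
        verdict = is_large and is_ht and delayed and spans
        call = FragilityCall(
            gene_id=g.gene_id,
            is_large=is_large,
            is_highly_transcribed=is_ht,
            is_rt_delayed=delayed,
            spans_boundary=spans,
            verdict=verdict,
            delay_magnitude=mag,
            supporting_regions=rids,
            boundary_ids=bids,
        )
        if delta_track is not None and verdict:
            vres = v_shape_for_gene(
                delta_track, g, v_flank_bp, v_sigma_bins, v_min_depth, cfr_fraction
            )
            call.cfr = vres.cfr
            call.v_depth = vres.depth
            call.is_v = vres.is_v
            if require_v and not vres.is_v:
                call.verdict = False
        calls.append(call)
    funnel = {
        "n_genes": len(calls),
        "large": sum(c.is_large for c in calls),
        "large_transcribed": sum(c.is_large and c.is_highly_transcribed for c in calls),
        "large_transcribed_delayed": sum(
            c.is_large and c.is_highly_transcribed and c.is_rt_delayed for c in calls
        ),
        "candidates": sum(c.verdict for c in calls),
    }
    return calls, funnel


def calls_to_frame(calls: Sequence[FragilityCall], genes: Sequence[GeneRecord]) -> pd.DataFrame:
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for c in calls:
        g = by_id[c.gene_id]
        rows.append(
            {
                "gene_id": c.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "length": g.length,
                "is_large": c.is_large,
                "is_highly_transcribed": c.is_highly_transcribed,
                "is_rt_delayed": c.is_rt_delayed,
                "spans_boundary": c.spans_boundary,
                "verdict": c.verdict,
                "delay_magnitude": c.delay_magnitude,
                "v_depth": c.v_depth,
                "is_v": c.is_v,
                "cfr_start": c.cfr.start if c.cfr else -1,
                "cfr_end": c.cfr.end if c.cfr else -1,
                "n_supporting_regions": len(c.supporting_regions),
                "n_boundaries": len(c.boundary_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "length", "is_large",
            "is_highly_transcribed", "is_rt_delayed", "spans_boundary", "verdict",
            "delay_magnitude", "v_depth", "is_v", "cfr_start", "cfr_end",
            "n_supporting_regions", "n_boundaries",
        ],
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """File inputs, thresholds and seed for a full pipeline run.

    ``early`` / ``late`` map condition ("control" / "APH") to lists of
    per-replicate bedGraph paths (same order in both).  ``nascent`` maps
    condition to a (counts bedGraph, library size) pair.  TAD boundaries
    come from a BED file or from dense contact-matrix files (one per
    chromosome).  The variability threshold defaults to the fixed
    1.0-RT-unit calibration; setting it to None estimates it instead as
    2 x SD of pairwise control-replicate differences, falling back to
    1.0 when fewer than two replicates exist.
    """

    chrom_sizes: str
    genes: str
    early: dict[str, list[str]]
    late: dict[str, list[str]]
    nascent: dict[str, tuple[str, float]]
    boundaries_bed: str | None = None
    contact_matrices: dict[str, str] | None = None
    ctcf_peaks_bed: str | None = None
    bands_tsv: str | None = None
    fragile_band_ids: list[str] = field(default_factory=list)
    out_dir: str = "fragsig_out"
    seed: int = 0
    bin_size: int = 5000
    expr_bin_size: int = 1000
    window: int = 100_000
    threshold: float | None = 1.0
    pseudocount: float = 1.0
    min_coverage: float = 10.0
    k_signatures: int = 5
    kmeans_restarts: int = 50
    large_cutoff: int = 300_000
    small_cutoff: int = 250_000
    silence_floor: float = 0.5
    matrix_bin_size: int = 25_000
    sep_window_bins: int = 10
    boundary_min_depth: float = 0.3
    boundary_min_separation: int = 4
    v_flank_bp: int = 500_000
    v_sigma_bins: float = 2.0
    v_min_depth: float = 0.5
    cfr_fraction: float = 0.8
    require_v: bool = False
    enrichment_iterations: int = 0  # 0 disables the CTCF shuffle test


@dataclass
class PipelineResult:
    genes: list[GeneRecord]
    profiles: list[rs.RTProfile]
    windows: list[rv.RTWindow]
    regions: list[rv.RTVariableRegion]
    signatures: list[rv.RTSignature]
    calls: list[FragilityCall]
    funnel: dict[str, int]
    threshold: float
    out_dir: Path
    band_summary: dict | None = None
    enrichment: ta.EnrichmentResult | None = None


def _load_profiles(cfg: PipelineConfig, genome: iog.GenomeTable) -> list[rs.RTProfile]:
    profiles = []
    for condition in (rs.CONTROL, rs.APH):
        early_paths = cfg.early.get(condition, [])
        late_paths = cfg.late.get(condition, [])
        if len(early_paths) != len(late_paths):
            raise ValueError(f"{condition}: early/late replicate counts differ")
        for rep, (ep, lp) in enumerate(zip(early_paths, late_paths)):
            e = iog.read_bedgraph(ep, genome, cfg.bin_size)
            l = iog.read_bedgraph(lp, genome, cfg.bin_size)
            profiles.append(
                rs.compute_rt_profile(
                    e, l, cfg.pseudocount, cfg.min_coverage,
                    sample_id=f"{condition}_{rep + 1}", condition=condition, replicate=rep,
                )
            )
    return profiles


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full fragility-mapping pipeline from files to reports.

    Stages: RT profiling -> quantile normalization -> RT variability
    (windows, regions, signatures) -> expression quantification and
    classification -> TAD boundaries and gene architecture -> fragility
    signature calls with CFRs.  Every output table is written with fixed
    formatting, so a rerun with identical config and seed is
    byte-identical.  A stage failure aborts with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        genome = iog.GenomeTable.from_file(cfg.chrom_sizes)
        genes = iog.read_gene_annotation(cfg.genes, "bed12")

        stage = "repliseq"
        profiles = _load_profiles(cfg, genome)
        profiles = rs.quantile_normalize(profiles)
        ctrl_profiles = [p for p in profiles if p.condition == rs.CONTROL]
        aph_profiles = [p for p in profiles if p.condition == rs.APH]
        ctrl_mean = rs.condition_mean(profiles, rs.CONTROL)
        aph_mean = rs.condition_mean(profiles, rs.APH)
        delta = rs.delta_track(ctrl_mean, aph_mean)
        for name, track in (
            ("rt_control_mean", ctrl_mean),
            ("rt_aph_mean", aph_mean),
            ("rt_delta", delta),
        ):
            iog.write_bedgraph(track, out / f"{name}.bedgraph")
        trisection = rs.trisect_rt(
            rs.RTProfile(ctrl_mean, "control_mean", rs.CONTROL)
        )

        stage = "rt_variability"
        threshold = cfg.threshold
        if threshold is None:
            if len(ctrl_profiles) >= 2:
                threshold = rv.estimate_variability_threshold(ctrl_profiles, cfg.window)
            else:
                threshold = 1.0
        windows = rv.detect_variable_windows(
            ctrl_profiles, aph_profiles, cfg.window, threshold
        )
        regions = rv.merge_contiguous(windows)
        n_flagged = sum(w.flagged for w in windows)
        k = min(cfg.k_signatures, n_flagged)
        signatures = (
            rv.cluster_rt_signatures(windows, k, cfg.kmeans_restarts, cfg.seed)
            if k >= 1
            else []
        )

        stage = "transcription"
        counts_path, lib = cfg.nascent[rs.CONTROL]
        counts = iog.read_bedgraph(counts_path, genome, cfg.expr_bin_size)
        # bedGraph averaging recovers per-bin counts; NaN bins carry no reads
        for chrom in genome:
            v = counts.values[chrom]
            counts.values[chrom] = np.where(np.isnan(v), 0.0, v)
        expr = tx.quantify_expression(counts, lib, genes, rs.CONTROL, cfg.silence_floor)
        expr = tx.classify_quartiles(expr)
        sizes = tx.classify_sizes(genes, cfg.large_cutoff, cfg.small_cutoff)

        stage = "tad_architecture"
        if cfg.boundaries_bed:
            boundaries = ta.boundaries_from_bed(iog.read_bed(cfg.boundaries_bed))
        elif cfg.contact_matrices:
            boundaries = []
            for chrom, mpath in cfg.contact_matrices.items():
                cm = ta.ContactMatrix.from_dense_file(mpath, chrom, cfg.matrix_bin_size)
                score = ta.separation_score(cm, cfg.sep_window_bins)
                boundaries.extend(
                    ta.call_boundaries(
                        score, chrom, cfg.matrix_bin_size,
                        cfg.boundary_min_depth, cfg.boundary_min_separation,
                    )
                )
            boundaries.sort(key=lambda b: (b.interval.chrom, b.interval.start))
        else:
            raise ValueError("need boundaries_bed or contact_matrices")
        arch = ta.classify_gene_architecture(genes, boundaries)
        enrichment = None
        if cfg.ctcf_peaks_bed and cfg.enrichment_iterations > 0:
            peaks_df = iog.read_bed(cfg.ctcf_peaks_bed)
            peaks = [
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in peaks_df.itertuples()
            ]
            enrichment = ta.ctcf_boundary_enrichment(
                peaks, boundaries, genome, cfg.enrichment_iterations, cfg.seed
            )

        stage = "fragility"
        calls, funnel = call_fragility_signature(
            genes, sizes, expr, arch, regions, delta,
            require_v=cfg.require_v, v_flank_bp=cfg.v_flank_bp,
            v_sigma_bins=cfg.v_sigma_bins, v_min_depth=cfg.v_min_depth,
            cfr_fraction=cfg.cfr_fraction,
        )

        stage = "report"
        band_summary = None
        if cfg.bands_tsv:
            bands = iog.read_tsv(cfg.bands_tsv)
            region_rt = [
                _region_mean(ctrl_mean, r.interval) for r in regions
            ]
            per_band, band_summary = rv.annotate_bands(
                regions, bands, cfg.fragile_band_ids, region_rt,
                (trisection.early_cut, trisection.late_cut),
            )
            iog.write_interval_table(per_band, out / "band_summary.tsv", "tsv")
        _write_reports(cfg, out, genes, windows, regions, signatures, calls, funnel,
                       threshold, trisection, band_summary, enrichment)
        return PipelineResult(
            genes, profiles, windows, regions, signatures, calls, funnel,
            float(threshold), out, band_summary, enrichment,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _region_mean(track: BinnedTrack, iv: GenomicInterval) -> float:
    bs = track.bin_size
    seg = track.values[iv.chrom][iv.start // bs : (iv.end - 1) // bs + 1]
    return float(np.nanmean(seg)) if not np.all(np.isnan(seg)) else np.nan


def _score_from_delay(mag: float) -> int:
    if np.isnan(mag):
        return 0
    return int(np.clip(abs(mag) * 100, 0, 1000))


def _write_reports(cfg, out, genes, windows, regions, signatures, calls, funnel,
                   threshold, trisection, band_summary, enrichment) -> None:
    ev = calls_to_frame(calls, genes)
    iog.write_interval_table(ev, out / "gene_evidence.tsv", "tsv")
    cand = ev[ev["verdict"]].copy()
    cand["name"] = cand["gene_id"]
    cand["score"] = [
        _score_from_delay(m) for m in cand["delay_magnitude"]
    ]
    iog.write_interval_table(
        cand[["chrom", "start", "end", "name", "score"]], out / "candidates.bed", "bed"
    )
    win_df = pd.DataFrame(
        {
            "chrom": [w.interval.chrom for w in windows],
            "start": [w.interval.start for w in windows],
            "end": [w.interval.end for w in windows],
            "name": [f"window_{w.index}" for w in windows],
            "score": [int(np.clip(abs(w.delta) * 100, 0, 1000)) if np.isfinite(w.delta) else 0 for w in windows],
            "delta": [w.delta for w in windows],
            "flagged": [w.flagged for w in windows],
        }
    )
    iog.write_interval_table(
        win_df[win_df["flagged"]][["chrom", "start", "end", "name", "score"]],
        out / "variable_windows.bed",
        "bed",
    )
    reg_df = pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "direction": [r.direction for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "mean_delta": [r.mean_delta for r in regions],
        }
    )
    iog.write_interval_table(reg_df, out / "regions.tsv", "tsv")
    sig_df = pd.DataFrame(
        {
            "cluster_id": [s.cluster_id for s in signatures],
            "label": [s.label for s in signatures],
            "n_windows": [len(s.member_windows) for s in signatures],
            "p_value": [s.p_value for s in signatures],
            "p_adjusted": [s.p_adjusted for s in signatures],
        }
    )
    sig_df.to_csv(out / "signatures.tsv", sep="\t", index=False, float_format=iog.FLOAT_FMT)
    funnel_df = pd.DataFrame(
        {"cohort": list(funnel.keys()), "count": list(funnel.values())}
    )
    funnel_df.to_csv(out / "funnel.tsv", sep="\t", index=False)
    log = {
        "seed": cfg.seed,
        "threshold_rt_units": float(threshold),
        "trisection_cuts": [trisection.early_cut, trisection.late_cut],
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if isinstance(v, (int, float, str, bool, type(None)))
        },
        "n_flagged_windows": int(sum(w.flagged for w in windows)),
        "n_regions": len(regions),
        "n_delayed_regions": int(sum(r.direction == rv.DELAYED for r in regions)),
        "funnel": funnel,
    }
    if band_summary is not None:
        log["band_summary"] = band_summary
    if enrichment is not None:
        log["ctcf_enrichment"] = {
            "observed": enrichment.observed,
            "null_mean": enrichment.null_mean,
            "fold": enrichment.fold,
            "p_value": enrichment.p_value,
        }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
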