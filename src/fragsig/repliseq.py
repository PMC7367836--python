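"""Replication-timing (RT) profiles from early/late S-phase read counts.

The RT value of a genomic bin is log2(early/late) of its read counts;
positive values mean early replication.  This module builds per-sample RT
profiles, makes them comparable by rank-based quantile normalization,
smooths them, summarises sample relationships (correlation matrix and a
two-component PCA projection), trisects S phase into early/mid/late by
genome-wide tertiles, and computes size-sorted metagene RT matrices in
which every gene body is stretched to a common number of columns flanked
by fixed-width native-resolution flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .io_genomics import BinnedTrack, GeneRecord

logger = logging.getLogger(__name__)

CONTROL = "control"
APH = "APH"


@dataclass
class RTProfile:
    """One sample's RT track: log2(early/late) per fixed-width bin."""

    track: BinnedTrack
    sample_id: str
    condition: str = CONTROL
    replicate: int = 0

    def copy(self) -> "RTProfile":
        return RTProfile(self.track.copy(), self.sample_id, self.condition, self.replicate)


@dataclass
class SPhaseFractionLabel:
    """Per-bin early/mid/late label plus the two RT cut points used.

    ``early_cut`` and ``late_cut`` live on the RT scale with
    early_cut > late_cut; early bins have RT >= early_cut, late bins
    RT <= late_cut.  Labels are stored as one character per bin
    ('E'/'M'/'L', masked bins '.').
    """

    labels: dict[str, np.ndarray]
    early_cut: float
    late_cut: float

    def counts(self) -> dict[str, int]:
        flat = np.concatenate(list(self.labels.values()))
        return {
            "early": int((flat == "E").sum()),
            "mid": int((flat == "M").sum()),
            "late": int((flat == "L").sum()),
        }


@dataclass
class MetageneMatrix:
    """Genes x (flank | stretched body | flank) matrix of mean RT (or dRT).

    Rows are sorted by gene length descending; the body occupies the same
    column span for every row.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    gene_lengths: list[int]
    body_bins: int
    flank_bins: int

    @property
    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)


def compute_rt_profile(
    early: BinnedTrack,
    late: BinnedTrack,
    pseudocount: float = 1.0,
    min_coverage: float = 10.0,
    sample_id: str = "sample",
    condition: str = CONTROL,
    replicate: int = 0,
) -> RTProfile:
    """RT = log2((early + pseudocount) / (late + pseudocount)) per bin.

    Bins whose combined early+late count falls below ``min_coverage`` are
    masked (log-ratios in read deserts are dominated by shot noise).
    Swapping the early and late tracks negates every unmasked value.
    """
    if not early.compatible_with(late):
        raise ValueError("early and late tracks must share genome and bin size")
    out = BinnedTrack.allocate(early.genome, early.bin_size)
    for chrom in early.genome:
        e = early.values[chrom]
        l = late.values[chrom]
        if np.nanmin(e, initial=0.0) < 0 or np.nanmin(l, initial=0.0) < 0:
            raise ValueError(f"negative read counts on {chrom}")
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.log2((e + pseudocount) / (l + pseudocount))
        v[np.isnan(e) | np.isnan(l)] = np.nan
        v[(e + l) < min_coverage] = np.nan
        out.values[chrom] = v
    return RTProfile(out, sample_id, condition, replicate)


def joint_unmasked(profiles: Sequence[RTProfile]) -> np.ndarray:
    """Boolean flat mask of bins unmasked in every profile."""
    ok = ~np.isnan(profiles[0].track.flat())
    for p in profiles[1:]:
        ok &= ~np.isnan(p.track.flat())
    return ok


def quantile_normalize(profiles: Sequence[RTProfile]) -> list[RTProfile]:
    """Rank-based quantile normalization across samples.

    Each profile's unmasked values (restricted to jointly unmasked bins)
    are replaced by the rank-matched mean quantile across all profiles,
    so every output profile has the identical sorted value vector while
    within-profile rank order is preserved exactly.
    """
    if len(profiles) < 2:
        raise ValueError("quantile normalization needs >= 2 profiles")
    for p in profiles[1:]:
        if not p.track.compatible_with(profiles[0].track):
            raise ValueError("profiles must share genome and bin size")
    ok = joint_unmasked(profiles)
    mat = np.stack([p.track.flat()[ok] for p in profiles])
    order = np.argsort(mat, axis=1, kind="stable")
    mean_sorted = np.sort(mat, axis=1).mean(axis=0)
    out: list[RTProfile] = []
    for i, p in enumerate(profiles):
        new = p.copy()
        flat = np.full(len(ok), np.nan)
        vals = np.empty(mat.shape[1])
        vals[order[i]] = mean_sorted
        flat[ok] = vals
        new.track.set_flat(flat)
        out.append(new)
    return out


def _smooth_array(v: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing applied independently to each unmasked run."""
    if sigma_bins < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_bins == 0:
        return v.copy()
    out = np.full_like(v, np.nan)
    ok = ~np.isnan(v)
    if not ok.any():
        return out
    # contiguous unmasked runs: smoothing never leaks across masked gaps
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        out[s:e] = gaussian_filter1d(v[s:e], sigma_bins, mode="reflect")
    return out


def smooth_profile(profile: RTProfile, sigma_bins: float) -> RTProfile:
    """Gaussian kernel smoothing over unmasked runs (sigma 0 = identity).

    Masked bins neither contribute to nor receive smoothed values.
    """
    new = profile.copy()
    for chrom in new.track.genome:
        new.track.values[chrom] = _smooth_array(new.track.values[chrom], sigma_bins)
    return new


def correlate_profiles(
    profiles: Sequence[RTProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlation matrix and 2-component PCA projection.

    Restricted to jointly unmasked bins.  A constant profile has an
    undefined correlation; its off-diagonal entries are reported as NaN.
    The projection holds the first two principal components of the
    profile-by-bin matrix after bin-wise mean centering.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    ok = joint_unmasked(profiles)
    mat = np.stack([p.track.flat()[ok] for p in profiles])
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    const = sd == 0
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    n_comp = min(2, len(profiles), mat.shape[1])
    proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(mat)
    if n_comp < 2:
        proj = np.pad(proj, ((0, 0), (0, 2 - n_comp)))
    return corr, proj


def trisect_rt(
    profile: RTProfile,
    method: str = "tertiles",
    cuts: tuple[float, float] | None = None,
) -> SPhaseFractionLabel:
    """Partition unmasked bins into early / mid / late S phase.

    ``tertiles`` assigns the top third of genome-wide RT values to early
    and the bottom third to late by rank (so the three label counts agree
    with N/3 to within one bin even for skewed distributions); the
    resulting boundary values are reported as the cut points.
    ``fixed_cuts`` labels by the supplied ``(early_cut, late_cut)``.
    """
    labels = {c: np.full(len(v), ".", dtype="<U1") for c, v in profile.track.values.items()}
    flat = profile.track.flat()
    ok = ~np.isnan(flat)
    vals = flat[ok]
    lab_flat = np.full(len(flat), ".", dtype="<U1")
    if method == "tertiles":
        if len(vals) == 0:
            early_cut, late_cut = np.nan, np.nan
        elif np.all(vals == vals[0]):
            logger.warning("degenerate RT distribution: all bins labeled mid")
            lab_flat[ok] = "M"
            early_cut, late_cut = vals[0], vals[0]
        else:
            n = len(vals)
            n_late = int(round(n / 3))
            n_early = int(round(n / 3))
            order = np.argsort(vals, kind="stable")
            lab = np.full(n, "M", dtype="<U1")
            lab[order[:n_late]] = "L"
            lab[order[n - n_early:]] = "E"
            late_cut = float(vals[order[n_late - 1]]) if n_late else float("-inf")
            early_cut = float(vals[order[n - n_early]]) if n_early else float("inf")
            lab_flat[ok] = lab
    elif method == "fixed_cuts":
        if cuts is None:
            raise ValueError("fixed_cuts requires cuts=(early_cut, late_cut)")
        early_cut, late_cut = cuts
        if not early_cut > late_cut:
            raise ValueError("require early_cut > late_cut")
        lab = np.full(len(vals), "M", dtype="<U1")
        lab[vals >= early_cut] = "E"
        lab[vals <= late_cut] = "L"
        lab_flat[ok] = lab
    else:
        raise ValueError(f"unknown trisection method {method!r}")
    off = 0
    for chrom in profile.track.genome:
        n = len(profile.track.values[chrom])
        labels[chrom] = lab_flat[off : off + n]
        off += n
    return SPhaseFractionLabel(labels, float(early_cut), float(late_cut))


def metagene_rt(
    track: BinnedTrack,
    genes: Sequence[GeneRecord],
    body_bins: int = 100,
    flank_bp: int = 1_000_000,
) -> MetageneMatrix:
    """Size-sorted metagene matrix of a binned RT (or dRT) signal.

    Each gene body is linearly resampled to ``body_bins`` columns (so a
    linear ramp over the body stays a linear ramp with identical
    endpoints); flanks are taken at native bin resolution for
    ``flank_bp`` on each side and masked where they run off the
    chromosome.  Rows are ordered largest gene first.
    """
    bs = track.bin_size
    flank_bins = flank_bp // bs
    order = sorted(range(len(genes)), key=lambda i: (-genes[i].length, genes[i].gene_id))
    rows = []
    ids, lengths = [], []
    for i in order:
        g = genes[i]
        if g.length < bs:
            raise ValueError(f"gene {g.gene_id} shorter than one bin")
        v = track.values[g.chrom]
        nb = len(v)
        b0 = g.start // bs
        b1 = (g.end - 1) // bs + 1  # bins overlapping the body
        body_src = v[max(b0, 0) : min(b1, nb)]
        if len(body_src) == 1:
            body = np.full(body_bins, body_src[0])
        else:
            x_src = np.arange(len(body_src), dtype=float)
            x_tgt = np.linspace(0, len(body_src) - 1, body_bins)
            if np.isnan(body_src).any():
                okb = ~np.isnan(body_src)
                if okb.sum() >= 2:
                    body = np.interp(x_tgt, x_src[okb], body_src[okb])
                elif okb.sum() == 1:
                    body = np.full(body_bins, body_src[okb][0])
                else:
                    body = np.full(body_bins, np.nan)
            else:
                body = np.interp(x_tgt, x_src, body_src)
        left = np.full(flank_bins, np.nan)
        src_lo = b0 - flank_bins
        take = v[max(src_lo, 0) : b0]
        if len(take):
            left[flank_bins - len(take) :] = take
        right = np.full(flank_bins, np.nan)
        take = v[b1 : min(b1 + flank_bins, nb)]
        if len(take):
            right[: len(take)] = take
        rows.append(np.concatenate([left, body, right]))
        ids.append(g.gene_id)
        lengths.append(g.length)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * flank_bins + body_bins))
    return MetageneMatrix(matrix, ids, lengths, body_bins, flank_bins)


def condition_mean(profiles: Sequence[RTProfile], condition: str) -> BinnedTrack:
    """Mean RT track over the replicates of one condition (NaN-aware)."""
    sel = [p for p in profiles if p.condition == condition]
    if not sel:
        raise ValueError(f"no profiles with condition {condition!r}")
    out = BinnedTrack.allocate(sel[0].track.genome, sel[0].track.bin_size)
    for chrom in out.genome:
        stack = np.stack([p.track.values[chrom] for p in sel])
        with np.errstate(invalid="ignore"):
            out.values[chrom] = np.nanmean(stack, axis=0)
    return out


def delta_track(ctrl_mean: BinnedTrack, aph_mean: BinnedTrack) -> BinnedTrack:
    """Per-bin RT change, mean(APH) - mean(control); negative = delayed."""
    if not ctrl_mean.compatible_with(aph_mean):
        raise ValueError("tracks must share genome and bin size")
    out = BinnedTrack.allocate(ctrl_mean.genome, ctrl_mean.bin_size)
    for chrom in out.genome:
        out.values[chrom] = aph_mean.values[chrom] - ctrl_mean.values[chrom]
    return out
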