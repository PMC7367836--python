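"""TAD boundaries from contact matrices and architecture classification.

Boundaries are called from a binned chromatin contact matrix via a
diamond separation score: for each bin the mean contact frequency of the
window_bins x window_bins block linking the upstream window to the
downstream window, expressed as a log2 ratio to the chromosome-wide mean
of that statistic.  Insulating positions (TAD boundaries) are local
minima of the score.  External boundary BED files can be used as a
bypass for matrices processed elsewhere.

Also provided: classification of genes as TAD-boundary-spanning versus
intra-TAD (a gene spans a boundary when a boundary midpoint lies in the
strict interior of its body), CTCF peak overlap per gene, and a
shuffle-based enrichment test of CTCF binding at boundaries with an
empirical permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_genomics import GenomeTable, GenomicInterval, GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact matrix for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if m.size == 0:
            raise ValueError("empty contact matrix")
        if not np.allclose(m, m.T, rtol=1e-6, atol=1e-8, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(m) < 0:
            raise ValueError("contact matrix must be non-negative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_dense_file(cls, path: str | Path, chrom: str, bin_size: int) -> "ContactMatrix":
        return cls(chrom, bin_size, np.loadtxt(path, ndmin=2))

    def to_dense_file(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, fmt="%.10g", delimiter="\t")

    @classmethod
    def from_triplet_file(cls, path: str | Path, chrom: str, bin_size: int) -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "value"])
        n = int(max(df["i"].max(), df["j"].max())) + 1
        m = np.zeros((n, n))
        m[df["i"], df["j"]] = df["value"]
        m[df["j"], df["i"]] = df["value"]
        return cls(chrom, bin_size, m)


@dataclass
class TADBoundary:
    """A boundary bin with its separation score (lower = stronger)."""

    interval: GenomicInterval
    score: float

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class EnrichmentResult:
    """Observed-versus-shuffled overlap of boundaries with a peak set."""

    observed: int
    null_mean: float
    null_sd: float
    fold: float
    p_value: float
    n_iterations: int
    seed: int | None
    null_counts: np.ndarray | None = None


def separation_score(
    cm: ContactMatrix,
    window_bins: int = 10,
    multi_window: bool = False,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Per-bin diamond separation score (log2 ratio to chromosome mean).

    score(i) = log2(mean of matrix[i-w:i, i:i+w] / chromosome-wide mean of
    that diamond statistic).  Bins within ``window_bins`` of either end
    are masked (NaN).  The score is invariant to global scaling of the
    matrix; a uniform matrix scores 0 everywhere.  With ``multi_window``
    the mean of single-window scores over {w, 2w, 3w} is returned (each
    component masked at its own edges).
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if cm.n_bins < 2 * window_bins + 1:
        raise ValueError("matrix too small for this window")
    if multi_window:
        comps = []
        for w in (window_bins, 2 * window_bins, 3 * window_bins):
            if cm.n_bins >= 2 * w + 1:
                comps.append(separation_score(cm, w, False, pseudocount))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
            return np.nanmean(np.stack(comps), axis=0)
    m = cm.matrix + pseudocount
    n = cm.n_bins
    w = window_bins
    # summed-area table for O(1) diamond sums
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
    score = np.full(n, np.nan)
    means = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        r0, r1 = i - w, i
        c0, c1 = i, i + w
        total = sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]
        means[i] = total / (w * w)
    valid = ~np.isnan(means)
    global_mean = means[valid].mean()
    if global_mean <= 0:
        raise ValueError("contact matrix has no signal in the scored region")
    with np.errstate(divide="ignore"):
        score[valid] = np.log2(means[valid] / global_mean)
    return score


def call_boundaries(
    score: np.ndarray,
    chrom: str,
    bin_size: int,
    min_depth: float = 0.3,
    min_separation_bins: int = 4,
) -> list[TADBoundary]:
    """TAD boundaries as prominent local minima of the separation score.

    Minima need topographic prominence >= ``min_depth`` and are kept
    greedily by depth, at least ``min_separation_bins`` apart.  An empty
    list (e.g. a flat score) is a valid result.
    """
    score = np.asarray(score, dtype=float)
    ok = ~np.isnan(score)
    if not ok.any():
        return []
    idx = np.flatnonzero(ok)
    lo, hi = idx[0], idx[-1] + 1
    seg = score[lo:hi].copy()
    if np.isnan(seg).any():  # interior gaps: fill high so no minimum is created
        fill = np.nanmax(seg) + 10 * max(min_depth, 1.0)
        seg = np.where(np.isnan(seg), fill, seg)
    finite_min = seg[np.isfinite(seg)].min() if np.isfinite(seg).any() else 0.0
    seg = np.where(np.isneginf(seg), finite_min - 10 * max(min_depth, 1.0), seg)
    peaks, _props = find_peaks(-seg, prominence=min_depth, distance=max(1, min_separation_bins))
    out = []
    for p in sorted(peaks):
        b = lo + int(p)
        out.append(
            TADBoundary(
                GenomicInterval(chrom, b * bin_size, (b + 1) * bin_size),
                float(score[b]),
            )
        )
    return out


def boundaries_from_bed(df: pd.DataFrame) -> list[TADBoundary]:
    """Adapt an external boundary BED (score column optional)."""
    out = []
    for _, r in df.iterrows():
        score = float(r["score"]) if "score" in df.columns and not pd.isna(r.get("score")) else np.nan
        out.append(TADBoundary(GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])), score))
    return sorted(out, key=lambda b: (b.interval.chrom, b.interval.start))


def classify_gene_architecture(
    genes: Sequence[GeneRecord], boundaries: Sequence[TADBoundary]
) -> pd.DataFrame:
    """Flag each gene boundary-spanning or intra-TAD.

    A gene spans a boundary iff at least one boundary midpoint lies
    strictly inside the gene body (start < midpoint < end); a midpoint
    exactly at the gene start or end does not count.  The two flags
    partition the gene set.
    """
    mids: dict[str, np.ndarray] = {}
    bidx: dict[str, np.ndarray] = {}
    for chrom in {b.interval.chrom for b in boundaries}:
        pairs = [(b.midpoint, i) for i, b in enumerate(boundaries) if b.interval.chrom == chrom]
        pairs.sort()
        mids[chrom] = np.array([m for m, _ in pairs])
        bidx[chrom] = np.array([i for _, i in pairs])
    rows = []
    for g in genes:
        if g.chrom in mids:
            m = mids[g.chrom]
            lo = np.searchsorted(m, g.start, side="right")  # first mid > start
            hi = np.searchsorted(m, g.end, side="left")  # mids < end
            # exclude a midpoint exactly at end (side='left' already does)
            ids = bidx[g.chrom][lo:hi].tolist()
        else:
            ids = []
        rows.append(
            {
                "gene_id": g.gene_id,
                "spans_boundary": len(ids) > 0,
                "boundary_ids": ids,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "spans_boundary", "boundary_ids"])


def _overlap_any(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> np.ndarray:
    """For each query interval, does any subject interval overlap it?

    Sorted-scan implementation: subjects sorted by start with a running
    maximum of ends, so 'exists subject with start < q.end and
    end > q.start' becomes two binary searches.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in subject}:
        subs = sorted((s.start, s.end) for s in subject if s.chrom == chrom)
        starts = np.array([s for s, _ in subs])
        ends = np.array([e for _, e in subs])
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    out = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        if q.chrom not in by_chrom:
            continue
        starts, run_max_end = by_chrom[q.chrom]
        k = np.searchsorted(starts, q.end, side="left")  # subjects with start < q.end
        out[i] = k > 0 and run_max_end[k - 1] > q.start
    return out


def ctcf_gene_binding(
    genes: Sequence[GeneRecord], peaks: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-gene flag: >=1 peak overlaps the gene body."""
    bound = _overlap_any([g.interval for g in genes], peaks)
    return pd.DataFrame({"gene_id": [g.gene_id for g in genes], "ctcf_bound": bound})


def _allowed_segments(
    genome: GenomeTable, exclude: Sequence[GenomicInterval]
) -> dict[str, list[tuple[int, int]]]:
    segs: dict[str, list[tuple[int, int]]] = {}
    for chrom in genome:
        zones = sorted(
            (iv.start, iv.end) for iv in exclude if iv.chrom == chrom
        )
        merged: list[list[int]] = []
        for s, e in zones:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out, pos = [], 0
        for s, e in merged:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < genome[chrom]:
            out.append((pos, genome[chrom]))
        segs[chrom] = out
    return segs


def _place_nonoverlapping(
    sizes: np.ndarray,
    segments: list[tuple[int, int]],
    rng: np.random.Generator,
    max_retries: int = 200,
) -> np.ndarray:
    """Place intervals uniformly at random in the allowed segments,
    mutually non-overlapping; returns start positions (same order as
    ``sizes``).  Colliding intervals are re-drawn up to ``max_retries``
    sweeps."""
    sizes = np.asarray(sizes, dtype=np.int64)
    seg_start = np.array([s for s, _ in segments], dtype=np.int64)
    seg_len = np.array([e - s for s, e in segments], dtype=np.int64)
    starts = np.full(len(sizes), -1, dtype=np.int64)
    pending = np.arange(len(sizes))
    equal = len(sizes) > 0 and np.all(sizes == sizes[0])
    for _sweep in range(max_retries):
        if len(pending) == 0:
            return starts
        if equal:
            cap = np.maximum(0, seg_len - sizes[0]).astype(float)
            if cap.sum() <= 0:
                raise ValueError("no room to place interval in allowed segments")
            seg_choice = rng.choice(len(segments), size=len(pending), p=cap / cap.sum())
        else:
            seg_choice = np.empty(len(pending), dtype=int)
            for j, gi in enumerate(pending):
                cap = np.maximum(0, seg_len - sizes[gi]).astype(float)
                if cap.sum() <= 0:
                    raise ValueError("no room to place interval in allowed segments")
                seg_choice[j] = rng.choice(len(segments), p=cap / cap.sum())
        room = seg_len[seg_choice] - sizes[pending]
        starts[pending] = seg_start[seg_choice] + (
            rng.random(len(pending)) * (room + 1)
        ).astype(np.int64)
        # reject mutual overlaps: keep leftmost of each collision, retry rest
        order = np.argsort(starts, kind="stable")
        last_end = -1
        for gi in order:
            if starts[gi] < last_end:
                starts[gi] = -1
            else:
                last_end = starts[gi] + sizes[gi]
        pending = np.flatnonzero(starts < 0)
    raise ValueError("could not place intervals without overlap (genome too full)")


def ctcf_boundary_enrichment(
    peaks: Sequence[GenomicInterval],
    boundaries: Sequence[TADBoundary],
    genome: GenomeTable,
    n_iter: int = 1000,
    seed: int | None = None,
    chrom_constrained: bool = True,
    keep_null: bool = False,
) -> EnrichmentResult:
    """Permutation test of CTCF-peak overlap at TAD boundaries.

    Observed statistic: number of boundaries overlapping >=1 peak.  Each
    null iteration places size-matched random intervals uniformly,
    mutually non-overlapping, excluding the observed boundary loci
    (and, when ``chrom_constrained``, keeping each interval on its own
    chromosome).  The empirical p uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_iter), so p is never 0; fold is
    observed / null mean.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    b_ivs = [b.interval for b in boundaries]
    observed = int(_overlap_any(b_ivs, peaks).sum())
    rng = np.random.default_rng(seed)
    # pre-sort peaks per chromosome once for fast overlap counting
    peak_sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = sorted((p.start, p.end) for p in peaks if p.chrom == chrom)
        starts = np.array([s for s, _ in ps])
        ends = np.maximum.accumulate(np.array([e for _, e in ps]))
        peak_sorted[chrom] = (starts, ends)
    segs_by_chrom = _allowed_segments(genome, b_ivs)
    if chrom_constrained:
        groups = [(c, np.array([iv.length for iv in b_ivs if iv.chrom == c])) for c in genome]
        groups = [(c, sz) for c, sz in groups if len(sz)]
    else:
        all_segs = [
            (chrom, s, e) for chrom in genome for s, e in segs_by_chrom[chrom]
        ]
    null_counts = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        count = 0
        if chrom_constrained:
            for chrom, sizes in groups:
                starts = _place_nonoverlapping(sizes, segs_by_chrom[chrom], rng)
                count += _count_overlapping(chrom, starts, sizes, peak_sorted)
        else:
            sizes = np.array([iv.length for iv in b_ivs])
            virtual = [(0, sum(e - s for _, s, e in all_segs))]
            # virtual concatenated space; map back to (chrom, offset)
            starts_v = _place_nonoverlapping(sizes, virtual, rng)
            cum = 0
            bounds_v = []
            for chrom, s, e in all_segs:
                bounds_v.append((cum, cum + (e - s), chrom, s))
                cum += e - s
            for sv, size in zip(starts_v, sizes):
                for v0, v1, chrom, s0 in bounds_v:
                    if v0 <= sv < v1:
                        start = s0 + (sv - v0)
                        count += _count_overlapping(
                            chrom, np.array([start]), np.array([size]), peak_sorted
                        )
                        break
        null_counts[it] = count
    null_mean = float(null_counts.mean())
    p = float((1 + (null_counts >= observed).sum()) / (1 + n_iter))
    if observed == 0:
        fold = 0.0
    elif null_mean == 0:
        fold = float("inf")
    else:
        fold = observed / null_mean
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=float(null_counts.std(ddof=1)) if n_iter > 1 else 0.0,
        fold=fold,
        p_value=p,
        n_iterations=n_iter,
        seed=seed,
        null_counts=null_counts if keep_null else None,
    )


def _count_overlapping(
    chrom: str,
    starts: np.ndarray,
    sizes: np.ndarray,
    peak_sorted: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    if chrom not in peak_sorted:
        return 0
    pstarts, run_max_end = peak_sorted[chrom]
    k = np.searchsorted(pstarts, starts + sizes, side="left")
    hit = (k > 0) & (run_max_end[np.maximum(k - 1, 0)] > starts)
    return int(hit.sum())
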