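"""Detection of replication-stress-responsive RT regions.

The genome is segmented into fixed windows (100 kb by default), each
summarised by the mean of its RT bins per sample.  A window is called
RT-variable when the condition-mean RT change exceeds a threshold — by
default 1 RT unit, the calibration obtained as two standard deviations of
pairwise technical-replicate differences — and every cross-condition
replicate pair agrees on the sign of the change.  Contiguous same-direction
windows are merged into differentially replicated regions, the variable
windows are clustered into k RT signatures by k-means, and regions are
summarised against cytogenetic band / fragile-band tables.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_genomics import BinnedTrack, GenomicInterval
from .repliseq import APH, CONTROL, RTProfile

logger = logging.getLogger(__name__)

DELAYED = "delayed"
ADVANCED = "advanced"


@dataclass
class RTWindow:
    """One fixed genomic window with per-sample mean RT values."""

    interval: GenomicInterval
    sample_means: np.ndarray  # order: ctrl replicates then APH replicates
    n_ctrl: int
    ctrl_mean: float
    aph_mean: float
    delta: float  # mean(APH) - mean(control); negative = delayed
    masked_frac: float
    flagged: bool
    index: int = -1

    @property
    def direction(self) -> str:
        return DELAYED if self.delta < 0 else ADVANCED


@dataclass
class RTVariableRegion:
    """Maximal run of adjacent flagged windows sharing a direction."""

    interval: GenomicInterval
    direction: str
    n_windows: int
    mean_delta: float
    member_windows: list[int] = field(default_factory=list)


@dataclass
class RTSignature:
    """One k-means cluster of RT-variable windows."""

    cluster_id: int
    member_windows: list[int]
    centroid: np.ndarray
    label: str
    p_value: float
    p_adjusted: float


def window_means(
    track: BinnedTrack, window: int
) -> tuple[list[GenomicInterval], np.ndarray, np.ndarray]:
    """Mean of the track's bins per fixed window, plus masked fraction.

    Window size must be a multiple of the bin size so windows tile the
    bin grid exactly.
    """
    if window % track.bin_size != 0:
        raise ValueError("window size must be a multiple of the bin size")
    per = window // track.bin_size
    intervals: list[GenomicInterval] = []
    means: list[float] = []
    fracs: list[float] = []
    for chrom in track.genome:
        v = track.values[chrom]
        clen = track.genome[chrom]
        n_win = len(v) // per  # trailing partial window dropped
        for w in range(n_win):
            seg = v[w * per : (w + 1) * per]
            masked = np.isnan(seg)
            fracs.append(masked.mean())
            means.append(float(np.nanmean(seg)) if not masked.all() else np.nan)
            intervals.append(GenomicInterval(chrom, w * window, min((w + 1) * window, clen)))
    return intervals, np.asarray(means), np.asarray(fracs)


def estimate_variability_threshold(
    profiles: Sequence[RTProfile], window: int = 100_000
) -> float:
    """Two standard deviations of pooled pairwise replicate differences.

    Technical replicates of a single condition are summarised as window
    means; differences over all within-condition replicate pairs are
    pooled and the threshold returned is 2 x their standard deviation
    (the calibration that yields ~1 RT unit for real technical repeats).
    With fewer than two replicates the caller should fall back to the
    fixed 1.0 RT-unit threshold.
    """
    if len(profiles) < 2:
        raise ValueError(
            "need >= 2 technical replicates; use the fixed threshold of 1.0 RT units"
        )
    conditions = {p.condition for p in profiles}
    if len(conditions) > 1:
        raise ValueError("replicates must all come from one condition")
    mats = [window_means(p.track, window)[1] for p in profiles]
    diffs = []
    for a, b in itertools.combinations(mats, 2):
        d = a - b
        diffs.append(d[~np.isnan(d)])
    pooled = np.concatenate(diffs)
    if len(pooled) < 2:
        raise ValueError("not enough jointly covered windows")
    return 2.0 * float(np.std(pooled, ddof=1))


def detect_variable_windows(
    ctrl_profiles: Sequence[RTProfile],
    aph_profiles: Sequence[RTProfile],
    window: int = 100_000,
    threshold: float = 1.0,
    max_masked_frac: float = 0.5,
    mode: str = "condition_mean",
) -> list[RTWindow]:
    """Flag windows whose RT responds to replication stress.

    A window is flagged when |mean(APH) − mean(control)| >= threshold
    (``condition_mean`` mode) or when any single cross-condition replicate
    pair exceeds the threshold (``any_pair`` mode), and in either mode
    every cross-condition replicate pair agrees on the sign of the
    change.  Windows with more than ``max_masked_frac`` masked bins are
    excluded (never flagged, means still reported).
    """
    if not ctrl_profiles or not aph_profiles:
        raise ValueError("need >= 1 replicate per condition")
    if mode not in ("condition_mean", "any_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    intervals = None
    ctrl_mat, aph_mat, fracs_all = [], [], []
    for p in ctrl_profiles:
        ivs, m, f = window_means(p.track, window)
        if intervals is None:
            intervals = ivs
        ctrl_mat.append(m)
        fracs_all.append(f)
    for p in aph_profiles:
        _, m, f = window_means(p.track, window)
        aph_mat.append(m)
        fracs_all.append(f)
    ctrl = np.stack(ctrl_mat)  # (n_ctrl, n_win)
    aph = np.stack(aph_mat)
    masked_frac = np.stack(fracs_all).max(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ctrl_mean = np.nanmean(ctrl, axis=0)
        aph_mean = np.nanmean(aph, axis=0)
        delta = aph_mean - ctrl_mean
        pair_diffs = aph[:, None, :] - ctrl[None, :, :]  # (n_aph, n_ctrl, n_win)
        signs = np.sign(pair_diffs)
        sign_ok = (np.nanmin(signs, axis=(0, 1)) == np.nanmax(signs, axis=(0, 1))) & (
            np.nanmax(np.abs(signs), axis=(0, 1)) > 0
        )
        if mode == "condition_mean":
            exceeds = np.abs(delta) >= threshold
        else:
            exceeds = np.nanmax(np.abs(pair_diffs), axis=(0, 1)) >= threshold
    usable = (masked_frac <= max_masked_frac) & ~np.isnan(delta)
    flag = usable & exceeds & sign_ok
    out: list[RTWindow] = []
    for i, iv in enumerate(intervals):
        out.append(
            RTWindow(
                interval=iv,
                sample_means=np.concatenate([ctrl[:, i], aph[:, i]]),
                n_ctrl=ctrl.shape[0],
                ctrl_mean=float(ctrl_mean[i]),
                aph_mean=float(aph_mean[i]),
                delta=float(delta[i]),
                masked_frac=float(masked_frac[i]),
                flagged=bool(flag[i]),
                index=i,
            )
        )
    return out


def merge_contiguous(windows: Sequence[RTWindow]) -> list[RTVariableRegion]:
    """Merge adjacent flagged windows with the same direction into regions.

    Windows must be sorted and non-overlapping (as produced by
    :func:`detect_variable_windows`).  Region delta is the mean of member
    window deltas.  The operation is idempotent and partition-preserving:
    the member windows of all regions are exactly the flagged windows.
    """
    regions: list[RTVariableRegion] = []
    run: list[RTWindow] = []

    def close_run() -> None:
        if not run:
            return
        regions.append(
            RTVariableRegion(
                interval=GenomicInterval(
                    run[0].interval.chrom, run[0].interval.start, run[-1].interval.end
                ),
                direction=run[0].direction,
                n_windows=len(run),
                mean_delta=float(np.mean([w.delta for w in run])),
                member_windows=[w.index for w in run],
            )
        )
        run.clear()

    for w in windows:
        if not w.flagged:
            close_run()
            continue
        if run and not (
            w.interval.chrom == run[-1].interval.chrom
            and w.interval.start == run[-1].interval.end
            and w.direction == run[-1].direction
        ):
            close_run()
        run.append(w)
    close_run()
    return regions


def _signature_label(
    centroid_ctrl: float,
    centroid_aph: float,
    early_cut: float = 0.5,
    late_cut: float = -0.5,
) -> str:
    """Auto-label a cluster centroid, e.g. 'early-delayed' for regions that
    replicate early in control cells and are delayed under stress."""

    def frac(v: float) -> str:
        if v >= early_cut:
            return "early"
        if v <= late_cut:
            return "late"
        return "mid"

    direction = DELAYED if centroid_aph < centroid_ctrl else ADVANCED
    f_ctrl, f_aph = frac(centroid_ctrl), frac(centroid_aph)
    if f_ctrl == f_aph:
        return f"within-{f_ctrl}-{direction}"
    return f"{f_ctrl}-{direction}"


def cluster_rt_signatures(
    windows: Sequence[RTWindow],
    k: int = 5,
    restarts: int = 50,
    seed: int | None = None,
    early_cut: float = 0.5,
    late_cut: float = -0.5,
) -> list[RTSignature]:
    """k-means clustering of flagged windows into RT signatures.

    Rows are the flagged windows, columns the per-sample window means.
    The best of ``restarts`` seeded initialisations (lowest inertia) is
    kept.  Each cluster is auto-labelled from its centroid's control and
    stress means, and a paired t-test of control vs APH window means is
    reported per cluster, raw and Benjamini-Hochberg adjusted.
    """
    flagged = [w for w in windows if w.flagged]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(flagged):
        raise ValueError(f"k={k} exceeds the number of flagged windows ({len(flagged)})")
    mat = np.stack([w.sample_means for w in flagged])
    mat = np.where(np.isnan(mat), np.nanmean(mat), mat)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    assign = km.fit_predict(mat)
    n_ctrl = flagged[0].n_ctrl
    p_raw: list[float] = []
    sigs: list[RTSignature] = []
    for c in range(k):
        members = [flagged[i].index for i in np.flatnonzero(assign == c)]
        centroid = km.cluster_centers_[c]
        c_ctrl = float(centroid[:n_ctrl].mean())
        c_aph = float(centroid[n_ctrl:].mean())
        idx = np.flatnonzero(assign == c)
        if len(idx) >= 2:
            ctrl_means = np.array([flagged[i].ctrl_mean for i in idx])
            aph_means = np.array([flagged[i].aph_mean for i in idx])
            p = float(stats.ttest_rel(ctrl_means, aph_means).pvalue)
        else:
            p = np.nan
        p_raw.append(p)
        sigs.append(
            RTSignature(
                cluster_id=c + 1,
                member_windows=members,
                centroid=centroid,
                label=_signature_label(c_ctrl, c_aph, early_cut, late_cut),
                p_value=p,
                p_adjusted=np.nan,
            )
        )
    finite = ~np.isnan(p_raw)
    if finite.any():
        adj = np.full(k, np.nan)
        adj[finite] = multipletests(np.asarray(p_raw)[finite], method="fdr_bh")[1]
        for s, a in zip(sigs, adj):
            s.p_adjusted = float(a) if not np.isnan(a) else np.nan
    return sigs


def annotate_bands(
    regions: Sequence[RTVariableRegion],
    band_table: pd.DataFrame,
    fragile_band_ids: Sequence[str],
    region_ctrl_rt: Sequence[float] | None = None,
    trisection_cuts: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Summarise variable regions against cytogenetic bands.

    ``band_table`` needs columns band_id/chrom/start/end.  A region
    straddling two bands is counted in both (overlap semantics).  The
    summary reports, over the fragile bands, the fractions containing
    delayed-only / advanced-only / both / neither regions; when
    ``region_ctrl_rt`` (control-condition mean RT per region) and
    trisection cuts are supplied, the early/mid/late composition of the
    delayed regions inside fragile bands is added.
    """
    required = {"band_id", "chrom", "start", "end"}
    if not required.issubset(band_table.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    fragile = set(fragile_band_ids)
    unknown = fragile - set(band_table["band_id"])
    if unknown:
        raise ValueError(f"fragile band ids not in table: {sorted(unknown)}")
    rows = []
    delayed_in_fragile: list[int] = []
    for _, band in band_table.iterrows():
        biv = GenomicInterval(band["chrom"], int(band["start"]), int(band["end"]))
        n_del = n_adv = 0
        for ri, reg in enumerate(regions):
            if reg.interval.overlaps(biv):
                if reg.direction == DELAYED:
                    n_del += 1
                    if band["band_id"] in fragile:
                        delayed_in_fragile.append(ri)
                else:
                    n_adv += 1
        rows.append(
            {
                "band_id": band["band_id"],
                "chrom": band["chrom"],
                "start": int(band["start"]),
                "end": int(band["end"]),
                "fragile": band["band_id"] in fragile,
                "n_delayed": n_del,
                "n_advanced": n_adv,
            }
        )
    per_band = pd.DataFrame(rows)
    frag = per_band[per_band["fragile"]]
    n_frag = len(frag)
    summary: dict = {"n_fragile_bands": n_frag}
    if n_frag:
        has_del = frag["n_delayed"] > 0
        has_adv = frag["n_advanced"] > 0
        summary.update(
            frac_fragile_with_delayed=float(has_del.mean()),
            frac_fragile_with_advanced=float(has_adv.mean()),
            frac_delayed_only=float((has_del & ~has_adv).mean()),
            frac_advanced_only=float((~has_del & has_adv).mean()),
            frac_both=float((has_del & has_adv).mean()),
            frac_neither=float((~has_del & ~has_adv).mean()),
        )
    if region_ctrl_rt is not None and trisection_cuts is not None:
        early_cut, late_cut = trisection_cuts
        comp = {"early": 0, "mid": 0, "late": 0}
        for ri in sorted(set(delayed_in_fragile)):
            rt = region_ctrl_rt[ri]
            if np.isnan(rt):
                continue
            if rt >= early_cut:
                comp["early"] += 1
            elif rt <= late_cut:
                comp["late"] += 1
            else:
                comp["mid"] += 1
        total = sum(comp.values())
        summary["delayed_in_fragile_trisection"] = comp
        if total:
            summary["frac_delayed_in_fragile_early_or_mid"] = (
                comp["early"] + comp["mid"]
            ) / total
    return per_band, summary
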