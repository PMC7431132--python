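"""Genome-wide fixed-size window statistics.

Whole-chromosome analyses are performed on 1 kb windows tiling the genome:
per-window mean normalized depth, ChIP/input or mutant/WT ratios with a
pseudocount floor, rank-based arm-vs-center comparison of heterochromatin
signal, and Pearson correlation between marks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack, DEFAULT_EXTENSION
from .genome import GenomeLayout

DEFAULT_WINDOW = 1_000

# ratio band inside which a statistically significant arm/center difference
# is flagged as biologically negligible
NEGLIGIBLE_BAND = 1.1


def make_windows(layout: GenomeLayout, window_size: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Contiguous non-overlapping windows covering every chromosome.

    The last window of a chromosome may be short. Returns a DataFrame with
    ``chrom, start, end`` (0-based half-open).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    frames = []
    for chrom, length in layout.chrom_lengths.items():
        starts = np.arange(0, length, window_size)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window_size, length),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def window_signal(
    tracks: CoverageTrack | Sequence[CoverageTrack],
    windows: pd.DataFrame,
) -> np.ndarray:
    """Mean normalized per-base depth per window, averaged across replicates.

    Requires the track bin size to divide the window size (use a track at
    bin_size 1 for per-base resolution). Bin means are combined with
    length weighting so a short terminal bin is handled exactly.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    per_track = []
    for track in tracks:
        bs = track.bin_size
        vals = np.empty(len(windows))
        for chrom, grp in windows.groupby("chrom", sort=False):
            vec = track.values[chrom]
            length = track.layout.chrom_lengths[chrom]
            for i, (s, e) in zip(grp.index, zip(grp["start"], grp["end"])):
                if s % bs != 0 or (e % bs != 0 and e != length):
                    raise ValueError(
                        f"window [{s},{e}) not aligned to bin size {bs}; "
                        "recompute the track at bin_size 1 for per-base mode"
                    )
                lo, hi = s // bs, -(-e // bs)
                bin_ends = np.minimum(np.arange(lo, hi) * bs + bs, length)
                bin_starts = np.arange(lo, hi) * bs
                lens = np.minimum(bin_ends, e) - np.maximum(bin_starts, s)
                vals[i] = float(np.dot(vec[lo:hi], lens) / (e - s))
        per_track.append(vals)
    return np.mean(per_track, axis=0)


def default_pseudocount(
    depth: int, window_size: int = DEFAULT_WINDOW, extension: int = DEFAULT_EXTENSION
) -> float:
    """Normalized signal of a single read's mass spread over one window.

    A scale-aware floor: one extended fragment contributes ``extension`` bp
    of mass, i.e. mean per-base depth ``extension / window_size`` in a
    window, normalized by ``1e6 / depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    return extension / window_size * 1e6 / depth


def ratio_signal(
    numerator: np.ndarray, denominator: np.ndarray, pseudocount: float
) -> np.ndarray:
    """Elementwise ``(num + pc) / (den + pc)`` enrichment ratio."""
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if numerator.shape != denominator.shape:
        raise ValueError("numerator and denominator have different lengths")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (numerator + pseudocount) / (denominator + pseudocount)


@dataclass
class ArmCenterSummary:
    """Arm-vs-center window-signal comparison (overall and per chromosome).

    ``significant_but_negligible`` echoes the caution that a tiny shift can
    reach significance on many windows yet mean little biologically: it is
    set when p < 0.05 while the arm/center median ratio stays within
    [1/1.1, 1.1].
    """

    effect_ratio: float
    p_value: float
    arm_quartiles: tuple[float, float, float]
    center_quartiles: tuple[float, float, float]
    n_arm: int
    n_center: int
    significant_but_negligible: bool
    per_chromosome: pd.DataFrame


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q = np.percentile(x, [25, 50, 75])
    return float(q[0]), float(q[1]), float(q[2])


def arm_center_compare(
    signal: np.ndarray, windows: pd.DataFrame, layout: GenomeLayout
) -> ArmCenterSummary:
    """Compare window signal between chromosome arms and centers.

    Windows are assigned by midpoint. The test is a two-sided
    Mann-Whitney U (rank-based, robust to the heavy right tail of ChIP
    coverage); the effect size is the arm/center median ratio.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(windows):
        raise ValueError("signal length does not match windows")
    mids = (windows["start"] + windows["end"]) // 2
    compartment = np.array(
        [layout.compartment(c, m) for c, m in zip(windows["chrom"], mids)]
    )
    is_arm = compartment == "arm"

    def summarize(mask_arm: np.ndarray, sig: np.ndarray) -> tuple[float, float]:
        arm, cen = sig[mask_arm], sig[~mask_arm]
        if len(arm) == 0 or len(cen) == 0:
            raise ValueError("a chromosome has zero arm or zero center windows")
        if np.ptp(sig) == 0:
            return 1.0, 1.0  # no discrimination possible
        stat = stats.mannwhitneyu(arm, cen, alternative="two-sided")
        med_c = np.median(cen)
        ratio = float(np.median(arm) / med_c) if med_c > 0 else float("inf")
        return ratio, float(stat.pvalue)

    rows = []
    for chrom in layout.chromosomes:
        sel = (windows["chrom"] == chrom).to_numpy()
        ratio_c, p_c = summarize(is_arm[sel], signal[sel])
        rows.append(
            {
                "chrom": chrom,
                "effect_ratio": ratio_c,
                "p_value": p_c,
                "arm_median": float(np.median(signal[sel & is_arm])),
                "center_median": float(np.median(signal[sel & ~is_arm])),
            }
        )
    ratio, p = summarize(is_arm, signal)
    negligible = p < 0.05 and 1.0 / NEGLIGIBLE_BAND <= ratio <= NEGLIGIBLE_BAND
    return ArmCenterSummary(
        effect_ratio=ratio,
        p_value=p,
        arm_quartiles=_quartiles(signal[is_arm]),
        center_quartiles=_quartiles(signal[~is_arm]),
        n_arm=int(is_arm.sum()),
        n_center=int((~is_arm).sum()),
        significant_but_negligible=negligible,
        per_chromosome=pd.DataFrame(rows),
    )


def correlate_marks(
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    log2: bool = False,
    labels: tuple[str, str] = ("mark_a", "mark_b"),
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of two window signals plus a scatter export.

    The scatter table carries both signals (optionally log2-transformed)
    and two-fold guide columns for plotting.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must share their windows")
    finite = np.isfinite(a) & np.isfinite(b)
    a, b = a[finite], b[finite]
    if len(a) < 3:
        raise ValueError("need at least 3 windows with finite values")
    if log2:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log2 transform requires strictly positive signals")
        a, b = np.log2(a), np.log2(b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a signal; correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    scatter = pd.DataFrame({labels[0]: a, labels[1]: b})
    scatter["twofold_up"] = 2.0 * scatter[labels[0]] if not log2 else scatter[labels[0]] + 1
    scatter["twofold_down"] = scatter[labels[0]] / 2.0 if not log2 else scatter[labels[0]] - 1
    return r, scatter
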