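"""Factor-dependent gene calling and region-class ratio summaries.

A gene's histone-mark signal is called *dependent* on a factor when the
mutant shows at least a two-fold decrease relative to wild type with a
significant count test (p < 0.05) in every replicate pair. Fold changes are
computed on depth-normalized signals with a pseudocount; significance comes
from a depth-conditioned count test on the raw weighted read masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack, DEFAULT_EXTENSION, Library, per_base_depth
from .genome import GenomeLayout

FOLD_THRESHOLD = 2.0
ALPHA = 0.05


def gene_signal(
    track: CoverageTrack, gene: tuple[str, int, int], flank: int = 0
) -> tuple[float, float]:
    """Signal of one gene from a coverage track.

    Returns ``(signal, mass)``: the mean normalized per-base depth over the
    flank-extended span clipped to the chromosome, and the unnormalized
    weighted read mass in that span (integrated per-base depth divided by
    the fragment extension length, i.e. equivalent fragment count).
    """
    chrom, start, end = gene
    if chrom not in track.layout.chrom_lengths:
        raise ValueError(f"gene on unknown chromosome {chrom!r}")
    length = track.layout.chrom_lengths[chrom]
    s, e = max(0, start - flank), min(length, end + flank)
    if not (0 <= s < e <= length):
        raise ValueError(f"gene span {gene} outside layout")
    signal = track.span_mean(chrom, s, e)
    mass = signal / track.normalization_factor * (e - s) / track.extension
    return float(signal), float(mass)


def _gene_table(
    library: Library,
    layout: GenomeLayout,
    genes: pd.DataFrame,
    extension: int,
    flank: int,
) -> pd.DataFrame:
    """Exact per-gene normalized signal and weighted read mass of a library.

    Uses cumulative per-base depth, so spans need not align to any binning.
    """
    depth = library.depth
    if depth == 0:
        raise ValueError("empty library")
    base = per_base_depth(library, layout, extension)
    csum = {c: np.concatenate(([0.0], np.cumsum(d))) for c, d in base.items()}
    rows = []
    for _, g in genes.iterrows():
        chrom = g["chrom"]
        length = layout.chrom_lengths[chrom]
        s = max(0, int(g["start"]) - flank)
        e = min(length, int(g["end"]) + flank)
        integral = csum[chrom][e] - csum[chrom][s]
        rows.append(
            {
                "gene_id": g["name"],
                "signal": integral / (e - s) * 1e6 / depth,
                "mass": integral / extension,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def count_test_binomial(
    mass_a: float, mass_b: float, depth_a: int, depth_b: int
) -> float:
    """Conditional binomial test for loss of signal in sample b.

    Masses are rounded half-to-even to integers; given their sum, the
    a-side count is binomial with success probability equal to a's depth
    share under the null of equal per-depth signal. One-sided for
    enrichment in a (i.e. depletion in b).
    """
    ka, kb = int(np.rint(mass_a)), int(np.rint(mass_b))
    n = ka + kb
    if n == 0:
        return 1.0
    p0 = depth_a / (depth_a + depth_b)
    return float(stats.binomtest(ka, n, p0, alternative="greater").pvalue)


def count_test_fisher(
    mass_a: float, mass_b: float, depth_a: int, depth_b: int
) -> float:
    """Fisher exact test on the 2x2 (in-gene mass vs rest of library) table."""
    ka, kb = int(np.rint(mass_a)), int(np.rint(mass_b))
    table = [[ka, depth_a - ka], [kb, depth_b - kb]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


COUNT_TESTS = {"binomial": count_test_binomial, "fisher": count_test_fisher}


def call_dependent_genes(
    wt: list[Library],
    mutant: list[Library],
    genes: pd.DataFrame,
    layout: GenomeLayout,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
    mode: str = "p",
    extension: int = DEFAULT_EXTENSION,
    flank: int = 0,
    pseudocount: float | None = None,
    test: str = "binomial",
) -> pd.DataFrame:
    """Call genes whose signal depends on the mutated factor.

    Replicates are paired by index (WT rep i vs mutant rep i). Per pair and
    gene, the fold change is WT/mutant on depth-normalized signals with a
    pseudocount floor; the p-value is a depth-conditioned count test on raw
    weighted masses. With ``mode='fdr'`` the per-pair p-values are
    Benjamini-Hochberg adjusted across genes before thresholding.

    A gene is ``dependent`` iff every replicate pair shows
    ``fold >= fold_threshold`` and an (adjusted) p-value below ``alpha``.
    The full per-gene table is returned, not only the called set.
    """
    if not wt or not mutant:
        raise ValueError("need at least one WT and one mutant replicate")
    if len(wt) != len(mutant):
        raise ValueError(
            f"replicates are paired by index: got {len(wt)} WT vs {len(mutant)} mutant"
        )
    if mode not in ("p", "fdr"):
        raise ValueError("mode must be 'p' or 'fdr'")
    test_fn = COUNT_TESTS[test]

    out = pd.DataFrame({"gene_id": genes["name"]}).set_index("gene_id")
    pass_all = np.ones(len(out), dtype=bool)
    for i, (lib_wt, lib_mut) in enumerate(zip(wt, mutant), start=1):
        twt = _gene_table(lib_wt, layout, genes, extension, flank)
        tmut = _gene_table(lib_mut, layout, genes, extension, flank)
        # scale-aware floor: one read's mass over the median gene span
        if pseudocount is None:
            span = float(np.median(genes["end"] - genes["start"])) + 2 * flank
            pc = extension / span * 1e6 / min(lib_wt.depth, lib_mut.depth)
        else:
            pc = pseudocount
        fold = (twt["signal"] + pc) / (tmut["signal"] + pc)
        pvals = np.array(
            [
                test_fn(mw, mm, lib_wt.depth, lib_mut.depth)
                for mw, mm in zip(twt["mass"], tmut["mass"])
            ]
        )
        padj = stats.false_discovery_control(pvals, method="bh")
        crit = padj if mode == "fdr" else pvals
        out[f"wt_signal_{i}"] = twt["signal"]
        out[f"mut_signal_{i}"] = tmut["signal"]
        out[f"fold_change_{i}"] = fold
        out[f"p_value_{i}"] = pvals
        out[f"p_adjusted_{i}"] = padj
        pass_all &= (fold.to_numpy() >= fold_threshold) & (crit < alpha)
    out["dependent"] = pass_all
    return out.reset_index()


@dataclass
class RegionClassSummary:
    """Mutant/WT window-ratio distribution of one region class."""

    label: str
    n_windows: int
    quartiles: tuple[float, float, float]
    ratios: np.ndarray


def region_class_summary(
    ratios: np.ndarray,
    windows: pd.DataFrame,
    regions: pd.DataFrame | None,
) -> dict[str, RegionClassSummary]:
    """Assign each window to a region class by midpoint and summarize ratios.

    ``regions`` is a BED-like frame whose ``name`` column carries the class
    (e.g. GRH, GRTS); unassigned windows fall into ``"rest"``. Empty classes
    are reported with zero windows rather than raising.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) != len(windows):
        raise ValueError("ratio vector does not match windows")
    labels = np.full(len(windows), "rest", dtype=object)
    classes = ["rest"]
    if regions is not None and len(regions):
        classes = list(dict.fromkeys(regions["name"])) + ["rest"]
        mids = ((windows["start"] + windows["end"]) // 2).to_numpy()
        chroms = windows["chrom"].to_numpy()
        for _, r in regions.iterrows():
            hit = (chroms == r["chrom"]) & (mids >= r["start"]) & (mids < r["end"])
            labels[hit] = r["name"]
    out = {}
    for cls in classes:
        vals = ratios[labels == cls]
        q = (
            (float("nan"),) * 3
            if len(vals) == 0
            else tuple(float(x) for x in np.percentile(vals, [25, 50, 75]))
        )
        out[cls] = RegionClassSummary(cls, len(vals), q, vals)
    return out
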