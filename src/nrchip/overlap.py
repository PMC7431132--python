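"""Gene-set overlap statistics and repeat composition of target genes.

Venn-style intersections of dependent-gene sets are tested for enrichment
with a one-sided Fisher's exact test (hypergeometric tail) over a fixed
gene universe. Target genes are additionally intersected with a
RepeatMasker-style repeat annotation to report what fraction contains
repeat DNA and of which classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


@dataclass
class VennResult:
    """Single/pairwise/triple intersection sizes plus pairwise Fisher tests.

    ``sizes`` maps a tuple of set labels to the size of their intersection
    (singletons included); ``fisher`` maps a label pair to
    ``(p_value, odds_ratio)``.
    """

    labels: list[str]
    sizes: dict[tuple[str, ...], int]
    universe_size: int
    fisher: dict[tuple[str, str], tuple[float, float]]


def fisher_overlap(
    set_a: set, set_b: set, universe: set
) -> tuple[float, float, list[list[int]]]:
    """One-sided Fisher's exact test for gene-set overlap enrichment.

    The 2x2 table partitions the universe by membership in A and in B; the
    p-value is the hypergeometric upper tail P(X >= observed overlap). The
    odds ratio is the conditional MLE reported by the exact test.
    """
    if not universe:
        raise ValueError("empty universe")
    for name, s in (("A", set_a), ("B", set_b)):
        extra = s - universe
        if extra:
            raise ValueError(f"set {name} has {len(extra)} elements outside the universe")
    n = len(universe)
    k = len(set_a & set_b)
    a, b = len(set_a), len(set_b)
    table = [[k, a - k], [b - k, n - a - b + k]]
    odds = float(stats.fisher_exact(table, alternative="greater")[0])
    # hypergeometric survival gives the tail at full precision
    p = float(stats.hypergeom.sf(k - 1, n, a, b))
    return p, odds, table


def venn(sets: dict[str, set], universe: set) -> VennResult:
    """Exact intersection sizes of 2-3 labeled gene-id sets.

    Reports every single, pairwise and (for three sets) triple intersection
    size plus a pairwise Fisher enrichment test over the universe.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn analysis takes 2 or 3 sets")
    labels = list(sets)
    for label, s in sets.items():
        if s - universe:
            raise ValueError(f"set {label!r} has elements outside the universe")
    sizes: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = set(universe)
            for label in combo:
                inter &= sets[label]
            sizes[combo] = len(inter)
    fisher = {
        (la, lb): fisher_overlap(sets[la], sets[lb], universe)[:2]
        for la, lb in combinations(labels, 2)
    }
    return VennResult(labels, sizes, len(universe), fisher)


@dataclass
class RepeatComposition:
    """How many target genes contain repeat DNA, and of which classes.

    Class fractions are computed among repeat-containing genes; a gene
    holding several classes is counted once per class, so class counts may
    exceed ``n_genes_with_repeat``.
    """

    n_genes: int
    n_genes_with_repeat: int
    fraction_with_repeat: float
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    per_gene: pd.DataFrame


def annotate_repeats(
    genes: pd.DataFrame, repeats: pd.DataFrame
) -> RepeatComposition:
    """Intersect genes with a repeat annotation (any overlap, half-open).

    ``genes`` and ``repeats`` are BED-like frames; the repeat ``name``
    column is its class label (LTR, DNA, Low_complexity, ...). Returns the
    composition summary plus a per-gene record of overlapping classes
    (pie-chart export).
    """
    for frame, what in ((genes, "gene"), (repeats, "repeat")):
        if ((frame["end"] - frame["start"]) <= 0).any():
            raise ValueError(f"malformed {what} interval (end <= start)")
    trees: dict[str, IntervalTree] = {}
    for _, r in repeats.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]), r["name"]
        )
    rows = []
    class_genes: dict[str, set] = {}
    for _, g in genes.iterrows():
        tree = trees.get(g["chrom"])
        hits = tree.overlap(int(g["start"]), int(g["end"])) if tree else set()
        classes = sorted({h.data for h in hits})
        for cls in classes:
            class_genes.setdefault(cls, set()).add(g["name"])
        rows.append(
            {
                "gene_id": g["name"],
                "has_repeat": bool(classes),
                "repeat_classes": ",".join(classes),
            }
        )
    per_gene = pd.DataFrame(rows)
    n_with = int(per_gene["has_repeat"].sum()) if len(per_gene) else 0
    counts = {cls: len(ids) for cls, ids in sorted(class_genes.items())}
    return RepeatComposition(
        n_genes=len(genes),
        n_genes_with_repeat=n_with,
        fraction_with_repeat=n_with / len(genes) if len(genes) else 0.0,
        class_counts=counts,
        class_fractions={c: k / n_with for c, k in counts.items()} if n_with else {},
        per_gene=per_gene,
    )
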