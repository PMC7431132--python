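"""Synthetic genomes and ChIP/input alignment libraries with planted truth.

The generator emulates, at the alignment level, the experimental design of a
germline nuclear-RNAi ChIP-seq study in a small worm-like genome:

* chromosomes partitioned into heterochromatin-enriched arms and a center;
* GRH/GRTS-style nuclear-RNAi target regions placed on the arms;
* annotated genes, a subset of which are enrichment targets whose histone
  mark depends on genotype (e.g. an hrde-1-like mutant with effect
  multiplier 0 loses the mark entirely);
* repeat families whose identical-length copies induce multimapping: a read
  sampled wholly inside one copy is reported at every copy with
  ``n_hits = copy_number``;
* geometric decay of planted enrichment across generations after an RNAi
  trigger is removed: ``fold(g) = 1 + (fold_0 - 1) * d**g``.

Read 5'-start positions are drawn from a mixture of a uniform background and
per-element excess proportional to ``planted_fold - 1``, so the expected
in-region/background count ratio equals the planted fold. Sequence content
and the alignment step itself are not simulated: libraries are emitted
directly as alignment records.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .coverage import AlignmentRecord, Library, LibraryMeta
from .genome import GenomeLayout

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class SimulationError(RuntimeError):
    """Raised when the requested annotation cannot be placed on the genome."""


@dataclass
class SimConfig:
    """Full parameterization of the toy genome and read generator.

    Folds are multiplicative enrichment levels (>= 1); genotype effect
    multipliers scale the planted excess ``fold - 1`` and live in [0, 1],
    as does the per-generation decay factor ``generation_decay``.
    """

    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chrI", 1_000_000), ("chrII", 1_000_000), ("chrIII", 1_000_000)]
    )
    arm_fraction: float = 0.25
    n_genes: int = 200
    gene_length: int = 2_000
    n_grh: int = 8
    n_grts: int = 8
    region_length: int = 2_000
    repeat_families: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("Low_complexity", 5, 200),
            ("DNA", 4, 400),
            ("LTR", 3, 500),
        ]
    )
    background_enrichment_arms: float = 3.0
    target_enrichment: dict[str, float] = field(
        default_factory=lambda: {"H3K23me3": 8.0, "H3K9me3": 8.0}
    )
    genotype_effects: dict[str, float] = field(
        default_factory=lambda: {
            "WT": 1.0,
            "hrde-1": 0.0,
            "set-32": 0.0,
            "met-2 set-25": 0.5,
        }
    )
    generation_decay: float = 0.7
    n_target_genes: int = 20
    repeat_in_target_fraction: float = 0.6
    n_reads: int = 100_000
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for _, l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.arm_fraction <= 0.5:
            raise ValueError("arm_fraction must be in [0, 0.5]")
        for label, copies, length in self.repeat_families:
            if copies <= 0 or length <= 0:
                raise ValueError(f"repeat family {label!r} needs positive copies/length")
        if min(self.n_genes, self.gene_length, self.n_grh + 1, self.n_grts + 1,
               self.region_length, self.n_reads, self.read_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.background_enrichment_arms < 1 or any(
            f < 1 for f in self.target_enrichment.values()
        ):
            raise ValueError("enrichment folds must be >= 1")
        if not all(0.0 <= e <= 1.0 for e in self.genotype_effects.values()):
            raise ValueError("genotype effect multipliers must be in [0, 1]")
        if not 0.0 <= self.generation_decay <= 1.0:
            raise ValueError("generation_decay must be in [0, 1]")
        if not 0 <= self.n_target_genes <= self.n_genes:
            raise ValueError("n_target_genes must not exceed n_genes")
        if not 0.0 <= self.repeat_in_target_fraction <= 1.0:
            raise ValueError("repeat_in_target_fraction must be in [0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth: every annotated element with its base enrichment.

    ``elements`` has one row per gene, region and repeat copy with columns
    ``kind, id, chrom, start, end, class, is_target`` plus one
    ``fold_<mark>`` column per mark (the F0 wild-type planted fold).
    Genotype- and generation-resolved folds are derived via :meth:`fold`.
    """

    elements: pd.DataFrame
    genotype_effects: dict[str, float]
    generation_decay: float
    background_enrichment_arms: float
    marks: list[str]

    def fold(self, base_fold: float, genotype: str, generation: int = 0) -> float:
        """Planted fold for one condition: ``1 + (f0-1) * effect * d**g``."""
        if genotype not in self.genotype_effects:
            raise KeyError(f"unknown genotype {genotype!r}")
        eff = self.genotype_effects[genotype]
        return 1.0 + (base_fold - 1.0) * eff * self.generation_decay**generation

    def condition_frame(
        self, genotypes: list[str] | None = None, generations: list[int] = (0,)
    ) -> pd.DataFrame:
        """Expand to one row per (element, mark, genotype, generation)."""
        genotypes = genotypes or list(self.genotype_effects)
        rows = []
        for _, el in self.elements.iterrows():
            for mark in self.marks:
                for gt in genotypes:
                    for g in generations:
                        rows.append(
                            {
                                "kind": el["kind"],
                                "id": el["id"],
                                "mark": mark,
                                "genotype": gt,
                                "generation": g,
                                "fold": self.fold(el[f"fold_{mark}"], gt, g),
                            }
                        )
        return pd.DataFrame(rows)

    def target_genes(self) -> list[str]:
        el = self.elements
        return list(el.loc[(el["kind"] == "gene") & el["is_target"], "id"])


def _place(
    rng: np.random.Generator,
    occupied: dict[str, IntervalTree],
    windows: list[tuple[str, int, int]],
    length: int,
    max_tries: int = 2000,
) -> tuple[str, int, int]:
    """Place one interval of ``length`` uniformly inside the candidate windows,
    rejecting overlaps with anything already placed."""
    fitting = [(c, a, b) for c, a, b in windows if b - a >= length]
    if not fitting:
        raise SimulationError(f"no window can hold an interval of {length} bp")
    weights = np.array([b - a - length + 1 for _, a, b in fitting], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        c, a, b = fitting[rng.choice(len(fitting), p=weights)]
        start = int(rng.integers(a, b - length + 1))
        if not occupied[c].overlap(start, start + length):
            occupied[c].addi(start, start + length)
            return c, start, start + length
    raise SimulationError(
        f"failed to place an interval of {length} bp after {max_tries} tries "
        f"({sum(len(t) for t in occupied.values())} intervals already placed)"
    )


def build_toy_genome(
    config: SimConfig,
) -> tuple[GenomeLayout, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate the toy genome: layout, gene/repeat/region annotations, truth.

    Deterministic given ``config.seed``. GRH/GRTS regions land only on arms;
    genes anywhere; repeat-family copies are identical-length intervals, a
    configured fraction of target genes containing one copy (the rest of the
    copies fall in otherwise unoccupied sequence).

    Returns ``(layout, genes, repeats, regions, truth)`` with annotations as
    BED6-style DataFrames (0-based half-open).
    """
    rng = np.random.default_rng(config.seed)
    layout = GenomeLayout.from_arm_fraction(config.chrom_lengths, config.arm_fraction)
    occupied = {c: IntervalTree() for c in layout.chromosomes}
    whole = [(c, 0, l) for c, l in layout.chrom_lengths.items()]
    arm_windows = [
        (c, a, b)
        for c in layout.chromosomes
        for name, (a, b) in layout.arm_intervals(c).items()
        if name != "center" and b > a
    ]

    regions = []
    for label, count in (("GRH", config.n_grh), ("GRTS", config.n_grts)):
        for i in range(count):
            c, s, e = _place(rng, occupied, arm_windows, config.region_length)
            regions.append((c, s, e, label, 0, "."))
    regions_df = pd.DataFrame(regions, columns=BED_COLUMNS)

    genes = []
    for i in range(config.n_genes):
        c, s, e = _place(rng, occupied, whole, config.gene_length)
        strand = "+" if rng.integers(2) else "-"
        genes.append((c, s, e, f"gene_{i + 1:04d}", 0, strand))
    genes_df = pd.DataFrame(genes, columns=BED_COLUMNS)
    target_ids = set(genes_df["name"].iloc[: config.n_target_genes])

    # repeat copies: some planted inside target genes, the rest in free space
    n_in_targets = int(round(config.repeat_in_target_fraction * config.n_target_genes))
    host_genes = list(genes_df["name"].iloc[:n_in_targets])
    fitting_fams = [
        i for i, (_, _, ln) in enumerate(config.repeat_families) if ln <= config.gene_length
    ]
    if host_genes and not fitting_fams:
        raise SimulationError("no repeat family short enough to fit inside a gene")
    repeats = []
    planted_per_fam: dict[int, int] = {i: 0 for i in range(len(config.repeat_families))}
    for j, gid in enumerate(host_genes):
        fam = fitting_fams[j % len(fitting_fams)]
        label, copies, ln = config.repeat_families[fam]
        row = genes_df.loc[genes_df["name"] == gid].iloc[0]
        mid = (int(row["start"]) + int(row["end"]) - ln) // 2
        repeats.append((row["chrom"], mid, mid + ln, label, 0, "."))
        planted_per_fam[fam] += 1
    for fam, (label, copies, ln) in enumerate(config.repeat_families):
        for _ in range(max(0, copies - planted_per_fam[fam])):
            c, s, e = _place(rng, occupied, whole, ln)
            repeats.append((c, s, e, label, 0, "."))
    repeats_df = pd.DataFrame(repeats, columns=BED_COLUMNS)
    repeats_df = repeats_df.sort_values(["chrom", "start"], ignore_index=True)

    marks = list(config.target_enrichment)
    rows = []
    for _, g in genes_df.iterrows():
        is_t = g["name"] in target_ids
        row = {
            "kind": "gene", "id": g["name"], "chrom": g["chrom"],
            "start": g["start"], "end": g["end"], "class": "", "is_target": is_t,
        }
        for m in marks:
            row[f"fold_{m}"] = config.target_enrichment[m] if is_t else 1.0
        rows.append(row)
    for i, r in regions_df.iterrows():
        row = {
            "kind": "region", "id": f"{r['name']}_{i + 1:03d}", "chrom": r["chrom"],
            "start": r["start"], "end": r["end"], "class": r["name"], "is_target": True,
        }
        for m in marks:
            row[f"fold_{m}"] = config.target_enrichment[m]
        rows.append(row)
    for i, r in repeats_df.iterrows():
        row = {
            "kind": "repeat", "id": f"rep_{i + 1:04d}", "chrom": r["chrom"],
            "start": r["start"], "end": r["end"], "class": r["name"], "is_target": False,
        }
        for m in marks:
            row[f"fold_{m}"] = 1.0
        rows.append(row)
    truth = TruthTable(
        elements=pd.DataFrame(rows),
        genotype_effects=dict(config.genotype_effects),
        generation_decay=config.generation_decay,
        background_enrichment_arms=config.background_enrichment_arms,
        marks=marks,
    )
    return layout, genes_df, repeats_df, regions_df, truth


def _library_seed(config: SimConfig, mark: str, genotype: str, role: str,
                  replicate: int, generation: int) -> np.random.Generator:
    tag = zlib.crc32(f"{mark}|{genotype}|{role}|{replicate}|{generation}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _repeat_index(truth: TruthTable) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome sorted (starts, ends, family-group id) of repeat copies."""
    reps = truth.elements[truth.elements["kind"] == "repeat"]
    fam_codes = pd.Categorical(reps["class"]).codes
    out = {}
    for chrom in reps["chrom"].unique():
        sel = reps["chrom"] == chrom
        order = np.argsort(reps.loc[sel, "start"].to_numpy())
        out[chrom] = (
            reps.loc[sel, "start"].to_numpy()[order],
            reps.loc[sel, "end"].to_numpy()[order],
            fam_codes[np.flatnonzero(sel)][order],
        )
    return out


def simulate_library(
    config: SimConfig,
    truth: TruthTable,
    mark: str,
    genotype: str,
    role: str = "chip",
    replicate: int = 1,
    generation: int = 0,
    seed: int | None = None,
) -> Library:
    """Draw one sequencing library of exactly ``config.n_reads`` reads.

    ChIP libraries sample read starts from the planted-enrichment mixture
    (arm background plus per-element excess); input libraries are uniform
    background only. Reads wholly inside a repeat copy become multimappers:
    one record per copy of the family, all with ``n_hits = copy_number``.
    """
    if role not in ("chip", "input"):
        raise ValueError(f"role must be 'chip' or 'input', got {role!r}")
    if mark not in config.target_enrichment:
        raise KeyError(f"unknown mark {mark!r}")
    if genotype not in config.genotype_effects:
        raise KeyError(f"unknown genotype {genotype!r}")
    if config.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else _library_seed(config, mark, genotype, role, replicate, generation)
    )
    layout = GenomeLayout.from_arm_fraction(config.chrom_lengths, config.arm_fraction)
    rl = config.read_length

    # piecewise-constant start-position intensity per chromosome
    seg_chrom, seg_start, seg_end, seg_int = [], [], [], []
    for chrom, length in layout.chrom_lengths.items():
        domain = length - rl + 1  # valid 5'-leftmost start positions
        if domain <= 0:
            continue
        diff = np.zeros(domain + 1)
        if role == "chip":
            a, b = layout.arms[chrom]
            excess = truth.background_enrichment_arms - 1.0
            if excess > 0:
                for s, e in ((0, a), (b, length)):
                    s, e = min(s, domain), min(e, domain)
                    if e > s:
                        diff[s] += excess
                        diff[e] -= excess
            els = truth.elements
            planted = els[(els["chrom"] == chrom) & els["is_target"]]
            for _, el in planted.iterrows():
                f = truth.fold(el[f"fold_{mark}"], genotype, generation)
                if f > 1.0:
                    s, e = min(int(el["start"]), domain), min(int(el["end"]), domain)
                    if e > s:
                        diff[s] += f - 1.0
                        diff[e] -= f - 1.0
        intensity = np.cumsum(diff[:-1]) + 1.0
        change = np.flatnonzero(np.diff(intensity)) + 1
        bounds = np.concatenate(([0], change, [domain]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg_chrom.append(chrom)
            seg_start.append(int(s))
            seg_end.append(int(e))
            seg_int.append(float(intensity[s]))

    seg_start_a = np.array(seg_start)
    seg_len = np.array(seg_end) - seg_start_a
    w = np.asarray(seg_int) * seg_len
    counts = rng.multinomial(config.n_reads, w / w.sum())

    rep_index = _repeat_index(truth)
    fam_sizes: dict[int, int] = {}
    fam_members: dict[int, list[tuple[str, int]]] = {}
    reps = truth.elements[truth.elements["kind"] == "repeat"]
    fam_codes = pd.Categorical(reps["class"]).codes
    for (chrom, start), code in zip(zip(reps["chrom"], reps["start"]), fam_codes):
        fam_members.setdefault(int(code), []).append((chrom, int(start)))
    fam_sizes = {c: len(m) for c, m in fam_members.items()}

    records: list[AlignmentRecord] = []
    read_no = 0
    for i in np.flatnonzero(counts):
        chrom = seg_chrom[i]
        starts = seg_start_a[i] + rng.integers(0, seg_len[i], size=counts[i])
        strands = rng.integers(0, 2, size=counts[i])
        # which reads lie wholly inside a repeat copy (vectorized lookup)
        fams = np.full(counts[i], -1)
        offsets = np.zeros(counts[i], dtype=int)
        idx = rep_index.get(chrom)
        if idx is not None:
            rs, re, rf = idx
            k = np.searchsorted(rs, starts, side="right") - 1
            kc = np.clip(k, 0, None)
            inside = (k >= 0) & (starts + rl <= re[kc])
            fams[inside] = rf[kc[inside]]
            offsets[inside] = starts[inside] - rs[kc[inside]]
        for s, st, fam, offset in zip(starts, strands, fams, offsets):
            read_no += 1
            rid = f"r{read_no:07d}"
            strand = "+" if st else "-"
            if fam >= 0 and fam_sizes[int(fam)] > 1:
                n = fam_sizes[int(fam)]
                for cchrom, cstart in fam_members[int(fam)]:
                    records.append(
                        AlignmentRecord(rid, cchrom, cstart + int(offset), strand, rl, n)
                    )
            else:
                records.append(AlignmentRecord(rid, chrom, int(s), strand, rl, 1))

    meta = LibraryMeta(
        sample=f"{mark}_{genotype.replace(' ', '-')}_{role}_rep{replicate}_F{generation}",
        mark=mark, genotype=genotype, role=role,
        replicate=replicate, generation=generation,
    )
    return Library(records, meta)


def simulate_heritable_series(
    config: SimConfig,
    truth: TruthTable,
    mark: str,
    generations: int,
    genotype: str = "WT",
) -> list[tuple[Library, Library]]:
    """One (ChIP, input) library pair per generation F0..F(generations).

    The planted fold at every target decays geometrically:
    ``f_g = 1 + (f_0 - 1) * d**g`` with ``d = config.generation_decay``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    series = []
    for g in range(generations + 1):
        chip = simulate_library(config, truth, mark, genotype, "chip", generation=g)
        inp = simulate_library(config, truth, mark, genotype, "input", generation=g)
        series.append((chip, inp))
    return series
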