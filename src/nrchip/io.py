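"""File formats: chrom sizes, BED6, minimal SAM / alignment TSV, bedGraph.

All intervals are 0-based half-open internally and in every BED/bedGraph
written; GFF input is converted from 1-based closed coordinates on read.
Output tables carry ``#`` comment headers naming the units and parameters
used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .coverage import AlignmentRecord, CoverageTrack, Library, LibraryMeta
from .genome import GenomeLayout
from .simulate import BED_COLUMNS, SimConfig, TruthTable

log = logging.getLogger("nrchip")

TSV_COLUMNS = ["read_id", "chrom", "start0", "strand", "read_len", "n_hits"]


# -- genome layout ----------------------------------------------------------

def write_layout(layout: GenomeLayout, sizes_path: str | Path, arms_path: str | Path) -> None:
    """Write chromosome sizes as two-column TSV and the arm partition as BED."""
    with open(sizes_path, "w") as fh:
        for name, length in layout.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")
    with open(arms_path, "w") as fh:
        for chrom in layout.chromosomes:
            for name, (a, b) in layout.arm_intervals(chrom).items():
                fh.write(f"{chrom}\t{a}\t{b}\t{name}\n")


def read_layout(sizes_path: str | Path, arms_path: str | Path | None = None) -> GenomeLayout:
    sizes = {}
    with open(sizes_path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split()[:2]
                sizes[name] = int(length)
    arms: dict[str, tuple[int, int]] = {}
    if arms_path is not None:
        bounds: dict[str, dict[str, tuple[int, int]]] = {}
        with open(arms_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, name = line.split()[:4]
                bounds.setdefault(chrom, {})[name] = (int(start), int(end))
        arms = {c: (iv["center"][0], iv["center"][1]) for c, iv in bounds.items()}
    return GenomeLayout(sizes, arms)


# -- BED / GFF annotations --------------------------------------------------

def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6 annotation (name column carries gene id or repeat class)."""
    frame[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BED_COLUMNS, usecols=range(6),
    )
    return frame.astype({"start": int, "end": int})


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open).

    Only ``gene``/``mRNA`` features are kept; the ``ID`` attribute is the
    gene id.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "mRNA"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                (f[0], int(f[3]) - 1, int(f[4]), attrs.get("ID", f"{f[0]}:{f[3]}"),
                 0, f[6] if f[6] in "+-" else ".")
            )
    return pd.DataFrame(rows, columns=BED_COLUMNS)


# -- alignment libraries ----------------------------------------------------

def write_library_tsv(library: Library, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for r in library.records:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.strand}\t{r.read_length}\t{r.n_hits}\n")


def write_library_sam(library: Library, layout: GenomeLayout, path: str | Path) -> None:
    """Write a minimal SAM: QNAME/FLAG/RNAME/POS/MAPQ 255/CIGAR plus NH tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": l} for c, l in layout.chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(layout.chromosomes)}
        for r in library.records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{r.read_length}M"
            a.set_tag("NH", r.n_hits, "i")
            out.write(a)


def _validate_read_groups(records: list[AlignmentRecord]) -> None:
    counts: dict[str, int] = {}
    hits: dict[str, int] = {}
    bad = set()
    for r in records:
        counts[r.read_id] = counts.get(r.read_id, 0) + 1
        if hits.setdefault(r.read_id, r.n_hits) != r.n_hits:
            bad.add(r.read_id)
    bad |= {rid for rid, c in counts.items() if c != hits[rid]}
    if bad:
        raise ValueError(
            f"{len(bad)} reads violate n_hits consistency: "
            + ", ".join(sorted(bad)[:10])
        )


def read_library_tsv(path: str | Path, meta: LibraryMeta | None = None) -> Library:
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, names=TSV_COLUMNS)
    records = [
        AlignmentRecord(str(r.read_id), str(r.chrom), int(r.start0), str(r.strand),
                        int(r.read_len), int(r.n_hits))
        for r in frame.itertuples(index=False)
    ]
    _validate_read_groups(records)
    return Library(records, meta or LibraryMeta())


def read_library_sam(path: str | Path, meta: LibraryMeta | None = None) -> Library:
    """Read a minimal SAM; unmapped records are skipped with a logged count."""
    records = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                skipped += 1
                continue
            n_hits = int(a.get_tag("NH")) if a.has_tag("NH") else 1
            records.append(
                AlignmentRecord(
                    a.query_name, a.reference_name, a.reference_start,
                    "-" if a.is_reverse else "+", a.query_alignment_length or a.infer_query_length() or 0,
                    n_hits,
                )
            )
    if skipped:
        log.info("skipped %d unmapped records in %s", skipped, path)
    _validate_read_groups(records)
    return Library(records, meta or LibraryMeta())


# -- truth table ------------------------------------------------------------

def write_truth(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# planted enrichment truth; fold_<mark> is the WT F0 fold; "
            f"genotype_effects={truth.genotype_effects}; "
            f"generation_decay={truth.generation_decay}; "
            f"background_enrichment_arms={truth.background_enrichment_arms}\n"
        )
        truth.elements.to_csv(fh, sep="\t", index=False)


# -- coverage tracks --------------------------------------------------------

def write_track(track: CoverageTrack, path: str | Path, emit_zeros: bool = True) -> None:
    """Write a coverage track as bedGraph, merging adjacent equal-value bins.

    With ``emit_zeros=False`` zero-valued intervals are omitted (sparse
    dialect); the default writes them so the file tiles each chromosome.
    Values are printed with 10 significant digits.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# bedGraph coverage, reads-per-million units; bin_size={track.bin_size} "
            f"extension={track.extension} normalization_factor={track.normalization_factor:.10g}\n"
        )
        for chrom in track.layout.chromosomes:
            vec = track.values[chrom]
            length = track.layout.chrom_lengths[chrom]
            i = 0
            while i < len(vec):
                j = i
                while j + 1 < len(vec) and vec[j + 1] == vec[i]:
                    j += 1
                start = i * track.bin_size
                end = min((j + 1) * track.bin_size, length)
                if emit_zeros or vec[i] != 0:
                    fh.write(f"{chrom}\t{start}\t{end}\t{vec[i]:.10g}\n")
                i = j + 1


def read_track(
    path: str | Path,
    layout: GenomeLayout,
    bin_size: int,
    normalization_factor: float = 1.0,
    extension: int = 500,
) -> CoverageTrack:
    values = {
        c: np.zeros(-(-l // bin_size)) for c, l in layout.chrom_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            s, e, v = int(start), int(end), float(value)
            values[chrom][s // bin_size: -(-e // bin_size)] = v
    return CoverageTrack(layout, bin_size, values, normalization_factor, extension)


def write_table(frame: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    """Write a TSV with a '#' header naming units/parameters."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run parameterization (defaults follow the pipeline's
    standard settings: 500 bp extension, 1 kb windows, two-fold cutoff,
    alpha 0.05)."""

    sim: SimConfig = field(default_factory=SimConfig)
    mark: str = "H3K23me3"
    genotypes: list[str] = field(default_factory=lambda: ["hrde-1", "set-32", "met-2 set-25"])
    replicates: int = 2
    extension: int = 500
    bin_size: int = 25
    window_size: int = 1000
    fold_threshold: float = 2.0
    alpha: float = 0.05
    mode: str = "p"
    flank: int = 0
    pseudocount: float | None = None
    outdir: str = "nrchip_out"


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = raw.pop("sim", {})
    if "chrom_lengths" in sim_kwargs:
        sim_kwargs["chrom_lengths"] = [tuple(x) for x in sim_kwargs["chrom_lengths"]]
    if "repeat_families" in sim_kwargs:
        sim_kwargs["repeat_families"] = [tuple(x) for x in sim_kwargs["repeat_families"]]
    return RunConfig(sim=SimConfig(**sim_kwargs), **raw)
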