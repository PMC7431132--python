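"""Genome layout: chromosome sizes and the arm/center partition.

C. elegans autosomes carry heterochromatin-enriched distal "arms" flanking a
gene-dense center. Everything downstream (coverage binning, window
classification, arm-vs-center statistics) is expressed in this coordinate
frame. All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with an arm/center/arm partition of each.

    Parameters
    ----------
    chrom_lengths:
        Mapping of chromosome name to length in bp, in genome order
        (insertion order is preserved and significant).
    arms:
        Mapping of chromosome name to ``(left_arm_end, right_arm_start)``.
        The three intervals ``[0, left_arm_end)``, ``[left_arm_end,
        right_arm_start)`` and ``[right_arm_start, length)`` tile the
        chromosome exactly.
    """

    chrom_lengths: dict[str, int]
    arms: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if not self.arms:
            # degenerate partition: everything is "center"
            object.__setattr__(
                self, "arms", {n: (0, l) for n, l in self.chrom_lengths.items()}
            )
        for name in self.arms:
            if name not in self.chrom_lengths:
                raise ValueError(f"arm entry for unknown chromosome {name!r}")
        for name, length in self.chrom_lengths.items():
            if name not in self.arms:
                raise ValueError(f"chromosome {name!r} missing an arm partition")
            a, b = self.arms[name]
            if not (0 <= a <= b <= length):
                raise ValueError(
                    f"arm boundaries {(a, b)} of {name!r} do not partition [0, {length})"
                )

    @classmethod
    def from_arm_fraction(
        cls, chrom_lengths: dict[str, int] | list[tuple[str, int]], arm_fraction: float
    ) -> "GenomeLayout":
        """Build a layout where each arm spans ``arm_fraction`` of its chromosome."""
        if not 0.0 <= arm_fraction <= 0.5:
            raise ValueError("arm_fraction must be in [0, 0.5]")
        lengths = dict(chrom_lengths)
        arms = {
            n: (int(round(l * arm_fraction)), l - int(round(l * arm_fraction)))
            for n, l in lengths.items()
        }
        return cls(lengths, arms)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def arm_intervals(self, chrom: str) -> dict[str, tuple[int, int]]:
        """The left/center/right intervals of one chromosome."""
        a, b = self.arms[chrom]
        return {
            "left_arm": (0, a),
            "center": (a, b),
            "right_arm": (b, self.chrom_lengths[chrom]),
        }

    def compartment(self, chrom: str, pos: int) -> str:
        """Classify a position as ``"arm"`` or ``"center"``."""
        a, b = self.arms[chrom]
        return "center" if a <= pos < b else "arm"

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return (
            chrom in self.chrom_lengths
            and 0 <= start <= end <= self.chrom_lengths[chrom]
        )
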