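"""Annotated G-quadruplex-forming sequences and expected unfolding step sizes.

The sequences studied here are four-G-tract parallel G4 designs written with
their tracts space-separated, e.g. ``TTGTGGT GGGT GGGT GGGT``: twelve
tetrad-core guanines (three per tract), thymine loops/flanks, and optionally a
thymine bulge interrupting one of the eight successive guanine pairs of the
core columns.

The expected unfolding step size of a folding topology is the inclusive
nucleotide span between the outermost *structured* core guanines: loops and
internal bulges count, dangling tails do not.  Peeling the 5′- or 3′-terminal
core guanine out of the tetrad core (a guanine-vacancy-bearing G4, GVBQ)
shortens the span accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources

__all__ = [
    "FoldingTopology",
    "SequenceAnnotation",
    "parse_spaced_tracts",
    "expected_step_nt",
    "load_reference_sequences",
]

_ALPHABET = set("ACGT")


class FoldingTopology(Enum):
    """Which guanines form the tetrad core."""

    FULL = "full"          # all core guanines structured
    GVBQ_5P = "gvbq_5p"    # 5'-terminal core guanine flipped out
    GVBQ_3P = "gvbq_3p"    # 3'-terminal core guanine flipped out


@dataclass(frozen=True)
class SequenceAnnotation:
    """A G4-forming sequence with its tetrad-core guanine positions.

    sequence        : concatenated 5'→3' sequence (ACGT)
    tract_guanines  : 1-based positions of the tetrad-core guanines,
                      strictly increasing
    bulge_position  : 1-based index (1–8) of the guanine-pair gap holding the
                      bulge, or None for bulge-free designs
    bulge_length    : bulge length in nt (0 iff no bulge)
    """

    name: str
    sequence: str
    tract_guanines: tuple[int, ...]
    bulge_position: int | None
    bulge_length: int

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _ALPHABET:
            raise ValueError(f"{self.name}: sequence contains non-ACGT characters")
        pos = self.tract_guanines
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.name}: tract guanine positions must increase")
        for p in pos:
            if not 1 <= p <= len(self.sequence) or self.sequence[p - 1] != "G":
                raise ValueError(f"{self.name}: position {p} is not a guanine")
        if (self.bulge_length == 0) != (self.bulge_position is None):
            raise ValueError(f"{self.name}: bulge_length and bulge_position disagree")


def parse_spaced_tracts(name: str, spaced_sequence: str) -> SequenceAnnotation:
    """Parse a space-separated four-tract G4 design.

    The whitespace grouping is the tract specification: each of the four
    blocks carries one G-tract (the first block also carries the 5' flank).
    All guanines in the sequence are tetrad-core guanines; a gap between two
    successive guanines *within* a block is a bulge, indexed 1–8 over the
    guanine pairs of the four tracts.
    """
    blocks = spaced_sequence.split()
    if len(blocks) != 4:
        raise ValueError(f"{name}: expected 4 space-separated tracts, got {len(blocks)}")
    sequence = "".join(blocks)
    if not set(sequence) <= _ALPHABET:
        raise ValueError(f"{name}: sequence contains non-ACGT characters")

    guanines: list[int] = []
    bulge_position: int | None = None
    bulge_length = 0
    pair_index = 0
    offset = 0
    for block in blocks:
        block_gs = [offset + i + 1 for i, base in enumerate(block) if base == "G"]
        if len(block_gs) < 2:
            raise ValueError(f"{name}: tract {block!r} holds fewer than 2 guanines")
        for a, b in zip(block_gs, block_gs[1:]):
            pair_index += 1
            gap = b - a - 1
            if gap > 0:
                if bulge_position is not None:
                    raise ValueError(f"{name}: more than one bulge found")
                if set(sequence[a : b - 1]) - _ALPHABET:
                    raise ValueError(f"{name}: malformed bulge in tract {block!r}")
                bulge_position = pair_index
                bulge_length = gap
        guanines.extend(block_gs)
        offset += len(block)
    if len(guanines) != 12:
        raise ValueError(
            f"{name}: expected 12 tetrad-core guanines, found {len(guanines)}"
        )
    return SequenceAnnotation(
        name=name,
        sequence=sequence,
        tract_guanines=tuple(guanines),
        bulge_position=bulge_position,
        bulge_length=bulge_length,
    )


def expected_step_nt(
    annotation: SequenceAnnotation, topology: FoldingTopology
) -> int:
    """Expected released nucleotides for a folding topology.

    Inclusive span between the outermost structured core guanines:

    - FULL:     last − first + 1
    - GVBQ_5P:  last − second + 1  (5'-terminal core guanine peeled)
    - GVBQ_3P:  second-to-last − first + 1  (3'-terminal peeled)
    """
    g = annotation.tract_guanines
    if len(g) < 2:
        raise ValueError("annotation must hold at least two core guanines")
    if topology is FoldingTopology.FULL:
        return g[-1] - g[0] + 1
    if topology is FoldingTopology.GVBQ_5P:
        return g[-1] - g[1] + 1
    if topology is FoldingTopology.GVBQ_3P:
        return g[-2] - g[0] + 1
    raise ValueError(f"unknown topology: {topology!r}")


def load_reference_sequences() -> dict[str, SequenceAnnotation]:
    """Load the packaged reference panel of bulged G4 designs (TSV:
    name <TAB> spaced sequence)."""
    text = (
        resources.files("g4tweezers").joinpath("data/g4_sequences.tsv").read_text()
    )
    annotations: dict[str, SequenceAnnotation] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, spaced = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"g4_sequences.tsv line {lineno}: {exc}") from exc
        annotations[name] = parse_spaced_tracts(name, spaced)
    return annotations
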