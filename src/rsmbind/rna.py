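"""RNA sequence + secondary-structure container and local-context extraction.

Structures are plain pseudoknot-free dot-bracket strings; base pairs are held
in a pair table (``partner[i]`` is the paired index or ``None``).  All
coordinates are 0-based half-open internally; user-facing reports are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "RnaParseError",
    "RnaMolecule",
    "LoopContext",
    "parse_vienna",
    "parse_vienna_file",
    "build_pair_table",
    "to_vienna",
    "hairpin_context",
    "pairing_status",
]

_BASES = frozenset("ACGU")


class RnaParseError(ValueError):
    """Raised for malformed Vienna records (names the record and problem)."""


def normalize_sequence(raw: str) -> str:
    """Uppercase, map T to U, reject anything outside A/C/G/U."""
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - _BASES
    if bad:
        raise RnaParseError(f"illegal sequence character(s): {sorted(bad)}")
    return seq


def build_pair_table(structure: str) -> tuple[Optional[int], ...]:
    """Pair table for a balanced ``()``/``.`` dot-bracket string.

    Returns a tuple where entry i is the partner index of position i, or
    ``None`` if unpaired.  Only plain parentheses are accepted; square or
    curly brackets (pseudoknot notation) are an error.
    """
    partner: list[Optional[int]] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise RnaParseError(f"unbalanced structure at position {i + 1}")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif ch != ".":
            raise RnaParseError(f"illegal structure character {ch!r} at position {i + 1}")
    if stack:
        raise RnaParseError(f"unbalanced structure: {len(stack)} unclosed '('")
    return tuple(partner)


@dataclass(frozen=True)
class RnaMolecule:
    """A named RNA with sequence, dot-bracket structure and pair table."""

    name: str
    sequence: str
    structure: str
    pairs: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise RnaParseError(
                f"record {self.name!r}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_strings(cls, name: str, sequence: str, structure: str) -> "RnaMolecule":
        seq = normalize_sequence(sequence)
        struct = structure.strip()
        if len(seq) != len(struct):
            raise RnaParseError(
                f"record {name!r}: sequence length {len(seq)} != structure length {len(struct)}"
            )
        try:
            pairs = build_pair_table(struct)
        except RnaParseError as exc:
            raise RnaParseError(f"record {name!r}: {exc}") from None
        return cls(name=name, sequence=seq, structure=struct, pairs=pairs)

    def is_paired(self, pos: int) -> bool:
        return self.pairs[pos] is not None


@dataclass(frozen=True)
class LoopContext:
    """Local unpaired context around a position.

    ``is_hairpin`` is True only for a loop of >= 3 unpaired nucleotides closed
    by a single base pair.  Unpaired stretches that are not hairpin loops
    (exterior/single-stranded regions, internal loops, bulges, loops on a
    lone pair) carry ``is_hairpin=False`` and no closing pair.
    """

    loop_start: int  # 0-based, inclusive
    loop_end: int  # 0-based, exclusive
    is_hairpin: bool
    closing_pair: Optional[tuple[int, int]] = None  # indices (5', 3')
    closing_bases: Optional[tuple[str, str]] = None
    penultimate_bases: Optional[tuple[str, str]] = None
    stem_length: int = 0

    @property
    def loop_length(self) -> int:
        return self.loop_end - self.loop_start


def parse_vienna(text: str) -> list[RnaMolecule]:
    """Parse multi-record Vienna text (``>name`` / sequence / structure).

    Record order is preserved.  T is normalized to U, case folded; structural
    brackets are validated.  Errors name the offending record and line.
    """
    molecules: list[RnaMolecule] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise RnaParseError(f"line {i + 1}: expected '>' header, got {line[:30]!r}")
        name = line[1:].strip() or f"record_{len(molecules) + 1}"
        if i + 2 >= len(lines) + 1 and i + 2 > len(lines):
            raise RnaParseError(f"record {name!r}: truncated (missing sequence/structure)")
        body = [l.strip() for l in lines[i + 1 : i + 3] if l.strip()]
        if len(body) < 2:
            raise RnaParseError(f"record {name!r} (line {i + 1}): missing sequence or structure line")
        molecules.append(RnaMolecule.from_strings(name, body[0], body[1]))
        i += 3
    return molecules


def parse_vienna_file(path: str) -> list[RnaMolecule]:
    with open(path) as fh:
        text = fh.read()
    mols = parse_vienna(text)
    if not mols:
        raise RnaParseError(f"no records in {path}")
    return mols


def to_vienna(molecules: Iterable[RnaMolecule]) -> str:
    """Serialize molecules back to multi-record Vienna text."""
    chunks = [f">{m.name}\n{m.sequence}\n{m.structure}" for m in molecules]
    return "\n".join(chunks) + "\n"


def _unpaired_run(rna: RnaMolecule, pos: int) -> tuple[int, int]:
    """Maximal unpaired interval [a, b) containing unpaired pos."""
    a, b = pos, pos + 1
    while a > 0 and rna.pairs[a - 1] is None:
        a -= 1
    while b < len(rna) and rna.pairs[b] is None:
        b += 1
    return a, b


def hairpin_context(rna: RnaMolecule, pos: int) -> Optional[LoopContext]:
    """Local context of ``pos``: hairpin loop, single-stranded, or None.

    Returns ``None`` when the position is base-paired ("not in a hairpin").
    For an unpaired position the maximal unpaired run is inspected: if it is
    closed by one base pair on both sides (``pairs[a-1] == b``) and is at
    least 3 nt long, it is a hairpin loop and the closing pair, penultimate
    pair and contiguous stem length are reported; any other unpaired context
    is flagged single-stranded.
    """
    if pos < 0 or pos >= len(rna):
        raise IndexError(f"position {pos} out of range for {rna.name!r} (length {len(rna)})")
    if rna.pairs[pos] is not None:
        return None
    a, b = _unpaired_run(rna, pos)
    is_closed = a > 0 and b < len(rna) and rna.pairs[a - 1] == b
    if not is_closed or (b - a) < 3:
        return LoopContext(loop_start=a, loop_end=b, is_hairpin=False)
    # contiguous stacked pairs below the closing pair (no bulge tolerance)
    stem = 0
    while (
        a - 1 - stem >= 0
        and b + stem < len(rna)
        and rna.pairs[a - 1 - stem] == b + stem
    ):
        stem += 1
    closing = (a - 1, b)
    penult = None
    if stem >= 2:
        penult = (rna.sequence[a - 2], rna.sequence[b + 1])
    return LoopContext(
        loop_start=a,
        loop_end=b,
        is_hairpin=True,
        closing_pair=closing,
        closing_bases=(rna.sequence[closing[0]], rna.sequence[closing[1]]),
        penultimate_bases=penult,
        stem_length=stem,
    )


def pairing_status(rna: RnaMolecule, span: tuple[int, int]) -> tuple[int, int]:
    """Count base-paired positions in half-open ``span`` -> (n_paired, n_total)."""
    start, end = span
    if end <= start:
        raise ValueError(f"empty span {span}")
    if start < 0 or end > len(rna):
        raise IndexError(f"span {span} out of range for {rna.name!r}")
    n_paired = sum(1 for i in range(start, end) if rna.pairs[i] is not None)
    return n_paired, end - start
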