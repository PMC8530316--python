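"""Restriction digest model and proximity-ligation junction enumeration.

In a Hi-C prep, restriction enzymes leave 5' overhangs that are end-filled
with biotinylated nucleotides before blunt ligation.  The resulting ligation
junction therefore carries a predictable sequence: the end-filled terminus of
the upstream fragment followed by the end-filled terminus of the downstream
fragment.  For a single palindromic enzyme this is the recognition context
with its overhang duplicated (DpnII ``^GATC`` -> ``GATCGATC``, 8 bp; HindIII
``A^AGCTT`` -> ``AAGCTAGCTT``, 10 bp).  Dual digests produce every ordered
combination of end types.

This module models enzymes (by name or caret notation), enumerates the
junction motif set for one- or two-enzyme digests, expands IUPAC ambiguity
codes into concrete search sequences, and locates recognition sites on a
reference sequence.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "Enzyme",
    "JunctionMotif",
    "JunctionSet",
    "parse_enzyme",
    "junction_set",
    "expand_ambiguity",
    "find_cut_sites",
    "DigestError",
]

# Degenerate-base expansions, e.g. N -> ACGT, R -> AG.  Keys include ACGT.
_IUPAC: dict[str, str] = {b: v for b, v in ambiguous_dna_values.items()}

# Small built-in table of 5'-overhang enzymes in common Hi-C use.
# Caret marks the top-strand cut within the recognition site.
_BUILTIN_ENZYMES: dict[str, str] = {
    "DpnII": "^GATC",
    "Sau3AI": "^GATC",
    "MluCI": "^AATT",
    "HindIII": "A^AGCTT",
    "HinfI": "G^ANTC",
    "MboI": "^GATC",
}

MAX_EXPANSION = 256


class DigestError(ValueError):
    """Raised for unsupported or malformed enzyme/junction specifications."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with a 5'-overhang-producing, palindromic site.

    ``cut_offset_top`` is the 0-based offset of the top-strand cut within
    the site (the cut falls immediately before ``site[cut_offset_top]``).
    """

    name: str
    site: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if not site or any(b not in _IUPAC for b in site):
            raise DigestError(f"invalid recognition site {self.site!r}")
        object.__setattr__(self, "site", site)
        if not 0 <= self.cut_offset_top <= len(site):
            raise DigestError("cut offset outside recognition site")
        if reverse_complement(site) != site:
            raise DigestError(
                f"{self.name}: non-palindromic sites are not supported"
            )
        ov = len(site) - 2 * self.cut_offset_top
        if ov == 0:
            raise DigestError(
                f"{self.name}: blunt cutter leaves no overhang, so ligation "
                "creates no junction duplication"
            )
        if ov < 0:
            raise DigestError(
                f"{self.name}: 3' overhangs are not modelled (end-fill "
                "chemistry assumes 5' overhangs)"
            )

    @property
    def overhang(self) -> str:
        """The 5' single-stranded overhang produced by the cut."""
        return self.site[self.cut_offset_top : len(self.site) - self.cut_offset_top]

    @property
    def overhang_sense(self) -> str:
        return "five-prime"

    @property
    def end_fill_left(self) -> str:
        """End-filled terminal sequence of the fragment left of the cut."""
        return self.site[: len(self.site) - self.cut_offset_top]

    @property
    def end_fill_right(self) -> str:
        """End-filled leading sequence of the fragment right of the cut."""
        return self.site[self.cut_offset_top :]


@dataclass(frozen=True)
class JunctionMotif:
    """One ligation-junction motif (possibly IUPAC-ambiguous)."""

    sequence: str
    source: tuple[str, str]

    @property
    def l_la(self) -> int:
        return len(self.sequence)


@dataclass
class JunctionSet:
    """All junction motifs of a digest plus their concrete expansions.

    ``concrete`` is ambiguity-expanded and closed under reverse complement,
    so searching a read finds junctions regardless of which strand was
    sequenced.
    """

    motifs: tuple[JunctionMotif, ...]
    enzymes: tuple[Enzyme, ...]
    concrete: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        seqs: set[str] = set()
        for m in self.motifs:
            for s in expand_ambiguity(m.sequence):
                seqs.add(s)
                seqs.add(reverse_complement(s))
        self.concrete = tuple(sorted(seqs))

    @property
    def l_la_max(self) -> int:
        return max(m.l_la for m in self.motifs)

    @property
    def l_la_min(self) -> int:
        return min(m.l_la for m in self.motifs)


def parse_enzyme(spec: str) -> Enzyme:
    """Parse an enzyme name (built-in table) or caret notation ``A^AGCTT``."""
    spec = spec.strip()
    if spec in _BUILTIN_ENZYMES:
        caret = _BUILTIN_ENZYMES[spec]
        return Enzyme(spec, caret.replace("^", ""), caret.index("^"))
    if "^" in spec:
        if spec.count("^") != 1:
            raise DigestError(f"{spec!r}: exactly one caret expected")
        return Enzyme(spec, spec.replace("^", ""), spec.index("^"))
    if re.fullmatch(r"[A-Za-z]+", spec) and all(b in _IUPAC for b in spec.upper()):
        raise DigestError(
            f"{spec!r}: no cut position; use caret notation, e.g. G^AATTC"
        )
    raise DigestError(f"unknown enzyme {spec!r}")


def junction_set(enz_a: Enzyme, enz_b: Enzyme | None = None) -> JunctionSet:
    """Enumerate junction motifs for a one- or two-enzyme digest.

    Each motif is the concatenation of an end-filled upstream terminus and an
    end-filled downstream terminus, over all ordered enzyme combinations.
    The set is reverse-complement closed by construction (palindromic sites).
    """
    enzymes = (enz_a,) if enz_b is None else (enz_a, enz_b)
    seen: dict[str, JunctionMotif] = {}
    for a, b in itertools.product(enzymes, repeat=2):
        seq = a.end_fill_left + b.end_fill_right
        if seq not in seen:
            seen[seq] = JunctionMotif(seq, (a.name, b.name))
    return JunctionSet(tuple(seen.values()), enzymes)


def expand_ambiguity(sequence: str) -> tuple[str, ...]:
    """Expand IUPAC ambiguity codes into all concrete ACGT sequences."""
    if not sequence:
        raise DigestError("empty sequence")
    try:
        choices = [_IUPAC[b] for b in sequence.upper()]
    except KeyError as exc:
        raise DigestError(f"invalid base {exc.args[0]!r}") from exc
    n = 1
    for c in choices:
        n *= len(c)
    if n > MAX_EXPANSION:
        raise DigestError(
            f"ambiguity expansion of {sequence!r} yields {n} sequences "
            f"(cap {MAX_EXPANSION})"
        )
    return tuple("".join(p) for p in itertools.product(*choices))


def _site_regex(site: str) -> re.Pattern[str]:
    pat = "".join(b if len(_IUPAC[b]) == 1 else f"[{_IUPAC[b]}]" for b in site)
    return re.compile(f"(?=({pat}))")  # lookahead: overlapping occurrences


def find_cut_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut positions (0-based) of ``enzyme`` on ``sequence``.

    Palindromic sites match identically on both strands, so a single
    forward scan suffices; each occurrence yields one cut coordinate.
    """
    seq = sequence.upper()
    rx = _site_regex(enzyme.site)
    return [m.start() + enzyme.cut_offset_top for m in rx.finditer(seq)]
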