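"""Frame-aware nucleotide sequence primitives.

Provides the two domain types used throughout the package — :class:`NucSeq`
(a validated DNA string with linear or circular topology) and :class:`Orf`
(a frame-anchored open reading frame) — plus reverse complementation,
codon iteration, translation and FASTA/GenBank I/O.

Conventions
-----------
* Coordinates are 0-based, half-open.  On circular sequences positions are
  taken modulo length and fragment extraction wraps across the origin.
* Translation uses the standard genetic code (NCBI table 1).  Codons
  containing ``N`` translate to ``X`` and are never treated as stops.
* Input is uppercased on ingest; ``U`` is rejected (DNA only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LINEAR = "linear"
CIRCULAR = "circular"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_VALID_BASES = frozenset("ACGTN")

# Standard code (table 1).  Built from Biopython's table so the mapping has a
# single authoritative source; the test suite checks it against an independent
# hand-written table.
_CODON_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
_CODON_TABLE.update({c: "*" for c in STOP_CODONS})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Input contains characters outside {A, C, G, T, N}."""


class FrameError(ValueError):
    """Sequence length is incompatible with the requested reading frame."""


@dataclass(frozen=True)
class NucSeq:
    """A DNA sequence with explicit topology.

    Parameters
    ----------
    bases:
        Nucleotide string over ``ACGT`` (``N`` permitted).  Lowercase input
        is uppercased; ``U`` raises :class:`SequenceAlphabetError`.
    topology:
        ``"linear"`` or ``"circular"``.  Immutable after construction.
    id:
        Free-text identifier (FASTA header, plasmid name, ...).
    """

    bases: str
    topology: str = LINEAR
    id: str = ""

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise SequenceAlphabetError("empty sequence")
        if "U" in bases:
            raise SequenceAlphabetError("RNA base 'U' not accepted (DNA only)")
        bad = set(bases) - _VALID_BASES
        if bad:
            raise SequenceAlphabetError(
                f"invalid nucleotide characters: {sorted(bad)!r}"
            )
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def fragment(self, start: int, end: int) -> str:
        """Bases in ``[start, end)``; wraps across the origin when circular.

        For circular sequences ``start`` may be any integer (taken modulo
        length) and ``end - start`` must lie in ``[0, len]``.
        """
        n = len(self.bases)
        if not self.is_circular:
            if start < 0 or end > n or start > end:
                raise IndexError(f"[{start}, {end}) out of range for linear length {n}")
            return self.bases[start:end]
        span = end - start
        if span < 0 or span > n:
            raise IndexError(f"fragment span {span} invalid for circular length {n}")
        start %= n
        if start + span <= n:
            return self.bases[start:start + span]
        return self.bases[start:] + self.bases[:start + span - n]

    def rotated(self, offset: int) -> "NucSeq":
        """The same circle written starting from ``offset``."""
        if not self.is_circular:
            raise ValueError("rotation is only defined for circular sequences")
        n = len(self.bases)
        offset %= n
        return NucSeq(self.bases[offset:] + self.bases[:offset], CIRCULAR, self.id)

    def reverse_complement(self) -> "NucSeq":
        return reverse_complement(self)


def reverse_complement(seq: "NucSeq | str") -> "NucSeq | str":
    """Watson–Crick reverse complement; topology (and type) preserved.

    Accepts either a :class:`NucSeq` or a plain string for convenience in
    frame arithmetic; validation is applied in both cases.
    """
    if isinstance(seq, NucSeq):
        return NucSeq(seq.bases.translate(_COMPLEMENT)[::-1], seq.topology, seq.id)
    # route through NucSeq so alphabet checking is uniform
    return NucSeq(seq).bases.translate(_COMPLEMENT)[::-1]


def rotation_equal(a: NucSeq, b: NucSeq) -> bool:
    """True if two circular sequences are identical up to rotation."""
    if not (a.is_circular and b.is_circular):
        raise ValueError("rotation equality is defined for circular sequences")
    return len(a) == len(b) and a.bases in (b.bases + b.bases)


def codons(bases: str, offset: int = 0) -> Iterator[str]:
    """Iterate in-frame triplets of ``bases`` starting at ``offset``.

    Trailing bases that do not fill a codon are ignored.
    """
    for i in range(offset, len(bases) - 2, 3):
        yield bases[i:i + 3]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon`` (``*`` for stops, ``X`` if it contains N)."""
    if "N" in codon:
        return "X"
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class Orf:
    """An open reading frame anchored at offset 0 of a linear sequence.

    ``has_terminal_stop`` distinguishes a complete gene (ends in TAA/TAG/TGA)
    from a cloning-ready amplicon with the stop removed, the form required for
    C-terminal tagging and orientation screening.  By default the no-internal-
    stop invariant is enforced; ``strict=False`` admits ORFs with in-frame
    stops so the screening module can analyse (and warn about) them.
    """

    seq: NucSeq
    has_terminal_stop: bool = False
    strict: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.seq.is_circular:
            raise ValueError("an Orf must be linear")
        if len(self.seq) % 3 != 0:
            raise FrameError(f"ORF length {len(self.seq)} is not a multiple of 3")
        if self.strict:
            stops = self.stop_indices()
            if self.has_terminal_stop:
                last = len(self.seq) // 3 - 1
                if stops != [last]:
                    raise FrameError(
                        "terminal-stop ORF must end in a stop codon and contain no other"
                    )
            elif stops:
                raise FrameError(
                    f"stop codon at codon index {stops[0]} in a stop-free ORF"
                )

    @property
    def bases(self) -> str:
        return self.seq.bases

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, index: int) -> str:
        return self.seq.bases[3 * index:3 * index + 3]

    def codon_list(self) -> list[str]:
        return list(codons(self.seq.bases))

    def stop_indices(self) -> list[int]:
        return [i for i, c in enumerate(codons(self.seq.bases)) if c in STOP_CODONS]


class Translation(NamedTuple):
    """Result of :func:`translate`: peptide up to the first stop, plus all stop indices."""

    protein: str
    stops: list[int]


def translate(orf: "Orf | NucSeq | str") -> Translation:
    """Translate an in-frame sequence with the standard genetic code.

    The peptide is truncated at the first stop codon (exclusive); ``stops``
    lists the 0-based codon indices of *all* in-frame stops so that premature
    termination can be located.
    """
    if isinstance(orf, Orf):
        bases = orf.seq.bases
    elif isinstance(orf, NucSeq):
        bases = orf.bases
    else:
        bases = NucSeq(orf).bases
    if len(bases) % 3 != 0:
        raise FrameError(f"length {len(bases)} is not a multiple of 3")
    aas = [translate_codon(c) for c in codons(bases)]
    stops = [i for i, aa in enumerate(aas) if aa == "*"]
    cut = stops[0] if stops else len(aas)
    return Translation("".join(aas[:cut]), stops)


# ---------------------------------------------------------------------------
# FASTA / GenBank I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = LINEAR) -> list[NucSeq]:
    """Read a (multi-record) FASTA file into :class:`NucSeq` objects."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return [NucSeq(str(r.seq), topology, r.id) for r in records]


def write_fasta(seqs: Iterable[NucSeq], path: str | Path) -> None:
    """Write records wrapped at 60 columns (Biopython's FASTA default)."""
    records = [
        SeqRecord(Seq(s.bases), id=s.id or f"seq{i}", description="")
        for i, s in enumerate(seqs, start=1)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genbank(path: str | Path) -> SeqRecord:
    """Read a single annotated GenBank record (plasmid map)."""
    return SeqIO.read(str(path), "genbank")
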