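"""DNA sequence containers, FASTA I/O and IUPAC-degenerate PAM matching.

Sequences are plain upper-case strings over ``A C G T N`` (extended IUPAC
letters are admitted only when a genome is read with ``strict=False``).
Coordinates inside this module are 0-based; user-facing 1-based inclusive
coordinates are produced by the enumeration/search layers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: degeneracy sets of the IUPAC nucleotide one-letter codes
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_STRICT_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Malformed sequence input (illegal characters, bad FASTA, ...)."""


def normalize_sequence(seq: str, strict: bool = True, what: str = "sequence") -> str:
    """Upper-case, map U->T and validate the alphabet.

    With ``strict`` (the default) only A/C/G/T/N survive; otherwise any IUPAC
    nucleotide letter is preserved.
    """
    s = "".join(seq.split()).upper().replace("U", "T")
    allowed = _STRICT_ALPHABET if strict else frozenset(IUPAC_SETS)
    bad = set(s) - allowed
    if bad:
        raise SequenceError(
            f"illegal character(s) {sorted(bad)} in {what}"
            + (" (strict mode admits only A/C/G/T/N)" if strict else "")
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    bad = set(seq) - _STRICT_ALPHABET
    if bad:
        raise SequenceError(f"illegal character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """One named reference sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("contig id must be non-empty")
        bad = set(self.residues) - frozenset(IUPAC_SETS)
        if bad:
            raise SequenceError(f"illegal character(s) {sorted(bad)} in contig {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Genome:
    """Ordered collection of contigs the off-target search runs against."""

    contigs: tuple[Contig, ...]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise SequenceError("genome must contain at least one contig")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate contig id(s): {dup}")
        if self.total_length == 0:
            raise SequenceError("genome has zero total length")

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass(frozen=True)
class PamPattern:
    """A protospacer-adjacent-motif pattern in IUPAC code, e.g. NGG or NRG."""

    code: str

    def __post_init__(self) -> None:
        code = self.code.upper()
        object.__setattr__(self, "code", code)
        if not code:
            raise SequenceError("PAM pattern must be non-empty")
        bad = set(code) - frozenset(IUPAC_SETS)
        if bad:
            raise SequenceError(f"invalid IUPAC letter(s) {sorted(bad)} in PAM pattern {code!r}")

    @property
    def length(self) -> int:
        return len(self.code)

    def __str__(self) -> str:
        return self.code


def iupac_match(pattern: PamPattern, seq: str) -> bool:
    """True iff ``seq`` lies in the degeneracy set of ``pattern`` at every position.

    A degenerate letter in ``seq`` (e.g. an N in a genome) matches only a
    pattern position whose degeneracy set contains its whole set, so N in a
    genome satisfies only an N in the pattern.
    """
    if len(seq) != pattern.length:
        raise SequenceError(
            f"sequence length {len(seq)} != pattern length {pattern.length}"
        )
    try:
        return all(
            IUPAC_SETS[s] <= IUPAC_SETS[p] for s, p in zip(seq, pattern.code)
        )
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise SequenceError(f"illegal character {exc} in sequence") from exc


def pam_match_positions(seq: str, pattern: PamPattern) -> np.ndarray:
    """0-based start positions of all windows of ``seq`` matching ``pattern``.

    Vectorised over the whole sequence; semantics identical to scanning
    ``iupac_match`` across every window.
    """
    n, pl = len(seq), pattern.length
    if n < pl:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    nwin = n - pl + 1
    ok = np.ones(nwin, dtype=bool)
    for k, pch in enumerate(pattern.code):
        table = np.zeros(256, dtype=bool)
        for letter, degset in IUPAC_SETS.items():
            table[ord(letter)] = degset <= IUPAC_SETS[pch]
        ok &= table[arr[k : k + nwin]]
    return np.flatnonzero(ok).astype(np.int64)


def read_fasta(path: Union[str, Path], strict: bool = True) -> Genome:
    """Read a (multi-record) FASTA file into a Genome.

    Residues are upper-cased and U is mapped to T; in strict mode any letter
    outside A/C/G/T/N is rejected, otherwise extended IUPAC letters survive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    contigs = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(
            Contig(rec.id, normalize_sequence(str(rec.seq), strict=strict, what=f"record {rec.id!r}"))
        )
    return Genome(tuple(contigs))


def write_fasta(genome: Genome, path: Union[str, Path]) -> None:
    """Write a Genome back to (wrapped) FASTA."""
    records = [
        SeqRecord(Seq(c.residues), id=c.id, description="") for c in genome
    ]
    SeqIO.write(records, str(path), "fasta")


def load_query(source: Union[str, Path], strict: bool = True) -> str:
    """Resolve a query given as a raw sequence, FASTA text, or FASTA path.

    A single-record FASTA is required when the source is a file or FASTA text;
    otherwise the string itself is normalized and returned.
    """
    text = str(source)
    if isinstance(source, Path) or (len(text) < 4096 and "\n" not in text and Path(text).is_file()):
        records = list(SeqIO.parse(str(source), "fasta"))
    elif text.lstrip().startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    else:
        return normalize_sequence(text, strict=strict, what="query")
    if len(records) != 1:
        raise SequenceError(
            f"query FASTA must contain exactly one record, found {len(records)}"
        )
    return normalize_sequence(str(records[0].seq), strict=strict, what="query")
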