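"""SPOP-binding degron motif scanning.

SPOP, a CUL3-family E3 ligase adaptor, recognizes substrates through a short
linear motif with consensus Φ-π-S-S/T-S/T (nonpolar, polar, then a serine-rich
triplet); in EWS–FLI1 the instance is VTSSS (S464/S465/S466), and mutating the
three serines to alanine (the "3A" mutant) ablates SPOP binding.  The position
classes here follow the canonical SPOP-degron literature and are configurable.

Coordinates are 1-based, matching protein residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

NONPOLAR = frozenset("AVLIMFPGWYC")
POLAR = frozenset("STNQDEHKRYC")


@dataclass(frozen=True)
class DegronMotif:
    """Five position classes: [Φ][π][S][S/T][S/T] by default."""

    classes: tuple = (NONPOLAR, POLAR, frozenset("S"), frozenset("ST"), frozenset("ST"))

    def __post_init__(self):
        if len(self.classes) == 0 or any(not c or not set(c) <= AMINO_ACIDS for c in self.classes):
            raise ValueError("each position class must be a nonempty subset of the 20 amino acids")

    @property
    def length(self) -> int:
        return len(self.classes)

    def matches(self, peptide: str) -> bool:
        return len(peptide) == self.length and all(
            aa in cls for aa, cls in zip(peptide, self.classes))


@dataclass(frozen=True)
class DegronMatch:
    sequence_id: str
    start: int          # 1-based
    peptide: str


def _validate(seq: str, sequence_id: str = "") -> str:
    seq = seq.upper()
    for i, aa in enumerate(seq):
        if aa not in AMINO_ACIDS and aa != "X":
            raise ValueError(f"illegal character {aa!r} at position {i + 1}"
                             f"{' in ' + sequence_id if sequence_id else ''}")
    return seq


def scan_spop_degrons(seq: str, motif: DegronMotif | None = None,
                      sequence_id: str = "") -> list[DegronMatch]:
    """All overlapping windows matching the motif, ascending start.  'X' is
    allowed in the sequence but never matches a class."""
    motif = motif or DegronMotif()
    seq = _validate(seq, sequence_id)
    L = motif.length
    out = []
    for i in range(len(seq) - L + 1):
        pep = seq[i:i + L]
        if motif.matches(pep):
            out.append(DegronMatch(sequence_id=sequence_id, start=i + 1, peptide=pep))
    return out


def mutate_and_rescan(seq: str, substitutions: dict[int, str],
                      motif: DegronMotif | None = None, sequence_id: str = ""):
    """Apply residue substitutions (1-based position -> residue) and report
    (matches_before, matches_after)."""
    seq = _validate(seq, sequence_id)
    chars = list(seq)
    for pos, aa in substitutions.items():
        if not 1 <= pos <= len(chars):
            raise IndexError(f"position {pos} out of range 1..{len(chars)}")
        if aa.upper() not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {aa!r}")
        chars[pos - 1] = aa.upper()
    before = scan_spop_degrons(seq, motif, sequence_id)
    after = scan_spop_degrons("".join(chars), motif, sequence_id)
    return before, after


def scan_fasta(path, motif: DegronMotif | None = None) -> list[DegronMatch]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.extend(scan_spop_degrons(str(rec.seq), motif, sequence_id=rec.id))
    return out
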