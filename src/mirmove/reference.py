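"""Reference sequence and mature-miRNA annotation containers.

Coordinates are 0-based, half-open on the forward genomic strand throughout
the package; file formats that use other conventions (GFF3, VCF) are converted
at the IO boundary. Sequences are stored in the DNA alphabet (U normalized to
T); user-facing tables report the RNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 24

#: padding (nt) required between annotated loci for a bundle to be valid
LOCUS_PADDING = 10


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and normalize U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and normalize T -> U (for reporting)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MatureAnnotation:
    """One annotated mature miRNA locus.

    ``mature_seq`` is the biological 5'->3' sequence of the mature miRNA; on
    the minus strand it is the reverse complement of the genomic substring
    ``genome[start:end]``.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", to_dna(self.mature_seq))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.mature_seq):
            raise ValueError(
                f"{self.id}: end-start ({self.end - self.start}) != mature length "
                f"({len(self.mature_seq)})"
            )
        if not MIN_MATURE_LEN <= len(self.mature_seq) <= MAX_MATURE_LEN:
            raise ValueError(
                f"{self.id}: mature length {len(self.mature_seq)} outside "
                f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
            )

    @property
    def length(self) -> int:
        return len(self.mature_seq)


@dataclass
class ReferenceBundle:
    """A synthetic single-chromosome genome plus its mature-miRNA annotations."""

    genome: str
    annotations: list[MatureAnnotation] = field(default_factory=list)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.genome = to_dna(self.genome)

    def validate(self, padding: int = LOCUS_PADDING) -> None:
        """Check bundle invariants; raise ``ValueError`` on the first violation.

        Invariants: coordinates within the genome, annotated mature sequence
        equals the (strand-oriented) genomic substring, loci non-overlapping
        after ``padding`` nt of symmetric padding.
        """
        glen = len(self.genome)
        for ann in self.annotations:
            if ann.chrom != self.chrom:
                raise ValueError(f"{ann.id}: chrom {ann.chrom!r} != {self.chrom!r}")
            if not (0 <= ann.start < ann.end <= glen):
                raise ValueError(f"{ann.id}: coordinates outside genome")
            if self.locus_sequence(ann) != ann.mature_seq:
                raise ValueError(f"{ann.id}: mature_seq disagrees with genome")
        spans = sorted(
            (a.start - padding, a.end + padding, a.id) for a in self.annotations
        )
        for (s1, e1, i1), (s2, e2, i2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"loci {i1} and {i2} overlap within {padding} nt padding")

    def locus_sequence(self, ann: MatureAnnotation) -> str:
        """Strand-oriented genomic sequence at the annotated locus."""
        sub = self.genome[ann.start : ann.end]
        return revcomp(sub) if ann.strand == "-" else sub

    def anchored_window(self, ann: MatureAnnotation, length: int) -> str:
        """Strand-oriented genomic sequence starting at the annotation's 5' end.

        Returns up to ``length`` nt downstream (in miRNA orientation) of the
        biological 5' position; shorter if the genome ends first. Raises if the
        annotation itself lies outside the genome.
        """
        if not (0 <= ann.start < ann.end <= len(self.genome)):
            raise ValueError(f"{ann.id}: annotation window exceeds genome bounds")
        if ann.strand == "+":
            return self.genome[ann.start : ann.start + length]
        lo = max(0, ann.end - length)
        return revcomp(self.genome[lo : ann.end])

    def nested_window(self, ann: MatureAnnotation, flank: int = 5) -> str:
        """Strand-oriented genomic sequence of the locus enlarged by ``flank`` nt
        on both sides, clipped to the genome."""
        lo = max(0, ann.start - flank)
        hi = min(len(self.genome), ann.end + flank)
        sub = self.genome[lo:hi]
        return revcomp(sub) if ann.strand == "-" else sub

    def next_templated_base(self, ann: MatureAnnotation) -> str | None:
        """Genomic base immediately 3' of the mature end, in miRNA orientation.

        ``None`` at a genome edge. Used by the read simulator to guarantee that
        non-templated tails are distinguishable from templated extensions.
        """
        if ann.strand == "+":
            return self.genome[ann.end] if ann.end < len(self.genome) else None
        if ann.start - 1 >= 0:
            return revcomp(self.genome[ann.start - 1 : ann.start])
        return None
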