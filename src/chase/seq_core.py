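"""Sequence model, codon machinery, coordinates and FASTA/FASTQ I/O.

All coordinates are 0-based, half-open.  Codon numbering is 1-based
(codon 1 = start codon) to match conventional residue numbering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: minimum flank required on each side of an ORF for design
#: (50-bp homology arm + 20-bp guide + 3-bp PAM reach)
MIN_DESIGN_FLANK = 73


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T,N}."""


class FastaFormatError(ValueError):
    """A FASTA/FASTQ record is malformed."""


def clean_seq(s: str) -> str:
    """Uppercase ``s`` and verify it is over the {A,C,G,T,N} alphabet."""
    s = s.upper()
    if set(s) - ALPHABET:
        bad = sorted(set(s) - ALPHABET)
        raise SequenceAlphabetError(f"invalid characters in sequence: {bad}")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick complement, reversed.  N maps to N."""
    s = clean_seq(s)
    return s.translate(_COMPLEMENT)[::-1]


def translate(orf: str) -> str:
    """Translate ``orf`` under the standard nuclear code, stops as '*'.

    Translation is full-length: it does not stop at internal stop codons.
    """
    orf = clean_seq(orf)
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} is not a multiple of 3")
    return str(Seq(orf).translate())


def gc_fraction(s: str) -> float:
    """(G + C) / length.  Raises on empty input."""
    s = clean_seq(s)
    if not s:
        raise ValueError("gc_fraction of empty sequence is undefined")
    return (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-line) FASTA file into [(id, sequence), ...].

    Sequences are uppercased on ingestion.  An empty sequence or missing
    header raises :class:`FastaFormatError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record without identifier")
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append((rec.id, clean_seq(seq)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a 4-line Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, clean_seq(str(rec.seq)), quals


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise FastaFormatError(f"read {rid!r}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Gene target and codons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTarget:
    """An ORF embedded in genomic context, ORF on the plus strand of ``context``.

    ``orf_start`` is the 0-based offset of the ORF's first base;
    ``orf_length`` includes the terminal stop codon and is a multiple of 3.
    """

    gene_id: str
    context: str
    orf_start: int
    orf_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "context", clean_seq(self.context))
        if self.orf_length % 3 != 0:
            raise ValueError(f"orf_length {self.orf_length} is not a multiple of 3")
        if self.orf_start < 0 or self.orf_start + self.orf_length > len(self.context):
            raise ValueError("ORF interval outside context")

    @property
    def orf_end(self) -> int:
        return self.orf_start + self.orf_length

    @property
    def orf(self) -> str:
        return self.context[self.orf_start : self.orf_end]

    @property
    def n_codons(self) -> int:
        return self.orf_length // 3

    def left_flank(self) -> int:
        return self.orf_start

    def right_flank(self) -> int:
        return len(self.context) - self.orf_end

    def check_design_flanks(self) -> None:
        if self.left_flank() < MIN_DESIGN_FLANK or self.right_flank() < MIN_DESIGN_FLANK:
            raise ValueError(
                f"{self.gene_id}: flanks ({self.left_flank()}, {self.right_flank()}) "
                f"are below the {MIN_DESIGN_FLANK}-bp minimum required for design"
            )

    def codon_site(self, codon_index: int) -> "CodonSite":
        """Return the :class:`CodonSite` for a 1-based codon index."""
        if not 1 <= codon_index <= self.n_codons:
            raise IndexError(f"codon_index {codon_index} outside [1, {self.n_codons}]")
        offset = self.orf_start + 3 * (codon_index - 1)
        wt = self.context[offset : offset + 3]
        return CodonSite(codon_index=codon_index, offset=offset, wt_codon=wt, wt_aa=translate(wt))

    def codon_sites(self, first: int = 1, last: int | None = None) -> list["CodonSite"]:
        last = self.n_codons if last is None else last
        return [self.codon_site(i) for i in range(first, last + 1)]


@dataclass(frozen=True)
class CodonSite:
    codon_index: int  # 1-based
    offset: int  # 0-based position of first base in context
    wt_codon: str
    wt_aa: str


def gene_target_from_gff(
    genome: list[tuple[str, str]] | str | Path,
    gff_path: str | Path,
    gene_id: str,
    flank: int = 500,
) -> GeneTarget:
    """Build a :class:`GeneTarget` from a genome FASTA plus one GFF3 CDS interval.

    The CDS must be a single interval (no introns).  Minus-strand genes are
    re-oriented so that the ORF reads 5'->3' on the plus strand of the
    returned context.
    """
    if not isinstance(genome, list):
        genome = read_fasta(genome)
    seqs = dict(genome)
    intervals = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            if gene_id not in cols[8]:
                continue
            intervals.append((cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]))
    if not intervals:
        raise ValueError(f"no CDS feature for {gene_id!r} in {gff_path}")
    if len(intervals) > 1:
        raise ValueError(f"{gene_id!r} has {len(intervals)} CDS intervals; introns unsupported")
    chrom, start, end, strand = intervals[0]
    seq = seqs[chrom]
    lo, hi = max(0, start - flank), min(len(seq), end + flank)
    region = seq[lo:hi]
    if strand == "-":
        region = reverse_complement(region)
        orf_start = hi - end
    else:
        orf_start = start - lo
    return GeneTarget(gene_id=gene_id, context=region, orf_start=orf_start, orf_length=end - start)


# ---------------------------------------------------------------------------
# Codon table
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _load_usage() -> list[tuple[str, str, float]]:
    rows = []
    with resources.files("chase.data").joinpath("codon_usage_sc.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append((row["codon"], row["aa"], float(row["freq_per_thousand"])))
    return rows


@dataclass
class CodonTable:
    """Standard nuclear code plus per-amino-acid representative design codons.

    ``representative`` defaults to the most frequent S. cerevisiae codon for
    each amino acid; ``stop_codon`` defaults to TAA.  Both are configurable.
    """

    code: dict[str, str] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)
    stop_codon: str = "TAA"
    _by_freq: dict[str, list[str]] = field(default_factory=dict, repr=False)

    @classmethod
    def default(
        cls,
        representative_overrides: dict[str, str] | None = None,
        stop_codon: str = "TAA",
    ) -> "CodonTable":
        usage = _load_usage()
        code = {codon: aa for codon, aa, _ in usage}
        by_freq: dict[str, list[str]] = {}
        for codon, aa, _freq in sorted(usage, key=lambda r: -r[2]):
            by_freq.setdefault(aa, []).append(codon)
        representative = {aa: codons[0] for aa, codons in by_freq.items() if aa != "*"}
        if representative_overrides:
            for aa, codon in representative_overrides.items():
                if code[codon] != aa:
                    raise ValueError(f"representative {codon} does not encode {aa}")
                representative[aa] = codon
        if code[stop_codon] != "*":
            raise ValueError(f"{stop_codon} is not a stop codon")
        tab = cls(code=code, representative=representative, stop_codon=stop_codon)
        tab._by_freq = by_freq
        return tab

    def aa(self, codon: str) -> str:
        return self.code[codon]

    def synonyms(self, codon: str) -> list[str]:
        """Codons encoding the same amino acid as ``codon``, excluding itself,
        ordered by decreasing usage frequency."""
        return [c for c in self._by_freq[self.code[codon]] if c != codon]

    def design_codon(self, target_aa: str, wt_codon: str) -> str | None:
        """Codon used to encode ``target_aa`` at a site whose wild type is
        ``wt_codon``.

        Returns the representative codon; for a synonymous design (target ==
        wild-type amino acid) where the representative equals the wild-type
        codon, the next most frequent synonym is used.  None when no distinct
        codon exists (single-codon amino acids Met and Trp).
        """
        if target_aa == "*":
            cand = self.stop_codon
            return cand if cand != wt_codon else None
        cand = self.representative[target_aa]
        if cand != wt_codon:
            return cand
        for alt in self._by_freq[target_aa]:
            if alt != wt_codon:
                return alt
        return None
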