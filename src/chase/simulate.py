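"""Synthetic fixture generation: toy genes with planted sequence features and
edited amplicon reads at controlled abundances and error rates.

Everything is driven by a seeded ``numpy`` generator, so fixed seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library_builder import parse_substitutions
from .quantify import AmpliconSegment
from .seq_core import GeneTarget, reverse_complement, translate

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    seed: int = 0
    orf_codons: int = 30  # includes start and terminal stop
    flank: int = 100
    gc_bias: float = 0.45
    planted: list[tuple[int, str]] = field(default_factory=list)  # (offset, seq)
    error_rate: float = 0.0
    read_depth: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.orf_codons < 5:
            raise ValueError("orf_codons must be >= 5")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _random_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOP_CODONS and codon != "ATG":
            return codon


def make_toy_gene(config: SimConfig, gene_id: str = "toy") -> GeneTarget:
    """Random context with an in-frame ORF and verbatim planted features.

    The ORF starts with ATG, has no internal stop, and ends with TAA.
    Planted (offset, sequence) features are injected after generation;
    overlapping features raise, and a feature that creates an internal stop
    codon raises as well.
    """
    rng = np.random.default_rng(config.seed)
    n_sense = config.orf_codons - 2
    orf = "ATG" + "".join(_random_sense_codon(rng, config.gc_bias) for _ in range(n_sense)) + "TAA"
    context = (
        _random_bases(rng, config.flank, config.gc_bias)
        + orf
        + _random_bases(rng, config.flank, config.gc_bias)
    )
    occupied: list[tuple[int, int]] = []
    ctx = list(context)
    for offset, seq in config.planted:
        if offset < 0 or offset + len(seq) > len(ctx):
            raise ValueError(f"planted feature at {offset} outside context")
        for lo, hi in occupied:
            if offset < hi and offset + len(seq) > lo:
                raise ValueError(f"planted features overlap at {offset}")
        occupied.append((offset, offset + len(seq)))
        ctx[offset : offset + len(seq)] = seq
    context = "".join(ctx)
    target = GeneTarget(
        gene_id=gene_id,
        context=context,
        orf_start=config.flank,
        orf_length=3 * config.orf_codons,
    )
    protein = translate(target.orf)
    if "*" in protein[:-1]:
        raise ValueError("planted feature introduced an internal stop codon")
    if not protein.endswith("*") or not target.orf.startswith("ATG"):
        raise ValueError("planted feature destroyed the start or stop codon")
    return target


def segment_for_target(
    target: GeneTarget,
    start: int | None = None,
    end: int | None = None,
    primer_len: int = 20,
    segment_id: str = "seg1",
) -> AmpliconSegment:
    """Amplicon segment covering [start, end) of the context (default: the
    ORF plus primer-length margins)."""
    if start is None:
        start = target.orf_start - primer_len
    if end is None:
        end = target.orf_end + primer_len
    ref = target.context[start:end]
    return AmpliconSegment(
        segment_id=segment_id,
        reference=ref,
        fwd_primer=ref[:primer_len],
        rev_primer=reverse_complement(ref[-primer_len:]),
        context_offset=start,
    )


def _apply_subs_to_segment(segment: AmpliconSegment, subs) -> str:
    lo, hi = segment.interval
    seq = list(segment.reference)
    for pos, ref, alt in subs:
        if lo <= pos < hi:
            if seq[pos - lo] != ref:
                raise ValueError(f"substitution ref mismatch at context offset {pos}")
            seq[pos - lo] = alt
    return "".join(seq)


def simulate_reads(
    manifest: pd.DataFrame,
    segments: list[AmpliconSegment],
    abundances: dict[str, int],
    config: SimConfig,
    multinomial: bool = False,
) -> list[tuple[str, str, str]]:
    """Error-free or noisy reads at given per-genotype counts.

    ``abundances`` maps cassette ids (or "WT") to read counts per segment.
    By default counts are exact so round-trip tests are deterministic; with
    ``multinomial`` the counts are sampled.  Each read is emitted in a random
    orientation with constant quality 'I'.
    """
    rng = np.random.default_rng(config.seed)
    subs_by_id = {
        row.id: parse_substitutions(row.substitutions) for row in manifest.itertuples()
    }
    unknown = set(abundances) - set(subs_by_id) - {"WT"}
    if unknown:
        raise ValueError(f"abundances reference unknown cassette ids: {sorted(unknown)}")
    genotypes = sorted(abundances)
    if multinomial:
        total = sum(abundances.values())
        p = np.array([abundances[g] for g in genotypes], dtype=float)
        p /= p.sum()
        counts = rng.multinomial(total, p)
        abundances = dict(zip(genotypes, counts))

    reads: list[tuple[str, str, str]] = []
    i = 0
    for segment in segments:
        for gid in genotypes:
            base_seq = (
                segment.reference
                if gid == "WT"
                else _apply_subs_to_segment(segment, subs_by_id[gid])
            )
            for _ in range(abundances[gid]):
                seq = base_seq
                if config.error_rate > 0:
                    arr = list(seq)
                    hits = np.flatnonzero(rng.random(len(arr)) < config.error_rate)
                    for pos in hits:
                        arr[pos] = rng.choice([b for b in BASES if b != arr[pos]])
                    seq = "".join(arr)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                reads.append((f"read{i}|{segment.segment_id}|{gid}", seq, "I" * len(seq)))
                i += 1
    return reads
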