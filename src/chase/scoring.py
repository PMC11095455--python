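"""Cassette filters, rank features, the 12-bp seed off-target index, and
top-k selection.

Sort-key priority (documented choice; emitted in report metadata): off-target
count ascending, PAM-codon distance ascending, 4-bp seed purine fraction
descending, guide GC in the 30-80% range (inclusive) before out-of-range,
then (offset, strand) as a deterministic tie-break.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .design_engine import IUPAC, Guide, matches_iupac
from .seq_core import reverse_complement

GC_RANGE = (0.30, 0.80)  # inclusive bounds
POLYT = "TTTTT"

SORT_KEY_ORDER = ("offtargets", "distance", "seed4_purine", "gc_in_range", "position")


def has_polyT(oligo: str) -> bool:
    """True iff the transcribed cassette (donor + guide, adapters excluded)
    contains a run of five or more T's."""
    return POLYT in oligo


def seed_purine_fraction(guide: Guide | str) -> float:
    seed = guide.seed4 if isinstance(guide, Guide) else guide
    return (seed.count("A") + seed.count("G")) / len(seed)


def gc_in_range(gc: float) -> bool:
    return GC_RANGE[0] <= gc <= GC_RANGE[1]


def _iupac_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping PAM occurrences are all reported
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in pattern) + ")")


@dataclass
class SeedIndex:
    """Exact-match lookup of k-mer protospacer seeds adjacent to a PAM.

    Keys are seeds read 5'->3' on their strand, immediately 5' of a
    PAM matching ``pam_pattern``.  Values are (sequence_id, plus-strand
    offset of the seed window start, strand) triples.
    """

    k: int
    pam_pattern: str
    index: dict[str, list[tuple[str, int, str]]]

    def lookup(self, seed: str) -> list[tuple[str, int, str]]:
        return self.index.get(seed, [])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tseq_id\toffset\tstrand\n")
            for kmer in sorted(self.index):
                for sid, off, strand in self.index[kmer]:
                    fh.write(f"{kmer}\t{sid}\t{off}\t{strand}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int, pam_pattern: str) -> "SeedIndex":
        index: dict[str, list[tuple[str, int, str]]] = {}
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("kmer")
            for line in fh:
                kmer, sid, off, strand = line.rstrip("\n").split("\t")
                index.setdefault(kmer, []).append((sid, int(off), strand))
        return cls(k=k, pam_pattern=pam_pattern, index=index)


def build_seed_index(
    genome: list[tuple[str, str]],
    k: int = 12,
    pam_pattern: str = "NGN",
    restrict_to: set[str] | None = None,
) -> SeedIndex:
    """Index both strands of ``genome`` for k-mer seeds 5' of a matching PAM.

    ``restrict_to`` limits stored keys to a known seed set, which keeps
    memory bounded when indexing a full genome for a specific library.
    K-mers containing N are never indexed.
    """
    pam_re = _iupac_regex(pam_pattern)
    # minus strand: scan for plus-strand triplets whose rc matches the pattern
    rc_scan = re.compile(
        "(?=" + "".join(f"[{_rc_class(c)}]" for c in reversed(pam_pattern)) + ")"
    )
    index: dict[str, list[tuple[str, int, str]]] = {}
    valid = set("ACGT")
    for sid, seq in genome:
        n = len(seq)
        # plus strand: seed at [m.start()-k, m.start()), PAM at match position
        for m in pam_re.finditer(seq):
            p = m.start()
            if p < k:
                continue
            kmer = seq[p - k : p]
            if restrict_to is not None and kmer not in restrict_to:
                continue
            if set(kmer) - valid:
                continue
            index.setdefault(kmer, []).append((sid, p - k, "+"))
        # the seed of a minus-strand hit occupies [j+3, j+3+k) in plus coords
        for m in rc_scan.finditer(seq):
            j = m.start()
            if j + 3 + k > n:
                continue
            window = seq[j + 3 : j + 3 + k]
            if set(window) - valid:
                continue
            kmer = reverse_complement(window)
            if restrict_to is not None and kmer not in restrict_to:
                continue
            index.setdefault(kmer, []).append((sid, j + 3, "-"))
    return SeedIndex(k=k, pam_pattern=pam_pattern, index=index)


_RC_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc_class(c: str) -> str:
    return "".join(sorted(_RC_BASE[b] for b in IUPAC[c]))


def count_offtargets(
    index: SeedIndex | None,
    guide: Guide,
    on_target: tuple[str, int, str] | None = None,
    require_on_target: bool = False,
) -> int:
    """Number of seed-index hits for the guide's 12-bp seed, excluding the
    on-target occurrence.  With no index every guide scores 0."""
    if index is None:
        return 0
    if len(guide.seed12) != index.k:
        raise ValueError(f"seed length {len(guide.seed12)} != index k {index.k}")
    hits = index.lookup(guide.seed12)
    if on_target is None:
        return len(hits)
    n_on = sum(1 for h in hits if h == on_target)
    if n_on == 0 and require_on_target:
        raise ValueError(f"on-target {on_target} not found in seed index")
    return len(hits) - n_on


def find_seed_matches(
    genome: list[tuple[str, str]],
    seed12: str,
    min_match: int = 10,
) -> list[tuple[str, int, str, int]]:
    """Sites whose PAM-proximal alignment matches >= ``min_match`` contiguous
    bases of the seed's PAM-proximal (3') end, with no PAM requirement.

    Returns (seq_id, plus-strand offset of the matched suffix window, strand,
    match_length) tuples.  ``min_match`` = len(seed) reduces to exact lookup.
    """
    if not 10 <= min_match <= len(seed12):
        raise ValueError("min_match must be in [10, len(seed)]")
    suffix = seed12[-min_match:]
    out = []
    for sid, seq in genome:
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            start = 0
            while True:
                i = s.find(suffix, start)
                if i == -1:
                    break
                # extend the match 5'-ward along the seed
                ext = 0
                while (
                    min_match + ext < len(seed12)
                    and i - ext - 1 >= 0
                    and s[i - ext - 1] == seed12[-(min_match + ext + 1)]
                ):
                    ext += 1
                if strand == "+":
                    offset = i
                else:
                    offset = len(seq) - (i + min_match)
                out.append((sid, offset, strand, min_match + ext))
                start = i + 1
    return sorted(out)


@dataclass(frozen=True)
class RankKey:
    distance: int
    seed4_purine: float
    gc_in_range: bool
    offtargets: int
    position_tiebreak: tuple[int, str]

    def as_tuple(self) -> tuple:
        return (
            self.offtargets,
            self.distance,
            -self.seed4_purine,
            0 if self.gc_in_range else 1,
            self.position_tiebreak,
        )


def passes_polyt(cassette, policy: str = "any") -> bool:
    """PolyT admissibility of a cassette under the given policy.

    'any'             discard when the transcribed cassette (donor + guide)
                      contains TTTTT at all;
    'edit_introduced' discard only when the edits are responsible for the
                      run: a cassette whose wild-type window (same
                      orientation) already contains TTTTT is tolerated.
    """
    dirty = has_polyT(cassette.oligo_core)
    if policy == "any" or not dirty:
        return not dirty
    if policy != "edit_introduced":
        raise ValueError(f"unknown polyT policy {policy!r}")
    if cassette.donor.deletion is not None:
        return False  # positions shift under a deletion; be conservative
    return has_polyT(cassette.wt_oligo_core)


def rank_and_select(
    cassettes: list, k: int = 4, strict_gc: bool = False, polyt_policy: str = "any"
) -> list:
    """PolyT-filter, sort by RankKey, and return the top ``k`` with ranks.

    ``cassettes`` are any objects exposing ``.oligo_core`` / ``.wt_oligo_core``
    (donor + guide, adapters excluded) and ``.rank_key`` attributes; the
    returned cassettes get their ``rank`` attribute set to 0..k-1.
    """
    survivors = [c for c in cassettes if passes_polyt(c, polyt_policy)]
    if strict_gc:
        survivors = [c for c in survivors if c.rank_key.gc_in_range]
    survivors.sort(key=lambda c: c.rank_key.as_tuple())
    selected = survivors[:k]
    for rank, c in enumerate(selected):
        c.rank = rank
    return selected
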