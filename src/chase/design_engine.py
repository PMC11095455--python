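"""Guide/PAM enumeration and HDR donor construction.

A design unit couples one candidate PAM near a target codon with a donor
carrying (a) the codon edit and (b) synonymous substitutions that destroy
the PAM and/or protospacer so that neither the donor nor the edited locus
can be re-cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .seq_core import CodonTable, CodonSite, GeneTarget, gc_fraction, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PROTOSPACER_LEN = 20
ARM_LEN = 50
SEED4_LEN = 4
PROXIMAL_LEN = 10  # protospacer bases counted as PAM-proximal for fallback kills


class DesignInfeasible(Exception):
    """No synonymous substitution set can satisfy the re-cutting policy."""


def matches_iupac(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(b in IUPAC[p] for b, p in zip(seq, pattern))


@dataclass(frozen=True)
class PamSite:
    """A PAM occurrence.  ``offset`` is the plus-strand position of the
    triplet's first base regardless of strand; ``pam_seq`` is read 5'->3'
    on ``strand``."""

    offset: int
    strand: str  # '+' or '-'
    pam_seq: str
    pattern: str

    @property
    def interval(self) -> tuple[int, int]:
        return self.offset, self.offset + 3


@dataclass(frozen=True)
class Guide:
    protospacer: str  # 20-mer, 5'->3' on the PAM's strand
    seed4: str
    seed12: str
    gc: float

    @classmethod
    def from_protospacer(cls, protospacer: str) -> "Guide":
        if len(protospacer) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be {PROTOSPACER_LEN} bases")
        return cls(
            protospacer=protospacer,
            seed4=protospacer[-4:],
            seed12=protospacer[-12:],
            gc=gc_fraction(protospacer),
        )


@dataclass(frozen=True, order=True)
class Substitution:
    offset: int  # plus-strand context position
    ref: str
    alt: str
    purpose: str = "codon_edit"  # codon_edit | pam_kill | protospacer_kill

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("substitution with ref == alt")


@dataclass(frozen=True)
class Donor:
    substitutions: tuple[Substitution, ...]
    core_start: int  # plus-strand interval spanning the outermost edits
    core_end: int
    left_arm: str
    right_arm: str
    emitted_seq: str  # as synthesized (reverse-complemented for minus-strand guides)
    wt_emitted_seq: str  # the same window without the edits, same orientation
    strand: str
    deletion: tuple[int, int] | None = None

    def edited_positions(self) -> set[int]:
        """0-based positions within ``emitted_seq`` that carry a substitution."""
        start = self.core_start - ARM_LEN
        end = self.core_end + ARM_LEN
        out = set()
        for s in self.substitutions:
            if self.strand == "+":
                out.add(s.offset - start)
            else:
                out.add(end - 1 - s.offset)
        return out


def guide_for_pam(context: str, pam: PamSite) -> Guide:
    """The 20-mer protospacer immediately 5' of ``pam`` on its strand."""
    p = pam.offset
    if pam.strand == "+":
        if p < PROTOSPACER_LEN:
            raise ValueError("protospacer window outside context")
        proto = context[p - PROTOSPACER_LEN : p]
    else:
        if p + 3 + PROTOSPACER_LEN > len(context):
            raise ValueError("protospacer window outside context")
        proto = reverse_complement(context[p + 3 : p + 3 + PROTOSPACER_LEN])
    return Guide.from_protospacer(proto)


def protospacer_interval(pam: PamSite) -> tuple[int, int]:
    """Plus-strand interval occupied by the protospacer."""
    if pam.strand == "+":
        return pam.offset - PROTOSPACER_LEN, pam.offset
    return pam.offset + 3, pam.offset + 3 + PROTOSPACER_LEN


def seed_interval(pam: PamSite, n: int) -> tuple[int, int]:
    """Plus-strand interval of the ``n`` PAM-proximal protospacer bases."""
    if pam.strand == "+":
        return pam.offset - n, pam.offset
    return pam.offset + 3, pam.offset + 3 + n


def enumerate_pams(
    context: str,
    pattern: str,
    window: tuple[int, int] | None = None,
    require_protospacer: bool = False,
) -> list[PamSite]:
    """All PAM occurrences on both strands whose triplet lies inside ``window``.

    ``window`` is a half-open plus-strand interval constraining the triplet;
    None scans the whole context.  With ``require_protospacer`` the 20-base
    protospacer must additionally fit inside the context.
    """
    lo, hi = window if window is not None else (0, len(context))
    if lo < 0 or hi > len(context):
        raise ValueError(f"window {window} outside context of length {len(context)}")
    sites: list[PamSite] = []
    for p in range(lo, hi - 2):
        triplet = context[p : p + 3]
        if matches_iupac(triplet, pattern):
            if not require_protospacer or p >= PROTOSPACER_LEN:
                sites.append(PamSite(offset=p, strand="+", pam_seq=triplet, pattern=pattern))
        rc_triplet = reverse_complement(triplet)
        if matches_iupac(rc_triplet, pattern):
            if not require_protospacer or p + 3 + PROTOSPACER_LEN <= len(context):
                sites.append(PamSite(offset=p, strand="-", pam_seq=rc_triplet, pattern=pattern))
    sites.sort(key=lambda s: (s.offset, s.strand))
    return sites


def pam_codon_distance(pam: PamSite, site: CodonSite) -> int:
    """Bases strictly between the codon and PAM intervals on the plus strand;
    0 when they overlap or abut."""
    c0, c1 = site.offset, site.offset + 3
    p0, p1 = pam.interval
    if p1 <= c0:
        return c0 - p1
    if c1 <= p0:
        return p0 - c1
    return 0


def candidate_pams_for_codon(
    target: GeneTarget,
    site: CodonSite,
    pattern: str,
    max_distance: int = 20,
) -> list[PamSite]:
    """PAMs within ``max_distance`` of the codon whose protospacer fits in context."""
    lo = max(0, site.offset - max_distance - 3)
    hi = min(len(target.context), site.offset + 3 + max_distance + 3)
    sites = enumerate_pams(target.context, pattern, (lo, hi), require_protospacer=True)
    return [s for s in sites if pam_codon_distance(s, site) <= max_distance]


def plan_codon_edit(site: CodonSite, new_codon: str) -> list[Substitution]:
    """Substitutions converting the wild-type codon to ``new_codon``."""
    if new_codon == site.wt_codon:
        raise ValueError(f"codon edit is a no-op: {new_codon} at codon {site.codon_index}")
    if len(new_codon) != 3:
        raise ValueError("new_codon must be a 3-mer")
    return [
        Substitution(offset=site.offset + i, ref=w, alt=n, purpose="codon_edit")
        for i, (w, n) in enumerate(zip(site.wt_codon, new_codon))
        if w != n
    ]


def apply_substitutions(context: str, subs: list[Substitution] | tuple[Substitution, ...]) -> str:
    out = list(context)
    for s in subs:
        if out[s.offset] != s.ref:
            raise ValueError(
                f"substitution ref mismatch at {s.offset}: context has "
                f"{out[s.offset]!r}, expected {s.ref!r}"
            )
        out[s.offset] = s.alt
    return "".join(out)


def is_cleavable(edited_context: str, pam: PamSite, guide: Guide, pattern: str) -> bool:
    """True if the (protospacer, PAM) pair still matches the edited locus
    with 0 mismatches and a pattern-conforming PAM."""
    p = pam.offset
    if pam.strand == "+":
        proto = edited_context[p - PROTOSPACER_LEN : p]
        pam_now = edited_context[p : p + 3]
    else:
        proto = reverse_complement(edited_context[p + 3 : p + 3 + PROTOSPACER_LEN])
        pam_now = reverse_complement(edited_context[p : p + 3])
    return proto == guide.protospacer and matches_iupac(pam_now, pattern)


def _codons_overlapping(target: GeneTarget, lo: int, hi: int) -> list[CodonSite]:
    """ORF codon sites whose interval intersects [lo, hi)."""
    first = max(1, (lo - target.orf_start) // 3 + 1)
    last = min(target.n_codons, (hi - 1 - target.orf_start) // 3 + 1)
    out = []
    for i in range(first, last + 1):
        s = target.codon_site(i)
        if s.offset < hi and s.offset + 3 > lo:
            out.append(s)
    return out


def _creates_polyt(edited: str, subs: list[Substitution], strand: str) -> bool:
    """True if any new substitution sits inside a 5-T run of the synthesized
    strand (minus-strand donors are emitted reverse-complemented, so a plus
    strand A-run becomes a T-run there)."""
    run = "TTTTT" if strand == "+" else "AAAAA"
    for s in subs:
        lo, hi = max(0, s.offset - 4), min(len(edited), s.offset + 5)
        if run in edited[lo:hi]:
            return True
    return False


def _synonymous_ok(target: GeneTarget, subs: list[Substitution]) -> bool:
    """Verify a combined substitution set leaves every touched non-target
    codon's translation unchanged (two swaps in one codon can interact)."""
    from .seq_core import translate

    by_codon: dict[int, list[Substitution]] = {}
    for s in subs:
        if target.orf_start <= s.offset < target.orf_end:
            by_codon.setdefault((s.offset - target.orf_start) // 3 + 1, []).append(s)
    for idx, group in by_codon.items():
        site = target.codon_site(idx)
        codon = list(site.wt_codon)
        for s in group:
            codon[s.offset - site.offset] = s.alt
        if translate("".join(codon)) != site.wt_aa:
            return False
    return True


def eliminate_recutting(
    target: GeneTarget,
    pam: PamSite,
    guide: Guide,
    existing_subs: list[Substitution],
    codon_table: CodonTable,
    pattern: str,
    forbidden_codons: frozenset[int] | None = None,
) -> list[Substitution]:
    """Minimal synonymous substitutions making the edited locus non-cleavable.

    Returns [] when ``existing_subs`` already destroy the PAM or protospacer
    match.  Preference order: (1) break the PAM pattern synonymously, (2) put
    >=1 synonymous mismatch in the 4-bp seed, (3) put >=2 synonymous
    mismatches in the PAM-proximal 10 protospacer bases.  Raises
    :class:`DesignInfeasible` when no option exists.
    """
    context = target.context
    edited = apply_substitutions(context, existing_subs)
    if not is_cleavable(edited, pam, guide, pattern):
        return []
    forbidden = forbidden_codons or frozenset()

    def synonymous_swaps(region_lo: int, region_hi: int, purpose: str):
        """Candidate whole-codon synonymous swaps touching [region_lo, region_hi)."""
        for site in _codons_overlapping(target, region_lo, region_hi):
            if site.codon_index in forbidden or site.wt_aa == "*":
                continue
            for alt_codon in codon_table.synonyms(site.wt_codon):
                subs = [
                    Substitution(offset=site.offset + i, ref=w, alt=a, purpose=purpose)
                    for i, (w, a) in enumerate(zip(site.wt_codon, alt_codon))
                    if w != a
                ]
                if not any(region_lo <= s.offset < region_hi for s in subs):
                    continue  # swap does not touch the required region
                yield subs

    def viable(subs: list[Substitution]) -> bool:
        try:
            new_edited = apply_substitutions(edited, subs)
        except ValueError:
            return False  # collides with an existing substitution
        if is_cleavable(new_edited, pam, guide, pattern):
            return False
        if _creates_polyt(new_edited, subs, pam.strand):
            return False
        return _synonymous_ok(target, subs)

    def rank_key(subs: list[Substitution]):
        closest = min(
            min(abs(s.offset - pam.offset), abs(s.offset - (pam.offset + 2))) for s in subs
        )
        return (len(subs), closest, "".join(s.alt for s in sorted(subs)))

    # level 1: synonymously break the PAM pattern itself
    p0, p1 = pam.interval
    candidates = []
    for subs in synonymous_swaps(p0, p1, "pam_kill"):
        try:
            new_edited = apply_substitutions(edited, subs)
        except ValueError:
            continue
        if pam.strand == "+":
            pam_now = new_edited[p0:p1]
        else:
            pam_now = reverse_complement(new_edited[p0:p1])
        if matches_iupac(pam_now, pattern):
            continue
        if viable(subs):
            candidates.append(subs)
    if candidates:
        return min(candidates, key=rank_key)

    # level 2: >=1 synonymous mismatch in the 4-bp PAM-proximal seed
    s0, s1 = seed_interval(pam, SEED4_LEN)
    candidates = [subs for subs in synonymous_swaps(s0, s1, "protospacer_kill") if viable(subs)]
    if candidates:
        return min(candidates, key=rank_key)

    # level 3: >=2 synonymous mismatches in the PAM-proximal 10 bases
    q0, q1 = seed_interval(pam, PROXIMAL_LEN)
    singles = list(synonymous_swaps(q0, q1, "protospacer_kill"))
    candidates = [
        subs
        for subs in singles
        if sum(q0 <= s.offset < q1 for s in subs) >= 2 and viable(subs)
    ]
    if not candidates:
        for a, b in combinations(singles, 2):
            offsets_a = {s.offset for s in a}
            if any(s.offset in offsets_a for s in b):
                continue
            merged = sorted(a + b)
            if sum(q0 <= s.offset < q1 for s in merged) >= 2 and viable(merged):
                candidates.append(merged)
    if candidates:
        return min(candidates, key=rank_key)

    raise DesignInfeasible(
        f"no synonymous kill available for PAM at {pam.offset}{pam.strand}"
    )


def build_donor(
    target: GeneTarget,
    substitutions: list[Substitution],
    strand: str = "+",
    deletion: tuple[int, int] | None = None,
) -> Donor:
    """Donor spanning the outermost edits plus 50-bp homology arms.

    For a deletion donor the arms directly flank the deleted interval and
    ``substitutions`` may be empty.  ``strand`` is the guide strand; minus
    strand donors are emitted reverse-complemented.
    """
    context = target.context
    if deletion is not None:
        d0, d1 = deletion
        positions = [d0, d1 - 1] + [s.offset for s in substitutions]
    else:
        if not substitutions:
            raise ValueError("donor requires at least one substitution")
        positions = [s.offset for s in substitutions]
    lo, hi = min(positions), max(positions) + 1
    if deletion is not None:
        lo, hi = min(lo, deletion[0]), max(hi, deletion[1])
    start, end = lo - ARM_LEN, hi + ARM_LEN
    if start < 0 or end > len(context):
        raise ValueError(
            f"insufficient flank for donor spanning [{lo}, {hi}) in context of "
            f"length {len(context)}"
        )
    edited = apply_substitutions(context, substitutions)
    if deletion is not None:
        window = edited[start : deletion[0]] + edited[deletion[1] : end]
    else:
        window = edited[start:end]
    wt_window = context[start:end]
    if strand == "-":
        window, wt_window = reverse_complement(window), reverse_complement(wt_window)
    return Donor(
        substitutions=tuple(sorted(substitutions)),
        core_start=lo,
        core_end=hi,
        left_arm=context[start : start + ARM_LEN],
        right_arm=context[end - ARM_LEN : end],
        emitted_seq=window,
        wt_emitted_seq=wt_window,
        strand=strand,
        deletion=deletion,
    )


def donor_is_cleavable(donor: Donor, guide: Guide, pattern: str) -> bool:
    """True if the donor itself still contains a cleavable protospacer+PAM
    for its own guide (checked on both strands of the emitted sequence)."""
    for seq in (donor.emitted_seq, reverse_complement(donor.emitted_seq)):
        start = 0
        while True:
            i = seq.find(guide.protospacer, start)
            if i == -1:
                break
            pam = seq[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + 3]
            if len(pam) == 3 and matches_iupac(pam, pattern):
                return True
            start = i + 1
    return False


def assemble_cassette(donor: Donor, guide: Guide, adapters: tuple[str, str] = ("", "")) -> str:
    """Full oligo: 5' adapter + donor + 20-bp guide + 3' adapter."""
    return adapters[0] + donor.emitted_seq + guide.protospacer + adapters[1]
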