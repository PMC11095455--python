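"""Amplicon-NGS quantification of editing outcomes.

Reads are merged single-end amplicon reads.  The model is substitution-only:
a retained read must carry both primers and match the segment reference
length exactly.  A read is a *perfect* edit call when its observed base
substitutions equal exactly one designed cassette's substitution set
(restricted to the segment); a non-empty proper subset is *imperfect*; any
substitution at a position no cassette designs makes the read *unmatched*.

Normalization follows: normalized = raw * 1,000,000 / total retained reads
of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .library_builder import load_manifest, parse_substitutions
from .seq_core import reverse_complement

NORM_SCALE = 1_000_000

STATUSES = ("filtered_primer", "filtered_length", "wild_type", "perfect", "imperfect", "unmatched")


@dataclass(frozen=True)
class AmpliconSegment:
    segment_id: str
    reference: str  # wild-type segment sequence, fwd-primer orientation
    fwd_primer: str
    rev_primer: str
    context_offset: int  # 0-based offset of the segment within the design context

    def __post_init__(self) -> None:
        if not self.reference.startswith(self.fwd_primer):
            raise ValueError(f"{self.segment_id}: reference does not start with fwd_primer")
        if not self.reference.endswith(reverse_complement(self.rev_primer)):
            raise ValueError(f"{self.segment_id}: reference does not end with rc(rev_primer)")

    @property
    def interval(self) -> tuple[int, int]:
        return self.context_offset, self.context_offset + len(self.reference)


def read_segments_tsv(path: str | Path) -> list[AmpliconSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        AmpliconSegment(
            segment_id=str(r.segment_id),
            reference=r.reference,
            fwd_primer=r.fwd_primer,
            rev_primer=r.rev_primer,
            context_offset=int(r.context_offset),
        )
        for r in df.itertuples()
    ]


def write_segments_tsv(path: str | Path, segments: list[AmpliconSegment]) -> None:
    pd.DataFrame(
        [
            {
                "segment_id": s.segment_id,
                "fwd_primer": s.fwd_primer,
                "rev_primer": s.rev_primer,
                "context_offset": s.context_offset,
                "reference": s.reference,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EditCall:
    read_id: str
    status: str
    cassette_id: str | None = None
    observed: tuple[tuple[int, str, str], ...] = ()  # (context offset, ref, alt)


class LibraryIntegrityError(ValueError):
    """Two cassettes share an identical substitution set."""


@dataclass
class SegmentLibrary:
    """Designed substitution sets of one segment, keyed for exact matching."""

    segment: AmpliconSegment
    perfect_sets: dict[frozenset, list[str]] = field(default_factory=dict)
    designed_positions: set[int] = field(default_factory=set)
    ambiguous_sets: int = 0

    @classmethod
    def from_manifest(
        cls,
        manifest: pd.DataFrame,
        segment: AmpliconSegment,
        on_duplicate: str = "error",
    ) -> "SegmentLibrary":
        """Build the matching structures for one segment.

        ``on_duplicate`` controls cassettes with byte-identical substitution
        sets (genomically indistinguishable designs, e.g. two PAMs both
        destroyed by the codon edit itself): 'error' raises a
        :class:`LibraryIntegrityError`; 'merge' attributes perfect calls to
        the lexicographically smallest cassette id of each duplicate group.
        """
        if on_duplicate not in ("error", "merge"):
            raise ValueError("on_duplicate must be 'error' or 'merge'")
        lib = cls(segment=segment)
        lo, hi = segment.interval
        full_sets: dict[frozenset, str] = {}
        for row in manifest.itertuples():
            subs = parse_substitutions(row.substitutions)
            full = frozenset(subs)
            if full in full_sets and on_duplicate == "error":
                raise LibraryIntegrityError(
                    f"cassettes {full_sets[full]} and {row.id} share an identical "
                    "substitution set"
                )
            full_sets.setdefault(full, row.id)
            restricted = frozenset(s for s in subs if lo <= s[0] < hi)
            if not restricted:
                continue
            lib.perfect_sets.setdefault(restricted, []).append(row.id)
            lib.designed_positions.update(s[0] for s in restricted)
        for ids in lib.perfect_sets.values():
            ids.sort()
            if len(ids) > 1:
                lib.ambiguous_sets += 1
        return lib

    def duplicate_groups(self) -> list[list[str]]:
        return [ids for ids in self.perfect_sets.values() if len(ids) > 1]


def merge_pairs(
    r1: tuple[str, str, str],
    r2: tuple[str, str, str],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[str, str, str] | None:
    """Exact-overlap merger for a FASTQ pair (convenience only).

    r2 is reverse-complemented and the best-scoring 3' overlap with r1 is
    taken; in the overlap the higher-quality base wins.  Returns the merged
    (id, seq, qual) or None when no overlap passes the thresholds.
    """
    rid, s1, q1 = r1
    _, s2, q2 = r2
    if len(s1) != len(q1) or len(s2) != len(q2):
        raise ValueError(f"read {rid!r}: sequence/quality length mismatch")
    s2 = reverse_complement(s2)
    q2 = q2[::-1]
    best = None
    for ov in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        a, b = s1[-ov:], s2[:ov]
        mism = sum(x != y for x, y in zip(a, b))
        if mism / ov <= max_mismatch_frac:
            score = ov - 2 * mism
            if best is None or score > best[0]:
                best = (score, ov, mism)
    if best is None:
        return None
    _, ov, _ = best
    qa, qb = q1[-ov:], q2[:ov]
    consensus = "".join(
        x if (x == y or qa[i] >= qb[i]) else y for i, (x, y) in enumerate(zip(s1[-ov:], s2[:ov]))
    )
    cons_qual = "".join(max(qa[i], qb[i]) for i in range(ov))
    return rid, s1[:-ov] + consensus + s2[ov:], q1[:-ov] + cons_qual + q2[ov:]


def orient_read(seq: str, segment: AmpliconSegment) -> str | None:
    """Return the read in fwd-primer orientation, or None if neither
    orientation carries both primers at its ends."""
    rc_rev = reverse_complement(segment.rev_primer)
    for s in (seq, reverse_complement(seq)):
        if s.startswith(segment.fwd_primer) and s.endswith(rc_rev):
            return s
    return None


def call_read(
    read_id: str, seq: str, segment: AmpliconSegment, library: SegmentLibrary
) -> EditCall:
    """Filter, orient and classify a single merged read."""
    oriented = orient_read(seq, segment)
    if oriented is None:
        return EditCall(read_id, "filtered_primer")
    if len(oriented) != len(segment.reference):
        return EditCall(read_id, "filtered_length")
    observed = tuple(
        (segment.context_offset + i, r, a)
        for i, (r, a) in enumerate(zip(segment.reference, oriented))
        if r != a
    )
    if not observed:
        return EditCall(read_id, "wild_type")
    obs_set = frozenset(observed)
    ids = library.perfect_sets.get(obs_set)
    if ids:
        return EditCall(read_id, "perfect", cassette_id=ids[0], observed=observed)
    if any(pos not in library.designed_positions for pos, _, _ in observed):
        return EditCall(read_id, "unmatched", observed=observed)
    for designed in library.perfect_sets:
        if obs_set < designed:
            return EditCall(read_id, "imperfect", observed=observed)
    return EditCall(read_id, "unmatched", observed=observed)


def call_edits(
    reads: list[tuple[str, str]] | list[tuple[str, str, str]],
    segment: AmpliconSegment,
    library: SegmentLibrary,
) -> list[EditCall]:
    """Classify merged reads against one segment. Reads are (id, seq[, qual])."""
    return [call_read(r[0], r[1], segment, library) for r in reads]


@dataclass
class CountTable:
    segment_id: str
    total_retained: int
    status_counts: dict[str, int]
    raw: dict[str, int]  # cassette id -> raw perfect count
    normalized: dict[str, float] | None  # None when no retained reads

    def status_normalized(self) -> dict[str, float] | None:
        if self.total_retained == 0:
            return None
        return {
            s: self.status_counts.get(s, 0) * NORM_SCALE / self.total_retained
            for s in ("wild_type", "perfect", "imperfect", "unmatched")
        }


def count_and_normalize(calls: list[EditCall], segment: AmpliconSegment) -> CountTable:
    status_counts = {s: 0 for s in STATUSES}
    raw: dict[str, int] = {}
    for c in calls:
        status_counts[c.status] += 1
        if c.status == "perfect":
            raw[c.cassette_id] = raw.get(c.cassette_id, 0) + 1
    total = sum(status_counts[s] for s in ("wild_type", "perfect", "imperfect", "unmatched"))
    normalized = (
        {cid: n * NORM_SCALE / total for cid, n in raw.items()} if total > 0 else None
    )
    return CountTable(
        segment_id=segment.segment_id,
        total_retained=total,
        status_counts=status_counts,
        raw=raw,
        normalized=normalized,
    )


def combine_counts(tables: list[CountTable]) -> dict[str, int]:
    """Total raw perfect counts per cassette across segments."""
    out: dict[str, int] = {}
    for t in tables:
        for cid, n in t.raw.items():
            out[cid] = out.get(cid, 0) + n
    return out


def saturation_summary(tables: list[CountTable], manifest: pd.DataFrame) -> dict:
    """Per-codon editing and observed/designed percentages by category."""
    raw = combine_counts(tables)
    observed_ids = {cid for cid, n in raw.items() if n > 0}
    per_codon: dict[int, set[str]] = {}
    designed_by_cat: dict[str, set[str]] = {"all": set()}
    observed_by_cat: dict[str, set[str]] = {"all": set()}
    designed_swaps: dict[str, set[tuple[int, str]]] = {"all": set()}
    observed_swaps: dict[str, set[tuple[int, str]]] = {"all": set()}
    for row in manifest.itertuples():
        cat = row.category
        swap = (int(row.codon_index), str(row.new_aa))
        for key in ("all", cat):
            designed_by_cat.setdefault(key, set()).add(row.id)
            designed_swaps.setdefault(key, set()).add(swap)
        if row.id in observed_ids:
            per_codon.setdefault(int(row.codon_index), set()).add(row.id)
            for key in ("all", cat):
                observed_by_cat.setdefault(key, set()).add(row.id)
                observed_swaps.setdefault(key, set()).add(swap)
    codons_designed = sorted({int(r) for r in manifest["codon_index"]})
    edited = {i: len(per_codon.get(i, ())) for i in codons_designed}
    pct = lambda o, d: 100.0 * len(o) / len(d) if d else None
    return {
        "codons_designed": len(codons_designed),
        "codons_edited": sum(1 for n in edited.values() if n >= 1),
        "codons_edited_redundant": sum(1 for n in edited.values() if n >= 2),
        "pct_codons_edited": 100.0 * sum(1 for n in edited.values() if n >= 1) / len(codons_designed)
        if codons_designed
        else None,
        "per_codon_cassettes_observed": edited,
        "pct_cassettes_observed": {
            cat: pct(observed_by_cat.get(cat, set()), designed)
            for cat, designed in designed_by_cat.items()
        },
        "pct_aa_swaps_observed": {
            cat: pct(observed_swaps.get(cat, set()), designed)
            for cat, designed in designed_swaps.items()
        },
    }


def quantify_run(
    reads: list[tuple[str, str, str]],
    manifest: pd.DataFrame,
    segments: list[AmpliconSegment],
    on_duplicate: str = "error",
) -> tuple[list[CountTable], dict]:
    """Full pipeline: assign reads to segments, call, count, summarize.

    Each read is assigned to the first segment whose primers it carries.
    """
    libs = [SegmentLibrary.from_manifest(manifest, seg, on_duplicate) for seg in segments]
    per_segment_calls: dict[str, list[EditCall]] = {s.segment_id: [] for s in segments}
    for rid, seq, *_ in reads:
        call = None
        for seg, lib in zip(segments, libs):
            if orient_read(seq, seg) is not None:
                call = call_read(rid, seq, seg, lib)
                per_segment_calls[seg.segment_id].append(call)
                break
        if call is None:
            # count the rejection against the first segment for conservation
            per_segment_calls[segments[0].segment_id].append(
                EditCall(rid, "filtered_primer")
            )
    tables = [
        count_and_normalize(per_segment_calls[s.segment_id], s) for s in segments
    ]
    summary = saturation_summary(tables, manifest)
    summary["ambiguous_restricted_sets"] = sum(l.ambiguous_sets for l in libs)
    return tables, summary


def counts_frame(tables: list[CountTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for cid in sorted(t.raw):
            rows.append(
                {
                    "segment_id": t.segment_id,
                    "cassette_id": cid,
                    "raw": t.raw[cid],
                    "normalized": t.normalized[cid] if t.normalized else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["segment_id", "cassette_id", "raw", "normalized"])
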