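"""Whole-library design orchestration, landscape analytics, and oligo export.

Modes
-----
saturation : every codon in range x 21 target classes (the 20 amino acids,
             including one synonymous design, plus a stop codon)
stop_scan  : every codon in range x one stop-codon target
custom     : caller-supplied substitution sets or deletion intervals

Per (codon, target) slot, up to ``k`` top-ranked cassettes are kept; every
unfilled slot is recorded as missing with a reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import design_engine as de
from . import scoring
from .seq_core import AMINO_ACIDS, CodonTable, CodonSite, GeneTarget, translate, write_fasta

N_TARGET_CLASSES = 21  # 20 amino acids (incl. synonymous) + stop

MISSING_REASONS = (
    "no_pam_in_window",
    "polyT_all",
    "synonymous_kill_infeasible",
    "flank_bounds",
    "no_alternative_codon",
    "too_few_candidates",
)


@dataclass
class DesignSpec:
    pam_pattern: str = "NGN"
    window: int = 20
    k: int = 4
    mode: str = "saturation"  # saturation | stop_scan | custom
    codon_range: tuple[int, int] | None = None  # 1-based inclusive; None = all non-start sense codons
    adapters: tuple[str, str] = ("", "")
    codon_table: CodonTable = field(default_factory=CodonTable.default)
    strict_gc: bool = False
    #: 'any' discards every cassette whose donor+guide contains TTTTT;
    #: 'edit_introduced' discards only runs created by the edits (wild-type
    #: runs already present in the locus are tolerated)
    polyt_policy: str = "any"
    genome: list[tuple[str, str]] | None = None  # for off-target indexing
    seed_k: int = 12
    #: when the indexed genome contains the target locus, each guide's own
    #: site contributes one hit which is subtracted from its off-target count
    genome_contains_target: bool = True

    def resolve_range(self, target: GeneTarget) -> tuple[int, int]:
        if self.codon_range is not None:
            lo, hi = self.codon_range
        else:
            # default: all non-start codons, excluding a terminal stop codon
            hi = target.n_codons
            if target.codon_site(hi).wt_aa == "*":
                hi -= 1
            lo = 2
        if lo < 2:
            raise ValueError("codon_range must exclude the start codon (begin at 2)")
        if hi > target.n_codons:
            raise ValueError("codon_range beyond ORF")
        return lo, hi


@dataclass
class Cassette:
    """One donor+guide editing unit; the library atom."""

    gene_id: str
    codon_index: int
    wt_codon: str
    new_codon: str
    wt_aa: str
    new_aa: str
    category: str  # synonymous | missense | stop
    pam: de.PamSite
    guide: de.Guide
    donor: de.Donor
    substitutions: tuple[de.Substitution, ...]
    rank_key: scoring.RankKey
    adapters: tuple[str, str] = ("", "")
    rank: int = -1

    @property
    def oligo_core(self) -> str:
        """Donor + guide, adapters excluded (the transcribed cassette)."""
        return self.donor.emitted_seq + self.guide.protospacer

    @property
    def wt_oligo_core(self) -> str:
        """The same window with edits reverted (for polyT policy checks)."""
        return self.donor.wt_emitted_seq + self.guide.protospacer

    @property
    def oligo(self) -> str:
        return self.adapters[0] + self.oligo_core + self.adapters[1]

    @property
    def id(self) -> str:
        aa = self.new_aa if self.new_aa != "*" else "*"
        return f"{self.gene_id}|c{self.codon_index}|{self.wt_aa}{self.codon_index}{aa}|r{self.rank}"

    def subs_str(self) -> str:
        return ";".join(f"{s.offset}:{s.ref}>{s.alt}" for s in self.substitutions)


@dataclass
class LibraryReport:
    gene_id: str
    mode: str
    pam_pattern: str
    k: int
    codon_range: tuple[int, int]
    n_cassettes: int = 0
    missing: list[dict] = field(default_factory=list)
    per_codon_counts: dict[int, int] = field(default_factory=dict)
    per_slot_counts: dict[str, int] = field(default_factory=dict)  # "codon:new_aa" -> n
    sort_key_order: tuple[str, ...] = scoring.SORT_KEY_ORDER

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    def summary(self) -> dict:
        lo, hi = self.codon_range
        n_codons = hi - lo + 1
        targets = N_TARGET_CLASSES if self.mode == "saturation" else 1
        upper = n_codons * targets * self.k
        counts = [self.per_codon_counts.get(i, 0) for i in range(lo, hi + 1)]
        reasons: dict[str, int] = {}
        for m in self.missing:
            reasons[m["reason"]] = reasons.get(m["reason"], 0) + 1
        return {
            "gene_id": self.gene_id,
            "mode": self.mode,
            "pam_pattern": self.pam_pattern,
            "k": self.k,
            "codon_range": list(self.codon_range),
            "total_cassettes": self.n_cassettes,
            "missing_slots": self.n_missing,
            "slot_upper_bound": upper,
            "design_success_rate": self.n_cassettes / upper if upper else None,
            "codons_with_zero": sum(1 for c in counts if c == 0),
            "codons_with_one": sum(1 for c in counts if c == 1),
            "codons_with_two_plus": sum(1 for c in counts if c >= 2),
            "pct_codons_zero": 100.0 * sum(1 for c in counts if c == 0) / n_codons,
            "pct_codons_one": 100.0 * sum(1 for c in counts if c == 1) / n_codons,
            "missing_reasons": reasons,
            "sort_key_order": list(self.sort_key_order),
        }


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------

def _build_candidates(
    target: GeneTarget,
    site: CodonSite,
    new_codon: str,
    spec: DesignSpec,
    seed_index: scoring.SeedIndex | None,
    pam_cache: dict[int, list[de.PamSite]] | None = None,
) -> tuple[list[Cassette], str | None]:
    """All viable cassettes for one (codon, new_codon) slot, pre-ranking.

    Returns (candidates, failure_reason) where the reason is set when no
    candidate could be built.
    """
    table = spec.codon_table
    if pam_cache is not None and site.codon_index in pam_cache:
        pams = pam_cache[site.codon_index]
    else:
        pams = de.candidate_pams_for_codon(target, site, spec.pam_pattern, spec.window)
        if pam_cache is not None:
            pam_cache[site.codon_index] = pams
    if not pams:
        return [], "no_pam_in_window"

    new_aa = translate(new_codon)
    category = (
        "stop" if new_aa == "*" else ("synonymous" if new_aa == site.wt_aa else "missense")
    )
    edit_subs = de.plan_codon_edit(site, new_codon)

    candidates: list[Cassette] = []
    any_kill_infeasible = False
    any_flank_bounds = False
    for pam in pams:
        try:
            guide = de.guide_for_pam(target.context, pam)
        except ValueError:
            continue
        try:
            kill_subs = de.eliminate_recutting(
                target, pam, guide, edit_subs, table, spec.pam_pattern,
                forbidden_codons=frozenset({site.codon_index}),
            )
        except de.DesignInfeasible:
            any_kill_infeasible = True
            continue
        all_subs = sorted(edit_subs + kill_subs)
        try:
            donor = de.build_donor(target, all_subs, strand=pam.strand)
        except ValueError:
            any_flank_bounds = True
            continue
        if de.donor_is_cleavable(donor, guide, spec.pam_pattern):
            any_kill_infeasible = True
            continue
        offt = scoring.count_offtargets(seed_index, guide)
        if seed_index is not None and spec.genome_contains_target:
            offt = max(0, offt - 1)
        key = scoring.RankKey(
            distance=de.pam_codon_distance(pam, site),
            seed4_purine=scoring.seed_purine_fraction(guide),
            gc_in_range=scoring.gc_in_range(guide.gc),
            offtargets=offt,
            position_tiebreak=(pam.offset, pam.strand),
        )
        candidates.append(
            Cassette(
                gene_id=target.gene_id,
                codon_index=site.codon_index,
                wt_codon=site.wt_codon,
                new_codon=new_codon,
                wt_aa=site.wt_aa,
                new_aa=new_aa,
                category=category,
                pam=pam,
                guide=guide,
                donor=donor,
                substitutions=tuple(all_subs),
                rank_key=key,
                adapters=spec.adapters,
            )
        )
    if not candidates:
        if any_kill_infeasible:
            return [], "synonymous_kill_infeasible"
        if any_flank_bounds:
            return [], "flank_bounds"
        return [], "no_pam_in_window"
    return candidates, None


def _slot_reason(candidates: list[Cassette], selected: list[Cassette], reason: str | None) -> str:
    if reason is not None:
        return reason
    if candidates and not selected:
        return "polyT_all"
    return "too_few_candidates"


def _design_slots(
    target: GeneTarget,
    slots: list[tuple[CodonSite, str, str | None, str | None]],
    spec: DesignSpec,
) -> tuple[list[Cassette], LibraryReport]:
    """Shared driver: ``slots`` are (site, target_aa, new_codon, reason)."""
    target.check_design_flanks()
    seed_index = _seed_index_for(target, spec)
    lo, hi = spec.resolve_range(target)
    report = LibraryReport(
        gene_id=target.gene_id, mode=spec.mode, pam_pattern=spec.pam_pattern,
        k=spec.k, codon_range=(lo, hi),
    )
    cassettes: list[Cassette] = []
    pam_cache: dict[int, list[de.PamSite]] = {}
    for site, label, new_codon, precomputed in slots:
        if precomputed is not None:
            selected: list[Cassette] = []
            reason: str | None = precomputed
            candidates = []
        else:
            candidates, reason = _build_candidates(
                target, site, new_codon, spec, seed_index, pam_cache
            )
            selected = scoring.rank_and_select(candidates, spec.k, spec.strict_gc, spec.polyt_policy)
        cassettes.extend(selected)
        report.per_codon_counts[site.codon_index] = (
            report.per_codon_counts.get(site.codon_index, 0) + len(selected)
        )
        report.per_slot_counts[f"{site.codon_index}:{label}"] = len(selected)
        for _ in range(spec.k - len(selected)):
            report.missing.append(
                {
                    "codon_index": site.codon_index,
                    "wt_codon": site.wt_codon,
                    "new_codon": new_codon or "",
                    "new_aa": label,
                    "reason": _slot_reason(candidates, selected, reason),
                }
            )
    report.n_cassettes = len(cassettes)
    return cassettes, report


def _seed_index_for(target: GeneTarget, spec: DesignSpec) -> scoring.SeedIndex | None:
    if spec.genome is None:
        return None
    # restrict the index to seeds actually reachable from this gene: all
    # protospacer seeds adjacent to any PAM in the extended ORF window
    pams = de.enumerate_pams(target.context, spec.pam_pattern, require_protospacer=True)
    seeds = set()
    for pam in pams:
        try:
            seeds.add(de.guide_for_pam(target.context, pam).seed12)
        except ValueError:
            continue
    return scoring.build_seed_index(spec.genome, spec.seed_k, spec.pam_pattern, restrict_to=seeds)


def saturation_targets(
    site: CodonSite, table: CodonTable
) -> list[tuple[str, str | None, str | None]]:
    """(target_aa, new_codon, failure_reason) per target class for one codon."""
    out: list[tuple[str, str | None, str | None]] = []
    for aa in list(AMINO_ACIDS) + ["*"]:
        codon = table.design_codon(aa, site.wt_codon)
        out.append((aa, codon, None) if codon else (aa, None, "no_alternative_codon"))
    return out


def design_saturation_library(
    target: GeneTarget, spec: DesignSpec
) -> tuple[list[Cassette], LibraryReport]:
    if spec.mode != "saturation":
        raise ValueError("spec.mode must be 'saturation'")
    lo, hi = spec.resolve_range(target)
    slots = []
    for site in target.codon_sites(lo, hi):
        for aa, new_codon, reason in saturation_targets(site, spec.codon_table):
            slots.append((site, aa, new_codon, reason))
    return _design_slots(target, slots, spec)


def design_stop_library(
    target: GeneTarget, spec: DesignSpec
) -> tuple[list[Cassette], LibraryReport]:
    if spec.mode != "stop_scan":
        raise ValueError("spec.mode must be 'stop_scan'")
    lo, hi = spec.resolve_range(target)
    slots = []
    for site in target.codon_sites(lo, hi):
        stop = spec.codon_table.design_codon("*", site.wt_codon)
        slots.append((site, "*", stop, None if stop else "no_alternative_codon"))
    return _design_slots(target, slots, spec)


def design_custom(
    target: GeneTarget,
    edits: list[dict],
    spec: DesignSpec,
) -> tuple[list[Cassette], LibraryReport]:
    """Design cassettes for caller-specified edits.

    Each edit is either {"codon_index": i, "new_codon": "XYZ"} or
    {"deletion": [start, end]} with context coordinates.
    """
    target.check_design_flanks()
    seed_index = _seed_index_for(target, spec)
    report = LibraryReport(
        gene_id=target.gene_id, mode="custom", pam_pattern=spec.pam_pattern,
        k=spec.k, codon_range=(2, target.n_codons),
    )
    cassettes: list[Cassette] = []
    for edit in edits:
        if "deletion" in edit:
            cassettes.extend(_design_deletion(target, tuple(edit["deletion"]), spec, seed_index, report))
        else:
            site = target.codon_site(edit["codon_index"])
            candidates, reason = _build_candidates(
                target, site, edit["new_codon"], spec, seed_index
            )
            selected = scoring.rank_and_select(candidates, spec.k, spec.strict_gc, spec.polyt_policy)
            cassettes.extend(selected)
            for _ in range(spec.k - len(selected)):
                report.missing.append(
                    {
                        "codon_index": site.codon_index,
                        "wt_codon": site.wt_codon,
                        "new_codon": edit["new_codon"],
                        "new_aa": translate(edit["new_codon"]),
                        "reason": _slot_reason(candidates, selected, reason),
                    }
                )
    report.n_cassettes = len(cassettes)
    return cassettes, report


def _design_deletion(target, interval, spec, seed_index, report) -> list[Cassette]:
    d0, d1 = interval
    # nearest codon used for labeling/distance only
    idx = min(max(1, (d0 - target.orf_start) // 3 + 1), target.n_codons)
    site = target.codon_site(idx)
    pams = de.enumerate_pams(
        target.context,
        spec.pam_pattern,
        (max(0, d0 - spec.window - 3), min(len(target.context), d1 + spec.window + 3)),
        require_protospacer=True,
    )
    candidates = []
    for pam in pams:
        try:
            guide = de.guide_for_pam(target.context, pam)
        except ValueError:
            continue
        try:
            donor = de.build_donor(target, [], strand=pam.strand, deletion=(d0, d1))
        except ValueError:
            continue
        # the deletion must disrupt the protospacer or PAM so the edited
        # locus (and donor) cannot be re-cut
        if de.donor_is_cleavable(donor, guide, spec.pam_pattern):
            continue
        p0, p1 = de.protospacer_interval(pam)
        if not (d0 < max(p1, pam.interval[1]) and d1 > min(p0, pam.interval[0])):
            continue
        key = scoring.RankKey(
            distance=0,
            seed4_purine=scoring.seed_purine_fraction(guide),
            gc_in_range=scoring.gc_in_range(guide.gc),
            offtargets=scoring.count_offtargets(seed_index, guide),
            position_tiebreak=(pam.offset, pam.strand),
        )
        candidates.append(
            Cassette(
                gene_id=target.gene_id, codon_index=site.codon_index,
                wt_codon=site.wt_codon, new_codon="---", wt_aa=site.wt_aa,
                new_aa="-", category="deletion", pam=pam, guide=guide,
                donor=donor, substitutions=(), rank_key=key, adapters=spec.adapters,
            )
        )
    selected = scoring.rank_and_select(candidates, spec.k, spec.strict_gc, spec.polyt_policy)
    for _ in range(spec.k - len(selected)):
        report.missing.append(
            {
                "codon_index": site.codon_index, "wt_codon": site.wt_codon,
                "new_codon": "---", "new_aa": "-",
                "reason": "no_pam_in_window" if not candidates else "polyT_all",
            }
        )
    return selected


# ---------------------------------------------------------------------------
# landscape analytics
# ---------------------------------------------------------------------------

def landscape_matrix(target: GeneTarget, spec: DesignSpec) -> pd.DataFrame:
    """Counts of polyT-surviving candidates (pre top-k) per codon x target.

    Rows are codon indices, columns the 20 amino acids plus '*'.
    """
    target.check_design_flanks()
    lo, hi = spec.resolve_range(target)
    cols = list(AMINO_ACIDS) + ["*"]
    data = {}
    pam_cache: dict[int, list[de.PamSite]] = {}
    for site in target.codon_sites(lo, hi):
        row = []
        for _aa, new_codon, reason in saturation_targets(site, spec.codon_table):
            if reason is not None:
                row.append(0)
                continue
            candidates, _ = _build_candidates(target, site, new_codon, spec, None, pam_cache)
            row.append(sum(1 for c in candidates if scoring.passes_polyt(c, spec.polyt_policy)))
        data[site.codon_index] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def landscape_summary(matrix: pd.DataFrame) -> dict:
    """Per-codon design-space statistics under several readings.

    The headline percentages use the worst-covered swap per codon
    (min across target classes): a codon counts as uneditable when at least
    one swap has no available cassette, and as single-cassette when its
    worst-covered swap has exactly one.  Total-across-targets and per-slot
    readings are emitted alongside for diagnosis.
    """
    totals = matrix.sum(axis=1)
    mins = matrix.min(axis=1)
    n = len(matrix)
    per_target_zero = int((matrix == 0).sum().sum())
    return {
        "n_codons": n,
        "codons_uneditable": int((mins == 0).sum()),
        "codons_single_cassette": int((mins == 1).sum()),
        "pct_codons_zero": 100.0 * float((mins == 0).mean()),
        "pct_codons_one": 100.0 * float((mins == 1).mean()),
        # alternative readings, for diagnosis
        "pct_codons_zero_total": 100.0 * float((totals == 0).mean()),
        "pct_codons_one_total": 100.0 * float((totals == 1).mean()),
        "pct_slots_zero": 100.0 * per_target_zero / matrix.size,
    }


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "id", "gene_id", "codon_index", "wt_codon", "new_codon", "wt_aa", "new_aa",
    "category", "rank", "guide", "pam_seq", "pam_offset", "strand",
    "pam_codon_distance", "seed4_purine", "guide_gc", "gc_in_range", "offtargets",
    "donor", "donor_start", "donor_end", "substitutions", "oligo",
]


def export_library(
    cassettes: list[Cassette],
    report: LibraryReport,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write oligos FASTA, manifest TSV and report JSON under ``prefix``."""
    if not cassettes:
        raise ValueError("refusing to export an empty library")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(".oligos.fa"),
        "manifest": prefix.with_suffix(".manifest.tsv"),
        "report": prefix.with_suffix(".report.json"),
    }
    ids = [c.id for c in cassettes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cassette ids in library")
    write_fasta(paths["fasta"], [(c.id, c.oligo) for c in cassettes])
    df = manifest_frame(cassettes)
    df.to_csv(paths["manifest"], sep="\t", index=False)
    with open(paths["report"], "w") as fh:
        json.dump(report.summary() | {"missing": report.missing}, fh, indent=1)
    return paths


def manifest_frame(cassettes: list[Cassette]) -> pd.DataFrame:
    rows = []
    for c in cassettes:
        rows.append(
            {
                "id": c.id, "gene_id": c.gene_id, "codon_index": c.codon_index,
                "wt_codon": c.wt_codon, "new_codon": c.new_codon,
                "wt_aa": c.wt_aa, "new_aa": c.new_aa, "category": c.category,
                "rank": c.rank, "guide": c.guide.protospacer, "pam_seq": c.pam.pam_seq,
                "pam_offset": c.pam.offset, "strand": c.pam.strand,
                "pam_codon_distance": c.rank_key.distance,
                "seed4_purine": c.rank_key.seed4_purine,
                "guide_gc": c.guide.gc, "gc_in_range": c.rank_key.gc_in_range,
                "offtargets": c.rank_key.offtargets,
                "donor": c.donor.emitted_seq,
                "donor_start": c.donor.core_start - de.ARM_LEN,
                "donor_end": c.donor.core_end + de.ARM_LEN,
                "substitutions": c.subs_str(),
                "oligo": c.oligo,
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"substitutions": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def parse_substitutions(s: str) -> list[tuple[int, str, str]]:
    """Parse an 'offset:ref>alt;...' manifest column."""
    if not s or pd.isna(s):
        return []
    out = []
    for item in str(s).split(";"):
        pos, rest = item.split(":")
        ref, alt = rest.split(">")
        out.append((int(pos), ref, alt))
    return out
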