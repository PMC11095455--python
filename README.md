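# chase

Saturation-editing cassette design and amplicon-NGS quantification for
CRISPR/HDR codon-swap libraries in yeast.

A *cassette* is a single synthesized oligo fusing an HDR donor (5') to its
20-bp guide sequence (3'). For every codon of a target ORF and every target
class (the 20 amino acids, including one synonymous design, plus a stop
codon), the designer enumerates candidate PAMs near the codon, builds donors
carrying the codon edit plus synonymous substitutions that destroy the PAM
and/or protospacer seed (so neither the donor nor the edited locus is
re-cut), filters polyT-containing cassettes, ranks the rest, and keeps the
top *k* (default 4). The companion quantifier calls designed edits in merged
amplicon reads and produces normalized count tables and per-codon saturation
summaries. A simulator generates toy genes and synthetic edited reads so the
whole loop is testable without sequencing data.

## Layout

| module                  | role |
|-------------------------|------|
| `chase.seq_core`        | sequences, codons, coordinates, FASTA/FASTQ/GFF3 I/O |
| `chase.design_engine`   | PAM/guide enumeration, donor construction, re-cut elimination |
| `chase.scoring`         | polyT filter, rank features, 12-bp seed off-target index, top-k |
| `chase.library_builder` | whole-library orchestration, landscape analytics, export |
| `chase.quantify`        | read filtering/orientation, cassette calling, normalization |
| `chase.simulate`        | toy genes and synthetic edited reads |

`data/` holds the S288C-derived inputs used by the acceptance checks: the
nuclear genome as plain FASTA (for off-target indexing) and the ADE2
(YOR128C) / SPT15 (YER148W) regions with 500-bp flanks, oriented so each ORF
reads 5'→3' on the plus strand.

## CLI

```sh
# design a stop-scan library (codons 2-250, NGN PAMs, 4 cassettes per codon)
chase design --fasta data/ade2_region.fa --orf-start 500 --orf-len 1716 \
    --pam NGN --mode stop --k 4 --codon-range 2:250 \
    --genome data/s288c/genome.fa --out out/ade2_ngn

# per-codon design-space matrix (candidates per target class)
chase landscape --fasta data/ade2_region.fa --orf-start 500 --orf-len 1716 \
    --pam NGG --out out/ade2_ngg_landscape.tsv

# simulate edited amplicon reads from a manifest, then quantify them
chase simulate --library out/lib.manifest.tsv --segments segments.tsv \
    --config sim.json --out reads.fastq
chase quant --reads reads.fastq --library out/lib.manifest.tsv \
    --segments segments.tsv --out out/quant
```

`chase design` emits an oligo FASTA, a TSV manifest (one row per cassette:
guide, PAM, strand, donor, substitutions as `offset:ref>alt` lists, rank
features) and a JSON report with per-slot missing-design accounting.

## PolyT policy

Cassettes are transcribed from a type III promoter, which terminates at runs
of five or more T's. Two filter policies are available via
`DesignSpec.polyt_policy`:

* `any` (default) — discard every cassette whose donor+guide contains
  `TTTTT`, the conservative reading of the published rule;
* `edit_introduced` — tolerate runs already present in the wild-type locus
  and discard only runs created by the edits. This is the policy that
  reproduces the published library sizes (AT-rich loci contain wild-type
  T-runs in nearly every donor window, yet the published libraries retain
  full coverage there), and is what `scripts/acceptance.py` uses.

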