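{
 "ADE2": {
  "gene_id": "ADE2",
  "systematic": "YOR128C",
  "chrom": "chrXV",
  "genome_start": 563975,
  "genome_end": 566691,
  "strand": "-",
  "orf_start": 500,
  "orf_length": 1716
 },
 "SPT15": {
  "gene_id": "SPT15",
  "systematic": "YER148W",
  "chrom": "chrV",
  "genome_start": 464802,
  "genome_end": 466525,
  "strand": "+",
  "orf_start": 500,
  "orf_length": 723
 }
}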