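import json
from pathlib import Path

import pytest

from chase.seq_core import CodonTable, GeneTarget, read_fasta
from chase.simulate import SimConfig, make_toy_gene

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def codon_table() -> CodonTable:
    return CodonTable.default()


@pytest.fixture(scope="session")
def toy_target() -> GeneTarget:
    return make_toy_gene(SimConfig(seed=11, orf_codons=30, flank=100))


@pytest.fixture(scope="session")
def ade2_target() -> GeneTarget:
    meta = json.load(open(DATA_DIR / "regions.json"))["ADE2"]
    _, seq = read_fasta(DATA_DIR / "ade2_region.fa")[0]
    return GeneTarget("ADE2", seq, meta["orf_start"], meta["orf_length"])


@pytest.fixture(scope="session")
def spt15_target() -> GeneTarget:
    meta = json.load(open(DATA_DIR / "regions.json"))["SPT15"]
    _, seq = read_fasta(DATA_DIR / "spt15_region.fa")[0]
    return GeneTarget("SPT15", seq, meta["orf_start"], meta["orf_length"])
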