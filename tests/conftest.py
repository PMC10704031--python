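"""Shared fixtures: a small genome, a simulated scenario and toy gene models.

All fixtures are generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from bsamap.effects import GeneModel
from bsamap.io import RunConfig
from bsamap.pipeline import run_scenario
from bsamap.simulate import GenomeSpec


@pytest.fixture(scope="session")
def genome() -> GenomeSpec:
    return GenomeSpec((("chr3", 40_000_000), ("chr8", 60_000_000)), recombination_rate=2.5)


@pytest.fixture(scope="session")
def scenario():
    """One dual-design simulated experiment at the default operating points."""
    cfg = RunConfig()
    cfg.seed = 11
    return run_scenario(cfg)


def _build_minus_gene() -> tuple[GeneModel, int]:
    """A 5-exon minus-strand gene whose CDS position 401 holds an A in an
    AAT codon at codon 134, mapped (by hand) to genomic position 1100.

    Transcript-order CDS exon lengths 100/100/100/80/121 put CDS base 401
    at offset 21 of exon 5; that exon's genomic interval is 1000..1120 on
    the minus strand, so the base sits at 1120 - 21 + 1 = 1100.
    """
    cds_seq = list("GCT" * 167)  # 501 bases of Ala codons
    cds_seq[399:402] = list("AAT")  # codon 134
    cds_seq = "".join(cds_seq)
    # ascending genomic CDS intervals = transcript exons 5..1
    ivs = ((1000, 1120), (1171, 1250), (1301, 1400), (1451, 1550), (1601, 1700))
    model = GeneModel(
        gene_id="toy_minus",
        chrom="chr8",
        strand="-",
        tx_start=1000,
        tx_end=1700,
        exons=ivs,
        cds=ivs,
        cds_seq=cds_seq,
    )
    return model, 1100


@pytest.fixture(scope="session")
def minus_gene() -> GeneModel:
    return _build_minus_gene()[0]


@pytest.fixture(scope="session")
def minus_gene_hit() -> int:
    """Genomic position mapping to CDS 401 of the minus-strand toy gene."""
    return _build_minus_gene()[1]


@pytest.fixture(scope="session")
def plus_gene() -> GeneModel:
    """A 2-exon plus-strand gene with a 30 bp intron; all-exon CDS."""
    rng = np.random.default_rng(42)
    len1, len2 = 60, 90
    cds_seq = "ATG" + "".join(rng.choice(list("ACGT"), size=len1 + len2 - 6)) + "TAA"
    return GeneModel(
        gene_id="toy_plus",
        chrom="chr3",
        strand="+",
        tx_start=5000,
        tx_end=5000 + len1 + 30 + len2 - 1,
        exons=((5000, 5000 + len1 - 1), (5000 + len1 + 30, 5000 + len1 + 30 + len2 - 1)),
        cds=((5000, 5000 + len1 - 1), (5000 + len1 + 30, 5000 + len1 + 30 + len2 - 1)),
        cds_seq=cds_seq,
    )


def chromosome_sequence_for(model: GeneModel, length: int) -> str:
    """A reference chromosome consistent with a gene model's CDS sequence."""
    seq = ["G"] * length
    spliced = model.cds_seq
    if model.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    i = 0
    for s, e in model.cds:
        n = e - s + 1
        seq[s - 1 : e] = list(spliced[i : i + n])
        i += n
    return "".join(seq)
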