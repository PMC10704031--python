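"""Strand-aware variant-to-gene mapping and codon-level effect calls.

A :class:`GeneModel` is a single-transcript gene: genomic exon and CDS
intervals plus the spliced, strand-corrected CDS sequence. Variants are
placed into the genic-region classes a mapping study reports — exon,
intron, upstream (within 2 kb of the transcription start), downstream
(within 2 kb of the termination site) or intergenic — and rendered as
compact labels (``exon5:401``, ``intron3:84``, ``upstream dist:976``,
``downstream dist:781``) where the exon offset is a 1-based position in
the spliced CDS and the intron offset counts from the intron's 5' end in
transcript orientation. Coding substitutions are resolved to the codon
and amino-acid change under the standard nuclear code.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "RegionAnnotation",
    "CodingEffect",
    "OutsideCDSError",
    "ReferenceMismatchError",
    "locate_variant",
    "genomic_to_cds",
    "cds_to_genomic",
    "cds_alleles",
    "annotate_coding_effect",
    "classify_indel",
    "parse_region_label",
    "FLANK_BP",
]

#: extent of the regulatory flank: 2 kb on either side of the transcript
FLANK_BP = 2000


class OutsideCDSError(ValueError):
    """Coordinate does not fall in any CDS interval of the model."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the CDS sequence."""


@dataclass(frozen=True)
class GeneModel:
    """One gene, one transcript.

    ``exons`` and ``cds`` are genomic ``(start, end)`` intervals, 1-based
    inclusive, sorted by genomic start regardless of strand; ``cds_seq``
    is the spliced coding sequence 5'->3' on the coding strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    cds_seq: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for ivs in (self.exons, self.cds):
            prev_end = 0
            for s, e in ivs:
                if s > e:
                    raise ValueError(f"bad interval ({s}, {e}) in {self.gene_id}")
                if s <= prev_end:
                    raise ValueError(f"overlapping intervals in {self.gene_id}")
                prev_end = e
        n = self.cds_length
        if n % 3 != 0:
            raise ValueError(f"CDS length {n} of {self.gene_id} not divisible by 3")
        if self.cds_seq and len(self.cds_seq) != n:
            raise ValueError(
                f"CDS sequence length {len(self.cds_seq)} != interval total {n}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns_tx_order(self) -> tuple[tuple[int, int], ...]:
        gaps = [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] + 1 <= self.exons[i + 1][0] - 1
        ]
        return tuple(gaps) if self.strand == "+" else tuple(reversed(gaps))


@dataclass(frozen=True)
class RegionAnnotation:
    """Region class of a variant relative to its nearest gene.

    ``ordinal`` numbers exons/introns in transcript orientation (1-based);
    ``offset`` is the 1-based CDS position for coding exon hits, the
    distance from the intron's transcript-5' end for intron hits, or the
    distance to the TSS/TTS for flank hits. A coding-exon variant carries
    the gene and both pieces; a UTR exon variant has ``offset=None``.
    """

    region: str  # exon | intron | upstream | downstream | intergenic
    gene_id: str | None = None
    ordinal: int | None = None
    offset: int | None = None

    @property
    def label(self) -> str:
        if self.region == "exon":
            off = "UTR" if self.offset is None else self.offset
            return f"exon{self.ordinal}:{off}"
        if self.region == "intron":
            return f"intron{self.ordinal}:{self.offset}"
        if self.region in ("upstream", "downstream"):
            return f"{self.region} dist:{self.offset}"
        return "intergenic"


_LABEL_RE = re.compile(
    r"^(?:(exon|intron)(\d+):(\d+|UTR)|(upstream|downstream) dist:(\d+)|(intergenic))$"
)


def parse_region_label(label: str, gene_id: str | None = None) -> RegionAnnotation:
    """Parse a region label back into its structured form (label round-trips)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable region label {label!r}")
    if m.group(1):
        off = None if m.group(3) == "UTR" else int(m.group(3))
        return RegionAnnotation(m.group(1), gene_id, int(m.group(2)), off)
    if m.group(4):
        return RegionAnnotation(m.group(4), gene_id, None, int(m.group(5)))
    return RegionAnnotation("intergenic", gene_id)


def _in(pos: int, iv: tuple[int, int]) -> bool:
    return iv[0] <= pos <= iv[1]


def genomic_to_cds(pos: int, model: GeneModel) -> int:
    """Map a genomic coordinate to its 1-based position in the spliced CDS.

    Minus-strand genes count from the transcript 5' end, i.e. from the
    highest-coordinate CDS interval downwards.
    """
    if model.strand == "+":
        cum = 0
        for s, e in model.cds:
            if _in(pos, (s, e)):
                return cum + (pos - s + 1)
            cum += e - s + 1
    else:
        cum = 0
        for s, e in reversed(model.cds):
            if _in(pos, (s, e)):
                return cum + (e - pos + 1)
            cum += e - s + 1
    raise OutsideCDSError(f"{model.chrom}:{pos} is not in the CDS of {model.gene_id}")


def cds_to_genomic(cds_pos: int, model: GeneModel) -> int:
    """Inverse of :func:`genomic_to_cds`."""
    if not 1 <= cds_pos <= model.cds_length:
        raise OutsideCDSError(f"CDS position {cds_pos} outside 1..{model.cds_length}")
    rem = cds_pos
    if model.strand == "+":
        for s, e in model.cds:
            n = e - s + 1
            if rem <= n:
                return s + rem - 1
            rem -= n
    else:
        for s, e in reversed(model.cds):
            n = e - s + 1
            if rem <= n:
                return e - rem + 1
            rem -= n
    raise AssertionError("unreachable")


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def cds_alleles(ref: str, alt: str, strand: str) -> tuple[str, str]:
    """Genomic alleles expressed on the coding strand."""
    if strand == "+":
        return ref, alt
    return ref.translate(_COMP), alt.translate(_COMP)


def _locate_in_gene(pos: int, g: GeneModel) -> RegionAnnotation | None:
    """Region of a position inside a gene's transcript span, else None."""
    if not _in(pos, (g.tx_start, g.tx_end)):
        return None
    try:
        cds_pos = genomic_to_cds(pos, g)
    except OutsideCDSError:
        cds_pos = None
    for ordinal, (s, e) in enumerate(g.exons_tx_order(), start=1):
        if _in(pos, (s, e)):
            return RegionAnnotation("exon", g.gene_id, ordinal, cds_pos)
    for ordinal, (s, e) in enumerate(g.introns_tx_order(), start=1):
        if _in(pos, (s, e)):
            off = (pos - s + 1) if g.strand == "+" else (e - pos + 1)
            return RegionAnnotation("intron", g.gene_id, ordinal, off)
    # inside the span but in no exon or intron (e.g. before the first exon
    # of a partial model): treat as intron-less gap -> intergenic
    return RegionAnnotation("intergenic", g.gene_id)


def _flank(pos: int, g: GeneModel) -> RegionAnnotation | None:
    if g.strand == "+":
        up_anchor, down_anchor = g.tx_start, g.tx_end
        up_dist, down_dist = up_anchor - pos, pos - down_anchor
    else:
        up_anchor, down_anchor = g.tx_end, g.tx_start
        up_dist, down_dist = pos - up_anchor, down_anchor - pos
    if 1 <= up_dist <= FLANK_BP:
        return RegionAnnotation("upstream", g.gene_id, None, up_dist)
    if 1 <= down_dist <= FLANK_BP:
        return RegionAnnotation("downstream", g.gene_id, None, down_dist)
    return None


def locate_variant(variant, models: Iterable[GeneModel] | Mapping[str, GeneModel]):
    """Region annotation of a variant against a gene-model collection.

    A gene whose transcript span contains the variant wins over flank
    hits; among several qualifying genes the smallest distance wins, ties
    broken by lexicographic gene id. A chromosome with no models yields an
    intergenic call with a logged warning.
    """
    if isinstance(models, Mapping):
        models = models.values()
    chrom_models = [g for g in models if g.chrom == variant.chrom]
    if not chrom_models:
        logger.warning("no gene models on %s; %s:%d called intergenic",
                       variant.chrom, variant.chrom, variant.pos)
        return RegionAnnotation("intergenic")
    containing = []
    for g in sorted(chrom_models, key=lambda g: g.gene_id):
        ann = _locate_in_gene(variant.pos, g)
        if ann is not None and ann.region != "intergenic":
            containing.append(ann)
    if containing:
        return containing[0]
    flanks = []
    for g in sorted(chrom_models, key=lambda g: g.gene_id):
        ann = _flank(variant.pos, g)
        if ann is not None:
            flanks.append((ann.offset, ann.gene_id, ann))
    if flanks:
        flanks.sort(key=lambda t: (t[0], t[1]))
        return flanks[0][2]
    return RegionAnnotation("intergenic")


@dataclass(frozen=True)
class CodingEffect:
    """A substitution resolved to its codon and amino-acid consequence."""

    cds_pos: int
    codon_index: int
    codon_position: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous | stop_gained | stop_lost


def annotate_coding_effect(
    cds_pos: int, ref_allele_cds: str, alt_allele_cds: str, cds_sequence: str
) -> CodingEffect:
    """Codon-level consequence of a single-base CDS substitution.

    ``cds_pos`` is 1-based in the spliced CDS; alleles are given on the
    coding strand. The stated reference allele is checked against the CDS
    sequence and a mismatch raises, never proceeds silently.
    """
    cds_sequence = cds_sequence.upper()
    n = len(cds_sequence)
    if n % 3 != 0:
        raise ValueError(f"CDS length {n} not divisible by 3")
    if not 1 <= cds_pos <= n:
        raise OutsideCDSError(f"CDS position {cds_pos} outside 1..{n}")
    ref_allele_cds = ref_allele_cds.upper()
    alt_allele_cds = alt_allele_cds.upper()
    if cds_sequence[cds_pos - 1] != ref_allele_cds:
        raise ReferenceMismatchError(
            f"CDS position {cds_pos} carries {cds_sequence[cds_pos - 1]!r}, "
            f"not the stated reference {ref_allele_cds!r}"
        )
    codon_index = (cds_pos + 2) // 3  # ceil(cds_pos / 3)
    codon_position = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds_sequence[start : start + 3]
    alt_codon = (
        ref_codon[: codon_position - 1] + alt_allele_cds + ref_codon[codon_position:]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    elif ref_aa == "*":
        effect = "stop_lost"
    else:
        effect = "nonsynonymous"
    return CodingEffect(
        cds_pos, codon_index, codon_position, ref_codon, alt_codon, ref_aa, alt_aa, effect
    )


def classify_indel(ref: str, alt: str) -> str:
    """Coarse indel flag: frameshift unless the length change is a multiple of 3."""
    d = abs(len(ref) - len(alt))
    if d == 0:
        raise ValueError("not an indel")
    return "inframe_indel" if d % 3 == 0 else "frameshift"
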