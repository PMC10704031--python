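"""Readers and writers for counts tables, gene models and run configs.

The on-disk atoms are plain text: a tidy TSV of per-(site, pool) allele
depths, a minimal VCF 4.2 with one sample column per pool carrying
``AD``-style ref,alt depths, GFF3 + FASTA gene models, and a YAML run
configuration echoed verbatim into every output directory. All genomic
coordinates are 1-based inclusive in every format.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .effects import GeneModel
from .simulate import COUNT_COLUMNS, F2Individual, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts_tsv",
    "write_counts_vcf",
    "read_gene_models",
    "write_truth_sites",
    "write_genotypes",
    "RunConfig",
]

_KEY = ["chrom", "pos", "ref", "alt"]


class CountsParseError(ValueError):
    """A malformed row in a counts table, reported with its line number."""


# ---------------------------------------------------------------- counts TSV

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.loc[:, list(COUNT_COLUMNS)].to_csv(path, sep="\t", index=False)


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise CountsParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("ref_count", "alt_count", "pos"):
        bad = df.index[df[col] < 0]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based numbering
            raise CountsParseError(
                f"{path} line {bad[0] + 2}: negative value in column {col!r}"
            )
    return df.loc[:, list(COUNT_COLUMNS)]


# ---------------------------------------------------------------- counts VCF

def write_counts_vcf(
    counts: pd.DataFrame,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a pool-counts table as VCF 4.2, one sample column per pool.

    Allele depths go in the per-sample ``AD`` field as ``ref,alt``; sites
    absent from a pool get ``.``.
    """
    pools = sorted(counts["pool"].unique())
    wide = counts.pivot_table(
        index=_KEY, columns="pool", values=["ref_count", "alt_count"], aggfunc="first"
    )
    contigs = dict.fromkeys(counts["chrom"])
    lines = ["##fileformat=VCFv4.2", "##source=bsamap"]
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pools)
    )
    order = {c: i for i, c in enumerate(contigs)}
    for key in sorted(wide.index, key=lambda k: (order[k[0]], k[1])):
        chrom, pos, ref, alt = key
        fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "AD"]
        for p in pools:
            try:
                rc = wide.loc[key, ("ref_count", p)]
                ac = wide.loc[key, ("alt_count", p)]
            except KeyError:
                rc = ac = None
            if rc is None or pd.isna(rc):
                fields.append(".")
            else:
                fields.append(f"{int(rc)},{int(ac)}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_counts_vcf(path: Path) -> pd.DataFrame:
    rows = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) != 2 or ad[0] is None:
                    continue
                rows.append(
                    (rec.chrom, rec.pos, rec.ref, rec.alts[0], s, int(ad[0]), int(ad[1]))
                )
    if n_multi:
        logger.warning("%s: skipped %d multi-allelic record(s)", path, n_multi)
    return pd.DataFrame(rows, columns=list(COUNT_COLUMNS))


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a per-(site, pool) allele-count table from TSV or VCF.

    Format is inferred from the extension when not given. Multi-allelic
    VCF records are skipped with a logged count (biallelic-only contract);
    malformed TSV rows raise with their line number.
    """
    path = Path(path)
    fmt = format or ("vcf" if path.suffix.lower() == ".vcf" else "tsv")
    if fmt == "vcf":
        return _read_counts_vcf(path)
    if fmt == "tsv":
        return _read_counts_tsv(path)
    raise ValueError(f"unknown counts format {fmt!r}")


# ---------------------------------------------------------------- gene models

def read_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> dict[str, GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 and its FASTA.

    Expects the usual gene -> mRNA -> exon/CDS hierarchy with one
    transcript per gene (the first mRNA is used). The spliced CDS is
    extracted from the FASTA and reverse-complemented for minus-strand
    genes. Genes violating the model invariants (overlapping exons, CDS
    length not divisible by 3) are rejected with a logged warning.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(parent, featuretype="CDS"))
        if not exons:
            exons = cds
        chrom_seq = seqs.get(gene.seqid)
        if chrom_seq is None:
            logger.warning("gene %s: chromosome %s absent from FASTA; skipped",
                           gene.id, gene.seqid)
            continue
        spliced = "".join(chrom_seq[s - 1 : e] for s, e in cds)
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        try:
            model = GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=parent.start,
                tx_end=parent.end,
                exons=tuple(exons),
                cds=tuple(cds),
                cds_seq=spliced,
            )
        except ValueError as exc:
            logger.warning("gene %s rejected: %s", gene.id, exc)
            continue
        models[model.gene_id] = model
    return models


# ---------------------------------------------------------------- truth files

def write_truth_sites(sites: list[VariantSite], path: str | Path) -> None:
    """The simulated site table, causal flag included — the answer key."""
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "is_causal": [int(s.is_causal) for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


def write_genotypes(
    population: list[F2Individual], sites: list[VariantSite], path: str | Path
) -> None:
    """Per-individual alt-allele dosages (rows) by site (columns)."""
    cols = {"individual": [f"ind_{i:04d}" for i in range(len(population))],
            "phenotype": [ind.phenotype for ind in population]}
    frame = pd.DataFrame(cols)
    dosage = pd.DataFrame(
        [ind.dosages for ind in population],
        columns=[f"{s.chrom}:{s.pos}" for s in sites],
    )
    pd.concat([frame, dosage], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """A full simulation/analysis scenario, serializable to YAML.

    Defaults are the study's stated operating points: pools of 28
    (single-pool design) and 45 + 50 (two-pool design), parent depths
    ~33x, F2 pool depths ~34x (single-pool) and ~110x (two-pool).
    """

    genome: dict = field(default_factory=lambda: {
        "chromosomes": [{"name": "chr3", "length": 40_000_000},
                        {"name": "chr8", "length": 60_000_000}],
        "recombination_rate": 2.5,
    })
    ems: dict = field(default_factory=lambda: {
        "n_background": 300,
        "transition_fraction": 0.9,
        "causal": {"chrom": "chr8", "pos": 47_106_679},
    })
    populations: dict = field(default_factory=lambda: {
        "mutmap_f2_size": 200, "qtlseq_f2_size": 300,
    })
    pools: dict = field(default_factory=lambda: {
        "mutmap_mutant": 28, "qtlseq_mutant": 45, "qtlseq_wildtype": 50,
    })
    depths: dict = field(default_factory=lambda: {
        "mutmap_parent": 33, "mutmap_pool": 34,
        "qtlseq_parent": 32, "qtlseq_pool": 110,
    })
    error_rate: float = 0.001
    statistics: dict = field(default_factory=lambda: {
        "window_size": 2_000_000, "step": 50_000, "min_sites": 10,
        "min_depth": 8, "ci_reps": 10_000, "levels": [0.95, 0.99],
    })
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.__dict__, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
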