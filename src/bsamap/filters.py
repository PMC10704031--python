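"""Candidate-SNP exclusion cascades for MutMap and QTL-seq designs.

A pooled genotype is called from its read counts by fixed index
thresholds; the cascades then drop, in a fixed and fully recorded order,
sites that cannot carry a recessive causal mutation: heterozygous in the
mutant-phenotype pool, congruent with the reference genome, or (in the
two-pool design) indistinguishable between the contrasting pool or the
distant parent and the mutant parent. Every excluded site records the
stage that excluded it, so stage-by-stage survivor counts are reportable.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "CallThresholds",
    "CandidateSet",
    "RegionBreakdown",
    "classify_pool_genotype",
    "classify_table",
    "mutmap_filter",
    "qtlseq_filter",
    "intersect_candidates",
    "summarize_regions",
]

_KEY = ["chrom", "pos", "ref", "alt"]


class GenotypeCall(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


@dataclass(frozen=True)
class CallThresholds:
    """Index thresholds converting pool counts to a genotype call.

    A pool is called homozygous-alternate at index >= ``hom_alt_min``,
    homozygous-reference at index <= ``hom_ref_max``, heterozygous in
    between, and missing below ``min_depth`` reads.
    """

    hom_alt_min: float = 0.9
    hom_ref_max: float = 0.1
    min_depth: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.hom_ref_max < self.hom_alt_min <= 1.0):
            raise ValueError("require 0 <= hom_ref_max < hom_alt_min <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def classify_pool_genotype(
    ref_count: int, alt_count: int, thresholds: CallThresholds = CallThresholds()
) -> GenotypeCall:
    """Call one pool's genotype at one site from its read counts."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_count + alt_count
    if depth < thresholds.min_depth:
        return GenotypeCall.MISSING
    index = alt_count / depth
    if index >= thresholds.hom_alt_min:
        return GenotypeCall.HOM_ALT
    if index <= thresholds.hom_ref_max:
        return GenotypeCall.HOM_REF
    return GenotypeCall.HET


def classify_table(
    counts: pd.DataFrame, thresholds: CallThresholds = CallThresholds()
) -> pd.DataFrame:
    """Vectorised genotype calls; adds a ``call`` column."""
    out = counts.copy()
    depth = out["ref_count"].to_numpy() + out["alt_count"].to_numpy()
    if (out["ref_count"] < 0).any() or (out["alt_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(depth > 0, out["alt_count"].to_numpy() / np.where(depth > 0, depth, 1), np.nan)
    call = np.full(len(out), GenotypeCall.HET, dtype=object)
    call[index >= thresholds.hom_alt_min] = GenotypeCall.HOM_ALT
    call[index <= thresholds.hom_ref_max] = GenotypeCall.HOM_REF
    call[depth < thresholds.min_depth] = GenotypeCall.MISSING
    out["call"] = call
    return out


@dataclass
class CandidateSet:
    """Variants with per-stage filter provenance.

    ``frame`` holds one row per input site keyed on (chrom, pos, ref, alt)
    with one boolean ``pass_<stage>`` column per cascade stage, a
    ``retained`` flag and ``excluded_by`` (name of the first failed stage,
    empty for retained sites). ``len()`` is the retained count — the
    cascade's survivor tally.
    """

    frame: pd.DataFrame
    stages: tuple[str, ...]

    def __len__(self) -> int:
        return int(self.frame["retained"].sum())

    @property
    def retained(self) -> pd.DataFrame:
        return self.frame[self.frame["retained"]].reset_index(drop=True)

    def keys(self) -> set[tuple]:
        return set(map(tuple, self.retained[_KEY].itertuples(index=False, name=None)))

    def stage_counts(self) -> dict[str, int]:
        """Survivors after each successive stage (the audit trail)."""
        alive = np.ones(len(self.frame), dtype=bool)
        out: dict[str, int] = {}
        for st in self.stages:
            alive &= self.frame[f"pass_{st}"].to_numpy(dtype=bool)
            out[st] = int(alive.sum())
        return out


def _assemble(frame: pd.DataFrame, stages: list[tuple[str, np.ndarray]]) -> CandidateSet:
    out = frame[_KEY].copy()
    alive = np.ones(len(out), dtype=bool)
    excluded_by = np.full(len(out), "", dtype=object)
    for name, mask in stages:
        mask = np.asarray(mask, dtype=bool)
        out[f"pass_{name}"] = mask
        newly = alive & ~mask
        excluded_by[newly] = name
        alive &= mask
    out["retained"] = alive
    out["excluded_by"] = excluded_by
    cs = CandidateSet(out, tuple(n for n, _ in stages))
    logger.info(
        "filter cascade: %d sites in, %d retained; survivors per stage: %s",
        len(out), len(cs), cs.stage_counts(),
    )
    return cs


def mutmap_filter(
    pool_counts: pd.DataFrame,
    thresholds: CallThresholds = CallThresholds(),
    restrict_to: tuple[str, int, int] | None = None,
) -> CandidateSet:
    """Single-pool (MutMap) cascade.

    Retains sites called homozygous-alternate in the mutant-phenotype pool:
    heterozygous sites, reference-congruent sites and depth-missing sites
    are excluded, optionally after restricting to a peak interval
    ``(chrom, start, end)``.
    """
    calls = classify_table(pool_counts, thresholds)
    call = calls["call"].to_numpy(dtype=object)
    stages: list[tuple[str, np.ndarray]] = []
    if restrict_to is not None:
        chrom, start, end = restrict_to
        in_region = (
            (calls["chrom"] == chrom) & (calls["pos"] >= start) & (calls["pos"] <= end)
        ).to_numpy()
        stages.append(("in_region", in_region))
    stages.append(("called", call != GenotypeCall.MISSING))
    stages.append(("not_heterozygous", call != GenotypeCall.HET))
    stages.append(("not_reference_congruent", call != GenotypeCall.HOM_REF))
    return _assemble(calls, stages)


def _calls_by_key(counts: pd.DataFrame, thresholds: CallThresholds) -> pd.DataFrame:
    t = classify_table(counts, thresholds)
    return t[_KEY + ["call"]]


def qtlseq_filter(
    sf_counts: pd.DataFrame,
    hl_counts: pd.DataFrame,
    mutant_parent_counts: pd.DataFrame,
    distant_parent_counts: pd.DataFrame,
    thresholds: CallThresholds = CallThresholds(),
) -> CandidateSet:
    """Two-pool (QTL-seq) cascade.

    Site universe is the SF (mutant-phenotype) pool. Stages, in order:
    the SF pool must be callable, not heterozygous and not
    reference-congruent (leaving homozygous-alternate sites); both parent
    calls must be available; the HL (contrasting) pool call must differ
    from the mutant parent's; and the distant parent's call must differ
    from the mutant parent's. Sites absent from a parent table are excluded
    at the parent-availability stage and counted in the log.
    """
    sf = classify_table(sf_counts, thresholds)
    hl = _calls_by_key(hl_counts, thresholds).rename(columns={"call": "call_hl"})
    mp = _calls_by_key(mutant_parent_counts, thresholds).rename(columns={"call": "call_mp"})
    dp = _calls_by_key(distant_parent_counts, thresholds).rename(columns={"call": "call_dp"})
    m = sf.rename(columns={"call": "call_sf"})
    for other in (hl, mp, dp):
        m = m.merge(other, on=_KEY, how="left")

    def col(name):
        return m[name].to_numpy(dtype=object)

    sf_call, hl_call, mp_call, dp_call = map(col, ["call_sf", "call_hl", "call_mp", "call_dp"])
    parent_present = pd.notna(m["call_mp"]).to_numpy() & pd.notna(m["call_dp"]).to_numpy()
    n_absent = int((~parent_present).sum())
    if n_absent:
        logger.warning("%d sites lacked a parent genotype call and were excluded", n_absent)

    def differs(a, b):
        # a difference can only be established when both calls exist and
        # neither is MISSING; calls compare by value (str-backed enum, and
        # pandas may have downcast them to plain strings)
        out = np.zeros(len(m), dtype=bool)
        for i, (x, y) in enumerate(zip(a, b)):
            if isinstance(x, str) and isinstance(y, str):
                out[i] = (
                    x != GenotypeCall.MISSING.value
                    and y != GenotypeCall.MISSING.value
                    and x != y
                )
        return out

    stages = [
        ("sf_called", sf_call != GenotypeCall.MISSING),
        ("sf_not_heterozygous", sf_call != GenotypeCall.HET),
        ("sf_not_reference_congruent", sf_call != GenotypeCall.HOM_REF),
        ("parent_calls_present", parent_present),
        ("hl_differs_from_mutant_parent", differs(hl_call, mp_call)),
        ("distant_parent_differs_from_mutant_parent", differs(dp_call, mp_call)),
    ]
    return _assemble(m, stages)


def intersect_candidates(
    set_a: CandidateSet, set_b: CandidateSet
) -> tuple[CandidateSet, CandidateSet, CandidateSet]:
    """Exact key intersection and differences of two retained sets."""
    ka, kb = set_a.keys(), set_b.keys()

    def subset(cs: CandidateSet, keys: set[tuple]) -> CandidateSet:
        r = cs.retained
        mask = [tuple(row) in keys for row in r[_KEY].itertuples(index=False, name=None)]
        f = r.loc[mask, _KEY].reset_index(drop=True).copy()
        f["retained"] = True
        f["excluded_by"] = ""
        return CandidateSet(f, ())

    return subset(set_a, ka & kb), subset(set_a, ka - kb), subset(set_b, kb - ka)


@dataclass(frozen=True)
class RegionBreakdown:
    """Counts of candidate variants by genic-region class."""

    exon: int = 0
    intron: int = 0
    upstream: int = 0
    downstream: int = 0
    intergenic: int = 0

    @property
    def total(self) -> int:
        return self.exon + self.intron + self.upstream + self.downstream + self.intergenic


def summarize_regions(
    candidates: CandidateSet, annotations: Mapping[tuple, "object"]
) -> RegionBreakdown:
    """Tally retained candidates by region class.

    ``annotations`` maps (chrom, pos, ref, alt) keys to objects with a
    ``region`` attribute (see :mod:`bsamap.effects`). Every retained
    candidate must be annotated.
    """
    counter: Counter[str] = Counter()
    for key in map(tuple, candidates.retained[_KEY].itertuples(index=False, name=None)):
        if key not in annotations:
            raise KeyError(f"candidate {key} has no region annotation")
        counter[annotations[key].region] += 1
    bd = RegionBreakdown(**{k: counter.get(k, 0) for k in
                            ("exon", "intron", "upstream", "downstream", "intergenic")})
    assert bd.total == len(candidates)
    return bd
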