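"""Segregation chi-square tests, marker co-segregation and 2^-ddCt.

The chi-square here is the 1-degree-of-freedom goodness-of-fit test of a
two-class segregation count against a Mendelian ratio, with or without
the Yates continuity correction, judged against the printed critical
value 3.84 (alpha = 0.05, df = 1). Co-segregation asks whether every
recessive-phenotype individual is homozygous for the marker's mutant
allele. Relative expression uses the standard 2^-ddCt quantification
against a reference gene and control condition.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

from .filters import GenotypeCall

__all__ = [
    "SegregationResult",
    "CosegResult",
    "ExpressionResult",
    "segregation_chi_square",
    "cosegregation_test",
    "ddct_fold_change",
    "CHI2_CRITICAL_5PCT_DF1",
]

#: upper 5% point of chi-square with one degree of freedom
CHI2_CRITICAL_5PCT_DF1 = 3.84


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, int]
    expected: tuple[float, float]
    expected_ratio: tuple[float, float]
    chi_square: float
    df: int
    correction: str
    ratio_text: str
    passes: bool

    def summary(self) -> str:
        return (
            f"observed {self.observed[0]}:{self.observed[1]} "
            f"(ratio {self.ratio_text}), expected {self.expected_ratio[0]:g}:"
            f"{self.expected_ratio[1]:g}, chi2={self.chi_square:.2f} "
            f"({self.correction}), {'consistent' if self.passes else 'rejected'} "
            f"at the 5% level (critical {CHI2_CRITICAL_5PCT_DF1})"
        )


def segregation_chi_square(
    observed: tuple[int, int],
    expected_ratio: tuple[float, float],
    correction: str = "none",
    critical: float = CHI2_CRITICAL_5PCT_DF1,
) -> SegregationResult:
    """Two-class segregation test against an a:b Mendelian ratio.

    ``correction='yates'`` applies the continuity correction
    (|O-E| - 0.5)^2 / E. ``passes`` is True when the statistic falls below
    the critical value, i.e. the counts are consistent with the ratio.
    """
    o1, o2 = observed
    a, b = expected_ratio
    if o1 < 0 or o2 < 0:
        raise ValueError("observed counts must be non-negative")
    total = o1 + o2
    if total <= 0:
        raise ValueError("total count must be positive")
    if a <= 0 or b <= 0:
        raise ValueError("expected ratio parts must be positive")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    e1 = total * a / (a + b)
    e2 = total * b / (a + b)
    if e1 == 0 or e2 == 0:
        raise ValueError("zero expected count")
    if correction == "yates":
        stat = sum((abs(o - e) - 0.5) ** 2 / e for o, e in ((o1, e1), (o2, e2)))
    else:
        stat = sum((o - e) ** 2 / e for o, e in ((o1, e1), (o2, e2)))
    ratio_text = f"{o1 / o2:.2f}:1" if o2 > 0 else ""
    return SegregationResult(
        observed=(o1, o2),
        expected=(e1, e2),
        expected_ratio=(float(a), float(b)),
        chi_square=float(stat),
        df=1,
        correction=correction,
        ratio_text=ratio_text,
        passes=stat < critical,
    )


@dataclass(frozen=True)
class CosegResult:
    n_tested: int
    n_discordant: int
    n_missing: int
    co_segregates: bool

    def summary(self) -> str:
        return (
            f"{self.n_tested} mutant-phenotype individuals tested, "
            f"{self.n_discordant} discordant, {self.n_missing} missing calls: "
            f"marker {'co-segregates' if self.co_segregates else 'does not co-segregate'}"
        )


def cosegregation_test(
    marker_genotypes: Sequence[GenotypeCall],
    phenotypes: Sequence[str],
    mutant_allele_call: GenotypeCall = GenotypeCall.HOM_ALT,
    mutant_phenotype: str = "mutant",
) -> CosegResult:
    """Marker-phenotype co-segregation over a recessive-phenotype panel.

    Counts phenotyped mutants whose marker call differs from
    ``mutant_allele_call``; the marker co-segregates iff none do. Missing
    calls among mutants are tallied separately and excluded from
    ``n_tested``.
    """
    if len(marker_genotypes) != len(phenotypes):
        raise ValueError(
            f"{len(marker_genotypes)} genotypes vs {len(phenotypes)} phenotypes"
        )
    n_tested = n_discordant = n_missing = 0
    for call, phen in zip(marker_genotypes, phenotypes):
        if phen != mutant_phenotype:
            continue
        if call == GenotypeCall.MISSING:
            n_missing += 1
            continue
        n_tested += 1
        if call != mutant_allele_call:
            n_discordant += 1
    return CosegResult(n_tested, n_discordant, n_missing, n_discordant == 0)


@dataclass(frozen=True)
class ExpressionResult:
    delta_delta_ct: float
    fold_change: float


def ddct_fold_change(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> ExpressionResult:
    """Relative expression by 2^-ddCt against a reference gene and control."""
    for v in (ct_target_sample, ct_reference_sample, ct_target_control, ct_reference_control):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_reference_sample) - (
        ct_target_control - ct_reference_control
    )
    return ExpressionResult(ddct, 2.0 ** (-ddct))
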