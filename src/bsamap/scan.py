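"""SNP-index and delta-SNP-index scans with Monte-Carlo confidence bands.

The SNP-index of a pool at a biallelic site is the fraction of reads
carrying the alternate allele, ``alt / (ref + alt)``; in a bulk of F2
individuals selected for a recessive phenotype it approaches 1 at the
causal locus and 0.5 at unlinked loci. The delta-SNP-index is the
difference of the indexes of two contrasting pools. Both statistics are
smoothed by a sliding-window mean, and significance is judged against
depth-conditional null bands obtained by simulating unselected pools.

Two statsmodels-style entry points wrap the functional layer:
:class:`MutMapScan` (single mutant-phenotype pool) and :class:`QTLSeqScan`
(two contrasting pools); their ``fit()`` returns a :class:`BSAScanResults`
carrying the per-site records, window fits, null band and peak calls.
"""

from __future__ import annotations

import textwrap
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "snp_index",
    "delta_snp_index",
    "index_table",
    "delta_table",
    "sliding_window_fit",
    "CIBand",
    "simulate_ci",
    "simulate_ci_grid",
    "nearest_band",
    "call_peak_regions",
    "MutMapScan",
    "QTLSeqScan",
    "BSAScanResults",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
    "DEFAULT_MIN_SITES",
    "DEFAULT_MIN_DEPTH",
]

#: defaults for the window fit; the statistic's scale, not the data, sets them
DEFAULT_WINDOW = 2_000_000
DEFAULT_STEP = 50_000
DEFAULT_MIN_SITES = 10
DEFAULT_MIN_DEPTH = 8

_KEY = ["chrom", "pos", "ref", "alt"]


def snp_index(ref_count, alt_count, min_depth: int = DEFAULT_MIN_DEPTH):
    """Alternate-allele read fraction, or NaN below the depth floor.

    Accepts scalars or arrays. Sites with ``ref + alt < min_depth`` are
    reported missing (NaN) rather than as unstable low-depth ratios.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(depth >= min_depth, alt / np.where(depth > 0, depth, 1), np.nan)
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(idx)
    return idx


def delta_snp_index(index_high, index_low):
    """Difference of two pool indexes; missing (NaN) propagates."""
    return np.subtract(index_high, index_low)


def index_table(counts: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-site SNP-index records from a tidy counts table (one pool)."""
    out = counts.copy()
    out["depth"] = out["ref_count"] + out["alt_count"]
    out["index"] = snp_index(
        out["ref_count"].to_numpy(), out["alt_count"].to_numpy(), min_depth
    )
    return out


def delta_table(
    counts_high: pd.DataFrame,
    counts_low: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per-site delta records: high-pool index minus low-pool index.

    Sites are matched on (chrom, pos, ref, alt); a site missing from either
    pool, or below the depth floor in either, yields a missing delta.
    """
    hi = index_table(counts_high, min_depth)[_KEY + ["index", "depth"]]
    lo = index_table(counts_low, min_depth)[_KEY + ["index", "depth"]]
    merged = hi.merge(lo, on=_KEY, how="outer", suffixes=("_high", "_low"))
    merged["delta"] = delta_snp_index(
        merged["index_high"].to_numpy(), merged["index_low"].to_numpy()
    )
    return merged.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def sliding_window_fit(
    records: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
    value_col: str = "index",
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean of a per-site statistic in tiling windows.

    Windows on each chromosome are ``[k*step + 1, k*step + window_size]``
    for k = 0, 1, ...; the mean is taken over non-missing sites whose
    position falls in the window, and windows holding fewer than
    ``min_sites`` such sites are reported missing. Chromosome extent is
    taken from ``chrom_lengths`` when given, else from the last site.
    """
    if not (window_size >= step > 0):
        raise ValueError("require window_size >= step > 0")
    frames = []
    if records.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "mean"])
    for chrom, sub in records.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        val = sub[value_col].to_numpy(dtype=float)
        ok = ~np.isnan(val)
        # prefix sums -> O(1) per window
        cn = np.concatenate([[0], np.cumsum(ok)])
        cv = np.concatenate([[0.0], np.cumsum(np.where(ok, val, 0.0))])
        extent = (chrom_lengths or {}).get(chrom, int(pos.max()))
        n_win = max(1, int(np.ceil(extent / step)))
        starts = np.arange(n_win, dtype=np.int64) * step + 1
        ends = starts + window_size - 1
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = cn[hi] - cn[lo]
        s = cv[hi] - cv[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n >= min_sites, s / np.where(n > 0, n, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "n_sites": n, "mean": mean}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CIBand:
    """Empirical null band for a pooled-sequencing statistic.

    ``bounds`` maps confidence level (e.g. 0.95) to (lower, upper) empirical
    quantiles of the simulated null statistic at the stated depth and pool
    size(s). Bands at higher levels contain those at lower levels, and bands
    widen as depth falls.
    """

    design: str
    depth: int
    pool_sizes: tuple[int, ...]
    n_reps: int
    bounds: dict[float, tuple[float, float]]

    def lower(self, level: float) -> float:
        return self.bounds[level][0]

    def upper(self, level: float) -> float:
        return self.bounds[level][1]

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted(self.bounds))


def _null_index(
    rng: np.random.Generator, pool_size: int, depth: int, n_reps: int
) -> np.ndarray:
    # unselected F2 genotypes are 1:2:1, i.e. per-individual alt dosage is
    # Binomial(2, 1/2); the pool's alt haplotype count is Binomial(2n, 1/2)
    alt_haps = rng.binomial(2 * pool_size, 0.5, size=n_reps)
    f = alt_haps / (2.0 * pool_size)
    return rng.binomial(depth, f) / depth


def simulate_ci(
    design: str,
    pool_sizes: Sequence[int],
    depth: int,
    n_reps: int = 10_000,
    levels: Sequence[float] = (0.95, 0.99),
    seed: int | None = None,
) -> CIBand:
    """Monte-Carlo null band for the no-linkage hypothesis.

    ``design='mutmap'`` simulates the SNP-index of one unselected pool;
    ``design='qtlseq'`` the delta-SNP-index of two independent unselected
    pools. Pool genotypes are drawn from the 1:2:1 F2 distribution, reads
    binomially at the given depth; the band is the (a/2, 1-a/2) empirical
    quantile pair with linear interpolation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if design == "mutmap":
        (n1,) = pool_sizes
        stat = _null_index(rng, n1, depth, n_reps)
    elif design == "qtlseq":
        n1, n2 = pool_sizes
        stat = _null_index(rng, n1, depth, n_reps) - _null_index(rng, n2, depth, n_reps)
    else:
        raise ValueError(f"unknown design {design!r}; expected 'mutmap' or 'qtlseq'")
    bounds = {}
    for lv in levels:
        a = 1.0 - lv
        lo, hi = np.quantile(stat, [a / 2.0, 1.0 - a / 2.0])
        bounds[float(lv)] = (float(lo), float(hi))
    return CIBand(design, int(depth), tuple(int(n) for n in pool_sizes), n_reps, bounds)


def simulate_ci_grid(
    design: str,
    pool_sizes: Sequence[int],
    depths: Sequence[int],
    n_reps: int = 10_000,
    levels: Sequence[float] = (0.95, 0.99),
    seed: int | None = None,
) -> dict[int, CIBand]:
    """Bands on a grid of depths; match a site via :func:`nearest_band`."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(depths))
    return {
        int(d): simulate_ci(design, pool_sizes, int(d), n_reps, levels,
                            np.random.default_rng(child))
        for d, child in zip(depths, children)
    }


def nearest_band(grid: dict[int, CIBand], depth: float) -> CIBand:
    """The band whose grid depth is closest to ``depth`` (ties: lower depth)."""
    if not grid:
        raise ValueError("empty band grid")
    best = min(grid, key=lambda d: (abs(d - depth), d))
    return grid[best]


def call_peak_regions(
    windows: pd.DataFrame, band: CIBand, level: float = 0.99
) -> pd.DataFrame:
    """Maximal runs of windows above the band's upper bound.

    Consecutive qualifying windows on a chromosome are merged (windows
    overlap whenever step <= window size) into intervals reported with
    their peak window statistic.
    """
    thr = band.upper(level)
    out = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub[sub["mean"] > thr].sort_values("start", kind="stable")
        run_start = prev_end = None
        peak = -np.inf
        for start, end, mean in zip(sub["start"], sub["end"], sub["mean"]):
            if run_start is not None and start <= prev_end + 1:
                prev_end = max(prev_end, end)
                peak = max(peak, mean)
            else:
                if run_start is not None:
                    out.append((chrom, run_start, prev_end, peak))
                run_start, prev_end, peak = start, end, mean
        if run_start is not None:
            out.append((chrom, run_start, prev_end, peak))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "peak_value"])


class _BaseScan:
    """Shared fitting machinery for the two scan designs."""

    design: str
    value_col: str

    def fit(
        self,
        window_size: int = DEFAULT_WINDOW,
        step: int = DEFAULT_STEP,
        min_sites: int = DEFAULT_MIN_SITES,
        n_reps: int = 10_000,
        levels: Sequence[float] = (0.95, 0.99),
        seed: int | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ) -> "BSAScanResults":
        records = self._records()
        windows = sliding_window_fit(
            records, window_size, step, min_sites,
            value_col=self.value_col, chrom_lengths=chrom_lengths,
        )
        depth = int(round(float(np.nanmedian(self._depths(records))))) or 1
        band = simulate_ci(self.design, self.pool_sizes, depth, n_reps, levels, seed)
        return BSAScanResults(self, records, windows, band)

    def _records(self) -> pd.DataFrame:  # pragma: no cover - abstract
        raise NotImplementedError

    def _depths(self, records: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MutMapScan(_BaseScan):
    """Single-pool scan: SNP-index of a recessive-phenotype F2 bulk.

    Parameters
    ----------
    counts
        Tidy counts table (``chrom,pos,ref,alt,pool,ref_count,alt_count``).
    pool
        Name of the mutant-phenotype pool within ``counts``.
    pool_size
        Number of individuals bulked — sets the null-band simulation.
    min_depth
        Depth floor below which a site's index is missing.
    """

    design = "mutmap"
    value_col = "index"

    def __init__(self, counts: pd.DataFrame, pool: str, pool_size: int,
                 min_depth: int = DEFAULT_MIN_DEPTH):
        self.counts = counts[counts["pool"] == pool].reset_index(drop=True)
        if self.counts.empty:
            raise ValueError(f"no counts for pool {pool!r}")
        self.pool = pool
        self.pool_sizes = (int(pool_size),)
        self.min_depth = min_depth

    def _records(self) -> pd.DataFrame:
        return index_table(self.counts, self.min_depth)

    def _depths(self, records: pd.DataFrame) -> np.ndarray:
        return records["depth"].to_numpy(dtype=float)


class QTLSeqScan(_BaseScan):
    """Two-pool scan: delta-SNP-index between contrasting F2 bulks."""

    design = "qtlseq"
    value_col = "delta"

    def __init__(self, counts: pd.DataFrame, high_pool: str, low_pool: str,
                 pool_sizes: tuple[int, int], min_depth: int = DEFAULT_MIN_DEPTH):
        self.high = counts[counts["pool"] == high_pool].reset_index(drop=True)
        self.low = counts[counts["pool"] == low_pool].reset_index(drop=True)
        if self.high.empty or self.low.empty:
            raise ValueError("both pools must be present in the counts table")
        self.high_pool, self.low_pool = high_pool, low_pool
        self.pool_sizes = (int(pool_sizes[0]), int(pool_sizes[1]))
        self.min_depth = min_depth

    def _records(self) -> pd.DataFrame:
        return delta_table(self.high, self.low, self.min_depth)

    def _depths(self, records: pd.DataFrame) -> np.ndarray:
        d = np.minimum(
            records["depth_high"].to_numpy(dtype=float),
            records["depth_low"].to_numpy(dtype=float),
        )
        return d


@dataclass
class BSAScanResults:
    """Fitted scan: per-site records, window means, null band, peaks."""

    model: _BaseScan
    records: pd.DataFrame
    windows: pd.DataFrame
    band: CIBand

    def peak_regions(self, level: float = 0.99) -> pd.DataFrame:
        return call_peak_regions(self.windows, self.band, level)

    def summary(self) -> str:
        n_sites = len(self.records)
        n_used = int((~np.isnan(self.records[self.model.value_col])).sum())
        lines = [
            f"BSA scan ({self.band.design} design)",
            f"  sites: {n_sites} ({n_used} with a valid statistic)",
            f"  pool size(s): {self.band.pool_sizes}, band depth {self.band.depth}x, "
            f"{self.band.n_reps} null reps",
        ]
        for lv in self.band.levels:
            lo, hi = self.band.bounds[lv]
            lines.append(f"  {lv:.0%} band: [{lo:+.3f}, {hi:+.3f}]")
        for lv in self.band.levels:
            peaks = self.peak_regions(lv)
            if peaks.empty:
                lines.append(f"  peaks > {lv:.0%} band: none")
            else:
                for _, r in peaks.iterrows():
                    lines.append(
                        f"  peak > {lv:.0%} band: {r.chrom}:{int(r.start)}-{int(r.end)}"
                        f" (max {r.peak_value:.3f})"
                    )
        return "\n".join(lines)

    def plot(self, ax=None, level: float = 0.99):
        """Manhattan-style plot: per-site statistic, window fit and band."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(9, 3))
        col = self.model.value_col
        offset = 0
        ticks, labels = [], []
        for chrom, sub in self.records.groupby("chrom", sort=False):
            x = sub["pos"].to_numpy() + offset
            ax.plot(x, sub[col], ".", ms=2, alpha=0.5)
            wsub = self.windows[self.windows["chrom"] == chrom]
            wx = (wsub["start"] + wsub["end"]).to_numpy() / 2 + offset
            ax.plot(wx, wsub["mean"], "-", lw=1.5, color="black")
            ticks.append(offset + sub["pos"].max() / 2)
            labels.append(chrom)
            offset += int(sub["pos"].max()) + 1
        for lv, colr in zip(self.band.levels, ("tab:blue", "tab:red")):
            ax.axhline(self.band.upper(lv), color=colr, ls="--", lw=1)
            if self.band.design == "qtlseq":
                ax.axhline(self.band.lower(lv), color=colr, ls="--", lw=1)
        ax.set_xticks(ticks, labels)
        ax.set_ylabel("SNP-index" if col == "index" else "ΔSNP-index")
        return ax
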