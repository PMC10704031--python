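"""Scenario runner: one config in, a full simulated experiment out.

Simulates both mapping designs from a single EMS line: the single-pool
(MutMap-style) cross of the mutant to its own progenitor line, and the
two-pool (QTL-seq-style) cross to a distant accession, with
phenotype-selected pools and pooled sequencing of pools and parents.
Pool names in the emitted counts tables: ``WT``, ``sip``, ``AC``,
``F2dw_pool`` (28 mutants), ``SF_pool`` (45 mutants), ``HL_pool``
(50 wild types) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import simulate as sim
from .io import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["ScenarioResult", "run_scenario"]


@dataclass
class ScenarioResult:
    """Everything a downstream analysis or a recovery test needs."""

    config: RunConfig
    genome: sim.GenomeSpec
    sites: list[sim.VariantSite]
    causal: sim.VariantSite
    mutmap_population: list[sim.F2Individual]
    qtlseq_population: list[sim.F2Individual]
    pools: dict[str, sim.Pool]
    counts: pd.DataFrame


def _genome_from_config(cfg: RunConfig) -> sim.GenomeSpec:
    chroms = tuple((c["name"], c["length"]) for c in cfg.genome["chromosomes"])
    return sim.GenomeSpec(chroms, cfg.genome.get("recombination_rate", 2.5))


def run_scenario(cfg: RunConfig, outdir: str | Path | None = None) -> ScenarioResult:
    """Simulate the full dual-design experiment described by ``cfg``.

    When ``outdir`` is given, writes ``counts.tsv``, ``counts.vcf``,
    ``truth_sites.tsv``, per-population genotype matrices and a verbatim
    echo of the configuration. Identical (config, seed) reproduce every
    output bitwise.
    """
    genome = _genome_from_config(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    (s_ems, s_f2m, s_f2q, s_poolm, s_poolsf, s_poolhl,
     s_cm, s_csf, s_chl, s_cwt, s_csip, s_cac) = ss.spawn(12)

    causal = (cfg.ems["causal"]["chrom"], cfg.ems["causal"]["pos"])
    sites, sip = sim.simulate_ems_line(
        genome,
        n_background=cfg.ems["n_background"],
        ems_transition_fraction=cfg.ems["transition_fraction"],
        causal_chrom_pos=causal,
        seed=s_ems,
        name="sip",
    )
    wt = sim.reference_line("WT", sites)
    ac = sim.reference_line("AC", sites)

    pop_m = sim.simulate_f2(wt, sip, cfg.populations["mutmap_f2_size"], genome, s_f2m)
    pop_q = sim.simulate_f2(ac, sip, cfg.populations["qtlseq_f2_size"], genome, s_f2q)

    pools = {
        "F2dw_pool": sim.select_pool(
            pop_m, sim.MUTANT, cfg.pools["mutmap_mutant"], s_poolm, name="F2dw_pool"
        ),
        "SF_pool": sim.select_pool(
            pop_q, sim.MUTANT, cfg.pools["qtlseq_mutant"], s_poolsf, name="SF_pool"
        ),
        "HL_pool": sim.select_pool(
            pop_q, sim.WILDTYPE, cfg.pools["qtlseq_wildtype"], s_poolhl, name="HL_pool"
        ),
    }

    err = cfg.error_rate
    counts = pd.concat(
        [
            sim.simulate_pool_counts(
                pools["F2dw_pool"], pop_m, sites, cfg.depths["mutmap_pool"], err, s_cm
            ),
            sim.simulate_pool_counts(
                pools["SF_pool"], pop_q, sites, cfg.depths["qtlseq_pool"], err, s_csf
            ),
            sim.simulate_pool_counts(
                pools["HL_pool"], pop_q, sites, cfg.depths["qtlseq_pool"], err, s_chl
            ),
            sim.simulate_parent_counts(wt, cfg.depths["mutmap_parent"], err, s_cwt),
            sim.simulate_parent_counts(sip, cfg.depths["mutmap_parent"], err, s_csip),
            sim.simulate_parent_counts(ac, cfg.depths["qtlseq_parent"], err, s_cac),
        ],
        ignore_index=True,
    )

    result = ScenarioResult(
        config=cfg,
        genome=genome,
        sites=sites,
        causal=sites[sim.causal_index(sites)],
        mutmap_population=pop_m,
        qtlseq_population=pop_q,
        pools=pools,
        counts=counts,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bio.write_counts_tsv(counts, outdir / "counts.tsv")
        bio.write_counts_vcf(
            counts, outdir / "counts.vcf",
            contig_lengths=dict(genome.chromosomes),
        )
        bio.write_truth_sites(sites, outdir / "truth_sites.tsv")
        bio.write_genotypes(pop_m, sites, outdir / "genotypes_mutmap.tsv")
        bio.write_genotypes(pop_q, sites, outdir / "genotypes_qtlseq.tsv")
        cfg.to_yaml(outdir / "config.yaml")
        logger.info(
            "scenario written to %s (seed=%s, config=%s): %d sites, pools %s",
            outdir, cfg.seed, cfg.hash(),
            len(sites), {k: p.size for k, p in pools.items()},
        )
    return result
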