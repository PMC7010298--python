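"""Simulation-based power estimation for genome-wide QTL detection.

Estimates the probability that a single additive QTL of a given effect size
(fraction of trait variance) is detected at genome-wide permutation
significance in a CC-like panel: each replicate simulates a fresh 47-strain
8-founder mosaic genome, plants one QTL at a random locus with the exact
in-sample effect size, RINTs the trait, scans it, builds a genome-wide
permutation/GEV null, and scores a detection when the scan peak reaches
permP_G below the threshold and lies near the planted locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import GEVNull, permutation_orderings
from .scan import ScanEngine
from .synthetic_data import (QTLPlant, SimConfig, TraitSpec, assign_batches,
                             simulate_founder_mosaics, simulate_trait_panel)
from .trait_prep import rank_inverse_normal


@dataclass
class PowerResult:
    power: float
    n_replicates: int
    n_detected: int
    effect_size: float
    alpha: float


def genome_wide_power(effect_size: float = 0.55, n_replicates: int = 100,
                      n_perm: int = 200, alpha: float = 0.05,
                      proximity_bp: float = 5e6, seed: int = 1,
                      config: SimConfig | None = None,
                      use_batch: bool = True) -> PowerResult:
    """Monte-Carlo power of genome-wide QTL detection at one effect size.

    A replicate counts as a detection when the genome-wide scan peak has
    ``permP_G < alpha`` (GEV fitted to ``n_perm`` permutation maxima) and
    lies within ``proximity_bp`` of the planted locus on its chromosome.
    """
    base = config or SimConfig()
    reps = np.random.SeedSequence([seed, 808]).spawn(n_replicates)
    hits = 0
    for rep_ss in reps:
        s = int(rep_ss.generate_state(1)[0] % 2**31)
        cfg = SimConfig(n_strains=base.n_strains, chromosomes=base.chromosomes,
                        mean_block_length=base.mean_block_length,
                        batch_levels=base.batch_levels, batch_sd=base.batch_sd,
                        seed=s)
        fdm = simulate_founder_mosaics(cfg)
        batch = assign_batches(cfg.n_strains, cfg.batch_levels, s) if use_batch else None
        rng = np.random.default_rng(np.random.SeedSequence([s, 809]))
        planted_iloc = int(rng.integers(fdm.n_loci))
        lid = str(fdm.locus_map["locus_id"].iloc[planted_iloc])
        panel, _ = simulate_trait_panel(
            fdm, [TraitSpec("t", [QTLPlant(lid, effect_size=effect_size)])],
            batch=batch, seed=s, batch_sd=cfg.batch_sd)
        y = rank_inverse_normal(panel.y("t"))
        engine = ScanEngine(fdm, batch=batch)
        logp = engine.logp_matrix(y[:, None])[:, 0]
        peak = int(np.argmax(logp))
        orderings = permutation_orderings(cfg.n_strains, n_perm, s)
        maxima = engine.permutation_maxima(
            y, orderings, {"G": np.arange(fdm.n_loci)})["G"]
        null = GEVNull.fit(maxima, scope="genome")
        permp = null.permp(float(logp[peak]))
        prow = fdm.locus_map.iloc[peak]
        trow = fdm.locus_map.iloc[planted_iloc]
        near = (str(prow["chrom"]) == str(trow["chrom"])
                and abs(float(prow["pos_bp"]) - float(trow["pos_bp"])) <= proximity_bp)
        if permp < alpha and near:
            hits += 1
    return PowerResult(hits / n_replicates, n_replicates, hits, effect_size, alpha)
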