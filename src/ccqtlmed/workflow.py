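"""End-to-end pipeline: simulate -> prep -> scan/detect -> pair -> mediate.

One structured configuration drives the run; every stage writes TSV/JSON
outputs plus a manifest with seeds, package versions, and content hashes so
a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import analysis_C, analysis_G, analysis_L, calls_to_frame, permutation_orderings
from .crosstissue import classify_pairs, pair_qtl, pairs_to_frame
from .mediation import call_mediators, mediation_null, mediation_scan, records_to_frame
from .scan import ScanEngine
from .synthetic_data import (QTLPlant, SimConfig, TraitSpec, assign_batches,
                             simulate_founder_mosaics, simulate_trait_panel)
from .trait_prep import rint_matrix


@dataclass
class RunConfig:
    """Configuration of a full simulated run."""

    sim: SimConfig = field(default_factory=SimConfig)
    tissues: tuple[str, ...] = ("tissueA",)
    n_null_traits: int = 10
    n_qtl_traits: int = 10
    effect_size: float = 0.5
    shared_effects: bool = True  # same planted beta in every tissue
    analyses: tuple[str, ...] = ("L", "C", "G")
    fdr: float = 0.1
    n_perm: int = 200
    local_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, v in (("fdr", self.fdr), ("local_alpha", self.local_alpha)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("need >= 100 permutations for GEV fitting")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "chromosomes" in sim_raw:
            sim_raw["chromosomes"] = tuple(tuple(c) for c in sim_raw["chromosomes"])
        cfg = cls(sim=SimConfig(**sim_raw), **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the configured pipeline and write all stage outputs to ``outdir``."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))

    fdm = simulate_founder_mosaics(config.sim)
    fdm.to_tsv(out / "dosages.tsv", out / "locus_map.tsv")
    batch = assign_batches(fdm.n_strains, config.sim.batch_levels, config.sim.seed)
    pd.DataFrame({"strain": fdm.strains, "batch": batch}).to_csv(
        out / "batches.tsv", sep="\t", index=False)

    # one trait panel per tissue; planted QTL shared or tissue-specific
    locus_ids = fdm.locus_map["locus_id"].to_numpy()
    qtl_loci = rng.choice(locus_ids, size=config.n_qtl_traits, replace=False)
    shared_betas = rng.normal(size=(config.n_qtl_traits, 8))
    engines = {}
    calls_by_tissue = {}
    truth_all = {}
    orderings = permutation_orderings(fdm.n_strains, config.n_perm, config.seed)
    for t_i, tissue in enumerate(config.tissues):
        specs = [TraitSpec(f"null_{j:03d}") for j in range(config.n_null_traits)]
        for j, lid in enumerate(qtl_loci):
            beta = shared_betas[j] if config.shared_effects else None
            specs.append(TraitSpec(
                f"qtl_{j:03d}",
                [QTLPlant(str(lid), effect_size=config.effect_size,
                          beta=beta if beta is not None else None)]))
        panel, truth = simulate_trait_panel(
            fdm, specs, batch=batch, seed=config.seed * 1000 + t_i,
            batch_sd=config.sim.batch_sd)
        truth_all[tissue] = truth
        panel = rint_matrix(panel)
        panel.to_tsv(out / f"traits_{tissue}.tsv", out / f"annotations_{tissue}.tsv")
        engine = ScanEngine(fdm, batch=batch)
        engines[tissue] = engine
        tissue_calls = []
        if "L" in config.analyses:
            for tid in panel.trait_ids:
                call = analysis_L(panel.y(tid), engine, panel.anchor(tid),
                                  orderings, alpha=config.local_alpha,
                                  trait_id=tid, tissue=tissue,
                                  fdm=fdm, batch=batch)
                if call is not None:
                    tissue_calls.append(call)
        if "C" in config.analyses:
            tissue_calls += analysis_C(panel, engine, orderings, fdr=config.fdr,
                                       tissue=tissue, fdm=fdm, batch=batch)
        if "G" in config.analyses:
            tissue_calls += analysis_G(panel, fdm, orderings, batch=batch,
                                       fdr=config.fdr, tissue=tissue)
        calls_by_tissue[tissue] = tissue_calls
        calls_to_frame(tissue_calls).to_csv(out / f"qtl_calls_{tissue}.tsv",
                                            sep="\t", index=False)
        truth.to_json(out / f"truth_{tissue}.json")

    if len(config.tissues) > 1:
        pairs = classify_pairs(pair_qtl(calls_by_tissue), fdr=config.fdr)
        pairs_to_frame(pairs).to_csv(out / "qtl_pairs.tsv", sep="\t", index=False)

    summary = _summarize(calls_by_tissue, truth_all)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    manifest = {
        "package": "ccqtlmed",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_perm": config.n_perm,
        "stages": ["simulate", "prep", "detect"]
                  + (["pair"] if len(config.tissues) > 1 else []),
        "files": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _summarize(calls_by_tissue, truth_all) -> pd.DataFrame:
    rows = []
    for tissue, calls in calls_by_tissue.items():
        truth = truth_all[tissue]
        planted = {(q["trait_id"], q["locus_id"]) for q in truth.qtl}
        planted_traits = {t for t, _ in planted}
        for analysis in ("L", "C", "G"):
            det = [c for c in calls if c.analysis == analysis and c.detected]
            hits = {c.trait_id for c in det} & planted_traits
            false = [c for c in det if c.trait_id not in planted_traits]
            rows.append({
                "tissue": tissue, "analysis": analysis,
                "n_detected": len(det),
                "n_planted_recovered": len(hits),
                "n_planted": len(planted_traits),
                "n_false_traits": len(false),
            })
    return pd.DataFrame(rows)
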