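"""Synthetic Collaborative-Cross-like genomes and molecular traits.

Every downstream stage (scans, permutation thresholds, BLUPs, cross-tissue
pairing, mediation) is exercised against data with known ground truth.  The
generator emulates the salient features of a recombinant-inbred 8-founder
panel: homozygous founder mosaics with exponentially distributed block
lengths, planted local/distal QTL of exact in-sample effect size, a 5-level
batch factor, cross-tissue shared vs tissue-specific effects, mediation
chains (QTL -> mediator -> outcome), low-signal traits, and single-point
outliers.  It does not attempt realistic CC ancestry, recombination maps,
heterozygosity, or sex effects.

All randomness flows from one integer seed through ``numpy`` seed sequences;
the planted truth is recorded in a :class:`TruthTable`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .haplotypes import FOUNDERS, N_FOUNDERS, FounderDosageMatrix
from .trait_prep import TraitMatrix

#: default genome: 20 chromosomes x 100 Mb x 100 loci (~2,000 tests)
DEFAULT_CHROMOSOMES: tuple[tuple[str, float, int], ...] = tuple(
    (str(i + 1), 100.0, 100) for i in range(20)
)


@dataclass
class SimConfig:
    """Study-design constants for the simulated panel.

    One mouse per strain (47 strains by default), five sequencing batches,
    8-founder mosaics with mean haplotype block length 16.3 Mb.
    """

    n_strains: int = 47
    chromosomes: tuple[tuple[str, float, int], ...] = DEFAULT_CHROMOSOMES
    mean_block_length: float = 16.3  # Mb
    batch_levels: int = 5
    batch_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        if self.mean_block_length <= 0:
            raise ValueError("mean block length must be positive")
        for name, length, n_loci in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")
            if n_loci < 1:
                raise ValueError(f"chromosome {name}: need at least 1 locus")
        if self.batch_levels < 1:
            raise ValueError("need at least one batch level")


@dataclass
class QTLPlant:
    """One planted QTL: a locus and either a target variance fraction or a beta."""

    locus_id: str
    effect_size: float | None = None
    beta: np.ndarray | None = None


@dataclass
class TraitSpec:
    """Specification of one simulated trait (possibly multiple QTL, or none)."""

    trait_id: str
    qtl: list[QTLPlant] = field(default_factory=list)
    cls: str = "gene"
    anchor_chrom: str | None = None
    anchor_bp: float | None = None


@dataclass
class TruthTable:
    """Ground truth of a simulation: planted QTL, mediation edges, outliers."""

    qtl: list[dict] = field(default_factory=list)
    mediation: list[dict] = field(default_factory=list)
    outliers: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=default)


# -------------------------------------------------------------------- genomes

def simulate_founder_mosaics(config: SimConfig) -> FounderDosageMatrix:
    """Simulate fully inbred founder mosaics and their dosages at map loci.

    Haplotype block lengths follow Exponential(mean_block_length) along each
    chromosome, with the founder of each block drawn uniformly from the eight;
    loci are evenly spaced and carry the one-hot-times-two dosage of the
    founder whose block covers them.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    strains = [f"CC{i + 1:03d}" for i in range(config.n_strains)]
    rows = []
    per_chrom_pos = {}
    for name, length, n_loci in config.chromosomes:
        pos_mb = (np.arange(n_loci) + 0.5) * (length / n_loci)
        per_chrom_pos[name] = pos_mb
        for j in range(n_loci):
            rows.append({"locus_id": f"c{name}_{j:04d}", "chrom": name,
                         "pos_bp": float(round(pos_mb[j] * 1e6))})
    locus_map = pd.DataFrame(rows)
    dosages = np.zeros((config.n_strains, len(locus_map), N_FOUNDERS))
    col = 0
    for name, length, n_loci in config.chromosomes:
        pos_mb = per_chrom_pos[name]
        for s in range(config.n_strains):
            founders_at = _mosaic_founders(rng, length, pos_mb,
                                           config.mean_block_length)
            dosages[s, np.arange(col, col + n_loci), founders_at] = 2.0
        col += n_loci
    return FounderDosageMatrix(dosages, strains, locus_map)


def _mosaic_founders(rng, length_mb: float, pos_mb: np.ndarray,
                     mean_block: float) -> np.ndarray:
    # breakpoints from an exponential inter-arrival process
    breaks = []
    x = rng.exponential(mean_block)
    while x < length_mb:
        breaks.append(x)
        x += rng.exponential(mean_block)
    founders = rng.integers(0, N_FOUNDERS, size=len(breaks) + 1)
    return founders[np.searchsorted(np.array(breaks), pos_mb)]


def realized_block_lengths(config: SimConfig, n_strains: int, seed: int) -> np.ndarray:
    """Realized (chromosome-censored) block lengths, for diagnostics/tests."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    out = []
    for name, length, n_loci in config.chromosomes:
        for _ in range(n_strains):
            breaks = []
            x = rng.exponential(config.mean_block_length)
            while x < length:
                breaks.append(x)
                x += rng.exponential(config.mean_block_length)
            edges = np.concatenate([[0.0], breaks, [length]])
            out.append(np.diff(edges))
    return np.concatenate(out)


# --------------------------------------------------------------------- batches

def assign_batches(n: int, levels: int, seed: int) -> np.ndarray:
    """Random assignment of strains to sequencing batches (balanced draw)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    base = np.tile(np.arange(levels), n // levels + 1)[:n]
    return rng.permutation(base)


# ---------------------------------------------------------------------- traits

def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        nb = b @ b
        if nb > 0:
            v = v - b * (b @ v) / nb
    return v


def simulate_trait_panel(fdm: FounderDosageMatrix, specs: list[TraitSpec],
                         batch: np.ndarray | None = None, noise_sd: float = 1.0,
                         seed: int = 0, batch_sd: float = 0.5,
                         ) -> tuple[TraitMatrix, TruthTable]:
    """Simulate traits with planted QTL of exact in-sample effect size.

    Each trait is built as intercept + batch effect + sum of QTL terms +
    Gaussian noise.  QTL terms with a target ``effect_size`` are rescaled
    against the realized sample so the term explains exactly that fraction of
    the trait's sample variance: planted terms are Gram-Schmidt
    orthogonalized in order and the non-QTL remainder is orthogonalized
    against all of them, making the variance decomposition additive and the
    requested fractions exact.  An explicit ``beta`` without a target effect
    size enters unscaled.
    """
    n = fdm.n_strains
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    truth = TruthTable(seed=seed)
    values = np.zeros((len(specs), n))
    ann_rows = []
    for t, spec in enumerate(specs):
        total_es = sum(q.effect_size or 0.0 for q in spec.qtl)
        for q in spec.qtl:
            if q.effect_size is not None and not (0.0 <= q.effect_size < 1.0):
                raise ValueError("effect size must be in [0, 1)")
        if total_es >= 1.0:
            raise ValueError("planted effect sizes must sum to < 1")
        noise = rng.normal(0.0, noise_sd, size=n)
        if batch is not None:
            effects = rng.normal(0.0, batch_sd, size=int(np.max(batch)) + 1)
            e = noise + effects[batch]
        else:
            e = noise
        e = e - e.mean()

        g_basis: list[np.ndarray] = []
        y = np.zeros(n)
        for q in spec.qtl:
            X = fdm.locus_X(q.locus_id)
            beta = q.beta if q.beta is not None else rng.normal(0.0, 1.0, N_FOUNDERS)
            beta = np.asarray(beta, dtype=float)
            g = X @ beta
            g = g - g.mean()
            if q.effect_size is None:
                y = y + g
                g_basis.append(g)
                truth.qtl.append({"trait_id": spec.trait_id, "locus_id": q.locus_id,
                                  "beta": beta, "effect_size": None})
                continue
            g = _orthogonalize(g, g_basis)
            vg = float(g @ g) / n
            if vg <= 0:
                raise ValueError(
                    f"locus {q.locus_id} is constant after conditioning; cannot "
                    f"plant an effect there")
            scale = np.sqrt(q.effect_size / vg)
            y = y + scale * g
            g_basis.append(g)
            truth.qtl.append({"trait_id": spec.trait_id, "locus_id": q.locus_id,
                              "beta": beta * scale, "effect_size": q.effect_size})
        e = _orthogonalize(e, g_basis)
        ve = float(e @ e) / n
        resid_frac = 1.0 - total_es
        if ve > 0 and resid_frac > 0:
            y = y + e * np.sqrt(resid_frac / ve)
        values[t] = y
        chrom, pos = (spec.anchor_chrom, spec.anchor_bp)
        if chrom is None:
            if spec.qtl:
                chrom, pos = fdm.locus_position(spec.qtl[0].locus_id)
            else:  # null trait: arbitrary anchor at a random locus
                li = int(rng.integers(fdm.n_loci))
                row = fdm.locus_map.iloc[li]
                chrom, pos = str(row["chrom"]), float(row["pos_bp"])
        ann_rows.append({"trait_id": spec.trait_id, "chrom": chrom,
                         "anchor_bp": pos, "cls": spec.cls})
    ann = pd.DataFrame(ann_rows).set_index("trait_id")
    vals = pd.DataFrame(values, index=ann.index, columns=fdm.strains)
    return TraitMatrix(vals, ann), truth


def inject_outliers(matrix: TraitMatrix, outliers: list[tuple[str, str]],
                    magnitude_sd: float = 8.0,
                    truth: TruthTable | None = None) -> TraitMatrix:
    """Shift single observations by ``magnitude_sd`` trait SDs (recorded in truth)."""
    values = matrix.values.copy()
    for trait_id, strain in outliers:
        sd = values.loc[trait_id].std()
        values.loc[trait_id, strain] += magnitude_sd * (sd if sd > 0 else 1.0)
        if truth is not None:
            truth.outliers.append({"trait_id": trait_id, "strain": strain,
                                   "magnitude_sd": magnitude_sd})
    return TraitMatrix(values, matrix.annotations)


def simulate_raw_panel(matrix: TraitMatrix, seed: int = 0,
                       n_low_signal: int = 0, scale: float = 50.0) -> TraitMatrix:
    """Map latent traits onto a non-negative TPM-like scale, plus low-signal traits.

    Latent values are exponentiated (lognormal-like abundances).  Additional
    all-low traits (values <= 1) are appended to exercise the low-signal
    filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    raw = np.exp(matrix.values.to_numpy(float)) * scale
    values = pd.DataFrame(raw, index=matrix.values.index, columns=matrix.values.columns)
    ann = matrix.annotations.copy()
    for i in range(n_low_signal):
        tid = f"lowsig_{i:03d}"
        values.loc[tid] = rng.uniform(0.0, 0.9, size=values.shape[1])
        ann.loc[tid] = ann.iloc[i % len(matrix.annotations)]
    return TraitMatrix(values, ann)


# ------------------------------------------------------------------- mediation

def simulate_mediation_trio(fdm: FounderDosageMatrix, locus_id: str,
                            chain_strength: float, seed: int = 0,
                            qtl_effect_size: float = 0.6,
                            batch: np.ndarray | None = None,
                            batch_sd: float = 0.5,
                            mediator_id: str = "mediator",
                            outcome_id: str = "outcome",
                            ) -> tuple[TraitMatrix, TruthTable]:
    """Simulate a full-mediation chain QTL -> mediator -> outcome.

    The mediator carries the QTL directly (variance fraction
    ``qtl_effect_size``); the outcome is ``a * mediator + noise`` with
    ``a = chain_strength`` on the standardized scale and the outcome noise
    orthogonalized in-sample against the mediator, so with ``chain_strength
    1`` the outcome is an exact copy and conditioning on the mediator removes
    the QTL association entirely.  By construction QTL -> mediator is
    stronger than QTL -> outcome (outcome QTL variance fraction is
    ``chain_strength^2 * qtl_effect_size``).
    """
    if not (0.0 < chain_strength <= 1.0):
        raise ValueError("chain_strength must be in (0, 1]")
    spec = TraitSpec(mediator_id, [QTLPlant(locus_id, effect_size=qtl_effect_size)])
    med, truth = simulate_trait_panel(fdm, [spec], batch=batch, seed=seed,
                                      batch_sd=batch_sd)
    m = med.y(mediator_id)
    m_std = (m - m.mean()) / m.std()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    noise = rng.normal(size=m.size)
    noise = _orthogonalize(noise - noise.mean(), [m_std])
    resid = 1.0 - chain_strength ** 2
    vn = float(noise @ noise) / noise.size
    y = chain_strength * m_std
    if resid > 0 and vn > 0:
        y = y + noise * np.sqrt(resid / vn)
    chrom, pos = fdm.locus_position(locus_id)
    values = pd.DataFrame(np.vstack([m, y]), index=[mediator_id, outcome_id],
                          columns=fdm.strains)
    ann = pd.DataFrame({
        "chrom": [chrom, chrom],
        "anchor_bp": [pos, pos],
        "cls": ["chromatin", "gene"],
    }, index=[mediator_id, outcome_id])
    truth.mediation.append({"locus_id": locus_id, "mediator": mediator_id,
                            "outcome": outcome_id, "chain_strength": chain_strength})
    return TraitMatrix(values, ann), truth
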