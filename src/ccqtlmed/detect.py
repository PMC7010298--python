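"""Permutation-based significance and the three QTL detection protocols.

Family-wise error at chromosome or genome scope is controlled by permuting
the trait vector against the genotype/batch rows (a shared, seeded list of
orderings reused across traits), recording the maximum logP of each permuted
scan, and fitting a generalized extreme value (GEV) distribution to the
maxima.  The permutation p-value of an observed peak is the GEV upper tail,
``permP = 1 - F_GEV(logP)``.

Three protocols of increasing stringency then declare QTL:

* **Analysis L** — the peak within +/-10 Mb of the trait anchor, tested
  against the chromosome-wide null at permP_C < 0.05 (strong prior on local
  regulation; no FDR step).
* **Analysis C** — the single chromosome-wide peak per trait, with
  Benjamini-Hochberg FDR across traits on permP_C.
* **Analysis G** — the genome-wide peak per trait with BH across traits on
  permP_G, iterated: each detection triggers a new scan and a new
  permutation null conditioning on all loci already detected for that trait,
  so multiple independent QTL per trait can be found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import genextreme, kstest
from statsmodels.stats.multitest import multipletests

from .haplotypes import LOCAL_WINDOW_BP, FounderDosageMatrix
from .scan import EffectEstimate, ScanEngine, blup_effects, effect_size_fixed, fit_locus_model
from .trait_prep import TraitMatrix

MIN_PERM_FOR_GEV = 100


def permutation_orderings(n: int, n_perm: int, seed: int) -> np.ndarray:
    """A shared, seeded list of sample-index permutations (n_perm x n)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    return np.array([rng.permutation(n) for _ in range(n_perm)])


@dataclass
class GEVNull:
    """GEV fitted to permutation extrema for one scope.

    ``tail='upper'`` models maxima of QTL scans; ``tail='lower'`` models
    minima of mediation scans (the fit is performed on the negated minima).
    When the extrema are degenerate or the MLE fails, the empirical survival
    function with +1 smoothing is used instead (``fitted`` is False).
    """

    scope: str
    extrema: np.ndarray
    shape: float = np.nan
    loc: float = np.nan
    scale: float = np.nan
    fitted: bool = False
    tail: str = "upper"

    @classmethod
    def fit(cls, extrema: np.ndarray, scope: str = "genome",
            tail: str = "upper") -> "GEVNull":
        extrema = np.asarray(extrema, dtype=float)
        null = cls(scope=scope, extrema=extrema, tail=tail)
        vals = extrema if tail == "upper" else -extrema
        if extrema.size < MIN_PERM_FOR_GEV or np.std(vals) < 1e-12:
            return null
        try:
            c, loc, scale = genextreme.fit(vals)
        except Exception:
            return null
        if not (np.isfinite(c) and np.isfinite(loc) and scale > 0):
            return null
        null.shape, null.loc, null.scale, null.fitted = c, loc, scale, True
        return null

    def permp(self, logp: float | np.ndarray) -> float | np.ndarray:
        """Permutation p-value of an observed logP (strictly monotone in logP)."""
        x = np.asarray(logp, dtype=float)
        v = x if self.tail == "upper" else -x
        if self.fitted:
            out = genextreme.sf(v, self.shape, loc=self.loc, scale=self.scale)
        else:
            ref = self.extrema if self.tail == "upper" else -self.extrema
            out = (np.sum(ref[None, :] >= np.atleast_1d(v)[:, None], axis=1) + 1.0) \
                / (ref.size + 1.0)
            out = out.reshape(np.shape(v))
        return float(out) if np.isscalar(logp) else out


def permutation_null(y: np.ndarray, engine: ScanEngine, orderings: np.ndarray,
                     scope_idx: np.ndarray, scope: str = "genome") -> GEVNull:
    """Fit a GEV to per-permutation scan maxima within a scope."""
    maxima = engine.permutation_maxima(y, orderings, {scope: scope_idx})[scope]
    return GEVNull.fit(maxima, scope=scope, tail="upper")


def gev_pvalue(null: GEVNull, logp: float) -> float:
    if not null.fitted and null.extrema.size == 0:
        raise ValueError("null has not been fitted")
    return null.permp(logp)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone-enforced step-up)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class QTLCall:
    """One detected (or evaluated) QTL."""

    trait_id: str
    locus_id: str
    chrom: str
    pos_bp: float
    logp: float
    permp_c: float | None = None
    permp_g: float | None = None
    q: float | None = None
    analysis: str = "L"
    stage: int = 1
    local: bool | None = None
    tissue: str = ""
    effect: EffectEstimate | None = None
    detected: bool = False

    def effect_size(self) -> float | None:
        return None if self.effect is None else self.effect.r2_fixed


def _call_row(call: QTLCall) -> dict:
    d = {k: getattr(call, k) for k in
         ("trait_id", "tissue", "analysis", "stage", "locus_id", "chrom", "pos_bp",
          "logp", "permp_c", "permp_g", "q", "local", "detected")}
    d["effect_size"] = call.effect_size()
    return d


def calls_to_frame(calls: list[QTLCall]) -> pd.DataFrame:
    return pd.DataFrame([_call_row(c) for c in calls])


def _locus_info(engine: ScanEngine, idx: int) -> tuple[str, str, float]:
    row = engine.locus_map.iloc[idx]
    return str(row["locus_id"]), str(row["chrom"]), float(row["pos_bp"])


def _is_local(chrom: str, pos: float, anchor_chrom: str, anchor_bp: float) -> bool:
    return chrom == anchor_chrom and abs(pos - anchor_bp) <= LOCAL_WINDOW_BP


def _attach_effect(call: QTLCall, y, fdm: FounderDosageMatrix, batch,
                   conditioned=()) -> None:
    X = fdm.locus_X(call.locus_id)
    call.effect = blup_effects(y, X, batch=batch, conditioned=conditioned)


# ------------------------------------------------------------------ Analysis L

def analysis_L(y: np.ndarray, engine: ScanEngine, anchor: tuple[str, float],
               orderings: np.ndarray, alpha: float = 0.05,
               trait_id: str = "trait", tissue: str = "",
               with_genome_null: bool = True,
               fdm: FounderDosageMatrix | None = None,
               batch: np.ndarray | None = None) -> QTLCall | None:
    """Local-window detection against the chromosome-wide permutation null.

    Returns the evaluated call (``detected`` flag set by permP_C < alpha) or
    None when no locus falls in the window.
    """
    chrom, anchor_bp = anchor
    window = engine.scope_indices("local", chrom, anchor_bp)
    if window.size == 0:
        return None
    chrom_idx = engine.scope_indices("chromosome", chrom)
    scopes = {"C": chrom_idx}
    if with_genome_null:
        scopes["G"] = engine.scope_indices("genome")
    maxima = engine.permutation_maxima(y, orderings, scopes)
    logp_all = engine.logp_matrix(y[:, None])[:, 0]
    peak_local = window[np.argmax(logp_all[window])]
    lid, lchrom, lpos = _locus_info(engine, int(peak_local))
    logp = float(logp_all[peak_local])
    null_c = GEVNull.fit(maxima["C"], scope=f"chr{chrom}")
    permp_c = null_c.permp(logp)
    permp_g = None
    if with_genome_null:
        permp_g = GEVNull.fit(maxima["G"], scope="genome").permp(logp)
    call = QTLCall(trait_id, lid, lchrom, lpos, logp, permp_c=permp_c,
                   permp_g=permp_g, analysis="L", tissue=tissue,
                   local=True, detected=bool(permp_c < alpha))
    if call.detected and fdm is not None:
        _attach_effect(call, y, fdm, batch)
    return call


# ------------------------------------------------------------------ Analysis C

def analysis_C(traits: TraitMatrix, engine: ScanEngine, orderings: np.ndarray,
               fdr: float = 0.1, tissue: str = "",
               fdm: FounderDosageMatrix | None = None,
               batch: np.ndarray | None = None) -> list[QTLCall]:
    """Chromosome-wide peaks with BH FDR across traits.

    Only the single chromosome peak per trait is eligible, so a stronger
    distal peak on the chromosome masks a local one.  Returns all evaluated
    calls with q-values; ``detected`` marks q <= fdr.
    """
    calls: list[QTLCall] = []
    for tid in traits.trait_ids:
        chrom, anchor_bp = traits.anchor(tid)
        idx = engine.scope_indices("chromosome", chrom)
        if idx.size == 0:
            continue
        y = traits.y(tid)
        logp_all = engine.logp_matrix(y[:, None])[:, 0]
        peak = idx[np.argmax(logp_all[idx])]
        lid, lchrom, lpos = _locus_info(engine, int(peak))
        null_c = permutation_null(y, engine, orderings, idx, scope=f"chr{chrom}")
        logp = float(logp_all[peak])
        calls.append(QTLCall(tid, lid, lchrom, lpos, logp,
                             permp_c=null_c.permp(logp), analysis="C",
                             tissue=tissue,
                             local=_is_local(lchrom, lpos, chrom, anchor_bp)))
    if not calls:
        return calls
    q = bh_fdr(np.array([c.permp_c for c in calls]))
    for c, qi in zip(calls, q):
        c.q = float(qi)
        c.detected = bool(qi <= fdr)
        if c.detected and fdm is not None:
            _attach_effect(c, traits.y(c.trait_id), fdm, batch)
    return calls


# ------------------------------------------------------------------ Analysis G

def analysis_G(traits: TraitMatrix, fdm: FounderDosageMatrix,
               orderings: np.ndarray, batch: np.ndarray | None = None,
               fdr: float = 0.1, max_stages: int = 3,
               tissue: str = "") -> list[QTLCall]:
    """Genome-wide multi-stage conditional detection with per-stage BH FDR.

    Stage 1 evaluates the genome peak of every trait against its genome-wide
    permutation null.  For each detection, subsequent stages rescan the trait
    (and re-permute) with all previously detected loci included in both null
    and full models; local/distal status plays no role in detection.
    """
    base_engine = ScanEngine(fdm, batch=batch)
    genome = np.arange(fdm.n_loci)
    all_calls: list[QTLCall] = []
    active = {tid: [] for tid in traits.trait_ids}  # conditioned locus ids
    for stage in range(1, max_stages + 1):
        stage_calls: list[QTLCall] = []
        for tid in list(active):
            cond_ids = active[tid]
            if stage == 1:
                engine = base_engine
            else:
                engine = ScanEngine(
                    fdm, batch=batch,
                    conditioned=[fdm.locus_X(l) for l in cond_ids])
            y = traits.y(tid)
            logp_all = engine.logp_matrix(y[:, None])[:, 0]
            peak = int(np.argmax(logp_all))
            lid, lchrom, lpos = _locus_info(engine, peak)
            null_g = permutation_null(y, engine, orderings, genome)
            logp = float(logp_all[peak])
            chrom_a, anchor_bp = traits.anchor(tid)
            stage_calls.append(QTLCall(
                tid, lid, lchrom, lpos, logp, permp_g=null_g.permp(logp),
                analysis="G", stage=stage, tissue=tissue,
                local=_is_local(lchrom, lpos, chrom_a, anchor_bp)))
        if not stage_calls:
            break
        q = bh_fdr(np.array([c.permp_g for c in stage_calls]))
        detected = []
        for c, qi in zip(stage_calls, q):
            c.q = float(qi)
            c.detected = bool(qi <= fdr)
            if c.detected:
                detected.append(c)
        all_calls.extend(stage_calls)
        nxt = {}
        for c in detected:
            cond = active[c.trait_id] + [c.locus_id]
            y = traits.y(c.trait_id)
            _attach_effect(c, y, fdm, batch,
                           conditioned=[fdm.locus_X(l) for l in active[c.trait_id]])
            nxt[c.trait_id] = cond
        active = nxt
        if not active:
            break
    return all_calls


# ----------------------------------------------------------------- diagnostics

def ks_uniform(values: np.ndarray) -> float:
    """KS-test p-value against Uniform(0,1) (for permP calibration checks)."""
    return float(kstest(values, "uniform").pvalue)
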