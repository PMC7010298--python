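"""Genome-wide mediation of eQTL through chromatin or transcript intermediates.

For a detected eQTL X acting on outcome trait Y, the mediation scan re-tests
the X -> Y association conditioning on each candidate mediator M in turn:

    alt:   y = mu + QTL + m_k + batch (+ conditioned loci)
    null:  y = mu +       m_k + batch (+ conditioned loci)

compared by F-test, yielding a mediated logP per candidate.  Mediators that
carry the QTL's information pull the mediated logP down sharply; candidates
with no relation to the QTL leave it near the unmediated value, so the
genome-wide panel doubles as a background.  Significance is calibrated by
permuting the mediator matrix rows (strain labels, one shared ordering per
permutation), recording the *minimum* mediated logP of each permuted scan,
fitting a GEV to the minima, and reporting the lower tail
``permP^m = F_GEV(logP)``.

A mediator is *called* only if (i) permP^m is below the threshold, (ii) it
has its own QTL co-localizing with X (peak within 10 Mb), and (iii) that QTL
is stronger than the outcome's eQTL in both logP and fixed effect size —
the pattern implied by a causal chain X -> M -> Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import GEVNull, QTLCall
from .haplotypes import LOCAL_WINDOW_BP
from .scan import _orth_basis, batch_design, _logp_from_f
from .trait_prep import TraitMatrix

_RCOND = 1e-10


class MediationScanner:
    """Vectorized per-mediator conditional F-tests for one outcome/eQTL pair.

    Precomputes the covariate basis (intercept + batch + conditioned loci)
    and the residualized outcome and QTL design; each scan (observed or
    permuted) then costs one batched SVD over mediators.
    """

    def __init__(self, y: np.ndarray, X_eqtl: np.ndarray, mediators: TraitMatrix,
                 batch: np.ndarray | None = None,
                 conditioned: list[np.ndarray] | tuple = ()):
        y = np.asarray(y, dtype=float)
        n = y.size
        C = np.hstack([batch_design(batch, n)]
                      + [np.atleast_2d(c.T).T for c in conditioned])
        self.Qc = _orth_basis(C)
        self.rank_c = self.Qc.shape[1]
        self.n = n
        self.y_r = y - self.Qc @ (self.Qc.T @ y)
        self.X_r = X_eqtl - self.Qc @ (self.Qc.T @ X_eqtl)
        self._x_scale = float(np.linalg.norm(X_eqtl))
        self.M_raw = mediators.values.to_numpy(float).T  # (n, K)
        self.mediator_ids = list(mediators.trait_ids)
        self.K = self.M_raw.shape[1]

    def scan(self, ordering: np.ndarray | None = None) -> np.ndarray:
        """Mediated logP per mediator; NaN where the mediator is collinear
        with the covariates (test undefined)."""
        M = self.M_raw if ordering is None else self.M_raw[ordering, :]
        Mr = M - self.Qc @ (self.Qc.T @ M)
        norms = np.linalg.norm(Mr, axis=0)
        ok = norms > 1e-10 * max(np.abs(M).max(), 1.0)
        U = np.where(ok, Mr / np.where(norms > 0, norms, 1.0), 0.0)
        a = U.T @ self.y_r                        # (K,)
        yr_ss = float(self.y_r @ self.y_r)
        y2ss = np.maximum(yr_ss - a ** 2, 0.0)    # RSS of null (covars + m)
        # a mediator that absorbs (numerically) all outcome variance leaves
        # nothing for the QTL term to explain: the comparison is 0/0, the
        # mediated association is nil
        exhausted = y2ss <= 1e-12 * max(yr_ss, 1e-300)
        UX = U.T @ self.X_r                       # (K, 8)
        Xa = self.X_r[None, :, :] - U.T[:, :, None] * UX[:, None, :]
        u, s, _ = np.linalg.svd(Xa, full_matrices=False)
        tol = np.maximum(s[:, [0]], self._x_scale) * _RCOND
        mask = s > tol
        Y2 = self.y_r[None, :] - U.T * a[:, None]  # (K, n)
        proj = np.einsum("kne,kn->ke", u, Y2)
        ss = np.sum(proj ** 2 * mask, axis=1)
        ranks = mask.sum(axis=1)
        df_den = self.n - self.rank_c - 1 - ranks
        rss1 = np.maximum(y2ss - ss, 0.0)
        logp = np.zeros(self.K)
        testable = ok & (ranks > 0) & (df_den > 0) & ~exhausted
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / np.maximum(ranks, 1)) / (rss1 / np.maximum(df_den, 1))
        F = np.where(np.isfinite(F), F, np.inf)
        for r, d in set(zip(ranks[testable], df_den[testable])):
            m = testable & (ranks == r) & (df_den == d)
            logp[m] = _logp_from_f(F[m], r, d)
        logp[~ok] = np.nan
        return logp


def mediation_scan(y: np.ndarray, X_eqtl: np.ndarray, mediators: TraitMatrix,
                   batch: np.ndarray | None = None,
                   conditioned: list[np.ndarray] | tuple = ()) -> pd.Series:
    """Mediated logP of the eQTL for each candidate mediator."""
    sc = MediationScanner(y, X_eqtl, mediators, batch=batch, conditioned=conditioned)
    return pd.Series(sc.scan(), index=sc.mediator_ids, name="logp_mediated")


def mediation_null(y: np.ndarray, X_eqtl: np.ndarray, mediators: TraitMatrix,
                   orderings: np.ndarray, batch: np.ndarray | None = None,
                   conditioned: list[np.ndarray] | tuple = (),
                   scope: str = "genome") -> GEVNull:
    """GEV null of minimum mediated logP under joint mediator-row permutation.

    Each permutation shuffles the strain labels of the whole mediator matrix
    with one shared ordering, reruns the scan, and records the minimum logP;
    the GEV is fitted to the minima (lower tail).
    """
    sc = MediationScanner(y, X_eqtl, mediators, batch=batch, conditioned=conditioned)
    minima = np.empty(orderings.shape[0])
    for i, ordering in enumerate(orderings):
        lp = sc.scan(ordering)
        minima[i] = np.nanmin(lp) if np.isfinite(lp).any() else 0.0
    return GEVNull.fit(minima, scope=scope, tail="lower")


@dataclass
class MediationRecord:
    """Evaluation of one candidate mediator for one outcome eQTL."""

    outcome_id: str
    eqtl_locus: str
    mediator_id: str
    mediator_class: str
    logp_unmediated: float
    logp_mediated: float
    permp_m: float | None = None
    mediator_qtl_colocalizes: bool = False
    mediator_assoc_stronger: bool = False
    mediator_effectsize_larger: bool = False
    verdict: str = "not_called"
    reason: str = ""


def call_mediators(mediated_logp: pd.Series, null: GEVNull,
                   outcome_call: QTLCall,
                   mediator_qtl_calls: dict[str, QTLCall],
                   mediator_classes: pd.Series | dict,
                   alpha: float = 0.05,
                   window_bp: float = LOCAL_WINDOW_BP) -> list[MediationRecord]:
    """Apply the three mediation calling criteria to every candidate.

    ``mediator_qtl_calls`` maps mediator id -> its detected QTL call (absent
    entries mean no QTL was detected, failing criterion ii).  Criterion (iii)
    compares both logP and fixed effect size of the mediator's QTL against
    the outcome's eQTL.
    """
    records = []
    out_es = outcome_call.effect_size()
    for mid, lp in mediated_logp.items():
        rec = MediationRecord(
            outcome_id=outcome_call.trait_id, eqtl_locus=outcome_call.locus_id,
            mediator_id=str(mid),
            mediator_class=str(dict(mediator_classes).get(mid, "")),
            logp_unmediated=outcome_call.logp, logp_mediated=float(lp))
        if np.isnan(lp):
            rec.reason = "mediator collinear with covariates"
            records.append(rec)
            continue
        rec.permp_m = null.permp(float(lp))
        mcall = mediator_qtl_calls.get(mid)
        if mcall is not None and mcall.detected:
            rec.mediator_qtl_colocalizes = (
                mcall.chrom == outcome_call.chrom
                and abs(mcall.pos_bp - outcome_call.pos_bp) <= window_bp)
            rec.mediator_assoc_stronger = mcall.logp > outcome_call.logp
            m_es = mcall.effect_size()
            if m_es is not None and out_es is not None:
                rec.mediator_effectsize_larger = m_es > out_es
            else:
                rec.reason = "effect sizes unavailable"
        else:
            rec.reason = "no mediator QTL detected"
        if (rec.permp_m < alpha and rec.mediator_qtl_colocalizes
                and rec.mediator_assoc_stronger and rec.mediator_effectsize_larger):
            rec.verdict = "called"
        records.append(rec)
    return records


def records_to_frame(records: list[MediationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
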