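"""Cross-tissue QTL pairing and founder-effect correlation tests.

QTL detected for the same trait in two tissues are paired when they
co-localize: local QTL must both lie within the +/-10 Mb window around the
shared anchor (so at most 20 Mb apart), distal QTL must be within 10 Mb of
each other (inclusive).  Consistency of a pair is then assessed by the
Pearson correlation ``r`` of their centered/scaled 8-element BLUP vectors,
tested with the exact null ``r sqrt(6) / sqrt(1 - r^2) ~ t_6`` (n = 8
founders, df = 6).  Both one-sided alternatives (r > 0, r < 0) are tested;
each one-sided family is BH-adjusted separately, classifying pairs as
correlated, anticorrelated, or neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .detect import QTLCall, bh_fdr
from .haplotypes import LOCAL_WINDOW_BP

_DF = 6  # 8 founder effects -> n - 2 degrees of freedom


def effect_correlation_test(blup_j: np.ndarray, blup_k: np.ndarray
                            ) -> tuple[float, float, float]:
    """Pearson r of two 8-vectors with one-sided t(6) p-values.

    Returns ``(r, p_pos, p_neg)`` with ``p_pos + p_neg = 1``.  Raises on a
    zero-variance vector (test undefined).
    """
    a = np.asarray(blup_j, dtype=float)
    b = np.asarray(blup_k, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance effect vector; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    r = min(1.0, max(-1.0, r))
    denom = np.sqrt(max(1.0 - r * r, 1e-300))
    t = r * np.sqrt(_DF) / denom
    p_pos = float(t_dist.sf(t, _DF))
    return r, p_pos, 1.0 - p_pos


@dataclass
class QTLPair:
    """Two co-localizing QTL calls for the same trait in two tissues."""

    trait_id: str
    tissue_a: str
    tissue_b: str
    call_a: QTLCall
    call_b: QTLCall
    distance_bp: float
    kind: str  # 'local' or 'distal'
    r: float = np.nan
    p_pos: float = np.nan
    p_neg: float = np.nan
    q_pos: float = np.nan
    q_neg: float = np.nan
    classification: str = "neither"


def pair_qtl(calls_by_tissue: dict[str, list[QTLCall]],
             window_bp: float = LOCAL_WINDOW_BP) -> list[QTLPair]:
    """Pair QTL for shared traits across tissue pairs and score correlations.

    Only calls carrying BLUP effect estimates are usable.  When several calls
    of one tissue co-localize with one of another, the pair with the smallest
    peak distance is kept (ties broken by higher mean logP) — one pair per
    trait/tissue-pair/kind.
    """
    tissues = sorted(calls_by_tissue)
    pairs: list[QTLPair] = []
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1:]:
            by_trait_a = _group(calls_by_tissue[ta])
            by_trait_b = _group(calls_by_tissue[tb])
            for trait in sorted(set(by_trait_a) & set(by_trait_b)):
                for kind in ("local", "distal"):
                    cand = _candidates(by_trait_a[trait], by_trait_b[trait],
                                       kind, window_bp)
                    if not cand:
                        continue
                    cand.sort(key=lambda c: (c[0], -c[1]))
                    dist, _, ca, cb = cand[0]
                    pair = QTLPair(trait, ta, tb, ca, cb, dist, kind)
                    pair.r, pair.p_pos, pair.p_neg = effect_correlation_test(
                        ca.effect.blup_scaled, cb.effect.blup_scaled)
                    pairs.append(pair)
    return pairs


def _group(calls: list[QTLCall]) -> dict[str, list[QTLCall]]:
    out: dict[str, list[QTLCall]] = {}
    for c in calls:
        if c.detected and c.effect is not None:
            out.setdefault(c.trait_id, []).append(c)
    return out


def _candidates(calls_a, calls_b, kind, window_bp):
    out = []
    for ca in calls_a:
        for cb in calls_b:
            if kind == "local":
                if not (ca.local and cb.local):
                    continue  # both peaks within the +/-10Mb anchor window
            else:
                if ca.local or cb.local:
                    continue
                if ca.chrom != cb.chrom or abs(ca.pos_bp - cb.pos_bp) > window_bp:
                    continue
            if ca.chrom != cb.chrom:
                continue
            dist = abs(ca.pos_bp - cb.pos_bp)
            out.append((dist, (ca.logp + cb.logp) / 2.0, ca, cb))
    return out


def classify_pairs(pairs: list[QTLPair], fdr: float = 0.1) -> list[QTLPair]:
    """BH-adjust the two one-sided families separately and classify each pair."""
    if not pairs:
        return pairs
    q_pos = bh_fdr(np.array([p.p_pos for p in pairs]))
    q_neg = bh_fdr(np.array([p.p_neg for p in pairs]))
    for pair, qp, qn in zip(pairs, q_pos, q_neg):
        pair.q_pos, pair.q_neg = float(qp), float(qn)
        if qp <= fdr:
            pair.classification = "correlated"
        elif qn <= fdr:
            pair.classification = "anticorrelated"
        else:
            pair.classification = "neither"
    return pairs


def pairs_to_frame(pairs: list[QTLPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        es_a, es_b = p.call_a.effect_size(), p.call_b.effect_size()
        rows.append({
            "trait_id": p.trait_id, "tissue_a": p.tissue_a, "tissue_b": p.tissue_b,
            "kind": p.kind, "peak_a": p.call_a.locus_id, "peak_b": p.call_b.locus_id,
            "distance_bp": p.distance_bp, "r": p.r,
            "p_pos": p.p_pos, "p_neg": p.p_neg, "q_pos": p.q_pos, "q_neg": p.q_neg,
            "class": p.classification,
            "effect_size_a": es_a, "effect_size_b": es_b,
        })
    df = pd.DataFrame(rows)
    return df


def effect_size_correlation(pairs: list[QTLPair]) -> float:
    """Pearson correlation of fixed effect sizes across paired QTL (summary)."""
    a = np.array([p.call_a.effect_size() for p in pairs], dtype=float)
    b = np.array([p.call_b.effect_size() for p in pairs], dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
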