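"""Small utilities from the differential-analysis side of the pipeline.

Simes' combination of p-values for merged runs of adjacent chromatin
windows, and the signed pathway-analysis gene weight
``weight_g = sign(Delta_g) * (1 - q_g)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simes_combine(p) -> float:
    """Simes' combined p-value: ``min_k n * p_(k) / k`` over sorted p."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("Simes' method needs at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    ps = np.sort(p)
    n = ps.size
    return float(np.min(n * ps / np.arange(1, n + 1)))


def gsaa_weight(sign_delta: int, q: float) -> float:
    """Signed pathway weight: direction of change scaled by 1 - q."""
    if sign_delta not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    return sign_delta * (1.0 - q)


def merge_adjacent_windows(windows: pd.DataFrame, significant: np.ndarray,
                           max_gap_bp: int = 0) -> pd.DataFrame:
    """Merge runs of adjacent significant same-direction windows; Simes per run.

    ``windows`` must be BED-ordered with columns ``chrom``, ``start``,
    ``end``, ``p``, ``direction`` (+1/-1); ``significant`` is a boolean mask.
    Returns merged regions with member count and combined Simes p-value.
    """
    req = {"chrom", "start", "end", "p", "direction"}
    if not req.issubset(windows.columns):
        raise ValueError(f"windows needs columns {sorted(req)}")
    rows = []
    current: dict | None = None
    for (_, w), sig in zip(windows.iterrows(), np.asarray(significant, bool)):
        if not sig:
            if current:
                rows.append(current)
            current = None
            continue
        joinable = (
            current is not None
            and w["chrom"] == current["chrom"]
            and w["direction"] == current["direction"]
            and w["start"] - current["end"] <= max_gap_bp
        )
        if joinable:
            current["end"] = max(current["end"], w["end"])
            current["members"].append(w["p"])
        else:
            if current:
                rows.append(current)
            current = {"chrom": w["chrom"], "start": w["start"], "end": w["end"],
                       "direction": w["direction"], "members": [w["p"]]}
    if current:
        rows.append(current)
    out = pd.DataFrame([{
        "chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
        "direction": int(r["direction"]), "n_windows": len(r["members"]),
        "p_simes": simes_combine(r["members"]),
    } for r in rows])
    return out
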