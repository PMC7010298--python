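"""Trait matrix container, normalization, filtering, and transformation.

Molecular traits (gene expression TPM, chromatin-window counts) arrive as a
traits x strains matrix keyed to genomic anchors (gene TSS or window
midpoint).  Before QTL mapping they are TMM-normalized, stripped of
low-signal traits and single-outlier traits, and rank inverse normal
transformed (RINT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: default "low" thresholds per trait class, applied after TMM rescaling
LOW_SIGNAL_THRESHOLDS = {"gene": 1.0, "chromatin": 5.0}


class TraitMatrix:
    """Traits x strains values with genomic anchors.

    ``values`` is a DataFrame indexed by trait id with strain columns;
    ``annotations`` is indexed by trait id with columns ``chrom``,
    ``anchor_bp`` and ``cls`` (``gene`` or ``chromatin``).
    """

    def __init__(self, values: pd.DataFrame, annotations: pd.DataFrame):
        if not values.index.equals(annotations.index):
            annotations = annotations.loc[values.index]
        self.values = values
        self.annotations = annotations

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.index)

    def anchor(self, trait_id: str) -> tuple[str, float]:
        row = self.annotations.loc[trait_id]
        return str(row["chrom"]), float(row["anchor_bp"])

    def trait_class(self, trait_id: str) -> str:
        return str(self.annotations.loc[trait_id, "cls"])

    def y(self, trait_id: str) -> np.ndarray:
        return self.values.loc[trait_id].to_numpy(float)

    def subset(self, trait_ids) -> "TraitMatrix":
        return TraitMatrix(self.values.loc[trait_ids], self.annotations.loc[trait_ids])

    def copy_with(self, values: np.ndarray) -> "TraitMatrix":
        return TraitMatrix(
            pd.DataFrame(values, index=self.values.index, columns=self.values.columns),
            self.annotations,
        )

    # --------------------------------------------------------------------- io
    def to_tsv(self, values_path, annotations_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="trait_id")
        if annotations_path is not None:
            self.annotations.to_csv(annotations_path, sep="\t", index_label="trait_id")

    @classmethod
    def from_tsv(cls, values_path, annotations_path) -> "TraitMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="trait_id")
        ann = pd.read_csv(annotations_path, sep="\t", index_col="trait_id")
        ann["chrom"] = ann["chrom"].astype(str)
        return cls(values, ann)

    def chromatin_bed(self, path, window_bp: int = 300) -> None:
        """Write chromatin-window traits as BED (0-based half-open) around midpoints."""
        ann = self.annotations
        chrom_rows = ann[ann["cls"] == "chromatin"]
        half = window_bp // 2
        start = (chrom_rows["anchor_bp"].astype(int) - 1 - half).clip(lower=0)
        bed = pd.DataFrame({
            "chrom": chrom_rows["chrom"],
            "start": start,
            "end": start + window_bp,
            "name": chrom_rows.index,
        })
        bed.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class FilterReport:
    """Per-trait keep/remove flags with the triggering statistic."""

    table: pd.DataFrame  # trait_id, flag, statistic

    def kept(self) -> list[str]:
        t = self.table
        return list(t.loc[t["flag"] == "kept", "trait_id"])

    def removed(self) -> list[str]:
        t = self.table
        return list(t.loc[t["flag"] != "kept", "trait_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------- TMM

def tmm_factors(matrix: TraitMatrix | pd.DataFrame,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values scaling factors, one per sample.

    The reference sample is the one whose upper-quartile of library-size-scaled
    values is closest to the mean upper quartile.  For each sample, log2 ratios
    M and average abundances A versus the reference are computed over traits
    nonzero in both; the top/bottom ``logratio_trim`` of M and ``sum_trim`` of
    A are discarded and the factor is 2**(inverse-asymptotic-variance weighted
    mean of the remaining M).  Factors are renormalized to geometric mean 1.
    """
    values = matrix.values if isinstance(matrix, TraitMatrix) else matrix
    Y = values.to_numpy(float)
    if (Y < 0).any():
        raise ValueError("TMM requires non-negative values")
    if Y.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = Y.sum(axis=0)
    for j, s in enumerate(values.columns):
        if lib[j] == 0:
            raise ValueError(f"sample {s!r} has an all-zero library")
    scaled = Y / lib
    uq = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(Y.shape[1])
    for k in range(Y.shape[1]):
        if k == ref:
            continue
        factors[k] = _tmm_pair_factor(Y[:, k], Y[:, ref], lib[k], lib[ref],
                                      logratio_trim, sum_trim)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


def _tmm_pair_factor(y, y_ref, n, n_ref, logratio_trim, sum_trim) -> float:
    ok = (y > 0) & (y_ref > 0)
    if not ok.any():
        return 1.0
    y, y_ref = y[ok], y_ref[ok]
    m = np.log2((y / n) / (y_ref / n_ref))
    a = 0.5 * np.log2((y / n) * (y_ref / n_ref))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # asymptotic (delta-method) variance of M for count data
    w = (n - y) / (n * y) + (n_ref - y_ref) / (n_ref * y_ref)
    n_obs = m.size
    lo_m = np.floor(n_obs * logratio_trim) + 1
    hi_m = n_obs + 1 - lo_m
    lo_a = np.floor(n_obs * sum_trim) + 1
    hi_a = n_obs + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore"):
        inv = np.where(w[keep] > 0, 1.0 / w[keep], 0.0)
    if inv.sum() == 0:
        return 1.0
    return float(2.0 ** (np.sum(inv * m[keep]) / inv.sum()))


def tmm_normalize(matrix: TraitMatrix) -> tuple[TraitMatrix, pd.Series]:
    """Rescale samples by TMM factor x relative library size.

    Each sample column is divided by ``factor_k * lib_k / mean(lib)`` so that
    a doubled library with unchanged composition maps back onto the original
    values.  Returns the rescaled matrix and the factors.
    """
    factors = tmm_factors(matrix)
    lib = matrix.values.sum(axis=0)
    eff = factors * lib / lib.mean()
    return matrix.copy_with(matrix.values.to_numpy(float) / eff.to_numpy()), factors


# -------------------------------------------------------------------- filters

def filter_low_signal(matrix: TraitMatrix, thresholds: dict | None = None,
                      min_fraction: float = 0.5) -> tuple[TraitMatrix, FilterReport]:
    """Drop traits that are at or below the class threshold in most samples.

    A trait is removed iff the fraction of samples with value <= threshold is
    >= ``min_fraction``.  Low-but-not-absent traits invite spurious QTL driven
    by a handful of nonzero observations, hence the exclusion.
    """
    if len(matrix.trait_ids) == 0:
        raise ValueError("empty trait matrix")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    thresholds = {**LOW_SIGNAL_THRESHOLDS, **(thresholds or {})}
    Y = matrix.values.to_numpy(float)
    thr = np.array([thresholds[matrix.trait_class(t)] for t in matrix.trait_ids])
    frac_low = (Y <= thr[:, None]).mean(axis=1)
    removed = frac_low >= min_fraction
    report = FilterReport(pd.DataFrame({
        "trait_id": matrix.trait_ids,
        "flag": np.where(removed, "removed_low_signal", "kept"),
        "statistic": frac_low,
    }))
    kept_ids = [t for t, r in zip(matrix.trait_ids, removed) if not r]
    return matrix.subset(kept_ids), report


def _best_1d_split(x: np.ndarray) -> tuple[int, float]:
    """Exact optimal two-means partition of sorted 1-D data.

    Returns (size of left cluster, within-cluster sum of squares); enumerates
    all n-1 sorted split points, which attains the 1-D K=2 optimum.
    """
    xs = np.sort(x)
    n = xs.size
    cs = np.cumsum(xs)
    css = np.cumsum(xs ** 2)
    k = np.arange(1, n)
    left = css[:-1] - cs[:-1] ** 2 / k
    right = (css[-1] - css[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    wss = left + right
    best = int(np.argmin(wss))
    return best + 1, float(wss[best])


def kmeans_outlier_filter(matrix: TraitMatrix) -> tuple[TraitMatrix, FilterReport]:
    """Remove traits where the optimal 1-D 2-means split isolates one sample.

    A lone extreme observation produces a smaller cluster of cardinality 1 and
    can by itself generate a spurious QTL; such traits are dropped.  Constant
    traits are kept (both clusters degenerate, no outlier).
    """
    rows = []
    kept_ids = []
    for t in matrix.trait_ids:
        x = matrix.y(t)
        if x.size < 3:
            raise ValueError("kmeans_outlier_filter needs >= 3 samples per trait")
        if np.ptp(x) == 0:
            rows.append((t, "kept", 0.0))
            kept_ids.append(t)
            continue
        n_left, _ = _best_1d_split(x)
        small = min(n_left, x.size - n_left)
        if small == 1:
            rows.append((t, "removed_outlier", 1.0))
        else:
            rows.append((t, "kept", float(small)))
            kept_ids.append(t)
    report = FilterReport(pd.DataFrame(rows, columns=["trait_id", "flag", "statistic"]))
    return matrix.subset(kept_ids), report


# ----------------------------------------------------------------------- RINT

def rank_inverse_normal(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank inverse normal transform with Blom offset (ties -> average ranks).

    ``out_k = Phi^{-1}((rank_k - c) / (n - 2c + 1))``.  An all-equal vector
    maps to all zeros.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("RINT needs length >= 2")
    if np.ptp(x) == 0:
        return np.zeros(n)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def rint_matrix(matrix: TraitMatrix) -> TraitMatrix:
    """Apply RINT to every trait row."""
    Y = matrix.values.to_numpy(float)
    out = np.vstack([rank_inverse_normal(row) for row in Y])
    return matrix.copy_with(out)


def prepare_traits(matrix: TraitMatrix, thresholds: dict | None = None,
                   min_fraction: float = 0.5, normalize: bool = True,
                   rint: bool = True) -> tuple[TraitMatrix, FilterReport]:
    """TMM-normalize, filter low-signal and outlier traits, then RINT.

    Standard preprocessing ahead of QTL mapping; filters operate on the
    normalized raw scale, the transform comes last.
    """
    if normalize:
        matrix, _ = tmm_normalize(matrix)
    matrix, rep1 = filter_low_signal(matrix, thresholds, min_fraction)
    matrix, rep2 = kmeans_outlier_filter(matrix)
    report = FilterReport(pd.concat([
        rep2.table,
        rep1.table[rep1.table["flag"] != "kept"],
    ], ignore_index=True))
    if rint:
        matrix = rint_matrix(matrix)
    return matrix, report
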