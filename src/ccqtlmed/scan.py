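"""Per-locus linear-model fitting, genome scans, and founder-effect BLUPs.

The association model at a locus is

    y_i = mu + batch_b[i] + beta' x_i + eps_i,     eps_i ~ N(0, sigma^2)

where ``x_i`` is the strain's 8-vector of founder haplotype dosages.  The fit
is compared with the null model (intercept + batch + any conditioned loci) by
an F-test; significance is reported as logP = -log10(p).  The eight dosage
columns are collinear with the intercept (they sum to 2), so degrees of
freedom come from numerical rank rather than from dropping a named column,
preserving founder symmetry — the numerator df is typically 7.

``ScanEngine`` precomputes, per locus, an orthonormal basis of the dosage
block residualized against the null design.  A scan of any trait (or of
thousands of permuted traits at once) then reduces to a single matrix
multiplication followed by segment sums, which is what makes the
permutation-based significance machinery affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import f as f_dist

from .haplotypes import FounderDosageMatrix

_RCOND = 1e-10
_MIN_P = 1e-320  # floor before log10, keeps noiseless fits finite


def batch_design(batch: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus full one-hot batch dummies (rank handled downstream)."""
    cols = [np.ones((n, 1))]
    if batch is not None:
        batch = np.asarray(batch)
        for lvl in np.unique(batch):
            cols.append((batch == lvl).astype(float)[:, None])
    return np.hstack(cols)


def _orth_basis(A: np.ndarray, rcond: float = _RCOND,
                ref_scale: float | None = None) -> np.ndarray:
    """Orthonormal basis of the column space of A (rank by scaled SVD cutoff).

    ``ref_scale`` anchors the cutoff when A is a residualized block: singular
    values are compared against the scale of the *original* block so that a
    block lying (numerically) inside the space it was residualized against
    gets rank zero rather than a spurious rank from rounding noise.
    """
    if A.size == 0:
        return np.zeros((A.shape[0], 0))
    u, s, _ = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((A.shape[0], 0))
    scale = max(s[0], ref_scale or 0.0)
    r = int(np.sum(s > scale * rcond))
    return u[:, :r]


@dataclass
class ModelFit:
    """Two-model comparison at one locus."""

    rss_null: float
    rss_full: float
    df_num: int
    df_den: int
    fstat: float
    p: float
    logp: float
    testable: bool = True

    @property
    def r2(self) -> float:
        return 1.0 - self.rss_full / self.rss_null


def _logp_from_f(F, df_num, df_den):
    with np.errstate(over="ignore", invalid="ignore"):
        p = f_dist.sf(F, df_num, df_den)
    p = np.maximum(p, _MIN_P)
    return -np.log10(p)


def fit_locus_model(y: np.ndarray, X_locus: np.ndarray,
                    batch: np.ndarray | None = None,
                    conditioned: list[np.ndarray] | tuple = ()) -> ModelFit:
    """Fit null (intercept + batch + conditioned) vs full (+ locus) by F-test."""
    y = np.asarray(y, dtype=float)
    n = y.size
    N = np.hstack([batch_design(batch, n)] + [np.atleast_2d(c.T).T for c in conditioned])
    Qn = _orth_basis(N)
    Qf = _orth_basis(np.hstack([N, X_locus]))
    rank_n, rank_f = Qn.shape[1], Qf.shape[1]
    rss_null = float(y @ y - (Qn.T @ y) @ (Qn.T @ y))
    rss_full = float(y @ y - (Qf.T @ y) @ (Qf.T @ y))
    df_num = rank_f - rank_n
    df_den = n - rank_f
    if df_num < 1 or df_den < 1 or rss_null <= 0:
        return ModelFit(rss_null, rss_full, df_num, df_den, 0.0, 1.0, 0.0, testable=False)
    F = ((rss_null - rss_full) / df_num) / (rss_full / df_den) if rss_full > 0 else np.inf
    logp = float(_logp_from_f(F, df_num, df_den)) if np.isfinite(F) else -np.log10(_MIN_P)
    p = float(10.0 ** (-logp))
    return ModelFit(rss_null, rss_full, df_num, df_den, float(F), p, logp)


def effect_size_fixed(fit: ModelFit) -> float:
    """QTL effect size: fraction of null-model RSS explained by the QTL term."""
    if fit.rss_null <= 0:
        raise ValueError("null RSS is zero; effect size undefined")
    if not fit.testable:
        return 0.0
    return 1.0 - fit.rss_full / fit.rss_null


@dataclass
class ScanResult:
    """Per-locus logP for one trait under optional conditioning."""

    trait_id: str
    logp: np.ndarray
    locus_ids: np.ndarray
    conditioned: tuple[str, ...] = ()

    def peak(self) -> tuple[str, float]:
        i = int(np.argmax(self.logp))
        return str(self.locus_ids[i]), float(self.logp[i])

    def to_frame(self, locus_map: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"locus_id": self.locus_ids, "logp": self.logp})
        df.insert(0, "trait_id", self.trait_id)
        if locus_map is not None:
            df = df.merge(locus_map[["locus_id", "chrom", "pos_bp"]], on="locus_id")
        return df


class ScanEngine:
    """Vectorized multi-locus, multi-trait F-test scans against one null design.

    Parameters
    ----------
    fdm:
        Founder dosage matrix; each locus contributes its 8-column block.
        Alternatively pass ``blocks`` (a list of (n, k) arrays, e.g. 1-column
        variant dosages) together with a locus map.
    batch:
        Optional per-strain batch labels (categorical covariate).
    conditioned:
        Design blocks included in both null and full models (conditional
        scans of previously detected QTL).
    """

    def __init__(self, fdm: FounderDosageMatrix | None = None,
                 batch: np.ndarray | None = None,
                 conditioned: list[np.ndarray] | tuple = (),
                 blocks: list[np.ndarray] | None = None,
                 locus_map: pd.DataFrame | None = None):
        if fdm is not None:
            n = fdm.n_strains
            blocks_arr = fdm.dosages  # (n, L, 8)
            L = fdm.n_loci
            widths = np.full(L, blocks_arr.shape[2])
            X = blocks_arr.reshape(n, L * blocks_arr.shape[2])
            self.locus_map = fdm.locus_map
            self._fdm = fdm
        else:
            if blocks is None or locus_map is None:
                raise ValueError("provide either fdm or (blocks, locus_map)")
            n = blocks[0].shape[0]
            L = len(blocks)
            widths = np.array([b.shape[1] for b in blocks])
            X = np.hstack(blocks)
            self.locus_map = locus_map.reset_index(drop=True)
            self._fdm = None
        self.n = n
        self.n_loci = L
        N = np.hstack([batch_design(batch, n)] + [np.atleast_2d(c.T).T for c in conditioned])
        self.Q0 = _orth_basis(N)
        self.rank0 = self.Q0.shape[1]
        # residualize all locus blocks against the null design in one pass
        Xr = X - self.Q0 @ (self.Q0.T @ X)
        bases = []
        ranks = np.zeros(L, dtype=int)
        col = 0
        for l in range(L):
            k = widths[l]
            ref = float(np.linalg.norm(X[:, col:col + k]))
            U = _orth_basis(Xr[:, col:col + k], ref_scale=ref)
            ranks[l] = U.shape[1]
            if U.shape[1]:
                bases.append(U)
            col += k
        self.ranks = ranks
        self.Q = np.hstack(bases) if bases else np.zeros((n, 0))
        self.offsets = np.concatenate([[0], np.cumsum(ranks)])
        self.df_den = n - self.rank0 - ranks
        self.testable = (ranks > 0) & (self.df_den > 0)

    # ------------------------------------------------------------- internals
    def _proj_ss(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus explained SS and per-trait null RSS for trait columns Y (n, T)."""
        U0 = self.Q0.T @ Y
        rss0 = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", U0, U0)
        P2 = (self.Q.T @ Y) ** 2
        pos = np.flatnonzero(self.ranks > 0)
        ss = np.zeros((self.n_loci, Y.shape[1]))
        if pos.size:
            starts = self.offsets[pos]
            ss[pos] = np.add.reduceat(P2, starts, axis=0)
        return ss, rss0

    def _fstats(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss, rss0 = self._proj_ss(Y)
        rss1 = np.maximum(rss0[None, :] - ss, 0.0)
        r = np.maximum(self.ranks, 1)[:, None]
        d = np.maximum(self.df_den, 1)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / r) / (rss1 / d)
        F = np.where(self.testable[:, None], F, 0.0)
        F = np.where(np.isfinite(F), F, np.inf)
        return F, rss1

    # ----------------------------------------------------------------- scans
    def logp_matrix(self, Y: np.ndarray) -> np.ndarray:
        """logP for every locus (rows) and every trait column of Y (n, T)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        F, _ = self._fstats(Y)
        logp = np.zeros_like(F)
        for r, d in set(zip(self.ranks[self.testable], self.df_den[self.testable])):
            m = self.testable & (self.ranks == r) & (self.df_den == d)
            logp[m] = _logp_from_f(F[m], r, d)
        return logp

    def scan(self, y: np.ndarray, trait_id: str = "trait",
             loci: np.ndarray | None = None) -> ScanResult:
        """Scan one trait; ``loci`` restricts to a scope (index array)."""
        logp = self.logp_matrix(y[:, None])[:, 0]
        ids = self.locus_map["locus_id"].to_numpy()
        if loci is not None:
            logp, ids = logp[loci], ids[loci]
        return ScanResult(trait_id, logp, ids)

    def scope_indices(self, scope: str, chrom: str | None = None,
                      anchor_bp: float | None = None,
                      radius_bp: float = 10_000_000) -> np.ndarray:
        """Locus indices for a scope: 'genome', 'chromosome', or 'local'."""
        if scope == "genome":
            return np.arange(self.n_loci)
        ch = self.locus_map["chrom"].to_numpy().astype(str)
        on = np.flatnonzero(ch == str(chrom))
        if scope == "chromosome":
            return on
        if scope == "local":
            pos = self.locus_map["pos_bp"].to_numpy()[on]
            return on[np.abs(pos - anchor_bp) <= radius_bp]
        raise ValueError(f"unknown scope {scope!r}")

    def permutation_maxima(self, y: np.ndarray, orderings: np.ndarray,
                           scopes: dict[str, np.ndarray],
                           chunk: int = 512) -> dict[str, np.ndarray]:
        """Max logP per permutation within each scope's locus set.

        ``orderings`` is (n_perm, n); the trait vector is permuted against the
        fixed genotype/batch rows.  F statistics are reduced to per-scope,
        per-df-group maxima before the (expensive) tail evaluation.
        """
        n_perm = orderings.shape[0]
        out = {k: np.empty(n_perm) for k in scopes}
        groups = {}
        for name, idx in scopes.items():
            idx = idx[self.testable[idx]]
            key_list = []
            for r, d in set(zip(self.ranks[idx], self.df_den[idx])):
                sub = idx[(self.ranks[idx] == r) & (self.df_den[idx] == d)]
                key_list.append((r, d, sub))
            groups[name] = key_list
        for start in range(0, n_perm, chunk):
            sl = slice(start, min(start + chunk, n_perm))
            Y = y[orderings[sl]].T  # (n, chunk)
            F, _ = self._fstats(Y)
            for name, key_list in groups.items():
                best = np.full(Y.shape[1], 0.0)
                for r, d, sub in key_list:
                    fmax = F[sub].max(axis=0)
                    best = np.maximum(best, _logp_from_f(fmax, r, d))
                out[name][sl] = best
        return out


# ----------------------------------------------------------------------- BLUP

@dataclass
class EffectEstimate:
    """Shrunken (BLUP) founder haplotype effects at a locus.

    ``blup`` are the raw BLUPs; ``blup_scaled`` is the centered, unit-SD
    version used for cross-tissue correlation; ``tau2`` the REML haplotype
    variance; ``r2_fixed``/``r2_random`` the fixed-effect and shrunken
    effect-size estimates.
    """

    blup: np.ndarray
    blup_scaled: np.ndarray
    tau2: float
    sigma2: float
    r2_fixed: float
    r2_random: float
    ols: np.ndarray
    shrunk_to_zero: bool = False


def blup_effects(y: np.ndarray, X_locus: np.ndarray,
                 batch: np.ndarray | None = None,
                 conditioned: list[np.ndarray] | tuple = ()) -> EffectEstimate:
    """REML fit of the one-variance-component model beta ~ N(0, I tau^2).

    The fixed-effects haplotype vector is unstable (collinear dosages, rare
    founders), so effects are re-estimated as a random effect and reported as
    BLUPs, equivalent to ridge with penalty sigma^2/tau^2 on the residualized
    dosage design.  Returned centered then scaled to unit SD.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Z = np.asarray(X_locus, dtype=float)
    N = np.hstack([batch_design(batch, n)] + [np.atleast_2d(c.T).T for c in conditioned])
    Qw = _orth_basis(N)
    p = Qw.shape[1]
    Uz, sz, _ = np.linalg.svd(Z, full_matrices=False)
    d = sz ** 2  # eigenvalues of ZZ'

    yc = y - Qw @ (Qw.T @ y)
    rss0 = float(yc @ yc)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        shrink = lam * d / (1.0 + lam * d)
        def hinv(M):
            return M - Uz @ (shrink[:, None] * (Uz.T @ M))
        WtHiW = Qw.T @ hinv(Qw)
        WtHiy = Qw.T @ hinv(y[:, None])[:, 0]
        alpha = np.linalg.solve(WtHiW, WtHiy)
        r = y - Qw @ alpha
        quad = float(r @ hinv(r[:, None])[:, 0])
        sign, logdet_w = np.linalg.slogdet(WtHiW)
        logdet_h = float(np.sum(np.log1p(lam * d)))
        return 0.5 * ((n - p) * np.log(max(quad, 1e-300)) + logdet_h + logdet_w)

    grid = np.linspace(-12.0, 8.0, 33)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    lam = float(np.exp(res.x))
    if neg_reml(np.log(1e-12)) <= res.fun:  # boundary: no haplotype variance
        lam = 0.0

    # OLS (pseudo-inverse) effects on the residualized design, for comparison
    Zr = Z - Qw @ (Qw.T @ Z)
    ols = np.linalg.pinv(Zr, rcond=_RCOND) @ yc

    if lam == 0.0:
        sigma2 = rss0 / max(n - p, 1)
        fit = fit_locus_model(y, Z, batch=batch, conditioned=conditioned)
        return EffectEstimate(np.zeros(Z.shape[1]), np.zeros(Z.shape[1]), 0.0,
                              sigma2, effect_size_fixed(fit) if fit.rss_null > 0 else 0.0,
                              0.0, ols, shrunk_to_zero=True)

    shrink = lam * d / (1.0 + lam * d)
    def hinv(M):
        return M - Uz @ (shrink[:, None] * (Uz.T @ M))
    WtHiW = Qw.T @ hinv(Qw)
    alpha = np.linalg.solve(WtHiW, Qw.T @ hinv(y[:, None])[:, 0])
    r = y - Qw @ alpha
    hr = hinv(r[:, None])[:, 0]
    beta = lam * (Z.T @ hr)
    sigma2 = float(r @ hr) / max(n - p, 1)
    tau2 = lam * sigma2
    yhat = Qw @ alpha + Z @ beta
    rss_shrunk = float(np.sum((y - yhat) ** 2))
    r2_random = 1.0 - rss_shrunk / rss0 if rss0 > 0 else 0.0
    fit = fit_locus_model(y, Z, batch=batch, conditioned=conditioned)
    r2_fixed = effect_size_fixed(fit) if fit.rss_null > 0 else 0.0
    centered = beta - beta.mean()
    sd = centered.std(ddof=1)
    scaled = centered / sd if sd > 0 else centered
    return EffectEstimate(beta, scaled, tau2, sigma2, r2_fixed, r2_random, ols)


def variant_scan(y: np.ndarray, dosage_cols: np.ndarray, variant_ids,
                 batch: np.ndarray | None = None,
                 conditioned: list[np.ndarray] | tuple = (),
                 trait_id: str = "trait") -> ScanResult:
    """Association scan over imputed single-variant dosages (df_num = 1).

    Monomorphic variants are skipped (logP = 0); same model comparison as the
    haplotype scan with a one-column QTL term.
    """
    dosage_cols = np.asarray(dosage_cols, dtype=float)
    blocks = [dosage_cols[:, [j]] for j in range(dosage_cols.shape[1])]
    lm = pd.DataFrame({"locus_id": list(variant_ids),
                       "chrom": "NA", "pos_bp": np.arange(len(blocks))})
    eng = ScanEngine(blocks=blocks, locus_map=lm, batch=batch, conditioned=conditioned)
    return eng.scan(y, trait_id=trait_id)
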