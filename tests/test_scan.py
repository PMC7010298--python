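"""Locus-model fits, scan engine equivalence, BLUPs, variant association."""

import numpy as np
import pytest
from scipy.stats import f as f_dist, kstest

from ccqtlmed.scan import (ScanEngine, batch_design, blup_effects,
                           effect_size_fixed, fit_locus_model, variant_scan,
                           _orth_basis)
from ccqtlmed.synthetic_data import QTLPlant, TraitSpec, simulate_trait_panel


def _brute_force_logp(y, X_locus, batch=None, conditioned=()):
    """Independent two-model OLS + F oracle using lstsq ranks."""
    n = y.size
    N = np.hstack([batch_design(batch, n)] + [np.atleast_2d(c.T).T for c in conditioned])
    full = np.hstack([N, X_locus])
    def rss_rank(A):
        beta, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        return float(((y - A @ beta) ** 2).sum()), rank
    rss0, r0 = rss_rank(N)
    rss1, r1 = rss_rank(full)
    dfn, dfd = r1 - r0, n - r1
    if dfn < 1 or dfd < 1:
        return 0.0
    F = ((rss0 - rss1) / dfn) / (rss1 / dfd)
    return -np.log10(max(f_dist.sf(F, dfn, dfd), 1e-320))


def test_two_founder_worked_example():
    """n=4 two-group fit: RSS 1.04 -> 0.04, F(1,2)=50, R^2=0.9615."""
    y = np.array([1.1, 0.9, 0.1, -0.1])
    X = np.zeros((4, 8))
    X[:2, 0] = 2.0
    X[2:, 1] = 2.0
    fit = fit_locus_model(y, X)
    assert fit.rss_null == pytest.approx(1.04)
    assert fit.rss_full == pytest.approx(0.04)
    assert (fit.df_num, fit.df_den) == (1, 2)
    assert fit.fstat == pytest.approx(50.0)
    # exact F(1,2) tail: p = 1 - t/sqrt(t^2+2), t = sqrt(50)
    t = np.sqrt(50.0)
    assert fit.p == pytest.approx(1.0 - t / np.sqrt(t * t + 2.0), rel=1e-10)
    assert effect_size_fixed(fit) == pytest.approx(0.9615384615)


def test_constant_locus_is_untestable():
    y = np.random.default_rng(0).normal(size=10)
    X = np.zeros((10, 8))
    X[:, 2] = 2.0
    fit = fit_locus_model(y, X)
    assert not fit.testable and fit.logp == 0.0


def test_fit_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(12, 40))
        founders = rng.integers(0, 8, n)
        X = np.zeros((n, 8))
        X[np.arange(n), founders] = 2.0
        y = rng.normal(size=n)
        batch = rng.integers(0, 3, n) if rng.random() < 0.5 else None
        fit = fit_locus_model(y, X, batch=batch)
        assert fit.logp == pytest.approx(
            _brute_force_logp(y, X, batch=batch), abs=1e-8)


def test_engine_equals_per_locus_fits(small_fdm, small_batch):
    rng = np.random.default_rng(5)
    y = rng.normal(size=small_fdm.n_strains)
    engine = ScanEngine(small_fdm, batch=small_batch)
    logp = engine.logp_matrix(y[:, None])[:, 0]
    for i in [0, 17, 50, 99]:
        lid = small_fdm.locus_map["locus_id"].iloc[i]
        fit = fit_locus_model(y, small_fdm.locus_X(lid), batch=small_batch)
        assert logp[i] == pytest.approx(fit.logp, abs=1e-8)


def test_conditioning_never_increases_rss(small_fdm, small_batch):
    rng = np.random.default_rng(8)
    y = rng.normal(size=small_fdm.n_strains)
    X = small_fdm.locus_X("c1_0010")
    C = small_fdm.locus_X("c2_0010")
    plain = fit_locus_model(y, X, batch=small_batch)
    cond = fit_locus_model(y, X, batch=small_batch, conditioned=[C])
    assert cond.rss_null <= plain.rss_null + 1e-10
    assert cond.rss_full <= plain.rss_full + 1e-10


def test_null_pvalues_are_uniform(small_fdm):
    """Independent traits give uniform nominal p at a fixed polymorphic locus."""
    rng = np.random.default_rng(99)
    X = small_fdm.locus_X("c1_0030")
    ps = [fit_locus_model(rng.normal(size=small_fdm.n_strains), X).p
          for _ in range(1000)]
    assert kstest(ps, "uniform").pvalue > 0.01


def test_local_scope_is_inclusive(small_fdm):
    engine = ScanEngine(small_fdm)
    # loci at 1,3,...,99 Mb; anchor at 31 Mb catches 21..41 Mb inclusive
    idx = engine.scope_indices("local", "1", 31e6)
    pos = small_fdm.locus_map["pos_bp"].to_numpy()[idx]
    assert pos.min() == 21e6 and pos.max() == 41e6


# ---------------------------------------------------------------------- BLUPs

def test_blups_shrink_toward_zero_on_noise(small_fdm, small_batch):
    rng = np.random.default_rng(17)
    X = small_fdm.locus_X("c1_0025")
    taus, norms = [], []
    for _ in range(10):
        est = blup_effects(rng.normal(size=47), X, batch=small_batch)
        taus.append(est.tau2)
        norms.append(np.linalg.norm(est.blup))
    assert np.median(taus) < 0.05
    assert np.median(norms) < 0.3


def test_shrinkage_norm_inequality_always_holds(small_fdm, small_batch):
    rng = np.random.default_rng(23)
    for i in range(20):
        lid = small_fdm.locus_map["locus_id"].iloc[int(rng.integers(100))]
        y = rng.normal(size=47) + small_fdm.locus_X(lid) @ rng.normal(size=8) * 0.3
        est = blup_effects(y, small_fdm.locus_X(lid), batch=small_batch)
        assert np.linalg.norm(est.blup) <= np.linalg.norm(est.ols) + 1e-9


def test_blup_equals_ridge_solution(small_fdm, small_batch):
    rng = np.random.default_rng(31)
    lid = "c2_0040"
    y = rng.normal(size=47) + small_fdm.locus_X(lid) @ rng.normal(size=8) * 0.5
    est = blup_effects(y, small_fdm.locus_X(lid), batch=small_batch)
    assert est.tau2 > 0
    W = batch_design(small_batch, 47)
    Qw = _orth_basis(W)
    Z = small_fdm.locus_X(lid)
    Zr = Z - Qw @ (Qw.T @ Z)
    yr = y - Qw @ (Qw.T @ y)
    lam = est.tau2 / est.sigma2
    ridge = np.linalg.solve(Zr.T @ Zr + np.eye(8) / lam, Zr.T @ yr)
    np.testing.assert_allclose(est.blup, ridge, atol=1e-8)


def test_blup_recovers_planted_effects(small_fdm, small_batch):
    """Mean correlation with the planted 8-vector >= 0.95 at effect size 0.6."""
    lid = "c1_0025"
    rs = []
    for i in range(100):
        panel, truth = simulate_trait_panel(
            small_fdm, [TraitSpec("t", [QTLPlant(lid, effect_size=0.6)])],
            batch=small_batch, seed=1000 + i)
        est = blup_effects(panel.y("t"), small_fdm.locus_X(lid), batch=small_batch)
        rs.append(np.corrcoef(est.blup, truth.qtl[0]["beta"])[0, 1])
    assert np.mean(rs) >= 0.95


# --------------------------------------------------------------------- variant

def test_variant_scan_beats_haplotype_model_when_biallelic_truth(small_fdm):
    """If the trait is driven by a single founder contrast, the 1-df variant
    test at that contrast is at least as significant as the 7-df haplotype test."""
    rng = np.random.default_rng(3)
    lid = "c1_0020"
    X = small_fdm.locus_X(lid)
    allele = np.zeros(8)
    allele[5] = 1.0  # CAST-private variant
    dosage = X @ allele
    y = 0.8 * dosage + rng.normal(size=47)
    hap = fit_locus_model(y, X)
    var = variant_scan(y, dosage[:, None], ["v0"])
    assert var.logp[0] >= hap.logp - 1e-9


def test_variant_scan_skips_monomorphic():
    y = np.random.default_rng(0).normal(size=20)
    res = variant_scan(y, np.zeros((20, 1)), ["v_mono"])
    assert res.logp[0] == 0.0
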