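"""Permutation nulls, GEV tails, BH, and the L/C/G detection protocols."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import genextreme

from ccqtlmed.detect import (GEVNull, QTLCall, analysis_C, analysis_G,
                             analysis_L, bh_fdr, gev_pvalue, permutation_null,
                             permutation_orderings)
from ccqtlmed.scan import ScanEngine
from ccqtlmed.synthetic_data import (QTLPlant, TraitSpec, simulate_trait_panel)
from ccqtlmed.trait_prep import TraitMatrix, rint_matrix


def test_bh_hand_example_and_edge_cases():
    np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.04, 0.5])),
                               [0.04, 0.04, 0.04 * 4 / 3, 0.5])
    np.testing.assert_allclose(bh_fdr(np.array([0.3, 0.3, 0.3])), 0.3)
    np.testing.assert_allclose(bh_fdr(np.array([0.123])), 0.123)
    with pytest.raises(ValueError):
        bh_fdr(np.array([0.5, 1.2]))


def test_bh_qvalues_monotone_in_p():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_gev_mle_recovers_known_parameters():
    """MLE on 1000 draws from GEV(loc 3, scale 0.5, shape 0.1) within 15%."""
    rng = np.random.default_rng(77)
    # scipy's genextreme shape c corresponds to -xi for the standard GEV
    draws = genextreme.rvs(-0.1, loc=3.0, scale=0.5, size=1000, random_state=rng)
    null = GEVNull.fit(draws)
    assert null.fitted
    assert null.loc == pytest.approx(3.0, rel=0.15)
    assert null.scale == pytest.approx(0.5, rel=0.15)
    assert -null.shape == pytest.approx(0.1, abs=0.15 * 0.1 + 0.03)


def test_permp_is_monotone_and_tail_behaved():
    rng = np.random.default_rng(5)
    null = GEVNull.fit(rng.gumbel(3.0, 0.5, size=500))
    grid = np.linspace(0, 10, 50)
    permp = null.permp(grid)
    # non-increasing everywhere; strictly decreasing inside the GEV support
    assert (np.diff(permp) <= 0).all()
    interior = (permp[:-1] < 1) & (permp[1:] > 0)
    assert (np.diff(permp)[interior] < 0).all()
    assert null.permp(1e6) < 1e-12
    median = genextreme.ppf(0.5, null.shape, loc=null.loc, scale=null.scale)
    assert null.permp(float(median)) == pytest.approx(0.5, abs=1e-9)


def test_degenerate_maxima_fall_back_to_empirical():
    null = GEVNull.fit(np.full(300, 2.5))
    assert not null.fitted
    assert null.permp(3.0) == pytest.approx(1.0 / 301.0)
    assert null.permp(2.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gev_pvalue(GEVNull(scope="genome", extrema=np.array([])), 1.0)


def test_orderings_are_shared_and_deterministic():
    a = permutation_orderings(47, 50, 123)
    b = permutation_orderings(47, 50, 123)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (50, 47)
    assert all(np.sort(row).tolist() == list(range(47)) for row in a)


def test_permutation_null_tail_consistency(small_fdm, small_batch):
    rng = np.random.default_rng(2)
    y = rng.normal(size=47)
    engine = ScanEngine(small_fdm, batch=small_batch)
    orderings = permutation_orderings(47, 300, 9)
    null = permutation_null(y, engine, orderings, np.arange(small_fdm.n_loci))
    # permP of the largest recorded maximum is of order 1/n_perm
    assert null.permp(float(null.extrema.max())) < 2.0 / 300.0


def _panel(fdm, batch, specs, seed):
    panel, truth = simulate_trait_panel(fdm, specs, batch=batch, seed=seed)
    return rint_matrix(panel), truth


def test_analysis_L_detects_strong_local_qtl(small_fdm, small_batch):
    lid = "c1_0025"
    chrom, pos = small_fdm.locus_position(lid)
    orderings = permutation_orderings(47, 200, 31)
    engine = ScanEngine(small_fdm, batch=small_batch)
    hits = 0
    for i in range(10):
        panel, _ = _panel(small_fdm, small_batch,
                          [TraitSpec("t", [QTLPlant(lid, effect_size=0.6)])],
                          seed=400 + i)
        call = analysis_L(panel.y("t"), engine, (chrom, pos), orderings,
                          fdm=small_fdm, batch=small_batch)
        hits += call.detected
        assert call.permp_g is not None
    assert hits >= 8


def test_analysis_L_empty_window_returns_none(small_fdm, small_batch):
    engine = ScanEngine(small_fdm, batch=small_batch)
    call = analysis_L(np.random.default_rng(0).normal(size=47), engine,
                      ("17", 5e6), permutation_orderings(47, 120, 1))
    assert call is None


def test_analysis_C_scope_and_single_trait_q(small_fdm, small_batch):
    # trait anchored on chromosome 2 but QTL planted on chromosome 1
    lid = "c1_0025"
    panel, _ = _panel(small_fdm, small_batch,
                      [TraitSpec("t", [QTLPlant(lid, effect_size=0.6)],
                                 anchor_chrom="2", anchor_bp=50e6)], seed=77)
    engine = ScanEngine(small_fdm, batch=small_batch)
    orderings = permutation_orderings(47, 200, 13)
    calls = analysis_C(panel, engine, orderings, fdm=small_fdm, batch=small_batch)
    assert len(calls) == 1
    # scanning only the anchor chromosome misses the off-chromosome QTL...
    assert not calls[0].detected
    # ...and BH with one trait leaves q = permP_C
    assert calls[0].q == pytest.approx(calls[0].permp_c)


def test_analysis_C_detects_on_anchor_chromosome(small_fdm, small_batch):
    specs = [TraitSpec(f"q{i}", [QTLPlant("c2_0020", effect_size=0.6)])
             for i in range(3)]
    panel, _ = _panel(small_fdm, small_batch, specs, seed=55)
    engine = ScanEngine(small_fdm, batch=small_batch)
    orderings = permutation_orderings(47, 200, 17)
    calls = analysis_C(panel, engine, orderings, fdm=small_fdm, batch=small_batch)
    assert sum(c.detected for c in calls) == 3
    assert all(c.local for c in calls if c.detected)
    assert all(c.effect is not None for c in calls if c.detected)


def test_analysis_G_single_qtl_panel_rarely_reaches_stage_two(small_fdm, small_batch):
    """One-QTL traits: stage 1 recovers the planted locus; stage 2, whose
    conditional nulls are FDR-controlled across the panel, adds almost
    nothing."""
    specs = [TraitSpec(f"t{i}", [QTLPlant("c1_0030", effect_size=0.65)])
             for i in range(10)]
    panel, _ = _panel(small_fdm, small_batch, specs, seed=91)
    orderings = permutation_orderings(47, 200, 19)
    calls = analysis_G(panel, small_fdm, orderings, batch=small_batch)
    stage1 = [c for c in calls if c.stage == 1 and c.detected]
    stage2 = [c for c in calls if c.stage == 2 and c.detected]
    assert len(stage1) >= 8
    planted_pos = small_fdm.locus_position("c1_0030")[1]
    assert all(c.chrom == "1" and abs(c.pos_bp - planted_pos) <= 5e6
               for c in stage1)
    assert len(stage2) <= 2


def test_analysis_G_conditioning_nullifies_stage1_peak(small_fdm, small_batch):
    panel, _ = _panel(small_fdm, small_batch,
                      [TraitSpec("t", [QTLPlant("c2_0015", effect_size=0.65)])],
                      seed=93)
    orderings = permutation_orderings(47, 200, 23)
    calls = analysis_G(panel, small_fdm, orderings, batch=small_batch)
    peak = calls[0].locus_id
    engine2 = ScanEngine(small_fdm, batch=small_batch,
                         conditioned=[small_fdm.locus_X(peak)])
    logp2 = engine2.logp_matrix(panel.y("t")[:, None])[:, 0]
    i = small_fdm.locus_iloc(peak)
    assert logp2[i] == pytest.approx(0.0, abs=1e-9)
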