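"""Simulator: junction construction, truth consistency, determinism, distributions."""

import numpy as np
import pytest
from scipy import stats as sps

from tcrgamma import revcomp, sample_rearrangement, simulate_dataset
from tcrgamma.reference import UTR_SEQ
from tcrgamma.simulate import (
    SimulationConfig,
    TruthRecord,
    emit_paired_reads,
    is_productive_cdr3,
)


def reconstruct_amplicon(truth, db, cfg, barcode):
    """Rebuild the error-free amplicon from a truth record + germline db."""
    v, j = db[truth.v_id], db[truth.j_id]
    c = db.by_kind("C")[0]
    reps = -(-cfg.utr_len // len(UTR_SEQ))
    utr = (UTR_SEQ * reps)[: cfg.utr_len]
    return (utr + v.leader_nt + v.seq_nt[: len(v.seq_nt) - truth.v_trim]
            + truth.p_v + truth.n_insert + truth.p_j + j.seq_nt[truth.j_trim:]
            + c.seq_nt[: cfg.amplicon_c_prefix_len] + revcomp(barcode))


def test_germline_junction_reproduces_germline_cdr3(db, rng):
    cfg = SimulationConfig(p_nt_max=0, n_len_geom_p=0.999999, trim_geom_p=0.999999)
    mrna, truth = sample_rearrangement(cfg, db, rng)
    assert truth.v_trim == truth.j_trim == 0
    assert truth.n_insert == truth.p_v == truth.p_j == ""
    v, j = db[truth.v_id], db[truth.j_id]
    assert truth.cdr3_nt_truth == v.cdr3_germline_nt + j.cdr3_germline_nt
    assert truth.cdr3_nt_truth in mrna


def test_p_nucleotides_are_reverse_complement_of_segment_end(db, rng):
    cfg = SimulationConfig(p_nt_max=2, trim_geom_p=0.999999, n_len_geom_p=0.999999)
    seen_v = seen_j = False
    for _ in range(200):
        _, t = sample_rearrangement(cfg, db, rng)
        v, j = db[t.v_id], db[t.j_id]
        if t.p_v:
            assert t.p_v == revcomp(v.seq_nt[-len(t.p_v):])
            seen_v = True
        if t.p_j:
            assert t.p_j == revcomp(j.seq_nt[: len(t.p_j)])
            seen_j = True
    assert seen_v and seen_j


def test_p_nucleotides_forbidden_at_trimmed_ends():
    with pytest.raises(ValueError):
        TruthRecord("r", "s", "Vg1.2", "Jg1", v_trim=2, j_trim=0,
                    p_v="AC", n_insert="", p_j="", cdr3_nt_truth="",
                    productive_truth=False)


def test_trim_lengths_match_truncated_geometric_mean(db):
    """Empirical mean V-trim vs the closed-form mean of min(Geom(p), cap)."""
    p, cap = 0.3, 10
    cfg = SimulationConfig(trim_geom_p=p, trim_max=cap,
                           v_weights={"Vg3.7": 1.0},  # 17-nt tail: cap binds, not the tail
                           j_weights={"Jg3": 1.0},
                           n_sequences=10_000, seed=5)
    ds = simulate_dataset(cfg, db)
    trims = ds.truth["v_trim"].to_numpy()
    q = 1 - p
    expected_mean = sum(q ** k for k in range(1, cap + 1))
    expected_var = sum((2 * k - 1) * q ** k for k in range(1, cap + 1)) - expected_mean ** 2
    se = np.sqrt(expected_var / trims.size)
    assert abs(trims.mean() - expected_mean) < 3 * se


def test_truth_reconstruction_matches_emitted_amplicon(db, small_dataset):
    """Re-assembling the transcript from truth + germline reproduces the
    merged amplicon exactly (zero sequencing error)."""
    cfg, ds = small_dataset
    for r1, r2, t in zip(ds.r1[:100], ds.r2[:100],
                         ds.truth.head(100).itertuples(index=False)):
        amplicon = reconstruct_amplicon(t, db, cfg, cfg.barcodes[t.sample_id])
        overlap = len(r1.seq) + len(r2.seq) - len(amplicon)
        assert r1.seq == amplicon[:250]
        assert revcomp(r2.seq) == amplicon[-250:]
        assert overlap >= 10


def test_productive_truth_is_frame_and_stop_exact(small_dataset):
    _, ds = small_dataset
    for t in ds.truth.itertuples(index=False):
        assert t.productive_truth == is_productive_cdr3(t.cdr3_nt_truth)
        if t.productive_truth:
            assert len(t.cdr3_nt_truth) % 3 == 0


def test_identical_seed_gives_identical_output(db):
    cfg = SimulationConfig(n_sequences=50, seed=99)
    a = simulate_dataset(cfg, db)
    b = simulate_dataset(cfg, db)
    assert a.r1 == b.r1 and a.r2 == b.r2
    assert a.truth.equals(b.truth)


def test_concentrated_weights_yield_single_pair(db):
    cfg = SimulationConfig(vj_weights={("Vg2.13", "Jg1"): 1.0},
                           n_sequences=50, seed=3)
    ds = simulate_dataset(cfg, db)
    assert set(ds.truth["v_id"]) == {"Vg2.13"}
    assert set(ds.truth["j_id"]) == {"Jg1"}


def test_weights_must_cover_functional_segments_only(db, rng):
    cfg = SimulationConfig(v_weights={"Vg1.4": 1.0}, j_weights={"Jg1": 1.0})
    with pytest.raises(Exception, match="Vg1.4"):
        sample_rearrangement(cfg, db, rng)


def test_v_usage_chi2_goodness_of_fit(db):
    """Marginal V usage of truth records converges to configured weights."""
    weights = {"Vg1.2": 0.5, "Vg2.1": 0.3, "Vg3.1": 0.2}
    cfg = SimulationConfig(v_weights=weights, j_weights={"Jg1": 1.0},
                           n_sequences=10_000, seed=8)
    ds = simulate_dataset(cfg, db)
    counts = ds.truth["v_id"].value_counts()
    obs = [counts.get(v, 0) for v in weights]
    exp = [w * cfg.n_sequences for w in weights.values()]
    assert sps.chisquare(obs, exp).pvalue > 0.01


def test_substitution_errors_match_binomial_expectation(db):
    cfg = SimulationConfig(n_sequences=250, seed=21, subst_error_rate=0.01)
    noisy = simulate_dataset(cfg, db)
    n_sub = n_base = 0
    for r1, r2, t in zip(noisy.r1, noisy.r2, noisy.truth.itertuples(index=False)):
        amplicon = reconstruct_amplicon(t, db, cfg, cfg.barcodes[t.sample_id])
        for read, ref in ((r1.seq, amplicon[:250]), (r2.seq, revcomp(amplicon[-250:]))):
            n_sub += sum(x != y for x, y in zip(read, ref))
            n_base += len(read)
    expected = 0.01 * n_base
    se = np.sqrt(n_base * 0.01 * 0.99)
    assert abs(n_sub - expected) < 3 * se


def test_amplicon_outside_mergeable_range_rejected(db, rng):
    cfg = SimulationConfig()
    with pytest.raises(ValueError, match="amplicon length"):
        emit_paired_reads("A" * 500, cfg, rng)
    r1, r2 = emit_paired_reads("A" * 125 + "C" * 125, cfg, rng)
    assert r1.seq == "A" * 125 + "C" * 125
    assert r2.seq == revcomp("A" * 125 + "C" * 125)
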