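"""Generative simulator: determinism, steady-state closure, independence."""

import numpy as np
import pandas as pd
import pytest

from asnmd.effective_output import estimate_degradation_factor
from asnmd.simulate import (
    SimConfig,
    default_events,
    simulate_decay_course,
    simulate_development_course,
    simulate_nmd_ko_contrast,
    simulate_tissue_panel,
)
from asnmd.splicing import (
    FourIsoformCounts,
    compute_psi,
    conditional_inclusion,
    nmd_contrast_folds,
    psi_table,
)


def test_fixed_seed_is_byte_identical(tmp_path):
    cfg = SimConfig()
    d1 = simulate_tissue_panel(cfg, 17).write(tmp_path / "a")
    d2 = simulate_tissue_panel(cfg, 17).write(tmp_path / "b")
    for name in ("samples.tsv", "junctions.tsv", "expression.tsv", "truth.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    # a different seed changes the data
    d3 = simulate_tissue_panel(cfg, 18).write(tmp_path / "c")
    assert (d1 / "junctions.tsv").read_bytes() != (d3 / "junctions.tsv").read_bytes()


def test_noiseless_panel_reproduces_reference_group_means():
    """With noise off, steady-state totals and productive levels equal the
    configured group means and observed PSI matches the post-decay truth."""
    cfg = SimConfig(noiseless=True)
    res = simulate_tissue_panel(cfg, 0)
    merged = res.expression.merge(res.samples, on="sample_id")
    for group, expected_total in (("neural", 68.5), ("non_neural", 8.0)):
        sub = merged[merged["tissue_group"] == group]
        assert sub["tpm"].mean() == pytest.approx(expected_total, rel=1e-12)
    psi = psi_table(res.junctions)
    for tissue, truth in res.truth["tissues"].items():
        got = psi[(psi["sample_id"] == f"{tissue}_rep1") & (psi["event_id"] == "E8")].iloc[0]
        assert got["psi"] == pytest.approx(truth["psi8_steady_state"], rel=1e-12)


def test_post_decay_psi_matches_two_state_steady_state_oracle():
    """Transcription-level PSI 50 with a 7.7-fold degraded inclusion isoform
    gives steady-state PSI (50/7.7)/(50/7.7+50)*100 ≈ 11.49."""
    cfg = SimConfig(
        noiseless=True,
        total_tpm_mean={"neural": 100 * (0.5 + 0.5 / 7.7), "non_neural": 8.0},
        productive_tpm_mean={"neural": 50.0, "non_neural": 0.9},
    )
    res = simulate_tissue_panel(cfg, 0)
    truth = res.truth["tissues"]["cortex"]
    assert truth["psi8_transcription"] == pytest.approx(50.0, rel=1e-9)
    oracle = 100.0 * (50 / 7.7) / (50 / 7.7 + 50)
    assert truth["psi8_steady_state"] == pytest.approx(oracle, rel=1e-12)
    assert oracle == pytest.approx(11.4942528736, abs=1e-6)


def test_lambda_one_zero_noise_recovers_psi_exactly():
    cfg = SimConfig(
        noiseless=True,
        lambda_true=1.0,
        total_tpm_mean={"neural": 100.0, "non_neural": 100.0},
        productive_tpm_mean={"neural": 50.0, "non_neural": 50.0},
    )
    res = simulate_tissue_panel(cfg, 0)
    truth = res.truth["tissues"]["cortex"]
    # with lambda=1 observed total equals transcription and PSI is undistorted
    assert truth["total_tpm_steady_state"] == pytest.approx(truth["transcription_tpm"])
    psi = psi_table(res.junctions)
    got = psi[(psi["sample_id"] == "cortex_rep1") & (psi["event_id"] == "E8")].iloc[0]
    assert got["psi"] == pytest.approx(50.0, rel=1e-12)


def test_noiseless_junction_counts_are_even_in_molecule_units():
    res = simulate_tissue_panel(SimConfig(noiseless=True), 0)
    incl = res.junctions["incl_up"] + res.junctions["incl_down"]
    m_incl = incl / 2.0  # I = 2*m_incl by construction
    informative = m_incl + res.junctions["excl"]
    assert np.allclose(informative, SimConfig().junction_depth)


def test_nmd_ko_contrast_noiseless_fold_equals_lambda():
    for lam in (1.0, 7.7):
        cfg = SimConfig(noiseless=True, lambda_true=lam)
        res = simulate_nmd_ko_contrast(cfg, 3)
        psi = psi_table(res.junctions)
        folds = nmd_contrast_folds(psi, res.samples, "E8")
        assert folds == pytest.approx([lam] * len(folds), rel=1e-9)


def test_noisy_contrast_recovers_lambda_within_10_percent():
    cfg = SimConfig(lambda_true=7.7, junction_depth=500)
    estimates = []
    for seed in range(20):
        res = simulate_nmd_ko_contrast(cfg, seed)
        folds = nmd_contrast_folds(psi_table(res.junctions), res.samples, "E8")
        estimates.append(estimate_degradation_factor(folds).value)
    pooled = float(np.exp(np.mean(np.log(estimates))))
    assert pooled == pytest.approx(7.7, rel=0.10)


def test_development_course_trajectories_and_independence():
    cfg = SimConfig(noiseless=True)
    res = simulate_development_course(cfg, 5)
    psi = psi_table(res.junctions).merge(res.samples, on="sample_id")
    stage_means = (
        psi.groupby(["stage", "event_id"])["psi"].mean().unstack().loc[list(cfg.stages)]
    )
    assert (np.diff(stage_means["E8"]) < 0).all()  # NMD exon falls
    assert (np.diff(stage_means["E10"]) > 0).all()  # coding exon rises
    # independence: conditional coding-exon inclusion equal in E8+/E8- mRNAs
    for _, row in res.four_isoform.iterrows():
        cond = conditional_inclusion(
            FourIsoformCounts(row["sample_id"], row["n_pp"], row["n_pm"], row["n_mp"], row["n_mm"])
        )
        assert cond["e10_given_e8pos"] == pytest.approx(cond["e10_given_e8neg"], abs=1e-9)


def test_e8_knockout_raises_total_expression():
    cfg = SimConfig(noiseless=True)
    wt = simulate_development_course(cfg, 5)
    ko = simulate_development_course(cfg, 5, e8_knockout=True)
    wt_tot = wt.expression.merge(wt.samples, on="sample_id").groupby("stage")["tpm"].mean()
    ko_tot = ko.expression.merge(ko.samples, on="sample_id").groupby("stage")["tpm"].mean()
    assert (ko_tot > wt_tot).all()  # removing the NMD drain raises steady state
    # largest relative gain at the earliest stage, where NMD-exon inclusion peaks
    gain = (ko_tot / wt_tot).loc[list(cfg.stages)]
    assert gain.iloc[0] == gain.max()


def test_decay_course_generation():
    exact = simulate_decay_course(4.3, sigma=0.0, seed=0)
    assert exact.fractions == pytest.approx(tuple(0.5 ** (t / 4.3) for t in exact.timepoints))
    noisy = simulate_decay_course(4.3, sigma=0.1, seed=0)
    assert noisy.fractions[0] == 1.0
    assert noisy.fractions != exact.fractions
    # the two reported half-lives diverge sharply by 12 h in a pure exponential
    short = simulate_decay_course(1.9, sigma=0.0, seed=0)
    long = simulate_decay_course(4.3, sigma=0.0, seed=0)
    assert short.fractions[4] == pytest.approx(0.0125, abs=5e-4)
    assert long.fractions[4] == pytest.approx(0.1446, abs=5e-4)
    with pytest.raises(ValueError):
        simulate_decay_course(4.3, sigma=-0.1)


def test_default_events_flags():
    ev = default_events()
    assert ev["E8"].nmd_on_inclusion and not ev["E8"].frameshift_on_skipping
    assert ev["E10"].frameshift_on_skipping and not ev["E10"].nmd_on_inclusion
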