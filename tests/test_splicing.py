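"""PSI estimation: molecule-oracle equivalence, monotonicity, joint analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from asnmd.splicing import (
    FLAG_LOW,
    FLAG_OK,
    FourIsoformCounts,
    average_psi_by_tissue,
    compute_psi,
    conditional_inclusion,
    nmd_contrast_folds,
    nmd_fold_change,
    nmd_ratio,
    psi_table,
)


@pytest.mark.parametrize(
    "incl,excl,expected",
    [
        (0, 10, 0.0),  # no inclusion evidence
        (20, 0, 100.0),  # no exclusion evidence
        # 15 inclusion molecules -> 30 inclusive reads; 15 exclusion molecules
        # -> 15 exclusive reads; true inclusion fraction 15/30 = 50%
        (30, 15, 50.0),
    ],
)
def test_psi_worked_examples(incl, excl, expected):
    est = compute_psi(incl, excl)
    assert est.psi == pytest.approx(expected)
    assert est.exclusion == pytest.approx(100.0 - expected)


def test_psi_zero_coverage_is_undefined_not_an_error():
    est = compute_psi(0, 0)
    assert math.isnan(est.psi)
    assert est.flag == FLAG_LOW


def test_psi_rejects_negative_counts():
    with pytest.raises(ValueError):
        compute_psi(-1, 5)


def test_low_coverage_flag_matches_informative_threshold():
    # informative reads = 0.5*I + E
    assert compute_psi(10, 4, min_informative=10).flag == FLAG_LOW  # 9 < 10
    assert compute_psi(12, 4, min_informative=10).flag == FLAG_OK  # 10 >= 10


@given(
    m_incl=st.integers(min_value=0, max_value=10_000),
    m_excl=st.integers(min_value=0, max_value=10_000),
)
def test_molecule_oracle_equivalence(m_incl, m_excl):
    """Each inclusion molecule yields two inclusion junction reads, so
    PSI(2*m_incl, m_excl) must equal the true molecule inclusion fraction."""
    est = compute_psi(2 * m_incl, m_excl, min_informative=1)
    if m_incl + m_excl == 0:
        assert math.isnan(est.psi)
    else:
        assert est.psi == pytest.approx(100.0 * m_incl / (m_incl + m_excl), abs=1e-12)


@given(
    i=st.integers(min_value=0, max_value=1000),
    e=st.integers(min_value=1, max_value=1000),
    di=st.integers(min_value=1, max_value=100),
)
def test_psi_monotone_in_counts(i, e, di):
    base = compute_psi(i, e).psi
    assert compute_psi(i + di, e).psi >= base  # non-decreasing in I
    assert compute_psi(i, e + di).psi <= base  # non-increasing in E


def test_psi_table_matches_scalar_path(junction_tsv):
    from asnmd.data_model import read_junctions

    junctions = read_junctions(junction_tsv)
    table = psi_table(junctions, min_informative=10)
    for _, row in table.iterrows():
        jr = junctions[
            (junctions["sample_id"] == row["sample_id"]) & (junctions["event_id"] == row["event_id"])
        ].iloc[0]
        est = compute_psi(jr["incl_up"] + jr["incl_down"], jr["excl"], 10)
        assert row["psi"] == pytest.approx(est.psi, nan_ok=True)
        assert row["flag"] == est.flag


def test_statistical_consistency_at_depth_500():
    """Binomial junction sampling at >=500 informative reads keeps the mean
    absolute PSI error under 3 percentage points (200 replicates)."""
    rng = np.random.default_rng(2024)
    true_psi = 37.0
    errors = []
    for _ in range(200):
        n = 500
        m_incl = rng.binomial(n, true_psi / 100.0)
        est = compute_psi(2 * m_incl, n - m_incl)
        errors.append(abs(est.psi - true_psi))
    assert np.mean(errors) < 3.0


def test_replicate_averaging_excludes_undefined(samples_tsv):
    from asnmd.data_model import read_samples

    samples = read_samples(samples_tsv)
    psi = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "event_id": ["E8", "E8"],
            "psi": [40.0, np.nan],
            "exclusion": [60.0, np.nan],
            "informative_reads": [100.0, 0.0],
            "flag": ["ok", "low_coverage"],
        }
    )
    out = average_psi_by_tissue(psi, samples)
    cortex = out[out["tissue"] == "cortex"].iloc[0]
    liver = out[out["tissue"] == "liver"].iloc[0]
    assert cortex["psi"] == 40.0
    assert math.isnan(liver["psi"])  # NaN excluded, not zero-filled


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((0, 10, 5, 5), {"e10_given_e8pos": 0.0}),
        ((10, 0, 10, 0), {"e10_given_e8pos": 100.0, "e10_given_e8neg": 100.0}),
        (
            (30, 70, 60, 40),
            {"e10_given_e8pos": 30.0, "e10_given_e8neg": 60.0, "marginal_e10": 45.0},
        ),
    ],
)
def test_conditional_inclusion_examples(counts, expected):
    result = conditional_inclusion(FourIsoformCounts("s", *counts))
    for key, val in expected.items():
        assert result[key] == pytest.approx(val)


@given(
    counts=st.tuples(*[st.floats(min_value=0, max_value=1e4)] * 4).filter(lambda c: sum(c) > 0)
)
def test_marginals_reproduce_psi_on_collapsed_counts(counts):
    c = FourIsoformCounts("s", *counts)
    res = conditional_inclusion(c)
    # marginal E10 equals PSI computed on collapsed inclusion/exclusion molecules
    incl = c.n_pp + c.n_mp
    excl = c.n_pm + c.n_mm
    expected = compute_psi(2 * incl, excl, min_informative=1).psi
    assert res["marginal_e10"] == pytest.approx(expected, nan_ok=True, abs=1e-9)


def test_conditional_zero_denominator_is_nan():
    res = conditional_inclusion(FourIsoformCounts("s", 0, 0, 3, 1))
    assert math.isnan(res["e10_given_e8pos"])
    assert res["e10_given_e8neg"] == pytest.approx(75.0)


def test_nmd_fold_change_examples():
    assert nmd_fold_change(0.4, 0.4) == pytest.approx(1.0)
    assert nmd_fold_change(2.0, 0.25) == pytest.approx(8.0)
    # ratio-of-ratios from isoform levels
    assert nmd_fold_change(nmd_ratio(20, 10), nmd_ratio(2, 10)) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        nmd_fold_change(1.0, 0.0)


def test_nmd_contrast_folds_pairs_by_stage_and_replicate():
    samples = pd.DataFrame(
        {
            "sample_id": ["wt1", "ko1", "wt2", "ko2"],
            "condition": ["WT", "NMD_KO", "WT", "NMD_KO"],
            "stage": ["E14.5", "E14.5", "P1", "P1"],
            "replicate": [1, 1, 1, 1],
        }
    )
    # WT psi 20 -> ratio 0.25; KO psi 50 -> ratio 1.0 => fold 4
    psi = pd.DataFrame(
        {
            "sample_id": ["wt1", "ko1", "wt2", "ko2"],
            "event_id": ["E8"] * 4,
            "psi": [20.0, 50.0, 20.0, 50.0],
        }
    )
    folds = nmd_contrast_folds(psi, samples, "E8")
    assert folds == pytest.approx([4.0, 4.0])
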