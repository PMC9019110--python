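"""Percent-spliced-in (PSI) estimation from splice-junction reads.

Each molecule that includes the cassette exon contributes two inclusion
junction reads (upstream-exon→cassette and cassette→downstream), while a
skipping molecule contributes a single exclusion junction read.  PSI
therefore weights the inclusion count by 0.5:

    PSI = 100 * (0.5*I) / (0.5*I + E)

so that for an idealized molecule population (m_incl, m_excl) with
I = 2*m_incl and E = m_excl the estimate equals the true inclusion
fraction m_incl/(m_incl+m_excl) exactly.  The informative-read depth of
an estimate is 0.5*I + E (the molecule-equivalent coverage).

Also provides the four-isoform joint analysis for a gene with two
cassette exons (conditional exon-10 inclusion given exon-8 status) and
the NMD-isoform normalization statistic used in NMD-pathway knockout
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PsiEstimate",
    "FourIsoformCounts",
    "compute_psi",
    "psi_table",
    "average_psi_by_tissue",
    "conditional_inclusion",
    "nmd_ratio",
    "nmd_fold_change",
]

FLAG_OK = "ok"
FLAG_LOW = "low_coverage"


@dataclass(frozen=True)
class PsiEstimate:
    sample_id: str
    event_id: str
    psi: float  # percent in [0, 100]; NaN when I = E = 0
    exclusion: float  # 100 - psi
    informative_reads: float  # 0.5*I + E
    flag: str  # "ok" | "low_coverage"


def compute_psi(
    inclusive_reads: float,
    exclusive_reads: float,
    min_informative: float = 10.0,
    sample_id: str = "",
    event_id: str = "",
) -> PsiEstimate:
    """Estimate PSI from inclusion (I) and exclusion (E) junction reads.

    Zero informative reads yield an undefined (NaN) PSI flagged
    ``low_coverage``, never an exception; negative counts are an error.
    """
    if inclusive_reads < 0 or exclusive_reads < 0:
        raise ValueError("junction read counts must be non-negative")
    informative = 0.5 * inclusive_reads + exclusive_reads
    if informative == 0:
        psi = float("nan")
    else:
        psi = 100.0 * (0.5 * inclusive_reads) / informative
    flag = FLAG_OK if informative >= min_informative else FLAG_LOW
    return PsiEstimate(
        sample_id=sample_id,
        event_id=event_id,
        psi=psi,
        exclusion=100.0 - psi,
        informative_reads=informative,
        flag=flag,
    )


def psi_table(junctions: pd.DataFrame, min_informative: float = 10.0) -> pd.DataFrame:
    """Per-(sample, event) PSI estimates from a loaded junction table.

    Expects the frame produced by :func:`asnmd.data_model.read_junctions`
    (columns ``sample_id, event_id, incl_up, incl_down, excl``).
    """
    incl = junctions["incl_up"].to_numpy(float) + junctions["incl_down"].to_numpy(float)
    excl = junctions["excl"].to_numpy(float)
    if (incl < 0).any() or (excl < 0).any():
        raise ValueError("junction read counts must be non-negative")
    informative = 0.5 * incl + excl
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(informative > 0, 100.0 * (0.5 * incl) / np.where(informative > 0, informative, 1.0), np.nan)
    return pd.DataFrame(
        {
            "sample_id": junctions["sample_id"].to_numpy(),
            "event_id": junctions["event_id"].to_numpy(),
            "psi": psi,
            "exclusion": 100.0 - psi,
            "informative_reads": informative,
            "flag": np.where(informative >= min_informative, FLAG_OK, FLAG_LOW),
        }
    )


def average_psi_by_tissue(psi: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-average PSI per (tissue, event).

    PSI is computed per replicate and then arithmetically averaged —
    replicates are never pooled at the read level.  Undefined PSIs are
    excluded from the mean rather than zero-filled.
    """
    merged = psi.merge(samples[["sample_id", "tissue", "tissue_group"]], on="sample_id")
    out = (
        merged.groupby(["tissue", "tissue_group", "event_id"], as_index=False)
        .agg(psi=("psi", "mean"), exclusion=("exclusion", "mean"), n_replicates=("psi", "size"))
    )
    return out


@dataclass(frozen=True)
class FourIsoformCounts:
    """Joint abundances of the four isoforms of a two-cassette-exon gene.

    ``n_pp, n_pm, n_mp, n_mm`` are the (E8+E10+, E8+E10−, E8−E10+,
    E8−E10−) abundances.  Real-valued abundances (e.g. densitometry) are
    accepted, not only integer counts.
    """

    sample_id: str
    n_pp: float
    n_pm: float
    n_mp: float
    n_mm: float

    def __post_init__(self) -> None:
        vals = (self.n_pp, self.n_pm, self.n_mp, self.n_mm)
        if any(v < 0 for v in vals):
            raise ValueError("isoform abundances must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one isoform abundance must be positive")


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def conditional_inclusion(counts: FourIsoformCounts) -> dict[str, float]:
    """Conditional and marginal inclusion percentages from joint abundances.

    Returns ``e10_given_e8pos`` (= n_pp/(n_pp+n_pm)), ``e10_given_e8neg``
    (= n_mp/(n_mp+n_mm)), and the marginal inclusion percentages of each
    exon.  A zero denominator makes the corresponding conditional NaN.
    The marginals are the abundance-weighted combinations of the
    conditionals, so they reproduce PSI on the collapsed counts.
    """
    total = counts.n_pp + counts.n_pm + counts.n_mp + counts.n_mm
    e8pos = counts.n_pp + counts.n_pm
    e8neg = counts.n_mp + counts.n_mm
    return {
        "e10_given_e8pos": _pct(counts.n_pp, e8pos),
        "e10_given_e8neg": _pct(counts.n_mp, e8neg),
        "marginal_e8": _pct(e8pos, total),
        "marginal_e10": _pct(counts.n_pp + counts.n_mp, total),
    }


def nmd_ratio(nmd_level: float, non_nmd_level: float, sample_id: str = "") -> float:
    """NMD-isoform level normalized by the non-NMD (productive) isoform level."""
    if non_nmd_level <= 0:
        raise ValueError("non-NMD isoform level must be positive")
    if nmd_level < 0:
        raise ValueError("NMD isoform level must be non-negative")
    return nmd_level / non_nmd_level


def nmd_fold_change(ratio_case: float, ratio_control: float) -> float:
    """Fold change of the NMD/non-NMD ratio between a case (e.g. an
    NMD-pathway knockout) and its control; equals 1 when they match."""
    if ratio_control <= 0:
        raise ValueError("control NMD ratio must be positive")
    if ratio_case < 0:
        raise ValueError("case NMD ratio must be non-negative")
    return ratio_case / ratio_control


def nmd_contrast_folds(
    psi: pd.DataFrame,
    samples: pd.DataFrame,
    event_id: str,
    case_condition: str = "NMD_KO",
    control_condition: str = "WT",
) -> list[float]:
    """Per-pair NMD-ratio fold-changes from a paired knockout contrast.

    For the NMD-inducing event, the NMD/non-NMD isoform level ratio within
    a sample is psi/(100−psi) (the total TPM cancels).  Samples are paired
    by (stage, replicate); each pair contributes ratio_case/ratio_control.
    These folds feed :func:`asnmd.effective_output.estimate_degradation_factor`.
    """
    merged = psi[psi["event_id"] == event_id].merge(
        samples[["sample_id", "condition", "stage", "replicate"]], on="sample_id"
    )
    merged = merged.dropna(subset=["psi"])
    merged["ratio"] = merged["psi"] / (100.0 - merged["psi"])
    wide = merged.pivot_table(
        index=["stage", "replicate"], columns="condition", values="ratio", aggfunc="first"
    )
    if case_condition not in wide.columns or control_condition not in wide.columns:
        raise ValueError("contrast requires both case and control samples")
    paired = wide.dropna(subset=[case_condition, control_condition])
    if paired.empty:
        raise ValueError("no complete case/control pairs found")
    return [
        nmd_fold_change(row[case_condition], row[control_condition])
        for _, row in paired.iterrows()
    ]
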