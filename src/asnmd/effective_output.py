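"""Isoform-level effective expression and NMD-corrected transcriptional output.

Steady-state TPM of a gene with an NMD-inducing cassette exon
underestimates its transcription: the inclusion (PTC-bearing) isoform is
degraded λ-fold more efficiently than the productive skipping isoform.
This module decomposes total TPM into isoform-level outputs using the
exon PSIs,

    productive_tpm  = total_tpm * exclusion(NMD exon)/100
    nmd_tpm         = total_tpm - productive_tpm
    coding_long_tpm = total_tpm * inclusion(coding exon)/100

estimates λ from NMD-deficient vs control fold-changes of the NMD/non-NMD
isoform ratio, and reconstructs the NMD-corrected transcriptional output

    corrected = productive_tpm + λ * nmd_tpm

i.e. the expression the gene would show had the NMD isoform not been
degraded.  The correction is linear, so it commutes with group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegradationFactor",
    "GroupComparison",
    "isoform_tpm",
    "decompose",
    "estimate_degradation_factor",
    "corrected_output",
    "group_fold_change",
]

MODE_PRODUCTIVE = "exclusion_productive"
MODE_CODING = "inclusion_coding"


@dataclass(frozen=True)
class DegradationFactor:
    """Fold by which the NMD isoform is degraded relative to the productive one."""

    value: float
    method: str
    inputs: tuple[float, ...]

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    fold: float
    fold_nearest_int: float
    fold_nearest_ten: float


def isoform_tpm(total_tpm: float, psi: float, mode: str) -> float:
    """Isoform-level TPM from total TPM and an exon PSI (percent).

    ``exclusion_productive`` returns total*(100−psi)/100 (the
    NMD-exon-skipping, productive isoform); ``inclusion_coding`` returns
    total*psi/100 (the coding-exon-including isoform).  An undefined PSI
    (NaN) propagates to NaN.
    """
    if total_tpm < 0:
        raise ValueError("total_tpm must be non-negative")
    if np.isnan(psi):
        return float("nan")
    if not 0.0 <= psi <= 100.0:
        raise ValueError("psi must lie in [0, 100]")
    if mode == MODE_PRODUCTIVE:
        return total_tpm * (100.0 - psi) / 100.0
    if mode == MODE_CODING:
        return total_tpm * psi / 100.0
    raise ValueError(f"unknown mode {mode!r}")


def decompose(
    expression: pd.DataFrame,
    psi: pd.DataFrame,
    nmd_event: str,
    coding_event: str,
    lam: "DegradationFactor | float | None" = None,
) -> pd.DataFrame:
    """Per-sample isoform decomposition of steady-state TPM.

    ``expression`` carries (sample_id, gene_id, tpm); ``psi`` is the
    per-sample PSI table for both events.  Returns one row per sample
    with total, productive (NMD-exon exclusion), nmd, and coding-long
    (coding-exon inclusion) TPM; when ``lam`` is given the NMD-corrected
    output column is included.  Conservation productive+nmd=total holds
    exactly whenever the NMD-exon PSI is defined.
    """
    wide = psi.pivot_table(index="sample_id", columns="event_id", values="psi", aggfunc="first")
    for ev in (nmd_event, coding_event):
        if ev not in wide.columns:
            wide[ev] = np.nan
    out = expression[["sample_id", "gene_id", "tpm"]].rename(columns={"tpm": "total_tpm"}).copy()
    out = out.merge(wide[[nmd_event, coding_event]], left_on="sample_id", right_index=True, how="left")
    out["productive_tpm"] = out["total_tpm"] * (100.0 - out[nmd_event]) / 100.0
    out["nmd_tpm"] = out["total_tpm"] - out["productive_tpm"]
    out["coding_long_tpm"] = out["total_tpm"] * out[coding_event] / 100.0
    out = out.rename(columns={nmd_event: "psi_nmd_exon", coding_event: "psi_coding_exon"})
    if lam is not None:
        out["corrected_output"] = corrected_output(
            out["total_tpm"].to_numpy(), out["productive_tpm"].to_numpy(), lam
        )
    return out


def estimate_degradation_factor(
    fold_changes: Sequence[float], method: str = "geometric"
) -> DegradationFactor:
    """Aggregate NMD-deficient-vs-control fold-changes into one λ estimate.

    Each fold-change is the NMD/non-NMD isoform ratio in an NMD-deficient
    sample divided by the matched control ratio; under the model its
    expectation is λ itself.  The default aggregation is the geometric
    mean (fold-changes are ratios); the arithmetic mean is also exposed.
    """
    folds = tuple(float(f) for f in fold_changes)
    if not folds:
        raise ValueError("fold_changes must be non-empty")
    if any(f <= 0 for f in folds):
        raise ValueError("fold_changes must all be positive")
    if method == "geometric":
        value = float(np.exp(np.mean(np.log(folds))))
    elif method == "arithmetic":
        value = float(np.mean(folds))
    else:
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    return DegradationFactor(value=value, method=method, inputs=folds)


def corrected_output(total_tpm, productive_tpm, lam) -> np.ndarray | float:
    """NMD-corrected transcriptional output: productive + λ·(total − productive).

    Accepts scalars or arrays; λ may be a float or a
    :class:`DegradationFactor`.  Requires 0 ≤ productive ≤ total and λ ≥ 1.
    """
    lam_v = float(lam)
    if lam_v < 1.0:
        raise ValueError("degradation factor must be >= 1")
    total = np.asarray(total_tpm, dtype=float)
    prod = np.asarray(productive_tpm, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(prod > total + 1e-9 * np.maximum(1.0, np.abs(total))):
            raise ValueError("productive_tpm cannot exceed total_tpm")
        if np.any(prod < -1e-12):
            raise ValueError("productive_tpm must be non-negative")
    out = prod + lam_v * (total - prod)
    if np.isscalar(total_tpm) or np.ndim(total_tpm) == 0:
        return float(out)
    return out


def group_fold_change(
    values_a: Iterable[float], values_b: Iterable[float], metric: str = ""
) -> GroupComparison:
    """Fold-change of group means (mean_a / mean_b) with reporting roundings.

    Alongside the full-precision fold the comparison carries the fold
    rounded to the nearest integer and to the nearest ten, the two
    precisions used when quoting such contrasts.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = float(np.nanmean(a))
    mean_b = float(np.nanmean(b))
    if mean_b == 0:
        raise ValueError("denominator group mean is zero")
    fold = mean_a / mean_b
    return GroupComparison(
        metric=metric,
        mean_a=mean_a,
        mean_b=mean_b,
        fold=fold,
        fold_nearest_int=float(round(fold)),
        fold_nearest_ten=float(round(fold / 10.0) * 10.0),
    )
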