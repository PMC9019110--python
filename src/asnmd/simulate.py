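"""Seeded generative simulator for every input the pipeline consumes.

The generative model mirrors the biology being quantified.  A gene
carries two cassette exons: an NMD exon whose inclusion routes the
transcript to degradation (λ-fold faster decay than the productive
isoform) and a coding exon whose inclusion/skipping switches the protein
isoform.  Per tissue *t* with transcription rate T_t and
transcription-level inclusion fractions p8, p10:

    productive steady state  = T_t · (1 − p8)
    NMD steady state         = T_t · p8 / λ
    observed total TPM       = productive + NMD   (× replicate noise)

RNA-seq measures steady-state RNA, so junction reads are sampled at the
*post-decay* isoform proportions — the steady-state inclusion fraction
of the NMD exon is (p8/λ) / (p8/λ + (1 − p8)), which is why steady-state
PSI understates transcription-level inclusion of an NMD target.  Each
inclusion molecule contributes two inclusion junction reads (I = 2·m_incl)
and each skipping molecule one exclusion read.  The coding exon is
simulated independently of the NMD exon by default (a dependence knob
exists); NMD removes E8+ transcripts irrespective of their coding-exon
status, so post-decay coding-exon inclusion equals its transcription
level.

Group-level defaults are expressed as the steady-state group means of
the reference adult-tissue panel (total 68.5/8.0 TPM, productive
35.6/0.9 TPM for neural/non-neural, coding-exon PSI 96/27, λ = 7.7);
transcription-level parameters are derived from these, so the noiseless
model reproduces those means exactly.  Dispersion parameters (tissue and
replicate lognormal σ, PSI beta concentration) are not reported by any
reference dataset and are package defaults chosen to give qualitatively
realistic spreads.

All draws derive from ``numpy.random.default_rng([seed, scenario])``
with a fixed per-scenario code, so scenarios can be regenerated
independently and identical (config, seed) pairs are bit-identical.
``noiseless=True`` switches every draw to its expectation (molecule-exact
mode, fractional junction counts allowed) for exact model-closure checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExonEvent, write_tsv
from .kinetics import DecayCourse

__all__ = [
    "SimConfig",
    "SimResult",
    "default_events",
    "simulate_tissue_panel",
    "simulate_nmd_ko_contrast",
    "simulate_development_course",
    "simulate_decay_course",
]

# fixed per-scenario seed-stream codes
_SCENARIO_CODE = {"panel": 1, "nmd_ko": 2, "development": 3, "decay": 4}

NEURAL_TISSUES = ("cortex", "cerebellum", "frontal_lobe")
NON_NEURAL_TISSUES = (
    "liver",
    "heart",
    "kidney",
    "lung",
    "spleen",
    "thymus",
    "stomach",
    "testis",
    "adrenal",
)


@dataclass
class SimConfig:
    """Generative parameters; defaults reproduce the reference study design."""

    gene_id: str = "Trim46"
    nmd_event: str = "E8"
    coding_event: str = "E10"

    neural_tissues: tuple[str, ...] = NEURAL_TISSUES
    non_neural_tissues: tuple[str, ...] = NON_NEURAL_TISSUES
    n_replicates: int = 2

    # group steady-state means (TPM); transcription-level params are derived
    total_tpm_mean: Mapping[str, float] = field(
        default_factory=lambda: {"neural": 68.5, "non_neural": 8.0}
    )
    productive_tpm_mean: Mapping[str, float] = field(
        default_factory=lambda: {"neural": 35.6, "non_neural": 0.9}
    )
    psi10_mean: Mapping[str, float] = field(
        default_factory=lambda: {"neural": 96.0, "non_neural": 27.0}
    )
    lambda_true: float = 7.7

    junction_depth: float = 500.0  # expected informative reads per event
    tissue_log_sigma: float = 0.3  # lognormal spread of transcription across tissues
    replicate_sigma: float = 0.2  # lognormal TPM replicate noise
    psi_concentration: float = 100.0  # beta concentration of per-tissue PSI

    # 5-stage differentiation course: NMD-exon PSI falls, coding-exon PSI rises
    stages: tuple[str, ...] = ("EB_D8", "DIV1", "DIV3", "DIV5", "DIV7")
    stage_psi8: tuple[float, ...] = (85.0, 70.0, 55.0, 40.0, 30.0)
    stage_psi10: tuple[float, ...] = (10.0, 25.0, 40.0, 55.0, 65.0)
    stage_transcription: float = 100.0
    exon_dependence: float = 0.0  # 0 = independent exons; ±1 shifts E10|E8+ vs E10|E8−

    # protein decay assay
    half_lives: Mapping[str, float] = field(
        default_factory=lambda: {"short_isoform": 1.9, "long_isoform": 4.3}
    )
    decay_timepoints: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)
    decay_sigma: float = 0.1
    synthesis_ratio: float = 1.0

    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.lambda_true < 1:
            raise ValueError("lambda_true must be >= 1")
        if self.junction_depth < 1:
            raise ValueError("junction_depth must be >= 1")
        for g in ("neural", "non_neural"):
            if not 0 <= self.psi10_mean[g] <= 100:
                raise ValueError("psi10 means must lie in [0, 100]")
            if not 0 <= self.productive_tpm_mean[g] <= self.total_tpm_mean[g]:
                raise ValueError("productive mean must lie in [0, total mean]")
        if len(self.stage_psi8) != len(self.stages) or len(self.stage_psi10) != len(self.stages):
            raise ValueError("stage trajectories must match the stage list length")

    # -- derived transcription-level ground truth -------------------------
    def transcription_params(self, group: str) -> tuple[float, float]:
        """(transcription rate T, transcription-level NMD-exon PSI) for a group.

        Inverts the steady-state model: T = productive + λ·(total − productive);
        transcription-level inclusion = λ·(total − productive)/T.
        """
        total = float(self.total_tpm_mean[group])
        prod = float(self.productive_tpm_mean[group])
        nmd_tx = self.lambda_true * (total - prod)
        t_rate = prod + nmd_tx
        psi8_tx = 100.0 * nmd_tx / t_rate if t_rate > 0 else 0.0
        return t_rate, psi8_tx

    def tissue_table(self) -> list[tuple[str, str]]:
        return [(t, "neural") for t in self.neural_tissues] + [
            (t, "non_neural") for t in self.non_neural_tissues
        ]


@dataclass
class SimResult:
    samples: pd.DataFrame
    junctions: pd.DataFrame
    expression: pd.DataFrame
    truth: dict
    four_isoform: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(self.samples, out / "samples.tsv")
        write_tsv(self.junctions, out / "junctions.tsv")
        write_tsv(self.expression, out / "expression.tsv")
        if self.four_isoform is not None:
            write_tsv(self.four_isoform, out / "four_isoform.tsv")
        (out / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        return out


def default_events(config: SimConfig | None = None) -> dict[str, ExonEvent]:
    """Event definitions for the simulated two-cassette-exon gene."""
    cfg = config or SimConfig()
    return {
        cfg.nmd_event: ExonEvent(
            event_id=cfg.nmd_event,
            gene_id=cfg.gene_id,
            chrom="chr3",
            exon_start=89_000_000,
            exon_end=89_000_100,
            strand="+",
            nmd_on_inclusion=True,
        ),
        cfg.coding_event: ExonEvent(
            event_id=cfg.coding_event,
            gene_id=cfg.gene_id,
            chrom="chr3",
            exon_start=89_002_000,
            exon_end=89_002_150,
            strand="+",
            frameshift_on_skipping=True,
        ),
    }


# ---------------------------------------------------------------------------
# draw helpers (every one collapses to its expectation in noiseless mode)


def _lognormal_factor(rng: np.random.Generator, sigma: float, noiseless: bool) -> float:
    if noiseless or sigma == 0:
        return 1.0
    # mean-one multiplicative noise
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def _beta_psi(rng: np.random.Generator, mean_pct: float, conc: float, noiseless: bool) -> float:
    mu = mean_pct / 100.0
    if noiseless or conc == np.inf or mu in (0.0, 1.0):
        return mean_pct
    a, b = mu * conc, (1.0 - mu) * conc
    return 100.0 * float(rng.beta(a, b))


def _junction_counts(
    rng: np.random.Generator, depth: float, incl_fraction: float, noiseless: bool
) -> tuple[float, float]:
    """Sample (I, E) at a given steady-state inclusion fraction.

    Molecule model: N informative molecules (Poisson at ``depth``), each
    inclusion molecule yields two inclusion junction reads, each skipping
    molecule one exclusion read.  In noiseless (molecule-exact) mode the
    expected, possibly fractional, counts are returned and I = 2·f·N is
    even in molecule units.
    """
    if noiseless:
        m_incl = depth * incl_fraction
        return 2.0 * m_incl, depth - m_incl
    n = rng.poisson(depth)
    m_incl = rng.binomial(n, incl_fraction) if n > 0 else 0
    return float(2 * m_incl), float(n - m_incl)


def _steady_state(t_rate: float, p8: float, lam: float) -> tuple[float, float]:
    """(productive, NMD) steady-state abundances from transcription-level p8."""
    productive = t_rate * (1.0 - p8 / 100.0)
    nmd = t_rate * (p8 / 100.0) / lam
    return productive, nmd


# ---------------------------------------------------------------------------
# scenarios


def simulate_tissue_panel(config: SimConfig, seed: int) -> SimResult:
    """Multi-tissue adult panel: expression, junction counts, metadata, truth."""
    rng = np.random.default_rng([seed, _SCENARIO_CODE["panel"]])
    cfg = config
    rows_s, rows_j, rows_e = [], [], []
    truth_tissues: dict[str, dict] = {}
    for tissue, group in cfg.tissue_table():
        t_mean, psi8_tx_mean = cfg.transcription_params(group)
        t_rate = t_mean * _lognormal_factor(rng, cfg.tissue_log_sigma, cfg.noiseless)
        psi8_tx = _beta_psi(rng, psi8_tx_mean, cfg.psi_concentration, cfg.noiseless)
        psi10 = _beta_psi(rng, cfg.psi10_mean[group], cfg.psi_concentration, cfg.noiseless)
        productive, nmd = _steady_state(t_rate, psi8_tx, cfg.lambda_true)
        total_ss = productive + nmd
        f8_ss = nmd / total_ss if total_ss > 0 else 0.0
        truth_tissues[tissue] = {
            "group": group,
            "transcription_tpm": t_rate,
            "psi8_transcription": psi8_tx,
            "psi8_steady_state": 100.0 * f8_ss,
            "psi10": psi10,
            "total_tpm_steady_state": total_ss,
            "productive_tpm": productive,
            "nmd_tpm": nmd,
        }
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{tissue}_rep{rep}"
            rows_s.append(
                {
                    "sample_id": sid,
                    "tissue": tissue,
                    "tissue_group": group,
                    "condition": "WT",
                    "stage": "adult",
                    "replicate": rep,
                }
            )
            tpm = total_ss * _lognormal_factor(rng, cfg.replicate_sigma, cfg.noiseless)
            rows_e.append({"sample_id": sid, "gene_id": cfg.gene_id, "tpm": tpm})
            i8, e8 = _junction_counts(rng, cfg.junction_depth, f8_ss, cfg.noiseless)
            i10, e10 = _junction_counts(rng, cfg.junction_depth, psi10 / 100.0, cfg.noiseless)
            rows_j.append(
                {"sample_id": sid, "event_id": cfg.nmd_event, "incl_up": i8 / 2.0, "incl_down": i8 / 2.0, "excl": e8}
            )
            rows_j.append(
                {"sample_id": sid, "event_id": cfg.coding_event, "incl_up": i10 / 2.0, "incl_down": i10 / 2.0, "excl": e10}
            )
    truth = {
        "scenario": "panel",
        "seed": seed,
        "lambda_true": cfg.lambda_true,
        "noiseless": cfg.noiseless,
        "tissues": truth_tissues,
    }
    junctions = pd.DataFrame(rows_j)
    junctions["combined"] = False
    return SimResult(
        samples=pd.DataFrame(rows_s),
        junctions=junctions,
        expression=pd.DataFrame(rows_e),
        truth=truth,
    )


def simulate_nmd_ko_contrast(config: SimConfig, seed: int) -> SimResult:
    """Paired WT vs NMD-pathway-knockout samples at two developmental stages.

    Knockout samples are generated with λ = 1 (no NMD), wild type with
    λ = λ*, sharing transcription rate and transcription-level PSIs, so
    the expected NMD-ratio fold-change (KO vs WT) equals λ* exactly in
    the noiseless limit.
    """
    cfg = config
    if cfg.lambda_true < 1:
        raise ValueError("lambda_true must be >= 1")
    rng = np.random.default_rng([seed, _SCENARIO_CODE["nmd_ko"]])
    t_mean, psi8_tx_mean = cfg.transcription_params("neural")
    rows_s, rows_j, rows_e = [], [], []
    truth_pairs = {}
    for stage in ("E14.5", "P1"):
        for rep in range(1, cfg.n_replicates + 1):
            t_rate = t_mean * _lognormal_factor(rng, cfg.tissue_log_sigma, cfg.noiseless)
            psi8_tx = _beta_psi(rng, psi8_tx_mean, cfg.psi_concentration, cfg.noiseless)
            psi10 = _beta_psi(rng, cfg.psi10_mean["neural"], cfg.psi_concentration, cfg.noiseless)
            truth_pairs[f"{stage}_rep{rep}"] = {
                "transcription_tpm": t_rate,
                "psi8_transcription": psi8_tx,
                "psi10": psi10,
            }
            for condition, lam in (("WT", cfg.lambda_true), ("NMD_KO", 1.0)):
                sid = f"{condition}_{stage}_rep{rep}"
                rows_s.append(
                    {
                        "sample_id": sid,
                        "tissue": "cortex",
                        "tissue_group": "neural",
                        "condition": condition,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
                productive, nmd = _steady_state(t_rate, psi8_tx, lam)
                total_ss = productive + nmd
                f8 = nmd / total_ss if total_ss > 0 else 0.0
                tpm = total_ss * _lognormal_factor(rng, cfg.replicate_sigma, cfg.noiseless)
                rows_e.append({"sample_id": sid, "gene_id": cfg.gene_id, "tpm": tpm})
                i8, e8 = _junction_counts(rng, cfg.junction_depth, f8, cfg.noiseless)
                i10, e10 = _junction_counts(rng, cfg.junction_depth, psi10 / 100.0, cfg.noiseless)
                rows_j.append(
                    {"sample_id": sid, "event_id": cfg.nmd_event, "incl_up": i8 / 2.0, "incl_down": i8 / 2.0, "excl": e8}
                )
                rows_j.append(
                    {"sample_id": sid, "event_id": cfg.coding_event, "incl_up": i10 / 2.0, "incl_down": i10 / 2.0, "excl": e10}
                )
    truth = {
        "scenario": "nmd_ko",
        "seed": seed,
        "lambda_true": cfg.lambda_true,
        "noiseless": cfg.noiseless,
        "pairs": truth_pairs,
    }
    junctions = pd.DataFrame(rows_j)
    junctions["combined"] = False
    return SimResult(
        samples=pd.DataFrame(rows_s),
        junctions=junctions,
        expression=pd.DataFrame(rows_e),
        truth=truth,
    )


def simulate_development_course(
    config: SimConfig, seed: int, e8_knockout: bool = False
) -> SimResult:
    """Five-stage differentiation course with opposing PSI trajectories.

    The NMD-exon PSI declines and the coding-exon PSI rises across the
    configured stages.  Four-isoform joint abundances are generated under
    exon independence by default (``exon_dependence`` shifts the
    conditional coding-exon inclusion in E8+ vs E8− transcripts).  With
    ``e8_knockout`` the NMD-exon inclusion is forced to zero, so observed
    total TPM exceeds the wild-type level (the NMD drain is removed).
    """
    cfg = config
    import warnings

    if any(np.diff(cfg.stage_psi8) > 0) or any(np.diff(cfg.stage_psi10) < 0):
        warnings.warn("stage trajectories are not monotone as configured", stacklevel=2)
    rng = np.random.default_rng([seed, _SCENARIO_CODE["development"], int(e8_knockout)])
    rows_s, rows_j, rows_e, rows_f = [], [], [], []
    truth_stages = {}
    condition = "E8_KO" if e8_knockout else "WT"
    for stage, psi8_cfg, psi10_cfg in zip(cfg.stages, cfg.stage_psi8, cfg.stage_psi10):
        psi8_tx = 0.0 if e8_knockout else psi8_cfg
        truth_stages[stage] = {"psi8_transcription": psi8_tx, "psi10": psi10_cfg}
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{condition}_{stage}_rep{rep}"
            rows_s.append(
                {
                    "sample_id": sid,
                    "tissue": "esc_neuron",
                    "tissue_group": "neural",
                    "condition": condition,
                    "stage": stage,
                    "replicate": rep,
                }
            )
            t_rate = cfg.stage_transcription
            psi8 = _beta_psi(rng, psi8_tx, cfg.psi_concentration, cfg.noiseless) if psi8_tx else 0.0
            psi10 = _beta_psi(rng, psi10_cfg, cfg.psi_concentration, cfg.noiseless)
            productive, nmd = _steady_state(t_rate, psi8, cfg.lambda_true)
            total_ss = productive + nmd
            f8 = nmd / total_ss if total_ss > 0 else 0.0
            # conditional coding-exon inclusion in E8+ vs E8− transcripts
            p10 = psi10 / 100.0
            shift = cfg.exon_dependence * min(p10, 1.0 - p10)
            p10_e8pos = np.clip(p10 + shift, 0.0, 1.0)
            p10_e8neg = np.clip(p10 - shift * (f8 / (1 - f8)) if f8 < 1 else p10, 0.0, 1.0)
            f10 = f8 * p10_e8pos + (1.0 - f8) * p10_e8neg
            tpm = total_ss * _lognormal_factor(rng, cfg.replicate_sigma, cfg.noiseless)
            rows_e.append({"sample_id": sid, "gene_id": cfg.gene_id, "tpm": tpm})
            i8, e8 = _junction_counts(rng, cfg.junction_depth, f8, cfg.noiseless)
            i10, e10 = _junction_counts(rng, cfg.junction_depth, f10, cfg.noiseless)
            rows_j.append(
                {"sample_id": sid, "event_id": cfg.nmd_event, "incl_up": i8 / 2.0, "incl_down": i8 / 2.0, "excl": e8}
            )
            rows_j.append(
                {"sample_id": sid, "event_id": cfg.coding_event, "incl_up": i10 / 2.0, "incl_down": i10 / 2.0, "excl": e10}
            )
            noise = _lognormal_factor(rng, cfg.replicate_sigma, cfg.noiseless)
            rows_f.append(
                {
                    "sample_id": sid,
                    "n_pp": nmd * p10_e8pos * noise,
                    "n_pm": nmd * (1.0 - p10_e8pos) * noise,
                    "n_mp": productive * p10_e8neg * noise,
                    "n_mm": productive * (1.0 - p10_e8neg) * noise,
                }
            )
    truth = {
        "scenario": "development",
        "seed": seed,
        "lambda_true": cfg.lambda_true,
        "noiseless": cfg.noiseless,
        "condition": condition,
        "stages": truth_stages,
        "stage_transcription": cfg.stage_transcription,
    }
    junctions = pd.DataFrame(rows_j)
    junctions["combined"] = False
    return SimResult(
        samples=pd.DataFrame(rows_s),
        junctions=junctions,
        expression=pd.DataFrame(rows_e),
        truth=truth,
        four_isoform=pd.DataFrame(rows_f),
    )


def simulate_decay_course(
    half_life: float,
    timepoints: Sequence[float] = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0),
    sigma: float = 0.1,
    seed: int = 0,
    label: str = "isoform",
) -> DecayCourse:
    """CHX-chase course: fraction(t) = 0.5^(t/t½) × lognormal noise, f(0)=1."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng([seed, _SCENARIO_CODE["decay"]])
    frac = 0.5 ** (t / half_life)
    if sigma > 0:
        frac = frac * rng.lognormal(mean=0.0, sigma=sigma, size=t.size)
    frac[0] = 1.0
    return DecayCourse(label=label, timepoints=tuple(t), fractions=tuple(frac))
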