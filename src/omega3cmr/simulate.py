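"""Synthetic imaging phantoms and trial cohorts with known ground truth.

Two generators make every pipeline stage testable without patient data:

- :func:`generate_phantom` builds inversion-recovery curves per AHA segment
  and blood pool at four contrast states (pre and 5/15/25 min post), with
  myocardial R1 tied to blood R1 exactly through a configured partition
  coefficient before noise, plus one LGE slice with a planted
  hyperenhanced region.
- :func:`generate_cohort` draws a randomized two-arm cohort whose genotype
  frequencies, ArA/LA distributions and per-(genotype, arm) 6-month endpoint
  changes default to the published trial summaries, with on-drug EPA/DHA
  rises coupled to the LVESVi change through a Gaussian copula.

Both emit their ground truth alongside the data so closure tests (estimate
vs truth) are direct.  All randomness flows from a single
``numpy.random.default_rng(seed)`` stream per generator call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecv import AHA16_SEGMENTS
from .exceptions import DomainError
from .infarct import LGESlice
from .relaxometry import IRCurve

# ---------------------------------------------------------------------------
# Imaging phantom
# ---------------------------------------------------------------------------

#: Contrast-state labels in acquisition order.
TIMEPOINTS = ("pre", "5min", "15min", "25min")


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth parameters for one imaging phantom.

    Blood T1 defaults approximate a 3 T study: native blood T1 1.9 s, then
    progressively recovering post-contrast values at 5/15/25 minutes.
    Myocardial R1 at each state is derived exactly as
    ``r1_myo = lambda_true * r1_blood + r1_intercept`` so the partition
    coefficient is recoverable by regression.  IR curves use a fixed
    amplitude ratio ``b_over_a`` (the Look-Locker correction factor is then
    ``b_over_a - 1``).
    """

    t1_blood_s: tuple[float, ...] = (1.90, 0.40, 0.55, 0.70)
    lambda_true: float = 0.45
    r1_intercept: float = 0.618  # gives native myocardial T1 ~= 1.17 s
    hct: float = 0.40
    a_amplitude: float = 1000.0
    b_over_a: float = 1.8
    inversion_times_s: tuple[float, ...] = tuple(np.round(np.arange(0.1, 3.01, 0.2), 3))
    noise_sd: float = 0.0
    grid_shape: tuple[int, int] = (64, 64)
    lge_remote_mean: float = 100.0
    lge_remote_sd: float = 5.0
    lge_positive_segments: tuple[str, ...] = ("mid_anterior", "mid_anteroseptal")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lambda_true < 1):
            raise DomainError("lambda_true must be in (0, 1)")
        if not (0 < self.hct < 1):
            raise DomainError("hct must be in (0, 1)")
        if self.b_over_a <= 1:
            raise DomainError("b_over_a must exceed 1 for a physical recovery")
        if self.a_amplitude <= 0 or self.lge_remote_sd <= 0:
            raise DomainError("amplitudes and remote SD must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if len(self.t1_blood_s) != len(TIMEPOINTS):
            raise DomainError(f"t1_blood_s must have {len(TIMEPOINTS)} entries")
        if any(t <= 0 for t in self.t1_blood_s):
            raise DomainError("blood T1 values must be positive")
        unknown = set(self.lge_positive_segments) - set(AHA16_SEGMENTS)
        if unknown:
            raise DomainError(f"unknown AHA segments: {sorted(unknown)}")


@dataclass(frozen=True)
class PhantomBundle:
    """Generated phantom: IR curves, LGE slice, and the ground-truth record."""

    curves: dict  # {timepoint: {label: IRCurve}}; labels are segments + "blood"
    lge: LGESlice
    infarct_region: np.ndarray  # planted hyperenhanced pixels (boolean grid)
    truth: dict


def _ir_curve(rng, label, t1_s, cfg: PhantomConfig) -> IRCurve:
    """Sample one IR curve with the configured amplitude ratio and noise."""
    a = cfg.a_amplitude
    b = cfg.b_over_a * a
    t1_star = t1_s / (cfg.b_over_a - 1.0)  # so the corrected T1 equals t1_s
    ti = np.asarray(cfg.inversion_times_s)
    signal = a - b * np.exp(-ti / t1_star)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=ti.size)
    return IRCurve(inversion_times=ti, signals=signal, label=label)


def generate_phantom(config: PhantomConfig) -> PhantomBundle:
    """Generate IR curves per segment/blood per contrast state plus an LGE slice.

    The LGE remote myocardium uses a deterministic two-level texture
    (mean +/- sd on alternating pixels) so its sample SD is well defined even
    in the noise-free phantom; the planted infarct sits at mean + 6 sd and
    Gaussian noise of ``noise_sd`` (scaled to the LGE intensity range) is
    added on top when configured.
    """
    rng = np.random.default_rng(config.seed)

    r1_blood = 1.0 / np.asarray(config.t1_blood_s)
    r1_myo = config.lambda_true * r1_blood + config.r1_intercept
    t1_myo = 1.0 / r1_myo

    curves: dict[str, dict[str, IRCurve]] = {}
    for tp, t1b, t1m in zip(TIMEPOINTS, config.t1_blood_s, t1_myo):
        curves[tp] = {"blood": _ir_curve(rng, "blood", t1b, config)}
        for seg in AHA16_SEGMENTS:
            curves[tp][seg] = _ir_curve(rng, seg, t1m, config)

    # LGE slice: myocardium is a central block, infarct a sub-block, remote the rest.
    nr, nc = config.grid_shape
    if nr < 16 or nc < 16:
        raise DomainError("grid_shape must be at least 16x16")
    myo = np.zeros((nr, nc), dtype=bool)
    r0, r1_, c0, c1 = nr // 4, 3 * nr // 4, nc // 4, 3 * nc // 4
    myo[r0:r1_, c0:c1] = True
    infarct = np.zeros_like(myo)
    infarct[r0 : r0 + (r1_ - r0) // 3, c0 : c0 + (c1 - c0) // 3] = True
    infarct &= myo
    remote = myo & ~infarct

    mean, sd = config.lge_remote_mean, config.lge_remote_sd
    rows, cols = np.indices((nr, nc))
    texture = np.where((rows + cols) % 2 == 0, mean - sd, mean + sd)
    img = np.zeros((nr, nc), dtype=float)
    img[remote] = texture[remote]
    img[infarct] = mean + 6.0 * sd
    if config.noise_sd > 0:
        # scale imaging noise to the LGE intensity range relative to the IR amplitude
        lge_noise = config.noise_sd * (mean / config.a_amplitude)
        img = img + rng.normal(0.0, lge_noise, size=img.shape)

    lge = LGESlice(
        pixel_intensities=img,
        myocardial_mask=myo,
        remote_mask=remote,
        pixel_area_mm2=1.0,
        slice_thickness_mm=8.0,
    )

    truth = {
        "lambda_true": config.lambda_true,
        "r1_intercept": config.r1_intercept,
        "hct": config.hct,
        "ecv_true": config.lambda_true * (1.0 - config.hct),
        "t1_blood_s": tuple(config.t1_blood_s),
        "t1_myo_s": tuple(float(t) for t in t1_myo),
        "a": config.a_amplitude,
        "b": config.b_over_a * config.a_amplitude,
        "t1_star_myo_s": tuple(float(t / (config.b_over_a - 1.0)) for t in t1_myo),
        "lge_threshold_floor": mean + 2.0 * sd,
        "n_infarct_pixels": int(infarct.sum()),
        "lge_positive_segments": tuple(config.lge_positive_segments),
        "seed": config.seed,
    }
    return PhantomBundle(curves=curves, lge=lge, infarct_region=infarct, truth=truth)


# ---------------------------------------------------------------------------
# Trial cohort
# ---------------------------------------------------------------------------

#: Per-endpoint (genotype -> (drug mean, drug SD, placebo mean, placebo SD))
#: 6-month changes.  Imaging endpoints and GG biomarkers follow the published
#: stratified summaries; AA/AG biomarker strata (reported only as "similar
#: between arms") use arm-similar values consistent with the overall cohort.
DEFAULT_EFFECTS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "lvesvi": {
        "AA": (-2.5, 6.7, -1.0, 8.3),
        "AG": (-3.6, 6.6, -1.2, 7.8),
        "GG": (-4.4, 5.6, 1.2, 4.1),
    },
    "lvedvi": {
        "AA": (-1.2, 12.4, -0.2, 13.2),
        "AG": (-2.9, 12.3, -0.6, 12.5),
        "GG": (-4.2, 9.5, 2.3, 8.3),
    },
    "ecv_noninfarct": {
        "AA": (-2.0, 5.2, -1.1, 4.2),
        "AG": (-1.0, 5.6, 3.1, 7.8),
        "GG": (2.0, 5.3, -2.9, 2.0),
    },
    "infarct_size": {
        "AA": (-3.4, 8.2, -1.3, 7.1),
        "AG": (0.03, 5.4, -1.6, 6.4),
        "GG": (-1.8, 9.7, -3.5, 10.2),
    },
    "lvef": {
        "AA": (2.3, 5.8, 1.1, 6.5),
        "AG": (2.8, 4.9, 1.1, 7.1),
        "GG": (2.4, 4.6, 0.02, 4.8),
    },
    "ntprobnp": {
        "AA": (-560.0, 1000.0, -560.0, 1350.0),
        "AG": (-560.0, 1000.0, -560.0, 1350.0),
        "GG": (-733.0, 672.0, -181.0, 139.0),
    },
    "galectin3": {
        "AA": (-0.6, 4.8, -0.1, 3.5),
        "AG": (-0.6, 4.8, -0.1, 3.5),
        "GG": (-1.96, 4.16, 0.51, 3.97),
    },
    "lipoprotein_a": {
        "AA": (-1.0, 8.0, 0.2, 8.0),
        "AG": (-4.0, 8.0, 0.2, 8.0),
        "GG": (-8.4, 7.62, 0.43, 8.26),
    },
    "hscrp": {
        "AA": (-0.2, 3.0, -0.1, 3.0),
        "AG": (-0.2, 3.0, -0.1, 3.0),
        "GG": (-0.2, 3.0, -0.1, 3.0),
    },
}

#: ArA/LA ratio (mean, SD) by genotype: the product/precursor gradient of
#: desaturase activity across rs1535 genotypes.
DEFAULT_ARALA: dict[str, tuple[float, float]] = {
    "AA": (2.01, 0.36),
    "AG": (1.76, 0.35),
    "GG": (1.62, 0.35),
}

#: 6-month fatty-acid changes (mean, SD) per arm, percent of RBC fatty acids.
DEFAULT_FA_RISES = {
    "epa": {"drug": (2.4, 1.3), "placebo": (0.0, 0.4)},
    "dha": {"drug": (2.0, 1.3), "placebo": (0.0, 0.5)},
}

#: Racial category frequencies of the cohort.
DEFAULT_RACE_PROBS = {"Caucasian": 0.81, "Hispanic": 0.07, "Black": 0.07, "other": 0.05}

#: Baseline distributions (mean, SD, lower clip) for normal draws and
#: (log-median, log-SD) for log-normal draws.
_BASELINE_NORMAL = {
    "lvesvi": (37.0, 12.0, 12.0),
    "lvedvi": (84.0, 20.0, 30.0),
    "lvef": (54.0, 9.0, 15.0),
    "ecv_noninfarct": (34.0, 5.0, 15.0),
    "epa": (1.2, 0.5, 0.2),
    "dha": (4.6, 1.2, 1.0),
}
_BASELINE_LOGNORMAL = {
    "infarct_size": (math.log(13.0), 0.8),
    "ntprobnp": (math.log(470.0), 0.9),
    "galectin3": (math.log(15.0), 0.25),
    "lipoprotein_a": (math.log(27.0), 1.0),
    "hscrp": (math.log(2.5), 1.1),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the published trial summaries.

    ``n_per_genotype_arm`` switches from Hardy-Weinberg genotype sampling of
    ``n_patients`` to balanced blocks (useful for parameter-recovery runs).
    ``spearman_*`` are the within-patient Gaussian-copula coupling targets
    between on-study fatty-acid rises and the LVESVi change.
    """

    n_patients: int = 312
    freq_g: float = 190.0 / 624.0  # minor-allele frequency from 2*34 + 122 of 624
    arm_ratio: float = 0.5
    arala: dict = field(default_factory=lambda: dict(DEFAULT_ARALA))
    effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()})
    fa_rises: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FA_RISES.items()})
    spearman_epa: float = -0.17
    spearman_dha: float = -0.31
    race_probs: dict = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    n_per_genotype_arm: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.freq_g < 1):
            raise DomainError("freq_g must be in (0, 1)")
        if not (0 < self.arm_ratio < 1):
            raise DomainError("arm_ratio must be in (0, 1)")
        if self.n_patients < 1:
            raise DomainError("n_patients must be positive")
        for rs in (self.spearman_epa, self.spearman_dha):
            if not (-1 < rs < 1):
                raise DomainError("spearman targets must be in (-1, 1)")
        for ep, by_gt in self.effects.items():
            for gt, (m_d, s_d, m_p, s_p) in by_gt.items():
                if s_d < 0 or s_p < 0:
                    raise DomainError(f"negative SD for {ep}/{gt}")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise DomainError("race_probs must sum to 1")


def _copula_rho(spearman_target: float) -> float:
    """Bivariate-normal correlation achieving a given Spearman's rho."""
    return 2.0 * math.sin(math.pi * spearman_target / 6.0)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort DataFrame (trial column dictionary) plus its ground truth.

    Genotypes follow Hardy-Weinberg proportions of ``freq_g``; arms are
    Bernoulli(``arm_ratio``); every 6-month endpoint change is Normal with
    the configured (genotype, arm) mean/SD; EPA and DHA rises share a latent
    Gaussian factor with the LVESVi change so their rank correlation
    approximates the configured Spearman targets (the omega-3 index change
    is the sum of the two, so its coupling is emergent, not configured).
    """
    rng = np.random.default_rng(config.seed)

    if config.n_per_genotype_arm is not None:
        k = config.n_per_genotype_arm
        genotypes = np.repeat(["AA", "AG", "GG"], 2 * k)
        arms = np.tile(np.repeat(["drug", "placebo"], k), 3)
        n = genotypes.size
    else:
        n = config.n_patients
        q = config.freq_g
        p = 1.0 - q
        genotypes = rng.choice(
            ["AA", "AG", "GG"], size=n, p=[p * p, 2 * p * q, q * q]
        )
        arms = np.where(rng.random(n) < config.arm_ratio, "drug", "placebo")

    races = rng.choice(
        list(config.race_probs.keys()), size=n, p=list(config.race_probs.values())
    )
    hct = np.clip(rng.normal(0.395, 0.05, n), 0.25, 0.55)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "genotype": genotypes,
            "arm": arms,
            "race": races,
            "hct": hct,
        }
    )

    # RBC fatty-acid baseline profile; ArA/LA ratio is genotype dependent.
    la = np.clip(rng.normal(8.5, 1.0, n), 4.0, None)
    arala_mean = np.array([config.arala[g][0] for g in genotypes])
    arala_sd = np.array([config.arala[g][1] for g in genotypes])
    ratio = np.clip(rng.normal(arala_mean, arala_sd), 0.05, None)
    df["la_pct"] = la
    df["ara_pct"] = ratio * la

    for stem, (mu, sd, lo) in _BASELINE_NORMAL.items():
        df[f"{stem}_baseline"] = np.clip(rng.normal(mu, sd, n), lo, None)
    for stem, (logmu, logsd) in _BASELINE_LOGNORMAL.items():
        df[f"{stem}_baseline"] = np.exp(rng.normal(logmu, logsd, n))
    df["o3i_baseline"] = df["epa_baseline"] + df["dha_baseline"]

    # Endpoint changes: LVESVi first (its z-score is the copula latent).
    z_lvesvi = rng.standard_normal(n)
    is_drug = arms == "drug"

    def _stratum_params(endpoint: str) -> tuple[np.ndarray, np.ndarray]:
        by_gt = config.effects[endpoint]
        m = np.empty(n)
        s = np.empty(n)
        for gt in ("AA", "AG", "GG"):
            sel = genotypes == gt
            m_d, s_d, m_p, s_p = by_gt[gt]
            m[sel] = np.where(is_drug[sel], m_d, m_p)
            s[sel] = np.where(is_drug[sel], s_d, s_p)
        return m, s

    m, s = _stratum_params("lvesvi")
    deltas = {"lvesvi": m + s * z_lvesvi}
    for endpoint in config.effects:
        if endpoint == "lvesvi":
            continue
        m, s = _stratum_params(endpoint)
        deltas[endpoint] = rng.normal(m, s)

    # Fatty-acid rises, copula-coupled to the LVESVi change.
    truth_rho = {}
    for acid in ("epa", "dha"):
        target = config.spearman_epa if acid == "epa" else config.spearman_dha
        rho = _copula_rho(target)
        truth_rho[acid] = rho
        z = rho * z_lvesvi + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        m_d, s_d = config.fa_rises[acid]["drug"]
        m_p, s_p = config.fa_rises[acid]["placebo"]
        mu = np.where(is_drug, m_d, m_p)
        sd = np.where(is_drug, s_d, s_p)
        deltas[acid] = mu + sd * z
    deltas["o3i"] = deltas["epa"] + deltas["dha"]

    for stem, d in deltas.items():
        df[f"{stem}_6mo"] = df[f"{stem}_baseline"] + d

    truth = {
        "freq_g": config.freq_g,
        "hwe_probs": {
            "AA": (1 - config.freq_g) ** 2,
            "AG": 2 * config.freq_g * (1 - config.freq_g),
            "GG": config.freq_g**2,
        },
        "arala": dict(config.arala),
        "effects": {k: dict(v) for k, v in config.effects.items()},
        "fa_rises": {k: dict(v) for k, v in config.fa_rises.items()},
        "copula_rho": truth_rho,
        "spearman_targets": {"epa": config.spearman_epa, "dha": config.spearman_dha},
        "seed": config.seed,
        "n": n,
    }
    return df, truth
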