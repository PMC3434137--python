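"""Seeded generators for every input the analysis stages consume.

Real inputs for this pipeline are wet-lab measurements (manual mitochondrial
diameters, OCT heart-tube traces, climbing counts, eye micrometry) and
database score lookups, none of which are redistributable here.  These
generators emulate their statistical structure so every stage is testable
end-to-end:

* coding regions — uniform random sense codons (no stops), any length;
* predictor score tables — class-conditional Beta score distributions, a
  "benign_like" profile for an unselected mutation spectrum and a "cmt_like"
  profile mimicking a disease-linked spectrum in which most changes are
  flagged damaging;
* mitochondrial size samples — lognormal diameters: a control population
  with median 1 µm, a fragmented population shifted to 60% of control
  median, a heterogeneous population with doubled log-scale spread, and a
  fragmented population carrying a 10% mega-mitochondria component at three
  times control median;
* heart-tube traces — a sinusoid oscillating between EDD and ESD plus
  Gaussian measurement noise;
* geotaxis trials — binomial counts with a per-genotype logistic decline in
  climb probability over the study.

All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .codon_scan import SENSE_CODONS, CodingRegion, CodonSnv
from .mito_morphometry import SizeSample
from .organ_function import GeotaxisTrial, HeartTrace

__all__ = [
    "SCORE_PROFILES",
    "MITO_SCENARIOS",
    "gen_coding_region",
    "gen_score_table",
    "gen_mito_sample",
    "gen_heart_trace",
    "gen_geotaxis",
]

#: class-conditional Beta(a, b) parameters for (pp2, sift) score draws
SCORE_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "benign_like": {"pp2": (1.0, 10.0), "sift": (5.0, 2.0)},
    "cmt_like": {"pp2": (8.0, 2.0), "sift": (20.0, 1.0)},
}

#: per-scenario (median µm, lognormal sigma) of the main size component
MITO_SCENARIOS = ("control", "rnai_fragmented", "heterogeneous", "fragmented_megamito")

_CONTROL_MEDIAN_UM = 1.0
_CONTROL_SIGMA = 0.25
_FRAGMENTED_SHIFT = 0.6  # fragmented median as a fraction of control
_MEGA_FACTOR = 3.0  # mega-mitochondria median as a multiple of control
_MEGA_WEIGHT = 0.10


def gen_coding_region(
    n_codons: int,
    seed: int,
    name: str = "synthetic",
    first_residue_number: int = 1,
) -> CodingRegion:
    """Uniform random sense codons; never contains a reference stop codon."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    return CodingRegion(
        name=name,
        sequence="".join(codons),
        first_residue_number=first_residue_number,
    )


def gen_score_table(
    snvs: list[CodonSnv], class_profile: str, seed: int
) -> pd.DataFrame:
    """Draw predictor scores for every distinct missense amino-acid change.

    Scores are in the damaging-high orientation.  ``class_profile`` selects
    the Beta distributions (see :data:`SCORE_PROFILES`).  One row per
    distinct (residue_number, ref_aa, alt_aa); multiple nucleotide routes to
    the same amino-acid change share a single score row, as in a
    per-substitution score database.
    """
    if not snvs:
        raise ValueError("empty SNV list")
    if class_profile not in SCORE_PROFILES:
        raise ValueError(
            f"unknown profile {class_profile!r}; choose from {sorted(SCORE_PROFILES)}"
        )
    params = SCORE_PROFILES[class_profile]
    changes = sorted(
        {
            (s.residue_number, s.ref_aa, s.alt_aa)
            for s in snvs
            if s.consequence == "missense"
        }
    )
    rng = np.random.default_rng(seed)
    pp2 = rng.beta(*params["pp2"], size=len(changes))
    sift = rng.beta(*params["sift"], size=len(changes))
    return pd.DataFrame(
        {
            "residue_number": [c[0] for c in changes],
            "ref_aa": [c[1] for c in changes],
            "alt_aa": [c[2] for c in changes],
            "sift_score": sift,
            "pp2_score": pp2,
        }
    )


def gen_mito_sample(scenario: str, n: int, seed: int) -> SizeSample:
    """Lognormal mitochondrial diameter sample for one genetic scenario."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if scenario == "control":
        d = rng.lognormal(np.log(_CONTROL_MEDIAN_UM), _CONTROL_SIGMA, size=n)
    elif scenario == "rnai_fragmented":
        d = rng.lognormal(
            np.log(_CONTROL_MEDIAN_UM * _FRAGMENTED_SHIFT), _CONTROL_SIGMA, size=n
        )
    elif scenario == "heterogeneous":
        d = rng.lognormal(np.log(_CONTROL_MEDIAN_UM), 2 * _CONTROL_SIGMA, size=n)
    elif scenario == "fragmented_megamito":
        is_mega = rng.random(n) < _MEGA_WEIGHT
        d = np.where(
            is_mega,
            rng.lognormal(
                np.log(_CONTROL_MEDIAN_UM * _MEGA_FACTOR), _CONTROL_SIGMA, size=n
            ),
            rng.lognormal(
                np.log(_CONTROL_MEDIAN_UM * _FRAGMENTED_SHIFT), _CONTROL_SIGMA, size=n
            ),
        )
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {MITO_SCENARIOS}"
        )
    return SizeSample(group=scenario, diameters=d)


def gen_heart_trace(
    edd: float,
    esd: float,
    rate_hz: float,
    duration_s: float,
    noise_sd: float,
    seed: int,
    sample_rate_hz: float = 100.0,
) -> HeartTrace:
    """Sinusoidal diameter trace oscillating between EDD and ESD.

    The clean signal starts at end-diastole; Gaussian noise with standard
    deviation ``noise_sd`` µm is added pointwise.
    """
    if not (edd > esd > 0):
        raise ValueError(f"need EDD > ESD > 0, got EDD={edd}, ESD={esd}")
    if rate_hz <= 0 or duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("rate_hz, duration_s and sample_rate_hz must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    mid = (edd + esd) / 2.0
    amp = (edd - esd) / 2.0
    d = mid + amp * np.cos(2 * np.pi * rate_hz * t)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, size=t.size)
    d = np.maximum(d, 1e-6)  # keep diameters physical under extreme noise
    return HeartTrace(times=t, diameters=d, sample_rate_hz=sample_rate_hz)


def _decline_curve(
    days: np.ndarray, p0: float, decline_rate: float, d50: float
) -> np.ndarray:
    # normalised logistic: p(1) = p0 exactly; decline_rate = 0 gives constant p0
    return p0 * expit(decline_rate * (d50 - days)) / expit(decline_rate * (d50 - 1))


def gen_geotaxis(
    genotype_params: dict[str, tuple[float, ...]],
    days: int = 28,
    sessions_per_day: int = 2,
    n_total: int = 150,
    seed: int = 0,
) -> list[GeotaxisTrial]:
    """Binomial climbing counts with genotype-specific temporal decline.

    ``genotype_params`` maps genotype -> (p0, decline_rate) or
    (p0, decline_rate, d50): p0 is the day-1 climb probability,
    decline_rate the logistic steepness per day (0 = no decline), and d50
    the day at which the probability has halved (default two thirds of the
    study, matching a decline that becomes apparent in week three).  One
    cohort of ``n_total`` flies per genotype is scored
    ``sessions_per_day`` times per day.
    """
    if days < 1 or sessions_per_day < 1 or n_total < 1:
        raise ValueError("days, sessions_per_day and n_total must be >= 1")
    rng = np.random.default_rng(seed)
    day_grid = np.arange(1, days + 1, dtype=float)
    trials: list[GeotaxisTrial] = []
    for genotype in sorted(genotype_params):
        params = genotype_params[genotype]
        if len(params) == 2:
            p0, rate = params
            d50 = 2.0 * days / 3.0
        elif len(params) == 3:
            p0, rate, d50 = params
        else:
            raise ValueError(
                f"{genotype!r}: expected (p0, decline_rate[, d50]), got {params!r}"
            )
        p = _decline_curve(day_grid, p0, rate, d50)
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{genotype!r}: climb probability leaves [0, 1]")
        for day_idx, day in enumerate(day_grid):
            for session in range(1, sessions_per_day + 1):
                trials.append(
                    GeotaxisTrial(
                        genotype=genotype,
                        day=int(day),
                        session=session,
                        n_climbed=int(rng.binomial(n_total, p[day_idx])),
                        n_total=n_total,
                    )
                )
    return trials
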