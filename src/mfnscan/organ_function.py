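"""Organ-level phenotype quantification: heart-tube contraction, climbing, eye size.

Heart-tube contraction is read out as percent fractional shortening,
%FS = 100 * (EDD - ESD) / EDD, where EDD and ESD are the end-diastolic and
end-systolic internal chamber diameters.  From a diameter-versus-time trace
the per-beat EDD/ESD pairs are the alternating local maxima and minima found
by prominence-based peak detection.

Negative geotaxis (the innate drive of flies to climb after being knocked
down) is scored as the fraction of a cohort climbing past a height criterion
within a fixed time.  Longitudinal genotype differences are tested with a
two-way mixed (split-plot) ANOVA on session-level climb fractions — genotype
is the between factor, day the repeated factor, and the session index the
subject followed across days.

Eye size enters as two manual axial measurements; groups are compared on an
area proxy with one-way ANOVA plus Bonferroni-adjusted pairwise t tests.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import signal, stats

__all__ = [
    "InsufficientBeatsError",
    "InvalidMeasurementError",
    "HeartTrace",
    "BeatMeasures",
    "GeotaxisTrial",
    "EyeMeasure",
    "fractional_shortening",
    "extract_beats",
    "climb_fraction",
    "geotaxis_trend_test",
    "eye_group_compare",
]

logger = logging.getLogger(__name__)


class InsufficientBeatsError(ValueError):
    """Fewer than two complete beats detected in a trace."""


class InvalidMeasurementError(ValueError):
    """Physically impossible diameter measurement (ESD > EDD, EDD <= 0...)."""


# ---------------------------------------------------------------------------
# heart tube
# ---------------------------------------------------------------------------

def fractional_shortening(edd: float, esd: float) -> float:
    """Percent fractional shortening, 100 * (EDD - ESD) / EDD.

    EDD must be positive and ESD must satisfy 0 <= ESD <= EDD; the result
    lies in [0, 100] (0 = no contraction, 100 = complete chamber closure).
    """
    if edd <= 0:
        raise InvalidMeasurementError(f"EDD must be positive, got {edd}")
    if esd < 0 or esd > edd:
        raise InvalidMeasurementError(f"need 0 <= ESD <= EDD, got ESD={esd}, EDD={edd}")
    return 100.0 * (edd - esd) / edd


@dataclass(frozen=True)
class HeartTrace:
    """A heart-tube internal-diameter trace sampled over time."""

    times: np.ndarray = field(repr=False)
    diameters: np.ndarray = field(repr=False)
    sample_rate_hz: float = 0.0  # derived from times when omitted

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        if t.ndim != 1 or t.size != d.size:
            raise ValueError("times and diameters must be 1-D and the same length")
        if t.size < 4:
            raise ValueError("trace too short")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(d > 0):
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "diameters", d)
        if self.sample_rate_hz <= 0:
            object.__setattr__(
                self, "sample_rate_hz", float(1.0 / np.median(np.diff(t)))
            )


@dataclass(frozen=True)
class BeatMeasures:
    """Per-beat EDD/ESD pairs and the summary fractional shortening."""

    beats: tuple[tuple[float, float], ...]  # (EDD, ESD) per beat, µm
    mean_edd: float
    mean_esd: float
    fs_percent: float  # from mean EDD and mean ESD
    per_beat_fs: tuple[float, ...]

    @property
    def n_beats(self) -> int:
        return len(self.beats)


def _smooth_trace(d: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Low-pass the trace with a Savitzky-Golay filter before extrema picking.

    Raw extrema of a noisy trace are biased (maxima up, minima down), which
    inflates %FS.  The window is a quarter of the dominant oscillation
    period, estimated from the detrended spectrum, so genuine beat extrema
    pass through nearly unattenuated while sample-scale noise is averaged
    out.  Traces too short or aperiodic for a spectral estimate are returned
    unchanged.
    """
    centred = d - d.mean()
    spectrum = np.abs(np.fft.rfft(centred))
    freqs = np.fft.rfftfreq(d.size, 1.0 / sample_rate_hz)
    if spectrum[1:].size == 0:
        return d
    f_dom = freqs[1:][int(np.argmax(spectrum[1:]))]
    if f_dom <= 0:
        return d
    window = int(round(sample_rate_hz / (4.0 * f_dom)))
    window = max(5, window | 1)  # odd, at least 5
    if window >= d.size:
        return d
    return signal.savgol_filter(d, window_length=window, polyorder=2)


def extract_beats(trace: HeartTrace, min_prominence: float | None = None) -> BeatMeasures:
    """Detect beats in a diameter trace and summarise EDD/ESD/%FS.

    The trace is first low-pass filtered (see :func:`_smooth_trace`); local
    maxima of the filtered trace are end-diastolic diameters and the
    interleaved minima end-systolic diameters; a beat is a (maximum,
    following minimum) pair.  ``min_prominence`` defaults to 25% of the
    trace's peak-to-peak range, which rejects noise ripples while keeping
    genuinely depressed beats.  The summary %FS uses the means of the
    per-beat EDD and ESD; per-beat FS values are also reported.
    """
    if float(np.ptp(trace.diameters)) == 0:
        raise InsufficientBeatsError("flat trace: no beats to extract")
    d = _smooth_trace(trace.diameters, trace.sample_rate_hz)
    ptp = float(np.ptp(d))
    if ptp == 0:
        raise InsufficientBeatsError("flat trace: no beats to extract")
    if min_prominence is None:
        min_prominence = 0.25 * ptp
    peaks, _ = signal.find_peaks(d, prominence=min_prominence)
    troughs, _ = signal.find_peaks(-d, prominence=min_prominence)
    if len(peaks) < 2:
        raise InsufficientBeatsError(
            f"only {len(peaks)} diastolic peak(s) detected; need >= 2 beats"
        )
    beats: list[tuple[float, float]] = []
    for p0, p1 in itertools.pairwise(peaks):
        between = troughs[(troughs > p0) & (troughs < p1)]
        if between.size == 0:
            continue
        edd = float(d[p0])
        esd = float(d[between].min())
        if esd > edd:  # cannot happen with prominence-gated extrema
            raise InvalidMeasurementError("detected ESD exceeds EDD")
        beats.append((edd, esd))
    if len(beats) < 1:
        raise InsufficientBeatsError("no complete diastole-systole pairs detected")
    edds = np.array([b[0] for b in beats])
    esds = np.array([b[1] for b in beats])
    mean_edd = float(edds.mean())
    mean_esd = float(esds.mean())
    return BeatMeasures(
        beats=tuple(beats),
        mean_edd=mean_edd,
        mean_esd=mean_esd,
        fs_percent=fractional_shortening(mean_edd, mean_esd),
        per_beat_fs=tuple(fractional_shortening(e, s) for e, s in beats),
    )


# ---------------------------------------------------------------------------
# negative geotaxis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeotaxisTrial:
    """One climbing session: how many of a cohort passed the height criterion."""

    genotype: str
    day: int
    session: int
    n_climbed: int
    n_total: int

    def __post_init__(self) -> None:
        if self.day < 1 or self.n_total <= 0:
            raise ValueError("need day >= 1 and n_total > 0")
        if not (0 <= self.n_climbed <= self.n_total):
            raise ValueError("need 0 <= n_climbed <= n_total")


def climb_fraction(trial: GeotaxisTrial) -> float:
    """Fraction of the cohort that climbed past the criterion."""
    return trial.n_climbed / trial.n_total


def trials_frame(trials: list[GeotaxisTrial]) -> pd.DataFrame:
    """Tabulate trials with their climb fractions."""
    return pd.DataFrame(
        {
            "genotype": [t.genotype for t in trials],
            "day": [t.day for t in trials],
            "session": [t.session for t in trials],
            "n_climbed": [t.n_climbed for t in trials],
            "n_total": [t.n_total for t in trials],
            "climb_fraction": [climb_fraction(t) for t in trials],
        }
    )


def geotaxis_trend_test(trials: list[GeotaxisTrial]) -> pd.DataFrame:
    """Pairwise two-way repeated-measures ANOVA of climb fraction over days.

    For every genotype pair a mixed (split-plot) ANOVA is fitted on the
    session-level climb fractions, with day as the repeated (within) factor
    and the session index as the subject carried across days.  Returns one
    row per pair with the genotype main-effect, day and genotype x day
    interaction p-values.  Sessions missing any day are dropped listwise
    with a warning.
    """
    df = trials_frame(trials)
    genotypes = sorted(df["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes")
    if df["day"].nunique() < 2:
        raise ValueError("need >= 2 days for a trend test")
    df = df.assign(subject=df["genotype"] + "/s" + df["session"].astype(str))

    n_days = df["day"].nunique()
    complete = df.groupby("subject")["day"].nunique() == n_days
    incomplete = complete.index[~complete].tolist()
    if incomplete:
        warnings.warn(
            f"dropping sessions with missing days (listwise): {incomplete}",
            stacklevel=2,
        )
        df = df[df["subject"].isin(complete.index[complete])]

    rows = []
    for g1, g2 in itertools.combinations(genotypes, 2):
        sub = df[df["genotype"].isin([g1, g2])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-sample sphericity notices
            aov = pg.mixed_anova(
                data=sub,
                dv="climb_fraction",
                within="day",
                subject="subject",
                between="genotype",
            )
        aov = aov.set_index("Source")
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        rows.append(
            {
                "genotype_a": g1,
                "genotype_b": g2,
                "genotype_p": float(aov.loc["genotype", p_col]),
                "day_p": float(aov.loc["day", p_col]),
                "interaction_p": float(aov.loc["Interaction", p_col]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eye size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeMeasure:
    """Manual eye measurements: vertical and horizontal extents (µm)."""

    genotype: str
    vertical_um: float
    horizontal_um: float

    def __post_init__(self) -> None:
        if self.vertical_um <= 0 or self.horizontal_um <= 0:
            raise ValueError("eye measurements must be positive")

    def area_proxy(self, shape: str = "rect") -> float:
        """Vertical x horizontal, optionally with the elliptical pi/4 factor.

        Group *ratios* are identical under either convention; only the
        absolute scale differs.
        """
        area = self.vertical_um * self.horizontal_um
        if shape == "ellipse":
            area *= np.pi / 4.0
        elif shape != "rect":
            raise ValueError("shape must be 'rect' or 'ellipse'")
        return area


def eye_group_compare(
    measures: list[EyeMeasure], shape: str = "rect"
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Compare eye areas across genotypes.

    Returns ``(group_stats, anova_p, pairwise)`` where group_stats has one
    row per genotype (n, mean area, SEM), anova_p is the one-way ANOVA
    p-value over all groups, and pairwise holds Student t tests for every
    genotype pair with Bonferroni-adjusted p = min(1, raw p x #pairs).
    """
    df = pd.DataFrame(
        {
            "genotype": [m.genotype for m in measures],
            "area": [m.area_proxy(shape) for m in measures],
        }
    )
    groups = sorted(df["genotype"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 genotypes")
    by_group = {g: df.loc[df["genotype"] == g, "area"].to_numpy() for g in groups}
    for g, vals in by_group.items():
        if vals.size < 2:
            raise ValueError(f"genotype {g!r} has n={vals.size} < 2")

    group_stats = pd.DataFrame(
        {
            "genotype": groups,
            "n": [by_group[g].size for g in groups],
            "mean_area": [by_group[g].mean() for g in groups],
            "sem_area": [
                by_group[g].std(ddof=1) / np.sqrt(by_group[g].size) for g in groups
            ],
        }
    )
    f_stat, anova_p = stats.f_oneway(*(by_group[g] for g in groups))
    if np.isnan(anova_p):  # all values identical in every group
        anova_p = 1.0

    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        t_res = stats.ttest_ind(by_group[g1], by_group[g2], equal_var=True)
        raw_p = 1.0 if np.isnan(t_res.pvalue) else float(t_res.pvalue)
        rows.append(
            {
                "genotype_a": g1,
                "genotype_b": g2,
                "raw_p": raw_p,
                "adj_p": min(1.0, raw_p * len(pairs)),
            }
        )
    return group_stats, float(anova_p), pd.DataFrame(rows)
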