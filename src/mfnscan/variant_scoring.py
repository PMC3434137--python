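"""Predictor-threshold classification and per-residue damage-potential scoring.

Scores follow the dbNSFP-converted orientation in which *larger means more
damaging* for both SIFT and PolyPhen2 (a SIFT score here is ``1 - native
SIFT``; a native SIFT below 0.05 is "damaging", which maps to > 0.95 on this
scale).  Do not feed native-orientation SIFT scores to these classifiers.

Classification bands:

* SIFT: score > 0.95 -> ``Damaging``, otherwise ``Tolerated``.
* PolyPhen2: score > 0.85 -> ``Probably damaging``; score < 0.15 ->
  ``Benign``; the closed middle band [0.15, 0.85] -> ``Possibly damaging``.

The per-residue damage potential sums a 0/1/2 category over all nine
nucleotide substitutions of the codon: benign = 0, possibly damaging = 1,
probably damaging or truncating (stop-gain) = 2.  Counting is per
*nucleotide* change, so an amino-acid substitution reachable through several
nucleotide routes (e.g. Met->Ile via any of three third-position changes)
contributes once per route.  Only PolyPhen2 categories enter the profile;
SIFT participates only in tabular classification and the damaging flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .codon_scan import CodingRegion, CodonSnv, enumerate_snvs

__all__ = [
    "SIFT_DAMAGING",
    "SIFT_TOLERATED",
    "PP2_BENIGN",
    "PP2_POSSIBLY",
    "PP2_PROBABLY",
    "MISSING_LABEL",
    "InvalidScoreError",
    "MissingScoreError",
    "ClassifierThresholds",
    "ClassComparison",
    "classify_sift",
    "classify_pp2",
    "damage_category",
    "position_damage_profile",
    "variant_flagged_damaging",
    "compare_mutation_classes",
    "load_table1_fixture",
]

logger = logging.getLogger(__name__)

SIFT_DAMAGING = "Damaging"
SIFT_TOLERATED = "Tolerated"
PP2_BENIGN = "Benign"
PP2_POSSIBLY = "Possibly damaging"
PP2_PROBABLY = "Probably damaging"
MISSING_LABEL = "NA"

_PP2_CATEGORY = {PP2_BENIGN: 0, PP2_POSSIBLY: 1, PP2_PROBABLY: 2}


class InvalidScoreError(ValueError):
    """Predictor score outside [0, 1]."""


class MissingScoreError(ValueError):
    """A required predictor score is absent."""


def _is_missing(score: float | None) -> bool:
    return score is None or (isinstance(score, float) and math.isnan(score))


@dataclass(frozen=True)
class ClassifierThresholds:
    """Cut-points for the two predictors (damaging-high orientation)."""

    sift_damaging_gt: float = 0.95
    pp2_probably_gt: float = 0.85
    pp2_benign_lt: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_damaging_gt <= 1.0):
            raise InvalidScoreError("sift_damaging_gt must lie in [0, 1]")
        if not (0.0 <= self.pp2_benign_lt <= self.pp2_probably_gt <= 1.0):
            raise InvalidScoreError(
                "need 0 <= pp2_benign_lt <= pp2_probably_gt <= 1"
            )


DEFAULT_THRESHOLDS = ClassifierThresholds()


def _check_score(score: float, what: str) -> float:
    score = float(score)
    if not (0.0 <= score <= 1.0):
        raise InvalidScoreError(f"{what} score {score} outside [0, 1]")
    return score


def classify_sift(
    score: float | None, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Binary SIFT call: strictly above the cut is Damaging, else Tolerated."""
    if _is_missing(score):
        return MISSING_LABEL
    score = _check_score(score, "SIFT")
    return SIFT_DAMAGING if score > thresholds.sift_damaging_gt else SIFT_TOLERATED


def classify_pp2(
    score: float | None, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Three-band PolyPhen2 call; band boundaries belong to the middle band."""
    if _is_missing(score):
        return MISSING_LABEL
    score = _check_score(score, "PolyPhen2")
    if score > thresholds.pp2_probably_gt:
        return PP2_PROBABLY
    if score < thresholds.pp2_benign_lt:
        return PP2_BENIGN
    return PP2_POSSIBLY


def damage_category(
    snv: CodonSnv,
    pp2_label: str | None = None,
    missing_policy: str = "permissive",
) -> int:
    """Map one substitution to its 0/1/2 damage category.

    Stop-gains are category 2 regardless of any score.  Missense changes
    require a PolyPhen2 label; a missing label raises under
    ``missing_policy='strict'`` and counts as 0 with a warning under the
    default ``'permissive'``.
    """
    if snv.consequence == "synonymous":
        raise ValueError(
            f"synonymous change {snv.ref_codon}>{snv.alt_codon} has no damage category"
        )
    if snv.consequence == "nonsense":
        return 2
    if pp2_label is None or pp2_label == MISSING_LABEL:
        msg = (
            f"no PolyPhen2 score for {snv.ref_aa}{snv.residue_number}{snv.alt_aa}"
        )
        if missing_policy == "strict":
            raise MissingScoreError(msg)
        logger.warning("%s; counting as benign (category 0)", msg)
        return 0
    return _PP2_CATEGORY[pp2_label]


def _score_lookup(scores: pd.DataFrame) -> dict[tuple[int, str, str], float]:
    required = {"residue_number", "ref_aa", "alt_aa", "pp2_score"}
    missing_cols = required - set(scores.columns)
    if missing_cols:
        raise ValueError(f"score table lacks columns: {sorted(missing_cols)}")
    keys = list(
        zip(scores["residue_number"].astype(int), scores["ref_aa"], scores["alt_aa"])
    )
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (residue_number, ref_aa, alt_aa) in score table")
    return dict(zip(keys, scores["pp2_score"].astype(float)))


def position_damage_profile(
    region: CodingRegion,
    scores: pd.DataFrame,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    missing_policy: str = "permissive",
) -> pd.Series:
    """Per-residue damage potential: sum of categories over the 9 SNVs per codon.

    ``scores`` needs columns residue_number, ref_aa, alt_aa, pp2_score (one
    row per distinct missense amino-acid change; row order is irrelevant).
    Synonymous changes contribute 0; stop-gains contribute 2 without a score.
    The result is an integer Series indexed by residue_number, each value in
    [0, 18].
    """
    lookup = _score_lookup(scores)
    profile = {r: 0 for r in region.residue_numbers}
    for snv in enumerate_snvs(region):
        if snv.consequence == "synonymous":
            continue
        if snv.consequence == "missense":
            key = (snv.residue_number, snv.ref_aa, snv.alt_aa)
            pp2 = lookup.get(key)
            if pp2 is None or math.isnan(pp2):
                label = None
            else:
                label = classify_pp2(pp2, thresholds)
        else:
            label = None
        profile[snv.residue_number] += damage_category(snv, label, missing_policy)
    return pd.Series(profile, name="damage_potential", dtype=int).rename_axis(
        "residue_number"
    )


def variant_flagged_damaging(
    sift_score: float | None,
    pp2_score: float | None,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Flag a variant as potentially damaging.

    True iff SIFT calls it Damaging or PolyPhen2 calls it anything other
    than Benign.  A missing score simply cannot trigger its clause; both
    missing is an error.
    """
    if _is_missing(sift_score) and _is_missing(pp2_score):
        raise MissingScoreError("both predictor scores are missing")
    sift_hit = classify_sift(sift_score, thresholds) == SIFT_DAMAGING
    pp2_label = classify_pp2(pp2_score, thresholds)
    pp2_hit = pp2_label not in (PP2_BENIGN, MISSING_LABEL)
    return sift_hit or pp2_hit


@dataclass(frozen=True)
class ClassComparison:
    """Two-group comparison of damaging fractions and raw predictor scores."""

    n_a: int
    n_b: int
    damaging_a: int
    damaging_b: int
    frac_a: float
    frac_b: float
    fisher_p: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_stat: float
    t_p: float


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def compare_mutation_classes(
    scores_a: "np.typing.ArrayLike",
    flags_a: "np.typing.ArrayLike",
    scores_b: "np.typing.ArrayLike",
    flags_b: "np.typing.ArrayLike",
) -> ClassComparison:
    """Compare two mutation classes (e.g. all-possible vs disease-linked).

    The damaging/not-damaging 2x2 table is tested with the two-sided Fisher
    exact probability; the raw scores with a pooled-variance two-tailed
    Student t test.  SEM = sd / sqrt(n) with the n-1 sample sd.  If either
    group has fewer than two scores the t statistic cannot be formed: those
    fields are NaN and a warning is logged, while the Fisher result is still
    returned.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    fa = np.asarray(flags_a, dtype=bool)
    fb = np.asarray(flags_b, dtype=bool)
    if len(fa) == 0 or len(fb) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(fa), len(fb)
    d_a, d_b = int(fa.sum()), int(fb.sum())
    table = [[d_a, n_a - d_a], [d_b, n_b - d_b]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")

    if len(a) < 2 or len(b) < 2:
        logger.warning(
            "a group has fewer than 2 scores (n_a=%d, n_b=%d); t-test not computed",
            len(a),
            len(b),
        )
        t_stat, t_p = float("nan"), float("nan")
    else:
        t_res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        if math.isnan(t_p):  # zero pooled variance with equal means
            t_stat, t_p = 0.0, 1.0
    return ClassComparison(
        n_a=n_a,
        n_b=n_b,
        damaging_a=d_a,
        damaging_b=d_b,
        frac_a=d_a / n_a,
        frac_b=d_b / n_b,
        fisher_p=float(fisher_p),
        mean_a=float(a.mean()) if len(a) else float("nan"),
        sem_a=_sem(a),
        mean_b=float(b.mean()) if len(b) else float("nan"),
        sem_b=_sem(b),
        t_stat=t_stat,
        t_p=t_p,
    )


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged table of the four rare human MFN2 HR1 variants.

    Columns: residue_number, ref_aa, alt_aa, allele_frequency (annotation
    only), sift_score, pp2_score.  Scores are in the damaging-high
    orientation.
    """
    with resources.files("mfnscan.data").joinpath(
        "table1_hr1_variants.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
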