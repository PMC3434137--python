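# Methods

## Saturation mutagenesis scan

A coding region is a stop-free, in-frame nucleotide sequence with a 1-based
protein residue offset (`first_residue_number`), so a domain such as
mitofusin-2 HR1 can be scanned in its native coordinates. The default span
used in examples is 44 codons anchored at residue 391 (literature
descriptions of the HR1 boundary vary by one residue, 391–434 vs 392–435;
both spans are 44 codons and the offset is user-settable). Every codon
yields exactly 9 single-nucleotide substitutions, enumerated in a fixed
order — (residue, position in codon, alphabetical alternate base) — so
joins with external score tables are reproducible. Consequences come from
the standard genetic code (biopython's table 1): synonymous, missense, or
nonsense (stop-gain).

Stop-gain substitutions count toward the non-synonymous total by default
because the damage scoring treats truncating changes as maximally damaging;
`consequence_counts(..., include_stop_gains=False)` gives a missense-only
total for comparison with counts whose convention is unknown.

Only the coding strand is considered; reverse-strand input is the caller's
responsibility. No transcript/genome coordinate mapping or VCF output is
attempted.

## Predictor thresholds and the damaging flag

Both predictors are taken in the dbNSFP-converted, damaging-high
orientation. Defaults (`ClassifierThresholds`):

| parameter         | default | meaning                                  |
|-------------------|---------|------------------------------------------|
| `sift_damaging_gt`| 0.95    | SIFT strictly above ⇒ Damaging            |
| `pp2_probably_gt` | 0.85    | PolyPhen2 strictly above ⇒ Probably damaging |
| `pp2_benign_lt`   | 0.15    | PolyPhen2 strictly below ⇒ Benign         |

The PolyPhen2 band boundaries belong to the middle band ("possibly
damaging" covers [0.15, 0.85]), consistent with the strict inequalities of
the outer bands. A variant is *flagged damaging* iff SIFT calls it Damaging
or PolyPhen2 calls it anything other than Benign; a missing score cannot
trigger its clause, and both missing is an error.

## Damage-potential profile

Per residue, the profile sums a 0/1/2 category over all nine nucleotide
substitutions: benign 0, possibly damaging 1, probably damaging **or
stop-gain** 2. Counting is per *nucleotide* change: an amino-acid change
reachable by several routes (Met→Ile via any third-position change of ATG)
contributes once per route, which is why the profile is bounded by 18
rather than by the number of distinct amino-acid targets. Only PolyPhen2
categories enter the profile; SIFT participates only in classification and
the flag. Missing missense scores either raise (`missing_policy="strict"`)
or count as category 0 with a logged warning (`"permissive"`, the default).

## Mutation-class comparison

Damaging fractions of two variant classes are compared with the two-sided
Fisher exact probability (conditional definition: sum of the probabilities
of all 2×2 tables with the observed margins whose probability does not
exceed the observed table's). Raw scores are compared with a two-tailed
pooled-variance Student *t* (not Welch), SEM = sd/√n with the n−1 sd. The
"±" values reported alongside means are SEMs. If a group has fewer than two
scores the *t* fields are NaN with a logged warning while the Fisher result
is still returned — the categorical comparison is defined down to n = 1.

## Fragmentation statistic

The control group's empirical 20th percentile (linear interpolation between
order statistics, numpy's default convention — the source analyses do not
state one) defines the cutoff; "fragmented" means strictly below it, with
ties at the cutoff assigned to the upper group by default (`ties="below"`
flips this). The below/at-or-above × control/test table is tested with the
two-sided Fisher exact probability. By construction the control proportion
is ~0.20, up to sample-size discreteness. Distribution *width* (the
heterogeneity phenotype) is reported descriptively as IQR and variance —
no hypothesis test is attached because none is defined for it. Density
curves use a Gaussian kernel with Silverman's-rule bandwidth by default;
`bandwidth` is the kernel sd in µm when given. The ECDF is right-continuous.
"Diameter" is treated as an abstract 1-D size; no image segmentation is
performed.

## Heart-tube fractional shortening

`%FS = 100·(EDD − ESD)/EDD`, bounded [0, 100]. Beat extraction first
low-passes the trace with a Savitzky–Golay filter (window = a quarter of
the dominant oscillation period from the detrended spectrum, order 2,
minimum 5 samples) because raw extrema of a noisy trace are biased — maxima
up, minima down — which systematically inflates %FS. End-diastolic
diameters are then the prominence-gated local maxima (default prominence
25% of the filtered peak-to-peak range) and end-systolic diameters the
interleaved minima; a beat is a maximum paired with the deepest following
minimum. The summary %FS uses the means of per-beat EDD and ESD (per-beat
FS values and the beat count are also reported, since the number of beats
averaged per recording is an output, not an assumption). Fewer than two
detected diastolic peaks, or a flat trace, is an error.

## Negative geotaxis

A trial records how many of a cohort (~150 flies) climbed past the height
criterion in one session; the climb fraction is the binomial proportion.
The trend test is a two-way mixed (split-plot) repeated-measures ANOVA
(pingouin's `mixed_anova`) on session-level climb fractions per genotype
pair: genotype between, day within, subject = the session index carried
across days. Treating the twice-daily session as the replication unit is an
assumption forced by the design (one cohort per genotype); uncorrected
p-values for the genotype main effect, day effect and genotype×day
interaction are reported, the interaction being the decline readout.
Sessions missing any day are dropped listwise with a warning.

## Eye-size comparison

With only two axial measurements per eye, area is proxied as vertical ×
horizontal (rectangle); an elliptical option multiplies by π/4 and leaves
every group *ratio* unchanged. Groups are compared by one-way ANOVA plus
pairwise pooled-variance t tests with Bonferroni adjustment
(p × number of pairs, capped at 1).

## Synthetic data

All distributional choices are artifact conventions chosen to reproduce the
direction and rough magnitude of the phenotype contrasts, not to fit any
empirical curve; generators are bit-reproducible under (seed, parameters).

* **Coding regions** — uniform random sense codons. Real domains have
  biased codon usage; none of the consequence-counting logic depends on it.
* **Score tables** — one row per distinct missense amino-acid change;
  class-conditional Beta draws: "benign_like" pp2 ~ Beta(1,10), sift ~
  Beta(5,2) (≈22% flagged damaging, an unselected spectrum); "cmt_like"
  pp2 ~ Beta(8,2), sift ~ Beta(20,1) (nearly all flagged, a disease-linked
  spectrum). Real score tables have residue-level correlation that these
  i.i.d. draws lack, so passing tests show the *pipeline arithmetic*, not
  predictor behaviour on real proteins.
* **Mitochondrial sizes** — lognormal: control median 1.0 µm, σ = 0.25;
  fragmented median ×0.6; heterogeneous σ doubled; fragmented-with-
  megamitochondria = 90% fragmented + 10% at ×3 control median.
* **Heart traces** — sinusoid between EDD and ESD at the given beat rate
  (default sampling 100 Hz) plus i.i.d. Gaussian noise; real recordings
  have beat-to-beat variability and baseline drift this omits.
* **Geotaxis** — n_climbed ~ Binomial(n_total, p(day)) with
  p(day) = p0·expit(k·(d50 − day))/expit(k·(d50 − 1)), a normalised
  logistic: k = 0 gives a constant p0, and d50 (default 2/3 of the study)
  places the decline's midpoint in week three of a four-week study. The
  defaults used in tests (p0 = 0.8, k = 0.3, d50 = 19 over 28 days) decline
  to p ≈ 0.05 by day 28 — a cohort that ends the study largely earth-bound.

## Numerical and testing choices

Fisher p-values are cross-checked in the tests against an independent
integer-arithmetic hypergeometric enumeration (shared-denominator weights
compared exactly as integers, summed as a `Fraction`), exhaustively over
every 2×2 table with total ≤ 40; agreement is required to 1e-12. Simulation
sizes in the test suite (e.g. 1,000 null pairs at n = 100 for the type-I
check, 200 replicates for geotaxis null uniformity, 60 for power) were
chosen to give stable pass/fail behaviour at seeded determinism while
keeping the default suite fast.

Known limitations: predictor scores are *inputs* — nothing here recomputes
SIFT/PolyPhen2 from alignments or structure, and the damaging fractions
reported for real proteins therefore depend entirely on the score table
supplied; the repeated-measures ANOVA treats proportions as Gaussian, which
is adequate for cohort sizes near 150 but not for very small cohorts or
probabilities near 0/1; beat extraction assumes a roughly periodic trace
and will reject arrhythmic recordings rather than segment them.
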