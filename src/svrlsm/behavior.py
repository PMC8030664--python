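"""Psychometric scoring of working-memory span and input-processing tasks.

Two span tasks feed the lesion-symptom analysis: a digit matching span task
(phonological working memory; list lengths 2-6) and a category probe task
(semantic working memory; list lengths 1-4).  Both are scored by linear
interpolation of the list length at which accuracy crosses 75%.  Single-word
input processing is measured with a picture-word matching task scored as
signal-detection d' against phonological and semantic foils; the two d'
scores are summarised by the first principal component.  The dependent
variables for lesion-symptom mapping are the ordinary-least-squares residuals
of each span score (regressing out lesion size, the input-processing
composite, and the opposing span score), min-max scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpanTask",
    "SpanCurve",
    "SpanScore",
    "DetectionCounts",
    "DPrime",
    "CompositeScore",
    "DependentVector",
    "InvalidCurveError",
    "DegenerateCurveError",
    "score_span",
    "score_dprime",
    "compute_composite",
    "residualize_and_scale",
    "screen_covariates",
    "read_span_tables",
    "read_detection_tables",
    "score_cohort",
]


class SpanTask(str, Enum):
    """Span task identity; fixes list-length bounds and edge-rule anchors."""

    phonological_digit_matching = "phonological_digit_matching"
    semantic_category_probe = "semantic_category_probe"

    @property
    def min_length(self) -> int:
        return 2 if self is SpanTask.phonological_digit_matching else 1

    @property
    def max_length(self) -> int:
        return 6 if self is SpanTask.phonological_digit_matching else 4

    @property
    def floor_anchor(self) -> int:
        """Virtual list length assumed at 100% accuracy below the floor."""
        return self.min_length - 1

    @property
    def ceiling_anchor(self) -> int:
        """Virtual list length assumed at 50% accuracy above the ceiling."""
        return self.max_length + 1


class InvalidCurveError(ValueError):
    """A span curve violates administration rules (bounds, stop rule...)."""


class DegenerateCurveError(ValueError):
    """Interpolation denominator vanishes at the reported list length."""

    def __init__(self, list_length: int):
        self.list_length = list_length
        super().__init__(
            f"equal accuracies at the lengths spanning the threshold "
            f"(list length {list_length}): interpolation undefined"
        )


@dataclass(frozen=True)
class SpanCurve:
    """Per-list-length trial tallies for one subject on one span task.

    ``entries`` is an ordered sequence of ``(list_length, n_trials,
    n_correct)``.  Administration stops at the first list length scored
    below 75%, so only the final entry may fall below threshold; a curve
    may instead run to the task maximum with every entry at or above it.
    """

    task: SpanTask
    entries: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(tuple(e) for e in self.entries))

    def validate(self, threshold: float = 0.75) -> None:
        if not self.entries:
            raise InvalidCurveError("empty span curve")
        prev = None
        for length, n_trials, n_correct in self.entries:
            if n_trials <= 0:
                raise InvalidCurveError(f"non-positive trial count at length {length}")
            if not 0 <= n_correct <= n_trials:
                raise InvalidCurveError(
                    f"n_correct={n_correct} outside [0, {n_trials}] at length {length}"
                )
            if not self.task.min_length <= length <= self.task.max_length:
                raise InvalidCurveError(
                    f"list length {length} outside task bounds "
                    f"[{self.task.min_length}, {self.task.max_length}]"
                )
            if prev is not None and length <= prev:
                raise InvalidCurveError("list lengths must be strictly increasing")
            prev = length
        accs = self.accuracies()
        for i, acc in enumerate(accs[:-1]):
            if acc < threshold:
                raise InvalidCurveError(
                    "administration continued past a below-threshold list length "
                    f"({self.entries[i][0]})"
                )
        if accs[-1] >= threshold and self.entries[-1][0] != self.task.max_length:
            raise InvalidCurveError(
                "curve ends at or above threshold before the task maximum "
                f"(length {self.entries[-1][0]})"
            )

    def accuracies(self) -> list[float]:
        return [c / n for _, n, c in self.entries]


@dataclass(frozen=True)
class SpanScore:
    """Interpolated span, in items (dimensionless list length)."""

    value: float
    task: SpanTask


@dataclass(frozen=True)
class DetectionCounts:
    """Hit / false-alarm tallies for one foil condition of picture-word matching."""

    n_match: int
    n_hits: int
    n_foil: int
    n_false_alarms: int

    def validate(self) -> None:
        if self.n_match <= 0 or self.n_foil <= 0:
            raise ValueError("zero trials in a detection category")
        if not 0 <= self.n_hits <= self.n_match:
            raise ValueError(f"n_hits={self.n_hits} outside [0, {self.n_match}]")
        if not 0 <= self.n_false_alarms <= self.n_foil:
            raise ValueError(
                f"n_false_alarms={self.n_false_alarms} outside [0, {self.n_foil}]"
            )


@dataclass(frozen=True)
class DPrime:
    value: float


@dataclass(frozen=True)
class CompositeScore:
    """First-principal-component summary of two standardized scores.

    ``scores`` are per-subject component scores (standardized-unit scale);
    ``loadings`` is the eigenvector scaled by the square root of its
    eigenvalue, signed so that loadings are positive for positively
    correlated inputs.
    """

    scores: np.ndarray
    loadings: tuple[float, float]
    explained_variance_fraction: float


@dataclass(frozen=True)
class DependentVector:
    """A residualized, min-max-scaled dependent variable for the LSM stage."""

    subject_ids: tuple
    raw: np.ndarray
    residual: np.ndarray
    scaled: np.ndarray
    covariates_used: tuple[str, ...]
    scale_min: float = field(default=float("nan"))
    scale_max: float = field(default=float("nan"))


def score_span(curve: SpanCurve, threshold: float = 0.75) -> SpanScore:
    """Score a span curve by linear interpolation at the accuracy threshold.

    The span is the list length at which accuracy crosses ``threshold``
    (75% by default): with ``L`` the last administered length at or above
    threshold and the next length below it,

        span = L + (acc_L - 75) / (acc_L - acc_next)

    with accuracies in percentage points (the ratio is unit-invariant).
    Edge rules: if even the shortest list is below threshold, a virtual
    length one below the task minimum is assumed at 100% accuracy; if the
    longest list is still at or above threshold, a virtual length one above
    the task maximum is assumed at 50%.

    Raises
    ------
    InvalidCurveError
        Empty curve or administration-rule violations.
    DegenerateCurveError
        Equal accuracies at the two lengths spanning the threshold.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must lie in (0.5, 1.0)")
    curve.validate(threshold)
    lengths = [e[0] for e in curve.entries]
    accs = curve.accuracies()

    if accs[0] < threshold:
        # floor rule: virtual anchor one item below the task minimum at 100%
        lo_len, lo_acc = curve.task.floor_anchor, 1.0
        hi_len, hi_acc = lengths[0], accs[0]
    elif accs[-1] >= threshold:
        # ceiling rule: virtual anchor one item above the task maximum at 50%
        lo_len, lo_acc = lengths[-1], accs[-1]
        hi_len, hi_acc = curve.task.ceiling_anchor, 0.5
    else:
        lo_len, lo_acc = lengths[-2], accs[-2]
        hi_len, hi_acc = lengths[-1], accs[-1]

    denom = lo_acc - hi_acc
    if denom <= 0:
        raise DegenerateCurveError(lo_len)
    value = lo_len + (hi_len - lo_len) * (lo_acc - threshold) / denom
    return SpanScore(value=value, task=curve.task)


def score_dprime(counts: DetectionCounts, correction: str = "half_trial") -> DPrime:
    """Signal-detection d' = z(hit rate) - z(false-alarm rate).

    Under the ``half_trial`` correction, proportions of exactly 0 or 1 are
    replaced by 1/(2N) and 1 - 1/(2N), with N the trial count of that
    category, so the statistic stays finite at ceiling and floor.
    """
    counts.validate()
    if correction not in ("half_trial", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    def _rate(k: int, n: int) -> float:
        p = k / n
        if correction == "half_trial":
            if p == 0.0:
                p = 1.0 / (2 * n)
            elif p == 1.0:
                p = 1.0 - 1.0 / (2 * n)
        return p

    h = _rate(counts.n_hits, counts.n_match)
    f = _rate(counts.n_false_alarms, counts.n_foil)
    if h in (0.0, 1.0) or f in (0.0, 1.0):
        raise ValueError("extreme proportion without correction: d' undefined")
    return DPrime(value=float(stats.norm.ppf(h) - stats.norm.ppf(f)))


def compute_composite(
    phon_d: Sequence[float], sem_d: Sequence[float]
) -> CompositeScore:
    """First principal component of two standardized d' scores.

    Both inputs are standardized to mean 0, SD 1 (sample SD); the 2x2
    correlation matrix is eigendecomposed in closed form.  For correlation
    r > 0 the leading eigenvalue is 1 + r, the explained-variance fraction
    is (1 + r)/2 and both loadings equal sqrt((1 + r)/2).  The component is
    signed so loadings are positive (higher composite = better processing).
    """
    x = np.asarray(phon_d, dtype=float)
    y = np.asarray(sem_d, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("composite requires at least 3 subjects")
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise ValueError("zero-variance input: composite undefined")

    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    r = float(np.dot(zx, zy) / (x.size - 1))
    if r < 0:
        warnings.warn(
            "negative correlation between d' inputs; first component is the "
            "difference, signed so the first loading is positive",
            stacklevel=2,
        )
    # 2x2 correlation matrix: eigenvalues 1 +/- r with eigenvectors (1, +/-1)/sqrt(2)
    if r >= 0:
        eigval, vec = 1.0 + r, np.array([1.0, 1.0]) / np.sqrt(2.0)
    else:
        eigval, vec = 1.0 - r, np.array([1.0, -1.0]) / np.sqrt(2.0)
    loadings = vec * np.sqrt(eigval)
    scores = np.column_stack([zx, zy]) @ vec
    return CompositeScore(
        scores=scores,
        loadings=(float(loadings[0]), float(loadings[1])),
        explained_variance_fraction=eigval / 2.0,
    )


def residualize_and_scale(
    raw: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | None = None,
    subject_ids: Sequence | None = None,
) -> DependentVector:
    """OLS-residualize ``raw`` on the covariates, then min-max scale to [0, 1].

    A single multiple regression with intercept removes all covariates
    simultaneously; the residuals are then mapped through
    (value - min) / (max - min).

    Raises on a rank-deficient design (naming the collinear covariates) and
    on constant residuals (nothing left to scale).
    """
    y = np.asarray(raw, dtype=float)
    covariates = dict(covariates or {})
    n = y.size
    if subject_ids is None:
        subject_ids = tuple(range(n))
    cols = [np.ones(n)]
    for name, v in covariates.items():
        v = np.asarray(v, dtype=float)
        if v.shape != y.shape:
            raise ValueError(f"covariate {name!r} length mismatch")
        cols.append(v)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which covariates do not add rank when appended in order
        culprits, acc = [], [np.ones(n)]
        for name, v in covariates.items():
            trial = np.column_stack(acc + [np.asarray(v, dtype=float)])
            if np.linalg.matrix_rank(trial) == len(acc):
                culprits.append(name)
            else:
                acc.append(np.asarray(v, dtype=float))
        raise ValueError(f"rank-deficient design; collinear covariates: {culprits}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    residual = y - X @ beta
    lo, hi = float(residual.min()), float(residual.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        raise ValueError("constant residuals: cannot min-max scale")
    scaled = (residual - lo) / (hi - lo)
    return DependentVector(
        subject_ids=tuple(subject_ids),
        raw=y,
        residual=residual,
        scaled=scaled,
        covariates_used=tuple(covariates),
        scale_min=lo,
        scale_max=hi,
    )


def screen_covariates(
    dependent: Sequence[float],
    candidates: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen of candidate covariates with Bonferroni correction.

    Returns one row per candidate with ``r``, ``p_raw``,
    ``p_bonferroni`` (= min(1, p_raw * n_candidates)) and a ``flagged``
    column marking candidates whose corrected p falls below ``alpha``
    (those would be carried into the residualization).  Constant candidates
    have undefined correlation and are reported with NaN, never flagged.
    """
    y = np.asarray(dependent, dtype=float)
    if y.size < 4:
        raise ValueError("screening requires at least 4 subjects")
    m = len(candidates)
    rows = []
    for name, v in candidates.items():
        v = np.asarray(v, dtype=float)
        if v.shape != y.shape:
            raise ValueError(f"candidate {name!r} length mismatch")
        if np.ptp(v) == 0:
            rows.append((name, np.nan, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(y, v)
        p_adj = min(1.0, p * m)
        rows.append((name, float(r), float(p), float(p_adj), bool(p_adj < alpha)))
    return pd.DataFrame(
        rows, columns=["candidate", "r", "p_raw", "p_bonferroni", "flagged"]
    )


# ---------------------------------------------------------------------------
# cohort-level table I/O and scoring

_TASK_ALIASES = {
    "phonological_digit_matching": SpanTask.phonological_digit_matching,
    "digit_matching": SpanTask.phonological_digit_matching,
    "semantic_category_probe": SpanTask.semantic_category_probe,
    "category_probe": SpanTask.semantic_category_probe,
}


def read_span_tables(path) -> dict:
    """Read a long-format span TSV into per-subject, per-task SpanCurves.

    Columns: ``subject_id, task, list_length, n_trials, n_correct``.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for (sid, task_name), grp in df.groupby(["subject_id", "task"], sort=True):
        task = _TASK_ALIASES[str(task_name)]
        grp = grp.sort_values("list_length")
        entries = tuple(
            (int(r.list_length), int(r.n_trials), int(r.n_correct))
            for r in grp.itertuples()
        )
        out.setdefault(sid, {})[task] = SpanCurve(task=task, entries=entries)
    return out


def read_detection_tables(path) -> dict:
    """Read picture-word matching tallies into per-subject DetectionCounts.

    Long format with columns ``subject_id, condition, n_trials, n_correct``
    where condition is ``match``, ``phonological_foil`` or ``semantic_foil``.
    Hits come from the shared match trials; false alarms of a foil condition
    are its incorrect "same" responses (n_trials - n_correct).
    """
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        rows = {str(r.condition): (int(r.n_trials), int(r.n_correct)) for r in grp.itertuples()}
        n_match, n_hits = rows["match"]
        per = {}
        for cond in ("phonological_foil", "semantic_foil"):
            n_foil, n_cr = rows[cond]
            per[cond.removesuffix("_foil")] = DetectionCounts(
                n_match=n_match,
                n_hits=n_hits,
                n_foil=n_foil,
                n_false_alarms=n_foil - n_cr,
            )
        out[sid] = per
    return out


def score_cohort(
    span_curves: Mapping,
    detections: Mapping,
    lesion_volumes: Mapping | None = None,
    threshold: float = 0.75,
    correction: str = "half_trial",
) -> tuple[pd.DataFrame, dict]:
    """Score every subject and assemble the LSM dependent variables.

    Returns a per-subject table (spans, d' per foil condition, composite,
    residualized and scaled dependents) and a JSON-ready sidecar recording
    the covariates used, the d' correction mode and the scaling extremes.
    When ``lesion_volumes`` is given (voxel counts per subject), each span
    is residualized on lesion size, the input-processing composite and the
    opposing span, following the confound-control logic of the analysis.
    """
    sids = sorted(set(span_curves) & set(detections))
    if not sids:
        raise ValueError("no subjects present in both behavioral tables")
    rec = []
    for sid in sids:
        curves = span_curves[sid]
        phon = score_span(curves[SpanTask.phonological_digit_matching], threshold)
        sem = score_span(curves[SpanTask.semantic_category_probe], threshold)
        d_ph = score_dprime(detections[sid]["phonological"], correction)
        d_se = score_dprime(detections[sid]["semantic"], correction)
        rec.append((sid, phon.value, sem.value, d_ph.value, d_se.value))
    df = pd.DataFrame(
        rec,
        columns=["subject_id", "phon_span", "sem_span", "phon_dprime", "sem_dprime"],
    )
    comp = compute_composite(df["phon_dprime"], df["sem_dprime"])
    df["input_composite"] = comp.scores

    sidecar = {
        "dprime_correction": correction,
        "span_threshold": threshold,
        "composite": {
            "loadings": list(comp.loadings),
            "explained_variance_fraction": comp.explained_variance_fraction,
        },
    }
    if lesion_volumes is not None:
        vols = np.array([float(lesion_volumes[s]) for s in df["subject_id"]])
        for score, other in (("phon_span", "sem_span"), ("sem_span", "phon_span")):
            dv = residualize_and_scale(
                df[score].to_numpy(),
                {
                    "lesion_size": vols,
                    "input_composite": df["input_composite"].to_numpy(),
                    "other_wm": df[other].to_numpy(),
                },
                subject_ids=df["subject_id"].tolist(),
            )
            df[f"{score}_residual"] = dv.residual
            df[f"{score}_scaled"] = dv.scaled
            sidecar[score] = {
                "covariates": list(dv.covariates_used),
                "scale_min": dv.scale_min,
                "scale_max": dv.scale_max,
            }
    return df, sidecar
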