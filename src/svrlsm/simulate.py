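"""Synthetic lesion-deficit cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the mapping analysis
assumes: spatially clustered (blob-like) lesions on a shared template grid
with a right-skewed (lognormal) volume distribution, two ground-truth
regions whose damage lowers two distinct working-memory scores, a shared
behavioral factor producing the observed between-score correlation, and
trial-level behavioral tables (span curves with the 75% stop rule,
picture-word matching tallies) so the scoring stage is exercised end to
end, not bypassed.

The default grid (24 x 24 x 18 voxels at 1 mm) is a desk-scale stand-in
for a hemisphere; sampled lesion volumes follow the clinical lognormal
(mean 14 098 mm3, SD 18 641 mm3, clipped to [135, 104 243] mm3) scaled by
``volume_scale`` (default 1/64, i.e. the grid behaves like a hemisphere
sampled at 4 mm equivalent resolution).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.special import expit

from ._streams import substream
from .behavior import DetectionCounts, SpanCurve, SpanTask
from .lesions import LesionMask, LesionMatrix

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "lognormal_from_moments",
    "simulate_lesions",
    "simulate_behavior",
    "simulate_cohort",
    "evaluate_recovery",
]

# clinical lesion-volume distribution: mean 14 098, SD 18 641, range 135-104 243 mm3
_VOL_MEAN = 14098.0
_VOL_SD = 18641.0
_VOL_CLIP = (135.0, 104243.0)

_SPAN_LENGTHS = {
    SpanTask.phonological_digit_matching: ((2, 6), (3, 8), (4, 6), (5, 8), (6, 10)),
    SpanTask.semantic_category_probe: ((1, 8), (2, 8), (3, 12), (4, 16)),
}


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the analysis targets: 94 subjects, a
    right-skewed lesion-volume distribution, two disjoint truth regions
    driving two scores correlated at ~0.51, and input-processing d'
    scores correlated at ~0.69.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 94
    lesion_lognormal: tuple[float, float] = field(
        default_factory=lambda: lognormal_from_moments(_VOL_MEAN, _VOL_SD)
    )
    volume_clip_mm3: tuple[float, float] = _VOL_CLIP
    volume_scale: float = 1.0 / 64.0
    # spatial prior: blob seed centers (voxel coords) with draw weights
    blob_centers: tuple[tuple[float, float, float], ...] = (
        (7.0, 12.0, 9.0),
        (16.0, 12.0, 9.0),
        (11.0, 7.0, 9.0),
        (12.0, 16.0, 8.0),
        (12.0, 12.0, 12.0),
    )
    blob_weights: tuple[float, ...] = (0.25, 0.25, 0.2, 0.15, 0.15)
    center_jitter_sd: float = 2.5
    growth_irregularity: float = 0.35
    # disjoint ground-truth regions: spheres (center, radius in voxels)
    truth_a: tuple[tuple[float, float, float], float] = ((7.0, 12.0, 9.0), 3.0)
    truth_b: tuple[tuple[float, float, float], float] = ((16.0, 12.0, 9.0), 3.0)
    # behavioral generative model; defaults calibrated so the scored cohort
    # reproduces the clinical score distributions (phon span ~4.9 +/- 1.6,
    # sem span ~2.2 +/- 1.4)
    phon_baseline: float = 5.4
    sem_baseline: float = 2.5
    effect_phon: float = 5.0  # span-unit drop for full damage of region A
    effect_sem: float = 4.5  # span-unit drop for full damage of region B
    size_coef_phon: float = 0.4  # per SD of log lesion volume
    size_coef_sem: float = 0.4
    noise_sd: float = 0.6
    cross_score_corr: float = 0.51
    # input processing (picture-word matching)
    ip_phon_baseline: float = 3.1
    ip_sem_baseline: float = 2.7
    ip_size_coef: float = 0.45
    ip_noise_sd: float = 0.45
    input_proc_corr: float = 0.69
    span_slope: float = 2.0  # logistic steepness of accuracy vs list length
    min_truth_overlap: int = 5
    seed: int = 0

    def __post_init__(self):
        if not -1 < self.cross_score_corr < 1 or not -1 < self.input_proc_corr < 1:
            raise ValueError("correlation targets must lie in (-1, 1)")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if min(self.volume_clip_mm3) <= 0 or self.volume_scale <= 0:
            raise ValueError("volumes and scale must be positive")
        a, b = self.truth_masks()
        if np.any(a & b):
            raise ValueError("truth regions must be disjoint")

    def truth_masks(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            _sphere(self.grid_shape, *self.truth_a),
            _sphere(self.grid_shape, *self.truth_b),
        )


@dataclass
class SyntheticCohort:
    """Masks plus trial-level behavior and the latents that generated them."""

    config: SimConfig
    masks: list[LesionMask]
    truth_phon: np.ndarray  # boolean truth region for the phonological score
    truth_sem: np.ndarray
    span_curves: dict  # subject -> {SpanTask: SpanCurve}
    detections: dict  # subject -> {"phonological"/"semantic": DetectionCounts}
    latents: pd.DataFrame  # per-subject generating latents

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.masks]

    @property
    def lesion_voxel_counts(self) -> dict:
        return {m.subject_id: m.n_lesioned_voxels for m in self.masks}


def _sphere(shape, center, radius) -> np.ndarray:
    grid = np.indices(shape).reshape(3, -1).T
    d = np.linalg.norm(grid - np.asarray(center), axis=1)
    return (d <= radius).reshape(shape)


def _grow_blob(
    shape, center, n_voxels: int, irregularity: float, rng: np.random.Generator
) -> np.ndarray:
    """Connected blob of ``n_voxels`` around ``center``.

    Voxels accrete in order of distance-from-center perturbed by seeded
    noise (a priority flood), so blobs are compact but irregular, and
    6-connected by construction.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    start = tuple(
        int(np.clip(round(c), 0, s - 1)) for c, s in zip(center, shape)
    )
    heap = [(0.0, start)]
    seen = {start}
    taken = 0
    while heap and taken < n_voxels:
        _, v = heapq.heappop(heap)
        mask[v] = 1
        taken += 1
        for dim in range(3):
            for step in (-1, 1):
                w = list(v)
                w[dim] += step
                if not 0 <= w[dim] < shape[dim]:
                    continue
                w = tuple(w)
                if w in seen:
                    continue
                seen.add(w)
                d = math.dist(w, center)
                prio = d * (1.0 + irregularity * rng.random())
                heapq.heappush(heap, (prio, w))
    return mask


def simulate_lesions(cfg: SimConfig) -> list[LesionMask]:
    """Draw one blob lesion per subject from the spatial and size priors.

    Target volumes come from the clipped lognormal times ``volume_scale``;
    the cohort is resampled (logged on the returned masks' order) until
    each truth region contains at least ``min_truth_overlap`` subjects'
    damage somewhere, so the coverage filter cannot erase the signal.
    """
    rng = substream(cfg.seed, "lesion-sim")
    vox_mm3 = float(np.prod(cfg.voxel_dims))
    grid_n = int(np.prod(cfg.grid_shape))
    mu, sigma = cfg.lesion_lognormal
    centers = np.asarray(cfg.blob_centers, dtype=float)
    weights = np.asarray(cfg.blob_weights, dtype=float)
    weights = weights / weights.sum()
    need = min(cfg.min_truth_overlap, cfg.n_subjects)
    truth_a, truth_b = cfg.truth_masks()

    def draw_mask(sid: str, force_center=None) -> LesionMask:
        vol_mm3 = float(
            np.clip(rng.lognormal(mu, sigma), *cfg.volume_clip_mm3)
        ) * cfg.volume_scale
        n_vox = max(1, int(round(vol_mm3 / vox_mm3)))
        if n_vox > grid_n:
            raise ValueError(
                f"target lesion of {n_vox} voxels exceeds the {grid_n}-voxel grid"
            )
        if force_center is None:
            c = centers[rng.choice(len(centers), p=weights)]
        else:
            c = np.asarray(force_center, dtype=float)
        c = c + rng.normal(0.0, cfg.center_jitter_sd, size=3)
        c = np.clip(c, 0, np.asarray(cfg.grid_shape) - 1)
        blob = _grow_blob(cfg.grid_shape, tuple(c), n_vox, cfg.growth_irregularity, rng)
        return LesionMask(
            subject_id=sid,
            volume=blob,
            affine=np.diag([*cfg.voxel_dims, 1.0]),
            voxel_dims=cfg.voxel_dims,
        )

    masks = [draw_mask(f"sub-{i:03d}") for i in range(cfg.n_subjects)]

    # guarantee mappable coverage inside each truth region
    for _ in range(50):
        cov = np.sum([m.volume for m in masks], axis=0)
        ok_a = cov[truth_a].max(initial=0) >= need
        ok_b = cov[truth_b].max(initial=0) >= need
        if ok_a and ok_b:
            break
        region = cfg.truth_a if not ok_a else cfg.truth_b
        i = int(rng.integers(cfg.n_subjects))
        masks[i] = draw_mask(masks[i].subject_id, force_center=region[0])
    else:
        raise RuntimeError("could not achieve truth-region coverage; priors too thin")
    return masks


def _solve_shared_weight(a1, a2, noise_sd, target) -> float:
    """Shared-factor weight c so corr(a1 + c g + e1, a2 + c g + e2) = target."""
    v1, v2 = np.var(a1), np.var(a2)
    c12 = float(np.cov(a1, a2)[0, 1])

    def corr(c):
        return (c12 + c * c) / math.sqrt(
            (v1 + c * c + noise_sd**2) * (v2 + c * c + noise_sd**2)
        )

    if corr(0.0) > target:
        raise ValueError(
            f"correlation target {target} infeasible: lesion-driven correlation "
            f"already {corr(0.0):.3f} at the chosen noise level"
        )
    hi = 1.0
    while corr(hi) < target and hi < 1e3:
        hi *= 2.0
    return float(optimize.brentq(lambda c: corr(c) - target, 0.0, hi))


def simulate_behavior(masks: list[LesionMask], cfg: SimConfig) -> SyntheticCohort:
    """Generate trial-level behavior from lesion-driven latent scores.

    Latent score_k = baseline_k - effect_k * (damaged fraction of truth
    region k) - size_coef_k * z(log volume) + c*g + noise, with the shared
    factor weight c solved so the latent correlation hits
    ``cross_score_corr``.  Latents map to span curves via a logistic
    accuracy model whose 75% crossing sits at the latent (so the scored
    span estimates it), honouring the stop rule; input-processing latents
    map to picture-word-matching tallies with shared match trials.

    Trial-level sampling attenuates correlations between *scored*
    variables below the latent ones, so calibration is two-pass: a first
    draw measures the attenuation (reliability of each scored variable
    against its latent) and the shared weight is re-solved against the
    disattenuated target before the final draw.
    """
    if tuple(masks[0].volume.shape) != tuple(cfg.grid_shape):
        raise ValueError("masks are not on the configured grid")
    rng = substream(cfg.seed, "behavior-sim")
    truth_a, truth_b = cfg.truth_masks()
    n = len(masks)

    frac_a = np.array([m.volume[truth_a].mean() for m in masks])
    frac_b = np.array([m.volume[truth_b].mean() for m in masks])
    logvol = np.log([max(m.n_lesioned_voxels, 1) for m in masks])
    zvol = (logvol - logvol.mean()) / (logvol.std() or 1.0)

    a_phon = cfg.phon_baseline - cfg.effect_phon * frac_a - cfg.size_coef_phon * zvol
    a_sem = cfg.sem_baseline - cfg.effect_sem * frac_b - cfg.size_coef_sem * zvol
    a_ip_ph = cfg.ip_phon_baseline - cfg.ip_size_coef * zvol
    a_ip_se = cfg.ip_sem_baseline - cfg.ip_size_coef * zvol

    def draw(c_wm: float, c_ip: float):
        g = rng.normal(size=n)
        lat_phon = a_phon + c_wm * g + rng.normal(0.0, cfg.noise_sd, n)
        lat_sem = a_sem + c_wm * g + rng.normal(0.0, cfg.noise_sd, n)
        h = rng.normal(size=n)
        lat_ip_ph = a_ip_ph + c_ip * h + rng.normal(0.0, cfg.ip_noise_sd, n)
        lat_ip_se = a_ip_se + c_ip * h + rng.normal(0.0, cfg.ip_noise_sd, n)
        span_curves: dict = {}
        detections: dict = {}
        for i, m in enumerate(masks):
            sid = m.subject_id
            span_curves[sid] = {
                SpanTask.phonological_digit_matching: _draw_span_curve(
                    SpanTask.phonological_digit_matching,
                    lat_phon[i], cfg.span_slope, rng,
                ),
                SpanTask.semantic_category_probe: _draw_span_curve(
                    SpanTask.semantic_category_probe,
                    lat_sem[i], cfg.span_slope, rng,
                ),
            }
            detections[sid] = _draw_detections(lat_ip_ph[i], lat_ip_se[i], rng)
        return (lat_phon, lat_sem, lat_ip_ph, lat_ip_se), span_curves, detections

    # feasibility check at the configured targets (raises, naming the bound)
    c_wm = _solve_shared_weight(a_phon, a_sem, cfg.noise_sd, cfg.cross_score_corr)
    c_ip = _solve_shared_weight(a_ip_ph, a_ip_se, cfg.ip_noise_sd, cfg.input_proc_corr)

    # fixed-point calibration: adjust the latent correlation targets until the
    # *scored* correlations (which sampling attenuates and shared match trials
    # inflate) land on the configured targets
    t_wm, t_ip = cfg.cross_score_corr, cfg.input_proc_corr
    for _ in range(3):
        reps = [_scored_correlations(*draw(c_wm, c_ip)[1:]) for _ in range(3)]
        r_wm = float(np.mean([r[0] for r in reps]))
        r_ip = float(np.mean([r[1] for r in reps]))
        if (abs(r_wm - cfg.cross_score_corr) < 0.02
                and abs(r_ip - cfg.input_proc_corr) < 0.02):
            break
        t_wm = float(np.clip(t_wm * cfg.cross_score_corr / max(r_wm, 0.05), 0.02, 0.98))
        t_ip = float(np.clip(t_ip * cfg.input_proc_corr / max(r_ip, 0.05), 0.02, 0.98))
        c_wm = _solve_or_keep(a_phon, a_sem, cfg.noise_sd, t_wm, c_wm)
        c_ip = _solve_or_keep(a_ip_ph, a_ip_se, cfg.ip_noise_sd, t_ip, c_ip)
    lats, span_curves, detections = draw(c_wm, c_ip)
    lat_phon, lat_sem, lat_ip_ph, lat_ip_se = lats

    latents = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in masks],
            "frac_truth_phon": frac_a,
            "frac_truth_sem": frac_b,
            "latent_phon": lat_phon,
            "latent_sem": lat_sem,
            "latent_ip_phon": lat_ip_ph,
            "latent_ip_sem": lat_ip_se,
        }
    )
    return SyntheticCohort(
        config=cfg,
        masks=masks,
        truth_phon=truth_a,
        truth_sem=truth_b,
        span_curves=span_curves,
        detections=detections,
        latents=latents,
    )


def _solve_or_keep(a1, a2, noise_sd, target, fallback) -> float:
    """Shared weight for an adjusted internal target; keep ``fallback`` if
    the adjusted target is infeasible."""
    try:
        return _solve_shared_weight(a1, a2, noise_sd, target)
    except ValueError:
        return fallback


def _scored_correlations(span_curves, detections) -> tuple[float, float]:
    """Pearson correlations of the scored spans and the scored d' pairs."""
    from .behavior import score_dprime, score_span

    sids = list(span_curves)
    s_ph = [score_span(span_curves[s][SpanTask.phonological_digit_matching]).value
            for s in sids]
    s_se = [score_span(span_curves[s][SpanTask.semantic_category_probe]).value
            for s in sids]
    d_ph = [score_dprime(detections[s]["phonological"]).value for s in sids]
    d_se = [score_dprime(detections[s]["semantic"]).value for s in sids]
    return (
        float(np.corrcoef(s_ph, s_se)[0, 1]),
        float(np.corrcoef(d_ph, d_se)[0, 1]),
    )


def _draw_span_curve(
    task: SpanTask, latent: float, slope: float, rng: np.random.Generator
) -> SpanCurve:
    """Binomial trials per list length with accuracy 0.5 + 0.5*logistic;
    the 75% crossing sits at list length = latent.  Administration stops
    once sample accuracy drops below 75%."""
    entries = []
    for length, n_trials in _SPAN_LENGTHS[task]:
        p = 0.5 + 0.5 * expit(slope * (latent - length))
        n_correct = int(rng.binomial(n_trials, p))
        entries.append((length, n_trials, n_correct))
        if n_correct / n_trials < 0.75:
            break
    return SpanCurve(task=task, entries=tuple(entries))


def _draw_detections(
    d_phon: float, d_sem: float, rng: np.random.Generator, n_trials: int = 17
) -> dict:
    """Picture-word matching tallies with shared match trials.

    Match ability is the mean latent; foil-specific false-alarm rates are
    placed so the expected d' of condition k equals its latent.
    """
    ability = (d_phon + d_sem) / 2.0
    hit_p = float(stats.norm.cdf(ability / 2.0))
    n_hits = int(rng.binomial(n_trials, hit_p))
    z_hit = ability / 2.0
    out = {}
    for name, d in (("phonological", d_phon), ("semantic", d_sem)):
        fa_p = float(stats.norm.cdf(z_hit - d))
        n_fa = int(rng.binomial(n_trials, fa_p))
        out[name] = DetectionCounts(
            n_match=n_trials, n_hits=n_hits, n_foil=n_trials, n_false_alarms=n_fa
        )
    return out


def simulate_cohort(cfg: SimConfig | None = None, **overrides) -> SyntheticCohort:
    """Lesions + behavior in one call; ``overrides`` patch the default config."""
    cfg = replace(cfg or SimConfig(), **overrides) if overrides else (cfg or SimConfig())
    masks = simulate_lesions(cfg)
    return simulate_behavior(masks, cfg)


def evaluate_recovery(
    significance_map: np.ndarray,
    truth_map: np.ndarray,
    lm: LesionMatrix,
) -> dict:
    """Voxelwise confusion of a significance map against a truth region.

    Counts are restricted to covered voxels (those surviving the coverage
    filter) — outside coverage the method is silent by construction.
    Returns sensitivity, false-positive rate and Dice.
    """
    significance_map = np.asarray(significance_map)
    truth_map = np.asarray(truth_map, dtype=bool)
    if significance_map.shape != truth_map.shape or truth_map.shape != lm.grid_shape:
        raise ValueError("grid mismatch between map, truth and lesion matrix")
    covered = np.zeros(lm.grid_shape, dtype=bool).reshape(-1)
    covered[lm.voxel_index] = True
    covered = covered.reshape(lm.grid_shape)
    sig = np.nan_to_num(significance_map.astype(float), nan=0.0) != 0
    sig &= covered
    truth = truth_map & covered
    tp = int(np.count_nonzero(sig & truth))
    fp = int(np.count_nonzero(sig & ~truth))
    fn = int(np.count_nonzero(~sig & truth))
    tn = int(np.count_nonzero(~sig & ~truth & covered))
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "fpr": fp / (fp + tn) if fp + tn else 0.0,
        "dice": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }
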