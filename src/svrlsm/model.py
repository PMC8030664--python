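"""Multivariate SVR lesion-symptom mapping.

All lesion patches enter one epsilon-SVR with an RBF kernel that predicts
the (residualized, [0,1]-scaled) behavioral score from the damage pattern.
Patch multiplicities enter the kernel as squared-distance weights,

    k(u, v) = exp(-gamma * sum_j m_j (u_j - v_j)^2),

which makes the compressed patch fit exactly equivalent to fitting on the
full voxel matrix.  Hyperparameters (cost C, RBF gamma) are chosen on a
log grid by the permutation rank of the 5-fold cross-validated MSE:
shuffling the scores many times yields a null distribution of CV errors,
and the pair whose real error ranks lowest in its null wins.  Per-patch
inference then refits the chosen model on shuffled scores and ranks each
patch's back-projected beta in its permutation null; only the negative
tail (damage lowers performance) counts as evidence.

The statsmodels-style surface is :class:`SvrLsm` (model) and
:class:`SvrLsmResults` (results with ``summary()``); the underlying steps
are also exposed as functions (``fit_svr``, ``cv_mse``, ``select_params``,
``beta_map``, ``patch_inference``, ``run_lsm``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR

from ._streams import substream
from .lesions import LesionMatrix, PatchedMatrix, expand_map, summarize_regions

__all__ = [
    "HyperParams",
    "GridSearchResult",
    "LsmResult",
    "FittedSvr",
    "default_grid",
    "weighted_rbf_kernel",
    "fit_svr",
    "cv_mse",
    "select_params",
    "beta_map",
    "patch_inference",
    "run_lsm",
    "SvrLsm",
    "SvrLsmResults",
]

COST_BOUNDS = (1e-2, 1e9)
GAMMA_BOUNDS = (1e-9, 1e3)
# Bounded iterations keep pathological (huge-C) grid corners from stalling a
# grid search; at these problem sizes libsvm converges far below the cap.
_MAX_ITER = 2_000_000


@dataclass(frozen=True)
class HyperParams:
    """epsilon-SVR hyperparameters: cost C, RBF gamma, tube epsilon."""

    cost: float
    gamma: float
    epsilon: float = 0.1

    def __post_init__(self):
        if not COST_BOUNDS[0] <= self.cost <= COST_BOUNDS[1]:
            raise ValueError(f"cost {self.cost} outside {COST_BOUNDS}")
        if not GAMMA_BOUNDS[0] <= self.gamma <= GAMMA_BOUNDS[1]:
            raise ValueError(f"gamma {self.gamma} outside {GAMMA_BOUNDS}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class GridSearchResult:
    """Grid of (hyperparameters, CV MSE, permutation p) and the chosen pair."""

    grid: tuple[tuple[HyperParams, float, float], ...]
    chosen: HyperParams
    model_p: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class LsmResult:
    """Fitted map with per-patch permutation inference."""

    params: HyperParams
    patch_betas: np.ndarray
    patch_p: np.ndarray
    model_p: float
    significant_patches: np.ndarray  # boolean
    n_permutations: int
    seed: int
    alpha: float
    n_resampled_permutations: int = 0


@dataclass(frozen=True)
class FittedSvr:
    """Dual-form epsilon-SVR fit: signed alphas over support rows plus bias."""

    dual_coef: np.ndarray  # alpha_i (already signed), one per support vector
    support: np.ndarray  # row indices of support vectors in X
    intercept: float
    params: HyperParams


def default_grid(
    cost_bounds: tuple[float, float] = COST_BOUNDS,
    gamma_bounds: tuple[float, float] = GAMMA_BOUNDS,
    epsilon: float = 0.1,
) -> list[HyperParams]:
    """Decade-stepped log grid over the cost and gamma bounds (12 x 13 pairs
    at the default bounds)."""
    costs = _decades(*cost_bounds)
    gammas = _decades(*gamma_bounds)
    return [HyperParams(c, g, epsilon) for c in costs for g in gammas]


def _decades(lo: float, hi: float) -> list[float]:
    lo_e = math.ceil(round(math.log10(lo), 9))
    hi_e = math.floor(round(math.log10(hi), 9))
    out = [10.0 ** e for e in range(lo_e, hi_e + 1)]
    if not math.isclose(out[0], lo, rel_tol=1e-9):
        out.insert(0, lo)
    if not math.isclose(out[-1], hi, rel_tol=1e-9):
        out.append(hi)
    return out


def weighted_rbf_kernel(
    X: np.ndarray,
    gamma: float,
    multiplicities: np.ndarray | None = None,
    Y: np.ndarray | None = None,
) -> np.ndarray:
    """RBF kernel with per-feature squared-distance weights.

    With multiplicities m (patch voxel counts) this equals the plain RBF
    kernel on the voxel-expanded matrix, because identical voxel columns
    contribute m_j copies of the same squared difference.
    """
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if multiplicities is not None:
        w = np.sqrt(np.asarray(multiplicities, dtype=float))
        X = X * w
        Y = Y * w
    sq_x = np.einsum("ij,ij->i", X, X)
    sq_y = np.einsum("ij,ij->i", Y, Y)
    d2 = sq_x[:, None] + sq_y[None, :] - 2.0 * (X @ Y.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-gamma * d2)


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-d with at least 2 subjects")
    if y.shape != (X.shape[0],):
        raise ValueError("y length does not match X rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if np.ptp(y) == 0:
        raise ValueError("constant dependent variable: SVR fit is degenerate")
    return X, y


def _fit_precomputed(K: np.ndarray, y: np.ndarray, hp: HyperParams) -> SVR:
    svr = SVR(
        kernel="precomputed", C=hp.cost, epsilon=hp.epsilon, max_iter=_MAX_ITER, tol=1e-4
    )
    svr.fit(K, y)
    return svr


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    multiplicities: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> FittedSvr:
    """Fit the multiplicity-weighted RBF epsilon-SVR.

    ``kernel`` may carry a precomputed training kernel (permutation loops
    reuse it — the kernel does not depend on y).
    """
    X, y = _check_Xy(X, y)
    if kernel is None:
        kernel = weighted_rbf_kernel(X, hp.gamma, multiplicities)
    svr = _fit_precomputed(kernel, y, hp)
    return FittedSvr(
        dual_coef=svr.dual_coef_.ravel().copy(),
        support=svr.support_.copy(),
        intercept=float(svr.intercept_[0]),
        params=hp,
    )


def cv_mse(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    k: int = 5,
    seed: int = 0,
    multiplicities: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Mean over k shuffled folds of the held-out mean squared error."""
    X, y = _check_Xy(X, y)
    n = X.shape[0]
    if folds is None:
        folds = make_folds(n, k, substream(seed, "cv-folds"))
    if kernel is None:
        kernel = weighted_rbf_kernel(X, hp.gamma, multiplicities)
    errs = []
    for train, test in folds:
        if np.ptp(y[train]) == 0:
            # a fold with constant training scores carries no signal; predict
            # its constant
            pred = np.full(test.size, y[train][0])
        else:
            svr = _fit_precomputed(kernel[np.ix_(train, train)], y[train], hp)
            pred = svr.predict(kernel[np.ix_(test, train)])
        errs.append(float(np.mean((y[test] - pred) ** 2)))
    return float(np.mean(errs))


def make_folds(
    n: int, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold partition of ``range(n)``."""
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must lie in [2, n={n}]")
    perm = rng.permutation(n)
    parts = np.array_split(perm, k)
    return [
        (np.sort(np.concatenate(parts[:i] + parts[i + 1:])), np.sort(parts[i]))
        for i in range(k)
    ]


def select_params(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[HyperParams] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    k: int = 5,
    multiplicities: np.ndarray | None = None,
) -> GridSearchResult:
    """Choose hyperparameters by permutation rank of the cross-validated MSE.

    For each grid pair, the real CV MSE is ranked within the CV MSEs of
    ``n_perm`` score shuffles (one shared seeded set of shuffles scores the
    whole grid):  perm_p = (1 + #{null <= real}) / (n_perm + 1).  The pair
    with the smallest perm_p wins; ties break on the real CV MSE, then on
    smaller cost, then smaller gamma.  The winner's perm_p is the model
    significance.
    """
    X, y = _check_Xy(X, y)
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = X.shape[0]
    folds = make_folds(n, k, substream(seed, "cv-folds"))
    perm_rng = substream(seed, "param-perms")
    perms = [perm_rng.permutation(n) for _ in range(n_perm)]

    kernels = {}
    for hp in grid:
        if hp.gamma not in kernels:
            kernels[hp.gamma] = weighted_rbf_kernel(X, hp.gamma, multiplicities)

    entries = []
    for hp in grid:
        K = kernels[hp.gamma]
        real = cv_mse(X, y, hp, k=k, kernel=K, folds=folds)
        worse = sum(
            cv_mse(X, y[p], hp, k=k, kernel=K, folds=folds) <= real for p in perms
        )
        perm_p = (1 + worse) / (n_perm + 1)
        entries.append((hp, real, perm_p))

    chosen = min(entries, key=lambda e: (e[2], e[1], e[0].cost, e[0].gamma))
    return GridSearchResult(
        grid=tuple(entries),
        chosen=chosen[0],
        model_p=chosen[2],
        n_permutations=n_perm,
        seed=seed,
    )


def beta_map(fitted: FittedSvr, X: np.ndarray) -> np.ndarray:
    """Back-project the dual solution onto patch space.

    beta_j = sum over support vectors i of alpha_i * X_ij — the standard
    multivariate SVR-LSM sensitivity map.  Only the ranking of betas is
    interpreted (the scale depends on C and gamma).
    """
    if fitted.support.size == 0:
        raise ValueError("model has no support vectors; beta map undefined")
    X = np.asarray(X, dtype=float)
    return fitted.dual_coef @ X[fitted.support]


def sensitivity_map(
    fitted: FittedSvr,
    X: np.ndarray,
    multiplicities: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic-gradient alternative to back-projection.

    Mean over training rows of d f(x)/d x_j for the RBF decision function;
    exposed for comparison, not used by default inference.
    """
    if fitted.support.size == 0:
        raise ValueError("model has no support vectors")
    X = np.asarray(X, dtype=float)
    hp = fitted.params
    K = weighted_rbf_kernel(X, hp.gamma, multiplicities, Y=X[fitted.support])
    m = (
        np.ones(X.shape[1])
        if multiplicities is None
        else np.asarray(multiplicities, dtype=float)
    )
    # d/dx_j exp(-g*sum m (x-s)^2) = -2 g m_j (x_j - s_j) K(x, s)
    diffs = X[:, None, :] - X[fitted.support][None, :, :]
    grads = np.einsum("s,nsj,ns->nj", fitted.dual_coef, diffs, K)
    return (-2.0 * hp.gamma) * m * grads.mean(axis=0)


def patch_inference(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    multiplicities: np.ndarray | None = None,
    model_p: float = float("nan"),
    permutations: list[np.ndarray] | None = None,
    fdr: bool = False,
) -> LsmResult:
    """Per-patch permutation significance of the back-projected betas.

    The model is refit on ``n_perm`` shuffles of y; each patch's p-value is
    the add-one lower-tail rank of its observed beta in its permutation
    null, p = (1 + #{null beta <= observed}) / (n_perm + 1).  A patch is
    significant when p < alpha AND its observed beta is negative (damage is
    only expected to lower performance).  By default no correction across
    patches is applied; ``fdr=True`` switches the threshold to
    Benjamini-Hochberg-adjusted p-values instead.  A failed permutation
    fit is resampled (count recorded).
    """
    X, y = _check_Xy(X, y)
    n = X.shape[0]
    K = weighted_rbf_kernel(X, hp.gamma, multiplicities)
    observed = beta_map(fit_svr(X, y, hp, kernel=K), X)

    rng = substream(seed, "inference-perms")
    if permutations is not None:
        if len(permutations) != n_perm:
            raise ValueError("len(permutations) != n_perm")
        perm_iter = list(permutations)
    else:
        perm_iter = [rng.permutation(n) for _ in range(n_perm)]

    worse = np.zeros(X.shape[1], dtype=int)
    n_resampled = 0
    done = 0
    queue = list(perm_iter)
    while done < n_perm:
        p = queue.pop(0) if queue else rng.permutation(n)
        try:
            bperm = beta_map(fit_svr(X, y[p], hp, kernel=K), X)
        except ValueError:
            n_resampled += 1
            if n_resampled > 10 * n_perm:
                raise RuntimeError("permutation fits keep failing")
            queue.append(rng.permutation(n))
            continue
        worse += bperm <= observed
        done += 1

    patch_p = (1 + worse) / (n_perm + 1)
    if fdr:
        from scipy.stats import false_discovery_control

        significant = (false_discovery_control(patch_p) < alpha) & (observed < 0)
    else:
        significant = (patch_p < alpha) & (observed < 0)
    return LsmResult(
        params=hp,
        patch_betas=observed,
        patch_p=patch_p,
        model_p=model_p,
        significant_patches=significant,
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
        n_resampled_permutations=n_resampled,
    )


# ---------------------------------------------------------------------------
# Model / Results objects


class SvrLsm:
    """SVR lesion-symptom mapping model for one dependent variable.

    Parameters
    ----------
    endog : array-like
        Scaled dependent scores in [0, 1], one per subject (e.g. the
        ``scaled`` field of a :class:`~svrlsm.behavior.DependentVector`).
    patches : PatchedMatrix
        Compressed lesion design.
    lesion_matrix : LesionMatrix, optional
        Needed to expand results back onto the voxel grid.
    """

    def __init__(
        self,
        endog,
        patches: PatchedMatrix,
        lesion_matrix: LesionMatrix | None = None,
    ):
        y = np.asarray(endog, dtype=float)
        if y.shape != (patches.matrix.shape[0],):
            raise ValueError("endog length does not match subjects in design")
        self.endog = y
        self.patches = patches
        self.lesion_matrix = lesion_matrix
        self.exog = patches.matrix.astype(float)
        self.multiplicities = patches.patch_sizes.astype(float)

    @classmethod
    def from_cohort(cls, masks, endog, min_subjects: int = 5) -> "SvrLsm":
        """Build the design from lesion masks (coverage filter + patching)."""
        from .lesions import build_matrix, compress_patches

        lm = build_matrix(masks, min_subjects=min_subjects)
        pm = compress_patches(lm)
        return cls(endog, pm, lesion_matrix=lm)

    def fit(
        self,
        params: HyperParams | None = None,
        grid: list[HyperParams] | None = None,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int = 0,
        k: int = 5,
        reuse_selection_perms: bool = False,
    ) -> "SvrLsmResults":
        """Select hyperparameters (unless given) and run patch inference.

        ``reuse_selection_perms`` feeds the parameter-selection shuffles to
        patch inference instead of drawing fresh ones.
        """
        search = None
        if params is None:
            search = select_params(
                self.exog,
                self.endog,
                grid=grid,
                n_perm=n_perm,
                seed=seed,
                k=k,
                multiplicities=self.multiplicities,
            )
            params = search.chosen
            model_p = search.model_p
        else:
            model_p = float("nan")
        perms = None
        if reuse_selection_perms:
            n = self.exog.shape[0]
            perm_rng = substream(seed, "param-perms")
            perms = [perm_rng.permutation(n) for _ in range(n_perm)]
        inference = patch_inference(
            self.exog,
            self.endog,
            params,
            n_perm=n_perm,
            alpha=alpha,
            seed=seed,
            multiplicities=self.multiplicities,
            model_p=model_p,
            permutations=perms,
        )
        return SvrLsmResults(self, inference, search)


@dataclass
class SvrLsmResults:
    """Fitted SVR-LSM: chosen hyperparameters, beta map, permutation p-values.

    Wraps the model, the per-patch inference and (when a grid search ran)
    the search trace; exposes voxel-space expansions and a text summary.
    """

    model: SvrLsm
    inference: LsmResult
    search: GridSearchResult | None = None

    # -- convenience accessors -------------------------------------------
    @property
    def params(self) -> HyperParams:
        return self.inference.params

    @property
    def patch_betas(self) -> np.ndarray:
        return self.inference.patch_betas

    @property
    def patch_p(self) -> np.ndarray:
        return self.inference.patch_p

    @property
    def model_p(self) -> float:
        return self.inference.model_p

    @property
    def significant_patches(self) -> np.ndarray:
        return self.inference.significant_patches

    # -- voxel-space views ------------------------------------------------
    def _require_lm(self) -> LesionMatrix:
        if self.model.lesion_matrix is None:
            raise ValueError("no LesionMatrix attached; voxel expansion unavailable")
        return self.model.lesion_matrix

    def beta_volume(self) -> np.ndarray:
        return expand_map(self.patch_betas, self.model.patches, self._require_lm())

    def p_volume(self) -> np.ndarray:
        return expand_map(self.patch_p, self.model.patches, self._require_lm())

    def significance_volume(self) -> np.ndarray:
        return expand_map(
            self.significant_patches.astype(float),
            self.model.patches,
            self._require_lm(),
            fill_value=0.0,
        )

    def region_table(self, atlas_volume, min_volume_mm3: float = 100.0, region_names=None):
        lm = self._require_lm()
        return summarize_regions(
            self.significance_volume(),
            atlas_volume,
            lm.voxel_dims,
            min_volume_mm3=min_volume_mm3,
            region_names=region_names,
        )

    def summary(self) -> str:
        inf = self.inference
        n_sig = int(inf.significant_patches.sum())
        lines = [
            "SVR lesion-symptom mapping results",
            "==================================",
            f"subjects:              {self.model.exog.shape[0]}",
            f"patches:               {self.model.exog.shape[1]}",
            f"voxels (covered):      {int(self.model.multiplicities.sum())}",
            f"cost (C):              {inf.params.cost:g}",
            f"gamma:                 {inf.params.gamma:g}",
            f"epsilon:               {inf.params.epsilon:g}",
            f"model p (permutation): {inf.model_p:.4g}",
            f"permutations:          {inf.n_permutations}",
            f"alpha:                 {inf.alpha:g}  (one-sided, negative betas)",
            f"significant patches:   {n_sig} "
            f"({100.0 * n_sig / max(1, inf.patch_p.size):.1f}%)",
            f"seed:                  {inf.seed}",
        ]
        if inf.n_resampled_permutations:
            lines.append(
                f"resampled permutations: {inf.n_resampled_permutations}"
            )
        return "\n".join(lines)


def run_lsm(
    masks,
    endog,
    atlas_volume=None,
    min_subjects: int = 5,
    params: HyperParams | None = None,
    grid: list[HyperParams] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    output_dir=None,
    region_names=None,
) -> SvrLsmResults:
    """End-to-end mapping: masks -> matrix -> patches -> fit -> maps.

    Deterministic given ``seed``.  When ``output_dir`` is given, writes the
    beta / p / significance maps as NIfTI, the search trace as JSON and the
    region table (if an atlas is supplied) as TSV.
    """
    model = SvrLsm.from_cohort(masks, endog, min_subjects=min_subjects)
    res = model.fit(
        params=params, grid=grid, n_perm=n_perm, alpha=alpha, seed=seed
    )
    if output_dir is not None:
        from .io import save_results

        save_results(res, output_dir, atlas_volume=atlas_volume, region_names=region_names)
    return res
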