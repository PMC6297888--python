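"""Presence/background species distribution modeling and the CA50 fallback.

The occurrence model is a maximum-entropy-style presence/background model
fit as its penalized-logistic equivalent (maxnet family): linear plus
quadratic features of the 26 predictors, L1-regularized, standardized
against background statistics. Species with fewer than
``MIN_PRESENCES_FOR_MODEL`` georeferenced presences fall back to the CA50
circular-buffer model (all cells within 50 km of an occurrence point).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .core_grid import GridSpec, RasterLayer, cell_center, cell_index, haversine_km_vec
from .predictors import PredictorStack

logger = logging.getLogger(__name__)

MIN_PRESENCES_FOR_MODEL = 10
DEFAULT_BACKGROUND_SIZE = 10_000
DEFAULT_K_FOLDS = 5
DEFAULT_REGULARIZATION = 1.0
AUC_PASS_MEAN = 0.7
AUC_PASS_SD = 0.15
CA50_RADIUS_KM = 50.0


@dataclass
class ValidationMetrics:
    mean_test_auc: float = float("nan")
    sd_test_auc: float = float("nan")
    fold_count: int = 0
    n_presence: int = 0
    n_background: int = 0
    threshold: float = float("nan")

    def passed(self, mean_floor: float = AUC_PASS_MEAN, sd_cap: float = AUC_PASS_SD) -> bool:
        return bool(
            np.isfinite(self.mean_test_auc)
            and self.mean_test_auc >= mean_floor
            and self.sd_test_auc <= sd_cap
        )


@dataclass
class SDMOutput:
    species_id: str
    probability: RasterLayer | None
    presence: RasterLayer
    model_kind: str  # "maxent_like" | "ca50"
    metrics: ValidationMetrics = field(default_factory=ValidationMetrics)
    passed: bool = False


class TooFewPresencesError(ValueError):
    """Raised when a species has too few presences for the model pathway."""


def sample_pseudo_absences(
    mask: RasterLayer,
    presence_cells: set[tuple[int, int]],
    n: int,
    seed: int,
) -> list[tuple[float, float]]:
    """Draw ``n`` distinct cell centres uniformly from mask=1 cells,
    excluding presence cells. Reproducible for a fixed seed."""
    if mask.semantics != "binary":
        raise ValueError("mask must be binary")
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = np.nonzero(mask.values == 1)
    eligible = [
        (int(r), int(c)) for r, c in zip(rows, cols) if (int(r), int(c)) not in presence_cells
    ]
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} eligible background cells for n={n}; drawing all",
            stacklevel=2,
        )
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    return [cell_center(mask.grid, r, c) for r, c in chosen]


def _points_to_cells(points, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    for lon, lat in points:
        r, c = cell_index(grid, lon, lat)
        rows.append(r)
        cols.append(c)
    return np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)


def _design_matrix(x: np.ndarray) -> np.ndarray:
    """Linear + quadratic features, column-stacked."""
    return np.hstack([x, x**2])


class _FittedModel:
    """Standardization + L1 logistic coefficient bundle."""

    def __init__(self, mean, std, keep, clf, feature_names):
        self.mean = mean
        self.std = std
        self.keep = keep
        self.clf = clf
        self.feature_names = feature_names

    def decision(self, x_raw: np.ndarray) -> np.ndarray:
        z = (x_raw - self.mean) / self.std
        feats = _design_matrix(z)[:, self.keep]
        return self.clf.decision_function(feats)

    def coefficients(self) -> dict[str, float]:
        coefs = np.zeros(len(self.feature_names))
        coefs[self.keep] = self.clf.coef_.ravel()
        return dict(zip(self.feature_names, coefs))


def _fit(
    x_pres: np.ndarray,
    x_back: np.ndarray,
    stack_names: list[str],
    reg: float,
    seed: int,
) -> _FittedModel:
    mean = np.nanmean(x_back, axis=0)
    std = np.nanstd(x_back, axis=0)
    degenerate = ~np.isfinite(std) | (std == 0)
    if degenerate.any():
        logger.warning(
            "dropping zero-variance predictors: %s",
            [stack_names[i] for i in np.nonzero(degenerate)[0]],
        )
    std = np.where(degenerate, 1.0, std)

    zp = (x_pres - mean) / std
    zb = (x_back - mean) / std
    fp = _design_matrix(zp)
    fb = _design_matrix(zb)
    feature_names = [f"{n}" for n in stack_names] + [f"{n}^2" for n in stack_names]
    # degenerate predictors yield constant features in both blocks: drop
    keep = np.ones(fp.shape[1], dtype=bool)
    keep[: len(stack_names)][degenerate] = False
    keep[len(stack_names):][degenerate] = False

    X = np.vstack([fp, fb])[:, keep]
    y = np.concatenate([np.ones(len(fp)), np.zeros(len(fb))])
    X = np.nan_to_num(X, nan=0.0)

    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=1.0 / reg,
        solver="liblinear",
        max_iter=2000,
        random_state=seed,
    )
    clf.fit(X, y)
    if clf.n_iter_.max() >= 2000:
        raise RuntimeError(
            f"logistic fit did not converge in {clf.n_iter_.max()} iterations "
            f"(n_presence={len(fp)}, n_background={len(fb)}, reg={reg})"
        )
    return _FittedModel(mean, std, keep, clf, feature_names)


def fit_occurrence_model(
    presences: list[tuple[float, float]],
    background: list[tuple[float, float]],
    stack: PredictorStack,
    mask: RasterLayer,
    reg: float = DEFAULT_REGULARIZATION,
    seed: int = 0,
) -> tuple[RasterLayer, _FittedModel]:
    """Fit the presence/background model and predict over all mask cells.

    Returns a probability layer rescaled to [0, 1] over mask cells
    (nodata elsewhere) and the fitted model.
    """
    if len(presences) < MIN_PRESENCES_FOR_MODEL:
        raise TooFewPresencesError(
            f"{len(presences)} presences < minimum {MIN_PRESENCES_FOR_MODEL}"
        )
    grid = stack.grid
    pr, pc = _points_to_cells(presences, grid)
    br, bc = _points_to_cells(background, grid)
    x_pres = stack.values_at_cells(pr, pc)
    x_back = stack.values_at_cells(br, bc)
    model = _fit(x_pres, x_back, stack.names, reg, seed)

    mrows, mcols = np.nonzero(mask.values == 1)
    x_all = stack.values_at_cells(mrows, mcols)
    scores = model.decision(np.nan_to_num(x_all, nan=0.0))
    # logistic output: in [0,1], flat when the penalty zeroes the weights
    prob = 1.0 / (1.0 + np.exp(-np.clip(scores, -500, 500)))

    out = np.full(grid.shape, grid.nodata, dtype=float)
    out[mrows, mcols] = prob
    return RasterLayer(grid, out, "continuous"), model


def validate_kfold(
    presences: list[tuple[float, float]],
    background: list[tuple[float, float]],
    stack: PredictorStack,
    mask: RasterLayer,
    k: int = DEFAULT_K_FOLDS,
    seed: int = 0,
    reg: float = DEFAULT_REGULARIZATION,
) -> ValidationMetrics:
    """k-fold cross-validation over presences (background shared)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(presences) < k or len(presences) < MIN_PRESENCES_FOR_MODEL:
        raise TooFewPresencesError(
            f"{len(presences)} presences insufficient for {k}-fold validation"
        )
    grid = stack.grid
    pr, pc = _points_to_cells(presences, grid)
    br, bc = _points_to_cells(background, grid)
    x_pres = stack.values_at_cells(pr, pc)
    x_back = np.nan_to_num(stack.values_at_cells(br, bc), nan=0.0)

    aucs = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(x_pres):
        model = _fit(x_pres[train_idx], x_back, stack.names, reg, seed)
        s_test = model.decision(np.nan_to_num(x_pres[test_idx], nan=0.0))
        s_back = model.decision(x_back)
        y = np.concatenate([np.ones(len(s_test)), np.zeros(len(s_back))])
        aucs.append(roc_auc_score(y, np.concatenate([s_test, s_back])))

    return ValidationMetrics(
        mean_test_auc=float(np.mean(aucs)),
        sd_test_auc=float(np.std(aucs, ddof=0)),
        fold_count=k,
        n_presence=len(presences),
        n_background=len(background),
    )


def threshold_presence(
    probability: RasterLayer,
    presences: list[tuple[float, float]],
    background: list[tuple[float, float]] | None = None,
) -> tuple[RasterLayer, float]:
    """Binarize by the threshold maximizing sensitivity + specificity.

    Candidates are the distinct predicted values at presences and
    background points (background defaults to all data cells). Cells with
    probability >= threshold become 1.
    """
    grid = probability.grid
    pr, pc = _points_to_cells(presences, grid)
    p_pres = probability.values[pr, pc]
    if background is None:
        b_vals = probability.values[probability.data_mask()]
    else:
        br, bc = _points_to_cells(background, grid)
        b_vals = probability.values[br, bc]

    candidates = np.unique(np.concatenate([p_pres, b_vals]))
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        sens = np.mean(p_pres >= t)
        spec = np.mean(b_vals < t)
        j = sens + spec
        if j > best_j:
            best_j, best_t = j, t

    data = probability.data_mask()
    out = np.zeros(grid.shape, dtype=float)
    out[data & (probability.values >= best_t)] = 1.0
    return RasterLayer(grid, out, "binary"), float(best_t)


def ca50(
    occurrence_points: list[tuple[float, float]],
    grid: GridSpec,
    mask: RasterLayer,
    radius_km: float = CA50_RADIUS_KM,
) -> RasterLayer:
    """Circular-buffer model: cell=1 iff its centre lies within
    ``radius_km`` of any occurrence point, intersected with the mask."""
    if not occurrence_points:
        raise ValueError("ca50 requires at least one georeferenced occurrence")
    lats = grid.row_center_lats()
    lons = grid.col_center_lons()
    lon_g, lat_g = np.meshgrid(lons, lats)
    within = np.zeros(grid.shape, dtype=bool)
    for lon, lat in occurrence_points:
        d = haversine_km_vec(lon_g, lat_g, lon, lat)
        within |= d <= radius_km
    out = (within & (mask.values == 1)).astype(float)
    return RasterLayer(grid, out, "binary")


def run_species_sdm(
    species_id: str,
    presence_points: list[tuple[float, float]],
    stack: PredictorStack,
    mask: RasterLayer,
    seed: int = 0,
    n_background: int = DEFAULT_BACKGROUND_SIZE,
    k: int = DEFAULT_K_FOLDS,
    reg: float = DEFAULT_REGULARIZATION,
) -> SDMOutput:
    """Full per-species pathway: model + validation when possible,
    thresholded presence if validation passes, CA50 fallback otherwise."""
    grid = stack.grid
    try:
        pr, pc = _points_to_cells(presence_points, grid)
        presence_cells = set(zip(pr.tolist(), pc.tolist()))
        if len(presence_points) < MIN_PRESENCES_FOR_MODEL:
            raise TooFewPresencesError("below modeling minimum")
        background = sample_pseudo_absences(mask, presence_cells, n_background, seed)
        metrics = validate_kfold(presence_points, background, stack, mask, k=k, seed=seed, reg=reg)
        if metrics.passed():
            prob, _model = fit_occurrence_model(
                presence_points, background, stack, mask, reg=reg, seed=seed
            )
            presence, thr = threshold_presence(prob, presence_points, background)
            metrics.threshold = thr
            return SDMOutput(species_id, prob, presence, "maxent_like", metrics, True)
        buffer = ca50(presence_points, grid, mask)
        return SDMOutput(species_id, None, buffer, "ca50", metrics, False)
    except TooFewPresencesError:
        buffer = ca50(presence_points, grid, mask)
        return SDMOutput(species_id, None, buffer, "ca50", ValidationMetrics(), False)
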