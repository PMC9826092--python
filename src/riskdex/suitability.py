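"""Minimal ensemble niche modelling.

The protocol, per species: correlation-based variable pre-selection
(pairwise Pearson |r| < 0.8 among retained variables), 1000 uniformly drawn
pseudo-absences shared by all replicates, repeated 70/30
calibration/validation splits, several lightweight learner families fitted
per split, Kappa/TSS/AUC validation metrics, per-replicate max-TSS
binarization, and an AUC-weighted ensemble of the replicate binary maps,
itself binarized by max-TSS on pooled validation data.  Projection is
restricted to the species' calibration/transference area (the limited
full-dispersal assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import ClimateStack, GridSpec, RasterGrid, check_same_grid
from .occurrences import CalibrationArea
from .synthetic_world import ScenarioSpec

DEFAULT_R_MAX = 0.8
DEFAULT_N_PSEUDO_ABSENCES = 1000
DEFAULT_CALIBRATION_FRACTION = 0.7
DEFAULT_N_REPLICATES = 10
MIN_ENSEMBLE_AUC = 0.5


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def confusion_counts(obs: np.ndarray, scores: np.ndarray,
                     threshold: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN); a score equal to the threshold counts as presence."""
    obs = np.asarray(obs).astype(bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & obs))
    fp = int(np.sum(pred & ~obs))
    tn = int(np.sum(~pred & ~obs))
    fn = int(np.sum(~pred & obs))
    return tp, fp, tn, fn


def tss(tp: int, fp: int, tn: int, fn: int) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if tp + fn == 0:
        raise ZeroDivisionError("TSS undefined: no observed presences")
    if tn + fp == 0:
        raise ZeroDivisionError("TSS undefined: no observed absences")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def kappa(tp: int, fp: int, tn: int, fn: int) -> float:
    """Cohen's kappa from the 2x2 confusion table."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ZeroDivisionError("kappa undefined: empty table")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def auc(obs: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Ties between a presence and an absence score count one half.
    """
    obs = np.asarray(obs).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n1 = int(obs.sum())
    n0 = int((~obs).sum())
    if n1 == 0 or n0 == 0:
        raise ZeroDivisionError("AUC undefined: one class missing")
    ranks = rankdata(scores)
    return float((ranks[obs].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def max_tss_threshold(obs: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing TSS over midpoints of sorted unique scores + {0, 1}.

    Ties in TSS break toward the lowest threshold.  Returns (threshold, tss).
    """
    obs = np.asarray(obs).astype(bool)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    candidates = [0.0]
    candidates.extend(((uniq[:-1] + uniq[1:]) / 2.0).tolist())
    candidates.append(1.0)
    best_t, best_v = 0.0, -np.inf
    for t in sorted(set(candidates)):
        v = tss(*confusion_counts(obs, scores, t))
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return float(best_t), float(best_v)


# ---------------------------------------------------------------------------
# variable pre-selection
# ---------------------------------------------------------------------------

def preselect_variables(stack: ClimateStack, points: np.ndarray,
                        r_max: float = DEFAULT_R_MAX) -> list[str]:
    """Iteratively drop collinear variables until all pairwise |r| < r_max.

    Pearson correlations are computed on values sampled at the supplied
    points (occurrences plus pseudo-absences).  At each step the variable
    with the largest mean |r| against all remaining ones is dropped (ties
    drop the later-ordered variable).  Constant variables are dropped with
    a warning before correlation is attempted.
    """
    names = list(stack.names)
    if len(names) < 2:
        return names
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to estimate correlations")
    X = stack.sample(pts[:, 0], pts[:, 1], names)

    keep = []
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0:
            warnings.warn(f"variable {name!r} constant at sample points; dropped")
        else:
            keep.append(j)
    names = [names[j] for j in keep]
    X = X[:, keep]
    if len(names) < 2:
        return names

    while True:
        r = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(r, 0.0)
        if r.max() < r_max or X.shape[1] == 1:
            return names
        mean_r = r.mean(axis=1)
        # later-ordered variable wins the drop on ties
        worst = int(np.flatnonzero(mean_r >= mean_r.max() - 1e-12)[-1])
        del names[worst]
        X = np.delete(X, worst, axis=1)


# ---------------------------------------------------------------------------
# pseudo-absences and splits
# ---------------------------------------------------------------------------

def area_mask(polygon, grid: GridSpec) -> np.ndarray:
    """Boolean raster of cells whose centres fall inside a polygon."""
    lon, lat = grid.cell_centers()
    return shapely.contains_xy(polygon, lon.ravel(), lat.ravel()).reshape(grid.shape)


def sample_pseudo_absences(area: CalibrationArea | np.ndarray, grid: GridSpec,
                           n: int = DEFAULT_N_PSEUDO_ABSENCES,
                           rng: np.random.Generator | int | None = None
                           ) -> np.ndarray:
    """n background points uniform over the calibration area's cells."""
    rng = np.random.default_rng(rng)
    mask = area if isinstance(area, np.ndarray) else area_mask(area.polygon, grid)
    cells = np.flatnonzero(mask.ravel())
    if cells.size == 0:
        raise ValueError("calibration area covers no grid cells")
    if n == 0:
        return np.empty((0, 2))
    replace = cells.size < n
    if replace:
        warnings.warn(
            f"calibration area has {cells.size} cells < {n} pseudo-absences; "
            "sampling with replacement")
    chosen = rng.choice(cells, size=n, replace=replace)
    lon, lat = grid.cell_centers()
    return np.column_stack([lon.ravel()[chosen], lat.ravel()[chosen]])


def split_records(presences: np.ndarray, pseudo_absences: np.ndarray,
                  calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION,
                  rng: np.random.Generator | int | None = None):
    """Stratified 70/30 split; presence count rounded half-up."""
    rng = np.random.default_rng(rng)
    pres = np.atleast_2d(np.asarray(presences, dtype=float))
    absn = np.atleast_2d(np.asarray(pseudo_absences, dtype=float))
    if pres.shape[0] < 2:
        raise ValueError("need at least 2 presences to split")

    def _split(arr):
        n = arr.shape[0]
        k = int(np.floor(calibration_fraction * n + 0.5))
        k = min(max(k, 1), n - 1) if n > 1 else n
        order = rng.permutation(n)
        return arr[order[:k]], arr[order[k:]]

    p_tr, p_te = _split(pres)
    a_tr, a_te = _split(absn) if absn.shape[0] > 1 else (absn, absn[:0])
    return (p_tr, a_tr), (p_te, a_te)


# ---------------------------------------------------------------------------
# learner families
# ---------------------------------------------------------------------------

class LogisticQuadraticLearner:
    """Regularized logistic regression on linear + quadratic climate terms."""

    name = "logistic"

    def __init__(self, random_state: int = 0):
        self.model = make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(C=1.0, max_iter=2000))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticQuadraticLearner":
        self.model.fit(X, y)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


class TreeLearner:
    """Recursive-partition classification tree."""

    name = "tree"

    def __init__(self, random_state: int = 0):
        self.model = DecisionTreeClassifier(max_depth=6, min_samples_leaf=5,
                                            random_state=random_state)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeLearner":
        self.model.fit(X, y)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


class EnvelopeLearner:
    """Rectilinear climate envelope over the training presences.

    Inside the presence min-max box on every variable the score is 1;
    outside it decays with the summed normalized exceedance, so training
    presences always score strictly above any clearly unsuitable cell.
    """

    name = "envelope"

    def __init__(self, random_state: int = 0, decay: float = 5.0):
        self.decay = decay
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None
        self.width: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnvelopeLearner":
        pres = np.asarray(X)[np.asarray(y).astype(bool)]
        if pres.shape[0] == 0:
            raise ValueError("envelope learner needs at least one presence")
        self.lo = pres.min(axis=0)
        self.hi = pres.max(axis=0)
        self.width = np.maximum(self.hi - self.lo, 1e-9)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        below = np.maximum(self.lo - X, 0.0) / self.width
        above = np.maximum(X - self.hi, 0.0) / self.width
        exceed = (below + above).sum(axis=1)
        return np.exp(-self.decay * exceed)


DEFAULT_LEARNER_FAMILIES = (LogisticQuadraticLearner, TreeLearner, EnvelopeLearner)


@dataclass
class ModelReplicate:
    """One fitted learner with its validation record."""

    family: str
    replicate_index: int
    learner: object
    threshold: float           # max-TSS threshold on this replicate's validation
    metrics: dict              # kappa, tss, auc on validation
    val_X: np.ndarray = field(repr=False, default=None)
    val_y: np.ndarray = field(repr=False, default=None)

    def binary(self, X: np.ndarray) -> np.ndarray:
        return (self.learner.score_samples(X) >= self.threshold).astype(float)


def fit_replicates(presence_X: np.ndarray, absence_X: np.ndarray,
                   learner_families=DEFAULT_LEARNER_FAMILIES,
                   n_replicates: int = DEFAULT_N_REPLICATES,
                   rng: np.random.Generator | int | None = None
                   ) -> list[ModelReplicate]:
    """R replicates per family, each on a fresh 70/30 resplit."""
    rng = np.random.default_rng(rng)
    presence_X = np.atleast_2d(presence_X)
    absence_X = np.atleast_2d(absence_X)
    if presence_X.shape[0] == 0 or absence_X.shape[0] == 0:
        raise ValueError("degenerate training data: a class is empty")
    replicates = []
    for rep in range(1, n_replicates + 1):
        (p_tr, a_tr), (p_te, a_te) = split_records(presence_X, absence_X,
                                                   rng=rng)
        X_tr = np.vstack([p_tr, a_tr])
        y_tr = np.concatenate([np.ones(len(p_tr)), np.zeros(len(a_tr))])
        X_te = np.vstack([p_te, a_te])
        y_te = np.concatenate([np.ones(len(p_te)), np.zeros(len(a_te))])
        for family in learner_families:
            learner = family(random_state=int(rng.integers(2 ** 31))).fit(X_tr, y_tr)
            scores = learner.score_samples(X_te)
            thr, tss_val = max_tss_threshold(y_te, scores)
            metrics = {
                "kappa": kappa(*confusion_counts(y_te, scores, thr)),
                "tss": tss_val,
                "auc": auc(y_te, scores),
            }
            replicates.append(ModelReplicate(
                family=learner.name, replicate_index=rep, learner=learner,
                threshold=thr, metrics=metrics, val_X=X_te, val_y=y_te))
    return replicates


# ---------------------------------------------------------------------------
# ensembling and projection
# ---------------------------------------------------------------------------

@dataclass
class SuitabilityMap:
    """Per species x scenario continuous/binary suitability surfaces."""

    species_id: str
    scenario: ScenarioSpec
    continuous: RasterGrid     # [0,1] inside the transference area, NaN outside
    binary: RasterGrid         # {0,1} inside, NaN outside
    threshold: float
    metrics: list[dict]

    @property
    def pda_pixels(self) -> int:
        return int(np.nansum(self.binary.values == 1))


def ensemble(replicates: list[ModelReplicate], stack: ClimateStack,
             mask: np.ndarray, variable_names: list[str],
             species_id: str, scenario: ScenarioSpec) -> SuitabilityMap:
    """AUC-weighted mean of replicate binary maps, max-TSS binarized.

    Replicates with validation AUC <= 0.5 carry no information beyond chance
    and are dropped (with a warning); the ensemble threshold is the max-TSS
    cut of the ensemble score evaluated on the pooled validation data of the
    retained replicates.
    """
    kept = [r for r in replicates if r.metrics["auc"] > MIN_ENSEMBLE_AUC]
    if not kept:
        raise ValueError("no replicate with validation AUC > 0.5")
    # canonical order makes the floating-point sum independent of the
    # caller's replicate ordering
    kept.sort(key=lambda r: (r.family, r.replicate_index, -r.metrics["auc"]))
    if len(kept) < len(replicates):
        warnings.warn(f"dropped {len(replicates) - len(kept)} replicate(s) "
                      "with AUC <= 0.5 from the ensemble")
    weights = np.array([r.metrics["auc"] for r in kept])
    wsum = weights.sum()

    rows, cols = np.nonzero(mask)
    lon, lat = stack.spec.cell_centers()
    X_cells = stack.sample(lon[rows, cols], lat[rows, cols], variable_names)

    cont_cells = np.zeros(len(rows))
    for w, rep in zip(weights, kept):
        cont_cells += w * rep.binary(X_cells)
    cont_cells /= wsum

    # ensemble threshold from pooled validation data
    pool_X = np.vstack([r.val_X for r in kept])
    pool_y = np.concatenate([r.val_y for r in kept])
    pool_scores = np.zeros(len(pool_X))
    for w, rep in zip(weights, kept):
        pool_scores += w * rep.binary(pool_X)
    pool_scores /= wsum
    thr, _ = max_tss_threshold(pool_y, pool_scores)

    continuous = np.full(stack.spec.shape, np.nan)
    continuous[rows, cols] = cont_cells
    binary = np.full(stack.spec.shape, np.nan)
    binary[rows, cols] = (cont_cells >= thr).astype(float)

    metrics = [{"family": r.family, "replicate": r.replicate_index,
                **r.metrics, "threshold": r.threshold} for r in kept]
    return SuitabilityMap(species_id=species_id, scenario=scenario,
                          continuous=RasterGrid(stack.spec, continuous),
                          binary=RasterGrid(stack.spec, binary),
                          threshold=thr, metrics=metrics)


def model_species(species_id: str, occurrences: np.ndarray,
                  calibration: CalibrationArea,
                  climate: dict[str, ClimateStack],
                  scenarios: list[ScenarioSpec],
                  current: ScenarioSpec,
                  n_pseudo_absences: int = DEFAULT_N_PSEUDO_ABSENCES,
                  n_replicates: int = DEFAULT_N_REPLICATES,
                  learner_families=DEFAULT_LEARNER_FAMILIES,
                  r_max: float = DEFAULT_R_MAX,
                  rng: np.random.Generator | int | None = None
                  ) -> dict[str, SuitabilityMap]:
    """Fit the full per-species protocol and project to every scenario."""
    rng = np.random.default_rng(rng)
    cur_stack = climate[current.key]
    grid = check_same_grid(*[s.spec for s in climate.values()])
    mask = area_mask(calibration.polygon, grid)
    pseudo = sample_pseudo_absences(mask, grid, n=n_pseudo_absences, rng=rng)
    sample_pts = np.vstack([occurrences, pseudo])
    variables = preselect_variables(cur_stack, sample_pts, r_max=r_max)
    pres_X = cur_stack.sample(occurrences[:, 0], occurrences[:, 1], variables)
    abs_X = cur_stack.sample(pseudo[:, 0], pseudo[:, 1], variables)
    replicates = fit_replicates(pres_X, abs_X, learner_families=learner_families,
                                n_replicates=n_replicates, rng=rng)
    return {
        scen.key: ensemble(replicates, climate[scen.key], mask, variables,
                           species_id, scen)
        for scen in scenarios
    }
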