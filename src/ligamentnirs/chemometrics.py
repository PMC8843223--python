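"""PLSR calibration with wavelength selection and repeated cross-validation.

The model-construction procedure, run once per reference property:

1. enumerate preprocessing options (see :mod:`ligamentnirs.preprocess`);
2. reject the 10% of wavelengths with the lowest variance;
3. keep the top 87.5% of the remainder by univariate regression F-score;
4. choose the number of PLS latent variables by 5-fold cross-validation;
5. shrink the wavelength set by backwards feature elimination under PLSR,
   stopping at the latent-variable count, keeping the step along the
   elimination path with the lowest cross-validated RMSE;
6. evaluate the final model by 10-fold cross-validation repeated 10 times
   with randomized splits, reporting the median per-fold explained variance,
   Pearson r, R² and RMSE with percentile-bootstrap confidence intervals.

Steps 2-5 run once on the full dataset before the final cross-validation, so
the reported fold metrics share information with the selection stages; this
mirrors the evaluated procedure and is documented rather than corrected.

PLS is single-response NIPALS on mean-centered data with no per-feature
scaling (derivative spectra are already commensurate across wavelengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureMatrix, PreprocessConfig, apply_config

__all__ = [
    "SelectionMask",
    "PLSModel",
    "MetricSet",
    "CVResult",
    "ModelReport",
    "standardize_reference",
    "variance_filter",
    "univariate_select",
    "choose_latent_variables",
    "fit_pls",
    "predict",
    "backward_eliminate",
    "explained_variance",
    "compute_metrics",
    "repeated_cv",
    "bootstrap_ci",
    "run_model_search",
    "top_influential_wavelengths",
]

DEFAULT_MAX_LV = 20


@dataclass
class SelectionMask:
    """Boolean keep-mask over features with per-stage provenance."""

    keep: np.ndarray
    provenance: dict = field(default_factory=dict)  # stage name -> boolean mask

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def combine(self, other: "SelectionMask") -> "SelectionMask":
        """AND-compose with a mask defined on this mask's kept features."""
        if other.keep.size != self.n_kept:
            raise ValueError("mask to combine must cover the kept features")
        keep = self.keep.copy()
        keep[self.keep] = other.keep
        prov = dict(self.provenance)
        for stage, m in other.provenance.items():
            full = self.keep.copy()
            full[self.keep] = m
            prov[stage] = full
        return SelectionMask(keep=keep, provenance=prov)


@dataclass
class PLSModel:
    """A fitted single-response PLS regression."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x n_lv
    x_loadings: np.ndarray  # p x n_lv
    y_loadings: np.ndarray  # n_lv
    coefficients: np.ndarray  # p

    def __post_init__(self) -> None:
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        if self.coefficients.size != self.x_mean.size:
            raise ValueError("coefficient count must match feature count")


@dataclass
class MetricSet:
    explained_variance: float
    r: float
    R2: float
    RMSE: float

    def as_dict(self) -> dict:
        return {
            "explained_variance": self.explained_variance,
            "r": self.r,
            "R2": self.R2,
            "RMSE": self.RMSE,
        }


@dataclass
class CVResult:
    """Fold-level metrics of a repeated k-fold evaluation plus summaries."""

    fold_records: list  # dicts: repeat, fold, explained_variance, r, R2, RMSE
    medians: dict
    ci: dict  # metric -> (lo, hi)
    n_lv: int
    mask: SelectionMask | None = None

    def __post_init__(self) -> None:
        for metric, med in self.medians.items():
            lo, hi = self.ci[metric]
            if not (lo <= med <= hi):
                raise ValueError(f"CI for {metric} does not bracket the median")


@dataclass
class ModelReport:
    """Best calibration found for one reference property."""

    property_name: str
    config: PreprocessConfig
    n_lv: int
    mask: SelectionMask
    cv: CVResult
    model: PLSModel
    feature_wavelengths: np.ndarray
    feature_detectors: np.ndarray
    n_features_initial: int
    y_mean: float
    y_sd: float


# ---------------------------------------------------------------------------
# Standardization and wavelength selection
# ---------------------------------------------------------------------------


def standardize_reference(y: np.ndarray) -> tuple:
    """Whole-dataset z-scoring of a reference variable (ddof=1 SD)."""
    y = np.asarray(y, dtype=float)
    mean = y.mean()
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant reference variable")
    return (y - mean) / sd, mean, sd


def variance_filter(
    X: np.ndarray, wavelengths: np.ndarray, reject_frac: float = 0.10
) -> SelectionMask:
    """Reject floor(reject_frac * p) lowest-variance features.

    Variance ties are broken by rejecting the lower wavelength first, so the
    outcome is deterministic for any input.
    """
    if not 0 <= reject_frac < 1:
        raise ValueError("reject_frac must be in [0, 1)")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    p = X.shape[1]
    n_reject = int(np.floor(reject_frac * p))
    keep = np.ones(p, dtype=bool)
    if n_reject:
        var = X.var(axis=0, ddof=1)
        order = np.lexsort((wavelengths, var))  # ascending variance, then λ
        keep[order[:n_reject]] = False
    return SelectionMask(keep=keep, provenance={"variance_filter": keep.copy()})


def univariate_select(
    X: np.ndarray, y: np.ndarray, wavelengths: np.ndarray, keep_frac: float = 0.875
) -> SelectionMask:
    """Keep ceil(keep_frac * p) features by univariate-regression F-score.

    Each feature is scored by the F statistic of the simple linear regression
    of y on that feature (monotone in |r|, so |r| or its p-value would rank
    identically).  Score ties are broken by keeping the lower wavelength.
    """
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    var = X.var(axis=0, ddof=1)
    if np.any(var == 0):
        bad = wavelengths[var == 0][:5]
        raise ValueError(
            f"zero-variance features present (λ {bad.tolist()}); "
            "run the variance filter first"
        )
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    r = (Xc.T @ yc) / denom
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-15)
    f_score = r2 * (n - 2) / (1.0 - r2)
    n_keep = int(np.ceil(keep_frac * p))
    order = np.lexsort((wavelengths, -f_score))  # descending score, then λ asc
    keep = np.zeros(p, dtype=bool)
    keep[order[:n_keep]] = True
    return SelectionMask(keep=keep, provenance={"univariate_select": keep.copy()})


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) with coefficient paths
# ---------------------------------------------------------------------------


def _pls1_paths(X: np.ndarray, y: np.ndarray, n_lv: int) -> tuple:
    """NIPALS PLS1 returning per-component state.

    Returns (x_mean, y_mean, W, P, q, B_path) where B_path[:, k-1] are the
    regression coefficients of the k-component model.  For a single response
    each component is computed in closed form; no iteration is needed.
    Components stop early (coefficients frozen) once the residual is
    numerically exhausted from the y side; exhausting the rank of X raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(
            f"n_lv={n_lv} outside the valid range 1..{min(n - 1, p)} "
            f"for {n} samples x {p} features"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xk = X - x_mean
    yk = y - y_mean
    y_scale = max(np.abs(yk).max(), 1.0)
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    B_path = np.zeros((p, n_lv))
    B = np.zeros(p)
    n_done = 0
    for k in range(n_lv):
        w = Xk.T @ yk
        wn = np.linalg.norm(w)
        if wn < 1e-12 * y_scale:
            B_path[:, k:] = B[:, None]
            break
        w /= wn
        t = Xk @ w
        tt = float(t @ t)
        if tt < 1e-24:
            raise ValueError(f"rank of X exhausted after {k} latent variables")
        pk = Xk.T @ t / tt
        qk = float(yk @ t) / tt
        W[:, k] = w
        P[:, k] = pk
        q[k] = qk
        Xk -= np.outer(t, pk)
        yk = yk - qk * t
        n_done = k + 1
        # B_k = W_k (P_k' W_k)^-1 q_k  — (P'W) is small and triangular-ish
        R = P[:, : k + 1].T @ W[:, : k + 1]
        B = W[:, : k + 1] @ np.linalg.solve(R, q[: k + 1])
        B_path[:, k] = B
    return x_mean, y_mean, W[:, :n_done], P[:, :n_done], q[:n_done], B_path


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a single-response PLS model on mean-centered, unscaled data."""
    x_mean, y_mean, W, P, q, B_path = _pls1_paths(X, y, n_lv)
    return PLSModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=B_path[:, n_lv - 1],
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _cv_rmse_per_lv(
    X: np.ndarray, y: np.ndarray, max_lv: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-fold k-fold CV RMSE for every component count 1..max_lv.

    Returns a (k, max_lv) array; one PLS decomposition per fold yields the
    whole component path at once.
    """
    n = X.shape[0]
    folds = _kfold_indices(n, k, rng)
    out = np.zeros((k, max_lv))
    for i, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        _, _, _, _, _, B_path = _pls1_paths(X[train], y[train], max_lv)
        x_mean = X[train].mean(axis=0)
        y_mean = y[train].mean()
        pred = (X[test] - x_mean) @ B_path + y_mean  # n_test x max_lv
        out[i] = np.sqrt(((pred - y[test, None]) ** 2).mean(axis=0))
    return out


def choose_latent_variables(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = DEFAULT_MAX_LV,
    k: int = 5,
    seed: int = 0,
) -> int:
    """Pick the LV count by k-fold CV RMSE with a parsimony rule.

    The winner is the smallest component count whose mean CV RMSE lies
    within one standard error of the overall minimum (the usual one-SE
    rule).  With float fold metrics, exact RMSE ties essentially never
    occur, so near-ties must resolve to the simpler model: a flat CV curve
    (e.g. a response unrelated to the spectra) then yields one component
    instead of an arbitrary large count.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    largest_train = n - int(np.ceil(n / k))
    bound = min(largest_train - 1, p)
    if bound < 1:
        raise ValueError(f"too few samples ({n}) for {k}-fold LV selection")
    max_lv = min(max_lv, bound)
    if max_lv == 1:
        return 1
    rng = np.random.default_rng(seed)
    fold_rmse = _cv_rmse_per_lv(X, y, max_lv, k, rng)
    mean = fold_rmse.mean(axis=0)
    best = int(np.argmin(mean))
    se = fold_rmse[:, best].std(ddof=1) / np.sqrt(k)
    within = np.flatnonzero(mean <= mean[best] + se)
    return int(within[0]) + 1


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    n_lv: int,
    k: int = 5,
    seed: int = 0,
) -> SelectionMask:
    """Backwards feature elimination under PLSR at fixed LV count.

    Repeatedly drops the feature with the smallest |coefficient| (refitting
    each step), recording the k-fold CV RMSE of every intermediate feature
    set, until the feature count reaches ``n_lv`` (the cut-off).  Returns the
    mask of the step with minimal CV RMSE along the path; RMSE ties resolve
    to the smaller feature set, and coefficient-magnitude ties drop the
    higher wavelength so identical copies leave the lowest-wavelength one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p <= n_lv:
        raise ValueError(f"need more than n_lv={n_lv} features, got {p}")
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k, rng)  # one fixed partition along the path
    train_sets = [np.setdiff1d(np.arange(n), test) for test in folds]

    def cv_rmse(cols: np.ndarray) -> float:
        sq = 0.0
        for train, test in zip(train_sets, folds):
            Xt = X[np.ix_(train, cols)]
            _, _, _, _, _, B_path = _pls1_paths(Xt, y[train], n_lv)
            pred = (X[np.ix_(test, cols)] - Xt.mean(axis=0)) @ B_path[:, -1] + y[
                train
            ].mean()
            sq += float(((pred - y[test]) ** 2).sum())
        return float(np.sqrt(sq / n))

    cols = np.arange(p)
    best_cols = cols.copy()
    best_rmse = cv_rmse(cols)
    while cols.size > n_lv:
        model = fit_pls(X[:, cols], y, n_lv)
        absc = np.abs(model.coefficients)
        # smallest |coefficient|; ties -> drop the highest wavelength
        m = absc.min()
        tied = np.flatnonzero(absc <= m * (1 + 1e-12))
        drop = tied[np.argmax(wavelengths[cols[tied]])]
        cols = np.delete(cols, drop)
        rmse = cv_rmse(cols)
        # relative tolerance so exact ties (e.g. duplicated features) resolve
        # to the smaller feature set despite last-bit float noise
        if rmse <= best_rmse * (1.0 + 1e-9):
            best_rmse = rmse
            best_cols = cols.copy()
    keep = np.zeros(p, dtype=bool)
    keep[best_cols] = True
    return SelectionMask(keep=keep, provenance={"backward_elimination": keep.copy()})


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def explained_variance(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - Var{y - yhat} / Var{y}; offset-invariant, may be negative."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("explained variance undefined for constant y")
    return float(1.0 - (y - yhat).var(ddof=1) / vy)


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricSet:
    """Explained variance, Pearson r, R² and RMSE of a prediction."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    if y.std() == 0:
        raise ValueError("metrics undefined for constant y")
    ev = explained_variance(y, yhat)
    if yhat.std() == 0:
        r = np.nan  # correlation with a constant prediction is undefined
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(((y - yhat) ** 2).mean()))
    return MetricSet(explained_variance=ev, r=r, R2=r2, RMSE=rmse)


def bootstrap_ci(
    values, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple:
    """Percentile bootstrap CI of the median."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap CI needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    # the percentile interval of resampled medians always brackets the
    # sample median up to quantile interpolation; enforce the bracket
    med = float(np.median(values))
    return (min(float(lo), med), max(float(hi), med))


METRIC_NAMES = ("explained_variance", "r", "R2", "RMSE")


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    n_boot: int = 1000,
    standardize_per_fold: bool = False,
) -> CVResult:
    """k-fold CV repeated ``reps`` times with randomized splits.

    The model is refit on each training fold at fixed n_lv; metrics are
    computed per held-out fold (k x reps records).  Summary = median over all
    folds, with a percentile-bootstrap CI of that median.  A fold whose
    held-out y is constant gets NaN r/R²/EV, excluded from medians.

    ``standardize_per_fold`` re-centers and re-scales y with the training
    fold's statistics before fitting (predictions are mapped back to the
    input scale), removing the mild leakage of the default global
    standardization; off by default to match the evaluated procedure.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    root = np.random.SeedSequence(seed)
    fold_seeds, boot_seed = root.spawn(reps), root.spawn(1)[0]
    records = []
    for rep, child in enumerate(fold_seeds):
        rng = np.random.default_rng(child)
        for fold, test in enumerate(_kfold_indices(n, k, rng)):
            train = np.setdiff1d(np.arange(n), test)
            y_train = y[train]
            if standardize_per_fold:
                mu, sd = y_train.mean(), y_train.std(ddof=1)
                if sd == 0:
                    raise ValueError("constant y in a training fold")
                model = fit_pls(X[train], (y_train - mu) / sd, n_lv)
                yhat = predict(model, X[test]) * sd + mu
            else:
                model = fit_pls(X[train], y_train, n_lv)
                yhat = predict(model, X[test])
            yt = y[test]
            rec = {"repeat": rep, "fold": fold}
            if yt.std() == 0:
                rec.update(
                    explained_variance=np.nan,
                    r=np.nan,
                    R2=np.nan,
                    RMSE=float(np.sqrt(((yt - yhat) ** 2).mean())),
                )
            else:
                rec.update(compute_metrics(yt, yhat).as_dict())
            records.append(rec)
    medians = {}
    ci = {}
    boot_rng_seeds = boot_seed.generate_state(len(METRIC_NAMES))
    for name, bseed in zip(METRIC_NAMES, boot_rng_seeds):
        vals = np.array([rec[name] for rec in records])
        vals = vals[~np.isnan(vals)]
        medians[name] = float(np.median(vals))
        ci[name] = bootstrap_ci(vals, n_boot=n_boot, seed=int(bseed % (2**31)))
    return CVResult(fold_records=records, medians=medians, ci=ci, n_lv=n_lv)


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------


def build_model_for_config(
    features: FeatureMatrix,
    y_std: np.ndarray,
    seed: int = 0,
    max_lv: int = DEFAULT_MAX_LV,
    cv_k: int = 10,
    cv_reps: int = 10,
    n_boot: int = 1000,
) -> tuple:
    """Steps 2-6 on one preprocessed feature matrix.

    Returns (mask, n_lv, cv_result, model) with the mask over the full
    feature set of ``features`` and the model fit on the finally retained
    wavelengths using all samples.
    """
    wl = features.feature_wavelengths
    mask_var = variance_filter(features.X, wl)
    fm1 = features.select(mask_var.keep)
    mask_uni = univariate_select(fm1.X, y_std, fm1.feature_wavelengths)
    mask = mask_var.combine(mask_uni)
    fm2 = features.select(mask.keep)
    n_lv = choose_latent_variables(fm2.X, y_std, max_lv=max_lv, k=5, seed=seed)
    mask_be = backward_eliminate(
        fm2.X, y_std, fm2.feature_wavelengths, n_lv, k=5, seed=seed
    )
    mask = mask.combine(mask_be)
    fm3 = features.select(mask.keep)
    cv = repeated_cv(
        fm3.X, y_std, n_lv, k=cv_k, reps=cv_reps, seed=seed, n_boot=n_boot
    )
    cv.mask = mask
    model = fit_pls(fm3.X, y_std, n_lv)
    return mask, n_lv, cv, model


def run_model_search(
    records: list,
    refs,
    property_name: str,
    grid: list,
    seed: int = 0,
    max_lv: int = DEFAULT_MAX_LV,
    cv_k: int = 10,
    cv_reps: int = 10,
    n_boot: int = 1000,
    log=None,
) -> ModelReport:
    """Run the full procedure for one property over a preprocessing grid.

    The winning configuration is the one with the highest median
    cross-validated explained variance.  ``log`` may be a callable taking a
    message string (used by the CLI for progress reporting).
    """
    if property_name not in refs.data.columns:
        raise KeyError(
            f"unknown property {property_name!r}; available: "
            f"{list(refs.data.columns)}"
        )
    if not grid:
        raise ValueError("preprocessing grid is empty")
    order = {rec.key: i for i, rec in enumerate(records)}
    y_raw = np.array(
        [refs.data.loc[key, property_name] for key in (r.key for r in records)]
    )
    y_std, y_mean, y_sd = standardize_reference(y_raw)
    best = None
    failures = []
    for i, cfg in enumerate(grid):
        try:
            features = apply_config(records, cfg)
            mask, n_lv, cv, model = build_model_for_config(
                features,
                y_std,
                seed=seed,
                max_lv=max_lv,
                cv_k=cv_k,
                cv_reps=cv_reps,
                n_boot=n_boot,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"config {i} ({cfg.label()}): {exc}")
            continue
        ev = cv.medians["explained_variance"]
        if log is not None:
            log(f"config {i:3d} median EV {ev:+.3f}  {cfg.label()}")
        if best is None or ev > best[0]:
            best = (ev, cfg, mask, n_lv, cv, model, features)
    if best is None:
        raise RuntimeError(
            "every preprocessing configuration failed:\n" + "\n".join(failures)
        )
    _, cfg, mask, n_lv, cv, model, features = best
    return ModelReport(
        property_name=property_name,
        config=cfg,
        n_lv=n_lv,
        mask=mask,
        cv=cv,
        model=model,
        feature_wavelengths=features.feature_wavelengths[mask.keep],
        feature_detectors=features.feature_detectors[mask.keep],
        n_features_initial=features.n_features,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def top_influential_wavelengths(
    model: PLSModel, wavelengths: np.ndarray, k: int = 5
) -> list:
    """The k features with the largest |coefficient|, descending."""
    if k > model.coefficients.size:
        raise ValueError(
            f"k={k} exceeds the model's {model.coefficients.size} features"
        )
    order = np.argsort(-np.abs(model.coefficients), kind="stable")[:k]
    return [(float(wavelengths[i]), float(model.coefficients[i])) for i in order]
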