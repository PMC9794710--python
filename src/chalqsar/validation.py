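"""Internal/external validation battery and applicability-domain diagnostics.

Implements the statistics conventionally reported for MLR-QSAR models:
fitting (R², adjusted R², Friedman LOF, Kxx/ΔK multivariate-correlation
indices, RMSE/MAE/RSS, concordance correlation, residual standard error,
F), leave-one-out and leave-many-out cross-validation, Y-scrambling,
external-prediction metrics (Q²-F1/F2/F3, CCC, regression angle,
through-origin slopes k/k' and r²m variants) and the Golbraikh–Tropsha
threshold battery, plus Williams-plot leverages.

Definitions:

* ``Q² = 1 - PRESS / Σ(y - ȳ)²`` with LOO PRESS from the exact hat-matrix
  shortcut (verified against explicit refitting).
* ``CCC = 2·Σ(ŷ-ȳ̂)(y-ȳ) / [Σ(ŷ-ȳ̂)² + Σ(y-ȳ)² + n(ȳ̂-ȳ)²]``.
* ``K`` (from eigenvalues λ of a correlation matrix of m variables)
  ``= Σ|λ_i/Σλ - 1/m| / (2(m-1)/m)``; ``Kxx`` uses the descriptor block,
  ``ΔK = Kxy - Kxx`` adds the response.
* ``Q²F1`` references the training mean, ``Q²F2`` the test mean and
  ``Q²F3`` compares per-row external PRESS with training variance.
* through-origin slopes ``k = Σyŷ/Σŷ²``, ``k' = Σyŷ/Σy²``;
  ``r²m = r²(1 - sqrt(r² - r²o))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CollinearityError, SizeError
from .mlr import DataTable, MLRModel, design_matrix, fit_mlr, predict

__all__ = [
    "FitStats",
    "CVStats",
    "ScrambleStats",
    "ExternalStats",
    "ADReport",
    "fit_stats",
    "q2_loo",
    "q2_lmo",
    "y_scramble",
    "external_stats",
    "gt_check",
    "applicability_domain",
]


def _ccc(y: np.ndarray, yhat: np.ndarray) -> float:
    n = len(y)
    yb, hb = y.mean(), yhat.mean()
    num = 2.0 * float(((yhat - hb) * (y - yb)).sum())
    den = float(((yhat - hb) ** 2).sum() + ((y - yb) ** 2).sum() + n * (hb - yb) ** 2)
    return num / den


def _k_index(block: np.ndarray) -> float:
    m = block.shape[1]
    if m < 2:
        return 0.0
    corr = np.corrcoef(block, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    return float(np.abs(lam / lam.sum() - 1.0 / m).sum() / (2.0 * (m - 1) / m))


@dataclass(frozen=True)
class FitStats:
    r2_tr: float
    r2_adj: float
    lof: float
    kxx: float
    delta_k: float
    rmse_tr: float
    mae_tr: float
    rss_tr: float
    ccc_tr: float
    s: float
    f: float


def fit_stats(model: MLRModel, table_train: DataTable, lof_d: float = 0.5) -> FitStats:
    """Training-set statistics for a fitted model.

    ``lof_d`` is the smoothing parameter of the Friedman lack-of-fit score
    ``LOF = (RSS/n) / (1 - (c + d·p)/n)²`` with c = p + 1 model terms.
    """
    subset = model.subset
    n, p = table_train.n, len(subset)
    if n <= p + 1:
        raise SizeError(f"need n > p + 1 rows (n={n}, p={p})")
    y = table_train.y
    yhat = predict(model, table_train)
    rss = float(((y - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    c = p + 1
    lof = (rss / n) / (1.0 - (c + lof_d * p) / n) ** 2
    X = table_train.columns(subset)
    kxx = _k_index(X)
    kxy = _k_index(np.column_stack([X, y]))
    return FitStats(
        r2_tr=r2,
        r2_adj=r2_adj,
        lof=lof,
        kxx=kxx,
        delta_k=kxy - kxx,
        rmse_tr=float(np.sqrt(rss / n)),
        mae_tr=float(np.abs(y - yhat).mean()),
        rss_tr=rss,
        ccc_tr=_ccc(y, yhat),
        s=float(np.sqrt(rss / (n - p - 1))),
        f=float("inf") if r2 == 1.0 else (r2 / p) / ((1.0 - r2) / (n - p - 1)),
    )


@dataclass(frozen=True)
class CVStats:
    q2_loo: float
    rmse_cv: float
    mae_cv: float
    press_cv: float
    ccc_cv: float
    q2_lmo: float = float("nan")
    lmo_fraction: float = float("nan")
    lmo_iterations: int = 0
    seed: int | None = None


def loo_predictions(table: DataTable, subset: tuple[str, ...]) -> np.ndarray:
    """Leave-one-out predictions via the exact hat-matrix shortcut."""
    A = design_matrix(table, subset)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise CollinearityError("design matrix rank deficient")
    beta, *_ = np.linalg.lstsq(A, table.y, rcond=None)
    residuals = table.y - A @ beta
    hat = np.einsum("ij,ji->i", A, np.linalg.pinv(A))
    return table.y - residuals / (1.0 - hat)


def q2_loo(table_train: DataTable, subset: tuple[str, ...]) -> CVStats:
    """Leave-one-out cross-validation statistics."""
    p = len(subset)
    if table_train.n < p + 3:
        raise SizeError(f"LOO needs n >= p + 3 (n={table_train.n}, p={p})")
    y = table_train.y
    yloo = loo_predictions(table_train, tuple(subset))
    press = float(((y - yloo) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return CVStats(
        q2_loo=1.0 - press / tss,
        rmse_cv=float(np.sqrt(press / table_train.n)),
        mae_cv=float(np.abs(y - yloo).mean()),
        press_cv=press,
        ccc_cv=_ccc(y, yloo),
    )


def q2_lmo(
    table_train: DataTable,
    subset: tuple[str, ...],
    leave_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int = 0,
) -> float:
    """Mean Q² over seeded random leave-many-out partitions.

    Per iteration the left-out deviance is referenced to the mean of the
    retained rows: ``Q²_i = 1 - Σ(y_out - ŷ_out)² / Σ(y_out - ȳ_in)²``.
    """
    if not 0 < leave_fraction <= 0.5:
        raise SizeError(f"leave_fraction must be in (0, 0.5], got {leave_fraction}")
    if iterations < 100:
        raise SizeError("LMO needs at least 100 iterations")
    subset = tuple(subset)
    n = table_train.n
    n_out = max(1, int(round(leave_fraction * n)))
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, bool)
        mask[out] = False
        inner = DataTable(
            ids=tuple(np.array(table_train.ids)[mask]),
            X=table_train.X[mask],
            y=table_train.y[mask],
            descriptor_names=table_train.descriptor_names,
        )
        model = fit_mlr(inner, subset)
        X_out = table_train.X[~mask][:, [table_train.descriptor_names.index(s) for s in subset]]
        yhat = predict(model, X_out)
        y_out = table_train.y[~mask]
        denom = float(((y_out - inner.y.mean()) ** 2).sum())
        if denom == 0:
            continue
        scores.append(1.0 - float(((y_out - yhat) ** 2).sum()) / denom)
    return float(np.mean(scores))


@dataclass(frozen=True)
class ScrambleStats:
    r2_yscr_mean: float
    q2_yscr_mean: float
    iterations: int
    seed: int
    r2_values: np.ndarray = field(repr=False, compare=False, default=None)
    q2_values: np.ndarray = field(repr=False, compare=False, default=None)


def y_scramble(
    table_train: DataTable,
    subset: tuple[str, ...],
    iterations: int = 1000,
    seed: int = 0,
) -> ScrambleStats:
    """Refit after permuting the response; evidence the model is not chance.

    Identity permutations are redrawn.  The full R²/Q² distributions are
    retained for plotting.
    """
    if iterations < 100:
        raise SizeError("Y-scrambling needs at least 100 iterations")
    subset = tuple(subset)
    rng = np.random.default_rng(seed)
    n = table_train.n
    tssless = lambda y: float(((y - y.mean()) ** 2).sum())  # noqa: E731
    A = design_matrix(table_train, subset)
    hat = np.einsum("ij,ji->i", A, np.linalg.pinv(A))
    r2s, q2s = [], []
    for _ in range(iterations):
        perm = rng.permutation(n)
        while np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        y = table_train.y[perm]
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        residuals = y - A @ beta
        tss = tssless(y)
        r2s.append(1.0 - float(residuals @ residuals) / tss)
        press = float(((residuals / (1.0 - hat)) ** 2).sum())
        q2s.append(1.0 - press / tss)
    r2s, q2s = np.array(r2s), np.array(q2s)
    return ScrambleStats(
        r2_yscr_mean=float(r2s.mean()),
        q2_yscr_mean=float(q2s.mean()),
        iterations=iterations,
        seed=seed,
        r2_values=r2s,
        q2_values=q2s,
    )


@dataclass(frozen=True)
class ExternalStats:
    rmse_ex: float
    mae_ex: float
    press_ext: float
    r2_ex: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    ccc_ex: float
    angle_from_diagonal_deg: float
    r2o: float
    r2o_prime: float
    k: float
    k_prime: float
    r2m: float
    r2m_prime: float


def external_stats(
    model: MLRModel, table_test: DataTable, table_train: DataTable
) -> ExternalStats:
    """External-prediction metrics on a held-out test set (>= 3 rows)."""
    if table_test.n < 3:
        raise SizeError(f"need >= 3 test rows, have {table_test.n}")
    if set(table_test.ids) & set(table_train.ids):
        raise SizeError("test set overlaps training set")
    y = table_test.y
    yhat = predict(model, table_test)
    n_ext = table_test.n
    press = float(((y - yhat) ** 2).sum())
    y_tr = table_train.y
    tss_tr = float(((y_tr - y_tr.mean()) ** 2).sum())

    r = np.corrcoef(y, yhat)[0, 1]
    r2 = float(r**2)
    k = float((y * yhat).sum() / (yhat**2).sum())
    k_prime = float((y * yhat).sum() / (y**2).sum())
    r2o = 1.0 - float(((y - k * yhat) ** 2).sum()) / float(((y - y.mean()) ** 2).sum())
    r2o_prime = 1.0 - float(((yhat - k_prime * y) ** 2).sum()) / float(
        ((yhat - yhat.mean()) ** 2).sum()
    )
    r2m = r2 * (1.0 - np.sqrt(max(r2 - r2o, 0.0)))
    r2m_prime = r2 * (1.0 - np.sqrt(max(r2 - r2o_prime, 0.0)))

    slope = float(np.polyfit(y, yhat, 1)[0])
    angle = abs(45.0 - np.degrees(np.arctan(slope)))

    return ExternalStats(
        rmse_ex=float(np.sqrt(press / n_ext)),
        mae_ex=float(np.abs(y - yhat).mean()),
        press_ext=press,
        r2_ex=r2,
        q2_f1=1.0 - press / float(((y - y_tr.mean()) ** 2).sum()),
        q2_f2=1.0 - press / float(((y - y.mean()) ** 2).sum()),
        q2_f3=1.0 - (press / n_ext) / (tss_tr / table_train.n),
        ccc_ex=_ccc(y, yhat),
        angle_from_diagonal_deg=float(angle),
        r2o=float(r2o),
        r2o_prime=float(r2o_prime),
        k=k,
        k_prime=k_prime,
        r2m=float(r2m),
        r2m_prime=float(r2m_prime),
    )


def gt_check(fit: FitStats, cv: CVStats, ext: ExternalStats) -> dict[str, dict]:
    """Golbraikh–Tropsha style threshold battery.

    Returns one entry per criterion with the evaluated inequality and a
    boolean outcome; ``all_pass`` summarises.
    """
    checks = {
        "r2_tr >= 0.6": fit.r2_tr >= 0.6,
        "q2_loo >= 0.5": cv.q2_loo >= 0.5,
        "q2_lmo >= 0.6": cv.q2_lmo >= 0.6,
        "r2_tr > q2_loo": fit.r2_tr > cv.q2_loo,
        "r2_ex >= 0.6": ext.r2_ex >= 0.6,
        "rmse_tr < rmse_cv": fit.rmse_tr < cv.rmse_cv,
        "delta_k >= 0.05": fit.delta_k >= 0.05,
        "ccc_tr >= 0.80": fit.ccc_tr >= 0.80,
        "ccc_ex >= 0.80": ext.ccc_ex >= 0.80,
        "r2m >= 0.6": ext.r2m >= 0.6,
        "(1 - r2/r2o) < 0.1 or (1 - r2/r2o') < 0.1": (
            (1.0 - ext.r2_ex / ext.r2o) < 0.1 or (1.0 - ext.r2_ex / ext.r2o_prime) < 0.1
        ),
        "0.9 <= k <= 1.1 or 0.9 <= k' <= 1.1": (
            0.9 <= ext.k <= 1.1 or 0.9 <= ext.k_prime <= 1.1
        ),
        "|r2o - r2o'| < 0.3": abs(ext.r2o - ext.r2o_prime) < 0.3,
    }
    report = {name: {"passed": bool(ok)} for name, ok in checks.items()}
    report["all_pass"] = {"passed": all(ok for ok in checks.values())}
    return report


@dataclass(frozen=True)
class ADReport:
    leverages: dict[str, float]
    h_star: float
    std_residuals: dict[str, float]
    outliers: tuple[str, ...]
    outside_domain: tuple[str, ...]


def applicability_domain(
    model: MLRModel, table_train: DataTable, table_query: DataTable | None = None
) -> ADReport:
    """Williams-plot diagnostics: leverages, h* = 3(p+1)/n, residual outliers.

    Query rows (Insubria-style screening of unmeasured compounds) reuse the
    training (X'X)⁻¹; rows with a known response also get a standardized
    residual and the |r| > 3 outlier call.
    """
    subset = model.subset
    A_tr = design_matrix(table_train, subset)
    gram = A_tr.T @ A_tr
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise CollinearityError("X'X singular; cannot compute leverages")
    inv = np.linalg.inv(gram)
    p = len(subset)
    h_star = 3.0 * (p + 1) / table_train.n

    leverages: dict[str, float] = {}
    std_res: dict[str, float] = {}
    s = model.sigma

    def leverage_of(row: np.ndarray) -> float:
        x = np.concatenate([[1.0], row])
        return float(x @ inv @ x)

    yhat_tr = predict(model, table_train)
    for i, cid in enumerate(table_train.ids):
        h = leverage_of(table_train.columns(subset)[i])
        leverages[cid] = h
        std_res[cid] = float((table_train.y[i] - yhat_tr[i]) / (s * np.sqrt(max(1.0 - h, 1e-12))))

    if table_query is not None:
        Xq = table_query.columns(subset)
        yhat_q = predict(model, table_query)
        for i, cid in enumerate(table_query.ids):
            leverages[cid] = leverage_of(Xq[i])
            if np.isfinite(table_query.y[i]):
                std_res[cid] = float((table_query.y[i] - yhat_q[i]) / s)

    outliers = tuple(cid for cid, r in std_res.items() if abs(r) > 3.0)
    outside = tuple(cid for cid, h in leverages.items() if h > h_star)
    return ADReport(
        leverages=leverages,
        h_star=h_star,
        std_residuals=std_res,
        outliers=outliers,
        outside_domain=outside,
    )
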