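"""Fitting, internal-validation and external-validation statistics.

Conventions (documented because published tables only make sense under
a consistent pair of divisors):

* RMSE uses divisor n (so a training RMSE and the standard error of the
  estimate s, which uses n - p - 1, can both be reported).
* Q²(LOO) uses the closed-form PRESS: the deleted residual of an OLS
  fit is e_i / (1 - h_ii), so no explicit refitting is needed; the
  closed form is algebraically identical to n refits.
* External R² is computed with the total sum of squares centered on the
  external set's own mean by default; training-mean centering (the
  Q²F1-style variant) is available via ``center``.
* CCC is Lin's concordance correlation coefficient with population
  (divisor n) moments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    pass


# ------------------------------------------------------------ primitives


def ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.var(), y.var()
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx + sy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValidationError("CCC undefined: both series constant and equal")
    return float(2 * cov / denom)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS with intercept: returns (beta, fitted, hat diagonal)."""
    d = np.column_stack([np.ones(len(X)), X])
    n, q = d.shape
    if np.linalg.matrix_rank(d) < q:
        raise ValidationError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(d, y, rcond=None)
    # hat diagonal via the thin-QR factor: h_ii = ||Q_i.||²
    qmat, _ = np.linalg.qr(d)
    hat = (qmat**2).sum(axis=1)
    return beta, d @ beta, hat


# --------------------------------------------------------- fit statistics


@dataclass
class FitMetrics:
    r2: float
    r2_adj: float
    rmse: float
    mae: float
    ccc: float
    s: float
    F: float
    n: int
    p: int


def fit_metrics(
    y: Sequence[float], yhat: Sequence[float], p: int
) -> FitMetrics:
    """Training-set fitting criteria for a p-descriptor linear model."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError("y and yhat must have equal length")
    n = len(y)
    if n < p + 2:
        raise ValidationError(f"need n >= p+2 = {p + 2}, got {n}")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("zero response variance")
    resid = y - yhat
    ss_res = float((resid**2).sum())
    ss_reg = ss_tot - ss_res
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    dof = n - p - 1
    return FitMetrics(
        r2=r2,
        r2_adj=r2_adj,
        rmse=float(np.sqrt(ss_res / n)),
        mae=float(np.abs(resid).mean()),
        ccc=ccc(y, yhat) if ss_res > 0 else 1.0,
        s=float(np.sqrt(ss_res / dof)),
        F=float((ss_reg / p) / (ss_res / dof)) if ss_res > 0 else np.inf,
        n=n,
        p=p,
    )


def external_metrics(
    y_ext: Sequence[float],
    yhat_ext: Sequence[float],
    y_train_mean: float | None = None,
    center: str = "external",
) -> dict:
    """External-set R², RMSE, MAE and CCC.

    ``center='external'`` uses the external responses' own mean in the
    total sum of squares; ``center='training'`` uses the training mean
    (requires ``y_train_mean``).
    """
    y = np.asarray(y_ext, dtype=float)
    yhat = np.asarray(yhat_ext, dtype=float)
    if center == "training":
        if y_train_mean is None:
            raise ValidationError("training centering needs y_train_mean")
        mu = float(y_train_mean)
    elif center == "external":
        mu = float(y.mean())
    else:
        raise ValidationError(f"unknown centering {center!r}")
    ss_tot = float(((y - mu) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("zero external response variance")
    resid = y - yhat
    return {
        "r2_ext": 1.0 - float((resid**2).sum()) / ss_tot,
        "rmse_ext": float(np.sqrt((resid**2).mean())),
        "mae_ext": float(np.abs(resid).mean()),
        "ccc_ext": ccc(y, yhat),
    }


# ------------------------------------------------------- cross-validation


def q2_loo(
    X: np.ndarray, y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Leave-one-out Q² by closed-form PRESS.

    Returns (q2, rmse_cv, mae_cv, ccc_cv), where the cross-validated
    predictions are y_i - e_i/(1 - h_ii).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 3:
        raise ValidationError(f"need n >= p+3 = {p + 3}, got {n}")
    beta, fitted, hat = _ols(X, y)
    if np.any(hat >= 1 - 1e-12):
        raise ValidationError("degenerate leverage h_ii = 1: LOO undefined")
    deleted = (y - fitted) / (1.0 - hat)
    press = float((deleted**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("zero response variance")
    loo_pred = y - deleted
    return (
        1.0 - press / ss_tot,
        float(np.sqrt(press / n)),
        float(np.abs(deleted).mean()),
        ccc(y, loo_pred),
    )


def q2_lmo(
    X: np.ndarray,
    y: Sequence[float],
    leave_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int = 0,
) -> float:
    """Leave-many-out Q² over seeded random holdout groups.

    Each iteration removes round(leave_fraction·n) compounds and refits
    on the rest; prediction errors and total squares (held-out responses
    centered on the full-set mean) are pooled over iterations, giving
    Q²LMO = 1 - ΣPRESS_group / ΣSS_group.  Pooling keeps single-compound
    holdout groups well defined, so the statistic reduces to Q²LOO as
    the groups shrink.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 0 < leave_fraction < 0.5:
        raise ValidationError("leave_fraction must be in (0, 0.5)")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    g = max(1, int(round(leave_fraction * n)))
    if n - g < p + 2:
        raise ValidationError(
            f"holdout of {g} leaves too few rows ({n - g}) to refit"
        )
    rng = np.random.default_rng(seed)
    mu = y.mean()
    press_total = 0.0
    ss_total = 0.0
    for _ in range(iterations):
        out = rng.choice(n, size=g, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        d_in = np.column_stack([np.ones(mask.sum()), X[mask]])
        beta, *_ = np.linalg.lstsq(d_in, y[mask], rcond=None)
        pred = np.column_stack([np.ones(g), X[out]]) @ beta
        press_total += float(((y[out] - pred) ** 2).sum())
        ss_total += float(((y[out] - mu) ** 2).sum())
    if ss_total == 0:
        raise ValidationError("all holdout groups had zero variance")
    return 1.0 - press_total / ss_total


# ----------------------------------------------------------- y-scrambling


@dataclass
class YScrambleResult:
    r2: np.ndarray
    q2: np.ndarray
    r2_unscrambled: float
    q2_unscrambled: float

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    @property
    def mean_q2(self) -> float:
        return float(self.q2.mean())


def y_scramble(
    X: np.ndarray,
    y: Sequence[float],
    iterations: int = 100,
    seed: int = 0,
) -> YScrambleResult:
    """Refit against permuted responses to probe chance correlation.

    A real structure-activity model should have scrambled R²/Q² far
    below the unscrambled values; a model of pure noise will not.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if iterations < 10:
        raise ValidationError("iterations must be >= 10")
    if n < p + 3:
        raise ValidationError(f"need n >= p+3 = {p + 3}, got {n}")
    rng = np.random.default_rng(seed)
    _, fitted, _ = _ols(X, y)
    r2_true = fit_metrics(y, fitted, p).r2
    q2_true = q2_loo(X, y)[0]
    r2s, q2s = [], []
    for _ in range(iterations):
        yp = rng.permutation(y)
        _, fp, _ = _ols(X, yp)
        r2s.append(fit_metrics(yp, fp, p).r2)
        q2s.append(q2_loo(X, yp)[0])
    return YScrambleResult(
        r2=np.array(r2s),
        q2=np.array(q2s),
        r2_unscrambled=r2_true,
        q2_unscrambled=q2_true,
    )


# ------------------------------------------------------------ full report


@dataclass
class ValidationReport:
    """Fitting / internal / external criteria for one model."""

    r2_tr: float
    r2_adj: float
    rmse_tr: float
    mae_tr: float
    ccc_tr: float
    s: float
    F: float
    q2_loo: float | None
    rmse_cv: float | None
    mae_cv: float | None
    ccc_cv: float | None
    q2_lmo: float | None
    r2_ext: float | None
    rmse_ext: float | None
    mae_ext: float | None
    ccc_ext: float | None
    n_train: int
    n_test: int
    p: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def format(self) -> str:
        """Human-readable block layout: fitting / internal / external."""
        lines = [
            "Fitting criteria",
            f"  R2 tr = {self.r2_tr:.3f}, R2 adj = {self.r2_adj:.3f}, "
            f"RMSE = {self.rmse_tr:.3f}, MAE tr = {self.mae_tr:.3f},",
            f"  CCC tr = {self.ccc_tr:.3f}, s = {self.s:.3f}, "
            f"F = {self.F:.3f}",
            "Internal validation criteria",
        ]

        def fmt(v):
            return "n/a" if v is None else f"{v:.3f}"

        lines.append(
            f"  Q2 LOO = {fmt(self.q2_loo)}, RMSE cv = {fmt(self.rmse_cv)}, "
            f"MAE cv = {fmt(self.mae_cv)},"
        )
        lines.append(
            f"  Q2 LMO = {fmt(self.q2_lmo)}, CCC cv = {fmt(self.ccc_cv)}"
        )
        lines.append("External validation criteria")
        if self.r2_ext is None:
            lines.append("  (no external set)")
        else:
            lines.append(
                f"  R2 ext = {self.r2_ext:.3f}, "
                f"RMSE ext = {self.rmse_ext:.3f}, "
                f"MAE ext = {self.mae_ext:.3f}, "
                f"CCC ext = {self.ccc_ext:.3f}"
            )
        return "\n".join(lines)


def validate_model(
    X_train: np.ndarray,
    y_train: Sequence[float],
    yhat_train: Sequence[float],
    p: int,
    y_test: Sequence[float] | None = None,
    yhat_test: Sequence[float] | None = None,
    lmo_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    seed: int = 0,
    external_center: str = "external",
) -> ValidationReport:
    """Assemble the full criteria table for one fitted/fixed model.

    Internal criteria (Q²LOO, Q²LMO) refit OLS on the model's own
    descriptor columns, which is the standard practice for reporting
    cross-validated statistics of a fixed descriptor subset.
    """
    y_train = np.asarray(y_train, dtype=float)
    fm = fit_metrics(y_train, yhat_train, p)
    try:
        q2, rmse_cv, mae_cv, ccc_cv = q2_loo(X_train, y_train)
    except ValidationError:
        # degenerate training descriptors (e.g. constant columns of a
        # fixed external model): internal CV is undefined, not fatal
        q2 = rmse_cv = mae_cv = ccc_cv = None
    try:
        lmo = q2_lmo(
            X_train, y_train, lmo_fraction, lmo_iterations, seed=seed
        )
    except (ValidationError, np.linalg.LinAlgError):
        lmo = None
    ext = {"r2_ext": None, "rmse_ext": None, "mae_ext": None, "ccc_ext": None}
    n_test = 0
    if y_test is not None and len(np.atleast_1d(y_test)) > 0:
        ext = external_metrics(
            y_test,
            yhat_test,
            y_train_mean=float(y_train.mean()),
            center=external_center,
        )
        n_test = len(np.atleast_1d(y_test))
    return ValidationReport(
        r2_tr=fm.r2,
        r2_adj=fm.r2_adj,
        rmse_tr=fm.rmse,
        mae_tr=fm.mae,
        ccc_tr=fm.ccc,
        s=fm.s,
        F=fm.F,
        q2_loo=q2,
        rmse_cv=rmse_cv,
        mae_cv=mae_cv,
        ccc_cv=ccc_cv,
        q2_lmo=lmo,
        n_train=fm.n,
        n_test=n_test,
        p=p,
        **ext,
    )
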