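"""Leverage-based applicability domain (Williams plot).

A compound is a structural outlier of a fitted linear model when its
leverage h = x (XᵀX)⁻¹ xᵀ (X the training design matrix with intercept)
exceeds the critical hat h* = 3(p+1)/n, and a response outlier when its
standardized residual exceeds 3 standard-deviation units.  Training
leverages are the diagonal of the hat matrix and sum to p+1, so h* is
exactly three times the mean training leverage.

Standardized residuals divide by the training residual standard error
s = sqrt(SSres/(n-p-1)); internally studentized residuals
(residual / (s·sqrt(1-h))) are available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .modeling import MLRModel, predict

RESIDUAL_CUTOFF = 3.0


class DomainError(ValueError):
    pass


def critical_hat(p: int, n: int) -> float:
    """Critical leverage h* = 3(p+1)/n."""
    if n <= 0:
        raise DomainError("n must be positive")
    if p < 1:
        raise DomainError("p must be >= 1")
    return 3.0 * (p + 1) / n


def hat_values(
    X_train: np.ndarray, X_query: np.ndarray | None = None
) -> np.ndarray:
    """Leverages of query rows against a training design matrix.

    Both matrices are descriptor columns only; the intercept column is
    added here.  With ``X_query=None`` the training hat diagonal is
    returned (sums to p+1).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X_query is None:
        X_query = X_train
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    if X_query.shape[1] != X_train.shape[1]:
        raise DomainError("query columns do not match training columns")
    d_train = np.column_stack([np.ones(len(X_train)), X_train])
    d_query = np.column_stack([np.ones(len(X_query)), X_query])
    gram = d_train.T @ d_train
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise DomainError("singular XᵀX: training matrix rank-deficient")
    solved = np.linalg.solve(gram, d_query.T)
    return np.einsum("ij,ji->i", d_query, solved)


CATEGORIES = ("in_domain", "structural_outlier", "response_outlier", "both")


@dataclass
class ADRecord:
    """Williams-plot coordinates and classification for one compound."""

    compound_id: str
    leverage: float
    std_residual: float
    category: str
    h_star: float
    is_training: bool


def classify(leverage: float, std_residual: float, h_star: float) -> str:
    structural = leverage > h_star
    response = abs(std_residual) > RESIDUAL_CUTOFF
    if structural and response:
        return "both"
    if structural:
        return "structural_outlier"
    if response:
        return "response_outlier"
    return "in_domain"


def williams(
    model: MLRModel,
    matrix: DescriptorMatrix,
    y: Sequence[float],
    train_ids: Sequence[str] | None = None,
    studentized: bool = False,
) -> tuple[list[ADRecord], pd.DataFrame]:
    """Score every compound of the matrix against the model's domain.

    ``train_ids`` defaults to the model's own training ids; all leverage
    and residual scales derive from the training rows (test compounds
    are scored with the training (XᵀX)⁻¹ and training s).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != matrix.shape[0]:
        raise DomainError("observed responses do not match matrix rows")
    if np.any(~np.isfinite(y)):
        raise DomainError("missing observed response values")
    ids = matrix.compound_ids
    if train_ids is None:
        train_ids = model.train_ids
    if train_ids is None:
        train_ids = ids  # no split recorded: everything is training
    train_set = set(train_ids)
    missing = train_set - set(ids)
    if missing:
        raise DomainError(f"training id(s) not in matrix: {sorted(missing)}")
    is_train = np.array([i in train_set for i in ids])

    sub = matrix.subset(model.descriptor_names)
    X = sub.values
    X_train = X[is_train]
    n, p = X_train.shape[0], model.n_descriptors
    h_star = critical_hat(p, n)
    lev = hat_values(X_train, X)
    resid = y - predict(model, sub)
    dof = n - p - 1
    if dof <= 0:
        raise DomainError("not enough training compounds for residual scale")
    s = float(np.sqrt((resid[is_train] ** 2).sum() / dof))
    if s == 0:
        raise DomainError("zero training residual scale")
    std = resid / s
    if studentized:
        std = std / np.sqrt(np.clip(1.0 - lev, 1e-12, None))

    records = [
        ADRecord(
            compound_id=cid,
            leverage=float(lev[i]),
            std_residual=float(std[i]),
            category=classify(float(lev[i]), float(std[i]), h_star),
            h_star=h_star,
            is_training=bool(is_train[i]),
        )
        for i, cid in enumerate(ids)
    ]
    table = pd.DataFrame([asdict(r) for r in records])
    return records, table


def write_ad_report(
    records: list[ADRecord], csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    table = pd.DataFrame([asdict(r) for r in records])
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "h_star": records[0].h_star if records else None,
            "n": len(records),
            "n_in_domain": sum(r.category == "in_domain" for r in records),
            "outliers": [
                {"compound_id": r.compound_id, "category": r.category}
                for r in records
                if r.category != "in_domain"
            ],
        }
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def plot_williams(
    records: list[ADRecord], path: str | Path, title: str = "Williams plot"
) -> None:
    """Static Williams scatter: leverage vs standardized residual."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for training, color, label in (
        (True, "tab:blue", "training"),
        (False, "tab:orange", "test"),
    ):
        pts = [r for r in records if r.is_training == training]
        if pts:
            ax.scatter(
                [r.leverage for r in pts],
                [r.std_residual for r in pts],
                c=color,
                label=label,
                s=30,
            )
    if records:
        ax.axvline(records[0].h_star, ls="--", c="gray")
    for cut in (-RESIDUAL_CUTOFF, RESIDUAL_CUTOFF):
        ax.axhline(cut, ls="--", c="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
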