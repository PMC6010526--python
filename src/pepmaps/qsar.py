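"""PLSR QSAR linking log10(IC50) to the 12 terminal v-scale descriptors.

The response is Y = log10(IC50 in µM) and the model is

    Y = c + sum_ij a_ij N_ij + sum_ij b_ij C_ij + eps

with N_ij / C_ij the j-th normalized descriptor of the i-th residue from
the N- and C-terminus (i in {1,2}, j in {1,2,3}).  Fitting uses partial
least squares (NIPALS, mean-centered, no unit-variance scaling: the
descriptors already share a common normalized scale).  With the number of
latent variables equal to the rank of the centered descriptor matrix the
fit coincides with ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .descriptors import DescriptorScale, VECTOR_COLUMNS, encode_peptide, parse_peptide

N_DESCRIPTORS = len(VECTOR_COLUMNS)
COEFFICIENT_NAMES = ("c",) + VECTOR_COLUMNS


@dataclass(frozen=True)
class ActivityRecord:
    """One peptide with its measured half-maximal inhibitory concentration."""

    peptide: str
    ic50: float  # µM

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", parse_peptide(self.peptide))
        if not np.isfinite(self.ic50) or self.ic50 <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50!r} for {self.peptide}")

    @property
    def y(self) -> float:
        """log10(IC50 / µM), the modeled response."""
        return float(np.log10(self.ic50))


@dataclass(frozen=True)
class FitStats:
    r2: float
    rmse: float          # residual standard error, sqrt(SSres / (n - k - 1))
    f_stat: float
    p_model: float
    rmse_raw: float      # sqrt(SSres / n)
    p_lack_of_fit: float | None = None
    r2_cv: float | None = None


@dataclass
class PlsrModel:
    """Fitted terminal-descriptor PLSR.

    ``coefficients`` are on the original (normalized-descriptor) scale in
    the order of :data:`VECTOR_COLUMNS`; ``intercept`` is the constant c.
    ``a`` and ``b`` expose the N- and C-side coefficient blocks as (2, 3)
    arrays indexed [position i - 1, descriptor j - 1].
    """

    intercept: float
    coefficients: np.ndarray
    n_latent: int
    rank: int
    fitted: np.ndarray
    residuals: np.ndarray
    y: np.ndarray
    peptides: list[str]
    loo_rmsep: dict[int, float] = field(default_factory=dict)

    @property
    def a(self) -> np.ndarray:
        return self.coefficients[:6].reshape(2, 3)

    @property
    def b(self) -> np.ndarray:
        return self.coefficients[6:].reshape(2, 3)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


def design_matrix(
    records: list[ActivityRecord], scale: DescriptorScale
) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([encode_peptide(r.peptide, scale) for r in records])
    y = np.array([r.y for r in records])
    return X, y


def _pls_fit(X: np.ndarray, y: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """NIPALS PLS with k latent variables; returns (intercept, coefficients)."""
    model = PLSRegression(n_components=k, scale=False).fit(X, y)
    coef = np.asarray(model.coef_).reshape(-1)
    # sklearn predicts on centered X; fold the centering into the constant
    intercept = float(np.mean(y) - X.mean(axis=0) @ coef)
    return intercept, coef


def _centered_rank(X: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(X - X.mean(axis=0)))


def _loo_rmsep(X: np.ndarray, y: np.ndarray, k: int) -> float:
    n = len(y)
    errs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        kk = min(k, _centered_rank(X[mask]))
        c0, beta = _pls_fit(X[mask], y[mask], kk)
        errs[i] = y[i] - (X[i] @ beta + c0)
    return float(np.sqrt(np.mean(errs**2)))


def fit_plsr(
    records: list[ActivityRecord],
    scale: DescriptorScale,
    n_latent: int | str = "auto",
) -> PlsrModel:
    """Fit the terminal-descriptor PLSR.

    ``n_latent`` may be an explicit latent-variable count (at most the rank
    of the centered descriptor matrix) or ``"auto"``, which sweeps 1..rank
    and keeps the count minimizing the leave-one-out RMSEP, ties broken
    toward fewer components.  The sweep is stored in ``loo_rmsep``.
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    X, y = design_matrix(records, scale)
    rank = _centered_rank(X)
    loo = {}
    if n_latent == "auto":
        for k in range(1, rank + 1):
            loo[k] = _loo_rmsep(X, y, k)
        k_best = min(loo, key=lambda k: (round(loo[k], 12), k))
    else:
        k_best = int(n_latent)
        if not 1 <= k_best <= rank:
            raise ValueError(f"n_latent must be in 1..{rank}, got {k_best}")
        if len(records) < k_best + 2:
            raise ValueError("too few records for the requested latent-variable count")
    intercept, coef = _pls_fit(X, y, k_best)
    fitted = X @ coef + intercept
    return PlsrModel(
        intercept=intercept,
        coefficients=coef,
        n_latent=k_best,
        rank=rank,
        fitted=fitted,
        residuals=y - fitted,
        y=y,
        peptides=[r.peptide for r in records],
        loo_rmsep=loo,
    )


def predict_log_ic50(
    model: PlsrModel, peptide: str, scale: DescriptorScale
) -> tuple[float, float]:
    """Predict (log10 IC50, IC50 in µM) for one peptide."""
    x = encode_peptide(peptide, scale)
    y = float(x @ model.coefficients + model.intercept)
    return y, float(10.0**y)


def fit_statistics(model: PlsrModel) -> FitStats:
    """Training-set fit statistics.

    R² = 1 - SSres/SStot.  ``rmse`` is the residual standard error with the
    effective model degrees of freedom taken as the latent-variable count,
    sqrt(SSres / (n - k - 1)); the uncorrected sqrt(SSres / n) is kept as
    ``rmse_raw``.  The overall F test likewise uses df = (k, n - k - 1).
    """
    n = len(model.y)
    ss_tot = float(np.sum((model.y - model.y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    ss_res = float(np.sum(model.residuals**2))
    r2 = 1.0 - ss_res / ss_tot
    k = model.n_latent
    df_res = n - k - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    if r2 >= 1.0:
        f_stat, p_model = np.inf, 0.0
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / df_res)
        p_model = float(stats.f.sf(f_stat, k, df_res))
    return FitStats(
        r2=r2,
        rmse=float(np.sqrt(ss_res / df_res)),
        f_stat=float(f_stat),
        p_model=p_model,
        rmse_raw=float(np.sqrt(ss_res / n)),
    )


def lack_of_fit_test(
    model: PlsrModel, records: list[ActivityRecord], scale: DescriptorScale
) -> float:
    """F-test of the PLSR against the full-rank least-squares reference.

    With no replicate measurements available for a pure-error term, the
    reference "full" model is the 12-descriptor ordinary least squares fit.
    A PLSR already at full rank is the reference itself and returns p = 1.
    """
    X, y = design_matrix(records, scale)
    n = len(y)
    if model.n_latent >= model.rank:
        return 1.0
    Z = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    ss_full = float(np.sum((y - Z @ beta) ** 2))
    df_full = n - (model.rank + 1)
    ss_model = float(np.sum(model.residuals**2))
    df_model = n - (model.n_latent + 1)
    extra_df = df_model - df_full
    if df_full <= 0 or extra_df <= 0:
        return 1.0
    if ss_full == 0.0:
        return 0.0 if ss_model > 0 else 1.0
    f = ((ss_model - ss_full) / extra_df) / (ss_full / df_full)
    return float(stats.f.sf(max(f, 0.0), extra_df, df_full))


def repeated_split_cv(
    records: list[ActivityRecord],
    scale: DescriptorScale,
    n_latent: int,
    n_repeats: int = 100,
    n_train: int = 28,
    n_test: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated R² from repeated random train/test splits.

    Each repeat fits on ``n_train`` records and predicts the ``n_test``
    held-out records; predictions are pooled over all repeats and
    R²cv = 1 - SSres/SStot over the pooled held-out set.  Splits are
    uniform without replacement; the same seed gives identical results.
    Training subsets whose centered rank falls below ``n_latent`` are fit
    at their own rank.
    """
    n = len(records)
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test must equal {n}, got {n_train}+{n_test}")
    X, y = design_matrix(records, scale)
    rng = np.random.default_rng(seed)
    preds, obs = [], []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        kk = min(n_latent, _centered_rank(X[tr]))
        c0, beta = _pls_fit(X[tr], y[tr], kk)
        preds.append(X[te] @ beta + c0)
        obs.append(y[te])
    preds = np.concatenate(preds)
    obs = np.concatenate(obs)
    ss_res = float(np.sum((obs - preds) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def coefficient_significance(
    records: list[ActivityRecord],
    scale: DescriptorScale,
    n_latent: int,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "residual",
) -> pd.DataFrame:
    """Bootstrap two-sided sign-crossing p-values for c and the 12 coefficients.

    ``method="residual"`` (default) resamples residuals around the fitted
    values with the descriptor matrix held fixed — appropriate here because
    the peptide panel is fixed by design.  Residuals are inflated by
    sqrt(n / (n - k - 1)) so the resampled errors carry the unbiased
    variance estimate rather than the optimistic training-residual spread.  ``method="case"`` resamples
    whole records; with a small collinear panel the resampled designs are
    frequently near-singular, which inflates coefficient variance (the
    trade-off is documented in the methods note).  Degenerate resamples
    (constant response) are skipped and redrawn.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-values will be coarse", stacklevel=2)
    if method not in ("residual", "case"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    X, y = design_matrix(records, scale)
    n = len(y)
    rank = _centered_rank(X)
    k = min(n_latent, rank)
    c0, beta0 = _pls_fit(X, y, k)
    fitted = X @ beta0 + c0
    resid = y - fitted
    # rescale so the resampled errors have the unbiased residual variance
    df_res = max(n - k - 1, 1)
    resid_scaled = resid * np.sqrt(n / df_res)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 1 + N_DESCRIPTORS))
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 50 * n_boot:
            raise RuntimeError("too many degenerate bootstrap resamples")
        if method == "residual":
            Xb = X
            yb = fitted + rng.choice(resid_scaled, size=n, replace=True)
        else:
            idx = rng.integers(0, n, n)
            Xb, yb = X[idx], y[idx]
        if np.ptp(yb) == 0.0:
            continue
        kb = min(k, _centered_rank(Xb))
        cb, bb = _pls_fit(Xb, yb, kb)
        draws[b] = np.concatenate([[cb], bb])
        b += 1
    estimates = np.concatenate([[c0], beta0])
    p_values = [
        2.0 * min(np.mean(col <= 0.0), np.mean(col >= 0.0)) for col in draws.T
    ]
    return pd.DataFrame(
        {
            "coefficient": list(COEFFICIENT_NAMES),
            "estimate": estimates,
            "boot_se": draws.std(axis=0, ddof=1),
            "p_value": np.minimum(p_values, 1.0),
        }
    ).set_index("coefficient")
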