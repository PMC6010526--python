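"""Dose-response IC50 estimation and inhibition-mode classification.

IC50 comes from a logistic dose-response with the bottom fixed at 0%, the
top at 100% and a free Hill slope.  The inhibition mode is decided by
globally fitting the general mixed-inhibition rate law

    v = Vmax [S] / ( Km (1 + [I]/Kic) + [S] (1 + [I]/Kiu) )

and its nested special cases (competitive: Kiu -> inf; uncompetitive:
Kic -> inf; non-competitive: Kic = Kiu), comparing them with the
small-sample Akaike criterion.  Lineweaver-Burk double-reciprocal lines
are fitted per inhibitor level for display, not inference: a common
1/v-axis intercept across inhibitor levels is the classical signature of
competitive inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODES = ("competitive", "uncompetitive", "non-competitive", "mixed")

#: Relative |Kic - Kiu| tolerance under which a winning full model is
#: reported as non-competitive rather than mixed.
KI_EQUALITY_RTOL = 0.20

#: Extra evidence margin (beyond AICc's own complexity penalty) the full
#: model must clear to be preferred over the best nested 3-parameter model.
#: The default of 0 lets the small-sample criterion itself arbitrate
#: parsimony; the penalty for the 4th parameter already demands a
#: substantial fit improvement, and stacking a further margin on top makes
#: mixed-type inhibition practically undetectable on the assay's own
#: measurement design (see the methods note).
AICC_MARGIN = 0.0


@dataclass(frozen=True)
class DoseResponseCurve:
    """Replicate % inhibition measurements over a concentration grid (µM)."""

    concentrations: np.ndarray          # (n_conc,) µM, strictly increasing
    inhibition: np.ndarray              # (n_conc, n_rep) percent

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        inh = np.atleast_2d(np.asarray(self.inhibition, dtype=float))
        if conc.ndim != 1 or np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(conc) < 4:
            raise ValueError("need at least 4 concentrations to fit a curve")
        if inh.shape[0] != len(conc):
            raise ValueError("inhibition rows must match concentrations")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "inhibition", inh)


def percent_inhibition(rate_sample: float, rate_control: float) -> float:
    """Percent inhibition of a rate relative to the uninhibited control."""
    if rate_control <= 0:
        raise ValueError(f"control rate must be positive, got {rate_control}")
    if rate_sample < 0:
        raise ValueError(f"rates must be non-negative, got {rate_sample}")
    return 100.0 * (1.0 - rate_sample / rate_control)


def logistic_inhibition(conc: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    """Logistic % inhibition with bottom 0, top 100: 100 / (1 + (IC50/c)^h)."""
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + (ic50 / conc) ** hill)


def _fit_logistic(conc: np.ndarray, pct: np.ndarray) -> tuple[float, float]:
    lo, hi = conc.min(), conc.max()
    # crude interpolation start for IC50
    order = np.argsort(conc)
    ic0 = float(np.interp(50.0, np.clip(pct[order], -50, 150), conc[order],
                          left=lo, right=hi))
    popt, _ = optimize.curve_fit(
        logistic_inhibition, conc, pct,
        p0=[np.clip(ic0, lo, hi), 1.0],
        bounds=([lo * 1e-3, 0.1], [hi * 1e3, 10.0]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


def estimate_ic50(curve: DoseResponseCurve) -> tuple[float, float]:
    """Estimate (IC50 µM, SD µM) from a replicate dose-response table.

    The central estimate pools all replicate points; the SD is the spread
    of per-replicate fits, mirroring mean ± SD reporting over replicate
    curves.  The mean curve must bracket 50% inhibition and the estimate
    must fall inside the tested concentration range.
    """
    conc = curve.concentrations
    mean_pct = curve.inhibition.mean(axis=1)
    if mean_pct.min() >= 50.0 or mean_pct.max() <= 50.0:
        raise ValueError("IC50 outside tested range: curve does not cross 50% inhibition")
    n_rep = curve.inhibition.shape[1]
    conc_all = np.repeat(conc, n_rep)
    ic50, _ = _fit_logistic(conc_all, curve.inhibition.ravel())
    if not conc.min() <= ic50 <= conc.max():
        raise ValueError("IC50 outside tested range")
    per_rep = []
    for j in range(n_rep):
        try:
            est, _ = _fit_logistic(conc, curve.inhibition[:, j])
            per_rep.append(est)
        except RuntimeError:
            continue
    sd = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0
    return float(ic50), sd


@dataclass(frozen=True)
class KineticsDataset:
    """Initial rates over a substrate (mM) x inhibitor (µM) grid.

    ``table`` columns: ``S_mM``, ``I_uM``, ``rate``.  Must contain an
    inhibitor-free control series ([I] = 0) and non-negative rates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"S_mM", "I_uM", "rate"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"kinetics table needs columns {sorted(required)}")
        if (self.table["rate"] < 0).any():
            raise ValueError("rates must be non-negative")
        if not (self.table["I_uM"] == 0).any():
            raise ValueError("dataset must include an inhibitor-free control series")

    @property
    def inhibitor_levels(self) -> np.ndarray:
        return np.sort(self.table["I_uM"].unique())


def mixed_rate(
    S: np.ndarray, I: np.ndarray, vmax: float, km: float, kic: float, kiu: float
) -> np.ndarray:
    """General mixed-inhibition rate law; Kic or Kiu may be ``np.inf``."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    comp = 1.0 + I / kic if np.isfinite(kic) else 1.0
    uncomp = 1.0 + I / kiu if np.isfinite(kiu) else 1.0
    return vmax * S / (km * comp + S * uncomp)


def lineweaver_burk_lines(data: KineticsDataset) -> pd.DataFrame:
    """Per-inhibitor-level least-squares line of 1/v against 1/[S].

    Returns slope (= apparent Km/Vmax), intercept (= 1/apparent Vmax) and
    the implied apparent parameters.  Requires at least three substrate
    levels per series and strictly positive rates.
    """
    if (data.table["rate"] <= 0).any():
        raise ValueError("zero or negative rate: reciprocal plot undefined")
    rows = []
    for level, grp in data.table.groupby("I_uM"):
        if grp["S_mM"].nunique() < 3:
            raise ValueError(f"need >= 3 substrate levels for [I]={level}")
        fit = stats.linregress(1.0 / grp["S_mM"], 1.0 / grp["rate"])
        rows.append(
            {
                "I_uM": level,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "app_Vmax": 1.0 / fit.intercept if fit.intercept != 0 else np.inf,
                "app_Km": fit.slope / fit.intercept if fit.intercept != 0 else np.inf,
            }
        )
    return pd.DataFrame(rows).sort_values("I_uM").reset_index(drop=True)


@dataclass
class ModeResult:
    mode: str
    vmax: float
    km: float
    kic: float | None
    kiu: float | None
    aicc: dict[str, float]
    parameters: dict[str, dict[str, float]]
    lb_lines: pd.DataFrame = field(repr=False, default=None)


_MODEL_PARAMS = {
    "competitive": ("vmax", "km", "kic"),
    "uncompetitive": ("vmax", "km", "kiu"),
    "non-competitive": ("vmax", "km", "ki"),
    "mixed": ("vmax", "km", "kic", "kiu"),
}


def _model_rate(name: str, S: np.ndarray, I: np.ndarray, theta: np.ndarray) -> np.ndarray:
    p = np.exp(theta)  # positivity via log-parameterization
    if name == "competitive":
        return mixed_rate(S, I, p[0], p[1], p[2], np.inf)
    if name == "uncompetitive":
        return mixed_rate(S, I, p[0], p[1], np.inf, p[2])
    if name == "non-competitive":
        return mixed_rate(S, I, p[0], p[1], p[2], p[2])
    return mixed_rate(S, I, p[0], p[1], p[2], p[3])


def _aicc(ss: float, n: int, k: int, scale: float) -> float:
    ss = max(ss, n * (1e-12 * scale) ** 2)  # floor for noiseless fits
    aic = n * np.log(ss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def _hanes_init(data: KineticsDataset) -> tuple[float, float]:
    """Vmax/Km starting values from a Hanes-Woolf line on the control series."""
    ctrl = data.table[data.table["I_uM"] == 0]
    fit = stats.linregress(ctrl["S_mM"], ctrl["S_mM"] / ctrl["rate"])
    vmax = 1.0 / fit.slope if fit.slope > 0 else ctrl["rate"].max()
    km = fit.intercept * vmax if fit.intercept * vmax > 0 else ctrl["S_mM"].median()
    return float(abs(vmax)), float(abs(km))


def classify_mode(
    data: KineticsDataset,
    seed: int = 0,
    n_starts: int = 3,
    aicc_margin: float = AICC_MARGIN,
) -> ModeResult:
    """Classify the inhibition mode by nested nonlinear model comparison.

    All four rate-law variants are fitted by least squares (log-parameter
    multi-start from Hanes-Woolf estimates).  The winner is the model with
    the lowest small-sample Akaike criterion, except that the 4-parameter
    full model must beat the best 3-parameter model by at least
    ``aicc_margin``; a winning full model whose Kic and Kiu agree within
    ``KI_EQUALITY_RTOL`` is reported as non-competitive.
    """
    if (data.table["I_uM"] > 0).sum() == 0 or data.table["I_uM"].nunique() < 3:
        raise ValueError("need a control plus at least 2 inhibitor levels")
    S = data.table["S_mM"].to_numpy(dtype=float)
    I = data.table["I_uM"].to_numpy(dtype=float)
    v = data.table["rate"].to_numpy(dtype=float)
    n = len(v)
    vmax0, km0 = _hanes_init(data)
    ki0 = float(np.median(I[I > 0]))
    rng = np.random.default_rng(seed)

    results: dict[str, tuple[float, np.ndarray]] = {}
    for name, pnames in _MODEL_PARAMS.items():
        base = np.log([vmax0, km0] + [ki0] * (len(pnames) - 2))
        best = None
        for s in range(n_starts):
            theta0 = base if s == 0 else base + rng.normal(0.0, 0.5, size=base.size)
            try:
                sol = optimize.least_squares(
                    lambda th: _model_rate(name, S, I, th) - v,
                    theta0,
                    method="lm",
                    max_nfev=5000,
                )
            except Exception:
                continue
            ss = float(np.sum(sol.fun**2))
            if best is None or ss < best[0] - 1e-14:
                best = (ss, sol.x)
        if best is None:
            raise RuntimeError(f"non-convergence fitting {name} model after multi-start")
        results[name] = best

    scale = float(np.max(v)) if np.max(v) > 0 else 1.0
    aicc = {
        name: _aicc(ss, n, len(_MODEL_PARAMS[name]), scale)
        for name, (ss, _) in results.items()
    }
    simple = [m for m in MODES if m != "mixed"]
    best_simple = min(simple, key=lambda m: aicc[m])
    if aicc["mixed"] < aicc[best_simple] - aicc_margin:
        winner = "mixed"
    else:
        winner = best_simple

    params = {
        name: dict(zip(_MODEL_PARAMS[name], np.exp(theta)))
        for name, (_, theta) in results.items()
    }
    chosen = params[winner]
    mode = winner
    kic = chosen.get("kic", chosen.get("ki"))
    kiu = chosen.get("kiu", chosen.get("ki"))
    if winner == "mixed":
        lo, hi = sorted([chosen["kic"], chosen["kiu"]])
        if (hi - lo) / hi <= KI_EQUALITY_RTOL:
            mode = "non-competitive"
    if winner == "competitive":
        kiu = None
    if winner == "uncompetitive":
        kic = None
    return ModeResult(
        mode=mode,
        vmax=chosen["vmax"],
        km=chosen["km"],
        kic=kic,
        kiu=kiu,
        aicc=aicc,
        parameters=params,
        lb_lines=lineweaver_burk_lines(data) if (data.table["rate"] > 0).all() else None,
    )
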