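"""Synthetic data with the statistical structure the analysis stages assume.

Every generator draws from a sub-stream spawned off one global seed, so
adding a generator never perturbs the outputs of another, and the same
configuration reproduces bit-identical data.  Out-of-range percentages are
truncated (not resampled) and flagged in an auxiliary column so estimators
can exclude saturated points.

Defaults emulate the study conditions of the terminal-descriptor QSAR
(log10 IC50 linear in 12 descriptors, Gaussian noise in log units), the
15-point hydrophobicity design (% inhibition quadratic in three coded
levels), logistic dose-response at 0.37-500 µM, and mixed-model
Michaelis-Menten rates on the 0.1-0.6 mM substrate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorScale, STANDARD_RESIDUES
from .design import FACTOR_COLUMNS, expand_quadratic
from .kinetics import (
    DoseResponseCurve,
    KineticsDataset,
    logistic_inhibition,
    mixed_rate,
)
from .qsar import ActivityRecord

_STREAMS = {"qsar": 0, "design": 1, "dose": 2, "rates": 3}

#: Assay-style dose grid: 3-fold serial dilution down from 500 µM, 7 points.
DEFAULT_DOSE_GRID_UM = tuple(500.0 / 3.0**k for k in reversed(range(7)))

#: Substrate grid 0.1-0.6 mM, six levels, as in the rate assay.
DEFAULT_SUBSTRATE_GRID_MM = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named sub-stream of a global seed."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown stream {stream!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters and noise levels for all generators.

    QSAR: log10 IC50 = c + a.N + b.C + N(0, qsar_noise_sd); the default
    coefficient pattern concentrates signal on the terminal hydrophobicity
    terms (a[0,2], b[1,2]) as observed for this enzyme.  Noise SDs are in
    log10 units (QSAR), percentage points (design, dose-response) and
    relative fraction (rates).
    """

    seed: int = 0
    n_records: int = 40
    qsar_noise_sd: float = 0.2
    intercept: float = 2.4
    a: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0, -0.9], [0.0, 0.0, 0.0]])
    )
    b: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.5]])
    )
    beta: np.ndarray = field(
        default_factory=lambda: np.array(
            [75.0, 0.0, 5.0, 0.0, 0.0, -40.0, 0.0, 0.0, 0.0, 0.0]
        )
    )
    design_noise_sd: float = 5.0
    ic50_uM: float = 120.0
    hill: float = 1.0
    dose_noise_sd: float = 5.0
    n_rep_dose: int = 3
    vmax: float = 1.0
    km_mM: float = 0.2
    kic_uM: float = 10.0
    kiu_uM: float = np.inf
    rate_rel_noise: float = 0.03
    n_rep_rates: int = 4

    def __post_init__(self) -> None:
        for name in ("qsar_noise_sd", "design_noise_sd", "dose_noise_sd", "rate_rel_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_activity_dataset(
    cfg: SimulationConfig, scale: DescriptorScale
) -> list[ActivityRecord]:
    """Random peptides (lengths 2-9) with log-linear descriptor activity."""
    from .qsar import design_matrix  # local import to avoid cycle at module load

    rng = stream_rng(cfg.seed, "qsar")
    coef = np.concatenate([cfg.a.ravel(), cfg.b.ravel()])
    if coef.size != 12:
        raise ValueError("a and b must each hold 2 x 3 coefficients")
    peptides = []
    for _ in range(cfg.n_records):
        length = int(rng.integers(2, 10))
        peptides.append("".join(rng.choice(list(STANDARD_RESIDUES), size=length)))
    records = [ActivityRecord(p, 1.0) for p in peptides]  # placeholder activities
    X, _ = design_matrix(records, scale)
    y = cfg.intercept + X @ coef + rng.normal(0.0, cfg.qsar_noise_sd, size=len(peptides))
    return [ActivityRecord(p, float(10.0**yi)) for p, yi in zip(peptides, y)]


def gen_design_responses(
    design: pd.DataFrame,
    beta: np.ndarray,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Quadratic-surface % inhibition responses with truncation to [0, 100]."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (10,):
        raise ValueError(f"beta must have 10 entries, got shape {beta.shape}")
    rng = stream_rng(seed, "design")
    points = design[list(FACTOR_COLUMNS)].to_numpy(dtype=float)
    raw = expand_quadratic(points) @ beta + rng.normal(0.0, noise_sd, size=len(points))
    out = design.copy()
    out["response_pct"] = np.clip(raw, 0.0, 100.0)
    out["saturated"] = (raw < 0.0) | (raw > 100.0)
    return out


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    conc_grid: tuple[float, ...] = DEFAULT_DOSE_GRID_UM,
    n_rep: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> DoseResponseCurve:
    """Logistic dose-response replicates, clipped to [0, 100] percent."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    rng = stream_rng(seed, "dose")
    conc = np.sort(np.asarray(conc_grid, dtype=float))
    truth = logistic_inhibition(conc, ic50, hill)
    noisy = truth[:, None] + rng.normal(0.0, noise_sd, size=(len(conc), n_rep))
    return DoseResponseCurve(concentrations=conc, inhibition=np.clip(noisy, 0.0, 100.0))


def gen_rate_data(
    vmax: float = 1.0,
    km: float = 0.2,
    kic: float = 10.0,
    kiu: float = np.inf,
    substrate_grid: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID_MM,
    inhibitor_levels: tuple[float, ...] | None = None,
    n_rep: int = 4,
    rel_noise: float = 0.03,
    seed: int = 0,
) -> KineticsDataset:
    """Initial rates under the general mixed-inhibition law.

    ``kic``/``kiu`` may be ``np.inf`` (uncompetitive / competitive limits).
    When ``inhibitor_levels`` is omitted they are set to IC50/{16, 8, 4}
    plus the control, with IC50 derived from the rate law at a 0.2 mM
    assay substrate concentration.
    """
    if min(vmax, km) <= 0 or kic <= 0 or kiu <= 0:
        raise ValueError("kinetic parameters must be positive")
    if inhibitor_levels is None:
        ic50 = ic50_from_kinetics(vmax, km, kic, kiu, s_assay=0.2)
        inhibitor_levels = (0.0, ic50 / 16.0, ic50 / 8.0, ic50 / 4.0)
    rng = stream_rng(seed, "rates")
    rows = []
    for level in inhibitor_levels:
        for s in substrate_grid:
            truth = float(mixed_rate(s, level, vmax, km, kic, kiu))
            noise = rng.normal(0.0, rel_noise, size=n_rep)
            for rep in truth * (1.0 + noise):
                rows.append((s, level, max(rep, 0.0)))
    return KineticsDataset(pd.DataFrame(rows, columns=["S_mM", "I_uM", "rate"]))


def ic50_from_kinetics(
    vmax: float, km: float, kic: float, kiu: float, s_assay: float = 0.2
) -> float:
    """Inhibitor concentration halving the rate at the assay substrate level.

    Solves v(I)/v(0) = 1/2 for the general law:
    IC50 = (Km + S) / (Km/Kic + S/Kiu).
    """
    denom = (km / kic if np.isfinite(kic) else 0.0) + (
        s_assay / kiu if np.isfinite(kiu) else 0.0
    )
    if denom <= 0:
        raise ValueError("at least one inhibition constant must be finite")
    return (km + s_assay) / denom
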