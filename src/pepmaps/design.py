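"""Three-factor hydrophobicity design and quadratic response-surface model.

Each factor is the normalized side-chain hydrophobicity (v3) of one
position of a tripeptide, coded on [-1, +1].  The 15-point face-centered
central composite layout (8 factorial corners, 6 face centers, 1 center)
identifies the full quadratic model

    % inhibition = b0 + b1 x + b2 y + b3 z + b4 x^2 + b5 y^2 + b6 z^2
                   + b7 xy + b8 xz + b9 yz + eps

of percent enzyme inhibition at a fixed dose.  Candidate tripeptides are
then scored by mapping residues to their v3 levels and ranked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .descriptors import DescriptorScale, STANDARD_RESIDUES, parse_peptide

TERM_NAMES = ("b0", "x", "y", "z", "x^2", "y^2", "z^2", "xy", "xz", "yz")
FACTOR_COLUMNS = ("x", "y", "z")


def generate_design() -> pd.DataFrame:
    """The 15-point face-centered central composite design.

    Deterministic order: 8 corners (itertools product over ±1), then the
    6 face centers (±1 on one axis), then the center point.
    """
    corners = [list(p) for p in itertools.product((-1.0, 1.0), repeat=3)]
    faces = []
    for axis in range(3):
        for level in (-1.0, 1.0):
            pt = [0.0, 0.0, 0.0]
            pt[axis] = level
            faces.append(pt)
    points = corners + faces + [[0.0, 0.0, 0.0]]
    return pd.DataFrame(points, columns=list(FACTOR_COLUMNS))


def assign_residues(
    point: tuple[float, float, float],
    scale: DescriptorScale,
    pool: set[str] | list[str],
) -> str:
    """Assign the pool residue with v3 closest to each coded level.

    Ties are broken alphabetically.  The published analog set deviates
    from pure nearest-residue assignment, which is why the pool is an
    explicit argument rather than the full alphabet.
    """
    pool = sorted({r.upper() for r in pool})
    if not pool:
        raise ValueError("residue pool is empty")
    residues = []
    for level in point:
        if not -1.0 <= level <= 1.0:
            raise ValueError(f"coded level {level} outside [-1, 1]")
        residues.append(min(pool, key=lambda r: (abs(scale.v3(r) - level), r)))
    return "".join(residues)


def expand_quadratic(points: np.ndarray) -> np.ndarray:
    """Expand (n, 3) coded levels into the 10-column quadratic model matrix."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    return np.column_stack(
        [np.ones(len(pts)), x, y, z, x**2, y**2, z**2, x * y, x * z, y * z]
    )


@dataclass
class QuadraticModel:
    """Fitted quadratic response surface: beta ordered as TERM_NAMES."""

    beta: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    points: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": TERM_NAMES, "beta": self.beta, "p_value": self.p_values}
        ).set_index("term")

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        """Terms with two-sided t-test p < alpha (no multiplicity correction)."""
        return [t for t, p in zip(TERM_NAMES, self.p_values) if p < alpha]


def fit_quadratic(design: pd.DataFrame, responses: np.ndarray) -> QuadraticModel:
    """Ordinary least squares fit of the 10-term quadratic expansion.

    Raises if the expanded matrix is rank-deficient (e.g. a corners-only
    design, on which all three squared terms are confounded with the
    intercept).
    """
    points = design[list(FACTOR_COLUMNS)].to_numpy(dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(points) != len(responses):
        raise ValueError("design and responses differ in length")
    Z = expand_quadratic(points)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError(
            "design cannot identify quadratic model: expanded matrix is rank-deficient"
        )
    ols = sm.OLS(responses, Z).fit()
    return QuadraticModel(
        beta=np.asarray(ols.params, dtype=float),
        p_values=np.asarray(ols.pvalues, dtype=float),
        residuals=np.asarray(ols.resid, dtype=float),
        fitted=np.asarray(ols.fittedvalues, dtype=float),
        points=points,
    )


def levels_for_tripeptide(peptide: str, scale: DescriptorScale) -> np.ndarray:
    seq = parse_peptide(peptide)
    if len(seq) != 3:
        raise ValueError(f"expected a tripeptide, got {peptide!r} (length {len(seq)})")
    return np.array([scale.v3(r) for r in seq])


def predict_percent_inhibition(
    model: QuadraticModel,
    levels: tuple[float, float, float] | None = None,
    peptide: str | None = None,
    scale: DescriptorScale | None = None,
) -> tuple[float, float]:
    """Predict % inhibition at coded levels or for a tripeptide.

    Returns ``(raw, clipped)`` where ``clipped`` is the raw polynomial
    value truncated to [0, 100] for reporting (predictions beyond the
    physical range are common near the design boundary).
    """
    if levels is None:
        if peptide is None or scale is None:
            raise ValueError("provide either levels or (peptide, scale)")
        levels = levels_for_tripeptide(peptide, scale)
    raw = float(expand_quadratic(np.asarray(levels))[0] @ model.beta)
    return raw, float(np.clip(raw, 0.0, 100.0))


def enumerate_and_rank(
    model: QuadraticModel,
    scale: DescriptorScale,
    position2: str = "free",
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Enumerate tripeptides, score them, and rank the candidates.

    With ``position2`` fixed to a residue the space is the 20 x 20
    Xaa1-(pos2)-Xaa3 library (400 sequences); with ``position2="free"``
    all 20^3 = 8000 tripeptides are enumerated.  Candidates with clipped
    predicted inhibition >= ``threshold`` are returned sorted by
    descending prediction, ties alphabetical.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    if position2 == "free":
        middles = STANDARD_RESIDUES
    else:
        middles = (parse_peptide(position2 + position2)[0],)
    v3 = {r: scale.v3(r) for r in STANDARD_RESIDUES}
    rows = []
    for r1, r2, r3 in itertools.product(STANDARD_RESIDUES, middles, STANDARD_RESIDUES):
        raw, clipped = predict_percent_inhibition(model, levels=(v3[r1], v3[r2], v3[r3]))
        rows.append((r1 + r2 + r3, v3[r1], v3[r2], v3[r3], raw, clipped))
    table = pd.DataFrame(
        rows, columns=["peptide", "x", "y", "z", "predicted_raw", "predicted_pct"]
    )
    table = table[table["predicted_pct"] >= threshold]
    table = table.sort_values(
        ["predicted_pct", "peptide"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
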