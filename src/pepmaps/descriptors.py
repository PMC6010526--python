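"""Amino-acid v-scale descriptors and terminal-position peptide encoding.

The three-component structural v-scale assigns every standard residue a
van der Waals volume score (``v1``), a net charge index (``v2``) and a
side-chain hydrophobicity (``v3``).  Each column is brought onto a common
dimensionless scale ("z-centered" in the design-of-experiments sense) by a
per-column affine map, after which a peptide of any length from 2 to 9
residues is represented by the 12 descriptor values of its two N-terminal
and two C-terminal residues.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Printed normalized v3 values used to calibrate the normalization
#: convention.  They pin the affine map for the hydrophobicity column:
#: the extremes (W = +1, R = -1) identify it as range scaling to [-1, 1].
V3_ANCHORS: dict[str, float] = {
    "I": 0.725,
    "P": 0.059,
    "A": -0.194,
    "F": 0.716,
    "R": -1.000,
    "K": -0.991,
    "W": 1.000,
}

#: Maximum tolerated |normalized - anchor| residual after calibration.
ANCHOR_TOLERANCE = 0.005

DESCRIPTOR_NAMES = ("v1", "v2", "v3")

#: Column order of the 12-entry descriptor vector: two N-terminal residues
#: then two C-terminal residues (C1 = last, C2 = second-to-last), three
#: descriptors each.
VECTOR_COLUMNS = tuple(
    f"{side}{i}_{d}" for side in "NC" for i in (1, 2) for d in DESCRIPTOR_NAMES
)

MIN_PEPTIDE_LENGTH = 2
MAX_PEPTIDE_LENGTH = 9

THREE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class UnknownResidueError(ValueError):
    """A residue code absent from the descriptor scale."""


def parse_peptide(sequence: str) -> str:
    """Return the validated one-letter sequence for ``sequence``.

    Accepts bare one-letter strings (``"IPI"``) or dash-separated
    three-letter names (``"Ile-Pro-Ile"``); input is uppercased.
    Non-standard codes (B, Z, X, U, O) are rejected.
    """
    seq = sequence.strip()
    if "-" in seq:
        parts = [p.strip().upper() for p in seq.split("-") if p.strip()]
        try:
            seq = "".join(THREE_LETTER[p] for p in parts)
        except KeyError as exc:
            raise UnknownResidueError(f"unknown residue name {exc.args[0]!r}") from None
    else:
        seq = seq.upper()
    for ch in seq:
        if ch not in STANDARD_RESIDUES:
            raise UnknownResidueError(f"unknown residue {ch!r} in peptide {sequence!r}")
    if len(seq) < MIN_PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide {sequence!r} has length {len(seq)}; minimum is {MIN_PEPTIDE_LENGTH}"
        )
    return seq


def normalize_column(
    raw: dict[str, float] | pd.Series,
    anchors: dict[str, float] | None = None,
) -> tuple[dict[str, float], tuple[float, float]]:
    """Affine-normalize one descriptor column over the 20 residues.

    With ``anchors`` given, the slope and offset are the two-parameter
    least-squares fit mapping the raw values of the anchor residues onto
    their target normalized values; residuals above ``ANCHOR_TOLERANCE``
    raise a "normalization convention mismatch" error.  Without anchors the
    column is min-max scaled to [-1, 1] (the convention the anchored fit
    empirically resolves to).  A constant column maps to all zeros.

    Returns the normalized column and the fitted ``(slope, offset)``.
    """
    raw = dict(raw)
    values = np.asarray(list(raw.values()), dtype=float)
    if anchors:
        missing = sorted(set(anchors) - set(raw))
        if missing:
            raise UnknownResidueError(f"anchor residues missing from scale: {missing}")
        x = np.array([raw[r] for r in anchors], dtype=float)
        t = np.array([anchors[r] for r in anchors], dtype=float)
        design = np.column_stack([x, np.ones_like(x)])
        (slope, offset), *_ = np.linalg.lstsq(design, t, rcond=None)
        resid = np.abs(design @ [slope, offset] - t)
        if resid.max() > ANCHOR_TOLERANCE:
            raise ValueError(
                "normalization convention mismatch: anchor residual "
                f"{resid.max():.4f} exceeds {ANCHOR_TOLERANCE}"
            )
    else:
        span = values.max() - values.min()
        if span == 0.0:
            slope, offset = 0.0, 0.0
        else:
            slope = 2.0 / span
            offset = -1.0 - slope * values.min()
    normalized = {r: slope * v + offset for r, v in raw.items()}
    return normalized, (float(slope), float(offset))


@dataclass(frozen=True)
class DescriptorScale:
    """Per-residue descriptor table in raw and normalized form.

    ``raw`` and ``normalized`` map each of the 20 standard residues to its
    (v1, v2, v3) triple; ``transforms`` records the per-column affine
    (slope, offset) so the normalization convention is reproducible.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    transforms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df in (self.raw, self.normalized):
            if sorted(df.index) != sorted(STANDARD_RESIDUES):
                raise ValueError("scale must cover exactly the 20 standard residues")
            if list(df.columns) != list(DESCRIPTOR_NAMES):
                raise ValueError(f"scale columns must be {DESCRIPTOR_NAMES}")

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(self.raw.index)

    def descriptor_triple(self, residue: str) -> np.ndarray:
        """Normalized (v1, v2, v3) of one residue."""
        if residue not in self.normalized.index:
            raise UnknownResidueError(f"unknown residue {residue!r}")
        return self.normalized.loc[residue].to_numpy(dtype=float)

    def v3(self, residue: str) -> float:
        """Normalized side-chain hydrophobicity of one residue."""
        return float(self.descriptor_triple(residue)[2])


def load_scale(source: str | None = None) -> DescriptorScale:
    """Load the v-scale table and calibrate its normalization.

    ``source`` is a TSV with columns ``residue v1 v2 v3``; by default the
    bundled 20-residue fixture is used.  The v3 column is normalized
    against the printed anchor values, v1 and v2 by min-max to [-1, 1].
    """
    if source is None:
        source = str(
            importlib.resources.files("pepmaps.data").joinpath("v_scale.tsv")
        )
    table = pd.read_csv(source, sep="\t", comment="#")
    required = {"residue", *DESCRIPTOR_NAMES}
    if not required.issubset(table.columns):
        raise ValueError(f"scale table must have columns {sorted(required)}")
    if table["residue"].duplicated().any():
        dupes = table.loc[table["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residues in scale table: {dupes}")
    table = table.set_index("residue")
    missing = sorted(set(STANDARD_RESIDUES) - set(table.index))
    if missing:
        raise UnknownResidueError(f"scale table missing residues: {missing}")
    if table[list(DESCRIPTOR_NAMES)].isna().any().any():
        bad = table.index[table[list(DESCRIPTOR_NAMES)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing descriptor values for residues: {bad}")

    raw = table.loc[list(STANDARD_RESIDUES), list(DESCRIPTOR_NAMES)].astype(float)
    normalized = {}
    transforms = {}
    for name in DESCRIPTOR_NAMES:
        anchors = V3_ANCHORS if name == "v3" else None
        col, params = normalize_column(raw[name].to_dict(), anchors=anchors)
        normalized[name] = col
        transforms[name] = params
    norm_df = pd.DataFrame(normalized).loc[list(STANDARD_RESIDUES)]
    return DescriptorScale(raw=raw, normalized=norm_df, transforms=transforms)


def encode_peptide(peptide: str, scale: DescriptorScale) -> np.ndarray:
    """Encode a peptide into its 12-entry terminal descriptor vector.

    The vector holds the normalized (v1, v2, v3) triples of the first and
    second residues counted from the N-terminus followed by those of the
    first and second residues counted from the C-terminus, in the order of
    :data:`VECTOR_COLUMNS`.  For dipeptides the two blocks reuse the same
    residue pair, so the full 12-term model remains applicable.
    """
    seq = parse_peptide(peptide)
    terminal = (seq[0], seq[1], seq[-1], seq[-2])
    return np.concatenate([scale.descriptor_triple(r) for r in terminal])


def encode_table(peptides: list[str], scale: DescriptorScale) -> pd.DataFrame:
    """Encode many peptides; rows indexed by sequence, columns VECTOR_COLUMNS."""
    rows = [encode_peptide(p, scale) for p in peptides]
    return pd.DataFrame(rows, index=[parse_peptide(p) for p in peptides],
                        columns=list(VECTOR_COLUMNS))
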