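"""Additive null model for multi-guide knockout arrays.

A pool of n-position guide arrays enumerates every combination of an
essential or non-essential guide at each position (2**n masks per pool).
After anchoring fold changes to the all-non-essential arrays, the
fitness of an array should, absent genetic interaction and position
artifacts, be the sum of per-position single-knockout effects:

    y ~ A beta

with A the k x n binary design matrix (A[i, j] = 1 iff array i carries an
essential guide at position j) and beta the per-position knockout
phenotypes.  Fitting on arrays encoding at most two essentials avoids the
saturation of higher-order knockouts; predictions for held-in masks are the
summed betas.  Per-position means of single-essential arrays, and the
forward-versus-reverse orientation comparison, expose position-dependent
loss of guide efficacy near the array's 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd


class DesignError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass
class ArrayDesign:
    """Arrays (one per pool x mask x orientation) with optional observed LFC.

    ``frame`` columns: array_id, pool, mask (0/1 string, position 1 first),
    orientation ("forward"/"reverse"), and optionally lfc (or several
    ``lfc_<label>`` columns for multiple timepoints).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"array_id", "pool", "mask", "orientation"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DesignError(f"design missing columns {sorted(missing)}")
        key = self.frame[["pool", "mask", "orientation"]]
        if key.duplicated().any():
            raise DesignError("duplicate (pool, mask, orientation) rows")

    @property
    def n_positions(self) -> int:
        return len(self.frame["mask"].iloc[0])

    @property
    def lfc_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c == "lfc" or c.startswith("lfc_")]

    def popcounts(self) -> pd.Series:
        return self.frame["mask"].map(lambda m: m.count("1"))

    def with_lfc(self, values: np.ndarray, column: str = "lfc") -> "ArrayDesign":
        frame = self.frame.copy()
        frame[column] = np.asarray(values, dtype=float)
        return ArrayDesign(frame)


@dataclass
class ArrayModelFit:
    beta: np.ndarray  # per-position coefficients
    intercept: float
    k_rows: int
    design_matrix: np.ndarray
    response: np.ndarray
    residual: np.ndarray

    def predict_mask(self, mask: str) -> float:
        bits = np.array([int(b) for b in mask], dtype=float)
        return float(self.intercept + bits @ self.beta)


def enumerate_design(n_positions: int = 7, n_pools: int = 3) -> ArrayDesign:
    """All 2**n essential/non-essential masks, once per pool (forward)."""
    if n_positions < 1:
        raise DesignError("n_positions must be >= 1")
    rows = []
    for pool in range(1, n_pools + 1):
        for bits in product("01", repeat=n_positions):
            mask = "".join(bits)
            rows.append(
                {
                    "array_id": f"pool{pool}_{mask}",
                    "pool": pool,
                    "mask": mask,
                    "orientation": "forward",
                }
            )
    return ArrayDesign(pd.DataFrame(rows))


def normalize_to_all_nonessential(design: ArrayDesign) -> ArrayDesign:
    """Shift each LFC column so all-non-essential arrays average zero.

    Columns (timepoints/samples) are normalized independently; the shift is
    uniform across arrays, so between-array differences are untouched.
    """
    frame = design.frame.copy()
    zero_mask = frame["mask"].map(lambda m: "1" not in m)
    if not zero_mask.any():
        raise DesignError("no all-non-essential array to anchor normalization")
    for col in design.lfc_columns:
        frame[col] = frame[col] - frame.loc[zero_mask, col].mean()
    return ArrayDesign(frame)


def filter_low_order(design: ArrayDesign, max_essentials: int = 2) -> ArrayDesign:
    """Keep arrays encoding at most ``max_essentials`` essential guides."""
    keep = design.popcounts() <= max_essentials
    return ArrayDesign(design.frame.loc[keep].reset_index(drop=True))


def _design_matrix(design: ArrayDesign) -> np.ndarray:
    return np.array(
        [[int(b) for b in mask] for mask in design.frame["mask"]], dtype=float
    )


def fit_additive_model(design: ArrayDesign, lfc_column: str = "lfc") -> ArrayModelFit:
    """Least-squares fit of LFC on the binary position matrix (with intercept).

    After anchoring to the all-non-essential arrays the intercept is ~0 and
    the formulation coincides with the intercept-free additive model.
    """
    if lfc_column not in design.frame.columns:
        raise FitError(f"design has no column {lfc_column!r}")
    A = _design_matrix(design)
    y = design.frame[lfc_column].to_numpy(dtype=float)
    keep = np.isfinite(y)
    A, y = A[keep], y[keep]
    X = np.column_stack([np.ones(len(A)), A])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent (constant within retained rows) positions
        constant = [j + 1 for j in range(A.shape[1]) if np.ptp(A[:, j]) == 0]
        raise FitError(f"design matrix rank-deficient; degenerate positions: {constant}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return ArrayModelFit(
        beta=coef[1:],
        intercept=float(coef[0]),
        k_rows=len(y),
        design_matrix=A,
        response=y,
        residual=y - fitted,
    )


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def predict_and_score(
    fit: ArrayModelFit,
    design: ArrayDesign,
    order: int = 2,
    lfc_column: str = "lfc",
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Predict arrays of knockout order <= ``order`` and score R² per pool.

    The prediction for a mask is the intercept plus the sum of the betas of
    its essential positions, compared against the observed LFC.
    """
    keep = design.popcounts() <= order
    sub = design.frame.loc[keep].copy()
    sub["predicted"] = [fit.predict_mask(m) for m in sub["mask"]]
    r2 = {}
    for pool, grp in sub.groupby("pool"):
        obs = grp[lfc_column].to_numpy(dtype=float)
        r2[pool] = _r_squared(obs, grp["predicted"].to_numpy())
    return sub, r2


def position_effects(design: ArrayDesign, lfc_column: str = "lfc") -> pd.Series:
    """Mean LFC of single-essential arrays, by array position (1-based).

    Positions with no single-essential array are absent from the result.
    """
    frame = design.frame
    singles = frame.loc[design.popcounts() == 1]
    means = {}
    for position in range(1, design.n_positions + 1):
        at_pos = singles.loc[singles["mask"].map(lambda m: m[position - 1] == "1")]
        if len(at_pos):
            means[position] = float(at_pos[lfc_column].mean())
    return pd.Series(means, name="mean_lfc").rename_axis("position")


def forward_vs_reverse(
    forward: ArrayDesign, reverse: ArrayDesign, lfc_column: str = "lfc"
) -> pd.DataFrame:
    """Pair single-essential arrays across orientations, per guide.

    The reverse design carries the same guides with position i mapped to
    n+1-i, so the single-essential array whose forward position is i matches
    the reverse array essential at n+1-i within the same pool.  Deviation is
    forward minus reverse LFC; off-diagonal points flag position-specific
    efficacy loss.
    """
    n = forward.n_positions
    f_singles = forward.frame.loc[forward.popcounts() == 1]
    r_singles = reverse.frame.loc[
        reverse.frame["mask"].map(lambda m: m.count("1") == 1)
    ]
    rows = []
    for row in f_singles.itertuples(index=False):
        fwd_pos = row.mask.index("1") + 1
        rev_pos = n + 1 - fwd_pos
        rev_mask = "".join("1" if p == rev_pos else "0" for p in range(1, n + 1))
        match = r_singles.loc[
            (r_singles["pool"] == row.pool) & (r_singles["mask"] == rev_mask)
        ]
        if match.empty:
            continue
        f_lfc = getattr(row, lfc_column)
        r_lfc = float(match.iloc[0][lfc_column])
        rows.append(
            {
                "pool": row.pool,
                "position": fwd_pos,
                "forward_lfc": f_lfc,
                "reverse_lfc": r_lfc,
                "deviation": f_lfc - r_lfc,
            }
        )
    return pd.DataFrame(rows, columns=["pool", "position", "forward_lfc", "reverse_lfc", "deviation"])
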