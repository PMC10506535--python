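"""Discrete-frequency band selection by spectral reconstruction.

A small set of Raman shifts is judged by how well an ordinary-least-squares
regression on those bands (plus intercept) reconstructs the full
hyperspectral spectrum of every pixel.  Bands are chosen greedily: at each
step the candidate that most reduces held-out reconstruction MSE is added,
with ties broken toward the lower shift.  An exhaustive-subset search is
provided for small ``k`` as a global reference.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np

from .phantom import HyperspectralCube

__all__ = [
    "ReconstructionModel",
    "fit_reconstruction",
    "greedy_select",
    "exhaustive_select",
]


@dataclass
class ReconstructionModel:
    """OLS map from k selected band intensities (plus intercept) to all B
    bands, with held-out goodness of fit."""

    selected_shifts: list
    weights: np.ndarray  # (k+1) x B: row 0 intercept, then one row per band
    r2: float
    mse: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.selected_shifts) + 1:
            raise ValueError("weights must have k+1 rows (intercept + bands)")
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.mse < 0:
            raise ValueError("mse cannot be negative")

    def predict(self, selected_values: np.ndarray) -> np.ndarray:
        """Reconstruct full spectra from selected-band intensities
        (n_pixels × k) → (n_pixels × B)."""
        x = np.asarray(selected_values, dtype=float)
        design = np.hstack([np.ones((x.shape[0], 1)), x])
        return design @ self.weights

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["weights"] = self.weights.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReconstructionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            selected_shifts=payload["selected_shifts"],
            weights=np.asarray(payload["weights"]),
            r2=payload["r2"],
            mse=payload["mse"],
        )


def _pixel_matrix(cube: HyperspectralCube) -> np.ndarray:
    h, w, b = cube.shape
    return cube.values.reshape(h * w, b).astype(float)


def _split(n_pixels: int, holdout_fraction: float, seed: int):
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pixels)
    n_test = max(1, int(round(holdout_fraction * n_pixels)))
    return perm[n_test:], perm[:n_test]


def _shift_indices(cube: HyperspectralCube, shifts) -> list[int]:
    axis = cube.axis.values
    idx = []
    for s in shifts:
        hit = np.nonzero(np.isclose(axis, float(s)))[0]
        if hit.size == 0:
            raise ValueError(f"shift {s} cm^-1 is not on the cube axis")
        idx.append(int(hit[0]))
    return idx


def _ols_eval(train: np.ndarray, test: np.ndarray, cols: list[int]):
    """Fit intercept+cols OLS on train pixels, return (weights, test mse,
    test r2)."""
    x_tr = np.hstack([np.ones((train.shape[0], 1)), train[:, cols]])
    x_te = np.hstack([np.ones((test.shape[0], 1)), test[:, cols]])
    w, *_ = np.linalg.lstsq(x_tr, train, rcond=None)
    resid = test - x_te @ w
    mse = float(np.mean(resid**2))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((test - test.mean(axis=0)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return w, mse, r2


def fit_reconstruction(cube: HyperspectralCube, selected_shifts,
                       holdout_fraction: float = 0.25,
                       seed: int = 0) -> ReconstructionModel:
    """Per-band OLS of the full spectrum on the selected band intensities,
    evaluated on a seeded held-out pixel split."""
    shifts = list(selected_shifts)
    if not shifts:
        raise ValueError("selected_shifts must be nonempty")
    dupes = {s for s in shifts if shifts.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate bands selected: {sorted(dupes)}")
    cols = _shift_indices(cube, shifts)
    pixels = _pixel_matrix(cube)
    tr, te = _split(pixels.shape[0], holdout_fraction, seed)
    w, mse, r2 = _ols_eval(pixels[tr], pixels[te], cols)
    return ReconstructionModel(selected_shifts=shifts, weights=w, r2=r2, mse=mse)


def _gram_mse(g_tr_xx, g_tr_xy, g_te_xx, g_te_xy, g_te_yy, n_te, b, cols):
    """Held-out reconstruction SSE for one band subset from precomputed
    Gram/cross matrices (intercept included as column 0)."""
    sel = [0] + [c + 1 for c in cols]
    a = g_tr_xx[np.ix_(sel, sel)]
    rhs = g_tr_xy[sel]
    # near-singular normal equations mean the bands carry no independent
    # signal; score them as useless rather than trust a cancelled SSE
    if np.linalg.cond(a) > 1e10:
        return float("inf")
    w = np.linalg.solve(a, rhs)
    # ||Y - Xw||^2 over the test pixels via the test Gram matrices
    sse = g_te_yy - 2.0 * np.sum(w * g_te_xy[sel]) + np.sum(
        w * (g_te_xx[np.ix_(sel, sel)] @ w)
    )
    return max(float(sse), 0.0) / (n_te * b)


def _gram_matrices(pixels: np.ndarray, tr, te):
    ones_tr = np.ones((tr.size, 1))
    ones_te = np.ones((te.size, 1))
    x_tr = np.hstack([ones_tr, pixels[tr]])
    x_te = np.hstack([ones_te, pixels[te]])
    y_tr, y_te = pixels[tr], pixels[te]
    return (
        x_tr.T @ x_tr,
        x_tr.T @ y_tr,
        x_te.T @ x_te,
        x_te.T @ y_te,
        float(np.sum(y_te**2)),
    )


def greedy_select(cube: HyperspectralCube, k: int, candidate_shifts=None,
                  holdout_fraction: float = 0.25,
                  seed: int = 0) -> ReconstructionModel:
    """Forward band selection minimizing held-out reconstruction MSE.

    Returns the model fit on the final selection; ``selected_shifts`` is in
    selection order.
    """
    axis = cube.axis.values
    candidates = sorted(candidate_shifts) if candidate_shifts is not None else list(axis)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate bands")
    cand_cols = _shift_indices(cube, candidates)
    pixels = _pixel_matrix(cube)
    tr, te = _split(pixels.shape[0], holdout_fraction, seed)
    grams = _gram_matrices(pixels, tr, te)
    b = pixels.shape[1]
    chosen: list[int] = []
    chosen_shifts: list[float] = []
    remaining = list(zip(cand_cols, candidates))
    for _ in range(k):
        best = None
        for col, shift in remaining:
            mse = _gram_mse(*grams, te.size, b, chosen + [col])
            # strict '<' keeps the earlier (lower-shift) candidate on ties
            if best is None or mse < best[0] - 1e-15:
                best = (mse, col, shift)
        _, col, shift = best
        chosen.append(col)
        chosen_shifts.append(shift)
        remaining = [(c, s) for c, s in remaining if c != col]
    model = fit_reconstruction(cube, chosen_shifts, holdout_fraction, seed)
    return model


def exhaustive_select(cube: HyperspectralCube, k: int, candidate_shifts=None,
                      holdout_fraction: float = 0.25,
                      seed: int = 0) -> ReconstructionModel:
    """Globally optimal k-band subset by exhaustive search (feasible for
    small k; C(B, k) subsets are scored via precomputed Gram matrices)."""
    axis = cube.axis.values
    candidates = sorted(candidate_shifts) if candidate_shifts is not None else list(axis)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate bands")
    cand_cols = _shift_indices(cube, candidates)
    pixels = _pixel_matrix(cube)
    tr, te = _split(pixels.shape[0], holdout_fraction, seed)
    grams = _gram_matrices(pixels, tr, te)
    b = pixels.shape[1]
    best = None
    for combo in itertools.combinations(range(len(candidates)), k):
        cols = [cand_cols[i] for i in combo]
        mse = _gram_mse(*grams, te.size, b, cols)
        if best is None or mse < best[0] - 1e-15:
            best = (mse, combo)
    shifts = [candidates[i] for i in best[1]]
    return fit_reconstruction(cube, shifts, holdout_fraction, seed)
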