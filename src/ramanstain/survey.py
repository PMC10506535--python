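"""Pathologist-survey statistics: multi-rater agreement and score summaries.

Fleiss' kappa measures chance-corrected agreement between a fixed number of
raters assigning categorical labels (e.g., Gleason patterns) to a set of
images: κ = (P̄ − P̄ₑ)/(1 − P̄ₑ), where P̄ is the mean over items of the
pairwise rater agreement and P̄ₑ = Σⱼ pⱼ² the chance agreement implied by
the category marginals.  The 95% confidence interval uses the Fleiss
large-sample variance with a normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatingsTable",
    "KappaResult",
    "fleiss_kappa",
    "interpret_kappa",
    "summarize_scores",
    "simulate_ratings",
]


@dataclass
class RatingsTable:
    """Items × raters categorical ratings under one condition."""

    ratings: np.ndarray  # (n_items, n_raters), values drawn from `categories`
    categories: tuple
    condition: str = "virtual"

    def __post_init__(self):
        self.ratings = np.asarray(self.ratings)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be items × raters")
        cats = set(self.categories)
        present = set(np.unique(self.ratings).tolist())
        if not present <= cats:
            raise ValueError(f"ratings outside declared categories: {present - cats}")

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def counts(self) -> np.ndarray:
        """Item × category count matrix."""
        cat_index = {c: j for j, c in enumerate(self.categories)}
        out = np.zeros((self.n_items, len(self.categories)), dtype=int)
        for i in range(self.n_items):
            for r in range(self.n_raters):
                out[i, cat_index[self.ratings[i, r]]] += 1
        return out

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "RatingsTable":
        """Load from long-format CSV with columns item_id, rater_id,
        condition, rating."""
        df = pd.read_csv(path)
        required = {"item_id", "rater_id", "condition", "rating"}
        if not required <= set(df.columns):
            raise ValueError(f"ratings CSV needs columns {sorted(required)}")
        if condition is not None:
            df = df[df["condition"] == condition]
            if df.empty:
                raise ValueError(f"no rows with condition {condition!r}")
        else:
            conds = df["condition"].unique()
            if len(conds) > 1:
                raise ValueError(
                    f"multiple conditions present ({list(conds)}); pick one"
                )
            condition = str(conds[0])
        wide = df.pivot(index="item_id", columns="rater_id", values="rating")
        if wide.isna().any().any():
            raise ValueError("every item must be rated by every rater")
        cats = tuple(sorted(pd.unique(df["rating"])))
        return cls(wide.to_numpy(), cats, condition)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_items: int
    n_raters: int
    interpretation: str

    def __post_init__(self):
        if not (self.ci_low <= self.kappa <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.kappa > 1:
            raise ValueError("kappa cannot exceed 1")


def fleiss_kappa(table: RatingsTable, ci_method: str = "normal",
                 n_boot: int = 2000, seed: int = 0) -> KappaResult:
    """Fleiss' kappa with a 95% confidence interval.

    ``ci_method="normal"`` (default) uses the Fleiss large-sample variance;
    ``"bootstrap"`` resamples items.
    """
    if table.n_raters < 2 or table.n_items < 2:
        raise ValueError("need at least 2 raters and 2 items")
    counts = table.counts()
    if (counts > 0).sum(axis=0).astype(bool).sum() < 2:
        raise ValueError("kappa undefined: all ratings fall in one category")
    kappa, p_bar_e, p_j = _kappa_from_counts(counts)
    n_items, _ = counts.shape
    n = table.n_raters
    if ci_method == "normal":
        # Fleiss (1971) large-sample variance of the overall kappa
        num = p_bar_e - (2 * n - 3) * p_bar_e**2 + 2 * (n - 2) * np.sum(p_j**3)
        var = 2.0 / (n_items * n * (n - 1)) * num / (1 - p_bar_e) ** 2
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        lo, hi = kappa - half, kappa + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            pick = rng.integers(0, n_items, size=n_items)
            try:
                reps.append(_kappa_from_counts(counts[pick])[0])
            except ZeroDivisionError:
                continue
        lo, hi = np.percentile(reps, [2.5, 97.5])
        lo, hi = min(lo, kappa), max(hi, kappa)
    else:
        raise ValueError("ci_method must be 'normal' or 'bootstrap'")
    return KappaResult(
        kappa=float(kappa), ci_low=float(min(lo, 1.0)), ci_high=float(min(hi, 1.0)),
        n_items=n_items, n_raters=n, interpretation=interpret_kappa(kappa),
    )


def _kappa_from_counts(counts: np.ndarray):
    n_items = counts.shape[0]
    n = int(counts[0].sum())
    p_j = counts.sum(axis=0) / (n_items * n)
    p_bar_e = float(np.sum(p_j**2))
    p_i = (np.sum(counts**2, axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    if p_bar_e >= 1.0:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return (p_bar - p_bar_e) / (1 - p_bar_e), p_bar_e, p_j


_BANDS = [
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def interpret_kappa(value: float) -> str:
    """Map a kappa value to its conventional agreement band; values at or
    below 0 indicate agreement no better than chance."""
    if value > 1:
        raise ValueError("kappa cannot exceed 1")
    if value <= 0:
        return "chance or worse"
    for upper, label in _BANDS:
        if value <= upper + 1e-12:
            return label
    return "almost perfect"


def summarize_scores(virtual: RatingsTable, real: RatingsTable | None = None):
    """Per-rater and overall mean ± SD of numeric quality scores, formatted
    "m.mm ± s.ss", plus (when a paired condition is given) a two-sided
    paired t test per rater across items.

    Returns a dict with keys ``per_rater``, ``overall`` and optionally
    ``comparison``.
    """

    def _numeric(table: RatingsTable) -> np.ndarray:
        try:
            return table.ratings.astype(float)
        except (TypeError, ValueError) as exc:
            raise TypeError(
                "scores must be numeric; for categorical ratings use fleiss_kappa"
            ) from exc

    def _fmt(m, s):
        return f"{m:.2f} ± {s:.2f}"

    v = _numeric(virtual)
    out = {"per_rater": {}, "overall": {}}
    per = []
    for r in range(v.shape[1]):
        m, s = v[:, r].mean(), v[:, r].std(ddof=1)
        per.append((m, s))
        out["per_rater"][f"rater_{r + 1}"] = {"mean": m, "sd": s,
                                              "formatted": _fmt(m, s)}
    m_all, s_all = v.mean(), v.std(ddof=1)
    out["overall"] = {"mean": m_all, "sd": s_all, "formatted": _fmt(m_all, s_all)}
    if real is not None:
        w = _numeric(real)
        if w.shape != v.shape:
            raise ValueError("paired comparison needs matching table shapes")
        comparison = {}
        for r in range(v.shape[1]):
            diff = v[:, r] - w[:, r]
            if np.allclose(diff, 0):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(v[:, r], w[:, r])
            comparison[f"rater_{r + 1}"] = {"t": float(t), "p": float(p)}
        out["comparison"] = comparison
    return out


def simulate_ratings(seed: int, n_items: int = 35, n_raters: int = 5,
                     categories=(1, 2, 3, 4, 5), agreement: float = 0.5,
                     condition: str = "virtual") -> RatingsTable:
    """Synthetic ratings with tunable agreement: each item has a true
    category; each rater reports it with probability ``agreement`` and
    otherwise rates uniformly at random.  Mirrors the survey design shape
    (35 items × 5 raters) at the default sizes."""
    rng = np.random.default_rng(seed)
    cats = list(categories)
    truth = rng.integers(0, len(cats), size=n_items)
    ratings = np.empty((n_items, n_raters), dtype=np.asarray(cats).dtype)
    for i in range(n_items):
        for r in range(n_raters):
            if rng.random() < agreement:
                ratings[i, r] = cats[truth[i]]
            else:
                ratings[i, r] = cats[rng.integers(0, len(cats))]
    return RatingsTable(ratings, tuple(cats), condition)
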