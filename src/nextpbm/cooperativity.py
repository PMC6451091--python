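"""Cooperativity scoring by deviation from an autonomous-binding reference.

A TF that binds a composite element cooperatively with a cofactor present
only in nuclear extract shows *enhanced* extract binding relative to what
its cofactor-free (IVT) binding predicts.  The reference relation is a
degree-2 polynomial fit by ordinary least squares to the extract (y1) vs
IVT (x1) z-scores of canonical, autonomously bound probes:

    y1 = b0 + b1*x1 + b2*x1^2 + e1

(the quadratic term absorbs concentration-driven non-linearity).  Each
composite probe is then scored by its deviation from that curve:

    e2 = y2 - (b0 + b1*x2 + b2*x2^2),     score = |e2| / var(e1)

with var(e1) the sample variance (n-1) of the canonical residuals.  The
absolute value conflates enhanced and depleted binding, so the signed
residual is always reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class CooperativityFit:
    """Degree-2 reference polynomial fit on canonical probes."""

    beta: np.ndarray  # (b0, b1, b2)
    eps1: np.ndarray
    var_eps1: float
    n_canonical: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta[0] + self.beta[1] * x + self.beta[2] * x**2

    @property
    def null_scores(self) -> np.ndarray:
        """Empirical null: canonical probes scored against their own fit
        (|e1| / var(e1)); used for percentile context only."""
        return np.abs(self.eps1) / self.var_eps1


@dataclass
class CooperativityResult:
    """Per-composite-probe scores against a canonical reference fit."""

    x2: np.ndarray
    y2: np.ndarray
    eps2: np.ndarray
    score: np.ndarray
    fit: CooperativityFit

    def to_dataframe(self, sequences: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x2": self.x2, "y2": self.y2, "eps2": self.eps2, "score": self.score}
        )
        if sequences is not None:
            df.insert(0, "unique_seq", list(sequences))
        return df


def fit_reference(x1: np.ndarray, y1: np.ndarray) -> CooperativityFit:
    """OLS fit of the degree-2 reference polynomial to canonical probes."""
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    if x1.shape != y1.shape or x1.ndim != 1:
        raise ValueError("x1 and y1 must be equal-length 1-D vectors")
    if not (np.isfinite(x1).all() and np.isfinite(y1).all()):
        raise ValueError("x1 and y1 must be finite")
    n = len(x1)
    if n < 10:
        raise ValueError(f"need >= 10 canonical probes to fit, got {n}")
    if len(np.unique(x1)) <= 3:
        raise ValueError("rank-deficient design: <= 3 distinct x values")
    design = np.column_stack([np.ones(n), x1, x1**2])
    beta, _, rank, _ = np.linalg.lstsq(design, y1, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design matrix")
    eps1 = y1 - design @ beta
    var_eps1 = float(eps1.var(ddof=1))
    # a numerically perfect fit leaves only rounding noise in eps1
    if var_eps1 <= 1e-20 * max(1.0, float(y1.var())):
        raise ValueError(
            "variance of canonical residuals is zero (perfect fit); "
            "cooperativity scores are undefined"
        )
    return CooperativityFit(beta=beta, eps1=eps1, var_eps1=var_eps1, n_canonical=n)


def score_composites(
    fit: CooperativityFit, x2: np.ndarray, y2: np.ndarray
) -> CooperativityResult:
    """Score composite probes: |residual from the canonical curve| scaled
    by the canonical residual variance."""
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if x2.shape != y2.shape or x2.ndim != 1:
        raise ValueError("x2 and y2 must be equal-length 1-D vectors")
    if not (np.isfinite(x2).all() and np.isfinite(y2).all()):
        raise ValueError("x2 and y2 must be finite")
    if fit.var_eps1 <= 0:
        raise ValueError("invalid fit: var(eps1) <= 0")
    eps2 = y2 - fit.predict(x2)
    return CooperativityResult(
        x2=x2, y2=y2, eps2=eps2, score=np.abs(eps2) / fit.var_eps1, fit=fit
    )


def score_from_zscore_tables(
    ivt: pd.DataFrame,
    extract: pd.DataFrame,
    canonical_categories: Sequence[str] = ("seed",),
    composite_categories: Sequence[str] = ("synthetic_composite",),
) -> tuple[CooperativityFit, CooperativityResult, pd.DataFrame]:
    """Fit and score directly from two z-score tables sharing a design.

    Canonical probes (the reference set) and composite probes are selected
    by manifest category; keeping composites out of the reference fit is
    what makes the score a deviation measure rather than a tautology.
    """
    joined = ivt.merge(
        extract[["unique_seq", "z"]],
        on="unique_seq",
        suffixes=("_ivt", "_extract"),
    )
    canon = joined[joined["category"].isin(canonical_categories)]
    comp = joined[joined["category"].isin(composite_categories)]
    if comp.empty:
        raise ValueError(f"no composite probes with category in {composite_categories}")
    fit = fit_reference(canon["z_ivt"].to_numpy(), canon["z_extract"].to_numpy())
    result = score_composites(
        fit, comp["z_ivt"].to_numpy(), comp["z_extract"].to_numpy()
    )
    table = result.to_dataframe(sequences=comp["unique_seq"].tolist())
    table["seed_id"] = comp["seed_id"].to_numpy()
    return fit, result, table


def compare_conditions(
    scores_by_condition: Mapping[str, np.ndarray],
    dilution_order: Sequence[str] | None = None,
    min_probes: int = 5,
) -> pd.DataFrame:
    """Summarize score distributions across extract conditions.

    Returns per-condition n/median/quartiles; if *dilution_order* names an
    ordered series of conditions, the result's ``attrs`` carry a
    ``monotone_decreasing`` report across that series.
    """
    rows = {}
    for name, scores in scores_by_condition.items():
        scores = np.asarray(scores, dtype=float)
        if len(scores) < min_probes:
            warnings.warn(
                f"condition {name!r} has only {len(scores)} composite probes "
                f"(< {min_probes}); excluded"
            )
            continue
        rows[name] = {
            "n": len(scores),
            "median": float(np.median(scores)),
            "q1": float(np.quantile(scores, 0.25)),
            "q3": float(np.quantile(scores, 0.75)),
        }
    if len(rows) < 2:
        raise ValueError("need >= 2 usable conditions to compare")
    out = pd.DataFrame.from_dict(rows, orient="index")
    if dilution_order is not None:
        order = [c for c in dilution_order if c in out.index]
        medians = out.loc[order, "median"].to_numpy()
        out.attrs["dilution_order"] = order
        out.attrs["monotone_decreasing"] = bool(np.all(np.diff(medians) < 0))
    return out
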