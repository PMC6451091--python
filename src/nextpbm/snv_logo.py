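"""Per-seed binding models from single-nucleotide-variant z-scores.

For one seed sequence of length L the array carries the seed plus all 3L
single-base variants, so binding z-scores fill a 4 x L matrix (the seed's
own base at each position takes the seed's z-score).  Centering each
column on its median gives the delta-z matrix, the quantity plotted as a
binding logo: positions where only one base supports binding show a large
positive delta-z for that base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probe_design import SeedSite, iter_snv_probes
from .sequences import DNA_BASES

BASES = list(DNA_BASES)


@dataclass
class SNVMatrix:
    """4 x L z-score matrix for one seed in one channel."""

    seed_id: str
    seed_sequence: str
    z: pd.DataFrame  # index ACGT, columns 0..L-1
    seed_z: float
    channel: str = ""
    missing: list[tuple[str, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.z.shape[1]

    @property
    def completeness(self) -> float:
        total = 3 * self.length
        return 1.0 - len(self.missing) / total


def build_snv_matrix(
    zscores: pd.DataFrame,
    seed: SeedSite,
    channel: str = "",
    max_missing_fraction: float = 0.10,
) -> SNVMatrix:
    """Populate the 4 x L matrix by looking up each variant's z-score.

    The seed sequence must be present; up to 10% of the 3L variants may be
    missing (dropped spots), beyond which the matrix is rejected.
    """
    lookup = dict(zip(zscores["unique_seq"], zscores["z"]))
    if seed.sequence not in lookup:
        raise ValueError(
            f"seed sequence for {seed.seed_id!r} absent from the z-score table"
        )
    seed_z = float(lookup[seed.sequence])
    L = seed.length
    mat = pd.DataFrame(np.nan, index=BASES, columns=range(L))
    missing: list[tuple[str, int]] = []
    for pos, base, variant in iter_snv_probes(seed):
        zval = lookup.get(variant)
        if zval is None or not np.isfinite(zval):
            missing.append((base, pos))
        else:
            mat.loc[base, pos] = float(zval)
    for pos, base in enumerate(seed.sequence):
        mat.loc[base, pos] = seed_z
    if len(missing) > max_missing_fraction * 3 * L:
        raise ValueError(
            f"seed {seed.seed_id!r}: {len(missing)}/{3 * L} SNVs missing "
            f"(> {max_missing_fraction:.0%}): {missing[:10]}"
        )
    if not channel and "channel" in zscores.columns and len(zscores):
        channel = str(zscores["channel"].iloc[0])
    return SNVMatrix(
        seed_id=seed.seed_id,
        seed_sequence=seed.sequence,
        z=mat,
        seed_z=seed_z,
        channel=channel,
        missing=missing,
    )


def delta_z(matrix: SNVMatrix) -> pd.DataFrame:
    """Column-median-centered z-scores: dz(b, i) = z(b, i) - median_b z(b, i).

    Columns with fewer than 4 finite values are centered over the values
    available and flagged with a warning.
    """
    z = matrix.z
    incomplete = [int(c) for c in z.columns if z[c].notna().sum() < 4]
    if incomplete:
        warnings.warn(
            f"seed {matrix.seed_id!r}: columns {incomplete} have < 4 finite "
            f"values; medians taken over available values"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(z.to_numpy(float), axis=0)
    return z - medians


def logo_matrix(delta: pd.DataFrame, mode: str = "positive-clip") -> pd.DataFrame:
    """Convert a delta-z matrix into non-negative letter heights.

    ``positive-clip`` (default): negative delta-z are clipped to 0 and each
    column is rescaled so its heights sum to the column's maximum delta-z
    (an all-non-positive column stays blank).  ``probability``: per-column
    softmax of delta-z at temperature 1.  Both transforms are monotone, so
    the dominant base per column is identical.
    """
    vals = delta.to_numpy(float)
    if mode == "positive-clip":
        clipped = np.clip(vals, 0.0, None)
        colsum = clipped.sum(axis=0)
        colmax = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=0)
        heights = np.zeros_like(clipped)
        ok = (colsum > 0) & (colmax > 0)
        heights[:, ok] = clipped[:, ok] * (colmax[ok] / colsum[ok])
    elif mode == "probability":
        safe = np.where(np.isnan(vals), -np.inf, vals)
        ex = np.exp(safe - np.nanmax(safe, axis=0))
        heights = ex / ex.sum(axis=0)
    else:
        raise ValueError(f"unknown logo mode {mode!r}")
    return pd.DataFrame(heights, index=delta.index, columns=delta.columns)


def seed_quality_filter(seed_z: float, threshold: float = 2.0) -> bool:
    """Gate on seed binding strength: binding models are only trusted when
    the unmutated seed probe itself scores at least *threshold* (default
    z >= 2.0) over background."""
    if not np.isfinite(seed_z):
        raise ValueError(f"seed_z must be finite, got {seed_z}")
    return bool(seed_z >= threshold)


def write_delta_z(delta: pd.DataFrame, path) -> None:
    delta.to_csv(path, sep="\t", index_label="base")


def plot_logo(heights: pd.DataFrame, ax=None, title: str = ""):
    """Best-effort logo rendering (stacked per-base bars); requires the
    optional matplotlib dependency."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * heights.shape[1] + 1, 2.2))
    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    x = np.arange(heights.shape[1])
    for col in x:
        bottom = 0.0
        order = heights.iloc[:, col].sort_values()
        for base, h in order.items():
            if h <= 0:
                continue
            ax.bar(col, h, bottom=bottom, color=colors[base], width=0.85)
            ax.text(col, bottom + h / 2, base, ha="center", va="center",
                    fontsize=8, color="white", fontweight="bold")
            bottom += h
    ax.set_xticks(x)
    ax.set_xlabel("position")
    ax.set_ylabel("height")
    if title:
        ax.set_title(title)
    return ax
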