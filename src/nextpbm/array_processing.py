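"""From spot intensities to sequence-level binding z-scores.

The processing chain is: read probe-level fluorescence tables keyed by
probe ID, normalize arrays onto a common scale, take the median
log-intensity over the (default 10) replicate spots of each unique
sequence, and standardize against the random-background probe
distribution, so that a z-score of 0 means "binds like background" and the
background set has unit variance by construction.

All intensity work is done on natural-log intensities; z-scores are
base-invariant so the choice is purely a declared convention.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .probe_design import DesignManifest

DEFAULT_COLUMN_MAP = {"probe_id": "probe_id", "intensity": "intensity", "flag": "flag"}

#: column map for GenePix-Pro-style exports (GPR dialect)
GPR_COLUMN_MAP = {"probe_id": "Name", "intensity": "F635 Median", "flag": "Flags"}

#: manifest columns carried through to intensity rows
_MANIFEST_CARRY = [
    "probe_id",
    "seed_id",
    "category",
    "variant_position",
    "variant_base",
    "orientation",
    "variable_region",
    "unique_seq",
]


def _normalize_flags(flags: pd.Series) -> pd.Series:
    """Map GenePix-style numeric flags (< 0 = bad) or ok/bad strings to
    the canonical ok/bad vocabulary."""
    if flags.dtype.kind in "if":
        return pd.Series(np.where(flags < 0, "bad", "ok"), index=flags.index)
    return flags.astype(str).str.lower().map(lambda s: "bad" if s == "bad" else "ok")


def read_intensity_table(
    path,
    manifest: DesignManifest,
    column_map: Mapping[str, str] | None = None,
    array_id: str = "array1",
    channel: str = "channel1",
    skiprows: int = 0,
) -> pd.DataFrame:
    """Read a tab-delimited probe-level intensity table and join it to the
    design manifest.

    Unmatched probe IDs are dropped with a warning; rows with non-positive
    intensity are flagged bad and excluded downstream.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep="\t", skiprows=skiprows)
    missing = [v for v in (cmap["probe_id"], cmap["intensity"]) if v not in raw.columns]
    if missing:
        raise ValueError(
            f"intensity table {path} missing required columns {missing}; "
            f"found {list(raw.columns)}"
        )
    df = pd.DataFrame(
        {
            "probe_id": raw[cmap["probe_id"]],
            "intensity": pd.to_numeric(raw[cmap["intensity"]], errors="coerce"),
        }
    )
    flag_col = cmap.get("flag")
    if flag_col and flag_col in raw.columns:
        df["flag"] = _normalize_flags(raw[flag_col])
    else:
        df["flag"] = "ok"
    return attach_manifest(df, manifest, array_id=array_id, channel=channel)


def attach_manifest(
    df: pd.DataFrame,
    manifest: DesignManifest,
    array_id: str = "array1",
    channel: str = "channel1",
) -> pd.DataFrame:
    """Join intensity rows onto manifest records; drop unknown probe IDs."""
    mdf = manifest.to_dataframe()[_MANIFEST_CARRY]
    joined = df.merge(mdf, on="probe_id", how="inner", validate="many_to_one")
    n_dropped = len(df) - len(joined)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} intensity rows had probe_ids absent from the "
            f"manifest and were dropped"
        )
    if joined.empty:
        raise ValueError("no intensity rows matched the design manifest")
    joined = joined.copy()
    bad_value = ~(joined["intensity"] > 0) | ~np.isfinite(joined["intensity"])
    joined.loc[bad_value, "flag"] = "bad"
    joined["array_id"] = array_id
    joined["channel"] = channel
    return joined


def normalize_arrays(
    tables: Sequence[pd.DataFrame],
    min_shared: int = 100,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> list[pd.DataFrame]:
    """Bring arrays onto a common scale via regression against the
    across-array median log-intensity profile.

    Each array's log-intensities are regressed (OLS, degree 1) onto the
    per-probe median profile over all arrays, then affinely rescaled so
    that slope = 1 and intercept = 0 against the reference; residuals (the
    biology) are preserved.  Reference and rescaling are iterated to a
    fixed point, so re-applying the function changes nothing beyond *tol*.
    A single array is returned unchanged apart from gaining the
    ``log_intensity`` column.

    The total affine transform applied to array *i* is recorded in
    ``result[i].attrs["norm_slope"]`` / ``attrs["norm_intercept"]``
    (log_norm = (log_raw - intercept) / slope).
    """
    if not tables:
        raise ValueError("normalize_arrays requires at least one table")
    out = []
    for t in tables:
        t = t.copy()
        vals = t["intensity"].to_numpy(float)
        ok = ((t["flag"] == "ok") & (vals > 0) & np.isfinite(vals)).to_numpy()
        log_vals = np.full(len(t), np.nan)
        log_vals[ok] = np.log(vals[ok])
        t["log_intensity"] = log_vals
        t.attrs["norm_slope"] = 1.0
        t.attrs["norm_intercept"] = 0.0
        out.append(t)
    if len(out) == 1:
        return out

    for iteration in range(max_iter):
        profiles = [
            t.dropna(subset=["log_intensity"])
            .groupby("probe_id")["log_intensity"]
            .median()
            for t in out
        ]
        ref = pd.concat(profiles, axis=1).median(axis=1)
        max_change = 0.0
        for i, t in enumerate(out):
            per_probe = profiles[i]
            shared = per_probe.index.intersection(ref.index)
            if len(shared) < min_shared:
                raise ValueError(
                    f"array {i} shares only {len(shared)} probes with the "
                    f"reference profile (need >= {min_shared})"
                )
            x = ref.loc[shared].to_numpy()
            y = per_probe.loc[shared].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            if abs(slope) < 1e-12:
                raise ValueError(f"array {i}: degenerate regression slope ~ 0")
            new = (t["log_intensity"] - intercept) / slope
            change = np.nanmax(np.abs(new - t["log_intensity"]), initial=0.0)
            max_change = max(max_change, change)
            t["log_intensity"] = new
            # compose: total transform stays (raw - B) / A
            t.attrs["norm_slope"] = t.attrs["norm_slope"] * slope
            t.attrs["norm_intercept"] = (
                t.attrs["norm_intercept"] + intercept * t.attrs["norm_slope"] / slope
            )
        if max_change < tol:
            break
    else:
        warnings.warn(
            f"array normalization did not converge below {tol} in "
            f"{max_iter} iterations (last change {max_change:.3g})"
        )
    return out


def aggregate_replicates(
    table: pd.DataFrame, min_spots: int = 1
) -> pd.DataFrame:
    """Collapse spots to one row per unique (orientation-collapsed)
    sequence: the median log-intensity over all unflagged spots of both
    orientations, with the number of spots used recorded."""
    if "log_intensity" not in table.columns:
        raise ValueError("table must be normalized first (no log_intensity column)")
    usable = table[(table["flag"] == "ok") & np.isfinite(table["log_intensity"])]
    n_dropped_seqs = table["unique_seq"].nunique() - usable["unique_seq"].nunique()
    if n_dropped_seqs:
        warnings.warn(
            f"{n_dropped_seqs} unique sequences had no usable spots and were dropped"
        )
    if usable.empty:
        raise ValueError("no usable spots after flag filtering")
    agg = (
        usable.groupby("unique_seq", sort=False)
        .agg(
            log_agg=("log_intensity", "median"),
            n_spots_used=("log_intensity", "size"),
            seed_id=("seed_id", "first"),
            category=("category", "first"),
            variant_position=("variant_position", "first"),
            variant_base=("variant_base", "first"),
            channel=("channel", "first"),
        )
        .reset_index()
    )
    return agg[agg["n_spots_used"] >= min_spots].reset_index(drop=True)


def compute_zscores(
    aggregates: pd.DataFrame,
    background_mask: pd.Series | None = None,
    min_background: int = 20,
) -> pd.DataFrame:
    """Standardize aggregated log-intensities against the background set.

    z = (log_agg - mean(background)) / sd(background), with the sample
    standard deviation (n-1); the transform is applied to every sequence
    including the backgrounds themselves, so the background set has mean 0
    and sd 1 exactly by construction.
    """
    if background_mask is None:
        background_mask = aggregates["category"] == "background"
    bg = aggregates.loc[background_mask, "log_agg"].to_numpy(float)
    if len(bg) < min_background:
        raise ValueError(
            f"need >= {min_background} background sequences to reference "
            f"z-scores, found {len(bg)}"
        )
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValueError("background standard deviation is zero; degenerate input")
    out = aggregates.copy()
    out["z"] = (out["log_agg"] - bg.mean()) / sd
    return out


def process_experiment(
    manifest: DesignManifest,
    tables: Sequence[pd.DataFrame],
    min_shared: int = 100,
) -> pd.DataFrame:
    """Convenience chain: normalize -> pool arrays -> aggregate -> z-scores."""
    normed = normalize_arrays(tables, min_shared=min_shared)
    pooled = pd.concat(normed, ignore_index=True)
    return compute_zscores(aggregate_replicates(pooled))


def replicate_agreement(
    table_a: pd.DataFrame, table_b: pd.DataFrame, min_shared: int = 10
) -> tuple[dict, pd.DataFrame]:
    """Agreement between two z-score tables over their shared sequences.

    Returns overall and per-category Pearson r plus the joined table.
    """
    joined = table_a.merge(
        table_b[["unique_seq", "z"]], on="unique_seq", suffixes=("_a", "_b")
    )
    if len(joined) < min_shared:
        raise ValueError(
            f"only {len(joined)} shared sequences between replicates "
            f"(need >= {min_shared})"
        )
    r_all = stats.pearsonr(joined["z_a"], joined["z_b"]).statistic
    per_category = {}
    for cat, sub in joined.groupby("category"):
        if len(sub) >= 3 and sub["z_a"].std() > 0 and sub["z_b"].std() > 0:
            per_category[cat] = stats.pearsonr(sub["z_a"], sub["z_b"]).statistic
    return {"pearson_r": float(r_all), "per_category": per_category}, joined


def write_zscore_table(zs: pd.DataFrame, path) -> None:
    cols = [
        "unique_seq", "seed_id", "category", "variant_position",
        "variant_base", "n_spots_used", "log_agg", "z", "channel",
    ]
    zs[[c for c in cols if c in zs.columns]].to_csv(path, sep="\t", index=False)


def read_zscore_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_base": "string"})
    if "z" not in df.columns or "unique_seq" not in df.columns:
        raise ValueError(f"{path} is not a z-score table (need unique_seq and z)")
    return df
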