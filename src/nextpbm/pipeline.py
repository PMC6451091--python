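"""Cooperative-binding discovery workflow.

Ties the modules into the end-to-end chain: z-score both channels,
fit the autonomous reference on canonical probes, score every candidate
probe's deviation, rank candidates above an empirical null cutoff, and
(optionally) build SNV logos for top candidates when their SNV series is
on the array.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import array_processing as ap
from .cooperativity import compare_conditions, score_from_zscore_tables
from .probe_design import DesignManifest, SeedSite
from .snv_logo import build_snv_matrix, delta_z, seed_quality_filter, write_delta_z

logger = logging.getLogger("nextpbm")


@dataclass
class RunConfig:
    """Configuration for one discovery run."""

    manifest: DesignManifest
    ivt_tables: list[pd.DataFrame]
    extract_tables: list[pd.DataFrame]
    out_dir: Path | None = None
    seed_z_threshold: float = 2.0
    candidate_null_quantile: float = 0.99
    canonical_categories: tuple[str, ...] = ("seed",)
    composite_categories: tuple[str, ...] = ("synthetic_composite",)
    build_logos_for_top: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.candidate_null_quantile < 1):
            raise ValueError("candidate_null_quantile must be in (0, 1)")


def run_discovery_workflow(config: RunConfig) -> dict:
    """Execute z-score -> cooperativity -> candidate ranking (-> logos).

    Returns a machine-readable report; tables are written under
    ``config.out_dir`` when given.  Any stage failure aborts with the
    stage named in the exception.
    """
    report: dict = {"stages": {}}

    def stage(name, fn):
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: done", name)
        return result

    zs_ivt = stage("zscore_ivt",
                   lambda: ap.process_experiment(config.manifest, config.ivt_tables))
    zs_extract = stage(
        "zscore_extract",
        lambda: ap.process_experiment(config.manifest, config.extract_tables),
    )
    report["stages"]["zscore"] = {
        "n_ivt_sequences": int(len(zs_ivt)),
        "n_extract_sequences": int(len(zs_extract)),
    }

    def coop():
        return score_from_zscore_tables(
            zs_ivt,
            zs_extract,
            canonical_categories=config.canonical_categories,
            composite_categories=config.composite_categories,
        )

    fit, result, table = stage("cooperativity", coop)
    cutoff = float(np.quantile(fit.null_scores, config.candidate_null_quantile))
    # enhanced binding only: positive deviation from the autonomous curve
    candidates = (
        table[(table["score"] > cutoff) & (table["eps2"] > 0)]
        .sort_values("score", ascending=False)
        .reset_index(drop=True)
    )
    report["stages"]["cooperativity"] = {
        "n_canonical": int(fit.n_canonical),
        "n_scored": int(len(table)),
        "beta": [float(b) for b in fit.beta],
        "var_eps1": float(fit.var_eps1),
        "candidate_cutoff": cutoff,
        "n_candidates": int(len(candidates)),
    }

    logos_written = []
    if config.build_logos_for_top:
        snv_seeds = {
            r.seed_id
            for r in config.manifest.records
            if r.category == "snv"
        }
        for _, row in candidates.head(config.build_logos_for_top).iterrows():
            sid = row["seed_id"]
            if sid not in snv_seeds:
                continue
            seed = SeedSite(sid, row["unique_seq"], category_label="composite")
            for name, zs in (("extract", zs_extract), ("ivt", zs_ivt)):
                try:
                    mat = build_snv_matrix(zs, seed)
                except ValueError:
                    continue
                if not seed_quality_filter(mat.seed_z, config.seed_z_threshold):
                    continue
                dz = delta_z(mat)
                if config.out_dir is not None:
                    path = Path(config.out_dir) / f"logo_{sid}_{name}.tsv"
                    write_delta_z(dz, path)
                    logos_written.append(str(path))
    report["stages"]["logos"] = {"written": logos_written}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ap.write_zscore_table(zs_ivt, out / "zscores_ivt.tsv")
        ap.write_zscore_table(zs_extract, out / "zscores_extract.tsv")
        table.to_csv(out / "cooperativity.tsv", sep="\t", index=False)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)

    report["candidates"] = candidates
    report["zscores"] = {"ivt": zs_ivt, "extract": zs_extract}
    report["fit"] = fit
    return report
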