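"""Ground-truth-annotated synthetic nextPBM experiments.

The generator emulates a two-channel experiment over a designed probe
manifest: an IVT channel (cofactor-free reference) and a nuclear-extract
channel in which intact composite elements receive a cooperative boost.
Per-spot log-intensity follows

    log I = offset + gain * (E(seq) + c * boost(seq) * [extract]) + N(0, sd)

where the autonomous energy E is the best PWM log-odds over both strands
(clipped at 0, plus a small per-sequence flank jitter), boost is the
planted cooperative term Delta for composite-lineage sequences whose
ETS-IRF architecture (GGAA-N2-GAAA(C/G), either strand) is intact, and c
is the extract concentration factor.  Default set sizes match the study
conditions this emulates: 2499 canonical sites, 116 composites, 500
backgrounds, boost 3 z-units, spot noise sd 0.5.

Everything is a pure function of (config, rng_seed): identical configs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .motif_scan import PWM, max_scores_many
from .probe_design import (
    DesignManifest,
    SeedSite,
    expand_replicates,
    has_intact_eice,
    iter_snv_probes,
    make_background_probes,
    make_synthetic_composite,
)
from .sequences import DNA_BASES, random_dna


def default_ets_pwm() -> PWM:
    """Planted ETS-type energy model: a 6-bp GGAAGT-consensus PWM with a
    near-invariant GGAA core and weaker 3' extension."""
    core = [0.97, 0.01, 0.01, 0.01]
    ext = [0.70, 0.10, 0.10, 0.10]

    def col(consensus_base, weights):
        c = np.full(4, 0.0)
        others = [b for b in DNA_BASES if b != consensus_base]
        c[DNA_BASES.index(consensus_base)] = weights[0]
        for b, wgt in zip(others, weights[1:]):
            c[DNA_BASES.index(b)] = wgt
        return c

    probs = np.column_stack(
        [col(b, core) for b in "GGAA"] + [col(b, ext) for b in "GT"]
    )
    return PWM(probs, name="ets_core", pseudocount=1e-3)


#: positions of the near-invariant consensus core within the default PWM
ETS_CORE_POSITIONS = (0, 1, 2, 3)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-channel experiment."""

    rng_seed: int = 0
    n_canonical: int = 2499
    n_composite: int = 116
    n_background: int = 500
    probe_length: int = 20
    ets_embed_offset: int = 4
    boost: float = 3.0  # cooperative term Delta at concentration 1
    concentration: float = 1.0  # extract concentration factor c in (0, 1]
    noise_sd: float = 0.5  # per-spot Gaussian noise, log-intensity units
    gain: float = 1.0  # energy -> log-intensity scale
    offset: float = 8.0  # baseline log-intensity
    flank_jitter_sd: float = 0.1  # per-sequence autonomous-energy jitter
    flag_rate: float = 0.01  # fraction of spots flagged bad
    n_rep: int = 5
    irf_consensus: str = "GAAAC"

    def __post_init__(self) -> None:
        if min(self.n_canonical, self.n_composite, self.n_background) < 0:
            raise ValueError("set sizes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 < self.concentration <= 1):
            raise ValueError("concentration must be in (0, 1]")
        if not (0 <= self.flag_rate < 1):
            raise ValueError("flag_rate must be in [0, 1)")


@dataclass
class SimulatedExperiment:
    """Bundle of one simulated experiment with its ground truth."""

    manifest: DesignManifest
    ivt: pd.DataFrame
    extract: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    pwm: PWM = field(default_factory=default_ets_pwm)


def _embed(core: str, length: int, offset: int, rng: np.random.Generator) -> str:
    flank = random_dna(1, length, rng)[0]
    return flank[:offset] + core + flank[offset + len(core) :]


def _sample_pwm_sites(pwm: PWM, n: int, rng: np.random.Generator) -> list[str]:
    """Draw *n* sites from the PWM's per-column base distributions."""
    u = rng.random((n, pwm.width))
    cum = np.cumsum(pwm.probs, axis=0)  # (4, w)
    codes = (u[None, :, :] > cum[:, None, :]).sum(axis=0)
    lut = np.array(list(DNA_BASES))
    return ["".join(row) for row in lut[codes]]


def _build_seeds(
    config: SimulationConfig, pwm: PWM, rng: np.random.Generator
) -> list[tuple[SeedSite, str]]:
    """Return (seed, manifest category) pairs for all unique sites."""
    out: list[tuple[SeedSite, str]] = []
    seen: set[str] = set()
    off = config.ets_embed_offset

    def fresh(make_seq, label):
        # sampled sites can collide (near-deterministic cores share most
        # bases); unique sequences are a design invariant, so re-draw
        for _ in range(1000):
            seq = make_seq()
            if seq not in seen:
                seen.add(seq)
                return seq
        raise RuntimeError(f"could not draw a unique {label} sequence")

    if config.n_canonical:
        for i in range(config.n_canonical):
            def make_canonical():
                core = _sample_pwm_sites(pwm, 1, rng)[0]
                flank = random_dna(1, config.probe_length, rng)[0]
                return flank[:off] + core + flank[off + len(core):]

            seq = fresh(make_canonical, "canonical")
            out.append(
                (SeedSite(f"can{i:05d}", seq, category_label="canonical"), "seed")
            )
    for i in range(config.n_composite):
        def make_composite():
            flank = random_dna(1, config.probe_length, rng)[0]
            weak_seq = flank[:off] + "GGAA" + flank[off + 4:]
            weak = SeedSite(f"weak{i:05d}", weak_seq, category_label="weak")
            return make_synthetic_composite(
                weak,
                irf_consensus=config.irf_consensus,
                ets_offset=config.ets_embed_offset,
            ).sequence

        seq = fresh(make_composite, "composite")
        comp = SeedSite(f"weak{i:05d}_eice", seq, category_label="composite")
        out.append((comp, "synthetic_composite"))
    if config.n_background:
        bg_seed = int(rng.integers(0, 2**31))
        for bg in make_background_probes(
            config.n_background, length=config.probe_length, rng_seed=bg_seed
        ):
            out.append((bg, "background"))
    return out


def _ground_truth(
    seqs: list[str],
    seed_ids: list[str],
    categories: list[str],
    config: SimulationConfig,
    pwm: PWM,
    rng: np.random.Generator,
) -> pd.DataFrame:
    energy = np.maximum(max_scores_many(seqs, pwm), 0.0)
    energy = energy + rng.normal(0.0, config.flank_jitter_sd, size=len(seqs))
    composite_lineage = {
        sid for sid, cat in zip(seed_ids, categories)
        if cat in ("synthetic_composite", "seed_composite")
    }
    boost = np.array(
        [
            config.boost
            if (sid in composite_lineage and has_intact_eice(seq))
            else 0.0
            for sid, seq in zip(seed_ids, seqs)
        ]
    )
    return pd.DataFrame(
        {
            "unique_seq": seqs,
            "seed_id": seed_ids,
            "category": categories,
            "energy": energy,
            "boost": boost,
        }
    )


def _intensity_table(
    manifest: DesignManifest,
    truth: pd.DataFrame,
    config: SimulationConfig,
    channel: str,
    array_id: str,
    extract_channel: bool,
    concentration: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    df = manifest.to_dataframe()[
        [
            "probe_id",
            "seed_id",
            "category",
            "variant_position",
            "variant_base",
            "orientation",
            "variable_region",
            "unique_seq",
        ]
    ]
    df = df.merge(truth[["unique_seq", "energy", "boost"]], on="unique_seq",
                  validate="many_to_one")
    mu = config.offset + config.gain * df["energy"].to_numpy()
    if extract_channel:
        mu = mu + config.gain * concentration * df["boost"].to_numpy()
    log_i = mu + rng.normal(0.0, config.noise_sd, size=len(df))
    df = df.drop(columns=["energy", "boost"])
    df["intensity"] = np.exp(log_i)
    df["flag"] = np.where(
        rng.random(len(df)) < config.flag_rate, "bad", "ok"
    )
    df["array_id"] = array_id
    df["channel"] = channel
    return df


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """One full two-channel experiment over a fresh design."""
    pwm = default_ets_pwm()
    root = np.random.SeedSequence(config.rng_seed)
    s_design, s_truth, s_ivt, s_extract = root.spawn(4)
    rng_design = np.random.default_rng(s_design)

    seeds = _build_seeds(config, pwm, rng_design)
    records = []
    for seed, category in seeds:
        records.extend(
            expand_replicates(
                seed.sequence, config.n_rep, seed_id=seed.seed_id,
                category=category,
            )
        )
    manifest = DesignManifest(records=records, params={"n_rep": config.n_rep})
    manifest.validate()

    seqs = [s.sequence for s, _ in seeds]
    truth = _ground_truth(
        seqs,
        [s.seed_id for s, _ in seeds],
        [c for _, c in seeds],
        config,
        pwm,
        np.random.default_rng(s_truth),
    )
    ivt = _intensity_table(
        manifest, truth, config, "TF_ivt", "ivt_1", False, 1.0,
        np.random.default_rng(s_ivt),
    )
    extract = _intensity_table(
        manifest, truth, config, "TF_extract", "extract_1", True,
        config.concentration, np.random.default_rng(s_extract),
    )
    return SimulatedExperiment(manifest, ivt, extract, truth, config, pwm)


def simulate_snv_series(
    config: SimulationConfig, seed_site: SeedSite | None = None
) -> SimulatedExperiment:
    """A seed plus its full SNV series (and backgrounds), both channels.

    By default the seed is a composite element, so SNVs hitting the ETS
    core lose autonomous binding in both channels, SNVs hitting the IRF
    half-site lose only the extract-channel boost, and flank SNVs perturb
    binding mildly.
    """
    pwm = default_ets_pwm()
    root = np.random.SeedSequence(config.rng_seed)
    s_design, s_truth, s_ivt, s_extract = root.spawn(4)
    rng_design = np.random.default_rng(s_design)

    if seed_site is None:
        weak_seq = _embed("GGAA", config.probe_length, config.ets_embed_offset,
                          rng_design)
        weak = SeedSite("snvseed", weak_seq, category_label="weak")
        seed_site = make_synthetic_composite(
            weak, irf_consensus=config.irf_consensus,
            ets_offset=config.ets_embed_offset,
        )
        seed_site = SeedSite(
            "snvseed", seed_site.sequence, category_label="composite"
        )

    lineage = (
        "seed_composite"
        if seed_site.category_label == "composite"
        else "seed"
    )
    records = list(
        expand_replicates(
            seed_site.sequence, config.n_rep, seed_id=seed_site.seed_id,
            category="seed",
        )
    )
    seqs = [seed_site.sequence]
    seed_ids = [seed_site.seed_id]
    categories = [lineage]
    for pos, base, variant in iter_snv_probes(seed_site):
        records.extend(
            expand_replicates(
                variant, config.n_rep, seed_id=seed_site.seed_id,
                category="snv", variant_position=pos, variant_base=base,
            )
        )
        seqs.append(variant)
        seed_ids.append(seed_site.seed_id)
        categories.append(lineage)
    if config.n_background:
        bg_seed = int(rng_design.integers(0, 2**31))
        for bg in make_background_probes(
            config.n_background, length=config.probe_length, rng_seed=bg_seed
        ):
            records.extend(
                expand_replicates(
                    bg.sequence, config.n_rep, seed_id=bg.seed_id,
                    category="background",
                )
            )
            seqs.append(bg.sequence)
            seed_ids.append(bg.seed_id)
            categories.append("background")

    manifest = DesignManifest(records=records, params={"n_rep": config.n_rep})
    manifest.validate()
    truth = _ground_truth(
        seqs, seed_ids, categories, config, pwm,
        np.random.default_rng(s_truth),
    )
    ivt = _intensity_table(
        manifest, truth, config, "TF_ivt", "ivt_1", False, 1.0,
        np.random.default_rng(s_ivt),
    )
    extract = _intensity_table(
        manifest, truth, config, "TF_extract", "extract_1", True,
        config.concentration, np.random.default_rng(s_extract),
    )
    return SimulatedExperiment(manifest, ivt, extract, truth, config, pwm)


@dataclass
class ConditionPanel:
    """Shared design scored under several extract conditions."""

    manifest: DesignManifest
    truth: pd.DataFrame
    ivt: pd.DataFrame
    extracts: dict[str, pd.DataFrame]
    config: SimulationConfig


def simulate_condition_panel(
    base_config: SimulationConfig,
    conditions: Mapping[str, tuple[float, float]],
) -> ConditionPanel:
    """One experiment per condition over shared sequences and energies.

    *conditions* maps name -> (concentration c, boost multiplier); e.g.
    a 2-fold dilution series is c in {1, .5, .25, .125} with multiplier 1,
    and cofactor knockout / immune-depletion is multiplier 0.  Only the
    cooperative term differs between conditions; each condition draws its
    own spot noise.
    """
    pwm = default_ets_pwm()
    root = np.random.SeedSequence(base_config.rng_seed)
    spawned = root.spawn(3 + len(conditions))
    s_design, s_truth, s_ivt = spawned[:3]
    rng_design = np.random.default_rng(s_design)

    seeds = _build_seeds(base_config, pwm, rng_design)
    records = []
    for seed, category in seeds:
        records.extend(
            expand_replicates(
                seed.sequence, base_config.n_rep, seed_id=seed.seed_id,
                category=category,
            )
        )
    manifest = DesignManifest(records=records, params={"n_rep": base_config.n_rep})
    manifest.validate()
    truth = _ground_truth(
        [s.sequence for s, _ in seeds],
        [s.seed_id for s, _ in seeds],
        [c for _, c in seeds],
        base_config,
        pwm,
        np.random.default_rng(s_truth),
    )
    ivt = _intensity_table(
        manifest, truth, base_config, "TF_ivt", "ivt_1", False, 1.0,
        np.random.default_rng(s_ivt),
    )
    extracts = {}
    for (name, (c, mult)), seed_seq in zip(conditions.items(), spawned[3:]):
        if not (0 < c <= 1):
            raise ValueError(f"condition {name!r}: concentration {c} not in (0, 1]")
        cond_truth = truth.copy()
        cond_truth["boost"] = truth["boost"] * mult
        extracts[name] = _intensity_table(
            manifest, cond_truth, base_config, f"TF_extract_{name}",
            f"extract_{name}", True, c, np.random.default_rng(seed_seq),
        )
    return ConditionPanel(manifest, truth, ivt, extracts, base_config)
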