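"""Probe library design for nextPBM arrays.

A design starts from *seed sites* -- short genomic or synthetic binding-site
sequences (default 20 bp) -- and compiles them into the full manifest of
array spots: the seed itself, its single-nucleotide-variant (SNV) series,
half-site ablations of composite elements, synthetic ETS-IRF composites
built from weak sites, and random background probes.  Every unique variable
region is expanded into replicate spots in both orientations (default
5 x 2 = 10 spots per unique site).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import DNA_BASES, contains_motif, random_dna, revcomp, validate_dna

SEED_LABELS = ("canonical", "composite", "weak", "background-derived")
PROBE_CATEGORIES = (
    "seed",
    "snv",
    "ablation_ets",
    "ablation_irf",
    "synthetic_composite",
    "background",
)
ORIENTATIONS = ("fwd", "rev")

#: core k-mers used for background exclusion and ablation verification:
#: the ETS core (GGAA) and the IRF core (GAAA), each with its reverse
#: complement so both strands are screened.
DEFAULT_EXCLUSION_MOTIFS = ("GGAA", "TTCC", "GAAA", "TTTC")

#: ETS-IRF composite element architecture: GGAA, 2-base linker, GAAA(C/G).
EICE_PATTERN = re.compile(r"GGAA..GAAA[CG]")

#: Placeholder 24-nt double-stranding primer region appended 3' of the
#: variable region.  The vendor primer is proprietary configuration; any
#: fixed sequence exercises the "constant scaffold" contract.
DEFAULT_PRIMER_3P = "GTCTGTGTTCCGTTGTCCGTGCTG"


@dataclass(frozen=True)
class Scaffold:
    """Constant sequence context surrounding the variable region."""

    five_prime: str = ""
    three_prime: str = DEFAULT_PRIMER_3P

    def embed(self, variable_region: str) -> str:
        return self.five_prime + variable_region + self.three_prime


DEFAULT_SCAFFOLD = Scaffold()


@dataclass(frozen=True)
class SeedSite:
    """A unique binding-site sequence anchoring probes on the array."""

    seed_id: str
    sequence: str
    category_label: str = "canonical"
    origin: tuple[str, int, int, str] | None = None  # (chrom, start, end, strand)

    def __post_init__(self) -> None:
        validate_dna(self.sequence, f"seed {self.seed_id!r}")
        if self.category_label not in SEED_LABELS:
            raise ValueError(
                f"unknown seed category label {self.category_label!r}; "
                f"expected one of {SEED_LABELS}"
            )
        if "|" in self.seed_id:
            raise ValueError("seed_id may not contain '|' (probe_id separator)")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProbeRecord:
    """One array spot: a replicate of a unique sequence in one orientation."""

    probe_id: str
    seed_id: str
    category: str
    variant_position: int | None
    variant_base: str | None
    orientation: str
    replicate_index: int
    variable_region: str
    full_sequence: str

    @property
    def unique_seq(self) -> str:
        """The orientation-collapsed (forward-frame) variable region."""
        if self.orientation == "rev":
            return revcomp(self.variable_region)
        return self.variable_region


def make_probe_id(
    seed_id: str,
    category: str,
    variant_position: int | None,
    variant_base: str | None,
    orientation: str,
    replicate_index: int,
) -> str:
    """Deterministic, sortable probe identifier.

    Grammar: ``<seed_id>|<category>|p<pos>|<base>|<orient>|r<rep>`` with
    ``.`` for null variant fields.
    """
    pos = "." if variant_position is None else str(variant_position)
    base = "." if variant_base is None else variant_base
    return f"{seed_id}|{category}|p{pos}|{base}|{orientation}|r{replicate_index}"


def make_snv_probes(seed: SeedSite) -> list[str]:
    """All single-nucleotide variants of a seed's variable region.

    Returns exactly ``3 * L`` sequences in deterministic order
    (position-major, variant base alphabetical); together with the seed
    they cover all four bases at every position.
    """
    seq = seed.sequence
    out: list[str] = []
    for pos, ref in enumerate(seq):
        for base in DNA_BASES:
            if base == ref:
                continue
            out.append(seq[:pos] + base + seq[pos + 1 :])
    return out


def iter_snv_probes(seed: SeedSite):
    """Yield ``(position, variant_base, sequence)`` in the same order as
    :func:`make_snv_probes`."""
    seq = seed.sequence
    for pos, ref in enumerate(seq):
        for base in DNA_BASES:
            if base == ref:
                continue
            yield pos, base, seq[:pos] + base + seq[pos + 1 :]


def expand_replicates(
    variable_region: str,
    n_rep: int = 5,
    *,
    seed_id: str,
    category: str = "seed",
    variant_position: int | None = None,
    variant_base: str | None = None,
    scaffold: Scaffold = DEFAULT_SCAFFOLD,
) -> list[ProbeRecord]:
    """Expand one unique sequence into ``n_rep`` replicate spots per
    orientation (so ``2 * n_rep`` records; reverse-orientation spots carry
    the exact reverse complement of the variable region)."""
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    validate_dna(variable_region, "variable_region")
    if category not in PROBE_CATEGORIES:
        raise ValueError(f"unknown probe category {category!r}")
    records = []
    for orientation in ORIENTATIONS:
        region = variable_region if orientation == "fwd" else revcomp(variable_region)
        for rep in range(1, n_rep + 1):
            records.append(
                ProbeRecord(
                    probe_id=make_probe_id(
                        seed_id, category, variant_position, variant_base,
                        orientation, rep,
                    ),
                    seed_id=seed_id,
                    category=category,
                    variant_position=variant_position,
                    variant_base=variant_base,
                    orientation=orientation,
                    replicate_index=rep,
                    variable_region=region,
                    full_sequence=scaffold.embed(region),
                )
            )
    return records


# --- half-site ablation -----------------------------------------------------

# Deterministic replacement policies, tried in order until the mutated
# sequence passes verification.  Each maps every base to a different base,
# so the replacement differs from the original at every position.
_REPLACEMENT_POLICIES = (
    str.maketrans("ACGT", "CATG"),  # transversions A<->C, G<->T
    str.maketrans("ACGT", "TGCA"),  # transversions A<->T, C<->G
    str.maketrans("ACGT", "GTAC"),  # transitions A<->G, C<->T
)


def _span_creates_core_match(
    seq: str, span: tuple[int, int], core_motifs: Sequence[str]
) -> bool:
    """Check whether any core motif (either strand) overlaps *span*."""
    for motif in core_motifs:
        for m in (motif, revcomp(motif)):
            w = len(m)
            lo = max(0, span[0] - w + 1)
            hi = min(len(seq), span[1] + w - 1)
            if m in seq[lo:hi]:
                return True
    return False


def make_ablation_probes(
    composite: SeedSite,
    ets_span: tuple[int, int],
    irf_span: tuple[int, int],
    core_motifs: Sequence[str] = ("GGAA", "GAAA"),
) -> tuple[SeedSite, SeedSite]:
    """Ablate the ETS and IRF half-sites of a composite element.

    Returns two seeds: one with the ETS core span replaced and one with the
    IRF core span replaced by a different k-mer.  The replacement (a)
    differs from the original at every position and (b) does not create a
    new match to either core consensus on either strand; a deterministic
    ladder of base-substitution policies is tried until (b) holds.
    """
    L = composite.length
    for name, (lo, hi) in (("ets_span", ets_span), ("irf_span", irf_span)):
        if not (0 <= lo < hi <= L):
            raise ValueError(f"{name} {lo, hi} outside [0, {L})")
    if ets_span[0] < irf_span[1] and irf_span[0] < ets_span[1]:
        raise ValueError(f"spans overlap: ets={ets_span} irf={irf_span}")

    def ablate(span: tuple[int, int], suffix: str) -> SeedSite:
        lo, hi = span
        for policy in _REPLACEMENT_POLICIES:
            kmer = composite.sequence[lo:hi].translate(policy)
            mutated = composite.sequence[:lo] + kmer + composite.sequence[hi:]
            if not _span_creates_core_match(mutated, span, core_motifs):
                return SeedSite(
                    seed_id=f"{composite.seed_id}_{suffix}",
                    sequence=mutated,
                    category_label="composite",
                    origin=composite.origin,
                )
        raise ValueError(
            f"no replacement policy ablates {composite.seed_id!r} span {span} "
            f"without creating a new core match"
        )

    return ablate(ets_span, "ablETS"), ablate(irf_span, "ablIRF")


# --- synthetic composite elements -------------------------------------------

def find_eice(sequence: str) -> tuple[int, str] | None:
    """Locate an intact composite (EICE) architecture GGAA-N2-GAAA(C/G).

    Returns ``(offset, strand)`` of the first match scanning the forward
    strand then the reverse strand, or ``None``.
    """
    m = EICE_PATTERN.search(sequence)
    if m:
        return m.start(), "+"
    m = EICE_PATTERN.search(revcomp(sequence))
    if m:
        return len(sequence) - m.end(), "-"
    return None


def has_intact_eice(sequence: str) -> bool:
    return find_eice(sequence) is not None


def make_synthetic_composite(
    weak_site: SeedSite,
    irf_consensus: str = "GAAAC",
    spacing: int = 2,
    ets_offset: int | None = None,
) -> SeedSite:
    """Convert a weak ETS site into a synthetic composite element.

    The IRF half-site consensus is written ``spacing`` bases downstream of
    the GGAA core (overwriting, not shifting, so probe length is
    preserved); linker bases come from the original weak site.  The weak
    site must contain a GGAA core; if the core is only present on the
    reverse strand the construction is done in that frame.
    """
    validate_dna(irf_consensus, "irf_consensus")
    seq = weak_site.sequence
    frame_rev = False
    if ets_offset is None:
        ets_offset = seq.find("GGAA")
        if ets_offset < 0:
            rc = revcomp(seq)
            ets_offset = rc.find("GGAA")
            if ets_offset < 0:
                raise ValueError(
                    f"weak site {weak_site.seed_id!r} contains no GGAA core "
                    f"on either strand"
                )
            seq, frame_rev = rc, True
    elif seq[ets_offset : ets_offset + 4] != "GGAA":
        raise ValueError(
            f"weak site {weak_site.seed_id!r} has no GGAA core at "
            f"offset {ets_offset}"
        )
    irf_start = ets_offset + 4 + spacing
    if irf_start + len(irf_consensus) > len(seq):
        raise ValueError(
            f"weak site {weak_site.seed_id!r}: ETS core at offset {ets_offset} "
            f"is too close to the 3' edge to fit the IRF half-site"
        )
    composite = (
        seq[:irf_start] + irf_consensus + seq[irf_start + len(irf_consensus) :]
    )
    if frame_rev:
        composite = revcomp(composite)
    return SeedSite(
        seed_id=f"{weak_site.seed_id}_eice",
        sequence=composite,
        category_label="composite",
        origin=weak_site.origin,
    )


def make_background_probes(
    n: int,
    length: int = 20,
    rng_seed: int = 0,
    exclusion_motifs: Sequence[str] = DEFAULT_EXCLUSION_MOTIFS,
    max_attempts_per_probe: int = 1000,
) -> list[SeedSite]:
    """Random uniform-composition background probes, free of the excluded
    core motifs on both strands; reproducible from *rng_seed*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out: list[SeedSite] = []
    attempts = 0
    budget = max_attempts_per_probe * n
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"background rejection sampling exceeded {budget} attempts "
                f"({len(out)}/{n} accepted); relax exclusion_motifs or length"
            )
        batch = random_dna(min(4 * n, budget - attempts), length, rng)
        attempts += len(batch)
        for seq in batch:
            if any(contains_motif(seq, m) for m in exclusion_motifs):
                continue
            out.append(
                SeedSite(
                    seed_id=f"bg{len(out):05d}",
                    sequence=seq,
                    category_label="background-derived",
                )
            )
            if len(out) == n:
                break
    return out


# --- manifest assembly ------------------------------------------------------

MANIFEST_COLUMNS = [
    "probe_id",
    "seed_id",
    "category",
    "variant_position",
    "variant_base",
    "orientation",
    "replicate",
    "variable_region",
    "full_sequence",
]


@dataclass
class DesignManifest:
    """Ordered collection of probe records plus the design parameters."""

    records: list[ProbeRecord]
    params: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return len(self.records)

    @property
    def unique_sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.unique_seq)
        return list(seen)

    def validate(self) -> None:
        ids = [r.probe_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            raise ValueError(
                f"duplicate probe_ids in manifest: {dupes[dupes > 1].index.tolist()[:5]}"
            )
        n_rep = self.params.get("n_rep")
        if n_rep is not None and self.records:
            expected = len(self.unique_sequences) * n_rep * 2
            if self.n_spots != expected:
                raise ValueError(
                    f"spot accounting broken: {self.n_spots} spots != "
                    f"{len(self.unique_sequences)} unique x {n_rep} reps x 2 "
                    f"orientations = {expected}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "probe_id": [r.probe_id for r in self.records],
                "seed_id": [r.seed_id for r in self.records],
                "category": [r.category for r in self.records],
                "variant_position": [r.variant_position for r in self.records],
                "variant_base": [r.variant_base for r in self.records],
                "orientation": [r.orientation for r in self.records],
                "replicate": [r.replicate_index for r in self.records],
                "variable_region": [r.variable_region for r in self.records],
                "full_sequence": [r.full_sequence for r in self.records],
            }
        )
        df["unique_seq"] = [r.unique_seq for r in self.records]
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe()[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)

    def write_fasta(self, path) -> None:
        from .io import write_probe_fasta

        write_probe_fasta(self.records, path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, params: dict | None = None
                       ) -> "DesignManifest":
        records = []
        for row in df.itertuples(index=False):
            vp = row.variant_position
            vp = None if pd.isna(vp) else int(vp)
            vb = row.variant_base
            vb = None if (vb is None or (isinstance(vb, float) and np.isnan(vb))) else str(vb)
            records.append(
                ProbeRecord(
                    probe_id=row.probe_id,
                    seed_id=row.seed_id,
                    category=row.category,
                    variant_position=vp,
                    variant_base=vb,
                    orientation=row.orientation,
                    replicate_index=int(row.replicate),
                    variable_region=row.variable_region,
                    full_sequence=row.full_sequence,
                )
            )
        return cls(records=records, params=params or {})

    @classmethod
    def read_tsv(cls, path) -> "DesignManifest":
        df = pd.read_csv(path, sep="\t", dtype={"variant_base": "string"})
        manifest = cls.from_dataframe(df)
        reps = {r.replicate_index for r in manifest.records}
        if reps:
            manifest.params["n_rep"] = max(reps)
        return manifest


def assemble_design(
    seeds: Iterable[SeedSite],
    *,
    snv_seed_ids: Sequence[str] = (),
    ablation_seed_ids: Sequence[str] = (),
    composite_seed_ids: Sequence[str] = (),
    n_background: int = 0,
    n_rep: int = 5,
    rng_seed: int = 0,
    scaffold: Scaffold = DEFAULT_SCAFFOLD,
    exclusion_motifs: Sequence[str] = DEFAULT_EXCLUSION_MOTIFS,
    irf_consensus: str = "GAAAC",
    max_spots: int | None = 60000,
) -> DesignManifest:
    """Compile seeds into a full probe manifest.

    Per options this adds, for each seed: the seed probe; its full SNV
    series (``snv_seed_ids``); ETS/IRF half-site ablations of composites
    whose EICE architecture is auto-located (``ablation_seed_ids``);
    a synthetic composite built from a weak site (``composite_seed_ids``);
    plus ``n_background`` random background probes.  Everything is expanded
    into ``n_rep`` replicates per orientation.
    """
    seeds = list(seeds)
    ids = [s.seed_id for s in seeds]
    if len(set(ids)) != len(ids):
        raise ValueError("seed IDs must be unique within a design")
    by_id = {s.seed_id: s for s in seeds}
    for name, wanted in (
        ("snv_seed_ids", snv_seed_ids),
        ("ablation_seed_ids", ablation_seed_ids),
        ("composite_seed_ids", composite_seed_ids),
    ):
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise ValueError(f"{name} not present among seeds: {missing}")

    records: list[ProbeRecord] = []

    def add(variable_region, category, seed_id, pos=None, base=None):
        records.extend(
            expand_replicates(
                variable_region,
                n_rep,
                seed_id=seed_id,
                category=category,
                variant_position=pos,
                variant_base=base,
                scaffold=scaffold,
            )
        )

    for seed in seeds:
        add(seed.sequence, "seed", seed.seed_id)
        if seed.seed_id in snv_seed_ids:
            for pos, base, variant in iter_snv_probes(seed):
                add(variant, "snv", seed.seed_id, pos, base)
        if seed.seed_id in ablation_seed_ids:
            hit = find_eice(seed.sequence)
            if hit is None:
                raise ValueError(
                    f"seed {seed.seed_id!r} flagged for ablation has no "
                    f"intact composite architecture"
                )
            offset, strand = hit
            seq = seed.sequence if strand == "+" else revcomp(seed.sequence)
            if strand == "-":
                offset = len(seq) - offset - 11
            framed = replace(seed, sequence=seq)
            abl_ets, abl_irf = make_ablation_probes(
                framed, (offset, offset + 4), (offset + 6, offset + 11)
            )
            ets_seq = abl_ets.sequence if strand == "+" else revcomp(abl_ets.sequence)
            irf_seq = abl_irf.sequence if strand == "+" else revcomp(abl_irf.sequence)
            add(ets_seq, "ablation_ets", seed.seed_id)
            add(irf_seq, "ablation_irf", seed.seed_id)
        if seed.seed_id in composite_seed_ids:
            comp = make_synthetic_composite(seed, irf_consensus=irf_consensus)
            add(comp.sequence, "synthetic_composite", seed.seed_id)

    if n_background:
        for bg in make_background_probes(
            n_background,
            length=seeds[0].length if seeds else 20,
            rng_seed=rng_seed,
            exclusion_motifs=exclusion_motifs,
        ):
            add(bg.sequence, "background", bg.seed_id)

    manifest = DesignManifest(
        records=records,
        params={
            "n_rep": n_rep,
            "rng_seed": rng_seed,
            "scaffold_5p": scaffold.five_prime,
            "scaffold_3p": scaffold.three_prime,
        },
    )
    manifest.validate()
    if max_spots is not None and manifest.n_spots > max_spots:
        raise ValueError(
            f"design exceeds array capacity: {manifest.n_spots} spots "
            f"({len(manifest.unique_sequences)} unique x {n_rep} reps x 2 "
            f"orientations) > {max_spots}"
        )
    return manifest
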