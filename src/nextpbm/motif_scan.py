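"""PWM log-odds scanning used for binding-site selection.

Scores follow the HOMER convention: natural-log odds of a window against a
uniform 0.25 background, summed over positions,

    score(w) = sum_i ln(p_i(base_i) / 0.25),

evaluated on both strands; a region is summarized by its maximum-scoring
window.  Significance thresholds are calibrated empirically as a high
quantile of max-scores over random uniform sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .sequences import DNA_BASES, encode, encode_many, revcomp

BACKGROUND_P = 0.25


@dataclass(frozen=True)
class ScanHit:
    """Best-scoring PWM window within one region."""

    seq_id: str | None
    offset: int  # 0-based, on the forward strand
    strand: str  # "+" or "-"
    score: float
    passes_threshold: bool | None = None


class PWM:
    """Position probability matrix with uniform-background log-odds scoring.

    *probs* is 4 x w (rows A, C, G, T); a pseudocount is added and columns
    renormalized at construction so zero-probability bases stay scoreable.
    """

    def __init__(self, probs, name: str = "pwm", pseudocount: float = 1e-3):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"PWM probs must be 4 x w, got shape {probs.shape}")
        if (probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM columns must sum to 1; sums are {colsums}")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        adjusted = probs + pseudocount
        adjusted = adjusted / adjusted.sum(axis=0)
        self.name = name
        self.pseudocount = float(pseudocount)
        self.probs = adjusted
        # with pseudocount 0 a zero-probability base scores -inf, i.e. the
        # window can never be the maximum unless every window contains one
        with np.errstate(divide="ignore"):
            self.log_odds_matrix = np.log(adjusted / BACKGROUND_P)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA_BASES[i] for i in self.probs.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds_matrix.max(axis=0).sum())

    def to_file(self, path) -> None:
        df = pd.DataFrame(
            self.probs, index=list(DNA_BASES), columns=range(1, self.width + 1)
        )
        df.to_csv(path, sep="\t", index_label="base")

    @classmethod
    def from_file(cls, path, name: str | None = None,
                  pseudocount: float = 1e-3) -> "PWM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            probs = df.loc[list(DNA_BASES)].to_numpy(float)
        except KeyError as exc:
            raise ValueError(
                f"PWM file {path} must have rows labelled A, C, G, T"
            ) from exc
        import os

        return cls(
            probs,
            name=name or os.path.splitext(os.path.basename(str(path)))[0],
            pseudocount=pseudocount,
        )


def log_odds(window: str, pwm: PWM) -> float:
    """Log-odds score of a single window (length must equal PWM width).

    Windows containing ambiguity codes are unscoreable and raise; scanners
    skip them.
    """
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    codes = encode(window)
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"ambiguous base {window[pos]!r} at position {pos}")
    return float(pwm.log_odds_matrix[codes, np.arange(pwm.width)].sum())


def _window_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Scores for every window along a 1-D code array; NaN where the
    window contains an ambiguous base."""
    w = pwm.width
    if len(codes) < w:
        raise ValueError(f"sequence length {len(codes)} < PWM width {w}")
    wins = sliding_window_view(codes, w)
    valid = (wins >= 0).all(axis=1)
    scores = np.full(len(wins), np.nan)
    if valid.any():
        scores[valid] = pwm.log_odds_matrix[
            wins[valid], np.arange(w)
        ].sum(axis=1)
    return scores


def scan_scores(sequence: str, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset scores on the forward and reverse strand.

    Both arrays are indexed by forward-strand offset: the reverse-strand
    score at offset i is the score of the reverse complement of
    ``sequence[i:i+w]``.
    """
    codes = encode(sequence)
    fwd = _window_scores(codes, pwm)
    # complement then reverse; ambiguous codes (-1) would map to 4, keep -1
    rc_codes = (3 - codes[::-1]).astype(np.int8)
    rc_codes[codes[::-1] < 0] = -1
    rev = _window_scores(rc_codes, pwm)[::-1]
    return fwd, rev


def max_scan(sequence: str, pwm: PWM, seq_id: str | None = None) -> ScanHit:
    """Maximum log-odds hit over all windows on both strands.

    Ties break to the smallest forward-strand offset, then to the forward
    strand.
    """
    fwd, rev = scan_scores(sequence, pwm)
    interleaved = np.empty(2 * len(fwd))
    interleaved[0::2] = np.where(np.isnan(fwd), -np.inf, fwd)
    interleaved[1::2] = np.where(np.isnan(rev), -np.inf, rev)
    if not np.isfinite(interleaved).any():
        raise ValueError("no scoreable window (all windows ambiguous)")
    k = int(np.argmax(interleaved))  # first maximum: offset-major, fwd first
    return ScanHit(
        seq_id=seq_id,
        offset=k // 2,
        strand="+" if k % 2 == 0 else "-",
        score=float(interleaved[k]),
    )


def max_scores_many(sequences: Sequence[str], pwm: PWM,
                    chunk: int = 2000) -> np.ndarray:
    """Vectorized max log-odds (both strands) for equal-length ACGT
    sequences; the workhorse behind threshold calibration and simulation."""
    if not sequences:
        return np.empty(0)
    out = np.empty(len(sequences))
    w = pwm.width
    lo = pwm.log_odds_matrix
    for start in range(0, len(sequences), chunk):
        codes = encode_many(list(sequences[start : start + chunk]))
        if (codes < 0).any():
            raise ValueError("max_scores_many requires strict-ACGT sequences")
        if codes.shape[1] < w:
            raise ValueError(f"sequence length {codes.shape[1]} < PWM width {w}")
        wins = sliding_window_view(codes, w, axis=1)
        s_f = lo[wins, np.arange(w)].sum(axis=2).max(axis=1)
        rc = (3 - codes)[:, ::-1]
        wins_r = sliding_window_view(rc, w, axis=1)
        s_r = lo[wins_r, np.arange(w)].sum(axis=2).max(axis=1)
        out[start : start + len(codes)] = np.maximum(s_f, s_r)
    return out


def calibrate_threshold(
    pwm: PWM,
    n_random: int = 10000,
    length: int = 200,
    quantile: float = 0.999,
    rng_seed: int = 0,
) -> float:
    """Empirical significance threshold: the given quantile of max-scan
    scores over random uniform sequences."""
    if n_random < 1000:
        raise ValueError("n_random must be >= 1000 for a stable quantile")
    rng = np.random.default_rng(rng_seed)
    from .sequences import random_dna

    seqs = random_dna(n_random, length, rng)
    scores = max_scores_many(seqs, pwm)
    return float(np.quantile(scores, quantile))


def significant_hits(sequence: str, pwm: PWM, threshold: float,
                     seq_id: str | None = None) -> list[ScanHit]:
    """All windows scoring >= threshold, on either strand."""
    fwd, rev = scan_scores(sequence, pwm)
    hits = []
    for offset in range(len(fwd)):
        for strand, arr in (("+", fwd), ("-", rev)):
            s = arr[offset]
            if np.isfinite(s) and s >= threshold:
                hits.append(ScanHit(seq_id, offset, strand, float(s), True))
    return hits


def _count_merged_sites(hits: list[ScanHit], width: int) -> int:
    """Cluster hits closer than one motif width (e.g. the same site seen
    on both strands) and count clusters."""
    if not hits:
        return 0
    offsets = sorted(h.offset for h in hits)
    n = 1
    cluster_end = offsets[0]
    for o in offsets[1:]:
        if o - cluster_end >= width:
            n += 1
        cluster_end = o
    return n


@dataclass
class RegionSelection:
    """Partition of regions by significant-site count."""

    single: list[tuple[str, ScanHit]]  # exactly one significant site
    multi: list[str]  # more than one; excluded from designs
    weak: list[tuple[str, ScanHit]]  # none significant; best hit reported

    def summary(self) -> dict:
        return {
            "single": len(self.single),
            "multi": len(self.multi),
            "weak": len(self.weak),
        }


def select_single_site_regions(
    regions: Iterable[tuple[str, str]], pwm: PWM, threshold: float
) -> RegionSelection:
    """Partition regions into exactly-one-significant-site (kept),
    multi-site (excluded) and no-significant-site ('weak': kept with the
    maximum-score hit).  Partitions are disjoint and exhaustive."""
    single: list[tuple[str, ScanHit]] = []
    multi: list[str] = []
    weak: list[tuple[str, ScanHit]] = []
    for region_id, seq in regions:
        hits = significant_hits(seq, pwm, threshold, seq_id=region_id)
        n_sites = _count_merged_sites(hits, pwm.width)
        if n_sites == 1:
            best = max(hits, key=lambda h: h.score)
            single.append((region_id, best))
        elif n_sites > 1:
            multi.append(region_id)
        else:
            weak.append((region_id, max_scan(seq, pwm, seq_id=region_id)))
    return RegionSelection(single=single, multi=multi, weak=weak)


def hits_to_dataframe(hits: Iterable[ScanHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [h.seq_id for h in hits],
            "offset": [h.offset for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
        }
    )
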