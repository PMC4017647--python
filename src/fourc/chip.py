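"""Rank correlation between 4C-seq profiles and ChIP-seq coverage.

The Table-1-style methodology: within a stated region, every restriction
fragment receives the length-weighted mean ChIP coverage over its
interval; fragments are then ranked and Spearman's rank correlation is
computed between 4C and ChIP vectors (or any pair of per-fragment
vectors). For a repressed viewpoint, the best-correlating mark is
expected to be H3K27me3; for an active one, H3K4me3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import RestrictionFragmentMap
from .profiles import NormalizedProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChipTrack:
    """Scored coverage intervals on one chromosome, 0-based half-open."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        scores = np.asarray(self.scores, dtype=float)
        if not (len(starts) == len(ends) == len(scores)):
            raise ValueError("starts, ends and scores must have equal length")
        if np.any(ends <= starts):
            raise ValueError("intervals must have positive length")
        if np.any(scores < 0):
            raise ValueError("coverage scores must be non-negative")
        order = np.argsort(starts, kind="stable")
        starts, ends, scores = starts[order], ends[order], scores[order]
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError("coverage intervals overlap after sorting")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_bedgraph(cls, df: pd.DataFrame, chrom: str | None = None) -> "ChipTrack":
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        elif df["chrom"].nunique() > 1:
            raise ValueError("bedGraph covers several chromosomes; pass chrom=")
        name = chrom if chrom is not None else str(df["chrom"].iloc[0])
        return cls(
            chrom=name,
            starts=df["start"].to_numpy(),
            ends=df["end"].to_numpy(),
            scores=df["value"].to_numpy(),
        )


@dataclass
class FragmentChipSignal:
    """Mean ChIP coverage per fragment, restricted to an analysis region."""

    fragment_indices: np.ndarray
    values: np.ndarray
    region: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.fragment_indices) != len(self.values):
            raise ValueError("indices and values must have equal length")


def aggregate_chip(
    track: ChipTrack,
    fragment_map: RestrictionFragmentMap,
    region: tuple[int, int] | None = None,
) -> FragmentChipSignal:
    """Assign the length-weighted mean ChIP coverage to each fragment.

    Only fragments lying fully within ``region`` are kept; bases not
    covered by any interval count as zero coverage.
    """
    if track.chrom != fragment_map.chrom:
        raise ValueError("ChIP track and fragment map are on different chromosomes")
    lo, hi = region if region is not None else fragment_map.span
    keep = np.nonzero((fragment_map.starts >= lo) & (fragment_map.ends <= hi))[0]
    if len(keep) == 0:
        logger.warning("aggregate_chip: region %s disjoint from the map", (lo, hi))
        return FragmentChipSignal(
            fragment_indices=keep, values=np.empty(0), region=(lo, hi)
        )
    values = np.empty(len(keep))
    for out_i, f in enumerate(keep):
        fs, fe = fragment_map.starts[f], fragment_map.ends[f]
        first = np.searchsorted(track.ends, fs, side="right")
        last = np.searchsorted(track.starts, fe, side="left")
        overlap = np.minimum(track.ends[first:last], fe) - np.maximum(
            track.starts[first:last], fs
        )
        covered = float(np.sum(overlap * track.scores[first:last]))
        values[out_i] = covered / (fe - fs)
    return FragmentChipSignal(fragment_indices=keep, values=values, region=(lo, hi))


def spearman_correlation(x, y) -> float:
    """Spearman's rho: Pearson correlation of mid-ranked values.

    Ties share their mean rank. Requires at least 3 paired observations
    and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class CorrelationTable:
    """Matrix of Spearman rho between 4C profiles (rows) and ChIP tracks (cols).

    ``best`` flags, for each 4C profile, the highest-correlating ChIP
    sample — the machine-readable analogue of bolding the best match.
    """

    rho: pd.DataFrame
    best: pd.Series

    def to_tsv(self, path) -> None:
        out = self.rho.copy()
        out["best_match"] = self.best
        out.to_csv(path, sep="\t")


def correlation_table(
    profiles: dict[str, NormalizedProfile | np.ndarray],
    chip: dict[str, FragmentChipSignal],
) -> CorrelationTable:
    """Spearman rho for every (4C profile, ChIP track) pair on shared fragments.

    Profiles restricted to each ChIP signal's fragments; masked (non-OK)
    fragments are dropped pairwise.
    """
    rows = {}
    for pname, profile in profiles.items():
        rows[pname] = {}
        for cname, csig in chip.items():
            if isinstance(profile, NormalizedProfile):
                idx = csig.fragment_indices
                ok = profile.ok[idx]
                x = profile.values[idx][ok]
                y = csig.values[ok]
            else:
                x = np.asarray(profile, dtype=float)[csig.fragment_indices]
                y = csig.values
            rows[pname][cname] = spearman_correlation(x, y)
    rho = pd.DataFrame.from_dict(rows, orient="index")
    return CorrelationTable(rho=rho, best=rho.idxmax(axis=1))
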