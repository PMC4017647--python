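"""Virtual 4C extraction from a binned Hi-C contact matrix.

A Hi-C matrix row is the genome-wide contact profile of its bin; summing
the rows of every bin overlapping a viewpoint locus gives a *virtual 4C*
profile comparable, after binning the 4C-seq track to the same
resolution, with the sequencing-based profile. The comparison statistic
here is rank-based (desert-bin Spearman rho plus each profile's desert
tropism), so no matrix balancing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip import spearman_correlation
from .longrange import DesertAnnotation
from .profiles import NormalizedProfile


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C counts with a bin table (chrom/start/end)."""

    bins: pd.DataFrame
    matrix: np.ndarray
    resolution: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.bins)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match the bin table")
        if np.any(self.matrix < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        starts = self.bins["start"].to_numpy()
        ends = self.bins["end"].to_numpy()
        if n > 1 and np.any(starts[1:] != ends[:-1]):
            raise ValueError("bins must tile the span contiguously")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bins_overlapping(self, start: int, end: int) -> np.ndarray:
        starts = self.bins["start"].to_numpy()
        ends = self.bins["end"].to_numpy()
        return np.nonzero((starts < end) & (ends > start))[0]


@dataclass
class VirtualProfile:
    """Per-bin contact signal of a viewpoint locus, self-bins masked."""

    viewpoint_bins: np.ndarray
    signal: np.ndarray        # normalized to sum 1 over unmasked bins
    raw_signal: np.ndarray    # pre-normalization row sum, self-bins zeroed
    mask: np.ndarray          # True on self-bins


def virtual_profile(
    matrix: ContactMatrix, viewpoint_interval: tuple[int, int]
) -> VirtualProfile:
    """Sum the matrix rows of every bin overlapping the viewpoint interval.

    The viewpoint bins themselves are masked out, and the remaining
    signal is normalized to sum to one. A multi-bin viewpoint profile is,
    before normalization, exactly the sum of the single-bin profiles.
    """
    vp_bins = matrix.bins_overlapping(*viewpoint_interval)
    if len(vp_bins) == 0:
        raise ValueError("viewpoint interval overlaps no bin of the matrix")
    raw = matrix.matrix[vp_bins].sum(axis=0)
    mask = np.zeros(matrix.n_bins, dtype=bool)
    mask[vp_bins] = True
    raw = np.where(mask, 0.0, raw)
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            "degenerate input: no off-viewpoint contacts to normalize"
        )
    return VirtualProfile(
        viewpoint_bins=vp_bins, signal=raw / total, raw_signal=raw, mask=mask
    )


def bin_profile(profile: NormalizedProfile, bins: pd.DataFrame) -> np.ndarray:
    """Sum per-fragment OK signal into bins, conserving the total.

    A fragment straddling a bin edge contributes to each bin in
    proportion to the base-pair overlap.
    """
    fmap = profile.fragment_map
    values = np.where(profile.ok, profile.values, 0.0)
    out = np.zeros(len(bins))
    bin_starts = bins["start"].to_numpy()
    bin_ends = bins["end"].to_numpy()
    for f in np.nonzero(values != 0)[0]:
        fs, fe = int(fmap.starts[f]), int(fmap.ends[f])
        first = np.searchsorted(bin_ends, fs, side="right")
        last = np.searchsorted(bin_starts, fe, side="left")
        if first >= last:
            continue
        overlap = np.minimum(bin_ends[first:last], fe) - np.maximum(
            bin_starts[first:last], fs
        )
        # split by bp overlap; bases outside the bin span are dropped, so
        # the total is conserved only when fragments lie within the span
        out[first:last] += values[f] * (overlap / (fe - fs))
    return out


@dataclass(frozen=True)
class VirtualComparison:
    rho: float
    tropism_virtual: tuple[float, float]
    tropism_binned: tuple[float, float]


def _bin_tropism(
    signal: np.ndarray, bins: pd.DataFrame, annotation: DesertAnnotation
) -> tuple[float, float]:
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()

    def in_interval(lo, hi):
        return (starts >= lo) & (ends <= hi)

    cen = float(signal[in_interval(*annotation.centromeric)].sum())
    tel = float(signal[in_interval(*annotation.telomeric)].sum())
    if cen + tel <= 0:
        raise ValueError("no desert signal in the binned profile")
    return cen / (cen + tel), tel / (cen + tel)


def compare_virtual(
    virtual: VirtualProfile,
    binned4c: np.ndarray,
    bins: pd.DataFrame,
    annotation: DesertAnnotation,
) -> VirtualComparison:
    """Compare a virtual 4C profile with a binned 4C-seq profile.

    Spearman rho is computed over desert bins only (bins fully within a
    desert interval; cluster and partially overlapping bins excluded),
    alongside each profile's (p_cen, p_tel) desert split.
    """
    binned4c = np.asarray(binned4c, dtype=float)
    if len(binned4c) != len(virtual.signal):
        raise ValueError("profiles are on different bin tables")
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    desert = ((starts >= annotation.centromeric[0]) & (ends <= annotation.centromeric[1])) | (
        (starts >= annotation.telomeric[0]) & (ends <= annotation.telomeric[1])
    )
    rho = spearman_correlation(virtual.signal[desert], binned4c[desert])
    return VirtualComparison(
        rho=rho,
        tropism_virtual=_bin_tropism(virtual.signal, bins, annotation),
        tropism_binned=_bin_tropism(binned4c, bins, annotation),
    )
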