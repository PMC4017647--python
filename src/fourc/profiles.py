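"""Per-fragment signal processing for 4C-seq viewpoint profiles.

The processing chain mirrors the standard fragment-level 4C workflow:

1. divide raw counts by a bait-free *random library* that carries the same
   fragment-specific capture/amplification biases (BAC-derived in the
   original protocol);
2. drop fragments the random library does not cover, fragments on a
   blacklist of known-aberrant intervals, and fragments around the
   viewpoint itself;
3. scale the remaining signal to a fixed total;
4. compare conditions through log2 ratios and smooth display tracks with
   a centred running mean (window 11 in the reference analyses).

Masked fragments are excluded — never imputed or zero-filled — from every
sum, mean and correlation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

from .fragments import FragmentCounts, RestrictionFragmentMap

logger = logging.getLogger(__name__)

NORMALIZATION_TOTAL = 1e6

#: Restriction fragments that return aberrant values after random-library
#: correction due to sequence abnormalities in the BAC template (mm9
#: coordinates); applied automatically when a map on those chromosomes is
#: corrected.
DEFAULT_BLACKLIST: tuple[tuple[str, int, int], ...] = (
    ("chr2", 74_597_000, 74_597_732),
    ("chr2", 74_608_796, 74_609_312),
    ("chr11", 95_999_958, 96_000_916),
)


class FragmentStatus(IntEnum):
    OK = 0
    VIEWPOINT = 1
    ABERRANT = 2
    UNCOVERED = 3
    EXCLUDED = 4


@dataclass(frozen=True)
class RandomLibraryTrack:
    """Expected capture signal per fragment from a bait-free control library."""

    fragment_map: RestrictionFragmentMap
    values: np.ndarray
    coverage_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(values) != self.fragment_map.n_fragments:
            raise ValueError("random-library track length must match the map")
        if np.any(values < 0):
            raise ValueError("random-library values must be non-negative")
        interval = self.coverage_interval or self.fragment_map.span
        if interval[1] <= interval[0]:
            raise ValueError("coverage interval must be non-empty")
        object.__setattr__(self, "coverage_interval", tuple(interval))


@dataclass
class NormalizedProfile:
    """Corrected per-fragment 4C signal with a fragment-status mask.

    ``values`` holds the signal on OK fragments and 0 elsewhere;
    ``normalization_constant`` is None until :func:`normalize` is applied.
    """

    fragment_map: RestrictionFragmentMap
    values: np.ndarray
    status: np.ndarray
    viewpoint_id: str = "viewpoint"
    bait_fragment: int | None = None
    normalization_constant: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        n = self.fragment_map.n_fragments
        if len(self.values) != n or len(self.status) != n:
            raise ValueError("values/status length must match the fragment map")
        self.values = np.where(self.ok, self.values, 0.0)

    @property
    def ok(self) -> np.ndarray:
        return self.status == FragmentStatus.OK

    @property
    def ok_total(self) -> float:
        return float(self.values[self.ok].sum())

    def copy(self) -> "NormalizedProfile":
        return replace(self, values=self.values.copy(), status=self.status.copy())


@dataclass
class RatioTrack:
    """Per-fragment log2 ratio between two normalized profiles.

    Values are defined only where both inputs were OK; elsewhere the shared
    mask records the reason and the value is NaN.
    """

    fragment_map: RestrictionFragmentMap
    values: np.ndarray
    ok: np.ndarray
    pseudocount: float
    label_a: str = "A"
    label_b: str = "B"


def _blacklist_mask(
    fragment_map: RestrictionFragmentMap, blacklist
) -> np.ndarray:
    mask = np.zeros(fragment_map.n_fragments, dtype=bool)
    for chrom, start, end in blacklist:
        if chrom != fragment_map.chrom:
            continue
        mask[fragment_map.overlapping(start, end)] = True
    return mask


def correct_by_random_library(
    raw: FragmentCounts,
    random: RandomLibraryTrack,
    blacklist=None,
    include_default_blacklist: bool = True,
) -> NormalizedProfile:
    """Divide raw counts by the random-library signal, fragment by fragment.

    Fragments where the random library is zero or outside its coverage
    interval become UNCOVERED; fragments intersecting blacklist intervals
    become ABERRANT. The default blacklist carries the known aberrant
    mm9 fragments and only applies on matching chromosomes.
    """
    fmap = raw.fragment_map
    if fmap is not random.fragment_map and (
        fmap.chrom != random.fragment_map.chrom
        or fmap.n_fragments != random.fragment_map.n_fragments
        or np.any(fmap.starts != random.fragment_map.starts)
    ):
        raise ValueError("raw counts and random library are on different maps")
    if not np.any(random.values > 0):
        raise ValueError("random library is entirely zero; nothing is correctable")

    entries = list(blacklist) if blacklist is not None else []
    if include_default_blacklist:
        entries.extend(DEFAULT_BLACKLIST)

    cov_lo, cov_hi = random.coverage_interval
    covered = (fmap.starts >= cov_lo) & (fmap.ends <= cov_hi) & (random.values > 0)
    status = np.full(fmap.n_fragments, FragmentStatus.OK, dtype=np.int8)
    status[~covered] = FragmentStatus.UNCOVERED
    aberrant = _blacklist_mask(fmap, entries)
    status[aberrant] = FragmentStatus.ABERRANT

    values = np.zeros(fmap.n_fragments)
    use = status == FragmentStatus.OK
    values[use] = raw.counts[use] / random.values[use]
    return NormalizedProfile(
        fragment_map=fmap,
        values=values,
        status=status,
        viewpoint_id=raw.viewpoint_id,
        bait_fragment=raw.bait_fragment,
    )


def mask_viewpoint(
    profile: NormalizedProfile,
    bait_fragment: int | None = None,
    halfwidth_fragments: int = 2,
) -> NormalizedProfile:
    """Mask the bait fragment and ``halfwidth_fragments`` neighbours per side."""
    if halfwidth_fragments < 0:
        raise ValueError("halfwidth must be >= 0")
    bait = profile.bait_fragment if bait_fragment is None else bait_fragment
    if bait is None:
        raise ValueError("no bait fragment recorded or given")
    n = profile.fragment_map.n_fragments
    if not 0 <= bait < n:
        raise ValueError(f"bait fragment {bait} outside map of {n} fragments")
    out = profile.copy()
    lo = max(0, bait - halfwidth_fragments)
    hi = min(n, bait + halfwidth_fragments + 1)
    out.status[lo:hi] = FragmentStatus.VIEWPOINT
    out.values[lo:hi] = 0.0
    out.bait_fragment = bait
    out.normalization_constant = None
    return out


def normalize(
    profile: NormalizedProfile, total: float = NORMALIZATION_TOTAL
) -> NormalizedProfile:
    """Scale OK-fragment signal so it sums to ``total`` (default 1e6)."""
    ok_sum = profile.ok_total
    if ok_sum <= 0:
        raise ValueError("profile has no positive OK signal to normalize")
    out = profile.copy()
    out.values = np.where(out.ok, out.values * (total / ok_sum), 0.0)
    out.normalization_constant = float(total)
    return out


def log2_ratio(
    a: NormalizedProfile,
    b: NormalizedProfile,
    pseudocount: float = 1.0,
    label_a: str = "A",
    label_b: str = "B",
) -> RatioTrack:
    """log2((a + pseudocount) / (b + pseudocount)) on jointly OK fragments.

    The ratio is exactly antisymmetric under swapping the two profiles.
    The default pseudocount of 1 is on the normalized (per-million) scale.
    """
    if a.fragment_map.n_fragments != b.fragment_map.n_fragments or np.any(
        a.fragment_map.starts != b.fragment_map.starts
    ):
        raise ValueError("profiles are on different maps")
    ok = a.ok & b.ok
    if pseudocount <= 0 and (
        np.any(a.values[ok] == 0) or np.any(b.values[ok] == 0)
    ):
        raise ValueError("pseudocount must be > 0 when either track contains zeros")
    values = np.full(a.fragment_map.n_fragments, np.nan)
    # difference of logs, not log of ratio: antisymmetric to the last bit
    values[ok] = np.log2(a.values[ok] + pseudocount) - np.log2(
        b.values[ok] + pseudocount
    )
    return RatioTrack(
        fragment_map=a.fragment_map,
        values=values,
        ok=ok,
        pseudocount=pseudocount,
        label_a=label_a,
        label_b=label_b,
    )


def running_mean_masked(values: np.ndarray, ok: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean over OK entries; masked entries are skipped.

    Near the array edges the window shrinks symmetrically so the mean stays
    centred. Entries that are not OK come back as NaN.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    values = np.asarray(values, dtype=float)
    ok = np.asarray(ok, dtype=bool)
    n = len(values)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if not ok[i]:
            continue
        k = min(half, i, n - 1 - i)
        window_ok = ok[i - k : i + k + 1]
        out[i] = values[i - k : i + k + 1][window_ok].mean()
    return out


def running_mean(track, window: int = 11):
    """Smooth a profile or plain array with a centred running mean.

    For a :class:`NormalizedProfile`, masked fragments are skipped (never
    zero-filled) and stay masked in the output. A plain array is treated
    as fully OK.
    """
    if isinstance(track, NormalizedProfile):
        if window > int(track.ok.sum()):
            raise ValueError("window exceeds the number of OK fragments")
        out = track.copy()
        smoothed = running_mean_masked(track.values, track.ok, window)
        out.values = np.where(track.ok, smoothed, 0.0)
        out.normalization_constant = None
        return out
    values = np.asarray(track, dtype=float)
    if window > len(values):
        raise ValueError("window exceeds the track length")
    return running_mean_masked(values, np.ones(len(values), dtype=bool), window)


def exclude_interval(
    profile: NormalizedProfile, start: int, end: int
) -> NormalizedProfile:
    """Mark every fragment overlapping [start, end) as EXCLUDED."""
    out = profile.copy()
    idx = profile.fragment_map.overlapping(start, end)
    out.status[idx] = FragmentStatus.EXCLUDED
    out.values[idx] = 0.0
    out.normalization_constant = None
    return out
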