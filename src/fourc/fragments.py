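"""Restriction-fragment maps and read-to-fragment translation.

4C-seq quantifies chromatin contacts at the resolution of restriction
fragments: the intervals between consecutive occurrences of the primary
restriction enzyme's recognition site (NlaIII in the classical protocol).
A fragment is *blind* when it lacks a site for the secondary enzyme
(DpnII) and is therefore poorly captured by the circularisation step.

Everything downstream of this module works on per-fragment vectors indexed
by the fragment order of a :class:`RestrictionFragmentMap`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_SITE_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class RestrictionFragmentMap:
    """Ordered tiling of a chromosome by primary restriction fragments.

    Coordinates are 0-based half-open. Fragment ``k`` ends exactly where
    fragment ``k + 1`` starts; every internal boundary coincides with the
    first base of a primary recognition-site occurrence.

    Attributes
    ----------
    chrom
        Chromosome (or contig) name.
    starts, ends
        Per-fragment interval bounds, strictly increasing, gap-free.
    valid
        True where the fragment contains at least one secondary-enzyme
        site, i.e. the fragment is not blind.
    primary_site, secondary_site
        Recognition sequences used for the digestion.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    valid: np.ndarray
    primary_site: str
    secondary_site: str

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "valid", valid)
        if not (len(starts) == len(ends) == len(valid)):
            raise ValueError("starts, ends and valid must have equal length")
        if len(starts) == 0:
            raise ValueError("a fragment map needs at least one fragment")
        if np.any(ends <= starts):
            raise ValueError("every fragment must have positive length")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("fragments must tile without gaps or overlaps")

    @property
    def n_fragments(self) -> int:
        return len(self.starts)

    @property
    def span(self) -> tuple[int, int]:
        """(start, end) of the digested interval."""
        return int(self.starts[0]), int(self.ends[-1])

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def locate(self, position: int) -> int:
        """Index of the fragment whose half-open interval contains ``position``.

        Raises
        ------
        IndexError
            If the position falls outside the digested interval.
        """
        lo, hi = self.span
        if not lo <= position < hi:
            raise IndexError(
                f"position {position} outside digested interval [{lo}, {hi})"
            )
        return int(np.searchsorted(self.starts, position, side="right") - 1)

    def overlapping(self, start: int, end: int) -> np.ndarray:
        """Indices of fragments overlapping the half-open interval [start, end)."""
        if end <= start:
            return np.empty(0, dtype=np.int64)
        idx = np.nonzero((self.starts < end) & (self.ends > start))[0]
        return idx


@dataclass(frozen=True)
class ReadPlacement:
    """A mapped read position, possibly representing several identical reads."""

    chrom: str
    position: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if self.position < 0:
            raise ValueError("read position must be >= 0")


@dataclass
class FragmentCounts:
    """Raw 4C-seq signal: one non-negative count per fragment of a map."""

    fragment_map: RestrictionFragmentMap
    counts: np.ndarray
    viewpoint_id: str = "viewpoint"
    bait_fragment: int | None = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.fragment_map.n_fragments:
            raise ValueError("counts length must match the fragment map")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _check_site(site: str, name: str) -> str:
    if not site:
        raise ValueError(f"{name} recognition site must be non-empty")
    site = site.upper()
    if not set(site) <= _SITE_BASES:
        raise ValueError(f"{name} recognition site must contain only A/C/G/T: {site!r}")
    return site


def _find_sites(sequence: str, site: str) -> list[int]:
    """All start positions of ``site`` in ``sequence``, overlaps included."""
    positions = []
    start = sequence.find(site)
    while start != -1:
        positions.append(start)
        start = sequence.find(site, start + 1)
    return positions


def digest_sequence(
    sequence: str,
    primary_site: str,
    secondary_site: str,
    chrom: str = "chr",
) -> RestrictionFragmentMap:
    """In-silico digestion of a sequence with a primary restriction enzyme.

    Fragment boundaries are placed at the first base of every exact
    occurrence of ``primary_site`` (overlapping occurrences count).  A
    fragment is flagged valid when it contains at least one occurrence of
    ``secondary_site``.  ``N`` bases never match a recognition site.

    Parameters
    ----------
    sequence
        Uppercase A/C/G/T/N nucleotide string.
    primary_site, secondary_site
        Recognition sequences, e.g. ``"CATG"`` (NlaIII) and ``"GATC"``
        (DpnII).
    chrom
        Name recorded on the resulting map.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    if not set(sequence) <= _VALID_BASES:
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"sequence contains invalid characters: {bad}")
    primary_site = _check_site(primary_site, "primary")
    secondary_site = _check_site(secondary_site, "secondary")

    cuts = sorted({0, *(_find_sites(sequence, primary_site)), len(sequence)})
    # an occurrence at position 0 coincides with the interval start
    boundaries = [c for c in cuts if c < len(sequence)] + [len(sequence)]
    starts = np.asarray(boundaries[:-1], dtype=np.int64)
    ends = np.asarray(boundaries[1:], dtype=np.int64)
    valid = np.fromiter(
        (sequence.find(secondary_site, s, e) != -1 for s, e in zip(starts, ends)),
        dtype=bool,
        count=len(starts),
    )
    return RestrictionFragmentMap(
        chrom=chrom,
        starts=starts,
        ends=ends,
        valid=valid,
        primary_site=primary_site,
        secondary_site=secondary_site,
    )


def assign_reads(
    reads,
    fragment_map: RestrictionFragmentMap,
    viewpoint_id: str = "viewpoint",
    bait_fragment: int | None = None,
) -> FragmentCounts:
    """Translate mapped read positions into per-fragment counts.

    Each read's count is added to the unique fragment whose half-open
    interval contains its leftmost position. Reads outside the digested
    interval (or on another chromosome) are skipped with a warning and
    reported through :attr:`FragmentCounts.n_skipped`.
    """
    counts = np.zeros(fragment_map.n_fragments, dtype=float)
    lo, hi = fragment_map.span
    skipped = 0
    for read in reads:
        if read.chrom != fragment_map.chrom or not lo <= read.position < hi:
            skipped += 1
            continue
        counts[fragment_map.locate(read.position)] += read.count
    if skipped:
        logger.warning(
            "assign_reads: skipped %d read placement(s) outside %s:[%d, %d)",
            skipped,
            fragment_map.chrom,
            lo,
            hi,
        )
    return FragmentCounts(
        fragment_map=fragment_map,
        counts=counts,
        viewpoint_id=viewpoint_id,
        bait_fragment=bait_fragment,
        n_skipped=skipped,
    )
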