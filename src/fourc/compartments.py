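"""Compartment calling and condition-preference statistics.

A 4C viewpoint inside a repressed Hox cluster concentrates the bulk of its
contacts within a contiguous chromatin compartment around the bait. The
compartment extent is called here as the smallest contiguous fragment
interval containing the bait that captures a stated fraction of the total
signal, grown greedily toward whichever flank currently offers more
signal. Fragments are then split into inside/outside the compartment and,
from a between-condition log2 ratio track, into "positive in A" versus
"positive in B"; the association between location and preference is
tested with a G-test (log-likelihood-ratio test) of independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .profiles import NormalizedProfile, RatioTrack

logger = logging.getLogger(__name__)

LABEL_A = "A"
LABEL_B = "B"
LABEL_TIED = "tied"


@dataclass(frozen=True)
class CompartmentCall:
    """Contiguous high-interaction domain around a bait.

    ``start``/``end`` are fragment indices, half-open, so the compartment
    covers fragments ``start .. end - 1`` and always contains the bait.
    """

    start: int
    end: int
    bait_fragment: int
    threshold: float
    captured_fraction: float

    def __post_init__(self) -> None:
        if not self.start <= self.bait_fragment < self.end:
            raise ValueError("bait must lie inside the called interval")

    @property
    def n_fragments(self) -> int:
        return self.end - self.start

    def inside(self, n_fragments: int) -> np.ndarray:
        """Boolean in/out label per fragment of a map of ``n_fragments``."""
        labels = np.zeros(n_fragments, dtype=bool)
        labels[self.start : self.end] = True
        return labels


@dataclass(frozen=True)
class PreferenceTable:
    """2x2 contingency table: location (inside/outside) x preference (A/B)."""

    inside_a: int
    inside_b: int
    outside_a: int
    outside_b: int

    def __post_init__(self) -> None:
        if min(self.inside_a, self.inside_b, self.outside_a, self.outside_b) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def observed(self) -> np.ndarray:
        return np.array(
            [[self.inside_a, self.inside_b], [self.outside_a, self.outside_b]],
            dtype=float,
        )

    @property
    def row_margins(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.observed.sum())


def call_compartment(
    profile: NormalizedProfile,
    bait_fragment: int | None = None,
    signal_fraction_threshold: float = 0.8,
) -> CompartmentCall:
    """Call the compartment interval around the bait from a 4C profile.

    Starting from the bait fragment, the interval is extended one fragment
    at a time toward the flank whose next fragment carries more signal
    (left wins ties), until the interval holds at least
    ``signal_fraction_threshold`` of the total OK signal. Masked fragments
    contribute no signal but may be traversed. Deterministic for fixed
    input, and monotone: a higher threshold never shrinks the interval.
    """
    if not 0 < signal_fraction_threshold <= 1:
        raise ValueError("signal fraction threshold must be in (0, 1]")
    bait = profile.bait_fragment if bait_fragment is None else bait_fragment
    if bait is None:
        raise ValueError("no bait fragment recorded or given")
    n = profile.fragment_map.n_fragments
    if not 0 <= bait < n:
        raise ValueError("bait fragment outside the map")
    total = profile.ok_total
    if total <= 0:
        raise ValueError("profile has no OK signal")

    values = np.where(profile.ok, profile.values, 0.0)
    target = signal_fraction_threshold * total
    lo = hi = bait
    captured = values[bait]
    while captured < target and not np.isclose(captured, target, rtol=1e-12):
        left = values[lo - 1] if lo > 0 else -np.inf
        right = values[hi + 1] if hi < n - 1 else -np.inf
        if left == right == -np.inf:
            break
        if left >= right:
            lo -= 1
            captured += values[lo]
        else:
            hi += 1
            captured += values[hi]
    return CompartmentCall(
        start=lo,
        end=hi + 1,
        bait_fragment=bait,
        threshold=signal_fraction_threshold,
        captured_fraction=float(captured / total),
    )


def classify_fragments(ratio: RatioTrack) -> np.ndarray:
    """Label each fragment by condition preference from a log2 ratio track.

    Returns an array of ``"A"`` (ratio > 0), ``"B"`` (ratio < 0) or
    ``"tied"`` (exact zero, or masked). Tied fragments are excluded from
    contingency tables.
    """
    if not np.any(ratio.ok):
        raise ValueError("ratio track is empty after masking")
    labels = np.full(len(ratio.values), LABEL_TIED, dtype=object)
    with np.errstate(invalid="ignore"):
        labels[ratio.ok & (ratio.values > 0)] = LABEL_A
        labels[ratio.ok & (ratio.values < 0)] = LABEL_B
    if not np.any((labels == LABEL_A) | (labels == LABEL_B)):
        logger.warning("classify_fragments: all fragments tied; table is empty")
    return labels


def preference_table(labels: np.ndarray, inside: np.ndarray) -> PreferenceTable:
    """Cross-tabulate preference labels against an inside/outside partition."""
    labels = np.asarray(labels, dtype=object)
    inside = np.asarray(inside, dtype=bool)
    if len(labels) != len(inside):
        raise ValueError("labels and inside mask must have equal length")
    return PreferenceTable(
        inside_a=int(np.sum(inside & (labels == LABEL_A))),
        inside_b=int(np.sum(inside & (labels == LABEL_B))),
        outside_a=int(np.sum(~inside & (labels == LABEL_A))),
        outside_b=int(np.sum(~inside & (labels == LABEL_B))),
    )


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    pvalue: float


def gtest_independence(table, williams_correction: bool = False) -> GTestResult:
    """G-test (log-likelihood ratio) of independence for a contingency table.

    G = 2 * sum over cells of O * ln(O / E), with expectations from the
    margin products; zero cells contribute nothing. The p-value comes from
    the chi-square upper tail with (r-1)(c-1) degrees of freedom. Williams'
    continuity correction is off by default and available as an option.
    """
    observed = table.observed if isinstance(table, PreferenceTable) else np.asarray(
        table, dtype=float
    )
    if observed.ndim != 2 or min(observed.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(observed < 0):
        raise ValueError("contingency cells must be non-negative")
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("G-test undefined with a zero row or column margin")
    total = observed.sum()
    expected = np.outer(rows, cols) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
    g = 2.0 * float(terms.sum())
    g = max(g, 0.0)  # guard against -0.0 from rounding on homogeneous tables
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    if williams_correction:
        q = 1.0 + ((total * (1.0 / rows).sum() - 1.0) * (
            total * (1.0 / cols).sum() - 1.0
        )) / (6.0 * total * df)
        g = g / q
    pvalue = float(stats.chi2.sf(g, df))
    return GTestResult(g=g, df=df, pvalue=pvalue)
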