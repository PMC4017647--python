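"""Synthetic 4C/ChIP/Hi-C data with a known generative truth.

The generator emulates the structure of a silent Hox cluster locus: a
gene cluster split by a boundary into two chromatin compartments (a
"negative", repressive-mark-covered one and a "positive" one holding
active promoters), flanked on each side by a large gene desert that the
cluster contacts at long range. One :class:`SimulationModel` drives every
data type — fragment map, viewpoint 4C counts, bait-free random-library
counts sharing the same fragment biases, compartment-coincident ChIP
coverage, and a TAD-structured Hi-C matrix — so cross-assay consistency
checks have an exact shared truth.

Contact probabilities for a viewpoint in compartment ``c`` are built as

    p_f  ∝  bias_f * m_f

where the bias-free mass ``m_f`` allocates a fixed fraction of contacts
to the cluster (power-law distance decay from the bait, attenuated by
``alpha`` across the compartment boundary, plus a small uniform floor)
and the remainder to the deserts, split exactly ``tau`` telomeric versus
``1 - tau`` centromeric (gentler decay from the cluster edge plus a
floor). Reads are multinomial draws at fixed depth, matching
fixed-sequencing-depth reality and making normalization exactly testable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .chip import ChipTrack
from .fragments import FragmentCounts, RestrictionFragmentMap, digest_sequence
from .profiles import RandomLibraryTrack
from .virtual4c import ContactMatrix


@dataclass
class SimulationModel:
    """Generative parameters for the synthetic Hox-like locus.

    Geometry defaults follow the reference locus at reduced scale: a
    120-fragment cluster with its compartment boundary at fragment 60,
    flanked by 400-fragment gene deserts on each side.

    Parameters
    ----------
    n_centromeric, n_cluster, n_telomeric
        Fragment counts of the three regions (deserts flank the cluster).
    boundary
        Compartment boundary as a cluster-local fragment index: cluster
        fragments ``[0, boundary)`` form the negative compartment,
        ``[boundary, n_cluster)`` the positive one.
    mean_fragment_length, min_fragment_length
        Fragment length distribution (uniform on
        ``[min, 2*mean - min]``), in bp. NlaIII fragments average a few
        hundred bp; the default keeps the synthetic locus compact.
    alpha
        Cross-compartment attenuation in (0, 1]: contact weight of a
        cluster fragment on the far side of the boundary, relative to the
        bait's own compartment.
    gamma, desert_gamma
        Distance-decay exponents (in fragment index): within the cluster
        from the bait, and within deserts from the nearest cluster edge.
        Desert contacts are broad TAD-wide plateaus, hence the gentler
        default decay.
    tau
        Fraction of desert-directed signal going to the telomeric desert.
    cluster_mass
        Fraction of all contacts landing within the cluster; the
        remaining ``1 - cluster_mass`` is desert mass.
    cluster_floor, desert_floor
        Uniform within-region background mixture weights, so no fragment
        has exactly zero contact probability.
    bias_sigma
        Lognormal sigma of the multiplicative fragment-specific capture
        bias shared between viewpoint and random libraries.
    depth, random_depth
        Sequencing depths (total read counts) of a viewpoint library and
        of the bait-free random library.
    hic_depth, hic_resolution
        Total Hi-C read pairs and bin width in bp.
    hic_cross_tad, hic_desert_desert
        Hi-C contact attenuation between the cluster and a desert TAD
        (scaled by the tau split), and between the two deserts.
    blind_fraction
        Fraction of fragments generated without a secondary-enzyme site.
    """

    n_centromeric: int = 400
    n_cluster: int = 120
    n_telomeric: int = 400
    boundary: int = 60
    mean_fragment_length: int = 800
    min_fragment_length: int = 200
    alpha: float = 0.05
    gamma: float = 1.0
    desert_gamma: float = 0.5
    tau: float = 0.5
    cluster_mass: float = 0.82
    cluster_floor: float = 0.02
    desert_floor: float = 0.15
    bias_sigma: float = 0.5
    depth: int = 100_000
    random_depth: int = 1_000_000
    hic_depth: int = 5_000_000
    hic_resolution: int = 32_000
    hic_cross_tad: float = 0.1
    hic_desert_desert: float = 0.02
    blind_fraction: float = 0.1
    chrom: str = "chrSim"
    primary_site: str = "CATG"
    secondary_site: str = "GATC"

    def __post_init__(self) -> None:
        if self.n_centromeric + self.n_cluster + self.n_telomeric < 10:
            raise ValueError("need at least 10 fragments")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must lie in [0, 1]")
        if self.gamma < 0 or self.desert_gamma < 0:
            raise ValueError("decay exponents must be >= 0")
        if not 0 < self.boundary < self.n_cluster:
            raise ValueError("boundary must split the cluster")
        if not 0 < self.cluster_mass < 1:
            raise ValueError("cluster_mass must lie in (0, 1)")
        if self.min_fragment_length < 12:
            raise ValueError("fragments must be long enough to carry both sites")
        if self.mean_fragment_length < self.min_fragment_length:
            raise ValueError("mean fragment length below the minimum")

    # --- geometry helpers -------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return self.n_centromeric + self.n_cluster + self.n_telomeric

    @property
    def cluster_range(self) -> tuple[int, int]:
        """Global fragment-index range [start, end) of the cluster."""
        return self.n_centromeric, self.n_centromeric + self.n_cluster

    @property
    def boundary_fragment(self) -> int:
        """Global fragment index of the compartment boundary."""
        return self.n_centromeric + self.boundary

    def default_bait(self) -> int:
        """Centre of the negative compartment (global index)."""
        return self.n_centromeric + self.boundary // 2

    def compartment_labels(self) -> np.ndarray:
        """Per-fragment region label: cen_desert/negative/positive/tel_desert."""
        labels = np.empty(self.n_fragments, dtype=object)
        c0, c1 = self.cluster_range
        labels[:c0] = "cen_desert"
        labels[c0 : self.boundary_fragment] = "negative"
        labels[self.boundary_fragment : c1] = "positive"
        labels[c1:] = "tel_desert"
        return labels

    # --- config round trip ------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SimulationModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside each simulated viewpoint."""

    contact_probability: np.ndarray   # bias-free m_f, sums to 1
    biased_probability: np.ndarray    # bias_f * m_f, renormalized
    biases: np.ndarray
    compartment_labels: np.ndarray
    bait_fragment: int
    boundary_fragment: int
    bait_compartment_range: tuple[int, int]
    tau: float


# --- fragment map ----------------------------------------------------------


def _safe_extend(rng, parts: list[str], tail: str, n: int, forbidden: set[str]) -> str:
    """Append ``n`` random bases, never completing a forbidden 4-mer."""
    bases = "ACGT"
    out = []
    for _ in range(n):
        choices = [b for b in bases if (tail + b)[-4:] not in forbidden]
        b = choices[rng.integers(len(choices))]
        out.append(b)
        tail = (tail + b)[-4:]
    parts.append("".join(out))
    return tail


def _append_site(rng, parts: list[str], tail: str, site: str, forbidden: set[str]) -> str:
    """Append ``site`` verbatim, padding first so that no junction 4-mer is
    forbidden (other than the site itself)."""
    while True:
        probe = tail + site
        junction = {
            probe[i : i + 4] for i in range(max(0, len(probe) - 7), len(probe) - 4)
        }
        if not junction & forbidden:
            break
        tail = _safe_extend(rng, parts, tail, 1, forbidden)
    parts.append(site)
    return (tail + site)[-4:]


def simulate_map(
    model: SimulationModel, seed: int = 0
) -> tuple[RestrictionFragmentMap, str]:
    """Generate a sequence whose digestion yields exactly the intended map.

    The sequence is built fragment by fragment: each internal boundary is
    a verbatim primary-site occurrence, fragment bodies are sampled so
    that no stray primary or secondary site ever forms (including across
    junctions), and non-blind fragments get one secondary site inserted
    mid-fragment. Digesting the emitted sequence therefore reproduces the
    intended fragment boundaries and validity flags exactly.
    """
    if model.n_fragments < 10:
        raise ValueError("need at least 10 fragments")
    rng = np.random.default_rng(seed)
    n = model.n_fragments
    low = model.min_fragment_length
    high = 2 * model.mean_fragment_length - model.min_fragment_length
    lengths = rng.integers(low, high + 1, size=n)
    blind = rng.random(n) < model.blind_fraction
    forbidden = {model.primary_site, model.secondary_site}
    site_len = len(model.primary_site)

    parts: list[str] = []
    tail = ""
    for i in range(n):
        if i > 0:
            tail = _append_site(rng, parts, tail, model.primary_site, forbidden)
        body = int(lengths[i]) - (0 if i == 0 else site_len)
        if blind[i]:
            tail = _safe_extend(rng, parts, tail, body, forbidden)
        else:
            half = body // 2
            tail = _safe_extend(rng, parts, tail, max(half, 4), forbidden)
            tail = _append_site(rng, parts, tail, model.secondary_site, forbidden)
            tail = _safe_extend(
                rng, parts, tail, max(body - half - len(model.secondary_site), 0), forbidden
            )
    sequence = "".join(parts)
    fmap = digest_sequence(
        sequence, model.primary_site, model.secondary_site, chrom=model.chrom
    )
    if fmap.n_fragments != n:
        raise RuntimeError("internal error: constructed sequence mis-digested")
    return fmap, sequence


# --- viewpoint 4C ----------------------------------------------------------


def contact_mass(model: SimulationModel, bait_fragment: int) -> np.ndarray:
    """Bias-free per-fragment contact probability m_f for one bait.

    Sums to 1 exactly (before bias multiplication and sampling). The
    telomeric-desert share of the desert mass is exactly ``tau``.
    """
    c0, c1 = model.cluster_range
    if not c0 <= bait_fragment < c1:
        raise ValueError("bait must lie within the cluster region")
    n = model.n_fragments
    b = model.boundary_fragment
    m = np.zeros(n)

    idx = np.arange(c0, c1)
    d = np.abs(idx - bait_fragment)
    same = (idx < b) == (bait_fragment < b)
    w = np.where(same, 1.0, model.alpha) * (1.0 + d) ** -model.gamma
    shape = (1 - model.cluster_floor) * w / w.sum() + model.cluster_floor / model.n_cluster
    m[c0:c1] = model.cluster_mass * shape

    desert_mass = 1.0 - model.cluster_mass
    wc = (1.0 + np.arange(model.n_centromeric)[::-1]) ** -model.desert_gamma
    m[:c0] = desert_mass * (1 - model.tau) * (
        (1 - model.desert_floor) * wc / wc.sum()
        + model.desert_floor / model.n_centromeric
    )
    wt = (1.0 + np.arange(model.n_telomeric)) ** -model.desert_gamma
    m[c1:] = desert_mass * model.tau * (
        (1 - model.desert_floor) * wt / wt.sum()
        + model.desert_floor / model.n_telomeric
    )
    return m / m.sum()


def simulate_biases(model: SimulationModel, seed: int = 0) -> np.ndarray:
    """Fragment-specific multiplicative capture biases (lognormal)."""
    rng = np.random.default_rng(seed)
    return rng.lognormal(0.0, model.bias_sigma, model.n_fragments)


def simulate_viewpoint(
    model: SimulationModel,
    fragment_map: RestrictionFragmentMap,
    bait_fragment: int | None = None,
    seed: int = 0,
    biases: np.ndarray | None = None,
) -> tuple[FragmentCounts, RandomLibraryTrack, SimulationTruth]:
    """Simulate one viewpoint's raw counts plus its matched random library.

    Counts are multinomial at fixed depth over ``bias_f * m_f``; the
    random library is multinomial over the biases alone, so dividing the
    two cancels the bias in expectation. Pass a shared ``biases`` array
    to simulate several viewpoints from the same underlying library.
    """
    if fragment_map.n_fragments != model.n_fragments:
        raise ValueError("fragment map does not match the model geometry")
    bait = model.default_bait() if bait_fragment is None else bait_fragment
    rng = np.random.default_rng(seed)
    if biases is None:
        biases = rng.lognormal(0.0, model.bias_sigma, model.n_fragments)
    m = contact_mass(model, bait)
    p = biases * m
    p = p / p.sum()
    counts = rng.multinomial(model.depth, p).astype(float)
    q = biases / biases.sum()
    random_counts = rng.multinomial(model.random_depth, q).astype(float)

    c0, c1 = model.cluster_range
    b = model.boundary_fragment
    comp_range = (c0, b) if bait < b else (b, c1)
    truth = SimulationTruth(
        contact_probability=m,
        biased_probability=p,
        biases=np.asarray(biases, dtype=float),
        compartment_labels=model.compartment_labels(),
        bait_fragment=bait,
        boundary_fragment=b,
        bait_compartment_range=comp_range,
        tau=model.tau,
    )
    raw = FragmentCounts(
        fragment_map=fragment_map,
        counts=counts,
        viewpoint_id=f"sim_bait_{bait}",
        bait_fragment=bait,
    )
    random_track = RandomLibraryTrack(
        fragment_map=fragment_map, values=random_counts
    )
    return raw, random_track, truth


# --- ChIP tracks -----------------------------------------------------------


def simulate_chip(
    model: SimulationModel,
    fragment_map: RestrictionFragmentMap,
    seed: int = 0,
    noise_sigma: float = 0.8,
    repressive_high: float = 5.0,
    repressive_low: float = 0.5,
    active_peak: float = 6.0,
    active_baseline: float = 0.3,
    promoter_spacing: int = 6,
) -> tuple[ChipTrack, ChipTrack, dict[str, tuple[int, int]]]:
    """Repressive-like and active-like ChIP coverage from the same model.

    The repressive track is a two-level step: high over the negative
    compartment, low elsewhere. The active track is baseline coverage
    with narrow peaks at promoter fragments spaced through the positive
    compartment. Gaussian noise (clipped at zero) is added per fragment;
    with ``noise_sigma=0`` both tracks are exact step/peak functions.
    Returns the two tracks plus the true domain intervals in bp.
    """
    if fragment_map.n_fragments != model.n_fragments:
        raise ValueError("fragment map does not match the model geometry")
    rng = np.random.default_rng(seed)
    c0, c1 = model.cluster_range
    b = model.boundary_fragment
    n = model.n_fragments

    rep = np.full(n, repressive_low)
    rep[c0:b] = repressive_high
    act = np.full(n, active_baseline)
    promoters = np.arange(b, c1, promoter_spacing)
    act[promoters] = active_peak
    if noise_sigma > 0:
        rep = np.clip(rep + rng.normal(0, noise_sigma, n), 0, None)
        act = np.clip(act + rng.normal(0, noise_sigma, n), 0, None)

    def track(scores):
        return ChipTrack(
            chrom=fragment_map.chrom,
            starts=fragment_map.starts.copy(),
            ends=fragment_map.ends.copy(),
            scores=scores,
        )

    domains = {
        "repressive": (int(fragment_map.starts[c0]), int(fragment_map.ends[b - 1])),
        "active": (int(fragment_map.starts[b]), int(fragment_map.ends[c1 - 1])),
    }
    return track(rep), track(act), domains


# --- Hi-C ------------------------------------------------------------------


def hic_bins(model: SimulationModel, fragment_map: RestrictionFragmentMap) -> pd.DataFrame:
    """Fixed-resolution bin table over the map's span (last bin clipped)."""
    lo, hi = fragment_map.span
    starts = np.arange(lo, hi, model.hic_resolution)
    ends = np.minimum(starts + model.hic_resolution, hi)
    return pd.DataFrame(
        {"chrom": fragment_map.chrom, "start": starts, "end": ends}
    )


def simulate_hic(
    model: SimulationModel,
    fragment_map: RestrictionFragmentMap,
    seed: int = 0,
) -> ContactMatrix:
    """TAD-structured Hi-C matrix sharing the viewpoint model's truth.

    Bins fall into three TADs (centromeric desert, cluster, telomeric
    desert, assigned by bin midpoint). Expected counts combine power-law
    distance decay with block attenuation: 1 within a TAD,
    ``hic_cross_tad`` scaled by the tau split for cluster-desert blocks
    (so the cluster row reproduces the model's desert tropism), and
    ``hic_desert_desert`` between the deserts. Counts are Poisson draws
    on the upper triangle, mirrored for exact symmetry.
    """
    bins = hic_bins(model, fragment_map)
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    c0, c1 = model.cluster_range
    cluster_lo = int(fragment_map.starts[c0])
    cluster_hi = int(fragment_map.ends[c1 - 1])
    tad = np.zeros(len(bins), dtype=int)  # 0 cen desert, 1 cluster, 2 tel desert
    tad[(mids >= cluster_lo) & (mids < cluster_hi)] = 1
    tad[mids >= cluster_hi] = 2

    att = {
        (0, 0): 1.0,
        (1, 1): 1.0,
        (2, 2): 1.0,
        (0, 1): 2.0 * (1.0 - model.tau) * model.hic_cross_tad,
        (1, 2): 2.0 * model.tau * model.hic_cross_tad,
        (0, 2): model.hic_desert_desert,
    }
    nb = len(bins)
    i, j = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
    pair = np.empty((nb, nb))
    for (a, b), v in att.items():
        mask = ((tad[i] == a) & (tad[j] == b)) | ((tad[i] == b) & (tad[j] == a))
        pair[mask] = v
    expected = pair * (1.0 + np.abs(i - j)) ** -model.gamma
    expected *= model.hic_depth / expected.sum()

    rng = np.random.default_rng(seed)
    upper = np.triu(rng.poisson(expected))
    matrix = upper + upper.T - np.diag(np.diag(upper))
    return ContactMatrix(bins=bins, matrix=matrix.astype(float), resolution=model.hic_resolution)


# --- convenience -----------------------------------------------------------


def desert_annotation(
    model: SimulationModel, fragment_map: RestrictionFragmentMap
):
    """The model's cluster/desert intervals in bp, as a DesertAnnotation."""
    from .longrange import DesertAnnotation

    c0, c1 = model.cluster_range
    lo, hi = fragment_map.span
    return DesertAnnotation(
        centromeric=(lo, int(fragment_map.starts[c0])),
        cluster=(int(fragment_map.starts[c0]), int(fragment_map.starts[c1])),
        telomeric=(int(fragment_map.starts[c1]), hi),
    )
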