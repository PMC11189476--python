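"""Core data containers shared across the analysis modules.

All containers are plain dataclasses around numpy arrays with light
validation. Units follow the conventions of the field: distances in nm,
times in ns for simulation-derived data, currents in pA, potentials in mV,
conductances in pS (single channel) or nS (whole cell), capacitance in pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DistanceTable",
    "PlanarTrack",
    "ContactMatrix",
    "ResidueContactProfile",
    "DensityMap",
    "DistanceSeries",
    "ChannelTrace",
    "AmplitudeHistogram",
    "GaussianSumModel",
    "StateFractions",
    "RampSweepSet",
    "IVCurve",
]


def _as_str_array(x: Sequence[str]) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class DistanceTable:
    """Time-resolved minimum distances between lipids and protein residues.

    ``distances`` is indexed ``[frame, lipid, residue]`` in nm; this is the
    substrate of all contact analysis (counts, profiles, binding events).
    """

    times: np.ndarray  # (n_frames,) ns, uniform spacing
    distances: np.ndarray  # (n_frames, n_lipids, n_residues) nm
    lipid_species: np.ndarray  # (n_lipids,) species label per lipid
    residue_ids: np.ndarray  # (n_residues,)
    repeat: int = 0
    lipid_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.lipid_species = _as_str_array(self.lipid_species)
        self.residue_ids = np.asarray(self.residue_ids)
        if self.lipid_ids is None:
            self.lipid_ids = np.arange(self.n_lipids)
        if self.distances.ndim != 3:
            raise ValueError("distances must be [frame, lipid, residue]")
        if self.distances.shape[0] != self.times.size:
            raise ValueError("frame count mismatch between times and distances")
        if self.distances.shape[1] != self.lipid_species.size:
            raise ValueError("lipid count mismatch")
        if self.distances.shape[2] != self.residue_ids.size:
            raise ValueError("residue count mismatch")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if self.times.size > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-10):
                raise ValueError("times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.distances.shape[1]

    @property
    def n_residues(self) -> int:
        return self.distances.shape[2]

    @property
    def dt(self) -> float:
        """Frame spacing in ns (0 for a single-frame table)."""
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def species_index(self, species: str) -> np.ndarray:
        idx = np.flatnonzero(self.lipid_species == species)
        if idx.size == 0:
            raise KeyError(f"species {species!r} not present in table")
        return idx


@dataclass
class PlanarTrack:
    """Planar head-group positions of lipids, per frame, with leaflet tags."""

    times: np.ndarray  # (n_frames,) ns
    xy: np.ndarray  # (n_frames, n_lipids, 2) nm
    leaflet: np.ndarray  # (n_lipids,) "lower" | "upper"
    species: np.ndarray  # (n_lipids,)
    box_xy: tuple[float, float]
    repeat: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.leaflet = _as_str_array(self.leaflet)
        self.species = _as_str_array(self.species)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ValueError("xy must be [frame, lipid, 2]")
        if self.xy.shape[1] != self.species.size or self.xy.shape[1] != self.leaflet.size:
            raise ValueError("per-lipid label size mismatch")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.xy.shape[1]


@dataclass
class ContactMatrix:
    """Boolean lipid-residue contact mask from thresholding a DistanceTable."""

    mask: np.ndarray  # (n_frames, n_lipids, n_residues) bool
    cutoff: float  # nm
    times: np.ndarray
    lipid_species: np.ndarray
    residue_ids: np.ndarray
    repeat: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        self.lipid_species = _as_str_array(self.lipid_species)
        self.residue_ids = np.asarray(self.residue_ids)

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def species_index(self, species: str) -> np.ndarray:
        idx = np.flatnonzero(self.lipid_species == species)
        if idx.size == 0:
            raise KeyError(f"species {species!r} not present")
        return idx


@dataclass
class ResidueContactProfile:
    """Per-residue contact duration and maximum single-lipid occupancy.

    Contact duration is the total time a residue is in contact with any
    lipid of the species; maximum occupancy is the longest continuous
    engagement of one lipid with the residue. Both in ns, restricted to
    the analysis window.
    """

    residue_ids: np.ndarray
    contact_duration: np.ndarray  # ns
    max_occupancy: np.ndarray  # ns
    window: tuple[float, float]  # ns
    species: str
    normalised_duration: np.ndarray | None = None
    normalised_occupancy: np.ndarray | None = None


@dataclass
class DensityMap:
    """Time-averaged 2D lipid counts per planar bin for one species/leaflet."""

    counts: np.ndarray  # (nx, ny) mean lipids per bin per frame
    bin_size: float  # nm
    extent: tuple[float, float, float, float]  # x0, x1, y0, y1 (nm)
    species: str
    leaflet: str
    n_repeats: int = 1

    @property
    def total_mass(self) -> float:
        """Mean number of tracked lipids per frame (sum over bins)."""
        return float(self.counts.sum())


@dataclass
class DistanceSeries:
    """A single residue-pair or donor-acceptor distance series."""

    times: np.ndarray  # ns
    distance: np.ndarray  # nm
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.times.shape != self.distance.shape:
            raise ValueError("times and distance must align")
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ChannelTrace:
    """A sampled single-channel current trace.

    ``state_path`` and ``state_levels``, when present, are simulation
    ground truth carried alongside the data for parameter-recovery tests.
    """

    current: np.ndarray  # pA
    sample_rate: float  # Hz
    holding_potential: float = 0.0  # mV
    filter_info: dict = field(default_factory=dict)
    state_path: np.ndarray | None = None  # (n_samples,) int, ground truth
    state_levels: np.ndarray | None = None  # pA per state index

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class AmplitudeHistogram:
    """Histogram of sampled current amplitudes (counts on linear scale)."""

    edges: np.ndarray  # pA, len = n_bins + 1
    counts: np.ndarray  # per bin
    log_display: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.edges.size != self.counts.size + 1:
            raise ValueError("edges must have one more entry than counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class GaussianSumModel:
    """Sum-of-Gaussians amplitude model.

    Primary parameters per component: alpha (count amplitude), beta (pA)
    and gamma (1/pA), so each component reads
    ``alpha * exp(-((x - beta) * gamma)**2)``. The derived parameters are
    the familiar normal-density ones: mu = beta, sigma = (2 gamma^2)^(-1/2)
    and the component area rho = sqrt(pi) * alpha / gamma.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    rho: np.ndarray | None = None
    labels: list[str] | None = None  # "c", "s", ..., "o"
    residual: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if not (self.alpha.shape == self.beta.shape == self.gamma.shape):
            raise ValueError("alpha, beta, gamma must align")
        if np.any(self.gamma <= 0):
            raise ValueError("gamma must be positive")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")

    @property
    def n(self) -> int:
        return self.alpha.size

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the model in its primary (alpha/beta/gamma) form."""
        x = np.asarray(x, dtype=float)
        arg = (x[..., None] - self.beta) * self.gamma
        return np.sum(self.alpha * np.exp(-(arg**2)), axis=-1)

    def eval_scaled_normal(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the equivalent sum of scaled normal densities."""
        if self.mu is None or self.sigma is None or self.rho is None:
            raise ValueError("derived parameters not populated; call derive_params")
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.mu) / self.sigma
        dens = np.exp(-0.5 * z**2) / (self.sigma * np.sqrt(2.0 * np.pi))
        return np.sum(self.rho * dens, axis=-1)


@dataclass
class StateFractions:
    """Fraction of events attributed to closed / sublevel / open classes."""

    fractions: dict  # label -> fraction (labels "c", "s1".., "o")
    by_class: dict  # {"closed": f, "sub": f, "open": f}
    ambiguous: bool = False

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"fractions must sum to 1 (got {total})")


@dataclass
class RampSweepSet:
    """Repeated whole-cell voltage-ramp sweeps with cell capacitance."""

    voltage: np.ndarray  # (n_samples,) mV, shared ramp command
    currents: np.ndarray  # (n_sweeps, n_samples) pA
    capacitance: float  # pF
    sweep_times: np.ndarray  # (n_sweeps,) s, start time of each sweep

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        self.sweep_times = np.asarray(self.sweep_times, dtype=float)
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        dv = np.diff(self.voltage)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("ramp voltage must be monotonic")
        if self.currents.shape[1] != self.voltage.size:
            raise ValueError("sweep length mismatch")
        if self.currents.shape[0] != self.sweep_times.size:
            raise ValueError("sweep count mismatch")

    @property
    def n_sweeps(self) -> int:
        return self.currents.shape[0]


@dataclass
class IVCurve:
    """Current-voltage relationship on a uniform potential grid."""

    potentials: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # pA or pA/pF
    normalised: bool = False

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.any(np.diff(self.potentials) <= 0):
            raise ValueError("potentials must be strictly increasing")
        if self.potentials.shape != self.currents.shape:
            raise ValueError("potentials and currents must align")
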