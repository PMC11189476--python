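"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators:

* :func:`gen_contact_trajectory` — lipids diffusing in a periodic planar
  membrane patch around an excluded protein disc, with exponential
  dwell-time binding at planted residue footprints. Emits per-repeat
  distance tables and planar tracks together with the ground-truth bound
  intervals.
* :func:`gen_channel_trace` — a continuous-time Markov chain over
  closed / sublevel / open current levels, sampled with Gaussian noise
  and optional Gaussian low-pass filtering; the true state path rides
  along as ground truth.
* :func:`gen_ramp_sweeps` — whole-cell voltage-ramp sweep sets with an
  ohmic leak plus a per-sweep channel-conductance time course.

Everything is driven by a single integer seed; equal seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ChannelTrace, DistanceTable, PlanarTrack, RampSweepSet

__all__ = [
    "PlantedSite",
    "ContactSimConfig",
    "BoundInterval",
    "ContactRealization",
    "gen_contact_trajectory",
    "ChannelSimConfig",
    "gen_channel_trace",
    "RampSimConfig",
    "gen_ramp_sweeps",
    "levels_from_conductance",
]

# Default inner-leaflet composition (counts per 100 lipids) for a membrane
# with 2% PIP2 of total lipid: PC 18, Chol 30, PE 35, PS 15, PIP2 2.
DEFAULT_SPECIES_COUNTS = {"PC": 18, "Chol": 30, "PE": 35, "PS": 15, "PIP2": 2}


@dataclass
class PlantedSite:
    """A binding site: residue footprint + exponential dwell kinetics."""

    footprint: tuple[int, ...]
    mean_bound_dwell: float  # ns
    mean_unbound_dwell: float  # ns; inf disables binding at this site
    species: str = "PIP2"

    def __post_init__(self) -> None:
        self.footprint = tuple(int(r) for r in self.footprint)
        if len(self.footprint) == 0:
            raise ValueError("site footprint must not be empty")
        if self.mean_bound_dwell <= 0:
            raise ValueError("mean bound dwell must be positive")
        if self.mean_unbound_dwell <= 0:
            raise ValueError("mean unbound dwell must be positive")


@dataclass
class ContactSimConfig:
    """Configuration of the lipid-contact simulator.

    The protein is an excluded disc of radius ``protein_radius`` at the
    box centre; residues are points equally spaced on its perimeter.
    Unbound lipids perform an overdamped 2D random walk (diffusion
    coefficient ``diffusion`` nm^2/ns) with periodic wrap and cannot
    approach the residue ring closer than ``approach_floor``. A bound
    lipid is parked at an anchor point radially outward of its footprint
    and its footprint distances are drawn uniformly in [0.3, 0.55] nm,
    safely below the 0.6 nm contact cutoff.
    """

    species_counts: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_COUNTS))
    box_xy: tuple[float, float] = (24.0, 24.0)  # nm
    n_residues: int = 40
    planted_sites: list = field(
        default_factory=lambda: [PlantedSite((3, 4, 5, 6), 8000.0, 2000.0, "PIP2")]
    )
    frame_dt: float = 10.0  # ns
    n_frames: int = 2000  # 20 us per repeat by default
    n_repeats: int = 5
    seed: int = 0
    diffusion: float = 0.05  # nm^2/ns, free parameter of the emulation
    protein_radius: float = 4.0  # nm
    approach_floor: float = 0.45  # nm; >= cutoff disables chance encounters
    bound_offset: float = 1.0  # nm, anchor distance outside the residue ring

    def __post_init__(self) -> None:
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        for s in self.planted_sites:
            if s.species not in self.species_counts:
                raise ValueError(f"planted-site species {s.species!r} not simulated")
            if any(r < 0 or r >= self.n_residues for r in s.footprint):
                raise ValueError("footprint outside residue index range")


@dataclass
class BoundInterval:
    """Ground-truth binding episode (continuous time, ns)."""

    site: int
    lipid: int
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ContactRealization:
    """One repeat of the contact simulator with its ground truth."""

    table: DistanceTable
    track: PlanarTrack
    bound_intervals: list


def _residue_ring(cfg: ContactSimConfig) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(cfg.n_residues) / cfg.n_residues
    centre = np.array(cfg.box_xy) / 2.0
    return centre + cfg.protein_radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)


def _site_anchor(cfg: ContactSimConfig, site: PlantedSite) -> np.ndarray:
    theta = 2.0 * np.pi * np.asarray(site.footprint) / cfg.n_residues
    # circular mean of the footprint directions, pushed radially outward
    direction = np.array([np.cos(theta).mean(), np.sin(theta).mean()])
    direction /= np.linalg.norm(direction)
    centre = np.array(cfg.box_xy) / 2.0
    return centre + (cfg.protein_radius + cfg.bound_offset) * direction


def _min_image_dist(xy: np.ndarray, points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image planar distances, broadcasting lipids against points."""
    delta = xy[..., None, :] - points  # (..., n_points, 2)
    delta -= box * np.round(delta / box)
    return np.linalg.norm(delta, axis=-1)


def _schedule_site(
    rng: np.random.Generator,
    site_idx: int,
    site: PlantedSite,
    eligible: np.ndarray,
    total_time: float,
) -> list:
    """Alternating-renewal occupancy of one site; capacity one lipid."""
    intervals: list[BoundInterval] = []
    if not math.isfinite(site.mean_unbound_dwell):
        return intervals
    t = rng.exponential(site.mean_unbound_dwell)
    while t < total_time:
        lipid = int(rng.choice(eligible))
        dwell = rng.exponential(site.mean_bound_dwell)
        intervals.append(BoundInterval(site_idx, lipid, t, min(t + dwell, total_time)))
        t += dwell + rng.exponential(site.mean_unbound_dwell)
    return intervals


def _simulate_repeat(
    cfg: ContactSimConfig, repeat: int, rng: np.random.Generator
) -> ContactRealization:
    box = np.asarray(cfg.box_xy, dtype=float)
    centre = box / 2.0
    residues = _residue_ring(cfg)
    exclusion = cfg.protein_radius + cfg.approach_floor

    species = np.concatenate(
        [np.full(n, name, dtype=object) for name, n in cfg.species_counts.items()]
    )
    n_lipids = species.size
    times = np.arange(cfg.n_frames) * cfg.frame_dt
    total_time = cfg.n_frames * cfg.frame_dt

    # site occupancy schedules (continuous time), one pass per site;
    # overlapping claims on the same lipid are resolved first-come
    intervals: list[BoundInterval] = []
    for s_idx, site in enumerate(cfg.planted_sites):
        eligible = np.flatnonzero(species == site.species)
        intervals.extend(_schedule_site(rng, s_idx, site, eligible, total_time))
    intervals.sort(key=lambda iv: iv.t_start)
    kept: list[BoundInterval] = []
    busy_until: dict[int, float] = {}
    for iv in intervals:
        if busy_until.get(iv.lipid, -np.inf) <= iv.t_start:
            kept.append(iv)
            busy_until[iv.lipid] = iv.t_end
    intervals = kept

    # per-frame bound state: -1 free, else site index
    bound_site = np.full((cfg.n_frames, n_lipids), -1, dtype=int)
    for iv in intervals:
        f0 = int(np.searchsorted(times, iv.t_start, side="left"))
        f1 = int(np.searchsorted(times, iv.t_end, side="right"))
        bound_site[f0:f1, iv.lipid] = iv.site

    anchors = np.array([_site_anchor(cfg, s) for s in cfg.planted_sites]).reshape(-1, 2)

    # initial positions: uniform in the box outside the exclusion disc
    xy0 = np.empty((n_lipids, 2))
    filled = 0
    while filled < n_lipids:
        cand = rng.uniform(0.0, box, size=(n_lipids - filled, 2))
        ok = np.linalg.norm(cand - centre, axis=1) > exclusion
        n_ok = int(ok.sum())
        xy0[filled : filled + n_ok] = cand[ok]
        filled += n_ok

    step_sd = math.sqrt(2.0 * cfg.diffusion * cfg.frame_dt)
    steps = rng.normal(0.0, step_sd, size=(cfg.n_frames, n_lipids, 2))

    xy = np.empty((cfg.n_frames, n_lipids, 2))
    pos = xy0
    for f in range(cfg.n_frames):
        if f > 0:
            pos = pos + steps[f]
        pos = np.mod(pos, box)
        # radial push-out of the excluded disc
        rel = pos - centre
        r = np.linalg.norm(rel, axis=1)
        inside = r < exclusion
        if np.any(inside):
            safe_r = np.where(r[inside] > 1e-12, r[inside], 1e-12)
            pos[inside] = centre + rel[inside] * (exclusion / safe_r)[:, None]
        b = bound_site[f]
        parked = b >= 0
        if np.any(parked):
            pos[parked] = anchors[b[parked]]
        xy[f] = pos

    distances = _min_image_dist(xy, residues, box)  # (frames, lipids, residues)

    # bound lipids: footprint residues sit in [0.3, 0.55] nm
    for s_idx, site in enumerate(cfg.planted_sites):
        sel = bound_site == s_idx  # (frames, lipids)
        n_sel = int(sel.sum())
        if n_sel:
            fp = np.asarray(site.footprint)
            draw = rng.uniform(0.3, 0.55, size=(n_sel, fp.size))
            idx_f, idx_l = np.nonzero(sel)
            distances[idx_f[:, None], idx_l[:, None], fp[None, :]] = draw

    table = DistanceTable(
        times=times,
        distances=distances,
        lipid_species=species,
        residue_ids=np.arange(cfg.n_residues),
        repeat=repeat,
    )
    track = PlanarTrack(
        times=times,
        xy=xy,
        leaflet=np.full(n_lipids, "lower", dtype=object),
        species=species,
        box_xy=tuple(box),
        repeat=repeat,
    )
    return ContactRealization(table=table, track=track, bound_intervals=intervals)


def gen_contact_trajectory(cfg: ContactSimConfig) -> list:
    """Generate ``cfg.n_repeats`` independent contact realizations.

    Returns a list of :class:`ContactRealization`, one per repeat, each
    carrying a frame-consistent :class:`~lipgate.core.DistanceTable` and
    :class:`~lipgate.core.PlanarTrack` plus ground-truth bound intervals.
    """
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repeats)
    return [
        _simulate_repeat(cfg, rep, np.random.default_rng(seq))
        for rep, seq in enumerate(seqs)
    ]


# ---------------------------------------------------------------------------
# single-channel traces
# ---------------------------------------------------------------------------


def levels_from_conductance(
    conductance_pS: float,
    potential_mV: float,
    sublevel_fractions: tuple[float, ...] = (),
) -> np.ndarray:
    """Current levels (pA) for closed, sublevels, open given gamma and V.

    The open level is gamma * V (pS * mV -> fA, /1000 -> pA); sublevels
    are the given fractions of it; closed is the 0 pA baseline.
    """
    open_level = conductance_pS * potential_mV / 1000.0
    subs = [f * open_level for f in sublevel_fractions]
    return np.array([0.0, *subs, open_level])


@dataclass
class ChannelSimConfig:
    """Markov gating simulator configuration.

    ``state_levels`` are ordered closed, sublevels..., open (pA, closed
    first at the 0 pA baseline). ``rate_matrix`` is the generator Q in
    1/s: rows sum to zero, non-negative off-diagonal.
    """

    state_levels: tuple  # pA
    rate_matrix: np.ndarray  # (n_states, n_states), 1/s
    sample_rate: float = 50_000.0  # Hz
    duration: float = 60.0  # s
    noise_sd: float = 0.5  # pA
    filter_cutoff: float | None = 1500.0  # Hz, None disables
    holding_potential: float = 80.0  # mV
    unitary_conductance: float | None = None  # pS, metadata
    start_state: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        q = self.rate_matrix
        n = len(self.state_levels)
        if q.shape != (n, n):
            raise ValueError("rate matrix must be square over the states")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("rate matrix rows must sum to zero (conservative)")
        if self.filter_cutoff is not None and self.sample_rate <= 2 * self.filter_cutoff:
            raise ValueError("sample_rate must exceed twice the filter cutoff")


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a conservative rate matrix (pi Q = 0)."""
    q = np.asarray(rate_matrix, dtype=float)
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return pi


def gen_channel_trace(cfg: ChannelSimConfig) -> ChannelTrace:
    """Sample a CTMC gating trace with noise and optional filtering."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    q = cfg.rate_matrix
    n_states = q.shape[0]
    n_samples = int(round(cfg.duration * cfg.sample_rate))

    # Gillespie jump chain
    jump_times = [0.0]
    jump_states = [cfg.start_state]
    t, s = 0.0, cfg.start_state
    while t < cfg.duration:
        rate_out = -q[s, s]
        if rate_out <= 0:
            break
        t += rng.exponential(1.0 / rate_out)
        if t >= cfg.duration:
            break
        probs = q[s].copy()
        probs[s] = 0.0
        probs /= rate_out
        s = int(rng.choice(n_states, p=probs))
        jump_times.append(t)
        jump_states.append(s)

    sample_t = np.arange(n_samples) / cfg.sample_rate
    idx = np.searchsorted(jump_times, sample_t, side="right") - 1
    state_path = np.asarray(jump_states)[idx]
    levels = np.asarray(cfg.state_levels, dtype=float)
    current = levels[state_path]
    if cfg.noise_sd > 0:
        current = current + rng.normal(0.0, cfg.noise_sd, size=n_samples)

    trace = ChannelTrace(
        current=current,
        sample_rate=cfg.sample_rate,
        holding_potential=cfg.holding_potential,
        state_path=state_path,
        state_levels=levels,
    )
    if cfg.filter_cutoff is not None:
        from .single_channel import gaussian_lowpass

        trace = gaussian_lowpass(trace, cfg.filter_cutoff)
        trace.state_path = state_path
        trace.state_levels = levels
    return trace


# ---------------------------------------------------------------------------
# whole-cell voltage ramps
# ---------------------------------------------------------------------------


@dataclass
class RampSimConfig:
    """Whole-cell ramp simulator: ohmic leak + per-sweep channel conductance."""

    v_start: float = -130.0  # mV
    v_end: float = 80.0  # mV
    ramp_duration: float = 0.2  # s
    n_sweeps: int = 30
    capacitance: float = 10.0  # pF
    leak_conductance: float = 0.5  # nS
    channel_conductance_timecourse: np.ndarray | None = None  # nS per sweep
    reversal_potential: float = 0.0  # mV
    noise_sd: float = 2.0  # pA
    sample_rate: float = 8000.0  # Hz
    sweep_interval: float = 1.0  # s between sweep starts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_start >= self.v_end:
            raise ValueError("v_start must be below v_end")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.channel_conductance_timecourse is None:
            self.channel_conductance_timecourse = np.zeros(self.n_sweeps)
        self.channel_conductance_timecourse = np.asarray(
            self.channel_conductance_timecourse, dtype=float
        )
        if self.channel_conductance_timecourse.size != self.n_sweeps:
            raise ValueError("conductance time course must have one entry per sweep")


def gen_ramp_sweeps(cfg: RampSimConfig) -> RampSweepSet:
    """I(t) = (g_leak + g_channel(sweep)) * (V(t) - E_rev) + noise."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_samples = int(round(cfg.ramp_duration * cfg.sample_rate))
    voltage = np.linspace(cfg.v_start, cfg.v_end, n_samples)
    g_total = cfg.leak_conductance + cfg.channel_conductance_timecourse  # nS
    # nS * mV = pA
    currents = g_total[:, None] * (voltage[None, :] - cfg.reversal_potential)
    if cfg.noise_sd > 0:
        currents = currents + rng.normal(0.0, cfg.noise_sd, size=currents.shape)
    return RampSweepSet(
        voltage=voltage,
        currents=currents,
        capacitance=cfg.capacitance,
        sweep_times=np.arange(cfg.n_sweeps) * cfg.sweep_interval,
    )
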