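"""Lipid-protein contact metrics and membrane density maps.

Operations on distance tables and planar tracks: boolean contact
thresholding (a contact is two particles closer than 0.6 nm by default),
lipid-count time series across repeats, per-residue contact-duration and
maximum-occupancy profiles, per-species contact fractions, leaflet 2D
density maps, and pair-distance histograms (salt bridges, hydrogen-bond
distance criteria, Calpha separations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ContactMatrix,
    DensityMap,
    DistanceSeries,
    DistanceTable,
    PlanarTrack,
    ResidueContactProfile,
)

__all__ = [
    "DEFAULT_CUTOFF",
    "compute_contact_matrix",
    "lipid_count_timeseries",
    "contact_profiles",
    "species_contact_fractions",
    "density_map_2d",
    "pair_distance_stats",
    "longest_run_lengths",
]

#: Contact cutoff in nm: two particles closer than this are in contact.
DEFAULT_CUTOFF = 0.6


def compute_contact_matrix(table: DistanceTable, cutoff: float = DEFAULT_CUTOFF) -> ContactMatrix:
    """Threshold a distance table into a boolean contact mask.

    The inequality is strict: distance < cutoff counts as a contact, a
    distance exactly at the cutoff does not.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if table.n_frames == 0:
        raise ValueError("empty distance table")
    return ContactMatrix(
        mask=table.distances < cutoff,
        cutoff=cutoff,
        times=table.times,
        lipid_species=table.lipid_species,
        residue_ids=table.residue_ids,
        repeat=table.repeat,
    )


@dataclass
class LipidCountResult:
    """Per-repeat lipid counts near the protein with cross-repeat summary."""

    times: np.ndarray  # ns
    counts: np.ndarray  # (n_repeats, n_frames)
    mean: np.ndarray  # (n_frames,)
    sd: np.ndarray  # (n_frames,)
    species: str


def lipid_count_timeseries(
    tables: list[DistanceTable] | DistanceTable,
    cutoff: float = DEFAULT_CUTOFF,
    species: str = "PIP2",
) -> LipidCountResult:
    """Number of lipids of a species within the cutoff of the protein, per frame.

    A lipid counts at frame t iff its minimum distance over residues is
    below the cutoff. With several repeats the mean and population SD
    across repeats are reported alongside the per-repeat counts.
    """
    if isinstance(tables, DistanceTable):
        tables = [tables]
    if not tables:
        raise ValueError("no tables given")
    per_repeat = []
    for table in tables:
        idx = table.species_index(species)
        mind = table.distances[:, idx, :].min(axis=2)  # (frames, lipids)
        per_repeat.append((mind < cutoff).sum(axis=1))
    counts = np.asarray(per_repeat, dtype=float)
    return LipidCountResult(
        times=tables[0].times,
        counts=counts,
        mean=counts.mean(axis=0),
        sd=counts.std(axis=0),
        species=species,
    )


def longest_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Longest run of True along axis 0, per remaining index.

    ``mask`` is (n_frames, ...); returns the per-column maximum run
    length in frames.
    """
    mask = np.asarray(mask, dtype=bool)
    out_shape = mask.shape[1:]
    run = np.zeros(out_shape, dtype=int)
    best = np.zeros(out_shape, dtype=int)
    for f in range(mask.shape[0]):
        run = np.where(mask[f], run + 1, 0)
        best = np.maximum(best, run)
    return best


def contact_profiles(
    cm: ContactMatrix,
    species: str,
    window: tuple[float, float] | None = None,
    normalise: bool = True,
) -> ResidueContactProfile:
    """Per-residue contact duration and maximum occupancy for one species.

    contact_duration(r) = dt x number of frames in the window where any
    lipid of the species touches residue r. max_occupancy(r) = dt x the
    longest contiguous run of frames in which one particular lipid
    touches r. With ``normalise`` both profiles are divided by their
    maximum over residues so the peak residue reads 1.0.

    By default the window discards the first quarter of the frames as
    equilibration; pass an explicit ``(t_start, t_end)`` in ns to
    override.
    """
    times = cm.times
    if window is None:
        t0 = times[0] + 0.25 * (times[-1] - times[0])
        window = (float(t0), float(times[-1]))
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("zero-length analysis window")
    if t_start < times[0] - 1e-9 or t_end > times[-1] + 1e-9:
        raise ValueError("window outside the data time span")
    in_win = (times >= t_start) & (times <= t_end)
    idx = cm.species_index(species)
    sub = cm.mask[np.ix_(np.flatnonzero(in_win), idx, np.arange(cm.mask.shape[2]))]
    dt = cm.dt if cm.dt > 0 else 1.0

    duration = dt * sub.any(axis=1).sum(axis=0).astype(float)  # (n_residues,)
    max_occ = dt * longest_run_lengths(sub).max(axis=0).astype(float)

    norm_dur = norm_occ = None
    if normalise:
        norm_dur = duration / duration.max() if duration.max() > 0 else duration.copy()
        norm_occ = max_occ / max_occ.max() if max_occ.max() > 0 else max_occ.copy()
    return ResidueContactProfile(
        residue_ids=cm.residue_ids,
        contact_duration=duration,
        max_occupancy=max_occ,
        window=(float(t_start), float(t_end)),
        species=species,
        normalised_duration=norm_dur,
        normalised_occupancy=norm_occ,
    )


@dataclass
class SpeciesFractionResult:
    """Relative contribution of each species to the contacts at residues."""

    residue_ids: np.ndarray
    species: list
    fractions: np.ndarray  # (n_species, n_residues), columns sum to 1 or 0
    no_contact: np.ndarray  # (n_residues,) bool, True where nothing ever touched


def species_contact_fractions(
    cm: ContactMatrix, residues: np.ndarray | list
) -> SpeciesFractionResult:
    """Fraction of contact-frames each lipid species contributes per residue.

    fraction(species, r) = contact-frames of that species at r divided by
    the total contact-frames of all species at r. Residues that are never
    contacted report zeros and are flagged in ``no_contact``.
    """
    residues = np.asarray(residues)
    if residues.size == 0:
        raise ValueError("residue subset must not be empty")
    res_pos = np.array([np.flatnonzero(cm.residue_ids == r)[0] for r in residues])
    species = sorted(set(cm.lipid_species.tolist()))
    counts = np.zeros((len(species), residues.size))
    for i, sp in enumerate(species):
        lip = np.flatnonzero(cm.lipid_species == sp)
        # every (frame, lipid) contact counts one frame toward the species
        counts[i] = cm.mask[:, lip, :][:, :, res_pos].sum(axis=(0, 1))
    totals = counts.sum(axis=0)
    no_contact = totals == 0
    fractions = np.divide(
        counts, totals, out=np.zeros_like(counts), where=totals > 0
    )
    return SpeciesFractionResult(
        residue_ids=residues, species=species, fractions=fractions, no_contact=no_contact
    )


def density_map_2d(
    tracks: list[PlanarTrack] | PlanarTrack,
    species: str,
    leaflet: str = "lower",
    bin_size: float = 0.5,
) -> DensityMap:
    """Time-averaged planar lipid density for one species and leaflet.

    Each frame increments the bin containing each matching lipid; counts
    are divided by the number of frames and averaged across repeats, so
    the map sums to the mean number of tracked lipids per frame (mass
    conservation).
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if isinstance(tracks, PlanarTrack):
        tracks = [tracks]
    box = np.asarray(tracks[0].box_xy, dtype=float)
    nx = max(1, int(np.ceil(box[0] / bin_size)))
    ny = max(1, int(np.ceil(box[1] / bin_size)))
    x_edges = np.linspace(0.0, box[0], nx + 1)
    y_edges = np.linspace(0.0, box[1], ny + 1)

    acc = np.zeros((nx, ny))
    matched_any = False
    for track in tracks:
        sel = (track.species == species) & (track.leaflet == leaflet)
        if not np.any(sel):
            continue
        matched_any = True
        pts = track.xy[:, sel, :].reshape(-1, 2)
        h, _, _ = np.histogram2d(
            np.clip(pts[:, 0], 0, box[0]), np.clip(pts[:, 1], 0, box[1]),
            bins=[x_edges, y_edges],
        )
        acc += h / track.n_frames
    if not matched_any:
        raise ValueError(f"no lipid matches species={species!r} leaflet={leaflet!r}")
    return DensityMap(
        counts=acc / len(tracks),
        bin_size=bin_size,
        extent=(0.0, float(box[0]), 0.0, float(box[1])),
        species=species,
        leaflet=leaflet,
        n_repeats=len(tracks),
    )


@dataclass
class PairDistanceResult:
    """Histogram of a pair-distance series plus the formed-state fraction."""

    edges: np.ndarray  # nm
    counts: np.ndarray
    formed_fraction: float
    formed_cutoff: float  # nm
    label: str


def pair_distance_stats(
    series: DistanceSeries,
    bins: int | np.ndarray = 50,
    formed_cutoff: float = 0.45,
) -> PairDistanceResult:
    """Distance histogram and fraction of frames below a formed cutoff.

    Used for salt-bridge stability (e.g. an arginine-glutamate pair),
    hydrogen-bond distance criteria (0.35 nm cutoff) and Calpha
    separations alike; the interaction is "formed" in a frame when the
    distance is strictly below the cutoff.
    """
    if formed_cutoff <= 0:
        raise ValueError("formed_cutoff must be positive")
    if series.distance.size == 0:
        raise ValueError("empty distance series")
    counts, edges = np.histogram(series.distance, bins=bins)
    formed = float(np.mean(series.distance < formed_cutoff))
    return PairDistanceResult(
        edges=edges,
        counts=counts,
        formed_fraction=formed,
        formed_cutoff=formed_cutoff,
        label=series.label,
    )
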