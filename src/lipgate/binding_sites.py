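"""Long-lived lipid binding events and their clustering into binding sites.

The procedure: (1) per lipid, contiguous runs of frames with the lipid
within the contact cutoff of any residue become binding events, kept only
when they persist beyond a minimum duration (10 us by default); (2) each
event's binary residue x time fingerprint is condensed into a residue
co-occurrence (adjacency) matrix by pairwise Pearson correlation of the
residue rows, with a zero convention for residues that never make
contact; (3) pairs of events are compared by the phi (Matthews)
coefficient of their binarised adjacencies; (4) events are agglomerated
by single-linkage hierarchical clustering on distance 1 - phi, with the
default cut joining events only through positive phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

from .core import DistanceTable
from .lipid_contacts import DEFAULT_CUTOFF

__all__ = [
    "DEFAULT_MIN_DURATION",
    "BindingEvent",
    "CooccurrenceMatrix",
    "EventSimilarityMatrix",
    "ClusterResult",
    "SitePipelineConfig",
    "SitePipelineResult",
    "extract_binding_events",
    "residue_cooccurrence",
    "event_similarity",
    "similarity_matrix",
    "cluster_events",
    "site_pipeline",
    "phi_coefficient",
]

#: Persistence filter in ns: only interactions longer than 10 us are analysed.
DEFAULT_MIN_DURATION = 10_000.0


@dataclass
class BindingEvent:
    """One lipid's contiguous interaction interval with the protein."""

    lipid: int
    species: str
    repeat: int
    t_start: float  # ns
    t_end: float  # ns (exclusive end: t_start + n_frames * dt)
    fingerprint: np.ndarray  # (n_residues, n_event_frames) bool
    residue_ids: np.ndarray

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=bool)
        if self.duration <= 0:
            raise ValueError("event duration must be positive")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_frames(self) -> int:
        return self.fingerprint.shape[1]

    @property
    def contacted_residues(self) -> np.ndarray:
        """Residue ids with at least one contact frame in this event."""
        return self.residue_ids[self.fingerprint.any(axis=1)]


@dataclass
class CooccurrenceMatrix:
    """Residue x residue Pearson co-occurrence of one binding event."""

    values: np.ndarray  # symmetric, in [-1, 1]
    residue_ids: np.ndarray
    contacting: np.ndarray  # (n_residues,) bool


@dataclass
class EventSimilarityMatrix:
    """Pairwise phi coefficients between binding events."""

    values: np.ndarray  # (n_events, n_events), symmetric, unit diagonal
    flagged_constant: np.ndarray  # bool mask of pairs where phi fell back to 0


@dataclass
class ClusterResult:
    """Single-linkage clustering of binding events."""

    labels: np.ndarray  # (n_events,) cluster ids starting at 1
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: np.ndarray  # dendrogram leaf order for matrix display
    consensus_residues: dict = field(default_factory=dict)  # label -> residue ids


def _runs_with_gaps(occupied: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal runs of True, bridging internal False gaps <= gap_tolerance.

    Returns inclusive (start, end) frame pairs.
    """
    idx = np.flatnonzero(occupied)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > gap_tolerance + 1)
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def extract_binding_events(
    table: DistanceTable,
    cutoff: float = DEFAULT_CUTOFF,
    min_duration: float = DEFAULT_MIN_DURATION,
    gap_tolerance: int = 0,
    species: str | None = "PIP2",
) -> list[BindingEvent]:
    """Extract per-lipid binding events longer than ``min_duration`` (ns).

    A lipid interacts with the protein at a frame when its minimum
    distance over all residues is below ``cutoff``. Internal gaps of at
    most ``gap_tolerance`` frames above the cutoff are bridged. The
    duration of a run of k frames is k * dt, and only events with
    duration strictly greater than ``min_duration`` are returned.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be non-negative")
    dt = table.dt if table.dt > 0 else 1.0
    lipids = (
        np.flatnonzero(table.lipid_species == species)
        if species is not None
        else np.arange(table.n_lipids)
    )
    contact = table.distances < cutoff  # (frames, lipids, residues)
    events: list[BindingEvent] = []
    for lip in lipids:
        occupied = contact[:, lip, :].any(axis=1)
        for f0, f1 in _runs_with_gaps(occupied, gap_tolerance):
            duration = (f1 - f0 + 1) * dt
            if duration > min_duration:
                events.append(
                    BindingEvent(
                        lipid=int(lip),
                        species=str(table.lipid_species[lip]),
                        repeat=table.repeat,
                        t_start=float(table.times[f0]),
                        t_end=float(table.times[f0] + duration),
                        fingerprint=contact[f0 : f1 + 1, lip, :].T,
                        residue_ids=table.residue_ids,
                    )
                )
    return events


def residue_cooccurrence(event: BindingEvent) -> CooccurrenceMatrix:
    """Pearson correlation between the residue rows of an event fingerprint.

    Any pair involving a constant row (a residue always or never in
    contact over the event) is 0 by convention, except the diagonal,
    which is 1 for contacting residues and 0 for residues that never
    contact the lipid during the event.
    """
    b = event.fingerprint.astype(float)
    if b.shape[1] < 2:
        raise ValueError("co-occurrence needs an event with at least 2 frames")
    contacting = event.fingerprint.any(axis=1)
    centred = b - b.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    unit = centred / safe[:, None]
    corr = unit @ unit.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, np.where(contacting, 1.0, 0.0))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CooccurrenceMatrix(values=corr, residue_ids=event.residue_ids, contacting=contacting)


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Phi (Matthews) coefficient of two binary vectors.

    phi = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)). A
    constant vector makes the denominator zero; the convention here is
    phi = 0 with a flag, mirroring the Pearson zero convention.
    """
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    tp = float(np.sum(a & b))
    tn = float(np.sum(~a & ~b))
    fp = float(np.sum(~a & b))
    fn = float(np.sum(a & ~b))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0, True
    return (tp * tn - fp * fn) / np.sqrt(denom), False


def _binarised_vector(
    adj: CooccurrenceMatrix, triangle: str, include_diagonal: bool
) -> np.ndarray:
    m = adj.values > 0
    n = m.shape[0]
    if triangle == "upper":
        k = 0 if include_diagonal else 1
        iu = np.triu_indices(n, k=k)
        return m[iu]
    if triangle == "full":
        return m.ravel()
    raise ValueError("triangle must be 'upper' or 'full'")


def event_similarity(
    adj_a: CooccurrenceMatrix,
    adj_b: CooccurrenceMatrix,
    triangle: str = "upper",
    include_diagonal: bool = True,
) -> tuple[float, bool]:
    """Phi coefficient between two binarised adjacency matrices.

    Entries > 0 (simultaneous-contact evidence) are binarised to 1; the
    upper triangle including the diagonal is flattened by default.
    Returns (phi, flagged) with flagged True when either vector is
    constant and phi fell back to the 0 convention.
    """
    if adj_a.values.shape != adj_b.values.shape:
        raise ValueError("adjacency matrices must share the residue universe")
    va = _binarised_vector(adj_a, triangle, include_diagonal)
    vb = _binarised_vector(adj_b, triangle, include_diagonal)
    return phi_coefficient(va, vb)


def similarity_matrix(
    adjacencies: list[CooccurrenceMatrix],
    triangle: str = "upper",
    include_diagonal: bool = True,
) -> EventSimilarityMatrix:
    """All-pairs phi similarity between event adjacency matrices."""
    n = len(adjacencies)
    values = np.eye(n)
    flagged = np.zeros((n, n), dtype=bool)
    vecs = [_binarised_vector(a, triangle, include_diagonal) for a in adjacencies]
    for i in range(n):
        for j in range(i + 1, n):
            phi, flag = phi_coefficient(vecs[i], vecs[j])
            values[i, j] = values[j, i] = phi
            flagged[i, j] = flagged[j, i] = flag
    return EventSimilarityMatrix(values=values, flagged_constant=flagged)


def cluster_events(
    sim: EventSimilarityMatrix,
    cut: float | None = None,
    n_clusters: int | None = None,
    events: list[BindingEvent] | None = None,
    consensus_threshold: float = 0.5,
) -> ClusterResult:
    """Single-linkage clustering of events on distance d = 1 - phi.

    The default cut joins events only through positive phi (merges at
    d < 1), so clusters are the single-linkage groups connected by
    positive similarity. Pass ``cut`` (a distance level) or
    ``n_clusters`` to override. When the originating events are given,
    each cluster also reports a consensus residue set: residues
    contacted in at least ``consensus_threshold`` of its member events.
    """
    values = sim.values
    n = values.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 events")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    iu = np.triu_indices(n, k=1)
    z = hierarchy.linkage(dist[iu], method="single")
    leaf_order = hierarchy.leaves_list(z)
    if n_clusters is not None:
        labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        level = (1.0 - 1e-9) if cut is None else cut
        labels = hierarchy.fcluster(z, t=level, criterion="distance")

    consensus: dict[int, np.ndarray] = {}
    if events is not None:
        if len(events) != n:
            raise ValueError("event list does not match similarity matrix")
        for lab in np.unique(labels):
            members = [events[i] for i in np.flatnonzero(labels == lab)]
            counts = np.zeros(members[0].residue_ids.size)
            for ev in members:
                counts += ev.fingerprint.any(axis=1)
            consensus[int(lab)] = members[0].residue_ids[
                counts / len(members) >= consensus_threshold
            ]
    return ClusterResult(
        labels=labels, linkage=z, leaf_order=leaf_order, consensus_residues=consensus
    )


@dataclass
class SitePipelineConfig:
    """Knobs of the end-to-end binding-site pipeline."""

    cutoff: float = DEFAULT_CUTOFF  # nm
    min_duration: float = DEFAULT_MIN_DURATION  # ns
    gap_tolerance: int = 0  # frames
    species: str = "PIP2"
    triangle: str = "upper"
    include_diagonal: bool = True
    cut: float | None = None
    n_clusters: int | None = None
    consensus_threshold: float = 0.5


@dataclass
class SitePipelineResult:
    """Events, similarity, clusters and summary of the site pipeline."""

    events: list
    similarity: EventSimilarityMatrix | None
    clusters: ClusterResult | None
    n_events: int
    durations: np.ndarray  # ns
    notice: str = ""


def site_pipeline(
    tables: list[DistanceTable] | DistanceTable,
    cfg: SitePipelineConfig | None = None,
) -> SitePipelineResult:
    """Run extraction, co-occurrence, phi similarity and clustering.

    Accepts one table or a list of per-repeat tables; events are never
    merged across repeats or lipids. With fewer than 2 surviving events
    the similarity and clustering stages are skipped with a notice.
    """
    cfg = cfg or SitePipelineConfig()
    if isinstance(tables, DistanceTable):
        tables = [tables]
    events: list[BindingEvent] = []
    for table in tables:
        events.extend(
            extract_binding_events(
                table,
                cutoff=cfg.cutoff,
                min_duration=cfg.min_duration,
                gap_tolerance=cfg.gap_tolerance,
                species=cfg.species,
            )
        )
    durations = np.array([ev.duration for ev in events])
    if len(events) == 0:
        return SitePipelineResult(
            events=[], similarity=None, clusters=None, n_events=0,
            durations=durations,
            notice="no binding event survived the persistence filter",
        )
    if len(events) == 1:
        return SitePipelineResult(
            events=events, similarity=None, clusters=None, n_events=1,
            durations=durations,
            notice="only one event; clustering skipped",
        )
    adjacencies = [residue_cooccurrence(ev) for ev in events]
    sim = similarity_matrix(
        adjacencies, triangle=cfg.triangle, include_diagonal=cfg.include_diagonal
    )
    clusters = cluster_events(
        sim,
        cut=cfg.cut,
        n_clusters=cfg.n_clusters,
        events=events,
        consensus_threshold=cfg.consensus_threshold,
    )
    return SitePipelineResult(
        events=events,
        similarity=sim,
        clusters=clusters,
        n_events=len(events),
        durations=durations,
    )
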