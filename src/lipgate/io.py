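"""Readers and writers for the formats the pipeline consumes and emits.

Reads: the GROMACS .xvg dialect produced by ``gmx mindist -respertime``
(``#`` and ``@`` comment lines, time in the first column, one distance
column per residue, residue names recoverable from the legend), plain
TSV tables, and a named-array .npz container for whole distance tables,
tracks and traces. Writes: TSV profiles/events/matrices, density maps as
matrix text with a header, and JSON manifests recording config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChannelTrace, DistanceTable, PlanarTrack
from .lipid_contacts import PairDistanceResult
from .core import DensityMap, ResidueContactProfile

__all__ = [
    "read_xvg",
    "read_mindist_xvg",
    "assemble_distance_table",
    "save_distance_table",
    "load_distance_table",
    "save_planar_track",
    "load_planar_track",
    "read_trace_tsv",
    "write_trace_tsv",
    "save_trace",
    "load_trace",
    "read_abf",
    "write_events_tsv",
    "write_profile_tsv",
    "write_density_map",
    "write_matrix_tsv",
    "write_manifest",
    "linkage_to_newick",
]

_LEGEND_RE = re.compile(r'@\s*s(\d+)\s+legend\s+"([^"]*)"')


def read_xvg(path: str | Path) -> tuple[np.ndarray, dict[int, str]]:
    """Parse an .xvg file into a data array and its column legends.

    Returns ``(data, legends)`` where data is (n_rows, n_cols) with the
    time axis in column 0, and legends maps data-set index (column 1 is
    set 0) to its legend string when present.
    """
    legends: dict[int, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                m = _LEGEND_RE.match(line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                continue
            rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    return np.asarray(rows), legends


def read_mindist_xvg(path: str | Path, time_unit: float = 1e-3) -> pd.DataFrame:
    """Read a ``gmx mindist -respertime`` .xvg as a tidy DataFrame.

    Columns: time (ns) as the index and one distance column (nm) per
    residue, named from the legend when available. ``time_unit``
    converts the file's time column to ns (GROMACS writes ps by
    default, hence 1e-3).
    """
    data, legends = read_xvg(path)
    n_res = data.shape[1] - 1
    names = [legends.get(i, f"res{i}") for i in range(n_res)]
    df = pd.DataFrame(data[:, 1:], columns=names)
    df.index = pd.Index(data[:, 0] * time_unit, name="time_ns")
    return df


def assemble_distance_table(
    lipid_frames: list[tuple[str, pd.DataFrame]],
    repeat: int = 0,
) -> DistanceTable:
    """Stack per-lipid residue-distance frames into a DistanceTable.

    ``lipid_frames`` is a list of (species, frame) pairs as returned by
    :func:`read_mindist_xvg`, one per lipid, sharing the same time axis
    and residue columns.
    """
    if not lipid_frames:
        raise ValueError("no lipid frames given")
    species = [sp for sp, _ in lipid_frames]
    first = lipid_frames[0][1]
    distances = np.stack([df.to_numpy() for _, df in lipid_frames], axis=1)
    return DistanceTable(
        times=first.index.to_numpy(),
        distances=distances,
        lipid_species=np.asarray(species, dtype=object),
        residue_ids=first.columns.to_numpy(),
        repeat=repeat,
    )


def save_distance_table(path: str | Path, table: DistanceTable) -> None:
    np.savez_compressed(
        path,
        times=table.times,
        distances=table.distances,
        lipid_species=np.asarray(table.lipid_species, dtype=str),
        residue_ids=table.residue_ids,
        repeat=np.array(table.repeat),
    )


def load_distance_table(path: str | Path) -> DistanceTable:
    with np.load(path, allow_pickle=False) as z:
        return DistanceTable(
            times=z["times"],
            distances=z["distances"],
            lipid_species=z["lipid_species"].astype(object),
            residue_ids=z["residue_ids"],
            repeat=int(z["repeat"]),
        )


def save_planar_track(path: str | Path, track: PlanarTrack) -> None:
    np.savez_compressed(
        path,
        times=track.times,
        xy=track.xy,
        leaflet=np.asarray(track.leaflet, dtype=str),
        species=np.asarray(track.species, dtype=str),
        box_xy=np.asarray(track.box_xy),
        repeat=np.array(track.repeat),
    )


def load_planar_track(path: str | Path) -> PlanarTrack:
    with np.load(path, allow_pickle=False) as z:
        return PlanarTrack(
            times=z["times"],
            xy=z["xy"],
            leaflet=z["leaflet"].astype(object),
            species=z["species"].astype(object),
            box_xy=tuple(z["box_xy"]),
            repeat=int(z["repeat"]),
        )


def read_trace_tsv(path: str | Path) -> ChannelTrace:
    """Read a two-column trace TSV (time s, current pA).

    The header comment lines carry ``sample_rate_hz`` and
    ``holding_potential_mv`` as ``# key: value`` pairs; when the rate is
    absent it is inferred from the time column.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, val = line[1:].split(":", 1)
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
    df = pd.read_csv(path, sep="\t", comment="#")
    t = df.iloc[:, 0].to_numpy()
    i = df.iloc[:, 1].to_numpy()
    rate = meta.get("sample_rate_hz")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    return ChannelTrace(
        current=i,
        sample_rate=float(rate),
        holding_potential=float(meta.get("holding_potential_mv", 0.0)),
    )


def write_trace_tsv(path: str | Path, trace: ChannelTrace) -> None:
    t = np.arange(trace.n_samples) / trace.sample_rate
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {trace.sample_rate}\n")
        fh.write(f"# holding_potential_mv: {trace.holding_potential}\n")
        fh.write("time_s\tcurrent_pA\n")
        for ti, ii in zip(t, trace.current):
            fh.write(f"{ti:.8g}\t{ii:.6g}\n")


def save_trace(path: str | Path, trace: ChannelTrace) -> None:
    kwargs = dict(
        current=trace.current,
        sample_rate=np.array(trace.sample_rate),
        holding_potential=np.array(trace.holding_potential),
    )
    if trace.state_path is not None:
        kwargs["state_path"] = trace.state_path
    if trace.state_levels is not None:
        kwargs["state_levels"] = trace.state_levels
    np.savez_compressed(path, **kwargs)


def load_trace(path: str | Path) -> ChannelTrace:
    with np.load(path, allow_pickle=False) as z:
        return ChannelTrace(
            current=z["current"],
            sample_rate=float(z["sample_rate"]),
            holding_potential=float(z["holding_potential"]),
            state_path=z["state_path"] if "state_path" in z else None,
            state_levels=z["state_levels"] if "state_levels" in z else None,
        )


def read_abf(path: str | Path, sweep: int = 0) -> ChannelTrace:
    """Read one sweep of an Axon Binary Format file, if pyabf is installed.

    ABF support is optional: a clear ImportError is raised when no
    reader is available at runtime.
    """
    try:
        import pyabf  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading ABF files requires the optional pyabf package"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover
    abf.setSweep(sweep)  # pragma: no cover
    return ChannelTrace(  # pragma: no cover
        current=np.asarray(abf.sweepY, dtype=float),
        sample_rate=float(abf.dataRate),
    )


def write_events_tsv(path: str | Path, events: list) -> None:
    """Events table: lipid, species, repeat, start, end, duration, residues."""
    columns = [
        "lipid", "species", "repeat", "t_start_ns", "t_end_ns",
        "duration_ns", "residues",
    ]
    rows = [
        {
            "lipid": ev.lipid,
            "species": ev.species,
            "repeat": ev.repeat,
            "t_start_ns": ev.t_start,
            "t_end_ns": ev.t_end,
            "duration_ns": ev.duration,
            "residues": ",".join(str(r) for r in ev.contacted_residues),
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_profile_tsv(path: str | Path, profile: ResidueContactProfile) -> None:
    df = pd.DataFrame(
        {
            "residue": profile.residue_ids,
            "contact_duration_ns": profile.contact_duration,
            "max_occupancy_ns": profile.max_occupancy,
        }
    )
    if profile.normalised_duration is not None:
        df["norm_duration"] = profile.normalised_duration
        df["norm_occupancy"] = profile.normalised_occupancy
    with open(path, "w") as fh:
        fh.write(f"# species: {profile.species}\n")
        fh.write(f"# window_ns: {profile.window[0]} {profile.window[1]}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_density_map(path: str | Path, dmap: DensityMap) -> None:
    header = (
        f"species: {dmap.species}\nleaflet: {dmap.leaflet}\n"
        f"bin_size_nm: {dmap.bin_size}\n"
        f"extent_nm: {' '.join(f'{v:g}' for v in dmap.extent)}\n"
        f"n_repeats: {dmap.n_repeats}\n"
        "rows are x bins, columns are y bins; mean lipids per bin per frame"
    )
    np.savetxt(path, dmap.counts, header=header)


def write_matrix_tsv(path: str | Path, values: np.ndarray, labels=None) -> None:
    df = pd.DataFrame(values)
    if labels is not None:
        df.index = labels
        df.columns = labels
    df.to_csv(path, sep="\t")


def write_manifest(path: str | Path, config, seed: int | None = None) -> None:
    """JSON manifest of a generator config (dataclasses serialised)."""

    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"cannot serialise {type(obj)}")

    payload = {"config": config, "seed": seed}
    Path(path).write_text(json.dumps(payload, default=default, indent=2))


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string.

    Leaves sit at height 0; each branch length is the merge-height
    difference between parent and child.
    """
    n = len(labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(linkage[node - n, 2])

    def build(node: int, parent_height: float) -> str:
        h = height(node)
        if node < n:
            body = labels[node]
        else:
            left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
            body = f"({build(left, h)},{build(right, h)})"
        return f"{body}:{parent_height - h:.6g}"

    root = 2 * n - 2
    return build(root, height(root)) + ";"
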