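"""Plain-text snapshot and mask output: columnar tables and legacy VTK.

Snapshots are whitespace-separated columns (id, x, y, vx, vy, damage, flag)
with a ``#``-comment header carrying time and expansion metadata; the same
format round-trips through :func:`read_snapshot`.  Particle clouds can also
be written as legacy-ASCII VTK polydata for visualization.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_snapshot(path, snapshot, membrane) -> None:
    """Write one trajectory snapshot as a columnar text table."""
    n = snapshot.positions.shape[0]
    flags = np.zeros(n, dtype=int)
    flags[membrane.boundary_layer_ids] = 1
    flags[membrane.pinned_ids] = 2
    header = (f"time = {float(snapshot.time)!r}\n"
              f"expansion = {float(snapshot.expansion)!r}\n"
              f"broken_bonds_total = {snapshot.broken_bonds_total}\n"
              "columns: id x y vx vy damage flag  "
              "(flag: 0 interior, 1 driven layer, 2 pinned)")
    data = np.column_stack([
        np.arange(n), snapshot.positions, snapshot.velocities,
        snapshot.damage, flags])
    np.savetxt(path, data, header=header,
               fmt=["%d", "%.10g", "%.10g", "%.10g", "%.10g", "%.6g", "%d"])


def read_snapshot(path):
    """Read a columnar snapshot back as a dict of arrays and metadata."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if "=" in stripped:
                key, val = stripped.split("=", 1)
                meta[key.strip()] = float(val)
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    return {
        "ids": data[:, 0].astype(int),
        "positions": data[:, 1:3],
        "velocities": data[:, 3:5],
        "damage": data[:, 5],
        "flags": data[:, 6].astype(int),
        "time": meta.get("time", 0.0),
        "expansion": meta.get("expansion", 1.0),
    }


def write_membrane_table(path, membrane, network=None) -> None:
    """Columnar text dump of the reference lattice (id, x, y, flags, bonds)."""
    n = membrane.n_particles
    flags = np.zeros(n, dtype=int)
    flags[membrane.boundary_layer_ids] = 1
    flags[membrane.pinned_ids] = 2
    cols = [np.arange(n), membrane.positions_ref[:, 0],
            membrane.positions_ref[:, 1], flags]
    fmt = ["%d", "%.10g", "%.10g", "%d"]
    header = (f"h = {membrane.spacing_h}\ndiameter_0 = {membrane.diameter_0}\n"
              "columns: id x y flag")
    if network is not None:
        cols.append(network.initial_bond_count)
        fmt.append("%d")
        header += " n_bonds"
    np.savetxt(path, np.column_stack(cols), header=header, fmt=fmt)


def write_vtk_polydata(path, positions: np.ndarray,
                       point_data: dict[str, np.ndarray] | None = None,
                       description: str = "perimem particles") -> None:
    """Legacy-ASCII VTK polydata of a particle cloud with scalar fields."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{description}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for x, y in positions:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(values, dtype=float):
                    fh.write(f"{v:.6g}\n")


def write_mask_png(path, mask) -> None:
    """1-bit PNG of a rupture mask (occupied pixels white)."""
    from PIL import Image
    img = Image.fromarray(mask.pixels.T[::-1].astype(np.uint8) * 255).convert("1")
    img.save(path)


def write_trajectory(outdir, trajectory) -> None:
    """Write every snapshot of a trajectory (text + VTK) plus a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, snap in enumerate(trajectory.snapshots):
        write_snapshot(outdir / f"snapshot_{k:04d}.txt", snap,
                       trajectory.membrane)
        write_vtk_polydata(outdir / f"snapshot_{k:04d}.vtk", snap.positions,
                           {"damage": snap.damage})
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"status = {trajectory.status}\n")
        fh.write(f"accepted_steps = {trajectory.accepted_steps}\n")
        fh.write(f"rejected_steps = {trajectory.rejected_steps}\n")
        fh.write(f"final_expansion = {float(trajectory.final.expansion)!r}\n")
        fh.write(f"final_time = {float(trajectory.final.time)!r}\n")
        fh.write("# t  dt\n")
        for t, dt in trajectory.dt_history[:: max(1, len(trajectory.dt_history) // 2000)]:
            fh.write(f"{t:.8g} {dt:.4g}\n")
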