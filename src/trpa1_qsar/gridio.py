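"""Plain-text OpenDX regular-grid export of per-point scalar fields.

Writes the classic ``gridpositions``/``gridconnections`` OpenDX layout that
molecular-graphics programs (PyMOL, VMD, Chimera) read for isosurface
display. The package's internal point order is x-fastest; OpenDX stores
z-fastest, so values are reordered on the way out and back in.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fields import GridSpec

__all__ = ["write_dx", "read_dx"]


def _x_fastest_to_dx(values: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = dims
    # internal flat index = ix + nx*(iy + ny*iz) -> array indexed [iz,iy,ix]
    return values.reshape(nz, ny, nx).transpose(2, 1, 0).ravel()


def _dx_to_x_fastest(values: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = dims
    return values.reshape(nx, ny, nz).transpose(2, 1, 0).ravel()


def write_dx(path: str | Path, values: np.ndarray, grid: GridSpec,
             metadata: dict | None = None) -> None:
    """Write one scalar field (internal x-fastest order) as an OpenDX file."""
    values = np.asarray(values, float)
    if values.size != grid.n_points:
        raise ValueError(f"expected {grid.n_points} values, got {values.size}")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    lines = []
    if metadata:
        for k, v in metadata.items():
            lines.append(f"# {k}: {v}")
    lines += [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    dxvals = _x_fastest_to_dx(values, grid.dims)
    for i in range(0, dxvals.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in dxvals[i : i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_dx(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an OpenDX file written by :func:`write_dx`."""
    dims = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("object 1"):
            dims = tuple(int(x) for x in line.split()[-3:])
        elif line.startswith("origin"):
            origin = tuple(float(x) for x in line.split()[1:])
        elif line.startswith("delta"):
            deltas.append([float(x) for x in line.split()[1:]])
        elif "data follows" in line:
            n_items = int(line.split()[-3])
        elif n_items is not None and len(data) < n_items:
            if line.startswith(("attribute", "object", "component")):
                continue
            data.extend(float(x) for x in line.split())
    if dims is None or origin is None or n_items is None:
        raise ValueError(f"not a regular-grid OpenDX file: {path}")
    spacing = float(deltas[0][0])
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims, margin=0.0)
    values = _dx_to_x_fastest(np.array(data[:n_items]), dims)
    return values, grid
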