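"""Molecular interaction fields on a rectangular lattice.

CoMFA channels are probe-atom interaction energies in kcal/mol:

* steric   — Lennard-Jones 6-12, ``E = sum_i eps_i [(R*_i/r_i)^12 - 2 (R*_i/r_i)^6]``
* electrostatic — Coulomb with distance-dependent dielectric D(r) = r,
  ``E = sum_i 332.0636 q_i q_probe / r_i^2``

both truncated at +/-30 kcal/mol, the conventional cutoff. CoMSIA channels
are Gaussian similarity indices, ``A(q) = -sum_i w_probe w_i exp(-alpha r_iq^2)``
with attenuation factor alpha = 0.3 A^-2; they are finite everywhere and need
no truncation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .prep import Conformer

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldMatrix",
    "COMFA_CHANNELS",
    "COMSIA_CHANNELS",
    "ALL_CHANNELS",
    "make_grid",
    "comfa_steric",
    "comfa_electrostatic",
    "comsia_field",
    "assemble_field_matrix",
    "save_field_matrix",
    "load_field_matrix",
]

COULOMB_CONSTANT = 332.0636     # kcal mol^-1 A e^-2
ENERGY_TRUNCATION = 30.0        # kcal/mol
ATTENUATION_ALPHA = 0.3         # A^-2

COMFA_CHANNELS = ("comfa_steric", "comfa_elec")
COMSIA_CHANNELS = (
    "comsia_steric",
    "comsia_electrostatic",
    "comsia_hydrophobic",
    "comsia_donor",
    "comsia_acceptor",
)
ALL_CHANNELS = COMFA_CHANNELS + COMSIA_CHANNELS

CHANNEL_UNITS = {c: "kcal/mol" for c in COMFA_CHANNELS}
CHANNEL_UNITS.update({c: "similarity index" for c in COMSIA_CHANNELS})


@dataclass(frozen=True)
class GridSpec:
    """World-axis-aligned lattice; points enumerated x-fastest."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]
    margin: float

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), x varying fastest."""
        nx, ny, nz = self.dims
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        # x-fastest: flat index = ix + nx*(iy + ny*iz)
        grid = np.stack(np.meshgrid(ix, iy, iz, indexing="ij"), axis=-1)
        pts = grid.transpose(2, 1, 0, 3).reshape(-1, 3).astype(float)
        return np.asarray(self.origin, float) + pts * self.spacing


@dataclass(frozen=True)
class ProbeSpec:
    """The CoMFA/CoMSIA probe: sp3 carbon, +1 e, radius 1.0 A, unit weights."""

    element: str = "C"
    charge: float = 1.0
    radius: float = 1.0
    r_star: float = 1.70        # LJ parameters of an sp3 carbon probe
    epsilon: float = 0.107
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "steric": 1.0,
            "electrostatic": 1.0,
            "hydrophobic": 1.0,
            "donor": 1.0,
            "acceptor": 1.0,
        }
    )


def make_grid(
    conformers: Sequence[Conformer], spacing: float = 1.0, margin: float = 4.0
) -> GridSpec:
    """Smallest axis-aligned lattice holding every atom >= ``margin`` inside.

    Origin sits at (min - margin); the lattice extends in steps of
    ``spacing`` until it covers (max + margin). Deterministic and invariant
    to the order of the conformers.
    """
    if len(conformers) == 0:
        raise ValueError("cannot build a grid around an empty conformer set")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = np.vstack([c.coords for c in conformers])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    # ceil so the top face clears max + margin; -1e-9 guards exact multiples
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing - 1e-9)) + 1 for k in range(3))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=float(spacing),
                    dims=dims, margin=float(margin))


def _distances(conformer: Conformer, points: np.ndarray) -> np.ndarray:
    """(n_points, n_atoms) Euclidean distance matrix."""
    diff = points[:, None, :] - conformer.coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def comfa_steric(
    conformer: Conformer, grid: GridSpec, probe: ProbeSpec = ProbeSpec()
) -> np.ndarray:
    """Lennard-Jones 6-12 probe energies (kcal/mol), truncated at +30.

    Probe-atom pair parameters combine as R* = r*_i + r*_probe (radius sum)
    and eps = sqrt(eps_i * eps_probe).
    """
    r = _distances(conformer, grid.points())
    if conformer.n_atoms == 0:
        return np.zeros(grid.n_points)
    r_star = conformer.radii + probe.r_star
    eps = np.sqrt(conformer.epsilons * probe.epsilon)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        s6 = (r_star[None, :] / r) ** 6
        e = (eps[None, :] * (s6**2 - 2.0 * s6)).sum(axis=1)
    e = np.nan_to_num(e, nan=np.inf, posinf=np.inf)
    return np.clip(e, -ENERGY_TRUNCATION, ENERGY_TRUNCATION)


def comfa_electrostatic(
    conformer: Conformer, grid: GridSpec, probe: ProbeSpec = ProbeSpec()
) -> np.ndarray:
    """Coulomb probe energies with D(r) = r (kcal/mol), truncated at +/-30."""
    if conformer.n_atoms == 0:
        return np.zeros(grid.n_points)
    r = _distances(conformer, grid.points())
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (COULOMB_CONSTANT * probe.charge * conformer.charges[None, :] / r**2).sum(axis=1)
    e = np.nan_to_num(e, nan=ENERGY_TRUNCATION, posinf=np.inf, neginf=-np.inf)
    return np.clip(e, -ENERGY_TRUNCATION, ENERGY_TRUNCATION)


def comsia_field(
    conformer: Conformer,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    channel: str = "steric",
    alpha: float = ATTENUATION_ALPHA,
) -> np.ndarray:
    """Gaussian similarity index for one CoMSIA property channel."""
    key = channel.removeprefix("comsia_")
    if key not in conformer.weights:
        raise KeyError(f"unknown CoMSIA channel {channel!r}")
    if conformer.n_atoms == 0:
        return np.zeros(grid.n_points)
    w = conformer.weights[key]
    r2 = ((grid.points()[:, None, :] - conformer.coords[None, :, :]) ** 2).sum(axis=-1)
    return -(probe.weights[key] * w[None, :] * np.exp(-alpha * r2)).sum(axis=1)


@dataclass(frozen=True)
class FieldMatrix:
    """compounds x grid-points x channels descriptor block."""

    compound_ids: tuple[int, ...]
    channels: tuple[str, ...]
    values: np.ndarray          # (n_compounds, n_points, n_channels)
    grid: GridSpec
    units: dict[str, str] = field(default_factory=dict)

    def channel_block(self, channels: Sequence[str]) -> np.ndarray:
        """Flatten selected channels to a (n_compounds, n_points*len) matrix.

        Column order is channel-major: all grid points of the first channel,
        then the next, so every column belongs to exactly one channel.
        """
        idx = [self.channels.index(c) for c in channels]
        blocks = [self.values[:, :, j] for j in idx]
        return np.concatenate(blocks, axis=1)

    def channel_of_column(self, channels: Sequence[str]) -> np.ndarray:
        """Channel label of every column of :meth:`channel_block`."""
        return np.repeat(list(channels), self.grid.n_points)


def assemble_field_matrix(
    conformers: Sequence[Conformer],
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    channels: Sequence[str] = ALL_CHANNELS,
    electrostatic_mean_fill: bool = True,
) -> FieldMatrix:
    """Evaluate all requested channels for every aligned conformer.

    At grid points where a compound's steric energy is truncated (probe
    inside the molecule), its electrostatic value is replaced by the mean of
    the untruncated compounds at that point (classic CoMFA convention;
    switch off with ``electrostatic_mean_fill=False``). Rows follow the
    input conformer order; points are enumerated x-fastest.
    """
    n_c, n_p = len(conformers), grid.n_points
    values = np.zeros((n_c, n_p, len(channels)))
    steric_clamped = np.zeros((n_c, n_p), dtype=bool)
    need_clamp_info = "comfa_elec" in channels and electrostatic_mean_fill
    if need_clamp_info or "comfa_steric" in channels:
        for i, conf in enumerate(conformers):
            st = comfa_steric(conf, grid, probe)
            steric_clamped[i] = st >= ENERGY_TRUNCATION
            if "comfa_steric" in channels:
                values[i, :, list(channels).index("comfa_steric")] = st
    for j, ch in enumerate(channels):
        if ch == "comfa_steric":
            continue
        for i, conf in enumerate(conformers):
            if ch == "comfa_elec":
                values[i, :, j] = comfa_electrostatic(conf, grid, probe)
            else:
                values[i, :, j] = comsia_field(conf, grid, probe, ch)
    if need_clamp_info:
        j = list(channels).index("comfa_elec")
        elec = values[:, :, j]
        ok = ~steric_clamped
        with np.errstate(invalid="ignore"):
            col_mean = np.where(ok.any(axis=0), (elec * ok).sum(axis=0) / ok.sum(axis=0), 0.0)
        values[:, :, j] = np.where(steric_clamped, col_mean[None, :], elec)
    return FieldMatrix(
        compound_ids=tuple(c.compound_id for c in conformers),
        channels=tuple(channels),
        values=values,
        grid=grid,
        units={c: CHANNEL_UNITS[c] for c in channels},
    )


def save_field_matrix(fm: FieldMatrix, path: str | Path) -> None:
    """Persist as a compressed array archive plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=fm.values)
    meta = {
        "compound_ids": list(fm.compound_ids),
        "channels": list(fm.channels),
        "units": fm.units,
        "grid": {
            "origin": list(fm.grid.origin),
            "spacing": fm.grid.spacing,
            "dims": list(fm.grid.dims),
            "margin": fm.grid.margin,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_field_matrix(path: str | Path) -> FieldMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npz"))["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    g = meta["grid"]
    return FieldMatrix(
        compound_ids=tuple(meta["compound_ids"]),
        channels=tuple(meta["channels"]),
        values=values,
        grid=GridSpec(tuple(g["origin"]), g["spacing"], tuple(g["dims"]), g["margin"]),
        units=meta["units"],
    )
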