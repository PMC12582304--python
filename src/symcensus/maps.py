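"""Minimal MRC2014 volume I/O (via gemmi's CCP4/MRC map support)."""

from __future__ import annotations

import numpy as np
import gemmi

__all__ = ["write_mrc", "read_mrc"]


def write_mrc(path, volume: np.ndarray, voxel_size: float) -> None:
    """Write a cubic voxel grid as an MRC2014 map with the voxel size recorded."""
    vol = np.ascontiguousarray(volume, dtype=np.float32)
    grid = gemmi.FloatGrid(*vol.shape)
    nx, ny, nz = vol.shape
    grid.set_unit_cell(
        gemmi.UnitCell(nx * voxel_size, ny * voxel_size, nz * voxel_size, 90, 90, 90)
    )
    np.asarray(grid, dtype=np.float32)[...] = vol
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map; returns (volume, voxel size along x)."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    vol = np.array(ccp4.grid, copy=True)
    voxel = ccp4.grid.unit_cell.a / ccp4.grid.nu
    return vol, voxel
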