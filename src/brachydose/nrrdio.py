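"""Minimal NRRD reader/writer (ASCII encoding) for dose grids and masks.

Writes NRRD0004 files with ``space origin`` / ``space directions`` carrying
the grid's origin and spacing in mm, text-encoded data (the deliverables
here are small grids; text keeps the files diffable and portable).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .anatomy import VoxelGrid

_TYPES = {"double": np.float64, "float": np.float32, "int": np.int32,
          "uint8": np.uint8, "unsigned char": np.uint8}


def write_nrrd(path, array: np.ndarray, grid: VoxelGrid) -> None:
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError("array shape must match grid shape")
    if array.dtype == bool:
        array = array.astype(np.uint8)
    tname = {np.dtype(np.float64): "double", np.dtype(np.float32): "float",
             np.dtype(np.int32): "int", np.dtype(np.uint8): "uint8"}.get(array.dtype)
    if tname is None:
        array = array.astype(np.float64)
        tname = "double"
    sx, sy, sz = grid.spacing_mm
    header = [
        "NRRD0004",
        f"type: {tname}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}",
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: ascii",
        f"space origin: ({grid.origin_mm[0]},{grid.origin_mm[1]},{grid.origin_mm[2]})",
        "",  # blank line terminates the NRRD header
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header))
        # NRRD stores the first axis fastest; emit in Fortran order
        flat = array.ravel(order="F")
        for lo in range(0, flat.size, 16):
            fh.write(" ".join(repr(v) for v in flat[lo:lo + 16].tolist()) + "\n")


def read_nrrd(path):
    """Returns (array, VoxelGrid)."""
    text = Path(path).read_text().split("\n")
    if not text[0].startswith("NRRD"):
        raise ValueError("not an NRRD file")
    fields = {}
    i = 1
    while i < len(text) and text[i].strip():
        if ":" in text[i]:
            k, v = text[i].split(":", 1)
            fields[k.strip()] = v.strip()
        i += 1
    if fields.get("encoding") != "ascii":
        raise ValueError("only ascii encoding supported")
    shape = tuple(int(s) for s in fields["sizes"].split())
    dtype = _TYPES[fields["type"]]

    def _vec(s):
        return [float(x) for x in s.strip("()").split(",")]

    dirs = [
        _vec(tok) for tok in fields["space directions"].replace(") (", ")|(").split("|")
    ]
    spacing = tuple(dirs[d][d] for d in range(3))
    origin = tuple(_vec(fields["space origin"]))
    data = np.array(" ".join(text[i + 1:]).split(), dtype=np.float64)
    array = data.astype(dtype).reshape(shape, order="F")
    grid = VoxelGrid(origin_mm=origin, spacing_mm=spacing, shape=shape)
    return array, grid
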