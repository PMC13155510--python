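"""HDF5 / CSV serialization helpers for simulator states and p.d.f. grids."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .surrogate import PdfGrid

__all__ = ["save_pdf_grid", "load_pdf_grid", "save_result_csv",
           "save_seed_manifest"]


def save_pdf_grid(grid: PdfGrid, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=grid.t)
        f.create_dataset("c", data=grid.c)
        f.create_dataset("P", data=grid.P)
        f.create_dataset("absorbed", data=grid.absorbed)
        f.create_dataset("cured", data=grid.cured)


def load_pdf_grid(path) -> PdfGrid:
    with h5py.File(path, "r") as f:
        return PdfGrid(t=f["t"][:], c=f["c"][:], P=f["P"][:],
                       absorbed=f["absorbed"][:], cured=f["cured"][:])


def save_result_csv(result, path) -> None:
    """Write a SimulationResult's density time series as tidy CSV."""
    result.to_frame().to_csv(path, index=False)


def save_seed_manifest(path, **seeds) -> None:
    """Record every named seed of a run so it can be replayed exactly."""
    Path(path).write_text(json.dumps(seeds, indent=2, default=int))
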