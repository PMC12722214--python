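"""Parameter grids and simulated MRF dictionaries.

A dictionary is the Cartesian product of per-parameter value lists, each row
simulated through one MRF protocol.  Rows are ordered lexicographically over
the declared parameter order and are generated in fixed-size chunks, so the
result is bitwise identical for any worker count.

Grid parameter names map onto the simulator as::

    water_t1, water_t2          water pool relaxation (s)
    f_ss, k_ssw                 semisolid volume fraction / exchange rate
    f_amide, k_amide            amide pool (fraction / 1/s)
    f_rnoe, k_rnoe              rNOE pool
    glu_concentration, k_glu    glutamate (mM, converted to a proton
                                volume fraction internally) / 1/s
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import h5py
import numpy as np
import yaml

from .phantom import glu_conc_to_fraction
from .physics import simulate_batch
from .pools import TissueModel
from .presets import base_tissue
from .schedules import AcquisitionSchedule

__all__ = ["ParameterGrid", "Dictionary", "generate_dictionary", "l2_normalize",
           "load_default_grid", "tissue_for_grid"]

_CHUNK_ROWS = 4096
_MAX_ROWS_DEFAULT = 5_000_000

# grid key -> simulator parameter key (glutamate converts mM -> fraction)
_SIM_KEYS = {
    "water_t1": "water_t1", "water_t2": "water_t2",
    "f_ss": "f_ss", "k_ssw": "k_ss",
    "f_amide": "f_amide", "k_amide": "k_amide",
    "f_rnoe": "f_rnoe", "k_rnoe": "k_rnoe",
    "glu_concentration": "f_glu", "k_glu": "k_glu",
}


@dataclass
class ParameterGrid:
    """Ordered per-parameter value lists defining a Cartesian dictionary."""

    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, vals in self.values.items():
            if name not in _SIM_KEYS:
                raise ValueError(f"unknown grid parameter {name!r}")
            arr = np.asarray(vals, dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"parameter {name!r} has an empty value list")
            if name.startswith("f_") and np.any((arr < 0) | (arr >= 1)):
                raise ValueError(f"{name}: volume fractions must be in [0, 1)")
            if name.startswith("k_") and np.any(arr < 0):
                raise ValueError(f"{name}: rates must be >= 0")
            if np.unique(arr).size != arr.size:
                # Degenerate lists are deduplicated (order of first occurrence
                # preserved); the resulting size is visible via len/size.
                _, idx = np.unique(arr, return_index=True)
                arr = arr[np.sort(idx)]
            clean[name] = arr
        self.values = clean

    @property
    def param_names(self) -> list[str]:
        return list(self.values.keys())

    @property
    def size(self) -> int:
        n = 1
        for arr in self.values.values():
            n *= arr.size
        return n

    def combinations(self) -> np.ndarray:
        """(size, n_params) array, lexicographic over declared order."""
        grids = np.meshgrid(*self.values.values(), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def bounds(self, name: str) -> tuple[float, float]:
        arr = self.values[name]
        return float(arr.min()), float(arr.max())

    def to_dict(self) -> dict:
        return {k: [float(x) for x in v] for k, v in self.values.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterGrid":
        return cls(values={k: np.asarray(v, dtype=float) for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterGrid":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_default_grid(name: str) -> ParameterGrid:
    """Load one of the shipped desk-scale grids: 'mt', 'rnoe' or 'amideglu'."""
    text = resources.files("cestmrf.data").joinpath(f"grid_{name}.yaml").read_text()
    return ParameterGrid.from_dict(yaml.safe_load(text))


def tissue_for_grid(grid: ParameterGrid, background: tuple[str, ...] = (),
                    **kwargs) -> TissueModel:
    """Template tissue containing the pools the grid varies.

    ``background`` names additional pools held fixed at their nominal
    defaults; including the non-target metabolites this way removes the
    small systematic bias their spectral bleed would otherwise imprint on
    the estimates (e.g. the broad fast-exchanging glutamate line underneath
    the >= 6 ppm semisolid-MT offsets).
    """
    varied = tuple(
        name for name in ("rnoe", "amide", "glu")
        if f"f_{name}" in grid.values or f"k_{name}" in grid.values
        or (name == "glu" and "glu_concentration" in grid.values)
    )
    solutes = varied + tuple(b for b in background if b not in varied)
    semisolid = "f_ss" in grid.values or "k_ssw" in grid.values
    return base_tissue(solutes=solutes, semisolid=semisolid, **kwargs)


@dataclass
class Dictionary:
    """Simulated (parameters -> trajectory) pairs for one MRF protocol."""

    grid: ParameterGrid
    param_names: list[str]
    parameter_matrix: np.ndarray  # (n, n_params)
    trajectory_matrix: np.ndarray  # (n, n_entries), raw signal incl. M0
    schedule_name: str
    schedule_hash: str

    def __len__(self) -> int:
        return self.parameter_matrix.shape[0]

    @property
    def normalized_matrix(self) -> np.ndarray:
        """Unit-norm encoding vectors (M0-referenced, M0 entry dropped)."""
        return l2_normalize(self.trajectory_matrix)

    def column(self, name: str) -> np.ndarray:
        return self.parameter_matrix[:, self.param_names.index(name)]

    # -- persistence (HDF5 container) --------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("parameters", data=self.parameter_matrix)
            fh.create_dataset("trajectories", data=self.trajectory_matrix)
            fh.create_dataset("normalized", data=self.normalized_matrix)
            fh.attrs["param_names"] = yaml.safe_dump(self.param_names)
            fh.attrs["grid"] = yaml.safe_dump(self.grid.to_dict())
            fh.attrs["schedule_name"] = self.schedule_name
            fh.attrs["schedule_hash"] = self.schedule_hash

    @classmethod
    def load(cls, path) -> "Dictionary":
        with h5py.File(path, "r") as fh:
            return cls(
                grid=ParameterGrid.from_dict(yaml.safe_load(fh.attrs["grid"])),
                param_names=yaml.safe_load(fh.attrs["param_names"]),
                parameter_matrix=fh["parameters"][()],
                trajectory_matrix=fh["trajectories"][()],
                schedule_name=str(fh.attrs["schedule_name"]),
                schedule_hash=str(fh.attrs["schedule_hash"]),
            )


def _sim_params(param_names: list[str], combos: np.ndarray) -> dict[str, np.ndarray]:
    params = {}
    for j, name in enumerate(param_names):
        col = combos[:, j]
        if name == "glu_concentration":
            col = glu_conc_to_fraction(col)
        params[_SIM_KEYS[name]] = col
    return params


def _simulate_block(args) -> np.ndarray:
    template, schedule, param_names, combos = args
    return simulate_batch(template, _sim_params(param_names, combos), schedule)


def generate_dictionary(grid: ParameterGrid, schedule: AcquisitionSchedule,
                        template: Optional[TissueModel] = None, workers: int = 1,
                        max_rows: int = _MAX_ROWS_DEFAULT) -> Dictionary:
    """Simulate the full Cartesian grid through ``schedule``.

    Deterministic row order (lexicographic over the declared parameter
    order); identical output for any ``workers`` value because rows are
    always processed in the same fixed-size chunks.
    """
    if grid.size > max_rows:
        raise MemoryError(
            f"grid has {grid.size} rows, exceeding the configured budget of "
            f"{max_rows}; thin the value lists or raise max_rows")
    if template is None:
        template = tissue_for_grid(grid)
    combos = grid.combinations()
    blocks = [combos[i: i + _CHUNK_ROWS] for i in range(0, len(combos), _CHUNK_ROWS)]
    jobs = [(template, schedule, grid.param_names, blk) for blk in blocks]
    if workers > 1 and len(blocks) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_simulate_block, jobs))
    else:
        results = [_simulate_block(job) for job in jobs]
    return Dictionary(
        grid=grid, param_names=grid.param_names, parameter_matrix=combos,
        trajectory_matrix=np.vstack(results), schedule_name=schedule.name,
        schedule_hash=schedule.content_hash(),
    )


def l2_normalize(trajectory: np.ndarray, use_m0: bool = True) -> np.ndarray:
    """M0-reference then scale the saturated entries to unit Euclidean norm.

    Accepts a single trajectory ``(n_entries,)`` or a matrix
    ``(n_rows, n_entries)``; entry 0 is the M0 acquisition.
    """
    traj = np.asarray(trajectory, dtype=float)
    single = traj.ndim == 1
    if single:
        traj = traj[None, :]
    sat = traj[:, 1:]
    if use_m0:
        m0 = traj[:, :1]
        if np.any(m0 == 0):
            raise ValueError("zero M0 entry; cannot normalize")
        sat = sat / m0
    norm = np.linalg.norm(sat, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm trajectory; cannot normalize")
    out = sat / norm
    return out[0] if single else out
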