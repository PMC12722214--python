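"""Digital multi-compound phantoms.

A phantom is a 5 x 5 array of circular vials in which the amide proton
volume fraction varies along one axis and the glutamate concentration along
the other, replicated over several semisolid-MT background volume
fractions (5 x 5 x 4 = 100 unique parameter combinations by default).
Every pixel's four MRF trajectories are simulated from its vial's tissue
model and injected with white Gaussian noise scaled to the unsaturated (M0)
signal.  The phantom doubles as the package's synthetic ground-truth
fixture: the truth maps are piecewise constant per vial and exactly
recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .physics import simulate_batch
from .pools import TissueModel
from .presets import base_tissue
from .schedules import AcquisitionSchedule

__all__ = [
    "PhantomSpec", "PhantomDataset", "make_digital_phantom", "add_noise",
    "glu_conc_to_fraction", "glu_fraction_to_conc", "WATER_PROTON_MM",
]

# Water proton concentration: 2 protons x 55.5 M, in mM.
WATER_PROTON_MM = 111_000.0


def glu_conc_to_fraction(concentration_mM, protons_per_molecule: int = 3):
    """Glutamate concentration (mM) -> amine proton volume fraction.

    Three exchangeable amine protons per molecule, referenced to the water
    proton concentration (111 M).
    """
    conc = np.asarray(concentration_mM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = protons_per_molecule * conc / WATER_PROTON_MM
    return float(out) if np.ndim(concentration_mM) == 0 else out


def glu_fraction_to_conc(fraction, protons_per_molecule: int = 3):
    """Inverse of :func:`glu_conc_to_fraction`."""
    frac = np.asarray(fraction, dtype=float)
    out = frac * WATER_PROTON_MM / protons_per_molecule
    return float(out) if np.ndim(fraction) == 0 else out


@dataclass
class PhantomSpec:
    """Layout and ground-truth values of the digital phantom."""

    amide_fractions: np.ndarray = field(
        default_factory=lambda: np.array([0.0009, 0.0027, 0.0045, 0.0063, 0.0081]))
    glu_concentrations: np.ndarray = field(
        default_factory=lambda: np.array([5.0, 10.0, 15.0, 20.0, 25.0]))  # mM
    mt_fractions: np.ndarray = field(
        default_factory=lambda: np.array([0.06, 0.10, 0.14, 0.18]))
    image_size: int = 64
    vial_radius: int = 4
    vial_spacing: int = 12
    base_tissue: Optional[TissueModel] = None

    def __post_init__(self):
        self.amide_fractions = np.asarray(self.amide_fractions, dtype=float)
        self.glu_concentrations = np.asarray(self.glu_concentrations, dtype=float)
        self.mt_fractions = np.asarray(self.mt_fractions, dtype=float)
        if self.base_tissue is None:
            self.base_tissue = base_tissue(solutes=("rnoe", "amide", "glu"))

    @property
    def n_rows(self) -> int:
        return self.amide_fractions.size

    @property
    def n_cols(self) -> int:
        return self.glu_concentrations.size

    @property
    def n_backgrounds(self) -> int:
        return self.mt_fractions.size

    def vial_centers(self) -> np.ndarray:
        """(n_rows * n_cols, 2) pixel centers; amide varies along rows,
        glutamate along columns."""
        extent_r = (self.n_rows - 1) * self.vial_spacing
        extent_c = (self.n_cols - 1) * self.vial_spacing
        r0 = (self.image_size - extent_r) // 2
        c0 = (self.image_size - extent_c) // 2
        centers = [(r0 + i * self.vial_spacing, c0 + j * self.vial_spacing)
                   for i in range(self.n_rows) for j in range(self.n_cols)]
        return np.asarray(centers)

    def validate(self) -> None:
        if self.vial_spacing <= 2 * self.vial_radius:
            raise ValueError("vials overlap: spacing must exceed the diameter")
        centers = self.vial_centers()
        if (centers - self.vial_radius < 0).any() or \
                (centers + self.vial_radius >= self.image_size).any():
            raise ValueError("vial geometry overflows the image bounds")
        self.base_tissue.validate()

    def vial_label_map(self) -> np.ndarray:
        """(H, W) int map; 0 = background, 1..n_vials label each vial."""
        size = self.image_size
        rr, cc = np.mgrid[0:size, 0:size]
        labels = np.zeros((size, size), dtype=int)
        for v, (r, c) in enumerate(self.vial_centers(), start=1):
            inside = (rr - r) ** 2 + (cc - c) ** 2 <= self.vial_radius**2
            labels[inside] = v
        return labels

    def to_dict(self) -> dict:
        return {
            "amide_fractions": self.amide_fractions.tolist(),
            "glu_concentrations_mM": self.glu_concentrations.tolist(),
            "mt_fractions": self.mt_fractions.tolist(),
            "image_size": self.image_size,
            "vial_radius": self.vial_radius,
            "vial_spacing": self.vial_spacing,
        }


@dataclass
class PhantomDataset:
    """Simulated phantom: truth maps, per-protocol trajectory stacks, water
    relaxation maps, and the noise/seed provenance.

    Array layout: ``(n_backgrounds, H, W)`` for maps and
    ``(n_backgrounds, H, W, n_entries)`` for trajectory stacks.
    """

    spec: PhantomSpec
    truth_maps: dict[str, np.ndarray]
    trajectory_stacks: dict[str, np.ndarray]
    t1_map: np.ndarray
    t2_map: np.ndarray
    vial_labels: np.ndarray  # (H, W), shared by all backgrounds
    noise_sigma: float
    seed: int

    @property
    def mask(self) -> np.ndarray:
        return self.vial_labels > 0

    def vial_means(self, maps: np.ndarray) -> np.ndarray:
        """Per-vial means over ``(n_backgrounds, H, W)`` maps ->
        ``(n_backgrounds, n_vials)``."""
        labels = self.vial_labels
        n_vials = labels.max()
        out = np.zeros((maps.shape[0], n_vials))
        for v in range(1, n_vials + 1):
            sel = labels == v
            out[:, v - 1] = maps[:, sel].mean(axis=1)
        return out

    def save(self, directory) -> None:
        from .io import write_nifti

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.truth_maps.items():
            write_nifti(directory / f"truth_{name}.nii", arr)
        for name, arr in self.trajectory_stacks.items():
            write_nifti(directory / f"mrf_{name}.nii", arr)
        write_nifti(directory / "t1_map.nii", self.t1_map)
        write_nifti(directory / "t2_map.nii", self.t2_map)
        write_nifti(directory / "vial_labels.nii", self.vial_labels.astype(np.int16))
        meta = {"spec": self.spec.to_dict(), "noise_sigma": self.noise_sigma,
                "seed": self.seed,
                "protocols": sorted(self.trajectory_stacks.keys())}
        with open(directory / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)

    @classmethod
    def load(cls, directory) -> "PhantomDataset":
        from .io import read_nifti

        directory = Path(directory)
        with open(directory / "metadata.yaml") as fh:
            meta = yaml.safe_load(fh)
        sd = meta["spec"]
        spec = PhantomSpec(
            amide_fractions=sd["amide_fractions"],
            glu_concentrations=sd["glu_concentrations_mM"],
            mt_fractions=sd["mt_fractions"], image_size=sd["image_size"],
            vial_radius=sd["vial_radius"], vial_spacing=sd["vial_spacing"],
        )
        truth = {p.stem.removeprefix("truth_"): read_nifti(p)
                 for p in sorted(directory.glob("truth_*.nii"))}
        stacks = {name: read_nifti(directory / f"mrf_{name}.nii")
                  for name in meta["protocols"]}
        return cls(
            spec=spec, truth_maps=truth, trajectory_stacks=stacks,
            t1_map=read_nifti(directory / "t1_map.nii"),
            t2_map=read_nifti(directory / "t2_map.nii"),
            vial_labels=read_nifti(directory / "vial_labels.nii").astype(int),
            noise_sigma=float(meta["noise_sigma"]), seed=int(meta["seed"]),
        )


def add_noise(trajectories: np.ndarray, sigma: float, seed: int,
              m0: Optional[np.ndarray] = None) -> np.ndarray:
    """Add independent zero-mean Gaussian noise with std ``sigma * M0``.

    ``m0`` defaults to each trajectory's own entry 0 along the last axis.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    traj = np.asarray(trajectories, dtype=float)
    if sigma == 0:
        return traj.copy()
    if m0 is None:
        m0 = traj[..., :1]
    rng = np.random.default_rng(seed)
    return traj + rng.standard_normal(traj.shape) * sigma * np.asarray(m0)


def make_digital_phantom(spec: PhantomSpec,
                         schedules: dict[str, AcquisitionSchedule],
                         noise_sigma: float = 0.01,
                         seed: int = 0) -> PhantomDataset:
    """Simulate the digital phantom through every supplied MRF protocol.

    All pixels of a vial share one tissue model; noise is then injected
    per pixel and per entry.  Deterministic given ``seed``.
    """
    spec.validate()
    labels = spec.vial_label_map()
    n_bg = spec.n_backgrounds
    n_vials = spec.n_rows * spec.n_cols
    size = spec.image_size

    # Per-vial truth, row-major over (amide row, glu column).
    amide = np.repeat(spec.amide_fractions, spec.n_cols)
    glu = np.tile(spec.glu_concentrations, spec.n_rows)

    # One batch row per (background, vial).
    f_ss = np.repeat(spec.mt_fractions, n_vials)
    params = {
        "f_amide": np.tile(amide, n_bg),
        "f_glu": glu_conc_to_fraction(np.tile(glu, n_bg)),
        "f_ss": f_ss,
    }

    truth_maps = {
        "f_amide": np.zeros((n_bg, size, size)),
        "glu_concentration": np.zeros((n_bg, size, size)),
        "f_ss": np.zeros((n_bg, size, size)),
    }
    inside = labels > 0
    vial_of_pixel = labels[inside] - 1
    for b in range(n_bg):
        truth_maps["f_amide"][b][inside] = amide[vial_of_pixel]
        truth_maps["glu_concentration"][b][inside] = glu[vial_of_pixel]
        truth_maps["f_ss"][b][inside] = spec.mt_fractions[b]

    t1_map = np.where(inside, spec.base_tissue.water_t1, 0.0)
    t2_map = np.where(inside, spec.base_tissue.water_t2, 0.0)

    stacks: dict[str, np.ndarray] = {}
    seed_root = np.random.SeedSequence([int(seed), 2210]).generate_state(
        len(schedules))
    for i, (target, schedule) in enumerate(sorted(schedules.items())):
        vial_traj = simulate_batch(spec.base_tissue, params, schedule)
        vial_traj = vial_traj.reshape(n_bg, n_vials, -1)
        stack = np.zeros((n_bg, size, size, vial_traj.shape[-1]))
        stack[:, inside, :] = vial_traj[:, vial_of_pixel, :]
        if noise_sigma > 0:
            noisy = add_noise(stack[:, inside, :], noise_sigma,
                              seed=int(seed_root[i]))
            stack[:, inside, :] = noisy
        stacks[target] = stack

    return PhantomDataset(
        spec=spec, truth_maps=truth_maps, trajectory_stacks=stacks,
        t1_map=t1_map, t2_map=t2_map, vial_labels=labels,
        noise_sigma=noise_sigma, seed=seed,
    )
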