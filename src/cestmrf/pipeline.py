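"""Sequential three-network quantification pipeline.

The pipeline decodes eight parameter maps from the four MRF trajectory
stacks plus separately measured water T1/T2 maps, pixel by pixel:

1. The **MT network** sees the (L2-normalized) semisolid-MT trajectory plus
   T1 and T2 and estimates ``(f_ss, k_ssw)``.
2. Its outputs feed, together with the respective trajectories, the **rNOE
   network** -> ``(f_rnoe, k_rnoe)`` and the combined **amide/glutamate
   network`` (which sees both the amide and the glutamate trajectories so
   that the spectral overlap of the two pools at +3.5 / +3 ppm is resolved
   jointly) -> ``(f_amide, k_amide, glu_concentration, k_glu)``.

Scalars entering a network are min-max scaled: water T1/T2 by the global
tissue envelope, upstream (f_ss, k_ssw) by the downstream network's own
training-grid bounds; targets by each parameter's grid range (matching the
sigmoid output).  Training inputs are assembled from simulated
dictionaries with fresh Gaussian noise (std = sigma x M0) injected into the
raw trajectories every epoch, before M0 normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dictionary import Dictionary, l2_normalize
from .nn import MLP, NetworkSpec, TrainingConfig, train_mlp, HIDDEN_WIDTH
from .phantom import PhantomDataset
from .presets import WATER_T1_RANGE, WATER_T2_RANGE

__all__ = ["NETWORKS", "TrainingSet", "build_training_set", "train_network",
           "run_pipeline", "QuantMaps", "evaluate_recovery"]

# Network wiring: which trajectory stacks and which upstream scalars feed
# each network, and what it regresses.
NETWORKS = {
    "mt": {"trajectories": ["mt"], "upstream": [],
           "outputs": ["f_ss", "k_ssw"], "hidden": [HIDDEN_WIDTH] * 2},
    "rnoe": {"trajectories": ["rnoe"], "upstream": ["f_ss", "k_ssw"],
             "outputs": ["f_rnoe", "k_rnoe"], "hidden": [HIDDEN_WIDTH] * 2},
    "amideglu": {"trajectories": ["amide", "glu"], "upstream": ["f_ss", "k_ssw"],
                 "outputs": ["f_amide", "k_amide", "glu_concentration", "k_glu"],
                 "hidden": [HIDDEN_WIDTH] * 4},
}

PERCENT_PARAMS = ("f_ss", "f_rnoe", "f_amide")  # reported as %


def _scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


@dataclass
class TrainingSet:
    """Raw dictionary trajectories + scalar features + scaled targets.

    Holding the *raw* trajectories (rather than pre-normalized inputs) lets
    the trainer draw a fresh noise realization every epoch.
    """

    spec: NetworkSpec
    raw_trajectories: dict[str, np.ndarray]  # target -> (n, n_entries)
    scalar_features: np.ndarray  # (n, n_scalars), already scaled
    targets_scaled: np.ndarray  # (n, n_out)
    noise_sigma: float
    input_spec: dict  # serializable recipe used again at inference
    schedule_hashes: dict[str, str] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.scalar_features.shape[0]

    def assemble(self, rng: Optional[np.random.Generator] = None):
        """(X, Y) float32 for one epoch; noise injected when rng given."""
        blocks = []
        for name in self.input_spec["trajectories"]:
            raw = self.raw_trajectories[name]
            if rng is not None and self.noise_sigma > 0:
                raw = raw + rng.standard_normal(raw.shape) * \
                    (self.noise_sigma * raw[:, :1])
            blocks.append(l2_normalize(raw))
        blocks.append(self.scalar_features)
        X = np.hstack(blocks).astype(np.float32)
        Y = self.targets_scaled.astype(np.float32)
        return X, Y

    def sampler(self, rng):
        return self.assemble(rng)


def build_training_set(dictionaries: dict[str, Dictionary], network: str,
                       noise_sigma: float = 0.01) -> TrainingSet:
    """Assemble the training set for one of the three pipeline networks.

    ``dictionaries`` maps protocol targets to dictionaries simulated on the
    *same* parameter grid (one per trajectory the network consumes).
    """
    wiring = NETWORKS[network]
    missing = [t for t in wiring["trajectories"] if t not in dictionaries]
    if missing:
        raise ValueError(f"network {network!r} needs dictionaries for {missing}")
    dicts = [dictionaries[t] for t in wiring["trajectories"]]
    first = dicts[0]
    for d in dicts[1:]:
        if not np.array_equal(d.parameter_matrix, first.parameter_matrix):
            raise ValueError("dictionaries do not share a parameter grid")
    for name in wiring["outputs"] + wiring["upstream"] + ["water_t1", "water_t2"]:
        if name not in first.param_names:
            raise ValueError(
                f"dictionary grid lacks parameter {name!r} required by "
                f"network {network!r}")

    grid = first.grid
    scaling = {name: grid.bounds(name) for name in wiring["outputs"]}
    upstream_scaling = {name: grid.bounds(name) for name in wiring["upstream"]}

    scalars = [
        _scale(first.column("water_t1"), *WATER_T1_RANGE),
        _scale(first.column("water_t2"), *WATER_T2_RANGE),
    ]
    for name in wiring["upstream"]:
        scalars.append(_scale(first.column(name), *upstream_scaling[name]))
    scalar_features = np.stack(scalars, axis=1)

    n_traj_inputs = sum(d.trajectory_matrix.shape[1] - 1 for d in dicts)
    spec = NetworkSpec(
        input_size=n_traj_inputs + scalar_features.shape[1],
        output_names=list(wiring["outputs"]), output_scaling=scaling,
        hidden_layers=list(wiring["hidden"]),
    )
    targets = np.stack([first.column(n) for n in wiring["outputs"]], axis=1)
    input_spec = {
        "network": network,
        "trajectories": list(wiring["trajectories"]),
        "upstream": list(wiring["upstream"]),
        "upstream_scaling": {k: [float(a), float(b)]
                             for k, (a, b) in upstream_scaling.items()},
        "water_t1_range": list(WATER_T1_RANGE),
        "water_t2_range": list(WATER_T2_RANGE),
    }
    return TrainingSet(
        spec=spec,
        raw_trajectories={t: d.trajectory_matrix for t, d in
                          zip(wiring["trajectories"], dicts)},
        scalar_features=scalar_features,
        targets_scaled=spec.scale_targets(targets),
        noise_sigma=noise_sigma, input_spec=input_spec,
        schedule_hashes={t: d.schedule_hash for t, d in
                         zip(wiring["trajectories"], dicts)},
    )


def train_network(training_set: TrainingSet,
                  config: Optional[TrainingConfig] = None) -> MLP:
    """Train one pipeline network; deterministic given ``config.seed``."""
    config = config or TrainingConfig()
    if abs(config.noise_sigma - training_set.noise_sigma) > 1e-12:
        training_set.noise_sigma = config.noise_sigma
    model = MLP(training_set.spec,
                rng=np.random.default_rng([config.seed, 555]))
    model.schedule_hashes = dict(training_set.schedule_hashes)
    model.extras["input_spec"] = training_set.input_spec
    train_mlp(model, training_set.sampler, config)
    return model


@dataclass
class QuantMaps:
    """The eight decoded parameter maps.

    Volume fractions (f_ss, f_rnoe, f_amide) are in percent, exchange rates
    in 1/s, glutamate concentration in mM.  Maps share the spatial shape of
    the input stacks; pixels outside the mask are 0.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def _predict_network(model: MLP, stacks: dict[str, np.ndarray],
                     t1: np.ndarray, t2: np.ndarray,
                     upstream: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    recipe = model.extras["input_spec"]
    blocks = [l2_normalize(stacks[t]) for t in recipe["trajectories"]]
    blocks.append(np.stack([
        _scale(t1, *recipe["water_t1_range"]),
        _scale(t2, *recipe["water_t2_range"]),
    ], axis=1))
    if recipe["upstream"]:
        blocks.append(np.stack([
            _scale(upstream[name], *recipe["upstream_scaling"][name])
            for name in recipe["upstream"]], axis=1))
    X = np.hstack(blocks).astype(np.float32)
    pred = model.predict(X)
    return {name: pred[:, j] for j, name in enumerate(model.spec.output_names)}


def run_pipeline(stacks: dict[str, np.ndarray], t1_map: np.ndarray,
                 t2_map: np.ndarray, models: dict[str, MLP],
                 mask: Optional[np.ndarray] = None,
                 schedule_hashes: Optional[dict[str, str]] = None) -> QuantMaps:
    """Apply the sequential pipeline pixelwise over trajectory stacks.

    ``stacks`` maps protocol targets ('mt', 'rnoe', 'amide', 'glu') to
    arrays of shape ``(..., n_entries)`` sharing their spatial shape with
    ``t1_map``/``t2_map``.  When ``schedule_hashes`` is given it is checked
    against the hashes recorded in each trained model; a mismatch means the
    model was trained for a different protocol and inference is refused.
    """
    spatial = t1_map.shape
    for name, stack in stacks.items():
        if stack.shape[:-1] != spatial:
            raise ValueError(f"stack {name!r} shape {stack.shape[:-1]} does not "
                             f"match maps {spatial}")
    if schedule_hashes:
        for model_name, model in models.items():
            for target, expected in model.schedule_hashes.items():
                got = schedule_hashes.get(target)
                if got is not None and got != expected:
                    raise ValueError(
                        f"model {model_name!r} was trained on a different "
                        f"{target!r} protocol (schedule hash mismatch)")

    if mask is None:
        mask = np.ones(spatial, dtype=bool)
        for stack in stacks.values():
            mask &= stack[..., 0] > 0
    flat_idx = np.flatnonzero(mask.ravel())
    out_names = [n for w in NETWORKS.values() for n in w["outputs"]]
    maps = {name: np.zeros(spatial) for name in out_names}
    if flat_idx.size:
        pix_stacks = {name: stack.reshape(-1, stack.shape[-1])[flat_idx]
                      for name, stack in stacks.items()}
        t1 = t1_map.ravel()[flat_idx]
        t2 = t2_map.ravel()[flat_idx]
        mt_est = _predict_network(models["mt"], pix_stacks, t1, t2, {})
        upstream = {"f_ss": mt_est["f_ss"], "k_ssw": mt_est["k_ssw"]}
        results = dict(mt_est)
        results.update(_predict_network(models["rnoe"], pix_stacks, t1, t2, upstream))
        results.update(_predict_network(models["amideglu"], pix_stacks, t1, t2,
                                        upstream))
        for name, values in results.items():
            if name in PERCENT_PARAMS:
                values = values * 100.0
            maps[name].ravel()[flat_idx] = values
    return QuantMaps(maps=maps, mask=mask)


def evaluate_recovery(quant: QuantMaps, truth: PhantomDataset) -> pd.DataFrame:
    """Per-parameter recovery statistics over vial means.

    For every varied truth parameter: Pearson r (+p), absolute-agreement ICC
    (+p), bias and RMSE, computed over all vials pooled ('all') and per MT
    background ('bg0'...).  Volume-fraction parameters are compared in
    percent, matching the map units.
    """
    from .evaluation import recovery_row

    rows = []
    for name, truth_map in truth.truth_maps.items():
        truth_vials = truth.vial_means(truth_map)
        if np.ptp(truth_vials) == 0:
            continue  # constant truth; correlation undefined
        est_map = quant[name]
        if est_map.ndim != truth_map.ndim:
            raise ValueError("QuantMaps geometry does not match the phantom")
        if name in PERCENT_PARAMS:
            truth_vials = truth_vials * 100.0
        est_vials = truth.vial_means(est_map)
        rows.append(recovery_row(name, "all", truth_vials.ravel(),
                                 est_vials.ravel()))
        for b in range(truth_vials.shape[0]):
            if np.ptp(truth_vials[b]) == 0:
                continue  # e.g. f_ss is constant within one background
            rows.append(recovery_row(name, f"bg{b}", truth_vials[b], est_vials[b]))
    return pd.DataFrame(rows)
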