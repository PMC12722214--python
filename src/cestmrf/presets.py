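"""Default pool parameters and tissue construction helpers.

These defaults emulate brain-like tissue at 7 T: a water pool bracketing
white/grey matter relaxation, slow-exchanging amide protons at +3.5 ppm,
aliphatic rNOE protons at -3.5 ppm, fast-exchanging glutamate amine protons
at +3 ppm, and a super-Lorentzian semisolid MT pool.  Solute T1/T2 values
follow common multi-pool simulation practice; trajectory encoding is
dominated by (f_s, k_sw) and the water relaxation, so these fixed values
are secondary.
"""

from __future__ import annotations

from .pools import Pool, SemisolidPool, TissueModel

__all__ = [
    "WATER_T1_RANGE", "WATER_T2_RANGE", "make_pool", "base_tissue",
    "POOL_DEFAULTS",
]

# Global water relaxation ranges used for grids and for scaling the T1/T2
# network inputs to [0, 1] (grey/white-matter-like envelope at 7 T; no CSF).
WATER_T1_RANGE = (1.2, 2.4)  # s
WATER_T2_RANGE = (0.030, 0.120)  # s

# name -> (chemical shift ppm, T1 s, T2 s, default k_sw 1/s, default f_s)
POOL_DEFAULTS = {
    "amide": (3.5, 1.0, 0.040, 300.0, 0.0045),
    "glu": (3.0, 1.0, 0.200, 7000.0, 4.05e-4),  # default ~= 15 mM
    "rnoe": (-3.5, 1.0, 0.005, 20.0, 0.005),
}
SEMISOLID_DEFAULTS = {"shift": -2.5, "t1": 1.0, "t2": 1.0e-5,
                      "k": 40.0, "f": 0.10, "lineshape": "super_lorentzian"}


def make_pool(name: str, **overrides) -> Pool:
    if name == "ss":
        d = SEMISOLID_DEFAULTS
        pool = SemisolidPool(
            name="ss", chemical_shift=d["shift"], t1=d["t1"], t2=d["t2"],
            exchange_rate=d["k"], volume_fraction=d["f"], lineshape=d["lineshape"],
        )
    else:
        shift, t1, t2, k, f = POOL_DEFAULTS[name]
        pool = Pool(name=name, chemical_shift=shift, t1=t1, t2=t2,
                    exchange_rate=k, volume_fraction=f)
    for key, value in overrides.items():
        setattr(pool, key, value)
    return pool


def base_tissue(solutes: tuple[str, ...] = (), semisolid: bool = True,
                water_t1: float = 1.8, water_t2: float = 0.075,
                b0_shift: float = 0.0, **pool_overrides) -> TissueModel:
    """Assemble a tissue model from named default pools.

    ``pool_overrides`` takes per-pool dicts, e.g. ``amide={"volume_fraction": 0.003}``.
    """
    pools = [make_pool(s, **pool_overrides.get(s, {})) for s in solutes]
    ss = make_pool("ss", **pool_overrides.get("ss", {})) if semisolid else None
    tissue = TissueModel(water_t1=water_t1, water_t2=water_t2,
                         solute_pools=pools, semisolid=ss, b0_shift=b0_shift)
    tissue.validate()
    return tissue
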