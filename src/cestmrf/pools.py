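"""Tissue model containers for multi-pool saturation-transfer simulation.

A tissue is described by a free water pool, zero or more mobile solute pools
(amide, amine, aliphatic rNOE protons, ...) that exchange magnetization with
water, and an optional motion-restricted semisolid pool whose saturation is
governed by a broad absorption lineshape rather than full Bloch dynamics.

Conventions
-----------
* Chemical shifts are in ppm relative to water; positive is downfield
  (amide +3.5 ppm, glutamate amine +3 ppm, aliphatic rNOE -3.5 ppm).
* ``volume_fraction`` is the solute proton pool size relative to the water
  pool (water == 1), so equilibrium longitudinal magnetization of pool *s*
  equals ``f_s``.
* ``exchange_rate`` is the solute-to-water rate ``k_sw`` in 1/s; the reverse
  (water-to-solute) rate follows from mass balance as ``f_s * k_sw``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["Pool", "SemisolidPool", "TissueModel"]

LINESHAPES = ("lorentzian", "super_lorentzian")


@dataclass
class Pool:
    """A mobile solute proton pool exchanging with water."""

    name: str
    chemical_shift: float  # ppm relative to water
    t1: float  # s
    t2: float  # s
    exchange_rate: float  # k_sw, 1/s, solute -> water
    volume_fraction: float  # f_s, dimensionless, relative to water == 1

    def validate(self) -> None:
        if not (self.t1 > 0 and math.isfinite(self.t1)):
            raise ValueError(f"pool {self.name!r}: t1 must be positive, got {self.t1}")
        if not (self.t2 > 0 and math.isfinite(self.t2)):
            raise ValueError(f"pool {self.name!r}: t2 must be positive, got {self.t2}")
        if not (self.exchange_rate >= 0 and math.isfinite(self.exchange_rate)):
            raise ValueError(
                f"pool {self.name!r}: exchange_rate must be >= 0, got {self.exchange_rate}"
            )
        if not (0 <= self.volume_fraction < 1):
            raise ValueError(
                f"pool {self.name!r}: volume_fraction must be in [0, 1), "
                f"got {self.volume_fraction}"
            )


@dataclass
class SemisolidPool(Pool):
    """Motion-restricted macromolecular pool (semisolid MT).

    Only the longitudinal component is simulated; RF saturation enters as a
    rate ``pi * w1^2 * g(dw)`` with ``g`` the configured absorption lineshape
    evaluated at the offset from the pool's resonance.  ``t2`` is on the
    microsecond scale.
    """

    lineshape: str = "super_lorentzian"

    def validate(self) -> None:
        super().validate()
        if self.t2 > 1e-3:
            raise ValueError(
                f"semisolid t2 must be <= 1 ms (microsecond scale), got {self.t2}"
            )
        if self.lineshape not in LINESHAPES:
            raise ValueError(
                f"lineshape must be one of {LINESHAPES}, got {self.lineshape!r}"
            )


@dataclass
class TissueModel:
    """Water pool + mobile solute pools + optional semisolid pool.

    This is the parameter vector the quantification pipeline estimates:
    water T1/T2, per-pool (f_s, k_sw), the semisolid (f_ss, k_ssw), and a
    local static-field offset ``b0_shift`` (ppm) added to every resonance.
    """

    water_t1: float  # s
    water_t2: float  # s
    solute_pools: list[Pool] = field(default_factory=list)
    semisolid: Optional[SemisolidPool] = None
    b0_shift: float = 0.0  # ppm

    def validate(self) -> None:
        if not (self.water_t1 > 0 and self.water_t2 > 0):
            raise ValueError("water_t1 and water_t2 must be positive")
        if self.water_t1 < self.water_t2:
            raise ValueError("water_t1 must be >= water_t2")
        if not math.isfinite(self.b0_shift):
            raise ValueError("b0_shift must be finite")
        total_f = 0.0
        names = set()
        for pool in self.solute_pools:
            pool.validate()
            if pool.name in names:
                raise ValueError(f"duplicate pool name {pool.name!r}")
            names.add(pool.name)
            total_f += pool.volume_fraction
        if self.semisolid is not None:
            self.semisolid.validate()
            total_f += self.semisolid.volume_fraction
        if total_f >= 1:
            raise ValueError(
                f"total solute + semisolid volume fraction must be < 1, got {total_f}"
            )

    def pool_by_name(self, name: str) -> Pool:
        for pool in self.solute_pools:
            if pool.name == name:
                return pool
        if self.semisolid is not None and self.semisolid.name == name:
            return self.semisolid
        raise KeyError(name)

    def with_pool(self, name: str, **changes) -> "TissueModel":
        """Return a copy with one named pool's parameters replaced."""
        pools = [
            replace(p, **changes) if p.name == name else p for p in self.solute_pools
        ]
        semisolid = self.semisolid
        if semisolid is not None and semisolid.name == name:
            semisolid = replace(semisolid, **changes)
        return replace(self, solute_pools=pools, semisolid=semisolid)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def pool_dict(p: Pool) -> dict:
            d = {"name": p.name, "shift_ppm": p.chemical_shift, "t1_s": p.t1,
                 "t2_s": p.t2, "k_sw": p.exchange_rate, "f": p.volume_fraction}
            if isinstance(p, SemisolidPool):
                d["lineshape"] = p.lineshape
            return d

        out = {"water_t1_s": self.water_t1, "water_t2_s": self.water_t2,
               "b0_shift_ppm": self.b0_shift,
               "solute_pools": [pool_dict(p) for p in self.solute_pools]}
        if self.semisolid is not None:
            out["semisolid"] = pool_dict(self.semisolid)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TissueModel":
        def make(pd: dict, semisolid: bool) -> Pool:
            kwargs = dict(name=pd["name"], chemical_shift=float(pd["shift_ppm"]),
                          t1=float(pd["t1_s"]), t2=float(pd["t2_s"]),
                          exchange_rate=float(pd["k_sw"]),
                          volume_fraction=float(pd["f"]))
            if semisolid:
                return SemisolidPool(lineshape=pd.get("lineshape",
                                                      "super_lorentzian"),
                                     **kwargs)
            return Pool(**kwargs)

        ss = d.get("semisolid")
        tissue = cls(
            water_t1=float(d["water_t1_s"]), water_t2=float(d["water_t2_s"]),
            solute_pools=[make(pd, False) for pd in d.get("solute_pools", [])],
            semisolid=make(ss, True) if ss else None,
            b0_shift=float(d.get("b0_shift_ppm", 0.0)),
        )
        tissue.validate()
        return tissue
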