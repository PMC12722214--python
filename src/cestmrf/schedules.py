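"""Acquisition schedules: MRF protocols, Z-spectrum sweeps and WASSR.

An :class:`AcquisitionSchedule` is an ordered list of entries; each entry
optionally applies a continuous-wave saturation block and is followed by an
idealized spin-echo readout (90 degree excitation, TE decay, spoiling) and
recovery for the remainder of TR.

The four fingerprinting protocols (semisolid MT, rNOE, amide, glutamate)
acquire 31 images each: an unsaturated M0 reference (TR/TE = 15000/20 ms)
followed by 30 saturated acquisitions whose B1 amplitudes vary
pseudo-randomly within a target-appropriate range so that different
(f_s, k_sw) combinations are encoded into distinguishable trajectories.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "SaturationEvent",
    "ScheduleEntry",
    "AcquisitionSchedule",
    "default_schedule",
    "zspectrum_protocol",
    "wassr_protocol",
    "MRF_TARGETS",
]

MRF_TARGETS = ("mt", "rnoe", "amide", "glu")

# Per-target CW saturation design: offset placement (ppm), B1 range (uT)
# and per-entry saturation/TR (s).  MT encodes at >= 6 ppm where mobile
# metabolites are invisible; rNOE uses low powers at -3.5 ppm; amide
# intermediate powers at +3.5 ppm.  The fast-exchanging glutamate amine
# pool needs high powers at +3 ppm; its entries alternate between +3 and
# -3 ppm so that the (small) glutamate effect is differential across the
# trajectory and survives L2 normalization -- the fingerprinting analogue
# of the GluCEST asymmetry reference.
_TARGET_RANGES = {
    "mt": {"offsets": (6.0, 8.0, 10.0, 12.0, 14.0), "b1": (1.0, 6.0),
           "sat": 2.5, "tr": 3.7, "alternate": False},
    "rnoe": {"offsets": (-3.5,), "b1": (0.2, 2.0),
             "sat": 2.5, "tr": 3.7, "alternate": False},
    "amide": {"offsets": (3.5,), "b1": (0.5, 4.0),
              "sat": 2.5, "tr": 3.7, "alternate": False},
    "glu": {"offsets": (3.0,), "b1": (3.0, 8.0),
            "sat": 3.0, "tr": 4.0, "alternate": True},
}

_M0_TR = 15.0  # s
_M0_TE = 0.020  # s


@dataclass
class SaturationEvent:
    """A continuous-wave saturation block."""

    b1_amplitude: float  # uT
    frequency_offset: float  # ppm
    duration: float  # s
    shape: str = "continuous_wave"

    def validate(self) -> None:
        if self.b1_amplitude < 0:
            raise ValueError("b1_amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("saturation duration must be > 0")
        if self.shape != "continuous_wave":
            raise ValueError(f"unsupported saturation shape {self.shape!r}")


@dataclass
class ScheduleEntry:
    """One acquisition: optional saturation, then readout; absent saturation
    marks an unsaturated M0 acquisition."""

    saturation: Optional[SaturationEvent]
    tr: float  # s
    te: float  # s
    excitation_flip: float = 90.0  # degrees

    @property
    def is_m0(self) -> bool:
        return self.saturation is None

    @property
    def saturation_duration(self) -> float:
        return 0.0 if self.saturation is None else self.saturation.duration

    def validate(self) -> None:
        if self.saturation is not None:
            self.saturation.validate()
        if self.tr <= self.saturation_duration + self.te:
            raise ValueError(
                f"tr ({self.tr}) must exceed saturation duration + te "
                f"({self.saturation_duration + self.te})"
            )


@dataclass
class AcquisitionSchedule:
    entries: list[ScheduleEntry] = field(default_factory=list)
    b0_field: float = 7.0  # tesla
    name: str = ""
    # Dummy scans: number of saturated entries (directly after the M0 entry)
    # acquired only to put the spin system into its cyclic steady state;
    # their signal is discarded when a Z-spectrum is assembled.
    dummy_entries: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_duration(self) -> float:
        return float(sum(e.tr for e in self.entries))

    def validate(self, mrf: bool = False) -> None:
        if self.b0_field <= 0:
            raise ValueError("b0_field must be > 0")
        for entry in self.entries:
            entry.validate()
        if mrf:
            if len(self.entries) != 31:
                raise ValueError(f"MRF protocol needs 31 entries, got {len(self.entries)}")
            first = self.entries[0]
            if not first.is_m0 or first.tr != _M0_TR or first.te != _M0_TE:
                raise ValueError("MRF protocol must start with an M0 entry at TR/TE = 15/0.020 s")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        entries = []
        for e in self.entries:
            d = {"tr_s": e.tr, "te_s": e.te, "flip_deg": e.excitation_flip}
            if e.saturation is not None:
                d.update(
                    b1_uT=e.saturation.b1_amplitude,
                    offset_ppm=e.saturation.frequency_offset,
                    sat_duration_s=e.saturation.duration,
                    shape=e.saturation.shape,
                )
            entries.append(d)
        return {"name": self.name, "b0_field_T": self.b0_field,
                "dummy_entries": self.dummy_entries, "entries": entries}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        entries = []
        for ed in d["entries"]:
            sat = None
            if "b1_uT" in ed:
                sat = SaturationEvent(
                    b1_amplitude=float(ed["b1_uT"]),
                    frequency_offset=float(ed["offset_ppm"]),
                    duration=float(ed["sat_duration_s"]),
                    shape=ed.get("shape", "continuous_wave"),
                )
            entries.append(
                ScheduleEntry(
                    saturation=sat,
                    tr=float(ed["tr_s"]),
                    te=float(ed["te_s"]),
                    excitation_flip=float(ed.get("flip_deg", 90.0)),
                )
            )
        return cls(entries=entries, b0_field=float(d.get("b0_field_T", 7.0)),
                   name=str(d.get("name", "")),
                   dummy_entries=int(d.get("dummy_entries", 0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Stable hash of the acquisition parameters (used to guard that
        trained models are only applied to data from the matching protocol)."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_schedule(target: str, seed: int = 2026, n_entries: int = 31,
                     b0_field: float = 7.0) -> AcquisitionSchedule:
    """Build the default pseudo-random MRF protocol for one molecular target.

    The first entry is the unsaturated M0 acquisition (TR 15 s, TE 20 ms);
    the remaining 30 entries saturate at the target's offset with B1 drawn
    uniformly from the target's power range.  The glutamate protocol
    additionally alternates the offset between +3 and -3 ppm (see
    ``_TARGET_RANGES``).  Total protocol duration sits in the 120-135 s
    per-protocol envelope.  Generation is fully seeded.
    """
    if target not in MRF_TARGETS:
        raise ValueError(f"target must be one of {MRF_TARGETS}, got {target!r}")
    rng = np.random.default_rng([seed, MRF_TARGETS.index(target)])
    ranges = _TARGET_RANGES[target]
    entries = [ScheduleEntry(saturation=None, tr=_M0_TR, te=_M0_TE)]
    lo, hi = ranges["b1"]
    offsets = ranges["offsets"]
    for j in range(n_entries - 1):
        b1 = float(rng.uniform(lo, hi))
        offset = float(offsets[rng.integers(len(offsets))])
        if ranges["alternate"] and j % 2 == 1:
            offset = -offset
        entries.append(
            ScheduleEntry(
                saturation=SaturationEvent(b1, offset, duration=ranges["sat"]),
                tr=ranges["tr"],
                te=0.020,
            )
        )
    sched = AcquisitionSchedule(entries=entries, b0_field=b0_field, name=f"mrf_{target}")
    sched.validate(mrf=(n_entries == 31))
    return sched


def zspectrum_protocol(b1_uT: float, sat_duration: float, increment_ppm: float = 0.25,
                       sweep: tuple[float, float] = (7.0, -7.0), tr: float = 8.0,
                       te: float = 0.020, b0_field: float = 7.0,
                       name: str = "zspec") -> AcquisitionSchedule:
    """Z-spectrum sweep (default 7 -> -7 ppm), preceded by an M0 entry.

    Defaults mirror the three conventional CEST protocols: 0.7 uT / 3 s for
    slow-exchanging amide and rNOE pools, 5.9 uT / 0.5 s for the
    fast-exchanging glutamate amine pool, and 1.5 uT / 4 s (0.2 ppm steps)
    for pH-weighted AACID analysis.
    """
    hi, lo = sweep
    n_steps = int(round(abs(hi - lo) / increment_ppm)) + 1
    offsets = np.linspace(hi, lo, n_steps)
    entries = [ScheduleEntry(saturation=None, tr=_M0_TR, te=te)]
    # One dummy scan so every recorded entry starts from the identical
    # post-readout recovery state (the first entry would otherwise carry the
    # long-TR M0 transient and break the +-offset symmetry).
    for offset in np.concatenate([offsets[:1], offsets]):
        entries.append(
            ScheduleEntry(
                saturation=SaturationEvent(b1_uT, float(offset), sat_duration),
                tr=tr,
                te=te,
            )
        )
    sched = AcquisitionSchedule(entries=entries, b0_field=b0_field, name=name,
                                dummy_entries=1)
    sched.validate()
    return sched


def wassr_protocol(b0_field: float = 7.0) -> AcquisitionSchedule:
    """Low-power water saturation shift referencing sweep: 0.3 uT, 3 s
    saturation, -1 to 1 ppm in 0.1 ppm steps, TR/TE = 8000/20 ms."""
    return zspectrum_protocol(
        b1_uT=0.3, sat_duration=3.0, increment_ppm=0.1, sweep=(1.0, -1.0),
        tr=8.0, te=0.020, b0_field=b0_field, name="wassr",
    )
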