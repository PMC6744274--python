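"""Sampled experimental records: force-spectroscopy and transcription traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["Trace", "TxnTrace"]

PROTOCOLS = ("constant_velocity", "constant_force", "fixed_separation")


@dataclass
class Trace:
    """Uniformly sampled (time, force, extension) record of one tether.

    Attributes
    ----------
    time : array, s (strictly increasing, uniform)
    force : array, pN
    extension : array, nm (bead-to-bead distance minus handles is resolved
        downstream; this is the raw tether extension)
    sample_rate : Hz (800 for pulling, 2500 for hopping by convention)
    protocol : one of ``constant_velocity``, ``constant_force``,
        ``fixed_separation``
    metadata : free-form labels (construct, nucleosome type, trap separation)
    """

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    sample_rate: float = 800.0
    protocol: str = "constant_velocity"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if not (len(self.time) == len(self.force) == len(self.extension)):
            raise ValidationError("time/force/extension must have equal length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(
                f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TxnTrace:
    """Transcription trajectory at constant assisting force.

    ``position`` is the contour transcribed in nm (from the bead-to-bead
    distance increase at constant force).  After ruler registration,
    ``registered_bp`` holds template positions normalized to the NPS start
    and ``leading_edge_bp`` adds the polymerase footprint offset.
    """

    time: np.ndarray
    position: np.ndarray
    force: float = 10.0
    sample_rate: float = 800.0
    registered_bp: np.ndarray | None = None
    leading_edge_bp: np.ndarray | None = None
    registration: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    #: leading edge of Pol II sits this many bp ahead of its active site
    FOOTPRINT_BP: int = 16

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if len(self.time) != len(self.position):
            raise ValidationError("time/position must have equal length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)
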