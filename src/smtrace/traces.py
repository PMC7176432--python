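"""In-memory containers for single-molecule fluorescence traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smtrace.errors import InvalidArgumentError


@dataclass
class FluorescenceTrace:
    """One spot's intensity time series.

    Parameters
    ----------
    trace_id : str
        Identifier, unique within a dataset.
    time : ndarray
        Acquisition time of each frame in seconds, strictly increasing.
    intensity : ndarray
        Integrated intensity per frame, arbitrary camera units (A.U.).
    frame_interval : float
        Nominal frame interval in seconds.
    channel : str
        Emission channel label (e.g. ``"eGFP"``).
    provenance : str
        Where the trace came from: ``"roi"`` for extracted traces,
        ``"synthetic"`` for simulated ones.
    meta : dict
        Free-form metadata (e.g. the normalisation scale applied).
    """

    trace_id: str
    time: np.ndarray
    intensity: np.ndarray
    frame_interval: float = 0.1
    channel: str = "eGFP"
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise InvalidArgumentError(
                "time and intensity must have equal length"
            )
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.size


@dataclass
class FretTrace:
    """Paired donor/acceptor intensity series for one FRET pair.

    The first ``check_frames`` frames are recorded under direct acceptor
    excitation (presence check for the acceptor dye); the remaining frames
    are donor-excitation analysis frames.
    """

    trace_id: str
    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    check_frames: int = 15
    frame_interval: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.time.shape == self.donor.shape == self.acceptor.shape):
            raise InvalidArgumentError("channel lengths must match")
        if self.check_frames < 0 or self.check_frames >= self.time.size:
            raise InvalidArgumentError(
                "check block must precede at least one analysis frame"
            )
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def analysis_slice(self) -> slice:
        """Frames recorded under donor excitation."""
        return slice(self.check_frames, self.n_frames)
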