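"""Sample-level container for monocular eye-tracking recordings.

A :class:`SampleTrace` holds one recording's time series of gaze position
(degrees), pupil value (device area units before calibration, mm after) and
a per-sample validity flag, at a fixed sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SampleTrace"]


@dataclass
class SampleTrace:
    """One recording's sample stream.

    Attributes
    ----------
    t : ndarray
        Sample timestamps in ms since recording start, strictly increasing
        with constant step ``1000 / rate``.
    gaze_x, gaze_y : ndarray
        Gaze position in degrees of visual angle.
    pupil : ndarray
        Pupil value; device area units when ``unit == "area"``, diameter in
        mm when ``unit == "mm"``.
    valid : ndarray of bool
        Tracker validity flag per sample (False during blinks / data loss).
    rate : float
        Sampling rate in Hz.
    unit : str
        ``"area"`` or ``"mm"``.
    """

    t: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    rate: float
    unit: str = "area"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        for name in ("gaze_x", "gaze_y", "pupil", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from t")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def dt(self) -> float:
        """Sampling step in ms."""
        return 1000.0 / self.rate

    def __len__(self) -> int:
        return self.t.size

    def copy(self) -> "SampleTrace":
        return replace(
            self,
            t=self.t.copy(),
            gaze_x=self.gaze_x.copy(),
            gaze_y=self.gaze_y.copy(),
            pupil=self.pupil.copy(),
            valid=self.valid.copy(),
        )

    def window(self, t_lo: float, t_hi: float) -> "SampleTrace":
        """Sub-trace with ``t_lo <= t <= t_hi`` (closed window)."""
        m = (self.t >= t_lo) & (self.t <= t_hi)
        return replace(
            self,
            t=self.t[m],
            gaze_x=self.gaze_x[m],
            gaze_y=self.gaze_y[m],
            pupil=self.pupil[m],
            valid=self.valid[m],
        )
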