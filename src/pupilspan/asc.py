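"""Minimal EyeLink ASC text importer (optional entry point).

Parses the two line types needed by this pipeline from an `edf2asc`
export: sample lines (``<time> <x> <y> <pupil> ...``, missing data as
dots) and ``MSG <time> <text>`` event markers.  Gaze is returned in the
file's native units (pixels unless the export was degree-calibrated);
pupil in device area units.  This importer is a convenience for feeding
real recordings into the canonical TSV formats — the pipeline itself
reads only those.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trace import SampleTrace

__all__ = ["read_asc"]


def read_asc(path: str | Path, rate: float = 500.0
             ) -> tuple[SampleTrace, pd.DataFrame]:
    """Parse an ASC export into a trace and a message table."""
    times, xs, ys, pupils, valid = [], [], [], [], []
    messages = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "MSG" and len(parts) >= 3:
                messages.append({"time_ms": float(parts[1]),
                                 "message": " ".join(parts[2:])})
                continue
            if not parts[0].lstrip("-").isdigit() or len(parts) < 4:
                continue  # header / event lines
            t = float(parts[0])
            try:
                x, y, p = (float(parts[1]), float(parts[2]),
                           float(parts[3]))
                ok = p > 0
            except ValueError:  # missing data rendered as dots
                x = y = p = np.nan
                ok = False
            times.append(t)
            xs.append(x)
            ys.append(y)
            pupils.append(p)
            valid.append(ok)
    if not times:
        raise ValueError(f"no sample lines found in {path}")
    trace = SampleTrace(t=np.asarray(times), gaze_x=np.asarray(xs),
                        gaze_y=np.asarray(ys), pupil=np.asarray(pupils),
                        valid=np.asarray(valid), rate=rate, unit="area")
    return trace, pd.DataFrame(messages, columns=["time_ms", "message"])
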