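"""Container for sampled extension/force records at constant trap separation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A uniformly sampled extension-time (and force-time) record.

    ``trap_separation_nm`` is constant over the record; molecule/construct
    information travels in ``metadata``.
    """

    time_s: np.ndarray
    extension_nm: np.ndarray
    force_pn: np.ndarray | None = None
    trap_separation_nm: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        if self.force_pn is not None:
            self.force_pn = np.asarray(self.force_pn, dtype=float)
        n = self.time_s.size
        if n < 2:
            raise ValueError("a trajectory needs at least two samples")
        if self.extension_nm.size != n or (
            self.force_pn is not None and self.force_pn.size != n
        ):
            raise ValueError("time, extension and force must have equal length")
        if not np.all(np.isfinite(self.time_s)) or not np.all(
            np.isfinite(self.extension_nm)
        ):
            raise ValueError("trajectory contains non-finite values")
        if self.force_pn is not None and not np.all(np.isfinite(self.force_pn)):
            raise ValueError("trajectory contains non-finite forces")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time base must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time base must be uniform")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.dt_s

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + self.dt_s

    def __len__(self) -> int:
        return int(self.time_s.size)
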