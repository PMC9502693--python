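"""Delta and acceleration (dynamic) feature expansion.

The delta of a feature sequence is the regression-slope estimate over a
window of ``M`` neighbours on each side,

    delta[r, i] = sum_{m=1..M} m * (v[r+m, i] - v[r-m, i])
                  / (2 * sum_{m=1..M} m**2),

the standard construction used for speech frame features.  Out-of-range
indices are clamped to the first/last row (edge replication).
Acceleration is the delta of the delta.  The default half-width M=2 gives
a 5-sample window.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["DynamicsConfig", "delta", "expand_dynamics"]


@dataclasses.dataclass(frozen=True)
class DynamicsConfig:
    """Window half-width for dynamic features: M neighbours each side."""

    M: int = 2

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"dynamics half-width M must be >= 1, got {self.M}")


def delta(matrix: np.ndarray, config: DynamicsConfig = DynamicsConfig()) -> np.ndarray:
    """Regression-slope delta of each column, with edge replication.

    Parameters
    ----------
    matrix : (R, D) array
        One row per time index, one column per feature.

    Returns
    -------
    (R, D) array of per-index delta values.
    """
    v = np.atleast_2d(np.asarray(matrix, dtype=float))
    if v.size == 0:
        raise ValueError("cannot compute dynamics of an empty matrix")
    r, _ = v.shape
    m_vals = np.arange(1, config.M + 1)
    denom = 2.0 * np.sum(m_vals**2)
    idx = np.arange(r)
    out = np.zeros_like(v)
    for m in m_vals:
        fwd = np.clip(idx + m, 0, r - 1)
        bwd = np.clip(idx - m, 0, r - 1)
        out += m * (v[fwd] - v[bwd])
    out /= denom
    return out


def expand_dynamics(
    matrix: np.ndarray, config: DynamicsConfig = DynamicsConfig()
) -> np.ndarray:
    """Append delta and acceleration columns: (R, D) -> (R, 3D).

    Column order is [static | delta | acceleration].  Applied to the ten
    cardiovascular measures this yields 30 columns per beat; applied to a
    three-formant track it yields 9 columns per frame.
    """
    v = np.atleast_2d(np.asarray(matrix, dtype=float))
    d = delta(v, config)
    a = delta(d, config)
    return np.hstack([v, d, a])
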