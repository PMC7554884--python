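"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (print-table convention).

    Python's built-in ``round`` uses banker's rounding; report tables
    conventionally round 0.05 up, so we do it explicitly.
    """
    factor = 10.0**ndigits
    scaled = value * factor
    # nudge by an epsilon proportional to magnitude to absorb float error in
    # quantities like 100*21/41 that are exact decimals mathematically
    eps = 1e-9 * max(1.0, abs(scaled))
    if scaled >= 0:
        return math.floor(scaled + 0.5 + eps) / factor
    return -math.floor(-scaled + 0.5 + eps) / factor


def as_vec3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} has non-finite components: {v}")
    return v


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (via normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
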