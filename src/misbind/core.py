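"""Angular arithmetic and shared enumerations.

All public angles are degrees in ``[0, 360)``; density code works in radians
internally and the conversion helpers live here so no other module owns a
conversion convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Angle",
    "Condition",
    "Permutation",
    "PROBE_CONDITIONS",
    "PARAM_GROUPS",
    "PERMUTATIONS",
    "wrap_angle",
    "circ_dist",
    "deg2rad",
    "rad2deg",
]

#: Alias documenting intent: an angle in degrees, wrapped to [0, 360).
Angle = float

#: Probe conditions: one feature dimension cued, or free whole report with
#: either colour (uncued_CL) or location (uncued_LC) reproduced first.
PROBE_CONDITIONS = ("cued_by_colour", "cued_by_location", "uncued_LC", "uncued_CL")

#: Parameter-sharing groups: the two cued probes share one parameter set.
PARAM_GROUPS = ("cued", "uncued_LC", "uncued_CL")

_PROBE_TO_GROUP = {
    "cued_by_colour": "cued",
    "cued_by_location": "cued",
    "uncued_LC": "uncued_LC",
    "uncued_CL": "uncued_CL",
}


@dataclass(frozen=True)
class Condition:
    """A probe condition and the parameter group it resolves to."""

    probe: str

    def __post_init__(self) -> None:
        if self.probe not in PROBE_CONDITIONS:
            raise ValueError(f"unknown probe condition {self.probe!r}")

    @property
    def param_group(self) -> str:
        return _PROBE_TO_GROUP[self.probe]

    @property
    def is_cued(self) -> bool:
        return self.param_group == "cued"

    @property
    def report_dim(self) -> str:
        """The freely recalled dimension in cued conditions ('colour'/'location');
        'both' for whole report."""
        if self.probe == "cued_by_colour":
            return "location"
        if self.probe == "cued_by_location":
            return "colour"
        return "both"


@dataclass(frozen=True)
class Permutation:
    """Bijection from the 3 response slots to the 3 object indices (0-based).

    ``mapping[s] == o`` means response slot ``s`` reports object ``o``.
    """

    mapping: tuple[int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.mapping) != [0, 1, 2]:
            raise ValueError(f"not a permutation of (0,1,2): {self.mapping}")

    @property
    def id(self) -> int:
        """Integer label 1-6 in lexicographic order of the mapping."""
        return PERMUTATIONS.index(self) + 1

    def inverse(self) -> "Permutation":
        inv = [0, 0, 0]
        for s, o in enumerate(self.mapping):
            inv[o] = s
        return Permutation(tuple(inv))

    def slot_of(self, obj: int) -> int:
        return self.mapping.index(obj)


#: All six report orders, lexicographic; PERMUTATIONS[0] is the identity.
PERMUTATIONS = tuple(
    Permutation(p) for p in itertools.permutations((0, 1, 2))
)

IDENTITY_PERMUTATION = PERMUTATIONS[0]


def _check_finite(x, name: str = "angle") -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite {name}")


def wrap_angle(x):
    """Wrap degrees onto ``[0, 360)``.  Accepts scalars or arrays."""
    _check_finite(x)
    wrapped = np.mod(x, 360.0)
    # np.mod maps tiny negatives to exactly 360.0 on occasion; fold back.
    wrapped = np.where(wrapped == 360.0, 0.0, wrapped)
    return float(wrapped) if np.isscalar(x) or np.ndim(x) == 0 else wrapped


def circ_dist(a, b):
    """Signed circular difference ``a - b`` in degrees, in ``(-180, 180]``.

    The antipodal case (exactly 180 deg apart) resolves to +180 so the result
    is deterministic.  Accepts scalars or broadcastable arrays.
    """
    _check_finite(a)
    _check_finite(b)
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    return float(out) if np.ndim(out) == 0 else out


def deg2rad(x):
    return np.asarray(x, dtype=float) * (math.pi / 180.0)


def rad2deg(x):
    return np.asarray(x, dtype=float) * (180.0 / math.pi)
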