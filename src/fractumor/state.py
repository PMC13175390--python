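"""State vector for the 15-compartment tumor-immune-microenvironment model.

Compartments
------------
N1, N2   sensitive / partially resistant tumor cells (arbitrary count units)
I1, I2   cytotoxic / regulatory immune cells
P        metastatic potential (dimensionless)
A        angiogenesis factor (dimensionless)
Q        quiescent tumor cells
R1, R2   type-1 / type-2 resistant tumor cells
S        senescent tumor cells
D        drug concentration (dimensionless, sum over drug types)
Dm       metabolized drug
G        genetic stability index in [0, 1]
M        metabolism status (glycolytic shift)
H        hypoxia level
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

STATE_NAMES = (
    "N1", "N2", "I1", "I2", "P", "A", "Q",
    "R1", "R2", "S", "D", "Dm", "G", "M", "H",
)

#: indices of the compartments that count toward total tumor burden
TUMOR_INDICES = (0, 1, 6, 7, 8, 9)

#: nonnegativity floor applied at every derivative evaluation
STATE_FLOOR = 1e-6


class InvalidStateError(ValueError):
    """Raised when a state vector contains non-finite entries."""


@dataclass
class StateVector:
    """One point of the 15-compartment state, by name."""

    N1: float = 0.0
    N2: float = 0.0
    I1: float = 0.0
    I2: float = 0.0
    P: float = 0.0
    A: float = 0.0
    Q: float = 0.0
    R1: float = 0.0
    R2: float = 0.0
    S: float = 0.0
    D: float = 0.0
    Dm: float = 0.0
    G: float = 1.0
    M: float = 0.0
    H: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(STATE_NAMES),):
            raise InvalidStateError(f"expected {len(STATE_NAMES)} components, got {arr.shape}")
        return cls(**dict(zip(STATE_NAMES, arr)))

    def floored(self, floor: float = STATE_FLOOR) -> "StateVector":
        return StateVector.from_array(np.maximum(self.to_array(), floor))


def as_state_array(state) -> np.ndarray:
    """Accept a :class:`StateVector` or an array-like and return a (15,) float array."""
    if isinstance(state, StateVector):
        arr = state.to_array()
    else:
        arr = np.asarray(state, dtype=float)
    if arr.shape != (len(STATE_NAMES),):
        raise InvalidStateError(f"expected {len(STATE_NAMES)} components, got {arr.shape}")
    return arr


def initial_state() -> StateVector:
    """Reference initial condition used for the 500-day simulations."""
    return StateVector(
        N1=190.0, N2=10.0, I1=40.0, I2=10.0, P=0.1, A=1.0, Q=0.1,
        R1=1.0, R2=1.0, S=0.1, D=0.0, Dm=0.0, G=1.0, M=1.0, H=0.0,
    )


def _check_finite(arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(arr))]
        raise InvalidStateError(f"non-finite state components: {bad}")


# keep dataclass field order in sync with STATE_NAMES
assert tuple(f.name for f in fields(StateVector)) == STATE_NAMES
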