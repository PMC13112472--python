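"""Bundled rigid gas probes and host nonbonded parameter container.

O2 is modelled as two LJ sites 1.21 Å apart with near-zero partial charges
(±0.02 e), CO2 as a linear three-site model (C–O 1.16 Å) with +0.6 e on
carbon and −0.3 e on each oxygen.  LJ parameters are CHARMM-style values
for molecular oxygen and carbon dioxide.  Insertion maps computed for CO2
should be treated with caution: its sizable partial charges make
orientation-implicit free-energy estimates unreliable for polar media, and
the mapper emits a warning when asked for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ProbeLigand, ProbeSite

__all__ = ["O2", "CO2", "HostParams", "get_probe"]

O2 = ProbeLigand(
    name="O2",
    sites=(
        ProbeSite("O1", epsilon=0.112, sigma=3.029, charge=+0.02, local_position=(0.0, 0.0, -0.605)),
        ProbeSite("O2", epsilon=0.112, sigma=3.029, charge=-0.02, local_position=(0.0, 0.0, +0.605)),
    ),
)

CO2 = ProbeLigand(
    name="CO2",
    sites=(
        ProbeSite("C", epsilon=0.058, sigma=2.785, charge=+0.60, local_position=(0.0, 0.0, 0.0)),
        ProbeSite("O1", epsilon=0.165, sigma=3.014, charge=-0.30, local_position=(0.0, 0.0, -1.16)),
        ProbeSite("O2", epsilon=0.165, sigma=3.014, charge=-0.30, local_position=(0.0, 0.0, +1.16)),
    ),
)

_BUILTIN = {"o2": O2, "co2": CO2}


def get_probe(name: str) -> ProbeLigand:
    """Look up a bundled probe by name (case-insensitive)."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise KeyError(f"unknown probe {name!r}; bundled probes: {sorted(_BUILTIN)}")


@dataclass
class HostParams:
    """Per-atom nonbonded parameters of the host, aligned with a Structure."""

    epsilon: np.ndarray  # kcal/mol
    sigma: np.ndarray  # Å
    charge: np.ndarray  # e

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        if not (self.epsilon.shape == self.sigma.shape == self.charge.shape):
            raise ValueError("epsilon, sigma, charge must have equal lengths")

    @property
    def n_atoms(self) -> int:
        return self.epsilon.shape[0]

    @staticmethod
    def uniform(n_atoms: int, epsilon: float, sigma: float, charge: float = 0.0) -> "HostParams":
        return HostParams(
            epsilon=np.full(n_atoms, epsilon),
            sigma=np.full(n_atoms, sigma),
            charge=np.full(n_atoms, charge),
        )
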