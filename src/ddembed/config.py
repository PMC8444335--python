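"""Run configuration shared by the library, the CLI and the readers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .ddcosmo import SolverConfig, f_of_eps
from .errors import ConfigurationError
from .grids import SUPPORTED_ORDERS


@dataclass
class TreeConfig:
    """Settings of the tree-code accelerator."""

    order: int = 8  # multipole expansion order p
    theta: float = 0.5  # opening criterion (0: always direct)
    leaf_size: int = 32
    tolerance: float = 0.0  # target relative accuracy; 0 = no advisory

    def __post_init__(self):
        if self.order < 2:
            raise ConfigurationError("tree expansion order must be >= 2")
        if not (0.0 <= self.theta < 1.0):
            raise ConfigurationError("opening criterion theta must be in [0, 1)")


@dataclass
class RunConfig:
    """All tunables of an embedding calculation, with validation.

    ``epsilon_optical`` is accepted for forward compatibility with
    response calculations and is unused by the ground-state engine.
    """

    epsilon: float = 15.0
    epsilon_optical: float = 2.0
    f_scheme: str = "cosmo"
    lmax: int = 6
    grid_order: int = 110
    eta: float = 0.1
    tol: float = 1e-8
    max_iter: int = 500
    diis_depth: int = 10
    macro_tol: float = 0.0  # 0 -> use tol
    macro_max_iter: int = 100
    thole: float = 0.39
    d_scale: float = 1.0
    p_scale: float = 1.0
    energy_dipole_branch: str = "symmetric"
    acceleration: bool = False
    tree: TreeConfig = field(default_factory=TreeConfig)
    coord_unit: str = "angstrom"
    seed: int = 0

    def __post_init__(self):
        if not (self.epsilon >= 1.0 or np.isinf(self.epsilon)):
            raise ConfigurationError(
                "epsilon must be >= 1 (1: no continuum; inf: conductor limit)"
            )
        f_of_eps(self.epsilon, self.f_scheme)
        if self.grid_order not in SUPPORTED_ORDERS:
            raise ConfigurationError(
                f"grid_order {self.grid_order} unsupported; choose from {SUPPORTED_ORDERS}"
            )
        if not (0 <= self.lmax <= 16):
            raise ConfigurationError("lmax must be in [0, 16]")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if self.energy_dipole_branch != "symmetric":
            raise ConfigurationError(
                "only the symmetric dipole-branch energy convention is implemented"
            )
        if self.coord_unit not in ("angstrom", "bohr"):
            raise ConfigurationError("coord_unit must be 'angstrom' or 'bohr'")

    @property
    def f(self) -> float:
        return f_of_eps(self.epsilon, self.f_scheme)

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            lmax=self.lmax,
            grid_order=self.grid_order,
            epsilon=self.epsilon,
            f_scheme=self.f_scheme,
            tol=self.tol,
            max_iter=self.max_iter,
            diis_depth=self.diis_depth,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
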