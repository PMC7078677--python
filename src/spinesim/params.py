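"""Model parameters for the spine-fluctuation simulator.

:class:`ModelParams` is the single source of parameter truth.  Its defaults
are the standard parameterization of the model: a mature spine of radius
0.5 μm with a fixed post-synaptic density (PSD) and neck, actin kinetics of
the dynamic F-actin pool (branching, capping, uncapping, severing), and a
Helfrich-type membrane with pressure, line tension, and bending rigidity.

All lengths are in μm, times in s, forces in pN, concentrations in μM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .errors import ConfigurationError

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """All model constants plus derived remeshing/tolerance constants.

    Parameters
    ----------
    dt : float
        Time-step length (s).
    delta_s : float
        Target edge length of the membrane mesh (μm).
    r_s : float
        Initial spine radius (μm).
    r_neck : float
        Neck radius; vertices below the neck level are fixed (μm).
    r_PSD : float
        PSD radius; vertices above the PSD level are fixed (μm).
    n_f0 : int
        Number of polymerization foci inserted at the start of a run.
    gamma_cap, gamma_uncap, gamma_sever, gamma_f : float
        Barbed-end capping, minus-end uncapping, minus-end severing, and
        focus-nucleation rates (s^-1).
    a : float
        Profilin-ATP-actin concentration available for polymerization (μM).
    phi : float
        Branching-rate amplitude (μm^-2).
    k_on : float
        Barbed-end monomer assembly rate constant (μM^-1 s^-1).
    delta : float
        Length of an actin monomer (μm).
    kBT : float
        Thermal energy (pN μm).
    P : float
        Difference between internal and external pressure (pN μm^-2).
    tau : float
        Line tension (pN μm^-1).
    kappa : float
        Bending modulus (pN μm).
    alpha : float
        Amplitude of the Gaussian force kernel of a focus (pN).
    sigma : float
        Width of the Gaussian force kernel (used as a μm distance scale).
    zeta : float
        Mobility converting net force into vertex velocity (μm^2 s^-1 pN^-1).
    lam : float
        Distance scale of the PSD-distance weighting of nucleation (μm).
    nucleation_shell : float
        Membrane/PSD proximity radius used during nucleation (μm).
    d_tol : float
        Displacement tolerance of the adaptive membrane integrator (μm).
    d_min, d_max : float
        Remeshing bounds on edge lengths (μm); by default (3/5) delta_s and
        (4/3) delta_s.
    """

    dt: float = 1.0 / 8.0
    delta_s: float = 0.03
    r_s: float = 0.5
    r_neck: float = 0.0995
    r_PSD: float = 0.3571
    n_f0: int = 4
    gamma_cap: float = 1.0
    gamma_uncap: float = 1.0 / 30.0
    gamma_sever: float = 1.0
    gamma_f: float = 0.1
    a: float = 3.8
    phi: float = 75.0
    k_on: float = 11.6
    delta: float = 0.0022
    kBT: float = 0.0041
    P: float = 85.7143
    tau: float = 15.0
    kappa: float = 0.18
    alpha: float = 3.8
    sigma: float = 0.3
    zeta: float = 0.002
    lam: float = 0.025
    nucleation_shell: float = 0.1
    d_tol: float = 0.0001
    d_min: float = None  # type: ignore[assignment]  # derived: (3/5) delta_s
    d_max: float = None  # type: ignore[assignment]  # derived: (4/3) delta_s

    def __post_init__(self) -> None:
        if self.d_min is None:
            object.__setattr__(self, "d_min", 3.0 / 5.0 * self.delta_s)
        if self.d_max is None:
            object.__setattr__(self, "d_max", 4.0 / 3.0 * self.delta_s)
        self._validate()

    def _validate(self) -> None:
        positive = (
            "dt", "delta_s", "r_s", "kBT", "delta", "k_on", "zeta",
            "lam", "nucleation_shell", "d_tol", "d_min", "d_max",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = (
            "r_neck", "r_PSD", "gamma_cap", "gamma_uncap", "gamma_sever",
            "gamma_f", "a", "phi", "P", "tau", "kappa", "alpha", "sigma",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_f0 < 0:
            raise ConfigurationError(f"n_f0 must be >= 0, got {self.n_f0}")
        if self.r_PSD >= self.r_s:
            raise ConfigurationError(f"r_PSD ({self.r_PSD}) must be < r_s ({self.r_s})")
        if self.r_neck >= self.r_s:
            raise ConfigurationError(f"r_neck ({self.r_neck}) must be < r_s ({self.r_s})")
        if self.d_min >= self.d_max:
            raise ConfigurationError("d_min must be < d_max")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed.

        Derived remeshing bounds are re-derived from ``delta_s`` unless set
        explicitly in *changes*.
        """
        fields = dataclasses.asdict(self)
        if "delta_s" in changes and "d_min" not in changes:
            fields["d_min"] = None
        if "delta_s" in changes and "d_max" not in changes:
            fields["d_max"] = None
        fields.update(changes)
        return ModelParams(**fields)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    # -- plain-text configuration ------------------------------------------

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "ModelParams":
        """Read a flat ``key = value`` plain-text configuration file.

        Blank lines and lines starting with ``#`` are ignored.  Keys must be
        :class:`ModelParams` field names; values are parsed as numbers
        (``n_f0`` as an integer).
        """
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigurationError(f"{path}:{lineno}: unknown parameter {key!r}")
            try:
                values[key] = int(val) if key == "n_f0" else float(val)
            except ValueError as exc:
                raise ConfigurationError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
        return cls(**values)

    def to_config(self, path: Union[str, Path]) -> None:
        """Write the parameters as a flat ``key = value`` file."""
        lines = [f"{k} = {v!r}" for k, v in self.asdict().items()]
        Path(path).write_text("\n".join(lines) + "\n")
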