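"""Surgical patch material library and biaxial-test property extraction.

Patch and arterial tissues are modeled as isotropic, nearly incompressible
linear-elastic membranes.  Young's modulus and Poisson's ratio of the
patch fabrics come from planar biaxial tests: square samples stretched
sinusoidally in both axes; (E, nu) are recovered by a linear least-squares
fit of the plane-stress constitutive model over the arterial operating
strain range.  A synthetic biaxial-record generator reproduces that
protocol for testing and demonstration.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd


class MaterialError(KeyError):
    pass


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic shell material (SI units)."""

    name: str
    youngs_modulus: float      # Pa
    poissons_ratio: float
    thickness: float           # m

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError(f"E must be > 0, got {self.youngs_modulus}")
        if not (0.0 <= self.poissons_ratio < 0.5):
            raise ValueError(
                f"nu must be in [0, 0.5), got {self.poissons_ratio}")
        if self.thickness <= 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")


_LIBRARY = {
    # name: (nu, E [MPa], thickness [mm])
    "porcine xenopericardium": (0.39, 2.89, 0.4),
    "human pericardium": (0.40, 3.40, 0.5),
    "PTFE": (0.31, 1.40, 0.7),
    "Dacron": (0.42, 1.19, 0.6),
    "MPA artery 9yr": (0.45, 0.75, 1.0),
}

_ALIASES = {
    "artery": "MPA artery 9yr",
    "mpa": "MPA artery 9yr",
    "ptfe": "PTFE",
    "dacron": "Dacron",
}


def material_library() -> Dict[str, MaterialModel]:
    """The five measured materials: four patch fabrics plus the pediatric
    main-pulmonary-artery wall."""
    return {
        name: MaterialModel(name, e_mpa * 1e6, nu, t_mm * 1e-3)
        for name, (nu, e_mpa, t_mm) in _LIBRARY.items()
    }


def get_material(name: str) -> MaterialModel:
    lib = material_library()
    if name in lib:
        return lib[name]
    key = _ALIASES.get(name.strip().lower())
    if key is not None:
        return lib[key]
    raise MaterialError(
        f"unknown material {name!r}; available: {sorted(lib)}")


# ---------------------------------------------------------------------------
# Plane-stress constitutive model
# ---------------------------------------------------------------------------


def plane_stress_forward(E: float, nu: float, strain_x, strain_y):
    """Stresses of the isotropic plane-stress law.

    sigma_x = E/(1 - nu^2) * (eps_x + nu * eps_y), and symmetrically for y.
    """
    if nu >= 0.5:
        raise ValueError("nu must be < 0.5")
    ex = np.asarray(strain_x, dtype=float)
    ey = np.asarray(strain_y, dtype=float)
    k = E / (1.0 - nu * nu)
    return k * (ex + nu * ey), k * (ey + nu * ex)


# ---------------------------------------------------------------------------
# Biaxial dataset
# ---------------------------------------------------------------------------


@dataclass
class BiaxialDataset:
    """Planar biaxial test records: time, engineering strain pair, stress pair."""

    time: np.ndarray
    strain_x: np.ndarray
    strain_y: np.ndarray
    stress_x: np.ndarray          # Pa
    stress_y: np.ndarray          # Pa
    sample_size: float = 0.010    # m, square side
    protocol: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("strain_x", "strain_y", "stress_x", "stress_y"):
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")
        for s in (self.strain_x, self.strain_y):
            if np.any(s < -0.05) or np.any(s > 0.25):
                raise ValueError("strains outside the valid [-0.05, 0.25] range")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.time, "eps_x": self.strain_x, "eps_y": self.strain_y,
            "sig_x": self.stress_x, "sig_y": self.stress_y})

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_table(cls, path, **kw) -> "BiaxialDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(df["t"].to_numpy(), df["eps_x"].to_numpy(),
                   df["eps_y"].to_numpy(), df["sig_x"].to_numpy(),
                   df["sig_y"].to_numpy(), **kw)


def synth_biaxial(E: float, nu: float, peak_strain: float = 0.20,
                  n_cycles: float = 3.0, n_samples: int = 601,
                  phase_offset: float = np.pi / 3.0,
                  noise_level: float = 0.0,
                  seed: Optional[int] = None) -> BiaxialDataset:
    """Synthetic sinusoidal biaxial stretch of a square sample.

    Both axes are stretched sinusoidally up to ``peak_strain`` (default
    20%, the tested protocol); a phase offset between the axes breaks
    strain proportionality so that E and nu are separately identifiable.
    ``noise_level`` adds multiplicative Gaussian noise to the stresses.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if noise_level > 0 and seed is None:
        raise ValueError("seed required when noise_level > 0")
    t = np.linspace(0.0, n_cycles, n_samples)
    ex = 0.5 * peak_strain * (1.0 - np.cos(2.0 * np.pi * t))
    ey = 0.5 * peak_strain * (1.0 - np.cos(2.0 * np.pi * t + phase_offset))
    sx, sy = plane_stress_forward(E, nu, ex, ey)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        sx = sx * (1.0 + noise_level * rng.standard_normal(n_samples))
        sy = sy * (1.0 + noise_level * rng.standard_normal(n_samples))
    return BiaxialDataset(
        t, ex, ey, sx, sy,
        protocol=f"sinusoidal biaxial, peak {peak_strain:.0%}, "
                 f"phase offset {phase_offset:.3f} rad",
        metadata={"E_true": E, "nu_true": nu, "noise_level": noise_level,
                  "seed": seed, "strain_source": "synthetic"})


# ---------------------------------------------------------------------------
# Least-squares (E, nu) extraction
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    youngs_modulus: float
    poissons_ratio: float
    residual_norm: float
    r2_x: float
    r2_y: float
    n_used: int
    identifiable: bool = True
    identifiable_modulus: Optional[float] = None  # E/(1-nu) when degenerate


def fit_linear_elastic(data: BiaxialDataset,
                       strain_window: Tuple[float, float] = (0.0, 0.15),
                       ) -> FitResult:
    """Recover (E, nu) from biaxial records by linear least squares.

    The plane-stress law is linear in a = E/(1-nu^2) and b = nu*E/(1-nu^2):
    sigma_x = a*eps_x + b*eps_y, sigma_y = b*eps_x + a*eps_y.  Stacking both
    channels gives an ordinary least-squares problem; E and nu follow from
    (a, b).  Records are restricted to the operating strain window of the
    artery (default 0-15% on both axes).

    Strictly proportional (e.g. equibiaxial) strain paths leave only the
    combination E/(1-nu) identifiable; a warning is raised and that
    combination reported.
    """
    lo, hi = strain_window
    keep = ((data.strain_x >= lo) & (data.strain_x <= hi)
            & (data.strain_y >= lo) & (data.strain_y <= hi))
    n = int(keep.sum())
    if n < 10:
        raise ValueError(
            f"only {n} records inside strain window {strain_window}; >=10 required")
    ex, ey = data.strain_x[keep], data.strain_y[keep]
    sx, sy = data.stress_x[keep], data.stress_y[keep]

    A = np.block([[ex[:, None], ey[:, None]], [ey[:, None], ex[:, None]]])
    rhs = np.concatenate([sx, sy])
    coef, _, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    a, b = coef
    resid = A @ coef - rhs
    residual_norm = float(np.linalg.norm(resid))

    def _r2(pred, obs):
        ss = np.sum((obs - obs.mean()) ** 2)
        return 1.0 - np.sum((obs - pred) ** 2) / ss if ss > 0 else 1.0

    pred = A @ coef
    m = len(ex)
    r2x = _r2(pred[:m], sx)
    r2y = _r2(pred[m:], sy)

    degenerate = rank < 2 or (sv[0] > 0 and sv[1] / sv[0] < 1e-8)
    if degenerate:
        # only sigma/(eps_x + eps_y) = E/(1-nu) is determined
        e_over = float(a + b)
        warnings.warn(
            "proportional strain paths: E and nu are not separately "
            f"identifiable; only E/(1-nu) = {e_over:.6g} Pa is determined",
            stacklevel=2)
        return FitResult(np.nan, np.nan, residual_norm, r2x, r2y, n,
                         identifiable=False, identifiable_modulus=e_over)

    nu = float(b / a)
    E = float(a * (1.0 - nu * nu))
    return FitResult(E, nu, residual_norm, r2x, r2y, n)
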