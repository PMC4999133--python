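"""Diffusion acquisition protocols and gradient-direction schemes.

Unit convention
---------------
Internally b-values are expressed in ms/µm² (a stored value of 1.2
corresponds to 1200 s/mm²) and diffusivities in µm²/ms, so that the
product ``b * D`` is dimensionless.  Converters to and from s/mm² are
provided for file interchange.

The volume ordering convention throughout the package is *b0 first*:
a scheme with ``n_b0`` unweighted volumes and ``n`` weighted ones maps
to a 4D series whose first ``n_b0`` volumes are unweighted.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientScheme",
    "ProtocolTiming",
    "AcquisitionProtocol",
    "builtin_protocol",
    "protocol_from_config",
    "generate_directions",
    "design_matrix",
    "is_tensor_estimable",
    "b_from_s_mm2",
    "b_to_s_mm2",
    "read_fsl_tables",
    "write_fsl_tables",
    "SLICE_AXIS",
    "READ_AXIS",
    "B0_THRESHOLD_S_MM2",
    "SchemeError",
]

#: slice-select axis of the imaging frame (the cord runs along it)
SLICE_AXIS = np.array([0.0, 0.0, 1.0])
#: readout axis of the imaging frame (in-plane, perpendicular to the cord)
READ_AXIS = np.array([1.0, 0.0, 0.0])

#: b-values below this (in s/mm²) are classified as unweighted
B0_THRESHOLD_S_MM2 = 50.0

_UNIT_TOL = 1e-9


class SchemeError(ValueError):
    """Raised for invalid gradient schemes or protocol definitions."""


def b_from_s_mm2(b):
    """Convert b-values from s/mm² to the internal ms/µm² convention."""
    return np.asarray(b, dtype=float) * 1e-3


def b_to_s_mm2(b):
    """Convert internal b-values (ms/µm²) to s/mm²."""
    return np.asarray(b, dtype=float) * 1e3


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion encoding: weighted directions, b-values, and b0 count.

    Parameters
    ----------
    directions : (n, 3) array
        Unit direction vector per *weighted* volume.
    bvalues : (n,) array
        b-value per weighted volume, ms/µm².
    n_b0 : int
        Number of unweighted volumes (stored first in the 4D series).
    """

    directions: np.ndarray
    bvalues: np.ndarray
    n_b0: int = 1

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        bvals = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise SchemeError("directions must be an (n, 3) array")
        if len(dirs) != len(bvals):
            raise SchemeError(
                f"direction count ({len(dirs)}) != b-value count ({len(bvals)})"
            )
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SchemeError("all weighted directions must be unit vectors")
        # tighten to exact unit norm
        object.__setattr__(self, "directions", dirs / norms[:, None])
        if np.any(bvals < 0):
            raise SchemeError("b-values must be non-negative")
        if self.n_b0 < 0:
            raise SchemeError("n_b0 must be non-negative")
        if np.any(bvals > 0) and self.n_b0 < 1:
            raise SchemeError("n_b0 >= 1 required when weighted volumes exist")

    @property
    def n_weighted(self) -> int:
        return len(self.bvalues)

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_weighted

    def full_bvalues(self) -> np.ndarray:
        """b-value per volume (b0 volumes first), ms/µm²."""
        return np.concatenate([np.zeros(self.n_b0), self.bvalues])

    def full_directions(self) -> np.ndarray:
        """Direction per volume (zero vectors for the b0 volumes)."""
        return np.vstack([np.zeros((self.n_b0, 3)), self.directions])

    def write_fsl(self, bval_path, bvec_path) -> None:
        """Write the scheme as FSL-dialect bval/bvec text tables (s/mm²)."""
        write_fsl_tables(bval_path, bvec_path,
                         b_to_s_mm2(self.full_bvalues()),
                         self.full_directions())


@dataclass(frozen=True)
class ProtocolTiming:
    """Pulse timing metadata in ms (informational only: the signal model
    depends on the sequence only through the total b-value)."""

    delta: float = 0.0     # gradient duration δ
    Delta: float = 0.0     # gradient separation Δ
    te: float = 0.0
    tr: float = 0.0


@dataclass(frozen=True)
class AcquisitionProtocol:
    """A gradient scheme plus its averaging structure and timing."""

    name: str
    scheme: GradientScheme
    n_averages: int = 1      # NA: complex-domain averages per volume
    n_repetitions: int = 1   # NR: magnitude-domain repetitions
    timing: ProtocolTiming = field(default_factory=ProtocolTiming)

    def __post_init__(self):
        if self.n_averages < 1 or self.n_repetitions < 1:
            raise SchemeError("n_averages and n_repetitions must be >= 1")


_BUILTIN = {
    "A": dict(ndir=126, bvalues_s_mm2=[700.0], nb0=10, na=6, nr=1,
              timing=ProtocolTiming(delta=3.0, Delta=11.0, te=22.3, tr=2100.0)),
    "B": dict(ndir=12, bvalues_s_mm2=[1200.0], nb0=5, na=4, nr=15,
              timing=ProtocolTiming(delta=4.0, Delta=11.0, te=23.3, tr=2100.0)),
    "C": dict(bvalues_s_mm2=[200.0, 400.0, 800.0, 1200.0, 1500.0],
              nb0=5, na=4, nr=20,
              timing=ProtocolTiming(delta=4.0, Delta=11.0, te=23.3, tr=2100.0)),
}


@functools.lru_cache(maxsize=None)
def builtin_protocol(name: str, seed: int = 2016) -> AcquisitionProtocol:
    """Return one of the three built-in acquisition protocols.

    * ``A`` — 126 directions, b = 700 s/mm², 10 b0, NA=6, NR=1.
    * ``B`` — 12 directions, b = 1200 s/mm², 5 b0, NA=4, NR=15.
    * ``C`` — slice and read axes at b = 200/400/800/1200/1500 s/mm²,
      5 b0, NA=4, NR=20.  Not tensor-estimable (two directions only).

    ``seed`` controls the electrostatic direction layout of A and B
    (the two-direction scheme of C is fixed by the imaging frame).
    """
    key = str(name).upper()
    if key not in _BUILTIN:
        raise SchemeError(
            f"unknown protocol {name!r}; valid labels: {sorted(_BUILTIN)}"
        )
    p = _BUILTIN[key]
    if key == "C":
        # per b-value: one volume along the slice axis, one along read
        dirs, bvals = [], []
        for b in p["bvalues_s_mm2"]:
            dirs.extend([SLICE_AXIS, READ_AXIS])
            bvals.extend([b, b])
        scheme = GradientScheme(np.array(dirs), b_from_s_mm2(bvals), p["nb0"])
    else:
        dirs = generate_directions(p["ndir"], seed=seed)
        b = float(p["bvalues_s_mm2"][0])
        scheme = GradientScheme(dirs, b_from_s_mm2(np.full(p["ndir"], b)),
                                p["nb0"])
    return AcquisitionProtocol(name=key, scheme=scheme,
                               n_averages=p["na"], n_repetitions=p["nr"],
                               timing=p["timing"])


def protocol_from_config(cfg: dict) -> AcquisitionProtocol:
    """Build a protocol from a config mapping.

    Either ``{"name": "A"|"B"|"C", "seed": int}`` for a built-in, or a
    custom definition with keys ``name, ndir, bvalues_s_mm2, nb0, na,
    nr, seed`` (each b-value is applied to every direction).
    """
    name = str(cfg.get("name", "custom"))
    if name.upper() in _BUILTIN and "ndir" not in cfg:
        return builtin_protocol(name, seed=int(cfg.get("seed", 2016)))
    ndir = int(cfg["ndir"])
    bvals_s = [float(b) for b in np.atleast_1d(cfg["bvalues_s_mm2"])]
    dirs = generate_directions(ndir, seed=int(cfg.get("seed", 2016)))
    all_dirs = np.vstack([dirs] * len(bvals_s))
    all_b = np.repeat(bvals_s, ndir)
    scheme = GradientScheme(all_dirs, b_from_s_mm2(all_b),
                            int(cfg.get("nb0", 1)))
    return AcquisitionProtocol(name=name, scheme=scheme,
                               n_averages=int(cfg.get("na", 1)),
                               n_repetitions=int(cfg.get("nr", 1)))


def _pair_energy(g: np.ndarray) -> float:
    """Electrostatic energy of an antipodally symmetric point set."""
    diff = g[:, None, :] - g[None, :, :]
    summ = g[:, None, :] + g[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(len(g), k=1)
    return float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))


def _energy_grad(g: np.ndarray) -> np.ndarray:
    diff = g[:, None, :] - g[None, :, :]
    summ = g[:, None, :] + g[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    grad = -(diff / dd[..., None] ** 3).sum(axis=1)
    grad -= (summ / ds[..., None] ** 3).sum(axis=1)
    return grad


def generate_directions(n: int, seed: int = 0,
                        max_iter: int = 1000, tol: float = 1e-8) -> np.ndarray:
    """Generate ``n`` antipodally symmetric unit directions.

    Minimizes the electrostatic repulsion energy
    ``sum_{i<j} 1/|gi-gj| + 1/|gi+gj|`` by projected gradient descent
    on the unit sphere from a seeded random start.  Deterministic for a
    fixed ``(n, seed)`` pair.
    """
    if n < 2:
        raise SchemeError("at least 2 directions are required")
    rng = np.random.default_rng([int(seed), n])
    g = rng.normal(size=(n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)

    energy = _pair_energy(g)
    step = 0.1 / n
    for _ in range(max_iter):
        grad = _energy_grad(g)
        # project onto the tangent space of the sphere
        grad -= (grad * g).sum(axis=1, keepdims=True) * g
        moved = False
        for _ in range(40):  # backtracking line search
            trial = g - step * grad
            trial /= np.linalg.norm(trial, axis=1, keepdims=True)
            e_trial = _pair_energy(trial)
            if e_trial < energy:
                moved = True
                break
            step *= 0.5
        if not moved:
            break
        improvement = energy - e_trial
        g, energy = trial, e_trial
        step *= 1.3
        if improvement < tol:
            break
    # canonical hemisphere: slice-axis component >= 0
    flip = g[:, 2] < 0
    g[flip] *= -1.0
    return g


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear DTI design matrix, one row per volume (b0 rows first).

    Row for b-value ``b`` and direction ``g``::

        [-b*gx², -b*gy², -b*gz², -2b*gx*gy, -2b*gx*gz, -2b*gy*gz, 1]

    so that ``X @ [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0]`` equals
    ``ln S`` under the mono-exponential tensor model.
    """
    b = scheme.full_bvalues()
    g = scheme.full_directions()
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        -b * gx ** 2, -b * gy ** 2, -b * gz ** 2,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
        np.ones_like(b),
    ])


def is_tensor_estimable(scheme: GradientScheme) -> bool:
    """True when the scheme's design matrix has full column rank (7)."""
    return int(np.linalg.matrix_rank(design_matrix(scheme))) == 7


def write_fsl_tables(bval_path, bvec_path, bvals_s_mm2, directions) -> None:
    """Write FSL-dialect gradient tables.

    ``bval``: one space-separated row of b-values in s/mm²;
    ``bvec``: three rows (x, y, z) of direction components, ``%.6f``.
    """
    bvals = np.atleast_1d(np.asarray(bvals_s_mm2, dtype=float))
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if dirs.shape[0] != len(bvals):
        raise SchemeError("bval/bvec length mismatch")
    with open(bval_path, "w") as fh:
        fh.write(" ".join("%g" % b for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join("%.6f" % v for v in dirs[:, axis]) + "\n")


def read_fsl_tables(bval_path, bvec_path):
    """Read FSL-dialect gradient tables.

    Returns ``(bvals_s_mm2, directions)`` with ``directions`` of shape
    (n, 3); direction vectors are returned as stored (not normalized).
    """
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=float)
    bvecs = np.loadtxt(bvec_path, ndmin=2, dtype=float)
    if bvecs.shape[0] != 3:
        raise SchemeError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != len(bvals):
        raise SchemeError(
            f"bval/bvec column mismatch: {len(bvals)} vs {bvecs.shape[1]}"
        )
    return bvals, bvecs.T
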