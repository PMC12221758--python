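"""Gridded probability beliefs and the bounded reflected-diffusion density.

Beliefs over the stimulus space (unbounded, Gaussian-dominated) and the
decision-variable (DV) space (the unit interval) are represented as densities
evaluated on fixed grids.  The DV measurement distribution B(v, sigma) is the
stationary density of a Brownian particle released at ``v`` on [0, 1] with
reflecting walls; it is constructed, as in the generative story it encodes,
by laying down N(v, sigma) on an effectively bounded space [-b, b] and
repeatedly folding the mass outside [0, 1] back inside (reflection about 0,
then about 1, and so on) until nothing is left outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, InvalidArgumentError

__all__ = [
    "GridBelief",
    "stimulus_grid",
    "dv_grid",
    "gaussian_belief",
    "uniform_dv_belief",
    "bounded_density",
    "dv_likelihood",
    "leak_convolve",
    "refine_argmax",
    "DV_GRID_SIZE",
    "STIM_GRID_SIZE",
    "DEFAULT_BOUND",
]

#: default grid resolutions; the DV grid spacing (1/1000) divides both the
#: unit interval and the bound b=4 exactly, so reflections about 0 and 1 map
#: grid points onto grid points.
DV_GRID_SIZE = 1001
STIM_GRID_SIZE = 2001
DEFAULT_BOUND = 4.0

_NORM_CONST = 1.0 / np.sqrt(2.0 * np.pi)


def _npdf(x, mu, sigma):
    """Normal density without scipy call overhead (hot path)."""
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return _NORM_CONST / sigma * np.exp(-0.5 * z * z)


@dataclass(eq=False)
class GridBelief:
    """A discretized probability density on an ordered 1-D grid.

    Parameters
    ----------
    support : ndarray
        Strictly increasing evaluation points (stimulus units or DV units).
    density : ndarray
        Nonnegative density values at the grid points; the trapezoidal
        integral over the support is 1.
    space_tag : {"stimulus", "dv"}
        Which representational space the belief lives in.
    """

    support: np.ndarray
    density: np.ndarray
    space_tag: str = "stimulus"
    _cdf: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.support.ndim != 1 or self.support.shape != self.density.shape:
            raise InvalidArgumentError("support and density must be matching 1-D arrays")
        if self.space_tag not in ("stimulus", "dv"):
            raise InvalidArgumentError(f"unknown space_tag {self.space_tag!r}")
        if np.any(self.density < -1e-12):
            raise InvalidArgumentError("density must be nonnegative")

    @property
    def spacing(self) -> float:
        return float(self.support[1] - self.support[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.support))

    def normalized(self) -> "GridBelief":
        z = self.integral()
        if z <= 0:
            raise InvalidArgumentError("cannot normalize a zero-mass belief")
        return GridBelief(self.support, self.density / z, self.space_tag)

    def cdf(self) -> np.ndarray:
        """Cumulative trapezoidal integral of the density (cached)."""
        if self._cdf is None:
            d = self.density
            inc = 0.5 * (d[1:] + d[:-1]) * np.diff(self.support)
            c = np.concatenate(([0.0], np.cumsum(inc)))
            self._cdf = c / c[-1]
        return self._cdf

    def cdf_at(self, x: float) -> float:
        """CDF evaluated at ``x`` by linear interpolation, clipped to [0, 1]."""
        if not np.isfinite(x):
            raise InvalidArgumentError("cdf_at requires a finite point")
        c = self.cdf()
        if x <= self.support[0]:
            return 0.0
        if x >= self.support[-1]:
            return 1.0
        return float(np.clip(np.interp(x, self.support, c), 0.0, 1.0))

    def quantile(self, q: float) -> float:
        """Inverse CDF by linear interpolation."""
        if not 0.0 <= q <= 1.0:
            raise InvalidArgumentError("quantile level must lie in [0, 1]")
        c = self.cdf()
        return float(np.interp(q, c, self.support))

    def copy(self) -> "GridBelief":
        return GridBelief(self.support, self.density.copy(), self.space_tag)


def stimulus_grid(s0: float, sigma_s0: float, n: int = STIM_GRID_SIZE,
                  half_width: float = 6.0) -> np.ndarray:
    """Stimulus-space grid covering ``s0 +/- half_width * sigma_s0``."""
    if sigma_s0 <= 0:
        raise InvalidArgumentError("sigma_s0 must be positive")
    return np.linspace(s0 - half_width * sigma_s0, s0 + half_width * sigma_s0, n)


def dv_grid(n: int = DV_GRID_SIZE) -> np.ndarray:
    """DV-space grid: the unit interval inclusive of both endpoints."""
    return np.linspace(0.0, 1.0, n)


def gaussian_belief(mu: float, sigma: float, support: np.ndarray,
                    space_tag: str = "stimulus") -> GridBelief:
    if sigma <= 0 or not np.isfinite(mu):
        raise InvalidArgumentError("need finite mu and positive sigma")
    return GridBelief(support, _npdf(support, mu, sigma), space_tag).normalized()


def uniform_dv_belief(n: int = DV_GRID_SIZE) -> GridBelief:
    g = dv_grid(n)
    return GridBelief(g, np.ones_like(g), "dv")


def _fold_into_unit(dens: np.ndarray, i0: int, i1: int, tol: float = 0.0,
                    max_iter: int = 200) -> np.ndarray:
    """Fold a density on an extended grid back into the inside range.

    ``i0`` and ``i1`` index the grid points at exactly 0 and 1 of an evenly
    spaced extended grid.  Each pass reflects the tail left of 0 about 0 and
    then the tail right of 1 about 1 (the boundary limits included, matching
    the pointwise convention f(x) + f(-x) of the image expansion), moving any
    mass a reflection throws past the opposite bound into that bound's tail
    for the next pass.  Returns the folded density on the inside grid points
    ``i0..i1`` once the outside mass falls to ``tol`` of the total (each pass
    pushes the outside images two units further into the normal's tail, so
    with the default ``tol=0.0`` the remainder underflows to exactly zero
    within a handful of passes).
    """
    n_in = i1 - i0 + 1
    total = float(dens.sum())
    if total <= 0:
        raise InvalidArgumentError("cannot fold a zero-mass density")
    acc = dens[i0:i1 + 1].copy()
    left = dens[:i0 + 1].copy()   # values on x <= 0; left[-1] is the limit at 0
    right = dens[i1:].copy()      # values on x >= 1; right[0] is the limit at 1
    for it in range(max_iter):
        lmass = float(left[:-1].sum()) if left.size > 1 else 0.0
        rmass = float(right[1:].sum()) if right.size > 1 else 0.0
        # always run the first pass so the boundary-limit convention
        # f(0) + f(-0) holds even when the tail mass is negligible
        if it > 0 and lmass + rmass <= tol * total:
            return acc
        if lmass > 0 or it == 0:
            rev = left[::-1]                 # reflected: values on x = 0, h, ...
            m = min(n_in, rev.size)
            acc[:m] += rev[:m]
            if rev.size >= n_in:             # reflected mass past x = 1
                spill = rev[n_in - 1:]
                mr = min(spill.size, right.size)
                right[:mr] += spill[:mr]
            left[:] = 0.0
        rmass = float(right[1:].sum()) if right.size > 1 else 0.0
        if rmass > 0 or it == 0:
            rev = right[::-1]                # reflected: values on x = ..., 1
            m = min(n_in, rev.size)
            acc[n_in - m:] += rev[-m:]
            if rev.size >= n_in:             # reflected mass past x = 0
                spill = rev[:rev.size - n_in + 1]
                ml = min(spill.size, left.size)
                left[-ml:] += spill[-ml:]
            right[:] = 0.0
    raise ConvergenceError("folding did not converge within max_iter passes")


def bounded_density(v: float, sigma: float, grid: np.ndarray | None = None,
                    b: float = DEFAULT_BOUND) -> GridBelief:
    """B(v, sigma): reflected-diffusion density on [0, 1].

    A normal N(v, sigma) is laid out on the effectively bounded space
    [-b, b] (b defaults to 4, where the normal density is vanishingly small
    for the diffusion strengths of interest) and folded about 0 and 1 until
    all mass lies inside the unit interval; the result is normalized on the
    DV grid.

    Parameters
    ----------
    v : float
        Diffusion start point in [0, 1].
    sigma : float
        Diffusion strength (SD of the unreflected normal), > 0.
    grid : ndarray, optional
        DV grid on [0, 1]; defaults to the package's 1001-point grid.
    b : float
        Half-width of the effectively bounded construction space.
    """
    if not (np.isfinite(v) and np.isfinite(sigma)):
        raise InvalidArgumentError("v and sigma must be finite")
    if not 0.0 <= v <= 1.0:
        raise InvalidArgumentError("diffusion start point must lie in [0, 1]")
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be positive")
    if grid is None:
        grid = dv_grid()
    n = grid.size
    h = grid[1] - grid[0]
    # extended grid from -b to 1 + (b - 1) = b with the same spacing; both 0
    # and 1 fall on grid points because h divides 1 (and b is a multiple of h)
    n_left = int(round(b / h))
    n_right = int(round((b - 1.0) / h))
    ext = np.concatenate([
        -h * np.arange(n_left, 0, -1),
        grid,
        1.0 + h * np.arange(1, n_right + 1),
    ])
    dens = _npdf(ext, v, sigma)
    inside = _fold_into_unit(dens, n_left, n_left + n - 1)
    return GridBelief(grid, inside, "dv").normalized()


def dv_likelihood(m_v: float, sigma: float, grid: np.ndarray | None = None,
                  b: float = DEFAULT_BOUND,
                  convention: str = "generative") -> np.ndarray:
    """Likelihood of each DV state v given a DV measurement ``m_v``.

    Under the generative convention the likelihood of v is the density of
    B(v, sigma) evaluated at m_v (the measurement diffuses away from the
    state).  The folded density obeys the reflection-symmetry identity
    B(v, sigma)(x) = B(x, sigma)(v) -- each image term N(x; +/-v + 2k, sigma)
    is symmetric under exchanging x and v -- so the whole likelihood profile
    over v equals the single density B(m_v, sigma) evaluated on the v grid.
    The truncation of the construction space at +/-b perturbs the identity
    only by mass beyond b, which is negligible (< 1e-48 for the parameter
    ranges considered).  The alternate convention reads the measurement as
    the diffusion start point, which yields the same array here and is kept
    for interface completeness.
    """
    if convention not in ("generative", "measurement_start"):
        raise InvalidArgumentError(f"unknown likelihood convention {convention!r}")
    if not 0.0 <= m_v <= 1.0:
        raise InvalidArgumentError("m_v must lie in [0, 1]")
    return bounded_density(m_v, sigma, grid=grid, b=b).density


def leak_convolve(belief: GridBelief, sigma_leak: float,
                  fold: bool | None = None) -> GridBelief:
    """Convolve a belief with the leak kernel N(0, sigma_leak).

    DV-space beliefs are folded back into [0, 1] by the same reflection
    procedure used for B(v, sigma); stimulus-space beliefs are unbounded and
    simply renormalized on their grid.
    """
    if sigma_leak < 0:
        raise InvalidArgumentError("sigma_leak must be nonnegative")
    if fold is None:
        fold = belief.space_tag == "dv"
    h = belief.spacing
    if sigma_leak < 0.5 * h:
        # below grid resolution the kernel is a delta: identity transform
        return belief.normalized()
    half = max(1, int(np.ceil(6.0 * sigma_leak / h)))
    kx = h * np.arange(-half, half + 1)
    kernel = _npdf(kx, 0.0, sigma_leak) * h
    if fold:
        n = belief.support.size
        padded = np.zeros(n + 2 * half)
        padded[half:half + n] = belief.density
        conv = np.convolve(padded, kernel, mode="same")
        inside = _fold_into_unit(conv, half, half + n - 1)
        out = GridBelief(belief.support, inside, belief.space_tag)
    else:
        conv = np.convolve(belief.density, kernel, mode="same")
        out = GridBelief(belief.support, conv, belief.space_tag)
    return out.normalized()


def refine_argmax(support: np.ndarray, values: np.ndarray,
                  lo: float | None = None, hi: float | None = None) -> float:
    """Grid argmax refined by quadratic interpolation around the peak."""
    i = int(np.argmax(values))
    x = float(support[i])
    if 0 < i < values.size - 1:
        y0, y1, y2 = values[i - 1], values[i], values[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper local maximum
            x += 0.5 * (y0 - y2) / denom * (support[i + 1] - support[i])
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x
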