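"""Natural cubic spline basis with quantile knots.

The functional clustering model represents each latent MRD curve as a linear
combination of p natural cubic spline basis functions.  Natural splines are
the conventional choice for sparse longitudinal data: they are cubic between
knots and constrained to be linear beyond the boundary knots, which keeps
extrapolation at late follow-up times tame.

The basis used here is the standard truncated-power construction: with knots
xi_1 < ... < xi_p the functions are

    N_1(t) = 1,   N_2(t) = t,
    N_{k+2}(t) = d_k(t) - d_{p-1}(t),    k = 1..p-2,

    d_k(t) = [ (t - xi_k)_+^3 - (t - xi_p)_+^3 ] / (xi_p - xi_k),

which spans all natural cubic splines on those knots (dimension p for p
knots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NaturalCubicBasis", "build_basis"]


@dataclass(frozen=True)
class NaturalCubicBasis:
    """Natural cubic spline basis on a fixed ordered knot vector."""

    knots: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("need at least 2 distinct knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)

    @property
    def dimension(self) -> int:
        return int(self.knots.size)

    def evaluate(self, times) -> np.ndarray:
        """Design matrix S (n x p) of the basis at the query times."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        xi = self.knots
        p = xi.size
        S = np.empty((t.size, p))
        S[:, 0] = 1.0
        S[:, 1] = t
        if p > 2:
            pos = np.clip(t[:, None] - xi[None, :], 0.0, None) ** 3  # (n, p)
            d = (pos[:, :-1] - pos[:, -1:]) / (xi[-1] - xi[:-1])[None, :]
            S[:, 2:] = d[:, :-1] - d[:, -1:]
        if not np.all(np.isfinite(S)):
            raise FloatingPointError("non-finite basis evaluation")
        return S


def build_basis(all_times, p: int) -> NaturalCubicBasis:
    """Basis of dimension p with knots at quantiles of the pooled times.

    Raises a ``ValueError`` when fewer than p distinct times are available.
    """
    t = np.unique(np.asarray(all_times, dtype=float))
    if p < 2:
        raise ValueError("basis dimension p must be >= 2")
    if t.size < p:
        raise ValueError(
            f"basis dimension p={p} exceeds the {t.size} distinct observed times"
        )
    knots = np.quantile(t, np.linspace(0.0, 1.0, p))
    knots = np.unique(knots)
    if knots.size < p:  # quantile collisions on gappy grids: fall back to spread
        knots = np.linspace(t[0], t[-1], p)
    return NaturalCubicBasis(knots=knots)
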