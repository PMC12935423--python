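"""Singular spectrum analysis (SSA) of one time series.

SSA decomposes a length-``N`` series by (1) embedding it into an ``L x K``
Hankel trajectory matrix (``K = N - L + 1``) whose columns are lagged
windows, (2) taking the singular value decomposition of that matrix,
(3) grouping the rank-one terms ("eigentriples"), and (4) mapping each
group back to a series by diagonal (anti-diagonal) averaging. Summing all
reconstructed components returns the original series.

The interface follows the model/results convention: :class:`SSA` is
constructed from the data and ``fit()`` returns an
:class:`SSADecomposition` carrying the eigentriples, with reconstruction,
w-correlation and a ``summary()`` table hanging off the results object.

Numerical conventions (all deterministic):

* thin SVD of the trajectory matrix (never a randomized solver);
* eigentriples sorted by singular value, ties kept in original order;
* sign fixed by making the largest-magnitude entry of each left singular
  vector positive;
* singular values below ``1e-12 * sigma_1`` are treated as numerical zeros.

Eigentriple indices exposed to users are 1-based (index 1 is the leading
eigentriple), matching the convention of the SSA literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from scipy.signal import fftconvolve

from .exceptions import ParameterError

RANK_RTOL = 1e-12
DEFAULT_NEIG_CAP = 50


def default_window(n: int, fs: Optional[float] = None) -> int:
    """Default SSA window length for a length-``n`` series.

    One second of samples (``L = fs``) when the series is at least two
    seconds long — a window proportional to the tremor periodicity and far
    below ``N/2``, so slow voluntary trends do not mix into the oscillatory
    eigentriples — otherwise ``floor(n / 2)``.
    """
    if fs is not None and n >= 2 * int(fs):
        return int(fs)
    return max(2, n // 2)


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Hankel embedding of a series: entry (i, j) = x[i + j]."""

    values: np.ndarray
    L: int
    K: int
    N: int


def embed(series: Sequence[float], L: int) -> TrajectoryMatrix:
    """Embed ``series`` into its ``L x K`` Hankel trajectory matrix.

    Row ``i`` is ``(x_i, ..., x_{i+K-1})``; column ``j`` is the lagged
    window ``(x_j, ..., x_{j+L-1})``. Requires ``2 <= L <= N - 1``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if x.ndim != 1 or n < 3:
        raise ParameterError("series must be 1-D with at least 3 samples")
    if not 2 <= L <= n - 1:
        raise ParameterError(f"window length L={L} outside [2, {n - 1}]")
    values = scipy.linalg.hankel(x[:L], x[L - 1:])
    return TrajectoryMatrix(values=values, L=L, K=n - L + 1, N=n)


def diagonal_weights(L: int, K: int) -> np.ndarray:
    """Anti-diagonal multiplicities w_n = #{(i, j): i + j = n}, length N."""
    return np.convolve(np.ones(L), np.ones(K))


def _rank1_series(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    # anti-diagonal sums of outer(u, v) are exactly the linear convolution
    out = fftconvolve(u, v)
    return out / w


@dataclass(frozen=True)
class Grouping:
    """Named disjoint sets of 1-based eigentriple indices.

    Indices not assigned to any named group belong to the residual
    component, labelled ``residual_label``.
    """

    groups: Mapping[str, Tuple[int, ...]]
    residual_label: str = "residual"

    def __post_init__(self) -> None:
        seen: set = set()
        clean: Dict[str, Tuple[int, ...]] = {}
        for label, idx in self.groups.items():
            idx = tuple(sorted(int(i) for i in idx))
            for i in idx:
                if i < 1:
                    raise ParameterError(f"group {label!r}: index {i} < 1")
                if i in seen:
                    raise ParameterError(f"index {i} assigned to two groups")
                seen.add(i)
            clean[label] = idx
        object.__setattr__(self, "groups", clean)
        if self.residual_label in clean:
            raise ParameterError("residual label collides with a group name")

    def validate(self, d: int) -> None:
        for label, idx in self.groups.items():
            if idx and idx[-1] > d:
                raise ParameterError(
                    f"group {label!r}: index {idx[-1]} exceeds rank d={d}"
                )

    def assigned(self) -> Tuple[int, ...]:
        return tuple(sorted(i for idx in self.groups.values() for i in idx))


@dataclass(frozen=True)
class ComponentSet:
    """Reconstructed component series, one per group plus the residual."""

    components: Dict[str, np.ndarray]
    residual_label: str

    def __getitem__(self, label: str) -> np.ndarray:
        return self.components[label]

    def total(self) -> np.ndarray:
        """Sum of every component including the residual."""
        return np.sum(list(self.components.values()), axis=0)


class SSA:
    """SSA model for one series; ``fit()`` performs the decomposition.

    Parameters
    ----------
    series : array-like
        The time series to decompose.
    L : int, optional
        Window length; defaults to :func:`default_window`.
    neig : int, optional
        Cap on the number of retained eigentriples
        (default ``min(L, K, 50)``).
    fs : float, optional
        Sampling rate, used only to pick the default window.
    """

    def __init__(self, series, L: Optional[int] = None,
                 neig: Optional[int] = None, fs: Optional[float] = None):
        self.series = np.asarray(series, dtype=float)
        if self.series.ndim != 1 or self.series.size < 3:
            raise ParameterError("series must be 1-D with at least 3 samples")
        if not np.all(np.isfinite(self.series)):
            raise ParameterError("series must be finite")
        self.L = int(L) if L is not None else default_window(self.series.size, fs)
        if neig is not None and neig < 1:
            raise ParameterError("neig must be >= 1")
        self.neig = neig

    def fit(self) -> "SSADecomposition":
        traj = embed(self.series, self.L)
        U, sigma, Vt = scipy.linalg.svd(traj.values, full_matrices=False)
        # numerical rank: drop sigma below 1e-12 * sigma_1 (all of them if
        # the series is identically zero)
        if sigma.size and sigma[0] > 0:
            d = int(np.sum(sigma >= RANK_RTOL * sigma[0]))
        else:
            d = 0
        cap = self.neig if self.neig is not None else min(
            traj.L, traj.K, DEFAULT_NEIG_CAP)
        d = min(d, cap)
        U, sigma, V = U[:, :d].copy(), sigma[:d].copy(), Vt[:d].T.copy()
        # fixed sign convention: largest-magnitude entry of each U_i positive
        for i in range(d):
            j = int(np.argmax(np.abs(U[:, i])))
            if U[j, i] < 0:
                U[:, i] = -U[:, i]
                V[:, i] = -V[:, i]
        return SSADecomposition(
            series=self.series, L=traj.L, K=traj.K, N=traj.N,
            d=d, sigma=sigma, U=U, V=V,
        )


@dataclass(frozen=True)
class SSADecomposition:
    """Fitted SSA decomposition: eigentriples of one series.

    ``sigma`` holds the ``d`` retained singular values (non-increasing);
    ``U`` (``L x d``) the left singular vectors and ``V`` (``K x d``) the
    factor vectors, each column unit-norm.
    """

    series: np.ndarray
    L: int
    K: int
    N: int
    d: int
    sigma: np.ndarray
    U: np.ndarray
    V: np.ndarray
    _weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_weights", diagonal_weights(self.L, self.K))

    def elementary(self, i: int) -> np.ndarray:
        """Reconstructed series of the single eigentriple ``i`` (1-based)."""
        if not 1 <= i <= self.d:
            raise ParameterError(f"eigentriple index {i} outside 1..{self.d}")
        k = i - 1
        return self.sigma[k] * _rank1_series(
            self.U[:, k], self.V[:, k], self._weights)

    def reconstruct(self, grouping: Grouping) -> ComponentSet:
        """Diagonal-average each group; the residual absorbs the rest.

        The residual is the original series minus every named component, so
        the components plus the residual reproduce the input exactly.
        """
        grouping.validate(self.d)
        comps: Dict[str, np.ndarray] = {}
        for label, idx in grouping.groups.items():
            if idx:
                comps[label] = np.sum([self.elementary(i) for i in idx], axis=0)
            else:
                comps[label] = np.zeros(self.N)
        total = np.sum(list(comps.values()), axis=0) if comps else np.zeros(self.N)
        comps[grouping.residual_label] = self.series - total
        return ComponentSet(components=comps,
                            residual_label=grouping.residual_label)

    def w_correlation(self, k: Optional[int] = None) -> np.ndarray:
        """w-correlation matrix of the ``k`` leading elementary components.

        Entry (i, j) is the inner product of elementary components i and j
        under the anti-diagonal multiplicity weights, normalised to [-1, 1];
        near-zero means the eigentriples are separable, near ±1 that they
        belong to one oscillatory component.
        """
        if k is None:
            k = self.d
        if not 1 <= k <= self.d:
            raise ParameterError(f"k={k} outside 1..{self.d}")
        F = np.stack([self.elementary(i + 1) for i in range(k)])
        G = (F * self._weights) @ F.T
        norms = np.sqrt(np.diag(G))
        wcor = G / np.outer(norms, norms)
        np.fill_diagonal(wcor, 1.0)
        return np.clip(wcor, -1.0, 1.0)

    def summary(self) -> str:
        """Plain-text overview of the decomposition."""
        lam = self.sigma**2
        share = lam / lam.sum() if self.d else lam
        lines = [
            "SSA decomposition",
            f"  N = {self.N}, L = {self.L}, K = {self.K}, d = {self.d}",
            "  i      sigma_i   eigenvalue share",
        ]
        for i in range(min(self.d, 12)):
            lines.append(
                f"  {i + 1:<3d} {self.sigma[i]:>12.5g} {share[i]:>12.4%}")
        if self.d > 12:
            lines.append(f"  ... ({self.d - 12} further eigentriples)")
        return "\n".join(lines)


def decompose(series, L: Optional[int] = None, neig: Optional[int] = None,
              fs: Optional[float] = None) -> SSADecomposition:
    """Functional shorthand for ``SSA(series, L, neig, fs).fit()``."""
    return SSA(series, L=L, neig=neig, fs=fs).fit()


def reconstruct(model: SSADecomposition, grouping: Grouping) -> ComponentSet:
    """Functional shorthand for ``model.reconstruct(grouping)``."""
    return model.reconstruct(grouping)


def w_correlation(model: SSADecomposition, k: Optional[int] = None) -> np.ndarray:
    """Functional shorthand for ``model.w_correlation(k)``."""
    return model.w_correlation(k)
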