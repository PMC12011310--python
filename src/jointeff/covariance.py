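"""Covariance components of combined and separated mixed models.

The joint ("combined") model carries a full random-effects covariance ``D``
(Kq x Kq, blocked by measure) and a cross-measure residual covariance rule
built from a K x K per-observation matrix ``R``: residuals of two different
measures are correlated only when observed at the same time.  The
"separated" working model zeroes every cross-measure block of ``D`` and
every off-diagonal entry of ``R``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .design import SubjectDesign, assemble_block_design

__all__ = [
    "CovarianceComponents",
    "WorkingModel",
    "psd_repair",
    "build_bivariate_D",
    "build_bivariate_R",
    "build_residual_cov",
    "marginal_cov",
    "separate_components",
]

#: eigenvalue tolerance used by PSD validity checks
PSD_TOL = 1e-10

#: shared-visit tie tolerance for residual covariance
TIME_TIE_TOL = 1e-9


def psd_repair(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix to PSD, preserving its diagonal.

    Eigenvalue clipping with diagonal renormalisation: eigendecompose
    ``M = S diag(lam) S'``, clip ``lam`` at ``floor``, reconstruct, then
    rescale rows/columns so the original diagonal is restored.  Already-PSD
    input is returned unchanged.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("psd_repair expects a square matrix")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("psd_repair expects a symmetric matrix")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    lam, S = np.linalg.eigh((M + M.T) / 2.0)
    if lam.min() >= max(floor, 0.0) - 1e-14:
        return M
    lam_clipped = np.maximum(lam, floor)
    M2 = (S * lam_clipped) @ S.T
    d_orig = np.diag(M)
    d_new = np.diag(M2)
    if np.any((np.abs(d_orig) < 1e-14) & (np.abs(M).sum(axis=1) > 1e-12)):
        raise ValueError("cannot preserve diagonal: zero diagonal entry with nonzero row")
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(d_new > 0, np.sqrt(np.where(d_new > 0, d_orig / np.where(d_new > 0, d_new, 1.0), 1.0)), 0.0)
    out = M2 * np.outer(scale, scale)
    # exact symmetry and diagonal
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, d_orig)
    return out


@dataclass(frozen=True)
class CovarianceComponents:
    """Random-effects covariance ``D`` and residual covariance ``R``.

    ``D`` is (sum_k q_k) x (sum_k q_k), blocked in the measure order of the
    study; ``R`` is K x K in per-observation variance units.  ``q_per_measure``
    gives the block sizes of ``D``.
    """

    D: np.ndarray
    R: np.ndarray
    q_per_measure: tuple[int, ...]

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        q = tuple(int(v) for v in self.q_per_measure)
        if D.shape != (sum(q), sum(q)):
            raise ValueError(f"D has shape {D.shape}, expected {(sum(q), sum(q))}")
        if R.shape != (len(q), len(q)):
            raise ValueError(f"R has shape {R.shape}, expected {(len(q), len(q))}")
        for name, M in (("D", D), ("R", R)):
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if M.size and np.linalg.eigvalsh((M + M.T) / 2).min() < -PSD_TOL:
                raise ValueError(f"{name} is not positive semi-definite")
        object.__setattr__(self, "D", (D + D.T) / 2.0)
        object.__setattr__(self, "R", (R + R.T) / 2.0)
        object.__setattr__(self, "q_per_measure", q)

    @property
    def K(self) -> int:
        return len(self.q_per_measure)

    def block_slices(self) -> list[slice]:
        """Slices of D corresponding to each measure's random effects."""
        edges = np.concatenate([[0], np.cumsum(self.q_per_measure)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def is_separated(self, tol: float = 0.0) -> bool:
        off_D = self.D.copy()
        for s in self.block_slices():
            off_D[s, s] = 0.0
        off_R = self.R - np.diag(np.diag(self.R))
        return bool(np.abs(off_D).max(initial=0.0) <= tol and np.abs(off_R).max(initial=0.0) <= tol)


def separate_components(components: CovarianceComponents) -> CovarianceComponents:
    """Zero every cross-measure block of D and off-diagonal entry of R."""
    D = np.zeros_like(components.D)
    for s in components.block_slices():
        D[s, s] = components.D[s, s]
    R = np.diag(np.diag(components.R))
    return CovarianceComponents(D=D, R=R, q_per_measure=components.q_per_measure)


@dataclass(frozen=True)
class WorkingModel:
    """A labelled covariance specification used for estimator weights."""

    label: Literal["separated", "combined"]
    components: CovarianceComponents

    def __post_init__(self) -> None:
        if self.label not in ("separated", "combined"):
            raise ValueError("label must be 'separated' or 'combined'")
        if self.label == "separated" and not self.components.is_separated(tol=0.0):
            raise ValueError("separated working model must have zero cross-measure blocks")

    @classmethod
    def combined(cls, components: CovarianceComponents) -> "WorkingModel":
        return cls("combined", components)

    @classmethod
    def separated_from(cls, components: CovarianceComponents) -> "WorkingModel":
        """Separated working model obtained by zeroing the given components."""
        return cls("separated", separate_components(components))


# ---------------------------------------------------------------------------
# Bivariate two-measure parameterisation (cases A, B, C)
# ---------------------------------------------------------------------------

_CASE_D_DIAG = {"A": (1.0, 1.0, 1.0, 1.0), "B": (1.0, 1.0, 1.0, 1.0), "C": (1.0, 1.0, 1.0, 4.0)}
_CASE_R_DIAG = {"A": (1.0, 1.0), "B": (1.0, 4.0), "C": (1.0, 1.0)}


def _check_corr(name: str, value: float) -> float:
    value = float(value)
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [-1, 1], got {value}")
    return value


def build_bivariate_D(
    case: str, rho_b: float, rho_k1: float, rho_k2: float | None = None
) -> np.ndarray:
    """4x4 random-effects covariance of the two-measure study.

    Coordinates are (intercept1, slope1, intercept2, slope2).  ``rho_k1`` /
    ``rho_k2`` are the within-measure intercept-slope correlations, ``rho_b``
    the common cross-measure correlation applied to all four cross entries.
    Case A/B: unit variances; case C: slope-2 variance 4.  The raw matrix is
    passed through :func:`psd_repair`, so the result is always PSD.
    """
    if case not in _CASE_D_DIAG:
        raise ValueError(f"case must be one of A, B, C; got {case!r}")
    if rho_k2 is None:
        rho_k2 = rho_k1
    rho_b = _check_corr("rho_b", rho_b)
    rho_k1 = _check_corr("rho_k1", rho_k1)
    rho_k2 = _check_corr("rho_k2", rho_k2)
    d = np.asarray(_CASE_D_DIAG[case])
    C = np.eye(4)
    C[0, 1] = C[1, 0] = rho_k1
    C[2, 3] = C[3, 2] = rho_k2
    for i in (0, 1):
        for j in (2, 3):
            C[i, j] = C[j, i] = rho_b
    s = np.sqrt(d)
    D = C * np.outer(s, s)
    return psd_repair(D)


def build_bivariate_R(case: str, rho_r: float) -> np.ndarray:
    """2x2 per-observation residual covariance; case B has var(e2) = 4."""
    if case not in _CASE_R_DIAG:
        raise ValueError(f"case must be one of A, B, C; got {case!r}")
    rho_r = _check_corr("rho_r", rho_r)
    r = np.asarray(_CASE_R_DIAG[case])
    R = np.diag(r).astype(float)
    R[0, 1] = R[1, 0] = rho_r * np.sqrt(r[0] * r[1])
    return R


# ---------------------------------------------------------------------------
# Subject-level covariance assembly
# ---------------------------------------------------------------------------


def build_residual_cov(subject: SubjectDesign, R: np.ndarray) -> np.ndarray:
    """Residual covariance Sigma_i of the stacked observation vector.

    Within a measure, errors are independent with variance ``R[k, k]``.
    Across measures k != k', observations taken at the same time (within a
    1e-9 tie tolerance) have covariance ``R[k, k']``; observations at
    different times are uncorrelated.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape != (subject.K, subject.K):
        raise ValueError(f"R has shape {R.shape}, expected ({subject.K}, {subject.K})")
    times = subject.stacked_times()
    meas = subject.obs_measure_index()
    same_time = np.abs(times[:, None] - times[None, :]) <= TIME_TIE_TOL
    same_meas = meas[:, None] == meas[None, :]
    Sigma = np.where(same_time & ~same_meas, R[np.ix_(meas, meas)], 0.0)
    n = times.shape[0]
    Sigma[np.arange(n), np.arange(n)] = R[meas, meas]
    # same-measure off-diagonal stays zero even for duplicated times
    Sigma[same_meas & ~np.eye(n, dtype=bool)] = 0.0
    if np.linalg.eigvalsh((Sigma + Sigma.T) / 2).min() < -1e-8:
        raise AssertionError("residual covariance assembly produced a non-PSD matrix")
    return Sigma


def marginal_cov(
    subject: SubjectDesign, components: CovarianceComponents, return_inverse: bool = False
):
    """Marginal covariance ``V_i = Z_i D Z_i' + Sigma_i`` (and its inverse)."""
    _, Z = assemble_block_design(subject)
    Sigma = build_residual_cov(subject, components.R)
    V = Z @ components.D @ Z.T + Sigma
    V = (V + V.T) / 2.0
    if not return_inverse:
        return V
    try:
        W = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("degenerate marginal covariance") from exc
    resid = np.abs(W @ V - np.eye(V.shape[0])).max()
    if not np.isfinite(resid) or resid > 1e-6:
        raise np.linalg.LinAlgError("degenerate marginal covariance")
    W = (W + W.T) / 2.0
    return V, W


# ---------------------------------------------------------------------------
# CSV round trip for covariance components
# ---------------------------------------------------------------------------


def components_to_frames(components: CovarianceComponents, measure_ids):
    """(D, R) as labelled pandas DataFrames ('<measure>:<effect>' headers)."""
    import pandas as pd

    labels = []
    for mid, q in zip(measure_ids, components.q_per_measure):
        names = ("intercept", "slope") if q == 2 else tuple(f"re{j}" for j in range(q))
        labels.extend(f"{mid}:{n}" for n in names)
    D = pd.DataFrame(components.D, index=labels, columns=labels)
    R = pd.DataFrame(components.R, index=list(measure_ids), columns=list(measure_ids))
    return D, R


def components_from_frames(D_frame, R_frame) -> CovarianceComponents:
    measure_ids = list(R_frame.columns)
    q = []
    for mid in measure_ids:
        q.append(sum(1 for c in D_frame.columns if str(c).split(":")[0] == mid))
    return CovarianceComponents(
        D=D_frame.to_numpy(dtype=float), R=R_frame.to_numpy(dtype=float), q_per_measure=tuple(q)
    )
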