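"""Design containers for multivariate linear mixed models.

A study observes K longitudinal measures on each subject.  Measure ``k`` of
subject ``i`` contributes ``n_ik`` observations with fixed-effects design
``X_k`` (n_ik x p_k) and random-effects design ``Z_k`` (n_ik x q_k).  The
joint model stacks measures in declared order, time-ascending within each
measure, and the subject-level design matrices are block-diagonal (direct
sums) of the per-measure blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import block_diag

__all__ = ["MarkerDesign", "SubjectDesign", "assemble_block_design"]


@dataclass(frozen=True)
class MarkerDesign:
    """Design blocks for one measure of one subject.

    Parameters
    ----------
    measure_id : str
        Label of the measure (e.g. ``"pFVC"``).
    times : (n_ik,) array
        Observation times, ascending.
    X : (n_ik, p_k) array
        Fixed-effects design block.
    Z : (n_ik, q_k) array
        Random-effects design block.
    """

    measure_id: str
    times: np.ndarray
    X: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if times.size == 0:
            X = X.reshape(0, X.shape[-1] if X.size else 0)
            Z = Z.reshape(0, Z.shape[-1] if Z.size else 0)
        if X.shape[0] != times.shape[0] or Z.shape[0] != times.shape[0]:
            raise ValueError(
                f"measure {self.measure_id!r}: X has {X.shape[0]} rows, "
                f"Z has {Z.shape[0]}, but there are {times.shape[0]} times"
            )
        n = times.shape[0]
        # Z must identify the subject's random effects on its own; X need
        # only be identifiable pooled across subjects (covariate columns are
        # constant within a subject), which gls_map enforces.
        if n >= Z.shape[1] > 0 and np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError(f"measure {self.measure_id!r}: Z is rank deficient")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)

    @property
    def n_obs(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass(frozen=True)
class SubjectDesign:
    """Ordered collection of the K marker designs of one subject."""

    subject_id: str
    markers: tuple[MarkerDesign, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(self.markers) == 0:
            raise ValueError("subject must have at least one measure")

    @property
    def K(self) -> int:
        return len(self.markers)

    @property
    def n_obs(self) -> int:
        return sum(m.n_obs for m in self.markers)

    @property
    def measure_ids(self) -> tuple[str, ...]:
        return tuple(m.measure_id for m in self.markers)

    @property
    def q_total(self) -> int:
        return sum(m.q for m in self.markers)

    @property
    def p_total(self) -> int:
        return sum(m.p for m in self.markers)

    def obs_measure_index(self) -> np.ndarray:
        """Measure index (0..K-1) of each stacked observation row."""
        return np.repeat(np.arange(self.K), [m.n_obs for m in self.markers])

    def stacked_times(self) -> np.ndarray:
        return np.concatenate([m.times for m in self.markers])

    def re_labels(self) -> list[str]:
        """Coordinate labels of the stacked random-effect vector."""
        labels = []
        for m in self.markers:
            if m.q == 2:
                names = ("intercept", "slope")
            else:
                names = tuple(f"re{j}" for j in range(m.q))
            labels.extend(f"{m.measure_id}:{name}" for name in names)
        return labels

    def fe_labels(self) -> list[str]:
        labels = []
        for m in self.markers:
            labels.extend(f"{m.measure_id}:beta{j}" for j in range(m.p))
        return labels


def assemble_block_design(subject: SubjectDesign) -> tuple[np.ndarray, np.ndarray]:
    """Direct-sum (block diagonal) subject design matrices.

    Returns ``(X_i, Z_i)`` with ``X_i = X_1 (+) ... (+) X_K`` of shape
    ``(n_i, sum p_k)`` and likewise for ``Z_i``; rows group measure 1 first,
    then measure 2, each in time order.
    """
    if subject.n_obs == 0:
        raise ValueError(f"subject {subject.subject_id!r} has no observations")
    X = block_diag(*[m.X for m in subject.markers])
    Z = block_diag(*[m.Z for m in subject.markers])
    return X, Z
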