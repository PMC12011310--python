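"""Bivariate simulation study: efficiency of the separated model over a
grid of correlation structures, missingness fractions and design sizes.

Two measures share equally spaced observation times scaled to [-1, 1];
measure 1 is fully observed while a fraction ``pmiss`` of measure 2 is
missing, either completely at random or as drop-out (only the first ``n2``
visits observed).  Fixed effects are treated as known, so the comparison
isolates the random-effects (BLUP) shrinkage: the combined working model
shrinks in the joint 4-dimensional effect space, the separated model within
each measure.  The quantity of interest is the MSE ratio of the measure-2
random effects (combined over separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .covariance import build_bivariate_D, build_bivariate_R
from .efficiency import MSEDecomposition

__all__ = [
    "GridCell",
    "GridResult",
    "GridSpec",
    "build_times_Z",
    "likely_mask",
    "evaluate_cell",
    "run_grid",
    "summarize_grid",
    "heatmap_table",
    "results_to_frame",
    "DEFAULT_RHO_GRID",
]

#: correlation grid of the default study: -0.9, -0.7, ..., 0.7, 0.9
DEFAULT_RHO_GRID: tuple[float, ...] = tuple(np.round(np.arange(-0.9, 1.0, 0.2), 1))

_RE_LABELS = ("m1:intercept", "m1:slope", "m2:intercept", "m2:slope")


@dataclass(frozen=True)
class GridCell:
    """One configuration of the bivariate study."""

    case: str
    rho_b: float
    rho_r: float
    rho_k: float
    n1: int = 6
    pmiss: float = 0.0
    pattern: str = "random"

    def __post_init__(self) -> None:
        if self.case not in ("A", "B", "C"):
            raise ValueError("case must be A, B or C")
        if self.pattern not in ("random", "dropout"):
            raise ValueError("pattern must be 'random' or 'dropout'")
        if not 0.0 <= self.pmiss < 1.0:
            raise ValueError("pmiss must be in [0, 1)")
        if self.n2 < 1:
            raise ValueError("measure 2 fully missing")

    @property
    def n2(self) -> int:
        return int(round((1.0 - self.pmiss) * self.n1))


@dataclass(frozen=True)
class GridResult:
    cell: GridCell
    ratio_b2: float
    decomposition_C: MSEDecomposition
    decomposition_S: MSEDecomposition
    likely: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio_b2 <= 1.0 + 1e-9):
            raise ValueError(f"ratio_b2 = {self.ratio_b2} outside (0, 1]")


def build_times_Z(
    n1: int, pmiss: float, pattern: str = "random", seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Design of one bivariate subject.

    Returns ``(Z1, Z2, times, keep)`` where ``times`` are the ``n1`` equally
    spaced points on [-1, 1], ``Z1 = [1, t]`` on the full grid, and ``Z2``
    keeps the rows indexed by ``keep`` (first ``n2`` for drop-out, a seeded
    uniform subset for the random pattern; times retain their full-grid
    values).
    """
    if n1 < 2:
        raise ValueError("n1 must be at least 2")
    n2 = int(round((1.0 - pmiss) * n1))
    if n2 < 1:
        raise ValueError("measure 2 fully missing")
    times = np.linspace(-1.0, 1.0, n1)
    Z1 = np.column_stack([np.ones(n1), times])
    if n2 == n1:
        keep = np.arange(n1)
    elif pattern == "dropout":
        keep = np.arange(n2)
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(n1, size=n2, replace=False))
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return Z1, Z1[keep], times, keep


def likely_mask(rho_b: float, rho_r: float, threshold: float = 0.5) -> bool:
    """False for "unlikely" combinations: strong correlations of opposite
    sign (both magnitudes >= threshold), which rarely occur in practice."""
    if np.sign(rho_b) * np.sign(rho_r) < 0 and min(abs(rho_b), abs(rho_r)) >= threshold:
        return False
    return True


def _pattern_seed(base_seed: int, n1: int, pmiss: float, draw: int) -> int:
    """Deterministic per-draw seed; independent of the correlation values so
    that sign-flip symmetry holds cell by cell."""
    ss = np.random.SeedSequence((int(base_seed), int(n1), int(round(pmiss * 1000)), int(draw)))
    return int(ss.generate_state(1)[0] % (2**31))


def _mse_matrices(Z1: np.ndarray, Z2: np.ndarray, keep: np.ndarray, D: np.ndarray, R: np.ndarray):
    """Bias/variance MSE matrices (4x4) of both working models, beta known.

    The combined working model is the truth ``(D, R)``; the separated one
    zeroes the cross-measure blocks.  Fast closed-form path used by the grid;
    cross-validated against the generic machinery in the test suite.
    """
    n1, n2 = Z1.shape[0], Z2.shape[0]
    Z = block_diag(Z1, Z2)
    Sigma = np.zeros((n1 + n2, n1 + n2))
    Sigma[:n1, :n1] = R[0, 0] * np.eye(n1)
    Sigma[n1:, n1:] = R[1, 1] * np.eye(n2)
    Sigma[keep, n1 + np.arange(n2)] = R[0, 1]
    Sigma[n1 + np.arange(n2), keep] = R[0, 1]
    D_S = D.copy()
    D_S[:2, 2:] = 0.0
    D_S[2:, :2] = 0.0
    Sigma_S = Sigma.copy()
    Sigma_S[:n1, n1:] = 0.0
    Sigma_S[n1:, :n1] = 0.0
    out = {}
    eye4 = np.eye(4)
    for label, (D_w, Sig_w) in {"combined": (D, Sigma), "separated": (D_S, Sigma_S)}.items():
        V_w = Z @ D_w @ Z.T + Sig_w
        L = np.linalg.solve(V_w, Z @ D_w).T  # D_w Z' V_w^{-1}
        Mshrink = L @ Z - eye4
        bias_mat = Mshrink @ D @ Mshrink.T
        var_mat = L @ Sigma @ L.T
        out[label] = (bias_mat, var_mat)
    return out


def evaluate_cell(
    cell: GridCell, n_pattern_draws: int = 20, base_seed: int = 0
) -> GridResult:
    """Closed-form MSE ratio of the measure-2 random effects for one cell.

    For the random pattern with ``pmiss > 0`` the bias and variance matrices
    of both working models are averaged over ``n_pattern_draws`` seeded
    missingness draws before the ratio is formed; ``pmiss = 0`` and drop-out
    are deterministic.
    """
    D = build_bivariate_D(cell.case, cell.rho_b, cell.rho_k)
    R = build_bivariate_R(cell.case, cell.rho_r)
    stochastic = cell.pattern == "random" and cell.pmiss > 0 and cell.n2 < cell.n1
    draws = range(n_pattern_draws) if stochastic else (0,)
    acc = {w: [np.zeros((4, 4)), np.zeros((4, 4))] for w in ("combined", "separated")}
    for draw in draws:
        seed = _pattern_seed(base_seed, cell.n1, cell.pmiss, draw)
        Z1, Z2, _, keep = build_times_Z(cell.n1, cell.pmiss, cell.pattern, seed)
        mats = _mse_matrices(Z1, Z2, keep, D, R)
        for w, (b, v) in mats.items():
            acc[w][0] += b
            acc[w][1] += v
    ndraws = len(tuple(draws))
    decs = {
        w: MSEDecomposition.from_matrices(b / ndraws, v / ndraws, _RE_LABELS)
        for w, (b, v) in acc.items()
    }
    m2 = slice(2, 4)
    num = decs["combined"].per_coordinate[m2].sum()
    den = decs["separated"].per_coordinate[m2].sum()
    return GridResult(
        cell=cell,
        ratio_b2=float(num / den),
        decomposition_C=decs["combined"],
        decomposition_S=decs["separated"],
        likely=likely_mask(cell.rho_b, cell.rho_r),
    )


@dataclass(frozen=True)
class GridSpec:
    """Factorial specification of the default study grid."""

    cases: tuple[str, ...] = ("A", "B", "C")
    rho_b_values: tuple[float, ...] = DEFAULT_RHO_GRID
    rho_r_values: tuple[float, ...] = DEFAULT_RHO_GRID
    rho_k_values: tuple[float, ...] = (-0.5, 0.0, 0.5)
    n1_values: tuple[int, ...] = (6, 9, 15)
    pmiss_values: tuple[float, ...] = (0.0, 1.0 / 3.0, 2.0 / 3.0)
    patterns: tuple[str, ...] = ("random", "dropout")
    n_pattern_draws: int = 20
    base_seed: int = 0

    def cells(self) -> Iterable[GridCell]:
        for pattern in self.patterns:
            for pmiss in self.pmiss_values:
                if pmiss == 0.0 and pattern != self.patterns[0]:
                    continue  # patterns coincide with complete data
                for n1 in self.n1_values:
                    for case in self.cases:
                        for rho_k in self.rho_k_values:
                            for rho_b in self.rho_b_values:
                                for rho_r in self.rho_r_values:
                                    yield GridCell(
                                        case=case,
                                        rho_b=rho_b,
                                        rho_r=rho_r,
                                        rho_k=rho_k,
                                        n1=n1,
                                        pmiss=pmiss,
                                        pattern=pattern,
                                    )


def run_grid(spec: GridSpec | None = None, n_pattern_draws: int | None = None) -> list[GridResult]:
    """Evaluate every cell of the (default) factorial grid.

    Designs and per-draw MSE matrices are cached across the correlation loop
    since the missingness draws do not depend on the correlation values.
    """
    spec = spec or GridSpec()
    ndraws = spec.n_pattern_draws if n_pattern_draws is None else n_pattern_draws
    results = []
    design_cache: dict[tuple, list] = {}

    def designs_for(n1: int, pmiss: float, pattern: str):
        key = (n1, round(pmiss, 9), pattern)
        if key not in design_cache:
            stochastic = pattern == "random" and pmiss > 0
            draws = range(ndraws) if stochastic else (0,)
            design_cache[key] = [
                build_times_Z(n1, pmiss, pattern, _pattern_seed(spec.base_seed, n1, pmiss, d))
                for d in draws
            ]
        return design_cache[key]

    cov_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for cell in spec.cells():
        ckey = (cell.case, cell.rho_b, cell.rho_k, cell.rho_r)
        if ckey not in cov_cache:
            cov_cache[ckey] = (
                build_bivariate_D(cell.case, cell.rho_b, cell.rho_k),
                build_bivariate_R(cell.case, cell.rho_r),
            )
        D, R = cov_cache[ckey]
        accs = {w: [np.zeros((4, 4)), np.zeros((4, 4))] for w in ("combined", "separated")}
        designs = designs_for(cell.n1, cell.pmiss, cell.pattern)
        for Z1, Z2, _, keep in designs:
            mats = _mse_matrices(Z1, Z2, keep, D, R)
            for w, (b, v) in mats.items():
                accs[w][0] += b
                accs[w][1] += v
        nd = len(designs)
        decs = {
            w: MSEDecomposition.from_matrices(b / nd, v / nd, _RE_LABELS)
            for w, (b, v) in accs.items()
        }
        num = decs["combined"].per_coordinate[2:4].sum()
        den = decs["separated"].per_coordinate[2:4].sum()
        results.append(
            GridResult(
                cell=cell,
                ratio_b2=float(num / den),
                decomposition_C=decs["combined"],
                decomposition_S=decs["separated"],
                likely=likely_mask(cell.rho_b, cell.rho_r),
            )
        )
    return results


def results_to_frame(results: Sequence[GridResult]) -> pd.DataFrame:
    """Tidy frame: one row per evaluated cell (draw-averaged)."""
    rows = []
    for r in results:
        c = r.cell
        rows.append(
            {
                "case": c.case,
                "pattern": c.pattern,
                "pmiss": c.pmiss,
                "n1": c.n1,
                "n2": c.n2,
                "rho_b": c.rho_b,
                "rho_r": c.rho_r,
                "rho_k": c.rho_k,
                "likely": r.likely,
                "ratio_b2": r.ratio_b2,
                "mse_C_b2": float(r.decomposition_C.per_coordinate[2:4].sum()),
                "mse_S_b2": float(r.decomposition_S.per_coordinate[2:4].sum()),
                "bias2_C_b2": float(r.decomposition_C.per_coordinate_bias2[2:4].sum()),
                "bias2_S_b2": float(r.decomposition_S.per_coordinate_bias2[2:4].sum()),
            }
        )
    return pd.DataFrame(rows)


def summarize_grid(
    results: Sequence[GridResult] | pd.DataFrame,
    groupby: Sequence[str] = ("case", "pattern", "pmiss", "n1"),
) -> pd.DataFrame:
    """Five-number summary of ratio_b2 over likely cells per group."""
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    frame = frame[frame["likely"]]
    if frame.empty:
        raise ValueError("no likely cells selected")
    agg = frame.groupby(list(groupby))["ratio_b2"].agg(
        ["min", lambda s: s.quantile(0.25), "median", lambda s: s.quantile(0.75), "max", "mean"]
    )
    agg.columns = ["min", "q25", "median", "q75", "max", "mean"]
    return agg.reset_index()


def heatmap_table(
    results: Sequence[GridResult] | pd.DataFrame,
    n1: int = 6,
    rho_k: float = 0.0,
    pattern: str = "random",
) -> pd.DataFrame:
    """Long-format rho_b x rho_r table per (case, pmiss), one slice of the
    grid in the layout of the study's heatmap figure."""
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    sel = frame[
        (frame["n1"] == n1)
        & (np.isclose(frame["rho_k"], rho_k))
        & ((frame["pattern"] == pattern) | (frame["pmiss"] == 0.0))
    ]
    if sel.empty:
        raise ValueError("no cells match the requested heatmap slice")
    return sel[["case", "pmiss", "rho_b", "rho_r", "ratio_b2", "likely"]].reset_index(drop=True)


def plot_heatmap(results, case: str = "A", pmiss: float = 0.0, ax=None, **kwargs):
    """Convenience rho_b x rho_r heatmap of ratio_b2 for one (case, pmiss)
    slice (n1 = 6, rho_k = 0); unlikely cells are masked.  Requires
    matplotlib."""
    import matplotlib.pyplot as plt

    hm = heatmap_table(results, **kwargs)
    hm = hm[(hm.case == case) & np.isclose(hm.pmiss, pmiss)]
    piv = hm.pivot(index="rho_r", columns="rho_b", values="ratio_b2")
    mask = hm.pivot(index="rho_r", columns="rho_b", values="likely").to_numpy()
    data = np.where(mask, piv.to_numpy(), np.nan)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(data, origin="lower", vmin=0, vmax=1, cmap="viridis",
                   extent=[-1, 1, -1, 1])
    ax.set_xlabel(r"$\rho_b$")
    ax.set_ylabel(r"$\rho_r$")
    ax.set_title(f"MSE ratio of $b_2$: case {case}, pmiss={pmiss:.0%}")
    plt.colorbar(im, ax=ax, label="MSE ratio")
    return ax
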