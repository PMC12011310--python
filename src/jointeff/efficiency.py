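"""Closed-form efficiency of separated versus combined mixed-model estimators.

Both working models (separated and combined) define linear estimators of the
fixed effects (GLS), the random effects (BLUP-type shrinkage) and the
subject-level predictions.  Each estimator is evaluated under the *true*
joint distribution, giving exact mean squared error, squared bias and
variance without simulation:

* fixed effects: ``beta_hat_w = (sum_i X_i' W_wi X_i)^{-1} sum_i X_i' W_wi Y_i``
  is unbiased under any working covariance, so its MSE is pure variance,
  ``sum_i A_wi V_i A_wi'`` with ``V_i`` the true marginal covariance.
* random effects with known beta: ``b_hat_wi = L_wi (Y_i - X_i beta)`` with
  ``L_wi = D_w Z_i' W_wi``; the error splits as ``(L Z - I) b + L e`` with
  ``b`` independent of ``e``, so the squared bias (averaged over
  ``b ~ N(0, D)``) is ``tr[(LZ - I) D (LZ - I)']`` and the variance is
  ``tr[L Sigma L']``.
* with estimated beta the error picks up ``-L_i X_i (beta_hat_w - beta)``,
  which is itself linear in every subject's ``(b_j, e_j)``; the full
  covariance of the composite linear map is accumulated analytically.

The MSE ratio (combined over separated) of any coordinate subset follows by
summing the selected per-coordinate MSEs.  When the working combined model
equals the truth its predictor is MSE-optimal, so every ratio is <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .covariance import CovarianceComponents, WorkingModel, marginal_cov, separate_components
from .design import SubjectDesign, assemble_block_design

__all__ = [
    "MSEDecomposition",
    "GLSMap",
    "gls_map",
    "fixed_effects_mse",
    "blup_map",
    "random_effects_mse",
    "predicted_values_mse",
    "mse_ratio",
    "EfficiencyStudy",
    "EfficiencyResults",
]


@dataclass(frozen=True)
class MSEDecomposition:
    """Exact MSE of a linear estimator, split into squared bias and variance.

    ``per_coordinate_*`` hold the diagonal of the corresponding MSE matrix;
    coordinate labels ("<measure>:<effect>") support block selections.
    """

    per_coordinate_bias2: np.ndarray
    per_coordinate_var: np.ndarray
    coordinate_labels: tuple[str, ...]
    per_subject: tuple["MSEDecomposition", ...] | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.per_coordinate_bias2, dtype=float)
        v = np.asarray(self.per_coordinate_var, dtype=float)
        if b.shape != v.shape or b.shape[0] != len(self.coordinate_labels):
            raise ValueError("per-coordinate arrays and labels must align")
        object.__setattr__(self, "per_coordinate_bias2", b)
        object.__setattr__(self, "per_coordinate_var", v)
        object.__setattr__(self, "coordinate_labels", tuple(self.coordinate_labels))

    @classmethod
    def from_matrices(
        cls, bias_mat: np.ndarray, var_mat: np.ndarray, labels: Sequence[str]
    ) -> "MSEDecomposition":
        return cls(
            per_coordinate_bias2=np.diag(np.asarray(bias_mat, dtype=float)).copy(),
            per_coordinate_var=np.diag(np.asarray(var_mat, dtype=float)).copy(),
            coordinate_labels=tuple(labels),
        )

    @classmethod
    def sum_over(cls, parts: Sequence["MSEDecomposition"]) -> "MSEDecomposition":
        """Aggregate subjects by summing traces coordinate-wise."""
        if not parts:
            raise ValueError("nothing to aggregate")
        labels = parts[0].coordinate_labels
        if all(p.coordinate_labels == labels for p in parts):
            b = np.sum([p.per_coordinate_bias2 for p in parts], axis=0)
            v = np.sum([p.per_coordinate_var for p in parts], axis=0)
        else:  # ragged designs (e.g. predictions): concatenate coordinates
            b = np.concatenate([p.per_coordinate_bias2 for p in parts])
            v = np.concatenate([p.per_coordinate_var for p in parts])
            labels = tuple(l for p in parts for l in p.coordinate_labels)
        return cls(b, v, labels, per_subject=tuple(parts))

    @property
    def per_coordinate(self) -> np.ndarray:
        return self.per_coordinate_bias2 + self.per_coordinate_var

    @property
    def squared_bias(self) -> float:
        return float(self.per_coordinate_bias2.sum())

    @property
    def variance(self) -> float:
        return float(self.per_coordinate_var.sum())

    @property
    def mse(self) -> float:
        return self.squared_bias + self.variance

    def select_mask(self, select) -> np.ndarray:
        """Boolean mask over coordinates for a selection spec.

        ``select`` may be None/"all", "intercept", "slope",
        "measure:<id>" (all effects of one measure), an explicit list of
        labels, or a callable on labels.
        """
        labels = self.coordinate_labels
        if select is None or select == "all":
            return np.ones(len(labels), dtype=bool)
        if callable(select):
            return np.array([bool(select(l)) for l in labels])
        if isinstance(select, str):
            if select in ("intercept", "slope"):
                return np.array([l.split(":", 1)[1] == select for l in labels])
            if select.startswith("measure:"):
                mid = select.split(":", 1)[1]
                return np.array([l.split(":", 1)[0] == mid for l in labels])
            raise ValueError(f"unknown selection {select!r}")
        wanted = set(select)
        return np.array([l in wanted for l in labels])

    def selected_mse(self, select=None) -> float:
        mask = self.select_mask(select)
        if not mask.any():
            raise ValueError(f"selection {select!r} matches no coordinate")
        return float(self.per_coordinate[mask].sum())


def mse_ratio(numerator: MSEDecomposition, denominator: MSEDecomposition, select=None) -> float:
    """Ratio of selected MSE traces (combined over separated, by convention)."""
    if numerator.coordinate_labels != denominator.coordinate_labels:
        raise ValueError("decompositions have mismatched coordinate labels")
    den = denominator.selected_mse(select)
    if den <= 0:
        raise ZeroDivisionError("degenerate comparison: denominator MSE is zero")
    return numerator.selected_mse(select) / den


# ---------------------------------------------------------------------------
# Estimator maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GLSMap:
    """Linear map of the working-model GLS fixed-effects estimator.

    ``beta_hat = sum_i A_i Y_i`` with ``A_i = Ainv X_i' W_i`` and
    ``Ainv = (sum_i X_i' W_i X_i)^{-1}``.
    """

    Ainv: np.ndarray
    A: tuple[np.ndarray, ...]
    labels: tuple[str, ...]


def _working_W(subjects: Sequence[SubjectDesign], components: CovarianceComponents):
    return [marginal_cov(s, components, return_inverse=True)[1] for s in subjects]


def _as_components(working) -> CovarianceComponents:
    return working.components if isinstance(working, WorkingModel) else working


def gls_map(
    subjects: Sequence[SubjectDesign],
    working,
    W_list: Sequence[np.ndarray] | None = None,
) -> GLSMap:
    """GLS coefficient map under a working covariance model."""
    comps = _as_components(working)
    if W_list is None:
        W_list = _working_W(subjects, comps)
    XtWX = None
    XtW = []
    for s, W in zip(subjects, W_list):
        X, _ = assemble_block_design(s)
        XtW_i = X.T @ W
        XtWX = XtW_i @ X if XtWX is None else XtWX + XtW_i @ X
        XtW.append(XtW_i)
    try:
        Ainv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("fixed effects not identifiable") from exc
    if np.abs(Ainv @ XtWX - np.eye(XtWX.shape[0])).max() > 1e-6:
        raise np.linalg.LinAlgError("fixed effects not identifiable")
    A = tuple(Ainv @ M for M in XtW)
    return GLSMap(Ainv=Ainv, A=A, labels=tuple(subjects[0].fe_labels()))


def fixed_effects_mse(
    subjects: Sequence[SubjectDesign],
    working,
    true_components: CovarianceComponents,
) -> MSEDecomposition:
    """MSE of the working-model GLS estimator under the true model.

    Both working models give unbiased estimators, so squared bias is exactly
    zero and the MSE is the trace of ``sum_i A_i V_true,i A_i'``.
    """
    gmap = gls_map(subjects, working)
    p = gmap.Ainv.shape[0]
    cov = np.zeros((p, p))
    for s, A_i in zip(subjects, gmap.A):
        V_i = marginal_cov(s, true_components)
        cov += A_i @ V_i @ A_i.T
    return MSEDecomposition.from_matrices(np.zeros((p, p)), cov, gmap.labels)


def blup_map(subject: SubjectDesign, working, W: np.ndarray | None = None) -> np.ndarray:
    """Shrinkage map ``L_wi = D_w Z_i' W_wi`` of the random-effects predictor."""
    comps = _as_components(working)
    if W is None:
        _, W = marginal_cov(subject, comps, return_inverse=True)
    _, Z = assemble_block_design(subject)
    return comps.D @ Z.T @ W


def _per_subject_cache(subjects, comps_w, comps_true):
    """Precompute per-subject designs, working inverses and true covariances."""
    cache = []
    for s in subjects:
        X, Z = assemble_block_design(s)
        _, W = marginal_cov(s, comps_w, return_inverse=True)
        V_true = marginal_cov(s, comps_true)
        from .covariance import build_residual_cov

        Sigma_true = build_residual_cov(s, comps_true.R)
        L = comps_w.D @ Z.T @ W
        cache.append({"X": X, "Z": Z, "W": W, "V": V_true, "Sigma": Sigma_true, "L": L})
    return cache


def random_effects_mse(
    subjects,
    working,
    true_components: CovarianceComponents,
    beta_known: bool = True,
) -> MSEDecomposition:
    """Exact MSE decomposition of the random-effects predictor.

    Squared bias is the covariance contribution of the ``b`` terms of the
    error map (the conditional bias given ``b`` averaged over
    ``b ~ N(0, D_true)``); variance is the contribution of the ``e`` terms.
    With estimated beta the shared GLS estimate couples subjects; each
    subject's decomposition is its own trace contribution.
    """
    single = isinstance(subjects, SubjectDesign)
    subjects = [subjects] if single else list(subjects)
    comps_w = _as_components(working)
    D_true = true_components.D
    cache = _per_subject_cache(subjects, comps_w, true_components)
    parts = []
    if beta_known:
        for s, c in zip(subjects, cache):
            L, Z = c["L"], c["Z"]
            Mshrink = L @ Z - np.eye(L.shape[0])
            bias_mat = Mshrink @ D_true @ Mshrink.T
            var_mat = L @ c["Sigma"] @ L.T
            parts.append(MSEDecomposition.from_matrices(bias_mat, var_mat, s.re_labels()))
    else:
        gmap = gls_map(subjects, comps_w, W_list=[c["W"] for c in cache])
        p = gmap.Ainv.shape[0]
        # U_tot = Cov_b(beta_hat), S_tot = Cov_e(beta_hat) under the truth
        U = [A @ c["Z"] @ D_true @ c["Z"].T @ A.T for A, c in zip(gmap.A, cache)]
        S = [A @ c["Sigma"] @ A.T for A, c in zip(gmap.A, cache)]
        U_tot = np.sum(U, axis=0)
        S_tot = np.sum(S, axis=0)
        for i, (s, c) in enumerate(zip(subjects, cache)):
            L, Z, X = c["L"], c["Z"], c["X"]
            G = L @ X
            A_i = gmap.A[i]
            Tb = (L @ Z - np.eye(L.shape[0])) - G @ (A_i @ Z)
            Te = L - G @ A_i
            bias_mat = Tb @ D_true @ Tb.T + G @ (U_tot - U[i]) @ G.T
            var_mat = Te @ c["Sigma"] @ Te.T + G @ (S_tot - S[i]) @ G.T
            parts.append(MSEDecomposition.from_matrices(bias_mat, var_mat, s.re_labels()))
    if single:
        return parts[0]
    return MSEDecomposition.sum_over(parts)


def predicted_values_mse(
    subjects,
    working,
    true_components: CovarianceComponents,
    beta_known: bool = True,
) -> MSEDecomposition:
    """Exact MSE of ``y_hat_wi = X_i beta_hat + Z_i b_hat_wi`` against
    ``E(y_i | b_i) = X_i beta + Z_i b_i``."""
    single = isinstance(subjects, SubjectDesign)
    subjects = [subjects] if single else list(subjects)
    comps_w = _as_components(working)
    D_true = true_components.D
    cache = _per_subject_cache(subjects, comps_w, true_components)
    parts = []

    def obs_labels(s: SubjectDesign) -> list[str]:
        return [f"{m.measure_id}:y" for m in s.markers for _ in range(m.n_obs)]

    if beta_known:
        for s, c in zip(subjects, cache):
            L, Z = c["L"], c["Z"]
            Mshrink = L @ Z - np.eye(L.shape[0])
            bias_mat = Z @ Mshrink @ D_true @ Mshrink.T @ Z.T
            var_mat = Z @ L @ c["Sigma"] @ L.T @ Z.T
            parts.append(MSEDecomposition.from_matrices(bias_mat, var_mat, obs_labels(s)))
    else:
        gmap = gls_map(subjects, comps_w, W_list=[c["W"] for c in cache])
        U = [A @ c["Z"] @ D_true @ c["Z"].T @ A.T for A, c in zip(gmap.A, cache)]
        S = [A @ c["Sigma"] @ A.T for A, c in zip(gmap.A, cache)]
        U_tot = np.sum(U, axis=0)
        S_tot = np.sum(S, axis=0)
        for i, (s, c) in enumerate(zip(subjects, cache)):
            L, Z, X = c["L"], c["Z"], c["X"]
            G = L @ X
            H = X - Z @ G  # multiplies (beta_hat - beta) in the prediction error
            A_i = gmap.A[i]
            P = Z @ (L @ Z - np.eye(L.shape[0])) + H @ (A_i @ Z)
            Q = Z @ L + H @ A_i
            bias_mat = P @ D_true @ P.T + H @ (U_tot - U[i]) @ H.T
            var_mat = Q @ c["Sigma"] @ Q.T + H @ (S_tot - S[i]) @ H.T
            parts.append(MSEDecomposition.from_matrices(bias_mat, var_mat, obs_labels(s)))
    if single:
        return parts[0]
    return MSEDecomposition.sum_over(parts)


# ---------------------------------------------------------------------------
# Model/Results front end
# ---------------------------------------------------------------------------


class EfficiencyStudy:
    """Efficiency comparison of separated vs combined working models.

    Parameters
    ----------
    subjects : sequence of SubjectDesign
        Observed designs (times, X, Z) of the study subjects.
    true_components : CovarianceComponents
        The true (combined) covariance components under which every
        estimator is evaluated.
    beta_known : bool
        If True, fixed effects are treated as known (the bivariate-study
        convention) and only random effects / predictions are compared.

    The separated working model is obtained by zeroing the cross-measure
    blocks of the true components; the combined working model is the truth
    itself, hence MSE-optimal.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectDesign],
        true_components: CovarianceComponents,
        beta_known: bool = False,
    ):
        self.subjects = list(subjects)
        if not self.subjects:
            raise ValueError("at least one subject is required")
        self.true_components = true_components
        self.beta_known = beta_known
        self.working = {
            "combined": WorkingModel.combined(true_components),
            "separated": WorkingModel.separated_from(true_components),
        }
        self.measure_ids = self.subjects[0].measure_ids

    def fit(self) -> "EfficiencyResults":
        decomps: dict[tuple[str, str], MSEDecomposition] = {}
        for label, wm in self.working.items():
            if not self.beta_known:
                decomps[("beta", label)] = fixed_effects_mse(
                    self.subjects, wm, self.true_components
                )
            decomps[("b", label)] = random_effects_mse(
                self.subjects, wm, self.true_components, beta_known=self.beta_known
            )
            decomps[("y", label)] = predicted_values_mse(
                self.subjects, wm, self.true_components, beta_known=self.beta_known
            )
        return EfficiencyResults(self, decomps)


class EfficiencyResults:
    """MSE decompositions of both working models and their ratios."""

    def __init__(self, model: EfficiencyStudy, decompositions):
        self.model = model
        self.decompositions = decompositions

    def decomposition(self, estimand: str, working: str) -> MSEDecomposition:
        return self.decompositions[(estimand, working)]

    def ratio(self, estimand: str, select=None, how: str = "ratio_of_means") -> float:
        """MSE ratio (combined / separated) for an estimand and selection.

        ``how='ratio_of_means'`` (default) divides summed traces across
        subjects; ``'mean_of_ratios'`` averages per-subject ratios.
        """
        num = self.decompositions[(estimand, "combined")]
        den = self.decompositions[(estimand, "separated")]
        if how == "ratio_of_means" or num.per_subject is None:
            return mse_ratio(num, den, select)
        ratios = [
            mse_ratio(n, d, select) for n, d in zip(num.per_subject, den.per_subject)
        ]
        return float(np.mean(ratios))

    def fixed_effects_table(self) -> pd.DataFrame:
        """Overall and measure-wise MSE ratio of the fixed effects."""
        if ("beta", "combined") not in self.decompositions:
            raise ValueError("fixed effects were not compared (beta known)")
        cols = {"Overall": self.ratio("beta")}
        for mid in self.model.measure_ids:
            cols[mid] = self.ratio("beta", f"measure:{mid}")
        return pd.DataFrame(cols, index=["MSE ratio of beta"])

    def random_effects_table(self, how: str = "ratio_of_means") -> pd.DataFrame:
        """Measure-wise MSE ratios of random effects (all / intercept /
        slope) and of predicted values."""
        rows = {}
        for name, (estimand, sel_fmt) in {
            "MSE ratio of b": ("b", "measure:{m}"),
            "MSE ratio of b_intercept": ("b", "{m}:intercept"),
            "MSE ratio of b_slope": ("b", "{m}:slope"),
            "MSE ratio of y": ("y", "measure:{m}"),
        }.items():
            row = {}
            for mid in self.model.measure_ids:
                sel = sel_fmt.format(m=mid)
                if ":" in sel and not sel.startswith("measure:"):
                    sel = [sel]
                row[mid] = self.ratio(estimand, sel, how=how)
            rows[name] = row
        return pd.DataFrame(rows).T

    def to_tidy(self) -> pd.DataFrame:
        """One row per (estimand, working model, coordinate block)."""
        records = []
        for (estimand, working), dec in self.decompositions.items():
            parts = dec.per_subject or (dec,)
            ids = (
                [s.subject_id for s in self.model.subjects]
                if dec.per_subject
                else ["(all)"]
            )
            for sid, part in zip(ids, parts):
                for mid in self.model.measure_ids:
                    mask = part.select_mask(f"measure:{mid}")
                    records.append(
                        {
                            "subject": sid,
                            "estimand": estimand,
                            "selection": mid,
                            "working_model": working,
                            "mse": float(part.per_coordinate[mask].sum()),
                            "bias2": float(part.per_coordinate_bias2[mask].sum()),
                            "var": float(part.per_coordinate_var[mask].sum()),
                        }
                    )
        return pd.DataFrame.from_records(records)

    def summary(self) -> str:
        lines = [
            "Efficiency of separated vs combined mixed models",
            f"  subjects: {len(self.model.subjects)}   measures: "
            + ", ".join(self.model.measure_ids),
            f"  beta known: {self.model.beta_known}",
            "",
        ]
        if ("beta", "combined") in self.decompositions:
            lines.append(self.fixed_effects_table().round(4).to_string())
            lines.append("")
        lines.append(self.random_effects_table().round(4).to_string())
        return "\n".join(lines)
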