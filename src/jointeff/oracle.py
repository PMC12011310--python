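"""Monte Carlo validation of the closed-form MSE decompositions.

Simulates ``(b_i, e_i, Y_i)`` from the true joint model, applies the
working-model estimators replicate by replicate (vectorised as matrix
products, since every estimator is linear) and compares empirical MSE,
squared bias and variance with the closed forms.

The empirical squared bias uses a paired-noise design: each replicate draws
one set of random effects ``b`` and two independent error vectors, giving
two estimates whose error cross-product is an unbiased estimate of the
squared conditional bias ``||E(b_hat - b | b)||^2`` averaged over ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import block_diag, cholesky

from .covariance import CovarianceComponents, build_residual_cov, psd_repair
from .design import SubjectDesign, assemble_block_design
from .efficiency import MSEDecomposition, blup_map, gls_map, marginal_cov

__all__ = ["OracleReport", "simulate_subject", "empirical_mse"]


@dataclass(frozen=True)
class OracleReport:
    """Empirical decomposition with its Monte Carlo standard error."""

    empirical_mse: float
    empirical_bias2: float
    empirical_var: float
    mc_se: float
    n_reps: int
    closed_form: MSEDecomposition | float
    seed: int | None = None

    @property
    def closed_mse(self) -> float:
        if isinstance(self.closed_form, MSEDecomposition):
            return self.closed_form.mse
        return float(self.closed_form)

    @property
    def z_score(self) -> float:
        return (self.empirical_mse - self.closed_mse) / self.mc_se

    def to_dict(self) -> dict:
        return {
            "empirical_mse": self.empirical_mse,
            "empirical_bias2": self.empirical_bias2,
            "empirical_var": self.empirical_var,
            "mc_se": self.mc_se,
            "n_reps": self.n_reps,
            "closed_form_mse": self.closed_mse,
            "z_score": self.z_score,
            "seed": self.seed,
        }


def _psd_factor(M: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Lower-triangular-ish factor F with F F' = M, tolerating PSD input."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return M.reshape(0, 0)
    try:
        return cholesky(M + floor * np.eye(M.shape[0]), lower=True)
    except np.linalg.LinAlgError:
        lam, S = np.linalg.eigh((M + M.T) / 2)
        lam = np.maximum(lam, floor)
        return S * np.sqrt(lam)


def simulate_subject(
    subject: SubjectDesign,
    true_components: CovarianceComponents,
    beta: np.ndarray,
    rng: np.random.Generator,
    n_reps: int = 1,
):
    """Draw ``(Y_i, b_i, e_i)`` from the true model.

    With ``n_reps > 1`` the arrays have a trailing replicate axis.
    """
    X, Z = assemble_block_design(subject)
    Sigma = build_residual_cov(subject, true_components.R)
    Fb = _psd_factor(true_components.D)
    Fe = _psd_factor(Sigma)
    b = Fb @ rng.standard_normal((Fb.shape[1], n_reps))
    e = Fe @ rng.standard_normal((Fe.shape[1], n_reps))
    Y = (X @ np.asarray(beta, dtype=float))[:, None] + Z @ b + e
    if n_reps == 1:
        return Y[:, 0], b[:, 0], e[:, 0]
    return Y, b, e


def empirical_mse(
    subjects,
    working,
    true_components: CovarianceComponents,
    estimand: str = "b",
    beta_known: bool = True,
    beta: np.ndarray | None = None,
    n_reps: int = 100_000,
    seed: int = 0,
    closed_form: MSEDecomposition | float | None = None,
    select=None,
) -> OracleReport:
    """Empirical MSE of a working-model estimator under the true model.

    estimand : {"beta", "b", "y"}
        Fixed effects, random effects, or predictions of ``E(y|b)``.
    select : optional coordinate selection (labels as in MSEDecomposition)
        restricts the squared-error norm to a coordinate subset.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be at least 1000 for a usable oracle")
    single = isinstance(subjects, SubjectDesign)
    subjects = [subjects] if single else list(subjects)
    rng = np.random.default_rng(seed)
    from .efficiency import _as_components

    comps_w = _as_components(working)
    X_list, Z_list = zip(*[assemble_block_design(s) for s in subjects])
    Sigma_list = [build_residual_cov(s, true_components.R) for s in subjects]
    W_list = [marginal_cov(s, comps_w, return_inverse=True)[1] for s in subjects]
    L_list = [comps_w.D @ Z.T @ W for Z, W in zip(Z_list, W_list)]
    p_tot = sum(X.shape[1] for X in X_list)
    if beta is None:
        beta = np.zeros(p_tot)
    beta = np.asarray(beta, dtype=float)
    gmap = None if (beta_known and estimand != "beta") else gls_map(subjects, comps_w, W_list=W_list)

    Fb = _psd_factor(true_components.D)
    Fe_list = [_psd_factor(S) for S in Sigma_list]
    q = Fb.shape[0]
    m = len(subjects)

    # replicate-stacked draws: one b per subject per replicate, two error sets
    b_draws = [Fb @ rng.standard_normal((q, n_reps)) for _ in range(m)]
    e_draws = [
        [Fe @ rng.standard_normal((Fe.shape[1], n_reps)) for Fe in Fe_list] for _ in range(2)
    ]

    # per-measure beta offsets: X_i beta uses the subject's block columns
    def subject_beta_slice():
        out, start = [], 0
        for X in X_list:
            out.append(slice(start, start + X.shape[1]))
            start += X.shape[1]
        return out

    err_pair = []
    for e_set in e_draws:
        resid = [Z_list[i] @ b_draws[i] + e_set[i] for i in range(m)]  # Y_i - X_i beta
        if gmap is not None:
            beta_err = np.sum([gmap.A[i] @ resid[i] for i in range(m)], axis=0)
        if estimand == "beta":
            err = beta_err
            labels = subjects[0].fe_labels()
        elif estimand == "b":
            errs = []
            for i in range(m):
                centred = resid[i] if beta_known else resid[i] - X_list[i] @ beta_err
                errs.append(L_list[i] @ centred - b_draws[i])
            err = np.concatenate(errs, axis=0)
            labels = [l for s in subjects for l in s.re_labels()]
        elif estimand == "y":
            errs = []
            for i in range(m):
                centred = resid[i] if beta_known else resid[i] - X_list[i] @ beta_err
                bhat = L_list[i] @ centred
                pred_err = Z_list[i] @ (bhat - b_draws[i])
                if not beta_known:
                    pred_err = pred_err + X_list[i] @ beta_err
                errs.append(pred_err)
            err = np.concatenate(errs, axis=0)
            labels = [f"{mk.measure_id}:y" for s in subjects for mk in s.markers for _ in range(mk.n_obs)]
        else:
            raise ValueError(f"unknown estimand {estimand!r}")
        err_pair.append(err)

    if select is not None:
        probe = MSEDecomposition(np.zeros(len(labels)), np.zeros(len(labels)), tuple(labels))
        mask = probe.select_mask(select)
        err_pair = [e[mask] for e in err_pair]

    sq1 = (err_pair[0] ** 2).sum(axis=0)
    mse = float(sq1.mean())
    mc_se = float(sq1.std(ddof=1) / np.sqrt(n_reps))
    if estimand == "beta":
        # GLS is unconditionally unbiased; the paired product would instead
        # measure the b-attributable variance, so use the mean error norm.
        bias2 = float((err_pair[0].mean(axis=1) ** 2).sum())
    else:
        bias2 = float((err_pair[0] * err_pair[1]).sum(axis=0).mean())
    if closed_form is None:
        closed_form = float("nan")
    return OracleReport(
        empirical_mse=mse,
        empirical_bias2=bias2,
        empirical_var=mse - bias2,
        mc_se=mc_se,
        n_reps=n_reps,
        closed_form=closed_form,
        seed=seed,
    )
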