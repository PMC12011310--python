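"""Covariance-component estimation without a joint fit.

Within-measure components come from per-measure linear mixed models fitted
by maximum likelihood (an ECM iteration on per-subject sufficient
statistics: the GLS step for the coefficients uses the Woodbury identity,
the E step the usual random-effect posterior).  Cross-measure blocks are
completed by a method of moments: per-subject *unshrunken* effect estimates
``b*_ik = (Z'Z)^-1 Z'(y - X beta_hat)`` have cross covariance
``D_kk' + R_kk' P_k S P_k''`` (``S`` the shared-visit incidence), so the
empirical cross covariance of ``(b*_ik, b*_ik')`` minus the residual-driven
correction estimates ``D_kk'``.  Cross-measure residual covariance is
estimated from products of projection residuals at shared visit times.

The assembled 10x10 / 5x5 estimates are projected to PSD and can be plugged
directly into the efficiency formulas, replacing a joint (e.g. Bayesian)
fit of the combined model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import CovarianceComponents, psd_repair, separate_components
from .design import SubjectDesign

__all__ = [
    "LMMResults",
    "UnivariateLMM",
    "ComponentEstimates",
    "fit_separated_lmm",
    "cross_covariance_moments",
    "empirical_yearly_correlation",
    "implied_yearly_correlation",
]


@dataclass
class LMMResults:
    """ML estimates of one univariate random-intercept-and-slope model."""

    measure_id: str
    beta: np.ndarray
    D: np.ndarray  # 2x2 random-effects covariance
    sigma2: float
    loglike_trace: np.ndarray
    n_iter: int
    converged: bool
    n_subjects: int
    n_obs: int
    column_names: list[str] | None = None

    @property
    def llf(self) -> float:
        return float(self.loglike_trace[-1])

    def summary(self) -> str:
        lines = [
            f"Univariate LMM ({self.measure_id}), ML via ECM",
            f"  subjects {self.n_subjects}, observations {self.n_obs}",
            f"  log-likelihood {self.llf:.3f}  iterations {self.n_iter}"
            + ("" if self.converged else "  (NOT converged)"),
            f"  sigma2 {self.sigma2:.5f}",
            f"  D (intercept, slope):\n{np.array_str(self.D, precision=5)}",
        ]
        return "\n".join(lines)


class UnivariateLMM:
    """Per-measure linear mixed model (random intercept + slope, iid error).

    Built from the study's subject designs and aligned response vectors;
    ``fit`` runs ECM maximum likelihood on per-subject sufficient
    statistics until the relative log-likelihood change falls below ``tol``.
    """

    def __init__(self, subjects: list[SubjectDesign], values: list[np.ndarray], measure_id: str):
        if len(subjects) < 2:
            raise ValueError("variance components are not identifiable from a single subject")
        self.measure_id = measure_id
        ys, Xs, Zs = [], [], []
        for subj, y in zip(subjects, values):
            offset = 0
            for mk in subj.markers:
                if mk.measure_id == measure_id:
                    ys.append(np.asarray(y)[offset : offset + mk.n_obs])
                    Xs.append(mk.X)
                    Zs.append(mk.Z)
                offset += mk.n_obs
        keep = [i for i, yv in enumerate(ys) if yv.size >= 1]
        self._stats = self._sufficient_stats([ys[i] for i in keep], [Xs[i] for i in keep], [Zs[i] for i in keep])
        self.n_subjects = len(keep)
        self.column_names: list[str] | None = None

    @staticmethod
    def _sufficient_stats(ys, Xs, Zs):
        m = len(ys)
        p = Xs[0].shape[1]
        q = Zs[0].shape[1]
        S = {
            "ZtZ": np.empty((m, q, q)),
            "ZtX": np.empty((m, q, p)),
            "Zty": np.empty((m, q)),
            "XtX": np.empty((m, p, p)),
            "Xty": np.empty((m, p)),
            "yty": np.empty(m),
            "n": np.empty(m),
        }
        for i, (y, X, Z) in enumerate(zip(ys, Xs, Zs)):
            S["ZtZ"][i] = Z.T @ Z
            S["ZtX"][i] = Z.T @ X
            S["Zty"][i] = Z.T @ y
            S["XtX"][i] = X.T @ X
            S["Xty"][i] = X.T @ y
            S["yty"][i] = y @ y
            S["n"][i] = len(y)
        return S

    def fit(self, tol: float = 1e-8, max_iter: int = 500) -> LMMResults:
        S = self._stats
        m = S["n"].shape[0]
        N = S["n"].sum()
        p = S["ZtX"].shape[2]
        XtX_sum = S["XtX"].sum(axis=0)
        XtZ = S["ZtX"].transpose(0, 2, 1)  # (m, p, q)

        # initial values: OLS residual variance split between error and level
        beta = np.linalg.lstsq(XtX_sum, S["Xty"].sum(axis=0), rcond=None)[0]
        rtr0 = self._rtr(S, beta).sum()
        var0 = max(rtr0 / N, 1e-8)
        mean_t2 = max(S["ZtZ"][:, 1, 1].sum() / N, 1e-8)
        D = np.diag([var0 / 2.0, var0 / (2.0 * mean_t2)])
        sigma2 = var0 / 2.0

        trace = []
        converged = False
        it = 0
        floored = False
        for it in range(1, max_iter + 1):
            if np.linalg.eigvalsh(D).min() < 1e-8 * max(D[0, 0], D[1, 1], 1e-12):
                if not floored:
                    warnings.warn(
                        f"{self.measure_id}: random-effects covariance near boundary; "
                        "eigenvalue floor applied"
                    )
                    floored = True
                D = psd_repair(D, floor=1e-8 * max(np.diag(D).max(), 1e-8))
            Dinv = np.linalg.inv(D)
            M = Dinv[None, :, :] + S["ZtZ"] / sigma2
            det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
            Vb = np.empty_like(M)
            Vb[:, 0, 0] = M[:, 1, 1] / det
            Vb[:, 1, 1] = M[:, 0, 0] / det
            Vb[:, 0, 1] = Vb[:, 1, 0] = -M[:, 0, 1] / det
            # GLS step for beta via Woodbury on the sufficient statistics
            XtVX = (
                XtX_sum - np.einsum("mpa,mab,mbq->pq", XtZ, Vb, S["ZtX"]) / sigma2
            ) / sigma2
            XtVy = (
                S["Xty"].sum(axis=0)
                - np.einsum("mpa,mab,mb->p", XtZ, Vb, S["Zty"]) / sigma2
            ) / sigma2
            beta = np.linalg.solve(XtVX, XtVy)
            # E step with the updated beta
            Ztr = S["Zty"] - np.einsum("map,p->ma", S["ZtX"], beta)
            bhat = np.einsum("mab,mb->ma", Vb, Ztr) / sigma2
            Ebb = np.einsum("ma,mb->mab", bhat, bhat) + Vb
            rtr = self._rtr(S, beta)
            # M step
            D = Ebb.mean(axis=0)
            e2 = (
                rtr
                - 2.0 * np.einsum("ma,ma->m", bhat, Ztr)
                + np.einsum("mab,mba->m", Ebb, S["ZtZ"])
            )
            sigma2 = max(e2.sum() / N, 1e-12)
            trace.append(self._loglik(S, beta, D, sigma2))
            if it > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"{self.measure_id}: ECM did not converge in {max_iter} iterations "
                f"(log-likelihood trace tail: {trace[-5:]})"
            )
        res = LMMResults(
            measure_id=self.measure_id,
            beta=beta,
            D=(D + D.T) / 2.0,
            sigma2=float(sigma2),
            loglike_trace=np.asarray(trace),
            n_iter=it,
            converged=converged,
            n_subjects=m,
            n_obs=int(N),
            column_names=self.column_names,
        )
        return res

    @classmethod
    def _loglik(cls, S, beta, D, sigma2):
        """Observed-data log-likelihood at one consistent parameter set."""
        N = S["n"].sum()
        Dinv = np.linalg.inv(D)
        M = Dinv[None, :, :] + S["ZtZ"] / sigma2
        det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        Vb = np.empty_like(M)
        Vb[:, 0, 0] = M[:, 1, 1] / det
        Vb[:, 1, 1] = M[:, 0, 0] / det
        Vb[:, 0, 1] = Vb[:, 1, 0] = -M[:, 0, 1] / det
        Ztr = S["Zty"] - np.einsum("map,p->ma", S["ZtX"], beta)
        rtr = cls._rtr(S, beta)
        A = np.einsum("ab,mbc->mac", D, S["ZtZ"]) / sigma2
        logdet = np.log((1 + A[:, 0, 0]) * (1 + A[:, 1, 1]) - A[:, 0, 1] * A[:, 1, 0])
        quad = (rtr - np.einsum("ma,mab,mb->m", Ztr, Vb, Ztr) / sigma2) / sigma2
        return float(-0.5 * (N * np.log(2 * np.pi * sigma2) + logdet.sum() + quad.sum()))

    @staticmethod
    def _rtr(S, beta):
        return (
            S["yty"]
            - 2.0 * S["Xty"] @ beta
            + np.einsum("mpq,p,q->m", S["XtX"], beta, beta)
        )


def fit_separated_lmm(
    subjects: list[SubjectDesign],
    values: list[np.ndarray],
    measure_id: str,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LMMResults:
    """ML fit of one measure's univariate mixed model (see UnivariateLMM)."""
    return UnivariateLMM(subjects, values, measure_id).fit(tol=tol, max_iter=max_iter)


@dataclass
class ComponentEstimates:
    """Assembled covariance estimates and per-measure fit diagnostics."""

    components: CovarianceComponents
    beta_hat: dict[str, np.ndarray]
    fits: dict[str, LMMResults]
    raw_D: np.ndarray | None = None
    raw_R: np.ndarray | None = None

    @property
    def measure_ids(self) -> tuple[str, ...]:
        return tuple(self.fits.keys())


def _unshrunken_effects(subjects, values, fits, measure_ids):
    """Per-subject projection estimates b*_ik and residuals per measure.

    Returns dicts keyed by measure: lists (one entry per subject) of
    ``(b_star, resid, P, times)`` or None when the measure has fewer
    observations than random effects for that subject.
    """
    out = {mid: [] for mid in measure_ids}
    for subj, y in zip(subjects, values):
        offset = 0
        for mk in subj.markers:
            yk = np.asarray(y)[offset : offset + mk.n_obs]
            offset += mk.n_obs
            mid = mk.measure_id
            if mid not in out:
                continue
            fit = fits[mid]
            if mk.n_obs < mk.q or np.unique(mk.times).size < mk.q:
                out[mid].append(None)
                continue
            r = yk - mk.X @ fit.beta
            P = np.linalg.solve(mk.Z.T @ mk.Z, mk.Z.T)
            b_star = P @ r
            resid = r - mk.Z @ b_star
            annih = np.eye(mk.n_obs) - mk.Z @ P  # resid = annih @ e
            out[mid].append((b_star, resid, P, mk.times, annih))
    return out


def cross_covariance_moments(
    subjects: list[SubjectDesign],
    values: list[np.ndarray],
    fits: dict[str, LMMResults],
    tie_tol: float = 1e-9,
) -> ComponentEstimates:
    """Moment-based completion of the cross-measure covariance blocks.

    Within-measure blocks of D and the residual variances come from the
    per-measure ML fits; cross blocks from the empirical covariance of
    unshrunken per-subject effects, corrected for the shared-visit residual
    contribution; cross residual covariances from products of projection
    residuals at shared visit times.  The assembled matrices are projected
    to PSD with diagonal preservation.
    """
    measure_ids = tuple(fits.keys())
    K = len(measure_ids)
    q = 2
    eff = _unshrunken_effects(subjects, values, fits, measure_ids)
    D = np.zeros((K * q, K * q))
    R = np.zeros((K, K))
    for k, mid in enumerate(measure_ids):
        D[k * q : (k + 1) * q, k * q : (k + 1) * q] = fits[mid].D
        R[k, k] = fits[mid].sigma2

    # cross-measure residual covariance from shared-time residual products
    shared_stats = {}
    for a in range(K):
        for b in range(a + 1, K):
            num = 0.0
            den = 0.0
            for ea, eb in zip(eff[measure_ids[a]], eff[measure_ids[b]]):
                if ea is None or eb is None:
                    continue
                _, ra, _, ta, Aa = ea
                _, rb, _, tb, Ab = eb
                Sab = (np.abs(ta[:, None] - tb[None, :]) <= tie_tol).astype(float)
                if not Sab.any():
                    continue
                # resid = (I - Z P) e, so E[sum_shared resid_a resid_b] =
                # R_ab * sum over shared index pairs of [Aa Sab Ab']
                num += float(ra @ Sab @ rb)
                den += float(np.einsum("ij,ij->", Aa @ Sab @ Ab.T, Sab))
            if den > 0:
                R[a, b] = R[b, a] = num / den
            shared_stats[(a, b)] = den

    # cross blocks of D from unshrunken-effect cross covariance
    for a in range(K):
        for b in range(a + 1, K):
            pairs = [
                (ea, eb)
                for ea, eb in zip(eff[measure_ids[a]], eff[measure_ids[b]])
                if ea is not None and eb is not None
            ]
            if len(pairs) < 3:
                warnings.warn(
                    f"no eligible subjects for pair ({measure_ids[a]}, {measure_ids[b]}); "
                    "cross block set to 0"
                )
                continue
            Ba = np.vstack([ea[0] for ea, _ in pairs])
            Bb = np.vstack([eb[0] for _, eb in pairs])
            cross = ((Ba - Ba.mean(0)).T @ (Bb - Bb.mean(0))) / (len(pairs) - 1)
            corr = np.zeros((q, q))
            for ea, eb in pairs:
                _, _, Pa, ta, _ = ea
                _, _, Pb, tb, _ = eb
                Sab = (np.abs(ta[:, None] - tb[None, :]) <= tie_tol).astype(float)
                corr += Pa @ Sab @ Pb.T
            cross = cross - R[a, b] * corr / len(pairs)
            D[a * q : (a + 1) * q, b * q : (b + 1) * q] = cross
            D[b * q : (b + 1) * q, a * q : (a + 1) * q] = cross.T
    raw_D, raw_R = D.copy(), R.copy()
    D = psd_repair((D + D.T) / 2.0)
    R = psd_repair((R + R.T) / 2.0)
    components = CovarianceComponents(D=D, R=R, q_per_measure=(q,) * K)
    return ComponentEstimates(
        components=components,
        beta_hat={mid: fits[mid].beta for mid in measure_ids},
        fits=fits,
        raw_D=raw_D,
        raw_R=raw_R,
    )


def empirical_yearly_correlation(
    records: pd.DataFrame,
    years: range = range(0, 11),
    measures: tuple[str, ...] | None = None,
    min_subjects: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete correlation of subject-year mean values.

    Rows/columns are labelled ``"<measure>:<year>"`` (measure-major); a pair
    observed by fewer than ``min_subjects`` subjects is left missing.
    """
    if measures is None:
        measures = tuple(pd.unique(records["measure"]))
    df = records.copy()
    df["year"] = np.floor(df["time"]).astype(int)
    df = df[df["year"].isin(list(years))]
    cell = (
        df.groupby(["subject_id", "measure", "year"])["value"].mean().reset_index()
    )
    cell["col"] = cell["measure"].astype(str) + ":" + cell["year"].astype(str)
    wide = cell.pivot(index="subject_id", columns="col", values="value")
    order = [f"{mid}:{yr}" for mid in measures for yr in years]
    wide = wide.reindex(columns=order)
    return wide.corr(min_periods=min_subjects)


def implied_yearly_correlation(
    components: CovarianceComponents,
    measures: tuple[str, ...],
    years: range = range(0, 11),
) -> pd.DataFrame:
    """Model-implied correlation of yearly values.

    ``Cov(Y_{k,s}, Y_{k',t}) = z_s' D_{kk'} z_t + [s = t] R_{kk'}`` with
    ``z_t = (1, t)``; a separated model therefore implies exactly zero
    cross-measure correlation.
    """
    q = 2
    K = components.K
    yrs = np.asarray(list(years), dtype=float)
    Zy = np.column_stack([np.ones(len(yrs)), yrs])
    n = K * len(yrs)
    cov = np.zeros((n, n))
    for a in range(K):
        for b in range(K):
            Dab = components.D[a * q : (a + 1) * q, b * q : (b + 1) * q]
            block = Zy @ Dab @ Zy.T + components.R[a, b] * np.eye(len(yrs))
            cov[a * len(yrs) : (a + 1) * len(yrs), b * len(yrs) : (b + 1) * len(yrs)] = block
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    labels = [f"{mid}:{int(yr)}" for mid in measures for yr in yrs]
    return pd.DataFrame(corr, index=labels, columns=labels)
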