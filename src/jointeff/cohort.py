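"""Synthetic five-marker longitudinal cohorts.

Emulates a scleroderma-registry-like study: five approximately Gaussian
(quantile-normalised) measures — pFVC, pDLCO, EF, RVSP, mRSS — observed at
irregular visit times over up to 40 years since disease onset, with the
cardiac measures (EF, RVSP) collected more sparsely than the pulmonary and
skin measures.  Each subject carries a random intercept and slope per
measure with a full 10x10 cross-measure covariance, and residuals of
different measures are correlated when recorded on the same visit day.

Visit times come from a shared per-subject clinic-day process: the two lung
measures are recorded on common days, the two cardiac measures on common
days, and the skin score on clinic days, so cross-measure residual
correlation is actually realised in the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import CovarianceComponents, build_residual_cov, psd_repair
from .design import MarkerDesign, SubjectDesign

__all__ = [
    "MEASURES",
    "CohortSpec",
    "CohortTable",
    "default_components",
    "sample_visit_process",
    "simulate_cohort",
    "build_cohort_design",
    "quantile_normalize",
    "orient_measures",
]

MEASURES: tuple[str, ...] = ("pFVC", "pDLCO", "EF", "RVSP", "mRSS")

#: observation-count targets (mean, sd) per measure of the emulated registry
VISIT_TARGETS: dict[str, tuple[float, float]] = {
    "pFVC": (12.83, 6.20),
    "pDLCO": (12.40, 6.01),
    "EF": (9.13, 3.71),
    "RVSP": (7.47, 3.28),
    "mRSS": (19.09, 7.61),
}

#: measures flipped so that larger values mean better disease status
ORIENT_FLIP: tuple[str, ...] = ("RVSP", "mRSS")

_DEFAULT_COVARIATES = {
    # baseline covariate generators: (kind, params)
    "age_onset_std": ("normal", (0.0, 1.0)),  # standardised age at onset
    "female": ("bernoulli", 0.85),
    "race_black": ("bernoulli", 0.3),
    "diffuse_skin": ("bernoulli", 0.35),
    "aca": ("bernoulli", 0.25),
    "scl70": ("bernoulli", 0.2),
    "rnapol3": ("bernoulli", 0.15),
}


def default_components(
    sd_intercept: float = 0.7,
    sd_slope: float = 0.02,
    rho_within: float = 0.25,
    resid_var: float = 0.3,
) -> CovarianceComponents:
    """Default true covariance components of the synthetic cohort.

    The 10x10 random-effects covariance is a Kronecker structure: a 5x5
    cross-measure correlation (lungs strongly correlated; RVSP correlated
    with lungs and skin; EF uncorrelated with everything) times the 2x2
    within-measure intercept-slope correlation, scaled by per-measure
    standard deviations.  Residuals share modest same-day correlation within
    the lung pair and the cardiac pair.
    """
    C5 = np.eye(5)

    def set_corr(a, b, r):
        i, j = MEASURES.index(a), MEASURES.index(b)
        C5[i, j] = C5[j, i] = r

    set_corr("pFVC", "pDLCO", 0.8)
    set_corr("pFVC", "RVSP", 0.6)
    set_corr("pDLCO", "RVSP", 0.6)
    set_corr("pFVC", "mRSS", 0.5)
    set_corr("pDLCO", "mRSS", 0.5)
    set_corr("RVSP", "mRSS", 0.7)
    C5 = psd_repair(C5)
    C2 = np.array([[1.0, rho_within], [rho_within, 1.0]])
    s = np.tile([sd_intercept, sd_slope], 5)
    D = np.kron(C5, C2) * np.outer(s, s)
    D = psd_repair(D)
    R = resid_var * np.eye(5)
    lung = (MEASURES.index("pFVC"), MEASURES.index("pDLCO"))
    heart = (MEASURES.index("EF"), MEASURES.index("RVSP"))
    R[lung[0], lung[1]] = R[lung[1], lung[0]] = 0.3 * resid_var
    R[heart[0], heart[1]] = R[heart[1], heart[0]] = 0.2 * resid_var
    return CovarianceComponents(D=D, R=R, q_per_measure=(2,) * 5)


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one synthetic cohort."""

    m: int = 200
    measures: tuple[str, ...] = MEASURES
    visit_targets: dict = field(default_factory=lambda: dict(VISIT_TARGETS))
    time_horizon: float = 40.0
    min_obs: int = 4
    components: CovarianceComponents = field(default_factory=default_components)
    covariate_model: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        for mid in self.measures:
            mean, _ = self.visit_targets[mid]
            if mean < self.min_obs:
                raise ValueError(
                    f"{mid}: target mean count {mean} below the minimum of {self.min_obs}"
                )


@dataclass
class CohortTable:
    """Long-format synthetic cohort with its generating truth."""

    records: pd.DataFrame  # subject_id, measure, time, value
    covariates: pd.DataFrame  # indexed by subject_id
    spec: CohortSpec
    true_effects: pd.DataFrame | None = None  # per-subject true random effects
    beta: np.ndarray | None = None

    @property
    def measures(self) -> tuple[str, ...]:
        return self.spec.measures

    def to_csv(self, records_path, covariates_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if covariates_path is not None:
            self.covariates.to_csv(covariates_path)

    def sidecar(self) -> dict:
        """JSON-serialisable record of the generating parameters."""
        return {
            "m": self.spec.m,
            "seed": self.spec.seed,
            "measures": list(self.spec.measures),
            "D_true": self.spec.components.D.tolist(),
            "R_true": self.spec.components.R.tolist(),
            "beta": None if self.beta is None else np.asarray(self.beta).tolist(),
        }


def _draw_count(rng: np.random.Generator, mean: float, sd: float, min_obs: int) -> int:
    """Negative-binomial count matched to (mean, sd), floored at min_obs."""
    var = sd**2
    if sd == 0:
        k = int(round(mean))
    elif var <= mean:  # at or below Poisson dispersion
        k = int(rng.poisson(mean))
    else:
        size = mean**2 / (var - mean)
        p = size / (size + mean)
        k = int(rng.negative_binomial(size, p))
    return max(k, min_obs)


def sample_visit_process(spec: CohortSpec, rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    """Per-subject, per-measure visit-time vectors.

    A master clinic-day process (uniform order statistics on [0, horizon])
    is thinned into measure-specific subsets: pFVC/pDLCO share lung days,
    EF/RVSP share echo days, mRSS uses clinic days directly.
    """
    groups = [("pFVC", "pDLCO"), ("EF", "RVSP"), ("mRSS",)]
    out = []
    for _ in range(spec.m):
        counts = {
            mid: _draw_count(rng, *spec.visit_targets[mid], spec.min_obs)
            for mid in spec.measures
        }
        n_master = max(counts.values())
        master = np.sort(rng.uniform(0.0, spec.time_horizon, n_master))
        times = {}
        for group in groups:
            n_group = max(counts[mid] for mid in group)
            gdays = np.sort(rng.choice(master, size=n_group, replace=False))
            for mid in group:
                if counts[mid] == n_group:
                    times[mid] = gdays
                else:
                    times[mid] = np.sort(rng.choice(gdays, size=counts[mid], replace=False))
        out.append(times)
    return out


def _sample_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, (kind, params) in spec.covariate_model.items():
        if kind == "normal":
            mu, sd = params
            cols[name] = rng.normal(mu, sd, spec.m)
        elif kind == "bernoulli":
            cols[name] = rng.binomial(1, params, spec.m).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    idx = pd.Index([f"s{i:05d}" for i in range(spec.m)], name="subject_id")
    return pd.DataFrame(cols, index=idx)


# ---------------------------------------------------------------------------
# Spline design
# ---------------------------------------------------------------------------


class SplineBasis:
    """Natural cubic spline basis of time (default 3 df, constant excluded),
    memorised on a reference set of times so new times evaluate consistently.

    Built from a (df+1)-column cubic-regression-spline basis with knots at
    reference-time quantiles; that basis is a partition of unity, so taking
    first-column differences yields df columns whose span excludes the
    constant — making [1, NS(t)] full rank by construction.
    """

    def __init__(self, reference_times: np.ndarray, df: int = 3):
        from patsy import dmatrix

        ref = np.asarray(reference_times, dtype=float)
        self._design_info = dmatrix(f"cr(t, df={df + 1}) - 1", {"t": ref}).design_info
        self.df = df

    def __call__(self, times: np.ndarray) -> np.ndarray:
        from patsy import build_design_matrices

        (mat,) = build_design_matrices([self._design_info], {"t": np.asarray(times, dtype=float)})
        mat = np.asarray(mat)
        return mat[:, 1:] - mat[:, :1]


def _design_columns(
    times: np.ndarray,
    cov_row: pd.Series,
    basis: SplineBasis,
    ns: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects rows: [1, NS(t), covariates, covariates x NS(t)]."""
    if ns is None:
        ns = basis(times)
    n = len(times)
    cols = [np.ones(n)] + [ns[:, j] for j in range(ns.shape[1])]
    names = ["intercept"] + [f"ns{j+1}" for j in range(ns.shape[1])]
    for cname, cval in cov_row.items():
        cols.append(np.full(n, float(cval)))
        names.append(cname)
        for j in range(ns.shape[1]):
            cols.append(float(cval) * ns[:, j])
            names.append(f"{cname}:ns{j+1}")
    return np.column_stack(cols), names


def default_beta(column_names: list[str]) -> np.ndarray:
    """Deterministic default fixed effects: declining mean trajectory with
    modest baseline-covariate shifts (exact values immaterial to efficiency
    ratios, which depend only on the designs and covariances)."""
    beta = np.zeros(len(column_names))
    for i, name in enumerate(column_names):
        if name == "intercept":
            beta[i] = 0.4
        elif name.startswith("ns") and ":" not in name:
            beta[i] = -0.25 * int(name[2:])
        elif ":" in name:
            beta[i] = 0.03 * (-1) ** i
        else:
            beta[i] = 0.15 * (-1) ** i
    return beta


def build_cohort_design(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    basis: SplineBasis | None = None,
    measures: tuple[str, ...] = MEASURES,
    return_values: bool = False,
):
    """Subject designs from a long-format cohort table.

    X_k = [1, NS(t), covariates, covariates x NS(t)] with a natural cubic
    spline of time (3 df, knots at pooled-time quantiles); Z_k = [1, t].
    Column definitions are identical across measures.  Constant covariate
    columns are dropped with a warning.
    """
    import warnings

    if basis is None:
        basis = SplineBasis(records["time"].to_numpy())
    keep_cov = []
    for c in covariates.columns:
        if covariates[c].nunique() < 2:
            warnings.warn(f"covariate {c!r} is constant; dropped from the design")
        else:
            keep_cov.append(c)
    covariates = covariates[keep_cov]
    subjects = []
    values: list[np.ndarray] = []
    names: list[str] = []
    recs = records.sort_values(["subject_id", "measure", "time"], kind="mergesort")
    recs = recs.reset_index(drop=True)
    ns_all = basis(recs["time"].to_numpy(dtype=float))
    for sid, sub in recs.groupby("subject_id", sort=True):
        markers = []
        y_parts = []
        cov_row = covariates.loc[sid]
        for mid in measures:
            block = sub[sub["measure"] == mid]
            t = block["time"].to_numpy(dtype=float)
            X, names = _design_columns(t, cov_row, basis, ns=ns_all[block.index.to_numpy()])
            Z = np.column_stack([np.ones(len(t)), t])
            markers.append(MarkerDesign(mid, t, X, Z))
            if return_values:
                y_parts.append(block["value"].to_numpy(dtype=float))
        subjects.append(SubjectDesign(str(sid), tuple(markers)))
        if return_values:
            values.append(np.concatenate(y_parts) if y_parts else np.empty(0))
    if return_values:
        return subjects, names, basis, values
    return subjects, names, basis


def simulate_cohort(spec: CohortSpec, beta: np.ndarray | None = None) -> CohortTable:
    """Simulate a full cohort from the true joint model."""
    rng = np.random.default_rng(spec.seed)
    visits = sample_visit_process(spec, rng)
    covariates = _sample_covariates(spec, rng)
    basis = SplineBasis(np.linspace(0.0, spec.time_horizon, 101))
    comps = spec.components
    K = len(spec.measures)
    from .oracle import _psd_factor

    Fb = _psd_factor(comps.D)
    rows = {"subject_id": [], "measure": [], "time": [], "value": []}
    true_b = []
    beta_vec = beta
    # evaluate the spline basis once over every visit time
    all_times = np.concatenate(
        [times[mid] for times in visits for mid in spec.measures]
    )
    ns_all = basis(all_times)
    ns_offset = 0
    for i, (sid, times) in enumerate(zip(covariates.index, visits)):
        markers = []
        for mid in spec.measures:
            t = times[mid]
            ns_block = ns_all[ns_offset : ns_offset + len(t)]
            ns_offset += len(t)
            X, names = _design_columns(t, covariates.loc[sid], basis, ns=ns_block)
            Z = np.column_stack([np.ones(len(t)), t])
            markers.append(MarkerDesign(mid, t, X, Z))
        if beta_vec is None:
            beta_vec = default_beta(names)
        subj = SubjectDesign(str(sid), tuple(markers))
        Sigma = build_residual_cov(subj, comps.R)
        Fe = _psd_factor(Sigma)
        b = Fb @ rng.standard_normal(Fb.shape[1])
        e = Fe @ rng.standard_normal(Fe.shape[1])
        offset = 0
        mean = np.concatenate([mk.X @ beta_vec for mk in markers])
        zb = np.concatenate(
            [mk.Z @ b[2 * k : 2 * k + 2] for k, mk in enumerate(markers)]
        )
        y = mean + zb + e
        for k, mk in enumerate(markers):
            n = mk.n_obs
            rows["subject_id"].extend([str(sid)] * n)
            rows["measure"].extend([mk.measure_id] * n)
            rows["time"].extend(mk.times.tolist())
            rows["value"].extend(y[offset : offset + n].tolist())
            offset += n
        true_b.append(b)
    records = pd.DataFrame(rows)
    eff_cols = [f"{mid}:{e}" for mid in spec.measures for e in ("intercept", "slope")]
    true_effects = pd.DataFrame(np.vstack(true_b), index=covariates.index, columns=eff_cols)
    return CohortTable(
        records=records,
        covariates=covariates,
        spec=spec,
        true_effects=true_effects,
        beta=beta_vec,
    )


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map a sample to standard Gaussian quantiles of its empirical CDF.

    Ranks are scaled by n/(n+1) (i.e. rank/(n+1)) so the largest value maps
    below +inf; ties share the average rank; the transform is rank
    preserving.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("quantile_normalize requires at least 2 distinct values")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf(ranks / (len(values) + 1.0))


def orient_measures(
    records: pd.DataFrame, flip: tuple[str, ...] = ORIENT_FLIP
) -> pd.DataFrame:
    """Multiply the listed measures' values by -1 (an involution), so that
    increases in every measure indicate improvement."""
    known = set(records["measure"].unique())
    unknown = [mid for mid in flip if mid not in known]
    if unknown:
        raise ValueError(f"unknown measure label(s): {unknown}")
    out = records.copy()
    mask = out["measure"].isin(flip)
    out.loc[mask, "value"] = -out.loc[mask, "value"]
    return out
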