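"""Standard Monte Carlo validation set for the closed-form decompositions.

Twenty seeded random study configurations spanning one, two and five
measures, varied design sizes and missingness, against which every released
closed form (fixed effects, random effects with known and estimated
coefficients, predictions; both working models) is checked within Monte
Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import CovarianceComponents, psd_repair, separate_components
from .design import MarkerDesign, SubjectDesign
from .efficiency import (
    fixed_effects_mse,
    predicted_values_mse,
    random_effects_mse,
)
from .oracle import empirical_mse

__all__ = ["random_configuration", "validate_closed_forms", "pooled_form_z"]


def _random_corr(rng: np.random.Generator, dim: int, strength: float = 0.7) -> np.ndarray:
    """Random PSD correlation matrix (scaled factor structure)."""
    A = rng.uniform(-strength, strength, size=(dim, max(2, dim)))
    C = A @ A.T
    s = np.sqrt(np.diag(C)) + 1e-12
    C = C / np.outer(s, s)
    C = 0.6 * C + 0.4 * np.eye(dim)
    np.fill_diagonal(C, 1.0)
    return psd_repair(C)


def random_configuration(seed: int) -> tuple[list[SubjectDesign], CovarianceComponents]:
    """One random multi-subject study: designs, true components."""
    rng = np.random.default_rng(seed)
    K = int(rng.choice([1, 2, 5]))
    n_subjects = int(rng.integers(2, 5))
    q = 2
    subjects = []
    for i in range(n_subjects):
        # shared candidate visit grid so measures overlap at some times
        grid = np.sort(rng.uniform(-1.0, 1.0, 10))
        markers = []
        for k in range(K):
            n_k = int(rng.integers(q + 1, 8))
            t = np.sort(rng.choice(grid, size=n_k, replace=False))
            X = np.column_stack([np.ones(n_k), t, t**2])
            Z = X[:, :q]
            markers.append(MarkerDesign(f"m{k + 1}", t, X, Z))
        subjects.append(SubjectDesign(f"s{i + 1}", tuple(markers)))
    Cb = _random_corr(rng, K * q)
    sd_b = rng.uniform(0.5, 1.5, K * q)
    D = psd_repair(Cb * np.outer(sd_b, sd_b))
    Cr = _random_corr(rng, K, strength=0.5)
    sd_r = rng.uniform(0.5, 1.5, K)
    R = psd_repair(Cr * np.outer(sd_r, sd_r))
    comps = CovarianceComponents(D=D, R=R, q_per_measure=(q,) * K)
    return subjects, comps


def validate_closed_forms(
    n_configs: int = 20,
    n_reps: int = 100_000,
    seed: int = 0,
    estimands: tuple[str, ...] = ("beta", "b", "y"),
) -> pd.DataFrame:
    """Closed forms vs empirical MSE on the standard validation set.

    One row per (configuration, estimand, beta mode, working model) with the
    closed-form and empirical decompositions and the z-score of their MSE
    difference.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    config_seeds = root.generate_state(n_configs) % (2**31)
    for c, cseed in enumerate(config_seeds):
        subjects, true_c = random_configuration(int(cseed))
        working = {
            "combined": true_c,
            "separated": separate_components(true_c),
        }
        modes = [(est, bk) for est in estimands for bk in ((True, False) if est != "beta" else (False,))]
        for est, beta_known in modes:
            for wlabel, wcomps in working.items():
                if est == "beta":
                    closed = fixed_effects_mse(subjects, wcomps, true_c)
                elif est == "b":
                    closed = random_effects_mse(subjects, wcomps, true_c, beta_known=beta_known)
                else:
                    closed = predicted_values_mse(subjects, wcomps, true_c, beta_known=beta_known)
                rep = empirical_mse(
                    subjects,
                    wcomps,
                    true_c,
                    estimand=est,
                    beta_known=beta_known,
                    n_reps=n_reps,
                    seed=int(cseed) + 17,
                    closed_form=closed,
                )
                rows.append(
                    {
                        "config": c,
                        "config_seed": int(cseed),
                        "K": subjects[0].K,
                        "estimand": est,
                        "beta_known": beta_known,
                        "working": wlabel,
                        "closed_mse": closed.mse,
                        "closed_bias2": closed.squared_bias,
                        "closed_var": closed.variance,
                        "empirical_mse": rep.empirical_mse,
                        "empirical_bias2": rep.empirical_bias2,
                        "mc_se": rep.mc_se,
                        "z": rep.z_score,
                        "n_reps": n_reps,
                    }
                )
    return pd.DataFrame(rows)


def pooled_form_z(report: pd.DataFrame) -> pd.DataFrame:
    """Per-form z of the pooled (summed over configurations) MSE.

    Pooling across the independent configurations tests each closed form for
    *systematic* disagreement with the simulation at far higher power than
    any single configuration, while individual-run z-values fluctuate as
    standard normals by construction.
    """
    grp = report.groupby(["estimand", "beta_known", "working"])
    out = grp.apply(
        lambda g: pd.Series(
            {
                "closed_mse": g.closed_mse.sum(),
                "empirical_mse": g.empirical_mse.sum(),
                "pooled_se": np.sqrt((g.mc_se**2).sum()),
                "pooled_z": (g.empirical_mse.sum() - g.closed_mse.sum())
                / np.sqrt((g.mc_se**2).sum()),
                "n_configs": len(g),
            }
        ),
        include_groups=False,
    )
    return out.reset_index()
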