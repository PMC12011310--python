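import numpy as np
import pytest

from jointeff import (
    CovarianceComponents,
    MarkerDesign,
    SubjectDesign,
    build_bivariate_D,
    build_bivariate_R,
    separate_components,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bivariate_subject(n1=6, n2=None, dropout=True, keep=None, subject_id="s1"):
    """Bivariate subject on the equally spaced [-1, 1] grid; X = Z = [1, t]."""
    t = np.linspace(-1.0, 1.0, n1)
    Z1 = np.column_stack([np.ones(n1), t])
    if keep is None:
        n2 = n1 if n2 is None else n2
        keep = np.arange(n2) if dropout else np.arange(n1)
    Z2 = Z1[keep]
    m1 = MarkerDesign("m1", t, Z1, Z1)
    m2 = MarkerDesign("m2", t[keep], Z2, Z2)
    return SubjectDesign(subject_id, (m1, m2))


def bivariate_components(case="A", rho_b=0.5, rho_r=0.5, rho_k=0.0):
    D = build_bivariate_D(case, rho_b, rho_k)
    R = build_bivariate_R(case, rho_r)
    return CovarianceComponents(D=D, R=R, q_per_measure=(2, 2))


@pytest.fixture
def bivariate_cell():
    """A representative bivariate configuration with missing data and its
    separated working components."""
    subject = make_bivariate_subject(n1=6, n2=4)
    true_c = bivariate_components("B", rho_b=0.7, rho_r=0.6, rho_k=0.3)
    return subject, true_c, separate_components(true_c)


@pytest.fixture
def scalar_case():
    """One observation, one measure, unit variances: shrinkage factor 1/2."""
    md = MarkerDesign("m1", [0.0], np.array([[1.0]]), np.array([[1.0]]))
    subject = SubjectDesign("s1", (md,))
    comps = CovarianceComponents(D=np.array([[1.0]]), R=np.array([[1.0]]), q_per_measure=(1,))
    return subject, comps
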