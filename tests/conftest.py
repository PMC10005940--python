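import numpy as np
import pandas as pd
import pytest

from cortilong.simulate import CohortConfig, EffectSpec, generate_cohort, generate_thickness
from cortilong.surface import make_icosphere


@pytest.fixture(scope="session")
def ico162():
    return make_icosphere(subdivisions=2, radius=50.0)


@pytest.fixture(scope="session")
def ico642():
    return make_icosphere(subdivisions=3, radius=50.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced three-group cohort, no dropout: 12 subjects x 3 scans."""
    cfg = CohortConfig(n_hc=4, n_chrnc=4, n_chrc=4,
                       scan_schedule_months=(0.0, 2.0, 4.0),
                       visit_jitter_sd=0.0, dropout_prob_per_visit=0.0,
                       n_scanners=2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_dataset(ico642):
    """Cohort + smoothed thickness with a CHR-C-only thinning patch."""
    from cortilong.surface import smooth_surface

    cfg = CohortConfig(n_hc=30, n_chrnc=60, n_chrc=30,
                       scan_schedule_months=(0.0, 2.0, 4.0, 6.0),
                       dropout_prob_per_visit=0.2, n_scanners=3, seed=21)
    cohort = generate_cohort(cfg)
    eff = EffectSpec(patch_center_vertices=(10,), patch_radius_mm=9.8,
                     slope_hc=0.0, slope_chrnc=0.0, slope_chrc=-0.02)
    Y = generate_thickness(ico642, cohort, eff, seed=22)
    return cohort, smooth_surface(ico642, Y, 10.0), eff


def lme_sim(seed, m=40, k=3, beta=(2.5, -0.05, 0.1), s2b=0.04, s2e=0.01):
    """Small random-intercept dataset with known parameters."""
    rng = np.random.default_rng(seed)
    N = m * k
    subjects = np.repeat(np.arange(m), k)
    X = np.column_stack([np.ones(N), np.tile(np.arange(k, dtype=float), m),
                         rng.standard_normal((N, len(beta) - 2))])
    y = (X @ np.asarray(beta)
         + np.repeat(rng.normal(0, np.sqrt(s2b), m), k)
         + rng.normal(0, np.sqrt(s2e), N))
    return X, subjects, y


def reml_oracle(X, subjects, y):
    """Brute-force profile-REML via dense marginal covariance and a generic
    bounded scalar optimiser; independent of the package's solver."""
    from scipy.optimize import minimize_scalar

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N, p = X.shape
    same = subjects[:, None] == subjects[None, :]

    def crit(lam):
        V = np.eye(N) + lam * same
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        bh = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ bh
        return ((N - p) * np.log(r @ Vi @ r)
                + np.linalg.slogdet(V)[1] + np.linalg.slogdet(A)[1])

    res = minimize_scalar(crit, bounds=(1e-9, 1e4), method="bounded",
                          options={"xatol": 1e-13})
    lam = res.x
    if crit(0.0) < res.fun:
        lam = 0.0
    V = np.eye(N) + lam * same
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    s2e = (r @ Vi @ r) / (N - p)
    return beta, lam * s2e, s2e, lam


def toy_cohort(rows) -> pd.DataFrame:
    """Cohort frame from (subject, group, months[, scanner]) tuples."""
    recs = []
    for row in rows:
        sid, group, month = row[:3]
        scanner = row[3] if len(row) > 3 else "siteA"
        recs.append(dict(subject_id=sid, group=group, sex="F",
                         age_first_scan=20.0, scanner=scanner,
                         months_from_baseline=float(month), converted=0,
                         post_conversion=0, cpz_dose=np.nan))
    return pd.DataFrame(recs)
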