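"""Vertex-wise random-intercept linear mixed-effects modelling.

The longitudinal model fitted at every vertex v is

    y_iv = x_i' beta_v + b_{s(i), v} + e_iv,
    b ~ N(0, sigma2_b),  e ~ N(0, sigma2_e),

with fixed effects for time from first scan, clinical group, the
group-by-time interaction, age at first scan (centred), age^2, sex and
scanner, and a random intercept per subject. Estimation is REML via a
deterministic one-dimensional profile over the variance ratio
lambda = sigma2_b / sigma2_e: for fixed lambda the GLS solution for beta and
the profiled sigma2_e are closed-form, so the whole mass-univariate fit
reduces to a 1-D minimisation per vertex. The marginal covariance
V = I + lambda * Z Z' is block compound-symmetric by subject, which makes
every quantity expressible through per-subject sums — all vertices are fitted
simultaneously with dense matrix algebra.

Wald F/T tests for group-by-time contrasts use the naive residual degrees of
freedom ddf = N_scans - rank(X) - (N_subjects - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "Design",
    "VertexStatMaps",
    "filter_scans",
    "build_design",
    "fit_vertex_lme",
    "fit_all_vertices",
    "interaction_f_test",
    "contrast_f_test",
    "contrast_t_test",
    "compare_random_slope",
]

GROUP_LEVELS = ("HC", "CHR-NC", "CHR-C")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random-effect structure of the longitudinal thickness model.

    Reference levels: group = first element of ``group_levels`` (HC), sex =
    'F', scanner = first lexicographic. Age is centred at the sample mean
    before squaring (pure reparameterisation; cannot change the interaction
    test). ``df_method`` currently supports only the naive residual-df
    convention.
    """

    time_var: str = "months_from_baseline"
    group_var: str = "group"
    group_levels: tuple[str, ...] = GROUP_LEVELS
    include_cpz: bool = False
    df_method: str = "naive"

    def __post_init__(self):
        if self.df_method == "satterthwaite":
            raise NotImplementedError(
                "Satterthwaite degrees of freedom are not implemented; "
                "only the naive residual-df convention is available")
        if self.df_method != "naive":
            raise ValueError("df_method must be 'naive'")


@dataclass
class Design:
    """Encoded fixed-effect design shared by all vertices."""

    X: np.ndarray                 # (N, p) full-rank fixed-effect matrix
    columns: list[str]
    subjects: np.ndarray          # (N,) integer subject codes 0..m-1
    subject_ids: np.ndarray       # (m,) original subject identifiers
    row_mask: np.ndarray          # boolean mask into the cohort rows used
    spec: ModelSpec = None
    age_center: float = 0.0
    n_dropped_missing: int = 0

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.shape[0]

    def col(self, name: str) -> int:
        return self.columns.index(name)

    @property
    def time(self) -> np.ndarray:
        return self.X[:, self.col("time")]

    def interaction_cols(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.endswith(":time")]

    def interaction_contrast(self) -> np.ndarray:
        """Contrast matrix (k-1, p) testing all group-by-time terms = 0."""
        idx = self.interaction_cols()
        C = np.zeros((len(idx), len(self.columns)))
        for r, i in enumerate(idx):
            C[r, i] = 1.0
        return C

    def slope_contrast(self, group_a: str, group_b: str) -> np.ndarray:
        """Contrast vector for slope(group_a) - slope(group_b).

        Positive T means group_a's thickness slope is larger (thins slower)
        than group_b's.
        """
        ref = self.spec.group_levels[0] if self.spec else GROUP_LEVELS[0]
        c = np.zeros(len(self.columns))
        for g, sign in ((group_a, 1.0), (group_b, -1.0)):
            if g == ref:
                continue
            name = f"{g}:time"
            if name not in self.columns:
                raise ValueError(f"unknown group {g!r}")
            c[self.col(name)] += sign
        if not c.any():
            raise ValueError("contrast is identically zero")
        return c


def filter_scans(
    cohort: pd.DataFrame,
    max_months: float = 12.0,
    exclude_post_conversion: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Drop scans acquired more than ``max_months`` after the first scan
    (guards against right-skewed follow-up times), optionally drop scans
    flagged as post-conversion, and remove subjects left with no scans.

    Returns the filtered table and a log record of removal counts.
    """
    n0 = len(cohort)
    keep = cohort["months_from_baseline"].to_numpy() <= max_months
    n_late = int((~keep).sum())
    n_post = 0
    if exclude_post_conversion and "post_conversion" in cohort:
        post = cohort["post_conversion"].fillna(False).astype(bool).to_numpy()
        n_post = int((keep & post).sum())
        keep &= ~post
    out = cohort.loc[keep].copy()
    before = cohort["subject_id"].nunique()
    after = out["subject_id"].nunique()
    log = {
        "n_scans_in": n0,
        "n_removed_late": n_late,
        "n_removed_post_conversion": n_post,
        "n_subjects_dropped": before - after,
        "n_scans_out": len(out),
    }
    return out, log


def build_design(cohort: pd.DataFrame, spec: ModelSpec | None = None) -> Design:
    """Encode the cohort table into the fixed-effect design matrix.

    Treatment coding: group reference = first of ``spec.group_levels``, sex
    reference 'F', scanner reference first lexicographic. Scans with missing
    model variables are listwise-deleted (count reported on the Design).
    Raises if a declared group level is absent or the design is rank
    deficient, naming the offending columns.
    """
    spec = spec or ModelSpec()
    needed = ["subject_id", spec.group_var, "sex", "age_first_scan", "scanner",
              spec.time_var]
    if spec.include_cpz:
        needed.append("cpz_dose")
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {missing_cols}")
    sub = cohort[needed]
    ok = sub.notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    sub = sub.loc[ok]

    present = set(sub[spec.group_var].unique())
    empty = [g for g in spec.group_levels if g not in present]
    if empty:
        raise ValueError(f"group levels with no observations: {empty}")
    extra = present - set(spec.group_levels)
    if extra:
        raise ValueError(f"unexpected group levels in data: {sorted(extra)}")

    time = sub[spec.time_var].to_numpy(dtype=float)
    age = sub["age_first_scan"].to_numpy(dtype=float)
    age_center = float(age.mean())
    age_c = age - age_center
    sex = (sub["sex"].astype(str).to_numpy() == "M").astype(float)

    cols: list[str] = ["intercept", "time"]
    mats: list[np.ndarray] = [np.ones_like(time), time]
    for g in spec.group_levels[1:]:
        mats.append((sub[spec.group_var].to_numpy() == g).astype(float))
        cols.append(g)
    for g in spec.group_levels[1:]:
        mats.append((sub[spec.group_var].to_numpy() == g) * time)
        cols.append(f"{g}:time")
    mats += [age_c, age_c ** 2, sex]
    cols += ["age", "age2", "sex_M"]
    scanners = np.sort(sub["scanner"].astype(str).unique())
    for s in scanners[1:]:
        mats.append((sub["scanner"].astype(str).to_numpy() == s).astype(float))
        cols.append(f"scanner_{s}")
    if spec.include_cpz:
        mats.append(sub["cpz_dose"].to_numpy(dtype=float))
        cols.append("cpz_dose")

    X = np.column_stack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        bad = [cols[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")

    ids, codes = np.unique(sub["subject_id"].to_numpy(), return_inverse=True)
    return Design(X=X, columns=cols, subjects=codes, subject_ids=ids,
                  row_mask=ok, spec=spec, age_center=age_center,
                  n_dropped_missing=n_dropped)


@dataclass
class VertexStatMaps:
    """Per-vertex REML fit results for a shared design."""

    beta: np.ndarray       # (V, p)
    cov: np.ndarray        # (V, p, p) covariance of beta-hat
    sigma2_b: np.ndarray   # (V,)
    sigma2_e: np.ndarray   # (V,)
    lam: np.ndarray        # (V,) variance ratio at the REML optimum
    loglik: np.ndarray     # (V,) restricted log-likelihood
    converged: np.ndarray  # (V,) bool
    ddf: int
    n_obs: int
    n_subjects: int
    columns: list[str] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.beta.shape[0]

    @property
    def n_nonconverged(self) -> int:
        return int((~self.converged).sum())


class _ProfiledREML:
    """Sufficient statistics and profile-criterion evaluations for the
    random-intercept model with design X shared across vertices."""

    def __init__(self, X: np.ndarray, subjects: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0] or X.shape[0] != subjects.shape[0]:
            raise ValueError("X, subjects and Y must agree on the number of scans")
        _, codes = np.unique(subjects, return_inverse=True)
        self.N, self.p = X.shape
        self.m = int(codes.max()) + 1
        self.n = np.bincount(codes).astype(float)          # scans per subject
        if (self.n >= 2).sum() < 2:
            raise ValueError(
                "need at least 2 subjects with at least 2 scans to identify "
                "the random-intercept variance"
            )
        self.X, self.Y, self.codes = X, Y, codes
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.yy = np.einsum("nv,nv->v", Y, Y)
        # per-subject sums
        self.S = np.zeros((self.m, self.p))
        np.add.at(self.S, codes, X)
        self.Ty = np.zeros((self.m, Y.shape[1]))
        np.add.at(self.Ty, codes, Y)
        self.SS = (self.S[:, :, None] * self.S[:, None, :]).reshape(self.m, -1)
        self.Tyy = self.Ty * self.Ty

    # ---- criterion at a single lambda, all vertices (shared algebra) ----
    def crit_shared(self, lam: float) -> np.ndarray:
        from scipy.linalg import cho_factor, cho_solve

        g = lam / (1.0 + self.n * lam)
        A = self.XtX - self.S.T @ (g[:, None] * self.S)
        b = self.XtY - self.S.T @ (g[:, None] * self.Ty)
        q = self.yy - g @ self.Tyy
        cf = cho_factor(A, lower=True)
        beta = cho_solve(cf, b)
        rss = q - np.einsum("pv,pv->v", beta, b)
        logdetA = 2.0 * np.log(np.diag(cf[0])).sum()
        logdetV = np.log1p(self.n * lam).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.N - self.p) * np.log(rss) + logdetV + logdetA

    def substats(self, idx: np.ndarray) -> tuple:
        """Column-sliced sufficient statistics for a vertex subset."""
        return (self.XtY[:, idx].T.copy(), self.Ty[:, idx].copy(),
                self.Tyy[:, idx].copy(), self.yy[idx].copy())

    # ---- criterion at per-vertex lambdas (batched algebra) ----
    def crit_pervertex(self, lam: np.ndarray, sub: tuple) -> np.ndarray:
        """Profile criterion at one lambda per vertex.

        RSS and log|X'V^-1 X| come from a single batched Cholesky of the
        bordered matrix [[A, b], [b', q]]: the last pivot is the GLS
        residual sum of squares.
        """
        XtYt, Ty, Tyy, yy = sub
        n = self.n[:, None]
        G = lam[None, :] / (1.0 + n * lam[None, :])        # (m, R)
        R, p = XtYt.shape[0], self.p
        M = np.empty((R, p + 1, p + 1))
        M[:, :p, :p] = (self.XtX.ravel()[None, :] - G.T @ self.SS
                        ).reshape(-1, p, p)
        bt = XtYt - (G * Ty).T @ self.S                    # (R, p)
        M[:, :p, p] = bt
        M[:, p, :p] = bt
        M[:, p, p] = yy - np.einsum("mr,mr->r", G, Tyy)
        try:
            L = np.linalg.cholesky(M)
            d = np.diagonal(L, axis1=1, axis2=2)
            logdetA = 2.0 * np.log(d[:, :p]).sum(axis=1)
            rss = d[:, p] ** 2
        except np.linalg.LinAlgError:
            # fall back for (near-)zero residuals: factor A alone
            A, q = M[:, :p, :p], M[:, p, p]
            L = np.linalg.cholesky(A)
            beta = np.linalg.solve(A, bt[:, :, None])[..., 0]
            rss = np.maximum(q - np.einsum("rp,rp->r", beta, bt), 1e-300)
            logdetA = 2.0 * np.log(
                np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        logdetV = np.log1p(n * lam[None, :]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.N - self.p) * np.log(rss) + logdetV + logdetA

    # ---- full solution at per-vertex lambda ----
    def solve_at(self, lam: np.ndarray):
        n = self.n[:, None]
        G = lam[None, :] / (1.0 + n * lam[None, :])
        A = (self.XtX.ravel()[None, :] - G.T @ self.SS).reshape(-1, self.p, self.p)
        bt = self.XtY.T - (G * self.Ty).T @ self.S
        q = self.yy - np.einsum("mv,mv->v", G, self.Tyy)
        Ainv = np.linalg.inv(A)
        beta = np.einsum("vpq,vq->vp", Ainv, bt)
        rss = q - np.einsum("vp,vp->v", beta, bt)
        dfe = self.N - self.p
        sigma2_e = rss / dfe
        sigma2_b = lam * sigma2_e
        cov = Ainv * sigma2_e[:, None, None]
        sign, logdetA = np.linalg.slogdet(A)
        logdetV = np.log1p(n * lam[None, :]).sum(axis=0)
        loglik = -0.5 * (dfe * (np.log(2 * np.pi * sigma2_e) + 1.0)
                         + logdetV + logdetA)
        return beta, cov, sigma2_b, sigma2_e, rss, loglik


_LAM_GRID = np.concatenate([[0.0], np.logspace(-4.0, 4.0, 17)])


def fit_all_vertices(
    X: np.ndarray,
    subjects: np.ndarray,
    Y: np.ndarray,
    refine_iters: int = 12,
    columns: list[str] | None = None,
) -> VertexStatMaps:
    """REML-fit the random-intercept model at every vertex (column of Y).

    The profile REML criterion in lambda is evaluated on a fixed log-spaced
    grid (all vertices at once), then minimised per vertex by safeguarded
    successive parabolic interpolation in log-lambda within the bracketing
    grid cell. lambda = 0 (no subject variance) is handled as a boundary
    solution. Fully deterministic.
    """
    prof = _ProfiledREML(X, subjects, Y)
    V = prof.Y.shape[1]
    grid = _LAM_GRID
    crit = np.empty((grid.size, V))
    for k, lam in enumerate(grid):
        crit[k] = prof.crit_shared(lam)
    kbest = np.nanargmin(crit, axis=0)
    lam_hat = grid[kbest].astype(float)

    interior = (kbest > 0) & (kbest < grid.size - 1)
    idx = np.flatnonzero(interior)
    if idx.size and refine_iters > 0:
        sub = prof.substats(idx)
        kb = kbest[idx]
        # bracket in t = log(lambda); for kb == 1 the left neighbour is
        # lambda=0, use a point one grid-step further left instead
        step = np.log(grid[2] / grid[1])
        tl = np.where(kb > 1, np.log(grid[np.maximum(kb - 1, 1)]),
                      np.log(grid[1]) - step)
        tr = np.log(grid[kb + 1])
        t0 = np.log(grid[kb])
        f0 = crit[kb, idx]
        fl = crit[np.maximum(kb - 1, 1), idx]
        need_left = kb == 1
        if need_left.any():
            fl_ext = prof.crit_pervertex(np.exp(tl), sub)
            fl = np.where(need_left, fl_ext, fl)
        fr = crit[kb + 1, idx]
        t1, f1, t2, f2 = tl.copy(), fl.copy(), tr.copy(), fr.copy()
        for _ in range(refine_iters):
            d1, d2 = t0 - t1, t0 - t2
            g1, g2 = f0 - f1, f0 - f2
            denom = d1 * g2 - d2 * g1
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = t0 - 0.5 * (d1 * d1 * g2 - d2 * d2 * g1) / denom
            span = tr - tl
            bad = (~np.isfinite(tp)) | (tp <= tl) | (tp >= tr) \
                | (np.abs(tp - t0) < 1e-12) | (np.abs(denom) < 1e-300)
            bisect = np.where(tr - t0 > t0 - tl, 0.5 * (t0 + tr), 0.5 * (tl + t0))
            tp = np.where(bad, bisect, tp)
            fp = prof.crit_pervertex(np.exp(tp), sub)
            better = fp < f0
            # bracket update
            tl = np.where(better & (tp > t0), t0, np.where(~better & (tp < t0), tp, tl))
            tr = np.where(better & (tp < t0), t0, np.where(~better & (tp > t0), tp, tr))
            # rotate interpolation points
            t2 = np.where(better, t1, t2)
            f2 = np.where(better, f1, f2)
            t1 = np.where(better, t0, tp)
            f1 = np.where(better, f0, fp)
            t0 = np.where(better, tp, t0)
            f0 = np.where(better, fp, f0)
            if span.max() < 1e-10:
                break
        lam_hat[idx] = np.exp(t0)

    beta, cov, s2b, s2e, rss, loglik = prof.solve_at(lam_hat)
    converged = np.isfinite(rss) & (rss > 0)
    ddf = prof.N - prof.p - (prof.m - 1)
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} vertices failed to produce a valid fit",
            RuntimeWarning, stacklevel=2,
        )
    for arr in (beta, cov, s2b, s2e, loglik):
        arr[~converged] = np.nan
    return VertexStatMaps(
        beta=beta, cov=cov, sigma2_b=s2b, sigma2_e=s2e, lam=lam_hat,
        loglik=loglik, converged=converged, ddf=ddf,
        n_obs=prof.N, n_subjects=prof.m,
        columns=list(columns) if columns is not None else [],
    )


def fit_vertex_lme(
    X: np.ndarray, subjects: np.ndarray, y: np.ndarray, refine_iters: int = 12
) -> VertexStatMaps:
    """Single-response convenience wrapper; identical code path to
    :func:`fit_all_vertices` with a one-column response."""
    return fit_all_vertices(X, subjects, np.asarray(y, dtype=float).reshape(-1, 1),
                            refine_iters=refine_iters)


def contrast_f_test(maps: VertexStatMaps, C: np.ndarray):
    """Wald F-test of C @ beta = 0 per vertex.

    Returns (F, p) arrays; vertices with singular contrast covariance get
    NaN. The null reference is F(q, ddf) with the naive residual df.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    q = C.shape[0]
    cb = maps.beta @ C.T                                   # (V, q)
    Vc = np.einsum("qp,vpr,sr->vqs", C, maps.cov, C)       # (V, q, q)
    F = np.full(maps.n_vertices, np.nan)
    ok = maps.converged.copy()
    with np.errstate(all="ignore"):
        det = np.linalg.det(Vc)
    ok &= np.isfinite(det) & (det > 0)
    if ok.any():
        sol = np.linalg.solve(Vc[ok], cb[ok][:, :, None])[..., 0]
        F[ok] = np.einsum("vq,vq->v", cb[ok], sol) / q
    F = np.where(ok & (F >= 0), F, np.nan)
    p = stats.f.sf(F, q, maps.ddf)
    p = np.where(np.isfinite(F), np.maximum(p, np.finfo(float).tiny), np.nan)
    return F, p


def interaction_f_test(maps: VertexStatMaps, design: Design):
    """F-test for the group-by-time interaction (all interaction terms = 0)."""
    return contrast_f_test(maps, design.interaction_contrast())


def contrast_t_test(maps: VertexStatMaps, c: np.ndarray):
    """Two-sided Wald T-test of c' beta = 0 per vertex.

    Sign convention: with c = slope_contrast(a, b), positive T means group a
    thins more slowly than group b.
    """
    c = np.asarray(c, dtype=float).ravel()
    if c.shape[0] != maps.beta.shape[1]:
        raise ValueError("contrast length must equal the coefficient count")
    if not c.any():
        raise ValueError("contrast vector is identically zero")
    est = maps.beta @ c
    var = np.einsum("p,vpq,q->v", c, maps.cov, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = est / np.sqrt(var)
    T = np.where(maps.converged & (var > 0), T, np.nan)
    p = 2.0 * stats.t.sf(np.abs(T), maps.ddf)
    p = np.where(np.isfinite(T), np.maximum(p, np.finfo(float).tiny), np.nan)
    return T, p


def compare_random_slope(
    X: np.ndarray, subjects: np.ndarray, time: np.ndarray, y: np.ndarray
) -> dict:
    """Compare random-intercept vs random-intercept+slope models by REML.

    Both models share the fixed effects X; the extended model adds a random
    time slope (with intercept-slope covariance, a 2-parameter extension).
    Reports the likelihood-ratio statistic against the boundary-corrected
    50:50 mixture of chi2(1) and chi2(2), plus AIC/BIC differences. Fitting
    uses statsmodels MixedLM. If the slope model does not converge the
    comparison is marked unavailable.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    out: dict = {"available": False}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = sm.MixedLM(y, X, groups=subjects).fit(reml=True)
        try:
            exog_re = np.column_stack([np.ones_like(time), time])
            m1 = sm.MixedLM(y, X, groups=subjects, exog_re=exog_re).fit(reml=True)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            out.update(loglik_intercept=float(m0.llf), error=str(exc))
            return out
    if not m1.converged:
        out.update(loglik_intercept=float(m0.llf), error="slope model did not converge")
        return out
    ll0, ll1 = float(m0.llf), float(m1.llf)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = 0.5 * stats.chi2.sf(lr, 1) + 0.5 * stats.chi2.sf(lr, 2)
    k0 = X.shape[1] + 2           # fixed + (sigma2_b, sigma2_e)
    k1 = k0 + 2                   # + slope variance + covariance
    n = y.shape[0]
    aic0, aic1 = 2 * k0 - 2 * ll0, 2 * k1 - 2 * ll1
    bic0, bic1 = k0 * np.log(n) - 2 * ll0, k1 * np.log(n) - 2 * ll1
    out.update(
        available=True, loglik_intercept=ll0, loglik_slope=ll1,
        lr_statistic=lr, p_value=float(p),
        aic_intercept=aic0, aic_slope=aic1, delta_aic=aic1 - aic0,
        bic_intercept=bic0, bic_slope=bic1, delta_bic=bic1 - bic0,
        slope_preferred=bool(p < 0.05),
    )
    return out
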