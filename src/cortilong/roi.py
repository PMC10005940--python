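"""ROI summaries and the percent-thickness-change (PC) statistic.

PC normalises the thickness change between two scans of a subject by the
baseline thickness and the interscan interval:

    PC = ((T2 - T1) / T1) / delta_months * 100     [% per month]

so negative PC means thinning and values are comparable across differing
interscan intervals. The ``scan2`` variant pairs the first scan with the
chronologically second one (shortest observable interval); ``final`` pairs
the first with the last scan. Group comparisons of PC are covariate-adjusted
ordinary least squares (one record per subject, so no random effects are
needed), with BH-FDR across the ROI x contrast family.

The ROI itself is typically the union of same-hemisphere clusters found by
the vertex-wise discovery stage; because the ROI is discovered on the same
data, PC group contrasts inherit that circularity (documented in the methods
note) — the prediction analyses are the guard against over-interpretation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import CONTRAST_PAIRS, bh_fdr
from .surface import SurfaceMesh

__all__ = [
    "roi_series",
    "percent_change",
    "build_pc_table",
    "pc_group_regression",
    "baseline_group_test",
    "cohens_d",
]


def roi_series(
    mesh: SurfaceMesh,
    Y: np.ndarray,
    cohort: pd.DataFrame,
    roi_vertices,
    area_weighted: bool = True,
) -> np.ndarray:
    """Mean thickness over the ROI per scan, aligned to cohort rows.

    Area-weighted by default (irregular meshes otherwise bias the mean
    toward densely triangulated regions); pass ``area_weighted=False`` for
    the unweighted mean.
    """
    roi = np.asarray(roi_vertices, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    if Y.shape[0] != len(cohort):
        raise ValueError("thickness rows must align with cohort rows")
    if area_weighted:
        w = mesh.vertex_area[roi]
        w = w / w.sum()
    else:
        w = np.full(roi.size, 1.0 / roi.size)
    return Y[:, roi] @ w


def percent_change(T1: float, T2: float, delta_months: float):
    """((T2 - T1)/T1)/delta_months * 100, in % per month."""
    T1a = np.asarray(T1, dtype=float)
    dt = np.asarray(delta_months, dtype=float)
    if np.any(T1a <= 0):
        raise ValueError("T1 must be > 0")
    if np.any(dt <= 0):
        raise ValueError("delta_months must be > 0")
    return ((np.asarray(T2, dtype=float) - T1a) / T1a) / dt * 100.0


def build_pc_table(
    cohort: pd.DataFrame,
    series: np.ndarray,
    variant: str = "scan2",
    roi_id: str = "roi",
) -> pd.DataFrame:
    """Per-subject PC records from a per-scan ROI series.

    Subjects with fewer than two scans are excluded (their count is in the
    table attribute ``attrs['n_excluded_single_scan']``). ``variant='scan2'``
    pairs first and chronologically second scans; ``'final'`` first and
    last. For two-scan subjects the variants coincide exactly.
    """
    if variant not in ("scan2", "final"):
        raise ValueError("variant must be 'scan2' or 'final'")
    df = cohort.copy()
    df["_roi_value"] = np.asarray(series, dtype=float)
    df = df.sort_values(["subject_id", "months_from_baseline"], kind="stable")
    rows = []
    n_single = 0
    for sid, g in df.groupby("subject_id", sort=True):
        if len(g) < 2:
            n_single += 1
            continue
        first = g.iloc[0]
        other = g.iloc[1] if variant == "scan2" else g.iloc[-1]
        dt = float(other["months_from_baseline"] - first["months_from_baseline"])
        t1 = float(first["_roi_value"])
        t2 = float(other["_roi_value"])
        rows.append({
            "subject_id": sid,
            "roi_id": roi_id,
            "group": first["group"],
            "T1": t1,
            "T2": t2,
            "delta_months": dt,
            "pc": float(percent_change(t1, t2, dt)),
            "variant": variant,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_excluded_single_scan"] = n_single
    return out


def _ols_group_contrasts(pc: pd.DataFrame, cohort: pd.DataFrame,
                         include_cpz: bool = False) -> list[dict]:
    """OLS of pc on group + covariates; all pairwise group contrasts."""
    import statsmodels.api as sm

    base = cohort.sort_values(["subject_id", "months_from_baseline"],
                              kind="stable").groupby("subject_id", sort=True)
    covs = base.first()[["age_first_scan", "sex", "scanner"]
                        + (["cpz_dose"] if include_cpz else [])]
    df = pc.merge(covs, left_on="subject_id", right_index=True, how="left")
    groups = [g for g in ("HC", "CHR-NC", "CHR-C") if g in set(df["group"])]
    if len(groups) < 2:
        raise ValueError("need at least two groups for PC regression")
    age_c = df["age_first_scan"].to_numpy(float)
    age_c = age_c - age_c.mean()
    cols = {"intercept": np.ones(len(df)),
            "age": age_c, "age2": age_c ** 2,
            "sex_M": (df["sex"].astype(str) == "M").astype(float).to_numpy()}
    for g in groups[1:]:
        cols[g] = (df["group"] == g).astype(float).to_numpy()
    for s in np.sort(df["scanner"].astype(str).unique())[1:]:
        cols[f"scanner_{s}"] = (df["scanner"].astype(str) == s
                                ).astype(float).to_numpy()
    if include_cpz:
        cols["cpz_dose"] = df["cpz_dose"].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"PC design is rank deficient; offending columns: {bad}")
    fit = sm.OLS(df["pc"].to_numpy(float), X).fit()
    res = []
    for a, b in CONTRAST_PAIRS:
        if a not in groups or b not in groups:
            continue
        c = np.zeros(X.shape[1])
        if a != groups[0]:
            c[names.index(a)] += 1.0
        if b != groups[0]:
            c[names.index(b)] -= 1.0
        t = fit.t_test(c)
        res.append({"contrast": f"{a}_vs_{b}",
                    "T": float(np.squeeze(t.tvalue)),
                    "p": float(np.squeeze(t.pvalue)), "n": int(len(df))})
    return res


def pc_group_regression(
    pc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    include_cpz: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted group comparisons of PC, per ROI.

    For each ROI in ``pc_table`` an OLS of pc on group, age (centred),
    age^2, sex and scanner is fitted and all pairwise group slope contrasts
    are tested (two-sided). BH-FDR is applied across ROIs within each
    contrast. Returns a tidy frame: roi_id, contrast, T, p, q, n.
    """
    frames = []
    for roi_id, sub in pc_table.groupby("roi_id", sort=True):
        for rec in _ols_group_contrasts(sub, cohort, include_cpz=include_cpz):
            rec["roi_id"] = roi_id
            frames.append(rec)
    out = pd.DataFrame(frames)
    out["q"] = np.nan
    for contrast, idx in out.groupby("contrast", sort=False).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out[["roi_id", "contrast", "T", "p", "q", "n"]]


def baseline_group_test(cohort: pd.DataFrame, series: np.ndarray):
    """One-way ANOVA of first-scan ROI thickness across clinical groups.

    Returns (F, p). Rejects if any group has fewer than two subjects.
    """
    df = cohort.copy()
    df["_v"] = np.asarray(series, dtype=float)
    df = df.sort_values(["subject_id", "months_from_baseline"], kind="stable")
    first = df.groupby("subject_id", sort=True).first()
    samples = [g["_v"].to_numpy() for _, g in first.groupby("group", sort=True)]
    if any(len(s) < 2 for s in samples) or len(samples) < 2:
        raise ValueError("each group needs at least 2 subjects for the ANOVA")
    F, p = stats.f_oneway(*samples)
    return float(F), float(p)


def cohens_d(a, b) -> float:
    """Cohen's d: mean difference over the pooled (n-1) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))
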