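"""Intraclass correlations for the travelling-subjects scanner study.

Scanner reliability is quantified with the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation ICC(2,1),

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

from the standard mean-squares decomposition of a complete subjects x
raters table (n subjects, k raters). Absolute agreement is the relevant
form because systematic scanner offsets are precisely the error of concern;
the consistency form ICC(3,1) is available for comparison. Raters are
sites for between-site reliability (day-averaged values) or scanner x day
for within-site test-retest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "icc_two_way",
    "average_icc",
    "parcel_iccs",
    "travelling_to_ratings",
]


def icc_two_way(table, form: str = "2,1") -> float:
    """ICC from a complete subjects x raters table.

    Parameters
    ----------
    table : (n, k) array or wide DataFrame
        One row per subject, one column per rater; no missing cells
        (incomplete tables are rejected, no imputation).
    form : '2,1' (absolute agreement, default) or '3,1' (consistency).

    The raw value is returned (it can be slightly negative in pure-noise
    data); callers may clip for reporting.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("incomplete ratings table (missing cells)")
    if form not in ("2,1", "3,1"):
        raise ValueError("form must be '2,1' or '3,1'")
    n, k = x.shape
    grand = x.mean()
    rm = x.mean(axis=1)
    cm = x.mean(axis=0)
    msr = k * ((rm - grand) ** 2).sum() / (n - 1)
    msc = n * ((cm - grand) ** 2).sum() / (k - 1)
    resid = x - rm[:, None] - cm[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    if form == "2,1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        return 1.0 if msr == mse == 0 else 0.0
    return float((msr - mse) / denom)


def travelling_to_ratings(
    travelling: pd.DataFrame, mode: str = "between_site", site: str | None = None
) -> pd.DataFrame:
    """Convert the subject x site x day travelling table into a long
    ratings table (subject, rater, parcel, value).

    ``between_site``: raters are sites, values averaged over days.
    ``within_site``: raters are the days of one ``site`` (test-retest).
    """
    if mode == "between_site":
        out = (travelling.groupby(["subject", "site", "parcel"],
                                  sort=True, as_index=False)["value"].mean()
               .rename(columns={"site": "rater"}))
        return out
    if mode == "within_site":
        if site is None:
            raise ValueError("within_site mode requires a site")
        sub = travelling[travelling["site"] == site]
        if sub.empty:
            raise ValueError(f"no rows for site {site!r}")
        out = sub[["subject", "day", "parcel", "value"]].copy()
        out["rater"] = out.pop("day").map(lambda d: f"day{d}")
        return out[["subject", "rater", "parcel", "value"]]
    raise ValueError("mode must be 'between_site' or 'within_site'")


def parcel_iccs(
    ratings: pd.DataFrame,
    exclude_raters: set | tuple = (),
    form: str = "2,1",
) -> pd.Series:
    """Per-parcel ICC from a long ratings table, excluding named raters."""
    sub = ratings[~ratings["rater"].isin(set(exclude_raters))]
    if sub["rater"].nunique() < 2:
        raise ValueError("exclusion leaves fewer than 2 raters")
    out = {}
    for parcel, g in sub.groupby("parcel", sort=True):
        wide = g.pivot(index="subject", columns="rater", values="value")
        if wide.isna().any().any():
            raise ValueError(
                f"parcel {parcel!r}: ratings table is not a complete "
                "crossed design")
        out[parcel] = icc_two_way(wide.to_numpy(), form=form)
    return pd.Series(out, name="icc")


def average_icc(
    ratings: pd.DataFrame,
    exclude_raters: set | tuple = (),
    form: str = "2,1",
) -> dict:
    """Unweighted mean of per-parcel ICCs, with and without the named
    raters. Returns {'included': .., 'excluded': .., 'n_parcels': ..,
    'excluded_raters': [...]}; 'excluded' is None when nothing is excluded.
    """
    inc = parcel_iccs(ratings, (), form=form)
    exc = None
    if exclude_raters:
        exc = float(parcel_iccs(ratings, exclude_raters, form=form).mean())
    return {
        "included": float(inc.mean()),
        "excluded": exc,
        "n_parcels": int(inc.size),
        "excluded_raters": sorted(exclude_raters),
    }
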