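"""Age/sex adjustment, twin correlations, and demographic group tests.

Regional values are first residualized on age and sex with a single linear
model pooled over zygosity groups.  Twin resemblance per region/metric is
then summarized by the double-entry Pearson correlation: every complete
pair contributes both orderings (t1, t2) and (t2, t1), which makes the
estimate invariant to within-pair labelling and equal to the ANOVA
intraclass correlation of the stacked data.  MZ and DZ correlations are
compared with a one-sided Fisher z test (MZ > DZ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationEstimate",
    "CorrelationComparison",
    "DemographicsSummary",
    "adjust_age_sex",
    "twin_correlation",
    "correlation_table",
    "compare_twin_correlations",
    "summarize_metric_correlations",
    "demographics_tests",
    "round_half_up",
]

MIN_PAIRS = 3


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.705 -> 0.71), as used in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CorrelationEstimate:
    region: str
    metric: str
    zygosity: str
    r: float
    n_pairs: int
    adjusted: bool = True


@dataclass(frozen=True)
class CorrelationComparison:
    region: str
    metric: str
    z: float
    p: float  # one-sided, MZ > DZ

    @property
    def direction(self) -> str:
        return "MZ>DZ" if self.z >= 0 else "DZ>MZ"


@dataclass(frozen=True)
class DemographicsSummary:
    chi2: float
    chi2_p: float
    t: float
    t_p: float
    group_stats: pd.DataFrame


def _subject_covariates(roster_frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in roster_frame.itertuples(index=False):
        for idx, sex in ((1, row.sex_1), (2, row.sex_2)):
            rows.append(
                {
                    "subject_id": f"{row.pair_id}_{idx}",
                    "pair_id": row.pair_id,
                    "zygosity": row.zygosity,
                    "age": float(row.age),
                    "male": 1.0 if sex == "M" else 0.0,
                }
            )
    return pd.DataFrame(rows)


def adjust_age_sex(table: pd.DataFrame, roster_frame: pd.DataFrame) -> pd.DataFrame:
    """Residualize values on age and sex per region/metric, pooled over zygosity.

    Returns the table with ``value`` replaced by least-squares residuals
    (mean-zero, orthogonal to age and to the sex indicator).  Missing cells
    stay missing.
    """
    cov = _subject_covariates(roster_frame).set_index("subject_id")
    missing = set(table["subject_id"].unique()) - set(cov.index)
    if missing:
        raise ValueError(f"subjects without roster covariates: {sorted(missing)[:5]}")

    out = table.copy()
    age = cov.loc[out["subject_id"], "age"].to_numpy()
    male = cov.loc[out["subject_id"], "male"].to_numpy()
    resid = np.full(len(out), np.nan)
    values = out["value"].to_numpy(float)
    for _, idx in out.groupby(["region", "metric"], sort=False).groups.items():
        idx = np.asarray(idx)
        y = values[idx]
        ok = np.isfinite(y)
        X = np.column_stack([np.ones(ok.sum()), age[idx][ok], male[idx][ok]])
        coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        r = np.full(idx.size, np.nan)
        r[ok] = y[ok] - X @ coef
        resid[idx] = r
    out["value"] = resid
    return out


def twin_correlation(
    residuals: pd.DataFrame, roster_frame: pd.DataFrame, zygosity: str
) -> list[CorrelationEstimate]:
    """Double-entry Pearson twin correlation per region/metric for one group.

    Pairs with a missing member value for a region/metric are dropped
    pairwise; fewer than 3 complete pairs yields no estimate (logged).
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity {zygosity!r}")
    pairs = roster_frame[roster_frame["zygosity"] == zygosity]["pair_id"]
    sub = residuals[residuals["pair_id"].isin(set(pairs))]
    estimates: list[CorrelationEstimate] = []
    for (region, metric), grp in sub.groupby(["region", "metric"], sort=False):
        wide = grp.pivot_table(
            index="pair_id", columns="twin_index", values="value", dropna=False
        )
        if not {1, 2} <= set(wide.columns):
            continue
        wide = wide.dropna()
        n = len(wide)
        if n < MIN_PAIRS:
            log.warning("%s/%s %s: only %d complete pairs; no estimate", region, metric, zygosity, n)
            continue
        x = wide[1].to_numpy()
        y = wide[2].to_numpy()
        # double entry: both orderings
        xx = np.concatenate([x, y])
        yy = np.concatenate([y, x])
        r = float(np.corrcoef(xx, yy)[0, 1])
        estimates.append(
            CorrelationEstimate(region=region, metric=metric, zygosity=zygosity, r=r, n_pairs=n)
        )
    return estimates


def correlation_table(
    residuals: pd.DataFrame, roster_frame: pd.DataFrame
) -> pd.DataFrame:
    """MZ and DZ correlations side by side with the Fisher-z comparison.

    Columns: region, metric, r_mz, n_mz, r_dz, n_dz, z, p.
    """
    mz = {(e.region, e.metric): e for e in twin_correlation(residuals, roster_frame, "MZ")}
    dz = {(e.region, e.metric): e for e in twin_correlation(residuals, roster_frame, "DZ")}
    rows = []
    for key in [k for k in mz if k in dz]:
        emz, edz = mz[key], dz[key]
        cmp_ = compare_twin_correlations(
            emz.r, emz.n_pairs, edz.r, edz.n_pairs, region=key[0], metric=key[1]
        )
        rows.append(
            {
                "region": key[0],
                "metric": key[1],
                "r_mz": emz.r,
                "n_mz": emz.n_pairs,
                "r_dz": edz.r,
                "n_dz": edz.n_pairs,
                "z": cmp_.z,
                "p": cmp_.p,
            }
        )
    return pd.DataFrame(rows)


def compare_twin_correlations(
    r_mz: float,
    n_mz: int,
    r_dz: float,
    n_dz: int,
    region: str = "",
    metric: str = "",
) -> CorrelationComparison:
    """One-sided Fisher z test of r_MZ > r_DZ.

    z = (atanh(r_mz) - atanh(r_dz)) / sqrt(1/(n_mz-3) + 1/(n_dz-3)).
    """
    if n_mz < 4 or n_dz < 4:
        raise ValueError("need at least 4 pairs per group")
    if abs(r_mz) >= 1 or abs(r_dz) >= 1:
        raise ValueError("correlation of +/-1: Fisher transform diverges")
    z = (np.arctanh(r_mz) - np.arctanh(r_dz)) / np.sqrt(
        1.0 / (n_mz - 3) + 1.0 / (n_dz - 3)
    )
    p = float(stats.norm.sf(z))
    return CorrelationComparison(region=region, metric=metric, z=float(z), p=p)


def summarize_metric_correlations(
    estimates: list[CorrelationEstimate] | pd.Series,
) -> tuple[float, float, float]:
    """(mean, min, max) of regional correlations, half-up rounded to 2 dp."""
    if isinstance(estimates, pd.Series):
        r = estimates.to_numpy(float)
    else:
        r = np.array([e.r for e in estimates], float)
    if r.size == 0:
        raise ValueError("no correlation estimates to summarize")
    return (
        round_half_up(float(np.mean(r))),
        round_half_up(float(np.min(r))),
        round_half_up(float(np.max(r))),
    )


def demographics_tests(roster_frame: pd.DataFrame) -> DemographicsSummary:
    """Chi-square for pair sex composition and unpaired t for age, by zygosity.

    Sex composition per pair is MM / FF / opposite-sex; all-empty columns
    are dropped before the chi-square (MZ pairs cannot be opposite-sex).
    """
    df = roster_frame[roster_frame["excluded_reason"] == "none"] if "excluded_reason" in roster_frame else roster_frame
    groups = df.groupby("zygosity")
    if groups.ngroups < 2:
        raise ValueError("need both MZ and DZ groups")

    comp = df.apply(
        lambda r: "OS" if r.sex_1 != r.sex_2 else ("MM" if r.sex_1 == "M" else "FF"),
        axis=1,
    )
    ct = pd.crosstab(df["zygosity"], comp)
    ct = ct.loc[:, ct.sum(axis=0) > 0]
    chi2, chi2_p, _, _ = stats.chi2_contingency(ct, correction=False)

    ages = {z: g["age"].to_numpy() for z, g in groups}
    if any(len(a) < 2 for a in ages.values()):
        raise ValueError("t-test needs >= 2 pairs per zygosity group")
    if ages["MZ"].std() == 0 and ages["DZ"].std() == 0 and ages["MZ"].mean() == ages["DZ"].mean():
        t, t_p = 0.0, 1.0  # degenerate constant groups: no difference by construction
    else:
        t, t_p = stats.ttest_ind(ages["MZ"], ages["DZ"], equal_var=True)
    group_stats = groups["age"].agg(["count", "mean", "std"])
    return DemographicsSummary(
        chi2=float(chi2), chi2_p=float(chi2_p), t=float(t), t_p=float(t_p), group_stats=group_stats
    )
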