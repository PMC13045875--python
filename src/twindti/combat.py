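"""Empirical-Bayes location/scale (ComBat) harmonization of regional tables.

Removes additive and multiplicative scanner/batch effects from a features x
subjects matrix while preserving specified biological covariates (here age
and sex).  The model for feature g, subject j in batch i is

    y_gij = alpha_g + X_j beta_g + gamma_gi + delta_gi * eps_gij

Features are standardized with the covariate-adjusted grand mean and pooled
variance; per-batch location (gamma) and scale (delta^2) estimates are then
shrunk toward their across-feature moments via parametric empirical Bayes —
a normal prior on gamma and an inverse-gamma prior on delta^2, with the
conditional posterior-mean updates iterated to convergence — and the data
are adjusted with the shrunk estimates and back-transformed.

Conventions follow the reference parametric implementation: pooled variance
uses an n divisor, per-batch variances n-1, prior hyperparameters are
moment-matched, and the EB iteration stops when the largest relative change
drops below 1e-4 (cap 100 iterations).  Missing cells are excluded
feature-wise from estimation and passed through unmodified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "fit_combat", "apply_combat", "harmonize_table"]


@dataclass
class CombatModel:
    """Fitted harmonization parameters for one feature matrix."""

    batches: list[str]
    features: list[str]
    grand_mean: np.ndarray  # (G,)
    var_pooled: np.ndarray  # (G,)
    beta: np.ndarray  # (n_covariates, G) covariate coefficients
    gamma_star: np.ndarray  # (n_batch, G)
    delta_star_sq: np.ndarray  # (n_batch, G)
    hyper: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "batches": self.batches,
            "features": self.features,
            "grand_mean": self.grand_mean.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "beta": self.beta.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
            "hyper": {k: np.asarray(v).tolist() for k, v in self.hyper.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _design(batch: pd.Series, covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    batches = sorted(batch.unique())
    onehot = np.column_stack([(batch == b).to_numpy(float) for b in batches])
    X = covariates.to_numpy(float)
    design = np.column_stack([onehot, X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confounded design: batch collinear with covariates")
    return design, onehot, batches


def _covariate_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Age unscaled; sex as a single male indicator column."""
    out = pd.DataFrame(index=covariates.index)
    out["age"] = covariates["age"].astype(float)
    sex = covariates["sex"]
    if sex.dtype == object:
        out["sex_male"] = (sex == "M").astype(float)
    else:
        out["sex_male"] = sex.astype(float)
    return out


def fit_combat(
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame,
) -> CombatModel:
    """Fit the EB harmonization model.

    ``data`` is features x subjects (rows = region/metric features, columns
    = subject ids); ``batch`` and ``covariates`` (columns ``age``, ``sex``)
    are indexed by subject id.
    """
    subjects = list(data.columns)
    batch = batch.loc[subjects]
    X = _covariate_matrix(covariates.loc[subjects])
    if batch.nunique() < 2:
        raise ValueError(
            "single batch: harmonization is a no-op, skip it rather than fitting"
        )
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every batch needs >= 2 subjects, got {counts.to_dict()}")

    design, onehot, batches = _design(batch, X)
    Y = data.to_numpy(float)  # (G, n)
    G, n = Y.shape
    if G < 2:
        raise ValueError("empirical-Bayes shrinkage needs >= 2 features")
    mask = np.isfinite(Y)
    n_batch = len(batches)
    B_hat = np.empty((design.shape[1], G))
    var_pooled = np.empty(G)
    for g in range(G):
        m = mask[g]
        if m.sum() <= design.shape[1]:
            raise ValueError(f"feature {g}: too few observed values to fit design")
        Dg = design[m]
        yg = Y[g, m]
        B_hat[:, g], *_ = np.linalg.lstsq(Dg, yg, rcond=None)
        resid = yg - Dg @ B_hat[:, g]
        var_pooled[g] = (resid**2).sum() / m.sum()  # n divisor, reference convention
    if np.any(var_pooled <= 0):
        raise ValueError("feature with zero residual variance; cannot standardize")

    n_per_batch = onehot.sum(axis=0)
    grand_mean = (n_per_batch / n) @ B_hat[:n_batch]  # (G,)
    beta = B_hat[n_batch:]

    # standardize
    stand_mean = grand_mean[:, None] + (design[:, n_batch:] @ beta).T
    Z = np.where(mask, (Y - stand_mean) / np.sqrt(var_pooled)[:, None], np.nan)

    gamma_hat = np.empty((n_batch, G))
    delta_hat_sq = np.empty((n_batch, G))
    for i, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        Zi = Z[:, cols]
        gamma_hat[i] = np.nanmean(Zi, axis=1)
        delta_hat_sq[i] = np.nanvar(Zi, axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)  # (n_batch,)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m_d = delta_hat_sq.mean(axis=1)
    s2_d = delta_hat_sq.var(axis=1, ddof=1)
    a_prior = (2 * s2_d + m_d**2) / s2_d
    b_prior = (m_d * s2_d + m_d**3) / s2_d

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    for i, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        Zi = Z[:, cols]
        n_obs = np.isfinite(Zi).sum(axis=1).astype(float)
        g_old = gamma_hat[i].copy()
        d_old = delta_hat_sq[i].copy()
        for _ in range(100):
            g_new = (tau_sq[i] * n_obs * gamma_hat[i] + d_old * gamma_bar[i]) / (
                tau_sq[i] * n_obs + d_old
            )
            sum2 = np.nansum((Zi - g_new[:, None]) ** 2, axis=1)
            d_new = (0.5 * sum2 + b_prior[i]) / (n_obs / 2.0 + a_prior[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
            if change < 1e-4:
                break
        gamma_star[i] = g_old
        delta_star_sq[i] = d_old
    if np.any(delta_star_sq <= 0):
        raise ValueError("non-positive shrunk scale estimate")

    return CombatModel(
        batches=batches,
        features=list(data.index),
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        beta=beta,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        hyper={
            "gamma_bar": gamma_bar,
            "tau_sq": tau_sq,
            "a_prior": a_prior,
            "b_prior": b_prior,
        },
    )


def apply_combat(
    model: CombatModel,
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Adjust a feature matrix with a fitted model; shape and NaNs preserved."""
    subjects = list(data.columns)
    batch = batch.loc[subjects]
    unseen = set(batch.unique()) - set(model.batches)
    if unseen:
        raise ValueError(f"batch labels not in model: {sorted(unseen)}")
    if list(data.index) != model.features:
        raise ValueError("feature rows do not match the fitted model")
    X = _covariate_matrix(covariates.loc[subjects]).to_numpy(float)

    Y = data.to_numpy(float)
    mask = np.isfinite(Y)
    stand_mean = model.grand_mean[:, None] + (X @ model.beta).T
    sd = np.sqrt(model.var_pooled)[:, None]
    Z = (Y - stand_mean) / sd
    out = np.array(Y)
    for i, b in enumerate(model.batches):
        cols = (batch == b).to_numpy()
        if not cols.any():
            continue
        adj = (Z[:, cols] - model.gamma_star[i][:, None]) / np.sqrt(
            model.delta_star_sq[i]
        )[:, None]
        out[:, cols] = adj * sd + stand_mean[:, cols]
    out[~mask] = np.nan
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def harmonize_table(
    table: pd.DataFrame,
    roster_frame: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, CombatModel]]:
    """Harmonize a long regional table per metric, preserving age and sex.

    ``table`` has columns subject_id/region/metric/value; ``roster_frame``
    is the pair-level roster (scanner, age, sexes).  Returns the adjusted
    long table (same row order) and the fitted models keyed by metric.
    """
    subj = _subject_covariates(roster_frame)
    out = table.copy()
    models: dict[str, CombatModel] = {}
    for metric, sub in table.groupby("metric", sort=False):
        wide = sub.pivot_table(
            index="region", columns="subject_id", values="value", dropna=False
        )
        wide = wide[[s for s in subj.index if s in wide.columns]]
        model = fit_combat(
            wide, subj.loc[wide.columns, "scanner"], subj.loc[wide.columns, ["age", "sex"]]
        )
        adj = apply_combat(model, wide, subj["scanner"], subj[["age", "sex"]])
        long = adj.stack(future_stack=True).rename("value").reset_index()
        key = out["metric"] == metric
        merged = (
            out.loc[key, ["subject_id", "region"]]
            .merge(long, on=["region", "subject_id"], how="left")["value"]
            .to_numpy()
        )
        out.loc[key, "value"] = merged
        models[metric] = model
    return out, models


def _subject_covariates(roster_frame: pd.DataFrame) -> pd.DataFrame:
    """Pair-level roster -> per-subject scanner/age/sex, indexed by subject id."""
    rows = []
    for row in roster_frame.itertuples(index=False):
        for idx, sex in ((1, row.sex_1), (2, row.sex_2)):
            rows.append(
                {
                    "subject_id": f"{row.pair_id}_{idx}",
                    "scanner": row.scanner,
                    "age": float(row.age),
                    "sex": sex,
                }
            )
    return pd.DataFrame(rows).set_index("subject_id")
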