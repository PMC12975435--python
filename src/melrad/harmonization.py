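"""Reference-batch empirical-Bayes harmonization of feature tables (ComBat).

Location/scale batch effects are removed per feature while the reference
batch is left exactly unchanged: features are standardized against the
reference batch's mean and SD, per-batch location (gamma) and scale
(delta^2) are estimated for the other batches, shrunk toward batch-level
priors (normal prior on gamma, inverse-gamma on delta^2) by the standard
iterative conditional-means update, and the adjusted values are mapped back
to the reference scale.

The model can be fit once and applied out-of-sample to new tables carrying
the same batch labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "combat_fit", "combat_apply", "harmonize"]

META_COLUMNS = ("patient_id", "batch")


@dataclass
class CombatModel:
    reference: str
    feature_names: list[str]
    ref_mean: np.ndarray          # per feature
    ref_sd: np.ndarray            # per feature; 0 marks degenerate features
    gamma_star: dict[str, np.ndarray] = field(default_factory=dict)
    delta2_star: dict[str, np.ndarray] = field(default_factory=dict)
    priors: dict[str, dict[str, float]] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self):
        for batch, d2 in self.delta2_star.items():
            ok = self.ref_sd > 0
            if np.any(d2[ok] <= 0):
                raise ValueError(f"delta^2 must be > 0 (batch {batch})")

    @property
    def batches(self) -> list[str]:
        return [self.reference] + sorted(self.gamma_star)

    def to_json(self, path) -> None:
        payload = {
            "reference": self.reference,
            "feature_names": self.feature_names,
            "ref_mean": self.ref_mean.tolist(),
            "ref_sd": self.ref_sd.tolist(),
            "gamma_star": {b: g.tolist() for b, g in self.gamma_star.items()},
            "delta2_star": {b: d.tolist() for b, d in self.delta2_star.items()},
            "priors": self.priors,
            "degenerate": self.degenerate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CombatModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            reference=p["reference"],
            feature_names=p["feature_names"],
            ref_mean=np.asarray(p["ref_mean"]),
            ref_sd=np.asarray(p["ref_sd"]),
            gamma_star={b: np.asarray(g) for b, g in p["gamma_star"].items()},
            delta2_star={b: np.asarray(d) for b, d in p["delta2_star"].items()},
            priors=p["priors"],
            degenerate=p["degenerate"],
        )


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = [c for c in table.columns if c not in META_COLUMNS]
    X = table[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains missing or non-finite values")
    return X, names


def _eb_shrink(Z: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Empirical-Bayes shrinkage of one batch's standardized data.

    Z is (samples, features), already standardized to the reference scale.
    Returns (gamma_star, delta2_star) per feature. Normal prior on gamma,
    inverse-gamma prior on delta^2, hyperparameters by method of moments,
    solved by iterated conditional means.
    """
    n = Z.shape[0]
    g_hat = Z.mean(axis=0)
    d2_hat = Z.var(axis=0, ddof=1) if n > 1 else np.ones(Z.shape[1])
    d2_hat = np.maximum(d2_hat, 1e-12)

    g_bar = float(g_hat.mean())
    t2 = float(g_hat.var(ddof=1)) if g_hat.size > 1 else 1.0
    t2 = max(t2, 1e-12)
    m = float(d2_hat.mean())
    s2 = float(d2_hat.var(ddof=1)) if d2_hat.size > 1 else 1.0
    s2 = max(s2, 1e-12)
    # inverse-gamma moments: lambda (shape), theta (scale)
    lam = (2.0 * s2 + m**2) / s2
    theta = (m * s2 + m**3) / s2

    g_star = g_hat.copy()
    d2_star = d2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d2_star * g_bar) / (n * t2 + d2_star)
        ss = ((Z - g_new) ** 2).sum(axis=0)
        d2_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        d2_new = np.maximum(d2_new, 1e-12)
        change = max(
            np.abs(g_new - g_star).max(initial=0.0),
            np.abs(d2_new - d2_star).max(initial=0.0),
        )
        g_star, d2_star = g_new, d2_new
        if change < tol:
            break
    priors = {"gamma_bar": g_bar, "tau2": t2, "lambda": lam, "theta": theta}
    return g_star, d2_star, priors


def combat_fit(
    table: pd.DataFrame, reference: str, shrink: bool = True
) -> CombatModel:
    """Fit the harmonization model with ``reference`` as the fixed batch.

    Every feature must have nonzero variance in the reference batch;
    features that do not are flagged and passed through unharmonized.
    With ``shrink=False`` the per-batch location/scale estimates are used
    directly (no empirical-Bayes pooling); that variant maps each batch's
    moments exactly onto the reference scale, so refitting on its own
    output is an exact identity.
    """
    if "batch" not in table.columns:
        raise ValueError("feature table must carry a 'batch' column")
    batches = table["batch"].unique().tolist()
    if reference not in batches:
        raise ValueError(f"reference batch {reference!r} not present in table")
    X, names = _feature_matrix(table)
    labels = table["batch"].to_numpy()

    ref_rows = labels == reference
    if ref_rows.sum() < 2:
        raise ValueError("reference batch needs >= 2 patients")
    ref_mean = X[ref_rows].mean(axis=0)
    ref_sd = X[ref_rows].std(axis=0, ddof=0)
    degenerate = [names[j] for j in np.flatnonzero(ref_sd == 0)]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} feature(s) constant in the reference batch; "
            "passed through unharmonized",
            stacklevel=2,
        )
    ok = ref_sd > 0

    model = CombatModel(
        reference=reference,
        feature_names=names,
        ref_mean=ref_mean,
        ref_sd=ref_sd,
        degenerate=degenerate,
    )
    for batch in batches:
        if batch == reference:
            continue
        rows = labels == batch
        if rows.sum() < 2:
            raise ValueError(f"batch {batch!r} needs >= 2 patients for fitting")
        Z = (X[rows][:, ok] - ref_mean[ok]) / ref_sd[ok]
        if shrink:
            g_star, d2_star, priors = _eb_shrink(Z)
        else:
            g_star = Z.mean(axis=0)
            d2_star = np.maximum(Z.var(axis=0, ddof=0), 1e-12)
            priors = {}
        g_full = np.zeros(len(names))
        d2_full = np.ones(len(names))
        g_full[ok] = g_star
        d2_full[ok] = d2_star
        model.gamma_star[batch] = g_full
        model.delta2_star[batch] = d2_full
        model.priors[batch] = priors
    return model


def combat_apply(model: CombatModel, table: pd.DataFrame) -> pd.DataFrame:
    """Harmonize a table with a fitted model.

    Reference-batch rows are returned bit-identical; rows from other fitted
    batches are adjusted to the reference location/scale; unknown batch
    labels are rejected.
    """
    X, names = _feature_matrix(table)
    if names != model.feature_names:
        raise ValueError("table features do not match the fitted model")
    labels = table["batch"].to_numpy()
    unknown = set(labels) - set(model.batches)
    if unknown:
        raise ValueError(f"unknown batch label(s): {sorted(unknown)}")

    out = X.copy()
    ok = model.ref_sd > 0
    for batch in set(labels):
        if batch == model.reference:
            continue
        rows = labels == batch
        Z = (X[rows][:, ok] - model.ref_mean[ok]) / model.ref_sd[ok]
        g = model.gamma_star[batch][ok]
        d2 = model.delta2_star[batch][ok]
        Zadj = (Z - g) / np.sqrt(d2)
        block = X[rows].copy()
        block[:, ok] = Zadj * model.ref_sd[ok] + model.ref_mean[ok]
        out[rows] = block
    result = table.copy()
    result[names] = out
    return result


def harmonize(
    table: pd.DataFrame, reference: str, shrink: bool = True
) -> tuple[pd.DataFrame, CombatModel]:
    """Fit-and-apply convenience wrapper (single call for the pipeline).

    The reference batch's standardization statistics are frozen at fit time,
    so the reference cohort is a fixed point and the same model can later be
    applied to further tables from the fitted batches.
    """
    model = combat_fit(table, reference, shrink=shrink)
    return combat_apply(model, table), model
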