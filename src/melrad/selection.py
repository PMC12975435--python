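"""Two-step feature screen: Mann-Whitney association, Spearman redundancy.

Step 1 keeps features whose two-sided Mann-Whitney U test against the
1-year progression status reaches p < alpha (no multiplicity adjustment at
this exploratory stage). Step 2 walks the retained features in ascending-p
order and keeps a feature only if its absolute Spearman correlation with
every already-kept feature stays at or below rho_max, so the more
significant member of each correlated pair survives. Ties in p are broken
lexicographically by identifier, making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SelectionResult", "mann_whitney_screen", "spearman_dedupe", "select_features"]


@dataclass
class SelectionResult:
    p_values: pd.Series
    step1: list[str] = field(default_factory=list)
    step2: list[str] = field(default_factory=list)
    discarded: list[tuple[str, str, float]] = field(default_factory=list)
    alpha: float = 0.05
    rho_max: float = 0.7

    def report(self) -> pd.DataFrame:
        """Flat per-feature report: p, retention stage, blocking feature."""
        blocked = {f: (against, rho) for f, against, rho in self.discarded}
        rows = []
        for name, p in self.p_values.sort_values().items():
            stage = 2 if name in self.step2 else 1 if name in self.step1 else 0
            against, rho = blocked.get(name, ("", np.nan))
            rows.append(
                {"feature": name, "p_value": p, "kept_at_step": stage,
                 "discarded_against": against, "spearman_rho": rho}
            )
        return pd.DataFrame(rows)


def _mw_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free groups, normal
    approximation with tie correction otherwise; constant features get 1."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def mann_whitney_screen(
    features: pd.DataFrame, status, alpha: float = 0.05
) -> SelectionResult:
    """Step 1: retain features associated with the binary outcome at p < alpha."""
    status = np.asarray(status).astype(bool)
    names = [c for c in features.columns if c not in ("patient_id", "batch")]
    if status.sum() == 0 or (~status).sum() == 0:
        raise ValueError("both outcome groups must be non-empty")
    X = features[names].to_numpy(dtype=float)
    pvals = pd.Series(
        [_mw_pvalue(X[status, j], X[~status, j]) for j in range(len(names))],
        index=names,
        name="p_value",
    )
    step1 = [name for name in names if pvals[name] < alpha]
    return SelectionResult(p_values=pvals, step1=step1, alpha=alpha)


def spearman_dedupe(
    features: pd.DataFrame, result: SelectionResult, rho_max: float = 0.7
) -> SelectionResult:
    """Step 2: greedy redundancy pruning in ascending-p order."""
    result.rho_max = rho_max
    order = sorted(result.step1, key=lambda f: (result.p_values[f], f))
    kept: list[str] = []
    for name in order:
        x = features[name].to_numpy(dtype=float)
        blocker = None
        for other in kept:
            rho = stats.spearmanr(x, features[other].to_numpy(dtype=float)).statistic
            if np.isnan(rho):
                rho = 0.0
            if abs(rho) > rho_max:
                blocker = (other, float(rho))
                break
        if blocker is None:
            kept.append(name)
        else:
            result.discarded.append((name, blocker[0], blocker[1]))
    result.step2 = kept
    return result


def select_features(
    features: pd.DataFrame,
    status,
    alpha: float = 0.05,
    rho_max: float = 0.7,
) -> SelectionResult:
    """Run both steps on a development table."""
    result = mann_whitney_screen(features, status, alpha=alpha)
    return spearman_dedupe(features, result, rho_max=rho_max)
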