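"""Hypergeometric over-representation analysis and median-split survival.

Pathway enrichment is the exact upper-tail hypergeometric test of a query
gene list against GMT gene sets restricted to the analysis universe (raw
p < alpha selects a set as enriched; no multiplicity correction by default,
a BH option is available).  Survival analysis dichotomizes samples at the
median expression of a candidate gene (ties to the low group) and compares
the groups by Kaplan–Meier curves, the log-rank test, and a univariate Cox
model fitted by Newton iteration on the Breslow partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .preprocess import bh_fdr

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "cox_partial_loglik",
    "CoxResult",
]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {i}: fewer than 3 fields")
        name, _desc, *members = parts
        members = [m for m in members if m]
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(f"GMT set {name}: duplicate members removed")
        if name in sets:
            raise ValueError(f"GMT line {i}: duplicate set name {name!r}")
        sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{name}\t-\t" + "\t".join(members) for name, members in sets.items()]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def hypergeometric_enrichment(
    query: list[str],
    universe: list[str],
    sets: dict[str, list[str]],
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    With universe size N, set size K (after intersecting with the universe),
    and query size n, the p-value is P(X >= k) for the observed overlap k.
    Results are sorted by p; ``enriched`` marks p < alpha (or BH-adjusted
    p < alpha when ``bh``).
    """
    uni = set(universe)
    q = set(query)
    outside = sorted(q - uni)
    if outside:
        raise ValueError(f"query genes outside universe: {outside[:10]}")
    big_n, n = len(uni), len(q)
    rows = []
    for name, members in sets.items():
        inset = set(members) & uni
        big_k = len(inset)
        k = len(inset & q)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append({"name": name, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    out = pd.DataFrame(rows, columns=["name", "k", "K", "n", "N", "p"])
    if out.empty:
        out["enriched"] = pd.Series(dtype=bool)
        return out
    crit = bh_fdr(out["p"]) if bh else out["p"].to_numpy()
    out["enriched"] = crit < alpha
    return out.sort_values(["p", "name"], ignore_index=True)


# ---------------------------------------------------------------------------
# survival


def median_split(expression: pd.Series | np.ndarray) -> np.ndarray:
    """Label samples high (1) when strictly above the median, else low (0)."""
    x = np.asarray(expression, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for a median split")
    if np.ptp(x) == 0:
        raise ValueError("all expression values identical; no split possible")
    return (x > np.median(x)).astype(int)


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival curve as a (time, survival) table."""
    t = np.asarray(time, dtype=float)
    if (t < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) on 1 df."""
    g = np.asarray(group)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank needs exactly two non-empty groups")
    mask = g == labels[1]
    res = _ll_logrank(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    hr: float
    coef: float
    se: float
    p: float
    n_high: int
    n_low: int
    converged: bool


def cox_partial_loglik(beta: float, time, event, group) -> float:
    """Breslow partial log-likelihood of a univariate binary-covariate Cox model."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(group, dtype=float)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    theta = np.exp(beta * x)
    # suffix sums over the risk set; ties share one denominator (Breslow)
    ll = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        d = (t == ti) & (e == 1)
        ll += beta * x[d].sum() - d.sum() * np.log(theta[at_risk].sum())
    return float(ll)


def cox_hr(time, event, group, tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    """Univariate Cox proportional-hazards fit for a binary group.

    Newton iteration on the Breslow partial likelihood; the hazard ratio is
    exp(beta) for the high (group = 1) versus low group.  Non-convergence or
    a monotone likelihood (complete separation) yields a flagged result
    rather than an exception.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(group, dtype=float)
    n_high = int((x == 1).sum())
    n_low = int((x == 0).sum())
    if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
        warnings.warn("a group has no events; Cox fit is degenerate")
        return CoxResult(np.nan, np.nan, np.nan, np.nan, n_high, n_low, False)

    event_times = np.unique(t[e == 1])
    risk_masks = [t >= ti for ti in event_times]
    d_x = np.array([x[(t == ti) & (e == 1)].sum() for ti in event_times])
    d_n = np.array([int(((t == ti) & (e == 1)).sum()) for ti in event_times])

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        theta = np.exp(beta * x)
        s0 = np.array([theta[m].sum() for m in risk_masks])
        s1 = np.array([(theta * x)[m].sum() for m in risk_masks])
        mean_x = s1 / s0
        score = float((d_x - d_n * mean_x).sum())
        info = float((d_n * mean_x * (1 - mean_x)).sum())
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 15:  # monotone likelihood
            break
        if abs(step) < tol:
            converged = True
            break
    theta = np.exp(beta * x)
    s0 = np.array([theta[m].sum() for m in risk_masks])
    s1 = np.array([(theta * x)[m].sum() for m in risk_masks])
    mean_x = s1 / s0
    info = float((d_n * mean_x * (1 - mean_x)).sum())
    se = np.sqrt(1.0 / info) if info > 0 else np.nan
    z = beta / se if se and np.isfinite(se) else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    if not converged:
        warnings.warn("Cox fit did not converge; result flagged")
    return CoxResult(float(np.exp(beta)), float(beta), float(se), p, n_high, n_low, converged)
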