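"""Random-effects meta-analysis and false-discovery-rate control.

Cohort-level standardized coefficients for the same metric are pooled
under the random-effects model beta_i ~ N(mu, v_i + tau^2), with the
between-cohort variance tau^2 estimated by iterative REML (Fisher
scoring on the restricted likelihood, floored at zero). With only three
cohorts REML can fail to converge; in that case the DerSimonian-Laird
moment estimator is used and the result is flagged rather than silently
substituted. Pooled weights are w_i = 1/(v_i + tau^2), so the pooled
coefficient is always a convex combination of the inputs.

Multiple comparisons within each metric family (one family per
weighting x scale, e.g. the 85 SC nodes) are corrected by the
Benjamini-Hochberg step-up procedure via statsmodels, reported as
q-values (cumulative-minimum adjusted p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MetaResult:
    metric_id: str
    beta_meta: float
    se_meta: float
    ci95: tuple[float, float]
    p: float
    tau2: float
    k: int
    estimator: str  # "REML" or "DL" (fallback)
    q_value: float = np.nan
    significant: bool = False


def _dersimonian_laird(betas: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = (w * betas).sum() / w.sum()
    Q = (w * (betas - mu) ** 2).sum()
    k = len(betas)
    c = w.sum() - (w**2).sum() / w.sum()
    return max((Q - (k - 1)) / c, 0.0) if c > 0 else 0.0


def reml_tau2(betas: np.ndarray, v: np.ndarray, tol: float = 1e-10,
              max_iter: int = 100) -> tuple[float, bool]:
    """REML estimate of tau^2 by Fisher scoring; returns (tau2, converged)."""
    tau2 = max(_dersimonian_laird(betas, v), 1e-6)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = w.sum()
        mu = (w * betas).sum() / sw
        r2 = (betas - mu) ** 2
        # restricted score and expected information in tau^2
        score = 0.5 * ((w**2 * r2).sum() - w.sum() + (w**2).sum() / sw)
        info = 0.5 * ((w**2).sum() - 2 * (w**3).sum() / sw
                      + ((w**2).sum() / sw) ** 2)
        if info <= 0:
            return tau2, False
        step = score / info
        new = max(tau2 + step, 0.0)
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new, True
        tau2 = new
    return tau2, False


def random_effects_meta(betas, ses, metric_id: str = "") -> MetaResult:
    """Pool k >= 2 cohort coefficients under a random-effects model."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("need at least 2 studies")
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)):
        raise ValueError("standard errors must be positive and finite")
    v = ses**2
    if np.allclose(betas, betas[0]):
        tau2, estimator = 0.0, "REML"  # identical effects: no heterogeneity
    else:
        tau2, converged = reml_tau2(betas, v)
        estimator = "REML"
        if not converged:
            tau2 = _dersimonian_laird(betas, v)
            estimator = "DL"
    w = 1.0 / (v + tau2)
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    ci = (beta - 1.96 * se, beta + 1.96 * se)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MetaResult(metric_id, beta, se, ci, p, float(tau2),
                      int(betas.size), estimator)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, reject flags at level q)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def meta_batch(cohort_tables: list[pd.DataFrame], q: float = 0.05) -> pd.DataFrame:
    """Meta-analyse aligned per-cohort association tables into one family.

    Each table needs columns metric_id, beta, se (the output of
    :func:`netcog.association.batch_associate`); metric_ids must align
    across cohorts. Rows flagged in any cohort are pooled over the
    remaining cohorts when at least two are usable, else flagged.
    FDR correction is applied across the family's p-values.
    """
    ids = list(cohort_tables[0]["metric_id"])
    for t in cohort_tables[1:]:
        if list(t["metric_id"]) != ids:
            raise ValueError("metric_ids misaligned across cohorts")
    rows = []
    for idx, mid in enumerate(ids):
        betas, ses = [], []
        for t in cohort_tables:
            r = t.iloc[idx]
            if (not r.get("flag", "")) and np.isfinite(r["beta"]) \
                    and np.isfinite(r["se"]) and r["se"] > 0:
                betas.append(r["beta"])
                ses.append(r["se"])
        if len(betas) >= 2:
            m = random_effects_meta(betas, ses, metric_id=str(mid))
        else:
            m = MetaResult(str(mid), np.nan, np.nan, (np.nan, np.nan),
                           np.nan, np.nan, len(betas), "insufficient")
        rows.append(m)
    out = pd.DataFrame(
        {
            "metric_id": [m.metric_id for m in rows],
            "beta_meta": [m.beta_meta for m in rows],
            "se_meta": [m.se_meta for m in rows],
            "ci_lo": [m.ci95[0] for m in rows],
            "ci_hi": [m.ci95[1] for m in rows],
            "p": [m.p for m in rows],
            "tau2": [m.tau2 for m in rows],
            "k": [m.k for m in rows],
            "estimator": [m.estimator for m in rows],
        }
    )
    ok = out["p"].notna().to_numpy()
    qvals = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if ok.any():
        qvals[ok], rej[ok] = bh_fdr(out.loc[ok, "p"].to_numpy(), q)
    out["q_value"] = qvals
    out["significant"] = rej
    return out
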