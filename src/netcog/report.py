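"""Edge-wise composite prediction and reference-network reporting.

Composite scores predict latent g from the masked edges: every edge is
z-scored and multiplied by its meta-analytic coefficient, and the sum
over edges is the participant's predicted score. Evaluating the
correlation between composite scores and observed g on a held-out
sample (scored with training-derived weights) measures out-of-sample
replicability.

Reporting utilities classify reference-network edges by hemisphere and
lobe, quantify cross-cohort agreement and hemispheric symmetry of
coefficient maps, and correlate nodal coefficients with external
regional maps (e.g. cortical morphometry effects on the same atlas).
Percentages are reported to one decimal with round-half-even.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas
from .connectome import EdgeMask

logger = logging.getLogger(__name__)


def pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of total, round-half-even to the given decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * count / total, decimals))


# ---------------------------------------------------------------------------
# composite prediction


def composite_predict(edges: np.ndarray, weights: np.ndarray,
                      means: np.ndarray | None = None,
                      sds: np.ndarray | None = None) -> np.ndarray:
    """Weighted sum of standardized edge weights, one score per participant.

    ``edges`` is participants x masked-edges in mask order and
    ``weights`` the matching meta-analytic coefficients. By default
    edges are standardized within the evaluated sample; passing
    ``means``/``sds`` (e.g. training moments) gives strict out-of-sample
    semantics. Zero-variance columns are dropped with a warning.
    """
    E = np.asarray(edges, dtype=float)
    w = np.asarray(weights, dtype=float)
    if E.shape[1] != w.size:
        raise ValueError("weights must align with edge columns")
    if not np.any(w != 0):
        logger.warning("all composite weights are zero; scores will be zero "
                       "and downstream correlations undefined")
    mu = E.mean(axis=0) if means is None else np.asarray(means, dtype=float)
    sd = E.std(axis=0, ddof=0) if sds is None else np.asarray(sds, dtype=float)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance edge column(s)",
                       int((~keep).sum()))
    Z = (E[:, keep] - mu[keep]) / sd[keep]
    return Z @ w[keep]


def agreement(beta_a, beta_b) -> float:
    """Pearson correlation between two aligned coefficient vectors."""
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(a, b)[0])


def hemispheric_symmetry(node_betas, atlas: Atlas) -> float:
    """Correlation of left-node coefficients with their right homologues.

    The brainstem, as the only unpaired midline node, is excluded.
    """
    v = np.asarray(node_betas, dtype=float)
    pairs = np.array(atlas.bilateral_pairs)
    return agreement(v[pairs[:, 0]], v[pairs[:, 1]])


# ---------------------------------------------------------------------------
# edge classification


@dataclass
class EdgeClassification:
    table: pd.DataFrame          # per-edge categories
    hemisphere_summary: pd.DataFrame
    lobe_summary: pd.DataFrame
    lobe_pair_counts: pd.DataFrame


def classify_edges(mask: EdgeMask, atlas: Atlas) -> EdgeClassification:
    """Classify every mask edge by hemisphere and lobe membership.

    Hemisphere categories are exhaustive and exclusive: edges touching
    the midline brainstem are 'brainstem_involved'; the rest are
    'intra_left', 'intra_right' or 'inter'. Lobar categories are
    'intra_lobe'/'inter_lobe' with a sorted lobe-pair label. Summary
    tables give counts and percentages of mask size (one decimal).
    """
    hemis = atlas.hemispheres
    lobes = atlas.lobes
    rows = []
    for i, j in mask.sorted_pairs():
        if hemis[i] == "midline" or hemis[j] == "midline":
            hcat = "brainstem_involved"
        elif hemis[i] != hemis[j]:
            hcat = "inter"
        else:
            hcat = f"intra_{hemis[i]}"
        lcat = "intra_lobe" if lobes[i] == lobes[j] else "inter_lobe"
        pair_label = "-".join(sorted((lobes[i], lobes[j])))
        rows.append({"i": i, "j": j, "hemisphere": hcat, "lobar": lcat,
                     "lobe_pair": pair_label})
    table = pd.DataFrame(rows)
    total = len(mask)

    def summarize(col: str) -> pd.DataFrame:
        counts = table[col].value_counts().sort_index()
        return pd.DataFrame({
            "category": counts.index,
            "count": counts.values,
            "pct": [pct(c, total) for c in counts.values],
        })

    lobe_names = sorted(set(lobes))
    pair_counts = pd.DataFrame(0, index=lobe_names, columns=lobe_names)
    for _, r in table.iterrows():
        a, b = r["lobe_pair"].split("-", 1)
        pair_counts.loc[a, b] += 1
        if a != b:
            pair_counts.loc[b, a] += 1
    return EdgeClassification(table, summarize("hemisphere"),
                              summarize("lobar"), pair_counts)


def spatial_map_correlation(node_betas: pd.Series,
                            external_map: pd.Series) -> tuple[float, list[str]]:
    """Correlate nodal coefficients with an external regional map.

    Both inputs are indexed by atlas region name; matching is by name
    over the regions present in both (typically the 68 cortical nodes).
    Returns (Pearson r, unmatched external region names).
    """
    common = node_betas.index.intersection(external_map.index)
    unmatched = [str(r) for r in external_map.index.difference(node_betas.index)]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} regions matched; need at least 3")
    if unmatched:
        logger.warning("%d external regions unmatched: %s", len(unmatched),
                       unmatched[:5])
    r = agreement(node_betas.loc[common].to_numpy(),
                  external_map.loc[common].to_numpy())
    return r, unmatched


# ---------------------------------------------------------------------------
# report writing


def write_report(meta_node: pd.DataFrame, mask: EdgeMask, atlas: Atlas,
                 outdir: str) -> None:
    """Write classification tables, symmetry stats and schematic plots.

    Every figure has a CSV twin so nothing is locked inside an image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    cls = classify_edges(mask, atlas)
    cls.table.to_csv(os.path.join(outdir, "edge_classification.csv"), index=False)
    cls.hemisphere_summary.to_csv(
        os.path.join(outdir, "hemisphere_summary.csv"), index=False)
    cls.lobe_summary.to_csv(os.path.join(outdir, "lobe_summary.csv"), index=False)
    cls.lobe_pair_counts.to_csv(os.path.join(outdir, "lobe_pair_counts.csv"))

    betas = meta_node["beta_meta"].to_numpy()
    sym = hemispheric_symmetry(betas, atlas)
    pd.DataFrame({"statistic": ["hemispheric_symmetry_r"], "value": [sym]}).to_csv(
        os.path.join(outdir, "symmetry.csv"), index=False)

    order = np.argsort(betas)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(range(len(betas)), betas[order])
    ax.set_xlabel("node (sorted by meta-analytic beta)")
    ax.set_ylabel("standardized beta")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "node_betas.png"), dpi=100)
    plt.close(fig)
    pd.DataFrame({
        "node": np.arange(len(betas))[order],
        "name": np.array(atlas.names)[order] if len(betas) == len(atlas.names)
        else np.arange(len(betas))[order],
        "beta_meta": betas[order],
    }).to_csv(os.path.join(outdir, "node_betas.csv"), index=False)
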