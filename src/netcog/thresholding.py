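"""Two-step reference-network construction.

Scanner and protocol differences leave cohorts with different network
densities, so raw per-cohort networks are not directly comparable. The
remedy implemented here is (1) consistency thresholding within each
cohort — keep the edges whose streamline-count weight has the lowest
coefficient of variation (CV = sd/mean) across participants, down to a
target density — and (2) intersection of the per-cohort masks, keeping
only edges retained in every cohort. The intersected mask is then
applied to all weightings alike.

CV is computed over all participants, counting an absent connection as
zero streamlines; excluding zeros would bias rarely reconstructed edges
toward apparent consistency. A zeros-excluded variant is available via
``zeros="exclude"``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import N_PAIRS
from .connectome import Connectome, EdgeMask, edge_pairs, matrix_to_edge_vector


def consistency_table(stack: Sequence[Connectome] | np.ndarray,
                      zeros: str = "include") -> pd.DataFrame:
    """Per-edge weight statistics across a cohort.

    Accepts a list of SC connectomes or an (n_participants, 3570) edge
    array. Returns one row per possible pair with mean, sd, CV and the
    number of participants with a nonzero weight. CV is NaN where the
    mean weight is zero (edge absent in everyone).
    """
    if zeros not in ("include", "exclude"):
        raise ValueError("zeros must be 'include' or 'exclude'")
    E = _as_edge_array(stack)
    if E.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    n_nonzero = (E > 0).sum(axis=0)
    if zeros == "include":
        mean = E.mean(axis=0)
        sd = E.std(axis=0, ddof=1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n_nonzero > 0, E.sum(axis=0) / np.maximum(n_nonzero, 1), 0.0)
            # sd over nonzero entries only
            sumsq = (E**2).sum(axis=0)
            var = np.where(
                n_nonzero > 1,
                (sumsq - n_nonzero * mean**2) / np.maximum(n_nonzero - 1, 1),
                0.0,
            )
            sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    pairs = edge_pairs()
    return pd.DataFrame(
        {
            "i": pairs[:, 0],
            "j": pairs[:, 1],
            "mean_weight": mean,
            "sd_weight": sd,
            "cv": cv,
            "n_nonzero": n_nonzero,
        }
    )


def consistency_threshold(stack: Sequence[Connectome] | np.ndarray,
                          density: float, zeros: str = "include") -> EdgeMask:
    """Retain the K = round(density * 3570) most consistent (lowest-CV) edges.

    Edges with zero mean weight are ineligible. Ties on CV are broken by
    higher mean weight, then by (i, j) lexicographic order, so the result
    is deterministic. Raises if fewer than K edges are eligible.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    table = consistency_table(stack, zeros=zeros)
    K = int(round(density * N_PAIRS))
    eligible = table[table["mean_weight"] > 0]
    if len(eligible) < K:
        raise ValueError(
            f"only {len(eligible)} eligible edges but density {density} needs {K}"
        )
    ranked = eligible.sort_values(
        by=["cv", "mean_weight", "i", "j"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).head(K)
    return EdgeMask.from_pairs(
        zip(ranked["i"], ranked["j"]),
        provenance=f"consistency threshold at density {density} ({K} edges)",
    )


def intersect_masks(masks: Sequence[EdgeMask]) -> EdgeMask:
    """Edges present in every input mask; provenance records pairwise overlaps."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to intersect")
    edges = frozenset.intersection(*(m.edges for m in masks))
    overlaps = []
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            overlaps.append(f"|{a}&{b}|={len(masks[a].edges & masks[b].edges)}")
    prov = (
        "intersection of "
        + "/".join(str(len(m)) for m in masks)
        + " edge masks; "
        + ", ".join(overlaps)
    )
    return EdgeMask(edges, prov)


def pairwise_overlap(masks: Sequence[EdgeMask]) -> pd.DataFrame:
    """Pairwise shared-edge counts and percentages (of the smaller mask)."""
    rows = []
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            shared = len(masks[a].edges & masks[b].edges)
            denom = min(len(masks[a]), len(masks[b]))
            rows.append(
                {
                    "mask_a": a,
                    "mask_b": b,
                    "size_a": len(masks[a]),
                    "size_b": len(masks[b]),
                    "shared": shared,
                    "pct_of_smaller": 100.0 * shared / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)


def mask_density(m: EdgeMask) -> float:
    """Fraction of the 3570 possible node pairs present in the mask."""
    return len(m) / N_PAIRS


def _as_edge_array(stack) -> np.ndarray:
    if isinstance(stack, np.ndarray):
        if stack.ndim != 2 or stack.shape[1] != N_PAIRS:
            raise ValueError(f"edge array must be (n, {N_PAIRS})")
        return stack
    mats = list(stack)
    if not mats:
        raise ValueError("empty connectome stack")
    return np.stack([matrix_to_edge_vector(c.W) for c in mats])
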