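"""End-to-end orchestration: simulate -> threshold -> metrics -> fit-g ->
associate -> meta -> predict -> report.

Each stage writes its outputs as CSV/JSON under the run directory so any
stage can be re-run from its on-disk inputs. A manifest records the
package version, seed, a hash of the configuration and per-stage row
counts. All randomness flows from the single root seed through the
generator's deterministic per-cohort expansion, so identical
configurations give byte-identical outputs. Floats are serialized at 10
significant digits.

The largest cohort plays the role of the main + hold-out pair: it is
split in half, the first half enters association and meta-analysis, and
the second half is touched only by the composite-prediction stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .association import batch_associate
from .cfa import GFactorSpec, factor_scores, fit_g_model
from .connectome import EdgeMask, edge_pairs as _edge_pairs, write_mask
from .meta import meta_batch
from .metrics import global_efficiency, local_efficiency, mean_clustering
from .connectome import edge_vector_to_matrix
from .report import agreement, classify_edges, composite_predict, \
    hemispheric_symmetry
from .simulate import CohortData, SimConfig, default_config, \
    generate_three_cohorts, config_to_dict
from .thresholding import consistency_threshold, intersect_masks, \
    mask_density, pairwise_overlap
from .atlas import default_atlas

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

GLOBAL_METRICS = ("mean_edge_weight", "global_efficiency", "mean_clustering")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    density: float = 0.30
    fdr_q: float = 0.05
    sim_scale: float = 0.25          # multiplies default cohort sizes
    estimator_global: str = "sem"    # one-step SEM for the 9 global metrics
    estimator_regional: str = "two_stage"  # fast estimator for node/edge batches
    moderation: bool = True
    include_sd: bool = False
    holdout_fraction: float = 0.5
    weightings: tuple[str, ...] = ("SC", "FA", "MD")

    def sim_config(self) -> SimConfig:
        return default_config(seed=self.seed, scale=self.sim_scale)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, **kw)


def _split_main_holdout(c: CohortData, fraction: float):
    n_hold = int(round(c.n * fraction))
    n_main = c.n - n_hold
    main = _subset(c, slice(0, n_main))
    hold = _subset(c, slice(n_main, c.n))
    return main, hold


def _subset(c: CohortData, sl: slice) -> CohortData:
    return CohortData(
        c.cohort_id,
        c.covariates.iloc[sl].reset_index(drop=True),
        c.tests.iloc[sl],
        {k: v[sl] for k, v in c.edge_weights.items()},
        c.node_volumes[sl],
    )


def _cohort_metrics(c: CohortData, mask: EdgeMask,
                    weightings) -> dict[str, pd.DataFrame]:
    """Global metrics + per-node local efficiency per weighting."""
    ind = mask.indicator()
    out = {}
    for wt in weightings:
        E = np.where(ind, c.edge_weights[wt], 0.0)
        rows = []
        for ev in E:
            W = edge_vector_to_matrix(ev)
            rows.append(
                [ev[ind].mean(), global_efficiency(W), mean_clustering(W)]
                + list(local_efficiency(W))
            )
        cols = list(GLOBAL_METRICS) + [f"eloc_{k}" for k in range(85)]
        df = pd.DataFrame(rows, columns=cols)
        df.insert(0, "participant_id", c.covariates["participant_id"].values)
        out[wt] = df
    return out


def run_pipeline(cfg: RunConfig, outdir: str) -> dict:
    """Execute the full chain; returns the manifest dictionary."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "netcog_version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "config": asdict(cfg),
        "stages": {},
    }
    atlas = default_atlas()
    sim = cfg.sim_config()
    with open(os.path.join(outdir, "sim_config.json"), "w") as f:
        json.dump(config_to_dict(sim), f, indent=1, sort_keys=True)

    # ---- simulate --------------------------------------------------------
    cohorts = generate_three_cohorts(sim, weightings=cfg.weightings)
    weightings = list(cfg.weightings)
    if cfg.include_sd:
        pairs = _edge_pairs()
        for c in cohorts:
            denom = (c.node_volumes[:, pairs[:, 0]]
                     + c.node_volumes[:, pairs[:, 1]])
            c.edge_weights["SD"] = c.edge_weights["SC"] / denom
        weightings.append("SD")
    main_c, holdout = _split_main_holdout(cohorts[0], cfg.holdout_fraction)
    analysis = [main_c] + cohorts[1:]
    for c in analysis:
        cdir = os.path.join(outdir, c.cohort_id)
        os.makedirs(cdir, exist_ok=True)
        _write(c.covariates.drop(columns=["true_g"]),
               os.path.join(cdir, "covariates.csv"))
        c.tests.reset_index().to_csv(os.path.join(cdir, "tests.csv"),
                                     index=False, float_format=_FLOAT_FMT)
    manifest["stages"]["simulate"] = {
        c.cohort_id: c.n for c in analysis} | {"holdout": holdout.n}

    # ---- thresholding ----------------------------------------------------
    cohort_masks = [consistency_threshold(c.edge_weights["SC"], cfg.density)
                    for c in analysis]
    ref_mask = intersect_masks(cohort_masks)
    for c, m in zip(analysis, cohort_masks):
        write_mask(m, os.path.join(outdir, c.cohort_id, "cohort_mask.csv"))
    write_mask(ref_mask, os.path.join(outdir, "reference_mask.csv"))
    _write(pairwise_overlap(cohort_masks),
           os.path.join(outdir, "mask_overlap.csv"))
    manifest["stages"]["threshold"] = {
        "cohort_mask_sizes": [len(m) for m in cohort_masks],
        "reference_edges": len(ref_mask),
        "reference_density": mask_density(ref_mask),
    }

    # ---- metrics ---------------------------------------------------------
    metrics: dict[str, dict[str, pd.DataFrame]] = {}
    for c in analysis:
        metrics[c.cohort_id] = _cohort_metrics(c, ref_mask, weightings)
        for wt, df in metrics[c.cohort_id].items():
            _write(df, os.path.join(outdir, c.cohort_id, f"metrics_{wt}.csv"))
    manifest["stages"]["metrics"] = {
        "rows": sum(len(df) for m in metrics.values() for df in m.values())}

    # ---- latent g --------------------------------------------------------
    spec = GFactorSpec(tuple(analysis[0].tests.columns),
                       ((sim.residual_cov_pair,)
                        if sim.residual_cov_pair is not None else ()))
    gfits = {}
    for c in analysis:
        fit = fit_g_model(c.tests, spec)
        gfits[c.cohort_id] = fit
        scores = factor_scores(fit, c.tests)
        scores.reset_index().to_csv(
            os.path.join(outdir, c.cohort_id, "gscores.csv"),
            index=False, float_format=_FLOAT_FMT)
        with open(os.path.join(outdir, c.cohort_id, "gfit.json"), "w") as f:
            json.dump({"CFI": fit.cfi, "TLI": fit.tli, "RMSEA": fit.rmsea,
                       "SRMR": fit.srmr, "loadings": list(fit.std_loadings),
                       "converged": fit.converged, "n": fit.n_used},
                      f, indent=1)
    manifest["stages"]["latent_g"] = {
        cid: {"CFI": round(f.cfi, 6), "converged": f.converged}
        for cid, f in gfits.items()}

    # ---- associations ----------------------------------------------------
    assoc: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    narrow_age = []
    for c in analysis:
        cdir = os.path.join(outdir, c.cohort_id)
        for wt in weightings:
            mt = metrics[c.cohort_id][wt]
            glob = batch_associate(
                mt[list(GLOBAL_METRICS)], c.tests, spec,
                c.covariates, c.cohort_id, estimator=cfg.estimator_global)
            node = batch_associate(
                mt[[f"eloc_{k}" for k in range(85)]], c.tests, spec,
                c.covariates, c.cohort_id, estimator=cfg.estimator_regional)
            ind = ref_mask.indicator()
            edge_cols = [f"edge_{i}_{j}" for i, j in ref_mask.sorted_pairs()]
            edges_df = pd.DataFrame(c.edge_weights[wt][:, ind],
                                    columns=edge_cols)
            edge = batch_associate(edges_df, c.tests, spec, c.covariates,
                                   c.cohort_id,
                                   estimator=cfg.estimator_regional)
            assoc[(c.cohort_id, wt)] = {"global": glob, "node": node,
                                        "edge": edge}
            for scale, df in assoc[(c.cohort_id, wt)].items():
                _write(df, os.path.join(cdir, f"assoc_{wt}_{scale}.csv"))
            if cfg.moderation:
                mod = batch_associate(
                    mt[list(GLOBAL_METRICS)], c.tests, spec, c.covariates,
                    c.cohort_id, estimator=cfg.estimator_regional,
                    moderation=True)
                if (mod["flag"] == "skipped").all():
                    narrow_age.append((c.cohort_id, wt))
                _write(mod, os.path.join(cdir, f"moderation_{wt}_global.csv"))
    manifest["stages"]["associate"] = {
        "families": len(assoc) * 3,
        "moderation_skipped": sorted(set(c for c, _ in narrow_age)),
    }

    # ---- meta-analysis + FDR --------------------------------------------
    meta: dict[tuple[str, str], pd.DataFrame] = {}
    for wt in weightings:
        for scale in ("global", "node", "edge"):
            tables = [assoc[(c.cohort_id, wt)][scale] for c in analysis]
            m = meta_batch(tables, q=cfg.fdr_q)
            meta[(wt, scale)] = m
            _write(m, os.path.join(outdir, f"meta_{wt}_{scale}.csv"))
    manifest["stages"]["meta"] = {
        f"{wt}_{scale}": int(m["significant"].sum())
        for (wt, scale), m in meta.items()}

    # ---- prediction ------------------------------------------------------
    ind = ref_mask.indicator()
    pred_rows = []
    for wt in weightings:
        w = meta[(wt, "edge")]["beta_meta"].fillna(0.0).to_numpy()
        for label, c in [(analysis[0].cohort_id + "_main", analysis[0]),
                         (analysis[1].cohort_id, analysis[1]),
                         (analysis[2].cohort_id, analysis[2]),
                         (analysis[0].cohort_id + "_holdout", holdout)]:
            scores = composite_predict(c.edge_weights[wt][:, ind], w)
            gfit = gfits.get(c.cohort_id)
            if gfit is None:  # holdout shares the main cohort's measurement fit
                gfit = gfits[analysis[0].cohort_id]
            g = factor_scores(gfit, c.tests).to_numpy()
            ok = ~np.isnan(g)
            r = float(np.corrcoef(scores[ok], g[ok])[0, 1]) \
                if scores[ok].std() > 0 else np.nan
            pred_rows.append({"weighting": wt, "sample": label,
                              "r": r, "n": int(ok.sum())})
    pred = pd.DataFrame(pred_rows)
    _write(pred, os.path.join(outdir, "prediction.csv"))
    manifest["stages"]["predict"] = {"rows": len(pred)}

    # ---- report ----------------------------------------------------------
    cls = classify_edges(ref_mask, atlas)
    cls.hemisphere_summary.to_csv(
        os.path.join(outdir, "hemisphere_summary.csv"), index=False)
    cls.lobe_summary.to_csv(os.path.join(outdir, "lobe_summary.csv"),
                            index=False)
    cls.lobe_pair_counts.to_csv(os.path.join(outdir, "lobe_pair_counts.csv"))
    sym_rows, agr_rows = [], []
    for wt in weightings:
        betas = meta[(wt, "node")]["beta_meta"].to_numpy()
        sym_rows.append({"weighting": wt,
                         "symmetry_r": hemispheric_symmetry(betas, atlas)})
        for a in range(len(analysis)):
            for b in range(a + 1, len(analysis)):
                ra = assoc[(analysis[a].cohort_id, wt)]["node"]["beta"]
                rb = assoc[(analysis[b].cohort_id, wt)]["node"]["beta"]
                agr_rows.append({
                    "weighting": wt,
                    "pair": f"{analysis[a].cohort_id}-{analysis[b].cohort_id}",
                    "r": agreement(ra.to_numpy(), rb.to_numpy()),
                })
    _write(pd.DataFrame(sym_rows), os.path.join(outdir, "symmetry.csv"))
    _write(pd.DataFrame(agr_rows), os.path.join(outdir, "agreement.csv"))
    manifest["stages"]["report"] = {"written": True}

    with open(os.path.join(outdir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest
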