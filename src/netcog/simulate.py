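"""Multi-cohort synthetic data with the statistical structure the
analysis assumes.

The real cohorts behind this kind of study are access-restricted, so
every downstream stage is exercised on generated data that reproduces
the features the pipeline depends on:

* three cohorts of distinct size, age range and site structure, with
  cohort-specific network density and weight scale (scanner effects);
* a shared group-level SC template with distance-dependent log-normal
  weights, perturbed per participant (edge presence is Bernoulli per
  edge with template probability, weights are jittered);
* FA edge values in [0.2, 0.7] decreasing with age, MD in
  [0.6, 1.2] x 1e-3 mm^2/s increasing with age, both zero wherever the
  participant has no streamlines;
* a latent g, mildly age-correlated, generating test scores
  x_j = lambda_j g + eps_j with loadings spanning the moderate-to-high
  range and scores missing completely at random;
* network-g coupling through a global SC multiplier (effect size
  ``beta_global``), optional edge-specific effects, and an age x g
  interaction (``beta_age_moderation``) so that moderation analyses
  have a recoverable target;
* total brain volume constructed to hit a target correlation with
  total streamline count (default 0.80).

Identical seeds give bit-identical output; all randomness flows from
``SimConfig.seed`` expanded deterministically per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .atlas import N_NODES, N_PAIRS
from .connectome import Connectome, edge_pairs, edge_vector_to_matrix

# fixed anatomical template: node coordinates are part of the package's
# synthetic anatomy, not of any cohort's randomness
_TEMPLATE_SEED = 714025


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    n: int
    age_range: tuple[float, float]
    n_sites: int
    density_target: float
    weight_scale: float  # median streamline count on core edges

    def __post_init__(self) -> None:
        if not 0 < self.density_target <= 1:
            raise ValueError("density_target must be in (0, 1]")
        if self.n < self.n_sites:
            raise ValueError("n too small for requested number of sites")


@dataclass(frozen=True)
class SimConfig:
    cohorts: tuple[CohortSpec, ...]
    loadings: tuple[float, ...] = (0.28, 0.45, 0.55, 0.65, 0.73)
    missing_rate: float = 0.10
    residual_cov_pair: tuple[int, int] | None = (0, 1)
    residual_cov_value: float = 0.10
    beta_global: float = 0.20
    beta_edge_map: tuple[tuple[int, int, float], ...] = ()
    beta_age_moderation: float = 0.0
    fa_g_coupling: float = 0.13
    md_g_coupling: float = -0.08
    age_g_corr: float = -0.20
    fa_age_slope: float = -0.015   # FA units per SD age
    md_age_slope: float = 0.030    # 1e-3 mm^2/s per SD age
    sc_tbv_corr_target: float = 0.80
    subject_log_sd: float = 0.15   # SD of the global log-weight multiplier
    edge_log_jitter: float = 0.40  # per-edge log-normal weight jitter
    site_log_sd: float = 0.05      # scanner shift on log weights
    fa_subject_sd: float = 0.020   # between-subject FA shift per SD of coupling
    fa_edge_noise: float = 0.030
    md_subject_sd: float = 0.030
    md_edge_noise: float = 0.040
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < l < 1 for l in self.loadings):
            raise ValueError("loadings must lie in (0, 1)")
        if abs(self.sc_tbv_corr_target) >= 1:
            raise ValueError("infeasible correlation target (|r| >= 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_tests(self) -> int:
        return len(self.loadings)


def default_config(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Three-cohort default: large wide-age 4-site, small wide-age 2-site,
    small narrow-age 1-site, with descending density targets.

    ``scale`` multiplies all cohort sizes (floor 100 participants).
    """
    def sz(n: int) -> int:
        return max(int(round(n * scale)), 100)

    cohorts = (
        CohortSpec("cohortA", sz(2000), (45.0, 82.0), 4, 0.35, 25.0),
        CohortSpec("cohortB", sz(500), (26.0, 84.0), 2, 0.32, 20.0),
        CohortSpec("cohortC", sz(400), (71.0, 74.0), 1, 0.30, 15.0),
    )
    # a few dozen short-range edges carry genuine edge-specific g signal
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    order = np.argsort(_template_distances())
    chosen = order[rng.choice(400, size=60, replace=False)]
    pairs = edge_pairs()[chosen]
    effects = tuple(
        (int(i), int(j), float(b))
        for (i, j), b in zip(pairs, rng.uniform(0.05, 0.20, size=60))
    )
    return SimConfig(cohorts=cohorts, beta_edge_map=effects, seed=seed)


@dataclass
class CohortData:
    """Generated cohort: covariates, test scores and per-weighting edge arrays.

    Edge arrays are (n_participants, 3570) in canonical edge order;
    ``connectomes`` expands them to symmetric matrices on demand.
    """

    cohort_id: str
    covariates: pd.DataFrame   # participant_id, age, sex, site, tbv, true_g
    tests: pd.DataFrame        # participant_id index, NaN = missing
    edge_weights: dict[str, np.ndarray]
    node_volumes: np.ndarray   # (n, 85), mm^3

    @property
    def n(self) -> int:
        return len(self.covariates)

    def connectomes(self, weighting: str):
        ids = self.covariates["participant_id"]
        for pid, ev in zip(ids, self.edge_weights[weighting]):
            yield Connectome(pid, weighting, edge_vector_to_matrix(ev))


# ---------------------------------------------------------------------------
# anatomical template


def _node_coordinates() -> np.ndarray:
    """Synthetic 3-D node positions: hemispheres mirrored about x = 0."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    left = np.column_stack([
        rng.uniform(-70, -8, 34), rng.uniform(-90, 60, 34), rng.uniform(-40, 70, 34)
    ])
    sub_left = np.column_stack([
        rng.uniform(-30, -5, 8), rng.uniform(-40, 20, 8), rng.uniform(-20, 20, 8)
    ])
    right = left * np.array([-1.0, 1.0, 1.0])
    sub_right = sub_left * np.array([-1.0, 1.0, 1.0])
    brainstem = np.array([[0.0, -30.0, -30.0]])
    return np.vstack([left, right, sub_left, sub_right, brainstem])


def _template_distances() -> np.ndarray:
    xyz = _node_coordinates()
    pairs = edge_pairs()
    return np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)


def _template_fields() -> dict[str, np.ndarray]:
    """Distance-dependent connection scores and base FA/MD per pair."""
    d = _template_distances()
    rng = np.random.default_rng(_TEMPLATE_SEED + 2)
    score = np.exp(-d / 45.0) * np.exp(rng.normal(0.0, 0.35, N_PAIRS))
    fa_base = rng.uniform(0.35, 0.60, N_PAIRS)
    md_base = rng.uniform(0.70, 1.00, N_PAIRS)
    vol_base = rng.uniform(2000.0, 9000.0, N_NODES)
    return {"distance": d, "score": score, "fa_base": fa_base,
            "md_base": md_base, "vol_base": vol_base}


def _calibrate_presence(score: np.ndarray, density: float) -> np.ndarray:
    """Scale template scores to presence probabilities with the target mean."""
    lo, hi = 0.0, 1e6
    for _ in range(200):
        c = 0.5 * (lo + hi)
        p = np.clip(c * score, 0.0, 0.995)
        if p.mean() < density:
            lo = c
        else:
            hi = c
    p = np.clip(0.5 * (lo + hi) * score, 0.0, 0.995)
    if abs(p.mean() - density) > 0.01:
        raise ValueError(f"cannot reach density target {density}")
    return p


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(cfg: SimConfig, cohort_id: str,
                    weightings: tuple[str, ...] = ("SC", "FA", "MD")) -> CohortData:
    """Generate one cohort named in ``cfg.cohorts``."""
    index = next(i for i, c in enumerate(cfg.cohorts)
                 if c.cohort_id == cohort_id)
    return _generate(cfg, cfg.cohorts[index], index, weightings)


def generate_three_cohorts(cfg: SimConfig,
                           weightings: tuple[str, ...] = ("SC", "FA", "MD")
                           ) -> list[CohortData]:
    return [_generate(cfg, spec, k, weightings)
            for k, spec in enumerate(cfg.cohorts)]


def _generate(cfg: SimConfig, spec: CohortSpec, cohort_index: int,
              weightings: tuple[str, ...]) -> CohortData:
    rng = np.random.default_rng([cfg.seed, 1000 + cohort_index])
    n = spec.n
    tpl = _template_fields()

    # covariates -----------------------------------------------------------
    age = rng.uniform(*spec.age_range, n)
    age_z = (age - age.mean()) / age.std(ddof=0)
    sex = rng.choice(["F", "M"], n)
    site = np.array([f"{spec.cohort_id}_s{k}"
                     for k in rng.integers(0, spec.n_sites, n)])
    rho = cfg.age_g_corr
    g = rho * age_z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    # cognitive tests ------------------------------------------------------
    lam = np.asarray(cfg.loadings)
    eps = rng.standard_normal((n, cfg.n_tests)) * np.sqrt(1.0 - lam**2)
    tests = g[:, None] * lam[None, :] + eps
    if cfg.residual_cov_pair is not None and cfg.residual_cov_value > 0:
        a, b = cfg.residual_cov_pair
        shared = rng.standard_normal(n) * np.sqrt(cfg.residual_cov_value)
        tests[:, a] += shared
        tests[:, b] += shared
    if cfg.missing_rate > 0:
        miss = rng.random((n, cfg.n_tests)) < cfg.missing_rate
        tests = np.where(miss, np.nan, tests)

    # SC networks ----------------------------------------------------------
    prob = _calibrate_presence(tpl["score"], spec.density_target)
    present = rng.random((n, N_PAIRS)) < prob

    bg = cfg.beta_global
    u_noise = rng.standard_normal(n)
    u = bg * g + cfg.beta_age_moderation * age_z * g \
        + np.sqrt(max(1.0 - bg**2, 0.0)) * u_noise
    site_levels = np.unique(site)
    site_shift = dict(zip(site_levels,
                          rng.normal(0.0, cfg.site_log_sd, site_levels.size)))
    site_term = np.array([site_shift[s] for s in site])

    log_mu = np.log(spec.weight_scale) + 0.8 * np.log(tpl["score"] / np.median(tpl["score"]))
    log_w = (log_mu[None, :]
             + cfg.subject_log_sd * u[:, None]
             + site_term[:, None]
             + rng.normal(0.0, cfg.edge_log_jitter, (n, N_PAIRS)))
    for i, j, beta_e in cfg.beta_edge_map:
        k = _edge_pos(i, j)
        e_noise = rng.standard_normal(n)
        ue = beta_e * g + np.sqrt(1.0 - beta_e**2) * e_noise
        log_w[:, k] += 0.5 * ue  # edge-specific log shift, SD 0.5
    sc = np.where(present, np.maximum(np.rint(np.exp(log_w)), 1.0), 0.0)

    out: dict[str, np.ndarray] = {}
    if "SC" in weightings:
        out["SC"] = sc

    # FA / MD networks (zero where no streamlines) -------------------------
    if "FA" in weightings:
        cf = cfg.fa_g_coupling
        uf = cf * g + np.sqrt(1.0 - cf**2) * rng.standard_normal(n)
        shift = cfg.fa_subject_sd * uf + cfg.fa_age_slope * age_z
        fa = (tpl["fa_base"][None, :] + shift[:, None]
              + rng.normal(0.0, cfg.fa_edge_noise, (n, N_PAIRS)))
        out["FA"] = np.where(present, np.clip(fa, 0.2, 0.7), 0.0)
    if "MD" in weightings:
        cm = cfg.md_g_coupling
        um = cm * g + np.sqrt(1.0 - cm**2) * rng.standard_normal(n)
        shift = cfg.md_subject_sd * um + cfg.md_age_slope * age_z
        md = (tpl["md_base"][None, :] + shift[:, None]
              + rng.normal(0.0, cfg.md_edge_noise, (n, N_PAIRS)))
        out["MD"] = np.where(present, np.clip(md, 0.6, 1.2), 0.0)

    # brain volumes --------------------------------------------------------
    total_sc = sc.sum(axis=1)
    tz = (total_sc - total_sc.mean()) / total_sc.std(ddof=0)
    r = cfg.sc_tbv_corr_target
    tbv_z = r * tz + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    tbv = 1.2e6 * (1.0 + 0.08 * tbv_z)
    vol_scale = (tbv / 1.2e6)[:, None]
    node_vol = (tpl["vol_base"][None, :] * vol_scale
                * np.exp(rng.normal(0.0, 0.03, (n, N_NODES))))

    ids = [f"{spec.cohort_id}_{k:05d}" for k in range(n)]
    covars = pd.DataFrame({
        "participant_id": ids, "age": age, "sex": sex, "site": site,
        "tbv": tbv, "true_g": g,
    })
    tests_df = pd.DataFrame(
        tests, columns=[f"test_{j}" for j in range(cfg.n_tests)])
    tests_df.insert(0, "participant_id", ids)
    tests_df = tests_df.set_index("participant_id")
    return CohortData(spec.cohort_id, covars, tests_df, out, node_vol)


def _edge_pos(i: int, j: int) -> int:
    from .connectome import pair_to_edge_index

    return int(pair_to_edge_index(np.array([min(i, j)]), np.array([max(i, j)]))[0])


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["cohorts"] = tuple(CohortSpec(**{**c, "age_range": tuple(c["age_range"])})
                         for c in d["cohorts"])
    d["loadings"] = tuple(d["loadings"])
    if d.get("residual_cov_pair") is not None:
        d["residual_cov_pair"] = tuple(d["residual_cov_pair"])
    d["beta_edge_map"] = tuple(tuple(e) for e in d.get("beta_edge_map", ()))
    return SimConfig(**d)
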