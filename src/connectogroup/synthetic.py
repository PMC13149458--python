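"""Synthetic two-group connectome cohorts with planted, parameterized effects.

This module stands in for a full diffusion-MRI tractography pipeline.  It
emulates the *statistical structure* of dense weighted undirected
connectomes — not streamlines or images — so that every downstream stage
(edge inference, graph metrics, group statistics, classification) can be
exercised against known ground truth.

Generative model
----------------
* SC (streamline count): log-normal per edge around a population log-mean
  with a latent hub structure and distance decay, times a per-subject global
  scaling factor (inter-subject streamline-count variability).
* FA: logit-normal (bounded in (0, 1)).
* AD, RD: log-normal; MD is derived as (AD + 2 RD) / 3, mimicking the
  coupling of tensor-derived scalars.
* Tractogram filtering is emulated at the level of its output: a per-edge
  multiplier m_ij in [0, 1], Beta-distributed with a mean that decreases
  with a latent per-edge "implausibility" score.  Filtered SC equals
  m_ij x the plausible part of the unfiltered SC; mean-metric connectomes
  are pulled toward the subject's multiplier-weighted mean value.
* Group effects are planted on configurable edge or node sets as a
  standardized mean difference (Cohen's d) on the metric's analysis scale
  (log for SC/AD/RD/MD, logit for FA), with three filtering stages:

  - ``both``: the effect survives filtering (null effect of filtering).
  - ``unfiltered_only``: the effect is carried by implausible streamlines:
    it appears only in the unfiltered connectome and the affected edges get
    small, noisy multipliers, so filtering removes the difference
    ("removal").
  - ``masked_until_filtered``: artifact streamlines swamp the effect in the
    unfiltered connectome; filtering suppresses them and the effect emerges
    ("emergence").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .atlas import aal90, generic_atlas
from .core import Cohort, CohortManifest, Connectome, METRICS

__all__ = [
    "EffectSpec", "SimulationConfig", "FilteringTrace",
    "simulate_cohort", "empirical_effect_size", "sift2_weight_histograms",
    "cohens_d", "scenario_config",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference (positive d => PD > HC).

    ``members`` is a tuple of strictly-upper-triangle edges ``(i, j)`` with
    ``i < j`` for ``target='edge_set'``, or region indices for
    ``target='node_set'`` (the effect is applied to every edge incident to
    the node).
    """

    target: str = "edge_set"            # edge_set | node_set | none
    members: tuple = ()
    cohens_d: float = 0.0
    metric: str = "SC"
    stage: str = "both"                 # both | unfiltered_only | masked_until_filtered

    def __post_init__(self) -> None:
        if self.target not in ("edge_set", "node_set", "none"):
            raise ConfigError(f"unknown effect target {self.target!r}")
        if self.stage not in ("both", "unfiltered_only", "masked_until_filtered"):
            raise ConfigError(f"unknown effect stage {self.stage!r}")
        if not np.isfinite(self.cohens_d):
            raise ConfigError("cohens_d must be finite")
        if self.target != "none" and len(self.members) == 0:
            raise ConfigError("effect members must be non-empty")
        if self.target == "edge_set":
            for (i, j) in self.members:
                if not i < j:
                    raise ConfigError(
                        f"edge members must be strictly-upper-triangle pairs, got {(i, j)}")

    def edge_mask(self, n: int) -> np.ndarray:
        """Boolean (n, n) symmetric mask of affected edges."""
        mask = np.zeros((n, n), dtype=bool)
        if self.target == "edge_set":
            for (i, j) in self.members:
                if j >= n:
                    raise ConfigError(f"edge {(i, j)} outside a {n}-region atlas")
                mask[i, j] = mask[j, i] = True
        elif self.target == "node_set":
            for i in self.members:
                if i >= n:
                    raise ConfigError(f"node {i} outside a {n}-region atlas")
                mask[i, :] = mask[:, i] = True
            np.fill_diagonal(mask, False)
        return mask


# Cohort composition of the PPMI-derived study sample: 67 HC (24 F / 43 M),
# 166 PD (61 F / 105 M), with the published per-group, per-sex age moments.
DEFAULT_DEMOGRAPHICS = {
    "HC": {"F": (24, 58.79, 8.56), "M": (43, 61.81, 11.97)},
    "PD": {"F": (61, 60.12, 8.99), "M": (105, 61.68, 9.69)},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a simulated cohort.

    Baseline families (per metric, on the analysis scale):

    * ``sc_log_mean`` / ``sc_log_between_sd``: population structure of log SC
      (hubs and distance decay add on top of the mean);
    * ``sc_log_noise_sd``: per-subject, per-edge log-normal noise;
    * ``subject_scale_sd``: sd of the per-subject global log scaling factor
      applied to SC (default 10% streamline-count variability);
    * ``fa_logit_mean`` / ``fa_logit_sd``: logit-normal FA;
    * ``ad_log_mean`` / ``rd_log_mean`` / ``diff_log_*_sd``: log-normal
      diffusivities in um^2/ms (AD > RD in healthy white matter);
    * ``filter_mean_high`` / ``filter_mean_low``: multiplier mean for the
      most / least plausible edges; ``filter_concentration``: Beta
      concentration of the per-subject multiplier draw.
    """

    n_hc: int = 67
    n_pd: int = 166
    n_regions: int = 90
    demographics: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)
    metrics: tuple[str, ...] = METRICS
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    # baseline edge-weight model
    sc_log_mean: float = 3.0
    sc_log_between_sd: float = 1.0
    sc_log_noise_sd: float = 0.25
    subject_scale_sd: float = 0.10
    fa_logit_mean: float = 0.0          # FA ~ 0.5 on average along streamlines
    fa_logit_between_sd: float = 0.5
    fa_logit_noise_sd: float = 0.15
    ad_log_mean: float = 0.30           # ~1.35 um^2/ms
    rd_log_mean: float = -0.40          # ~0.67 um^2/ms
    diff_log_between_sd: float = 0.10
    diff_log_noise_sd: float = 0.08

    # SIFT2-like filtering model (no group dependence)
    filter_mean_high: float = 0.95
    filter_mean_low: float = 0.35
    filter_concentration: float = 30.0

    # removal / emergence machinery; the artifact term is sized to swamp a
    # node-level planted effect in the unfiltered connectome (its per-edge
    # noise sd is an order of magnitude above typical clean edge weights)
    removal_multiplier_mean: float = 0.12
    removal_concentration: float = 1.5
    artifact_log_sd: float = 1.25
    artifact_scale: float = 6.0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_pd < 2:
            raise ConfigError("need at least 2 subjects per group")
        if self.n_regions < 3:
            raise ConfigError("need at least 3 regions")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ConfigError(f"unknown metrics {sorted(unknown)}")
        if not (0.0 < self.filter_mean_low <= self.filter_mean_high <= 1.0):
            raise ConfigError("filter multiplier means must satisfy 0 < low <= high <= 1")
        for e in self.effects:
            if e.metric not in METRICS:
                raise ConfigError(f"effect on unknown metric {e.metric!r}")
            if e.metric == "FA":
                # shifting the logit mean by d*sigma must keep FA computable
                shift = abs(e.cohens_d) * self.analysis_sd("FA")
                if abs(self.fa_logit_mean) + 3 * self.fa_logit_between_sd + shift > 12:
                    raise ConfigError("FA effect pushes the logit mean out of numeric range")
            e.edge_mask(self.n_regions)  # validates member indices

    def analysis_sd(self, metric: str) -> float:
        """Within-group sd on the analysis (log / logit) scale."""
        if metric == "SC":
            return float(np.hypot(self.sc_log_noise_sd, self.subject_scale_sd))
        if metric == "FA":
            return self.fa_logit_noise_sd
        return self.diff_log_noise_sd


@dataclass
class FilteringTrace:
    """Realized per-subject, per-edge multipliers m_ij = filtered/unfiltered SC.

    ``multipliers`` maps subject_id -> symmetric (n, n) matrix in [0, 1].
    This is the simulated ground truth that filtering-impact analyses (and
    the SIFT2-weight histogram comparison) read back.
    """

    multipliers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for sid, m in self.multipliers.items():
            if (m < -1e-12).any() or (m > 1 + 1e-12).any():
                raise ValueError(f"multipliers for {sid} outside [0, 1]")
            if not np.allclose(m, m.T):
                raise ValueError(f"multipliers for {sid} not symmetric")


def _sample_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> CohortManifest:
    rows = []
    for group, n_group in (("HC", cfg.n_hc), ("PD", cfg.n_pd)):
        demo = cfg.demographics[group]
        n_total_spec = demo["F"][0] + demo["M"][0]
        n_f = int(round(n_group * demo["F"][0] / n_total_spec))
        sexes = ["F"] * n_f + ["M"] * (n_group - n_f)
        for k, sex in enumerate(sexes):
            _, mu, sd = demo[sex]
            age = float(np.clip(rng.normal(mu, sd), 30.0, 95.0))
            rows.append({
                "subject_id": f"{group.lower()}{k + 1:04d}",
                "group": group, "sex": sex, "age": round(age, 1),
            })
    return CohortManifest(pd.DataFrame(rows))


def _population_structure(cfg: SimulationConfig, rng: np.random.Generator):
    """Latent population-level edge structure shared by all subjects."""
    n = cfg.n_regions

    def sym(a):
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        return a

    pos = rng.uniform(0.0, 1.0, size=(n, 3))            # latent region layout
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    hub = rng.normal(0.0, 0.6, size=n)                  # hub propensity
    sc_mu = sym(cfg.sc_log_mean + hub[:, None] + hub[None, :] - 2.0 * dist
                + rng.normal(0.0, cfg.sc_log_between_sd, size=(n, n)))
    fa_mu = sym(cfg.fa_logit_mean + rng.normal(0.0, cfg.fa_logit_between_sd, size=(n, n)))
    ad_mu = sym(cfg.ad_log_mean + rng.normal(0.0, cfg.diff_log_between_sd, size=(n, n)))
    rd_mu = sym(cfg.rd_log_mean + rng.normal(0.0, cfg.diff_log_between_sd, size=(n, n)))

    # implausibility in [0, 1]: weak edges rank high and get down-weighted
    iu = np.triu_indices(n, 1)
    rank = stats.rankdata(-sc_mu[iu]) / iu[0].size
    implaus = np.zeros((n, n))
    implaus[iu] = rank
    implaus += implaus.T
    return sc_mu, fa_mu, ad_mu, rd_mu, implaus


def _shift_matrix(cfg: SimulationConfig, metric: str, group: str, state: str) -> np.ndarray:
    """Planted mean shift per edge on the analysis scale for one group.

    Effects with ``stage='unfiltered_only'`` contribute only to the
    unfiltered state; ``both`` and ``masked_until_filtered`` contribute to
    both states (the latter is hidden in the unfiltered connectome by
    artifact noise, not by the mean structure).
    """
    n = cfg.n_regions
    shift = np.zeros((n, n))
    if group != "PD":
        return shift
    for spec in cfg.effects:
        applies = spec.metric == metric or (metric in ("AD", "RD") and spec.metric == "MD")
        if not applies:
            continue
        if spec.stage == "unfiltered_only" and state != "unfiltered":
            continue
        shift[spec.edge_mask(n)] += spec.cohens_d * cfg.analysis_sd(spec.metric)
    return shift


def simulate_cohort(cfg: SimulationConfig) -> tuple[Cohort, FilteringTrace]:
    """Generate a two-group cohort of paired filtered/unfiltered connectomes.

    Deterministic given ``cfg.seed``.  Returns the cohort together with the
    realized filtering multipliers (ground truth for filtering analyses).
    The planted population standardized mean difference on each target
    element equals the spec's Cohen's d on the analysis scale; on the raw
    weight scale the empirical d matches to within Monte-Carlo and
    transform-curvature error.
    """
    master = np.random.SeedSequence(cfg.seed)
    s_pop, s_manifest, s_subjects = master.spawn(3)
    manifest = _sample_manifest(cfg, np.random.default_rng(s_manifest))

    n = cfg.n_regions
    labels = aal90() if n == 90 else generic_atlas(n)
    sc_mu, fa_mu, ad_mu, rd_mu, implaus = _population_structure(
        cfg, np.random.default_rng(s_pop))
    iu = np.triu_indices(n, 1)

    # per-edge multiplier distribution; removal-target edges are implausible
    mult_mean = cfg.filter_mean_high - (cfg.filter_mean_high - cfg.filter_mean_low) * implaus
    concentration = np.full((n, n), cfg.filter_concentration)
    emergence_mask = np.zeros((n, n), dtype=bool)
    for spec in cfg.effects:
        if spec.stage == "unfiltered_only":
            m_ = spec.edge_mask(n)
            mult_mean[m_] = cfg.removal_multiplier_mean
            concentration[m_] = cfg.removal_concentration
        elif spec.stage == "masked_until_filtered":
            emergence_mask |= spec.edge_mask(n)

    shifts = {
        (metric, state): _shift_matrix(cfg, metric, "PD", state)
        for metric in ("SC", "FA", "AD", "RD")
        for state in ("unfiltered", "filtered")
    }
    want = set(cfg.metrics)
    needs_diff = bool({"AD", "RD", "MD"} & want)

    connectomes: dict[tuple[str, str, str], Connectome] = {}
    multipliers: dict[str, np.ndarray] = {}

    for row, sseed in zip(manifest.table.itertuples(index=False),
                          s_subjects.spawn(len(manifest))):
        rng = np.random.default_rng(sseed)
        sid, group = row.subject_id, row.group
        is_pd = group == "PD"

        def sym_noise(sd: float) -> np.ndarray:
            z = np.zeros((n, n))
            z[iu] = rng.normal(0.0, sd, size=iu[0].size)
            return z + z.T

        def shifted(metric: str, state: str) -> np.ndarray:
            return shifts[(metric, state)] if is_pd else 0.0

        # multipliers: per-subject Beta draw around the population mean
        a = mult_mean * concentration
        b = (1.0 - mult_mean) * concentration
        m = np.zeros((n, n))
        m[iu] = rng.beta(a[iu], b[iu])
        m += m.T

        # --- SC ---
        g_s = rng.normal(0.0, cfg.subject_scale_sd)      # subject global factor
        latent_sc = sc_mu + g_s + sym_noise(cfg.sc_log_noise_sd)
        sc_unf_clean = np.exp(latent_sc + shifted("SC", "unfiltered"))
        sc_fil_clean = np.exp(latent_sc + shifted("SC", "filtered"))
        np.fill_diagonal(sc_unf_clean, 0.0)
        np.fill_diagonal(sc_fil_clean, 0.0)

        artifact = np.zeros((n, n))
        if emergence_mask.any():
            art = np.zeros((n, n))
            art[iu] = np.exp(rng.normal(0.0, cfg.artifact_log_sd, size=iu[0].size))
            art += art.T
            artifact = np.where(emergence_mask,
                                cfg.artifact_scale * np.exp(sc_mu) * art, 0.0)
            np.fill_diagonal(artifact, 0.0)

        sc_unf = sc_unf_clean + artifact
        sc_fil = m * sc_fil_clean                        # artifacts get ~zero weight
        with np.errstate(invalid="ignore", divide="ignore"):
            m_eff = np.where(sc_unf > 0, sc_fil / sc_unf, m)
        np.fill_diagonal(m_eff, 0.0)
        multipliers[sid] = np.clip(m_eff, 0.0, 1.0)

        if "SC" in want:
            connectomes[(sid, "SC", "unfiltered")] = Connectome(
                sid, "SC", "unfiltered", sc_unf, labels)
            connectomes[(sid, "SC", "filtered")] = Connectome(
                sid, "SC", "filtered", sc_fil, labels)

        def mean_metric_pair(base_mu: np.ndarray, metric: str, inv) -> tuple:
            """(unfiltered, filtered) matrices for a mean-metric connectome."""
            sd = cfg.fa_logit_noise_sd if metric == "FA" else cfg.diff_log_noise_sd
            latent = base_mu + sym_noise(sd)
            unf = inv(latent + shifted(metric, "unfiltered"))
            if emergence_mask.any():
                noisy = inv(latent + shifted(metric, "unfiltered") + sym_noise(6.0 * sd))
                unf = np.where(emergence_mask, noisy, unf)
            fil_clean = inv(latent + shifted(metric, "filtered"))
            # filtering pulls each edge toward the multiplier-weighted mean
            wbar = float(np.average(fil_clean[iu], weights=m[iu] + 1e-12))
            fil = m * fil_clean + (1.0 - m) * wbar
            np.fill_diagonal(unf, 0.0)
            np.fill_diagonal(fil, 0.0)
            return unf, fil

        if "FA" in want:
            fa_unf, fa_fil = mean_metric_pair(fa_mu, "FA", expit)
            connectomes[(sid, "FA", "unfiltered")] = Connectome(
                sid, "FA", "unfiltered", fa_unf, labels)
            connectomes[(sid, "FA", "filtered")] = Connectome(
                sid, "FA", "filtered", fa_fil, labels)

        if needs_diff:
            ad_unf, ad_fil = mean_metric_pair(ad_mu, "AD", np.exp)
            rd_unf, rd_fil = mean_metric_pair(rd_mu, "RD", np.exp)
            pairs = {"AD": (ad_unf, ad_fil), "RD": (rd_unf, rd_fil),
                     "MD": ((ad_unf + 2.0 * rd_unf) / 3.0, (ad_fil + 2.0 * rd_fil) / 3.0)}
            for metric, (unf, fil) in pairs.items():
                if metric in want:
                    connectomes[(sid, metric, "unfiltered")] = Connectome(
                        sid, metric, "unfiltered", unf, labels)
                    connectomes[(sid, metric, "filtered")] = Connectome(
                        sid, metric, "filtered", fil, labels)

    return Cohort(manifest, connectomes, labels), FilteringTrace(multipliers)


def cohens_d(x_pd: np.ndarray, x_hc: np.ndarray) -> np.ndarray:
    """Classical pooled-sd Cohen's d (PD minus HC), vectorized over columns.

    NaN marks elements whose pooled variance is zero (undefined d).
    """
    x_pd = np.atleast_2d(np.asarray(x_pd, dtype=float))
    x_hc = np.atleast_2d(np.asarray(x_hc, dtype=float))
    n1, n2 = x_pd.shape[0], x_hc.shape[0]
    v1 = x_pd.var(axis=0, ddof=1)
    v2 = x_hc.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (x_pd.mean(axis=0) - x_hc.mean(axis=0)) / pooled
    return np.where(pooled > 0, d, np.nan)


def empirical_effect_size(cohort: Cohort, metric: str, filtering: str,
                          statistic: str = "edge") -> np.ndarray:
    """Cohen's d per edge or per node-measure, for verifying planted effects.

    ``statistic='edge'`` returns a symmetric (n, n) matrix of per-edge d;
    ``statistic in {'strength', 'betweenness', 'clustering'}`` returns a
    length-n vector of d on that node measure.
    """
    cohort.manifest.require_two_groups()
    if statistic == "edge":
        x = cohort.edge_matrix(metric, filtering)
    else:
        from .graph_metrics import node_measure_matrix
        x = node_measure_matrix(cohort, metric, filtering, statistic)
    pd_mask = cohort.manifest.group_mask("PD")
    d = cohens_d(x[pd_mask], x[~pd_mask])
    if statistic != "edge":
        return d
    n = len(cohort.labels)
    out = np.full((n, n), np.nan)
    iu = np.triu_indices(n, 1)
    out[iu] = d
    out.T[iu] = d
    return out


def sift2_weight_histograms(trace: FilteringTrace, manifest: CohortManifest,
                            n_subjects: int = 20, seed: int = 0,
                            bins: int = 50) -> tuple[pd.DataFrame, float, float]:
    """Per-group histograms of filtering multipliers plus a KS distance.

    Draws ``n_subjects/2`` subjects per group at random, pools their edge
    multipliers, and compares the two samples with a two-sample
    Kolmogorov-Smirnov test — the quantitative version of asking whether
    filtering affects patients more than controls.

    Returns ``(histogram_table, ks_statistic, ks_pvalue)``.
    """
    rng = np.random.default_rng(seed)
    per_group = n_subjects // 2
    samples = {}
    for group in ("HC", "PD"):
        ids = [s for s in manifest.group_ids(group) if s in trace.multipliers]
        if len(ids) < per_group:
            raise ValueError(
                f"requested {per_group} {group} subjects but only {len(ids)} available")
        chosen = rng.choice(ids, size=per_group, replace=False)
        vals = [trace.multipliers[sid][np.triu_indices(
            trace.multipliers[sid].shape[0], 1)] for sid in chosen]
        samples[group] = np.concatenate(vals)

    edges = np.linspace(0.0, 1.0, bins + 1)
    table = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "HC": np.histogram(samples["HC"], bins=edges)[0],
        "PD": np.histogram(samples["PD"], bins=edges)[0],
    })
    if np.ptp(samples["HC"]) == 0 and np.ptp(samples["PD"]) == 0 and \
            samples["HC"][0] == samples["PD"][0]:
        return table, 0.0, 1.0      # degenerate single-bin histograms
    ks = stats.ks_2samp(samples["HC"], samples["PD"])
    return table, float(ks.statistic), float(ks.pvalue)


# -- scenario presets --------------------------------------------------------

def clique_edges(nodes) -> tuple[tuple[int, int], ...]:
    """All strictly-upper-triangle edges among a set of regions."""
    nodes = sorted(int(v) for v in nodes)
    return tuple((i, j) for k, i in enumerate(nodes) for j in nodes[k + 1:])


def scenario_config(name: str, *, seed: int = 0, n_regions: int = 90,
                    n_hc: int = 67, n_pd: int = 166,
                    cohens_d: float = 1.5, n_targets: int = 6) -> SimulationConfig:
    """Preset configurations for the canonical study conditions.

    ``null``: no planted effect; ``edge_effect``: a 10-edge connected
    component spanning five regions; ``node_effect``: four affected regions;
    ``removal`` / ``emergence``: a clique effect among ``n_targets`` regions
    that is visible only before filtering, or only revealed by it.  The
    removal and emergence effects are confined to edges *within* the target
    set so that the planted signal does not spill into other nodes' strengths.
    """
    base = SimulationConfig(n_hc=n_hc, n_pd=n_pd, n_regions=n_regions, seed=seed)
    if name == "null":
        return base
    rng = np.random.default_rng(seed + 104729)
    nodes = [int(v) for v in rng.choice(n_regions, size=max(5, n_targets), replace=False)]
    if name == "edge_effect":
        eff = EffectSpec("edge_set", clique_edges(nodes[:5]), cohens_d, "SC", "both")
    elif name == "node_effect":
        eff = EffectSpec("node_set", tuple(nodes[:4]), cohens_d, "SC", "both")
    elif name == "removal":
        eff = EffectSpec("edge_set", clique_edges(nodes[:n_targets]), cohens_d,
                         "SC", "unfiltered_only")
    elif name == "emergence":
        eff = EffectSpec("edge_set", clique_edges(nodes[:n_targets]), cohens_d,
                         "SC", "masked_until_filtered")
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    return replace(base, effects=(eff,))
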