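"""Synthetic subtype-structured expression cohorts.

The generator reproduces the statistical structure that motivates
personalized classification in heterogeneous tumor cohorts:

* **latent subtypes** whose members correlate positively with one another and
  weakly or negatively with members of other subtypes — centroids are placed
  at the vertices of a regular simplex embedded in gene space, so pairwise
  centroid inner products are negative by construction;
* **subtype-specific outcome rules** — the log-odds of a poor outcome is a
  linear function of a block of signal genes whose coefficients flip sign
  between subtypes (so a single pooled linear model faces cancelling
  effects while a subtype-aware model does not);
* **class imbalance** — the intercept is calibrated so the poor fraction
  matches a target prevalence;
* **multi-study batch structure** — each study contributes an additive
  per-gene mean shift.

The label-generating oracle (true probabilities and per-subtype coefficient
vectors) is retained in ``dataset.attrs`` so tests can compare fitted models
against the Bayes-optimal ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import ExpressionDataset

__all__ = [
    "GeneratorConfig",
    "PlatformShift",
    "generate_cohort",
    "generate_paired_cohorts",
    "generate_feature_stability_cohort",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a cohort of 400 patients, 500 genes and 3 latent
    subtypes with a poor-outcome prevalence near 0.28 (the imbalance typical
    of five-year metastasis cohorts) spread over 4 studies.
    """

    n_samples: int = 400
    n_genes: int = 500
    n_subtypes: int = 3
    subtype_proportions: Optional[Sequence[float]] = None  # default: equal
    n_signal_genes_per_subtype: int = 20
    signal_effect: float = 0.6  # logit units per unit expression
    #: genes whose outcome effect is identical in every subtype. This is what
    #: makes anti-correlated patients informative (their labels constrain the
    #: same coefficients from the opposite side of expression space); only in
    #: shared_reversed mode.
    n_shared_signal_genes: int = 10
    shared_signal_effect: float = 0.6
    centroid_scale: float = 1.0  # RMS per-gene centroid magnitude
    #: per-subtype multipliers on centroid_scale. Real cohorts mix tight and
    #: loose subtypes; the spread also governs how many anti-correlated
    #: patients each threshold admits. None -> linspace(1.4, 0.6, K).
    subtype_tightness: Optional[Sequence[float]] = None
    noise_sd: float = 1.0
    poor_prevalence_target: float = 0.28
    n_studies: int = 4
    study_shift_sd: float = 0.3
    #: "shared_reversed": one signal block for all subtypes, coefficient signs
    #: reversed between subtypes (pooled effects cancel). "disjoint": each
    #: subtype has its own signal block.
    signal_mode: str = "shared_reversed"
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.subtype_proportions is None:
            p = np.full(self.n_subtypes, 1.0 / self.n_subtypes)
        else:
            p = np.asarray(self.subtype_proportions, dtype=float)
        if len(p) != self.n_subtypes or not np.isclose(p.sum(), 1.0):
            raise ValueError("subtype proportions must sum to 1, one per subtype")
        return p

    def validate(self) -> None:
        self.proportions()
        if self.signal_mode not in ("shared_reversed", "disjoint"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        need = (
            self.n_signal_genes_per_subtype * self.n_subtypes
            if self.signal_mode == "disjoint"
            else self.n_signal_genes_per_subtype + self.n_shared_signal_genes
        )
        if need > self.n_genes:
            raise ValueError("signal genes exceed total genes")
        if not 0 < self.poor_prevalence_target < 1:
            raise ValueError("poor_prevalence_target must lie in (0, 1)")
        if min(self.noise_sd, self.signal_effect, self.centroid_scale) <= 0:
            raise ValueError("noise_sd, signal_effect, centroid_scale must be positive")
        if self.subtype_tightness is not None:
            t = np.asarray(self.subtype_tightness, dtype=float)
            if len(t) != self.n_subtypes or (t <= 0).any():
                raise ValueError(
                    "subtype_tightness needs one positive multiplier per subtype"
                )


@dataclass
class PlatformShift:
    """Monotone per-gene distortion emulating a platform/processing change.

    Each value of the second cohort is mapped through
    ``a_s * (a_g * x + b_g + cubic_coef * x^3) + b_s`` with positive gains
    (strictly monotone per gene): per-gene gain/offset emulate probe effects,
    the per-sample gain/offset emulate array intensity variation (the batch
    structure quantile normalization classically removes), and a random
    fraction of genes is dropped to emulate differing gene panels.
    ``PlatformShift()`` is the identity.
    """

    gene_scale_range: tuple[float, float] = (1.0, 1.0)
    gene_offset_sd: float = 0.0
    cubic_coef: float = 0.0
    sample_scale_range: tuple[float, float] = (1.0, 1.0)
    sample_offset_sd: float = 0.0
    dropout_fraction: float = 0.0

    def is_identity(self) -> bool:
        return (
            self.gene_scale_range == (1.0, 1.0)
            and self.gene_offset_sd == 0
            and self.cubic_coef == 0
            and self.sample_scale_range == (1.0, 1.0)
            and self.sample_offset_sd == 0
            and self.dropout_fraction == 0
        )


def _simplex_centroids(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    tightness: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Subtype centroids with pairwise-negative inner products.

    K unit vectors of a regular (K-1)-simplex (pairwise inner product
    -1/(K-1)) are embedded in gene space through a random orthonormal basis
    and scaled so subtype k's per-gene RMS magnitude is
    ``centroid_scale * tightness[k]``. Unequal tightness gives subtypes of
    different compactness, so the fraction of (anti-)correlated patients a
    threshold admits varies by subtype as it does in real cohorts.
    """
    k, g = cfg.n_subtypes, cfg.n_genes
    if k == 1:
        return np.zeros((1, g))
    if tightness is None:
        tightness = cfg.subtype_tightness
    if tightness is None:
        tightness = np.linspace(1.4, 0.6, k)
    tightness = np.asarray(tightness, dtype=float)
    # regular simplex vertices in R^(K-1)
    verts = np.eye(k) - 1.0 / k
    u, s, vt = np.linalg.svd(verts, full_matrices=False)
    simplex = (verts @ vt[: k - 1].T)
    simplex /= np.linalg.norm(simplex, axis=1, keepdims=True)
    basis, _ = np.linalg.qr(rng.standard_normal((g, k - 1)))
    scaled = cfg.centroid_scale * tightness[:, None] * simplex
    return np.sqrt(g) * scaled @ basis.T


def _signal_structure(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Signal-gene indices and the K x n_genes coefficient matrix."""
    k, g, m = cfg.n_subtypes, cfg.n_genes, cfg.n_signal_genes_per_subtype
    betas = np.zeros((k, g))
    if cfg.signal_mode == "disjoint":
        genes = rng.choice(g, size=k * m, replace=False)
        for j in range(k):
            block = genes[j * m : (j + 1) * m]
            betas[j, block] = cfg.signal_effect * rng.choice([-1.0, 1.0], size=m)
        return np.sort(genes), betas
    # shared_reversed: a reversed block whose per-subtype sign patterns are
    # centered so the proportion-weighted mean coefficient is exactly zero
    # per gene (pooling cancels), plus a shared block with identical
    # coefficients in every subtype (anti-correlated patients inform it)
    m_sh = cfg.n_shared_signal_genes
    genes = rng.choice(g, size=m + m_sh, replace=False)
    rev_genes, sh_genes = genes[:m], genes[m:]
    props = cfg.proportions()
    while True:
        signs = rng.choice([-1.0, 1.0], size=(k, m))
        if k == 1 or not (signs == signs[0]).all(axis=0).all():
            break
    centered = signs - props @ signs
    betas[:, rev_genes] = cfg.signal_effect * centered
    if m_sh:
        betas[:, sh_genes] = cfg.shared_signal_effect * rng.choice(
            [-1.0, 1.0], size=m_sh
        )
    return np.sort(genes), betas


def _draw_expression(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    centroids: np.ndarray,
    study_shifts: np.ndarray,
    n: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    props = cfg.proportions()
    subtype_idx = rng.choice(cfg.n_subtypes, size=n, p=props)
    study_idx = rng.integers(cfg.n_studies, size=n)
    x = (
        centroids[subtype_idx]
        + study_shifts[study_idx]
        + rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_genes))
    )
    return x, subtype_idx, study_idx


def _calibrated_labels(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    x: np.ndarray,
    subtype_idx: np.ndarray,
    betas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    raw = np.einsum("ij,ij->i", x, betas[subtype_idx])

    def excess(b: float) -> float:
        return expit(raw + b).mean() - cfg.poor_prevalence_target

    intercept = brentq(excess, -50.0, 50.0)
    probs = expit(raw + intercept)
    labels = (rng.random(len(probs)) < probs).astype(int)
    return labels, probs, float(intercept)


def _assemble(
    cfg: GeneratorConfig,
    x: np.ndarray,
    labels: np.ndarray,
    probs: np.ndarray,
    subtype_idx: np.ndarray,
    study_idx: np.ndarray,
    signal_genes: np.ndarray,
    betas: np.ndarray,
    intercept: float,
    prefix: str = "S",
) -> ExpressionDataset:
    n = len(labels)
    return ExpressionDataset(
        matrix=x,
        gene_ids=np.array([f"G{j:04d}" for j in range(cfg.n_genes)], dtype=object),
        sample_ids=np.array([f"{prefix}{i:04d}" for i in range(n)], dtype=object),
        labels=labels,
        subtypes=np.array([f"subtype{j}" for j in subtype_idx], dtype=object),
        studies=np.array([f"study{j}" for j in study_idx], dtype=object),
        attrs={
            "true_probs": probs,
            "betas": betas,
            "intercept": intercept,
            "signal_genes": signal_genes,
            "subtype_index": subtype_idx,
            "config": asdict(cfg),
        },
    )


def generate_cohort(cfg: GeneratorConfig = GeneratorConfig()) -> ExpressionDataset:
    """Draw one synthetic cohort; same config (incl. seed) → identical cohort."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    centroids = _simplex_centroids(cfg, rng)
    signal_genes, betas = _signal_structure(cfg, rng)
    study_shifts = rng.normal(0.0, cfg.study_shift_sd, size=(cfg.n_studies, cfg.n_genes))
    x, subtype_idx, study_idx = _draw_expression(
        cfg, rng, centroids, study_shifts, cfg.n_samples
    )
    labels, probs, intercept = _calibrated_labels(cfg, rng, x, subtype_idx, betas)
    return _assemble(
        cfg, x, labels, probs, subtype_idx, study_idx, signal_genes, betas, intercept
    )


def generate_feature_stability_cohort(
    n_samples: int = 300,
    n_genes: int = 300,
    n_subtypes: int = 3,
    n_modules: int = 15,
    genes_per_module: int = 8,
    module_sd: float = 1.0,
    gene_noise_sd: float = 0.6,
    module_effect: float = 1.5,
    effect_decay: float = 8.0,
    centroid_scale: float = 0.65,
    noise_sd: float = 1.0,
    poor_prevalence_target: float = 0.28,
    n_studies: int = 4,
    study_shift_sd: float = 0.3,
    seed: int = 0,
) -> ExpressionDataset:
    """Cohort tailored to split-half feature-stability analysis.

    Three properties of real expression data matter for whether a model's
    top-feature list is reproducible across disjoint patient halves, and this
    generator supplies all of them explicitly:

    * **correlated gene modules** — outcome-relevant genes come in co-expressed
      blocks (a shared module factor plus gene-level noise), so any single
      sparse fit picks an arbitrary member of each module while score vectors
      averaged over many fits spread mass across whole modules;
    * **a decaying effect spectrum** — module effects on the outcome fall off
      exponentially (``module_effect * exp(-j / effect_decay)``), so rankings
      have a well-defined head at every list depth instead of an
      exchangeable plateau;
    * **subtype-reversed effects with no prevalence leak** — module effects
      flip sign between subtypes (weighted to a pooled mean of exactly zero)
      and the log-odds is taken on the deviation from the subtype centroid,
      so the poor-outcome rate is identical across subtypes and pooled
      models cannot substitute subtype membership for real signal.

    ``centroid_scale`` is set so that cross-subtype |PCC| stays below the
    similarity thresholds while within-subtype PCC stays above them, making
    personalized selections subtype-enriched at the thresholds used for
    robustness analysis.
    """
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        n_subtypes=n_subtypes,
        centroid_scale=centroid_scale,
        noise_sd=noise_sd,
        poor_prevalence_target=poor_prevalence_target,
        n_studies=n_studies,
        study_shift_sd=study_shift_sd,
        seed=seed,
    )
    cfg.validate()
    if n_modules * genes_per_module > n_genes:
        raise ValueError("module genes exceed total genes")
    k, g = n_subtypes, n_genes
    # uniform tightness: subtype selectivity at the robustness threshold is
    # governed by centroid_scale alone in this scenario
    centroids = _simplex_centroids(cfg, rng, tightness=np.ones(k))
    genes = rng.choice(g, size=n_modules * genes_per_module, replace=False)
    modules = [
        genes[j * genes_per_module : (j + 1) * genes_per_module]
        for j in range(n_modules)
    ]
    props = cfg.proportions()
    while True:
        signs = rng.choice([-1.0, 1.0], size=(k, n_modules))
        if k == 1 or not (signs == signs[0]).all(axis=0).all():
            break
    centered = signs - props @ signs
    gamma = module_effect * np.exp(-np.arange(n_modules) / effect_decay)

    study_shifts = rng.normal(0.0, study_shift_sd, size=(n_studies, g))
    subtype_idx = rng.choice(k, size=n_samples, p=props)
    study_idx = rng.integers(n_studies, size=n_samples)
    x = (
        centroids[subtype_idx]
        + study_shifts[study_idx]
        + rng.normal(0.0, noise_sd, size=(n_samples, g))
    )
    factors = rng.normal(0.0, module_sd, size=(n_samples, n_modules))
    for j, mod in enumerate(modules):
        x[:, mod] += factors[:, [j]] + rng.normal(
            0.0, gene_noise_sd, size=(n_samples, len(mod))
        )

    # log-odds on module factors (deviation scale): zero mean in every subtype
    raw = np.einsum("ij,ij->i", factors, (gamma * centered)[subtype_idx])
    intercept = brentq(
        lambda b: expit(raw + b).mean() - poor_prevalence_target, -80.0, 80.0
    )
    probs = expit(raw + intercept)
    labels = (rng.random(n_samples) < probs).astype(int)

    betas = np.zeros((k, g))
    for j, mod in enumerate(modules):
        betas[:, mod] = (gamma[j] * centered[:, j])[:, None]
    d = _assemble(
        cfg, x, labels, probs, subtype_idx, study_idx, np.sort(genes), betas, intercept
    )
    d.attrs["modules"] = modules
    return d


def generate_paired_cohorts(
    cfg: GeneratorConfig = GeneratorConfig(),
    platform_shift: PlatformShift = PlatformShift(),
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Two cohorts from one generating process; the second is distorted.

    Both cohorts share centroids, coefficient vectors and calibration; the
    second cohort's expression is passed through the monotone per-gene
    distortion of ``platform_shift`` and loses a random gene subset,
    exercising gene intersection and joint quantile normalization downstream.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    centroids = _simplex_centroids(cfg, rng)
    signal_genes, betas = _signal_structure(cfg, rng)
    study_shifts = rng.normal(0.0, cfg.study_shift_sd, size=(cfg.n_studies, cfg.n_genes))

    cohorts = []
    for prefix in ("A", "B"):
        x, subtype_idx, study_idx = _draw_expression(
            cfg, rng, centroids, study_shifts, cfg.n_samples
        )
        labels, probs, intercept = _calibrated_labels(
            cfg, rng, x, subtype_idx, betas
        )
        cohorts.append(
            _assemble(
                cfg, x, labels, probs, subtype_idx, study_idx,
                signal_genes, betas, intercept, prefix=prefix,
            )
        )
    a, b = cohorts

    if not platform_shift.is_identity():
        lo, hi = platform_shift.gene_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_scale_range must be positive with lo <= hi")
        scale = rng.uniform(lo, hi, size=cfg.n_genes)
        offset = rng.normal(0.0, platform_shift.gene_offset_sd, size=cfg.n_genes)
        xb = scale * b.matrix + offset + platform_shift.cubic_coef * b.matrix**3
        s_lo, s_hi = platform_shift.sample_scale_range
        if s_lo <= 0 or s_hi < s_lo:
            raise ValueError("sample_scale_range must be positive with lo <= hi")
        s_scale = rng.uniform(s_lo, s_hi, size=(cfg.n_samples, 1))
        s_offset = rng.normal(
            0.0, platform_shift.sample_offset_sd, size=(cfg.n_samples, 1)
        )
        xb = s_scale * xb + s_offset
        b = b.with_matrix(xb)
        if platform_shift.dropout_fraction > 0:
            keep = rng.random(cfg.n_genes) >= platform_shift.dropout_fraction
            b = b.subset_genes(np.flatnonzero(keep))
    return a, b
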