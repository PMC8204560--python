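"""Seeded generator of multi-omics survival tables with planted structure.

The generator emulates the shape of a TCGA-style multi-omics input: blocks
of gene-expression / methylation / miRNA features, a survival time and event
column, and optionally a stage-like label. Features are standard normal with
per-subtype mean shifts; event times follow a proportional-hazards model
h(t|x) = h0(t) exp(beta . x) whose baseline is exponential or Weibull, drawn
by inverting the closed-form cumulative hazard; censoring is an independent
exponential time and/or an administrative cutoff. Ground truth (prognostic
feature ids, coefficients, subtype labels) is returned alongside for
calibration and recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tabular_io import OmicsClinicalTable


@dataclass
class GeneratorConfig:
    """Study-design knobs for a synthetic multi-omics survival cohort.

    Defaults describe the cohort used throughout the package's own
    calibration suites: 300 samples, 200 features across three omics blocks,
    5 prognostic features with |beta| = 1 on standardized features, an
    exponential baseline with mean 20 time units and independent exponential
    censoring yielding roughly 30% censored samples.
    """

    n_samples: int = 300
    n_gene: int = 100
    n_methyl: int = 50
    n_mirna: int = 50
    n_prognostic: int = 5
    beta: float | list[float] = 1.0
    baseline: str = "exponential"  # {"exponential", "weibull"}
    baseline_rate: float = 0.05  # exponential rate
    weibull_shape: float = 1.5
    weibull_scale: float = 20.0
    censor_rate: float = 0.02  # exponential censoring rate; 0 disables
    admin_cutoff: float | None = None
    n_subtypes: int = 3
    subtype_shift: float = 1.0
    n_subtype_features: int = 30  # features carrying the subtype mean shift
    block_rho: float = 0.0  # optional exchangeable within-block correlation
    missing_fraction: float = 0.0
    outlier_fraction: float = 0.0
    with_stage_label: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        for name in ("missing_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must lie in [0, 1)")
        if self.n_prognostic > self.n_features:
            raise ParameterError("more prognostic features than features")
        if self.baseline not in ("exponential", "weibull"):
            raise ParameterError(f"unknown baseline family {self.baseline!r}")
        if not (0.0 <= self.block_rho < 1.0):
            raise ParameterError("block_rho must lie in [0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_gene + self.n_methyl + self.n_mirna

    @property
    def beta_vector(self) -> np.ndarray:
        if np.isscalar(self.beta):
            b = np.full(self.n_prognostic, float(self.beta))
            b[1::2] *= -1.0  # alternate sign: protective and hazardous features
            return b
        b = np.asarray(self.beta, dtype=float)
        if b.size != self.n_prognostic:
            raise ParameterError("beta vector length must equal n_prognostic")
        return b


@dataclass
class GroundTruth:
    """What the generator planted, for recovery/calibration tests."""

    prognostic_ids: list[str]
    beta: np.ndarray
    linear_predictor: np.ndarray
    subtype_labels: np.ndarray
    event_times: np.ndarray  # latent, pre-censoring
    censor_times: np.ndarray
    config: GeneratorConfig

    def true_survival(self, t: float) -> np.ndarray:
        """Model survival probability S(t | x) per sample."""
        cfg = self.config
        if cfg.baseline == "exponential":
            H0 = cfg.baseline_rate * t
        else:
            H0 = (t / cfg.weibull_scale) ** cfg.weibull_shape
        return np.exp(-H0 * np.exp(self.linear_predictor))

    def to_json(self, path) -> None:
        obj = {
            "prognostic_ids": self.prognostic_ids,
            "beta": self.beta.tolist(),
            "subtype_labels": self.subtype_labels.tolist(),
            "seed": self.config.seed,
            "n_samples": self.config.n_samples,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _feature_names(cfg: GeneratorConfig) -> tuple[list[str], dict[str, str]]:
    names, blocks = [], {}
    for block, prefix, count in (
        ("gene", "gene_", cfg.n_gene),
        ("methyl", "cg_", cfg.n_methyl),
        ("mirna", "mir_", cfg.n_mirna),
    ):
        for i in range(count):
            nm = f"{prefix}{i:04d}"
            names.append(nm)
            blocks[nm] = block
    return names, blocks


def _inverse_hazard_time(u: np.ndarray, eta: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Draw event times by inverting H(t|x) = H0(t) exp(eta) at -log(u)."""
    target = -np.log(u) / np.exp(eta)
    if cfg.baseline == "exponential":
        return target / cfg.baseline_rate
    return cfg.weibull_scale * target ** (1.0 / cfg.weibull_shape)


def generate(config: GeneratorConfig | None = None, **overrides):
    """Generate an :class:`OmicsClinicalTable` plus its :class:`GroundTruth`.

    Fully reproducible per ``config.seed``. Missing values and outliers are
    injected after survival generation, so the planted coefficients are
    unaffected by them.
    """
    cfg = config or GeneratorConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_features
    names, blocks = _feature_names(cfg)

    X = rng.standard_normal((n, p))
    if cfg.block_rho > 0:
        # exchangeable correlation within each omics block via a shared factor
        offsets = np.cumsum([0, cfg.n_gene, cfg.n_methyl, cfg.n_mirna])
        for b0, b1 in zip(offsets[:-1], offsets[1:]):
            if b1 > b0:
                shared = rng.standard_normal((n, 1))
                X[:, b0:b1] = (
                    np.sqrt(cfg.block_rho) * shared + np.sqrt(1 - cfg.block_rho) * X[:, b0:b1]
                )

    subtypes = rng.integers(0, cfg.n_subtypes, size=n)
    n_shift = min(cfg.n_subtype_features, p)
    if cfg.n_subtypes > 1 and n_shift > 0 and cfg.subtype_shift != 0.0:
        # each subtype shifts a disjoint slice of the shifted feature set
        centers = rng.standard_normal((cfg.n_subtypes, n_shift))
        centers *= cfg.subtype_shift / np.linalg.norm(centers, axis=1, keepdims=True) * np.sqrt(n_shift)
        X[:, :n_shift] += centers[subtypes]

    prog_idx = rng.choice(p, size=cfg.n_prognostic, replace=False)
    beta = cfg.beta_vector
    eta = X[:, prog_idx] @ beta

    u = rng.uniform(size=n)
    t_event = _inverse_hazard_time(u, eta, cfg)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    if cfg.admin_cutoff is not None:
        t_cens = np.minimum(t_cens, cfg.admin_cutoff)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    feats = pd.DataFrame(X, columns=names, index=[f"S{i:04d}" for i in range(n)])
    if cfg.missing_fraction > 0:
        mask = rng.uniform(size=(n, p)) < cfg.missing_fraction
        feats = feats.mask(pd.DataFrame(mask, index=feats.index, columns=feats.columns))
    if cfg.outlier_fraction > 0:
        omask = rng.uniform(size=(n, p)) < cfg.outlier_fraction
        bump = np.sign(rng.standard_normal((n, p))) * rng.uniform(8.0, 15.0, size=(n, p))
        feats = feats.where(
            ~pd.DataFrame(omask, index=feats.index, columns=feats.columns), feats + bump
        )

    labels = None
    if cfg.with_stage_label:
        labels = pd.Series(
            [f"stage_{s + 1}" for s in subtypes], index=feats.index, name="stage"
        )

    table = OmicsClinicalTable(
        features=feats,
        time=pd.Series(time, index=feats.index, name="time"),
        event=pd.Series(event, index=feats.index, name="event"),
        blocks=blocks,
        labels=labels,
    )
    truth = GroundTruth(
        prognostic_ids=[names[i] for i in prog_idx],
        beta=beta,
        linear_predictor=eta,
        subtype_labels=subtypes,
        event_times=t_event,
        censor_times=t_cens,
        config=cfg,
    )
    return table, truth
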