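"""Seeded generators for TPM matrices and qPCR plates with known truth.

Both generators emulate the study design the analysis code targets — a
tissue/stage expression atlas of a flowering plant and a 5-tissue × 3
biological × 3 technical replicate qPCR experiment with three reference
genes — so every pipeline stage can be exercised against known ground
truth without any external download.

Noise models (documented assumptions, see docs/methods.md):

* TPM values get multiplicative log-normal noise — expression is
  non-negative and right-skewed, and the mean-normalized profile
  transform is scale-free, so a multiplicative model is the natural
  perturbation.
* Cq values get additive normal noise on the cycle scale, the
  conventional qPCR error model; a biological offset shared by all
  genes of one (sample, bio rep) cDNA pool models pipetting/input
  variation and cancels in ΔCt by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression_io import ExpressionMatrix
from .qpcr import CqTable

__all__ = [
    "ARCHETYPE_SHAPES",
    "archetype_profile",
    "ModuleSpec",
    "TpmSimConfig",
    "simulate_tpm",
    "PlateSimConfig",
    "simulate_plate",
    "default_plate_config",
    "STUDY_TISSUES",
    "STUDY_REFERENCE_GENES",
    "STUDY_CALIBRATOR",
]

# The qPCR design of the emulated study: five reproductive tissues,
# anther stage 12 as calibrator, three reference genes.
STUDY_TISSUES = [
    "pistil_st11",
    "pistil_st12",
    "anther_st12",
    "pistil_st14",
    "silique_st17",
]
STUDY_CALIBRATOR = "anther_st12"
STUDY_REFERENCE_GENES = {"RCE1": 20.0, "TUA2": 21.0, "YLS8": 22.0}


def _peak(n: int, where: float, width: float = 0.12) -> np.ndarray:
    pos = np.linspace(0.0, 1.0, n)
    return 0.2 + np.exp(-((pos - where) ** 2) / (2.0 * width**2))


# Qualitative profile shapes over an ordered tissue series: fixtures
# mirroring common atlas patterns (a stage-specific peak, monotone
# rise/decline through development, flat housekeeping-like expression).
ARCHETYPE_SHAPES: dict[str, Callable[[int], np.ndarray]] = {
    "flat": lambda n: np.ones(n),
    "increasing": lambda n: np.linspace(0.2, 2.0, n),
    "decreasing": lambda n: np.linspace(2.0, 0.2, n),
    "early-peak": lambda n: _peak(n, 0.1),
    "mid-peak": lambda n: _peak(n, 0.5),
    "stigma-peak": lambda n: _peak(n, 0.9),
}


def archetype_profile(shape: str | Sequence[float], n_samples: int) -> np.ndarray:
    """Resolve a named shape or an explicit positive vector of length n_samples."""
    if isinstance(shape, str):
        if shape not in ARCHETYPE_SHAPES:
            raise ValueError(
                f"unknown archetype shape {shape!r}; "
                f"known: {sorted(ARCHETYPE_SHAPES)}"
            )
        return ARCHETYPE_SHAPES[shape](n_samples)
    arr = np.asarray(shape, dtype=float)
    if arr.shape != (n_samples,):
        raise ValueError(
            f"archetype profile has length {arr.size}, expected {n_samples}"
        )
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("archetype profile values must be finite and > 0")
    return arr


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: genes sharing one archetype profile."""

    size: int
    archetype: str | tuple[float, ...] = "mid-peak"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")


@dataclass(frozen=True)
class TpmSimConfig:
    """Configuration of the synthetic TPM-matrix generator.

    ``noise_sd`` is the standard deviation of the multiplicative noise on
    the natural-log scale; ``background_log_mean``/``background_log_sd``
    parameterize the per-sample log-normal background (scalars or one
    value per sample); ``zero_gene_fraction`` of the genes are identically
    zero across all samples (they carry no profile and are removed by the
    zero-mean filter).
    """

    n_genes: int = 500
    sample_labels: tuple[str, ...] = (
        "flower_st9",
        "flower_st10",
        "flower_st11",
        "flower_st12",
        "carpel_st12",
        "stigma_st13",
        "ovule_st13",
        "anther_st12",
    )
    modules: tuple[ModuleSpec, ...] = ()
    background_log_mean: float | tuple[float, ...] = 1.0
    background_log_sd: float | tuple[float, ...] = 1.0
    noise_sd: float = 0.05
    zero_gene_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.sample_labels) < 2:
            raise ValueError("need at least 2 sample labels")
        if len(set(self.sample_labels)) != len(self.sample_labels):
            raise ValueError("sample labels must be unique")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.zero_gene_fraction < 1:
            raise ValueError("zero_gene_fraction must be in [0, 1)")
        sds = np.atleast_1d(np.asarray(self.background_log_sd, dtype=float))
        if (sds <= 0).any():
            raise ValueError("background_log_sd values must be > 0")
        n_module = sum(m.size for m in self.modules)
        n_zero = round(self.zero_gene_fraction * self.n_genes)
        if n_module + n_zero > self.n_genes:
            raise ValueError(
                f"module sizes ({n_module}) plus zero genes ({n_zero}) "
                f"exceed n_genes ({self.n_genes})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TpmSimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        modules = tuple(
            ModuleSpec(
                size=int(m["size"]),
                archetype=(
                    m["archetype"]
                    if isinstance(m.get("archetype", "mid-peak"), str)
                    else tuple(float(v) for v in m["archetype"])
                ),
            )
            for m in raw.get("modules", [])
        )
        kwargs = {k: v for k, v in raw.items() if k != "modules"}
        if "sample_labels" in kwargs:
            kwargs["sample_labels"] = tuple(kwargs["sample_labels"])
        for key in ("background_log_mean", "background_log_sd"):
            if isinstance(kwargs.get(key), list):
                kwargs[key] = tuple(kwargs[key])
        return cls(modules=modules, **kwargs)


def _per_sample(value: float | tuple[float, ...], n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n, arr[0])
    if arr.size != n:
        raise ValueError(f"expected a scalar or {n} per-sample values, got {arr.size}")
    return arr


def simulate_tpm(config: TpmSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a TPM matrix with planted modules and its truth table.

    Module genes are the module archetype multiplied by a gene-specific
    positive scale (log-normal, sd 1) and perturbed by multiplicative
    log-normal noise of sd ``noise_sd``; background genes are drawn
    independently per sample; a ``zero_gene_fraction`` of genes is set
    identically to zero.  Deterministic given the seed.

    Returns the matrix and a truth table with columns ``gene_id``,
    ``module`` (0-based module index, −1 for background/zero genes) and
    ``is_zero``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    labels = list(config.sample_labels)
    n_s = len(labels)
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n)]

    values = np.zeros((n, n_s))
    module_of = np.full(n, -1)
    row = 0
    for m_idx, mod in enumerate(config.modules):
        arch = archetype_profile(
            mod.archetype if isinstance(mod.archetype, str) else list(mod.archetype),
            n_s,
        )
        for _ in range(mod.size):
            scale = rng.lognormal(mean=2.0, sigma=1.0)
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=n_s))
            values[row] = scale * arch * noise
            module_of[row] = m_idx
            row += 1

    n_zero = round(config.zero_gene_fraction * n)
    n_background = n - row - n_zero
    log_mean = _per_sample(config.background_log_mean, n_s)
    log_sd = _per_sample(config.background_log_sd, n_s)
    for _ in range(n_background):
        values[row] = rng.lognormal(mean=log_mean, sigma=log_sd)
        row += 1
    # remaining n_zero rows stay identically zero

    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=labels)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "module": module_of,
            "is_zero": [i >= n - n_zero for i in range(n)],
        }
    )
    return ExpressionMatrix(df), truth


@dataclass(frozen=True)
class PlateSimConfig:
    """Configuration of the synthetic qPCR-plate generator.

    ``target_folds`` maps each target gene to its true fold change per
    sample relative to the calibrator (the calibrator's fold is 1 by
    definition and is filled in if omitted).  ``cq_noise_sd`` is the
    technical (well-to-well) noise and ``bio_noise_sd`` the biological
    offset shared by all genes of one (sample, bio rep) cDNA pool; both
    in cycles.
    """

    sample_labels: tuple[str, ...] = tuple(STUDY_TISSUES)
    calibrator: str = STUDY_CALIBRATOR
    target_folds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"AGP24": {}}
    )
    target_base_cq: float = 24.0
    reference_base_cq: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_REFERENCE_GENES)
    )
    n_bio: int = 3
    n_tech: int = 3
    cq_noise_sd: float = 0.1
    bio_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibrator not in self.sample_labels:
            raise ValueError(
                f"calibrator {self.calibrator!r} not among sample labels"
            )
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if self.cq_noise_sd < 0 or self.bio_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.reference_base_cq:
            raise ValueError("need at least one reference gene")
        if not self.target_folds:
            raise ValueError("need at least one target gene")
        for gene, folds in self.target_folds.items():
            if gene in self.reference_base_cq:
                raise ValueError(f"{gene!r} is both target and reference")
            cal_fold = folds.get(self.calibrator, 1.0)
            if cal_fold != 1.0:
                raise ValueError(
                    f"calibrator fold for {gene!r} must be 1, got {cal_fold}"
                )
            for s, f in folds.items():
                if s not in self.sample_labels:
                    raise ValueError(f"unknown sample {s!r} in folds for {gene!r}")
                if not f > 0:
                    raise ValueError(f"fold for ({gene!r}, {s!r}) must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateSimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sample_labels" in raw:
            raw["sample_labels"] = tuple(raw["sample_labels"])
        return cls(**raw)


def default_plate_config(seed: int = 0) -> PlateSimConfig:
    """The canonical study-design plate: 5 tissues, 3 refs, 3 bio × 3 tech."""
    folds = {
        s: f
        for s, f in zip(STUDY_TISSUES, (0.25, 0.5, 1.0, 2.0, 4.0))
        if s != STUDY_CALIBRATOR
    }
    return PlateSimConfig(target_folds={"AGP24": folds}, seed=seed)


def simulate_plate(config: PlateSimConfig) -> tuple[CqTable, pd.DataFrame]:
    """Generate a Cq plate with known fold changes and its truth table.

    Cq_target(s, b, t) = base − log2(fold(s)) + bio_offset(s, b) + tech
    noise; reference genes share the same bio_offset(s, b) so plate-wide
    and pool-wide shifts cancel in ΔCt.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    samples = list(config.sample_labels)
    records: list[dict] = []
    truth_rows: list[dict] = []

    bio_offset = {
        (s, b): rng.normal(0.0, config.bio_noise_sd)
        for s in samples
        for b in range(1, config.n_bio + 1)
    }

    for gene, folds in config.target_folds.items():
        for s in samples:
            fold = 1.0 if s == config.calibrator else folds.get(s, 1.0)
            truth_rows.append({"gene": gene, "sample": s, "true_fold": fold})
            for b in range(1, config.n_bio + 1):
                base = config.target_base_cq - np.log2(fold) + bio_offset[(s, b)]
                for t in range(1, config.n_tech + 1):
                    records.append(
                        {
                            "sample": s,
                            "gene": gene,
                            "role": "target",
                            "bio_rep": b,
                            "tech_rep": t,
                            "cq": base + rng.normal(0.0, config.cq_noise_sd),
                        }
                    )
    for gene, base_cq in config.reference_base_cq.items():
        for s in samples:
            for b in range(1, config.n_bio + 1):
                base = base_cq + bio_offset[(s, b)]
                for t in range(1, config.n_tech + 1):
                    records.append(
                        {
                            "sample": s,
                            "gene": gene,
                            "role": "reference",
                            "bio_rep": b,
                            "tech_rep": t,
                            "cq": base + rng.normal(0.0, config.cq_noise_sd),
                        }
                    )

    table = CqTable(pd.DataFrame.from_records(records))
    truth = pd.DataFrame(truth_rows)
    return table, truth
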