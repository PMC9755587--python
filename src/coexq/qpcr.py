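"""qPCR relative quantification: standard-curve QC and 2^-ΔΔCt.

Workflow
--------
1. **Primer efficiency QC.**  A standard curve is fit by ordinary least
   squares to Cq versus log10 template dilution.  The amplification
   efficiency follows from the slope as E = (10^(−1/slope) − 1) × 100 %;
   a slope of −1/log10(2) ≈ −3.32 corresponds to perfect doubling
   (E = 100 %).  A primer pair passes QC when R² > 0.980 and
   90 % ≤ E ≤ 110 %.

2. **Relative quantification.**  Technical replicates are averaged to
   one Cq per (sample, gene, biological replicate).  Per biological
   replicate, ΔCt = Cq_target − mean(Cq of the reference genes); the
   arithmetic mean over reference Cqs is equivalent to normalizing to
   the geometric mean of the reference quantities.  ΔΔCt subtracts the
   calibrator sample's mean ΔCt, and the fold change is 2^(−ΔΔCt).
   Quantification assumes perfect doubling (the literal 2); measured
   efficiencies are used for QC only.  Fold changes are summarized as
   mean ± SEM over biological replicates.

3. **Testing.**  One-way ANOVA followed by Dunnett's comparison of every
   sample against the calibrator, by default on the per-replicate ΔCt
   values (log-scale, variance-stabilized); ``test_on="fold"`` tests the
   fold changes instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dunnett import dunnett_vs_control, significance_label

__all__ = [
    "CqValidationError",
    "CqTable",
    "StandardCurveFit",
    "CurveQC",
    "efficiency_from_slope",
    "fit_standard_curve",
    "fit_standard_curves",
    "qc_standard_curve",
    "aggregate_technical",
    "RelativeQuantification",
    "delta_delta_ct",
    "quantify",
    "R2_MIN",
    "EFFICIENCY_BOUNDS",
]

R2_MIN = 0.980
EFFICIENCY_BOUNDS = (90.0, 110.0)

_CQ_COLUMNS = ["sample", "gene", "role", "bio_rep", "tech_rep", "cq"]


class CqValidationError(ValueError):
    """Raised when a Cq table violates its invariants."""


@dataclass(frozen=True)
class CqTable:
    """Long-format quantification-cycle records with replicate structure.

    ``data`` columns: sample, gene, role ('target' or 'reference'),
    bio_rep, tech_rep, cq.  The canonical design is 5 tissues × 3
    biological × 3 technical replicates with 3 reference genes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _CQ_COLUMNS if c not in df.columns]
        if missing:
            raise CqValidationError(f"missing column(s): {', '.join(missing)}")
        df = df[_CQ_COLUMNS].copy()
        df["cq"] = pd.to_numeric(df["cq"], errors="raise")
        if not np.isfinite(df["cq"]).all() or (df["cq"] <= 0).any():
            bad = df.loc[~np.isfinite(df["cq"]) | (df["cq"] <= 0)].iloc[0]
            raise CqValidationError(
                f"non-positive or non-finite Cq for (sample={bad['sample']}, "
                f"gene={bad['gene']}, bio_rep={bad['bio_rep']}, "
                f"tech_rep={bad['tech_rep']})"
            )
        bad_roles = set(df["role"]) - {"target", "reference"}
        if bad_roles:
            raise CqValidationError(
                f"role(s) must be 'target' or 'reference', got: {sorted(bad_roles)}"
            )
        key = ["sample", "gene", "bio_rep", "tech_rep"]
        dup = df.duplicated(subset=key)
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise CqValidationError(
                "duplicate (sample, gene, bio_rep, tech_rep) record: "
                f"({row['sample']}, {row['gene']}, {row['bio_rep']}, {row['tech_rep']})"
            )
        if not self.reference_genes_of(df):
            raise CqValidationError("the reference gene set must be non-empty")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @staticmethod
    def reference_genes_of(df: pd.DataFrame) -> list[str]:
        return sorted(df.loc[df["role"] == "reference", "gene"].unique())

    @property
    def reference_genes(self) -> list[str]:
        return self.reference_genes_of(self.data)

    @property
    def target_genes(self) -> list[str]:
        return sorted(self.data.loc[self.data["role"] == "target", "gene"].unique())

    @property
    def sample_labels(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "CqTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent: E = (10^(−1/slope) − 1) × 100."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of Cq against log10 dilution for one primer pair."""

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float


def fit_standard_curve(
    log10_dilution: Sequence[float],
    cq: Sequence[float],
    gene_id: str = "",
) -> StandardCurveFit:
    """Fit cq = slope · log10_dilution + intercept by least squares.

    Needs at least three points with at least three distinct dilution
    values (the canonical series is 1:10, 1:100, 1:1000).  R² is the
    squared Pearson correlation of the fit.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size != y.size:
        raise ValueError("dilution and Cq series differ in length")
    if x.size < 3:
        raise ValueError(f"need >= 3 standard-curve points, got {x.size}")
    if len(np.unique(x)) < 3:
        raise ValueError(
            "standard-curve fit is singular: need >= 3 distinct dilution values"
        )
    fit = stats.linregress(x, y)
    return StandardCurveFit(
        gene_id=gene_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_pct=efficiency_from_slope(float(fit.slope)),
    )


@dataclass(frozen=True)
class CurveQC:
    passed: bool
    reasons: tuple[str, ...] = ()


def qc_standard_curve(fit: StandardCurveFit) -> CurveQC:
    """Pass iff R² > 0.980 and 90 ≤ E ≤ 110 (failures list each bound)."""
    lo, hi = EFFICIENCY_BOUNDS
    reasons = []
    if not fit.r_squared > R2_MIN:
        reasons.append(f"R^2 = {fit.r_squared:.4f} not > {R2_MIN}")
    if not lo <= fit.efficiency_pct <= hi:
        reasons.append(
            f"efficiency = {fit.efficiency_pct:.2f}% outside [{lo:g}%, {hi:g}%]"
        )
    return CurveQC(passed=not reasons, reasons=tuple(reasons))


def fit_standard_curves(series: pd.DataFrame) -> list[StandardCurveFit]:
    """Fit one curve per gene from a long table (gene, log10_dilution, cq)."""
    needed = {"gene", "log10_dilution", "cq"}
    if not needed.issubset(series.columns):
        raise ValueError(f"series table needs columns {sorted(needed)}")
    return [
        fit_standard_curve(grp["log10_dilution"], grp["cq"], gene_id=str(gene))
        for gene, grp in series.groupby("gene", sort=False)
    ]


def aggregate_technical(cq_table: CqTable) -> pd.DataFrame:
    """Mean Cq per (sample, gene, bio_rep) with the technical-replicate count."""
    agg = (
        cq_table.data.groupby(["sample", "gene", "role", "bio_rep"], sort=False)["cq"]
        .agg(cq="mean", n_tech="size")
        .reset_index()
    )
    return agg


@dataclass(frozen=True)
class RelativeQuantification:
    """2^-ΔΔCt results for one target gene across samples.

    ``per_rep`` holds one row per (sample, bio_rep) with delta_ct,
    delta_delta_ct and fold; ``summary`` one row per sample with
    mean_fold, sem_fold and (after :func:`quantify`) p_adjusted and
    label.  The calibrator's p_adjusted is undefined (NaN).
    """

    target: str
    calibrator: str
    reference_genes: list[str]
    per_rep: pd.DataFrame
    summary: pd.DataFrame
    anova: dict = field(default_factory=dict)


def delta_delta_ct(
    cq_table: CqTable, target: str, calibrator: str
) -> RelativeQuantification:
    """Per-biological-replicate 2^-ΔΔCt fold changes for ``target``.

    ΔCt(s, b) = Cq_target(s, b) − mean over reference genes of their
    aggregated Cq(s, b); ΔΔCt(s, b) = ΔCt(s, b) − mean_b ΔCt(calibrator, b);
    fold(s, b) = 2^(−ΔΔCt(s, b)).  SEM is the sample standard deviation
    of the per-replicate folds divided by √n_bio.
    """
    refs = cq_table.reference_genes
    if target not in set(cq_table.data["gene"]):
        raise CqValidationError(f"target gene {target!r} not in the Cq table")
    if target in refs:
        raise CqValidationError(f"{target!r} is tagged as a reference gene")

    agg = aggregate_technical(cq_table)
    samples = list(dict.fromkeys(agg["sample"]))
    if calibrator not in samples:
        raise CqValidationError(f"calibrator sample {calibrator!r} not in the table")

    tgt = agg.loc[agg["gene"] == target].set_index(["sample", "bio_rep"])["cq"]
    ref_wide = (
        agg.loc[agg["gene"].isin(refs)]
        .pivot_table(index=["sample", "bio_rep"], columns="gene", values="cq")
    )
    missing_ref = ref_wide.reindex(tgt.index)
    if missing_ref.isna().any().any():
        cell = missing_ref.stack(future_stack=True)
        cell = cell[cell.isna()].index[0]
        raise CqValidationError(
            f"missing reference measurement for (sample={cell[0]}, "
            f"bio_rep={cell[1]}, gene={cell[2]})"
        )
    ref_mean = missing_ref.mean(axis=1)

    per_rep = pd.DataFrame(
        {"cq_target": tgt, "cq_ref_mean": ref_mean}
    ).reset_index()
    per_rep["delta_ct"] = per_rep["cq_target"] - per_rep["cq_ref_mean"]

    cal_rows = per_rep.loc[per_rep["sample"] == calibrator, "delta_ct"]
    if cal_rows.empty:
        raise CqValidationError(
            f"no target measurements for calibrator sample {calibrator!r}"
        )
    dct_cal = cal_rows.mean()
    per_rep["delta_delta_ct"] = per_rep["delta_ct"] - dct_cal
    per_rep["fold"] = 2.0 ** (-per_rep["delta_delta_ct"])

    grouped = per_rep.groupby("sample", sort=False)["fold"]
    summary = grouped.agg(mean_fold="mean", sd="std", n_bio="size").reset_index()
    summary["sem_fold"] = (summary["sd"] / np.sqrt(summary["n_bio"])).fillna(0.0)
    summary = summary.drop(columns="sd")
    summary["p_adjusted"] = np.nan
    summary["label"] = ""

    # preserve the sample order of the input table
    order = {s: i for i, s in enumerate(samples)}
    summary = summary.sort_values("sample", key=lambda s: s.map(order))
    return RelativeQuantification(
        target=target,
        calibrator=calibrator,
        reference_genes=refs,
        per_rep=per_rep,
        summary=summary.reset_index(drop=True),
    )


def quantify(
    cq_table: CqTable,
    target: str,
    calibrator: str,
    alpha: float = 0.05,
    test_on: str = "dct",
) -> RelativeQuantification:
    """Full relative-quantification workflow for one target gene.

    Runs :func:`delta_delta_ct` and then one-way ANOVA with Dunnett's
    comparison of every sample against the calibrator.  ``test_on``
    selects the tested statistic: per-replicate ΔCt values (``"dct"``,
    default) or fold changes (``"fold"``).
    """
    if test_on not in ("dct", "fold"):
        raise ValueError(f"test_on must be 'dct' or 'fold', got {test_on!r}")
    rq = delta_delta_ct(cq_table, target, calibrator)
    column = "delta_ct" if test_on == "dct" else "fold"
    groups = {
        str(s): grp[column].to_numpy()
        for s, grp in rq.per_rep.groupby("sample", sort=False)
    }
    res = dunnett_vs_control(groups, control=calibrator, alpha=alpha)
    pmap = dict(zip(res.comparisons["group"], res.comparisons["p_adjusted"]))
    summary = rq.summary.copy()
    summary["p_adjusted"] = summary["sample"].map(pmap)
    summary["label"] = [
        "" if s == calibrator else significance_label(p)
        for s, p in zip(summary["sample"], summary["p_adjusted"])
    ]
    anova = {
        "f_stat": res.f_stat,
        "df_between": res.df_between,
        "df_within": res.df_within,
        "p_anova": res.p_anova,
        "alpha": alpha,
        "test_on": test_on,
    }
    return RelativeQuantification(
        target=rq.target,
        calibrator=rq.calibrator,
        reference_genes=rq.reference_genes,
        per_rep=rq.per_rep,
        summary=summary,
        anova=anova,
    )
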