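"""Composite scores and linear models for suppression observations.

The cognitive composites are weighted sums of z-standardized task scores,
with weights taken from a two-factor solution over the five tasks
(vocabulary, flanker, working memory, card sort, pattern comparison):
``Control`` loads on flanker, pattern and card sort; ``Working Memory``
loads chiefly on the working-memory task with small cross-loadings. The
loadings are consumed as constants; factor estimation is out of scope.

Three models relate per-trial suppression (delta dB, stimulus minus
baseline; negative = suppression) to subject covariates:

- cognitive:     delta ~ Control + WorkingMemory + Control:WorkingMemory
- group:         delta ~ bilingual + baseline SOAE level (+ optional ear)
- residualized:  residuals(cognitive) ~ bilingual

Observations are trial-level and fitted by ordinary least squares. Because
trials are clustered within subject, naive OLS standard errors are
anticonservative; a cluster-robust option (``se="cluster"``, groups =
subject, t inference at G-1 degrees of freedom) is provided and is the one
used by the package's own calibration checks. The naive variant remains the
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_LOADINGS",
    "ModelFit",
    "zscore",
    "composite_scores",
    "composites_from_tasks",
    "fit_linear_model",
    "cognitive_model",
    "group_model",
    "aoa_within_bilinguals_model",
    "residualized_group_model",
    "correlation_t",
]

#: Factor loadings of the five tasks on the two composites. Only the
#: non-negligible cells of the two-factor solution are present.
DEFAULT_LOADINGS: dict[str, dict[str, float]] = {
    "control": {"flanker": 0.922, "pattern": 0.525, "card_sort": 0.509},
    "working_memory": {
        "working_memory": 0.999,
        "vocabulary": 0.223,
        "card_sort": -0.119,
        "pattern": -0.128,
    },
}

SALIENT_THRESHOLD = 0.3  # |loading| cutoff for the salient-only variant


@dataclass
class ModelFit:
    """An OLS fit: coefficients, inference, residuals, and bookkeeping."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid: np.ndarray
    n: int
    df_resid: float
    description: str
    row_index: pd.Index = field(default_factory=lambda: pd.Index([]))
    conf_int_95: pd.DataFrame | None = None

    def report(self) -> pd.DataFrame:
        """Term-by-term table (beta, SE, t, p) plus n and df."""
        out = pd.DataFrame(
            {"beta": self.params, "se": self.se, "t": self.tvalues,
             "p": self.pvalues}
        )
        out["n"] = self.n
        out["df"] = self.df_resid
        return out


def zscore(values, name: str = "task") -> np.ndarray:
    """Z-standardize across subjects: mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"z-scoring {name!r} needs at least 2 subjects")
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"task {name!r} has zero variance; cannot z-score")
    return (x - np.mean(x)) / sd


def _active_loadings(loadings: dict | None, salient_only: bool) -> dict:
    loadings = loadings if loadings is not None else DEFAULT_LOADINGS
    if not salient_only:
        return loadings
    return {
        comp: {task: w for task, w in weights.items()
               if abs(w) >= SALIENT_THRESHOLD}
        for comp, weights in loadings.items()
    }


def composite_scores(
    z_table: pd.DataFrame,
    loadings: dict | None = None,
    salient_only: bool = False,
) -> pd.DataFrame:
    """Loading-weighted sums of z-scored tasks, per subject.

    ``z_table`` holds one z-scored column per task, indexed by subject.
    Returns a frame with one column per composite. The operation is linear
    in the z-scores.
    """
    loadings = _active_loadings(loadings, salient_only)
    out = {}
    for comp, weights in loadings.items():
        missing = sorted(set(weights) - set(z_table.columns))
        if missing:
            raise ValueError(f"composite {comp!r} needs task scores {missing}")
        cols = z_table[list(weights)]
        if cols.isna().any().any():
            bad = z_table.index[cols.isna().any(axis=1)].tolist()
            raise ValueError(f"missing task scores for subjects {bad}")
        out[comp] = sum(w * z_table[task] for task, w in weights.items())
    return pd.DataFrame(out, index=z_table.index)


def composites_from_tasks(
    tasks: pd.DataFrame,
    loadings: dict | None = None,
    salient_only: bool = False,
) -> pd.DataFrame:
    """Z-score raw task columns across subjects, then form the composites."""
    z = pd.DataFrame(
        {col: zscore(tasks[col].to_numpy(), name=col) for col in tasks.columns},
        index=tasks.index,
    )
    return composite_scores(z, loadings, salient_only)


def fit_linear_model(
    y,
    design: pd.DataFrame,
    add_intercept: bool = True,
    cluster_groups=None,
    description: str = "",
) -> ModelFit:
    """Ordinary least squares with t-based two-sided inference.

    With ``cluster_groups`` given, standard errors are cluster-robust and
    p-values use a t distribution with (number of clusters - 1) degrees of
    freedom. Raises on rank-deficient designs, naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    X = design.astype(float).copy()
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    if y.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more observations ({y.shape[0]}) than terms ({X.shape[1]})"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"design is rank deficient; check columns {list(X.columns)} "
            "for collinearity"
        )
    model = sm.OLS(y, X)
    if cluster_groups is not None:
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": np.asarray(cluster_groups)},
            use_t=True,
        )
        df_resid = float(res.df_resid_inference)
    else:
        res = model.fit()
        df_resid = float(res.df_resid)
    row_index = design.index if isinstance(design.index, pd.Index) else pd.Index([])
    return ModelFit(
        params=res.params,
        se=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        resid=np.asarray(res.resid),
        n=int(res.nobs),
        df_resid=df_resid,
        description=description,
        row_index=row_index,
        conf_int_95=res.conf_int(alpha=0.05).rename(columns={0: "lo", 1: "hi"}),
    )


def _join_measurements(measurements: pd.DataFrame, subject_table: pd.DataFrame,
                       columns: list[str]) -> pd.DataFrame:
    """Join per-trial rows to per-subject covariates; drop flagged rows."""
    rows = measurements[measurements["missing_reason"].fillna("") == ""].copy()
    rows = rows.dropna(subset=["delta_db"])
    joined = rows.merge(subject_table[["subject_id"] + columns],
                        on="subject_id", how="left", validate="many_to_one")
    unmatched = joined[joined[columns[0]].isna()]["subject_id"].unique().tolist()
    if unmatched:
        raise ValueError(f"no covariates for subjects {unmatched}")
    return joined


def _aggregate_by_subject(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse usable trial rows to one mean-delta row per subject.

    Subject-mean regression targets the same coefficients as the trial-level
    fit (covariates are subject-level) with classical t inference that is
    well calibrated at small cohort sizes, where cluster-robust trial-level
    standard errors undercover.
    """
    rows = measurements[measurements["missing_reason"].fillna("") == ""]
    rows = rows.dropna(subset=["delta_db"])
    agg = rows.groupby("subject_id", as_index=False).agg(
        delta_db=("delta_db", "mean"),
        baseline_level_db=("baseline_level_db", "mean"),
        soae_frequency_hz=("soae_frequency_hz", "first"),
    )
    agg["missing_reason"] = ""
    return agg


def cognitive_model(
    measurements: pd.DataFrame,
    composites: pd.DataFrame,
    se: str = "ols",
    aggregate: str = "trial",
) -> ModelFit:
    """Per-trial delta ~ Control + WorkingMemory + their interaction.

    ``aggregate="subject"`` fits the same design to per-subject mean deltas
    with classical OLS inference instead of trial-level rows.
    """
    if aggregate == "subject":
        measurements = _aggregate_by_subject(measurements)
        se = "ols"
    comp = composites.reset_index()
    if "subject_id" not in comp.columns:
        comp = comp.rename(columns={comp.columns[0]: "subject_id"})
    data = _join_measurements(measurements, comp, ["control", "working_memory"])
    design = pd.DataFrame(
        {
            "control": data["control"],
            "working_memory": data["working_memory"],
            "control:working_memory": data["control"] * data["working_memory"],
        },
        index=data.index,
    )
    groups = data["subject_id"] if se == "cluster" else None
    return fit_linear_model(
        data["delta_db"], design, cluster_groups=groups,
        description="delta_db ~ control * working_memory (trial-level OLS)",
    )


def _bilingual_indicator(metadata: pd.DataFrame) -> pd.Series:
    if metadata["group"].nunique() < 2:
        raise ValueError("group model needs at least two language groups")
    return metadata["group"].isin(["early_bi", "late_bi"]).astype(float)


def group_model(
    measurements: pd.DataFrame,
    metadata: pd.DataFrame,
    include_ear: bool = False,
    se: str = "ols",
    aggregate: str = "trial",
) -> ModelFit:
    """Per-trial delta ~ bilingual + baseline SOAE level (+ optional ear).

    The baseline-level covariate is the subject-level mean baseline level of
    each emission (one value per subject x SOAE), not the per-trial reading.
    ``aggregate="subject"`` fits per-subject mean deltas with classical OLS.
    """
    if aggregate == "subject":
        measurements = _aggregate_by_subject(measurements)
        se = "ols"
    meta = metadata.copy()
    meta["bilingual"] = _bilingual_indicator(meta)
    cols = ["bilingual"] + (["test_ear"] if include_ear else [])
    data = _join_measurements(measurements, meta, cols)
    soae_level = (
        measurements.groupby(["subject_id", "soae_frequency_hz"])["baseline_level_db"]
        .mean()
        .rename("soae_baseline_level")
    )
    data = data.join(soae_level, on=["subject_id", "soae_frequency_hz"])
    design = pd.DataFrame(
        {"bilingual": data["bilingual"],
         "baseline_level": data["soae_baseline_level"]},
        index=data.index,
    )
    if include_ear:
        design["ear_right"] = (data["test_ear"] == "right").astype(float)
    groups = data["subject_id"] if se == "cluster" else None
    return fit_linear_model(
        data["delta_db"], design, cluster_groups=groups,
        description="delta_db ~ bilingual + baseline_level"
        + (" + ear" if include_ear else "") + " (trial-level OLS)",
    )


def aoa_within_bilinguals_model(
    measurements: pd.DataFrame,
    metadata: pd.DataFrame,
    se: str = "ols",
) -> ModelFit:
    """Within bilinguals: per-trial delta ~ age of English acquisition."""
    bi = metadata[metadata["group"].isin(["early_bi", "late_bi"])]
    if bi.empty:
        raise ValueError("no bilingual subjects in metadata")
    rows = measurements[measurements["subject_id"].isin(bi["subject_id"])]
    data = _join_measurements(rows, bi, ["english_aoa"])
    design = pd.DataFrame({"english_aoa": data["english_aoa"]}, index=data.index)
    groups = data["subject_id"] if se == "cluster" else None
    return fit_linear_model(
        data["delta_db"], design, cluster_groups=groups,
        description="delta_db ~ english_aoa (bilinguals only, trial-level OLS)",
    )


def residualized_group_model(
    cognitive_fit: ModelFit,
    measurements: pd.DataFrame,
    metadata: pd.DataFrame,
    se: str = "ols",
) -> ModelFit:
    """Residuals of the cognitive model regressed on language group.

    Assesses the group effect left after accounting for the cognitive
    composites.
    """
    rows = measurements.loc[cognitive_fit.row_index]
    if len(rows) != cognitive_fit.resid.shape[0]:
        raise ValueError(
            "cognitive fit residuals are not aligned to the measurement rows"
        )
    meta = metadata.copy()
    meta["bilingual"] = _bilingual_indicator(meta)
    data = rows[["subject_id"]].merge(meta[["subject_id", "bilingual"]],
                                      on="subject_id", how="left")
    design = pd.DataFrame({"bilingual": data["bilingual"].to_numpy()})
    groups = data["subject_id"] if se == "cluster" else None
    return fit_linear_model(
        cognitive_fit.resid, design, cluster_groups=groups,
        description="resid(cognitive) ~ bilingual (trial-level OLS)",
    )


def correlation_t(r: float, n: int) -> tuple[float, int]:
    """t statistic and degrees of freedom for a Pearson correlation.

    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with ``df = n - 2``.
    """
    if not abs(r) < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return t, n - 2
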