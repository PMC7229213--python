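"""Cross-validation orchestration, accuracy statistics and diagnostics.

Prediction accuracy is the Pearson correlation between measured fresh
weight and the predicted growth value on held-out accessions, aggregated
over repeated k-fold cross-validation (3 folds x 50 repeats by default, 150
evaluations).  Pipelines are callables ``(train_ids, test_ids) -> {accession:
prediction}``; factories for the classical-GS, netGS and cross-environment
netGS pipelines are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, NetgsError, ValidationError
from .gs import GenotypeMatrix, fit_flux_models, fit_rrblup, predict_gebv
from .model import MetabolicModel, RatioConstraints
from .projection import predict_growth
from .transfer import ExchangeRatioSet, project_cross_env


@dataclass
class CVPlan:
    """Reproducible fold assignments for repeated k-fold cross-validation."""

    n_folds: int
    n_repeats: int
    seed: int
    fold_assignments: pd.DataFrame  # repeats x accessions, values in 0..n_folds-1

    def folds(self, repeat: int):
        """Yield (train_ids, test_ids) for each fold of one repeat."""
        row = self.fold_assignments.iloc[repeat]
        for f in range(self.n_folds):
            test = list(row.index[row == f])
            train = list(row.index[row != f])
            yield train, test

    def evaluations(self):
        for rep in range(self.n_repeats):
            for fold, (train, test) in enumerate(self.folds(rep)):
                yield rep, fold, train, test


@dataclass
class AccuracyRecord:
    """Per-evaluation Pearson accuracies of one prediction method."""

    method: str
    r_values: np.ndarray          # NaN where an evaluation was degenerate
    detail: pd.DataFrame = None   # repeat, fold, r

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.r_values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.r_values, ddof=1))

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.r_values)))


def make_cv_plan(
    accessions: list[str], n_folds: int = 3, n_repeats: int = 50, seed: int = 0
) -> CVPlan:
    """Balanced fold assignments by shuffled round-robin, reproducible by seed."""
    n = len(accessions)
    if n_folds > n:
        raise ValidationError(f"cannot make {n_folds} folds from {n} accessions")
    rng = np.random.default_rng(seed)
    rows = []
    base = np.arange(n) % n_folds
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        assign[perm] = base
        rows.append(assign)
    return CVPlan(
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
        fold_assignments=pd.DataFrame(rows, columns=list(accessions)),
    )


def run_cv(plan: CVPlan, pipeline, observed: pd.Series, method: str = "pipeline") -> AccuracyRecord:
    """Run a prediction pipeline over every CV evaluation and score it.

    ``observed`` maps accession to the measured trait.  Degenerate
    evaluations (constant predictions or fewer than three scored
    accessions) are recorded as missing.
    """
    rows = []
    for rep, fold, train, test in plan.evaluations():
        preds = pipeline(train, test)
        obs, pred = [], []
        for acc in test:
            p = preds.get(acc, np.nan)
            if np.isfinite(p):
                obs.append(float(observed.loc[acc]))
                pred.append(float(p))
        try:
            r = pearson(np.array(obs), np.array(pred))
        except (DegenerateInputError, ValidationError):
            warnings.warn(
                f"{method}: degenerate evaluation (repeat {rep}, fold {fold})", stacklevel=2
            )
            r = np.nan
        rows.append({"repeat": rep, "fold": fold, "r": r})
    detail = pd.DataFrame(rows)
    return AccuracyRecord(method=method, r_values=detail["r"].to_numpy(), detail=detail)


# ----------------------------------------------------------------------
# Pipelines
# ----------------------------------------------------------------------

def classical_gs_pipeline(G: GenotypeMatrix, phenotype: pd.Series, covariates=None):
    """Classical GS: rrBLUP directly on the measured trait."""
    cov_df = (
        pd.DataFrame(covariates, index=G.accession_ids) if covariates is not None else None
    )

    def pipeline(train_ids, test_ids):
        Gtr = G.subset(train_ids)
        ytr = phenotype.loc[train_ids].to_numpy(float)
        ctr = cov_df.loc[train_ids].to_numpy() if cov_df is not None else None
        cte = cov_df.loc[test_ids].to_numpy() if cov_df is not None else None
        model = fit_rrblup(Gtr, ytr, covariates=ctr, trait_id="fresh_weight")
        preds = predict_gebv(model, G.subset(test_ids), covariates=cte)
        return dict(zip(test_ids, preds))

    return pipeline


def netgs_pipeline(
    G: GenotypeMatrix,
    flux_matrix: pd.DataFrame,
    model_by_accession,
    ratios: RatioConstraints | None = None,
    retained: set[str] | None = None,
    covariates=None,
):
    """netGS: per-reaction rrBLUP on estimated fluxes, then steady-state projection.

    ``model_by_accession`` is ``accession -> MetabolicModel`` (a dict or a
    callable); passing the same reference model for every accession
    reproduces the reference-biomass-only ablation.  ``retained`` optionally
    restricts the projection to reactions whose flux models passed an
    accuracy threshold.
    """
    getter = model_by_accession if callable(model_by_accession) else model_by_accession.__getitem__
    cov_df = (
        pd.DataFrame(covariates, index=G.accession_ids) if covariates is not None else None
    )

    def pipeline(train_ids, test_ids):
        Gtr = G.subset(train_ids)
        ctr = cov_df.loc[train_ids].to_numpy() if cov_df is not None else None
        cte = cov_df.loc[test_ids].to_numpy() if cov_df is not None else None
        models = fit_flux_models(Gtr, flux_matrix.loc[train_ids], covariates=ctr)
        return predict_growth(
            models,
            G.subset(test_ids),
            {acc: getter(acc) for acc in test_ids},
            retained=retained,
            ratios=ratios,
            covariates=cte,
        )

    return pipeline


def netgs_cross_env_pipeline(
    G: GenotypeMatrix,
    flux_matrix_E1: pd.DataFrame,
    model_by_accession_E1,
    xr: ExchangeRatioSet,
    ratios: RatioConstraints | None = None,
    retained: set[str] | None = None,
):
    """Cross-environment netGS: E1-trained flux models, E2 exchange-ratio bands."""
    getter = (
        model_by_accession_E1
        if callable(model_by_accession_E1)
        else model_by_accession_E1.__getitem__
    )

    def pipeline(train_ids, test_ids):
        Gtr = G.subset(train_ids)
        models = fit_flux_models(Gtr, flux_matrix_E1.loc[train_ids])
        use = set(models.models) if retained is None else set(retained) & set(models.models)
        # exchange reactions in P always carry their GEBV, independent of selection
        use |= set(xr.P) & set(models.models)
        Gte = G.subset(test_ids)
        gebv_table = {rid: predict_gebv(models.models[rid], Gte) for rid in sorted(use)}
        out = {}
        for i, acc in enumerate(test_ids):
            gebv = {rid: float(v[i]) for rid, v in gebv_table.items()}
            try:
                res = project_cross_env(getter(acc), gebv, xr, ratios)
                out[acc] = res.growth_gebv
            except NetgsError as exc:
                warnings.warn(f"cross-env projection failed for {acc}: {exc}", stacklevel=2)
                out[acc] = np.nan
        return out

    return pipeline


# ----------------------------------------------------------------------
# Statistics
# ----------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("vectors must have equal length")
    if len(x) < 3:
        raise DegenerateInputError("need at least three pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on the differences a - b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b):
        raise ValidationError("paired vectors must have equal length")
    if len(a) < 3:
        raise DegenerateInputError("need at least three pairs")
    if np.std(a - b) == 0:
        raise DegenerateInputError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def mantel(
    D1: np.ndarray, D2: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Mantel correlation between two similarity/distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the p-value
    comes from jointly permuting rows and columns of the second matrix.
    """
    D1, D2 = np.asarray(D1, float), np.asarray(D2, float)
    if D1.shape != D2.shape or D1.ndim != 2 or D1.shape[0] != D1.shape[1]:
        raise ValidationError("matrices must be square and of equal shape")
    for name, D in (("first", D1), ("second", D2)):
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValidationError(f"{name} matrix is not symmetric")
    n = D1.shape[0]
    if n < 4:
        raise ValidationError("need at least four observations")
    iu = np.triu_indices(n, k=1)
    r_obs = pearson(D1[iu], D2[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = pearson(D1[iu], D2[np.ix_(perm, perm)][iu])
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def flux_cv(flux_matrix: pd.DataFrame, zero_mean_tol: float = 1e-9) -> pd.Series:
    """Per-reaction coefficient of variation sd/|mean| across accessions.

    Reactions whose mean flux is ~0 get NaN (CV undefined) rather than a
    spurious large value.
    """
    mean = flux_matrix.mean(axis=0)
    sd = flux_matrix.std(axis=0, ddof=1)
    cv = sd / mean.abs()
    cv[mean.abs() <= zero_mean_tol] = np.nan
    return cv


def vmax_check(
    flux_matrix: pd.DataFrame,
    vmax: pd.DataFrame,
    reaction_to_enzyme: dict[str, str],
) -> pd.DataFrame:
    """Flag fluxes exceeding the accession-specific enzyme V_max.

    ``vmax`` is accessions x enzymes (positive rates); reactions without an
    enzyme mapping are skipped with a warning.  Returns the violation table
    (accession, reaction, flux, vmax).
    """
    if (vmax.to_numpy() <= 0).any():
        raise ValidationError("V_max values must be positive")
    rows = []
    skipped = []
    for rid in flux_matrix.columns:
        enzyme = reaction_to_enzyme.get(rid)
        if enzyme is None or enzyme not in vmax.columns:
            skipped.append(rid)
            continue
        for acc in flux_matrix.index:
            flux = float(flux_matrix.loc[acc, rid])
            limit = float(vmax.loc[acc, enzyme])
            if abs(flux) > limit:
                rows.append({"accession": acc, "reaction": rid, "flux": flux, "vmax": limit})
    if skipped:
        warnings.warn(f"no enzyme mapping for {len(skipped)} reactions; skipped", stacklevel=2)
    return pd.DataFrame(rows, columns=["accession", "reaction", "flux", "vmax"])
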