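"""Genotype preparation and rrBLUP mixed models for quantitative traits.

The statistical model is ridge-regression BLUP:

    y = X b + Z u + e,   u ~ N(0, sigma_u^2 I_p),   e ~ N(0, sigma_e^2 I_n)

with ``Z`` the column-centered dosage matrix and ``X`` an intercept plus
optional covariates (e.g. genotype principal components).  The variance
ratio ``lambda = sigma_e^2 / sigma_u^2`` is estimated by restricted maximum
likelihood, profiled through a single eigendecomposition of the marker
cross-product ``Z Z'`` restricted to the orthogonal complement of ``X``
(exact and fast in the n << p regime typical of breeding panels).  Marker
effects follow as ``u = Z' (Z Z' + lambda I)^-1 (y - X b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DegenerateInputError, ValidationError


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with ids and marker classes."""

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    marker_class: list[str] | None = None  # per-marker: enzymatic / genome_wide

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        na, nm = self.dosages.shape
        if len(self.accession_ids) != na or len(self.marker_ids) != nm:
            raise ValidationError("dosage matrix shape does not match id lists")
        for name, ids in (("accession", self.accession_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")
        if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
            raise ValidationError("dosages must lie in [0, 2]")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset(self, accessions: list[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [pos[a] for a in accessions]
        return GenotypeMatrix(
            list(accessions), list(self.marker_ids), self.dosages[idx],
            marker_class=self.marker_class,
        )

    def row(self, accession: str) -> np.ndarray:
        return self.dosages[self.accession_ids.index(accession)]


@dataclass
class FluxModel:
    """A fitted rrBLUP model for one trait (a reaction flux or fresh weight)."""

    intercept: float
    marker_effects: np.ndarray
    marker_ids: list[str]
    marker_means: np.ndarray
    variance_components: tuple[float, float]  # (sigma2_marker, sigma2_residual)
    trait_id: str = "trait"
    covariate_effects: np.ndarray | None = None
    cv_accuracy: float | None = None

    def __post_init__(self):
        self.marker_effects = np.asarray(self.marker_effects, float)
        if not np.all(np.isfinite(self.marker_effects)):
            raise ValidationError(f"non-finite marker effects for trait {self.trait_id!r}")
        if self.cv_accuracy is not None and not -1.0 <= self.cv_accuracy <= 1.0 + 1e-12:
            raise ValidationError("cv_accuracy must lie in [-1, 1]")


@dataclass
class FluxModelSet:
    """One rrBLUP model per reaction with non-zero reference flux."""

    models: dict[str, FluxModel]
    training_fold: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # reaction -> reason
    constants: dict[str, float] = field(default_factory=dict)  # zero-variance fluxes

    def reaction_ids(self) -> list[str]:
        return list(self.models)

    def accuracies(self) -> dict[str, float]:
        return {
            rid: m.cv_accuracy for rid, m in self.models.items() if m.cv_accuracy is not None
        }


# ----------------------------------------------------------------------
# Genotype preparation
# ----------------------------------------------------------------------

def prepare_genotypes(
    raw: pd.DataFrame,
    maf_threshold: float = 0.05,
    class_filter: str | None = None,
    marker_classes: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Impute, MAF-filter and optionally class-restrict a raw dosage table.

    ``raw`` is accessions x markers with values in [0, 2]; missing entries
    are mean-imputed per marker.  Markers with minor allele frequency below
    ``maf_threshold`` and constant columns are removed.  ``class_filter``
    restricts to markers of one class (e.g. ``"enzymatic"``) using the
    ``marker_classes`` map.
    """
    table = raw.copy().astype(float)
    if table.isna().any().any():
        n_missing = int(table.isna().sum().sum())
        warnings.warn(f"mean-imputing {n_missing} missing genotype calls", stacklevel=2)
        table = table.fillna(table.mean(axis=0))
    if class_filter is not None:
        if marker_classes is None:
            raise ValidationError("class_filter requires a marker_classes map")
        keep = [m for m in table.columns if marker_classes.get(m) == class_filter]
        table = table[keep]
    freq = table.to_numpy().mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    variable = table.to_numpy().std(axis=0) > 0
    mask = (maf >= maf_threshold) & variable
    table = table.loc[:, mask]
    if table.shape[1] == 0:
        raise ValidationError("no markers left after MAF filtering")
    classes = (
        [marker_classes.get(m, "genome_wide") for m in table.columns]
        if marker_classes
        else None
    )
    return GenotypeMatrix(
        [str(a) for a in table.index],
        [str(m) for m in table.columns],
        table.to_numpy(),
        marker_class=classes,
    )


def compute_pcs(G: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal-component scores of the column-centered dosage matrix."""
    if k >= G.n_accessions:
        raise ValidationError(f"k={k} must be smaller than the {G.n_accessions} accessions")
    from sklearn.decomposition import PCA

    return PCA(n_components=k, svd_solver="full").fit_transform(
        G.dosages - G.dosages.mean(axis=0)
    )


# ----------------------------------------------------------------------
# Mixed model
# ----------------------------------------------------------------------

def _reml_lambda(xi: np.ndarray, eta2: np.ndarray, nq: int) -> float:
    """Profile-REML estimate of lambda = sigma_e^2 / sigma_u^2."""

    def neg_restricted_ll(log_lam):
        lam = np.exp(log_lam)
        d = xi + lam
        return nq * np.log(np.sum(eta2 / d)) + np.sum(np.log(d))

    res = minimize_scalar(neg_restricted_ll, bounds=(-20.0, 20.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


def fit_rrblup(
    G: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    trait_id: str = "trait",
    lam: float | None = None,
) -> FluxModel:
    """Fit the rrBLUP mixed model for one trait.

    ``lam`` fixes the variance ratio instead of estimating it by REML (used
    for closed-form cross-checks).
    """
    y = np.asarray(y, float)
    n = G.n_accessions
    if len(y) != n:
        raise ValidationError("trait vector length does not match accessions")
    if np.std(y) == 0:
        raise DegenerateInputError(f"trait {trait_id!r} has zero variance")
    means = G.dosages.mean(axis=0)
    Z = G.dosages - means
    X = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            raise ValidationError("covariate rows do not match accessions")
        X = np.hstack([X, covariates])
    q = X.shape[1]
    K = Z @ Z.T
    # orthonormal basis of the complement of col(X)
    Q, _ = np.linalg.qr(X, mode="complete")
    U0 = Q[:, q:]
    K2 = U0.T @ K @ U0
    y2 = U0.T @ y
    xi, V = np.linalg.eigh(K2)
    xi = np.maximum(xi, 0.0)
    eta = V.T @ y2
    if lam is None:
        lam = _reml_lambda(xi, eta**2, n - q)
    sigma2_u = float(np.sum(eta**2 / (xi + lam)) / (n - q))
    sigma2_e = float(lam * sigma2_u)
    Vinv = np.linalg.inv(K + lam * np.eye(n))
    XtVinv = X.T @ Vinv
    beta = np.linalg.solve(XtVinv @ X, XtVinv @ y)
    u = Z.T @ (Vinv @ (y - X @ beta))
    return FluxModel(
        intercept=float(beta[0]),
        marker_effects=u,
        marker_ids=list(G.marker_ids),
        marker_means=means,
        variance_components=(sigma2_u, sigma2_e),
        trait_id=trait_id,
        covariate_effects=beta[1:] if q > 1 else None,
    )


def predict_gebv(
    model: FluxModel, G: GenotypeMatrix, covariates: np.ndarray | None = None
) -> np.ndarray:
    """GEBVs ``mu + C b + Z u`` for the accessions of ``G`` (aligned by marker id)."""
    missing = [m for m in model.marker_ids if m not in G.marker_ids]
    if missing:
        raise ValidationError(f"genotype matrix lacks markers: {missing[:5]}"
                              + ("..." if len(missing) > 5 else ""))
    pos = {m: i for i, m in enumerate(G.marker_ids)}
    idx = [pos[m] for m in model.marker_ids]
    Z = G.dosages[:, idx] - model.marker_means
    yhat = model.intercept + Z @ model.marker_effects
    if model.covariate_effects is not None:
        if covariates is None:
            raise ValidationError(f"model {model.trait_id!r} was fit with covariates")
        yhat = yhat + np.atleast_2d(covariates) @ model.covariate_effects
    return yhat


def fit_flux_models(
    G: GenotypeMatrix,
    flux_matrix: pd.DataFrame,
    covariates: np.ndarray | None = None,
    cv_folds: list[tuple[list[str], list[str]]] | None = None,
) -> FluxModelSet:
    """One rrBLUP fit per reaction column of an accessions x reactions table.

    Zero-variance columns are recorded as constants (their flux is fully
    determined by stoichiometry) and excluded from modeling.  When
    ``cv_folds`` (train-ids/test-ids pairs) are supplied, each model also
    records its cross-validated Pearson accuracy.
    """
    flux_matrix = flux_matrix.loc[G.accession_ids]
    models: dict[str, FluxModel] = {}
    dropped: dict[str, str] = {}
    constants: dict[str, float] = {}
    for rid in flux_matrix.columns:
        y = flux_matrix[rid].to_numpy(float)
        if np.std(y) < 1e-12:
            constants[rid] = float(y.mean())
            continue
        try:
            model = fit_rrblup(G, y, covariates=covariates, trait_id=str(rid))
        except (DegenerateInputError, ValidationError) as exc:
            dropped[str(rid)] = str(exc)
            continue
        if cv_folds:
            model.cv_accuracy = _cv_accuracy(G, y, covariates, cv_folds)
        models[str(rid)] = model
    if constants:
        warnings.warn(
            f"{len(constants)} flux columns are constant and passed through as constants",
            stacklevel=2,
        )
    return FluxModelSet(
        models=models, training_fold=list(G.accession_ids),
        dropped=dropped, constants=constants,
    )


def save_model_set(models: FluxModelSet, path) -> None:
    """Serialize a model set: one effects table (TSV) plus JSON metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if models.models:
        any_model = next(iter(models.models.values()))
        effects = pd.DataFrame(
            {rid: m.marker_effects for rid, m in models.models.items()},
            index=any_model.marker_ids,
        )
        effects.index.name = "marker"
        effects.to_csv(path / "effects.tsv", sep="\t")
        pd.DataFrame(
            {rid: m.marker_means for rid, m in models.models.items()},
            index=any_model.marker_ids,
        ).to_csv(path / "marker_means.tsv", sep="\t")
    meta = {
        "training_fold": models.training_fold,
        "dropped": models.dropped,
        "constants": models.constants,
        "models": {
            rid: {
                "intercept": m.intercept,
                "variance_components": list(m.variance_components),
                "cv_accuracy": m.cv_accuracy,
                "covariate_effects": None
                if m.covariate_effects is None
                else list(map(float, m.covariate_effects)),
            }
            for rid, m in models.models.items()
        },
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_model_set(path) -> FluxModelSet:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    models: dict[str, FluxModel] = {}
    if meta["models"]:
        effects = pd.read_csv(path / "effects.tsv", sep="\t", index_col=0)
        means = pd.read_csv(path / "marker_means.tsv", sep="\t", index_col=0)
        for rid, info in meta["models"].items():
            models[rid] = FluxModel(
                intercept=info["intercept"],
                marker_effects=effects[rid].to_numpy(),
                marker_ids=[str(m) for m in effects.index],
                marker_means=means[rid].to_numpy(),
                variance_components=tuple(info["variance_components"]),
                trait_id=rid,
                covariate_effects=None
                if info["covariate_effects"] is None
                else np.asarray(info["covariate_effects"]),
                cv_accuracy=info["cv_accuracy"],
            )
    return FluxModelSet(
        models=models,
        training_fold=meta["training_fold"],
        dropped=meta["dropped"],
        constants=meta["constants"],
    )


def _cv_accuracy(G, y, covariates, folds) -> float:
    """Mean Pearson r between held-out trait values and their GEBVs."""
    rs = []
    y_ser = pd.Series(y, index=G.accession_ids)
    for train_ids, test_ids in folds:
        Gtr, Gte = G.subset(train_ids), G.subset(test_ids)
        ytr = y_ser.loc[train_ids].to_numpy()
        if np.std(ytr) < 1e-12:
            continue
        cov_tr = cov_te = None
        if covariates is not None:
            cov = pd.DataFrame(covariates, index=G.accession_ids)
            cov_tr, cov_te = cov.loc[train_ids].to_numpy(), cov.loc[test_ids].to_numpy()
        m = fit_rrblup(Gtr, ytr, covariates=cov_tr)
        pred = predict_gebv(m, Gte, covariates=cov_te)
        obs = y_ser.loc[test_ids].to_numpy()
        if np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
            continue
        rs.append(float(np.corrcoef(obs, pred)[0, 1]))
    return float(np.mean(rs)) if rs else np.nan
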