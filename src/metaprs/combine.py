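"""Meta-combination: candidate selection, elasticnet CV, and weight collapse.

The meta-score is built in two steps.  Step 1 picks, for every GWAS-like
source, the candidate weight vector whose PC-adjusted, standardized score
maximizes the logistic-regression AUC for combined prevalent+incident case
status (adjusting for age and sex).  Step 2 combines the K selected
component scores with elasticnet-penalized logistic regression, scanning
mixing parameters alpha over {0, 0.1, 0.25, 0.5, 0.75, 0.9, 1} and a
log-spaced lambda path with 10-fold cross-validation, choosing the
(alpha, lambda) pair with the greatest mean out-of-fold AUC.  The fitted
combination is finally collapsed to a single per-SNP weight table:

    w_i = sum_j (beta_j / sigma_j) * gamma_{i,j}

where gamma_{.,j} are component j's per-SNP weights and sigma_j its
training-cohort score SD.  The division by sigma_j is required because the
elasticnet consumed *standardized* scores; a ``literal`` mode omits it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .elasticnet import enet_logistic_fit, enet_logistic_path, lambda_max
from .exceptions import ContractError
from .scoring import (
    GenotypeMatrix,
    ScoreVector,
    VariantWeightTable,
    adjust_for_pcs,
    compute_prs,
    harmonize,
    standardize,
)

DEFAULT_ALPHAS = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)


# ---------------------------------------------------------------------------
# Panels and fits
# ---------------------------------------------------------------------------


@dataclass
class ComponentPanel:
    """K component scores over a training cohort plus collapse bookkeeping."""

    component_ids: list[str]
    scores: pd.DataFrame  # samples x K, PC-adjusted (raw scale)
    training_sd: pd.Series  # sigma_j
    training_mean: pd.Series
    weight_tables: dict[str, VariantWeightTable]
    pc_projection: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.component_ids) < 1:
            raise ContractError("ComponentPanel requires K >= 1 components")
        if (self.training_sd <= 0).any():
            raise ContractError("non-positive training SD in panel")

    @property
    def k(self) -> int:
        return len(self.component_ids)

    def standardized_scores(self) -> pd.DataFrame:
        return (self.scores - self.training_mean) / self.training_sd


@dataclass
class MetaFit:
    """Selected elasticnet combination of component scores."""

    alpha: float
    lambda_: float
    beta: pd.Series  # per component, on the standardized-score scale
    covariate_coefficients: pd.Series
    intercept: float
    cv_grid: pd.DataFrame  # columns: alpha, lambda, mean_auc
    seed: int
    n_folds: int

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "beta": self.beta.to_dict(),
            "covariate_coefficients": self.covariate_coefficients.to_dict(),
            "intercept": self.intercept,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "cv_grid": self.cv_grid.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MetaFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alpha=d["alpha"],
            lambda_=d["lambda"],
            beta=pd.Series(d["beta"]),
            covariate_coefficients=pd.Series(d["covariate_coefficients"]),
            intercept=d["intercept"],
            cv_grid=pd.DataFrame(d["cv_grid"]),
            seed=d["seed"],
            n_folds=d["n_folds"],
        )


# ---------------------------------------------------------------------------
# Step 1: candidate selection
# ---------------------------------------------------------------------------


def _prepare_candidate_score(
    table: VariantWeightTable,
    geno: GenotypeMatrix,
    pcs: np.ndarray | None,
) -> ScoreVector:
    harm, _ = harmonize(table, geno)
    score = compute_prs(geno, harm)
    if pcs is not None and pcs.shape[1] > 0:
        score = adjust_for_pcs(score, pcs)
    return standardize(score)


def select_candidate(
    candidates: list[VariantWeightTable],
    geno: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    pcs: np.ndarray | None = None,
) -> tuple[VariantWeightTable, pd.DataFrame]:
    """Pick the candidate table maximizing logistic AUC for case status.

    Each candidate's score is PC-adjusted and standardized, then entered in
    a logistic regression with the covariates (age, sex); the AUC of the
    fitted linear predictor is the selection statistic.  Ties break toward
    the earlier candidate.  Candidates that cannot be scored (e.g. an empty
    table after thresholding) get AUC NaN; if all fail, a hard error.
    """
    if len(candidates) == 0:
        raise ContractError("select_candidate: no candidates")
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ContractError("select_candidate: outcome is constant")
    cov = (
        covariates.to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(y), 0))
    )

    aucs = []
    for tab in candidates:
        try:
            score = _prepare_candidate_score(tab, geno, pcs)
            X = np.column_stack([score.values, cov])
            lr = LogisticRegression(C=np.inf, max_iter=1000)
            lr.fit(X, y)
            lp = X @ lr.coef_.ravel()
            aucs.append(roc_auc_score(y, lp))
        except Exception:
            aucs.append(np.nan)
    report = pd.DataFrame(
        {
            "candidate": [t.metadata.get("name", f"candidate{i}") for i, t in enumerate(candidates)],
            "auc": aucs,
        }
    )
    if report["auc"].isna().all():
        raise ContractError("select_candidate: all candidates failed to score")
    best = int(np.nanargmax(np.asarray(aucs, dtype=float)))
    return candidates[best], report


def build_panel(
    chosen: dict[str, VariantWeightTable],
    geno: GenotypeMatrix,
    pcs: np.ndarray | None = None,
) -> ComponentPanel:
    """Score the chosen per-source tables on the training cohort and record
    the PC projections, means and SDs needed for collapse and replay."""
    ids, cols, sds, means, thetas = [], {}, {}, {}, {}
    for cid, tab in chosen.items():
        harm, _ = harmonize(tab, geno)
        score = compute_prs(geno, harm)
        if pcs is not None and pcs.shape[1] > 0:
            score = adjust_for_pcs(score, pcs)
            thetas[cid] = score.pc_theta_
        std = standardize(score)
        ids.append(cid)
        cols[cid] = score.values
        sds[cid] = std.sd_
        means[cid] = std.mean_
    return ComponentPanel(
        component_ids=ids,
        scores=pd.DataFrame(cols),
        training_sd=pd.Series(sds),
        training_mean=pd.Series(means),
        weight_tables=dict(chosen),
        pc_projection=thetas,
    )


# ---------------------------------------------------------------------------
# Step 2: elasticnet cross-validation
# ---------------------------------------------------------------------------


def fit_elasticnet_cv(
    panel: ComponentPanel,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> MetaFit:
    """CV scan over (alpha, lambda); refit the arg-max pair on all samples.

    The lambda path for each alpha is computed once on the full training
    data and shared across folds (glmnet style).  Mean out-of-fold AUC of
    the full linear predictor (components + covariates) is the model-
    selection statistic; ties break toward the larger lambda (sparser fit).
    Covariates are never penalized.
    """
    y = np.asarray(outcome, dtype=float)
    Z = panel.standardized_scores().to_numpy()
    cov_names = list(covariates.columns) if covariates is not None else []
    C = (
        covariates.to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(y), 0))
    )
    X = np.column_stack([Z, C])
    if not np.all(np.isfinite(X)):
        raise ContractError("non-finite predictor values")
    pf = np.r_[np.ones(panel.k), np.zeros(C.shape[1])]

    folds = list(
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X, y)
    )

    rows = []
    for alpha in alphas:
        lmax = lambda_max(X, y, alpha, pf)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
        fold_auc = np.zeros((n_folds, n_lambda))
        for f, (tr, te) in enumerate(folds):
            path = enet_logistic_path(X[tr], y[tr], alpha, pf, lambdas=lambdas)
            lp = X[te] @ path.coefs.T + path.intercepts  # (n_te, n_lambda)
            for k in range(n_lambda):
                fold_auc[f, k] = roc_auc_score(y[te], lp[:, k])
        mean_auc = fold_auc.mean(axis=0)
        for k in range(n_lambda):
            rows.append((alpha, float(lambdas[k]), float(mean_auc[k])))

    grid = pd.DataFrame(rows, columns=["alpha", "lambda", "mean_auc"])
    # arg-max mean AUC; ties toward larger lambda (grid is stored lambda-
    # descending per alpha, so the first maximum within an alpha is sparser)
    best = grid.sort_values(
        ["mean_auc", "lambda"], ascending=[False, False], kind="stable"
    ).iloc[0]
    alpha_star, lambda_star = float(best["alpha"]), float(best["lambda"])

    beta_full, b0 = enet_logistic_fit(X, y, alpha_star, lambda_star, pf)
    return MetaFit(
        alpha=alpha_star,
        lambda_=lambda_star,
        beta=pd.Series(beta_full[: panel.k], index=panel.component_ids),
        covariate_coefficients=pd.Series(beta_full[panel.k :], index=cov_names),
        intercept=float(b0),
        cv_grid=grid,
        seed=seed,
        n_folds=n_folds,
    )


# ---------------------------------------------------------------------------
# Collapse
# ---------------------------------------------------------------------------


def collapse_weights(
    panel: ComponentPanel, fit: MetaFit, literal: bool = False
) -> VariantWeightTable:
    """Collapse the elasticnet combination into one per-SNP weight table.

    Default: ``w_i = sum_j (beta_j / sigma_j) gamma_{i,j}`` over the union of
    component supports (absent entries contribute 0).  ``literal=True``
    reproduces the plain weighted sum ``sum_j beta_j gamma_{i,j}`` without
    the training-SD rescaling, for comparison.  Covariate coefficients and
    the intercept are cohort-level terms and are dropped.  The collapsed
    score equals the fitted linear combination of standardized component
    scores up to an additive constant (exactly so when PC adjustment is
    disabled).
    """
    missing = [cid for cid in panel.component_ids if cid not in fit.beta.index]
    if missing:
        raise ContractError(f"fit has no coefficient for component(s): {missing}")

    parts = []
    for cid in panel.component_ids:
        b = float(fit.beta[cid])
        sigma = float(panel.training_sd[cid])
        scale = b if literal else b / sigma
        if scale == 0.0:
            continue
        part = panel.weight_tables[cid].df[
            ["variant_id", "chr", "pos", "effect_allele", "other_allele", "weight"]
        ].copy()
        part["weight"] = part["weight"].to_numpy() * scale
        parts.append(part)
    if not parts:
        raise ContractError("collapse produced an empty table (all beta_j == 0?)")

    allv = pd.concat(parts, ignore_index=True)
    # canonical orientation per variant: first occurrence; same-pair entries
    # in the opposite orientation contribute with flipped sign
    canon = allv.drop_duplicates("variant_id").set_index("variant_id")
    ea = canon["effect_allele"].reindex(allv["variant_id"]).to_numpy()
    oa = canon["other_allele"].reindex(allv["variant_id"]).to_numpy()
    direct = allv["effect_allele"].to_numpy() == ea
    swapped = (allv["effect_allele"].to_numpy() == oa) & (
        allv["other_allele"].to_numpy() == ea
    )
    if not np.all(direct | swapped):
        bad = allv.loc[~(direct | swapped), "variant_id"].iloc[0]
        raise ContractError(f"inconsistent alleles for {bad!r} across components")
    if np.any(direct & (allv["other_allele"].to_numpy() != oa)):
        bad = allv.loc[direct & (allv["other_allele"].to_numpy() != oa), "variant_id"].iloc[0]
        raise ContractError(f"inconsistent alleles for {bad!r} across components")
    signed = np.where(direct, allv["weight"].to_numpy(), -allv["weight"].to_numpy())
    summed = pd.Series(signed).groupby(allv["variant_id"].to_numpy()).sum()

    df = canon.reset_index()[["variant_id", "chr", "pos", "effect_allele", "other_allele"]]
    df["weight"] = summed.reindex(df["variant_id"]).to_numpy()
    df = df.sort_values(["chr", "pos"], kind="stable")
    return VariantWeightTable(
        df=df.reset_index(drop=True),
        metadata={
            "name": "metaPRS_collapsed",
            "collapse_mode": "literal" if literal else "sd_scaled",
            "components": list(panel.component_ids),
            "beta": {c: float(fit.beta[c]) for c in panel.component_ids},
            "sigma": {c: float(panel.training_sd[c]) for c in panel.component_ids},
            "alpha": fit.alpha,
            "lambda": fit.lambda_,
        },
    )
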