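"""End-to-end runner: simulate -> score -> tune -> combine -> collapse -> evaluate.

Pure dataflow through the output directory: each stage reads its inputs,
writes its outputs, and never mutates another stage's files.  The manifest
records versions, seeds, and SHA-256 checksums of every artifact so a rerun
with the same configuration can be verified bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .clinical import absolute_risk_10yr, categorical_nri, compare_screening
from .combine import build_panel, collapse_weights, fit_elasticnet_cv, select_candidate
from .config import PipelineConfig
from .exceptions import MetaPRSError
from .metrics import cox_association, delta_cindex, logistic_association
from ._cox import cox_newton
from .scoring import (
    GenotypeMatrix,
    adjust_for_pcs,
    compute_prs,
    harmonize,
    read_score_file,
    standardize,
    write_score_file,
)
from .simulate import (
    pc_columns,
    simulate_architecture,
    simulate_candidate_weights,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)


class StageError(MetaPRSError):
    def __init__(self, stage: str, code: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed [{code}]: {cause}")
        self.stage = stage
        self.code = code


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _cohort_splits(n: int, split, seed: int):
    rng = np.random.default_rng([seed, 100])
    perm = rng.permutation(n)
    n_tune = int(round(split.tune_frac * n))
    n_train = int(round(split.train_frac * n))
    return (
        np.sort(perm[:n_tune]),
        np.sort(perm[n_tune : n_tune + n_train]),
        np.sort(perm[n_tune + n_train :]),
    )


def _subset_geno(geno: GenotypeMatrix, idx: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        sample_ids=geno.sample_ids[idx],
        variants=geno.variants.copy(),
        dosages=geno.dosages[idx],
    )


def _meta_score(geno, table, pcs):
    harm, rep = harmonize(table, geno)
    score = compute_prs(geno, harm)
    if pcs is not None and pcs.shape[1] > 0:
        score = adjust_for_pcs(score, pcs)
    return standardize(score), rep


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full study flow; returns (and writes) the run manifest."""
    cfg.validate()
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "sim_seed": cfg.simulate.seed,
        "stages": {},
        "outputs": {},
    }

    # ---- stage: simulate ---------------------------------------------------
    try:
        if cfg.genotypes_path:
            geno = GenotypeMatrix.from_dosage_tsv(cfg.genotypes_path)
            cohort = pd.read_csv(cfg.cohort_path, sep="\t")
            sources = [[read_score_file(p)] for p in cfg.weight_table_paths]
        else:
            sim = cfg.simulate
            geno = simulate_genotypes(sim)
            arch = simulate_architecture(sim, geno)
            sources = simulate_candidate_weights(sim, arch, geno)
            cohort = simulate_phenotypes(geno, arch, sim)
            geno.to_dosage_tsv(os.path.join(out, "genotypes.tsv"))
            cohort.to_csv(os.path.join(out, "cohort.tsv"), sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "n_samples": geno.n_samples,
            "n_variants": geno.n_variants,
            "n_sources": len(sources),
        }
    except Exception as exc:
        raise StageError("simulate", "E_SIM", exc) from exc

    pcs_all = cohort[pc_columns(cohort)].to_numpy(dtype=float)
    y_all = ((cohort["prevalent"] == 1) | (cohort["event"] == 1)).to_numpy(int)
    covs_all = cohort[["age", "sex"]]

    tune_idx, train_idx, test_idx = _cohort_splits(geno.n_samples, cfg.split, cfg.seed)

    # ---- stage: tune (per-source candidate selection) ----------------------
    try:
        g_tune = _subset_geno(geno, tune_idx)
        chosen = {}
        tuning_reports = {}
        for s, cands in enumerate(sources):
            tab, report = select_candidate(
                cands,
                g_tune,
                y_all[tune_idx],
                covariates=covs_all.iloc[tune_idx],
                pcs=pcs_all[tune_idx],
            )
            cid = f"source{s}"
            chosen[cid] = tab
            tuning_reports[cid] = report.to_dict(orient="list")
        manifest["stages"]["tune"] = {
            "chosen": {c: t.metadata.get("name") for c, t in chosen.items()}
        }
    except Exception as exc:
        raise StageError("tune", "E_TUNE", exc) from exc

    # ---- stage: combine (elasticnet CV on training split) ------------------
    try:
        g_train = _subset_geno(geno, train_idx)
        panel = build_panel(chosen, g_train, pcs=pcs_all[train_idx])
        fit = fit_elasticnet_cv(
            panel,
            y_all[train_idx],
            covariates=covs_all.iloc[train_idx].reset_index(drop=True),
            alphas=cfg.meta.alphas,
            n_folds=cfg.meta.n_folds,
            seed=cfg.seed + 1,
            n_lambda=cfg.meta.n_lambda,
            lambda_min_ratio=cfg.meta.lambda_min_ratio,
        )
        fit.to_json(os.path.join(out, "metafit.json"))
        manifest["stages"]["combine"] = {
            "alpha": fit.alpha,
            "lambda": fit.lambda_,
            "n_nonzero": int((fit.beta != 0).sum()),
        }
    except Exception as exc:
        raise StageError("combine", "E_COMBINE", exc) from exc

    # ---- stage: collapse ----------------------------------------------------
    try:
        collapsed = collapse_weights(panel, fit, literal=cfg.meta.collapse_mode == "literal")
        write_score_file(collapsed, os.path.join(out, "metaprs_weights.txt"))
        manifest["stages"]["collapse"] = {"n_variants": collapsed.n_variants}
    except Exception as exc:
        raise StageError("collapse", "E_COLLAPSE", exc) from exc

    # ---- stage: evaluate (held-out test split) ------------------------------
    try:
        g_test = _subset_geno(geno, test_idx)
        co = cohort.iloc[test_idx].reset_index(drop=True)
        meta_score, _ = _meta_score(g_test, collapsed, pcs_all[test_idx])

        prevalent = co["prevalent"].to_numpy(int)
        logit_res = logistic_association(
            meta_score, prevalent, co[["age", "sex"]],
            n_boot=cfg.evaluate.n_boot_auc, seed=cfg.seed + 2,
        )

        inc = co[co["prevalent"] == 0].reset_index(drop=True)
        inc_score = meta_score.values[co["prevalent"].to_numpy() == 0]
        cox_res = cox_association(
            inc_score, inc["time"].to_numpy(), inc["event"].to_numpy(),
            inc[["age", "sex"]],
        )

        evaluation = {
            "prevalent_or_per_sd": logit_res.effect,
            "prevalent_or_ci": [logit_res.ci_low, logit_res.ci_high],
            "prevalent_auc": logit_res.discrimination,
            "prevalent_auc_ci": list(logit_res.discrimination_ci),
            "incident_hr_per_sd": cox_res.effect,
            "incident_hr_ci": [cox_res.ci_low, cox_res.ci_high],
            "incident_cindex": cox_res.discrimination,
            "incident_cindex_ci": list(cox_res.discrimination_ci),
        }

        # clinical integration on the incident (non-prevalent) test samples
        ev = cfg.evaluate
        t_inc = inc["time"].to_numpy()
        e_inc = inc["event"].to_numpy(bool)
        clin = np.clip(inc["clinical_risk"].to_numpy(), 1e-12, 1 - 1e-12)
        logit_clin = np.log(clin / (1 - clin))
        biom = inc["biomarker"].to_numpy()
        prs = inc_score

        def risk_of(Xcols):
            X = np.column_stack(Xcols)
            f = cox_newton(X, t_inc, e_inc)
            return absolute_risk_10yr(
                X @ f.beta, t_inc, e_inc, horizon=ev.horizon
            ).risk10

        risk_a = risk_of([logit_clin])  # stage-1 clinical model
        risk_a_prs = risk_of([logit_clin, prs])
        risk_c = risk_of([logit_clin, biom])  # biomarker-informed model
        risk_c_prs = risk_of([logit_clin, biom, prs])

        case10 = (e_inc & (t_inc <= ev.horizon)).astype(int)
        dc = delta_cindex(
            np.column_stack([logit_clin]),
            np.column_stack([logit_clin, prs]),
            t_inc, e_inc,
            n_boot=ev.n_boot_delta, seed=cfg.seed + 3,
        )
        nri = categorical_nri(
            risk_a, risk_a_prs, case10, ev.nri_threshold,
            n_boot=ev.n_boot_nri, seed=cfg.seed + 4,
        )
        screen = compare_screening(
            risk_a, risk_c, risk_a_prs, risk_c_prs,
            ev.stage1_threshold, ev.stage2_threshold, case10,
            n_boot=ev.n_boot_screen, seed=cfg.seed + 5,
        )
        evaluation.update(
            {
                "delta_cindex": dc.delta,
                "delta_cindex_ci": list(dc.ci),
                "delta_cindex_p": dc.p_value,
                "nri_case_pct": nri.case_nri_pct,
                "nri_noncase_pct": nri.noncase_nri_pct,
                "nns_base": screen.base.nns,
                "nns_augmented": screen.augmented.nns,
                "delta_nns": screen.delta_nns,
                "nnt_base": screen.base.nnt,
                "nnt_augmented": screen.augmented.nnt,
                "delta_nnt": screen.delta_nnt,
            }
        )
        with open(os.path.join(out, "evaluation.json"), "w") as fh:
            json.dump(evaluation, fh, indent=1, sort_keys=True)
        manifest["stages"]["evaluate"] = evaluation
    except Exception as exc:
        raise StageError("evaluate", "E_EVAL", exc) from exc

    for name in sorted(os.listdir(out)):
        p = os.path.join(out, name)
        if os.path.isfile(p) and name != "manifest.json":
            manifest["outputs"][name] = _sha256(p)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
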