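"""End-to-end study orchestration.

``run_study`` executes the whole pipeline in memory: simulate (or accept)
a cohort, integrate platforms by Spearman filtering on training samples,
split train/test, select the penalty by repeated two-fold cross-validated
CPE, extract the sparse signature, and evaluate it on the withheld
cohort. ``run_pipeline`` wraps it for the CLI and writes every artifact
(integrated matrix, CV trace, signature, strata, report) with the
materialized configuration and its hash.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .integration import FeatureMatrix, IntegratedDataset, IntegrationConfig, SpearmanIntegrator
from .model_selection import CoxLassoCV, train_test_split
from .prognosis import PredictionReport, Signature, evaluate
from .ranking import FeatureRanking, rank_features
from .simulate import SimConfig, SimulatedCohort, default_causal_features, simulate_cohort
from .survival import SurvivalOutcome

__all__ = ["StudyResult", "run_study", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    cohort: SimulatedCohort | None
    integrated: IntegratedDataset
    split: np.ndarray
    model: CoxLassoCV
    signature: Signature
    report: PredictionReport
    ranking: FeatureRanking


def _sim_config_from_run(config: RunConfig, null_signal: bool = False) -> SimConfig:
    causal = (
        []
        if null_signal
        else default_causal_features(config.n_genes, config.n_mirnas,
                                     config.n_causal, config.causal_effect)
    )
    return SimConfig(
        n_samples=config.n_samples, n_genes=config.n_genes,
        n_mirnas=config.n_mirnas, causal_features=causal,
        rho_cna=config.rho_cna, rho_meth=config.rho_meth,
        rho_mirna=config.rho_mirna, baseline_scale=config.baseline_scale,
        censor_target=config.censor_target, seed=config.seed,
    )


def run_study(config: RunConfig, cohort: SimulatedCohort | None = None,
              platforms: dict | None = None, outcomes: SurvivalOutcome | None = None,
              pairing: pd.DataFrame | None = None,
              null_signal: bool = False) -> StudyResult:
    """Execute simulate-or-load -> integrate -> split -> CV-fit ->
    signature -> evaluate and return all intermediate objects."""
    if platforms is None:
        if cohort is None:
            cohort = simulate_cohort(_sim_config_from_run(config, null_signal))
            logger.info("simulated cohort: %d samples, %d genes, %d miRNAs",
                        config.n_samples, config.n_genes, config.n_mirnas)
        platforms = {p: FeatureMatrix(df, p) for p, df in cohort.platforms.items()}
        outcomes = cohort.outcomes
        pairing = cohort.pairing
    if outcomes is None:
        raise ValueError("outcomes are required when platforms are supplied directly")

    sample_ids = list(platforms["mRNA"].values.index)
    split = train_test_split(sample_ids, config.train_fraction,
                             seed=config.seed + 1, outcome=outcomes,
                             stratify_events=config.stratify_events)
    train_mask = split == "train"

    integ_cfg = IntegrationConfig(
        cutoff_cna=config.cutoff_cna, cutoff_meth=config.cutoff_meth,
        cutoff_mirna=config.cutoff_mirna, sign_policy=config.sign_policy,
        max_missing=config.max_missing,
    )
    integrator = SpearmanIntegrator(integ_cfg)
    integrated = integrator.fit_transform(platforms, outcomes, pairing, train_mask)
    logger.info("integrated feature space: %d features (%s)",
                integrated.features.shape[1],
                integrated.features.columns.get_level_values(0).value_counts().to_dict())

    X = integrated.features
    X_train, X_test = X.loc[train_mask], X.loc[~train_mask]
    y_train = outcomes.subset(train_mask)
    y_test = outcomes.subset(~train_mask)

    model = CoxLassoCV(
        lambda2=config.lambda2, n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio, cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats, random_state=config.seed + 2,
    )
    model.fit(X_train, y_train)
    signature = Signature.from_cv_model(model)
    logger.info("selected lambda=%.4g with %d signature features",
                model.lambda_, len(signature))

    report = evaluate(signature, X_train, y_train, X_test, y_test,
                      baseline=model.baseline_)
    if len(signature):
        ranking = rank_features(X[list(signature.features)], outcomes,
                                config.rank_low_q, config.rank_high_q)
    else:
        ranking = FeatureRanking(table=pd.DataFrame(
            columns=["feature", "low_threshold", "high_threshold", "chi2", "p", "rank"]
        ))
    return StudyResult(cohort=cohort, integrated=integrated, split=split,
                       model=model, signature=signature, report=report,
                       ranking=ranking)


def run_pipeline(config: RunConfig, out_dir) -> PredictionReport:
    """Run the study end-to-end and write all artifacts under ``out_dir``."""
    from .io import write_clinical, write_feature_matrix, write_pairing, write_report, write_signature
    from .io import ClinicalTable

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    result = run_study(config)

    config.to_yaml(out / "run_config.yaml")
    if result.cohort is not None:
        for platform, fm in result.cohort.platforms.items():
            write_feature_matrix(FeatureMatrix(fm, platform), out / f"{platform}.tsv",
                                 config_hash=chash)
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": result.cohort.sample_ids,
            "time_months": result.cohort.outcomes.time,
            "event": result.cohort.outcomes.event,
        }))
        write_clinical(clin, out / "clinical.tsv", config_hash=chash)
        write_pairing(result.cohort.pairing, out / "mirna_pairing.tsv", config_hash=chash)

    integ = result.integrated.features.copy()
    integ.columns = [f"{p}:{f}" for p, f in integ.columns]
    with open(out / "integrated_matrix.tsv", "w") as fh:
        fh.write(f"# omicox config_hash={chash}\n")
        integ.T.rename_axis("feature_id").to_csv(fh, sep="\t")
    with open(out / "retention_report.tsv", "w") as fh:
        fh.write(f"# omicox config_hash={chash}\n")
        result.integrated.retention.to_csv(fh, sep="\t", index=False)

    cvres = result.model.cv_result_
    nz = (result.model.path_model_.coef_path_ != 0).sum(axis=1)
    cv_trace = pd.DataFrame({"lambda": cvres.lambdas, "mean_cv_cpe": cvres.mean_cpe,
                             "sd_cv_cpe": cvres.sd_cpe, "n_nonzero": nz})
    with open(out / "cv_trace.tsv", "w") as fh:
        fh.write(f"# omicox config_hash={chash}\n")
        cv_trace.to_csv(fh, sep="\t", index=False)

    write_signature(result.signature, out / "signature.tsv", config_hash=chash)
    with open(out / "ranking.tsv", "w") as fh:
        fh.write(f"# omicox config_hash={chash}\n")
        result.ranking.table.to_csv(fh, sep="\t", index=False)
    with open(out / "per_patient.tsv", "w") as fh:
        fh.write(f"# omicox config_hash={chash}\n")
        result.report.median_times.to_csv(fh, sep="\t", index=False)
    write_report(result.report, out / "report.json", config=config.to_dict(),
                 config_hash=chash)
    return result.report
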