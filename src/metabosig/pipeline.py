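"""End-to-end run orchestration with a provenance log.

Stage order for one tissue dataset: weight normalization (tissue only) ->
LOQ filter with chi-squared rescue -> censored-value imputation -> PCA
outlier screen (flagged samples removed, downstream stages run on the
reduced matrix) -> univariate statistics and indicator ratios -> stability
selection -> over-representation analysis.  Every decision (removed
metabolites, imputed cells, flagged samples, failed rounds) lands in the
provenance log, and all analytical outputs are reproducible from config +
seed.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .decomposition import flag_outliers, pca
from .enrichment import demo_pathways, load_pathways, ora, select_input_list
from .indicators import builtin_catalog, evaluate, load_definitions
from .qc import filter_by_loq, impute_censored, normalize_by_weight, standardize
from .quant import VALID, read_quant_matrix
from .simulate import MetaboliteCatalog
from .stability import StabilitySelection
from .univariate import volcano_table


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    matrix_path: str
    loq_path: str
    samples_path: str
    output_dir: str
    catalog_path: str | None = None
    pathways_path: str | None = None
    indicators_path: str | None = None
    loq_threshold: float = 0.30
    loq_alpha: float = 0.05
    pca_components: int = 2
    outlier_z: float = 4.0
    n_iterations: int = 30
    train_fraction: float = 0.70
    exclude_quantile: float = 0.25
    majority: float = 0.5
    min_selection_count: int = 3
    shap_permutations: int = 50
    boruta_max_iter: int = 100
    boruta_perc: float = 100.0
    boruta_alpha: float = 0.05
    seed: int = 0
    timestamps: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


class ProvenanceLog:
    """Append-only record of pipeline decisions."""

    def __init__(self, timestamps: bool = True) -> None:
        self.events: list[dict] = []
        self.timestamps = timestamps

    def log(self, stage: str, **info) -> None:
        event = {"stage": stage, **info}
        if self.timestamps:
            event["time"] = datetime.now(timezone.utc).isoformat()
        self.events.append(event)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.events, indent=1))


def _digest(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a dict of result objects and
    writes every stage output under ``config.output_dir``.

    On a stage failure the partial outputs and the provenance log written so
    far are preserved and the exception propagates."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = ProvenanceLog(timestamps=config.timestamps)
    log.log("start", version=__version__, seed=config.seed)
    try:
        return _run_pipeline(config, out, log)
    except Exception as exc:
        log.log("error", message=str(exc))
        raise
    finally:
        log.write(out / "provenance.json")


def _run_pipeline(config: RunConfig, out: Path, log: ProvenanceLog) -> dict:
    log.log(
        "inputs",
        matrix=_digest(config.matrix_path),
        loq=_digest(config.loq_path),
        samples=_digest(config.samples_path),
    )
    matrix = read_quant_matrix(config.matrix_path, config.loq_path, config.samples_path)
    log.log("load", n_samples=matrix.n_samples, n_metabolites=matrix.n_metabolites)

    if (matrix.samples["tissue"] != "plasma").any():
        matrix = normalize_by_weight(matrix)
        log.log("normalize_by_weight", applied=True)

    matrix, report = filter_by_loq(
        matrix, threshold=config.loq_threshold, alpha=config.loq_alpha
    )
    report.to_tsv(out / "filter_report.tsv")
    (out / "filter_summary.json").write_text(json.dumps(report.summary(), indent=1))
    for met in report.removed:
        log.log("filter_by_loq", metabolite=met, decision="removed")
    for met in report.rescued:
        log.log("filter_by_loq", metabolite=met, decision="retained_by_rescue")
    log.log("filter_by_loq_summary", **report.summary())

    n_censored = int((matrix.status != VALID).to_numpy().sum())
    matrix = impute_censored(matrix)
    log.log("impute_censored", rule="below->LLOQ/2, above->ULOQ", n_cells=n_censored)

    # PCA screen on the standardized full matrix
    z, scaler = standardize(matrix)
    for col in scaler.dropped:
        log.log("standardize", column=col, action="dropped_zero_variance")
    k = min(config.pca_components, z.shape[0] - 1, z.shape[1])
    result = pca(z, k=max(k, 1))
    result.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    result.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", index_label="metabolite_id")
    flags = flag_outliers(result, k=max(k, 1), z_threshold=config.outlier_z)
    outliers = list(flags.index[flags["outlier"]])
    for sid in outliers:
        log.log(
            "flag_outliers", sample=sid,
            robust_z=float(flags.loc[sid, "robust_z"]), action="removed",
        )
    if outliers:
        keep = [s for s in matrix.sample_ids if s not in set(outliers)]
        matrix = matrix.subset_samples(keep)
        log.log("outlier_removal", n_removed=len(outliers), n_remaining=len(keep))

    catalog = (
        MetaboliteCatalog.from_json(config.catalog_path)
        if config.catalog_path
        else None
    )
    defs = (
        load_definitions(config.indicators_path)
        if config.indicators_path
        else builtin_catalog()
    )
    indicator_values = evaluate(matrix, defs, catalog=catalog)
    indicator_values.to_csv(out / "indicators.tsv", sep="\t", index_label="sample_id")

    table = volcano_table(matrix, indicator_values)
    table.to_csv(out / "univariate.tsv", sep="\t")
    table[["log2_fc", "neg_log10_q"]].to_csv(out / "volcano.tsv", sep="\t")
    log.log(
        "univariate", n_features=len(table),
        n_significant=int((table["q"] < 0.05).sum()),
    )

    model = StabilitySelection(
        matrix,
        n_iterations=config.n_iterations,
        train_fraction=config.train_fraction,
        exclude_quantile=config.exclude_quantile,
        majority=config.majority,
        boruta_params={
            "max_iter": config.boruta_max_iter,
            "perc": config.boruta_perc,
            "alpha": config.boruta_alpha,
        },
        shap_permutations=config.shap_permutations,
    )
    results = model.fit(seed=config.seed)
    for rec in results.records:
        if rec.failed:
            log.log("stability_round_failed", index=rec.index, reason=rec.failure_reason)
    results.to_json(out / "stability.json")
    consensus = results.consensus_table()
    consensus.to_csv(out / "consensus_signature.tsv", sep="\t")
    log.log(
        "stability",
        median_test_auc=results.median_test_auc,
        consensus=results.consensus,
    )

    pathways = (
        load_pathways(config.pathways_path)
        if config.pathways_path
        else demo_pathways()
    )
    selected = select_input_list(results.records, min_count=config.min_selection_count)
    selected = [m for m in selected if m in set(matrix.metabolites)]
    enrich = ora(selected, matrix.metabolites, pathways)
    enrich.to_csv(out / "enrichment.tsv", sep="\t")
    log.log("enrichment", n_selected=len(selected), n_pathways=len(enrich))

    log.log("done")
    return {
        "matrix": matrix,
        "filter_report": report,
        "pca": result,
        "outliers": outliers,
        "univariate": table,
        "stability": results,
        "enrichment": enrich,
    }
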