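"""End-to-end analysis pipeline: load -> score -> network -> risk ->
protection -> cluster -> reliability/power -> report bundle.

The pipeline is deterministic: an identical configuration (including seed)
produces a byte-identical output bundle, and the manifest records the config
hash. Any stage error aborts the run with the stage name; partial outputs
are discarded.
"""
from __future__ import annotations

import json
import logging
import shutil
import tempfile
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import symptoms as sym
from . import risk as riskmod
from . import protection as protmod
from . import reliability as rel
from .stratify import stratify as _stratify
from .dataset import SurveyDataset, load_survey, write_survey, config_hash
from .instrument import Codebook, default_codebook, load_codebook
from .synth import GeneratorConfig, default_config, generate

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass
class PipelineConfig:
    survey_path: str | None = None
    codebook_path: str | None = None
    synthetic: bool = False
    seed: int = 42
    n: int = 62
    missing_policy: str = "error"
    node_min_prevalence: float = 0.20
    edge_quantile: float = 0.30
    alpha: float = 0.05
    crs_weights: dict = field(default_factory=lambda: dict(riskmod.DEFAULT_WEIGHTS))
    cpe_weights: dict = field(default_factory=lambda: dict(protmod.DEFAULT_WEIGHTS))
    k: int | None = None
    k_max: int = 8
    restarts: int = 10
    power_d: float = 0.5
    power_target: float = 0.80
    power_allocations: list = field(default_factory=lambda: [[31, 31], [40, 22]])

    def validate(self) -> None:
        if not 0 < self.edge_quantile <= 1:
            raise ValueError(f"edge_quantile must lie in (0, 1], got {self.edge_quantile}")
        if not 0 <= self.node_min_prevalence <= 1:
            raise ValueError("node_min_prevalence must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_max < 3:
            raise ValueError("k_max must be >= 3")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not self.synthetic and self.survey_path is None:
            raise ValueError("either a survey path or the synthetic flag is required")
        if not self.synthetic:
            for name in ("survey_path", "codebook_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")

    def to_dict(self) -> dict:
        return asdict(self)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Report-style rounding (0.5 always rounds away from zero)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_demographics(demographics: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category level, one row per level."""
    n = len(demographics)
    rows = []
    for variable in demographics.columns:
        counts = demographics[variable].value_counts()
        for level in sorted(counts.index):
            k = int(counts[level])
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "n": k,
                    "pct": round_half_up(100 * k / n, 1) if n else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "level", "n", "pct"])


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage: %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest. Outputs are written atomically: everything is
    produced in a temporary directory first and moved into place only on
    success.
    """
    config.validate()
    out_dir = Path(out_dir)
    collected_warnings: list[str] = []

    with tempfile.TemporaryDirectory() as tmp:
        tmp_dir = Path(tmp) / "bundle"
        tmp_dir.mkdir()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            manifest = _run_stages(config, tmp_dir)
            collected_warnings = [str(w.message) for w in caught]
        manifest["warnings"] = collected_warnings
        (tmp_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
        )
        if out_dir.exists():
            shutil.rmtree(out_dir)
        shutil.move(str(tmp_dir), str(out_dir))
    return manifest


def _run_stages(config: PipelineConfig, out: Path) -> dict:
    load = _stage("load")(_load_inputs)
    codebook, dataset = load(config)

    tables: dict[str, pd.DataFrame] = {}

    tables["demographics"] = _stage("demographics")(summarize_demographics)(
        dataset.demographics
    )

    summary = _stage("symptoms")(sym.summarize_symptoms)(dataset.symptoms, codebook)
    tables["symptom_items"] = summary.per_item
    tables["symptom_systems"] = summary.per_system
    tables["symptom_burden"] = pd.DataFrame(
        {"respondent_id": dataset.respondent_ids, "tsb": summary.per_respondent}
    )

    network = _stage("network")(sym.cooccurrence_network)(
        dataset.symptoms,
        codebook,
        node_min_prevalence=config.node_min_prevalence,
        edge_quantile=config.edge_quantile,
    )
    sym.export_network(network, out, layout_seed=config.seed)
    if network.centrality is not None:
        tables["network_centrality"] = network.centrality

    risk_table = _stage("risk")(riskmod.rank_risk_factors)(
        dataset, codebook, alpha=config.alpha, weights=config.crs_weights
    )
    tables["risk_scores"] = risk_table.scores
    tables["risk_system_pvalues"] = risk_table.system_pvalues

    prot_table, prot_categories = _stage("protection")(protmod.rank_measures)(
        dataset, codebook, weights=config.cpe_weights
    )
    tables["protection_scores"] = prot_table
    tables["protection_categories"] = prot_categories

    scores = sym.system_scores(dataset.symptoms, codebook)
    nonconstant = scores.loc[:, scores.std(ddof=0) > 0]
    result = _stage("cluster")(_stratify)(
        nonconstant,
        summary.per_respondent,
        k=config.k,
        k_max=config.k_max,
        seed=config.seed,
        restarts=config.restarts,
    )
    tables["cluster_labels"] = pd.DataFrame(
        {"respondent_id": dataset.respondent_ids, "cluster": result.labels}
    )
    tables["cluster_centers"] = pd.DataFrame(
        result.centers, columns=nonconstant.columns
    )
    tables["wcss_curve"] = pd.DataFrame(
        {"k": list(result.wcss_curve), "wcss": list(result.wcss_curve.values())}
    )
    tables["cluster_profiles"] = result.profiles

    tables["reliability"] = _stage("reliability")(rel.reliability_report)(
        dataset.symptoms, codebook
    )
    power = _stage("power")(rel.power_report)(
        [tuple(a) for a in config.power_allocations],
        d=config.power_d,
        alpha=config.alpha,
        target_power=config.power_target,
    )
    tables["power"] = power.scenarios.assign(
        d=config.power_d, required_total_n=power.required_total_n
    )

    for name, table in tables.items():
        table.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
    write_survey(dataset, out / "survey.csv")

    return {
        "n_respondents": dataset.n,
        "tables": sorted(f"{n}.csv" for n in tables),
        "network_metrics": network.metrics,
        "selected_k": result.k,
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
    }


def _load_inputs(config: PipelineConfig) -> tuple[Codebook, SurveyDataset]:
    if config.synthetic:
        gen = default_config(n=config.n, seed=config.seed)
        return gen.codebook, generate(gen)
    codebook = (
        load_codebook(config.codebook_path)
        if config.codebook_path
        else default_codebook()
    )
    dataset = load_survey(config.survey_path, codebook, missing=config.missing_policy)
    return codebook, dataset
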