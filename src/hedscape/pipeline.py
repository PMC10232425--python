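"""End-to-end orchestration: genotypes -> divergence -> categories -> KIR-ligand
status -> survival models -> lesion summaries, with a manifest and per-stage
logging. Any stage failure aborts with the stage name attached."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .hed import (
    SCORE_SLOTS,
    ReferenceCutoffs,
    categories_table,
    compute_hed_table,
    compute_reference_cutoffs,
    profiles_from_table,
)
from .hla import read_allele_sequences, read_genotype_table
from .kir import c_status_table
from .lesions import read_lesion_table, tabulate
from .outcomes import (
    DEATH,
    RELAPSE,
    cif_aalen_johansen,
    cox_cause_specific,
    frame_to_outcomes,
    km_estimate,
    logrank_test,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("hedscape.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and modeling choices for one pipeline run.

    Exactly one of ``controls_path`` (genotypes defining the reference
    distribution) or ``cutoffs_path`` (a JSON of precomputed 50th-percentile
    cutoffs) must be given.
    """

    genotypes_path: str
    sequences_path: str
    outdir: str
    controls_path: str | None = None
    cutoffs_path: str | None = None
    outcomes_path: str | None = None
    lesions_path: str | None = None
    patients_path: str | None = None
    covariates: tuple[str, ...] = ("class2_hed",)
    reference_levels: Mapping[str, Sequence[str]] = field(default_factory=dict)
    group_covariate: str = "class2_hed"
    ties: str = "efron"
    seed: int = 0
    delimiter: str = "\t"

    def validate(self) -> None:
        if (self.controls_path is None) == (self.cutoffs_path is None):
            raise PipelineError(
                "config: exactly one of controls_path or cutoffs_path is required"
            )
        for label in ("genotypes_path", "sequences_path", "controls_path",
                      "cutoffs_path", "outcomes_path", "lesions_path",
                      "patients_path"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {label} does not exist: {value}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in asdict(config).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _curve_payload(curve) -> dict:
    return {
        "times": [float(t) for t in curve.times],
        "values": [float(v) for v in curve.values],
        "variance": [float(v) for v in curve.variance],
        "kind": curve.kind,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle to ``outdir``.

    Returns a manifest dict (also written as manifest.json) listing outputs,
    package version, seed and a hash of the configuration.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "setup"

    def _write_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        outputs[name] = str(path)

    try:
        stage = "read-genotypes"
        logger.info("stage %s: %s", stage, config.genotypes_path)
        genotypes = read_genotype_table(config.genotypes_path, delimiter=config.delimiter)

        stage = "read-sequences"
        logger.info("stage %s: %s", stage, config.sequences_path)
        dictionary = read_allele_sequences(config.sequences_path)

        stage = "hed"
        hed_table = compute_hed_table(genotypes, dictionary)
        _write_df(hed_table, "hed_table.tsv")

        stage = "cutoffs"
        if config.controls_path is not None:
            control_genotypes = read_genotype_table(
                config.controls_path, delimiter=config.delimiter
            )
            control_table = compute_hed_table(control_genotypes, dictionary)
            cutoffs = compute_reference_cutoffs(
                profiles_from_table(control_table), source=str(config.controls_path)
            )
        else:
            with open(config.cutoffs_path) as fh:
                raw = json.load(fh)
            cutoffs = ReferenceCutoffs(
                source=str(config.cutoffs_path),
                cutoffs={k: float(v) for k, v in raw.items()},
            )
        with open(outdir / "cutoffs.json", "w") as fh:
            json.dump({"source": cutoffs.source, "cutoffs": dict(cutoffs.cutoffs)}, fh, indent=1)
        outputs["cutoffs.json"] = str(outdir / "cutoffs.json")

        stage = "categories"
        categories = categories_table(hed_table, cutoffs)
        _write_df(categories, "hed_categories.tsv")

        stage = "c-status"
        with_c = [g for g in genotypes if "C" in g.alleles]
        if with_c:
            _write_df(c_status_table(with_c), "c_status.tsv")

        report: dict = {"schema_version": 1}
        if config.outcomes_path is not None:
            stage = "read-outcomes"
            out_df = pd.read_csv(config.outcomes_path, sep=config.delimiter)
            out_df["event"] = out_df["event"].replace({"death": DEATH})
            cats = categories.reset_index().rename(
                columns={f"{s}_cat": f"{s}_hed" for s in SCORE_SLOTS}
            )
            new_cols = ["subject_id"] + [
                c for c in cats.columns
                if c != "subject_id" and c not in out_df.columns
            ]
            merged = out_df.merge(cats[new_cols], on="subject_id", how="left")
            outcomes = frame_to_outcomes(merged)

            stage = "km"
            report["km_os"] = _curve_payload(km_estimate(outcomes))
            stage = "cif"
            report["cif_relapse"] = _curve_payload(cif_aalen_johansen(outcomes, RELAPSE))
            report["cif_death"] = _curve_payload(cif_aalen_johansen(outcomes, DEATH))
            stage = "logrank"
            stat, p = logrank_test(outcomes, config.group_covariate)
            report["logrank"] = {
                "group": config.group_covariate, "statistic": stat, "p": p,
            }
            stage = "cox"
            fit = cox_cause_specific(
                outcomes, RELAPSE, list(config.covariates),
                reference_levels=config.reference_levels, ties=config.ties,
            )
            report["cox_relapse"] = {
                "ties": fit.ties,
                "n": fit.n,
                "n_events": fit.n_events,
                "log_likelihood": fit.log_likelihood,
                "terms": {k: asdict(t) for k, t in fit.terms.items()},
            }
            with open(outdir / "models.json", "w") as fh:
                json.dump(report, fh, indent=1)
            outputs["models.json"] = str(outdir / "models.json")

        if config.lesions_path is not None and config.patients_path is not None:
            stage = "lesions"
            lesions = read_lesion_table(config.lesions_path, delimiter=config.delimiter)
            assayed = pd.read_csv(config.patients_path, sep=config.delimiter)
            summaries = tabulate(lesions, assayed, group_by="timepoint")
            _write_df(
                pd.DataFrame(
                    [{"group": s.group, "numerator": s.numerator,
                      "denominator": s.denominator, "percent": s.percent,
                      "n_mutation_lesions": s.n_mutation_lesions,
                      "n_loss_lesions": s.n_loss_lesions}
                     for s in summaries]
                ).set_index("group"),
                "lesion_summaries.tsv",
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "hedscape",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
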