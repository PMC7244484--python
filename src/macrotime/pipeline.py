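"""End-to-end pipeline: simulate/load → step detection → DE → profiles →
signature → ORA, with a run manifest and seeded reproducibility.

A single run seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage is independently
reproducible; currently only the simulation stage consumes randomness.
Identical configuration and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datamodel import DataModelError, check_annotation_covers
from .diffexpr import DEFAULT_FDR_THRESHOLD, differential_expression
from .io import (
    read_expression_matrix,
    read_gmt,
    read_sample_annotation,
    write_expression_matrix,
    write_table,
)
from .profiles import DEFAULT_MAX_WEEK, aggregate_by_week, hierarchical_order, lps_ratio
from .signatures import ora_hypergeometric, resilience_signature, time_dependent_sets
from .stepminer import (
    DEFAULT_M,
    DEFAULT_MIN_SEGMENT,
    DEFAULT_P_THRESHOLD,
    run_stepminer,
)
from .synthetic import SimConfig, generate_cohort

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (
    "day1_bpd_vs_none",
    "day7_severe_vs_nonemild",
    "lps_vs_control_day1",
    "lps_vs_control_day7",
)


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    output_dir: Path
    seed: int = 0
    matrix_path: Path | None = None
    annotation_path: Path | None = None
    gmt_path: Path | None = None
    sim: SimConfig | None = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    m: int = DEFAULT_M
    min_segment: int = DEFAULT_MIN_SEGMENT
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    max_week: int = DEFAULT_MAX_WEEK
    linkage: str = "complete"
    direction_filter: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_block = raw.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataModelError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise DataModelError("config requires output_dir")
        config = cls(**{**raw, "output_dir": Path(raw["output_dir"])})
        for key in ("matrix_path", "annotation_path", "gmt_path"):
            value = getattr(config, key)
            if value is not None:
                setattr(config, key, Path(value))
        if sim_block is not None:
            config.sim = SimConfig(**sim_block)
        if isinstance(config.contrasts, list):
            config.contrasts = tuple(config.contrasts)
        return config

    def validate(self) -> None:
        if (self.matrix_path is None) != (self.annotation_path is None):
            raise DataModelError(
                "matrix_path and annotation_path must be given together"
            )
        for key in ("matrix_path", "annotation_path", "gmt_path"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise DataModelError(f"{key} does not exist: {value}")
        if self.matrix_path is None and self.sim is None:
            self.sim = SimConfig()
        if self.sim is not None:
            self.sim.validate()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written as JSON).

    Any stage failure aborts with the failing stage named; outputs of the
    completed stages are retained in ``output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "p_threshold": config.p_threshold,
            "m": config.m,
            "min_segment": config.min_segment,
            "fdr_threshold": config.fdr_threshold,
            "max_week": config.max_week,
            "linkage": config.linkage,
            "direction_filter": config.direction_filter,
        },
        "outputs": {},
        "counts": {},
    }
    stage = "load"
    try:
        if config.matrix_path is not None:
            matrix = read_expression_matrix(config.matrix_path)
            annotation = read_sample_annotation(config.annotation_path)
            truth = None
        else:
            stage = "simulate"
            sim = dataclasses.replace(config.sim, seed=seeds[0])
            matrix, annotation, truth = generate_cohort(sim)
            write_expression_matrix(matrix, out / "matrix.tsv")
            write_table(annotation, out / "annotation.tsv", seed=config.seed)
            write_table(truth, out / "truth.tsv", seed=config.seed)
            manifest["outputs"]["matrix"] = "matrix.tsv"
            manifest["outputs"]["annotation"] = "annotation.tsv"
            manifest["outputs"]["truth"] = "truth.tsv"
            manifest["parameters"]["sim"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(sim).items()
                if k != "group_counts"
            }
        check_annotation_covers(matrix, annotation)

        stage = "stepminer"
        step_tables = {}
        for group in ("resilient", "severe"):
            table = run_stepminer(
                matrix, annotation, group,
                p_threshold=config.p_threshold, m=config.m,
                min_segment=config.min_segment,
            )
            step_tables[group] = table
            name = f"step_{group}.tsv"
            write_table(table, out / name, seed=config.seed)
            manifest["outputs"][f"step_{group}"] = name
            manifest["counts"][f"step_significant_{group}"] = int(
                table["significant"].sum()
            )

        stage = "diffexp"
        for contrast in config.contrasts:
            table = differential_expression(
                matrix, annotation, contrast, fdr_threshold=config.fdr_threshold
            )
            name = f"de_{contrast}.tsv"
            write_table(table, out / name, seed=config.seed)
            manifest["outputs"][f"de_{contrast}"] = name
            manifest["counts"][f"de_significant_{contrast}"] = int(
                table["significant"].sum()
            )

        stage = "profiles"
        control = aggregate_by_week(matrix, annotation, "control", config.max_week)
        lps = aggregate_by_week(matrix, annotation, "LPS", config.max_week)
        ratio = lps_ratio(control, lps)
        for name, frame in (
            ("profile_control", control),
            ("profile_lps", lps),
            ("profile_ratio", ratio),
        ):
            write_table(
                frame.reset_index(), out / f"{name}.tsv", seed=config.seed
            )
            manifest["outputs"][name] = f"{name}.tsv"
        order, _ = hierarchical_order(ratio, method=config.linkage)
        write_table(
            ratio.loc[order].reset_index()[["gene_id"]].rename(
                columns={"gene_id": "gene_id_in_leaf_order"}
            ),
            out / "profile_row_order.tsv",
            seed=config.seed,
        )
        manifest["outputs"]["profile_row_order"] = "profile_row_order.tsv"

        stage = "signature"
        set_res, set_sev, venn = time_dependent_sets(
            step_tables["resilient"], step_tables["severe"],
            direction_filter=config.direction_filter,
        )
        signature = resilience_signature(
            step_tables["resilient"], step_tables["severe"], matrix, annotation
        )
        write_table(signature, out / "signature.tsv", seed=config.seed)
        venn_payload = {
            "set_resilient": len(set_res),
            "set_severe": len(set_sev),
            **venn.counts,
        }
        (out / "venn.json").write_text(json.dumps(venn_payload, indent=2) + "\n")
        manifest["outputs"]["signature"] = "signature.tsv"
        manifest["outputs"]["venn"] = "venn.json"
        manifest["counts"].update(
            {f"venn_{k}": v for k, v in venn_payload.items()}
        )
        manifest["counts"]["signature_genes"] = len(signature)

        if config.gmt_path is not None:
            stage = "ora"
            collection = read_gmt(config.gmt_path)
            universe = set(matrix.gene_ids)
            query = set(signature["gene_id"]) or set_res
            if query:
                ora = ora_hypergeometric(query, collection, universe)
                write_table(ora, out / "ora_signature.tsv", seed=config.seed)
                manifest["outputs"]["ora_signature"] = "ora_signature.tsv"
                manifest["counts"]["ora_sets_tested"] = len(ora)
    except Exception as exc:
        raise DataModelError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if truth is not None:
        from .synthetic import truth_signature

        manifest["counts"]["truth_step_resilient"] = len(
            truth_signature(truth, "resilient")
        )
        manifest["counts"]["truth_step_severe"] = len(
            truth_signature(truth, "severe")
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
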