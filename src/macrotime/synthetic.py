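"""Synthetic longitudinal cohorts with ground truth for pipeline validation.

The generator emulates the study design the analysis modules target: two
outcome groups ("severe" and "resilient", i.e. none/mild disease) sampled at
days 1, 7, 14 and 21 of life with monotone attrition (patients present at a
later day are a subset of those present at day 1), and a paired LPS-treated
aliquot for every control sample.  Default per-day control-sample counts are
severe 25/14/9/4 and resilient 13/5/4/3 for days 1/7/14/21.

Planted gene patterns (all on the log2 scale):

* flat genes — constant baseline;
* step-up / step-down genes — an ideal Heaviside shift of ``step_amplitude``
  at a planted day, possibly in only one group (resilient-only,
  severe-only) or in both (shared, same day);
* LPS-responsive genes — an additive ``lps_effect`` in every LPS aliquot,
  identical across outcome groups, so that a correct analysis finds no
  group difference in the LPS response;
* day-1 inflammatory genes — an additive offset in the severe group's day-1
  samples only (a perinatal-inflammation transient).

Gaussian noise of ``noise_sd`` log2 units is added independently to every
sample value.  Baseline means are drawn Uniform(4, 12) log2 units, a typical
normalized-microarray range.  The annotation table (cohort structure) is a
pure function of the configuration, independent of the seed; only values
and the random class assignments change with the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataModelError, ExpressionMatrix, validate_annotation


def _default_group_counts() -> dict[str, dict[int, int]]:
    return {
        "severe": {1: 25, 7: 14, 14: 9, 21: 4},
        "resilient": {1: 13, 7: 5, 14: 4, 21: 3},
    }


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Pattern fractions (``frac_flat + frac_step_up + frac_step_down``) must
    sum to 1, as must the resilient-only/severe-only/shared split of step
    genes in ``group_specific_step_fracs``.  Gene counts per class are fixed
    by largest-remainder rounding, so planted set sizes are deterministic;
    which genes carry which class is shuffled by the seed.
    """

    n_genes: int = 2000
    frac_flat: float = 0.8
    frac_step_up: float = 0.1
    frac_step_down: float = 0.1
    step_day_choices: tuple[int, ...] = (7, 14, 21)
    step_amplitude: float = 2.0
    noise_sd: float = 0.5
    group_counts: dict[str, dict[int, int]] = field(default_factory=_default_group_counts)
    lps_frac: float = 0.1
    lps_effect: float = 3.0
    day1_inflammatory_frac: float = 0.05
    day1_inflammatory_offset: float = 2.0
    # split of step genes: (resilient-only, severe-only, shared)
    group_specific_step_fracs: tuple[float, float, float] = (0.75, 0.125, 0.125)
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_flat, self.frac_step_up, self.frac_step_down)
        if any(f < 0 or f > 1 for f in fracs):
            raise DataModelError("pattern fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise DataModelError(
                f"pattern fractions sum to {sum(fracs)}, expected 1"
            )
        if abs(sum(self.group_specific_step_fracs) - 1.0) > 1e-9:
            raise DataModelError("group_specific_step_fracs must sum to 1")
        if any(f < 0 for f in self.group_specific_step_fracs):
            raise DataModelError("group_specific_step_fracs must be >= 0")
        for name, value in (
            ("step_amplitude", self.step_amplitude),
            ("noise_sd", self.noise_sd),
            ("lps_effect", self.lps_effect),
            ("day1_inflammatory_offset", self.day1_inflammatory_offset),
        ):
            if value < 0:
                raise DataModelError(f"{name} must be >= 0")
        if not (0 <= self.lps_frac <= 1 and 0 <= self.day1_inflammatory_frac <= 1):
            raise DataModelError("lps_frac and day1_inflammatory_frac must be in [0,1]")
        if self.n_genes < 1:
            raise DataModelError("n_genes must be >= 1")
        if not self.step_day_choices or not set(self.step_day_choices) <= {7, 14, 21}:
            raise DataModelError("step_day_choices must be a non-empty subset of {7,14,21}")
        for group, counts in self.group_counts.items():
            days = sorted(counts)
            if any(counts[d] < 1 for d in days):
                raise DataModelError(f"group {group!r}: counts must be >= 1 per day")
            sizes = [counts[d] for d in days]
            if any(b > a for a, b in zip(sizes, sizes[1:])):
                raise DataModelError(
                    f"group {group!r}: per-day counts must be non-increasing "
                    "(monotone attrition)"
                )


def _largest_remainder(n: int, fracs) -> list[int]:
    """Integer class counts summing to n, proportional to fracs."""
    raw = [n * f for f in fracs]
    counts = [int(x) for x in raw]
    for _ in range(n - sum(counts)):
        i = max(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i))
        counts[i] += 1
    return counts


def _build_annotation(config: SimConfig) -> pd.DataFrame:
    rows = []
    for group in sorted(config.group_counts):
        counts = config.group_counts[group]
        bpd = "severe" if group == "severe" else "none"
        prefix = group[:3].upper()
        for day in sorted(counts):
            # monotone attrition: the first counts[day] patients remain
            for i in range(counts[day]):
                patient = f"{prefix}{i + 1:03d}"
                for treatment in ("control", "LPS"):
                    tag = "ctrl" if treatment == "control" else "lps"
                    rows.append(
                        {
                            "sample_id": f"{patient}_d{day:02d}_{tag}",
                            "patient_id": patient,
                            "day_of_life": day,
                            "treatment": treatment,
                            "bpd_group": bpd,
                        }
                    )
    return validate_annotation(pd.DataFrame(rows))


def generate_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort: expression matrix, annotation, and ground truth.

    The control value of gene g in sample (patient, day d) of group G is

        baseline(g) + direction * amplitude * 1[d >= step_day(g, G)]
        + offset * 1[g day-1 inflammatory, G = severe, d = 1]
        + Normal(0, noise_sd)

    and the paired LPS value is the same deterministic mean plus
    ``lps_effect`` for LPS-responsive genes plus independent noise.
    Identical seeds give bit-identical output.

    Returns ``(matrix, annotation, truth)`` where ``truth`` has one row per
    gene: ``gene_id, pattern_resilient, pattern_severe, step_day_resilient,
    step_day_severe, lps_responsive, day1_inflammatory, baseline_mean``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation = _build_annotation(config)
    n_genes = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    n_flat, n_up, n_down = _largest_remainder(
        n_genes, (config.frac_flat, config.frac_step_up, config.frac_step_down)
    )
    directions = np.array([0] * n_flat + [1] * n_up + [-1] * n_down)
    rng.shuffle(directions)

    step_genes = np.flatnonzero(directions != 0)
    n_res_only, n_sev_only, n_shared = _largest_remainder(
        len(step_genes), config.group_specific_step_fracs
    )
    scope = np.array(
        ["resilient"] * n_res_only + ["severe"] * n_sev_only + ["shared"] * n_shared
    )
    rng.shuffle(scope)

    day_choices = np.array(sorted(config.step_day_choices))
    step_day = rng.choice(day_choices, size=n_genes)  # used only for step genes

    pattern = {"resilient": np.full(n_genes, "flat", dtype=object),
               "severe": np.full(n_genes, "flat", dtype=object)}
    planted_day = {"resilient": np.zeros(n_genes, dtype=int),
                   "severe": np.zeros(n_genes, dtype=int)}
    for pos, g in enumerate(step_genes):
        label = "step_up" if directions[g] > 0 else "step_down"
        groups = ("resilient", "severe") if scope[pos] == "shared" else (scope[pos],)
        for group in groups:
            pattern[group][g] = label
            planted_day[group][g] = step_day[g]

    lps_responsive = np.zeros(n_genes, dtype=bool)
    n_lps = int(round(config.lps_frac * n_genes))
    if n_lps:
        lps_responsive[rng.choice(n_genes, size=n_lps, replace=False)] = True

    # day-1 inflammatory transients are planted on genes flat in the severe
    # group so they do not confound the planted step patterns there
    day1_inflammatory = np.zeros(n_genes, dtype=bool)
    n_day1 = int(round(config.day1_inflammatory_frac * n_genes))
    flat_in_severe = np.flatnonzero(pattern["severe"] == "flat")
    if n_day1:
        if n_day1 > len(flat_in_severe):
            raise DataModelError(
                "day1_inflammatory_frac exceeds the fraction of genes flat "
                "in the severe group"
            )
        day1_inflammatory[
            rng.choice(flat_in_severe, size=n_day1, replace=False)
        ] = True

    baseline = rng.uniform(*config.baseline_range, size=n_genes)

    values = np.empty((n_genes, len(annotation)))
    for j, row in annotation.iterrows():
        group = "severe" if row["resilience_class"] == "severe" else "resilient"
        day = row["day_of_life"]
        mean = baseline.copy()
        stepped = (planted_day[group] > 0) & (day >= planted_day[group])
        mean += np.where(
            pattern[group] == "step_up", config.step_amplitude, 0.0
        ) * stepped
        mean -= np.where(
            pattern[group] == "step_down", config.step_amplitude, 0.0
        ) * stepped
        if group == "severe" and day == 1:
            mean += config.day1_inflammatory_offset * day1_inflammatory
        if row["treatment"] == "LPS":
            mean += config.lps_effect * lps_responsive
        values[:, j] = mean + rng.normal(0.0, config.noise_sd, size=n_genes)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=list(annotation["sample_id"]))
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "pattern_resilient": pattern["resilient"],
            "pattern_severe": pattern["severe"],
            "step_day_resilient": planted_day["resilient"],
            "step_day_severe": planted_day["severe"],
            "lps_responsive": lps_responsive,
            "day1_inflammatory": day1_inflammatory,
            "baseline_mean": baseline,
        }
    )
    return matrix, annotation, truth


def truth_signature(truth: pd.DataFrame, group: str) -> frozenset:
    """Planted time-dependent genes of one group (step up or down)."""
    if group not in ("resilient", "severe"):
        raise DataModelError(f"group must be 'resilient' or 'severe', got {group!r}")
    column = f"pattern_{group}"
    mask = truth[column].isin(["step_up", "step_down"])
    return frozenset(truth.loc[mask, "gene_id"])
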