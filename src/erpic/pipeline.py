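"""End-to-end orchestration: simulate → decompose → match → features → SVM.

:func:`run_pipeline` ties the stages into one reproducible run driven by a
:class:`RunConfig` and a single master seed.  The stage order mirrors the
study design it emulates:

1. simulate a synthetic two-group ERP cohort (or load one from disk),
2. average-reference all ERPs,
3. per preparatory set, decompose the case and control sub-cohorts
   separately and match their ICs (component stability table), then
   decompose the total sample to obtain the working filters,
4. exclude ocular-artifact ICs and drop duplicate set-independent ICs,
5. pick each IC's electrode site and dominant condition(s), extract the
   window-grid feature matrix,
6. estimate accuracy by nested cross-validation, run forward selection on
   the full sample, train the final SVM,
7. simulate an all-case validation sample, decompose it with the *frozen*
   main-sample filters and report external validation accuracy.

The run report is a plain JSON-serializable dict; all randomness derives
from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cohort import ERPCohort, SET_CONDITIONS
from .classify import (
    CVConfig,
    external_validate,
    forward_select,
    nested_cv,
    train_final,
)
from .errors import InvalidParameterError
from .features import (
    CohortActivations,
    FeatureTemplate,
    build_feature_matrix,
    select_conditions,
    select_site,
)
from .ica import (
    DEFAULT_N_ICS,
    ICADecomposition,
    MatchCriteria,
    decompose_cohort,
    exclude_artifact_ics,
    match_components,
)
from .montage import Montage, standard_1020
from .synthetic import CohortParams, GroundTruth, default_sources, simulate_cohort
from . import io as erpio

logger = logging.getLogger("erpic")


@dataclass
class RunConfig:
    """All pipeline parameters with the published defaults where printed.

    Defaults: 8 ms window step, 114 ms base width ±25/50%, 0-700 ms span,
    10-fold CV, up to 10 features, dual matching thresholds r > 0.5.
    """

    seed: int = 0
    # cohort generation
    n_per_group: int = 50
    noise_sd: float = 1.0
    subject_latency_jitter_sd: float = 8.0
    subject_amplitude_sd: float = 0.2
    latency_shift_ms: float = 40.0
    amplitude_scale: float = 1.5
    cohort_path: str | None = None  # load instead of simulating
    # decomposition
    n_ics_continue: int = DEFAULT_N_ICS["continue"]
    n_ics_discontinue: int = DEFAULT_N_ICS["discontinue"]
    algorithm: str = "fastica"
    artifact_r_threshold: float = 0.8
    manual_exclude: list[str] = field(default_factory=list)
    # matching
    topo_r_min: float = 0.5
    curve_r_min: float = 0.5
    # features
    template: FeatureTemplate = field(default_factory=FeatureTemplate)
    condition_ratio_threshold: float = 0.8
    # classification
    n_folds: int = 10
    k_max: int = 10
    tolerance: float = 0.01
    screen_top: int | None = 40
    nested: bool = True
    final_grid: tuple = ((1.0, "scale"), (10.0, "scale"), (1.0, 0.1), (10.0, 0.1))
    # validation
    n_validation: int = 17
    validate: bool = True

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(8) % (2 ** 31)
        names = ("simulate", "ica_continue", "ica_discontinue", "cv",
                 "validation", "spare0", "spare1", "spare2")
        return {n: int(s) for n, s in zip(names, state)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "template" in d and isinstance(d["template"], dict):
            tf = {f.name for f in dataclasses.fields(FeatureTemplate)}
            bad = set(d["template"]) - tf
            if bad:
                raise InvalidParameterError(f"unknown template keys: {sorted(bad)}")
            t = dict(d["template"])
            for k in ("width_scales", "kinds"):
                if k in t:
                    t[k] = tuple(t[k])
            d["template"] = FeatureTemplate(**t)
        if "final_grid" in d:
            d["final_grid"] = tuple(tuple(p) for p in d["final_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["template"] = dataclasses.asdict(self.template)
        d["final_grid"] = [list(p) for p in self.final_grid]
        return d


# ---------------------------------------------------------------------------
# Stage helpers


def average_reference_cohort(cohort: ERPCohort) -> ERPCohort:
    """Common-average reference applied to every subject/condition ERP."""
    data = cohort.data - cohort.data.mean(axis=2, keepdims=True)
    return ERPCohort(cohort.subjects, data, cohort.montage,
                     cohort.sampling_rate, cohort.conditions)


def eog_template(montage: Montage, smoothness: float = 0.7) -> np.ndarray:
    """Fronto-polar topography typical of eye-movement components."""
    d = montage.distances()
    bump = np.exp(-(d[montage.index("Fp1")] ** 2) / (2 * smoothness ** 2)) + np.exp(
        -(d[montage.index("Fp2")] ** 2) / (2 * smoothness ** 2)
    )
    return bump / np.linalg.norm(bump)


def cross_set_twins(
    continue_decomp: ICADecomposition,
    discontinue_decomp: ICADecomposition,
    r_min: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Set-independent ICs: topography pairs correlated across the two sets.

    Returns (continue_index, discontinue_index, r) triples from an exact
    assignment restricted to pairs with r > ``r_min``.
    """
    from scipy.optimize import linear_sum_assignment

    from .ica import _pearson_matrix

    r = _pearson_matrix(continue_decomp.topographies, discontinue_decomp.topographies)
    admissible = r > r_min
    n = max(r.shape)
    weight = np.zeros((n, n))
    weight[: r.shape[0], : r.shape[1]] = np.where(admissible, np.abs(r), 0.0)
    rows, cols = linear_sum_assignment(weight, maximize=True)
    return [
        (int(i), int(j), float(r[i, j]))
        for i, j in zip(rows, cols)
        if i < r.shape[0] and j < r.shape[1] and admissible[i, j]
    ]


def collect_activations(
    cohort: ERPCohort,
    decomps: dict[str, ICADecomposition],
    selections: dict[str, dict[str, Any]],
) -> CohortActivations:
    """Individual IC activation curves at each IC's site.

    ``selections`` maps ic_label -> {"set_id", "index", "site", "conditions"};
    entries are ordered set-major then IC index then condition.
    """
    entries: list[tuple[str, str]] = []
    plan: list[tuple[str, int, int, int]] = []  # (set_id, ic idx, site, cond idx)
    for label, sel in selections.items():
        for cond in sel["conditions"]:
            entries.append((label, cond))
            plan.append(
                (sel["set_id"], sel["index"], sel["site"], cohort.condition_index(cond))
            )
    curves = np.empty((cohort.n_subjects, len(entries), cohort.n_samples))
    for e, (set_id, idx, site, ci) in enumerate(plan):
        decomp = decomps[set_id]
        gain = decomp.topographies[site, idx]
        curves[:, e, :] = gain * np.tensordot(
            cohort.data[:, ci], decomp.filters[idx], axes=([1], [0])
        )
    return CohortActivations(
        subject_ids=cohort.subject_ids,
        groups=cohort.groups,
        entries=entries,
        curves=curves,
    )


def make_selections(
    decomps: dict[str, ICADecomposition],
    twins: list[tuple[int, int, float]],
    ratio_threshold: float = 0.8,
) -> dict[str, dict[str, Any]]:
    """Site and condition selection per retained IC.

    Continue-set twins of set-independent ICs are dropped; their
    discontinue-set counterparts are forced to the ignore condition.
    """
    drop_continue = {i for i, _, _ in twins}
    force_ignore_disc = {j for _, j, _ in twins}
    selections: dict[str, dict[str, Any]] = {}
    for set_id, decomp in decomps.items():
        for i in range(decomp.n_ics):
            if set_id == "continue" and i in drop_continue:
                continue
            label = decomp.ic_labels[i]
            grand = {
                c: decomp.grand_activations[c][i]
                for c in SET_CONDITIONS[set_id]
            }
            site = select_site(decomp.topographies[:, i], list(grand.values()))
            force = set_id == "discontinue" and i in force_ignore_disc
            conds = select_conditions(grand, ratio_threshold, force_ignore=force)
            selections[label] = {
                "set_id": set_id,
                "index": i,
                "site": site,
                "conditions": conds,
            }
    return selections


def _match_table(result) -> list[dict[str, Any]]:
    return [
        {
            "ic_a": p.index_a,
            "ic_b": p.index_b,
            "r_topography": p.r_topography,
            "r_curves": p.r_curves,
        }
        for p in result.pairs
    ]


def _report_metrics(rep) -> dict[str, Any]:
    return {
        "accuracy": rep.accuracy,
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "per_fold_accuracies": list(rep.per_fold_accuracies),
        "fold_averaged_accuracy": rep.fold_averaged_accuracy,
        "n": rep.n,
        "single_class": rep.single_class,
    }


# ---------------------------------------------------------------------------
# The pipeline


def run_pipeline(
    config: RunConfig, outdir: str | Path | None = None
) -> dict[str, Any]:
    """Execute all stages; returns (and optionally writes) the run report."""
    seeds = config.stage_seeds()
    logger.info("run_pipeline: stage seeds %s", seeds)
    montage = standard_1020()
    stage = "simulate"
    try:
        specs = default_sources(config.latency_shift_ms, config.amplitude_scale)
        params = CohortParams(
            n_per_group=config.n_per_group,
            n_sources=len(specs),
            noise_sd=config.noise_sd,
            subject_latency_jitter_sd=config.subject_latency_jitter_sd,
            subject_amplitude_sd=config.subject_amplitude_sd,
            seed=seeds["simulate"],
        )
        if config.cohort_path:
            cohort = erpio.read_cohort(config.cohort_path)
            truth: GroundTruth | None = None
        else:
            cohort, truth = simulate_cohort(params, specs, montage)
        cohort = average_reference_cohort(cohort)

        report: dict[str, Any] = {
            "config": config.to_dict(),
            "stage_seeds": seeds,
            "n_subjects": cohort.n_subjects,
        }

        stage = "decompose/match"
        criteria = MatchCriteria(config.topo_r_min, config.curve_r_min)
        n_ics = {
            "continue": config.n_ics_continue,
            "discontinue": config.n_ics_discontinue,
        }
        decomps: dict[str, ICADecomposition] = {}
        match_tables: dict[str, Any] = {}
        for set_id in ("continue", "discontinue"):
            seed = seeds[f"ica_{set_id}"]
            d_ctrl = decompose_cohort(cohort.subset("control"), set_id,
                                      n_ics[set_id], seed, config.algorithm)
            d_case = decompose_cohort(cohort.subset("case"), set_id,
                                      n_ics[set_id], seed + 1, config.algorithm)
            match_tables[set_id] = _match_table(
                match_components(d_case, d_ctrl, criteria)
            )
            total = decompose_cohort(cohort, set_id, n_ics[set_id], seed + 2,
                                     config.algorithm)
            total = exclude_artifact_ics(
                total, [eog_template(montage)], config.artifact_r_threshold
            )
            if config.manual_exclude:
                keep = [i for i, lab in enumerate(total.ic_labels)
                        if lab not in config.manual_exclude]
                total = dataclasses.replace(
                    total,
                    topographies=total.topographies[:, keep],
                    filters=total.filters[np.asarray(keep, dtype=int)],
                    grand_activations={c: a[np.asarray(keep, dtype=int)]
                                       for c, a in total.grand_activations.items()},
                    sites=total.sites[np.asarray(keep, dtype=int)],
                    ic_labels=tuple(total.ic_labels[i] for i in keep),
                )
            decomps[set_id] = total
        report["match"] = match_tables
        report["exclusions"] = {
            s: [list(e) for e in d.exclusions] for s, d in decomps.items()
        }

        stage = "feature-extraction"
        twins = cross_set_twins(decomps["continue"], decomps["discontinue"],
                                config.topo_r_min)
        report["set_independent_pairs"] = [list(t) for t in twins]
        selections = make_selections(decomps, twins,
                                     config.condition_ratio_threshold)
        report["selections"] = {
            k: {"set_id": v["set_id"], "index": v["index"],
                "site": montage.labels[v["site"]],
                "conditions": list(v["conditions"])}
            for k, v in selections.items()
        }
        acts = collect_activations(cohort, decomps, selections)
        fm = build_feature_matrix(acts, config.template)
        report["n_features"] = fm.values.shape[1]

        stage = "classification"
        cv_config = CVConfig(n_folds=config.n_folds, seed=seeds["cv"])
        if config.nested:
            nested_rep, per_fold = nested_cv(
                fm, cv_config, config.k_max, config.tolerance,
                config.screen_top, config.final_grid,
            )
            report["nested_cv"] = _report_metrics(nested_rep)
            report["nested_cv"]["per_fold_selected"] = per_fold
        trace = forward_select(fm, config=cv_config, k_max=config.k_max,
                               tolerance=config.tolerance,
                               screen_top=config.screen_top)
        final_cfg = CVConfig(n_folds=config.n_folds, seed=seeds["cv"],
                             inner_grid=config.final_grid)
        model, final_rep = train_final(fm, trace.chosen_keys, final_cfg)
        report["selection_trace"] = [
            {"key": s.key, "accuracy": s.accuracy,
             "sensitivity": s.sensitivity, "specificity": s.specificity}
            for s in trace.steps
        ]
        report["chosen_k"] = trace.chosen_k
        report["cv"] = _report_metrics(final_rep)
        report["model"] = final_rep.model_desc

        stage = "validation"
        if config.validate and truth is not None:
            v_params = dataclasses.replace(params, seed=seeds["validation"])
            v_cohort, _ = simulate_cohort(
                v_params, specs, montage,
                group_sizes={"case": config.n_validation},
                mixing=truth.mixing,
            )
            v_cohort = average_reference_cohort(v_cohort)
            # frozen main-sample filters; only the model's features are needed,
            # but extracting the full grid keeps the path identical
            v_acts = collect_activations(v_cohort, decomps, selections)
            v_fm = build_feature_matrix(v_acts, config.template)
            v_rep = external_validate(model, v_fm)
            report["validation"] = _report_metrics(v_rep)

        if outdir is not None:
            stage = "persist"
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            for set_id, d in decomps.items():
                erpio.write_decomposition(d, outdir / f"decomposition_{set_id}")
            erpio.write_feature_matrix(fm, outdir / "features.csv")
            with open(outdir / "model.json", "w") as fh:
                json.dump(model.to_dict(), fh)
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=1, default=_json_default)
        return report
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
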