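"""End-to-end scenario orchestration.

A *scenario* is one cell of the study grid: which SNP panel feeds the
GBLUP (the selected whole-genome SNPs, the chip panel, their merge as
one relationship matrix, their merge as two relationship matrices, or
every simulated SNP) and which feature-selection strategy produced the
selected set (EN, LASSO, or the rank-by-p-value comparators LMM_EN /
LMM_LASSO that take the same number of SNPs from the GWAS ranking).

Each scenario runs QC -> reference/validation split -> (GWAS ->
selection) -> GRM construction -> reliability-weighted GBLUP on the
reference -> GRM-projection of GEBVs onto the validation set ->
accuracy/bias evaluation, with a manifest recording stages, seeds and
sizes.  A :class:`PipelineContext` caches the GWAS scan and feature
selections so the scenario grid re-uses them instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, PhenotypeTable
from .evaluate import evaluate_predictions, partition_population
from .featselect import (FeatureSet, RegularizationConfig, cv_select_1se,
                         top_n_by_pvalue)
from .gblup import aireml_fit, predict_validation, residual_weights
from .grm import grm_vanraden1
from .gwas import fit_loco_nulls, preselect_by_threshold, wald_scan
from .qc import QcThresholds, run_qc

__all__ = [
    "SCENARIO_NAMES",
    "Scenario",
    "MergedSets",
    "ScenarioReport",
    "PipelineContext",
    "merge_snp_sets",
    "run_scenario",
    "run_scenario_grid",
]

_LOG = logging.getLogger(__name__)

SCENARIO_NAMES = (
    "selected_only",
    "chip_only",
    "wgs_all",
    "chip_plus_selected_oneG",
    "chip_plus_selected_twoG",
)
_STRATEGIES = ("EN", "LASSO", "LMM_EN", "LMM_LASSO", "none")


@dataclass(frozen=True)
class Scenario:
    """One cell of the scenario grid."""

    name: str
    strategy: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        needs_selection = self.name not in ("chip_only", "wgs_all")
        if needs_selection and self.strategy == "none":
            raise ValueError(f"scenario {self.name!r} requires a strategy")
        if not needs_selection and self.strategy != "none":
            raise ValueError(f"scenario {self.name!r} takes strategy 'none'")


@dataclass
class MergedSets:
    """Union of chip and selected SNP sets with overlap bookkeeping."""

    union: np.ndarray
    overlap_count: int
    chip_minus_overlap: np.ndarray
    selected: np.ndarray


def merge_snp_sets(chip_set: np.ndarray, selected_set: np.ndarray) -> MergedSets:
    """Merge the chip panel with a selected-SNP set.

    Overlapping SNPs are removed from the chip side, so
    |union| = |chip| + |selected| - |overlap| holds exactly and the
    two-GRM scenario can use (chip - overlap) and selected separately.
    """
    chip = np.unique(np.asarray(chip_set))
    sel = np.unique(np.asarray(selected_set))
    overlap = np.intersect1d(chip, sel, assume_unique=True)
    chip_minus = np.setdiff1d(chip, overlap, assume_unique=True)
    union = np.union1d(chip, sel)
    if union.size == 0:
        raise ValueError("merging two empty SNP sets")
    return MergedSets(
        union=union,
        overlap_count=int(overlap.size),
        chip_minus_overlap=chip_minus,
        selected=sel,
    )


@dataclass
class PipelineContext:
    """Per-population cache shared by the scenarios of one run."""

    geno: GenotypeMatrix
    pheno: PhenotypeTable
    chip_indices: np.ndarray
    tbv: np.ndarray | None = None
    cutoff_year: int = 2013
    min_reliability: float = 0.40
    preselect_p: float = 0.05
    selection_config: RegularizationConfig | None = None
    qc_thresholds: QcThresholds | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        geno, qc_report = run_qc(
            self.geno, self.qc_thresholds or QcThresholds()
        )
        self._cache["qc_report"] = qc_report
        pheno = self.pheno.aligned_to(geno.ids)
        if self.tbv is not None:
            keep = {i: k for k, i in enumerate(self.pheno.ids)}
            self.tbv = np.asarray(self.tbv)[[keep[i] for i in geno.ids]]
        # QC may renumber SNP columns; map chip indices through retained ids
        retained = {s: j for j, s in enumerate(geno.snp_ids)}
        chip_ids = self.geno.snp_ids[np.asarray(self.chip_indices)]
        self.chip_indices = np.asarray(
            sorted(retained[s] for s in chip_ids if s in retained)
        )
        self.geno, self.pheno = geno, pheno
        ref_ids, val_ids = partition_population(
            pheno, self.cutoff_year, self.min_reliability
        )
        pos = {i: k for k, i in enumerate(geno.ids)}
        self.ref_idx = np.asarray([pos[i] for i in ref_ids])
        self.val_idx = np.asarray([pos[i] for i in val_ids])

    @property
    def qc_report(self):
        return self._cache["qc_report"]

    def gwas_result(self):
        """LOCO mixed-model scan on the reference population (cached)."""
        if "gwas" not in self._cache:
            geno_ref = self.geno.subset_individuals(self.ref_idx)
            y_ref = self.pheno.drp[self.ref_idx]
            nulls = fit_loco_nulls(geno_ref, y_ref, method="gcta_eq2")
            self._cache["gwas"] = wald_scan(geno_ref, y_ref, nulls)
        return self._cache["gwas"]

    def preselected(self) -> np.ndarray:
        if "preselected" not in self._cache:
            self._cache["preselected"] = preselect_by_threshold(
                self.gwas_result(), self.preselect_p
            )
        return self._cache["preselected"]

    def feature_set(self, strategy: str, seed: int = 0) -> FeatureSet:
        """Selected SNPs (global indices) for a strategy, cached."""
        key = ("select", strategy, seed)
        if key in self._cache:
            return self._cache[key]
        cfg = self.selection_config or RegularizationConfig(fold_seed=seed)
        if strategy in ("EN", "LASSO"):
            pre = self.preselected()
            if pre.size == 0:
                raise ValueError("GWAS pre-selection returned no SNPs")
            geno_ref = self.geno.subset_individuals(self.ref_idx)
            X = np.nan_to_num(geno_ref.codes[:, pre], nan=0.0)
            y = self.pheno.drp[self.ref_idx]
            fs = cv_select_1se(
                X, y, cfg, mode="lasso" if strategy == "LASSO" else "en"
            )
            fs = FeatureSet(
                snp_indices=pre[fs.snp_indices],
                coefficients=fs.coefficients,
                strategy=strategy,
                alpha=fs.alpha,
                lam=fs.lam,
                cv_curves=fs.cv_curves,
            )
        elif strategy in ("LMM_EN", "LMM_LASSO"):
            paired = self.feature_set(strategy.removeprefix("LMM_"), seed)
            if paired.n_selected == 0:
                raise ValueError(
                    f"paired {strategy} selection is empty; no size to match"
                )
            fs = top_n_by_pvalue(
                self.gwas_result(), paired.n_selected, strategy=strategy
            )
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        self._cache[key] = fs
        return fs


@dataclass
class ScenarioReport:
    scenario: Scenario
    accuracy: float
    bias: float
    n_validation: int
    n_snps_used: int
    n_selected: int
    overlap_count: int
    variance_components: list
    sigma2_e: float
    converged: bool
    n_iter: int
    tbv_correlation: float | None
    stages: list
    manifest: dict

    def to_json(self) -> str:
        payload = dict(
            scenario=self.scenario.name,
            strategy=self.scenario.strategy,
            seed=self.scenario.seed,
            accuracy=self.accuracy,
            bias=self.bias,
            n_validation=self.n_validation,
            n_snps_used=self.n_snps_used,
            n_selected=self.n_selected,
            overlap_count=self.overlap_count,
            variance_components=self.variance_components,
            sigma2_e=self.sigma2_e,
            converged=self.converged,
            n_iter=self.n_iter,
            tbv_correlation=self.tbv_correlation,
            stages=self.stages,
            manifest=self.manifest,
        )
        return json.dumps(payload, sort_keys=True, indent=2)


def _config_hash(ctx: PipelineContext, scenario: Scenario) -> str:
    blob = json.dumps(
        dict(
            scenario=scenario.name, strategy=scenario.strategy,
            seed=scenario.seed, cutoff=ctx.cutoff_year,
            min_rel=ctx.min_reliability, p=ctx.preselect_p,
            n_ind=ctx.geno.n_individuals, n_snp=ctx.geno.n_snps,
            chip=int(ctx.chip_indices.size),
        ),
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_scenario(
    scenario: Scenario,
    ctx: PipelineContext,
    workdir: str | None = None,
    feature_set_override: np.ndarray | None = None,
    max_iter: int = 1000,
) -> ScenarioReport:
    """Execute one scenario end-to-end and evaluate on the validation set.

    ``feature_set_override`` substitutes an explicit set of (global)
    SNP indices for the strategy's selection — used for random-panel
    baselines.  Two-GRM non-convergence is reported in the result, not
    raised.
    """
    t0 = time.time()
    stages = ["qc", "partition"]
    sel_idx = np.empty(0, dtype=int)
    overlap = 0
    if scenario.name in ("selected_only", "chip_plus_selected_oneG",
                         "chip_plus_selected_twoG"):
        if feature_set_override is not None:
            sel_idx = np.asarray(feature_set_override, dtype=int)
            stages.append("selection(override)")
        else:
            stages += ["gwas", "selection"]
            sel_idx = ctx.feature_set(scenario.strategy, scenario.seed).snp_indices

    grm_subsets: list[np.ndarray]
    if scenario.name == "selected_only":
        if sel_idx.size == 0:
            raise ValueError("selected_only scenario with an empty SNP set")
        grm_subsets = [sel_idx]
    elif scenario.name == "chip_only":
        grm_subsets = [ctx.chip_indices]
    elif scenario.name == "wgs_all":
        grm_subsets = [np.arange(ctx.geno.n_snps)]
    else:
        merged = merge_snp_sets(ctx.chip_indices, sel_idx)
        overlap = merged.overlap_count
        if scenario.name == "chip_plus_selected_oneG":
            grm_subsets = [merged.union]
        else:  # two GRMs: chip-minus-overlap and selected
            if merged.selected.size == 0:
                raise ValueError("two-GRM scenario with an empty selected set")
            grm_subsets = [merged.chip_minus_overlap, merged.selected]
    stages.append("grm")
    grms = [grm_vanraden1(ctx.geno, subset) for subset in grm_subsets]

    stages.append("gblup")
    r2 = ctx.pheno.reliability
    w_ref = residual_weights(r2[ctx.ref_idx])
    y_ref = ctx.pheno.drp[ctx.ref_idx]
    sub = np.ix_(ctx.ref_idx, ctx.ref_idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence is reported below
        fit = aireml_fit(
            y_ref, [g.matrix[sub] for g in grms], weights=w_ref,
            max_iter=max_iter,
        )
    gebv_val = predict_validation(
        fit, grms, y_ref, ctx.ref_idx, ctx.val_idx, weights_ref=w_ref
    )

    stages.append("evaluate")
    report = evaluate_predictions(
        ctx.pheno.drp[ctx.val_idx], gebv_val, r2[ctx.val_idx]
    )
    tbv_corr = None
    if ctx.tbv is not None and np.std(ctx.tbv[ctx.val_idx]) > 0:
        tbv_corr = float(np.corrcoef(gebv_val, ctx.tbv[ctx.val_idx])[0, 1])

    n_used = int(sum(g.snp_subset.size for g in grms))
    manifest = dict(
        config_hash=_config_hash(ctx, scenario),
        seed=scenario.seed,
        n_reference=int(ctx.ref_idx.size),
        n_validation=int(ctx.val_idx.size),
        grm_sizes=[int(g.snp_subset.size) for g in grms],
    )
    # timing goes to the log, never the manifest (reports stay byte-identical)
    _LOG.info("scenario %s/%s finished in %.2fs", scenario.name,
              scenario.strategy, time.time() - t0)
    result = ScenarioReport(
        scenario=scenario,
        accuracy=report.accuracy,
        bias=report.bias,
        n_validation=report.n_validation,
        n_snps_used=n_used,
        n_selected=int(sel_idx.size),
        overlap_count=overlap,
        variance_components=[float(v) for v in fit.variance_components],
        sigma2_e=fit.sigma2_e,
        converged=fit.converged,
        n_iter=fit.n_iter,
        tbv_correlation=tbv_corr,
        stages=stages,
        manifest=manifest,
    )
    if workdir is not None:
        os.makedirs(workdir, exist_ok=True)
        out = os.path.join(
            workdir, f"{scenario.name}_{scenario.strategy}.json"
        )
        with open(out, "w") as fh:
            fh.write(result.to_json())
    return result


def run_scenario_grid(
    ctx: PipelineContext,
    strategy: str = "EN",
    seed: int = 0,
    workdir: str | None = None,
    max_iter: int = 1000,
) -> dict[str, ScenarioReport]:
    """All five scenarios for one selection strategy."""
    reports = {}
    for name in SCENARIO_NAMES:
        strat = "none" if name in ("chip_only", "wgs_all") else strategy
        sc = Scenario(name=name, strategy=strat, seed=seed)
        reports[name] = run_scenario(sc, ctx, workdir=workdir,
                                     max_iter=max_iter)
    return reports
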