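"""End-to-end pipeline: cohort -> preprocessing -> ROI FC -> integration ->
seed maps -> thresholding -> consistency -> group statistics -> behavior
correlations, with provenance capture.

Each stage is also available as a library function; this module wires them
in the fixed analysis order and writes the result bundle.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_atlas, extract_signals
from .behavior import phenotype_summary
from .cohort import Cohort, CohortConfig, generate_cohort
from .connectivity import (
    integration_score,
    pairwise_fc,
    seed_map,
    threshold_map,
)
from .group import (
    consistency_map,
    edgewise_group_test,
    pearson_with_p,
    two_sample_t,
)
from .preprocess import PreprocessConfig, preprocess_run

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    Either ``cohort`` (an in-memory config for the synthetic generator) or
    ``cohort_dir`` (a manifest directory written by ``write_cohort``) supplies
    the input data.  ``seed_rois`` restricts the voxel-wise seed-map stage to
    selected ROI labels (e.g. ["L3", "L10"]); None means all 20.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alpha: float = 0.05
    cluster_k: int = 20
    connectivity_rule: int = 26
    extent_op: str = ">"
    do_seed_maps: bool = True
    seed_rois: list[str] | None = None
    correlation_group: str = "expert"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            cdict = dict(kwargs["cohort"])
            if "grid" in cdict:
                from .grid import GridSpec

                cdict["grid"] = GridSpec(**cdict["grid"])
            kwargs["cohort"] = CohortConfig(**cdict)
        if "preprocess" in kwargs:
            pdict = dict(kwargs["preprocess"])
            if "band_hz" in pdict:
                pdict["band_hz"] = tuple(pdict["band_hz"])
            kwargs["preprocess"] = PreprocessConfig(**pdict)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    cohort: Cohort
    integration: pd.DataFrame
    fc_matrices: list
    edge_tests: pd.DataFrame
    group_tests: pd.DataFrame
    correlations: pd.DataFrame
    consistency: dict
    phenotypes: dict
    provenance: dict


def _integration_table(scores, phenotypes) -> pd.DataFrame:
    group_of = {p.subject_id: p.group for p in phenotypes}
    at_of = {p.subject_id: p.at_hours_per_week for p in phenotypes}
    rows = [
        {
            "subject_id": s.subject_id,
            "group": group_of[s.subject_id],
            "hemisphere": s.hemisphere,
            "r": s.r_value,
            "z": s.z_value,
            "at_hours_per_week": at_of[s.subject_id],
        }
        for s in scores
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; deterministic given (inputs, config, seed)."""
    from statsmodels.stats.multitest import multipletests

    if config.cohort_dir is not None:
        from . import io as io_mod

        cohort = io_mod.read_cohort(config.cohort_dir)
        log.info("loaded cohort of %d subjects from %s", len(cohort.runs), config.cohort_dir)
    else:
        cohort = generate_cohort(config.cohort)
        log.info("generated cohort of %d subjects (seed=%d)",
                 len(cohort.runs), config.cohort.seed)

    grid = cohort.runs[0].grid if cohort.runs else cohort.config.grid
    atlas = build_atlas(cohort.config.roi_table, grid)
    roi_by_label = {roi.label: roi for roi in atlas}
    seed_labels = config.seed_rois or list(roi_by_label)
    unknown = [lbl for lbl in seed_labels if lbl not in roi_by_label]
    if unknown:
        raise ValueError(f"unknown seed ROI labels {unknown}")

    scores, fc_matrices = [], []
    masks: dict[tuple[str, str], list] = {}
    for run, conf, pheno in zip(cohort.runs, cohort.confounds, cohort.phenotypes):
        try:
            clean, conf_used = preprocess_run(run, conf, config.preprocess)
            signals = extract_signals(clean, atlas)
            fc_matrices.append((pheno.group, pairwise_fc(signals)))
            for hemi in ("L", "R"):
                scores.append(integration_score(signals, hemi))
            if config.do_seed_maps:
                for lbl in seed_labels:
                    roi = roi_by_label[lbl]
                    smap = seed_map(clean, signals.signals[roi.roi_id], conf_used, roi=roi)
                    smap.sig_mask = threshold_map(
                        smap.p_map, alpha=config.alpha, k=config.cluster_k,
                        connectivity_rule=config.connectivity_rule,
                        extent_op=config.extent_op,
                    )
                    masks.setdefault((pheno.group, lbl), []).append(smap.sig_mask)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage failed for subject {run.subject_id}: {err}"
            ) from err

    integration = _integration_table(scores, cohort.phenotypes)

    # group-level statistics
    group_rows = []
    for hemi in ("L", "R"):
        sub = integration[integration["hemisphere"] == hemi]
        res = two_sample_t(
            sub[sub["group"] == "expert"]["z"],
            sub[sub["group"] == "amateur"]["z"],
            contrast=f"integration_{hemi}: expert vs amateur",
        )
        group_rows.append({"contrast": res.contrast, "hemisphere": hemi, "t": res.t,
                           "df": res.df, "p": res.p,
                           "mean_expert_z": res.mean_a, "mean_amateur_z": res.mean_b})
    group_tests = pd.DataFrame(group_rows)
    reject, qvals, *_ = multipletests(group_tests["p"], alpha=config.alpha, method="fdr_bh")
    group_tests["q"] = qvals
    group_tests["significant"] = reject

    fc_e = [m for g, m in fc_matrices if g == "expert"]
    fc_a = [m for g, m in fc_matrices if g == "amateur"]
    edge_tests = (edgewise_group_test(fc_e, fc_a, alpha=config.alpha)
                  if len(fc_e) >= 2 and len(fc_a) >= 2 else pd.DataFrame())

    # behavior: correlations within the configured group (default experts)
    corr_rows = []
    sel = integration[integration["group"] == config.correlation_group]
    for hemi in ("L", "R"):
        sub = sel[sel["hemisphere"] == hemi]
        if len(sub) >= 3 and sub["z"].std() > 0 and sub["at_hours_per_week"].std() > 0:
            res = pearson_with_p(sub["z"], sub["at_hours_per_week"],
                                 pair=f"integration_{hemi} vs AT ({config.correlation_group})")
            corr_rows.append({"pair": res.pair, "r": res.r, "n": res.n, "p": res.p})
    gmv_key = "long_insular_gyrus_central_sulcus_L"
    gmv_map = {p.subject_id: p.gmv_mm3[gmv_key] for p in cohort.phenotypes
               if p.gmv_mm3 and gmv_key in p.gmv_mm3}
    if gmv_map:
        sub = sel[sel["hemisphere"] == "L"]
        sub = sub[sub["subject_id"].isin(gmv_map)]
        if len(sub) >= 3:
            gmv_vals = sub["subject_id"].map(gmv_map)
            for other, label in (("z", "integration_L"), ("at_hours_per_week", "AT")):
                res = pearson_with_p(gmv_vals, sub[other],
                                     pair=f"GMV {gmv_key} vs {label} ({config.correlation_group})")
                corr_rows.append({"pair": res.pair, "r": res.r, "n": res.n, "p": res.p})
    correlations = pd.DataFrame(corr_rows)

    consistency = {}
    for (group, lbl), mask_list in masks.items():
        consistency[(group, lbl)] = consistency_map(
            mask_list, n_subjects=len(mask_list), group=group,
            roi_id=roi_by_label[lbl].roi_id,
        )

    phenos = phenotype_summary(cohort.phenotypes)

    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cohort.config.seed,
        "n_expert": cohort.config.n_expert,
        "n_amateur": cohort.config.n_amateur,
        "preprocess": asdict(config.preprocess),
        "alpha": config.alpha,
        "cluster_k": config.cluster_k,
        "connectivity_rule": config.connectivity_rule,
        "extent_op": config.extent_op,
        "seed_rois": seed_labels if config.do_seed_maps else [],
    }

    result = PipelineResult(
        cohort=cohort,
        integration=integration,
        fc_matrices=[m for _, m in fc_matrices],
        edge_tests=edge_tests,
        group_tests=group_tests,
        correlations=correlations,
        consistency=consistency,
        phenotypes=phenos,
        provenance=provenance,
    )
    if config.out_dir is not None:
        _write_results(result, config)
    return result


def _write_results(result: PipelineResult, config: PipelineConfig) -> None:
    from . import io as io_mod

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.integration.to_csv(out / "integration.tsv", sep="\t", index=False,
                              float_format="%.10g")
    result.group_tests.to_csv(out / "group_tests.tsv", sep="\t", index=False,
                              float_format="%.10g")
    if len(result.edge_tests):
        result.edge_tests.to_csv(out / "edge_tests.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    if len(result.correlations):
        result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False,
                                   float_format="%.10g")
    result.phenotypes["summary"].to_csv(out / "phenotype_summary.tsv", sep="\t",
                                        index=False, float_format="%.10g")
    result.phenotypes["tests"].to_csv(out / "phenotype_tests.tsv", sep="\t",
                                      index=False, float_format="%.10g")
    grid = result.cohort.runs[0].grid if result.cohort.runs else result.cohort.config.grid
    for (group, lbl), cmap in result.consistency.items():
        io_mod.save_volume(cmap.values, grid, out / f"consistency_{group}_{lbl}.nii")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, default=str)
    log.info("wrote result bundle to %s", out)
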