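"""End-to-end study analysis: simulate/read -> exclude -> bin -> normalize ->
{glog branch -> univariate tables; Pareto branch -> PCA screen -> OPLS-DA ->
permutation -> pseudo-spectra} -> SUS -> networks -> report.

All stage randomness derives from one master seed by fixed offsets, so a
rerun with an identical configuration is bit-identical and stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from . import io as nio
from .chemometrics import fit_opls_da, fit_pca, flag_outliers
from .comparative import (
    correlation_network,
    filter_network_by_sus,
    network_edge_table,
    sus_plot,
    venn_categorize,
)
from .containers import FeatureMatrix
from .preprocess import (
    BinningConfig,
    DEFAULT_WATER_REGION,
    aggregate_to_metabolites,
    ai_bin,
    estimate_noise_sd,
    exclude_regions,
    glog_transform,
    normalize_total_area,
    pareto_scale,
)
from .synthetic import StudyDesign, make_default_library, simulate_study
from .univariate import fold_change_table, lesion_summary, render_color_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

# seed offsets per stage, so stages are independently reproducible
_SEED_SIM = 0
_SEED_CV = 1009
_SEED_PERM = 2003


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved configuration for one tissue's analysis.

    ``comparisons`` are ordered (case, reference) group pairs; the SUS stage
    pairs up the first two comparisons that share a reference class.
    """

    spectra_path: str | None = None
    metadata_path: str | None = None
    design: StudyDesign | None = None
    exclusion_regions: list[tuple[float, float]] = field(
        default_factory=lambda: [DEFAULT_WATER_REGION]
    )
    binning: BinningConfig = field(default_factory=BinningConfig)
    normalization_target: float = 100.0
    glog_lambda: float | None = None  # None: noise-region estimate squared
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("model", "control"), ("CNC", "model"), ("JHC", "model")]
    )
    n_orthogonal: int = 1
    cv_folds: int = 7
    n_permutations: int = 2000
    sus_threshold: float = 0.5
    network_threshold: float = 0.6
    outlier_alpha: float = 0.05
    remove_outliers: bool = True
    aggregation_tolerance: float = 0.015
    lesion_counts: dict[str, tuple[int, int, int]] | None = None
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if not 0 < self.sus_threshold <= 1:
            raise ValueError("SUS threshold must be in (0, 1]")
        if not 0 < self.network_threshold < 1:
            raise ValueError("network threshold must be in (0, 1)")
        if not 0 < self.outlier_alpha < 1:
            raise ValueError("outlier alpha must be in (0, 1)")

    def resolved_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.design is not None:
            dd = dataclasses.asdict(self.design)
            dd["effects"] = self.design.effects.to_dict()
            d["design"] = dd
        d["binning"] = dataclasses.asdict(self.binning)
        return d


def _validate(config: PipelineConfig, groups: set) -> None:
    for case, ref in config.comparisons:
        for g in (case, ref):
            if g not in groups:
                raise PipelineError(
                    "validate", f"comparison group {g!r} not among study groups {sorted(groups)}"
                )


def run_pipeline(config: PipelineConfig, output_dir) -> dict:
    """Run the full analysis; writes stage outputs and returns the report dict."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.resolved_dict(), "stages": {}, "models": {}}
    library = make_default_library()

    # ------------------------------------------------------------------ input
    if config.design is not None:
        design = dataclasses.replace(config.design, seed=config.seed + _SEED_SIM)
        spectra, truth = simulate_study(design, library)
        truth.rename_axis("sample_id").to_csv(out / "ground_truth_concentrations.csv")
        nio.write_spectra(spectra, out / "spectra.csv", out / "sample_metadata.csv")
    elif config.spectra_path and config.metadata_path:
        spectra = nio.read_spectra(config.spectra_path, config.metadata_path)
    else:
        raise PipelineError("input", "need either a simulation design or input paths")
    groups = set(spectra.groups)
    _validate(config, groups)
    report["stages"]["input"] = {
        "n_samples": spectra.n_samples,
        "groups": {g: int((spectra.groups == g).sum()) for g in sorted(groups)},
    }

    # ------------------------------------------------------------- preprocess
    try:
        noise_sd = estimate_noise_sd(spectra, config.binning.noise_region)
        retained = exclude_regions(spectra, config.exclusion_regions)
        bins = ai_bin(retained, config.binning)
    except ValueError as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    nio.write_bin_table(bins, out / "bin_definitions.csv", out / "bin_integrals.csv")
    fm_bins = normalize_total_area(bins, config.normalization_target)
    lam = config.glog_lambda if config.glog_lambda is not None else noise_sd**2
    fm_metab = aggregate_to_metabolites(fm_bins, library, config.aggregation_tolerance)
    nio.write_feature_matrix(fm_metab, out / "metabolite_features.csv")
    report["stages"]["preprocess"] = {
        "n_bins": bins.n_bins,
        "n_metabolite_features": len(fm_metab.feature_names),
        "noise_sd": noise_sd,
        "glog_lambda": lam,
    }

    # ------------------------------------------- Pareto branch: PCA screening
    fm_pareto = pareto_scale(fm_metab)
    pca = fit_pca(fm_pareto, n_components=2)
    outliers = flag_outliers(pca, config.outlier_alpha)
    report["stages"]["pca_screen"] = {
        "outliers": list(outliers),
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
    }
    if outliers and config.remove_outliers:
        keep = [s for s in fm_metab.sample_ids if s not in set(outliers)]
        fm_metab = FeatureMatrix(
            values=fm_metab.values.loc[keep],
            metadata=fm_metab.metadata.loc[keep],
            normalized=fm_metab.normalized,
        )

    # ------------------------------------------------- glog branch: univariate
    fm_glog = glog_transform(fm_metab, lam)
    fct = fold_change_table(fm_metab, fm_glog, config.comparisons)
    colored = render_color_table(fct)
    colored.to_csv(out / "fold_change_table.csv")
    if config.make_plots:
        from .plotting import color_table_figure

        fig = color_table_figure(colored)
        fig.savefig(out / "fold_change_table.png", dpi=150)

    # ------------------------------------------------------- OPLS-DA per pair
    fm_model = pareto_scale(fm_metab)
    results = {}
    for case, ref in config.comparisons:
        name = f"{case}_vs_{ref}"
        try:
            res = fit_opls_da(
                fm_model, groups=(case, ref), n_orthogonal=config.n_orthogonal,
                positive_class=case,
            )
        except ValueError as exc:
            raise PipelineError(f"opls:{name}", str(exc)) from exc
        res.q2(folds=config.cv_folds, seed=config.seed + _SEED_CV)
        res.permutation_test(
            n_permutations=config.n_permutations,
            seed=config.seed + _SEED_PERM,
            folds=config.cv_folds,
        )
        results[name] = res
        nio.write_json(res.to_dict(), out / f"opls_{name}.json")
        res.pseudospectrum().to_csv(out / f"pseudospectrum_{name}.csv", index=False)
        report["models"][name] = {
            "r2y": res.r2y,
            "q2y": res.q2y,
            "permutation_p": res.permutation_p,
            "n_orthogonal": res.n_orthogonal,
        }
        if config.make_plots:
            from .plotting import pseudospectrum_plot, score_plot

            score_plot(res).savefig(out / f"scores_{name}.png", dpi=150)
            pseudospectrum_plot(res.pseudospectrum()).savefig(
                out / f"pseudospectrum_{name}.png", dpi=150
            )

    # ---------------------------------------------------------------- SUS
    sus = None
    by_ref: dict[str, list[str]] = {}
    for case, ref in config.comparisons:
        by_ref.setdefault(ref, []).append(f"{case}_vs_{ref}")
    sus_pair = next((v[:2] for v in by_ref.values() if len(v) >= 2), None)
    if sus_pair:
        res_a, res_b = results[sus_pair[0]], results[sus_pair[1]]
        sus = sus_plot(res_a, res_b, config.sus_threshold)
        sus.rename_axis("feature").to_csv(out / "sus_table.csv")
        venn = venn_categorize(sus)
        nio.write_json(
            {
                "A_only": sorted(venn["A_only"]),
                "B_only": sorted(venn["B_only"]),
                "shared": {k: list(v) for k, v in venn["shared"].items()},
                "models": sus_pair,
            },
            out / "sus_venn.json",
        )
        report["stages"]["sus"] = {
            "models": sus_pair,
            "n_shared": len(venn["shared"]),
            "n_unique_A": len(venn["A_only"]),
            "n_unique_B": len(venn["B_only"]),
        }
        if config.make_plots:
            from .plotting import sus_scatter

            sus_scatter(sus).savefig(out / "sus_plot.png", dpi=150)

    # ------------------------------------------------------------- networks
    report["stages"]["networks"] = {}
    for group in sorted(groups):
        if (fm_metab.groups == group).sum() < 4:
            continue
        net = correlation_network(fm_metab, group=group, threshold=config.network_threshold)
        if sus is not None:
            net = filter_network_by_sus(net, sus)
        network_edge_table(net).to_csv(out / f"network_{group}.csv", index=False)
        nx.write_graphml(net, out / f"network_{group}.graphml")
        report["stages"]["networks"][group] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
        }
        if config.make_plots and net.number_of_nodes():
            from .plotting import network_plot

            network_plot(net, seed=config.seed).savefig(
                out / f"network_{group}.png", dpi=150
            )

    # ------------------------------------------------------------- lesions
    if config.lesion_counts:
        summary = lesion_summary(config.lesion_counts)
        summary.table.rename_axis("group").to_csv(out / "lesion_summary.csv")
        report["stages"]["lesions"] = summary.table.to_dict()

    nio.write_json(report, out / "report.json")
    return report
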