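"""Stage orchestration: morphometrics -> diet -> growth, JSON results.

Results are serialized as JSON with numbers rounded to 10 significant
digits and sorted keys, so identical seed + inputs produce byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diet as diet_mod, morphometrics as mm
from .growth import compare_growth, fit_backcalc
from .tables import read_diet_table, read_growth_table, read_trait_table
from .tps import read_tps
from .types import MORPHS, AnalysisConfig, LandmarkSet

log = logging.getLogger("morphdiverge")


def _round_sig(x, sig: int = 10):
    """Recursively round floats to ``sig`` significant digits for JSON."""
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if not np.isfinite(x):
            return None
        if x == 0.0:
            return 0.0
        return float(f"{x:.{sig}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _round_sig(x.tolist(), sig)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def write_results_json(results: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_sig(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_morphometrics(
    landmarks: list[LandmarkSet], traits: pd.DataFrame, config: AnalysisConfig
) -> dict:
    """Superimpose, correct for allometry, cluster and discriminate.

    Following the field protocol, morphs are first identified by UPGMA on
    the combined feature set (seven linear traits + first shape PCs); the
    discriminant analysis is then run on the cluster-defined groups. When
    the trait table carries a prior morph column, cluster agreement with
    it is reported.
    """
    order = {s.specimen_id: s for s in landmarks}
    missing = [sid for sid in traits["specimen_id"] if sid not in order]
    if missing:
        raise ValueError(f"trait table specimens missing from TPS file: {missing[:5]}")
    sets = [order[sid] for sid in traits["specimen_id"]]

    shapes = mm.gpa(sets)
    allom = mm.allometry_residuals(shapes, size_transform=config.allometry_size)
    pca = mm.shape_pca(allom.residuals)
    features, names = mm.feature_matrix(
        traits, pca, n_pcs=config.n_pcs, standardize=config.standardize_features
    )
    clusters = mm.upgma(features, metric=config.distance_metric)

    results: dict = {
        "n_specimens": len(sets),
        "gpa": {
            "iterations": shapes.iterations,
            "converged": shapes.converged,
            "mean_centroid_size": float(shapes.centroid_sizes.mean()),
        },
        "allometry": {
            "size_transform": allom.size_transform,
            "pct_shape_variance_explained_by_size": allom.pct_variance_explained,
        },
        "pca_variance_explained": pca.variance_explained[: max(config.n_pcs, 5)],
        "feature_names": names,
        "cluster_sizes": np.bincount(clusters.labels)[1:].tolist(),
    }

    known = traits["morph"].to_numpy() if "morph" in traits.columns else None
    if known is not None and set(pd.unique(known)) == set(MORPHS):
        results["cluster_agreement_with_morph_labels"] = mm.cluster_agreement(
            clusters.labels, known
        )
        # name clusters by majority morph
        lab1 = pd.Series(known[clusters.labels == 1]).mode().iloc[0]
        lab2 = MORPHS[1] if lab1 == MORPHS[0] else MORPHS[0]
        cluster_morphs = np.where(clusters.labels == 1, lab1, lab2)
    else:
        cluster_morphs = np.where(clusters.labels == 1, "morph_1", "morph_2")
    results["cluster_morphs"] = pd.Series(cluster_morphs).value_counts().to_dict()

    if len(np.unique(cluster_morphs)) == 2 and min(np.bincount(clusters.labels)[1:]) >= 2:
        dfa = mm.lda_two_group(features, cluster_morphs)
        results["dfa_features"] = {
            "wilks_lambda": dfa.wilks_lambda,
            "jackknife_pct": {str(k): v for k, v in dfa.jackknife_pct.items()},
            "confusion": dfa.confusion,
            "groups": [str(g) for g in dfa.group_names],
        }
        # shape-only DFA: allometry-corrected Procrustes coordinates
        # projected onto enough PCs for a nonsingular within-covariance
        cum = np.cumsum(pca.variance_explained)
        n_keep = int(np.searchsorted(cum, 0.95) + 1)
        n_keep = min(n_keep, pca.scores.shape[1], len(sets) - 3)
        dfa_shape = mm.lda_two_group(pca.scores[:, :n_keep], cluster_morphs)
        results["dfa_shape"] = {
            "wilks_lambda": dfa_shape.wilks_lambda,
            "n_pcs_used": n_keep,
            "jackknife_pct": {str(k): v for k, v in dfa_shape.jackknife_pct.items()},
        }
        manova = mm.manova_and_posthoc(features, cluster_morphs, names)
        results["manova"] = manova
        if "parasite" in traits.columns and traits["parasite"].nunique() > 1:
            results["parasite_ancova"] = {
                name: mm.ancova_covariate(
                    features[:, j],
                    cluster_morphs,
                    traits["parasite"].to_numpy().astype(float),
                )
                for j, name in enumerate(names)
            }
    if "sex" in traits.columns and traits["sex"].nunique() == 2:
        results["sex_ttests"] = mm.sex_ttests(
            features, traits["sex"].to_numpy(), names
        ).to_dict(orient="records")

    results["_arrays"] = {
        "pc_scores": pca.scores[:, : config.n_pcs],
        "specimen_id": traits["specimen_id"].tolist(),
        "cluster_labels": clusters.labels,
        "group_means": mm.mean_shape_by_group(shapes, cluster_morphs),
    }
    return results


def run_diet(diet: pd.DataFrame, config: AnalysisConfig) -> dict:
    morphs = sorted(diet["morph"].unique())
    compositions = {m: diet_mod.diet_composition(diet, m) for m in morphs}
    results: dict = {
        "compositions": {
            m: {
                "n_guts_with_food": c.n_total,
                "total_weight_g": c.w_total,
                "F_pct": c.f_pct.to_dict(),
                "W_pct": c.w_pct.to_dict(),
            }
            for m, c in compositions.items()
        }
    }
    if len(morphs) == 2:
        overlap = diet_mod.overlap_from_table(diet, basis="pooled")
        results["schoener_overlap"] = {
            "C_xy": overlap.c_xy,
            "biologically_significant": overlap.significant,
            "threshold": diet_mod.OVERLAP_THRESHOLD,
        }
        results["kruskal_wallis"] = diet_mod.category_tests(diet).to_dict(
            orient="records"
        )
    results["_compositions"] = compositions
    return results


def run_growth(growth: pd.DataFrame, config: AnalysisConfig) -> dict:
    results: dict = {"df_convention": config.arss_df_convention}
    results["backcalc"] = {
        m: asdict(fit_backcalc(growth, group=m))
        for m in sorted(growth["morph"].unique())
    }
    comparisons = {}
    if growth["morph"].nunique() == 2:
        comparisons["morphs_both_sexes"] = compare_growth(
            growth, "morph", config.arss_df_convention
        )
        for sex in sorted(growth["sex"].unique()):
            sub = growth[growth["sex"] == sex]
            if sub["morph"].nunique() == 2:
                try:
                    comparisons[f"morphs_{sex}"] = compare_growth(
                        sub, "morph", config.arss_df_convention
                    )
                except ValueError as exc:
                    log.warning("skipping morph comparison for sex %s: %s", sex, exc)
    for m in sorted(growth["morph"].unique()):
        sub = growth[growth["morph"] == m]
        if sub["sex"].nunique() == 2:
            try:
                comparisons[f"sexes_{m}"] = compare_growth(
                    sub, "sex", config.arss_df_convention
                )
            except ValueError as exc:
                log.warning("skipping sex comparison within %s: %s", m, exc)
    for name, comp in comparisons.items():
        arss = comp["arss"]
        results[name] = {
            "fits": {
                str(g): asdict(f) for g, f in comp["fits"].items()
            },
            "pooled_fit": asdict(comp["pooled_fit"]),
            "arss": asdict(arss),
        }
    results["_comparisons"] = comparisons
    return results


# ---------------------------------------------------------------------------
# Whole pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: AnalysisConfig, inputs: dict) -> dict:
    """Run the configured stages and write JSON results, tables and figures.

    ``inputs`` maps stage inputs to paths or in-memory objects:
    ``tps`` (path or list of LandmarkSet), ``traits``/``diet``/``growth``
    (paths or DataFrames). All inputs for the configured stages are
    validated before any stage runs; any stage failure aborts with the
    stage name and cause.
    """
    from . import plots

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    needed = {"morpho": ("tps", "traits"), "diet": ("diet",), "growth": ("growth",)}
    loaded: dict = {}
    for stage in config.stages:
        for key in needed[stage]:
            if key not in inputs:
                raise FileNotFoundError(f"stage {stage!r} requires input {key!r}")
            value = inputs[key]
            if isinstance(value, (str, Path)):
                if not Path(value).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r}: input file {value} does not exist"
                    )
        # load after existence checks
    for stage in config.stages:
        for key in needed[stage]:
            value = inputs[key]
            if isinstance(value, (str, Path)):
                reader = {
                    "tps": read_tps,
                    "traits": read_trait_table,
                    "diet": read_diet_table,
                    "growth": read_growth_table,
                }[key]
                loaded[key] = reader(value)
            else:
                loaded[key] = value

    report: dict = {
        "config": {
            "seed": config.random_seed,
            "stages": list(config.stages),
            "distance_metric": config.distance_metric,
            "standardize_features": config.standardize_features,
            "allometry_size": config.allometry_size,
            "arss_df_convention": config.arss_df_convention,
            "n_pcs": config.n_pcs,
        },
        "versions": {
            "morphdiverge": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    log.info("pipeline seed=%s stages=%s", config.random_seed, config.stages)

    stage_runners = {
        "morpho": lambda: run_morphometrics(loaded["tps"], loaded["traits"], config),
        "diet": lambda: run_diet(loaded["diet"], config),
        "growth": lambda: run_growth(loaded["growth"], config),
    }
    for stage in config.stages:
        try:
            report[stage] = stage_runners[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # figures and side tables from the non-serializable payloads
    if "morpho" in report:
        arrays = report["morpho"].pop("_arrays")
        pd.DataFrame(
            arrays["pc_scores"],
            columns=[f"PC{i + 1}" for i in range(arrays["pc_scores"].shape[1])],
        ).assign(
            specimen_id=arrays["specimen_id"], cluster=arrays["cluster_labels"]
        ).to_csv(out_dir / "pc_scores.csv", index=False)
        plots.shape_difference_plot(
            arrays["group_means"]["means"], out_dir / "shape_difference.svg"
        )
    if "diet" in report:
        comps = report["diet"].pop("_compositions")
        plots.diet_composition_plot(
            {m: c.w_pct for m, c in comps.items()}, out_dir / "diet_composition.svg"
        )
    if "growth" in report:
        comps = report["growth"].pop("_comparisons")
        if "morphs_both_sexes" in comps:
            comp = comps["morphs_both_sexes"]
            comp["observations"].to_csv(
                out_dir / "backcalculated_lengths.csv", index=False
            )
            plots.growth_curves_plot(
                comp["observations"], comp["fits"], out_dir / "growth_curves.svg"
            )

    write_results_json(report, out_dir / "results.json")
    return report
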