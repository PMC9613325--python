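"""End-to-end pipeline orchestration.

``run_pipeline`` consumes a YAML config (or an equivalent dict) naming
either a synthetic-data spec or the three input files, then executes the
seven analysis stages — preprocess (filter -> log10 -> impute -> scale),
univariate screening, PCA, Random Forest, PCLRC networks with differential
connectivity, COVSCA, and overrepresentation — writing deterministic TSV
outputs and a JSON run manifest with every stage's parameters and derived
seed.  Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covsca as covsca_mod
from . import datasets, enrichment, explore, io, pclrc, preprocess, univariate
from .containers import AbundanceTable, StudyDesign, split_by_group

STAGES = (
    "preprocess",
    "univariate",
    "pca",
    "random_forest",
    "network",
    "covsca",
    "enrichment",
)

FLOAT_FMT = "%.10g"


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    manifest: dict
    output_dir: Path
    table: AbundanceTable | None = None
    design: StudyDesign | None = None
    annotation: pd.DataFrame | None = None
    results: dict = field(default_factory=dict)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _synthetic_config(spec: dict, seed: int) -> datasets.SyntheticConfig:
    blocks = tuple(
        datasets.BlockSpec(
            start=b["start"], size=b["size"], rho=b["rho"],
            active_groups=tuple(b.get("groups", ())),
        )
        for b in spec.get("blocks", [])
    )
    hubs = tuple(
        datasets.HubSpec(
            index=h["index"],
            neighbors={str(k): int(v) for k, v in h.get("neighbors", {}).items()},
            rho=h.get("rho", 0.9),
        )
        for h in spec.get("hubs", [])
    )
    shift = spec.get("shift")
    shifted = (
        datasets.ShiftSpec(
            indices=tuple(shift["indices"]),
            keyword=shift.get("keyword", "shifted"),
            group=shift["group"],
            log10_shift=shift["log10_shift"],
        )
        if shift
        else None
    )
    return datasets.SyntheticConfig(
        n_per_group=spec.get("n_per_group", 75),
        n_proteins=spec.get("n_proteins", 687),
        base_log10_mean=spec.get("base_log10_mean", 6.0),
        base_log10_sd=spec.get("base_log10_sd", 0.8),
        protein_mean_sd=spec.get("protein_mean_sd", 0.5),
        block_spec=blocks,
        hub_spec=hubs,
        shifted_set=shifted,
        censor_quantile=spec.get("censor_quantile", 0.0),
        censor_softness=spec.get("censor_softness", 0.15),
        seed=seed,
    )


def _write(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_pipeline(config, output_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis described by ``config`` (YAML path or dict).

    Top-level config keys: ``seed``, ``output_dir``, ``synthetic`` (a
    synthetic spec) or ``inputs`` (paths), and one optional block per stage
    (``filter``, ``impute``, ``univariate``, ``pca``, ``random_forest``,
    ``network``, ``covsca``, ``enrichment``), each accepting ``enabled``
    plus the stage function's keyword arguments.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(output_dir or cfg.get("output_dir", "milknet_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    # fixed stage seed layout so disabling one arm leaves the others unchanged
    master = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(("data", *STAGES), master.spawn(1 + len(STAGES)))
    }

    manifest: dict = {"seed": seed, "stages": {}, "stage_order": list(STAGES)}
    result = PipelineResult(manifest=manifest, output_dir=out_dir)

    # ---- inputs -----------------------------------------------------------
    if "synthetic" in cfg:
        syn_cfg = _synthetic_config(cfg["synthetic"], stage_seeds["data"])
        table, design, annotation, truth = datasets.generate_lfq_dataset(syn_cfg)
        result.results["truth"] = truth
        manifest["inputs"] = {
            "kind": "synthetic",
            "n_per_group": syn_cfg.n_per_group,
            "n_proteins": syn_cfg.n_proteins,
            "censor_quantile": syn_cfg.censor_quantile,
            "seed": stage_seeds["data"],
        }
    elif "inputs" in cfg:
        paths = cfg["inputs"]
        table = io.read_protein_table(paths["abundance"])
        design = io.read_design(paths["design"])
        annotation = io.read_annotation(paths["annotation"])
        manifest["inputs"] = {"kind": "files", **{k: str(v) for k, v in paths.items()}}
    else:
        raise PipelineStageError("preprocess", "config names neither synthetic nor inputs")
    result.design = design
    result.annotation = annotation

    def stage_cfg(name: str) -> dict:
        block = dict(cfg.get(name, {}) or {})
        block.pop("enabled", None)
        return block

    def enabled(name: str) -> bool:
        return bool((cfg.get(name, {}) or {}).get("enabled", True))

    # ---- preprocess -------------------------------------------------------
    try:
        filt = stage_cfg("filter")
        min_valid = int(filt.get("min_valid", 25))
        filtered = preprocess.filter_by_group_validity(table, design, min_valid=min_valid)
        logged = preprocess.log10_transform(filtered)
        imp_cfg = stage_cfg("impute")
        imp = preprocess.impute_left_censored(
            logged, design, seed=stage_seeds["preprocess"], **imp_cfg
        )
        imputed = imp.table
        manifest["stages"]["preprocess"] = {
            "enabled": True,
            "min_valid": min_valid,
            "n_proteins_before": table.n_proteins,
            "n_proteins_after": filtered.n_proteins,
            "impute": {**imp_cfg, "n_sweeps_run": imp.n_sweeps},
            "seed": stage_seeds["preprocess"],
        }
        _write(imputed.data, out_dir / "imputed_log10.tsv")
        result.table = imputed
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("preprocess", str(exc)) from exc

    # ---- univariate -------------------------------------------------------
    if enabled("univariate"):
        try:
            uni_cfg = stage_cfg("univariate")
            kw = univariate.kruskal_wallis_screen(imputed, design)
            dunn = univariate.dunn_posthoc(
                imputed, design,
                kw_results=kw,
                candidate_alpha=uni_cfg.get("candidate_alpha", 0.05),
                bh_family=uni_cfg.get("bh_family", "pooled"),
            )
            screen = univariate.screening_table(kw, dunn, annotation)
            _write(kw, out_dir / "kruskal_wallis.tsv")
            _write(dunn, out_dir / "dunn_posthoc.tsv", index=False)
            _write(screen, out_dir / "screening_table.tsv", index=False)
            pair = tuple(uni_cfg.get("trend_pair", design.group_labels[:2]))
            per_protein, per_keyword = univariate.abundance_trend_summary(
                imputed, design, annotation, pair
            )
            _write(per_protein, out_dir / "trend_per_protein.tsv")
            _write(per_keyword, out_dir / "trend_per_keyword.tsv")
            manifest["stages"]["univariate"] = {
                "enabled": True,
                "candidate_alpha": uni_cfg.get("candidate_alpha", 0.05),
                "bh_family": uni_cfg.get("bh_family", "pooled"),
                "trend_pair": list(pair),
                "n_dunn_tests": int(len(dunn)),
            }
            result.results["univariate"] = {"kw": kw, "dunn": dunn, "screen": screen}
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("univariate", str(exc)) from exc
    else:
        manifest["stages"]["univariate"] = {"enabled": False}

    scaled = None
    if enabled("pca") or enabled("random_forest"):
        scaled = preprocess.scale_unit_variance(imputed)

    # ---- pca --------------------------------------------------------------
    if enabled("pca"):
        try:
            pca_cfg = stage_cfg("pca")
            n_comp = int(pca_cfg.get("n_components", 2))
            pca = explore.pca_explore(scaled, design, n_components=n_comp)
            _write(pca.scores, out_dir / "pca_scores.tsv")
            _write(pca.loadings, out_dir / "pca_loadings.tsv")
            manifest["stages"]["pca"] = {
                "enabled": True,
                "n_components": n_comp,
                "variance_explained_pct": [
                    round(float(v), 6) for v in pca.variance_explained_pct
                ],
            }
            result.results["pca"] = pca
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("pca", str(exc)) from exc
    else:
        manifest["stages"]["pca"] = {"enabled": False}

    # ---- random forest ----------------------------------------------------
    if enabled("random_forest"):
        try:
            rf_cfg = stage_cfg("random_forest")
            n_trees = int(rf_cfg.get("n_trees", 500))
            n_perm = int(rf_cfg.get("n_permutations", 1000))
            rf = explore.pairwise_rf_reports(
                scaled, design, n_trees=n_trees, n_permutations=n_perm,
                seed=stage_seeds["random_forest"],
            )
            _write(rf, out_dir / "rf_pairwise.tsv", index=False)
            manifest["stages"]["random_forest"] = {
                "enabled": True, "n_trees": n_trees,
                "n_permutations": n_perm, "seed": stage_seeds["random_forest"],
            }
            result.results["random_forest"] = rf
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("random_forest", str(exc)) from exc
    else:
        manifest["stages"]["random_forest"] = {"enabled": False}

    # ---- network (PCLRC + differential connectivity) ----------------------
    networks: dict[str, pclrc.AssociationNetwork] = {}
    shared: list[str] = []
    if enabled("network"):
        try:
            net_cfg = stage_cfg("network")
            n_iter = int(net_cfg.get("n_iterations", 1000))
            keep = float(net_cfg.get("keep_fraction", 0.30))
            subsample = float(net_cfg.get("subsample_fraction", 0.75))
            tau = float(net_cfg.get("tau", 0.99))
            delta_threshold = float(net_cfg.get("delta_threshold", 50.0))
            per_group = split_by_group(imputed, design)
            group_seeds = {
                g: int(c.generate_state(1)[0] % 2**31)
                for g, c in zip(
                    design.group_labels,
                    np.random.SeedSequence(stage_seeds["network"]).spawn(
                        len(design.group_labels)
                    ),
                )
            }
            chis = {}
            for group, block in per_group.items():
                net = pclrc.infer_group_network(
                    block, n_iterations=n_iter, subsample_fraction=subsample,
                    keep_fraction=keep, tau=tau, seed=group_seeds[group],
                    group=group,
                )
                networks[group] = net
                chis[group] = pclrc.connectivity(net)
                safe = group.replace("+", "p").replace("-", "n")
                _write(net.edge_list(), out_dir / f"edges_{safe}.tsv", index=False)
            chi_frame = pd.DataFrame(chis)
            _write(chi_frame, out_dir / "connectivity.tsv")
            scatter = pd.concat(
                [
                    chi_frame[[a, b]].rename(columns={a: "chi_a", b: "chi_b"}).assign(
                        group_a=a, group_b=b
                    )
                    for a, b in itertools.combinations(design.group_labels, 2)
                ]
            )
            _write(scatter, out_dir / "connectivity_scatter.tsv")

            reference = net_cfg.get("reference_group", "M-C-")
            deltas: dict[str, pd.Series] = {}
            for group in design.group_labels:
                if group == reference:
                    continue
                deltas[f"{group} vs {reference}"] = pclrc.differential_connectivity(
                    chis[group], chis[reference]
                )
            delta_frame = pd.DataFrame(deltas)
            _write(delta_frame, out_dir / "differential_connectivity.tsv")
            selections, shared = pclrc.select_candidates(
                deltas, delta_threshold=delta_threshold
            )
            with open(out_dir / "dc_selection.json", "w") as fh:
                json.dump(
                    {
                        "per_comparison": {k: v for k, v in selections.items()},
                        "shared": shared,
                        "delta_threshold": delta_threshold,
                    },
                    fh, indent=2, sort_keys=True,
                )
            perm_cfg = dict(net_cfg.get("permutations", {}) or {})
            if perm_cfg.get("enabled", False):
                dc_tables = {}
                for name in deltas:
                    group = name.split(" vs ")[0]
                    dc = pclrc.dc_permutation_pvalues(
                        per_group[group], per_group[reference],
                        n_permutations=int(perm_cfg.get("n_permutations", 99)),
                        n_iterations=int(perm_cfg.get("n_iterations", 100)),
                        subsample_fraction=subsample, keep_fraction=keep,
                        tau=tau, seed=group_seeds[group],
                    )
                    safe = name.replace("+", "p").replace("-", "n").replace(" ", "_")
                    _write(dc.table, out_dir / f"dc_pvalues_{safe}.tsv")
                    dc_tables[name] = dc
                result.results["dc_permutations"] = dc_tables
            manifest["stages"]["network"] = {
                "enabled": True, "n_iterations": n_iter, "keep_fraction": keep,
                "subsample_fraction": subsample, "tau": tau,
                "delta_threshold": delta_threshold, "reference_group": reference,
                "seed": stage_seeds["network"],
                "n_selected_shared": len(shared),
            }
            result.results["networks"] = networks
            result.results["connectivity"] = chi_frame
            result.results["deltas"] = deltas
            result.results["shared_selection"] = shared
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("network", str(exc)) from exc
    else:
        manifest["stages"]["network"] = {"enabled": False}

    # ---- covsca -----------------------------------------------------------
    if enabled("covsca") and networks:
        try:
            cov_cfg = stage_cfg("covsca")
            collection = covsca_mod.NetworkCollection.from_networks(
                networks,
                mode=cov_cfg.get("mode", "absolute"),
                diagonal=cov_cfg.get("diagonal", "zero"),
            )
            model = covsca_mod.fit_covsca(
                collection,
                n_components=int(cov_cfg.get("n_components", 2)),
                n_starts=int(cov_cfg.get("n_starts", 20)),
                max_iter=int(cov_cfg.get("max_iter", 1000)),
                seed=stage_seeds["covsca"],
            )
            selection = covsca_mod.loading_selection(
                model, z_threshold=float(cov_cfg.get("z_threshold", 2.0))
            )
            _write(model.weights, out_dir / "covsca_scores.tsv")
            _write(selection, out_dir / "covsca_loadings.tsv", index=False)
            with open(out_dir / "covsca_model.json", "w") as fh:
                json.dump(
                    {
                        "weights": model.weights.round(10).to_dict(),
                        "gof_pct": round(model.gof_pct, 6),
                        "ranks": list(model.ranks),
                        "n_starts": model.n_starts,
                        "converged": model.converged,
                    },
                    fh, indent=2, sort_keys=True,
                )
            manifest["stages"]["covsca"] = {
                "enabled": True,
                "n_components": int(cov_cfg.get("n_components", 2)),
                "gof_pct": round(model.gof_pct, 6),
                "seed": stage_seeds["covsca"],
            }
            result.results["covsca"] = model
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("covsca", str(exc)) from exc
    else:
        manifest["stages"]["covsca"] = {
            "enabled": False,
            "reason": None if enabled("covsca") else "disabled",
        }

    # ---- enrichment -------------------------------------------------------
    if enabled("enrichment") and networks:
        try:
            background = result.table.protein_ids
            rows = enrichment.overrepresentation_test(
                [p for p in shared], background, annotation
            )
            _write(rows, out_dir / "enrichment.tsv", index=False)
            manifest["stages"]["enrichment"] = {
                "enabled": True,
                "target_size": len(shared),
                "background_size": len(background),
            }
            result.results["enrichment"] = rows
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("enrichment", str(exc)) from exc
    else:
        manifest["stages"]["enrichment"] = {
            "enabled": False,
            "reason": None if enabled("enrichment") else "disabled",
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
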