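"""Config-driven orchestration of the full analysis.

``run_pipeline`` sequences the stages — cohort intake (or simulation),
Z-scores and cut-offs, signatures/heatmap/ratios, per-subgroup correlation
networks with connectivity and hub accounting, preserved/lost/acquired
classification, PCA, and univariate group tests — and writes a report
bundle of machine-readable CSVs, network exports (SIF/GraphML), a couple
of standard figures and a JSON run manifest. Given the same config and
seed the bundle is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import network as net
from . import signatures as sig
from .cohort import Cohort, SubgroupKey, load_cohort, write_cohort
from .multivariate import group_comparisons, loading_vectors, pc23_projection, run_pca
from .panel import DEFAULT_PANEL
from .simulate import generate_cohort, paperlike_config

logger = logging.getLogger(__name__)

SUBGROUPS = [SubgroupKey(g, t) for g in ("HC", "COVID") for t in (1, 2, 3)]


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Effective pipeline parameters; defaults mirror the method's rules
    (r_min 0.67, alpha 0.05, hub k 5, 50% signature rule, ratio bins)."""

    input_path: str | None = None
    input_layout: str = "long"
    simulate: bool = False
    seed: int = 0
    outdir: str = "mediatornet_run"
    reference: str = "combined"
    transform: str = "raw"
    cutoff_mode: str = "both"        # global | trimester | both
    rule: str = "spearman"
    r_min: float = 0.67
    alpha: float = 0.05
    min_n: int = 5
    hub_k: int = 5
    dunn_adjust: str | None = "bonferroni"
    missing_rate: float = 0.0
    figures: bool = True


_VALID = {
    "input_layout": ("long", "wide"),
    "reference": ("combined", "HC_only"),
    "transform": ("raw", "log10"),
    "cutoff_mode": ("global", "trimester", "both"),
    "rule": net.RULES,
    "dunn_adjust": ("bonferroni", None),
}


def validate_config(source: str | Path | dict | None) -> tuple[PipelineConfig, list[str]]:
    """Normalise a config mapping or YAML/JSON file into a PipelineConfig.

    Unknown keys are rejected and every type/range violation is reported at
    once. Returns the config plus a list of warnings (e.g. an alpha that
    departs from the conventional 0.05).
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {source} must contain a mapping")

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors: list[str] = []
    warns: list[str] = []
    unknown = sorted(set(raw) - known)
    for key in unknown:
        import difflib
        hint = difflib.get_close_matches(key, known, n=1)
        suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
        errors.append(f"unknown key {key!r}{suffix}")
    values = {k: v for k, v in raw.items() if k in known}
    for key, allowed in _VALID.items():
        if key in values and values[key] not in allowed:
            import difflib
            hint = difflib.get_close_matches(str(values[key]),
                                             [str(a) for a in allowed], n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"{key}={values[key]!r} not in {allowed}{suffix}")
    if "r_min" in values and not (0 <= float(values["r_min"]) <= 1):
        errors.append(f"r_min={values['r_min']} must be in [0, 1]")
    if "alpha" in values:
        a = float(values["alpha"])
        if not (0 < a < 1):
            errors.append(f"alpha={a} must be in (0, 1)")
        elif a != 0.05:
            warns.append(f"alpha={a} departs from the conventional 0.05")
    if "missing_rate" in values and not (0 <= float(values["missing_rate"]) < 1):
        errors.append(f"missing_rate={values['missing_rate']} must be in [0, 1)")
    for key in ("min_n", "hub_k", "seed"):
        if key in values and int(values[key]) != values[key]:
            errors.append(f"{key}={values[key]} must be an integer")
    if "min_n" in values and int(values.get("min_n", 5)) < 3:
        errors.append("min_n must be >= 3")
    if "hub_k" in values and int(values.get("hub_k", 5)) < 1:
        errors.append("hub_k must be >= 1")
    if not values.get("simulate", False) and values.get("input_path") is None \
            and ("simulate" in values or "input_path" in raw):
        errors.append("either input_path or simulate=true is required")
    if errors:
        raise ConfigError("invalid configuration:\n- " + "\n- ".join(errors))
    return PipelineConfig(**values), warns


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    cohort: Cohort
    networks: dict[str, net.MediatorNetwork]
    venn: dict[int, net.VennResult]


def _write_signature_outputs(outdir: Path, z, cohort, mode_label, cutoffs_by_t,
                             counts: dict) -> None:
    """Signatures + ratios for one cut-off mode (cutoffs_by_t maps trimester
    -> CutoffSet; a global mode passes the same set for every trimester)."""
    sig_rows, ratio_rows, profiles = [], [], []
    for key in SUBGROUPS:
        cuts = cutoffs_by_t[key.trimester]
        profile = sig.signature_proportions(z, cuts, key)
        profiles.append(profile)
        for analyte, row in profile.table.iterrows():
            sig_rows.append({"subgroup": key.label(), "analyte": analyte,
                             "proportion_above": row["proportion_above"],
                             "n_evaluated": row["n_evaluated"],
                             "category": row["category"]})
    for t in (1, 2, 3):
        cuts = cutoffs_by_t[t]
        p_hc = sig.signature_proportions(z, cuts, SubgroupKey("HC", t))
        p_cv = sig.signature_proportions(z, cuts, SubgroupKey("COVID", t))
        ratios = sig.covid_hc_ratio(p_cv, p_hc)
        for analyte, row in ratios.table.iterrows():
            ratio_rows.append({"trimester": t, "analyte": analyte,
                               "ratio": row["ratio"],
                               "display_ratio": row["display_ratio"],
                               "class": row["class"]})
    pd.DataFrame(sig_rows).to_csv(outdir / f"signatures_{mode_label}.csv", index=False)
    pd.DataFrame(ratio_rows).to_csv(outdir / f"ratios_{mode_label}.csv", index=False)
    sig.signature_heatmap(
        profiles, csv_path=outdir / f"heatmap_{mode_label}.csv",
        figure_path=(outdir / f"heatmap_{mode_label}.png") if counts["figures"] else None)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.outdir``.

    Any stage failure removes the partially written bundle and raises
    :class:`PipelineStageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    stage = "setup"
    try:
        stage = "cohort"
        if config.simulate or config.input_path is None:
            sim = paperlike_config(seed=config.seed,
                                   missing_rate=config.missing_rate)
            cohort = generate_cohort(sim)
            logger.info("simulated cohort: %d samples", len(cohort.samples))
        else:
            cohort = load_cohort(config.input_path, layout=config.input_layout)
            logger.info("loaded cohort from %s: %d samples",
                        config.input_path, len(cohort.samples))
        sizes = cohort.subgroup_sizes()
        pd.DataFrame([{"group": g, "trimester": t, "n": n}
                      for (g, t), n in sorted(sizes.items())]
                     ).to_csv(emit(outdir / "cohort_subgroups.csv"), index=False)
        emit(write_cohort(cohort, outdir / "cohort_long.csv", layout="long"))

        stage = "zscores"
        z = sig.compute_zscores(cohort, reference=config.reference,
                                transform=config.transform)

        stage = "cutoffs"
        cutoff_rows = []
        modes: dict[str, dict] = {}
        if config.cutoff_mode in ("global", "both"):
            cuts = sig.derive_cutoffs(z, mode="global_HC")
            modes["global"] = {t: cuts for t in (1, 2, 3)}
            cutoff_rows += [{"mode": cuts.mode, "analyte": a, "cutoff": v}
                            for a, v in cuts.values.items()]
        if config.cutoff_mode in ("trimester", "both"):
            per_t = {t: sig.derive_cutoffs(z, mode="trimester_HC", trimester=t)
                     for t in (1, 2, 3)}
            modes["trimester"] = per_t
            for t, cuts in per_t.items():
                cutoff_rows += [{"mode": cuts.mode, "analyte": a, "cutoff": v}
                                for a, v in cuts.values.items()]
        pd.DataFrame(cutoff_rows).to_csv(emit(outdir / "cutoffs.csv"), index=False)

        stage = "signatures"
        counts = {"figures": config.figures}
        for mode_label, cutoffs_by_t in modes.items():
            _write_signature_outputs(outdir, z, cohort, mode_label,
                                     cutoffs_by_t, counts)
            for suffix in ("signatures", "ratios", "heatmap"):
                emit(outdir / f"{suffix}_{mode_label}.csv")
            if config.figures:
                emit(outdir / f"heatmap_{mode_label}.png")

        stage = "networks"
        networks: dict[str, net.MediatorNetwork] = {}
        conn_rows, hub_rows = [], []
        for key in SUBGROUPS:
            records = net.correlation_matrix(cohort, key, min_n=config.min_n)
            network = net.build_edges(records, rule=config.rule,
                                      r_min=config.r_min, alpha=config.alpha,
                                      subgroup=key,
                                      nodes=cohort.panel.mediators)
            networks[key.label()] = network
            report = net.connectivity(network, cohort.panel)
            conn_rows.append({"subgroup": key.label(),
                              "edges": network.graph.number_of_edges(),
                              "total_connections": report.total_connections,
                              **{f"connections_{c}": report.by_category[c]
                                 for c in report.by_category}})
            for a in sorted(net.hub_set(network, k=config.hub_k)):
                hub_rows.append({"subgroup": key.label(), "analyte": a,
                                 "degree": int(report.degrees[a])})
            base = outdir / f"network_{key.label()}"
            emit(net.export_network(network, base.with_suffix(".csv"), "csv"))
            emit(net.export_network(network, base.with_suffix(".sif"), "sif"))
            emit(net.export_network(network, base.with_suffix(".graphml"), "graphml"))
            logger.info("network %s: %d edges", key.label(),
                        network.graph.number_of_edges())
        pd.DataFrame(conn_rows).to_csv(emit(outdir / "connectivity.csv"), index=False)
        pd.DataFrame(hub_rows).to_csv(emit(outdir / "hubs.csv"), index=False)

        stage = "venn"
        venn: dict[int, net.VennResult] = {}
        venn_rows = []
        for t in (1, 2, 3):
            hubs_hc = net.hub_set(networks[f"HC_t{t}"], k=config.hub_k)
            hubs_cv = net.hub_set(networks[f"COVID_t{t}"], k=config.hub_k)
            result = net.venn_classify(hubs_hc, hubs_cv, t, cohort.panel)
            venn[t] = result
            for cls in ("preserved", "lost", "acquired"):
                for a in sorted(getattr(result, cls)):
                    venn_rows.append({"trimester": t, "class": cls, "analyte": a})
        pd.DataFrame(venn_rows, columns=["trimester", "class", "analyte"]
                     ).to_csv(emit(outdir / "venn.csv"), index=False)

        stage = "pca"
        pca = run_pca(z, complete_case=True)
        projection = pc23_projection(pca)
        vectors = loading_vectors(pca, centroids=projection.centroids)
        pca.scores.to_csv(emit(outdir / "pca_scores.csv"))
        pca.loadings.to_csv(emit(outdir / "pca_loadings.csv"))
        pd.DataFrame({"component": pca.scores.columns,
                      "explained_variance_ratio": pca.explained_variance_ratio}
                     ).to_csv(emit(outdir / "pca_explained.csv"), index=False)
        projection.coordinates.to_csv(emit(outdir / "pca_pc23_coordinates.csv"))
        projection.separation.to_csv(emit(outdir / "pca_separation.csv"), index=False)
        vectors.to_csv(emit(outdir / "pca_loading_vectors.csv"))
        if config.figures:
            _plot_pc23(projection, emit(outdir / "pca_pc23.png"))

        stage = "tests"
        kw_rows, dunn_frames, mw_frames = [], [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for analyte in cohort.panel.mediators:
                res = group_comparisons(cohort, analyte, alpha=config.alpha,
                                        dunn_adjust=config.dunn_adjust)
                kw_rows.append({"analyte": analyte,
                                "H": res.kruskal_statistic, "p": res.kruskal_p,
                                "significant": res.kruskal_p < config.alpha})
                dunn_frames.append(res.dunn.assign(analyte=analyte))
                mw_frames.append(res.mannwhitney.assign(analyte=analyte))
        pd.DataFrame(kw_rows).to_csv(emit(outdir / "tests_kruskal.csv"), index=False)
        pd.concat(dunn_frames, ignore_index=True).to_csv(
            emit(outdir / "tests_dunn.csv"), index=False)
        pd.concat(mw_frames, ignore_index=True).to_csv(
            emit(outdir / "tests_mannwhitney.csv"), index=False)

        stage = "manifest"
        try:
            version = metadata.version("mediatornet")
        except metadata.PackageNotFoundError:
            version = "unknown"
        manifest = {
            "package": "mediatornet",
            "version": version,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "config_hash": _config_hash(config),
            "counts": {
                "samples": len(cohort.samples),
                "subgroups": {f"{g}_t{t}": n for (g, t), n in sorted(sizes.items())},
                "edges": {label: nw.graph.number_of_edges()
                          for label, nw in networks.items()},
                "hubs": {label: len(net.hub_set(nw, k=config.hub_k))
                         for label, nw in networks.items()},
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        emit(outdir / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - stage-labelled rethrow
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc
    return PipelineResult(outdir=outdir, manifest=manifest, cohort=cohort,
                          networks=networks, venn=venn)


def _plot_pc23(projection, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    palette = {"HC": "tab:blue", "COVID": "tab:red"}
    for (group, t), sub in projection.coordinates.groupby(["group", "trimester"]):
        ax.scatter(sub["PC2"], sub["PC3"], s=18, alpha=0.7,
                   color=palette[group], marker=["o", "s", "^"][int(t) - 1],
                   label=f"{group} t{t}")
    ax.set_xlabel("PC2")
    ax.set_ylabel("PC3")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
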