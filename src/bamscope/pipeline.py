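"""End-to-end orchestration: simulate -> bam -> tscore -> phenoprint ->
cluster -> associate -> predict -> report.

A single master seed deterministically derives per-stage seeds (keyed by
stage name), so any stage can be reproduced in isolation. Every stage
writes plain standard formats (HDF5/CSV/JSON/PNG) and records parameter
values, seeds and file hashes in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .atc_association import DEFAULT_ALPHA, hypergeom_overrep
from .bam_mapping import compute_tscore_bam, make_default_template
from .consensus_clustering import (
    DEFAULT_N_ITERATIONS,
    DEFAULT_SUBSAMPLE_FRAC,
    coherence_tests,
    consensus_cluster,
    cut_clusters,
    select_k,
)
from .functional_prediction import DEFAULT_N_TREES, classify, rank_candidates, train_forest
from .phenoprint import DEFAULT_N_COMPONENTS, fit_pca, project_library
from .synthetic_data import ScenarioConfig, simulate_bam_library

logger = logging.getLogger("bamscope.pipeline")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_report", "derive_seed"]

STAGES = ("simulate", "bam", "tscore", "phenoprint", "cluster", "associate", "predict", "report")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed from the master seed, stable across runs and platforms."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the screen's protocol
    (0.2 Hz high-pass, mean+2SD threshold, n=5 replicates, 20 PCs, 1000
    consensus resamples, <1% AUC plateau, alpha=0.05, 100 trees)."""

    out_dir: str = "bamscope_run"
    seed: int = 0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    n_components: int = DEFAULT_N_COMPONENTS
    k_min: int = 2
    k_max: int = 15
    n_iterations: int = DEFAULT_N_ITERATIONS
    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC
    rel_increase_threshold: float = 0.01
    alpha: float = DEFAULT_ALPHA
    n_trees: int = DEFAULT_N_TREES
    stages: tuple[str, ...] = STAGES

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        scenario = raw.pop("scenario", {})
        stages = tuple(raw.pop("stages", STAGES))
        return cls(scenario=ScenarioConfig(**scenario), stages=stages, **raw)


@dataclass
class RunManifest:
    """Per-stage parameters, seeds, output hashes and timing."""

    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    complete: bool = False
    version: str = "0.1.0"

    def record(self, stage: str, seed: int | None, params: dict, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "seed": seed,
            "params": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "stages": self.stages,
                    "complete": self.complete,
                    "version": self.version,
                },
                indent=2,
                default=str,
            )
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order, persisting every intermediate.

    Any stage failure aborts with the failing stage named; the manifest is
    still written, marked incomplete, and partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(config=cfg_dict)
    manifest_path = out / "manifest.json"
    enabled = [s for s in STAGES if s in config.stages]
    state: dict[str, object] = {}
    try:
        for stage in enabled:
            seed = derive_seed(config.seed, stage)
            logger.info("stage %s (seed %d)", stage, seed)
            outputs = _STAGE_FUNCS[stage](config, state, out, seed)
            manifest.record(stage, seed, _stage_params(config, stage), outputs)
            manifest.save(manifest_path)
        manifest.complete = True
    except Exception as exc:
        manifest.save(manifest_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest.save(manifest_path)
    return manifest


def _stage_params(config: RunConfig, stage: str) -> dict:
    if stage == "simulate":
        return dataclasses.asdict(config.scenario)
    if stage == "phenoprint":
        return {"n_components": config.n_components}
    if stage == "cluster":
        return {
            "k_range": [config.k_min, config.k_max],
            "n_iterations": config.n_iterations,
            "subsample_frac": config.subsample_frac,
            "rel_increase_threshold": config.rel_increase_threshold,
        }
    if stage == "associate":
        return {"alpha": config.alpha}
    if stage == "predict":
        return {"n_trees": config.n_trees}
    return {}


# --- stage implementations -------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    scenario = dataclasses.replace(config.scenario, seed=seed)
    library, truth, table = simulate_bam_library(scenario)
    state["library"], state["truth"], state["table"] = library, truth, table
    bio.save_bam_library(out / "bams.h5", library)
    bio.save_ground_truth(out / "ground_truth.json", truth)
    bio.save_drug_table(out / "drugs.csv", table)
    return [out / "bams.h5", out / "ground_truth.json", out / "drugs.csv"]


def _stage_bam(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    # when movies are the input this stage would mesh/filter/count/register;
    # the simulated scenario already provides BAM-level data, so it verifies
    # and passes the library through
    if "library" not in state:
        path = Path(config.out_dir) / "bams.h5"
        if not path.exists():
            raise FileNotFoundError(f"simulate disabled and BAM library missing: {path}")
        state["library"] = bio.load_bam_library(path)
        drugs = Path(config.out_dir) / "drugs.csv"
        if not drugs.exists():
            raise FileNotFoundError(f"simulate disabled and drug table missing: {drugs}")
        state["table"] = bio.load_drug_table(drugs)
    library = state["library"]
    template = make_default_template(library.grid_h, library.grid_w)
    state["template"] = template
    return []


def _stage_tscore(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    library = state["library"]
    maps = {d: compute_tscore_bam(s) for d, s in library.bams.items()}
    state["tscore"] = maps
    bio.save_tscore_maps(out / "tscore.h5", maps)
    return [out / "tscore.h5"]


def _stage_phenoprint(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    table: pd.DataFrame = state["table"]
    maps = state["tscore"]
    template = state["template"]
    train_ids = list(table.loc[table["set"] == "training", "compound_id"])
    test_ids = list(table.loc[table["set"] == "test", "compound_id"])
    model = fit_pca(
        np.stack([maps[d] for d in train_ids]), template.mask, config.n_components
    )
    pp_train = pd.DataFrame(
        project_library(np.stack([maps[d] for d in train_ids]), model),
        index=train_ids,
        columns=[f"pc{i+1}" for i in range(model.n_components)],
    )
    pp_test = pd.DataFrame(
        project_library(np.stack([maps[d] for d in test_ids]), model) if test_ids else [],
        index=test_ids,
        columns=pp_train.columns,
    )
    state["pcmodel"], state["pp_train"], state["pp_test"] = model, pp_train, pp_test
    bio.save_pcmodel(out / "pcmodel.h5", model)
    bio.save_phenoprints(out / "phenoprints_train.csv", pp_train)
    bio.save_phenoprints(out / "phenoprints_test.csv", pp_test)
    return [out / "pcmodel.h5", out / "phenoprints_train.csv", out / "phenoprints_test.csv"]


def _stage_cluster(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    pp: pd.DataFrame = state["pp_train"]
    result = consensus_cluster(
        pp.to_numpy(),
        list(pp.index),
        k_range=range(config.k_min, config.k_max + 1),
        n_iterations=config.n_iterations,
        subsample_frac=config.subsample_frac,
        seed=seed,
    )
    k = select_k(result, config.rel_increase_threshold)
    assignment = cut_clusters(result, k, tscore_maps=state["tscore"])
    coherence = coherence_tests(result, assignment, phenoprints=pp.to_numpy())
    state["consensus"], state["assignment"], state["coherence"] = result, assignment, coherence
    bio.save_consensus(out / "consensus.h5", result)
    labels = assignment.labels.rename_axis("compound_id").reset_index()
    labels.to_csv(out / "cluster_labels.csv", index=False)
    coherence.to_csv(out / "coherence.csv")
    pd.DataFrame({"k": result.ks, "auc_cdf": [result.aucs[k_] for k_ in result.ks]}).to_csv(
        out / "auc_cdf.csv", index=False
    )
    return [out / "consensus.h5", out / "cluster_labels.csv", out / "coherence.csv", out / "auc_cdf.csv"]


def _stage_associate(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    assoc = hypergeom_overrep(
        state["assignment"], state["table"], alpha=config.alpha, phenoprints=state["pp_train"]
    )
    state["association"] = assoc
    assoc.table.to_csv(out / "association.csv", index=False)
    return [out / "association.csv"]


def _stage_predict(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    model = train_forest(
        state["pp_train"], state["assignment"], n_trees=config.n_trees, seed=seed
    )
    state["forest"] = model
    pp_test: pd.DataFrame = state["pp_test"]
    if pp_test.empty:
        preds = pd.DataFrame(columns=["cluster", "category", "r", "rank"])
    else:
        assignments = classify(model, pp_test)
        preds = rank_candidates(assignments, pp_test, state["association"]).join(
            assignments.drop(columns="cluster")
        )
    state["predictions"] = preds
    preds.rename_axis("compound_id").to_csv(out / "predictions.csv")
    return [out / "predictions.csv"]


def _stage_report(config: RunConfig, state: dict, out: Path, seed: int) -> list[Path]:
    return render_report(state, out)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "bam": _stage_bam,
    "tscore": _stage_tscore,
    "phenoprint": _stage_phenoprint,
    "cluster": _stage_cluster,
    "associate": _stage_associate,
    "predict": _stage_predict,
    "report": _stage_report,
}


def render_report(state: dict, out: Path) -> list[Path]:
    """Figure-style report bundle: consensus heat map, AUC-CDF curves,
    cluster-pattern gallery, association heat map, ranked tables and a run
    summary. Panels with missing inputs are skipped with a notice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    outputs: list[Path] = []
    result = state.get("consensus")
    assignment = state.get("assignment")

    if result is not None and assignment is not None:
        order = np.argsort(assignment.labels.loc[result.drug_ids].to_numpy(), kind="stable")
        m = result.consensus[assignment.k][np.ix_(order, order)]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(m, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"Consensus matrix (k={assignment.k})")
        fig.colorbar(im, ax=ax, label="co-clustering frequency")
        p = out / "consensus_heatmap.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        outputs.append(p)

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for k in result.ks:
            vals = np.sort(result.consensus[k][np.triu_indices(len(result.drug_ids), 1)])
            axes[0].plot(vals, np.linspace(0, 1, vals.size), lw=0.8, label=f"k={k}")
        axes[0].set_xlabel("consensus value")
        axes[0].set_ylabel("CDF")
        axes[1].plot(result.ks, [result.aucs[k] for k in result.ks], "o-")
        axes[1].axvline(assignment.k, color="r", ls="--", lw=0.8)
        axes[1].set_xlabel("k")
        axes[1].set_ylabel("AUC of consensus CDF")
        fig.tight_layout()
        p = out / "cdf_auc.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        outputs.append(p)
    else:
        logger.warning("report: consensus panels skipped (missing stage output)")

    if assignment is not None and assignment.patterns:
        ks = sorted(assignment.patterns)
        dmso = state.get("tscore", {}).get("DMSO")
        ncol = min(5, len(ks) + (dmso is not None))
        total = len(ks) + (dmso is not None)
        nrow = int(np.ceil(total / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow), squeeze=False)
        flat = axes.ravel()
        vmax = max(np.nanmax(np.abs(p_)) for p_ in assignment.patterns.values())
        for ax, c in zip(flat, ks):
            ax.imshow(assignment.patterns[c], cmap="coolwarm", vmin=-vmax, vmax=vmax)
            ax.set_title(f"cluster {c}", fontsize=8)
            ax.axis("off")
        if dmso is not None:
            ax = flat[len(ks)]
            ax.imshow(dmso, cmap="coolwarm", vmin=-vmax, vmax=vmax)
            ax.set_title("DMSO control", fontsize=8)
            ax.axis("off")
        for ax in flat[total:]:
            ax.axis("off")
        fig.tight_layout()
        p = out / "cluster_patterns.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        outputs.append(p)

    assoc = state.get("association")
    if assoc is not None:
        pv = assoc.pvalues
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(-np.log10(pv.to_numpy(dtype=float)), cmap="Reds", aspect="auto")
        ax.set_xticks(range(pv.shape[1]), pv.columns, rotation=45)
        ax.set_yticks(range(pv.shape[0]), [f"cluster {c}" for c in pv.index])
        fig.colorbar(im, ax=ax, label="-log10 p (hypergeometric)")
        fig.tight_layout()
        p = out / "association_heatmap.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        outputs.append(p)

    preds = state.get("predictions")
    if preds is not None and not preds.empty:
        ranked = preds.dropna(subset=["r"]).sort_values(["cluster", "rank"])
        p = out / "ranked_candidates.csv"
        ranked.rename_axis("compound_id").to_csv(p)
        outputs.append(p)

    summary = {
        "n_drugs": len(state.get("table", [])),
        "k_selected": getattr(assignment, "k", None),
        "n_significant_pairs": int(assoc.table["significant"].sum()) if assoc is not None else None,
        "n_predictions": 0 if preds is None else int(len(preds)),
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2))
    outputs.append(p)
    return outputs
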