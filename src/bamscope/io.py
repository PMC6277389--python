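"""Persistence for movies, BAM libraries, PCA models and result tables.

All on-disk formats are standard: HDF5 for arrays (one dataset per drug or
replicate), CSV for tables, TIFF for movies, JSON for ground-truth
sidecars. Nothing is pickled.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .phenoprint import PCModel
from .synthetic_data import BAMLibrary, CalciumMovie, GroundTruth

__all__ = [
    "save_bam_library",
    "load_bam_library",
    "save_tscore_maps",
    "load_tscore_maps",
    "save_pcmodel",
    "load_pcmodel",
    "save_phenoprints",
    "load_phenoprints",
    "save_drug_table",
    "load_drug_table",
    "save_ground_truth",
    "load_ground_truth",
    "save_movie_tiff",
    "save_movie_hdf5",
    "load_movie_hdf5",
    "save_consensus",
]


def save_bam_library(path: str | Path, library: BAMLibrary) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("bams")
        g.attrs["grid_h"] = library.grid_h
        g.attrs["grid_w"] = library.grid_w
        for drug, stack in library.bams.items():
            dg = g.create_group(drug)
            for r in range(stack.shape[0]):
                dg.create_dataset(str(r), data=stack[r].astype(np.int32))


def load_bam_library(path: str | Path) -> BAMLibrary:
    with h5py.File(path, "r") as f:
        g = f["bams"]
        bams = {}
        for drug in g:
            reps = sorted(g[drug], key=int)
            bams[drug] = np.stack([g[drug][r][()] for r in reps])
        return BAMLibrary(bams=bams, grid_h=int(g.attrs["grid_h"]), grid_w=int(g.attrs["grid_w"]))


def save_tscore_maps(path: str | Path, maps: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("tscore_bams")
        for drug, m in maps.items():
            g.create_dataset(drug, data=np.asarray(m, dtype=np.float64))


def load_tscore_maps(path: str | Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        g = f["tscore_bams"]
        return {drug: g[drug][()] for drug in g}


def save_pcmodel(path: str | Path, model: PCModel) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("pcmodel")
        g.create_dataset("mean", data=model.mean)
        g.create_dataset("loadings", data=model.loadings)
        g.create_dataset("evr", data=model.explained_variance_ratio)
        g.create_dataset("mask", data=model.mask.astype(np.uint8))


def load_pcmodel(path: str | Path) -> PCModel:
    with h5py.File(path, "r") as f:
        g = f["pcmodel"]
        return PCModel(
            mean=g["mean"][()],
            loadings=g["loadings"][()],
            explained_variance_ratio=g["evr"][()],
            mask=g["mask"][()].astype(bool),
        )


def save_phenoprints(path: str | Path, phenoprints: pd.DataFrame) -> None:
    df = phenoprints.copy()
    df.index.name = "compound_id"
    df.to_csv(path)


def load_phenoprints(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="compound_id")


def save_drug_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_drug_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"compound_id", "name", "atc_codes", "set"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table lacks column(s): {sorted(missing)}")
    return df


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """JSON sidecar: labels and links; effect templates/maps as nested lists."""
    payload = {
        "true_cluster": truth.true_cluster,
        "linked_category": {str(k): v for k, v in truth.linked_category.items()},
        "membership": truth.membership,
        "templates": np.asarray(truth.templates).tolist(),
        "effect_maps": {d: np.asarray(m).tolist() for d, m in truth.effect_maps.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_cluster={k: int(v) for k, v in payload["true_cluster"].items()},
        templates=np.asarray(payload["templates"]),
        linked_category={int(k): v for k, v in payload["linked_category"].items()},
        effect_maps={d: np.asarray(m) for d, m in payload["effect_maps"].items()},
        membership=payload["membership"],
    )


def save_movie_tiff(path_stem: str | Path, movie: CalciumMovie) -> list[Path]:
    """One multi-page TIFF per z-plane (T x H x W), metadata in tags."""
    paths = []
    for p in range(movie.data.shape[1]):
        path = Path(f"{path_stem}_plane{p}.tif")
        tifffile.imwrite(
            path,
            movie.data[:, p],
            metadata={
                "fs": movie.fs,
                "pixel_area_um2": movie.pixel_area_um2,
                "plane_spacing_um": movie.plane_spacing_um,
                "pre_frames": list(movie.pre_frames),
                "post_frames": list(movie.post_frames),
            },
        )
        paths.append(path)
    return paths


def save_movie_hdf5(path: str | Path, movie: CalciumMovie) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("movie")
        for p in range(movie.data.shape[1]):
            g.create_dataset(f"plane{p}", data=movie.data[:, p])
        g.attrs["fs"] = movie.fs
        g.attrs["pixel_area_um2"] = movie.pixel_area_um2
        g.attrs["plane_spacing_um"] = movie.plane_spacing_um
        g.attrs["pre_frames"] = movie.pre_frames
        g.attrs["post_frames"] = movie.post_frames


def load_movie_hdf5(path: str | Path) -> CalciumMovie:
    with h5py.File(path, "r") as f:
        g = f["movie"]
        planes = sorted((k for k in g if k.startswith("plane")), key=lambda s: int(s[5:]))
        data = np.stack([g[p][()] for p in planes], axis=1)
        return CalciumMovie(
            data=data,
            fs=float(g.attrs["fs"]),
            pixel_area_um2=float(g.attrs["pixel_area_um2"]),
            plane_spacing_um=float(g.attrs["plane_spacing_um"]),
            pre_frames=tuple(int(v) for v in g.attrs["pre_frames"]),
            post_frames=tuple(int(v) for v in g.attrs["post_frames"]),
        )


def save_consensus(path: str | Path, result) -> None:
    """Consensus matrices to HDF5 under /consensus/k=<k>, AUCs as attrs."""
    with h5py.File(path, "w") as f:
        g = f.create_group("consensus")
        g.attrs["drug_ids"] = [d.encode() for d in result.drug_ids]
        g.attrs["n_iterations"] = result.n_iterations
        g.attrs["subsample_frac"] = result.subsample_frac
        g.attrs["seed"] = result.seed
        for k in result.ks:
            d = g.create_dataset(f"k={k}", data=result.consensus[k])
            d.attrs["auc_cdf"] = result.aucs[k]
        g.create_dataset("cosample_counts", data=result.cosample_counts)
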