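"""Pheno-Prints: low-dimensional PCA fingerprints of T-score BAMs.

A principal-component basis is fitted once, on the training library of
T-score maps (mean-centred, no per-ROI rescaling — T scores already share a
scale); every map, training or test, is then projected onto the top
``n_components`` (default 20) loadings to give its Pheno-Print. The basis
also supports reconstruction, i.e. denoised maps from truncated expansions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCModel", "fit_pca", "project", "reconstruct"]

DEFAULT_N_COMPONENTS = 20


@dataclass
class PCModel:
    """Fitted PCA basis over template-masked, flattened T-score maps.

    ``loadings`` has orthonormal rows (components x masked ROIs);
    ``explained_variance_ratio`` fractions refer to the total variance of
    the fitting library, so they are comparable across component counts.
    """

    mean: np.ndarray  # (n_masked,)
    loadings: np.ndarray  # (n_components, n_masked)
    explained_variance_ratio: np.ndarray  # (n_components,)
    mask: np.ndarray  # bool (grid_h, grid_w)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def flatten(self, tscore_map: np.ndarray) -> np.ndarray:
        tscore_map = np.asarray(tscore_map, dtype=float)
        if tscore_map.shape != self.mask.shape:
            raise ValueError(
                f"map shape {tscore_map.shape} does not match template mask {self.mask.shape}"
            )
        return tscore_map[self.mask]

    def embed(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = flat
        return out


def _as_matrix(tscore_maps: np.ndarray | list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    maps = np.asarray(tscore_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected a stack of 2-D T-score maps")
    if maps.shape[1:] != mask.shape:
        raise ValueError("maps do not match the template mask shape")
    return maps[:, mask]


def fit_pca(
    tscore_maps: np.ndarray | list[np.ndarray],
    mask: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> PCModel:
    """Fit the principal-component basis on a library of T-score maps.

    Exact SVD of the mean-centred matrix (deterministic); the sign of each
    loading is fixed so that its largest-magnitude entry is positive, making
    Pheno-Prints reproducible across platforms.
    """
    mask = np.asarray(mask, dtype=bool)
    x = _as_matrix(tscore_maps, mask)
    n = x.shape[0]
    if n < n_components:
        raise ValueError(
            f"library has {n} maps but {n_components} components requested; "
            "reduce n_components"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    total_var = float((xc**2).sum())
    if total_var <= 1e-12:
        raise ValueError("degenerate library: all maps identical (zero variance)")
    # economy SVD; rows of vt are the principal axes
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    evr = (s**2) / total_var
    loadings = vt[:n_components].copy()
    # deterministic sign convention
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
    return PCModel(
        mean=mean,
        loadings=loadings,
        explained_variance_ratio=evr[:n_components].copy(),
        mask=mask,
    )


def project(tscore_map: np.ndarray, model: PCModel) -> np.ndarray:
    """Pheno-Print of a T-score map: coefficients on the fitted loadings.

    Test-set maps must be projected with the training-set model (there is
    one basis per screen).
    """
    flat = model.flatten(tscore_map) - model.mean
    return model.loadings @ flat


def project_library(
    tscore_maps: np.ndarray | list[np.ndarray], model: PCModel
) -> np.ndarray:
    """Project a stack of maps at once; rows are Pheno-Prints."""
    x = _as_matrix(tscore_maps, model.mask) - model.mean
    return x @ model.loadings.T


def reconstruct(phenoprint: np.ndarray, model: PCModel) -> np.ndarray:
    """Map a Pheno-Print back to a (denoised) T-score map on the template.

    ROIs outside the mask are NaN.
    """
    pp = np.asarray(phenoprint, dtype=float)
    if pp.shape != (model.n_components,):
        raise ValueError(
            f"coefficient length {pp.shape} does not match n_components {model.n_components}"
        )
    flat = model.mean + model.loadings.T @ pp
    return model.embed(flat)
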