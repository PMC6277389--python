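"""Synthetic calcium movies, BAM libraries and ATC-labelled drug tables.

This module plants a known ground truth — cluster effect templates, per-drug
effect maps, transient times, and a statistical link between phenotype
clusters and therapeutic (ATC) categories — so that every downstream stage
of the screen (transient counting, T-score maps, Pheno-Prints, consensus
clustering, enrichment, prediction) can be validated against what was
actually simulated.

The emulated study design: a training library of clinical drugs in a small
number of latent phenotype clusters, a test library of unlabelled compounds
drawn from the same clusters, vehicle (DMSO) controls that carry no signal,
and replicate-level acquisition noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger("bamscope.synthetic_data")

__all__ = [
    "ConfigurationError",
    "ScenarioConfig",
    "GroundTruth",
    "BAMLibrary",
    "CalciumMovie",
    "DEFAULT_ATC_CATEGORIES",
    "make_cluster_templates",
    "simulate_bam_library",
    "resimulate_replicates",
    "simulate_movie",
    "assign_atc",
]

#: Level-2 ATC codes used as the default category universe (seven categories,
#: matching the breadth of a CNS-focused clinical library).
DEFAULT_ATC_CATEGORIES = ("N03", "N04", "N05", "N06", "A03", "C01", "R06")


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is invalid or unsatisfiable."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the simulated screening campaign.

    Amplitudes and noise SDs are in calcium-transient-count units (the unit
    of a BAM entry): ``effect_amplitude`` is the mean absolute change in
    transient counts a drug induces in its affected regions,
    ``within_cluster_sd`` the SD of a drug's deviation from its cluster
    template, and ``replicate_sd`` the per-acquisition (per-larva)
    measurement noise SD.
    """

    n_train_drugs: int = 179
    n_test_drugs: int = 121
    n_clusters: int = 10
    n_replicates: int = 5
    grid_h: int = 60
    grid_w: int = 40
    n_layers: int = 2
    effect_amplitude: float = 8.0
    within_cluster_sd: float | None = None  # default 0.25 * effect_amplitude
    replicate_sd: float | None = None  # default 0.5 * effect_amplitude
    atc_purity: float = 0.6
    n_atc_categories: int = 7
    n_dmso_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_train_drugs": self.n_train_drugs,
            "n_test_drugs": self.n_test_drugs,
            "n_clusters": self.n_clusters,
            "n_replicates": self.n_replicates,
            "grid_h": self.grid_h,
            "grid_w": self.grid_w,
            "n_layers": self.n_layers,
            "n_atc_categories": self.n_atc_categories,
            "n_dmso_replicates": self.n_dmso_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_clusters > self.n_train_drugs:
            raise ConfigurationError("n_clusters may not exceed n_train_drugs")
        if not (0.0 <= self.atc_purity <= 1.0):
            raise ConfigurationError(f"atc_purity must lie in [0, 1], got {self.atc_purity}")
        for name in ("effect_amplitude", "within_cluster_sd", "replicate_sd"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")

    @property
    def within_sd(self) -> float:
        return 0.25 * self.effect_amplitude if self.within_cluster_sd is None else self.within_cluster_sd

    @property
    def rep_sd(self) -> float:
        return 0.5 * self.effect_amplitude if self.replicate_sd is None else self.replicate_sd


@dataclass
class GroundTruth:
    """Planted truth of a simulated library.

    Attributes
    ----------
    true_cluster
        drug_id -> planted cluster label (1-based). Controls are absent.
    templates
        (n_clusters, grid_h, grid_w) signed effect templates, max |.| = 1.
    linked_category
        cluster label -> the ATC category statistically linked to it.
    effect_maps
        drug_id -> the drug's personal mean BAM (template x amplitude plus
        the drug-specific offset); the expectation of every replicate.
    membership
        drug_id -> "training" | "test" | "control".
    transient_times
        Populated by :func:`simulate_movie` callers: per-ROI planted event
        times, keyed however the caller chooses.
    """

    true_cluster: dict[str, int]
    templates: np.ndarray
    linked_category: dict[int, str]
    effect_maps: dict[str, np.ndarray]
    membership: dict[str, str]
    transient_times: dict = field(default_factory=dict)

    def labels_for(self, membership: str) -> pd.Series:
        ids = [d for d, m in self.membership.items() if m == membership]
        return pd.Series({d: self.true_cluster[d] for d in ids}, name="true_cluster")


@dataclass
class BAMLibrary:
    """Stacks of replicate BAMs keyed by compound id.

    ``bams[drug_id]`` is an int array of shape (n_replicates, grid_h, grid_w).
    """

    bams: dict[str, np.ndarray]
    grid_h: int
    grid_w: int

    @property
    def drug_ids(self) -> list[str]:
        return list(self.bams)


@dataclass
class CalciumMovie:
    """A multi-plane fluorescence time series with acquisition metadata."""

    data: np.ndarray  # (T, n_planes, H_px, W_px), arbitrary fluorescence units
    fs: float  # frames / s
    pixel_area_um2: float
    plane_spacing_um: float
    pre_frames: tuple[int, int]  # [start, stop) frame indices of the pre epoch
    post_frames: tuple[int, int]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("movie intensities must be finite and non-negative")
        if not (self.pre_frames[0] < self.pre_frames[1] <= self.post_frames[0] < self.post_frames[1]):
            raise ValueError("pre and post intervals must be disjoint and ordered")


# ---------------------------------------------------------------------------
# Cluster effect templates
# ---------------------------------------------------------------------------

def _random_template(rng: np.random.Generator, grid_h: int, grid_w: int) -> np.ndarray:
    """One smooth, signed, mirror-symmetric effect map from 3-5 blocks.

    Blocks are horizontal bands (forebrain / midbrain / hindbrain style) or
    lateralised patch pairs mirrored about the vertical midline.
    """
    n_bands = 6 if grid_h >= 24 else max(2, grid_h // 4)
    band_edges = np.linspace(0, grid_h, n_bands + 1).astype(int)
    n_blocks = int(rng.integers(3, 6))
    m = np.zeros((grid_h, grid_w))
    for _ in range(n_blocks):
        band = int(rng.integers(n_bands))
        r0, r1 = band_edges[band], band_edges[band + 1]
        sign = -1.0 if rng.random() < 0.5 else 1.0
        amp = sign * rng.uniform(0.7, 1.0)
        if rng.random() < 0.5:  # full-width band
            m[r0:r1, :] += amp
        else:  # lateralised mirrored patch pair
            w = int(rng.integers(max(2, grid_w // 8), max(3, grid_w // 3)))
            c0 = int(rng.integers(0, max(1, grid_w // 2 - w + 1)))
            m[r0:r1, c0:c0 + w] += amp
            m[r0:r1, grid_w - c0 - w:grid_w - c0] += amp
    m = gaussian_filter(m, sigma=1.5, mode="nearest")
    m = 0.5 * (m + m[:, ::-1])  # enforce exact left-right symmetry
    peak = np.max(np.abs(m))
    if peak > 0:
        # unit scale = mean |value| over the affected region, so that
        # effect_amplitude is the mean absolute change where the drug acts
        affected = np.abs(m) > 0.25 * peak
        m /= np.abs(m[affected]).mean()
    return m


def make_cluster_templates(
    n_clusters: int,
    grid_h: int,
    grid_w: int,
    seed: int,
    max_pairwise_corr: float = 0.5,
    max_tries: int = 500,
) -> np.ndarray:
    """Generate ``n_clusters`` distinct spatial effect templates.

    Templates are smooth signed maps built from 3-5 contiguous anatomical
    blocks, left-right mirror-symmetric, with pairwise Pearson correlation
    below ``max_pairwise_corr`` (rejection sampling).
    """
    if grid_h < 8 or grid_w < 8:
        raise ConfigurationError("grid too small to place anatomical blocks (need >= 8x8)")
    if n_clusters < 1:
        raise ConfigurationError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n_clusters:
        tries += 1
        if tries > max_tries * n_clusters:
            raise ConfigurationError(
                "could not place mutually decorrelated templates; enlarge the grid "
                "or reduce n_clusters"
            )
        cand = _random_template(rng, grid_h, grid_w)
        if np.std(cand) == 0:
            continue
        ok = all(
            abs(np.corrcoef(cand.ravel(), t.ravel())[0, 1]) < max_pairwise_corr
            for t in accepted
        )
        if ok:
            accepted.append(cand)
    return np.stack(accepted)


# ---------------------------------------------------------------------------
# BAM library simulation
# ---------------------------------------------------------------------------

def _replicate_stack(
    rng: np.random.Generator, effect: np.ndarray, n_rep: int, rep_sd: float
) -> np.ndarray:
    noisy = effect[None, :, :] + rng.normal(0.0, rep_sd, size=(n_rep,) + effect.shape)
    return np.rint(noisy).astype(np.int32)  # BAM entries are count differences


def simulate_bam_library(
    config: ScenarioConfig,
) -> tuple[BAMLibrary, GroundTruth, pd.DataFrame]:
    """Simulate the full screening library at the BAM level.

    Each replicate BAM is ``template * effect_amplitude + drug offset +
    replicate noise``, rounded to integers (BAM entries are differences of
    transient counts). DMSO controls are signal-free.

    Returns the library, the planted ground truth, and the drug table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    templates = make_cluster_templates(
        cfg.n_clusters, cfg.grid_h, cfg.grid_w, seed=int(rng.integers(2**31))
    )

    def _assign_clusters(n: int) -> np.ndarray:
        # each cluster gets at least one drug; the rest are uniform
        base = np.arange(cfg.n_clusters) % cfg.n_clusters
        if n <= cfg.n_clusters:
            return rng.permutation(base[:n]) + 1
        extra = rng.integers(cfg.n_clusters, size=n - cfg.n_clusters)
        labels = np.concatenate([base, extra])
        return rng.permutation(labels) + 1

    true_cluster: dict[str, int] = {}
    effect_maps: dict[str, np.ndarray] = {}
    membership: dict[str, str] = {}
    bams: dict[str, np.ndarray] = {}

    for prefix, n_drugs, member in (
        ("TRAIN", cfg.n_train_drugs, "training"),
        ("TEST", cfg.n_test_drugs, "test"),
    ):
        labels = _assign_clusters(n_drugs)
        for i, lab in enumerate(labels, start=1):
            drug = f"{prefix}-{i:03d}"
            effect = cfg.effect_amplitude * templates[lab - 1] + rng.normal(
                0.0, cfg.within_sd, size=templates[lab - 1].shape
            )
            true_cluster[drug] = int(lab)
            effect_maps[drug] = effect
            membership[drug] = member
            bams[drug] = _replicate_stack(rng, effect, cfg.n_replicates, cfg.rep_sd)

    # vehicle control: signal-free, noise-only replicates
    zero = np.zeros((cfg.grid_h, cfg.grid_w))
    effect_maps["DMSO"] = zero
    membership["DMSO"] = "control"
    bams["DMSO"] = _replicate_stack(rng, zero, cfg.n_dmso_replicates, cfg.rep_sd)

    if cfg.n_atc_categories <= len(DEFAULT_ATC_CATEGORIES):
        categories = DEFAULT_ATC_CATEGORIES[: cfg.n_atc_categories]
    else:
        categories = tuple(f"X{i:02d}" for i in range(cfg.n_atc_categories))
    linked = {c + 1: categories[c % cfg.n_atc_categories] for c in range(cfg.n_clusters)}
    ground_truth = GroundTruth(
        true_cluster=true_cluster,
        templates=templates,
        linked_category=linked,
        effect_maps=effect_maps,
        membership=membership,
    )
    table = assign_atc(
        ground_truth,
        cfg.atc_purity,
        seed=int(rng.integers(2**31)),
        n_categories=cfg.n_atc_categories,
    )
    library = BAMLibrary(bams=bams, grid_h=cfg.grid_h, grid_w=cfg.grid_w)
    return library, ground_truth, table


def resimulate_replicates(
    ground_truth: GroundTruth,
    drug_ids: list[str],
    n_replicates: int,
    replicate_sd: float,
    seed: int,
) -> BAMLibrary:
    """Independent re-acquisition of replicate BAMs for the given compounds.

    Uses the planted per-drug effect maps with fresh replicate noise,
    emulating a second pass of the same compounds through the instrument.
    """
    rng = np.random.default_rng(seed)
    bams = {}
    for drug in drug_ids:
        if drug not in ground_truth.effect_maps:
            raise KeyError(f"unknown drug id {drug!r}")
        bams[drug] = _replicate_stack(rng, ground_truth.effect_maps[drug], n_replicates, replicate_sd)
    h, w = next(iter(bams.values())).shape[1:]
    return BAMLibrary(bams=bams, grid_h=h, grid_w=w)


# ---------------------------------------------------------------------------
# Calcium movie simulation
# ---------------------------------------------------------------------------

def simulate_movie(
    rate_change_map: np.ndarray,
    duration_pre_s: float = 600.0,
    duration_post_s: float = 900.0,
    fs: float = 2.0,
    seed: int = 0,
    baseline_rate_hz: float = 0.05,
    baseline_f: float = 100.0,
    transient_amp: float = 30.0,
    drift_amp: float = 2.0,
    drift_freq_hz: float = 0.01,
    noise_sd: float = 1.0,
    px_per_roi: int = 2,
    n_layers: int = 1,
    plane_spacing_um: float = 100.0,
) -> tuple[CalciumMovie, dict[tuple[int, int, int], np.ndarray]]:
    """Render a synthetic calcium movie with planted transients.

    Per ROI, events are an inhomogeneous Poisson process: rate
    ``baseline_rate_hz`` during the pre epoch and ``baseline_rate_hz +
    rate_change_map[i, j]`` (Hz) during the post epoch, clipped at zero.
    Events are convolved with a fast-rise (~0.1 s) / slow-decay (~1 s)
    indicator kernel, on top of a slow sinusoidal illumination drift and
    white noise.

    Returns the movie and the planted event times keyed by
    ``(layer, roi_row, roi_col)``.
    """
    if fs < 1.0:
        raise ValueError("fs must be >= 1 Hz")
    if duration_pre_s <= 0 or duration_post_s <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    grid_h, grid_w = rate_change_map.shape
    n_pre = int(round(duration_pre_s * fs))
    n_post = int(round(duration_post_s * fs))
    n_frames = n_pre + n_post
    t = np.arange(n_frames) / fs

    # double-exponential transient kernel: ~0.1 s rise, ~1 s decay
    tk = np.arange(0, int(6 * fs) + 1) / fs
    kernel = np.exp(-tk / 1.0) - np.exp(-tk / 0.1)
    if kernel.max() > 0:
        kernel = transient_amp * kernel / kernel.max()

    drift = drift_amp * np.sin(2 * np.pi * drift_freq_hz * t)

    h_px, w_px = grid_h * px_per_roi, grid_w * px_per_roi
    data = np.empty((n_frames, n_layers, h_px, w_px), dtype=np.float32)
    events: dict[tuple[int, int, int], np.ndarray] = {}
    n_clipped = 0
    for layer in range(n_layers):
        plane = np.zeros((n_frames, grid_h, grid_w), dtype=np.float64)
        for i in range(grid_h):
            for j in range(grid_w):
                post_rate = baseline_rate_hz + rate_change_map[i, j]
                if post_rate < 0:
                    post_rate = 0.0
                    n_clipped += 1
                ev_pre = _poisson_times(rng, baseline_rate_hz, duration_pre_s)
                ev_post = duration_pre_s + _poisson_times(rng, post_rate, duration_post_s)
                ev = np.concatenate([ev_pre, ev_post])
                events[(layer, i, j)] = ev
                trace = np.zeros(n_frames)
                if ev.size:
                    idx = np.minimum((ev * fs).astype(int), n_frames - 1)
                    impulses = np.bincount(idx, minlength=n_frames).astype(float)
                    trace = np.convolve(impulses, kernel)[:n_frames]
                plane[:, i, j] = baseline_f + drift + trace
        if noise_sd > 0:
            plane = plane + rng.normal(0.0, noise_sd, size=plane.shape)
        np.clip(plane, 0.0, None, out=plane)
        data[:, layer] = np.repeat(
            np.repeat(plane, px_per_roi, axis=1), px_per_roi, axis=2
        ).astype(np.float32)
    if n_clipped:
        logger.warning("negative post-treatment rate clipped to 0 in %d ROI(s)", n_clipped)

    # ROI area is 15.21 um^2 by convention; one ROI = px_per_roi^2 pixels
    movie = CalciumMovie(
        data=data,
        fs=fs,
        pixel_area_um2=15.21 / px_per_roi**2,
        plane_spacing_um=plane_spacing_um,
        pre_frames=(0, n_pre),
        post_frames=(n_pre, n_frames),
    )
    return movie, events


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


# ---------------------------------------------------------------------------
# ATC labelling
# ---------------------------------------------------------------------------

def assign_atc(
    ground_truth: GroundTruth,
    atc_purity: float,
    seed: int,
    n_categories: int = 7,
) -> pd.DataFrame:
    """Build the drug table, statistically linking clusters to ATC categories.

    Each training drug receives its cluster's linked category with
    probability ``atc_purity`` and otherwise a uniformly random *other*
    category. Test drugs carry no ATC code; controls are labelled as such.
    """
    if not (0.0 <= atc_purity <= 1.0):
        raise ConfigurationError("atc_purity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    categories = sorted(set(ground_truth.linked_category.values()))
    if len(categories) < n_categories:
        pool = [c for c in DEFAULT_ATC_CATEGORIES if c not in categories]
        categories = sorted(categories + pool[: n_categories - len(categories)])
    rows = []
    for drug, member in ground_truth.membership.items():
        code = ""
        if member == "training":
            linked = ground_truth.linked_category[ground_truth.true_cluster[drug]]
            if rng.random() < atc_purity or len(categories) == 1:
                code = linked
            else:
                others = [c for c in categories if c != linked]
                code = others[int(rng.integers(len(others)))]
        rows.append(
            {"compound_id": drug, "name": drug.lower(), "atc_codes": code, "set": member}
        )
    return pd.DataFrame(rows)
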