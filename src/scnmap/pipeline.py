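"""End-to-end orchestration of the analysis chain for one image stack.

Stages (in order): despike -> coarsen to superpixels -> mask the
extra-tissue area -> k-medoid clustering (gap-selected or fixed k) ->
amplitude rank/trim -> per-cluster Fourier spectra with white-noise
lines -> circadian notch filter and re-cluster -> spectral-graph
clustering and embedding -> clock face and embedding coherence.  All
artifacts are written as CSV/TIFF/JSON and a machine-readable summary is
returned; identical (input, config, seed) reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import cluster as kmc
from . import graph as sg
from . import preprocess as pp
from . import spectra as sp
from .io import ImageStack, SeriesMatrix, read_stack, write_label_image

logger = logging.getLogger("scnmap")

# Summary-flag thresholds: a partition is called spatially organised when
# spectral clusters are essentially contiguous patches of the grid, and
# temporally organised when most high-amplitude clusters carry
# significant circadian power.
CONTIGUITY_THRESHOLD = 0.8
CIRCADIAN_MAJORITY = 0.5


@dataclass
class RunConfig:
    """All knobs of the pipeline; defaults follow the reference analysis."""

    input_path: str | None = None
    output_dir: str = "scnmap_out"
    dt_hours: float = 0.5
    superpixel_factor: int = 2
    despike_quantile: float = 0.0001
    mask_path: str | None = None
    k_policy: str = "auto"        # "auto" (gap statistic) or "fixed"
    k_fixed: int = 5
    k_max: int = 8
    gap_references: int = 50
    top_n: int = 6                # restrict to 5 or 6 highest-amplitude
    notch_band: tuple = (18.0, 30.0)
    sigma: float = 0.95
    embedding_dim: int = 2
    spectral_k: int = 5
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(str(source))
        payload = json.loads(p.read_text() if p.exists() else str(source))
        payload["notch_band"] = tuple(payload.get("notch_band", (18.0, 30.0)))
        return cls(**payload)


@dataclass
class PipelineResult:
    """Everything run_pipeline computed, plus the summary dict."""

    series: SeriesMatrix
    mask: np.ndarray
    kmedoid: kmc.ClusterResult
    trimmed: kmc.ClusterResult
    spectra: sp.SpectrumSet
    notched_result: kmc.ClusterResult
    notch_recluster_ari: float
    embedding: sg.EmbeddingResult
    trace: sg.ClockFaceTrace
    summary: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, stack: ImageStack | None = None,
                 write: bool = True) -> PipelineResult:
    """Execute the full analysis on a stack (loaded or passed in)."""
    if stack is None:
        if config.input_path is None:
            raise ValueError("no input stack: set input_path or pass a stack")
        stack = read_stack(config.input_path)
        stack = ImageStack(stack.data, dt_hours=config.dt_hours
                           if config.dt_hours else stack.dt_hours,
                           pixel_size_um=stack.pixel_size_um)
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_json(outdir / "config.json")

    logger.info("despiking (quantile=%g)", config.despike_quantile)
    clean = pp.despike(stack, config.despike_quantile)

    logger.info("coarsening (factor=%d)", config.superpixel_factor)
    series = pp.coarsen(clean, factor=config.superpixel_factor)

    user_mask = None
    if config.mask_path:
        import tifffile

        user_mask = tifffile.imread(config.mask_path) > 0
    mask = pp.auto_mask(clean, factor=config.superpixel_factor,
                        user_mask=user_mask)
    series = pp.apply_mask(series, mask)
    logger.info("mask keeps %d / %d superpixels",
                int(series.in_mask.sum()), series.n_series)

    # --- k-medoid clustering -------------------------------------------
    gap_curve = None
    if config.k_policy == "auto":
        gap_curve = kmc.gap_select_k(series, k_max=config.k_max,
                                     B=config.gap_references,
                                     seed=config.seed)
        k = gap_curve.chosen_k
        logger.info("gap statistic chose k = %d", k)
    else:
        k = config.k_fixed
    result = kmc.kmedoids(series, k=k, seed=config.seed)
    result.gap_curve = gap_curve
    trimmed = kmc.rank_and_trim(result, top_n=min(config.top_n, k))

    # --- Fourier spectra of the retained cluster means -----------------
    spectrum_set = sp.cluster_spectra(trimmed.mean_series, series.dt_hours,
                                      band_hours=config.notch_band)

    # --- notch filter and re-cluster ------------------------------------
    notch = sp.NotchFilter(dt_hours=series.dt_hours,
                           band_hours=config.notch_band)
    notched = SeriesMatrix(
        notch.fit(series.series).transform(series.series),
        series.coords, series.in_mask,
        dt_hours=series.dt_hours,
        superpixel_size_px=series.superpixel_size_px,
        grid_shape=series.grid_shape,
    )
    notched_result = kmc.kmedoids(notched, k=k, seed=config.seed)
    both = (result.labels >= 0) & (notched_result.labels >= 0)
    notch_ari = float(adjusted_rand_score(result.labels[both],
                                          notched_result.labels[both]))

    # --- spectral graph, embedding, clock face --------------------------
    embedding = sg.spectral_analysis(series, sigma=config.sigma,
                                     k=config.spectral_k,
                                     l=config.embedding_dim,
                                     seed=config.seed)
    trace = sg.clockface(embedding, series)
    hand = sg.clockhand_summary(trace)

    coherence = sg.spatial_coherence(embedding.labels,
                                     series.coords[embedding.node_indices])
    contiguity = sg.cluster_contiguity(
        embedding.labels, series.coords[embedding.node_indices],
        series.grid_shape,
    )
    frac_sig = float(np.mean(spectrum_set.significant_circadian))
    summary = {
        "chosen_k": int(k),
        "top_n": int(trimmed.k),
        "cluster_circadian_significant":
            [bool(s) for s in spectrum_set.significant_circadian],
        "fraction_clusters_circadian_significant": frac_sig,
        "circadian_significant": bool(frac_sig > CIRCADIAN_MAJORITY),
        "spatial_coherence_ratio": float(coherence),
        "cluster_contiguity": float(contiguity),
        "spatially_organised": bool(contiguity >= CONTIGUITY_THRESHOLD),
        "rho_mean": float(embedding.rho_mean),
        "clockhand_monotonicity": hand["monotonicity"],
        "clockhand_circ_corr": hand["circ_corr"],
        "clockhand_turns_per_24h": hand["turns_per_period"],
        "notch_recluster_ari": notch_ari,
        "n_superpixels_in_mask": int(series.in_mask.sum()),
        "seed": int(config.seed),
    }

    out = PipelineResult(
        series=series, mask=mask, kmedoid=result, trimmed=trimmed,
        spectra=spectrum_set, notched_result=notched_result,
        notch_recluster_ari=notch_ari, embedding=embedding, trace=trace,
        summary=summary,
    )
    if write:
        _write_artifacts(outdir, out, series, config)
    return out


def _write_artifacts(outdir: Path, res: PipelineResult,
                     series: SeriesMatrix, config: RunConfig) -> None:
    import pandas as pd

    grid = series.grid_shape
    write_label_image(outdir / "kmedoid_labels.tif",
                      res.trimmed.label_map(grid, series.coords))
    pd.DataFrame(res.trimmed.mean_series).to_csv(
        outdir / "cluster_mean_series.csv", index=False)
    if res.kmedoid.gap_curve is not None:
        res.kmedoid.gap_curve.to_frame().to_csv(
            outdir / "gap_curve.csv", index=False)
    res.spectra.to_frame().to_csv(outdir / "cluster_spectra.csv", index=False)

    emb = res.embedding
    coords = series.coords[emb.node_indices]
    pd.DataFrame({
        "node": emb.node_indices,
        "row": coords[:, 0],
        "col": coords[:, 1],
        "x": emb.coordinates[:, 0],
        "y": emb.coordinates[:, 1],
        "label": emb.labels,
        "rho": emb.rho,
    }).to_csv(outdir / "embedding.csv", index=False)
    pd.DataFrame({"eigenvalue": emb.eigenvalues}).to_csv(
        outdir / "eigenvalues.csv", index=False)
    img = np.zeros(grid, dtype=np.int32)
    img[coords[:, 0], coords[:, 1]] = emb.labels + 1
    write_label_image(outdir / "spectral_labels.tif", img)
    pd.DataFrame({
        "time_hours": res.trace.frame_times,
        "theta_rad": res.trace.theta,
        "n_peak_nodes": res.trace.n_peak_nodes,
    }).to_csv(outdir / "clockface.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(res.summary, indent=2, sort_keys=True))


def classify_phenotype(summary: dict) -> dict:
    """Reduce a run summary to the 2x2 spatial/temporal dissociation."""
    return {
        "spatial": bool(summary["spatially_organised"]),
        "temporal": bool(summary["circadian_significant"]),
    }


def compare_roi_vs_superpixel(roi_result: kmc.ClusterResult,
                              sp_result: kmc.ClusterResult,
                              roi_coords: np.ndarray,
                              sp_series: SeriesMatrix) -> float:
    """ARI between ROI cluster labels and the superpixel labels they sit on.

    Each ROI (pixel coordinates) inherits the label of the superpixel
    containing it; ROIs landing on excluded/masked superpixels are
    dropped and reported.  The adjusted Rand index is invariant to label
    permutation, so no explicit matching step is needed.
    """
    roi_coords = np.asarray(roi_coords)
    factor = sp_series.superpixel_size_px
    if sp_series.grid_shape is None:
        raise ValueError("superpixel series must carry its grid shape")
    h, w = sp_series.grid_shape
    grid_labels = np.full((h, w), -1, dtype=int)
    grid_labels[sp_series.coords[:, 0],
                sp_series.coords[:, 1]] = sp_result.labels

    inherited, kept = [], []
    for i, (r, c) in enumerate(roi_coords):
        gr, gc = int(r) // factor, int(c) // factor
        if not (0 <= gr < h and 0 <= gc < w) or grid_labels[gr, gc] < 0:
            logger.info("ROI %d at (%s, %s) outside mask: excluded", i, r, c)
            continue
        inherited.append(grid_labels[gr, gc])
        kept.append(i)
    if len(kept) < 2:
        raise ValueError("fewer than 2 ROIs fall on labeled superpixels")
    roi_labels = roi_result.labels[kept]
    ok = roi_labels >= 0
    return float(adjusted_rand_score(roi_labels[ok],
                                     np.asarray(inherited)[ok]))
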