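"""End-to-end image -> feature-vector pipeline."""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .edges import extract_vessel_skeleton
from .features import (
    classify_elements,
    compute_features,
    find_master_structure,
    find_meshes,
)
from .graph import build_skeleton_graph, prune_spurs
from .io import GrayscaleImage


class PipelineError(RuntimeError):
    """Stage failure wrapper carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    image: GrayscaleImage | np.ndarray,
    config: AnalysisConfig | None = None,
    return_intermediates: bool = False,
):
    """Deterministic composition of every pipeline stage.

    canny_edges -> clean_mask -> skeletonize_mask -> build_skeleton_graph
    -> classify_elements -> find_master_structure -> find_meshes ->
    compute_features. A pure function of (pixels, config): identical input
    yields bit-identical output.
    """
    config = config or AnalysisConfig()
    pixels = image.pixels if isinstance(image, GrayscaleImage) else np.asarray(image)
    stage = "edge_detection"
    try:
        mask, skeleton = extract_vessel_skeleton(pixels, config)
        if config.prune_spur_px > 0:
            skeleton = prune_spurs(
                skeleton, config.prune_spur_px, diagonal_step=config.diagonal_step
            )
        stage = "skeleton_graph"
        graph = build_skeleton_graph(skeleton, diagonal_step=config.diagonal_step)
        stage = "classify_elements"
        classification = classify_elements(graph)
        stage = "find_master_structure"
        master = find_master_structure(graph, classification)
        stage = "find_meshes"
        meshes = find_meshes(graph, master, scope=config.mesh_scope)
        stage = "compute_features"
        features = compute_features(graph, classification, master, meshes)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if return_intermediates:
        return features, {
            "mask": mask,
            "skeleton": skeleton,
            "graph": graph,
            "classification": classification,
            "master": master,
            "meshes": meshes,
        }
    return features
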