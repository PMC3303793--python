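"""End-to-end pipeline: simulate -> segment -> quantify -> fit -> track -> spatial.

Every stage logs its parameters to stderr and writes its artifact under the
configured output directory; the final JSON report is byte-identical across
runs with the same config and seed.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import segmentation, spatial_stats, synthetic_data, tracking
from .core_io import (
    ChannelStack,
    LabelMask,
    PipelineConfig,
    PipelineError,
    dumps_canonical,
    write_json,
    write_labels,
    write_nucleus_table,
    write_stack,
)
from .division_mixture import assign_populations, fit_halving_constrained, fit_mixture, select_K
from .quantification import measure_nuclei

logger = logging.getLogger("photolineage")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def _stage(name: str, **params):
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))


def segment_stack(
    stack: ChannelStack,
    k_bg: float = 3.0,
    min_size_px: int = 20,
    membrane_guided: bool = False,
    channel: str = "nuclear_converted",
) -> tuple[list[LabelMask], dict[str, segmentation.BackgroundEstimate]]:
    """Segment every frame of one nuclear channel; returns per-frame masks
    plus per-channel background estimates from frame 0."""
    masks = []
    backgrounds = {
        role: segmentation.estimate_background(stack.channel(role)[0])
        for role in stack.channel_roles
    }
    img = stack.channel(channel)
    membrane = stack.channel("membrane") if "membrane" in stack.channel_roles else None
    for t in range(stack.n_frames):
        frame = img[t]
        bg = segmentation.estimate_background(frame)
        squeeze = frame.shape[0] == 1
        mask = segmentation.segment_nuclei(
            frame[0] if squeeze else frame, bg, k_bg=k_bg, min_size_px=min_size_px, frame_index=t
        )
        if membrane_guided and membrane is not None:
            memb = membrane[t][0] if squeeze else membrane[t]
            mask = segmentation.membrane_guided_split(mask, memb)
        masks.append(mask)
    return masks, backgrounds


def quantify_stack(
    masks: list[LabelMask],
    stack: ChannelStack,
    backgrounds: dict[str, segmentation.BackgroundEstimate],
) -> pd.DataFrame:
    tables = [measure_nuclei(m, stack, backgrounds=backgrounds) for m in masks]
    return pd.concat(tables, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline for a named scenario; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    stage = "simulate"
    try:
        _stage(stage, scenario=config.scenario, seed=config.seed, no_noise=config.no_noise)
        scenario = synthetic_data.scenario_preset(
            config.scenario, seed=config.seed, no_noise=config.no_noise
        )
        stack, truth = synthetic_data.simulate_tissue(scenario)
        write_stack(stack, out / "stack.tif")
        truth.cells.to_csv(out / "truth_cells.csv", index=False)
        write_json(truth.lineage_dict(), out / "truth_lineage.json")
        (out / "scenario.yaml").write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=True))

        stage = "segment"
        _stage(stage, k_bg=config.k_bg, min_size=config.min_size_px,
               membrane_guided=config.membrane_guided)
        masks, backgrounds = segment_stack(
            stack,
            k_bg=config.k_bg,
            min_size_px=config.min_size_px,
            membrane_guided=config.membrane_guided,
        )
        write_labels(masks[-1], out / "labels.tif")

        stage = "quantify"
        _stage(stage)
        records = quantify_stack(masks, stack, backgrounds)
        write_nucleus_table(records, out / "nuclei.csv")
        final = records[records["frame"] == stack.n_frames - 1].reset_index(drop=True)
        report["n_nuclei"] = int(len(final))

        stage = "fit"
        _stage(stage, k_min=config.k_min, k_max=config.k_max, restarts=config.restarts,
               seed=config.seed)
        column = "bgsub_mean_nuclear_converted"
        included = final[final[column] > 0].reset_index(drop=True)
        report["n_excluded_below_background"] = int(len(final) - len(included))
        x = included[column].to_numpy(dtype=float)
        if config.halving_constrained:
            model = fit_halving_constrained(
                x, [0, 2, 5], restarts=config.restarts, seed=config.seed
            )
            bic_table = pd.DataFrame(
                [{"k": model.k, "log_likelihood": model.log_likelihood, "bic": model.bic}]
            )
        elif config.force_k is not None:
            model = fit_mixture(x, config.force_k, restarts=config.restarts, seed=config.seed)
            bic_table = pd.DataFrame(
                [{"k": model.k, "log_likelihood": model.log_likelihood, "bic": model.bic}]
            )
        else:
            model, bic_table = select_K(
                x, config.k_min, config.k_max, restarts=config.restarts, seed=config.seed
            )
        write_json(model.to_dict(), out / "mixture.json")
        report["selected_k"] = int(model.k)
        report["components"] = [
            {"weight": float(w), "mean": float(m), "sd": float(s)}
            for w, m, s in zip(model.weights, model.means, model.sds)
        ]
        report["bic_table"] = bic_table.to_dict(orient="records")
        assignment = assign_populations(model, included, column=column)
        counts = assignment.table["component"].value_counts().sort_index()
        report["population_counts"] = {int(k): int(v) for k, v in counts.items()}

        if stack.n_frames > 1:
            stage = "track"
            gate = config.gate_um or 4.0 * scenario.nuclear_radius_um
            _stage(stage, gate_um=gate, direction=config.direction)
            frames = [
                records[records["frame"] == t].reset_index(drop=True)
                for t in range(stack.n_frames)
            ]
            forest = tracking.build_forest(frames, gate, direction=config.direction)
            write_json(forest.to_dict(), out / "lineage.json")
            report["tracking"] = tracking.summarize_forest(forest)

        stage = "spatial"
        _stage(stage, n_perm=config.n_perm, bright_rule=config.bright_rule, seed=config.seed)
        points = spatial_stats.select_bright(
            assignment.table, included, bright_rule=config.bright_rule
        )
        h, w = stack.spatial_shape[1], stack.spatial_shape[2]
        mask = np.ones((h, w), dtype=bool)
        spatial = spatial_stats.permutation_test(
            points,
            mask,
            n_perm=config.n_perm,
            seed=config.seed,
            pixel_size_um=stack.pixel_size_um[1:],
        )
        write_json(spatial.to_dict(), out / "spatial.json")
        report["spatial"] = spatial.to_dict()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    (out / "report.json").write_bytes(dumps_canonical(report))
    return report
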