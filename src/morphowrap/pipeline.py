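"""End-to-end study orchestration: extract -> wrap -> align -> stats ->
ellipsoids -> render, from one YAML configuration.

A study is either *synthetic* (the generator fabricates both treatment
groups, so the whole pipeline runs without any input files) or
*specimen-based* (each record points at an intensity stack or surface
mesh plus a landmark file).  Stage outputs land in a run directory with
a JSON manifest recording the configuration hash, the seed, per-stage
outputs and the package version; re-running with an unchanged
configuration reuses casts already on disk, and all stages are pure
functions of their declared inputs plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ellipsoids import confidence_ellipsoids, overlap_map, permute_and_test
from .io_core import (
    SpecimenRecord,
    StudyConfig,
    export_point_table,
    read_cast,
    read_landmarks,
    read_mesh,
    read_stack,
    write_cast,
)
from .stats import (
    AXES,
    displacement_field,
    mean_model,
    qvalue_set,
    significance_counts,
    wilcoxon_map,
)
from .superimpose import align_group
from .surface import extract_surface, gaussian_blur, smooth_mesh
from .synthetic import (
    BodyParams,
    GroupEffect,
    LocalBump,
    default_grid_bbox,
    make_population,
)
from .viz import ColorMapSpec, colorize, render_model
from .wrap import build_grid, wrap_specimen

logger = logging.getLogger("morphowrap")

__all__ = ["StudyResult", "run_study", "load_study_yaml"]


@dataclass
class StudyResult:
    """In-memory bundle of everything a completed study produced."""

    config: StudyConfig
    group_labels: tuple[str, str] | tuple[str]
    casts_a: list
    casts_b: list | None
    mean_a: object | None = None
    mean_b: object | None = None
    displacement: object | None = None
    displacement_scaled: object | None = None
    tests: object | None = None
    qvalues: object | None = None
    counts: dict | None = None
    overlap: object | None = None
    permuted_overlap: list | None = None
    truth: object | None = None
    paths: dict = field(default_factory=dict)


def load_study_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise ValueError("study configuration must be a mapping")
    return spec


def _effect_from_dict(d: dict) -> GroupEffect:
    bumps = [LocalBump(tuple(b["center"]), b["sigma"], b["amplitude"]) for b in d.get("local_bumps", [])]
    kwargs = {k: v for k, v in d.items() if k not in ("local_bumps",)}
    if "local_bumps" in d:
        return GroupEffect(local_bumps=bumps, **kwargs)
    return GroupEffect(**kwargs)


def _simulate_stage(spec: dict, config: StudyConfig, out: Path):
    syn = spec["synthetic"]
    params = BodyParams(**syn.get("body", {}))
    effect = _effect_from_dict(syn.get("effect", {}))
    grid = build_grid(config.grid_rows, config.grid_cols, default_grid_bbox(params))
    study = make_population(
        grid,
        params,
        effect,
        n_control=syn.get("n_control", 10),
        n_treated=syn.get("n_treated", 9),
        seed=config.seed,
    )
    cast_dir = out / "casts"
    cast_dir.mkdir(parents=True, exist_ok=True)
    for i, cast in enumerate(study.control):
        write_cast(cast, cast_dir / f"control_{i:02d}.obj")
    for i, cast in enumerate(study.treated):
        write_cast(cast, cast_dir / f"treated_{i:02d}.obj")
    return study.control, study.treated, study.truth, grid


def _specimen_cast(rec: SpecimenRecord, config: StudyConfig, spec: dict, out: Path):
    if rec.mesh_path is not None:
        mesh = read_mesh(rec.mesh_path)
    else:
        stack_spec = spec.get("stack", {})
        spacing = stack_spec.get("spacing")
        vol = read_stack(rec.stack_path, spacing=tuple(spacing) if spacing else None)
        vol = gaussian_blur(vol, config.blur_sigma_um)
        threshold = stack_spec.get("threshold")
        if threshold is None:
            raise ValueError(f"specimen {rec.specimen_id}: extract stage needs 'stack: threshold'")
        mesh = extract_surface(vol, threshold, config.cube_size_um)
        mesh = smooth_mesh(mesh, config.smoothing_passes)
    bbox = spec.get("grid_bbox")
    if bbox is None:
        lo = mesh.vertices[:, :2].min(axis=0)
        hi = mesh.vertices[:, :2].max(axis=0)
        bbox = (lo[0], hi[0], lo[1], hi[1])
    template = build_grid(config.grid_rows, config.grid_cols, bbox)
    pairs = read_landmarks(rec.landmarks_path) if rec.landmarks_path else None
    cast = wrap_specimen(mesh, template, landmark_pairs=pairs)
    write_cast(cast, out / "casts" / f"{rec.specimen_id}.obj")
    return cast


def run_study(spec: dict | str | Path, out_dir: str | Path) -> StudyResult:
    """Execute the configured stages and write the result bundle.

    ``spec`` is the study configuration (mapping, or path to its YAML).
    Statistics and ellipsoid stages require two groups with at least two
    specimens each; wrap-only and alignment runs work with less.
    """
    if not isinstance(spec, dict):
        spec = load_study_yaml(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = StudyConfig(**spec.get("study", {}))
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }
    truth = None

    cast_dir = out / "casts"
    reuse = _can_reuse_casts(out, manifest["config_hash"])
    if "synthetic" in spec:
        labels = ("control", "treated")
        if reuse:
            casts_a = [read_cast(p) for p in sorted(cast_dir.glob("control_*.obj"))]
            casts_b = [read_cast(p) for p in sorted(cast_dir.glob("treated_*.obj"))]
            logger.info("reusing %d + %d cached casts", len(casts_a), len(casts_b))
        else:
            casts_a, casts_b, truth, _ = _simulate_stage(spec, config, out)
        manifest["stages"]["simulate"] = {"casts": sorted(p.name for p in cast_dir.glob("*.obj"))}
    elif "specimens" in spec:
        records = [SpecimenRecord(**r) for r in spec["specimens"]]
        by_group: dict[str, list] = {}
        (out / "casts").mkdir(exist_ok=True)
        for rec in records:
            by_group.setdefault(rec.group_label, []).append(
                _specimen_cast(rec, config, spec, out)
            )
        labels = tuple(by_group)
        if len(labels) > 2:
            raise ValueError(f"expected at most two groups, got {labels}")
        casts_a = by_group[labels[0]]
        casts_b = by_group[labels[1]] if len(labels) == 2 else None
        manifest["stages"]["wrap"] = {"n_casts": len(records)}
    else:
        raise ValueError("study configuration needs a 'synthetic' or 'specimens' section")

    result = StudyResult(config, labels, casts_a, casts_b, truth=truth)
    stages = spec.get("stages", ["align", "stats", "ellipsoids", "render"])

    aligned_a = aligned_b = None
    if "align" in stages:
        prototype = casts_a[0]
        aligned_a = align_group(casts_a, prototype=0, allow_scaling=config.allow_scaling)
        if casts_b is not None:
            aligned_b = align_group(casts_b, prototype=prototype, allow_scaling=config.allow_scaling)
        manifest["stages"]["align"] = {
            "prototype": f"{labels[0]}[0]",
            "allow_scaling": config.allow_scaling,
        }

    two_group_stats = casts_b is not None and len(casts_a) >= 2 and len(casts_b) >= 2
    if "stats" in stages:
        if not two_group_stats:
            raise ValueError("stats stage requires two groups with >= 2 specimens each")
        result.mean_a = mean_model(aligned_a)
        result.mean_b = mean_model(aligned_b)
        result.displacement = displacement_field(result.mean_a, result.mean_b, allow_scaling=False)
        result.displacement_scaled = displacement_field(
            result.mean_a, result.mean_b, allow_scaling=True
        )
        result.tests = wilcoxon_map(aligned_a, aligned_b)
        result.qvalues = qvalue_set(result.tests)
        result.counts = significance_counts(result.tests, config.p_threshold)
        stats_path = out / "stats.tsv"
        _write_stats_table(result, stats_path)
        export_point_table(result.mean_a, out / f"mean_{labels[0]}.csv")
        export_point_table(result.mean_b, out / f"mean_{labels[1]}.csv")
        manifest["stages"]["stats"] = {
            "table": stats_path.name,
            "significant_counts": result.counts,
            "pi0": [float(v) for v in result.qvalues.pi0],
        }

    if "ellipsoids" in stages:
        if not two_group_stats:
            raise ValueError("ellipsoid stage requires two groups with >= 2 specimens each")
        ell_a = confidence_ellipsoids(aligned_a, ci_level=config.ci_level)
        ell_b = confidence_ellipsoids(aligned_b, ci_level=config.ci_level)
        result.overlap = overlap_map(ell_a, ell_b)
        ov_path = out / "overlap.tsv"
        _write_overlap_table(result.overlap, ov_path)
        perm_spec = spec.get("permutation", {})
        if perm_spec.get("enabled", False):
            result.permuted_overlap = permute_and_test(
                aligned_a.casts,
                aligned_b.casts,
                fraction=perm_spec.get("fraction", 0.5),
                n_permutations=perm_spec.get("n_permutations", 3),
                seed=config.seed,
                ci_level=config.ci_level,
            )
        manifest["stages"]["ellipsoids"] = {
            "table": ov_path.name,
            "fraction_overlapping": result.overlap.fraction_overlapping(),
        }

    if "render" in stages and result.displacement is not None:
        d = result.displacement
        colors = colorize(d.magnitude[d.valid], ColorMapSpec("magnitude"))
        render_model(result.mean_b, _expand_colors(result.mean_b, d, colors), out / "displacement.ply")
        if result.overlap is not None:
            ov = result.overlap
            oc = colorize(ov.overlap[ov.valid], ColorMapSpec("overlap"))
            render_model(result.mean_b, _expand_colors(result.mean_b, ov, oc), out / "overlap.ply")
        manifest["stages"]["render"] = {"files": ["displacement.ply", "overlap.ply"]}

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.paths = {"out": str(out), "manifest": str(out / "manifest.json")}
    return result


def _can_reuse_casts(out: Path, config_hash: str) -> bool:
    mpath = out / "manifest.json"
    if not mpath.exists():
        return False
    try:
        with open(mpath) as fh:
            previous = json.load(fh)
    except (OSError, json.JSONDecodeError):
        return False
    return (
        previous.get("config_hash") == config_hash
        and bool(list((out / "casts").glob("*.obj")))
    )


def _expand_colors(model, fielded, colors: np.ndarray) -> np.ndarray:
    """Map colours given on a field's valid ids onto a model's valid ids."""
    model_ids = np.flatnonzero(model.valid)
    field_ids = np.flatnonzero(fielded.valid)
    lookup = {int(i): k for k, i in enumerate(field_ids)}
    out = np.full((len(model_ids), 3), 0.7)
    for row, i in enumerate(model_ids):
        k = lookup.get(int(i))
        if k is not None:
            out[row] = colors[k]
    return out


def _write_stats_table(result: StudyResult, path: Path) -> None:
    tests = result.tests
    ids = np.flatnonzero(tests.tested)
    d = result.displacement
    rows = []
    for axis_i, axis in enumerate(AXES):
        rows.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "axis": axis,
                    "p": tests.p[ids, axis_i],
                    "q": result.qvalues.q[ids, axis_i],
                    "mean_a": result.mean_a.coords[ids, axis_i],
                    "mean_b": result.mean_b.coords[ids, axis_i],
                    "dx": d.vectors[ids, 0],
                    "dy": d.vectors[ids, 1],
                    "dz": d.vectors[ids, 2],
                    "magnitude": d.magnitude[ids],
                }
            )
        )
    pd.concat(rows).sort_values(["id", "axis"]).to_csv(path, sep="\t", index=False)


def _write_overlap_table(overlap, path: Path) -> None:
    ids = np.flatnonzero(overlap.valid)
    pd.DataFrame(
        {"id": ids, "overlap": overlap.overlap[ids].astype(int), "color": overlap.colors()[ids]}
    ).to_csv(path, sep="\t", index=False)
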