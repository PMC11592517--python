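"""End-to-end workflows: mixture calibration and group comparison.

``run_calibration_workflow`` reproduces the calibration experiment in
silico: a 5-level mixture series (0/25/50/75/100% methylation) with
replicates is generated, preprocessed, read out at the four CH3 marker
windows and regressed against the nominal fraction, one calibration line
per marker.

``run_comparison_workflow`` emulates the knockdown experiment: a control
group at full effective methylation versus a perturbed group at a reduced
effective fraction, compared at the cellular marker bands, optionally with
a CD condition comparison alongside.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any

from .bands import ftir_catalog
from .io import RunConfig
from .preprocess import PreprocessConfig, preprocess_replicates
from .quantify import (
    DEFAULT_CELLULAR_WINDOWS,
    DEFAULT_SYNTHETIC_WINDOWS,
    CalibrationModel,
    ComparisonReport,
    band_intensity,
    compare_groups,
    fit_calibration,
)
from .cd import CDComparison, compare_cd
from .synthetic import (
    BaselineDrift,
    GeneratorConfig,
    generate_cd,
    generate_replicates,
    mixture_fractions,
)

log = logging.getLogger("epispec")

#: Structure of the machine-readable calibration report.
CALIBRATION_REPORT_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": ["config_hash", "seed", "levels_pct", "n_replicates", "markers"],
    "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "levels_pct": {"type": "array", "items": {"type": "number"}},
        "n_replicates": {"type": "integer"},
        "markers": {
            "type": "object",
            "additionalProperties": {
                "type": "object",
                "required": ["slope", "intercept", "r_squared", "n_points",
                             "residual_sd", "points"],
                "properties": {
                    "slope": {"type": "number"},
                    "intercept": {"type": "number"},
                    "r_squared": {"type": "number"},
                    "n_points": {"type": "integer"},
                    "residual_sd": {"type": "number"},
                    "points": {"type": "array"},
                },
            },
        },
    },
}

_TYPES = {"object": dict, "array": list, "string": str, "integer": int,
          "number": (int, float)}


def _check_node(node: Any, schema: dict, path: str) -> list[str]:
    errors = []
    expected = _TYPES.get(schema.get("type", ""))
    if expected is not None and not isinstance(node, expected):
        errors.append(f"{path}: expected {schema['type']}, got {type(node).__name__}")
        return errors
    if schema.get("type") == "object":
        for key in schema.get("required", []):
            if key not in node:
                errors.append(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, value in node.items():
            if key in props:
                errors.extend(_check_node(value, props[key], f"{path}.{key}"))
            elif isinstance(extra, dict):
                errors.extend(_check_node(value, extra, f"{path}.{key}"))
    elif schema.get("type") == "array" and "items" in schema:
        for i, item in enumerate(node):
            errors.extend(_check_node(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_calibration_report(report: dict) -> list[str]:
    """Structural validation against :data:`CALIBRATION_REPORT_SCHEMA`;
    returns a list of problems (empty when valid)."""
    return _check_node(report, CALIBRATION_REPORT_SCHEMA, "report")


def _generator_config(cfg: RunConfig) -> GeneratorConfig:
    kw = dict(cfg.generator)
    kw.setdefault("seed", cfg.seed)
    # YAML carries the drift as a plain mapping (or null for "no drift")
    if "baseline" in kw and not isinstance(kw["baseline"], BaselineDrift):
        b = kw["baseline"]
        if b is None:
            kw["baseline"] = BaselineDrift()
        else:
            kw["baseline"] = BaselineDrift(
                coeffs=tuple(b.get("coeffs", ())),
                hump=tuple(b["hump"]) if b.get("hump") else None,
            )
    return GeneratorConfig.ftir(**kw)


def _preprocess_config(cfg: RunConfig) -> PreprocessConfig:
    return PreprocessConfig(**cfg.preprocess)


def run_calibration_workflow(
    cfg: RunConfig,
) -> tuple[dict[str, CalibrationModel], dict]:
    """Generate, preprocess and calibrate the 5-level mixture series.

    Returns ``(models_by_marker, report)`` where the report is a plain
    dict validating against :data:`CALIBRATION_REPORT_SCHEMA`.
    """
    gen_cfg = _generator_config(cfg)
    pre_cfg = _preprocess_config(cfg)
    catalog = ftir_catalog(cfg.variant)
    windows = (DEFAULT_SYNTHETIC_WINDOWS if cfg.variant == "synthetic_oligo"
               else DEFAULT_CELLULAR_WINDOWS)
    fractions = mixture_fractions()
    points: dict[str, list[tuple[float, float]]] = {w.label: [] for w in windows}

    for li, f in enumerate(fractions):
        log.info("calibration level %d%%: %d replicates x %d acquisitions",
                 int(100 * f), cfg.n_replicates, cfg.n_acquisitions)
        for r in range(cfg.n_replicates):
            # each replicate = the average of n_acquisitions sequential scans
            base_seed = cfg.seed + 1000 * li + 100 * r
            scans = generate_replicates(
                catalog, f, gen_cfg, cfg.n_acquisitions, base_seed,
                sample_id=f"mix{int(round(100 * f))}_rep{r}",
            )
            avg, _ = preprocess_replicates(scans, pre_cfg)
            for w in windows:
                m = band_intensity(avg, w, mode=cfg.apex_mode)
                points[w.label].append((100.0 * f, m.intensity))

    models = {
        label: fit_calibration(pts, marker=label) for label, pts in points.items()
    }
    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "levels_pct": [100.0 * f for f in fractions],
        "n_replicates": cfg.n_replicates,
        "markers": {
            label: {
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "n_points": m.n_points,
                "residual_sd": m.residual_sd,
                "points": [list(p) for p in points[label]],
            }
            for label, m in models.items()
        },
    }
    problems = validate_calibration_report(report)
    if problems:  # defensive: a schema violation is a programming error
        raise AssertionError("invalid calibration report: " + "; ".join(problems))
    return models, report


def run_comparison_workflow(
    cfg: RunConfig, with_cd: bool = True
) -> tuple[ComparisonReport, CDComparison | None, dict]:
    """Control-vs-perturbed comparison at the cellular CH3 markers.

    The control group is generated at effective fraction 1.0, the test
    group at ``cfg.knockdown_factor`` (default 0.8, emulating the partial
    loss of global methylation after writer-enzyme knockdown). Returns
    ``(ftir_report, cd_comparison, summary_dict)``.
    """
    gen_cfg = _generator_config(cfg)
    pre_cfg = _preprocess_config(cfg)
    catalog = ftir_catalog("cellular")

    def group(f: float, tag: str, offset: int):
        out = []
        for r in range(cfg.n_replicates):
            scans = generate_replicates(
                catalog, f, gen_cfg, cfg.n_acquisitions,
                cfg.seed + offset + 100 * r, sample_id=f"{tag}_rep{r}",
            )
            out.append(preprocess_replicates(scans, pre_cfg)[0])
        return out

    group_a = group(1.0, "control", 0)
    group_b = group(cfg.knockdown_factor, "knockdown", 5000)
    report = compare_groups(group_a, group_b, DEFAULT_CELLULAR_WINDOWS,
                            mode=cfg.apex_mode)

    cd_cmp = None
    if with_cd:
        ref = generate_cd(cfg.cd_reference)
        test = generate_cd(cfg.cd_test)
        cd_cmp = compare_cd(ref, test)

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "direction": report.direction,
        "markers": {
            mc.window.label: {
                "mean_control": mc.mean_a,
                "mean_test": mc.mean_b,
                "rel_difference": mc.rel_difference,
                "p_value": mc.p_value,
                "direction": mc.direction,
            }
            for mc in report.markers
        },
    }
    if cd_cmp is not None:
        summary["cd_matched"] = [
            {
                "reference_position": p.reference.position,
                "test_position": p.test.position,
                "d_position": p.d_position,
                "d_amplitude": p.d_amplitude,
                "d_amplitude_pct": p.d_amplitude_pct,
            }
            for p in cd_cmp.matched
        ]
    return report, cd_cmp, summary


def asdict_model(m: CalibrationModel) -> dict:
    return dataclasses.asdict(m)
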