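"""End-to-end experiment orchestration from a single YAML config.

Emulates the study design: each synthetic specimen is generated once,
deformed by the wet-condition scenario (time point 1) and then — on top
of the wet result, because the dry month followed the wet month on the
same physical specimens — by the dry-condition scenario (time point 2).
Scan noise is added independently per time point; the later scan of each
pair is best-fit aligned onto the earlier one, the signed deviation
field is summarised at the shared cutoff, and the six outcomes are
compared D vs W with the exact Wilcoxon signed-rank test.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deviation import (
    DEFAULT_CUTOFF_MM,
    classify_deviation,
    deformation_summary,
    export_color_map,
    signed_deviation_field,
)
from .errors import ValidationError
from .mesh import write_stl
from .paired_stats import PairedOutcomes, compare_conditions
from .register import ICPConfig, apply_transform, best_fit_align
from .spherefit import AccuracyReport, derive_cutoff
from .synthetic import (
    ArchParams,
    DeformationScenario,
    apply_deformation,
    apply_scan_noise,
    generate_arch_appliance,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    arch: ArchParams
    wet_scenario: DeformationScenario
    dry_scenario: DeformationScenario
    noise_sigma: float = 0.0279
    n_specimens: int = 8
    cutoff: float = DEFAULT_CUTOFF_MM
    cutoff_source: str = "fixed"  # "fixed" | path of an accuracy report JSON
    magnitude_jitter: float = 0.2  # relative per-specimen scatter of magnitudes
    seed: int = 0
    output_dir: str = "archmorph_out"
    icp: ICPConfig = field(default_factory=ICPConfig)
    write_meshes: bool = True
    write_colormaps: bool = False

    def __post_init__(self) -> None:
        problems = []
        if self.n_specimens < 1:
            problems.append("n_specimens must be >= 1")
        if self.noise_sigma < 0:
            problems.append("noise_sigma must be >= 0")
        if self.cutoff_source == "fixed" and self.cutoff <= 0:
            problems.append("cutoff must be > 0 when fixed")
        if not 0.0 <= self.magnitude_jitter < 1.0:
            problems.append("magnitude_jitter must be in [0, 1)")
        if problems:
            raise ValidationError("; ".join(problems))


_CONFIG_KEYS = {
    "seed",
    "specimens",
    "noise_sigma_mm",
    "cutoff",
    "arch",
    "wet_scenario",
    "dry_scenario",
    "icp",
    "magnitude_jitter",
    "output_dir",
    "write_meshes",
    "write_colormaps",
}
_ARCH_KEYS = {
    "span_mm",
    "depth_mm",
    "band_width_mm",
    "occlusal_height_mm",
    "resolution_mm",
}
_SCENARIO_KEYS = {
    "posterior_shrink_mm",
    "palatal_lift_mm",
    "buccal_retraction_mm",
    "smoothness_mm",
}
_ICP_KEYS = {"max_iter", "rms_tol", "sample_size", "trim_fraction"}
_CUTOFF_KEYS = {"mode", "value_mm", "report_path"}


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate the YAML experiment config, listing ALL violations."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")

    problems: list[str] = []

    def check_keys(d: dict, allowed: set, where: str) -> None:
        unknown = set(d) - allowed
        if unknown:
            problems.append(f"{where}: unknown keys {sorted(unknown)}")

    check_keys(raw, _CONFIG_KEYS, "top level")
    if "seed" not in raw:
        problems.append("top level: 'seed' is required and must be explicit")

    arch_raw = raw.get("arch", {}) or {}
    check_keys(arch_raw, _ARCH_KEYS, "arch")
    scen = {}
    for name in ("wet_scenario", "dry_scenario"):
        s = raw.get(name, {}) or {}
        check_keys(s, _SCENARIO_KEYS, name)
        for key in ("posterior_shrink_mm", "palatal_lift_mm", "buccal_retraction_mm"):
            if key in s and s[key] < 0:
                problems.append(f"{name}.{key}: must be >= 0")
        scen[name] = s
    icp_raw = raw.get("icp", {}) or {}
    check_keys(icp_raw, _ICP_KEYS, "icp")
    cutoff_raw = raw.get("cutoff", {}) or {}
    check_keys(cutoff_raw, _CUTOFF_KEYS, "cutoff")
    mode = cutoff_raw.get("mode", "fixed")
    if mode not in ("fixed", "accuracy_report"):
        problems.append(f"cutoff.mode: unknown mode {mode!r}")
    if mode == "fixed" and cutoff_raw.get("value_mm", DEFAULT_CUTOFF_MM) <= 0:
        problems.append("cutoff.value_mm: must be > 0")
    if mode == "accuracy_report" and not cutoff_raw.get("report_path"):
        problems.append("cutoff.report_path: required for mode=accuracy_report")

    if problems:
        raise ValidationError("invalid config:\n  " + "\n  ".join(problems))

    arch = ArchParams(
        span=arch_raw.get("span_mm", 50.0),
        depth=arch_raw.get("depth_mm", 40.0),
        band_width=arch_raw.get("band_width_mm", 8.0),
        occlusal_height=arch_raw.get("occlusal_height_mm", 3.0),
        resolution=arch_raw.get("resolution_mm", 0.8),
    )

    def scenario(d: dict) -> DeformationScenario:
        return DeformationScenario(
            posterior_shrink=d.get("posterior_shrink_mm", 0.0),
            palatal_lift=d.get("palatal_lift_mm", 0.0),
            buccal_retraction=d.get("buccal_retraction_mm", 0.0),
            smoothness=d.get("smoothness_mm", 10.0),
        )

    if mode == "accuracy_report":
        report_path = Path(cutoff_raw["report_path"])
        if not report_path.is_absolute():
            report_path = path.parent / report_path
        report = _load_accuracy_report(report_path)
        cutoff_value = derive_cutoff(report)
        cutoff_source = str(report_path)
    else:
        cutoff_value = float(cutoff_raw.get("value_mm", DEFAULT_CUTOFF_MM))
        cutoff_source = "fixed"

    cfg = ExperimentConfig(
        arch=arch,
        wet_scenario=scenario(scen["wet_scenario"]),
        dry_scenario=scenario(scen["dry_scenario"]),
        noise_sigma=float(raw.get("noise_sigma_mm", 0.0279)),
        n_specimens=int(raw.get("specimens", 8)),
        cutoff=cutoff_value,
        cutoff_source=cutoff_source,
        magnitude_jitter=float(raw.get("magnitude_jitter", 0.2)),
        seed=int(raw["seed"]),
        output_dir=str(raw.get("output_dir", "archmorph_out")),
        icp=ICPConfig(
            max_iter=int(icp_raw.get("max_iter", 200)),
            rms_tol=float(icp_raw.get("rms_tol", 1e-6)),
            sample_size=int(icp_raw.get("sample_size", 50_000)),
            seed=int(raw["seed"]),
            trim_fraction=float(icp_raw.get("trim_fraction", 0.0)),
        ),
        write_meshes=bool(raw.get("write_meshes", True)),
        write_colormaps=bool(raw.get("write_colormaps", False)),
    )
    log.info("loaded config: %s", cfg)
    return cfg


def _load_accuracy_report(path: Path) -> AccuracyReport:
    d = json.loads(Path(path).read_text())
    return AccuracyReport(
        radii=np.asarray(d["radii_mm"], dtype=np.float64),
        true_radius=float(d["true_radius_mm"]),
        n_points=int(d["n_points"]),
        n_iterations=int(d["n_iterations"]),
        seed=int(d["seed"]),
    )


def _jitter_scenario(
    scenario: DeformationScenario, rel: float, rng: np.random.Generator
) -> DeformationScenario:
    """Scale each magnitude by an independent factor in [1-rel, 1+rel]."""
    if rel == 0.0:
        return scenario
    factors = rng.uniform(1.0 - rel, 1.0 + rel, size=3)
    return replace(
        scenario,
        posterior_shrink=scenario.posterior_shrink * factors[0],
        palatal_lift=scenario.palatal_lift * factors[1],
        buccal_retraction=scenario.buccal_retraction * factors[2],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_pair(
    reference, test, cutoff: float, icp: ICPConfig
) -> tuple:
    """Align test onto reference, compute the field, summarise.

    Returns (transform, report, field, summary).
    """
    transform, report = best_fit_align(test, reference, icp)
    aligned = apply_transform(test, transform)
    fld = signed_deviation_field(aligned, reference)
    classes = classify_deviation(fld, cutoff)
    summary = deformation_summary(fld, classes)
    return transform, report, fld, summary


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study analog; returns paths and results.

    Output tree: one directory per specimen (meshes, transforms,
    summaries), a top-level outcomes.csv, comparison.csv/json and
    manifest.json.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    seed_root = np.random.SeedSequence(config.seed)
    specimen_seeds = seed_root.spawn(config.n_specimens)

    wet_list, dry_list, ids = [], [], []
    t_start = time.time()
    for i in range(config.n_specimens):
        sid = f"specimen_{i:02d}"
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        streams = specimen_seeds[i].spawn(5)
        int_seed = lambda ss: int(ss.generate_state(1)[0])  # noqa: E731

        try:
            base = generate_arch_appliance(config.arch)
            rng_jitter = np.random.default_rng(streams[0])
            scen_w = _jitter_scenario(config.wet_scenario, config.magnitude_jitter, rng_jitter)
            scen_d = _jitter_scenario(config.dry_scenario, config.magnitude_jitter, rng_jitter)

            shape_w0 = base
            shape_w4 = apply_deformation(shape_w0, scen_w)
            shape_d4 = apply_deformation(shape_w4, scen_d)  # D0 == W4 by design

            scan_w0 = apply_scan_noise(shape_w0, config.noise_sigma, int_seed(streams[1]))
            scan_w4 = apply_scan_noise(shape_w4, config.noise_sigma, int_seed(streams[2]))
            scan_d4 = apply_scan_noise(shape_d4, config.noise_sigma, int_seed(streams[3]))
            scan_d0 = scan_w4  # same physical time point, same scan

            if config.write_meshes:
                for label, m in (("w0", scan_w0), ("w4", scan_w4), ("d4", scan_d4)):
                    p = sdir / f"scan_{label}.stl"
                    write_stl(m, p)
                    written[f"{sid}/scan_{label}.stl"] = p

            results = {}
            for cond, (ref, test) in {
                "W": (scan_w0, scan_w4),
                "D": (scan_d0, scan_d4),
            }.items():
                t0 = time.time()
                transform, report, fld, summary = analyze_pair(
                    ref, test, config.cutoff, config.icp
                )
                log.info(
                    "stage=align+deviate specimen=%s cond=%s iters=%d rms=%.2e "
                    "elapsed=%.1fs",
                    sid,
                    cond,
                    report.iterations,
                    report.rms_history[-1],
                    time.time() - t0,
                )
                p = sdir / f"transform_{cond}.json"
                p.write_text(
                    json.dumps(
                        {
                            **transform.to_dict(),
                            "rms_history": report.rms_history,
                            "iterations": report.iterations,
                            "converged": report.converged,
                        },
                        indent=2,
                    )
                )
                written[f"{sid}/transform_{cond}.json"] = p
                p = sdir / f"summary_{cond}.json"
                p.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
                written[f"{sid}/summary_{cond}.json"] = p
                if config.write_colormaps:
                    aligned = apply_transform(test, transform)
                    ply, csvp = export_color_map(
                        aligned, fld, config.cutoff, sdir / f"colormap_{cond}.ply"
                    )
                    written[f"{sid}/colormap_{cond}.ply"] = ply
                    written[f"{sid}/colormap_{cond}.csv"] = csvp
                results[cond] = summary
        except Exception as exc:
            raise RuntimeError(f"stage failed for {sid}: {exc}") from exc

        ids.append(sid)
        wet_list.append(results["W"])
        dry_list.append(results["D"])

    paired = PairedOutcomes(ids, wet_list, dry_list)
    outcomes = paired.to_frame()
    outcomes_path = out / "outcomes.csv"
    outcomes.to_csv(outcomes_path, index=False, float_format="%.12g")
    written["outcomes.csv"] = outcomes_path

    comparison = compare_conditions(paired)
    cmp_path = out / "comparison.csv"
    comparison.to_csv(cmp_path, index=False, float_format="%.12g")
    written["comparison.csv"] = cmp_path
    (out / "comparison.json").write_text(
        comparison.to_json(orient="records", indent=2)
    )
    written["comparison.json"] = out / "comparison.json"

    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest(),
        "seed": config.seed,
        "cutoff_mm": config.cutoff,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t_start, 2),
        "checksums": {k: _sha256(p) for k, p in sorted(written.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("experiment complete: %d specimens in %.1fs", config.n_specimens, manifest["elapsed_s"])

    return {
        "output_dir": out,
        "outcomes": outcomes,
        "comparison": comparison,
        "paired": paired,
        "manifest": manifest,
    }
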