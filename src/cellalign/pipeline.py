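"""End-to-end alignment pipeline and command-line interface.

Chain: ingest cell tables (μm conversion at the boundary) → optional
super-cell reduction for oversized inputs → rigid CPD coarse alignment →
windowed graph-matching refinement → final similarity transform → optional
landmark-based evaluation (ΔD/ΔT/Δθ). The moving/source side is H&E and the
fixed/target side MxIF, matching the direction the registration is used in
practice; the CLI makes the direction explicit via --source/--target.

Subcommands: ``simulate`` (write a synthetic core pair with ground truth),
``align`` (two cell tables → transform JSON + match TSV + report JSON) and
``evaluate`` (transform JSON + landmark TSV → metrics JSON).
"""

from __future__ import annotations

import argparse
import math
import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cpd import CpdConfig, CpdState, cpd_align, supercell_reduce
from .geometry import (
    AlignmentMetrics,
    LandmarkPairs,
    RigidTransform,
    evaluate_alignment,
    fit_similarity,
)
from .graphmatch import (
    GraphMatchConfig,
    MatchSet,
    RefinementFailedError,
    match_cells,
    refine_transform,
)
from .io_tables import (
    CellTable,
    read_cell_table,
    read_landmarks,
    read_transform,
    write_landmarks,
    write_match_table,
    write_cell_table,
    write_transform,
)
from .synthetic import SyntheticConfig, generate_core_pair

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AlignmentReport", "align", "load_config", "cli_main", "main"]


@dataclass
class PipelineConfig:
    """Top-level configuration: CPD and graph-matching sections plus toggles."""

    cpd: CpdConfig = field(default_factory=CpdConfig)
    graphmatch: GraphMatchConfig = field(default_factory=GraphMatchConfig)
    refine: bool = True  # disable to stop after CPD
    source_pixel_size: float = 1.0  # μm/px of source (H&E) table
    target_pixel_size: float = 1.0  # μm/px of target (MxIF) table
    source_dialect: str = "auto"
    target_dialect: str = "auto"


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file with cpd/graphmatch/io sections.

    Every key is optional; unspecified fields keep their defaults.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "cpd" in raw:
        cfg.cpd = dataclasses.replace(cfg.cpd, **raw["cpd"])
    if "graphmatch" in raw:
        gm = dict(raw["graphmatch"])
        if "node_features" in gm:
            gm["node_features"] = tuple(gm["node_features"])
        cfg.graphmatch = dataclasses.replace(cfg.graphmatch, **gm)
    io_sec = raw.get("io", {})
    for key in ("source_pixel_size", "target_pixel_size", "source_dialect", "target_dialect"):
        if key in io_sec:
            setattr(cfg, key, io_sec[key])
    if "refine" in raw:
        cfg.refine = bool(raw["refine"])
    return cfg


@dataclass
class AlignmentReport:
    """Everything the pipeline learned about one core pair."""

    cpd_transform: RigidTransform
    refined_transform: RigidTransform
    cpd_state: CpdState
    matches: MatchSet | None
    n_putative_pairs: int
    n_kept_pairs: int
    refinement_rms: float | None
    metrics_cpd: AlignmentMetrics | None = None
    metrics_refined: AlignmentMetrics | None = None
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self, include_timings: bool = True) -> dict:
        d = {
            "cpd_transform": self.cpd_transform.to_dict(),
            "refined_transform": self.refined_transform.to_dict(),
            "n_putative_pairs": self.n_putative_pairs,
            "n_kept_pairs": self.n_kept_pairs,
            "refinement_rms_um": self.refinement_rms,
            "cpd": {
                "iterations": self.cpd_state.iterations,
                "objective": self.cpd_state.objective,
                "sigma2_um2": self.cpd_state.sigma2,
                "converged": self.cpd_state.converged,
                "restart_angle_deg": self.cpd_state.restart_angle_deg,
            },
            "metrics_cpd": self.metrics_cpd.to_dict() if self.metrics_cpd else None,
            "metrics_refined": self.metrics_refined.to_dict() if self.metrics_refined else None,
            "warnings": self.warnings,
        }
        if include_timings:
            d["timings_s"] = self.timings
        return d


def _accept_refinement(
    src_xy: np.ndarray,
    tgt_xy: np.ndarray,
    cpd_tf: RigidTransform,
    min_pairs: int = 8,
) -> tuple[bool, str]:
    """Decide whether the graph-matching fit replaces the CPD transform.

    The coarse CPD solution is only replaced when the matched-cell evidence
    shows a clear improvement on data the candidate was not fitted to:
    two deterministic folds (by index parity), each fold's transform fitted
    on the complement, held-out residual medians pooled, and the candidate
    adopted only if it beats the CPD residual median by more than one
    standard error of the median. With too few pairs for a meaningful
    comparison the candidate is adopted outright (nothing to test against).
    """
    n = len(src_xy)
    if n < min_pairs:
        return True, "too few pairs to cross-validate"
    held_out: list[np.ndarray] = []
    for parity in (0, 1):
        test = np.arange(n) % 2 == parity
        try:
            fold_tf = refine_transform(src_xy[~test], tgt_xy[~test]).transform
        except RefinementFailedError:
            return True, "degenerate fold"
        held_out.append(
            np.linalg.norm(tgt_xy[test] - fold_tf.apply(src_xy[test]), axis=1)
        )
    res_gm = np.concatenate(held_out)
    res_cpd = np.linalg.norm(tgt_xy - cpd_tf.apply(src_xy), axis=1)
    m_gm = float(np.median(res_gm))
    m_cpd = float(np.median(res_cpd))
    # standard error of the median under approximate normality
    se = 1.253 * float(np.std(res_cpd)) / math.sqrt(n)
    if m_gm < m_cpd - se:
        return True, ""
    return False, (
        f"held-out pair residual {m_gm:.3f} um does not improve on CPD {m_cpd:.3f} um"
    )


def align(
    source: CellTable,
    target: CellTable,
    config: PipelineConfig | None = None,
    seed: int = 0,
    landmarks: LandmarkPairs | None = None,
) -> AlignmentReport:
    """Run the full alignment chain source→target, deterministically under ``seed``.

    If graph-matching refinement fails (too few reliable pairs), the CPD
    transform is returned as the refined transform with a warning — never a
    silent partial result. When landmarks are supplied, ΔD/ΔT/Δθ are computed
    for both the CPD-only and the refined transform against the
    landmark-derived ground truth.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    timings: dict[str, float] = {}

    cpd_source, cpd_target = source, target
    cap = config.cpd.supercell_cap
    for name, tab in (("source", source), ("target", target)):
        if len(tab) > cap:
            t0 = time.perf_counter()
            reduced = supercell_reduce(tab, linkage_distance=15.0)
            timings[f"supercell_{name}"] = time.perf_counter() - t0
            warnings.append(
                f"{name} table exceeded {cap} cells; CPD ran on {len(reduced)} super-cells"
            )
            if name == "source":
                cpd_source = reduced
            else:
                cpd_target = reduced

    t0 = time.perf_counter()
    cpd_tf, cpd_state = cpd_align(cpd_source, cpd_target, config.cpd)
    timings["cpd"] = time.perf_counter() - t0
    warnings.extend(cpd_state.warnings)

    refined_tf = cpd_tf
    matches: MatchSet | None = None
    rms: float | None = None
    if config.refine:
        t0 = time.perf_counter()
        try:
            matches = match_cells(source, target, cpd_tf, config.graphmatch, rng)
            kept = matches.kept
            if kept.sum() < 2:
                raise RefinementFailedError(
                    f"only {int(kept.sum())} pairs survived LPM filtering"
                )
            src_xy = source.xy[matches.source_index[kept]]
            tgt_xy = target.xy[matches.target_index[kept]]
            fit = refine_transform(src_xy, tgt_xy)
            adopt, reason = _accept_refinement(src_xy, tgt_xy, cpd_tf)
            if adopt:
                refined_tf = fit.transform
                rms = fit.rms_residual
            else:
                warnings.append(f"refinement not adopted ({reason}); keeping CPD transform")
        except (RefinementFailedError, ValueError) as exc:
            warnings.append(f"graph-matching refinement failed ({exc}); using CPD transform")
            logger.warning(warnings[-1])
        timings["graphmatch"] = time.perf_counter() - t0

    metrics_cpd = metrics_refined = None
    if landmarks is not None:
        gt = fit_similarity(landmarks, fix_scale=False).transform
        metrics_cpd = evaluate_alignment(cpd_tf, gt, landmarks)
        metrics_refined = evaluate_alignment(refined_tf, gt, landmarks)

    return AlignmentReport(
        cpd_transform=cpd_tf,
        refined_transform=refined_tf,
        cpd_state=cpd_state,
        matches=matches,
        n_putative_pairs=len(matches) if matches is not None else 0,
        n_kept_pairs=matches.n_kept if matches is not None else 0,
        refinement_rms=rms,
        metrics_cpd=metrics_cpd,
        metrics_refined=metrics_refined,
        warnings=warnings,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# CLI


def _cmd_simulate(args: argparse.Namespace) -> int:
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(
        n_cells=args.n_cells,
        jitter_sd=args.jitter_sd,
        dropout_rate=args.dropout_rate,
        split_rate=args.split_rate,
        merge_rate=args.merge_rate,
        seed=args.seed,
    )
    source, target, landmarks, truth = generate_core_pair(cfg)
    write_cell_table(source, out / "source_cells.tsv")
    write_cell_table(target, out / "target_cells.tsv")
    write_landmarks(landmarks, out / "landmarks.tsv")
    write_transform(truth, out / "true_transform.json")
    print(
        f"simulated core pair: {len(source)} source cells, {len(target)} target cells, "
        f"{len(landmarks)} landmarks -> {out}"
    )
    return 0


def _cmd_align(args: argparse.Namespace) -> int:
    cfg = load_config(args.config)
    if args.source_pixel_size is not None:
        cfg.source_pixel_size = args.source_pixel_size
    if args.target_pixel_size is not None:
        cfg.target_pixel_size = args.target_pixel_size
    source = read_cell_table(
        args.source, cfg.source_pixel_size, cfg.source_dialect, modality="HE"
    )
    target = read_cell_table(
        args.target, cfg.target_pixel_size, cfg.target_dialect, modality="MxIF"
    )
    landmarks = read_landmarks(args.landmarks) if args.landmarks else None
    report = align(source, target, cfg, seed=args.seed, landmarks=landmarks)

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_transform(report.refined_transform, out / "transform.json")
    write_transform(report.cpd_transform, out / "cpd_transform.json")
    if report.matches is not None:
        write_match_table(report.matches, source, target, out / "matches.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    tf = report.refined_transform
    print(
        f"aligned {len(source)} -> {len(target)} cells: "
        f"theta={tf.theta_degrees:.4f} deg, t=({tf.dx:.3f}, {tf.dy:.3f}) um, "
        f"{report.n_kept_pairs}/{report.n_putative_pairs} pairs kept"
    )
    if report.metrics_refined is not None:
        m = report.metrics_refined
        print(
            f"landmark evaluation: dD={m.delta_D:.3f} um, dT={m.delta_T:.3f} um, "
            f"dtheta={m.delta_theta:.4f} deg"
        )
    return 0


def _cmd_evaluate(args: argparse.Namespace) -> int:
    estimated = read_transform(args.transform)
    landmarks = read_landmarks(args.landmarks)
    gt = fit_similarity(landmarks, fix_scale=False).transform
    metrics = evaluate_alignment(estimated, gt, landmarks)
    payload = {
        "metrics": metrics.to_dict(),
        "ground_truth_transform": gt.to_dict(),
        "n_landmarks": len(landmarks),
    }
    with open(args.out, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    print(
        f"dD={metrics.delta_D:.3f} um, dT={metrics.delta_T:.3f} um, "
        f"dtheta={metrics.delta_theta:.4f} deg ({len(landmarks)} landmarks)"
    )
    return 0


def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="cellalign",
        description="Cell-anchored rigid registration of multimodal histopathology.",
    )
    p.add_argument("--log-level", default="WARNING", help="logging level (e.g. INFO)")
    sub = p.add_subparsers(dest="command", required=True)

    ps = sub.add_parser("simulate", help="generate a synthetic TMA core pair")
    ps.add_argument("--out-dir", required=True)
    ps.add_argument("--seed", type=int, default=0)
    ps.add_argument("--n-cells", type=int, default=1000)
    ps.add_argument("--jitter-sd", type=float, default=1.0)
    ps.add_argument("--dropout-rate", type=float, default=0.2)
    ps.add_argument("--split-rate", type=float, default=0.02)
    ps.add_argument("--merge-rate", type=float, default=0.02)
    ps.set_defaults(func=_cmd_simulate)

    pa = sub.add_parser("align", help="align a source (H&E) table onto a target (MxIF) table")
    pa.add_argument("--source", required=True, help="moving cell table (H&E)")
    pa.add_argument("--target", required=True, help="fixed cell table (MxIF)")
    pa.add_argument("--out-dir", required=True)
    pa.add_argument("--landmarks", default=None, help="optional landmark TSV for evaluation")
    pa.add_argument("--config", default=None, help="YAML config (cpd/graphmatch/io sections)")
    pa.add_argument("--seed", type=int, default=0)
    pa.add_argument("--source-pixel-size", type=float, default=None, help="um/px")
    pa.add_argument("--target-pixel-size", type=float, default=None, help="um/px")
    pa.set_defaults(func=_cmd_align)

    pe = sub.add_parser("evaluate", help="evaluate a transform against landmark pairs")
    pe.add_argument("--transform", required=True)
    pe.add_argument("--landmarks", required=True)
    pe.add_argument("--out", required=True)
    pe.set_defaults(func=_cmd_evaluate)
    return p


def cli_main(argv: list[str] | None = None) -> int:
    """Entry point; returns a process exit code (0 success, 1 failure, 2 usage)."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    logging.basicConfig(level=getattr(logging, args.log_level.upper(), logging.WARNING))
    try:
        return args.func(args)
    except Exception as exc:  # surface a single diagnostic line, fail nonzero
        print(f"cellalign: error: {exc}", file=sys.stderr)
        return 1


def main() -> None:
    raise SystemExit(cli_main(sys.argv[1:]))
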