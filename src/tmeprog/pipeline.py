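"""End-to-end orchestration: images -> fractions -> cohort -> report.

The demo pipeline generates all inputs from a single seed: per-patient H&E
tiles and replicate IHC cores are quantified to marker fractions, a
simulated survival cohort is built, thresholds are either searched (train
mode) or fixed (validate mode, defaults 0.027 / 0.56), and the
risk-stratified survival report is emitted together with a manifest that
makes the run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GridConfig, IhcConfig, StromaConfig
from .ihc import patient_mean_fraction, quantify_core
from .marker import MarkerThresholds, grid_search
from .stroma import CalibrationPair, estimate_calibration, quantify_tile
from .survival import stratified_report
from .synthetic import CohortSpec, HeTileSpec, IhcCoreSpec, generate_cohort, generate_he_tile, generate_ihc_core


@dataclass
class RunConfig:
    output_dir: str = "tmeprog_run"
    mode: str = "validate"  # 'train' | 'validate'
    seed: int = 0
    cd8_threshold: float = 0.027
    stroma_threshold: float = 0.56
    n_image_patients: int = 6
    cohort_n: int = 600
    stroma_config: StromaConfig = field(default_factory=StromaConfig)
    ihc_config: IhcConfig = field(default_factory=IhcConfig)
    grid_config: GridConfig = field(default_factory=GridConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("train", "validate"):
            raise ValueError("mode must be 'train' or 'validate'")


def estimate_renderer_calibration(
    n_tiles: int = 8,
    seed: int = 1000,
    stroma_config: StromaConfig = StromaConfig(),
    tile_size: int = 384,
) -> CalibrationPair:
    """Calibrate the stroma pipeline against the synthetic renderer.

    Mirrors the cross-scanner calibration procedure: raw pipeline fractions
    are regressed on ground-truth fractions over a set of generated tiles,
    yielding the (cf1, cf2) pair that maps raw estimates back to the
    ground-truth scale.  The calibration tiles use their own seed stream so
    they are disjoint from any evaluation set.
    """
    targets = np.linspace(0.15, 0.85, n_tiles)
    pairs = []
    for k, target in enumerate(targets):
        spec = HeTileSpec(
            width=tile_size, height=tile_size,
            target_stroma_fraction=float(target), seed=seed + k,
        )
        tile, _, realized = generate_he_tile(spec)
        result = quantify_tile(
            tile, stroma_config, calibration=CalibrationPair(0.0, 1.0)
        )
        pairs.append((realized, result.raw_fraction))
    return estimate_calibration(pairs, scanner_label="synthetic renderer")


def _quantify_image_patients(config: RunConfig, rng: np.random.Generator,
                             calibration: CalibrationPair) -> pd.DataFrame:
    rows = []
    for i in range(config.n_image_patients):
        tile_seed = int(rng.integers(2**31))
        target = float(rng.uniform(0.2, 0.8))
        tile, _, truth = generate_he_tile(
            HeTileSpec(target_stroma_fraction=target, seed=tile_seed)
        )
        stroma_res = quantify_tile(tile, config.stroma_config, calibration)
        core_results = []
        for _ in range(2):
            n_pos = int(rng.integers(5, 60))
            n_neg = int(rng.integers(150, 300))
            core, _ = generate_ihc_core(
                IhcCoreSpec(n_pos, n_neg, seed=int(rng.integers(2**31)))
            )
            core_results.append(quantify_core(core, config.ihc_config))
        # demo cores are small; average over all cores regardless of QC here
        fractions = [c.fraction for c in core_results if c.fraction is not None]
        cd8_mean = float(np.mean(fractions)) if fractions else None
        rows.append(
            {
                "patient_id": f"IMG{i:03d}",
                "stroma_fraction_true": truth,
                "stroma_fraction_est": stroma_res.corrected_fraction,
                "cd8_fraction_est": cd8_mean,
                "n_cores": len(core_results),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full demo pipeline; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    calibration = estimate_renderer_calibration(
        seed=int(rng.integers(2**31)), stroma_config=config.stroma_config
    )
    image_table = _quantify_image_patients(config, rng, calibration)
    image_table.to_csv(out / "image_patients.csv", index=False)

    cohort = generate_cohort(CohortSpec(n_patients=config.cohort_n,
                                        seed=int(rng.integers(2**31))))
    cohort.to_csv(out / "cohort.csv", index=False)

    from .survival import derive_endpoints

    ep = derive_endpoints(cohort, "ttr")
    table = cohort.join(ep)

    if config.mode == "train":
        gs = grid_search(table, config.grid_config)
        thresholds = gs.best
        gs.table.to_csv(out / "grid.csv", index=False)
        grid_info = {
            "best_c_index": gs.best_c_index,
            "n_combinations": gs.n_combinations,
        }
    else:
        thresholds = MarkerThresholds(config.cd8_threshold, config.stroma_threshold)
        grid_info = None

    report = stratified_report(table, thresholds, endpoint="ttr")
    report_os = stratified_report(table, thresholds, endpoint="os")
    with open(out / "report_ttr.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "report_os.json", "w") as fh:
        json.dump(report_os, fh, indent=2)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": {
            "cd8": thresholds.cd8_threshold,
            "stroma": thresholds.stroma_threshold,
        },
        "calibration": {"cf1": calibration.cf1, "cf2": calibration.cf2},
        "grid": grid_info,
        "config_hash": hashlib.sha256(
            json.dumps(
                dataclasses.asdict(config), sort_keys=True, default=str
            ).encode()
        ).hexdigest(),
        "outputs": {},
    }
    for name in ("image_patients.csv", "cohort.csv", "report_ttr.json", "report_os.json"):
        path = out / name
        if path.exists():
            manifest["outputs"][name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
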