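"""End-to-end cohort pipeline: prepare -> filter -> classify -> standardize ->
normalize -> cluster -> statistics -> report.

The cohort is either a phantom recipe (default: 6 responders + 2 progressors,
mirroring the study layout) or a list of per-patient NIfTI paths.  Output is
a :class:`CohortResult` plus ``result.json``, ``proportions.csv``,
``clusters.csv`` and a human-readable ``report.md``; everything is
deterministic under fixed seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .gmm import CLUSTER_NAMES, assign_clusters, correlate_within_clusters, fit_gmm
from .standardize import standardize_size, znormalize_table
from .stats import linear_regression, point_biserial, wilcoxon_signed_rank
from .tissue import GROUPS, TissueThresholds, classify_table, compare_timepoints, group_proportions
from .volumes import extract_masked_pairs, read_mask, read_volume, resample_to_grid
from .voxels import VoxelTable, filter_outliers, summarize

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Phantom-cohort recipe and analysis settings."""

    n_response: int = 6
    n_progression: int = 2
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    n_blobs: int = 40
    vital_coupling: float = -0.4
    thresholds: TissueThresholds = field(default_factory=TissueThresholds)
    n_target: int = 1000
    cluster_mode: str = "2d"  # "2d" | "1d"
    cluster_feature: str = "suv"  # 1D mode only
    cluster_scope: str = "per_subset"  # "per_subset" | "pooled"
    #: optional real-data inputs: list of dicts with keys
    #: patient_id, mode, and per-timepoint suv/adc/mask paths
    patients: list[dict] | None = None

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = TissueThresholds(**raw["thresholds"])
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CohortResult:
    """Everything the pipeline reports, JSON-serializable."""

    per_patient: dict
    cohort: dict
    constants: dict
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_patient": self.per_patient,
                "cohort": self.cohort,
                "normalization_constants": self.constants,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, TissueThresholds):
        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def prepare_patient(suv_path, adc_path, mask_path, patient_id: str, timepoint: str) -> VoxelTable:
    """Read volumes, resample SUV onto the MR grid, extract masked voxel pairs."""
    suv = read_volume(suv_path, "suv")
    adc = read_volume(adc_path, "adc")
    mask = read_mask(mask_path)
    suv_mr = resample_to_grid(suv, mask.grid(), "trilinear")
    df = extract_masked_pairs(suv_mr, adc, mask)
    df["patient_id"] = patient_id
    df["timepoint"] = timepoint
    return VoxelTable(df, spacing=mask.spacing)


def table_from_phantom(p: ph.Phantom, patient_id: str) -> VoxelTable:
    """Run the prepare stage on an in-memory phantom (PET -> MR grid route)."""
    suv_mr = resample_to_grid(p.suv_pet, p.mask.grid(), "trilinear")
    df = extract_masked_pairs(suv_mr, p.adc, p.mask)
    df["patient_id"] = patient_id
    df["timepoint"] = p.timepoint
    return VoxelTable(df, spacing=p.mask.spacing)


def _phantom_cohort(config: CohortConfig):
    """Yield (patient_id, mode, baseline table, post table)."""
    modes = ["response"] * config.n_response + ["progression"] * config.n_progression
    for i, mode in enumerate(modes):
        pid = f"P{i + 1:02d}"
        pcfg = ph.PhantomConfig(
            grid_shape=config.grid_shape,
            n_blobs=config.n_blobs,
            vital_coupling=config.vital_coupling,
            seed=config.seed * 1000 + i,
        )
        base = ph.generate_phantom(pcfg)
        post = ph.apply_therapy_course(base, mode)
        yield pid, mode, table_from_phantom(base, pid), table_from_phantom(post, pid)


def _file_cohort(config: CohortConfig):
    for entry in config.patients:
        pid = entry["patient_id"]
        mode = entry.get("mode", "response")
        tables = {}
        for tp in ("baseline", "post"):
            spec = entry[tp]
            tables[tp] = prepare_patient(spec["suv"], spec["adc"], spec["mask"], pid, tp)
        yield pid, mode, tables["baseline"], tables["post"]


def run_pipeline(config: CohortConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Execute the full analysis and (optionally) write report files."""
    thresholds = config.thresholds
    rng = np.random.default_rng(config.seed)

    source = _file_cohort(config) if config.patients else _phantom_cohort(config)

    per_patient: dict = {}
    standardized_frames = []
    prop_rows = []
    modes: dict[str, str] = {}
    for pid, mode, base_table, post_table in source:
        modes[pid] = mode
        per_patient[pid] = {"mode": mode}
        props = {}
        for tp, table in (("baseline", base_table), ("post", post_table)):
            table = filter_outliers(table, thresholds.adc_outlier)
            table = classify_table(table, thresholds)
            gp = group_proportions(table, thresholds)
            props[tp] = gp
            stats = summarize(table)
            per_patient[pid][tp] = {
                "summary": stats.as_dict(),
                "proportions": gp.fractions,
                "group_volume_ml": gp.volume_ml,
            }
            prop_rows.append({"patient_id": pid, "mode": mode, "timepoint": tp,
                              **{f"frac_{g}": gp.fractions[g] for g in GROUPS}})
            std = standardize_size(table, config.n_target, rng)
            standardized_frames.append(std.df)
        per_patient[pid]["change"] = compare_timepoints(props["baseline"], props["post"])

    pooled = VoxelTable(pd.concat(standardized_frames, ignore_index=True))
    pooled, constants = znormalize_table(pooled)

    cluster_out, labeled_df = _cluster_stage(pooled, config, rng)

    cohort_stats = _cohort_statistics(per_patient, modes)

    result = CohortResult(
        per_patient=per_patient,
        cohort={"clusters": cluster_out, "tests": cohort_stats},
        constants=constants,
        config={
            "n_response": config.n_response,
            "n_progression": config.n_progression,
            "seed": config.seed,
            "n_target": config.n_target,
            "cluster_mode": config.cluster_mode,
            "cluster_scope": config.cluster_scope,
            "thresholds": asdict(config.thresholds),
        },
    )
    if out_dir is not None:
        _write_outputs(result, labeled_df, prop_rows, Path(out_dir))
    return result


def _cluster_subset(df: pd.DataFrame, config: CohortConfig, seed: int):
    table = VoxelTable(df)
    if config.cluster_mode == "2d":
        data = df[["adc_norm", "suv_norm"]].to_numpy()
    else:
        data = df[f"{config.cluster_feature}_norm"].to_numpy()
    model = fit_gmm(data, k=3, seed=seed)
    labeled, proportions = assign_clusters(model, table, feature=config.cluster_feature)
    correlations = correlate_within_clusters(labeled)
    out = {
        "proportions": proportions,
        "correlations": correlations,
        "model": json.loads(model.to_json()),
    }
    return out, labeled.df


def _cluster_stage(pooled: VoxelTable, config: CohortConfig, rng) -> tuple[dict, pd.DataFrame]:
    df = pooled.df
    if config.cluster_scope == "pooled":
        subsets = {"all": df}
    else:  # mirror the study's per-subset displays
        subsets = {
            "baseline": df[df["timepoint"] == "baseline"],
            "post": df[df["timepoint"] == "post"],
        }
    out = {}
    labeled_frames = []
    for name, sub in subsets.items():
        if len(sub) < 30:
            logger.warning("cluster subset %r too small (%d voxels); skipped", name, len(sub))
            continue
        seed = int(rng.integers(2**31 - 1))
        out[name], labeled = _cluster_subset(sub.reset_index(drop=True), config, seed)
        labeled["subset"] = name
        labeled_frames.append(labeled)
    labeled_df = pd.concat(labeled_frames, ignore_index=True) if labeled_frames else pd.DataFrame()
    return out, labeled_df


def _paired_test(per_patient, pids, key_fn):
    pre = [key_fn(per_patient[p]["baseline"]) for p in pids]
    post = [key_fn(per_patient[p]["post"]) for p in pids]
    w, p = wilcoxon_signed_rank(pre, post)
    return {"n": len(pids), "pre_mean": float(np.mean(pre)), "post_mean": float(np.mean(post)),
            "W": w, "p": p}


def _cohort_statistics(per_patient: dict, modes: dict) -> dict:
    tests: dict = {}
    by_mode = {
        "all": list(per_patient),
        "response": [p for p, m in modes.items() if m == "response"],
        "progression": [p for p, m in modes.items() if m == "progression"],
    }
    for mode, pids in by_mode.items():
        if not pids:
            continue
        entry = {}
        entry["adc_mean"] = _paired_test(per_patient, pids, lambda d: d["summary"]["adc_mean"])
        entry["suv_mean"] = _paired_test(per_patient, pids, lambda d: d["summary"]["suv_mean"])
        for g in GROUPS:
            entry[f"frac_{g}"] = _paired_test(per_patient, pids, lambda d, g=g: d["proportions"][g])
        tests[mode] = entry

    # association between responding and the change in vital subvolume
    pids = list(per_patient)
    if len({modes[p] for p in pids}) == 2 and len(pids) >= 3:
        binary = np.array([1 if modes[p] == "response" else 0 for p in pids])
        delta_vital = np.array([
            per_patient[p]["post"]["proportions"]["vital"]
            - per_patient[p]["baseline"]["proportions"]["vital"]
            for p in pids
        ])
        r, p_val = point_biserial(binary, delta_vital)
        slope, intercept, r2 = linear_regression(binary.astype(float), delta_vital)
        tests["response_vs_delta_vital"] = {
            "point_biserial_r": r, "p": p_val,
            "slope": slope, "intercept": intercept, "r_squared": r2,
        }
    return tests


def _format_pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def _write_outputs(result: CohortResult, labeled: pd.DataFrame, prop_rows, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    clusters = result.cohort["clusters"]

    (out_dir / "result.json").write_text(result.to_json() + "\n")
    pd.DataFrame(prop_rows).to_csv(out_dir / "proportions.csv", index=False)
    if not labeled.empty:
        labeled.to_csv(out_dir / "clusters.csv", index=False)

    lines = ["# Cohort report", ""]
    lines += ["## Tissue-group proportions (threshold rule)", ""]
    lines += ["| group | " + " | ".join(
        f"{m} {tp}" for m in ("response", "progression") for tp in ("baseline", "post")) + " |"]
    lines += ["|" + "---|" * 5]
    by_mode_tp: dict = {}
    for row in prop_rows:
        by_mode_tp.setdefault((row["mode"], row["timepoint"]), []).append(row)
    for g in GROUPS:
        cells = []
        for m in ("response", "progression"):
            for tp in ("baseline", "post"):
                rows = by_mode_tp.get((m, tp), [])
                if rows:
                    cells.append(_format_pct(float(np.mean([r[f"frac_{g}"] for r in rows]))))
                else:
                    cells.append("-")
        lines.append(f"| {g} | " + " | ".join(cells) + " |")
    lines += ["", "## GMM clusters", ""]
    for name, entry in clusters.items():
        lines.append(f"### subset: {name}")
        for cl in CLUSTER_NAMES:
            frac = entry["proportions"][cl]
            corr = entry["correlations"][cl]
            r_txt = "n/a" if corr["r"] is None else f"{corr['r']:.3f}"
            lines.append(f"- {cl}: {_format_pct(frac)} of voxels, ADC-SUV R = {r_txt} (n={corr['n']})")
        lines.append("")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
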