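"""End-to-end pipeline: simulate -> segment -> quantify -> kinetics -> compare.

The pipeline is driven by a :class:`PipelineConfig` (loadable from
YAML), writes every artifact (movie and mask TIFFs, feature CSV, fit
and statistics JSON) into an output directory together with a manifest
(config hash, seed, package versions, per-file checksums), and is fully
deterministic under a fixed seed: re-running an identical config
reproduces byte-identical feature tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import ImageStack, PhotoactivationProtocol
from .kinetics import compare_groups, fit_recruitment, summarize_embryo
from .quantify import QuantificationParams, build_feature_table
from .segmentation import SegmentationParams, segment_stack
from .synthetic import SyntheticParams, save_movie, simulate_movie

__all__ = ["StatsPlan", "PipelineConfig", "read_stack", "write_stack", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "quantify", "kinetics", "compare")


@dataclass(frozen=True)
class StatsPlan:
    """Group comparison run by the `compare` stage.

    Groups cells of the final frame by activation-region membership and
    compares the chosen variable between the groups.
    """

    variable: str = "area_um2"
    test: str = "student_pooled"
    log_transform: bool = True
    m_comparisons: int = 1


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible pipeline run."""

    out_dir: str = "optofurrow_out"
    input_stack: str | None = None  # None -> synthetic movie
    n_frames: int = 10
    seed: int = 0
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)
    protocol: PhotoactivationProtocol = field(default_factory=PhotoactivationProtocol)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    quantification: QuantificationParams = field(default_factory=QuantificationParams)
    stats: StatsPlan = field(default_factory=StatsPlan)
    summary_z: int = 0  # z plane used for embryo-level summaries (apical-most)
    embryo_id: str = "embryo"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        # propagate the run seed into the generator
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "input_stack": self.input_stack,
            "n_frames": self.n_frames,
            "seed": self.seed,
            "synthetic": self.synthetic.to_dict(),
            "protocol": self.protocol.to_dict(),
            "segmentation": dataclasses.asdict(self.segmentation),
            "quantification": dataclasses.asdict(self.quantification),
            "stats": dataclasses.asdict(self.stats),
            "summary_z": self.summary_z,
            "embryo_id": self.embryo_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticParams.from_dict(d["synthetic"])
        if "protocol" in d:
            d["protocol"] = PhotoactivationProtocol.from_dict(d["protocol"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "quantification" in d:
            d["quantification"] = QuantificationParams(**d["quantification"])
        if "stats" in d:
            d["stats"] = StatsPlan(**d["stats"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a TZCYX TIFF with calibration in the image description."""
    meta = {
        "axes": "TZCYX",
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_roles": list(stack.channel_roles),
    }
    tifffile.imwrite(Path(path), stack.data.astype(np.float32), description=json.dumps(meta))


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_roles: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a TIFF stack into TZCYX form.

    Axes and calibration come from the JSON image description written
    by :func:`write_stack`; explicit arguments override it.  A missing
    pixel size or frame interval without an override is a hard error —
    never a silent default.  A plain 2-D TIFF is promoted to
    T = Z = C = 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    axes = meta.get("axes")
    if arr.ndim == 2:
        arr = arr[None, None, None]
    elif arr.ndim == 5:
        if axes is not None and axes != "TZCYX":
            raise ValueError(f"ambiguous axes {axes!r}: expected TZCYX")
    else:
        raise ValueError(
            f"cannot interpret {arr.ndim}-D TIFF without TZCYX metadata (shape {arr.shape})"
        )

    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if px is None:
        raise ValueError("missing calibration: pixel_size_um (no metadata, no override)")
    if dt is None:
        raise ValueError("missing calibration: frame_interval_s (no metadata, no override)")
    roles = channel_roles or tuple(meta.get("channel_roles", ()))
    if not roles:
        roles = ("membrane", "reporter")[: arr.shape[2]] or ("membrane",)
    return ImageStack(arr, float(px), float(dt), tuple(roles))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the output bundle.

    Returns the manifest dictionary (also written to ``manifest.json``):
    completed stages, config hash, seed, versions, and a checksum for
    every output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("optofurrow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    completed: list[str] = []
    files: dict[str, Path] = {}
    try:
        # -- simulate ------------------------------------------------------
        stage = "simulate"
        if config.input_stack is None:
            stack, truths = simulate_movie(config.synthetic, config.protocol, config.n_frames)
            paths = save_movie(out, stack, truths, config.synthetic, config.protocol)
            files.update(paths)
            logger.info("simulated %d frames, %d cells", config.n_frames, truths[0].n_cells)
        else:
            stack = read_stack(config.input_stack)
            logger.info("loaded stack %s: %s", config.input_stack, stack.data.shape)
        completed.append(stage)

        # -- segment -------------------------------------------------------
        stage = "segment"
        masks = segment_stack(stack, config.segmentation)
        mask_arr = np.stack(
            [[masks[t][z].labels.astype(np.uint16) for z in range(stack.n_z)] for t in range(stack.n_t)]
        )
        mask_path = out / "masks.tif"
        tifffile.imwrite(
            mask_path,
            mask_arr,
            description=json.dumps({"axes": "TZYX", "pixel_size_um": stack.pixel_size_um}),
        photometric="minisblack",
        )
        files["masks"] = mask_path
        n_cells = [int(masks[t][config.summary_z].labels.max()) for t in range(stack.n_t)]
        logger.info("segmented %d frames; cells per frame at z=%d: %s", stack.n_t, config.summary_z, n_cells)
        completed.append(stage)

        # -- quantify ------------------------------------------------------
        stage = "quantify"
        feats = build_feature_table(
            stack, masks, config.protocol, config.quantification, config.embryo_id
        )
        feat_path = out / "features.csv"
        feats.to_csv(feat_path, index=False, float_format="%.9g")
        files["features"] = feat_path
        logger.info("feature table: %d rows, %d dropped", len(feats), feats.attrs["n_dropped"])
        completed.append(stage)

        # -- kinetics ------------------------------------------------------
        stage = "kinetics"
        fits: dict = {}
        fz = feats[feats.z_index == config.summary_z]
        act = fz[fz.in_activation_region & fz.activation_log2_ratio.notna()]
        if len(act) and act.t_index.nunique() >= 3:
            traj = act.groupby("t_index").activation_log2_ratio.mean()
            t_exp = np.asarray(
                config.protocol.exposure_time(traj.index.to_numpy() * stack.frame_interval_s)
            )
            fit = fit_recruitment(t_exp, traj.to_numpy())
            fits["recruitment"] = {
                "plateau_log2": fit.plateau,
                "t_half_s": fit.t_half,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
                "good_fit": fit.good_fit,
            }
            logger.info("recruitment fit: t_half=%.3g s plateau=%.3g", fit.t_half, fit.plateau)
        else:
            logger.info("kinetics: no activated-cell trajectory to fit")
        fit_path = out / "fits.json"
        fit_path.write_text(json.dumps(fits, indent=2))
        files["fits"] = fit_path
        completed.append(stage)

        # -- compare -------------------------------------------------------
        stage = "compare"
        last = fz[fz.t_index == fz.t_index.max()]
        groups = {
            "activated": last[last.in_activation_region][config.stats.variable].to_numpy(),
            "non_activated": last[~last.in_activation_region][config.stats.variable].to_numpy(),
        }
        stats_rows = []
        if all(len(v) >= 2 for v in groups.values()):
            res = compare_groups(
                groups["activated"],
                groups["non_activated"],
                test=config.stats.test,
                log_transform=config.stats.log_transform,
                m_comparisons=config.stats.m_comparisons,
                names=("activated", "non_activated"),
            )
            stats_rows.append(dataclasses.asdict(res))
            logger.info("compare %s: t=%.3g p=%.3g", config.stats.variable, res.statistic, res.p)
        else:
            logger.info("compare: fewer than 2 cells in a group, skipped test")
        summary = summarize_embryo(fz, config.stats.variable)
        stats_path = out / "stats.csv"
        pd.DataFrame(stats_rows).to_csv(stats_path, index=False)
        files["stats"] = stats_path
        summary_path = out / "summary.csv"
        summary.to_csv(summary_path, index=False, float_format="%.9g")
        files["summary"] = summary_path
        completed.append(stage)
    except Exception as exc:
        logger.exception("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "stages": completed,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": {"optofurrow": __version__, "numpy": np.__version__},
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in files.items()},
    }
    manifest["files"]["log"] = {"path": log_path.name, "sha256": _sha256(log_path)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
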