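"""Readers, writers, configuration and the full-analysis orchestrator.

Tabular interchange is CSV throughout (written with a ``# key: value``
provenance header that the readers skip); masks are accepted as binary PNG
images or single-slice NIfTI volumes.  ``run_full_analysis`` ties the
stages together: for each requested comparison (A/B/C/D/NcRH) and each
dependent-variable variant (absolute, covariate-adjusted, relative) it fits
the total-area model and the 100-segment thickness model and writes
Table-1-style and segment-map reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ehi import score_table
from .morphometry import BinaryMask, MaskError, profile_pipeline
from .normalization import add_relative_columns
from .stats import (
    build_comparison,
    fit_anova,
    report,
    segmentwise_analysis,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_mask",
    "read_cohort",
    "read_cohort_inputs",
    "read_ehi_csv",
    "run_full_analysis",
    "validate_config",
    "write_cohort",
]

logger = logging.getLogger("callothick")

VARIANTS = ("absolute", "covariate", "relative")


class ConfigError(ValueError):
    """Raised with every configuration violation listed at once."""


@dataclass
class RunConfig:
    """Normalized run configuration (YAML file and/or CLI overrides)."""

    ehi_csv: str | None = None
    masks_dir: str | None = None
    fbv_csv: str | None = None
    out_dir: str = "results"
    spacing: tuple[float, float] = (0.7, 0.7)
    n_points: int = 100
    alpha: float = 0.05
    fdr_q: float = 0.05
    rel_scale: float = 100.0
    seed: int = 0
    comparisons: tuple[str, ...] = ("A", "B", "C", "D")
    variants: tuple[str, ...] = VARIANTS
    mapping: str = "standard"
    item_columns: dict | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(raw: dict | None, **overrides) -> RunConfig:
    """Normalize a parsed YAML mapping (plus keyword overrides, which take
    precedence) into a :class:`RunConfig`, reporting all violations at
    once.  An empty/missing file yields all defaults."""
    data = dict(raw or {})
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    errors = [f"unknown config key: {k}" for k in data if k not in known]
    cfg = RunConfig(**{k: v for k, v in data.items() if k in known})
    if isinstance(cfg.spacing, (list, tuple)):
        cfg.spacing = tuple(float(v) for v in cfg.spacing)
    else:
        cfg.spacing = (float(cfg.spacing), float(cfg.spacing))
    if min(cfg.spacing) <= 0:
        errors.append(f"spacing must be positive, got {cfg.spacing}")
    if cfg.n_points < 10:
        errors.append(f"n_points must be >= 10, got {cfg.n_points}")
    for name in ("alpha", "fdr_q"):
        v = getattr(cfg, name)
        if not 0 < v < 1:
            errors.append(f"{name} must lie in (0, 1), got {v}")
    if cfg.rel_scale <= 0:
        errors.append(f"rel_scale must be positive, got {cfg.rel_scale}")
    bad = [c for c in cfg.comparisons if c not in ("A", "B", "C", "D", "NcRH")]
    if bad:
        errors.append(f"unknown comparisons: {bad}")
    bad = [v for v in cfg.variants if v not in VARIANTS]
    if bad:
        errors.append(f"unknown variants: {bad}")
    if errors:
        raise ConfigError("; ".join(errors))
    cfg.comparisons = tuple(cfg.comparisons)
    cfg.variants = tuple(cfg.variants)
    logger.info("effective config: %s", asdict(cfg))
    return cfg


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    raw = None
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return validate_config(raw, **overrides)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _provenance_lines(cfg: RunConfig | None, seed: int | None = None) -> list[str]:
    lines = [f"# callothick_version: {__version__}"]
    if cfg is not None:
        lines.append(f"# config_hash: {cfg.digest()}")
        lines.append(f"# seed: {cfg.seed if seed is None else seed}")
    elif seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_cohort(
    df: pd.DataFrame, path: str | Path, cfg: RunConfig | None = None
) -> None:
    """Write a cohort table as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(cfg):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#")


def read_ehi_csv(path: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Read and score a questionnaire CSV (columns: participant_id, sex,
    one column per item with AL/UL/NP/UR/AR answers)."""
    raw = pd.read_csv(path, comment="#", dtype=str)
    cfg = cfg or RunConfig()
    return score_table(raw, mapping=cfg.mapping, item_columns=cfg.item_columns)


def read_fbv_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not {"participant_id", "fbv_mm3"} <= set(df.columns):
        raise ValueError("FBV CSV needs participant_id and fbv_mm3 columns")
    df["participant_id"] = df["participant_id"].astype(str)
    return df[["participant_id", "fbv_mm3"]]


def load_mask(path: str | Path, spacing: tuple[float, float] | None = None) -> BinaryMask:
    """Load a binary mask from PNG (any nonzero pixel is foreground) or a
    single-slice NIfTI volume (spacing taken from the header unless
    overridden)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.squeeze(np.asanyarray(img.dataobj))
        if data.ndim != 2:
            raise MaskError(f"{path.name}: expected a single-slice volume")
        if spacing is None:
            zooms = img.header.get_zooms()
            keep = [z for z, n in zip(zooms, img.shape) if n > 1]
            spacing = (float(keep[0]), float(keep[1]))
        grid = data > 0
    else:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            data = data[..., 0]
        grid = data > 0
        if spacing is None:
            spacing = (0.7, 0.7)
    return BinaryMask(grid=grid.astype(np.uint8), spacing=spacing)


def read_cohort_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Join questionnaire scores, morphometry of the mask directory, and
    FBV into one analysis table.

    Participants missing a mask (or whose mask fails extraction) are
    excluded and logged, mirroring the exclusion accounting of a real
    cohort.  Raises on duplicate ids or an empty join.
    """
    if cfg.ehi_csv is None or cfg.masks_dir is None or cfg.fbv_csv is None:
        raise ConfigError("ehi_csv, masks_dir and fbv_csv are all required")
    scores = read_ehi_csv(cfg.ehi_csv, cfg)
    if scores["participant_id"].duplicated().any():
        dup = scores.loc[scores["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicate participant ids: {sorted(set(dup))}")
    fbv = read_fbv_csv(cfg.fbv_csv)
    masks_dir = Path(cfg.masks_dir)
    exclusions: list[dict] = []
    rows = []
    for pid in scores["participant_id"]:
        candidates = (
            list(masks_dir.glob(f"{pid}.png"))
            + list(masks_dir.glob(f"{pid}.nii"))
            + list(masks_dir.glob(f"{pid}.nii.gz"))
        )
        if not candidates:
            exclusions.append({"participant_id": pid, "reason": "missing mask"})
            continue
        try:
            mask = load_mask(candidates[0], spacing=cfg.spacing)
            result = profile_pipeline(mask, n_points=cfg.n_points)
        except (MaskError, ValueError) as exc:
            exclusions.append(
                {"participant_id": pid, "reason": f"extraction failed: {exc}"}
            )
            continue
        row = {"participant_id": pid, "area_mm2": result.area.area_mm2}
        for k, val in enumerate(result.profile.thickness):
            row[f"thickness_{k + 1:03d}"] = val
        rows.append(row)
    for exc in exclusions:
        logger.info("excluded %(participant_id)s: %(reason)s", exc)
    if not rows:
        raise ValueError("no participant has a usable mask: empty join")
    morph = pd.DataFrame(rows)
    table = scores.merge(morph, on="participant_id", how="inner").merge(
        fbv, on="participant_id", how="inner"
    )
    if table.empty:
        raise ValueError("joining EHI, morphometry and FBV produced no rows")
    table = add_relative_columns(table, scale=cfg.rel_scale)
    return table, exclusions


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------


def _variant_spec(variant: str, cfg: RunConfig, thick_cols: list[str]):
    """(area dependent, area covariate, thickness columns, thickness cov)."""
    rel_cols = ["rel_" + c for c in thick_cols]
    return {
        "absolute": ("area_mm2", None, thick_cols, None),
        "covariate": ("area_mm2", "fbv_23", thick_cols, "fbv_13"),
        "relative": ("rel_area", None, rel_cols, None),
    }[variant]


def run_full_analysis(cohort: pd.DataFrame, cfg: RunConfig) -> dict:
    """Fit every requested comparison x variant on area and thickness.

    Per-analysis failures are isolated and recorded under ``failures``
    instead of aborting the whole run.  Writes the report files under
    ``cfg.out_dir`` and returns the in-memory bundle.
    """
    thick_cols = [f"thickness_{k + 1:03d}" for k in range(cfg.n_points)]
    area_results = []
    segment_maps = []
    failures = []
    for scheme in cfg.comparisons:
        try:
            design = build_comparison(cohort, scheme)
        except ValueError as exc:
            failures.append({"comparison": scheme, "stage": "build", "error": str(exc)})
            logger.error("comparison %s failed to build: %s", scheme, exc)
            continue
        for variant in cfg.variants:
            tag = {"comparison": scheme, "variant": variant}
            area_dep, area_cov, t_cols, t_cov = _variant_spec(variant, cfg, thick_cols)
            try:
                res = fit_anova(design, area_dep, covariate=area_cov)
                area_results.append((tag | {"dependent": "area"}, res))
                segmap = segmentwise_analysis(
                    design, t_cols, covariate=t_cov, alpha=cfg.alpha, fdr_q=cfg.fdr_q
                )
                segment_maps.append((tag, segmap))
            except (ValueError, KeyError) as exc:
                failures.append({**tag, "error": str(exc)})
                logger.error("analysis %s failed: %s", tag, exc)
    out_dir = Path(cfg.out_dir)
    bundle = report(area_results, segment_maps, out_dir=out_dir)
    bundle["failures"] = failures
    meta = {
        "version": __version__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "n_participants": int(len(cohort)),
        "failures": failures,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return bundle
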