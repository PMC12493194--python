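"""Synthetic cohorts for exercising the full analysis chain.

No open corpus callosum cohort ships with this package, so every stage is
validated against generated data with known ground truth:

* **EHI answers** are drawn from a three-class latent mixture (consistent
  right / mixed / consistent left, defaulting to 0.60 / 0.365 / 0.035) with
  class-conditional answer distributions, reproducing the J-shaped
  laterality-quotient distribution of adult cohorts (mass at strong right
  preference, a small secondary mode at strong left preference).
* **Callosal geometry** comes from a phantom: an arch-shaped spline midline
  with an in-bent anterior hook, thickened by a prescribed thickness
  function t(s) and rasterized onto a pixel grid, with the analytic area,
  the 100-point thickness ground truth and the true landmark coordinates
  recorded.
* **Forebrain volume** is constructed so that the sample correlation of
  FBV^(2/3) with callosal area hits a target r^2 (default 0.13) exactly,
  with a male-larger mean shift.
* **Effect injection** adds a standardized mean shift to chosen groups at
  chosen profile segments, enabling type-I-error and parameter-recovery
  simulations.

All generators are deterministic under a fixed seed.  The default cohort
path draws areas and thickness profiles from the calibrated statistical
model directly; ``mask_based=True`` instead rasterizes one phantom per
participant and runs the full morphometry pass on it (slower, used for
closed-loop validation at small n).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import cKDTree

from . import ehi as ehi_mod
from .ehi import EHIResponse, classify_direction, classify_habib, classify_witelson, compute_lq
from .morphometry import BinaryMask, profile_pipeline
from .normalization import add_relative_columns

__all__ = [
    "CohortSpec",
    "PhantomParams",
    "PhantomTruth",
    "build_cohort",
    "default_thickness",
    "generate_ehi",
    "generate_fbv",
    "generate_mask",
    "generate_profiles",
    "half_annulus_mask",
    "inject_effect",
]

#: Class-conditional answer emission probabilities, calibrated so that the
#: Witelson classifier recovers the latent class for essentially every draw
#: (a bounded rejection step guarantees exact recovery).
CLASS_EMISSIONS: dict[str, dict[str, float]] = {
    "consistent_right": {
        "always_right": 0.78,
        "usually_right": 0.18,
        "no_preference": 0.04,
    },
    "mixed": {
        "always_left": 0.13,
        "usually_left": 0.22,
        "no_preference": 0.22,
        "usually_right": 0.23,
        "always_right": 0.20,
    },
    "consistent_left": {
        "always_left": 0.78,
        "usually_left": 0.18,
        "no_preference": 0.04,
    },
}

_CLASS_TO_WITELSON = {
    "consistent_right": "cRH",
    "mixed": "MH",
    "consistent_left": "cLH",
}

_FALLBACK_PATTERNS = {
    "consistent_right": lambda: {i: "always_right" for i in ehi_mod.EHI_ITEMS},
    "consistent_left": lambda: {i: "always_left" for i in ehi_mod.EHI_ITEMS},
    "mixed": lambda: {
        i: ("usually_left" if i == "throwing" else "always_right")
        for i in ehi_mod.EHI_ITEMS
    },
}


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the adult reference cohort the analysis is designed
    for: ~60% consistent right-handers, ~36.5% mixed, ~3.5% consistent
    left-handers; 55% female; callosal area 691.3 +/- 94.1 mm^2 with a
    male-larger shift of 0.23 standard deviations; FBV^(2/3) explaining 13%
    of area variance at a mean FBV near 1.03e6 mm^3.
    """

    n: int = 1057
    seed: int = 0
    handedness_mixture: tuple[float, float, float] = (0.60, 0.365, 0.035)
    sex_ratio_female: float = 581 / 1057
    area_mean_mm2: float = 691.3
    area_sd_mm2: float = 94.1
    sex_area_d: float = 0.23  # male minus female, in area SD units
    fbv_area_r2: float = 0.13
    fbv_mean_mm3: float = 1.03e6
    fbv23_sd: float = 480.0
    fbv_sex_weight: float = 0.5  # male FBV shift beyond the area channel
    #: list of (label column, group level, 1-based segments, standardized d)
    injected_effects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if abs(sum(self.handedness_mixture) - 1.0) > 1e-9:
            raise ValueError("handedness mixture proportions must sum to 1")
        if not 0.0 <= self.fbv_area_r2 < 1.0:
            raise ValueError("fbv_area_r2 must lie in [0, 1)")


# ---------------------------------------------------------------------------
# EHI answers
# ---------------------------------------------------------------------------


def _draw_items(rng: np.random.Generator, emissions: dict[str, float]) -> dict:
    levels = list(emissions)
    probs = np.array([emissions[a] for a in levels])
    idx = rng.choice(len(levels), size=len(ehi_mod.EHI_ITEMS), p=probs)
    return {item: levels[k] for item, k in zip(ehi_mod.EHI_ITEMS, idx)}


def generate_ehi(
    spec: CohortSpec, rng: np.random.Generator | None = None, sexes: Sequence[str] | None = None
) -> tuple[list[EHIResponse], np.ndarray]:
    """Draw EHI answer patterns from the latent handedness mixture.

    Each participant first receives a latent class, then item answers from
    the class-conditional table; draws whose Witelson label disagrees with
    the latent class are redrawn (bounded, with a deterministic fallback
    pattern), so latent classes and qualitative labels coincide.  Returns
    the responses and the latent class per participant.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    classes = np.array(list(CLASS_EMISSIONS))[
        rng.choice(3, size=spec.n, p=np.asarray(spec.handedness_mixture))
    ]
    if sexes is None:
        sexes = np.where(
            rng.random(spec.n) < spec.sex_ratio_female, "female", "male"
        )
    responses = []
    for i in range(spec.n):
        cls = classes[i]
        target = _CLASS_TO_WITELSON[cls]
        items = None
        for _ in range(100):
            cand = _draw_items(rng, CLASS_EMISSIONS[cls])
            resp = EHIResponse(f"P{i + 1:05d}", cand, str(sexes[i]))
            if classify_witelson(resp) == target:
                items = cand
                break
        if items is None:  # astronomically unlikely; keep determinism anyway
            items = _FALLBACK_PATTERNS[cls]()
            resp = EHIResponse(f"P{i + 1:05d}", items, str(sexes[i]))
        responses.append(resp)
    return responses, classes


# ---------------------------------------------------------------------------
# phantom masks
# ---------------------------------------------------------------------------

#: Control polygon of the default arch midline (mm): an open-C arch about
#: 70 mm long and 30 mm high whose anterior end bends in and points
#: posteriorly (the rostrum hook).  x grows anterior -> posterior, y grows
#: dorsal -> ventral.
DEFAULT_CONTROL_POINTS: np.ndarray = np.array(
    [
        [14.0, 40.0],  # rostrum hook tip (posterior-pointing)
        [8.5, 38.0],
        [6.5, 30.0],
        [9.0, 18.0],
        [17.0, 10.5],
        [30.0, 7.5],
        [43.0, 7.0],
        [55.0, 9.5],
        [64.0, 15.0],
        [68.0, 25.0],
        [66.5, 36.0],  # splenium bottom
    ]
)


def default_thickness(s: np.ndarray) -> np.ndarray:
    """Callosum-like thickness profile over arc length s in [0, 1]: thin
    rostrum tip, thick genu and splenium bulbs, thinner body."""
    s = np.asarray(s, dtype=float)
    return (
        2.5
        + 5.0 * np.exp(-(((s - 0.13) / 0.11) ** 2))
        + 6.0 * np.exp(-(((s - 0.89) / 0.09) ** 2))
        + 2.8 * np.exp(-(((s - 0.50) / 0.25) ** 2))
    )


@dataclass
class PhantomParams:
    """Parameters of the rasterized band phantom."""

    control_points: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTROL_POINTS.copy()
    )
    thickness: Callable[[np.ndarray], np.ndarray] | float = default_thickness
    spacing: tuple[float, float] = (0.7, 0.7)
    scale: float = 1.0  # geometric similarity factor (lengths scale by this)
    jitter: float = 0.0  # boundary noise amplitude, mm
    margin_mm: float = 5.0
    curve_samples: int = 4000


@dataclass
class PhantomTruth:
    """Analytic ground truth recorded alongside a generated mask."""

    area_mm2: float
    thickness: np.ndarray  # t(s) at 100 equidistant arc positions
    arc_length_mm: float
    rostrum_tip: tuple[float, float]
    splenium_base: tuple[float, float]
    midline: np.ndarray  # dense arc-length-uniform midline samples (mask frame)
    thickness_dense: np.ndarray  # t(s) on the dense midline grid

    def thickness_at_points(self, points: np.ndarray) -> np.ndarray:
        """True band thickness at the arc positions nearest the given
        points (e.g. a measured midline), for alignment-free comparison of
        a measured profile with the generating thickness function."""
        tree = cKDTree(self.midline)
        _, idx = tree.query(np.asarray(points, float))
        return self.thickness_dense[idx]


def _thickness_values(params: PhantomParams, s: np.ndarray) -> np.ndarray:
    if callable(params.thickness):
        t = np.asarray(params.thickness(s), dtype=float)
    else:
        t = np.full_like(np.asarray(s, float), float(params.thickness))
    t = t * params.scale
    if np.any(t <= 0):
        raise ValueError("phantom thickness must be positive everywhere")
    return t


def _midline_curve(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length-uniform samples of the spline midline and the s grid."""
    cp = np.asarray(params.control_points, float) * params.scale
    tck, _ = interpolate.splprep([cp[:, 0], cp[:, 1]], s=0, k=3)
    u = np.linspace(0, 1, params.curve_samples)
    xy = np.column_stack(interpolate.splev(u, tck))
    seg = np.hypot(*np.diff(xy, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s_uniform = np.linspace(0, cum[-1], params.curve_samples)
    x = np.interp(s_uniform, cum, xy[:, 0])
    y = np.interp(s_uniform, cum, xy[:, 1])
    return np.column_stack([x, y]), s_uniform / cum[-1]


def _check_band_valid(midline: np.ndarray, t: np.ndarray) -> None:
    """Reject bands thicker than twice the local curvature radius (the
    offset outlines would self-intersect)."""
    d1 = np.gradient(midline, axis=0)
    d2 = np.gradient(d1, axis=0)
    speed = np.hypot(*d1.T)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.abs(cross) / speed**3
    interior = slice(5, -5)
    radius = np.where(curvature[interior] > 0, 1.0 / curvature[interior], np.inf)
    if np.any(radius < t[interior] / 2):
        raise ValueError(
            "phantom band self-intersects: thickness exceeds twice the local "
            "curvature radius"
        )


def generate_mask(
    params: PhantomParams, seed: int | None = None
) -> tuple[BinaryMask, PhantomTruth]:
    """Rasterize the band {midline(s) +/- t(s)/2} onto the pixel grid.

    A pixel is foreground iff its centre lies within t(s*)/2 of the
    midline, where s* is the nearest midline position (this rounds the two
    end caps).  The recorded analytic area is the band integral plus the
    two half-disc caps; ``jitter`` adds zero-mean noise to the local radius
    threshold, emulating segmentation noise on the boundary.
    """
    midline, s = _midline_curve(params)
    t = _thickness_values(params, s)
    _check_band_valid(midline, t)
    row_mm, col_mm = params.spacing
    m = params.margin_mm
    x0, y0 = midline.min(axis=0) - (t.max() / 2 + m)
    x1, y1 = midline.max(axis=0) + (t.max() / 2 + m)
    n_cols = int(np.ceil((x1 - x0) / col_mm))
    n_rows = int(np.ceil((y1 - y0) / row_mm))
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    px = x0 + (cols + 0.5) * col_mm
    py = y0 + (rows + 0.5) * row_mm
    centers = np.column_stack([px.ravel(), py.ravel()])
    tree = cKDTree(midline)
    dist, idx = tree.query(centers, k=1)
    radius = t[idx] / 2
    if params.jitter > 0:
        rng = np.random.default_rng(seed)
        radius = radius + params.jitter * rng.standard_normal(len(radius))
    grid = (dist <= radius).reshape(n_rows, n_cols)
    arc = _arc_len(midline)
    area = float(np.trapezoid(t, arc)) + np.pi * (t[0] / 2) ** 2 / 2 + np.pi * (
        t[-1] / 2
    ) ** 2 / 2
    s100 = np.linspace(0, 1, 100)
    truth = PhantomTruth(
        area_mm2=area,
        thickness=_thickness_values(params, s100),
        arc_length_mm=float(arc[-1]),
        rostrum_tip=tuple(
            midline[0] + _unit(midline[0] - midline[1]) * t[0] / 2 - [x0, y0]
        ),
        splenium_base=tuple(midline[-1] + [0.0, t[-1] / 2] - [x0, y0]),
        midline=midline - [x0, y0],
        thickness_dense=t,
    )
    return BinaryMask(grid=grid, spacing=params.spacing), truth


def _arc_len(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.hypot(*v)


def half_annulus_mask(
    r_inner: float = 10.0,
    r_outer: float = 16.0,
    spacing: tuple[float, float] = (0.7, 0.7),
    margin_mm: float = 3.0,
) -> tuple[BinaryMask, dict]:
    """Flat-cut half-annulus phantom (constant thickness r_outer - r_inner).

    The band spans the upper half plane around the centre (apex dorsal),
    with flat cut faces at the ends.  Returns the mask and a truth dict
    with the analytic area, the constant thickness, and landmark-override
    coordinates at the midpoints of the two cut faces.
    """
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    row_mm, col_mm = spacing
    cx = cy = r_outer + margin_mm
    n_cols = int(np.ceil((2 * r_outer + 2 * margin_mm) / col_mm))
    n_rows = int(np.ceil((r_outer + 2 * margin_mm) / row_mm))
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    px = (cols + 0.5) * col_mm
    py = (rows + 0.5) * row_mm
    rho = np.hypot(px - cx, py - cy)
    grid = (rho >= r_inner) & (rho <= r_outer) & (py <= cy)
    r_mid = 0.5 * (r_inner + r_outer)
    truth = {
        "area_mm2": np.pi * (r_outer**2 - r_inner**2) / 2,
        "thickness_mm": r_outer - r_inner,
        "landmark_override": ((cx - r_mid, cy), (cx + r_mid, cy)),
        "center": (cx, cy),
    }
    return BinaryMask(grid=grid, spacing=spacing), truth


# ---------------------------------------------------------------------------
# areas, FBV, profiles
# ---------------------------------------------------------------------------


def generate_areas(
    sexes: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Callosal areas with the spec'd mean/SD and male-larger shift."""
    male = sexes == "male"
    p_m = male.mean()
    delta = spec.sex_area_d * spec.area_sd_mm2
    shift = np.where(male, (1 - p_m) * delta, -p_m * delta)
    var_shift = p_m * (1 - p_m) * delta**2
    noise_sd = np.sqrt(max(spec.area_sd_mm2**2 - var_shift, 1e-6))
    return spec.area_mean_mm2 + shift + rng.normal(0, noise_sd, len(sexes))


def generate_fbv(
    areas: np.ndarray,
    sexes: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forebrain volumes whose converted form FBV^(2/3) correlates with
    area at exactly the target r^2 (in-sample, by construction), with a
    male-larger component beyond the shared-size channel."""
    n = len(areas)
    if n < 3:
        raise ValueError("need at least 3 participants to calibrate FBV")
    z = (areas - areas.mean()) / areas.std()
    male = (sexes == "male").astype(float)
    s_tilde = (male - male.mean()) / (male.std() if male.std() > 0 else 1.0)
    rho = float(np.mean(z * s_tilde))
    b2 = spec.fbv_sex_weight
    b1 = np.sqrt(spec.fbv_area_r2) - b2 * rho
    eps = rng.standard_normal(n)
    # orthogonalize the noise against area and sex so the target correlation
    # is met in-sample, not only in expectation
    basis = np.column_stack([np.ones(n), z, s_tilde])
    eps = eps - basis @ np.linalg.lstsq(basis, eps, rcond=None)[0]
    eps = eps / eps.std()
    explained = b1**2 + b2**2 + 2 * b1 * b2 * rho
    b3 = np.sqrt(max(1.0 - explained, 0.01))
    fbv23 = spec.fbv_mean_mm3 ** (2 / 3) + spec.fbv23_sd * (
        b1 * z + b2 * s_tilde + b3 * eps
    )
    if np.any(fbv23 <= 0):
        raise ValueError("FBV calibration produced non-positive volumes")
    return fbv23 ** 1.5


#: Mean thickness template (mm) over 100 segments: genu and splenium bulges
#: with a thinner truncus, scaled per participant by relative callosal size.
def _profile_template(n_points: int) -> np.ndarray:
    s = np.linspace(0, 1, n_points)
    return (
        5.0
        + 3.2 * np.exp(-(((s - 0.08) / 0.10) ** 2))
        + 4.0 * np.exp(-(((s - 0.92) / 0.08) ** 2))
        - 1.1 * np.exp(-(((s - 0.45) / 0.22) ** 2))
    )


def generate_profiles(
    areas: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
    n_points: int = 100,
    smooth_sd: float = 0.55,
    white_sd: float = 0.35,
    smooth_width: int = 8,
) -> np.ndarray:
    """Statistical thickness profiles: the template scaled by each
    participant's relative callosal size, plus spatially smooth subject
    noise and white measurement noise (values floored at 0.3 mm)."""
    n = len(areas)
    template = _profile_template(n_points)
    base = np.outer(areas / spec.area_mean_mm2, template)
    white = rng.standard_normal((n, n_points + 4 * smooth_width))
    kernel = np.exp(-0.5 * (np.arange(-2 * smooth_width, 2 * smooth_width + 1) / smooth_width) ** 2)
    kernel /= np.sqrt(np.sum(kernel**2))
    smooth = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, white
    )[:, :n_points]
    out = base + smooth_sd * smooth + white_sd * rng.standard_normal((n, n_points))
    return np.maximum(out, 0.3)


def inject_effect(
    profiles: np.ndarray,
    group_mask: np.ndarray,
    segments: Sequence[int],
    d: float,
    segment_sd: np.ndarray | None = None,
) -> np.ndarray:
    """Add ``d`` per-segment standard deviations to one group's thickness
    at the given 1-based segments.  Returns a copy."""
    profiles = np.asarray(profiles, float)
    segments = np.asarray(segments, int)
    if np.any((segments < 1) | (segments > profiles.shape[1])):
        raise ValueError(
            f"segment indices must lie in 1..{profiles.shape[1]}"
        )
    if d == 0:
        return profiles.copy()
    sd = profiles.std(axis=0) if segment_sd is None else np.asarray(segment_sd)
    out = profiles.copy()
    cols = segments - 1
    out[np.ix_(np.asarray(group_mask, bool), cols)] += d * sd[cols]
    return out


def moment_matched_cohort(
    emm_rh: float,
    emm_other: float,
    resid_sd: float,
    n_rh: int,
    n_other: int,
    seed: int = 0,
    rh_level: str = "cRH",
    other_level: str = "MH",
    female_fraction: float = 0.55,
) -> pd.DataFrame:
    """Two-group cohort whose sample EMMs and model residual SD equal the
    given values *exactly* (not just in expectation).

    Residuals are drawn, de-meaned within every group-by-sex cell (making
    the cell means — and hence the estimated marginal means of the
    group-by-sex model — exact) and rescaled so that the residual standard
    deviation of the saturated two-factor model equals ``resid_sd``.  Used
    to check that the effect-size plumbing reproduces a known standardized
    difference from known moments.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for level, mean, n in ((rh_level, emm_rh, n_rh), (other_level, emm_other, n_other)):
        n_f = int(round(n * female_fraction))
        for sex, n_cell in (("female", n_f), ("male", n - n_f)):
            if n_cell < 2:
                raise ValueError("each group-by-sex cell needs >= 2 members")
            resid = rng.standard_normal(n_cell)
            resid -= resid.mean()
            rows.append(
                pd.DataFrame(
                    {"group_label": level, "sex": sex, "mean": mean, "resid": resid}
                )
            )
    df = pd.concat(rows, ignore_index=True)
    dof = len(df) - 4
    ssr = float(np.sum(df["resid"] ** 2))
    df["resid"] *= resid_sd / np.sqrt(ssr / dof)
    df["area_mm2"] = df["mean"] + df["resid"]
    df["participant_id"] = [f"P{i + 1:05d}" for i in range(len(df))]
    return df[["participant_id", "sex", "group_label", "area_mm2"]]


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def build_cohort(
    spec: CohortSpec,
    n_points: int = 100,
    mask_based: bool = False,
    rel_scale: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a complete analysis-ready cohort table plus ground truth.

    The table carries the same schema the real-data ingestion path
    produces: participant_id, sex, lq, abs_lq, witelson/habib/direction
    labels, area_mm2, fbv_mm3, thickness_001..NNN and the derived
    fbv_23/fbv_13/rel_area/rel_thickness_* columns.  The ground-truth
    sidecar records latent classes, the spec and any injected effects.

    With ``mask_based=True``, a phantom mask is rasterized per participant
    (geometrically scaled to the drawn target area) and area/thickness are
    measured by the morphometry pass instead of drawn statistically.
    """
    rng = np.random.default_rng(spec.seed)
    sexes = np.where(rng.random(spec.n) < spec.sex_ratio_female, "female", "male")
    responses, classes = generate_ehi(spec, rng, sexes=sexes)
    areas = generate_areas(sexes, spec, rng)
    areas = np.maximum(areas, 50.0)
    fbv = generate_fbv(areas, sexes, spec, rng)

    truth: dict = {"latent_classes": classes, "spec": spec, "target_areas": areas.copy()}
    if mask_based:
        base_params = PhantomParams()
        _, base_truth = generate_mask(base_params)
        measured_area = np.empty(spec.n)
        profiles = np.empty((spec.n, n_points))
        phantom_truths = []
        for i in range(spec.n):
            scale = float(np.sqrt(areas[i] / base_truth.area_mm2))
            params = replace(base_params, scale=scale)
            mask, ptruth = generate_mask(params, seed=int(rng.integers(2**31)))
            result = profile_pipeline(mask, n_points=n_points)
            measured_area[i] = result.area.area_mm2
            profiles[i] = result.profile.thickness
            phantom_truths.append(ptruth)
        areas = measured_area
        truth["phantoms"] = phantom_truths
    else:
        profiles = generate_profiles(areas, spec, rng, n_points=n_points)

    rows = []
    for resp in responses:
        lq = compute_lq(resp)
        rows.append(
            {
                "participant_id": resp.participant_id,
                "sex": resp.sex,
                "lq": lq.lq,
                "abs_lq": lq.abs_lq,
                "witelson": classify_witelson(resp),
                "habib": classify_habib(lq),
                "direction": classify_direction(lq),
            }
        )
    df = pd.DataFrame(rows)
    df["area_mm2"] = areas
    df["fbv_mm3"] = fbv
    for eff in spec.injected_effects:
        label_col, level, segments, d = eff
        mask_rows = df[label_col].to_numpy() == level
        profiles = inject_effect(profiles, mask_rows, segments, d)
    thick_cols = [f"thickness_{k + 1:03d}" for k in range(n_points)]
    df = pd.concat(
        [df, pd.DataFrame(profiles, columns=thick_cols, index=df.index)], axis=1
    )
    df = add_relative_columns(df, scale=rel_scale)
    truth["injected_effects"] = list(spec.injected_effects)
    return df, truth
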