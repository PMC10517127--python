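"""Synthetic paired en-face OCT/OCTA cohorts with known planted structure.

No public scans accompany the study design this pipeline implements, so the
generator fabricates what the analysis consumes: per eye, a branching
vessel-tree OCTA image over dark stroma with multiplicative-style speckle, a
co-registered structural image, a circular foveal-avascular-zone mask, and a
covariate row.  Disease structure is planted explicitly:

- each eye carries a perivascular reflectivity elevation ``delta`` (8-bit
  intensity units) added to the structural image on a dilated band around
  vessels, confined to the designated obstructive quadrant;
- group means of ``delta`` are ordered recurrent > indolent > control (= 0),
  calibrated so the measured corrected reflectivity lands near the
  1.31 / 1.22 / 1.19 regime typical of recurrent / indolent / healthy eyes;
- the annualized intravitreal-injection rate and the refractive error are
  linearly linked to ``delta``, so the regression stage has a real signal
  to recover.

Ground truth (delta, obstructive quadrant, vessel mask) is retained for
recovery tests only; analysis modules never see it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .images import EnFaceImage, Modality, Quadrant, quadrant_mask
from .vascular import FazMask

GROUPS = ("recurrent", "indolent", "control")

_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class GroupCovariates:
    """Normal-model parameters for one group's covariate draws."""

    age: tuple[float, float]
    iop: tuple[float, float]
    refraction_se: tuple[float, float]
    bcva_logmar: tuple[float, float]
    p_female: float
    p_hypertension: float
    p_diabetes: float
    duration_months: tuple[float, float] | None = None
    sfct_um: tuple[float, float] | None = None
    cmt_um: tuple[float, float] | None = None


# (mean, SD) models chosen to emulate a typical elderly vein-occlusion cohort
DEFAULT_COVARIATES: dict[str, GroupCovariates] = {
    "recurrent": GroupCovariates(
        age=(64.6, 10.2), iop=(14.2, 3.3), refraction_se=(-1.09, 1.97),
        bcva_logmar=(0.34, 0.26), p_female=28 / 45, p_hypertension=0.40,
        p_diabetes=0.18, duration_months=(34.8, 22.7),
        sfct_um=(296.8, 81.2), cmt_um=(466.0, 155.0),
    ),
    "indolent": GroupCovariates(
        age=(64.3, 10.5), iop=(15.6, 3.9), refraction_se=(-1.75, 2.09),
        bcva_logmar=(0.25, 0.19), p_female=20 / 30, p_hypertension=0.60,
        p_diabetes=0.20, duration_months=(28.6, 23.1),
        sfct_um=(294.3, 104.0), cmt_um=(336.5, 158.0),
    ),
    "control": GroupCovariates(
        age=(62.0, 8.3), iop=(14.5, 2.2), refraction_se=(-0.90, 1.94),
        bcva_logmar=(0.05, 0.07), p_female=30 / 45, p_hypertension=0.29,
        p_diabetes=0.20,
    ),
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults ARE the study conditions.

    Intensity parameters are in 8-bit units.  ``delta_*`` are the planted
    perivascular elevations whose group ordering the pipeline must recover.
    """

    seed: int = 0
    side_px: int = 320
    extent_mm: float = 3.0
    n_per_group: tuple[int, int, int] = (45, 30, 45)  # recurrent, indolent, control

    # vessel tree
    vessel_halfwidth_px: int = 2
    target_vessel_coverage: float = 0.35
    coverage_rtol: float = 0.20
    turn_sd: float = 0.22  # radians of heading jitter per 1-px step
    max_branches: int = 400

    # intensity model (8-bit units)
    struct_background_mean: float = 110.0
    struct_background_sd: float = 10.0
    struct_vessel_contrast: float = 36.0
    octa_background_mean: float = 90.0
    octa_background_sd: float = 25.0
    octa_vessel_base: float = 120.0
    octa_speckle_scale: float = 45.0
    flow_field_rel_sigma: float = 0.05  # correlation length of the flow
    # heterogeneity field, as a fraction of the image side
    flow_field_log_sd: float = 0.4  # log-SD of the multiplicative field
    smooth_sigma: float = 0.8  # px; emulates the ~2-px speckle grain
    rim_dilation_px: int = 2

    # planted group effects (structural-intensity elevation, 8-bit units)
    delta_recurrent: float = 18.0
    delta_indolent: float = 4.5
    delta_sd: float = 6.0

    # covariate links to the planted elevation
    inj_intercept: float = 0.30
    inj_slope: float = 0.11  # injections/year per 8-bit unit of delta
    inj_noise_sd: float = 0.60
    se_delta_slope: float = 0.03  # dioptres per 8-bit unit of centered delta

    faz_radius_frac: float = 0.1125  # 36 px at side 320
    quality_mean: float = 80.0
    quality_sd: float = 5.0
    covariates: dict[str, GroupCovariates] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )

    def group_delta_mean(self, group: str) -> float:
        return {
            "recurrent": self.delta_recurrent,
            "indolent": self.delta_indolent,
            "control": 0.0,
        }[group]

    @property
    def faz_radius_px(self) -> int:
        return int(round(self.faz_radius_frac * self.side_px))


@dataclass
class SyntheticEye:
    """One simulated eye: images, FAZ mask, covariate row, and truth."""

    eye_id: str
    group: str
    structural: EnFaceImage
    octa: EnFaceImage
    faz: FazMask
    record: dict
    truth: dict  # delta, obstructive_quadrant, vessel_mask — tests only


# ---------------------------------------------------------------------------
# vessel tree


def _walk(rng, start, heading, n_steps, side, turn_sd):
    headings = heading + np.cumsum(rng.normal(0.0, turn_sd, n_steps))
    ys = start[0] + np.cumsum(np.sin(headings))
    xs = start[1] + np.cumsum(np.cos(headings))
    yi = np.clip(np.rint(ys).astype(np.intp), 0, side - 1)
    xi = np.clip(np.rint(xs).astype(np.intp), 0, side - 1)
    return yi, xi


def generate_vessel_tree(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Connected branching curvilinear vessel mask at the target coverage.

    Centreline branches are correlated random walks; the first starts at a
    field edge heading inward, subsequent branches sprout from random
    existing centreline pixels (keeping the tree connected).  The mask is
    the centreline dilated to ``2 * vessel_halfwidth_px + 1`` px width.
    Branches are added until coverage reaches the target; if the target is
    not within ``coverage_rtol`` after ``max_branches`` attempts an error
    is raised.  A zero coverage target yields an empty mask.
    """
    side = config.side_px
    target = config.target_vessel_coverage
    if target <= 0:
        return np.zeros((side, side), dtype=bool)

    h = side // 2
    quarters = (
        (slice(0, h), slice(0, h)),
        (slice(0, h), slice(h, side)),
        (slice(h, side), slice(0, h)),
        (slice(h, side), slice(h, side)),
    )

    def _dilate(p):
        return ndimage.binary_dilation(
            p, structure=_STRUCT_3X3, iterations=config.vessel_halfwidth_px
        )

    path = np.zeros((side, side), dtype=bool)
    coverage = 0.0
    width = 2 * config.vessel_halfwidth_px + 1
    for branch in range(config.max_branches):
        if branch == 0:
            edge = rng.integers(4)
            pos = float(rng.uniform(0.2 * side, 0.8 * side))
            start, heading = {
                0: ((0.0, pos), np.pi / 2),    # top edge, heading down
                1: ((side - 1.0, pos), -np.pi / 2),
                2: ((pos, 0.0), 0.0),
                3: ((pos, side - 1.0), np.pi),
            }[int(edge)]
            heading += rng.normal(0.0, 0.4)
        else:
            # sprout from (or head toward) the least-covered quadrant: the
            # downstream statistics are per quadrant, so the tree must not
            # leave any quadrant nearly avascular
            counts = [path[rs, cs].sum() for rs, cs in quarters]
            qi = int(np.argmin(counts))
            rs, cs = quarters[qi]
            sub = np.flatnonzero(path[rs, cs])
            if sub.size:
                rows = sub // h + (0 if qi < 2 else h)
                cols = sub % h + (0 if qi % 2 == 0 else h)
                seeds = rows * side + cols
                idx = seeds[rng.integers(seeds.size)]
                start = (float(idx // side), float(idx % side))
                heading = float(rng.uniform(0.0, 2.0 * np.pi))
            else:
                seeds = np.flatnonzero(path)
                idx = seeds[rng.integers(seeds.size)]
                start = (float(idx // side), float(idx % side))
                qc_y = h / 2 if qi < 2 else 1.5 * h
                qc_x = h / 2 if qi % 2 == 0 else 1.5 * h
                heading = float(
                    np.arctan2(qc_y - start[0], qc_x - start[1])
                    + rng.normal(0.0, 0.3)
                )
        n_steps = int(rng.uniform(0.35, 0.8) * side)
        if coverage > 0:
            # close to target: shorten branches to the remaining deficit so
            # a single long branch cannot overshoot the tolerance band
            deficit_steps = max(12, int((target - coverage) * path.size / width) + 12)
            n_steps = min(n_steps, deficit_steps)
        yi, xi = _walk(rng, start, heading, n_steps, side, config.turn_sd)
        path[yi, xi] = True

        # dilation is the expensive step; skip it while the centreline alone
        # cannot possibly reach the target yet (width factor < full stamp)
        if coverage == 0.0 and path.sum() * (width + 1.5) < target * path.size:
            continue
        mask = _dilate(path)
        coverage = mask.mean()
        if coverage >= target * 1.1:
            return mask  # balanced enough is better than overshooting
        if coverage >= target * 0.98:
            qcov = [mask[rs, cs].mean() for rs, cs in quarters]
            if min(qcov) >= 0.6 * coverage:
                return mask
    mask = _dilate(path)
    coverage = mask.mean()
    if abs(coverage - target) <= config.coverage_rtol * target:
        return mask
    raise ParameterError(
        f"vessel coverage target {target:.3f} unreachable: reached "
        f"{coverage:.3f} after {config.max_branches} branches"
    )


def make_faz_mask(config: SyntheticConfig) -> FazMask:
    """Central circular foveal avascular zone."""
    side = config.side_px
    yy, xx = np.ogrid[:side, :side]
    c = (side - 1) / 2.0
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= config.faz_radius_px**2
    return FazMask(disc, provenance="synthetic")


# ---------------------------------------------------------------------------
# rendering


def render_pair(
    vessel_mask: np.ndarray,
    config: SyntheticConfig,
    delta: float,
    obstructive_quadrant: Quadrant | None,
    rng: np.random.Generator,
    quality: float | None = None,
    eye_id: str | None = None,
) -> tuple[EnFaceImage, EnFaceImage, np.ndarray]:
    """Render one structural/OCTA image pair from a vessel mask.

    OCTA: Gaussian stromal background plus, on vessels, Rayleigh-speckled
    flow signal modulated by a smooth log-normal heterogeneity field (flow
    is stronger in some vessel segments than others, as in real
    angiograms); the bright patches of that field are what survive the
    mean + 2 SD threshold downstream as contiguous high-signal particles.
    Structural: Gaussian background, a moderate
    vessel contrast, and the planted elevation ``delta`` on the dilated
    perivascular band (vessel plus a ``rim_dilation_px`` halo, so the
    elevation overlaps the high-signal pixels) restricted to the
    obstructive quadrant.  Both images are clipped and quantized to 8 bits.

    Returns ``(structural, octa, rim_mask)``.
    """
    if delta < 0:
        raise ParameterError(f"delta must be >= 0, got {delta}")
    side = config.side_px
    shape = (side, side)

    octa = rng.normal(config.octa_background_mean, config.octa_background_sd, shape)
    noise = ndimage.gaussian_filter(
        rng.normal(size=shape), config.flow_field_rel_sigma * side
    )
    flow_field = np.exp(config.flow_field_log_sd * noise / noise.std())
    n_vessel = int(vessel_mask.sum())
    octa[vessel_mask] = config.octa_vessel_base + flow_field[
        vessel_mask
    ] * rng.rayleigh(config.octa_speckle_scale, n_vessel)
    if config.smooth_sigma > 0:
        octa = ndimage.gaussian_filter(octa, config.smooth_sigma)

    rim = ndimage.binary_dilation(
        vessel_mask, structure=_STRUCT_3X3, iterations=config.rim_dilation_px
    )
    structural = rng.normal(
        config.struct_background_mean, config.struct_background_sd, shape
    )
    structural[vessel_mask] += config.struct_vessel_contrast
    if delta > 0 and obstructive_quadrant is not None:
        qmask = quadrant_mask(side, obstructive_quadrant)
        structural[rim & qmask] += delta
    if config.smooth_sigma > 0:
        structural = ndimage.gaussian_filter(structural, config.smooth_sigma)

    def _quantize(a):
        return np.clip(np.rint(a), 0, 255).astype(np.uint8)

    struct_img = EnFaceImage(
        _quantize(structural), Modality.STRUCTURAL, config.extent_mm,
        quality=quality, eye_id=eye_id,
    )
    octa_img = EnFaceImage(
        _quantize(octa), Modality.ANGIOGRAPHY, config.extent_mm,
        quality=quality, eye_id=eye_id,
    )
    return struct_img, octa_img, rim


# ---------------------------------------------------------------------------
# cohort


def _draw_covariates(
    group: str, cov: GroupCovariates, delta: float, delta_mean: float,
    config: SyntheticConfig, rng: np.random.Generator,
) -> dict:
    rec = {
        "age": float(rng.normal(*cov.age)),
        "sex": "F" if rng.random() < cov.p_female else "M",
        "laterality": "OD" if rng.random() < 0.5 else "OS",
        "hypertension": int(rng.random() < cov.p_hypertension),
        "diabetes": int(rng.random() < cov.p_diabetes),
        "iop_mmhg": float(rng.normal(*cov.iop)),
        "refractive_error_se": float(
            np.clip(
                rng.normal(*cov.refraction_se)
                + config.se_delta_slope * (delta - delta_mean),
                -6.0, 6.0,
            )
        ),
        "bcva_logmar": float(max(0.0, rng.normal(*cov.bcva_logmar))),
    }
    if group == "control":
        rec.update(
            injections_per_year=np.nan, duration_months=np.nan,
            sfct_um=np.nan, cmt_um=np.nan,
        )
    else:
        inj = (
            config.inj_intercept
            + config.inj_slope * delta
            + rng.normal(0.0, config.inj_noise_sd)
        )
        rec.update(
            injections_per_year=float(max(0.0, inj)),
            duration_months=float(max(1.0, rng.normal(*cov.duration_months))),
            sfct_um=float(rng.normal(*cov.sfct_um)),
            cmt_um=float(rng.normal(*cov.cmt_um)),
        )
    return rec


def generate_cohort(config: SyntheticConfig) -> tuple[list[SyntheticEye], pd.DataFrame]:
    """Simulate a three-group cohort of eyes plus its tidy covariate table.

    Per eye: vessel tree, rendered image pair, FAZ mask, planted elevation
    ``delta`` drawn from the group's normal model (truncated at 0; exactly
    0 for controls), and covariates.  Obstructive quadrants are drawn
    uniformly for disease eyes; controls get a matched analysis quadrant
    but no obstruction (``delta = 0``).  The same (seed, config) pair
    reproduces the cohort byte-identically.
    """
    if any(n < 1 for n in config.n_per_group):
        raise ParameterError("each group needs n >= 1")
    root = np.random.SeedSequence(config.seed)
    eye_seeds = root.spawn(sum(config.n_per_group))
    faz = make_faz_mask(config)

    eyes: list[SyntheticEye] = []
    rows: list[dict] = []
    i = 0
    for group, n in zip(GROUPS, config.n_per_group):
        cov = config.covariates[group]
        dmean = config.group_delta_mean(group)
        for _ in range(n):
            rng = np.random.default_rng(eye_seeds[i])
            eye_id = f"{group[:3]}{i:03d}"
            delta = (
                0.0 if group == "control"
                else float(max(0.0, rng.normal(dmean, config.delta_sd)))
            )
            quadrant = Quadrant(f"Q{1 + rng.integers(4)}")
            quality = float(rng.normal(config.quality_mean, config.quality_sd))

            vessels = generate_vessel_tree(config, rng)
            vessels &= ~faz.mask  # fovea is avascular
            structural, octa, _ = render_pair(
                vessels, config, delta,
                quadrant if group != "control" else quadrant,
                rng, quality=quality, eye_id=eye_id,
            )
            record = {
                "eye_id": eye_id,
                "group": group,
                "quadrant": quadrant.value,
                "quality": quality,
                **_draw_covariates(group, cov, delta, dmean, config, rng),
            }
            truth = {
                "delta": delta,
                "obstructive_quadrant": None if group == "control" else quadrant,
                "vessel_mask": vessels,
            }
            eyes.append(
                SyntheticEye(eye_id, group, structural, octa, faz, record, truth)
            )
            rows.append(record)
            i += 1
    return eyes, pd.DataFrame(rows)


def config_to_dict(config: SyntheticConfig) -> dict:
    """JSON-serializable dump of a config (for provenance embedding)."""
    d = dataclasses.asdict(config)
    d["covariates"] = {
        g: dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
        for g, c in config.covariates.items()
    }
    return d


# ---------------------------------------------------------------------------
# record-level generator (statistics testbed, no images)


def generate_records(
    n: int,
    seed: int,
    beta_injections: float = 0.3,
    beta_injections_late: float | None = None,
    n_null_predictors: int = 0,
    reflectivity_mean: float = 1.25,
    reflectivity_sd: float = 0.10,
    duration_range: tuple[float, float] = (6.0, 72.0),
) -> pd.DataFrame:
    """Covariate rows with an exact planted standardized association.

    Bypasses image rendering: the corrected reflectivity is drawn directly
    and the injection rate is constructed so that its population-level
    standardized regression coefficient (equivalently Pearson correlation)
    on reflectivity equals ``beta_injections``.  If
    ``beta_injections_late`` is given, the link strength differs between
    eyes below and at-or-above 36 months of disease duration (the
    duration sub-analysis testbed).  ``n_null_predictors`` adds
    independent noise columns ``null_1 .. null_k`` for type-I-error
    checks.  Variables live on plausible clinical scales but are not
    clipped, so planted coefficients are exact.
    """
    if not -1.0 <= beta_injections <= 1.0:
        raise ParameterError("beta_injections must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    duration = rng.uniform(*duration_range, size=n)

    def _linked(beta, rows):
        eps = rng.normal(size=rows.sum())
        return beta * z[rows] + np.sqrt(1.0 - beta**2) * eps

    inj_z = np.empty(n)
    if beta_injections_late is None:
        inj_z[:] = _linked(beta_injections, np.ones(n, dtype=bool))
    else:
        early = duration < 36.0
        inj_z[early] = _linked(beta_injections, early)
        inj_z[~early] = _linked(beta_injections_late, ~early)

    df = pd.DataFrame(
        {
            "eye_id": [f"rec{i:05d}" for i in range(n)],
            "corrected_reflectivity": reflectivity_mean + reflectivity_sd * z,
            "injections_per_year": 2.0 + 0.8 * inj_z,
            "duration_months": duration,
        }
    )
    for j in range(n_null_predictors):
        df[f"null_{j + 1}"] = rng.normal(size=n)
    return df
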