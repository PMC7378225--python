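"""Synthetic aneurysm-sac phantom cohort generator.

Real post-EVAR follow-up CTs cannot be redistributed, so the pipeline is
exercised on phantoms that carry the statistical structure the analysis
assumes: a bright stent lumen inside a thrombus-filled sac annulus, where
expansion-prone sacs contain spatially heterogeneous contrast pockets
(mimicking uneven contrast distribution under endoleak pressure) and stable
sacs are homogeneous.  Volumes, volume changes, endoleak frequencies and
clinical covariates are drawn from the distributions of the study cohort the
pipeline was designed for: first-interval volume 156.9 +/- 133.6 cc,
relative change 9.8% +/- 9.9% for expanders and -8.7% +/- 10.7% for
non-expanders, and covariates matched to the cohort's printed means/SDs.

Clinical covariates are drawn independently of the group, so any clinical
model fitted on phantoms has an expected AUC of 0.5; image heterogeneity is
the only group-linked channel, and its strength is governed by
``pocket_amplitude``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomParams",
    "CohortParams",
    "render_sac_image",
    "generate_cohort",
    "MANIFEST_COLUMNS",
]

IMAGE_MAX = 65535  # 16-bit raster range


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity model of a single sac phantom.

    Intensities are HU-like arbitrary units on a 16-bit scale.  With
    ``n_pockets = 0`` or ``pocket_amplitude = 0`` the sac is statistically
    homogeneous (stationary correlated noise around ``thrombus_mean``).
    """

    image_size: int = 96
    lumen_radius_frac: float = 0.35
    sac_radius_px: float = 38.0
    thrombus_mean: float = 1000.0
    thrombus_sd: float = 80.0
    n_pockets: int = 4
    pocket_amplitude: float = 500.0
    pocket_sigma_px: float = 5.0
    smoothing_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lumen_radius_frac < 1.0):
            raise ValueError(
                f"lumen_radius_frac must be in (0, 1), got {self.lumen_radius_frac}"
            )
        if not (0 < self.sac_radius_px < self.image_size / 2):
            raise ValueError(
                f"sac_radius_px must be in (0, image_size/2), got {self.sac_radius_px}"
            )
        if self.n_pockets < 0:
            raise ValueError(f"n_pockets must be >= 0, got {self.n_pockets}")


# per-group endoleak probabilities (type I, type II); remainder is "none".
# Defaults reproduce the study cohort's tallies: 6 and 6 of 38 expanders,
# 1 and 6 of 61 non-expanders.
_DEFAULT_ENDOLEAK = {
    "expander": (6 / 38, 6 / 38),
    "non_expander": (1 / 61, 6 / 61),
}


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level distributions for volumes, labels and covariates."""

    n_total: int = 99
    n_expanders: int = 38
    v1_mean: float = 156.9
    v1_sd: float = 133.6
    delta_exp_mean: float = 0.098
    delta_exp_sd: float = 0.099
    delta_non_mean: float = -0.087
    delta_non_sd: float = 0.107
    endoleak_rates: dict = field(default_factory=lambda: dict(_DEFAULT_ENDOLEAK))
    endoleak_mode: str = "exact"  # "exact" counts or "bernoulli" draws
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_expanders <= self.n_total):
            raise ValueError(
                f"need 0 <= n_expanders <= n_total, got {self.n_expanders}/{self.n_total}"
            )
        for sd in (self.v1_sd, self.delta_exp_sd, self.delta_non_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for group, (p1, p2) in self.endoleak_rates.items():
            if p1 < 0 or p2 < 0 or p1 + p2 > 1:
                raise ValueError(f"invalid endoleak rates for group {group!r}")
        if self.endoleak_mode not in ("exact", "bernoulli"):
            raise ValueError(f"unknown endoleak_mode {self.endoleak_mode!r}")


def render_sac_image(
    params: PhantomParams, expander: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom slice and its sac-annulus mask.

    Returns ``(image, mask)``: a uint16 grey image and a boolean mask that is
    True on the sac annulus (outside the lumen, inside the outer contour).
    If ``expander`` is true, ``n_pockets`` isotropic Gaussian contrast
    pockets are added at uniformly random in-mask centres.  Identical
    parameters (including the seed) give bit-identical output.
    """
    n = params.image_size
    rng = np.random.default_rng(params.seed)
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    lumen_r = params.lumen_radius_frac * params.sac_radius_px
    mask = (r <= params.sac_radius_px) & (r > lumen_r)
    if not mask.any():
        raise ValueError(
            "degenerate geometry: empty sac annulus "
            f"(sac_radius_px={params.sac_radius_px}, "
            f"lumen_radius_frac={params.lumen_radius_frac})"
        )

    image = np.full((n, n), 100.0)  # soft-tissue background
    image[r <= lumen_r] = 3.0 * params.thrombus_mean  # contrast-filled lumen
    image[mask] = params.thrombus_mean

    if params.thrombus_sd > 0:
        noise = rng.standard_normal((n, n))
        if params.smoothing_sigma_px > 0:
            noise = gaussian_filter(noise, params.smoothing_sigma_px)
            noise /= noise.std()  # restore unit variance after the blur
        image[mask] += params.thrombus_sd * noise[mask]

    if expander and params.n_pockets > 0:
        flat = np.flatnonzero(mask)
        centres = rng.choice(flat, size=params.n_pockets, replace=False)
        for idx in centres:
            cy, cx = np.unravel_index(idx, mask.shape)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            image[mask] += params.pocket_amplitude * np.exp(
                -d2[mask] / (2.0 * params.pocket_sigma_px**2)
            )

    image = np.clip(np.rint(image), 0, IMAGE_MAX).astype(np.uint16)
    return image, mask


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError(f"log-normal mean must be positive, got {mean}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _allocate_exact(n: int, probs: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items over categories."""
    raw = [p * n for p in probs]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # most-negative first
    for k in order[:rem]:
        counts[k] += 1
    return counts


def _draw_endoleaks(rng, n: int, rates: tuple[float, float], mode: str) -> np.ndarray:
    types = np.array(["type_I", "type_II", "none"])
    if mode == "bernoulli":
        p = np.array([rates[0], rates[1], 1.0 - rates[0] - rates[1]])
        return rng.choice(types, size=n, p=p)
    counts = _allocate_exact(n, (rates[0], rates[1], 1.0 - rates[0] - rates[1]))
    pool = np.repeat(types, counts)
    return rng.permutation(pool)


#: documented manifest header (clinical covariates follow the study cohort)
MANIFEST_COLUMNS = [
    "id", "group", "image_path", "mask_path", "V1", "V2", "endoleak",
    "max_diameter_mm", "age_yr", "sex_male", "hypertension",
    "hypertension_duration_yr", "systolic_mmHg", "diastolic_mmHg",
    "heart_disease", "diabetes", "smoking_history", "current_smoking",
    "smoking_duration_yr", "alcohol_history", "current_drinking",
    "total_cholesterol", "triglyceride", "hdl_c", "ldl_c",
]

# covariate distributions matched to the study cohort's overall summaries;
# all are drawn independently of the expansion group.
_COVARIATE_SPEC = {
    "max_diameter_mm": ("normal", 50.9, 14.8),
    "age_yr": ("normal", 68.5, 8.3),
    "sex_male": ("bernoulli", 87 / 99),
    "hypertension": ("bernoulli", 60 / 96),
    "hypertension_duration_yr": ("normal_nonneg", 9.7, 13.7),
    "systolic_mmHg": ("normal", 146.3, 26.4),
    "diastolic_mmHg": ("normal", 83.6, 16.1),
    "heart_disease": ("bernoulli", 33 / 99),
    "diabetes": ("bernoulli", 14 / 98),
    "smoking_history": ("bernoulli", 61 / 98),
    "current_smoking": ("bernoulli", 31 / 95),
    "smoking_duration_yr": ("normal_nonneg", 21.6, 20.4),
    "alcohol_history": ("bernoulli", 31 / 97),
    "current_drinking": ("bernoulli", 19 / 97),
    "total_cholesterol": ("normal", 4.2, 1.0),
    "triglyceride": ("normal_nonneg", 1.6, 0.9),
    "hdl_c": ("normal_nonneg", 1.0, 0.3),
    "ldl_c": ("normal_nonneg", 2.5, 1.0),
}


def _draw_covariates(rng, n: int) -> dict[str, np.ndarray]:
    out = {}
    for name, spec in _COVARIATE_SPEC.items():
        kind = spec[0]
        if kind == "bernoulli":
            out[name] = (rng.random(n) < spec[1]).astype(int)
        else:
            x = rng.normal(spec[1], spec[2], n)
            if kind == "normal_nonneg":
                x = np.clip(x, 0.0, None)
            out[name] = np.round(x, 3)
    return out


def generate_cohort(
    cparams: CohortParams,
    pparams: PhantomParams | None = None,
    out_dir: str | Path | None = None,
    write_images: bool = True,
) -> pd.DataFrame:
    """Generate a phantom cohort and (optionally) write it to disk.

    Each patient gets a group flag, V1 drawn log-normal (moment-matched to
    ``v1_mean``/``v1_sd``), V2 = V1 * (1 + delta) with delta drawn normal per
    group, an endoleak type per the group rates, clinical covariates drawn
    independently of group, and — when ``write_images`` — a rendered phantom
    image and sac mask (16-bit / 8-bit PNG).  The manifest is returned as a
    DataFrame with :data:`MANIFEST_COLUMNS` and, when ``out_dir`` is given,
    written to ``manifest.csv`` with a ``params.json`` sidecar.

    Expansion follows the sac texture by construction: expander-group
    patients receive pocketed images.  Downstream labels, however, come from
    the (V2-V1)/V1 > 2% rule, so with nonzero delta SDs a small fraction of
    patients carries a label that disagrees with its generating group.
    """
    if pparams is None:
        pparams = PhantomParams()
    if write_images and out_dir is None:
        raise ValueError("out_dir is required when write_images=True")
    rng = np.random.default_rng(cparams.seed)
    n, n_exp = cparams.n_total, cparams.n_expanders
    if n == 0:
        raise ValueError("n_total must be >= 1")

    group = np.array(["expander"] * n_exp + ["non_expander"] * (n - n_exp))
    mu, sigma = _lognormal_moments(cparams.v1_mean, cparams.v1_sd)
    v1 = rng.lognormal(mu, sigma, n)
    delta = np.where(
        group == "expander",
        rng.normal(cparams.delta_exp_mean, cparams.delta_exp_sd, n),
        rng.normal(cparams.delta_non_mean, cparams.delta_non_sd, n),
    )
    v2 = np.clip(v1 * (1.0 + delta), 0.0, None)

    endoleak = np.empty(n, dtype=object)
    for g in ("expander", "non_expander"):
        sel = group == g
        if sel.any():
            rates = tuple(cparams.endoleak_rates.get(g, (0.0, 0.0)))
            endoleak[sel] = _draw_endoleaks(
                rng, int(sel.sum()), rates, cparams.endoleak_mode
            )

    covars = _draw_covariates(rng, n)
    image_seeds = rng.integers(0, 2**31 - 1, size=n)

    ids = [f"P{k + 1:04d}" for k in range(n)]
    img_paths, msk_paths = [], []
    if write_images:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio

        for k, pid in enumerate(ids):
            pp = dataclasses.replace(pparams, seed=int(image_seeds[k]))
            image, mask = render_sac_image(pp, expander=(group[k] == "expander"))
            ip = f"images/{pid}.png"
            mp = f"masks/{pid}.png"
            iio.imwrite(out_dir / ip, image)
            iio.imwrite(out_dir / mp, (mask.astype(np.uint8)) * 255)
            img_paths.append(ip)
            msk_paths.append(mp)
    else:
        img_paths = [""] * n
        msk_paths = [""] * n

    manifest = pd.DataFrame(
        {
            "id": ids,
            "group": group,
            "image_path": img_paths,
            "mask_path": msk_paths,
            "V1": np.round(v1, 4),
            "V2": np.round(v2, 4),
            "endoleak": endoleak,
            **covars,
        }
    )[MANIFEST_COLUMNS]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        sidecar = {
            "cohort_params": {
                k: (v if not isinstance(v, dict) else {g: list(r) for g, r in v.items()})
                for k, v in dataclasses.asdict(cparams).items()
            },
            "phantom_params": dataclasses.asdict(pparams),
            "write_images": write_images,
        }
        (out_dir / "params.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
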