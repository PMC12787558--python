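"""Synthetic paired (image, sensor record, labels) urban-tree datasets.

The real study data — arborist health labels, synchronized sensor records
and background-suppressed tree photographs — is private, so this module
generates a documented stand-in with the same statistical skeleton:

* a 12-species mix with the four dominant species at 27/18/14/12 % and
  eight rare species at ~3.6 % each;
* a latent health score ``u`` in [0, 1], discretised by fixed thresholds
  into the four ordinal classes (0 = very poor ... 3 = good/healthy);
* a modality split: ``u = w_vis * a + (1 - w_vis) * b`` where the visual
  component ``a`` is expressed in the rendered image (canopy hue, leaf
  browning) and the sensor component ``b`` drives the environmental
  channels and biometrics.  Neither modality alone determines ``u``, so an
  observer fusing both demonstrably beats either alone;
* environmental channels with documented linear links to ``b`` (soil
  moisture rises with health, pollutant loads and AQI fall) plus Gaussian
  sensor noise;
* gas targets from an explicit stand-in physiological rule,
  ``O2 = a0 * canopy_width^2 * crown_density * (0.5 + 0.5 u) + eps`` and
  ``CO2 = 1.375 * O2 * (1 + delta)`` — the 1.375 factor is the 44/32
  CO2:O2 molar-mass ratio, giving the two targets stoichiometric coupling;
* a procedural renderer drawing each tree on a constant dark background
  (emulating background-removed photographs): a trunk rectangle with
  damage patches, and an elliptical canopy of coloured blobs whose hue
  tracks ``a`` and whose fill fraction tracks crown density.

Units of the gas targets are arbitrary "daily rate" units; no attempt is
made to reproduce the real physiological model, only its statistical role.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .sensors import (
    BIOMETRIC_COLUMNS,
    CONTINUOUS_SENSOR_COLUMNS,
    SPECIES,
    URBAN_ZONES,
)

__all__ = [
    "GeneratorConfig",
    "sample_population",
    "derive_targets",
    "render_tree",
    "generate_dataset",
    "load_dataset",
    "oracle_sensor_estimate",
    "oracle_image_estimate",
    "classify_latent",
]

#: default species proportions: four dominant species (27/18/14/12 %) and
#: eight rare species sharing the remaining 29 % equally.
DEFAULT_PROPORTIONS = (0.27, 0.18, 0.14, 0.12) + (0.29 / 8,) * 8

#: per-species size factor in [0, 1] (drives height / canopy width scale).
SPECIES_SIZE = (0.90, 0.55, 0.65, 0.45, 0.50, 0.80, 0.60, 0.70, 0.55, 0.35, 0.40, 0.75)

ZONE_PROBS = (0.35, 0.20, 0.30, 0.15)

#: environmental channel links: column -> (intercept, slope on b, noise sd).
#: Healthier trees (larger b) sit in moister soil and cleaner air.
ENV_LINKS = {
    "Soil_Moisture_%": (12.0, 28.0, 1.5),
    "Ambient_Temperature_C": (24.0, -4.0, 2.0),
    "Humidity_%": (35.0, 25.0, 2.5),
    "CO2_ppm": (480.0, -90.0, 10.0),
    "PM2.5_ug_m3": (45.0, -30.0, 3.0),
    "NO2_ppb": (38.0, -22.0, 3.0),
    "O3_ppb": (55.0, -25.0, 4.0),
}

#: AQI is computed from the pollutant channels (plus reporting noise).
AQI_WEIGHTS = {"PM2.5_ug_m3": 0.4, "NO2_ppb": 0.25, "O3_ppb": 0.2, "CO2_ppm": 0.05}
AQI_NOISE = 2.0

# canopy colour anchors (RGB): healthy green vs degraded brown
GREEN = np.array([50.0, 150.0, 60.0])
BROWN = np.array([120.0, 85.0, 30.0])
TRUNK_COLOR = np.array([101.0, 67.0, 33.0])
PATCH_COLOR = np.array([35.0, 22.0, 10.0])

# blob radius range relative to the canopy x-radius
BLOB_R = (0.10, 0.18)


@dataclass(frozen=True)
class GeneratorConfig:
    n_trees: int = 800
    seed: int = 7
    resolution: int = 96
    species_proportions: tuple = DEFAULT_PROPORTIONS
    class_prior: tuple = (0.15, 0.25, 0.30, 0.30)
    class_thresholds: tuple = (0.25, 0.50, 0.75)
    #: fraction of the health signal expressed visually (the rest in sensors)
    visual_fraction: float = 0.35
    #: multiplier on every sensor / biometric observation noise sd
    sensor_noise_scale: float = 1.0
    #: additive gas noise sd, original "daily rate" units
    gas_sigma: float = 0.6
    #: coefficient a0 in the O2 stand-in rule
    gas_coefficient: float = 0.25
    #: half-width of the bounded CO2:O2 ratio perturbation
    gas_ratio_jitter: float = 0.05
    #: multiplier on per-blob colour jitter in the renderer
    render_jitter: float = 1.0

    def __post_init__(self):
        if len(self.species_proportions) != len(SPECIES):
            raise ValueError(f"expected {len(SPECIES)} species proportions")
        if abs(sum(self.species_proportions) - 1.0) > 1e-9:
            raise ValueError("species proportions must sum to 1")
        if abs(sum(self.class_prior) - 1.0) > 1e-9:
            raise ValueError("class prior must sum to 1")
        if self.resolution not in (96, 224):
            raise ValueError("resolution must be 96 or 224")
        if min(self.sensor_noise_scale, self.gas_sigma, self.render_jitter) < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0.0 < self.visual_fraction < 1.0:
            raise ValueError("visual fraction must lie strictly in (0, 1)")


def classify_latent(u, cfg: GeneratorConfig) -> np.ndarray:
    """Discretise the latent health score by the configured thresholds."""
    return np.digitize(np.asarray(u), cfg.class_thresholds).astype(np.int64)


def _latent_bands(cfg):
    edges = (0.0, *cfg.class_thresholds, 1.0)
    return list(zip(edges[:-1], edges[1:]))


def sample_population(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw the latent records and observable sensor table for a population.

    Deterministic given the config seed.  Columns include the latent state
    (``u``, ``a``, ``b``, noise-free biometrics ``*_true``), the observed
    sensor-table values, the health class, and the gas targets.
    """
    if cfg.n_trees < len(cfg.class_prior):
        raise ValueError("need at least one tree per health class")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trees
    ns = cfg.sensor_noise_scale

    species_idx = rng.choice(len(SPECIES), size=n, p=cfg.species_proportions)
    zone_idx = rng.choice(len(URBAN_ZONES), size=n, p=ZONE_PROBS)
    size_k = np.asarray(SPECIES_SIZE)[species_idx]

    # latent health: class from the prior, u from a Beta within the class band
    cls = rng.choice(4, size=n, p=cfg.class_prior)
    bands = _latent_bands(cfg)
    lo = np.array([bands[c][0] for c in cls])
    hi = np.array([bands[c][1] for c in cls])
    u = lo + (hi - lo) * rng.beta(1.2, 1.2, size=n)

    # modality split: u = w_a * a + w_b * b with a, b in [0, 1]
    w_a = cfg.visual_fraction
    w_b = 1.0 - w_a
    a_lo = np.maximum(0.0, (u - w_b) / w_a)
    a_hi = np.minimum(1.0, u / w_a)
    a = a_lo + (a_hi - a_lo) * rng.uniform(size=n)
    b = (u - w_a * a) / w_b

    df = pd.DataFrame({
        "tree_id": [f"T{i:05d}" for i in range(n)],
        "species": [SPECIES[i] for i in species_idx],
        "species_idx": species_idx,
        "urban_zone": [URBAN_ZONES[i] for i in zone_idx],
        "u": u, "a": a, "b": b,
        "health_class": cls,
    })

    # noise-free biometric state (monotone links in the latent components)
    df["height_true"] = 3.0 + 7.0 * size_k + 2.0 * b + ns * rng.normal(0, 0.3, n)
    df["canopy_width_true"] = 2.0 + 3.5 * size_k + 2.0 * b + ns * rng.normal(0, 0.3, n)
    df["crown_density_true"] = np.clip(
        0.25 + 0.6 * b + ns * rng.normal(0, 0.05, n), 0.05, 0.98)
    df["bark_damage_true"] = np.clip(
        4.0 * (1.0 - b) + ns * rng.normal(0, 0.4, n), 0.0, None)
    df["leaf_color_dev_true"] = 5.0 * (1.0 - a)

    # observed biometrics (measurement noise on top of the latent state)
    df["height_m"] = df["height_true"] + ns * rng.normal(0, 0.15, n)
    df["canopy_width_m"] = df["canopy_width_true"] + ns * rng.normal(0, 0.15, n)
    df["crown_density"] = np.clip(
        df["crown_density_true"] + ns * rng.normal(0, 0.03, n), 0.0, 1.0)
    df["bark_damage_score"] = np.clip(
        df["bark_damage_true"] + ns * rng.normal(0, 0.35, n), 0.0, None)
    df["leaf_color_deviation"] = np.clip(
        df["leaf_color_dev_true"] + ns * rng.normal(0, 0.6, n), 0.0, 5.0)
    df["root_exposure_score"] = np.clip(
        3.0 * (1.0 - b) + ns * rng.normal(0, 0.5, n), 0.0, None)

    # environmental channels, linear in b
    for col, (icpt, slope, sd) in ENV_LINKS.items():
        df[col] = icpt + slope * b + ns * rng.normal(0, sd, n)
    df["Air_Quality_Index"] = sum(
        w * df[c] for c, w in AQI_WEIGHTS.items()
    ) - AQI_WEIGHTS["CO2_ppm"] * 400.0 + ns * rng.normal(0, AQI_NOISE, n)

    derive_targets(df, cfg, rng)
    return df


def derive_targets(df: pd.DataFrame, cfg: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach the stand-in gas targets to a population frame (in place).

    ``O2 = a0 * cw^2 * cd * (0.5 + 0.5 u) + eps`` with ``eps ~ N(0, sigma)``;
    ``CO2 = 1.375 * O2 * (1 + delta)`` with ``delta ~ U(-0.05, 0.05)``.
    Noise-free components are kept under ``o2_det`` / ``co2_det``.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = len(df)
    cw = df["canopy_width_true"].to_numpy()
    cd = df["crown_density_true"].to_numpy()
    u = df["u"].to_numpy()
    o2_det = cfg.gas_coefficient * cw ** 2 * cd * (0.5 + 0.5 * u)
    eps = rng.normal(0.0, cfg.gas_sigma, n) if cfg.gas_sigma > 0 else np.zeros(n)
    j = cfg.gas_ratio_jitter
    delta = rng.uniform(-j, j, n) if j > 0 else np.zeros(n)
    o2 = o2_det + eps
    co2 = 1.375 * o2 * (1.0 + delta)
    df["o2_det"] = o2_det
    df["co2_det"] = 1.375 * o2_det
    df["O2_rate"] = o2
    df["CO2_rate"] = co2
    return df


# ---------------------------------------------------------------------------
# renderer


def render_tree(tree, resolution: int, seed: int,
                render_jitter: float = 1.0) -> np.ndarray:
    """Procedurally draw one tree as an (H, W, 3) uint8 image.

    Constant dark background (the model consumes background-suppressed
    photographs); trunk rectangle with ``bark_damage_true`` dark patches;
    elliptical canopy of random blobs whose count tracks crown density and
    whose hue interpolates from healthy green to brown as the visual health
    component ``a`` falls.  Bit-identical for a fixed (tree, seed).
    """
    res = int(resolution)
    rng = np.random.default_rng(seed)
    img = np.zeros((res, res, 3), dtype=np.float64)
    yy, xx = np.mgrid[0:res, 0:res]
    ys, xs = yy / res, xx / res

    height = float(tree["height_true"])
    cw = float(tree["canopy_width_true"])
    cd = float(tree["crown_density_true"])
    bark = float(tree["bark_damage_true"])
    a = 1.0 - float(tree["leaf_color_dev_true"]) / 5.0

    # trunk
    trunk_w = 0.025 + 0.02 * np.clip((height - 3.0) / 9.0, 0.0, 1.0)
    trunk = (np.abs(xs - 0.5) < trunk_w / 2) & (ys > 0.45) & (ys < 0.97)
    img[trunk] = TRUNK_COLOR + rng.normal(0, 2.0, 3)

    # bark damage patches on the trunk
    for _ in range(int(round(bark))):
        py = rng.uniform(0.48, 0.93)
        ph = rng.uniform(0.02, 0.05)
        patch = trunk & (ys > py) & (ys < py + ph)
        img[patch] = PATCH_COLOR

    # canopy: ellipse of coloured blobs
    cx, cy = 0.5, 0.33
    rx = float(np.clip(0.12 + 0.04 * cw, 0.15, 0.46))
    ry = 0.8 * rx
    base = GREEN * a + BROWN * (1.0 - a)
    n_blobs = int(15 + 90 * cd)
    for _ in range(n_blobs):
        # uniform position inside the ellipse
        while True:
            ox, oy = rng.uniform(-1, 1), rng.uniform(-1, 1)
            if ox * ox + oy * oy <= 1.0:
                break
        bx, by = cx + ox * rx, cy + oy * ry
        r = rng.uniform(*BLOB_R) * rx
        colour = np.clip(base + rng.normal(0, 6.0 * render_jitter, 3), 0, 255)
        mask = (xs - bx) ** 2 + (ys - by) ** 2 <= r * r
        img[mask] = colour

    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset emission


TRUTH_COLUMNS = ["tree_id", "u", "a", "b", "health_class",
                 "height_true", "canopy_width_true", "crown_density_true",
                 "bark_damage_true", "leaf_color_dev_true", "o2_det", "co2_det"]

SENSOR_TABLE_COLUMNS = (["tree_id", "species", "urban_zone"]
                        + CONTINUOUS_SENSOR_COLUMNS + BIOMETRIC_COLUMNS
                        + ["health_class", "O2_rate", "CO2_rate"])


def _tree_render_seed(cfg_seed: int, index: int) -> int:
    h = hashlib.sha256(f"{cfg_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def generate_dataset(cfg: GeneratorConfig, outdir, overwrite: bool = False) -> Path:
    """Write a full dataset: images/, sensors.csv, truth.csv, manifest.csv
    and a generator.json echo of the configuration.

    Regenerating with the same config yields byte-identical files.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{outdir} exists and is not empty")
        shutil.rmtree(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)

    pop = sample_population(cfg)
    manifest = []
    for i, row in pop.iterrows():
        img = render_tree(row, cfg.resolution, _tree_render_seed(cfg.seed, i),
                          render_jitter=cfg.render_jitter)
        rel = f"images/{row['tree_id']}.png"
        Image.fromarray(img).save(outdir / rel)
        manifest.append({"tree_id": row["tree_id"], "image_path": rel})

    pop[SENSOR_TABLE_COLUMNS].to_csv(outdir / "sensors.csv", index=False)
    pop[TRUTH_COLUMNS].to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "generator.json", "w") as fh:
        json.dump({"config": asdict(cfg)}, fh, indent=1)
    return outdir


def load_dataset(path):
    """Read a generated dataset directory back into memory.

    Returns ``(sensors, truth, images)`` where ``images`` is a uint8 array
    (N, H, W, 3) ordered like the sensor table.
    """
    path = Path(path)
    sensors = pd.read_csv(path / "sensors.csv")
    truth = pd.read_csv(path / "truth.csv")
    manifest = pd.read_csv(path / "manifest.csv").set_index("tree_id")
    images = np.stack([
        np.asarray(Image.open(path / manifest.loc[tid, "image_path"]))
        for tid in sensors["tree_id"]
    ])
    return sensors, truth, images


# ---------------------------------------------------------------------------
# generative-rule oracles (no training involved)


def oracle_sensor_estimate(sensors: pd.DataFrame,
                           cfg: GeneratorConfig) -> np.ndarray:
    """Recover the latent health score from the sensor table alone.

    Inverts the documented linear channel links to a precision-weighted
    estimate of the sensor component ``b``, reads the visual component
    through the (coarse) leaf-colour-deviation score, and combines them
    with the modality-split weights.
    """
    est, weights = [], []
    for col, (icpt, slope, sd) in ENV_LINKS.items():
        b_hat = (sensors[col].to_numpy() - icpt) / slope
        info_sd = abs(sd / slope) * max(cfg.sensor_noise_scale, 1e-6)
        est.append(b_hat)
        weights.append(1.0 / info_sd ** 2)
    size_k = np.asarray(SPECIES_SIZE)[
        [SPECIES.index(s) for s in sensors["species"]]]
    ns = max(cfg.sensor_noise_scale, 1e-6)
    biometric_links = [
        # (observed column, b_hat expression, effective sd on b)
        ("canopy_width_m",
         (sensors["canopy_width_m"].to_numpy() - 2.0 - 3.5 * size_k) / 2.0,
         np.hypot(0.3, 0.15) / 2.0 * ns),
        ("crown_density",
         (sensors["crown_density"].to_numpy() - 0.25) / 0.6,
         np.hypot(0.05, 0.03) / 0.6 * ns),
        ("root_exposure_score",
         1.0 - sensors["root_exposure_score"].to_numpy() / 3.0,
         0.5 / 3.0 * ns),
    ]
    for _, b_hat, sd in biometric_links:
        est.append(b_hat)
        weights.append(1.0 / sd ** 2)
    weights = np.asarray(weights)
    b_est = np.clip(
        np.average(np.stack(est), axis=0, weights=weights), 0.0, 1.0)
    a_est = np.clip(1.0 - sensors["leaf_color_deviation"].to_numpy() / 5.0, 0.0, 1.0)
    w_a = cfg.visual_fraction
    return w_a * a_est + (1 - w_a) * b_est


def _canopy_pixels(img: np.ndarray):
    res = img.shape[0]
    ys = np.arange(res)[:, None] / res
    xs = np.arange(res)[None, :] / res
    fg = img.max(axis=2) > 12
    trunk_zone = (np.abs(xs - 0.5) < 0.05) & (ys > 0.45)
    return fg & ~np.broadcast_to(trunk_zone, fg.shape), ys, xs


def oracle_image_estimate(images: np.ndarray,
                          cfg: GeneratorConfig) -> np.ndarray:
    """Recover the latent health score from rendered images alone.

    Estimates the visual component from the mean canopy hue (projection on
    the green-to-brown axis) and the sensor component coarsely from the
    canopy fill fraction via a Poisson coverage model, then combines with
    the modality-split weights.
    """
    axis = GREEN - BROWN
    denom = float(axis @ axis)
    mean_r2 = (BLOB_R[0] ** 2 + BLOB_R[0] * BLOB_R[1] + BLOB_R[1] ** 2) / 3.0
    u_hat = np.empty(len(images))
    for i, img in enumerate(images):
        canopy, ys, xs = _canopy_pixels(img)
        if canopy.sum() == 0:
            u_hat[i] = 0.5
            continue
        mean_colour = img[canopy].mean(axis=0)
        a_est = float(np.clip((mean_colour - BROWN) @ axis / denom, 0.0, 1.0))
        # canopy extent -> ellipse area; coverage -> blob count -> density
        col_any = canopy.any(axis=0)
        rx = max((col_any * np.abs(xs[0] - 0.5)).max(), 0.15)
        ellipse_area = np.pi * rx * (0.8 * rx)
        coverage = min(canopy.sum() / img.shape[0] ** 2 / ellipse_area, 0.99)
        lam = -np.log1p(-coverage)
        n_blobs = lam * 0.8 / mean_r2  # lam = n * mean_r2 / 0.8
        cd_est = np.clip((n_blobs - 15.0) / 90.0, 0.0, 1.0)
        b_est = np.clip((cd_est - 0.25) / 0.6, 0.0, 1.0)
        w_a = cfg.visual_fraction
        u_hat[i] = w_a * a_est + (1 - w_a) * b_est
    return u_hat
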