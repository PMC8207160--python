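"""Synthetic data generators for the full analysis pipeline.

Three generators emulate the three data sources of the study design:

* replicated bilateral landmark configurations with explicit variance
  components (individual shape variation, directional asymmetry, fluctuating
  asymmetry, imaging error, digitizing error) and a nested replicate design
  (images per side, digitizings per image);
* microsatellite genotype tables under an inbreeding coefficient F, with
  P(A_i A_i) = p_i^2 + F p_i (1 - p_i) and P(A_i A_j) = 2 p_i p_j (1 - F);
* binary habitat rasters with spatial autocorrelation, obtained by
  thresholding Gaussian-smoothed white noise at the quantile that yields the
  requested habitat fraction.

``gen_study`` bundles all three into a coherent multi-site study with a
configurable rule linking habitat amount to the FA variance, mirroring a
design of eight forest-remnant sites with roughly 8-15 specimens each,
10 landmarks per hemimandible, 2 images per side, 3 digitizings per image,
and 7 microsatellite loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import HabitatRaster
from .popgen import GenotypeTable
from .tpsio import LandmarkConfiguration, LandmarkDataset, ReplicateDesign

__all__ = [
    "LandmarkModel",
    "GenotypeModel",
    "SiteScenario",
    "StudyScenario",
    "StudyBundle",
    "default_mandible_shape",
    "gen_landmark_dataset",
    "gen_genotypes",
    "gen_habitat_raster",
    "gen_study",
    "habitat_fa_scenario",
]

# stream tags keeping per-site substreams independent
_STREAM_LANDMARKS = 1
_STREAM_GENOTYPES = 2
_STREAM_RASTER = 3
_STREAM_SEX = 4


def default_mandible_shape(k: int = 10) -> np.ndarray:
    """A mandible-like 2-D outline of k landmarks, centered, unit centroid
    size.  For k != 10 the outline is resampled from the same closed curve."""
    base = np.array([
        [0.95, 0.10],   # anterior incisor alveolus, upper
        [0.60, 0.22],   # diastema
        [0.25, 0.30],   # molar root junction
        [-0.15, 0.45],  # coronoid base
        [-0.85, 0.30],  # articular process
        [-0.70, 0.00],  # angular notch
        [-0.95, -0.35], # angular process tip
        [-0.40, -0.42], # angular process base
        [0.45, -0.30],  # symphysis inner edge
        [0.90, -0.12],  # posterior incisor alveolus
    ])
    if k != 10:
        if k < 3:
            raise ValueError("need at least 3 landmarks")
        t = np.linspace(0, 2 * np.pi, k, endpoint=False)
        base = np.column_stack([np.cos(t) * (1 + 0.3 * np.sin(2 * t)),
                                0.6 * np.sin(t)])
    base = base - base.mean(axis=0)
    return base / np.sqrt((base**2).sum())


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class LandmarkModel:
    """Variance-component model for replicated bilateral landmark data.

    All SDs are per coordinate, in units of the (unit centroid size) mean
    shape; ``scale`` converts to nominal physical units.  ``da_vector`` is a
    fixed k x 2 side difference (directional asymmetry); the individual
    asymmetry a_i ~ N(da_vector, sigma_fa^2 I) enters the two sides as
    +a_i/2 and -a_i/2, so the signed left-minus-right difference has mean
    da_vector and per-coordinate variance sigma_fa^2.
    """

    mean_shape: np.ndarray = field(default_factory=default_mandible_shape)
    sigma_ind: float = 0.02
    da_vector: np.ndarray | None = None
    sigma_fa: float = 0.005
    sigma_image: float = 0.0005
    sigma_digit: float = 0.002
    n_individuals: int = 11
    n_images: int = 2
    n_digitizings: int = 3
    scale: float = 20.0
    rotation_jitter: float = 0.05   # radians, per-image placement nuisance
    translation_jitter: float = 0.05  # fraction of scale, per image
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        if self.mean_shape.ndim != 2 or self.mean_shape.shape[1] != 2:
            raise ValueError("mean_shape must be k x 2")
        k = self.mean_shape.shape[0]
        if k < 3:
            raise ValueError("mean_shape needs at least 3 landmarks")
        centered = self.mean_shape - self.mean_shape.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
            raise ValueError("mean_shape landmarks are collinear")
        for name in ("sigma_ind", "sigma_fa", "sigma_image", "sigma_digit",
                     "rotation_jitter", "translation_jitter"):
            _check_nonneg(name, getattr(self, name))
        if self.n_individuals < 1 or self.n_images < 1 or self.n_digitizings < 1:
            raise ValueError("counts must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.da_vector is None:
            self.da_vector = np.zeros_like(self.mean_shape)
        else:
            self.da_vector = np.asarray(self.da_vector, dtype=float)
            if self.da_vector.shape != self.mean_shape.shape:
                raise ValueError("da_vector must match mean_shape")

    @property
    def k(self) -> int:
        return self.mean_shape.shape[0]


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def gen_landmark_dataset(
    model: LandmarkModel,
    population: str = "pop1",
    specimen_prefix: str = "sp",
    rng: np.random.Generator | None = None,
) -> LandmarkDataset:
    """Draw a replicated bilateral landmark dataset from a variance model.

    Left side = mean + individual effect + a_i/2 (+ errors); right side is
    the mirror (x negated) of mean + individual effect - a_i/2 (+ errors).
    Imaging error and a small placement nuisance (rotation/translation,
    removed later by Procrustes alignment) apply per image; digitizing error
    applies per digitizing.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    k = model.k
    configs = []
    width = len(str(model.n_individuals))
    for i in range(model.n_individuals):
        spec_id = f"{specimen_prefix}{i + 1:0{width}d}"
        ind_effect = rng.normal(0.0, model.sigma_ind, size=(k, 2)) if model.sigma_ind > 0 \
            else np.zeros((k, 2))
        a_i = model.da_vector + (
            rng.normal(0.0, model.sigma_fa, size=(k, 2)) if model.sigma_fa > 0
            else np.zeros((k, 2))
        )
        for side, sgn in (("left", +1.0), ("right", -1.0)):
            true_side = model.mean_shape + ind_effect + sgn * a_i / 2.0
            if side == "right":
                true_side = true_side * np.array([-1.0, 1.0])  # mirror
            for img in range(1, model.n_images + 1):
                content = true_side + (
                    rng.normal(0.0, model.sigma_image, size=(k, 2))
                    if model.sigma_image > 0 else 0.0
                )
                theta = rng.normal(0.0, model.rotation_jitter) if model.rotation_jitter > 0 else 0.0
                shift = (rng.normal(0.0, model.translation_jitter, size=2)
                         if model.translation_jitter > 0 else np.zeros(2))
                placed = content @ _rot(theta).T + shift
                for dig in range(1, model.n_digitizings + 1):
                    coords = placed + (
                        rng.normal(0.0, model.sigma_digit, size=(k, 2))
                        if model.sigma_digit > 0 else 0.0
                    )
                    configs.append(
                        LandmarkConfiguration(
                            specimen_id=spec_id,
                            population=population,
                            side=side,
                            image_rep=img,
                            digit_rep=dig,
                            coords=coords * model.scale,
                        )
                    )
    return LandmarkDataset(
        configs,
        design=ReplicateDesign(model.n_images, model.n_digitizings),
    )


@dataclass
class GenotypeModel:
    """Per-locus allele frequencies plus an inbreeding coefficient F.

    Each frequency vector must sum to 1; F in [0, 1).  Under F, genotype
    probabilities are P(A_i A_i) = p_i^2 + F p_i (1 - p_i) and
    P(A_i A_j) = 2 p_i p_j (1 - F) for i != j, giving
    E[Ho] = (1 - F)(1 - sum p_i^2) per locus.
    """

    allele_freqs: list[np.ndarray]
    inbreeding_f: float = 0.0
    n_individuals: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = []
        for j, p in enumerate(self.allele_freqs):
            p = np.asarray(p, dtype=float)
            if np.any(p < 0):
                raise ValueError(f"locus {j}: negative allele frequency")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"locus {j}: frequencies sum to {p.sum()}, not 1")
            freqs.append(p)
        self.allele_freqs = freqs
        if not (0.0 <= self.inbreeding_f < 1.0):
            raise ValueError("inbreeding_f must be in [0, 1)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def gen_genotypes(
    model: GenotypeModel,
    population: str = "pop1",
    individual_prefix: str = "ind",
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Draw a genotype table under the inbreeding model.

    The second allele of a call copies the first with probability F
    (identity by descent) and is an independent draw otherwise; allele
    indices are mapped to microsatellite-like sizes 100, 102, 104, ...
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = model.n_individuals
    L = len(model.allele_freqs)
    alleles = np.zeros((n, L, 2), dtype=int)
    for j, p in enumerate(model.allele_freqs):
        first = rng.choice(len(p), size=n, p=p)
        ibd = rng.random(n) < model.inbreeding_f
        second = np.where(ibd, first, rng.choice(len(p), size=n, p=p))
        alleles[:, j, 0] = 100 + 2 * first
        alleles[:, j, 1] = 100 + 2 * second
    width = len(str(n))
    individuals = pd.DataFrame(
        {
            "individual_id": [f"{individual_prefix}{i + 1:0{width}d}" for i in range(n)],
            "population": population,
        }
    )
    return GenotypeTable(individuals, [f"locus_{j + 1}" for j in range(L)], alleles)


def gen_habitat_raster(
    proportion: float,
    shape: tuple[int, int] = (200, 200),
    smoothing: float = 5.0,
    seed: int = 0,
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> HabitatRaster:
    """Binary raster with the requested global habitat fraction.

    White noise is Gaussian-smoothed (length scale ``smoothing`` cells, which
    produces spatially autocorrelated patches resembling forest fragments)
    and thresholded at the empirical quantile, so the achieved fraction
    matches ``proportion`` to within one cell.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows, cols = shape
    if proportion == 1.0:
        grid = np.ones(shape, dtype=int)
    elif proportion == 0.0:
        grid = np.zeros(shape, dtype=int)
    else:
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=smoothing, mode="wrap")
        n_habitat = int(round(proportion * rows * cols))
        flat = smooth.ravel()
        if n_habitat == 0:
            grid = np.zeros(shape, dtype=int)
        else:
            threshold = np.partition(flat, len(flat) - n_habitat)[len(flat) - n_habitat]
            grid = (smooth >= threshold).astype(int)
    return HabitatRaster(grid, cell_size=cell_size, origin=origin)


# ---------------------------------------------------------------------------
# Whole-study scenarios


@dataclass
class SiteScenario:
    """Per-site parameters of a synthetic study."""

    site_id: str
    habitat_proportion: float
    n_specimens: int
    sigma_fa: float
    inbreeding_f: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.habitat_proportion <= 1.0):
            raise ValueError(f"{self.site_id}: habitat proportion outside [0, 1]")
        if self.n_specimens < 1:
            raise ValueError(f"{self.site_id}: n_specimens must be >= 1")
        _check_nonneg("sigma_fa", self.sigma_fa)


@dataclass
class StudyScenario:
    """A multi-site study: site list plus shared generator settings."""

    sites: list[SiteScenario]
    landmark_template: LandmarkModel = field(default_factory=LandmarkModel)
    n_loci: int = 7
    n_alleles: int = 5
    raster_shape: tuple[int, int] = (120, 120)
    raster_cell_size: float = 30.0
    raster_smoothing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("scenario needs at least one site")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")


@dataclass
class StudyBundle:
    """Coherent synthetic inputs for the whole pipeline."""

    landmarks: LandmarkDataset
    genotypes: GenotypeTable
    rasters: dict[str, HabitatRaster]
    sites: pd.DataFrame       # site_id, x_m, y_m, habitat_proportion, n
    specimens: pd.DataFrame   # specimen_id, population, sex
    scenario: StudyScenario


def habitat_fa_scenario(
    effect: float = 0.005,
    sigma_fa_base: float = 0.005,
    seed: int = 0,
    habitat_proportions: tuple[float, ...] = (
        0.1886, 0.2815, 0.3926, 0.6625, 0.7102, 0.7322, 0.9959, 1.0,
    ),
    sample_sizes: tuple[int, ...] = (8, 9, 11, 11, 15, 11, 13, 9),
) -> StudyScenario:
    """Eight-site scenario with the FA noise decreasing in habitat amount.

    sigma_fa(site) = sigma_fa_base + effect * (1 - habitat proportion): the
    fully forested site has the base developmental noise and the most
    deforested site roughly double.  ``effect=0`` yields the null scenario
    (no habitat-FA relationship).  Habitat proportions and sample sizes
    default to the observed range of the reference study system (~19-100%
    forest cover, 8-15 specimens per site).
    """
    sites = [
        SiteScenario(
            site_id=f"site{i + 1}",
            habitat_proportion=h,
            n_specimens=n,
            sigma_fa=sigma_fa_base + effect * (1.0 - h),
        )
        for i, (h, n) in enumerate(zip(habitat_proportions, sample_sizes))
    ]
    return StudyScenario(sites=sites, seed=seed)


def gen_study(scenario: StudyScenario) -> StudyBundle:
    """Generate landmark datasets, genotypes, rasters and site coordinates
    for all sites of a scenario.  Per-site substreams are derived from the
    scenario seed, so sites are independent and the whole bundle is
    reproducible from a single integer seed."""
    all_configs = []
    geno_frames = []
    rasters: dict[str, HabitatRaster] = {}
    site_rows = []
    spec_rows = []
    equifreq = np.full(scenario.n_alleles, 1.0 / scenario.n_alleles)

    for s_idx, site in enumerate(scenario.sites):
        lm = LandmarkModel(
            mean_shape=scenario.landmark_template.mean_shape,
            sigma_ind=scenario.landmark_template.sigma_ind,
            da_vector=scenario.landmark_template.da_vector,
            sigma_fa=site.sigma_fa,
            sigma_image=scenario.landmark_template.sigma_image,
            sigma_digit=scenario.landmark_template.sigma_digit,
            n_individuals=site.n_specimens,
            n_images=scenario.landmark_template.n_images,
            n_digitizings=scenario.landmark_template.n_digitizings,
            scale=scenario.landmark_template.scale,
            rotation_jitter=scenario.landmark_template.rotation_jitter,
            translation_jitter=scenario.landmark_template.translation_jitter,
        )
        lm_rng = np.random.default_rng([scenario.seed, s_idx, _STREAM_LANDMARKS])
        ds = gen_landmark_dataset(
            lm, population=site.site_id,
            specimen_prefix=f"{site.site_id}_sp", rng=lm_rng,
        )
        all_configs.extend(ds.configurations)

        gm = GenotypeModel(
            allele_freqs=[equifreq.copy() for _ in range(scenario.n_loci)],
            inbreeding_f=site.inbreeding_f,
            n_individuals=site.n_specimens,
        )
        g_rng = np.random.default_rng([scenario.seed, s_idx, _STREAM_GENOTYPES])
        geno = gen_genotypes(
            gm, population=site.site_id,
            individual_prefix=f"{site.site_id}_sp", rng=g_rng,
        )
        geno_frames.append(geno.to_frame())

        r_rng = np.random.default_rng([scenario.seed, s_idx, _STREAM_RASTER])
        raster = gen_habitat_raster(
            site.habitat_proportion,
            shape=scenario.raster_shape,
            smoothing=scenario.raster_smoothing,
            cell_size=scenario.raster_cell_size,
            rng=r_rng,
        )
        rasters[site.site_id] = raster
        cx, cy = raster.center()
        site_rows.append(
            {
                "site_id": site.site_id, "x_m": cx, "y_m": cy,
                "habitat_proportion": site.habitat_proportion,
                "n": site.n_specimens,
            }
        )

        sex_rng = np.random.default_rng([scenario.seed, s_idx, _STREAM_SEX])
        sexes = sex_rng.choice(["F", "M"], size=site.n_specimens)
        width = len(str(site.n_specimens))
        for i in range(site.n_specimens):
            spec_rows.append(
                {
                    "specimen_id": f"{site.site_id}_sp{i + 1:0{width}d}",
                    "population": site.site_id,
                    "sex": sexes[i],
                }
            )

    landmarks = LandmarkDataset(
        all_configs,
        design=ReplicateDesign(
            scenario.landmark_template.n_images,
            scenario.landmark_template.n_digitizings,
        ),
    )
    genotypes = GenotypeTable.from_frame(pd.concat(geno_frames, ignore_index=True))
    return StudyBundle(
        landmarks=landmarks,
        genotypes=genotypes,
        rasters=rasters,
        sites=pd.DataFrame(site_rows),
        specimens=pd.DataFrame(spec_rows),
        scenario=scenario,
    )
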