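"""Synthetic stand-ins for the private three-hospital ultrasound study.

The real study data are per-patient 2048-dimensional deep-feature vectors
extracted from B-mode breast ultrasound, with a binary axillary lymph node
metastasis (ALNM) label established by sentinel-node biopsy or dissection.
Those data are not public, so this module generates cohorts with the same
statistical skeleton the downstream pipeline assumes:

* class-conditional equal-covariance Gaussian informative features, whose
  Bayes-optimal AUC is available in closed form, ``Phi(delta / sqrt(2))``
  for a Mahalanobis class separation ``delta``;
* planted high-correlation redundant columns (linear-plus-noise copies of
  informative partners) that exercise the |Spearman rho| > 0.85 filter;
* pure nuisance noise columns;
* optional toy grayscale "lesion" images with bounding boxes, so the image
  preprocessing / feature-extraction stages can be driven end to end.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from ._utils import stage_seed

# Cohort structure of the study: one training hospital and two external
# validation hospitals, with the observed metastasis prevalences.
STUDY_SIZES = (621, 112, 87)
STUDY_PREVALENCES = (0.346, 0.402, 0.402)


@dataclass(frozen=True)
class CohortSpec:
    """Generative recipe for one synthetic patient cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    prevalence : float
        Probability a patient is metastasis-positive (label 1).
    n_features : int
        Total feature columns (default 2048, the deep-feature width).
    n_informative : int
        Columns carrying class signal.
    n_redundant : int
        Columns that are noisy monotone copies of informative partners.
    redundancy_rho : float
        Target absolute Spearman correlation of each redundant pair; must
        exceed 0.85 so the redundancy filter can remove the planted pairs.
    class_separation : float
        Mahalanobis distance between the class means in the informative
        subspace (equal identity covariance), so the Bayes AUC is
        ``Phi(class_separation / sqrt(2))``.
    seed : int
        RNG seed; identical specs produce bitwise-identical cohorts.
    id_prefix : str
        Prefix for patient identifiers (keeps cohorts disjoint).
    mean_shift : float
        Optional per-feature mean offset applied to the whole cohort,
        a knob for emulating external-cohort distribution shift. Default 0.
    """

    n_patients: int
    prevalence: float
    n_features: int = 2048
    n_informative: int = 22
    n_redundant: int = 0
    redundancy_rho: float = 0.95
    class_separation: float = 2.0
    seed: int = 0
    id_prefix: str = "P"
    mean_shift: float = 0.0

    def __post_init__(self) -> None:
        for name in ("prevalence", "redundancy_rho", "class_separation", "mean_shift"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.prevalence * self.n_patients < 1:
            raise ValueError("expected positive count below 1; enlarge cohort or prevalence")
        if self.n_informative < 1:
            raise ValueError("n_informative must be positive")
        if self.n_redundant < 0:
            raise ValueError("n_redundant must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant exceeds n_features")
        if not 0.85 < self.redundancy_rho <= 1.0:
            raise ValueError("redundancy_rho must lie in (0.85, 1] so planted pairs are removable")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")

    @property
    def bayes_auc(self) -> float:
        """Closed-form AUC of the Bayes rule for the equal-covariance model."""
        return float(norm.cdf(self.class_separation / np.sqrt(2.0)))


@dataclass
class CohortTruth:
    """Planted structure of a synthetic cohort (for oracle checks)."""

    informative: np.ndarray          # column indices carrying signal
    redundant: np.ndarray            # planted redundant column indices
    partners: dict[int, tuple[int, float]]  # redundant column -> (partner, coupling sign)
    bayes_auc: float
    direction: np.ndarray            # unit class-mean difference in informative subspace

    def __post_init__(self) -> None:
        if np.intersect1d(self.informative, self.redundant).size:
            raise ValueError("informative and redundant truth indices overlap")


@dataclass
class SyntheticCohort:
    """One generated cohort: ids, feature matrix, labels, planted truth."""

    ids: list[str]
    features: np.ndarray
    labels: np.ndarray
    truth: CohortTruth
    spec: CohortSpec | None = None

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids, features and labels must have matching length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("patient ids must be unique")
        d = self.features.shape[1]
        for idx in (self.truth.informative, self.truth.redundant):
            if idx.size and (idx.min() < 0 or idx.max() >= d):
                raise ValueError("truth indices out of range")

    @property
    def n_patients(self) -> int:
        return self.features.shape[0]

    def oracle_scores(self) -> np.ndarray:
        """Bayes-rule discriminant score (projection on the class-mean axis)."""
        return self.features[:, self.truth.informative] @ self.truth.direction

    def to_csv(self, path: str | Path) -> Path:
        """Write ``id, f0000..fNNNN, label`` CSV (the interchange format)."""
        path = Path(path)
        d = self.features.shape[1]
        width = max(4, len(str(d - 1)))
        header = ["id"] + [f"f{j:0{width}d}" for j in range(d)] + ["label"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for pid, row, lab in zip(self.ids, self.features, self.labels):
                w.writerow([pid] + [repr(float(v)) for v in row] + [int(lab)])
        return path


@dataclass
class ToyImage:
    """A synthetic grayscale lesion image with a tight bounding box.

    ``bbox`` is (x_min, y_min, x_max, y_max), 0-based, half-open.
    """

    pixels: np.ndarray
    bbox: tuple[int, int, int, int]
    label: int
    id: str = ""

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        x0, y0, x1, y1 = self.bbox
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"bbox {self.bbox} outside {w}x{h} image")
        if (x1 - x0) * (y1 - y0) < 4:
            raise ValueError("bbox area must be at least 4 pixels")


def _spearman_to_pearson(rho_s: float) -> float:
    # For bivariate Gaussians, rho_spearman = (6/pi) asin(rho_pearson / 2).
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_feature_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the class-conditional Gaussian model.

    Labels are Bernoulli(prevalence). Informative columns are N(+-delta/2 * u, I)
    per class with ||delta * u|| = class_separation. Each redundant column is a
    signed linear copy of an informative partner plus Gaussian noise calibrated
    so the pair's Spearman correlation is ``redundancy_rho`` in expectation.
    Remaining columns are standard normal noise. Column roles are shuffled
    into random positions.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_patients, spec.n_features
    k, r = spec.n_informative, spec.n_redundant

    labels = (rng.random(n) < spec.prevalence).astype(int)

    # informative block: equal spread over the k informative axes
    u = np.full(k, 1.0 / np.sqrt(k))
    offset = 0.5 * spec.class_separation * u
    informative = rng.standard_normal((n, k))
    informative += np.where(labels[:, None] == 1, offset, -offset)

    # redundant block: signed linear copy + calibrated noise
    partners_local = rng.integers(0, k, size=r) if r else np.empty(0, dtype=int)
    signs = rng.choice([-1.0, 1.0], size=r)
    rho_p = _spearman_to_pearson(spec.redundancy_rho)
    # partner columns have variance ~1 within class; corr = 1/sqrt(1+sigma^2)
    sigma = np.sqrt(max(1.0 / rho_p**2 - 1.0, 0.0))
    redundant = (
        informative[:, partners_local] * signs + sigma * rng.standard_normal((n, r))
        if r
        else np.empty((n, 0))
    )

    noise = rng.standard_normal((n, d - k - r))

    perm = rng.permutation(d)
    features = np.empty((n, d))
    informative_idx = perm[:k]
    redundant_idx = perm[k : k + r]
    noise_idx = perm[k + r :]
    features[:, informative_idx] = informative
    features[:, redundant_idx] = redundant
    features[:, noise_idx] = noise
    features += spec.mean_shift

    partners = {
        int(redundant_idx[j]): (int(informative_idx[partners_local[j]]), float(signs[j]))
        for j in range(r)
    }
    truth = CohortTruth(
        informative=np.sort(informative_idx),
        redundant=np.sort(redundant_idx),
        partners=partners,
        bayes_auc=spec.bayes_auc,
        direction=u,
    )
    # direction is in the *sorted* informative basis; u is symmetric so sorting
    # the index set leaves the discriminant unchanged.
    ids = [f"{spec.id_prefix}{i:05d}" for i in range(n)]
    return SyntheticCohort(ids=ids, features=features, labels=labels, truth=truth, spec=spec)


def make_study_cohorts(
    seed: int = 0,
    n_features: int = 2048,
    n_informative: int = 22,
    n_redundant: int = 61,
    class_separation: float = 2.0,
    redundancy_rho: float = 0.95,
) -> tuple[SyntheticCohort, SyntheticCohort, SyntheticCohort]:
    """The three-hospital study layout: 621/112/87 patients at prevalences
    0.346/0.402/0.402, all drawn from one shared generative model (same
    planted column roles) so selectors fitted on the training cohort transfer
    to the validation cohorts.

    Defaults: 61 planted redundant columns, so the redundancy filter removes
    roughly the 2048 -> 1987 count observed on the real features, and 22
    informative columns, matching the selected-feature count.
    """
    rng = np.random.default_rng(stage_seed(seed, "synthetic"))
    # narrow matrices (tests, demos): scale the planted structure down
    n_informative = min(n_informative, max(2, n_features // 3))
    n_redundant = min(n_redundant, n_features - n_informative - 1)
    # one column-role permutation and partner map shared by all three cohorts
    base = CohortSpec(
        n_patients=STUDY_SIZES[0],
        prevalence=STUDY_PREVALENCES[0],
        n_features=n_features,
        n_informative=n_informative,
        n_redundant=n_redundant,
        redundancy_rho=redundancy_rho,
        class_separation=class_separation,
        seed=int(rng.integers(2**31 - 1)),
        id_prefix="TR",
    )
    train = generate_feature_cohort(base)

    cohorts = [train]
    for prefix, size, prev in (
        ("V1", STUDY_SIZES[1], STUDY_PREVALENCES[1]),
        ("V2", STUDY_SIZES[2], STUDY_PREVALENCES[2]),
    ):
        sub = _redraw_with_truth(
            train, n_patients=size, prevalence=prev, seed=int(rng.integers(2**31 - 1)), id_prefix=prefix
        )
        cohorts.append(sub)
    return tuple(cohorts)


def _redraw_with_truth(
    template: SyntheticCohort, n_patients: int, prevalence: float, seed: int, id_prefix: str
) -> SyntheticCohort:
    """Draw a new cohort reusing the template's planted column structure."""
    spec = template.spec
    assert spec is not None
    rng = np.random.default_rng(seed)
    n = n_patients
    k = spec.n_informative

    labels = (rng.random(n) < prevalence).astype(int)
    u = template.truth.direction
    offset = 0.5 * spec.class_separation * u

    features = rng.standard_normal((n, spec.n_features))
    inf_idx = template.truth.informative
    features[:, inf_idx] += np.where(labels[:, None] == 1, offset, -offset)

    rho_p = _spearman_to_pearson(spec.redundancy_rho)
    sigma = np.sqrt(max(1.0 / rho_p**2 - 1.0, 0.0))
    # redundant columns reuse the training cohort's partner map and coupling
    # signs, so cross-cohort feature geometry is consistent
    for red_col, (partner, sign) in template.truth.partners.items():
        features[:, red_col] = features[:, partner] * sign + sigma * rng.standard_normal(n)

    truth = CohortTruth(
        informative=template.truth.informative.copy(),
        redundant=template.truth.redundant.copy(),
        partners=dict(template.truth.partners),
        bayes_auc=spec.bayes_auc,
        direction=u.copy(),
    )
    ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    new_spec = CohortSpec(
        n_patients=n,
        prevalence=prevalence,
        n_features=spec.n_features,
        n_informative=spec.n_informative,
        n_redundant=spec.n_redundant,
        redundancy_rho=spec.redundancy_rho,
        class_separation=spec.class_separation,
        seed=seed,
        id_prefix=id_prefix,
    )
    return SyntheticCohort(ids=ids, features=features, labels=labels, truth=truth, spec=new_spec)


def generate_toy_images(
    n: int,
    prevalence: float = 0.4,
    seed: int = 0,
    size: int = 96,
) -> list[ToyImage]:
    """Speckled grayscale images, one elliptical lesion each.

    Positive-label lesions are larger and have irregular margins, so a shape-
    or texture-sensitive extractor has real signal to find. Bounding boxes are
    tight around the lesion support, 0-based and half-open.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    images: list[ToyImage] = []
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        label = int(rng.random() < prevalence)
        # speckle: Rayleigh-like background typical of B-mode texture
        background = rng.rayleigh(scale=0.18, size=(size, size))
        cx = rng.uniform(0.3 * size, 0.7 * size)
        cy = rng.uniform(0.3 * size, 0.7 * size)
        base_r = rng.uniform(0.10, 0.16) * size
        if label:
            base_r *= rng.uniform(1.35, 1.7)
        ax = base_r * rng.uniform(0.8, 1.2)
        ay = base_r * rng.uniform(0.8, 1.2)
        theta = np.arctan2(yy - cy, xx - cx)
        wobble = (
            1.0 + 0.25 * np.sin(rng.integers(3, 7) * theta + rng.uniform(0, 2 * np.pi))
            if label
            else 1.0 + 0.05 * np.sin(3 * theta)
        )
        mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= wobble
        img = background.copy()
        img[mask] *= 0.25  # hypoechoic (dark) lesion
        img = np.clip(img, 0.0, 1.0)

        ys, xs = np.nonzero(mask)
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        images.append(ToyImage(pixels=img, bbox=(x0, y0, x1, y1), label=label, id=f"IMG{i:05d}"))
    return images


def write_toy_images(images: list[ToyImage], out_dir: str | Path) -> Path:
    """Write PNGs plus a bbox CSV (id, x_min, y_min, x_max, y_max, label)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        arr = np.clip(im.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / f"{im.id}.png")
        rows.append([im.id, *im.bbox, im.label])
    csv_path = out_dir / "bboxes.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x_min", "y_min", "x_max", "y_max", "label"])
        w.writerows(rows)
    return csv_path
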