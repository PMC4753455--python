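"""BioVision: supervised Gaussian-mixture segmentation of IHC stainings.

Each pixel of a stained section is described by a 4-D feature vector:
its R, G, B intensities plus a *local intensity* — the mean luminance
over the pixel and its 4-connected in-plane neighbors, which makes the
classifier robust to pixel-level noise in neuropathology images. From
expert-annotated patches, the joint feature distribution of each class
(positively stained tissue, non-stained tissue, background) is modeled
with a multivariate Gaussian mixture fitted by EM; new pixels are then
assigned by Bayes rule (maximum prior x class-conditional density).
Segmentation quality is summarized by precision, recall and F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

__all__ = [
    "CLASS_ORDER",
    "LABEL_CODES",
    "GroundTruthPatchSet",
    "BioVisionModel",
    "SegmentationMetrics",
    "extract_features",
    "fit_model",
    "classify",
    "classify_volume",
    "evaluate_f1",
    "TrainingError",
]

# Tie-breaking order for Bayes-rule assignment: first class wins.
CLASS_ORDER = ("stained", "unstained", "background")
LABEL_CODES = {"unlabeled": 0, "stained": 1, "unstained": 2, "background": 3}


class TrainingError(ValueError):
    """A class has too few labeled pixels to fit its mixture."""


def extract_features(image: np.ndarray, include_center: bool = True) -> np.ndarray:
    """Per-pixel 4-D features (R, G, B, local intensity) of an RGB section.

    Local intensity is the mean of the per-pixel luminance (mean of R, G,
    B) over the 4-connected in-plane neighborhood; with
    ``include_center`` (the default) the pixel itself is part of the
    average (a 5-pixel cross). Borders are handled by edge replication.

    Returns an ``(h, w, 4)`` float array.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("extract_features expects an RGB image (h, w, 3)")
    img = image.astype(float)
    lum = img.mean(axis=-1)
    if include_center:
        kernel = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=float) / 5.0
    else:
        kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float) / 4.0
    local = ndimage.correlate(lum, kernel, mode="nearest")
    return np.concatenate([img, local[..., None]], axis=-1)


@dataclass
class GroundTruthPatchSet:
    """Expert-annotated (RGB image, label image) patch pairs.

    Label codes: 0 = unlabeled, 1 = stained, 2 = unstained,
    3 = background.
    """

    patches: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        for img, lab in self.patches:
            lab = np.asarray(lab)
            if lab.max(initial=0) > 3 or lab.min(initial=0) < 0:
                raise ValueError("label codes must be within 0..3")
            if not (lab > 0).any():
                raise ValueError("every patch must contain at least one labeled pixel")

    def features_by_class(self, include_center: bool = True) -> dict[str, np.ndarray]:
        feats: dict[str, list[np.ndarray]] = {c: [] for c in CLASS_ORDER}
        for img, lab in self.patches:
            f = extract_features(img, include_center)
            lab = np.asarray(lab)
            for cls in CLASS_ORDER:
                sel = lab == LABEL_CODES[cls]
                if sel.any():
                    feats[cls].append(f[sel])
        return {c: (np.concatenate(v) if v else np.empty((0, 4))) for c, v in feats.items()}


@dataclass
class BioVisionModel:
    """Per-class Gaussian mixture over the 4-D feature space + class priors."""

    classes: tuple[str, ...]
    weights: dict[str, np.ndarray]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    n_components: dict[str, int]
    seed: int = 0
    include_center: bool = True
    reg_covar: float = 1e-3

    def __post_init__(self):
        for c in self.classes:
            w = np.asarray(self.weights[c], dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
                raise ValueError(f"mixture weights of class {c!r} must be >= 0 and sum to 1")
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class priors must sum to 1")

    def log_density(self, feats: np.ndarray, cls: str) -> np.ndarray:
        """Log mixture density of ``cls`` at feature rows (n, 4)."""
        w = np.asarray(self.weights[cls])
        mu = np.asarray(self.means[cls])
        cov = np.asarray(self.covariances[cls])
        n, d = feats.shape
        comp = np.empty((n, len(w)))
        for k in range(len(w)):
            diff = feats - mu[k]
            chol = np.linalg.cholesky(cov[k])
            sol = np.linalg.solve(chol, diff.T)
            maha = (sol ** 2).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            comp[:, k] = -0.5 * (maha + logdet + d * np.log(2 * np.pi)) + np.log(max(w[k], 1e-300))
        m = comp.max(axis=1)
        return m + np.log(np.exp(comp - m[:, None]).sum(axis=1))

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "weights": {c: np.asarray(self.weights[c]).tolist() for c in self.classes},
            "means": {c: np.asarray(self.means[c]).tolist() for c in self.classes},
            "covariances": {c: np.asarray(self.covariances[c]).tolist() for c in self.classes},
            "priors": dict(self.priors),
            "n_components": dict(self.n_components),
            "seed": self.seed,
            "include_center": self.include_center,
            "reg_covar": self.reg_covar,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BioVisionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(d["classes"]),
            weights={c: np.array(v) for c, v in d["weights"].items()},
            means={c: np.array(v) for c, v in d["means"].items()},
            covariances={c: np.array(v) for c, v in d["covariances"].items()},
            priors=d["priors"],
            n_components=d["n_components"],
            seed=d.get("seed", 0),
            include_center=d.get("include_center", True),
            reg_covar=d.get("reg_covar", 1e-3),
        )


def fit_model(truth: GroundTruthPatchSet, n_components: int | dict[str, int] = 3,
              seed: int = 0, priors: str = "proportional",
              include_center: bool = True, reg_covar: float = 1e-3,
              return_loglik: bool = False):
    """Fit one Gaussian mixture per class on the labeled pixel features.

    EM is initialized with k-means under a fixed seed so the fit is
    deterministic. Class priors default to the labeled-pixel class
    proportions (``priors="uniform"`` for equal priors).

    Raises
    ------
    TrainingError
        If a class has fewer than ``10 * n_components`` labeled pixels.
    """
    if isinstance(n_components, int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        n_components = {c: n_components for c in CLASS_ORDER}
    if any(n < 1 for n in n_components.values()):
        raise ValueError("n_components must be >= 1 for every class")
    feats = truth.features_by_class(include_center)
    counts = {c: len(feats[c]) for c in CLASS_ORDER}
    weights, means, covs = {}, {}, {}
    logliks: dict[str, list[float]] = {}
    for cls in CLASS_ORDER:
        k = n_components[cls]
        if counts[cls] < 10 * k:
            raise TrainingError(
                f"class {cls!r} has {counts[cls]} labeled pixels; "
                f"needs >= {10 * k} for {k} components")
        x = feats[cls]
        # run EM one step at a time so the log-likelihood trace is exposed
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=reg_covar, random_state=seed,
                             init_params="kmeans", max_iter=1, warm_start=True,
                             tol=0.0)
        trace = []
        prev = -np.inf
        import warnings
        for _ in range(200):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            ll = float(gm.score(x))
            trace.append(ll)
            if ll - prev < 1e-7 and len(trace) > 1:
                break
            prev = ll
        logliks[cls] = trace
        weights[cls] = gm.weights_.copy()
        means[cls] = gm.means_.copy()
        covs[cls] = gm.covariances_.copy()
    n_total = sum(counts.values())
    if priors == "uniform":
        pri = {c: 1.0 / len(CLASS_ORDER) for c in CLASS_ORDER}
    else:
        pri = {c: counts[c] / n_total for c in CLASS_ORDER}
    model = BioVisionModel(CLASS_ORDER, weights, means, covs, pri,
                           n_components, seed, include_center, reg_covar)
    if return_loglik:
        return model, logliks
    return model


def classify(image: np.ndarray, model: BioVisionModel) -> np.ndarray:
    """Bayes-rule pixel classification of an RGB section.

    Each pixel is assigned the class maximizing prior x mixture density
    at its feature vector; exact ties go to the first class in the
    declared order (stained < unstained < background). Returns a label
    image with the ground-truth codes (1 = stained, 2 = unstained,
    3 = background).
    """
    feats = extract_features(image, model.include_center).reshape(-1, 4)
    log_post = np.empty((feats.shape[0], len(model.classes)))
    for j, cls in enumerate(model.classes):
        log_post[:, j] = model.log_density(feats, cls) + np.log(max(model.priors[cls], 1e-300))
    if not np.isfinite(log_post).all():
        raise FloatingPointError("non-finite class density (degenerate covariance?)")
    winner = np.argmax(log_post, axis=1)  # argmax takes the first maximum: tie rule
    codes = np.array([LABEL_CODES[c] for c in model.classes])
    return codes[winner].reshape(image.shape[:2]).astype(np.uint8)


def classify_volume(vol, model: BioVisionModel):
    """Classify a reconstructed RGB histology volume section by section.

    Features are in-plane, so classification runs per coronal plane and
    the per-plane stained masks are stacked; invalid planes stay empty.
    Returns a mask Volume (1 = stained).
    """
    from .volumes import Volume
    if vol.data.ndim != 4:
        raise ValueError("classify_volume expects an RGB histology volume")
    out = np.zeros(vol.shape, dtype=np.uint8)
    for k in range(vol.shape[2]):
        if not vol.valid_planes[k]:
            continue
        labels = classify(vol.data[:, :, k, :], model)
        out[:, :, k] = (labels == LABEL_CODES["stained"]).astype(np.uint8)
    return Volume(out, vol.voxel_size, modality="mask",
                  valid_planes=vol.valid_planes.copy())


@dataclass
class SegmentationMetrics:
    """Voxelwise precision, recall and their harmonic mean (F1)."""

    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    fn: int = 0


def evaluate_f1(pred_mask: np.ndarray, truth_mask: np.ndarray) -> SegmentationMetrics:
    """Voxelwise P, R and F1 = 2PR/(P+R) of a binary segmentation.

    Conventions: P = 1 when nothing is predicted positive, R = 1 when the
    truth has no positives, and F1 = 0 when P + R = 0.
    """
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must have the same shape")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    p = tp / (tp + fp) if tp + fp else 1.0
    r = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return SegmentationMetrics(p, r, f1, tp, fp, fn)
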