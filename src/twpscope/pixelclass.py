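"""Trainable pixel classification: TWP-candidate vs background.

Re-creates an interactive trainable-segmentation workflow in library form:
sparse pixel labels train a random forest on colour + multiscale texture
features, the forest predicts a per-pixel TWP probability, and an IsoData
automatic threshold binarizes it. A rule-based darkness classifier (all
channels at or below a cap) is provided as a fast, deterministic
alternative for headless runs; the forest is the default path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata
from sklearn.ensemble import RandomForestClassifier

from .preprocess import FilterImage
from .scene import DARKNESS_CAP

__all__ = [
    "LabelSet",
    "ForestModel",
    "RuleModel",
    "ClassMap",
    "extract_features",
    "train_classifier",
    "classify",
    "binarize",
    "labels_from_truth",
]

DEFAULT_SCALES = (1.0, 2.0, 4.0)


@dataclass
class LabelSet:
    """Sparse pixel annotations: (row, col) coordinates with a class each.

    Class 1 marks black TWP-candidate pixels, class 0 background (including
    coloured particles). The same pixel may not carry both classes.
    """

    coords: np.ndarray  # (N, 2) int, row/col
    classes: np.ndarray  # (N,) int in {0, 1}
    image_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.classes = np.asarray(self.classes, dtype=np.int64).ravel()
        if len(self.coords) != len(self.classes):
            raise ValueError("coords and classes length mismatch")
        if not np.isin(self.classes, [0, 1]).all():
            raise ValueError("classes must be 0 (background) or 1 (TWP)")
        key = self.coords[:, 0] * np.int64(2**32) + self.coords[:, 1]
        order = np.argsort(key, kind="stable")
        k, c = key[order], self.classes[order]
        same = k[1:] == k[:-1]
        if np.any(same & (c[1:] != c[:-1])):
            raise ValueError("a pixel is labelled with both classes")

    def validate_for(self, shape: tuple[int, int]) -> None:
        if (
            (self.coords < 0).any()
            or (self.coords[:, 0] >= shape[0]).any()
            or (self.coords[:, 1] >= shape[1]).any()
        ):
            raise ValueError("label coordinates fall outside the image")

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabelSet":
        df = pd.read_csv(path, comment="#")
        image_id = str(df["image_id"].iloc[0]) if "image_id" in df else ""
        return cls(df[["row", "col"]].to_numpy(), df["cls"].to_numpy(), image_id)

    def write_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "row": self.coords[:, 0],
                "col": self.coords[:, 1],
                "cls": self.classes,
                "image_id": self.image_id,
            }
        )
        df.to_csv(path, index=False)
        return Path(path)


@dataclass
class ForestModel:
    """Random-forest pixel classifier plus the feature recipe it expects."""

    forest: RandomForestClassifier
    scales: tuple[float, ...]
    feature_names: tuple[str, ...]
    seed: int
    oob_accuracy: float
    class_order: tuple[int, int] = (0, 1)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(
            {
                "config": json.dumps(
                    {
                        "scales": list(self.scales),
                        "feature_names": list(self.feature_names),
                        "seed": self.seed,
                        "oob_accuracy": self.oob_accuracy,
                        "class_order": list(self.class_order),
                    }
                ),
                "forest": self.forest,
            },
            path,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        blob = joblib.load(path)
        cfg = json.loads(blob["config"])
        return cls(
            forest=blob["forest"],
            scales=tuple(cfg["scales"]),
            feature_names=tuple(cfg["feature_names"]),
            seed=cfg["seed"],
            oob_accuracy=cfg["oob_accuracy"],
            class_order=tuple(cfg["class_order"]),
        )


@dataclass(frozen=True)
class RuleModel:
    """Deterministic darkness rule: all channels <= cap is TWP."""

    darkness_cap: int = DARKNESS_CAP


@dataclass
class ClassMap:
    """Per-pixel TWP probability and hard class, with provenance."""

    prob: np.ndarray  # (H, W) float32 in [0, 1]
    hard: np.ndarray  # (H, W) bool, True = TWP
    model_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.prob.shape != self.hard.shape:
            raise ValueError("prob and hard rasters must share a shape")
        if float(self.prob.min(initial=0.0)) < 0 or float(self.prob.max(initial=0.0)) > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def extract_features(
    image: FilterImage | np.ndarray, scales: tuple[float, ...] = DEFAULT_SCALES
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-pixel feature stack: raw RGB, multiscale Gaussians, gradient
    magnitude, grey local min/max (texture) and the channel-min darkness.

    Returns an (H, W, F) float32 array and the feature names.
    """
    if len(scales) == 0:
        raise ValueError("scales must be a nonempty list of smoothing radii")
    rgb = image.rgb if isinstance(image, FilterImage) else np.asarray(image)
    rgbf = rgb.astype(np.float32)
    planes: list[np.ndarray] = []
    names: list[str] = []
    for i, ch in enumerate("RGB"):
        planes.append(rgbf[..., i])
        names.append(ch)
    for s in scales:
        for i, ch in enumerate("RGB"):
            planes.append(ndi.gaussian_filter(rgbf[..., i], sigma=s))
            names.append(f"{ch}_gauss{s:g}")
    lum = rgbf.mean(axis=2)
    planes.append(ndi.gaussian_gradient_magnitude(lum, sigma=1.0))
    names.append("grad_mag")
    foot = np.ones((3, 3), bool)
    planes.append(ndi.grey_erosion(lum, footprint=foot))
    names.append("local_min")
    planes.append(ndi.grey_dilation(lum, footprint=foot))
    names.append("local_max")
    planes.append(rgbf.min(axis=2))
    names.append("darkness")
    return np.stack(planes, axis=-1).astype(np.float32), tuple(names)


def train_classifier(
    feature_stack: np.ndarray,
    labels: LabelSet,
    seed: int = 0,
    n_trees: int = 100,
    min_per_class: int = 10,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    feature_names: tuple[str, ...] = (),
) -> ForestModel:
    """Train the random forest on the labelled pixels only.

    Out-of-bag accuracy on the training labels is stored on the model.
    Training is reproducible under a fixed seed.
    """
    labels.validate_for(feature_stack.shape[:2])
    counts = np.bincount(labels.classes, minlength=2)
    if (counts == 0).any():
        raise ValueError("labels must contain both classes (TWP and background)")
    if (counts < min_per_class).any():
        raise ValueError(
            f"need at least {min_per_class} labelled pixels per class, got {counts.tolist()}"
        )
    x = feature_stack[labels.coords[:, 0], labels.coords[:, 1], :]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(seed),
        oob_score=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oob on tiny label sets
        forest.fit(x, labels.classes)
    oob = float(getattr(forest, "oob_score_", np.nan))
    return ForestModel(
        forest=forest,
        scales=tuple(scales),
        feature_names=tuple(feature_names) or tuple(f"f{i}" for i in range(x.shape[1])),
        seed=int(seed),
        oob_accuracy=oob,
    )


def _predict_prob(model: ForestModel, feats: np.ndarray) -> np.ndarray:
    h, w, f = feats.shape
    flat = feats.reshape(-1, f)
    out = np.empty(flat.shape[0], dtype=np.float32)
    cls1 = list(model.forest.classes_).index(1)
    chunk = 1 << 20
    for i in range(0, flat.shape[0], chunk):
        out[i : i + chunk] = model.forest.predict_proba(flat[i : i + chunk])[:, cls1]
    return out.reshape(h, w)


def classify(image: FilterImage, model: ForestModel | RuleModel) -> ClassMap:
    """Predict the per-pixel TWP probability map for a whole image.

    Pixels under the image's exclusion mask are forced to background after
    prediction — exclusion beats classification.
    """
    if isinstance(model, RuleModel):
        prob = (image.rgb.max(axis=2) <= model.darkness_cap).astype(np.float32)
        model_id = f"rule(cap={model.darkness_cap})"
    elif isinstance(model, ForestModel):
        feats, names = extract_features(image, model.scales)
        if feats.shape[-1] != len(model.feature_names):
            raise ValueError(
                f"feature stack has {feats.shape[-1]} planes but the model "
                f"expects {len(model.feature_names)}"
            )
        prob = _predict_prob(model, feats)
        model_id = f"forest(seed={model.seed})"
    else:
        raise TypeError(f"unsupported model type: {type(model).__name__}")
    if image.exclusion_mask is not None:
        prob[image.exclusion_mask] = 0.0
    return ClassMap(prob=prob, hard=prob >= 0.5, model_id=model_id)


def binarize(class_map: ClassMap) -> np.ndarray:
    """Binarize the probability map with the IsoData automatic threshold.

    The probability raster is first scaled to 8 bits; IsoData picks the
    threshold; TWP is the foreground (high-probability) side. A degenerate
    single-valued raster yields an empty mask with a warning.
    """
    raster = np.round(class_map.prob * 255).astype(np.uint8)
    vals = np.unique(raster)
    if len(vals) == 1:
        warnings.warn("degenerate probability raster: no threshold, empty mask")
        return np.zeros(raster.shape, dtype=bool)
    thresh = threshold_isodata(raster)
    mask = raster > thresh
    if not mask.any():
        warnings.warn("binarization produced an empty foreground")
    return mask


def labels_from_truth(
    image: FilterImage,
    truth,
    n_per_class: int = 1500,
    seed: int = 0,
) -> LabelSet:
    """Sample a sparse training label set from a scene's ground truth.

    Black core pixels of TWP and charcoal particles become class 1;
    background, chromatic halo and organic-distractor pixels become class 0
    — mirroring an annotator marking black particles as TWP candidates and
    everything coloured as background.
    """
    rng = np.random.default_rng(seed)
    label = truth.rasters["label"]
    core = truth.rasters["core"].copy()
    # include charcoal cores as "black particle" annotations
    dark = image.rgb.max(axis=2) <= DARKNESS_CAP
    core |= (label > 0) & dark
    bg = ~core
    fg_idx = np.argwhere(core)
    bg_idx = np.argwhere(bg)
    if len(fg_idx) == 0:
        raise ValueError("scene has no black core pixels to label")
    take_fg = fg_idx[rng.choice(len(fg_idx), min(n_per_class, len(fg_idx)), replace=False)]
    take_bg = bg_idx[rng.choice(len(bg_idx), min(n_per_class, len(bg_idx)), replace=False)]
    coords = np.vstack([take_fg, take_bg])
    classes = np.r_[np.ones(len(take_fg), int), np.zeros(len(take_bg), int)]
    return LabelSet(coords, classes, image_id="synthetic-truth")
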