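"""Point-based planar registration between image and array coordinates.

Replaces manual georeferencing of the fluorescence/histology frame onto the
transcript-array frame with a least-squares fitted similarity or affine
transform from user-supplied control-point pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import AffineTransform, SimilarityTransform

__all__ = ["ControlPoints", "PlanarTransform", "DegenerateControlPointsError",
           "fit_transform", "apply_transform", "read_control_points"]

_MIN_PAIRS = {"similarity": 2, "affine": 3}


class DegenerateControlPointsError(ValueError):
    """Control points do not determine the requested transform (rank deficiency)."""


@dataclass
class ControlPoints:
    """Paired (image -> array) coordinates: columns x_img, y_img, x_arr, y_arr."""

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["x_img", "y_img", "x_arr", "y_arr"]
        missing = [c for c in req if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"control points missing column(s) {missing}")
        self.pairs = self.pairs.loc[:, req].astype(float).reset_index(drop=True)
        src = self.pairs[["x_img", "y_img"]].to_numpy()
        if len(src) != len(np.unique(src, axis=0)):
            raise ValueError("duplicated source control points")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def src(self) -> np.ndarray:
        return self.pairs[["x_img", "y_img"]].to_numpy()

    @property
    def dst(self) -> np.ndarray:
        return self.pairs[["x_arr", "y_arr"]].to_numpy()


@dataclass
class PlanarTransform:
    """2x3 affine coefficient matrix mapping (x, y, 1) -> (x', y')."""

    matrix: np.ndarray  # shape (2, 3)
    model: str
    rms_residual: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if not np.isfinite(self.matrix).all():
            raise ValueError("transform matrix contains non-finite values")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "model": self.model,
                    "matrix": self.matrix.tolist(),
                    "rms_residual": float(self.rms_residual),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlanarTransform":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(matrix=np.asarray(d["matrix"]), model=d["model"],
                   rms_residual=float(d["rms_residual"]))

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
                   model="similarity", rms_residual=0.0)


def read_control_points(path) -> ControlPoints:
    return ControlPoints(pairs=pd.read_csv(path, sep="\t"))


def fit_transform(cp: ControlPoints, model: str = "similarity") -> PlanarTransform:
    """Least-squares fit of a similarity (default) or affine transform.

    Minimizes the sum of squared residuals in the target (array) frame and
    reports the root-mean-square residual over the control points.
    """
    if model not in _MIN_PAIRS:
        raise ValueError(f"model must be one of {sorted(_MIN_PAIRS)}")
    if len(cp) < _MIN_PAIRS[model]:
        raise ValueError(
            f"{model} fit needs >= {_MIN_PAIRS[model]} control point pairs, got {len(cp)}"
        )
    # rank check: affine needs 2-D spread of sources; similarity needs >= 2
    # distinct points (duplicates are rejected by ControlPoints already)
    centered = cp.src - cp.src.mean(axis=0)
    src_rank = np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(cp.src).max()))
    if (model == "affine" and src_rank < 2) or (model == "similarity" and src_rank < 1):
        raise DegenerateControlPointsError(
            f"control points are degenerate (e.g. collinear) for the {model} model"
        )
    est = SimilarityTransform() if model == "similarity" else AffineTransform()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ok = est.estimate(cp.src, cp.dst)
    matrix = np.asarray(est.params)[:2, :]
    if not ok or not np.isfinite(matrix).all():
        raise DegenerateControlPointsError(
            f"control points are degenerate for the {model} model"
        )
    mapped = apply_transform_matrix(matrix, cp.src)
    rms = float(np.sqrt(np.mean(np.sum((mapped - cp.dst) ** 2, axis=1))))
    return PlanarTransform(matrix=matrix, model=model, rms_residual=rms)


def apply_transform_matrix(matrix: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    return pts @ matrix[:, :2].T + matrix[:, 2]


def apply_transform(t: PlanarTransform, pts: np.ndarray) -> np.ndarray:
    """Exact affine map of each (x, y) point; length preserved."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    return apply_transform_matrix(t.matrix, pts)
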