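"""Image-quality and agreement metrics for before/after comparisons.

SSIM follows the standard windowed formulation: local means, variances
and covariance under an 11×11 Gaussian window (σ = 1.5), stabilizers
C₁ = (k₁·L)² and C₂ = (k₂·L)² with k₁ = 0.01, k₂ = 0.03 and L the dynamic
range.  The reported value is the mean of the local SSIM map over an
evaluation mask (default: the interior, excluding the half-window border
where the local statistics are padding-contaminated).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import pearsonr, ttest_rel

from .disc import CestStack

_SSIM_SIGMA = 1.5
_SSIM_RADIUS = 5  # 11x11 window


def ssim(
    image: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float | None = None,
) -> float:
    """Mean structural similarity of ``image`` against ``reference``.

    ``dynamic_range`` defaults to the maximum of the reference.  Note the
    default makes the score direction-dependent; pass ``dynamic_range``
    explicitly for a symmetric comparison.
    """
    a = np.asarray(image, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image and reference shapes differ")
    if dynamic_range is None:
        dynamic_range = float(b.max())
    if dynamic_range <= 0:
        raise ValueError("dynamic range must be positive")
    smap = ssim_map(a, b, k1=k1, k2=k2, dynamic_range=dynamic_range)
    if mask is None:
        mask = np.zeros(a.shape, dtype=bool)
        mask[_SSIM_RADIUS:-_SSIM_RADIUS, _SSIM_RADIUS:-_SSIM_RADIUS] = True
    return float(smap[np.asarray(mask, bool)].mean())


def ssim_map(
    image: np.ndarray,
    reference: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float = 1.0,
) -> np.ndarray:
    """Local SSIM map under the 11×11 Gaussian window."""
    a = np.asarray(image, dtype=float)
    b = np.asarray(reference, dtype=float)
    blur = lambda im: gaussian_filter(im, _SSIM_SIGMA, radius=_SSIM_RADIUS)
    mu_a, mu_b = blur(a), blur(b)
    var_a = blur(a * a) - mu_a * mu_a
    var_b = blur(b * b) - mu_b * mu_b
    cov = blur(a * b) - mu_a * mu_b
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return num / den


def dataset_ssim(
    stack_a: CestStack | np.ndarray,
    stack_b: CestStack | np.ndarray,
    mask: np.ndarray | None = None,
    dynamic_range: float | None = None,
) -> tuple[list[float], float]:
    """SSIM per corresponding frame plus the unweighted mean over frames.

    Each frame's dynamic range defaults to that reference frame's maximum
    unless a common ``dynamic_range`` is given.
    """
    a = stack_a.data if isinstance(stack_a, CestStack) else np.asarray(stack_a, float)
    b = stack_b.data if isinstance(stack_b, CestStack) else np.asarray(stack_b, float)
    if a.shape != b.shape:
        raise ValueError("stacks have mismatched shapes")
    if isinstance(stack_a, CestStack) and isinstance(stack_b, CestStack):
        if stack_a.schedule.n_frames != stack_b.schedule.n_frames:
            raise ValueError("stacks have mismatched schedules")
    per_frame = [
        ssim(a[..., f], b[..., f], mask=mask, dynamic_range=dynamic_range)
        for f in range(a.shape[2])
    ]
    return per_frame, float(np.mean(per_frame))


def roi_pearson(means_a, means_b) -> tuple[float, int]:
    """Pearson correlation of paired per-ROI mean values."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired ROI means")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in ROI means; correlation undefined")
    r = pearsonr(a, b).statistic
    return float(r), int(a.size)


def paired_test(values_a, values_b, method: str = "t") -> tuple[float, float]:
    """Paired two-sided test on A − B differences.

    ``method='t'`` is the paired t-test; ``method='permutation'`` is the
    exact sign-flip permutation test (all 2ⁿ flips, n ≤ 12) on the mean
    difference, with the t statistic still reported.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]) and np.std(d) == 0:
        raise ValueError("zero difference variance; test undefined")
    t, p = ttest_rel(a, b)
    if method == "t":
        return float(t), float(p)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if d.size > 12:
        raise ValueError("exact permutation test limited to n <= 12 pairs")
    obs = abs(d.mean())
    count = 0
    total = 0
    for signs in itertools.product((1.0, -1.0), repeat=d.size):
        total += 1
        if abs((d * np.asarray(signs)).mean()) >= obs - 1e-15:
            count += 1
    return float(t), count / total


@dataclass
class EvalReport:
    """Aggregated comparison of one corrected dataset against a reference."""

    per_frame_ssim: list[float]
    dataset_ssim: float
    map_ssim: dict = field(default_factory=dict)
    pearson_r: float | None = None
    pearson_n: int | None = None
    paired_t: float | None = None
    paired_p: float | None = None
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
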