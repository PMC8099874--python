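"""Saliency analysis of the first-stage CNN and the population-level
pixel-wise z-test with normal-CDF significance masks.

Per-signal class-activation maps (gradient-weighted, taken at the last
convolutional layer) are min-max normalized to [0, 1], accumulated per true
class over correctly classified assessments, and compared pixel by pixel:

    z = (g_ET - g_PD) / sqrt(var_ET/n_ET + var_PD/n_PD)

Positive z marks pixels the network attends to more for ET; masks threshold
the standard normal CDF at 1 - alpha/2 and alpha/2 (alpha = 0.02 -> 0.99 /
0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as spstats

from .data import Group
from .stage1 import ET_CLASS, PD_CLASS, SignalDataset, Stage1Model

__all__ = [
    "SaliencyMap",
    "GroupSaliencyStats",
    "SignificanceMasks",
    "gradcam",
    "gradcam_batch",
    "collect_group_maps",
    "pixelwise_z",
    "significance_masks",
    "normality_gate",
]


@dataclass
class SaliencyMap:
    weights: np.ndarray  # (129, 191) in [0, 1]
    target_class: int
    source: dict | None = None
    degenerate: bool = False  # all-zero map (zero gradient)


@dataclass
class GroupSaliencyStats:
    """Streaming per-pixel mean/variance (Welford) over saliency maps."""

    shape: tuple
    n: int = 0
    mean: np.ndarray = field(default=None)
    _m2: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = np.zeros(self.shape)
        if self._m2 is None:
            self._m2 = np.zeros(self.shape)

    def update(self, grid: np.ndarray) -> None:
        if grid.shape != tuple(self.shape):
            raise ValueError("saliency map shape mismatch")
        self.n += 1
        delta = grid - self.mean
        self.mean = self.mean + delta / self.n
        self._m2 = self._m2 + delta * (grid - self.mean)

    @property
    def variance(self) -> np.ndarray:
        if self.n < 2:
            raise ValueError("variance requires n >= 2 maps")
        return self._m2 / (self.n - 1)


def _bilinear_resize(a: np.ndarray, shape: tuple) -> np.ndarray:
    """Corner-aligned bilinear upsampling."""
    hh, ww = shape
    h, w = a.shape
    if (h, w) == (hh, ww):
        return a.copy()
    rows = np.linspace(0.0, h - 1.0, hh)
    cols = np.linspace(0.0, w - 1.0, ww)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    top = a[np.ix_(r0, c0)] * (1 - fc) + a[np.ix_(r0, c1)] * fc
    bot = a[np.ix_(r1, c0)] * (1 - fc) + a[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def gradcam_batch(
    model: Stage1Model, X: np.ndarray, hints: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw class-activation maps for a batch.

    Returns (maps (N, 129, 191) min-max normalized to [0,1], degenerate flags).
    Only the target logit's gradient is backpropagated; the other output node
    is zeroed, so it cannot influence the map.
    """
    X = np.asarray(X, dtype=float)
    hints = np.asarray(hints, dtype=float)
    targets = np.asarray(targets, dtype=int)
    net = model.network
    _, cache = net.forward(model.params, X, hints)
    dlogits = np.zeros((X.shape[0], 2))
    dlogits[np.arange(X.shape[0]), targets] = 1.0
    _, d_conv_relu, _ = net.backward(model.params, cache, dlogits)
    activations = cache["conv2_relu"]  # (N, F, h, w)
    channel_w = d_conv_relu.mean(axis=(2, 3))  # spatial-average gradients
    cams = np.maximum(np.einsum("nf,nfhw->nhw", channel_w, activations), 0.0)

    out = np.empty((X.shape[0],) + net.input_shape)
    degenerate = np.zeros(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        up = _bilinear_resize(cams[i], net.input_shape)
        lo, hi = up.min(), up.max()
        if hi - lo < 1e-30:
            out[i] = np.zeros(net.input_shape)
            degenerate[i] = True
        else:
            out[i] = (up - lo) / (hi - lo)
    return out, degenerate


def gradcam(
    model: Stage1Model,
    spec_grid: np.ndarray,
    hint: np.ndarray,
    target_class: int,
    source: dict | None = None,
) -> SaliencyMap:
    """Saliency map for one signal, normalized to [0, 1].

    A model whose target logit does not depend on the input yields an all-zero
    map, flagged ``degenerate``.
    """
    maps, degenerate = gradcam_batch(
        model,
        np.asarray(spec_grid)[None, ...],
        np.asarray(hint)[None, :],
        np.array([target_class]),
    )
    return SaliencyMap(
        weights=maps[0],
        target_class=int(target_class),
        source=source,
        degenerate=bool(degenerate[0]),
    )


def collect_group_maps(
    model: Stage1Model,
    dataset: SignalDataset,
    correct_keys: Iterable[tuple],
    batch_size: int = 64,
    keep_maps: bool = False,
) -> tuple[GroupSaliencyStats, GroupSaliencyStats] | tuple:
    """Per-class saliency statistics over correctly classified assessments.

    Maps are computed for every signal whose assessment key is in
    ``correct_keys``, targeting the signal's true class, and accumulated
    streamingly by true class.  Returns (et_stats, pd_stats); with
    ``keep_maps`` also the raw maps per group (for the normality gate).
    """
    correct = set(correct_keys)
    include = np.array([k in correct for k in dataset.assessment_keys], dtype=bool)
    if not include.any():
        raise ValueError("no correctly classified assessments to analyze")
    sub = dataset.subset(include)

    shape = model.network.input_shape
    stats = {ET_CLASS: GroupSaliencyStats(shape), PD_CLASS: GroupSaliencyStats(shape)}
    raw: dict[int, list] = {ET_CLASS: [], PD_CLASS: []}
    for s in range(0, len(sub), batch_size):
        sl = slice(s, s + batch_size)
        maps, _ = gradcam_batch(model, sub.X[sl], sub.hints[sl], sub.labels[sl])
        for grid, label in zip(maps, sub.labels[sl]):
            stats[int(label)].update(grid)
            if keep_maps:
                raw[int(label)].append(np.asarray(grid, dtype=np.float32))
    for cls, st in stats.items():
        if st.n < 2:
            raise ValueError(
                f"group {'ET' if cls == ET_CLASS else 'PD'} has n={st.n} < 2 maps"
            )
    if keep_maps:
        return (
            stats[ET_CLASS],
            stats[PD_CLASS],
            np.stack(raw[ET_CLASS]),
            np.stack(raw[PD_CLASS]),
        )
    return stats[ET_CLASS], stats[PD_CLASS]


def pixelwise_z(et: GroupSaliencyStats, pd: GroupSaliencyStats) -> np.ndarray:
    """Two-sample z statistic per pixel; zero pooled variance maps to z = 0."""
    if tuple(et.shape) != tuple(pd.shape):
        raise ValueError("group statistics shape mismatch")
    pooled = et.variance / et.n + pd.variance / pd.n
    zero = pooled <= 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} pixels have zero pooled variance; z set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero, 0.0, (et.mean - pd.mean) / np.sqrt(np.where(zero, 1.0, pooled)))
    return z


@dataclass
class SignificanceMasks:
    z: np.ndarray
    et_mask: np.ndarray
    pd_mask: np.ndarray
    alpha: float
    masked_mean_et: np.ndarray | None = None
    masked_mean_pd: np.ndarray | None = None


def significance_masks(
    z: np.ndarray,
    alpha: float = 0.02,
    mean_et: np.ndarray | None = None,
    mean_pd: np.ndarray | None = None,
) -> SignificanceMasks:
    """Threshold Phi(z) at 1 - alpha/2 (ET mask) and alpha/2 (PD mask).

    Masked means are the group mean saliency grids zeroed outside the
    corresponding mask (when the grids are provided).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not np.all(np.isfinite(z)):
        raise ValueError("z grid must be finite")
    cdf = spstats.norm.cdf(z)
    et_mask = cdf > 1.0 - alpha / 2.0
    pd_mask = cdf < alpha / 2.0
    return SignificanceMasks(
        z=z,
        et_mask=et_mask,
        pd_mask=pd_mask,
        alpha=alpha,
        masked_mean_et=None if mean_et is None else np.where(et_mask, mean_et, 0.0),
        masked_mean_pd=None if mean_pd is None else np.where(pd_mask, mean_pd, 0.0),
    )


def normality_gate(maps: np.ndarray, min_n: int = 20) -> np.ndarray | None:
    """Per-pixel omnibus normality p-values (skew + kurtosis test).

    Advisory only: the pipeline proceeds regardless of the outcome.  Returns
    a p-value grid, with NaN at constant pixels (test undefined there), or
    None with a warning when n < min_n.
    """
    maps = np.asarray(maps)
    n = maps.shape[0]
    if n < min_n:
        warnings.warn(
            f"normality gate skipped: n={n} < {min_n}", RuntimeWarning, stacklevel=2
        )
        return None
    flat = maps.reshape(n, -1)
    constant = flat.std(axis=0) <= 0.0
    pvals = np.full(flat.shape[1], np.nan)
    ok = ~constant
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = spstats.normaltest(flat[:, ok], axis=0)
        pvals[ok] = p
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant pixels: normality test undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return pvals.reshape(maps.shape[1:])
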