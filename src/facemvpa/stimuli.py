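"""Low-level visual feature control: stimulus equalization, V1-like
Gabor features, and multiclass leave-one-sample-out classification.

The point of this control is to show (or plant, in synthetic data) that
category structure in images is — or is not — recoverable from early
visual features alone.  Images are first physically equalized (common
luminance histogram and common Fourier amplitude spectrum, phases
retained); simple-cell (S1) responses are Gabor filter magnitudes over
orientations and scales, complex-cell (C1) responses their local maxima
over space and adjacent scales; a linear one-vs-one SVM is then scored
with leave-one-sample-per-class-out cross-validation against a
label-permutation chance test.

Real photographs are not redistributable, so the module is exercised on
generated textured oval stimuli with controllable class structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel
from sklearn.svm import SVC

from .core import derive_rng

EQUALIZE_ROUNDS = 3
GABOR_ORIENTATIONS = 4
#: simple-cell filter sizes in pixels, 8 scales pooled into 4 bands
GABOR_SIZES = (7, 9, 11, 13, 15, 17, 19, 21)
C1_POOL_SIZES = (8, 10, 12, 14)  # spatial pooling cells for the 4 scale bands


def oval_aperture(shape: tuple[int, int], fraction: float = 0.8) -> np.ndarray:
    """Boolean oval support centered in the frame."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = fraction * h / 2.0, fraction * w * 0.75 / 2.0  # taller than wide
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def make_oval_stimuli(
    n_per_class: int,
    n_classes: int = 5,
    shape: tuple[int, int] = (64, 64),
    class_amplitude: float = 1.0,
    noise_amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Synthetic textured oval stimuli with controllable class structure.

    Each class has a fixed random smooth texture template; every exemplar
    is template * class_amplitude + fresh noise texture * noise_amplitude,
    masked by the oval aperture and rescaled into [0, 1].  With
    class_amplitude = 0 the classes are statistically identical.
    """
    rng = derive_rng(seed, 600)
    aperture = oval_aperture(shape)

    def smooth_texture() -> np.ndarray:
        base = rng.standard_normal(shape)
        kern = np.outer(np.hanning(9), np.hanning(9))
        return fftconvolve(base, kern / kern.sum(), mode="same")

    templates = [smooth_texture() for _ in range(n_classes)]
    images, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = class_amplitude * templates[c] + noise_amplitude * smooth_texture()
            img = img - img.min()
            if img.max() > 0:
                img = img / img.max()
            img = img * aperture
            images.append(img)
            labels.append(c)
    return images, np.array(labels)


def _match_histogram(image: np.ndarray, sorted_target: np.ndarray) -> np.ndarray:
    """Impose a target sorted-value profile by rank matching (ties broken
    by stable order, deterministic)."""
    flat = image.reshape(-1)
    order = np.argsort(flat, kind="stable")
    out = np.empty_like(flat)
    out[order] = sorted_target
    return out.reshape(image.shape)


def _match_spectrum(image: np.ndarray, target_amplitude: np.ndarray) -> np.ndarray:
    """Impose a target Fourier amplitude spectrum, retaining the phase."""
    f = np.fft.fft2(image)
    phase = np.angle(f)
    return np.real(np.fft.ifft2(target_amplitude * np.exp(1j * phase)))


def equalize_images(images: list[np.ndarray], n_rounds: int = EQUALIZE_ROUNDS) -> list[np.ndarray]:
    """Match all images to the set-average luminance histogram and
    Fourier amplitude spectrum (phases retained), iterating a fixed
    number of rounds.  Each round applies the histogram step then the
    spectrum step, so the output amplitude spectra agree exactly.
    """
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images must share one shape, got {shapes}")
    out = [np.asarray(im, dtype=float) for im in images]
    for _ in range(n_rounds):
        sorted_target = np.mean([np.sort(im.reshape(-1)) for im in out], axis=0)
        out = [_match_histogram(im, sorted_target) for im in out]
        target_amp = np.mean([np.abs(np.fft.fft2(im)) for im in out], axis=0)
        out = [_match_spectrum(im, target_amp) for im in out]
    return out


def radial_power_spectrum(image: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Orientation-averaged Fourier power as a function of spatial frequency."""
    f = np.fft.fftshift(np.abs(np.fft.fft2(image)) ** 2)
    h, w = image.shape
    y, x = np.mgrid[0:h, 0:w]
    rad = np.hypot(y - h // 2, x - w // 2)
    edges = np.linspace(0.5, rad.max(), n_bins + 1)
    power = np.empty(n_bins)
    for i in range(n_bins):
        sel = (rad >= edges[i]) & (rad < edges[i + 1])
        power[i] = f[sel].mean()
    return power


@dataclass
class GaborBank:
    kernels: list[np.ndarray]  # zero-mean, unit-norm, real Gabor kernels
    orientations: int
    n_scales: int


def build_gabor_bank(
    orientations: int = GABOR_ORIENTATIONS,
    sizes: tuple[int, ...] = GABOR_SIZES,
) -> GaborBank:
    """Simple-cell Gabor bank with fixed pixel sizes.

    Per scale, sigma grows with the filter size and the wavelength tracks
    sigma (lambda = sigma / 0.8), the standard simple-cell
    parameterization; kernels are truncated to the nominal size, DC
    corrected, and unit-normalized.
    """
    kernels = []
    for size in sizes:
        sigma = 0.0036 * size**2 + 0.35 * size + 0.18
        freq = 0.8 / sigma
        n_stds = (size - 1) / (2.0 * sigma)
        for oi in range(orientations):
            theta = np.pi * oi / orientations
            k = np.real(gabor_kernel(freq, theta=theta, sigma_x=sigma,
                                     sigma_y=sigma, n_stds=n_stds))
            k = k - k.mean()  # zero DC: responses invariant to constant offsets
            k = k / np.linalg.norm(k)
            kernels.append(k)
    return GaborBank(kernels, orientations, len(sizes))


def gabor_c1_maps(
    image: np.ndarray,
    bank: GaborBank | None = None,
    pool_sizes: tuple[int, ...] = C1_POOL_SIZES,
) -> list[list[np.ndarray]]:
    """Complex-cell (C1) maps of one image, indexed [band][orientation].

    S1 = |image * gabor| per orientation and scale; C1 pools the maximum
    over adjacent scale pairs and over local spatial cells whose size
    grows with the band, then subsamples the pooled map.
    """
    bank = build_gabor_bank() if bank is None else bank
    if bank.n_scales % 2:
        raise ValueError("scale count must be even (scales pool in adjacent pairs)")
    if bank.n_scales // 2 != len(pool_sizes):
        raise ValueError("one pool size per scale band is required")
    biggest = max(k.shape[0] for k in bank.kernels)
    if biggest > min(image.shape):
        raise ValueError(
            f"largest filter ({biggest}px) exceeds the image {image.shape}"
        )
    s1 = []
    for k in bank.kernels:
        resp = np.abs(fftconvolve(image, k, mode="same"))
        h = k.shape[0] // 2  # zero the border where the filter overlaps padding
        resp[:h, :] = resp[-h:, :] = 0.0
        resp[:, :h] = resp[:, -h:] = 0.0
        s1.append(resp)
    n_ori = bank.orientations
    maps: list[list[np.ndarray]] = []
    for band in range(bank.n_scales // 2):
        pool = pool_sizes[band]
        row = []
        for oi in range(n_ori):
            a = s1[(2 * band) * n_ori + oi]
            b = s1[(2 * band + 1) * n_ori + oi]
            scale_max = np.maximum(a, b)  # max over the two adjacent scales
            pooled = maximum_filter(scale_max, size=pool, mode="constant")
            step = max(pool // 2, 1)  # 50%-overlapping cells: smoother under shifts
            row.append(pooled[pool // 2 :: step, pool // 2 :: step])
        maps.append(row)
    return maps


def gabor_c1_features(
    image: np.ndarray,
    bank: GaborBank | None = None,
    pool_sizes: tuple[int, ...] = C1_POOL_SIZES,
) -> np.ndarray:
    """Concatenated C1 feature vector (see ``gabor_c1_maps``)."""
    maps = gabor_c1_maps(image, bank, pool_sizes)
    return np.concatenate([m.reshape(-1) for row in maps for m in row])


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # expected class x predicted class

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def per_class_tpr(self) -> np.ndarray:
        return np.diag(self.counts) / self.counts.sum(axis=1)


def multiclass_loocv(
    features: np.ndarray,
    labels: np.ndarray,
    cost: float = 1.0,
) -> tuple[float, ConfusionMatrix]:
    """Leave-one-sample-per-class-out multiclass linear SVM.

    Each fold holds out exactly one sample from every class (classes must
    be balanced), trains a one-vs-one linear SVM on the rest, and
    accumulates the confusion matrix over folds.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(set(counts)) != 1:
        raise ValueError(f"class sizes must be equal, got {dict(zip(classes, counts))}")
    n_folds = counts[0]
    # fold f holds out the f-th sample of every class (order of appearance)
    fold_of = np.empty(labels.size, dtype=int)
    for c in classes:
        fold_of[labels == c] = np.arange(n_folds)
    counts_mat = np.zeros((classes.size, classes.size), dtype=int)
    class_pos = {c: i for i, c in enumerate(classes)}
    for f in range(n_folds):
        test = fold_of == f
        clf = SVC(kernel="linear", C=cost, decision_function_shape="ovo")
        clf.fit(features[~test], labels[~test])
        pred = clf.predict(features[test])
        for true, p in zip(labels[test], pred):
            counts_mat[class_pos[true], class_pos[p]] += 1
    cm = ConfusionMatrix(counts_mat)
    return cm.accuracy, cm


def permutation_chance(
    features: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    cost: float = 1.0,
) -> np.ndarray:
    """Null accuracies from re-running the classifier with labels shuffled
    within the dataset (class balance preserved)."""
    rng = derive_rng(seed, 700)
    labels = np.asarray(labels)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = rng.permutation(labels)
        out[i], _ = multiclass_loocv(features, shuffled, cost=cost)
    return out
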