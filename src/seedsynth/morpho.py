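"""Seed morphometry: contours, shape descriptors, EFD and shape-space PCA.

Eight descriptors summarize each segmented seed: area (A_S), length (L) and
width (W) — the major/minor axis lengths of the ellipse sharing the mask's
normalized second central moments — their ratio (LWR), eccentricity (E),
solidity (S = area / convex-hull area), perimeter (PL, arc length of the
sub-pixel iso-contour) and circularity (C_S = 4*pi*A / PL^2, 1 for a disc).

Contour shape beyond these scalars is captured by elliptic Fourier
descriptors (EFD): the closed contour (x(t), y(t)) is expanded, under
chord-length parameterization, into per-harmonic coefficient quadruples
(a_n, b_n, c_n, d_n) following Kuhl & Giardina.  Normalization by the first
harmonic's ellipse removes size, rotation and starting-point effects, pinning
(a1, b1, c1) to (1, 0, 0); with 20 harmonics the remaining 77 coefficients
form a similarity-invariant shape vector suitable for PCA.  The PCA transform
is invertible, so points along a principal axis can be mapped back to
coefficient arrays and rendered as contours — a morph sequence through the
population's shape space.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from sklearn.decomposition import PCA as _SkPCA


@dataclasses.dataclass
class Contour:
    """Closed sub-pixel contour, counter-clockwise, without duplicate endpoint."""

    points: np.ndarray  # (N, 2) of (x, y)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 8:
            raise ValueError("contour needs >= 8 (x, y) points")

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def arc_length(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclasses.dataclass
class MorphometricRecord:
    area: float
    length: float
    width: float
    lwr: float
    eccentricity: float
    solidity: float
    perimeter: float
    circularity: float

    FIELDS = ("area", "length", "width", "lwr", "eccentricity", "solidity", "perimeter", "circularity")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class EFDCoefficients:
    """Per-harmonic (a, b, c, d) quadruples, rows = harmonics."""

    coeffs: np.ndarray  # (harmonics, 4)
    locus: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False

    @property
    def harmonics(self) -> int:
        return self.coeffs.shape[0]


def extract_contour(mask: np.ndarray, smooth_sigma: float = 1.0) -> Contour:
    """Trace the outer sub-pixel contour of a binary mask.

    Marching squares at iso-level 0.5 on a 1-px zero-padded copy, so contours
    are closed even when the mask touches the raster border.  The float mask
    is first smoothed with a small Gaussian (``smooth_sigma``, default 1 px):
    iso-contours of a hard binary raster are pixel-level staircases that
    overestimate arc length by ~6%, which would bias perimeter and
    circularity; after smoothing a rasterized disc's contour length is within
    0.5% of the true circumference.  If several closed contours exist (e.g.
    interior holes), the one enclosing the largest absolute area is returned.
    Orientation is normalized so the signed (shoelace) area in (x, y) is
    positive.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.pad(mask, 2).astype(float)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    contours = measure.find_contours(padded, 0.5)
    if not contours and smooth_sigma > 0:
        # thin masks can be smoothed below the iso-level; fall back to hard tracing
        padded = np.pad(mask, 2).astype(float)
        contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no iso-contour found")

    def shoelace(rc: np.ndarray) -> float:
        y, x = rc[:, 0], rc[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    best = max(contours, key=lambda c: abs(shoelace(c)))
    if np.allclose(best[0], best[-1]):
        best = best[:-1]
    pts = np.column_stack([best[:, 1] - 2.0, best[:, 0] - 2.0])  # (x, y), unpad
    c = Contour(points=pts)
    if c.signed_area < 0:
        c = Contour(points=pts[::-1])
    return c


def compute_descriptors(mask: np.ndarray, dpi: float | None = None) -> MorphometricRecord:
    """The eight shape descriptors of a single-component binary mask.

    With ``dpi`` given, lengths are reported in mm and area in mm^2
    (25.4 mm per inch); otherwise everything is in pixels.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    _, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(
            f"mask has {n} connected components; label and screen instances first"
        )
    props = measure.regionprops(mask.astype(np.uint8))[0]
    contour = extract_contour(mask)
    area = float(props.area)
    length = float(props.axis_major_length)
    width = float(props.axis_minor_length)
    perimeter = contour.arc_length
    scale = 25.4 / dpi if dpi else 1.0
    return MorphometricRecord(
        area=area * scale**2,
        length=length * scale,
        width=width * scale,
        lwr=length / width if width > 0 else np.inf,
        eccentricity=float(props.eccentricity),
        solidity=float(props.solidity),
        perimeter=perimeter * scale,
        circularity=4.0 * np.pi * area / perimeter**2,
    )


def _closed_diffs(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment vectors, lengths and cumulative arc positions of a closed polygon."""
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 1e-12
    d, dt = d[keep], dt[keep]
    if len(dt) < 3:
        raise ValueError("degenerate contour: zero total length")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return d, dt, t


def efd_coefficients(
    contour: Contour, harmonics: int = 20, normalize: bool = True
) -> EFDCoefficients:
    """Kuhl–Giardina elliptic Fourier coefficients of a closed contour.

    The polygon is parameterized by chord length; each harmonic's
    coefficients come from the closed-form integral over the piecewise-linear
    traversal.  With ``normalize``, size, rotation and starting point are
    removed so the first harmonic is a unit-semi-major-axis ellipse aligned
    to the x-axis: (a1, b1, c1) = (1, 0, 0).
    """
    if harmonics < 1:
        raise ValueError("harmonics must be >= 1")
    d, dt, t = _closed_diffs(contour.points)
    T = t[-1]
    n = np.arange(1, harmonics + 1)[:, None]  # (H, 1)
    phi = 2.0 * np.pi * t / T  # (K+1,)
    cos_diff = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, K)
    sin_diff = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n.ravel() ** 2) * np.pi**2)  # (H,)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (cos_diff @ vx)
    b = const * (sin_diff @ vx)
    c = const * (cos_diff @ vy)
    dd = const * (sin_diff @ vy)
    coeffs = np.column_stack([a, b, c, dd])

    # locus (DC term) of the traversal
    x0, y0 = contour.points[0]
    # segment start offsets relative to the first point
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])]) - d[:, 0] / dt * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])]) - d[:, 1] / dt * t[:-1]
    A0 = (1.0 / T) * np.sum(d[:, 0] / (2 * dt) * (t[1:] ** 2 - t[:-1] ** 2) + xi * dt)
    C0 = (1.0 / T) * np.sum(d[:, 1] / (2 * dt) * (t[1:] ** 2 - t[:-1] ** 2) + delta * dt)
    locus = (float(x0 + A0), float(y0 + C0))

    out = EFDCoefficients(coeffs=coeffs, locus=locus, normalized=False)
    return _normalize_efd(out) if normalize else out


def _normalize_efd(efd: EFDCoefficients) -> EFDCoefficients:
    """Size/rotation/starting-point normalization of EFD coefficients."""
    C = efd.coeffs.copy()
    a1, b1, c1, d1 = C[0]
    # starting-point phase: zero the cross term a*b + c*d of harmonic 1
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    # ensure the phase lands on the semi-MAJOR axis of the first ellipse
    for extra in (0.0, np.pi / 2.0):
        th = theta + extra
        ct, st = np.cos(th), np.sin(th)
        a_, c_ = a1 * ct + b1 * st, c1 * ct + d1 * st
        b_, d_ = -a1 * st + b1 * ct, -c1 * st + d1 * ct
        if a_**2 + c_**2 >= b_**2 + d_**2:
            theta = th
            break
    H = C.shape[0]
    for k in range(H):
        nth = (k + 1) * theta
        R = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        M = C[k].reshape(2, 2) @ R
        C[k] = M.ravel()
    a1, b1, c1, d1 = C[0]
    psi = np.arctan2(c1, a1)
    E = np.hypot(a1, c1)
    if E <= 0:
        raise ValueError("degenerate first harmonic; cannot normalize")
    Rpsi = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for k in range(H):
        C[k] = (Rpsi @ C[k].reshape(2, 2)).ravel() / E
    return EFDCoefficients(coeffs=C, locus=(0.0, 0.0), normalized=True)


def efd_features(coeffs: EFDCoefficients) -> np.ndarray:
    """Flatten normalized coefficients and drop the constant (a1, b1, c1).

    Harmonic-major order (a1, b1, c1, d1, a2, ..., d_H) gives 4H values; the
    first three are 1, 0, 0 by normalization and carry no information, so the
    feature vector has 4H - 3 entries (77 at the default 20 harmonics).
    """
    if not coeffs.normalized:
        raise ValueError("features require normalized coefficients")
    return coeffs.coeffs.ravel()[3:].copy()


def features_to_coeffs(vector: np.ndarray) -> EFDCoefficients:
    """Inverse of :func:`efd_features`: re-insert (1, 0, 0) and reshape."""
    vector = np.asarray(vector, dtype=float)
    if (vector.size + 3) % 4:
        raise ValueError("feature vector length must be 4*harmonics - 3")
    full = np.concatenate([[1.0, 0.0, 0.0], vector])
    return EFDCoefficients(coeffs=full.reshape(-1, 4), normalized=True)


def efd_reconstruct(coeffs: EFDCoefficients, n_points: int = 300) -> Contour:
    """Evaluate the truncated Fourier series at uniform parameter values."""
    if n_points < 3 * coeffs.harmonics:
        raise ValueError("n_points must be >= 3 * harmonics for a faithful polygon")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coeffs.harmonics + 1)[:, None]
    cos = np.cos(2.0 * np.pi * n * t)
    sin = np.sin(2.0 * np.pi * n * t)
    a, b, c, d = coeffs.coeffs.T
    x = coeffs.locus[0] + a @ cos + b @ sin
    y = coeffs.locus[1] + c @ cos + d @ sin
    return Contour(points=np.column_stack([x, y]))


def mean_contour(group: list[EFDCoefficients], n_points: int = 300) -> Contour:
    """Average normalized coefficient arrays over a group, then reconstruct."""
    if not group:
        raise ValueError("empty group")
    H = group[0].harmonics
    if any(g.harmonics != H for g in group):
        raise ValueError("mixed harmonic counts")
    if not all(g.normalized for g in group):
        raise ValueError("mean contour requires normalized coefficients")
    mean = np.mean([g.coeffs for g in group], axis=0)
    return efd_reconstruct(EFDCoefficients(coeffs=mean, normalized=True), n_points)


def efd_from_mask(mask: np.ndarray, harmonics: int = 20) -> EFDCoefficients:
    """Convenience: contour extraction followed by normalized EFD."""
    return efd_coefficients(extract_contour(mask), harmonics=harmonics, normalize=True)


@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (p, k), orthonormal columns
    explained_ratio: np.ndarray  # (k,)
    mean: np.ndarray  # (p,)
    scale: np.ndarray  # (p,), ones when unstandardized
    columns: list | None = None

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(scores)
        return self.mean + (scores @ self.loadings.T) * self.scale


def pca_fit(matrix, standardize: bool = False) -> PCAResult:
    """Principal component analysis of an n x p feature table.

    Columns are centered, and scaled to unit variance when ``standardize``
    (use this for the eight descriptors, whose units differ; EFD features
    share a scale and are left unstandardized).  Loadings' signs are fixed so
    each component's largest-magnitude loading is positive.
    """
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    scale = np.ones(X.shape[1])
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            name = columns[zero[0]] if columns else int(zero[0])
            raise ValueError(f"zero-variance column {name!r} cannot be standardized")
        scale = sd
    Xs = (X - X.mean(axis=0)) / scale

    pca = _SkPCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T.copy()
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_ratio=pca.explained_variance_ratio_.copy(),
        mean=X.mean(axis=0),
        scale=scale,
        columns=columns,
    )


def latent_axis_contours(
    pca: PCAResult, axis: int, positions, n_points: int = 300
) -> list[Contour]:
    """Reconstruct contours at chosen score positions along one PCA axis.

    The PCA must have been fitted on EFD feature vectors (length 4H - 3).
    Each position maps to a feature vector with all other axes at zero, the
    normalization constants (1, 0, 0) are re-inserted, and the coefficient
    array is rendered as a contour.
    """
    if not 0 <= axis < pca.loadings.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    contours = []
    for pos in np.atleast_1d(np.asarray(positions, dtype=float)):
        if not np.isfinite(pos):
            raise ValueError("positions must be finite")
        score = np.zeros(pca.loadings.shape[1])
        score[axis] = pos
        vec = pca.inverse_transform(score)[0]
        contours.append(efd_reconstruct(features_to_coeffs(vec), n_points))
    return contours


def save_contour_plot(contours: list[Contour], path, labels=None) -> None:
    """Render closed contours side by side to an SVG/PNG file.

    Used for latent-axis morph sequences and per-cultivar mean shapes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(contours)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.4), squeeze=False)
    for k, (ax, c) in enumerate(zip(axes[0], contours)):
        pts = np.vstack([c.points, c.points[:1]])
        ax.plot(pts[:, 0], pts[:, 1], lw=1.2)
        ax.set_aspect("equal")
        ax.invert_yaxis()  # image convention: y down
        ax.axis("off")
        if labels is not None:
            ax.set_title(str(labels[k]), fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component of a binary mask."""
    labels, n = ndimage.label(np.asarray(mask).astype(bool))
    if n <= 1:
        return labels > 0
    sizes = ndimage.sum_labels(np.ones(labels.shape), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def descriptor_table(label_map: np.ndarray, cultivar: str = "", dpi: float | None = None) -> pd.DataFrame:
    """One MorphometricRecord row per instance id in a label map.

    Occlusion can split a visible mask into fragments; only the largest
    fragment is measured (such instances are low-solidity and are meant to be
    removed by the screening cascade anyway).
    """
    rows = []
    for iid in np.unique(label_map):
        if iid == 0:
            continue
        rec = compute_descriptors(largest_component(label_map == iid), dpi=dpi)
        rows.append({"instance_id": int(iid), "cultivar": cultivar, **rec.as_dict()})
    return pd.DataFrame(rows)
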