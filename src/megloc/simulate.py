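"""Labeled MEG sample generation.

Builds a shell source grid inside the conductor, draws random active
dipoles, synthesizes correlation-controlled sinusoidal time courses, and
adds white Gaussian sensor noise at an exact Frobenius-norm SNR.  The
batch streamer feeds on-the-fly network training.

Conventions fixed here (all configurable):

* 16-sample time courses at fs = 1 kHz, mixtures of 3 sinusoids with
  frequencies uniform in 10-90 Hz;
* every pair of source rows has empirical Pearson correlation exactly
  ``rho`` (equicorrelated construction: center, Gram-Schmidt, mix with
  the Cholesky factor of the equicorrelation matrix);
* SNR in amplitude-dB: ||Y_clean||_F / ||noise||_F = 10^(snr_db/20),
  enforced exactly per trial by scaling the noise draw;
* ground-truth rows sorted lexicographically by (x, y, z) so regression
  targets are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .forward import SensorArray, SphereModel, lead_field_grid

__all__ = [
    "SourceSpace",
    "MEGSample",
    "StreamConfig",
    "build_source_space",
    "generate_timecourses",
    "synthesize",
    "add_noise",
    "make_sample",
    "batch_stream",
    "grid_topographies",
    "canonical_order",
]


@dataclass(frozen=True)
class SourceSpace:
    """Candidate dipole grid: locations (m) and fixed tangential moment directions."""

    points: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if pts.shape != ori.shape or pts.shape[1] != 3:
            raise ValueError("points and orientations must both be (n, 3)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class MEGSample:
    """One simulated trial: measurements plus ground truth."""

    Y: np.ndarray  # (M, N)
    true_locations: np.ndarray  # (Q, 3), canonical order
    true_orientations: np.ndarray  # (Q, 3)
    snr_db: float
    rho: float
    seed_record: tuple[int, ...] = ()
    grid_indices: tuple[int, ...] = ()


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tangential_orientation(radial: np.ndarray) -> np.ndarray:
    """Deterministic unit tangent per radial direction (east-pointing; x-fallback at poles)."""
    zhat = np.array([0.0, 0.0, 1.0])
    t = np.cross(zhat, radial)
    norms = np.linalg.norm(t, axis=1)
    polar = norms < 1e-12
    if np.any(polar):
        t[polar] = np.cross(np.array([1.0, 0.0, 0.0]), radial[polar])
        norms = np.linalg.norm(t, axis=1)
    return t / norms[:, None]


def build_source_space(
    sphere: SphereModel,
    n_points: int = 2000,
    shell_radius_fraction: float = 0.8,
) -> SourceSpace:
    """Quasi-uniform Fibonacci lattice on a shell at ``shell_radius_fraction * R``.

    A spherical-shell stand-in for a cortical surface grid.  Moment
    directions are deterministic unit tangents — radial moments are
    magnetically silent in the sphere model, so only tangential sources
    are observable.
    """
    if not 0 < shell_radius_fraction < 1:
        raise ValueError("shell_radius_fraction must lie in (0, 1)")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    radial = _fibonacci_sphere(n_points)
    points = sphere.center + shell_radius_fraction * sphere.radius * radial
    return SourceSpace(points=points, orientations=_tangential_orientation(radial))


def generate_timecourses(
    q: int,
    n: int,
    rho: float,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (10.0, 90.0),
    fs: float = 1000.0,
    n_sinusoids: int = 3,
    max_retries: int = 50,
) -> np.ndarray:
    """Q x N source time courses with exact pairwise Pearson correlation ``rho``.

    Each row starts as an equal-amplitude mixture of ``n_sinusoids``
    random-frequency, random-phase sinusoids.  For Q >= 2 the rows are
    mean-centered, orthonormalized (Gram-Schmidt over the N samples) and
    mixed with the Cholesky factor of the Q x Q equicorrelation matrix,
    which pins every pairwise sample correlation to rho exactly.  Rows
    are returned unit-norm.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if not 0.0 <= rho <= 0.9:
        raise ValueError("rho must lie in [0, 0.9]")
    if q >= 2 and n < 2:
        raise ValueError("sample correlation is undefined for N < 2")
    if q >= 2 and rho <= -1.0 / (q - 1):
        raise ValueError(f"equicorrelation rho={rho} infeasible for q={q}")

    def draw() -> np.ndarray:
        freqs = rng.uniform(*freq_range, size=(q, n_sinusoids))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(q, n_sinusoids))
        t = np.arange(n) / fs
        s = np.sin(2.0 * np.pi * freqs[..., None] * t + phases[..., None]).sum(axis=1)
        return s  # (q, n)

    if q == 1:
        s = draw()
        return s / np.linalg.norm(s)

    for _ in range(max_retries):
        s = draw()
        sc = s - s.mean(axis=1, keepdims=True)
        # Gram-Schmidt over rows; a degenerate draw (near-collinear rows) is redrawn
        basis = []
        ok = True
        for row in sc:
            v = row.copy()
            for b in basis:
                v -= (v @ b) * b
            nv = np.linalg.norm(v)
            if nv < 1e-8 * np.linalg.norm(row):
                ok = False
                break
            basis.append(v / nv)
        if not ok:
            continue
        B = np.asarray(basis)  # (q, n), orthonormal zero-mean rows
        C = np.full((q, q), rho) + (1.0 - rho) * np.eye(q)
        Lc = np.linalg.cholesky(C)
        S = Lc @ B  # rows have unit norm, zero mean, pairwise correlation rho
        return S / np.linalg.norm(S, axis=1, keepdims=True)
    raise RuntimeError(f"could not draw non-degenerate time courses after {max_retries} tries")


def synthesize(A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Noiseless measurements Y = A @ S."""
    A = np.asarray(A, dtype=float)
    S = np.asarray(S, dtype=float)
    if A.ndim != 2 or S.ndim != 2 or A.shape[1] != S.shape[0]:
        raise ValueError(f"shape mismatch: A is {A.shape}, S is {S.shape}")
    return A @ S


def add_noise(
    y_clean: np.ndarray, snr_db: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Add white Gaussian noise scaled for an exact Frobenius-norm SNR.

    Returns ``(y_clean + noise, noise)`` with
    ``||y_clean||_F / ||noise||_F == 10**(snr_db / 20)`` exactly (the
    noise draw is rescaled per call, so the stated SNR holds per trial,
    not merely in expectation).
    """
    y_clean = np.asarray(y_clean, dtype=float)
    sig = np.linalg.norm(y_clean)
    if sig == 0.0:
        raise ValueError("SNR undefined for an all-zero clean measurement")
    noise = rng.standard_normal(y_clean.shape)
    noise *= sig / (10.0 ** (snr_db / 20.0) * np.linalg.norm(noise))
    return y_clean + noise, noise


def canonical_order(locations: np.ndarray) -> np.ndarray:
    """Indices sorting rows lexicographically by (x, y, z)."""
    loc = np.atleast_2d(locations)
    return np.lexsort((loc[:, 2], loc[:, 1], loc[:, 0]))


def grid_topographies(
    space: SourceSpace, sensors: SensorArray, sphere: SphereModel
) -> np.ndarray:
    """(n_grid, M) topographies of unit moments along the grid's fixed orientations."""
    L = lead_field_grid(space.points, sensors, sphere)  # (n, M, 3)
    return np.einsum("nmk,nk->nm", L, space.orientations)


def _source_amplitudes(
    q: int, n: int, rho: float, rng: np.random.Generator, fs: float
) -> tuple[np.ndarray, float]:
    """Time courses for a trial; N=1 degenerates to unit-magnitude random signs."""
    if n == 1:
        s = rng.choice([-1.0, 1.0], size=(q, 1))
        return s, float("nan")
    return generate_timecourses(q, n, rho, rng, fs=fs), rho


def make_sample(
    space: SourceSpace,
    sensors: SensorArray,
    sphere: SphereModel,
    q: int,
    snr_db: float,
    rho: float,
    n_times: int,
    rng: np.random.Generator,
    topographies: np.ndarray | None = None,
    seed_record: tuple[int, ...] = (),
) -> MEGSample:
    """Simulate one labeled trial: Q random grid dipoles, time courses, noise."""
    if q > space.n_points:
        raise ValueError(f"cannot draw {q} distinct sources from {space.n_points} grid points")
    if topographies is None:
        topographies = grid_topographies(space, sensors, sphere)
    idx = rng.choice(space.n_points, size=q, replace=False)
    S, rho_eff = _source_amplitudes(q, n_times, rho, rng, fs=1000.0)
    y_clean = synthesize(topographies[idx].T, S)
    Y, _ = add_noise(y_clean, snr_db, rng)
    order = canonical_order(space.points[idx])
    return MEGSample(
        Y=Y,
        true_locations=space.points[idx][order],
        true_orientations=space.orientations[idx][order],
        snr_db=snr_db,
        rho=rho_eff,
        seed_record=seed_record,
        grid_indices=tuple(int(i) for i in idx[order]),
    )


@dataclass(frozen=True)
class StreamConfig:
    """On-the-fly batch generation settings."""

    batch_size: int = 32
    q: int = 1
    n_times: int = 1
    snr_db: float = 10.0
    rho: float | str = 0.0  # a float, or "uniform" for rho ~ U[0, 0.9] per trial
    fs: float = 1000.0
    rho_max: float = 0.9

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.q < 1 or self.n_times < 1:
            raise ValueError("q and n_times must be >= 1")
        if isinstance(self.rho, str) and self.rho != "uniform":
            raise ValueError("rho must be a float or 'uniform'")


def _batch_timecourses(
    batch: int, q: int, n: int, rho: np.ndarray, rng: np.random.Generator,
    fs: float, freq_range: tuple[float, float] = (10.0, 90.0), n_sinusoids: int = 3,
) -> np.ndarray:
    """Vectorized equivalent of :func:`generate_timecourses` for a whole batch."""
    freqs = rng.uniform(*freq_range, size=(batch, q, n_sinusoids))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(batch, q, n_sinusoids))
    t = np.arange(n) / fs
    s = np.sin(2.0 * np.pi * freqs[..., None] * t + phases[..., None]).sum(axis=2)
    if q == 1:
        return s / np.linalg.norm(s, axis=2, keepdims=True)
    s -= s.mean(axis=2, keepdims=True)
    # batched Gram-Schmidt over the q rows of every sample
    B = np.empty_like(s)
    for i in range(q):
        v = s[:, i].copy()
        for j in range(i):
            v -= np.einsum("bn,bn->b", v, B[:, j])[:, None] * B[:, j]
        B[:, i] = v / np.linalg.norm(v, axis=1, keepdims=True)
    C = rho[:, None, None] * np.ones((q, q)) + (1.0 - rho)[:, None, None] * np.eye(q)
    Lc = np.linalg.cholesky(C)
    S = np.einsum("bij,bjn->bin", Lc, B)
    return S / np.linalg.norm(S, axis=2, keepdims=True)


def batch_stream(
    space: SourceSpace,
    sensors: SensorArray,
    sphere: SphereModel,
    config: StreamConfig,
    master_seed: int,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Endless deterministic stream of freshly simulated (inputs, labels) batches.

    Inputs have shape (batch, M) for single snapshots or (batch, M, N)
    otherwise; labels are flattened canonical-order coordinates
    (batch, 3Q) in meters.  The whole stream is a pure function of
    ``master_seed``.  Generation is batch-vectorized (the per-trial
    construction of :func:`make_sample`, applied to all trials at once),
    which is what makes on-the-fly training practical.
    """
    topo = grid_topographies(space, sensors, sphere)
    rng = np.random.default_rng(master_seed)
    m = sensors.n_sensors
    bsz, q, n = config.batch_size, config.q, config.n_times
    if q > space.n_points:
        raise ValueError(f"cannot draw {q} distinct sources from {space.n_points} grid points")
    while True:
        rho = (
            rng.uniform(0.0, config.rho_max, size=bsz)
            if config.rho == "uniform"
            else np.full(bsz, float(config.rho))
        )
        # q distinct grid indices per trial
        idx = np.argpartition(rng.random((bsz, space.n_points)), q, axis=1)[:, :q]
        if n == 1:
            S = rng.choice([-1.0, 1.0], size=(bsz, q, 1))
        else:
            S = _batch_timecourses(bsz, q, n, rho, rng, config.fs)
        y_clean = np.einsum("bqm,bqn->bmn", topo[idx], S)
        noise = rng.standard_normal((bsz, m, n))
        sig = np.linalg.norm(y_clean, axis=(1, 2))
        noise *= (sig / (10.0 ** (config.snr_db / 20.0) * np.linalg.norm(noise, axis=(1, 2))))[
            :, None, None
        ]
        X = y_clean + noise
        labels = np.empty((bsz, 3 * q))
        for b in range(bsz):
            pts = space.points[idx[b]]
            labels[b] = pts[canonical_order(pts)].ravel()
        yield (X[:, :, 0] if n == 1 else X), labels
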