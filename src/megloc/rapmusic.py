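"""RAP-MUSIC scanning localizer.

The MUSIC family localizes dipoles by scanning a source grid for
locations whose lead-field column space is maximally correlated with
the signal subspace of the data.  The recursive variant implemented
here finds one source per iteration: after each find, the topography of
the found dipole is projected out of both the signal subspace and every
candidate lead field, turning the hard problem of picking several local
maxima into a sequence of global-maximum searches.

Numerical choices:

* the signal subspace comes from a direct SVD of the data matrix (not
  an explicitly formed covariance) — safer for short windows where
  N << M; a single snapshot degenerates to the rank-1 span of the data
  vector itself;
* spherical-conductor lead fields have effective rank 2 (the radial
  moment is silent), so orthonormalization truncates singular values
  below 1e-10 of the largest and canonical correlations are computed in
  the reduced basis;
* grid argmax ties break to the lowest index, making scans
  deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import SourceSpace

__all__ = [
    "SignalSubspace",
    "FoundDipole",
    "ScanResult",
    "signal_subspace",
    "prepare_lead_fields",
    "PreparedLeadFields",
    "subspace_correlation",
    "rap_music_scan",
]

RANK_TOL = 1e-10  # relative singular-value cutoff for lead-field rank


@dataclass(frozen=True)
class SignalSubspace:
    basis: np.ndarray  # (M, k) orthonormal columns
    singular_values: np.ndarray  # all singular values of the data matrix


@dataclass(frozen=True)
class FoundDipole:
    grid_index: int
    location: np.ndarray
    orientation: np.ndarray
    subcorr: float


@dataclass(frozen=True)
class ScanResult:
    dipoles: tuple[FoundDipole, ...]  # discovery order
    localizer: np.ndarray  # (steps, n_grid) subcorr values per recursion step

    @property
    def locations(self) -> np.ndarray:
        return np.array([d.location for d in self.dipoles])


def signal_subspace(y: np.ndarray, q: int) -> SignalSubspace:
    """Top-q left singular vectors of the data matrix Y (M x N)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    m, n = y.shape
    if q > min(m, n):
        raise ValueError(f"q={q} exceeds min(M, N)={min(m, n)}")
    u, s, _ = np.linalg.svd(y, full_matrices=False)
    rank = int(np.sum(s > RANK_TOL * s[0])) if s[0] > 0 else 0
    if rank < q:
        warnings.warn(
            f"data matrix has numerical rank {rank} < q={q}; "
            "using the available signal subspace",
            stacklevel=2,
        )
        q = max(rank, 1)
    return SignalSubspace(basis=u[:, :q], singular_values=s)


def _orth_columns(L: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-truncated SVD of L: (U_r, s_r, V_r) with s above RANK_TOL * s_max."""
    u, s, vt = np.linalg.svd(L, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return u[:, :0], s[:0], vt[:0].T
    keep = s > RANK_TOL * s[0]
    return u[:, keep], s[keep], vt[keep].T


def subspace_correlation(
    L: np.ndarray, subspace: np.ndarray
) -> tuple[float, np.ndarray]:
    """Largest canonical correlation between span(L) and the signal subspace.

    Returns ``(subcorr, orientation)`` where the orientation is the unit
    moment vector whose topography ``L @ q`` achieves it.  A zero lead
    field yields subcorr 0 with a zero orientation flag.
    """
    L = np.asarray(L, dtype=float)
    U = np.asarray(subspace, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    ul, s, v = _orth_columns(L)
    if ul.shape[1] == 0:
        return 0.0, np.zeros(L.shape[1])
    c = ul.T @ U  # (r, k)
    uc, sc, _ = np.linalg.svd(c, full_matrices=False)
    subcorr = float(min(sc[0], 1.0)) if sc.size else 0.0
    # moment achieving the max: map the optimal direction in the reduced
    # basis back through the (truncated) pseudo-inverse of L
    q = v @ (uc[:, 0] / s)
    nq = np.linalg.norm(q)
    orientation = q / nq if nq > 0 else np.zeros(L.shape[1])
    return subcorr, orientation


@dataclass(frozen=True)
class PreparedLeadFields:
    """Per-grid precomputation that amortizes scanning across trials.

    ``tangent`` holds the two principal (non-silent) moment directions of
    every lead field; in the sphere model the third direction is the
    radial one and carries no field.  ``gram2`` is the 2x2 Gram of the
    lead field in that basis.  ``full_rank`` flags grids whose lead
    fields genuinely have rank 3 (e.g. imported realistic models), for
    which the scan falls back to the general SVD path.
    """

    G: np.ndarray  # (n, M, 3)
    tangent: np.ndarray  # (n, 3, 2)
    reduced: np.ndarray  # (n, M, 2) lead fields in the tangent basis
    gram2: np.ndarray  # (n, 2, 2)
    full_rank: bool


def prepare_lead_fields(G: np.ndarray) -> PreparedLeadFields:
    G = np.asarray(G, dtype=float)
    gram = np.einsum("nmi,nmj->nij", G, G)
    w, v = np.linalg.eigh(gram)  # ascending
    full_rank = bool(np.any(w[:, 0] > 1e-9 * np.maximum(w[:, 2], 1e-300)))
    tangent = v[:, :, [2, 1]]
    reduced = np.einsum("nmi,nij->nmj", G, tangent)
    gram2 = np.einsum("nmi,nmj->nij", reduced, reduced)
    return PreparedLeadFields(
        G=G, tangent=tangent, reduced=reduced, gram2=gram2, full_rank=full_rank
    )


def _eigh2(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closed-form eigendecomposition of symmetric 2x2 [[a, b], [b, c]] batches.

    Returns eigenvalues (l1 >= l2) and the orthonormal eigenvectors as
    column stacks; robust to b = 0 via norm-based branch selection.
    """
    tr = a + c
    disc = np.sqrt((a - c) ** 2 + 4.0 * b * b)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    # eigenvector for l1: (b, l1-a) or (l1-c, b), whichever is better conditioned
    v1x = np.where(np.abs(b) + np.abs(l1 - a) >= np.abs(l1 - c) + np.abs(b), b, l1 - c)
    v1y = np.where(np.abs(b) + np.abs(l1 - a) >= np.abs(l1 - c) + np.abs(b), l1 - a, b)
    norm = np.hypot(v1x, v1y)
    deg = norm < 1e-300
    v1x = np.where(deg, 1.0, v1x / np.where(deg, 1.0, norm))
    v1y = np.where(deg, 0.0, v1y / np.where(deg, 1.0, norm))
    # second eigenvector is the perpendicular
    return l1, l2, v1x, v1y


def _batch_subcorr_tangent(
    A2: np.ndarray, C2: np.ndarray, rel_tol: float = 1e-12
) -> np.ndarray:
    """Largest canonical correlation per point from 2x2 reduced matrices.

    ``A2`` is the (projected) lead-field Gram in the tangent basis,
    ``C2`` the (n, 2, k) cross-products with the projected signal
    subspace.  Solves max_q (q^T C2 C2^T q) / (q^T A2 q) by whitening
    A2 with its closed-form eigendecomposition; directions whose Gram
    eigenvalue falls below ``rel_tol`` of the largest (out-projected or
    silent) are dropped.
    """
    a, b, c = A2[:, 0, 0], A2[:, 0, 1], A2[:, 1, 1]
    l1, l2, v1x, v1y = _eigh2(a, b, c)
    lmax = np.maximum(l1, 1e-300)
    keep1 = l1 > 0
    keep2 = l2 > rel_tol * lmax
    # whitened direction vectors (2-vectors), zeroed when dropped
    w1 = np.where(keep1, 1.0 / np.sqrt(np.where(keep1, l1, 1.0)), 0.0)
    w2 = np.where(keep2, 1.0 / np.sqrt(np.where(keep2, l2, 1.0)), 0.0)
    u1 = np.stack([v1x, v1y], axis=1) * w1[:, None]  # (n, 2)
    u2 = np.stack([-v1y, v1x], axis=1) * w2[:, None]
    p1 = np.einsum("ni,nik->nk", u1, C2)  # (n, k)
    p2 = np.einsum("ni,nik->nk", u2, C2)
    m11 = np.einsum("nk,nk->n", p1, p1)
    m12 = np.einsum("nk,nk->n", p1, p2)
    m22 = np.einsum("nk,nk->n", p2, p2)
    lam, _, _, _ = _eigh2(m11, m12, m22)
    return np.sqrt(np.clip(lam, 0.0, 1.0))


def _batch_orth(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched rank-truncated orthonormalization of (n, M, 3) lead fields.

    Via eigendecomposition of the 3x3 Gram matrices (fast for thousands
    of grid points).  Columns below the rank cutoff are zeroed, so they
    contribute nothing to subsequent correlations.
    """
    gram = np.einsum("nmi,nmj->nij", G, G)
    w, v = np.linalg.eigh(gram)  # ascending eigenvalues
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    s = np.sqrt(np.clip(w, 0.0, None))  # singular values of G, descending
    smax = s[:, :1]
    keep = s > RANK_TOL * np.where(smax > 0, smax, 1.0)
    s_safe = np.where(keep, s, 1.0)
    U = np.einsum("nmi,nij->nmj", G, v) / s_safe[:, None, :]
    U *= keep[:, None, :]
    return U, np.where(keep, s, 0.0), v


def _batch_subcorr(U: np.ndarray, subspace: np.ndarray) -> np.ndarray:
    """Max canonical correlation per grid point; U is (n, M, 3) zero-padded orthonormal."""
    c = np.einsum("nmk,ms->nks", U, subspace)  # (n, 3, k)
    gram = np.einsum("nks,nls->nkl", c, c)
    w = np.linalg.eigvalsh(gram)[:, -1]
    return np.sqrt(np.clip(w, 0.0, 1.0))


def rap_music_scan(
    y: np.ndarray,
    source_space: SourceSpace,
    lead_field_provider,
    q: int,
    lead_fields: np.ndarray | None = None,
) -> ScanResult:
    """Recursively locate ``q`` dipoles on the grid.

    ``lead_field_provider`` maps grid points to (n, M, 3) lead fields.
    Pass precomputed lead fields — raw arrays or, faster, the output of
    :func:`prepare_lead_fields` — to amortize the forward model and its
    tangent-basis reduction across Monte-Carlo trials.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if source_space.n_points < 1:
        raise ValueError("empty source grid")
    if isinstance(lead_fields, PreparedLeadFields):
        prep = lead_fields
    else:
        G = lead_fields if lead_fields is not None else lead_field_provider(source_space.points)
        prep = prepare_lead_fields(G)
    G = prep.G
    y2 = np.asarray(y, dtype=float)
    if y2.ndim == 1:
        y2 = y2[:, None]
    # a short window (or single snapshot) caps the subspace rank below q;
    # the recursion still extracts q dipoles by out-projection
    subspace = signal_subspace(y2, min(q, *y2.shape)).basis

    found: list[FoundDipole] = []
    localizer_steps: list[np.ndarray] = []
    topos: list[np.ndarray] = []  # original (unprojected) topographies of found dipoles
    sub_p = subspace
    qa = None
    for _ in range(q):
        if topos:
            qa, _ = np.linalg.qr(np.column_stack(topos))
            proj = subspace - qa @ (qa.T @ subspace)
            # re-orthonormalize the projected subspace, dropping collapsed directions
            u, s, _ = np.linalg.svd(proj, full_matrices=False)
            keep = s > RANK_TOL * (s[0] if s.size and s[0] > 0 else 1.0)
            sub_p = u[:, keep]
            if sub_p.shape[1] == 0:
                warnings.warn(
                    f"projected signal subspace collapsed after {len(found)} of {q} sources; "
                    "stopping early",
                    stacklevel=2,
                )
                break
        if prep.full_rank:
            # general path: project and re-orthonormalize every lead field
            if qa is not None:
                tmp = np.einsum("mr,nmk->nrk", qa, G)
                Gp = G - np.einsum("mr,nrk->nmk", qa, tmp)
            else:
                Gp = G
            U, _, _ = _batch_orth(Gp)
            sc = _batch_subcorr(U, sub_p)
        else:
            # tangent-reduced path: rank-one Gram updates + closed-form 2x2
            # generalized Rayleigh quotients (note sub_p is orthogonal to the
            # out-projected topographies, so reduced^T sub_p needs no update)
            if qa is not None:
                x2 = np.einsum("nmj,mr->njr", prep.reduced, qa)
                A2 = prep.gram2 - np.einsum("njr,nkr->njk", x2, x2)
            else:
                A2 = prep.gram2
            C2 = np.einsum("nmj,ms->njs", prep.reduced, sub_p)
            sc = _batch_subcorr_tangent(A2, C2)
        localizer_steps.append(sc)
        best = int(np.argmax(sc))  # ties break to the lowest grid index
        Gp_best = G[best] if qa is None else G[best] - qa @ (qa.T @ G[best])
        subcorr, orientation = subspace_correlation(Gp_best, sub_p)
        topo = G[best] @ orientation
        topos.append(topo)
        found.append(
            FoundDipole(
                grid_index=best,
                location=source_space.points[best].copy(),
                orientation=orientation,
                subcorr=subcorr,
            )
        )
    return ScanResult(dipoles=tuple(found), localizer=np.array(localizer_steps))
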