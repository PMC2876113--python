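"""Geometric morphometrics of landmark configurations.

Generalized Procrustes analysis (GPA) removes position, scale and
orientation (rotation only — reflections are not allowed, and configurations
needing one to fit are flagged); shape variables are partial-warp scores
(principal-warp projections of the tangent-space residuals) plus the uniform
(affine) component, 2k-4 variables for k 2-D landmarks; group discrimination
uses Mahalanobis distances under the pooled within-group covariance with
label-permutation tests and resubstitution reclassification scores
(leave-one-out available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panels import DistanceMatrix, LandmarkPanel

__all__ = ["ProcrustesResult", "ShapeVariables", "CVAResult",
           "gpa", "partial_warps", "mahalanobis_cva"]


@dataclass
class ProcrustesResult:
    aligned: np.ndarray          # (n, k, 2)
    consensus: np.ndarray        # (k, 2), centred, unit centroid size
    centroid_sizes: np.ndarray   # (n,)
    iterations: int
    final_change: float
    poor_fit: list[int] = field(default_factory=list)  # reflection-limited


@dataclass
class ShapeVariables:
    scores: np.ndarray           # (n, 2k-4)
    basis: np.ndarray            # (2k, 2k-4) orthonormal tangent-space basis
    reference: np.ndarray        # consensus shape (k, 2)
    n_nonuniform: int
    n_uniform: int = 2


@dataclass
class CVAResult:
    groups: list[str]
    d_matrix: DistanceMatrix
    p_matrix: np.ndarray
    reclassified: dict[str, tuple[int, int]]   # group -> (correct, total)
    n_perm: int
    seed: int


def _center_and_scale(cfg: np.ndarray) -> tuple[np.ndarray, float]:
    centred = cfg - cfg.mean(axis=0)
    size = np.sqrt((centred ** 2).sum())
    if size == 0:
        raise ValueError("degenerate (all-coincident) configuration")
    return centred / size, size


def _optimal_rotation(cfg: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det = +1) best superimposing cfg onto target."""
    u, _, vt = np.linalg.svd(cfg.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


def gpa(panel: LandmarkPanel, tol: float = 1e-8,
        max_iter: int = 100) -> ProcrustesResult:
    """Iterative generalized Procrustes alignment."""
    n, k = panel.n, panel.k
    aligned = np.empty_like(panel.configs)
    sizes = np.empty(n)
    for i in range(n):
        aligned[i], sizes[i] = _center_and_scale(panel.configs[i])
    consensus, _ = _center_and_scale(aligned[0])
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new_consensus, _ = _center_and_scale(aligned.mean(axis=0))
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            break
    # flag poorly fitting configurations: far from the consensus in shape
    # space (e.g. digitized mirror-imaged, since reflections are not allowed)
    # or fitted much better by their reflection
    poor = []
    for i in range(n):
        res = ((aligned[i] - consensus) ** 2).sum()
        flipped = aligned[i] * np.array([1.0, -1.0])
        flipped -= flipped.mean(axis=0)
        flipped = flipped @ _optimal_rotation(flipped, consensus)
        flipped_res = ((flipped - consensus) ** 2).sum()
        if res > 0.09 or flipped_res < 0.25 * res:   # distance > 0.3
            poor.append(i)
    return ProcrustesResult(aligned=aligned, consensus=consensus,
                            centroid_sizes=sizes, iterations=it,
                            final_change=change, poor_fit=poor)


def _bending_energy(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of the reference shape."""
    k = reference.shape[0]
    d2 = ((reference[:, None, :] - reference[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(d2 > 0, d2 * np.log(d2), 0.0)  # r^2 log r^2
    Q = np.hstack([np.ones((k, 1)), reference])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = S
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular bending-energy system "
                         "(collinear landmarks)") from exc
    return Linv[:k, :k]


def partial_warps(proc: ProcrustesResult) -> ShapeVariables:
    """Partial-warp scores (nonuniform) plus the uniform component.

    The 2k-4-dimensional tangent space at the consensus is split into
    2(k-3) nonuniform directions (principal warps of the bending-energy
    matrix, applied to x and y) and the 2-dimensional uniform complement;
    residuals are projected onto an orthonormal basis of that space, so the
    score-vector norm equals the tangent-space Procrustes distance.
    """
    ref = proc.consensus
    k = ref.shape[0]
    if k < 4:
        raise ValueError("need k >= 4 landmarks")
    be = _bending_energy(ref)
    eigval, eigvec = np.linalg.eigh(be)
    nonzero = eigval > 1e-10 * eigval.max()
    warps = eigvec[:, nonzero]                      # (k, k-3)
    n_nonuniform = 2 * warps.shape[1]

    # similarity subspace at the reference: translations, rotation, scale
    ones = np.ones(k)
    zero = np.zeros(k)
    tx = np.stack([ones, zero], axis=1).ravel()
    ty = np.stack([zero, ones], axis=1).ravel()
    sc = ref.ravel()
    rot = np.stack([-ref[:, 1], ref[:, 0]], axis=1).ravel()
    sim = np.stack([tx, ty, sc, rot], axis=1)

    nonuni = np.zeros((2 * k, n_nonuniform))
    for j in range(warps.shape[1]):
        vx = np.stack([warps[:, j], zero], axis=1).ravel()
        vy = np.stack([zero, warps[:, j]], axis=1).ravel()
        nonuni[:, 2 * j] = vx
        nonuni[:, 2 * j + 1] = vy
    # orthonormalize the nonuniform block within the tangent space
    sim_q, _ = np.linalg.qr(sim)
    nonuni -= sim_q @ (sim_q.T @ nonuni)
    nonuni_q, _ = np.linalg.qr(nonuni)
    # uniform component: orthogonal complement of similarity + nonuniform
    span = np.hstack([sim_q, nonuni_q])
    u, s, _ = np.linalg.svd(span, full_matrices=True)
    null_dim = 2 * k - span.shape[1]
    uniform_q = u[:, span.shape[1]:]
    assert uniform_q.shape[1] == null_dim == 2
    basis = np.hstack([nonuni_q, uniform_q])        # (2k, 2k-4)

    resid = (proc.aligned - ref).reshape(proc.aligned.shape[0], 2 * k)
    # project residuals into the tangent space before scoring
    resid -= resid @ sim_q @ sim_q.T
    scores = resid @ basis
    return ShapeVariables(scores=scores, basis=basis, reference=ref,
                          n_nonuniform=n_nonuniform)


# --------------------------------------------------------------------------
# discriminant analysis
# --------------------------------------------------------------------------

def _pooled_cov(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    groups = np.unique(labels)
    p = X.shape[1]
    S = np.zeros((p, p))
    dof = 0
    for g in groups:
        sub = X[labels == g]
        if len(sub) < 2:
            continue
        S += (len(sub) - 1) * np.cov(sub, rowvar=False)
        dof += len(sub) - 1
    return S / dof


def _mahalanobis(mean_a, mean_b, S_inv) -> float:
    d = mean_a - mean_b
    return float(np.sqrt(d @ S_inv @ d))


def mahalanobis_cva(shape: ShapeVariables | np.ndarray, groups,
                    n_perm: int = 1000, seed: int = 0,
                    leave_one_out: bool = False) -> CVAResult:
    """Pairwise Mahalanobis distances, permutation P-values and
    reclassification scores on shape-variable scores.

    The permutation test for each pair permutes only the two groups'
    individuals. Reclassification assigns each individual to the group with
    the smallest Mahalanobis distance (resubstitution by default).
    """
    X = shape.scores if isinstance(shape, ShapeVariables) else np.asarray(shape)
    labels = np.asarray(groups)
    names = [g for g in dict.fromkeys(labels.tolist())]
    sizes = {g: int((labels == g).sum()) for g in names}
    kept = [g for g in names if sizes[g] >= 2]
    dropped = [g for g in names if sizes[g] < 2]
    if dropped:
        import warnings
        warnings.warn(f"groups of size 1 excluded: {dropped}")
        mask = np.isin(labels, kept)
        X, labels = X[mask], labels[mask]
    names = kept
    m = len(names)
    rng = np.random.default_rng(seed)

    S = _pooled_cov(X, labels)
    S_inv = _safe_inverse(S)
    means = {g: X[labels == g].mean(axis=0) for g in names}
    D = np.zeros((m, m))
    P = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = names[i], names[j]
            D[i, j] = D[j, i] = _mahalanobis(means[a], means[b], S_inv)
            # pairwise permutation using the two groups only
            pair_mask = np.isin(labels, (a, b))
            Xp = X[pair_mask]
            lp = (labels[pair_mask] == b).astype(int)
            obs = _pair_d2(Xp, lp)
            cnt = 0
            for _ in range(n_perm):
                null = _pair_d2(Xp, rng.permutation(lp))
                if null >= obs:
                    cnt += 1
            P[i, j] = P[j, i] = (cnt + 1) / (n_perm + 1)

    # reclassification
    correct = {g: 0 for g in names}
    totals = {g: 0 for g in names}
    for idx in range(len(X)):
        if leave_one_out:
            keep = np.arange(len(X)) != idx
            S_i = _safe_inverse(_pooled_cov(X[keep], labels[keep]))
            mns = {g: X[keep][labels[keep] == g].mean(axis=0) for g in names}
        else:
            S_i, mns = S_inv, means
        d = {g: _mahalanobis(X[idx], mns[g], S_i) for g in names}
        best = min(d, key=d.get)
        totals[labels[idx]] += 1
        if best == labels[idx]:
            correct[labels[idx]] += 1
    reclass = {g: (correct[g], totals[g]) for g in names}
    return CVAResult(groups=names,
                     d_matrix=DistanceMatrix(names, D, "mahalanobis"),
                     p_matrix=P, reclassified=reclass, n_perm=n_perm,
                     seed=seed)


def _pair_d2(X: np.ndarray, labels01: np.ndarray) -> float:
    """Squared Mahalanobis distance between two groups (pair-local pooled
    covariance) — the permutation statistic."""
    Xa, Xb = X[labels01 == 0], X[labels01 == 1]
    S = _pooled_cov(X, labels01)
    S_inv = _safe_inverse(S)
    d = Xa.mean(axis=0) - Xb.mean(axis=0)
    return float(d @ S_inv @ d)


def _safe_inverse(S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(S)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(S)
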