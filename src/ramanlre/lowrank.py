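"""Low-rank estimation (LRE) denoising by Frank-Wolfe iterations.

The denoiser approximates a spectral data matrix ``A`` by a low-rank
matrix ``X`` built greedily from rank-1 components.  Each iteration
estimates the leading singular triple of the residual ``A - X`` by
alternating least squares (ALS), takes the full rank-1 approximation
``sigma * u v^T`` as the search direction, moves along it with an exact
line search over step lengths in [0, 1], and updates ``X`` as a convex
combination.  Iteration stops once the residual's leading singular value
falls below ``m`` times the data's leading singular value (the low-rank
constraint factor, typically 0.001-0.01) or after ``N`` iterations
(typically 5-20).

Because noise-free Raman matrices are low rank (each spectrum is a
linear mixture of a few endmember spectra) while noise is full rank,
truncating the expansion separates signal from noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "Rank1Component",
    "LREConfig",
    "LREResult",
    "als_rank1",
    "fw_line_search",
    "lre_denoise",
    "augment_matrix",
]


@dataclasses.dataclass(frozen=True)
class Rank1Component:
    """Leading singular triple (u, v, sigma) of a matrix.

    ``left_vector`` (length n_samples) and ``right_vector`` (length
    n_channels) are unit-norm whenever ``singular_value > 0``; as a
    matrix the component is ``singular_value * outer(u, v)``.
    """

    left_vector: np.ndarray
    right_vector: np.ndarray
    singular_value: float

    def as_matrix(self) -> np.ndarray:
        return self.singular_value * np.outer(self.left_vector, self.right_vector)


@dataclasses.dataclass(frozen=True)
class LREConfig:
    """Tunables of the Frank-Wolfe denoiser.

    ``max_iterations`` caps the number of rank-1 components (paper-style
    range 5-20); ``constraint_factor`` m stops iteration once the residual's
    leading singular value drops below m * sigma_1(A) (range 0.001-0.01).
    ``update_mode='additive'`` replaces the convex combination by
    ``X + r*s``, which does not shrink previously added components.
    """

    max_iterations: int = 20
    constraint_factor: float = 0.005
    als_tolerance: float = 1e-10
    als_max_inner: int = 500
    update_mode: str = "convex"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.constraint_factor > 0:
            raise ValueError("constraint_factor must be > 0")
        if not self.als_tolerance > 0:
            raise ValueError("als_tolerance must be > 0")
        if self.update_mode not in ("convex", "additive"):
            raise ValueError("update_mode must be 'convex' or 'additive'")


@dataclasses.dataclass
class LREResult:
    """Denoised matrix plus the per-iteration trace.

    ``residual_norms`` holds Frobenius norms ``||A - X^i||_F`` starting
    with ``||A||_F`` for the zero initialization, so it has length
    ``iterations_run + 1`` and is non-increasing.  ``stop_reason`` is
    ``'criterion'`` (residual singular value fell below the constraint),
    ``'max_iter'``, or ``'stalled'`` (the line search returned a zero
    step, a Frank-Wolfe fixed point that no further iteration can leave).
    """

    denoised: np.ndarray
    iterations_run: int
    residual_norms: np.ndarray
    step_lengths: np.ndarray
    components: list[Rank1Component]
    stop_reason: str

    def to_trace_dict(self) -> dict:
        """JSON-serializable diagnostics (no matrices)."""
        return {
            "iterations_run": self.iterations_run,
            "residual_norms": [float(x) for x in self.residual_norms],
            "step_lengths": [float(x) for x in self.step_lengths],
            "singular_values": [float(c.singular_value) for c in self.components],
            "stop_reason": self.stop_reason,
        }


def _validate_finite(name: str, m: np.ndarray) -> np.ndarray:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains NaN or Inf")
    return m


def als_rank1(
    matrix: np.ndarray,
    tolerance: float = 1e-10,
    max_inner: int = 500,
    seed: int = 0,
) -> Rank1Component:
    """Estimate the leading singular triple of ``matrix`` by ALS.

    The two factors are solved for alternately, each by least squares
    with the other held fixed, which for a rank-1 fit reduces to
    ``u <- Mv/||Mv||``, ``v <- M^T u/||M^T u||``, ``sigma <- u^T M v``,
    repeated until the relative change in sigma drops below
    ``tolerance`` or ``max_inner`` sweeps.  The right vector starts from
    the channel-wise mean of ``|M|`` (the all-positive leading component
    of spectra), with a seeded random fallback if that mean is zero, so
    the routine is deterministic for a given seed.

    Sign convention: the largest-magnitude entry of the right vector is
    made positive.  The zero matrix yields ``sigma = 0`` with arbitrary
    unit vectors.
    """
    m = _validate_finite("matrix", matrix)
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    n, c = m.shape
    if not np.any(m):
        u = np.zeros(n)
        u[0] = 1.0
        v = np.zeros(c)
        v[0] = 1.0
        return Rank1Component(u, v, 0.0)

    v = np.mean(np.abs(m), axis=0)
    nv = np.linalg.norm(v)
    if nv == 0.0:
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(c)
        nv = np.linalg.norm(v)
    v = v / nv

    sigma = 0.0
    u = np.zeros(n)
    for _ in range(int(max_inner)):
        mv = m @ v
        norm_mv = np.linalg.norm(mv)
        if norm_mv == 0.0:
            # v landed exactly in the null space; restart from random
            rng = np.random.default_rng(seed + 1)
            v = rng.standard_normal(c)
            v /= np.linalg.norm(v)
            continue
        u = mv / norm_mv
        mtu = m.T @ u
        norm_mtu = np.linalg.norm(mtu)
        v = mtu / norm_mtu
        new_sigma = float(u @ (m @ v))
        if sigma > 0 and abs(new_sigma - sigma) <= tolerance * abs(new_sigma):
            sigma = new_sigma
            break
        sigma = new_sigma

    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
        u = -u
    return Rank1Component(u, v, float(sigma))


def fw_line_search(A: np.ndarray, X: np.ndarray, S: np.ndarray) -> float:
    """Exact step length for the Frank-Wolfe update.

    Minimizes ``||A - (X + r (S - X))||_F`` over r in [0, 1]; the
    objective is quadratic in r, so the minimizer has the closed form
    ``<A - X, S - X>_F / ||S - X||_F^2`` clipped to [0, 1].  When
    ``S == X`` the objective is constant and the tie is broken toward
    no movement (r = 0).
    """
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if A.shape != X.shape or A.shape != S.shape:
        raise ValueError("A, X, S must share a shape")
    d = S - X
    denom = float(np.sum(d * d))
    if denom == 0.0:
        return 0.0
    num = float(np.sum((A - X) * d))
    return float(np.clip(num / denom, 0.0, 1.0))


def lre_denoise(A: np.ndarray, config: LREConfig | None = None) -> LREResult:
    """Denoise a spectral matrix by greedy rank-1 Frank-Wolfe estimation.

    Starting from ``X = 0``, each iteration adds the ALS rank-1
    approximation of the residual with an exactly line-searched step in
    [0, 1] (convex update by default).  Iteration stops when the
    residual's leading singular value falls below
    ``constraint_factor * sigma_1(A)`` or at ``max_iterations``.

    The residual norm trace is non-increasing by construction: if a
    proposed step fails to lower the computed residual norm (which can
    happen only at rounding-error level), the step is rejected.

    The convex update can reach a Frank-Wolfe fixed point before either
    stopping rule fires: the line search returns exactly 0 and the
    iterate no longer moves.  Every later iteration would recompute the
    identical component and step, so the loop exits early with
    ``stop_reason='stalled'`` instead of spinning to ``max_iterations``.

    Returns an :class:`LREResult`; an all-zero input returns ``X = 0``
    with zero iterations and ``stop_reason='criterion'``.
    """
    cfg = config or LREConfig()
    A = _validate_finite("A", A)

    top = als_rank1(A, cfg.als_tolerance, cfg.als_max_inner, cfg.seed)
    sigma1 = top.singular_value
    X = np.zeros_like(A)
    norms = [float(np.linalg.norm(A))]
    steps: list[float] = []
    comps: list[Rank1Component] = []
    stop = "criterion"

    if sigma1 == 0.0:
        return LREResult(X, 0, np.asarray(norms), np.asarray(steps), comps, stop)

    stop = "max_iter"
    iterations = 0
    for i in range(cfg.max_iterations):
        comp = als_rank1(A - X, cfg.als_tolerance, cfg.als_max_inner, cfg.seed) \
            if i else top
        if comp.singular_value <= cfg.constraint_factor * sigma1:
            stop = "criterion"
            break
        S = comp.as_matrix()
        r = fw_line_search(A, X, S)
        X_new = (1.0 - r) * X + r * S if cfg.update_mode == "convex" else X + r * S
        norm_new = float(np.linalg.norm(A - X_new))
        if norm_new > norms[-1]:
            # no numerical improvement along this direction: stay put
            r, X_new, norm_new = 0.0, X, norms[-1]
        if r == 0.0:
            # fixed point: the next iteration would repeat this one exactly
            stop = "stalled"
            break
        X = X_new
        iterations += 1
        comps.append(comp)
        steps.append(r)
        norms.append(norm_new)
    else:
        # loop exhausted; check whether the criterion also just became true
        comp = als_rank1(A - X, cfg.als_tolerance, cfg.als_max_inner, cfg.seed)
        if comp.singular_value <= cfg.constraint_factor * sigma1:
            stop = "criterion"

    return LREResult(
        denoised=X,
        iterations_run=iterations,
        residual_norms=np.asarray(norms),
        step_lengths=np.asarray(steps),
        components=comps,
        stop_reason=stop,
    )


def augment_matrix(
    test_matrix: np.ndarray, donor_matrix: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack donor spectra under a small test matrix before denoising.

    A richer matrix strengthens the low-rank estimate, so when the test
    block is small the (raw) training spectra are appended below it as a
    supplement; they are used only to support the factorization and must
    be discarded afterwards.  Returns the stacked matrix and an index
    map: ``stacked[index_map]`` recovers exactly the test rows, in order.
    """
    test = np.atleast_2d(np.asarray(test_matrix, dtype=float))
    if donor_matrix is None or np.size(donor_matrix) == 0:
        return test.copy(), np.arange(test.shape[0])
    donor = np.atleast_2d(np.asarray(donor_matrix, dtype=float))
    if donor.shape[1] != test.shape[1]:
        raise ValueError(
            f"channel mismatch: test has {test.shape[1]}, donor {donor.shape[1]}"
        )
    return np.vstack([test, donor]), np.arange(test.shape[0])
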