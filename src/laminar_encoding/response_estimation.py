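"""Per-sound response estimates (betas) from run-wise BOLD time series.

The signal model is rank-1 bilinear: each voxel has one FIR hemodynamic
response (common to all sounds) and one beta per sound,

    y(t) = sum_j h_j * [sum_s beta_s stick_s(t - j)] + drift(t) + noise,

estimated by alternating least squares (ALS) between the betas (with
polynomial drift) and the FIR coefficients.  The scale/sign ambiguity of
the factorisation is resolved by constraining the HRF to unit norm with a
positive peak.  One-back repeat trials are excluded from the betas and
absorbed into a single nuisance stick column; silent trials are baseline
and carry no regressor.

Run time series are first high-pass filtered (Fourier drift components of
up to 2 cycles per run plus the constant) and temporally smoothed over 2
volumes.  Voxel selection uses the omnibus F-test of the full model
against drift-only, p < 0.05 uncorrected by default.

Estimation is vectorised across voxels by precomputing stick-matrix Gram
blocks per design, so each ALS sweep only assembles and solves small
per-voxel normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

from .encoding import FoldPlan
from .synthetic_data import BoldTimeseries, EventDesign, SILENT

__all__ = [
    "HrfEstimate",
    "VoxelResponses",
    "FoldResponses",
    "preprocess_timeseries",
    "DesignOperator",
    "estimate_hrf_and_betas",
    "betas_given_hrf",
    "estimate_fold_responses",
    "select_responsive_voxels",
]


@dataclass
class HrfEstimate:
    """Per-voxel FIR HRF over a fixed post-onset window (TR units)."""

    coefficients: np.ndarray  # (n_voxels, window)
    window: int
    converged: np.ndarray
    degenerate: np.ndarray
    n_iter: int


@dataclass
class VoxelResponses:
    """Per-sound betas (S x V) with sound bookkeeping."""

    values: np.ndarray
    sound_ids: np.ndarray
    split_tag: str = "train"
    fold_of_sound: np.ndarray | None = None


@dataclass
class FoldResponses:
    """Cross-validated response estimates.

    ``train`` maps fold id -> VoxelResponses of the fold's 108 training
    sounds (estimated on the 9 training runs); ``test`` holds every
    sound's test beta, estimated on its own set's 3 runs with the HRF fit
    on the fold's training runs.
    """

    train: dict
    test: VoxelResponses
    hrf: dict
    glm_info: dict = field(default_factory=dict)


def preprocess_timeseries(
    run: np.ndarray, drift_cycles: int = 2, smooth_points: int = 2
) -> np.ndarray:
    """Temporal high-pass plus short boxcar smoothing of one run.

    Removes the constant and all Fourier components of up to
    ``drift_cycles`` cycles per run by projection, then applies a causal
    ``smooth_points``-volume moving average (shorter at the run start).
    """
    run = np.asarray(run, dtype=float)
    squeeze = run.ndim == 1
    if squeeze:
        run = run[:, None]
    n = run.shape[0]
    if n < 8:
        raise ValueError("run too short to filter (need >= 8 volumes)")
    t = np.arange(n)
    cols = [np.ones(n)]
    for k in range(1, drift_cycles + 1):
        cols += [np.sin(2 * np.pi * k * t / n), np.cos(2 * np.pi * k * t / n)]
    basis, _ = np.linalg.qr(np.stack(cols, axis=1))
    resid = run - basis @ (basis.T @ run)
    if smooth_points > 1:
        kernel = np.ones(smooth_points)
        smoothed = np.apply_along_axis(
            lambda y: np.convolve(y, kernel, mode="full")[:n], 0, resid
        )
        norm = np.minimum(t + 1, smooth_points)
        out = smoothed / norm[:, None]
    else:
        out = resid
    return out[:, 0] if squeeze else out


def _legendre_basis(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1, 1, n)
    return np.stack(
        [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)], axis=1
    )


class DesignOperator:
    """Precomputed stick/drift machinery for one set of runs.

    Builds the shifted stick matrices S_j (one column per estimated sound
    plus, when present, one nuisance column for excluded repeat trials),
    the per-run Legendre drift block and all Gram blocks needed by the
    ALS sweeps:  G[j,k] = S_j^T S_k, C[j] = S_j^T D and D^T D.
    """

    def __init__(
        self,
        designs: list[EventDesign],
        fir_window: int = 8,
        drift_order: int = 3,
        sound_ids: np.ndarray | None = None,
    ):
        if fir_window < 4:
            raise ValueError("FIR window must span >= 4 volumes")
        self.designs = designs
        self.window = fir_window
        if sound_ids is None:
            ids: set[int] = set()
            for d in designs:
                ids.update(
                    int(s)
                    for s, sil, rep in zip(d.sound_id, d.is_silent, d.is_repeat)
                    if not sil and not rep and s != SILENT
                )
            sound_ids = np.array(sorted(ids))
        self.sound_ids = np.asarray(sound_ids)
        col_of = {int(s): i for i, s in enumerate(self.sound_ids)}
        n_sounds = len(self.sound_ids)
        self.has_nuisance = any(d.is_repeat.any() for d in designs)
        nc = n_sounds + int(self.has_nuisance)
        self.n_sounds = n_sounds
        self.n_cols = nc

        run_lengths = [d.n_volumes for d in designs]
        offsets = np.concatenate([[0], np.cumsum(run_lengths)])
        self.n_time = int(offsets[-1])

        shifted = []
        for j in range(fir_window):
            rows, cols = [], []
            for d, off in zip(designs, offsets[:-1]):
                for onset, sid, sil, rep in zip(
                    d.onsets, d.sound_id, d.is_silent, d.is_repeat
                ):
                    if sil:
                        continue
                    t = onset + j
                    if t >= d.n_volumes:
                        continue
                    c = nc - 1 if rep else col_of[int(sid)]
                    rows.append(off + t)
                    cols.append(c)
            shifted.append(
                sparse.csr_matrix(
                    (np.ones(len(rows)), (rows, cols)), shape=(self.n_time, nc)
                )
            )
        self._sticks = shifted

        drift_blocks = [_legendre_basis(n, drift_order) for n in run_lengths]
        self.drift = np.asarray(sparse.block_diag(drift_blocks).todense())
        self.n_drift = self.drift.shape[1]

        J = fir_window
        self.G = np.empty((J, J, nc, nc))
        for j in range(J):
            for k in range(j, J):
                g = (shifted[j].T @ shifted[k]).toarray()
                self.G[j, k] = g
                self.G[k, j] = g.T
        self.C = np.stack([(shifted[j].T @ self.drift) for j in range(J)])
        self.DtD = self.drift.T @ self.drift

    def project(self, Y: np.ndarray):
        """Per-voxel inner products with the data: S_j^T Y, D^T Y, y^T y."""
        r = np.stack([self._sticks[j].T @ Y for j in range(self.window)])
        return r, self.drift.T @ Y, np.einsum("tv,tv->v", Y, Y)


def _canonical_fir(window: int, tr_s: float) -> np.ndarray:
    from .synthetic_data import double_gamma_hrf

    h = double_gamma_hrf(np.arange(window) * tr_s)
    return h / np.linalg.norm(h)


def _normalize_hrf(h: np.ndarray) -> np.ndarray:
    """Unit norm, sign fixed so the largest-magnitude tap is positive."""
    nrm = np.linalg.norm(h, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    h = h / nrm
    peak = np.take_along_axis(
        h, np.argmax(np.abs(h), axis=1)[:, None], axis=1
    )
    sign = np.where(peak >= 0, 1.0, -1.0)
    return h * sign


def _beta_step(op: DesignOperator, h: np.ndarray, r, dty, ridge: float = 1e-9):
    """Solve for (betas, drift) given per-voxel HRFs; batched over voxels."""
    V = h.shape[0]
    nc, nd = op.n_cols, op.n_drift
    J = op.window
    hh = (h[:, :, None] * h[:, None, :]).reshape(V, J * J)
    M = (hh @ op.G.reshape(J * J, nc * nc)).reshape(V, nc, nc)
    P = np.tensordot(h, op.C.reshape(J, nc * nd), axes=(1, 0)).reshape(V, nc, nd)
    rhs_b = np.einsum("vj,jcv->vc", h, r)
    p = nc + nd
    N = np.empty((V, p, p))
    N[:, :nc, :nc] = M
    N[:, :nc, nc:] = P
    N[:, nc:, :nc] = P.transpose(0, 2, 1)
    N[:, nc:, nc:] = op.DtD
    diag = np.arange(p)
    N[:, diag, diag] += ridge * (1.0 + N[:, diag, diag])
    rhs = np.concatenate([rhs_b, dty.T], axis=1)
    x = np.linalg.solve(N, rhs[..., None])[..., 0]
    return x[:, :nc], x[:, nc:], x, rhs


def _hrf_step(op: DesignOperator, beta: np.ndarray, r, dty, ridge: float = 1e-9):
    """Solve for (HRF, drift) given per-voxel betas; batched over voxels."""
    V = beta.shape[0]
    J, nd = op.window, op.n_drift
    nc = op.n_cols
    gb = np.tensordot(op.G.reshape(J * J * nc, nc), beta.T, axes=(1, 0))
    gb = gb.reshape(J, J, nc, V)
    A = np.einsum("vc,jkcv->vjk", beta, gb)
    Q = np.einsum("jcd,vc->vjd", op.C, beta)
    rhs_h = np.einsum("jcv,vc->vj", r, beta)
    p = J + nd
    N = np.empty((V, p, p))
    N[:, :J, :J] = A
    N[:, :J, J:] = Q
    N[:, J:, :J] = Q.transpose(0, 2, 1)
    N[:, J:, J:] = op.DtD
    diag = np.arange(p)
    N[:, diag, diag] += ridge * (1.0 + N[:, diag, diag])
    rhs = np.concatenate([rhs_h, dty.T], axis=1)
    x = np.linalg.solve(N, rhs[..., None])[..., 0]
    return x[:, :J]


@dataclass
class GlmFitResult:
    """Bookkeeping of one joint HRF/beta fit, for the omnibus F-test."""

    rss_full: np.ndarray
    rss_reduced: np.ndarray
    n_time: int
    n_model_params: int
    n_sound_params: int

    @property
    def dof_residual(self) -> int:
        return self.n_time - self.n_model_params


def estimate_hrf_and_betas(
    runs: list[np.ndarray] | BoldTimeseries,
    designs: list[EventDesign],
    fir_window: int = 8,
    drift_order: int = 3,
    tol: float = 1e-6,
    max_iter: int = 100,
    chunk: int = 128,
) -> tuple[HrfEstimate, VoxelResponses, GlmFitResult]:
    """Alternating least squares for the rank-1 HRF x beta model.

    ``runs`` are (volumes x voxels) arrays matching ``designs``.  Returns
    the per-voxel FIR HRF (unit norm, positive peak), the per-sound betas
    and a fit summary usable for responsive-voxel selection.  Voxels that
    do not converge within ``max_iter`` sweeps are flagged, not raised;
    all-zero voxels yield zero betas and a degenerate flag.
    """
    if isinstance(runs, BoldTimeseries):
        runs = runs.runs
    if len(runs) != len(designs):
        raise ValueError("need one time-series array per design")
    op = DesignOperator(designs, fir_window, drift_order)
    Y = np.concatenate([np.asarray(r, dtype=float) for r in runs], axis=0)
    if Y.shape[0] != op.n_time:
        raise ValueError("run lengths do not match the designs")
    V = Y.shape[1]
    tr = designs[0].tr_s

    r, dty, yty = op.project(Y)
    scale = np.sqrt(yty / op.n_time)
    degenerate = scale <= 1e-12 * max(scale.max(), 1.0)

    h = np.tile(_canonical_fir(fir_window, tr), (V, 1))
    converged = np.zeros(V, dtype=bool)
    converged[degenerate] = True
    n_iter = 0
    active = np.flatnonzero(~converged)
    while active.size and n_iter < max_iter:
        n_iter += 1
        for start in range(0, active.size, chunk):
            idx = active[start : start + chunk]
            beta, _, _, _ = _beta_step(op, h[idx], r[:, :, idx], dty[:, idx])
            h_new = _normalize_hrf(_hrf_step(op, beta, r[:, :, idx], dty[:, idx]))
            delta = np.abs(h_new - h[idx]).max(axis=1)
            h[idx] = h_new
            converged[idx] = delta < tol
        active = np.flatnonzero(~converged)

    # final consistent beta/drift solve at the converged HRFs
    betas = np.zeros((op.n_cols, V))
    rss_full = yty.copy()
    for start in range(0, V, chunk):
        idx = np.arange(start, min(start + chunk, V))
        beta, _, x, rhs = _beta_step(op, h[idx], r[:, :, idx], dty[:, idx])
        betas[:, idx] = beta.T
        rss_full[idx] = np.maximum(yty[idx] - np.einsum("vp,vp->v", x, rhs), 0.0)
    betas[:, degenerate] = 0.0

    x0 = np.linalg.solve(
        op.DtD + 1e-12 * np.eye(op.n_drift) * np.trace(op.DtD), dty
    )
    rss_reduced = np.maximum(yty - np.einsum("dv,dv->v", dty, x0), 0.0)

    hrf = HrfEstimate(
        coefficients=h,
        window=fir_window,
        converged=converged.copy(),
        degenerate=degenerate,
        n_iter=n_iter,
    )
    sound_betas = betas[: op.n_sounds]
    responses = VoxelResponses(values=sound_betas, sound_ids=op.sound_ids)
    info = GlmFitResult(
        rss_full=rss_full,
        rss_reduced=rss_reduced,
        n_time=op.n_time,
        n_model_params=op.n_cols + op.n_drift + fir_window - 1,
        n_sound_params=op.n_cols + fir_window - 1,
    )
    return hrf, responses, info


def betas_given_hrf(
    runs: list[np.ndarray],
    designs: list[EventDesign],
    hrf: HrfEstimate,
    drift_order: int = 3,
    chunk: int = 128,
) -> VoxelResponses:
    """Linear beta estimation with each voxel's HRF held fixed.

    Used for test sounds: their betas are computed on the test runs with
    the HRF estimated from the training runs.
    """
    op = DesignOperator(designs, hrf.window, drift_order)
    Y = np.concatenate([np.asarray(rr, dtype=float) for rr in runs], axis=0)
    r, dty, _ = op.project(Y)
    V = Y.shape[1]
    betas = np.zeros((op.n_cols, V))
    for start in range(0, V, chunk):
        idx = np.arange(start, min(start + chunk, V))
        beta, _, _, _ = _beta_step(
            op, hrf.coefficients[idx], r[:, :, idx], dty[:, idx]
        )
        betas[:, idx] = beta.T
    return VoxelResponses(values=betas[: op.n_sounds], sound_ids=op.sound_ids)


def omnibus_glm(
    runs: list[np.ndarray],
    designs: list[EventDesign],
    fir_window: int = 8,
    drift_order: int = 3,
    chunk: int = 256,
) -> GlmFitResult:
    """Linear omnibus GLM at the canonical HRF, for voxel selection.

    Fitting the sound betas with a *fixed* canonical FIR keeps the model
    linear, so the omnibus F-statistic of sounds-vs-drift follows its
    nominal F distribution under white noise; the per-voxel HRF of the
    bilinear estimator would make the same test anticonservative.
    """
    op = DesignOperator(designs, fir_window, drift_order)
    Y = np.concatenate([np.asarray(rr, dtype=float) for rr in runs], axis=0)
    r, dty, yty = op.project(Y)
    V = Y.shape[1]
    tr = designs[0].tr_s
    h0 = np.tile(_canonical_fir(fir_window, tr), (V, 1))
    rss_full = np.empty(V)
    for start in range(0, V, chunk):
        idx = np.arange(start, min(start + chunk, V))
        _, _, x, rhs = _beta_step(op, h0[idx], r[:, :, idx], dty[:, idx])
        rss_full[idx] = np.maximum(
            yty[idx] - np.einsum("vp,vp->v", x, rhs), 0.0
        )
    x0 = np.linalg.solve(
        op.DtD + 1e-12 * np.eye(op.n_drift) * np.trace(op.DtD), dty
    )
    rss_reduced = np.maximum(yty - np.einsum("dv,dv->v", dty, x0), 0.0)
    return GlmFitResult(
        rss_full=rss_full,
        rss_reduced=rss_reduced,
        n_time=op.n_time,
        n_model_params=op.n_cols + op.n_drift,
        n_sound_params=op.n_cols,
    )


def estimate_fold_responses(
    bold: BoldTimeseries | list[np.ndarray],
    designs: list[EventDesign],
    plan: FoldPlan,
    preprocess: bool = True,
    fir_window: int = 8,
    drift_order: int = 3,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FoldResponses:
    """Cross-validated betas with strict fold hygiene.

    For each fold the HRF and the training-sound betas come from the 9
    training runs only; test-sound betas come from the fold's 3 test runs
    with that training HRF.  Because each sound set is confined to its own
    runs, train and test betas always derive from disjoint run sets.
    """
    runs = bold.runs if isinstance(bold, BoldTimeseries) else bold
    if preprocess:
        runs = [preprocess_timeseries(rr) for rr in runs]

    train: dict = {}
    hrfs: dict = {}
    infos: dict = {}
    test_vals, test_ids, test_fold = [], [], []
    for fold in sorted(plan.folds):
        train_idx = [i for i, d in enumerate(designs) if d.set_id != fold]
        test_idx = [i for i, d in enumerate(designs) if d.set_id == fold]
        if not train_idx or not test_idx:
            raise ValueError(f"fold {fold}: empty train or test run set")
        assert not set(train_idx) & set(test_idx)
        hrf, resp, info = estimate_hrf_and_betas(
            [runs[i] for i in train_idx],
            [designs[i] for i in train_idx],
            fir_window=fir_window,
            drift_order=drift_order,
            tol=tol,
            max_iter=max_iter,
        )
        train[fold] = resp
        hrfs[fold] = hrf
        # selection info from the linear canonical-HRF GLM (calibrated F)
        infos[fold] = omnibus_glm(
            [runs[i] for i in train_idx],
            [designs[i] for i in train_idx],
            fir_window=fir_window,
            drift_order=drift_order,
        )
        test_resp = betas_given_hrf(
            [runs[i] for i in test_idx],
            [designs[i] for i in test_idx],
            hrf,
            drift_order=drift_order,
        )
        test_vals.append(test_resp.values)
        test_ids.append(test_resp.sound_ids)
        test_fold.append(np.full(len(test_resp.sound_ids), fold))

    ids = np.concatenate(test_ids)
    order = np.argsort(ids)
    test = VoxelResponses(
        values=np.concatenate(test_vals, axis=0)[order],
        sound_ids=ids[order],
        split_tag="test",
        fold_of_sound=np.concatenate(test_fold)[order],
    )
    return FoldResponses(train=train, test=test, hrf=hrfs, glm_info=infos)


def select_responsive_voxels(fit: GlmFitResult, alpha: float = 0.05) -> np.ndarray:
    """Mask of voxels responding to the sounds (omnibus F, uncorrected).

    Compares the full HRF x beta + drift model against drift alone:
    F = ((RSS0 - RSS1)/q) / (RSS1/dof) with q the number of sound-related
    parameters (betas plus the HRF's free directions).
    """
    dof = fit.dof_residual
    if dof <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    q = fit.n_sound_params
    rss1 = np.maximum(fit.rss_full, np.finfo(float).tiny)
    f = ((fit.rss_reduced - fit.rss_full) / q) / (rss1 / dof)
    p = stats.f.sf(f, q, dof)
    return p < alpha
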