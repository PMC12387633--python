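"""PCA, NIPALS PLS, and multiblock PLS with super-score deflation.

Multiblock PLS (MBPLS) is a supervised latent-variable model over several
predictor blocks sharing samples.  Per component, every block contributes a
*block score* ``t_b = X_b w_b``; the block scores are combined through
unit-norm *super weights* into a consensus *super score* ``t`` that predicts
the (centered) response ``Y``.  Both the blocks and ``Y`` are deflated by
the super score, so later components model what earlier ones left.

The iterative scheme per component ``a``:

1. initialise the Y-score ``u`` with the Y column of maximal variance;
2. per block: ``w_b ∝ X_bᵀu`` (unit norm), ``t_b = X_b w_b``;
3. super weights ``w_T ∝ Tᵀu`` (unit norm, ``T = [t_1 … t_B]``),
   super score ``t = T w_T``;
4. Y-weights ``q = Yᵀt / tᵀt``, new ``u = Y q / qᵀq``; iterate 2–4 until
   ``u`` is stable;
5. block loadings ``p_b = X_bᵀt / tᵀt``; deflate ``X_b ← X_b − t p_bᵀ``
   and ``Y ← Y − t qᵀ``.

With a single block the scheme reduces exactly to NIPALS PLS2.  The sign
convention makes the largest-magnitude block-weight entry of each component
positive, so refits are bit-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockMatrix, ResponseMatrix, check_aligned

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 5000


class ConvergenceError(RuntimeError):
    """NIPALS iteration failed to stabilise within ``max_iter``."""


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, BlockMatrix) else np.asarray(X, float)


def _init_u(Yc: np.ndarray) -> np.ndarray:
    """Y column of maximal variance; ties broken by lowest column index."""
    return Yc[:, int(np.argmax(np.var(Yc, axis=0)))].copy()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray                # n x A
    loadings: np.ndarray              # p x A, orthonormal columns
    explained_variance: np.ndarray    # A, eigenvalues of the covariance
    explained_variance_ratio: np.ndarray


def fit_pca(X, n_components: int) -> PCAResult:
    """PCA by SVD of the column-centered matrix.

    Centering is idempotent for already-centered preprocessed blocks.
    """
    V = _as_values(X)
    Vc = V - V.mean(axis=0)
    rank = np.linalg.matrix_rank(Vc)
    if not (1 <= n_components <= rank):
        raise ValueError(f"n_components must be in [1, rank={rank}]")
    U, s, Vt = np.linalg.svd(Vc, full_matrices=False)
    # deterministic sign: largest |loading| entry positive
    for a in range(len(s)):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] = -Vt[a]
            U[:, a] = -U[:, a]
    ev = s ** 2 / max(V.shape[0] - 1, 1)
    total = np.var(Vc, axis=0, ddof=1).sum()
    A = n_components
    return PCAResult(scores=U[:, :A] * s[:A], loadings=Vt[:A].T,
                     explained_variance=ev[:A],
                     explained_variance_ratio=ev[:A] / total)


# ---------------------------------------------------------------------------
# single-block PLS (NIPALS PLS2)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray    # p x A
    x_scores: np.ndarray     # n x A
    x_loadings: np.ndarray   # p x A
    y_weights: np.ndarray    # g x A
    y_mean: np.ndarray
    r2y_cum: np.ndarray      # cumulative R2Y after each component

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients B with Ŷ = X B + ȳ."""
        W, P, Q = self.x_weights, self.x_loadings, self.y_weights
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X) -> np.ndarray:
        return _as_values(X) @ self.coefficients + self.y_mean


def fit_pls(X, Y, n_components: int, tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER) -> PLSModel:
    """NIPALS PLS2 on one preprocessed block.

    ``Y`` (a :class:`ResponseMatrix` or array) is column-centered
    internally.  Returns weights, scores, loadings and cumulative R²Y.
    """
    Xd = _as_values(X).copy()
    if not (1 <= n_components <= Xd.shape[0] - 1):
        raise ValueError(
            f"n_components must be in [1, n-1 = {Xd.shape[0] - 1}]")
    Yv = Y.Y if isinstance(Y, ResponseMatrix) else np.asarray(Y, float)
    y_mean = Yv.mean(axis=0)
    Yc = Yv - y_mean
    ss_y = np.sum(Yc ** 2)
    n, p = Xd.shape
    A = n_components
    W = np.zeros((p, A)); T = np.zeros((n, A)); P = np.zeros((p, A))
    Q = np.zeros((Yc.shape[1], A)); r2 = np.zeros(A)
    for a in range(A):
        u = _init_u(Yc)
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"component {a + 1} exceeds the rank of X")
            w /= nw
            t = Xd @ w
            q = Yc.T @ t / (t @ t)
            u_new = Yc @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= tol * max(1.0, np.linalg.norm(u_new)):
                u = u_new
                break
            u = u_new
        else:
            raise ConvergenceError(
                f"PLS component {a + 1} did not converge in {max_iter} iterations")
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w, t = -w, -t
        tt = t @ t
        pl = Xd.T @ t / tt
        q = Yc.T @ t / tt
        Xd -= np.outer(t, pl)
        Yc -= np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pl, q
        r2[a] = 1.0 - np.sum(Yc ** 2) / ss_y
    return PLSModel(A, W, T, P, Q, y_mean, r2)


# ---------------------------------------------------------------------------
# multiblock PLS
# ---------------------------------------------------------------------------

@dataclass
class MBPLSModel:
    """Fitted MBPLS model.

    ``super_scores`` holds the consensus components T₁..T_A; ``block_weights``
    the per-block weight matrices W^MBPLS whose columns are the biplot
    variable coordinates; ``block_r2`` the incremental fraction of each
    block's initial sum of squares explained per component.
    """

    n_components: int
    block_ids: list[str]
    groups: list[str]
    variables: dict                    # block id -> variable ids
    super_scores: np.ndarray           # n x A
    super_weights: np.ndarray          # B x A, unit-norm columns
    block_weights: dict                # block id -> p_b x A
    block_scores: dict                 # block id -> n x A
    block_loadings: dict               # block id -> p_b x A
    y_weights: np.ndarray              # g x A
    y_mean: np.ndarray
    r2y_cum: np.ndarray                # cumulative R2Y per component
    block_r2: dict                     # block id -> (A,) incremental R2_{b,a}
    block_divisors: dict = field(default_factory=dict)
    deflation: str = "super-score"
    fitted_y: np.ndarray | None = None

    @property
    def r2y(self) -> float:
        return float(self.r2y_cum[-1])

    def block_contributions(self, kind: str = "r2") -> dict:
        """Per-block contribution per component.

        ``kind="r2"``: incremental explained block variance R²_{b,a} (the
        figure-style report); ``kind="super_weight"``: squared super
        weights, the share of each block in the consensus score.
        """
        if kind == "r2":
            return {b: np.asarray(v) for b, v in self.block_r2.items()}
        if kind == "super_weight":
            return {b: self.super_weights[i] ** 2
                    for i, b in enumerate(self.block_ids)}
        raise ValueError("kind must be 'r2' or 'super_weight'")

    def predict(self, blocks, n_components: int | None = None) -> np.ndarray:
        """Predict continuous Y scores for new (already preprocessed with
        the training parameters) blocks; class call is the row argmax."""
        A = self.n_components if n_components is None else n_components
        if not (1 <= A <= self.n_components):
            raise ValueError("n_components out of fitted range")
        order = {b.block_id if isinstance(b, BlockMatrix) else self.block_ids[i]: b
                 for i, b in enumerate(blocks)}
        Xd = {}
        for bid in self.block_ids:
            if bid not in order:
                raise ValueError(f"missing block {bid} in prediction input")
            blk = order[bid]
            if isinstance(blk, BlockMatrix) and list(blk.variables) != list(self.variables[bid]):
                raise ValueError(f"variable ids of block {bid} do not match training")
            Xd[bid] = _as_values(blk).copy()
        n_new = next(iter(Xd.values())).shape[0]
        Yhat = np.tile(self.y_mean, (n_new, 1))
        for a in range(A):
            tb = np.column_stack([Xd[bid] @ self.block_weights[bid][:, a]
                                  for bid in self.block_ids])
            t = tb @ self.super_weights[:, a]
            Yhat += np.outer(t, self.y_weights[:, a])
            for bid in self.block_ids:
                Xd[bid] -= np.outer(t, self.block_loadings[bid][:, a])
        return Yhat

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "block_ids": self.block_ids,
            "groups": self.groups,
            "variables": {b: list(v) for b, v in self.variables.items()},
            "super_scores": self.super_scores.tolist(),
            "super_weights": self.super_weights.tolist(),
            "block_weights": {b: w.tolist() for b, w in self.block_weights.items()},
            "block_scores": {b: s.tolist() for b, s in self.block_scores.items()},
            "block_loadings": {b: p.tolist() for b, p in self.block_loadings.items()},
            "y_weights": self.y_weights.tolist(),
            "y_mean": self.y_mean.tolist(),
            "r2y_cum": self.r2y_cum.tolist(),
            "block_r2": {b: np.asarray(v).tolist() for b, v in self.block_r2.items()},
            "block_divisors": self.block_divisors,
            "deflation": self.deflation,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MBPLSModel":
        with open(path) as fh:
            d = json.load(fh)
        arr = np.asarray
        return cls(n_components=d["n_components"], block_ids=d["block_ids"],
                   groups=d["groups"], variables=d["variables"],
                   super_scores=arr(d["super_scores"]),
                   super_weights=arr(d["super_weights"]),
                   block_weights={b: arr(w) for b, w in d["block_weights"].items()},
                   block_scores={b: arr(s) for b, s in d["block_scores"].items()},
                   block_loadings={b: arr(p) for b, p in d["block_loadings"].items()},
                   y_weights=arr(d["y_weights"]), y_mean=arr(d["y_mean"]),
                   r2y_cum=arr(d["r2y_cum"]),
                   block_r2={b: arr(v) for b, v in d["block_r2"].items()},
                   block_divisors=d["block_divisors"], deflation=d["deflation"])


def fit_mbpls(blocks: list, Y, n_components: int = 4,
              tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER
              ) -> MBPLSModel:
    """Fit the multiblock PLS model on preprocessed, block-scaled blocks.

    Parameters
    ----------
    blocks:
        List of :class:`BlockMatrix` (or plain arrays) sharing samples in
        identical order; for the intended use each is fully preprocessed
        (centered, column-scaled, block-scaled).
    Y:
        :class:`ResponseMatrix` or an (n x g) array; column-centered
        internally.
    n_components:
        Number of consensus components A.
    """
    bms = [b for b in blocks if isinstance(b, BlockMatrix)]
    if len(bms) == len(blocks) and len(blocks) > 1:
        check_aligned(bms)
    block_ids = [b.block_id if isinstance(b, BlockMatrix) else f"B{i + 1}"
                 for i, b in enumerate(blocks)]
    variables = {bid: (list(b.variables) if isinstance(b, BlockMatrix)
                       else list(range(_as_values(b).shape[1])))
                 for bid, b in zip(block_ids, blocks)}
    divisors = {bid: (float(b.params.get("block_divisor", 1.0))
                      if isinstance(b, BlockMatrix) else 1.0)
                for bid, b in zip(block_ids, blocks)}

    Xd = {bid: _as_values(b).copy() for bid, b in zip(block_ids, blocks)}
    ns = {v.shape[0] for v in Xd.values()}
    if len(ns) != 1:
        raise ValueError("blocks disagree on the number of samples")
    n = ns.pop()
    if not (1 <= n_components <= n - 1):
        raise ValueError(f"n_components must be in [1, n-1 = {n - 1}]")

    if isinstance(Y, ResponseMatrix):
        groups, Yv = list(Y.groups), Y.Y
    else:
        Yv = np.asarray(Y, float)
        groups = [f"class_{j}" for j in range(Yv.shape[1])]
    if Yv.shape[0] != n:
        raise ValueError("Y and blocks disagree on the number of samples")
    y_mean = Yv.mean(axis=0)
    Yc = Yv - y_mean
    ss_y = np.sum(Yc ** 2)
    if ss_y == 0:
        raise ValueError("Y has zero variance")

    ss_init = {bid: np.sum(v ** 2) for bid, v in Xd.items()}
    ss_prev = dict(ss_init)
    A, B = n_components, len(block_ids)
    T = np.zeros((n, A)); Wsup = np.zeros((B, A))
    Wb = {bid: np.zeros((Xd[bid].shape[1], A)) for bid in block_ids}
    Tb = {bid: np.zeros((n, A)) for bid in block_ids}
    Pb = {bid: np.zeros((Xd[bid].shape[1], A)) for bid in block_ids}
    Q = np.zeros((Yc.shape[1], A))
    r2y = np.zeros(A)
    br2 = {bid: np.zeros(A) for bid in block_ids}

    for a in range(A):
        u = _init_u(Yc)
        for _ in range(max_iter):
            wb, tb = {}, []
            for bid in block_ids:
                w = Xd[bid].T @ u
                nw = np.linalg.norm(w)
                wb[bid] = w / nw if nw > 0 else w
                tb.append(Xd[bid] @ wb[bid])
            Tmat = np.column_stack(tb)
            v = Tmat.T @ u
            nv = np.linalg.norm(v)
            if nv == 0:
                raise ValueError(
                    f"component {a + 1} exceeds the informative rank of the blocks")
            ws = v / nv
            t = Tmat @ ws
            q = Yc.T @ t / (t @ t)
            u_new = Yc @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= tol * max(1.0, np.linalg.norm(u_new)):
                u = u_new
                break
            u = u_new
        else:
            raise ConvergenceError(
                f"MBPLS component {a + 1} did not converge in {max_iter} iterations")

        # sign convention: largest |entry| of the concatenated block weights
        wcat = np.concatenate([wb[bid] for bid in block_ids])
        if wcat[np.argmax(np.abs(wcat))] < 0:
            for bid in block_ids:
                wb[bid] = -wb[bid]
            Tmat, t = -Tmat, -t
        tt = t @ t
        q = Yc.T @ t / tt
        for i, bid in enumerate(block_ids):
            pl = Xd[bid].T @ t / tt
            Xd[bid] -= np.outer(t, pl)
            ss_new = np.sum(Xd[bid] ** 2)
            br2[bid][a] = (ss_prev[bid] - ss_new) / ss_init[bid] \
                if ss_init[bid] > 0 else 0.0
            ss_prev[bid] = ss_new
            Wb[bid][:, a] = wb[bid]
            Tb[bid][:, a] = Tmat[:, i]
            Pb[bid][:, a] = pl
        Yc -= np.outer(t, q)
        r2y[a] = 1.0 - np.sum(Yc ** 2) / ss_y
        T[:, a] = t
        Wsup[:, a] = ws
        Q[:, a] = q

    model = MBPLSModel(n_components=A, block_ids=block_ids, groups=groups,
                       variables=variables, super_scores=T, super_weights=Wsup,
                       block_weights=Wb, block_scores=Tb, block_loadings=Pb,
                       y_weights=Q, y_mean=y_mean, r2y_cum=r2y, block_r2=br2,
                       block_divisors=divisors)
    model.fitted_y = model.predict(blocks)
    return model


def block_explained_variance(model: MBPLSModel) -> dict:
    """R²_{b,a} table: the incremental fraction of block b's initial sum of
    squares removed by component a's deflation (each in [0, 1], cumulative
    sum over a at most 1 per block)."""
    if model.super_scores is None:
        raise ValueError("model is not fitted")
    return {b: np.asarray(v).copy() for b, v in model.block_r2.items()}
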