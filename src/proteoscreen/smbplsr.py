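"""Sparse multiblock partial least-squares regression (SMBPLSR).

Given K predictor blocks X_1..X_K (samples x features; here typically a
protein-abundance block and a phosphorylation-site block) and a response
block Y (samples x drugs; AUC values), each component solves

    argmax_{u_1..u_K, v}  sum_k cov^2(X_k u_k, Y v)

subject to sparsity on every loading vector: exactly ``k_drugs`` nonzero
drug loadings in v and ``k_features`` nonzero feature loadings pooled over
the predictor blocks. The sparsity penalty is implemented in its cardinality
(top-k hard-threshold) form, which delivers the configured support sizes
deterministically; loadings are L2-normalised on their support.

The solver alternates: with the drug score s = Y v fixed, u_k is the
hard-thresholded, renormalised X_k' s (which maximises cov(X_k u_k, s) over
unit-norm sparse u_k); with the block scores t_k = X_k u_k fixed, v is the
hard-thresholded, renormalised Y' (sum_k t_k). Iterates are accepted only
while the objective does not decrease, so convergence is monotone. After a
component, blocks are deflated by regressing out their own score and Y by
the summed block score, and the next component is fitted on the residuals.

Sign convention: the largest-|loading| drug entry of v is made positive
(u_k and scores flipped along with it), so a negative feature loading times
a positive drug loading reads as "higher abundance, lower AUC" =
sensitivity marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("proteoscreen")

#: feature-side multi-starts are exhaustive only up to this total dimension
_FEATURE_START_LIMIT = 64


@dataclass
class SMBPLSRInput:
    """Column-centred predictor blocks and response block."""

    X_blocks: list[np.ndarray]  # each samples x features_k, centred
    Y: np.ndarray  # samples x drugs, centred
    block_names: list[str] = field(default_factory=list)
    feature_names: list[list[str]] = field(default_factory=list)
    drug_names: list[str] = field(default_factory=list)

    @classmethod
    def from_matrices(cls, X_blocks, Y, block_names=None, feature_names=None,
                      drug_names=None) -> "SMBPLSRInput":
        """Centre the columns of every block and of Y."""
        Xc = [np.asarray(X, float) - np.asarray(X, float).mean(axis=0) for X in X_blocks]
        Yc = np.asarray(Y, float) - np.asarray(Y, float).mean(axis=0)
        n = Yc.shape[0]
        for X in Xc:
            if X.shape[0] != n:
                raise ValueError("all blocks must share the sample index")
        return cls(
            X_blocks=Xc,
            Y=Yc,
            block_names=block_names or [f"block{k}" for k in range(len(Xc))],
            feature_names=feature_names
            or [[f"b{k}f{j}" for j in range(X.shape[1])] for k, X in enumerate(Xc)],
            drug_names=drug_names or [f"drug{j}" for j in range(Yc.shape[1])],
        )

    def copy(self) -> "SMBPLSRInput":
        return SMBPLSRInput(
            [X.copy() for X in self.X_blocks],
            self.Y.copy(),
            list(self.block_names),
            [list(f) for f in self.feature_names],
            list(self.drug_names),
        )


@dataclass
class SMBPLSRComponent:
    u: list[np.ndarray]  # per-block feature loadings, sparse, unit norm
    v: np.ndarray  # drug loadings, sparse, unit norm
    t: list[np.ndarray]  # block scores X_k u_k
    s: np.ndarray  # response score Y v
    objective: float  # sum_k cov^2(t_k, s)
    converged: bool
    n_iter: int
    selected_drugs: list[str] = field(default_factory=list)
    selected_features: list[tuple[str, str, float]] = field(default_factory=list)
    # (block name, feature name, loading)


@dataclass
class SMBPLSRModel:
    components: list[SMBPLSRComponent]

    def __len__(self) -> int:
        return len(self.components)


def _sparsify(w: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest-|w| entries, zero the rest, L2-normalise."""
    out = np.zeros_like(w)
    if k >= len(w):
        out = w.copy()
    else:
        keep = np.argpartition(np.abs(w), -k)[-k:]
        out[keep] = w[keep]
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def _allocate_budget(masses: np.ndarray, dims: np.ndarray, total: int) -> np.ndarray:
    """Split the pooled feature budget across blocks.

    Proportional to each block's |X_k' s| mass (largest-remainder rounding),
    capped at the block dimension; leftover budget spills to blocks with
    spare capacity.
    """
    total = min(total, int(dims.sum()))
    if masses.sum() <= 0:
        masses = dims.astype(float)
    raw = masses / masses.sum() * total
    alloc = np.minimum(np.floor(raw).astype(int), dims)
    while alloc.sum() < total:
        room = alloc < dims
        frac = np.where(room, raw - alloc, -np.inf)
        alloc[int(np.argmax(frac))] += 1
    return alloc


def _objective(t: list[np.ndarray], s: np.ndarray) -> float:
    n = len(s)
    return float(sum((tk @ s) ** 2 for tk in t) / (n - 1) ** 2)


def fit_component(
    data: SMBPLSRInput,
    k_drugs: int = 6,
    k_features: int = 50,
    tol: float = 1e-6,
    max_iter: int = 500,
    multi_start: bool = True,
) -> SMBPLSRComponent:
    """Fit one sparse component by monotone alternating maximisation.

    The alternating scheme only guarantees a local optimum, so by default
    the solver runs a deterministic set of starts — the leading right
    singular vector of Y, every single-drug indicator and, on problems small
    enough to afford it, the drug-score direction induced by every single
    feature — and keeps the best objective. ``multi_start=False`` uses the
    SVD start alone.
    """
    X, Y = data.X_blocks, data.Y
    q = Y.shape[1]
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    starts = [vt[0]]
    if multi_start:
        starts += [np.eye(q)[j] for j in range(q)]
        if sum(Xk.shape[1] for Xk in X) <= _FEATURE_START_LIMIT:
            for Xk in X:
                # v direction best aligned with each single-feature score
                starts += [Y.T @ Xk[:, j] for j in range(Xk.shape[1])]
    best: SMBPLSRComponent | None = None
    for v0 in starts:
        if np.linalg.norm(v0) == 0:
            continue
        cand = _fit_component_from(data, v0, k_drugs, k_features, tol, max_iter)
        if best is None or cand.objective > best.objective:
            best = cand
    return best


def _fit_component_from(
    data: SMBPLSRInput,
    v0: np.ndarray,
    k_drugs: int,
    k_features: int,
    tol: float,
    max_iter: int,
) -> SMBPLSRComponent:
    X, Y = data.X_blocks, data.Y
    n, q = Y.shape
    dims = np.array([Xk.shape[1] for Xk in X])
    k_drugs = min(k_drugs, q)

    v = np.asarray(v0, float)
    norm = np.linalg.norm(v)
    v = v / norm if norm > 0 else v

    best_obj = -np.inf
    best: tuple | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = Y @ v
        grads = [Xk.T @ s for Xk in X]
        masses = np.array([np.abs(g).sum() for g in grads])
        budget = _allocate_budget(masses, dims, k_features)
        u = [_sparsify(g, k) for g, k in zip(grads, budget)]
        t = [Xk @ uk for Xk, uk in zip(X, u)]
        v_new = _sparsify(Y.T @ sum(t), k_drugs)
        obj = _objective(t, Y @ v_new)
        if obj < best_obj - 1e-12:  # non-improving move: stop at best iterate
            break
        if best_obj > -np.inf and abs(obj - best_obj) < tol * max(1.0, best_obj):
            best_obj, best, v = obj, (u, v_new, t), v_new
            converged = True
            break
        best_obj, best, v = obj, (u, v_new, t), v_new
    if not converged:
        logger.debug("component stopped after %d iterations (obj %.3g)", it, best_obj)

    u, v, t = best
    s = Y @ v
    # sign convention: dominant drug loading positive
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
        s = -s
        u = [-uk for uk in u]
        t = [-tk for tk in t]
    selected_drugs = [data.drug_names[i] for i in np.flatnonzero(v)]
    selected_features = [
        (data.block_names[k], data.feature_names[k][i], float(u[k][i]))
        for k in range(len(X))
        for i in np.flatnonzero(u[k])
    ]
    return SMBPLSRComponent(
        u=u, v=v, t=t, s=s, objective=_objective(t, s), converged=converged,
        n_iter=it, selected_drugs=selected_drugs,
        selected_features=selected_features,
    )


def deflate(data: SMBPLSRInput, component: SMBPLSRComponent) -> SMBPLSRInput:
    """Remove a fitted component: regress each X_k on its own score t_k and
    Y on the summed block score. Centred columns stay centred."""
    out = data.copy()
    for k, tk in enumerate(component.t):
        denom = tk @ tk
        if denom <= 1e-30:
            logger.warning("zero-norm block score; skipping deflation of block %d", k)
            continue
        out.X_blocks[k] = out.X_blocks[k] - np.outer(tk, tk @ out.X_blocks[k]) / denom
    tbar = sum(component.t)
    denom = tbar @ tbar
    if denom > 1e-30:
        out.Y = out.Y - np.outer(tbar, tbar @ out.Y) / denom
    else:
        logger.warning("zero-norm summed score; Y not deflated")
    return out


def fit(
    data: SMBPLSRInput,
    n_components: int = 12,
    k_drugs: int = 6,
    k_features: int = 50,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SMBPLSRModel:
    """Fit a sequence of sparse components with deflation in between.

    Stops early (with a warning) once the residual response block carries
    essentially no variance left.
    """
    current = data.copy()
    components: list[SMBPLSRComponent] = []
    y_scale = float(np.linalg.norm(data.Y))
    for i in range(n_components):
        if np.linalg.norm(current.Y) < 1e-9 * max(y_scale, 1.0):
            logger.warning(
                "response block exhausted after %d components (requested %d)",
                i, n_components,
            )
            break
        comp = fit_component(current, k_drugs=k_drugs, k_features=k_features,
                             tol=tol, max_iter=max_iter)
        components.append(comp)
        current = deflate(current, comp)
    return SMBPLSRModel(components=components)
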