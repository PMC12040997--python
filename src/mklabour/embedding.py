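"""Unsupervised multiple-kernel-learning dimensionality reduction (MKL-DR).

Learns a low-dimensional, similarity-ordered representation of heterogeneous
admission-time data by combining per-feature kernels.  The fit alternates

1. a generalised eigenproblem for the projection directions ``A`` given the
   kernel weights (graph-embedding step:  minimise the affinity-weighted sum
   of squared embedded distances subject to a degree normalisation), and
2. a constrained update of the kernel weight vector ``beta`` on the
   probability simplex given ``A`` (sequential quadratic programming started
   at the current iterate, with a monotonicity guard).

The tracked objective is the sum over embedding dimensions of the graph
Rayleigh quotients  a' K L K a / (a' K D' K a), where D' is the degree form
deflated against the constant vector; both steps optimise it over one fixed,
well-conditioned subspace, so it is non-increasing across alternations by
construction.  Out-of-sample points are projected by evaluating the training
kernels at the new point and applying the learned ``beta`` and ``A``
(a Nystrom-style extension), which reproduces in-sample coordinates exactly
for training points.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import eigh
from scipy.optimize import minimize

from .cohort import DILATATION
from .exceptions import ValidationError
from .kernels import KernelSpec, build_kernels, default_specs, evaluate_kernel
from .pipeline import EncodedCohort, SubjectState

# coefficient-of-variation threshold below which an embedded direction is
# considered constant (the trivial graph mode); non-trivial directions are
# degree-orthogonal to the constant one, so their CV is O(1)
_DEGENERATE_STD = 1e-3


@dataclass
class EmbeddedPoint:
    subject_id: str
    t: float
    coordinates: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError(f"subject {self.subject_id}: non-finite embedded coordinates")


@dataclass
class Trajectory:
    """Time-indexed low-dimensional positions for one subject."""

    subject_id: str
    times: np.ndarray  # hours since admission
    coords: np.ndarray  # (n_followups, n_dims)

    def __len__(self):
        return len(self.times)

    def points(self) -> list[EmbeddedPoint]:
        return [EmbeddedPoint(self.subject_id, float(t), c) for t, c in zip(self.times, self.coords)]


def knn_affinity(similarity: np.ndarray, k: int) -> np.ndarray:
    """Symmetric k-nearest-neighbour adjacency from a similarity matrix."""
    n = similarity.shape[0]
    if k >= n:
        raise ValidationError(f"n_neighbors={k} must be < n_samples={n}")
    W = np.zeros_like(similarity)
    for i in range(n):
        order = np.argsort(-similarity[i], kind="stable")
        order = order[order != i][:k]
        W[i, order] = 1.0
    return np.maximum(W, W.T)


def _eigen_step(H, lap, dp, n_dims, jitter_rel=1e-12):
    """Minimise the graph Rayleigh quotients over the fixed reduced space.

    Solves  min_c  (c' H' L H c) / (c' H' D' H c)  for the first ``n_dims``
    directions as a generalised symmetric eigenproblem in the
    (well-conditioned, beta-independent) reduced space.  ``Dp`` is the
    degree form deflated against the constant vector, so the trivial
    constant mode has zero denominator norm and cannot appear among (or be
    mixed into) the minimisers; a coefficient-of-variation filter remains
    as a numerical backstop.  Directions are ordered by increasing
    eigenvalue (most informative first).
    """
    r = H.shape[1]
    if r <= n_dims:
        raise ValidationError("combined kernel rank too low for the requested n_dims")
    Lred = H.T @ lap(H)
    Dred = H.T @ dp(H)
    jit = jitter_rel * max(float(np.trace(Dred)) / r, 1e-300)
    n_cand = min(r - 1, n_dims + 3)
    vals = C_cand = None
    for _ in range(4):
        try:
            vals, C_cand = eigh(
                0.5 * (Lred + Lred.T),
                0.5 * (Dred + Dred.T) + jit * np.eye(r),
                subset_by_index=[0, n_cand],
            )
            break
        except np.linalg.LinAlgError:
            jit *= 1e3
    if vals is None:
        raise ValidationError("reduced degree form is numerically singular")
    Y_cand = H @ C_cand
    kept = []
    for j in range(vals.size):
        y = Y_cand[:, j]
        cv = np.std(y) / (np.abs(np.mean(y)) + np.std(y) + 1e-300)
        if cv > _DEGENERATE_STD:
            kept.append(j)
        if len(kept) == n_dims:
            break
    if len(kept) < n_dims:
        raise ValidationError(
            f"only {len(kept)} non-degenerate embedding directions available; reduce n_dims"
        )
    kept = np.asarray(kept)
    return vals[kept], C_cand[:, kept]


def _beta_objective_terms(G_list, C, lap, dp):
    """Quartic-form tensors for the beta objective.

    With the projection coefficients ``C`` fixed, the embedded coordinate
    block is  Y(beta) = sum_m beta_m T_m  with  T_m = G_m C , so both
    Y' L Y and Y' D Y are (P x P)-valued quadratics in beta; the tensors
    returned here are their (M, M, P, P) coefficient arrays.
    """
    T = [Gm @ C for Gm in G_list]
    LT = [lap(Tm) for Tm in T]
    DT = [dp(Tm) for Tm in T]
    M = len(T)
    P = C.shape[1]
    Nq = np.empty((M, M, P, P))
    Dq = np.empty((M, M, P, P))
    for a in range(M):
        for b in range(M):
            Nq[a, b] = T[a].T @ LT[b]
            Dq[a, b] = T[a].T @ DT[b]
    return Nq, Dq


def _beta_step(beta, Nq, Dq):
    """Update the kernel weights on the probability simplex.

    Minimises the ratio-trace of the graph pencil restricted to the span of
    the current projections,  tr[(Y'DY)^{-1} (Y'LY)]  with  Y = Y(beta).
    At the current beta this equals the eigen-step objective, and for any
    beta it upper-bounds the objective the next eigen step will attain
    (the restricted trace dominates the sum of the smallest eigenvalues),
    so any decrease found here guarantees a monotone alternation.
    """

    def g(b):
        Nm = np.einsum("i,j,ijpq->pq", b, b, Nq)
        Dm = np.einsum("i,j,ijpq->pq", b, b, Dq)
        Dm = 0.5 * (Dm + Dm.T)
        try:
            return float(np.trace(np.linalg.solve(Dm, 0.5 * (Nm + Nm.T))))
        except np.linalg.LinAlgError:
            return np.inf

    g0 = g(beta)
    res = minimize(
        g,
        beta,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * beta.size,
        constraints=[{"type": "eq", "fun": lambda b: np.sum(b) - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    # accept any feasible improving iterate (SLSQP may stop with a
    # line-search warning at a good point); else keep the current beta
    b = np.clip(res.x, 0.0, None)
    if b.sum() > 0 and abs(b.sum() - 1.0) < 1e-6:
        b = b / b.sum()
        gb = g(b)
        if gb < g0:
            return b, float(gb)
    return beta, g0  # monotonicity guard: keep the current iterate


class MKLEmbedding:
    """Model object: training data plus embedding hyperparameters.

    Parameters
    ----------
    X : array-like or DataFrame
        Complete (no missing entries) admission-time state matrix,
        one row per training subject.
    feature_names : sequence of str, optional (taken from DataFrame columns)
    specs : kernel specifications; default one kernel per feature with
        family chosen by dtype-kind via the schema (use ``from_cohort``)
        or Gaussian for plain matrices.
    n_dims : number of embedding dimensions (default 6).
    n_neighbors : k of the symmetric kNN affinity graph (default 10).
    anchor_feature : feature used to orient dimension signs (each dimension
        is flipped so its correlation with the anchor is non-negative).
    """

    def __init__(
        self,
        X,
        feature_names=None,
        specs=None,
        n_dims: int = 6,
        n_neighbors: int = 10,
        anchor_feature: str | None = DILATATION,
        subject_ids=None,
        schema_hash: str | None = None,
    ):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            if subject_ids is None:
                subject_ids = list(X.index)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        if np.isnan(self.X).any():
            raise ValidationError("training matrix contains missing entries")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(self.X.shape[1])]
        self.feature_names = list(feature_names)
        if specs is None:
            specs = [KernelSpec(features=(f,), family="gaussian") for f in self.feature_names]
        self.specs = list(specs)
        if n_dims >= self.X.shape[0]:
            raise ValidationError("n_dims must be smaller than the number of training samples")
        self.n_dims = int(n_dims)
        self.n_neighbors = int(n_neighbors)
        self.anchor_feature = anchor_feature
        self.subject_ids = list(subject_ids) if subject_ids is not None else [
            str(i) for i in range(self.X.shape[0])
        ]
        self.schema_hash = schema_hash

    @classmethod
    def from_cohort(
        cls, cohort: EncodedCohort, subject_ids=None, n_dims=6, n_neighbors=10,
        anchor_feature: str | None = DILATATION, specs=None,
    ) -> "MKLEmbedding":
        adm = cohort.admission_matrix(subject_ids)
        if specs is None:
            specs = default_specs(cohort.schema)
        return cls(
            adm, specs=specs, n_dims=n_dims, n_neighbors=n_neighbors,
            anchor_feature=anchor_feature, schema_hash=schema_hash(cohort.schema),
        )

    def fit(self, max_alternations: int = 50, tol: float = 1e-6, rank_tol: float = 1e-12):
        grams, specs = build_kernels(self.X, self.feature_names, self.specs)
        M = len(grams)
        n = self.X.shape[0]
        S_mean = sum(grams) / M
        W = knn_affinity(S_mean, self.n_neighbors)
        D_diag = W.sum(axis=1)
        L_sparse = sparse.diags(D_diag) - sparse.csr_matrix(W)

        def lap(X):
            return L_sparse @ X

        # degree form deflated against the constant vector: constants have
        # zero norm under it, which removes the trivial graph mode from the
        # optimisation space altogether
        d_tot = float(D_diag.sum())

        def dp(X):
            return D_diag[:, None] * X - np.outer(D_diag, D_diag @ X) / d_tot

        # Fixed sample-space dictionary: the significant eigenvectors of the
        # mean kernel, whitened under the uniform-mix degree form.  Both
        # alternating steps optimise in this same fixed, well-conditioned
        # space, which keeps their objectives consistent (the alternation is
        # then monotone by construction) and excludes the numerical
        # nullspace of the kernels, where spurious zero-cost directions
        # would otherwise live.
        lam0, V0 = np.linalg.eigh(S_mean)
        keep0 = lam0 > rank_tol * max(lam0[-1], 0.0)
        basis0 = V0[:, keep0]
        Phi_u = basis0 * lam0[keep0]  # = S_mean @ basis0
        Dred_u = Phi_u.T @ dp(Phi_u)
        s, Q = np.linalg.eigh(0.5 * (Dred_u + Dred_u.T))
        keep_w = s > 1e-10 * max(s[-1], 0.0)
        if keep_w.sum() <= self.n_dims:
            raise ValidationError("kernel rank too low for the requested n_dims")
        basis = basis0 @ (Q[:, keep_w] / np.sqrt(s[keep_w]))
        G_list = [K @ basis for K in grams]

        beta = np.full(M, 1.0 / M)
        objective_path = []
        converged = False
        C = eigvals = None
        prev = None
        prev_beta = beta
        for _ in range(max_alternations):
            H = sum(b * Gm for b, Gm in zip(beta, G_list))
            new_eigvals, new_C = _eigen_step(H, lap, dp, self.n_dims)
            F = float(np.sum(new_eigvals))
            if prev is not None and F > prev * (1.0 + tol) + tol * 1e-12:
                # numerically shifted minimum; keep the best iterate
                beta = prev_beta
                converged = True
                break
            eigvals, C = new_eigvals, new_C
            objective_path.append(F)
            if prev is not None and np.abs(prev - F) <= tol * max(np.abs(prev), 1e-12):
                converged = True
                break
            prev = F
            prev_beta = beta
            if M == 1:
                converged = True
                break
            Nq, Dq = _beta_objective_terms(G_list, C, lap, dp)
            new_beta, _ = _beta_step(beta, Nq, Dq)
            if np.allclose(new_beta, beta, atol=1e-12):
                converged = True
                break
            beta = new_beta
        if not converged:
            warnings.warn(
                "MKL embedding did not converge within max_alternations; returning best iterate",
                RuntimeWarning,
            )

        A = basis @ C
        K_beta = sum(b * K for b, K in zip(beta, grams))
        Y = K_beta @ A
        # gauge fix: the deflated degree form is blind to constant shifts,
        # so centre each dimension to zero degree-weighted mean
        center = (D_diag / D_diag.sum()) @ Y
        Y = Y - center

        # Sign convention: orient each dimension so its correlation with the
        # anchor feature is non-negative (makes trajectory direction stable).
        if self.anchor_feature in self.feature_names:
            anchor = self.X[:, self.feature_names.index(self.anchor_feature)]
            if np.std(anchor) > 0:
                for p in range(self.n_dims):
                    if np.std(Y[:, p]) > 0 and np.corrcoef(anchor, Y[:, p])[0, 1] < 0:
                        A[:, p] = -A[:, p]
                        Y[:, p] = -Y[:, p]
                        center[p] = -center[p]

        return MKLEmbeddingResults(
            model=self,
            specs=specs,
            kernel_weights=beta,
            coefficients=A,
            eigenvalues=eigvals,
            embedding=Y,
            objective_path=np.asarray(objective_path),
            converged=converged,
            affinity=W,
            center=center,
        )


class MKLEmbeddingResults:
    """Fitted MKL embedding: kernel weights, projections and diagnostics."""

    def __init__(self, model, specs, kernel_weights, coefficients, eigenvalues,
                 embedding, objective_path, converged, affinity=None, center=None):
        self.model = model
        self.specs = specs
        self.kernel_weights_ = np.asarray(kernel_weights, dtype=float)
        self.coefficients_ = np.asarray(coefficients, dtype=float)
        self.center_ = (
            np.zeros(self.coefficients_.shape[1]) if center is None
            else np.asarray(center, dtype=float)
        )
        self.eigenvalues_ = np.asarray(eigenvalues, dtype=float)
        self.embedding_ = np.asarray(embedding, dtype=float)
        self.objective_path_ = np.asarray(objective_path, dtype=float)
        self.converged_ = bool(converged)
        self.affinity_ = affinity

    @property
    def n_dims(self) -> int:
        return self.model.n_dims

    @property
    def subject_ids(self) -> list:
        return self.model.subject_ids

    def embedding_frame(self) -> pd.DataFrame:
        cols = [f"dim{p + 1}" for p in range(self.n_dims)]
        return pd.DataFrame(self.embedding_, index=self.model.subject_ids, columns=cols)

    def project(self, X) -> np.ndarray:
        """Out-of-sample coordinates for complete state vectors (rows)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.model.feature_names):
            raise ValidationError(
                f"expected {len(self.model.feature_names)} features, got {X.shape[1]}"
            )
        if np.isnan(X).any():
            raise ValidationError("state vector contains missing entries; propagate/impute first")
        Kq = None
        for b, spec in zip(self.kernel_weights_, self.specs):
            if b == 0.0:
                continue
            Km = evaluate_kernel(spec, self.model.X, self.model.feature_names, X)
            Kq = b * Km if Kq is None else Kq + b * Km
        return Kq.T @ self.coefficients_ - self.center_

    def project_point(self, state: SubjectState) -> EmbeddedPoint:
        coords = self.project(state.values[None, :])[0]
        return EmbeddedPoint(state.subject_id, state.t, coords)

    def project_trajectory(self, states: list[SubjectState]) -> Trajectory:
        """One embedded point per follow-up, same time stamps."""
        if not states:
            raise ValidationError("cannot project an empty state sequence")
        times = np.array([s.t for s in states], dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError("subject states must be strictly time-ordered")
        mat = np.vstack([s.values for s in states])
        coords = self.project(mat)
        return Trajectory(states[0].subject_id, times, coords)

    def summary(self) -> str:
        lines = []
        lines.append("Multiple-kernel-learning embedding")
        lines.append("=" * 50)
        lines.append(f"training samples     : {self.model.X.shape[0]}")
        lines.append(f"features / kernels   : {self.model.X.shape[1]} / {len(self.specs)}")
        lines.append(f"embedding dimensions : {self.n_dims}")
        lines.append(f"kNN affinity (k)     : {self.model.n_neighbors}")
        lines.append(f"alternations         : {len(self.objective_path_)}"
                     f" (converged: {self.converged_})")
        lines.append(f"final objective      : {self.objective_path_[-1]:.6g}")
        lines.append("")
        lines.append("eigenvalues: " + ", ".join(f"{v:.4g}" for v in self.eigenvalues_))
        lines.append("")
        lines.append(f"{'kernel':<24}{'family':<12}{'bandwidth':>12}{'weight':>10}")
        lines.append("-" * 58)
        order = np.argsort(-self.kernel_weights_)
        for m in order:
            spec = self.specs[m]
            bw = f"{spec.bandwidth:.4g}" if spec.bandwidth is not None else "-"
            lines.append(
                f"{'+'.join(spec.features):<24}{spec.family:<12}{bw:>12}"
                f"{self.kernel_weights_[m]:>10.4f}"
            )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, path):
        """Write a single npz-compatible archive with reproducible bytes.

        Members are written with a fixed zip timestamp so that identical
        fits produce byte-identical archives.
        """
        import zipfile
        from numpy.lib import format as npformat

        config = {
            "feature_names": self.model.feature_names,
            "subject_ids": self.model.subject_ids,
            "n_dims": self.model.n_dims,
            "n_neighbors": self.model.n_neighbors,
            "anchor_feature": self.model.anchor_feature,
            "schema_hash": self.model.schema_hash,
            "converged": self.converged_,
            "specs": [
                {"features": list(s.features), "family": s.family, "bandwidth": s.bandwidth}
                for s in self.specs
            ],
        }
        members = {
            "X": self.model.X,
            "A": self.coefficients_,
            "beta": self.kernel_weights_,
            "eigenvalues": self.eigenvalues_,
            "embedding": self.embedding_,
            "objective_path": self.objective_path_,
            "center": self.center_,
            "config": np.frombuffer(json.dumps(config).encode(), dtype=np.uint8),
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name, arr in members.items():
                buf = _io.BytesIO()
                npformat.write_array(buf, np.asanyarray(arr), allow_pickle=False)
                info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path, expected_schema_hash: str | None = None) -> "MKLEmbeddingResults":
        with np.load(path) as z:
            config = json.loads(bytes(z["config"].tobytes()).decode())
            if expected_schema_hash is not None and config["schema_hash"] != expected_schema_hash:
                raise ValidationError(
                    "model archive schema hash does not match the provided schema"
                )
            specs = [
                KernelSpec(features=tuple(d["features"]), family=d["family"],
                           bandwidth=d["bandwidth"])
                for d in config["specs"]
            ]
            model = MKLEmbedding(
                z["X"], feature_names=config["feature_names"], specs=specs,
                n_dims=config["n_dims"], n_neighbors=config["n_neighbors"],
                anchor_feature=config["anchor_feature"],
                subject_ids=config["subject_ids"], schema_hash=config["schema_hash"],
            )
            return cls(
                model=model, specs=specs, kernel_weights=z["beta"], coefficients=z["A"],
                eigenvalues=z["eigenvalues"], embedding=z["embedding"],
                objective_path=z["objective_path"], converged=config["converged"],
                center=z["center"] if "center" in z.files else None,
            )

    def plot_embedding(self, color=None, dims=(0, 1), ax=None, **scatter_kw):
        """Scatter of the training embedding in two chosen dimensions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(
            self.embedding_[:, dims[0]], self.embedding_[:, dims[1]], c=color,
            s=scatter_kw.pop("s", 12), **scatter_kw,
        )
        ax.set_xlabel(f"dimension {dims[0] + 1}")
        ax.set_ylabel(f"dimension {dims[1] + 1}")
        if color is not None:
            plt.colorbar(sc, ax=ax)
        return ax


def schema_hash(schema) -> str:
    """Stable hash of a feature schema, used to guard model archives."""
    payload = json.dumps(schema.to_dicts(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
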