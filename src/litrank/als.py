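"""Implicit-feedback alternating-least-squares matrix factorization.

The interaction matrix is modelled in the implicit-feedback collaborative
filtering formulation (Hu, Koren & Volinsky): every cell carries a binary
preference p_ij = 1[counts_ij > 0] and a confidence c_ij = 1 + alpha *
counts_ij, and the factors W (agents × k) and H (k × themes) minimize

    sum_ij c_ij (p_ij - W_i . H_j)^2 + lambda (||W||^2 + ||H||^2)

over ALL cells of the matrix, zeros included at unit confidence.  The fit
alternates exact ridge solves: each row of W given H, then each column of
H given W, for a fixed number of full sweeps.  Because each half-step is
an exact minimization of the joint objective in one block of variables,
the objective is non-increasing across sweeps.

The reconstructed surface X2 = W . H scores every ordered gene pair; the
entry X2[a, b] is the model's consistency score for the directed relation
a -> b, whether or not that relation was observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import json

import numpy as np
import scipy.sparse as sp

from .relations import InteractionMatrix

__all__ = ["ALSConfig", "ImplicitALS", "ALSResults", "fit_implicit_als", "objective"]


@dataclass(frozen=True)
class ALSConfig:
    """Hyperparameters of the implicit-ALS factorization.

    Parameters
    ----------
    rank
        Number of latent factors k.  Default 20.
    iterations
        Number of full alternating sweeps (one W update + one H update).
        Default 20.
    lam
        L2 regularization weight lambda; strictly positive keeps every
        ridge system positive definite.  Default 0.1.
    alpha
        Confidence slope: c_ij = 1 + alpha * counts_ij.  Default 0.1.
    seed
        Seed for the factor initialization.
    init_scale
        Magnitude of the uniform random initial factors; a small start
        keeps the first ridge solves well conditioned.
    use_counts
        If True (default) article counts feed the confidence weights; if
        False the matrix is binarized first, so every observed cell gets
        confidence 1 + alpha.
    """

    rank: int = 20
    iterations: int = 20
    lam: float = 0.1
    alpha: float = 0.1
    seed: int = 0
    init_scale: float = 0.01
    use_counts: bool = True

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        if self.iterations < 1:
            raise ValueError("iterations must be a positive integer")
        if self.lam < 0 or self.alpha < 0:
            raise ValueError("lam and alpha must be non-negative")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def _confidence_counts(matrix: InteractionMatrix, config: ALSConfig) -> sp.csr_matrix:
    """Counts that enter the confidence weights (raw or binarized)."""
    return matrix.counts if config.use_counts else matrix.binary


class ImplicitALS:
    """Implicit-feedback ALS model over a gene-gene interaction matrix.

    Examples
    --------
    >>> from litrank.relations import RelationTriple, build_matrix
    >>> m = build_matrix([RelationTriple("BTK", "Regulation", "PLCG2", 4)])
    >>> results = ImplicitALS(m, rank=1, iterations=5).fit(seed=0)
    >>> results.score("BTK", "PLCG2") > results.score("PLCG2", "BTK")
    True
    """

    def __init__(
        self,
        matrix: InteractionMatrix,
        rank: int = 20,
        iterations: int = 20,
        lam: float = 0.1,
        alpha: float = 0.1,
        init_scale: float = 0.01,
        use_counts: bool = True,
    ):
        config = ALSConfig(
            rank=rank,
            iterations=iterations,
            lam=lam,
            alpha=alpha,
            init_scale=init_scale,
            use_counts=use_counts,
        )
        if matrix.counts.nnz == 0 and lam == 0:
            raise ValueError("all-zero matrix with lam=0 is degenerate")
        if config.rank > min(matrix.shape):
            raise ValueError(
                f"rank {config.rank} exceeds matrix dimension {min(matrix.shape)}"
            )
        self.matrix = matrix
        self.config = config

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "ImplicitALS":
        """Build the model from an (agent, relation, theme, count) frame."""
        from .relations import RelationTriple, build_matrix

        triples = [
            RelationTriple(str(r.agent), str(getattr(r, "relation", "Association")),
                           str(r.theme), int(r.count))
            for r in df.itertuples(index=False)
        ]
        return cls(build_matrix(triples), **kwargs)

    # -- solver ----------------------------------------------------------

    def _init_factors(self, seed: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        m, n = self.matrix.shape
        k, s = self.config.rank, self.config.init_scale
        W = rng.uniform(0.0, s, size=(m, k))
        H = rng.uniform(0.0, s, size=(k, n))
        return W, H

    @staticmethod
    def _half_step(
        C: sp.csr_matrix, F: np.ndarray, lam: float
    ) -> np.ndarray:
        """Solve every ridge system for one side of the factorization.

        For each row u of the (counts-as-confidence) matrix ``C``, the
        exact minimizer of the objective in that row's factor is

            (F^T Cu F + lam I)^-1 F^T Cu p_u

        where Cu = diag(1 + alpha*counts_u) and p_u is the binary
        preference row.  Since Cu - I is zero outside the row's nonzeros,
        F^T Cu F = F^T F + F_nz^T diag(alpha*counts_nz) F_nz, which keeps
        each solve O(nnz_u * k^2 + k^3).  ``C.data`` must already hold
        alpha * counts.
        """
        n, k = F.shape
        FtF = F.T @ F
        eye = lam * np.eye(k)
        out = np.empty((C.shape[0], k))
        indptr, indices, data = C.indptr, C.indices, C.data
        for u in range(C.shape[0]):
            lo, hi = indptr[u], indptr[u + 1]
            idx = indices[lo:hi]
            ac = data[lo:hi]  # alpha * counts on this row's nonzeros
            Fnz = F[idx]
            A = FtF + (Fnz * ac[:, None]).T @ Fnz + eye
            # p_u is 1 on nonzeros: rhs = F^T (1 + alpha*counts) over them
            b = Fnz.T @ (1.0 + ac)
            out[u] = np.linalg.solve(A, b)
        return out

    def fit(self, seed: int | None = None) -> "ALSResults":
        """Run the alternating sweeps and return the fitted factors.

        Deterministic given the seed: identical (matrix, config, seed)
        give bitwise-identical factors on one platform.
        """
        config = self.config if seed is None else replace(self.config, seed=seed)
        W, H = self._init_factors(config.seed)
        counts = _confidence_counts(self.matrix, config)
        Ca = counts.astype(np.float64).tocsr()
        Ca.data = config.alpha * Ca.data
        CaT = Ca.T.tocsr()

        trajectory: list[float] = []
        for it in range(config.iterations):
            W = self._half_step(Ca, H.T, config.lam)
            H = self._half_step(CaT, W, config.lam).T
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
                raise FloatingPointError(
                    f"non-finite factors at iteration {it + 1}"
                )
            trajectory.append(objective(self.matrix, W, H, config))
        return ALSResults(self, W, H, config, trajectory)


def objective(
    matrix: InteractionMatrix,
    W: np.ndarray,
    H: np.ndarray,
    config: ALSConfig,
) -> float:
    """Confidence-weighted squared error plus L2 penalty, over all cells.

    Computed without materializing W.H: the unit-confidence zero-target
    background contributes ||W H||_F^2 = tr((W^T W)(H H^T)), and each
    nonzero cell replaces its background term with c (1 - wh)^2.
    """
    m, n = matrix.shape
    if W.shape != (m, config.rank) or H.shape != (config.rank, n):
        raise ValueError(
            f"factor shapes {W.shape}, {H.shape} do not conform to "
            f"({m}, {config.rank}), ({config.rank}, {n})"
        )
    counts = _confidence_counts(matrix, config).tocoo()
    total = float(np.trace((W.T @ W) @ (H @ H.T)))
    if counts.nnz:
        wh = np.einsum("ij,ij->i", W[counts.row], H.T[counts.col])
        c = 1.0 + config.alpha * counts.data
        total += float(np.sum(c * (1.0 - wh) ** 2 - wh**2))
    total += config.lam * (float(np.sum(W**2)) + float(np.sum(H**2)))
    return total


class ALSResults:
    """Fitted factor matrices and everything that hangs off them.

    Attributes
    ----------
    W : ndarray of shape (n_genes, rank)
        Agent-side latent factors.
    H : ndarray of shape (rank, n_genes)
        Theme-side latent factors.
    loss_trajectory : list of float
        Objective value after each full sweep; non-increasing.
    """

    def __init__(
        self,
        model: ImplicitALS,
        W: np.ndarray,
        H: np.ndarray,
        config: ALSConfig,
        loss_trajectory: list[float],
    ):
        self.model = model
        self.matrix = model.matrix
        self.W = W
        self.H = H
        self.config = config
        self.loss_trajectory = loss_trajectory

    def score(self, agent: str, theme: str) -> float:
        """Consistency score W_agent . H_theme for the relation agent->theme."""
        i = self.matrix.index.row(agent)
        j = self.matrix.index.col(theme)
        return float(self.W[i] @ self.H[:, j])

    def score_matrix(self) -> np.ndarray:
        """The full reconstructed surface X2 = W . H (dense)."""
        return self.W @ self.H

    def score_downstream(self, target: str) -> np.ndarray:
        """Scores X2[target, :] for every theme."""
        return self.W[self.matrix.index.row(target)] @ self.H

    def score_upstream(self, target: str) -> np.ndarray:
        """Scores X2[:, target] for every agent."""
        return self.W @ self.H[:, self.matrix.index.col(target)]

    def rank_genes(self, target: str, direction: str = "downstream", **kwargs):
        """Rank all other genes for a directed relation to ``target``.

        Thin convenience wrapper; see :func:`litrank.ranking.rank_from_results`.
        """
        from .ranking import rank_from_results

        return rank_from_results(self, target, direction, **kwargs)

    def objective(self) -> float:
        return objective(self.matrix, self.W, self.H, self.config)

    def summary(self) -> str:
        """Plain-text fit summary."""
        m, n = self.matrix.shape
        lines = [
            "Implicit-feedback ALS factorization",
            "=" * 44,
            f"genes (agents x themes):  {m} x {n}",
            f"nonzero relation cells:   {self.matrix.counts.nnz}",
            f"rank (latent factors):    {self.config.rank}",
            f"iterations:               {self.config.iterations}",
            f"lambda (regularization):  {self.config.lam}",
            f"alpha (confidence slope): {self.config.alpha}",
            f"confidence source:        {'article counts' if self.config.use_counts else 'binary'}",
            f"seed:                     {self.config.seed}",
            f"initial objective:        {self.loss_trajectory[0]:.6g}",
            f"final objective:          {self.loss_trajectory[-1]:.6g}",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Text container: JSON header line, then row-major factor values."""
        header = {
            "shape": list(self.matrix.shape),
            "rank": self.config.rank,
            "symbols": self.matrix.index.symbols,
            "config": self.config.__dict__,
            "loss_trajectory": self.loss_trajectory,
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, self.W.reshape(1, -1))
            np.savetxt(fh, self.H.reshape(1, -1))

    @staticmethod
    def load(path, matrix: InteractionMatrix) -> "ALSResults":
        with open(path) as fh:
            header = json.loads(fh.readline())
            W = np.array(fh.readline().split(), dtype=float)
            H = np.array(fh.readline().split(), dtype=float)
        m, n = header["shape"]
        k = header["rank"]
        if header["symbols"] != matrix.index.symbols:
            raise ValueError("saved factors index a different gene universe")
        config = ALSConfig(**header["config"])
        model = ImplicitALS(
            matrix,
            rank=config.rank,
            iterations=config.iterations,
            lam=config.lam,
            alpha=config.alpha,
            init_scale=config.init_scale,
            use_counts=config.use_counts,
        )
        return ALSResults(
            model,
            W.reshape(m, k),
            H.reshape(k, n),
            config,
            list(header["loss_trajectory"]),
        )


def fit_implicit_als(matrix: InteractionMatrix, config: ALSConfig) -> ALSResults:
    """Functional entry point mirroring ``ImplicitALS(...).fit()``."""
    model = ImplicitALS(
        matrix,
        rank=config.rank,
        iterations=config.iterations,
        lam=config.lam,
        alpha=config.alpha,
        init_scale=config.init_scale,
        use_counts=config.use_counts,
    )
    return model.fit(seed=config.seed)
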