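"""Model/Results interface for fitting ELCA to a hypergraph.

`ELCAModel` is constructed from data plus the cluster counts (G, K);
``fit()`` runs the restarted ECM algorithm and returns an `ELCAResults`
carrying the estimates, posterior cluster memberships, BIC and a printable
``summary()``.  This mirrors the model/results split used by statsmodels:
the model object is immutable data + design, the results object owns the
estimates and diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _em
from ._em import FitConfig, FitResult, JointResponsibilities
from .data import IncidenceMatrix
from .likelihood import log_likelihood
from .params import ELCAParams, n_parameters
from .selection import bic as bic_formula

__all__ = ["ELCAModel", "ELCAResults"]


class ELCAModel:
    """Extended latent class analysis of a binary incidence matrix.

    Parameters
    ----------
    incidence : IncidenceMatrix or array-like of shape (N, M)
        Vertex-by-hyperedge binary data.
    n_primary : int
        Number of primary clusters G (membership profiles phi).
    n_additional : int, default 1
        Number of additional size clusters K; ``K = 1`` is exactly the
        standard latent class analysis model.
    """

    def __init__(self, incidence, n_primary: int, n_additional: int = 1):
        if not isinstance(incidence, IncidenceMatrix):
            incidence = IncidenceMatrix(np.asarray(incidence))
        if n_primary < 1 or n_additional < 1:
            raise ValueError("cluster counts must be >= 1")
        self.data = incidence
        self.n_primary = int(n_primary)
        self.n_additional = int(n_additional)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, n_primary: int, n_additional: int = 1
    ) -> "ELCAModel":
        """Build from a hyperedge-by-vertex DataFrame (rows = hyperedges).

        Column labels become vertex names and the index hyperedge ids; the
        frame is transposed into the internal vertex-by-hyperedge layout.
        """
        x = frame.to_numpy()
        inc = IncidenceMatrix(
            x.T,
            vertex_names=[str(c) for c in frame.columns],
            hyperedge_ids=[str(i) for i in frame.index],
        )
        return cls(inc, n_primary, n_additional)

    @property
    def n_vertices(self) -> int:
        return self.data.n_vertices

    @property
    def n_hyperedges(self) -> int:
        return self.data.effective_n_hyperedges

    def loglike(self, params: ELCAParams) -> float:
        """Observed-data log-likelihood at the given parameters."""
        return log_likelihood(self.data, params)

    def fit(
        self,
        n_restarts: int = 10,
        max_iterations: int = 1000,
        tolerance: float = 1e-8,
        mm_inner_iterations: int = 2,
        seed: int = 0,
        param_floor: float = 1e-6,
        start_params: ELCAParams | None = None,
    ) -> "ELCAResults":
        """Fit by restarted ECM with MM inner steps; returns results."""
        config = FitConfig(
            n_restarts=n_restarts,
            max_iterations=max_iterations,
            tolerance=tolerance,
            mm_inner_iterations=mm_inner_iterations,
            seed=seed,
            param_floor=param_floor,
        )
        raw = _em.fit(
            self.data, self.n_primary, self.n_additional, config, init=start_params
        )
        return ELCAResults(self, raw, config)


class ELCAResults:
    """Estimates, posteriors and diagnostics of a fitted ELCA model."""

    def __init__(self, model: ELCAModel, raw: FitResult, config: FitConfig):
        self.model = model
        self._raw = raw
        self.config = config

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> ELCAParams:
        return self._raw.params

    @property
    def llf(self) -> float:
        """Final observed-data log-likelihood."""
        return self._raw.loglik

    @property
    def llf_trace(self) -> list[float]:
        return self._raw.loglik_trace

    @property
    def bic(self) -> float:
        return self._raw.bic

    @property
    def df_model(self) -> int:
        return n_parameters(
            self.model.n_primary, self.model.n_additional, self.model.n_vertices
        )

    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def n_iterations(self) -> int:
        return self._raw.n_iterations

    @property
    def restart_logliks(self) -> list[float]:
        return self._raw.restart_logliks

    @property
    def responsibilities(self) -> JointResponsibilities:
        return self._raw.responsibilities

    # -- posteriors --------------------------------------------------------
    @property
    def primary_posterior(self) -> np.ndarray:
        """M x G posterior membership of the primary clusters."""
        return self.responsibilities.primary_marginal()

    @property
    def additional_posterior(self) -> np.ndarray:
        """M x K posterior membership of the additional (size) clusters."""
        return self.responsibilities.additional_marginal()

    def predict_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Hard (primary, additional) labels, 1-based."""
        return (
            self.primary_posterior.argmax(axis=1) + 1,
            self.additional_posterior.argmax(axis=1) + 1,
        )

    def posterior_frame(self) -> pd.DataFrame:
        """Per-hyperedge posteriors: joint (g, k) columns then marginals."""
        G, K = self.model.n_primary, self.model.n_additional
        M = self.responsibilities.n_hyperedges
        ids = self.model.data.hyperedge_ids or [f"e{j + 1}" for j in range(M)]
        cols = {}
        flat = self.responsibilities.z.reshape(M, G * K)
        for g in range(G):
            for k in range(K):
                cols[f"joint_g{g + 1}_k{k + 1}"] = flat[:, g * K + k]
        p1 = self.primary_posterior
        for g in range(G):
            cols[f"primary_g{g + 1}"] = p1[:, g]
        p2 = self.additional_posterior
        for k in range(K):
            cols[f"additional_k{k + 1}"] = p2[:, k]
        return pd.DataFrame(cols, index=pd.Index(ids, name="hyperedge_id"))

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit."""
        theta = self.params
        m = self.model
        vnames = m.data.vertex_names or [f"v{i + 1}" for i in range(m.n_vertices)]
        phi = pd.DataFrame(
            theta.phi,
            index=vnames,
            columns=[f"cluster {g + 1}" for g in range(theta.G)],
        )
        lines = [
            "Extended Latent Class Analysis results",
            "=" * 54,
            f"vertices (N):        {m.n_vertices}",
            f"hyperedges (M):      {m.n_hyperedges}",
            f"primary clusters G:  {m.n_primary}",
            f"additional K:        {m.n_additional}",
            f"free parameters:     {self.df_model}",
            f"log-likelihood:      {self.llf:.4f}",
            f"BIC:                 {self.bic:.4f}",
            f"converged:           {self.converged} ({self.n_iterations} iterations)",
            "-" * 54,
            "pi  (primary weights):    " + np.array2string(theta.pi, precision=3),
            "tau (additional weights): " + np.array2string(theta.tau, precision=3),
            "a   (size multipliers):   " + np.array2string(theta.a, precision=3),
            "-" * 54,
            "phi (vertex membership probabilities by primary cluster):",
            phi.round(3).to_string(),
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        """Serialize parameters, trace, BIC and marginal posteriors."""
        doc = {
            "params": self.params.to_dict(),
            "loglik_trace": [float(v) for v in self.llf_trace],
            "loglik": float(self.llf),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "restart_logliks": [float(v) for v in self.restart_logliks],
            "primary_posterior": self.primary_posterior.tolist(),
            "additional_posterior": self.additional_posterior.tolist(),
        }
        Path(path).write_text(json.dumps(doc) + "\n")

    def _check_bic(self) -> float:
        return bic_formula(
            self.llf,
            self.model.n_primary,
            self.model.n_additional,
            self.model.n_vertices,
            self.model.n_hyperedges,
        )
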