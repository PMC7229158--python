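"""Model/Results interface for burst-kinetics inference.

``BurstingModel`` holds one condition's filtered count vector and exposes
the log-likelihood/posterior; ``fit()`` runs the Metropolis-Hastings
sampler and returns ``BurstingResults`` carrying the MAP estimate, 95%
credible intervals, derived burst kinetics and convergence diagnostics,
with a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mcmc
from .data import CountData
from .stats import DEFAULT_MAX_COUNT
from .zinb import BurstKinetics, ZINBParams, statistical_to_kinetics

__all__ = ["BurstingModel", "BurstingResults"]


class BurstingModel:
    """Zero-inflated negative binomial model of single-cell mRNA counts.

    Parameters
    ----------
    counts : array-like of int or CountData
        Per-cell mRNA copy numbers for a single condition.
    max_count : int
        Cells above this count are treated as artefacts and excluded
        (default 150).
    condition : str, optional
        Label carried through to the results.
    """

    def __init__(self, counts, max_count: int = DEFAULT_MAX_COUNT, condition: str | None = None):
        if isinstance(counts, CountData):
            conds = counts.conditions
            if condition is None:
                if len(conds) != 1:
                    raise ValueError(
                        "CountData has multiple conditions; pass condition="
                    )
                condition = conds[0]
            arr = counts.counts(condition)
        else:
            arr = np.asarray(counts, dtype=np.int64)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        self.condition = condition or "cond"
        self.max_count = max_count
        self.n_cells_total = int(arr.size)
        self.endog = arr[arr <= max_count]
        self.n_cells_filtered = self.n_cells_total - int(self.endog.size)
        if self.endog.size == 0:
            raise ValueError("no cells left after filtering")

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, condition: str | None = None, max_count: int = DEFAULT_MAX_COUNT
    ) -> "BurstingModel":
        data = CountData(frame=frame)
        if condition is not None:
            mask = (data.frame["condition"] == condition).to_numpy()
            data = data.subset(mask)
        return cls(data, max_count=max_count, condition=condition)

    # -- probability surface -------------------------------------------------

    def loglike(self, params: ZINBParams) -> float:
        return mcmc.log_likelihood(self.endog, params)

    def logprior(self, params: ZINBParams, settings: mcmc.MCMCSettings | None = None) -> float:
        return mcmc.log_prior(params, settings)

    def logposterior(self, params: ZINBParams, settings: mcmc.MCMCSettings | None = None) -> float:
        return mcmc.log_posterior(self.endog, params, settings)

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        settings: mcmc.MCMCSettings | None = None,
        level: float = 0.95,
        **kwargs,
    ) -> "BurstingResults":
        """Run the MCMC and package the posterior.

        Keyword arguments (``n_samples``, ``burn_in``, ``thin``, ``seed``,
        ``proposal_scale``, ``hastings_correction``, ...) override fields
        of ``settings``.
        """
        if settings is None:
            settings = mcmc.MCMCSettings(**kwargs)
        elif kwargs:
            from dataclasses import replace

            settings = replace(settings, **kwargs)
        chain = mcmc.run_mcmc(self.endog, settings)
        return BurstingResults(self, chain, level=level)


class BurstingResults:
    """Posterior summary of a fitted :class:`BurstingModel`."""

    def __init__(self, model: BurstingModel, chain: mcmc.PosteriorChain, level: float = 0.95):
        self.model = model
        self.chain = chain
        self.level = level
        self.params: ZINBParams = mcmc.map_estimate(chain)
        self.kinetics: BurstKinetics = statistical_to_kinetics(self.params)

    def conf_int(self, level: float | None = None) -> dict[str, tuple[float, float]]:
        """Equal-tailed credible intervals for omega, r, p."""
        return mcmc.credible_intervals(self.chain, level or self.level)

    def kinetics_conf_int(self, level: float | None = None) -> dict[str, tuple[float, float]]:
        """Credible intervals for burst frequency, burst size and omega."""
        return mcmc.kinetics_intervals(self.chain, level or self.level)

    def diagnostics(self) -> mcmc.ConvergenceReport:
        return mcmc.convergence_report(self.chain)

    def resume(self, n_additional: int, seed: int | None = None) -> "BurstingResults":
        """Continue sampling from the chain's final state."""
        chain = mcmc.resume_mcmc(self.chain, self.model.endog, n_additional, seed)
        return BurstingResults(self.model, chain, level=self.level)

    def chain_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omega": self.chain.omega,
                "r": self.chain.r,
                "p": self.chain.p,
                "log_posterior": self.chain.log_posteriors,
            }
        )

    def to_dict(self) -> dict:
        ci = self.conf_int()
        kci = self.kinetics_conf_int()
        rep = self.diagnostics() if len(self.chain) >= 200 else None
        out = {
            "condition": self.model.condition,
            "n_cells_used": int(self.model.endog.size),
            "n_cells_filtered": self.model.n_cells_filtered,
            "map": {"omega": self.params.omega, "r": self.params.r, "p": self.params.p},
            "credible_intervals": {k: list(v) for k, v in ci.items()},
            "kinetics": {
                "burst_frequency": self.kinetics.burst_frequency,
                "burst_size": self.kinetics.burst_size,
                "omega": self.kinetics.omega,
            },
            "kinetics_intervals": {k: list(v) for k, v in kci.items()},
            "acceptance_rate": self.chain.acceptance_rate,
            "n_retained": len(self.chain),
            "data_digest": self.chain.data_digest,
        }
        if rep is not None:
            out["diagnostics"] = {
                "ess": rep.ess,
                "split_rhat": rep.split_rhat,
                "flags": rep.flags,
            }
        return out

    def summary(self) -> str:
        ci = self.conf_int()
        kci = self.kinetics_conf_int()
        lines = [
            "Bursting model fit (zero-inflated negative binomial, MH MCMC)",
            "=" * 62,
            f"condition: {self.model.condition}",
            f"cells used: {self.model.endog.size} "
            f"(filtered out: {self.model.n_cells_filtered}, "
            f"count cap: {self.model.max_count})",
            f"retained samples: {len(self.chain)}   "
            f"acceptance rate: {self.chain.acceptance_rate:.3f}",
            "",
            f"{'parameter':>16} {'MAP':>10} {'{:.0%} CI low'.format(self.level):>12} "
            f"{'CI high':>10}",
        ]
        rows = [
            ("omega", self.params.omega, *ci["omega"]),
            ("r", self.params.r, *ci["r"]),
            ("p", self.params.p, *ci["p"]),
            ("burst_frequency", self.kinetics.burst_frequency, *kci["burst_frequency"]),
            ("burst_size", self.kinetics.burst_size, *kci["burst_size"]),
        ]
        for name, val, lo, hi in rows:
            lines.append(f"{name:>16} {val:>10.4g} {lo:>12.4g} {hi:>10.4g}")
        if self.chain.warnings:
            lines.append("")
            lines.extend(f"warning: {w}" for w in self.chain.warnings)
        return "\n".join(lines)
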