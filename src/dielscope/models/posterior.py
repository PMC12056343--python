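"""Posterior containers, derived quantities and convergence diagnostics.

All inference follows the credible-interval rule: an effect is supported
when its central 95% CrI excludes zero.  No p-values are computed anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PosteriorSummary",
    "repeatability",
    "habitat_contrasts",
    "convergence_diagnostics",
]


def _rhat_ess(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={k: v for k, v in draws.items()})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = [
        {
            "parameter": k,
            "rhat": float(rhat[k].values),
            "ess_bulk": float(ess[k].values),
        }
        for k in draws
    ]
    return pd.DataFrame(rows)


@dataclass
class PosteriorSummary:
    """Draws and metadata from one fitted hierarchical model.

    ``draws`` maps scalar parameter names to arrays of shape
    (chains, draws); ``beta_draws`` (if present) has shape
    (chains, kept_draws, p) aligned with ``colnames``.
    """

    draws: dict[str, np.ndarray]
    beta_draws: Optional[np.ndarray] = None
    colnames: list[str] = field(default_factory=list)
    species_levels: list[str] = field(default_factory=list)
    season_levels: list[str] = field(default_factory=list)
    response: str = ""
    model: str = ""
    converged: bool = True
    failure: str = ""
    meta: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """All chains of a scalar parameter concatenated."""
        return self.draws[name].reshape(-1)

    def median_ci(self, name: str) -> tuple[float, float, float]:
        x = self.stacked(name)
        return (
            float(np.median(x)),
            float(np.quantile(x, 0.025)),
            float(np.quantile(x, 0.975)),
        )

    def summary(self) -> pd.DataFrame:
        diag = _rhat_ess(self.draws)
        rows = []
        for name in self.draws:
            med, lo, hi = self.median_ci(name)
            rows.append({"parameter": name, "median": med, "q2.5": lo, "q97.5": hi})
        out = pd.DataFrame(rows).merge(diag, on="parameter")
        return out

    def beta_stacked(self) -> np.ndarray:
        """Location-parameter draws flattened to (total_draws, p)."""
        if self.beta_draws is None:
            raise ValueError("this posterior carries no location-parameter draws")
        c, d, p = self.beta_draws.shape
        return self.beta_draws.reshape(c * d, p)


def repeatability(posterior: PosteriorSummary, habitat: str) -> dict:
    """Habitat-specific repeatability R = sigma_B^2 / (sigma_B^2 + sigma_W^2).

    Computed per posterior draw from the habitat's between-individual and
    within-individual SDs; site and date variance are excluded from the
    denominator.  Returns the draws and their median and central 95% CrI.
    """
    sb = posterior.stacked(f"sigma_B_{habitat}")
    sw = posterior.stacked(f"sigma_W_{habitat}")
    r = sb**2 / (sb**2 + sw**2)
    return {
        "habitat": habitat,
        "draws": r,
        "median": float(np.median(r)),
        "q2.5": float(np.quantile(r, 0.025)),
        "q97.5": float(np.quantile(r, 0.975)),
    }


def _coef_index(posterior: PosteriorSummary, name: str) -> Optional[int]:
    try:
        return posterior.colnames.index(name)
    except ValueError:
        return None


def habitat_contrasts(posterior: PosteriorSummary, by: str = "species") -> pd.DataFrame:
    """Urban-minus-forest marginal contrasts from the location draws.

    ``by="species"``: the habitat effect at each species, averaged over the
    season levels in the model.  ``by="season"``: the habitat effect in each
    season, averaged over species (equal weights).  The evidence flag is
    true when the central 95% CrI excludes zero.
    """
    B = posterior.beta_stacked()
    i_hab = _coef_index(posterior, "habitat_urban")
    if i_hab is None:
        raise ValueError("model has no habitat term; cannot form habitat contrasts")
    base = B[:, i_hab]

    def sp_term(s: str) -> np.ndarray:
        i = _coef_index(posterior, f"habitat_urban:species_{s}")
        return B[:, i] if i is not None else np.zeros(B.shape[0])

    def sn_term(t: str) -> np.ndarray:
        i = _coef_index(posterior, f"habitat_urban:season_{t}")
        return B[:, i] if i is not None else np.zeros(B.shape[0])

    seasons = posterior.season_levels or [""]
    species = posterior.species_levels
    season_avg = np.mean([sn_term(t) for t in seasons], axis=0)
    species_avg = np.mean([sp_term(s) for s in species], axis=0)

    rows = []
    if by == "species":
        for s in species:
            c = base + sp_term(s) + season_avg
            rows.append(_contrast_row("species", s, c))
    elif by == "season":
        for t in seasons:
            c = base + species_avg + sn_term(t)
            rows.append(_contrast_row("season", t, c))
    else:
        raise ValueError(f"unknown contrast grouping {by!r}")
    return pd.DataFrame(rows)


def _contrast_row(kind: str, level: str, draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "by": kind,
        "level": level,
        "median": float(np.median(draws)),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "evidence": bool(lo > 0 or hi < 0),
    }


def convergence_diagnostics(
    posterior: PosteriorSummary, max_rhat: float = 1.01
) -> pd.DataFrame:
    """R-hat and bulk effective sample size for every scalar parameter.

    With a single chain the split-R-hat is still computed but flagged as a
    limited diagnostic.  Degenerate (identical) chains raise a warning.
    """
    first = next(iter(posterior.draws.values()))
    if first.shape[0] < 2:
        warnings.warn("only one chain: R-hat diagnostics are limited", stacklevel=2)
    for name, d in posterior.draws.items():
        if d.shape[0] >= 2 and np.allclose(d[0], d[1]):
            warnings.warn(
                f"chains for {name!r} are identical; R-hat is degenerate", stacklevel=2
            )
            break
    out = _rhat_ess(posterior.draws)
    out["passed"] = out["rhat"] < max_rhat
    return out
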