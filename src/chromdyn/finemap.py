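"""Wakefield approximate Bayes factors and 99% credible SNP sets.

For each SNP with estimated log odds ratio beta and variance V = se^2, the
approximate Bayes factor in favour of association under a N(0, omega)
effect prior is

    ABF = sqrt(V / (V + omega)) * exp(omega * beta^2 / (2 V (V + omega))),

with omega = 0.04 by default. Posterior probabilities of causality are the
ABFs normalised over the locus; the credible set is the minimal ABF-ranked
prefix whose cumulative posterior attains the level (default 0.99).
Computation is carried in log space so GWAS-scale Z values cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["approx_bayes_factor", "log_abf", "credible_set", "CredibleSet"]

DEFAULT_OMEGA = 0.04
DEFAULT_LEVEL = 0.99
_LEVEL_SLACK = 1e-9  # float-rounding slack so exact ties attain the level


def log_abf(beta, V, omega: float = DEFAULT_OMEGA):
    """Natural log of the Wakefield approximate Bayes factor."""
    beta = np.asarray(beta, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return 0.5 * np.log(V / (V + omega)) + omega * beta**2 / (2.0 * V * (V + omega))


def approx_bayes_factor(beta: float, V: float, omega: float = DEFAULT_OMEGA) -> float:
    """Wakefield ABF; may overflow to inf only for astronomically large beta^2/V."""
    return float(np.exp(log_abf(beta, V, omega)))


@dataclass
class CredibleSet:
    """Ranked per-locus fine-mapping result.

    ``table`` is sorted by ABF descending (ties broken by position then
    rsid) with columns ``abf``, ``posterior``, ``cum_posterior``,
    ``in_set``; ``members`` is the list of rsids in the credible set.
    """

    locus_id: str
    level: float
    omega: float
    table: pd.DataFrame

    @property
    def members(self) -> list:
        return self.table.loc[self.table["in_set"], "rsid"].tolist()

    @property
    def size(self) -> int:
        return int(self.table["in_set"].sum())


def credible_set(
    stats: pd.DataFrame,
    level: float = DEFAULT_LEVEL,
    omega: float = DEFAULT_OMEGA,
    locus_id: str = "locus",
) -> CredibleSet:
    """Construct the credible set for one locus.

    ``stats`` needs columns ``rsid``, ``beta`` and either ``se`` or ``V``;
    ``pos`` is used for deterministic tie-breaking when present.
    """
    if len(stats) == 0:
        raise ValueError("empty locus")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    df = stats.copy()
    V = df["V"].to_numpy(float) if "V" in df else df["se"].to_numpy(float) ** 2
    la = log_abf(df["beta"].to_numpy(float), V, omega)
    with np.errstate(over="ignore"):  # abf may print as inf; posteriors use logs
        df["abf"] = np.exp(la)
    df["posterior"] = np.exp(la - logsumexp(la))
    pos = df["pos"] if "pos" in df else pd.Series(np.arange(len(df)), index=df.index)
    df = (
        df.assign(_la=la, _pos=pos.to_numpy())
        .sort_values(["_la", "_pos", "rsid"], ascending=[False, True, True], kind="mergesort")
        .drop(columns=["_la", "_pos"])
        .reset_index(drop=True)
    )
    df["cum_posterior"] = df["posterior"].cumsum()
    reached = df["cum_posterior"] >= level - _LEVEL_SLACK
    cutoff = int(np.argmax(reached.to_numpy())) if reached.any() else len(df) - 1
    df["in_set"] = np.arange(len(df)) <= cutoff
    return CredibleSet(locus_id=locus_id, level=level, omega=omega, table=df)
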