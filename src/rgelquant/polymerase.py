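"""Replicative-polymerase contributions to nuclear genome synthesis.

Steric-gate polymerase variants (Pol α-L868M, δ-L612M, ϵ-M644G) incorporate
rNMPs at known in-vitro frequencies F (rNMP per dNMP). In an RNase-H2-null
background, the excess genomic rNMPs of a variant strain over the all-WT-Pol
strain, ΔN = N_polx − N_base, is proportional to (DNA synthesized by that
polymerase) × F. Dividing each ΔN by its F and normalizing therefore yields
each polymerase's percentage share of genome synthesis:

    share_x = (ΔN_x / F_x) / Σ_y (ΔN_y / F_y) × 100.

A lower incorporation propensity (Pol δ-L612M, 1/300) up-weights its ΔN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_INCORPORATION_FREQUENCIES",
    "PolContributionInput",
    "PolContributionResult",
    "pol_contributions",
]

#: In-vitro rNMP incorporation frequencies (rNMP per dNMP) of the
#: rNTP-permissive variants: α-L868M 1/40, δ-L612M 1/300, ϵ-M644G 1/100.
DEFAULT_INCORPORATION_FREQUENCIES: Mapping[str, float] = MappingProxyType(
    {"alpha": 1.0 / 40.0, "delta": 1.0 / 300.0, "epsilon": 1.0 / 100.0})


@dataclass
class PolContributionInput:
    """rNMP totals and incorporation frequencies for one condition.

    ``n_base``: total genomic rNMPs of the RNase-H2-null strain with all-WT
    polymerases. ``n_pol``: totals of the matching variant strains, keyed by
    polymerase name. ``f``: incorporation frequencies on the same keys.
    """

    n_base: float
    n_pol: Mapping[str, float]
    f: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INCORPORATION_FREQUENCIES))
    sem_base: float | None = None
    sem_pol: Mapping[str, float] | None = None


@dataclass
class PolContributionResult:
    """Per-polymerase synthesis shares and the δ:ϵ comparison."""

    delta_n: dict
    weighted: dict                 # ΔN / F
    percent: dict                  # % of genome synthesis, sums to 100
    ratio_delta_over_epsilon: float | None
    percent_sem: dict | None = None

    def to_dict(self) -> dict:
        out = {"delta_N": self.delta_n, "weighted": self.weighted,
               "percent": self.percent,
               "ratio_delta_over_epsilon": self.ratio_delta_over_epsilon}
        if self.percent_sem is not None:
            out["percent_sem"] = self.percent_sem
        return out


def pol_contributions(inputs: PolContributionInput) -> PolContributionResult:
    """Compute percentage synthesis shares from strain rNMP totals.

    Requires every polymerase in ``n_pol`` to have a frequency; a variant
    strain with fewer rNMPs than the base strain is rejected by name (it
    signals inconsistent inputs, e.g. lanes from different gels).
    """
    if not inputs.n_pol:
        raise ValueError("no polymerase totals supplied")
    missing = sorted(set(inputs.n_pol) - set(inputs.f))
    if missing:
        raise ValueError(f"missing incorporation frequency for: {', '.join(missing)}")
    delta_n: dict[str, float] = {}
    weighted: dict[str, float] = {}
    for pol, n in inputs.n_pol.items():
        dn = float(n) - float(inputs.n_base)
        if dn < 0:
            raise ValueError(
                f"polymerase {pol!r}: variant-strain total {n:g} below base total "
                f"{inputs.n_base:g} (negative ΔN)")
        freq = float(inputs.f[pol])
        if freq <= 0:
            raise ValueError(f"polymerase {pol!r}: incorporation frequency must be positive")
        delta_n[pol] = dn
        weighted[pol] = dn / freq
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("all ΔN are zero; shares undefined")
    percent = {pol: 100.0 * w / total for pol, w in weighted.items()}
    ratio = None
    if "delta" in weighted and "epsilon" in weighted and weighted["epsilon"] > 0:
        ratio = weighted["delta"] / weighted["epsilon"]

    percent_sem = None
    if inputs.sem_pol is not None and inputs.sem_base is not None:
        percent_sem = _propagate_sem(inputs, weighted, total)
    return PolContributionResult(delta_n=delta_n, weighted=weighted, percent=percent,
                                 ratio_delta_over_epsilon=ratio, percent_sem=percent_sem)


def _propagate_sem(inputs: PolContributionInput, weighted: dict, total: float) -> dict:
    """First-order propagation of the strain-total SEMs into the percents."""
    pols = list(weighted)
    var_dn = {p: float(inputs.sem_pol.get(p, 0.0)) ** 2 + float(inputs.sem_base) ** 2
              for p in pols}
    out = {}
    for p in pols:
        grads = []
        variances = []
        for q in pols:
            w_q = weighted[q]
            # d(percent_p)/d(ΔN_q) with weighted_q = ΔN_q / F_q
            if q == p:
                g = 100.0 * (total - w_q) / total ** 2 / float(inputs.f[q])
            else:
                g = -100.0 * weighted[p] / total ** 2 / float(inputs.f[q])
            grads.append(g)
            variances.append(var_dn[q])
        out[p] = float(np.sqrt(np.sum(np.square(grads) * np.array(variances))))
    return out
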